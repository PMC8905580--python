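# Methods

This note documents the models, parameter choices and numerical decisions
behind `pepagg`, and what the synthetic generators do and do not emulate.

## NMR concentration-series statistics

**Model.** A ¹H spectrum of a partially aggregated peptide is treated as the
sum of a sharp component from NMR-visible material (monomers and small,
fast-tumbling oligomers) and signal lost or broadened beyond detection from
large aggregates.  For a region integral `Int_C` at concentration *C*,
normalized to the lowest concentration *C*min of the series:

* `NAI = Int_C / Int_Cmin`
* `SI = (I_max / Int_C) / (I_max,Cmin / Int_Cmin)`
* `CNAI = (Int_C / C) / (Int_Cmin / C_min) = NAI · (C_min / C)`

`CNAI` is computed from `NAI` so the identity holds exactly in floating
point.  All three are kept in one small formula layer
(`pepagg.nmr.stats`, top of file) so an alternative normalization can be
swapped in one place.  `SI` is emitted both normalized (`si`) and raw
(`si_raw = I_max/Int_C`), since either convention is in use; for a
Lorentzian, `I_max/Area = 2/(π·FWHM)`, so SI is inversely proportional to
line width within one lineshape family.

**Processing assumptions.** Spectra are assumed phase- and baseline-corrected
upstream; an optional linear baseline (straight line through the region's
endpoint intensities) can be subtracted at integration time but is off by
default.  Integration is the trapezoid rule on the native grid — on grids of
a few thousand points this agrees with a dense-grid quadrature to well below
1 % for Lorentzian lines, because the composite trapezoid error is governed
by the derivative mismatch at the region ends, which is negligible out in
the tails.  Region truncation (a finite region never captures the full
Lorentzian area) cancels exactly in NAI/SI/CNAI because every sample in a
series shares the lineshape.

**Referencing.** The ppm axis is rigidly shifted so the tallest point inside
a search window lands on a target shift (default 0.7 ppm, the well-separated
leucine/nor-leucine methyl signal).  Ties between equally tall points break
toward the lowest ppm (the rightmost peak in display order) —
deterministic, and matching the convention of referencing to the rightmost
resonance of the group.

**Onset flag.** The aggregation onset is the lowest concentration whose CNAI
is below a threshold (default 0.8) with every higher concentration also
below.  If that already happens at the second point of the series *and*
CNAI is declining from the very first point, the onset is reported as
`below-range`: aggregation is substantial at the bottom of the studied range
and its onset cannot be located within it.  The 0.8 default is a pragmatic
choice — published analyses flag aggregation qualitatively — and is exposed
as a parameter everywhere.

**Coexisting broad class.** Some peptides populate monomers, intermediately
sized aggregates (distinct broad peaks) and invisible large aggregates at
once.  The detector scales the low-concentration spectrum by the
concentration ratio, subtracts on the high-concentration grid, smooths with
an 11-point moving mean and flags maximal intervals where the residual
exceeds 5× its median absolute deviation for at least 0.05 ppm, with
exclusion regions (e.g. solvent) masked.  The window/threshold/width values
are implementation defaults (the phenomenon is identified by inspection in
practice) and are all parameters.  Note that with a very low noise floor the
detector legitimately follows the broad component's Lorentzian tails, so
flagged intervals can be wider than the nominal peak region.

**Counterion fate.** With peptide and counterion statistics on one
concentration grid and a tolerance `tol` (default 0.2): `excluded` when the
counterion's CNAI stays within `tol` of 1 everywhere while the peptide's
falls below 1 − tol somewhere (the ion stays free in solution, its signal
growing linearly with nominal concentration); `included` when the ion's CNAI
tracks the peptide's (max |Δ| ≤ tol) while both fall below 1 − tol;
otherwise `ambiguous`.

**Time series.** Statistics are computed per time point, each time point
normalized to its own lowest-concentration record, so changes over time
appear as ΔCNAI between time points rather than being mixed into one
normalization.

## Trajectory analytics

**Containers.** A `Topology` (molecules → residues → atoms with radii and
donor/acceptor/hydrophobic flags), `Frame`s holding coordinates in nm with
an orthorhombic box, and a `Trajectory`.  Boxes are orthorhombic only;
triclinic inputs are rejected with a clear error.  The canonical fixture
format is a plain multi-frame text dialect (header
`natoms box_x box_y box_z time_ns`, then `mol residue atom x y z` per atom);
standard formats (PDB/GRO + XTC/TRR) are read through an MDAnalysis adapter
that converts Å to nm on ingest.  All distances use the minimum-image
convention.

**Aggregates.** Two molecules are in the same aggregate when *any* atom pair
lies within the contact cutoff (default 0.5 nm); no hydrogen exclusion is
applied.  Aggregates per frame are the single-linkage connected components
of the molecule contact graph (computed with scipy's sparse graph routines;
the test suite checks every tested frame against an independent brute-force
BFS).  Output ordering is deterministic (members sorted, sets ordered by
smallest member).

**Nonaggregated fraction.** Per frame, 100 × (molecules in aggregates of
size < n)/N for aggregate cutoff sizes n (2, 4, 6, 10 by convention).

**Transition networks.** Aggregates are tracked between consecutive frames
by maximal molecule-membership overlap; ties break toward the smaller
target, then the smallest member index.  A matched pair with different sizes
adds one count to the (size→size) edge; same-size persistence is recorded as
node occupancy, not as an edge, matching the usual between-size-arrow
depiction.  Occupancies count every aggregate observation, so newly
appearing aggregates enter the network even when nothing transitions into
them.

**Events and CAP.** Per molecule pair, the contact status per frame is
thresholded at the cutoff; the pair's *settled* state starts as its first
frame's status and flips only when a new status persists ≥ `debounce`
frames (default 1 = every raw transition; the persistence filter exists
because flicker at the cutoff is a sampling artifact at coarse strides).
Events per pair therefore alternate strictly; a trajectory that starts
dispersed begins with a bind event, and the conservation identity
`n_bind − n_unbind = bound(end) − bound(start)` (settled states) holds
exactly and is asserted in the tests.  CAP defaults to
`(n_bind − n_unbind)/n_bind` clipped to [0, 1] — 1 when binding is never
reversed, 0 when it always is; the alternative `n_bind/(n_bind+n_unbind)`
is selectable (`formula="ratio"`).  Both cumulative and time-windowed event
counts are available (`EventLog.windowed_counts`).

**Contact maps.** Homomeric systems only (all molecules share one residue
template; anything else raises).  For each frame and ordered molecule pair,
a residue pair contributes one contact when its minimum atom–atom distance
is within the cutoff (the aggregate cutoff, 0.5 nm, is reused by default);
counting both orderings makes the matrix symmetric, and the mean over frames
can be divided by an external reference total so maps of different species
share one scale.

**Hydrogen bonds.** Geometric criterion: donor–acceptor minimum-image
distance ≤ 0.35 nm and H–donor–acceptor angle ≤ 30°, the conventional
choice for aqueous simulations.  Donor hydrogens are identified by the
topology's `h_parent` map; donors without an attached hydrogen are skipped
with a warning and reported.  Bonds are partitioned into peptide–peptide,
peptide–water and water–water by residue name (water = {SOL, WAT, HOH,
TIP3}, configurable); intra-molecular triples are excluded.

**SASA.** Shrake–Rupley with test points on a deterministic golden-spiral
lattice (default 960 points, probe 0.14 nm), so results are reproducible bit
for bit at fixed settings.  A point on atom *i*'s probe-expanded sphere is
accessible when no neighbor's expanded sphere covers it (minimum-image).
hSASA per molecule sums atoms flagged hydrophobic — the flag is
topology-supplied, with carbons (and hydrogens on carbon) the intended
convention.  At 960 points the isolated-sphere error is ≲ 0.1 % and the
two-sphere overlap case agrees with the spherical-cap closed form to well
under 2 %.

## Synthetic generators

**NMR series.** Defaults mirror the standard study conditions: six
concentrations {0.1, 0.5, 1, 2, 5, 10} mM, a 4096-point grid over 0–10 ppm,
a methyl-like doublet at 0.72/0.76 ppm (FWHM 0.015 ppm), an acetate-like
counterion singlet at 1.80 ppm, Gaussian noise of SD 0.01 intensity units
(signal-to-noise of a few hundred at the lowest concentration, typical for
¹H series).  Sharp-peak areas scale as `visible_fraction(C) · C` with the
pseudo-phase model `visible_fraction = min(1, CAC/C)` — the simplest model
that pins the free concentration at the CAC above onset and reproduces the
observed CNAI phenomenology; alternative visibility models plug in as a
callable.  The counterion singlet scales as `C` (`excluded`) or
`visible_fraction·C` (`included`).  One master seed spawns an independent
substream per spectrum, so outputs are bit-reproducible and stable under
config edits.  The generator emulates *visibility arithmetic plus noise*
only: no chemical-shift changes with concentration, no exchange broadening,
no baseline/phase artifacts — so passing tests validate the statistics and
classifiers, not robustness to real-instrument pathologies.

**Sticky spheres.** Rigid linear bead chains (default 20 molecules × 3
beads, 0.3 nm spacing, 0.15 nm radii) diffuse in a periodic cube (default
15 nm, ≈ 10 mM at 20 molecules); clusters of k bound molecules move rigidly
with per-step displacement SD `0.25/√k` nm.  Unbound molecules within the
0.5 nm contact cutoff bind with probability `p_bind` per step (the joining
cluster is snapped to a 0.4 nm rest separation); each bond breaks with
probability `p_unbind` per step, after which the freed cluster is pushed
just beyond the cutoff (cutoff + 0.15 nm) so the unbinding is resolvable at
the frame rate — a stand-in for local escape — and a short rebind
refractory (5 steps) prevents immediate re-registration.  The simulator
records its own bind/unbind decisions and per-bond-step trial counts in the
ground truth, so the per-step unbinding hazard recovered from the counts can
be checked against the configured `p_unbind` (binomially, within standard
errors).  This is **not** a physical MD surrogate: no forces, rotations,
hydrodynamics or realistic kinetics — only known ground truth (stickiness
ranks, irreversibility limits, event algebra) for validating the analytics.

## Problem sizes and determinism

The validation experiments use 20-molecule, 300-step simulator runs and
4096-point spectra — sizes chosen so the full analytic chain (clustering,
event detection over all 190 pairs per frame, statistics) is exercised end
to end while a complete run of the suite and the acceptance script stays
fast on a laptop.  The CAP rank experiment uses p_unbind ∈ {0, 0.005, 0.02,
0.05} at p_bind = 1: levels spread across the CAP response so the configured
order is resolvable above seed noise (at much higher unbinding rates CAP
saturates at its clipped floor and levels become indistinguishable).  Every
stochastic component is driven by explicit seeds; identical seed + config
give bit-identical outputs.

## Known limitations

* Heavy Lorentzian tails make region integrals capture-fraction dependent;
  this cancels in the normalized statistics but means absolute integrals
  depend on the chosen region width.
* The coexisting-class detector reports noise-floor exceedance intervals,
  which widen with the component's tails; it locates, not deconvolves.
* The event detector defines events per molecule *pair* from contact
  geometry alone; a pair held together indirectly through a shared partner
  counts as bound.
* Contact maps require homomeric systems; heteromeric topologies are out of
  scope.
* The MDAnalysis adapter guesses elements, radii and donor/acceptor flags
  from atom names when the source format lacks them; for quantitative
  H-bond or SASA work supply a topology with explicit flags and radii.
* The toy simulator's CAP values characterize the simulator, not any real
  peptide; only orderings and limits are meaningful.
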