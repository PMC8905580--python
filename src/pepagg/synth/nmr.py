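"""Synthetic NMR concentration/time series with known ground truth.

The generator emulates what aggregation does to a 1D proton spectrum series:
above a pseudo-phase aggregation onset (the CAC), only the monomeric/small-
oligomer fraction of the peptide stays sharp and NMR-visible, so sharp-peak
areas grow as visible_fraction(C) * C instead of C.  Optionally a distinct
broad component (intermediately sized aggregates) appears in a chosen region,
and a counterion singlet either stays fully visible ("excluded": area ∝ C) or
tracks the peptide's visibility ("included": area ∝ visible_fraction(C) * C).

Peaks are Lorentzians on a fixed ppm grid; Gaussian noise is added from
per-spectrum substreams of one master seed, so outputs are bit-reproducible
and stable under config edits.  The default visibility model is the
pseudo-phase form min(1, CAC/C): below the CAC everything is visible, above
it the free concentration stays pinned at the CAC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ..nmr.io import Spectrum, write_spectrum

__all__ = [
    "NmrSeriesConfig",
    "lorentzian",
    "make_spectrum",
    "generate_nmr_series",
    "integral_noise_sd",
]

DEFAULT_CONCENTRATIONS = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
# (center ppm, relative area, FWHM ppm): a methyl-like doublet at 0.7-0.8 ppm
DEFAULT_PEAKS = ((0.72, 0.5, 0.015), (0.76, 0.5, 0.015))
DEFAULT_COUNTERION_PEAK = (1.80, 1.0, 0.012)  # acetate-like singlet


def lorentzian(x: np.ndarray, center: float, area: float,
               fwhm: float) -> np.ndarray:
    """Lorentzian with given total area; height at center = 2*area/(pi*FWHM)."""
    hw = fwhm / 2.0
    return area / np.pi * hw / ((x - center) ** 2 + hw * hw)


@dataclass
class NmrSeriesConfig:
    """Study conditions for one synthetic concentration/time series.

    ``cac`` (mM) sets the default pseudo-phase visibility model
    min(1, cac/C); ``visible_fraction_model`` overrides it with any map
    C -> [0, 1].  ``aggregate_component`` is (ppm_lo, ppm_hi, fwhm,
    area_fraction): a group of broad peaks spread over the region whose
    total area is area_fraction * (1 - visible_fraction) * C.
    """

    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    time_points: Sequence[float] = (48.0,)
    cac: float | None = None
    visible_fraction_model: Callable[[float], float] | None = None
    peak_set: Sequence[tuple[float, float, float]] = DEFAULT_PEAKS
    aggregate_component: tuple[float, float, float, float] | None = None
    counterion_mode: str = "excluded"
    counterion_peak: tuple[float, float, float] = DEFAULT_COUNTERION_PEAK
    noise_sd: float = 0.01
    ppm_range: tuple[float, float] = (0.0, 10.0)
    n_points: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        cs = np.asarray(self.concentrations, dtype=float)
        if np.any(cs <= 0) or np.any(np.diff(cs) <= 0):
            raise ValueError("concentrations must be positive and increasing")
        if self.counterion_mode not in {"excluded", "included"}:
            raise ValueError("counterion_mode must be 'excluded' or 'included'")
        for _, _, w in self.peak_set:
            if w <= 0:
                raise ValueError("peak FWHM must be > 0")

    def visible_fraction(self, c: float) -> float:
        if self.visible_fraction_model is not None:
            v = self.visible_fraction_model(c)
        elif self.cac is not None:
            v = min(1.0, self.cac / c)
        else:
            v = 1.0
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"visible fraction {v} outside [0, 1] at C={c}")
        return v

    def grid(self) -> np.ndarray:
        lo, hi = self.ppm_range
        return np.linspace(lo, hi, self.n_points)


def make_spectrum(cfg: NmrSeriesConfig, concentration: float,
                  time_point: float, rng: np.random.Generator) -> Spectrum:
    """One synthetic spectrum at one concentration and time point."""
    x = cfg.grid()
    y = np.zeros_like(x)
    vis = cfg.visible_fraction(concentration)
    for center, rel_area, fwhm in cfg.peak_set:
        y += lorentzian(x, center, rel_area * vis * concentration, fwhm)
    if cfg.aggregate_component is not None:
        lo, hi, fwhm, frac = cfg.aggregate_component
        total = frac * (1.0 - vis) * concentration
        if total > 0:
            centers = np.linspace(lo + fwhm, hi - fwhm, 5)
            for c0 in centers:
                y += lorentzian(x, c0, total / centers.size, fwhm)
    ic, ia, iw = cfg.counterion_peak
    ion_area = ia * concentration
    if cfg.counterion_mode == "included":
        ion_area *= vis
    y += lorentzian(x, ic, ion_area, iw)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=x.size)
    return Spectrum(x, y, label=f"C{concentration:g}mM_t{time_point:g}h",
                    concentration=concentration, time_point=time_point)


def integral_noise_sd(cfg: NmrSeriesConfig,
                      region_width_ppm: float) -> float:
    """Propagated standard deviation of a trapezoidal integral over a region.

    For iid noise of SD sigma on an even grid of spacing dx, the trapezoid
    sum over n points has SD ~= sigma * dx * sqrt(n); used by tests to set
    noise-aware tolerances on NAI/CNAI.
    """
    lo, hi = cfg.ppm_range
    dx = (hi - lo) / (cfg.n_points - 1)
    n = max(2, int(round(region_width_ppm / dx)))
    return cfg.noise_sd * dx * np.sqrt(n)


def generate_nmr_series(cfg: NmrSeriesConfig, outdir: str | Path,
                        ) -> tuple[Path, Path]:
    """Write spectrum files, a series manifest and a ground-truth JSON.

    The manifest carries the standard columns plus region column pairs for
    ``leu_methyl`` (0.7-0.8 ppm) and ``counterion`` (a window around the
    counterion singlet), so it can be loaded without a separate region
    config.  Returns (manifest_path, ground_truth_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(cfg.seed)
    n_spectra = len(cfg.concentrations) * len(cfg.time_points)
    streams = master.spawn(n_spectra)
    ic, _, iw = cfg.counterion_peak
    rows = []
    truth = {"concentrations": list(map(float, cfg.concentrations)),
             "time_points": list(map(float, cfg.time_points)),
             "visible_fraction": {},
             "counterion_mode": cfg.counterion_mode,
             "cac_mM": cfg.cac, "noise_sd": cfg.noise_sd, "seed": cfg.seed}
    k = 0
    for tp in cfg.time_points:
        for c in cfg.concentrations:
            rng = np.random.default_rng(streams[k]); k += 1
            s = make_spectrum(cfg, c, tp, rng)
            fname = f"spectrum_C{c:g}mM_t{tp:g}h.txt"
            write_spectrum(s, outdir / fname)
            rows.append({
                "file": fname, "label": s.label,
                "concentration_mM": c, "time_point_h": tp,
                "leu_methyl_lo_ppm": 0.7, "leu_methyl_hi_ppm": 0.8,
                "counterion_lo_ppm": round(ic - 0.1, 6),
                "counterion_hi_ppm": round(ic + 0.1, 6),
            })
            truth["visible_fraction"][f"{c:g}"] = cfg.visible_fraction(c)
    import pandas as pd

    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return manifest, truth_path
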