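"""Aggregation statistics derived from NMR concentration series.

Signal loss and line broadening in 1D proton spectra report on peptide
self-assembly: molecules in large, slowly tumbling aggregates broaden beyond
detection, so the visible signal stops growing in proportion to the nominal
concentration.  Three dimensionless statistics condense a series, each
normalized to the lowest-concentration sample (the reference, at C_min):

* NAI  = Int_C / Int_Cmin — normalized absolute integral; linear in C for a
  fully visible species, sub-linear (or falling) once signal is lost.
* SI   = (I_max/Int_C) / (I_max,Cmin/Int_Cmin) — shape index; the
  intensity-to-integral ratio falls as peaks broaden (for a Lorentzian,
  height/area = 2/(pi*FWHM)), so SI < 1 flags broadening.
* CNAI = (Int_C/C) / (Int_Cmin/C_min) = NAI * (C_min/C) — concentration-
  normalized absolute integral; identically 1 while all material stays
  NMR-visible and falls toward 0 as signal disappears into aggregates.

The formula layer is isolated in the three small functions at the top so an
alternative normalization can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntegralRecord, SeriesTable, Spectrum

__all__ = [
    "AggregationCall",
    "nai_formula",
    "si_formula",
    "cnai_formula",
    "compute_stats",
    "compute_nai",
    "compute_si",
    "compute_cnai",
    "flag_aggregation",
    "detect_coexisting_class",
    "classify_counterion_fate",
]


# ---------------------------------------------------------------------------
# formula layer (kept together so alternates can be swapped in one place)


def nai_formula(int_c: float, int_cmin: float) -> float:
    """Normalized absolute integral: Int_C / Int_Cmin."""
    if int_cmin <= 0:
        raise ValueError(f"degenerate reference integral Int_Cmin={int_cmin}")
    return int_c / int_cmin


def cnai_formula(int_c: float, c: float, int_cmin: float, c_min: float) -> float:
    """Concentration-normalized absolute integral: (Int_C/C) / (Int_Cmin/C_min)."""
    if int_cmin <= 0:
        raise ValueError(f"degenerate reference integral Int_Cmin={int_cmin}")
    if c <= 0 or c_min <= 0:
        raise ValueError("concentrations must be positive")
    return (int_c / c) / (int_cmin / c_min)


def si_formula(i_max: float, int_c: float, i_max_ref: float, int_c_ref: float) -> float:
    """Shape index: intensity-to-integral ratio, normalized to the reference."""
    if int_c <= 0 or int_c_ref <= 0:
        raise ValueError("shape index undefined for non-positive integral")
    if i_max_ref <= 0:
        raise ValueError("shape index undefined for non-positive reference intensity")
    return (i_max / int_c) / (i_max_ref / int_c_ref)


# ---------------------------------------------------------------------------
# series-level computation


@dataclass
class AggregationCall:
    """Summary verdict for one series.

    ``onset_concentration`` is a concentration from the series (mM), or
    ``"below-range"`` when aggregation is already substantial at the bottom
    of the studied range, or ``"none"``.
    """

    onset_concentration: float | str
    coexisting_class_regions: list[tuple[float, float]] = field(default_factory=list)
    counterion_fate: str = "ambiguous"


def compute_nai(t: SeriesTable) -> pd.DataFrame:
    """NAI per (region, concentration, time point)."""
    return compute_stats(t)[
        ["region", "concentration_mM", "time_point_h", "nai"]
    ]


def compute_cnai(t: SeriesTable) -> pd.DataFrame:
    """CNAI per (region, concentration, time point)."""
    return compute_stats(t)[
        ["region", "concentration_mM", "time_point_h", "cnai"]
    ]


def compute_si(rec: IntegralRecord, ref: IntegralRecord) -> float:
    """Shape index of one record against its reference record."""
    return si_formula(rec.i_max, rec.int_c, ref.i_max, ref.int_c)


def compute_stats(t: SeriesTable) -> pd.DataFrame:
    """Tidy table of NAI, SI and CNAI for a whole series.

    Statistics are computed per time point: the reference for each (region,
    time point) group is that group's record at the lowest concentration of
    the series.  Columns: region, concentration_mM, time_point_h, int_c,
    i_max, nai, si, si_raw, cnai (``si_raw`` is the unnormalized
    intensity-to-integral ratio).
    """
    if not t.records:
        raise ValueError("empty series")
    rows = []
    c_min = t.c_min
    for region in t.region_names:
        recs = t.region_records(region)
        times = sorted({r.time_point for r in recs})
        for tp in times:
            ref = t.reference(region, tp)
            if ref.concentration != c_min:
                raise ValueError(
                    f"region {region!r} at t={tp} h lacks a record at the "
                    f"series minimum concentration {c_min} mM"
                )
            for r in recs:
                if r.time_point != tp:
                    continue
                nai_val = nai_formula(r.int_c, ref.int_c)
                rows.append({
                    "region": region,
                    "concentration_mM": r.concentration,
                    "time_point_h": r.time_point,
                    "int_c": r.int_c,
                    "i_max": r.i_max,
                    "nai": nai_val,
                    "si": si_formula(r.i_max, r.int_c, ref.i_max, ref.int_c),
                    "si_raw": r.i_max / r.int_c if r.int_c > 0 else np.nan,
                    # from NAI so the identity CNAI == NAI*(c_min/C) is
                    # exact in floating point, not just in algebra
                    "cnai": nai_val * (c_min / r.concentration),
                })
    return pd.DataFrame(rows).sort_values(
        ["region", "time_point_h", "concentration_mM"]
    ).reset_index(drop=True)


def flag_aggregation(
    stats: pd.DataFrame,
    threshold: float = 0.8,
    region: str | None = None,
    time_point: float | None = None,
) -> AggregationCall:
    """Locate the concentration where CNAI falls — and stays — below a threshold.

    ``stats`` is a :func:`compute_stats` table (or any frame with
    ``concentration_mM`` and ``cnai`` columns).  The onset is the lowest
    concentration whose CNAI is below ``threshold`` with every higher
    concentration also below; if that happens already at the second-lowest
    point and CNAI is declining from the very first point, the onset is
    reported as ``"below-range"`` (it cannot be located within the studied
    range); if CNAI never settles below the threshold the call is ``"none"``.
    """
    df = stats
    if region is not None:
        df = df[df["region"] == region]
    if time_point is not None:
        df = df[df["time_point_h"] == time_point]
    df = df.sort_values("concentration_mM")
    conc = df["concentration_mM"].to_numpy(dtype=float)
    cnai = df["cnai"].to_numpy(dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations to flag aggregation")
    below = cnai < threshold
    # smallest index i with below[i:] all True
    onset_idx: int | None = None
    for i in range(conc.size):
        if below[i:].all():
            onset_idx = i
            break
    if onset_idx is None:
        return AggregationCall("none")
    if onset_idx <= 1 and cnai[1] < cnai[0]:
        return AggregationCall("below-range")
    return AggregationCall(float(conc[onset_idx]))


def detect_coexisting_class(
    s_low: Spectrum,
    s_high: Spectrum,
    exclusion_regions: list[tuple[float, float]] | None = None,
    smooth_window: int = 11,
    k_mad: float = 5.0,
    min_width_ppm: float = 0.05,
) -> list[tuple[float, float]]:
    """Find ppm intervals where a high-C spectrum holds signal beyond scaled low-C.

    Intermediately sized aggregates can give rise to a *distinct* group of
    broad peaks that exists at high concentration but not at low.  The test:
    scale the low-concentration spectrum by the concentration ratio, subtract
    from the high-concentration one on the high-C grid, smooth the residual
    with a moving mean, and report maximal intervals where the smoothed
    residual exceeds ``k_mad`` times the residual's median absolute deviation
    for at least ``min_width_ppm``.  ``exclusion_regions`` (e.g. solvent) are
    masked out of both the threshold estimate and the report.
    """
    if not (s_low.concentration > 0 and s_high.concentration > 0):
        raise ValueError("both spectra need positive concentrations")
    ratio = s_high.concentration / s_low.concentration
    if ratio <= 0:
        raise ValueError("concentration ratio must be positive")
    # interpolate low-C onto the high-C grid (ascending order for interp)
    x = s_high.ppm[::-1]
    y_high = s_high.intensity[::-1]
    y_low = np.interp(x, s_low.ppm[::-1], s_low.intensity[::-1])
    residual = y_high - ratio * y_low

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        residual = np.convolve(residual, kernel, mode="same")

    keep = np.ones_like(x, dtype=bool)
    for lo, hi in exclusion_regions or []:
        keep &= ~((x >= lo) & (x <= hi))
    masked = residual[keep]
    if masked.size == 0:
        return []
    mad = float(np.median(np.abs(masked - np.median(masked))))
    if mad == 0:
        mad = float(np.max(np.abs(masked))) or 1.0
    thr = k_mad * mad

    above = (residual > thr) & keep
    intervals: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            lo, hi = float(x[i]), float(x[j])
            if hi - lo >= min_width_ppm:
                intervals.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return intervals


def classify_counterion_fate(
    peptide: pd.DataFrame,
    counterion: pd.DataFrame,
    tol: float = 0.2,
) -> str:
    """Decide whether the counterion co-assembles with the peptide.

    Both arguments are per-region stat tables (``concentration_mM``, ``cnai``)
    on the same concentration grid.  ``"excluded"``: the counterion stays
    fully visible (CNAI within ``tol`` of 1 everywhere) while the peptide
    loses signal (CNAI < 1 - tol somewhere) — the ion stays free in solution.
    ``"included"``: the counterion's CNAI tracks the peptide's (max absolute
    difference <= tol) while both fall below 1 - tol — the ion broadens and
    vanishes together with the peptide.  Anything else is ``"ambiguous"``.
    """
    p = peptide.sort_values("concentration_mM")
    c = counterion.sort_values("concentration_mM")
    pc = p["concentration_mM"].to_numpy(dtype=float)
    cc = c["concentration_mM"].to_numpy(dtype=float)
    if pc.shape != cc.shape or not np.allclose(pc, cc):
        raise ValueError("peptide and counterion series use different "
                         "concentration grids")
    p_cnai = p["cnai"].to_numpy(dtype=float)
    c_cnai = c["cnai"].to_numpy(dtype=float)

    peptide_aggregates = bool((p_cnai < 1 - tol).any())
    ion_visible = bool((np.abs(c_cnai - 1) <= tol).all())
    ion_aggregates = bool((c_cnai < 1 - tol).any())
    tracks = bool(np.max(np.abs(p_cnai - c_cnai)) <= tol)

    if peptide_aggregates and ion_visible:
        return "excluded"
    if peptide_aggregates and ion_aggregates and tracks:
        return "included"
    return "ambiguous"
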