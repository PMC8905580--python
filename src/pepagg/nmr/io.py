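"""Reading, referencing and integration of 1D NMR spectra.

A concentration/time series of 1D proton spectra is the raw material for the
aggregation statistics in :mod:`pepagg.nmr.stats`.  Spectra arrive as plain
two-column text (ppm, intensity) or JCAMP-DX (AFFN ``XYDATA``); a CSV manifest
ties files to concentrations, time points and named integration regions.

Spectra are assumed phase- and baseline-corrected upstream; an optional linear
baseline (region endpoints) can be subtracted at integration time but is off
by default.  Units are fixed: ppm for chemical shift, mM for concentration,
hours for elapsed time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "RegionDefinition",
    "IntegralRecord",
    "SeriesTable",
    "SpectrumParseError",
    "ReferencingError",
    "read_spectrum",
    "write_spectrum",
    "read_jcampdx",
    "reference_spectrum",
    "integrate_region",
    "load_series",
    "read_regions_config",
]

MIN_POINTS = 16


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum files (names the offending line)."""


class ReferencingError(ValueError):
    """Raised when chemical-shift referencing cannot find a usable peak."""


@dataclass
class Spectrum:
    """One 1D spectrum: a ppm axis (stored descending) with intensities.

    Parameters
    ----------
    ppm : ndarray
        Chemical shifts in ppm, strictly monotone.  Stored descending
        (conventional NMR display order); ascending input is flipped.
    intensity : ndarray
        Real intensities, arbitrary units, same length as ``ppm``.
    label : str
        Free-text sample identifier.
    concentration : float
        Molar concentration of the sample in mM.
    time_point : float
        Elapsed time since sample preparation, in hours.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    label: str = ""
    concentration: float = float("nan")
    time_point: float = 0.0

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1D arrays of equal length")
        if self.ppm.size < MIN_POINTS:
            raise ValueError(
                f"spectrum has {self.ppm.size} points; at least {MIN_POINTS} required"
            )
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending input: normalize to descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def shifted(self, delta: float) -> "Spectrum":
        """Return a copy with the whole ppm axis rigidly shifted by ``delta``."""
        return replace(self, ppm=self.ppm + delta, intensity=self.intensity.copy())


@dataclass(frozen=True)
class RegionDefinition:
    """A named ppm interval to integrate, e.g. the leucine methyl region."""

    name: str
    ppm_lo: float
    ppm_hi: float
    overlap_note: str | None = None

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(f"region {self.name!r}: require ppm_lo < ppm_hi")


@dataclass(frozen=True)
class IntegralRecord:
    """Absolute integral and peak maximum of one region in one spectrum."""

    region: RegionDefinition
    int_c: float
    i_max: float
    concentration: float
    time_point: float
    label: str = ""


@dataclass
class SeriesTable:
    """All integral records of a concentration/time series, grouped by region.

    The lowest concentration in the series (``c_min``) provides the reference
    integral and intensity against which the derived statistics (NAI, SI,
    CNAI) are normalized, per region and time point.
    """

    records: list[IntegralRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, float, float]] = set()
        for r in self.records:
            key = (r.region.name, r.concentration, r.time_point)
            if key in seen:
                raise ValueError(
                    f"duplicate record for region={key[0]!r} "
                    f"concentration={key[1]} mM time={key[2]} h"
                )
            seen.add(key)
        if self.records and self.c_min <= 0:
            raise ValueError("lowest concentration in a series must be positive")

    @property
    def c_min(self) -> float:
        return min(r.concentration for r in self.records)

    @property
    def region_names(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.region.name not in out:
                out.append(r.region.name)
        return out

    def region_records(self, name: str) -> list[IntegralRecord]:
        recs = [r for r in self.records if r.region.name == name]
        return sorted(recs, key=lambda r: (r.concentration, r.time_point))

    def reference(self, region: str, time_point: float) -> IntegralRecord:
        """The c_min record for one region at one time point."""
        recs = [r for r in self.region_records(region) if r.time_point == time_point]
        if not recs:
            raise KeyError(f"no records for region {region!r} at t={time_point} h")
        return min(recs, key=lambda r: r.concentration)


# ---------------------------------------------------------------------------
# file I/O


def read_spectrum(
    path: str | Path,
    label: str = "",
    concentration: float = float("nan"),
    time_point: float = 0.0,
) -> Spectrum:
    """Read a two-column (ppm, intensity) text spectrum.

    Whitespace- or comma-delimited; lines starting with ``#`` are comments.
    Files with extension ``.jdx``/``.dx`` are dispatched to the JCAMP-DX
    reader.  The stored axis is descending regardless of file order.
    """
    path = Path(path)
    if path.suffix.lower() in {".jdx", ".dx"}:
        return read_jcampdx(path, label=label, concentration=concentration,
                            time_point=time_point)
    ppm: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: expected 2 columns, got "
                    f"{len(parts)}: {raw.strip()!r}"
                )
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: non-numeric value in {raw.strip()!r}"
                ) from exc
    if len(ppm) < MIN_POINTS:
        raise SpectrumParseError(
            f"{path}: only {len(ppm)} data points; at least {MIN_POINTS} required"
        )
    return Spectrum(np.array(ppm), np.array(inten), label=label,
                    concentration=concentration, time_point=time_point)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text, round-trip exact.

    Values are written with :func:`repr` so that ``write -> read`` reproduces
    the binary doubles bit for bit.
    """
    with open(path, "w") as fh:
        fh.write(f"# label={s.label} concentration_mM={s.concentration} "
                 f"time_point_h={s.time_point}\n")
        fh.write("# ppm intensity\n")
        for p, y in zip(s.ppm, s.intensity):
            fh.write(f"{float(p)!r} {float(y)!r}\n")


def read_jcampdx(
    path: str | Path,
    label: str = "",
    concentration: float = float("nan"),
    time_point: float = 0.0,
) -> Spectrum:
    """Minimal JCAMP-DX reader: AFFN ``XYDATA=(X++(Y..Y))`` tables only.

    Handles ``FIRSTX``/``LASTX``/``NPOINTS``/``XFACTOR``/``YFACTOR``; the X
    value of each data line seeds the row, remaining numbers are Y values on
    an even grid.  Compressed (SQZ/DIF/DUP) encodings are not supported.
    """
    path = Path(path)
    text = path.read_text()
    ldr: dict[str, str] = {}
    for m in re.finditer(r"^##\$?([^=]+)=\s*(.*)$", text, flags=re.M):
        ldr[m.group(1).strip().upper().replace(" ", "")] = m.group(2).strip()
    xf = float(ldr.get("XFACTOR", "1"))
    yf = float(ldr.get("YFACTOR", "1"))
    m = re.search(r"^##XYDATA=.*$", text, flags=re.M)
    if m is None:
        raise SpectrumParseError(f"{path}: no ##XYDATA= table found")
    block = text[m.end():]
    end = re.search(r"^##", block, flags=re.M)
    if end:
        block = block[: end.start()]
    xs: list[float] = []
    ys: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(block.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            nums = [float(v) for v in re.split(r"[,\s]+", line)]
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path}: non-AFFN value in XYDATA line {lineno}: {line!r}"
            ) from exc
        if len(nums) < 2:
            raise SpectrumParseError(
                f"{path}: XYDATA line {lineno} has no Y values: {line!r}"
            )
        rows.append(nums)
    if not rows:
        raise SpectrumParseError(f"{path}: empty XYDATA table")
    npoints = int(ldr["NPOINTS"]) if "NPOINTS" in ldr else sum(len(r) - 1 for r in rows)
    firstx = float(ldr.get("FIRSTX", rows[0][0] * xf))
    lastx = float(ldr.get("LASTX", rows[-1][0] * xf))
    dx = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
    for row in rows:
        x0 = row[0] * xf
        for k, y in enumerate(row[1:]):
            xs.append(x0 + k * dx)
            ys.append(y * yf)
    return Spectrum(np.array(xs), np.array(ys), label=label,
                    concentration=concentration, time_point=time_point)


# ---------------------------------------------------------------------------
# referencing and integration


def reference_spectrum(
    s: Spectrum,
    search_lo: float,
    search_hi: float,
    target: float = 0.7,
) -> Spectrum:
    """Rigidly shift the ppm axis so the tallest peak in a window sits at ``target``.

    Mirrors the usual practice of referencing to a well-separated resonance
    (here, by default, the leucine/nor-leucine methyl signal set to 0.7 ppm).
    Ties between equally tall points are broken toward the lowest ppm
    (rightmost in display order).  Intensities are untouched.
    """
    if not search_lo < search_hi:
        raise ValueError("require search_lo < search_hi")
    mask = (s.ppm >= search_lo) & (s.ppm <= search_hi)
    if not mask.any():
        raise ReferencingError(
            f"search window [{search_lo}, {search_hi}] ppm is outside the axis"
        )
    window = s.intensity[mask]
    if np.all(window == 0):
        raise ReferencingError("all-zero intensity in the referencing window")
    wppm = s.ppm[mask]
    peak = window.max()
    apex = wppm[window == peak].min()  # lowest-ppm (rightmost) apex on ties
    return s.shifted(target - apex)


def integrate_region(
    s: Spectrum,
    r: RegionDefinition,
    baseline: bool = False,
) -> IntegralRecord:
    """Trapezoidal absolute integral and peak maximum of one region.

    ``int_c`` is the trapezoid-rule integral of intensity over
    ``[ppm_lo, ppm_hi]`` in positive orientation (intensity·ppm); ``i_max``
    is the maximum intensity inside the region.  With ``baseline=True`` a
    straight line through the region's endpoint intensities is subtracted
    first.
    """
    lo, hi = r.ppm_lo, r.ppm_hi
    if hi < s.ppm.min() or lo > s.ppm.max():
        raise ValueError(
            f"region {r.name!r} [{lo}, {hi}] ppm outside axis "
            f"[{s.ppm.min():g}, {s.ppm.max():g}] ppm"
        )
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    # ascending order for a positive-orientation integral
    x = s.ppm[mask][::-1]
    y = s.intensity[mask][::-1]
    if x.size < 2:
        raise ValueError(f"region {r.name!r} covers fewer than 2 grid points")
    if baseline:
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        y = y - (y[0] + slope * (x - x[0]))
    int_c = float(np.trapezoid(y, x))
    i_max = float(y.max())
    return IntegralRecord(region=r, int_c=int_c, i_max=i_max,
                          concentration=s.concentration,
                          time_point=s.time_point, label=s.label)


# ---------------------------------------------------------------------------
# series manifests

MANIFEST_COLUMNS = ("file", "label", "concentration_mM", "time_point_h")


def read_regions_config(path: str | Path) -> dict[str, RegionDefinition]:
    """Parse a key/value region config: ``name = lo_ppm hi_ppm  [# note]``."""
    regions: dict[str, RegionDefinition] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {lineno}: expected 'name = lo hi'")
            name, rest = line.split("=", 1)
            parts = rest.split()
            if len(parts) != 2:
                raise ValueError(f"{path}, line {lineno}: expected two bounds")
            regions[name.strip()] = RegionDefinition(
                name.strip(), float(parts[0]), float(parts[1])
            )
    if not regions:
        raise ValueError(f"{path}: no regions defined")
    return regions


def _regions_from_manifest(df: pd.DataFrame) -> dict[str, RegionDefinition]:
    """Infer regions from ``<name>_lo_ppm`` / ``<name>_hi_ppm`` column pairs."""
    regions: dict[str, RegionDefinition] = {}
    for col in df.columns:
        if col.endswith("_lo_ppm"):
            name = col[: -len("_lo_ppm")]
            hi_col = f"{name}_hi_ppm"
            if hi_col not in df.columns:
                raise ValueError(f"manifest column {col!r} lacks its pair {hi_col!r}")
            lo = float(df[col].iloc[0])
            hi = float(df[hi_col].iloc[0])
            regions[name] = RegionDefinition(name, lo, hi)
    return regions


def load_series(
    manifest: str | Path,
    regions: Mapping[str, RegionDefinition] | str | Path | None = None,
    reference_window: tuple[float, float] | None = None,
    reference_target: float = 0.7,
    baseline: bool = False,
) -> SeriesTable:
    """Assemble a :class:`SeriesTable` from a CSV manifest of spectrum files.

    The manifest must carry columns ``file, label, concentration_mM,
    time_point_h``.  Integration regions come from (in order of precedence)
    the ``regions`` argument (mapping or path to a key/value config file) or
    per-region ``<name>_lo_ppm``/``<name>_hi_ppm`` column pairs in the
    manifest itself.  File paths are resolved relative to the manifest.

    With ``reference_window`` given, each spectrum is chemical-shift
    referenced (tallest peak in the window moved to ``reference_target``)
    before integration.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest} lacks required columns: {missing}")
    if isinstance(regions, (str, Path)):
        regions = read_regions_config(regions)
    if regions is None:
        regions = _regions_from_manifest(df)
    if not regions:
        raise ValueError("no integration regions supplied (argument or manifest)")

    records: list[IntegralRecord] = []
    for _, row in df.iterrows():
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = manifest.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"spectrum file not found: {fpath}")
        s = read_spectrum(fpath, label=str(row["label"]),
                          concentration=float(row["concentration_mM"]),
                          time_point=float(row["time_point_h"]))
        if reference_window is not None:
            s = reference_spectrum(s, *reference_window, target=reference_target)
        for region in regions.values():
            records.append(integrate_region(s, region, baseline=baseline))
    records.sort(key=lambda r: (r.concentration, r.time_point, r.region.name))
    return SeriesTable(records)
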