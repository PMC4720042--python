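"""1D proton-NMR spectrum handling: I/O, peak alignment and spectral bucketing.

A spectrum is a uniformly sampled chemical-shift trace (ppm, descending —
the NMR display convention) with an intensity vector in arbitrary units.
Spectra are reduced to a samples x buckets matrix by integrating fixed-width
(default 0.02 ppm) chemical-shift bins between 0.2 and 9.6 ppm, dropping any
bucket that overlaps an exclusion window (residual water, known contaminant
resonances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum1D",
    "ExclusionWindow",
    "BucketTable",
    "WATER_WINDOW",
    "METHANOL_WINDOW",
    "DEFAULT_EXCLUSIONS",
    "SpectrumParseError",
    "AxisError",
    "BucketConfigurationError",
    "read_spectrum",
    "write_spectrum",
    "align_spectra",
    "bucket_spectrum",
    "build_bucket_table",
    "detrend_baseline",
]

_AXIS_RTOL = 1e-9
_EPS = 1e-9


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed; the message names the line."""


class AxisError(ValueError):
    """Chemical-shift axes are non-uniform, mismatched or inconsistent."""


class BucketConfigurationError(ValueError):
    """Bucketing parameters leave no usable buckets or are inconsistent."""


@dataclass
class Spectrum1D:
    """A uniformly sampled 1D spectrum.

    The ppm axis is stored strictly descending; ascending input is reversed
    (with intensities kept paired) on construction.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise AxisError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise AxisError(
                f"ppm ({self.ppm.size}) and intensity ({self.intensity.size}) differ in length"
            )
        if self.ppm.size < 2:
            raise AxisError("a spectrum needs at least 2 points")
        if self.ppm[0] < self.ppm[-1]:  # ascending input -> flip to display order
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        diffs = np.diff(self.ppm)
        if not np.all(diffs < 0):
            raise AxisError(f"ppm axis of {self.sample_id!r} is not strictly monotone")
        step = diffs.mean()
        if np.max(np.abs(diffs - step)) > _AXIS_RTOL * abs(step) + 1e-15:
            raise AxisError(f"ppm axis of {self.sample_id!r} is not uniform")

    @property
    def step(self) -> float:
        """Absolute ppm increment between adjacent grid points."""
        return float(abs(self.ppm[0] - self.ppm[1]))

    def copy(self) -> "Spectrum1D":
        return Spectrum1D(self.sample_id, self.ppm.copy(), self.intensity.copy(), self.group_label)


@dataclass(frozen=True)
class ExclusionWindow:
    """A [low, high] ppm interval removed from bucketing."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"exclusion window needs low < high, got [{self.low}, {self.high}]")


#: Residual-water region, highly variable under imperfect solvent suppression.
WATER_WINDOW = ExclusionWindow(4.30, 5.00)
#: Methanol singlet at 3.36 ppm (laboratory contaminant).
METHANOL_WINDOW = ExclusionWindow(3.34, 3.38)
DEFAULT_EXCLUSIONS: tuple[ExclusionWindow, ...] = (WATER_WINDOW, METHANOL_WINDOW)


@dataclass
class BucketTable:
    """Samples x bucket-integral matrix with bucket midpoints as labels."""

    sample_ids: list[str]
    bucket_midpoints: np.ndarray
    values: np.ndarray
    width: float = 0.02
    excluded_windows: tuple[ExclusionWindow, ...] = ()
    group_labels: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.bucket_midpoints = np.asarray(self.bucket_midpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), self.bucket_midpoints.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.bucket_midpoints.size} buckets"
            )
        half = self.width / 2.0
        for win in self.excluded_windows:
            lo = self.bucket_midpoints - half
            hi = self.bucket_midpoints + half
            if np.any((lo < win.high - _EPS) & (hi > win.low + _EPS)):
                raise ValueError(f"bucket midpoint inside excluded window [{win.low}, {win.high}]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_buckets(self) -> int:
        return int(self.bucket_midpoints.size)

    def subset(self, sample_ids: Sequence[str]) -> "BucketTable":
        """Row-subset (in the requested order) keeping bucket structure."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in bucket table") from None
        groups = None
        if self.group_labels is not None:
            groups = [self.group_labels[i] for i in rows]
        return BucketTable(
            list(sample_ids),
            self.bucket_midpoints.copy(),
            self.values[rows],
            self.width,
            self.excluded_windows,
            groups,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{m:.3f}" for m in self.bucket_midpoints],
        )
        df.to_csv(path, sep="\t", float_format="%.10e")

    @classmethod
    def from_tsv(cls, path: str | Path, width: float = 0.02) -> "BucketTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mids = np.array([float(c) for c in df.columns])
        return cls(list(df.index.astype(str)), mids, df.to_numpy(dtype=float), width)


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(path: str | Path, dialect: str = "two-column") -> Spectrum1D:
    """Read a 1D spectrum from disk.

    Parameters
    ----------
    path:
        File to read. The sample id is the file stem.
    dialect:
        ``"two-column"`` — whitespace- or comma-separated ppm/intensity pairs,
        ``'#'`` comments allowed; or ``"jcamp"`` — JCAMP-DX with AFFN
        ``XYDATA=(X++(Y..Y))``.
    """
    path = Path(path)
    if dialect == "two-column":
        return _read_two_column(path)
    if dialect == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_two_column(path: Path) -> Spectrum1D:
    ppm: list[float] = []
    intens: list[float] = []
    group = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if raw.lstrip().startswith("# group:"):
                group = raw.split(":", 1)[1].strip() or None
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise SpectrumParseError(f"{path.name}: line {lineno}: expected two columns")
            try:
                ppm.append(float(fields[0]))
                intens.append(float(fields[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path.name}: line {lineno}: non-numeric value"
                ) from None
    if len(ppm) < 2:
        raise SpectrumParseError(f"{path.name}: fewer than 2 data rows")
    return Spectrum1D(path.stem, np.array(ppm), np.array(intens), group)


def _read_jcamp(path: Path) -> Spectrum1D:
    """Minimal JCAMP-DX reader: AFFN XYDATA=(X++(Y..Y)) records only."""
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.split("$$", 1)[0].strip()
                if key == "XYDATA":
                    if "X++(Y..Y)" not in value.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path.name}: line {lineno}: unsupported XYDATA form {value!r}"
                        )
                    in_data = True
                elif key == "END":
                    in_data = False
                else:
                    header[key] = value
                continue
            if in_data:
                try:
                    tokens = [float(t) for t in line.replace(",", " ").split()]
                except ValueError:
                    raise SpectrumParseError(
                        f"{path.name}: line {lineno}: non-numeric value"
                    ) from None
                ys.extend(tokens[1:])  # first token is the line's X check value
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        npoints = int(float(header["NPOINTS"]))
    except KeyError as exc:
        raise SpectrumParseError(f"{path.name}: missing ##{exc.args[0]}= record") from None
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    if len(ys) != npoints:
        raise SpectrumParseError(
            f"{path.name}: NPOINTS={npoints} but {len(ys)} Y values present"
        )
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    title = header.get("TITLE", path.stem) or path.stem
    return Spectrum1D(title, x, np.asarray(ys) * yfactor)


def write_spectrum(spectrum: Spectrum1D, path: str | Path) -> None:
    """Write a spectrum as two-column text (round-trips through read_spectrum)."""
    with open(path, "w") as fh:
        fh.write(f"# sample: {spectrum.sample_id}\n")
        if spectrum.group_label is not None:
            fh.write(f"# group: {spectrum.group_label}\n")
        for p, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(p)!r} {float(y)!r}\n")


# ---------------------------------------------------------------------------
# Alignment


def align_spectra(
    spectra: Sequence[Spectrum1D],
    segment_width: float = 0.08,
    max_shift: float = 0.01,
) -> list[Spectrum1D]:
    """Segment-wise cross-correlation alignment to the median spectrum.

    Each spectrum is split into contiguous segments of about ``segment_width``
    ppm.  Every segment is shifted by an integer number of grid points
    (|shift| <= ``max_shift``) to maximise its cross-correlation with the
    point-wise median reference; the points a shift vacates are filled by
    linear interpolation from the segment edges.  Axes are unchanged.
    """
    if len(spectra) < 2:
        raise ValueError("alignment needs at least 2 spectra")
    axis = spectra[0].ppm
    for sp in spectra[1:]:
        if sp.ppm.size != axis.size or not np.allclose(sp.ppm, axis, rtol=0, atol=1e-9):
            raise AxisError(f"spectrum {sp.sample_id!r} is on a different ppm axis")
    step = spectra[0].step
    max_pts = int(np.floor(max_shift / step + _EPS))
    if max_pts < 1:
        warnings.warn("max_shift smaller than the axis step; alignment is a no-op")
        return [sp.copy() for sp in spectra]

    n = axis.size
    seg_len = max(2, int(round(segment_width / step)))
    bounds = list(range(0, n, seg_len))
    if n - bounds[-1] < max(2, seg_len // 4) and len(bounds) > 1:
        bounds.pop()  # merge a stub tail into the previous segment
    bounds.append(n)

    reference = np.median(np.vstack([sp.intensity for sp in spectra]), axis=0)
    shift_order = sorted(range(-max_pts, max_pts + 1), key=lambda s: (abs(s), s))

    out: list[Spectrum1D] = []
    for sp in spectra:
        y = sp.intensity
        padded = np.concatenate([np.full(max_pts, y[0]), y, np.full(max_pts, y[-1])])
        aligned = np.empty_like(y)
        for a, b in zip(bounds[:-1], bounds[1:]):
            ref_seg = reference[a:b]
            best_s = 0
            best_score: float | None = None
            for s in shift_order:
                cand = padded[a - s + max_pts : b - s + max_pts]
                denom = float(np.linalg.norm(cand))
                # normalised cross-correlation: an unnormalised product would
                # favour dragging a taller neighbouring peak into the segment
                score = float(cand @ ref_seg) / denom if denom > 0 else 0.0
                # shift_order prefers small |s|; require a strict improvement
                if best_score is None or score > best_score + _EPS * max(1.0, abs(best_score)):
                    best_s, best_score = s, score
            aligned[a:b] = _shift_segment(y, a, b, best_s)
        out.append(Spectrum1D(sp.sample_id, axis.copy(), aligned, sp.group_label))
    return out


def _shift_segment(y: np.ndarray, a: int, b: int, s: int) -> np.ndarray:
    """Shift y[a:b] by s points; fill the gap linearly from the segment edges."""
    seg = y[a:b]
    if s == 0 or abs(s) >= seg.size:
        return seg.copy()
    out = np.empty_like(seg)
    if s > 0:
        out[s:] = seg[:-s]
        left_edge = y[a - 1] if a > 0 else seg[0]
        out[:s] = np.linspace(left_edge, seg[0], s + 2)[1:-1]
    else:
        k = -s
        out[:-k] = seg[k:]
        right_edge = y[b] if b < y.size else seg[-1]
        out[-k:] = np.linspace(seg[-1], right_edge, k + 2)[1:-1]
    return out


# ---------------------------------------------------------------------------
# Bucketing


def _tile_edges(low: float, high: float, width: float) -> np.ndarray:
    n_buckets = int(np.floor((high - low) / width + _EPS))
    return low + width * np.arange(n_buckets + 1)


def bucket_spectrum(
    spectrum: Spectrum1D,
    low: float = 0.2,
    high: float = 9.6,
    width: float = 0.02,
    exclusions: Sequence[ExclusionWindow] = DEFAULT_EXCLUSIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a spectrum into half-open [b, b+width) buckets.

    Bucket integrals use the trapezoidal rule over the grid points that fall
    inside each bucket.  Any bucket whose interval overlaps an exclusion
    window is dropped entirely.  Returns ``(values, midpoints)`` for the
    retained buckets, midpoints ascending.
    """
    if not high > low:
        raise BucketConfigurationError(f"need high > low, got [{low}, {high}]")
    if not width > spectrum.step:
        raise BucketConfigurationError(
            f"bucket width {width} must exceed the axis step {spectrum.step:.3g}"
        )
    edges = _tile_edges(low, high, width)
    keep = np.ones(edges.size - 1, dtype=bool)
    for win in exclusions:
        keep &= ~((edges[:-1] < win.high - _EPS) & (edges[1:] > win.low + _EPS))
    if not keep.any():
        raise BucketConfigurationError("exclusion windows removed every bucket")

    x = spectrum.ppm[::-1]  # ascending for integration
    yv = spectrum.intensity[::-1]
    i0 = np.searchsorted(x, edges[:-1], side="left")
    i1 = np.searchsorted(x, edges[1:], side="left")
    values = np.zeros(edges.size - 1)
    for k in np.flatnonzero(keep):
        if i1[k] - i0[k] >= 2:
            values[k] = np.trapezoid(yv[i0[k] : i1[k]], x[i0[k] : i1[k]])
    midpoints = (edges[:-1] + edges[1:]) / 2.0
    return values[keep], midpoints[keep]


def build_bucket_table(
    spectra: Sequence[Spectrum1D],
    low: float = 0.2,
    high: float = 9.6,
    width: float = 0.02,
    exclusions: Sequence[ExclusionWindow] = DEFAULT_EXCLUSIONS,
) -> BucketTable:
    """Bucket every spectrum and stack the rows (input order preserved)."""
    if not spectra:
        raise ValueError("no spectra given")
    rows = []
    mids_ref: np.ndarray | None = None
    for sp in spectra:
        vals, mids = bucket_spectrum(sp, low, high, width, exclusions)
        if mids_ref is None:
            mids_ref = mids
        elif mids.size != mids_ref.size or not np.allclose(mids, mids_ref, atol=1e-9):
            raise AxisError(f"spectrum {sp.sample_id!r} buckets to different midpoints")
        rows.append(vals)
    return BucketTable(
        [sp.sample_id for sp in spectra],
        mids_ref,
        np.vstack(rows),
        width,
        tuple(exclusions),
        [sp.group_label for sp in spectra],
    )


def detrend_baseline(spectrum: Spectrum1D, order: int = 3) -> Spectrum1D:
    """Subtract a least-squares polynomial baseline (off by default upstream)."""
    coeffs = np.polynomial.polynomial.polyfit(spectrum.ppm, spectrum.intensity, order)
    baseline = np.polynomial.polynomial.polyval(spectrum.ppm, coeffs)
    return Spectrum1D(
        spectrum.sample_id, spectrum.ppm.copy(), spectrum.intensity - baseline, spectrum.group_label
    )
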