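"""Wide-angle scattering: Bragg spacings, peak detection and assignment.

With q the momentum transfer, Bragg's relation reads d = 2π/q.  Peaks in a
WAXS pattern of a hydrated peptide gel sit on a broad water halo, so a
rolling-minimum baseline is subtracted before detection.  Detected peaks
are grouped into lamellar harmonic families (d, d/2, d/3, …) and screened
for the ~4.7–4.8 Å inter-strand spacing characteristic of β-sheets and the
~3.7 Å intra-chain residue spacing.

Unit dialects: q may arrive in Å⁻¹ (``invA``) or nm⁻¹ (``invnm``); the
dialect must always be declared — it is never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .saxs_models import ScatteringCurve

__all__ = [
    "WAXSPeak",
    "WAXSPeakSet",
    "q_to_d",
    "d_to_q",
    "detect_peaks",
    "assign_orders",
    "classify_beta_sheet",
    "BetaSheetReport",
]

_UNIT_TO_INV_A = {"invA": 1.0, "invnm": 0.1}  # q multiplier into Å⁻¹


def _check_units(units: str) -> float:
    try:
        return _UNIT_TO_INV_A[units]
    except KeyError:
        raise ValueError(
            f"unknown q unit dialect {units!r}; use 'invA' or 'invnm'"
        ) from None


def q_to_d(q, units: str = "invA"):
    """Bragg spacing d = 2π/q in Å, for q in the declared unit dialect."""
    factor = _check_units(units)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    d = 2.0 * np.pi / (q * factor)
    return d if d.ndim else float(d)


def d_to_q(d_angstrom, units: str = "invA"):
    """Inverse of :func:`q_to_d`: q = 2π/d, returned in the declared dialect."""
    factor = _check_units(units)
    d = np.asarray(d_angstrom, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    q = 2.0 * np.pi / d / factor
    return q if q.ndim else float(q)


@dataclass(frozen=True)
class WAXSPeak:
    """One detected Bragg peak; d in Å regardless of the input dialect."""

    q: float
    d: float
    amplitude: float
    width: float
    order: int | None = None
    family: int | None = None


@dataclass(frozen=True)
class WAXSPeakSet:
    """Peaks sorted by descending d, with optional harmonic assignments."""

    peaks: tuple[WAXSPeak, ...]
    units: str = "invA"

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def d_values(self) -> np.ndarray:
        return np.array([p.d for p in self.peaks])

    def most_intense(self) -> WAXSPeak:
        if not self.peaks:
            raise ValueError("empty peak set")
        return max(self.peaks, key=lambda p: p.amplitude)


def subtract_baseline(
    pattern: ScatteringCurve, window_fraction: float = 0.05
) -> np.ndarray:
    """Rolling-minimum baseline (then smoothed), as for a broad water halo."""
    n = max(3, int(round(window_fraction * pattern.q.size)))
    base = minimum_filter1d(pattern.i, size=n, mode="nearest")
    return uniform_filter1d(base, size=n, mode="nearest")


def detect_peaks(
    pattern: ScatteringCurve,
    prominence: float = 0.05,
    min_separation: float = 0.0,
    units: str = "invA",
    baseline_window: float = 0.05,
    smooth_points: int = 5,
) -> WAXSPeakSet:
    """Detect local maxima above ``prominence`` after baseline subtraction.

    ``prominence`` is absolute, in the intensity units of the pattern; a
    light boxcar smoothing (``smooth_points``) suppresses shot-noise spikes
    before detection.  Peaks closer than ``min_separation`` (q units of the
    declared dialect) are merged keeping the taller.  An empty result is
    legal.
    """
    _check_units(units)
    if pattern.q.size < 20:
        raise ValueError("pattern too short (need >= 20 points)")
    signal = pattern.i - subtract_baseline(pattern, baseline_window)
    if smooth_points > 1:
        signal = uniform_filter1d(signal, size=smooth_points, mode="nearest")
    idx, props = find_peaks(signal, prominence=prominence, width=1)

    def apex(j: int, k: int) -> float:
        """Sub-grid peak position: least-squares parabola over the apex.

        The fit window is half the detected FWHM on each side, which
        averages the noise down instead of amplifying it as a three-point
        interpolation would.
        """
        half = max(2, int(round(props["widths"][j] / 2)))
        lo, hi = max(0, k - half), min(signal.size - 1, k + half)
        x = pattern.q[lo : hi + 1] - pattern.q[k]
        a, b, _ = np.polyfit(x, signal[lo : hi + 1], 2)
        if a >= 0:
            return float(pattern.q[k])
        vertex = -b / (2 * a)
        return float(pattern.q[k] + np.clip(vertex, x[0], x[-1]))

    peaks = sorted(
        (
            WAXSPeak(
                q=apex(j, k),
                d=q_to_d(apex(j, k), units),
                amplitude=float(signal[k]),
                width=float(props["widths"][j] * np.median(np.diff(pattern.q))),
            )
            for j, k in enumerate(idx)
        ),
        key=lambda p: p.q,
    )
    if min_separation > 0:
        merged: list[WAXSPeak] = []
        for p in peaks:
            if merged and p.q - merged[-1].q < min_separation:
                if p.amplitude > merged[-1].amplitude:
                    merged[-1] = p
            else:
                merged.append(p)
        peaks = merged
    return WAXSPeakSet(
        peaks=tuple(sorted(peaks, key=lambda p: -p.d)), units=units
    )


def assign_orders(peak_set: WAXSPeakSet, tolerance: float = 0.05) -> WAXSPeakSet:
    """Group peaks into lamellar harmonic families d₁, d₁/2, d₁/3, …

    Greedy: walking fundamentals in descending d, a peak joins the family
    when its spacing ratio d₁/d is within ``tolerance`` (absolute, on the
    ratio) of an integer n ≥ 1; each peak belongs to at most one family;
    the largest family is numbered first.  Input order is irrelevant
    (peaks are re-sorted).
    """
    if not peak_set.peaks:
        raise ValueError("need at least one peak to assign orders")
    peaks = sorted(peak_set.peaks, key=lambda p: -p.d)
    taken: set[int] = set()
    families: list[list[tuple[int, int]]] = []  # [(peak index, order), ...]
    for i, fund in enumerate(peaks):
        if i in taken:
            continue
        members = [(i, 1)]
        for j in range(i + 1, len(peaks)):
            if j in taken:
                continue
            ratio = fund.d / peaks[j].d
            n = round(ratio)
            if n >= 1 and abs(ratio - n) <= tolerance:
                members.append((j, int(n)))
        for idx, _ in members:
            taken.add(idx)
        families.append(members)
    families.sort(key=len, reverse=True)
    annotated: dict[int, WAXSPeak] = {}
    for fam_id, members in enumerate(families):
        for idx, order in members:
            annotated[idx] = replace(peaks[idx], order=order, family=fam_id)
    out = tuple(annotated[i] for i in range(len(peaks)))
    return WAXSPeakSet(peaks=tuple(sorted(out, key=lambda p: -p.d)), units=peak_set.units)


@dataclass(frozen=True)
class BetaSheetReport:
    """Outcome of the β-sheet spacing screen."""

    is_beta_sheet: bool
    strand_peak: WAXSPeak | None
    residue_peak: WAXSPeak | None  # ~3.7 Å intra-chain residue spacing


def classify_beta_sheet(
    peak_set: WAXSPeakSet,
    window_angstrom: tuple[float, float] = (4.4, 5.0),
    residue_window_angstrom: tuple[float, float] = (3.5, 3.9),
) -> BetaSheetReport:
    """Screen for the β-sheet inter-strand spacing (~4.7–4.8 Å).

    True iff some peak lies inside ``window_angstrom``; also reports the
    intra-chain residue-spacing peak (~3.7 Å) when present.
    """

    def in_window(win):
        hits = [p for p in peak_set if win[0] <= p.d <= win[1]]
        return max(hits, key=lambda p: p.amplitude) if hits else None

    strand = in_window(window_angstrom)
    residue = in_window(residue_window_angstrom)
    return BetaSheetReport(
        is_beta_sheet=strand is not None, strand_peak=strand, residue_peak=residue
    )
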