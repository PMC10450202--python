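"""Structured/disordered segmentation of a chain from its confidence profile.

A predicted model's per-residue pLDDT separates structured domains (high
confidence) from intrinsically disordered segments (low confidence).  The
profile is median-smoothed, thresholded, and cleaned with run-length rules;
structured segments are then optionally refined by bisecting them where the
PAE matrix shows two internally-rigid blocks with high mutual error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .model_io import PAEMatrix, ResidueRange, StructureModel

STRUCTURED = "structured"
DISORDERED = "disordered"

#: conventional "low confidence" pLDDT boundary used in AFDB colouring
DEFAULT_PLDDT_CUTOFF = 70.0
DEFAULT_WINDOW = 9
DEFAULT_MIN_STRUCT = 10
DEFAULT_MIN_GAP = 4
DEFAULT_SPLIT_GAIN = 5.0
DEFAULT_MIN_SUBSEGMENT = 25


@dataclass(frozen=True)
class Segment:
    """One maximal run of residues with a single structured/disordered class."""

    range: ResidueRange
    klass: Literal["structured", "disordered"]
    mean_plddt: float

    def __len__(self) -> int:
        return len(self.range)

    @property
    def structured(self) -> bool:
        return self.klass == STRUCTURED


def assert_tiling(segments: Sequence[Segment], n: int) -> None:
    """Segments must tile [1, n] without gaps or overlaps."""
    if not segments:
        raise AssertionError("no segments for a non-empty chain")
    pos = 1
    for seg in segments:
        if seg.range.start != pos:
            raise AssertionError(
                f"segment tiling broken at residue {pos} (segment starts {seg.range.start})"
            )
        pos = seg.range.end + 1
    if pos != n + 1:
        raise AssertionError(f"segments end at {pos - 1}, chain length {n}")


def smooth_plddt(values: Sequence[float], window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Running median with shrinking windows at the chain ends.

    ``window`` must be odd so the window is centred; window 1 is the
    identity.  At each end the window shrinks symmetrically so that the
    output length equals the input length and no padding value leaks in.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    if window == 1 or len(values) <= 1:
        return values.copy()
    half = window // 2
    out = median_filter(values, size=window, mode="nearest")
    # shrink the window near the ends instead of padding
    for i in range(min(half, len(values))):
        k = i  # symmetric reach available at position i
        out[i] = np.median(values[: 2 * k + 1])
        j = len(values) - 1 - i
        out[j] = np.median(values[len(values) - (2 * k + 1):])
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of equal boolean value as (start_idx, end_idx, value)."""
    runs = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            runs.append((start, i - 1, bool(mask[start])))
            start = i
    return runs


def segment_disorder(
    model: StructureModel,
    plddt_cutoff: float = DEFAULT_PLDDT_CUTOFF,
    window: int = DEFAULT_WINDOW,
    min_struct: int = DEFAULT_MIN_STRUCT,
    min_gap: int = DEFAULT_MIN_GAP,
) -> list[Segment]:
    """Classify every residue structured/disordered and return maximal segments.

    Residues whose smoothed pLDDT is >= ``plddt_cutoff`` are structured.
    Structured runs shorter than ``min_struct`` are relabelled disordered
    (short isolated elements with residual secondary-structure propensity
    are not annotated); disordered runs shorter than ``min_gap`` sandwiched
    between structured runs are absorbed into them.
    """
    if min_struct < 1 or min_gap < 0:
        raise ValueError("min_struct >= 1 and min_gap >= 0 required")
    smoothed = smooth_plddt(model.plddt, window)
    mask = smoothed >= plddt_cutoff

    # drop short structured runs
    for start, end, val in _runs(mask):
        if val and (end - start + 1) < min_struct:
            mask[start : end + 1] = False
    # absorb short interior disordered gaps
    runs = _runs(mask)
    for k, (start, end, val) in enumerate(runs):
        if (
            not val
            and 0 < k < len(runs) - 1
            and (end - start + 1) < min_gap
        ):
            mask[start : end + 1] = True

    numbers = model.residue_numbers
    segments = []
    for start, end, val in _runs(mask):
        segments.append(
            Segment(
                range=ResidueRange(int(numbers[start]), int(numbers[end])),
                klass=STRUCTURED if val else DISORDERED,
                mean_plddt=float(np.mean(model.plddt[start : end + 1])),
            )
        )
    if numbers[0] == 1:
        assert_tiling(segments, int(numbers[-1]))
    return segments


def _bisection_gain(sym: np.ndarray, lo: int, hi: int, cut: int) -> float:
    """Gain of cutting block [lo, hi) at ``cut`` (absolute matrix indices).

    Gain = median cross-block PAE minus the mean of the two intra-block
    medians; large when the two halves are internally rigid but mutually
    flexible.
    """
    def offdiag_median(m: np.ndarray) -> float:
        if m.shape[0] < 2:
            return 0.0
        return float(np.median(m[np.triu_indices_from(m, k=1)]))

    cross = sym[lo:cut, cut:hi]
    intra = 0.5 * (offdiag_median(sym[lo:cut, lo:cut]) + offdiag_median(sym[cut:hi, cut:hi]))
    return float(np.median(cross) - intra)


def refine_segments_with_pae(
    segments: Sequence[Segment],
    pae: PAEMatrix,
    min_sub: int = DEFAULT_MIN_SUBSEGMENT,
    gain: float = DEFAULT_SPLIT_GAIN,
    plddt: Sequence[float] | None = None,
) -> list[Segment]:
    """Recursively bisect structured segments at PAE change-points.

    Each structured segment is cut at the point maximising the bisection
    gain; a cut is accepted only if the gain is >= ``gain`` Angstrom and
    both halves are at least ``min_sub`` residues.  Disordered segments are
    returned untouched.  Residue i of the chain maps to matrix index i-1.
    """
    from .rigidity import symmetrize_pae

    sym = symmetrize_pae(pae)
    plddt = np.asarray(plddt, dtype=float) if plddt is not None else None

    def split(lo: int, hi: int) -> list[tuple[int, int]]:
        best_cut, best_gain = None, -np.inf
        for cut in range(lo + min_sub, hi - min_sub + 1):
            g = _bisection_gain(sym, lo, hi, cut)
            if g > best_gain:
                best_cut, best_gain = cut, g
        if best_cut is None or best_gain < gain:
            return [(lo, hi)]
        return split(lo, best_cut) + split(best_cut, hi)

    out: list[Segment] = []
    for seg in segments:
        if not seg.structured:
            out.append(seg)
            continue
        lo, hi = seg.range.start - 1, seg.range.end  # matrix index window
        for a, b in split(lo, hi):
            mean = (
                float(np.mean(plddt[a:b])) if plddt is not None else seg.mean_plddt
            )
            out.append(
                Segment(range=ResidueRange(a + 1, b), klass=STRUCTURED, mean_plddt=mean)
            )
    return out
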