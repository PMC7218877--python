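"""Reference frequency grid, per-segment rate selection and SLI resampling.

Each active segment ``W_i`` has a local event rate ``Fs_i = N_i / L_i``.
The resampling frequency ``Frs_i`` is picked from a finite arithmetic grid
``Fref = {Fs_min, Fs_min + d, ..., Fr}`` of binary-weighted length Q
(``d = (Fr - Fs_min)/(Q - 1)``), so that each grid member can be paired
with a pre-designed reference filter.  Selection uses a uniform binary
search bounded by log2(Q) comparisons.  The segment is then uniformly
resampled by simplified linear interpolation (SLI), whose per-observation
error against the underlying band-limited signal is bounded by q/2 plus
the curvature term of the linear model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import Segment

__all__ = [
    "FrefGrid",
    "SelectionResult",
    "UniformSegment",
    "build_fref",
    "select_fref",
    "sli_resample",
    "sli_resample_counted",
]


@dataclass(frozen=True)
class FrefGrid:
    """Arithmetic grid of Q admissible resampling frequencies."""

    fs_min: float
    fr: float
    q_count: int
    delta: float
    values: np.ndarray

    def __len__(self) -> int:
        return self.q_count


@dataclass(frozen=True)
class SelectionResult:
    index: int
    fref_c: float
    comparisons: int


@dataclass
class UniformSegment:
    """A uniformly resampled segment at rate ``frs_i``."""

    samples: np.ndarray
    frs_i: float
    source_index: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def nr_i(self) -> int:
        return self.samples.size


def build_fref(fs_min: float = 75.0, fr: float = 360.0, q_count: int = 16) -> FrefGrid:
    """Build the reference grid; warns when Q is not a power of two."""
    if fr <= fs_min:
        raise ValueError("fr must exceed fs_min")
    if q_count < 2:
        raise ValueError("q_count must be >= 2")
    if q_count & (q_count - 1):
        warnings.warn("q_count is not a power of two; selector still works "
                      "but the binary-weighted contract is violated", RuntimeWarning)
    delta = (fr - fs_min) / (q_count - 1)
    values = fs_min + delta * np.arange(q_count, dtype=float)
    values[-1] = fr  # exact endpoint
    return FrefGrid(fs_min=fs_min, fr=fr, q_count=q_count, delta=delta, values=values)


def select_fref(fs_i: float, grid: FrefGrid) -> SelectionResult:
    """Smallest grid frequency >= ``fs_i`` (clamped at the grid ends).

    Implemented as a uniform binary search; the number of value
    comparisons is exposed and never exceeds ceil(log2(Q)).
    """
    if fs_i <= 0:
        raise ValueError("fs_i must be positive")
    values = grid.values
    q = grid.q_count
    pos = 0
    comparisons = 0
    # uniform binary search for the first value >= fs_i; for a power-of-two
    # grid this performs exactly log2(Q) comparisons
    step = 1 << ((q - 1).bit_length() - 1)
    while step:
        j = pos + step - 1
        if j < q:
            comparisons += 1
            if values[j] < fs_i:
                pos += step
        step >>= 1
    if pos >= q:  # fs_i above the top of the grid: clamp high
        pos = q - 1
    return SelectionResult(index=pos, fref_c=float(values[pos]), comparisons=comparisons)


def _target_grid(seg: Segment, frs_i: float) -> np.ndarray:
    t = seg.events.times
    l_i = float(t[-1] - t[0])
    nr = int(math.floor(l_i * frs_i)) + 1
    return t[0] + np.arange(nr) / frs_i


def sli_resample(seg: Segment, frs_i: float) -> UniformSegment:
    """Uniformly resample a segment by linear interpolation.

    The output grid is anchored at the first event and spans the segment:
    ``Nr_i = floor(L_i * Frs_i) + 1`` samples at step ``1/Frs_i``.
    """
    if frs_i <= 0:
        raise ValueError("frs_i must be positive")
    if seg.n_i < 2:
        raise ValueError("resampling needs at least 2 events")
    t = seg.events.times
    grid = _target_grid(seg, frs_i)
    samples = np.interp(grid, t, seg.events.amplitudes)
    return UniformSegment(samples, frs_i=frs_i, source_index=seg.index, t0=float(grid[0]))


def sli_resample_counted(seg: Segment, frs_i: float) -> tuple[UniformSegment, int]:
    """Instrumented SLI: returns the segment plus the addition count.

    Each resampled observation costs one addition (the slope term is a
    binary-weighted shift in the hardware formulation and is not booked),
    so the count equals Nr_i.
    """
    if frs_i <= 0:
        raise ValueError("frs_i must be positive")
    if seg.n_i < 2:
        raise ValueError("resampling needs at least 2 events")
    t = seg.events.times
    a = seg.events.amplitudes
    grid = _target_grid(seg, frs_i)
    out = np.empty(grid.size)
    additions = 0
    k = 0
    for m, tg in enumerate(grid):
        while k + 1 < t.size - 1 and t[k + 1] <= tg:
            k += 1
        slope = (a[k + 1] - a[k]) / (t[k + 1] - t[k])
        out[m] = a[k] + slope * (tg - t[k])
        additions += 1
    return (
        UniformSegment(out, frs_i=frs_i, source_index=seg.index, t0=float(grid[0])),
        additions,
    )
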