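"""Four-level wavelet decomposition and the 45-feature sub-band statistics.

Each denoised segment is decomposed into detail bands d1..d4 and the
level-4 approximation a4 with a Daubechies filter cascade (db4 by default,
'periodization' boundary mode so the transform is orthonormal and the band
energies sum to the input energy).  Because every segment carries its own
resampling rate ``Frs_i``, the physical band split of the dyadic cascade
adapts per segment (``Frs_i/2`` halved at each level).

Nine statistics are extracted from each band:

=====  ========================================================
PS     mean squared coefficient value (average power)
MAV    mean absolute value
STD    sample standard deviation
SK     standardized third central moment (skewness)
K      standardized fourth central moment (kurtosis, non-excess)
R      MAV(band) / MAV(a4)  (mean ratio; 1 for a4 itself)
PV     maximum value
NV     minimum value
NV2    second-smallest value
=====  ========================================================

The feature vector concatenates the bands band-major in the order
d1, d2, d3, d4, a4 with the statistics in the order above: 45 values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "BANDS",
    "STATS",
    "FEATURE_NAMES",
    "SubBands",
    "FeatureVector",
    "dwt4",
    "band_stats",
    "feature_vector",
]

log = logging.getLogger(__name__)

BANDS = ("d1", "d2", "d3", "d4", "a4")
STATS = ("ps", "mav", "std", "sk", "k", "r", "pv", "nv", "nv2")
#: Canonical feature order: band-major, statistic-minor.
FEATURE_NAMES = tuple(f"{b}_{s}" for b in BANDS for s in STATS)

_MIN_LEN = 16  # level-4 dyadic cascade needs at least 2^4 samples


@dataclass
class SubBands:
    """Detail (d1..d4) and approximation (a4) coefficients of one segment."""

    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray
    a4: np.ndarray
    frs_i: float = 0.0
    wavelet: str = "db4"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"d1": self.d1, "d2": self.d2, "d3": self.d3, "d4": self.d4, "a4": self.a4}


@dataclass
class FeatureVector:
    """45 ordered sub-band statistics, optionally labeled."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(FEATURE_NAMES):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} entries")


def dwt4(x: np.ndarray, wavelet: str = "db4", mode: str = "periodization",
         frs_i: float = 0.0) -> SubBands:
    """Four-level discrete wavelet decomposition of ``x``.

    Raises on inputs too short for four dyadic levels.  Segments shorter
    than the filter support at level 4 are still decomposed (boundary
    effects accepted for short active segments); PyWavelets' advisory
    warning about that case is silenced here on purpose.
    """
    x = np.asarray(x, dtype=float)
    if x.size < _MIN_LEN:
        raise ValueError(f"need at least {_MIN_LEN} samples for a 4-level decomposition")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*boundary effects.*")
        warnings.filterwarnings("ignore", message=".*Level value.*")
        a4, d4, d3, d2, d1 = pywt.wavedec(x, wavelet, mode=mode, level=4)
    return SubBands(d1=d1, d2=d2, d3=d3, d4=d4, a4=a4, frs_i=frs_i, wavelet=wavelet)


def band_stats(band: np.ndarray, a4_ref: np.ndarray) -> np.ndarray:
    """The nine statistics of one band, in :data:`STATS` order.

    Degenerate cases: SK and K of a zero-variance band are 0; NV2 falls
    back to NV for a single-coefficient band; R is 0 (logged) when the
    reference a4 band has zero mean absolute value.
    """
    band = np.asarray(band, dtype=float)
    a4_ref = np.asarray(a4_ref, dtype=float)
    if band.size == 0:
        raise ValueError("band must be non-empty")
    ps = float(np.mean(band**2))
    mav = float(np.mean(np.abs(band)))
    std = float(band.std(ddof=1)) if band.size > 1 else 0.0
    mean = float(band.mean())
    m2 = float(np.mean((band - mean) ** 2))
    if m2 > 0:
        sk = float(np.mean((band - mean) ** 3)) / m2**1.5
        kurt = float(np.mean((band - mean) ** 4)) / m2**2
    else:
        sk = 0.0
        kurt = 0.0
    mav_a4 = float(np.mean(np.abs(a4_ref))) if a4_ref.size else 0.0
    if mav_a4 > 0:
        r = mav / mav_a4
    else:
        log.warning("a4 band has zero mean absolute value; R set to 0")
        r = 0.0
    pv = float(band.max())
    nv = float(band.min())
    nv2 = float(np.partition(band, 1)[1]) if band.size > 1 else nv
    return np.array([ps, mav, std, sk, kurt, r, pv, nv, nv2])


def feature_vector(bands: SubBands, label: str | None = None) -> FeatureVector:
    """Assemble the 45-value feature vector in canonical order."""
    a4 = bands.a4
    parts = [band_stats(bands.as_dict()[b], a4) for b in BANDS]
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature encountered")
    return FeatureVector(values=values, label=label)
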