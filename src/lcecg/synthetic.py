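"""Synthetic test signals: calibration sinusoids and five-class ECG beats.

The beat generator emulates the statistical structure the event-driven
pipeline assumes: 0.9-s single-beat windows, band-limited to [0.5, 60] Hz,
with a dominant high-slope QRS complex, low-amplitude P/T waves and
class-distinct morphology for the five arrhythmia classes N (normal),
RBBB / LBBB (right/left bundle branch block), APC (atrial premature
contraction) and PVC (premature ventricular contraction).

Each beat is a sum of Gaussian bumps (one per PQRST wave) plus additive
white Gaussian noise, band-limited afterwards.  This is a morphological
surrogate, not a physiological ECG model: template parameters live in
:data:`BEAT_TEMPLATES` and are deliberately exaggerated along the axes that
distinguish the classes clinically (QRS width, R amplitude, P presence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "DenseSignal",
    "LabeledBeatSet",
    "BeatTemplate",
    "BEAT_TEMPLATES",
    "CLASSES",
    "BEAT_DURATION",
    "DEFAULT_FS_DENSE",
    "BAND",
    "gen_sinusoid",
    "gen_beat",
    "gen_dataset",
]

#: Length of one beat window in seconds.
BEAT_DURATION = 0.9
#: Default dense ("quasi-analog") rate, 360 Hz x an upsampling factor of 400.
DEFAULT_FS_DENSE = 144_000.0
#: Band limits of the quasi-analog ECG signal, Hz.
BAND = (0.5, 60.0)
#: The five beat classes.
CLASSES = ("N", "RBBB", "LBBB", "APC", "PVC")

# Internal generation rate: the [0.5, 60] Hz band-pass is numerically
# well-posed here; the result is spline-upsampled to fs_dense.
_FS_BUILD = 1440.0


@dataclass
class DenseSignal:
    """A uniformly sampled quasi-analog signal.

    Attributes
    ----------
    samples : np.ndarray
        Amplitude series (arbitrary units, nominally mV).
    fs_dense : float
        Uniform sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs_dense: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_dense <= 0:
            raise ValueError("fs_dense must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Window length in seconds (sample count / rate)."""
        return self.samples.size / self.fs_dense

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs_dense


@dataclass
class LabeledBeatSet:
    """A shuffled, class-balanced collection of fixed-duration beats."""

    beats: list[DenseSignal]
    labels: list[str]
    seed: int
    noise_sd: float = 0.0

    def __len__(self) -> int:
        return len(self.beats)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass(frozen=True)
class BeatTemplate:
    """Per-class PQRST template.

    ``waves`` holds (name, amplitude mV, center s, std-width s) Gaussian
    bumps on the 0.9-s window with the QRS centered at 0.45 s.  The three
    scalar attributes summarize the discriminative axes and back the
    pairwise-separability contract (ratio >= 1.5 in at least one axis).
    """

    label: str
    waves: tuple[tuple[str, float, float, float], ...]
    qrs_sigma: float  # effective QRS complex width (s)
    r_amp: float      # dominant R amplitude (mV)
    p_amp: float      # P-wave amplitude (mV); 0 means absent


BEAT_TEMPLATES: dict[str, BeatTemplate] = {
    # Normal: narrow QRS, clear P, upright T.
    "N": BeatTemplate(
        "N",
        (
            ("P", 0.15, 0.270, 0.022),
            ("Q", -0.12, 0.427, 0.009),
            ("R", 1.10, 0.450, 0.012),
            ("S", -0.22, 0.472, 0.010),
            ("T", 0.32, 0.620, 0.045),
        ),
        qrs_sigma=0.012, r_amp=1.10, p_amp=0.15,
    ),
    # RBBB: widened rSR'-shaped complex with a deep slurred S.
    "RBBB": BeatTemplate(
        "RBBB",
        (
            ("P", 0.14, 0.270, 0.022),
            ("R", 0.55, 0.441, 0.011),
            ("S", -0.35, 0.490, 0.030),
            ("R'", 0.50, 0.468, 0.018),
            ("T", 0.22, 0.640, 0.050),
        ),
        qrs_sigma=0.024, r_amp=0.55, p_amp=0.14,
    ),
    # LBBB: broad monophasic R, absent Q, discordant (negative) T.
    "LBBB": BeatTemplate(
        "LBBB",
        (
            ("P", 0.13, 0.260, 0.022),
            ("R", 0.90, 0.443, 0.028),
            ("R'", 0.55, 0.487, 0.020),
            ("T", -0.30, 0.650, 0.050),
        ),
        qrs_sigma=0.028, r_amp=0.90, p_amp=0.13,
    ),
    # APC: premature, low-amplitude P close to a narrow normal QRS.
    "APC": BeatTemplate(
        "APC",
        (
            ("P", 0.08, 0.330, 0.015),
            ("Q", -0.10, 0.427, 0.009),
            ("R", 1.00, 0.450, 0.012),
            ("S", -0.20, 0.472, 0.010),
            ("T", 0.30, 0.620, 0.045),
        ),
        qrs_sigma=0.012, r_amp=1.00, p_amp=0.08,
    ),
    # PVC: no P wave, broad high-amplitude ectopic complex, inverted T.
    "PVC": BeatTemplate(
        "PVC",
        (
            ("R", 1.80, 0.450, 0.034),
            ("S", -0.50, 0.510, 0.030),
            ("T", -0.45, 0.660, 0.055),
        ),
        qrs_sigma=0.034, r_amp=1.80, p_amp=0.0,
    ),
}


def gen_sinusoid(
    fsig: float,
    amplitude: float = 1.0,
    duration: float = 1.0,
    fs_dense: float = DEFAULT_FS_DENSE,
    phase: float = 0.0,
) -> DenseSignal:
    """Generate a pure sinusoid ``amplitude * sin(2*pi*fsig*t + phase)``.

    Used as the full-scale calibration input for the level-crossing
    converter figures of merit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs_dense <= 0:
        raise ValueError("fs_dense must be positive")
    if not 0 < fsig < fs_dense / 2:
        raise ValueError("fsig must lie in (0, fs_dense/2)")
    n = int(round(duration * fs_dense))
    t = np.arange(n) / fs_dense
    return DenseSignal(amplitude * np.sin(2 * np.pi * fsig * t + phase), fs_dense)


def _band_limit(x: np.ndarray, fs: float) -> np.ndarray:
    sos = butter(4, BAND, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def gen_beat(
    label: str,
    templates: dict[str, BeatTemplate] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs_dense: float = DEFAULT_FS_DENSE,
) -> DenseSignal:
    """Generate one 0.9-s beat of class ``label``.

    The beat is built as a sum of Gaussian bumps from the class template,
    plus white Gaussian noise of standard deviation ``noise_sd`` (mV),
    band-limited to [0.5, 60] Hz.  Deterministic given ``seed``.
    """
    templates = templates if templates is not None else BEAT_TEMPLATES
    if label not in templates:
        raise ValueError(f"unknown beat class {label!r}; expected one of {sorted(templates)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if fs_dense <= 0:
        raise ValueError("fs_dense must be positive")

    tpl = templates[label]
    n_build = int(round(BEAT_DURATION * _FS_BUILD))
    t = np.arange(n_build) / _FS_BUILD
    x = np.zeros(n_build)
    for _name, amp, mu, sigma in tpl.waves:
        x += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, n_build)
    x = _band_limit(x, _FS_BUILD)

    if fs_dense == _FS_BUILD:
        return DenseSignal(x, fs_dense)
    n_out = int(round(BEAT_DURATION * fs_dense))
    t_out = np.arange(n_out) / fs_dense
    dense = CubicSpline(t, x)(np.clip(t_out, t[0], t[-1]))
    return DenseSignal(dense, fs_dense)


def gen_dataset(
    n_per_class: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    templates: dict[str, BeatTemplate] | None = None,
    fs_dense: float = DEFAULT_FS_DENSE,
) -> LabeledBeatSet:
    """Generate a balanced, deterministically shuffled beat set.

    ``n_per_class`` beats are drawn for each of the five classes; per-beat
    noise seeds and the shuffle order both derive from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    templates = templates if templates is not None else BEAT_TEMPLATES
    master = np.random.default_rng(seed)
    labels = [lab for lab in CLASSES for _ in range(n_per_class)]
    beat_seeds = master.integers(0, 2**31 - 1, size=len(labels))
    order = master.permutation(len(labels))
    beats: list[DenseSignal] = []
    shuffled: list[str] = []
    for j in order:
        lab = labels[j]
        beats.append(
            gen_beat(lab, templates=templates, noise_sd=noise_sd,
                     seed=int(beat_seeds[j]), fs_dense=fs_dense)
        )
        shuffled.append(lab)
    return LabeledBeatSet(beats=beats, labels=shuffled, seed=seed, noise_sd=noise_sd)
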