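"""Standard-format I/O: beat sets, event streams, segments, features.

Beat sets travel as CSV (one row per beat: label, then samples) with a JSON
sidecar holding the generation parameters; event streams as CSV
(beat, tick, amplitude) with a JSON header carrying the converter
parameters.  The optional MIT-BIH reader needs the ``wfdb`` package
(``pip install lcecg[wfdb]``) and locally available records.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import LCConfig, LCEventStream
from .segmentation import Segment
from .synthetic import BEAT_DURATION, DenseSignal, LabeledBeatSet

__all__ = [
    "save_beats",
    "load_beats",
    "save_events",
    "load_events",
    "save_segments",
    "MITBIH_RECORDS",
    "MITBIH_SYMBOLS",
    "read_wfdb_beats",
]

#: Record-to-class mapping of the MIT-BIH study subset.
MITBIH_RECORDS: dict[str, tuple[str, ...]] = {
    "N": ("116", "119", "209"),
    "RBBB": ("118", "124", "212"),
    "LBBB": ("109", "111", "214"),
    "APC": ("118", "200", "209"),
    "PVC": ("119", "200", "233"),
}

#: MIT-BIH annotation symbol per class.
MITBIH_SYMBOLS: dict[str, str] = {"N": "N", "RBBB": "R", "LBBB": "L", "APC": "A", "PVC": "V"}


def save_beats(path: str | Path, beatset: LabeledBeatSet, params: dict | None = None) -> None:
    """Write a beat set as CSV plus a JSON parameter sidecar."""
    path = Path(path)
    rows = []
    for beat, label in zip(beatset.beats, beatset.labels):
        rows.append([label] + beat.samples.tolist())
    n = len(beatset.beats[0]) if beatset.beats else 0
    cols = ["label"] + [f"s{i}" for i in range(n)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = {
        "seed": beatset.seed,
        "noise_sd": beatset.noise_sd,
        "fs_dense": beatset.beats[0].fs_dense if beatset.beats else None,
        "duration": BEAT_DURATION,
    }
    if params:
        meta.update(params)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_beats(path: str | Path) -> LabeledBeatSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    fs = float(meta["fs_dense"])
    beats = [DenseSignal(row[1:].to_numpy(dtype=float), fs) for _, row in df.iterrows()]
    return LabeledBeatSet(beats=beats, labels=df["label"].tolist(),
                          seed=int(meta.get("seed", 0)),
                          noise_sd=float(meta.get("noise_sd", 0.0)))


def save_events(path: str | Path, streams: list[LCEventStream],
                labels: list[str] | None = None) -> None:
    """Write one or more event streams as CSV (beat, tick, amplitude)."""
    path = Path(path)
    frames = []
    for b, st in enumerate(streams):
        df = pd.DataFrame({"beat": b, "tick": st.ticks, "amplitude": st.amplitudes})
        if labels is not None:
            df["label"] = labels[b]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    cfg = streams[0].config
    header = {
        "delta_v": [st.config.delta_v for st in streams],
        "origin": [st.origin for st in streams],
        "m_bits": cfg.m_bits,
        "f_timer": cfg.f_timer,
        "timer_bits": cfg.timer_bits,
        "q": [st.config.q for st in streams],
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))


def load_events(path: str | Path) -> tuple[list[LCEventStream], list[str] | None]:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    streams = []
    labels = [] if "label" in df.columns else None
    for b, sub in df.groupby("beat"):
        cfg = LCConfig(delta_v=header["delta_v"][int(b)], m_bits=header["m_bits"],
                       f_timer=header["f_timer"], timer_bits=header["timer_bits"])
        streams.append(LCEventStream(sub["amplitude"].to_numpy(),
                                     sub["tick"].to_numpy(dtype=np.int64),
                                     cfg, origin=header["origin"][int(b)]))
        if labels is not None:
            labels.append(sub["label"].iloc[0])
    return streams, labels


def save_segments(path: str | Path, segments: list[Segment]) -> None:
    """Serialize segments as JSON records."""
    records = [
        {
            "index": s.index,
            "n_i": s.n_i,
            "l_i": s.l_i,
            "fs_i": s.fs_i,
            "first_tick": int(s.events.ticks[0]),
            "last_tick": int(s.events.ticks[-1]),
        }
        for s in segments
    ]
    Path(path).write_text(json.dumps(records, indent=2))


def read_wfdb_beats(
    data_dir: str | Path,
    records: dict[str, tuple[str, ...]] | None = None,
    n_per_class: int | None = 300,
    window: float = BEAT_DURATION,
    offset: float = 0.5,
    channel: int = 0,
) -> LabeledBeatSet:
    """Extract labeled beat windows from local MIT-BIH records.

    ``offset`` places the annotated R sample at that fraction of the
    window (0.5 = centered).  Beats whose window falls outside the record
    and unknown annotation codes are skipped.  Requires the optional
    ``wfdb`` dependency and the record/annotation files under ``data_dir``.
    """
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "the MIT-BIH workflow needs the optional 'wfdb' package: "
            "pip install lcecg[wfdb]"
        ) from exc

    records = records if records is not None else MITBIH_RECORDS
    data_dir = Path(data_dir)
    beats: list[DenseSignal] = []
    labels: list[str] = []
    counts = {c: 0 for c in records}
    for cls, recs in records.items():
        symbol = MITBIH_SYMBOLS.get(cls)
        for rec in recs:
            sig, fields = wfdb.rdsamp(str(data_dir / rec))
            ann = wfdb.rdann(str(data_dir / rec), "atr")
            fs = float(fields["fs"])
            half_pre = int(round(window * offset * fs))
            half_post = int(round(window * (1 - offset) * fs))
            x = sig[:, channel]
            for sample, sym in zip(ann.sample, ann.symbol):
                if sym != symbol:
                    continue
                if n_per_class is not None and counts[cls] >= n_per_class:
                    break
                a, b = sample - half_pre, sample + half_post
                if a < 0 or b > x.size:
                    continue
                beats.append(DenseSignal(x[a:b].astype(float), fs))
                labels.append(cls)
                counts[cls] += 1
    if n_per_class is not None:
        short = {c: k for c, k in counts.items() if k < n_per_class}
        if short:
            import warnings
            warnings.warn(f"fewer beats than requested for classes {short}", RuntimeWarning)
    return LabeledBeatSet(beats=beats, labels=labels, seed=0)
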