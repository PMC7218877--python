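"""Activity selection: partition an event stream into active segments.

The activity selection algorithm (ASA) exploits the non-uniformity of
level-crossing sampling: during the idle baseline the converter is silent,
so a run of events whose consecutive gaps satisfy ``dt_n <= T0``
(``T0 = 1/fmin``, the Nyquist bound for the lowest signal component) marks
an active portion of the signal.  A segment is closed early when its
first-to-last duration would exceed ``Lref``; runs of fewer than two
events carry no rate information and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sampler import LCEventStream

__all__ = ["ASAConfig", "Segment", "segment", "segment_rate"]


@dataclass(frozen=True)
class ASAConfig:
    """ASA parameters: ``t0`` = 1/fmin (s), ``lref`` = max segment length (s).

    Defaults follow the ECG band (fmin = 0.5 Hz -> T0 = 2 s) and Lref = 1 s.
    """

    t0: float = 2.0
    lref: float = 1.0

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.lref <= 0:
            raise ValueError("t0 and lref must be positive")


@dataclass
class Segment:
    """An ASA-selected active portion of the event stream."""

    events: LCEventStream
    index: int

    @property
    def n_i(self) -> int:
        """Event count N_i."""
        return len(self.events)

    @property
    def l_i(self) -> float:
        """Duration L_i in seconds, first to last event."""
        t = self.events.times
        return float(t[-1] - t[0])

    @property
    def fs_i(self) -> float:
        """Local event rate Fs_i = N_i / L_i (Hz)."""
        return segment_rate(self)


def segment_rate(seg: Segment) -> float:
    """Fs_i = N_i / L_i; raises on a zero-length segment."""
    l_i = seg.l_i
    if l_i <= 0:
        raise ValueError("zero-length segment has no rate")
    return seg.n_i / l_i


def segment(events: LCEventStream, config: ASAConfig | None = None) -> list[Segment]:
    """Partition ``events`` into active segments.

    Maximal runs with all gaps ``<= t0`` form segments; a segment is closed
    before the event that would stretch it past ``lref`` (that event starts
    the next segment, so closure never drops events).  Runs shorter than
    two events are discarded.
    """
    config = config if config is not None else ASAConfig()
    times = events.times
    n = len(events)
    if n > 1 and any(times[j] <= times[j - 1] for j in range(1, n)):
        raise ValueError("event times must be strictly increasing")

    segments: list[Segment] = []

    def close(a: int, b: int) -> None:
        # events [a, b] inclusive
        if b - a + 1 >= 2:
            segments.append(Segment(events.slice(a, b + 1), index=len(segments)))

    if n == 0:
        return segments
    start = 0
    for j in range(1, n):
        gap = times[j] - times[j - 1]
        if gap > config.t0 or times[j] - times[start] > config.lref:
            close(start, j - 1)
            start = j
    close(start, n - 1)
    return segments
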