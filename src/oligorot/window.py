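"""Time-window resolution shared by the analysis modules.

The canonical analysis window is the final 500 ns of a trajectory; short
synthetic trajectories fall back to the equivalent trailing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Trailing window length used by the published analyses (ns).
DEFAULT_LAST_NS = 500.0
#: Fallback trailing fraction when the trajectory is shorter than 500 ns.
DEFAULT_LAST_FRACTION = 0.25


@dataclass(frozen=True)
class TimeWindow:
    """Half-open specification of an analysis window on a time axis (ns)."""
    start_ns: float | None = None
    end_ns: float | None = None
    last_ns: float | None = None
    last_fraction: float | None = None

    @classmethod
    def interval(cls, start_ns: float, end_ns: float) -> "TimeWindow":
        return cls(start_ns=start_ns, end_ns=end_ns)

    @classmethod
    def last(cls, ns: float) -> "TimeWindow":
        return cls(last_ns=ns)

    @classmethod
    def fraction(cls, frac: float) -> "TimeWindow":
        return cls(last_fraction=frac)

    @classmethod
    def default(cls) -> "TimeWindow":
        """Final 500 ns, or the final quarter for shorter trajectories."""
        return cls()

    def mask(self, times_ns: np.ndarray) -> np.ndarray:
        times_ns = np.asarray(times_ns, dtype=float)
        span = times_ns[-1] - times_ns[0]
        if self.start_ns is not None or self.end_ns is not None:
            lo = -np.inf if self.start_ns is None else self.start_ns
            hi = np.inf if self.end_ns is None else self.end_ns
            m = (times_ns >= lo) & (times_ns <= hi)
        elif self.last_ns is not None:
            m = times_ns >= times_ns[-1] - self.last_ns
        elif self.last_fraction is not None:
            m = times_ns >= times_ns[-1] - span * self.last_fraction
        else:
            if span >= DEFAULT_LAST_NS:
                m = times_ns >= times_ns[-1] - DEFAULT_LAST_NS
            else:
                m = times_ns >= times_ns[-1] - span * DEFAULT_LAST_FRACTION
        if not m.any():
            raise ValueError("time window selects no frames")
        return m


def resolve_window(times_ns: np.ndarray,
                   window: "TimeWindow | tuple[float, float] | None") -> np.ndarray:
    """Boolean frame mask for ``window`` (``None`` -> trailing default)."""
    if window is None:
        window = TimeWindow.default()
    elif isinstance(window, tuple):
        window = TimeWindow.interval(*window)
    return window.mask(times_ns)
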