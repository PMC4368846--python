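"""Containers for time-resolved fluorescence records and pulse protocols."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PulseSegment", "PulseProtocol", "NoiseSpec", "FluorTrace"]

#: Finest supported sampling step, ms (instrument-class resolution: 10 us).
MIN_RESOLUTION = 0.01


@dataclass(frozen=True)
class PulseSegment:
    """One protocol segment: duration (ms), intensity (umol photons m^-2 s^-1), light flag."""

    duration: float
    intensity: float
    on: bool

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0 ms, got {self.duration}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not self.on and self.intensity != 0:
            raise ValueError("off-segments must have intensity 0")
        if self.on and self.intensity <= 0:
            raise ValueError("on-segments must have intensity > 0")


@dataclass(frozen=True)
class PulseProtocol:
    """An ordered light/dark pulse sequence with a fixed sampling step.

    ``resolution`` is the sampling interval in ms (>= 0.01 ms, i.e. 10 us,
    matching programmable instrument resolution).
    """

    segments: tuple[PulseSegment, ...]
    resolution: float = 0.01

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, PulseSegment) else PulseSegment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if self.resolution < MIN_RESOLUTION:
            raise ValueError(
                f"resolution must be >= {MIN_RESOLUTION} ms, got {self.resolution}"
            )

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def single_pulse(
        cls,
        duration: float,
        intensity: float = 3000.0,
        tail: float = 0.0,
        resolution: float = 0.01,
    ) -> "PulseProtocol":
        """A light pulse from a dark-adapted start, optionally with a dark tail."""
        segs = [PulseSegment(duration, intensity, True)]
        if tail > 0:
            segs.append(PulseSegment(tail, 0.0, False))
        return cls(tuple(segs), resolution=resolution)

    def describe(self) -> list[tuple[float, float, int]]:
        return [(s.duration, s.intensity, int(s.on)) for s in self.segments]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise: relative sd and RNG seed."""

    sd_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_rel < 0:
            raise ValueError(f"sd_rel must be >= 0, got {self.sd_rel}")


class FluorTrace:
    """A time-stamped relative-fluorescence record with light-state annotation.

    Parameters
    ----------
    time : array
        Sample times in ms, strictly increasing.
    f_rel : array
        F(t)/F_o values, strictly positive (F_o-normalized; the first
        light-on sample near t = 0.01 ms anchors the normalization at ~1).
    light_state : array of {0, 1}
        Per-sample illumination flag.
    protocol : list of (duration, intensity, on) or PulseProtocol, optional
        Protocol metadata; checked for consistency with ``light_state``
        when provided.
    meta : dict, optional
        Free-form header metadata (species label, normalization note, ...).
    """

    def __init__(self, time, f_rel, light_state, protocol=None, meta=None):
        self.time = np.asarray(time, dtype=float)
        self.f_rel = np.asarray(f_rel, dtype=float)
        self.light_state = np.asarray(light_state, dtype=int)
        if isinstance(protocol, PulseProtocol):
            protocol = protocol.describe()
        self.protocol = list(protocol) if protocol is not None else None
        self.meta = dict(meta) if meta else {}
        self._validate()

    def _validate(self) -> None:
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if not (len(self.time) == len(self.f_rel) == len(self.light_state)):
            raise ValueError("time, f_rel and light_state must have equal length")
        d = np.diff(self.time)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise ValueError(f"time must be strictly increasing (violated at sample {i + 1})")
        if np.any(self.f_rel <= 0):
            i = int(np.argmax(self.f_rel <= 0))
            raise ValueError(f"f_rel must be > 0 (violated at sample {i})")
        if not np.all(np.isin(self.light_state, (0, 1))):
            raise ValueError("light_state must be 0 or 1")
        if self.protocol is not None:
            self._check_protocol()

    def _check_protocol(self) -> None:
        edges = np.cumsum([d for d, _, _ in self.protocol])
        start = 0.0
        for (dur, _inten, on), end in zip(self.protocol, edges):
            sel = (self.time > start + 1e-12) & (self.time <= end + 1e-12)
            if np.any(self.light_state[sel] != int(on)):
                raise ValueError(
                    f"light_state inconsistent with protocol segment ending at {end} ms"
                )
            start = end

    def __len__(self) -> int:
        return len(self.time)

    def __repr__(self) -> str:
        on = int(self.light_state.sum())
        return (
            f"FluorTrace(n={len(self)}, span={self.time[0]:g}-{self.time[-1]:g} ms, "
            f"{on} light samples)"
        )

    # -- segment selection ------------------------------------------------

    def light_on_segment(self) -> "FluorTrace":
        """The first contiguous illuminated stretch."""
        return self._first_run(1)

    def dark_segment(self, local_time: bool = True) -> "FluorTrace":
        """The first contiguous dark stretch following illumination.

        With ``local_time`` the clock is restarted at the light-off instant
        (the decay's own t = 0), which is the convention for decay fitting:
        fitted amplitudes are then extrapolated values at light-off.
        """
        idx = np.flatnonzero(self.light_state == 1)
        if len(idx) == 0:
            raise ValueError("trace has no illuminated samples before a dark tail")
        after = np.flatnonzero((self.light_state == 0) & (np.arange(len(self)) > idx[0]))
        if len(after) == 0:
            raise ValueError("trace has no dark tail after illumination")
        first = after[0]
        run_end = first
        while run_end < len(self) and self.light_state[run_end] == 0:
            run_end += 1
        t = self.time[first:run_end]
        t_off = self.time[first - 1] if first > 0 else t[0]
        if local_time:
            t = t - t_off
        return FluorTrace(
            t, self.f_rel[first:run_end], self.light_state[first:run_end], meta=self.meta
        )

    def _first_run(self, state: int) -> "FluorTrace":
        idx = np.flatnonzero(self.light_state == state)
        if len(idx) == 0:
            raise ValueError(f"trace has no samples with light_state == {state}")
        first = idx[0]
        run_end = first
        while run_end < len(self) and self.light_state[run_end] == state:
            run_end += 1
        return FluorTrace(
            self.time[first:run_end],
            self.f_rel[first:run_end],
            self.light_state[first:run_end],
            meta=self.meta,
        )

    # -- DataFrame interop -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time, "F_rel": self.f_rel, "light_state": self.light_state}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protocol=None, meta=None) -> "FluorTrace":
        missing = {"time_ms", "F_rel", "light_state"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        return cls(
            df["time_ms"].to_numpy(),
            df["F_rel"].to_numpy(),
            df["light_state"].to_numpy(),
            protocol=protocol,
            meta=meta,
        )
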