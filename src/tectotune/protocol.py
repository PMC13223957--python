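"""Stimulus/acquisition schedule for size-sweep calcium imaging sessions.

A session presents moving dots of several angular sizes on the frontal visual
field of an agarose-embedded larva.  Each size is shown for a fixed number of
repetitions; one repetition is a 9 s there-and-back azimuthal sweep
(-90° -> +90° -> -90° at 40°/s) preceded by a 5 s pause during which the dot
stands still.  Sweep direction alternates clockwise / anti-clockwise across
repetitions.  Acquisition runs at 2 frames/s and starts 15 s before and ends
15 s after stimulus presentation.  The protocol object maps every acquired
frame to exactly one phase label: ``pre``, ``pause``, ``stim`` or ``post``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PHASE_PRE = "pre"
PHASE_PAUSE = "pause"
PHASE_STIM = "stim"
PHASE_POST = "post"

DEFAULT_SIZES_DEG = (2.0, 5.0, 10.0, 20.0, 30.0)


def _alternating_directions(n: int) -> tuple[str, ...]:
    return tuple("cw" if i % 2 == 0 else "acw" for i in range(n))


@dataclass(frozen=True)
class StimulusProtocol:
    """Full stimulus/acquisition schedule.

    Parameters mirror the recording configuration: sizes swept at
    ``sweep_speed_deg_s``, ``n_repetitions`` per size, ``stim_duration_s``
    stimulus phases each preceded by a ``pause_duration_s`` pause, with
    ``pre_session_s`` / ``post_session_s`` of stimulus-free recording framing
    the session at ``frame_rate_hz``.
    """

    sizes_deg: tuple[float, ...] = DEFAULT_SIZES_DEG
    n_repetitions: int = 6
    stim_duration_s: float = 9.0
    pause_duration_s: float = 5.0
    pre_session_s: float = 15.0
    post_session_s: float = 15.0
    frame_rate_hz: float = 2.0
    sweep_speed_deg_s: float = 40.0
    azimuth_range_deg: tuple[float, float] = (-90.0, 90.0)
    direction_schedule: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes_deg)
        object.__setattr__(self, "sizes_deg", sizes)
        if len(sizes) == 0:
            raise ConfigurationError("sizes_deg must be nonempty")
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("stimulus sizes must be positive")
        for name in ("stim_duration_s", "pause_duration_s", "frame_rate_hz",
                     "sweep_speed_deg_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if self.pre_session_s < 0 or self.post_session_s < 0:
            raise ConfigurationError("pre/post session durations must be >= 0")
        if not self.direction_schedule:
            object.__setattr__(
                self, "direction_schedule",
                _alternating_directions(self.n_repetitions))
        if len(self.direction_schedule) != self.n_repetitions:
            raise ConfigurationError(
                "direction_schedule length must equal n_repetitions")

    # -- frame bookkeeping -------------------------------------------------

    def _nframes(self, seconds: float) -> int:
        return int(round(self.frame_rate_hz * seconds))

    @property
    def pre_frames(self) -> int:
        return self._nframes(self.pre_session_s)

    @property
    def post_frames(self) -> int:
        return self._nframes(self.post_session_s)

    @property
    def pause_frames(self) -> int:
        return self._nframes(self.pause_duration_s)

    @property
    def stim_frames(self) -> int:
        return self._nframes(self.stim_duration_s)

    @property
    def n_frames(self) -> int:
        per_rep = self.pause_frames + self.stim_frames
        return (self.pre_frames + self.post_frames
                + len(self.sizes_deg) * self.n_repetitions * per_rep)

    @property
    def baseline_frames(self) -> range:
        """Frames of the stimulus-free pre-session used as the F0 baseline."""
        return range(0, self.pre_frames)

    def iter_blocks(self) -> Iterator[tuple[str, float | None, int | None,
                                            str | None, int, int]]:
        """Yield (phase, size_deg, repetition, direction, start, stop).

        Blocks are emitted in presentation order; intervals are half-open
        ``[start, stop)`` and tile ``range(n_frames)`` exactly.
        """
        cursor = 0
        if self.pre_frames:
            yield (PHASE_PRE, None, None, None, 0, self.pre_frames)
            cursor = self.pre_frames
        for size in self.sizes_deg:
            for rep in range(self.n_repetitions):
                direction = self.direction_schedule[rep]
                yield (PHASE_PAUSE, size, rep, direction,
                       cursor, cursor + self.pause_frames)
                cursor += self.pause_frames
                yield (PHASE_STIM, size, rep, direction,
                       cursor, cursor + self.stim_frames)
                cursor += self.stim_frames
        if self.post_frames:
            yield (PHASE_POST, None, None, None,
                   cursor, cursor + self.post_frames)

    def frame_table(self) -> pd.DataFrame:
        """Per-frame label table (frame, phase, size_deg, repetition, direction)."""
        rows = []
        for phase, size, rep, direction, start, stop in self.iter_blocks():
            for f in range(start, stop):
                rows.append((f, phase, size, rep, direction))
        return pd.DataFrame(
            rows, columns=["frame", "phase", "size_deg", "repetition",
                           "direction"])

    def stim_windows(self, size_deg: float) -> list[tuple[int, int]]:
        """Half-open frame intervals of the stimulus phases for one size."""
        out = [(start, stop)
               for phase, size, _rep, _d, start, stop in self.iter_blocks()
               if phase == PHASE_STIM and size == float(size_deg)]
        if not out:
            raise ConfigurationError(
                f"size {size_deg} is not part of this protocol")
        return out

    def label_of(self, frame: int) -> str:
        """Phase label of a single frame index."""
        if not 0 <= frame < self.n_frames:
            raise ConfigurationError(
                f"frame {frame} outside session of {self.n_frames} frames")
        for phase, _size, _rep, _d, start, stop in self.iter_blocks():
            if start <= frame < stop:
                return phase
        raise AssertionError("unreachable: blocks tile the session")

    def with_sizes(self, sizes_deg: Sequence[float]) -> "StimulusProtocol":
        return replace(self, sizes_deg=tuple(sizes_deg))


def make_protocol(config: Mapping | None = None) -> StimulusProtocol:
    """Build a :class:`StimulusProtocol` from a plain mapping.

    Unknown keys raise; omitted keys take the defaults above.
    """
    config = dict(config or {})
    valid = set(StimulusProtocol.__dataclass_fields__)
    unknown = set(config) - valid
    if unknown:
        raise ConfigurationError(f"unknown protocol keys: {sorted(unknown)}")
    if "sizes_deg" in config:
        config["sizes_deg"] = tuple(config["sizes_deg"])
    if "direction_schedule" in config:
        config["direction_schedule"] = tuple(config["direction_schedule"])
    if "azimuth_range_deg" in config:
        config["azimuth_range_deg"] = tuple(config["azimuth_range_deg"])
    return StimulusProtocol(**config)
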