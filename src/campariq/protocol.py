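"""Drifting-grating stimulus protocol: 8 directions x 5 repetitions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of a directional drifting-grating session.

    Each trial is a ``grating_s``-second grating moving in one of
    ``n_directions`` directions, followed by ``gray_s`` seconds of gray
    screen.  The session opens with one gray period so the first trial has a
    pre-onset baseline.  Default timing: 8 directions x 5 repetitions of 4-s
    gratings with 8-s gray at 30 frames/s.
    """

    n_directions: int = 8
    n_repetitions: int = 5
    grating_s: float = 4.0
    gray_s: float = 8.0
    frame_rate: float = 30.0
    baseline_s: float = 0.66
    direction_order: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (4.0 <= self.gray_s <= 12.0):
            raise ValueError(f"gray_s must be in [4, 12] s, got {self.gray_s}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.direction_order:
            # sequential sweep repeated each cycle
            order = tuple(
                int(d) for d in np.tile(np.arange(self.n_directions), self.n_repetitions)
            )
            object.__setattr__(self, "direction_order", order)
        if len(self.direction_order) != self.n_trials:
            raise ValueError(
                f"direction_order length {len(self.direction_order)} != "
                f"n_trials {self.n_trials}"
            )

    @property
    def n_trials(self) -> int:
        return self.n_directions * self.n_repetitions

    @property
    def grating_frames(self) -> int:
        return int(round(self.grating_s * self.frame_rate))

    @property
    def baseline_frames(self) -> int:
        return int(round(self.baseline_s * self.frame_rate))

    def onset_frames(self) -> np.ndarray:
        """Frame index at which each grating turns on."""
        period = self.gray_s + self.grating_s
        onsets_s = self.gray_s + np.arange(self.n_trials) * period
        return np.round(onsets_s * self.frame_rate).astype(int)

    @property
    def n_frames(self) -> int:
        """Total recording length in frames (trailing gray included)."""
        total_s = self.gray_s + self.n_trials * (self.grating_s + self.gray_s)
        return int(round(total_s * self.frame_rate))

    def direction_indicator(self, n_frames: int | None = None) -> np.ndarray:
        """Per-frame active direction id, -1 during gray periods."""
        n = self.n_frames if n_frames is None else n_frames
        ind = np.full(n, -1, dtype=int)
        g = self.grating_frames
        for onset, d in zip(self.onset_frames(), self.direction_order):
            if onset >= n:
                break
            ind[onset : min(onset + g, n)] = d
        return ind
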