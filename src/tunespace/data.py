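"""Core in-memory containers: stimulus spectrograms and neural responses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrogram", "ResponseSet"]


@dataclass
class Spectrogram:
    """Log-compressed filterbank spectrogram, ``values[f, t]`` at ``frame_rate`` Hz."""

    values: np.ndarray
    frame_rate: float = 100.0
    center_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be a 2-D (channels x time) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite entries")
        if self.center_freqs is not None:
            self.center_freqs = np.asarray(self.center_freqs, dtype=float)
            if len(self.center_freqs) != self.values.shape[0]:
                raise ValueError("center_freqs length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def slice_time(self, start: int, stop: int) -> "Spectrogram":
        return Spectrogram(self.values[:, start:stop], self.frame_rate, self.center_freqs)


@dataclass
class ResponseSet:
    """Per-neuron PSTHs (``psth[i, t]``, spikes/s) with optional trial rasters.

    ``rasters`` is ``(trials, neurons, time)`` spike counts per frame.
    ``metadata`` holds per-neuron annotations (e.g. depth in microns,
    spike width in ms) keyed by column name.
    """

    psth: np.ndarray
    frame_rate: float = 100.0
    rasters: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.psth = np.atleast_2d(np.asarray(self.psth, dtype=float))
        if self.rasters is not None:
            self.rasters = np.asarray(self.rasters)
            if self.rasters.shape[1:] != self.psth.shape:
                raise ValueError(
                    "rasters must be (trials, neurons, time) matching the PSTH"
                )

    @property
    def n_neurons(self) -> int:
        return self.psth.shape[0]

    @property
    def n_frames(self) -> int:
        return self.psth.shape[1]

    def slice_time(self, start: int, stop: int) -> "ResponseSet":
        rast = None if self.rasters is None else self.rasters[:, :, start:stop]
        return ResponseSet(self.psth[:, start:stop], self.frame_rate, rast, self.metadata)
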