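"""Shared data containers for the functional (calcium-imaging) pipeline.

These are deliberately thin dataclasses around numpy arrays: every stage of
the pipeline (simulation, trace processing, spike inference, connectivity)
passes one of these across its boundary, and the I/O helpers in
:mod:`gelfun.io` serialize them to plain-text formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class SpikeRaster:
    """Per-neuron activation-onset times.

    Parameters
    ----------
    events
        One sorted array of onset times (seconds) per neuron.
    duration
        Recording length in seconds.  All event times must lie in
        ``[0, duration]``.
    """

    events: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        self.events = [np.asarray(e, dtype=float) for e in self.events]
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for i, e in enumerate(self.events):
            if e.size and (e.min() < 0 or e.max() > self.duration):
                raise ValueError(f"neuron {i}: event times outside [0, duration]")
            if e.size > 1 and np.any(np.diff(e) <= 0):
                raise ValueError(f"neuron {i}: event times must be strictly increasing")

    @property
    def n_neurons(self) -> int:
        return len(self.events)

    @property
    def n_events(self) -> int:
        return int(sum(e.size for e in self.events))


@dataclass
class FluorescenceRecording:
    """Raw per-ROI fluorescence traces, uniformly sampled.

    ``F`` has shape ``(n_rois, n_frames)`` in arbitrary camera units;
    ``frame_rate`` is in frames per second.  ``roi_positions`` optionally
    carries the (x, y) center of each ROI in micrometres.
    """

    F: np.ndarray
    frame_rate: float
    roi_positions: np.ndarray | None = None
    roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.roi_ids is None:
            self.roi_ids = np.arange(self.F.shape[0])
        else:
            self.roi_ids = np.asarray(self.roi_ids)

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class NormalizedTraces:
    """Drift-corrected, baseline-normalized traces dF/F = (F - F0)/F0.

    ``dff`` has shape ``(n_rois, n_frames)``; ``F0`` is the per-ROI rest
    fluorescence used for normalization, and ``baseline`` the full
    time-resolved baseline (drift + F0) that was subtracted, so the raw
    trace is recoverable as ``F = dff * F0 + baseline``.
    """

    dff: np.ndarray
    F0: np.ndarray
    frame_rate: float
    baseline: np.ndarray | None = None
    roi_ids: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class PopulationActivity:
    """Fraction of neurons co-active in a sliding window.

    ``fraction_active[i]`` is the fraction of neurons with at least one
    event in ``[t_centers[i] - window/2, t_centers[i] + window/2)``.
    """

    t_centers: np.ndarray
    fraction_active: np.ndarray
    window: float
    step: float
    n_neurons: int
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
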