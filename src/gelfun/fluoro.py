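"""Fluorescence-trace processing: ROI grid, dF/F, spike inference, dynamics.

The functional recordings are wide-field calcium-imaging movies (15 min at
33 frames/s, 8-bit, 7.1 x 7.1 mm^2 at 5.9 um/px).  Analysis follows the
standard in-gel pipeline:

* a fixed grid of square ROIs (14 x 14 um^2, up to 30 x 30 = 900 ROIs) is
  laid over the field and the mean pixel intensity F_i(t) of each ROI
  extracted;
* ROIs without significant calcium transients are filtered out (about 100
  of the 900 typically survive in an active culture);
* traces are drift-corrected and normalized to dF/F_i(t) = (F_i - F_i0)/F_i0
  where F_i0 is the rest fluorescence;
* a Schmitt trigger (hysteretic two-threshold detector) converts each trace
  into activation onsets, building the spike raster;
* population activity — the fraction of neurons co-active in a sliding
  0.5 s window stepped by 0.1 s — summarizes collective dynamics; sharp
  peaks mark network synchronization events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import FluorescenceRecording, NormalizedTraces, PopulationActivity, SpikeRaster

__all__ = [
    "ROIGrid",
    "build_roi_grid",
    "extract_roi_traces",
    "filter_active_rois",
    "normalize_traces",
    "schmitt_detect",
    "population_activity",
    "detect_sync_peaks",
    "firing_rate",
]

ROI_SIZE_UM = 14.0
MAX_GRID_SIDE = 30  # up to 30 x 30 = 900 ROIs on the default field


@dataclass
class ROIGrid:
    """Fixed grid of square ROIs over the imaging field.

    ``bounds`` holds one ``(row, col, y0, y1, x0, x1)`` pixel window per
    ROI; ROIs are evenly spaced and never overlap.
    """

    shape: tuple[int, int]         # (rows, cols)
    roi_px: int
    roi_size_um: float
    px_um: float
    frame_shape: tuple[int, int]   # (height, width) in px
    bounds: list[tuple[int, int, int, int, int, int]]

    @property
    def n_rois(self) -> int:
        return len(self.bounds)

    def centers_um(self) -> np.ndarray:
        """(x, y) centre of each ROI in um from the field origin."""
        out = np.empty((self.n_rois, 2))
        for i, (_, _, y0, y1, x0, x1) in enumerate(self.bounds):
            out[i] = ((x0 + x1) / 2 * self.px_um, (y0 + y1) / 2 * self.px_um)
        return out


def build_roi_grid(frame_shape: tuple[int, int], px_um: float,
                   roi_um: float = ROI_SIZE_UM,
                   max_side: int = MAX_GRID_SIDE) -> ROIGrid:
    """Lay a deterministic grid of square ROIs over the field.

    The ROI pixel edge is ``round(roi_um / px_um)`` (14 um at 5.9 um/px
    gives 2 px).  Up to ``max_side`` ROIs per dimension are centred on an
    even spacing; when the field fits fewer, the grid shrinks (a field of
    exactly one ROI yields a single ROI covering all pixels).
    """
    if roi_um < px_um:
        raise ValueError("roi_um must be at least one pixel")
    h, w = int(frame_shape[0]), int(frame_shape[1])
    roi_px = max(1, int(round(roi_um / px_um)))
    if h < roi_px or w < roi_px:
        raise ValueError("field smaller than one ROI")
    rows = min(max_side, h // roi_px)
    cols = min(max_side, w // roi_px)
    bounds = []
    for r in range(rows):
        yc = (r + 0.5) * h / rows
        y0 = int(round(yc - roi_px / 2))
        y0 = min(max(y0, 0), h - roi_px)
        for c in range(cols):
            xc = (c + 0.5) * w / cols
            x0 = int(round(xc - roi_px / 2))
            x0 = min(max(x0, 0), w - roi_px)
            bounds.append((r, c, y0, y0 + roi_px, x0, x0 + roi_px))
    return ROIGrid(shape=(rows, cols), roi_px=roi_px, roi_size_um=roi_um,
                   px_um=px_um, frame_shape=(h, w), bounds=bounds)


def extract_roi_traces(stack: np.ndarray, grid: ROIGrid,
                       frame_rate: float = 33.0) -> FluorescenceRecording:
    """Mean pixel value inside each ROI per frame."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a nonempty (frames, height, width) array")
    if stack.shape[1:] != grid.frame_shape:
        raise ValueError("stack frame shape does not match the ROI grid")
    F = np.empty((grid.n_rois, stack.shape[0]))
    for i, (_, _, y0, y1, x0, x1) in enumerate(grid.bounds):
        F[i] = stack[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return FluorescenceRecording(F=F, frame_rate=frame_rate,
                                 roi_positions=grid.centers_um())


# --------------------------------------------------------------------------
# normalization


def _running_percentile(F: np.ndarray, frame_rate: float, window_s: float,
                        q: float) -> np.ndarray:
    """Centred running percentile, evaluated on a coarse grid and
    linearly interpolated between grid points (the baseline varies slowly)."""
    n_frames = F.shape[1]
    win = max(3, int(round(window_s * frame_rate)))
    step = max(1, win // 4)
    centers = np.arange(0, n_frames, step)
    vals = np.empty((F.shape[0], centers.size))
    for k, c in enumerate(centers):
        a = max(0, c - win // 2)
        b = min(n_frames, c + win // 2 + 1)
        vals[:, k] = np.percentile(F[:, a:b], q, axis=1)
    out = np.empty_like(F, dtype=float)
    idx = np.arange(n_frames, dtype=float)
    for i in range(F.shape[0]):
        out[i] = np.interp(idx, centers.astype(float), vals[i])
    return out


def normalize_traces(rec: FluorescenceRecording, f0_percentile: float = 10.0,
                     drift_window_s: float = 30.0,
                     correct_drift: bool = True) -> NormalizedTraces:
    """Drift-correct and normalize traces to dF/F = (F - F0)/F0.

    The rest level F_i0 is the ``f0_percentile``-th percentile of the raw
    trace (robust to transients); slow drift is removed by subtracting a
    running percentile baseline of the same order over ``drift_window_s``
    windows, re-anchored at F_i0.  The stored baseline makes the transform
    invertible: ``F = dff * F0 + baseline``.
    """
    F = rec.F
    F0 = np.percentile(F, f0_percentile, axis=1)
    if np.any(F0 <= 0):
        raise ValueError("nonpositive rest fluorescence F0; cannot normalize")
    if correct_drift:
        baseline = _running_percentile(F, rec.frame_rate, drift_window_s,
                                       f0_percentile)
    else:
        baseline = np.broadcast_to(F0[:, None], F.shape).copy()
    dff = (F - baseline) / F0[:, None]
    return NormalizedTraces(dff=dff, F0=F0, frame_rate=rec.frame_rate,
                            baseline=baseline, roi_ids=rec.roi_ids)


# --------------------------------------------------------------------------
# event detection


def _noise_thresholds(dff: np.ndarray, high_sigma: float, low_sigma: float):
    """Per-trace hysteresis thresholds from the noise floor (median + MAD)."""
    med = np.median(dff, axis=1)
    sigma = 1.4826 * np.median(np.abs(dff - med[:, None]), axis=1)
    sigma = np.maximum(sigma, 1e-12)
    return med + high_sigma * sigma, med + low_sigma * sigma


def schmitt_detect(traces: NormalizedTraces, high: float | np.ndarray | None = None,
                   low: float | np.ndarray | None = None,
                   min_duration: float = 7.0 / 33.0,
                   high_sigma: float = 4.0, low_sigma: float = 2.0,
                   smooth_frames: int = 5) -> SpikeRaster:
    """Hysteretic (Schmitt-trigger) event detection on dF/F traces.

    An event opens at the first sample exceeding ``high`` and closes when
    the signal falls below ``low``; between the two thresholds the detector
    cannot retrigger.  The reported time is the opening (onset) sample.
    Events that stay above ``low`` for less than ``min_duration`` seconds
    after onset are discarded.  When thresholds are not given they are set
    per trace from the noise floor: median + 4 sigma / + 2 sigma, with
    sigma from the median absolute deviation.

    A short centred boxcar (``smooth_frames``, default 5 frames = 0.15 s,
    well under the indicator rise time) is applied before thresholding: at
    moderate signal-to-noise the frame-to-frame noise otherwise dominates
    the onset-crossing jitter.  Set ``smooth_frames=0`` to threshold the
    raw trace.
    """
    dff = traces.dff
    if smooth_frames > 1:
        kern = np.ones(smooth_frames) / smooth_frames
        dff = np.apply_along_axis(lambda x: np.convolve(x, kern, "same"), 1, dff)
    n, n_frames = dff.shape
    if high is None or low is None:
        auto_hi, auto_lo = _noise_thresholds(dff, high_sigma, low_sigma)
        hi = auto_hi if high is None else np.broadcast_to(np.asarray(high, float), (n,))
        lo = auto_lo if low is None else np.broadcast_to(np.asarray(low, float), (n,))
    else:
        hi = np.broadcast_to(np.asarray(high, dtype=float), (n,)).astype(float)
        lo = np.broadcast_to(np.asarray(low, dtype=float), (n,)).astype(float)
    if np.any(hi <= lo):
        raise ValueError("require high > low")
    min_frames = max(1, int(round(min_duration * traces.frame_rate)))

    events = []
    for i in range(n):
        x = dff[i]
        above_low = x > lo[i]
        # contiguous runs above the low threshold
        edges = np.diff(above_low.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above_low[0]:
            starts = np.concatenate([[0], starts])
        if above_low[-1]:
            ends = np.concatenate([ends, [n_frames]])
        onsets = []
        for a, b in zip(starts, ends):
            seg_high = np.flatnonzero(x[a:b] > hi[i])
            if seg_high.size == 0:
                continue
            onset = a + seg_high[0]
            if b - onset >= min_frames:
                onsets.append(onset)
        events.append(np.asarray(onsets, dtype=float) / traces.frame_rate)
    return SpikeRaster(events=events, duration=n_frames / traces.frame_rate)


def filter_active_rois(rec: FluorescenceRecording, amp_min: float = 0.1,
                       min_events: int = 1,
                       **norm_kwargs) -> tuple[FluorescenceRecording, dict]:
    """Keep only ROIs showing significant calcium transients.

    A ROI survives when its peak dF/F reaches ``amp_min`` *and* the Schmitt
    trigger finds at least ``min_events`` activations in it.  Returns the
    reduced recording and a report with kept/discarded counts.  Warns when
    fewer than 10 ROIs survive.
    """
    traces = normalize_traces(rec, **norm_kwargs)
    raster = schmitt_detect(traces)
    peak = traces.dff.max(axis=1)
    keep = (peak >= amp_min) & np.array([e.size >= min_events for e in raster.events])
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size < 10:
        warnings.warn(f"only {kept_idx.size} ROIs passed the activity filter",
                      stacklevel=2)
    out = FluorescenceRecording(
        F=rec.F[kept_idx],
        frame_rate=rec.frame_rate,
        roi_positions=None if rec.roi_positions is None else rec.roi_positions[kept_idx],
        roi_ids=rec.roi_ids[kept_idx],
    )
    report = {"n_total": rec.n_rois, "n_kept": int(kept_idx.size),
              "n_discarded": int(rec.n_rois - kept_idx.size),
              "amp_min": amp_min, "min_events": min_events}
    return out, report


# --------------------------------------------------------------------------
# population dynamics


def population_activity(raster: SpikeRaster, window: float = 0.5,
                        step: float = 0.1) -> PopulationActivity:
    """Fraction of neurons with >= 1 event in a sliding window.

    Windows start at 0 and advance by ``step``; the last full window starts
    at ``duration - window`` (no partial windows).
    """
    if raster.duration <= 0:
        raise ValueError("raster duration must be positive")
    if window <= 0 or step <= 0 or window > raster.duration:
        raise ValueError("invalid window/step")
    n_win = int(np.floor((raster.duration - window) / step + 1e-9)) + 1
    starts = np.arange(n_win) * step
    counts = np.zeros(n_win)
    for ev in raster.events:
        if ev.size == 0:
            continue
        left = np.searchsorted(ev, starts, side="left")
        has = (left < ev.size) & (ev[np.minimum(left, ev.size - 1)] < starts + window)
        counts += has
    frac = counts / max(raster.n_neurons, 1)
    return PopulationActivity(t_centers=starts + window / 2, fraction_active=frac,
                              window=window, step=step, n_neurons=raster.n_neurons)


def detect_sync_peaks(pa: PopulationActivity, z_pk: float = 3.0,
                      min_fraction: float = 0.2,
                      merge_within: float | None = None) -> np.ndarray:
    """Synchronization peaks: local maxima above mean + z_pk * sd.

    A candidate window must also recruit at least ``min_fraction`` of the
    network — a synchronization event is collective by definition, and the
    floor keeps shot-noise fluctuations of a sparsely firing population
    from counting as peaks.  Candidates closer than ``merge_within``
    (default: one window width) are grouped and each group contributes its
    maximum.  A flat series has no peaks.
    """
    x = pa.fraction_active
    if x.size == 0:
        return np.empty(0)
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        pa.peak_times = np.empty(0)
        return pa.peak_times
    thr = max(mu + z_pk * sd, min_fraction)
    cand = np.flatnonzero(x > thr)
    if cand.size == 0:
        pa.peak_times = np.empty(0)
        return pa.peak_times
    merge = pa.window if merge_within is None else merge_within
    gap = max(1, int(round(merge / pa.step)))
    peaks = []
    group = [cand[0]]
    for c in cand[1:]:
        if c - group[-1] <= gap:
            group.append(c)
        else:
            peaks.append(group[np.argmax(x[group])])
            group = [c]
    peaks.append(group[np.argmax(x[group])])
    pa.peak_times = pa.t_centers[np.asarray(peaks)]
    return pa.peak_times


def firing_rate(raster: SpikeRaster) -> float:
    """Mean activation rate in events per neuron per minute."""
    if raster.duration <= 0:
        raise ValueError("duration must be positive")
    if raster.n_neurons == 0:
        return 0.0
    return raster.n_events / raster.n_neurons / (raster.duration / 60.0)
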