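"""Synthetic ground-truth generators for the mechano-functional pipeline.

The study this package reimplements recorded spontaneous calcium activity of
primary cortical networks grown in 3D fibrin hydrogels and, in parallel,
characterized the gels by small-amplitude oscillatory shear (SAOS) rheology.
Neither the recordings nor the sweep tables are public, so every input the
analysis consumes is emulated here with a *known* ground truth:

* :func:`generate_network` — a directed, spatially embedded, community-
  structured network of ~100 neurons inside a cylindrical gel volume;
* :func:`simulate_spikes` — a discrete-time stochastic cascade whose directed
  couplings are exactly the ground-truth edges (the signal that transfer
  entropy must later recover), with an optional global synchronous drive
  reproducing network-burst phenomenology;
* :func:`render_fluorescence` — GCaMP6s-like transients (difference of
  exponentials, fast rise / slow decay) plus noise and slow drift, sampled at
  the camera frame rate;
* :func:`render_frames` — an 8-bit wide-field movie with one Gaussian spot
  per neuron, matching the imaging geometry (7.1 x 7.1 mm^2, 5.9 um/px);
* :func:`generate_sweeps` — SAOS sweep tables (time, strain and frequency
  tests) with a low-frequency plateau, G'' about one tenth of G', and a
  high-frequency thickening transition.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import FluorescenceRecording, SpikeRaster

__all__ = [
    "GroundTruthNetwork",
    "SpikeSimParams",
    "CalciumParams",
    "RheoTruth",
    "generate_network",
    "simulate_spikes",
    "render_fluorescence",
    "render_frames",
    "generate_sweeps",
    "SWEEP_COLUMNS",
]

# imaging field of the wide-field setup: 7.1 mm square at 5.9 um/px, 8 bit
FIELD_MM = 7.1
PX_UM = 5.9
EXCITATORY_FRACTION = 0.8  # cortical cultures: 80% excitatory, 20% inhibitory


@dataclass
class GroundTruthNetwork:
    """Directed ground-truth network embedded in a cylindrical gel volume."""

    n_neurons: int
    positions: np.ndarray          # (n, 3) um, cylinder centred on origin
    adjacency: np.ndarray          # (n, n) binary, A[i, j] = 1 for edge i -> j
    weights: np.ndarray            # (n, n) nonnegative coupling strengths
    community_labels: np.ndarray   # (n,) int
    excitatory_mask: np.ndarray    # (n,) bool
    seed: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-edges are not allowed")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.community_labels)))

    def to_dict(self) -> dict:
        """JSON-serializable representation (adjacency as edge list)."""
        src, dst = np.nonzero(self.adjacency)
        return {
            "n_neurons": self.n_neurons,
            "edges": [[int(i), int(j)] for i, j in zip(src, dst)],
            "edge_weights": [float(self.weights[i, j]) for i, j in zip(src, dst)],
            "positions_um": self.positions.tolist(),
            "community_labels": self.community_labels.tolist(),
            "excitatory_mask": self.excitatory_mask.astype(int).tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthNetwork":
        n = d["n_neurons"]
        A = np.zeros((n, n), dtype=int)
        W = np.zeros((n, n), dtype=float)
        for (i, j), w in zip(d["edges"], d["edge_weights"]):
            A[i, j] = 1
            W[i, j] = w
        return cls(
            n_neurons=n,
            positions=np.asarray(d["positions_um"], dtype=float),
            adjacency=A,
            weights=W,
            community_labels=np.asarray(d["community_labels"], dtype=int),
            excitatory_mask=np.asarray(d["excitatory_mask"], dtype=bool),
            seed=d.get("seed"),
        )


@dataclass
class SpikeSimParams:
    """Parameters of the stochastic-cascade spiking model.

    ``baseline_rate`` is the spontaneous activation rate per neuron
    (events/s); the observed in-gel regime is about 2.9 activations per
    neuron per minute, i.e. ~0.048 events/s.  ``coupling_scale`` converts
    summed presynaptic input into extra firing probability per time step.
    ``sync_drive_rate`` adds network-wide synchronous events (Poisson, each
    recruiting a random 60-90% of the population), emulating the sharp
    population-activity peaks of soft-gel cultures; set it to 0 for
    asynchronous (stiff-gel-like) dynamics.
    """

    duration: float = 900.0          # s; 15-min recording
    dt: float = 1.0 / 33.0           # s; one camera frame
    baseline_rate: float = 2.9 / 60  # events/s per neuron
    coupling_scale: float = 0.0      # probability per unit summed input
    transmission_delay: float = 2.0 / 33.0  # s; one connectivity-analysis bin
    refractory: float = 0.3          # s
    sync_drive_rate: float = 0.0     # network events/s
    sync_recruit_range: tuple[float, float] = (0.6, 0.9)
    signed_coupling: bool = False    # subtract input from inhibitory neurons
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be at least 10 time steps")
        if min(self.baseline_rate, self.coupling_scale, self.sync_drive_rate) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class CalciumParams:
    """GCaMP6s-like calcium-transient rendering parameters.

    The kernel is a difference of exponentials with a fast rise and a slow
    decay; defaults (0.2 s rise, 1.0 s decay) follow published GCaMP6s
    kinetics.  One spike adds a transient of peak amplitude
    ``amplitude_per_spike * baseline_F0`` camera units.
    """

    amplitude_per_spike: float = 0.8  # dF/F units per event
    rise_time: float = 0.2            # s
    decay_time: float = 1.0           # s
    baseline_F0: float = 20.0         # a.u.
    noise_sd: float = 0.5             # a.u.
    drift_amplitude: float = 0.0      # a.u.
    drift_period: float = 300.0       # s
    frame_rate: float = 33.0          # frames/s
    seed: int = 0

    def validate(self) -> None:
        if not (self.decay_time > self.rise_time > 0):
            raise ValueError("require decay_time > rise_time > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be positive")


@dataclass
class RheoTruth:
    """Ground truth for synthetic SAOS sweeps.

    ``plateau_G1`` is the true low-frequency storage modulus G' (Pa);
    G'' is ``loss_ratio * G'`` (the gels are strongly elastic, G' about an
    order of magnitude above G'').  Past ``thickening_onset`` (rad/s) the
    storage modulus rises as a power law of exponent
    ``thickening_exponent``.  Time sweeps relax exponentially towards the
    plateau and settle (within a +/-5% band) at ``transient_time_true``
    seconds.  Noise is multiplicative with coefficient of variation
    ``noise_cv``.
    """

    plateau_G1: float = 200.0
    loss_ratio: float = 0.1
    thickening_onset: float = 50.0   # rad/s
    thickening_exponent: float = 2.0
    transient_time_true: float = 300.0  # s
    transient_depth: float = 0.3     # fractional undershoot at t = 0
    strain_softening_slope: float = 0.03  # -dlogG'/dlog(gamma0)
    noise_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.plateau_G1 <= 0:
            raise ValueError("plateau_G1 must be positive")
        if not (0 < self.loss_ratio < 1):
            raise ValueError("loss_ratio must be in (0, 1)")


# --------------------------------------------------------------------------
# network generation


def _cylinder_positions(n: int, radius_um: float, height_um: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Uniform positions in a cylinder centred on the origin (z in height)."""
    r = radius_um * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-height_um / 2, height_um / 2, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_network(
    n_neurons: int,
    density: float = 0.08,
    n_communities: int = 4,
    spatial_decay: float = 2000.0,
    seed: int = 0,
    radius_um: float = 3550.0,
    height_um: float = 800.0,
    community_affinity: float = 4.0,
) -> GroundTruthNetwork:
    """Generate a directed ground-truth network in a cylindrical gel volume.

    Edges are drawn independently with probability proportional to
    ``community_affinity`` (for same-community pairs) times an exponential
    decay in 3D distance with length scale ``spatial_decay`` (um), globally
    rescaled so the *expected* edge density equals ``density``.  Communities
    are contiguous angular sectors of the cylinder, so same-community neurons
    are also spatially close — mirroring the observation that functional
    communities in soft gels group physically neighbouring neurons.

    80% of neurons are excitatory (the cortical-culture ratio); the rest are
    inhibitory.  Edge weights are gamma-distributed with mean 1.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    if n_communities > n_neurons:
        raise ValueError("more communities than neurons")
    rng = np.random.default_rng(seed)
    pos = _cylinder_positions(n_neurons, radius_um, height_um, rng)

    # contiguous angular sectors -> spatially clustered, non-empty communities
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    order = np.argsort(theta)
    labels = np.empty(n_neurons, dtype=int)
    for c, chunk in enumerate(np.array_split(order, n_communities)):
        labels[chunk] = c

    dist = squareform(pdist(pos))
    w = np.exp(-dist / spatial_decay)
    same = labels[:, None] == labels[None, :]
    w = np.where(same, community_affinity * w, w)
    np.fill_diagonal(w, 0.0)
    m_pairs = n_neurons * (n_neurons - 1)
    p = density * m_pairs * w / w.sum()
    p = np.clip(p, 0.0, 1.0)

    A = (rng.random((n_neurons, n_neurons)) < p).astype(int)
    np.fill_diagonal(A, 0)

    W = np.where(A > 0, rng.gamma(10.0, 0.1, size=A.shape), 0.0)

    n_exc = int(round(EXCITATORY_FRACTION * n_neurons))
    exc = np.zeros(n_neurons, dtype=bool)
    exc[rng.permutation(n_neurons)[:n_exc]] = True

    return GroundTruthNetwork(
        n_neurons=n_neurons, positions=pos, adjacency=A, weights=W,
        community_labels=labels, excitatory_mask=exc, seed=seed,
    )


# --------------------------------------------------------------------------
# spiking simulation


def simulate_spikes(net: GroundTruthNetwork, params: SpikeSimParams) -> SpikeRaster:
    """Simulate spontaneous activity with a discrete-time stochastic cascade.

    Per time step of length ``dt`` each non-refractory neuron fires with
    probability ``baseline_rate * dt`` plus
    ``coupling_scale * (summed presynaptic input at t - transmission_delay)``,
    clipped to [0, 1].  Couplings are additive by default (the minimal
    model whose only directed temporal structure is the ground-truth edge
    set); with ``signed_coupling`` spikes from inhibitory neurons subtract
    their edge weight instead.  Optional network-wide synchronous events
    occur as a Poisson process of rate ``sync_drive_rate`` and recruit a
    random 60-90% subset of the population in one step.

    The model is intentionally minimal: its only directed temporal structure
    is the ground-truth coupling, which is exactly what transfer entropy is
    later asked to recover.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = net.n_neurons
    n_bins = int(round(params.duration / params.dt))
    delay = max(1, int(round(params.transmission_delay / params.dt)))
    refr = int(round(params.refractory / params.dt))
    p_base = params.baseline_rate * params.dt

    if params.signed_coupling:
        sign = np.where(net.excitatory_mask, 1.0, -1.0)
        Wt = (net.weights * sign[:, None]).T
    else:
        Wt = net.weights.T  # column j: input weights onto neuron j

    p_sync = params.sync_drive_rate * params.dt
    lo, hi = params.sync_recruit_range

    spikes = np.zeros((n_bins, n), dtype=bool)
    last_spike = np.full(n, -10 * refr - 1)
    for t in range(n_bins):
        p = np.full(n, p_base)
        if t >= delay:
            drive = Wt @ spikes[t - delay].astype(float)
            p += params.coupling_scale * drive
        if p_sync > 0 and rng.random() < p_sync:
            recruit = rng.random(n) < rng.uniform(lo, hi)
            p = np.where(recruit, 1.0, p)
        p = np.clip(p, 0.0, 1.0)
        fire = (rng.random(n) < p) & (t - last_spike > refr)
        spikes[t] = fire
        last_spike[fire] = t

    events = [np.flatnonzero(spikes[:, i]) * params.dt for i in range(n)]
    return SpikeRaster(events=events, duration=params.duration)


# --------------------------------------------------------------------------
# calcium-trace rendering


def _kernel_peak_scale(rise: float, decay: float) -> float:
    """Peak value of exp(-t/decay) - exp(-t/rise) for t >= 0."""
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    return np.exp(-t_peak / decay) - np.exp(-t_peak / rise)


def render_fluorescence(raster: SpikeRaster, params: CalciumParams) -> FluorescenceRecording:
    """Render per-neuron fluorescence traces from a spike raster.

    Each spike adds one difference-of-exponentials transient of peak height
    ``amplitude_per_spike * baseline_F0``, evaluated at the exact spike time
    (no frame quantization).  Gaussian noise of sd ``noise_sd`` and a slow
    sinusoidal drift of amplitude ``drift_amplitude`` (random phase per ROI)
    are added on top of the constant baseline.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = raster.n_neurons
    n_frames = int(round(raster.duration * params.frame_rate))
    t = np.arange(n_frames) / params.frame_rate

    peak = _kernel_peak_scale(params.rise_time, params.decay_time)
    amp = params.amplitude_per_spike * params.baseline_F0 / peak
    kern_len = int(np.ceil((params.rise_time + 8 * params.decay_time) * params.frame_rate))

    F = np.full((n, n_frames), params.baseline_F0)
    for i, ev in enumerate(raster.events):
        for ts in ev:
            j0 = int(np.ceil(ts * params.frame_rate))
            j1 = min(j0 + kern_len, n_frames)
            if j0 >= n_frames:
                continue
            dt = t[j0:j1] - ts
            F[i, j0:j1] += amp * (np.exp(-dt / params.decay_time)
                                  - np.exp(-dt / params.rise_time))
    if params.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, n)
        F += params.drift_amplitude * np.sin(
            2 * np.pi * t[None, :] / params.drift_period + phase[:, None])
    if params.noise_sd > 0:
        F += rng.normal(0.0, params.noise_sd, size=F.shape)
    np.clip(F, 0.0, None, out=F)
    return FluorescenceRecording(F=F, frame_rate=params.frame_rate)


# --------------------------------------------------------------------------
# frame rendering


def render_frames(
    recording: FluorescenceRecording,
    net: GroundTruthNetwork,
    field_mm: float = FIELD_MM,
    px_um: float = PX_UM,
    spot_sigma_um: float = 5.0,
    gain: float = 1.0,
) -> np.ndarray:
    """Render an 8-bit grayscale frame stack from per-neuron traces.

    Each neuron is a Gaussian spot of width ``spot_sigma_um`` at its (x, y)
    projection onto the imaging plane; pixel values are
    ``gain * F_i(t) * spot profile``, clipped to [0, 255].  The default
    field (7.1 mm at 5.9 um/px) gives 1203 x 1203 px frames.

    Warns when two neurons project within one ROI width (14 um) of each
    other, since their traces would then mix inside a single ROI.
    """
    field_um = field_mm * 1000.0
    n_px = int(field_um / px_um)
    xy = net.positions[:, :2] + field_um / 2.0  # cylinder origin -> field centre
    if np.any(xy < 0) or np.any(xy >= field_um):
        raise ValueError("neuron positions fall outside the imaging field")
    px = xy / px_um

    d2 = squareform(pdist(xy))
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 < 14.0):
        warnings.warn("some neurons project within one ROI width (14 um) of "
                      "each other; their traces will mix", stacklevel=2)

    sigma_px = spot_sigma_um / px_um
    half = max(1, int(np.ceil(3 * sigma_px)))
    stack = np.zeros((recording.n_frames, n_px, n_px), dtype=np.float32)
    for i in range(net.n_neurons):
        cx, cy = px[i]
        x0, x1 = max(0, int(cx) - half), min(n_px, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(n_px, int(cy) + half + 1)
        gx = np.arange(x0, x1) - cx
        gy = np.arange(y0, y1) - cy
        spot = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma_px ** 2))
        stack[:, y0:y1, x0:x1] += (gain * recording.F[i])[:, None, None] \
            * spot[None, :, :].astype(np.float32)
    return np.clip(stack, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# rheology sweep generation

SWEEP_COLUMNS = ["test_type", "DIV", "replicate", "time_s", "omega_rad_s",
                 "gamma0_pct", "G1_Pa", "G2_Pa", "torque_nNm"]

# instrument grids: time sweep at omega = 2*pi rad/s, gamma0 = 5%;
# strain sweep gamma0 0.1-100% at 2*pi rad/s; frequency sweep 0.6-600 rad/s at 5%
_DEFAULT_GRIDS = {
    "time": dict(t=np.arange(0.0, 900.0 + 1e-9, 5.0), omega=2 * np.pi, gamma0=5.0),
    "strain": dict(gamma0=np.geomspace(0.1, 100.0, 25), omega=2 * np.pi),
    "frequency": dict(omega=np.geomspace(0.6, 600.0, 30), gamma0=5.0),
}
TORQUE_COEFF = 0.01  # nN*m per (Pa * % strain); sets the instrument scale


def _true_moduli_frequency(truth: RheoTruth, omega: np.ndarray):
    G1 = truth.plateau_G1 * (1.0 + (omega / truth.thickening_onset) ** truth.thickening_exponent)
    return G1, truth.loss_ratio * G1


def generate_sweeps(
    truth: RheoTruth,
    test_type: str,
    div: int = 1,
    replicate: int = 0,
    grid: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate one synthetic SAOS sweep table.

    ``test_type`` is one of ``"time"`` (G' relaxing exponentially to the
    plateau, settling within +/-5% at ``transient_time_true``), ``"strain"``
    (near-flat G' with a slight negative log-log slope), or ``"frequency"``
    (plateau below ~10 rad/s, power-law thickening past
    ``thickening_onset``).  G'' is ``loss_ratio * G'`` throughout.  Noise is
    multiplicative log-normal with geometric CV ``noise_cv``; the oscillation
    torque scales with ``|G*| * gamma0``, so low-strain points can fall below
    the 2 nN*m instrument floor just as in the real measurements.
    """
    truth.validate()
    if test_type not in _DEFAULT_GRIDS:
        raise ValueError(f"unknown test_type {test_type!r}")
    g = dict(_DEFAULT_GRIDS[test_type])
    if grid:
        g.update(grid)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    if test_type == "time":
        tgrid = np.asarray(g["t"], dtype=float)
        if tgrid.size == 0:
            raise ValueError("empty grid")
        # tau chosen so G' enters the +/-5% terminal band at transient_time_true
        tau = truth.transient_time_true / np.log(truth.transient_depth / 0.05)
        G1 = truth.plateau_G1 * (1.0 - truth.transient_depth * np.exp(-tgrid / tau))
        omega = np.full_like(tgrid, g["omega"])
        gamma0 = np.full_like(tgrid, g["gamma0"])
        time_s = tgrid
    elif test_type == "strain":
        gamma0 = np.asarray(g["gamma0"], dtype=float)
        if gamma0.size == 0:
            raise ValueError("empty grid")
        G1 = truth.plateau_G1 * (gamma0 / 5.0) ** (-truth.strain_softening_slope)
        omega = np.full_like(gamma0, g["omega"])
        time_s = np.full_like(gamma0, np.nan)
    else:  # frequency
        omega = np.asarray(g["omega"], dtype=float)
        if omega.size == 0:
            raise ValueError("empty grid")
        G1, _ = _true_moduli_frequency(truth, omega)
        gamma0 = np.full_like(omega, g["gamma0"])
        time_s = np.full_like(omega, np.nan)

    G2 = truth.loss_ratio * G1
    if truth.noise_cv > 0:
        G1 = G1 * np.exp(rng.normal(0.0, truth.noise_cv, G1.shape))
        G2 = G2 * np.exp(rng.normal(0.0, truth.noise_cv, G2.shape))
    torque = TORQUE_COEFF * np.hypot(G1, G2) * gamma0

    return pd.DataFrame({
        "test_type": test_type,
        "DIV": div,
        "replicate": replicate,
        "time_s": time_s,
        "omega_rad_s": omega,
        "gamma0_pct": gamma0,
        "G1_Pa": G1,
        "G2_Pa": G2,
        "torque_nNm": torque,
    })[SWEEP_COLUMNS]
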