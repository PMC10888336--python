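"""End-to-end orchestration of the functional and rheological pipelines.

``run_functional`` chains simulation (or loading) of a calcium recording
through trace processing, spike inference, transfer-entropy connectivity
and network metrics; ``run_rheology`` chains sweep generation (or loading)
through torque filtering, plateau/transient reduction, Young's modulus and
developmental-stage statistics.  Both are driven by a :class:`RunConfig`
(YAML-loadable, unknown keys rejected) and are bit-reproducible for a fixed
seed; every file written carries a JSON sidecar with the full configuration
and input checksums.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import fluoro, io, netmetrics, rheo, synthdata, te_connectivity
from .presets import functional_preset, plateau_trajectory, rheo_preset
from .synthdata import CalciumParams, RheoTruth, SpikeSimParams
from .types import FluorescenceRecording

__all__ = ["RunConfig", "RunReport", "run_functional", "run_rheology",
           "embed_in_roi_field"]

_CONFIG_SECTIONS = {"preset", "seed", "network", "spikes", "calcium",
                    "processing", "te", "metrics", "rheology"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``processing.embed_grid`` controls whether simulated neuron traces are
    embedded into the full 900-ROI imaging grid (background ROIs carry
    noise only) before the activity filter, or fed to the filter directly.
    """

    preset: str | None = None
    seed: int = 0
    network: dict = dc_field(default_factory=dict)
    spikes: dict = dc_field(default_factory=dict)
    calcium: dict = dc_field(default_factory=dict)
    processing: dict = dc_field(default_factory=dict)
    te: dict = dc_field(default_factory=dict)
    metrics: dict = dc_field(default_factory=dict)
    rheology: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> "RunConfig":
        """Apply the preset (if any) underneath the explicit settings."""
        if self.preset is None:
            return self
        base = functional_preset(self.preset) if self.preset in \
            ("T1-like", "T2-like") else {}
        merged = {k: {**base.get(k, {}), **getattr(self, k)}
                  for k in ("network", "spikes", "calcium")}
        return RunConfig(preset=self.preset, seed=self.seed,
                         processing=dict(self.processing), te=dict(self.te),
                         metrics=dict(self.metrics),
                         rheology=dict(self.rheology), **merged)


@dataclass
class RunReport:
    """Headline metrics, per-stage timings and warnings of one run."""

    headline: dict
    timings: dict
    warnings: list[str]
    config: dict
    outputs: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(
            {"headline": self.headline, "timings": self.timings,
             "warnings": self.warnings, "config": self.config,
             "outputs": self.outputs}, indent=1, default=str))
        return Path(path)


def embed_in_roi_field(rec: FluorescenceRecording, net: synthdata.GroundTruthNetwork,
                       calcium: CalciumParams, grid_side: int = 30,
                       field_um: float = synthdata.FIELD_MM * 1000.0,
                       seed: int = 0) -> FluorescenceRecording:
    """Embed per-neuron traces into the full ROI grid of the imaging field.

    Each neuron is assigned to the grid cell its (x, y) position projects
    to; cells holding several neurons sum their transients (their ROIs mix).
    All remaining cells are background: baseline plus noise (and drift) with
    no transients — what the activity filter is expected to discard.
    """
    rng = np.random.default_rng(seed)
    n_cells = grid_side * grid_side
    xy = net.positions[:, :2] + field_um / 2.0
    cell = (np.clip((xy // (field_um / grid_side)), 0, grid_side - 1)
            .astype(int))
    flat = cell[:, 1] * grid_side + cell[:, 0]

    F = np.full((n_cells, rec.n_frames), calcium.baseline_F0)
    if calcium.noise_sd > 0:
        F += rng.normal(0.0, calcium.noise_sd, size=F.shape)
    if calcium.drift_amplitude > 0:
        t = rec.times
        phase = rng.uniform(0, 2 * np.pi, n_cells)
        F += calcium.drift_amplitude * np.sin(
            2 * np.pi * t[None, :] / calcium.drift_period + phase[:, None])
    for i in range(net.n_neurons):
        F[flat[i]] += rec.F[i] - calcium.baseline_F0
    np.clip(F, 0.0, None, out=F)
    centers = (np.stack(np.meshgrid(np.arange(grid_side), np.arange(grid_side)),
                        axis=-1).reshape(-1, 2) + 0.5) * (field_um / grid_side)
    return FluorescenceRecording(F=F, frame_rate=rec.frame_rate,
                                 roi_positions=centers)


def _catch_warnings(record: list[str]):
    class _Ctx(warnings.catch_warnings):
        def __enter__(self_inner):
            log = super().__enter__()
            warnings.simplefilter("always")
            self_inner._log = log
            return log

        def __exit__(self_inner, *exc):
            for w in self_inner._log:
                record.append(str(w.message))
            return super().__exit__(*exc)
    return _Ctx(record=True)


def run_functional(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Simulate (or load), process, infer and measure one functional run.

    Stages: ground-truth network -> spike simulation -> calcium rendering
    -> (optional) embedding in the 900-ROI field -> activity filter ->
    dF/F -> Schmitt trigger -> population activity & synchronization ->
    transfer-entropy connectivity (optionally excluding detected burst
    windows) -> network traits -> exports.
    """
    cfg = config.resolved()
    proc = cfg.processing
    timings: dict[str, float] = {}
    warns: list[str] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = round(time.perf_counter() - timings[stage], 3)

    try:
        tic("simulate")
        net = synthdata.generate_network(seed=cfg.seed, **cfg.network)
        sim = SpikeSimParams(seed=cfg.seed + 1, **cfg.spikes)
        true_raster = synthdata.simulate_spikes(net, sim)
        cal = CalciumParams(seed=cfg.seed + 2, **cfg.calcium)
        rec = synthdata.render_fluorescence(true_raster, cal)
        toc("simulate")
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        tic("process")
        with _catch_warnings(warns):
            if proc.get("embed_grid", False):
                rec = embed_in_roi_field(rec, net, cal,
                                         grid_side=proc.get("grid_side", 30),
                                         seed=cfg.seed + 3)
            filtered, filt_report = fluoro.filter_active_rois(
                rec, amp_min=proc.get("amp_min", 0.1),
                min_events=proc.get("min_events", 1))
            traces = fluoro.normalize_traces(filtered)
            raster = fluoro.schmitt_detect(traces)
            pa = fluoro.population_activity(
                raster, window=proc.get("window", 0.5), step=proc.get("step", 0.1))
            peaks = fluoro.detect_sync_peaks(pa)
            rate = fluoro.firing_rate(raster)
        toc("process")
    except Exception as err:
        raise RuntimeError(f"stage 'process' failed: {err}") from err

    try:
        tic("infer")
        te_cfg = te_connectivity.TEConfig(seed=cfg.seed + 4, **{
            k: v for k, v in cfg.te.items() if k != "conditioning"})
        bins = te_connectivity.binarize_raster(raster, te_cfg.bin_s)
        exclude = None
        if cfg.te.get("conditioning") == "exclude-burst-windows" and peaks.size:
            exclude = np.zeros(bins.shape[1], dtype=bool)
            for pt in peaks:
                a = int(max(0, (pt - pa.window) / te_cfg.bin_s))
                b = int(min(bins.shape[1], (pt + pa.window) / te_cfg.bin_s + 1))
                exclude[a:b] = True
        with _catch_warnings(warns):
            ec = te_connectivity.te_matrix(bins, te_cfg, exclude_bins=exclude)
        toc("infer")
    except Exception as err:
        raise RuntimeError(f"stage 'infer' failed: {err}") from err

    try:
        tic("metrics")
        traits = netmetrics.network_traits(
            ec.A, seed=cfg.metrics.get("seed", 0),
            symmetrize=cfg.metrics.get("symmetrize", False))
        toc("metrics")
    except Exception as err:
        raise RuntimeError(f"stage 'metrics' failed: {err}") from err

    headline = {
        "n_neurons_true": net.n_neurons,
        "n_rois_kept": filt_report["n_kept"],
        "firing_rate_per_min": round(rate, 4),
        "n_sync_peaks": int(peaks.size),
        "N": traits.n, "L": traits.L,
        "mean_k": round(traits.mean_k, 4),
        "GE": round(traits.GE, 4),
        "Q": None if np.isnan(traits.Q) else round(traits.Q, 4),
    }
    report = RunReport(headline=headline, timings=timings, warnings=warns,
                       config=asdict(cfg))

    if out is not None:
        params = asdict(cfg)
        io.write_raster(out / "raster.csv", raster)
        io.write_sidecar(out / "raster.csv", params)
        io.write_population_activity(out / "population_activity.csv", pa)
        io.write_matrix(out / "adjacency.csv", ec.A, ids=filtered.roi_ids)
        io.write_matrix(out / "z_matrix.csv", np.round(ec.z, 6), ids=filtered.roi_ids)
        te_connectivity.export_network(
            ec, str(out / "network.gexf"),
            positions=filtered.roi_positions, communities=traits.communities)
        io.write_ground_truth(out / "ground_truth.json", net, extra=params)
        (out / "traits.json").write_text(json.dumps(traits.to_dict(), indent=1))
        report.outputs = {p.name: io.checksum(p) for p in sorted(out.iterdir())
                          if p.suffix in (".csv", ".json", ".gexf")}
        report.to_json(out / "report.json")
    return report


# --------------------------------------------------------------------------
# rheology pipeline


def run_rheology(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Generate (or load) sweep tables per DIV, reduce them to Young's
    moduli and compare developmental stages.

    The rheology block selects a preset (``T1-like``/``T2-like``/
    ``T3-like``) or gives an explicit plateau trajectory; each measurement
    session produces time, strain and frequency sweeps for each replicate,
    with multiplicative measurement noise and log-normal sample-to-sample
    scatter.
    """
    cfg = config.resolved()
    rblock = dict(cfg.rheology)
    drop_torque = bool(rblock.pop("drop_torque_column", False))
    preset_name = rblock.pop("preset", "T2-like")
    preset = rheo_preset(preset_name)
    preset.update(rblock)
    rng = np.random.default_rng(cfg.seed)
    timings: dict[str, float] = {}
    warns: list[str] = []
    t0 = time.perf_counter()

    estimates: list[rheo.YoungsModulusEstimate] = []
    per_div: dict[int, dict] = {}
    lvr_flags = 0
    for div in preset["divs"]:
        g_true = float(plateau_trajectory(preset, div))
        div_E = []
        for rep in range(preset["replicates"]):
            scatter = float(np.exp(rng.normal(0.0, preset["sample_scatter_rel"])))
            truth = RheoTruth(
                plateau_G1=g_true * scatter,
                transient_time_true=preset["transient_time_true"],
                thickening_onset=preset["thickening_onset"],
                noise_cv=preset["noise_cv"],
            )
            sub = int(rng.integers(0, 2 ** 31 - 1))
            with _catch_warnings(warns):
                fsweep = synthdata.generate_sweeps(truth, "frequency", div=div,
                                                  replicate=rep, seed=sub)
                ssweep = synthdata.generate_sweeps(truth, "strain", div=div,
                                                   replicate=rep, seed=sub + 1)
                tsweep = synthdata.generate_sweeps(truth, "time", div=div,
                                                   replicate=rep, seed=sub + 2)
                if drop_torque:  # emulate a sweep table without torque readout
                    fsweep = fsweep.drop(columns=["torque_nNm"])
                    ssweep = ssweep.drop(columns=["torque_nNm"])
                fsweep = rheo.filter_torque_floor(fsweep)
                ssweep = rheo.filter_torque_floor(ssweep)
                lvr = rheo.check_lvr(ssweep)
                t_T, _ = rheo.detect_transient(tsweep)
                summary = rheo.plateau_modulus(fsweep, div=div)
            if not lvr["linear"] or lvr["moduli_cross"]:
                lvr_flags += 1
            est = rheo.youngs_modulus(summary.plateau_G1, summary.plateau_G2,
                                      div=div, replicate=rep)
            estimates.append(est)
            div_E.append(est.E)
        per_div[div] = {"E_mean": float(np.mean(div_E)),
                        "E_sem": float(np.std(div_E, ddof=1) / np.sqrt(len(div_E))),
                        "n": len(div_E), "transient_time_s": t_T}

    with _catch_warnings(warns):
        groups = rheo.stage_group(estimates)
    try:
        comparison = rheo.compare_stages(groups)
        comp_dict = {"means": comparison.means, "sds": comparison.sds,
                     "n": comparison.n, "p_values": comparison.p_values,
                     "stars": comparison.stars, "test": comparison.test}
    except ValueError as err:
        comp_dict = {"error": str(err)}
    timings["rheology"] = round(time.perf_counter() - t0, 3)

    headline = {
        "preset": preset_name,
        "E_per_DIV": per_div,
        "stage_comparison": comp_dict,
        "lvr_flags": lvr_flags,
    }
    report = RunReport(headline=headline, timings=timings, warnings=warns,
                       config=asdict(cfg))
    if out := (Path(outdir) if outdir is not None else None):
        out.mkdir(parents=True, exist_ok=True)
        (out / "stage_report.json").write_text(json.dumps(headline, indent=1,
                                                          default=str))
        report.to_json(out / "report.json")
    return report
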