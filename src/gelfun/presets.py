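"""Named study-condition presets.

The three hydrogel formulations behave very differently as culture
substrates, and the presets emulate those regimes end to end:

* ``T1-like`` — soft gel, lively culture: denser ground-truth connectivity,
  network-wide synchronous events (sharp population-activity peaks), firing
  in the ~3 activations/neuron/min regime.
* ``T2-like`` — stiff gel, viable but subdued culture: sparser connectivity,
  no synchronous drive, ~2 activations/neuron/min.
* ``T3-like`` — gel without a developing network (functional preset not
  defined; rheology only).

Rheology presets give each formulation its storage-modulus plateau
trajectory over days in vitro (DIV): T1 starts around G' ~ 120 Pa
(E ~ 300 Pa) and softens quickly; T2 starts around G' ~ 235 Pa (E ~ 590 Pa)
and decays gradually to roughly half; T3 stays flat near G' ~ 100 Pa
(E ~ 250 Pa).  The measurement schedule covers three weeks with three
replicates per session, and estimates are grouped into early (DIV 1-3),
young (DIV 4-8) and mature (DIV 13-20) stages.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FUNCTIONAL_PRESETS", "RHEO_PRESETS", "functional_preset",
           "rheo_preset", "plateau_trajectory"]


FUNCTIONAL_PRESETS: dict[str, dict] = {
    "T1-like": {
        "network": {"n_neurons": 100, "density": 0.10, "n_communities": 4,
                    "spatial_decay": 2000.0},
        "spikes": {"duration": 900.0, "baseline_rate": 1.2 / 60,
                   "coupling_scale": 0.05, "sync_drive_rate": 1.0 / 45,
                   "refractory": 0.3},
        "calcium": {"amplitude_per_spike": 0.8, "noise_sd": 0.5,
                    "drift_amplitude": 0.5, "baseline_F0": 20.0},
    },
    "T2-like": {
        "network": {"n_neurons": 100, "density": 0.06, "n_communities": 4,
                    "spatial_decay": 2600.0},
        "spikes": {"duration": 900.0, "baseline_rate": 1.5 / 60,
                   "coupling_scale": 0.05, "sync_drive_rate": 0.0,
                   "refractory": 0.3},
        "calcium": {"amplitude_per_spike": 0.8, "noise_sd": 0.5,
                    "drift_amplitude": 0.5, "baseline_F0": 20.0},
    },
}

# storage-modulus plateau trajectories G'(DIV) = late + (early-late)*exp(-(DIV-1)/tau)
RHEO_PRESETS: dict[str, dict] = {
    "T1-like": {"G1_early": 120.0, "G1_late": 80.0, "tau_div": 1.5,
                "transient_time_true": 150.0, "thickening_onset": 50.0},
    "T2-like": {"G1_early": 235.0, "G1_late": 135.0, "tau_div": 6.0,
                "transient_time_true": 300.0, "thickening_onset": 50.0},
    "T3-like": {"G1_early": 100.0, "G1_late": 100.0, "tau_div": 5.0,
                "transient_time_true": 150.0, "thickening_onset": 50.0},
}

# measurement schedule: every 3-4 days over three weeks, 3 replicates/session
RHEO_SCHEDULE = {"divs": [1, 2, 3, 4, 6, 8, 13, 16, 20], "replicates": 3,
                 "noise_cv": 0.05, "sample_scatter_rel": 0.15}


def functional_preset(name: str) -> dict:
    if name not in FUNCTIONAL_PRESETS:
        raise KeyError(f"unknown functional preset {name!r}; "
                       f"available: {sorted(FUNCTIONAL_PRESETS)}")
    return {k: dict(v) for k, v in FUNCTIONAL_PRESETS[name].items()}


def rheo_preset(name: str) -> dict:
    if name not in RHEO_PRESETS:
        raise KeyError(f"unknown rheology preset {name!r}; "
                       f"available: {sorted(RHEO_PRESETS)}")
    out = dict(RHEO_PRESETS[name])
    out.update({k: v for k, v in RHEO_SCHEDULE.items()})
    return out


def plateau_trajectory(preset: dict, div: int | np.ndarray) -> np.ndarray:
    """True plateau G' (Pa) at a given DIV for a rheology preset."""
    early, late, tau = preset["G1_early"], preset["G1_late"], preset["tau_div"]
    return late + (early - late) * np.exp(-(np.asarray(div) - 1) / tau)
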