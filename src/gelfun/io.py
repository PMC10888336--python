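"""Plain-text readers and writers for every pipeline artifact.

All formats are deliberately simple and round-trip exactly:

* trace tables — wide CSV, column 0 ``time_s``, one column per ROI;
* rasters — two-column CSV ``neuron_id, time_s`` sorted by neuron then time;
* population activity — CSV ``t_center_s, fraction_active``;
* sweep tables — CSV with the schema of ``synthdata.generate_sweeps``;
* adjacency / z matrices — dense CSV with neuron ids as header row/column;
* ground truth — JSON (edge list, positions, labels, parameters, seed);
* frame stacks — multi-page 8-bit grayscale TIFF.

Every writer can attach a JSON sidecar (``<file>.meta.json``) carrying the
generating parameters and sha256 checksums of the inputs, so each stage
output is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import SWEEP_COLUMNS, GroundTruthNetwork
from .types import FluorescenceRecording, PopulationActivity, SpikeRaster

__all__ = [
    "checksum",
    "write_sidecar",
    "read_sidecar",
    "write_traces",
    "read_traces",
    "write_raster",
    "read_raster",
    "write_population_activity",
    "write_sweeps",
    "read_sweeps",
    "write_matrix",
    "read_matrix",
    "write_ground_truth",
    "read_ground_truth",
    "write_tiff",
    "read_tiff",
]


def checksum(path: str | Path) -> str:
    """sha256 of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(path: str | Path, params: dict,
                  inputs: dict[str, str | Path] | None = None) -> Path:
    """Write ``<path>.meta.json`` with parameters and input checksums."""
    side = Path(str(path) + ".meta.json")
    meta = {"file": Path(path).name, "sha256": checksum(path), "params": params}
    if inputs:
        meta["inputs"] = {name: {"file": str(p), "sha256": checksum(p)}
                          for name, p in inputs.items()}
    side.write_text(json.dumps(meta, indent=1, default=str))
    return side


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".meta.json").read_text())


# --------------------------------------------------------------------------
# traces


def write_traces(path: str | Path, rec: FluorescenceRecording) -> Path:
    df = pd.DataFrame(rec.F.T, columns=[f"roi_{int(i)}" for i in rec.roi_ids])
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_traces(path: str | Path) -> FluorescenceRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace table needs at least 2 frames")
    frame_rate = 1.0 / float(np.median(np.diff(t)))
    ids = np.array([int(c.split("_", 1)[1]) for c in df.columns[1:]])
    return FluorescenceRecording(F=df.iloc[:, 1:].to_numpy().T,
                                 frame_rate=frame_rate, roi_ids=ids)


# --------------------------------------------------------------------------
# rasters and population activity


def write_raster(path: str | Path, raster: SpikeRaster) -> Path:
    rows = [(i, t) for i, ev in enumerate(raster.events) for t in ev]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    with open(path, "w") as fh:
        fh.write(f"# duration_s={raster.duration!r} n_neurons={raster.n_neurons}\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return Path(path)


def read_raster(path: str | Path) -> SpikeRaster:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    fields = dict(kv.split("=") for kv in header.lstrip("# ").split())
    duration = float(fields["duration_s"])
    n = int(fields["n_neurons"])
    events = [np.empty(0)] * n
    for i, grp in df.groupby("neuron_id"):
        events[int(i)] = np.sort(grp["time_s"].to_numpy(dtype=float))
    return SpikeRaster(events=events, duration=duration)


def write_population_activity(path: str | Path, pa: PopulationActivity) -> Path:
    pd.DataFrame({"t_center_s": pa.t_centers,
                  "fraction_active": pa.fraction_active}).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)


# --------------------------------------------------------------------------
# sweeps and matrices


def write_sweeps(path: str | Path, sweeps: pd.DataFrame) -> Path:
    sweeps[SWEEP_COLUMNS].to_csv(path, index=False, float_format="%.9g")
    return Path(path)


def read_sweeps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SWEEP_COLUMNS) - {"time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"sweep table missing columns: {sorted(missing)}")
    return df


def write_matrix(path: str | Path, M: np.ndarray,
                 ids: np.ndarray | None = None) -> Path:
    n = M.shape[0]
    ids = np.arange(n) if ids is None else np.asarray(ids)
    df = pd.DataFrame(M, index=ids, columns=ids)
    df.to_csv(path, index_label="neuron_id")
    return Path(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), df.index.to_numpy()


# --------------------------------------------------------------------------
# ground truth and frame stacks


def write_ground_truth(path: str | Path, net: GroundTruthNetwork,
                       extra: dict | None = None) -> Path:
    d = net.to_dict()
    if extra:
        d["params"] = extra
    Path(path).write_text(json.dumps(d))
    return Path(path)


def read_ground_truth(path: str | Path) -> GroundTruthNetwork:
    return GroundTruthNetwork.from_dict(json.loads(Path(path).read_text()))


def write_tiff(path: str | Path, stack: np.ndarray) -> Path:
    import tifffile
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8))
    return Path(path)


def read_tiff(path: str | Path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)
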