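"""Shared formats and plumbing: trace container, CSV import, projector export.

The trace container is an HDF5 file with datasets ``/traces`` (N x T x 2
float32), ``/meta`` (per-trace JSON strings), ``/labels/<name>`` (length N)
and ``/frame_labels/<name>`` (N x T).  One-color traces zero-fill the second
channel; the convention is enforced on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .simulate import Trace

__all__ = [
    "RunConfig",
    "write_trace_container",
    "read_trace_container",
    "import_csv_traces",
    "export_projector",
]

SCHEMA_VERSION = 1


class RunConfig(BaseModel):
    """Seeds and settings serialized alongside every artifact."""

    simulator_seed: int = 0
    model_seed: int = 0
    training_seed: int = 0
    reducer_seed: int = 0
    n_frames: int = 2000
    patch_width: int = 50
    embed_dim: int = 96
    n_layers: int = 4
    n_heads: int = 4
    extra: dict = Field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------

def write_trace_container(
    path: str | Path,
    traces: Sequence[Trace],
    labels: Optional[dict[str, np.ndarray]] = None,
    frame_labels: Optional[dict[str, np.ndarray]] = None,
    run_config: Optional[RunConfig] = None,
) -> None:
    import h5py

    N = len(traces)
    T = traces[0].n_frames
    data = np.stack([t.intensities for t in traces]).astype(np.float32)
    meta = [
        json.dumps(
            {
                "trace_id": t.trace_id,
                "frame_period": t.frame_period,
                "condition_tag": t.condition_tag,
                "one_color": t.is_one_color,
            }
        )
        for t in traces
    ]
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if run_config is not None:
            f.attrs["config_hash"] = run_config.config_hash()
            f.attrs["run_config"] = json.dumps(run_config.model_dump())
        f.create_dataset("traces", data=data)
        f.create_dataset("meta", data=np.array(meta, dtype=h5py.string_dtype()))
        for group, src, expect in (("labels", labels, (N,)),
                                   ("frame_labels", frame_labels, (N, T))):
            if not src:
                continue
            g = f.create_group(group)
            for name, arr in src.items():
                arr = np.asarray(arr)
                if arr.shape != expect:
                    raise ValueError(
                        f"dataset {group}/{name} has shape {arr.shape}, "
                        f"expected {expect}"
                    )
                g.create_dataset(name, data=arr)


def read_trace_container(path: str | Path) -> dict:
    """Read a container; returns traces, labels, frame_labels and metadata."""
    import h5py

    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unknown trace-container schema version {version} "
                f"(expected {SCHEMA_VERSION})"
            )
        data = f["traces"][()]
        meta = [json.loads(m) for m in f["meta"].asstr()[()]]
        N = data.shape[0]
        labels, frame_labels = {}, {}
        for group, dst in (("labels", labels), ("frame_labels", frame_labels)):
            if group in f:
                for name, ds in f[group].items():
                    arr = ds[()]
                    if arr.shape[0] != N:
                        raise ValueError(
                            f"dataset {group}/{name} has length {arr.shape[0]}"
                            f" but the container holds {N} traces"
                        )
                    dst[name] = arr
        config_json = f.attrs.get("run_config")

    traces = []
    for i in range(N):
        m = meta[i] if i < len(meta) else {}
        arr = data[i].astype(np.float32)
        if m.get("one_color"):
            arr[:, 1] = 0.0  # enforce the zero-filled channel convention
        traces.append(
            Trace(
                arr,
                frame_period=m.get("frame_period", 1.0),
                condition_tag=m.get("condition_tag"),
                trace_id=m.get("trace_id"),
            )
        )
    out = {"traces": traces, "labels": labels, "frame_labels": frame_labels}
    if config_json is not None:
        out["run_config"] = json.loads(config_json)
    return out


# ---------------------------------------------------------------------------
# CSV import
# ---------------------------------------------------------------------------

def import_csv_traces(directory: str | Path) -> list[Trace]:
    """Per-trace CSVs (header ``frame,donor[,acceptor]``), ordered by name."""
    import pandas as pd

    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    traces = []
    for p in paths:
        df = pd.read_csv(p)
        cols = {c.strip().lower(): c for c in df.columns}
        if "frame" not in cols or "donor" not in cols:
            raise ValueError(f"{p.name}: expected columns frame,donor[,acceptor]")
        frames = df[cols["frame"]].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError(f"{p.name}: frame column is not contiguous")
        donor = df[cols["donor"]].to_numpy(dtype=np.float32)
        if "acceptor" in cols:
            acceptor = df[cols["acceptor"]].to_numpy(dtype=np.float32)
        else:
            acceptor = np.zeros_like(donor)
        traces.append(Trace(np.stack([donor, acceptor], axis=1),
                            trace_id=p.stem))
    return traces


# ---------------------------------------------------------------------------
# projector export
# ---------------------------------------------------------------------------

def export_projector(
    points: np.ndarray,
    metadata: dict[str, Sequence],
    out_path: str | Path,
    manifest: Optional[dict] = None,
) -> None:
    """TSV of 2-D/3-D coordinates plus metadata columns, with a JSON manifest."""
    import pandas as pd

    points = np.asarray(points)
    n = points.shape[0]
    cols = {f"dim{j}": points[:, j] for j in range(points.shape[1])}
    for name, vals in metadata.items():
        if len(vals) != n:
            raise ValueError(f"metadata column {name!r} has length {len(vals)}, "
                             f"expected {n}")
        cols[name] = list(vals)
    out_path = Path(out_path)
    pd.DataFrame(cols).to_csv(out_path, sep="\t", index=False)
    manifest = dict(manifest or {})
    manifest.setdefault("n_points", n)
    manifest.setdefault("columns", list(cols))
    out_path.with_suffix(".manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
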