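"""Reading and writing the pipeline's on-disk formats.

Cluster tables and traces are plain CSV; image pairs are multi-channel TIFF
with a JSON sidecar recording channel order and pixel size; configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from ._util import ConfigError
from .bleach import BleachTrace, StepCountResult
from .imaging import DomainImageSet
from .synthetic import ClusterObservation

__all__ = [
    "write_clusters_csv",
    "read_clusters_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_image_set",
    "read_image_set",
    "write_results_csv",
    "load_yaml_config",
]

PathLike = Union[str, Path]

CLUSTER_COLUMNS = [
    "cluster_id",
    "condition",
    "copy_number",
    "vesicle_bound",
    "true_monomers",
    "true_oligomers",
]


def _tri_state(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        v = value.strip().upper()
        if v in ("", "NA", "NAN", "NONE"):
            return None
        return bool(int(v))
    return bool(int(value))


def write_clusters_csv(clusters: Sequence[ClusterObservation], path: PathLike) -> None:
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "condition": c.condition,
                "copy_number": c.copy_number,
                "vesicle_bound": "NA" if c.vesicle_bound is None else int(c.vesicle_bound),
                "true_monomers": "" if c.true_monomers is None else c.true_monomers,
                "true_oligomers": "" if c.true_oligomers is None else c.true_oligomers,
            }
        )
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, index=False)


def read_clusters_csv(path: PathLike) -> list[ClusterObservation]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if "copy_number" not in df.columns:
        raise ConfigError(f"{path}: missing required column 'copy_number'")
    out = []
    for i, row in df.iterrows():
        out.append(
            ClusterObservation(
                cluster_id=int(row.get("cluster_id", i)),
                condition=""
                if pd.isna(row.get("condition"))
                else str(row.get("condition", "")),
                copy_number=int(row["copy_number"]),
                vesicle_bound=_tri_state(row.get("vesicle_bound")),
                true_monomers=None
                if pd.isna(row.get("true_monomers"))
                else int(row["true_monomers"]),
                true_oligomers=None
                if pd.isna(row.get("true_oligomers"))
                else int(row["true_oligomers"]),
            )
        )
    return out


def write_traces_csv(traces: Sequence[BleachTrace], path: PathLike) -> None:
    """Long format: trace_id, frame, intensity."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(tr.intensity.size),
                    "intensity": tr.intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: PathLike, frame_interval: float = 1.0) -> list[BleachTrace]:
    df = pd.read_csv(path)
    if "trace_id" in df.columns:
        return [
            BleachTrace(
                trace_id=str(tid),
                intensity=grp.sort_values("frame")["intensity"].to_numpy(),
                frame_interval=frame_interval,
            )
            for tid, grp in df.groupby("trace_id", sort=True)
        ]
    return [
        BleachTrace(
            trace_id=Path(path).stem,
            intensity=df.sort_values("frame")["intensity"].to_numpy(),
            frame_interval=frame_interval,
        )
    ]


def write_results_csv(results: Sequence[StepCountResult], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "trace_id": r.trace_id,
                "method": r.method,
                "copy_number": r.copy_number_estimate,
                "unit_step": r.unit_step,
                "I0": r.initial_intensity,
                "residual": r.fit_residual,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_image_set(images: DomainImageSet, with_path: PathLike, without_path: PathLike) -> None:
    """Write the pair as TIFFs plus a JSON sidecar next to the 'with' image."""
    tifffile.imwrite(str(with_path), images.image_with.astype(np.float64))
    tifffile.imwrite(str(without_path), images.image_without.astype(np.float64))
    sidecar = {
        "channels": ["pip2", "lipopeptide"],
        "pixel_size_um": images.pixel_size,
        "background": list(images.background),
    }
    Path(str(with_path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_image_set(
    with_path: PathLike,
    without_path: PathLike,
    pixel_size: Optional[float] = None,
) -> DomainImageSet:
    sidecar_path = Path(str(with_path) + ".json")
    background = (0.0, 0.0)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size = pixel_size or sidecar.get("pixel_size_um")
        background = tuple(sidecar.get("background", background))
    if pixel_size is None:
        raise ConfigError("pixel size not given and no sidecar found")
    return DomainImageSet(
        image_with=tifffile.imread(str(with_path)),
        image_without=tifffile.imread(str(without_path)),
        pixel_size=float(pixel_size),
        background=background,
    )


def load_yaml_config(path: PathLike) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return doc
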