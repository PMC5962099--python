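"""Trained-map archives.

A map is stored as a single JSON document (text, portable, diff-able).
Floats are serialized with Python's shortest-repr round-trip guarantee, so
``load_map(save_map(m))`` reproduces every numeric field bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .engine import CodebookSet, TrainedMap, TrainingParams
from .grid import GridSpec

FORMAT_VERSION = 1


def save_map(map_: TrainedMap, path: str | Path) -> None:
    doc = {
        "format": "xyfsom-map",
        "version": FORMAT_VERSION,
        "grid": {
            "n_rows": map_.grid.n_rows,
            "n_cols": map_.grid.n_cols,
            "topology": map_.grid.topology,
            "neighborhood": map_.grid.neighborhood,
        },
        "params": {
            "rlen": map_.params.rlen,
            "lr_start": map_.params.lr_start,
            "lr_end": map_.params.lr_end,
            "alpha_xy": map_.params.alpha_xy,
            "radius_start": map_.params.radius_start,
            "seed": map_.params.seed,
        },
        "species_names": list(map_.species_names),
        "class_labels": list(map_.class_labels),
        "factors": list(map_.factors),
        "column_means": map_.column_means.tolist(),
        "column_sds": map_.column_sds.tolist(),
        "x_weights": map_.codebooks.x_weights.tolist(),
        "y_weights": map_.codebooks.y_weights.tolist(),
        "quantization_error": map_.quantization_error,
    }
    Path(path).write_text(json.dumps(doc))


def load_map(path: str | Path) -> TrainedMap:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path.name}: not a valid map archive ({err})") from err
    if not isinstance(doc, dict) or doc.get("format") != "xyfsom-map":
        raise ValueError(f"{path.name}: not an xyfsom map archive")
    version = doc.get("version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path.name}: archive version {version} not supported "
            f"(this build reads version {FORMAT_VERSION})"
        )
    grid = GridSpec(**doc["grid"])
    params = TrainingParams(**doc["params"])
    codebooks = CodebookSet(
        x_weights=np.array(doc["x_weights"], dtype=float),
        y_weights=np.array(doc["y_weights"], dtype=float),
    )
    return TrainedMap(
        grid=grid,
        codebooks=codebooks,
        column_means=np.array(doc["column_means"], dtype=float),
        column_sds=np.array(doc["column_sds"], dtype=float),
        species_names=tuple(doc["species_names"]),
        class_labels=tuple(doc["class_labels"]),
        factors=tuple(doc["factors"]),
        params=params,
        quantization_error=float(doc["quantization_error"]),
    )
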