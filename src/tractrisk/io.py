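"""Tabular and geographic interchange formats.

All tabular artifacts are headered CSV with a single leading ``#`` comment
line carrying provenance (package version, seed, stage). Tract geography is
a GeoJSON FeatureCollection with one Feature per tract; each feature stores
``tract_id`` and its rook-neighbor list as properties so an adjacency-only
round trip never needs geometry operations.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import shape, mapping

from . import __version__
from .errors import DataError
from .population import Tract, validate_tracts


def provenance_line(**meta) -> str:
    fields = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# tractrisk v{__version__} {fields}".rstrip()


def write_table(df: pd.DataFrame, path, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(**meta) + "\n")
        df.to_csv(fh, index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_geojson(tracts: list[Tract], path, **meta) -> None:
    validate_tracts(tracts)
    features = []
    for t in tracts:
        features.append({
            "type": "Feature",
            "properties": {
                "tract_id": t.tract_id,
                "neighbors": sorted(t.neighbors),
            },
            "geometry": mapping(t.geometry) if t.geometry is not None else None,
        })
    doc = {
        "type": "FeatureCollection",
        "metadata": {"generator": f"tractrisk v{__version__}", **meta},
        "features": features,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def read_geojson(path) -> list[Tract]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    tracts = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        if "tract_id" not in props:
            raise DataError(f"{path}: feature without tract_id property")
        geom = shape(feat["geometry"]) if feat.get("geometry") else None
        tracts.append(Tract(
            tract_id=str(props["tract_id"]),
            neighbors=frozenset(str(n) for n in props.get("neighbors", [])),
            geometry=geom,
        ))
    validate_tracts(tracts)
    return tracts
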