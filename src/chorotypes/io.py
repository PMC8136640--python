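"""Reading range maps and writing scan results.

Readers accept GeoJSON (one feature per species, id in the
``species_id`` -- or ``id``/``name`` -- property) and WKT tables (CSV
with ``species_id`` and ``wkt`` columns).  Multiple features sharing an
id are unioned into one range.  Because the congruence index is a
ratio of planar areas, inputs that look like raw longitude/latitude are
refused unless the caller either asserts the coordinates are planar or
asks for the built-in spherical cylindrical equal-area projection.

Writers emit plain CSV/JSON with fixed column order and 6-decimal
fixed-point numbers so reruns diff byte-identically.
"""

from __future__ import annotations

import csv
import json
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
from shapely import union_all
from shapely.geometry import mapping as geojson_mapping, shape
from shapely.ops import transform as geom_transform
import shapely.wkt

from .congruence import CongruenceNetwork, SpeciesRange
from .core import ScanResult
from .postprocess import ChorotypeFamily

__all__ = [
    "read_ranges",
    "write_geojson",
    "write_wkt_csv",
    "write_edge_list",
    "write_partial_table",
    "write_families",
    "write_nested",
    "write_summary",
    "cylindrical_equal_area",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def cylindrical_equal_area(lon, lat, standard_parallel: float = 0.0):
    """Spherical Lambert cylindrical equal-area projection, output in km.

    x = R * lon * cos(phi_s),  y = R * sin(lat) / cos(phi_s).  Equal-area
    on the sphere, so area ratios (all the congruence index uses) are
    preserved up to the spherical-vs-ellipsoidal approximation.
    """
    k = math.cos(math.radians(standard_parallel))
    rad = math.pi / 180.0
    import numpy as np

    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return EARTH_RADIUS_KM * lon * rad * k, EARTH_RADIUS_KM * np.sin(lat * rad) / k


def _looks_geographic(geoms: Sequence) -> bool:
    minx = min(g.bounds[0] for g in geoms)
    miny = min(g.bounds[1] for g in geoms)
    maxx = max(g.bounds[2] for g in geoms)
    maxy = max(g.bounds[3] for g in geoms)
    return -181.0 <= minx <= maxx <= 181.0 and -91.0 <= miny <= maxy <= 91.0


def _apply_projection(geoms: dict, projection: str | None):
    """Refuse lon/lat-looking input unless a projection choice was made."""
    if projection in (None, "planar"):
        if projection is None and _looks_geographic(list(geoms.values())):
            raise ValueError(
                "coordinates look like longitude/latitude; the congruence "
                "index needs equal-area planar coordinates. Re-project the "
                "input, or pass projection='cea' for the built-in cylindrical "
                "equal-area transform, or projection='planar' to assert the "
                "coordinates are already planar."
            )
        return geoms
    if projection == "cea":
        return {
            sid: geom_transform(cylindrical_equal_area, g) for sid, g in geoms.items()
        }
    raise ValueError(f"unknown projection {projection!r} (use 'cea' or 'planar')")


def _feature_id(feature: dict, index: int) -> str:
    props = feature.get("properties") or {}
    for key in ("species_id", "species", "id", "name"):
        if props.get(key) is not None:
            return str(props[key])
    if feature.get("id") is not None:
        return str(feature["id"])
    raise ValueError(f"feature {index} has no species_id/id/name property")


def read_ranges(
    path: str | Path,
    fmt: str | None = None,
    projection: str | None = None,
) -> list[SpeciesRange]:
    """Read species ranges from a GeoJSON file or a WKT CSV table.

    ``fmt`` is inferred from the suffix (``.geojson``/``.json`` vs
    ``.csv``/``.wkt``) when omitted.  Features with the same species id
    are unioned into a single range.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".geojson", ".json"):
            fmt = "geojson"
        elif suffix in (".csv", ".wkt", ".tsv"):
            fmt = "wkt"
        else:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    parts: dict[str, list] = {}
    if fmt == "geojson":
        with open(path) as fh:
            data = json.load(fh)
        features = data["features"] if data.get("type") == "FeatureCollection" else [data]
        for i, feature in enumerate(features):
            sid = _feature_id(feature, i)
            parts.setdefault(sid, []).append(shape(feature["geometry"]))
    elif fmt == "wkt":
        table = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
        missing = {"species_id", "wkt"} - set(table.columns)
        if missing:
            raise ValueError(f"WKT table lacks column(s): {sorted(missing)}")
        for row in table.itertuples(index=False):
            parts.setdefault(str(row.species_id), []).append(
                shapely.wkt.loads(row.wkt)
            )
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'geojson' or 'wkt')")

    geoms = {
        sid: union_all(gs) if len(gs) > 1 else gs[0] for sid, gs in parts.items()
    }
    geoms = _apply_projection(geoms, projection)
    return [SpeciesRange(sid, geom) for sid, geom in geoms.items()]


# ---------------------------------------------------------------------------
# writers

def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_geojson(ranges: Iterable[SpeciesRange], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species_id": r.species_id},
            "geometry": geojson_mapping(r.geometry),
        }
        for r in ranges
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_wkt_csv(ranges: Iterable[SpeciesRange], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "wkt"])
        for r in ranges:
            writer.writerow([r.species_id, r.geometry.wkt])


def write_edge_list(network: CongruenceNetwork, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_a", "species_b", "overlap_area", "cs"])
        for e in network.edges():
            writer.writerow([e.species_a, e.species_b, _fmt(e.overlap_area), _fmt(e.cs)])


def write_partial_table(result: ScanResult, path: str | Path) -> None:
    """Long-format partial-chorotype table, one row per (partial, member)."""
    cols = [
        "reference", "member", "cs_to_reference", "min_depth",
        "ct_max", "ct_min", "richness", "common_area", "total_area", "ratio",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for ref in sorted(result.references):
            for p in result[ref].partials:
                for member in sorted(p.species):
                    cs, depth = p.per_species[member]
                    writer.writerow(
                        [
                            ref, member, _fmt(cs), depth,
                            _fmt(p.ct_max), _fmt(p.ct_min), p.richness,
                            _fmt(p.common_area), _fmt(p.total_area), _fmt(p.ratio),
                        ]
                    )


def write_families(families: Sequence[ChorotypeFamily], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "synonyms", "canonical_members"])
        for f in families:
            writer.writerow(
                [f.name, ";".join(f.synonyms), ";".join(sorted(f.canonical_set))]
            )


def write_nested(
    pairs: Sequence[tuple[frozenset[str], frozenset[str]]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subset", "superset"])
        for sub, sup in pairs:
            writer.writerow([";".join(sorted(sub)), ";".join(sorted(sup))])


def write_summary(summary: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
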