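"""File formats: GeoJSON / WKT for polygons, CSV for tables and barcodes."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import mapping, shape

from .filtration import BettiCurve, FilteredComplex, PersistenceBar, Simplex
from .metrics import CentralityRecord
from .overlap import CoreRange, OverlapRecord, OverlapTable, DEFAULT_EPS_AREA_HA
from .phenology import PhenologyRecord

__all__ = [
    "read_core_ranges",
    "write_core_ranges",
    "write_core_ranges_wkt",
    "read_core_ranges_wkt",
    "read_overlap_table",
    "write_overlap_table",
    "read_complex",
    "write_complex",
    "read_barcode",
    "write_barcode",
    "write_betti_curves",
    "read_phenology",
    "write_phenology",
    "write_centrality",
]

MEMBER_SEP = ";"


def write_core_ranges(ranges: Sequence[CoreRange], path: str | Path) -> None:
    """Write core ranges as an RFC 7946 GeoJSON FeatureCollection."""
    features = []
    for r in ranges:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {
                    "individual_id": r.individual_id,
                    "season": r.season,
                    "year": r.year,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, sort_keys=True), encoding="utf-8")


def read_core_ranges(path: str | Path) -> list[CoreRange]:
    """Read a GeoJSON FeatureCollection of core ranges.

    Every feature must carry an ``individual_id`` property and a valid
    polygonal geometry; failures name the offending feature index.  An
    empty collection is an error, not an empty success.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    features = data.get("features", [])
    if not features:
        raise ValueError(f"{path}: FeatureCollection contains no features")
    ranges = []
    for i, feature in enumerate(features):
        props = feature.get("properties") or {}
        individual_id = props.get("individual_id")
        if not individual_id:
            raise ValueError(f"{path}: feature {i} lacks an individual_id property")
        try:
            geom = shape(feature["geometry"])
            ranges.append(
                CoreRange(
                    individual_id=str(individual_id),
                    geometry=geom,
                    season=props.get("season", "dry"),
                    year=props.get("year"),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: feature {i} ({individual_id!r}): {exc}") from exc
    return ranges


def write_core_ranges_wkt(ranges: Sequence[CoreRange], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in ranges],
            "season": [r.season for r in ranges],
            "year": [r.year for r in ranges],
            "wkt": [r.geometry.wkt for r in ranges],
        }
    )
    df.to_csv(path, index=False)


def read_core_ranges_wkt(path: str | Path) -> list[CoreRange]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: WKT table contains no rows")
    ranges = []
    for i, row in df.iterrows():
        try:
            ranges.append(
                CoreRange(
                    individual_id=str(row["individual_id"]),
                    geometry=shapely_wkt.loads(row["wkt"]),
                    season=str(row["season"]),
                    year=None if pd.isna(row.get("year")) else int(row["year"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return ranges


def write_overlap_table(table: OverlapTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "members": [MEMBER_SEP.join(r.members) for r in table.records],
            "n": [r.n for r in table.records],
            "intersection_ha": [r.intersection_ha for r in table.records],
            "union_ha": [r.union_ha for r in table.records],
            "w": [r.w for r in table.records],
            "alpha": [r.alpha for r in table.records],
        }
    )
    df.to_csv(path, index=False)


def read_overlap_table(
    path: str | Path,
    n_max: int | None = None,
    eps_area: float = DEFAULT_EPS_AREA_HA,
    season: str | None = None,
) -> OverlapTable:
    df = pd.read_csv(path)
    records = [
        OverlapRecord(
            members=tuple(sorted(str(row["members"]).split(MEMBER_SEP))),
            intersection_ha=float(row["intersection_ha"]),
            union_ha=float(row["union_ha"]),
            w=float(row["w"]),
            alpha=float(row["alpha"]),
        )
        for _, row in df.iterrows()
    ]
    if n_max is None:
        n_max = max((r.n for r in records), default=2)
    return OverlapTable(records=records, n_max=n_max, eps_area=eps_area, season=season)


def write_complex(complex: FilteredComplex, path: str | Path) -> None:
    simplices = complex.sorted_simplices()
    df = pd.DataFrame(
        {
            "simplex": [MEMBER_SEP.join(s) for s in simplices],
            "n": [len(s) for s in simplices],
            "entry_alpha": [complex.entries[s] for s in simplices],
        }
    )
    df.to_csv(path, index=False)


def read_complex(path: str | Path, n_max: int | None = None) -> FilteredComplex:
    df = pd.read_csv(path)
    entries: dict[Simplex, float] = {}
    for _, row in df.iterrows():
        simplex = tuple(sorted(str(row["simplex"]).split(MEMBER_SEP)))
        entries[simplex] = float(row["entry_alpha"])
    if n_max is None:
        n_max = max((len(s) for s in entries), default=1)
    cx = FilteredComplex(entries=entries, n_max=n_max)
    cx.validate()
    return cx


def write_barcode(bars: Sequence[PersistenceBar], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "dimension": [b.dimension for b in bars],
            "birth": [b.birth for b in bars],
            "death": [b.death for b in bars],
            "censored": [b.censored for b in bars],
        }
    )
    df.to_csv(path, index=False)


def read_barcode(path: str | Path) -> list[PersistenceBar]:
    df = pd.read_csv(path)
    return [
        PersistenceBar(
            dimension=int(row["dimension"]),
            birth=float(row["birth"]),
            death=float(row["death"]),
            censored=bool(row["censored"]),
        )
        for _, row in df.iterrows()
    ]


def write_betti_curves(curves: Sequence[BettiCurve], path: str | Path) -> None:
    rows = []
    for curve in curves:
        for bp, v in zip(curve.breakpoints, curve.values):
            rows.append({"dimension": curve.dimension, "breakpoint": bp, "value": v})
    pd.DataFrame(rows, columns=["dimension", "breakpoint", "value"]).to_csv(path, index=False)


def write_phenology(records: Sequence, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "period": [r.period for r in records],
            "Tf": [r.tf for r in records],
            "DBH": [r.dbh for r in records],
            "Den": [r.den for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_phenology(path: str | Path) -> list[PhenologyRecord]:
    df = pd.read_csv(path)
    return [
        PhenologyRecord(
            species=str(row["species"]),
            period=int(row["period"]),
            tf=float(row["Tf"]),
            dbh=float(row["DBH"]),
            den=float(row["Den"]),
        )
        for _, row in df.iterrows()
    ]


def write_centrality(records: Sequence[CentralityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "simplex": [MEMBER_SEP.join(r.simplex) for r in records],
            "size": [r.size for r in records],
            "degree": [r.degree for r in records],
        }
    )
    df.to_csv(path, index=False)
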