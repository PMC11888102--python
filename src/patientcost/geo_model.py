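"""Geography domain types, file I/O and a synthetic geography generator.

The model operates on small health regions (the smallest unit carrying a
population and a 1-7 urban/rural class code), grouped into broader health
authorities, with point facilities (emergency departments, taken as the
nearest place to access in-person care) and a road network whose edges
carry street length and speed limit.

The synthetic generator builds a planar grid-plus-spokes network: an urban
street grid hosting the facilities and urban region centroids, with long
winding spoke roads reaching out to rural centroids.  By construction every
edge is at least as long as the straight-line distance between its
endpoints, and the graph is connected, so routed street distance always
dominates the haversine distance -- the same ordering real road networks
exhibit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from shapely.geometry import Polygon

from .errors import ReferentialError, SchemaError
from .params import (  # noqa: F401  (re-exported: parameters are part of this surface)
    ALTERNATE_AGE_BINS,
    DEFAULT_AGE_BINS,
    AgeBand,
    AgeBins,
    CostParameters,
    ServiceTimeProfile,
    ServiceType,
    read_parameters,
)

__all__ = [
    "Region",
    "Authority",
    "Facility",
    "RoadNetwork",
    "Geography",
    "generate_synthetic_geography",
    "read_geography",
    "write_geography",
    "read_parameters",
    "CostParameters",
]

URBAN_MAX_CLASS = 4  # class codes 1-4 are urban, 5-7 rural


class Region(BaseModel):
    """A small health area: centroid, population and 1-7 urban/rural class."""

    id: str
    name: str
    authority_id: str
    class_code: int = Field(ge=1, le=7)
    population: int = Field(ge=0)
    lat: float = Field(ge=-90, le=90)
    lon: float = Field(ge=-180, le=180)
    #: optional polygon boundary, exterior ring as (lon, lat) pairs
    boundary: Optional[list[tuple[float, float]]] = None

    model_config = {"frozen": True}

    @property
    def is_urban(self) -> bool:
        return self.class_code <= URBAN_MAX_CLASS

    @property
    def centroid(self) -> tuple[float, float]:
        """(lat, lon) of the region centre.

        The geometric centroid of the boundary polygon when one is given,
        otherwise the stored point.
        """
        if self.boundary:
            c = Polygon(self.boundary).centroid
            return (c.y, c.x)
        return (self.lat, self.lon)


class Authority(BaseModel):
    """A broader health authority grouping several regions."""

    id: str
    name: str
    region_ids: list[str] = Field(default_factory=list)

    model_config = {"frozen": True}


class Facility(BaseModel):
    """A point location where in-person care is accessed."""

    id: str
    lat: float = Field(ge=-90, le=90)
    lon: float = Field(ge=-180, le=180)
    kind: str = "emergency_department"

    model_config = {"frozen": True}


class RoadNetwork:
    """An undirected road graph with per-edge street length and speed limit.

    Nodes carry WGS84 coordinates; edges carry ``length_km`` (> 0) and
    ``speed_kmh`` (> 0).  Street length must dominate the straight-line
    distance between the edge's endpoints.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node_id: str, lat: float, lon: float) -> None:
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise SchemaError(f"node {node_id!r}: coordinates ({lat}, {lon}) out of range")
        self.graph.add_node(node_id, lat=float(lat), lon=float(lon))

    def add_edge(self, u: str, v: str, length_km: float, speed_kmh: float) -> None:
        if length_km <= 0:
            raise SchemaError(f"edge ({u!r}, {v!r}): length_km must be > 0, got {length_km}")
        if speed_kmh <= 0:
            raise SchemaError(f"edge ({u!r}, {v!r}): speed_kmh must be > 0, got {speed_kmh}")
        for n in (u, v):
            if n not in self.graph:
                raise SchemaError(f"edge ({u!r}, {v!r}) references unknown node {n!r}")
        self.graph.add_edge(u, v, length_km=float(length_km), speed_kmh=float(speed_kmh))

    def node_coords(self, node_id: str) -> tuple[float, float]:
        d = self.graph.nodes[node_id]
        return (d["lat"], d["lon"])

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [
                {"id": n, "lat": d["lat"], "lon": d["lon"]}
                for n, d in self.graph.nodes(data=True)
            ]
        )
        edges = pd.DataFrame(
            [
                {"u": u, "v": v, "length_km": d["length_km"], "speed_kmh": d["speed_kmh"]}
                for u, v, d in self.graph.edges(data=True)
            ]
        )
        return nodes, edges

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "RoadNetwork":
        net = cls()
        for row in nodes.itertuples(index=False):
            net.add_node(str(row.id), float(row.lat), float(row.lon))
        for row in edges.itertuples(index=False):
            net.add_edge(str(row.u), str(row.v), float(row.length_km), float(row.speed_kmh))
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoadNetwork):
            return NotImplemented
        return nx.utils.graphs_equal(self.graph, other.graph)


@dataclass
class Geography:
    """A complete test geography: regions, authorities, facilities, roads."""

    regions: list[Region]
    authorities: list[Authority]
    facilities: list[Facility]
    network: RoadNetwork
    # synthetic geographies remember which network node each centroid sits on
    centroid_nodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {a.id for a in self.authorities}
        if len(known) != len(self.authorities):
            raise ReferentialError("duplicate authority ids")
        for r in self.regions:
            if r.authority_id not in known:
                raise ReferentialError(
                    f"region {r.id!r} references unknown authority {r.authority_id!r}"
                )

    def authority_of(self, region_id: str) -> str:
        return next(r.authority_id for r in self.regions if r.id == region_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Geography):
            return NotImplemented
        return (
            self.regions == other.regions
            and self.authorities == other.authorities
            and self.facilities == other.facilities
            and self.network == other.network
        )


# ---------------------------------------------------------------------------
# Synthetic geography generation
# ---------------------------------------------------------------------------

_BASE_LAT, _BASE_LON = 49.0, -123.0
_GRID_K = 5  # 5x5 urban street grid
_DLAT, _DLON = 0.04, 0.06  # grid spacing in degrees (~4.4 km)
_URBAN_WIND = 1.15  # street length / straight line, urban grid
_RURAL_WIND = 1.25  # spokes wind more


def _haversine(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    # local copy to avoid an import cycle with routing
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = math.radians(lat2 - lat1), math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * 6371.0 * math.asin(min(1.0, math.sqrt(a)))


def generate_synthetic_geography(
    n_regions: int = 20,
    urban_fraction: float = 0.5,
    seed: int = 0,
) -> Geography:
    """Generate a deterministic province-like test geography.

    Urban regions (class 1-4) sit on the street grid near the facilities;
    rural regions (class 5-7) hang off long spoke roads, so that
    nearest-facility street distances span from essentially zero up to a
    few hundred km -- the spread a sparse province exhibits.

    Parameters
    ----------
    n_regions : total number of regions (>= 2)
    urban_fraction : fraction of regions classed urban (rounded)
    seed : RNG seed; the output is a pure function of the arguments
    """
    if n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {n_regions}")
    if not 0.0 <= urban_fraction <= 1.0:
        raise ValueError(f"urban_fraction must be in [0, 1], got {urban_fraction}")

    rng = np.random.default_rng(seed)
    net = RoadNetwork()

    # -- urban street grid -------------------------------------------------
    def gid(i: int, j: int) -> str:
        return f"g{i}{j}"

    for i in range(_GRID_K):
        for j in range(_GRID_K):
            net.add_node(gid(i, j), _BASE_LAT + i * _DLAT, _BASE_LON + j * _DLON)
    for i in range(_GRID_K):
        for j in range(_GRID_K):
            for (i2, j2) in ((i + 1, j), (i, j + 1)):
                if i2 < _GRID_K and j2 < _GRID_K:
                    a, b = gid(i, j), gid(i2, j2)
                    d = _haversine(*net.node_coords(a), *net.node_coords(b))
                    net.add_edge(a, b, d * _URBAN_WIND, 50.0)

    n_urban = int(round(n_regions * urban_fraction))
    n_rural = n_regions - n_urban

    # facilities on grid nodes: centre first, then spread
    n_fac = max(1, n_regions // 10)
    fac_slots = [(2, 2), (0, 4), (4, 0), (0, 0), (4, 4)]
    facilities = []
    for k in range(min(n_fac, len(fac_slots))):
        i, j = fac_slots[k]
        lat, lon = net.node_coords(gid(i, j))
        facilities.append(Facility(id=f"f{k}", lat=lat, lon=lon))

    # -- rural spokes ------------------------------------------------------
    # Street lengths of the spoke chains are spread geometrically from ~8 km
    # to ~280 km so that, with the grid leg added, nearest-facility distances
    # for default settings cover at least [1, 100] km.
    border = [
        (i, j)
        for i in range(_GRID_K)
        for j in range(_GRID_K)
        if i in (0, _GRID_K - 1) or j in (0, _GRID_K - 1)
    ]
    spoke_lengths = (
        np.geomspace(8.0, 280.0, n_rural) if n_rural > 0 else np.array([])
    )
    rural_end_nodes: list[str] = []
    for k in range(n_rural):
        ai, aj = border[int(rng.integers(len(border)))]
        attach = gid(ai, aj)
        a_lat, a_lon = net.node_coords(attach)
        # direction pointing away from the grid centre, jittered
        theta = math.atan2(ai - (_GRID_K - 1) / 2, aj - (_GRID_K - 1) / 2)
        theta += float(rng.uniform(-0.5, 0.5))
        total_street = float(spoke_lengths[k])
        n_seg = 3
        seg_street = total_street / n_seg
        seg_line = seg_street / _RURAL_WIND  # straight-line step, km
        prev = attach
        for s in range(n_seg):
            dlat = (seg_line / 111.0) * math.sin(theta)
            dlon = (seg_line / (111.0 * math.cos(math.radians(a_lat)))) * math.cos(theta)
            a_lat, a_lon = a_lat + dlat, a_lon + dlon
            node = f"s{k:02d}_{s}"
            net.add_node(node, a_lat, a_lon)
            net.add_edge(prev, node, seg_street, 80.0)
            prev = node
        rural_end_nodes.append(prev)

    # -- regions -----------------------------------------------------------
    n_auth = 2 if n_regions < 10 else min(5, max(2, n_regions // 4))
    regions: list[Region] = []
    centroid_nodes: dict[str, str] = {}

    grid_nodes = [gid(i, j) for i in range(_GRID_K) for j in range(_GRID_K)]
    fac_nodes = [gid(*fac_slots[k]) for k in range(len(facilities))]
    # first urban region sits on a facility node (distance ~0); the rest
    # scatter over the grid
    urban_nodes = fac_nodes[:1] + [
        grid_nodes[int(x)]
        for x in rng.choice(len(grid_nodes), size=max(0, n_urban - 1), replace=n_urban - 1 > len(grid_nodes))
    ]
    for k in range(n_urban):
        node = urban_nodes[k]
        lat, lon = net.node_coords(node)
        rid = f"r{k:02d}"
        regions.append(
            Region(
                id=rid,
                name=f"Urban area {k}",
                authority_id=f"ha{k % n_auth}",
                class_code=int(rng.integers(1, URBAN_MAX_CLASS + 1)),
                population=int(rng.integers(20_000, 60_000)),
                lat=lat,
                lon=lon,
            )
        )
        centroid_nodes[rid] = node
    for k in range(n_rural):
        node = rural_end_nodes[k]
        lat, lon = net.node_coords(node)
        rid = f"r{n_urban + k:02d}"
        regions.append(
            Region(
                id=rid,
                name=f"Rural area {k}",
                authority_id=f"ha{(n_urban + k) % n_auth}",
                class_code=int(rng.integers(URBAN_MAX_CLASS + 1, 8)),
                population=int(rng.integers(500, 5_000)),
                lat=lat,
                lon=lon,
            )
        )
        centroid_nodes[rid] = node

    authorities = [
        Authority(
            id=f"ha{a}",
            name=f"Authority {a}",
            region_ids=[r.id for r in regions if r.authority_id == f"ha{a}"],
        )
        for a in range(n_auth)
    ]
    return Geography(regions, authorities, facilities, net, centroid_nodes)


# ---------------------------------------------------------------------------
# File I/O: GeoJSON layers + CSV edge list
# ---------------------------------------------------------------------------

REGIONS_FILE = "regions.geojson"
FACILITIES_FILE = "facilities.geojson"
AUTHORITIES_FILE = "authorities.json"
NODES_FILE = "network_nodes.csv"
EDGES_FILE = "network_edges.csv"


def _region_feature(r: Region) -> dict:
    if r.boundary:
        geometry = {"type": "Polygon", "coordinates": [[list(p) for p in r.boundary]]}
    else:
        geometry = {"type": "Point", "coordinates": [r.lon, r.lat]}
    return {
        "type": "Feature",
        "geometry": geometry,
        "properties": {
            "id": r.id,
            "name": r.name,
            "authority_id": r.authority_id,
            "class_code": r.class_code,
            "population": r.population,
            "lat": r.lat,
            "lon": r.lon,
        },
    }


def write_geography(geo: Geography, out_dir: str | Path) -> None:
    """Write a geography as GeoJSON layers plus CSV node/edge tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions_fc = {
        "type": "FeatureCollection",
        "features": [_region_feature(r) for r in geo.regions],
    }
    (out / REGIONS_FILE).write_text(json.dumps(regions_fc, indent=1))
    facilities_fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [f.lon, f.lat]},
                "properties": {"id": f.id, "kind": f.kind},
            }
            for f in geo.facilities
        ],
    }
    (out / FACILITIES_FILE).write_text(json.dumps(facilities_fc, indent=1))
    (out / AUTHORITIES_FILE).write_text(
        json.dumps(
            {
                "authorities": [a.model_dump() for a in geo.authorities],
                "centroid_nodes": geo.centroid_nodes,
            },
            indent=1,
        )
    )
    nodes, edges = geo.network.to_frames()
    nodes.to_csv(out / NODES_FILE, index=False)
    edges.to_csv(out / EDGES_FILE, index=False)


def _require(props: dict, key: str, record: str):
    if key not in props or props[key] is None:
        raise SchemaError(f"{record}: missing required field {key!r}")
    return props[key]


def read_geography(in_dir: str | Path) -> Geography:
    """Read a geography written by :func:`write_geography`.

    Raises :class:`SchemaError` for missing fields or out-of-range values
    (naming the offending record) and :class:`ReferentialError` for
    unresolved authority references.
    """
    src = Path(in_dir)
    regions = []
    for feat in json.loads((src / REGIONS_FILE).read_text())["features"]:
        props = feat["properties"]
        rid = props.get("id", "<missing id>")
        record = f"region {rid!r}"
        geom = feat["geometry"]
        boundary = None
        if geom["type"] == "Polygon":
            boundary = [tuple(p) for p in geom["coordinates"][0]]
            lat, lon = props.get("lat"), props.get("lon")
            if lat is None or lon is None:
                c = Polygon(boundary).centroid
                lat, lon = c.y, c.x
        else:
            lon, lat = geom["coordinates"]
        try:
            regions.append(
                Region(
                    id=str(rid),
                    name=str(_require(props, "name", record)),
                    authority_id=str(_require(props, "authority_id", record)),
                    class_code=_require(props, "class_code", record),
                    population=_require(props, "population", record),
                    lat=lat,
                    lon=lon,
                    boundary=boundary,
                )
            )
        except SchemaError:
            raise
        except Exception as exc:  # pydantic validation
            raise SchemaError(f"{record}: {exc}") from exc
    facilities = []
    for feat in json.loads((src / FACILITIES_FILE).read_text())["features"]:
        props = feat["properties"]
        lon, lat = feat["geometry"]["coordinates"]
        try:
            facilities.append(
                Facility(id=str(props["id"]), lat=lat, lon=lon,
                         kind=props.get("kind", "emergency_department"))
            )
        except Exception as exc:
            raise SchemaError(f"facility {props.get('id')!r}: {exc}") from exc
    auth_doc = json.loads((src / AUTHORITIES_FILE).read_text())
    authorities = [Authority(**a) for a in auth_doc["authorities"]]
    nodes = pd.read_csv(src / NODES_FILE, dtype={"id": str}, float_precision="round_trip")
    edges = pd.read_csv(
        src / EDGES_FILE, dtype={"u": str, "v": str}, float_precision="round_trip"
    )
    network = RoadNetwork.from_frames(nodes, edges)
    return Geography(
        regions, authorities, facilities, network,
        centroid_nodes=dict(auth_doc.get("centroid_nodes", {})),
    )
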