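"""Spatial environment: houses, stores, road network, nested shopping zones.

Coordinates are planar, in miles. The study area is small enough (~20 mi
across) that projected planar distances are indistinguishable from geodesic
ones at the reported precision, and planar fixtures stay hand-checkable.

The three shopping zones are nested: a neighborhood polygon strictly inside
a city polygon; everything outside the city is "suburbs". Polygon boundaries
belong to the innermost zone containing them (closed containment), which
makes zone labels exhaustive and mutually exclusive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, shape

from .errors import (
    ConnectivityError,
    PartitionError,
    SchemaError,
    SnapError,
    UnreachableError,
)

ZONES = ("neighborhood", "city", "suburbs")

#: store taxonomy used throughout the package
STORE_TYPES = (
    "chain_supermarket",
    "independent_supermarket",
    "convenience",
    "dollar",
    "other",
)

#: default snapping radius, miles
DEFAULT_SNAP_RADIUS = 0.25


@dataclass
class House:
    id: str
    x: float
    y: float
    tract_id: str
    node: int | None = None  # snapped network node


@dataclass
class Store:
    id: str
    x: float
    y: float
    store_type: str
    zone: str | None = None
    node: int | None = None


@dataclass
class ZonePartition:
    """Nested neighborhood ⊂ city polygons; the complement is the suburbs."""

    neighborhood: object  # shapely Polygon
    city: object

    def __post_init__(self) -> None:
        if not (self.neighborhood.is_valid and self.city.is_valid):
            raise PartitionError("zone polygons must be valid geometries")
        if not self.city.contains(self.neighborhood):
            raise PartitionError(
                "neighborhood polygon must be strictly contained in the city polygon"
            )

    def classify(self, x: float, y: float) -> str:
        p = Point(x, y)
        # covers() = closed containment: boundary points go to the inner zone
        if self.neighborhood.covers(p):
            return "neighborhood"
        if self.city.covers(p):
            return "city"
        return "suburbs"


def classify_zone(point: tuple[float, float], zones: ZonePartition) -> str:
    """Label a planar point as neighborhood / city / suburbs."""
    return zones.classify(point[0], point[1])


class RoadNetwork:
    """Undirected road graph with planar node coordinates and mile lengths."""

    def __init__(self, graph: nx.Graph):
        for u, v, d in graph.edges(data=True):
            if d.get("length", 0.0) <= 0.0:
                raise SchemaError(f"edge ({u}, {v}) has non-positive length")
        self.graph = graph
        self._nodes = list(graph.nodes)
        self._coords = np.array([graph.nodes[n]["pos"] for n in self._nodes])
        self._tree = cKDTree(self._coords)
        self._index = {n: i for i, n in enumerate(self._nodes)}

    @property
    def nodes(self):
        return self._nodes

    def coords(self, node) -> tuple[float, float]:
        return tuple(self.graph.nodes[node]["pos"])

    def nearest_node(self, x: float, y: float) -> tuple[int, float]:
        """Nearest node and its Euclidean distance to (x, y)."""
        dist, i = self._tree.query([x, y])
        return self._nodes[int(i)], float(dist)

    def snap(self, x: float, y: float, radius: float, label: str = "feature"):
        node, dist = self.nearest_node(x, y)
        if dist > radius:
            raise SnapError(
                f"{label} at ({x:.3f}, {y:.3f}) is {dist:.3f} mi from the nearest "
                f"road node (snap radius {radius} mi)"
            )
        return node

    def validate_connected(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ConnectivityError("empty road network")
        if not nx.is_connected(self.graph):
            comps = sorted(nx.connected_components(self.graph), key=len, reverse=True)
            orphans = [sorted(c)[:5] for c in comps[1:]]
            raise ConnectivityError(
                f"road network has {len(comps)} components; orphaned: {orphans}"
            )


def shortest_path_distance(net: RoadNetwork, a, b) -> float:
    """Length (miles) of the shortest path between two network nodes."""
    if a == b:
        return 0.0
    try:
        return float(nx.shortest_path_length(net.graph, a, b, weight="length"))
    except nx.NetworkXNoPath as exc:  # pragma: no cover - load validation forbids
        raise UnreachableError(f"no path between {a} and {b}") from exc


class ODMatrix:
    """Complete table of shortest network distances house → store, in miles."""

    def __init__(self, house_ids: list[str], store_ids: list[str], matrix: np.ndarray):
        self.house_ids = list(house_ids)
        self.store_ids = list(store_ids)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (len(self.house_ids), len(self.store_ids)):
            raise ValueError("OD matrix shape does not match id lists")
        if (self.matrix < 0).any():
            raise ValueError("OD distances must be nonnegative")
        self._hrow = {h: i for i, h in enumerate(self.house_ids)}
        self._scol = {s: j for j, s in enumerate(self.store_ids)}

    def distance(self, house_id: str, store_id: str) -> float:
        return float(self.matrix[self._hrow[house_id], self._scol[store_id]])

    def house_row(self, house_id: str) -> np.ndarray:
        return self.matrix[self._hrow[house_id]]

    def store_col_index(self, store_id: str) -> int:
        return self._scol[store_id]

    def to_frame(self) -> pd.DataFrame:
        h, s = np.meshgrid(
            np.arange(len(self.house_ids)), np.arange(len(self.store_ids)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "house_id": np.asarray(self.house_ids)[h.ravel()],
                "store_id": np.asarray(self.store_ids)[s.ravel()],
                "distance_miles": self.matrix.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ODMatrix":
        df = pd.read_csv(path)
        piv = df.pivot(index="house_id", columns="store_id", values="distance_miles")
        if piv.isna().any().any():
            raise SchemaError("OD table is not complete over house × store pairs")
        return cls(list(piv.index), list(piv.columns), piv.to_numpy())


def build_od_matrix(
    net: RoadNetwork,
    houses: list[House],
    stores: list[Store],
    snap_radius: float = DEFAULT_SNAP_RADIUS,
) -> ODMatrix:
    """Shortest-path distances between every house and every store.

    Locations snap to the nearest road node within ``snap_radius``;
    snapped-segment offsets are ignored. Runs one Dijkstra sweep per distinct
    store node, so the cost scales with stores, not house × store pairs.
    """
    for h in houses:
        h.node = net.snap(h.x, h.y, snap_radius, f"house {h.id}")
    for s in stores:
        s.node = net.snap(s.x, s.y, snap_radius, f"store {s.id}")

    store_nodes = sorted({s.node for s in stores})
    dist_from: dict[int, dict] = {}
    for node in store_nodes:
        dist_from[node] = nx.single_source_dijkstra_path_length(
            net.graph, node, weight="length"
        )

    matrix = np.empty((len(houses), len(stores)))
    for i, h in enumerate(houses):
        for j, s in enumerate(stores):
            try:
                matrix[i, j] = dist_from[s.node][h.node]
            except KeyError as exc:
                raise UnreachableError(
                    f"house {h.id} cannot reach store {s.id}"
                ) from exc
    return ODMatrix([h.id for h in houses], [s.id for s in stores], matrix)


@dataclass
class Environment:
    network: RoadNetwork
    houses: list[House]
    stores: list[Store]
    zones: ZonePartition
    snap_radius: float = DEFAULT_SNAP_RADIUS

    #: houses grouped by tract, filled on load
    houses_by_tract: dict[str, list[House]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h in self.houses:
            self.houses_by_tract.setdefault(h.tract_id, []).append(h)

    @property
    def stores_by_id(self) -> dict[str, Store]:
        return {s.id: s for s in self.stores}


def _require(props: dict, key: str, feature_kind: str, ident) -> object:
    if key not in props or props[key] is None:
        raise SchemaError(f"{feature_kind} feature {ident!r} lacks property {key!r}")
    return props[key]


def _read_collection(path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    return gj["features"]


def load_environment(
    houses_path,
    stores_path,
    roads_path,
    zones_path,
    snap_radius: float = DEFAULT_SNAP_RADIUS,
) -> Environment:
    """Load and validate the four GeoJSON layers into an environment bundle.

    Stores are annotated with their shopping zone; houses and stores are
    snapped to the road network, which must be connected.
    """
    # zones
    polys = {}
    for feat in _read_collection(zones_path):
        level = _require(feat.get("properties", {}), "level", "zone", feat.get("id"))
        polys[level] = shape(feat["geometry"])
    for level in ("neighborhood", "city"):
        if level not in polys:
            raise SchemaError(f"zones file lacks a polygon with level={level!r}")
    zones = ZonePartition(polys["neighborhood"], polys["city"])

    # roads
    g = nx.Graph()
    node_ids: dict[tuple[float, float], int] = {}

    def node_of(xy):
        key = (round(xy[0], 9), round(xy[1], 9))
        if key not in node_ids:
            node_ids[key] = len(node_ids)
            g.add_node(node_ids[key], pos=key)
        return node_ids[key]

    for feat in _read_collection(roads_path):
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise SchemaError("roads must be LineString features")
        coords = list(geom.coords)
        length_prop = feat.get("properties", {}).get("length")
        for a, b in zip(coords[:-1], coords[1:]):
            u, v = node_of(a), node_of(b)
            seg = float(np.hypot(b[0] - a[0], b[1] - a[1]))
            if length_prop is not None and len(coords) == 2:
                seg = float(length_prop)
            if seg <= 0:
                raise SchemaError(f"degenerate road segment at {a}")
            g.add_edge(u, v, length=seg)
    net = RoadNetwork(g)
    net.validate_connected()

    houses = []
    for feat in _read_collection(houses_path):
        props = feat.get("properties", {})
        ident = props.get("id", feat.get("id"))
        geom = shape(feat["geometry"])
        houses.append(
            House(
                id=str(_require(props, "id", "house", ident)),
                x=geom.x,
                y=geom.y,
                tract_id=str(_require(props, "tract_id", "house", ident)),
            )
        )

    stores = []
    for feat in _read_collection(stores_path):
        props = feat.get("properties", {})
        ident = props.get("id", feat.get("id"))
        geom = shape(feat["geometry"])
        stype = str(_require(props, "store_type", "store", ident))
        if stype not in STORE_TYPES:
            raise SchemaError(
                f"store {ident!r}: unknown store_type {stype!r} "
                f"(taxonomy: {STORE_TYPES})"
            )
        stores.append(
            Store(
                id=str(_require(props, "id", "store", ident)),
                x=geom.x,
                y=geom.y,
                store_type=stype,
                zone=zones.classify(geom.x, geom.y),
            )
        )

    for h in houses:
        h.node = net.snap(h.x, h.y, snap_radius, f"house {h.id}")
    for s in stores:
        s.node = net.snap(s.x, s.y, snap_radius, f"store {s.id}")
    return Environment(net, houses, stores, zones, snap_radius)
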