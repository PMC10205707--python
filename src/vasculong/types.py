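"""Core in-memory containers shared by all vasculong modules.

Physical conventions: coordinates and radii are in micrometres (µm),
voxel indices are 0-based, time is in seconds unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np


@dataclass
class VesselSegment:
    """One vessel segment: an edge of the vascular graph.

    Attributes
    ----------
    id : int
        Stable segment identifier within its network.
    endpoints : tuple
        Junction node ids at either end.
    centerline : (k, 3) ndarray
        Ordered centerline points, µm. k >= 2; first/last points coincide
        with the endpoint junction coordinates.
    radius_profile : (k,) ndarray
        Vessel radius at each centerline point, µm, all > 0.
    penetrating : bool
        True for penetrating arterioles/venules (diving vessels), False
        for capillaries.
    """

    id: int
    endpoints: tuple
    centerline: np.ndarray
    radius_profile: np.ndarray
    penetrating: bool = False

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points")
        if self.radius_profile.shape[0] != self.centerline.shape[0]:
            raise ValueError("radius profile length must match centerline")
        if np.any(self.radius_profile <= 0):
            raise ValueError("radii must be positive")


class VascularNetwork:
    """Spatial vascular graph: junction nodes (µm coordinates) joined by
    vessel-segment edges carrying centerline polylines and radius profiles.

    Thin wrapper around :class:`networkx.Graph`; node attribute ``pos`` is a
    3-tuple in µm, edge attributes are ``eid``, ``centerline``, ``radii``
    and ``penetrating``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------
    def add_junction(self, node_id, pos) -> None:
        self.graph.add_node(node_id, pos=tuple(float(c) for c in pos))

    def add_vessel(self, u, v, centerline=None, radii=None, radius=3.0,
                   penetrating=False, eid=None) -> int:
        """Add a vessel between junctions u and v.

        If no centerline is given, a straight 2-point polyline between the
        junction positions is used; a scalar ``radius`` expands to a
        constant profile.
        """
        if centerline is None:
            centerline = np.array([self.graph.nodes[u]["pos"],
                                   self.graph.nodes[v]["pos"]], dtype=float)
        centerline = np.asarray(centerline, dtype=float)
        if radii is None:
            radii = np.full(len(centerline), float(radius))
        radii = np.asarray(radii, dtype=float)
        if eid is None:
            eid = self.graph.number_of_edges()
        self.graph.add_edge(u, v, eid=int(eid), centerline=centerline,
                            radii=radii, penetrating=bool(penetrating))
        return int(eid)

    # -- queries ----------------------------------------------------------
    @property
    def n_vessels(self) -> int:
        return self.graph.number_of_edges()

    def segment(self, u, v) -> VesselSegment:
        d = self.graph.edges[u, v]
        return VesselSegment(id=d["eid"], endpoints=(u, v),
                             centerline=d["centerline"],
                             radius_profile=d["radii"],
                             penetrating=d.get("penetrating", False))

    def segments(self) -> Iterator[VesselSegment]:
        for u, v in self.graph.edges:
            yield self.segment(u, v)

    def vessel_graph(self) -> nx.Graph:
        """The vessel-adjacency ("line") graph: vessels are nodes, two
        vessels are adjacent iff they share a junction. Nodes are keyed by
        edge id; node attribute ``penetrating`` is carried over."""
        lg = nx.Graph()
        for u, v, d in self.graph.edges(data=True):
            lg.add_node(d["eid"], penetrating=d.get("penetrating", False))
        for node in self.graph.nodes:
            eids = [self.graph.edges[e]["eid"] for e in self.graph.edges(node)]
            for i in range(len(eids)):
                for j in range(i + 1, len(eids)):
                    lg.add_edge(eids[i], eids[j])
        return lg

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(self.graph.copy())


@dataclass
class ImageVolume:
    """3D grayscale/binary volume (or 2D en-face map) with isotropic voxel
    size metadata in µm. ``mask`` optionally carries a paired ground-truth
    binary segmentation."""

    data: np.ndarray
    voxel_um: float
    mask: np.ndarray | None = None
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")

    def to_voxel(self, points_um: np.ndarray) -> np.ndarray:
        """Map world µm coordinates to (rounded) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        o = np.asarray(self.origin_um)[: pts.shape[1]]
        return np.round((pts - o) / self.voxel_um).astype(int)


@dataclass
class TimeTrace:
    """Fixed-rate intensity time series at one centerline voxel.

    ``n_arrivals``/``true_flux`` hold simulation ground truth when the
    trace is synthetic (RBC passages actually drawn / their rate in RBC/s).
    """

    values: np.ndarray
    dt_s: float = 1.4e-3
    n_arrivals: int | None = None
    true_flux: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt_s <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.dt_s
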