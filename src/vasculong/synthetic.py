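"""Synthetic inputs with known ground truth.

Everything downstream — topology metrics, image measurement, flux
regression, longitudinal statistics — can be exercised on outputs of this
module: honeycomb lattices and 3D capillary beds, rasterized angiogram
volumes, RBC-passage time traces, longitudinal cohort tables and novel
object location (NOL) exploration times.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageVolume, TimeTrace, VascularNetwork

log = logging.getLogger(__name__)

#: default measurement ages, weeks of age (4-week imaging cadence, 7 visits)
DEFAULT_AGES_WEEKS = (11, 15, 19, 23, 27, 31, 35)

#: RBC-passage acquisition: 512 repeated B-scans at 1.4 ms
TRACE_LEN = 512
TRACE_DT_S = 1.4e-3


# ---------------------------------------------------------------------------
# trajectory / cohort specification
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Fixed- and random-effect description of one property in one group.

    shape="linear": value(age) = intercept * (1 + slope_pct_month/100 *
    (age - age0)/4), i.e. ``intercept`` is the group baseline at the first
    measurement age and ``slope_pct_month`` the percent change per month
    (1 month = 4 weeks).

    shape="sigmoid": value(age) = c + L / (1 + exp(k*(b - age))), the
    logistic trajectory with plateau offset c, amplitude L, steepness k
    (1/week) and midpoint b (weeks).

    Random effects are per-animal: ``re_intercept_sd`` shifts the baseline
    (linear) or c (sigmoid); ``re_slope_sd`` perturbs slope_pct_month
    (linear) or L (sigmoid). ``residual_sd`` is i.i.d. measurement noise.
    """

    shape: str = "linear"
    intercept: float = 1.0
    slope_pct_month: float = 0.0
    c: float = 1.0
    L: float = 0.0
    k: float = 0.5
    b: float = 23.0
    re_intercept_sd: float = 0.0
    re_slope_sd: float = 0.0
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "sigmoid"):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        if self.residual_sd < 0 or self.re_intercept_sd < 0 or self.re_slope_sd < 0:
            raise ValueError("SDs must be non-negative")

    def mean_curve(self, ages, age0: float) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.shape == "linear":
            return self.intercept * (1.0 + self.slope_pct_month / 100.0
                                     * (ages - age0) / 4.0)
        return self.c + self.L / (1.0 + np.exp(self.k * (self.b - ages)))


@dataclass
class CohortSpec:
    """Longitudinal cohort layout: two groups (AD/WT) measured at fixed
    ages, each property following a group-specific trajectory."""

    n_animals_per_group: dict = field(
        default_factory=lambda: {"AD": 7, "WT": 6})
    ages_weeks: tuple = DEFAULT_AGES_WEEKS
    trajectories: dict = field(default_factory=dict)  # property -> group -> TrajectorySpec
    seed: int = 0

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages_weeks, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        for g, n in self.n_animals_per_group.items():
            if n < 2:
                raise ValueError(f"need >= 2 animals per group, got {n} for {g}")


@dataclass
class NetworkSpec:
    """Geometry of a synthetic 3D capillary bed."""

    target_vessel_count: int = 120
    lattice_pitch: float = 50.0          # µm
    jitter_sd: float = 3.0               # µm
    n_penetrating: int = 2
    volume_extent: tuple = (400.0, 400.0, 150.0)   # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_vessel_count <= 0:
            raise ValueError("vessel count must be positive")
        if self.jitter_sd >= self.lattice_pitch / 2:
            raise ValueError("jitter_sd must be < lattice_pitch/2")


# ---------------------------------------------------------------------------
# honeycomb lattice
# ---------------------------------------------------------------------------

def make_honeycomb(n_vessels: int, pitch: float = 50.0,
                   radius: float = 3.0) -> VascularNetwork:
    """Planar hexagonal ("honeycomb") lattice patch with exactly
    ``n_vessels`` edges.

    A hexagonal lattice is grown until it holds at least ``n_vessels``
    edges, then trimmed to the exact count by repeatedly removing the
    removable edge farthest from the current patch centroid (ties broken
    by node index), which keeps the patch compact and connected. Interior
    nodes have degree 3, matching capillary junctions.
    """
    if n_vessels < 6:
        raise ValueError("a honeycomb patch needs at least 6 vessels")

    m = 1
    while True:
        g = nx.hexagonal_lattice_graph(m, m)
        if g.number_of_edges() >= n_vessels:
            break
        m += 1

    pos = nx.get_node_attributes(g, "pos")
    g = nx.Graph(g)  # strip lattice bookkeeping

    while g.number_of_edges() > n_vessels:
        cen = np.mean([pos[n] for n in g.nodes], axis=0)
        # removing a boundary edge leaves a dangling chain; eat dangles
        # first so the patch stays a clean 2-core of whole hexagons
        leaves = [(u, v) for u, v in g.edges
                  if g.degree[u] == 1 or g.degree[v] == 1]
        if leaves:
            candidates = leaves
        else:
            bridges = set(frozenset(e) for e in nx.bridges(g))
            candidates = [e for e in g.edges
                          if frozenset(e) not in bridges]
        best = None
        for u, v in candidates:
            mid = (np.asarray(pos[u]) + np.asarray(pos[v])) / 2.0
            key = (-float(np.hypot(*(mid - cen))), tuple(sorted((u, v))))
            if best is None or key < best[0]:
                best = (key, (u, v))
        u, v = best[1]
        g.remove_edge(u, v)
        for n in (u, v):
            if g.degree[n] == 0:
                g.remove_node(n)

    net = VascularNetwork()
    order = {n: i for i, n in enumerate(sorted(g.nodes))}
    for n in sorted(g.nodes):
        x, y = pos[n]
        net.add_junction(order[n], (x * pitch, y * pitch, 0.0))
    for eid, (u, v) in enumerate(sorted(g.edges, key=lambda e: tuple(sorted(e)))):
        net.add_vessel(order[u], order[v], radius=radius, eid=eid)
    return net


# ---------------------------------------------------------------------------
# 3D capillary bed
# ---------------------------------------------------------------------------

def make_capillary_bed(spec: NetworkSpec) -> VascularNetwork:
    """Synthetic 3D capillary bed: stacked, jittered honeycomb layers
    joined by vertical links at alternating junctions, plus
    ``n_penetrating`` diving vessels flagged ``penetrating``.

    The layered construction is the simplest 3-connected 3D bed whose
    junctions have the degree-3 signature of real capillary networks.
    """
    rng = np.random.default_rng(spec.seed)
    n_layers = max(2, int(round(spec.volume_extent[2] / spec.lattice_pitch)))

    # budget edges per layer so the total lands near the target
    def total_edges(e_layer: int) -> int:
        patch = make_honeycomb(max(6, e_layer), pitch=spec.lattice_pitch)
        n_nodes = patch.graph.number_of_nodes()
        links = (n_layers - 1) * ((n_nodes + 1) // 2)
        return n_layers * patch.n_vessels + links + spec.n_penetrating

    e_layer = max(6, spec.target_vessel_count // n_layers)
    for _ in range(20):
        t = total_edges(e_layer)
        if abs(t - spec.target_vessel_count) <= max(2, spec.target_vessel_count // 20):
            break
        e_layer = max(6, e_layer + (spec.target_vessel_count - t) // (n_layers + 1) or
                      (1 if t < spec.target_vessel_count else -1))
    patch = make_honeycomb(max(6, e_layer), pitch=spec.lattice_pitch)

    net = VascularNetwork()
    node_ids = sorted(patch.graph.nodes)
    nid = {}
    for layer in range(n_layers):
        z = layer * spec.lattice_pitch
        for n in node_ids:
            x, y, _ = patch.graph.nodes[n]["pos"]
            p = np.array([x, y, z]) + rng.normal(0.0, spec.jitter_sd, 3)
            nid[(n, layer)] = len(nid)
            net.add_junction(nid[(n, layer)], p)

    def _centerline(u, v):
        a = np.asarray(net.graph.nodes[u]["pos"])
        b = np.asarray(net.graph.nodes[v]["pos"])
        t = np.linspace(0.0, 1.0, 5)[:, None]
        pts = a * (1 - t) + b * t
        pts[1:-1] += rng.normal(0.0, spec.jitter_sd / 2.0, (3, 3))
        return pts

    eid = 0
    for layer in range(n_layers):
        for u, v in sorted(patch.graph.edges, key=lambda e: tuple(sorted(e))):
            a, b = nid[(u, layer)], nid[(v, layer)]
            net.add_vessel(a, b, centerline=_centerline(a, b),
                           radius=float(rng.uniform(2.0, 4.0)), eid=eid)
            eid += 1
    for layer in range(n_layers - 1):
        for n in node_ids[::2]:
            a, b = nid[(n, layer)], nid[(n, layer + 1)]
            net.add_vessel(a, b, centerline=_centerline(a, b),
                           radius=float(rng.uniform(2.0, 4.0)), eid=eid)
            eid += 1

    # diving vessels enter from above the top layer
    top = n_layers - 1
    anchors = node_ids[:: max(1, len(node_ids) // max(1, spec.n_penetrating))]
    for i in range(spec.n_penetrating):
        n = anchors[i % len(anchors)]
        a = nid[(n, top)]
        x, y, z = net.graph.nodes[a]["pos"]
        pid = len(nid) + i + 10_000
        net.add_junction(pid, (x, y, z + 2 * spec.lattice_pitch))
        net.add_vessel(pid, a, radius=6.0, penetrating=True, eid=eid)
        eid += 1
    return net


# ---------------------------------------------------------------------------
# angiogram rendering
# ---------------------------------------------------------------------------

def render_angiogram(net: VascularNetwork, voxel_um: float = 2.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     margin_um: float = 12.0) -> ImageVolume:
    """Rasterize a vascular network into a grayscale volume with a paired
    ground-truth binary mask.

    Each vessel gets a Gaussian cross-profile whose full width at half
    maximum equals its local diameter, so centerline voxels carry the
    maximal intensity and a half-maximum isophote traces the true wall.
    Additive Gaussian noise of SD ``noise_sd`` (intensity units; peak
    intensity is 1) is applied to the grayscale copy only.
    """
    if voxel_um <= 0:
        raise ValueError("voxel size must be positive")
    pts, rads = [], []
    for seg in net.segments():
        cl, rp = seg.centerline, seg.radius_profile
        for i in range(len(cl) - 1):
            d = float(np.linalg.norm(cl[i + 1] - cl[i]))
            n = max(2, int(np.ceil(d / (voxel_um / 2.0))) + 1)
            t = np.linspace(0.0, 1.0, n)
            pts.append(cl[i] * (1 - t[:, None]) + cl[i + 1] * t[:, None])
            rads.append(rp[i] * (1 - t) + rp[i + 1] * t)
    pts = np.concatenate(pts)
    rads = np.concatenate(rads)
    if voxel_um > float(rads.min()):
        log.warning("voxel size %.2f µm coarser than smallest radius %.2f µm",
                    voxel_um, float(rads.min()))

    origin = pts.min(axis=0) - margin_um
    shape = np.ceil((pts.max(axis=0) - origin + margin_um) / voxel_um).astype(int) + 1
    idx = np.round((pts - origin) / voxel_um).astype(int)

    skel = np.zeros(tuple(shape), dtype=bool)
    rvol = np.zeros(tuple(shape), dtype=float)
    skel[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    # keep the largest radius where several centerline samples share a voxel
    np.maximum.at(rvol, (idx[:, 0], idx[:, 1], idx[:, 2]), rads)

    dist, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~skel, sampling=voxel_um, return_indices=True)
    r_near = rvol[ix, iy, iz]
    # half-maximum at distance r from the centerline: FWHM = local diameter
    data = np.exp(-np.log(2.0) * (dist / r_near) ** 2)
    data[dist > 2.5 * r_near] = 0.0
    mask = dist <= r_near
    if noise_sd > 0:
        data = data + np.random.default_rng(seed).normal(0.0, noise_sd, data.shape)
    return ImageVolume(data=data, voxel_um=voxel_um, mask=mask,
                       origin_um=tuple(origin))


# ---------------------------------------------------------------------------
# RBC-passage traces
# ---------------------------------------------------------------------------

def simulate_rbc_trace(flux_rbc_per_s: float, duration_s: float | None = None,
                       dt_s: float = TRACE_DT_S, peak_width_ms: float = 7.0,
                       snr: float = 5.0, seed: int = 0,
                       amplitude: float = 1.0) -> TimeTrace:
    """Simulate the intensity time course at one capillary centerline voxel.

    RBC passages arrive as a Poisson process at rate ``flux_rbc_per_s``;
    each adds a Gaussian transient of FWHM ``peak_width_ms`` on a unit
    baseline. White noise of SD amplitude/snr is added (``snr=np.inf``
    for a noiseless trace). At high flux the transients merge — the
    returned ground-truth arrival count is retained regardless.
    """
    if flux_rbc_per_s < 0:
        raise ValueError("flux must be non-negative")
    if duration_s is None:
        duration_s = TRACE_LEN * dt_s
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s / dt_s))
    t = np.arange(n_samples) * dt_s
    n_arr = rng.poisson(flux_rbc_per_s * duration_s)
    trace = np.full(n_samples, 1.0)
    sig = peak_width_ms * 1e-3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if n_arr:
        times = rng.uniform(0.0, duration_s, n_arr)
        trace = trace + amplitude * np.exp(
            -((t[:, None] - times[None, :]) ** 2) / (2 * sig ** 2)).sum(axis=1)
    if np.isfinite(snr):
        trace = trace + rng.normal(0.0, amplitude / snr, n_samples)
    return TimeTrace(values=trace, dt_s=dt_s, n_arrivals=int(n_arr),
                     true_flux=float(flux_rbc_per_s))


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec, return_truth: bool = False):
    """Tidy longitudinal table (animal_id, group, age_weeks, property,
    value) drawn from the per-group trajectory specs.

    With ``return_truth=True`` also returns a per-animal ground-truth
    table of the realized trajectory parameters (population value plus
    that animal's random-effect draw) — the quantities a fitted fixed
    effect actually estimates for this particular cohort.
    """
    rng = np.random.default_rng(spec.seed)
    age0 = float(spec.ages_weeks[0])
    ages = np.asarray(spec.ages_weeks, dtype=float)
    rows, truth_rows = [], []
    for group in sorted(spec.n_animals_per_group):
        n_animals = spec.n_animals_per_group[group]
        for a in range(n_animals):
            animal = f"{group}{a + 1:02d}"
            for prop in sorted(spec.trajectories):
                tr = spec.trajectories[prop][group]
                d_int = rng.normal(0.0, tr.re_intercept_sd) if tr.re_intercept_sd else 0.0
                d_slp = rng.normal(0.0, tr.re_slope_sd) if tr.re_slope_sd else 0.0
                if tr.shape == "linear":
                    base = tr.intercept + d_int
                    vals = base * (1.0 + (tr.slope_pct_month + d_slp) / 100.0
                                   * (ages - age0) / 4.0)
                    truth_rows.append((animal, group, prop, "linear",
                                       base, tr.slope_pct_month + d_slp))
                else:
                    vals = (tr.c + d_int) + (tr.L + d_slp) / (
                        1.0 + np.exp(tr.k * (tr.b - ages)))
                    truth_rows.append((animal, group, prop, "sigmoid",
                                       tr.c + d_int, tr.L + d_slp))
                if tr.residual_sd:
                    vals = vals + rng.normal(0.0, tr.residual_sd, len(ages))
                for age, v in zip(ages, vals):
                    rows.append((animal, group, float(age), prop, float(v)))
    table = pd.DataFrame(rows, columns=["animal_id", "group", "age_weeks",
                                        "property", "value"])
    if not return_truth:
        return table
    truth = pd.DataFrame(truth_rows, columns=[
        "animal_id", "group", "property", "shape",
        "intercept_true", "slope_true"])
    return table, truth


def simulate_nol(n_animals: int, ages, decline_spec, seed: int = 0,
                 z_sd: float = 0.0, group: str = "AD",
                 total_time_s: float = 300.0) -> pd.DataFrame:
    """Novel object location exploration-time pairs.

    ``decline_spec`` is either a constant Z, a callable age -> Z, or a
    (z0, slope_per_week) tuple. The pair (T_NW, T_SE) is chosen so the
    discrimination index Z = T_SE/(T_NW+T_SE) follows the requested
    trajectory; Z is clipped to (0, 1).
    """
    rng = np.random.default_rng(seed)
    if callable(decline_spec):
        zfun = decline_spec
    elif np.isscalar(decline_spec):
        zfun = lambda age: float(decline_spec)
    else:
        z0, slope = decline_spec
        a0 = float(np.min(ages))
        zfun = lambda age: z0 + slope * (age - a0)
    rows = []
    for a in range(n_animals):
        animal = f"{group}{a + 1:02d}"
        for age in ages:
            z = zfun(float(age))
            if z_sd:
                z = z + rng.normal(0.0, z_sd)
            z = float(np.clip(z, 1e-6, 1 - 1e-6))
            total = total_time_s
            if z_sd:
                total = max(10.0, total_time_s + rng.normal(0.0, total_time_s / 10))
            rows.append((animal, group, float(age),
                         (1.0 - z) * total, z * total))
    return pd.DataFrame(rows, columns=["animal_id", "group", "age_weeks",
                                       "t_nw_s", "t_se_s"])
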