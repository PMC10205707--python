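"""Readers and writers for the on-disk formats.

Networks: GraphML (via networkx, polylines JSON-encoded in edge
attributes) or a nodes.csv/edges.csv pair. Volumes: multi-page TIFF with
the voxel size recorded in the image description. Cohort and NOL tables:
tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .types import ImageVolume, VascularNetwork

COHORT_COLUMNS = ["animal_id", "group", "age_weeks", "property", "value"]
NOL_COLUMNS = ["animal_id", "age_weeks", "t_nw_s", "t_se_s"]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_graphml(net: VascularNetwork, path) -> None:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(n, x=d["pos"][0], y=d["pos"][1], z=d["pos"][2])
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, eid=d["eid"],
                   centerline=json.dumps(np.asarray(d["centerline"]).tolist()),
                   radii=json.dumps(np.asarray(d["radii"]).tolist()),
                   penetrating=bool(d.get("penetrating", False)))
    nx.write_graphml(g, path)


def read_graphml(path) -> VascularNetwork:
    g = nx.read_graphml(path)
    net = VascularNetwork()
    for n, d in g.nodes(data=True):
        net.add_junction(_node_key(n), (d["x"], d["y"], d["z"]))
    for u, v, d in g.edges(data=True):
        net.add_vessel(_node_key(u), _node_key(v),
                       centerline=np.asarray(json.loads(d["centerline"])),
                       radii=np.asarray(json.loads(d["radii"])),
                       penetrating=bool(d.get("penetrating", False)),
                       eid=int(d["eid"]))
    return net


def _node_key(n):
    try:
        return int(n)
    except (TypeError, ValueError):
        return n


def write_network_csv(net: VascularNetwork, nodes_path, edges_path) -> None:
    nodes = pd.DataFrame(
        [(n, *d["pos"]) for n, d in net.graph.nodes(data=True)],
        columns=["node_id", "x_um", "y_um", "z_um"])
    edges = pd.DataFrame(
        [(d["eid"], u, v,
          json.dumps(np.asarray(d["centerline"]).tolist()),
          json.dumps(np.asarray(d["radii"]).tolist()),
          bool(d.get("penetrating", False)))
         for u, v, d in net.graph.edges(data=True)],
        columns=["eid", "u", "v", "centerline", "radii", "penetrating"])
    nodes.to_csv(nodes_path, index=False)
    edges.to_csv(edges_path, index=False)


def read_network_csv(nodes_path, edges_path) -> VascularNetwork:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    net = VascularNetwork()
    for _, r in nodes.iterrows():
        net.add_junction(_node_key(r["node_id"]),
                         (r["x_um"], r["y_um"], r["z_um"]))
    for _, r in edges.iterrows():
        net.add_vessel(_node_key(r["u"]), _node_key(r["v"]),
                       centerline=np.asarray(json.loads(r["centerline"])),
                       radii=np.asarray(json.loads(r["radii"])),
                       penetrating=bool(r["penetrating"]), eid=int(r["eid"]))
    return net


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_tiff(vol: ImageVolume, path) -> None:
    meta = {"voxel_um": vol.voxel_um, "origin_um": list(vol.origin_um)}
    tifffile.imwrite(path, np.asarray(vol.data, dtype=np.float32),
                     description=json.dumps(meta))


def read_tiff(path) -> ImageVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    return ImageVolume(data=data, voxel_um=float(meta.get("voxel_um", 1.0)),
                       origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def read_nol_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in NOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"NOL table missing columns: {missing}")
    return df


def validate_inputs(cohort: pd.DataFrame | None = None,
                    nol: pd.DataFrame | None = None) -> list:
    """Schema/content checks; returns a list of issue strings with row
    numbers (empty when everything is well-formed)."""
    issues = []
    if cohort is not None:
        for i, age in cohort["age_weeks"].items():
            if not np.isfinite(age) or age < 0:
                issues.append(f"cohort row {i}: invalid age_weeks {age!r}")
        bad_groups = set(cohort["group"].unique()) - {"AD", "WT"}
        if bad_groups:
            issues.append(f"cohort: unknown groups {sorted(bad_groups)}")
    if nol is not None:
        for i, r in nol.iterrows():
            if r["t_nw_s"] < 0 or r["t_se_s"] < 0:
                issues.append(f"NOL row {i}: negative exploration time")
            if r["age_weeks"] < 0:
                issues.append(f"NOL row {i}: negative age")
    if cohort is not None and nol is not None:
        only_nol = set(nol["animal_id"]) - set(cohort["animal_id"])
        if only_nol:
            issues.append(
                f"animal ids only in NOL table: {sorted(only_nol)}")
    return issues
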