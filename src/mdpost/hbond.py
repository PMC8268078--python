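"""Geometric hydrogen-bond detection, occupancy tables and network comparison.

A hydrogen bond D–H···A is counted in a frame when the donor-heavy to
acceptor-heavy distance d(D, A) is at or below ``distance_cutoff`` (default
3.0 Å) and the D–H–A angle is at or above ``angle_cutoff`` (default 135°);
both criteria inclusive.  This is the cpptraj convention: the distance is
measured between the heavy atoms, not H···A — the source analyses state
cutoffs only, so the geometric definition is a documented choice here.

Occupancy is the percentage of window frames in which the bond exists.
Donors are N/O/S heavy atoms bonded to at least one hydrogen (one donor pair
per bonded H, so chemically equivalent protons such as arginine NH1/NH2 are
reported separately); acceptors are all N/O atoms.  Intra-residue pairs are
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ComponentMap, Topology, Trajectory

__all__ = [
    "HBondConfig",
    "HBondError",
    "identify_donors_acceptors",
    "hbond_occupancy",
    "hbond_distance_series",
    "differential_network",
    "network_json",
]

DONOR_ELEMENTS = ("N", "O", "S")
ACCEPTOR_ELEMENTS = ("N", "O")


class HBondError(ValueError):
    pass


@dataclass(frozen=True)
class HBondConfig:
    distance_cutoff: float = 3.0   # Å, donor-heavy to acceptor-heavy
    angle_cutoff: float = 135.0    # degrees, D-H-A
    report_threshold: float = 10.0  # percent, network filter

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise HBondError("distance_cutoff must be > 0")
        if not (0 < self.angle_cutoff <= 180):
            raise HBondError("angle_cutoff must be in (0, 180]")


def identify_donors_acceptors(topology: Topology
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Donor (D, H) index pairs and acceptor atom indices.

    Requires the topology's bond list (to find D–H pairs); raises otherwise
    with instructions.
    """
    if not topology.bonds:
        raise HBondError(
            "topology has no bonds; supply a 'bonds' list in the parameter "
            "sidecar (atom serial pairs) so donor hydrogens can be found")
    elements = topology.elements
    donors = []
    for a, b in topology.bond_index_pairs():
        for heavy, hyd in ((a, b), (b, a)):
            if elements[hyd] == "H" and elements[heavy] in DONOR_ELEMENTS:
                donors.append((heavy, hyd))
    acceptors = np.array([i for i, e in enumerate(elements)
                          if e in ACCEPTOR_ELEMENTS], dtype=int)
    donor_arr = np.array(sorted(set(donors)), dtype=int).reshape(-1, 2)
    return donor_arr, acceptors


def _bond_exists(frames: np.ndarray, d: int, h: int, a: int,
                 config: HBondConfig) -> np.ndarray:
    """Boolean per-frame series for one D-H...A triple."""
    da = np.linalg.norm(frames[:, a] - frames[:, d], axis=1)
    v1 = frames[:, d] - frames[:, h]
    v2 = frames[:, a] - frames[:, h]
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (da <= config.distance_cutoff) & (angle >= config.angle_cutoff)


def hbond_occupancy(trajectory: Trajectory, topology: Topology,
                    config: HBondConfig = HBondConfig(),
                    component_map: ComponentMap | None = None,
                    include_zero: bool = False) -> pd.DataFrame:
    """Occupancy table over the trajectory window.

    Columns: ``donor``, ``hydrogen``, ``acceptor`` (labels like
    ``SER_110@O^CD94``), ``occupancy_percent`` (one decimal), plus the raw
    atom indices and window bounds.  Rows with zero occupancy are dropped
    unless ``include_zero``.
    """
    frames = trajectory.windowed
    n = frames.shape[0]
    if n == 0:
        raise HBondError("empty frame window")
    donors, acceptors = identify_donors_acceptors(topology)
    resi = topology.residue_indices
    rows = []
    for d, h in donors:
        for a in acceptors:
            if a == d or resi[a] == resi[d]:
                continue
            count = int(_bond_exists(frames, d, h, a, config).sum())
            if count == 0 and not include_zero:
                continue
            occ = 100.0 * count / n
            rows.append({
                "donor": topology.atom_label(d, component_map),
                "hydrogen": topology.atom_label(h, component_map),
                "acceptor": topology.atom_label(a, component_map),
                "occupancy_percent": round(occ, 1),
                "donor_index": int(d), "hydrogen_index": int(h),
                "acceptor_index": int(a),
                "window_start": trajectory.window[0],
                "window_end": trajectory.window[1],
            })
    cols = ["donor", "hydrogen", "acceptor", "occupancy_percent",
            "donor_index", "hydrogen_index", "acceptor_index",
            "window_start", "window_end"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["occupancy_percent", "donor", "acceptor"],
                          ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)


def hbond_distance_series(trajectory: Trajectory, topology: Topology,
                          donor, acceptor) -> np.ndarray:
    """Per-frame donor-heavy to acceptor-heavy distance in Å.

    ``donor``/``acceptor`` are atom indices or atom labels of the form
    ``RES_NUM@NAME`` (chain/component suffix optional).
    """
    d = _resolve_atom(topology, donor)
    a = _resolve_atom(topology, acceptor)
    frames = trajectory.windowed
    return np.linalg.norm(frames[:, a] - frames[:, d], axis=1)


def _resolve_atom(topology: Topology, ref) -> int:
    if isinstance(ref, (int, np.integer)):
        if not (0 <= ref < topology.n_atoms):
            raise HBondError(f"atom index {ref} out of range")
        return int(ref)
    core = str(ref).split("^")[0]
    for i, atom in enumerate(topology.atoms):
        if f"{atom.residue_name}_{atom.resid}@{atom.name}" == core:
            return i
    raise HBondError(f"unknown atom {ref!r}")


def differential_network(tables: dict[str, pd.DataFrame],
                         config: HBondConfig = HBondConfig()
                         ) -> pd.DataFrame:
    """Cross-system comparison over the union of (donor, H, acceptor) keys.

    Returns one row per bond with an ``occupancy_percent:<system>`` column
    per system (0 where the bond is absent) and ``in_network`` marking rows
    whose maximum occupancy reaches ``report_threshold``.  Systems sharing
    no keys at all trigger a warning (naming-convention mismatch), not an
    error.
    """
    if len(tables) < 2:
        raise HBondError("differential network requires at least 2 systems")
    systems = list(tables)
    keysets = {}
    for name, df in tables.items():
        keysets[name] = {(r.donor, r.hydrogen, r.acceptor): r.occupancy_percent
                         for r in df.itertuples()}
    all_keys = sorted(set().union(*keysets.values()))
    shared = set(keysets[systems[0]])
    for name in systems[1:]:
        if not shared.intersection(keysets[name]):
            warnings.warn(
                f"systems {systems[0]!r} and {name!r} share no hydrogen-bond "
                "keys; check that the atom naming convention matches",
                stacklevel=2)
    rows = []
    for key in all_keys:
        occ = [float(keysets[s].get(key, 0.0)) for s in systems]
        row = {"donor": key[0], "hydrogen": key[1], "acceptor": key[2]}
        row.update({f"occupancy_percent:{s}": o for s, o in zip(systems, occ)})
        row["in_network"] = max(occ) >= config.report_threshold
        rows.append(row)
    cols = (["donor", "hydrogen", "acceptor"]
            + [f"occupancy_percent:{s}" for s in systems] + ["in_network"])
    return pd.DataFrame(rows, columns=cols)


def network_json(comparison: pd.DataFrame) -> dict:
    """Graph view of a differential (or single) occupancy table.

    Nodes are residues, edges are bonds above the report threshold with the
    per-system occupancy vector as attribute.  Returns a node-link dict
    ready for JSON serialisation.
    """
    import networkx as nx

    occ_cols = [c for c in comparison.columns
                if c.startswith("occupancy_percent")]
    g = nx.Graph()
    view = comparison[comparison["in_network"]] \
        if "in_network" in comparison.columns else comparison
    for _, row in view.iterrows():
        dres = row["donor"].split("@")[0] + "^" + row["donor"].split("^")[-1]
        ares = row["acceptor"].split("@")[0] + "^" + row["acceptor"].split("^")[-1]
        g.add_node(dres)
        g.add_node(ares)
        g.add_edge(dres, ares,
                   donor=row["donor"], hydrogen=row["hydrogen"],
                   acceptor=row["acceptor"],
                   occupancy=[float(row[c]) for c in occ_cols])
    return nx.node_link_data(g, edges="edges")
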