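"""Topology, trajectory and component-map I/O.

The package reads structures from multi-model PDB files.  Per-atom physical
parameters (mass, partial charge, Lennard-Jones parameters, intrinsic
generalized-Born radius) are not carried by the PDB format and are supplied
by a YAML *parameter sidecar* keyed on ``(residue_name, atom_name)``::

    atoms:
      GLY:
        N:  {mass: 14.01, charge: -0.4157, rmin_half: 1.824, epsilon: 0.17,
             radius: 1.55, screen: 0.79}
        ...
    bonds:
      - [1, 2]        # atom serial pairs

Bonds are listed by atom serial.  ``screen`` (the HCT descreening scale) and
``radius`` are optional; ``screen`` defaults to an element-based table and a
missing ``radius`` only matters when a GB calculation is requested.

Residues are re-indexed 0-based internally (``residue_index``); user-facing
labels always carry the original PDB residue number and chain id, e.g.
``SER_110@O^CD94`` once a component map is attached.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "ComponentMap",
    "TopologyError",
    "TrajectoryError",
    "ComponentMapError",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "write_topology",
    "load_component_map",
    "default_mhc_component_map",
    "write_table",
    "read_table",
]

#: HCT descreening scale factors by element (Amber mbondi2 convention).
DEFAULT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "F": 0.88,
                  "P": 0.86, "S": 0.96}


class TopologyError(ValueError):
    pass


class TrajectoryError(ValueError):
    pass


class ComponentMapError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One parameterized atom.

    Units: mass in amu, charge in elementary charges, ``lj_rmin_half`` and
    ``intrinsic_radius`` in Å, ``lj_epsilon`` in kcal/mol.
    """

    serial: int
    name: str
    element: str
    mass: float
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    intrinsic_radius: float | None
    gb_screen: float
    residue_index: int
    residue_name: str
    chain_id: str
    resid: int  # original PDB residue number

    def __post_init__(self):
        if self.mass <= 0:
            raise TopologyError(
                f"atom {self.name} in {self.residue_name}_{self.resid}: mass must be > 0"
            )
        if self.intrinsic_radius is not None and self.intrinsic_radius <= 0:
            raise TopologyError(
                f"atom {self.name} in {self.residue_name}_{self.resid}: "
                "intrinsic radius must be > 0"
            )


@dataclass
class Residue:
    index: int            # 0-based internal index
    name: str
    chain_id: str
    resid: int            # original PDB number
    atom_indices: np.ndarray  # positions in Topology.atoms

    @property
    def label(self) -> str:
        return f"{self.name}_{self.resid}"


class Topology:
    """Ordered atoms plus derived residue/chain structure and bonds."""

    def __init__(self, atoms: Sequence[AtomRecord],
                 bonds: Iterable[tuple[int, int]] = ()):
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise TopologyError(f"duplicate atom serial(s): {dup}")
        self._serial_to_index = {s: i for i, s in enumerate(serials)}
        self.bonds: list[tuple[int, int]] = []
        for a, b in bonds:
            if a not in self._serial_to_index or b not in self._serial_to_index:
                raise TopologyError(f"bond ({a}, {b}) references unknown atom serial")
            self.bonds.append((a, b))
        self._build_residues()

    def _build_residues(self):
        self.residues: list[Residue] = []
        current_key = None
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.resid, atom.residue_name)
            if key != current_key:
                self.residues.append(Residue(
                    index=len(self.residues), name=atom.residue_name,
                    chain_id=atom.chain_id, resid=atom.resid,
                    atom_indices=np.array([], dtype=int)))
                current_key = key
            res = self.residues[-1]
            res.atom_indices = np.append(res.atom_indices, i)
            if atom.residue_index != res.index:
                # re-index: atoms may come with file-local numbering
                self.atoms[i] = replace(atom, residue_index=res.index)
        self.chains: list[str] = []
        for atom in self.atoms:
            if atom.chain_id not in self.chains:
                self.chains.append(atom.chain_id)

    # -- convenience array views ------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    @property
    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    @property
    def gb_screen(self) -> np.ndarray:
        return np.array([a.gb_screen for a in self.atoms])

    def intrinsic_radii(self) -> np.ndarray:
        radii = []
        for a in self.atoms:
            if a.intrinsic_radius is None:
                raise TopologyError(
                    f"atom {a.name} in {a.residue_name}_{a.resid} has no "
                    "intrinsic radius; a GB calculation requires one")
            radii.append(a.intrinsic_radius)
        return np.array(radii)

    def index_of_serial(self, serial: int) -> int:
        return self._serial_to_index[serial]

    def bond_index_pairs(self) -> np.ndarray:
        return np.array(
            [(self._serial_to_index[a], self._serial_to_index[b])
             for a, b in self.bonds], dtype=int).reshape(-1, 2)

    def atom_label(self, index: int,
                   component_map: "ComponentMap | None" = None) -> str:
        a = self.atoms[index]
        base = f"{a.residue_name}_{a.resid}@{a.name}"
        if component_map is not None:
            comp = component_map.component_of_residue(a.residue_index)
            suffix = comp if comp is not None else a.chain_id
        else:
            suffix = a.chain_id
        return f"{base}^{suffix}"

    def residue_label(self, residue_index: int,
                      component_map: "ComponentMap | None" = None) -> str:
        r = self.residues[residue_index]
        if component_map is not None:
            comp = component_map.component_of_residue(residue_index)
            suffix = comp if comp is not None else r.chain_id
        else:
            suffix = r.chain_id
        return f"{r.label}^{suffix}"


@dataclass
class Trajectory:
    """frames × atoms × 3 coordinates in Å with a half-open frame window."""

    coordinates: np.ndarray
    frame_times: np.ndarray | None = None  # ns
    window: tuple[int, int] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if self.window is None:
            self.window = (0, self.n_frames)
        start, end = self.window
        if not (0 <= start <= end <= self.n_frames):
            raise TrajectoryError(
                f"window {self.window} outside [0, {self.n_frames})")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def windowed(self) -> np.ndarray:
        start, end = self.window
        return self.coordinates[start:end]

    @property
    def window_length(self) -> int:
        return self.window[1] - self.window[0]

    def with_window(self, start: int, end: int) -> "Trajectory":
        return Trajectory(self.coordinates, self.frame_times, (start, end))

    def last_n_frames(self, n: int) -> "Trajectory":
        return self.with_window(max(0, self.n_frames - n), self.n_frames)

    def last_time(self, duration_ns: float) -> "Trajectory":
        """Window covering the trailing ``duration_ns`` of the run."""
        if self.frame_times is None:
            raise TrajectoryError("time-based selection requires frame_times")
        cut = self.frame_times[-1] - duration_ns
        start = int(np.searchsorted(self.frame_times, cut, side="left"))
        return self.with_window(start, self.n_frames)


@dataclass
class ComponentMap:
    """Assignment of residues to named components (HLA-E_a1, β2m, ...)."""

    entries: list[tuple[str, str, tuple[int, int]]]  # (name, chain, (lo, hi) resids, inclusive)
    residue_component: list[str | None]              # per internal residue index
    unassigned: list[int] = field(default_factory=list)

    @property
    def component_names(self) -> list[str]:
        seen: list[str] = []
        for name, _, _ in self.entries:
            if name not in seen:
                seen.append(name)
        return seen

    def component_of_residue(self, residue_index: int) -> str | None:
        return self.residue_component[residue_index]

    def residues_of(self, name: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.residue_component)
                         if c == name], dtype=int)

    def atoms_of(self, name: str, topology: Topology) -> np.ndarray:
        keep = set(self.residues_of(name).tolist())
        return np.array([i for i, a in enumerate(topology.atoms)
                         if a.residue_index in keep], dtype=int)


# ---------------------------------------------------------------------------
# readers


def _load_sidecar(params_path) -> tuple[dict, list[tuple[int, int]]]:
    with open(params_path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "atoms" not in data:
        raise TopologyError(f"{params_path}: sidecar must contain an 'atoms' mapping")
    bonds = [tuple(b) for b in data.get("bonds", [])]
    return data["atoms"], bonds


def read_topology(pdb_path, params_path) -> Topology:
    """Read a (first-model) PDB plus parameter sidecar into a Topology.

    Raises :class:`TopologyError` naming the residue and atom when the
    sidecar lacks an entry, and on duplicate serial numbers.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("topology", str(pdb_path))
    models = list(structure)
    if not models:
        raise TopologyError(f"{pdb_path}: no models found")
    params, bonds = _load_sidecar(params_path)

    atoms: list[AtomRecord] = []
    res_counter = -1
    prev_key = None
    for chain in models[0]:
        for residue in chain:
            resname = residue.get_resname().strip()
            resid = residue.get_id()[1]
            key = (chain.id, resid, resname)
            if key != prev_key:
                res_counter += 1
                prev_key = key
            res_params = params.get(resname, {})
            for atom in residue:
                name = atom.get_name().strip()
                p = res_params.get(name)
                if p is None:
                    raise TopologyError(
                        f"missing parameters for atom '{name}' of residue "
                        f"'{resname}' (chain {chain.id}, residue {resid}) "
                        f"in sidecar")
                for fld in ("mass", "charge", "rmin_half", "epsilon"):
                    if fld not in p:
                        raise TopologyError(
                            f"missing '{fld}' for atom '{name}' of residue "
                            f"'{resname}' in sidecar")
                element = p.get("element") or (atom.element or "").strip() \
                    or _guess_element(name)
                atoms.append(AtomRecord(
                    serial=int(atom.get_serial_number()),
                    name=name,
                    element=element,
                    mass=float(p["mass"]),
                    charge=float(p["charge"]),
                    lj_rmin_half=float(p["rmin_half"]),
                    lj_epsilon=float(p["epsilon"]),
                    intrinsic_radius=(None if p.get("radius") is None
                                      else float(p["radius"])),
                    gb_screen=float(p.get("screen",
                                          DEFAULT_SCREEN.get(element, 0.8))),
                    residue_index=res_counter,
                    residue_name=resname,
                    chain_id=chain.id,
                    resid=resid,
                ))
    return Topology(atoms, bonds)


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_trajectory(path, topology: Topology) -> Trajectory:
    """Read a multi-model PDB as a trajectory ordered by MODEL number."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("trajectory", str(path))
    models = sorted(structure, key=lambda m: m.serial_num)
    if not models:
        raise TrajectoryError(f"{path}: no models found")
    frames = []
    for k, model in enumerate(models):
        coords = np.array([atom.get_coord()
                           for chain in model
                           for residue in chain
                           for atom in residue], dtype=float)
        if coords.shape[0] != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: model {model.serial_num or k + 1} has "
                f"{coords.shape[0]} atoms, topology has {topology.n_atoms}")
        frames.append(coords)
    return Trajectory(np.stack(frames))


# ---------------------------------------------------------------------------
# writers

_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{alt:1s}{resname:<3s} {chain:1s}"
             "{resid:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
             "{b:6.2f}          {element:>2s}\n")


def _atom_line(atom: AtomRecord, xyz, bfactor: float = 0.0) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return _PDB_ATOM.format(
        serial=atom.serial % 100000, name=name, alt=" ",
        resname=atom.residue_name[:3], chain=atom.chain_id[:1] or "A",
        resid=atom.resid % 10000, icode=" ",
        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=bfactor,
        element=atom.element[:2])


def write_trajectory(path, topology: Topology, trajectory: Trajectory,
                     window_only: bool = False,
                     bfactors: np.ndarray | None = None) -> None:
    """Write a multi-model PDB (fixed 3-decimal coordinate precision)."""
    coords = trajectory.windowed if window_only else trajectory.coordinates
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for i, atom in enumerate(topology.atoms):
                b = 0.0 if bfactors is None else float(bfactors[i])
                fh.write(_atom_line(atom, frame[i], b))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_topology(pdb_path, params_path, topology: Topology,
                   coordinates: np.ndarray | None = None) -> None:
    """Write a single-model PDB plus the YAML parameter sidecar."""
    coords = (np.zeros((topology.n_atoms, 3))
              if coordinates is None else np.asarray(coordinates))
    with open(pdb_path, "w") as fh:
        fh.write("MODEL        1\n")
        for i, atom in enumerate(topology.atoms):
            fh.write(_atom_line(atom, coords[i]))
        fh.write("ENDMDL\nEND\n")
    params: dict = {}
    for a in topology.atoms:
        entry = {"mass": float(a.mass), "charge": float(a.charge),
                 "rmin_half": float(a.lj_rmin_half),
                 "epsilon": float(a.lj_epsilon),
                 "screen": float(a.gb_screen), "element": a.element}
        if a.intrinsic_radius is not None:
            entry["radius"] = float(a.intrinsic_radius)
        params.setdefault(a.residue_name, {})[a.name] = entry
    doc = {"atoms": params, "bonds": [list(b) for b in topology.bonds]}
    with open(params_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# component maps


def load_component_map(config, topology: Topology) -> ComponentMap:
    """Validate a component map against a topology.

    ``config`` is a sequence of mappings with keys ``component``, ``chain``,
    ``start``, ``stop`` (original PDB residue numbers, inclusive), or a path
    to a YAML file holding such a list under the key ``components``.
    Overlapping ranges and ranges outside their chain raise
    :class:`ComponentMapError`; unassigned residues are recorded, not fatal.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)["components"]
    entries: list[tuple[str, str, tuple[int, int]]] = []
    assignment: list[str | None] = [None] * topology.n_residues
    by_chain: dict[str, list[Residue]] = {}
    for r in topology.residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for item in config:
        name, chain = item["component"], str(item["chain"])
        lo, hi = int(item["start"]), int(item["stop"])
        if lo > hi:
            raise ComponentMapError(f"{name}: empty range {lo}-{hi}")
        if chain not in by_chain:
            raise ComponentMapError(f"{name}: chain '{chain}' not in topology")
        resids = {r.resid for r in by_chain[chain]}
        if lo < min(resids) or hi > max(resids):
            raise ComponentMapError(
                f"{name}: range {lo}-{hi} outside chain {chain} "
                f"({min(resids)}-{max(resids)})")
        for r in by_chain[chain]:
            if lo <= r.resid <= hi:
                if assignment[r.index] is not None:
                    raise ComponentMapError(
                        f"residue {r.label} (chain {chain}) assigned to both "
                        f"'{assignment[r.index]}' and '{name}'")
                assignment[r.index] = name
        entries.append((name, chain, (lo, hi)))
    unassigned = [i for i, c in enumerate(assignment) if c is None]
    if unassigned:
        labels = [topology.residues[i].label for i in unassigned[:10]]
        warnings.warn(f"{len(unassigned)} residue(s) unassigned by component "
                      f"map (e.g. {labels})", stacklevel=2)
    return ComponentMap(entries, assignment, unassigned)


def default_mhc_component_map(topology: Topology,
                              heavy_chain: str = "A",
                              b2m_chain: str = "B",
                              cd94_chain: str = "C",
                              nkg2c_chain: str = "N",
                              peptide_chain: str = "P") -> ComponentMap:
    """Conventional MHC class I heavy-chain domain split.

    α1 = residues 1–90, α2 = 91–182, α3 = 183–end of the heavy chain; every
    other chain becomes one whole-chain component.  The split is a field
    convention (the exact boundaries are structure-dependent) and should be
    overridden with :func:`load_component_map` when known.
    """
    by_chain: dict[str, list[Residue]] = {}
    for r in topology.residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    config = []
    names = {b2m_chain: "B2M", cd94_chain: "CD94",
             nkg2c_chain: "NKG2C", peptide_chain: "peptide"}
    for chain, residues in by_chain.items():
        lo = min(r.resid for r in residues)
        hi = max(r.resid for r in residues)
        if chain == heavy_chain:
            config.append({"component": "HLA-E_a1", "chain": chain,
                           "start": lo, "stop": min(90, hi)})
            if hi > 90:
                config.append({"component": "HLA-E_a2", "chain": chain,
                               "start": 91, "stop": min(182, hi)})
            if hi > 182:
                config.append({"component": "HLA-E_a3", "chain": chain,
                               "start": 183, "stop": hi})
        else:
            config.append({"component": names.get(chain, chain),
                           "chain": chain, "start": lo, "stop": hi})
    return load_component_map(config, topology)


# ---------------------------------------------------------------------------
# tabular output

FLOAT_DECIMALS = 6


def write_table(records, path, format: str = "tsv",
                columns: Sequence[str] | None = None) -> None:
    """Write records (DataFrame or list of dicts) as TSV or JSON.

    Column order is deterministic (explicit ``columns`` or first-record
    order); floats are written with :data:`FLOAT_DECIMALS` decimals and
    round-trip losslessly at that precision through :func:`read_table`.
    """
    fmt = format.lower()
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unsupported table format: {format!r}")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if columns is None and records:
            columns = list(records[0].keys())
        df = pd.DataFrame(records, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False,
                  float_format=f"%.{FLOAT_DECIMALS}f")
    else:
        rows = []
        for rec in df.to_dict(orient="records"):
            rows.append({k: (round(v, FLOAT_DECIMALS)
                             if isinstance(v, float) and math.isfinite(v)
                             else v)
                         for k, v in rec.items()})
        with open(path, "w") as fh:
            json.dump({"columns": list(df.columns), "records": rows}, fh,
                      indent=1, sort_keys=False)
            fh.write("\n")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    fmt = format.lower()
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        return pd.DataFrame(data["records"], columns=data["columns"])
    raise ValueError(f"unsupported table format: {format!r}")
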