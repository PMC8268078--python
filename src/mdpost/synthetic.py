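"""Synthetic topologies and trajectories with known statistical structure.

Every analysis stage in the package has a generator here that plants the
feature the stage is supposed to measure, so recovery can be checked
against an exact ground truth:

* :func:`gaussian_block_trajectory` — residue displacement fields with
  prescribed component-pair cross-correlations,
* :func:`scripted_hbond_trajectory` — a donor–H–acceptor construct toggling
  between bonded and broken geometry on a known schedule,
* :func:`conformer_mixture_trajectory` — frames drawn from k well-separated
  rigid conformers plus coordinate noise,
* :func:`toy_charged_complex` — small charged systems with closed-form
  energies.

Correlated displacement fields are realised through a shared-mode (factor)
model rather than a direct Cholesky draw: each requested component pair
gets one latent Gaussian mode with loadings ±sqrt(|ρ|) on its two
components.  A dedicated counterweight ("bath") component, split between
the two ends of the chain, carries per-mode loadings solved so that every
mode has zero net loading and zero first moment along the chain axis.  The
resulting displacement field is orthogonal to rigid-body motions by
construction, which matters because the analysis chain removes the best-fit
rigid motion of every frame before computing correlations — a field in
which whole components co-move *is* largely a rigid motion, and the fit
would subtract the very signal being planted.  The exact correlation
matrix implied by the loadings is returned alongside the data.

All generators are bit-reproducible for a fixed seed.  Atoms carry unit-ish
carbon parameters unless specified, so mass-weighting is exercised by
dedicated non-uniform-mass fixtures rather than entangled with statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AtomRecord, ComponentMap, Topology, Trajectory, \
    load_component_map

__all__ = [
    "SyntheticSpec",
    "SyntheticError",
    "GaussianBlockResult",
    "ScriptedHBondResult",
    "ConformerMixtureResult",
    "gaussian_block_trajectory",
    "scripted_hbond_trajectory",
    "conformer_mixture_trajectory",
    "toy_charged_complex",
    "born_ion",
    "charge_pair",
    "lj_pair",
    "charged_dimer",
]


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters for the generators; each generator reads its own subset."""

    components: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("A", 30, 1), ("B", 30, 1), ("C", 30, 1)])
    block_correlations: dict[tuple[str, str], float] = field(
        default_factory=dict)
    fluctuation_sigma: float = 0.5     # Å
    n_frames: int = 2000
    seed: int = 0
    hbond_schedule: object = 0.5       # bonded fraction or [((s, e), flag)]
    conformers: tuple = (3, 5.0, 0.1, None)  # (k, separation Å, noise Å, weights)

    def __post_init__(self):
        if self.n_frames < 2:
            raise SyntheticError("n_frames must be >= 2")


def _atom(serial, name, element, mass, residue_index, resname, chain, resid,
          charge=0.0, rmin_half=1.908, epsilon=0.086, radius=1.7,
          screen=0.72) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element, mass=mass,
                      charge=charge, lj_rmin_half=rmin_half,
                      lj_epsilon=epsilon, intrinsic_radius=radius,
                      gb_screen=screen, residue_index=residue_index,
                      residue_name=resname, chain_id=chain, resid=resid)


# ---------------------------------------------------------------------------
# correlated Gaussian block trajectories


@dataclass
class GaussianBlockResult:
    topology: Topology
    trajectory: Trajectory
    component_map: ComponentMap
    expected_density: pd.DataFrame   # exact block correlation densities
    loadings: np.ndarray             # residues × modes
    residue_correlation: np.ndarray  # exact residue-level target matrix

    def __iter__(self):  # tuple-style unpacking (topology, trajectory, map)
        return iter((self.topology, self.trajectory, self.component_map))


def gaussian_block_trajectory(spec: SyntheticSpec,
                              bath_size: int | None = None
                              ) -> GaussianBlockResult:
    """Trajectory whose residue DCC has prescribed component-pair values.

    ``spec.block_correlations`` maps ``(comp_a, comp_b)`` to the target
    cross-correlation ρ (``(a, a)`` entries plant within-component
    correlation and must be ≥ 0).  Requested pairs are realised exactly in
    expectation; unrequested pairs are 0.  Infeasible targets — loadings
    whose squares sum past 1 for some component, i.e. no valid correlation
    matrix — raise :class:`SyntheticError` naming the component.  A
    counterweight bath component (size ``bath_size`` per half, default the
    total named size) is appended when any mode is active.
    """
    comps = list(spec.components)
    if not comps:
        raise SyntheticError("at least one component required")
    atoms_per = {int(c[2]) for c in comps}
    if len(atoms_per) != 1:
        raise SyntheticError("all components must share atoms_per_residue")
    apr = atoms_per.pop()
    names = [c[0] for c in comps]

    # one latent mode per requested block target
    modes: list[dict[str, float]] = []
    for (a, b), rho in spec.block_correlations.items():
        if a not in names or b not in names:
            raise SyntheticError(f"block ({a}, {b}) references unknown component")
        if abs(rho) > 1:
            raise SyntheticError(f"block ({a}, {b}): |rho| must be <= 1")
        if a == b:
            if rho < 0:
                raise SyntheticError(
                    f"block ({a}, {a}): a within-component target must be "
                    ">= 0 (an all-pairs negative block is not a valid "
                    "correlation matrix)")
            modes.append({a: float(np.sqrt(rho))})
        else:
            root = float(np.sqrt(abs(rho)))
            modes.append({a: root, b: float(np.sign(rho)) * root})

    for name in names:
        ssq = sum(m.get(name, 0.0) ** 2 for m in modes)
        if ssq > 1 + 1e-12:
            raise SyntheticError(
                f"block correlation targets infeasible for component "
                f"'{name}' (summed squared loadings {ssq:.3f} > 1; the "
                "requested blocks do not form a valid correlation matrix)")

    total_named = sum(c[1] for c in comps)
    use_bath = bool(modes)
    nb = (total_named if bath_size is None else int(bath_size)) if use_bath else 0

    # global residue layout: bath half, named components, bath half
    segments: list[tuple[str, str, int]] = []   # (component, chain, n_res)
    if use_bath:
        segments.append(("bath", "0", nb))
    for i, (name, n_res, _) in enumerate(comps):
        segments.append((name, chr(ord("A") + i), n_res))
    if use_bath:
        segments.append(("bath", "1", nb))

    n_total = sum(s[2] for s in segments)
    g = np.arange(n_total)
    base = np.column_stack([3.8 * g, 1.5 * np.cos(0.7 * g),
                            1.5 * np.sin(0.7 * g)])

    # residue index ranges per segment
    bounds, pos = [], 0
    for _, _, n in segments:
        bounds.append((pos, pos + n))
        pos += n

    # loading matrix over residues; bath loadings solved per mode so each
    # mode has zero net loading and zero x-moment (rigid-motion-free field)
    loadings = np.zeros((n_total, len(modes)))
    x = base[:, 0]
    for m, mode in enumerate(modes):
        for (comp, _, _), (lo, hi) in zip(segments, bounds):
            if comp in mode:
                loadings[lo:hi, m] = mode[comp]
        if use_bath:
            (b1lo, b1hi) = bounds[0]
            (b2lo, b2hi) = bounds[-1]
            s0 = loadings[b1hi:b2lo, m].sum()
            s1 = (loadings[b1hi:b2lo, m] * x[b1hi:b2lo]).sum()
            mat = np.array([[nb, nb],
                            [x[b1lo:b1hi].sum(), x[b2lo:b2hi].sum()]])
            k1, k2 = np.linalg.solve(mat, [-s0, -s1])
            loadings[b1lo:b1hi, m] = k1
            loadings[b2lo:b2hi, m] = k2
    if use_bath:
        bath_ssq = (loadings[bounds[0][0]:bounds[0][1]] ** 2).sum(axis=1).max(
            initial=0.0)
        bath_ssq = max(bath_ssq,
                       (loadings[bounds[-1][0]:bounds[-1][1]] ** 2)
                       .sum(axis=1).max(initial=0.0))
        if bath_ssq > 1 + 1e-12:
            raise SyntheticError(
                "counterweight bath loadings exceed unit variance "
                f"({bath_ssq:.3f}); increase bath_size")

    noise_var = np.clip(1.0 - (loadings ** 2).sum(axis=1), 0.0, None)
    corr = loadings @ loadings.T + np.diag(noise_var)

    rng = np.random.default_rng(spec.seed)
    gmodes = rng.standard_normal((spec.n_frames, len(modes), 3))
    eps = rng.standard_normal((spec.n_frames, n_total, 3))
    disp = np.einsum("im,fmk->fik", loadings, gmodes) if modes else 0.0
    disp = spec.fluctuation_sigma * (disp + np.sqrt(noise_var)[None, :, None] * eps)

    # atoms: 'CA' plus optional satellites, rigidly following the residue
    offsets = np.zeros((apr, 3))
    for k in range(1, apr):
        ang = 2 * np.pi * k / max(apr - 1, 1)
        offsets[k] = 0.8 * np.array([0.0, np.cos(ang), np.sin(ang)])

    atoms, bonds = [], []
    serial = 1
    for (comp, chain, n), (lo, hi) in zip(segments, bounds):
        for r in range(lo, hi):
            first = serial
            for k in range(apr):
                name = "CA" if k == 0 else f"CB{k}"
                atoms.append(_atom(serial, name, "C", 12.011, r, "SYN",
                                   chain, r - lo + 1))
                if k > 0:
                    bonds.append((first, serial))
                serial += 1
    topology = Topology(atoms, bonds)

    res_coords = base[None, :, :] + disp                    # frames × res × 3
    coords = (res_coords[:, :, None, :] + offsets[None, None, :, :]) \
        .reshape(spec.n_frames, n_total * apr, 3)
    trajectory = Trajectory(coords)

    config = [{"component": comp, "chain": chain, "start": 1, "stop": n}
              for (comp, chain, n) in segments]
    cmap = load_component_map(config, topology)

    cnames = cmap.component_names
    dens = np.zeros((len(cnames), len(cnames)))
    for i, a in enumerate(cnames):
        ia = cmap.residues_of(a)
        for j, b in enumerate(cnames):
            ib = cmap.residues_of(b)
            dens[i, j] = corr[np.ix_(ia, ib)].mean()
    expected = pd.DataFrame(dens, index=cnames, columns=cnames)
    return GaussianBlockResult(topology, trajectory, cmap, expected,
                               loadings, corr)


# ---------------------------------------------------------------------------
# scripted hydrogen-bond trajectories


@dataclass
class ScriptedHBondResult:
    topology: Topology
    trajectory: Trajectory
    bonded: np.ndarray   # per-frame ground-truth flag

    def __iter__(self):
        return iter((self.topology, self.trajectory))


#: x-shift of the acceptor residue in broken frames (2.8 Å → 5.0 Å)
_HB_BROKEN_OFFSET = 2.2


def scripted_hbond_trajectory(spec: SyntheticSpec,
                              shuffle: bool = False) -> ScriptedHBondResult:
    """Donor–H–acceptor toy toggling between bonded and broken frames.

    Bonded frames place the acceptor O at d(N, O) = 2.8 Å on the N–H axis
    (angle 180°); broken frames move it to 5.0 Å.  ``spec.hbond_schedule``
    is either a bonded fraction p — ``round(p·n_frames)`` bonded frames,
    placed first (or shuffled under the seed when ``shuffle``) — or an
    explicit list of ``((start, end), bonded)`` half-open ranges that must
    tile the frame axis without overlap.
    """
    n = spec.n_frames
    schedule = spec.hbond_schedule
    bonded = np.zeros(n, dtype=bool)
    if isinstance(schedule, (int, float)):
        p = float(schedule)
        if not 0 <= p <= 1:
            raise SyntheticError("bonded fraction must be in [0, 1]")
        k = int(round(p * n))
        bonded[:k] = True
        if shuffle:
            rng = np.random.default_rng(spec.seed)
            bonded = bonded[rng.permutation(n)]
    else:
        seen = np.zeros(n, dtype=int)
        for (start, end), flag in schedule:
            if not (0 <= start <= end <= n):
                raise SyntheticError(f"schedule range ({start}, {end}) "
                                     f"outside [0, {n})")
            seen[start:end] += 1
            bonded[start:end] = bool(flag)
        if np.any(seen > 1):
            raise SyntheticError("overlapping schedule ranges")
        if np.any(seen == 0):
            raise SyntheticError("schedule does not cover all frames")

    atoms = [
        _atom(1, "N", "N", 14.007, 0, "DON", "A", 1, charge=-0.3),
        _atom(2, "H", "H", 1.008, 0, "DON", "A", 1, charge=0.3,
              rmin_half=0.6, epsilon=0.0157, radius=1.2, screen=0.85),
        _atom(3, "C", "C", 12.011, 1, "ACC", "A", 2, charge=0.3),
        _atom(4, "O", "O", 15.999, 1, "ACC", "A", 2, charge=-0.3,
              radius=1.5, screen=0.85),
    ]
    topology = Topology(atoms, bonds=[(1, 2), (3, 4)])

    frame_bonded = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [4.5, 0.8, 0.0], [2.8, 0.0, 0.0]])
    shift = np.array([_HB_BROKEN_OFFSET, 0.0, 0.0])
    coords = np.repeat(frame_bonded[None, :, :], n, axis=0)
    coords[~bonded, 2] += shift
    coords[~bonded, 3] += shift
    return ScriptedHBondResult(topology, Trajectory(coords), bonded)


# ---------------------------------------------------------------------------
# conformer mixtures


@dataclass
class ConformerMixtureResult:
    topology: Topology
    trajectory: Trajectory
    labels: np.ndarray          # generating conformer per frame
    conformers: np.ndarray      # k × atoms × 3

    def __iter__(self):
        return iter((self.topology, self.trajectory, self.labels))


_BACKBONE_TEMPLATE = [  # (name, element, mass, local offset)
    ("N", "N", 14.007, (0.0, 0.0, 0.0)),
    ("CA", "C", 12.011, (1.2, 0.9, 0.0)),
    ("C", "C", 12.011, (2.4, 0.0, 0.3)),
    ("O", "O", 15.999, (2.9, 1.0, 0.8)),
]


def conformer_mixture_trajectory(spec: SyntheticSpec,
                                 n_residues: int = 5
                                 ) -> ConformerMixtureResult:
    """Frames drawn from k rigid conformers plus isotropic noise.

    ``spec.conformers`` is ``(k, separation, noise, weights)``: conformer
    deformation fields are scaled until every pair differs by at least
    ``separation`` Å of best-fit mass-weighted backbone RMSD, frames are
    assigned multinomially by ``weights`` (uniform when None) and per-atom
    Gaussian noise of s.d. ``noise`` Å is added.  Ground-truth labels are
    returned.
    """
    from .geometry import kabsch_fit, select_backbone

    k, separation, noise, weights = spec.conformers
    k = int(k)
    if k < 1:
        raise SyntheticError("number of conformers must be >= 1")
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (k,) or abs(weights.sum() - 1.0) > 1e-9:
        raise SyntheticError("weights must be k probabilities summing to 1")

    atoms, base = [], []
    serial = 1
    for r in range(n_residues):
        for name, element, mass, off in _BACKBONE_TEMPLATE:
            atoms.append(_atom(serial, name, element, mass, r, "ALA", "A",
                               r + 1))
            base.append(np.array(off) + [3.8 * r, 0.0, 0.0])
            serial += 1
    topology = Topology(atoms)
    base = np.array(base)

    rng = np.random.default_rng(spec.seed)
    fields = rng.standard_normal((k, base.shape[0], 3))
    sel = select_backbone(topology)
    masses = topology.masses[sel]
    scale = float(separation) if k > 1 else 0.0
    conformers = base[None] + scale * fields
    if k > 1:
        for _ in range(20):
            min_rmsd = min(
                kabsch_fit(conformers[j, sel], conformers[i, sel],
                           masses).rmsd
                for i in range(k) for j in range(i + 1, k))
            if min_rmsd >= separation:
                break
            scale *= 1.05 * separation / max(min_rmsd, 1e-12)
            conformers = base[None] + scale * fields

    labels = rng.choice(k, size=spec.n_frames, p=weights)
    coords = conformers[labels] + noise * rng.standard_normal(
        (spec.n_frames, base.shape[0], 3))
    return ConformerMixtureResult(topology, Trajectory(coords), labels,
                                  conformers)


# ---------------------------------------------------------------------------
# toy charged systems for energy oracles


def toy_charged_complex(atom_specs: list[dict],
                        bonds: list[tuple[int, int]] = ()
                        ) -> tuple[Topology, np.ndarray]:
    """Small user-defined charged system for closed-form energy checks.

    Each atom spec may set ``name, element, charge, radius, rmin_half,
    epsilon, mass, screen, residue, resname, chain, position``; sensible
    defaults fill the rest.  Returns the topology and the coordinate array.
    """
    atoms, coords = [], []
    for i, a in enumerate(atom_specs):
        atoms.append(AtomRecord(
            serial=i + 1,
            name=a.get("name", f"X{i + 1}"),
            element=a.get("element", "C"),
            mass=a.get("mass", 12.011),
            charge=a.get("charge", 0.0),
            lj_rmin_half=a.get("rmin_half", 1.7),
            lj_epsilon=a.get("epsilon", 0.1),
            intrinsic_radius=a.get("radius", 1.5),
            gb_screen=a.get("screen", 1.0),
            residue_index=a.get("residue", i),
            residue_name=a.get("resname", "TOY"),
            chain_id=a.get("chain", "A"),
            resid=a.get("resid", a.get("residue", i) + 1),
        ))
        coords.append(a.get("position", (0.0, 0.0, 0.0)))
    return Topology(atoms, bonds), np.asarray(coords, dtype=float)


def born_ion(charge: float = 1.0, radius: float = 2.0):
    """Single ion: the Born-equation limit of the GB model."""
    return toy_charged_complex([{"charge": charge, "radius": radius,
                                 "name": "ION"}])


def charge_pair(separation: float = 1.0, q1: float = 1.0, q2: float = 1.0):
    """Two point charges; Coulomb energy k_e q1 q2 / r."""
    return toy_charged_complex([
        {"charge": q1, "position": (0.0, 0.0, 0.0), "residue": 0},
        {"charge": q2, "position": (separation, 0.0, 0.0), "residue": 1},
    ])


def lj_pair(rmin_half: float = 1.7, epsilon: float = 0.1,
            separation: float | None = None):
    """Two neutral LJ particles, by default at the potential minimum."""
    if separation is None:
        separation = 2 * rmin_half
    return toy_charged_complex([
        {"charge": 0.0, "rmin_half": rmin_half, "epsilon": epsilon,
         "position": (0.0, 0.0, 0.0), "residue": 0},
        {"charge": 0.0, "rmin_half": rmin_half, "epsilon": epsilon,
         "position": (separation, 0.0, 0.0), "residue": 1},
    ])


def charged_dimer(separation: float = 6.0):
    """Two charged beads in separate residues — an MM-GBSA toy system.

    At the default separation the LJ spheres do not overlap their solvent-
    accessible surfaces, so the ΔSASA term vanishes identically and the
    binding energy is purely electrostatic + LJ + GB desolvation.
    """
    return toy_charged_complex([
        {"charge": 1.0, "radius": 1.5, "rmin_half": 1.7, "epsilon": 0.1,
         "position": (0.0, 0.0, 0.0), "residue": 0, "chain": "A",
         "resname": "CAT"},
        {"charge": -1.0, "radius": 1.5, "rmin_half": 1.7, "epsilon": 0.1,
         "position": (separation, 0.0, 0.0), "residue": 1, "chain": "B",
         "resname": "ANI"},
    ])
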