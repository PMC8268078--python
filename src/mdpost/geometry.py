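"""Superposition, average structures, RMSD series and RMSF/B-factor profiles.

All fits are weighted least-squares rigid-body superpositions (Kabsch);
reflections are always rejected so chirality is preserved.  Removing the
best-fit rigid motion of every frame relative to the iteratively converged
average structure is what isolates internal dynamics before fluctuation and
correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "GeometryError",
    "kabsch_fit",
    "average_structure",
    "fit_trajectory",
    "rmsd_series",
    "rmsf",
    "select_all",
    "select_heavy",
    "select_backbone",
    "select_alpha_carbons",
]

BFACTOR_FACTOR = 8.0 * np.pi ** 2 / 3.0

BACKBONE_NAMES = ("N", "CA", "C", "O")


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# atom selections


def select_all(topology: Topology) -> np.ndarray:
    return np.arange(topology.n_atoms)


def select_heavy(topology: Topology) -> np.ndarray:
    return np.array([i for i, a in enumerate(topology.atoms)
                     if a.element != "H"], dtype=int)


def select_backbone(topology: Topology) -> np.ndarray:
    """N, CA, C, O atoms — the protein backbone convention."""
    return np.array([i for i, a in enumerate(topology.atoms)
                     if a.name in BACKBONE_NAMES], dtype=int)


def select_alpha_carbons(topology: Topology) -> np.ndarray:
    return np.array([i for i, a in enumerate(topology.atoms)
                     if a.name == "CA"], dtype=int)


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray    # 3×3 proper orthonormal
    translation: np.ndarray  # Å
    rmsd: float             # weighted RMSD after the fit, Å

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise GeometryError(f"weights shape {w.shape} != ({n},)")
    if np.any(w < 0):
        raise GeometryError("weights must be non-negative")
    if w.sum() <= 0:
        raise GeometryError("total weight must be positive")
    return w


def kabsch_fit(mobile_coords: np.ndarray, reference_coords: np.ndarray,
               weights=None) -> SuperpositionResult:
    """Optimal proper rigid transform taking ``mobile`` onto ``reference``.

    Minimizes ``sum_i w_i |ref_i - (R mob_i + t)|^2`` over proper rotations R
    (det = +1) and translations t; the returned ``rmsd`` is
    ``sqrt(min / sum(w))``, i.e. the (mass-)weighted RMSD after the fit.
    Degenerate inputs (fewer than 3 points, collinear points, zero total
    weight) raise :class:`GeometryError`.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 points")
    w = _check_weights(n, weights)
    wsum = w.sum()
    mob_c = (w[:, None] * mob).sum(axis=0) / wsum
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    for pts in (mob0, ref0):
        sv = np.linalg.svd(pts * np.sqrt(w)[:, None], compute_uv=False)
        if sv[1] <= 1e-10 * max(1.0, sv[0]):
            raise GeometryError("degenerate (collinear) point set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    # recompute the residual directly: align_vectors' rssd loses precision
    # near zero, and exact rigid motions must report rmsd ~ machine epsilon
    d2 = ((ref0 - mob0 @ R.T) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((w * d2).sum() / wsum))
    translation = ref_c - R @ mob_c
    return SuperpositionResult(R, translation, rmsd)


def fit_trajectory(trajectory: Trajectory, reference_coords: np.ndarray,
                   selection: np.ndarray | None = None,
                   weights=None) -> Trajectory:
    """Superpose every frame on ``reference_coords`` over ``selection``.

    The fit is computed on the selected atoms but applied to all atoms of the
    frame.  ``weights`` refers to the selected atoms (masses for a
    mass-weighted fit).
    """
    coords = trajectory.coordinates
    sel = np.arange(trajectory.n_atoms) if selection is None else selection
    ref_sel = np.asarray(reference_coords)[sel]
    out = np.empty_like(coords)
    for f in range(trajectory.n_frames):
        fit = kabsch_fit(coords[f, sel], ref_sel, weights)
        out[f] = fit.transform(coords[f])
    return Trajectory(out, trajectory.frame_times, trajectory.window)


def average_structure(trajectory: Trajectory,
                      selection: np.ndarray | None = None,
                      weights=None, tol: float = 1e-6,
                      max_iter: int = 20) -> np.ndarray:
    """Iterative rigid-motion-free mean structure of the window.

    Frames are fitted to the current mean (over ``selection``, with
    ``weights``), the mean is recomputed, and iteration stops once the mean
    displaces by less than ``tol`` Å (max per-coordinate change).  Raises on
    non-convergence, reporting the last displacement.
    """
    if tol <= 0:
        raise GeometryError("tol must be > 0")
    if max_iter < 1:
        raise GeometryError("max_iter must be >= 1")
    frames = trajectory.windowed
    if frames.shape[0] < 1:
        raise GeometryError("empty frame window")
    sel = np.arange(trajectory.n_atoms) if selection is None else selection
    mean = frames.mean(axis=0)
    for _ in range(max_iter):
        fitted = np.empty_like(frames)
        for f in range(frames.shape[0]):
            fit = kabsch_fit(frames[f, sel], mean[sel], weights)
            fitted[f] = fit.transform(frames[f])
        new_mean = fitted.mean(axis=0)
        displacement = np.abs(new_mean - mean).max()
        mean = new_mean
        if displacement < tol:
            return mean
    raise GeometryError(
        f"average structure did not converge in {max_iter} iterations "
        f"(last displacement {displacement:.3e} Å)")


def rmsd_series(trajectory: Trajectory, reference_coords: np.ndarray,
                selection: np.ndarray | None = None,
                weights=None, fit: bool = True) -> np.ndarray:
    """Per-frame (optionally mass-weighted, optionally fitted) RMSD in Å."""
    sel = np.arange(trajectory.n_atoms) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise GeometryError("empty selection")
    frames = trajectory.windowed[:, sel]
    ref = np.asarray(reference_coords)[sel]
    w = _check_weights(sel.size, weights)
    out = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        if fit:
            out[f] = kabsch_fit(frames[f], ref, w).rmsd
        else:
            d2 = ((frames[f] - ref) ** 2).sum(axis=1)
            out[f] = np.sqrt((w * d2).sum() / w.sum())
    return out


@dataclass
class FluctuationProfile:
    """Per-atom and per-residue RMSF (Å) with B-factors (Å²).

    ``bfactor = (8π²/3)·rmsf²`` elementwise, the crystallographic isotropic
    Debye-Waller conversion.
    """

    atom_rmsf: np.ndarray
    per_residue_rmsf: np.ndarray
    per_residue_bfactor: np.ndarray
    residue_labels: list[str]
    selection: str = "heavy atoms"

    def to_records(self):
        return [{"residue": lab,
                 "rmsf_A": float(r),
                 "bfactor_A2": float(b)}
                for lab, r, b in zip(self.residue_labels,
                                     self.per_residue_rmsf,
                                     self.per_residue_bfactor)]


def rmsf(trajectory: Trajectory, topology: Topology,
         selection: np.ndarray | None = None,
         selection_label: str = "heavy atoms") -> FluctuationProfile:
    """Root-mean-square fluctuations over the frame window.

    The trajectory is expected to have been fitted to its average structure
    beforehand (see :func:`average_structure` / :func:`fit_trajectory`);
    without that step rigid-body motion inflates the fluctuations.
    Per-residue values are mass-weighted means of the residue's selected
    atoms.
    """
    sel = select_heavy(topology) if selection is None else np.asarray(selection)
    frames = trajectory.windowed[:, sel]
    if frames.shape[0] < 2:
        raise GeometryError("RMSF requires a window of at least 2 frames")
    mean = frames.mean(axis=0)
    atom_rmsf = np.sqrt(((frames - mean) ** 2).sum(axis=2).mean(axis=0))
    masses = topology.masses[sel]
    res_of_sel = topology.residue_indices[sel]
    labels, res_rmsf = [], []
    for r in topology.residues:
        mask = res_of_sel == r.index
        if not mask.any():
            continue
        m = masses[mask]
        res_rmsf.append(float((m * atom_rmsf[mask]).sum() / m.sum()))
        labels.append(f"{r.label}^{r.chain_id}")
    res_rmsf = np.array(res_rmsf)
    return FluctuationProfile(
        atom_rmsf=atom_rmsf,
        per_residue_rmsf=res_rmsf,
        per_residue_bfactor=BFACTOR_FACTOR * res_rmsf ** 2,
        residue_labels=labels,
        selection=selection_label)
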