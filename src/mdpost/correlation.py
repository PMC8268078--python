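"""Dynamic cross-correlation and block correlation-density scores.

The dynamic cross-correlation (DCC) between residues i and j is the Pearson
normalisation of the scalar-product covariance of their displacement
vectors,

    CC_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²> <Δr_j²>),   Δr = r − <r>,

computed on a trajectory whose rigid-body motion has been removed by an
RMS fit to the average structure.  CC ranges from −1 (fully anticorrelated)
through 0 (uncorrelated) to +1 (fully correlated motion).

For a multi-component complex the N_res × N_res matrix is condensed into a
component-pair *correlation density*: the sum of CC_ij over the A×B block
divided by n_A·n_B, one dimensionless score per component pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ComponentMap, Topology, Trajectory

__all__ = [
    "CorrelationMatrix",
    "CorrelationError",
    "residue_representative_series",
    "cross_correlation_matrix",
    "block_correlation_density",
]


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    cc: np.ndarray             # N_res × N_res, symmetric, unit diagonal
    residue_labels: list[str]
    residue_indices: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cc, index=self.residue_labels,
                            columns=self.residue_labels)


def residue_representative_series(trajectory: Trajectory, topology: Topology,
                                  mode: str = "mass_center",
                                  selection: np.ndarray | None = None
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """One representative point per residue per frame.

    ``mode='mass_center'`` uses the mass-weighted centroid of the residue's
    heavy atoms (or of ``selection`` restricted to the residue);
    ``mode='alpha_carbon'`` uses the CA atom.  Returns ``(series, residue
    indices)`` with ``series`` of shape (frames, N_res, 3).  The trajectory
    should already be fitted to its average structure.
    """
    frames = trajectory.windowed
    if mode not in ("mass_center", "alpha_carbon"):
        raise CorrelationError(f"unknown mode {mode!r}")
    reps = []
    kept = []
    for r in topology.residues:
        idx = r.atom_indices
        if mode == "alpha_carbon":
            idx = np.array([i for i in idx if topology.atoms[i].name == "CA"],
                           dtype=int)
        else:
            idx = np.array([i for i in idx
                            if topology.atoms[i].element != "H"], dtype=int)
        if selection is not None:
            idx = np.intersect1d(idx, selection)
        if idx.size == 0:
            raise CorrelationError(
                f"residue {r.label} (chain {r.chain_id}) has no atoms under "
                f"mode {mode!r}")
        m = topology.masses[idx]
        reps.append((frames[:, idx] * m[None, :, None]).sum(axis=1) / m.sum())
        kept.append(r.index)
    return np.stack(reps, axis=1), np.array(kept, dtype=int)


def cross_correlation_matrix(reduced_series: np.ndarray,
                             topology: Topology | None = None,
                             residue_indices: np.ndarray | None = None
                             ) -> CorrelationMatrix:
    """Pearson DCC matrix of a (frames × N_res × 3) representative series.

    Zero-variance residues produce 0 off-diagonal and 1 on the diagonal
    (with a warning) instead of propagating NaN.
    """
    series = np.asarray(reduced_series, dtype=float)
    if series.ndim != 3 or series.shape[2] != 3:
        raise CorrelationError("reduced series must have shape (frames, N_res, 3)")
    n_frames, n_res = series.shape[:2]
    if n_frames < 2:
        raise CorrelationError("correlation requires at least 2 frames")
    disp = series - series.mean(axis=0, keepdims=True)
    # covariance of 3D displacement scalar products: sum over axes
    flat = disp.transpose(1, 0, 2)            # (N_res, frames, 3)
    cov = np.einsum("ifk,jfk->ij", flat, flat) / n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} residue(s) with zero variance; "
                      "their off-diagonal correlations are set to 0",
                      stacklevel=2)
        var[zero] = 1.0
    cc = cov / np.sqrt(np.outer(var, var))
    cc[zero, :] = 0.0
    cc[:, zero] = 0.0
    np.fill_diagonal(cc, 1.0)
    cc = np.clip(cc, -1.0, 1.0)
    if residue_indices is None:
        residue_indices = np.arange(n_res)
    if topology is not None:
        labels = [f"{topology.residues[i].label}^"
                  f"{topology.residues[i].chain_id}" for i in residue_indices]
    else:
        labels = [f"res_{i}" for i in residue_indices]
    return CorrelationMatrix(cc, labels, np.asarray(residue_indices))


def block_correlation_density(cc_matrix: CorrelationMatrix,
                              component_map: ComponentMap) -> pd.DataFrame:
    """Component-pair correlation densities.

    density(A, B) = sum of CC_ij over i ∈ A, j ∈ B divided by n_A·n_B; the
    diagonal block A = A includes the matrix diagonal.  Returns a symmetric
    component × component DataFrame.  Residues not assigned by the map raise
    :class:`CorrelationError` listing them.
    """
    names = component_map.component_names
    idx_of = {int(r): k for k, r in enumerate(cc_matrix.residue_indices)}
    missing = [cc_matrix.residue_labels[idx_of[i]]
               for i in idx_of
               if component_map.component_of_residue(i) is None]
    if missing:
        raise CorrelationError(
            f"residues not assigned to any component: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    groups = {}
    for name in names:
        rows = [idx_of[int(i)] for i in component_map.residues_of(name)
                if int(i) in idx_of]
        groups[name] = np.array(rows, dtype=int)
    out = np.zeros((len(names), len(names)))
    for a, na in enumerate(names):
        ia = groups[na]
        for b, nb in enumerate(names):
            ib = groups[nb]
            if ia.size == 0 or ib.size == 0:
                raise CorrelationError(f"component {na if ia.size == 0 else nb} "
                                       "has no residues in the matrix")
            out[a, b] = cc_matrix.cc[np.ix_(ia, ib)].sum() / (ia.size * ib.size)
    return pd.DataFrame(out, index=names, columns=names)
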