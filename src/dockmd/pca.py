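"""Pocket-restricted principal component analysis of pooled replicates.

The binding pocket is frozen from a single reference conformation (the
docked pose): heavy atoms of every residue having any heavy atom within a
cutoff of the ligand's heavy atoms, plus the ligand heavy atoms themselves.
PCA is an unweighted covariance eigendecomposition of the mean-centered
pocket coordinates pooled over all replicates; projections of the pooled
frames onto the top two components feed the free-energy landscape stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import AtomSelection, Structure, Trajectory

__all__ = [
    "PCModel",
    "define_pocket",
    "fit_pca",
    "project",
    "porcupine_extremes",
]


@dataclass
class PCModel:
    """PCA of pocket coordinates.

    ``eigenvectors`` has shape (3k, n_components), columns orthonormal and
    ordered by descending eigenvalue (A^2 variance).  The sign convention
    makes each column's largest-magnitude entry positive, so maps are
    reproducible across runs and BLAS builds.
    """

    selection: AtomSelection
    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("negative eigenvalue in PCModel")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues not sorted descending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors not orthonormal")

    def to_json(self, path) -> None:
        doc = {
            "selection_indices": self.selection.indices.tolist(),
            "selection_expression": self.selection.expression,
            "mean_A": self.mean.tolist(),
            "eigenvalues_A2": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "PCModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            selection=AtomSelection(
                indices=np.asarray(doc["selection_indices"], dtype=int),
                expression=doc["selection_expression"],
            ),
            mean=np.asarray(doc["mean_A"], dtype=float),
            eigenvectors=np.asarray(doc["eigenvectors"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues_A2"], dtype=float),
        )


def define_pocket(
    reference: Structure, ligand: AtomSelection, cutoff: float = 4.5
) -> AtomSelection:
    """Heavy atoms of residues within ``cutoff`` A of the ligand, plus the
    ligand's heavy atoms, evaluated on the reference (docked) coordinates."""
    from scipy.spatial import cKDTree

    ligand.validate(reference)
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    heavy = ~reference.is_hydrogen()
    lig_heavy = np.intersect1d(ligand.indices, np.where(heavy)[0])
    if len(lig_heavy) == 0:
        raise ValueError("ligand selection has no heavy atoms")
    cand = np.where(heavy)[0]
    near = np.zeros(reference.n_atoms, dtype=bool)
    if cutoff > 0 and len(cand):
        tree = cKDTree(reference.coords[lig_heavy])
        d, _ = tree.query(reference.coords[cand], k=1)
        near[cand[d <= cutoff]] = True
    resindex = reference.residue_index()
    hit = np.unique(resindex[near])
    pocket_mask = np.isin(resindex, hit) & heavy
    pocket_mask[lig_heavy] = True
    return AtomSelection(
        indices=np.where(pocket_mask)[0],
        expression=f"pocket(within {cutoff} of ligand)",
    )


def _pocket_matrix(trajs: list[Trajectory], pocket: AtomSelection) -> np.ndarray:
    """Pooled (n_frames_total, 3k) displacement matrix over replicates."""
    blocks = []
    for t in trajs:
        pocket.validate(t.topology)
        blocks.append(t.coords[:, pocket.indices, :].reshape(t.n_frames, -1))
    return np.concatenate(blocks, axis=0)


def fit_pca(trajs: list[Trajectory], pocket: AtomSelection) -> PCModel:
    """Covariance eigendecomposition of pooled, mean-centered pocket
    coordinates (no mass weighting)."""
    x = _pocket_matrix(trajs, pocket)
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 pooled frames")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # sign convention: largest-magnitude component of each eigenvector positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    return PCModel(selection=pocket, mean=mean, eigenvectors=v, eigenvalues=w)


def project(trajs: list[Trajectory], model: PCModel, k: int = 2) -> pd.DataFrame:
    """Project frames onto the first ``k`` components.

    Returns a DataFrame with columns (replicate, frame, pc1..pck);  the
    frames used to fit the model project with zero column means.
    """
    if k < 1 or k > model.eigenvectors.shape[1]:
        raise ValueError(f"k={k} outside available components")
    rows = []
    for t in trajs:
        model.selection.validate(t.topology)
        x = t.coords[:, model.selection.indices, :].reshape(t.n_frames, -1)
        if x.shape[1] != model.mean.shape[0]:
            raise ValueError("trajectory does not match the model's pocket")
        proj = (x - model.mean) @ model.eigenvectors[:, :k]
        block = pd.DataFrame(proj, columns=[f"pc{i+1}" for i in range(k)])
        block.insert(0, "frame", np.arange(t.n_frames))
        block.insert(0, "replicate", t.replicate_id)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def porcupine_extremes(model: PCModel, component: int = 1, scale: float = 2.0):
    """Extreme conformations along one component for porcupine-style vector
    plots.

    Returns (minus, plus, arrows): the mean structure displaced by
    -/+ ``scale * sqrt(eigenvalue)`` along the component, reshaped to
    (n_atoms, 3), and the per-atom displacement vectors from minus to plus.
    """
    if component < 1 or component > model.eigenvectors.shape[1]:
        raise ValueError("component out of range")
    vec = model.eigenvectors[:, component - 1]
    amp = scale * np.sqrt(model.eigenvalues[component - 1])
    minus = (model.mean - amp * vec).reshape(-1, 3)
    plus = (model.mean + amp * vec).reshape(-1, 3)
    return minus, plus, (plus - minus)


def write_projection_tsv(proj: pd.DataFrame, path) -> None:
    proj.to_csv(path, sep="\t", index=False)


def write_porcupine_tsv(model: PCModel, component: int, scale: float, path) -> None:
    minus, plus, arrows = porcupine_extremes(model, component, scale)
    df = pd.DataFrame(
        np.column_stack([minus, arrows]),
        columns=["x_A", "y_A", "z_A", "dx_A", "dy_A", "dz_A"],
    )
    df.insert(0, "atom_index_in_pocket", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
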