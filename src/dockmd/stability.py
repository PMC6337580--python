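"""Rigid superposition and stability statistics (RMSD, per-residue RMSF).

Alignment uses the Kabsch solution to the orthogonal Procrustes problem via
``scipy.spatial.transform.Rotation.align_vectors`` on the fit selection; the
fitted rotation/translation is then applied to the whole frame.  No mass
weighting is applied anywhere: fluctuations are plain per-atom statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import AtomSelection, Structure, Trajectory

__all__ = [
    "kabsch_align",
    "rmsd_series",
    "rmsd_summary",
    "rmsf_per_atom",
    "rmsf_per_residue",
]


def _check_fit_selection(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit selection is collinear or degenerate")


def kabsch_align(
    traj: Trajectory,
    reference: Structure,
    fit_selection: AtomSelection,
) -> Trajectory:
    """Superpose every frame onto the reference over the fit selection.

    Each frame is rigidly rotated/translated so that the RMSD of the fit
    selection against the reference coordinates is minimal; the transform is
    applied to all atoms of the frame.
    """
    fit_selection.validate(traj.topology)
    idx = fit_selection.indices
    ref = reference.coords[idx]
    _check_fit_selection(ref)
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center

    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mob = traj.coords[f][idx]
        _check_fit_selection(mob)
        mob_center = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_center)
        out[f] = rot.apply(traj.coords[f] - mob_center) + ref_center
    return Trajectory(
        coords=out,
        topology=traj.topology.with_coords(out[0]),
        timestep=traj.timestep,
        replicate_id=traj.replicate_id,
        metadata=dict(traj.metadata),
    )


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: AtomSelection,
    align: bool = False,
    fit_selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) of the selection against the reference.

    With ``align=True`` frames are first superposed using ``fit_selection``
    (defaults to ``selection``); otherwise the trajectory is assumed to be
    pre-aligned.
    """
    selection.validate(traj.topology)
    if align:
        traj = kabsch_align(traj, reference, fit_selection or selection)
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection")
    diff = traj.coords[:, idx, :] - reference.coords[idx]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def rmsd_summary(series_by_replicate: dict[int, np.ndarray]) -> pd.DataFrame:
    """Mean +/- sd of RMSD per replicate plus the frame-weighted pooled row."""
    rows = []
    for rep, series in sorted(series_by_replicate.items()):
        rows.append(
            {"replicate": rep, "n_frames": len(series),
             "mean_A": float(np.mean(series)), "sd_A": float(np.std(series))}
        )
    pooled = np.concatenate([series_by_replicate[r] for r in sorted(series_by_replicate)])
    rows.append(
        {"replicate": "pooled", "n_frames": len(pooled),
         "mean_A": float(np.mean(pooled)), "sd_A": float(np.std(pooled))}
    )
    return pd.DataFrame(rows)


def rmsf_per_atom(traj: Trajectory, selection: AtomSelection) -> np.ndarray:
    """Per-atom RMSF (A): sqrt of the time-mean squared deviation from the
    time-mean position.  The trajectory must be pre-aligned."""
    selection.validate(traj.topology)
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    x = traj.coords[:, selection.indices, :]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))


def rmsf_per_residue(traj: Trajectory, selection: AtomSelection) -> pd.DataFrame:
    """Per-residue RMSF: the per-atom RMSF averaged over each residue's
    selected atoms, in topology residue order."""
    per_atom = rmsf_per_atom(traj, selection)
    s = traj.topology
    idx = selection.indices
    resindex = s.residue_index()[idx]
    rows = []
    for r in sorted(set(resindex.tolist())):
        mask = resindex == r
        first = idx[mask][0]
        rows.append(
            {
                "chain": str(s.chains[first]),
                "resid": int(s.resids[first]),
                "resname": str(s.resnames[first]),
                "rmsf_A": float(per_atom[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
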