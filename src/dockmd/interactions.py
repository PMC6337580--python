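"""Contact-residue and hydrogen-bond characterization of binding poses.

Contacts are purely geometric: a residue is in contact in a frame when any
of its heavy atoms lies within a cutoff (default 4.5 A) of any ligand heavy
atom.  Hydrogen bonds use the common geometric convention — donor-acceptor
heavy-atom distance <= 3.5 A and D-H...A angle >= 135 degrees — since
different tools draw these thresholds differently; both are parameters.
Structures without hydrogens fall back to a distance-only criterion with a
logged caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import AtomSelection, Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "HBondRecord",
    "contact_residues",
    "hydrogen_bonds",
    "contacts_to_tsv",
    "hbonds_to_tsv",
]

#: elements that can donate/accept hydrogen bonds
_POLAR = {"N", "O", "F", "S"}


@dataclass
class ContactRecord:
    chain: str
    resid: int
    resname: str
    min_distance_A: float  # smallest heavy-atom distance seen in any frame
    occupancy: float       # fraction of frames in contact

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy outside [0, 1]")
        if self.min_distance_A <= 0:
            raise ValueError("distance must be positive")


@dataclass
class HBondRecord:
    donor: str     # "chain:resname resid:atom"
    hydrogen: str | None
    acceptor: str
    mean_distance_A: float
    mean_angle_deg: float | None
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy outside [0, 1]")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor are the same atom")


def _as_traj(traj_or_frame) -> Trajectory:
    if isinstance(traj_or_frame, Trajectory):
        return traj_or_frame
    if isinstance(traj_or_frame, Structure):
        return Trajectory(
            coords=traj_or_frame.coords[None], topology=traj_or_frame
        )
    raise TypeError("expected Trajectory or Structure")


def contact_residues(
    traj_or_frame,
    ligand: AtomSelection,
    cutoff: float = 4.5,
) -> list[ContactRecord]:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy
    atom, with per-residue occupancy over frames and the minimum distance
    observed.  The ligand's own residues are excluded from the list."""
    traj = _as_traj(traj_or_frame)
    s = traj.topology
    ligand.validate(s)
    heavy = ~s.is_hydrogen()
    lig_mask = np.zeros(s.n_atoms, dtype=bool)
    lig_mask[ligand.indices] = True
    lig_idx = np.where(lig_mask & heavy)[0]
    other_idx = np.where(~lig_mask & heavy)[0]
    if len(lig_idx) == 0:
        raise ValueError("ligand selection has no heavy atoms")
    if len(other_idx) == 0:
        return []

    resindex = s.residue_index()
    other_res = resindex[other_idx]
    res_ids = sorted(set(other_res.tolist()))
    min_d = {r: np.inf for r in res_ids}
    hits = {r: 0 for r in res_ids}
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        d = np.linalg.norm(
            xyz[other_idx][:, None, :] - xyz[lig_idx][None, :, :], axis=2
        ).min(axis=1)
        for r in res_ids:
            dr = d[other_res == r].min()
            if dr < min_d[r]:
                min_d[r] = dr
            if dr <= cutoff:
                hits[r] += 1
    out = []
    for r in res_ids:
        if hits[r] == 0:
            continue
        first = np.where(resindex == r)[0][0]
        out.append(
            ContactRecord(
                chain=str(s.chains[first]),
                resid=int(s.resids[first]),
                resname=str(s.resnames[first]),
                min_distance_A=float(min_d[r]),
                occupancy=hits[r] / traj.n_frames,
            )
        )
    return out


def _atom_label(s: Structure, i: int) -> str:
    return f"{s.chains[i]}:{s.resnames[i]} {s.resids[i]}:{s.names[i]}"


def _donors_acceptors(s: Structure):
    """Donor (heavy, [hydrogens]) pairs and acceptor heavy atoms.

    Donors are polar heavy atoms with at least one bonded hydrogen;
    acceptors are all polar heavy atoms.
    """
    elements = [str(e).upper() for e in s.elements]
    is_h = s.is_hydrogen()
    bonded_h: dict[int, list[int]] = {}
    for i, j in s.bonds:
        if is_h[j] and elements[i] in _POLAR:
            bonded_h.setdefault(i, []).append(j)
        if is_h[i] and elements[j] in _POLAR:
            bonded_h.setdefault(j, []).append(i)
    acceptors = [i for i in range(s.n_atoms) if elements[i] in _POLAR and not is_h[i]]
    donors = [(i, hs) for i, hs in sorted(bonded_h.items())]
    return donors, acceptors


def hydrogen_bonds(
    traj_or_frame,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 135.0,
) -> list[HBondRecord]:
    """Geometric hydrogen bonds aggregated over frames.

    A bond is counted in a frame when the donor-acceptor heavy-atom distance
    is <= ``dist_cutoff`` and some donor hydrogen makes a D-H...A angle >=
    ``angle_cutoff``.  Without hydrogens in the topology, a distance-only
    fallback is used (angle reported as None) with a logged caveat.
    Covalently bonded donor-acceptor pairs are skipped.
    """
    traj = _as_traj(traj_or_frame)
    s = traj.topology
    donors, acceptors = _donors_acceptors(s)
    has_h = bool(np.any(s.is_hydrogen()))
    if not has_h:
        elements = [str(e).upper() for e in s.elements]
        donors = [
            (i, []) for i in range(s.n_atoms) if elements[i] in _POLAR
        ]
        logger.warning(
            "no hydrogens in topology: using distance-only hydrogen-bond criterion"
        )
    if not donors or not acceptors:
        raise ValueError("no hydrogen-bond donors or acceptors identifiable")

    bonded = {tuple(sorted(b)) for b in s.bonds}
    stats: dict[tuple, dict] = {}
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for d_heavy, hs in donors:
            for a in acceptors:
                if a == d_heavy or tuple(sorted((d_heavy, a))) in bonded:
                    continue
                r_da = float(np.linalg.norm(xyz[d_heavy] - xyz[a]))
                if r_da > dist_cutoff:
                    continue
                best_angle = None
                best_h = None
                for h in hs:
                    v1 = xyz[d_heavy] - xyz[h]
                    v2 = xyz[a] - xyz[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    if best_angle is None or ang > best_angle:
                        best_angle, best_h = ang, h
                if has_h and (best_angle is None or best_angle < angle_cutoff):
                    continue
                key = (d_heavy, best_h, a)
                rec = stats.setdefault(
                    key, {"n": 0, "dist": 0.0, "ang": 0.0}
                )
                rec["n"] += 1
                rec["dist"] += r_da
                if best_angle is not None:
                    rec["ang"] += best_angle
    out = []
    for (d_heavy, h, a), rec in sorted(stats.items()):
        out.append(
            HBondRecord(
                donor=_atom_label(s, d_heavy),
                hydrogen=_atom_label(s, h) if h is not None else None,
                acceptor=_atom_label(s, a),
                mean_distance_A=rec["dist"] / rec["n"],
                mean_angle_deg=(rec["ang"] / rec["n"]) if h is not None else None,
                occupancy=rec["n"] / traj.n_frames,
            )
        )
    return out


def contacts_to_tsv(records: list[ContactRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def hbonds_to_tsv(records: list[HBondRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)
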