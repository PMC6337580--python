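"""Structure/trajectory I/O: PDB (single and multi-model), XYZ and DCD.

Readers and writers are thin adapters over MDAnalysis; the package-level
containers (:class:`~dockmd.structure.Structure`,
:class:`~dockmd.structure.Trajectory`) stay the working representation.
Multi-model PDB and XYZ are the portable text formats; DCD is available
behind :data:`HAS_DCD` for binary interchange.

A topology "sidecar" (JSON) carries the per-atom force-field parameters the
energetics stage needs — charges, Lennard-Jones, generalized-Born radii and
screening factors, LCPO coefficients, bonds and species masks — which no
coordinate format stores.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .structure import Structure, Trajectory, infer_element

logger = logging.getLogger(__name__)

HAS_DCD = True  # MDAnalysis ships the DCD reader/writer

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_topology_json",
    "write_topology_json",
    "HAS_DCD",
]


def _prevalidate_pdb(path: Path) -> None:
    """Cheap line-level scan so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(
                        f"{path}: malformed ATOM record at line {lineno} (too short)"
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable coordinates at line {lineno}"
                    ) from None


def _universe_from_structure(structure: Structure):
    import MDAnalysis as mda

    s = structure
    resindex = s.residue_index()
    n_res = int(resindex.max()) + 1 if s.n_atoms else 0
    first_atom = [int(np.argmax(resindex == r)) for r in range(n_res)]
    chains_per_res = [str(s.chains[i]) for i in first_atom]
    seg_names = list(dict.fromkeys(chains_per_res))
    seg_of = {c: k for k, c in enumerate(seg_names)}
    res_segindex = np.array([seg_of[c] for c in chains_per_res], dtype=int)

    u = mda.Universe.empty(
        s.n_atoms,
        n_residues=max(n_res, 1),
        n_segments=max(len(seg_names), 1),
        atom_resindex=resindex,
        residue_segindex=res_segindex if n_res else None,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in s.names])
    u.add_TopologyAttr("elements", [str(x) for x in s.elements])
    u.add_TopologyAttr("resnames", [str(s.resnames[i]) for i in first_atom] or ["UNK"])
    u.add_TopologyAttr("resids", [int(s.resids[i]) for i in first_atom] or [1])
    u.add_TopologyAttr("chainIDs", [str(c) for c in s.chains])
    u.add_TopologyAttr("segids", seg_names or ["A"])
    u.add_TopologyAttr("occupancies", np.ones(s.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(s.n_atoms))
    u.atoms.positions = s.coords.astype(np.float32)
    return u


def _structure_from_universe(u, ligand_resnames=frozenset({"LIG"})) -> Structure:
    atoms = u.atoms
    names = [a.name for a in atoms]
    resnames = [a.resname for a in atoms]
    try:
        elements = [a.element if a.element.strip() else "" for a in atoms]
    except Exception:
        elements = [""] * len(names)
    fixed = []
    inferred = False
    for nm, rn, el in zip(names, resnames, elements):
        if el:
            fixed.append(el.capitalize())
        else:
            fixed.append(infer_element(nm, rn))
            inferred = True
    if inferred:
        logger.warning("element column missing; elements inferred from atom names")
    try:
        chains = [a.chainID for a in atoms]
    except Exception:
        chains = [a.segid if a.segid else "A" for a in atoms]
    return Structure(
        names=names,
        elements=fixed,
        resnames=resnames,
        resids=[a.resid for a in atoms],
        chains=chains,
        coords=atoms.positions.astype(float),
        ligand_resnames=ligand_resnames,
    )


def read_structure(path, fmt: str = "pdb", ligand_resnames=frozenset({"LIG"})) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt.lower() != "pdb":
        raise ValueError(f"unsupported structure format {fmt!r}")
    _prevalidate_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _structure_from_universe(u, ligand_resnames)


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    import MDAnalysis as mda

    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(
    path,
    fmt: str | None = None,
    topology: Structure | None = None,
    timestep: float = 10.0,
    replicate_id: int = 0,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, XYZ or DCD).

    PDB files are self-describing; XYZ and DCD require a ``topology``
    Structure whose atom count must match the frames.  Frames containing
    non-finite coordinates are rejected.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dcd" and not HAS_DCD:
        raise RuntimeError("DCD support is not available")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            _prevalidate_pdb(path)
            u = mda.Universe(str(path))
            if topology is None:
                topology = _structure_from_universe(u)
        elif fmt == "xyz":
            if topology is None:
                raise ValueError("xyz trajectories require a topology Structure")
            u = mda.Universe(str(path))
        elif fmt == "dcd":
            if topology is None:
                raise ValueError("dcd trajectories require a topology Structure")
            u = mda.Universe(_universe_from_structure(topology)._topology, str(path))
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
        n_atoms = len(u.atoms)
        if n_atoms != topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: file has {n_atoms}, topology has "
                f"{topology.n_atoms}"
            )
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if not np.all(np.isfinite(frames)):
        bad = np.where(~np.isfinite(frames).all(axis=(1, 2)))[0]
        raise ValueError(f"non-finite coordinates in frames {bad.tolist()}")
    return Trajectory(
        coords=frames,
        topology=topology.with_coords(frames[0]) if len(frames) else topology,
        timestep=timestep,
        replicate_id=replicate_id,
    )


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-model PDB, XYZ or DCD."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dcd" and not HAS_DCD:
        raise RuntimeError("DCD support is not available")
    if fmt not in ("pdb", "xyz", "dcd"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    u = _universe_from_structure(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
            for frame in traj.coords:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# topology sidecar (JSON)
# ---------------------------------------------------------------------------

_SIDECAR_DOC = """Schema (all arrays indexed by atom):
{
  "atoms": [{"name", "element", "resname", "resid", "chain"}, ...],
  "charges": [e, ...],
  "lj": [[sigma_A, epsilon_kcal], ...],
  "gb": [[intrinsic_radius_A, screening_factor], ...],
  "lcpo": [[P1, P2, P3, P4, radius_A], ...],
  "bonds": [[i, j], ...],
  "masks": {"receptor": [...], "ligand": [...]},
  "ligand_resnames": [...],
  "provenance": {...}          # free-form (e.g. docking grid settings)
}"""


def write_topology_json(structure: Structure, path, masks: dict | None = None,
                        provenance: dict | None = None) -> None:
    """Write the force-field sidecar for a parameterized Structure."""
    s = structure
    doc = {
        "atoms": [
            {
                "name": str(s.names[i]),
                "element": str(s.elements[i]),
                "resname": str(s.resnames[i]),
                "resid": int(s.resids[i]),
                "chain": str(s.chains[i]),
            }
            for i in range(s.n_atoms)
        ],
        "bonds": [[int(i), int(j)] for i, j in s.bonds],
        "ligand_resnames": sorted(s.ligand_resnames),
    }
    if s.charges is not None:
        doc["charges"] = np.asarray(s.charges, dtype=float).tolist()
    if s.lj_sigma is not None and s.lj_epsilon is not None:
        doc["lj"] = np.column_stack([s.lj_sigma, s.lj_epsilon]).tolist()
    if s.gb_radius is not None and s.gb_screen is not None:
        doc["gb"] = np.column_stack([s.gb_radius, s.gb_screen]).tolist()
    if s.lcpo is not None:
        doc["lcpo"] = np.asarray(s.lcpo, dtype=float).tolist()
    if masks:
        doc["masks"] = {k: list(map(int, v)) for k, v in masks.items()}
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_topology_json(path, coords: np.ndarray | None = None):
    """Read a sidecar; returns (Structure, masks dict, provenance dict).

    ``coords`` supplies coordinates when the sidecar travels without a
    coordinate file (zeros otherwise).
    """
    with open(path) as fh:
        doc = json.load(fh)
    atoms = doc["atoms"]
    n = len(atoms)
    lj = np.asarray(doc["lj"], dtype=float) if "lj" in doc else None
    gb = np.asarray(doc["gb"], dtype=float) if "gb" in doc else None
    s = Structure(
        names=[a["name"] for a in atoms],
        elements=[a["element"] for a in atoms],
        resnames=[a["resname"] for a in atoms],
        resids=[a["resid"] for a in atoms],
        chains=[a["chain"] for a in atoms],
        coords=coords if coords is not None else np.zeros((n, 3)),
        charges=np.asarray(doc["charges"], dtype=float) if "charges" in doc else None,
        lj_sigma=lj[:, 0] if lj is not None else None,
        lj_epsilon=lj[:, 1] if lj is not None else None,
        gb_radius=gb[:, 0] if gb is not None else None,
        gb_screen=gb[:, 1] if gb is not None else None,
        lcpo=np.asarray(doc["lcpo"], dtype=float) if "lcpo" in doc else None,
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        ligand_resnames=frozenset(doc.get("ligand_resnames", ["LIG"])),
    )
    return s, doc.get("masks", {}), doc.get("provenance", {})
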