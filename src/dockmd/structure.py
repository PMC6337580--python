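"""Core data model: structures, trajectories and the atom-selection grammar.

Coordinates are in Angstroms throughout, frames are 0-indexed and times are
``frame_index * timestep`` (timestep in ps).  A :class:`Structure` carries the
atom metadata needed by every downstream stage plus the optional per-atom
force-field parameters (charges, Lennard-Jones, generalized-Born, LCPO)
consumed by the energetics stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "SelectionError",
    "select",
]

#: elements treated as hydrogen by the "heavy" keyword
_HYDROGEN = {"H", "D"}

# two-letter element symbols that occur in biomolecular PDB files; used when
# inferring elements from atom names
_TWO_LETTER = {
    "CL", "BR", "NA", "MG", "FE", "ZN", "CA", "MN", "CU", "SE", "NI", "CO", "CD", "HG",
}


def infer_element(name: str, resname: str = "") -> str:
    """Infer an element symbol from a PDB atom name (v3.3 conventions).

    The name is stripped of digits and primes; a leading two-character symbol
    is used only when the full stripped name matches a known two-letter
    element (``CL``, ``BR``, metal ions, ...) so that e.g. ``CA`` inside an
    amino-acid residue stays carbon.
    """
    stripped = re.sub(r"[0-9'\"]", "", name).strip().upper()
    if not stripped:
        return "X"
    res = resname.strip().upper()
    if stripped in _TWO_LETTER:
        # names like CA/CD collide with amino-acid carbons: only treat them as
        # the two-letter element when the residue itself is that species
        ambiguous = {"CA", "CD", "CO", "NA", "NI", "HG", "CU"}
        if stripped not in ambiguous or res == stripped:
            return stripped.capitalize()
    return stripped[0]


@dataclass
class Structure:
    """Atoms, coordinates and optional per-atom force-field parameters.

    Parameters
    ----------
    names, elements, resnames, chains : arrays of str, one entry per atom
    resids : int array, residue index per atom (non-decreasing within a chain)
    coords : (n_atoms, 3) float array, Angstroms
    charges : elementary charges (optional)
    lj_sigma, lj_epsilon : Lennard-Jones sigma (A) and epsilon (kcal/mol)
    gb_radius, gb_screen : intrinsic Born radius (A) and HCT screening factor
    lcpo : (n_atoms, 5) array of (P1, P2, P3, P4, radius_A)
    bonds : list of (i, j) covalent bonds (0-indexed)
    ligand_resnames : residue names treated as the ligand by selections
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None
    gb_radius: np.ndarray | None = None
    gb_screen: np.ndarray | None = None
    lcpo: np.ndarray | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    ligand_resnames: frozenset = frozenset({"LIG"})

    def __post_init__(self) -> None:
        for attr in ("names", "elements", "resnames", "chains"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        for chain in np.unique(self.chains):
            r = self.resids[self.chains == chain]
            if np.any(np.diff(r) < 0):
                raise ValueError(f"residue indices decrease within chain {chain!r}")
        self.ligand_resnames = frozenset(self.ligand_resnames)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        """Per-atom (chain, resid) keys identifying each atom's residue."""
        return list(zip(self.chains.tolist(), self.resids.tolist()))

    def residue_index(self) -> np.ndarray:
        """0-based residue index per atom, in order of first appearance."""
        keys = self.residue_keys
        seen: dict[tuple[str, int], int] = {}
        out = np.empty(self.n_atoms, dtype=int)
        for i, k in enumerate(keys):
            if k not in seen:
                seen[k] = len(seen)
            out[i] = seen[k]
        return out

    def is_hydrogen(self) -> np.ndarray:
        return np.array([str(e).upper() in _HYDROGEN for e in self.elements])

    def is_ligand(self) -> np.ndarray:
        return np.array([str(r) in self.ligand_resnames for r in self.resnames])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "Structure":
        """Extract an atom subset; bonds are remapped, dangling bonds dropped."""
        idx = np.asarray(indices, dtype=int)
        remap = {int(old): new for new, old in enumerate(idx)}
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]

        def take(a):
            return None if a is None else np.asarray(a)[idx]

        return Structure(
            names=self.names[idx],
            elements=self.elements[idx],
            resnames=self.resnames[idx],
            resids=self.resids[idx],
            chains=self.chains[idx],
            coords=self.coords[idx],
            charges=take(self.charges),
            lj_sigma=take(self.lj_sigma),
            lj_epsilon=take(self.lj_epsilon),
            gb_radius=take(self.gb_radius),
            gb_screen=take(self.gb_screen),
            lcpo=take(self.lcpo),
            bonds=bonds,
            ligand_resnames=self.ligand_resnames,
        )


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstroms.  ``metadata``
    may carry generator ground truth (e.g. per-frame state labels); analysis
    stages never read it.
    """

    coords: np.ndarray
    topology: Structure
    timestep: float = 10.0  # ps between stored frames
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


@dataclass(frozen=True)
class AtomSelection:
    """Sorted unique atom indices plus the expression that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, structure: Structure) -> None:
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= structure.n_atoms
        ):
            raise ValueError("selection indices out of topology bounds")


# ---------------------------------------------------------------------------
# selection grammar
#
#   expr    := or_expr
#   or_expr := and_expr ('or' and_expr)*
#   and_expr:= unary ('and' unary)*
#   unary   := 'not' unary | primary
#   primary := 'backbone' | 'calpha' | 'heavy' | 'ligand' | 'protein' | 'all'
#            | 'resid' range+            (range := N | N:M | N-M)
#            | 'within' FLOAT 'of' unary
#            | '(' expr ')'
#
# "within r of X" selects whole residues having any heavy atom within r A of
# any heavy atom of X (distances measured in the structure's reference
# coordinates); X's own residues are trivially included (distance 0).
# ---------------------------------------------------------------------------

BACKBONE_NAMES = {"CA", "N", "C", "O"}


class SelectionError(ValueError):
    """Raised when a selection expression fails to parse."""


_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, structure: Structure, expr: str):
        self.s = structure
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        if self.i >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection expression {self.expr!r}"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, tok, pos, why="unknown token"):
        raise SelectionError(
            f"{why} {tok!r} at position {pos} in {self.expr!r}"
        )

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.i < len(self.tokens):
            tok, pos = self.tokens[self.i]
            self.fail(tok, pos, "trailing token")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.next()
            return ~self.unary()
        return self.primary()

    def primary(self) -> np.ndarray:
        tok, pos = self.next()
        s = self.s
        if tok == "(":
            mask = self.or_expr()
            closing, cpos = self.next()
            if closing != ")":
                self.fail(closing, cpos, "expected ')' but found")
            return mask
        if tok == "all":
            return np.ones(s.n_atoms, dtype=bool)
        if tok == "backbone":
            names = np.array([str(n).strip().upper() for n in s.names])
            return np.isin(names, sorted(BACKBONE_NAMES)) & ~s.is_ligand()
        if tok == "calpha":
            names = np.array([str(n).strip().upper() for n in s.names])
            return (names == "CA") & ~s.is_ligand()
        if tok == "heavy":
            return ~s.is_hydrogen()
        if tok == "ligand":
            return s.is_ligand()
        if tok == "protein":
            return ~s.is_ligand()
        if tok == "resid":
            return self._resid()
        if tok == "within":
            return self._within()
        self.fail(tok, pos)

    def _resid(self) -> np.ndarray:
        s = self.s
        mask = np.zeros(s.n_atoms, dtype=bool)
        found = False
        range_re = re.compile(r"^(-?\d+)(?:[:\-](-?\d+))?$")
        while self.peek() is not None:
            m = range_re.match(self.peek())
            if m is None:
                break
            self.next()
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            mask |= (s.resids >= lo) & (s.resids <= hi)
            found = True
        if not found:
            tok, pos = self.tokens[self.i] if self.i < len(self.tokens) else ("<end>", len(self.expr))
            self.fail(tok, pos, "expected residue range after 'resid', found")
        return mask

    def _within(self) -> np.ndarray:
        tok, pos = self.next()
        try:
            cutoff = float(tok)
        except ValueError:
            self.fail(tok, pos, "expected distance after 'within', found")
        of, opos = self.next()
        if of != "of":
            self.fail(of, opos, "expected 'of', found")
        inner = self.unary()
        return _within_mask(self.s, inner, cutoff)


def _within_mask(s: Structure, inner: np.ndarray, cutoff: float) -> np.ndarray:
    """Whole residues with any heavy atom within ``cutoff`` of inner's heavy atoms."""
    from scipy.spatial import cKDTree

    heavy = ~s.is_hydrogen()
    ref_idx = np.where(inner & heavy)[0]
    if len(ref_idx) == 0:
        ref_idx = np.where(inner)[0]  # inner selection has no heavy atoms
    if len(ref_idx) == 0:
        return np.zeros(s.n_atoms, dtype=bool)
    cand_idx = np.where(heavy)[0]
    near = np.zeros(s.n_atoms, dtype=bool)
    if len(cand_idx) and cutoff >= 0:
        tree = cKDTree(s.coords[ref_idx])
        d, _ = tree.query(s.coords[cand_idx], k=1)
        near[cand_idx[d <= cutoff]] = True
    near[ref_idx] = True  # the reference atoms are within 0 of themselves
    # expand to whole residues
    resindex = s.residue_index()
    hit_residues = np.unique(resindex[near])
    return np.isin(resindex, hit_residues)


def select(structure: Structure, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a structure.

    Raises :class:`SelectionError` with the offending token and its position
    when the expression does not parse.
    """
    mask = _Parser(structure, expression).parse()
    return AtomSelection(indices=np.where(mask)[0], expression=expression)
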