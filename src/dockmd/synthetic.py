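"""Synthetic fixtures with known ground truth.

Three families of generators make every downstream stage testable without
external downloads:

* score tables with category structure, threshold-straddling values and the
  exact survivor sets of each triage stage;
* toy host-guest complexes with fully specified per-atom parameters, giving
  closed-form Coulomb/Born/SASA reference values;
* trajectories with known statistical structure — two-state (Bernoulli
  mixture of two reference conformations plus isotropic Gaussian noise) for
  free-energy-landscape recovery, and harmonic (pure Gaussian fluctuation
  about a reference) for RMSF recovery, where the per-atom fluctuation has
  the closed form RMSF = sigma * sqrt(3).

All generators are bit-reproducible for a fixed seed.  Ground-truth state
labels ride in trajectory ``metadata`` and are read only by tests, never by
analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import triage
from .structure import Structure, Trajectory

DEFAULT_TEMPERATURE_K = 300.0  # ensemble temperature recorded in metadata

__all__ = [
    "ToyComplexSpec",
    "TwoStateSpec",
    "ScoreTableFixture",
    "gen_score_table",
    "gen_toy_complex",
    "gen_two_state_trajectory",
    "gen_harmonic_trajectory",
]


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


@dataclass
class ScoreTableFixture:
    """A generated score table plus the ground-truth survivor sets
    (as (ligand_id, target_id) tuples) of each triage stage."""

    table: pd.DataFrame
    expected_screened: set
    expected_refined: set
    expected_validated: set


def gen_score_table(
    categories: list[str],
    n_per_category: int,
    score_range: tuple[float, float] = (-12.0, -5.0),
    seed: int = 0,
    ligand_id: str = "LIG1",
    forced: list[dict] | None = None,
) -> ScoreTableFixture:
    """Random docking-score table with known triage ground truth.

    Scores are uniform over ``score_range`` rounded to one decimal (the
    precision docking engines print), straddling the -8/-9/-10 kcal/mol
    thresholds for typical ranges.  ``forced`` rows (dicts with at least
    ``score_kcal_mol`` and ``cocrystal_score_kcal_mol``) are appended to pin
    specific worked examples.
    """
    if n_per_category < 0:
        raise ValueError("n_per_category must be >= 0")
    lo, hi = score_range
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("score_range must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for cat in categories:
        for k in range(n_per_category):
            score = round(float(rng.uniform(lo, hi)), 1)
            cc = round(float(rng.uniform(lo, hi)), 1)
            code = "".join(rng.choice(list("0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"), 4))
            rows.append(
                {
                    "ligand_id": ligand_id,
                    "target_id": f"{cat}_T{k:03d}",
                    "category": cat,
                    "structure_id": code,
                    "score_kcal_mol": score,
                    "cocrystal_score_kcal_mol": cc,
                }
            )
    for extra in forced or []:
        row = {
            "ligand_id": ligand_id,
            "target_id": f"FORCED_{len(rows):03d}",
            "category": categories[0] if categories else "forced",
            "structure_id": "XXXX",
        }
        row.update(extra)
        rows.append(row)
    table = triage.new_table(rows)

    def key(r):
        return (r["ligand_id"], r["target_id"])

    screened = {key(r) for _, r in table.iterrows()
                if r["score_kcal_mol"] <= triage.SCREEN_THRESHOLD}
    refined = {key(r) for _, r in table.iterrows()
               if key(r) in screened and r["score_kcal_mol"] <= triage.REFINE_THRESHOLD}
    validated = {key(r) for _, r in table.iterrows()
                 if key(r) in refined
                 and r["score_kcal_mol"] < r["cocrystal_score_kcal_mol"]}
    return ScoreTableFixture(
        table=table,
        expected_screened=screened,
        expected_refined=refined,
        expected_validated=validated,
    )


# ---------------------------------------------------------------------------
# toy host-guest complexes
# ---------------------------------------------------------------------------


@dataclass
class ToyComplexSpec:
    """A host ring of atoms plus a small ligand stack above its center.

    Per-atom parameter arrays cover host atoms first, then ligand atoms;
    scalar values broadcast.  ``separation`` is the gap (A) between the host
    plane and the first ligand atom; ``ring_radius`` may force a host ring
    radius (an error is raised if the requested atom count cannot keep the
    required spacing on that ring).
    """

    host_atom_count: int
    ligand_atom_count: int
    charges: np.ndarray | float = 0.0
    lj_sigma: np.ndarray | float = 1.5  # coarse beads: 3 A separation is sterically valid
    lj_epsilon: np.ndarray | float = 0.1
    gb_radii: np.ndarray | float = 1.7
    gb_screen: np.ndarray | float = 0.72
    lcpo_params: np.ndarray | None = None  # (n, 5): P1..P4, radius; default below
    separation: float = 3.0
    ring_radius: float | None = None
    jitter: float = 0.0
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if self.host_atom_count < 1:
            raise ValueError("host_atom_count must be >= 1")
        if self.ligand_atom_count < 0:
            raise ValueError("ligand_atom_count must be >= 0")
        n = self.n_atoms
        for name in ("charges", "lj_sigma", "lj_epsilon", "gb_radii", "gb_screen"):
            v = getattr(self, name)
            arr = np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must broadcast to {n} atoms")
            setattr(self, name, arr)
        if np.any(self.gb_radii <= 0):
            raise ValueError("all Born radii must be positive")
        if self.lcpo_params is None:
            # pairwise-exact LCPO set for sparse toy geometry; radius = LJ sigma/2
            self.lcpo_params = np.column_stack(
                [
                    np.ones(n),
                    -np.ones(n),
                    np.zeros(n),
                    np.zeros(n),
                    self.lj_sigma / 2.0,
                ]
            )
        else:
            self.lcpo_params = np.asarray(self.lcpo_params, dtype=float)
            if self.lcpo_params.shape != (n, 5):
                raise ValueError("lcpo_params must have shape (n_atoms, 5)")
        if np.any(self.lcpo_params[:, 4] <= 0):
            raise ValueError("all LCPO radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.host_atom_count + self.ligand_atom_count


def gen_toy_complex(spec: ToyComplexSpec) -> Structure:
    """Build the toy complex; guarantees no pair closer than 0.8 x the sum
    of LJ sigmas (raises on impossible geometry)."""
    nh, nl = spec.host_atom_count, spec.ligand_atom_count
    sig = spec.lj_sigma
    rng = np.random.default_rng(spec.geometry_seed)

    coords = np.zeros((spec.n_atoms, 3))
    if nh == 1:
        pass  # single host atom at the origin
    else:
        # ring spacing: adjacent atoms at >= 0.8 * (sigma_i + sigma_j)
        pad = 6.0 * spec.jitter  # spacing allowance so jitter keeps the guarantee
        need = max(
            0.8 * (sig[i] + sig[(i + 1) % nh]) for i in range(nh)
        ) + pad
        min_radius = need / (2.0 * np.sin(np.pi / nh)) * 1.001  # slack off the limit
        radius = spec.ring_radius if spec.ring_radius is not None else min_radius
        if radius < min_radius - 1e-12:
            raise ValueError(
                f"impossible geometry: {nh} host atoms need ring radius >= "
                f"{min_radius:.2f} A, got {radius:.2f} A"
            )
        ang = 2.0 * np.pi * np.arange(nh) / nh
        coords[:nh, 0] = radius * np.cos(ang)
        coords[:nh, 1] = radius * np.sin(ang)

    if nl:
        # ligand atoms stacked on the ring axis, starting `separation` above
        z0 = spec.separation
        step = (
            max(0.84 * (sig[nh:].max() * 2.0) + 6.0 * spec.jitter, 1.0)
            if nl > 1
            else 0.0
        )
        for k in range(nl):
            coords[nh + k] = (0.0, 0.0, z0 + k * step)

    def overlaps(xyz: np.ndarray) -> bool:
        if spec.n_atoms < 2:
            return False
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
        lim = 0.8 * (sig[:, None] + sig[None, :])
        np.fill_diagonal(d, np.inf)
        return bool(np.any(d < lim - 1e-9))

    if overlaps(coords):
        raise ValueError("impossible geometry: steric overlap in toy complex")
    if spec.jitter > 0:
        # rejection-sample the jitter so the steric guarantee survives it;
        # deterministic for a fixed geometry_seed
        for _ in range(200):
            trial = coords + rng.normal(scale=spec.jitter, size=coords.shape)
            if not overlaps(trial):
                coords = trial
                break
        else:
            raise ValueError(
                "impossible geometry: jitter cannot preserve steric spacing"
            )

    names = [f"H{i+1}" for i in range(nh)] + [f"L{k+1}" for k in range(nl)]
    return Structure(
        names=names,
        elements=["C"] * spec.n_atoms,
        resnames=["HST"] * nh + ["LIG"] * nl,
        resids=[1] * nh + [2] * nl,
        chains=["A"] * spec.n_atoms,
        coords=coords,
        charges=spec.charges,
        lj_sigma=spec.lj_sigma,
        lj_epsilon=spec.lj_epsilon,
        gb_radius=spec.gb_radii,
        gb_screen=spec.gb_screen,
        lcpo=spec.lcpo_params,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class TwoStateSpec:
    """Bernoulli mixture of two reference conformations plus isotropic
    Gaussian noise; per-frame ground-truth labels go into metadata."""

    population_a: float
    state_a_coords: np.ndarray
    state_b_coords: np.ndarray
    noise_sigma: float = 0.1
    n_frames: int = 1000
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_a <= 1.0:
            raise ValueError("population_a must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.state_a_coords = np.asarray(self.state_a_coords, dtype=float)
        self.state_b_coords = np.asarray(self.state_b_coords, dtype=float)
        if self.state_a_coords.shape != self.state_b_coords.shape:
            raise ValueError("state coordinate shapes differ")

    @property
    def population_b(self) -> float:
        return 1.0 - self.population_a


def _generic_topology(n_atoms: int, coords: np.ndarray) -> Structure:
    """One carbon per residue — a minimal topology for statistical fixtures."""
    return Structure(
        names=[f"C{i+1}" for i in range(n_atoms)],
        elements=["C"] * n_atoms,
        resnames=["MOL"] * n_atoms,
        resids=list(range(1, n_atoms + 1)),
        chains=["A"] * n_atoms,
        coords=coords,
    )


def gen_two_state_trajectory(spec: TwoStateSpec) -> list[Trajectory]:
    """One Trajectory per replicate; frames are state A or B (iid Bernoulli
    with probability ``population_a``) plus isotropic Gaussian noise."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out = []
    n_atoms = spec.state_a_coords.shape[0]
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        labels = rng.random(spec.n_frames) < spec.population_a
        frames = np.where(
            labels[:, None, None], spec.state_a_coords, spec.state_b_coords
        ).astype(float)
        if spec.noise_sigma > 0:
            frames = frames + rng.normal(
                scale=spec.noise_sigma, size=frames.shape
            )
        out.append(
            Trajectory(
                coords=frames,
                topology=_generic_topology(n_atoms, frames[0]),
                replicate_id=rep,
                metadata={
                    "true_state_a": labels,
                    "population_a": spec.population_a,
                    "temperature_K": DEFAULT_TEMPERATURE_K,
                },
            )
        )
    return out


def gen_harmonic_trajectory(
    reference: np.ndarray,
    sigma_per_atom: np.ndarray | float,
    n_frames: int,
    seed: int = 0,
    replicate_id: int = 0,
) -> Trajectory:
    """Frames are the reference plus iid isotropic Gaussian displacements of
    per-atom scale sigma; the expected per-atom RMSF is sigma * sqrt(3)."""
    reference = np.asarray(reference, dtype=float)
    n_atoms = reference.shape[0]
    sigma = (
        np.full(n_atoms, float(sigma_per_atom))
        if np.isscalar(sigma_per_atom)
        else np.asarray(sigma_per_atom, dtype=float)
    )
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0 per atom")
    if sigma.shape != (n_atoms,):
        raise ValueError("sigma_per_atom shape mismatch")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n_frames, n_atoms, 3)) * sigma[None, :, None]
    frames = reference[None] + noise
    return Trajectory(
        coords=frames,
        topology=_generic_topology(n_atoms, reference),
        replicate_id=replicate_id,
        metadata={
            "sigma_per_atom": sigma,
            "temperature_K": DEFAULT_TEMPERATURE_K,
        },
    )
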