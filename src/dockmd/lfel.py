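"""Local free-energy landscape over the (PC1, PC2) subspace.

Pooled projections are histogrammed on a regular 2D grid of microstates and
converted to free energies with a weighted-histogram (WHAM) estimator:

    F(a) = -kT ln [ sum_i n_ai / sum_j N_j exp((f_j - V_aj)/kT) ]

where ``n_ai`` is the count of microstate ``a`` in replicate ``i``, ``V_aj``
the time-averaged bias acting on microstate ``a`` in replicate ``j`` and the
normalization constants ``f_j`` are determined self-consistently.  With no
bias (plain MD replicates) all ``f_j`` vanish and the estimator reduces to
Boltzmann inversion of the pooled microstate frequencies.

Free energies are reported in kT.  Unoccupied microstates carry a cap
(default 10 kT) representing conformations that can barely be sampled;
occupied values are clipped at the cap as well.  Two reference modes exist:
``"minimum"`` puts the global minimum at 0 and ``"docked"`` zeroes the bin
containing the docked pose's projection (the (0, 0) point of the subspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)

__all__ = [
    "LandscapeGrid",
    "BiasModel",
    "MinimumInfo",
    "grid_microstates",
    "wham_free_energy",
    "find_minimum",
    "collect_neighborhood",
    "export_maps",
    "write_heatmap_tsv",
    "read_heatmap_tsv",
    "write_surface_tsv",
]


@dataclass
class LandscapeGrid:
    """2D microstate grid: bin edges, per-replicate counts and (after
    :func:`wham_free_energy`) free energies in kT."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (n_replicates, nx, ny)
    replicate_ids: list[int]
    assignments: pd.DataFrame  # per-frame: replicate, frame, ix, iy, pc1, pc2
    free_energy: np.ndarray | None = None  # (nx, ny), kT
    temperature: float = 300.0
    cap_kt: float = 10.0
    reference: str = "minimum"

    @property
    def n_bins(self) -> tuple[int, int]:
        return (len(self.x_edges) - 1, len(self.y_edges) - 1)

    @property
    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        return (_digitize(np.array([x]), self.x_edges)[0],
                _digitize(np.array([y]), self.y_edges)[0])


@dataclass
class BiasModel:
    """Per-replicate history-dependent bias evaluated at microstate centers.

    ``series`` has shape (n_replicates, n_times, nx, ny) and holds the
    instantaneous bias V_Gi(S_a, t) in kcal/mol; ``times`` are in ps.  The
    per-microstate bias used by WHAM is the time average over the window
    (t_eq, t_sim].
    """

    series: np.ndarray
    times: np.ndarray
    t_eq: float
    t_sim: float

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.series.ndim != 4:
            raise ValueError("bias series must have shape (reps, times, nx, ny)")
        if self.series.shape[1] != len(self.times):
            raise ValueError("bias series/time length mismatch")
        if not self.t_eq < self.t_sim:
            raise ValueError("t_eq must be smaller than t_sim")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("non-finite bias values")

    def time_average(self) -> np.ndarray:
        """V_ai: (n_replicates, nx, ny) kcal/mol averaged over the window."""
        window = (self.times > self.t_eq) & (self.times <= self.t_sim)
        if not window.any():
            raise ValueError("no bias samples inside (t_eq, t_sim]")
        return self.series[:, window].mean(axis=1)


@dataclass
class MinimumInfo:
    """Location of the landscape minimum and its representative frame."""

    ix: int
    iy: int
    f_kt: float
    replicate: int
    frame: int
    pc1: float
    pc2: float


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [e_i, e_{i+1}); the last bin is right-closed."""
    idx = np.searchsorted(edges, values, side="right") - 1
    n = len(edges) - 1
    idx[values == edges[-1]] = n - 1
    if np.any((idx < 0) | (idx >= n)):
        raise ValueError("projection value outside the grid range")
    return idx


def _edges(values: np.ndarray, n: int, margin: float) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0.0:
        lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = lo - margin * span, hi + margin * span
    return np.linspace(lo, hi, n + 1)


def grid_microstates(
    proj: pd.DataFrame,
    n_bins: tuple[int, int] = (32, 32),
    margin: float = 0.02,
) -> LandscapeGrid:
    """Assign every projected frame to exactly one microstate of a regular
    grid spanning the data range expanded by ``margin`` on each side."""
    if len(proj) < 1:
        raise ValueError("need at least one projected frame")
    x = proj["pc1"].to_numpy(dtype=float)
    y = proj["pc2"].to_numpy(dtype=float)
    x_edges = _edges(x, n_bins[0], margin)
    y_edges = _edges(y, n_bins[1], margin)
    ix = _digitize(x, x_edges)
    iy = _digitize(y, y_edges)
    reps = sorted(proj["replicate"].unique().tolist())
    counts = np.zeros((len(reps), n_bins[0], n_bins[1]), dtype=int)
    rep_pos = {r: k for k, r in enumerate(reps)}
    rep_arr = proj["replicate"].to_numpy()
    for k in range(len(proj)):
        counts[rep_pos[rep_arr[k]], ix[k], iy[k]] += 1
    assignments = pd.DataFrame(
        {
            "replicate": rep_arr,
            "frame": proj["frame"].to_numpy(),
            "ix": ix,
            "iy": iy,
            "pc1": x,
            "pc2": y,
        }
    )
    return LandscapeGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        replicate_ids=reps,
        assignments=assignments,
    )


def _solve_wham(counts: np.ndarray, v_kt: np.ndarray, tol: float, max_iter: int):
    """Self-consistent WHAM for p_a and f_j (all energies in kT).

    counts: (R, nx, ny); v_kt: (R, nx, ny).  Returns (p, f) with p the
    normalized microstate probabilities over occupied bins.
    """
    r = counts.shape[0]
    n_j = counts.sum(axis=(1, 2)).astype(float)  # frames per replicate
    n_a = counts.sum(axis=0).astype(float)       # pooled counts
    f = np.zeros(r)
    w = np.exp(-v_kt)  # (R, nx, ny)
    for _ in range(max_iter):
        # p_a = n_a / sum_j N_j exp(f_j - V_aj)
        denom = np.tensordot(n_j * np.exp(f), w, axes=(0, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_a > 0, n_a / denom, 0.0)
        p /= p.sum()
        f_new = -np.log(np.tensordot(w, p, axes=([1, 2], [0, 1])))
        f_new -= f_new[0]  # gauge: first replicate defines the zero
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            return p, f
    raise RuntimeError(
        f"WHAM normalization constants did not converge: residual {resid:.3e} kT "
        f"after {max_iter} iterations"
    )


def wham_free_energy(
    grid: LandscapeGrid,
    bias: BiasModel | None = None,
    temperature: float = 300.0,
    cap_kt: float = 10.0,
    reference: str = "minimum",
    docked_point: tuple[float, float] = (0.0, 0.0),
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> LandscapeGrid:
    """Compute microstate free energies in kT on a counted grid.

    With ``bias=None`` the self-consistency loop is skipped (all f_j = 0)
    and F(a) is the Boltzmann inversion of pooled frequencies.  ``reference``
    selects the zero: the global minimum, or the bin containing
    ``docked_point`` (the docked pose's projection).
    """
    pooled = grid.pooled_counts.astype(float)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("grid has no counts")
    occupied = pooled > 0
    if bias is None:
        p = pooled / total
    else:
        v_kt = bias.time_average() / (KB_KCAL * temperature)
        if v_kt.shape != grid.counts.shape:
            raise ValueError("bias grid shape does not match the landscape grid")
        p, _ = _solve_wham(grid.counts, v_kt, tol, max_iter)

    f = np.full(grid.n_bins, np.inf)
    f[occupied] = -np.log(p[occupied])
    if reference == "minimum":
        f -= f[occupied].min()
    elif reference == "docked":
        bx, by = grid.bin_of(*docked_point)
        if not occupied[bx, by]:
            raise ValueError("docked-pose bin is unoccupied; cannot reference it")
        f -= f[bx, by]
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    f = np.minimum(f, cap_kt)
    f[~occupied] = cap_kt
    return LandscapeGrid(
        x_edges=grid.x_edges,
        y_edges=grid.y_edges,
        counts=grid.counts,
        replicate_ids=grid.replicate_ids,
        assignments=grid.assignments,
        free_energy=f,
        temperature=temperature,
        cap_kt=cap_kt,
        reference=reference,
    )


def find_minimum(grid: LandscapeGrid) -> MinimumInfo:
    """Locate the minimum-F microstate and its representative frame.

    Ties on F break toward the larger pooled count, then the lowest bin
    index.  The representative frame is the assigned frame nearest the
    centroid of the bin's projections (ties by replicate then frame order).
    """
    if grid.free_energy is None:
        raise ValueError("run wham_free_energy first")
    pooled = grid.pooled_counts
    occupied = pooled > 0
    if not occupied.any():
        raise ValueError("no occupied microstate")
    f = np.where(occupied, grid.free_energy, np.inf)
    fmin = f.min()
    cand = np.argwhere(np.isclose(f, fmin, rtol=0, atol=1e-12))
    best = max(
        (tuple(c) for c in cand),
        key=lambda c: (pooled[c[0], c[1]], -c[0], -c[1]),
    )
    ix, iy = int(best[0]), int(best[1])
    members = grid.assignments[
        (grid.assignments["ix"] == ix) & (grid.assignments["iy"] == iy)
    ]
    centroid = members[["pc1", "pc2"]].to_numpy().mean(axis=0)
    d = np.linalg.norm(members[["pc1", "pc2"]].to_numpy() - centroid, axis=1)
    order = np.lexsort((members["frame"].to_numpy(), members["replicate"].to_numpy(), d))
    rep_row = members.iloc[order[0]]
    return MinimumInfo(
        ix=ix,
        iy=iy,
        f_kt=float(grid.free_energy[ix, iy]),
        replicate=int(rep_row["replicate"]),
        frame=int(rep_row["frame"]),
        pc1=float(rep_row["pc1"]),
        pc2=float(rep_row["pc2"]),
    )


def collect_neighborhood(
    proj: pd.DataFrame, minimum: MinimumInfo, n_frames: int = 100
) -> pd.DataFrame:
    """The ``n_frames`` frames nearest (in the PC1/PC2 plane) to the
    minimum's representative projection, ordered by distance with
    deterministic (replicate, frame) tie-breaking."""
    if n_frames < 1 or n_frames > len(proj):
        raise ValueError(f"n_frames={n_frames} outside [1, {len(proj)}]")
    xy = proj[["pc1", "pc2"]].to_numpy(dtype=float)
    d = np.linalg.norm(xy - np.array([minimum.pc1, minimum.pc2]), axis=1)
    order = np.lexsort((proj["frame"].to_numpy(), proj["replicate"].to_numpy(), d))
    sel = order[:n_frames]
    out = pd.DataFrame(
        {
            "rank": np.arange(n_frames),
            "replicate": proj["replicate"].to_numpy()[sel],
            "frame": proj["frame"].to_numpy()[sel],
            "distance": d[sel],
        }
    )
    return out


def export_maps(grid: LandscapeGrid, docked_point: tuple[float, float] = (0.0, 0.0)):
    """Heat-map matrix and 3D surface triples for plotting.

    Returns (heatmap, surface, docked_bin): the heat map is a DataFrame of F
    (kT) indexed by PC1 bin centers with PC2 bin centers as columns; the
    surface is a long-form (x, y, F) DataFrame; docked_bin marks the bin
    holding the docked-pose reference point.
    """
    if grid.free_energy is None:
        raise ValueError("run wham_free_energy first")
    xc, yc = grid.x_centers(), grid.y_centers()
    heat = pd.DataFrame(grid.free_energy, index=xc, columns=yc)
    heat.index.name = "pc1_center"
    heat.columns.name = "pc2_center"
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    surface = pd.DataFrame(
        {"pc1": xx.ravel(), "pc2": yy.ravel(), "f_kt": grid.free_energy.ravel()}
    )
    return heat, surface, grid.bin_of(*docked_point)


def write_heatmap_tsv(grid: LandscapeGrid, path) -> None:
    heat, _, _ = export_maps(grid)
    heat.to_csv(path, sep="\t")


def read_heatmap_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_surface_tsv(grid: LandscapeGrid, path) -> None:
    _, surface, _ = export_maps(grid)
    surface.to_csv(path, sep="\t", index=False)
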