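"""Subcellular-element cell mechanics with selective sorting.

Each cell is a cluster of 12 nodes arranged as two concentric hexagonal
layers (outer radius ``R_out``, inner radius ``R_in``).  Node dynamics
are overdamped and first order:

    dx/dt = v_ext + v_inter + v_inner

``v_ext`` is the convergent-extension velocity evaluated at the cell
centroid and applied identically to every node of the cell.
``v_inner`` are linear springs restoring the three intra-cell rest
lengths (``l_out`` between outer-layer neighbours, ``l_in`` between
inner-layer neighbours, ``l_inter`` between same-angle cross-layer
pairs).  ``v_inter`` are node-to-node pair forces between different
cells: a short-range exponential repulsion (excluded volume,
identity-blind) plus a longer-range exponential term whose sign and
magnitude follow the krox20-similarity weight

    F(K_i, K_j) = s_i s_j + (1 - s_i)(1 - s_j),
    s = logistic((K - threshold) / width),

so F = 1 (full attraction) when both cells are krox20-alike, F = 0
(repulsion) when exactly one expresses krox20, and F = 0.5 (neutral: the
long-range term vanishes) at indeterminate levels.  Pinning F to 0.5 for
all pairs removes sorting selectivity entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import apply_intra_forces, inter_ext_forces
from .geometry import DomainState, growth_velocity

__all__ = [
    "MechanicsParams",
    "CellCollection",
    "similarity_weight",
    "init_lattice",
    "intra_velocity",
    "inter_velocity",
    "external_velocity",
    "step_mechanics",
    "N_NODE",
    "NODES_PER_CELL",
]

N_NODE = 6
NODES_PER_CELL = 2 * N_NODE

#: Default number of cells: a 23 (A-P) x 15 (L-R) lattice.
N_ROWS_AP = 23
N_COLS_LR = 15
N_CELL = N_ROWS_AP * N_COLS_LR


@dataclass(frozen=True)
class MechanicsParams:
    """Force parameters (micron, micron/h, 1/h)."""

    R_out: float = 3.2  # outer-layer radius; the nominal cell radius
    R_in: float = 1.6
    k_intra: float = 500.0  # intra-cell spring stiffness (1/h)
    c_rep: float = 40.0  # short-range repulsion amplitude (micron/h)
    rho_rep: float = 2.0  # repulsion range (micron)
    c_att: float = 6.0  # long-range similarity term amplitude (micron/h)
    rho_att: float = 5.0  # attraction range (micron)
    sim_steepness: float = 0.25  # logistic width of the krox20 sigmoid (a.u.)
    cutoff: float = 12.0  # neighbour cutoff (micron)
    r_core: float = 1.5  # intra-cell volume-exclusion range (micron)
    dt_mech: float = 1e-3  # stand-alone mechanics time step (h)

    def __post_init__(self):
        if self.R_in >= self.R_out:
            raise ValueError("R_in must be smaller than R_out")
        if self.rho_rep >= self.rho_att:
            raise ValueError("repulsion range must be below attraction range")
        if self.cutoff <= 0 or self.rho_rep <= 0:
            raise ValueError("ranges must be positive")

    @property
    def rest_lengths(self) -> tuple[float, float, float]:
        """(l_out, l_in, l_inter): hexagon side lengths equal the layer
        radii; the cross-layer rest length is the radial gap."""
        return (self.R_out, self.R_in, self.R_out - self.R_in)


def _hex_template(params: MechanicsParams) -> np.ndarray:
    """Rest configuration of one cell's 12 nodes around the origin."""
    ang = np.arange(N_NODE) * (2.0 * np.pi / N_NODE)
    outer = params.R_out * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    inner = params.R_in * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return np.concatenate([outer, inner], axis=0)


def _intra_pairs(n_cells: int, params: MechanicsParams):
    """Spring topology (pair index arrays + rest lengths) for n cells."""
    l_out, l_in, l_inter = params.rest_lengths
    pi, pj, rest = [], [], []
    for k in range(N_NODE):
        pi.append(k)
        pj.append((k + 1) % N_NODE)
        rest.append(l_out)
    for k in range(N_NODE):
        pi.append(N_NODE + k)
        pj.append(N_NODE + (k + 1) % N_NODE)
        rest.append(l_in)
    for k in range(N_NODE):
        pi.append(k)
        pj.append(N_NODE + k)
        rest.append(l_inter)
    pi = np.asarray(pi, dtype=np.int64)
    pj = np.asarray(pj, dtype=np.int64)
    rest = np.asarray(rest, dtype=float)
    offs = (np.arange(n_cells) * NODES_PER_CELL)[:, None]
    return (
        (pi[None, :] + offs).ravel(),
        (pj[None, :] + offs).ravel(),
        np.tile(rest, n_cells),
    )


def _force_tables(params: "MechanicsParams", n: int = 2048):
    """Radial force-magnitude tables over [0, cutoff] for the hot loop."""
    d = np.linspace(0.0, params.cutoff, n + 1)
    rep = params.c_rep * np.exp(-d / params.rho_rep)
    att = params.c_att * np.exp(-d / params.rho_att)
    core = params.c_rep * (
        np.exp(-d / params.rho_rep) - np.exp(-params.r_core / params.rho_rep)
    )
    inv_dr = n / params.cutoff
    return (
        np.ascontiguousarray(rep),
        np.ascontiguousarray(att),
        np.ascontiguousarray(core),
        inv_dr,
    )


@dataclass
class CellCollection:
    """All cells of a simulation, stored as flat node arrays.

    ``nodes`` has shape (n_cells * 12, 2); nodes of cell ``c`` occupy the
    contiguous block ``[12 c, 12 c + 12)``.
    """

    nodes: np.ndarray
    params: MechanicsParams

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[0] % NODES_PER_CELL:
            raise ValueError("nodes must be (12 * n_cells, 2)")
        n = self.n_cells
        self.cell_of_node = np.repeat(np.arange(n, dtype=np.int64), NODES_PER_CELL)
        self._pair_i, self._pair_j, self._rest = _intra_pairs(n, self.params)
        self._tables = _force_tables(self.params)

    @property
    def n_cells(self) -> int:
        return self.nodes.shape[0] // NODES_PER_CELL

    @property
    def centroids(self) -> np.ndarray:
        """(n_cells, 2) arithmetic means of each cell's 12 nodes."""
        return self.nodes.reshape(-1, NODES_PER_CELL, 2).mean(axis=1)

    def radii_of_gyration(self) -> np.ndarray:
        blocks = self.nodes.reshape(-1, NODES_PER_CELL, 2)
        c = blocks.mean(axis=1, keepdims=True)
        return np.sqrt(np.mean(np.sum((blocks - c) ** 2, axis=2), axis=1))

    def copy(self) -> "CellCollection":
        return CellCollection(self.nodes.copy(), self.params)


def init_lattice(
    state: DomainState,
    params: MechanicsParams | None = None,
    n_rows: int = N_ROWS_AP,
    n_cols: int = N_COLS_LR,
) -> CellCollection:
    """Uniform lattice of cells filling the tissue domain.

    ``n_rows`` positions along A-P times ``n_cols`` along L-R (345 cells
    by default), each cell in its two-hexagon rest configuration around
    its lattice point.  Lattice points are placed at the centres of a
    uniform subdivision of the tissue rectangle.
    """
    params = params or MechanicsParams()
    x_lo, x_hi = state.tissue_x_min, state.tissue_x_max
    xs = x_lo + (np.arange(n_rows) + 0.5) * (x_hi - x_lo) / n_rows
    ys = -0.5 * state.L2 + (np.arange(n_cols) + 0.5) * state.L2 / n_cols
    centers = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    template = _hex_template(params)
    nodes = (centers[:, None, :] + template[None, :, :]).reshape(-1, 2)
    return CellCollection(nodes, params)


def intra_velocity(cell_nodes: np.ndarray, params: MechanicsParams) -> np.ndarray:
    """Shape-restoring node velocities of a single cell (12, 2).

    Zero at the rest configuration; internal forces cancel pairwise so
    they contribute no net force to the cell.
    """
    nodes = np.asarray(cell_nodes, dtype=float)
    pi, pj, rest = _intra_pairs(1, params)
    vel = np.zeros_like(nodes)
    d = nodes[pi] - nodes[pj]
    dist = np.linalg.norm(d, axis=1)
    ok = dist > 1e-12
    f = np.zeros_like(d)
    f[ok] = (-params.k_intra * (dist[ok] - rest[ok]) / dist[ok])[:, None] * d[ok]
    np.add.at(vel, pi, f)
    np.add.at(vel, pj, -f)
    return vel


def similarity_weight(k_i, k_j, threshold: float = 1.2, width: float = 0.1):
    """Krox20-similarity weight F in [0, 1] (1 alike, 0 dissimilar)."""
    si = 1.0 / (1.0 + np.exp(-(np.asarray(k_i, dtype=float) - threshold) / width))
    sj = 1.0 / (1.0 + np.exp(-(np.asarray(k_j, dtype=float) - threshold) / width))
    return si * sj + (1.0 - si) * (1.0 - sj)


def inter_velocity(
    nodes_a: np.ndarray,
    nodes_b: np.ndarray,
    F: float,
    params: MechanicsParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair forces between the nodes of two cells.

    Returns the velocity contributions to cell a's and cell b's nodes;
    antisymmetric between the paired nodes.
    """
    a = np.asarray(nodes_a, dtype=float)
    b = np.asarray(nodes_b, dtype=float)
    va = np.zeros_like(a)
    vb = np.zeros_like(b)
    diff = a[:, None, :] - b[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    mask = (d < params.cutoff) & (d > 1e-12)
    coef = np.zeros_like(d)
    coef[mask] = params.c_rep * np.exp(-d[mask] / params.rho_rep) - params.c_att * (
        2.0 * F - 1.0
    ) * np.exp(-d[mask] / params.rho_att)
    unit = np.where(mask[:, :, None], diff / np.where(d, d, 1.0)[:, :, None], 0.0)
    contrib = coef[:, :, None] * unit
    va += contrib.sum(axis=1)
    vb -= contrib.sum(axis=0)
    return va, vb


def external_velocity(cell_nodes: np.ndarray, state: DomainState) -> np.ndarray:
    """Convergent-extension velocity, centroid-evaluated, equal on all nodes."""
    c = np.asarray(cell_nodes, dtype=float).mean(axis=0)
    v = growth_velocity(c, state)
    return np.broadcast_to(v, np.asarray(cell_nodes).shape).copy()


def step_mechanics(
    cells: CellCollection,
    state: DomainState | None,
    dt: float,
    krox20_levels: np.ndarray,
    threshold: float = 1.2,
    neutral_similarity: bool = False,
    disable_ce: bool = False,
    intra_dt: float = 5e-4,
    max_disp_factor: float = 1.0,
) -> None:
    """Advance all node positions in place by ``dt``.

    ``krox20_levels`` are the per-cell K values feeding the similarity
    sigmoid; ``neutral_similarity`` pins F at 0.5 (no selective
    sorting).  With ``disable_ce`` (or ``state=None``) the external
    velocity is zero.

    The slowly varying external + inter-cell velocities are evaluated
    once per call; the stiff intra-cell shape springs are integrated
    with sub-steps no longer than ``intra_dt``.  Raises if any node
    moves more than one cell radius in a sub-step (stability guard).
    """
    p = cells.params
    sigma = 1.0 / (
        1.0 + np.exp(-(np.asarray(krox20_levels, dtype=float) - threshold) / p.sim_steepness)
    )
    sigma = np.ascontiguousarray(sigma)
    if state is None or disable_ce:
        a1 = a2 = 0.0
    else:
        a1 = state.dL1dt / state.L1
        a2 = state.dL2dt / state.L2
    rep_tab, att_tab, core_tab, inv_dr = cells._tables
    vel_slow = inter_ext_forces(
        cells.nodes,
        cells.cell_of_node,
        sigma,
        rep_tab,
        att_tab,
        core_tab,
        inv_dr,
        p.cutoff,
        neutral_similarity,
        a1,
        a2,
        float(NODES_PER_CELL),
        p.r_core,
    )
    # the inter-cell field is frozen over dt: reject a dt so large that
    # it would carry a node further than one cell radius
    if vel_slow.size:
        max_slow = float(np.abs(vel_slow).max())
        if dt * max_slow > max_disp_factor * p.R_out:
            raise ValueError(
                f"node displacement {dt * max_slow:.2f} um exceeds one cell "
                "radius; reduce the mechanics dt"
            )
    n_sub = max(int(np.ceil(dt / intra_dt)), 1)
    sub_dt = dt / n_sub
    for _ in range(n_sub):
        vel = vel_slow.copy()
        apply_intra_forces(
            cells.nodes, cells._pair_i, cells._pair_j, cells._rest, p.k_intra, vel
        )
        disp = sub_dt * vel
        max_disp = float(np.abs(disp).max()) if disp.size else 0.0
        if max_disp > max_disp_factor * p.R_out:
            raise ValueError(
                f"node displacement {max_disp:.2f} um exceeds one cell radius; "
                "reduce the mechanics dt"
            )
        cells.nodes += disp
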