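"""Stochastic morphogen dynamics on the deforming morphogen domain.

Two ligands are modelled as continuum fields: retinoic acid (RA) in
extracellular (``RAout``, diffusing) and intracellular (``RAin``,
non-diffusing) forms, and FGF as a free diffusing form (``FGFfree``)
and a bound receptor-complex signalling form (``FGFsignal``,
non-diffusing).  RA is produced in the posterior production region
``x1 > p(t)`` (a sharp Hill function of A-P position), degraded fast
there (cyp26a1) and slowly elsewhere, exchanged between the two forms,
and absorbed at the anterior boundary ``x1 = 0`` (MHB/forebrain sink).
FGF is produced in proportion to a saturating Hill function of the
local *hoxb1a* level interpolated from cell centres, with no-flux
boundaries on all four sides.

Moving domain
-------------
The rectangle ``[0, L1(t)] x [-L2/2, L2/2]`` is mapped to the fixed
computational unit square.  Because the convergent-extension velocity
is affine, computational coordinates are exactly Lagrangian: the
convection term reduces to the uniform dilution ``-(L1'/L1 + L2'/L2) C``
and the Laplacian picks up metric factors ``1/L1^2, 1/L2^2``.  With the
intracellular-advection ablation the non-diffusing forms instead keep
their lab-frame equations, which in the mapped frame is the residual
upwind transport ``+V . grad C`` with no dilution.

Numerics: explicit Euler-Maruyama, centred second-order diffusion on a
cell-centred grid, dt from the diffusion CFL with safety factor 0.4,
spatiotemporal white noise discretised per node and step, fields
clipped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

from .geometry import DomainState, Geometry
from ._kernels import morphogen_step

__all__ = [
    "RAParams",
    "FGFParams",
    "MorphogenGrid",
    "ra_production_rate",
    "ra_degradation_rate",
    "fgf_production_rate",
    "interpolate_grid_to_points",
    "interpolate_points_to_grid",
    "solve_ra_steady_state",
    "step_morphogens",
    "stable_dt",
]

logger = logging.getLogger(__name__)

#: Hill coefficient of the production-region indicator (sharp switch).
PRODUCTION_HILL = 20.0


@dataclass(frozen=True)
class RAParams:
    """RA field parameters (micron^2/h, a.u./h, 1/h)."""

    Dr: float = 2500.0  # diffusion; decay length ~40 micron
    vr: float = 10.0  # production rate in the production region
    kr: float = 1.0  # intracellular/extracellular exchange
    beta_r: float = 1.0  # extracellular degradation = beta_r * kr
    kmax: float = 8.0  # intracellular degradation inside production region
    k0: float = 1.0  # intracellular degradation elsewhere
    mu_r1: float = 0.1  # noise amplitude, extracellular
    mu_r2: float = 0.05  # noise amplitude, intracellular

    def __post_init__(self):
        if self.kmax < self.k0:
            raise ValueError("kmax must be >= k0")
        for name in ("Dr", "vr", "kr", "beta_r", "kmax", "k0", "mu_r1", "mu_r2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FGFParams:
    """FGF field parameters (micron^2/h, a.u./h, 1/h, dimensionless)."""

    Df: float = 950.0  # diffusion; short-range, decay length ~18 micron
    vf: float = 8.0  # maximal production rate
    ahf: float = 0.2  # Hill saturation of the hoxb1a input
    kf: float = 2.0  # receptor binding
    krf: float = 2.0  # complex dissociation
    df1: float = 2.0  # degradation of free FGF
    df2: float = 2.0  # degradation of the signalling complex
    mu_f1: float = 0.05
    mu_f2: float = 0.05

    def __post_init__(self):
        for name in ("Df", "vf", "ahf", "kf", "krf", "df1", "df2", "mu_f1", "mu_f2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MorphogenGrid:
    """Cell-centred fields on the fixed computational unit rectangle.

    ``field[i, j]`` lives at computational coordinates
    ``xi = (i + 1/2)/nx, eta = (j + 1/2)/ny`` which map to physical
    ``x1 = xi * L1, x2 = (eta - 1/2) * L2``.
    """

    nx: int
    ny: int
    RAout: np.ndarray = field(default=None)
    RAin: np.ndarray = field(default=None)
    FGFfree: np.ndarray = field(default=None)
    FGFsignal: np.ndarray = field(default=None)

    def __post_init__(self):
        for name in ("RAout", "RAin", "FGFfree", "FGFsignal"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((self.nx, self.ny)))
            else:
                arr = np.asarray(getattr(self, name), dtype=float)
                if arr.shape != (self.nx, self.ny):
                    raise ValueError(f"{name} must have shape (nx, ny)")
                setattr(self, name, arr)

    @property
    def xi(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) / self.nx

    @property
    def eta(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) / self.ny

    def x1(self, state: DomainState) -> np.ndarray:
        return self.xi * state.L1

    def x2(self, state: DomainState) -> np.ndarray:
        return (self.eta - 0.5) * state.L2

    def copy(self) -> "MorphogenGrid":
        return MorphogenGrid(
            self.nx,
            self.ny,
            self.RAout.copy(),
            self.RAin.copy(),
            self.FGFfree.copy(),
            self.FGFsignal.copy(),
        )


def ra_production_rate(x1, p: float, vr: float):
    """RA production rate: sharp Hill switch of A-P position.

    ``vr / (1 + (x1/p)^-20)``, evaluated through a logistic of
    ``log(x1/p)`` for numerical stability; the ``x1 -> 0`` limit is 0.
    """
    x1 = np.asarray(x1, dtype=float)
    with np.errstate(divide="ignore"):
        logratio = np.log(np.where(x1 > 0, x1, np.nan) / p)
    out = vr * expit(PRODUCTION_HILL * logratio)
    return np.where(x1 > 0, out, 0.0)


def ra_degradation_rate(x1, p: float, kmax: float, k0: float):
    """Piecewise intracellular RA degradation: ``kmax`` strictly inside
    the production region (``x1 > p``), ``k0`` otherwise."""
    return np.where(np.asarray(x1, dtype=float) > p, kmax, k0)


def fgf_production_rate(H, vf: float, ahf: float):
    """Saturating Hill production of FGF from the local hoxb1a level:
    ``vf H^2 / (1 + ahf H^2)`` (saturates at ``vf/ahf``)."""
    H2 = np.square(np.asarray(H, dtype=float))
    return vf * H2 / (1.0 + ahf * H2)


def interpolate_grid_to_points(
    field_arr: np.ndarray, points: np.ndarray, state: DomainState, warn: bool = True
) -> np.ndarray:
    """Bilinear interpolation of a grid field at physical points.

    Points outside the morphogen domain are clamped to the boundary
    (with a logged warning).  Exact for fields linear in position.
    """
    f = np.asarray(field_arr, dtype=float)
    nx, ny = f.shape
    pts = np.asarray(points, dtype=float)
    xi = pts[..., 0] / state.L1
    eta = pts[..., 1] / state.L2 + 0.5
    if warn and (np.any(xi < 0) or np.any(xi > 1) or np.any(eta < 0) or np.any(eta > 1)):
        logger.warning("interpolation points outside the morphogen domain; clamped")
    u = np.clip(xi * nx - 0.5, 0.0, nx - 1.0)
    v = np.clip(eta * ny - 0.5, 0.0, ny - 1.0)
    i0 = np.floor(u).astype(int)
    j0 = np.floor(v).astype(int)
    i1 = np.minimum(i0 + 1, nx - 1)
    j1 = np.minimum(j0 + 1, ny - 1)
    fu = u - i0
    fv = v - j0
    return (
        f[i0, j0] * (1 - fu) * (1 - fv)
        + f[i1, j0] * fu * (1 - fv)
        + f[i0, j1] * (1 - fu) * fv
        + f[i1, j1] * fu * fv
    )


def interpolate_points_to_grid(
    points: np.ndarray,
    values: np.ndarray,
    grid: MorphogenGrid,
    state: DomainState,
    rx: float = 9.0,
    ry: float = 22.0,
) -> np.ndarray:
    """Scatter cell-centre values (e.g. hoxb1a) onto the morphogen grid.

    A normalised elliptical tent (Shepard) kernel of half-widths
    ``rx, ry`` micron is used; the anisotropy reflects the initially
    wide L-R cell spacing.  Grid nodes with no cell inside the kernel
    support (in particular everywhere outside the tissue) get 0: there
    is no hoxb1a source outside the tissue domain.
    """
    from ._kernels import deposit_shepard

    pts = np.ascontiguousarray(np.asarray(points, dtype=float).reshape(-1, 2))
    vals = np.ascontiguousarray(np.asarray(values, dtype=float).ravel())
    if pts.shape[0] == 0:
        return np.zeros((grid.nx, grid.ny))
    gx = np.ascontiguousarray(grid.x1(state))
    gy = np.ascontiguousarray(grid.x2(state))
    return deposit_shepard(pts, vals, gx, gy, float(rx), float(ry))


def _ra_linear_coeff(grid: MorphogenGrid, state: DomainState, params: RAParams):
    """Net linear loss coefficient of RAout after eliminating RAin."""
    x1 = grid.x1(state)
    dr = ra_degradation_rate(x1, state.p, params.kmax, params.k0)
    # -(1+beta_r) kr + kr^2/(kr+dr)  (negative: net loss)
    return -(1.0 + params.beta_r) * params.kr + params.kr**2 / (params.kr + dr)


def solve_ra_steady_state(
    grid_shape: tuple[int, int],
    state: DomainState,
    params: RAParams,
    tol: float = 1e-10,
) -> MorphogenGrid:
    """Deterministic RA equilibrium on a frozen domain (V = 0, no noise).

    With ``RAin`` slaved locally (``RAin = kr RAout / (kr + dr)``), the
    extracellular equation becomes a linear elliptic problem solved by a
    sparse direct method: absorbing (Dirichlet-0) face at ``x1 = 0``,
    no-flux on the other three sides.  Returns a grid with the two RA
    fields filled in (FGF fields zero).
    """
    nx, ny = grid_shape
    grid = MorphogenGrid(nx, ny)
    dx = state.L1 / nx
    dy = state.L2 / ny
    x1 = grid.x1(state)
    A = np.broadcast_to(
        ra_production_rate(x1, state.p, params.vr)[:, None], (nx, ny)
    ).ravel()
    k_lin = np.broadcast_to(_ra_linear_coeff(grid, state, params)[:, None], (nx, ny))

    n = nx * ny
    idx = np.arange(n).reshape(nx, ny)
    D = params.Dr
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    cx, cy = D / dx**2, D / dy**2
    for i in range(nx):
        for j in range(ny):
            r = idx[i, j]
            diag = k_lin[i, j]
            # x-direction
            if i > 0:
                add(r, idx[i - 1, j], cx)
                diag -= cx
            else:  # absorbing face: ghost = -C
                diag -= 2.0 * cx
            if i < nx - 1:
                add(r, idx[i + 1, j], cx)
                diag -= cx
            # no-flux at i = nx-1: ghost = C, no diagonal contribution
            # y-direction (no-flux both sides)
            if j > 0:
                add(r, idx[i, j - 1], cy)
                diag -= cy
            if j < ny - 1:
                add(r, idx[i, j + 1], cy)
                diag -= cy
            add(r, r, diag)

    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    ra_out = spla.spsolve(M, -A).reshape(nx, ny)
    resid = np.abs(M @ ra_out.ravel() + A).max()
    scale = max(np.abs(A).max(), 1.0)
    if resid > tol * scale * n:
        logger.warning("RA steady state residual %.3e above tolerance", resid)
    ra_out = np.maximum(ra_out, 0.0)
    dr = ra_degradation_rate(x1, state.p, params.kmax, params.k0)[:, None]
    ra_in = params.kr * ra_out / (params.kr + dr)
    grid.RAout = ra_out
    grid.RAin = ra_in
    return grid


def stable_dt(
    geometry: Geometry,
    ra_params: RAParams,
    fgf_params: FGFParams,
    grid_shape: tuple[int, int],
    safety: float = 0.4,
    t_samples: int = 61,
) -> float:
    """Largest diffusion-stable time step over the whole schedule."""
    nx, ny = grid_shape
    ts = np.linspace(geometry.curves.t_min, geometry.curves.t_max, t_samples)
    worst = 0.0
    D = max(ra_params.Dr, fgf_params.Df)
    for t in ts:
        st = geometry.state(float(t))
        dx = st.L1 / nx
        dy = st.L2 / ny
        worst = max(worst, 2.0 * D * (1.0 / dx**2 + 1.0 / dy**2))
    if worst == 0.0:
        return 1e-3
    return safety / worst


def step_morphogens(
    grid: MorphogenGrid,
    state: DomainState,
    dt: float,
    rng: np.random.Generator,
    ra_params: RAParams,
    fgf_params: FGFParams,
    h_field: np.ndarray | None = None,
    advect_intracellular: bool = True,
    multiplicative_noise: bool = False,
    check_cfl: bool = True,
    ra_absorbing_left: bool = True,
) -> None:
    """One Euler-Maruyama step of all four fields, in place.

    ``h_field`` is the hoxb1a level on the grid (zero if omitted),
    driving FGF production.  With ``advect_intracellular=False`` the
    convection terms of the two non-diffusing forms are dropped.
    ``ra_absorbing_left=False`` switches the anterior RA boundary to
    no-flux (used for well-mixed and conservation analyses).
    Raises ``ValueError`` on a CFL violation.
    """
    nx, ny = grid.nx, grid.ny
    dx = state.L1 / nx
    dy = state.L2 / ny
    if check_cfl:
        D = max(ra_params.Dr, fgf_params.Df)
        if dt * 2.0 * D * (1.0 / dx**2 + 1.0 / dy**2) > 1.0:
            raise ValueError(f"dt={dt} violates the diffusion CFL limit")

    rp, fp = ra_params, fgf_params
    dil = state.dilution_rate
    inv_dx2, inv_dy2 = 1.0 / dx**2, 1.0 / dy**2

    x1 = grid.x1(state)
    A = np.ascontiguousarray(ra_production_rate(x1, state.p, rp.vr))
    dr_x = np.ascontiguousarray(
        ra_degradation_rate(x1, state.p, rp.kmax, rp.k0), dtype=float
    )
    if h_field is not None:
        Af = np.ascontiguousarray(fgf_production_rate(h_field, fp.vf, fp.ahf))
    else:
        Af = np.zeros((nx, ny))

    amp = np.sqrt(dt / (dx * dy))
    noise = rng.standard_normal((4, nx, ny))
    morphogen_step(
        grid.RAout,
        grid.RAin,
        grid.FGFfree,
        grid.FGFsignal,
        noise,
        A,
        dr_x,
        Af,
        dil,
        inv_dx2,
        inv_dy2,
        rp.Dr,
        rp.kr,
        rp.beta_r,
        fp.Df,
        fp.kf,
        fp.krf,
        fp.df1,
        fp.df2,
        dt,
        amp,
        rp.mu_r1,
        rp.mu_r2,
        fp.mu_f1,
        fp.mu_f2,
        state.dL1dt / state.L1,
        state.dL2dt / state.L2,
        1.0 / nx,
        1.0 / ny,
        advect_intracellular,
        multiplicative_noise,
        ra_absorbing_left,
    )
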