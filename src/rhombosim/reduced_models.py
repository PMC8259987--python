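"""Reduced models: the 1D gene-expression model and the sorting-only model.

The 1D model solves the morphogen/gene system on a fixed A-P segment
(no convergent extension, no cells): morphogen fields and gene levels
live on the same 1D grid, and steady states are reached by explicit
time integration so that bistable nodes settle into the basin selected
by the initial condition.  Two variants are provided:

* ``two_morphogen`` — the full circuit: RA activates *hoxb1a* and
  *vhnf1*; *hoxb1a* drives FGF production; FGF activates *krox20*.
  Because FGF peaks in the *hoxb1a* stripe (r4) and decays in both
  directions, *krox20* forms two flanking stripes and all four
  boundaries (r2/r3 ... r5/r6) are specified.
* ``one_morphogen`` — the RA-only reduction: the FGF equations are
  dropped and *krox20* is activated directly by intracellular RA (with
  an independently calibrated gain).  RA increases monotonically toward
  the posterior, so *krox20* has a single anterior onset: the r5/r6
  boundary cannot be specified, and whether the *hoxb1a* stripe (r4)
  forms at all becomes a race against *krox20* that is decided by the
  initial *hoxb1a* level.

The sorting-only model freezes identities (sampled from a position-
conditional Gaussian mixture over the five segments) and runs cell
mechanics alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .gene_network import GeneParams, gene_rhs
from .geometry import Geometry
from .mechanics import init_lattice, step_mechanics
from .metrics import quantify_pattern
from .morphogens import FGFParams, RAParams, fgf_production_rate, ra_production_rate
from .orchestrator import SimulationResult, _metrics_row

__all__ = [
    "OneDProfile",
    "IdentityMixture",
    "ONE_MORPHOGEN_K_GAIN",
    "run_1d_model",
    "phase_diagram",
    "noisy_ic_ensemble",
    "sample_identities_gmm",
    "default_identity_mixture",
    "run_sorting_only",
]

#: Domain length of the 1D model: the 14 hpf morphogen-domain A-P extent.
DOMAIN_LENGTH_1D = 300.0
#: Anterior edge of the RA production region in the 1D model (14 hpf).
RA_ONSET_1D = 230.0
#: Default grid resolution of the 1D model.
N_NODES_1D = 128

#: Calibrated gain of the direct RA -> krox20 activation in the
#: one-morphogen variant (chosen so the r2/r3 boundary of the
#: deterministic baseline matches the two-morphogen model).
ONE_MORPHOGEN_K_GAIN = 62.5


@dataclass
class OneDProfile:
    """Steady 1D profiles plus derived boundaries and lengths."""

    x: np.ndarray
    RA: np.ndarray  # intracellular RA
    RAout: np.ndarray
    H: np.ndarray
    K: np.ndarray
    V: np.ndarray
    I: np.ndarray
    FGF: np.ndarray  # FGF signalling (zero in the one-morphogen variant)
    boundaries: dict  # name -> position (micron) or nan
    lengths: dict  # r3/r4/r5 -> micron or nan
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x,
                "RAin": self.RA,
                "RAout": self.RAout,
                "H": self.H,
                "K": self.K,
                "V": self.V,
                "I": self.I,
                "FGF": self.FGF,
            }
        )


def _ra_steady_1d(x, dx, params: RAParams):
    """Deterministic 1D RA equilibrium (tridiagonal solve).

    Absorbing at x = 0, no-flux at the posterior end; RAin slaved
    locally as in the 2D solver.
    """
    n = x.size
    dr = np.where(x > RA_ONSET_1D, params.kmax, params.k0)
    k_lin = -(1.0 + params.beta_r) * params.kr + params.kr**2 / (params.kr + dr)
    A = ra_production_rate(x, RA_ONSET_1D, params.vr)
    c = params.Dr / dx**2
    main = k_lin - 2.0 * c
    main[0] = k_lin[0] - 3.0 * c  # absorbing ghost = -edge
    main[-1] = k_lin[-1] - c  # no-flux ghost = edge
    ab = np.zeros((3, n))
    ab[0, 1:] = c
    ab[1, :] = main
    ab[2, :-1] = c
    from scipy.linalg import solve_banded

    ra_out = solve_banded((1, 1), ab, -A)
    ra_out = np.maximum(ra_out, 0.0)
    ra_in = params.kr * ra_out / (params.kr + dr)
    return ra_out, ra_in


def _boundaries_from_profiles(x, H, K, threshold: float = 1.2) -> dict:
    """Boundary positions from threshold crossings of H and K.

    r3/r4 and r4/r5 are the edges of the hoxb1a-high stripe; r2/r3 is
    the anterior-most krox20 onset and r5/r6 the posterior-most krox20
    offset.  Any edge that does not exist inside the domain is nan.
    """

    def crossings(y):
        above = y >= threshold
        idx = np.nonzero(np.diff(above.astype(int)))[0]
        pos = []
        for i in idx:
            y0, y1 = y[i], y[i + 1]
            frac = (threshold - y0) / (y1 - y0)
            pos.append((x[i] + frac * (x[i + 1] - x[i]), above[i + 1]))
        return pos, above

    out = {k: np.nan for k in ("r2/r3", "r3/r4", "r4/r5", "r5/r6")}

    h_cross, h_above = crossings(np.asarray(H))
    ups = [p for p, rising in h_cross if rising]
    downs = [p for p, rising in h_cross if not rising]
    if ups:
        out["r3/r4"] = float(ups[0])
    if downs:
        out["r4/r5"] = float(downs[-1])
    if ups and not downs and h_above[-1]:
        out["r4/r5"] = np.nan  # stripe runs off the posterior end

    k_cross, k_above = crossings(np.asarray(K))
    k_ups = [p for p, rising in k_cross if rising]
    k_downs = [p for p, rising in k_cross if not rising]
    if k_ups:
        out["r2/r3"] = float(k_ups[0])
    if k_downs and not k_above[-1]:
        out["r5/r6"] = float(k_downs[-1])
    return out


def _lengths_from_boundaries(b: dict) -> dict:
    m23, m34, m45, m56 = (b[k] for k in ("r2/r3", "r3/r4", "r4/r5", "r5/r6"))
    return {
        "r3": m34 - m23 if np.isfinite(m34) and np.isfinite(m23) else np.nan,
        "r4": m45 - m34 if np.isfinite(m45) and np.isfinite(m34) else np.nan,
        "r5": m56 - m45 if np.isfinite(m56) and np.isfinite(m45) else np.nan,
    }


def run_1d_model(
    variant: str = "two_morphogen",
    initial_H=None,
    noise: bool = False,
    rng: np.random.Generator | None = None,
    gene_params: GeneParams | None = None,
    ra_params: RAParams | None = None,
    fgf_params: FGFParams | None = None,
    n_nodes: int = N_NODES_1D,
    max_hours: float = 40.0,
    rel_tol: float = 1e-6,
    dt: float | None = None,
) -> OneDProfile:
    """Integrate the 1D model to steady state.

    ``initial_H`` is a constant (default: the calibrated pre-pattern
    level 0.21) or an array over the grid.  With ``noise`` the gene
    equations carry their stochastic terms and the run has a fixed
    horizon (no steady state); convergence is otherwise declared when
    the largest relative change per hour falls below ``rel_tol``.
    """
    if variant not in ("two_morphogen", "one_morphogen"):
        raise ValueError(f"unknown variant {variant!r}")
    gp = gene_params or GeneParams()
    rp = ra_params or RAParams()
    fp = fgf_params or FGFParams()
    if noise and rng is None:
        raise ValueError("noise=True requires an rng")

    dx = DOMAIN_LENGTH_1D / n_nodes
    x = (np.arange(n_nodes) + 0.5) * dx
    ra_out, ra_in = _ra_steady_1d(x, dx, rp)

    # vhnf1/irx3 equilibrium under the RA profile (local ODEs)
    states = np.zeros((n_nodes, 4))
    for _ in range(4000):
        d = gene_rhs(states, ra_in, np.zeros(n_nodes), gp)
        states[:, 2:] += 5e-3 * d[:, 2:]
        np.maximum(states, 0.0, out=states)

    if initial_H is None:
        initial_H = gp.initial_H
    states[:, 0] = np.asarray(initial_H, dtype=float)
    states[:, 1] = 0.0

    one_morph = variant == "one_morphogen"
    if one_morph:
        gp_run = replace(gp, afk=ONE_MORPHOGEN_K_GAIN)
    else:
        gp_run = gp

    if dt is None:
        dt = 0.4 / (2.0 * rp.Dr / dx**2)
    f_free = np.zeros(n_nodes)
    f_sig = np.zeros(n_nodes)
    cdiff_f = fp.Df / dx**2

    mu = np.array([gp_run.mu_h, gp_run.mu_k, gp_run.mu_v, gp_run.mu_i])
    check_every = max(int(round(1.0 / dt)), 1)
    prev = states.copy()
    converged = not noise
    n_steps = int(round(max_hours / dt))
    for step in range(n_steps):
        if not one_morph:
            lap = np.empty_like(f_free)
            lap[1:-1] = f_free[2:] - 2.0 * f_free[1:-1] + f_free[:-2]
            lap[0] = f_free[1] - f_free[0]
            lap[-1] = f_free[-2] - f_free[-1]
            Af = fgf_production_rate(states[:, 0], fp.vf, fp.ahf)
            d_free = cdiff_f * lap + Af + fp.krf * f_sig - (fp.df1 + fp.kf) * f_free
            d_sig = fp.kf * f_free - (fp.krf + fp.df2) * f_sig
            f_free = np.maximum(f_free + dt * d_free, 0.0)
            f_sig = np.maximum(f_sig + dt * d_sig, 0.0)
        k_signal = ra_in if one_morph else f_sig
        d = gene_rhs(states, ra_in, k_signal, gp_run)
        states += dt * d
        if noise:
            states += mu * np.sqrt(dt) * rng.standard_normal(states.shape)
        np.maximum(states, 0.0, out=states)
        if not noise and (step + 1) % check_every == 0:
            change = np.max(np.abs(states - prev)) / max(np.max(np.abs(states)), 1e-12)
            prev = states.copy()
            if change < rel_tol:
                break
    else:
        if not noise:
            converged = False

    b = _boundaries_from_profiles(x, states[:, 0], states[:, 1], gp.classify_threshold)
    return OneDProfile(
        x=x,
        RA=ra_in,
        RAout=ra_out,
        H=states[:, 0],
        K=states[:, 1],
        V=states[:, 2],
        I=states[:, 3],
        FGF=f_sig,
        boundaries=b,
        lengths=_lengths_from_boundaries(b),
        converged=converged,
    )


def phase_diagram(
    variant: str,
    initial_H_grid,
    **kwargs,
) -> pd.DataFrame:
    """Boundary positions and segment lengths per constant initial
    hoxb1a level (deterministic runs; identical on re-run)."""
    rows = []
    for h0 in np.atleast_1d(initial_H_grid):
        prof = run_1d_model(variant, initial_H=float(h0), noise=False, **kwargs)
        row = {"initial_H": float(h0)}
        row.update({f"m_{k.replace('/', '')}": v for k, v in prof.boundaries.items()})
        row.update({f"len_{k}": v for k, v in prof.lengths.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def noisy_ic_ensemble(
    variant: str,
    ic_range: tuple[float, float],
    n: int,
    rng: np.random.Generator,
    n_nodes: int = N_NODES_1D,
    **kwargs,
) -> dict:
    """Ensemble over uniformly random initial hoxb1a fields.

    Each repeat draws an independent initial field with iid
    U[ic_range] node levels and integrates deterministically to steady
    state.  Returns per-position mean/SD profiles of H and K and the
    per-run boundary positions.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = ic_range
    Hs, Ks, rows = [], [], []
    for _ in range(n):
        ic = rng.uniform(lo, hi, size=n_nodes)
        prof = run_1d_model(variant, initial_H=ic, noise=False, n_nodes=n_nodes, **kwargs)
        Hs.append(prof.H)
        Ks.append(prof.K)
        rows.append({f"m_{k.replace('/', '')}": v for k, v in prof.boundaries.items()})
    Hs = np.asarray(Hs)
    Ks = np.asarray(Ks)
    return {
        "x": (np.arange(n_nodes) + 0.5) * DOMAIN_LENGTH_1D / n_nodes,
        "H_mean": Hs.mean(axis=0),
        "H_sd": Hs.std(axis=0, ddof=1),
        "K_mean": Ks.mean(axis=0),
        "K_sd": Ks.std(axis=0, ddof=1),
        "boundaries": pd.DataFrame(rows),
    }


@dataclass(frozen=True)
class IdentityMixture:
    """Position-conditional Gaussian mixture over the five identities.

    Component c (segment r2..r6) has weight proportional to
    ``exp(-(x - mean_c)^2 / (2 spread_c^2))`` at A-P position x; the
    normalised weights sum to 1 everywhere.
    """

    means: np.ndarray  # (5,) micron
    spreads: np.ndarray  # (5,) micron

    SEGMENTS = ("r2", "r3", "r4", "r5", "r6")
    IDENTITY_OF = {"r2": "none", "r3": "krox20", "r4": "hoxb1a",
                   "r5": "krox20", "r6": "none"}

    def weights(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(self.spreads <= 0):  # degenerate: nearest component wins
            d = np.abs(x[:, None] - self.means[None, :])
            w = np.zeros((x.size, 5))
            w[np.arange(x.size), np.argmin(d, axis=1)] = 1.0
            return w
        logw = -0.5 * ((x[:, None] - self.means[None, :]) / self.spreads[None, :]) ** 2
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        return w / w.sum(axis=1, keepdims=True)


def default_identity_mixture(state) -> IdentityMixture:
    """Five components at the expected segment centres of the tissue
    domain, spread = half the expected segment length."""
    lo, hi = state.tissue_x_min, state.tissue_x_max
    seg = (hi - lo) / 5.0
    means = lo + (np.arange(5) + 0.5) * seg
    spreads = np.full(5, seg / 2.0)
    return IdentityMixture(means=means, spreads=spreads)


def sample_identities_gmm(
    positions, mixture: IdentityMixture, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a segment label and identity for each cell position.

    Returns ``(segments, identities)`` where identities are the
    hoxb1a/krox20/none strings used by the metrics.
    """
    x = np.atleast_1d(np.asarray(positions, dtype=float))
    w = mixture.weights(x)
    cum = np.cumsum(w, axis=1)
    u = rng.random(x.size)
    comp = (u[:, None] > cum).sum(axis=1)
    segments = np.asarray(mixture.SEGMENTS, dtype=object)[comp].astype(str)
    identities = np.asarray(
        [mixture.IDENTITY_OF[s] for s in segments], dtype=object
    ).astype(str)
    return segments, identities


def run_sorting_only(
    schedule: str = "rapid",
    seed: int = 0,
    config: SimulationConfig | None = None,
    dt: float | None = None,
    snapshot_every: float = 0.1,
    k_on_level: float = 2.0,
) -> SimulationResult:
    """Mechanics-only simulation with frozen, GMM-sampled identities.

    Cells carry pre-assigned identities (no gene dynamics, no
    morphogens); krox20 cells get a fixed high level ``k_on_level``
    feeding the similarity function, all others zero.  Identity counts
    are exactly conserved; metrics are computed on the frozen labels.
    """
    config = config or SimulationConfig()
    config = replace(config, schedule=schedule, seed=seed)
    rng = np.random.default_rng(seed)
    geom = Geometry.default(
        schedule=schedule, r1=config.r1, r2=config.r2,
        reflection=config.slow_reflection,
    )
    state0 = geom.state(config.t_start)
    cells = init_lattice(state0, config.mech, config.n_rows, config.n_cols)
    mixture = default_identity_mixture(state0)
    _, identities = sample_identities_gmm(cells.centroids[:, 0], mixture, rng)
    k_levels = np.where(identities == "krox20", k_on_level, 0.0)

    dt = dt or config.mech_interval
    n_steps = int(round((config.t_end - config.t_start) / dt))
    snap_every = max(int(round(snapshot_every / dt)), 1)

    times, reports, cen_hist = [], [], []

    def snapshot(t):
        cen = cells.centroids
        rep = quantify_pattern(cen[:, 0], identities, geom.state(t), config.mech.R_out)
        times.append(t)
        reports.append(rep)
        cen_hist.append(cen.copy())

    snapshot(config.t_start)
    for step in range(n_steps):
        t = config.t_start + step * dt
        state = geom.state(min(t, config.t_end))
        step_mechanics(cells, state, dt, k_levels,
                       threshold=config.genes.classify_threshold)
        if (step + 1) % snap_every == 0 or step == n_steps - 1:
            snapshot(min(config.t_start + (step + 1) * dt, config.t_end))

    metrics = pd.DataFrame([_metrics_row(t, r) for t, r in zip(times, reports)])
    ident_hist = np.tile(identities, (len(times), 1))
    return SimulationResult(
        config=config,
        times=np.asarray(times),
        metrics=metrics,
        identity_history=ident_hist,
        centroid_history=np.asarray(cen_hist),
        gene_states=np.zeros((cells.n_cells, 4)),
        cells=cells,
        grid=None,
        reports=reports,
    )
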