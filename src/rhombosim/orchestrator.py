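"""Coupled multiscale simulation and the experiment runners.

One macro time step advances, in order: domain geometry, morphogen
fields (Euler-Maruyama on the co-deforming grid), per-cell gene states
(driven by the fields interpolated at cell centroids), and cell
mechanics.  Gene regulation can be restricted to a time window (states
frozen outside), selective sorting to another (similarity pinned to the
neutral 0.5 outside), and convergent extension or intracellular
advection disabled entirely.

The runners reproduce the study designs: a baseline run, independent
stochastic ensembles, the convergence-schedule comparison and the
random-parameter robustness sweep with its equal-length fraction curve.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .gene_network import GeneParams, classify_cells, step_genes
from .geometry import ConvergenceSchedule, DomainState, Geometry
from .mechanics import CellCollection, init_lattice, step_mechanics
from .metrics import BOUNDARY_NAMES, PatternReport, quantify_pattern
from .morphogens import (
    MorphogenGrid,
    interpolate_grid_to_points,
    interpolate_points_to_grid,
    solve_ra_steady_state,
    stable_dt,
    step_morphogens,
)

__all__ = [
    "SimulationResult",
    "EnsembleSummary",
    "run_burn_in",
    "run_full_model",
    "run_ensemble",
    "random_parameter_sweep",
    "cell_commitment_times",
    "equal_length_fraction",
    "EXPERIMENTAL_LENGTHS",
]

logger = logging.getLogger(__name__)

#: Measured mean A-P lengths (micron) of r3, r4, r5 at 14 hpf.
EXPERIMENTAL_LENGTHS = {"r3": 42.0, "r4": 34.0, "r5": 37.0}


def _frozen_geometry(geometry: Geometry, t0: float) -> Geometry:
    """Geometry pinned at its ``t0`` shape (no convergent extension)."""
    st = geometry.state(t0)

    def const_w(t, w=st.L2):
        return np.broadcast_to(w, np.shape(np.asarray(t, dtype=float))).copy() \
            if np.ndim(t) else w

    def zero(t):
        return np.zeros(np.shape(np.asarray(t, dtype=float))) if np.ndim(t) else 0.0

    curves = dataclasses.replace(
        geometry.curves,
        L1=lambda t, v=st.L1: np.full_like(np.asarray(t, dtype=float), v)
        if np.ndim(t)
        else v,
        p=lambda t, v=st.p: np.full_like(np.asarray(t, dtype=float), v)
        if np.ndim(t)
        else v,
        dL1dt=zero,
        dpdt=zero,
    )
    sched = ConvergenceSchedule(geometry.schedule.kind, const_w, zero)
    return Geometry(curves, sched, geometry.r1, geometry.r2)


def _geometry_for(config: SimulationConfig) -> Geometry:
    geom = Geometry.default(
        schedule=config.schedule,
        r1=config.r1,
        r2=config.r2,
        reflection=config.slow_reflection,
    )
    if config.disable_convergent_extension:
        geom = _frozen_geometry(geom, config.t_start)
    return geom


@dataclass
class SimulationResult:
    """Trajectory-level output of one run."""

    config: SimulationConfig
    times: np.ndarray  # snapshot times (hpf)
    metrics: pd.DataFrame  # per-snapshot SI/DC/length time series
    identity_history: np.ndarray  # (n_snapshots, n_cells) strings
    centroid_history: np.ndarray  # (n_snapshots, n_cells, 2)
    gene_states: np.ndarray  # final (n_cells, 4)
    cells: CellCollection  # final node positions
    grid: MorphogenGrid  # final morphogen fields
    reports: list  # per-snapshot PatternReport
    wall_time_s: float = 0.0

    @property
    def final_report(self) -> PatternReport:
        return self.reports[-1]

    def cell_table(self, snapshot: int = -1) -> pd.DataFrame:
        """Tidy per-cell table at one snapshot."""
        i = range(len(self.times))[snapshot]
        cen = self.centroid_history[i]
        ident = self.identity_history[i]
        return pd.DataFrame(
            {
                "time_hpf": self.times[i],
                "cell_id": np.arange(cen.shape[0]),
                "centroid_x_um": cen[:, 0],
                "centroid_y_um": cen[:, 1],
                "identity": ident,
            }
        )


def _metrics_row(t: float, report: PatternReport) -> dict:
    row = {"time_hpf": t}
    for name in BOUNDARY_NAMES:
        b = report.boundaries[name]
        key = name.replace("/", "")
        row[f"SI_{key}"] = np.nan if b is None else b.SI
        row[f"m_{key}"] = np.nan if b is None else b.m
    row["DC"] = report.DC_total
    for seg in ("r3", "r4", "r5"):
        row[f"len_{seg}"] = report.lengths[seg]
    row["failed"] = report.failed
    return row


def run_burn_in(
    geometry: Geometry,
    centroids: np.ndarray,
    gene_params: GeneParams,
    ra_params,
    fgf_params,
    rng: np.random.Generator,
    grid_shape=(128, 32),
    stage1_hours: float = 1.0,
    stage2_hours: float = 1.0,
    dt: float | None = None,
    noise_mode: str = "additive",
    t0: float = 11.0,
):
    """Two-stage pre-pattern burn-in on geometry frozen at ``t0``.

    Stage 1: RA at its deterministic equilibrium, then stochastic
    RA/vhnf1/irx3 dynamics from V = I = 0 (hoxb1a, krox20 and FGF held
    at zero).  Stage 2: hoxb1a reset to the uniform ``initial_H``,
    krox20 and FGF from zero, all species stochastic.  Returns
    ``(gene_states, grid)``.
    """
    frozen = _frozen_geometry(geometry, t0)
    state = frozen.state(t0)
    nx, ny = grid_shape
    grid = solve_ra_steady_state((nx, ny), state, ra_params)
    n_cells = centroids.shape[0]
    states = np.zeros((n_cells, 4))

    if dt is None:
        dt = stable_dt(frozen, ra_params, fgf_params, grid_shape)

    multiplicative = noise_mode == "multiplicative"

    def signals():
        ra = interpolate_grid_to_points(grid.RAin, centroids, state, warn=False)
        fs = interpolate_grid_to_points(grid.FGFsignal, centroids, state, warn=False)
        return ra, fs

    n1 = int(round(stage1_hours / dt))
    for _ in range(n1):
        step_morphogens(
            grid, state, dt, rng, ra_params, fgf_params,
            h_field=None, multiplicative_noise=multiplicative, check_cfl=False,
        )
        grid.FGFfree.fill(0.0)
        grid.FGFsignal.fill(0.0)
        ra, fs = signals()
        states = step_genes(states, ra, fs, dt, rng, gene_params, noise_mode)
        states[:, 0] = 0.0  # hoxb1a and krox20 join in stage 2
        states[:, 1] = 0.0

    states[:, 0] = gene_params.initial_H
    n2 = int(round(stage2_hours / dt))
    h_field = None
    for step in range(n2):
        if step % 10 == 0:
            h_field = interpolate_points_to_grid(centroids, states[:, 0], grid, state)
        step_morphogens(
            grid, state, dt, rng, ra_params, fgf_params,
            h_field=h_field, multiplicative_noise=multiplicative, check_cfl=False,
        )
        ra, fs = signals()
        states = step_genes(states, ra, fs, dt, rng, gene_params, noise_mode)
    return states, grid


def run_full_model(config: SimulationConfig) -> SimulationResult:
    """Run the coupled model from ``t_start`` to ``t_end``.

    Fully reproducible from (config, seed); pattern failure is reported
    in the metrics, not raised.
    """
    wall0 = _time.perf_counter()
    rng = np.random.default_rng(config.seed)
    geom = _geometry_for(config)
    grid_shape = (config.grid_nx, config.grid_ny)
    state0 = geom.state(config.t_start)
    cells = init_lattice(state0, config.mech, config.n_rows, config.n_cols)

    states, grid = run_burn_in(
        geom,
        cells.centroids,
        config.genes,
        config.ra,
        config.fgf,
        rng,
        grid_shape=grid_shape,
        stage1_hours=config.burn_in_stage1,
        stage2_hours=config.burn_in_stage2,
        noise_mode="multiplicative" if config.multiplicative_noise else "additive",
        t0=config.t_start,
    )

    dt = config.dt or stable_dt(geom, config.ra, config.fgf, grid_shape)
    n_steps = int(round((config.t_end - config.t_start) / dt))
    # evaluate the slowly varying inter-cell forces roughly every
    # mech_interval of simulated time, independent of the diffusion dt
    mech_every = max(int(round(config.mech_interval / dt)), 1)
    noise_mode = "multiplicative" if config.multiplicative_noise else "additive"
    advect = not config.disable_intracellular_advection
    thr = config.genes.classify_threshold

    times, reports, ident_hist, cen_hist = [], [], [], []
    h_field = None

    def snapshot(t):
        cen = cells.centroids
        ident = classify_cells(states[:, 0], states[:, 1], thr)
        rep = quantify_pattern(cen[:, 0], ident, geom.state(t), config.mech.R_out)
        times.append(t)
        reports.append(rep)
        ident_hist.append(ident)
        cen_hist.append(cen.copy())

    snap_every = max(int(round(config.snapshot_every / dt)), 1)
    snapshot(config.t_start)
    for step in range(n_steps):
        t = config.t_start + step * dt
        state = geom.state(min(t, config.t_end))
        if step % config.h_field_every == 0:
            h_field = interpolate_points_to_grid(
                cells.centroids, states[:, 0], grid, state
            )
        step_morphogens(
            grid, state, dt, rng, config.ra, config.fgf,
            h_field=h_field,
            advect_intracellular=advect,
            multiplicative_noise=config.multiplicative_noise,
            check_cfl=False,
        )
        if config.gene_window[0] <= t < config.gene_window[1]:
            cen = cells.centroids
            ra = interpolate_grid_to_points(grid.RAin, cen, state, warn=False)
            fs = interpolate_grid_to_points(grid.FGFsignal, cen, state, warn=False)
            states = step_genes(states, ra, fs, dt, rng, config.genes, noise_mode)
        if step % mech_every == 0:
            neutral = not (
                config.sorting_window[0] <= t <= config.sorting_window[1]
            )
            step_mechanics(
                cells,
                state,
                dt * mech_every,
                states[:, 1],
                threshold=thr,
                neutral_similarity=neutral,
                disable_ce=config.disable_convergent_extension,
                intra_dt=config.mech.dt_mech / 2.0,
            )
        if (step + 1) % snap_every == 0 or step == n_steps - 1:
            snapshot(min(config.t_start + (step + 1) * dt, config.t_end))

    metrics = pd.DataFrame([_metrics_row(t, r) for t, r in zip(times, reports)])
    return SimulationResult(
        config=config,
        times=np.asarray(times),
        metrics=metrics,
        identity_history=np.asarray(ident_hist),
        centroid_history=np.asarray(cen_hist),
        gene_states=states,
        cells=cells,
        grid=grid,
        reports=reports,
        wall_time_s=_time.perf_counter() - wall0,
    )


@dataclass
class EnsembleSummary:
    """Statistics over independent stochastic repeats."""

    results: list  # per-run SimulationResult (or final metrics only)
    final: pd.DataFrame  # one row per run: final SI/DC/lengths/success
    mean: pd.Series
    sd: pd.Series  # NaN if n = 1

    @property
    def n(self) -> int:
        return len(self.final)

    @property
    def success_fraction(self) -> float:
        return float(self.final["success"].mean())


def _final_row(res: SimulationResult) -> dict:
    rep = res.final_report
    row = {}
    for name in BOUNDARY_NAMES:
        b = rep.boundaries[name]
        key = name.replace("/", "")
        row[f"SI_{key}"] = np.nan if b is None else b.SI
        row[f"m_{key}"] = np.nan if b is None else b.m
    row["DC"] = rep.DC_total
    for seg in ("r3", "r4", "r5"):
        row[f"len_{seg}"] = rep.lengths[seg]
    boundaries_ok = all(rep.boundaries[n] is not None for n in BOUNDARY_NAMES)
    lengths_ok = all(np.isfinite(rep.lengths[s]) for s in ("r3", "r4", "r5"))
    row["failed"] = rep.failed
    row["success"] = boundaries_ok and lengths_ok and not rep.failed
    row["seed"] = res.config.seed
    return row


def run_ensemble(
    config: SimulationConfig,
    n: int,
    seeds=None,
    keep_results: bool = True,
    runner=run_full_model,
) -> EnsembleSummary:
    """``n`` independent runs differing only in seed.

    Seeds default to ``config.seed, config.seed + 1, ...``.  Individual
    run failures (numerical aborts) are recorded, not fatal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n)]
    results, rows = [], []
    for s in seeds:
        cfg = config.with_seed(s)
        try:
            res = runner(cfg)
        except (ValueError, FloatingPointError) as exc:  # instability: record
            logger.warning("run with seed %s aborted: %s", s, exc)
            rows.append({"seed": s, "success": False, "failed": True})
            continue
        rows.append(_final_row(res))
        if keep_results:
            results.append(res)
    final = pd.DataFrame(rows)
    num = final.select_dtypes(include=[np.number, bool])
    mean = num.mean(numeric_only=True)
    sd = num.std(numeric_only=True, ddof=1) if len(final) > 1 else num.mean() * np.nan
    return EnsembleSummary(results=results, final=final, mean=mean, sd=sd)


#: GeneParams fields perturbed by the random-parameter sweep (rate
#: constants only; noise amplitudes, threshold and initial level fixed).
SWEEP_FIELDS = (
    "vh", "ahh", "arh", "bkh", "bvh", "dh",
    "vk", "akk", "afk", "bhk", "dk",
    "vv", "arv", "biv", "dv",
    "vi", "bvi", "di",
)


def perturb_gene_params(
    params: GeneParams, rng: np.random.Generator, rel_range: float = 0.1
) -> GeneParams:
    """Independent multiplicative U[1-r, 1+r] perturbation of each rate."""
    factors = rng.uniform(1.0 - rel_range, 1.0 + rel_range, size=len(SWEEP_FIELDS))
    return replace(
        params, **{f: getattr(params, f) * c for f, c in zip(SWEEP_FIELDS, factors)}
    )


def equal_length_fraction(final: pd.DataFrame, d_grid) -> pd.DataFrame:
    """Fraction of runs with all three lengths within +-d% of the
    measured means (42, 34, 37 micron), as a function of d."""
    rows = []
    n = len(final)
    for d in np.atleast_1d(d_grid):
        ok = final["success"].to_numpy(dtype=bool).copy()
        for seg, m in EXPERIMENTAL_LENGTHS.items():
            ln = final[f"len_{seg}"].to_numpy() if f"len_{seg}" in final else np.nan
            ok &= np.abs(ln - m) <= m * d / 100.0
        rows.append({"d_percent": float(d), "fraction": float(np.sum(ok)) / n})
    return pd.DataFrame(rows)


def random_parameter_sweep(
    config: SimulationConfig,
    n: int,
    rel_range: float = 0.1,
    d_grid=(0, 5, 10, 15, 20, 30, 50, 100),
    runner=run_full_model,
) -> dict:
    """Robustness sweep with randomly perturbed gene-regulation rates.

    Each of the ``n`` runs draws independent multiplicative
    perturbations of the gene-network rate constants and an independent
    dynamics seed.  Returns the per-run final table, the success count
    and the equal-length fraction curve f(d).
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n)
    rows = []
    for i, child in enumerate(children):
        pr = np.random.default_rng(child)
        run_seed = int(pr.integers(0, 2**31 - 1))
        genes = perturb_gene_params(config.genes, pr, rel_range)
        cfg = replace(config, genes=genes, seed=run_seed)
        try:
            res = runner(cfg)
            rows.append(_final_row(res))
        except (ValueError, FloatingPointError) as exc:
            logger.warning("sweep run %d aborted: %s", i, exc)
            rows.append({"seed": run_seed, "success": False, "failed": True})
    final = pd.DataFrame(rows)
    return {
        "final": final,
        "n_success": int(final["success"].sum()),
        "f_curve": equal_length_fraction(final, d_grid),
    }


def cell_commitment_times(result: SimulationResult) -> pd.DataFrame:
    """Committed-cell fraction over time, per final rhombomere.

    A cell is committed at the first snapshot after which its identity
    never changes.  Cells are grouped into r2-r6 by their final centroid
    position relative to the final boundary locations.
    """
    ident = result.identity_history  # (n_t, n_cells)
    n_t, n_cells = ident.shape
    changed_after = np.zeros(n_cells, dtype=int)
    for k in range(1, n_t):
        switched = ident[k] != ident[k - 1]
        changed_after[switched] = k
    commit_time = result.times[changed_after]

    rep = result.final_report
    pos = rep.boundary_positions()
    edges = [
        -np.inf,
        pos["r2/r3"],
        pos["r3/r4"],
        pos["r4/r5"],
        pos["r5/r6"],
        np.inf,
    ]
    segs = ("r2", "r3", "r4", "r5", "r6")
    x = result.centroid_history[-1][:, 0]
    rows = []
    for t in result.times:
        row = {"time_hpf": t}
        for s, lo, hi in zip(segs, edges[:-1], edges[1:]):
            sel = (x >= lo) & (x < hi)
            row[s] = float(np.mean(commit_time[sel] <= t)) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
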