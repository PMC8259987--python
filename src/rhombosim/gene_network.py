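"""Per-cell stochastic gene regulation.

Each cell carries four expression levels driven by the interpolated
morphogen signals at its centroid:

* ``H`` (*hoxb1a*): activated by intracellular RA and by itself,
  repressed by *krox20* and *vhnf1*.  Marks r4.
* ``K`` (*krox20*): activated by FGF signalling and by itself,
  repressed by *hoxb1a*.  Marks r3 and r5.
* ``V`` (*vhnf1*): activated by RA, repressed by *irx3*; no
  self-activation, so it decays wherever RA is withdrawn.  High in
  r5-r6.
* ``I`` (*irx3*): constitutively produced, repressed by *vhnf1*.
  High anterior of the *vhnf1* border.

The shared Hill coefficient is 2.  ``H`` and ``K`` each combine
self-activation with a morphogen input inside a single saturating
competitive Hill term, which makes both subsystems bistable: cells
latch into mutually exclusive hoxb1a-high / krox20-high / neither
states, the three identities used for pattern quantification.

Dynamics are Euler-Maruyama with additive white noise by default
(multiplicative as an option); levels are clipped at zero after every
step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GeneParams",
    "gene_rhs",
    "step_genes",
    "classify_cell",
    "classify_cells",
    "initialize_pre_pattern",
]


@dataclass(frozen=True)
class GeneParams:
    """Rate constants of the four-gene network (a.u. and 1/h).

    Naming: ``v*`` maximal production rates, ``a**`` activation gains,
    ``b**`` repression gains (first letter = regulator, second = target),
    ``d*`` linear degradation rates, ``mu_*`` noise amplitudes.
    Defaults are calibrated so the baseline simulation reproduces the
    five-segment r2-r6 pattern; on-states sit near 2 a.u., well above
    the classification threshold.
    """

    # hoxb1a
    vh: float = 20.0
    ahh: float = 0.12
    arh: float = 26.0
    bkh: float = 2.0
    bvh: float = 25.0
    dh: float = 4.0
    # krox20
    vk: float = 16.0
    akk: float = 0.28
    afk: float = 0.55
    bhk: float = 4.0
    dk: float = 4.0
    # vhnf1
    vv: float = 6.0
    arv: float = 5.0
    biv: float = 8.0
    dv: float = 2.0
    # irx3
    vi: float = 2.0
    bvi: float = 8.0
    di: float = 2.0
    # noise amplitudes (a.u. / sqrt(h))
    mu_h: float = 0.05
    mu_k: float = 0.08
    mu_v: float = 0.06
    mu_i: float = 0.06
    # identity classification threshold (a.u.)
    classify_threshold: float = 1.2
    # uniform pre-pattern hoxb1a level (a.u.)
    initial_H: float = 0.21

    def with_noise_scaled(self, factor: float) -> "GeneParams":
        return replace(
            self,
            mu_h=self.mu_h * factor,
            mu_k=self.mu_k * factor,
            mu_v=self.mu_v * factor,
            mu_i=self.mu_i * factor,
        )


def gene_rhs(states: np.ndarray, ra_in, k_signal, params: GeneParams) -> np.ndarray:
    """Deterministic drift of the four-gene network.

    Parameters
    ----------
    states
        Array of shape (..., 4) holding (H, K, V, I).
    ra_in
        Intracellular RA level at each cell (a.u.).
    k_signal
        The *krox20*-activating signal at each cell: FGF signalling in
        the two-morphogen model, intracellular RA in the one-morphogen
        reduction.
    """
    s = np.asarray(states, dtype=float)
    H, K, V, I = s[..., 0], s[..., 1], s[..., 2], s[..., 3]
    R2 = np.square(np.asarray(ra_in, dtype=float))
    F2 = np.square(np.asarray(k_signal, dtype=float))
    p = params

    act_h = p.ahh * H**2 + p.arh * R2
    dH = p.vh * act_h / (1.0 + act_h + p.bkh * K**2 + p.bvh * V**2) - p.dh * H

    act_k = p.akk * K**2 + p.afk * F2
    dK = p.vk * act_k / (1.0 + act_k + p.bhk * H**2) - p.dk * K

    act_v = p.arv * R2
    dV = p.vv * act_v / (1.0 + act_v + p.biv * I**2) - p.dv * V

    dI = p.vi / (1.0 + p.bvi * V**2) - p.di * I

    return np.stack([dH, dK, dV, dI], axis=-1)


def step_genes(
    states: np.ndarray,
    ra_in,
    k_signal,
    dt: float,
    rng: np.random.Generator,
    params: GeneParams,
    noise_mode: str = "additive",
) -> np.ndarray:
    """One Euler-Maruyama step for every cell; returns the new states.

    ``noise_mode`` is ``"additive"`` (constant amplitude) or
    ``"multiplicative"`` (amplitude proportional to the current level).
    Negative excursions are clipped to zero.
    """
    s = np.asarray(states, dtype=float)
    drift = gene_rhs(s, ra_in, k_signal, params)
    mu = np.array([params.mu_h, params.mu_k, params.mu_v, params.mu_i])
    amp = mu * np.sqrt(dt)
    if noise_mode == "multiplicative":
        noise = amp * s * rng.standard_normal(s.shape)
    elif noise_mode == "additive":
        noise = amp * rng.standard_normal(s.shape)
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    out = s + dt * drift + noise
    np.maximum(out, 0.0, out=out)
    return out


def classify_cell(H: float, K: float, threshold: float = 1.2) -> str:
    """Identity of a single cell from its hoxb1a/krox20 levels."""
    return str(classify_cells(np.atleast_1d(H), np.atleast_1d(K), threshold)[0])


def classify_cells(H, K, threshold: float = 1.2) -> np.ndarray:
    """Vectorised identity classification.

    ``hoxb1a`` if H is above threshold and K below, ``krox20`` for the
    converse; if both exceed the threshold the larger wins (tie goes to
    krox20; transient co-expression is rare and low).  Otherwise
    ``none``.
    """
    H = np.asarray(H, dtype=float)
    K = np.asarray(K, dtype=float)
    h_on = H >= threshold
    k_on = K >= threshold
    out = np.full(H.shape, "none", dtype=object)
    out[h_on & ~k_on] = "hoxb1a"
    out[k_on & ~h_on] = "krox20"
    both = h_on & k_on
    out[both & (H > K)] = "hoxb1a"
    out[both & (K >= H)] = "krox20"
    return out.astype(str)


def initialize_pre_pattern(
    geometry,
    centroids: np.ndarray,
    params: GeneParams,
    ra_params,
    fgf_params,
    rng: np.random.Generator,
    grid_shape: tuple[int, int] = (128, 32),
    stage1_hours: float = 1.0,
    stage2_hours: float = 1.0,
    dt: float | None = None,
    noise_mode: str = "additive",
):
    """Two-stage burn-in producing the 11 hpf initial condition.

    Geometry is frozen at its 11 hpf shape (no convergent extension
    before the simulated window).  Stage 1 starts from the equilibrium
    RA fields and runs the stochastic RA / *vhnf1* / *irx3* dynamics for
    ``stage1_hours`` from V = I = 0, establishing the posterior-high
    *vhnf1* / anterior-high *irx3* pre-border.  Stage 2 adds *hoxb1a*
    (at the constant ``params.initial_H``), *krox20* and FGF (both from
    zero) and runs all species for ``stage2_hours``.

    Returns ``(gene_states, morphogen_grid)`` at 11 hpf.
    """
    from .orchestrator import run_burn_in  # deferred: avoids an import cycle

    return run_burn_in(
        geometry,
        centroids,
        params,
        ra_params,
        fgf_params,
        rng,
        grid_shape=grid_shape,
        stage1_hours=stage1_hours,
        stage2_hours=stage2_hours,
        dt=dt,
        noise_mode=noise_mode,
    )
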