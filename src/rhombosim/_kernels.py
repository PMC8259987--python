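"""Numba inner loops for the hot paths.

Everything here is deliberately free of Python objects: plain arrays in,
plain arrays out, so the JIT can cache compiled code across runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["deposit_shepard", "inter_ext_forces", "apply_intra_forces", "morphogen_step"]


@njit(cache=True)
def deposit_shepard(points, values, gx, gy, rx, ry):
    """Normalised elliptical-tent (Shepard) deposition onto a uniform grid.

    points : (n, 2) physical positions; values : (n,) sample values;
    gx : (nx,) grid x-coordinates (uniform); gy : (ny,) grid
    y-coordinates (uniform).  Nodes with no point inside the kernel
    support stay at zero.
    """
    nx = gx.shape[0]
    ny = gy.shape[0]
    num = np.zeros((nx, ny))
    den = np.zeros((nx, ny))
    dx = gx[1] - gx[0] if nx > 1 else 1.0
    dy = gy[1] - gy[0] if ny > 1 else 1.0
    for c in range(points.shape[0]):
        px = points[c, 0]
        py = points[c, 1]
        i_lo = max(int(np.ceil((px - rx - gx[0]) / dx)), 0)
        i_hi = min(int(np.floor((px + rx - gx[0]) / dx)), nx - 1)
        j_lo = max(int(np.ceil((py - ry - gy[0]) / dy)), 0)
        j_hi = min(int(np.floor((py + ry - gy[0]) / dy)), ny - 1)
        for i in range(i_lo, i_hi + 1):
            ux = (gx[i] - px) / rx
            for j in range(j_lo, j_hi + 1):
                uy = (gy[j] - py) / ry
                w = 1.0 - np.sqrt(ux * ux + uy * uy)
                if w > 0.0:
                    num[i, j] += w * values[c]
                    den[i, j] += w
    out = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            if den[i, j] > 0.0:
                out[i, j] = num[i, j] / den[i, j]
    return out


@njit(cache=True)
def apply_intra_forces(nodes, pair_i, pair_j, rest, k_intra, vel):
    """Linear springs between intra-cell node pairs; accumulates into vel."""
    for m in range(pair_i.shape[0]):
        i = pair_i[m]
        j = pair_j[m]
        dx = nodes[i, 0] - nodes[j, 0]
        dy = nodes[i, 1] - nodes[j, 1]
        d = np.sqrt(dx * dx + dy * dy)
        if d < 1e-12:
            continue
        f = -k_intra * (d - rest[m]) / d
        fx = f * dx
        fy = f * dy
        vel[i, 0] += fx
        vel[i, 1] += fy
        vel[j, 0] -= fx
        vel[j, 1] -= fy


@njit(cache=True)
def inter_ext_forces(
    nodes,
    cell_of_node,
    sigma,
    rep_tab,
    att_tab,
    core_tab,
    inv_dr,
    cutoff,
    neutral_similarity,
    a1,
    a2,
    n_per_cell,
    r_core,
):
    """Per-node velocities: convergent extension + intercell terms.

    Intra-cell shape springs are integrated separately (they are the
    stiff part and need smaller substeps than these slowly varying
    terms).  ``rep_tab``/``att_tab``/``core_tab`` tabulate the radial
    force magnitudes on a uniform grid of spacing ``1/inv_dr`` over
    [0, cutoff] (linear interpolation; avoids two exponentials per node
    pair in the hot loop).

    sigma : per-cell krox20-state sigmoid in [0, 1] driving the
    similarity weight F = s_i s_j + (1-s_i)(1-s_j) (1 both alike, 0
    dissimilar, 0.5 indeterminate).  With ``neutral_similarity`` True the
    weight is pinned at 0.5 (no selective sorting; only the short-range
    excluded-volume repulsion remains).  ``a1, a2`` are the growth-rate
    coefficients L1'/L1, L2'/L2 applied at cell centroids.
    Returns the (N, 2) velocity array.
    """
    n = nodes.shape[0]
    n_cells = sigma.shape[0]
    vel = np.zeros((n, 2))

    # --- convergent-extension velocity at each cell centroid ---
    cx = np.zeros(n_cells)
    cy = np.zeros(n_cells)
    for i in range(n):
        c = cell_of_node[i]
        cx[c] += nodes[i, 0]
        cy[c] += nodes[i, 1]
    for c in range(n_cells):
        cx[c] /= n_per_cell
        cy[c] /= n_per_cell
    for i in range(n):
        c = cell_of_node[i]
        vel[i, 0] += a1 * cx[c]
        vel[i, 1] += a2 * cy[c]

    # --- inter-cell pair forces via a uniform spatial hash ---
    xmin = nodes[0, 0]
    xmax = nodes[0, 0]
    ymin = nodes[0, 1]
    ymax = nodes[0, 1]
    for i in range(1, n):
        if nodes[i, 0] < xmin:
            xmin = nodes[i, 0]
        if nodes[i, 0] > xmax:
            xmax = nodes[i, 0]
        if nodes[i, 1] < ymin:
            ymin = nodes[i, 1]
        if nodes[i, 1] > ymax:
            ymax = nodes[i, 1]
    nbx = max(int((xmax - xmin) / cutoff) + 1, 1)
    nby = max(int((ymax - ymin) / cutoff) + 1, 1)
    head = np.full(nbx * nby, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        bx = int((nodes[i, 0] - xmin) / cutoff)
        by = int((nodes[i, 1] - ymin) / cutoff)
        if bx >= nbx:
            bx = nbx - 1
        if by >= nby:
            by = nby - 1
        b = bx * nby + by
        nxt[i] = head[b]
        head[b] = i

    cut2 = cutoff * cutoff
    for i in range(n):
        ci = cell_of_node[i]
        si = sigma[ci]
        bx = int((nodes[i, 0] - xmin) / cutoff)
        by = int((nodes[i, 1] - ymin) / cutoff)
        if bx >= nbx:
            bx = nbx - 1
        if by >= nby:
            by = nby - 1
        for ox in range(-1, 2):
            gx = bx + ox
            if gx < 0 or gx >= nbx:
                continue
            for oy in range(-1, 2):
                gy = by + oy
                if gy < 0 or gy >= nby:
                    continue
                j = head[gx * nby + gy]
                while j >= 0:
                    if j >= i:  # each unordered pair handled once
                        j = nxt[j]
                        continue
                    cj = cell_of_node[j]
                    dx = nodes[i, 0] - nodes[j, 0]
                    dy = nodes[i, 1] - nodes[j, 1]
                    d2 = dx * dx + dy * dy
                    if cj != ci:
                        if d2 < cut2 and d2 > 1e-24:
                            d = np.sqrt(d2)
                            if neutral_similarity:
                                F = 0.5
                            else:
                                sj = sigma[cj]
                                F = si * sj + (1.0 - si) * (1.0 - sj)
                            u = d * inv_dr
                            k = int(u)
                            w = u - k
                            rep = rep_tab[k] * (1.0 - w) + rep_tab[k + 1] * w
                            att = att_tab[k] * (1.0 - w) + att_tab[k + 1] * w
                            coef = (rep - (2.0 * F - 1.0) * att) / d
                            vel[i, 0] += coef * dx
                            vel[i, 1] += coef * dy
                            vel[j, 0] -= coef * dx
                            vel[j, 1] -= coef * dy
                    elif d2 < r_core * r_core and d2 > 1e-24:
                        # volume exclusion inside the cell: keeps the
                        # two-ring truss from folding through itself;
                        # vanishes at the rest configuration (all rest
                        # pair distances exceed r_core)
                        d = np.sqrt(d2)
                        u = d * inv_dr
                        k = int(u)
                        w = u - k
                        coef = (core_tab[k] * (1.0 - w) + core_tab[k + 1] * w) / d
                        vel[i, 0] += coef * dx
                        vel[i, 1] += coef * dy
                        vel[j, 0] -= coef * dx
                        vel[j, 1] -= coef * dy
                    j = nxt[j]
    return vel


@njit(cache=True)
def morphogen_step(
    ra_out,
    ra_in,
    f_free,
    f_sig,
    noise,
    A,
    dr_x,
    Af,
    dil,
    inv_dx2,
    inv_dy2,
    Dr,
    kr,
    beta_r,
    Df,
    kf,
    krf,
    df1,
    df2,
    dt,
    amp,
    mu_r1,
    mu_r2,
    mu_f1,
    mu_f2,
    a_xi_coef,
    a_eta_coef,
    nx_inv,
    ny_inv,
    advect_intracellular,
    multiplicative,
    absorbing_left,
):
    """Fused Euler-Maruyama update of all four morphogen fields.

    ``noise`` is (4, nx, ny) standard normals drawn by the caller (so
    the random stream stays owned by numpy); ``A`` and ``dr_x`` are the
    per-column RA production and degradation profiles, ``Af`` the FGF
    production field.  ``a_*_coef`` are L1'/L1 and L2'/L2 for the
    residual upwind transport used when intracellular advection is off.
    """
    nx, ny = ra_out.shape
    d_out = np.empty((nx, ny))
    d_free = np.empty((nx, ny))
    d_in = np.empty((nx, ny))
    d_sig = np.empty((nx, ny))
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            c = ra_out[i, j]
            left = ra_out[im, j] if i > 0 else (-c if absorbing_left else c)
            lap = (left - 2.0 * c + ra_out[ip, j]) * inv_dx2 + (
                ra_out[i, jm] - 2.0 * c + ra_out[i, jp]
            ) * inv_dy2
            d_out[i, j] = (
                Dr * lap
                + A[i]
                + kr * ra_in[i, j]
                - (1.0 + beta_r) * kr * c
                - dil * c
            )
            cf = f_free[i, j]
            lapf = (f_free[im, j] - 2.0 * cf + f_free[ip, j]) * inv_dx2 + (
                f_free[i, jm] - 2.0 * cf + f_free[i, jp]
            ) * inv_dy2
            d_free[i, j] = (
                Df * lapf
                + Af[i, j]
                + krf * f_sig[i, j]
                - (df1 + kf) * cf
                - dil * cf
            )
            di_ = kr * c - kr * ra_in[i, j] - dr_x[i] * ra_in[i, j]
            ds_ = kf * cf - (krf + df2) * f_sig[i, j]
            if advect_intracellular:
                di_ -= dil * ra_in[i, j]
                ds_ -= dil * f_sig[i, j]
            else:
                xi = (i + 0.5) * nx_inv
                eta = (j + 0.5) * ny_inv - 0.5
                a_xi = a_xi_coef * xi
                a_eta = a_eta_coef * eta
                # first-order upwind transport in computational coords
                if a_xi > 0.0:
                    di_ += a_xi * (ra_in[i, j] - ra_in[im, j]) / nx_inv
                    ds_ += a_xi * (f_sig[i, j] - f_sig[im, j]) / nx_inv
                else:
                    di_ += a_xi * (ra_in[ip, j] - ra_in[i, j]) / nx_inv
                    ds_ += a_xi * (f_sig[ip, j] - f_sig[i, j]) / nx_inv
                if a_eta > 0.0:
                    di_ += a_eta * (ra_in[i, j] - ra_in[i, jm]) / ny_inv
                    ds_ += a_eta * (f_sig[i, j] - f_sig[i, jm]) / ny_inv
                else:
                    di_ += a_eta * (ra_in[i, jp] - ra_in[i, j]) / ny_inv
                    ds_ += a_eta * (f_sig[i, jp] - f_sig[i, j]) / ny_inv
            d_in[i, j] = di_
            d_sig[i, j] = ds_
    for i in range(nx):
        for j in range(ny):
            if multiplicative:
                ra_out[i, j] += dt * d_out[i, j] + mu_r1 * amp * ra_out[i, j] * noise[0, i, j]
                ra_in[i, j] += dt * d_in[i, j] + mu_r2 * amp * ra_in[i, j] * noise[1, i, j]
                f_free[i, j] += dt * d_free[i, j] + mu_f1 * amp * f_free[i, j] * noise[2, i, j]
                f_sig[i, j] += dt * d_sig[i, j] + mu_f2 * amp * f_sig[i, j] * noise[3, i, j]
            else:
                ra_out[i, j] += dt * d_out[i, j] + mu_r1 * amp * noise[0, i, j]
                ra_in[i, j] += dt * d_in[i, j] + mu_r2 * amp * noise[1, i, j]
                f_free[i, j] += dt * d_free[i, j] + mu_f1 * amp * noise[2, i, j]
                f_sig[i, j] += dt * d_sig[i, j] + mu_f2 * amp * noise[3, i, j]
            if ra_out[i, j] < 0.0:
                ra_out[i, j] = 0.0
            if ra_in[i, j] < 0.0:
                ra_in[i, j] = 0.0
            if f_free[i, j] < 0.0:
                f_free[i, j] = 0.0
            if f_sig[i, j] < 0.0:
                f_sig[i, j] = 0.0
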