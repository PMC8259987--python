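"""Time-dependent hindbrain geometry.

The hindbrain plus the RA production region is modelled as a rectangle
(the *morphogen domain*) whose anterior-posterior (A-P) length ``L1(t)``
and left-right (L-R) width ``L2(t)`` follow smooth curves interpolated
through measured dimensions at 11-14 hpf.  The RA production region
occupies ``x1 > p(t)`` and the explicitly simulated *tissue domain*
(r2-r6) spans the fixed fractions ``[r1*L1, r2*L1]`` of the A-P axis.

Convergent extension is encoded purely in the time dependence of
``L1, L2``: a material point at ``x`` moves with the affine growth
velocity ``V(x) = (L1'/L1 * x1, L2'/L2 * x2)``, so fractional
(computational) coordinates are Lagrangian.

Three L-R convergence schedules are provided: *rapid* (the measured
curve, fast narrowing first), *medium* (linear in time) and *slow*
(the mirror image of rapid across the linear curve, i.e. slow narrowing
first).  All three share the measured endpoint widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DimensionTable",
    "DimensionCurves",
    "ConvergenceSchedule",
    "DomainState",
    "Geometry",
    "fit_dimension_curves",
    "make_schedule",
    "growth_velocity",
]

ScheduleKind = Literal["rapid", "medium", "slow"]

#: Measured L-R widths at the level of r4 (micron).  The 11/12/14 hpf
#: values are the published measurements; the 13 hpf entry and all A-P
#: lengths and RA-onset positions are fixture assumptions chosen to be
#: consistent with the published narrowing-rate drop (~75% between the
#: 11-12 and 12-14 hpf averages) and with a tissue domain spanning five
#: rhombomeres (~190 micron) at 14 hpf.
DEFAULT_DIMENSIONS = {
    "time_hpf": (11.0, 12.0, 13.0, 14.0),
    "L1_um": (250.0, 270.0, 285.0, 300.0),
    "L2_um": (283.0, 162.0, 120.0, 104.0),
    "p_um": (190.0, 205.0, 218.0, 230.0),
}

#: Default A-P fractions bounding the tissue domain (r2-r6).  With the
#: default dimension table these give a tissue span of 190 micron at
#: 14 hpf, i.e. about five rhombomeres of 34-42 micron each.
DEFAULT_R1 = 0.10
DEFAULT_R2 = 0.7333333333333333


@dataclass(frozen=True)
class DimensionTable:
    """Measured hindbrain dimensions over developmental time.

    Attributes
    ----------
    times : array of float
        Strictly increasing times (hpf) covering [11, 14].
    ap_length : array of float
        A-P extent of the morphogen domain, ``L1`` (micron).
    lr_width : array of float
        L-R width at the level of r4, ``L2`` (micron).
    ra_onset : array of float
        A-P position of the anterior edge of the RA production region,
        ``p`` (micron).
    """

    times: np.ndarray
    ap_length: np.ndarray
    lr_width: np.ndarray
    ra_onset: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        l1 = np.asarray(self.ap_length, dtype=float)
        l2 = np.asarray(self.lr_width, dtype=float)
        p = np.asarray(self.ra_onset, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ap_length", l1)
        object.__setattr__(self, "lr_width", l2)
        object.__setattr__(self, "ra_onset", p)
        if not (t.shape == l1.shape == l2.shape == p.shape):
            raise ValueError("dimension columns must have equal length")
        if t.size < 3:
            raise ValueError("cubic interpolation needs at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(p <= 0):
            raise ValueError("all lengths must be positive")
        if np.any(p > l1):
            raise ValueError("ra_onset must not exceed ap_length")
        if t[0] > 11.0 or t[-1] < 14.0:
            raise ValueError("times must cover [11, 14] hpf")

    @classmethod
    def default(cls) -> "DimensionTable":
        d = DEFAULT_DIMENSIONS
        return cls(d["time_hpf"], d["L1_um"], d["L2_um"], d["p_um"])

    @classmethod
    def from_csv(cls, path) -> "DimensionTable":
        df = pd.read_csv(path)
        return cls(
            df["time_hpf"].to_numpy(),
            df["L1_um"].to_numpy(),
            df["L2_um"].to_numpy(),
            df["p_um"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_hpf": self.times,
                "L1_um": self.ap_length,
                "L2_um": self.lr_width,
                "p_um": self.ra_onset,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class DimensionCurves:
    """Smooth interpolants ``L1(t), L2(t), p(t)`` with derivatives."""

    L1: Callable[[float], float]
    L2: Callable[[float], float]
    p: Callable[[float], float]
    dL1dt: Callable[[float], float]
    dL2dt: Callable[[float], float]
    dpdt: Callable[[float], float]
    t_min: float = 11.0
    t_max: float = 14.0


def fit_dimension_curves(table: DimensionTable) -> DimensionCurves:
    """Fit smooth monotone cubic (Hermite) curves through the table.

    The interpolants hit the measured values exactly at the knots and
    have continuous first derivatives.  A shape-preserving cubic is used
    so that the monotone trends of the data (non-increasing width,
    non-decreasing length) are preserved between knots.
    """
    t = table.times
    curves = {}
    for name, y in (
        ("L1", table.ap_length),
        ("L2", table.lr_width),
        ("p", table.ra_onset),
    ):
        f = PchipInterpolator(t, y)
        curves[name] = f
        curves["d" + name + "dt"] = f.derivative()
    return DimensionCurves(
        L1=curves["L1"],
        L2=curves["L2"],
        p=curves["p"],
        dL1dt=curves["dL1dt"],
        dL2dt=curves["dL2dt"],
        dpdt=curves["dpdt"],
        t_min=float(t[0]),
        t_max=float(t[-1]),
    )


@dataclass(frozen=True)
class ConvergenceSchedule:
    """One of the three L-R narrowing schedules.

    ``width_fn`` maps time (hpf) to L-R width (micron); ``dwidth_fn`` is
    its derivative.  All schedules agree at 11 and 14 hpf.
    """

    kind: str
    width_fn: Callable[[float], float]
    dwidth_fn: Callable[[float], float]


def _reflect_across_chord(
    width_fn: Callable, t0: float, t1: float, n: int = 2049
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror the graph of ``width_fn`` across its chord.

    Worked in chord-normalised coordinates (time and width both scaled
    to [0, 1]) the chord is the anti-diagonal and mirror reflection is
    the involution (tau, w) -> (1 - w, 1 - tau); for a strictly
    decreasing curve this is exactly the flipped inverse function, so
    the result is single-valued, strictly decreasing and shares both
    endpoints.
    """
    ts = np.linspace(t0, t1, n)
    w = np.asarray(width_fn(ts), dtype=float)
    w0, w1 = w[0], w[-1]
    tau = (ts - t0) / (t1 - t0)
    omega = (w - w1) / (w0 - w1)
    # reflected sample points (may be non-monotone in t if the source
    # curve is not strictly monotone; sort and de-duplicate)
    t_ref = t0 + (1.0 - omega) * (t1 - t0)
    w_ref = w1 + (1.0 - tau) * (w0 - w1)
    order = np.argsort(t_ref)
    t_ref, w_ref = t_ref[order], w_ref[order]
    keep = np.concatenate(([True], np.diff(t_ref) > 1e-12))
    t_ref, w_ref = t_ref[keep], w_ref[keep]
    # enforce monotone non-increase (no-op for strictly decreasing input)
    w_ref = np.minimum.accumulate(w_ref)
    return t_ref, w_ref


def make_schedule(
    kind: ScheduleKind,
    curves: DimensionCurves,
    reflection: Literal["geometric", "pointwise"] = "geometric",
) -> ConvergenceSchedule:
    """Build a convergence schedule from the measured (rapid) curve.

    Parameters
    ----------
    kind
        ``"rapid"`` returns the measured width curve itself; ``"medium"``
        the straight line between the endpoint widths; ``"slow"`` the
        reflection of the rapid graph across that straight line.
    reflection
        ``"geometric"`` (default) mirrors the graph across the chord in
        chord-normalised coordinates (an exact involution).
        ``"pointwise"`` uses ``2*linear(t) - rapid(t)``, which overshoots
        the initial width near 11 hpf and is kept only for comparison;
        it is clipped to the endpoint width and to monotone non-increase.
    """
    t0, t1 = curves.t_min, curves.t_max
    w0, w1 = float(curves.L2(t0)), float(curves.L2(t1))

    if kind == "rapid":
        return ConvergenceSchedule("rapid", curves.L2, curves.dL2dt)

    if kind == "medium":
        slope = (w1 - w0) / (t1 - t0)

        def width(t, w0=w0, t0=t0, slope=slope):
            return w0 + slope * (np.asarray(t, dtype=float) - t0)

        def dwidth(t, slope=slope):
            return np.broadcast_to(slope, np.shape(np.asarray(t, dtype=float))).copy() \
                if np.ndim(t) else slope

        return ConvergenceSchedule("medium", width, dwidth)

    if kind == "slow":
        if reflection == "geometric":
            t_ref, w_ref = _reflect_across_chord(curves.L2, t0, t1)
            f = PchipInterpolator(t_ref, w_ref)
        else:
            ts = np.linspace(t0, t1, 2049)
            lin = w0 + (w1 - w0) / (t1 - t0) * (ts - t0)
            w = 2.0 * lin - np.asarray(curves.L2(ts), dtype=float)
            w = np.minimum(w, w0)
            w = np.minimum.accumulate(w)
            w[-1] = w1
            f = PchipInterpolator(ts, w)
        return ConvergenceSchedule("slow", f, f.derivative())

    raise ValueError(f"unknown schedule kind: {kind!r}")


@dataclass(frozen=True)
class DomainState:
    """Geometry snapshot at a single time point.

    ``r1, r2`` are the dimensionless A-P fractions bounding the tissue
    domain; lengths in micron, rates in micron/h.
    """

    t: float
    L1: float
    L2: float
    p: float
    dL1dt: float
    dL2dt: float
    r1: float = DEFAULT_R1
    r2: float = DEFAULT_R2

    def __post_init__(self):
        if not (0.0 <= self.r1 < self.r2 <= 1.0):
            raise ValueError("need 0 <= r1 < r2 <= 1")
        if self.L2 <= 0:
            raise ValueError("L2 must be positive")
        if self.p > self.L1:
            raise ValueError("p must not exceed L1")

    @property
    def tissue_x_min(self) -> float:
        return self.r1 * self.L1

    @property
    def tissue_x_max(self) -> float:
        return self.r2 * self.L1

    @property
    def tissue_extent(self) -> float:
        """A-P extent of the tissue domain (micron)."""
        return (self.r2 - self.r1) * self.L1

    @property
    def dilution_rate(self) -> float:
        """Divergence of the growth velocity, ``L1'/L1 + L2'/L2`` (1/h)."""
        return self.dL1dt / self.L1 + self.dL2dt / self.L2


@dataclass(frozen=True)
class Geometry:
    """Bundle of dimension curves, schedule choice and tissue fractions."""

    curves: DimensionCurves
    schedule: ConvergenceSchedule
    r1: float = DEFAULT_R1
    r2: float = DEFAULT_R2

    @classmethod
    def default(
        cls,
        schedule: ScheduleKind = "rapid",
        table: DimensionTable | None = None,
        r1: float = DEFAULT_R1,
        r2: float = DEFAULT_R2,
        reflection: Literal["geometric", "pointwise"] = "geometric",
    ) -> "Geometry":
        curves = fit_dimension_curves(table or DimensionTable.default())
        return cls(curves, make_schedule(schedule, curves, reflection), r1, r2)

    def state(self, t: float) -> DomainState:
        """Domain geometry at time ``t`` (hpf)."""
        c = self.curves
        if t < c.t_min - 1e-9 or t > c.t_max + 1e-9:
            raise ValueError(f"t={t} outside [{c.t_min}, {c.t_max}] hpf")
        t = float(np.clip(t, c.t_min, c.t_max))
        return DomainState(
            t=t,
            L1=float(c.L1(t)),
            L2=float(self.schedule.width_fn(t)),
            p=float(c.p(t)),
            dL1dt=float(c.dL1dt(t)),
            dL2dt=float(self.schedule.dwidth_fn(t)),
            r1=self.r1,
            r2=self.r2,
        )


def domain_at(t: float, geometry: Geometry) -> DomainState:
    """Functional alias for :meth:`Geometry.state`."""
    return geometry.state(t)


def growth_velocity(x: np.ndarray, state: DomainState) -> np.ndarray:
    """Convergent-extension velocity at positions ``x`` (micron/h).

    ``x`` has shape (..., 2) with ``x[..., 0]`` the A-P and ``x[..., 1]``
    the L-R coordinate (L-R measured from the midline).  The velocity is
    linear in position, ``V = (L1'/L1 * x1, L2'/L2 * x2)``, and its
    divergence ``L1'/L1 + L2'/L2`` is spatially uniform.
    """
    x = np.asarray(x, dtype=float)
    v = np.empty_like(x)
    v[..., 0] = state.dL1dt / state.L1 * x[..., 0]
    v[..., 1] = state.dL2dt / state.L2 * x[..., 1]
    return v
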