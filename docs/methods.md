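# Methods

`rhombosim` simulates the formation and sharpening of rhombomere (r2–r6)
gene-expression boundaries in the zebrafish hindbrain between 11 and
14 hpf.  It couples four layers — tissue geometry, morphogen fields,
per-cell gene regulation, and cell mechanics — and quantifies the
resulting pattern with the boundary-location / sharpness-index /
dislocated-cell metrics used throughout the package.

## Domain geometry and convergent extension

The hindbrain plus the retinoic-acid (RA) production region is a
rectangle `[0, L1(t)] × [−L2/2, L2/2]`.  `L1(t)` (A-P length), `L2(t)`
(L-R width) and `p(t)` (anterior edge of the RA production region) are
monotone cubic Hermite interpolants through a measured-dimension table
at 11–14 hpf.  The widths 283/162/104 μm at 11/12/14 hpf are measured
values; the 13 hpf width (120 μm), the A-P lengths (250–300 μm) and the
RA-onset positions (190–230 μm) are documented fixture assumptions,
chosen so that (a) the mean L-R narrowing rate drops by ≈75 % between
the 11–12 and 12–14 hpf intervals and (b) the explicitly simulated
*tissue domain* — the fixed A-P fraction `[0.10 L1, 0.733 L1]` — spans
~190 μm at 14 hpf, i.e. five rhombomeres of 34–42 μm.

Convergent extension enters only through the affine growth velocity
`V(x) = (L1′/L1 · x1, L2′/L2 · x2)`.  Three L-R narrowing schedules
share the endpoint widths: *rapid* (the measured curve), *medium*
(linear in time) and *slow*.  Slow is the mirror image of rapid across
the linear curve, computed in chord-normalised coordinates where the
linear curve is the anti-diagonal and the reflection reduces to inverse
-function symmetry — an exact involution that is single-valued and
monotone without clipping.  A point-wise variant (`2·linear − rapid`,
clipped) is kept behind the `slow_reflection="pointwise"` switch for
comparison.

## Morphogen fields

Four continuum fields live on the deforming rectangle: extracellular
and intracellular RA, free FGF and FGF–receptor signalling.  RA is
produced posterior of `p(t)` (a Hill switch of exponent 20 in A-P
position), exchanged between the two forms, degraded fast inside the
production region (`kmax`, the cyp26a1 domain) and slowly elsewhere,
absorbed at the anterior boundary and reflected on the other sides.
FGF is produced in proportion to `vf·H²/(1 + ahf·H²)` of the local
hoxb1a level interpolated from cell centres and is reflected on all
four boundaries.

The moving domain is mapped to a fixed computational rectangle.
Because `V` is affine, computational coordinates are Lagrangian: the
convection term becomes the uniform dilution `−(L1′/L1 + L2′/L2)·C`
and the Laplacian carries metric factors `1/L1², 1/L2²`.  This makes
the L-R narrowing *concentrate* RA transiently (11–12 hpf under the
rapid schedule), the dynamical signal that drives early vhnf1 rise,
r4→r5 identity switching, and early commitment — the mechanism behind
all schedule comparisons.  With the intracellular-advection ablation
the two non-diffusing forms keep their lab-frame equations, which in
the mapped frame is a first-order upwind residual transport with no
dilution.

Numerics: explicit Euler–Maruyama, centred 5-point diffusion on a
cell-centred grid (ghost reflection for no-flux, negated ghost for the
absorbing face), dt from the diffusion CFL with safety factor 0.4
evaluated over the whole schedule.  Spatiotemporal white noise is
discretised per node and step with amplitude `μ·√(dt/ΔA)`; negative
excursions are clipped to zero.  Default grid 128 × 32 (A-P × L-R);
halving the spacing changes the deterministic steady fields by < 2 %
in relative L2 norm.  Grid→cell interpolation is bilinear in
computational coordinates; cell→grid deposition of hoxb1a uses a
normalised elliptical tent kernel (half-widths 9 × 22 μm, matching the
initially anisotropic cell spacing) and is zero outside the kernel
support, so there is no FGF source outside the tissue.

Key defaults: `Dr = 2500 μm²/h` (RA decay length ≈ 41 μm over the
tissue), `Df = 950 μm²/h` with binding/degradation rates 2/h (FGF
signalling decay length ≈ 18 μm — short-range), production rates
`vr = 10`, `vf = 8` a.u./h.  None of these rate constants are published
in the main text; they are calibrated (once, against the printed
phenomenology: a five-segment pattern with r3/r4/r5 ≈ 42/34/37 μm at
14 hpf, RA/FGF transients peaking near 12 hpf under rapid convergence)
and then frozen.

## Gene regulation

Each cell carries hoxb1a (H), krox20 (K), vhnf1 (V) and irx3 (I),
driven by RA and FGF interpolated at its centroid, with shared Hill
exponent 2, additive noise and zero-clipping:

* H: RA + self-activation, repressed by K and V.
* K: FGF + self-activation, repressed by H.
* V: RA activation, repressed by I (no self-activation: V decays at
  rate `dv` wherever RA support is withdrawn).
* I: constitutive, repressed by V.

Design targets of the calibration, in order of importance:

1. **Binary identities.**  H and K self-activation makes each
   subsystem a saturating toggle; K is slightly supercritical
   (`akk·vk²/(4·dk²) ≈ 1.12`), so a committed krox20 cell stays
   committed even as FGF later declines, while the barrier from K = 0
   (≈ 0.7 a.u.) is many noise standard deviations, so spurious
   latching in r2/r6 is negligible.  On-states sit at 2.5–3.5 a.u.,
   well above the classification threshold 1.2.
2. **Fast commitment.**  H and K use production/degradation rates of
   (20, 4) and (16, 4) /h.  These large rates are a pure time
   rescaling of the nullclines; they were required to push the
   co-expressing transit time (cells crossing the mutual-repression
   saddle) below ~0.5 h, which is what keeps the dislocated-cell count
   at 14 hpf in single digits.
3. **Positional thresholds.**  The RA input gains place the hoxb1a
   escape zone so the r3/r4 competition front lands near the measured
   position; the vhnf1/irx3 race (a bistable switch decided during the
   pre-pattern burn-in) puts the vhnf1 border at the prospective
   r4/r5 boundary; FGF spread from the hoxb1a stripe places the
   krox20 onsets that define r2/r3 and r5/r6.
4. **Noise.**  μ ≈ 0.05–0.08 a.u./√h on genes and 0.05–0.1 on the RA
   fields produce visibly rough boundaries at 12 hpf that sharpen by
   14 hpf.  Larger RA-field noise (μ ≈ 0.2) destabilises the
   krox20/hoxb1a race and produces occasional pattern blow-ups; this
   is the single most sensitive amplitude in the model.

Initial conditions follow a two-stage burn-in over the two hours
before 11 hpf with geometry frozen at its 11 hpf shape: stage 1 starts
from the deterministic RA equilibrium and runs stochastic RA/vhnf1/irx3
dynamics from V = I = 0 (establishing the posterior-high vhnf1 /
anterior-high irx3 pre-border); stage 2 sets H to the uniform 0.21,
K and FGF to zero, and runs all species.  The head start this gives
hoxb1a over krox20 (which must wait for hoxb1a-driven FGF) is what
guarantees r4 forms robustly in the two-morphogen model regardless of
the initial hoxb1a level — and its absence is exactly why the
one-morphogen reduction is initial-condition-sensitive (below).

Identities: hoxb1a if H ≥ 1.2 > K, krox20 for the converse, the larger
wins if both exceed the threshold (an exact tie goes to krox20;
co-expression is transient and rare), otherwise none.

## Cell mechanics

345 cells (23 A-P rows × 15 L-R columns at 11 hpf) are clusters of 12
nodes in two hexagonal rings (outer radius 3.2 μm, inner 1.6 μm).
Overdamped node dynamics sum three velocities: the convergent-extension
velocity at the cell centroid (identical for all 12 nodes), intra-cell
linear springs restoring the three rest lengths (outer ring, inner
ring, same-angle cross-layer) plus a short-range intra-cell volume
exclusion that prevents the two-ring truss from folding through
itself, and node-to-node inter-cell forces: exponential short-range
repulsion (identity-blind excluded volume) plus a longer-range
exponential term scaled by `2F − 1`, where the similarity weight

    F = s_i s_j + (1 − s_i)(1 − s_j),   s = logistic((K − 1.2)/0.25)

is 1 for krox20-alike pairs (attraction), 0 for dissimilar pairs
(repulsion) and 0.5 (no selective term) at indeterminate levels.
Pinning F ≡ 0.5 removes sorting selectivity.  Force amplitudes
(repulsion 40 μm/h over 2 μm, attraction 6 μm/h over 5 μm, cutoff
12 μm) were tuned on two-cell and cluster relaxation toys so that the
equilibrium centroid spacing of packed same-identity clusters (~7 μm)
matches the available area per cell at 14 hpf, dissimilar pairs are
expelled past the cutoff, and cell radii of gyration stay within ±25 %
of rest through a crowded simulated hour.

Integration splits timescales: the stiff intra-cell springs
(k = 500 /h) advance with sub-steps ≤ 5×10⁻⁴ h, while the slowly
varying inter-cell/external field is re-evaluated every 4×10⁻³ h of
simulated time (radial force magnitudes are tabulated and linearly
interpolated).  A guard rejects any step that would carry a node more
than one cell radius between force evaluations.

A known limitation of this short-range force family: a single cell
dislocated more than the 6r metric cutoff (≈ 19 μm) has no
same-identity neighbour within its interaction range and therefore no
directional cue; such cells are not rescued by sorting, and stripe
condensation can even deepen them.  Sorting robustly decreases the
total penetration penalty (SI) of interface-graded misplacement, which
is the property the unit suite asserts; deep-dislocation counts are
exercised at the system level.  This also shapes the schedule
comparison: the later cells commit (medium/slow convergence), the more
of the boundary roughness ends up *beyond* the 6r cutoff, so slow
convergence manifests mostly as more dislocated cells rather than a
proportionally higher SI — the DC ordering rapid < medium < slow is
strongly reproduced (≈ 3/12/28 at n = 6), while the SI ordering can
partially invert.

## Pattern metrics

For a candidate boundary position k, each cell on the wrong side
contributes its penetration depth (centroid offset by the cell radius
r = 3.2 μm).  SI is the root-sum-square of depths over cells within
6r, minimised over k on a 0.1 μm grid; the minimiser is the boundary
location m; cells deeper than 6r at m are dislocated cells, excluded
from SI.  Because a candidate that dislocates *every* cell also scores
zero, objective ties are broken toward the fewest dislocated cells
before taking the midpoint of the minimising set.  The four boundaries
are found by staged interval splitting (the hoxb1a mean position
splits the tissue; r3/r4 and r4/r5 are found first, then r2/r3 and
r5/r6 in the outer intervals); more than 8 dislocated cells in total
marks the pattern failed.  Segment lengths are boundary differences.

## Reduced models

**1D gene-expression model.**  The morphogen/gene system on a fixed
300 μm A-P segment (the 14 hpf morphogen extent; RA onset at 230 μm),
128 nodes, steady states by explicit time integration (relative change
< 10⁻⁶ per hour; integration rather than root-finding so bistable
nodes settle into the basin selected by the stated initial
conditions).  The *one-morphogen* variant drops the FGF equations and
feeds intracellular RA into krox20's activation with an independent
gain (62.5), calibrated to the transition regime where the
hoxb1a-versus-krox20 race is decided by the initial hoxb1a level: r4
is absent below IC ≈ 0.2 and more than doubles between IC 0.20 and
0.23, and boundary positions fluctuate strongly under per-node
U[0.19, 0.23] ICs while the two-morphogen model is insensitive even to
U[0, 0.3].  The absolute one-morphogen r4 lengths near the transition
(≈ 5–15 μm) are smaller than the published 21–44 μm; the ≥ 2-fold
expansion and the absence threshold are the calibrated contracts.

**Sorting-only model.**  Identities are drawn once from a
position-conditional five-component Gaussian mixture over the tissue
(component centres at the expected segment centres, spread = half the
expected segment length), mapped to none/krox20/hoxb1a/krox20/none,
and frozen; krox20 cells feed a fixed high level (2.0 a.u.) into the
similarity function.  Mechanics alone then runs 11–14 hpf.

## Experiments and problem sizes

The default coupled run (128 × 32 grid, 345 cells, 2 h burn-in + 3 h
simulation) takes ~15 s on one core.  The shipped experiment sizes:

* baseline ensemble and schedule comparison: n = 10 seeds per
  schedule at the default grid;
* sorting-only comparison: n = 10 per schedule;
* random-parameter sweep: n = 50 per schedule on a 48 × 16 grid, each
  gene-regulation rate constant independently perturbed by a
  multiplicative U[0.9, 1.1] factor.  The ±10 % range was chosen so
  that roughly half of the perturbed runs produce a valid five-segment
  pattern, matching the reported success proportion; at ±20 % the
  model's success rate falls to ~25 %.
* acceptance script: 5 independent seeds of the baseline at default
  resolution, reporting ensemble-mean r3/r4/r5 lengths at 14 hpf.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself: the dimension table is
a small measured/assumed fixture, and every simulation input is drawn
from seeded generators.  Passing tests demonstrate that the coupled
mechanism — two morphogens, noisy toggle-switch gene regulation,
selective sorting and measured-speed convergent extension — suffices
to reproduce the quantitative segment lengths, the failure threshold,
sharpening over 12–14 hpf, the robustness asymmetry between the one-
and two-morphogen circuits, and the direction of the
convergence-speed comparisons (most strongly in dislocated-cell
counts).  They do not validate the unpublished parameter values
against the original calibration, the behaviour of real tissues beyond
the printed summary statistics, cell division (excluded), or
three-dimensional effects.
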