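# Methods

`tumorvox` simulates macroscopic tumor growth on a cubic lattice of
N × N × N voxels of edge Δs (default 2 mm) with a time step Δτ (default
10 s).  The system is a discrete-time stochastic dynamical system: the state
comprises nine per-voxel vectors — live tumor cells *l*, necrotic tumor cells
*nc*, necrotic host cells *nn*; oxygen *o* and glucose *gl* stocks (pmol);
supply rates *o_b*, *gl_b* and their caps *o_b_max*, *gl_b_max* (pmol/s) —
plus a per-voxel angiogenesis switch.  Live host cells are not stored; their
count is always the derived `s(M − l − nc − nn)` with `s(x) = max(x, 0)`,
which encodes dislocation of host cells by invading tumor cells without a
tenth vector.  One step applies, in order, vascular remodeling (F_vr),
metabolism-driven proliferation/necrosis (F_pn), chemical diffusion
(F_o, F_gl) and — every κ steps (default 30, i.e. every 5 min) — cell
invasion (F_c), then recomputes the switch.

## Diffusion kernels and transition matrices

Chemical and cellular transport are driven by one-step transition kernels:
the probability that a particle placed uniformly in a voxel ends the step in
that voxel, in a specific neighbor, or beyond.  Isotropic diffusion with
coefficient D displaces by a Gaussian with per-axis variance 2DΔτ;
anisotropic (cell) diffusion displaces by `U diag(√(αλ_i)) b` with
`b ~ N(0, Δτ I)`, where `U`, `λ_i` define the diffusion ellipsoid and a
scalar coefficient maps through 2D = αλ.  Kernels are estimated by Monte
Carlo (default 10⁶ samples, fixed seed 12345) and, for the isotropic case,
cross-checked against a deterministic quadrature reference that factorizes
each class probability into three 1-D Gaussian-bin integrals.

The time discretization must satisfy a containment condition: essentially no
mass may leave the 27-voxel shell in one step.  For the defaults (oxygen
D = 1.8·10⁻⁵ cm²/s, Δs = 2 mm, Δτ = 10 s) the residual escape is below
10⁻¹⁴ by quadrature.  After the containment check, kernels are renormalized
so that `p_self + 6 p_face + 12 p_edge + 8 p_vertex = 1` exactly; this makes
a spatially uniform field an exact fixed point of the interior stencil and
removes slow escape-mass drift over the ~10⁵–10⁶ steps of a run.

Chemical matrices (T_o, T_gl) use time-independent Dirichlet boundaries:
surface-voxel rows are identity rows, everything else implements the
26-neighbor gather.  The cell matrix T_c uses a reflecting (homogeneous
Neumann) boundary: per source voxel, the out-probabilities over in-lattice
neighbors are renormalized to one and the self term is dropped, so T_c is
column-stochastic with zero diagonal and conserves cell mass exactly.

To emulate short-time stochastic variability of in-vivo chemical transport,
columns of T_o/T_gl inside or adjacent to the tumor are perturbed every 6
steps (default): each nonzero entry is scaled by `exp(ε·u)`, `u ~ U(−1,1)`,
ε = 0.1, and the column is rescaled to its original sum.  Perturbations are
drawn relative to the *baseline* matrix captured at operator construction,
not compounded across events: a compounding multiplicative walk (per-event
log-sd ≈ ε/√3) would erase the order-of-magnitude separation of the kernel
classes after a few hundred events, while baseline-anchored jitter provably
preserves entry rank order for ε ≤ 0.5 (a post-check still verifies and
redraws any violating column).

## Metabolism (F_pn)

A host cell consumes K_o = 2.5·10⁻⁴ pmol/s oxygen and K_gl = 5·10⁻⁵ pmol/s
glucose; combustion (Gl + 6 O₂ → 36 ATP) and glycolysis (Gl → 2 ATP) then
fix its ATP demand at `K_ATP = (17/3) K_o + 2 K_gl`.  A quiescent tumor cell
covers a fraction β of the same ATP demand by glycolysis, needing
`((17β+1)/36) K_ATP` glucose/s and `((1−β)/6) K_ATP` oxygen/s; an actively
proliferating cell needs λ times as much (default λ = 10).  The actively
proliferating count is the deterministic estimate `a·l·(cc/Δτ)` for mitosis
rate *a* and cell cycle cc = 24 h.

Per voxel and step: host cells consume first; if stock + supply falls short,
the surviving host count is set by the binding resource (leaving it exactly
exhausted) and the remainder turns necrotic.  The leftovers O_av, Gl_av then
constrain the tumor's glycolysis fraction to
`β ≥ β_ = 1 − 6 O_av/(l K_ATP Δτ)` and
`β ≤ β̄ = (36 Gl_av/(l K_ATP Δτ) − 1)/17`, intersected with the phenotype
window [β₁, β₂] (default [0.1, 0.2]).  If the intersection is empty the
voxel starves: β̃ ~ U[β₁, β₂] fixes the per-cell needs, the supportable cells
survive and the rest turn necrotic.  Otherwise β̃ is drawn uniformly on the
intersection and the voxel proliferates at
`ã = min(a_o(β̃), a_gl(β̃), a_max)`, the oxygen-/glucose-limited rates capped
by a_max (default 1.6·10⁻⁵ per step ≙ 5-day doubling).  Comparisons in the
case analysis are exact (inclusive) on the computed floats; stocks are
floored at zero against pathological over-absorption by the vasculature.

Populations are continuous nonnegative reals throughout; nothing is rounded.
One deliberate addition: a voxel whose live-tumor population falls below one
cell after F_pn is treated as locally extinct (the remainder becomes
necrotic).  Without a sub-cell floor a continuous population can decay
asymptotically but never reach the exact zero that defines tumor death, so
finite-horizon survival probabilities would be degenerate.  One cell is the
natural scale for this floor; it is configurable
(`ModelParams.extinction_threshold`).

F_pn and F_vr are implemented as numba-compiled per-voxel sweeps (the
per-voxel formulation mirrors the algorithm statement exactly and is an
order of magnitude faster at small N than masked numpy vectorization); the
test suite compares both against independent pure-Python per-voxel oracles
bit for bit, with the random draws stubbed.

## Vascular remodeling (F_vr)

The vasculature buffers both chemicals toward fixed blood-side levels
(o₀ = 1.2·10³, gl₀ = 4·10⁴ pmol per voxel): each step the supply rate moves
by a random fraction r ~ U[0,1] of the imbalance `(x₀ − x)/Δτ` and is then
clipped to ±cap.  Supply can be negative (absorption).  In tumor-free voxels
the caps are constant; in tumor-reached voxels (l + nc > 0) both caps evolve
by the shared stochastic factor
`1 − f_r r₃ v_r + sw f_e r₄ v_e`, with linear occupancy weights
`f_r = (l+nc)/M`, `f_e = (M−l−nc−nn)/M` (clamped to [0,1]), maximum
regression/expansion rates v_r, v_e (defaults: 5-day minimum halftime,
1-day minimum doubling time; rate = ln2/(days·86400/Δτ)), and the
angiogenesis switch sw, set when a voxel holds live tumor cells and is
hypoxic (o < 0.30 o₀) or hypoglycemic (gl < 0.50 gl₀).  Caps are floored at
zero and share one multiplicative history, so a single capacity rendering
serves both species.  r₁–r₄ are drawn independently per voxel per step; the
switch is recomputed at the end of each full step, after diffusion.

## Cell invasion (F_c)

Only live tumor cells in excess of the voxel's remaining maximum capacity
move: with `s₁ = s(M_max − nc − nn)` and `s₂ = min(l, s₁)`, the update is
`l ← s₂ + T_c (l − s₂)` (M_max = 1.02 M, M = 8·10⁶ cells).  Receiving voxels
may transiently exceed M_max; the excess is resolved at the next
application.  The default cell tensor is spatially constant with principal
axis (1/2, 1/2, √2/2), principal diffusivity 1.5·10⁻⁶ cm²/s and transverse
1.5·10⁻⁸ cm²/s — the extremes of the reported range for migrating tumor
cells — so invasion is strongly anisotropic.  A hook for dynamically
reweighting T_c (e.g. chemotaxis) exists but is disabled by default.

## Randomness and reproducibility

All stochastic draws flow through a single seeded `numpy` generator in a
fixed per-step order: matrix-perturbation factors (when the cadence fires),
then the four vascular uniforms per voxel, then the metabolism β̃ uniform per
voxel.  A master seed reproduces a trajectory bit for bit; ensemble
replicate *i* uses seed `base_seed + i`.  Kernel estimation uses its own
fixed seed so operator construction is independent of run seeds.

## Ensembles and reporting

An ensemble records, per replicate, daily totals and the final live
population.  Survival probability is the fraction of replicates with a
nonzero final live population; the conditional mean live count averages over
surviving replicates only (reported as missing when none survive).  Sweep
reports render the per-cell sorted final counts (descending), matching the
skewed-bar presentation style, plus per-day mean trajectories.

## Scaled-down study scenarios

Full-scale studies (N = 21, 90 days, 20 replicates) take tens of minutes per
replicate; the shipped acceptance checks use N = 11, 10-day horizons and 10
replicates.  At that horizon a small seed (5·10⁵ cells, the full-scale
choice) cannot raise voxel occupancy enough for occupancy-driven remodeling
to matter, so the scaled scenarios seed the central voxel directly at the
occupancies that activate the mechanism under test:

* **Necrotic core** — seed 2M cells (immediate overflow and invasion along
  the tensor axis).  The vascular caps of the saturated core regress while
  the lightly occupied rim stays supplied, reproducing the
  higher-necrotic-fraction-toward-the-center pattern.
* **Regression vs survival** — seed 0.7M cells with angiogenesis disabled,
  β ∈ [0, 0.1], λ = 10.  The tumor is oxygen-constrained from the start, so
  it never displaces the resident host cells; when regression (1-day
  halftime) drives the cap below the host demand, the binding resource is
  exhausted by hosts and the entire tumor population of the voxel starves to
  zero — at a 5-day halftime the cap stays above demand and the tumor
  survives.  This is the intermediate-occupancy regime: a near-capacity seed
  would eliminate the host cells and leave an extinction-proof,
  diffusion-fed tumor remnant.

Passing these scenario tests shows the implemented mechanisms interact as
designed (spatial starvation gradients; monotone effect of regression rate
on viability); it does not validate the model against biological data, and
the 10-day populations are not comparable to 90-day full-scale figures.

## Known limitations

* No lactate/acidity, growth factors, therapy, necrotic-debris removal, or
  multiple migrating cell species; single-threaded.
* The spatially varying anisotropic kernel path supports only a constant
  tensor (one shared offset map); no imaging-derived tensor ingestion.
* The operator order within a step (F_vr → F_pn → diffusion → F_c) is one
  natural sequencing of the coupled processes and is configurable in
  principle; no numerical-convergence study over Δs, Δτ is included.
* Host tissue is homogeneous; boundary voxels hold all quantities fixed
  (Dirichlet) for chemicals and reflect cells, so the lattice must be large
  enough that the tumor stays clear of the boundary.
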