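# Methods

## Mechanical model

The system is two-dimensional: filaments and crosslinkers live in the
plane, with coordinates in µm and the origin at the center of the
confining circle.  Energies are in pN·µm, forces in pN, time in s.

**Filaments** are bead-spring worm-like chains.  Each of the F
filaments has n beads at rest spacing `link_rest_length`; consecutive
links contribute a harmonic stretch term ½ k_stretch (ℓ − ℓ₀)² and a
harmonic bend term ½ k_bend θ², with θ the signed turning angle between
consecutive links.  Filaments have fixed lengths — no
assembly/disassembly — and there are no motor proteins.  Excluded
volume between unbound components is neglected; network behavior is
assumed to be dominated by connectivity.

**Crosslinkers** are linear springs with a binding head at each end:
stretch energy ½ κ (d − l)², where d is the head-to-head distance and l
the species rest length.  When both heads are bound, an
orientation-selective species additionally pays

    U^align = k_align (1 − cos θ),   θ ∈ [0, π],

for the angle θ between the two bridged links, with parallel links at
θ = 0.  Antiparallel links pay the full 2 k_align, which is what makes
the fascin-like species selective for parallel bundles; the
α-actinin-like species has k_align = 0 and no orientational preference.
The binding energy per bound head is treated as a constant offset: it
cancels from all force evaluations and is absorbed into the nominal
kinetic rates, so it never appears explicitly.

**Confinement** is a radial harmonic wall: ½ k_c (r − r_c)² beyond
r_c, zero inside, applied to every filament bead and crosslinker head.
The potential is continuous and once-differentiable at r = r_c.

Forces are the exact analytic gradients of these terms.  A bound head
is not a free coordinate: it sits at its attachment point, a fractional
position u ∈ [0, 1] along one link, and any force acting on it is
distributed to the two link beads with lever-rule weights (1 − u, u).
The test suite verifies the gradients against central differences of an
independently coded energy at 10⁻⁶ relative tolerance.

### Default parameters

| parameter | fascin-like | α-actinin-like | unit | origin |
|---|---|---|---|---|
| rest length l | 0.1 | 0.5 | µm | reference parameterization |
| stiffness κ | 1.0 | 0.1 | pN/µm | reference parameterization |
| k_on | 20 | 0.2 | s⁻¹ | reference parameterization |
| k_off | 0.5 | 0.05 | s⁻¹ | from on/off ratios 40 and 4 |
| k_align | 1/3 | 0 | pN·µm | reference parameterization |
| capture radius | = l | = l | µm | package default |
| occupancy o_c | 0.5 | 0.5 | µm | package default |

Filament defaults: 35 beads, link rest length 1 µm, k_stretch
100 pN/µm, k_bend 0.041 pN·µm (bare-filament persistence length
≈ 10 µm at k_BT = 0.0041 pN·µm), drag 0.5 pN·s/µm per bead and per
unbound head.  Confinement r_c = 15 µm, k_c = 10 pN/µm.  The spring
constants, drags and k_c are package choices (they are not part of the
reference parameter set) and every run logs the fully resolved
configuration so they are always visible; all are overridable through
the TOML config.

## Dynamics

Free coordinates (beads and unbound heads) follow overdamped Langevin
dynamics, integrated by Euler–Maruyama:

    x ← x + (F/γ) dt + sqrt(2 k_BT dt / γ) η,

with η standard normal per coordinate per step.  Bound heads move with
their attachment points.  The default step dt = 2×10⁻⁵ s gives a
stability margin dt·k_stretch/γ = 0.004 at full scale; the integrator
aborts with a diagnostic if any coordinate moves farther than one link
rest length in one step, or if a non-finite force appears (naming the
offending component).

### Binding kinetics and detailed balance

Each step, every head makes one kinetic Monte Carlo attempt:

- **Binding** (unbound head): with gate probability 1 − exp(−k_on dt),
  candidate sites are collected — the nearest point of every filament
  link within the capture radius, excluding sites on the partner's
  filament closer than o_c along the arc — one is chosen uniformly at
  random, and the move is accepted with min(1, exp(−ΔU/k_BT)), where
  ΔU is the mechanical energy change of teleporting the head from its
  current position to the site (spring stretch change plus any
  alignment penalty created).
- **Unbinding** (bound head): with probability
  min(1, (1 − exp(−k_off dt)) · exp(+E/k_BT)), where E is the stretch +
  alignment energy stored in the bound configuration relative to a
  relaxed spring.  The exponent is clipped at 50 for overflow safety;
  the probability itself saturates at 1.  The released head stays where
  it was.

At zero strain both rates reduce exactly to the nominal k_on and k_off.
For a head held at a fixed position the stationary bound:unbound odds
are (k_on/k_off)·exp(−E/k_BT) — Boltzmann in the crosslinker potential
— and a strained spring unbinds faster than a relaxed one (a slip
bond).  The asymmetry of the two factors reflects that the unbound
reference state of a released head is a relaxed spring: the escape flux
integrates over free configurations, which is what the +E factor
captures.  The test suite checks the zero-strain rates, the Boltzmann
stationary odds over a graded set of spring extensions on a frozen
scaffold, and the two configured on/off ratios (40 and 4) from long
single-site dwell-time runs.

Randomness: Langevin noise comes from a numpy Generator seeded with the
config seed; kMC decisions use numba's internal RNG seeded once per run
from the same seed.  A (config, seed) pair reproduces a trajectory
bit for bit.

## Initial conditions

Each filament is created centered on the origin with beads at rest
spacing.  The half from the center to the pointed end points at an
angle drawn uniformly from [0, 2π); the other half continues the
filament's direction of travel bent by a kink drawn uniformly from
[−π/4, π/4] — i.e. the turning angle at the center bead equals the
kink.  (Reading the kink as the angle between the two center-to-end
rays instead would fold every filament into a ≤ 45° hairpin costing
~50 k_BT of bending energy, contradicting the intent of a "random
initial bend".)  The filament is then translated by independent
Gaussian x and y offsets with 3 µm standard deviation.

Crosslinkers start unbound, their centers uniform in the axis-aligned
square of side r_c centered on the origin and their heads a rest length
apart at a random angle.  The square covers only the central part of
the confinement circle; this asymmetry is kept as-is.  The count per
species is density × π r_c² (the density is anchored to the vesicle
area; at 5 µm⁻² and r_c = 15 µm this gives 3534 per species), with a
square-area convention selectable in config.

## Sorting observables

At any frame, the spatial distribution of a species is the 2D histogram
of the **midpoints of doubly bound crosslinkers** (head positions
selectable) on an n_bins × n_bins grid (default 20) over the fixed
square [−r_c, r_c]², each bin divided by its area and the total count,
so the grid integrates to 1.  Bins are half-open with the last right
edge closed; bins outside the circle remain part of the grid and of the
spatial average.  A frame with zero doubly bound crosslinkers yields an
explicit empty-grid signal rather than NaNs.

The Binder cumulant of a grid is U₄ = 1 − ⟨s⁴⟩/(3⟨s²⟩²) with s the
per-bin PDF value and ⟨·⟩ the unweighted mean over all bins, zeros
included.  Closed forms used as test anchors: a constant grid gives
exactly 2/3; k equal nonzero bins of N give 1 − N/(3k), monotone in k.
U₄ falls as mass concentrates.  Replicate aggregation follows the
measure-then-average convention: U₄ per simulation per frame, then mean
and SD across replicates; final-frame PDFs are averaged element-wise
and remain normalized.

Note that U₄ compares meaningfully between species only when the
doubly-bound populations are large enough to occupy the grid (≳ 1
count per bin): below that, U₄ tracks the occupied-bin count — i.e.
sample size and clumping granularity — rather than the spatial spread
of the underlying distribution.  This matters for strongly reduced
simulations; see Limitations.

## Persistence-length estimation

For a skeletonized bundle (a 3D polyline), the orientational
correlation ⟨C(s)⟩ averages cos θ between bond vectors over all ordered
bond pairs, binning the pair separation (summed bond lengths between
the bonds' start points) to the nearest multiple of the median bond
length; C(0) = 1 by construction.  Assuming ⟨C(s)⟩ = C₀ e^(−s/L_p′),
an unweighted linear regression of ln⟨C(s)⟩ on s gives the slope
−1/L_p′ and the intercept ln C₀.  A fit is accepted only if R² > 0.8,
the contour length L lies strictly inside (8, 20) µm, and the slope is
negative.  Cohort output is the mean accepted L_p′ with SEM (headline)
and SD, the acceptance counts, and the largest |ln C₀| among accepted
fits — near zero when the model holds.

**Fit window.**  The default regression uses separations with C(s) > 0
up to min(L/2, 4 bond lengths).  For bundles much shorter than their
persistence length, essentially all slope information lives in the
first few separations: correlations at long separations are driven by
the same few bend events in the chain, fluctuate coherently, and
inflate the variance of the fitted slope — which the reciprocal in
L_p′ = −1/slope converts into a systematic upward bias of the cohort
mean (E[1/x] > 1/E[x]).  A window scan across ground-truth L_p from 33
to 100 µm shows the cohort-mean bias growing from ~+2% at a 3–4-bond
window to ~+25–30% at L/2; the 4-bond default keeps the estimator
consistent at the percent level across that range.  Both the window
and the L/2 cap are configurable (`max_bond_separations=None` restores
the plain L/2 rule).  The regression is unweighted; pair-count
weighting was considered and not adopted, to keep the estimator the
plain least-squares fit its output claims to be.

The package reports effective persistence lengths from the 3D relation
⟨cos θ⟩ = e^(−s/L_p) verbatim; no 2D factor-of-two correction is
applied to skeletonized (experimental-style) data.  The cohort spread
is reported both as SEM and SD, with SEM as the headline number.

## Synthetic data

The worm-like-chain generator produces discrete chains whose successive
bond directions satisfy E[cos θ_step] = exp(−b/L_p) exactly: in 3D via
von Mises–Fisher polar sampling about the previous bond with
concentration solved from coth κ − 1/κ = exp(−b/L_p) (exact inversion,
no small-angle approximation, so recovery tests stay unbiased at coarse
b), in 2D via Gaussian turning angles with σ² = 2b/L_p.  Tangent
correlations then decay as exp(−s/L_p) in expectation, which is the
ground truth against which the estimator is scored.  Default test
cohorts use bond length 0.2 µm and contour lengths uniform in
(8, 20) µm, mirroring the length-filter window.

What the generator does **not** emulate: measurement noise and
smoothing of the active-contour skeletonization, bundle thickness and
branching, membrane proximity effects, and non-exponential correlation
from mixed crosslinker populations.  Passing recovery tests therefore
demonstrate estimator correctness on ideal worm-like chains, not
robustness to imaging artifacts.

Aster scaffolds (straight filaments through a central or peripheral
hub) give the binding, alignment and density machinery a known
geometry.  Count tables are multinomial draws per experiment with
specified category probabilities and totals, emulating per-experiment
phenotype classification counts; probabilities are summarized as
mean ± SEM over experiments and compared with Welch's unequal-variance
t-test (via scipy), whose small-sample behavior at n = 3 is mildly
conservative.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen once: persistence-length cohorts of 100–300 chains; kinetic
calibration from single-site runs of 2×10⁷ steps (fast species) and
2–4×10⁸ steps (slow species) at dt = 10⁻⁴ s, sized so the slow species
accumulates >10³ dwell pairs and the stationary ratio carries a ~3%
standard error; and a reduced sorting simulation — r_c = 5 µm, 12
eleven-bead filaments, both species at 5 µm⁻² (393 crosslinkers each),
center spread 1 µm, dt = 2×10⁻⁴ s, 10 s, five seeds.  The full-scale
configuration (r_c = 15 µm, 50 filaments of 35 beads, 3534
crosslinkers per species, 100 s at dt = 2×10⁻⁵ s) is supported through
the same interfaces but is a long-running job.

## Known limitations

- The scheme's unbinding factor uses the stored energy relative to a
  relaxed spring; strictly, binding and unbinding Metropolis factors
  are not exact time-reverses of each other for a diffusing head
  (the head is released in place, not at its pre-binding position).
  The stationary distribution on frozen scaffolds is Boltzmann — the
  property the tests pin — but dynamical pathways near strong gradients
  are approximate.
- At the reduced sorting scale, doubly bound populations (tens per
  species) are far below one count per grid bin, so the 20-bin Binder
  cumulant reflects count sparsity more than spatial structure, and
  bundle maturation (the fascin-like zipping that flattens its
  distribution) is slower than the 10 s window at the default drag.
  The reduced-scale sorting check in the acceptance suite is sensitive
  to exactly this and documents the regime honestly rather than
  adjusting conditions to mask it.
- 2D mechanics only; no membrane deformation, no motors, no filament
  turnover, no excluded volume.
- SOAX reading targets the snake text dialect described in the reader's
  docstring; exotic variants may need the plain 4-column fallback.
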