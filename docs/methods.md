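# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of `qanet`, in the order the pipeline runs.

## Synthetic chip data

The generator emulates a 12K one-color oligonucleotide platform: 11,911
gene-of-interest features (a configurable fraction duplicate copies of the
same gene, default 1%) plus 633 negative controls, of which 88 are spike
quality-control features (4 distinct spikes × 22 replicates sharing one
concentration each). Four experiments are simulated on the common grid
0, 0.5, 1, 1.5, 2, 4, 6, 8 hr: QA shift, starvation shift, QA shift in a
*qa-1F* mutant, and a sucrose→sucrose control.

Observed intensity is

    clamp(baseline · 2^(shape(t) + ε), 0, 64000) + scanner_offset

with ε ~ N(0, σ) i.i.d. per feature and time point (duplicate features of a
gene get independent noise). Choices, fixed once:

- **Noise** σ = 0.4 on the log2 scale (~30% CV), a typical single-channel
  microarray noise level. Multiplicative log-normal noise is the standard
  model for scanner counts; the raw 0–64,000 range is clamped and clamping
  events are counted.
- **Baselines** log-uniform on [100, 5000] counts for ordinary genes;
  leaky responders log-uniform on [1500, 5000] so they exceed the 1,000-
  count leakiness threshold at t = 0. Negative controls are log-uniform on
  [200, 2500], whose median matches the gene-baseline median, so the
  fraction of gene features above the control median sits near 0.5 — the
  50–52% seen on real chips (checked as a calibration band, not a hard
  contract).
- **Scanner effect** one additive offset per experiment, U(0, 200) counts,
  reflecting that each experiment used a different scanner; it cancels in
  the within-chip normalization.
- **Response shapes** are parametric stand-ins for the visually sorted
  response categories: immediate (linear rise complete by 0.5 hr), gradual
  (linear over 8 hr), delayed (flat until a 2–4 hr onset, then linear),
  concave-down (rise to a 1.5–3 hr peak, decay losing 75% of the rise by
  8 hr), and a monotone decrease for control-experiment down-regulation.
  Log2 amplitudes are U(2, 4). The real categories were defined by eye, so
  any parametric family is a modeling choice; this one covers the
  qualitative portrait while keeping every class linearly parameterized.
- **Class composition** (defaults) mirrors the study's magnitudes so
  downstream counts are comparable: 50 QA responders (20 immediate, 10
  gradual, 10 delayed, 5 concave, 5 leaky), 49 starvation responders, 5
  responding to both, 10 down-regulated in the control, 2 spurious
  responders in the mutant experiment, remainder null.

What the generator does **not** emulate: spatial chip artifacts, intensity-
dependent (banana-shaped) noise, probe-sequence effects, partial RNA
degradation, or cross-hybridization. Tests passing on this generator
therefore validate the statistical chain's logic and calibration under
clean multiplicative noise, not robustness to platform-specific artifacts.

## Normalization

Per chip: subtract the minimum raw reading over genes of interest, then
log2 with a +1 pseudocount (the minimum gene maps exactly to 0; whether the
original analysis used a pseudocount or dropped zeros is not stated, and +1
is the smallest integer offset on a count scale). Features reading below
the gene minimum (possible for negative controls) floor at zero before the
log. The robust Z uses the median and (p95 − p5)/3.29; center and scale are
computed over genes of interest and applied to all features, mirroring the
background-minimum convention. Percentiles interpolate linearly between
order statistics everywhere in the package — p5/p50/p75/p95 all depend on
this convention, so it is fixed and shared. A chip whose p95 equals its p5
is rejected as degenerate. No information crosses chips.

## Detection chain

Per experiment, each feature contributes the point (Z₀, mean of the seven
later Z values). Lines:

- **OLS**: closed form.
- **LMS** (minimizes the median of squared residuals): candidate slopes
  from point pairs — all pairs when n ≤ 300, otherwise 60 seeded random
  pairs (25 already give a 99.9% chance of one outlier-free pair at 50%
  contamination) — each with the intercept at the midpoint of the
  narrowest band covering ⌊n/2⌋+1 slope-detrended values. The OLS line is
  always included as one extra candidate, which guarantees the returned
  objective never exceeds the OLS line's own median squared residual.
  First-found wins ties.
- **Averaged**: coefficient-wise mean of the two (equivalent to averaging
  predictions for straight lines).

Residuals from the averaged line are standardized by s = p75(|residual|)/
1.15. p-values are one-sided: responders are above-line, so the upper tail
1 − Φ(r) is corrected; the symmetric lower tail is exposed for the
down-regulation analysis of the control experiment. Benjamini–Yekutieli
step-up at α = 0.10 (c(m) = Σ 1/i) handles the dependence among features;
α ≤ 0 rejects nothing by convention.

Degenerate corners, handled rather than erroring: residuals below float
rounding noise (every point exactly on the line) are snapped to zero; when
s = 0 with some genuinely nonzero residuals (noise-free data, ≥75% of
points on the line), those residuals standardize to ±∞ and their p-values
to exactly 0/1, with a degeneracy flag set. This keeps the noise-free
validation path classifying correctly. Note that with zero noise and a
responder planted in a screening experiment, the deterministic line tilt
makes extreme-abundance features spuriously "significant" — an artifact
specific to noise-free data that disappears at any realistic noise level.

Duplicate features are called individually; a gene is reported responsive
if any of its features is. Classification across experiments: up-significant
under QA, not significant (either tail) in the mutant and control
experiments; starvation overlap is retained as its own class.

## Diagnostics

False-positive/negative rates come from negative controls and known
positive controls; power = 1 − FNR. GEL₅₀ is 2^(−β₀/β₁) from a logistic
regression of the call indicator on the per-gene log2 fold change (max over
later time points vs t = 0 on background-subtracted counts; mean available
as an option — the verbal "median fold change among called genes" reading
is likewise exposed as `method="median"`). Perfect separation returns the
between-group midpoint with a flag; a slope of zero flags the estimate as
degenerate instead of producing a number. Leakiness thresholds are strict
inequalities: > 1,000 counts on sucrose at t = 0 is leaky; a good reporter
is non-leaky and exceeds 10,000 counts on QA.

## QARE scanning

The 16 shipped patterns are 12-mers or two 6-bp half-sites with a `{4}`
token. `{4}` is interpreted as a 4-nt unconstrained spacer — the two-half-
site architecture of QA-1F sites — not as a regex repetition; the scanner
counts mismatches only at specified positions, allows 2 by default, slides
by 1 with no overhang, and treats N as matching nothing. Forward strand by
default (the site set is near-palindromic); reverse-complement scanning is
a flag. Coordinates are 0-based half-open from the upstream-sequence start.

## Network models

The registry (`src/qanet/data/registry.json`) is data: gene lists, extra
species/reactions, the regulator block and the variant rules are all
editable without code changes, and the builder validates the expanded
totals (38/54 core; 147 species with 204 or 239 reactions extended) —
counts that the original network inventory prints only as totals, so the
block decomposition here is one consistent reconstruction: per-gene blocks
(g0, g1, mRNA ± protein; activation toggled by the regulator, transcription
catalyzed by g1), QA transport and catabolism, repressor and catabolite-
repression binding pairs, 36 non-cluster responder blocks, and an NCU03643
protein block (translation, decay, and two catalyst-toggle pairs acting on
the NCU03643 and ncu05897 gene states). The dual-regulator variants add one
second activation reaction for each of the 35 non-NCU03643 responder genes;
variant C gives NCU03643 itself a single activation reaction carrying both
catalysts (rate ∝ [QA-1F]·[NCU03643 protein]), the one reading consistent
with all three variants sharing 239 reactions.

Kinetics are mass action: rate = k · Π reactants · Π catalysts, catalysts
conserved. Units: hours; concentrations in arbitrary units; k in 1/hr
(first order) or 1/(unit·hr) (second order). θ = rate constants (registry
order) followed by initial concentrations (species order).

**Solver.** Modified Euler (Heun): predictor x̃ = x + h·f(x), corrector
x + (h/2)(f(x) + f(x̃)); fixed step, default h = 0.01 hr over [0, 8];
negative components clamp to zero and are counted; grid values interpolate
the internal steps linearly; a non-finite state raises with a suggestion to
reduce h. The inner loop is numba-compiled with an identical pure-Python
fallback. Order-2 convergence and ≤1% agreement with a high-order reference
integrator at the default step are enforced by tests.

`reference_theta` supplies a documented demonstration regime (synthetic,
not fitted values): external QA high, sucrose absent, free activator
present, rates of order 0.1–2/hr, chosen so the cluster switches on within
hours and NCU03643-controlled genes lag — the qualitative portrait of the
shift experiment.

## Ensemble fitting

χ² = Σ (y − a·x(t))²/σ² with one scale a per (gene, platform) profiled
analytically (weighted least squares, floored at 0) — profiling rather than
sampling the scales reduces the dimension at the cost of ignoring scale
uncertainty in the bands; the risk is noted and accepted. σ defaults to
max(0.1, 0.2·|y|) when the data carry no replicate-based estimate.
Divergent trajectories score +∞ and are simply rejected moves.

Sampling targets exp(−χ²/2), the ensemble-method convention. One sweep is
a Metropolis update of every parameter in random order with Gaussian steps
in log10 space; bounds are log-uniform k ∈ [1e−4, 1e3]/hr and x₀ ∈
[1e−6, 1e3] a.u., and out-of-bounds proposals are rejected. Proposal widths
adapt toward a 25–45% acceptance rate during equilibration only, so
accumulation sweeps leave the target invariant. The full protocol (20
chains × (35,000 + 5,000) sweeps, best χ² seeding a 40,000-sweep
accumulation) is the package default; tests and the acceptance experiments
run reduced protocols sized for a single CPU — 4 chains × (2,000 + 500) +
6,000 sweeps on a two-gene cascade for parameter recovery, and 15 + 5
sweeps warm-started at the generating parameters for the variant
comparison. Warm-starting both variants at the same θ (their parameter
layouts coincide) makes the comparison symmetric while keeping it at desk
scale; with random starts the full protocol would be required. Chains use
seeds derived independently from the master seed, so results are identical
under any scheduling.

Ensemble trajectory bands are pointwise mean ± 2 SD of log10
concentrations across (thinned) samples, with the population SD so that
two samples give exactly the half-difference. Nested variants are compared
by Δχ² of the ensemble minima against χ²(df), df being the parameter-count
difference (386 − 351 = 35).

## Known limitations

- The detection chain's normality assumption for standardized residuals is
  only approximate on structured data: with realistic baseline spread the
  far tails are heavier than normal, and screening experiments show a
  handful of false calls — the same magnitude the original chips showed.
  The global-null FDR guarantee (mean FDP ≤ α, verified over 50
  replicates) applies to exchangeable null features.
- LMS beyond n = 300 is a randomized approximation; its candidate-pair
  sample is part of the estimator's definition and is seed-reproducible.
- Parameters on compensation ridges of the network (e.g. an activation
  rate trading off against the activator's synthesis) can concentrate in a
  saturated mode away from the generating value; the recovery test
  therefore screens for individually χ²-sensitive parameters and requires
  80% pooled coverage rather than 100%.
- The ensemble machinery fits synthetic data only; the original microarray
  and Northern observations are not packaged, so printed absolute χ²
  minima are not reproduced here — only the construction counts, the
  comparison procedure, and the method's operating characteristics.
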