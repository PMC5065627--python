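# Methods

This note documents the models, estimators and numerical choices behind
`lwdclock`, including the decisions taken where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Simplified clock models (Model I / Model II)

Each gene (CCA1, PRR9, TOC1, LWD1) is one state variable — an
mRNA-level abstraction with no explicit protein stage.  Gene *i*
evolves as

    dx_i/dt = dose_i · v_i · Π_rep K_e^h/(K_e^h + x_s^h)
                      · (1 + Σ_act a_e x_s^h/(K_e^h + x_s^h))
              + ox_i − d_i x_i

with a global Hill exponent h = 2.  Repressions are multiplicative
Hill factors with one parameter each (K_e); activations enter through a
shared additive numerator with two parameters each (a_e, K_e), so a
gene with no activator retains basal production and a newly added
activating edge costs exactly two parameters.

The wiring interlocks three motifs that the experimental literature
supports and that are jointly necessary for the package's purpose:

* the CCA1⊣TOC1 / TOC1⊣CCA1 double-negative loop;
* a repressilator closed through the pseudo-response regulators,
  CCA1⊣TOC1⊣PRR9⊣CCA1, together with the morning-loop activation
  CCA1→PRR9;
* the LWD1/PRR9 double-positive loop (PRR9→LWD1, LWD1→PRR9).

Model II adds the single activating edge LWD1→CCA1 (+2 parameters).
A network containing only the double-negative and double-positive loops
is sign-consistent (monotone), and monotone systems admit no attracting
limit cycles — such a model cannot oscillate for any parameters, so the
negative loops above are load-bearing.  Variants were compared before
committing: without TOC1⊣CCA1 the toc1 hypomorph loses its short-period
direction; without TOC1⊣PRR9 nothing oscillates; without CCA1→PRR9 the
prr9 direction is lost.

**Genotypes.**  `null` zeroes a gene's production (degradation
untouched); `overexpress` adds a constitutive term `strength · v_i`;
`knockdown` multiplies production by a dose in (0, 1).  lwd1 lwd2 is a
full null of the LWD1 node, which stands for the redundant LWD1/LWD2
pair.  The representative period-analysis mutants (cca1, prr9, toc1)
are 50 % knockdowns: a full null of any repressilator member destroys
the cycle and is always arrhythmic, whereas the corresponding plant
single mutants keep rhythm because of redundant paralogs (LHY for CCA1,
PRR7/PRR5 for PRR9) — the halved dose is the minimal representation of
that redundancy.

**Solver.**  Single simulations use LSODA with rtol 1e-6 / atol 1e-9,
output resampled on a 0.1-unit grid; states are clipped at zero inside
the derivative so solver excursions cannot corrupt the Hill terms.

## Random-parameter oscillation screen

Parameters are drawn log-uniformly and independently.  Default bounds
per class: v ∈ [0.5, 50], d ∈ [0.1, 2] (half-lives 0.35–7 time units),
a ∈ [1, 100], K ∈ [0.05, 5], all around an O(1) concentration scale.
Two-decade spans keep a desk-scale screen (10^5–10^6 draws) inside the
oscillatory regime; the four-decade `ParameterRanges.wide` variant is
retained for exploratory use and accepts at rates orders of magnitude
lower (comparable to cluster-scale screens).  Time is dimensionless
during screening; all reported mutant periods are rescaled per
parameter set so the wild-type period reads exactly 24 h.

**Acceptance criteria.**  A parameter set is accepted when

1. the wild type oscillates: ≥ `min_cycles` (default 5) complete
   peak-to-peak cycles of CCA1 after a 120-unit transient discard,
   every successive peak-height ratio (measured above the series mean)
   inside [0.95, 1.05], relative amplitude (mean peak − mean trough,
   over the mean) ≥ 0.1;
2. the lwd1 lwd2 mutant oscillates by the same standard; and
3. the mean CCA1 level is lower in lwd1 lwd2 than in the wild type —
   the defining experimental phenotype of the double mutant.

Criterion 3 is what separates the variants: in Model I, losing LWD1
lowers PRR9 and therefore *de-represses* CCA1 (the wrong direction), so
Model I sets almost never qualify; in Model II the direct LWD1→CCA1
activation reverses the sign.  Without it the two variants accept at
statistically indistinguishable rates.  The criterion can be switched
off (`require_reduced_reporter=False`).

**Fast kernel.**  The screen integrates with a fixed-step RK4 kernel
(numba, dt = 0.1, CCA1 recorded every 0.5 units), simulating the
wild type for every draw and the mutant only for wild-type passes.
Trajectories that lose finiteness are NON_INTEGRABLE and count as
rejects.  RK4 at this step size resolves periods ≥ a few units to far
better than the peak-interpolation error; the adaptive LSODA path is
the cross-check (the two agree to ~2e-4 time units on the archived
set, and the FFT-NLLS/peak-interval comparison on accepted sets agrees
to < 0.03 h after normalisation).

**Determinism.**  All draws come from one `default_rng(seed)` stream in
row-major order, so results are a pure function of (variant, ranges, n,
seed, criteria) and independent of chunking.

**Mutant period table.**  Accepted sets are re-simulated per genotype.
A mutant needs a stable measurable rhythm, not the full screening band,
so the table uses ≥ 3 cycles with peak ratios in [0.75, 1.25]; sets
failing that are tallied as arrhythmic and excluded from the box
statistics (median / quartiles / extremes of normalised periods).

## Comprehensive clock model

The extended model resolves mRNA and protein for CCA1/LHY (`CL`), a
lumped PRR9/PRR7 (`P9`), TOC1 (`T`), the evening complex (`EC`) and LWD
(`W`) — ten ODEs — under a binary light input: CL represses T and EC;
P9 represses CL; T represses CL, P9 and EC; EC represses P9 and
(weakly) T; CL and light activate P9; light adds acute CL induction and
destabilises the EC protein (its ELF3 component is degraded in light);
LWD transcription is activated by P9, closing the positive loop.
Coupling modes: `PRR9_ONLY` lets LWD protein activate P9 transcription,
`PRR9_AND_CCA1` adds the analogous term on CL, `NONE` reproduces the
base model exactly (the coupling terms vanish identically).

The kinetic constants are the package's own: they were fixed once by a
seeded random search over physiological rate ranges (mRNA half-lives
~1–2 h, protein half-lives ~1.5–4 h), keeping the first parameter set
that satisfied, simultaneously, (i) a self-sustained free-running
rhythm in constant light with a circadian period (22.9 h), (ii) an
entrained CCA1/LHY mRNA peak within ±2 h of dawn under 12L:12D, (iii)
all directional perturbation behaviours listed below, and (iv) a
wild-type period shift < 0.5 h when the LWD coupling is engaged versus
the base model.  The constants are archived in
`extended.BASE_PARAMETERS`; tests re-verify the behaviours, not the
numbers.

Directional behaviours (all boolean regression tests, entrainment of
10 LD cycles, phases from the last three cycles, free-run from LL48):

* dual coupling, lwd1 lwd2: shorter free-running period *and* lower
  CCA1/LHY amplitude than wild type;
* PRR9-only coupling: that joint signature is *not* produced (the
  mutant's CCA1 amplitude rises instead — removing LWD de-represses
  CL when LWD only feeds P9);
* cca1 lhy: TOC1 and evening-complex mRNA phases advanced ("advanced"
  means the wild-type peak trails the mutant peak by 0–12 h mod 24),
  TOC1 mRNA elevated;
* toc1 null raises, and TOC1-ox lowers, CCA1/LHY mRNA.

Light transitions are integration-segment boundaries, so the
discontinuous input is never stepped over.

## FFT-NLLS rhythm estimation

`fft_nlls` follows the standard pipeline: (1) polynomial detrend
(default order 1) *for FFT seeding only*; (2) seed up to
`max_components` (default 4) cosines from the largest local maxima of
the amplitude spectrum; (3) jointly refit all cosines (free amplitude,
period, phase via an (a, b, τ) parameterisation) *together with the
polynomial baseline* by nonlinear least squares — sequential
detrend-then-fit measurably biases the period when the window holds a
non-integer number of cycles, which is why the baseline is refit
jointly; (4) iteratively drop the least significant component whose
amplitude confidence half-width exceeds its amplitude, refitting after
each drop; (5) report the surviving in-bounds component (default
search bounds 15–40 h) of largest amplitude, or ARRHYTHMIC if none
survives with RAE ≤ 1.

**RAE.**  Amplitude half-widths use the joint-confidence-region
convention, `sqrt(p · F_0.95(p, n−p)) · σ_A`, with p the total number
of fitted parameters; RAE is that half-width over the amplitude.  The
joint region is deliberately wider than a marginal interval.  Because
components are seeded from the *largest* spectral peaks, the
significance level is additionally Bonferroni-adjusted for that
selection (conf^(1/m) per component for m seeds); without the
adjustment, noise-only traces pass as rhythmic ~8 % of the time
instead of ≤ 5 %.

**Window rule.**  The analysis window must span ≥ 1.5× the upper
period bound, so the conventional LL48–LL120 (72 h) window supports the
default 15–40 h bounds.

**What the recovery suite shows.**  The parameter-recovery panel uses
200 traces with periods 20–28 h, hourly sampling, damping up to
20 %/cycle, and SNR (amplitude over noise s.d.) drawn log-uniformly
from 5 to 50 — bright luciferase reporters span at least this range,
and 5 is kept as the hard floor.  Under these conditions the median
absolute period error is ~0.05 h and the maximum stays below 0.5 h.
Both bounds are information-limited at the hard corner: at SNR = 5 the
Cramér–Rao floor for the period on a 72 h window is ≈ 0.15 h s.d., and
combined with the ≈ 0.12 h bias that 20 %/cycle damping induces in an
undamped-cosine fit, occasional excursions near 0.5 h are expected for
traces drawn at that corner.

## Quantification formulas

Comparative CT: relative expression is 2^−(CT_target − CT_reference),
one value per technical replicate, then averaged; amplification
efficiency is fixed at 2 (no efficiency correction).  Undetermined CTs
are excluded and counted, not imputed.  Reports carry both s.d. and
s.e. over technical replicates.  Reporter series are normalised by the
(linearly interpolated) value at a reference time, e.g. LL14.  ChIP
enrichment is percent-of-input with dilution adjustment,
100 · 2^((CT_input − log2(1/f)) − CT_IP), ratioed between the target
amplicon and a negative-control amplicon (e.g. UBC21).

## Synthetic data

The luminescence generator emulates hourly-imaged seedling
bioluminescence over five days: cosine with geometric per-cycle
damping on a linear baseline plus i.i.d. Gaussian noise (additive
Gaussian because camera-integrated counts are high).  Damping is
parameterised per cycle so changing the period does not silently change
damping severity.  It does not model plate-position effects, vignetting
or non-stationary noise, so passing recovery tests establishes
estimator correctness under the assumed noise model, not robustness to
instrument artefacts.  The qPCR generator writes CT values through the
doubling law (CT_target = CT_ref − log2(level) + noise), so recovery
closes the loop against `qpcr`.  Every generator is seed-deterministic
and stores its ground truth in the output metadata.

`gen_screen_fixture` centres narrow (±0.05 decade) ranges on an
archived Model II parameter set found once by a seeded coarse search
and re-verified in CI, so full screen logic is exercised in seconds.

## Problem sizes

Default analysis scales, chosen as the package's study conditions: the
variant comparison screens 2×10^5 draws per variant with a matched
seed; the mutant period table uses every accepted set; FFT-NLLS
recovery uses 200 traces and the specificity check 100 noise
replicates; estimator cross-validation runs on every accepted set of a
2×10^4-draw screen.

## Known limitations

* The simplified models abstract away protein states, light input and
  the remaining PRRs; their screen statistics are qualitative
  (direction and significance), not quantitative reproductions.
* The comprehensive model is a structural analogue of the established
  multi-gene clock models, not a re-fit of any published parameter set;
  only the directional perturbation behaviours are claimed.
* FFT-NLLS assumes uniform sampling and stationary Gaussian noise; RAE
  is a linearised-covariance quantity and degrades for strongly damped
  or very short records.
* The screen's fixed-step kernel trades stiffness robustness for
  throughput; pathologically stiff parameter sets are rejected as
  NON_INTEGRABLE rather than resolved.
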