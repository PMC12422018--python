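# Methods

This note documents the model, the measurement definitions, the synthetic
data, and the numerical choices behind `crossfeed`, in the package's own
terms. Units are fixed throughout: rates in 1/h, lengths in μm, diffusion
in μm²/h, concentrations in units of the Monod constant.

## Community model

Each exchanged amino acid defines a producer→consumer direction with
parameters (u, l, μₙ, I_C):

- uptake is linear (non-saturating) at rate *u*; growth follows Monod
  kinetics μ = μₙ·I/(I+1); producers hold internal concentration I_C;
  leakage is passive at rate *l*; cells are homogeneously distributed and
  molecules diffuse only through the extracellular space,
  D_eff = (1−ρ)/(1+ρ/2)·D.
- Interaction range: with l̃ = lₙ/μₙ, α = ρ/(1−ρ),
  r₀ = √(D_eff/(α(uₙ+lₙ))) and a producer-flux parameter
  δ = (l_p I_C/2μₙ)·(2√(u_p+l_p)/(√(uₙ+lₙ)+√(u_p+l_p)))·((uₙ+lₙ)/(u_p+l_p)),

      R_int = r₀ · ln[ ((2l̃−δ)√(4δ+(l̃+δ)²) − δ(4+δ) + l̃(2l̃−3δ))
                       / (2l̃(l̃−δ) − δ) ]

  No low-leakage approximation is made. The numerator and denominator of
  the log argument share their root in δ (a removable singularity at
  δ* = 2l̃²/(1+2l̃)), so the expression is valid on both sides of δ*; the
  implementation raises a typed error only when the log argument is ≤ 1 or
  the denominator is exactly zero, carrying the offending intermediates so
  fitting code can penalize the trial point explicitly rather than receive
  a NaN. In a tiny neighbourhood of δ* the evaluation loses precision to
  cancellation; none of the fitting regimes approach it.
- Partner count: cells are spherocylinders (length L, width W); N is the
  shell volume within R_int of the cell surface over the cell volume, times
  ρ. N is used as a continuous, expectation-like weight — no rounding —
  because the composition formulas treat it as such and rounding would put
  steps into the fitting objective.
- Growth cap: Ê = l_p/(u_p+l_p)·I_C, Î the positive root of the
  uptake/leakage/growth-dilution balance, μ̂ = μₙ·Î/(1+Î).
- Equilibrium composition (death–birth dynamics on the interaction graph):

      f_ΔP = [μ̂_P(N_P−2)/N_P + (μ̂_P/N_P − μ̂_T/N_T)]
             / [μ̂_P(N_P−2)/N_P + μ̂_T(N_T−2)/N_T]

  The derivation assumes amino acids are always growth-limiting; for
  overproducers the raw value can leave [0,1], in which case it is clamped
  and flagged (`composition_out_of_bounds`) rather than erroring, so batch
  pipelines keep running with a diagnosable record. N ≤ 2 is an error: the
  formula's weights lose meaning there and no behaviour is defined for it.
- Relative growth: r_rel = f(1−f)/μₙ · [(N_P−2)/(N_P−1)·μ̂_P +
  (N_T−2)/(N_T−1)·μ̂_T]. When the two consumers' μₙ differ, the
  normalization uses their mean (they coincide for isogenic pairs).
- The agar beneath a colony acts as an absorbing boundary for leaked
  molecules; this is represented *only* as a lower "effective" leakage rate
  supplied by the caller (or recovered by the fit) — no separate correction
  is applied.

### Uptake scope

Uptake is a per-molecule property of the whole community in this model
(every cell imports a given amino acid at the same rate). A community-wide
uptake fold leaves Ê and (uₙ+lₙ)Ê — hence the growth caps — invariant, so
composition moves only through the partner count, while R_int shrinks as
1/√u: this is the model's uptake/leakage asymmetry, and the default scope
of `uptake_sweep`. A consumer-only scope (importer overexpression in one
strain) is available as an option; note that under that scope uptake and
producer leakage enter the growth cap through their product, so equal folds
shift composition comparably.

## Leakage inference

Effective leakage rates cannot be measured directly, so they are fitted:

- Baseline (two parameters, l_pro and l_trp): minimize
  ((f_pred−f_data)/f_data)² + ((r_pred−r_data)/r_data)² against the control
  community's mean observed composition and relative growth rate. The
  frequency term is evaluated on the tryptophan-auxotroph (minority)
  frequency, whose relative normalization is the informative one.
- Overproducers (one parameter): the overproduced amino acid's
  producer-side leakage is fitted to that community's composition alone,
  with the partner's leakage and the consumer-side leakage held at
  baseline; the result is reported as a fold change.
- Optimization is in log₁₀-leakage space, bounded, multi-start
  (Nelder–Mead from a seeded 16-point Latin hypercube); deterministic per
  seed. Default bounds are [u·10⁻⁶, u·10⁻³] per amino acid — leakage at
  least a thousandfold below uptake. Model-domain failures at a trial point
  return a finite penalty (10⁶) so bounded optimizers continue. Estimates
  within 0.1% (log-space) of a bound are flagged as pinned.
- When l ≪ u the model depends on l and I_C only through the product l·I_C,
  so fitted leakages automatically absorb changes in producer internal
  concentration; the joint-rescaling invariance is verified in the tests in
  the deep low-leakage regime (at moderate l/u the residual lₙ terms break
  it at the percent level).

### Synthetic study conditions

Recovery studies use the representative community (ρ = 0.65, D = 2×10⁵
μm²/h, L×W = 3×1 μm, u = 10³/h for both amino acids, μₙ = 0.5/h, I_C = 10)
with true leakages (l_pro, l_trp) = (0.02, 0.004)/h, chosen once: l/u ≤
2×10⁻⁵ respects the thousandfold prior; internal concentrations stay below
one Monod unit so growth is strongly amino-acid-limited (the regime the
composition formula assumes); and the resulting f_ΔP ≈ 0.65 makes the
proline auxotroph the majority strain, as observed in such communities.
Noisy-recovery experiments draw six replicate observations (multiplicative
Gaussian noise on f and r_rel) and fit their mean, mirroring how the real
measurements are summarized across six biological replicates; the 2×2
inverse problem amplifies observation noise by a factor ~3–4 in log-leakage
space, so fitting single noisy replicates would roughly triple the error.

## Image analysis

Per colony: maximum-intensity z-projection per channel; Otsu threshold per
channel (returned as the midpoint between the facing class extremes, so it
lies strictly between the classes); a 3×3 binary opening removes
salt-and-pepper speckle (a channel with no real signal otherwise thresholds
its noise into a percolating foreground); the colony mask is the union of
the two channels' foregrounds, hole-filled, largest connected component.
The second-moment ellipse (centre, a, b, φ) is mapped to an equivalent
circle of radius ρ₀ = (a+b)/2 by rotating the major axis onto x and scaling
by (ρ₀/a, ρ₀/b). Growth length is ρ₀ − ρ_c with the inoculum radius ρ_c
defaulting to 1.89×10³ μm (set by the deposited droplet volume;
configurable).

Within the 87.5–95% fractional-radius band (one concentric ellipse per
pixel of radial step), both channels are sampled by bilinear interpolation
at points uniformly spaced in arc length (step of one pixel); arc length
along an ellipse is the incomplete elliptic integral of the second kind,
evaluated via `scipy.special.ellipeinc`. Strain frequency is the intensity
ratio F_Y/(F_Y+F_B) summed over the band (raw intensities by default;
median-background subtraction is available as an option).

Sector width is a decorrelation length, not a geometric width: per ellipse,
the circular (periodic) autocorrelation of the mean-subtracted,
variance-normalized signal as a function of arc-length lag; the functions
are averaged across the colony's ellipses on a common lag grid (up to half
the smallest circumference), and the reported width is the smallest lag at
which the average first drops below 0.2 (linearly interpolated between lag
samples). Circular autocorrelation is the physically correct contract for
closed curves — linear autocorrelation would add artificial edge decay.
For an ideal alternating pattern with sector widths s_Y and s_B the lag is
0.8·s_Y·s_B/(s_Y+s_B) (0.4·s for equal widths), identical for both
channels; the generator's periodic mode reproduces this analytically.
Intensity (not binarized) signals are autocorrelated by default, since the
method's point is to avoid categorizing cells; a binary mode exists behind
a config switch. Widths are averaged across ellipses *within* a colony
before thresholding; across replicate colonies they are summarized by
medians.

Replicate outliers: an intercept-only Tukey bisquare fit (tuning constant
4.685, robust scale fixed at MAD/0.6745 about the median) — values with
exactly zero final weight are excluded and always listed. If the majority
of values coincide the robust scale is zero and any value off the median is
excluded; identical values are never excluded; two equal-sized clusters
exclude nothing.

Colonies touching the image border are flagged and measured anyway (with
edge-padded annulus sampling if the band leaves the frame) — real range
expansions can exceed the field of view. A blank image raises a
colony-not-found error.

## Synthetic colonies

The generator renders what the analysis assumes: an elliptical colony
(slight ellipticity, arbitrary orientation) with a mixed-speckle inoculum
disc of radius ρ_c and an annular expansion zone of radially coherent
sectors. Per-sector arc widths at the rim are lognormal around
2f·scale (yellow) and 2(1−f)·scale (blue) with configurable dispersion,
rescaled to tile the rim exactly; generation retries until the realized
yellow arc fraction is within 5% (relative) of the target. Sector
boundaries drift radially with independent Gaussian slopes. Intensities
carry Poisson shot noise and Gaussian read noise; the 15-plane z-stack
attenuates the in-focus signal toward the stack extremes so the maximum
projection recovers the ideal plane. Everything is reproducible bit-for-bit
from the spec's seed.

Ground truth includes the exact per-pixel label map and the noiseless
channel planes. Because the width metric is a lag statistic, its ground
truth is defined by applying the *identical* autocorrelation procedure to
the noiseless pattern with the true geometry — not by the geometric sector
width.

The default synthetic colony has ρ₀ = 540 μm and ρ_c = 180 μm at 1.3
μm/pixel — smaller than real range expansions (several mm) so rendered
images stay manageable; the analysis band, sector statistics and noise are
what the pipeline's validity depends on. What the generator does **not**
emulate: mechanistic pattern formation (sector statistics are imposed, not
emergent from the model), uneven colony boundaries, radial intensity
gradients, tile-stitching artifacts, or z-dependent pattern changes.
Passing round-trip tests therefore validate the measurement chain, not the
biology of pattern formation.

## Problem sizes and tolerances

The test suite and the acceptance script use: 20 random images for the
Otsu-vs-exhaustive comparison; 20 random (R, L, W, ρ) draws at 2×10⁵
Monte-Carlo samples for the partner-count oracle (agreement within 3
standard errors); arc length vs adaptive quadrature at 10⁻⁶ relative; a
3×3 grid of (fraction, sector scale) ∈ {0.25, 0.5, 0.75} × {10, 50, 200}
μm for the generator→analyzer round trip (frequency within 0.02, lag within
10% of the noiseless-pattern lag); and 20 repeat experiments of 6
replicates for the noisy-recovery study (median relative error < 10%).
Smaller colony geometries (ρ₀ = 270 μm, 3 z-planes) are used in unit tests
where only the measurement chain, not the default study conditions, is
under test.

## Known limitations

- The interaction-range expression loses precision near the removable
  singularity δ*; no compensated evaluation is attempted.
- The composition formula is clamped, not corrected, when growth limitation
  fails (overproducers); predictions there are flagged but quantitatively
  unreliable by construction.
- Effective leakage conflates membrane permeability with agar losses; only
  the product l·I_C is identifiable when l ≪ u.
- The annulus sampler assumes the fitted ellipse describes the colony rim
  well; strongly lobed colonies would need a boundary-following approach.
- Uncertainty on fitted leakages is reported only as restart dispersion and
  bound flags; no bootstrap confidence intervals are produced.
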