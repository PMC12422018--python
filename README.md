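# crossfeed

Tools for studying how amino-acid exchange shapes dense two-strain microbial
communities: an analytic cross-feeding model, inference of effective leakage
rates from observed community summaries, and an image-analysis pipeline that
quantifies sector patterns and strain frequencies in range-expansion
colonies — plus a seeded synthetic-colony generator so the whole pipeline is
testable with exact ground truth.

## The system

Two *E. coli* auxotrophs — ΔproC (cannot make proline) and ΔtrpC (cannot
make tryptophan) — grow together only by exchanging the amino acid each
partner lacks. Each cell takes up amino acids with a non-saturating rate
*u* (1/h), leaks them passively at rate *l* (1/h), and grows by Monod
kinetics μ = μₙ·I/(I+1) with the internal concentration *I* in units of the
Monod constant; producers hold a constant internal concentration I_C.
Molecules diffuse only between cells, so the solution diffusivity *D* is
reduced to D_eff = (1−ρ)/(1+ρ/2)·D at cell volume fraction ρ.

From these ingredients the model gives closed forms for:

- the **interaction range** R_int = r₀·ln(…), with
  r₀ = √(D_eff/(α(uₙ+lₙ))) and α = ρ/(1−ρ) — the length scale over which a
  leaked amino acid couples consumer growth to producer location;
- the **partner count** N: the number of cells within R_int of a
  spherocylindrical cell (length L, width W);
- the **growth cap** μ̂ = μₙ·Î/(1+Î): the best a consumer can do when fully
  surrounded by producers, with Ê = l_p/(u_p+l_p)·I_C;
- the **equilibrium frequency** f_ΔP of the proline auxotroph
  (death–birth dynamics on the interaction graph, finite-N corrected); and
- the **relative growth rate** r_rel of the cross-feeding community versus
  amino-acid-supplemented growth.

The model's central asymmetry: community-wide uptake changes reshape the
*spatial pattern* (R_int ∝ 1/√u) but barely move the *composition*, whereas
leakage changes move the composition strongly.

The image pipeline follows the corresponding experimental measurement:
maximum-intensity z-projection, Otsu segmentation of both fluorescence
channels, an ellipse fit mapped to an equivalent circle of radius
ρ₀ = (a+b)/2, sampling of both channels along concentric ellipses in the
87.5–95% radius band (uniform in arc length, one-pixel steps), strain
frequency f_yellow = F_Y/(F_Y+F_B), and a **sector width** defined as the
arc-length lag at which the ellipse-averaged circular autocorrelation of a
channel first drops below 0.2. Replicate outliers are removed by a Tukey
bisquare (zero-weight) rule.

## Worked example

```python
from crossfeed import default_community
from crossfeed.fitting import fit_baseline_leakage
from crossfeed.synthetic import (SyntheticColonySpec, generate_colony,
                                 generate_observations,
                                 ground_truth_measurements)
from crossfeed.imaging import AnalysisConfig, analyze_colony

community = default_community()          # rho=0.65, D=2e5 um^2/h, u=1e3/h ...
pred = community.predict(l_pro=0.02, l_trp=0.004)
print(f"f_dP = {pred.f_dP:.3f}   r_rel = {pred.r_rel:.3f}")
print(f"R_int(pro) = {pred.range_dP.R_int:.2f} um   N_dP = {pred.N_dP:.0f}")

obs = generate_observations(community, 0.02, 0.004, noise_sd=0.0,
                            n_replicates=1, seed=0)[0]
fit = fit_baseline_leakage(community, obs, seed=0)
print(fit.summary())

spec = SyntheticColonySpec(target_yellow_fraction=0.65, sector_scale=60.0,
                           seed=0)
image, truth = generate_colony(spec)
cfg = AnalysisConfig(rho_c=spec.rho_c)
meas, geom = analyze_colony(image, cfg)
gtm = ground_truth_measurements(truth, cfg)
print(f"measured f_yellow = {meas.f_yellow:.3f} "
      f"(ground truth {gtm['f_yellow']:.3f})")
```

prints

```
f_dP = 0.650   r_rel = 0.157
R_int(pro) = 8.10 um   N_dP = 971
Leakage fit results
================================================
  proline      l = 0.02 1/h  (bounds 0.001 .. 1)
  tryptophan   l = 0.004 1/h  (bounds 0.001 .. 1)
  objective     1.33008e-22
  converged     True  (restarts: 16)
  f_dP_pred     0.6502
  r_rel_pred    0.1572
measured f_yellow = 0.626 (ground truth 0.630)
```

At these leakage rates the proline auxotroph holds 65% of the community, the
community grows at 16% of its supplemented rate, and each cell interacts
with ~970 neighbours within an 8 μm range. The fit recovers the generating
leakage rates exactly (objective ~1e-22), and the image pipeline reproduces
the rendered colony's intensity-weighted strain frequency to better than
0.005.

A command-line interface wraps the same functionality
(`crossfeed analyze|aggregate|compare|predict|fit|sweep|simulate|report`);
see `crossfeed --help`.

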