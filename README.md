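# potlip

Pottery lipid residue analysis: from per-sherd fatty-acid δ13C
measurements to fat-source classification, Bayesian source
apportionment, and spatial surfaces of Δ13C and earliest Neolithic
arrival dates.

## The problem

Organic residues absorbed into archaeological ceramics preserve the two
dominant saturated fatty acids, palmitic (C16:0) and stearic (C18:0)
acid.  Their compound-specific carbon isotope values identify the animal
fats a vessel processed: the offset

```
Δ13C = δ13C_18:0 − δ13C_16:0        (‰ VPDB)
```

separates ruminant dairy (Δ ≤ −3.3‰), ruminant carcass (−3.3 < Δ <
−1.0‰) and non-ruminant fats (Δ ≥ −1.0‰), while the joint
(δ13C16:0, δ13C18:0) position is compared with 68% confidence ellipses
of modern reference fats (Suess-corrected for the industrial-era decline
of atmospheric δ13C).  For whole assemblages, a Bayesian
concentration-weighted mixing model apportions lipid weight among four
source classes (marine oils, ruminant adipose, ruminant dairy,
non-ruminant fats) from a region's median proxy pair:

```
μ_k = Σ_i f_i·c_ik·δ_ik / Σ_i f_i·c_ik ,   y_k ~ N(μ_k, 0.5‰)
f ~ Dirichlet(1, …, 1)
```

Spatial structure is modelled two ways: a thin-plate-spline GAMM with
site random intercepts (`Y_ij = s(lon, lat) + u_i + ε_ij`) interpolates
Δ13C across the study area with a standard-error mask, and a penalised
quantile regression at τ = 0.005 maps the earliest arrival of farming
as an extreme-quantile surface of site dates rather than a fragile
minimum.  A synthetic-data generator reproduces the full study
structure (sources, regional mixtures, latitudinal gradients, arrival
dates) so every stage is testable end to end and parameter recovery is
measurable.

The audience is archaeological-science groups doing organic residue
analysis who want the interpretation chain — screening, classification,
mixing, interpolation — as reviewable, reproducible code rather than a
spreadsheet plus GUI tools.

## Worked example

```python
import potlip
from potlip.mixing import DEFAULT_SOURCE_ORDER, MixingModel, MixingProblem

# synthetic Atlantic-transect study: 640 sherds, 56 sites, 120 reference fats
bundle = potlip.end_to_end(potlip.default_scenario(seed=1))
groups = potlip.fit_all_groups(bundle.reference_fats)   # Suess-corrected
classified = potlip.classify_samples(bundle.sherds, groups)

atlantic = [c for c in classified if c.region != "Western Baltic"]
rho, p, n = potlip.latitudinal_gradient(atlantic, bundle.sites)
print(f"Spearman rho = {rho:.2f} (p = {p:.2e}, n = {n})")

m16, m18, nr = potlip.regional_medians(
    classified, "Northern England, Ireland and Scotland")
sources = [groups[c] for c in DEFAULT_SOURCE_ORDER]
res = MixingModel(MixingProblem(y=(m16, m18), sources=sources)).fit(seed=1)
print(res.summary().round(3))
```

prints

```
Spearman rho = -0.55 (p = 1.40e-43, n = 544)
                   mean  median  ci68_lo  ci68_hi  ci95_lo  ci95_hi   rhat  ess_bulk
source
marine_oil        0.086   0.074    0.023    0.151    0.004    0.233  1.007  1146.015
ruminant_adipose  0.245   0.219    0.074    0.419    0.012    0.647  1.001  1089.831
ruminant_dairy    0.596   0.622    0.451    0.738    0.242    0.820  1.001  1776.471
non_ruminant      0.072   0.063    0.017    0.128    0.002    0.192  1.006   505.301
```

The negative Spearman coefficient is the designed latitudinal gradient:
Δ13C falls northward as dairy fats become more frequent.  The mixing
summary says ~60% of lipid weight in the northern region's pottery is
dairy fat (posterior median 0.62, 68% CI 0.45–0.74), with wide intervals
on the remaining sources — an honest statement of the equifinality of a
four-source/two-proxy problem.  `rhat`/`ess_bulk` are convergence
diagnostics (split-Rhat ≤ 1.05 indicates well-mixed chains).

The same pipeline is scriptable from a shell:

```sh
potlip --seed 1 --out-dir out simulate
potlip --out-dir out screen   --sherds out/sherds.csv
potlip --out-dir out classify --sherds out/sherds.csv \
       --sites out/sites.csv --refs out/reference_fats.csv
potlip --out-dir out mix      --sherds out/sherds.csv --refs out/reference_fats.csv
potlip --out-dir out surface  --sherds out/sherds.csv --sites out/sites.csv
potlip --out-dir out spread   --sites out/sites.csv
```

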