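# Methods

This note records the models implemented in `invrisk`, the parameters
that matter, the synthetic study system, and the numerical choices made
where the design was genuinely open.

## Spatial model

All rasters are regular lat-lon grids of square cells (`GridSpec`),
stored north-up (row 0 = northernmost, matching the ESRI ASCII layout)
with NaN as the internal nodata value. Point-in-cell lookups use
half-open cells: a point on an edge belongs to the cell with index
`floor((coord − origin)/cell_size)`. The on-disk format is the ESRI
ASCII grid only — plain text, diffable, and readable by every GIS;
non-square cells are rejected rather than resampled, and reprojection
is out of scope: inputs must arrive co-registered.

Areas are geodesic on a sphere of radius R = 6371 km: a cell spanning
latitudes [φ₁, φ₂] with longitude width Δλ has area
`R²·Δλ·(sin φ₂ − sin φ₁)`. All habitat areas are sums of these
latitude-dependent cell areas, never cell counts.

## Bioclim covariates

`derive_bioclim` computes the 19 standard bioclimatic summaries
(BIO1–BIO19) from monthly tmin/tmax/prec climatologies, with
`tmean = (tmin + tmax)/2`, temperatures in °C and precipitation in mm
(no integer ×10 packing). Quarters are circular windows of three
consecutive calendar months; ties between windows resolve to the
earliest in calendar order, which makes the derivation deterministic.
Two conventions worth stating: BIO4 is the *population* standard
deviation of monthly means ×100, and BIO15 is the coefficient of
variation of monthly precipitation with the mean offset by +1 mm so
fully arid cells stay defined. BIO3 (isothermality) is set to 0 where
the annual range BIO7 is 0 (both BIO2 and BIO7 vanish together only in
a perfectly constant climate).

## Occurrences

Cleaning drops rows with missing, non-numeric or out-of-range
coordinates and reports counts. Thinning keeps the first record per
grid cell (deterministic, order-stable) and removes records on nodata
cells; it is on by default because duplicate records within one cell
would otherwise pseudo-replicate at the model's grain. The train/test
split is uniformly random by record — no spatial blocking — with
`|train| = round(0.75·n)` clamped so both parts are non-empty.

## Covariate selection

Collinearity screening is sequential: a pairwise Pearson prefilter
(while any |r| > 0.7 strictly, drop from the worst pair the variable
with the larger mean |r| against the remaining set; ties drop the
later-input variable) followed by iterative VIF elimination (drop the
largest `VIF_j = 1/(1 − R²_j)` while it exceeds 10). Zero-variance
variables are removed first, and perfect collinearity yields an
infinite VIF and a drop, never an exception. The screening matrix is
the model's background sample, so selection reflects the fitting
domain rather than the whole globe. Both thresholds are parameters.

## Maxent suitability model

The core model is the presence-background maximum-entropy estimator:
a Gibbs distribution `q_λ(x) = exp(λ·f(x))/Z_λ` over the background
cells, fitted by maximising the penalised presence log-likelihood

    (1/n) Σᵢ λ·f(xᵢ) − log Z_λ − Σⱼ βⱼ|λⱼ|,   βⱼ = r · max(sⱼ, 10⁻⁶)/√n

with `sⱼ` the presence standard deviation of feature j and `r` the
regularisation multiplier (default 1.0). Features default to linear +
quadratic terms of each covariate after min-max scaling to [0, 1] on
the background; transform values are clamped to [0, 1] so projection
onto novel climates never extrapolates features. Hinge features exist
behind a flag but are off by default — the small default feature space
keeps the optimum verifiable against independent numeric optimisation.

The objective is convex; it is minimised by FISTA (accelerated proximal
gradient) with backtracking line search, momentum restart on objective
increase, exact soft-thresholding for the L1 term, relative objective
tolerance 1e-6 and a 5000-iteration cap. At convergence the KKT box
condition `|E_q[fⱼ] − presence mean fⱼ| ≤ βⱼ` holds for every feature;
the fitted model stores its violation so callers can assert it.
Presences are not removed from the background (background = landscape
sample). Prediction uses the logistic transform
`p = e^H q̃/(1 + e^H q̃)` with `q̃ = exp(λ·f − log Z)` and `H` the
entropy of the fitted distribution over the background, so a cell
indistinguishable from average background scores exactly 0.5. Models
serialise to JSON (scaling constants, λ, β, log Z, H, seed), making
projections reproducible without refitting.

## Evaluation and classification

AUC is the Mann–Whitney statistic with midrank ties, computed presence
vs background (no true absences exist in presence-only data);
held-out AUC uses the 25% test presences against a *fresh* seeded
background sample of the same size as the training background.
Discrimination labels: > 0.7 good, > 0.8 very good, > 0.9 excellent,
each band open at the bottom.

Two thresholds cut continuous suitability into classes: LTP (minimum
training-presence score; 100% training sensitivity by construction)
bounds *suitable low-risk habitat*, and maxSSS (the candidate score
maximising sensitivity + specificity, ties to the smallest candidate;
specificity measured against the background sample) bounds *suitable
high-risk habitat*. Both comparisons are inclusive (≥). With very few
presences LTP can exceed maxSSS; the pair is then collapsed
(t_high := t_low) and flagged rather than failed. Thresholds are
computed on training data only and applied unchanged to both climate
projections.

## Habitat change and prioritisation

Change in a habitat class between baseline and future is summarised as
delta (km²), percent change and future/baseline ratio; a zero baseline
leaves the relative metrics undefined (reported as empty, never a
division error) and raises a new-habitat flag. Headline change numbers
refer to the high-risk class by default (a flag switches to low+high).

The combined priority ranking is lexicographic: invasiveness category
tier (descending), then high-risk delta (descending), then species name.
The rule is deliberately simple and order-free; both the absolute delta
and the ratio are emitted because neither alone captures "21× from a
tiny base" vs "large absolute gain". Management tiers: `high` needs at
least Highly Invasive *and* growing habitat; `low` needs at most
Modestly Invasive *and* no growth; everything else is `watch`. A
three-column comparison table (risk-only / habitat-only / combined
ordering) makes visible where single-axis prioritisation misleads.

## Risk scoring

The scoring engine is schema-driven: criteria with point-valued answer
levels, grouped into the four standard attributes. The score is
`100 · Σ earned / Σ max` over *answered* criteria only, so unknown
traits neither reward nor punish; the answered fraction is reported and
results below 80% answered are flagged "insufficient information"
(configurable). Category bands are half-open: [80, 100] Extremely,
[70, 80) Highly, [60, 70) Moderately, [50, 60) Modestly, [40, 50)
Weakly, [0, 40) Very Weakly Invasive. The shipped default schema has
21 criteria totalling 100 points (40 ecological impact / 25 invasive
characteristics / 25 dispersal / 10 feasibility of control); its
prompts and point values are an editable default, not a normative
instrument — the scoring and band mathematics are the fixed part.

## Synthetic study system

The generator emulates the minimum structure the pipeline needs:

* **Climate.** Monthly mean temperature
  `t_ref − g·|lat| + A·cos(2π(m−7)/12) + ε` (defaults t_ref = 30 °C,
  g = 0.6 °C/deg, A = 15 °C), tmin/tmax at ±5 °C around it, and
  precipitation with analogous structure clipped at 0 (50 mm/month
  base, +1 mm/deg northward, ±20 mm seasonal). ε is seeded white noise
  smoothed with a Gaussian kernel (σ = 2 cells) — spatially
  autocorrelated without geostatistical machinery — and is shared
  between scenarios, so the future is *exactly* baseline + ΔT (default
  +3 °C) and ×1.1 precipitation. The default landscape is 100×100
  cells of 0.2°, latitudes 40–60 N.
* **Species.** A Gaussian niche in (BIO1, BIO12) with optima
  (8 °C, 700 mm) and breadths (2.5 °C, 400 mm):
  `s(x) = exp(−Σ (v−μ)²/2σ²)`, truly suitable where s ≥ 0.5. The
  thermal optimum sits warmer than almost the entire baseline
  landscape, so uniform warming must expand the truly suitable area —
  a known-sign truth for recovery tests. The breadth was set so the
  niche is strong by construction: scoring cells by the *analytic*
  suitability discriminates presences from background at AUC ≈ 0.89,
  an upper bound any fitted model can approach but not exceed.
* **Presences.** n cells (default 500) drawn with replacement with
  probability ∝ s, placed at cell centres; per-cell thinning dedupes
  them downstream. A niche-free variant samples uniformly over valid
  cells for null calibration.

What the generator does **not** emulate: topography, coastlines and
irregular study-area masks, sampling bias (roadside/herbarium effects),
coordinate error, spatial disequilibrium between occurrences and
climate, and non-uniform climate change. Passing tests therefore show
the machinery is correct and calibrated on clean data; they do not show
robustness to the biases real occurrence data carry.

## Problem sizes and validation experiments

Two seeded experiments quantify behaviour with known truth, sized to
run comfortably on one CPU (~5 s and ~20 s respectively):

* **Null calibration** — 50 replicates on a 60×60 grid, 200 uniform
  presences each: mean held-out AUC 0.50 (seed 1), i.e. the evaluation
  invents no discrimination where none exists. `scripts/acceptance.py`
  recomputes exactly this number.
* **Parameter recovery** — 20 replicates at full default size: the sign
  of the estimated high-risk area change matched the true suitable-area
  change in 20/20 seeds and held-out AUC was ≥ 0.85 in 20/20 (seed 1).

The estimated high-risk area does not numerically equal the true
s ≥ 0.5 area — maxSSS is a different, more inclusive cutoff and the
logistic output is not the true suitability — which is why recovery is
judged on the sign of the change, a quantity invariant to the cutoff
mismatch.

## Determinism

Every stochastic stage (noise fields, presence sampling, train/test
split, background samples) draws from a seed derived deterministically
from one master seed (per-species seeds mix in a CRC of the species
name so adding a species does not reshuffle the others). Two runs with
the same configuration produce byte-identical output tables; the run
manifest records seed, parameters and package version.

## Known limitations

* Linear + quadratic features cannot represent sharply asymmetric or
  multimodal responses; hinge features are available but unvalidated
  against an external implementation.
* The background-as-pseudo-absence convention makes AUC values
  prevalence-dependent; they are comparable within this pipeline, not
  across datasets with different background schemes.
* The collinearity screen is purely statistical; it may discard the
  mechanistically relevant member of a correlated pair.
* Occurrence ingestion assumes coordinates are trustworthy; there is no
  coordinate-uncertainty or outlier filtering.
* The priority rule treats all high-risk cells as equal — no habitat
  quality, dispersal constraint or protected-area weighting.
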