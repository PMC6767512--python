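# geodefol

Object-based mapping of insect defoliation in broadleaf forests, and
panel-data analysis of the climate and fire hazards that trigger it.

Insect defoliators (e.g. *Lymantria dispar*, *Erannis defoliaria*,
*Operophtera brumata*) strip canopy foliage, which raises green/red
reflectance and depresses NIR/SWIR reflectance in medium-resolution
satellite imagery. `geodefol` implements the full analysis chain a
forest-disturbance remote-sensing study needs, on synthetic scenes with
known ground truth or on user-supplied rasters and tables:

1. **Segmentation** — multiresolution pairwise region merging. A merge of
   adjacent regions is admissible while the weighted heterogeneity
   increase stays below the squared scale parameter:
   `Δh = w_shape·Δh_shape + (1−w_shape)·Σ_b w_b [n_m σ_b(m) − n_a σ_b(a) − n_b σ_b(b)]`,
   accepted when `Δh < scale²`, with mutual-best-fit scheduling.
2. **Object features** — 95 per-object features: band and spectral-index
   means/sds (NDVI, NDWI = (NIR−SWIR1)/(NIR+SWIR1), GEMI, IPVI, ARVI,
   EVI2, GVI, tasseled-cap brightness/greenness/wetness, max. band
   difference), six principal-component means, eight GLCM texture
   statistics per band, geometry (area, compactness, asymmetry), terrain
   (TWI, TPI, TRI) and majority forest type.
3. **Classification** — TreeNet-style stochastic gradient boosting on the
   log-odds scale: `f(x) = f₀ + ν Σₘ Tₘ(x)` with ≤6-leaf least-squares
   trees fitted stagewise to pseudo-residuals `y − p` on random
   half-samples, Newton leaf values `Σ(y−p)/Σp(1−p)`, ensemble size
   chosen by test ROC area, split-gain variable importance rescaled to
   top = 100, partial-dependence curves, and a ≥15%-importance refit.
4. **Hazard scoring** — monthly anomalies `z = (x−μ_m)/σ_m` (SPI via a
   per-month gamma fit for precipitation), yearly exceedance dimensions
   (severity Σ|z|, frequency, duration beyond |z| > 1), fuzzy
   linear/large memberships, and the fuzzy-gamma overlay
   `μ_γ = (1 − Π(1−μᵢ))^γ · (Πμᵢ)^(1−γ)`; ground-based fire severity
   from event frequency, burned area and burn duration.
5. **Panel econometrics** — balanced object × year panels
   `y_it = β′x_it + z_i α + ε_it` fitted by pooled OLS, fixed effects
   (within) and random effects (Swamy–Arora GLS,
   `θ = 1 − √(σ²_ε/(σ²_ε + T σ²_α))`), with the Chow poolability test and
   the Hausman FE-vs-RE contrast (χ² upper tails computed in-package).

A synthetic-data module generates Landsat-like six-band scenes with
irregular defoliated patches, correlated DEMs, monthly climate panels
with a known regression structure, and Poisson fire records, so every
stage is testable end to end without external data.

## Worked example

```bash
python examples/05_panel_models.py
```

prints (abridged):

```
true coefficients: {'fire_l1': 0.19, 'drought_t': 0.15, 'drought_l1': 0.05,
                    'tmax_t': 0.72, 'tmax_l1': 0.32, 'soilm_t': 0.15, 'soilm_l1': -0.13}
        constant  fire_l1  drought_t ...  tmax_t   tmax_l1   soilm_l1     R2
common     0.255  0.019 ns  0.168 ns ...  0.729**  0.320**  -0.229 ns  0.843
fixed      0.246  0.056 ns  0.300 ns ...  0.681**  0.278**  -0.257 ns  0.634
random     0.221  0.052 ns  0.248 ns ...  0.723**  0.318**  -0.233 ns  0.724

Chow    X2=121.97  df=18  p=0.000
Hausman X2=  8.67  df=7  p=0.277
```

On this 19-object × 8-year panel the strong heat coefficients (true
0.72/0.32) are recovered with two-star significance; the Chow test
rejects pooling (object intercepts matter), and the Hausman test's large
p-value says the efficient random-effects estimator is consistent.
`examples/01`–`04` walk the other capabilities (segmentation, the
95-feature table, the boosted classifier, hazard indices) the same way,
and `geodefol all --config <yaml> --seed <n> --out <dir>` runs the whole
pipeline from a single config.

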