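# iadfnet

Analysis pipeline for **intra-annual density fluctuations (IADFs)** in
European tree-ring networks.

IADFs are bands of latewood-like cells inside the earlywood (or vice versa)
that record within-season switches in cambial activity — typically a summer
drought pause followed by autumn re-activation.  Given a network of ring-width
series with per-ring IADF presence flags, site metadata and monthly climate,
`iadfnet`:

1. builds per-site/species **IADF frequency chronologies** with four
   standardizations — the relative frequency `F = N/n` (N rings with an IADF,
   n readable rings that year), the sample-depth-stabilized frequency
   `f = F·√n`, and residuals of `F` from a 3-parameter Weibull-peak curve in
   cambial age or a 3-parameter Chapman–Richards curve in ring width;
2. computes **annual climate summaries and SPEI-6** (standardized
   precipitation–evapotranspiration index: 6-month water-balance sums,
   per-month log-logistic fit by L-moments, normal-quantile transform) from
   monthly temperature and precipitation alone (Thornthwaite PET);
3. clusters sites on z-scored monthly climatologies plus coordinates with
   deterministic **PAM (k-medoids)**, choosing k by mean silhouette;
4. fits a semiparametric **zero-adjusted gamma (ZAGA) regression**

   ```
   IADF_cf = alt + f(lat) + f(rw) + tp*species + temp*species + SPEI*species + cluster
   ```

   as a hurdle: a Bernoulli model for the exact zeros and a penalized gamma
   log-link regression on the positive frequencies, with Eilers–Marx
   P-splines (cubic B-splines, second-order difference penalty, GCV-chosen
   smoothing) for latitude and ring width, and species-specific climate
   slopes summarized as a `+` / `−` / `n.s.` effect table;
5. screens monthly **Pearson climate–frequency correlations** and reports
   which standardization carries the strongest climate signal.

A fully synthetic network generator (sites in four climate archetypes,
eleven species with realistic growth curves and climate-driven IADF
occurrence) makes every stage testable without any data download.

## Worked example

```python
from iadfnet.pipeline import PipelineConfig, run

result = run(PipelineConfig(sites_per_archetype=4, seed=1), "out/demo")
print(result)
```

```
{'n_series': 240, 'n_rings': 13195, 'selected_k': 4,
 'mean_silhouette': 0.741, 'r_squared': 0.599, 'converged': True,
 'nu': 0.111, 'cvm_p': 0.086, 'best_method_mode': 'age_detrended'}
```

Reading the output: 240 simulated cores (13 195 rings) were aggregated into
site×species chronologies; silhouette-guided PAM recovered the four climate
archetypes (`selected_k = 4`, mean silhouette 0.74); the ZAGA model explains
about 60 % of the response variance (squared correlation of fitted vs
observed frequency); 11 % of chronology-years had no IADF at all (the zero
mass `nu`); the Cramér–von Mises p-value of 0.086 means the randomized
quantile residuals show no significant departure from normality; and for
most chronologies the age-detrended frequency correlated most strongly with
monthly climate.  The run directory contains every intermediate artifact
(RWL, flag/site/climate CSVs, chronologies, cluster assignment, fit JSON,
effect-sign table, correlation table, log).

The same pipeline runs from the shell:

```bash
iadf run --seed 1 --out out/demo
iadf simulate --seed 1 --out out/data            # just the synthetic files
iadf cluster --sites out/data/sites.csv --climate out/data/climate.csv --out out/clusters.csv
```

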