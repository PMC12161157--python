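# fgmq — data quality of self- vs proxy-reported FGM survey data

`fgmq` is an analysis pipeline for assessing the quality of reported **age
at female genital mutilation (FGM)** in household survey microdata, where
the same outcome is collected two ways: women aged 15–49 report on
themselves (*self-report*), and mothers report on their daughters under 15
(*proxy report*). Because the two collection modes differ in recall
accuracy, pooled trend estimates of the age at FGM can be distorted unless
the modes' data quality is compared explicitly. The package provides that
comparison for harmonized multi-wave survey series (DHS-style designs) and
ships a synthetic-data generator so every stage is testable without
restricted-access microdata.

## What it computes

Given harmonized respondent-level CSV microdata (one row per woman or
daughter; see the schema in `fgmq.schema.COLUMNS`) and per-survey eligible
population totals, the pipeline:

1. **Pools surveys** by denormalizing each wave's normalized sample
   weights: `w_denorm_i = w_norm_i * T_s / Σ_{j∈s} w_norm_j`, so each
   survey's weights sum to the eligible population `T_s` of its year.
2. **Cleans records**: drops internally inconsistent rows
   (`age_at_fgm > current_age`, audited) and resolves approximate
   *"during infancy"* answers by redistributing them over ages 0–5
   according to each survey's distribution of precise young-age answers
   (deterministic fractional splitting by default, or seeded stochastic
   assignment); the weighted FGM-positive mass is conserved exactly.
3. **Profiles completeness**: among FGM-positive respondents, the weighted
   share with missing age at FGM, by current age and module.
4. **Measures age heaping** at target ages *a* ∈ {5, 10, 15} with the
   smooth-transition index
   `ratio(a) = C(a) / [(C(a−1) + C(a+1)) / 2]`,
   where `C(x)` is the weighted count of FGM at age *x* — the observed
   count against the count expected under local linearity (classical
   Whipple/Myers indices do not apply below age 10).
5. **Models completeness** with a survey-weighted logistic regression
   (outcome: age reported vs missing, on FGM-positive records) controlling
   for survey wave, module, age, education and date-of-birth completeness.
   Variance is design-based Taylor linearization: score residuals
   aggregated to PSU totals, centered within strata with the
   `n_h/(n_h−1)` factor, sandwiched through the weighted information;
   CIs use *t*(#PSUs − #strata).
6. **Estimates medians**: lower weighted median age at FGM by birth cohort
   for each module and both pooled, plus unweighted composition tables.

## Worked example

```python
import fgmq

cfg = fgmq.preset_paper_like(scale=0.6)          # ten-wave synthetic series
records, truth = fgmq.generate(cfg, seed=1)      # ~114 000 respondents

pooled = fgmq.denormalize(records, cfg.totals_frame())
kept, audit = fgmq.exclude_inconsistent(pooled.records)
clean = fgmq.InfancyRedistributor().fit_transform(kept)

heap = fgmq.heaping_index(clean).set_index(["module", "age"])
print(round(heap.loc[("women", 5), "ratio"], 2),
      round(heap.loc[("daughters", 5), "ratio"], 2))
# 2.54 1.0

model, table, info = fgmq.completeness_model(clean)
print(table.set_index("term").loc["module[women]",
      ["odds_ratio", "ci_low", "ci_high"]].round(3).to_dict())
# {'odds_ratio': 0.154, 'ci_low': 0.118, 'ci_high': 0.2}
```

The women's (self-reported) module shows strong heaping at age 5
(2.5× the smooth-transition expectation) while the proxy-reported
daughters' module does not (ratio ≈ 1), and the odds of complete age
reporting in the women's module are about 0.15× those of the daughters'
module — the quality contrast the pipeline is designed to expose. The
command line runs the same pipeline end to end:

```bash
fgmq all --seed 1 --out-dir out/          # tables, figure data, manifest
```

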