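# isobolo

Fixed-ratio isobolographic analysis of drug-combination antinociception
data: log-dose linear regression of %MPE dose-effect tables, ED estimation
with delta-method variances, variance-weighted fixed-ratio mixture design,
and a composite t comparison of the experimental mixture ED against the
theoretical additive ED (Loewe additivity), including the interaction index
and isobologram coordinates.

The package ships five curated per-animal dose-effect tables (two single
drugs over two routes, plus both fixed-ratio combination experiments) and a
synthetic-data module that generates whole combination experiments with a
known ground-truth interaction index, so every stage of the pipeline is
testable end to end.

## Library overview

```python
import isobolo as ib

table_a = ib.load_fixture("sb_ipl")        # SB366791 intraplantar, N=60
fit = ib.fit_log_dose(table_a)             # OLS of %MPE on log10(dose)
test = ib.slope_test(fit)                  # b / sqrt(V(b)) vs tabular t
ed = ib.effective_dose(fit, gamma=20)      # ED20 + log-scale variance

ed_b = ib.effective_dose(ib.fit_log_dose(ib.load_fixture("pha_ipl")))
design = ib.design_mixture(ed, ed_b)       # f = V(B)/(V(A)+V(B)), doses
ladder = ib.dose_ladder(design)            # x3 geometric series of pairs

z_add, var_add = ib.theoretical_additive(ed, ed_b, design.f)
ed_mix = ib.effective_dose(ib.fit_log_dose(ib.load_fixture("combo_ipl_ipl")))
result = ib.composite_t_test(z_add, var_add, fit.df,
                             ed_mix.ed, ed_mix.variance, ed_mix.df)
result.verdict            # 'synergistic' | 'additive' | 'sub-additive'
result.alpha_index        # interaction index Z_mix / Z_add
```

Modules: `isobolo.io` (tables, %MPE, CSV I/O, fixtures), `isobolo.regression`
(fits, slope test, effective doses), `isobolo.design` (proportion factor,
dose ladder), `isobolo.additivity` (Z_add, composite t test, interaction
index, isobologram), `isobolo.simulate` (synthetic experiments),
`isobolo.cli` (command line and full pipeline).

Two critical-value modes exist everywhere a tabular t is used:
`paper-compat` (the default) fixes it at the large-sample 1.96; `strict`
uses exact Student quantiles at N-2 degrees of freedom.

## Command line

```sh
isobolo fit --input sb_ipl --gamma 20
isobolo design --drug-a sb_ipl --drug-b pha_ipl
isobolo test --drug-a sb_ipl --drug-b pha_ipl --mixture combo_ipl_ipl \
             --mode paper-compat --outdir report/
isobolo simulate --config sim.yaml --outdir simdata/ --seed 7
```

`--input`/`--drug-*`/`--mixture` accept either a CSV path or a bundled
fixture name (`sb_ipl`, `pha_ipl`, `pha_it`, `combo_ipl_ipl`,
`combo_ipl_it`). CSV dialect: header `regimen,dose,unit,response`
(`nmol/site` or `pmol/site`; everything is converted to nmol/site on read),
`#` comment lines allowed. `isobolo test --outdir` writes regression
summaries, the one-row comparison report, the interaction index, the dose
ladder, isobologram coordinates and a full-precision JSON log.

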