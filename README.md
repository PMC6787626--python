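# wstkit

Severity analysis for clinical cohorts built around the **weighted standing
time** (WST), an orthostatic-intolerance score:

```
WST = standing_time_minutes * (1 - difficulty / 14)
```

Standing time is recorded on a 2-minute grid (0–20 min). Participants who
complete the 20 minutes report a 0–10 difficulty; early stops receive fixed
codes (14 below 10 minutes, 12 between 10 and 20). From this the package
derives a 4-class severity label (healthy / mild / moderate / severe) and a
merged 3-class label (healthy+mild, moderate, severe) used for modelling.

The pipeline:

1. **synthetic cohort** — seeded generator with log-normal per-class marker
   marginals fitted to (median, q25, q75) targets, class-consistent
   standing-test pairs, configurable POTS prevalence and missingness in
   24-h urine markers. Markers are generated independently within class;
   no correlation structure is imposed (documented limitation).
2. **scoring** — WST, difficulty coding, POTS detection (HR rise ≥ 30 bpm
   on standing), severity classes.
3. **preprocessing** — one-sample Kolmogorov–Smirnov normality screen,
   class-median imputation (allow-listed markers only), median/IQR
   descriptives with a single repo-wide linear-interpolation quantile
   convention.
4. **nonparametric tests** — Mann–Whitney U, Kruskal–Wallis, and a
   from-scratch Jonckheere–Terpstra trend test (exact permutation p for
   total n ≤ 12, tie-corrected continuity-corrected normal approximation
   otherwise). A marker is flagged *robust* when both KW and J-T are
   significant at α.
5. **severity model** — seeded bootstrap random forest (defaults mtry=4,
   ntree=5000, sampling with replacement) over scikit-learn CART trees with
   full out-of-bag (OOB) bookkeeping: per-case OOB vote fractions,
   confusion/error rates, Gini importance and permutation importance
   (mean decrease in OOB accuracy). Also: pruned single decision trees for
   threshold rules, Cohen's kappa, and a repeated-CV ensemble comparison
   (RF / gradient boosting / SVM / boosted trees).
6. **ROC** — pairwise ROC/AUC between severity classes from OOB vote
   fractions, optionally restricted to correctly (OOB-)predicted cases.
7. **reference intervals** — median and 25th–75th IQR per marker per group
   with overlap reports. Note these are comparison bands, *not* clinical
   2.5–97.5 % reference ranges.

## CLI

```sh
wstkit synth --seed 1 --out cohort.csv          # synthetic cohort (97 rows)
wstkit score --input cohort.csv --out scored.csv
wstkit impute --input scored.csv --out imputed.csv
wstkit test  --input imputed.csv --out tests.tsv
wstkit model --input imputed.csv --out rf.json --ntree 500
wstkit roc   --input imputed.csv --out roc.tsv --pair 0 1 --correct-only
wstkit ri    --input imputed.csv --out intervals.tsv
wstkit run   --seed 1 --out-dir out/            # full pipeline + report.md
```

`wstkit synth --config cfg.yaml` accepts a YAML file mirroring
`CohortConfig` (class sizes, per-class marker quantile specs, missingness
rate, difficulty ranges, POTS rates). Without a config the bundled
per-class summaries for a 97-participant cohort (classes 17/19/38/23) are
used.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by stable hashing, so equal config and
seed yield byte-identical output bundles.
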