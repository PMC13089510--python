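# linkaudit

Evaluation pipeline for comparing two patient record-linkage engines across
two health-system registries:

- a **privacy-preserving token engine**: PII is normalized and reduced to
  arrays of one-way HMAC-SHA256 hashes of 18 feature combinations; candidate
  pairs are scored by weighted Jaccard token agreement, mapped through a
  monotone (isotonic) calibration to a 0–100 match-probability score, and cut
  at a strict/balanced/permissive (98/95/90) threshold family with structural
  containment;
- a **rule-based deterministic engine**: 12 weighted identifier comparisons
  (exact/soundex name, exact DOB, year of birth, email, phone, ...; SSN
  deliberately excluded) with a uniqueness-qualified point threshold.

Every cohort patient is placed in one of 8 exclusive agreement categories,
stratified audit samples are drawn from the 6 disagreement categories and
adjudicated (against simulation ground truth, or ingested from a completed
review file), and per-category false-match rates with exact
(Clopper–Pearson) binomial CIs are projected to the population to yield
per-algorithm precision and recall against the union proxy gold standard:

```
precision_a = (M_a − FM_a) / M_a          recall_a = (M_a − FM_a) / matches_any
```

A synthetic two-site registry generator (overlapping populations, ground-truth
linkage ledger, twins, common names, typos, nicknames, compound-surname
variants, stale contacts, per-field missingness) makes the whole pipeline
testable with no external data. Replication mode re-runs the estimation chain
on count tables from a published two-health-system evaluation, shipped as
package fixtures.

## CLI

```bash
# end-to-end synthetic run (simulate → tokenize → match → partition →
# sample → adjudicate → estimate), artifacts + manifest in OUT
linkaudit run-synthetic --config config.yaml --seed 7 --out OUT/

# replication mode: estimation chain over the packaged published count tables
linkaudit run-replication --out replication.json

# individual stages
linkaudit simulate --seed 1 --out sim/
linkaudit tokenize sim/registry_site_a.csv --salt "$LINKAUDIT_SALT" --out tok_a.csv
linkaudit match rule sim/registry_site_a.csv sim/registry_site_b.csv --out rule.csv
linkaudit match pprl tok_a.csv tok_b.csv --out pprl.csv
linkaudit partition rule.csv pprl.csv --out categories.csv --plot upset.png
linkaudit sample rule.csv pprl.csv --n-per-category 200 --seed 1 --out samples.csv
linkaudit estimate --categories categories.csv --reviews reviews.csv --out report.json
```

Exit codes: 0 success · 2 configuration error · 3 invariant violation ·
4 inestimable report. A YAML config may override any simulation rate, the
threshold family, rule weights, and audit parameters; all randomness flows
from a single seed and identical configs produce byte-identical outputs.

## Layout

| module | contents |
|---|---|
| `linkaudit.synth` | synthetic registries, truth ledger, corruption operators |
| `linkaudit.tokens` | PII normalization, 18-template token schema, HMAC tokens |
| `linkaudit.engines` | soundex, rule matcher, token similarity, calibration, threshold matching |
| `linkaudit.categories` | 8-category exclusive partition and per-algorithm totals |
| `linkaudit.review` | stratified audit sampling, adjudication, review tables |
| `linkaudit.estimate` | FM rates, exact CIs, projection, precision/recall |
| `linkaudit.pipeline` | orchestration, manifests, replication fixtures |
| `linkaudit.cli` | `linkaudit` command group |
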