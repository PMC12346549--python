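# ecgaudit

A model-agnostic audit toolkit for 12-lead ECG classifiers. It packages the
three pillars of a diagnostic-AI validation study — performance,
transparency, robustness — into one reproducible pipeline:

- **Performance**: AUROC (continuous and binarized) with DeLong or bootstrap
  CIs, AUPRC, operating-point Se/Sp/PPV/NPV with Wilson CIs,
  fixed-sensitivity thresholding, Pearson correlation, subgroup tables, and
  confusion-matrix reconstruction from published rates.
- **Transparency**: TCAV concept attribution over the classifier's four
  feature blocks (CAV training, directional derivatives, repeated-run CIs
  and significance against random concepts) and phenotype discovery on
  predicted positives (K-means with elbow selection, t-SNE embedding,
  cluster profiling).
- **Robustness**: the full limb-cable reversal simulator (all 24 placements,
  collapsed to their 12 unique morphology classes under the
  equipotential-legs model) and six artificial noise types (power line, EMG,
  baseline wander, baseline shift, partial white noise, time mask), each
  with a metrics harness.

Because no clinical data ships with the package, a seeded synthetic module
generates physically consistent 12-lead cohorts from a dipole/electrode-
potential model (Einthoven/Wilson identities hold exactly), plus concept
datasets for nine ECG concepts (AF, LBBB, RBBB, LAD, RAD, prolonged QT,
conduction disorder, abnormal Q wave, abnormal T wave). A small trainable
1-D residual network (stem + four feature blocks of three residual blocks +
fully connected head, 12x2500 input at 250 Hz, 0-100 score, operating
threshold 9.7) stands in for the model under audit; it runs on a
self-contained numpy layer engine, so no deep-learning framework is needed.

## CLI

```sh
ecg-audit simulate --out cohort/ --n-pos 20 --n-neg 80 --seed 0
ecg-audit train    --in cohort/ --meta cohort/metadata.csv --out model.ckpt
ecg-audit evaluate --scores scores.csv --meta cohort/metadata.csv --threshold 9.7 --out metrics.csv
ecg-audit reversal --model model.ckpt --in cohort/ --meta cohort/metadata.csv --out reversal.csv
ecg-audit noise    --model model.ckpt --in cohort/ --meta cohort/metadata.csv --out noise.csv
ecg-audit tcav     --model model.ckpt --in cohort/ --meta cohort/metadata.csv --out tcav.csv
ecg-audit cluster  --model model.ckpt --in cohort/ --meta cohort/metadata.csv --out clusters/
ecg-audit audit    --out report/ --seed 0        # full pipeline
```

`ecg-audit audit` runs simulate -> train -> evaluate -> TCAV -> clustering ->
reversal suite -> noise suite and writes CSV tables, a Markdown summary and a
manifest (config snapshot, per-stage seeds and status, artifact SHA-256
hashes). Reruns with the same config and seeds reproduce every CSV bitwise.
Exit codes: 0 success, 2 config error, 3 stage failure. Configuration is a
single YAML (`--config`) whose keys mirror `ecgaudit.pipeline.AuditConfig`.

## Data formats

Records are `(12, n)` matrices in mV with leads fixed in the order
I, II, III, aVR, aVL, aVF, V1-V6. Three on-disk formats round-trip through
`ecgaudit.records.read_ecg` / `write_ecg`:

- WFDB (`.hea` text header + int16 `.dat`, format 16, gain honored on read);
- CSV (`time_s,I,II,...,V6`, one row per sample, value-exact round trip);
- an array container (`.ecgz`, a zip with signal/fs/lead_names/record_id).

Cohorts are a directory of records plus `metadata.csv` with columns
`record_id,label,lvef_percent,age,sex,htn,dm,cad,ckd`.
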