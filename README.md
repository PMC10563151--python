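# cellscore

Weakly-supervised per-cell pathogenicity scoring for clinical flow
cytometry.

Clinical cytometry samples come labeled at the *sample* level — a diagnosis,
and often a cancer burden (the fraction of leukemic cells found by expert
gating) — but never at the cell level.  `cellscore` trains a small neural
network s(x; φ) that scores every cell's probability of being pathogenic
from that weak supervision alone, predicts sample-level outcomes by
averaging the scores, and then explains itself: which cells it called
leukemic, what marker cutoffs separate them (a data-driven gating
strategy), and whether an independent clustering of the raw data finds the
same populations.  It is aimed at computational cytometrists and
ML-for-hematology researchers who need cell-level answers from sample-level
labels.

## Model

A sample is a set X_i = {x_i1, …, x_in_i} of per-cell marker vectors.  The
scoring network (ReLU hidden layers, sigmoid output) maps each cell to
s_ij ∈ (0, 1); the sample statistic is the mean s̄_i = (1/n_i) Σ_j s_ij.
Two objectives are available:

* burden regression:  L = Σ_{y_i>0} (s̄_i − y_i)² + λ Σ_{y_i=0} s̄_i²,
  λ > 1, with ŷ_i = s̄_i as the burden estimate;
* classification:  P(y_i^L = 1 | X_i) = 1/(1 + exp(α + β s̄_i)), trained by
  (optionally class-weighted) cross-entropy.

Training is initialized from a density argument: with pooled negative-sample
cells estimating the healthy density P(x | z=0) by KDE and each positive
sample's cells estimating P(x | y>0), Bayes' rule gives per-cell scores
s' = clip(1 − P̂(x|z=0)(1−y_i)/P̂(x|y_i>0), 0, 1), and a network pretrained
on s' provides the starting weights.  Interpretation is post-hoc: score
thresholding → cell labels → a CART tree over markers (global and projected
per sample) → K-means "cancer-only cluster" validation → 2D dot-plot
exports in original units.  See `docs/methods.md` for the full account.

## Worked example

```python
import cellscore as cs
from cellscore.model import sample_auroc
from cellscore.pipeline import train_pipeline

train, _ = cs.generate_cohort(cs.standard_fixture_config(
    seed=2, n_pos=8, n_neg=8, cells_per_sample=(1500, 2500), id_prefix="tr_"))
test, truth = cs.generate_cohort(cs.standard_fixture_config(
    seed=3, n_pos=4, n_neg=4, cells_per_sample=(1500, 2500), id_prefix="te_"))

config = cs.TrainConfig(mode="reg", lam=4.0, epochs=120, n_restarts=3, seed=2)
result, dm, metrics = train_pipeline(train, config,
                                     density_kwargs={"max_fit_cells": 8000})
preds = cs.predict(result, test)
print(sample_auroc(preds, test))
for s in test.samples:
    print(s.sample_id, round(preds.sbar[s.sample_id], 3), round(s.burden, 3))
```

prints (abridged; `examples/03_train_and_predict.py` is the full script):

```
test sample AUROC: 1.000
burden correlation r: 1.000
  te_pos001: predicted burden 0.780, true 0.782
  te_pos002: predicted burden 0.613, true 0.614
  te_neg004: predicted burden 0.001, true 0.000
  te_neg007: predicted burden 0.002, true 0.000
```

AUROC 1.0 means every positive sample outscored every negative one; the
per-sample numbers show the mean cell score tracking the true pathogenic
fraction, with healthy samples pushed to ≈0 by the λ-weighted term.  The
other scripts in `examples/` walk through cohort simulation, the
density/Bayes initialization, and the interpretation outputs (tree cutoffs,
endotype paths, cancer-only clusters).

## Command line

The same pipeline is scriptable from a shell, driven by a YAML config whose
resolved copy (and seed) is written into every output directory:

```bash
cellscore simulate  --config run.yaml
cellscore train     --config run.yaml [--mode reg|class] [--no-density-init]
cellscore predict   --config run.yaml --checkpoint runs/out/checkpoint.json
cellscore interpret --config run.yaml --checkpoint runs/out/checkpoint.json
cellscore search    --config run.yaml     # CV grid search over λ / w / lr
```

## Layout

```
src/cellscore/     panel/cohort containers, FCS + TSV I/O, simulation,
                   density initialization, model + training, interpretation,
                   pipeline orchestration, CLI
examples/          one narrative script per capability
tests/             pytest suite (unit, property and end-to-end acceptance)
scripts/           acceptance.py (reproduction script)
docs/methods.md    model, assumptions, numerical choices, limitations
```
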