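# blastonet

Cell-contact network analysis for cleavage-stage embryos.

Given per-blastomere 3D surface meshes (one closed triangle mesh per cell),
blastonet derives the embryo's intercellular contact network by scaling each
mesh radially about its own volume centroid by a small factor (default 1.05)
and testing the scaled closed volumes for overlap. The networks are
summarized by degree-count vectors (entry *n* = number of cells with exactly
*n* contacts), a nickname taxonomy for the canonical 4-cell arrangements
(Tetrahedral, Pseudotetrahedral, Planar, Closed Y, Linear, Other), and the
mean number of contacts per blastomere — a single scalar biomarker. The
package also provides the downstream evaluation machinery: pooled two-sample
t-tests (raw and summary-statistic forms), bootstrap Spearman confidence
intervals, and a cross-validated threshold classifier calibrated by
exhaustive AUC search.

Because real clinical mesh data is confidential, a synthetic-embryo module
generates icosphere embryos with known ground-truth contact structure (five
canonical 4-cell layouts plus relaxation-packed 8-cell clusters) and
simulated outcome labels with prescribed group means/SDs, so the entire
pipeline is testable end to end.

## Library quick start

```python
from blastonet import (
    ArrangementSpec, generate_arrangement, contact_network,
    hickman_vector, mean_contacts, classify_arrangement_4cell,
)

embryo = generate_arrangement(ArrangementSpec(name="pseudotetrahedral"))
net = contact_network(embryo, scale_factor=1.05)
hv = hickman_vector(net)            # (0, 0, 2, 2)
classify_arrangement_4cell(hv)      # "Pseudotetrahedral"
mean_contacts(net)                  # 2.5
```

Statistics and prediction:

```python
from blastonet import pooled_t_from_summary, spearman_bootstrap, cross_validate

pooled_t_from_summary(2.54, 0.46, 203, 2.30, 0.61, 35).t_statistic  # ~2.71
rho, lo, hi = spearman_bootstrap(x, y, n_boot=10000, conf=0.95, seed=0)
report = cross_validate(feature, labels, k=5, seed=0)
report.summary["auc"]               # (mean, sd) over folds
```

## Command line

```sh
# synthetic cohort: per-cell PLY meshes + outcomes.csv + manifest
blastonet generate --out data/ --seed 7 --cohort "tetrahedral:10,planar:5"

# contact networks (GraphML + edge CSV) from an embryo directory tree
blastonet contacts --input data/ --out nets/ --scale-factor 1.05

# per-embryo descriptors (vector, mean contacts, arrangement label)
blastonet describe --input data/ --out descriptors.csv

# group comparisons and cross-validated prediction
blastonet stats --descriptors descriptors.csv --outcomes data/outcomes.csv --out stats.csv
blastonet cv --descriptors descriptors.csv --outcomes data/outcomes.csv \
    --feature mean_contacts --outcome live_birth --folds 5 --seed 0 --out cv.csv

# everything at once from a flat key=value config
blastonet run-all --config run.cfg
```

An embryo on disk is a subdirectory of per-cell mesh files (OBJ or PLY;
polygon faces are fan-triangulated on read) next to an `outcomes.csv` with
per-embryo labels (blastulated, Gardner grade, transferred, pregnancy, live
birth, miscarriage, euploid).

## Notes on conventions

- Student's pooled-variance (not Welch) t-test, two-sided p-values.
- Percentile bootstrap intervals for Spearman correlation (average-rank ties).
- The threshold classifier predicts positive when feature > theta; its AUC
  is the rank statistic of the hard prediction, identically
  (sensitivity + specificity) / 2. The continuous-feature AUC is reported
  per fold as an auxiliary column.
- Near-tangency: surfaces touching exactly at the scaled-radius sum are not
  contacts; faceted spheres may disagree with the analytic sphere criterion
  only within the tessellation chord-sag band (see
  `blastonet.meshes.tessellation_tolerance`).
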