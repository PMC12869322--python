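# fcselect

PCA-based feature selection for extracting *robust* case-control differences
from high-dimensional resting-state functional-connectivity (FC) data.

## The problem

A resting-state connectome parcellated into R regions yields
m = R(R−1)/2 FC features per subject — 71,631 Fisher-z-transformed Pearson
correlations for a 379-region parcellation — measured on cohorts of only a
few hundred patients and controls. Supervised feature selectors (LASSO,
mass-univariate t-tests) pick the connections that best discriminate the
*discovery* cohort, which in the p ≫ n regime means they chase
high-signal-to-noise features inflated by selection noise and by
site/protocol confounds; their selections shrink badly on independent
validation cohorts and barely overlap between cohorts.

`fcselect` implements the alternative: select features through an
*unsupervised* low-rank decomposition, using the diagnosis labels only to
screen components.

1. **Feature computation.** PCA of the subjects × m FC table (SVD of the
   centred matrix, no feature standardization — all FCs share the
   Fisher-z scale), giving at most n−1 components with orthonormal
   weight vectors w_k and subject scores s_k.
2. **Component screening.** Each component's scores are tested against
   diagnosis (two-sample t), symptom score / age / head motion (Pearson
   r), sex (t), and site (one-way ANOVA), with Benjamini–Hochberg FDR
   correction across components within each factor (q = 0.05).
3. **Component choice.** Among components significant for diagnosis, the
   one with the largest explained variance is the diagnosis component;
   if none is significant, nothing is selected (a valid null result).
4. **Feature selection.** The chosen component's m weights are
   standardized, z = (w − w̄)/sd(w); treating them as standard-normal
   draws, features with improbably large |z| (two-tailed, BH-corrected
   across features at q = 0.05) are the selected FCs, each labelled
   over- or under-connected by the sign of the patient-minus-control
   group mean.

Around the core method the package provides everything needed to
characterize it: FC construction from ROI time series (nuisance
regression, 0.01–0.08 Hz Butterworth band-pass, FD > 0.5 mm scrubbing,
Fisher-z correlation), ComBat harmonization (parametric empirical Bayes,
covariate-preserving) and traveling-subject site-bias subtraction,
baseline selectors (subsampled LASSO, univariate t-tests with FDR/
Bonferroni), a subsampling ensemble-LASSO diagnostic classifier with
in-fold feature selection, Hedge's-g effect-size audits across cohorts,
and traveling-subject variance decomposition (participant / scanner /
session / protocol). Synthetic generators with known planted structure
make every stage testable without access to clinical data.

## Worked example

A discovery/validation pair sharing one planted disorder component
(50 of 1,000 FCs, standardized effect 0.8 in discovery, 0.5 in
validation):

```python
import numpy as np
from scipy import stats
from fcselect import (
    ClinicalSimConfig, gen_discovery_validation_pair, pca_pipeline,
    project_scores, hedges_g, patient_indicator,
)

cfg = ClinicalSimConfig(
    n_control=200, n_patient=200, n_features=1000,
    disorder_effect=0.8, n_disorder_fcs=50,
    site_bias_sd=0.0, site_scale_sd=0.0, age_effect=0.0, sex_effect=0.0,
    seed=0,
)
(disc, disc_ph), (val, val_ph), truth = gen_discovery_validation_pair(
    cfg, {"disorder_effect": 0.5}
)
selection, pc, assoc = pca_pipeline(disc, disc_ph)
scores = project_scores(pc, selection.component, val)
y = patient_indicator(val_ph)
t, p = stats.ttest_ind(scores[y == 1], scores[y == 0])
```

which prints (see the docstrings for the exact reporting code):

```
diagnosis component: PC0 (explained variance 0.012)
selected FCs: 44 (44 over-, 0 under-connected)
planted-feature recovery: 44/50 (precision 1.00)
validation mean |g| of selected FCs: 0.523
projected scores separate groups in validation: t = 30.39, p = 8.76e-106
```

Interpretation: the screen flags exactly one diagnosis component; its
weight tail recovers 44 of the 50 planted connections with no false
selections; the selected set keeps a mean |Hedge's g| of 0.52 in the
independent cohort; and projecting the *discovery* weights onto
validation subjects separates the groups decisively — the selection
generalizes.

The same pipeline is scriptable from the shell:

```bash
fcselect simulate clinical --seed 7 --out-prefix sim
fcselect select pca --fc sim_fc.tsv --pheno sim_pheno.tsv --out selection.tsv
fcselect effects --fc sim_fc.tsv --pheno sim_pheno.tsv \
    --selections selection.tsv --out effects.tsv
```

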