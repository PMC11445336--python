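# metaconn

Subject-level metabolic and hemodynamic brain connectomics: from dynamic
constant-infusion [18F]FDG-PET (fPET), summed static PET (sPET) and BOLD
fMRI series to modality-specific connectivity matrices, significance-
thresholded adjacencies, multimodal common-edge connectomes, Sörensen–Dice
similarity, nodal-degree group statistics and severity correlations.

## The problem

Classical FDG-PET yields one static uptake image per subject, so "metabolic
connectivity" — the interregional correlation of glucose uptake — is only
defined at the group level, as an across-subject covariance. Constant-
infusion fPET changes this: slow continuous tracer infusion produces a
per-subject *time series* of uptake (90 one-minute frames), so metabolic
connectivity can be computed within a subject, exactly like hemodynamic
connectivity from fMRI. Comparing the three constructions — group-level
sPET covariance, subject-level fPET correlation, subject-level fMRI
correlation — and intersecting their significant edges tests whether the
metabolic network signature of a disease (here, exaggerated sensorimotor
coupling in Parkinson's disease) is visible at the individual level and
scales with motor severity.

`metaconn` implements that full analysis chain for methodologists and
imaging groups who want a tested, reusable reference pipeline, together
with a synthetic-data generator that plants a known network structure so
every stage is verifiable without access to patient scans.

## The core quantities

For regions $i, j$ with signals $x_i$ (uptake across subjects for sPET,
time series across frames for fPET/fMRI):

- connectivity $r_{ij}$ = Pearson correlation over all region pairs;
  $z_{ij} = \operatorname{atanh} r_{ij}$ (Fisher);
- group significance: one-sample t test of subjects' $z_{ij}$ against 0
  (time-series modalities) or the correlation t test with $n-2$ df (sPET);
- adjacency $A_{ij} \in \{-1, 0, +1\}$: the sign of significant edges
  ($p < 0.05$, uncorrected at edge level);
- multimodal (tertiary) connectome: edges significant in both modalities
  with the same sign;
- Dice similarity of two edge sets
  $DC = 2\,|M_1 \cap M_2| / (|M_1| + |M_2|)$;
- nodal degree = number of significant edges per region, aggregated per
  functional unit (lobule) and compared between groups with Shapiro-gated
  Welch-t / Mann-Whitney tests under Bonferroni–Holm correction;
- severity coupling: Spearman correlation between a patient's within-network
  subject-level degree and a motor-severity score.

Intrinsic networks are identified by group spatial ICA of temporally
concatenated, global-mean-normalized series (10 components; components
thresholded at z = 1.5, the sensorimotor one at z = 1.0) and parcellated
against the atlas.

## Worked example

```python
from metaconn import stats
from metaconn.pipeline import run_pipeline, default_config

# cohort-table statistics from printed group summaries
age = stats.t_from_summary(59.54, 5.13, 13, 62.92, 9.48, 12)
print(f"Age: t = {age.statistic:.2f} (df = {age.df:.1f}), p = {age.p:.2f}")
sex = stats.fisher_or([[7, 6], [9, 3]])
print(f"Sex: OR = {sex.statistic:.2f}, p = {sex.p:.2f}")

# full synthetic pipeline: 12 patients / 13 controls, 30 regions
m = run_pipeline(default_config(), seed=1)
print("network regions:", m.results["network_rois"])
s = m.results["severity_spearman"]
print(f"severity vs motor degree: rho = {s['rho']:.2f}, p = {s['p']:.3f}")
```

prints

```
Age: t = -1.10 (df = 16.6), p = 0.29
Sex: OR = 0.40, p = 0.41
network regions: [1, 2, 3, 4, 5]
severity vs motor degree: rho = 0.58, p = 0.049
```

The Welch t of −1.10 says the groups' ages are statistically comparable;
the conditional-MLE odds ratio of 0.40 likewise for sex. On the synthetic
cohort the ICA recovers exactly the five planted cortical-motor regions as
the sensorimotor network, and the patients' subject-level metabolic degree
in that network correlates positively (rho = 0.58) with the planted
severity score — the qualitative finding the pipeline is built to detect.
On the same run the patient group's motor-unit degree exceeds the control
group's in every multimodal connectome (e.g. 20 vs 6 in fPET–fMRI).

The command line mirrors the library: `metaconn simulate`, `extract`,
`connect`, `compare` and `metaconn run --config cfg.yaml --seed 1 --out out/`
drive the individual stages or the whole chain on files.

## Layout

- `metaconn.synthio` — toy atlas, latent-factor cohort simulator, ground truth
- `metaconn.preproc` — frame retention, global-mean normalization, ROI extraction
- `metaconn.networks` — group spatial ICA, thresholding, parcellation
- `metaconn.connectivity` — the three connectivity constructions + adjacency
- `metaconn.connectome` — common edges, Dice, nodal degree
- `metaconn.stats` — gated tests, Holm, Spearman, conditional-MLE OR
- `metaconn.io` / `metaconn.pipeline` / `metaconn.cli` — formats, driver, CLI

See `docs/methods.md` for the generative model, parameter choices and
limitations.
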