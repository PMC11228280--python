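# omicsmix

Unsupervised cancer subtyping from whole-genome multi-omics data, and
discovery of the biomarkers that distinguish the subtypes.

Tumor cohorts profiled across several molecular layers — RNA expression,
somatic mutation, copy-number alteration (CNA) and miRNA expression — carry
complementary signals about molecular subtype, but genome-wide matrices are
wide (10⁴–10⁵ features) and cohorts are small (10²). `omicsmix` addresses
this with a dual-stream adversarial autoencoder:

* an **early-integration stream** reshapes the concatenated multi-omics
  vector (length D, padded with ones to an H×W grid, H = W = ⌈√D/p⌉·p) into
  patch tokens and encodes them with MLP-Mixer blocks — alternating
  token-mixing and channel-mixing MLPs with residual connections and
  LayerNorm;
* a **per-omics stream** encodes each layer with its own fully connected
  network;
* the streams are fused to a 256-dimensional latent code *Z*, and a
  discriminator trained against draws from N(0, 1)²⁵⁶ pushes the latent
  toward the standard-normal prior (adversarial replacement for a KL term).

The training objective is

    L = λ₁·MSE(Xₐ, Dₐ(Z)) + λ₂·BCE(Desc(Z), 1) + λ₃·Σⱼ MSE(Xⱼ, Dⱼ(Z)),

with λ = (1, 1, 0.01), reconstruction errors summed over features and
averaged over samples, Adam at learning rate 0.005, batch size 64, and early
stopping. Latent codes are clustered with a full-covariance Gaussian mixture
model fitted by EM (subtype = maximum-posterior component); subtypes are
evaluated with the g-sample log-rank test on survival. A biomarker pipeline
then splits the cohort 6:4, fits a random forest (100 trees, depth 10) on
the training features against subtype labels, takes the top 50 features by
Gini importance, and validates each by a median-split log-rank test on the
held-out samples (p < 0.05 keeps a candidate).

Intended users: computational cancer-genomics researchers who want a
reproducible subtyping + biomarker pipeline they can exercise end to end on
synthetic cohorts before pointing it at real matrices.

## Worked example

Simulate a cohort with three planted subtypes (mean shift 6 sd on 30
informative features per layer, 10-fold hazard spread between subtypes, 10%
of samples missing one whole omics layer, one planted prognostic marker),
then run the full pipeline:

```bash
omicsmix simulate --out demo/data --seed 9 --n-samples 200 --k 3
omicsmix run-all --data demo/data --out demo/run --k 3 --seed 5
```

which prints (output of this exact command):

```
wrote synthetic cohort (200 samples, K=3) to demo/data
done: K=3, log-rank p=2.79e-21 (-log10 p=20.555), 32 significant biomarkers -> demo/run
```

The log-rank p-value (here 2.8e-21) tests whether the three recovered
subtypes differ in survival — the pipeline's headline metric, usually quoted
as −log₁₀ p. Of the 50 candidate biomarkers ranked by Gini importance, 32
survived median-split survival validation on the held-out 40% of samples.
`demo/run/` contains `subtypes.tsv`, `latent.tsv`, `biomarkers.tsv`,
`contributions_omics.tsv` (fraction of Gini importance per omics layer),
`contributions_regions.tsv` (per genomic region within Mut/CNA, splice-site
mass folded into CDS), `logrank.tsv`, `train_report.tsv` (per-epoch losses),
and a `manifest.json` recording the seed fan-out and configuration hash.

The same pipeline is available stage by stage (`omicsmix preprocess`,
`train`, `cluster`, `biomarkers`) and as a library:

```python
from omicsmix import SimulationConfig, simulate_multiomics, run_pipeline

dataset, truth = simulate_multiomics(SimulationConfig(seed=9))
result = run_pipeline(dataset, K=3, seed=5)
result.logrank_p, len(result.significant), result.contributions_omics
```

For real cohorts, `--cancer-code` supplies the established subtype count
(OV 3, CLLE 6, ESAD 2, MALY 3, PACA 6, RECA 4, BRCA 4) in place of `--k`.

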