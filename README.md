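# ifptml

Information-fusion perturbation-theory machine learning (IFPTML) for
screening drug × nanoparticle delivery-system candidates.

## The problem

Getting neurodegenerative-disease drugs (NDDs) across the blood–brain
barrier often requires a nanoparticle (NP) carrier, but the space of
candidate drug–nanoparticle systems is enormous and the two kinds of
evidence live in separate, heterogeneous tables: preclinical drug
bioactivity assays (many different activity parameters, targets, cell
lines, organisms) and NP cytotoxicity assays (cell lines, shapes, media,
coating agents). There are far too few assays of actual combined systems
to model them directly.

IFPTML addresses this by *fusing* the two assay tables into paired cases
and modeling the fused outcome. This package implements the full
pipeline for researchers in computational drug discovery / nano-QSAR:
data model and IO for both tables, a synthetic-data generator with a
plantable signal, desirability-based binarization and fusion,
perturbation-theory features, resampling, four classifier families, and
probability simulation over candidate grids.

## The model

Each assay reports a value $v$ whose meaning depends on its activity
parameter $c_0$ (IC50, EC50, activity %, …). A desirability
$d(c_0) \in \{-1, +1\}$ says whether smaller or larger values are
favorable, and a per-parameter cutoff turns values into Booleans:

$$f(v)_{obs} = 1 \iff (v > \mathrm{cutoff} \wedge d = +1) \lor
               (v < \mathrm{cutoff} \wedge d = -1)$$

A paired case (one drug assay × one NP assay) is positive only when both
sides are favorable: $f_{obs} = f(v_{ij})_{obs} \cdot f(v_{nj})_{obs}$.
The *reference* function is the per-stratum probability of a favorable
outcome, fused the same way:
$f_{ref} = p(f(v_{ij})=1)\cdot p(f(v_{nj})=1)$.

Features are perturbation-theory operators (PTOs): moving-average
deviations of structural descriptors from their expected value under a
partition $\mathbf{c}$ of assay-condition labels,

$$\Delta D_k(\mathbf{c}_j) = D_k - \langle D_k \rangle_{\mathbf{c}_j},$$

plus cross deviations (a drug descriptor conditioned on NP-side labels
and vice versa) and a moving-average-balance operator
$\Delta\Delta D(D_{ca1}, D_{ca2}, D_{dk})$ that balances a drug
descriptor deviation against its two homologous coating-agent descriptor
deviations. A linear discriminant scores cases as

$$f_{calc} = a_0 + a_1 f_{ref} + \sum_k a_k \Delta D_k,$$

with neural variants (LNN, MLP 7:11:1, DLN 7:10:10:1) for non-linear
structure, and probabilities via $p = 1/(1+e^{-f_{calc}})$, banded
high (≥ 0.61) / mid (≥ 0.17) / low for triage.

## Worked example

Generate a synthetic study with a planted linear signal (log P helps,
PSA hurts), run the pipeline on three 50,000-case working samples and fit
a discriminant and an MLP:

```python
from ifptml import SamplingPlan, run_study
from ifptml.operators import FeatureDef, FeatureSpec
from ifptml.synthetic import SignalSpec, SynthConfig, generate_study

config = SynthConfig(
    n_ndd_assays=2000, n_np_assays=500,
    n_unique_compounds=1000, n_unique_nps=60,
    signal_spec=SignalSpec(linear_weights={"ndd:logp": 1.0, "ndd:psa": -1.0},
                           noise_sd=0.25),
    seed=42)
ndd, np_table, desirability, truth = generate_study(config)

features = FeatureSpec((
    FeatureDef("reference", "f_ref"),
    FeatureDef("ma", "dD_logp", "logp", ("c_d0",)),
    FeatureDef("ma", "dD_psa", "psa", ("c_d0",)),
    FeatureDef("ma", "dD_lnp", "d_n02", ("c_n0",)),
))
plan = SamplingPlan(n_samples=3, cases_per_sample=50_000, base_seed=42)
result = run_study(ndd, np_table, desirability, cutoffs=truth.cutoffs,
                   plan=plan, feature_spec=features, families=("lda", "mlp"))

for (family, subset), rec in result.samples[0].metrics.items():
    print(f"sample 1 {family:>3} {subset}  Sn={rec.sn:5.1f}%  "
          f"Sp={rec.sp:5.1f}%  Ac={rec.ac:5.1f}%  AUROC={rec.auroc:.3f}")
rob = result.robustness[("lda", "v")]
print(f"LDA validation across 3 samples: "
      f"Sn {rob.mean['Sn']:.1f} +/- {rob.sdv['Sn']:.2f}, "
      f"Sp {rob.mean['Sp']:.1f} +/- {rob.sdv['Sp']:.2f}")
```

Output:

```
sample 1 lda t  Sn= 76.9%  Sp= 70.9%  Ac= 74.0%  AUROC=0.822
sample 1 lda v  Sn= 75.5%  Sp= 69.6%  Ac= 72.6%  AUROC=0.811
sample 1 mlp t  Sn= 75.8%  Sp= 71.8%  Ac= 73.9%  AUROC=0.822
sample 1 mlp v  Sn= 74.3%  Sp= 70.6%  Ac= 72.5%  AUROC=0.811
LDA validation across 3 samples: Sn 75.5 +/- 1.48, Sp 70.0 +/- 0.46
```

Sensitivity (Sn) is the percentage of truly favorable paired cases the
model flags, specificity (Sp) the percentage of unfavorable cases it
rejects; AUROC 0.81 on validation matches the planted signal's own
separability (the signal carries Bernoulli noise, so 0.81 — not 1.0 —
is the ceiling here). On linear data the MLP offers no advantage over
the discriminant; on interaction-structured data it does (see
`tests/test_acceptance.py`).

The same pipeline runs from the shell:

```sh
ifptml simulate-data --seed 4 --n-ndd 2000 --n-np 500 --out data/
ifptml run --ndd data/ndd_assays.csv --np data/np_assays.csv \
    --desirability data/desirability.csv --cutoffs data/cutoffs.csv \
    --n-samples 3 --cases-per-sample 50000 --out runs/demo
ifptml predict --state runs/demo --compounds compounds.csv \
    --np-conditions conditions.csv --out predictions.csv
```

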