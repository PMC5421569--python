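# mixcall

Presence/absence calling of gene expression from bulk cancer
transcriptomes via per-sample bimodal mixture decomposition, with
gene-panel tissue-specificity analysis.

## The problem

The distribution of log-scale expression values across a single sample's
transcriptome (RMA-normalised log2 microarray values, or log-transformed
RSEM values from RNA-seq) is typically bimodal: a broad low mode of
unexpressed/background genes and a high mode of expressed genes. `mixcall`
turns that observation into a per-gene, per-sample *expressed / not
expressed* call by decomposing each sample's expression vector into a
two-component Gaussian mixture

```
p(x) = w_l · N(x; μ_l, σ_l²) + w_h · N(x; μ_h, σ_h²),      μ_l ≤ μ_h
```

fitted by expectation-maximisation, and thresholding each gene's posterior
probability of the high component (its responsibility)

```
P(high | x_g) = w_h φ(x_g; μ_h, σ_h) / [ w_l φ(x_g; μ_l, σ_l) + w_h φ(x_g; μ_h, σ_h) ]
```

at a cutoff (default: posterior > 0.95). The motivating application is
ectopic expression of olfactory receptor (OR) genes in cancer cell lines
and tumours: a ~301-gene OR panel that is silent in most tissues, scored
across ~968 cell lines, with downstream questions about how many lines
express any OR, whether a line expresses a single receptor, whether the
G-protein/adenylate-cyclase effectors (GNA15, GNA13, GNAO1, GNAI1, GNAL,
ADCY3) are co-expressed, and whether a receptor's positive calls
concentrate in one tumour type (two-tailed Fisher's exact test on the
2×2 table of calls × tissue), probed for robustness across a ladder of
posterior thresholds (0.125 … 0.99).

Because the original expression compendia are external downloads, the
package ships a first-class synthetic-data generator that emulates the
assumed structure — per-sample bimodal log-expression, a mostly-silent
panel, one planted tissue-specific gene, effector co-expression — with
full ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from mixcall import (SimulationConfig, generate_matrix, call_expression,
                     summarize_panel, tissue_specificity, sweep_from_callset)
from mixcall.mixture import EMConfig

cfg = SimulationConfig(seed=1)          # 968 samples, 52 melanoma; 2000 genes,
                                        # 301-gene OR panel; OR2C3 planted in
                                        # 8/52 melanoma samples
matrix, truth = generate_matrix(cfg)
calls = call_expression(matrix, cfg.panel_gene_ids(),
                        list(cfg.effector_gene_ids), em=EMConfig(seed=1))

res = tissue_specificity(calls, "OR2C3", "melanoma")
print(res.table.tolist(), res.p_two_tailed)
curve = sweep_from_callset(calls, "OR2C3", "melanoma")
print(curve.focal_counts.tolist(), curve.other_counts.tolist())
s = summarize_panel(calls)
print(s.n_samples_expressing_any, s.to_dict()["fmt_effector_coexpression"])
```

prints

```
[[8, 44], [0, 916]] 4.0517346267750033e-11
[8, 8, 8, 8, 8, 8, 8] [0, 0, 0, 0, 0, 0, 0]
8 87.50
```

i.e. the planted receptor is called expressed in exactly the 8 planted
melanoma samples and nowhere else (Fisher p ≈ 4×10⁻¹¹, far below 10⁻⁴);
the count is flat across all seven sweep thresholds, the signature of a
genuinely tissue-specific signal rather than a threshold artefact; and
87.50% of expressing samples co-express at least one effector (7 of 8,
the generator's co-expression rate of 85.95% rounded to whole samples).

The scikit-learn estimator surface is available for composition with
sklearn tooling: `TwoComponentGaussianMixture` (fit / predict_proba /
score on one expression vector) and `ExpressionCaller` (fit once per
matrix, then `call(panel, effectors, threshold=...)` cheaply at any
threshold).

A CLI mirrors the library: `mixcall simulate | call | summarize |
specificity | sweep | run` (see `mixcall --help`). RNA-seq RSEM matrices
can be fed through `--rsem`, which applies `ln(RSEM+1)+1` before fitting.

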