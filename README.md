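# mirscreen

Network-based screening of microRNA biomarkers, with the downstream
classifier and clinical-association stages needed to take a candidate from
a regulatory network to a tissue-level validation readout.

## The problem

A single miRNA can repress hundreds of mRNAs, and most mRNAs are targeted
by several miRNAs. Most computational biomarker screens exploit this
many-to-many structure; `mirscreen` instead scores the *one-to-many*,
independent regulatory power of each miRNA inside a disease-specific
miRNA→mRNA network. Two per-miRNA indices drive the screen:

* **NOD** (novel out degree) — the number of target genes regulated by
  *no other* miRNA in the network (gene in-degree 1). A high-NOD miRNA
  carries non-redundant regulatory load: perturbing it cannot be buffered
  by other regulators, making it a vulnerable point of the network and a
  sensitive readout of disease state.
* **TFP** (transcription-factor percentage) — the fraction of a miRNA's
  in-network targets that are transcription factors,
  TFP(i) = |targets(i) ∩ TF| / |targets(i)|. It extends NOD to the
  functional level: deregulating a TF-rich miRNA propagates far
  downstream.

Both indices are tested against a **degree-preserving rewiring null**: the
bipartite network is randomized by edge swaps that keep every miRNA
out-degree and every gene in-degree fixed, and one-sided add-one
permutation p-values, p = (1 + #{null ≥ observed}) / (n_null + 1), are
computed per miRNA. Candidates must be significant on both indices in
*both* condition-specific networks (the miRNA-seeded Net1 and the
gene-seeded Net2).

Upstream of the indices the package provides:

* **netbuild** — assembly of the reference miRNA→mRNA network from
  validated interaction records (low-throughput evidence by default) and
  computational predictions filtered per tool (HOCTAR top-50% by score,
  ExprTarget score > 1, starBase readNUM ≥ 10 and BC ≥ 2) with ≥ 2-tool
  agreement.
* **descreen** — differential-expression screening: k-nearest-neighbour
  imputation, Welch t for miRNAs, and six statistics for mRNAs (t plus the
  cancer-outlier family COPA / OS / ORT / MOST / LSOSS, which detect
  shifts present in only a subset of disease samples), with the statistic
  chosen by cross-dataset overlap of its top-ranked lists.
* **classeval** — fivefold stratified CV-SVM (RBF kernel, cost 1,
  γ = 1/n_features) and rank-based ROC/AUC for single markers and all
  marker pairs, with sensitivity = TP/(TP+FN), specificity = TN/(FP+TN),
  accuracy = (TN+TP)/total from pooled out-of-fold predictions.
* **clinassoc** — the weighted ISH/IHC tissue score (percent-positive bin
  0–4 plus intensity 0–3; score ≥ 4 ⇒ "high" expression), Pearson χ²
  association (no continuity correction), Mann–Whitney U, and
  Kaplan–Meier / log-rank survival comparison.
* **synthdata** — a seeded generator that emulates every input (evidence
  table, log-scale two-group expression matrices, TF list, clinical/TMA
  table) with planted ground truth, so the whole pipeline is testable
  without any external download.

## Worked example

```python
from mirscreen.synthdata import SynthConfig, generate_network_evidence, generate_expression
from mirscreen.netbuild import evidence_from_frame
from mirscreen.pipeline import screen_biomarkers

config = SynthConfig(seed=1)                       # 300 miRNAs, 20 planted biomarkers
evidence, truth = generate_network_evidence(config)
mirna_study, mrna_studies = generate_expression(config, truth)

result = screen_biomarkers(
    evidence_from_frame(evidence), mirna_study, mrna_studies,
    truth.tf_genes, alpha=0.05, n_null=499, seed=17,
)
print("best DE statistic:", result.best_method.value)
print("candidates:", len(result.candidates))
found = {c.mirna_id for c in result.candidates}
planted = set(truth.planted_mirnas)
print("planted recovered:", len(found & planted), "of", len(planted))
```

prints

```
best DE statistic: LSOSS
candidates: 19
planted recovered: 19 of 20
```

— the subgroup-shifted DE genes make LSOSS (not the t statistic) the most
cross-study-consistent screen, and the candidates significant on NOD and
TFP in both condition-specific networks are exactly planted
exclusive-module, TF-rich miRNAs (19 of the 20 planted at this seed, with
no false positives).

The clinical stage works directly from printed 2×2 counts:

```python
from mirscreen.clinassoc import chi2_association
chi2_association([[16, 13], [19, 42]]).p_value   # 0.0289
```

A `mirscreen` command exposes each stage
(`mirscreen synthdata all`, `mirscreen netbuild`, `mirscreen descreen
genes|mirnas`, `mirscreen netstat`, `mirscreen classeval`,
`mirscreen clinassoc score|chi2|survival`); see `--help` on each.

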