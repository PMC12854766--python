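# aoptox

Hierarchical concentration–response modeling of high-throughput
screening (HTS) bioassay data for mechanistic toxicity scoring.

## The problem

Quantitative HTS programs deliver, for each compound–assay pair, a
fitted Hill model

    R(C) = Top · C^slope / (C^slope + AC50^slope)

but in vivo toxicity emerges from coordinated biology, not single
assays. `aoptox` organizes Hill-parametrized bioactivity along an
adverse-outcome-pathway-style hierarchy: assay responses are explained
by latent **protein** activities, proteins are aggregated into
**pathway** activities, and pathways are linked to in vivo **toxicity
endpoints** (LD50, NOAEL, hepatotoxicity) only where the data support
the association. The package is aimed at computational toxicologists
who want interpretable, mechanism-indexed toxicity scores from curve-fit
level screening data rather than black-box QSAR predictions.

## The model

Curves are evaluated on a standardized grid of 45 log-spaced
concentrations (1 pM – 100 µM), rescaled to a 0–100 % activity scale,
and stacked into a tensor `Assay` (assays × concentrations ×
chemicals) with an explicit observed-entry mask. Three bilinear stages
follow:

    Assay = M1 · Prot        M1: assays × proteins   (learned, masked)
    Prot  = M2 · Path        M2: proteins × pathways (learned, masked)
    Path  = M3 · Tox         M3: pathways × endpoints (fixed, binary)

`M1`/`M2` are constrained to the sparsity pattern of curated
assay→protein and protein→pathway annotations and trained together with
the latent tensors by minimizing the masked mean-squared reconstruction
error (alternating-least-squares warm start, then Adam with
plateau-triggered step decay and early stopping). `M3` is *not*
learned: a pathway–endpoint pair enters `M3` only if it survives
statistical filtering —

* continuous endpoints (−log10 dose): Pearson r ≥ 0.1, BH-FDR q < 0.05,
  and r ≥ 2/√n;
* binary endpoints: rank-biserial r_rb > 0 and q < 0.05, with the
  Wilcoxon rank-sum test when the pooled sample is tie-free and the
  Brunner–Munzel test otherwise.

Summarized `Tox` scores are min–max normalized per endpoint, stratified
into quartiles (Q4 = most toxic), and compared against GHS acute-oral
and NOAEL dose bands. Optional stages cluster compounds structurally
(MACCS fingerprints + Taylor–Butina at Tanimoto 0.7) and compare
modeled EC50 potencies against steady-state plasma concentrations
(Css, externally computed) to flag exposure-relevant bioactivity.

A first-class synthetic-data generator (`aoptox.synthetic_data`) emits
every input file format with known ground truth (mapping matrices,
latent pathway activities, endpoints with calibrated effect sizes), so
the whole pipeline is testable end to end without downloads.

## Worked example

```
aoptox simulate --seed 3 --out-dir study --n-chemicals 80 --n-assays 8
aoptox run-all --config study/config.yaml --out-dir out
```

The first command writes a synthetic study (assay table, mapping files,
endpoint tables, Css table, SMILES list) plus a ready `config.yaml`;
the second runs all seven stages and prints

```
pipeline complete: 7 stages, outputs in out
```

`out/manifest.json` records the stage list and headline counts, e.g.

```
{'assay_rows_dropped': 0, 'assays_retained': 8, 'proteins_mapped': 8,
 'pathway_endpoint_pairs_retained': 25, 'clusters_retained': 9,
 'compounds_with_css': 12}
```

`out/associations.csv` holds one row per pathway–endpoint pair with the
statistic, p, q, confidence interval, and retention flag:

```
pathway_id,endpoint_id,n,stat,p,q,test_used,...,retained
PW000,EP0_continuous,80,0.4446,3.59e-05,1.75e-04,pearson,...,True
```

(PW000's pathway score correlates r = 0.44 with the −log10 LD50-like
endpoint over n = 80 compounds; q ≪ 0.05 and r > 2/√80 = 0.22, so the
pair is retained in `M3`.) `out/tox_scores.csv` gives the normalized
score, quartile, and observed dose-band class per compound–endpoint:

```
chemical_id,endpoint_id,normalized_score,quartile,observed_class
C00000,EP0_continuous,0.7767,Q4,high
C00003,EP0_continuous,0.3569,Q2,low
```

— compound C00000 ranks in the top score quartile and is indeed in the
GHS high-toxicity band, while C00003 ranks low on both.
`out/exposure_flags.csv` compares each compound's modeled EC50s with
its 95th-percentile Css per layer and flags compounds whose modeled
effects fall inside plausible internal exposure.

## Layout

| module | contents |
| --- | --- |
| `aoptox.hill` | Hill evaluation, concentration grid, normalization, assay classification, tensor assembly |
| `aoptox.tensor_model` | masked bilinear factorization, training protocol, score summaries |
| `aoptox.assoc_filter` | association statistics and the supervised construction of `M3` |
| `aoptox.tox_scoring` | score normalization, quartiles, GHS/NOAEL bands, cluster z-scores |
| `aoptox.chem_cluster` | MACCS fingerprints, Tanimoto, Taylor–Butina, MCS SMARTS |
| `aoptox.exposure` | EC50 extraction and Css comparison |
| `aoptox.synthetic_data` | ground-truth study generator |
| `aoptox.io` / `aoptox.cli` | readers/writers, pipeline driver, `aoptox` CLI |
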