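# barseqfit

Analysis pipeline for pooled Bar-seq screens that track yeast deletion
mutants through proliferation *and* starvation-induced quiescence —
quantifying per-strain fitness, survival, their difference, and genetic
interactions with kinase query mutations, plus a fully parameterized
synthetic-data generator with known ground truth.

## The problem

In a pooled competition screen, thousands of barcoded deletion strains
grow in one culture; sequencing the strain barcodes (UPTAG/DNTAG) at
successive time points measures each mutant's relative abundance. When
the restricted nutrient (carbon, nitrogen, or phosphorus) runs out the
population arrests in quiescence, and continued sampling measures
differential *survival* instead of growth. The genes required to
proliferate and the genes required to survive starvation turn out to be
largely distinct sets, and crossing the library against quiescence
kinases (TOR1, RIM15, PHO85) reveals state- and condition-specific
genetic interactions.

`barseqfit` implements the full analysis:

* **simdata** — synthetic experiments (libraries × conditions ×
  replicates × time points) with known fitness, survival, and sparse
  interaction structure; multinomial sequencing at configurable depth;
  FASTQ read simulation with substitution errors.
* **barcode_counts** — FASTQ → strain × sample counts via fuzzy
  Levenshtein matching (≤ 2 for tags, ≤ 1 for sample indices), plus the
  screen's QC filters (library depth ≥ 10⁵ reads, count cells ≤ 4
  zeroed, strain coverage ≥ 3,000, presence in both tags).
* **normalize** — median-of-ratios size factors, pseudocount log2
  variance stabilization, reference-strain normalization.
* **phenotype** — per-strain OLS slopes on RMS-scaled time:
  fitness `F_Pro`, survival `S_Qui`, the ANCOVA phase difference
  `S_Qui − F_Pro`, and quiescence-specific gene classification.
* **interactions** — genetic interaction scores by ANCOVA
  (`GIS = f_aq − f_a`, the time × genotype coefficient) and by the
  multiplicative model (`ε = exp(f_aq) − exp(f_a)·exp(f_q)` with
  propagated error `S²_{a+q} = S²_a + S²_q` and a Welch–Satterthwaite
  test), with Benjamini–Hochberg FDR control.
* **profiles** — interaction-profile Pearson correlation, hierarchical
  clustering, replicate PCA QC, correlation networks, and a Monte-Carlo
  multiset intersection test for gene-set overlaps.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Simulate a 500-gene TOR1 double-mutant library plus its matched
single-mutant (HO) library, then score interactions both ways:

```python
import numpy as np
import barseqfit as bf

truth = bf.simulate_truth(n_strains=500, conditions=("C",), queries=("TOR1",),
                          effect_sd=0.2, interaction_fraction=0.1,
                          interaction_sd=0.2, seed=1)
design = bf.TimeCourseDesign(libraries=("HO", "TOR1"), conditions=("C",),
                             n_replicates=3, depth=1_000_000)
scores = bf.workflow.simulate_and_score(truth, design, query="TOR1",
                                        condition="C", seed=1)
print(scores[["gis", "q", "call", "epsilon", "gis_true"]].head())
```

```
            gis         q  call   epsilon  gis_true
gene
G0001  0.028853  0.994746  none -0.061362  0.000000
G0002 -0.035638  0.994746  none -0.122719  0.000000
G0003  0.164150  0.772216  none  0.056096  0.000000
G0004 -0.007303  0.994746  none -0.133959  0.000000
G0005  0.351843  0.221157  none  0.297561  0.323822
```

`gis` is the ANCOVA score (change in log2 relative abundance per unit
scaled time attributable to the query background), `q` its BH-adjusted
p-value, `epsilon` the multiplicative-model score, and `gis_true` the
planted interaction. G0005 carries a true interaction of 0.32 and is
estimated at 0.35; the null genes sit near zero.

```python
both = scores[["gis", "epsilon"]].dropna()
print("estimator agreement r =",
      round(float(np.corrcoef(both["gis"], both["epsilon"])[0, 1]), 3))
called = scores["q"] < 0.05
print("significant interactions:", int(called.sum()),
      "| true positives:", int((scores.loc[called, "gis_true"] != 0).sum()))
```

```
estimator agreement r = 0.924
significant interactions: 8 | true positives: 7
```

The two estimators agree strongly (r = 0.92 here), and of 8 calls at
q < 0.05, 7 are planted interactions — consistent with 5% FDR control.

The same pipeline is available from the shell:

```bash
barseqfit simulate --n-strains 500 --libraries HO,TOR1 --conditions C \
    --seed 1 --outdir sim/
barseqfit filter --up sim/counts.up.tsv --dn sim/counts.dn.tsv \
    --samples sim/counts.samples.tsv --out-prefix sim/filtered
barseqfit interact --counts sim/filtered.merged.tsv \
    --samples sim/filtered.samples.tsv --query TOR1 --condition C \
    --out sim/scores.tsv
```

(`count` turns FASTQ into counts; `fit` writes per-strain
fitness/survival/phase-difference tables; `profile` builds correlation
matrices, dendrograms, and networks from score tables.)

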