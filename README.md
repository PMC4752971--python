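# chemoprofile

A chemogenomics profiling toolkit for small-molecule / protein-target
interaction data. It is aimed at cheminformaticians and chemical biologists
who need to take a heterogeneous bioactivity table (IC50s, Kis, pIC50s, …
across many targets), put every measurement on one comparable scale,
organize the chemistry and the biology into navigable hierarchies, and fill
the gaps with statistical target prediction — the computational machinery
behind a compound–target pharmacology heatmap.

## What it computes

**Activity standardization.** Every readout is first *oriented* onto the
−log10 molar scale (pIC50-like, larger = stronger): concentration types
(IC50, EC50, Potency, AC50, Kd, Ki, in nM) map to −log10(value·10⁻⁹),
p-types (pIC50, pKi, pEC50) pass through, and LogKi is negated. Within each
(target, data type) group the oriented values are z-scored,

&nbsp;&nbsp;&nbsp;&nbsp;z = (x − μ_group) / s_group&nbsp;&nbsp;(sample SD),

so z = +2 always reads "two SDs more potent than typical for this target
and readout", regardless of the original units.

**Chemical space.** Five 1024-bit fingerprints (Daylight-style hashed paths
of 1–7 bonds; Morgan radius 2/3 in atom-type and feature flavors), Tanimoto
similarity Tc = |A∩B|/|A∪B|, and threshold search (default Tc > 0.85).
Compounds are organized into scaffold trees: the Murcko framework is pruned
one prioritized peripheral ring at a time down to a single-ring root, and
chains are merged into a forest that orders the heatmap rows.

**Target prediction.** Two complementary routes:

* *SEA* — a query set's summed above-threshold Tanimoto score against each
  target's ligand set (>10 ligands) is calibrated against random set pairs
  (mean and SD fitted linearly in n₁·n₂) and converted to an E-value through
  the Gumbel tail P(Z > z) = 1 − exp(−e^(−(zπ/√6 + γ))).
* *QSAR* — per target with >20 measured compounds, 15 Bernoulli Naive-Bayes
  models (5 fingerprints × potency cutoffs 4/5/6) trained on exactly
  balanced sets, each weighted by its 5-fold cross-validated MCC (clipped at
  0); the ensemble prediction Σwᵢpᵢ/Σwᵢ is a probability in [0, 1].

**Biology context.** A protein's PPI neighborhood is tested for annotation
enrichment (upper-tail hypergeometric, Benjamini–Hochberg per category),
and the heatmap assembler lays compounds (scaffold order) against targets
(family-tree order) with max-z cells, origin-tagged prediction gap-filling
and lossless TSV/JSON export.

All inputs can be generated synthetically: the `fixtures` module enumerates
compound libraries from a scaffold grammar and plants pharmacophore-driven
activities, PPI modules and covering annotation terms, so the entire
pipeline runs and is testable with no external database.

## Worked example

```python
from chemoprofile import ActivityRecord, DataType, compute_zscores, orient_records

records = orient_records([
    ActivityRecord("aspirin-like", "T1", DataType.IC50, 50.0,     unit="nM"),
    ActivityRecord("fragment-hit", "T1", DataType.IC50, 12_000.0, unit="nM"),
    ActivityRecord("lead",         "T1", DataType.IC50, 3.0,      unit="nM"),
])
records, stats = compute_zscores(records)
```

prints (see `examples/01_standardize_activities.py`):

```
group: target=T1 type=IC50 mean=6.915 sd=1.832 n=3
  aspirin-like  IC50=    50.0 nM  p-value=7.30  z=+0.211
  fragment-hit  IC50= 12000.0 nM  p-value=4.92  z=-1.089
          lead  IC50=     3.0 nM  p-value=8.52  z=+0.878
```

The 3 nM lead scores z = +0.88 — about one SD more potent than the typical
IC50 on this target — while the 12 µM fragment sits one SD below. An analog
search on a 200-compound synthetic library
(`examples/02_similarity_search.py`) finds six compounds at Tc > 0.85 of an
ethyl-benzofuran query, the closest at Tc = 0.944.

One runnable script per capability lives in `examples/`; the `chemoprofile`
console command exposes the same operations as subcommands (`zscore`,
`similar`, `scaffold`, `sea`, `qsar-train`, `qsar-predict`, `enrich`,
`heatmap`, `make-fixtures`).

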