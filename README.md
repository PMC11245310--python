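# affinomap

Quantitative affinity interactomics for SH3 domains and their proline-rich
binding motifs (PRMs), built around the holdup assay: an equilibrium
chromatographic-retention experiment that measures, for each prey, the
fraction depleted from solution by bait-saturated resin.

The package is aimed at interactomics and biophysics groups who want to turn
holdup-style depletion measurements — whether from native holdup coupled to
label-free mass spectrometry (thousands of endogenous full-length proteins at
once) or from fragmentomic peptide panels (site-resolved affinities for
hundreds of synthetic motifs) — into apparent equilibrium constants, and then
analyze those constants at interactome scale: binder calling, cross-bait
similarity, motif discovery, variant perturbation scoring and motif
conservation depth.

## The model

All stages share the single-site hyperbolic binding model. With immobilized
bait at concentration *b*, the binding intensity (BI, the depleted fraction of
a prey) relates to the dissociation constant by

    BI = b / (b + K_d)          K_d = b * (1 − BI) / BI

Affinities are carried as pK = −log₁₀(K_d/M), so a 100 µM K_d is pK 4 and a
100 nM K_d is pK 7, and differences in pK are proportional to binding
free-energy differences. Measurements at or below a panel's BI detection
threshold are *censored*: they carry the detection-threshold pK as an upper
bound on affinity, and every downstream statistic (profile distances,
specificity logos, conservation scores) treats them accordingly.

Around this core the package implements:

- **`affinity`** — BI ↔ K_d ↔ pK conversions with clamping and censoring.
- **`nhu`** — native-holdup MS statistics: median normalization, low-decile
  imputation of missing XIC intensities, equal-variance t-tests on log₂
  intensities, BI/affinity conversion, conjunctive (p, BI) binder calling,
  cross-experiment recall and affinity correlation, cross-bait similarity.
- **`titration`** — partial-activity titration fits, FB(c) = a·c/(c + K_d),
  where a < 1 means only part of the prey population is binding-competent.
- **`motifs`** — class 1 ([RK]xxPxxP) and class 2 (PxxPx[RK]) PxxP motif
  scanning within disordered regions, 15-mer peptide design, enrichment
  arithmetic.
- **`fragmentomics`** — plate-readout conversion with internal-standard
  correction, censored affinity profiles, full-length vs best-motif
  comparison, affinity-weighted specificity logos.
- **`variants`** — censoring-aware Euclidean distances between affinity
  profiles in pK space and WT-like / PAP / LOF classification.
- **`conservation`** — pseudocount log-odds PSSMs from verified binder
  motifs, human-normalized ortholog scoring, per-taxonomic-level
  conservation and conservation depth.
- **`synthetic`** — seed-deterministic generators emulating every input the
  pipeline consumes (proteomes with implanted motifs, nHU-MS tables, plate
  readouts, titration curves, ortholog sets, variant profiles).
- **`io` / `cli`** — TSV/FASTA/YAML readers and writers and an
  `affinomap` subcommand CLI (`simulate`, `scan`, `nhu`, `titrate`,
  `fragment`, `variant-distance`, `conserve`, `report`).

## Worked example

Simulate a 1,000-protein extract and run the full native-holdup pipeline
(`examples/nhu_pipeline.py`):

```python
from affinomap import BaitConcentration, analyze_depletion
from affinomap.synthetic import generate_proteome, simulate_nhu_ms

bait = BaitConcentration.from_micromolar(10.0)
truth = generate_proteome(n_proteins=1000, seed=1)
table = simulate_nhu_ms(truth, seed=2)
results = analyze_depletion(table, bait=bait, seed=3)
```

prints

```
1000 proteins assayed, 87 called significant binders
(ground truth planted 102 binders)

Strongest called partners (apparent pK at 10 uM bait):
  P00934: pK_app 7.06 (truth 7.27), p = 6.2e-04
  P00173: pK_app 7.02 (truth 6.71), p = 3.8e-03
  ...
Replicate experiment: recall 0.89 / 0.88, affinity PCC 0.947 over 71 shared partners
```

Each called partner carries its log₂ fold change, p-value, BI, apparent pK
and censoring flag; the recall line shows how a second, independently noisy
measurement of the same extract recovers the first experiment's binders
(counting sub-significant but depleted partners as recovered). The other
`examples/*.py` scripts walk through the holdup arithmetic, motif scanning,
titration fitting, fragmentomic profiling, variant classification and
conservation scoring in the same style.

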