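# Methods

This note documents the models, the defaults that matter, the synthetic-data
assumptions and the numerical choices behind `affinomap`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Equilibrium holdup model

A holdup experiment reaches binding equilibrium between a resin-immobilized
bait at effective concentration *b* and dilute prey, then separates the
phases; the measured quantity is the binding intensity BI, the depleted prey
fraction. Because the bait is in large excess over the summed prey, BI equals
the single-site fraction bound:

    BI = b / (b + K_d),    K_d = b · (1 − BI) / BI

Affinities are stored as pK = −log₁₀(K_d/M). Internally every concentration
is molar; the I/O layer converts µM/nM explicitly, which removes the most
common class of silent unit errors in pK arithmetic.

Raw BI values below 0 are measurement noise: they are clamped to 0 and
flagged. Raw values ≥ 1 are physically impossible (depletion cannot exceed
the equilibrium bound) and are rejected rather than clamped. A BI at or below
the panel's detection threshold is *censored*: the value carries the
threshold's pK and must be read as an upper bound. The boundary case
BI == threshold is censored, a deterministic tie-break. The package reports
unrounded pK values throughout (e.g. K_d = 0.5 µM is pK 6.301, 1.4 µM is
pK 5.854); rounded figures elsewhere are presentation choices, not model
outputs.

## Native-holdup MS statistics (`nhu`)

The nHU pipeline operates on a proteins × samples XIC intensity table with
bait and control arms:

1. **Median normalization.** Each sample's detected values are scaled by one
   factor so its median matches the grand median of all detected values.
   This corrects loading differences and is idempotent. It presumes binders
   are a small minority of the extract — with many strongly depleted
   proteins the bait-arm median itself shifts; the synthetic generator
   therefore defaults to low binder prevalence (below).
2. **Imputation.** Missing entries are drawn uniformly from the pool of
   detected intensities at or below the global 10% quantile (one pool for
   the entire dataset, not per sample). This mirrors the
   missing-not-at-random behaviour of label-free MS: values are missing
   mostly because they are low. Detected cells are never touched, and the
   draw is deterministic given the seed.
3. **Testing.** Per protein, an unpaired equal-variance two-sided t-test on
   log₂ intensities, bait vs control; injection replicates are treated as
   exchangeable. Zero pooled variance with equal means yields p = 1; with
   distinct means the p-value is floored at the smallest positive double.
4. **Conversion.** BI = 1 − 2^log2fc from the group-mean log₂ fold change
   (clamped at 0 for apparent enrichment). Using the log₂-domain mean keeps
   the estimate consistent with the quantity the t-test addresses and is
   robust to replicate skew, unlike a ratio of linear means.
5. **Calling.** significant = (p ≤ p_cap) AND (BI ≥ bi_threshold), defaults
   p_cap = 0.05 and bi_threshold = 0.128 (at 10 µM bait, BI 0.128
   corresponds to K_d ≈ 68 µM, pK ≈ 4.17). Both knobs are config-exposed and
   recorded in the output metadata.

**Expected null false-call rate.** The conjunctive gate does not control the
false-positive rate below the t-test's directional tail: under the null, 2.5%
of proteins land in the depleted tail at p ≤ 0.05, and whenever the replicate
noise is large enough that a 2.5σ depletion also clears BI ≥ 0.128 (true for
log-normal injection noise with CV ≳ 8% at 3 vs 3 replicates), nearly all of
them pass both gates. At the generator's default CV of 15% the expected null
false-call fraction is therefore ≈ 2.2%, and the test suite checks that
measured rate (≤ 3% with sampling error), not an arbitrarily smaller one.
Users who need a stricter rate should lower p_cap or raise bi_threshold.

**Cross-experiment recall** counts a partner significant in experiment A as
recovered in B if it is significant in B *or* depleted beyond the BI
threshold there (treating measured sub-significant depletion as real); the
stricter significant-only definition is available as an option. Affinity
correlations between experiments or baits use partners significant in both,
with an OLS fit, a pointwise 95% confidence band, and a two-sided p-value
from t = r·√((n−2)/(1−r²)); fewer than 3 shared partners flags the
correlation undefined.

## Titration fitting (`titration`)

Titration holdup varies effective bait concentration by mixing bait-saturated
and control resin (effective concentration = proportion × stock). Curves are
fit to the partial-activity model

    FB(c) = a · c / (c + K_d),   a ∈ (0, 1], K_d ∈ [1e−12, 1e−2] M

by unweighted least squares (replicate SDs, when present, are used as
weights). The free amplitude captures partial binding activity — prey
populations that are only fractionally binding-competent. Initialization is
scale-free: a₀ = max observed FB clipped into (0, 1], K_d₀ = the
concentration whose response is nearest a₀/2. Standard errors come from the
covariance at the optimum. Curves that never exceed 5% fraction bound are
reported as censored no-binding results instead of being force-fitted, and a
fitted K_d outside the titrated concentration range triggers a warning since
it is poorly constrained. On noiseless model data the fit recovers (K_d, a)
to ≤ 1e−6 relative error; with Gaussian noise of sd 0.03 over 8 two-decade
concentrations, the median errors are ≈ 0.04 log₁₀ units in K_d and ≈ 0.015
in a (computed by the acceptance script).

## Motif discovery (`motifs`)

Class 1 ([RK]..P..P, 7 residues) and class 2 (P..P.[RK], 6 residues) PxxP
consensus patterns are scanned with overlap-tolerant lookahead: every match
is reported, overlapping and tandem motifs included, and a window matching
both classes yields two records. "x" positions admit any residue, including
P/R/K. Coordinates are 1-based inclusive. Disorder masks are consumed as
input (from any upstream predictor); by default the entire core must lie in
disorder, with a config switch to require only the fixed consensus positions.
Peptide design centers a 15-mer on the core midpoint (ties toward the
N-terminus) and truncates — never shifts — at protein termini, flagging
shortened peptides. Scanning is property-tested against an exhaustive
sliding-window oracle.

## Fragmentomic profiling (`fragmentomics`)

Plate wells report tryptophan fluorescence of the filtrate plus two internal
standards (fluorescein, mCherry). The depletion ratio is corrected by the
geometric mean of the two standard ratios — a symmetric treatment of two
independent loading controls that exactly cancels any per-well multiplicative
loading factor — then BI = 1 − corrected ratio, clamped into [0, 1).
Censored profiles are built at the panel detection threshold (4 µM bait for
the peptide panels).

**Error propagation.** The pK error of a profile entry is approximately
sd(BI) / (ln10 · BI · (1 − BI)): small for strong binders, steep toward the
detection limit. With 2% per-channel fluorescence noise the corrected ratio
carries ≈ 3.5% noise, so binders with K_d ≤ 5 µM at 4 µM bait recover within
±0.15 pK while a log-uniform 0.5–100 µM panel is expected to land ≈ 87%
within ±0.15. Tests assert exactly this propagated behaviour.

Full-length vs motif comparison selects, per protein, the strongest
*uncensored* motif; proteins whose motifs are all censored are excluded from
the statistics and reported separately. The fraction "FL stronger" counts
strictly positive pK differences (ties excluded). The affinity-weighted
specificity logo weights each binder by its pK margin above the detection
threshold — proportional to its binding free-energy difference from the
detection limit — and normalizes per column; censored peptides contribute
nothing, and the logo is invariant to rescaling all margins.

## Variant scoring (`variants`)

Variant profiles are compared to wild type by the Euclidean distance in pK
space over the shared panel (ΔpK ∝ ΔΔG, so the distance aggregates binding
free-energy changes). Censored entries enter at the detection-threshold pK
and mark the result a lower bound; dimensions censored in both profiles
contribute zero because no information about either value exists. The
distance satisfies the metric axioms on uncensored profiles and never
decreases as additional variant dimensions are censored.

Classification: LOF when ≥ 90% (config) of wild-type-detectable motifs are
censored in the variant; otherwise PAP when the distance exceeds the noise
floor; otherwise WT-like. The noise floor is derived from replicate
wild-type profiles when available (1.5 × mean pairwise replicate distance;
the factor covers the concentration of high-dimensional noise distances)
and is otherwise a config scalar — no universal numeric PAP cutoff exists.

## Conservation depth (`conservation`)

The PSSM over the verified binder motifs (15-mer frames, PxxP core at
positions 7–10) is the canonical pseudocount log-odds:

    P[j, i] = ln( ((c_ij + B/20) / (m + B)) / D_i )

with counts c, pseudocount B = 5, m motifs and background frequencies D
(Swiss-Prot-style eukaryotic composition by default; strictly positive,
summing to 1). The smoothed frequencies exp(P)·D sum to 1 per column, which
is property-tested. Window scoring sums per-position entries; alignment gaps
and X score the column minimum, since a gap cannot support the motif.

Ortholog windows (sharing the reference alignment frame) are scored and
normalized by the human reference score; a nonpositive human score leaves the
ratio undefined rather than guessed. Levels are ordered by distance from
human — Mammalia, Vertebrata, Eumetazoa, Unicellular (eukaryotes only) — with
the human reference as the implicit nearest tier. A level needs ≥ 3 ortholog
instances (otherwise "insufficient"); it is conserved when its mean
normalized score exceeds 0.5; the depth is the most distal conserved level,
conservation at intermediate levels not required (gaps are reported so
stricter monotone rules can be applied downstream). No conserved or scorable
level yields "human-only".

## Synthetic data (`synthetic`)

The generators emulate the statistical shape of the measurements; all are
pure functions of (config, seed).

- **Proteome.** Random sequences at background residue frequencies,
  disordered stretches covering ~40% of each protein, class 1/2 cores
  implanted inside disorder. Motif K_d log-uniform on 0.5–300 µM; the
  protein-level apparent K_d is the best motif K_d divided by a log-uniform
  1–10× avidity factor, emulating full-length proteins binding stronger
  than their isolated motifs. Abundances are log-normal with σ_ln = 1.5
  (≈ 4 decades of dynamic range). The default implant rate of 0.1 keeps
  binder prevalence low, as in a real extract, so median normalization
  remains well-posed.
- **nHU-MS tables.** Control intensities = abundance × log-normal injection
  noise (default CV 15%); bait intensities additionally × (1 − BI_true) at
  10 µM bait. Missingness is logistic in log₁₀ intensity (location 4.5,
  scale 0.3 against a median abundance of 10⁶), the standard
  missing-not-at-random behaviour that the low-pool imputation presumes.
- **Plates.** A per-well log-normal loading factor multiplies all sample
  channels (removable by the internal-standard correction) plus independent
  2% CV fluorescence noise per channel.
- **Titrations.** Model curves plus Gaussian noise, sd 0.03.
- **Orthologs.** The reference motif survives with light substitution noise
  (8% per non-core position) through the planted depth and is fully
  randomized beyond it; flanks mutate freely.
- **Variants.** benign = N(0, 0.05 pK) noise on detectable motifs;
  PAP = the same noise plus a −0.8 pK shift on a random 60% of binders;
  LOF = everything censored. Values falling below detection are re-censored.

What the generators do *not* emulate: peptide-to-protein inference and
shared-peptide effects, correlated (batch) noise across samples, plate
recycling drift beyond a per-well scalar, indirect (complex-mediated)
interactions, real disorder predictor behaviour, and real phylogenetic
covariance among orthologs. Passing recovery tests therefore demonstrate
that the estimators invert the assumed measurement models at realistic noise,
not that every systematic effect in real data is handled.

## Numerical choices and limitations

- p-values are floored at the smallest positive double; correlations over
  < 3 points are flagged undefined rather than returned.
- The titration K_d search window is [1 pM, 10 mM]; fits outside the
  titrated range are warned about, not suppressed.
- Imputation uses a single global low-intensity pool; with very few detected
  values the pool degenerates to the minimum detected value.
- Multi-site, cooperative or avidity-explicit binding models are out of
  scope: full-length vs motif differences are quantified, not mechanistically
  decomposed. No multiple-testing correction is applied across proteins (the
  gate thresholds raw p-values); the expected null false-call rate of the
  default gate is ≈ 2% (see above).
- Conservation depth depends on ortholog sampling; levels with < 3 orthologs
  are reported as insufficient rather than interpolated.
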