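# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirshare`, and what the synthetic benchmark does and does not show.

## Disease gene sets

Associations are rows (gene_id, gene_symbol, term_id, disease_label,
source_class, score).  The provenance filter keeps source classes
`{curated, literature}` with minimum score 0 by default; a score cutoff is
exposed but not applied by default because curated/literature provenance is
the primary reliability filter.  Duplicate (gene, term) rows collapse to
the maximum score.  `gene_id` is the identifier namespace; symbols are
annotation only, because gene symbols are unstable and collide across
sources.  All serialized sets are written in lexicographic order so
repeated runs diff cleanly.

The intersection of two disease unions partitions A∪B into shared, A-only
and B-only sets; the partition identity |A∪B| = |shared| + |A-only| +
|B-only| is property-tested on arbitrary inputs.

## miRNA ranking

Aggregation collapses (miRNA, gene, source) rows to distinct pairs with a
distinct-source count.  `min_sources` defaults to 1 (pure union across
prediction databases); raising it gives a consensus filter.  The two
per-disease count columns are taken against the *full* disease gene
universes, not the exclusive sets — the published counts (e.g. 1588
glioblastoma targets for hsa-miR-16-5p against a 2424-gene exclusive set)
are only consistent with universe counting, and both countings are
available through `count_targets`.

Ranking sorts by shared-target count descending.  The tie-break —
glioblastoma-universe count, then Parkinson-universe count (both
descending), then miRNA id — is this package's deterministic convention;
only the primary key is inherited from the analysis being reproduced, and
the reproduced study's own top-five listing does not follow a pure
descending sort of its printed counts, so no attempt is made to match that
listing order.  Top-decile selection keeps the first ceil(0.10·M) records.

OneR-style clustering is interpreted as ordered equal-frequency binning of
the shared count into four clusters, cluster 1 highest.  Nominal bin sizes
come from an even split of M; a run of tied counts straddling a boundary
stays in the earlier cluster, so later clusters can be empty (an all-tied
input collapses into cluster 1, which is logged).  This keeps the binning
deterministic and monotone: the count never increases across a cluster
boundary.

## Enrichment

The term-level statistic is the hypergeometric upper tail P(X ≥ k) for a
query of size n, term of size K and background N, computed through SciPy's
survival function (k = 0 returns exactly 1).  This is identical to the
one-sided Fisher exact test for over-representation; depletion is not
tested.  BH adjustment is applied across all terms of one library (the
family the reproduced analysis used); cross-library adjustment is off.
Ranks 1..T are assigned over all tested terms by ascending
(p_adj, p, term name) — the term name is the documented tie-break — and the
report keeps terms with p_adj < 0.05 truncated to the top 5.  The
background size N is configurable and defaults to a 20 000-gene
"human genome" constant; tests use the synthetic universe size instead, and
N must be at least the query and every term size.

## Network

Nodes are targets of the two selected miRNAs intersected with the shared
gene list, grouped as A-only / shared / B-only by exclusive vs joint
targeting.  Edges require both endpoints present and confidence ≥ 0.4 (a
STRING-like default; the threshold is exposed).  Self-loops are dropped and
duplicate unordered pairs keep the maximum confidence.  Degree is the only
centrality, matching the "number of connections" criterion.  Cross-group
edges count toward degrees by default and are hidden only in the per-group
layout export — connectivity is assessed before between-group interactions
are hidden; `cross_group_in_degrees=False` provides the other reading,
which is genuinely ambiguous in the source analysis.  Hub lists take the
top 20 (shared) / 15 (per-miRNA) genes by (degree desc, gene id asc); the
circular layout places hubs clockwise from angle 0, evenly spaced on the
unit circle.

## Expression statistics

Relative expression is the efficiency-adjusted ratio
E_t^(ΔCt_t) / E_ref^(ΔCt_ref), ΔCt = calibrator mean Ct − sample Ct.
With both efficiencies exactly 2 this reduces to 2^(−ΔΔCt) (unit-tested to
1e−12).  Efficiencies must lie in (1, 2.2] and default to 2.0 when an
input omits them.  The calibrator is the control (discopathy) group mean in
plasma and the peritumoral mean in tissue — a convention of this package,
configurable, since the exact calibrator of the reproduced analysis is
unstated.  Ct > 40 is treated as missing rather than zero in all group
statistics; zeros would bias group means downward.

ANOVA is one-way fixed-effects computed from the between/within mean
squares; Fisher's LSD post hoc tests are pairwise t-tests on the pooled
within-group MSE with its df and no multiplicity adjustment (that is the
LSD definition, and matches the reproduced analysis's stated absence of a
formal correction).  With two groups F = t² for the pooled-variance t,
verified to 1e−10.  The tumor-vs-peritumoral contrast uses an unpaired
pooled-variance t-test by default; a paired mode exists because the
samples are patient-matched, but pairing was not stated in the source
analysis.  Fold-changes are ratios of group means, reported after half-up
rounding (2 decimals by default; 1 decimal where the published value has
one, e.g. the 2.2-fold protein change from means 0.08/0.036 pg/ng).
ELISA normalization divides analyte mass in the assayed volume by total
protein (pg/ng) and flags concentrations outside the kit range
[9.38, 600] pg/mL without dropping them.  Box-plot summaries use the
Tukey convention (quartile box, 1.5·IQR whiskers, outliers listed).

## Synthetic data: what is emulated

The generators define the benchmark conditions; no generative model exists
in the reproduced analysis (it queried real databases and measured real
samples), so all distributions here are package choices, fixed once:

- **Universe and partition.** 10 000 genes with stable ids/symbols; the
  disease sets (defaults 2177 and 3377 genes over 28 and 14 terms) and
  their 953-gene overlap are planted *exactly*, not sampled, so the set
  sizes reproduce by construction.  Genes get a round-robin-pinned primary
  term (every term non-empty) plus a 20 % chance of one extra term;
  source class is curated/literature (60/40) with Uniform(0,1) scores.
- **Predictions.** 140 miRNAs, the first 14 planted: planted miRNAs hit
  shared genes with probability 0.5 vs a 0.05 background — the same order
  of shared-target counts (≈ 480 of 953) as the published table.  Each
  pair joins each of 14 sources independently with probability 0.7
  (dropout 0.3), forced into ≥ 1 source.
- **GMT library.** 50 terms of 20–120 genes; planted terms draw ≥ 60 % of
  members from the planted pool (the shared genes), background terms draw
  uniformly.
- **Interactome.** Preferential attachment grown from a complete core of
  the planted hubs, each new node linking once to a uniformly chosen hub
  and twice preferentially by degree, so hubs lead the degree distribution
  by construction; or a configuration mode that realizes a prescribed
  degree sequence exactly (Havel–Hakimi plus degree-preserving double edge
  swaps).  Edge confidences are Uniform(0,1).
- **qPCR.** Ct = baseline − effect/log2(E) + Gaussian noise on the Ct
  scale (multiplicative on expression — the conventional qPCR error
  model); default group sizes 10/12/13 (control/PD/glioma) and 13 tissue
  pairs, within-group SD 0.3 Ct, reference (U6) SD 0.1, spike-in SD 0.15.
  Default planted effects equal the published group-mean ratios (plasma
  miR-16-5p 1.76/2.0/5.7; miR-32-5p 1.1/1.4/3.6; tissue miR-16-5p
  1.6/1.1), and miR-124-3p/miR-548c-3p are planted undetectable in plasma
  (Ct > 40).  The default SDs are package choices, *not* estimates of the
  study's variability, which was never published per sample.
- **ELISA.** Log-normal pg/ng levels around 0.08 (tumor) and 0.036
  (peritumoral) with σ = 0.3 on the log scale, back-computed to in-range
  concentrations against Uniform(300, 600) ng protein at 0.1 mL.

Each generator draws from `seed` plus a stable per-generator offset, so
identical config + seed is byte-identical and adding a generator never
perturbs the others.

**What passing does not show.** The benchmark plants clean, independent
Bernoulli/Gaussian structure.  Real gene–disease scores carry evidence
semantics, real prediction databases are strongly correlated (shared
algorithms and training data), real interactomes have degree–function
biases, and real qPCR has inter-plate and extraction effects beyond a
single Gaussian SD.  Recovery of the planted structure validates the
pipeline's correctness and statistical calibration, not the biological
claims of any particular study; the study's own F/t/p values and live
database counts are not reproducible without its unpublished raw data.

## Pipeline and determinism

Stages (simulate → genesets → rank → enrich → network → expression)
communicate only through declared files under the output directory; each
can run alone against a previous run's directory.  The manifest records
every output with a sha256 checksum and is byte-identical for identical
config + seed; per-stage wall time goes to the log, deliberately not into
the manifest, to keep it reproducible.  All thresholds sit in the run
config with defaults equal to the reproduced analysis's stated values
(top 10 %, top 5 terms, adjusted p < 0.05, 20/15 hubs, Ct cutoff 40) and
package conventions elsewhere (min_sources 1, confidence 0.4, background
20 000).

## Problem sizes in tests and the acceptance script

Unit tests run a reduced configuration (400-gene universe, 60/80/30 sets,
20 miRNAs); planted-recovery checks run the default full-scale
configuration over 50 seeds (ranking, enrichment), 100 seeds (hubs,
generator-level), and 200 seeds (qPCR fold recovery at SD 0.3, n = 10 per
group); ANOVA calibration uses 10 000 null simulations of 3 × 10 values.
`scripts/acceptance.py` uses 20/50/100 seeds and 5 000 simulations for the
same quantities — sizes chosen so the whole script completes in well under
a minute while keeping Monte-Carlo error far inside the tolerances tested.

## Known limitations

- OneR clustering is this package's explicit reading (equal-frequency,
  tie-preserving); the original tool's internal feature/target setup is
  unpublished.
- The enrichment background is a single constant; no per-library effective
  background is modeled.
- ELISA standard-curve fitting is out of scope; concentrations are taken
  as input.
- The pipeline's enrichment/network stages select the top two ranked
  miRNAs as the pair of interest; arbitrary pairs are available through
  the library API.
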