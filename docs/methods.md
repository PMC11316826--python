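# Methods

This note documents the evaluation model, the conventions pinned where the
field leaves room, and what the synthetic generator does and does not
emulate.

## Taxonomy synchronization

NCBI taxids are volatile: between taxonomy snapshots, ids are merged into
others or deleted. Evaluating a classifier built on one snapshot against a
truth expressed in another produces spurious mismatches, so every profile is
synchronized against one reference snapshot before evaluation:

- merged ids are rewritten to their current ids, following merge chains
  transitively with a visited-set cycle guard (real dumps are single-hop;
  the guard is cheap insurance);
- entries that collide after remapping are combined by summing counts and
  fractions, conserving abundance mass;
- deleted or unknown ids fall back to an exact, case-insensitive match on
  scientific names only — no fuzzy matching, which risks silent
  misassignment;
- entries that still cannot be placed are dropped, and the drop count and
  dropped abundance mass are reported (output mass + dropped mass = input
  mass to 1e-9).

Synchronization is idempotent: applying it twice equals applying it once.

## Rank projection

Evaluation happens at genus and species rank only; higher ranks are not
meaningful detection targets here and are rejected as arguments. Projection
walks parent links from each entry's resolved taxid:

- entries at or below the target rank map to their ancestor at the rank and
  merge by summation (strain and sub-species "no rank" nodes therefore roll
  up into their species);
- at species rank, an entry whose deepest resolvable rank is genus becomes
  "<Genus> unclassified" pseudo-mass keyed by the genus. These pseudo-entries
  name no species, so they are excluded from species-level detection sets and
  abundance vectors; their mass is tracked separately rather than silently
  discarded or counted as an FP. This is a documented choice — the field's
  reporting conventions do not pin down how genus-only calls should score at
  species rank, and counting them as species-level FPs would penalize
  classifiers for honest rank-level uncertainty;
- entries above genus (or whose lineage lacks the target rank entirely) are
  set aside as higher-rank mass. A taxon whose lineage lacks the target rank
  is reported absent at that rank, never substituted by a higher rank.

Count mass is conserved exactly across the three buckets (entries,
pseudo-unclassified, higher-rank).

## Relative abundance

All relative abundances are over classified reads only: the unclassified
fraction, higher-rank mass and pseudo-unclassified mass are excluded from
every denominator. When every entry carries an exact fraction, fractions are
preferred over integer read counts for normalization (counts are quantized);
kreport-derived profiles carry counts, which are used directly. A profile
with zero classified mass yields an empty vector, not an error.

Sequence abundance (fraction of reads) over-represents large genomes. For
profilers that report taxonomic abundance (fraction of organisms), the truth
is converted before comparison with the genome-length correction

    w'_i = (w_i / L_i) / Σ_j (w_j / L_j),

which is scale-invariant in the lengths L and involutive under reciprocal
lengths. Whole-genome lengths are the expected input; no 16S copy-number
correction is attempted.

## Detection metrics and thresholds

Precision, recall and F1 follow the standard TP/FP/FN definitions with the
0-on-empty-denominator convention. The L1 distance is computed over the
union support of the truth and predicted vectors; when a truth's exact
abundances are unknown, L1 is reported as unavailable and excluded from
aggregation denominators — never silently 0.

Abundance filtering removes taxa with classified-only abundance strictly
below the threshold; a taxon exactly at the threshold is retained ("below
the threshold" implies strict-less removal). Filtered weights are not
renormalized: filtering decides presence, and re-normalizing would move the
surviving taxa's abundances between thresholds. L1 is computed once per
sample on the unfiltered vector, not per threshold.

Two threshold sets are provided: the PR curve uses {0} plus every distinct
predicted abundance (the finest sweep the data supports), and the fixed
sweep grid runs 0% to 1.20% in 0.05% steps (25 rows) for cross-classifier
comparison. Recall and the FP count are non-increasing in the threshold;
precision is deliberately not asserted monotone — a high-abundance false
positive can make precision fall as filtering tightens.

AUPRC is integrated by the trapezoid rule after two pinned constructions:
for each distinct recall only the maximum precision is kept, and an anchor
at recall 0 carrying the precision of the smallest-recall point is
prepended. With this construction the analytic extremes are attainable: a
prediction whose TP abundances all strictly exceed its FP abundances scores
exactly 1, and a prediction disjoint from the truth scores exactly 0.

## Read statistics and preprocessing

- N50: the smallest length L such that reads of length ≥ L contain at least
  half the total bases.
- Q20/Q30: percentage of bases with Phred ≥ 20 / ≥ 30. The ≥ comparison
  follows the convention of standard stats tools.
- Mean read quality: per-base error probabilities are averaged and converted
  back to the Phred scale, −10·log10(mean(10^(−q/10))) — the nanopore
  community convention, which weights low-quality bases more heavily than an
  arithmetic mean of Phred values. The arithmetic mean is available behind
  `method="arithmetic"`.
- Filtering retains reads with length > 1000 and mean quality > 7, both
  strictly.
- Length quartiles use linear interpolation between order statistics, as do
  all medians/quartiles in aggregation (even-count medians are the mean of
  the two central order statistics).
- Subsampling shuffles reads with a seeded PCG64 generator (the algorithm is
  recorded as a module constant so byte-reproducibility is a stated
  contract) and accumulates until the base target is reached; the last read
  may overshoot. A target above the input total returns everything with a
  warning.
- Length-distribution matching bins the reference lengths into quantile bins
  and samples candidates without replacement per bin to the reference bin
  counts; candidates outside the reference length range never match, and
  per-bin shortfalls are reported rather than silently absorbed.

## Synthetic generator

The generator emulates the statistical structure the evaluation assumes:

- **Compositions.** Even (equal fractions), logarithmic (each species
  one-tenth of the previous), and staggered (seeded distinct magnitudes
  spanning at least two orders, normalized) — the three composition types of
  real commercial and consortium mocks. Genome lengths are drawn uniformly
  from 1.5–8 Mb, the typical bacterial range.
- **Classifier error.** Each truth taxon is independently missed with
  probability `fn_prob`; survivors get multiplicative lognormal abundance
  noise with coefficient of variation `noise_cv` (expectation 1, exactly 1
  at cv 0). `n_fp` off-truth species are planted with weights
  `fp_weight_scale` × a log-uniform draw spanning three decades — the heavy
  tail produces the occasional high-abundance false positive that makes
  precision non-monotone under filtering, as real read classifiers do.
  Classified weights are scaled so `unclassified_frac` of read mass stays
  unclassified; counts are materialized at `sequencing_depth` reads
  (default 100,000).
- **Reads.** Lognormal lengths (default ~4.5 kb median, typical of nanopore
  shotgun runs) and one Gaussian-drawn Phred value per read applied to all
  its bases (default mean 12, sd 3, an R9-era profile), clipped to [0, 60].

Simulation is at profile level: classifier internals (k-mer matching,
alignment, database content) are out of scope — the evaluation framework,
not any classifier, is the system under test. Passing tests therefore show
that the metrics, filtering and aggregation behave correctly on profiles
with known TP/FP/FN structure and known abundance error; they say nothing
about how any real classifier performs, and the generator does not emulate
database incompleteness beyond FN planting, chimeric or contaminant reads,
or nanopore error profiles.

Expected values under the generator: over replicates with miss probability
f and k planted FPs on an n-species truth, mean recall → 1 − f and mean
precision → n(1−f) / (n(1−f) + k); at cv 0 with no planted errors every
metric is exact (precision = recall = F1 = AUPRC = 1, L1 = 0). The test
suite checks these at 200 replicates within three standard errors.

## Problem sizes and determinism

Tests and the acceptance script run on mini taxonomies of tens of nodes,
profiles of ≤ 20 taxa, and read sets of ≤ a few hundred simulated reads —
the metrics are set-and-vector computations whose correctness does not
depend on scale, and the brute-force oracles they are checked against are
exact at any size. Every random draw flows through numpy's PCG64 generator
seeded explicitly; fixed seeds give byte-identical files (FASTQ, taxdump,
rendered reports).

## Known limitations

- The generic TSV dialect is the interoperability contract for classifiers
  without a dedicated parser (KMA `.res`, CCMetagen, Kaiju summaries); a
  converter must map their native columns onto it.
- Name-based matching requires exact scientific names; synonym tables and
  fuzzy matching are deliberately out of scope.
- No Bray-Curtis/UniFrac/Aitchison alternatives to L1, and no per-read
  accuracy metrics — profiles are the evaluation unit.
- The staggered composition is parametric, not a replica of any specific
  commercial product's lot sheet.
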