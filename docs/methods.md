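# Methods

## The mapping problem

`ptxmap` builds parent-specific genetic linkage maps for an outbred F1
family — the standard situation in forest-tree genetics, where both
parents are highly heterozygous and no inbred lines exist. At the vast
majority of SNP sites one parent is heterozygous and the other
homozygous, so each such marker segregates 1:1 among the progeny and is
informative for exactly one parent (the pseudo-testcross strategy).
Maternal-informative markers (segregation type *ab×aa*) are mapped like a
backcross onto the mother; paternal-informative markers (*aa×ab*) onto
the father. A pair of markers informative for *different* parents shares
no recombination information, which is why two separate parental maps are
built rather than one integrated map.

The package assumes the dual-reference calling design: the same family is
genotyped twice, once against each parent's rough (contig-level) genome
assembly, and the two call sets cross-validate each other.

## Filter cascade

Thresholds live in `FilterConfig`; defaults are the values used to
assemble a high-quality 1:1 SNP set in a 150-progeny poplar family.

| stage | rule | default |
|---|---|---|
| alignment record | drop if edit distance (NM) > max, best score (AS) < min, or second-best (XS) > best | NM ≤ 9, AS ≥ 60 |
| site discovery | site MQ and depth in at least one parent | MQ ≥ 20, DP ≥ 5 |
| genotype call | per-sample depth and quality; failing calls become missing | DP ≥ 10, GQ > 50 (strict) |
| marker QC | 1:1 chi-square p-value and missingness | p ≥ .01, missing ≤ 10 % |

The alignment rule follows the procedural description (absolute AS ≥ 60
and XS must not exceed AS); an alternative margin-based reading (AS at
least 60 above XS) can be expressed by adjusting both thresholds. The
missing-fraction rule is strict: exactly 10 % missing is kept. The
chi-square statistic is (n_aa − n_ab)²/(n_aa + n_ab) with 1 df and no
continuity correction — at n = 150 the Yates correction is immaterial.
On counts drawn from Bin(150, ½) the p < .01 cut is a discrete test with
true size ≈ 1.14 %, not exactly 1 %; tests compare against the exact size
computed from the binomial distribution.

A homozygous progeny call is coded `aa` regardless of which allele it
carries; a homozygote for the informative parent's private allele is a
Mendelian impossibility and, under this convention, surfaces as an excess
of `aa` caught by the segregation test rather than being silently
dropped.

## Cross-validation and binning

Two loci — one per reference view — are *identical* when their coded
aa/ab vectors have Hamming distance 0 over co-observed progeny.
Comparison is on coded vectors, never nucleotide labels: ref/alt labels
need not agree between two references, so nucleotide-level comparison
strictly deflates match counts. Because the ≤10 % missing filter leaves
differing missing patterns between views, strict all-position equality is
near-unsatisfiable; the default policy therefore requires equality at
every co-observed position (a strict mode is available). The A-side locus
of each match is the mapping unit.

Before ordering, completely linked and physically clustered markers are
binned: two markers merge when they lie on the same contig within 1 kb
and their vectors agree at all co-observed progeny; merging is
transitive, so chains collapse into one bin. The representative is the
member with fewest missing calls (ties: smallest contig, position).
Co-observed rather than byte identity is used so that a marker with a
few missing calls can still join its bin — which is also what makes the
fewest-missing representative rule meaningful. Binning is idempotent.

## Two-point linkage model

For a same-parent 1:1 marker pair, co-observed progeny fall into four
combined classes; under linkage with known phase the recombinant count k
is Binomial(n, r). Phase is unknown and inferred by minimising the
recombinant count (equivalently maximising the likelihood):
r̂ = min(m, n−m)/n with m the off-diagonal class count, phase coupling
when m is the minority, repulsion otherwise, undetermined on a tie
(r̂ = 0.5). The LOD score is the base-10 likelihood ratio against
independence,

    LOD = (n−k) log10(2(1−r̂)) + k log10(2 r̂),    0·log 0 ≡ 0,

the convention under which a pair at r = 0.30 in 150 progeny has expected
LOD n[(1−r)log10(2(1−r)) + r log10(2r)] = 5.36. Map distances use
Kosambi's function d = 25 ln((1+2r)/(1−2r)) cM (inverse
r = tanh(2d/100)/2, round-trip exact to 1e-9 relative over 0–200 cM).
Pairs at r̂ = 0.5 have infinite Kosambi distance; they are never mapped as
an adjacency and an ordering that leaves such a pair adjacent is rejected
as a broken chain. All-pairs matrices are computed by dense integer
matrix products over observation/genotype indicators, so results are
independent of any computation order.

## Grouping

Linkage groups are connected components of the graph with an edge where
pairwise LOD ≥ threshold (single linkage). Raising the threshold only
refines the partition. Published maps choose per-group thresholds from a
range (6–18); with no stated selection rule, `auto_threshold` scans a
threshold list (default 2–20) and picks the smallest threshold producing
exactly the expected number of multi-marker groups with no singletons,
falling back to the closest partition. Group labels are assigned by
decreasing size, then smallest member id, so output is deterministic.

## Ordering

The ordering criterion is the sum of adjacent recombination fractions
(SARF), minimised within each group. The optimiser builds greedy
nearest-neighbour tours from `restarts` random start markers (default
max(20, group size); the identity order is always one candidate) and
improves each by local search: 2-opt segment reversals alternated with
or-opt moves (relocating segments of length 1–3, optionally reversed),
iterated to a joint fixpoint; the best local optimum across restarts is
returned in canonical orientation (first index below last). 2-opt alone
provably gets stuck on a small fraction of random instances — the or-opt
moves close that gap; the combination attains the exhaustive optimum on
all random instances of size ≤ 8 exercised in the tests (the exhaustive
search over permutations modulo reversal is the independent oracle, and
refuses groups above 10 markers). Exact ties between orders are broken
lexicographically, so results are reproducible across runs.

## Map assembly and reports

Adjacent interval distances are Kosambi-transformed adjacent r̂ values;
cumulative positions start at 0 per group; the adjacent phase prediction
is copied from the two-point phase matrix. Summaries report per-group
marker counts and lengths to 2 dp and the map-wide mean adjacent
interval as total length / (markers − groups). Correlation reports are
Pearson, to 4 dp, over per-group statistics (≥ 3 groups required).
Collinearity reports merge a physical anchor table (marker id →
chromosome, bp) with map positions and give per-group anchored fractions
and Spearman rank correlations; scatter output is SVG.

## Synthetic data generator

The generator emulates the study conditions of a dense poplar
pseudo-testcross map: 150 progeny, 19 chromosomes, markers of both
segregation types interleaved along each chromosome, and two
independently noisy reference views of one underlying call set.

* **Meiosis.** Per chromosome and progeny, one maternal and one paternal
  gamete are two-state Markov chains over the marker list: the
  transmitted homolog starts uniformly and switches at each interval
  independently with its true recombination fraction r ∈ [0, 0.5) — no
  crossover interference. Truth is defined on r; Kosambi cM is only a
  reporting transform, matching how the estimators use it.
* **Phase.** The informative allele sits on one homolog throughout, so
  all true adjacent phases are coupling.
* **Parents** are error-free and fully genotyped: parental sites are
  vetted upstream of progeny genotyping, so parental noise is not the
  regime the filters address.
* **Noise.** Per-call missingness, then aa↔ab flips on surviving calls;
  optional viability-style distortion (a distorted marker's call is
  overridden to `aa` with probability d, giving marginal P(ab)=(1−d)/2);
  per-view locus drop-out and independent per-view call flips; synthetic
  DP/GQ drawn so configured call fractions fail the genotyping gates.
  Defaults are all 0 — the noise rates of the motivating study are not
  published, so they are free parameters chosen per experiment.
* **Determinism.** One master seed; each stage derives a child seed via a
  CRC-based `SeedSequence`, so identical (config, seed) reproduce
  byte-identical files (VCFv4.2 with GT/DP/GQ, tab-separated truth and
  key tables).

What the simulator does **not** model: read-level noise (no FASTQ or
alignments — record-level filters are exercised on structured values),
crossover interference, reference-specific allele drop-out correlated
with divergence, linked segregation distortion gradients, or
contig-assignment errors in the rough assemblies. Passing tests
therefore show correctness of the estimators and pipeline logic under
the stated sampling model, not robustness to every artefact of real
short-read data.

## Default problem sizes

The bundled end-to-end check uses 19 chromosomes × 20 markers per parent
per chromosome (alternating, 2.5 cM per adjacent interval, so ~5 cM
between same-parent neighbours), 150 progeny, no noise — a scaled-down
but structurally faithful analogue of a ~2000-marker poplar map; it runs
in seconds and recovers 19 groups per parent with true orders modulo
reversal. Estimator-accuracy checks use n = 10,000 progeny where
binomial standard errors must be small against the quantity checked.

## Known limitations

* Only 1:1 markers are handled; *ab×ab* and *ab×cd* formulas (needed for
  an integrated map) are out of scope.
* No multipoint likelihood: ordering is purely SARF-based; no EM over
  genotyping error.
* Single-linkage grouping can chain groups through one spurious
  high-LOD pair; the threshold scan mitigates but cannot exclude this.
* `--threads` is accepted for interface stability but is a no-op: the
  dense vectorised pairwise computation is already order-independent and
  fast at desk scale.
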