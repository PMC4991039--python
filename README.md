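# ptxmap

Parent-specific genetic linkage maps from pseudo-testcross SNP data in
outbred F1 families.

In crosses between two heterozygous, undomesticated parents (forest
trees being the classic case), most SNPs are heterozygous in exactly one
parent and segregate 1:1 in the progeny. Each parent can then be mapped
like a backcross — the pseudo-testcross strategy. `ptxmap` implements the
full analysis path for the dual-reference variant of this design, where
the family is genotyped twice, once against each parent's rough genome
assembly, and the two call sets validate each other:

1. **Filtering** — alignment-record, site-discovery, genotype-call
   (DP ≥ 10, GQ > 50) and marker-level QC (1:1 chi-square p ≥ .01,
   ≤ 10 % missing);
2. **Cross-validation** — loci called identically in both reference
   views (Hamming distance 0 over coded aa/ab vectors) form the
   high-quality marker set; completely linked markers within 1 kb on a
   contig are binned to one representative;
3. **Two-point linkage** — for each same-parent pair, maximum-likelihood
   recombination fraction r̂ = min(m, n−m)/n with phase, and LOD
   = (n−k)·log₁₀(2(1−r̂)) + k·log₁₀(2r̂) against independence;
4. **Grouping** — connected components at a LOD threshold, with an
   auto-scan targeting an expected group count;
5. **Ordering** — minimum sum of adjacent recombination fractions
   (SARF) by multi-start nearest-neighbour + 2-opt/or-opt local search,
   with an exhaustive oracle for small groups;
6. **Map building** — Kosambi distances d = 25·ln((1+2r)/(1−2r)) cM,
   cumulative positions, adjacent phases, summary statistics,
   correlation and collinearity reports.

A bundled F1 meiosis simulator generates dual-view VCF datasets with
known marker order, per-interval recombination fractions, genotyping
error, missingness, segregation distortion and per-view divergence, so
every stage can be scored against ground truth. See
[docs/methods.md](docs/methods.md) for the model and its assumptions.

## Worked example

Simulate a clean 19-chromosome family of 150 progeny (20 markers per
parent per chromosome) and run the whole pipeline:

```bash
ptxmap all --out demo --simulate --n-progeny 150 --seed 1
```

prints

```
maternal: 376 markers in 19 groups, 1759.90 cM, mean interval 4.93 cM
paternal: 380 markers in 19 groups, 1783.61 cM, mean interval 4.94 cM
```

Each parent's ~380 markers fall into 19 linkage groups — the simulated
karyotype — and within every group the recovered order equals the true
marker order up to reversal. The mean adjacent interval is total map
length / (markers − groups); the simulated truth per same-parent
interval is ~5 cM, and the two-point estimates at n = 150 reproduce it
within sampling error. (The maternal map has a few markers fewer than
the paternal one because the 1:1 chi-square filter removes ~1 % of
markers by test size alone.) `demo/` contains the filtered marker
tables, match/bin tables, rf/LOD matrices, group assignments, ordered
maps with Kosambi positions and phases, summaries and a run log; stage
subcommands (`simulate`, `filter`, `crossval`, `pairs`, `group`,
`order`, `map`, `report`) re-run any step from those files.

From the library, the core quantities are one call away:

```python
>>> from ptxmap import expected_lod, kosambi_distance
>>> round(expected_lod(0.30, 150), 2)   # expected LOD, r=0.30, n=150
5.36
>>> round(kosambi_distance(0.30), 2)    # cM
34.66
```

An expected LOD of 5.36 for a moderately linked pair (r = 0.30) in 150
progeny means such pairs comfortably clear usual grouping thresholds, so
a family of ~150 supports dense maps with adjacent intervals up to the
corresponding Kosambi distance of 34.66 cM.

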