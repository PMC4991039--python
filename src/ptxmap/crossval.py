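"""Cross-validation of the two reference-based call sets and marker binning.

Two call sets derived from the two parental rough references describe the
same family, so a genuine SNP should yield the same coded genotype vector
in both. Loci are declared *identical* when their coded (aa/ab) vectors
have Hamming distance 0 across the progeny; comparing coded vectors
rather than nucleotide-labelled genotypes is essential, because ref/alt
labels need not agree between references. Identical loci form the
high-quality marker set for mapping.

Before ordering, completely linked markers (identical coded vectors)
lying within a short physical window on one contig are collapsed to one
representative to avoid redundant zero-recombination blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

POLICY_CO_OBSERVED = "co-observed"
POLICY_STRICT = "strict"


@dataclass(frozen=True)
class LocusMatch:
    """One locus in dataset A with its identical partners in dataset B."""

    locus_a: str
    loci_b: tuple[str, ...]
    hamming: int
    n_compared: int


def match_identical_loci(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    policy: str = POLICY_CO_OBSERVED,
) -> list[LocusMatch]:
    """Report, per marker in A, all markers in B with identical coded vectors.

    Under the default co-observed policy, progeny where either vector is
    missing are excluded from the comparison and equality is required at
    every co-observed position. The strict policy requires equality at
    every position, missing included. Matching is over coded aa/ab
    vectors, never nucleotide labels.
    """
    if a.progeny != b.progeny:
        raise ValueError("the two datasets must be coded over the same progeny list")
    if policy not in (POLICY_CO_OBSERVED, POLICY_STRICT):
        raise ValueError(f"unknown missing-handling policy {policy!r}")

    matches: list[LocusMatch] = []
    ids_b = b.markers.index.to_numpy()
    if policy == POLICY_STRICT:
        # exact byte identity -> hash join
        keys_b: dict[bytes, list[int]] = {}
        for j, row in enumerate(b.calls):
            keys_b.setdefault(row.tobytes(), []).append(j)
        for i, row in enumerate(a.calls):
            hits = keys_b.get(row.tobytes(), [])
            if hits:
                n_comp = int((row != MISSING).sum())
                matches.append(
                    LocusMatch(a.markers.index[i], tuple(ids_b[hits]), 0, n_comp)
                )
        return matches

    obs_a, obs_b = a.observed(), b.observed()
    for i in range(a.n_markers):
        both = obs_a[i][None, :] & obs_b  # (n_b, n_progeny)
        diff = (a.calls[i][None, :] != b.calls) & both
        n_diff = diff.sum(axis=1)
        n_comp = both.sum(axis=1)
        hit = (n_diff == 0) & (n_comp > 0)
        if hit.any():
            matches.append(
                LocusMatch(
                    a.markers.index[i],
                    tuple(ids_b[hit]),
                    0,
                    int(n_comp[hit].min()),
                )
            )
    return matches


def matches_to_table(matches: list[LocusMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_a": [m.locus_a for m in matches],
            "loci_b": [",".join(m.loci_b) for m in matches],
            "hamming": [m.hamming for m in matches],
            "n_compared": [m.n_compared for m in matches],
        }
    )


def bin_markers(
    mat: GenotypeMatrix, window_bp: int = 1000
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Collapse completely linked, physically clustered markers.

    Two markers are merged when they lie on the same contig within
    ``window_bp`` of each other and their coded vectors agree at every
    co-observed progeny (complete linkage; missing calls do not break
    identity); merging is transitive, so chains of such pairs collapse
    into one bin. Each bin's representative is the member with the
    fewest missing calls, ties broken by smallest (contig, position).
    Returns the representative matrix (input order preserved) and a
    table mapping every marker to its representative.
    """
    m = mat.n_markers
    parent = np.arange(m)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    contig = mat.markers["contig"].to_numpy()
    pos = mat.markers["pos"].to_numpy()
    obs = mat.observed()
    order = np.lexsort((pos, contig.astype(str)))
    for a in range(m):
        i = order[a]
        for b in range(a + 1, m):
            j = order[b]
            if contig[j] != contig[i] or pos[j] - pos[i] > window_bp:
                break
            both = obs[i] & obs[j]
            if both.any() and not np.any((mat.calls[i] != mat.calls[j]) & both):
                union(i, j)

    n_missing = (mat.calls == MISSING).sum(axis=1)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    rep_of = {}
    for members in groups.values():
        members = sorted(
            members, key=lambda i: (n_missing[i], str(contig[i]), pos[i])
        )
        rep = mat.markers.index[members[0]]
        for i in members:
            rep_of[mat.markers.index[i]] = rep

    bin_table = pd.DataFrame(
        {
            "marker_id": list(rep_of),
            "representative": [rep_of[mid] for mid in rep_of],
        }
    ).set_index("marker_id")
    reps = set(bin_table["representative"])
    keep_mask = np.array([mid in reps for mid in mat.markers.index])
    return mat.take(keep_mask), bin_table


def venn_counts(
    datasets: dict[str, GenotypeMatrix], mode: str = "coded"
) -> pd.DataFrame:
    """Pairwise and overall identical-locus counts among >= 2 datasets.

    For each ordered pair (A, B) the count is the number of loci in A
    with at least one identical partner in B; the ``all`` row counts loci
    of each dataset identical to at least one locus of every other.
    ``mode`` selects coded aa/ab comparison or nucleotide-labelled
    comparison (the latter additionally requires equal ref/alt alleles,
    which deflates counts whenever labels differ between references).
    """
    if len(datasets) < 2:
        raise ValueError("at least two datasets required")
    names = list(datasets)

    def _match_ids(a: GenotypeMatrix, b: GenotypeMatrix) -> set[str]:
        matches = match_identical_loci(a, b)
        if mode == "coded":
            return {m.locus_a for m in matches}
        if mode != "nucleotide":
            raise ValueError(f"unknown comparison mode {mode!r}")
        # nucleotide mode: the coded vectors only spell the same base-pair
        # genotypes when ref/alt labels agree in the same orientation
        hits = set()
        for m in matches:
            a_ref, a_alt = a.markers.loc[m.locus_a, ["ref", "alt"]]
            for locus_b in m.loci_b:
                b_ref, b_alt = b.markers.loc[locus_b, ["ref", "alt"]]
                if a_ref == b_ref and a_alt == b_alt:
                    hits.add(m.locus_a)
                    break
        return hits

    rows = []
    per_pair: dict[tuple[str, str], set[str]] = {}
    for x, y in combinations(names, 2):
        hits_xy = _match_ids(datasets[x], datasets[y])
        hits_yx = _match_ids(datasets[y], datasets[x])
        per_pair[(x, y)], per_pair[(y, x)] = hits_xy, hits_yx
        rows.append({"datasets": f"{x}&{y}", "count_in_first": len(hits_xy)})
        rows.append({"datasets": f"{y}&{x}", "count_in_first": len(hits_yx)})
    for x in names:
        others = [per_pair[(x, y)] for y in names if y != x]
        rows.append(
            {"datasets": f"all(from {x})", "count_in_first": len(set.intersection(*others))}
        )
    return pd.DataFrame(rows)
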