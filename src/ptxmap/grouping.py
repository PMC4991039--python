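"""Partition markers into linkage groups at a LOD threshold.

Grouping is single linkage: markers are nodes, an edge joins every pair
whose two-point LOD meets the threshold, and linkage groups are the
connected components. Raising the threshold only refines the partition.
Because real maps are built with per-group thresholds chosen from a
range, a scan utility summarises the partition across thresholds and can
pick the smallest threshold yielding a target number of multi-marker
groups (e.g. the karyotype's chromosome count).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LinkageGroup:
    members: tuple[str, ...]
    threshold: float
    label: str

    def __len__(self) -> int:
        return len(self.members)


def group_markers(
    lod: np.ndarray, threshold: float, marker_ids=None
) -> list[LinkageGroup]:
    """Connected components of the LOD >= threshold graph.

    Groups are labelled ``LG1``, ``LG2``, ... ordered by decreasing size,
    ties broken by smallest member id, so labels are deterministic.
    """
    lod = np.asarray(lod)
    if lod.shape[0] != lod.shape[1]:
        raise ValueError("LOD matrix must be square")
    n = lod.shape[0]
    ids = list(marker_ids) if marker_ids is not None else list(range(n))
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    adj = np.asarray(lod) >= threshold
    np.fill_diagonal(adj, False)
    graph.add_edges_from(zip(*np.nonzero(np.triu(adj))))
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), str(ids[c[0]])))
    return [
        LinkageGroup(tuple(ids[i] for i in comp), threshold, f"LG{k + 1}")
        for k, comp in enumerate(comps)
    ]


def groups_to_table(groups: list[LinkageGroup]) -> pd.DataFrame:
    rows = [
        {"marker_id": m, "group": g.label, "threshold": g.threshold}
        for g in groups
        for m in g.members
    ]
    return pd.DataFrame(rows).set_index("marker_id")


def scan_thresholds(
    lod: np.ndarray, thresholds, marker_ids=None
) -> pd.DataFrame:
    """Partition summary per threshold (ascending).

    Columns: threshold, n_groups (multi-marker), n_singletons,
    largest_group.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        groups = group_markers(lod, t, marker_ids)
        sizes = [len(g) for g in groups]
        rows.append(
            {
                "threshold": t,
                "n_groups": sum(s > 1 for s in sizes),
                "n_singletons": sum(s == 1 for s in sizes),
                "largest_group": max(sizes) if sizes else 0,
            }
        )
    return pd.DataFrame(rows)


def auto_threshold(
    lod: np.ndarray,
    expected_groups: int,
    thresholds=None,
    marker_ids=None,
) -> tuple[float, list[LinkageGroup]]:
    """Smallest scanned threshold whose partition has exactly the expected
    number of multi-marker groups; falls back to the threshold whose
    group count is closest (preferring fewer singletons, then lower
    threshold)."""
    if thresholds is None:
        thresholds = list(range(2, 21))
    best = None
    for t in thresholds:
        groups = group_markers(lod, t, marker_ids)
        n_multi = sum(len(g) > 1 for g in groups)
        n_single = sum(len(g) == 1 for g in groups)
        score = (abs(n_multi - expected_groups), n_single, t)
        if n_multi == expected_groups and n_single == 0:
            return float(t), groups
        if best is None or score < best[0]:
            best = (score, float(t), groups)
    return best[1], best[2]
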