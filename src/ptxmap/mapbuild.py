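"""Assemble ordered linkage groups into parent maps and summary reports.

A parent map lists, per linkage group, the ordered markers with the
adjacent two-point recombination fraction, the Kosambi interval in cM,
the cumulative position from 0 and the predicted linkage phase between
adjacent markers. Summaries follow the conventions of published dense
maps: per-group marker counts and lengths, the mean adjacent interval
total length / (markers - groups), Pearson correlations among group
statistics, per-Mb length differences between the parents' homologous
groups, and genetic-vs-physical collinearity when markers carry anchors
on a reference genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import crossval, filtering, grouping, linkage, ordering, simdata
from .config import FilterConfig
from .matrix import SEG_MATERNAL, SEG_PATERNAL, GenotypeMatrix


@dataclass
class OrderedMap:
    """One parent's linkage map: a per-marker table plus identity metadata.

    ``table`` columns: group, rank, marker_id, r_next, interval_cm,
    cum_cm, phase_next (phase between this marker and the next within
    its group; empty for the last marker of a group).
    """

    table: pd.DataFrame
    parent: str = ""

    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    def group_length(self, group: str) -> float:
        sub = self.table[self.table["group"] == group]
        return float(sub["cum_cm"].iloc[-1])


def build_map(
    groups: list[grouping.LinkageGroup],
    orders: dict[str, ordering.MarkerOrder],
    rf: np.ndarray,
    marker_ids,
    coupling: np.ndarray | None = None,
    parent: str = "",
) -> OrderedMap:
    """Attach Kosambi distances, cumulative positions and phases.

    ``orders`` maps group label -> MarkerOrder over positions within the
    group's member tuple. Adjacent pairs with r_hat = 0.5 are rejected:
    they carry infinite Kosambi distance, so their presence means the
    chain produced by ordering is broken.
    """
    idx_of = {m: i for i, m in enumerate(marker_ids)}
    rows = []
    for grp in groups:
        order = orders[grp.label]
        ordered = [grp.members[i] for i in order.order]
        gi = [idx_of[m] for m in ordered]
        r_next = np.array(
            [rf[gi[i], gi[i + 1]] for i in range(len(gi) - 1)], dtype=float
        )
        if np.any(r_next >= 0.5):
            raise ValueError(
                f"group {grp.label}: adjacent pair at r = 0.5 — ordering "
                "produced a broken chain"
            )
        interval = linkage.kosambi_distance(r_next) if len(r_next) else np.array([])
        cum = np.concatenate([[0.0], np.cumsum(interval)])
        for rank, marker in enumerate(ordered):
            last = rank == len(ordered) - 1
            phase = ""
            if not last and coupling is not None:
                phase = (
                    linkage.COUPLING
                    if coupling[gi[rank], gi[rank + 1]]
                    else linkage.REPULSION
                )
            rows.append(
                {
                    "group": grp.label,
                    "rank": rank,
                    "marker_id": marker,
                    "r_next": np.nan if last else float(r_next[rank]),
                    "interval_cm": np.nan if last else float(interval[rank]),
                    "cum_cm": float(cum[rank]),
                    "phase_next": phase,
                }
            )
    return OrderedMap(pd.DataFrame(rows), parent=parent)


def map_summary(omap: OrderedMap) -> pd.DataFrame:
    """Per-group marker counts and lengths plus a Total row.

    The Total row's mean_interval_cm is total length / (markers -
    groups), the published convention for the average adjacent-marker
    distance of a multi-group map.
    """
    rows = []
    for group in omap.groups():
        sub = omap.table[omap.table["group"] == group]
        intervals = sub["interval_cm"].dropna()
        rows.append(
            {
                "group": group,
                "n_markers": len(sub),
                "length_cm": round(float(sub["cum_cm"].iloc[-1]), 2),
                "mean_interval_cm": (
                    round(float(intervals.mean()), 2) if len(intervals) else np.nan
                ),
                "max_interval_cm": (
                    round(float(intervals.max()), 2) if len(intervals) else np.nan
                ),
                "min_interval_cm": (
                    round(float(intervals.min()), 2) if len(intervals) else np.nan
                ),
            }
        )
    per_group = pd.DataFrame(rows)
    n_markers = int(per_group["n_markers"].sum())
    n_groups = len(per_group)
    total_len = float(per_group["length_cm"].sum())
    total = {
        "group": "Total",
        "n_markers": n_markers,
        "length_cm": round(total_len, 2),
        "mean_interval_cm": mean_adjacent_interval(total_len, n_markers, n_groups),
        "max_interval_cm": per_group["max_interval_cm"].max(),
        "min_interval_cm": per_group["min_interval_cm"].min(),
    }
    return pd.concat([per_group, pd.DataFrame([total])], ignore_index=True)


def mean_adjacent_interval(total_len_cm: float, n_markers: int, n_groups: int) -> float:
    """Average adjacent-marker distance: total cM over (markers - groups)."""
    intervals = n_markers - n_groups
    if intervals <= 0:
        raise ValueError("a map needs at least one adjacent interval")
    return round(total_len_cm / intervals, 2)


def per_mb_length_difference(
    group_a_len_cm: float, group_b_len_cm: float, chrom_size_mb: float
) -> float:
    """Absolute genetic-length difference between homologous groups per Mb."""
    if chrom_size_mb <= 0:
        raise ValueError("chromosome size must be positive")
    return round(abs(group_b_len_cm - group_a_len_cm) / chrom_size_mb, 2)


def group_stat_correlations(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among per-group statistics, to 4 dp.

    Expects one row per linkage group and numeric columns (e.g. maternal
    SNP number, maternal length, paternal SNP number, paternal length,
    chromosome size). At least 3 groups are required.
    """
    numeric = stats_table.select_dtypes("number")
    if len(numeric) < 3:
        raise ValueError("correlations need at least 3 groups")
    return numeric.corr(method="pearson").round(4)


def anchored_fraction(n_anchored: int, n_mapped: int) -> float:
    """Percentage of mapped markers with a physical anchor, to 1 dp."""
    if n_mapped <= 0:
        raise ValueError("no mapped markers")
    return round(100.0 * n_anchored / n_mapped, 1)


def collinearity_points(
    omap: OrderedMap, anchors: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genetic-vs-physical scatter data for anchored markers.

    ``anchors`` is indexed by marker id with columns ``chrom`` and
    ``bp``. Returns (points, per_group): points has one row per anchored
    mapped marker (group, cum_cm, chrom, mb); per_group reports the
    anchored fraction and the Spearman rank correlation of genetic vs
    physical position within each group (NaN with < 3 anchored markers
    or zero variance).
    """
    if anchors.empty:
        return (
            pd.DataFrame(columns=["group", "marker_id", "cum_cm", "chrom", "mb"]),
            pd.DataFrame(columns=["group", "n_markers", "n_anchored", "anchored_pct", "spearman"]),
        )
    merged = omap.table.merge(
        anchors, left_on="marker_id", right_index=True, how="left"
    )
    merged["mb"] = merged["bp"] / 1e6
    points = merged.dropna(subset=["bp"])[["group", "marker_id", "cum_cm", "chrom", "mb"]]
    rows = []
    for group, sub in omap.table.groupby("group", sort=False):
        pts = points[points["group"] == group]
        rho = np.nan
        if len(pts) >= 3 and pts["mb"].nunique() > 1 and pts["cum_cm"].nunique() > 1:
            rho = float(stats.spearmanr(pts["mb"], pts["cum_cm"]).statistic)
        rows.append(
            {
                "group": group,
                "n_markers": len(sub),
                "n_anchored": len(pts),
                "anchored_pct": anchored_fraction(len(pts), len(sub)) if len(sub) else np.nan,
                "spearman": rho,
            }
        )
    return points.reset_index(drop=True), pd.DataFrame(rows)


def plot_collinearity(points: pd.DataFrame, path: str | Path) -> Path:
    """SVG scatter of genetic (cM) against physical (Mb) positions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for group, sub in points.groupby("group", sort=False):
        ax.scatter(sub["mb"], sub["cum_cm"], s=6, label=str(group))
    ax.set_xlabel("physical position (Mb)")
    ax.set_ylabel("genetic position (cM)")
    if points["group"].nunique() <= 20:
        ax.legend(fontsize=5, ncol=2)
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path


# ----------------------------------------------------------------------
# End-to-end pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs and thresholds for one full run.

    Either both VCF paths are given, or ``simulate`` is set and a
    synthetic dataset is generated in the output directory first.
    """

    outdir: str = "ptxmap_out"
    vcf_a: str | None = None
    vcf_b: str | None = None
    mother: str = "MOTHER"
    father: str = "FATHER"
    filters: FilterConfig = field(default_factory=FilterConfig)
    lod_threshold: float | None = None
    expected_groups: int | None = 19
    bin_window_bp: int = 1000
    restarts: int | None = None
    seed: int = 0
    simulate: bool = False
    sim_n_progeny: int = 150
    sim_chromosomes: int = 19
    sim_markers_per_parent: int = 20
    sim_interval_cm: float = 2.5
    sim_missing_rate: float = 0.0
    sim_error_rate: float = 0.0


@dataclass
class PipelineResult:
    maps: dict[str, OrderedMap]
    summaries: dict[str, pd.DataFrame]
    filtered: dict[str, GenotypeMatrix]
    n_matched: dict[str, int]
    artifacts: dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Filter -> cross-validate -> bin -> pair -> group -> order -> map.

    Writes all intermediate tables and a run log of thresholds and seeds
    under ``config.outdir`` and returns the in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed\t{config.seed}", f"filters\t{config.filters}"]
    artifacts: dict[str, Path] = {}

    if config.simulate:
        spec = simdata.ParentSpec.regular(
            n_chromosomes=config.sim_chromosomes,
            markers_per_parent=config.sim_markers_per_parent,
            interval_cm=config.sim_interval_cm,
            seed=config.seed,
        )
        ds = simdata.simulate_dataset(
            spec,
            n_progeny=config.sim_n_progeny,
            seed=config.seed,
            missing_rate=config.sim_missing_rate,
            error_rate=config.sim_error_rate,
        )
        paths = simdata.write_dataset(ds, outdir / "sim")
        config.vcf_a, config.vcf_b = str(paths["vcf_a"]), str(paths["vcf_b"])
        artifacts.update(paths)
        log.append(f"simulated\tn={config.sim_n_progeny}")
    if not config.vcf_a or not config.vcf_b:
        raise ValueError("two input VCFs are required (or set simulate=True)")

    mats = {}
    for tag, path in (("A", config.vcf_a), ("B", config.vcf_b)):
        mat = filtering.matrix_from_vcf(
            path, config.mother, config.father, config.filters, source=tag
        )
        if mat.n_progeny == 0:
            raise ValueError(f"no progeny samples in {path}")
        mats[tag] = filtering.marker_qc(mat, config.filters)
        table_path = outdir / f"filtered_{tag}.tsv"
        mats[tag].to_table().to_csv(table_path, sep="\t")
        artifacts[f"filtered_{tag}"] = table_path

    maps: dict[str, OrderedMap] = {}
    summaries: dict[str, pd.DataFrame] = {}
    filtered: dict[str, GenotypeMatrix] = {}
    n_matched: dict[str, int] = {}
    for parent, seg in (("maternal", SEG_MATERNAL), ("paternal", SEG_PATERNAL)):
        a_seg = mats["A"].by_seg_type(seg)
        b_seg = mats["B"].by_seg_type(seg)
        matches = crossval.match_identical_loci(a_seg, b_seg)
        match_path = outdir / f"matches_{parent}.tsv"
        crossval.matches_to_table(matches).to_csv(match_path, sep="\t", index=False)
        artifacts[f"matches_{parent}"] = match_path
        matched = a_seg.select_ids([m.locus_a for m in matches])
        n_matched[parent] = matched.n_markers
        binned, bin_table = crossval.bin_markers(matched, config.bin_window_bp)
        bin_path = outdir / f"bins_{parent}.tsv"
        bin_table.to_csv(bin_path, sep="\t")
        artifacts[f"bins_{parent}"] = bin_path
        filtered[parent] = binned
        log.append(
            f"{parent}\tfiltered={a_seg.n_markers}\tmatched={matched.n_markers}"
            f"\tbinned={binned.n_markers}"
        )
        if binned.n_markers < 2:
            raise ValueError(f"too few {parent} markers after filtering/binning")

        rf, lod, n, coupling = linkage.pairwise_matrix(binned)
        ids = list(binned.marker_ids)
        for name, matx in (("rf", rf), ("lod", lod)):
            p = outdir / f"{name}_{parent}.tsv"
            pd.DataFrame(matx, index=ids, columns=ids).to_csv(p, sep="\t")
            artifacts[f"{name}_{parent}"] = p

        if config.lod_threshold is not None:
            threshold = float(config.lod_threshold)
            groups = grouping.group_markers(lod, threshold, ids)
        else:
            threshold, groups = grouping.auto_threshold(
                lod, config.expected_groups or 19, marker_ids=ids
            )
        log.append(f"{parent}\tlod_threshold={threshold}\tgroups={len(groups)}")
        group_path = outdir / f"groups_{parent}.tsv"
        grouping.groups_to_table(groups).to_csv(group_path, sep="\t")
        artifacts[f"groups_{parent}"] = group_path

        idx_of = {m: i for i, m in enumerate(ids)}
        orders = {}
        for grp in groups:
            gi = np.array([idx_of[m] for m in grp.members])
            orders[grp.label] = ordering.order_group(
                rf[np.ix_(gi, gi)],
                restarts=config.restarts,
                seed=simdata.child_seed(config.seed, f"order-{parent}-{grp.label}"),
            )
        omap = build_map(groups, orders, rf, ids, coupling=coupling, parent=parent)
        maps[parent] = omap
        map_path = outdir / f"map_{parent}.tsv"
        omap.table.to_csv(map_path, sep="\t", index=False)
        artifacts[f"map_{parent}"] = map_path
        summaries[parent] = map_summary(omap)
        sum_path = outdir / f"summary_{parent}.tsv"
        summaries[parent].to_csv(sum_path, sep="\t", index=False)
        artifacts[f"summary_{parent}"] = sum_path

    log_path = outdir / "run_log.tsv"
    log_path.write_text("\n".join(log) + "\n")
    artifacts["run_log"] = log_path
    return PipelineResult(maps, summaries, filtered, n_matched, artifacts)
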