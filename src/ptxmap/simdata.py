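"""Synthetic F1 pseudo-testcross datasets with known truth.

The simulator emulates the data situation of a dense linkage-mapping
study in an outbred tree cross: two heterozygous parents, N progeny,
markers segregating 1:1 (heterozygous in exactly one parent), and two
independently noisy "reference views" of the same underlying genotypes —
one call set per parental rough reference assembly.

Meiosis model
-------------
Each chromosome carries an ordered list of markers with a true
recombination fraction r in [0, 0.5) per adjacent interval. For every
progeny, one maternal and one paternal gamete are simulated as two-state
Markov chains along the marker list: the transmitted homolog starts
uniformly and switches at each interval independently with probability r
(no crossover interference across intervals). A maternal-informative
marker (abxaa) reads the maternal gamete — transmitted allele b codes the
progeny ab, allele a codes aa — and paternal-informative markers read the
paternal gamete. The informative parent's phase is coupling throughout
(allele b resides on one homolog), so true adjacent phases are coupling.

Noise is layered on afterwards: per-call missingness and aa<->ab call
errors (``degrade``), optional viability-style segregation distortion,
and per-view locus drop-out plus independent call flips with synthetic
DP/GQ values (``emit_dual_views``). All randomness derives from one
master seed via deterministic child streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import kosambi_distance, kosambi_inverse
from .matrix import AA, AB, MISSING, SEG_MATERNAL, SEG_PATERNAL, GenotypeMatrix

_BASES = np.array(list("ACGT"))


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31 (process-stable)."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))


@dataclass
class ChromosomeSpec:
    """Marker layout of one chromosome.

    ``r_intervals[i]`` is the true recombination fraction between markers
    i and i+1 over the full (interleaved maternal/paternal) marker list;
    both meioses use the same interval fractions.
    """

    name: str
    seg_types: list[str]
    r_intervals: np.ndarray
    positions_bp: np.ndarray       # genome coordinate, 1-based, increasing
    contigs: list[str]
    contig_pos: np.ndarray         # 1-based within-contig position
    distortion: np.ndarray | None = None  # per-marker P(override call to aa)

    def __post_init__(self) -> None:
        m = len(self.seg_types)
        self.r_intervals = np.asarray(self.r_intervals, dtype=float)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.contig_pos = np.asarray(self.contig_pos, dtype=np.int64)
        if len(self.r_intervals) != max(m - 1, 0):
            raise ValueError("need one r per adjacent marker pair")
        if np.any(self.r_intervals < 0) or np.any(self.r_intervals >= 0.5):
            raise ValueError("true recombination fractions must lie in [0, 0.5)")
        if m > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise ValueError("physical positions must be strictly increasing")
        bad = set(self.seg_types) - {SEG_MATERNAL, SEG_PATERNAL}
        if bad:
            raise ValueError(f"unknown segregation types: {bad}")
        if self.distortion is None:
            self.distortion = np.zeros(m)

    @property
    def n_markers(self) -> int:
        return len(self.seg_types)


@dataclass
class ParentSpec:
    """Full-genome marker layout for the cross."""

    chromosomes: list[ChromosomeSpec]

    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 19,
        markers_per_parent: int = 20,
        interval_cm: float = 5.0,
        marker_spacing_bp: int = 50_000,
        contig_bp: int = 200_000,
        distortion: float = 0.0,
        distorted_fraction: float = 0.0,
        seed: int = 0,
    ) -> "ParentSpec":
        """Evenly spaced layout: per chromosome, ``markers_per_parent``
        maternal and as many paternal markers, strictly alternating, with
        every adjacent interval worth ``interval_cm`` Kosambi cM. Contigs
        fragment each chromosome every ``contig_bp`` bases, mimicking a
        rough short-read assembly."""
        rng = np.random.default_rng(seed)
        r = float(kosambi_inverse(interval_cm))
        chroms = []
        for c in range(1, n_chromosomes + 1):
            m = 2 * markers_per_parent
            seg = [SEG_MATERNAL if i % 2 == 0 else SEG_PATERNAL for i in range(m)]
            pos = np.arange(1, m + 1, dtype=np.int64) * marker_spacing_bp
            contig_idx = (pos - 1) // contig_bp
            contigs = [f"chr{c:02d}_ctg{i:04d}" for i in contig_idx]
            contig_pos = pos - contig_idx * contig_bp
            dist = np.zeros(m)
            if distorted_fraction > 0:
                hit = rng.random(m) < distorted_fraction
                dist[hit] = distortion
            chroms.append(
                ChromosomeSpec(
                    name=f"chr{c:02d}",
                    seg_types=seg,
                    r_intervals=np.full(m - 1, r),
                    positions_bp=pos,
                    contigs=contigs,
                    contig_pos=contig_pos,
                    distortion=dist,
                )
            )
        return cls(chroms)

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)


@dataclass
class SimTruth:
    """Everything needed to score a pipeline run against the simulation."""

    spec: ParentSpec
    seed: int
    n_progeny: int
    error_rate: float = 0.0
    missing_rate: float = 0.0
    drop_prob: tuple[float, float] = (0.0, 0.0)
    flip_prob: tuple[float, float] = (0.0, 0.0)

    def table(self) -> pd.DataFrame:
        """True order / position / interval table, one row per marker."""
        rows = []
        for chrom in self.spec.chromosomes:
            r_next = list(chrom.r_intervals) + [np.nan]
            for i in range(chrom.n_markers):
                rows.append(
                    {
                        "marker_id": f"{chrom.name}_m{i:04d}",
                        "chrom": chrom.name,
                        "order_index": i,
                        "seg_type": chrom.seg_types[i],
                        "r_true_next": r_next[i],
                        "cm_true_next": (
                            kosambi_distance(r_next[i])
                            if np.isfinite(r_next[i])
                            else np.nan
                        ),
                        "pos_bp": int(chrom.positions_bp[i]),
                        "contig": chrom.contigs[i],
                        "contig_pos": int(chrom.contig_pos[i]),
                    }
                )
        return pd.DataFrame(rows).set_index("marker_id")


def simulate_progeny(spec: ParentSpec, n: int, seed: int) -> GenotypeMatrix:
    """Simulate true coded genotypes for n progeny of the cross."""
    if n < 1:
        raise ValueError("need at least one progeny")
    rng = _stage_rng(seed, "meiosis")
    progeny = [f"P{i + 1:03d}" for i in range(n)]
    blocks, meta = [], []
    for chrom in spec.chromosomes:
        m = chrom.n_markers
        gametes = {}
        for parent in ("mat", "pat"):
            start = rng.integers(0, 2, size=n, dtype=np.int8)
            if m > 1:
                switch = rng.random((m - 1, n)) < chrom.r_intervals[:, None]
                cum = np.vstack(
                    [np.zeros(n, dtype=np.int64), np.cumsum(switch, axis=0)]
                )
                state = ((start[None, :].astype(np.int64) + cum) % 2).astype(np.int8)
            else:
                state = start[None, :]
            gametes[parent] = state
        calls = np.empty((m, n), dtype=np.int8)
        for i, seg in enumerate(chrom.seg_types):
            src = gametes["mat"] if seg == SEG_MATERNAL else gametes["pat"]
            calls[i] = np.where(src[i] == 1, AB, AA)
            d = chrom.distortion[i]
            if d > 0:
                calls[i] = np.where(rng.random(n) < d, AA, calls[i])
        blocks.append(calls)
        ref = _BASES[rng.integers(0, 4, size=m)]
        alt_shift = rng.integers(1, 4, size=m)
        alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
        for i in range(m):
            meta.append(
                {
                    "marker_id": f"{chrom.name}_m{i:04d}",
                    "chrom": chrom.name,
                    "order_index": i,
                    "contig": chrom.contigs[i],
                    "pos": int(chrom.contig_pos[i]),
                    "chrom_pos": int(chrom.positions_bp[i]),
                    "ref": ref[i],
                    "alt": alt[i],
                    "seg_type": chrom.seg_types[i],
                }
            )
    markers = pd.DataFrame(meta).set_index("marker_id")
    return GenotypeMatrix(markers, np.vstack(blocks), progeny)


def degrade(
    true: GenotypeMatrix, missing_rate: float, error_rate: float, seed: int
) -> GenotypeMatrix:
    """Apply per-call missingness then aa<->ab call errors to progeny calls.

    Parents are never degraded (parental genotypes live in the marker
    metadata, not the call array)."""
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _stage_rng(seed, "degrade")
    calls = true.calls.copy()
    miss = rng.random(calls.shape) < missing_rate
    flip = rng.random(calls.shape) < error_rate
    surviving = ~miss & (calls != MISSING)
    calls[surviving & flip] = AB + AA - calls[surviving & flip]
    calls[miss] = MISSING
    return GenotypeMatrix(true.markers.copy(), calls, true.progeny, dp=None, gq=None)


# ----------------------------------------------------------------------
# Dual reference views
# ----------------------------------------------------------------------

def _synthesise_dp_gq(
    shape: tuple[int, int],
    rng: np.random.Generator,
    dp_fail_frac: float,
    gq_fail_frac: float,
    min_dp: int = 10,
    min_gq: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """DP/GQ drawn so configured call fractions fail the genotyping gates."""
    dp = min_dp + rng.poisson(15, size=shape)
    gq = min_gq + 1 + rng.integers(0, 48, size=shape)
    dp_fail = rng.random(shape) < dp_fail_frac
    gq_fail = rng.random(shape) < gq_fail_frac
    dp[dp_fail] = rng.integers(0, min_dp, size=int(dp_fail.sum()))
    gq[gq_fail] = rng.integers(0, min_gq + 1, size=int(gq_fail.sum()))
    return dp.astype(np.int32), gq.astype(np.int32)


def emit_dual_views(
    observed: GenotypeMatrix,
    truth: SimTruth,
    view_names: tuple[str, str] = ("PD", "PS"),
    dp_fail_frac: float = 0.0,
    gq_fail_frac: float = 0.0,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Derive the two reference-view call sets and their correspondence key.

    Each view renames loci into view-specific contig coordinates,
    independently drops loci (``truth.drop_prob``) and injects
    independent aa<->ab call errors (``truth.flip_prob``), and receives
    synthetic DP/GQ values. The key table records which loci in the two
    views are the same underlying marker (empty id where a view dropped
    the locus)."""
    views = []
    key = pd.DataFrame(index=observed.markers.index.copy())
    for v, name in enumerate(view_names):
        rng = _stage_rng(truth.seed, f"view-{name}")
        keep = rng.random(observed.n_markers) >= truth.drop_prob[v]
        sub = observed.take(keep)
        calls = sub.calls.copy()
        flip = (rng.random(calls.shape) < truth.flip_prob[v]) & (calls != MISSING)
        calls[flip] = AB + AA - calls[flip]
        markers = sub.markers.copy()
        markers["contig"] = [f"{name}_{c}" for c in markers["contig"]]
        new_ids = [
            f"{c}_{p}" for c, p in zip(markers["contig"], markers["pos"])
        ]
        markers.index = pd.Index(new_ids, name="marker_id")
        dp, gq = _synthesise_dp_gq(calls.shape, rng, dp_fail_frac, gq_fail_frac)
        views.append(GenotypeMatrix(markers, calls, sub.progeny, dp=dp, gq=gq))
        col = np.full(observed.n_markers, "", dtype=object)
        col[np.flatnonzero(keep)] = new_ids
        key[name] = col
    return views[0], views[1], key


# ----------------------------------------------------------------------
# VCF / truth-table output
# ----------------------------------------------------------------------

def write_vcf(view: GenotypeMatrix, path: str | Path, mq: int = 60) -> Path:
    """Write a view as a sorted VCFv4.2 file with GT/DP/GQ per sample.

    The two parents (MOTHER, FATHER) precede the progeny; parental calls
    follow the marker's segregation type and are emitted fully observed
    at high depth/quality, matching the upstream workflow in which
    parental sites are vetted before progeny genotyping."""
    path = Path(path)
    markers = view.markers
    order = np.lexsort((markers["pos"].to_numpy(), markers["contig"].to_numpy()))
    gt_str = {AA: "0/0", AB: "0/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for contig in pd.unique(markers["contig"].to_numpy()[order]):
        sub = markers[markers["contig"] == contig]
        lines.append(f"##contig=<ID={contig},length={int(sub['pos'].max()) + 1000}>")
    samples = ["MOTHER", "FATHER"] + list(view.progeny)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for idx in order:
        row = markers.iloc[idx]
        seg = row["seg_type"]
        mother = "0/1" if seg == SEG_MATERNAL else "0/0"
        father = "0/1" if seg == SEG_PATERNAL else "0/0"
        fields = [
            str(row["contig"]),
            str(int(row["pos"])),
            str(markers.index[idx]),
            str(row["ref"]),
            str(row["alt"]),
            "999",
            "PASS",
            f"MQ={mq}",
            "GT:DP:GQ",
            f"{mother}:60:99",
            f"{father}:60:99",
        ]
        dp = view.dp[idx] if view.dp is not None else np.full(view.n_progeny, 30)
        gq = view.gq[idx] if view.gq is not None else np.full(view.n_progeny, 99)
        for j in range(view.n_progeny):
            call = view.calls[idx, j]
            d = 0 if call == MISSING else int(dp[j])
            fields.append(f"{gt_str[call]}:{d}:{int(gq[j])}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    truth: SimTruth
    true_matrix: GenotypeMatrix
    observed: GenotypeMatrix
    view_a: GenotypeMatrix
    view_b: GenotypeMatrix
    key: pd.DataFrame
    view_names: tuple[str, str] = ("PD", "PS")


def simulate_dataset(
    spec: ParentSpec,
    n_progeny: int = 150,
    seed: int = 0,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    drop_prob: tuple[float, float] = (0.0, 0.0),
    flip_prob: tuple[float, float] = (0.0, 0.0),
    dp_fail_frac: float = 0.0,
    gq_fail_frac: float = 0.0,
) -> SimulatedDataset:
    """One-call generation of truth, degraded calls and both views."""
    truth = SimTruth(
        spec=spec,
        seed=seed,
        n_progeny=n_progeny,
        error_rate=error_rate,
        missing_rate=missing_rate,
        drop_prob=drop_prob,
        flip_prob=flip_prob,
    )
    true_matrix = simulate_progeny(spec, n_progeny, seed)
    observed = degrade(true_matrix, missing_rate, error_rate, seed)
    view_a, view_b, key = emit_dual_views(
        observed, truth, dp_fail_frac=dp_fail_frac, gq_fail_frac=gq_fail_frac
    )
    return SimulatedDataset(truth, true_matrix, observed, view_a, view_b, key)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write VCFs for both views, the truth table and the locus key."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf_a": write_vcf(ds.view_a, outdir / f"{ds.view_names[0]}.vcf"),
        "vcf_b": write_vcf(ds.view_b, outdir / f"{ds.view_names[1]}.vcf"),
        "truth": outdir / "truth.tsv",
        "key": outdir / "locus_key.tsv",
    }
    ds.truth.table().to_csv(paths["truth"], sep="\t")
    ds.key.to_csv(paths["key"], sep="\t")
    return paths
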