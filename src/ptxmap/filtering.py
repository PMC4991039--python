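"""SNP filter cascade: alignment records -> QC-passed genotype matrix.

The cascade mirrors the discovery-and-genotyping workflow for a
dual-reference F1 mapping family:

1. alignment-record filter on edit distance (NM), best alignment score
   (AS) and second-best score (XS);
2. parental site discovery at site mapping quality >= 20 and parental
   depth >= 5, merging sites found in either parent;
3. per-sample genotype calling at DP >= 10 and GQ > 50 (calls failing
   either are set missing);
4. segregation typing from the two parental genotypes (only markers
   heterozygous in exactly one parent segregate 1:1 and are mappable);
5. marker-level QC: 1:1 chi-square test at p >= .01 and missingness
   <= 10 % of the progeny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterConfig
from .matrix import (
    AA,
    AB,
    MAPPABLE_SEG_TYPES,
    MISSING,
    SEG_BOTH_HET,
    SEG_MATERNAL,
    SEG_MONOMORPHIC,
    SEG_PATERNAL,
    SEG_UNTYPED,
    GenotypeMatrix,
)


@dataclass(frozen=True)
class AlignmentRecordView:
    """The alignment-record fields the record filter inspects."""

    edit_distance: int            # NM tag
    best_score: int               # AS tag
    second_best_score: int | None = None  # XS tag, absent for unique hits

    def __post_init__(self) -> None:
        if self.edit_distance < 0:
            raise ValueError("edit distance must be non-negative")


def keep_alignment(record: AlignmentRecordView, cfg: FilterConfig = FilterConfig()) -> bool:
    """Record-level filter: drop noisy or ambiguously placed alignments.

    A record is dropped iff its edit distance exceeds the maximum, its
    best alignment score falls below the minimum, or a second-best
    alignment outscores the best. An absent second-best score never
    triggers the third clause.
    """
    if record.edit_distance > cfg.max_edit_distance:
        return False
    if record.best_score < cfg.min_best_score:
        return False
    if record.second_best_score is not None and record.second_best_score > record.best_score:
        return False
    return True


def discover_parental_sites(parent_calls, cfg: FilterConfig = FilterConfig()) -> list:
    """Select SNP sites discovered in either parent, deduplicated by locus.

    ``parent_calls`` is an iterable of mappings (or objects) with ``locus``,
    ``mq`` and ``dp`` entries; a site is retained when MQ >= min_site_mq and
    DP >= min_discovery_dp in at least one parent. The union of retained
    loci, in first-seen order, is returned.
    """
    seen: dict = {}
    for call in parent_calls:
        get = call.get if hasattr(call, "get") else lambda k, c=call: getattr(c, k)
        locus, mq, dp = get("locus"), get("mq"), get("dp")
        if mq >= cfg.min_site_mq and dp >= cfg.min_discovery_dp:
            seen.setdefault(locus, None)
    return list(seen)


def call_genotype(gt_code: int, dp: float, gq: float, cfg: FilterConfig = FilterConfig()) -> np.int8:
    """Code one progeny call as aa/ab/missing under depth/quality gates.

    ``gt_code`` uses the cyvcf2 convention (0 hom-ref, 1 het, 3 hom-alt,
    2 unknown). The returned code is relative to the segregating parent:
    heterozygous -> ab, homozygous -> aa. A call with DP below the
    genotype threshold or GQ not exceeding the quality threshold is
    missing.
    """
    if gt_code == 2 or dp < cfg.min_genotype_dp or gq <= cfg.min_gq:
        return MISSING
    return AB if gt_code == 1 else AA


def classify_segregation(maternal_gt: str, paternal_gt: str) -> str:
    """Segregation type of a biallelic SNP from the two parental genotypes.

    Genotypes are allele pairs like ``"A/C"``. A marker heterozygous in
    the mother and homozygous in the father is maternal-informative
    (abxaa); the reverse is paternal-informative (aaxab); both
    heterozygous is abxab (not 1:1, excluded from pseudo-testcross
    mapping); both homozygous is monomorphic in the cross. A missing
    parental genotype leaves the marker untyped.
    """

    def _het(gt: str) -> bool | None:
        if gt is None:
            return None
        alleles = gt.replace("|", "/").split("/")
        if len(alleles) != 2 or "." in alleles:
            return None
        return alleles[0] != alleles[1]

    mat, pat = _het(maternal_gt), _het(paternal_gt)
    if mat is None or pat is None:
        return SEG_UNTYPED
    if mat and not pat:
        return SEG_MATERNAL
    if pat and not mat:
        return SEG_PATERNAL
    if mat and pat:
        return SEG_BOTH_HET
    return SEG_MONOMORPHIC


def chi_square_1to1(n_aa: int, n_ab: int) -> tuple[float, float]:
    """1-df chi-square test of 1:1 segregation (no continuity correction).

    chi2 = (n_aa - n_ab)^2 / (n_aa + n_ab); p is the upper tail of the
    chi-square distribution with one degree of freedom.
    """
    if n_aa < 0 or n_ab < 0:
        raise ValueError("counts must be non-negative")
    n = n_aa + n_ab
    if n == 0:
        raise ValueError("chi-square of 1:1 segregation undefined for zero counts")
    chi2 = (n_aa - n_ab) ** 2 / n
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def annotate_qc(mat: GenotypeMatrix) -> GenotypeMatrix:
    """Attach per-marker chi2, p and missing_frac columns (vectorised)."""
    n_aa, n_ab = mat.segregation_counts()
    n = n_aa + n_ab
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (n_aa - n_ab) ** 2 / np.maximum(n, 1), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    markers = mat.markers.copy()
    markers["chi2"] = chi2
    markers["p"] = p
    markers["missing_frac"] = mat.missing_fraction()
    out = GenotypeMatrix(markers, mat.calls, mat.progeny, dp=mat.dp, gq=mat.gq)
    return out


def marker_qc(mat: GenotypeMatrix, cfg: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Marker-level QC for mapping.

    Retains markers of a 1:1 segregation type whose chi-square p-value is
    at least ``min_segregation_p`` and whose missing fraction does not
    exceed ``max_missing`` (a marker at exactly the missing bound is
    kept). Markers with undefined tests (all calls missing) are dropped.
    """
    if not {"p", "missing_frac"}.issubset(mat.markers.columns):
        mat = annotate_qc(mat)
    p = mat.markers["p"].to_numpy()
    miss = mat.markers["missing_frac"].to_numpy()
    seg_ok = mat.markers["seg_type"].isin(MAPPABLE_SEG_TYPES).to_numpy()
    keep = seg_ok & np.isfinite(p) & (p >= cfg.min_segregation_p) & (miss <= cfg.max_missing)
    return mat.take(keep)


# ----------------------------------------------------------------------
# VCF ingestion
# ----------------------------------------------------------------------

def matrix_from_vcf(
    path: str,
    mother: str,
    father: str,
    cfg: FilterConfig = FilterConfig(),
    source: str = "",
) -> GenotypeMatrix:
    """Read a VCF call set into a coded genotype matrix.

    The mother and father samples supply parental genotypes for site
    discovery (parental DP) and segregation typing; all remaining samples
    are treated as progeny and coded through :func:`call_genotype`.
    Sites failing the mapping-quality or parental-depth discovery gates,
    and non-biallelic or untypeable sites, are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    for parent in (mother, father):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not found in {path}")
    i_mo, i_fa = samples.index(mother), samples.index(father)
    progeny_idx = [i for i, s in enumerate(samples) if s not in (mother, father)]
    progeny = [samples[i] for i in progeny_idx]

    rows, call_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        mq = var.INFO.get("MQ")
        if mq is None or mq < cfg.min_site_mq:
            continue
        dp = var.format("DP")
        dp = np.zeros(len(samples)) if dp is None else dp.reshape(-1).astype(float)
        if max(dp[i_mo], dp[i_fa]) < cfg.min_discovery_dp:
            continue
        gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        bases = var.gt_bases
        seg = classify_segregation(bases[i_mo], bases[i_fa])
        if seg == SEG_UNTYPED:
            continue
        gq = var.format("GQ")
        gq = np.zeros(len(samples)) if gq is None else gq.reshape(-1).astype(float)
        coded = np.array(
            [call_genotype(int(gts[i]), dp[i], gq[i], cfg) for i in progeny_idx],
            dtype=np.int8,
        )
        rows.append(
            {
                "marker_id": f"{var.CHROM}_{var.POS}",
                "contig": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "seg_type": seg,
                "source": source,
            }
        )
        call_rows.append(coded)

    markers = pd.DataFrame(rows).set_index("marker_id") if rows else pd.DataFrame(
        columns=["contig", "pos", "ref", "alt", "seg_type", "source"]
    )
    calls = (
        np.vstack(call_rows)
        if call_rows
        else np.empty((0, len(progeny)), dtype=np.int8)
    )
    return annotate_qc(GenotypeMatrix(markers, calls, progeny))
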