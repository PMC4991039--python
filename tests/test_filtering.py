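"""Filter cascade: alignment records, site discovery, genotype calls,
segregation typing and marker-level QC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ptxmap import filtering
from ptxmap.config import FilterConfig
from ptxmap.filtering import (
    AlignmentRecordView,
    call_genotype,
    chi_square_1to1,
    classify_segregation,
    discover_parental_sites,
    keep_alignment,
    marker_qc,
)
from ptxmap.matrix import (
    AA,
    AB,
    MISSING,
    SEG_BOTH_HET,
    SEG_MATERNAL,
    SEG_MONOMORPHIC,
    SEG_PATERNAL,
    SEG_UNTYPED,
)

CFG = FilterConfig()


class TestKeepAlignment:
    @pytest.mark.parametrize(
        "nm,best,second,keep",
        [
            (10, 100, 50, False),   # edit distance over the cap
            (0, 60, None, True),    # all clauses pass at the boundary
            (5, 80, 81, False),     # outscored by a second-best alignment
            (9, 60, 60, True),      # ties everywhere are kept
            (5, 59, None, False),   # best score below the minimum
        ],
    )
    def test_predicate(self, nm, best, second, keep):
        rec = AlignmentRecordView(nm, best, second)
        assert keep_alignment(rec, CFG) is keep

    def test_negative_edit_distance_rejected(self):
        with pytest.raises(ValueError):
            AlignmentRecordView(-1, 100)

    def test_tightening_thresholds_never_keeps_more(self):
        records = [
            AlignmentRecordView(nm, best, second)
            for nm in (0, 5, 9, 10)
            for best in (59, 60, 80)
            for second in (None, 59, 80, 81)
        ]
        loose = {i for i, r in enumerate(records) if keep_alignment(r, CFG)}
        tight_cfg = CFG.replace(max_edit_distance=5, min_best_score=70)
        tight = {i for i, r in enumerate(records) if keep_alignment(r, tight_cfg)}
        assert tight <= loose


class TestDiscoverParentalSites:
    def test_boundaries(self):
        assert discover_parental_sites([{"locus": "x", "mq": 19, "dp": 100}]) == []
        assert discover_parental_sites([{"locus": "x", "mq": 20, "dp": 5}]) == ["x"]

    def test_enumerated_stream(self):
        stream = [
            {"locus": f"s{i}", "mq": mq, "dp": dp}
            for i, (mq, dp) in enumerate(
                [(30, 4), (30, 5), (19, 9), (25, 12), (20, 5), (50, 2)]
            )
        ]
        assert discover_parental_sites(stream) == ["s1", "s3", "s4"]

    def test_union_deduplicates_loci(self):
        stream = [
            {"locus": "x", "mq": 30, "dp": 10},
            {"locus": "x", "mq": 30, "dp": 20},
            {"locus": "y", "mq": 30, "dp": 10},
        ]
        assert discover_parental_sites(stream) == ["x", "y"]


class TestCallGenotype:
    @pytest.mark.parametrize(
        "gt,dp,gq,want",
        [
            (1, 10, 51, AB),        # inclusive DP, exclusive GQ boundaries
            (0, 9, 99, MISSING),    # depth one short
            (0, 50, 50, MISSING),   # GQ must strictly exceed 50
            (0, 30, 80, AA),
            (3, 30, 80, AA),        # homozygote codes aa regardless of allele
            (2, 99, 99, MISSING),   # no-call stays missing
        ],
    )
    def test_gates(self, gt, dp, gq, want):
        assert call_genotype(gt, dp, gq, CFG) == want


class TestClassifySegregation:
    @pytest.mark.parametrize(
        "mother,father,want",
        [
            ("A/C", "A/A", SEG_MATERNAL),
            ("G/G", "G/T", SEG_PATERNAL),
            ("A/C", "A/C", SEG_BOTH_HET),
            ("A/A", "C/C", SEG_MONOMORPHIC),
            (None, "A/A", SEG_UNTYPED),
            ("./.", "A/C", SEG_UNTYPED),
        ],
    )
    def test_types(self, mother, father, want):
        assert classify_segregation(mother, father) == want


class TestChiSquare:
    def test_perfect_ratio(self):
        chi2, p = chi_square_1to1(75, 75)
        assert chi2 == 0.0 and p == 1.0

    def test_retained_and_removed_examples(self):
        chi2, p = chi_square_1to1(90, 60)
        assert chi2 == pytest.approx(6.00)
        assert p == pytest.approx(0.0143, abs=5e-4)
        chi2, p = chi_square_1to1(95, 55)
        assert chi2 == pytest.approx(10.667, abs=5e-4)
        assert p == pytest.approx(0.00109, abs=5e-6)

    def test_against_normal_tail_oracle(self):
        """1-df upper tail equals twice the standard normal tail of
        sqrt(chi2) — an independent closed form."""
        for n_aa, n_ab in [(90, 60), (95, 55), (80, 70), (100, 50)]:
            chi2, p = chi_square_1to1(n_aa, n_ab)
            assert p == pytest.approx(2 * stats.norm.sf(np.sqrt(chi2)), rel=1e-10)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_symmetric_and_bounded(self, a, b):
        if a + b == 0:
            with pytest.raises(ValueError):
                chi_square_1to1(a, b)
            return
        chi2, p = chi_square_1to1(a, b)
        chi2_swapped, p_swapped = chi_square_1to1(b, a)
        assert chi2 == chi2_swapped and p == p_swapped
        assert chi2 >= 0.0 and 0.0 < p <= 1.0


class TestMarkerQc:
    def _matrix_with(self, toy, stats_rows):
        mat = toy([[AA] * 10] * len(stats_rows))
        mat.markers["chi2"] = 0.0
        mat.markers["p"] = [p for p, _ in stats_rows]
        mat.markers["missing_frac"] = [m for _, m in stats_rows]
        return mat

    def test_boundary_marker_retained(self, toy):
        mat = self._matrix_with(toy, [(0.011, 0.10)])
        assert marker_qc(mat, CFG).n_markers == 1

    def test_distorted_marker_removed(self, toy):
        mat = self._matrix_with(toy, [(0.009, 0.0)])
        assert marker_qc(mat, CFG).n_markers == 0

    def test_enumerated_toy_matrix(self, toy):
        rows = [(0.5, 0.0), (0.009, 0.0), (0.2, 0.11), (0.011, 0.1), (0.02, 0.05)]
        kept = marker_qc(self._matrix_with(toy, rows), CFG)
        assert list(kept.marker_ids) == ["m0", "m3", "m4"]

    def test_non_1to1_types_excluded(self, toy):
        mat = self._matrix_with(toy, [(0.5, 0.0), (0.5, 0.0)])
        mat.markers.loc["m1", "seg_type"] = SEG_BOTH_HET
        assert list(marker_qc(mat, CFG).marker_ids) == ["m0"]

    def test_monotone_in_thresholds(self, toy):
        rng = np.random.default_rng(5)
        calls = rng.choice([AA, AB, MISSING], size=(200, 150), p=[0.42, 0.48, 0.1])
        mat = toy(calls)
        base = set(marker_qc(mat, CFG).marker_ids)
        tighter = set(
            marker_qc(mat, CFG.replace(max_missing=0.05, min_segregation_p=0.05)).marker_ids
        )
        assert tighter <= base

    def test_computes_qc_columns_when_absent(self, toy):
        mat = toy([[AA] * 75 + [AB] * 75])
        kept = marker_qc(mat, CFG)
        assert kept.n_markers == 1
        assert kept.markers["p"].iloc[0] == 1.0


class TestVcfRoundTrip:
    def test_clean_view_survives_ingestion_unchanged(self, clean_dataset, tmp_path):
        """Writing a noise-free view to VCF and re-reading through the
        filter cascade preserves loci, coded calls and segregation types."""
        from ptxmap import simdata

        view = clean_dataset.view_a
        path = simdata.write_vcf(view, tmp_path / "view.vcf")
        mat = filtering.matrix_from_vcf(str(path), "MOTHER", "FATHER", CFG)
        assert mat.n_markers == view.n_markers
        assert mat.n_progeny == view.n_progeny
        reread = mat.select_ids(list(view.marker_ids))
        assert np.array_equal(reread.calls, view.calls)
        assert list(reread.markers["seg_type"]) == list(view.markers["seg_type"])
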