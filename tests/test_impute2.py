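"""Imputation-quality filtering and IMPUTE2 -> VCF conversion."""

import numpy as np
import pytest

import lofcall as lc
from lofcall.impute2 import (
    QualityThresholds,
    _called_matrix,
    call_genotype,
    convert_to_vcf,
    filter_by_info,
    read_impute2,
)


class TestFilterByInfo:
    def test_strict_threshold(self):
        keep = filter_by_info(np.array([0.85, 0.9, 0.95]), 0.9)
        assert keep.tolist() == [False, False, True]   # 0.85 and 0.9 dropped

    def test_zero_threshold_keeps_positive_scores(self):
        scores = np.array([0.0, 0.001, 1.0])
        assert filter_by_info(scores, 0.0).tolist() == [False, True, True]

    def test_uniform_fixture_matches_enumeration(self):
        rng = np.random.default_rng(123)
        scores = rng.uniform(size=100)
        for thr in (0.3, 0.6, 0.9):
            expected = sum(1 for s in scores if s > thr)
            assert filter_by_info(scores, thr).sum() == expected

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            filter_by_info(np.array([0.5, 1.2]), 0.3)


class TestCallGenotype:
    @pytest.mark.parametrize("cutoff", [0.0, 0.01, 0.1])
    def test_certain_triple(self, cutoff):
        assert call_genotype((1.0, 0.0, 0.0), cutoff) == 0

    def test_uncertain_triple_goes_missing(self):
        assert call_genotype((0.5, 0.3, 0.2), 0.05) is None  # 0.5 < 0.95

    def test_boundary_is_kept(self):
        assert call_genotype((0.95, 0.03, 0.02), 0.05) == 0

    def test_tie_breaks_toward_missing(self):
        assert call_genotype((0.5, 0.5, 0.0), 0.5) is None

    def test_negative_probability_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            call_genotype((-0.1, 0.6, 0.5), 0.05)

    def test_dirichlet_fixture_missing_rate_matches_recount(self):
        # 10,000 triples from Dirichlet(5, 2, 1), fixed seed
        rng = np.random.default_rng(2024)
        triples = rng.dirichlet((5.0, 2.0, 1.0), size=10_000)
        cutoff = 0.1
        scalar = [call_genotype(t, cutoff) for t in triples]
        vector = _called_matrix(triples[None, :, :], cutoff)[0]
        expected_missing = sum(1 for g in scalar if g is None)
        assert (vector == -1).sum() == expected_missing
        assert [None if v == -1 else int(v) for v in vector] == scalar


class TestConvertToVcf:
    @pytest.fixture
    def chunk(self, tmp_path):
        cfg = lc.SimulationConfig(seed=17, n_samples=30, n_variants=60)
        paths, truth = lc.generate_impute2(cfg, tmp_path / "imp")
        return paths, truth, tmp_path

    def test_empty_input_yields_header_only_vcf(self, tmp_path):
        (tmp_path / "e.gen").write_text("")
        (tmp_path / "e.haps").write_text("")
        (tmp_path / "e.sample").write_text(
            "ID_1 ID_2 missing\n0 0 0\nF1 S1 0\n")
        (tmp_path / "e.info").write_text("snp_id rs_id position info\n")
        out = convert_to_vcf(tmp_path / "e.gen", tmp_path / "e.haps",
                             tmp_path / "e.sample", tmp_path / "e.info",
                             QualityThresholds(0.3, 0.05),
                             tmp_path / "e.vcf")
        cohort = lc.read_annotated_vcf(out)
        assert cohort.n_variants == 0

    def test_certain_het_takes_phase_from_haps(self, tmp_path):
        (tmp_path / "c.gen").write_text("chr1 v1 100 A G 0 1 0\n")
        (tmp_path / "c.haps").write_text("chr1 v1 100 A G 0 1\n")
        (tmp_path / "c.sample").write_text("ID_1 ID_2 missing\n0 0 0\nF1 S1 0\n")
        (tmp_path / "c.info").write_text("snp_id rs_id position info\n1 v1 100 0.99\n")
        out = convert_to_vcf(tmp_path / "c.gen", tmp_path / "c.haps",
                             tmp_path / "c.sample", tmp_path / "c.info",
                             QualityThresholds(0.3, 0.05), tmp_path / "c.vcf")
        cohort = lc.read_annotated_vcf(out)
        call = cohort.call(0, "S1")
        assert (call.allele_a, call.allele_b, call.phased) == (0, 1, True)

    def test_record_count_equals_info_survivors(self, chunk):
        paths, truth, tmp_path = chunk
        thr = QualityThresholds(0.6, 0.05)
        out = convert_to_vcf(paths["gen"], paths["haps"], paths["sample"],
                             paths["info"], thr, tmp_path / "out.vcf")
        cohort = lc.read_annotated_vcf(out)
        assert cohort.n_variants \
            == int((truth.extra["info_scores"] > 0.6).sum())

    def test_missing_calls_match_per_call_recount(self, chunk):
        paths, truth, tmp_path = chunk
        thr = QualityThresholds(0.3, 0.1)
        out = convert_to_vcf(paths["gen"], paths["haps"], paths["sample"],
                             paths["info"], thr, tmp_path / "out.vcf")
        cohort = lc.read_annotated_vcf(out)
        kept = truth.extra["info_scores"] > 0.3
        expected = sum(
            call_genotype(t, 0.1) is None
            for row in truth.extra["probs"][kept] for t in row
        )
        assert int((cohort.allele_a == -1).sum()) == expected

    def test_surviving_calls_round_trip_haplotypes(self, chunk):
        paths, truth, tmp_path = chunk
        out = convert_to_vcf(paths["gen"], paths["haps"], paths["sample"],
                             paths["info"], QualityThresholds(0.0, 0.05),
                             tmp_path / "out.vcf")
        cohort = lc.read_annotated_vcf(out)
        keep = truth.extra["info_scores"] > 0.0
        nm = cohort.allele_a != -1
        assert np.array_equal(cohort.allele_a[nm],
                              truth.extra["hap_a"][keep][nm])
        assert np.array_equal(cohort.allele_b[nm],
                              truth.extra["hap_b"][keep][nm])
        assert cohort.phased[nm].all()

    def test_monotone_in_both_thresholds(self, chunk):
        paths, _, tmp_path = chunk
        grid = [(0.3, 0.01), (0.6, 0.05), (0.9, 0.1)]
        records, nonmissing = [], []
        for mi, pc in grid:
            out = convert_to_vcf(paths["gen"], paths["haps"], paths["sample"],
                                 paths["info"], QualityThresholds(mi, pc),
                                 tmp_path / "m.vcf")
            c = lc.read_annotated_vcf(out)
            records.append(c.n_variants)
            nonmissing.append(int((c.allele_a != -1).sum()) / max(c.n_variants, 1))
        assert records == sorted(records, reverse=True)

    def test_gen_without_haps_variant_fatal(self, tmp_path):
        (tmp_path / "g.gen").write_text("chr1 v1 100 A G 0 1 0\n")
        (tmp_path / "g.haps").write_text("chr1 v2 200 A G 0 1\n")
        (tmp_path / "g.sample").write_text("ID_1 ID_2 missing\n0 0 0\nF1 S1 0\n")
        (tmp_path / "g.info").write_text("snp_id rs_id position info\n1 v1 100 0.9\n")
        with pytest.raises(ValueError, match="absent from"):
            read_impute2(tmp_path / "g.gen", tmp_path / "g.haps",
                         tmp_path / "g.sample", tmp_path / "g.info")

    def test_missing_info_entry_fatal_with_key(self, tmp_path):
        (tmp_path / "i.gen").write_text("chr1 v1 100 A G 0 1 0\n")
        (tmp_path / "i.haps").write_text("chr1 v1 100 A G 0 1\n")
        (tmp_path / "i.sample").write_text("ID_1 ID_2 missing\n0 0 0\nF1 S1 0\n")
        (tmp_path / "i.info").write_text("snp_id rs_id position info\n1 other 999 0.9\n")
        with pytest.raises(ValueError, match="v1"):
            read_impute2(tmp_path / "i.gen", tmp_path / "i.haps",
                         tmp_path / "i.sample", tmp_path / "i.info")


def test_thresholds_validate_range():
    with pytest.raises(ValueError):
        QualityThresholds(min_info=1.5)
    with pytest.raises(ValueError):
        QualityThresholds(prob_cutoff=-0.1)
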