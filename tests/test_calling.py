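"""Core calling logic: zygosity, gene copy loss, CH detection, mechanisms,
frequencies and mismatched genes — checked against the brute-force
haplotype-string oracle and planted simulation truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lofcall as lc
from conftest import all_phased_configs, brute_force_gene_call, make_call
from lofcall.calling import (
    Mechanism,
    compute_gene_frequencies,
    compute_variant_frequencies,
    gene_copy_loss,
    mismatch_genes,
    variant_zygosity,
)


class TestVariantZygosity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0, 0, 0), (1, 0, 1), (0, 1, 1), (1, 1, 2), (None, None, None)],
    )
    def test_alt_allele_count(self, a, b, expected):
        assert variant_zygosity(make_call(a, b)) == expected

    def test_haplotype_swap_symmetry(self):
        assert variant_zygosity(make_call(0, 1)) \
            == variant_zygosity(make_call(1, 0))


class TestGeneCopyLoss:
    def test_single_hom_loses_both_copies(self):
        result = gene_copy_loss([make_call(1, 1)])
        assert (result.copies_lost, result.mechanism) \
            == (2, Mechanism.HOMOZYGOUS)

    def test_trans_pair_is_compound_het(self):
        result = gene_copy_loss([make_call(1, 0), make_call(0, 1)])
        assert (result.copies_lost, result.mechanism) \
            == (2, Mechanism.COMPOUND_HET)

    def test_cis_pair_loses_one_copy(self):
        result = gene_copy_loss([make_call(1, 0), make_call(1, 0)])
        assert (result.copies_lost, result.mechanism) \
            == (1, Mechanism.MULTI_CIS)

    def test_unphased_two_hets_is_ambiguous_single_copy(self):
        calls = [make_call(1, 0, phased=False), make_call(0, 1, phased=False)]
        result = gene_copy_loss(calls)
        assert result.copies_lost == 1
        assert result.ambiguous

    def test_unphased_hom_still_proves_two_copies(self):
        result = gene_copy_loss([make_call(1, 1, phased=False)])
        assert (result.copies_lost, result.mechanism) \
            == (2, Mechanism.HOMOZYGOUS)

    def test_all_missing_gene_is_missing(self):
        result = gene_copy_loss([make_call(None, None)] * 3)
        assert result.copies_lost is None
        assert result.mechanism is Mechanism.MISSING

    def test_unsplit_multiallelic_call_rejected(self):
        with pytest.raises(ValueError, match="biallelic"):
            gene_copy_loss([make_call(1, 2)])

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_exhaustive_oracle_agreement_small_genes(self, k):
        for calls in all_phased_configs(k):
            expected = brute_force_gene_call(calls)
            got = gene_copy_loss(calls)
            assert (got.copies_lost, got.mechanism, got.ambiguous) == expected

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([(0, 0), (0, 1), (1, 0), (1, 1), None]),
                st.booleans(),
            ),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=300, derandomize=True)
    def test_oracle_agreement_with_missing_and_mixed_phase(self, spec):
        calls = [
            make_call(None, None) if gt is None
            else make_call(gt[0], gt[1], phased=ph)
            for gt, ph in spec
        ]
        expected = brute_force_gene_call(calls)
        got = gene_copy_loss(calls)
        assert (got.copies_lost, got.mechanism, got.ambiguous) == expected


class TestFilterHc:
    def test_lc_only_variant_dropped_hc_retained(self, small_vcf):
        hc = lc.filter_hc(lc.read_annotated_vcf(small_vcf))
        ids = [v.variant_id for v in hc.calls.variants]
        assert "chr2_100_T_G" not in ids       # LC only
        assert "chr1_300_C_A" not in ids       # no LoF class
        assert set(ids) == {"chr1_100_A_T", "chr1_200_G_C", "chr2_200_A_C"}

    def test_matches_independent_text_scan(self, tiny_cohort):
        _, vcf_path, _ = tiny_cohort
        # oracle: scan raw CSQ strings for an HC sub-field, per line
        expected = set()
        for line in open(vcf_path):
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            csq = fields[7].removeprefix("CSQ=")
            if any(e.split("|")[5] == "HC" for e in csq.split(",")):
                expected.add(fields[2])
        hc = lc.filter_hc(lc.read_annotated_vcf(vcf_path))
        assert {v.variant_id for v in hc.calls.variants} == expected

    def test_hc_on_any_of_many_transcripts_retains(self, tmp_path):
        entries = ",".join(
            f"T|stop_gained|G1|ENSG01|T{i}|{'HC' if i == 3 else 'LC'}|"
            for i in range(5)
        )
        text = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="... '
            'Format: Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            f"chr1\t100\t.\tA\tT\t.\t.\tCSQ={entries}\tGT\t0|1\n"
        )
        p = tmp_path / "multi.vcf"
        p.write_text(text)
        hc = lc.filter_hc(lc.read_annotated_vcf(p))
        assert hc.calls.n_variants == 1

    def test_multi_gene_variant_maps_to_every_hc_gene(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="... '
            'Format: Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tT\t.\t.\t"
            "CSQ=T|stop_gained|G1|ENSG01|T1|HC|,"
            "T|stop_gained|G2|ENSG02|T2|HC|\tGT\t1|1\n"
        )
        p = tmp_path / "overlap.vcf"
        p.write_text(text)
        hc = lc.filter_hc(lc.read_annotated_vcf(p))
        assert hc.variant_genes == [("ENSG01", "ENSG02")]
        gm = lc.build_gene_matrix(hc)
        assert gm.entries.loc["ENSG01", "S1"] == 2
        assert gm.entries.loc["ENSG02", "S1"] == 2


class TestDetectChEvents:
    def _cohort(self, tmp_path, gts):
        """Three HC variants of one gene at positions 100/200/300."""
        rows = "\n".join(
            f"chr1\t{100 * (i + 1)}\t.\tA\tT\t.\t.\t"
            f"CSQ=T|stop_gained|G1|ENSG01|T1|HC|\tGT\t{gt}"
            for i, gt in enumerate(gts)
        )
        text = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="... '
            'Format: Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            f"{rows}\n"
        )
        p = tmp_path / "gene.vcf"
        p.write_text(text)
        return lc.filter_hc(lc.read_annotated_vcf(p))

    def test_trans_pair_yields_one_event(self, tmp_path):
        events = lc.detect_ch_events(self._cohort(tmp_path, ["1|0", "0|1", "0|0"]))
        assert len(events) == 1
        assert events[0].variant_pair == ("chr1_100_A_T", "chr1_200_A_T")
        assert events[0].haplotype_assignment == ("A", "B")

    def test_three_hets_pair_chosen_by_position(self, tmp_path):
        # two cis (positions 100, 200 on hap A) + one trans (300 on hap B):
        # the reported pair is the lowest-position variant on each haplotype
        events = lc.detect_ch_events(self._cohort(tmp_path, ["1|0", "1|0", "0|1"]))
        assert len(events) == 1
        assert events[0].variant_pair == ("chr1_100_A_T", "chr1_300_A_T")

    def test_unphased_cohort_yields_no_events(self, tmp_path):
        hc = self._cohort(tmp_path, ["1|0", "0|1", "0|0"])
        hc_unphased = lc.HcCohort(hc.calls.strip_phase(), hc.variant_genes,
                                  hc.gene_variants, hc.gene_symbols)
        assert lc.detect_ch_events(hc_unphased) == []

    def test_planted_event_count_recovered(self, tiny_cohort):
        _, vcf_path, truth = tiny_cohort
        hc = lc.filter_hc(lc.read_annotated_vcf(vcf_path))
        assert lc.detect_ch_events(hc) == truth.ch_events


class TestMechanismClassification:
    def test_partition_labels(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="... '
            'Format: Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            # gene 1: S1 hom knockout only
            "chr1\t100\t.\tA\tT\t.\t.\tCSQ=T|stop_gained|G1|ENSG01|T1|HC|"
            "\tGT\t1|1\t0|0\n"
            # gene 2: S1 compound het, S2 hom -> both
            "chr1\t200\t.\tA\tT\t.\t.\tCSQ=T|stop_gained|G2|ENSG02|T2|HC|"
            "\tGT\t1|0\t1|1\n"
            "chr1\t300\t.\tA\tT\t.\t.\tCSQ=T|stop_gained|G2|ENSG02|T2|HC|"
            "\tGT\t0|1\t0|0\n"
        )
        p = tmp_path / "mix.vcf"
        p.write_text(text)
        gm = lc.build_gene_matrix(lc.filter_hc(lc.read_annotated_vcf(p)))
        labels = lc.classify_two_copy_mechanism(gm)
        assert labels == {"ENSG01": "hom_only", "ENSG02": "both"}

    def test_planted_partition_recovered(self, tiny_cohort):
        _, vcf_path, truth = tiny_cohort
        gm = lc.build_gene_matrix(lc.filter_hc(lc.read_annotated_vcf(vcf_path)))
        assert lc.classify_two_copy_mechanism(gm) \
            == truth.gene_mechanism_labels

    def test_two_copy_entries_match_mechanisms(self, tiny_cohort):
        _, vcf_path, _ = tiny_cohort
        gm = lc.build_gene_matrix(lc.filter_hc(lc.read_annotated_vcf(vcf_path)))
        two_copy_mechs = {Mechanism.HOMOZYGOUS, Mechanism.COMPOUND_HET,
                          Mechanism.HOM_AND_CH}
        for g in gm.entries.index:
            for s in gm.sample_ids:
                entry = gm.entries.at[g, s]
                mech = gm.mechanism_at(g, s)
                assert (entry == 2) == (mech in two_copy_mechs)


class TestFrequencies:
    def test_small_hand_counts(self):
        entries = pd.DataFrame(
            [[1, 1, 2], [0, 0, 0], [1, -1, 2]],
            index=["v1", "v2", "v3"], columns=["a", "b", "c"], dtype="int8",
        )
        freqs = compute_variant_frequencies(entries)
        assert freqs.loc["v1"].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert freqs.loc["v2"].tolist() == pytest.approx([0.0, 0.0])
        assert freqs.loc["v3"].tolist() == pytest.approx([0.5, 0.5])

    def test_all_missing_row_has_no_frequency(self):
        entries = pd.DataFrame([[-1, -1]], index=["v1"], columns=["a", "b"],
                               dtype="int8")
        assert compute_variant_frequencies(entries).isna().all(axis=None)

    def test_random_matrix_matches_recount_and_conserves(self):
        rng = np.random.default_rng(42)
        entries = pd.DataFrame(
            rng.choice([-1, 0, 1, 2], size=(50, 30)).astype("int8"),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(30)],
        )
        freqs = compute_gene_frequencies(entries)
        for g in entries.index:
            row = entries.loc[g]
            nm = (row >= 0).sum()
            exp1 = (row == 1).sum() / nm
            exp2 = (row == 2).sum() / nm
            assert freqs.at[g, "1_copy_LoF_frequency"] == pytest.approx(exp1)
            assert freqs.at[g, "2_copy_LoF_frequency"] == pytest.approx(exp2)
            f0 = (row == 0).sum() / nm
            assert f0 + exp1 + exp2 == pytest.approx(1.0)

    def test_allele_frequency_definition(self, small_vcf):
        vm = lc.build_variant_matrix(lc.filter_hc(lc.read_annotated_vcf(small_vcf)))
        af = lc.allele_frequencies(vm)
        # chr1_100_A_T: states (0,1,2) over 3 samples -> (1+2)/6
        assert af["chr1_100_A_T"] == pytest.approx(0.5)
        # chr1_200_G_C: states (1,0,missing) -> 1/4
        assert af["chr1_200_G_C"] == pytest.approx(0.25)


class TestMismatchGenes:
    def _matrix(self, data, samples):
        entries = pd.DataFrame(data, index=[f"G{i}" for i in
                                            range(len(data))],
                               columns=samples, dtype="int8")
        ann = compute_gene_frequencies(entries)
        ann.insert(0, "gene_symbol", "")
        zeros = entries * 0
        return lc.GeneLossMatrix(entries=entries, mechanisms=zeros,
                                 ambiguous=zeros.astype(bool),
                                 annotations=ann)

    def test_directionality(self):
        gm = self._matrix([[0, 2], [2, 2], [2, 0], [1, -1]], ["A", "B"])
        out = mismatch_genes(gm, [("A", "B")])[("A", "B")]
        assert out["A->B"] == ["G0"]     # inactive in B, active in A
        assert out["B->A"] == ["G2"]
        # G1 inactive in both, G3 missing in B: in neither list

    def test_unknown_sample_is_fatal(self):
        gm = self._matrix([[0, 2]], ["A", "B"])
        with pytest.raises(KeyError, match="nope"):
            mismatch_genes(gm, [("A", "nope")])


class TestInvariances:
    def test_phase_swap_leaves_all_outputs_unchanged(self, tiny_cohort):
        _, vcf_path, _ = tiny_cohort
        cohort = lc.read_annotated_vcf(vcf_path)
        swapped = cohort.swap_haplotypes()   # swap in every sample
        out, out_sw = [], []
        for c in (cohort, swapped):
            hc = lc.filter_hc(c)
            vm = lc.build_variant_matrix(hc)
            gm = lc.build_gene_matrix(hc)
            ev = lc.detect_ch_events(hc)
            (out if c is cohort else out_sw).extend([
                vm.entries, vm.annotations, gm.entries, gm.mechanisms,
                [(e.sample_id, e.gene_id, e.variant_pair) for e in ev],
            ])
        for a, b in zip(out, out_sw):
            if isinstance(a, pd.DataFrame):
                pd.testing.assert_frame_equal(a, b)
            else:
                assert a == b

    def test_unphased_never_two_copies_without_hom(self, tiny_cohort):
        _, vcf_path, _ = tiny_cohort
        hc = lc.filter_hc(lc.read_annotated_vcf(vcf_path).strip_phase())
        gm = lc.build_gene_matrix(hc)
        assert lc.detect_ch_events(hc) == []
        two = gm.entries.to_numpy() == 2
        hom = gm.mechanisms.to_numpy() == list(Mechanism).index(
            Mechanism.HOMOZYGOUS)
        assert (two == (two & hom)).all()
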