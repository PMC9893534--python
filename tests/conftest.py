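"""Shared fixtures and the independent brute-force oracle.

The oracle deliberately avoids the package's vectorised code paths: it
materialises the two haplotype allele strings of a gene and reasons on
them directly, so agreement with the library is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import pytest

from lofcall.calling import Mechanism
from lofcall.vcf import GenotypeCall


def make_call(a, b, phased=True) -> GenotypeCall:
    if a is None:
        return GenotypeCall(None, None, phased=False)
    return GenotypeCall(a, b, phased=phased)


def brute_force_gene_call(calls):
    """Reference copy-loss verdict from explicit haplotype strings.

    Returns ``(copies_lost, Mechanism, ambiguous)``.
    """
    present = [c for c in calls if not c.missing]
    if not present:
        return None, Mechanism.MISSING, False

    homs = [c for c in present if c.allele_a == 1 and c.allele_b == 1]
    hets = [c for c in present if (c.allele_a == 1) != (c.allele_b == 1)]

    if all(c.phased for c in present):
        hap_a = "".join(str(c.allele_a) for c in present)
        hap_b = "".join(str(c.allele_b) for c in present)
        copies = int("1" in hap_a) + int("1" in hap_b)
        trans = any(
            (x.allele_a == 1 and y.allele_b == 1)
            or (x.allele_b == 1 and y.allele_a == 1)
            for x, y in itertools.combinations(hets, 2)
        )
        if homs and trans:
            mech = Mechanism.HOM_AND_CH
        elif homs:
            mech = Mechanism.HOMOZYGOUS
        elif trans:
            mech = Mechanism.COMPOUND_HET
        elif len(hets) >= 2:
            mech = Mechanism.MULTI_CIS
        elif len(hets) == 1:
            mech = Mechanism.SINGLE_HET
        else:
            mech = Mechanism.NONE
        return copies, mech, False

    if homs:
        return 2, Mechanism.HOMOZYGOUS, False
    if len(hets) >= 2:
        return 1, Mechanism.MULTI_CIS, True
    if len(hets) == 1:
        return 1, Mechanism.SINGLE_HET, False
    return 0, Mechanism.NONE, False


def all_phased_configs(k):
    """Every phased genotype configuration for k variants (4^k of them)."""
    states = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for combo in itertools.product(states, repeat=k):
        yield [make_call(a, b) for a, b in combo]


SMALL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tT\t.\t.\tCSQ=T|stop_gained|G1|ENSG01|T1|HC|\tGT\t0|0\t1|0\t1|1
chr1\t200\t.\tG\tC\t.\t.\tCSQ=C|frameshift_variant|G1|ENSG01|T1|HC|\tGT\t0|1\t0|0\t./.
chr1\t300\t.\tC\tA\t.\t.\tCSQ=A|missense_variant|G2|ENSG02|T2||\tGT\t0/1\t0|0\t0|0
chr2\t100\t.\tT\tG\t.\t.\tCSQ=G|splice_acceptor_variant|G2|ENSG02|T2|LC|\tGT\t1|1\t0|0\t0|0
chr2\t200\t.\tA\tC,G\t.\t.\tCSQ=C|stop_gained|G3|ENSG03|T3|HC|,G|stop_gained|G3|ENSG03|T3|LC|\tGT\t1|2\t0|0\t0|1
"""


@pytest.fixture
def small_vcf(tmp_path):
    """Handwritten 3-sample VCF covering HC/LC/none, phase, missingness
    and a multi-allelic record (splits to 6 biallelic variants)."""
    path = tmp_path / "small.vcf"
    path.write_text(SMALL_VCF)
    return path


@pytest.fixture
def tiny_cohort(tmp_path):
    """A small simulated cohort with truth tables (fast, deterministic)."""
    from lofcall.simulate import SimulationConfig, generate_cohort

    cfg = SimulationConfig(n_samples=40, n_genes=30, seed=11)
    vcf_path, truth = generate_cohort(cfg, tmp_path / "tiny")
    return cfg, vcf_path, truth
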