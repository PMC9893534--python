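"""Core loss-of-function calling: zygosity and gene copy-loss matrices,
compound-heterozygote detection and knockout-mechanism classification.

The central idea: a gene copy (haplotype) is considered lost when it carries
at least one high-confidence (HC) LoF allele anywhere in the gene.  With
phased genotypes the two haplotypes are assessed independently, which
distinguishes a compound heterozygote (two het LoF variants in *trans*,
both copies lost) from two variants in *cis* on the same haplotype (one
copy lost).  Unphased data can never support a compound-het call: only a
homozygous variant then proves a two-copy loss.

Matrix encodings follow the field convention: variant entries are alt-allele
counts (0 = non-carrier, 1 = heterozygous, 2 = homozygous) and gene entries
are copies lost (0, 1 or 2), with missing propagated.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csq import LofClass
from .vcf import MISSING, AnnotatedVariant, CohortCalls, GenotypeCall

logger = logging.getLogger(__name__)

__all__ = [
    "Mechanism",
    "HcCohort",
    "GeneCall",
    "CHEvent",
    "VariantZygosityMatrix",
    "GeneLossMatrix",
    "filter_hc",
    "variant_zygosity",
    "gene_copy_loss",
    "build_variant_matrix",
    "build_gene_matrix",
    "detect_ch_events",
    "classify_two_copy_mechanism",
    "compute_variant_frequencies",
    "compute_gene_frequencies",
    "allele_frequencies",
    "mismatch_genes",
]


class Mechanism(enum.Enum):
    """How (and whether) a sample's copies of a gene are inactivated."""

    NONE = "none"
    SINGLE_HET = "single_het"          # one het LoF allele: 1 copy lost
    MULTI_CIS = "multi_cis"            # >=2 het alleles on one haplotype: 1 copy
    HOMOZYGOUS = "homozygous"          # a homozygous LoF variant: 2 copies
    COMPOUND_HET = "compound_het"      # trans het pair: 2 copies
    HOM_AND_CH = "hom_and_ch"          # both a hom variant and a trans pair
    MISSING = "missing"                # every call in the gene is missing

    @property
    def copies_lost(self) -> int | None:
        return _MECHANISM_COPIES[self]


_MECHANISM_COPIES = {
    Mechanism.NONE: 0,
    Mechanism.SINGLE_HET: 1,
    Mechanism.MULTI_CIS: 1,
    Mechanism.HOMOZYGOUS: 2,
    Mechanism.COMPOUND_HET: 2,
    Mechanism.HOM_AND_CH: 2,
    Mechanism.MISSING: None,
}

# integer codes for the dense mechanism matrix
_MECH_CODE = {m: i for i, m in enumerate(Mechanism)}
_CODE_MECH = {i: m for m, i in _MECH_CODE.items()}


@dataclass
class HcCohort:
    """A cohort restricted to high-confidence LoF variants.

    ``variant_genes[i]`` lists every gene a consequence marks HC for
    variant ``i`` (a variant may hit more than one gene); ``gene_variants``
    is the inverse mapping.  ``gene_symbols`` maps gene_id -> symbol.
    """

    calls: CohortCalls
    variant_genes: list[tuple[str, ...]]
    gene_variants: dict[str, list[int]]
    gene_symbols: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_variants)


@dataclass(frozen=True)
class GeneCall:
    """Per-(sample, gene) copy-loss verdict."""

    copies_lost: int | None      # None when all calls are missing
    mechanism: Mechanism
    ambiguous: bool = False      # unphased multi-het: cis/trans unknowable


@dataclass(frozen=True)
class CHEvent:
    """A compound-heterozygous knockout: a trans het LoF pair in one gene.

    ``haplotype_assignment`` maps each variant_id of the pair to the
    haplotype ("A" or "B") carrying its alt allele in this sample.
    """

    sample_id: str
    gene_id: str
    variant_pair: tuple[str, str]
    haplotype_assignment: tuple[str, str]


def filter_hc(
    cohort: CohortCalls,
    transcript_policy: str = "any",
    keep_flagged: bool = True,
) -> HcCohort:
    """Restrict a cohort to high-confidence LoF variants with gene mapping.

    A variant is retained iff at least one transcript consequence carries
    LOFTEE class HC; it maps to every gene for which some consequence is HC.

    Parameters
    ----------
    transcript_policy:
        ``"any"`` (default) accepts HC on any transcript; ``"canonical"``
        restricts to consequences whose transcript is flagged canonical
        (a ``CANONICAL`` sub-field is not always present; transcripts whose
        entry lacks it are excluded under this policy).
    keep_flagged:
        When False, HC consequences bearing a non-empty ``LoF_flags``
        value are ignored.
    """
    if transcript_policy not in ("any", "canonical"):
        raise ValueError(f"unknown transcript policy {transcript_policy!r}")

    keep: list[int] = []
    variant_genes: list[tuple[str, ...]] = []
    gene_symbols: dict[str, str] = {}
    for i, variant in enumerate(cohort.variants):
        genes: dict[str, None] = {}
        for csq in variant.consequences:
            if csq.lof_class is not LofClass.HC:
                continue
            if not keep_flagged and csq.lof_flags:
                continue
            if transcript_policy == "canonical" and not _is_canonical(csq):
                continue
            if csq.gene_id:
                genes[csq.gene_id] = None
                gene_symbols.setdefault(csq.gene_id, csq.gene_symbol)
        if genes:
            keep.append(i)
            variant_genes.append(tuple(genes))

    sub = cohort.subset_variants(keep)
    order = sorted(range(len(keep)), key=lambda k: sub.variants[k].sort_key)
    sub = sub.subset_variants(order)
    variant_genes = [variant_genes[k] for k in order]

    gene_variants: dict[str, list[int]] = {}
    for idx, genes in enumerate(variant_genes):
        for g in genes:
            gene_variants.setdefault(g, []).append(idx)
    return HcCohort(
        calls=sub,
        variant_genes=variant_genes,
        gene_variants=gene_variants,
        gene_symbols=gene_symbols,
    )


def _is_canonical(csq) -> bool:
    return "CANONICAL" in csq.raw.split("|")  # crude: YES-only dialects vary


def variant_zygosity(call: GenotypeCall) -> int | None:
    """Alt-allele count of a biallelic call: 0, 1, 2, or None if missing."""
    return call.alt_count


def gene_copy_loss(calls: list[GenotypeCall]) -> GeneCall:
    """Copy-loss verdict for one sample over one gene's HC LoF variants.

    Phased rule: a haplotype is lost iff it carries >=1 alt allele across
    the gene's variants; copies lost = number of lost haplotypes.  If any
    non-missing call is unphased the sample-gene is treated as unphased
    (conservative): a homozygous variant still proves 2 copies, otherwise
    het alleles prove only 1, and cis/trans is flagged ambiguous when more
    than one het is present.
    """
    present = [c for c in calls if not c.missing]
    if not present:
        return GeneCall(None, Mechanism.MISSING)
    for c in present:
        if c.allele_a not in (0, 1) or c.allele_b not in (0, 1):
            raise ValueError(
                "gene_copy_loss requires split biallelic calls "
                f"(got alleles {c.allele_a}/{c.allele_b})"
            )

    n_hom = sum(1 for c in present if c.allele_a == 1 and c.allele_b == 1)
    hets = [c for c in present if c.alt_count == 1]

    if all(c.phased for c in present):
        lost_a = any(c.allele_a == 1 for c in present)
        lost_b = any(c.allele_b == 1 for c in present)
        copies = int(lost_a) + int(lost_b)
        het_a = sum(1 for c in hets if c.allele_a == 1)
        het_b = sum(1 for c in hets if c.allele_b == 1)
        trans = het_a >= 1 and het_b >= 1
        if n_hom and trans:
            mech = Mechanism.HOM_AND_CH
        elif n_hom:
            mech = Mechanism.HOMOZYGOUS
        elif trans:
            mech = Mechanism.COMPOUND_HET
        elif len(hets) >= 2:
            mech = Mechanism.MULTI_CIS
        elif len(hets) == 1:
            mech = Mechanism.SINGLE_HET
        else:
            mech = Mechanism.NONE
        return GeneCall(copies, mech)

    # unphased (or mixed-phase): compound hets are never called
    if n_hom:
        return GeneCall(2, Mechanism.HOMOZYGOUS)
    if len(hets) >= 2:
        return GeneCall(1, Mechanism.MULTI_CIS, ambiguous=True)
    if len(hets) == 1:
        return GeneCall(1, Mechanism.SINGLE_HET)
    return GeneCall(0, Mechanism.NONE)


@dataclass
class VariantZygosityMatrix:
    """Variants × samples alt-allele counts with per-row frequencies.

    ``entries`` is an int8 DataFrame indexed by variant_id (``-1`` encodes
    missing); ``annotations`` carries the consequence term and the het/hom
    sample-state frequencies per variant.
    """

    entries: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries.columns)

    def to_table(self) -> pd.DataFrame:
        """Assembled output table: ID, consequence, frequencies, samples."""
        out = self.annotations.join(
            self.entries.astype(object).where(self.entries >= 0, "NA")
        )
        out.index.name = "SNP_ID"
        return out


@dataclass
class GeneLossMatrix:
    """Genes × samples copies-lost matrix plus per-cell mechanisms.

    ``entries``: int8 DataFrame indexed by gene_id, ``-1`` = missing.
    ``mechanisms``: same shape, integer mechanism codes (see
    :meth:`mechanism_at`).  ``ambiguous``: boolean, set where an unphased
    multi-het made cis/trans indeterminate.
    """

    entries: pd.DataFrame
    mechanisms: pd.DataFrame
    ambiguous: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries.columns)

    def mechanism_at(self, gene_id: str, sample_id: str) -> Mechanism:
        return _CODE_MECH[int(self.mechanisms.at[gene_id, sample_id])]

    def gene_call(self, gene_id: str, sample_id: str) -> GeneCall:
        entry = int(self.entries.at[gene_id, sample_id])
        return GeneCall(
            None if entry < 0 else entry,
            self.mechanism_at(gene_id, sample_id),
            bool(self.ambiguous.at[gene_id, sample_id]),
        )

    def to_table(self) -> pd.DataFrame:
        out = self.annotations.join(
            self.entries.astype(object).where(self.entries >= 0, "NA")
        )
        out.index.name = "gene_ID"
        return out


def build_variant_matrix(hc: HcCohort) -> VariantZygosityMatrix:
    """Zygosity matrix over the HC LoF variants (one row per variant)."""
    calls = hc.calls
    A, B = calls.allele_a, calls.allele_b
    Z = ((A == 1).astype(np.int8) + (B == 1).astype(np.int8))
    Z[A == MISSING] = MISSING
    ids = [v.variant_id for v in calls.variants]
    entries = pd.DataFrame(Z, index=ids, columns=calls.sample_ids)
    annotations = compute_variant_frequencies(entries)
    annotations.insert(
        0, "Consequence",
        [_primary_consequence(v) for v in calls.variants],
    )
    return VariantZygosityMatrix(entries=entries, annotations=annotations)


def _primary_consequence(variant: AnnotatedVariant) -> str:
    for csq in variant.consequences:
        if csq.lof_class is LofClass.HC:
            return csq.consequence_terms[0]
    return variant.consequences[0].consequence_terms[0] if variant.consequences else "?"


def build_gene_matrix(hc: HcCohort) -> GeneLossMatrix:
    """Gene copy-loss matrix with per-cell knockout mechanisms.

    Vectorised per gene: haplotype-loss flags are OR-reductions of the alt
    indicators over the gene's variants.  A sample-gene with any unphased
    non-missing call falls back to the unphased rule.  The gene entry is
    missing only when every one of the gene's variant calls is missing for
    that sample.
    """
    calls = hc.calls
    genes = hc.gene_ids
    n_s = calls.n_samples
    entries = np.full((len(genes), n_s), MISSING, dtype=np.int8)
    mechs = np.full((len(genes), n_s), _MECH_CODE[Mechanism.MISSING], np.int8)
    ambig = np.zeros((len(genes), n_s), dtype=bool)

    for gi, gene in enumerate(genes):
        rows = hc.gene_variants[gene]
        A = calls.allele_a[rows]
        B = calls.allele_b[rows]
        P = calls.phased[rows]
        miss = A == MISSING
        all_miss = miss.all(axis=0)
        alt_a = (A == 1) & ~miss
        alt_b = (B == 1) & ~miss
        hom = alt_a & alt_b
        het_a = alt_a & ~alt_b
        het_b = alt_b & ~alt_a
        has_hom = hom.any(axis=0)
        n_het = (het_a | het_b).sum(axis=0)
        sample_phased = (P | miss).all(axis=0)

        lost_a = alt_a.any(axis=0)
        lost_b = alt_b.any(axis=0)
        trans = het_a.any(axis=0) & het_b.any(axis=0)

        copies_ph = lost_a.astype(np.int8) + lost_b.astype(np.int8)
        mech_ph = np.select(
            [has_hom & trans, has_hom, trans, n_het >= 2, n_het == 1],
            [_MECH_CODE[Mechanism.HOM_AND_CH],
             _MECH_CODE[Mechanism.HOMOZYGOUS],
             _MECH_CODE[Mechanism.COMPOUND_HET],
             _MECH_CODE[Mechanism.MULTI_CIS],
             _MECH_CODE[Mechanism.SINGLE_HET]],
            default=_MECH_CODE[Mechanism.NONE],
        ).astype(np.int8)

        copies_un = np.where(has_hom, 2, (n_het > 0).astype(np.int8)).astype(np.int8)
        mech_un = np.select(
            [has_hom, n_het >= 2, n_het == 1],
            [_MECH_CODE[Mechanism.HOMOZYGOUS],
             _MECH_CODE[Mechanism.MULTI_CIS],
             _MECH_CODE[Mechanism.SINGLE_HET]],
            default=_MECH_CODE[Mechanism.NONE],
        ).astype(np.int8)

        entries[gi] = np.where(sample_phased, copies_ph, copies_un)
        mechs[gi] = np.where(sample_phased, mech_ph, mech_un)
        ambig[gi] = ~sample_phased & ~has_hom & (n_het >= 2)
        entries[gi, all_miss] = MISSING
        mechs[gi, all_miss] = _MECH_CODE[Mechanism.MISSING]
        ambig[gi, all_miss] = False

    entries_df = pd.DataFrame(entries, index=genes, columns=calls.sample_ids)
    annotations = compute_gene_frequencies(entries_df)
    annotations.insert(
        0, "gene_symbol", [hc.gene_symbols.get(g, "") for g in genes]
    )
    return GeneLossMatrix(
        entries=entries_df,
        mechanisms=pd.DataFrame(mechs, index=genes, columns=calls.sample_ids),
        ambiguous=pd.DataFrame(ambig, index=genes, columns=calls.sample_ids),
        annotations=annotations,
    )


def detect_ch_events(hc: HcCohort) -> list[CHEvent]:
    """All compound-heterozygous knockouts: one event per (sample, gene).

    When more than one trans pair qualifies, the reported pair is the two
    lowest-position trans variants (ties broken on variant_id), making the
    output deterministic.  Samples whose gene calls include an unphased
    non-missing call yield no events; a fully unphased cohort yields an
    empty list with a prominent warning.
    """
    calls = hc.calls
    if calls.n_variants and not calls.phased[~calls.missing_mask].any():
        logger.warning(
            "cohort is unphased: compound heterozygotes cannot be detected; "
            "returning no events"
        )
        return []
    events: list[CHEvent] = []
    for gene in hc.gene_ids:
        rows = hc.gene_variants[gene]
        A = calls.allele_a[rows]
        B = calls.allele_b[rows]
        P = calls.phased[rows]
        miss = A == MISSING
        het_a = (A == 1) & (B == 0)
        het_b = (B == 1) & (A == 0)
        sample_phased = (P | miss).all(axis=0)
        cand = np.flatnonzero(het_a.any(axis=0) & het_b.any(axis=0) & sample_phased)
        variants = [calls.variants[r] for r in rows]
        order = sorted(range(len(rows)), key=lambda k: (variants[k].pos,
                                                        variants[k].variant_id))
        for s in cand:
            ia = next(k for k in order if het_a[k, s])
            ib = next(k for k in order if het_b[k, s])
            pair = sorted(
                [(variants[ia], "A"), (variants[ib], "B")],
                key=lambda t: (t[0].pos, t[0].variant_id),
            )
            events.append(
                CHEvent(
                    sample_id=calls.sample_ids[s],
                    gene_id=gene,
                    variant_pair=(pair[0][0].variant_id, pair[1][0].variant_id),
                    haplotype_assignment=(pair[0][1], pair[1][1]),
                )
            )
    events.sort(key=lambda e: (e.gene_id, e.sample_id))
    return events


def trans_pairs(hc: HcCohort, sample_id: str, gene_id: str) -> list[tuple[str, str]]:
    """The full list of trans het variant pairs for one sample and gene."""
    calls = hc.calls
    s = calls.sample_ids.index(sample_id)
    rows = hc.gene_variants[gene_id]
    variants = [calls.variants[r] for r in rows]
    A = calls.allele_a[rows, s]
    B = calls.allele_b[rows, s]
    P = calls.phased[rows, s]
    if not ((A == MISSING) | P).all():
        return []
    on_a = [variants[k] for k in range(len(rows)) if A[k] == 1 and B[k] == 0]
    on_b = [variants[k] for k in range(len(rows)) if B[k] == 1 and A[k] == 0]
    pairs = []
    for va, vb in itertools.product(on_a, on_b):
        pairs.append(tuple(sorted((va.variant_id, vb.variant_id))))
    return sorted(set(pairs))


def classify_two_copy_mechanism(gene_matrix: GeneLossMatrix) -> dict[str, str]:
    """Partition knocked-out genes by mechanism across the cohort.

    For every gene with at least one two-copy-loss sample: ``hom_only`` if
    every such sample lost both copies through a homozygous variant,
    ``ch_only`` if every such sample is a compound het, ``both`` otherwise
    (including any single sample with both a hom variant and a trans pair).
    Genes without a two-copy sample are excluded.
    """
    out: dict[str, str] = {}
    ent = gene_matrix.entries.to_numpy()
    mech = gene_matrix.mechanisms.to_numpy()
    hom_c = _MECH_CODE[Mechanism.HOMOZYGOUS]
    ch_c = _MECH_CODE[Mechanism.COMPOUND_HET]
    for gi, gene in enumerate(gene_matrix.entries.index):
        two = ent[gi] == 2
        if not two.any():
            continue
        m = mech[gi][two]
        if (m == hom_c).all():
            out[gene] = "hom_only"
        elif (m == ch_c).all():
            out[gene] = "ch_only"
        else:
            out[gene] = "both"
    return out


def _state_frequencies(entries: pd.DataFrame, labels: tuple[str, str]) -> pd.DataFrame:
    vals = entries.to_numpy()
    nonmiss = (vals >= 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = (vals == 1).sum(axis=1) / nonmiss
        f2 = (vals == 2).sum(axis=1) / nonmiss
    df = pd.DataFrame({labels[0]: f1, labels[1]: f2}, index=entries.index)
    df.loc[nonmiss == 0, :] = np.nan  # all-missing rows have no frequency
    return df


def compute_variant_frequencies(entries: pd.DataFrame) -> pd.DataFrame:
    """Het/hom sample-state frequencies per variant row.

    Frequencies are fractions of non-missing samples in each state, not
    allele frequencies (see :func:`allele_frequencies` for those).
    """
    return _state_frequencies(
        entries, ("heterozygous_LoF_frequency", "homozygous_LoF_frequency")
    )


def compute_gene_frequencies(entries: pd.DataFrame) -> pd.DataFrame:
    """One-copy / two-copy loss sample-state frequencies per gene row."""
    return _state_frequencies(
        entries, ("1_copy_LoF_frequency", "2_copy_LoF_frequency")
    )


def allele_frequencies(matrix: VariantZygosityMatrix) -> pd.Series:
    """Alt-allele frequency per variant: (het + 2*hom) / (2 * non-missing)."""
    vals = matrix.entries.to_numpy()
    nonmiss = (vals >= 0).sum(axis=1).astype(float)
    alt = np.where(vals > 0, vals, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt / (2 * nonmiss)
    return pd.Series(
        np.where(nonmiss > 0, af, np.nan),
        index=matrix.entries.index,
        name="alt_allele_frequency",
    )


def mismatch_genes(
    gene_matrix: GeneLossMatrix, pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], dict[str, list[str]]]:
    """Directional mismatched-gene lists for paired genomes.

    For a pair (A, B), direction ``"A->B"`` lists genes completely inactive
    in B (entry 2) while still active in one or two copies in A (entry 0 or
    1); ``"B->A"`` is symmetric.  A missing entry in either member excludes
    the gene from both directions for that pair.  Useful for donor/recipient
    or maternal/fetal genome comparisons.
    """
    ent = gene_matrix.entries
    known = set(ent.columns)
    out: dict[tuple[str, str], dict[str, list[str]]] = {}
    for a, b in pairs:
        for sid in (a, b):
            if sid not in known:
                raise KeyError(f"sample {sid!r} not present in the gene matrix")
        va = ent[a].to_numpy()
        vb = ent[b].to_numpy()
        ok = (va >= 0) & (vb >= 0)
        a_to_b = ent.index[ok & (vb == 2) & (va < 2)].tolist()
        b_to_a = ent.index[ok & (va == 2) & (vb < 2)].tolist()
        out[(a, b)] = {f"{a}->{b}": a_to_b, f"{b}->{a}": b_to_a}
    return out
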