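"""Reading and writing phased, annotation-bearing VCF cohorts.

This module is the contract boundary with the external annotation step
(VEP + LOFTEE): it consumes VCFs whose INFO ``CSQ`` field carries
per-transcript consequences with LoF confidence classes, and exposes the
cohort as dense numpy genotype arrays suitable for matrix construction.

Multi-allelic records are split on read so that downstream zygosity codes
``{0, 1, 2}`` are always per-alt-allele.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .csq import (
    CsqSchema,
    CsqSchemaError,
    TranscriptConsequence,
    parse_csq_entry,
    parse_csq_schema,
    vep_allele_token,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "AnnotatedVariant",
    "CohortCalls",
    "VcfParseError",
    "read_annotated_vcf",
    "split_multiallelic",
    "write_vcf",
]

MISSING = np.int8(-1)


class VcfParseError(ValueError):
    """A record-level parsing failure, tagged with the offending locus."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's allele pair at one (biallelic) variant.

    Haplotype identity (``allele_a`` vs ``allele_b``) is meaningful only
    when ``phased``; a missing call has both alleles ``None``.
    """

    allele_a: int | None
    allele_b: int | None
    phased: bool

    @property
    def missing(self) -> bool:
        return self.allele_a is None

    @property
    def alt_count(self) -> int | None:
        if self.missing:
            return None
        return int(self.allele_a == 1) + int(self.allele_b == 1)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A biallelic variant with its per-transcript consequence annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequences: tuple[TranscriptConsequence, ...] = ()

    @property
    def variant_id(self) -> str:
        """Canonical underscore-joined key, e.g. ``chr19_52300416_CT_C``."""
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def csq_string(self) -> str:
        return ",".join(c.raw for c in self.consequences)

    @property
    def sort_key(self) -> tuple:
        chrom = self.chrom.removeprefix("chr")
        return (len(chrom), chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortCalls:
    """A cohort of samples × biallelic variants with dense genotype arrays.

    ``allele_a`` / ``allele_b`` are ``int8`` arrays of shape
    ``(n_variants, n_samples)`` with ``-1`` marking a missing call;
    ``phased`` is a boolean array of the same shape.
    """

    sample_ids: list[str]
    variants: list[AnnotatedVariant]
    allele_a: np.ndarray
    allele_b: np.ndarray
    phased: np.ndarray
    header_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = (len(self.variants), len(self.sample_ids))
        for arr in (self.allele_a, self.allele_b, self.phased):
            if arr.shape != shape:
                raise ValueError(
                    f"genotype array shape {arr.shape} != {shape} "
                    "(variants x samples)"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.allele_a == MISSING

    @property
    def cohort_phased(self) -> bool:
        """True only if every non-missing call is phased."""
        nonmiss = ~self.missing_mask
        return bool(self.phased[nonmiss].all()) if nonmiss.any() else True

    def call(self, variant_index: int, sample: int | str) -> GenotypeCall:
        s = sample if isinstance(sample, int) else self.sample_ids.index(sample)
        a = int(self.allele_a[variant_index, s])
        b = int(self.allele_b[variant_index, s])
        if a < 0:
            return GenotypeCall(None, None, phased=False)
        return GenotypeCall(a, b, phased=bool(self.phased[variant_index, s]))

    def subset_variants(self, indices) -> "CohortCalls":
        indices = list(indices)
        return CohortCalls(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in indices],
            allele_a=self.allele_a[indices].copy(),
            allele_b=self.allele_b[indices].copy(),
            phased=self.phased[indices].copy(),
            header_lines=list(self.header_lines),
        )

    def strip_phase(self) -> "CohortCalls":
        """The same calls with all phase information discarded."""
        return replace(
            self,
            allele_a=self.allele_a.copy(),
            allele_b=self.allele_b.copy(),
            phased=np.zeros_like(self.phased),
            variants=list(self.variants),
            sample_ids=list(self.sample_ids),
            header_lines=list(self.header_lines),
        )

    def swap_haplotypes(self, samples=None) -> "CohortCalls":
        """Globally swap allele_a/allele_b within the given samples.

        Downstream matrices and events must be invariant under this.
        """
        a, b = self.allele_a.copy(), self.allele_b.copy()
        cols = slice(None) if samples is None else list(samples)
        a[:, cols], b[:, cols] = self.allele_b[:, cols], self.allele_a[:, cols]
        return replace(
            self,
            allele_a=a,
            allele_b=b,
            phased=self.phased.copy(),
            variants=list(self.variants),
            sample_ids=list(self.sample_ids),
            header_lines=list(self.header_lines),
        )


def _read_header_text(path: str | Path) -> str:
    opener = gzip.open if str(path).endswith(".gz") else open
    lines = []
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            lines.append(line.rstrip("\n"))
    return "\n".join(lines)


def split_multiallelic(
    record, schema: CsqSchema | None
) -> list[tuple[AnnotatedVariant, np.ndarray, np.ndarray, np.ndarray]]:
    """Split a cyvcf2 record into per-alt biallelic variants.

    For each alt allele the genotype is remapped so the focal alt is ``1``
    and every other allele (reference or another alt) is ``0``; consequence
    entries are assigned to the matching alt via the CSQ ``Allele``
    sub-field.  Returns ``(variant, allele_a, allele_b, phased)`` tuples.
    """
    gts = record.genotypes  # per sample: [a, b, phased] (or [a, phased])
    n = len(gts)
    raw_a = np.empty(n, dtype=np.int8)
    raw_b = np.empty(n, dtype=np.int8)
    phased = np.empty(n, dtype=bool)
    for s, g in enumerate(gts):
        alleles, ph = g[:-1], bool(g[-1])
        if len(alleles) == 1:  # haploid/hemizygous: count as two copies
            alleles = [alleles[0], alleles[0]]
            logger.debug(
                "haploid GT at %s:%d sample %d treated as homozygous",
                record.CHROM, record.POS, s,
            )
        a, b = int(alleles[0]), int(alleles[1])
        if a < 0 or b < 0:
            a = b = -1
            ph = False
        raw_a[s], raw_b[s], phased[s] = a, b, ph

    csq_entries: list[TranscriptConsequence] = []
    if schema is not None:
        raw_csq = record.INFO.get("CSQ")
        if raw_csq:
            for entry in str(raw_csq).split(","):
                try:
                    csq_entries.append(parse_csq_entry(entry, schema))
                except ValueError as exc:
                    raise VcfParseError(
                        f"{record.CHROM}:{record.POS}: {exc}"
                    ) from exc

    out = []
    for j, alt in enumerate(record.ALT, start=1):
        a = np.where(raw_a == -1, MISSING, (raw_a == j).astype(np.int8))
        b = np.where(raw_b == -1, MISSING, (raw_b == j).astype(np.int8))
        token = vep_allele_token(record.REF, alt)
        if len(record.ALT) == 1:
            csq = tuple(csq_entries)
            unmatched = ()
        else:
            csq = tuple(
                c for c in csq_entries if c.allele in (token, alt)
            )
            unmatched = [
                c for c in csq_entries
                if all(
                    c.allele not in (vep_allele_token(record.REF, x), x)
                    for x in record.ALT
                )
            ]
        for c in unmatched:
            logger.warning(
                "CSQ allele %r at %s:%d matches no ALT; consequence dropped",
                c.allele, record.CHROM, record.POS,
            )
        out.append(
            (
                AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    consequences=csq,
                ),
                a.astype(np.int8),
                b.astype(np.int8),
                phased.copy(),
            )
        )
    return out


def read_annotated_vcf(
    path: str | Path, schema: CsqSchema | None = None
) -> CohortCalls:
    """Read a (possibly gzip-compressed) VCF into a :class:`CohortCalls`.

    If ``schema`` is omitted it is resolved from the file's own header;
    a file without a CSQ definition is read with empty annotations (the
    state of an IMPUTE2-converted cohort before VEP/LOFTEE).
    """
    header_text = _read_header_text(path)
    if schema is None:
        try:
            schema = parse_csq_schema(header_text)
        except CsqSchemaError:
            schema = None
            logger.info("no CSQ definition in %s; reading genotypes only", path)

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    rows_a, rows_b, rows_p = [], [], []
    for record in vcf:
        for var, a, b, ph in split_multiallelic(record, schema):
            variants.append(var)
            rows_a.append(a)
            rows_b.append(b)
            rows_p.append(ph)
    vcf.close()

    n = len(sample_ids)
    shape = (len(variants), n)
    return CohortCalls(
        sample_ids=sample_ids,
        variants=variants,
        allele_a=(
            np.array(rows_a, dtype=np.int8)
            if variants else np.empty(shape, dtype=np.int8)
        ),
        allele_b=(
            np.array(rows_b, dtype=np.int8)
            if variants else np.empty(shape, dtype=np.int8)
        ),
        phased=(
            np.array(rows_p, dtype=bool)
            if variants else np.empty(shape, dtype=bool)
        ),
        header_lines=[ln for ln in header_text.split("\n") if ln],
    )


def write_vcf(cohort: CohortCalls, path: str | Path, provenance: str = "") -> Path:
    """Write a cohort back to a plain-text VCF, preserving CSQ strings.

    The original header meta-lines are reproduced, followed by a provenance
    line.  Round-tripping through :func:`read_annotated_vcf` reproduces
    calls, phase flags and CSQ strings exactly.
    """
    path = Path(path)
    lines: list[str] = []
    header = list(cohort.header_lines)
    if not any(ln.startswith("##fileformat") for ln in header):
        header.insert(0, "##fileformat=VCFv4.2")
    lines.extend(header)
    if provenance:
        lines.append(f"##lofcall_provenance={provenance}")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.sample_ids)
    )
    A, B, P = cohort.allele_a, cohort.allele_b, cohort.phased
    for i, v in enumerate(cohort.variants):
        info = f"CSQ={v.csq_string}" if v.consequences else "."
        gts = []
        for s in range(cohort.n_samples):
            if A[i, s] < 0:
                gts.append("./.")
            else:
                sep = "|" if P[i, s] else "/"
                gts.append(f"{A[i, s]}{sep}{B[i, s]}")
        lines.append(
            "\t".join(
                [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", ".",
                 info, "GT"] + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
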