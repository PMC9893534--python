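"""Parsing of VEP-style CSQ annotations carrying LOFTEE loss-of-function calls.

VEP packs per-transcript consequence annotations into the INFO ``CSQ`` field
as a comma-separated list of pipe-delimited entries.  The sub-field layout is
declared once in the VCF header (``##INFO=<ID=CSQ,...Format: A|B|C...>``).
LOFTEE adds two sub-fields: ``LoF`` (``HC`` high-confidence / ``LC``
low-confidence) and ``LoF_flags``.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "LofClass",
    "CsqSchema",
    "TranscriptConsequence",
    "CsqSchemaError",
    "parse_csq_schema",
    "parse_csq_entry",
    "vep_allele_token",
]


class CsqSchemaError(ValueError):
    """Raised when the VCF header lacks a usable CSQ definition."""


class LofClass(enum.Enum):
    """LOFTEE confidence class of a putative loss-of-function annotation."""

    HC = "HC"
    LC = "LC"
    NONE = ""


# sub-field names recognised for each required slot, in preference order
_FIELD_ALIASES = {
    "allele": ("Allele",),
    "gene": ("Gene",),
    "symbol": ("SYMBOL",),
    "consequence": ("Consequence",),
    "feature": ("Feature",),
    "lof": ("LoF",),
    "lof_flags": ("LoF_flags",),
}

_CSQ_FORMAT_RE = re.compile(
    r'##INFO=<ID=CSQ,.*?Description=".*?Format:\s*([^">]+)"', re.IGNORECASE
)


@dataclass(frozen=True)
class CsqSchema:
    """Ordered CSQ sub-field layout resolved from a VCF header.

    Indices point into the pipe-split annotation entry.  ``index_of_feature``
    and ``index_of_allele`` may be ``None`` (older VEP dialects); the LoF and
    gene slots are mandatory.
    """

    field_names: tuple[str, ...]
    index_of_allele: int | None
    index_of_gene: int
    index_of_symbol: int
    index_of_consequence: int
    index_of_feature: int | None
    index_of_lof: int
    index_of_lof_flags: int

    def __post_init__(self) -> None:
        if len(set(self.field_names)) != len(self.field_names):
            raise CsqSchemaError("duplicate CSQ sub-field names in header")


@dataclass(frozen=True)
class TranscriptConsequence:
    """One CSQ entry: the predicted effect of a variant on one transcript."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    consequence_terms: tuple[str, ...]
    lof_class: LofClass = LofClass.NONE
    lof_flags: str = ""
    allele: str = ""
    raw: str = field(default="", repr=False, compare=False)

    @property
    def is_hc(self) -> bool:
        return self.lof_class is LofClass.HC


def parse_csq_schema(header_text: str) -> CsqSchema:
    """Resolve the CSQ sub-field layout from VCF header text.

    Parameters
    ----------
    header_text:
        The ``##``-prefixed meta lines of a VCF (or the full header text).

    Raises
    ------
    CsqSchemaError
        If no CSQ INFO definition is present, or a required sub-field
        (``Gene``, ``SYMBOL``, ``Consequence``, ``LoF``, ``LoF_flags``)
        is absent from the declared format.
    """
    m = _CSQ_FORMAT_RE.search(header_text)
    if m is None:
        raise CsqSchemaError(
            "VCF header has no ##INFO=<ID=CSQ,...> definition with a "
            '"Format:" sub-field list; was the file annotated with VEP?'
        )
    names = tuple(s.strip() for s in m.group(1).split("|"))

    def find(slot: str, required: bool) -> int | None:
        for alias in _FIELD_ALIASES[slot]:
            if alias in names:
                return names.index(alias)
        if required:
            raise CsqSchemaError(
                f"CSQ format lacks the required sub-field "
                f"{_FIELD_ALIASES[slot][0]!r} (declared: {'|'.join(names)})"
            )
        return None

    return CsqSchema(
        field_names=names,
        index_of_allele=find("allele", required=False),
        index_of_gene=find("gene", required=True),
        index_of_symbol=find("symbol", required=True),
        index_of_consequence=find("consequence", required=True),
        index_of_feature=find("feature", required=False),
        index_of_lof=find("lof", required=True),
        index_of_lof_flags=find("lof_flags", required=True),
    )


def parse_csq_entry(entry: str, schema: CsqSchema) -> TranscriptConsequence:
    """Parse one pipe-delimited CSQ entry against a resolved schema.

    Raises
    ------
    ValueError
        If the entry's arity does not match the schema.
    """
    parts = entry.split("|")
    if len(parts) != len(schema.field_names):
        raise ValueError(
            f"CSQ entry has {len(parts)} sub-fields, header declares "
            f"{len(schema.field_names)}: {entry!r}"
        )

    lof_token = parts[schema.index_of_lof].strip()
    if lof_token == "HC":
        lof_class = LofClass.HC
    elif lof_token == "LC":
        lof_class = LofClass.LC
    elif lof_token == "":
        lof_class = LofClass.NONE
    else:
        logger.warning("unrecognised LoF token %r treated as non-LoF", lof_token)
        lof_class = LofClass.NONE

    consequence = parts[schema.index_of_consequence]
    terms = tuple(t for t in consequence.split("&") if t) or ("?",)
    feature = (
        parts[schema.index_of_feature] if schema.index_of_feature is not None else ""
    )
    allele = (
        parts[schema.index_of_allele] if schema.index_of_allele is not None else ""
    )
    return TranscriptConsequence(
        transcript_id=feature,
        gene_id=parts[schema.index_of_gene],
        gene_symbol=parts[schema.index_of_symbol],
        consequence_terms=terms,
        lof_class=lof_class,
        lof_flags=parts[schema.index_of_lof_flags].strip(),
        allele=allele,
        raw=entry,
    )


def vep_allele_token(ref: str, alt: str) -> str:
    """The token VEP writes in the CSQ ``Allele`` sub-field for an alt allele.

    SNVs keep the alt base.  For simple indels sharing a leading base, VEP
    trims that base: insertions keep the inserted sequence, deletions become
    ``-``.  More exotic alleles are left verbatim.
    """
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if ref and alt and ref[0] == alt[0]:
        if len(alt) > len(ref) and alt[: len(ref)] == ref:
            return alt[len(ref):]
        if len(ref) > len(alt) and len(alt) == 1:
            return "-"
        return alt[1:] or "-"
    return alt
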