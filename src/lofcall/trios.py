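"""Trio transmission validation of compound heterozygotes, and call-set
comparison between a truth cohort and a test cohort.

A predicted compound het in a proband is genuine only if its two LoF
alleles were donated by different parents: one parent must carry the first
variant of the pair and the other parent the second (in either assignment).
Parental phase is not required — carrier status (>=1 alt allele) suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import CHEvent
from .vcf import MISSING, CohortCalls

__all__ = [
    "Trio",
    "TransmissionResult",
    "TransmissionSummary",
    "CallsetComparison",
    "read_pedigree",
    "write_pedigree",
    "validate_ch_transmission",
    "compare_callsets",
]


@dataclass(frozen=True)
class Trio:
    proband_id: str
    father_id: str
    mother_id: str

    def __post_init__(self) -> None:
        if len({self.proband_id, self.father_id, self.mother_id}) != 3:
            raise ValueError(f"trio ids must be distinct: {self}")


@dataclass(frozen=True)
class TransmissionResult:
    """Verdict for one proband CH event against its parents' genotypes.

    ``true_transmission`` iff one variant of the pair has >=1 alt allele in
    the father and the other has >=1 alt allele in the mother, in either
    assignment.  ``missing_data`` marks events where a parent was missing
    at both variants; ``de_novo`` marks events with a variant absent from
    both parents.
    """

    event: CHEvent
    true_transmission: bool
    father_carries: tuple[bool | None, bool | None]
    mother_carries: tuple[bool | None, bool | None]
    missing_data: bool = False
    de_novo: bool = False


@dataclass(frozen=True)
class TransmissionSummary:
    n_events: int
    n_true: int
    n_false: int
    n_missing_data: int

    @property
    def rate_inclusive(self) -> float | None:
        """True-transmission fraction over all events."""
        return self.n_true / self.n_events if self.n_events else None

    @property
    def rate_excluding_missing(self) -> float | None:
        """True-transmission fraction excluding parental-missing events."""
        denom = self.n_events - self.n_missing_data
        return self.n_true / denom if denom else None


def read_pedigree(path: str | Path) -> list[Trio]:
    """Read a PED-like file (family, individual, father, mother, sex,
    phenotype; unknown parents coded 0) and return complete trios only."""
    trios = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed pedigree line: {line!r}")
        _, iid, fid, mid = parts[:4]
        if fid != "0" and mid != "0":
            trios.append(Trio(proband_id=iid, father_id=fid, mother_id=mid))
    return trios


def write_pedigree(trios: list[Trio], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for i, t in enumerate(trios, start=1):
        fam = f"FAM{i:04d}"
        lines.append(f"{fam}\t{t.father_id}\t0\t0\t1\t-9")
        lines.append(f"{fam}\t{t.mother_id}\t0\t0\t2\t-9")
        lines.append(f"{fam}\t{t.proband_id}\t{t.father_id}\t{t.mother_id}\t0\t-9")
    path.write_text("\n".join(lines) + "\n")
    return path


def _carrier(calls: CohortCalls, vmap: dict[str, int], vid: str,
             sample_idx: int) -> bool | None:
    """>=1 alt allele; None when the call (or the variant) is missing."""
    row = vmap.get(vid)
    if row is None:
        return None
    a = calls.allele_a[row, sample_idx]
    b = calls.allele_b[row, sample_idx]
    if a == MISSING:
        return None
    return bool(a == 1 or b == 1)


def validate_ch_transmission(
    trios: list[Trio], ch_events: list[CHEvent], cohort: CohortCalls
) -> tuple[list[TransmissionResult], TransmissionSummary]:
    """Check each proband CH event for bi-parental transmission.

    Events whose sample is not a proband of any trio are ignored.  A parent
    missing genotypes at both variants makes the verdict
    ``false_transmission`` with ``missing_data`` set (never silently
    dropped); an event with a variant carried by neither parent is flagged
    ``de_novo``.
    """
    by_proband = {t.proband_id: t for t in trios}
    sample_index = {s: i for i, s in enumerate(cohort.sample_ids)}
    vmap = {v.variant_id: i for i, v in enumerate(cohort.variants)}

    results: list[TransmissionResult] = []
    for event in ch_events:
        trio = by_proband.get(event.sample_id)
        if trio is None:
            continue
        for pid in (trio.father_id, trio.mother_id):
            if pid not in sample_index:
                raise KeyError(f"parent {pid!r} absent from cohort")
        v1, v2 = event.variant_pair
        fa = sample_index[trio.father_id]
        mo = sample_index[trio.mother_id]
        f1, f2 = _carrier(cohort, vmap, v1, fa), _carrier(cohort, vmap, v2, fa)
        m1, m2 = _carrier(cohort, vmap, v1, mo), _carrier(cohort, vmap, v2, mo)
        missing = (f1 is None and f2 is None) or (m1 is None and m2 is None)
        true_tx = bool((f1 and m2) or (f2 and m1))
        de_novo = (f1 is False and m1 is False) or (f2 is False and m2 is False)
        results.append(
            TransmissionResult(
                event=event,
                true_transmission=true_tx,
                father_carries=(f1, f2),
                mother_carries=(m1, m2),
                missing_data=missing,
                de_novo=de_novo,
            )
        )

    n_true = sum(r.true_transmission for r in results)
    summary = TransmissionSummary(
        n_events=len(results),
        n_true=n_true,
        n_false=len(results) - n_true,
        n_missing_data=sum(r.missing_data for r in results),
    )
    return results, summary


@dataclass(frozen=True)
class CallsetComparison:
    """Per-sample false positives/negatives of a test call set vs truth.

    A variant is "called" in a sample when the sample carries >=1 alt
    allele (optionally restricted to homozygous two-copy calls).  FN are
    truth-only calls, FP are test-only calls; averages are per shared
    sample.
    """

    sample_ids: list[str]
    fn_per_sample: np.ndarray
    fp_per_sample: np.ndarray

    @property
    def fn_average(self) -> float:
        return float(np.mean(self.fn_per_sample)) if self.sample_ids else 0.0

    @property
    def fp_average(self) -> float:
        return float(np.mean(self.fp_per_sample)) if self.sample_ids else 0.0


def _called_sets(
    cohort: CohortCalls, samples: list[str], two_copy_only: bool
) -> list[set[str]]:
    idx = {s: i for i, s in enumerate(cohort.sample_ids)}
    cols = [idx[s] for s in samples]
    A = cohort.allele_a[:, cols]
    B = cohort.allele_b[:, cols]
    alt = (A == 1).astype(np.int8) + (B == 1).astype(np.int8)
    alt[A == MISSING] = 0
    wanted = alt == 2 if two_copy_only else alt >= 1
    vids = [v.variant_id for v in cohort.variants]
    return [
        {vids[i] for i in np.flatnonzero(wanted[:, k])}
        for k in range(len(samples))
    ]


def compare_callsets(
    truth: CohortCalls, test: CohortCalls, two_copy_only: bool = False
) -> CallsetComparison:
    """Per-sample FP/FN counts between two call sets keyed by variant_id.

    Mirrors the accuracy analysis that compares LoF calls from sequencing
    (truth) with calls from imputed genotypes (test): FN = called in truth
    but not in test, FP = the converse.  Annotation differences between the
    call sets are ignored — only (chrom, pos, ref, alt) identity matters.
    """
    shared = [s for s in truth.sample_ids if s in set(test.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between the two call sets")
    truth_sets = _called_sets(truth, shared, two_copy_only)
    test_sets = _called_sets(test, shared, two_copy_only)
    fn = np.array([len(a - b) for a, b in zip(truth_sets, test_sets)])
    fp = np.array([len(b - a) for a, b in zip(truth_sets, test_sets)])
    return CallsetComparison(sample_ids=shared, fn_per_sample=fn,
                             fp_per_sample=fp)
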