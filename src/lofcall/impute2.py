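"""Quality filtering of IMPUTE2-format imputed genotypes and conversion to
phased VCF.

Imputed data carry two quality metrics: the per-variant INFO score
(imputation certainty, in [0, 1]) and the per-call genotype probability
triple (P(hom-ref), P(het), P(hom-alt)).  Variants are filtered on
``info_score > min_info``; per-call, the best-supported genotype (the
argmax of the triple) is accepted only when its probability is at least
``1 - prob_cutoff``, otherwise the call is set missing.  The probability
cutoff is thus a distance-from-certainty: cutoff 0.05 keeps calls whose
best genotype has probability >= 0.95.

Phase is taken from the SHAPEIT-style ``.haps`` file; the probabilities
decide only missingness.  When the haplotype pair disagrees with the
argmax genotype, the haplotypes win (and the conflict is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QualityThresholds",
    "ImputedCohort",
    "filter_by_info",
    "call_genotype",
    "read_impute2",
    "convert_to_vcf",
]

#: genotype index -> alt-allele count: 0 = hom-ref, 1 = het, 2 = hom-alt
_PROB_SUM_TOL = 1e-3


@dataclass(frozen=True)
class QualityThresholds:
    """Imputation quality cut-offs.

    ``min_info``: variants are kept when INFO score is strictly above this.
    ``prob_cutoff``: a genotype call is kept when its best probability is at
    least ``1 - prob_cutoff`` (default 0.05, the midpoint of the commonly
    examined 0.01–0.1 range).
    """

    min_info: float = 0.9
    prob_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_info", "prob_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ImputedCohort:
    """In-memory view of one IMPUTE2 chunk (same variants in .gen/.haps).

    ``probs``: float array (n_variants, n_samples, 3); ``hap_a``/``hap_b``:
    int8 phased haplotype alleles; ``info_scores``: per-variant INFO.
    """

    sample_ids: list[str]
    keys: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)
    probs: np.ndarray
    hap_a: np.ndarray
    hap_b: np.ndarray
    info_scores: np.ndarray


def filter_by_info(
    info_scores: np.ndarray | pd.Series, min_info: float
) -> np.ndarray:
    """Boolean keep-mask: strictly ``info > min_info``, order preserved."""
    scores = np.asarray(info_scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("INFO scores must lie in [0, 1]")
    return scores > min_info


def call_genotype(prob_triple, prob_cutoff: float) -> int | None:
    """Best-supported genotype from a probability triple, or None (missing).

    Returns the argmax alt-allele count (0/1/2) when its probability is at
    least ``1 - prob_cutoff``; ties between the top genotypes are broken
    toward missing.
    """
    p = np.asarray(prob_triple, dtype=float)
    if p.shape != (3,):
        raise ValueError("probability triple must have exactly 3 entries")
    if np.any(p < 0):
        raise ValueError(f"negative genotype probability: {p}")
    if abs(p.sum() - 1.0) > _PROB_SUM_TOL:
        raise ValueError(f"genotype probabilities sum to {p.sum():.4f}, not 1")
    best = int(np.argmax(p))
    if p[best] < 1.0 - prob_cutoff:
        return None
    if np.sum(p == p[best]) > 1:  # tied best genotypes: undecidable
        return None
    return best


def _called_matrix(probs: np.ndarray, prob_cutoff: float) -> np.ndarray:
    """Vectorised :func:`call_genotype` over (n_variants, n_samples, 3)."""
    if np.any(probs < 0):
        raise ValueError("negative genotype probability")
    best = probs.argmax(axis=2)
    best_p = probs.max(axis=2)
    ties = (probs == best_p[..., None]).sum(axis=2) > 1
    out = best.astype(np.int8)
    out[(best_p < 1.0 - prob_cutoff) | ties] = -1
    return out


def read_impute2(
    gen_path: str | Path,
    haps_path: str | Path,
    sample_path: str | Path,
    info_path: str | Path,
    info_column: str = "info",
) -> ImputedCohort:
    """Load one IMPUTE2 chunk (.gen + .haps + .sample + SNPTEST info file).

    The four files must describe the same variants and samples; a variant
    present in the .gen but absent from the .haps is fatal, because phase
    is required downstream.
    """
    sample_df = pd.read_csv(sample_path, sep=r"\s+")
    sample_ids = [
        str(s) for s in sample_df["ID_2"].tolist()[1:]  # row 0 is the type row
    ]

    try:
        gen = pd.read_csv(gen_path, sep=r"\s+", header=None)
    except pd.errors.EmptyDataError:
        n = len(sample_ids)
        return ImputedCohort(
            sample_ids=sample_ids, keys=[],
            probs=np.empty((0, n, 3)),
            hap_a=np.empty((0, n), dtype=np.int8),
            hap_b=np.empty((0, n), dtype=np.int8),
            info_scores=np.empty(0),
        )
    if len(gen.columns) < 5 or (len(gen.columns) - 5) % 3:
        raise ValueError(f"malformed .gen file {gen_path}")
    n_samples = (len(gen.columns) - 5) // 3
    if len(sample_ids) != n_samples:
        raise ValueError(
            f"sample file lists {len(sample_ids)} individuals, .gen has "
            f"{n_samples}"
        )

    keys = [
        (str(r[0]), int(r[2]), str(r[3]), str(r[4]))
        for r in gen.itertuples(index=False)
    ]
    rsids = [str(r[1]) for r in gen.itertuples(index=False)]
    probs = gen.iloc[:, 5:].to_numpy(dtype=float).reshape(len(keys), n_samples, 3)
    bad = np.abs(probs.sum(axis=2) - 1.0) > _PROB_SUM_TOL
    if bad.any():
        i, s = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"probability triple does not sum to 1 at variant {keys[i]} "
            f"sample {sample_ids[s]}"
        )

    haps = pd.read_csv(haps_path, sep=r"\s+", header=None)
    hap_keys = {
        (str(r[0]), int(r[2]), str(r[3]), str(r[4])): i
        for i, r in enumerate(haps.itertuples(index=False))
    }
    missing_keys = [k for k in keys if k not in hap_keys]
    if missing_keys:
        raise ValueError(
            f"variant {missing_keys[0]} present in .gen but absent from "
            ".haps; phased haplotypes are required"
        )
    hap_rows = [hap_keys[k] for k in keys]
    hmat = haps.iloc[:, 5:].to_numpy(dtype=np.int8)[hap_rows]
    if hmat.shape[1] != 2 * n_samples:
        raise ValueError(".haps column count does not match sample count")
    hap_a, hap_b = hmat[:, 0::2], hmat[:, 1::2]

    info_df = pd.read_csv(info_path, sep=r"\s+")
    if info_column not in info_df.columns:
        raise ValueError(
            f"info file lacks column {info_column!r} "
            f"(has: {list(info_df.columns)})"
        )
    pos_col = "position" if "position" in info_df.columns else info_df.columns[2]
    id_col = "rs_id" if "rs_id" in info_df.columns else info_df.columns[1]
    info_keyed = {
        (str(row[id_col]), int(row[pos_col])): float(row[info_column])
        for _, row in info_df.iterrows()
    }
    scores = np.empty(len(keys))
    for i, (rsid, k) in enumerate(zip(rsids, keys)):
        try:
            scores[i] = info_keyed[(rsid, k[1])]
        except KeyError:
            raise ValueError(
                f"info file has no entry for variant {rsid} at "
                f"{k[0]}:{k[1]}"
            ) from None

    return ImputedCohort(
        sample_ids=sample_ids,
        keys=keys,
        probs=probs,
        hap_a=hap_a,
        hap_b=hap_b,
        info_scores=scores,
    )


def convert_to_vcf(
    gen_path: str | Path,
    haps_path: str | Path,
    sample_path: str | Path,
    info_path: str | Path,
    thresholds: QualityThresholds,
    out_path: str | Path,
    info_column: str = "info",
) -> Path:
    """Filter an IMPUTE2 chunk and write a phased VCF.

    Records failing the INFO filter are omitted; calls whose best genotype
    probability falls below ``1 - prob_cutoff`` become ``./.``; surviving
    genotypes take their phased alleles from the .haps file.
    """
    cohort = read_impute2(gen_path, haps_path, sample_path, info_path,
                          info_column=info_column)
    keep = filter_by_info(cohort.info_scores, thresholds.min_info)
    called = _called_matrix(cohort.probs, thresholds.prob_cutoff)

    hap_gt = cohort.hap_a + cohort.hap_b
    conflicts = (called >= 0) & (called != hap_gt)
    if conflicts.any():
        logger.info(
            "%d calls where argmax genotype disagrees with haplotypes; "
            "haplotypes win for phase", int(conflicts.sum()),
        )

    out_path = Path(out_path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,'
        'Description="Imputation INFO score">',
        *(f"##contig=<ID={c}>" for c in
          dict.fromkeys(k[0] for k in cohort.keys)),
        f"##lofcall_provenance=impute2 conversion min_info>"
        f"{thresholds.min_info} prob_cutoff={thresholds.prob_cutoff}",
        "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO", "FORMAT"] + cohort.sample_ids),
    ]
    for i in np.flatnonzero(keep):
        chrom, pos, ref, alt = cohort.keys[i]
        gts = []
        for s in range(len(cohort.sample_ids)):
            if called[i, s] < 0:
                gts.append("./.")
            else:
                gts.append(f"{cohort.hap_a[i, s]}|{cohort.hap_b[i, s]}")
        lines.append(
            "\t".join(
                [chrom, str(pos), f"{chrom}_{pos}_{ref}_{alt}", ref, alt,
                 ".", ".", f"INFO_SCORE={cohort.info_scores[i]:.4f}", "GT"]
                + gts
            )
        )
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
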