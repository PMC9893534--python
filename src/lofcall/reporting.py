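"""Cohort-level descriptive statistics and the plain-text ``.info`` report."""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import CHEvent, GeneLossMatrix, VariantZygosityMatrix

__all__ = ["PerSampleStats", "CohortSummary", "summarize",
           "write_info_report", "parse_info_report"]


@dataclass(frozen=True)
class PerSampleStats:
    mean: float
    median: float
    min: int
    max: int

    @staticmethod
    def of(counts: np.ndarray) -> "PerSampleStats":
        if counts.size == 0:
            return PerSampleStats(0.0, 0.0, 0, 0)
        return PerSampleStats(
            float(np.mean(counts)), float(np.median(counts)),
            int(np.min(counts)), int(np.max(counts)),
        )


@dataclass(frozen=True)
class CohortSummary:
    """Totals and per-sample distributions of LoF variants and genes.

    Gene totals follow the overlapping-class convention: a gene counts as
    one-copy if any sample lost one copy and as two-copy if any sample lost
    both — a gene may appear in both classes, and the total is the number of
    distinct affected genes (so the class counts need not sum to the total).
    """

    n_samples: int
    n_lof_variants: int
    n_het_variants: int
    n_hom_variants: int
    n_ch_events: int
    n_lof_genes: int
    n_one_copy_genes: int
    n_two_copy_genes: int
    variants_per_sample: PerSampleStats
    het_variants_per_sample: PerSampleStats
    hom_variants_per_sample: PerSampleStats
    one_copy_genes_per_sample: PerSampleStats
    two_copy_genes_per_sample: PerSampleStats


def summarize(
    variant_matrix: VariantZygosityMatrix,
    gene_matrix: GeneLossMatrix,
    ch_events: list[CHEvent],
) -> CohortSummary:
    """Descriptive statistics over the two matrices and the CH event list.

    Totals count distinct variants/genes with at least one qualifying
    sample; per-sample statistics are computed over non-missing entries.
    """
    if list(variant_matrix.sample_ids) != list(gene_matrix.sample_ids):
        raise ValueError(
            "variant and gene matrices cover different sample sets"
        )
    V = variant_matrix.entries.to_numpy()
    G = gene_matrix.entries.to_numpy()

    def per_sample(mat: np.ndarray, state) -> np.ndarray:
        if mat.size == 0:
            return np.zeros(mat.shape[1] if mat.ndim == 2 else 0, dtype=int)
        return state(mat).sum(axis=0)

    return CohortSummary(
        n_samples=len(variant_matrix.sample_ids),
        n_lof_variants=int(((V == 1) | (V == 2)).any(axis=1).sum()) if V.size else 0,
        n_het_variants=int((V == 1).any(axis=1).sum()) if V.size else 0,
        n_hom_variants=int((V == 2).any(axis=1).sum()) if V.size else 0,
        n_ch_events=len(ch_events),
        n_lof_genes=int(((G == 1) | (G == 2)).any(axis=1).sum()) if G.size else 0,
        n_one_copy_genes=int((G == 1).any(axis=1).sum()) if G.size else 0,
        n_two_copy_genes=int((G == 2).any(axis=1).sum()) if G.size else 0,
        variants_per_sample=PerSampleStats.of(per_sample(V, lambda m: m >= 1)),
        het_variants_per_sample=PerSampleStats.of(per_sample(V, lambda m: m == 1)),
        hom_variants_per_sample=PerSampleStats.of(per_sample(V, lambda m: m == 2)),
        one_copy_genes_per_sample=PerSampleStats.of(per_sample(G, lambda m: m == 1)),
        two_copy_genes_per_sample=PerSampleStats.of(per_sample(G, lambda m: m == 2)),
    )


_SCALAR_LABELS = {
    "n_samples": "samples",
    "n_lof_variants": "total_LoF_variants",
    "n_het_variants": "total_heterozygous_LoF_variants",
    "n_hom_variants": "total_homozygous_LoF_variants",
    "n_ch_events": "total_CH_LoF_events",
    "n_lof_genes": "total_LoF_genes",
    "n_one_copy_genes": "total_1_copy_LoF_genes",
    "n_two_copy_genes": "total_2_copy_LoF_genes",
}
_DIST_LABELS = {
    "variants_per_sample": "LoF_variants_per_sample",
    "het_variants_per_sample": "heterozygous_LoF_variants_per_sample",
    "hom_variants_per_sample": "homozygous_LoF_variants_per_sample",
    "one_copy_genes_per_sample": "1_copy_LoF_genes_per_sample",
    "two_copy_genes_per_sample": "2_copy_LoF_genes_per_sample",
}


def write_info_report(
    summary: CohortSummary, path: str | Path, provenance: dict | None = None
) -> Path:
    """Write the key/value ``.info`` statistical report.

    Provenance (input paths, thresholds, version) is emitted as ``#``
    comment lines; every numeric field round-trips through
    :func:`parse_info_report`.
    """
    from . import __version__

    path = Path(path)
    lines = [
        "# lofcall statistical report",
        f"# version: {__version__}",
        f"# written: {datetime.datetime.now().isoformat(timespec='seconds')}",
    ]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    for name, label in _SCALAR_LABELS.items():
        lines.append(f"{label}\t{getattr(summary, name)}")
    for name, label in _DIST_LABELS.items():
        st: PerSampleStats = getattr(summary, name)
        lines.append(f"mean_{label}\t{st.mean:.6g}")
        lines.append(f"median_{label}\t{st.median:.6g}")
        lines.append(f"min_{label}\t{st.min}")
        lines.append(f"max_{label}\t{st.max}")
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_info_report(path: str | Path) -> CohortSummary:
    """Parse a ``.info`` report back into a :class:`CohortSummary`."""
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        label, _, raw = line.partition("\t")
        values[label] = float(raw)

    kwargs: dict = {}
    for name, label in _SCALAR_LABELS.items():
        kwargs[name] = int(values[label])
    for name, label in _DIST_LABELS.items():
        kwargs[name] = PerSampleStats(
            mean=values[f"mean_{label}"],
            median=values[f"median_{label}"],
            min=int(values[f"min_{label}"]),
            max=int(values[f"max_{label}"]),
        )
    return CohortSummary(**kwargs)
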