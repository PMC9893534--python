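"""Synthetic annotated cohorts, trios and IMPUTE2 chunks with exact truth.

Every generator plants knockout configurations (homozygous, compound-het,
cis pair, single het) at exactly the requested counts and emits the truth
tables alongside the files, so the calling pipeline can be validated
end-to-end without any external data.  Outputs are bit-reproducible for a
given configuration and seed.

The generators emulate the *logical* structure of real cohorts — phased
genotypes, VEP/LOFTEE-style CSQ annotations, rare alt alleles — not their
population-genetic texture (no LD, no coalescent history, no sequencing
error model beyond simple allele flips).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CHEvent, Mechanism
from .vcf import AnnotatedVariant

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "generate_cohort",
    "generate_trios",
    "generate_impute2",
]

_HC_TERMS = ("stop_gained", "frameshift_variant", "splice_acceptor_variant",
             "splice_donor_variant")
_BASES = ("A", "C", "G", "T")

CSQ_FORMAT = "Allele|Consequence|SYMBOL|Gene|Feature|LoF|LoF_flags"
CSQ_HEADER_LINE = (
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
    f'annotations from Ensembl VEP. Format: {CSQ_FORMAT}">'
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Rates are per (gene, sample) cell for the cohort generator.  Defaults
    describe a desk-scale cohort of 200 samples x 300 genes with rare
    knockouts; the trio generator defaults to 250 families with one planted
    compound het each.
    """

    n_samples: int = 200
    n_genes: int = 300
    min_variants_per_gene: int = 2
    max_variants_per_gene: int = 4
    fraction_hc: float = 0.8
    hom_rate: float = 0.01
    ch_rate: float = 0.01
    cis_rate: float = 0.005
    single_het_rate: float = 0.03
    lc_af_range: tuple[float, float] = (1e-4, 5e-3)
    missing_rate: float = 0.0
    # trio generator
    n_families: int = 250
    ch_per_family: int = 1
    parent_background_het_rate: float = 0.0
    genotype_error_rate: float = 0.0
    # impute2 generator
    n_variants: int = 150
    impute_af_range: tuple[float, float] = (0.05, 0.5)
    prob_noise_max: float = 0.15
    info_beta: tuple[float, float] = (1.0, 1.0)  # Beta params for INFO scores
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_hc", "hom_rate", "ch_rate", "cis_rate",
                     "single_het_rate", "missing_rate", "genotype_error_rate",
                     "parent_background_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.hom_rate + self.ch_rate + self.cis_rate + self.single_het_rate
        if total > 1.0:
            raise ValueError(f"planted rates sum to {total} > 1")
        if self.max_variants_per_gene < 2 and (self.ch_rate or self.cis_rate):
            raise ValueError(
                "compound-het / cis pairs cannot be planted in genes with "
                "fewer than 2 variants"
            )


@dataclass
class TruthTables:
    """Planted ground truth emitted alongside a synthetic data set."""

    variant_entries: pd.DataFrame            # HC variant_id x samples, int8
    gene_entries: pd.DataFrame               # gene_id x samples, int8 (-1 missing)
    mechanisms: pd.DataFrame                 # gene_id x samples, Mechanism values
    ch_events: list[CHEvent]
    gene_mechanism_labels: dict[str, str]    # hom_only / ch_only / both
    transmission_verdicts: dict = field(default_factory=dict)  # (proband, gene) -> bool
    extra: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.variant_entries.to_csv(out / "truth_variant_matrix.tsv", sep="\t")
        self.gene_entries.to_csv(out / "truth_gene_matrix.tsv", sep="\t")
        self.mechanisms.to_csv(out / "truth_mechanisms.tsv", sep="\t")
        with open(out / "truth_ch_events.tsv", "w") as fh:
            fh.write("sample_id\tgene_id\tvariant1\tvariant2\n")
            for e in self.ch_events:
                fh.write(f"{e.sample_id}\t{e.gene_id}\t"
                         f"{e.variant_pair[0]}\t{e.variant_pair[1]}\n")
        with open(out / "truth_gene_labels.tsv", "w") as fh:
            fh.write("gene_id\tlabel\n")
            for g, lab in sorted(self.gene_mechanism_labels.items()):
                fh.write(f"{g}\t{lab}\n")


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    chrom: str
    variants: list[AnnotatedVariant]
    hc_idx: list[int]        # indices into `variants` that are HC
    row_offset: int          # row of variants[0] in the global arrays


def _build_genes(cfg: SimulationConfig, rng: np.random.Generator,
                 n_genes: int) -> tuple[list[_Gene], list[dict]]:
    """Lay out genes and variants; returns genes plus per-variant metadata.

    The first two variants of every gene are forced HC so that every gene
    can host a planted pair; the remainder are HC with probability
    ``fraction_hc``.
    """
    genes: list[_Gene] = []
    var_meta: list[dict] = []
    offset = 0
    for gi in range(n_genes):
        chrom = f"chr{(gi % 22) + 1}"
        base = 1_000_000 + (gi // 22) * 500_000
        n_var = int(rng.integers(cfg.min_variants_per_gene,
                                 cfg.max_variants_per_gene + 1))
        gene_id = f"ENSG{gi + 1:011d}"
        symbol = f"GENE{gi + 1}"
        variants = []
        hc_idx = []
        for vi in range(n_var):
            pos = base + vi * 997 + int(rng.integers(0, 500))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            is_hc = vi < 2 or rng.random() < cfg.fraction_hc
            term = _HC_TERMS[int(rng.integers(0, len(_HC_TERMS)))]
            flags = "SINGLE_EXON" if is_hc and rng.random() < 0.1 else ""
            transcript = f"ENST{gi + 1:08d}{vi:03d}"
            csq = (f"{alt}|{term}|{symbol}|{gene_id}|{transcript}|"
                   f"{'HC' if is_hc else 'LC'}|{flags}")
            variants.append(
                AnnotatedVariant(chrom=chrom, pos=pos, ref=str(ref),
                                 alt=str(alt))
            )
            var_meta.append({"csq": csq, "hc": is_hc, "gene": gene_id})
            if is_hc:
                hc_idx.append(vi)
        genes.append(_Gene(gene_id, symbol, chrom, variants, hc_idx, offset))
        offset += n_var
    return genes, var_meta


def _write_cohort_vcf(path: Path, sample_ids: list[str],
                      genes: list[_Gene], var_meta: list[dict],
                      A: np.ndarray, B: np.ndarray,
                      provenance: str) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *(f"##contig=<ID=chr{c}>" for c in range(1, 23)),
        CSQ_HEADER_LINE,
        f"##lofcall_provenance={provenance}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    order = []
    for g in genes:
        for vi, v in enumerate(g.variants):
            order.append((v.sort_key, g.row_offset + vi, v))
    order.sort(key=lambda t: t[0])
    for _, row, v in order:
        gts = []
        for s in range(A.shape[1]):
            if A[row, s] < 0:
                gts.append("./.")
            else:
                gts.append(f"{A[row, s]}|{B[row, s]}")
        lines.append("\t".join(
            [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", ".",
             f"CSQ={var_meta[row]['csq']}", "GT"] + gts
        ))
    path.write_text("\n".join(lines) + "\n")


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, TruthTables]:
    """Generate a phased, annotated cohort VCF with planted knockouts.

    Planted configurations (homozygous knockout, trans compound-het pair,
    cis het pair, single het) are realised at exactly
    ``round(rate * n_genes * n_samples)`` cells each, one scenario per
    (gene, sample) cell.  Low-confidence (LC) variants additionally carry
    random rare het alleles that a correct pipeline must ignore.  Returns
    the VCF path and the :class:`TruthTables`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    genes, var_meta = _build_genes(cfg, rng, cfg.n_genes)
    n_var_total = sum(len(g.variants) for g in genes)
    A = np.zeros((n_var_total, cfg.n_samples), dtype=np.int8)
    B = np.zeros_like(A)

    n_cells = cfg.n_genes * cfg.n_samples
    counts = {
        "hom": round(cfg.hom_rate * n_cells),
        "ch": round(cfg.ch_rate * n_cells),
        "cis": round(cfg.cis_rate * n_cells),
        "het": round(cfg.single_het_rate * n_cells),
    }
    cells = rng.permutation(n_cells)[: sum(counts.values())]
    scenarios: dict[tuple[int, int], str] = {}
    pos = 0
    for name in ("hom", "ch", "cis", "het"):
        for c in cells[pos: pos + counts[name]]:
            scenarios[(int(c) // cfg.n_samples, int(c) % cfg.n_samples)] = name
        pos += counts[name]

    gene_truth = np.zeros((cfg.n_genes, cfg.n_samples), dtype=np.int8)
    mech_truth = np.full((cfg.n_genes, cfg.n_samples), Mechanism.NONE.value,
                         dtype=object)
    ch_events: list[CHEvent] = []
    planted_rows: set[tuple[int, int]] = set()  # (variant_row, sample)

    for (gi, s), scen in sorted(scenarios.items()):
        g = genes[gi]
        if scen == "hom":
            vi = int(rng.choice(g.hc_idx))
            row = g.row_offset + vi
            A[row, s] = B[row, s] = 1
            planted_rows.add((row, s))
            gene_truth[gi, s] = 2
            mech_truth[gi, s] = Mechanism.HOMOZYGOUS.value
        elif scen in ("ch", "cis"):
            vi, vj = sorted(int(x) for x in
                            rng.choice(g.hc_idx, size=2, replace=False))
            ri, rj = g.row_offset + vi, g.row_offset + vj
            if scen == "ch":
                flip = bool(rng.integers(0, 2))
                hap_i, hap_j = ("B", "A") if flip else ("A", "B")
                (A if hap_i == "A" else B)[ri, s] = 1
                (A if hap_j == "A" else B)[rj, s] = 1
                gene_truth[gi, s] = 2
                mech_truth[gi, s] = Mechanism.COMPOUND_HET.value
                vi_var, vj_var = g.variants[vi], g.variants[vj]
                ch_events.append(CHEvent(
                    sample_id=sample_ids[s], gene_id=g.gene_id,
                    variant_pair=(vi_var.variant_id, vj_var.variant_id),
                    haplotype_assignment=(hap_i, hap_j),
                ))
            else:
                hap = A if rng.integers(0, 2) == 0 else B
                hap[ri, s] = hap[rj, s] = 1
                gene_truth[gi, s] = 1
                mech_truth[gi, s] = Mechanism.MULTI_CIS.value
            planted_rows.update([(ri, s), (rj, s)])
        else:  # single het
            vi = int(rng.choice(g.hc_idx))
            row = g.row_offset + vi
            hap = A if rng.integers(0, 2) == 0 else B
            hap[row, s] = 1
            planted_rows.add((row, s))
            gene_truth[gi, s] = 1
            mech_truth[gi, s] = Mechanism.SINGLE_HET.value

    # rare background carriers on LC variants only (never affect HC truth)
    for g in genes:
        for vi in range(len(g.variants)):
            if vi in g.hc_idx:
                continue
            row = g.row_offset + vi
            af = float(np.exp(rng.uniform(np.log(cfg.lc_af_range[0]),
                                          np.log(cfg.lc_af_range[1]))))
            carriers = np.flatnonzero(rng.random(cfg.n_samples) < 2 * af)
            for s in carriers:
                (A if rng.integers(0, 2) == 0 else B)[row, s] = 1

    # missingness: applied only to alt-free HC calls, so planted scenarios
    # survive; a gene entry goes missing iff all its HC calls are masked
    if cfg.missing_rate > 0:
        hc_rows_by_gene = {
            gi: [genes[gi].row_offset + vi for vi in genes[gi].hc_idx]
            for gi in range(cfg.n_genes)
        }
        for gi, rows in hc_rows_by_gene.items():
            for row in rows:
                for s in np.flatnonzero(rng.random(cfg.n_samples)
                                        < cfg.missing_rate):
                    s = int(s)
                    if (row, s) in planted_rows:
                        continue
                    A[row, s] = B[row, s] = -1
        for gi, rows in hc_rows_by_gene.items():
            for s in range(cfg.n_samples):
                if all(A[r, s] < 0 for r in rows):
                    gene_truth[gi, s] = -1
                    mech_truth[gi, s] = Mechanism.MISSING.value

    vcf_path = out / "cohort.vcf"
    _write_cohort_vcf(vcf_path, sample_ids, genes, var_meta, A, B,
                      provenance=f"synthetic cohort seed={cfg.seed}")

    hc_rows, hc_ids = [], []
    for g in genes:
        for vi in g.hc_idx:
            hc_rows.append(g.row_offset + vi)
            hc_ids.append(g.variants[vi].variant_id)
    Z = ((A[hc_rows] == 1).astype(np.int8) + (B[hc_rows] == 1).astype(np.int8))
    Z[A[hc_rows] == -1] = -1

    labels: dict[str, str] = {}
    for gi, g in enumerate(genes):
        mechs = {m for m in mech_truth[gi]
                 if m in (Mechanism.HOMOZYGOUS.value,
                          Mechanism.COMPOUND_HET.value)}
        if mechs == {Mechanism.HOMOZYGOUS.value}:
            labels[g.gene_id] = "hom_only"
        elif mechs == {Mechanism.COMPOUND_HET.value}:
            labels[g.gene_id] = "ch_only"
        elif mechs:
            labels[g.gene_id] = "both"

    ch_events.sort(key=lambda e: (e.gene_id, e.sample_id))
    truth = TruthTables(
        variant_entries=pd.DataFrame(Z, index=hc_ids, columns=sample_ids),
        gene_entries=pd.DataFrame(
            gene_truth, index=[g.gene_id for g in genes], columns=sample_ids
        ),
        mechanisms=pd.DataFrame(
            mech_truth, index=[g.gene_id for g in genes], columns=sample_ids
        ),
        ch_events=ch_events,
        gene_mechanism_labels=labels,
    )
    truth.write(out)
    return vcf_path, truth


def generate_trios(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, TruthTables]:
    """Generate Mendelian trio families with planted compound hets.

    Each family contributes father, mother and offspring; the offspring's
    haplotype A is a copy of one paternal haplotype and haplotype B of one
    maternal haplotype, chosen per gene with no recombination within a
    gene.  A planted compound het gives the father one LoF allele and the
    mother a LoF allele of a *different* variant in the same gene, both on
    the transmitted haplotypes.  Parental genotype errors (allele flips at
    ``genotype_error_rate``) are injected after transmission, so they can
    break the observed parental carrier status but never the offspring's.

    Returns (vcf_path, pedigree_path, truth).
    """
    from .trios import Trio, write_pedigree

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_genes = max(cfg.n_genes, 1)
    genes, var_meta = _build_genes(cfg, rng, n_genes)
    n_var_total = sum(len(g.variants) for g in genes)

    sample_ids: list[str] = []
    trios: list[Trio] = []
    for f in range(cfg.n_families):
        fam = f"F{f + 1:04d}"
        sample_ids += [f"{fam}_fa", f"{fam}_mo", f"{fam}_ch"]
        trios.append(Trio(proband_id=f"{fam}_ch", father_id=f"{fam}_fa",
                          mother_id=f"{fam}_mo"))
    n_samples = len(sample_ids)
    A = np.zeros((n_var_total, n_samples), dtype=np.int8)
    B = np.zeros_like(A)

    ch_events: list[CHEvent] = []
    verdicts: dict[tuple[str, str], bool] = {}
    for f in range(cfg.n_families):
        fa, mo, ch = 3 * f, 3 * f + 1, 3 * f + 2
        # background parental hets (optional; off under the error-free design)
        if cfg.parent_background_het_rate > 0:
            for g in genes:
                for vi in g.hc_idx:
                    row = g.row_offset + vi
                    for p in (fa, mo):
                        if rng.random() < cfg.parent_background_het_rate:
                            (A if rng.integers(0, 2) == 0 else B)[row, p] = 1

        chosen = rng.choice(len(genes), size=cfg.ch_per_family, replace=False)
        planted = set()
        for gi in chosen:
            g = genes[int(gi)]
            vi, vj = sorted(int(x) for x in
                            rng.choice(g.hc_idx, size=2, replace=False))
            ri, rj = g.row_offset + vi, g.row_offset + vj
            # father donates variant i, mother donates variant j,
            # both on their haplotype A, which is the transmitted one
            A[ri, fa] = 1
            A[rj, mo] = 1
            planted.add(int(gi))
            vi_var, vj_var = g.variants[vi], g.variants[vj]
            ch_events.append(CHEvent(
                sample_id=sample_ids[ch], gene_id=g.gene_id,
                variant_pair=(vi_var.variant_id, vj_var.variant_id),
                haplotype_assignment=("A", "B"),
            ))
            verdicts[(sample_ids[ch], g.gene_id)] = True
        # transmission: per gene pick the transmitted parental haplotype;
        # planted genes always transmit haplotype A (the carrier one)
        for gi2, g in enumerate(genes):
            rows = slice(g.row_offset, g.row_offset + len(g.variants))
            if gi2 in planted:
                pa_hap, ma_hap = A, A
            else:
                pa_hap = A if rng.integers(0, 2) == 0 else B
                ma_hap = A if rng.integers(0, 2) == 0 else B
            A[rows, ch] = pa_hap[rows, fa]
            B[rows, ch] = ma_hap[rows, mo]

    if cfg.genotype_error_rate > 0:
        # a corrupted parental call is replaced by a random rare genotype
        # (each allele Bernoulli(0.05)), so errors can both erase a true
        # carrier and fabricate a spurious one
        parent_cols = [i for i in range(n_samples) if i % 3 != 2]
        shape = (n_var_total, len(parent_cols))
        bad = rng.random(shape) < cfg.genotype_error_rate
        rand_a = (rng.random(shape) < 0.05).astype(np.int8)
        rand_b = (rng.random(shape) < 0.05).astype(np.int8)
        A[:, parent_cols] = np.where(bad, rand_a, A[:, parent_cols])
        B[:, parent_cols] = np.where(bad, rand_b, B[:, parent_cols])

    vcf_path = out / "trios.vcf"
    _write_cohort_vcf(vcf_path, sample_ids, genes, var_meta, A, B,
                      provenance=f"synthetic trios seed={cfg.seed}")
    ped_path = write_pedigree(trios, out / "trios.ped")

    ch_events.sort(key=lambda e: (e.gene_id, e.sample_id))
    empty = pd.DataFrame(index=[], columns=sample_ids)
    truth = TruthTables(
        variant_entries=empty,
        gene_entries=pd.DataFrame(index=[], columns=sample_ids),
        mechanisms=pd.DataFrame(index=[], columns=sample_ids),
        ch_events=ch_events,
        gene_mechanism_labels={},
        transmission_verdicts=verdicts,
    )
    with open(out / "truth_ch_events.tsv", "w") as fh:
        fh.write("sample_id\tgene_id\tvariant1\tvariant2\n")
        for e in ch_events:
            fh.write(f"{e.sample_id}\t{e.gene_id}\t"
                     f"{e.variant_pair[0]}\t{e.variant_pair[1]}\n")
    return vcf_path, ped_path, truth


def generate_impute2(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], TruthTables]:
    """Generate an IMPUTE2 chunk (.gen/.haps/.sample/info) with truth.

    Haplotypes are drawn per variant at an allele frequency from
    ``impute_af_range``; each genotype-probability triple puts
    ``1 - noise`` on the true genotype (noise uniform on
    ``[0, prob_noise_max]``, split 70/30 over the other genotypes so ties
    cannot occur), and INFO scores are drawn Beta(*info_beta*).  The truth
    records the exact probabilities, haplotypes and INFO scores so any
    threshold grid can be recounted independently.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n_v, n_s = cfg.n_variants, cfg.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n_s)]
    keys = []
    for i in range(n_v):
        chrom = f"chr{(i % 22) + 1}"
        pos = 2_000_000 + i * 1337
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        keys.append((chrom, pos, str(ref), str(alt)))

    afs = rng.uniform(*cfg.impute_af_range, size=n_v)
    hap_a = (rng.random((n_v, n_s)) < afs[:, None]).astype(np.int8)
    hap_b = (rng.random((n_v, n_s)) < afs[:, None]).astype(np.int8)
    true_gt = hap_a + hap_b

    noise = rng.uniform(0.0, cfg.prob_noise_max, size=(n_v, n_s))
    probs = np.empty((n_v, n_s, 3))
    others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    for g, (o1, o2) in others.items():
        m = true_gt == g
        probs[m, g] = 1.0 - noise[m]
        probs[m, o1] = 0.7 * noise[m]
        probs[m, o2] = 0.3 * noise[m]
    # truth must carry exactly what the files carry: 4-decimal precision
    probs = probs.round(4)
    info = rng.beta(*cfg.info_beta, size=n_v).round(4)

    paths = {
        "gen": out / "chunk.gen",
        "haps": out / "chunk.haps",
        "sample": out / "chunk.sample",
        "info": out / "chunk_info.txt",
    }
    gen_lines, haps_lines, info_lines = [], [], ["snp_id rs_id position info"]
    for i, (chrom, pos, ref, alt) in enumerate(keys):
        rsid = f"{chrom}_{pos}_{ref}_{alt}"
        head = f"{chrom} {rsid} {pos} {ref} {alt}"
        trip = " ".join(
            f"{probs[i, s, g]:.4f}" for s in range(n_s) for g in range(3)
        )
        gen_lines.append(f"{head} {trip}")
        hap = " ".join(
            f"{hap_a[i, s]} {hap_b[i, s]}" for s in range(n_s)
        )
        haps_lines.append(f"{head} {hap}")
        info_lines.append(f"{i + 1} {rsid} {pos} {info[i]:.4f}")
    paths["gen"].write_text("\n".join(gen_lines) + "\n")
    paths["haps"].write_text("\n".join(haps_lines) + "\n")
    paths["info"].write_text("\n".join(info_lines) + "\n")
    sample_lines = ["ID_1 ID_2 missing", "0 0 0"] + [
        f"{s} {s} 0" for s in sample_ids
    ]
    paths["sample"].write_text("\n".join(sample_lines) + "\n")

    empty = pd.DataFrame(index=[], columns=sample_ids)
    truth = TruthTables(
        variant_entries=empty,
        gene_entries=pd.DataFrame(index=[], columns=sample_ids),
        mechanisms=pd.DataFrame(index=[], columns=sample_ids),
        ch_events=[],
        gene_mechanism_labels={},
        extra={
            "keys": keys,
            "probs": probs,
            "hap_a": hap_a,
            "hap_b": hap_b,
            "info_scores": info,
            "true_gt": true_gt,
            "sample_ids": sample_ids,
        },
    )
    return paths, truth
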