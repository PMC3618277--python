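"""Gene-level cohort analyses: LoF burden, knockouts, density ranking,
array concordance."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotation import (
    CohortAnnotation,
    FRAMESHIFT,
    MISSENSE,
    NONSENSE,
    NONSTOP,
    TranscriptModel,
)
from .variants import HEMIZYGOUS, HOMOZYGOUS, SNP

logger = logging.getLogger(__name__)

_KNOCKOUT_ZYGOSITIES = (HOMOZYGOUS, HEMIZYGOUS)


def lof_burden(
    annotation: CohortAnnotation,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-genome LoF counts (total, homozygous incl. hemizygous) + means."""
    rows = []
    for callset in annotation.cohort:
        total = hom = 0
        for call in callset.calls:
            if annotation[call.variant.key].is_lof:
                total += 1
                if call.zygosity in _KNOCKOUT_ZYGOSITIES:
                    hom += 1
        rows.append(
            {
                "individual_id": callset.individual_id,
                "total_lof": total,
                "homozygous_lof": hom,
            }
        )
    df = pd.DataFrame(rows)
    means = {
        "total_lof": float(df["total_lof"].mean()),
        "homozygous_lof": float(df["homozygous_lof"].mean()),
    }
    return df, means


@dataclass
class KnockoutReport:
    """Genes carrying homozygous/hemizygous LoF variants across a cohort.

    ``gene_counts`` maps gene_id -> number of genomes in which the gene is
    knocked out (>=1 hom/hemi LoF variant affecting it); genes never knocked
    out are omitted.  ``histogram`` counts genes per occurrence level.
    """

    gene_counts: dict[str, int]
    histogram: dict[int, int]
    n_genomes: int
    per_genome_lof: pd.DataFrame

    def genes_above(self, fraction: float = 0.30) -> list[str]:
        """Genes knocked out in more than ``fraction`` of the cohort."""
        cutoff = fraction * self.n_genomes
        return sorted(g for g, n in self.gene_counts.items() if n > cutoff)


def knockout_spectrum(annotation: CohortAnnotation) -> KnockoutReport:
    """Which genes are fully 'knocked out', and in how many genomes.

    A gene is knocked out in a genome iff that genome carries at least one
    LoF variant for the gene in homozygous or hemizygous state; compound
    heterozygotes do not count.
    """
    gene_counts: Counter[str] = Counter()
    for callset in annotation.cohort:
        ko_genes: set[str] = set()
        for call in callset.calls:
            if call.zygosity not in _KNOCKOUT_ZYGOSITIES:
                continue
            ko_genes.update(annotation[call.variant.key].lof_genes())
        gene_counts.update(ko_genes)
    histogram = Counter(gene_counts.values())
    burden_df, _ = lof_burden(annotation)
    return KnockoutReport(
        dict(gene_counts),
        dict(sorted(histogram.items())),
        len(annotation.cohort),
        burden_df,
    )


def _is_deleterious(vtype: str, effect: str) -> bool:
    # amino-acid changing: non-synonymous SNPs, frameshift indels/blocks
    if vtype == SNP:
        return effect in (MISSENSE, NONSENSE, NONSTOP)
    return effect == FRAMESHIFT


def rank_genes_by_deleterious_density(
    annotation: CohortAnnotation,
    transcripts: Iterable[TranscriptModel] | None = None,
) -> pd.DataFrame:
    """Rank genes by deleterious-variant density over summed CDS length.

    Sort keys, all descending: density, deleterious count, CDS length sum;
    residual ties break lexicographically by gene_id.  Genes with zero CDS
    length are excluded with a warning.
    """
    if transcripts is None:
        transcripts = annotation.index.transcripts
    cds_length: dict[str, int] = {}
    for t in transcripts:
        cds_length[t.gene_id] = cds_length.get(t.gene_id, 0) + t.cds_length

    counts: Counter[str] = Counter()
    for ann in annotation.variants.values():
        for gene_id, eff in ann.gene_effects.items():
            if _is_deleterious(ann.variant.vtype, eff.coding_effect):
                counts[gene_id] += 1

    rows = []
    for gene_id, length in cds_length.items():
        if length <= 0:
            logger.warning("gene %s has zero CDS length; excluded", gene_id)
            continue
        n = counts.get(gene_id, 0)
        rows.append(
            {
                "gene_id": gene_id,
                "deleterious_count": n,
                "cds_length_sum": length,
                "density": n / length,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "deleterious_count", "cds_length_sum", "density"]
    )
    return df.sort_values(
        ["density", "deleterious_count", "cds_length_sum", "gene_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class ConcordanceReport:
    call_rate: float
    concordance_hom: float
    concordance_het: float
    n_sites: int
    n_called: int
    n_excluded: int


def array_concordance(
    seq_genotypes: Mapping[tuple[str, int], tuple[str, str] | None],
    array_genotypes: pd.DataFrame,
) -> ConcordanceReport:
    """Concordance between sequencing genotypes and array genotypes.

    ``seq_genotypes`` maps (contig, 0-based position) to the sequencing
    genotype as an allele pair, or is missing/None for uncalled sites.
    ``array_genotypes`` needs columns contig, pos, ref, alt and genotype
    ("A/G"-style).  Array sites whose alleles are not drawn from {ref, alt}
    (e.g. strand flips) are excluded and counted in ``n_excluded``.
    Concordance is stratified by array zygosity; the call rate is the
    fraction of valid array sites with a sequencing genotype.
    """
    n_valid = n_called = n_excluded = 0
    agree = {"hom": 0, "het": 0}
    seen = {"hom": 0, "het": 0}
    for row in array_genotypes.itertuples(index=False):
        alleles = tuple(str(row.genotype).split("/"))
        if len(alleles) != 2 or not set(alleles) <= {row.ref, row.alt}:
            n_excluded += 1
            logger.warning(
                "array site %s:%s genotype %s incompatible with %s/%s; excluded",
                row.contig, row.pos, row.genotype, row.ref, row.alt,
            )
            continue
        n_valid += 1
        seq = seq_genotypes.get((row.contig, int(row.pos)))
        if seq is None:
            continue
        n_called += 1
        stratum = "hom" if alleles[0] == alleles[1] else "het"
        seen[stratum] += 1
        if sorted(seq) == sorted(alleles):
            agree[stratum] += 1
    return ConcordanceReport(
        call_rate=n_called / n_valid if n_valid else float("nan"),
        concordance_hom=agree["hom"] / seen["hom"] if seen["hom"] else float("nan"),
        concordance_het=agree["het"] / seen["het"] if seen["het"] else float("nan"),
        n_sites=n_valid,
        n_called=n_called,
        n_excluded=n_excluded,
    )


def plot_knockout_histogram(report: KnockoutReport, path: str) -> None:
    """Bar chart of the knockout occurrence spectrum (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    occ = sorted(report.histogram)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(occ, [report.histogram[k] for k in occ], color="#4878a8")
    ax.set_xlabel(f"knock-out occurrence among {report.n_genomes} genomes")
    ax.set_ylabel("number of genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
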