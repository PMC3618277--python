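"""Transcript-model functional annotation.

Variants are classified into a single region class under the hierarchy

    cds > utr > splice sites > intron > intergenic

taking the highest class achieved over all overlapping transcripts, so each
variant is counted exactly once in summary tables.  Coding effects are
predicted codon-wise for length-conserving variants and by the 3n rule for
length-changing ones.  Loss-of-function (LoF) variants are stop gains/losses,
frameshifts, and splice-site disruptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property, lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .variants import (
    BLOCK_SUBSTITUTION,
    SNP,
    GenomeCallset,
    VariantCall,
    _fetch,
    reverse_complement,
)

logger = logging.getLogger(__name__)

# region classes, ordered by hierarchy priority
CDS = "cds"
UTR = "utr"
SPLICE_DONOR = "splice_donor"
SPLICE_ACCEPTOR = "splice_acceptor"
INTRON = "intron"
INTERGENIC = "intergenic"

REGION_PRIORITY = {
    INTERGENIC: 0,
    INTRON: 1,
    SPLICE_ACCEPTOR: 2,
    SPLICE_DONOR: 2,
    UTR: 3,
    CDS: 4,
}

# coding effects
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
NONSTOP = "nonstop"
FRAMESHIFT = "frameshift"
FRAMESHIFT_PRESERVING = "frameshift_preserving"
NO_EFFECT = "none"

EFFECT_PRIORITY = {
    NO_EFFECT: 0,
    SYNONYMOUS: 1,
    FRAMESHIFT_PRESERVING: 2,
    MISSENSE: 3,
    FRAMESHIFT: 4,
    NONSTOP: 5,
    NONSENSE: 6,
}

LOF_EFFECTS = frozenset({NONSENSE, NONSTOP, FRAMESHIFT})
SPLICE_REGIONS = frozenset({SPLICE_DONOR, SPLICE_ACCEPTOR})


@lru_cache(maxsize=None)
def _codon_table(table_id: int) -> tuple[dict, frozenset]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid for a codon; ``*`` for stop, ``X`` if partial."""
    if len(codon) != 3:
        return "X"
    forward, stops = _codon_table(table_id)
    if codon in stops:
        return "*"
    return forward[codon]


@dataclass
class TranscriptModel:
    """A gene/transcript: strand, exon structure, CDS span and splice sites.

    ``exons`` are 0-based half-open intervals on the genome; ``cds_start``/
    ``cds_end`` delimit the translated span within the exons.  Splice donor/
    acceptor sites are the first/last two intronic bases of each intron,
    oriented by strand.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"empty exon interval [{s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        self.exons = exons
        if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
            raise ValueError("CDS span outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @cached_property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @cached_property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return tuple(out)

    @cached_property
    def utr_intervals(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            if s < self.cds_start:
                out.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                out.append((max(s, self.cds_end), e))
        return tuple(out)

    @cached_property
    def utr5_intervals(self) -> tuple[tuple[int, int], ...]:
        left = tuple(iv for iv in self.utr_intervals if iv[1] <= self.cds_start)
        right = tuple(iv for iv in self.utr_intervals if iv[0] >= self.cds_end)
        return left if self.strand == "+" else right

    @cached_property
    def utr3_intervals(self) -> tuple[tuple[int, int], ...]:
        left = tuple(iv for iv in self.utr_intervals if iv[1] <= self.cds_start)
        right = tuple(iv for iv in self.utr_intervals if iv[0] >= self.cds_end)
        return right if self.strand == "+" else left

    @cached_property
    def splice_donors(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.introns:
            width = min(2, e - s)
            if self.strand == "+":
                out.append((s, s + width))
            else:
                out.append((e - width, e))
        return tuple(out)

    @cached_property
    def splice_acceptors(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.introns:
            width = min(2, e - s)
            if self.strand == "+":
                out.append((e - width, e))
            else:
                out.append((s, s + width))
        return tuple(out)

    @cached_property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_sequence(self, reference) -> str:
        seq = "".join(
            _fetch(reference, self.contig, s, e) for s, e in self.cds_intervals
        )
        return reverse_complement(seq) if self.strand == "-" else seq

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic offset to a 0-based index into the spliced CDS
        (transcript orientation); ``None`` when outside the CDS."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                idx = offset + (pos - s)
                if self.strand == "-":
                    return self.cds_length - 1 - idx
                return idx
            offset += e - s
        return None

    def cds_to_genomic(self, index: int) -> int:
        """Inverse of :meth:`genomic_to_cds`."""
        if not 0 <= index < self.cds_length:
            raise IndexError(f"CDS index {index} out of range")
        if self.strand == "-":
            index = self.cds_length - 1 - index
        offset = 0
        for s, e in self.cds_intervals:
            if index < offset + (e - s):
                return s + (index - offset)
            offset += e - s
        raise AssertionError("unreachable")


class TranscriptIndex:
    """Interval lookup of transcripts by contig."""

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self._by_contig: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self._by_contig.setdefault(t.contig, []).append(t)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, ts in self._by_contig.items():
            ts.sort(key=lambda t: (t.start, t.end))
            self._starts[contig] = np.array([t.start for t in ts])
            self._ends[contig] = np.array([t.end for t in ts])

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for ts in self._by_contig.values() for t in ts]

    def overlapping(self, contig: str, start: int, end: int) -> list[TranscriptModel]:
        ts = self._by_contig.get(contig)
        if not ts:
            return []
        mask = (self._starts[contig] < end) & (self._ends[contig] > start)
        return [t for t, m in zip(ts, mask) if m]


def variant_span(variant: VariantCall) -> tuple[int, int]:
    """Reference interval a variant touches for region classification.

    A pure insertion occupies a zero-length span; for classification it is
    taken to touch both flanking reference bases.
    """
    if variant.ref_allele:
        return variant.start, variant.end
    return max(variant.start - 1, 0), variant.start + 1


def _overlaps(intervals: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def region_in_transcript(variant: VariantCall, transcript: TranscriptModel) -> str:
    start, end = variant_span(variant)
    if transcript.contig != variant.contig:
        return INTERGENIC
    if _overlaps(transcript.cds_intervals, start, end):
        return CDS
    if _overlaps(transcript.utr_intervals, start, end):
        return UTR
    if _overlaps(transcript.splice_donors, start, end):
        return SPLICE_DONOR
    if _overlaps(transcript.splice_acceptors, start, end):
        return SPLICE_ACCEPTOR
    if transcript.start < end and start < transcript.end:
        return INTRON
    return INTERGENIC


def locate(
    variant: VariantCall, transcripts: TranscriptIndex | Iterable[TranscriptModel]
) -> str:
    """Hierarchy-resolved region class over all overlapping transcripts."""
    if isinstance(transcripts, TranscriptIndex):
        span = variant_span(variant)
        candidates = transcripts.overlapping(variant.contig, *span)
    else:
        candidates = list(transcripts)
    best = INTERGENIC
    for t in candidates:
        region = region_in_transcript(variant, t)
        if REGION_PRIORITY[region] > REGION_PRIORITY[best]:
            best = region
    return best


def coding_effect(
    variant: VariantCall,
    transcript: TranscriptModel,
    reference,
    *,
    table_id: int = 1,
) -> str:
    """Predicted effect of a CDS-overlapping variant on the protein.

    Length-changing variants follow the 3n rule (frameshift vs
    frameshift-preserving).  Length-conserving variants are applied to the
    spliced CDS and affected codons are compared; columns falling outside the
    CDS (boundary-spanning blocks) are ignored.
    """
    if variant.length_change != 0:
        if variant.length_change % 3 != 0:
            return FRAMESHIFT
        return FRAMESHIFT_PRESERVING

    cds = transcript.cds_sequence(reference)
    changed: list[tuple[int, str]] = []
    for i, (rb, ab) in enumerate(zip(variant.ref_allele, variant.alt_allele)):
        if rb == ab:
            continue
        idx = transcript.genomic_to_cds(variant.start + i)
        if idx is None:
            continue
        base = ab if transcript.strand == "+" else reverse_complement(ab)
        changed.append((idx, base))
    if not changed:
        return SYNONYMOUS

    mutated = list(cds)
    codons = set()
    for idx, base in changed:
        mutated[idx] = base
        codons.add(idx // 3)
    stop_gain = stop_loss = aa_change = False
    for ci in sorted(codons):
        old = translate_codon(cds[3 * ci : 3 * ci + 3], table_id)
        new = translate_codon("".join(mutated[3 * ci : 3 * ci + 3]), table_id)
        if old == new:
            continue
        if new == "*":
            stop_gain = True
        elif old == "*":
            stop_loss = True
        else:
            aa_change = True
    if stop_gain:
        return NONSENSE
    if stop_loss:
        return NONSTOP
    if aa_change:
        return MISSENSE
    return SYNONYMOUS


def is_lof(annotated: "AnnotatedVariant") -> bool:
    """LoF = stop gain/loss, frameshift, or splice-site disruption."""
    return (
        annotated.coding_effect in LOF_EFFECTS
        or annotated.region_class in SPLICE_REGIONS
    )


@dataclass(frozen=True)
class GeneEffect:
    region_class: str
    coding_effect: str

    @property
    def is_lof(self) -> bool:
        return (
            self.coding_effect in LOF_EFFECTS
            or self.region_class in SPLICE_REGIONS
        )


@dataclass
class AnnotatedVariant:
    """A variant plus its hierarchy-resolved class and coding effect.

    ``gene_effects`` keeps the strongest (region, effect) per overlapping
    gene for gene-level analyses (knockouts, density ranking); the top-level
    ``region_class``/``coding_effect`` are the single per-variant values used
    in count tables.
    """

    variant: VariantCall
    region_class: str
    coding_effect: str
    gene_effects: dict[str, GeneEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_class != CDS and self.coding_effect != NO_EFFECT:
            raise ValueError("coding effect requires region_class == cds")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.gene_effects))

    @property
    def is_lof(self) -> bool:
        return is_lof(self) or any(g.is_lof for g in self.gene_effects.values())

    def lof_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, e in self.gene_effects.items() if e.is_lof))


def annotate_variant(
    variant: VariantCall,
    index: TranscriptIndex,
    reference,
    *,
    mito_contigs: frozenset[str] = frozenset(),
) -> AnnotatedVariant:
    span = variant_span(variant)
    table_id = 2 if variant.contig in mito_contigs else 1
    region = INTERGENIC
    effect = NO_EFFECT
    gene_effects: dict[str, GeneEffect] = {}
    for t in index.overlapping(variant.contig, *span):
        t_region = region_in_transcript(variant, t)
        if t_region == INTERGENIC:
            continue
        t_effect = NO_EFFECT
        if t_region == CDS:
            t_effect = coding_effect(variant, t, reference, table_id=table_id)
            if EFFECT_PRIORITY[t_effect] > EFFECT_PRIORITY[effect]:
                effect = t_effect
        if REGION_PRIORITY[t_region] > REGION_PRIORITY[region]:
            region = t_region
        prev = gene_effects.get(t.gene_id)
        cand = GeneEffect(t_region, t_effect)
        if prev is None or (
            REGION_PRIORITY[cand.region_class],
            EFFECT_PRIORITY[cand.coding_effect],
        ) > (
            REGION_PRIORITY[prev.region_class],
            EFFECT_PRIORITY[prev.coding_effect],
        ):
            gene_effects[t.gene_id] = cand
    if region != CDS:
        effect = NO_EFFECT
    return AnnotatedVariant(variant, region, effect, gene_effects)


# ---------------------------------------------------------------------------
# cohort-level annotation and the summary count table
# ---------------------------------------------------------------------------

#: variant classes used in the summary table; insertions and deletions are
#: reported jointly as "indel"
VARIANT_CLASSES = ("snp", "indel", "block_substitution")


def variant_class(variant: VariantCall) -> str:
    if variant.vtype == SNP:
        return "snp"
    if variant.vtype == BLOCK_SUBSTITUTION:
        return "block_substitution"
    return "indel"


@dataclass
class VariantClassCounts:
    """Region/effect tallies for one variant class (one Table-style block)."""

    total: int = 0
    by_region: dict[str, int] = field(default_factory=dict)
    by_effect: dict[str, int] = field(default_factory=dict)

    @property
    def intergenic(self) -> int:
        return self.by_region.get(INTERGENIC, 0)

    @property
    def intragenic(self) -> int:
        return self.total - self.intergenic

    @property
    def coding(self) -> int:
        return self.by_region.get(CDS, 0)

    @property
    def non_synonymous(self) -> int:
        return sum(
            self.by_effect.get(e, 0) for e in (MISSENSE, NONSENSE, NONSTOP)
        )

    def coding_fraction_pct(self, ndigits: int = 2) -> float:
        """Coding share of the class, as a percentage."""
        if self.total == 0:
            raise ZeroDivisionError("no variants in class")
        return round(100.0 * self.coding / self.total, ndigits)

    def add(self, annotated: AnnotatedVariant) -> None:
        self.total += 1
        self.by_region[annotated.region_class] = (
            self.by_region.get(annotated.region_class, 0) + 1
        )
        if annotated.coding_effect != NO_EFFECT:
            self.by_effect[annotated.coding_effect] = (
                self.by_effect.get(annotated.coding_effect, 0) + 1
            )


class CohortAnnotation:
    """Distinct-variant annotations plus per-genome membership for a cohort."""

    def __init__(
        self,
        cohort: Sequence[GenomeCallset],
        transcripts: Iterable[TranscriptModel],
        reference,
        *,
        mito_contigs: Iterable[str] = (),
    ) -> None:
        self.cohort = list(cohort)
        self.index = (
            transcripts
            if isinstance(transcripts, TranscriptIndex)
            else TranscriptIndex(transcripts)
        )
        self.mito_contigs = frozenset(mito_contigs)
        self.reference = reference
        self.variants: dict[tuple, AnnotatedVariant] = {}
        for callset in self.cohort:
            for call in callset.calls:
                key = call.variant.key
                if key not in self.variants:
                    self.variants[key] = annotate_variant(
                        call.variant,
                        self.index,
                        reference,
                        mito_contigs=self.mito_contigs,
                    )

    def __getitem__(self, key: tuple) -> AnnotatedVariant:
        return self.variants[key]

    def distinct_class_counts(self) -> dict[str, VariantClassCounts]:
        counts = {cls: VariantClassCounts() for cls in VARIANT_CLASSES}
        for ann in self.variants.values():
            counts[variant_class(ann.variant)].add(ann)
        return counts

    def per_genome_class_counts(self) -> dict[str, list[VariantClassCounts]]:
        out = {cls: [] for cls in VARIANT_CLASSES}
        for callset in self.cohort:
            counts = {cls: VariantClassCounts() for cls in VARIANT_CLASSES}
            for call in callset.calls:
                ann = self.variants[call.variant.key]
                counts[variant_class(ann.variant)].add(ann)
            for cls in VARIANT_CLASSES:
                out[cls].append(counts[cls])
        return out

    def count_table(self) -> pd.DataFrame:
        """Summary table of distinct counts and per-genome means.

        Rows mirror the taxonomy: per variant class a total, the region
        breakdown, and — for coding variants — the effect breakdown.
        """
        distinct = self.distinct_class_counts()
        per_genome = self.per_genome_class_counts()
        rows = []

        def emit(cls: str, category: str, total: int, pull) -> None:
            values = [pull(c) for c in per_genome[cls]]
            rows.append(
                {
                    "variant_class": cls,
                    "category": category,
                    "total": total,
                    "mean_per_genome": float(np.mean(values)) if values else 0.0,
                }
            )

        effect_rows = {
            "snp": (SYNONYMOUS, MISSENSE, NONSENSE, NONSTOP),
            "indel": (FRAMESHIFT, FRAMESHIFT_PRESERVING),
            "block_substitution": (
                SYNONYMOUS,
                MISSENSE,
                NONSENSE,
                NONSTOP,
                FRAMESHIFT,
                FRAMESHIFT_PRESERVING,
            ),
        }
        for cls in VARIANT_CLASSES:
            d = distinct[cls]
            emit(cls, "total", d.total, lambda c: c.total)
            emit(cls, "intergenic", d.intergenic, lambda c: c.intergenic)
            emit(cls, "intragenic", d.intragenic, lambda c: c.intragenic)
            for region in (INTRON, UTR, SPLICE_ACCEPTOR, SPLICE_DONOR):
                emit(
                    cls,
                    region,
                    d.by_region.get(region, 0),
                    lambda c, r=region: c.by_region.get(r, 0),
                )
            emit(cls, "coding", d.coding, lambda c: c.coding)
            if cls == "snp":
                emit(cls, "non_synonymous", d.non_synonymous, lambda c: c.non_synonymous)
            for eff in effect_rows[cls]:
                emit(
                    cls,
                    eff,
                    d.by_effect.get(eff, 0),
                    lambda c, e=eff: c.by_effect.get(e, 0),
                )
        return pd.DataFrame(rows)


def annotate_cohort(
    cohort: Sequence[GenomeCallset],
    transcripts: Iterable[TranscriptModel],
    reference,
    *,
    mito_contigs: Iterable[str] = (),
) -> CohortAnnotation:
    """Annotate every distinct variant of a cohort against transcript models."""
    if not cohort:
        raise ValueError("empty cohort")
    contigs = {c.variant.contig for cs in cohort for c in cs.calls}
    for contig in contigs:
        try:
            _fetch(reference, contig, 0, 1)
        except KeyError as exc:
            raise ValueError(
                f"contig {contig!r} present in callsets but absent from reference"
            ) from exc
    return CohortAnnotation(
        cohort, transcripts, reference, mito_contigs=mito_contigs
    )
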