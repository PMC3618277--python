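"""Synthetic cohort generation with fully recorded ground truth.

The generator builds a small reference genome, plants non-overlapping gene
models with valid ORFs, and draws a diploid cohort of variant sites from a
configurable site-frequency spectrum.  Every emitted variant carries a truth
record — type, hierarchy-resolved region class, coding effect, per-individual
genotypes and catalog memberships — derived *by construction* (positions are
sampled from a per-base region map painted independently of the annotation
module's interval logic; coding effects come from the codons the generator
itself wrote into the reference).

A fixed seed makes every downstream byte reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import annotation as ann
from .annotation import (
    CDS,
    INTERGENIC,
    INTRON,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    UTR,
    LOF_EFFECTS,
    NO_EFFECT,
    SPLICE_REGIONS,
    TranscriptIndex,
    TranscriptModel,
    translate_codon,
    variant_class,
    variant_span,
)
from .variants import (
    BLOCK_SUBSTITUTION,
    VariantCall,
    GenomeCallset,
    build_callset,
    normalize,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: per-base region codes; numeric order equals hierarchy priority
REGION_CODES = {
    INTERGENIC: 0,
    INTRON: 1,
    SPLICE_ACCEPTOR: 2,
    SPLICE_DONOR: 3,
    UTR: 4,
    CDS: 5,
}
CODE_REGIONS = {v: k for k, v in REGION_CODES.items()}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Everything the generator needs; the seed fixes every downstream byte."""

    seed: int = 0
    n_individuals: int = 12
    contigs: dict[str, int] = field(
        default_factory=lambda: {
            "ctg1": 400_000,
            "ctg2": 250_000,
            "ctgX": 150_000,
            "ctgM": 16_000,
        }
    )
    #: contigs assembled haploid in males (X non-PAR stand-in)
    male_haploid_contigs: tuple[str, ...] = ("ctgX",)
    #: contigs haploid in everyone, annotated with the vertebrate mito code
    mito_contigs: tuple[str, ...] = ("ctgM",)
    male_fraction: float = 0.5
    gc_fraction: float = 0.41
    n_genes: int = 40
    exon_count_range: tuple[int, int] = (1, 10)
    exon_length_range: tuple[int, int] = (120, 360)
    intron_length_range: tuple[int, int] = (60, 400)
    utr_length_range: tuple[int, int] = (24, 150)
    gene_spacing_range: tuple[int, int] = (300, 3000)
    # expected segregating sites per bp
    snp_rate: float = 6e-4
    ins_rate: float = 8e-5
    del_rate: float = 8e-5
    max_indel_length: int = 6
    #: Beta(a, b) minor-allele-frequency spectrum, truncated to (0, 0.5]
    sfs_beta: tuple[float, float] = (0.2, 2.0)
    #: probability a non-coding SNP spawns an in-phase neighbour < 2 bp away
    cluster_rate: float = 0.04
    # targeted coding/splice sites (exact effect known by construction)
    n_coding_snps: dict[str, int] = field(
        default_factory=lambda: {
            "synonymous": 30,
            "missense": 30,
            "nonsense": 10,
            "nonstop": 4,
        }
    )
    n_coding_indels: dict[str, int] = field(
        default_factory=lambda: {"frameshift": 12, "frameshift_preserving": 8}
    )
    n_coding_blocks: dict[str, int] = field(
        default_factory=lambda: {"missense": 6, "synonymous": 3, "nonsense": 2}
    )
    n_splice_snps: int = 12
    #: planted LoF sites draw their MAF uniformly from this range so that
    #: homozygous knockouts actually occur in small cohorts
    lof_maf_range: tuple[float, float] = (0.05, 0.5)
    # catalog coverage as a function of MAF
    catalog_common_p: dict[str, float] = field(
        default_factory=lambda: {"A": 0.95, "B": 0.90}
    )
    catalog_rare_p: dict[str, float] = field(
        default_factory=lambda: {"A": 0.30, "B": 0.45}
    )
    common_maf_threshold: float = 0.05
    catalog_indel_jitter: int = 5

    def __post_init__(self) -> None:
        for name, p in [
            ("male_fraction", self.male_fraction),
            ("gc_fraction", self.gc_fraction),
            ("cluster_rate", self.cluster_rate),
            *[(f"catalog_common_p[{k}]", v) for k, v in self.catalog_common_p.items()],
            *[(f"catalog_rare_p[{k}]", v) for k, v in self.catalog_rare_p.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for contig, length in self.contigs.items():
            if length <= 0:
                raise ValueError(f"contig {contig!r} has non-positive length")
        if self.catalog_indel_jitter < 0 or self.catalog_indel_jitter > 25:
            raise ValueError("catalog_indel_jitter must be in [0, 25]")


@dataclass
class TruthRecord:
    """Ground truth for one emitted variant locus."""

    variant: VariantCall
    primitives: tuple[VariantCall, ...]
    region_class: str
    coding_effect: str
    gene_id: str
    maf_target: float
    genotypes: tuple[tuple[int, ...], ...]
    in_catalog_a: bool = False
    in_catalog_b: bool = False

    @property
    def is_lof(self) -> bool:
        return self.coding_effect in LOF_EFFECTS or self.region_class in SPLICE_REGIONS

    @property
    def alt_count(self) -> int:
        return sum(sum(g) for g in self.genotypes)

    @property
    def n_alleles(self) -> int:
        return sum(len(g) for g in self.genotypes)


@dataclass
class TruthSet:
    """All truth records plus the cohort roster, with tally helpers."""

    records: list[TruthRecord]
    individuals: list[tuple[str, str]]  # (individual_id, sex)
    haploid_by_individual: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.records)

    def expected_class_counts(self) -> dict[str, ann.VariantClassCounts]:
        counts = {cls: ann.VariantClassCounts() for cls in ann.VARIANT_CLASSES}
        for rec in self.records:
            c = counts[variant_class(rec.variant)]
            c.total += 1
            c.by_region[rec.region_class] = c.by_region.get(rec.region_class, 0) + 1
            if rec.coding_effect != NO_EFFECT:
                c.by_effect[rec.coding_effect] = (
                    c.by_effect.get(rec.coding_effect, 0) + 1
                )
        return counts

    def expected_per_genome_class_counts(self) -> dict[str, list[dict]]:
        """Per individual, per class: total/region/effect tallies of carried
        variants (any alt allele)."""
        out = {cls: [] for cls in ann.VARIANT_CLASSES}
        for i, _ in enumerate(self.individuals):
            counts = {
                cls: {"total": 0, "by_region": {}, "by_effect": {}}
                for cls in ann.VARIANT_CLASSES
            }
            for rec in self.records:
                if sum(rec.genotypes[i]) == 0:
                    continue
                c = counts[variant_class(rec.variant)]
                c["total"] += 1
                c["by_region"][rec.region_class] = (
                    c["by_region"].get(rec.region_class, 0) + 1
                )
                if rec.coding_effect != NO_EFFECT:
                    c["by_effect"][rec.coding_effect] = (
                        c["by_effect"].get(rec.coding_effect, 0) + 1
                    )
            for cls in ann.VARIANT_CLASSES:
                out[cls].append(counts[cls])
        return out

    def expected_lof_burden(self) -> list[tuple[str, int, int]]:
        """(individual_id, total LoF carried, homozygous/hemizygous LoF)."""
        rows = []
        for i, (ind_id, _) in enumerate(self.individuals):
            total = hom = 0
            for rec in self.records:
                g = rec.genotypes[i]
                if not rec.is_lof or sum(g) == 0:
                    continue
                total += 1
                if all(a == 1 for a in g):
                    hom += 1
            rows.append((ind_id, total, hom))
        return rows

    def expected_knockout_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i, _ in enumerate(self.individuals):
            genes = set()
            for rec in self.records:
                g = rec.genotypes[i]
                if rec.is_lof and rec.gene_id and g and all(a == 1 for a in g):
                    genes.add(rec.gene_id)
            for gene in genes:
                counts[gene] = counts.get(gene, 0) + 1
        return counts

    def realized_frequencies(self) -> dict[tuple, tuple[int, int]]:
        return {rec.variant.key: (rec.alt_count, rec.n_alleles) for rec in self.records}

    def to_frame(self):
        import pandas as pd

        rows = []
        for rec in self.records:
            v = rec.variant
            rows.append(
                {
                    "contig": v.contig,
                    "start": v.start,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "vtype": v.vtype,
                    "n_merged": v.n_merged,
                    "region_class": rec.region_class,
                    "coding_effect": rec.coding_effect,
                    "gene_id": rec.gene_id,
                    "is_lof": rec.is_lof,
                    "maf_target": rec.maf_target,
                    "in_catalog_a": rec.in_catalog_a,
                    "in_catalog_b": rec.in_catalog_b,
                    "genotypes": ";".join(
                        "|".join(str(a) for a in g) for g in rec.genotypes
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """Per-individual, per-haplotype primitive calls (pipeline input)."""

    individuals: list[tuple[str, str]]
    haplotype_calls: dict[str, dict[str, list[list[VariantCall]]]]
    haploid_by_individual: dict[str, frozenset[str]]

    def to_callsets(self, reference) -> list[GenomeCallset]:
        """Run the per-haplotype block merge and assemble genotyped callsets."""
        out = []
        for ind_id, sex in self.individuals:
            out.append(
                build_callset(
                    ind_id,
                    sex,
                    self.haplotype_calls[ind_id],
                    reference,
                    haploid_contigs=self.haploid_by_individual[ind_id],
                )
            )
        return out


# ---------------------------------------------------------------------------
# reference and transcript simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Random reference sequences at the configured GC fraction."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        contig: rng.choice(codes, size=length, p=probs).tobytes().decode("ascii")
        for contig, length in config.contigs.items()
    }


def _stop_codons(table_id: int) -> frozenset[str]:
    from Bio.Data import CodonTable

    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


def _make_gene(
    contig: str,
    gene_start: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_idx: int,
) -> TranscriptModel:
    lo, hi = config.exon_count_range
    n_ex = int(rng.integers(lo, hi + 1))
    elo, ehi = config.exon_length_range
    exon_lens = rng.integers(elo, ehi + 1, n_ex).astype(int)
    ilo, ihi = config.intron_length_range
    intron_lens = rng.integers(ilo, ihi + 1, max(n_ex - 1, 0)).astype(int)
    ulo, uhi = config.utr_length_range
    u5 = int(rng.integers(ulo, uhi + 1))
    u3 = int(rng.integers(ulo, uhi + 1))
    # terminal exons must host their UTR plus at least a few CDS bases
    if n_ex == 1:
        exon_lens[0] = max(exon_lens[0], u5 + u3 + 18)
    else:
        exon_lens[0] = max(exon_lens[0], u5 + 12)
        exon_lens[-1] = max(exon_lens[-1], u3 + 12)
    cds_len = int(exon_lens.sum()) - u5 - u3
    u3 += cds_len % 3  # force CDS length to 3n; slack reserved above
    cds_len -= cds_len % 3

    exons = []
    cursor = gene_start
    for i, length in enumerate(exon_lens):
        exons.append((cursor, cursor + int(length)))
        cursor += int(length)
        if i < n_ex - 1:
            cursor += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        cds_start, cds_end = exons[0][0] + u5, exons[-1][1] - u3
    else:
        cds_start, cds_end = exons[0][0] + u3, exons[-1][1] - u5
    return TranscriptModel(
        gene_id=f"gene{gene_idx:04d}",
        transcript_id=f"tx{gene_idx:04d}",
        contig=contig,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def simulate_transcripts(
    reference: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Plant non-overlapping gene models and write valid ORFs into the genome.

    Every CDS is a 3n sequence starting ATG, ending at a stop codon, with no
    internal stop under the contig's genetic code; minus-strand genes are
    written reverse-complemented.  Returns the transcripts and the edited
    reference.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    mito = set(config.mito_contigs)
    edited = {c: bytearray(s, "ascii") for c, s in reference.items()}
    total_len = sum(config.contigs.values())
    transcripts: list[TranscriptModel] = []
    gene_idx = 0
    for contig, length in config.contigs.items():
        target = max(1, round(config.n_genes * length / total_len))
        table_id = 2 if contig in mito else 1
        stops = _stop_codons(table_id)
        non_stop = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in stops
        ]
        slo, shi = config.gene_spacing_range
        cursor = int(rng.integers(slo, shi + 1))
        made = 0
        while made < target:
            t = _make_gene(contig, cursor, config, rng, gene_idx)
            if t.end + 50 > length:
                break
            n_codons = t.cds_length // 3
            interior = rng.choice(non_stop, size=n_codons - 2)
            cds = "ATG" + "".join(interior) + "TAA"
            genomic = cds if t.strand == "+" else reverse_complement(cds)
            offset = 0
            for s, e in t.cds_intervals:
                edited[contig][s:e] = genomic[offset : offset + (e - s)].encode()
                offset += e - s
            transcripts.append(t)
            gene_idx += 1
            made += 1
            cursor = t.end + int(rng.integers(slo, shi + 1))
    return transcripts, {c: bytes(b).decode() for c, b in edited.items()}


def build_region_maps(
    reference: Mapping[str, str], transcripts: Iterable[TranscriptModel]
) -> dict[str, np.ndarray]:
    """Per-base hierarchy-resolved region codes (independent painting route)."""
    maps = {c: np.zeros(len(s), dtype=np.int8) for c, s in reference.items()}
    for t in transcripts:
        arr = maps[t.contig]

        def paint(intervals, code):
            for s, e in intervals:
                arr[s:e] = np.maximum(arr[s:e], code)

        paint([(t.start, t.end)], REGION_CODES[INTRON])
        paint(t.splice_acceptors, REGION_CODES[SPLICE_ACCEPTOR])
        paint(t.splice_donors, REGION_CODES[SPLICE_DONOR])
        paint(t.utr_intervals, REGION_CODES[UTR])
        paint(t.cds_intervals, REGION_CODES[CDS])
    return maps


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

class _SitePlanner:
    """Places variant sites subject to spacing and region-purity constraints."""

    #: reserved margin around each site so independent sites never merge
    MARGIN = 3

    def __init__(self, reference, region_maps, index: TranscriptIndex):
        self.reference = reference
        self.region_maps = region_maps
        self.index = index
        self.occupied = {
            c: np.zeros(len(s), dtype=bool) for c, s in reference.items()
        }
        self.sites: list[dict] = []

    def span_region(self, variant: VariantCall) -> str | None:
        """Uniform region code over the variant's touched span, else None."""
        lo, hi = variant_span(variant)
        codes = self.region_maps[variant.contig][lo:hi]
        if codes.size == 0 or not (codes == codes[0]).all():
            return None
        return CODE_REGIONS[int(codes[0])]

    def is_free(self, contig: str, lo: int, hi: int) -> bool:
        lo = max(lo, 0)
        return not self.occupied[contig][lo:hi].any()

    def reserve(self, contig: str, lo: int, hi: int) -> None:
        self.occupied[contig][max(lo, 0) : hi] = True

    def gene_at(self, variant: VariantCall) -> str:
        lo, hi = variant_span(variant)
        hits = self.index.overlapping(variant.contig, lo, hi)
        return hits[0].gene_id if hits else ""

    def try_place(
        self,
        variant: VariantCall,
        primitives: Sequence[VariantCall],
        *,
        want_region: str | None = None,
        effect: str = NO_EFFECT,
        gene_id: str | None = None,
    ) -> bool:
        v = normalize(variant, self.reference)
        lo = min(v.start, variant.start) - self.MARGIN
        hi = max(v.end, variant.end) + self.MARGIN
        if v.start < 2:
            return False  # keep room for a VCF anchor base
        if not self.is_free(v.contig, lo, hi):
            return False
        region = self.span_region(v)
        if region is None:
            return False
        if want_region is not None and region != want_region:
            return False
        if v.key != variant.key:
            # normalization moved the locus; primitives must shift with it
            if len(primitives) > 1:
                return False
            primitives = [v]
        self.reserve(v.contig, lo, hi)
        self.sites.append(
            {
                "variant": v,
                "primitives": tuple(primitives),
                "region": region,
                "effect": effect,
                "gene_id": self.gene_at(v) if gene_id is None else gene_id,
            }
        )
        return True


def _classify_codon_change(old: str, new: str, table_id: int) -> str:
    old_aa, new_aa = translate_codon(old, table_id), translate_codon(new, table_id)
    if old_aa == new_aa:
        return ann.SYNONYMOUS
    if new_aa == "*":
        return ann.NONSENSE
    if old_aa == "*":
        return ann.NONSTOP
    return ann.MISSENSE


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _merge_primitives(primitives: list[VariantCall], reference) -> VariantCall:
    """Local block assembly for planted clusters (all primitives SNPs)."""
    primitives = sorted(primitives, key=lambda v: v.start)
    contig = primitives[0].contig
    start, end = primitives[0].start, primitives[-1].end
    ref = str(reference[contig][start:end])
    alt = list(ref)
    for p in primitives:
        alt[p.start - start] = p.alt_allele
    return VariantCall(
        contig, start, ref, "".join(alt),
        vtype=BLOCK_SUBSTITUTION, n_merged=len(primitives),
    )


def _plant_coding_snps(planner, transcripts, cds_seqs, config, rng, mito):
    for effect, count in config.n_coding_snps.items():
        planted = attempts = 0
        while planted < count and attempts < 2000:
            attempts += 1
            t = transcripts[int(rng.integers(len(transcripts)))]
            table_id = 2 if t.contig in mito else 1
            cds = cds_seqs[t.transcript_id]
            n_codons = len(cds) // 3
            if n_codons < 4:
                continue
            if effect == ann.NONSTOP:
                ci = n_codons - 1
            else:
                ci = int(rng.integers(1, n_codons - 1))
            col = int(rng.integers(3))
            old_codon = cds[3 * ci : 3 * ci + 3]
            found = False
            for alt_b in rng.permutation([b for b in "ACGT" if b != old_codon[col]]):
                new_codon = old_codon[:col] + alt_b + old_codon[col + 1 :]
                if _classify_codon_change(old_codon, new_codon, table_id) != effect:
                    continue
                gpos = t.cds_to_genomic(3 * ci + col)
                ref_b = str(planner.reference[t.contig][gpos])
                alt_g = alt_b if t.strand == "+" else reverse_complement(alt_b)
                v = VariantCall(t.contig, gpos, ref_b, alt_g)
                if planner.try_place(
                    v, [v], want_region=CDS, effect=effect, gene_id=t.gene_id
                ):
                    found = True
                break
            planted += int(found)
        if planted < count:
            logger.warning("planted %d/%d coding %s SNPs", planted, count, effect)


def _plant_coding_indels(planner, transcripts, config, rng):
    length_pool = {
        ann.FRAMESHIFT: [1, 2, 4, 5],
        ann.FRAMESHIFT_PRESERVING: [3, 6],
    }
    for effect, count in config.n_coding_indels.items():
        pool = [l for l in length_pool[effect] if l <= config.max_indel_length]
        planted = attempts = 0
        while planted < count and attempts < 2000:
            attempts += 1
            t = transcripts[int(rng.integers(len(transcripts)))]
            ivs = [iv for iv in t.cds_intervals if iv[1] - iv[0] >= 30]
            if not ivs:
                continue
            s, e = ivs[int(rng.integers(len(ivs)))]
            length = int(pool[int(rng.integers(len(pool)))])
            pos = int(rng.integers(s + 6, e - 6 - length))
            if rng.random() < 0.5:
                v = VariantCall(
                    t.contig, pos, str(planner.reference[t.contig][pos : pos + length]), ""
                )
            else:
                v = VariantCall(t.contig, pos, "", _random_bases(rng, length))
            planted += int(
                planner.try_place(
                    v, [v], want_region=CDS, effect=effect, gene_id=t.gene_id
                )
            )
        if planted < count:
            logger.warning("planted %d/%d coding %s indels", planted, count, effect)


def _plant_coding_blocks(planner, transcripts, cds_seqs, config, rng, mito):
    for effect, count in config.n_coding_blocks.items():
        planted = attempts = 0
        while planted < count and attempts < 4000:
            attempts += 1
            t = transcripts[int(rng.integers(len(transcripts)))]
            table_id = 2 if t.contig in mito else 1
            cds = cds_seqs[t.transcript_id]
            n_codons = len(cds) // 3
            if n_codons < 4:
                continue
            ci = int(rng.integers(1, n_codons - 1))
            old = cds[3 * ci : 3 * ci + 3]
            candidates = []
            for a in "ACGT":
                for b in "ACGT":
                    for c in "ACGT":
                        nc = a + b + c
                        hamming = sum(x != y for x, y in zip(old, nc))
                        if hamming < 2:
                            continue
                        if _classify_codon_change(old, nc, table_id) == effect:
                            candidates.append(nc)
            if not candidates:
                continue
            nc = candidates[int(rng.integers(len(candidates)))]
            cols = [i for i in range(3) if old[i] != nc[i]]
            gpos = [t.cds_to_genomic(3 * ci + i) for i in cols]
            if max(gpos) - min(gpos) != max(cols) - min(cols):
                continue  # codon spans a splice junction
            prims = []
            for i, gp in zip(cols, gpos):
                ref_b = str(planner.reference[t.contig][gp])
                alt_b = nc[i] if t.strand == "+" else reverse_complement(nc[i])
                prims.append(VariantCall(t.contig, gp, ref_b, alt_b))
            block = _merge_primitives(prims, planner.reference)
            planted += int(
                planner.try_place(
                    block, prims, want_region=CDS, effect=effect, gene_id=t.gene_id
                )
            )
        if planted < count:
            logger.warning("planted %d/%d coding %s blocks", planted, count, effect)


def _plant_splice_snps(planner, transcripts, config, rng):
    multi = [t for t in transcripts if t.introns]
    planted = attempts = 0
    while multi and planted < config.n_splice_snps and attempts < 2000:
        attempts += 1
        t = multi[int(rng.integers(len(multi)))]
        which = SPLICE_DONOR if rng.random() < 0.5 else SPLICE_ACCEPTOR
        sites = t.splice_donors if which == SPLICE_DONOR else t.splice_acceptors
        s, e = sites[int(rng.integers(len(sites)))]
        pos = int(rng.integers(s, e))
        ref_b = str(planner.reference[t.contig][pos])
        alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
        v = VariantCall(t.contig, pos, ref_b, alt_b)
        planted += int(
            planner.try_place(
                v, [v], want_region=which, effect=NO_EFFECT, gene_id=t.gene_id
            )
        )
    if planted < config.n_splice_snps:
        logger.warning("planted %d/%d splice SNPs", planted, config.n_splice_snps)


def _background_effect(planner, v, region, mito, cds_seqs):
    """Coding effect of a randomly placed variant, from the generator's own
    codon bookkeeping."""
    if region != CDS:
        return NO_EFFECT, None
    lo, hi = variant_span(v)
    t = planner.index.overlapping(v.contig, lo, hi)[0]
    if v.length_change != 0:
        eff = (
            ann.FRAMESHIFT
            if v.length_change % 3 != 0
            else ann.FRAMESHIFT_PRESERVING
        )
        return eff, t
    table_id = 2 if v.contig in mito else 1
    cds = cds_seqs[t.transcript_id]
    idx = t.genomic_to_cds(v.start)
    base = v.alt_allele if t.strand == "+" else reverse_complement(v.alt_allele)
    ci, col = divmod(idx, 3)
    old = cds[3 * ci : 3 * ci + 3]
    new = old[:col] + base + old[col + 1 :]
    return _classify_codon_change(old, new, table_id), t


def _plant_background(planner, config, rng, mito, cds_seqs):
    cluster_ok = (INTERGENIC, INTRON, UTR)
    for contig, length in config.contigs.items():
        seq = planner.reference[contig]
        for vtype, rate in (
            ("snp", config.snp_rate),
            ("ins", config.ins_rate),
            ("del", config.del_rate),
        ):
            n_sites = int(rng.poisson(rate * length))
            for _ in range(n_sites):
                for _attempt in range(60):
                    pos = int(rng.integers(10, length - 10))
                    if vtype == "snp":
                        ref_b = seq[pos]
                        alt = str(rng.choice([b for b in "ACGT" if b != ref_b]))
                        v = VariantCall(contig, pos, ref_b, alt)
                    elif vtype == "ins":
                        n = int(rng.integers(1, config.max_indel_length + 1))
                        v = VariantCall(contig, pos, "", _random_bases(rng, n))
                    else:
                        n = int(rng.integers(1, config.max_indel_length + 1))
                        if pos + n + 5 > length:
                            continue
                        v = VariantCall(contig, pos, seq[pos : pos + n], "")
                    vn = normalize(v, planner.reference)
                    region = planner.span_region(vn)
                    if region is None:
                        continue
                    effect, _t = _background_effect(
                        planner, vn, region, mito, cds_seqs
                    )
                    # in-phase neighbour to exercise block merging
                    if (
                        vtype == "snp"
                        and region in cluster_ok
                        and rng.random() < config.cluster_rate
                    ):
                        d = int(rng.integers(1, 3))  # 0 or 1 intervening base
                        pos2 = vn.start + d
                        if pos2 + 1 >= length:
                            continue
                        ref2 = seq[pos2]
                        alt2 = str(rng.choice([b for b in "ACGT" if b != ref2]))
                        prims = [vn, VariantCall(contig, pos2, ref2, alt2)]
                        block = _merge_primitives(prims, planner.reference)
                        if planner.try_place(
                            block, prims, want_region=region, effect=NO_EFFECT
                        ):
                            break
                        continue
                    if planner.try_place(vn, [vn], effect=effect):
                        break


def _draw_maf(rng: np.random.Generator, a: float, b: float) -> float:
    for _ in range(200):
        p = float(rng.beta(a, b))
        if 0.0 < p <= 0.5:
            return p
    return 0.05


def _draw_genotypes(
    rng: np.random.Generator, p: float, ploidies: Sequence[int]
) -> tuple[tuple[int, ...], ...]:
    for _ in range(50):
        g = tuple(
            tuple(int(x) for x in (rng.random(k) < p)) for k in ploidies
        )
        if any(sum(h) for h in g):
            return g
    # force one carrier so the site segregates
    g = [tuple([0] * k) for k in ploidies]
    i = int(rng.integers(len(ploidies)))
    alleles = [0] * ploidies[i]
    alleles[int(rng.integers(ploidies[i]))] = 1
    g[i] = tuple(alleles)
    return tuple(g)


def simulate_cohort(
    reference: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SimulatedCohort, TruthSet]:
    """Draw a diploid cohort with recorded truth for every variant locus.

    Genotypes follow Hardy-Weinberg at the site's drawn MAF; males are
    hemizygous on the configured contigs; clustered variants are planted in
    phase so block merging is exercised deterministically.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    mito = frozenset(config.mito_contigs)
    male_haploid = frozenset(config.male_haploid_contigs)

    n = config.n_individuals
    n_males = int(round(n * config.male_fraction))
    sex_order = rng.permutation(
        np.array(["male"] * n_males + ["female"] * (n - n_males))
    )
    individuals = [(f"I{i:03d}", str(sex_order[i])) for i in range(n)]
    haploid_by_ind = {
        ind_id: frozenset(mito | (male_haploid if sex == "male" else frozenset()))
        for ind_id, sex in individuals
    }

    index = TranscriptIndex(transcripts)
    region_maps = build_region_maps(reference, transcripts)
    planner = _SitePlanner(reference, region_maps, index)
    cds_seqs = {t.transcript_id: t.cds_sequence(reference) for t in transcripts}

    _plant_coding_snps(planner, list(transcripts), cds_seqs, config, rng, mito)
    _plant_coding_indels(planner, list(transcripts), config, rng)
    _plant_coding_blocks(planner, list(transcripts), cds_seqs, config, rng, mito)
    _plant_splice_snps(planner, list(transcripts), config, rng)
    _plant_background(planner, config, rng, mito, cds_seqs)

    a, b = config.sfs_beta
    records: list[TruthRecord] = []
    for site in sorted(
        planner.sites, key=lambda s: (s["variant"].contig, s["variant"].start)
    ):
        v = site["variant"]
        region, effect = site["region"], site["effect"]
        lof_like = effect in LOF_EFFECTS or region in SPLICE_REGIONS
        if lof_like:
            maf = float(rng.uniform(*config.lof_maf_range))
        else:
            maf = _draw_maf(rng, a, b)
        ploidies = [
            1 if v.contig in haploid_by_ind[ind_id] else 2
            for ind_id, _ in individuals
        ]
        genotypes = _draw_genotypes(rng, maf, ploidies)
        records.append(
            TruthRecord(
                variant=v,
                primitives=site["primitives"],
                region_class=region,
                coding_effect=effect,
                gene_id=site["gene_id"],
                maf_target=maf,
                genotypes=genotypes,
            )
        )

    haplotype_calls: dict[str, dict[str, list[list[VariantCall]]]] = {}
    for i, (ind_id, _sex) in enumerate(individuals):
        per_contig: dict[str, list[list[VariantCall]]] = {}
        for contig in config.contigs:
            n_hap = 1 if contig in haploid_by_ind[ind_id] else 2
            per_contig[contig] = [[] for _ in range(n_hap)]
        haplotype_calls[ind_id] = per_contig
    for rec in records:
        contig = rec.variant.contig
        for i, (ind_id, _sex) in enumerate(individuals):
            for hap, allele in enumerate(rec.genotypes[i]):
                if allele:
                    haplotype_calls[ind_id][contig][hap].extend(rec.primitives)
    for per_contig in haplotype_calls.values():
        for haps in per_contig.values():
            for h in haps:
                h.sort(key=lambda v: v.start)

    cohort = SimulatedCohort(individuals, haplotype_calls, haploid_by_ind)
    truth = TruthSet(records, individuals, haploid_by_ind)
    return cohort, truth


def simulate_catalogs(
    truth: TruthSet,
    reference: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partial catalogs A and B: common variants mostly present, rare often
    absent.  Catalog indels are position-jittered to exercise windowed
    matching.  Membership flags are written back into the truth records."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    catalogs: dict[str, list[VariantCall]] = {"A": [], "B": []}
    jitter = config.catalog_indel_jitter
    for rec in truth.records:
        p_alt = rec.alt_count / rec.n_alleles
        maf = min(p_alt, 1.0 - p_alt)
        common = maf > config.common_maf_threshold
        for name in ("A", "B"):
            p_in = (
                config.catalog_common_p[name]
                if common
                else config.catalog_rare_p[name]
            )
            if rng.random() >= p_in:
                continue
            v = rec.variant
            if v.is_indel and jitter > 0:
                shift = int(rng.integers(-jitter, jitter + 1))
                start = max(2, v.start + shift)
                if v.ref_allele:  # deletion: re-anchor ref at shifted locus
                    seq = reference[v.contig]
                    if start + len(v.ref_allele) >= len(seq):
                        start = v.start
                    ref = str(seq[start : start + len(v.ref_allele)])
                    entry = VariantCall(v.contig, start, ref, "", vtype=v.vtype)
                else:
                    entry = VariantCall(v.contig, start, "", v.alt_allele, vtype=v.vtype)
                entry = normalize(entry, reference)
            else:
                entry = v
            catalogs[name].append(entry)
            if name == "A":
                rec.in_catalog_a = True
            else:
                rec.in_catalog_b = True
    return catalogs["A"], catalogs["B"]


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    cohort: SimulatedCohort
    truth: TruthSet
    catalog_a: list[VariantCall]
    catalog_b: list[VariantCall]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator from one master seed."""
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    reference = simulate_reference(config, streams[0])
    transcripts, reference = simulate_transcripts(reference, config, streams[1])
    cohort, truth = simulate_cohort(reference, transcripts, config, streams[2])
    catalog_a, catalog_b = simulate_catalogs(truth, reference, config, streams[3])
    return SimulationResult(
        config, reference, transcripts, cohort, truth, catalog_a, catalog_b
    )
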