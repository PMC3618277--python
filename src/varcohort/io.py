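"""Standard-format I/O: FASTA, GFF3, VCF v4.2, TSV.

Internal coordinates are 0-based half-open; these functions convert to and
from the 1-based conventions of GFF3 and VCF.  Block substitutions are
written as multi-base REF/ALT records with an INFO key ``BLOCK`` giving the
number of merged primitive variants.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .annotation import TranscriptModel
from .variants import BLOCK_SUBSTITUTION, VariantCall, normalize

# --------------------------------------------------------------------------
# FASTA / genome files
# --------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_genome_file(contig_lengths: Mapping[str, int], path: str) -> None:
    """samtools-style two-column contig/length text file."""
    with open(path, "w") as fh:
        for contig, length in contig_lengths.items():
            fh.write(f"{contig}\t{length}\n")


def read_genome_file(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, length = line.split()[:2]
            out[contig] = int(length)
    return out


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def write_gff3(transcripts: Iterable[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs_gene = f"ID={t.gene_id};gene_id={t.gene_id}"
            attrs_tx = (
                f"ID={t.transcript_id};Parent={t.gene_id};"
                f"gene_id={t.gene_id};transcript_id={t.transcript_id}"
            )
            rows = [
                (t.contig, "varcohort", "gene", t.start + 1, t.end, t.strand, ".", attrs_gene),
                (t.contig, "varcohort", "mRNA", t.start + 1, t.end, t.strand, ".", attrs_tx),
            ]
            for s, e in t.exons:
                rows.append(
                    (t.contig, "varcohort", "exon", s + 1, e, t.strand, ".",
                     f"Parent={t.transcript_id}")
                )
            cds_ivs = list(t.cds_intervals)
            if t.strand == "-":
                cds_ivs = cds_ivs[::-1]  # translation order
            cum = 0
            for s, e in cds_ivs:
                phase = (3 - cum % 3) % 3
                rows.append(
                    (t.contig, "varcohort", "CDS", s + 1, e, t.strand, str(phase),
                     f"Parent={t.transcript_id}")
                )
                cum += e - s
            for s, e in t.utr5_intervals:
                rows.append(
                    (t.contig, "varcohort", "five_prime_UTR", s + 1, e, t.strand,
                     ".", f"Parent={t.transcript_id}")
                )
            for s, e in t.utr3_intervals:
                rows.append(
                    (t.contig, "varcohort", "three_prime_UTR", s + 1, e, t.strand,
                     ".", f"Parent={t.transcript_id}")
                )
            rows.sort(key=lambda r: (r[3], r[2]))
            for contig, source, ftype, start, end, strand, phase, attrs in rows:
                fh.write(
                    f"{contig}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t"
                    f"{phase}\t{attrs}\n"
                )


def read_gff3(path: str) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
        )
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds:
            continue
        transcripts.append(
            TranscriptModel(
                gene_id=mrna.attributes.get("gene_id", [mrna.id])[0],
                transcript_id=mrna.attributes.get("transcript_id", [mrna.id])[0],
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
        )
    transcripts.sort(key=lambda t: (t.contig, t.start, t.transcript_id))
    return transcripts


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def _vcf_header(
    contig_lengths: Mapping[str, int], samples: Sequence[str] = ()
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line(
        '##INFO=<ID=BLOCK,Number=1,Type=Integer,'
        'Description="Number of primitive variants merged into this record">'
    )
    if samples:
        header.add_line(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
        for sample in samples:
            header.add_sample(sample)
    return header


def _vcf_alleles(v: VariantCall, reference) -> tuple[int, str, str]:
    """1-anchor-base conversion for records with an empty allele."""
    if v.ref_allele and v.alt_allele:
        return v.start, v.ref_allele, v.alt_allele
    if v.start == 0:
        raise ValueError(f"cannot anchor variant at contig start: {v}")
    anchor = str(reference[v.contig][v.start - 1 : v.start])
    return v.start - 1, anchor + v.ref_allele, anchor + v.alt_allele


def write_haplotype_vcf(
    path: str,
    haplotype_calls: Mapping[str, Sequence[Sequence[VariantCall]]],
    reference,
    contig_lengths: Mapping[str, int],
    sample: str,
) -> None:
    """One individual's calls as a phased single-sample VCF.

    ``haplotype_calls`` maps contig -> per-haplotype variant lists (one list
    for haploid contigs).  Variants present on both haplotypes come out as
    ``1|1``.
    """
    header = _vcf_header(contig_lengths, [sample])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for contig in contig_lengths:
            haps = haplotype_calls.get(contig)
            if not haps:
                continue
            by_key: dict[tuple, VariantCall] = {}
            hap_keys = []
            for hap in haps:
                hap_keys.append({v.key for v in hap})
                for v in hap:
                    by_key.setdefault(v.key, v)
            for key in sorted(by_key, key=lambda k: (k[1], k[2], k[3])):
                v = by_key[key]
                gt = tuple(int(key in keys) for keys in hap_keys)
                pos0, ref, alt = _vcf_alleles(v, reference)
                rec = vf.new_record(
                    contig=contig, start=pos0, alleles=(ref, alt)
                )
                if v.n_merged > 1:
                    rec.info["BLOCK"] = v.n_merged
                rec.samples[sample]["GT"] = gt
                rec.samples[sample].phased = True
                vf.write(rec)


def read_haplotype_vcf(
    path: str, reference
) -> tuple[str, dict[str, list[list[VariantCall]]]]:
    """Inverse of :func:`write_haplotype_vcf`: normalized per-haplotype calls."""
    out: dict[str, list[list[VariantCall]]] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF")
        sample = samples[0]
        for rec in vf:
            n_merged = int(rec.info.get("BLOCK", 1))
            v = VariantCall(
                rec.contig,
                rec.start,
                rec.ref,
                rec.alts[0],
                vtype=BLOCK_SUBSTITUTION if n_merged > 1 else "",
                n_merged=n_merged,
            )
            v = normalize(v, reference)
            gt = rec.samples[sample]["GT"]
            haps = out.setdefault(rec.contig, [[] for _ in gt])
            for hap, allele in enumerate(gt):
                if allele:
                    haps[hap].append(v)
    for haps in out.values():
        for hap in haps:
            hap.sort(key=lambda v: v.start)
    return sample, out


def write_sites_vcf(
    path: str,
    variants: Iterable[VariantCall],
    reference,
    contig_lengths: Mapping[str, int],
) -> None:
    """Genotype-free VCF for variant catalogs."""
    header = _vcf_header(contig_lengths)
    ordered = sorted(variants, key=lambda v: (v.contig, v.start, v.key))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in ordered:
            pos0, ref, alt = _vcf_alleles(v, reference)
            rec = vf.new_record(contig=v.contig, start=pos0, alleles=(ref, alt))
            if v.n_merged > 1:
                rec.info["BLOCK"] = v.n_merged
            vf.write(rec)


def read_sites_vcf(path: str, reference) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            n_merged = int(rec.info.get("BLOCK", 1))
            v = VariantCall(
                rec.contig,
                rec.start,
                rec.ref,
                rec.alts[0],
                vtype=BLOCK_SUBSTITUTION if n_merged > 1 else "",
                n_merged=n_merged,
            )
            out.append(normalize(v, reference))
    return out


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_array_genotypes(path: str) -> pd.DataFrame:
    """Array genotype TSV with columns contig, pos, ref, alt, genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "genotype": str})
    required = {"contig", "pos", "ref", "alt", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"array genotype file missing columns: {sorted(missing)}")
    return df
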