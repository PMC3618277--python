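"""Core variant data model: typing, normalization, block merging, summary stats.

Coordinates are 0-based half-open everywhere in this package; conversion to
1-based happens only at VCF I/O boundaries (:mod:`varcohort.io`).

A *block substitution* is a single variant locus formed by merging multiple
primitive variants (SNPs/indels) whose reference spans are separated by fewer
than two reference bases on a haplotype.  Merging is lossless: applying the
merged call to the reference reproduces exactly the haplotype implied by the
primitive calls.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# variant types
SNP = "snp"
INSERTION = "insertion"
DELETION = "deletion"
BLOCK_SUBSTITUTION = "block_substitution"
VARIANT_TYPES = (SNP, INSERTION, DELETION, BLOCK_SUBSTITUTION)

# zygosity
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"

_DNA = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidAlleleError(ValueError):
    """Allele contains non-ACGT characters or the allele pair is degenerate."""


class ReferenceMismatchError(ValueError):
    """A variant's ref_allele disagrees with the reference sequence."""


class OverlappingVariantsError(ValueError):
    """Two variants on one haplotype occupy overlapping reference spans."""


class UndefinedRatio(Exception):
    """Denominator of a summary ratio is zero; the ratio is reported absent."""


def _check_alleles(ref_allele: str, alt_allele: str) -> None:
    for allele in (ref_allele, alt_allele):
        if not _DNA.issuperset(allele):
            raise InvalidAlleleError(
                f"allele {allele!r} contains characters outside A/C/G/T"
            )
    if ref_allele == alt_allele:
        raise InvalidAlleleError(
            f"degenerate allele pair ({ref_allele!r}, {alt_allele!r})"
        )


def classify_variant_type(ref_allele: str, alt_allele: str) -> str:
    """Assign exactly one variant type to an allele pair.

    The pair is reduced by trimming shared suffix then prefix bases before
    typing, so VCF-style anchored representations classify identically to
    parsimonious ones.  Multi-base replacements that survive trimming are
    block substitutions.
    """
    _check_alleles(ref_allele, alt_allele)
    r, a = ref_allele, alt_allele
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
    if len(r) == 1 and len(a) == 1:
        return SNP
    if not r:
        return INSERTION
    if not a:
        return DELETION
    return BLOCK_SUBSTITUTION


@dataclass(frozen=True)
class VariantCall:
    """One alternate allele versus the reference at a locus.

    ``start`` is a 0-based offset; the reference span is
    ``[start, start + len(ref_allele))``.  A pure insertion has an empty
    ``ref_allele`` (zero-length span), a pure deletion an empty
    ``alt_allele``.  ``n_merged`` records how many primitive variants were
    merged to produce the call (1 for primitives).
    """

    contig: str
    start: int
    ref_allele: str
    alt_allele: str
    vtype: str = ""
    n_merged: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start offset {self.start}")
        if not self.vtype:
            object.__setattr__(
                self, "vtype", classify_variant_type(self.ref_allele, self.alt_allele)
            )
        else:
            _check_alleles(self.ref_allele, self.alt_allele)
            if self.vtype not in VARIANT_TYPES:
                raise ValueError(f"unknown variant type {self.vtype!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.ref_allele)

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_indel(self) -> bool:
        return self.vtype in (INSERTION, DELETION)

    @property
    def key(self) -> tuple:
        return (self.contig, self.start, self.ref_allele, self.alt_allele)

    def __str__(self) -> str:  # compact locus notation for logs
        return (
            f"{self.contig}:{self.start}"
            f"{self.ref_allele or '-'}>{self.alt_allele or '-'}"
        )


@dataclass(frozen=True)
class GenotypedCall:
    """A variant call with per-individual zygosity.

    ``allele_per_haplotype`` holds one allele index (0=ref, 1=alt) per
    haplotype; a singleton tuple marks a haploid locus.
    """

    variant: VariantCall
    zygosity: str
    allele_per_haplotype: tuple[int, ...] = (0, 1)
    phased: bool = True

    def __post_init__(self) -> None:
        alleles = self.allele_per_haplotype
        if self.zygosity == HEMIZYGOUS:
            if len(alleles) != 1 or alleles[0] != 1:
                raise ValueError("hemizygous call must carry a single alt allele")
        elif self.zygosity == HOMOZYGOUS:
            if alleles != (1, 1):
                raise ValueError("homozygous call must carry alt on both haplotypes")
        elif self.zygosity == HETEROZYGOUS:
            if sorted(alleles) != [0, 1]:
                raise ValueError("heterozygous call must carry exactly one alt allele")
        else:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass
class GenomeCallset:
    """All calls of one individual plus ploidy and callability metadata."""

    individual_id: str
    sex: str = "unknown"
    calls: list[GenotypedCall] = field(default_factory=list)
    callable_fraction: dict[str, float] = field(default_factory=dict)
    haploid_contigs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for contig, frac in self.callable_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"callable_fraction[{contig!r}]={frac} outside [0, 1]"
                )
        self.haploid_contigs = frozenset(self.haploid_contigs)

    def ploidy(self, contig: str) -> int:
        return 1 if contig in self.haploid_contigs else 2

    def variants(self) -> list[VariantCall]:
        return [c.variant for c in self.calls]

    def calls_by_key(self) -> dict[tuple, GenotypedCall]:
        return {c.variant.key: c for c in self.calls}


def _fetch(reference, contig: str, start: int, end: int) -> str:
    """Slice a reference that may be a plain string, a dict of strings, or a
    pyfaidx-style mapping of contig -> sliceable sequence."""
    if start < 0:
        raise ValueError("negative reference offset")
    if isinstance(reference, str):
        return reference[start:end]
    return str(reference[contig][start:end])


def is_transition(snp: VariantCall) -> bool:
    """True iff a SNP swaps purine<->purine or pyrimidine<->pyrimidine."""
    if snp.vtype != SNP:
        raise TypeError(f"is_transition requires a SNP, got {snp.vtype}")
    pair = {snp.ref_allele, snp.alt_allele}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def normalize(variant: VariantCall, reference) -> VariantCall:
    """Left-align and make parsimonious.  Idempotent.

    Shared suffix then prefix bases are trimmed; a pure indel is then shifted
    left one base at a time while the represented allele is unchanged.
    """
    observed = _fetch(reference, variant.contig, variant.start, variant.end)
    if observed != variant.ref_allele:
        raise ReferenceMismatchError(
            f"{variant}: reference has {observed!r} at "
            f"[{variant.start}, {variant.end})"
        )
    ref, alt, start = variant.ref_allele, variant.alt_allele, variant.start
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if bool(ref) != bool(alt):  # pure indel: left shift
        allele = ref or alt
        while start > 0:
            prev = _fetch(reference, variant.contig, start - 1, start)
            if not prev or prev != allele[-1]:
                break
            allele = prev + allele[:-1]
            start -= 1
        if ref:
            ref = allele
        else:
            alt = allele
    if (start, ref, alt) == (variant.start, variant.ref_allele, variant.alt_allele):
        return variant
    vtype = (
        BLOCK_SUBSTITUTION
        if variant.n_merged > 1
        else classify_variant_type(ref, alt)
    )
    return VariantCall(
        variant.contig, start, ref, alt, vtype=vtype, n_merged=variant.n_merged
    )


def group_into_blocks(
    calls: Sequence[VariantCall], reference, *, min_separation: int = 2
) -> list[VariantCall]:
    """Merge proximal variants on one haplotype into block substitutions.

    Consecutive variants whose reference spans are separated by fewer than
    ``min_separation`` reference bases are merged into a single call whose
    ref/alt spell out the full local reference and alternate sequences.
    Variants separated by at least ``min_separation`` bases stay separate.
    The output is a partition of the input.

    ``calls`` must be sorted by (contig, start) and non-overlapping.
    """
    merged: list[VariantCall] = []
    group: list[VariantCall] = []

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
            group.clear()
            return
        contig = group[0].contig
        start = group[0].start
        end = group[-1].end
        local_ref = _fetch(reference, contig, start, end)
        parts: list[str] = []
        cursor = start
        for v in group:
            parts.append(local_ref[cursor - start : v.start - start])
            parts.append(v.alt_allele)
            cursor = v.end
        parts.append(local_ref[cursor - start :])
        if "".join(parts) == local_ref:
            # e.g. an insertion immediately undone by an equal deletion
            raise InvalidAlleleError(
                f"cluster at {contig}:{start} cancels back to the reference"
            )
        merged.append(
            VariantCall(
                contig,
                start,
                local_ref,
                "".join(parts),
                vtype=BLOCK_SUBSTITUTION,
                n_merged=sum(v.n_merged for v in group),
            )
        )
        group.clear()

    for v in calls:
        if not group:
            group.append(v)
            continue
        prev = group[-1]
        if v.contig != prev.contig:
            flush()
            group.append(v)
            continue
        if v.start < prev.start:
            raise ValueError("calls must be sorted by (contig, start)")
        gap = v.start - prev.end
        if gap < 0 or (gap == 0 and v.start < prev.end):
            raise OverlappingVariantsError(f"{prev} overlaps {v}")
        if gap < min_separation:
            group.append(v)
        else:
            flush()
            group.append(v)
    flush()
    return merged


def group_genotyped_calls(
    calls: Sequence[GenotypedCall], reference, *, min_separation: int = 2
) -> list[GenotypedCall]:
    """Phase-aware merging over genotyped calls of one individual/contig.

    Runs of proximal calls are merged only when merging does not fabricate a
    haplotype: either every call in the run is homozygous (both haplotypes
    carry the full block), or all calls are phased (per-haplotype merging
    applies).  Runs containing an unphased heterozygote are left unmerged
    and a warning is logged.
    """
    out: list[GenotypedCall] = []
    run: list[GenotypedCall] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        elif all(c.zygosity in (HOMOZYGOUS, HEMIZYGOUS) for c in run):
            block = group_into_blocks(
                [c.variant for c in run], reference, min_separation=min_separation
            )[0]
            zyg = run[0].zygosity
            alleles = (1,) if zyg == HEMIZYGOUS else (1, 1)
            out.append(GenotypedCall(block, zyg, alleles))
        elif all(c.phased for c in run):
            n_hap = max(len(c.allele_per_haplotype) for c in run)
            for hap in range(n_hap):
                hap_vars = [
                    c.variant
                    for c in run
                    if len(c.allele_per_haplotype) > hap
                    and c.allele_per_haplotype[hap] == 1
                ]
                for block in group_into_blocks(
                    hap_vars, reference, min_separation=min_separation
                ):
                    alleles = tuple(
                        1 if h == hap else 0 for h in range(n_hap)
                    )
                    zyg = HEMIZYGOUS if n_hap == 1 else HETEROZYGOUS
                    out.append(GenotypedCall(block, zyg, alleles))
        else:
            logger.warning(
                "unphased heterozygous cluster at %s left unmerged",
                run[0].variant,
            )
            out.extend(run)
        run.clear()

    for call in sorted(calls, key=lambda c: (c.variant.contig, c.variant.start)):
        if not run:
            run.append(call)
            continue
        prev = run[-1].variant
        v = call.variant
        if v.contig == prev.contig and v.start - prev.end < min_separation:
            run.append(call)
        else:
            flush()
            run.append(call)
    flush()
    return out


def build_callset(
    individual_id: str,
    sex: str,
    haplotype_calls: Mapping[str, Sequence[Sequence[VariantCall]]],
    reference,
    *,
    haploid_contigs: Iterable[str] = (),
    callable_fraction: Mapping[str, float] | None = None,
) -> GenomeCallset:
    """Assemble a :class:`GenomeCallset` from per-haplotype primitive calls.

    ``haplotype_calls`` maps contig -> sequence of haplotype variant lists
    (two lists for diploid contigs, one for haploid).  Each haplotype list is
    block-merged independently, then the haplotypes are combined into
    genotyped calls.
    """
    haploid = frozenset(haploid_contigs)
    calls: list[GenotypedCall] = []
    for contig, haplotypes in haplotype_calls.items():
        expected = 1 if contig in haploid else 2
        if len(haplotypes) != expected:
            raise ValueError(
                f"{individual_id}/{contig}: expected {expected} haplotype "
                f"list(s), got {len(haplotypes)}"
            )
        merged = [
            group_into_blocks(sorted(h, key=lambda v: v.start), reference)
            for h in haplotypes
        ]
        if expected == 1:
            for v in merged[0]:
                calls.append(GenotypedCall(v, HEMIZYGOUS, (1,)))
        else:
            on_hap0 = {v.key for v in merged[0]}
            on_hap1 = {v.key for v in merged[1]}
            by_key = {v.key: v for v in merged[0] + merged[1]}
            for key, v in by_key.items():
                h0, h1 = key in on_hap0, key in on_hap1
                if h0 and h1:
                    calls.append(GenotypedCall(v, HOMOZYGOUS, (1, 1)))
                else:
                    calls.append(
                        GenotypedCall(v, HETEROZYGOUS, (1, 0) if h0 else (0, 1))
                    )
    calls.sort(key=lambda c: (c.variant.contig, c.variant.start, c.variant.key))
    return GenomeCallset(
        individual_id,
        sex,
        calls,
        dict(callable_fraction or {}),
        haploid,
    )


def apply_haplotype(sequence: str, variants: Sequence[VariantCall]) -> str:
    """Apply sorted, non-overlapping variants to a contig sequence."""
    parts: list[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.start):
        if v.start < cursor:
            raise OverlappingVariantsError(f"variant {v} overlaps previous edit")
        if sequence[v.start : v.end] != v.ref_allele:
            raise ReferenceMismatchError(f"{v}: ref allele mismatch")
        parts.append(sequence[cursor : v.start])
        parts.append(v.alt_allele)
        cursor = v.end
    parts.append(sequence[cursor:])
    return "".join(parts)


def transition_transversion_counts(snps: Iterable[VariantCall]) -> tuple[int, int]:
    ts = tv = 0
    for snp in snps:
        if is_transition(snp):
            ts += 1
        else:
            tv += 1
    return ts, tv


def tstv_ratio(snps: Iterable[VariantCall]) -> float | None:
    """Transitions over transversions; ``None`` when undefined (no Tv)."""
    ts, tv = transition_transversion_counts(snps)
    if tv == 0:
        return None
    return ts / tv


def het_hom_ratio(calls: Iterable[GenotypedCall]) -> float | None:
    """Heterozygous over homozygous calls; hemizygous calls are excluded.

    Returns ``None`` when there are no homozygous calls (undefined ratio).
    """
    counts = Counter(c.zygosity for c in calls)
    hom = counts[HOMOZYGOUS]
    if hom == 0:
        return None
    return counts[HETEROZYGOUS] / hom


def allele_frequencies(
    cohort: Sequence[GenomeCallset],
) -> dict[tuple, tuple[VariantCall, int, int]]:
    """Alternate allele counts over called alleles per distinct variant.

    Returns a mapping from variant key to ``(variant, alt_count, n_alleles)``
    where ``n_alleles`` is the number of called alleles in the cohort for
    that variant's contig (2 per diploid individual, 1 per haploid).
    """
    if not cohort:
        raise ValueError("empty cohort")
    result: dict[tuple, list] = {}
    for callset in cohort:
        for call in callset.calls:
            v = call.variant
            entry = result.setdefault(v.key, [v, 0])
            entry[1] += sum(call.allele_per_haplotype)
    contigs = {key[0] for key in result}
    an_by_contig = {
        contig: sum(cs.ploidy(contig) for cs in cohort) for contig in contigs
    }
    return {
        key: (v, ac, an_by_contig[key[0]]) for key, (v, ac) in result.items()
    }


def maf_spectrum(
    cohort: Sequence[GenomeCallset],
    bin_edges: Sequence[float],
    *,
    variant_keys: Iterable[tuple] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of minor allele frequencies over (0, 0.5].

    ``bin_edges`` are interior edges; bins are right-inclusive, so edges
    ``[0.05]`` produce bins (0, 0.05] and (0.05, 0.5].  Monomorphic variants
    (MAF 0) are excluded.  If ``variant_keys`` is given, only those variants
    are binned (e.g. the novel subset).
    """
    freqs = allele_frequencies(cohort)
    if variant_keys is not None:
        wanted = set(variant_keys)
        freqs = {k: v for k, v in freqs.items() if k in wanted}
    edges = np.unique(np.concatenate(([0.0], np.asarray(bin_edges, float), [0.5])))
    if edges[0] < 0.0 or edges[-1] > 0.5:
        raise ValueError("bin edges must lie within (0, 0.5)")
    mafs = []
    for _, ac, an in freqs.values():
        p = ac / an
        maf = min(p, 1.0 - p)
        if maf > 0.0:
            mafs.append(maf)
    idx = np.searchsorted(edges, np.asarray(mafs, float), side="left") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1) if mafs else np.zeros(
        len(edges) - 1, dtype=int
    )
    return counts.astype(int), edges
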