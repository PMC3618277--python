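"""Cross-catalog novelty and discovery-saturation analysis.

SNPs are matched against catalogs exactly (contig, position, allele pair);
indels are matched fuzzily: same contig, same type, same signed length
change, and normalized start offsets within a configurable window
(default 25 bp).  Block substitutions are matched exactly.

The discovery curve walks the cohort in permuted orders, counting at each
step the variants of the newly added genome not present in the catalogs nor
in any previously walked genome, using the same matching rules throughout.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .variants import (
    BLOCK_SUBSTITUTION,
    SNP,
    GenomeCallset,
    VariantCall,
)
from .annotation import variant_class

logger = logging.getLogger(__name__)

DEFAULT_INDEL_WINDOW = 25


class FitError(RuntimeError):
    """Trendline fitting failed (e.g. degenerate constant curve)."""


def indel_match(
    a: VariantCall,
    b: VariantCall,
    window: int = DEFAULT_INDEL_WINDOW,
    *,
    require_same_type: bool = True,
) -> bool:
    """Fuzzy indel equivalence: same contig, size and nearby position.

    Both variants are expected to be left-normalized.  "Same size" means the
    same signed length change; with ``require_same_type`` (default) the
    variant types must also agree, so an insertion never matches a deletion.
    """
    if a.contig != b.contig:
        return False
    if require_same_type and a.vtype != b.vtype:
        return False
    if a.length_change != b.length_change:
        return False
    return abs(a.start - b.start) <= window


class VariantIndex:
    """Matcher-aware variant set: exact SNP/block lookup, windowed indels."""

    def __init__(
        self,
        variants: Iterable[VariantCall] = (),
        *,
        require_same_type: bool = True,
    ) -> None:
        self._snps: set[tuple] = set()
        self._blocks: set[tuple] = set()
        self._indels: dict[tuple, list[int]] = {}
        self._require_same_type = require_same_type
        self._n = 0
        for v in variants:
            self.add(v)

    def __len__(self) -> int:
        return self._n

    def _indel_key(self, v: VariantCall) -> tuple:
        vtype = v.vtype if self._require_same_type else "indel"
        return (v.contig, vtype, v.length_change)

    def add(self, variant: VariantCall) -> None:
        self._n += 1
        if variant.vtype == SNP:
            self._snps.add(variant.key)
        elif variant.vtype == BLOCK_SUBSTITUTION:
            self._blocks.add(variant.key)
        else:
            insort(self._indels.setdefault(self._indel_key(variant), []), variant.start)

    def contains(
        self, variant: VariantCall, window: int = DEFAULT_INDEL_WINDOW
    ) -> bool:
        if variant.vtype == SNP:
            return variant.key in self._snps
        if variant.vtype == BLOCK_SUBSTITUTION:
            return variant.key in self._blocks
        starts = self._indels.get(self._indel_key(variant))
        if not starts:
            return False
        lo = bisect_left(starts, variant.start - window)
        hi = bisect_right(starts, variant.start + window)
        return hi > lo


class Catalog:
    """An immutable reference variant set (a dbSNP/1000G stand-in).

    Duplicate entries collapse; lookups are deterministic.
    """

    def __init__(
        self, name: str, variants: Iterable[VariantCall] = (), *,
        window: int = DEFAULT_INDEL_WINDOW,
    ) -> None:
        self.name = name
        self.window = window
        deduped = {v.key: v for v in variants}
        self.variants = list(deduped.values())
        self._index = VariantIndex(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant: VariantCall) -> bool:
        return self.contains(variant)

    def contains(self, variant: VariantCall, window: int | None = None) -> bool:
        return self._index.contains(
            variant, self.window if window is None else window
        )


def snp_in_catalog(snp: VariantCall, catalog: Catalog) -> bool:
    """Exact SNP membership: same contig, position and allele pair."""
    if snp.vtype != SNP:
        raise TypeError(f"snp_in_catalog requires a SNP, got {snp.vtype}")
    return catalog.contains(snp)


@dataclass(frozen=True)
class VennReport:
    """Two-catalog membership partition of a distinct variant set."""

    total: int
    a_only: int
    b_only: int
    both: int
    neither: int

    def __post_init__(self) -> None:
        if self.a_only + self.b_only + self.both + self.neither != self.total:
            raise ValueError("Venn cells do not partition the total")
        if min(self.total, self.a_only, self.b_only, self.both, self.neither) < 0:
            raise ValueError("negative Venn cell")

    @classmethod
    def from_membership_counts(
        cls, total: int, in_a: int, in_b: int, neither: int
    ) -> "VennReport":
        """Build the partition from total, |A|, |B| and the neither cell."""
        both = in_a + in_b + neither - total
        return cls(total, in_a - both, in_b - both, both, neither)

    @property
    def in_a(self) -> int:
        return self.a_only + self.both

    @property
    def in_b(self) -> int:
        return self.b_only + self.both

    def pct_in_a(self, ndigits: int = 1) -> float:
        return round(100.0 * self.in_a / self.total, ndigits)

    def pct_in_b(self, ndigits: int = 1) -> float:
        return round(100.0 * self.in_b / self.total, ndigits)

    def pct_neither(self, ndigits: int = 1) -> float:
        return round(100.0 * self.neither / self.total, ndigits)


def venn_partition(
    cohort_variants: Iterable[VariantCall],
    catalog_a: Catalog,
    catalog_b: Catalog,
    *,
    window: int = DEFAULT_INDEL_WINDOW,
) -> dict[str, VennReport]:
    """Membership cells (A only / B only / both / neither) per variant class.

    Returns one :class:`VennReport` per class plus the combined ``"all"``
    report.  SNPs/blocks use exact matching, indels the windowed matcher.
    """
    distinct = list({v.key: v for v in cohort_variants}.values())
    cells: dict[str, list[int]] = {}
    for v in distinct:
        in_a = catalog_a.contains(v, window)
        in_b = catalog_b.contains(v, window)
        cell = (
            2 * int(in_a) + int(in_b)
        )  # 0 neither, 1 b_only, 2 a_only, 3 both
        for cls in (variant_class(v), "all"):
            cells.setdefault(cls, [0, 0, 0, 0])[cell] += 1
    return {
        cls: VennReport(
            total=sum(c),
            a_only=c[2],
            b_only=c[1],
            both=c[3],
            neither=c[0],
        )
        for cls, c in cells.items()
    }


@dataclass
class DiscoveryCurve:
    """Mean number of previously unseen variants added by the k-th genome."""

    step_means: np.ndarray
    step_sds: np.ndarray
    n_permutations: int
    seed: int

    def __len__(self) -> int:
        return len(self.step_means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.step_means) + 1),
                "mean_novel": self.step_means,
                "sd_novel": self.step_sds,
            }
        )


def _genome_variants(genome) -> list[VariantCall]:
    if isinstance(genome, GenomeCallset):
        variants = genome.variants()
    else:
        variants = list(genome)
    return list({v.key: v for v in variants}.values())


def discovery_curve(
    genomes: Sequence,
    catalogs: Sequence[Catalog] = (),
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    window: int = DEFAULT_INDEL_WINDOW,
) -> DiscoveryCurve:
    """Permutation estimate of the variant discovery saturation curve.

    The genome order is permuted ``n_permutations`` times; at each step the
    variants of the added genome not matching the catalogs nor any variant of
    previously walked genomes are counted as novel.  Each permutation draws
    from its own seed substream, so results are independent of execution
    order.  Reproducible given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(genomes) < 1:
        raise ValueError("at least one genome required")
    variant_lists = [_genome_variants(g) for g in genomes]
    known = [
        np.array(
            [any(c.contains(v, window) for c in catalogs) for v in vs], dtype=bool
        )
        for vs in variant_lists
    ]
    n = len(genomes)
    steps = np.zeros((n_permutations, n))
    children = np.random.SeedSequence(seed).spawn(n_permutations)
    for p, child in enumerate(children):
        order = np.random.default_rng(child).permutation(n)
        seen = VariantIndex()
        for k, gi in enumerate(order):
            novel = 0
            for v, in_catalog in zip(variant_lists[gi], known[gi]):
                if not in_catalog and not seen.contains(v, window):
                    novel += 1
                seen.add(v)
            steps[p, k] = novel
    return DiscoveryCurve(
        step_means=steps.mean(axis=0),
        step_sds=steps.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trendline fitting
# ---------------------------------------------------------------------------

def _power_offset(k, a, b, c):
    return a * np.power(k, -b) + c


def _exponential_offset(k, a, b, c):
    return a * np.exp(-b * k) + c


_FAMILIES = {
    "power_offset": _power_offset,
    "exponential_offset": _exponential_offset,
}


@dataclass
class TrendlineFit:
    family: str
    params: dict[str, float]
    r_squared: float

    def predict(self, k: np.ndarray) -> np.ndarray:
        fn = _FAMILIES[self.family]
        return fn(np.asarray(k, float), **self.params)


def fit_trendline(
    curve: DiscoveryCurve | Sequence[float],
    family: str = "power_offset",
) -> TrendlineFit:
    """Least-squares decay fit to a discovery curve.

    Default family is a power law with offset, ``y = a * k**(-b) + c``.
    Degenerate (constant) curves raise :class:`FitError`.
    """
    y = np.asarray(
        curve.step_means if isinstance(curve, DiscoveryCurve) else curve, float
    )
    if len(y) < 3:
        raise ValueError("curve must have at least 3 steps")
    if np.ptp(y) == 0:
        raise FitError("constant curve: decay parameters are unidentifiable")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    fn = _FAMILIES[family]
    k = np.arange(1, len(y) + 1, dtype=float)
    p0 = (max(y[0] - y[-1], 1e-6), 1.0, y[-1])
    try:
        popt, _ = curve_fit(fn, k, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(str(exc)) from exc
    resid = y - fn(k, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return TrendlineFit(
        family=family,
        params={"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
        r_squared=r2,
    )
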