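"""Independent oracles and fixture generators shared across test modules.

Everything here is deliberately written without reusing the package's own
algorithms: the merge checker verifies losslessness by haplotype application
and checks the <2-base rule pairwise from raw coordinates; the discovery
oracle enumerates every genome ordering with plain set arithmetic.
"""

import itertools

import numpy as np

from varcohort.variants import VariantCall, apply_haplotype

BASES = "ACGT"


def random_reference(rng, length=90):
    return "".join(rng.choice(list(BASES), size=length))


def _has_cancelling_cluster(ref, calls, min_separation=2):
    """True when a <2-base-gap run of calls nets out to the unedited
    reference (insertion undone by an equal adjacent deletion, etc.)."""
    groups = [[calls[0]]]
    for v in calls[1:]:
        if v.start - groups[-1][-1].end < min_separation:
            groups[-1].append(v)
        else:
            groups.append([v])
    for g in groups:
        if len(g) < 2:
            continue
        s, e = g[0].start, g[-1].end
        shifted = [
            VariantCall(v.contig, v.start - s, v.ref_allele, v.alt_allele)
            for v in g
        ]
        if apply_haplotype(ref[s:e], shifted) == ref[s:e]:
            return True
    return False


def random_clustered_calls(rng, ref, max_calls=6):
    """Primitive variants with random small gaps (0-4 reference bases)."""
    for _attempt in range(20):
        calls = []
        cursor = int(rng.integers(0, 6))
        for i in range(int(rng.integers(1, max_calls + 1))):
            if i:
                cursor += int(rng.integers(0, 5))
            if cursor >= len(ref) - 8:
                break
            kind = rng.choice(["snp", "ins", "del"], p=[0.6, 0.2, 0.2])
            if kind == "snp":
                alt = str(rng.choice([b for b in BASES if b != ref[cursor]]))
                calls.append(VariantCall("c", cursor, ref[cursor], alt))
                cursor += 1
            elif kind == "del":
                n = int(rng.integers(1, 4))
                calls.append(VariantCall("c", cursor, ref[cursor : cursor + n], ""))
                cursor += n
            else:
                n = int(rng.integers(1, 4))
                ins = "".join(rng.choice(list(BASES), size=n))
                calls.append(VariantCall("c", cursor, "", ins))
        if calls and not _has_cancelling_cluster(ref, calls):
            return calls
    return []


def check_block_merge(ref, calls, merged, min_separation=2):
    """Assert merged output is a lossless partition obeying the <2-base rule."""
    # losslessness: both call lists imply the same haplotype sequence
    assert apply_haplotype(ref, calls) == apply_haplotype(ref, merged)
    # partition: every primitive belongs to exactly one output call
    assert sum(m.n_merged for m in merged) == len(calls)

    def owner(v):
        owners = [m for m in merged if m.start <= v.start and v.end <= m.end]
        assert owners, f"primitive {v} not covered by any output call"
        return owners[0]

    for a, b in zip(calls, calls[1:]):
        should_merge = (b.start - a.end) < min_separation
        assert (owner(a) is owner(b)) == should_merge, (a, b, merged)


def enumerate_discovery_means(genome_sets, catalog_set):
    """Exact step means over every ordering, with plain set arithmetic."""
    n = len(genome_sets)
    totals = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        seen = set(catalog_set)
        for k, gi in enumerate(order):
            totals[k] += len(set(genome_sets[gi]) - seen)
            seen |= set(genome_sets[gi])
        count += 1
    return totals / count


_SYMBOLS: dict = {}


def sym_snp(symbol):
    """Map a hashable symbol to a unique SNP (for toy discovery cohorts)."""
    idx = _SYMBOLS.setdefault(symbol, len(_SYMBOLS))
    return VariantCall("toy", 50 * idx + 5, "A", "G")
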