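"""Genome-binned variant density tracks and blockwise correlation profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .variants import VariantCall


@dataclass
class WindowTrack:
    """Counts of one variant class in consecutive non-overlapping windows.

    Windows tile ``[0, contig_length)``; the last window may be short.  A
    variant is counted in the window containing its start offset.
    """

    contig: str
    window_size: int
    counts: np.ndarray
    label: str = "all"

    def __len__(self) -> int:
        return len(self.counts)


def bin_counts(
    variants: Iterable[VariantCall],
    contig_lengths: Mapping[str, int],
    window_size: int,
    *,
    label: str = "all",
) -> dict[str, WindowTrack]:
    """Per-contig window tracks of variant start counts."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    tracks = {
        contig: np.zeros(-(-length // window_size), dtype=int)
        for contig, length in contig_lengths.items()
    }
    for v in variants:
        if v.contig not in tracks:
            raise KeyError(f"variant contig {v.contig!r} not in contig_lengths")
        tracks[v.contig][v.start // window_size] += 1
    return {
        contig: WindowTrack(contig, window_size, counts, label)
        for contig, counts in tracks.items()
    }


def _as_array(track) -> np.ndarray:
    if isinstance(track, WindowTrack):
        return np.asarray(track.counts, float)
    return np.asarray(track, float)


def blockwise_correlation(
    track_x,
    track_y,
    block: int = 100,
    *,
    keep_partial: bool = False,
) -> np.ndarray:
    """Pearson r of two aligned tracks over consecutive disjoint blocks.

    Each run of ``block`` windows yields one coefficient; blocks where either
    count vector is constant yield NaN (undefined, not a number in [-1, 1]).
    The trailing partial block is dropped unless ``keep_partial`` is set.
    """
    x, y = _as_array(track_x), _as_array(track_y)
    if len(x) != len(y):
        raise ValueError(f"track length mismatch: {len(x)} vs {len(y)}")
    if block < 3:
        raise ValueError("block must be >= 3")
    n_full = len(x) // block
    bounds = [(i * block, (i + 1) * block) for i in range(n_full)]
    if keep_partial and len(x) % block >= 3:
        bounds.append((n_full * block, len(x)))
    out = np.empty(len(bounds))
    for i, (lo, hi) in enumerate(bounds):
        bx, by = x[lo:hi], y[lo:hi]
        if np.ptp(bx) == 0 or np.ptp(by) == 0:
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(bx, by)[0, 1]
    return out


def novel_fraction_track(novel_track, total_track) -> np.ndarray:
    """Per-window novel/total proportions; 0/0 windows are NaN."""
    novel, total = _as_array(novel_track), _as_array(total_track)
    if len(novel) != len(total):
        raise ValueError("track length mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, novel / np.where(total > 0, total, 1), np.nan)
    return frac


def track_to_bed(
    track: WindowTrack, contig_length: int | None = None
) -> list[tuple[str, int, int, str, int]]:
    """BED rows (contig, start, end, name, score=count) for a track."""
    rows = []
    for i, count in enumerate(track.counts):
        start = i * track.window_size
        end = start + track.window_size
        if contig_length is not None:
            end = min(end, contig_length)
        rows.append((track.contig, start, end, track.label, int(count)))
    return rows
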