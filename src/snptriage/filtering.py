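"""Variant-call quality and read-depth filtering.

Two filters are applied to the raw call set before any classification:
a strict Phred-quality cutoff (quality > 30 by default) and removal of
variants inside genomic regions whose read depth exceeds a cutoff
(depth > 50 by default) — high-coverage regions are treated as repetitive
or otherwise unreliable and masked out wholesale.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import ConsistencyError, DepthInterval, VariantRecord


@dataclass(frozen=True)
class FilterConfig:
    min_quality: float = 30.0  # keep quality strictly greater than this
    max_depth: int = 50  # mask bases with depth strictly greater than this

    def __post_init__(self) -> None:
        if self.min_quality < 0 or self.max_depth < 0:
            raise ValueError("filter cutoffs must be non-negative")


@dataclass
class MaskSet:
    """Per-sequence sorted, merged 0-based half-open excluded intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    threshold: int = 50

    def contains(self, sequence_id: str, pos0: int) -> bool:
        """Is 0-based position ``pos0`` inside a masked interval?"""
        ivs = self.intervals.get(sequence_id)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    @property
    def total_masked_bases(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)


def filter_by_quality(
    records: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep exactly the records with quality strictly above the cutoff."""
    return [r for r in records if r.quality > config.min_quality]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_depth_mask(
    intervals: Sequence[DepthInterval], config: FilterConfig = FilterConfig()
) -> MaskSet:
    """Mask exactly the bases whose read depth is strictly > ``max_depth``.

    Input intervals must tile each sequence without overlap; adjacent
    qualifying intervals are merged in the mask.
    """
    by_seq: dict[str, list[DepthInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.sequence_id, []).append(iv)
    mask = MaskSet(threshold=config.max_depth)
    for seq, ivs in by_seq.items():
        ivs.sort(key=lambda iv: iv.start)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ConsistencyError(
                    f"{seq}: depth intervals overlap at {cur.start} < {prev.end}"
                )
        deep = [(iv.start, iv.end) for iv in ivs if iv.depth > config.max_depth]
        if deep:
            mask.intervals[seq] = _merge(deep)
    return mask


def remove_masked_variants(
    records: Iterable[VariantRecord], mask: MaskSet
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition records into (kept, removed) against a depth mask.

    A variant is removed iff its 0-based start coordinate (position - 1)
    lies inside a masked interval; indels are judged by their start
    position only.
    """
    kept: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    for rec in records:
        if mask.contains(rec.sequence_id, rec.position - 1):
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def apply_filters(
    records: Sequence[VariantRecord],
    depth_intervals: Sequence[DepthInterval],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantRecord], list[VariantRecord], MaskSet]:
    """Quality filter then depth mask; returns (kept, removed, mask)."""
    passing = filter_by_quality(records, config)
    low_quality = [r for r in records if r.quality <= config.min_quality]
    mask = build_depth_mask(depth_intervals, config)
    kept, masked = remove_masked_variants(passing, mask)
    return kept, low_quality + masked, mask
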