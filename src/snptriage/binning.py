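"""Genome-binned variant-density tracks (500-kb bins by default).

Produces the per-linkage-group histogram tracks used for circular genome
plots: a locus at 1-based position p on a sequence falls in bin
floor((p-1)/bin_size). The last partial bin keeps its natural shorter
span; counts are raw, not per-bp densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .records import ConsistencyError, GenomeSequence

DEFAULT_BIN_SIZE = 500_000


@dataclass
class BinTrack:
    sequence_id: str
    sequence_length: int
    bin_size: int
    counts: list[int]
    label: str

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_span(self, i: int) -> tuple[int, int]:
        """0-based half-open genomic span of bin i (last bin may be short)."""
        start = i * self.bin_size
        return start, min(start + self.bin_size, self.sequence_length)


def _locus_tuple(locus) -> tuple[str, int]:
    if isinstance(locus, tuple):
        return locus[0], locus[1]
    return locus.sequence_id, locus.position


def bin_variants(
    loci: Iterable,
    sequences: Sequence[GenomeSequence],
    bin_size: int = DEFAULT_BIN_SIZE,
    label: str = "variants",
) -> list[BinTrack]:
    """Count loci per fixed-size bin, one track per sequence.

    ``loci`` may be (sequence_id, position) tuples or any objects with
    ``sequence_id``/``position`` attributes (records, profiles). Sequences
    with no loci still get an all-zero track.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    lengths = {s.sequence_id: s.length for s in sequences}
    tracks = {
        s.sequence_id: BinTrack(
            sequence_id=s.sequence_id,
            sequence_length=s.length,
            bin_size=bin_size,
            counts=[0] * max(1, math.ceil(s.length / bin_size)),
            label=label,
        )
        for s in sequences
    }
    for locus in loci:
        seq, pos = _locus_tuple(locus)
        if seq not in tracks:
            raise ConsistencyError(f"locus on unknown sequence {seq!r}")
        if pos < 1 or pos > lengths[seq]:
            raise ConsistencyError(
                f"locus {seq}:{pos} beyond sequence length {lengths[seq]}"
            )
        tracks[seq].counts[(pos - 1) // bin_size] += 1
    return [tracks[s.sequence_id] for s in sequences]


def export_circos(tracks: Sequence[BinTrack], out_dir: str | Path) -> list[Path]:
    """Write plain-text histogram tracks, one file per label.

    Each line is ``sequence <tab> bin_start <tab> bin_end <tab> count``
    (0-based half-open, BED-style), ordered by sequence then bin index.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_label: dict[str, list[BinTrack]] = {}
    for t in tracks:
        by_label.setdefault(t.label, []).append(t)
    paths = []
    for label, ts in by_label.items():
        path = out_dir / f"{label}.track.bed"
        with open(path, "w") as fh:
            for t in ts:
                for i, count in enumerate(t.counts):
                    s, e = t.bin_span(i)
                    fh.write(f"{t.sequence_id}\t{s}\t{e}\t{count}\n")
        paths.append(path)
    return paths


def read_circos(path: str | Path) -> list[tuple[str, int, int, int]]:
    """Parse a written track file back into (sequence, start, end, count)."""
    out = []
    with open(path) as fh:
        for line in fh:
            seq, s, e, c = line.rstrip("\n").split("\t")
            out.append((seq, int(s), int(e), int(c)))
    return out


def coarsen(track: BinTrack, factor: int = 2) -> BinTrack:
    """Re-sum adjacent bins into a track with ``factor``-times-larger bins;
    refining then coarsening must reproduce the coarser track exactly."""
    counts = [
        sum(track.counts[i : i + factor]) for i in range(0, len(track.counts), factor)
    ]
    return BinTrack(
        sequence_id=track.sequence_id,
        sequence_length=track.sequence_length,
        bin_size=track.bin_size * factor,
        counts=counts,
        label=track.label,
    )


def plot_track(track: BinTrack, ax=None):
    """Simple linear histogram of one track (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2))
    mids = [(s + e) / 2 for s, e in (track.bin_span(i) for i in range(track.n_bins))]
    ax.bar(mids, track.counts, width=track.bin_size * 0.9)
    ax.set_xlabel(f"{track.sequence_id} position (bp)")
    ax.set_ylabel("variants / bin")
    ax.set_title(track.label)
    return ax
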