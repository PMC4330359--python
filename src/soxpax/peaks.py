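"""Interval algebra over ChIP-seq peak sets.

Co-bound regions for two factors are defined conservatively as the
intersection spans of overlapping peak pairs (not their union), merged when
the spans themselves overlap — every reported region is therefore a subset
of both factors' evidence.  Coordinates are BED-style 0-based half-open;
chromosome names are compared by exact string equality unless
``normalize_chr`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import pyranges as pr

from .motifs import CompositeMotif, IUPACWord, MotifHit, match_word, scan_composite

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedError",
    "read_bed",
    "write_bed",
    "intersect_peaks",
    "region_motif_fraction",
]


class BedError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BedError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakSet:
    """A labelled collection of intervals (one factor's peaks)."""

    intervals: tuple[GenomicInterval, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted_unique(self) -> "PeakSet":
        """Normalized copy: sorted by (chrom, start, end), duplicates removed."""
        seen = sorted({(iv.chrom, iv.start, iv.end, iv.name) for iv in self.intervals})
        return PeakSet(
            tuple(GenomicInterval(c, s, e, n) for c, s, e, n in seen), label=self.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self.intervals],
                "Start": [iv.start for iv in self.intervals],
                "End": [iv.end for iv in self.intervals],
            }
        )


def _normalize_chrom(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def read_bed(path, label: str = "", normalize_chr: bool = False) -> PeakSet:
    """Read BED3+ into a PeakSet; track/browser lines are skipped.

    Malformed lines (non-integer or inverted coordinates, too few fields)
    raise :class:`BedError` naming the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise BedError(f"{path}: line {lineno}: non-integer coordinates") from err
            if start >= end or start < 0:
                raise BedError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            if normalize_chr:
                chrom = _normalize_chrom(chrom)
            intervals.append(GenomicInterval(chrom, start, end, name))
    return PeakSet(tuple(intervals), label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED3 (or BED4 when interval names are present)."""
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            if iv.name:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def intersect_peaks(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Co-bound regions of two peak sets.

    Every a-peak/b-peak overlap of at least ``min_overlap`` bp contributes
    its intersection span; spans that themselves overlap or touch are then
    merged.  Output is sorted, pairwise disjoint and symmetric in (a, b).
    """
    if min_overlap < 1:
        raise BedError("min_overlap must be >= 1 bp")
    if len(a) == 0 or len(b) == 0:
        return PeakSet((), label=f"{a.label}&{b.label}")
    spans = pr.PyRanges(a.to_frame()).intersect(pr.PyRanges(b.to_frame()))
    df = spans.df if len(spans) else pd.DataFrame(columns=["Chromosome", "Start", "End"])
    df = df[(df["End"] - df["Start"]) >= min_overlap]
    if df.empty:
        return PeakSet((), label=f"{a.label}&{b.label}")
    merged = pr.PyRanges(df.reset_index(drop=True)).merge().df
    merged = merged.sort_values(["Chromosome", "Start", "End"]).reset_index(drop=True)
    intervals = tuple(
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in merged.itertuples()
    )
    return PeakSet(intervals, label=f"{a.label}&{b.label}")


def region_motif_fraction(
    regions: PeakSet,
    sequences: dict[str, str],
    motif: CompositeMotif | IUPACWord,
) -> tuple[int, float]:
    """Count regions containing >= 1 motif hit (both strands) and the fraction.

    ``sequences`` maps region names (or ``chrom:start-end`` for unnamed
    regions) to their DNA.  A region without a sequence is an error listing
    every missing id.
    """
    if len(regions) == 0:
        raise BedError("region set is empty")
    ids = [
        iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions.intervals
    ]
    missing = [i for i in ids if i not in sequences]
    if missing:
        raise BedError(f"regions without sequence: {', '.join(missing)}")
    n_hit = 0
    for rid in ids:
        seq = sequences[rid]
        if isinstance(motif, CompositeMotif):
            hits = scan_composite(motif, seq, both_strands=True, seq_id=rid)
            found = bool(hits)
        else:
            word = motif
            found = _word_occurs(word, seq)
        n_hit += int(found)
    return n_hit, n_hit / len(regions)


def _word_occurs(word: IUPACWord, seq: str) -> bool:
    from .motifs import reverse_complement

    for strand_seq in (seq, reverse_complement(seq)):
        for pos in range(len(strand_seq) - len(word) + 1):
            if match_word(word, strand_seq, pos):
                return True
    return False
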