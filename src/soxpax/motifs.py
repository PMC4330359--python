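"""Composite sox-pax motif representation, scanning and mutagenesis.

The composite elements studied here consist of a sox half-site and a pax
half-site in fixed order on the same strand, separated by a rigid spacer.
Half-sites are written as degenerate IUPAC words; a composite hit requires
both words to match at exactly the configured gap.  "Flipped" motifs reverse
the orientation of the pax word only (the reverse-complemented pax consensus
placed after the sox word), which is how flipped-consensus control elements
are constructed.

Also here: IUPAC-aware reverse complement and duplex annealing checks for
oligo bookkeeping, spacer-variant and nucleotide-switch mutagenesis used to
enumerate the element series of the binding studies, and JASPAR position
frequency matrix parsing with per-position information content to locate
high-information consensus positions that deviate from a degenerate
half-site.

Coordinates are 0-based half-open throughout; half-site switch positions
are the conventional 1-based labels (e.g. T3, G8, C9, T11 — consensus base
plus 1-based position within the half-site frame).
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "IUPACWord",
    "CompositeMotif",
    "MotifHit",
    "SwitchPositionSet",
    "SwitchVariant",
    "PositionFrequencyMatrix",
    "MotifError",
    "AnnealMismatch",
    "reverse_complement",
    "anneal_check",
    "match_word",
    "scan_composite",
    "enumerate_spacer_variants",
    "enumerate_switch_mutants",
    "build_flipped_composite",
    "parse_pfm",
    "information_content",
    "high_ic_deviations",
    "read_fasta",
    "write_fasta",
    "hits_to_bed",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class MotifError(ValueError):
    pass


class AnnealMismatch(MotifError):
    """Two oligos are not perfect reverse complements.

    ``position`` is the 0-based index on the reverse oligo of the first base
    that differs from the reverse complement of the forward oligo, or None
    for a length mismatch.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def _validate_iupac(seq: str, what: str = "sequence") -> None:
    bad = [(i, c) for i, c in enumerate(seq.upper()) if c not in IUPAC_CODES]
    if bad:
        i, c = bad[0]
        raise MotifError(f"invalid IUPAC letter {c!r} at position {i} in {what}")


@dataclass(frozen=True)
class IUPACWord:
    """A degenerate nucleotide word over the 15-letter IUPAC alphabet."""

    letters: str

    def __post_init__(self) -> None:
        if not self.letters:
            raise MotifError("IUPAC word must be non-empty")
        _validate_iupac(self.letters, "IUPAC word")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters


@dataclass(frozen=True)
class CompositeMotif:
    """sox word + gap + pax word, with the pax word's orientation.

    ``pax_orientation`` is ``"forward"`` for the native architecture and
    ``"flipped"`` when the pax word is to be matched as its reverse
    complement (still downstream of the sox word on the same strand).
    Negative gaps (overlapping half-sites) are a construction-time concept
    only and are rejected for scanning.
    """

    sox_word: IUPACWord
    pax_word: IUPACWord
    gap: int = 0
    pax_orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise MotifError("negative gaps are not scannable (overlapping half-sites)")
        if self.pax_orientation not in ("forward", "flipped"):
            raise MotifError(f"pax_orientation must be forward|flipped, got {self.pax_orientation!r}")

    @property
    def span_length(self) -> int:
        return len(self.sox_word) + self.gap + len(self.pax_word)


@dataclass(frozen=True)
class MotifHit:
    """One composite match.

    ``matched_span`` is the 0-based half-open footprint on the forward
    strand; ``offset`` is the forward-strand start of the sox word's
    footprint (equal to the span start on '+', the last ``len(sox)`` bases
    of the span on '-').  Hits sort by forward-strand span, '+' before '-'.
    """

    seq_id: str
    offset: int
    strand: str
    matched_span: tuple[int, int]

    def sort_key(self):
        return (self.seq_id, self.matched_span[0], self.matched_span[1], self.strand != "+")


@dataclass(frozen=True)
class SwitchPositionSet:
    """1-based positions within a half-site frame whose identity toggles
    between the degenerate (cooperative) and consensus (additive) modes."""

    positions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifError("switch position set must be non-empty")
        if any(p < 1 for p in self.positions):
            raise MotifError("switch positions are 1-based (>= 1)")

    def sorted(self) -> list[int]:
        return sorted(self.positions)


@dataclass(frozen=True)
class SwitchVariant:
    """One consensus-substituted half-site variant."""

    label: str
    positions: tuple[int, ...]
    sequence: str


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, S<->S, N<->N, ...); preserves case."""
    _validate_iupac(seq)
    return str(Seq(seq).reverse_complement())


def anneal_check(forward: str, reverse: str) -> int:
    """Verify two oligos anneal into a perfect duplex; return its length (bp).

    The reverse oligo must equal the reverse complement of the forward one.
    On failure, raises :class:`AnnealMismatch` naming the first mismatching
    0-based position on the reverse oligo (or the length difference).
    """
    if not forward or not reverse:
        raise MotifError("both oligos must be non-empty")
    expected = reverse_complement(forward)
    _validate_iupac(reverse, "reverse oligo")
    if len(reverse) != len(expected):
        raise AnnealMismatch(
            f"length mismatch: forward {len(forward)} bp, reverse {len(reverse)} bp"
        )
    for i, (want, got) in enumerate(zip(expected.upper(), reverse.upper())):
        if want != got:
            raise AnnealMismatch(
                f"mismatch at position {i} of the reverse oligo: expected {want}, got {got}",
                position=i,
            )
    return len(forward)


def match_word(
    word: IUPACWord, seq: str, pos: int, respect_mask: bool = False
) -> bool:
    """True iff every sequence base at ``pos`` falls in the IUPAC class of the
    corresponding word letter.

    Matching is case-insensitive; with ``respect_mask=True``, lowercase
    (soft-masked) sequence bases never match.  Ambiguous sequence bases match
    only letters whose class contains their whole class (subset semantics).
    """
    if pos < 0 or pos + len(word) > len(seq):
        raise MotifError(
            f"word of length {len(word)} does not fit at position {pos} in sequence of length {len(seq)}"
        )
    window = seq[pos : pos + len(word)]
    for w, b in zip(word.letters.upper(), window):
        if respect_mask and b.islower():
            return False
        bu = b.upper()
        if bu not in IUPAC_CODES:
            raise MotifError(f"invalid IUPAC letter {b!r} in sequence")
        if not IUPAC_CODES[bu] <= IUPAC_CODES[w]:
            return False
    return True


def _effective_pax(motif: CompositeMotif) -> IUPACWord:
    if motif.pax_orientation == "flipped":
        return IUPACWord(reverse_complement(motif.pax_word.letters).upper())
    return motif.pax_word


def _scan_one_strand(motif: CompositeMotif, seq: str, respect_mask: bool):
    pax = _effective_pax(motif)
    span = motif.span_length
    pax_off = len(motif.sox_word) + motif.gap
    for pos in range(len(seq) - span + 1):
        if match_word(motif.sox_word, seq, pos, respect_mask) and match_word(
            pax, seq, pos + pax_off, respect_mask
        ):
            yield pos


def scan_composite(
    motif: CompositeMotif,
    seq: str,
    both_strands: bool = True,
    seq_id: str = "seq",
    respect_mask: bool = False,
) -> list[MotifHit]:
    """Find all composite sox-gap-pax matches in a sequence.

    Both half-sites must match on the same strand with the sox word first
    (in that strand's reading direction).  Minus-strand hits are reported in
    forward-strand coordinates with ``strand='-'``.  Output is sorted by
    forward-strand span, '+' before '-' at ties.
    """
    _validate_iupac(seq)
    hits = [
        MotifHit(seq_id, pos, "+", (pos, pos + motif.span_length))
        for pos in _scan_one_strand(motif, seq, respect_mask)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        n, span = len(seq), motif.span_length
        for pos in _scan_one_strand(motif, rc, respect_mask):
            start = n - pos - span
            hits.append(
                MotifHit(seq_id, n - pos - len(motif.sox_word), "-", (start, start + span))
            )
    return sorted(hits, key=MotifHit.sort_key)


def enumerate_spacer_variants(
    template: str,
    sox_span: tuple[int, int],
    pax_span: tuple[int, int],
    deltas: list[int],
    insert_bases: str | None = None,
) -> list[tuple[int, str]]:
    """Generate spacer-length variants of a composite element.

    Positive deltas insert ``|delta|`` bases at the half-site junction (the
    leading bases of ``insert_bases``, which must be supplied explicitly —
    there is no default filler); negative deltas delete ``|delta|`` spacer
    bases adjacent to the pax half-site and are refused if they would cut
    into a half-site.  Both half-site subsequences are preserved verbatim in
    every variant; variant length is ``len(template) + delta``.
    """
    _validate_iupac(template, "template")
    s0, s1 = sox_span
    p0, p1 = pax_span
    if not (0 <= s0 < s1 <= p0 < p1 <= len(template)):
        raise MotifError(
            f"invalid half-site spans sox={sox_span}, pax={pax_span} "
            f"for template of length {len(template)}"
        )
    gap = p0 - s1
    out = []
    for delta in deltas:
        if delta == 0:
            out.append((0, template))
            continue
        if delta > 0:
            if insert_bases is None:
                raise MotifError(
                    "positive spacer deltas require explicit insert_bases (no silent default)"
                )
            _validate_iupac(insert_bases, "insert_bases")
            if len(insert_bases) < delta:
                raise MotifError(
                    f"insert_bases provides {len(insert_bases)} bases, delta +{delta} needs {delta}"
                )
            out.append((delta, template[:p0] + insert_bases[:delta] + template[p0:]))
        else:
            if -delta > gap:
                raise MotifError(
                    f"delta {delta} would delete into a half-site (spacer is only {gap} bp)"
                )
            out.append((delta, template[: p0 + delta] + template[p0:]))
    return out


def enumerate_switch_mutants(
    wild_halfsite: str,
    consensus_halfsite: str,
    positions: SwitchPositionSet,
    max_order: int,
) -> list[SwitchVariant]:
    """All consensus substitutions of the switch positions, up to ``max_order``
    positions at a time.

    Each variant carries the conventional label built from the consensus base
    and 1-based position of every substituted site (e.g. "G8C9", "T3G8C9").
    A position where wild and consensus already agree triggers a warning but
    the subset is still emitted.
    """
    _validate_iupac(wild_halfsite, "wild half-site")
    _validate_iupac(consensus_halfsite, "consensus half-site")
    if len(wild_halfsite) != len(consensus_halfsite):
        raise MotifError("wild and consensus half-sites must have equal length")
    pos_list = positions.sorted()
    if pos_list[-1] > len(wild_halfsite):
        raise MotifError(
            f"switch position {pos_list[-1]} exceeds half-site length {len(wild_halfsite)}"
        )
    for p in pos_list:
        if wild_halfsite[p - 1].upper() == consensus_halfsite[p - 1].upper():
            warnings.warn(
                f"switch position {p}: wild and consensus bases already agree "
                f"({wild_halfsite[p - 1]!r})",
                stacklevel=2,
            )
    variants = []
    for order in range(1, max_order + 1):
        for subset in itertools.combinations(pos_list, order):
            seq = list(wild_halfsite)
            for p in subset:
                seq[p - 1] = consensus_halfsite[p - 1]
            label = "".join(f"{consensus_halfsite[p - 1].upper()}{p}" for p in subset)
            variants.append(SwitchVariant(label=label, positions=subset, sequence="".join(seq)))
    return variants


def build_flipped_composite(motif: CompositeMotif) -> CompositeMotif:
    """Toggle the pax word's orientation (same sox word and gap)."""
    flipped = "flipped" if motif.pax_orientation == "forward" else "forward"
    return replace(motif, pax_orientation=flipped)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position A/C/G/T counts of a motif (JASPAR-style PFM)."""

    counts: np.ndarray  # shape (4, length), rows in A,C,G,T order
    motif_id: str

    BASES = "ACGT"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifError(f"PFM counts must be 4 x L, got shape {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise MotifError("PFM counts must be finite and non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise MotifError("every PFM column must have a positive total")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[1]

    def majority_base(self, position: int) -> str:
        """Most frequent base in a 0-based column (ties: first in A,C,G,T order)."""
        return self.BASES[int(np.argmax(self.counts[:, position]))]

    def consensus(self) -> str:
        return "".join(self.majority_base(i) for i in range(len(self)))


def parse_pfm(text: str) -> PositionFrequencyMatrix:
    """Parse a JASPAR-format PFM (``>ID name`` header, ``A [ ... ]`` rows)."""
    try:
        motif = bio_motifs.read(io.StringIO(text), "jaspar")
    except Exception as err:
        raise MotifError(f"failed to parse JASPAR PFM: {err}") from err
    try:
        columns = [[motif.counts[b][i] for b in "ACGT"] for i in range(motif.length)]
    except (KeyError, IndexError) as err:
        raise MotifError(f"JASPAR PFM is missing a base row: {err}") from err
    counts = np.asarray(columns, dtype=float).T
    motif_id = motif.matrix_id or motif.name or "PFM"
    return PositionFrequencyMatrix(counts=counts, motif_id=motif_id)


def information_content(
    pfm: PositionFrequencyMatrix, pseudocount: float = 0.25
) -> np.ndarray:
    """Per-position information content in bits: 2 minus the Shannon entropy
    of the pseudocount-smoothed base frequencies.

    Bounded in [0, 2] at pseudocount 0 and shrinking toward 0 (the uniform
    value) as the pseudocount grows.  The default 0.25 per base suits real
    count matrices; pass 0 for exact values on toy matrices.
    """
    if pseudocount < 0:
        raise MotifError("pseudocount must be >= 0")
    counts = pfm.counts + pseudocount
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return 2.0 + plogp.sum(axis=0)


def high_ic_deviations(
    pfm: PositionFrequencyMatrix,
    halfsite: str,
    ic_threshold: float,
    pseudocount: float = 0.25,
) -> frozenset[int]:
    """Positions (1-based) where the PFM is informative yet the half-site
    deviates: IC >= threshold and the half-site base differs from the PFM's
    majority base.  This is how candidate nucleotide-switch positions are
    located on a degenerate half-site.

    Returns a frozenset (possibly empty, with a warning, when the half-site
    already matches the consensus everywhere informative); wrap it in
    :class:`SwitchPositionSet` for downstream mutagenesis."""
    _validate_iupac(halfsite, "half-site")
    if len(halfsite) != len(pfm):
        raise MotifError(
            f"half-site length {len(halfsite)} does not match PFM length {len(pfm)}"
        )
    ic = information_content(pfm, pseudocount=pseudocount)
    hits = {
        i + 1
        for i in range(len(pfm))
        if ic[i] >= ic_threshold and halfsite[i].upper() != pfm.majority_base(i)
    }
    if not hits:
        warnings.warn("no high-information deviating positions found", stacklevel=2)
    return frozenset(hits)


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA file into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def hits_to_bed(hits: list[MotifHit], name: str = "composite") -> str:
    """Render hits as BED6 text (name = motif id + orientation, score 0)."""
    lines = [
        f"{h.seq_id}\t{h.matched_span[0]}\t{h.matched_span[1]}\t{name}\t0\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
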