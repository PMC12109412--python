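"""Oligonucleotide parsing, annealing and GC-skew/content analysis.

This module handles the sequence-level side of duplex cyclization
constructs: single strands (DNA or RNA) carrying dye/biotin labels, the
antiparallel duplexes they anneal into (duplex length, 5' overhangs,
looping-competent circumference), and strand-asymmetry statistics used
to characterize R-loop-prone promoter regions.

Conventions
-----------
Residues are stored 5'->3' in upper case; positions are 1-based.  GC skew
is (G - C) / (G + C) counted on a chosen strand orientation: the skew of
a strand is the negative of the skew of its complement, so the statistic
is reported together with an explicit ``orientation`` flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Oligo",
    "AnnealedDuplex",
    "ParseError",
    "NoDuplexError",
    "UndefinedSkewError",
    "parse_oligo",
    "reverse_complement",
    "anneal",
    "gc_skew",
    "gc_content",
    "read_fasta",
    "write_fasta",
]

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {
    "DNA": str.maketrans("ACGT", "TGCA"),
    "RNA": str.maketrans("ACGU", "UGCA"),
}

# Watson-Crick pairs across DNA/DNA, DNA/RNA and RNA/RNA duplexes.
_WC_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
)

# Dye prefixes recognized on the 5' end of a printed sequence.
_DYE_PREFIX = re.compile(r"^(Cy3|Cy5|Alexa\d+|FAM|TAMRA)-", re.IGNORECASE)


class ParseError(ValueError):
    """Raised when an annotated sequence string cannot be parsed."""


class NoDuplexError(ValueError):
    """Raised when two oligos share no antiparallel register of the
    required minimum contiguous Watson-Crick length."""


class UndefinedSkewError(ValueError):
    """Raised when GC skew is requested for a sequence with G + C = 0."""


@dataclass(frozen=True)
class Oligo:
    """A single labelled oligonucleotide strand, 5'->3'.

    ``labels`` is a tuple of ``(tag, position)`` pairs with 1-based
    residue positions; a 5'-terminal dye is attached at position 1.
    """

    id: str
    residues: str
    kind: str  # "DNA" | "RNA"
    labels: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("DNA", "RNA"):
            raise ValueError(f"kind must be 'DNA' or 'RNA', got {self.kind!r}")
        if len(self.residues) < 1:
            raise ValueError("oligo must contain at least one residue")
        alphabet = DNA_ALPHABET if self.kind == "DNA" else RNA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"residues {sorted(bad)} not allowed for kind {self.kind}"
            )
        for tag, pos in self.labels:
            if not 1 <= pos <= len(self.residues):
                raise ValueError(
                    f"label {tag!r} position {pos} outside 1..{len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnealedDuplex:
    """Two antiparallel strands in their maximal contiguous WC register.

    ``pairing`` maps 1-based positions of ``strand1`` onto positions of
    ``strand2``; indices on strand1 ascend while indices on strand2
    descend (antiparallel).  ``overhang1``/``overhang2`` are the lengths
    of the unpaired 5'-terminal runs.  When the two overhangs are
    mutually complementary, intramolecular hybridization can trap the
    molecule in a looped state, and ``circumference`` is the size of the
    resulting circle (duplex length + overhang length); otherwise it is
    ``None``.
    """

    strand1: Oligo
    strand2: Oligo
    pairing: tuple[tuple[int, int], ...]
    duplex_len: int
    overhang1: int
    overhang2: int
    overhangs_complementary: bool

    @property
    def circumference(self) -> int | None:
        if self.overhangs_complementary and self.overhang1 == self.overhang2:
            return self.duplex_len + self.overhang1
        return None


def _infer_kind(sequence: str) -> str:
    has_u = "U" in sequence
    has_t = "T" in sequence
    if has_u and has_t:
        raise ParseError("sequence mixes T and U; cannot infer kind")
    return "RNA" if has_u else "DNA"


def parse_oligo(text: str, kind: str | None = None, oligo_id: str = "oligo") -> Oligo:
    """Parse an annotated sequence string into an :class:`Oligo`.

    Recognized annotations, following how synthesis vendors and papers
    print labelled oligos:

    * a 5' dye prefix such as ``Cy5-`` or ``Cy3-`` -> label at position 1;
    * a ``biotin-`` prefix -> 5' biotin label at position 1;
    * a residue wrapped in markdown bold (``**T**``) -> internal
      biotin-dT; the residue itself counts as an ordinary base for all
      sequence computations.

    Parsing is case-insensitive; whitespace is ignored.  ``kind`` may be
    given explicitly or inferred from the presence of U vs T.
    """
    work = "".join(text.split())
    labels: list[tuple[str, int]] = []

    m = _DYE_PREFIX.match(work)
    if m:
        labels.append((m.group(1), 1))
        work = work[m.end():]
    elif work.lower().startswith("biotin-"):
        labels.append(("biotin", 1))
        work = work[len("biotin-"):]

    residues: list[str] = []
    i = 0
    while i < len(work):
        if work.startswith("**", i):
            end = work.find("**", i + 2)
            if end == -1 or end == i + 2:
                raise ParseError(f"unterminated bold marker at position {i + 1}")
            for ch in work[i + 2 : end]:
                residues.append(ch.upper())
                labels.append(("biotin", len(residues)))
            i = end + 2
            continue
        ch = work[i].upper()
        if ch not in "ACGTU":
            raise ParseError(
                f"unknown character {work[i]!r} at position {len(residues) + 1}"
            )
        residues.append(ch)
        i += 1

    seq = "".join(residues)
    if not seq:
        raise ParseError("empty sequence")
    if kind is None:
        kind = _infer_kind(seq)
    try:
        return Oligo(id=oligo_id, residues=seq, kind=kind, labels=tuple(labels))
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def reverse_complement(oligo: Oligo) -> Oligo:
    """Reverse complement, preserving kind; labels are re-indexed onto
    the complementary strand positions."""
    n = len(oligo.residues)
    seq = oligo.residues.translate(_COMPLEMENT[oligo.kind])[::-1]
    labels = tuple((tag, n - pos + 1) for tag, pos in oligo.labels)
    return replace(oligo, residues=seq, labels=labels)


def _is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC_PAIRS


def _mutually_complementary(seg1: str, seg2: str) -> bool:
    """Antiparallel complementarity of two equal-length 5' overhangs."""
    if len(seg1) != len(seg2) or not seg1:
        return False
    return all(_is_wc(a, b) for a, b in zip(seg1, seg2[::-1]))


def anneal(o1: Oligo, o2: Oligo, min_duplex_len: int = 10) -> AnnealedDuplex:
    """Find the ungapped antiparallel register maximizing contiguous
    Watson-Crick pairing between two strands.

    The search slides strand1 (5'->3') against the reverse of strand2 and
    keeps the longest contiguous run of WC pairs over all offsets.  Ties
    are broken toward the earliest register on strand1.  Raises
    :class:`NoDuplexError` if the best run is shorter than
    ``min_duplex_len``.
    """
    s1, s2 = o1.residues, o2.residues
    r2 = s2[::-1]
    n1, n2 = len(s1), len(r2)

    best_len = 0
    best = None  # (start1 in s1, start in r2)
    for shift in range(-(n2 - 1), n1):
        run = 0
        run_start = 0
        for i in range(max(0, shift), min(n1, n2 + shift)):
            j = i - shift
            if _is_wc(s1[i], r2[j]):
                if run == 0:
                    run_start = i
                run += 1
                if run > best_len:
                    best_len = run
                    best = (run_start, run_start - shift)
            else:
                run = 0

    if best is None or best_len < min_duplex_len:
        raise NoDuplexError(
            f"no antiparallel register with >= {min_duplex_len} contiguous "
            f"Watson-Crick pairs (best run: {best_len})"
        )

    start1, startr = best
    # r2 index j corresponds to s2 position (1-based) n2 - j.
    pairing = tuple(
        (start1 + k + 1, n2 - (startr + k)) for k in range(best_len)
    )
    overhang1 = start1  # unpaired 5' run on strand1
    # strand2's 5' end maps to the high end of r2.
    overhang2 = n2 - (startr + best_len)
    compl = _mutually_complementary(s1[:overhang1], s2[:overhang2])
    return AnnealedDuplex(
        strand1=o1,
        strand2=o2,
        pairing=pairing,
        duplex_len=best_len,
        overhang1=overhang1,
        overhang2=overhang2,
        overhangs_complementary=compl,
    )


def gc_skew(oligo: Oligo, orientation: str = "as-given") -> float:
    """Strand-specific GC skew, (G - C)/(G + C).

    ``orientation="as-given"`` counts on the stored strand;
    ``"complement"`` counts on its complement (equivalently, negates the
    as-given value).  Positive skew marks the G-rich strand.  Note that
    C-rich template strands of R-loop-forming promoter regions are
    conventionally summarized by the skew of their G-rich complement.
    """
    if orientation not in ("as-given", "complement"):
        raise ValueError(f"unknown orientation {orientation!r}")
    g = oligo.residues.count("G")
    c = oligo.residues.count("C")
    if g + c == 0:
        raise UndefinedSkewError("GC skew undefined: sequence contains no G or C")
    skew = (g - c) / (g + c)
    return -skew if orientation == "complement" else skew


def gc_content(oligo: Oligo) -> float:
    """Fraction of residues that are G or C."""
    g = oligo.residues.count("G")
    c = oligo.residues.count("C")
    return (g + c) / len(oligo.residues)


# ---------------------------------------------------------------------------
# FASTA I/O: labels carried in the description line as key=value tokens,
# e.g. ">rdh53_dna kind=DNA labels=Cy5:1,biotin:30".

def _record(oligo: Oligo) -> SeqRecord:
    desc = [f"kind={oligo.kind}"]
    if oligo.labels:
        desc.append(
            "labels=" + ",".join(f"{tag}:{pos}" for tag, pos in oligo.labels)
        )
    return SeqRecord(Seq(oligo.residues), id=oligo.id, description=" ".join(desc))


def write_fasta(oligos: Iterable[Oligo], path: str | Path) -> None:
    SeqIO.write([_record(o) for o in oligos], str(path), "fasta")


def read_fasta(path: str | Path) -> list[Oligo]:
    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kind = None
        labels: tuple[tuple[str, int], ...] = ()
        for token in rec.description.split()[1:]:
            if token.startswith("kind="):
                kind = token[5:]
            elif token.startswith("labels="):
                labels = tuple(
                    (t.split(":")[0], int(t.split(":")[1]))
                    for t in token[7:].split(",")
                    if t
                )
        seq = str(rec.seq).upper()
        if kind is None:
            kind = _infer_kind(seq)
        oligos.append(Oligo(id=rec.id, residues=seq, kind=kind, labels=labels))
    return oligos
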