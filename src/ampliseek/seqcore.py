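"""Core sequence types, IUPAC degeneracy, translation, ORF finding and FASTA/FASTQ I/O.

All coordinates are 0-based, half-open. Strand is recorded explicitly via
signed frame numbers; there is no implicit orientation convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucSeq",
    "QualRead",
    "PepSeq",
    "Orf",
    "AlphabetError",
    "IUPAC_EXPAND",
    "iupac_expand",
    "iupac_match",
    "iupac_code_for",
    "degeneracy",
    "reverse_complement",
    "translate",
    "translate_six_frames",
    "find_orfs",
    "longest_orf",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_peptides",
    "write_peptides",
]


class AlphabetError(ValueError):
    """Raised for characters outside the declared alphabet."""


#: IUPAC nucleotide ambiguity codes and their expansions.
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Minimal IUPAC code for each set of concrete bases.
_CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPAND.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

NUC_ALPHABET = frozenset(IUPAC_EXPAND)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Standard genetic code (DNA codons, '*' = stop).
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over the IUPAC alphabet."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        up = self.bases.upper()
        if not up:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(up) - NUC_ALPHABET
        if bad:
            raise AlphabetError(f"invalid nucleotide(s) {sorted(bad)} in {self.id!r}")
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    def revcomp(self) -> "NucSeq":
        return NucSeq(self.id, reverse_complement(self.bases))


@dataclass(frozen=True)
class QualRead:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        up = self.bases.upper()
        if len(up) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(up)} bases but {len(self.quals)} quality scores"
            )
        bad = set(up) - frozenset("ACGTN")
        if bad:
            raise AlphabetError(f"invalid base(s) {sorted(bad)} in read {self.id!r}")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"negative quality score in read {self.id!r}")
        object.__setattr__(self, "bases", up)
        object.__setattr__(self, "quals", tuple(self.quals))

    def __len__(self) -> int:
        return len(self.bases)

    def error_probs(self) -> list[float]:
        return [10.0 ** (-q / 10.0) for q in self.quals]


@dataclass(frozen=True)
class PepSeq:
    """A peptide sequence; ``residues`` may carry one trailing '*' stop marker."""

    id: str
    residues: str
    amidated: bool = False

    def __post_init__(self) -> None:
        up = self.residues.upper()
        core = up[:-1] if up.endswith("*") else up
        if "*" in core:
            raise ValueError(f"internal stop in peptide {self.id!r}")
        bad = set(core) - (AA_ALPHABET | {"X"})
        if bad:
            raise AlphabetError(f"invalid residue(s) {sorted(bad)} in {self.id!r}")
        object.__setattr__(self, "residues", up)

    @property
    def sequence(self) -> str:
        """Residues without any trailing stop marker."""
        return self.residues.rstrip("*")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """An open reading frame located on a nucleotide sequence.

    ``nt_start``/``nt_end`` are forward-strand coordinates of the encoding
    region regardless of frame sign; for negative frames the reverse
    complement of that slice encodes ``protein``.
    """

    frame: int
    nt_start: int
    nt_end: int
    protein: PepSeq

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF length not divisible by 3")


# ---------------------------------------------------------------------------
# IUPAC operations


def iupac_expand(code: str) -> frozenset[str]:
    """Expand a single IUPAC symbol to its set of concrete bases."""
    try:
        return IUPAC_EXPAND[code.upper()]
    except KeyError:
        raise AlphabetError(f"unknown IUPAC symbol {code!r}") from None


def iupac_match(a: str, b: str) -> bool:
    """True iff the expansions of two IUPAC symbols intersect (symmetric)."""
    return bool(iupac_expand(a) & iupac_expand(b))


def iupac_code_for(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of concrete bases."""
    key = frozenset(b.upper() for b in bases)
    bad = key - frozenset("ACGT")
    if bad or not key:
        raise AlphabetError(f"cannot encode base set {sorted(key)}")
    return _CODE_FOR[key]


def degeneracy(seq: str | NucSeq) -> int:
    """Number of concrete sequences encoded by a degenerate sequence."""
    bases = seq.bases if isinstance(seq, NucSeq) else seq.upper()
    return math.prod(len(iupac_expand(b)) for b in bases)


def reverse_complement(bases: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(bases.upper()))
    except KeyError as exc:
        raise AlphabetError(f"cannot complement {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Translation and ORFs


def _translate_codon(codon: str) -> str:
    """Translate one (possibly degenerate) codon; 'X' unless all expansions agree."""
    if codon in CODON_TABLE:
        return CODON_TABLE[codon]
    residues = {
        CODON_TABLE[b1 + b2 + b3]
        for b1 in iupac_expand(codon[0])
        for b2 in iupac_expand(codon[1])
        for b3 in iupac_expand(codon[2])
    }
    return residues.pop() if len(residues) == 1 else "X"


def translate(bases: str, frame: int = 1) -> str:
    """Translate ``bases`` in the given signed frame; trailing partial codons dropped.

    Stops appear as '*' characters (they are not translation terminators here).
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"invalid frame {frame}")
    seq = bases.upper() if frame > 0 else reverse_complement(bases)
    offset = abs(frame) - 1
    seq = seq[offset:]
    return "".join(
        _translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def translate_six_frames(seq: NucSeq) -> list[PepSeq]:
    """Translate in all six frames; always returns exactly 6 peptides.

    Internal stop codons are rendered as 'X': downstream profile scanning
    treats whole frames as plain residue strings, and PepSeq only admits a
    single trailing '*'.
    """
    out = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(seq.bases, frame).replace("*", "X")
        out.append(PepSeq(f"{seq.id}|frame{frame:+d}", prot or "X"))
    return out


def find_orfs(seq: NucSeq, require_start: bool = True, min_aa: int = 1) -> list[Orf]:
    """Enumerate start/stop-bounded ORFs in all six frames.

    An ORF runs from a start codon (or the first in-frame position when
    ``require_start`` is false) to the next stop codon; ORFs without a stop
    extend to the frame end. Proteins shorter than ``min_aa`` are dropped.
    """
    n = len(seq.bases)
    orfs: list[Orf] = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(seq.bases, frame)
        segments = _orf_segments(prot, require_start)
        for aa_start, aa_end, has_stop in segments:
            plen = aa_end - aa_start
            if plen < min_aa:
                continue
            protein = prot[aa_start:aa_end] + ("*" if has_stop else "")
            nt_len = 3 * (plen + (1 if has_stop else 0))
            offset = abs(frame) - 1
            if frame > 0:
                nt_start = offset + 3 * aa_start
                nt_end = nt_start + nt_len
            else:
                # coordinates on the forward strand for the revcomp-encoded region
                nt_end = n - offset - 3 * aa_start
                nt_start = nt_end - nt_len
            orfs.append(
                Orf(frame, nt_start, nt_end, PepSeq(f"{seq.id}|orf", protein))
            )
    return orfs


def _orf_segments(prot: str, require_start: bool) -> list[tuple[int, int, bool]]:
    """(aa_start, aa_end, stop_included) segments of a raw frame translation."""
    segments = []
    i = 0
    n = len(prot)
    while i < n:
        if prot[i] == "*":
            i += 1
            continue
        if require_start:
            while i < n and prot[i] != "M":
                if prot[i] == "*":
                    break
                i += 1
            if i >= n or prot[i] == "*":
                if i < n and prot[i] == "*":
                    i += 1
                continue
        start = i
        while i < n and prot[i] != "*":
            i += 1
        has_stop = i < n
        segments.append((start, i, has_stop))
        if has_stop:
            i += 1
    return segments


_FRAME_ORDER = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}


def longest_orf(seq: NucSeq, require_start: bool = True, min_aa: int = 1) -> Orf | None:
    """Longest ORF over all six frames; ties broken by frame order then leftmost.

    Returns ``None`` when no ORF reaches ``min_aa`` residues.
    """
    orfs = find_orfs(seq, require_start=require_start, min_aa=min_aa)
    if not orfs:
        return None
    return min(
        orfs, key=lambda o: (-len(o.protein), _FRAME_ORDER[o.frame], o.nt_start)
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[NucSeq]:
    return [NucSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, seqs: Iterable[NucSeq], width: int = 70) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> list[QualRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            QualRead(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(path: str | Path, reads: Iterable[QualRead]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_peptides(path: str | Path) -> list[PepSeq]:
    """Read a protein FASTA; a '-NH2' suffix on the sequence marks amidation."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        amidated = False
        if seq.upper().endswith("-NH2"):
            seq, amidated = seq[:-4], True
        out.append(PepSeq(rec.id, seq, amidated=amidated))
    return out


def write_peptides(path: str | Path, peps: Iterable[PepSeq]) -> None:
    with open(path, "w") as handle:
        for p in peps:
            suffix = "-NH2" if p.amidated else ""
            handle.write(f">{p.id}\n{p.sequence}{suffix}\n")


def iter_gapped_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, gapped sequence) pairs from an aligned FASTA ('-' allowed)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
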