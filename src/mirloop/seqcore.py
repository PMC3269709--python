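"""Sequence primitives shared by every stage of the stem-loop RT-PCR workflow.

Provides a validated nucleotide record (:class:`NucSeq`), reverse complement
and RNA/DNA interconversion, FASTA input/output, and global pairwise identity
scoring (Needleman-Wunsch via :mod:`Bio.Align`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "DNA"
RNA = "RNA"

_BASES = {DNA: frozenset("ACGT"), RNA: frozenset("ACGU")}
_COMPLEMENT = {
    DNA: str.maketrans("ACGT", "TGCA"),
    RNA: str.maketrans("ACGU", "UGCA"),
}


class AlphabetError(ValueError):
    """Sequence contains characters outside its declared alphabet."""


class FastaParseError(ValueError):
    """FASTA input is empty, has duplicate ids, or invalid residues."""


@dataclass(frozen=True)
class NucSeq:
    """A named, validated nucleotide sequence.

    Attributes
    ----------
    id : str
        Record label (for FASTA input, the header token up to the first
        whitespace, miRBase style).
    seq : str
        Uppercase sequence over ``ACGT`` (DNA) or ``ACGU`` (RNA).
    alphabet : str
        Either ``"DNA"`` or ``"RNA"``.
    """

    id: str
    seq: str
    alphabet: str = DNA

    def __post_init__(self) -> None:
        if self.alphabet not in _BASES:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        if self.seq != self.seq.upper():
            raise AlphabetError(f"record {self.id!r}: sequence must be uppercase")
        bad = set(self.seq) - _BASES[self.alphabet]
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid {self.alphabet} characters {sorted(bad)}"
            )

    @classmethod
    def from_string(cls, id: str, seq: str, alphabet: str | None = None) -> "NucSeq":
        """Build a record from raw text, uppercasing and inferring the alphabet.

        A sequence containing ``U`` is RNA, one containing ``T`` is DNA; a
        sequence with neither defaults to DNA. Mixing T and U is an error.
        """
        seq = seq.upper()
        if alphabet is None:
            has_t, has_u = "T" in seq, "U" in seq
            if has_t and has_u:
                raise AlphabetError(f"record {id!r}: mixes T and U")
            alphabet = RNA if has_u else DNA
        return cls(id=id, seq=seq, alphabet=alphabet)

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(s: NucSeq) -> NucSeq:
    """Reverse complement in the same alphabet; length preserved."""
    return replace(s, seq=s.seq.translate(_COMPLEMENT[s.alphabet])[::-1])


def rna_to_dna(s: NucSeq) -> NucSeq:
    """U -> T substitution; alphabet flag flipped to DNA."""
    if s.alphabet == DNA:
        return s
    return NucSeq(id=s.id, seq=s.seq.replace("U", "T"), alphabet=DNA)


def dna_to_rna(s: NucSeq) -> NucSeq:
    """T -> U substitution; alphabet flag flipped to RNA."""
    if s.alphabet == RNA:
        return s
    return NucSeq(id=s.id, seq=s.seq.replace("T", "U"), alphabet=RNA)


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a multi-record FASTA file into validated :class:`NucSeq` records.

    Order is preserved; the header up to the first whitespace becomes the id;
    sequences are uppercased and the alphabet inferred per record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    out: list[NucSeq] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(NucSeq.from_string(rec.id, str(rec.seq)))
        except AlphabetError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(records: Iterable[NucSeq], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA (wrapped at ``wrap`` columns)."""
    seqrecs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(seqrecs)


def global_identity(
    a: NucSeq,
    b: NucSeq,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity from an optimal global (Needleman-Wunsch) alignment.

    Scoring defaults to match +1 / mismatch 0 / linear gap -1; identity is
    matches divided by alignment columns (gap columns included in the
    denominator), reported to 0.1%. Among score-optimal alignments the one
    with the most matches, then the fewest columns, is used -- a
    deterministic tie-break that also makes the result symmetric in its
    arguments.
    """
    if a.alphabet != b.alphabet:
        raise AlphabetError("global_identity requires both sequences in one alphabet")
    sa, sb = a.seq, b.seq
    n, m = len(sa), len(sb)
    # cell = (score, matches, -columns), maximized lexicographically; all
    # three components are additive over alignment steps so the DP is exact
    prev = [(gap * j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(gap * i, 0, -i)]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            hit = ca == sb[j - 1]
            d = prev[j - 1]
            diag = (d[0] + (match if hit else mismatch), d[1] + hit, d[2] - 1)
            up = (prev[j][0] + gap, prev[j][1], prev[j][2] - 1)
            left = (cur[j - 1][0] + gap, cur[j - 1][1], cur[j - 1][2] - 1)
            cur.append(max(diag, up, left))
        prev = cur
    _, matches, neg_cols = prev[m]
    return round(100.0 * matches / -neg_cols, 1)


def as_dna_string(s: NucSeq | str) -> str:
    """DNA form of a sequence or raw string (convenience for primer math)."""
    if isinstance(s, NucSeq):
        return rna_to_dna(s).seq
    return s.upper().replace("U", "T")


def revcomp_str(seq: str, alphabet: str = DNA) -> str:
    """Reverse complement of a plain string (internal helper)."""
    return seq.translate(_COMPLEMENT[alphabet])[::-1]
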