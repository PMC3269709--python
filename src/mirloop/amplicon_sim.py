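"""In-silico RT and PCR: amplicon prediction, clone-read classification and
mature-sequence reconstruction.

The amplicon is bounded by the 5' ends of the forward and reverse primers
(standard PCR convention). Its top strand (forward-primer sense) is::

    prefix | covered mature | gap | anchor | revcomp(backbone tail)

so the full mature sequence -- including the gap bases covered by neither
primer -- is physically present in the product, and sequencing a clone
recovers it. Reads consisting of the two primers with no proper gap/anchor
context are classified as primer artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .assay_design import PrimerSet, StemLoopBackbone
from .seqcore import NucSeq, as_dna_string, dna_to_rna, revcomp_str


class PrimingError(ValueError):
    """Primer set and mature sequence are inconsistent (failed RT priming)."""


class ClassificationError(ValueError):
    """Operation requires a specific read but got a non-specific one."""


Segment = tuple[str, int, int]  # (label, start, end), 1-based inclusive


@dataclass(frozen=True)
class AmpliconModel:
    """Predicted PCR product with per-segment annotation."""

    mirna_id: str
    seq: str
    length: int
    segments: tuple[Segment, ...]


@dataclass(frozen=True)
class CloneCall:
    """Classification of one sequenced clone read.

    ``label`` is ``specific`` (full amplicon layout, mature recoverable),
    ``primer_only`` (forward + reverse primer with no proper mature context;
    the artifact class seen in blank controls) or ``other``. ``mismatches``
    counts differences in the template-determined non-primer region
    (anchor + backbone interior); gap bases are never counted because they
    are the unknowns the read is meant to reveal.
    """

    read_id: str
    label: str
    inferred_mature: str | None
    mismatches: int


class MatureHit(NamedTuple):
    found: bool
    start: int  # 1-based; 0 when not found
    arm: str    # "5p" | "3p" | "unknown"


def _check_assay(mature: NucSeq, ps: PrimerSet) -> str:
    """Validate primer set against a mature; return the mature DNA string."""
    mature_dna = as_dna_string(mature)
    if len(mature_dna) != ps.mature_len:
        raise PrimingError(
            f"{ps.mirna_id}: mature length {len(mature_dna)} != "
            f"cover+gap+anchor = {ps.mature_len}"
        )
    if mature_dna[-ps.anchor_len:] != ps.anchor_dna:
        raise PrimingError(
            f"{ps.mirna_id}: mature 3' end {mature_dna[-ps.anchor_len:]} does not "
            f"match RT-primer anchor {ps.anchor_dna} (RT priming would fail)"
        )
    if mature_dna[:ps.cover_len] != ps.covered:
        raise PrimingError(
            f"{ps.mirna_id}: mature 5' end does not match forward-primer cover"
        )
    return mature_dna


def simulate_cdna(mature: NucSeq, ps: PrimerSet, b: StemLoopBackbone) -> str:
    """cDNA produced by stem-loop RT: the extended RT primer.

    The RT primer anneals via its 3' anchor and is extended along the miRNA,
    so cDNA = rt_primer + revcomp(mature[1 .. L - anchor]).
    """
    mature_dna = _check_assay(mature, ps)
    template = mature_dna[: len(mature_dna) - ps.anchor_len]
    return ps.rt_primer + revcomp_str(template)


def predict_amplicon(mature: NucSeq, ps: PrimerSet, b: StemLoopBackbone) -> AmpliconModel:
    """Primer-bounded PCR product for a designed assay."""
    mature_dna = _check_assay(mature, ps)
    tail = revcomp_str(b.seq[b.rev_primer_start - 1:])
    seq = ps.forward + mature_dna[ps.cover_len:] + tail

    segments: list[Segment] = []
    pos = 0
    for label, n in (
        ("prefix", len(ps.prefix)),
        ("covered_mature", ps.cover_len),
        ("gap", ps.gap_len),
        ("anchor", ps.anchor_len),
        ("backbone_span", len(tail)),
    ):
        if n:
            segments.append((label, pos + 1, pos + n))
            pos += n
    assert pos == len(seq)
    return AmpliconModel(
        mirna_id=ps.mirna_id, seq=seq, length=len(seq), segments=tuple(segments)
    )


def _expected_layout(ps: PrimerSet, b: StemLoopBackbone) -> tuple[str, int, str]:
    """(forward, gap_len, template tail) defining the amplicon layout.

    Unlike :func:`predict_amplicon` this needs no mature sequence: everything
    except the gap bases is determined by the primers themselves.
    """
    tail = revcomp_str(b.seq[b.rev_primer_start - 1:])
    return ps.forward, ps.gap_len, ps.anchor_dna + tail


def classify_clone(
    read: NucSeq,
    ps: PrimerSet,
    b: StemLoopBackbone,
    max_mismatch: int = 0,
) -> CloneCall:
    """Classify a sequenced clone read against one assay.

    Either strand is accepted: the read is oriented by locating the forward
    primer on it or on its reverse complement (a hit on both strands is
    ambiguous and labelled ``other``). A ``specific`` read reproduces the
    amplicon layout -- forward primer, ``gap_len`` free bases, then the
    anchor and backbone tail with at most ``max_mismatch`` mismatches
    outside the primer regions. A read containing both primers without that
    context is ``primer_only``.
    """
    fwd = ps.forward
    rev_rc = revcomp_str(ps.reverse)
    read_dna = as_dna_string(read)
    if len(read_dna) < len(fwd) + len(ps.reverse):
        return CloneCall(read.id, "other", None, 0)

    fwd_top = fwd in read_dna
    rc_read = revcomp_str(read_dna)
    fwd_bot = fwd in rc_read
    if fwd_top == fwd_bot:  # absent from both strands, or ambiguous double hit
        return CloneCall(read.id, "other", None, 0)
    oriented = read_dna if fwd_top else rc_read

    p = oriented.find(fwd)
    _, gap_len, tail = _expected_layout(ps, b)
    amp_len = len(fwd) + gap_len + len(tail)
    if len(oriented) >= p + amp_len:
        window = oriented[p:p + amp_len]
        observed_tail = window[len(fwd) + gap_len:]
        # reverse-primer site (tail suffix) must match exactly; mismatch
        # budget applies to the template-determined interior only
        interior_len = len(tail) - len(ps.reverse)
        mism_interior = sum(
            1 for x, y in zip(observed_tail[:interior_len], tail[:interior_len]) if x != y
        )
        rev_ok = observed_tail[interior_len:] == tail[interior_len:]
        if rev_ok and mism_interior <= max_mismatch:
            gap = window[len(fwd):len(fwd) + gap_len]
            mature = dna_to_rna(
                NucSeq(read.id, ps.covered + gap + ps.anchor_dna, "DNA")
            ).seq
            return CloneCall(read.id, "specific", mature, mism_interior)

    if oriented.find(rev_rc, p + len(fwd)) >= 0:
        return CloneCall(read.id, "primer_only", None, 0)
    return CloneCall(read.id, "other", None, 0)


def infer_mature(read: NucSeq, ps: PrimerSet, b: StemLoopBackbone) -> str:
    """Reconstruct the cloned mature miRNA (RNA string) from a specific read.

    Forward-covered bases come from the primer design, gap bases are read
    from the clone, and the 3' anchor is the reverse complement of the RT
    primer tail.
    """
    call = classify_clone(read, ps, b)
    if call.label != "specific":
        raise ClassificationError(
            f"{read.id}: read is {call.label}, cannot infer a mature sequence"
        )
    assert call.inferred_mature is not None
    return call.inferred_mature


def contains_mature(precursor: NucSeq, mature: NucSeq) -> MatureHit:
    """Exact (RNA-normalized) search for the mature within a precursor.

    The arm is ``5p`` when the match midpoint falls in the first half of the
    precursor, ``3p`` otherwise.
    """
    if len(precursor) <= len(mature):
        raise ValueError("precursor must be longer than the mature")
    hay = as_dna_string(precursor)
    needle = as_dna_string(mature)
    i = hay.find(needle)
    if i < 0:
        return MatureHit(False, 0, "unknown")
    midpoint = i + len(needle) / 2.0
    arm = "5p" if midpoint <= len(hay) / 2.0 else "3p"
    return MatureHit(True, i + 1, arm)
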