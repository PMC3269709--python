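"""Stem-loop RT-qPCR primer-set construction and cross-reactivity screening.

A stem-loop assay extends a short mature miRNA into a PCR-amplifiable cDNA:
the RT primer is a universal self-complementary backbone plus a 3' anchor
(default 6 nt) complementary to the miRNA 3' end; the forward primer carries
a 5' Tm-boosting prefix plus the miRNA 5' end; the reverse primer is a
substring of the backbone. Bases covered by neither primer (the "gap") are
what lets sequencing distinguish genuine miRNA amplicons from primer-only
artifacts, so a zero gap is rejected by default.

Two backbone presets are built in (``group1``/``group2``) together with the
reference assays and mature sequences for miR-14, miR-2a and bantam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import NucSeq, as_dna_string, revcomp_str


class DesignError(ValueError):
    """Assay construction failed (constraints unsatisfiable or bad inputs)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StemLoopBackbone:
    """Universal (miRNA-independent) portion of the stem-loop RT primer.

    ``rev_primer_start``/``rev_primer_len`` locate the reverse primer inside
    the backbone, 1-based inclusive.
    """

    id: str
    seq: str
    rev_primer_start: int
    rev_primer_len: int

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise DesignError(f"backbone {self.id!r}: not a DNA string")
        if not (1 <= self.rev_primer_start and
                self.rev_primer_start + self.rev_primer_len - 1 <= len(self.seq)):
            raise DesignError(
                f"backbone {self.id!r}: reverse primer coordinates out of range"
            )

    @property
    def reverse_primer(self) -> str:
        i = self.rev_primer_start - 1
        return self.seq[i:i + self.rev_primer_len]


@dataclass(frozen=True)
class PrimerSet:
    """One mature miRNA's RT/forward/reverse primers plus design parameters."""

    mirna_id: str
    rt_primer: str
    forward: str
    reverse: str
    backbone_id: str
    anchor_len: int
    cover_len: int
    gap_len: int
    prefix: str

    @property
    def covered(self) -> str:
        """DNA form of the mature 5' bases embedded in the forward primer."""
        return self.forward[len(self.prefix):]

    @property
    def anchor_dna(self) -> str:
        """DNA form of the mature 3' anchor (revcomp of the RT primer tail)."""
        return revcomp_str(self.rt_primer[-self.anchor_len:])

    @property
    def mature_len(self) -> int:
        return self.cover_len + self.gap_len + self.anchor_len


@dataclass(frozen=True)
class DesignConfig:
    """Tunable assay-design parameters.

    ``cover_len``/``prefix`` of ``None`` mean automatic selection: cover is
    maximized subject to ``min_gap``; the prefix is found by a seeded random
    search over 4-16 nt candidates whose full-primer Tm falls in ``tm_range``.
    """

    anchor_len: int = 6
    cover_len: int | None = None
    prefix: str | None = None
    tm_range: tuple[float, float] = (52.0, 62.0)
    seed: int = 0
    min_gap: int = 1
    prefix_len_range: tuple[int, int] = (4, 16)
    search_budget: int = 5000

    def __post_init__(self) -> None:
        if self.anchor_len < 4:
            raise DesignError("anchor_len must be >= 4")
        if self.tm_range[0] >= self.tm_range[1]:
            raise DesignError("Tm range must satisfy low < high")
        if self.min_gap < 0:
            raise DesignError("min_gap must be >= 0")


@dataclass(frozen=True)
class BackboneReport:
    k_terminal_complement: int
    rev_primer_ok: bool

    @property
    def is_valid(self) -> bool:
        return self.k_terminal_complement >= 6 and self.rev_primer_ok


# ---------------------------------------------------------------------------
# presets: the two published design groups and their reference assays
# ---------------------------------------------------------------------------

GROUP1 = StemLoopBackbone(
    id="group1",
    seq="GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC",
    rev_primer_start=11,
    rev_primer_len=16,
)

GROUP2 = StemLoopBackbone(
    id="group2",
    seq="GCACTTCAGTGTCGTGGTCAGTGACGGCAATTTGAAGTGC",
    rev_primer_start=1,
    rev_primer_len=32,
)

BACKBONES: Mapping[str, StemLoopBackbone] = {"group1": GROUP1, "group2": GROUP2}

# Reference mature sequences for the three conserved assay targets. These are
# the D. melanogaster matures, to which the cloned S. litura sequences are
# identical; each is fully consistent with the published primer sets below.
REFERENCE_MATURES: Mapping[str, NucSeq] = {
    "sli-miR-14": NucSeq("sli-miR-14", "UCAGUCUUUUUCUCUCUCCUA", "RNA"),
    "sli-miR-2a": NucSeq("sli-miR-2a", "UAUCACAGCCAGCUUUGAUGAGC", "RNA"),
    "sli-bantam": NucSeq("sli-bantam", "UGAGAUCAUUUUGAAAGCUGAUU", "RNA"),
}

# Published forward-primer prefixes and cover lengths per design group.
GROUP1_DESIGNS: Mapping[str, dict] = {
    "sli-miR-14": {"prefix": "CGGGGC", "cover_len": 13},
    "sli-miR-2a": {"prefix": "GCCAG", "cover_len": 14},
    "sli-bantam": {"prefix": "GCCCCG", "cover_len": 13},
}
GROUP2_DESIGNS: Mapping[str, dict] = {
    "sli-miR-14": {"prefix": "CGCACGACGCATCAG", "cover_len": 13},
    "sli-miR-2a": {"prefix": "CGACACACACCATCAG", "cover_len": 14},
    "sli-bantam": {"prefix": "CGCATCGTAGCATCGC", "cover_len": 13},
}


def reference_assay(mirna_id: str, backbone_id: str = "group2") -> PrimerSet:
    """Build one of the published assays from its preset parameters."""
    designs = {"group1": GROUP1_DESIGNS, "group2": GROUP2_DESIGNS}[backbone_id]
    if mirna_id not in designs:
        raise DesignError(f"no reference assay for {mirna_id!r}")
    cfg = DesignConfig(**designs[mirna_id])
    return design_assay(REFERENCE_MATURES[mirna_id], BACKBONES[backbone_id], cfg)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate_backbone(b: StemLoopBackbone) -> BackboneReport:
    """Check terminal self-complementarity and the reverse-primer substring.

    Returns the largest ``k`` such that the backbone's 5' k-mer is the
    reverse complement of its 3' k-mer (the stem of the folded RT primer);
    validation fails when ``k < 6``.
    """
    k = 0
    for kk in range(1, len(b.seq) // 2 + 1):
        if b.seq[:kk] == revcomp_str(b.seq[-kk:]):
            k = kk
    expected = b.seq[b.rev_primer_start - 1:b.rev_primer_start - 1 + b.rev_primer_len]
    return BackboneReport(k_terminal_complement=k,
                          rev_primer_ok=expected == b.reverse_primer)


def design_rt_primer(mature: NucSeq, b: StemLoopBackbone, anchor_len: int = 6) -> str:
    """Backbone plus the reverse complement of the mature 3' anchor (DNA)."""
    if len(mature) < anchor_len + 1:
        raise DesignError(
            f"{mature.id}: mature length {len(mature)} too short for "
            f"anchor_len {anchor_len}"
        )
    anchor = as_dna_string(mature)[-anchor_len:]
    return b.seq + revcomp_str(anchor)


def derive_reverse_primer(b: StemLoopBackbone) -> str:
    """The reverse primer is the backbone substring at its recorded site."""
    return b.reverse_primer


def melting_temp(primer: str, dnac_nM: float = 250.0, Na_mM: float = 50.0) -> float:
    """Nearest-neighbor melting temperature (degC) of a DNA oligo.

    Uses the SantaLucia unified nearest-neighbor parameters via Biopython's
    ``Tm_NN`` with ``dnac_nM`` primer (default 250 nM, no complement excess)
    and ``Na_mM`` monovalent salt (default 50 mM). Deterministic.
    """
    if len(primer) < 8:
        raise DesignError("melting_temp requires length >= 8")
    return float(_mt.Tm_NN(Seq(primer), dnac1=dnac_nM, dnac2=0.0, Na=Na_mM))


def design_forward_primer(
    mature: NucSeq,
    cfg: DesignConfig,
    backbone: StemLoopBackbone | None = None,
) -> tuple[str, int, str]:
    """Forward primer = prefix + DNA form of the mature 5' cover bases.

    In auto-cover mode the largest cover honoring ``min_gap`` is used. In
    auto-prefix mode a seeded random search picks a 4-16 nt prefix whose
    full-primer Tm falls inside ``cfg.tm_range``. Independently of the
    prefix, the primer's 3'-terminal 8-mer must not be complementary to the
    backbone's reverse-primer region (primer-dimer guard), since both
    primers coexist in the PCR.

    Returns ``(forward, cover_len, prefix)``.
    """
    mature_dna = as_dna_string(mature)
    L = len(mature_dna)
    if cfg.cover_len is not None:
        cover_len = cfg.cover_len
        if cover_len + cfg.anchor_len + cfg.min_gap > L:
            raise DesignError(
                f"{mature.id}: cover_len {cover_len} leaves gap < {cfg.min_gap} "
                f"(mature {L} nt, anchor {cfg.anchor_len})"
            )
    else:
        cover_len = L - cfg.anchor_len - cfg.min_gap
    if cover_len < 1:
        raise DesignError(f"{mature.id}: mature too short for any forward cover")
    core = mature_dna[:cover_len]

    def _dimer_clash(full: str) -> bool:
        if backbone is None or len(full) < 8:
            return False
        return revcomp_str(full[-8:]) in backbone.reverse_primer

    if cfg.prefix is not None:
        forward = cfg.prefix + core
        if _dimer_clash(forward):
            raise DesignError(
                f"{mature.id}: forward 3' end complementary to reverse-primer region"
            )
        return forward, cover_len, cfg.prefix

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.prefix_len_range
    tms: list[float] = []
    for _ in range(cfg.search_budget):
        n = int(rng.integers(lo, hi + 1))
        prefix = "".join(rng.choice(list("ACGT"), size=n))
        forward = prefix + core
        if _dimer_clash(forward):
            continue
        tm = melting_temp(forward)
        tms.append(tm)
        if cfg.tm_range[0] <= tm <= cfg.tm_range[1]:
            return forward, cover_len, prefix
    raise DesignError(
        f"{mature.id}: no prefix found in {cfg.search_budget} tries; observed "
        f"Tm range [{min(tms):.1f}, {max(tms):.1f}] vs target {cfg.tm_range}"
    )


def design_assay(mature: NucSeq, b: StemLoopBackbone, cfg: DesignConfig) -> PrimerSet:
    """Assemble a full primer set for one mature miRNA.

    Warns for matures outside the typical 18-26 nt range; enforces
    ``cover + gap + anchor = mature length`` with ``gap >= min_gap``.
    """
    if not 18 <= len(mature) <= 26:
        warnings.warn(
            f"{mature.id}: length {len(mature)} outside typical mature "
            "miRNA range 18-26 nt", stacklevel=2,
        )
    rt = design_rt_primer(mature, b, cfg.anchor_len)
    forward, cover_len, prefix = design_forward_primer(mature, cfg, backbone=b)
    gap_len = len(mature) - cover_len - cfg.anchor_len
    return PrimerSet(
        mirna_id=mature.id,
        rt_primer=rt,
        forward=forward,
        reverse=derive_reverse_primer(b),
        backbone_id=b.id,
        anchor_len=cfg.anchor_len,
        cover_len=cover_len,
        gap_len=gap_len,
        prefix=prefix,
    )


# ---------------------------------------------------------------------------
# cross-reactivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossReactivityReport:
    """Which miRNAs in a set the assay can and cannot tell apart.

    ``anchor_groups`` maps each shared 3' anchor k-mer (RNA form) to the ids
    carrying it (RT-level cross-priming risk). Shared-anchor pairs are then
    classified: ``identical_pairs`` (same sequence), ``five_prime_variant_pairs``
    (differ only 5' of the gap -- masked by the forward primer, not resolvable
    by this method), ``gap_variant_pairs`` (differ only inside the gap --
    indistinguishable by the primers, resolvable only by sequencing the
    amplicon; requires ``cover_len``), and ``anchor_collision_pairs`` (any
    other shared-anchor pair, including unequal lengths).
    """

    anchor_groups: dict[str, tuple[str, ...]]
    identical_pairs: tuple[tuple[str, str], ...]
    five_prime_variant_pairs: tuple[tuple[str, str], ...]
    gap_variant_pairs: tuple[tuple[str, str], ...]
    anchor_collision_pairs: tuple[tuple[str, str], ...]


def classify_pair(
    a: NucSeq, b: NucSeq, anchor_len: int, cover_len: int | None
) -> str | None:
    """Category of one miRNA pair, or None when their 3' anchors differ."""
    sa = as_dna_string(a)
    sb = as_dna_string(b)
    if sa[-anchor_len:] != sb[-anchor_len:]:
        return None
    if sa == sb:
        return "identical"
    if len(sa) != len(sb):
        return "anchor_collision"
    diffs = [i + 1 for i, (x, y) in enumerate(zip(sa, sb)) if x != y]
    gap_lo = (cover_len or 0) + 1
    gap_hi = len(sa) - anchor_len
    if cover_len is not None and all(gap_lo <= d <= gap_hi for d in diffs):
        return "gap_variant"
    five_prime_hi = cover_len if cover_len is not None else gap_hi
    if all(d <= five_prime_hi for d in diffs):
        return "five_prime_variant"
    return "anchor_collision"


def hexamer_cross_reactivity(
    matures: Sequence[NucSeq],
    anchor_len: int = 6,
    cover_len: int | None = None,
) -> CrossReactivityReport:
    """All-pairs 3'-anchor collision report for a mature miRNA set."""
    if len(matures) < 2:
        raise DesignError("cross-reactivity needs >= 2 sequences")
    by_anchor: dict[str, list[str]] = {}
    for m in matures:
        by_anchor.setdefault(as_dna_string(m)[-anchor_len:], []).append(m.id)
    groups = {k: tuple(v) for k, v in by_anchor.items() if len(v) > 1}

    buckets: dict[str, list[tuple[str, str]]] = {
        "identical": [], "five_prime_variant": [],
        "gap_variant": [], "anchor_collision": [],
    }
    for a, b in combinations(matures, 2):
        cat = classify_pair(a, b, anchor_len, cover_len)
        if cat is not None:
            buckets[cat].append((a.id, b.id))
    return CrossReactivityReport(
        anchor_groups=groups,
        identical_pairs=tuple(buckets["identical"]),
        five_prime_variant_pairs=tuple(buckets["five_prime_variant"]),
        gap_variant_pairs=tuple(buckets["gap_variant"]),
        anchor_collision_pairs=tuple(buckets["anchor_collision"]),
    )
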