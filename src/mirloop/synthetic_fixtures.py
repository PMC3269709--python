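"""Seeded generators for every input class the toolkit consumes.

These emulate the study's experimental material: mature miRNA sets (with
family variants differing at the 5' end, 3' anchor or gap), pools of
sequenced clone reads (specific amplicons, primer-only artifacts like those
seen in blank controls, and junk), genomic fragments with a planted
precursor hairpin, and stage x replicate Ct tables with known fold changes.
All generators are deterministic under a fixed seed, and each is the exact
inverse of the corresponding analysis at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon_sim import predict_amplicon
from .assay_design import PrimerSet, StemLoopBackbone
from .seqcore import NucSeq, revcomp_str

RNA_BASES = np.array(list("ACGU"))

# Developmental stages sampled in the expression profile (egg through adult).
DEFAULT_STAGES = ("egg", "L1", "L3", "L4", "L6", "prepupa", "pupa", "adult")

# Published fold changes relative to the egg calibrator for the two assays
# that quantified reliably; used as generator defaults so the demo dataset
# reproduces the reported expression-profile shape.
MIR14_FOLD_CHANGES = (1.0, 1.47, 4.22, 3.78, 2.26, 1.87, 0.37, 9.07)
MIR2A_FOLD_CHANGES = (1.0, 2.89, 15.65, 24.55, 4.88, 2.23, 38.68, 1.81)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for all generators; defaults mirror the study conditions."""

    seed: int = 0
    n_mirnas: int = 10
    mature_len_range: tuple[int, int] = (18, 26)
    family_variant_mode: str | None = None  # "3prime" | "5prime" | "gap_only"
    clone_proportions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    sequencing_error_rate: float = 0.0
    ct_noise_sd: float = 0.2
    fold_changes: tuple[float, ...] = MIR14_FOLD_CHANGES
    n_replicates: int = 3
    stages: tuple[str, ...] = DEFAULT_STAGES
    reference_ct_mean: float = 16.0
    baseline_dct: float = 6.0
    precursor_total_len: int = 322
    hairpin_len: int = 82
    loop_len: int = 8
    arm_mismatches: int = 0
    gc_bias: float = 0.5  # P(G or C) per base

    def __post_init__(self) -> None:
        if abs(sum(self.clone_proportions) - 1.0) > 1e-9:
            raise ValueError("clone mixture proportions must sum to 1")
        if not 0.0 <= self.sequencing_error_rate <= 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1]")


def _random_rna(rng: np.random.Generator, n: int, gc_bias: float = 0.5) -> str:
    p_gc, p_at = gc_bias / 2.0, (1.0 - gc_bias) / 2.0
    return "".join(rng.choice(RNA_BASES, size=n, p=[p_at, p_gc, p_gc, p_at]))


def _mutate_at(rng: np.random.Generator, seq: str, pos: int) -> str:
    """Substitute the base at 0-based ``pos`` with a different one."""
    alt = [b for b in "ACGU" if b != seq[pos]]
    return seq[:pos] + str(rng.choice(alt)) + seq[pos + 1:]


def gen_matures(cfg: FixtureConfig) -> list[NucSeq]:
    """Random mature miRNA set, optionally with family-variant pairs.

    In a variant mode every base record ``mir-i`` is followed by a partner
    ``mir-iv`` differing at a single position: position 1 (``5prime``), the
    last base (``3prime``), or the last base before the 3' hexamer
    (``gap_only``, inside the gap for any cover leaving a gap >= 1).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mature_len_range
    out: list[NucSeq] = []
    for i in range(cfg.n_mirnas):
        n = int(rng.integers(lo, hi + 1))
        seq = _random_rna(rng, n, cfg.gc_bias)
        out.append(NucSeq(f"mir-{i + 1:03d}", seq, "RNA"))
        if cfg.family_variant_mode is not None:
            pos = {
                "5prime": 0,
                "3prime": n - 1,
                "gap_only": n - 7,
            }[cfg.family_variant_mode]
            out.append(NucSeq(f"mir-{i + 1:03d}v", _mutate_at(rng, seq, pos), "RNA"))
    return out


def gen_clone_reads(
    matures: Sequence[NucSeq],
    assays: Sequence[PrimerSet],
    backbone: StemLoopBackbone,
    cfg: FixtureConfig,
    n_reads: int = 30,
) -> tuple[list[NucSeq], pd.DataFrame]:
    """Clone-read pool with truth labels.

    Reads are drawn per assay from the configured mixture: the predicted
    amplicon (random strand), a forward+reverse primer artifact (optionally
    with random intervening bases), or a random sequence. Per-base
    substitution errors are applied at ``sequencing_error_rate``. Returns
    ``(reads, truth)`` where truth has columns read_id, mirna_id, label.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    by_id = {m.id: m for m in matures}
    reads: list[NucSeq] = []
    truth_rows = []
    labels = np.array(["specific", "primer_only", "other"])
    for ps in assays:
        amp = predict_amplicon(by_id[ps.mirna_id], ps, backbone).seq
        for r in range(n_reads):
            label = str(rng.choice(labels, p=list(cfg.clone_proportions)))
            if label == "specific":
                seq = amp
            elif label == "primer_only":
                spacer = ("" if rng.random() < 0.5 else
                          _random_rna(rng, int(rng.integers(1, 7))).replace("U", "T"))
                seq = ps.forward + spacer + revcomp_str(ps.reverse)
            else:
                seq = _random_rna(rng, len(amp)).replace("U", "T")
            if cfg.sequencing_error_rate > 0:
                chars = list(seq)
                for i in range(len(chars)):
                    if rng.random() < cfg.sequencing_error_rate:
                        alt = [b for b in "ACGT" if b != chars[i]]
                        chars[i] = str(rng.choice(alt))
                seq = "".join(chars)
            if rng.random() < 0.5:
                seq = revcomp_str(seq)
            read_id = f"{ps.mirna_id}_clone{r + 1:03d}"
            reads.append(NucSeq(read_id, seq, "DNA"))
            truth_rows.append({"read_id": read_id, "mirna_id": ps.mirna_id,
                               "label": label})
    return reads, pd.DataFrame(truth_rows)


def gen_precursor_context(
    mature: NucSeq, cfg: FixtureConfig
) -> tuple[NucSeq, dict]:
    """Genomic-style fragment with a planted precursor hairpin.

    The mature (RNA form) is embedded in the 3' arm of a constructed
    hairpin: arm3 = pad + mature + pad, arm5 = revcomp(arm3) with
    ``arm_mismatches`` substitutions, joined by a random loop, padded by
    random flanks to ``precursor_total_len``. Returns the fragment plus
    truth coordinates (1-based inclusive).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    mat = mature.seq.replace("T", "U")
    arm_len = (cfg.hairpin_len - cfg.loop_len) // 2
    if len(mat) > arm_len:
        raise ValueError("mature longer than the hairpin arm")
    pad_left = int(rng.integers(0, arm_len - len(mat) + 1))
    arm3 = (_random_rna(rng, pad_left) + mat
            + _random_rna(rng, arm_len - len(mat) - pad_left))
    arm5 = revcomp_str(arm3, alphabet="RNA")
    for pos in rng.choice(arm_len, size=cfg.arm_mismatches, replace=False):
        arm5 = _mutate_at(rng, arm5, int(pos))
    loop = _random_rna(rng, cfg.hairpin_len - 2 * arm_len)
    hairpin = arm5 + loop + arm3

    flank_total = cfg.precursor_total_len - len(hairpin)
    left = int(rng.integers(0, flank_total + 1))
    source_seq = (_random_rna(rng, left) + hairpin
                  + _random_rna(rng, flank_total - left))
    source = NucSeq(f"{mature.id}_context", source_seq, "RNA")
    coords = {
        "hairpin_start": left + 1,
        "hairpin_end": left + len(hairpin),
        "mature_start": left + len(arm5) + len(loop) + pad_left + 1,
        "mature_end": left + len(arm5) + len(loop) + pad_left + len(mat),
    }
    return source, coords


def gen_ct_table(cfg: FixtureConfig) -> pd.DataFrame:
    """Stage x replicate Ct table realizing the configured fold changes.

    Per replicate: ct_reference = reference mean + noise; ct_target =
    ct_reference + baseline dCt - log2(fold) + noise. Reference-gene noise
    therefore cancels in dCt, and at zero noise the comparative-Ct analysis
    returns the fold-change vector exactly (first stage is the calibrator
    with fold 1).
    """
    if len(cfg.fold_changes) != len(cfg.stages):
        raise ValueError("fold-change vector length must equal n_stages")
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    for stage, fold in zip(cfg.stages, cfg.fold_changes):
        for rep in range(1, cfg.n_replicates + 1):
            ct_ref = cfg.reference_ct_mean + rng.normal(0.0, cfg.ct_noise_sd)
            ct_tgt = (ct_ref + cfg.baseline_dct - np.log2(fold)
                      + rng.normal(0.0, cfg.ct_noise_sd))
            rows.append({"stage": stage, "replicate": rep,
                         "ct_target": float(ct_tgt),
                         "ct_reference": float(ct_ref)})
    return pd.DataFrame(rows)
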