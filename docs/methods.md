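# Methods

## Assay model

A stem-loop RT-qPCR assay for a mature miRNA *m* (length *L*, RNA) is
defined by four parameters: a backbone *B* (universal DNA portion of the RT
primer, with a recorded reverse-primer site), an anchor length *a*
(default 6), a cover length *c*, and a forward prefix *p*. The primers are

- RT primer = `B + revcomp(DNA(m[L−a+1 .. L]))` — the 3′ anchor is the sole
  source of 3′-end specificity;
- forward = `p + DNA(m[1 .. c])`;
- reverse = the backbone substring at its recorded site.

The gap `g = L − c − a` is required to be ≥ 1 by default: gap bases appear
in the amplicon but in neither primer, so sequencing a cloned product can
distinguish a genuine miRNA from a primer artifact. The two built-in
backbones place the reverse primer differently (`group2`: the 5′ 32-nt
prefix of a 40-nt backbone; `group1`: an interior 16-mer of a 44-nt
backbone); new backbones default to the 5′-anchored style.

Backbone validity is the largest *k* with `B[1..k] = revcomp(B[n−k+1..n])`
(the stem of the folded RT primer); *k* ≥ 6 is required. Direct computation
gives *k* = 14 for the `group1` preset and *k* = 8 for `group2`.

### Amplicon model

The predicted product is bounded by the two primers' 5′ ends (standard PCR
convention): top strand = `forward + DNA(m[c+1 .. L]) + revcomp(B[s ..])`
where *s* is the reverse-primer start. Its length is
`|forward| + g + a + (|B| − s + 1)`; for 5′-anchored reverse primers this
simplifies to `L + |prefix| + |B|`. This model reproduces the three
published Group 2 product sizes (76/79/79 bp) exactly. The published
Group 1 sizes (86/89/89 bp) are a constant 25 bp larger than any
primer-bounded product of the printed Group 1 primers (61/64/64 bp) and
cannot be derived from the primer sequences alone (plausibly the sequenced
inserts included vector-adjacent bases); they are therefore not used for
validation.

### Reference assays

The package ships the three published assays (miR-14, miR-2a, bantam) as
presets. Their mature sequences are the D. melanogaster homologues, to
which the cloned sequences are identical; each is fully consistent with
every printed primer (cover prefix, gap of 2/3/4 nt, 3′ anchor).

### Forward-prefix search

No published rule fixes the forward prefix, so it is treated as a free
design parameter: when not supplied, a seeded random search (numpy
`default_rng`) draws 4–16 nt candidates until the full primer's
nearest-neighbor Tm falls in the configured window (default 52–62 °C,
SantaLucia parameters via Biopython `Tm_NN`, 250 nM oligo, 50 mM Na⁺).
Independently of the prefix, a primer whose 3′-terminal 8-mer is
complementary to the reverse-primer region is rejected (primer-dimer
guard). The search is deterministic under a fixed seed.

### Cross-reactivity

Two miRNAs sharing a 3′ anchor hexamer cannot be separated at the RT step.
Shared-anchor pairs are classified further: *identical*; *5′ variant*
(differences confined to the forward-covered region — masked by the
forward primer, hence not resolvable by this method at all, the known
limitation for families like bantam); *gap variant* (differences confined
to the gap — invisible to the primers but resolvable by sequencing); and
*anchor collision* otherwise. The gap category requires a cover length;
without one, every pre-anchor difference counts as 5′-region variation.

## Clone classification

A read (either strand) is oriented by locating the forward primer; finding
it on both strands is ambiguous (`other`). A `specific` read reproduces the
amplicon layout at the forward hit: forward primer (exact), `g` free bases
(the measured gap — never counted as mismatches), then anchor + backbone
tail with at most `max_mismatch` differences (default 0) and an exact
reverse-primer site. The mature is reconstructed as
`cover (from design) + gap (from read) + anchor (from RT primer)`, in RNA.
Reads containing forward and reverse primer without that context are
`primer_only` — the artifact class observed in blank controls.

## Hairpin screening

Candidate precursors are triaged with a Nussinov-style dynamic program
maximizing a weighted pair count over GC/AU/GU pairs (defaults 3/2/1,
validated GU ≤ AU ≤ GC) with a minimum hairpin loop of 3 nt. This is a
deliberate substitution for thermodynamic folding: it is deterministic,
exhaustively testable against explicit structure enumeration, and adequate
for ranking stem-loop plausibility, but its pair score is **not** a free
energy and is not comparable to energy-minimization outputs. The O(n³)
fill is numba-compiled; the traceback is deterministic (prefer pairing the
3′ base over leaving it unpaired, taking the 5′-most admissible partner),
so equal-score structures resolve reproducibly.

`scan_precursors` folds every window of 70–90 nt (the canonical pre-miRNA
size range) containing each exact occurrence of the mature, and ranks
candidates by pair score, then paired fraction, then smaller window, then
leftmost start. Because the optimum is monotone under extension, the top
hit tends to the largest window containing the hairpin; recovery is judged
by overlap with the true hairpin interval, which that behavior preserves.
Reported statistics: paired fraction, terminal-loop length (the unpaired
run under the most deeply nested pair), the mature's paired fraction, and
its arm (5p/3p by midpoint).

## qPCR statistics

- **Standard curve**: OLS of Ct on log₁₀ relative template concentration
  (≥ 3 distinct dilutions); efficiency E = 10^(−1/slope), the per-cycle
  amplification factor (E = 2 at slope −3.3219). Efficiency is reported,
  not used to correct RQ (matching practice when E ≈ 2); an
  efficiency-corrected mode (E^−ΔΔCt) is available via a parameter.
- **Relative quantification**: per replicate ΔCt = Ct_target − Ct_ref;
  ΔΔCt from stage-mean ΔCt minus the calibrator stage mean, so the
  calibrator's RQ is exactly 1; per-stage SE from replicate-level 2^−ΔΔCt
  values. RQ is invariant to any shift applied to both Ct columns.
- **Duncan's multiple range test** runs on replicate-level −ΔCt (log₂
  expression scale, where variance homogeneity is more plausible than on
  the RQ scale). Pooled one-way-ANOVA MSE; least significant ranges
  R_p = q_p·√(MSE/n_h) with q_p the studentized-range quantile at Duncan's
  protection level (1−α)^(p−1) (scipy `studentized_range`, cross-checked
  against published table values at 20 df), harmonic-mean n for unequal
  groups. Ranges are tested widest-first and a non-significant range
  protects its sub-ranges; letters are assigned to maximal homogeneous
  runs in descending-expression order. With zero pooled variance the
  procedure degenerates to: equal means share a letter, unequal means
  do not.

## Synthetic data

The generators emulate the study's inputs at its stated scale: 8
developmental stages (egg, L1, L3, L4, L6, prepupa, pupa, adult) × 3
replicates; default fold-change vectors equal to the two published
expression profiles so the demo reproduces their shape; 0.2-cycle Gaussian
Ct noise as the default measurement error; 322-nt genomic fragments with a
planted 82-nt hairpin (arm = revcomp of arm, configurable mismatches, 8-nt
loop) holding the mature in the 3′ arm; clone pools mixing amplicons
(random strand), forward+reverse artifacts and junk at configurable
proportions with optional per-base substitution error. Ct tables follow
`ct_ref = μ_ref + ε₁`, `ct_target = ct_ref + ΔCt₀ − log₂(fold) + ε₂`, so
reference-gene noise cancels in ΔCt by construction and the zero-noise
tables invert the ΔΔCt analysis exactly.

What the fixtures do not emulate: real base-composition and secondary
structures of genomic context, quality-dependent sequencing error,
plate/batch effects, or reverse-transcription efficiency differences
between targets. Passing the synthetic suites therefore demonstrates the
correctness of the algorithms and their inverse relationships, not
wet-lab performance.

## Numerical and design choices

- Percent identity uses a global alignment DP (match +1, mismatch 0,
  linear gap −1, configurable) with denominator = alignment columns
  including gaps; among score-optimal alignments the tie-break is most
  matches, then fewest columns, which makes the reported identity
  deterministic and symmetric.
- The fold-change recovery suite (noise sd 0.2, n = 3, 500 seeded runs)
  scores the fraction of recovered per-stage fold changes within 25% of
  truth pooled over runs; the analytic expectation under the generator is
  ≈95%.
- Simulation sizes used by the test suite (200 enumeration-checked folds
  up to 22 nt, 1000 amplicon round trips, 100 planted-hairpin scans, 500
  Ct simulations) were chosen to exercise each property across its input
  space while keeping the whole suite around a minute on one core.
- Seeds: all randomized components take explicit seeds (numpy
  `default_rng`); generators derive independent streams by small fixed
  offsets from the configured seed.

## Known limitations

- Degenerate (IUPAC) primers are unsupported; degenerate precursor-primer
  design is out of scope.
- Exact-match mature search in precursor scanning: SNVs between the
  reference mature and the genomic copy hide an occurrence.
- The hairpin score has no energy model, no pseudoknots and no
  suboptimal-structure output.
- Single reference gene only; no multi-gene normalization.
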