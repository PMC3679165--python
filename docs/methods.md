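# Methods

## Repeat geometry and coordinates

A WD40 sequence repeat is modelled as Sd–Lda–Sa–Lab–Sb–Lbc–Sc with strands
fixed at six residues and loop lengths free within enumeration bounds
(Lda, Lab, Lbc ∈ [1, 15]; the inter-repeat Lcd ∈ [0, 25] for enumeration,
longer linkers priced by the linear penalty). Internally all coordinates
are 0-based half-open; every user-facing table prints 1-based inclusive
coordinates.

Thirty-one positions are profile-scored: all 24 strand positions and seven
conserved loop positions. The conserved loop positions are numbered on the
modal template — Sd(1–6), Lda(7–12), Sa(13–18), Lab(19–22), Sb(23–28),
Lbc(29–32), Sc(33–38) — giving Lda 2–3, Lab 1–4 and Lbc 3 in
element-relative terms. For loops of non-modal length the scored slots are
anchored at the N-terminal end of the loop (Lda's at offsets 1–2 from the
loop start); a slot beyond the actual loop length contributes background,
i.e. zero log-odds. This anchoring is the simplest deterministic rule for
variable-length loops; the absence of a residue in a short loop is already
priced by the loop-length score, so empty slots are deliberately neutral.

## The profile and its training

`RepeatProfile` bundles per-position residue frequencies (pseudo-count
10⁻⁴ per residue), position weights, a background composition, four
loop-length score tables, the SDHSW pentad statistics and the repeat-count
regulator.

**Weights.** The weight of a position is its information content,
log₂ 20 − H_k with H_k the Shannon entropy of its residue distribution, so
conserved positions dominate the score; a raw-entropy mode is available
behind a switch (`weight_mode`) but would up-weight the least conserved
positions and is not the default.

**Residue score.** `S_aa` uses the natural logarithm of the
frequency/background ratio. Residues outside the 20-letter alphabet score
at background with a warning.

**Loop scores.** From length counts, pseudo-counted frequencies
(pseudo-count 0.01 over the table domain) are log-transformed relative to
the never-observed floor, smoothed with a 1-2-1 moving average, and a
quadratic in l is fitted by least squares weighted by the smoothed
frequencies (smoothed weights keep the fit well-posed for concentrated
counts; a non-concave fit, which only arises for degenerate count
patterns, falls back to the smoothed curve itself). l₀ is the first length
past the fitted maximum where the fit drops below 1; beyond l₀ the linear
penalty 1 − t(l − l₀) applies, blended over a window of width t₀ (default
2) and forced strictly decreasing. Default penalty slopes are 0.5 per
residue (0.4 for Lcd). The profile file stores the final per-length table
as the source of truth; the fitting routine is used when training new
profiles.

**Tetrad statistics.** The pentad slots are Sc1, Lcd2, Lda3, Sb4, Sc5 with
accepted classes Ser/Thr, Asp, His, Ser/Thr, Trp. Lcd2 is read from the
inter-repeat loop preceding the repeat (its second residue); training
repeats without that context are excluded from the motif denominators.
The bonus for a matched motif is the log-odds of its observed probability
against slot-wise independence, clamped at zero; because a deeper motif
contains the shallower ones, the awarded bonus is the maximum over the
matched nested motifs (this keeps the award monotone in motif depth even
when the raw log-odds are not). At enumeration time the preceding repeat
is unknown, so the Asp requirement is waived and the award capped at the
tetrad level; once a domain is assembled, every repeat's S_corr is
re-scored with its true inter-repeat context, and tetrad evidence for
classification is taken from that contextual check only.

**Regulator.** R(N_rep) is tabulated for N_rep ∈ [1, 40]. The initial
table sums five Gaussians (amplitude 20, σ = 1) centred at 7, 14, 21, 28,
35. The packaged "modified" table additionally grants 0.4 × amplitude one
repeat either side of each centre (six- and eight-bladed propellers occur)
and penalizes chains below six repeats by 10 per missing repeat, steering
assembly toward complete domains. The regulator acts only during assembly;
all reported domain scores are computed without it.

**The packaged default profile** (`scripts/build_default_profile.py`)
transcribes the printed family-logo frequencies exactly where published
(Sa1, Sa4, Sa6, Sc2, Sc4, Lab2) and fills the remaining positions with the
family's documented consensus features (Gly-His in Lda with the tetrad His
at Lda3, Trp-Asp closing Sc, Ser/Thr at Sb4 and Sc1, small residues at the
Sb C-terminus, bulky hydrophobics at the sheet-core positions, Gly-rich
turns), at conservation levels comparable to the printed rows. The
analytically expected score of a profile-sampled repeat (≈ 35 for S_aa
plus ≈ 22 for loop terms) then sits well inside the 30–150 band that the
published decision thresholds (10 / 35 / 45 / 48) presume, with the same
comfortable margin over the ASr boundary that real repeats show. The
background is the Swiss-Prot-style eukaryotic composition and is
overridable. The profile file is a versioned key-value text format that
round-trips bit-exactly (floats stored at full repr precision).

## Detection pipeline

1. **Terminal trimming** (only with an external SS prediction): maximal
   terminal stretches whose 30-residue sliding helix fraction exceeds 0.5
   are excluded from the scan; interior residues are never removed.
2. **Enumeration**: every (start, l_da, l_ab, l_bc) combination is scored;
   the per-combination score vectors are computed by sliding-window sums,
   so the O(L·15³) grid costs a few hundred numpy passes. Candidates with
   S_repeat > 10 enter the pool.
3. **Overlap filter**: descending-score sweep (ties: smaller start, then
   shorter span); a candidate is discarded iff a retained candidate with
   score above 35 and strictly above its own overlaps it.
4. **Early exit**: if no candidate reaches 45 the protein is not a WD40.
5. **Pool threshold**: T = max(10, median pool score) — a stand-in policy
   for the unpublished threshold formula, pluggable and recorded in the
   report.
6. **Assembly**: the genetic algorithm (below), or the exact DP when
   requested. If the optimized chain has fewer than 7 repeats and T > 10,
   T is reset to 10 and assembly restarts.
7. **Classification**: the chain is sliced into domains of seven repeats
   where possible (a short tail merges into its predecessor); a domain
   qualifies with ≥ 6 repeats and (ASr ≥ 48 or a contextual DHSW tetrad).
   ASr is the mean repeat score with S_corr excluded. The domain count
   follows the total-repeat rule (> 8/16/24/32 → 2/3/4/5).
8. **Secondary structure**: E over the four strands of every reported
   repeat, C elsewhere, with strand identifiers per segment.

## Assembly engines

**Exact DP.** Weighted-interval-scheduling dynamic programming over
candidates sorted by end coordinate, with an explicit repeat-count state so
the count-dependent regulator is handled exactly: dp[c][j] is the best
unregulated score of a c-repeat chain ending at candidate j; the answer
maximizes dp[c][j] + R(c) over non-empty chains. O(N²·C) with vectorized
inner maximization.

**Genetic algorithm.** Individuals are ordered non-overlapping candidate
chains; fitness is the regulated domain score. Defaults: population 200,
crossover 0.5 (splice two parents at a random sequence coordinate),
mutation 0.2 (swap one repeat for an alternative fitting its gap, half
greedy / half uniform), elongation 0.3. The elongation operator, with
probability one half, runs a best-improvement local search over
single-chain edits — insert a candidate into any gap, replace one repeat
by the best alternative in its gap, or delete one repeat — until no edit
improves the regulated fitness; otherwise it appends one candidate at a
chain end. Each generation keeps the top chains and the best distinct
chains as elites, re-seeds 10% of the population with random singletons
(so crossover never runs out of building blocks), and fills the rest with
offspring from rank-based tournaments; every child undergoes at least one
operator, so exact copies do not flood the population. Convergence is
declared when the best ten individuals are one identical chain *and* no
improvement has surfaced for ten generations (the stall condition guards
against declaring convergence while copies of an early leader temporarily
dominate); the final answer is locally improved once more. The engine is
deterministic under a fixed seed and matches the exact DP score on every
random pool in the test batteries.

## Synthetic data and evaluation

`generate_wd40` samples strand and scored-loop residues from the profile
frequencies, unscored loop residues from the background, and loop lengths
from the exponentiated, normalized loop-score tables; flanks of 5–30
background residues are added. An optional flag plants a full SDHSW pentad
in every repeat. Decoys are i.i.d. background draws (composition-matched,
so decoy scores probe positional signal only), composition-preserving
shuffles of a generated sequence, or helix-rich decoys paired with an
all-helix prediction. Metrics: Q3 (percent matching two-state labels
against the planted reference) and loose/tight repeat recovery — a repeat
counts as found when strands a, b, c (loose) or a, b, c, d (tight) each
overlap their planted counterpart by at least 4 of 6 residues (the
tolerance is configurable; no published value exists). A generic
leave-one-out harness retrains the profile without one item and evaluates
on it.

What the synthetics do *not* emulate: real repeats correlate residues
across positions (the generator samples independently), Lcd loops carry
the tetrad Asp in real proteins but background residues here (unless
pentad-forced), and there is no homology structure or compositional bias
between proteins. Passing the synthetic batteries therefore demonstrates
the pipeline's statistical machinery and its engines, not performance on
real proteomes.

## Problem sizes and numerical choices

The test and acceptance batteries use 50 seven-repeat proteins plus 50
length-matched decoys for recovery/rejection, 100 random pools of ≤ 12
candidates for the engine-equivalence check, 200 sampled repeats for
parameter recovery, and a 36-item dataset for the leave-one-out harness —
the last sized so each fold trains on ~250 repeats, enough that the flat
10⁻⁴ pseudo-count leaves no large unseen-residue penalties (with much
smaller folds, trained-profile scores drop toward the decision thresholds
and fold verdicts become unstable; this sensitivity is a real property of
the flat pseudo-count at small n). Score comparisons in tests use 1e−6
absolute tolerance; human-readable tables print four decimals; the report
and profile files round-trip exactly.

## Known limitations

* The median pool-threshold policy can discard true repeats when the
  post-filter pool is small and nearly all-true — notably for 14-repeat
  double-propeller proteins, where the restart rule (which fires only
  below seven repeats) does not rescue the second domain. The policy is
  pluggable for this reason.
* Decision thresholds (10/35/45/48) are treated as calibrated to the
  packaged default profile; a profile trained on a small repeat set shifts
  the score scale and may need re-calibrated thresholds (all are
  configurable).
* Multi-domain slicing (seven per domain where possible) is a convention;
  only the domain-counting rule is externally specified.
* Strand d remains the weakest call without an external secondary-structure
  prediction; the S_PSIPRED term exists precisely to pin it.
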