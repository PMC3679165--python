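"""Score terms for repeats and domains.

The score of a single repeat is the sum of four terms:

* ``S_aa`` — entropy-weighted log-odds of the residues at the 31 scored
  positions against the eukaryotic background (natural log);
* ``S_loop_len`` — loop-length scores for Lda, Lab and Lbc;
* ``S_corr`` — the cooperative bonus for an SDHSW pentad, a DHSW tetrad or
  a DHS triad at the slots Sc1/Lcd2/Lda3/Sb4/Sc5;
* ``S_psipred`` — confidence-weighted agreement of an external secondary
  structure prediction over the 24 strand positions (coefficients
  +0.1 for E, -0.025 for C, -0.1 for H); zero when no prediction is given.

A domain score adds the Lcd linker scores over an ordered chain of repeats
and, during assembly only, the repeat-count regulator R(N_rep).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .profile_builder import (  # noqa: F401  (re-exported surface)
    RegulatorTable,
    RepeatProfile,
    TetradModel,
    AA_INDEX,
    initial_regulator,
    modified_regulator,
)
from .repeat_model import (
    DomainModel,
    PositionID,
    RepeatCandidate,
    STRANDS,
    STRAND_LENGTH,
    scored_offsets,
)

logger = logging.getLogger(__name__)

SS_COEFFICIENTS = {"E": 0.1, "C": -0.025, "H": -0.1}
SCORE_TERMS = ("S_aa", "S_loop_len", "S_corr", "S_psipred")


@dataclass
class SSPrediction:
    """Per-residue external secondary-structure states with confidences."""

    states: str  # each in {H, E, C}
    conf: list[int]  # each in [0, 9]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.conf):
            raise ValueError("states and confidences must have equal length")
        if set(self.states) - set("HEC"):
            raise ValueError("states must be drawn from {H, E, C}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ScoreBreakdown:
    S_aa: float
    S_loop_len: float
    S_corr: float
    S_psipred: float

    @property
    def S_repeat(self) -> float:
        return self.S_aa + self.S_loop_len + self.S_corr + self.S_psipred

    def as_dict(self) -> dict[str, float]:
        return {
            "S_aa": self.S_aa, "S_loop_len": self.S_loop_len,
            "S_corr": self.S_corr, "S_psipred": self.S_psipred,
        }


def score_aa(candidate: RepeatCandidate, profile: RepeatProfile) -> float:
    """Weighted log-odds sum over the 31 scored positions.

    Loop slots beyond the actual loop length, and residues outside the
    20-letter alphabet, contribute background (zero log-odds)."""
    wlo = profile.weighted_log_odds
    from .profile_builder import POSITION_INDEX

    total = 0.0
    for pos, offset in scored_offsets(candidate.loop_lengths):
        if offset is None:
            continue
        res = candidate.residues_by_position.get(pos)
        if res is None:
            continue
        col = AA_INDEX.get(res)
        if col is None:
            logger.warning("non-canonical residue %r at %s scored at background", res, pos)
            continue
        total += float(wlo[POSITION_INDEX[pos], col])
    return total


def score_loop_lengths(l_da: int, l_ab: int, l_bc: int, profile: RepeatProfile) -> float:
    """S(l_da) + S(l_ab) + S(l_bc) from the per-loop tables."""
    total = 0.0
    for name, l in (("Lda", l_da), ("Lab", l_ab), ("Lbc", l_bc)):
        table = profile.loop_scores[name]
        if l not in table.scores:
            logger.warning("loop %s length %d outside table; linear extrapolation", name, l)
        total += table.score(l)
    return total


def corr_motif_level(
    candidate: RepeatCandidate,
    tetrad: TetradModel,
    sequence: str | None = None,
    previous_end: int | None = None,
) -> str:
    """Deepest matched cooperative motif: pentad, tetrad, triad or none.

    The Lcd2 slot lives in the inter-repeat loop preceding this repeat; its
    residue is read from ``sequence`` when ``previous_end`` (the end of the
    preceding repeat) is known.  Without that context the Asp requirement
    cannot be checked: the check degrades, waiving the Asp slot and capping
    the award at the tetrad level.
    """
    def slot(pos: PositionID) -> str | None:
        return candidate.residues_by_position.get(pos)

    sc1, lda3 = slot(PositionID("Sc", 1)), slot(PositionID("Lda", 3))
    sb4, sc5 = slot(PositionID("Sb", 4)), slot(PositionID("Sc", 5))
    lcd2: str | None = None
    has_context = sequence is not None and previous_end is not None
    if has_context:
        lcd_len = candidate.start - previous_end
        if lcd_len >= 2:
            lcd2 = sequence[previous_end + 1]
        else:
            lcd2 = ""  # context known, loop too short to hold the Asp

    def ok(res: str | None, slot_name: str) -> bool:
        return res is not None and res in tetrad.classes[slot_name]

    d_ok = ok(lcd2, "Lcd2") if has_context else True  # waived without context
    if not (d_ok and ok(lda3, "Lda3") and ok(sb4, "Sb4")):
        return "none"
    if not ok(sc5, "Sc5"):
        return "triad"
    if has_context and ok(sc1, "Sc1"):
        return "pentad"
    return "tetrad"


def score_corr(
    candidate: RepeatCandidate,
    tetrad: TetradModel,
    sequence: str | None = None,
    previous_end: int | None = None,
) -> float:
    """Cooperative SDHSW bonus for one repeat.

    A deeper motif contains the shallower ones, so the award is the largest
    bonus among the matched nested motifs."""
    level = corr_motif_level(candidate, tetrad, sequence, previous_end)
    if level == "none":
        return 0.0
    if level == "triad":
        return tetrad.triad_bonus
    if level == "tetrad":
        return max(tetrad.tetrad_bonus, tetrad.triad_bonus)
    return max(tetrad.pentad_bonus, tetrad.tetrad_bonus, tetrad.triad_bonus)


def score_ss_term(
    candidate: RepeatCandidate,
    ss: SSPrediction | None,
    coefficients: dict[str, float] = SS_COEFFICIENTS,
) -> float:
    """Confidence-weighted external-SS agreement over the 24 strand positions."""
    if ss is None:
        return 0.0
    if len(ss) < candidate.end:
        raise ValueError(
            f"secondary structure prediction ({len(ss)} residues) shorter than "
            f"candidate end {candidate.end}"
        )
    total = 0.0
    for strand, (s0, s1) in candidate.strand_spans().items():
        for i in range(s0, s1):
            total += ss.conf[i] * coefficients[ss.states[i]]
    return total


def score_repeat(
    candidate: RepeatCandidate,
    profile: RepeatProfile,
    ss: SSPrediction | None = None,
    sequence: str | None = None,
    previous_end: int | None = None,
) -> ScoreBreakdown:
    """All four terms of one repeat's score; the breakdown is stored on the
    candidate so that ASr (which excludes S_corr) can be derived later."""
    breakdown = ScoreBreakdown(
        S_aa=score_aa(candidate, profile),
        S_loop_len=score_loop_lengths(
            candidate.loop_lengths["Lda"], candidate.loop_lengths["Lab"],
            candidate.loop_lengths["Lbc"], profile,
        ),
        S_corr=score_corr(candidate, profile.tetrad, sequence, previous_end),
        S_psipred=score_ss_term(candidate, ss),
    )
    candidate.score_terms = breakdown.as_dict()
    candidate.S_repeat = breakdown.S_repeat
    return breakdown


def regulator(n_rep: int, table: RegulatorTable) -> float:
    """R(N_rep) lookup; counts beyond the table clamp to its last entry."""
    if n_rep < 1:
        raise ValueError("N_rep must be >= 1")
    if n_rep > max(table.values):
        logger.warning("N_rep %d beyond regulator table; clamping", n_rep)
    return table.value(n_rep)


def lcd_score(length: int, profile: RepeatProfile) -> float:
    return profile.loop_scores["Lcd"].score(length)


def score_domain(domain: DomainModel, profile: RepeatProfile, use_regulator: bool = False) -> float:
    """Sum of repeat scores plus Lcd linker scores, optionally regulated.

    The regulator is only meaningful during assembly; final reported domain
    scores are computed with ``use_regulator=False``."""
    domain.validate()
    total = sum(r.S_repeat for r in domain.repeats)
    total += sum(lcd_score(l, profile) for l in domain.lcd_lengths)
    if use_regulator and domain.N_rep >= 1:
        total += regulator(domain.N_rep, profile.regulator)
    return total


def average_repeat_score(domain: DomainModel) -> float:
    """ASr: mean repeat score with the cooperative S_corr term excluded.

    This is the classification statistic thresholded at 48."""
    if domain.N_rep == 0:
        raise ValueError("ASr undefined for an empty domain")
    vals = [r.S_repeat - r.score_terms.get("S_corr", 0.0) for r in domain.repeats]
    return float(sum(vals) / len(vals))
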