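"""Canonical WD40 repeat geometry.

A WD40 sequence repeat is the strand succession Sd-Sa-Sb-Sc (the structural
blade Sa-Sb-Sc-Sd is phase-shifted by one strand).  Each strand is fixed at
six residues; the three intra-repeat loops Lda, Lab and Lbc vary in length,
and consecutive repeats are joined by the inter-repeat loop Lcd.  This module
defines the position naming shared by every other module, the template
arithmetic that maps a residue offset inside a repeat to its named position,
and the candidate / domain containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

STRAND_LENGTH = 6

#: Elements of one repeat in sequence order (Lcd precedes the next repeat's Sd).
STRANDS = ("Sd", "Sa", "Sb", "Sc")
LOOPS = ("Lda", "Lab", "Lbc", "Lcd")
ELEMENT_ORDER = ("Sd", "Lda", "Sa", "Lab", "Sb", "Lbc", "Sc")

#: Conserved loop positions included in the per-residue profile score, mapped
#: from the 42-column logo numbering onto element-relative indices assuming the
#: modal template Sd(1-6) Lda(7-12) Sa(13-18) Lab(19-22) Sb(23-28) Lbc(29-32)
#: Sc(33-38): logo columns 8-9 -> Lda 2-3, 19-22 -> Lab 1-4, 31 -> Lbc 3.
SCORED_LOOP_POSITIONS = (
    ("Lda", 2),
    ("Lda", 3),
    ("Lab", 1),
    ("Lab", 2),
    ("Lab", 3),
    ("Lab", 4),
    ("Lbc", 3),
)

#: Default loop-length enumeration bounds.  Training discards loops longer
#: than 15 residues; Lcd may run longer, priced by the linear penalty.
DEFAULT_LOOP_BOUNDS: dict[str, tuple[int, int]] = {
    "Lda": (1, 15),
    "Lab": (1, 15),
    "Lbc": (1, 15),
    "Lcd": (0, 25),
}


class PositionID(NamedTuple):
    """A named position inside a repeat: element plus 1-based index."""

    element: str
    index: int

    def __str__(self) -> str:  # e.g. "Sa1", "Lab2"
        return f"{self.element}{self.index}"


def parse_position(text: str) -> PositionID:
    """Parse a position label such as ``Sa1`` or ``Lab12``."""
    for element in STRANDS + LOOPS:
        if text.startswith(element) and text[len(element):].isdigit():
            return PositionID(element, int(text[len(element):]))
    raise ValueError(f"unparseable position label: {text!r}")


def scored_positions() -> tuple[PositionID, ...]:
    """The 31 profile-scored positions: 24 strand + 7 conserved loop slots."""
    out: list[PositionID] = []
    for element in ELEMENT_ORDER:
        if element in STRANDS:
            out.extend(PositionID(element, i) for i in range(1, STRAND_LENGTH + 1))
        else:
            out.extend(
                PositionID(e, i) for (e, i) in SCORED_LOOP_POSITIONS if e == element
            )
    return tuple(out)


SCORED_POSITIONS: tuple[PositionID, ...] = scored_positions()
assert len(SCORED_POSITIONS) == 31


@dataclass(frozen=True)
class RepeatTemplate:
    """Template constraints: fixed strand length, scored loop slots, bounds."""

    strand_length: int = STRAND_LENGTH
    scored_loop_positions: tuple[PositionID, ...] = tuple(
        PositionID(e, i) for (e, i) in SCORED_LOOP_POSITIONS
    )
    loop_length_bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.loop_length_bounds.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"bad loop bounds for {name}: ({lo}, {hi})")


def _element_lengths(loop_lengths: Mapping[str, int]) -> list[tuple[str, int]]:
    return [
        (el, STRAND_LENGTH if el in STRANDS else int(loop_lengths[el]))
        for el in ELEMENT_ORDER
    ]


def repeat_length(loop_lengths: Mapping[str, int]) -> int:
    """Total residue span of one repeat: 24 strand residues plus its loops."""
    return 4 * STRAND_LENGTH + sum(int(loop_lengths[l]) for l in ("Lda", "Lab", "Lbc"))


def template_position_of(repeat_offset: int, loop_lengths: Mapping[str, int]) -> PositionID:
    """Name the residue at ``repeat_offset`` (0-based from Sd1) in a repeat
    with the given intra-repeat loop lengths."""
    if repeat_offset < 0:
        raise IndexError(f"offset {repeat_offset} out of range")
    pos = repeat_offset
    for element, length in _element_lengths(loop_lengths):
        if pos < length:
            return PositionID(element, pos + 1)
        pos -= length
    raise IndexError(
        f"offset {repeat_offset} out of range for repeat of length "
        f"{repeat_length(loop_lengths)}"
    )


def offset_of_position(position: PositionID, loop_lengths: Mapping[str, int]) -> int:
    """Inverse of :func:`template_position_of`."""
    offset = 0
    for element, length in _element_lengths(loop_lengths):
        if element == position.element:
            if not 1 <= position.index <= length:
                raise IndexError(f"{position} out of range (element length {length})")
            return offset + position.index - 1
        offset += length
    raise IndexError(f"{position} not inside the repeat template")


def candidate_span(start: int, loop_lengths: Mapping[str, int]) -> tuple[int, int]:
    """Half-open residue interval occupied by a repeat anchored at ``start``."""
    if start < 0:
        raise IndexError(f"negative start: {start}")
    return start, start + repeat_length(loop_lengths)


def scored_offsets(loop_lengths: Mapping[str, int]) -> list[tuple[PositionID, int | None]]:
    """Offsets (from Sd1) of the 31 scored positions for the given loops.

    Scored loop slots are N-terminally anchored; a slot falling beyond the
    actual loop length maps to ``None`` and contributes background (zero
    log-odds) to the profile score.
    """
    out: list[tuple[PositionID, int | None]] = []
    offset = 0
    for element, length in _element_lengths(loop_lengths):
        if element in STRANDS:
            out.extend(
                (PositionID(element, i + 1), offset + i) for i in range(STRAND_LENGTH)
            )
        else:
            for (e, i) in SCORED_LOOP_POSITIONS:
                if e != element:
                    continue
                out.append(
                    (PositionID(e, i), offset + i - 1 if i <= length else None)
                )
        offset += length
    return out


@dataclass
class RepeatCandidate:
    """A concrete placement of the Sd-Lda-Sa-Lab-Sb-Lbc-Sc template."""

    sequence_id: str
    start: int  # 0-based inclusive index of Sd1
    loop_lengths: dict[str, int]  # keys Lda, Lab, Lbc
    residues_by_position: dict[PositionID, str] = field(default_factory=dict)
    score_terms: dict[str, float] = field(default_factory=dict)
    S_repeat: float = 0.0

    @property
    def end(self) -> int:
        """0-based exclusive index just past Sc6."""
        return self.start + repeat_length(self.loop_lengths)

    def strand_start(self, strand: str) -> int:
        return self.start + offset_of_position(PositionID(strand, 1), self.loop_lengths)

    def strand_spans(self) -> dict[str, tuple[int, int]]:
        """Half-open absolute spans of the four strands."""
        return {
            s: (self.strand_start(s), self.strand_start(s) + STRAND_LENGTH)
            for s in STRANDS
        }

    def validate(self) -> None:
        span = candidate_span(self.start, self.loop_lengths)
        if span[1] - span[0] != repeat_length(self.loop_lengths):
            raise ValueError("inconsistent candidate span")
        if self.score_terms:
            total = sum(self.score_terms.values())
            if abs(total - self.S_repeat) > 1e-6:
                raise ValueError(
                    f"S_repeat {self.S_repeat} != sum of terms {total}"
                )


@dataclass
class DomainModel:
    """An ordered, non-overlapping chain of repeats with Lcd linker lengths."""

    repeats: list[RepeatCandidate]
    lcd_lengths: list[int] = field(default_factory=list)
    S_domain: float = 0.0

    @property
    def N_rep(self) -> int:
        return len(self.repeats)

    def __iter__(self) -> Iterator[RepeatCandidate]:
        return iter(self.repeats)

    def validate(self) -> None:
        reps = self.repeats
        if len(self.lcd_lengths) != max(0, len(reps) - 1):
            raise ValueError("lcd_lengths must have N_rep - 1 entries")
        for prev, nxt, lcd in zip(reps, reps[1:], self.lcd_lengths):
            if lcd < 0:
                raise ValueError("negative Lcd length")
            if nxt.start - prev.end != lcd:
                raise ValueError("Lcd length inconsistent with repeat coordinates")
            if nxt.start < prev.end:
                raise ValueError("overlapping repeats in domain")


def domain_from_repeats(repeats: Sequence[RepeatCandidate]) -> DomainModel:
    """Build a DomainModel from ordered repeats, deriving Lcd lengths."""
    reps = sorted(repeats, key=lambda r: r.start)
    lcd = [nxt.start - prev.end for prev, nxt in zip(reps, reps[1:])]
    dom = DomainModel(repeats=list(reps), lcd_lengths=lcd)
    dom.validate()
    return dom
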