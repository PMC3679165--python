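"""Synthetic sequences with ground truth, and the evaluation metrics.

The generator emulates the statistical structure the profile encodes:
strand and scored-loop residues are drawn from the per-position frequency
distributions, unscored loop residues from the background composition, and
loop lengths from the exponentiated loop-score tables.  Decoys of three
flavours (i.i.d. background, composition-preserving shuffles of a real
synthetic, helix-rich) provide ground-truth negatives.  The metrics are
the three-state Q3 percentage and the loose/tight repeat-detection
criteria (strands a, b, c — or a, b, c, d — recovered with at least
``overlap_min`` of six residues each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import CandidatePool, ClassificationReport, detect
from .profile_builder import (
    ALPHABET,
    AnnotatedRepeat,
    POSITION_INDEX,
    RepeatProfile,
    build_profile,
)
from .repeat_model import (
    DEFAULT_LOOP_BOUNDS,
    PositionID,
    STRAND_LENGTH,
    STRANDS,
    scored_offsets,
    repeat_length,
)
from .scoring import SSPrediction


@dataclass
class PlantedRepeat:
    start: int
    loop_lengths: dict[str, int]
    strand_starts: dict[str, int] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + repeat_length(self.loop_lengths)


@dataclass
class SyntheticTruth:
    """A generated sequence with its planted-repeat ground truth."""

    sequence_id: str
    sequence: str
    planted_repeats: list[PlantedRepeat]
    is_wd40: bool
    seed: int
    params: dict = field(default_factory=dict)
    ss: SSPrediction | None = None

    def reference_ss(self) -> str:
        """E at planted strand residues, C elsewhere."""
        labels = ["C"] * len(self.sequence)
        for rep in self.planted_repeats:
            for strand, s0 in rep.strand_starts.items():
                for i in range(s0, s0 + STRAND_LENGTH):
                    labels[i] = "E"
        return "".join(labels)

    def annotated_repeats(self) -> list[AnnotatedRepeat]:
        return [
            AnnotatedRepeat(
                sequence=self.sequence, strand_starts=dict(rep.strand_starts),
                source_id=self.sequence_id,
            )
            for rep in self.planted_repeats
        ]


def _sample_length(table, bounds: tuple[int, int], rng: np.random.Generator) -> int:
    lo, hi = bounds
    ls = np.arange(lo, hi + 1)
    weights = np.exp([table.score(int(l)) for l in ls])
    return int(rng.choice(ls, p=weights / weights.sum()))


def _sample_aa(p: np.ndarray, rng: np.random.Generator) -> str:
    return ALPHABET[int(rng.choice(20, p=p / p.sum()))]


def generate_wd40(
    profile: RepeatProfile,
    n_repeats: int = 7,
    seed: int = 0,
    sequence_id: str = "synthetic_wd40",
    force_pentad: bool = False,
    flank_range: tuple[int, int] = (5, 30),
    loop_bounds: dict[str, tuple[int, int]] | None = None,
) -> SyntheticTruth:
    """Sample a WD40-like sequence of ``n_repeats`` planted repeats."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    bounds = loop_bounds or DEFAULT_LOOP_BOUNDS
    rng = np.random.default_rng(seed)
    bg = profile.background
    P = profile.frequencies.P

    def background_run(n: int) -> list[str]:
        return [_sample_aa(bg, rng) for _ in range(n)]

    seq: list[str] = []
    planted: list[PlantedRepeat] = []
    seq.extend(background_run(int(rng.integers(*flank_range))))
    for r in range(n_repeats):
        if r > 0:
            lcd = _sample_length(profile.loop_scores["Lcd"], bounds["Lcd"], rng)
            lcd = max(lcd, 2) if force_pentad else lcd
            lcd_res = background_run(lcd)
            if force_pentad and lcd >= 2:
                lcd_res[1] = "D"
            seq.extend(lcd_res)
        loops = {
            name: _sample_length(profile.loop_scores[name], bounds[name], rng)
            for name in ("Lda", "Lab", "Lbc")
        }
        if force_pentad:
            loops["Lda"] = max(loops["Lda"], 3)
        start = len(seq)
        residues: list[str] = []
        offsets = dict()
        for pos, off in scored_offsets(loops):
            if off is not None:
                offsets[off] = pos
        for off in range(repeat_length(loops)):
            pos = offsets.get(off)
            if pos is None:
                residues.append(_sample_aa(bg, rng))
            else:
                residues.append(_sample_aa(P[POSITION_INDEX[pos]], rng))
        if force_pentad:
            for pos_name, res in (("Sc1", "S"), ("Lda3", "H"), ("Sb4", "S"), ("Sc5", "W")):
                el, idx = pos_name[:-1], int(pos_name[-1])
                target = [o for o, p in offsets.items() if p == PositionID(el, idx)]
                if target:
                    residues[target[0]] = res
        seq.extend(residues)
        rep = PlantedRepeat(start=start, loop_lengths=loops)
        off = start
        for el in ("Sd", "Sa", "Sb", "Sc"):
            rep.strand_starts[el] = off
            off += STRAND_LENGTH
            if el != "Sc":
                loop = {"Sd": "Lda", "Sa": "Lab", "Sb": "Lbc"}[el]
                off += loops[loop]
        planted.append(rep)
    seq.extend(background_run(int(rng.integers(*flank_range))))
    return SyntheticTruth(
        sequence_id=sequence_id, sequence="".join(seq), planted_repeats=planted,
        is_wd40=True, seed=seed,
        params={"n_repeats": n_repeats, "force_pentad": force_pentad},
    )


def generate_decoy(
    length: int,
    profile: RepeatProfile,
    seed: int = 0,
    mode: str = "iid-background",
    sequence_id: str = "decoy",
) -> SyntheticTruth:
    """Ground-truth negative sequence.

    Modes: ``iid-background`` draws residues i.i.d. from the profile
    background (decoy scores then probe positional signal, not
    composition); ``shuffled-wd40`` permutes a generated WD40 sequence,
    preserving its exact residue counts; ``helix-rich`` is an i.i.d. decoy
    paired with an all-helix external prediction.
    """
    if length < 30:
        raise ValueError("decoy length must be >= 30")
    rng = np.random.default_rng(seed)
    ss = None
    if mode == "iid-background" or mode == "helix-rich":
        seq = "".join(
            ALPHABET[i] for i in rng.choice(20, size=length, p=profile.background)
        )
        if mode == "helix-rich":
            ss = SSPrediction(states="H" * length, conf=[9] * length)
    elif mode == "shuffled-wd40":
        src = generate_wd40(profile, n_repeats=max(1, length // 45), seed=seed)
        chars = np.array(list(src.sequence))
        rng.shuffle(chars)
        seq = "".join(chars[:length]) if len(chars) >= length else "".join(chars)
    else:
        raise ValueError(f"unknown decoy mode {mode!r}")
    return SyntheticTruth(
        sequence_id=sequence_id, sequence=seq, planted_repeats=[], is_wd40=False,
        seed=seed, params={"mode": mode}, ss=ss,
    )


def generate_candidate_pool(
    n: int,
    seed: int = 0,
    sequence_length: int = 400,
    span_range: tuple[int, int] = (27, 60),
    score_range: tuple[float, float] = (12.0, 90.0),
) -> CandidatePool:
    """A random candidate pool (for assembly-engine studies): random
    placements with random loop lengths and scores over a blank sequence."""
    rng = np.random.default_rng(seed)
    starts, ldas, labs, lbcs, scores = [], [], [], [], []
    for _ in range(n):
        a, b, c = rng.integers(1, 16, size=3)
        length = 24 + a + b + c
        starts.append(int(rng.integers(0, max(1, sequence_length - length))))
        ldas.append(int(a)); labs.append(int(b)); lbcs.append(int(c))
        scores.append(float(rng.uniform(*score_range)))
    score = np.array(scores)
    pool = CandidatePool(
        sequence_id="random_pool", sequence="A" * sequence_length,
        start=np.array(starts), lda=np.array(ldas), lab=np.array(labs),
        lbc=np.array(lbcs),
        s_aa=score, s_loop=np.zeros(n), s_corr=np.zeros(n), s_ss=np.zeros(n),
        score=score,
    )
    order = np.lexsort((pool.end, pool.start))
    return pool.subset(order)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def q3(predicted: str, reference: str) -> float:
    """Percentage of residues whose three-state label matches."""
    if len(predicted) != len(reference):
        raise ValueError("label strings must have equal length")
    if not predicted:
        raise ValueError("empty label strings")
    hits = sum(a == b for a, b in zip(predicted, reference))
    return 100.0 * hits / len(predicted)


def _strand_found(pred_span: tuple[int, int], true_start: int, overlap_min: int) -> bool:
    s0, s1 = pred_span
    t0, t1 = true_start, true_start + STRAND_LENGTH
    return min(s1, t1) - max(s0, t0) >= overlap_min


def detection_metrics(
    report: ClassificationReport,
    truth: SyntheticTruth,
    criterion: str = "loose",
    overlap_min: int = 4,
) -> tuple[float, list[bool]]:
    """Per-repeat recovery under the loose (Sa, Sb, Sc) or tight
    (plus Sd) criterion; accuracy as a percentage of the planted repeats."""
    if criterion not in ("loose", "tight"):
        raise ValueError(f"unknown criterion {criterion!r}")
    needed = ("Sa", "Sb", "Sc") if criterion == "loose" else ("Sa", "Sb", "Sc", "Sd")
    predicted = [rep for dom in report.domains for rep in dom.repeats]
    hits: list[bool] = []
    for true_rep in truth.planted_repeats:
        found = any(
            all(
                _strand_found(p.strand_spans()[s], true_rep.strand_starts[s], overlap_min)
                for s in needed
            )
            for p in predicted
        )
        hits.append(found)
    accuracy = 100.0 * sum(hits) / len(hits) if hits else 0.0
    return accuracy, hits


def jackknife(
    dataset: list[SyntheticTruth],
    trainer=None,
    detector=None,
    criterion: str = "loose",
) -> dict:
    """Leave-one-out harness: retrain the profile without item i, detect on
    item i, score Q3 and repeat recovery; returns per-item and mean metrics.

    ``trainer`` maps a list of AnnotatedRepeat to a RepeatProfile (default:
    :func:`build_profile`); ``detector`` maps (sequence, profile, ss) to a
    ClassificationReport (default: the standard pipeline).
    """
    if len(dataset) < 3:
        raise ValueError("jack-knife needs at least 3 items")
    trainer = trainer or (lambda reps: build_profile(reps))
    detector = detector or (
        lambda item, prof: detect(item.sequence, prof, ss=item.ss,
                                  sequence_id=item.sequence_id, seed=item.seed)
    )
    per_item = []
    for i, item in enumerate(dataset):
        train_reps = [
            rep for j, other in enumerate(dataset) if j != i
            for rep in other.annotated_repeats()
        ]
        profile = trainer(train_reps)
        report = detector(item, profile)
        acc, _ = detection_metrics(report, item, criterion=criterion)
        per_item.append({
            "sequence_id": item.sequence_id,
            "q3": q3(report.ss_string, item.reference_ss()),
            "detection_accuracy": acc,
        })
    return {
        "per_item": per_item,
        "mean_q3": float(np.mean([d["q3"] for d in per_item])),
        "mean_detection_accuracy": float(
            np.mean([d["detection_accuracy"] for d in per_item])
        ),
    }
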