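"""Training of the WD40 repeat profile from annotated repeats.

The profile is the trained model behind the whole detector: per-position
residue frequencies at the 31 scored positions, entropy-derived position
weights, a background composition, per-loop length-score tables, the
Ser/Thr-Asp-His-Ser/Thr-Trp (SDHSW) pentad statistics and the repeat-count
regulator used during domain assembly.

Training input is a set of :class:`AnnotatedRepeat` records carrying the
source sequence and the 0-based starts of the four six-residue strands;
everything else (loop lengths, scored loop residues, inter-repeat Lcd
context) is derived from those landmarks.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .repeat_model import (
    SCORED_POSITIONS,
    SCORED_LOOP_POSITIONS,
    STRAND_LENGTH,
    STRANDS,
    PositionID,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Swiss-Prot-style eukaryotic amino-acid composition (overridable background).
DEFAULT_BACKGROUND: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0657, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

FREQUENCY_PSEUDO_COUNT = 1e-4
LOOP_PSEUDO_COUNT = 0.01
MAX_TRAINING_LOOP = 15  # loops longer than this are excluded from statistics

POSITION_INDEX = {pos: i for i, pos in enumerate(SCORED_POSITIONS)}


def background_array(background: dict[str, float] | None = None) -> np.ndarray:
    """Background frequencies as a normalized length-20 array over ALPHABET."""
    bg = background or DEFAULT_BACKGROUND
    arr = np.array([bg[aa] for aa in ALPHABET], dtype=float)
    return arr / arr.sum()


# ---------------------------------------------------------------------------
# Annotated repeats and their alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedRepeat:
    """One repeat annotated on its source sequence by strand landmarks."""

    sequence: str  # the full source sequence (context for loops / Lcd)
    strand_starts: dict[str, int]  # 0-based starts of Sd, Sa, Sb, Sc
    source_id: str = ""

    def validate(self) -> None:
        starts = [self.strand_starts.get(s) for s in STRANDS]
        if any(v is None for v in starts):
            raise ValueError(f"repeat {self.source_id!r}: missing strand starts")
        sd, sa, sb, sc = starts
        if not (0 <= sd and sd + STRAND_LENGTH <= sa and sa + STRAND_LENGTH <= sb
                and sb + STRAND_LENGTH <= sc and sc + STRAND_LENGTH <= len(self.sequence)):
            raise ValueError(
                f"repeat {self.source_id!r}: strands must be in order "
                "Sd < Sa < Sb < Sc, six residues each, within the sequence"
            )

    def loop_lengths(self) -> dict[str, int]:
        s = self.strand_starts
        return {
            "Lda": s["Sa"] - (s["Sd"] + STRAND_LENGTH),
            "Lab": s["Sb"] - (s["Sa"] + STRAND_LENGTH),
            "Lbc": s["Sc"] - (s["Sb"] + STRAND_LENGTH),
        }

    def residue_at(self, pos: PositionID) -> str | None:
        """Residue at a scored position, or None if the loop is too short."""
        s = self.strand_starts
        if pos.element in STRANDS:
            return self.sequence[s[pos.element] + pos.index - 1]
        loop_start = {"Lda": s["Sd"], "Lab": s["Sa"], "Lbc": s["Sb"]}[pos.element] + STRAND_LENGTH
        if pos.index > self.loop_lengths()[pos.element]:
            return None
        return self.sequence[loop_start + pos.index - 1]


def align_annotated_repeats(
    repeats: list[AnnotatedRepeat],
    max_loop: int = MAX_TRAINING_LOOP,
) -> dict[PositionID, list[str]]:
    """Column-wise alignment of annotated repeats keyed by PositionID.

    Strand columns are exact (the six annotated residues per strand); scored
    loop slots are filled N-terminally anchored.  Loops longer than
    ``max_loop`` residues are excluded from the loop-column statistics, but
    the strands of such repeats still count.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 annotated repeats")
    for rep in repeats:
        rep.validate()
    columns: dict[PositionID, list[str]] = {pos: [] for pos in SCORED_POSITIONS}
    for rep in repeats:
        loops = rep.loop_lengths()
        for pos in SCORED_POSITIONS:
            if pos.element not in STRANDS and loops[pos.element] > max_loop:
                continue
            res = rep.residue_at(pos)
            if res is not None and res in AA_INDEX:
                columns[pos].append(res)
    return columns


# ---------------------------------------------------------------------------
# Frequencies and weights
# ---------------------------------------------------------------------------

@dataclass
class FrequencyMatrix:
    """Per-position residue distributions at the 31 scored positions.

    ``P[k, i]`` is the pseudo-counted probability of residue ``ALPHABET[i]``
    at scored position ``SCORED_POSITIONS[k]``; raw counts are retained for
    the split-half stability test.
    """

    P: np.ndarray  # (31, 20)
    counts: np.ndarray  # (31, 20)
    n_repeats: int

    def p_of(self, pos: PositionID, aa: str) -> float:
        return float(self.P[POSITION_INDEX[pos], AA_INDEX[aa]])

    def validate(self) -> None:
        if self.P.shape != (len(SCORED_POSITIONS), 20):
            raise ValueError("frequency matrix must be 31 x 20")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("position distributions must sum to 1")
        if np.any(self.P <= 0):
            raise ValueError("pseudo-counts must leave no zero probabilities")


def estimate_frequencies(
    alignment: dict[PositionID, list[str]],
    pseudo_count: float = FREQUENCY_PSEUDO_COUNT,
    background: np.ndarray | None = None,
) -> FrequencyMatrix:
    """Pseudo-counted per-position distributions from an alignment.

    Every observed count ``c`` becomes ``(c + pc) / (n + 20 pc)``.  A column
    with no observations at all (a loop slot never occupied) falls back to
    the background distribution so that its log-odds vanish.
    """
    if not any(alignment.values()):
        raise ValueError("empty alignment")
    bg = background if background is not None else background_array()
    counts = np.zeros((len(SCORED_POSITIONS), 20))
    n_rep = 0
    for k, pos in enumerate(SCORED_POSITIONS):
        col = alignment.get(pos, [])
        n_rep = max(n_rep, len(col))
        for aa, c in Counter(col).items():
            counts[k, AA_INDEX[aa]] = c
    P = np.empty_like(counts)
    for k in range(len(SCORED_POSITIONS)):
        n = counts[k].sum()
        if n == 0:
            P[k] = bg
        else:
            P[k] = (counts[k] + pseudo_count) / (n + 20 * pseudo_count)
    return FrequencyMatrix(P=P, counts=counts, n_repeats=int(n_rep))


def position_weight(p: np.ndarray, mode: str = "content") -> float:
    """Position weight from its residue distribution.

    ``content`` (default): information content log2(20) - H_k, so conserved
    positions weigh more; ``entropy``: the raw Shannon entropy H_k.
    """
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    H = float(-(p * np.log2(p)).sum())
    if mode == "content":
        return max(0.0, math.log2(20) - H)
    if mode == "entropy":
        return H
    raise ValueError(f"unknown weight mode {mode!r}")


# ---------------------------------------------------------------------------
# Loop-length scores
# ---------------------------------------------------------------------------

@dataclass
class LoopScoreTable:
    """Length -> score table for one loop, with the long-loop penalty.

    The fitted part covers lengths up to ``l0`` (where the fitted curve drops
    below 1); beyond that the empirical linear penalty ``1 - t (l - l0)``
    takes over, blended over a window of width ``t0``.
    """

    name: str
    scores: dict[int, float]
    t: float
    t0: float
    l0: int
    pseudo_count: float = LOOP_PSEUDO_COUNT

    def score(self, length: int) -> float:
        length = int(length)
        if length in self.scores:
            return self.scores[length]
        # outside the tabulated domain: linear-penalty extrapolation
        return 1.0 - self.t * (length - self.l0)

    @property
    def modal_length(self) -> int:
        return max(self.scores, key=self.scores.get)


def fit_loop_scores(
    counts: dict[int, int],
    lmin: int,
    lmax: int,
    pseudo_count: float = LOOP_PSEUDO_COUNT,
    penalty_slope: float = 0.5,
    smoothing_window: float = 2.0,
    name: str = "loop",
) -> LoopScoreTable:
    """Fit a loop-length score table from observed length counts.

    Procedure (documented in the methods note): pseudo-counted length
    frequencies are smoothed with a 1-2-1 moving average of their
    log-probabilities; a quadratic in ``l`` is fitted to the smoothed
    log-scores by frequency-weighted least squares; ``l0`` is the first
    length past the fitted maximum where the fit drops below 1; beyond
    ``l0`` the linear penalty ``1 - t (l - l0)`` applies, blended over a
    window of width ``t0`` and forced strictly decreasing.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero loop length counts")
    ls = np.arange(lmin, lmax + 1)
    K = len(ls)
    f = np.array([(counts.get(int(l), 0) + pseudo_count) for l in ls], dtype=float)
    f /= total + pseudo_count * K
    floor = pseudo_count / (total + pseudo_count * K)
    raw = np.log(f / floor)  # 0 for never-observed lengths
    # 1-2-1 smoothing of the log-scores and of the fit weights
    padded = np.concatenate([raw[:1], raw, raw[-1:]])
    smooth = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
    fpad = np.concatenate([f[:1], f, f[-1:]])
    f_smooth = 0.25 * fpad[:-2] + 0.5 * fpad[1:-1] + 0.25 * fpad[2:]
    W = np.sqrt(f_smooth)
    A = np.stack([np.ones_like(ls, dtype=float), ls.astype(float), ls.astype(float) ** 2], axis=1)
    coef, *_ = np.linalg.lstsq(A * W[:, None], smooth * W, rcond=None)
    fit = A @ coef
    if coef[2] >= 0:  # non-concave fit (degenerate counts): use the smoothed curve
        fit = smooth
    peak = int(ls[int(np.argmax(fit))])
    # l0: first length past the peak where the fitted score drops below 1
    l0 = int(ls[-1])
    for l, v in zip(ls, fit):
        if l > peak and v < 1.0:
            l0 = int(l)
            break
    t0 = max(smoothing_window, 1.0)
    scores: dict[int, float] = {}
    for l, v in zip(ls, fit):
        if l <= l0:
            scores[int(l)] = float(v)
        else:
            lam = min(1.0, (l - l0) / t0)
            penalty = 1.0 - penalty_slope * (l - l0)
            scores[int(l)] = float((1 - lam) * v + lam * penalty)
    # enforce strict decrease beyond l0
    for l in range(l0 + 1, int(ls[-1]) + 1):
        if l in scores and l - 1 in scores:
            scores[l] = min(scores[l], scores[l - 1] - 1e-9)
    return LoopScoreTable(
        name=name, scores=scores, t=penalty_slope, t0=t0, l0=l0,
        pseudo_count=pseudo_count,
    )


# ---------------------------------------------------------------------------
# Tetrad statistics
# ---------------------------------------------------------------------------

#: Pentad slot names in order and their accepted residue classes.
PENTAD_SLOTS = ("Sc1", "Lcd2", "Lda3", "Sb4", "Sc5")
PENTAD_CLASSES: dict[str, frozenset[str]] = {
    "Sc1": frozenset("ST"),
    "Lcd2": frozenset("D"),
    "Lda3": frozenset("H"),
    "Sb4": frozenset("ST"),
    "Sc5": frozenset("W"),
}


@dataclass
class TetradModel:
    """Probabilities of the SDHSW pentad and its nested tetrad / triad.

    Slots (Sc1, Lcd2, Lda3, Sb4, Sc5) accept (S/T, D, H, S/T, W).  The triad
    is D-H-S/T (slots Lcd2, Lda3, Sb4), the DHSW tetrad adds the Trp, the
    pentad adds the first Ser/Thr.  Bonuses are co-occurrence log-odds
    against slot-wise independence, clamped at zero.
    """

    p_pentad: float
    p_tetrad: float
    p_triad: float
    slot_marginals: dict[str, float]  # per-slot class probability
    classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(PENTAD_CLASSES)
    )

    def validate(self) -> None:
        if not (0 < self.p_pentad <= self.p_tetrad <= self.p_triad):
            raise ValueError("motif probabilities must nest: pentad <= tetrad <= triad")

    def _bonus(self, p_obs: float, slots: tuple[str, ...]) -> float:
        p_indep = 1.0
        for s in slots:
            p_indep *= self.slot_marginals[s]
        return max(0.0, math.log(p_obs / p_indep))

    @property
    def triad_bonus(self) -> float:
        return self._bonus(self.p_triad, ("Lcd2", "Lda3", "Sb4"))

    @property
    def tetrad_bonus(self) -> float:
        return self._bonus(self.p_tetrad, ("Lcd2", "Lda3", "Sb4", "Sc5"))

    @property
    def pentad_bonus(self) -> float:
        return self._bonus(self.p_pentad, PENTAD_SLOTS)


def _slot_residues(rep: AnnotatedRepeat, prev: AnnotatedRepeat | None) -> dict[str, str | None]:
    s = rep.strand_starts
    seq = rep.sequence
    out: dict[str, str | None] = {
        "Sc1": seq[s["Sc"]],
        "Lda3": rep.residue_at(PositionID("Lda", 3)),
        "Sb4": seq[s["Sb"] + 3],
        "Sc5": seq[s["Sc"] + 4],
        "Lcd2": None,
    }
    if prev is not None:
        lcd_start = prev.strand_starts["Sc"] + STRAND_LENGTH
        lcd_len = s["Sd"] - lcd_start
        if lcd_len >= 2:
            out["Lcd2"] = seq[lcd_start + 1]
    return out


def estimate_tetrad_model(
    repeats: list[AnnotatedRepeat],
    pseudo_count: float = LOOP_PSEUDO_COUNT,
) -> TetradModel:
    """Empirical pentad/tetrad/triad probabilities from annotated repeats.

    Repeats are grouped by source and ordered; the Lcd2 slot is read from
    the inter-repeat loop preceding each repeat.  Repeats without that
    context (first repeat of a source) are excluded from the denominators.
    """
    by_source: dict[str, list[AnnotatedRepeat]] = defaultdict(list)
    for rep in repeats:
        by_source[rep.source_id].append(rep)
    n = n_triad = n_tetrad = n_pentad = 0
    slot_hits = Counter()
    slot_n = Counter()
    for source, reps in by_source.items():
        reps = sorted(reps, key=lambda r: r.strand_starts["Sd"])
        for i, rep in enumerate(reps):
            prev = reps[i - 1] if i > 0 else None
            slots = _slot_residues(rep, prev)
            for name, res in slots.items():
                if res is not None:
                    slot_n[name] += 1
                    if res in PENTAD_CLASSES[name]:
                        slot_hits[name] += 1
            if slots["Lcd2"] is None:
                continue
            ok = {name: res is not None and res in PENTAD_CLASSES[name]
                  for name, res in slots.items()}
            n += 1
            if ok["Lcd2"] and ok["Lda3"] and ok["Sb4"]:
                n_triad += 1
                if ok["Sc5"]:
                    n_tetrad += 1
                    if ok["Sc1"]:
                        n_pentad += 1
    if n == 0:
        raise ValueError("no repeat has inter-repeat context for the Lcd2 slot")
    prob = lambda k: (k + pseudo_count) / (n + 2 * pseudo_count)
    marginals = {
        name: (slot_hits[name] + pseudo_count) / (slot_n[name] + 2 * pseudo_count)
        for name in PENTAD_SLOTS
    }
    model = TetradModel(
        p_pentad=prob(n_pentad), p_tetrad=prob(n_tetrad), p_triad=prob(n_triad),
        slot_marginals=marginals,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Regulator
# ---------------------------------------------------------------------------

@dataclass
class RegulatorTable:
    """Repeat-count regulator R(N_rep) used during domain assembly.

    Rewards domains with ~7-fold repeat counts (local maxima at 7, 14, 21,
    28, 35); only active while assembling, removed from final scores.
    """

    values: dict[int, float]
    provenance: str = "initial-gaussian"

    def value(self, n_rep: int) -> float:
        n = max(1, min(int(n_rep), max(self.values)))
        return self.values[n]


def initial_regulator(sigma: float = 1.0, amplitude: float = 20.0, n_max: int = 40) -> RegulatorTable:
    """Five overlapping Gaussians centred at 7, 14, 21, 28 and 35."""
    values = {}
    for n in range(1, n_max + 1):
        values[n] = float(sum(
            amplitude * math.exp(-((n - c) ** 2) / (2 * sigma ** 2))
            for c in (7, 14, 21, 28, 35)
        ))
    return RegulatorTable(values=values, provenance="initial-gaussian")


def modified_regulator(sigma: float = 1.0, amplitude: float = 20.0, n_max: int = 40) -> RegulatorTable:
    """Adjusted regulator: 6- and 8-repeat domains get partial credit
    (both occur in real propellers) and incomplete chains below six repeats
    are penalized, steering assembly toward complete domains."""
    base = initial_regulator(sigma=sigma, amplitude=amplitude, n_max=n_max)
    values = dict(base.values)
    for k in range(5):
        for d in (-1, 1):  # one repeat either side of each 7k centre
            n = 7 * (k + 1) + d
            if 1 <= n <= n_max:
                values[n] = max(values[n], 0.4 * amplitude)
    for n in range(1, 6):
        values[n] = values[n] - 10.0 * (6 - n)
    return RegulatorTable(values=values, provenance="modified")


# ---------------------------------------------------------------------------
# The assembled profile
# ---------------------------------------------------------------------------

@dataclass
class RepeatProfile:
    """The trained WD40 repeat model consumed by scoring and detection."""

    frequencies: FrequencyMatrix
    weights: np.ndarray  # (31,)
    background: np.ndarray  # (20,)
    loop_scores: dict[str, LoopScoreTable]  # keys Lda, Lab, Lbc, Lcd
    tetrad: TetradModel
    regulator: RegulatorTable
    provenance: str = ""
    weight_mode: str = "content"
    _wlo: np.ndarray | None = field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        self.frequencies.validate()
        if abs(float(self.background.sum()) - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        if self.weights.shape != (len(SCORED_POSITIONS),):
            raise ValueError("weights must cover the 31 scored positions")
        for name in ("Lda", "Lab", "Lbc", "Lcd"):
            if name not in self.loop_scores:
                raise ValueError(f"missing loop score table {name}")
        self.tetrad.validate()

    @property
    def weighted_log_odds(self) -> np.ndarray:
        """(31, 21) matrix of w_k * ln(P_k(i) / P_all(i)); the extra last
        column scores unknown residues at background (zero)."""
        if self._wlo is None:
            lo = np.log(self.frequencies.P) - np.log(self.background)[None, :]
            wlo = self.weights[:, None] * lo
            self._wlo = np.concatenate([wlo, np.zeros((wlo.shape[0], 1))], axis=1)
        return self._wlo


def compute_weights(freq: FrequencyMatrix, mode: str = "content") -> np.ndarray:
    return np.array([position_weight(freq.P[k], mode) for k in range(freq.P.shape[0])])


def build_profile(
    repeats: list[AnnotatedRepeat],
    background: dict[str, float] | None = None,
    weight_mode: str = "content",
    penalty_slopes: dict[str, float] | None = None,
    regulator: RegulatorTable | None = None,
    loop_bounds: dict[str, tuple[int, int]] | None = None,
    provenance: str = "trained",
) -> RepeatProfile:
    """Train a full RepeatProfile from annotated repeats."""
    from .repeat_model import DEFAULT_LOOP_BOUNDS

    bounds = loop_bounds or DEFAULT_LOOP_BOUNDS
    slopes = penalty_slopes or {}
    bg = background_array(background)
    alignment = align_annotated_repeats(repeats)
    freq = estimate_frequencies(alignment, background=bg)
    weights = compute_weights(freq, weight_mode)
    # loop length counts
    loop_counts: dict[str, Counter] = {name: Counter() for name in ("Lda", "Lab", "Lbc", "Lcd")}
    by_source: dict[str, list[AnnotatedRepeat]] = defaultdict(list)
    for rep in repeats:
        by_source[rep.source_id].append(rep)
        for name, l in rep.loop_lengths().items():
            if l <= MAX_TRAINING_LOOP:
                loop_counts[name][l] += 1
    for source, reps in by_source.items():
        reps = sorted(reps, key=lambda r: r.strand_starts["Sd"])
        for prev, nxt in zip(reps, reps[1:]):
            lcd = nxt.strand_starts["Sd"] - (prev.strand_starts["Sc"] + STRAND_LENGTH)
            if 0 <= lcd <= bounds["Lcd"][1]:
                loop_counts["Lcd"][lcd] += 1
    tables = {}
    for name in ("Lda", "Lab", "Lbc", "Lcd"):
        lmin, lmax = bounds[name]
        tables[name] = fit_loop_scores(
            dict(loop_counts[name]), lmin, lmax,
            penalty_slope=slopes.get(name, 0.5), name=name,
        )
    tetrad = estimate_tetrad_model(repeats)
    profile = RepeatProfile(
        frequencies=freq, weights=weights, background=bg, loop_scores=tables,
        tetrad=tetrad, regulator=regulator or modified_regulator(),
        provenance=provenance, weight_mode=weight_mode,
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Logo stability
# ---------------------------------------------------------------------------

def similarity_coefficient(X: FrequencyMatrix | np.ndarray, Y: FrequencyMatrix | np.ndarray) -> float:
    """Cosine similarity between two flattened frequency matrices.

    Equals 1 exactly when the two distributions are proportional after
    normalization, 0 on disjoint supports.
    """
    x = (X.P if isinstance(X, FrequencyMatrix) else np.asarray(X, dtype=float)).ravel()
    y = (Y.P if isinstance(Y, FrequencyMatrix) else np.asarray(Y, dtype=float)).ravel()
    if x.shape != y.shape:
        raise ValueError("matrices must share the same position set")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm frequency matrix")
    u, v = x / nx, y / ny
    if np.array_equal(u, v):  # proportional inputs: exactly 1
        return 1.0
    return float(min(1.0, np.dot(u, v)))


def split_half_stability(
    repeats: list[AnnotatedRepeat],
    n_trials: int = 10,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Random-halving logo stability: per-trial similarity coefficients and
    their mean.  Each trial permutes the repeats, splits at the midpoint,
    builds a frequency matrix from each half and compares the two."""
    if len(repeats) < 4:
        raise ValueError("need at least 4 repeats for a split-half test")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    for _ in range(n_trials):
        order = rng.permutation(len(repeats))
        half = len(repeats) // 2
        groups = ([repeats[i] for i in order[:half]], [repeats[i] for i in order[half:]])
        mats = [
            estimate_frequencies(align_annotated_repeats(g)) for g in groups
        ]
        values.append(similarity_coefficient(*mats))
    return values, float(np.mean(values))
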