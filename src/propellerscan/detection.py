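"""The full detection pipeline.

Stages, in order: terminal trimming on an external secondary-structure
prediction, exhaustive candidate enumeration over (start, l_da, l_ab, l_bc),
the overlap filter at the 35-score dominance level, the early exit when no
candidate reaches 45, pool thresholding (median policy, floor 10), domain
assembly by a genetic algorithm (with an exact dynamic-programming oracle
available), the WD40/non-WD40 classification at ASr 48 / DHSW-tetrad
evidence / six-repeat minimum, and per-residue secondary-structure output.

Candidate pools are held as flat numpy arrays for speed; individual
:class:`~propellerscan.repeat_model.RepeatCandidate` objects are
materialized only for the repeats that make it into a reported domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .profile_builder import AA_INDEX, POSITION_INDEX, RepeatProfile
from .repeat_model import (
    DEFAULT_LOOP_BOUNDS,
    DomainModel,
    PositionID,
    RepeatCandidate,
    STRAND_LENGTH,
    STRANDS,
    domain_from_repeats,
    scored_offsets,
)
from .scoring import (
    SSPrediction,
    SS_COEFFICIENTS,
    average_repeat_score,
    lcd_score,
    regulator,
    score_corr,
    score_domain,
    score_repeat,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds and assembly parameters of the pipeline."""

    min_repeat_score: float = 10.0  # candidate generation floor
    dominate_score: float = 35.0  # overlap filter dominance level
    early_exit_score: float = 45.0  # S_max below this -> not WD40
    asr_threshold: float = 48.0  # classification boundary on ASr
    min_repeats: int = 6  # minimum repeats for a WD40 domain
    restart_threshold: float = 10.0  # T reset value for the GA restart
    trim_window: int = 30
    trim_helix_fraction: float = 0.5
    loop_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_BOUNDS)
    )
    # genetic algorithm
    population_size: int = 200
    mutation_rate: float = 0.2
    crossover_rate: float = 0.5
    elongation_rate: float = 0.3
    max_generations: int = 500
    convergence_top: int = 10

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["loop_bounds"] = {k: list(v) for k, v in self.loop_bounds.items()}
        return d


# ---------------------------------------------------------------------------
# Terminal trimming
# ---------------------------------------------------------------------------

def trim_termini(
    sequence: str,
    ss: SSPrediction | None = None,
    window: int = 30,
    helix_fraction: float = 0.5,
) -> tuple[int, int]:
    """Sub-interval of the sequence worth scanning.

    Without an external prediction the full sequence is returned.  With one,
    maximal terminal stretches whose sliding helix fraction exceeds the
    cutoff are stripped from each end; interior residues are never removed.
    """
    L = len(sequence)
    if ss is None or L < window:
        return 0, L
    is_h = np.array([1.0 if s == "H" else 0.0 for s in ss.states[:L]])
    csum = np.concatenate([[0.0], np.cumsum(is_h)])
    def frac(i: int) -> float:  # helix fraction of window starting at i
        return (csum[i + window] - csum[i]) / window
    lo = 0
    while lo + window <= L and frac(lo) > helix_fraction:
        lo += 1
    hi = L
    while hi - window >= lo and frac(hi - window) > helix_fraction:
        hi -= 1
    if (lo, hi) != (0, L):
        logger.info("trimmed scan interval to [%d, %d) of %d residues", lo, hi, L)
    return lo, hi


# ---------------------------------------------------------------------------
# Candidate pool
# ---------------------------------------------------------------------------

@dataclass
class CandidatePool:
    """Flat arrays of enumerated repeat candidates, sorted by start."""

    sequence_id: str
    sequence: str
    start: np.ndarray
    lda: np.ndarray
    lab: np.ndarray
    lbc: np.ndarray
    s_aa: np.ndarray
    s_loop: np.ndarray
    s_corr: np.ndarray
    s_ss: np.ndarray
    score: np.ndarray
    T: float = 0.0

    @property
    def end(self) -> np.ndarray:
        return self.start + 24 + self.lda + self.lab + self.lbc

    @property
    def N(self) -> int:
        return int(self.score.size)

    @property
    def S_max(self) -> float:
        return float(self.score.max()) if self.N else float("-inf")

    def subset(self, idx: np.ndarray) -> "CandidatePool":
        return CandidatePool(
            sequence_id=self.sequence_id, sequence=self.sequence,
            start=self.start[idx], lda=self.lda[idx], lab=self.lab[idx],
            lbc=self.lbc[idx], s_aa=self.s_aa[idx], s_loop=self.s_loop[idx],
            s_corr=self.s_corr[idx], s_ss=self.s_ss[idx],
            score=self.score[idx], T=self.T,
        )

    def materialize(self, i: int) -> RepeatCandidate:
        """Build the full RepeatCandidate object for pool entry ``i``."""
        loops = {"Lda": int(self.lda[i]), "Lab": int(self.lab[i]), "Lbc": int(self.lbc[i])}
        start = int(self.start[i])
        residues = {}
        for pos, off in scored_offsets(loops):
            if off is not None:
                residues[pos] = self.sequence[start + off]
        cand = RepeatCandidate(
            sequence_id=self.sequence_id, start=start, loop_lengths=loops,
            residues_by_position=residues,
            score_terms={
                "S_aa": float(self.s_aa[i]), "S_loop_len": float(self.s_loop[i]),
                "S_corr": float(self.s_corr[i]), "S_psipred": float(self.s_ss[i]),
            },
            S_repeat=float(self.score[i]),
        )
        return cand


def candidate_at(
    sequence: str,
    start: int,
    loop_lengths: dict[str, int],
    sequence_id: str = "",
) -> RepeatCandidate:
    """A RepeatCandidate for a known template placement (unscored)."""
    residues = {}
    for pos, off in scored_offsets(loop_lengths):
        if off is not None and start + off < len(sequence):
            residues[pos] = sequence[start + off]
    return RepeatCandidate(
        sequence_id=sequence_id, start=start, loop_lengths=dict(loop_lengths),
        residues_by_position=residues,
    )


def _empty_pool(sequence_id: str, sequence: str) -> CandidatePool:
    z = np.zeros(0)
    zi = np.zeros(0, dtype=int)
    return CandidatePool(sequence_id, sequence, zi, zi, zi, zi, z, z, z, z, z)


def enumerate_candidates(
    sequence: str,
    profile: RepeatProfile,
    ss: SSPrediction | None = None,
    sequence_id: str = "",
    interval: tuple[int, int] | None = None,
    min_score: float = 10.0,
    loop_bounds: dict[str, tuple[int, int]] | None = None,
) -> CandidatePool:
    """Exhaustive enumeration of template placements scoring above the floor.

    For every (l_da, l_ab, l_bc) combination within the loop bounds the
    per-start scores are computed with sliding-window sums, so the whole
    O(L * 15^3) grid is covered in vectorized passes.
    """
    bounds = loop_bounds or DEFAULT_LOOP_BOUNDS
    lo, hi = interval if interval is not None else (0, len(sequence))
    sub = sequence[lo:hi]
    L = len(sub)
    if L < 24:
        return _empty_pool(sequence_id, sequence)

    codes = np.array([AA_INDEX.get(c, 20) for c in sub], dtype=np.int64)
    wlo = profile.weighted_log_odds  # (31, 21)

    def pos_row(el: str, idx: int) -> np.ndarray:
        return wlo[POSITION_INDEX[PositionID(el, idx)]]

    def padded(values: np.ndarray) -> np.ndarray:
        out = np.zeros(L)
        out[: values.size] = values
        return out

    def strand_arr(el: str) -> np.ndarray:
        m = L - STRAND_LENGTH + 1
        acc = np.zeros(m)
        for j in range(STRAND_LENGTH):
            acc += pos_row(el, j + 1)[codes[j : j + m]]
        return padded(acc)

    sd, sa, sb, sc = (strand_arr(e) for e in STRANDS)
    lda2 = padded(pos_row("Lda", 2)[codes[1:]])
    lda3 = padded(pos_row("Lda", 3)[codes[2:]])
    lab_part = [padded(pos_row("Lab", k)[codes[k - 1 :]]) for k in (1, 2, 3, 4)]
    lab_cum = {j: sum(lab_part[:j]) for j in (1, 2, 3, 4)}
    lbc3 = padded(pos_row("Lbc", 3)[codes[2:]])

    # sliding 6-window external-SS strand term
    if ss is not None:
        if len(ss) < len(sequence):
            raise ValueError("secondary structure prediction shorter than sequence")
        per_res = np.array(
            [ss.conf[lo + i] * SS_COEFFICIENTS[ss.states[lo + i]] for i in range(L)]
        )
        cs = np.concatenate([[0.0], np.cumsum(per_res)])
        pp6 = padded(cs[STRAND_LENGTH:] - cs[: L - STRAND_LENGTH + 1])
    else:
        pp6 = np.zeros(L)

    # context-free motif level (Asp slot waived; pentad needs context)
    classes = profile.tetrad.classes
    def class_arr(slot: str, offset: int) -> np.ndarray:
        members = classes[slot]
        flags = np.array([1.0 if c in members else 0.0 for c in sub])
        return padded(flags[offset:])
    lda3_ok = class_arr("Lda3", 2)
    sb4_ok = class_arr("Sb4", 3)
    sc5_ok = class_arr("Sc5", 4)
    triad_b = profile.tetrad.triad_bonus
    tetrad_b = max(profile.tetrad.tetrad_bonus, triad_b)  # nested-motif award

    ltab = {n: profile.loop_scores[n] for n in ("Lda", "Lab", "Lbc")}
    out_start, out_a, out_b, out_c = [], [], [], []
    out_aa, out_loop, out_corr, out_ss, out_total = [], [], [], [], []

    (a_lo, a_hi), (b_lo, b_hi) = bounds["Lda"], bounds["Lab"]
    c_lo, c_hi = bounds["Lbc"]
    for a in range(a_lo, a_hi + 1):
        for b in range(b_lo, b_hi + 1):
            for c in range(c_lo, c_hi + 1):
                length = 24 + a + b + c
                m = L - length + 1
                if m <= 0:
                    continue
                u2, u3 = 6 + a, 12 + a
                u4, u5, u6 = 12 + a + b, 18 + a + b, 18 + a + b + c
                s_aa = sd[:m] + sa[u2 : u2 + m] + sb[u4 : u4 + m] + sc[u6 : u6 + m]
                if a >= 2:
                    s_aa = s_aa + lda2[6 : 6 + m]
                if a >= 3:
                    s_aa = s_aa + lda3[6 : 6 + m]
                s_aa = s_aa + lab_cum[min(b, 4)][u3 : u3 + m]
                if c >= 3:
                    s_aa = s_aa + lbc3[u5 : u5 + m]
                s_loop = ltab["Lda"].score(a) + ltab["Lab"].score(b) + ltab["Lbc"].score(c)
                if a >= 3:
                    base = lda3_ok[6 : 6 + m] * sb4_ok[u4 : u4 + m]
                else:
                    base = np.zeros(m)
                s_corr = base * np.where(sc5_ok[u6 : u6 + m] > 0, tetrad_b, triad_b)
                s_ss = pp6[:m] + pp6[u2 : u2 + m] + pp6[u4 : u4 + m] + pp6[u6 : u6 + m]
                total = s_aa + s_loop + s_corr + s_ss
                keep = np.nonzero(total > min_score)[0]
                if keep.size:
                    out_start.append(keep + lo)
                    out_a.append(np.full(keep.size, a))
                    out_b.append(np.full(keep.size, b))
                    out_c.append(np.full(keep.size, c))
                    out_aa.append(s_aa[keep])
                    out_loop.append(np.full(keep.size, s_loop))
                    out_corr.append(s_corr[keep])
                    out_ss.append(s_ss[keep])
                    out_total.append(total[keep])
    if not out_start:
        return _empty_pool(sequence_id, sequence)
    pool = CandidatePool(
        sequence_id=sequence_id, sequence=sequence,
        start=np.concatenate(out_start).astype(int),
        lda=np.concatenate(out_a).astype(int),
        lab=np.concatenate(out_b).astype(int),
        lbc=np.concatenate(out_c).astype(int),
        s_aa=np.concatenate(out_aa), s_loop=np.concatenate(out_loop),
        s_corr=np.concatenate(out_corr), s_ss=np.concatenate(out_ss),
        score=np.concatenate(out_total),
    )
    order = np.lexsort((pool.end, pool.start))
    return pool.subset(order)


# ---------------------------------------------------------------------------
# Pool filters
# ---------------------------------------------------------------------------

def overlap_filter(pool: CandidatePool, dominate_score: float = 35.0) -> CandidatePool:
    """Drop candidates overlapped by a stronger retained candidate.

    Candidates are processed in descending score (ties: smaller start, then
    shorter span); one is removed iff it overlaps a retained candidate whose
    score exceeds the dominance level and strictly exceeds its own.
    """
    if pool.N == 0:
        return pool
    ends = pool.end
    spans = ends - pool.start
    order = np.lexsort((spans, pool.start, -pool.score))
    L = len(pool.sequence)
    coverage = np.zeros(L)  # max retained dominator score per residue
    keep = np.zeros(pool.N, dtype=bool)
    for i in order:
        s, e, sc = int(pool.start[i]), int(ends[i]), float(pool.score[i])
        if coverage[s:e].max(initial=0.0) > sc:
            continue
        keep[i] = True
        if sc > dominate_score:
            np.maximum(coverage[s:e], sc, out=coverage[s:e])
    n_removed = pool.N - int(keep.sum())
    if n_removed:
        logger.info("overlap filter removed %d of %d candidates", n_removed, pool.N)
    return pool.subset(np.nonzero(keep)[0])


def early_exit(pool: CandidatePool, threshold: float = 45.0) -> bool:
    """True iff the pool's best score falls below the cutoff (not a WD40)."""
    flag = pool.N == 0 or pool.S_max < threshold
    if flag:
        logger.info("early exit: S_max %.2f < %.2f", pool.S_max, threshold)
    return flag


def pool_threshold(pool: CandidatePool) -> float:
    """Median pool-score policy for the threshold T, floored at 10."""
    if pool.N == 0:
        raise ValueError("empty pool has no threshold")
    return max(10.0, float(np.median(pool.score)))


def apply_threshold(pool: CandidatePool, T: float) -> CandidatePool:
    out = pool.subset(np.nonzero(pool.score >= T)[0])
    out.T = T
    logger.info("pool threshold T=%.2f keeps %d of %d candidates", T, out.N, pool.N)
    return out


# ---------------------------------------------------------------------------
# Exact assembly oracle (weighted interval scheduling + count regulator)
# ---------------------------------------------------------------------------

def _lcd_lookup(profile: RepeatProfile, max_gap: int) -> np.ndarray:
    return np.array([lcd_score(g, profile) for g in range(max_gap + 1)])

def _chain_score(pool: CandidatePool, idx: list[int], profile: RepeatProfile,
                 use_regulator: bool) -> float:
    total = float(pool.score[idx].sum()) if idx else 0.0
    ends = pool.end
    for i, j in zip(idx, idx[1:]):
        total += lcd_score(int(pool.start[j] - ends[i]), profile)
    if use_regulator and idx:
        total += regulator(len(idx), profile.regulator)
    return total


def dp_optimal(pool: CandidatePool, profile: RepeatProfile) -> list[int]:
    """Exact maximization of the regulated domain score over ordered
    non-overlapping candidate subsets.

    Dynamic programming over candidates sorted by end coordinate with an
    explicit repeat-count state, so the count-dependent regulator is handled
    exactly.  Returns pool indices of the optimal chain (possibly empty).
    """
    N = pool.N
    if N == 0:
        return []
    ends = pool.end
    starts = pool.start
    order = np.argsort(ends, kind="stable")
    e_sorted = ends[order]
    s_sorted = starts[order]
    sc_sorted = pool.score[order]
    max_gap = int(len(pool.sequence))
    lcd_tab = _lcd_lookup(profile, max_gap)
    C = min(N, max(profile.regulator.values))
    NEG = -1e18
    dp = np.full((C + 1, N), NEG)
    parent = np.full((C + 1, N), -1, dtype=int)
    dp[1, :] = sc_sorted
    for j in range(N):
        compat = np.nonzero(e_sorted[: j] <= s_sorted[j])[0]
        if compat.size == 0:
            continue
        gaps = (s_sorted[j] - e_sorted[compat]).astype(int)
        link = lcd_tab[gaps]
        for c in range(2, C + 1):
            vals = dp[c - 1, compat] + link
            k = int(np.argmax(vals))
            if vals[k] > NEG / 2:
                dp[c, j] = sc_sorted[j] + vals[k]
                parent[c, j] = compat[k]
    # maximize over non-empty chains (every individual repeat is a candidate
    # domain; the empty chain is only returned for an empty pool)
    reg = np.array([regulator(c, profile.regulator) for c in range(1, C + 1)])
    totals = dp[1:, :] + reg[:, None]
    best_flat = int(np.argmax(totals))
    best_c, best_j = best_flat // N + 1, best_flat % N
    chain = []
    c, j = best_c, best_j
    while j >= 0 and c >= 1:
        chain.append(int(order[j]))
        j = int(parent[c, j])
        c -= 1
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def ga_combine(
    pool: CandidatePool,
    profile: RepeatProfile,
    seed: int = 0,
    config: DetectionConfig | None = None,
) -> list[int]:
    """Assemble repeats into a domain chain with a genetic algorithm.

    Individuals are ordered non-overlapping candidate subsets; fitness is
    the regulated domain score.  Operators: mutation (swap one repeat for a
    compatible alternative), crossover (splice two parents at a random
    sequence coordinate) and elongation (append a compatible candidate at
    either end).  Converges when the best ``convergence_top`` individuals
    are identical.  Fully reproducible under a fixed seed.
    """
    cfg = config or DetectionConfig()
    N = pool.N
    if N == 0:
        return []
    rng = np.random.default_rng(seed)
    starts, ends, scores = pool.start, pool.end, pool.score
    lcd_tab = _lcd_lookup(profile, int(len(pool.sequence)))
    reg_tab = profile.regulator

    def fitness(ind: tuple[int, ...]) -> float:
        if not ind:
            return -1e18
        total = float(scores[list(ind)].sum())
        for i, j in zip(ind, ind[1:]):
            total += lcd_tab[int(starts[j] - ends[i])]
        total += regulator(len(ind), reg_tab)
        return total

    def fits_between(cand: int, left: int | None, right: int | None) -> bool:
        if left is not None and starts[cand] < ends[left]:
            return False
        if right is not None and ends[cand] > starts[right]:
            return False
        return True

    def pick(options: np.ndarray) -> int:
        # half greedy, half uniform: explores while converging quickly
        if rng.random() < 0.5:
            return int(options[int(np.argmax(scores[options]))])
        return int(options[rng.integers(options.size)])

    def mutate(ind: tuple[int, ...]) -> tuple[int, ...]:
        if not ind:
            return ind
        k = int(rng.integers(len(ind)))
        left = ind[k - 1] if k > 0 else None
        right = ind[k + 1] if k < len(ind) - 1 else None
        lo = ends[left] if left is not None else 0
        hi = starts[right] if right is not None else len(pool.sequence)
        options = np.nonzero((starts >= lo) & (ends <= hi))[0]
        if options.size == 0:
            return ind
        return tuple(ind[:k] + (pick(options),) + ind[k + 1 :])

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        x = int(rng.integers(len(pool.sequence) + 1))
        left = [i for i in a if ends[i] <= x]
        right = [i for i in b if starts[i] >= x]
        return tuple(left + right)

    L = len(pool.sequence)

    def _link(a: int | None, b: int | None) -> float:
        if a is None or b is None:
            return 0.0
        return float(lcd_tab[int(starts[b] - ends[a])])

    def local_improve(ind: tuple[int, ...]) -> tuple[int, ...]:
        """Best-improvement local search: insert / replace / delete one
        repeat while the regulated fitness improves."""
        if not ind:
            return ind
        improved = True
        while improved:
            improved = False
            k = len(ind)
            best_gain, best_new = 1e-12, None
            d_ins = regulator(k + 1, reg_tab) - regulator(k, reg_tab)
            # insertion into every gap (incl. both termini)
            for i in range(k + 1):
                a = ind[i - 1] if i > 0 else None
                b = ind[i] if i < k else None
                lo = ends[a] if a is not None else 0
                hi = starts[b] if b is not None else L
                opts = np.nonzero((starts >= lo) & (ends <= hi))[0]
                if opts.size == 0:
                    continue
                link_a = lcd_tab[(starts[opts] - lo).astype(int)] if a is not None else 0.0
                link_b = lcd_tab[(hi - ends[opts]).astype(int)] if b is not None else 0.0
                gains = scores[opts] + link_a + link_b - _link(a, b) + d_ins
                j = int(np.argmax(gains))
                if gains[j] > best_gain:
                    best_gain = float(gains[j])
                    best_new = ind[:i] + (int(opts[j]),) + ind[i:]
            # replacement of every repeat by the best fit in its gap
            for i in range(k):
                a = ind[i - 1] if i > 0 else None
                b = ind[i + 1] if i < k - 1 else None
                lo = ends[a] if a is not None else 0
                hi = starts[b] if b is not None else L
                opts = np.nonzero((starts >= lo) & (ends <= hi))[0]
                if opts.size == 0:
                    continue
                link_a = lcd_tab[(starts[opts] - lo).astype(int)] if a is not None else 0.0
                link_b = lcd_tab[(hi - ends[opts]).astype(int)] if b is not None else 0.0
                old = scores[ind[i]] + _link(a, ind[i]) + _link(ind[i], b)
                gains = scores[opts] + link_a + link_b - old
                j = int(np.argmax(gains))
                if gains[j] > best_gain and int(opts[j]) != ind[i]:
                    best_gain = float(gains[j])
                    best_new = ind[:i] + (int(opts[j]),) + ind[i + 1:]
            # deletion
            if k >= 2:
                d_del = regulator(k - 1, reg_tab) - regulator(k, reg_tab)
                for i in range(k):
                    a = ind[i - 1] if i > 0 else None
                    b = ind[i + 1] if i < k - 1 else None
                    gain = (-scores[ind[i]] - _link(a, ind[i]) - _link(ind[i], b)
                            + _link(a, b) + d_del)
                    if gain > best_gain:
                        best_gain, best_new = float(gain), ind[:i] + ind[i + 1:]
            if best_new is not None:
                ind = best_new
                improved = True
        return ind

    def elongate(ind: tuple[int, ...]) -> tuple[int, ...]:
        if not ind:
            return (int(rng.integers(N)),)
        if rng.random() < 0.5:
            return local_improve(ind)
        at_front = bool(rng.integers(2))
        for front in (at_front, not at_front):
            options = np.nonzero(
                ends <= starts[ind[0]] if front else starts >= ends[ind[-1]]
            )[0]
            if options.size:
                chosen = pick(options)
                return (chosen,) + ind if front else ind + (chosen,)
        return ind

    pop_size = cfg.population_size
    if N >= pop_size:
        chosen = rng.choice(N, size=pop_size, replace=False)
        population = [(int(i),) for i in chosen]
    else:
        population = [(int(i),) for i in range(N)] + [
            (int(rng.integers(N)),) for _ in range(pop_size - N)
        ]

    cache: dict[tuple[int, ...], float] = {}

    def fit_cached(ind: tuple[int, ...]) -> float:
        if ind not in cache:
            cache[ind] = fitness(ind)
        return cache[ind]

    best: tuple[int, ...] = ()
    best_fit = float("-inf")
    stall = 0
    for gen in range(cfg.max_generations):
        fits = np.array([fit_cached(ind) for ind in population])
        order = np.argsort(-fits, kind="stable")
        population = [population[i] for i in order]
        fits = fits[order]
        if fits[0] > best_fit + 1e-12:
            best, best_fit = population[0], float(fits[0])
            stall = 0
        else:
            stall += 1
        # converged: the best individuals are one and the same chain and no
        # improvement has surfaced for a while
        top = population[: cfg.convergence_top]
        if len(set(top)) == 1 and stall >= 10:
            logger.info("GA converged at generation %d", gen)
            break
        # elites: the best distinct chains survive unchanged
        elites: list[tuple[int, ...]] = []
        seen: set[tuple[int, ...]] = set()
        for ind in population:
            if ind not in seen:
                elites.append(ind)
                seen.add(ind)
            if len(elites) >= cfg.convergence_top:
                break
        children: list[tuple[int, ...]] = list(population[: cfg.convergence_top])
        children.extend(elites)
        # immigration: keep every candidate alive as a building block so
        # crossover can still splice unexplored repeats into chains
        n_immigrants = max(1, pop_size // 10)
        for _ in range(n_immigrants):
            children.append((int(rng.integers(N)),))
        while len(children) < pop_size:
            i, j = rng.integers(len(population), size=2)
            parent_a = population[min(i, j)]  # rank-based tournament
            child = parent_a
            acted = False
            if rng.random() < cfg.crossover_rate:
                k, l = rng.integers(len(population), size=2)
                child = crossover(child, population[min(k, l)])
                acted = True
            if rng.random() < cfg.mutation_rate:
                child = mutate(child)
                acted = True
            if rng.random() < cfg.elongation_rate or not acted:
                child = elongate(child)
            children.append(child)
        population = children
    best = local_improve(best)
    if fitness(best) < best_fit:  # local search never worsens; guard anyway
        raise AssertionError("local improvement decreased fitness")
    return list(best)


# ---------------------------------------------------------------------------
# Classification and secondary-structure output
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Final verdict with the supporting evidence."""

    sequence_id: str
    verdict: str  # "WD40" | "not-WD40"
    domains: list[DomainModel]
    n_domains: int
    asr: list[float]
    tetrad_found: bool
    ss_string: str
    early_exit: bool
    seed: int
    pool_size: int = 0
    pool_s_max: float = float("-inf")
    threshold_T: float = 0.0
    config: dict = field(default_factory=dict)
    profile_provenance: str = ""
    profile_checksum: str = ""


def slice_domains(chain: list[RepeatCandidate]) -> list[list[RepeatCandidate]]:
    """Greedy slicing of an assembled chain into domains of 7 repeats where
    possible; a trailing slice shorter than 6 is merged into its
    predecessor."""
    if not chain:
        return []
    slices = [chain[i : i + 7] for i in range(0, len(chain), 7)]
    if len(slices) > 1 and len(slices[-1]) < 6:
        tail = slices.pop()
        slices[-1] = slices[-1] + tail
    return slices


def count_domains(total_repeats: int) -> int:
    """Domain count from the total repeat number: one more domain each time
    the total exceeds 8, 16, 24 and 32 repeats."""
    return 1 + sum(total_repeats > k for k in (8, 16, 24, 32))


def classify(
    chain: list[RepeatCandidate],
    sequence: str,
    profile: RepeatProfile,
    config: DetectionConfig | None = None,
) -> tuple[str, list[DomainModel], list[float], bool, int]:
    """Verdict plus qualifying domains from an assembled repeat chain.

    A domain qualifies when it has at least ``min_repeats`` repeats and its
    ASr reaches the threshold or it contains at least one DHSW tetrad
    (checked with real inter-repeat context).
    """
    cfg = config or DetectionConfig()
    domains: list[DomainModel] = []
    asr_values: list[float] = []
    any_tetrad = False
    for part in slice_domains(chain):
        dom = domain_from_repeats(part)
        # re-score S_corr with true inter-repeat context
        for k, rep in enumerate(dom.repeats):
            prev_end = dom.repeats[k - 1].end if k > 0 else None
            corr = score_corr(rep, profile.tetrad, sequence, prev_end)
            rep.score_terms["S_corr"] = corr
            rep.S_repeat = sum(rep.score_terms.values())
        dom.S_domain = score_domain(dom, profile, use_regulator=False)
        asr = average_repeat_score(dom)
        tetrad_here = any(
            _motif_at_least_tetrad(rep, dom.repeats[k - 1].end if k > 0 else None,
                                   sequence, profile)
            for k, rep in enumerate(dom.repeats)
        )
        qualifies = dom.N_rep >= cfg.min_repeats and (
            asr >= cfg.asr_threshold or tetrad_here
        )
        if qualifies:
            domains.append(dom)
            asr_values.append(asr)
            any_tetrad = any_tetrad or tetrad_here
    verdict = "WD40" if domains else "not-WD40"
    total = sum(d.N_rep for d in domains)
    n_domains = count_domains(total) if domains else 0
    return verdict, domains, asr_values, any_tetrad, n_domains


def _motif_at_least_tetrad(rep: RepeatCandidate, prev_end: int | None,
                           sequence: str, profile: RepeatProfile) -> bool:
    from .scoring import corr_motif_level

    level = corr_motif_level(rep, profile.tetrad, sequence, prev_end)
    return prev_end is not None and level in ("tetrad", "pentad")


def emit_secondary_structure(
    domains: list[DomainModel], length: int
) -> tuple[str, list[tuple[str, int, int]]]:
    """Per-residue E/C labels plus strand segments (id, start, end).

    E marks the four six-residue strands of every reported repeat; strand
    ids carry the strand letter and the repeat index within its domain."""
    labels = ["C"] * length
    segments: list[tuple[str, int, int]] = []
    for dom in domains:
        for r_idx, rep in enumerate(dom.repeats, start=1):
            for strand, (s0, s1) in rep.strand_spans().items():
                for i in range(s0, min(s1, length)):
                    labels[i] = "E"
                segments.append((f"{strand[1]}{r_idx}", s0, s1))
    segments.sort(key=lambda seg: seg[1])
    return "".join(labels), segments


# ---------------------------------------------------------------------------
# Top-level pipeline
# ---------------------------------------------------------------------------

def detect(
    sequence: str,
    profile: RepeatProfile,
    ss: SSPrediction | None = None,
    sequence_id: str = "",
    seed: int = 0,
    config: DetectionConfig | None = None,
    exact_dp: bool = False,
) -> ClassificationReport:
    """Run the complete pipeline on one sequence."""
    cfg = config or DetectionConfig()

    def report(verdict="not-WD40", domains=(), asr=(), tetrad=False, early=False,
               pool=None, T=0.0) -> ClassificationReport:
        ss_string, _ = emit_secondary_structure(list(domains), len(sequence))
        return ClassificationReport(
            sequence_id=sequence_id, verdict=verdict, domains=list(domains),
            n_domains=count_domains(sum(d.N_rep for d in domains)) if domains else 0,
            asr=list(asr), tetrad_found=tetrad, ss_string=ss_string,
            early_exit=early, seed=seed,
            pool_size=pool.N if pool is not None else 0,
            pool_s_max=pool.S_max if pool is not None and pool.N else float("-inf"),
            threshold_T=T, config=cfg.as_dict(),
            profile_provenance=profile.provenance,
        )

    interval = trim_termini(sequence, ss, cfg.trim_window, cfg.trim_helix_fraction)
    pool = enumerate_candidates(
        sequence, profile, ss, sequence_id=sequence_id, interval=interval,
        min_score=cfg.min_repeat_score, loop_bounds=cfg.loop_bounds,
    )
    pool = overlap_filter(pool, cfg.dominate_score)
    if early_exit(pool, cfg.early_exit_score):
        return report(early=True, pool=pool)
    T = pool_threshold(pool)
    working = apply_threshold(pool, T)

    def assemble(p: CandidatePool) -> list[int]:
        if exact_dp:
            return dp_optimal(p, profile)
        return ga_combine(p, profile, seed=seed, config=cfg)

    chain_idx = assemble(working)
    if len(chain_idx) < 7 and T > cfg.restart_threshold:
        logger.info("optimized domain has %d repeats; restarting with T=%.0f",
                    len(chain_idx), cfg.restart_threshold)
        T = cfg.restart_threshold
        working = apply_threshold(pool, T)
        chain_idx = assemble(working)

    chain = [working.materialize(i) for i in chain_idx]
    verdict, domains, asr, tetrad, n_domains = classify(chain, sequence, profile, cfg)
    rep = report(verdict=verdict, domains=domains, asr=asr, tetrad=tetrad,
                 pool=pool, T=T)
    rep.n_domains = n_domains
    return rep
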