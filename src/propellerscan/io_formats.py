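"""Readers and writers shared across the pipeline.

Inputs: FASTA sequences, PSIPRED-style ``.ss2`` secondary-structure
predictions (vertical format or a simplified two-column state+confidence
dialect) and the versioned key-value profile file.  Outputs: the repeat
table (TSV), per-residue secondary structure (two-line FASTA-like and
horizontal annotated blocks) and the machine-readable classification
report (versioned JSON with an integrity checksum).

All writers are deterministic: stable field order, scores printed at four
decimal places in the human-readable tables; the report and profile files
store floats at full precision so that they round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .detection import ClassificationReport, DetectionConfig
from .profile_builder import (
    ALPHABET,
    FrequencyMatrix,
    LoopScoreTable,
    RegulatorTable,
    RepeatProfile,
    TetradModel,
    PENTAD_CLASSES,
)
from .repeat_model import DomainModel, PositionID, RepeatCandidate, SCORED_POSITIONS, parse_position
from .scoring import SSPrediction

logger = logging.getLogger(__name__)

PROFILE_MAGIC = "propellerscan-profile"
PROFILE_VERSION = 1
REPORT_VERSION = 1

VALID_RESIDUES = set(ALPHABET) | set("XBZU")


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            logger.warning("sequence %s carries non-standard letters %s", self.id, sorted(bad))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: str | Path | io.TextIOBase) -> list[SequenceRecord]:
    """Order-preserving multi-record FASTA reader (wrapped lines tolerated)."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise ValueError("no FASTA records found")
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning("sequence %s contains lower-case residues; upcasing", rec.id)
            seq = seq.upper()
        out.append(SequenceRecord(id=rec.id, description=rec.description, residues=seq))
    return out


# ---------------------------------------------------------------------------
# PSIPRED .ss2
# ---------------------------------------------------------------------------

def read_ss2(path: str | Path, sequence: str | None = None) -> SSPrediction:
    """Parse a PSIPRED vertical-format prediction.

    Accepts the standard six-column layout (index, residue, state, coil /
    helix / strand confidences; the ``# PSIPRED`` header is optional) and a
    simplified two-column ``state confidence`` dialect.  Confidence is the
    strongest class probability scaled to 0-9 (or read directly in the
    two-column dialect).  When ``sequence`` is given, residue letters and
    length are cross-checked.
    """
    states: list[str] = []
    conf: list[int] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            try:
                if len(parts) >= 6:
                    residues.append(parts[1])
                    state = parts[2]
                    probs = [float(p) for p in parts[3:6]]
                    c = int(round(9 * max(probs)))
                elif len(parts) == 2:
                    state = parts[0]
                    c = int(parts[1])
                else:
                    raise ValueError("unrecognized column layout")
                if state not in "HEC" or not 0 <= c <= 9:
                    raise ValueError(f"bad state/confidence {state!r}/{c}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            states.append(state)
            conf.append(c)
    pred = SSPrediction(states="".join(states), conf=conf)
    if sequence is not None:
        if len(pred) != len(sequence):
            raise ValueError(
                f"{path}: prediction covers {len(pred)} residues, sequence has {len(sequence)}"
            )
        if residues and any(a != b for a, b in zip(residues, sequence) if a != "X"):
            logger.warning("%s: residue letters disagree with the target sequence", path)
    return pred


# ---------------------------------------------------------------------------
# Profile file
# ---------------------------------------------------------------------------

def write_profile(profile: RepeatProfile, path: str | Path) -> None:
    Path(path).write_text(dumps_profile(profile))


def dumps_profile(profile: RepeatProfile) -> str:
    out = [f"{PROFILE_MAGIC} {PROFILE_VERSION}"]
    out.append(f"provenance\t{profile.provenance}")
    out.append(f"weight_mode\t{profile.weight_mode}")
    out.append(f"n_repeats\t{profile.frequencies.n_repeats}")
    out.append("[background]")
    for i, aa in enumerate(ALPHABET):
        out.append(f"{aa}\t{float(profile.background[i])!r}")
    out.append("[frequencies]")
    for k, pos in enumerate(SCORED_POSITIONS):
        row = "\t".join(repr(float(v)) for v in profile.frequencies.P[k])
        out.append(f"{pos}\t{row}")
    out.append("[weights]")
    for k, pos in enumerate(SCORED_POSITIONS):
        out.append(f"{pos}\t{float(profile.weights[k])!r}")
    for name in ("Lda", "Lab", "Lbc", "Lcd"):
        table = profile.loop_scores[name]
        out.append(f"[loop {name}]")
        out.append(f"t\t{float(table.t)!r}")
        out.append(f"t0\t{float(table.t0)!r}")
        out.append(f"l0\t{table.l0}")
        out.append(f"pseudo_count\t{float(table.pseudo_count)!r}")
        for l in sorted(table.scores):
            out.append(f"{l}\t{float(table.scores[l])!r}")
    out.append("[tetrad]")
    out.append(f"p_pentad\t{float(profile.tetrad.p_pentad)!r}")
    out.append(f"p_tetrad\t{float(profile.tetrad.p_tetrad)!r}")
    out.append(f"p_triad\t{float(profile.tetrad.p_triad)!r}")
    for slot, q in profile.tetrad.slot_marginals.items():
        out.append(f"q_{slot}\t{float(q)!r}")
    out.append("[regulator]")
    out.append(f"provenance\t{profile.regulator.provenance}")
    for n in sorted(profile.regulator.values):
        out.append(f"{n}\t{float(profile.regulator.values[n])!r}")
    return "\n".join(out) + "\n"


def read_profile(path: str | Path) -> RepeatProfile:
    return loads_profile(Path(path).read_text())


def loads_profile(text: str) -> RepeatProfile:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split()
    if header[0] != PROFILE_MAGIC or int(header[1]) != PROFILE_VERSION:
        raise ValueError(f"unsupported profile header: {lines[0]!r}")
    meta: dict[str, str] = {}
    section = None
    background = np.zeros(20)
    P = np.zeros((len(SCORED_POSITIONS), 20))
    weights = np.zeros(len(SCORED_POSITIONS))
    loop_raw: dict[str, dict] = {}
    tetrad_raw: dict[str, float] = {}
    reg_values: dict[int, float] = {}
    reg_prov = "initial-gaussian"
    pos_index = {str(p): i for i, p in enumerate(SCORED_POSITIONS)}
    aa_index = {aa: i for i, aa in enumerate(ALPHABET)}
    for ln in lines[1:]:
        if ln.startswith("["):
            section = ln.strip("[]")
            if section.startswith("loop "):
                loop_raw[section.split()[1]] = {"scores": {}}
            continue
        key, *vals = ln.split("\t")
        if section is None:
            meta[key] = vals[0] if vals else ""
        elif section == "background":
            background[aa_index[key]] = float(vals[0])
        elif section == "frequencies":
            P[pos_index[key]] = [float(v) for v in vals]
        elif section == "weights":
            weights[pos_index[key]] = float(vals[0])
        elif section.startswith("loop "):
            entry = loop_raw[section.split()[1]]
            if key in ("t", "t0", "pseudo_count"):
                entry[key] = float(vals[0])
            elif key == "l0":
                entry[key] = int(vals[0])
            else:
                entry["scores"][int(key)] = float(vals[0])
        elif section == "tetrad":
            tetrad_raw[key] = float(vals[0])
        elif section == "regulator":
            if key == "provenance":
                reg_prov = vals[0]
            else:
                reg_values[int(key)] = float(vals[0])
    counts = np.zeros_like(P)
    n_rep = int(meta.get("n_repeats", "0"))
    freq = FrequencyMatrix(P=P, counts=counts, n_repeats=n_rep)
    tables = {
        name: LoopScoreTable(
            name=name, scores=raw["scores"], t=raw["t"], t0=raw["t0"],
            l0=raw["l0"], pseudo_count=raw.get("pseudo_count", 0.01),
        )
        for name, raw in loop_raw.items()
    }
    tetrad = TetradModel(
        p_pentad=tetrad_raw["p_pentad"], p_tetrad=tetrad_raw["p_tetrad"],
        p_triad=tetrad_raw["p_triad"],
        slot_marginals={k[2:]: v for k, v in tetrad_raw.items() if k.startswith("q_")},
    )
    profile = RepeatProfile(
        frequencies=freq, weights=weights, background=background,
        loop_scores=tables, tetrad=tetrad,
        regulator=RegulatorTable(values=reg_values, provenance=reg_prov),
        provenance=meta.get("provenance", ""),
        weight_mode=meta.get("weight_mode", "content"),
    )
    profile.validate()
    return profile


def profile_checksum(profile: RepeatProfile) -> str:
    return hashlib.sha256(dumps_profile(profile).encode()).hexdigest()[:16]


def default_profile() -> RepeatProfile:
    """Load the packaged default profile."""
    from importlib.resources import files

    text = files("propellerscan").joinpath("data/default_profile.txt").read_text()
    return loads_profile(text)


# ---------------------------------------------------------------------------
# Classification report (versioned JSON, integrity-checked)
# ---------------------------------------------------------------------------

def _candidate_to_json(c: RepeatCandidate) -> dict:
    return {
        "sequence_id": c.sequence_id,
        "start": c.start,
        "loop_lengths": c.loop_lengths,
        "residues_by_position": {str(p): r for p, r in c.residues_by_position.items()},
        "score_terms": c.score_terms,
        "S_repeat": c.S_repeat,
    }


def _candidate_from_json(d: dict) -> RepeatCandidate:
    return RepeatCandidate(
        sequence_id=d["sequence_id"], start=d["start"],
        loop_lengths={k: int(v) for k, v in d["loop_lengths"].items()},
        residues_by_position={parse_position(p): r for p, r in d["residues_by_position"].items()},
        score_terms=d["score_terms"], S_repeat=d["S_repeat"],
    )


def report_to_json(report: ClassificationReport) -> dict:
    payload = {
        "version": REPORT_VERSION,
        "sequence_id": report.sequence_id,
        "verdict": report.verdict,
        "n_domains": report.n_domains,
        "asr": report.asr,
        "tetrad_found": report.tetrad_found,
        "ss_string": report.ss_string,
        "early_exit": report.early_exit,
        "seed": report.seed,
        "pool_size": report.pool_size,
        "pool_s_max": report.pool_s_max,
        "threshold_T": report.threshold_T,
        "config": report.config,
        "profile_provenance": report.profile_provenance,
        "profile_checksum": report.profile_checksum,
        "domains": [
            {
                "repeats": [_candidate_to_json(r) for r in dom.repeats],
                "lcd_lengths": dom.lcd_lengths,
                "S_domain": dom.S_domain,
            }
            for dom in report.domains
        ],
    }
    payload["integrity"] = _payload_digest(payload)
    return payload


def _payload_digest(payload: dict) -> str:
    body = {k: v for k, v in payload.items() if k != "integrity"}
    return hashlib.sha256(json.dumps(body, sort_keys=True).encode()).hexdigest()[:16]


def write_report(report: ClassificationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_json(report), indent=1, sort_keys=True) + "\n")


def read_report(path: str | Path) -> ClassificationReport:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != REPORT_VERSION:
        raise ValueError(f"unsupported report version: {payload.get('version')!r}")
    if payload.get("integrity") != _payload_digest(payload):
        raise ValueError(f"{path}: report integrity checksum mismatch")
    domains = [
        DomainModel(
            repeats=[_candidate_from_json(r) for r in d["repeats"]],
            lcd_lengths=[int(v) for v in d["lcd_lengths"]],
            S_domain=d["S_domain"],
        )
        for d in payload["domains"]
    ]
    return ClassificationReport(
        sequence_id=payload["sequence_id"], verdict=payload["verdict"],
        domains=domains, n_domains=payload["n_domains"], asr=payload["asr"],
        tetrad_found=payload["tetrad_found"], ss_string=payload["ss_string"],
        early_exit=payload["early_exit"], seed=payload["seed"],
        pool_size=payload["pool_size"], pool_s_max=payload["pool_s_max"],
        threshold_T=payload["threshold_T"], config=payload["config"],
        profile_provenance=payload["profile_provenance"],
        profile_checksum=payload["profile_checksum"],
    )


# ---------------------------------------------------------------------------
# Human-readable outputs
# ---------------------------------------------------------------------------

def format_repeat_table(report: ClassificationReport) -> str:
    """Tab-separated repeat table; coordinates 1-based inclusive."""
    cols = [
        "sequence_id", "domain", "repeat", "start", "end",
        "Sd", "Sa", "Sb", "Sc",
        "S_aa", "S_loop_len", "S_corr", "S_psipred", "S_repeat",
    ]
    rows = ["\t".join(cols)]
    for d_idx, dom in enumerate(report.domains, start=1):
        for r_idx, rep in enumerate(dom.repeats, start=1):
            spans = rep.strand_spans()
            strand_cols = [
                f"{spans[s][0] + 1}-{spans[s][1]}" for s in ("Sd", "Sa", "Sb", "Sc")
            ]
            rows.append("\t".join(
                [report.sequence_id, str(d_idx), str(r_idx),
                 str(rep.start + 1), str(rep.end)]
                + strand_cols
                + [f"{rep.score_terms[k]:.4f}" for k in
                   ("S_aa", "S_loop_len", "S_corr", "S_psipred")]
                + [f"{rep.S_repeat:.4f}"]
            ))
    return "\n".join(rows) + "\n"


def format_ss_fasta(report: ClassificationReport) -> str:
    """Two-line FASTA-like per-residue secondary structure."""
    return f">{report.sequence_id} secondary_structure\n{report.ss_string}\n"


def format_ss_blocks(report: ClassificationReport, sequence: str, width: int = 60) -> str:
    """Horizontal annotated blocks: sequence over predicted labels."""
    out = []
    for i in range(0, len(sequence), width):
        out.append(f"{i + 1:>6} {sequence[i:i + width]}")
        out.append(f"{'':>6} {report.ss_string[i:i + width]}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None, **overrides) -> DetectionConfig:
    """Detection configuration from an optional YAML key-value file, with
    keyword overrides (CLI flags) winning."""
    import yaml

    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "loop_bounds" in data:
        data["loop_bounds"] = {k: tuple(v) for k, v in data["loop_bounds"].items()}
    valid = set(DetectionConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DetectionConfig(**data)


# ---------------------------------------------------------------------------
# Annotated repeats and synthetic truth tables
# ---------------------------------------------------------------------------

def read_annotated_repeats(path: str | Path) -> list:
    """Annotated-repeat training table: tab-separated, one repeat per row:
    source_id, sequence, Sd_start, Sa_start, Sb_start, Sc_start
    (coordinates 1-based inclusive in the file)."""
    from .profile_builder import AnnotatedRepeat

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            source_id, seq = parts[0], parts[1].upper()
            starts = {s: int(v) - 1 for s, v in zip(("Sd", "Sa", "Sb", "Sc"), parts[2:])}
            rep = AnnotatedRepeat(sequence=seq, strand_starts=starts, source_id=source_id)
            rep.validate()
            out.append(rep)
    if not out:
        raise ValueError(f"{path}: no annotated repeats")
    return out


def write_annotated_repeats(repeats: list, path: str | Path) -> None:
    lines = []
    for rep in repeats:
        starts = [str(rep.strand_starts[s] + 1) for s in ("Sd", "Sa", "Sb", "Sc")]
        lines.append("\t".join([rep.source_id, rep.sequence] + starts))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(truths: list, path: str | Path) -> None:
    """Ground-truth table for synthetic sequences: one row per planted
    repeat (is_wd40 negatives emit a single row with empty coordinates)."""
    lines = ["\t".join(["sequence_id", "is_wd40", "Sd_start", "Sa_start", "Sb_start", "Sc_start"])]
    for truth in truths:
        if not truth.planted_repeats:
            lines.append("\t".join([truth.sequence_id, "0", "", "", "", ""]))
        for rep in truth.planted_repeats:
            coords = [str(rep.strand_starts[s] + 1) for s in ("Sd", "Sa", "Sb", "Sc")]
            lines.append("\t".join([truth.sequence_id, "1"] + coords))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path: str | Path) -> dict:
    """Inverse of :func:`write_truth_table`: sequence_id -> SyntheticTruth
    skeletons carrying the planted strand coordinates."""
    from .synthetic_eval import PlantedRepeat, SyntheticTruth

    by_id: dict[str, SyntheticTruth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence_id"):
            raise ValueError(f"{path}: missing header row")
        for line in fh:
            if not line.strip():
                continue
            sid, is_wd40, *coords = line.rstrip("\n").split("\t")
            truth = by_id.setdefault(
                sid, SyntheticTruth(sequence_id=sid, sequence="", planted_repeats=[],
                                    is_wd40=is_wd40 == "1", seed=0)
            )
            if is_wd40 == "1" and all(coords):
                starts = {s: int(v) - 1 for s, v in zip(("Sd", "Sa", "Sb", "Sc"), coords)}
                loops = {
                    "Lda": starts["Sa"] - starts["Sd"] - 6,
                    "Lab": starts["Sb"] - starts["Sa"] - 6,
                    "Lbc": starts["Sc"] - starts["Sb"] - 6,
                }
                truth.planted_repeats.append(
                    PlantedRepeat(start=starts["Sd"], loop_lengths=loops,
                                  strand_starts=starts)
                )
    return by_id
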