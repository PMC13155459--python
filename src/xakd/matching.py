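"""Stage-wise teacher-student layer matching.

Per stage: compute the pairwise CKA matrix between the teacher and student
layers of that stage, retain the top-k pairs, refine with KCCA and keep the
single pair maximizing rho_bar. Ties break by higher CKA, then by (teacher
index, student index). Stages are paired positionally (teacher early with
student early, etc.); the matching is computed once on a fixed probing batch
and then frozen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MatchingError, XakdError
from .kcca import KccaConfig, kcca_rho_bar
from .probes import STAGE_NAMES, StagePartition
from .similarity import CkaMatrix, stage_cka_matrix

__all__ = [
    "CandidateSet",
    "BridgePair",
    "MatchResult",
    "select_candidates",
    "refine_with_kcca",
    "match_layers",
    "save_bridge_map",
    "load_bridge_map",
]

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    stage: str
    candidates: list  # [(teacher_layer, student_layer, cka_score)], descending

    def __post_init__(self):
        scores = [c[2] for c in self.candidates]
        if scores != sorted(scores, reverse=True):
            raise MatchingError("candidates must be sorted by CKA descending")
        pairs = [(c[0], c[1]) for c in self.candidates]
        if len(set(pairs)) != len(pairs):
            raise MatchingError("duplicate candidate pairs")

    def __len__(self):
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


@dataclass
class BridgePair:
    stage: str
    teacher_layer: int
    student_layer: int
    cka_score: float
    kcca_rho_bar: float

    def to_dict(self) -> dict:
        return {
            "teacher_layer": int(self.teacher_layer),
            "student_layer": int(self.student_layer),
            "cka": float(self.cka_score),
            "rho_bar": float(self.kcca_rho_bar),
        }


@dataclass
class MatchResult:
    """Three bridge pairs plus the full audit trail."""

    bridges: list  # [BridgePair] for (early, mid, late)
    cka_matrices: list = field(default_factory=list)
    candidate_sets: list = field(default_factory=list)
    kcca_scores: list = field(default_factory=list)  # per stage: {(t,s): rho_bar}


def select_candidates(cka: CkaMatrix, k: int = 3) -> CandidateSet:
    """The k highest-CKA (teacher, student) cells of one stage's matrix; ties
    break by smaller teacher index, then smaller student index."""
    if k < 1:
        raise MatchingError("k must be >= 1")
    vals = np.asarray(cka.values)
    if vals.size == 0 or np.all(np.isnan(vals)):
        raise MatchingError(f"no usable CKA scores in stage {cka.stage!r}")
    cells = [
        (float(vals[a, b]), cka.teacher_layers[a], cka.student_layers[b])
        for a in range(vals.shape[0])
        for b in range(vals.shape[1])
        if np.isfinite(vals[a, b])
    ]
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    top = [(t, s, score) for score, t, s in cells[:k]]
    return CandidateSet(stage=cka.stage, candidates=top)


def refine_with_kcca(candidates: CandidateSet, teacher_reps, student_reps,
                     cfg: KccaConfig = KccaConfig(), scores_out: dict | None = None) -> BridgePair:
    """Among CKA candidates, pick the pair maximizing rho_bar (mean of the
    top-m canonical correlations). KCCA failures on individual candidates are
    skipped with a warning; failure on all is a matching error."""
    if len(candidates) == 0:
        raise MatchingError(f"empty candidate set for stage {candidates.stage!r}")
    best = None
    for t, s, cka_score in candidates:
        try:
            result = kcca_rho_bar(teacher_reps[t], student_reps[s], cfg)
        except XakdError as exc:
            logger.warning("KCCA failed for pair (teacher %d, student %d): %s", t, s, exc)
            continue
        rho = result.rho_bar
        if scores_out is not None:
            scores_out[(t, s)] = rho
        key = (rho, cka_score, -t, -s)
        if best is None or key > best[0]:
            best = (key, BridgePair(candidates.stage, t, s, cka_score, rho))
    if best is None:
        raise MatchingError(f"KCCA failed on every candidate in stage {candidates.stage!r}")
    return best[1]


def match_layers(teacher_reps, student_reps, t_part: StagePartition,
                 s_part: StagePartition, k: int = 3,
                 cfg: KccaConfig = KccaConfig()) -> MatchResult:
    """One bridge pair per (early, mid, late) stage; deterministic given the
    representations. The CKA matrices, candidate sets and per-candidate KCCA
    scores are retained for audit."""
    if len(t_part.stages) != len(s_part.stages):
        raise MatchingError("teacher and student must have the same number of stages")
    result = MatchResult(bridges=[])
    for name, t_stage, s_stage in zip(STAGE_NAMES, t_part, s_part):
        try:
            cka = stage_cka_matrix(teacher_reps, student_reps, t_stage, s_stage, stage=name)
            cands = select_candidates(cka, k=k)
            scores: dict = {}
            bridge = refine_with_kcca(cands, teacher_reps, student_reps, cfg, scores_out=scores)
        except XakdError as exc:
            raise MatchingError(f"stage {name!r}: {exc}") from exc
        result.cka_matrices.append(cka)
        result.candidate_sets.append(cands)
        result.kcca_scores.append(scores)
        result.bridges.append(bridge)
    return result


def save_bridge_map(bridges, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {b.stage: b.to_dict() for b in bridges}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_bridge_map(path) -> list:
    data = json.loads(Path(path).read_text())
    return [
        BridgePair(stage, d["teacher_layer"], d["student_layer"], d["cka"], d["rho_bar"])
        for stage, d in ((s, data[s]) for s in STAGE_NAMES if s in data)
    ]
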