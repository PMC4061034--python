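"""Predictor-consensus candidate prioritization.

Each surviving candidate gets a consensus score from its functional
predictor calls (SIFT, MutationTaster, PolyPhen-2, PMut): the fraction of
available (non-missing) predictors voting damaging, plus a configurable
bonus when the GERP score marks the position as evolutionarily constrained.
Candidates are then totally ordered: absent from the healthy control panel
first, then score, then GERP, then gene symbol — a transparent, fully
reproducible replacement for opaque web-service gene ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import PredictorProfile

#: default GERP threshold above which a site counts as conserved; an
#: artifact choice (documented), not a published cutoff
DEFAULT_GERP_CONSERVED = 4.0
DEFAULT_CONSERVATION_BONUS = 0.25


@dataclass(frozen=True)
class ScoreRecord:
    key: str
    gene: str
    damaging_votes: int
    votes_available: int
    conserved: bool
    gerp: Optional[float]
    score: Optional[float]          # None when every predictor is missing
    undefined: bool = False


def consensus_score(key: str, gene: str, profile: PredictorProfile,
                    gerp_conserved_threshold: float = DEFAULT_GERP_CONSERVED,
                    conservation_bonus: float = DEFAULT_CONSERVATION_BONUS,
                    ) -> ScoreRecord:
    """Deterministic consensus score for one candidate.

    score = damaging_votes / votes_available + bonus * conserved;
    with every predictor missing the score is undefined and the candidate
    is flagged to rank last.
    """
    damaging, available = profile.votes()
    conserved = (profile.gerp is not None
                 and profile.gerp >= gerp_conserved_threshold)
    if available == 0:
        return ScoreRecord(key, gene, 0, 0, conserved, profile.gerp,
                           score=None, undefined=True)
    score = damaging / available + (conservation_bonus if conserved else 0.0)
    return ScoreRecord(key, gene, damaging, available, conserved,
                       profile.gerp, score=score)


def rank_candidates(scored: Sequence[ScoreRecord],
                    panel_occurrence: Mapping[str, int],
                    reference_occurrence: Mapping[str, int] | None = None,
                    ) -> list[ScoreRecord]:
    """Total order over candidates; stable, deterministic, input-order free.

    Sort key: candidates with defined scores before undefined ones; within
    those, absent from the healthy control panel first, then score
    descending, then GERP descending, then gene symbol lexicographic.
    ``panel_occurrence`` maps variant key (or gene) -> carrier count in the
    control panel; ``reference_occurrence`` (EVS / in-house counts) is
    carried for reporting and does not enter the order.
    """
    occ = dict(panel_occurrence)
    for count in occ.values():
        if count < 0:
            raise ValueError("occurrence counts must be >= 0")

    def lookup(rec: ScoreRecord) -> int:
        if rec.key in occ:
            return occ[rec.key]
        return occ.get(rec.gene, 0)

    def sort_key(rec: ScoreRecord):
        return (
            rec.undefined,
            lookup(rec) > 0,
            -(rec.score if rec.score is not None else float("-inf")),
            -(rec.gerp if rec.gerp is not None else float("-inf")),
            rec.gene,
            rec.key,
        )

    return sorted(scored, key=sort_key)
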