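"""Iterative beam-search knockout screening driven by the shadow-price score.

Starting from all knockout sets of size ``start_depth``, each generation
extends every parent set by every knockable unit not already in it,
keeps only children whose score strictly increased over their parent,
moves children whose score reached zero or became positive out of the
beam into the candidate store, and retains the ``parents_p`` highest
scoring children as the next generation's parents.  With the default
beam width P = N (N knockable units) the search visits at most P x N
sets per generation; iteration stops at ``max_knockouts`` simultaneous
deletions (default 25).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import cobra

from .environment import EnvironmentConfig
from .fba import ScoreRecord, shadow_price_score
from .reduction import KnockoutUnit

logger = logging.getLogger(__name__)


@dataclass
class ScreeningConfig:
    """Beam-search parameters.

    ``parents_p`` of ``None`` means P = N, the number of knockable
    units.  ``start_depth`` of 1 seeds the beam with single knockouts
    (cheaper, and finds size-1 candidates directly); 2 seeds with all
    pairs.  A child must improve its parent's score by more than
    ``improvement_epsilon`` to survive.
    """

    parents_p: int | None = None
    max_knockouts: int = 25
    start_depth: int = 1
    improvement_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.parents_p is not None and self.parents_p < 1:
            raise ValueError("parents_p must be >= 1")
        if self.start_depth not in (1, 2):
            raise ValueError("start_depth must be 1 or 2")
        if self.max_knockouts < self.start_depth:
            raise ValueError("max_knockouts must be >= start_depth")


@dataclass(frozen=True)
class GenerationEntry:
    """One surviving knockout set in the beam, with its lineage."""

    unit_ids: tuple[str, ...]
    score: float
    parent: tuple[str, ...] | None


@dataclass
class ScreeningResult:
    """Outcome of one target's screening run."""

    target: str
    candidates: list[ScoreRecord] = field(default_factory=list)
    candidate_units: list[frozenset[str]] = field(default_factory=list)
    generations: list[list[GenerationEntry]] = field(default_factory=list)
    evaluations: int = 0

    @property
    def min_knockouts(self) -> int | None:
        if not self.candidate_units:
            return None
        return min(len(u) for u in self.candidate_units)


def _sort_key(item: tuple[frozenset[str], float]):
    unit_set, score = item
    return (-score, tuple(sorted(unit_set)))


def screen(
    model: cobra.Model,
    env: EnvironmentConfig,
    target: str,
    units: Iterable[KnockoutUnit],
    cfg: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Run the beam search for one target metabolite.

    ``units`` may include non-knockable units; only knockable ones are
    offered as deletions.  Deterministic: ties in the top-P selection
    are broken by the lexicographic order of sorted unit ids.
    """
    cfg = cfg or ScreeningConfig()
    by_id: dict[str, KnockoutUnit] = {u.unit_id: u for u in units if u.knockable}
    if not by_id:
        raise ValueError("no knockable units to screen")
    unit_ids = sorted(by_id)
    n = len(unit_ids)
    p = cfg.parents_p if cfg.parents_p is not None else n

    result = ScreeningResult(target=target)
    cache: dict[frozenset[str], ScoreRecord] = {}

    def score_of(unit_set: frozenset[str]) -> ScoreRecord:
        rec = cache.get(unit_set)
        if rec is None:
            reactions = frozenset(
                rid for uid in unit_set for rid in by_id[uid].member_reactions
            )
            rec = shadow_price_score(model, env, target, reactions)
            rec = ScoreRecord(
                knockouts=unit_set,
                f_target=rec.f_target,
                classification=rec.classification,
                growth=rec.growth,
            )
            cache[unit_set] = rec
            result.evaluations += 1
        return rec

    seen_candidates: set[frozenset[str]] = set()

    def promote(rec: ScoreRecord) -> None:
        if rec.knockouts not in seen_candidates:
            seen_candidates.add(rec.knockouts)
            result.candidates.append(rec)
            result.candidate_units.append(rec.knockouts)

    # seed generation: all sets of size start_depth
    pool: list[tuple[frozenset[str], float, tuple[str, ...] | None]] = []
    for combo in combinations(unit_ids, cfg.start_depth):
        unit_set = frozenset(combo)
        rec = score_of(unit_set)
        if rec.classification == "infeasible":
            continue
        if rec.is_candidate:
            promote(rec)
        else:
            pool.append((unit_set, rec.f_target, None))

    parents = sorted(((s, f) for s, f, _ in pool), key=_sort_key)[:p]
    result.generations.append(
        [GenerationEntry(tuple(sorted(s)), f, None) for s, f in parents]
    )
    parent_scores = dict(parents)

    while parents and len(next(iter(parent_scores))) < cfg.max_knockouts:
        # child -> lowest score among the parents that generated it; a child
        # survives if it strictly improves on at least one such parent
        child_parent: dict[frozenset[str], tuple[float, tuple[str, ...]]] = {}
        for parent_set, parent_score in parents:
            for uid in unit_ids:
                if uid in parent_set:
                    continue
                child = parent_set | {uid}
                best = child_parent.get(child)
                if best is None or parent_score < best[0]:
                    child_parent[child] = (parent_score, tuple(sorted(parent_set)))
        survivors: list[tuple[frozenset[str], float, tuple[str, ...]]] = []
        for child in sorted(child_parent, key=lambda s: tuple(sorted(s))):
            parent_score, parent_key = child_parent[child]
            rec = score_of(child)
            if rec.classification == "infeasible":
                continue
            if not rec.f_target > parent_score + cfg.improvement_epsilon:
                continue
            if rec.is_candidate:
                promote(rec)
            else:
                survivors.append((child, rec.f_target, parent_key))
        selected = sorted(survivors, key=lambda t: _sort_key((t[0], t[1])))[:p]
        parents = [(s, f) for s, f, _ in selected]
        parent_scores = dict(parents)
        result.generations.append(
            [GenerationEntry(tuple(sorted(s)), f, pk) for s, f, pk in selected]
        )
        if not parents:
            break

    logger.info(
        "screen(%s): %d candidates, min knockouts %s, %d LP evaluations",
        target,
        len(result.candidates),
        result.min_knockouts,
        result.evaluations,
    )
    return result


def min_knockout_histogram(
    results: Mapping[str, ScreeningResult],
) -> tuple[dict[int, int], list[str]]:
    """Distribution of the minimum knockout count over targets.

    Returns ``(histogram, not_producible)`` where the histogram maps
    minimum set size to the number of targets attaining it, and
    ``not_producible`` lists targets for which screening stored no
    candidate.
    """
    if not results:
        raise ValueError("no screening results given")
    hist: Counter[int] = Counter()
    missing: list[str] = []
    for target, res in sorted(results.items()):
        if res.min_knockouts is None:
            missing.append(target)
        else:
            hist[res.min_knockouts] += 1
    return dict(sorted(hist.items())), missing
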