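"""Consensus connections across cross-validation folds.

A consensus connection is an edge selected in *every* LOOCV fold.  Each
consensus edge carries the mean of its discriminative powers (|tau|) over
folds, a normalized strength derived from its mean rank order (min-max
mapped so the best rank renders as 1 and the worst as a small positive
floor), and a direction of change (majority sign of tau across folds;
'tied' on an exact balance).  Region weights count the consensus edges
incident to each region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import ClassificationReport
from .ranking import Direction, RankedEdges

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusEdge",
    "ConsensusNetwork",
    "consensus_edges",
    "region_weights",
    "edge_summaries",
    "consensus_from_report",
]

#: floor of the min-max normalized strength: all rendered strengths positive
STRENGTH_FLOOR = 0.05


@dataclass(frozen=True)
class ConsensusEdge:
    edge: int                      # canonical edge index
    mean_power: float              # mean |tau| over folds
    mean_rank: float               # mean 1-based rank order over folds
    normalized_strength: float     # min-max over consensus edges, best -> 1
    direction: Direction


@dataclass(frozen=True)
class ConsensusNetwork:
    edges: tuple[ConsensusEdge, ...]
    region_weights: dict[int, int]

    @property
    def edge_ids(self) -> list[int]:
        return [e.edge for e in self.edges]


def consensus_edges(fold_selections) -> set[int]:
    """Exact intersection of the per-fold selected edge sets."""
    fold_selections = [set(int(e) for e in sel) for sel in fold_selections]
    if len(fold_selections) < 2:
        raise ValueError("need at least 2 folds")
    if any(len(s) == 0 for s in fold_selections):
        raise ValueError("every fold must select a non-empty edge set")
    return set.intersection(*fold_selections)


def region_weights(edges, edge_index) -> dict[int, int]:
    """Degree of each region in a consensus edge set.

    ``edges`` may be canonical edge indices (ints resolved through
    ``edge_index``) or explicit (i, j) pairs; all regions get an entry,
    absent ones with weight 0.
    """
    pairs = edge_index.pairs()
    weights = {r: 0 for r in range(edge_index.n_regions)}
    for e in edges:
        i, j = pairs[int(e)] if np.isscalar(e) or isinstance(e, (int, np.integer)) else e
        weights[int(i)] += 1
        weights[int(j)] += 1
    return weights


def edge_summaries(edges, fold_rankings: list[RankedEdges]) -> tuple[ConsensusEdge, ...]:
    """Mean power, normalized strength, and direction per consensus edge.

    The normalized strength maps the best (smallest) mean rank to 1 and the
    worst to ``STRENGTH_FLOOR``; with a single consensus edge the strength
    is 1.  It is a display quantity only.
    """
    edges = sorted(int(e) for e in edges)
    if not edges:
        return ()
    taus = np.array([[r.tau[e] for e in edges] for r in fold_rankings])
    ranks = np.array([[r.rank[e] for e in edges] for r in fold_rankings], float)
    mean_power = np.abs(taus).mean(axis=0)
    mean_rank = ranks.mean(axis=0)
    lo, hi = mean_rank.min(), mean_rank.max()
    if hi > lo:
        strength = 1.0 - (1.0 - STRENGTH_FLOOR) * (mean_rank - lo) / (hi - lo)
    else:
        strength = np.ones_like(mean_rank)
    out = []
    for col, e in enumerate(edges):
        signs = np.sign(taus[:, col])
        pos, neg = int((signs > 0).sum()), int((signs < 0).sum())
        if pos and neg:
            logger.warning(
                "edge %d flips tau sign across folds (%d positive, %d "
                "negative)", e, pos, neg,
            )
        if pos > neg:
            direction = Direction.DECREASED_IN_PATIENTS
        elif neg > pos:
            direction = Direction.INCREASED_IN_PATIENTS
        else:
            direction = Direction.TIED
        out.append(ConsensusEdge(
            edge=e,
            mean_power=float(mean_power[col]),
            mean_rank=float(mean_rank[col]),
            normalized_strength=float(strength[col]),
            direction=direction,
        ))
    return tuple(out)


def consensus_from_report(report: ClassificationReport, edge_index) -> ConsensusNetwork:
    """Build the full consensus network from a LOOCV classification report."""
    common = consensus_edges(report.fold_selections)
    summaries = edge_summaries(common, report.fold_rankings)
    weights = region_weights(common, edge_index)
    return ConsensusNetwork(edges=summaries, region_weights=weights)
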