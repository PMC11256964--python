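"""Segmentation evaluation metrics.

Predicted and reference assignments are compared by matching their domains
one-to-one (optimal bipartite matching maximizing total residue
intersection) and averaging intersection-over-union over the reference
domains; a reference domain left unmatched scores 0.  A domain counts as
correctly parsed when its matched IoU reaches 0.8.  Boundary placement is
scored separately with a tolerance sweep: at each tolerance t = 1..max_tol
the harmonic mean of boundary precision and recall (a boundary matches if
some counterpart lies within t positions) is computed, and the scores are
averaged over t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .labels import DomainAssignment

__all__ = [
    "EvalResult",
    "iou_score",
    "domain_correct_fraction",
    "boundary_distance_score",
    "evaluate_pair",
]

IOU_CORRECT_THRESHOLD = 0.8


@dataclass(frozen=True)
class EvalResult:
    """Per-chain evaluation summary."""

    iou: float
    per_domain_iou: tuple[tuple[int, int | None, float], ...]
    domain_correct_fraction: float
    boundary_score: float
    fault_flags: frozenset[str]


def _match_domains(
    pred: DomainAssignment, truth: DomainAssignment
) -> list[tuple[int, int | None, float]]:
    """Optimal one-to-one domain matching maximizing total intersection.

    Returns one entry per reference domain: (truth id, matched pred id or
    None, IoU of the matched residue sets).
    """
    if pred.length != truth.length:
        raise ValueError("assignments must have equal length")
    kp, kt = pred.n_domains, truth.n_domains
    if kt == 0:
        return []
    inter = np.zeros((kt, max(kp, 1)), dtype=np.int64)
    for t in range(1, kt + 1):
        t_mask = truth.labels == t
        for p in range(1, kp + 1):
            inter[t - 1, p - 1] = int((t_mask & (pred.labels == p)).sum())
    rows, cols = linear_sum_assignment(inter, maximize=True)
    matched = {int(r): int(c) for r, c in zip(rows, cols)}
    out: list[tuple[int, int | None, float]] = []
    for t in range(kt):
        p = matched.get(t)
        if p is None or inter[t, p] == 0:
            out.append((t + 1, None, 0.0))
            continue
        t_set = truth.labels == (t + 1)
        p_set = pred.labels == (p + 1)
        iou = float((t_set & p_set).sum() / (t_set | p_set).sum())
        out.append((t + 1, p + 1, iou))
    return out


def iou_score(
    pred: DomainAssignment, truth: DomainAssignment
) -> tuple[float, list[tuple[int, int | None, float]]]:
    """Mean matched IoU over reference domains, plus per-domain detail."""
    detail = _match_domains(pred, truth)
    if not detail:
        return (1.0 if pred.n_domains == 0 else 0.0), detail
    return float(np.mean([iou for _, _, iou in detail])), detail


def domain_correct_fraction(
    pairs: list[tuple[DomainAssignment, DomainAssignment]],
    threshold: float = IOU_CORRECT_THRESHOLD,
) -> float:
    """Fraction of reference domains across all chains with IoU >= threshold."""
    if not pairs:
        raise ValueError("need at least one (pred, truth) pair")
    ious: list[float] = []
    for pred, truth in pairs:
        ious.extend(iou for _, _, iou in _match_domains(pred, truth))
    if not ious:
        raise ValueError("reference assignments contain no domains")
    return float(np.mean([iou >= threshold for iou in ious]))


def _boundaries(assignment: DomainAssignment) -> np.ndarray:
    """Positions i (1..L−1) where the label changes, incl. null transitions."""
    lab = assignment.labels
    return np.flatnonzero(lab[1:] != lab[:-1]) + 1


def boundary_distance_score(
    pred: DomainAssignment, truth: DomainAssignment, max_tol: int = 8
) -> float:
    """Tolerance-swept harmonic-mean agreement of boundary positions."""
    if pred.length != truth.length:
        raise ValueError("assignments must have equal length")
    bp = _boundaries(pred)
    bt = _boundaries(truth)
    if bp.size == 0 and bt.size == 0:
        return 1.0
    if bp.size == 0 or bt.size == 0:
        return 0.0
    dist = np.abs(bp[:, None] - bt[None, :])
    scores = []
    for tol in range(1, max_tol + 1):
        precision = float((dist.min(axis=1) <= tol).mean())
        recall = float((dist.min(axis=0) <= tol).mean())
        if precision + recall == 0:
            scores.append(0.0)
        else:
            scores.append(2 * precision * recall / (precision + recall))
    return float(np.mean(scores))


def _fault_flags(
    pred: DomainAssignment,
    truth: DomainAssignment,
    detail: list[tuple[int, int | None, float]],
    boundary: float,
) -> frozenset[str]:
    flags = set()
    matched_pred = {p for _, p, _ in detail if p is not None}
    if pred.n_domains > truth.n_domains:
        flags.add("over_split")
    if 0 < pred.n_domains < truth.n_domains:
        flags.add("under_split")
    if any(p is None for _, p, _ in detail):
        flags.add("missing_domain")
    if pred.n_domains > len(matched_pred):
        flags.add("false_domain")
    if boundary < 1.0 and any(
        p is not None and iou < 1.0 for _, p, iou in detail
    ):
        flags.add("boundary_error")
    return frozenset(flags)


def evaluate_pair(
    pred: DomainAssignment, truth: DomainAssignment, max_tol: int = 8
) -> EvalResult:
    """Full per-chain evaluation bundle."""
    iou, detail = iou_score(pred, truth)
    boundary = boundary_distance_score(pred, truth, max_tol=max_tol)
    if detail:
        correct = float(np.mean([i >= IOU_CORRECT_THRESHOLD for _, _, i in detail]))
    else:
        correct = 1.0 if pred.n_domains == 0 else 0.0
    return EvalResult(
        iou=iou,
        per_domain_iou=tuple(detail),
        domain_correct_fraction=correct,
        boundary_score=boundary,
        fault_flags=_fault_flags(pred, truth, detail, boundary),
    )
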