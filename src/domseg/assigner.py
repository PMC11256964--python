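"""Greedy maximum-likelihood resolution of soft adjacencies into domains.

The network outputs an L x L matrix of probabilities that residue pairs
share a domain.  Treating those entries as independent Bernoulli
parameters, the likelihood of a candidate assignment V (one-hot rows,
null residues all-zero) is

    L(V, Â) = sum_{i<j} [ a_ij log â_ij + (1 − a_ij) log(1 − â_ij) ]

with a_ij the binary co-membership induced by V.  The search initializes
every residue to null, then sweeps residues in sequence order; for each
residue the score of joining every current domain (or staying null) is
evaluated incrementally in O(L) via log-odds sums, the best domain is
taken if it beats null, and whenever the last (overflow) column is chosen
a fresh zero column is appended so the number of domains is unbounded.
Ties break toward the lowest domain index.  For an exact (clipped) binary
adjacency the procedure provably recovers the generating assignment.

A brute-force enumeration oracle over all canonical labelings is provided
for small L to validate near-optimality of the greedy search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .labels import DomainAssignment, canonicalize_labels

__all__ = [
    "SoftAdjacency",
    "AssignerConfig",
    "log_likelihood",
    "delta_score",
    "assign_domains",
    "brute_force_assign",
]


@dataclass(frozen=True)
class SoftAdjacency:
    """Symmetric L x L matrix of pairwise same-domain probabilities.

    Entries are clipped to [eps, 1 − eps] on construction so that log
    terms stay finite even for saturated network outputs.
    """

    matrix: np.ndarray = field(repr=False)
    eps: float = 1e-4

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("soft adjacency must be square")
        if not (0.0 <= self.eps < 0.5):
            raise ValueError("eps must be in [0, 0.5)")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("soft adjacency must be symmetric")
        if m.min() < 0.0 or m.max() > 1.0:
            raise ValueError("soft adjacency entries must lie in [0, 1]")
        m = 0.5 * (m + m.T)
        m = np.clip(m, self.eps, 1.0 - self.eps)
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def log_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """(log â, log(1 − â)) with zeroed diagonals."""
        lp1 = np.log(self.matrix)
        lp0 = np.log1p(-self.matrix)
        np.fill_diagonal(lp1, 0.0)
        np.fill_diagonal(lp0, 0.0)
        return lp1, lp0


@dataclass(frozen=True)
class AssignerConfig:
    """Search parameters.

    k_init: initial number of (empty) domain columns.
    n_iter: maximum number of full sweeps over the sequence; the search
        stops early as soon as a sweep changes nothing.
    eps: probability clip applied to the soft adjacency.
    min_domain_size: domains smaller than this are demoted to null after
        the search (0 disables the filter).
    """

    k_init: int = 4
    n_iter: int = 3
    eps: float = 1e-4
    min_domain_size: int = 0

    def __post_init__(self) -> None:
        if self.k_init < 1 or self.n_iter < 1:
            raise ValueError("k_init and n_iter must be >= 1")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must be in (0, 0.5)")
        if self.min_domain_size < 0:
            raise ValueError("min_domain_size must be >= 0")


def log_likelihood(assignment: DomainAssignment, soft: SoftAdjacency) -> float:
    """Bernoulli log-likelihood of the induced binary adjacency under Â."""
    if assignment.length != soft.length:
        raise ValueError("assignment and soft adjacency lengths differ")
    lab = assignment.labels
    lp1, lp0 = soft.log_terms()
    same = (lab[:, None] == lab[None, :]) & (lab != 0)[:, None] & (lab != 0)[None, :]
    terms = np.where(same, lp1, lp0)
    iu = np.triu_indices(assignment.length, k=1)
    return float(terms[iu].sum())


def delta_score(
    assignment: DomainAssignment,
    soft: SoftAdjacency,
    j: int,
    k: int,
) -> float:
    """Change in log-likelihood from moving residue j to domain k (0 = null).

    Only the L − 1 pair terms involving residue j change, so the delta is
    a difference of two log-odds sums and costs O(L).
    """
    lab = assignment.labels
    L = lab.size
    if not (0 <= j < L):
        raise IndexError(f"residue index {j} out of range")
    if not (0 <= k <= lab.max(initial=0) + 1):
        raise ValueError(f"target domain {k} out of range")
    lp1, lp0 = soft.log_terms()
    odds = lp1[j] - lp0[j]
    cur = lab[j]
    gain = odds[(lab == k) & (np.arange(L) != j)].sum() if k != 0 else 0.0
    loss = odds[(lab == cur) & (np.arange(L) != j)].sum() if cur != 0 else 0.0
    return float(gain - loss)


def assign_domains(
    soft: SoftAdjacency, config: AssignerConfig | None = None
) -> DomainAssignment:
    """Run the greedy sweep search and return the canonicalized assignment."""
    config = config or AssignerConfig()
    soft = SoftAdjacency(soft.matrix, eps=config.eps)
    L = soft.length
    lp1, lp0 = soft.log_terms()
    odds = lp1 - lp0  # diagonal already zero

    labels = np.zeros(L, dtype=np.int64)  # 0 = null; 1..K = domain columns
    K = config.k_init
    for _ in range(config.n_iter):
        changed = False
        for j in range(L):
            col = odds[:, j]
            # score of each domain relative to the j-removed state: sum of
            # log-odds to that domain's members (excluding j itself)
            sums = np.bincount(labels, weights=col, minlength=K + 1)
            if labels[j] != 0:
                sums[labels[j]] -= col[j]
            scores = sums[1 : K + 1]
            k_star = int(np.argmax(scores)) + 1  # ties -> lowest index
            # Under the i<j likelihood a singleton domain scores exactly like
            # null, so a strict beat-null rule could never nucleate a domain:
            # ties break toward assignment (an empty column scores 0), and
            # leftover singletons are canonicalized back to null at the end.
            new_label = k_star if scores[k_star - 1] >= 0.0 else 0
            if new_label != labels[j]:
                labels[j] = new_label
                changed = True
            if k_star == K:
                K += 1  # overflow column so the domain count is unbounded
        if not changed:
            break

    # singleton domains are likelihood-equivalent to null; pick null
    counts = np.bincount(labels, minlength=1)
    singletons = np.flatnonzero(counts == 1)
    labels[np.isin(labels, singletons[singletons != 0])] = 0

    if config.min_domain_size > 0:
        for k in np.unique(labels[labels != 0]):
            if (labels == k).sum() < config.min_domain_size:
                labels[labels == k] = 0
    return DomainAssignment(canonicalize_labels(labels))


def _canonical_labelings(L: int, max_domains: int):
    """Yield all length-L labelings over {0, 1..max_domains} in canonical
    form (non-zero labels appear in order of first occurrence), in
    lexicographic order."""
    def rec(prefix: list[int], used: int):
        if len(prefix) == L:
            yield tuple(prefix)
            return
        for lab in range(0, min(used + 1, max_domains) + 1):
            yield from rec(prefix + [lab], max(used, lab))

    yield from rec([], 0)


def brute_force_assign(soft: SoftAdjacency, max_domains: int = 6) -> DomainAssignment:
    """Exhaustive global maximizer of the assignment log-likelihood.

    Enumerates every canonical labeling of the L residues over null plus up
    to ``max_domains`` domains; refuses L > 10.  Ties break toward the
    lexicographically smallest canonical labeling.
    """
    L = soft.length
    if L > 10:
        raise ValueError(f"brute force enumeration refused for L={L} > 10")
    lp1, lp0 = soft.log_terms()
    iu, ju = np.triu_indices(L, k=1)
    t1 = lp1[iu, ju]
    t0 = lp0[iu, ju]
    best: tuple[int, ...] | None = None
    best_score = -np.inf
    for labeling in _canonical_labelings(L, max_domains):
        lab = np.asarray(labeling)
        same = (lab[iu] == lab[ju]) & (lab[iu] != 0)
        score = float(np.where(same, t1, t0).sum())
        if score > best_score:
            best_score = score
            best = labeling
    assert best is not None
    return DomainAssignment(np.asarray(best))
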