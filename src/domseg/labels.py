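"""Domain assignments and their pairwise co-membership (adjacency) representation.

A domain assignment over a chain of L residues is a length-L integer vector:
0 marks a residue assigned to no domain (null), and 1..K index the domains.
The equivalent pairwise representation is the binary L x L matrix A with
``a_ij = 1`` iff residues i and j belong to the same domain.  A is invariant
to permutations of the domain labels and handles discontinuous domains with
no special casing, which is what makes it a convenient supervised-learning
target.  For a one-hot assignment matrix V (L x K, null residues are zero
rows), A = V V^T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainAssignment",
    "AdjacencyLabel",
    "canonicalize_labels",
    "assignment_to_adjacency",
    "adjacency_to_assignment",
]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber non-zero labels to 1..K in order of first occurrence."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass(frozen=True)
class DomainAssignment:
    """Per-residue domain labels; 0 = null, 1..K = domain ids.

    Labels are canonicalized on construction so that domain ids appear in
    order of first occurrence along the sequence.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D integer vector")
        if (labels < 0).any():
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", canonicalize_labels(labels))

    @property
    def length(self) -> int:
        return int(self.labels.size)

    @property
    def n_domains(self) -> int:
        return int(self.labels.max(initial=0))

    def domain_residues(self, k: int) -> np.ndarray:
        """Indices of residues in domain k (1-based domain id)."""
        return np.flatnonzero(self.labels == k)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainAssignment):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())


@dataclass(frozen=True)
class AdjacencyLabel:
    """Binary symmetric L x L co-membership matrix A = V V^T.

    The diagonal is 1 for residues inside some domain and 0 for null
    residues, so "assigned to no domain" is representable inside A.
    """

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])


def assignment_to_adjacency(assignment: DomainAssignment) -> AdjacencyLabel:
    """Build A from labels: ``a_ij = 1`` iff ``labels[i] == labels[j] != 0``."""
    lab = assignment.labels
    same = lab[:, None] == lab[None, :]
    nonnull = lab != 0
    a = same & nonnull[:, None] & nonnull[None, :]
    return AdjacencyLabel(a.astype(np.uint8))


def adjacency_to_assignment(adj: AdjacencyLabel) -> DomainAssignment:
    """Recover labels as the connected components of the co-membership graph.

    Residues with a zero diagonal become null.  Raises ``ValueError`` if the
    matrix is not block-structured (i.e. not of the form V V^T), naming a
    violating triple.
    """
    a = adj.matrix
    L = a.shape[0]
    diag = np.diag(a).astype(bool)
    labels = np.zeros(L, dtype=np.int64)
    next_label = 0
    for i in range(L):
        if not diag[i] or labels[i] != 0:
            continue
        next_label += 1
        members = np.flatnonzero(a[i])
        labels[members] = next_label
    # validate block structure: every pair inside a component must be linked,
    # no links across components or involving null residues
    expected = assignment_to_adjacency(DomainAssignment(labels)).matrix
    if not np.array_equal(expected, a):
        bad = np.argwhere(expected != a)
        i, j = bad[0]
        # find a k completing the intransitive triple for the error message
        k = i
        for c in np.flatnonzero(a[i] & a[j] if a[i, j] == 0 else a[i] ^ a[j]):
            k = c
            break
        raise ValueError(
            f"adjacency is not block-structured: transitivity fails at "
            f"residues ({i}, {j}, {k})"
        )
    return DomainAssignment(labels)
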