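"""Per-chain confidence for a resolved domain assignment.

The soft adjacency Â is read as an L x L multivariate Bernoulli
distribution and the final binary assignment matrix A' as an observation
from it.  The confidence score is the residue-averaged likelihood

    confidence = exp( L(A', Â) / L )

i.e. the geometric mean over residues of the probability the network
assigns to the realized co-membership pattern.  It is 1 only when Â is
saturated exactly on A' (in the eps -> 0 limit) and decreases as the
prediction becomes more ambiguous, so it flags chains whose assignment
admits plausible alternatives.

Normalizing by the number of residues (rather than the ~L^2/2 pairs) keeps
the score on the discriminative (0.5, 1.0] range seen on realistic inputs;
pair-normalization is available via ``per_pair=True``.
"""

from __future__ import annotations

import numpy as np

from .assigner import SoftAdjacency, log_likelihood
from .labels import DomainAssignment

__all__ = ["confidence_score"]


def confidence_score(
    assignment: DomainAssignment,
    soft: SoftAdjacency,
    per_pair: bool = False,
) -> float:
    """Geometric-mean per-residue likelihood of the assignment under Â."""
    if assignment.length != soft.length:
        raise ValueError("assignment and soft adjacency lengths differ")
    L = assignment.length
    norm = L * (L - 1) / 2 if per_pair else L
    if norm == 0:
        return 1.0
    return float(np.exp(log_likelihood(assignment, soft) / norm))
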