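"""domseg: protein domain segmentation from 3-D structure.

A fully convolutional network predicts, for every residue pair of a chain,
the probability that the two residues belong to the same structural
domain; a greedy maximum-likelihood search then resolves that soft
adjacency matrix into discrete (possibly discontinuous) domains, with a
calibrated per-chain confidence score.
"""

from __future__ import annotations

from .assigner import (
    AssignerConfig,
    SoftAdjacency,
    assign_domains,
    brute_force_assign,
    delta_score,
    log_likelihood,
)
from .confidence import confidence_score
from .features import (
    FeatureConfig,
    FeatureStack,
    SecondaryStructure,
    assign_secondary_structure,
    distance_matrix,
    featurize,
    read_ss_file,
    ss_channels,
)
from .labels import (
    AdjacencyLabel,
    DomainAssignment,
    adjacency_to_assignment,
    assignment_to_adjacency,
)
from .metrics import (
    EvalResult,
    boundary_distance_score,
    domain_correct_fraction,
    evaluate_pair,
    iou_score,
)
from .network import (
    CoMembershipNet,
    NetworkConfig,
    TrainingConfig,
    bce_loss,
    build_model,
    load_model,
    predict_soft_adjacency,
    save_model,
    train,
)
from .structure_io import (
    ProteinChain,
    format_chopping,
    parse_chopping,
    read_structure,
    write_chain,
)

__version__ = "0.1.0"


def segment_chain(
    chain: ProteinChain,
    model: CoMembershipNet,
    ss: SecondaryStructure | None = None,
    assigner_config: AssignerConfig | None = None,
):
    """Run the full pipeline on one chain.

    Returns ``(assignment, confidence, soft_adjacency)``.
    """
    stack = featurize(chain, ss)
    soft = predict_soft_adjacency(model, stack)
    assignment = assign_domains(soft, assigner_config)
    return assignment, confidence_score(assignment, soft), soft
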