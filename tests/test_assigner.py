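import numpy as np
import pytest

from domseg.assigner import (
    AssignerConfig,
    SoftAdjacency,
    assign_domains,
    brute_force_assign,
    delta_score,
    log_likelihood,
)
from domseg.labels import DomainAssignment, assignment_to_adjacency
from domseg.synthetic import corrupt_adjacency, random_assignment


def uniform_soft(seed, L=6):
    rng = np.random.default_rng(seed)
    m = rng.random((L, L))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return SoftAdjacency(m)


def exact_soft(labels):
    adj = assignment_to_adjacency(DomainAssignment(np.array(labels)))
    return corrupt_adjacency(adj, 0.0, seed=0)


def test_log_likelihood_hand_examples():
    s = SoftAdjacency(np.full((3, 3), 0.9))
    assert log_likelihood(DomainAssignment(np.array([1, 1, 1])), s) == pytest.approx(
        3 * np.log(0.9)
    )
    s_half = SoftAdjacency(np.full((3, 3), 0.5))
    assert log_likelihood(DomainAssignment(np.array([0, 0, 0])), s_half) == pytest.approx(
        3 * np.log(0.5)
    )


def test_log_likelihood_perfect_match_is_near_zero():
    s = exact_soft([1, 1, 2, 2])
    best = log_likelihood(DomainAssignment(np.array([1, 1, 2, 2])), s)
    assert -1e-2 < best <= 0.0


def test_delta_score_noop_is_zero():
    s = uniform_soft(0, L=8)
    v = DomainAssignment(np.array([1, 1, 2, 2, 0, 1, 2, 0]))
    assert delta_score(v, s, 3, v.labels[3]) == pytest.approx(0.0)


def test_delta_score_two_residue_hand_example():
    m = np.array([[0.5, 0.9], [0.9, 0.5]])
    s = SoftAdjacency(m)
    v = DomainAssignment(np.array([1, 0]))
    assert delta_score(v, s, 1, 1) == pytest.approx(np.log(0.9) - np.log(0.1))


def test_delta_score_matches_full_recompute():
    worst = 0.0
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 30))
        s = uniform_soft(seed, L=L)
        v = DomainAssignment(rng.integers(0, 4, size=L))
        j = int(rng.integers(L))
        k = int(rng.integers(0, v.n_domains + 2))
        moved = v.labels.copy()
        moved[j] = k
        full = log_likelihood(DomainAssignment(moved), s) - log_likelihood(v, s)
        worst = max(worst, abs(delta_score(v, s, j, k) - full))
    assert worst < 1e-9


@pytest.mark.parametrize(
    "labels",
    [
        [1, 1, 1, 2, 2, 2],
        [1, 1, 2, 2, 1, 1],  # discontinuous
        [0, 1, 1, 1, 1, 1, 0],  # null flanks
    ],
)
def test_assign_domains_recovers_exact_adjacency(labels):
    assert assign_domains(exact_soft(labels)).labels.tolist() == DomainAssignment(
        np.array(labels)
    ).labels.tolist()


def test_overflow_beyond_k_init():
    labels = np.repeat(np.arange(1, 7), 3)  # 6 domains of 3 on L=18
    result = assign_domains(exact_soft(labels), AssignerConfig(k_init=4))
    assert result.n_domains == 6
    assert np.array_equal(result.labels, labels)


def test_sub_even_adjacency_gives_all_null():
    s = SoftAdjacency(np.full((4, 4), 0.5 - 1e-4))
    assert assign_domains(s).labels.tolist() == [0, 0, 0, 0]


def test_output_invariant_to_extra_overflow_columns():
    for seed in range(20):
        s = uniform_soft(seed)
        a = assign_domains(s, AssignerConfig(k_init=4))
        b = assign_domains(s, AssignerConfig(k_init=9))
        assert np.array_equal(a.labels, b.labels)


def test_min_domain_size_filter():
    s = exact_soft([1, 1, 1, 1, 1, 2, 2])
    filtered = assign_domains(s, AssignerConfig(min_domain_size=3))
    assert filtered.labels.tolist() == [1, 1, 1, 1, 1, 0, 0]


def test_asymmetric_soft_rejected():
    m = np.zeros((3, 3))
    m[0, 1] = 0.9
    with pytest.raises(ValueError):
        SoftAdjacency(m)
    with pytest.raises(ValueError):
        SoftAdjacency(np.full((3, 3), 1.5))


def test_brute_force_exact_adjacency_and_refusal():
    s = exact_soft([1, 1, 2, 2, 0])
    assert brute_force_assign(s, max_domains=3).labels.tolist() == [1, 1, 2, 2, 0]
    with pytest.raises(ValueError):
        brute_force_assign(SoftAdjacency(np.full((11, 11), 0.4)), 3)


def test_brute_force_all_half_ties_to_null():
    s = SoftAdjacency(np.full((5, 5), 0.5))
    assert brute_force_assign(s, max_domains=3).labels.tolist() == [0] * 5


def test_greedy_never_exceeds_oracle():
    for seed in range(50):
        s = uniform_soft(seed)
        greedy = log_likelihood(assign_domains(s), s)
        oracle = log_likelihood(brute_force_assign(s, max_domains=4), s)
        assert greedy <= oracle + 1e-9


def test_perfect_predictor_recovery_sample():
    """Exact recovery from clipped exact adjacencies, small spot-check
    (the 500-instance version runs in the acceptance suite)."""
    for seed in range(50):
        L = int(np.random.default_rng(seed).integers(20, 120))
        truth = random_assignment(L, seed=seed + 1)
        s = corrupt_adjacency(assignment_to_adjacency(truth), 0.0, seed=seed)
        assert assign_domains(s) == truth


def test_config_validation():
    with pytest.raises(ValueError):
        AssignerConfig(k_init=0)
    with pytest.raises(ValueError):
        AssignerConfig(eps=0.7)
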