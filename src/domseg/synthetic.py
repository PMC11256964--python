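"""Synthetic protein-like chains with known domain structure.

The generator embodies the structural premise behind contact-based domain
parsing: the density of Cα contacts is higher within a domain than between
domains.  Each domain is a bounded 3.8 Å-step random walk confined to a
ball around its own centroid; centroids are mutually separated by well
over twice the intra-domain spread, so intra-domain pair distances are
typically much smaller than inter-domain ones.  Linkers are short extended
walks between consecutive segments, labelled null, and a disordered null
tail can be appended.  Discontinuous domains are realized by returning to
an earlier domain's centroid after an intervening domain.

Secondary-structure segments (alternating helix/strand runs inside
domains, coil in linkers and tails) are synthesized jointly with the
domain labels so the SS feature channels carry domain-correlated signal,
as they do in real proteins.  The point clouds are not physically
realistic backbones — the downstream method only consumes pairwise Cα
distances and coarse SS, so nothing more is needed.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import FeatureStack, SecondaryStructure, featurize
from .labels import AdjacencyLabel, DomainAssignment, assignment_to_adjacency
from .assigner import SoftAdjacency
from .structure_io import ProteinChain

__all__ = [
    "SyntheticSpec",
    "generate_chain",
    "corrupt_adjacency",
    "make_dataset",
    "random_assignment",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
STEP = 3.8  # Å, consecutive-Cα distance


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters (distances in Å).

    ``domain_sizes`` fixes the residue count of each domain when given;
    otherwise sizes are drawn uniformly from ``size_range``.  The invariant
    ``centroid_separation > 2 * intra_spread`` guarantees the intra/inter
    contact-density contrast.
    """

    n_domains: int = 2
    domain_sizes: tuple[int, ...] | None = None
    size_range: tuple[int, int] = (30, 120)
    linker_range: tuple[int, int] = (3, 8)
    discontinuous_prob: float = 0.2
    null_tail_prob: float = 0.1
    tail_range: tuple[int, int] = (5, 15)
    centroid_separation: float = 25.0
    intra_spread: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 0:
            raise ValueError("n_domains must be >= 0")
        sizes = self.domain_sizes
        if sizes is not None:
            if len(sizes) != self.n_domains or any(s < 5 for s in sizes):
                raise ValueError("domain_sizes must list n_domains sizes, each >= 5")
        if self.size_range[0] < 5:
            raise ValueError("domain sizes must be >= 5")
        if self.centroid_separation <= 2 * self.intra_spread:
            raise ValueError("centroid_separation must exceed 2 * intra_spread")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_centroids(
    n: int, separation: float, rng: np.random.Generator, max_tries: int = 200
) -> np.ndarray:
    centroids = [np.zeros(3)]
    for _ in range(1, n):
        for attempt in range(max_tries):
            base = centroids[rng.integers(len(centroids))]
            cand = base + _random_unit(rng) * separation * (1.0 + 0.3 * rng.random())
            if all(np.linalg.norm(cand - c) >= separation for c in centroids):
                centroids.append(cand)
                break
        else:
            raise RuntimeError("could not place mutually separated centroids")
    return np.array(centroids)


def _bounded_walk(
    start: np.ndarray,
    centroid: np.ndarray,
    n_steps: int,
    spread: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Random walk of fixed step length confined to a ball around centroid."""
    points = []
    pos = start
    for _ in range(n_steps):
        for _ in range(100):
            cand = pos + STEP * _random_unit(rng)
            if np.linalg.norm(cand - centroid) <= spread:
                pos = cand
                break
        else:
            # fall back: step straight toward the centroid
            direction = centroid - pos
            norm = np.linalg.norm(direction)
            pos = pos + STEP * (direction / norm if norm > 0 else _random_unit(rng))
        points.append(pos)
    return points


def _walk_towards(
    start: np.ndarray, target: np.ndarray, n_steps: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Extended linker walk: fixed-length steps biased toward the target."""
    points = []
    pos = start
    for _ in range(n_steps):
        direction = target - pos
        norm = np.linalg.norm(direction)
        d = direction / norm if norm > STEP else _random_unit(rng)
        step = d + 0.4 * rng.normal(size=3)
        pos = pos + STEP * step / np.linalg.norm(step)
        points.append(pos)
    return points


def _ss_for_segment(length: int, rng: np.random.Generator) -> str:
    """Alternating H/E runs separated by short coil gaps."""
    out: list[str] = []
    code = "H" if rng.random() < 0.6 else "E"
    while len(out) < length:
        run = int(rng.integers(6, 13)) if code == "H" else int(rng.integers(3, 7))
        out.extend(code * min(run, length - len(out)))
        gap = int(rng.integers(1, 4))
        out.extend("C" * min(gap, max(length - len(out), 0)))
        code = "E" if code == "H" else "H"
    return "".join(out[:length])


def generate_chain(
    spec: SyntheticSpec,
) -> tuple[ProteinChain, DomainAssignment, SecondaryStructure]:
    """Generate one chain with ground-truth domain labels and SS."""
    rng = np.random.default_rng(spec.seed)
    sizes = (
        list(spec.domain_sizes)
        if spec.domain_sizes is not None
        else [int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
              for _ in range(spec.n_domains)]
    )
    n = spec.n_domains

    # segment plan: (domain id 1..n, segment length); a discontinuous domain
    # contributes two segments sandwiching the next domain
    plan: list[tuple[int, int]] = []
    d = 0
    while d < n:
        size = sizes[d]
        if (
            d + 1 < n
            and size >= 20
            and rng.random() < spec.discontinuous_prob
        ):
            cut = int(rng.integers(8, size - 8 + 1))
            plan.append((d + 1, cut))
            plan.append((d + 2, sizes[d + 1]))
            plan.append((d + 1, size - cut))
            d += 2
        else:
            plan.append((d + 1, size))
            d += 1

    centroids = _place_centroids(max(n, 1), spec.centroid_separation, rng)

    coords: list[np.ndarray] = []
    domain_labels: list[int] = []
    ss: list[str] = []
    for seg_idx, (dom, seg_len) in enumerate(plan):
        centroid = centroids[dom - 1]
        if not coords:
            start = centroid + spec.intra_spread * 0.5 * _random_unit(rng)
        else:
            linker_len = int(rng.integers(spec.linker_range[0], spec.linker_range[1] + 1))
            linker = _walk_towards(coords[-1], centroid, linker_len, rng)
            coords.extend(linker)
            domain_labels.extend([0] * linker_len)
            ss.extend("C" * linker_len)
            start = coords[-1]
        seg = _bounded_walk(start, centroid, seg_len, spec.intra_spread, rng)
        coords.extend(seg)
        domain_labels.extend([dom] * seg_len)
        ss.extend(_ss_for_segment(seg_len, rng))

    if n == 0 or (spec.null_tail_prob > 0 and rng.random() < spec.null_tail_prob):
        tail_len = int(rng.integers(spec.tail_range[0], spec.tail_range[1] + 1))
        anchor = coords[-1] if coords else np.zeros(3)
        away = anchor + _random_unit(rng) * 100.0
        tail = _walk_towards(anchor if coords else np.zeros(3), away, tail_len, rng)
        coords.extend(tail)
        domain_labels.extend([0] * tail_len)
        ss.extend("C" * tail_len)

    L = len(coords)
    residues = tuple(
        (i + 1, _AA[int(rng.integers(len(_AA)))]) for i in range(L)
    )
    chain = ProteinChain("A", residues, np.array(coords))
    assignment = DomainAssignment(np.array(domain_labels))
    return chain, assignment, SecondaryStructure("".join(ss))


def corrupt_adjacency(
    truth: AdjacencyLabel, noise: float, seed: int, eps: float = 1e-4
) -> SoftAdjacency:
    """Blend the exact adjacency with symmetric uniform noise.

    ``â = clip((1 − noise) · a + noise · u, eps, 1 − eps)`` with u i.i.d.
    uniform(0, 1), symmetrized by averaging with the transpose.  noise = 0
    reproduces the clipped truth; noise = 1 is independent of it.
    """
    if not (0.0 <= noise <= 1.0):
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(truth.matrix.shape)
    u = 0.5 * (u + u.T)
    soft = (1.0 - noise) * truth.matrix.astype(np.float64) + noise * u
    return SoftAdjacency(np.clip(soft, eps, 1.0 - eps), eps=eps)


def random_assignment(
    L: int,
    max_domains: int = 6,
    min_size: int = 5,
    discontinuous_prob: float = 0.3,
    null_prob: float = 0.2,
    seed: int = 0,
) -> DomainAssignment:
    """Random ground-truth assignment over L residues.

    Segments of length >= min_size are dealt to domains (revisiting a
    domain makes it discontinuous); a leading/trailing null stretch is
    inserted with probability null_prob.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(L, dtype=np.int64)
    pos = 0
    if rng.random() < null_prob:
        pos = int(rng.integers(0, min(min_size, L // 4) + 1))
    k = 0
    open_domains: list[int] = []
    while L - pos >= min_size:
        remaining = L - pos
        size = int(rng.integers(min_size, max(min_size, remaining // 2) + 1))
        size = min(size, remaining)
        revisit = (
            open_domains
            and rng.random() < discontinuous_prob
            and k >= 2
        )
        if revisit:
            dom = int(rng.choice([d for d in open_domains if d != labels[pos - 1]] or open_domains))
        elif k < max_domains:
            k += 1
            dom = k
            open_domains.append(dom)
        else:
            dom = int(rng.choice(open_domains))
        labels[pos : pos + size] = dom
        pos += size
        if rng.random() < null_prob and L - pos >= 2:
            gap = int(rng.integers(1, min(4, L - pos) + 1))
            pos += gap
    return DomainAssignment(labels)


def default_spec_distribution(rng: np.random.Generator, seed: int) -> SyntheticSpec:
    """Spec distribution used for mini-training datasets: compact chains
    (1–3 domains of 20–45 residues) so that a small network can be trained
    quickly while covering single/multi-domain and discontinuous cases."""
    n_domains = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
    return SyntheticSpec(
        n_domains=n_domains,
        size_range=(20, 45),
        centroid_separation=25.0,
        intra_spread=8.0,
        discontinuous_prob=0.2,
        null_tail_prob=0.1,
        seed=seed,
    )


def make_dataset(
    n_chains: int,
    seed: int = 0,
    spec_fn=default_spec_distribution,
    use_true_ss: bool = False,
) -> list[tuple[FeatureStack, AdjacencyLabel, str]]:
    """Featurized chains with adjacency labels and a single/multi flag.

    The flag is ``"single"`` iff the chain has at most one domain; training
    uses it for class-weighted sampling.  By default chains are featurized
    exactly as at inference time (secondary structure re-derived from the
    geometry), so trained models see a consistent input distribution;
    ``use_true_ss=True`` substitutes the synthesized SS labels instead.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_chains):
        chain_seed = int(rng.integers(0, 2**31 - 1))
        spec = spec_fn(rng, chain_seed)
        chain, assignment, ss = generate_chain(spec)
        flag = "single" if assignment.n_domains <= 1 else "multi"
        stack = featurize(chain, ss if use_true_ss else None)
        out.append((stack, assignment_to_adjacency(assignment), flag))
    return out
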