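# domseg

Protein domain segmentation from 3-D structure.

Structural domains — compact, semi-independent folding units — are the
currency of structure classification (CATH, SCOP) and of downstream
annotation of predicted models.  `domseg` segments a protein chain into
domains, including discontinuous ones, in three steps:

1. **Featurize.**  From the Cα coordinates build five L × L channels:
   the pairwise distance matrix plus four coarse secondary-structure
   channels (helix/strand segment co-membership and start/end markers).
   The representation depends only on pairwise geometry, so it is
   invariant to rotations, translations and reflections.
2. **Predict pairwise co-membership.**  A fully convolutional dilated
   residual network maps the feature stack to a symmetric matrix Â of
   probabilities â_ij that residues i and j share a domain (the *soft
   adjacency matrix*).  One weight set serves chains of any length.
3. **Assign domains.**  Treating the â_ij as independent Bernoulli
   parameters, a greedy search maximizes the assignment log-likelihood

       L(V, Â) = Σ_{i<j} [ a_ij log â_ij + (1 − a_ij) log(1 − â_ij) ],

   where a_ij is the binary co-membership induced by the one-hot
   assignment matrix V (A = V Vᵀ).  Residues are swept in sequence order
   and moved to their best-scoring domain (or left unassigned) with an
   O(L) incremental score; an overflow column makes the number of
   domains unbounded.  For a perfect predictor the search provably
   recovers the generating assignment.  A per-chain confidence,
   exp(L(A′, Â)/L), reports how strongly the network supports the final
   assignment A′.

Assignments are written as CATH-style chopping strings
(`"1-100,101-150_201-250"`: commas separate domains, underscores join
the segments of a discontinuous domain).  A synthetic-structure
generator with known domain labels makes the whole pipeline trainable
and testable without any external dataset, and evaluation metrics
(per-domain IoU under optimal matching, correct-domain fraction at
IoU ≥ 0.8, boundary distance score) are included.  See
`docs/methods.md` for the model details and design choices.

## Worked example

Train a small model on synthetic chains, segment a synthetic two-domain
structure, and score the result:

```sh
domseg train --synthetic 200 --epochs 10 --seed 0 --out model.npz
domseg predict --structure two_domain.pdb --model model.npz
```

```
file            chain_id  nres  ndom  chopping      confidence
two_domain.pdb  A         74    2     1-28,36-74    0.3192
```

The chain has 74 residues parsed into two domains: residues 1–28 and
36–74 (the underscore form would appear if a domain were discontinuous).
Confidence is the geometric-mean per-residue likelihood of the final
assignment under the network's pairwise probabilities — near 1 when the
network is saturated and certain, lower when alternative assignments
remain plausible.  Scoring this prediction against the generator's
ground truth (`1-29,38-74`, linker residues unassigned):

```sh
domseg evaluate --pred pred.tsv --truth truth.tsv
```

```
key               iou     domain_correct_fraction  boundary_score  fault_flags
two_domain.pdb:A  0.9571  1.0000                   0.9375          boundary_error
```

Both domains are recovered (IoU ≥ 0.8 each, so the correct fraction is
1.0); the mean IoU of 0.957 and the boundary flag reflect the handful of
linker residues that the ground truth leaves unassigned and the
prediction absorbs into the adjacent domains.

The same pipeline is available as a library:

```python
from domseg import load_model, read_structure, segment_chain, format_chopping

chain = read_structure("two_domain.pdb")
assignment, confidence, soft = segment_chain(chain, load_model("model.npz"))
print(format_chopping(assignment, chain), round(confidence, 3))
```

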