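import numpy as np
import pytest
from scipy.stats import special_ortho_group

from domseg.features import (
    SecondaryStructure,
    assign_secondary_structure,
    distance_matrix,
    featurize,
    read_ss_file,
    ss_channels,
)
from domseg.structure_io import ProteinChain
from domseg.synthetic import SyntheticSpec, generate_chain

from conftest import make_chain


def test_distance_matrix_345_triangle():
    chain = make_chain([[0, 0, 0], [3, 4, 0]])
    d = distance_matrix(chain)
    assert d[0, 1] == pytest.approx(5.0)
    assert d[1, 0] == pytest.approx(5.0)
    assert d[0, 0] == 0.0


def test_distance_matrix_symmetry_and_rigid_invariance():
    chain, _, _ = generate_chain(SyntheticSpec(seed=2))
    d = distance_matrix(chain)
    assert np.array_equal(d, d.T)
    assert np.all(np.diag(d) == 0.0)
    R = special_ortho_group.rvs(3, random_state=1)
    moved = ProteinChain(
        "A", chain.residues, chain.ca_coords @ R.T + np.array([10.0, -3.0, 7.0])
    )
    assert np.allclose(distance_matrix(moved), d, atol=1e-9)


def test_ideal_helix_detected(ideal_helix_chain):
    ss = assign_secondary_structure(ideal_helix_chain)
    helices = [s for s in ss.segments if s[0] == "H"]
    assert len(helices) == 1
    _, start, end = helices[0]
    assert end - start + 1 >= 8
    assert "E" not in ss.labels


def test_straight_line_never_helix(straight_chain):
    ss = assign_secondary_structure(straight_chain)
    assert "H" not in ss.labels
    assert set(ss.labels) <= {"E", "C"}


def test_short_chain_all_coil():
    chain = make_chain(np.random.default_rng(0).normal(size=(4, 3)))
    assert assign_secondary_structure(chain).labels == "CCCC"


def test_ss_channels_helix_segment():
    ss = SecondaryStructure("CCHHHHCC")
    ch = ss_channels(ss, 8)
    helix_co = ch[0]
    expected = np.zeros((8, 8))
    expected[2:6, 2:6] = 1.0
    assert np.array_equal(helix_co, expected)
    # boundary vector: +1 at segment start, -1 at its end, broadcast on rows
    b = [0, 0, 1, 0, 0, -1, 0, 0]
    assert np.array_equal(ch[2], np.array(b, dtype=np.float32)[:, None] * np.ones(8))
    assert not ch[1].any() and not ch[3].any()


def test_ss_channels_two_segments_not_comembers():
    ss = SecondaryStructure("HHHHCHHHH")
    ch = ss_channels(ss, 9)
    assert ch[0][0, 5] == 0.0 and ch[0][1, 7] == 0.0
    assert ch[0][0, 3] == 1.0 and ch[0][5, 8] == 1.0


def test_no_segments_all_zero():
    ch = ss_channels(SecondaryStructure("CCCC"), 4)
    assert not ch.any()


def test_featurize_stack_layout(straight_chain):
    stack = featurize(straight_chain)
    assert stack.tensor.shape == (5, 10, 10)
    d = stack.tensor[0]
    assert d[0, 1] == pytest.approx(0.38)  # 3.8 Å / dist_scale 10
    assert np.array_equal(d, d.T)


def test_featurize_bitwise_invariant_under_rigid_and_reflection():
    chain, _, _ = generate_chain(SyntheticSpec(seed=3))
    ref = featurize(chain).tensor
    rng = np.random.default_rng(5)
    for trial in range(20):
        R = special_ortho_group.rvs(3, random_state=trial)
        if trial % 2:
            R = -R  # improper rotation: reflection included
        coords = chain.ca_coords @ R.T + rng.normal(scale=50.0, size=3)
        moved = ProteinChain("A", chain.residues, coords)
        assert np.array_equal(featurize(moved).tensor, ref)


def test_stride_and_dssp_readers(tmp_path, straight_chain):
    stride = tmp_path / "out.stride"
    stride.write_text(
        "REM  ------\n"
        "ASG  ALA A    1    1    H    AlphaHelix    -60.0    -45.0     20.0\n"
        "ASG  ALA A    2    2    G    310Helix      -60.0    -45.0     20.0\n"
        "ASG  ALA A    3    3    E    Strand       -120.0    130.0     20.0\n"
        "ASG  ALA A    4    4    C    Coil          -70.0    150.0     20.0\n"
    )
    ss = read_ss_file(stride, straight_chain)
    assert ss.labels[:4] == "HHEC" and ss.labels[4:] == "CCCCCC"

    dssp = tmp_path / "out.dssp"
    header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
    rows = [
        "    1    1 A A  H  >  S+\n",
        "    2    2 A A  B  >  S+\n",
        "    3    3 A A  I  >  S+\n",
    ]
    dssp.write_text("== some preamble ==\n" + header + "".join(rows))
    ss = read_ss_file(dssp, straight_chain)
    assert ss.labels[:3] == "HEH"
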