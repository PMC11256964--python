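"""Structure input and chopping-string output.

Reads a single protein chain (PDB or mmCIF, via gemmi) into the internal
``ProteinChain`` representation: an ordered list of residues with one
alpha-carbon coordinate each.  Internal residue indices are 0-based and
dense; author numbering is kept only so that domain assignments can be
written as CATH-style chopping strings, e.g. ``"1-100,101-150_201-250"``
(commas separate domains, underscores join the sequence segments of one
discontinuous domain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .labels import DomainAssignment

__all__ = [
    "ProteinChain",
    "read_structure",
    "write_chain",
    "format_chopping",
    "parse_chopping",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinChain:
    """Ordered residues of one chain with their Cα coordinates (Å).

    ``residues`` holds ``(author_residue_number, one_letter_code)`` in file
    order; ``ca_coords`` has exactly one row per residue.  ``plddt``
    optionally carries a per-residue confidence in [0, 100] (e.g. the
    B-factor column of a predicted model).
    """

    chain_id: str
    residues: tuple[tuple[int, str], ...]
    ca_coords: np.ndarray = field(repr=False)
    plddt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coords must be an L x 3 matrix")
        if len(self.residues) != coords.shape[0] or coords.shape[0] < 1:
            raise ValueError("need one Cα coordinate row per residue, L >= 1")
        if not np.isfinite(coords).all():
            raise ValueError("Cα coordinates must be finite")
        object.__setattr__(self, "ca_coords", coords)
        object.__setattr__(self, "residues", tuple(self.residues))
        if self.plddt is not None:
            p = np.asarray(self.plddt, dtype=np.float64)
            if p.shape != (coords.shape[0],):
                raise ValueError("plddt must be length L")
            object.__setattr__(self, "plddt", p)

    @property
    def length(self) -> int:
        return int(self.ca_coords.shape[0])

    @property
    def author_numbers(self) -> np.ndarray:
        return np.array([num for num, _ in self.residues], dtype=np.int64)

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def read_structure(path: str | Path, chain_id: str | None = None) -> ProteinChain:
    """Read one chain from a PDB or mmCIF file.

    The first model is used.  Only polymer (ATOM) amino-acid residues are
    considered; for alternate conformations the highest-occupancy Cα is
    kept.  Residues lacking a Cα atom are dropped with a warning.  If
    ``chain_id`` is None the first chain containing a Cα is used.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    structure.setup_entities()
    model = structure[0]

    chains = [c for c in model if chain_id is None or c.name == chain_id]
    if chain_id is not None and not chains:
        raise KeyError(f"chain {chain_id!r} not found in {path}")

    for chain in chains:
        residues: list[tuple[int, str]] = []
        coords: list[tuple[float, float, float]] = []
        bfactors: list[float] = []
        for res in chain:
            if res.het_flag == "H" and gemmi.find_tabulated_residue(res.name) is None:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            ca = None
            for atom in res:
                if atom.name == "CA" and (ca is None or atom.occ > ca.occ):
                    ca = atom
            if ca is None:
                logger.warning(
                    "residue %s %d in chain %s has no Cα atom; dropped",
                    res.name, res.seqid.num, chain.name,
                )
                continue
            residues.append((res.seqid.num, _one_letter(res.name)))
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
            bfactors.append(ca.b_iso)
        if residues:
            b = np.array(bfactors)
            plddt = b if ((0 <= b) & (b <= 100)).all() and b.any() else None
            return ProteinChain(chain.name, tuple(residues), np.array(coords), plddt)

    raise ValueError(f"no residues with Cα atoms found in {path}")


_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_chain(chain: ProteinChain, path: str | Path) -> None:
    """Write a Cα-only trace of the chain as PDB or mmCIF (by extension)."""
    structure = gemmi.Structure()
    structure.name = Path(path).stem
    model = gemmi.Model("1")
    gchain = gemmi.Chain(chain.chain_id)
    for idx, ((num, aa), xyz) in enumerate(zip(chain.residues, chain.ca_coords)):
        res = gemmi.Residue()
        res.name = _THREE_LETTER.get(aa, "UNK")
        res.seqid = gemmi.SeqId(num, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = float(chain.plddt[idx]) if chain.plddt is not None else 0.0
        res.add_atom(atom)
        gchain.add_residue(res)
    model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        structure.make_mmcif_document().write_file(str(path))
    else:
        structure.write_pdb(str(path))


def _segments_of(indices: np.ndarray) -> list[tuple[int, int]]:
    """Split sorted 0-based indices into runs of consecutive positions."""
    segs: list[tuple[int, int]] = []
    start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            segs.append((start, prev))
            start = prev = i
    segs.append((start, prev))
    return segs


def format_chopping(assignment: DomainAssignment, chain: ProteinChain) -> str:
    """Encode an assignment as a chopping string in author numbering.

    Null residues are omitted; domains are ordered by first residue;
    segments of a discontinuous domain are joined with ``_``.
    """
    if assignment.length != chain.length:
        raise ValueError(
            f"assignment length {assignment.length} != chain length {chain.length}"
        )
    numbers = chain.author_numbers
    parts = []
    for k in range(1, assignment.n_domains + 1):
        idx = assignment.domain_residues(k)
        segs = _segments_of(idx)
        parts.append(
            "_".join(f"{numbers[a]}-{numbers[b]}" for a, b in segs)
        )
    return ",".join(parts)


def parse_chopping(text: str, chain: ProteinChain) -> DomainAssignment:
    """Parse a chopping string back into a DomainAssignment.

    Inverse of :func:`format_chopping` up to canonical domain renumbering.
    Residue numbers must exist in the chain; overlapping ranges are an error.
    """
    numbers = chain.author_numbers
    index_of = {int(n): i for i, n in enumerate(numbers)}
    labels = np.zeros(chain.length, dtype=np.int64)
    text = text.strip()
    if not text:
        return DomainAssignment(labels)
    for k, item in enumerate(text.split(","), start=1):
        for seg in item.split("_"):
            try:
                start_s, end_s = seg.rsplit("-", 1)
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed chopping segment {seg!r}") from exc
            if start not in index_of or end not in index_of:
                raise KeyError(
                    f"segment {seg!r} refers to residue numbers absent from chain"
                )
            a, b = index_of[start], index_of[end]
            if b < a:
                raise ValueError(f"segment {seg!r} is reversed")
            span = labels[a : b + 1]
            if (span != 0).any():
                raise ValueError(f"segment {seg!r} overlaps a previous domain")
            labels[a : b + 1] = k
    return DomainAssignment(labels)
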