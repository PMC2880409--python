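"""Derive per-residue DNA/RNA-binding labels from complex structures.

A residue counts as a binding site when any of its side-chain or backbone
heavy atoms lies within a cutoff distance (3.5 Å by default, inclusive) of
any heavy atom of a nucleic-acid chain of the requested kind.  Hydrogens,
waters and heteroatoms are ignored; only the first model of a multi-model
file is considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .features import STANDARD_AA

BINDING_CUTOFF = 3.5  # Å, inclusive

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_DNA_RES = {"DA", "DC", "DG", "DT", "DI", "DU"}
_RNA_RES = {"A", "C", "G", "U", "I"}


class StructureFormatError(ValueError):
    """Structure file cannot be parsed or contains no chains."""


class NoPartnerError(ValueError):
    """No nucleic chain of the requested kind in the complex."""


class NoAtomsError(ValueError):
    """Distance requested against an empty atom list."""


@dataclass
class ResidueRecord:
    name: str
    number: int
    atoms: list[tuple[str, np.ndarray]]  # (element, xyz in Å)

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)


@dataclass
class ChainRecord:
    chain_id: str
    kind: str  # protein | dna | rna | other
    residues: list[ResidueRecord]

    def all_coords(self) -> np.ndarray:
        parts = [r.coords() for r in self.residues if r.atoms]
        if not parts:
            return np.empty((0, 3))
        return np.vstack(parts)


@dataclass
class LabeledSequence:
    """Amino-acid sequence with per-residue binary binding labels.

    ``labels`` uses +1 for binding and -1 for non-binding residues;
    ``source`` records provenance (structure/chain id or "synthetic").
    """

    id: str
    sequence: str
    labels: np.ndarray
    source: str = "synthetic"
    min_distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sequence):
            raise ValueError(
                f"{self.id}: {len(self.sequence)} residues vs "
                f"{len(self.labels)} labels"
            )
        if not np.all(np.isin(self.labels, (1, -1))):
            raise ValueError(f"{self.id}: labels must be +1/-1")

    @property
    def positive_fraction(self) -> float:
        return float(np.mean(self.labels == 1))


def _chain_kind(residue_names: list[str]) -> str:
    """Classify a chain by majority vote over its residue names."""
    votes = {"protein": 0, "dna": 0, "rna": 0, "other": 0}
    for name in residue_names:
        name = name.strip().upper()
        if name in _AA3TO1 or name in {"MSE", "SEC", "PYL", "UNK"}:
            votes["protein"] += 1
        elif name in _DNA_RES:
            votes["dna"] += 1
        elif name in _RNA_RES:
            votes["rna"] += 1
        else:
            votes["other"] += 1
    kind = max(votes, key=votes.get)
    return kind if votes[kind] > 0 else "other"


def classify_chains(structure_path: str | Path) -> list[ChainRecord]:
    """Parse a PDB file and assign each chain a kind (protein/dna/rna/other).

    Waters and heteroatom residues are dropped; hydrogen (and deuterium)
    atoms are excluded from the retained residues.  Only the first model
    is read.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("complex", str(structure_path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureFormatError(f"cannot parse {structure_path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise StructureFormatError(f"{structure_path}: no models")
    model = models[0]

    chains: list[ChainRecord] = []
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag != " ":  # waters and heteroatoms
                continue
            atoms = []
            for atom in res:
                element = (atom.element or atom.get_name()[:1]).strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append((element, np.asarray(atom.coord, dtype=float)))
            residues.append(ResidueRecord(res.resname.strip(), res.id[1], atoms))
        if residues:
            chains.append(
                ChainRecord(chain.id, _chain_kind([r.name for r in residues]), residues)
            )
    if not chains:
        raise StructureFormatError(f"{structure_path}: structure has no chains")
    return chains


def min_residue_distance(residue_atoms, nucleic_atoms) -> float:
    """Minimum Euclidean distance over all atom pairs, in Å.

    Accepts either coordinate arrays or (element, xyz) atom lists.
    """
    a = _as_coords(residue_atoms)
    b = _as_coords(nucleic_atoms)
    if a.size == 0 or b.size == 0:
        raise NoAtomsError("empty atom list in distance computation")
    return float(cdist(a, b).min())


def _as_coords(atoms) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return atoms.reshape(-1, 3).astype(float)
    coords = []
    for atom in atoms:
        if isinstance(atom, tuple) and len(atom) == 2:
            coords.append(np.asarray(atom[1], dtype=float))
        else:
            coords.append(np.asarray(atom, dtype=float))
    return np.array(coords, dtype=float).reshape(-1, 3)


def label_binding_residues(
    structure_path: str | Path,
    cutoff: float = BINDING_CUTOFF,
    target: str = "dna",
) -> list[LabeledSequence]:
    """Label every protein-chain residue against all ``target``-kind chains.

    A residue gets label +1 iff its minimum heavy-atom distance to the union
    of all target nucleic chains is <= ``cutoff``; otherwise -1.  Raises
    :class:`NoPartnerError` if the complex has no chain of the target kind,
    so an all-negative labelling can never be produced silently.
    """
    if target not in ("dna", "rna"):
        raise ValueError(f"target must be 'dna' or 'rna', got {target!r}")
    chains = classify_chains(structure_path)
    nucleic = [c for c in chains if c.kind == target]
    proteins = [c for c in chains if c.kind == "protein"]
    if not nucleic:
        raise NoPartnerError(f"no {target} chain in {structure_path}")
    if not proteins:
        raise NoPartnerError(f"no protein chain in {structure_path}")
    nucleic_coords = np.vstack([c.all_coords() for c in nucleic])

    structure_id = Path(structure_path).stem
    out: list[LabeledSequence] = []
    for chain in proteins:
        seq, labels, dists = [], [], []
        for res in chain.residues:
            seq.append(_AA3TO1.get(res.name, "X"))
            d = min_residue_distance(res.coords(), nucleic_coords)
            dists.append(d)
            labels.append(1 if d <= cutoff else -1)
        out.append(
            LabeledSequence(
                id=f"{structure_id}_{chain.chain_id}",
                sequence="".join(seq),
                labels=np.array(labels),
                source=f"{structure_id}/{chain.chain_id}",
                min_distances=np.array(dists),
            )
        )
    return out


def write_labeled_fasta(records: list[LabeledSequence], path: str | Path) -> None:
    """FASTA with a '+'/'-' label track line following each sequence line."""
    with open(path, "w") as fh:
        for rec in records:
            track = "".join("+" if y == 1 else "-" for y in rec.labels)
            fh.write(f">{rec.id} source={rec.source}\n{rec.sequence}\n{track}\n")


def read_labeled_fasta(path: str | Path) -> list[LabeledSequence]:
    records = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected FASTA header at line {i + 1}")
        header = lines[i][1:].split()
        source = "synthetic"
        for tok in header[1:]:
            if tok.startswith("source="):
                source = tok[len("source="):]
        seq, track = lines[i + 1], lines[i + 2]
        labels = np.array([1 if c == "+" else -1 for c in track])
        records.append(LabeledSequence(header[0], seq, labels, source))
        i += 3
    return records


def write_label_table(records: list[LabeledSequence], path: str | Path) -> None:
    """TSV: structure, chain, position (1-based), residue, label, min_distance."""
    with open(path, "w") as fh:
        fh.write("structure\tchain\tposition\tresidue\tlabel\tmin_distance\n")
        for rec in records:
            structure, _, chain = rec.source.partition("/")
            dists = rec.min_distances
            for i, (aa, y) in enumerate(zip(rec.sequence, rec.labels)):
                d = f"{dists[i]:.3f}" if dists is not None else "NA"
                fh.write(f"{structure}\t{chain}\t{i + 1}\t{aa}\t{y:+d}\t{d}\n")
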