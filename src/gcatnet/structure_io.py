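"""PDB input/output and the normalized atomic model shared by all modules.

The in-memory model keeps only what the contact-network analysis needs:
standard amino-acid residues, heavy atoms, one conformer per atom.
Residues are keyed by *author* numbering — ``(chain, seqnum, icode)`` — so
positions keep the numbering a structural biologist would use (e.g. a PDZ
domain spanning residues 301-415), not a zero-based index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBIO import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

logger = logging.getLogger(__name__)

#: Three-letter → one-letter codes for the 20 standard amino acids.
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: Mapping[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA: str = "".join(sorted(ONE_TO_THREE))

#: Backbone atom names. Everything else on a residue is side chain.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

_RESID_RE = re.compile(r"^(?P<chain>[A-Za-z0-9])(?P<seqnum>-?\d+)(?P<icode>[A-Za-z]?)$")


class EmptyStructureError(ValueError):
    """No standard amino-acid residues remain after filtering."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbered residue identity: chain, sequence number, insertion code.

    Ordering is lexicographic by ``(chain, seqnum, icode)``.
    """

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}{self.seqnum}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueId":
        """Parse a compact identifier like ``"A301"`` or ``"A301B"``."""
        m = _RESID_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse residue id {text!r}")
        return cls(m["chain"], int(m["seqnum"]), m["icode"])


@dataclass
class AtomRecord:
    """One heavy atom: name, element, coordinates (Å), occupancy, altloc."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0, 1]")


@dataclass
class Residue:
    """A standard amino-acid residue with its heavy atoms."""

    id: ResidueId
    aa_type: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if self.aa_type not in ONE_TO_THREE:
            raise ValueError(f"{self.id}: unknown amino-acid code {self.aa_type!r}")
        if not self.atoms:
            raise ValueError(f"{self.id}: residue has no atoms")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of atomic coordinates."""
        return np.array([a.coords for a in self.atoms])

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.id}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """An ordered, duplicate-free collection of residues from one PDB model."""

    residues: list[Residue] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.residues = sorted(self.residues, key=lambda r: r.id)
        ids = [r.id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate residue ids in structure")
        self._index = {r.id: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._index

    def __getitem__(self, rid: ResidueId) -> Residue:
        return self._index[rid]

    @property
    def ids(self) -> list[ResidueId]:
        return [r.id for r in self.residues]

    def copy(self, label: str | None = None) -> "Structure":
        residues = [
            Residue(r.id, r.aa_type, [AtomRecord(a.name, a.element, a.coords.copy(), a.occupancy, a.altloc) for a in r.atoms])
            for r in self.residues
        ]
        return Structure(residues, self.label if label is None else label)


def _pick_conformer(atom):
    """Resolve a (possibly disordered) Biopython atom to one conformer.

    Highest occupancy wins; ties break on the alphabetically first altloc.
    """
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_pdb(
    path: str | Path,
    chains: Iterable[str] | None = None,
    include_hetero: bool = False,
    label: str | None = None,
) -> Structure:
    """Read a PDB file into a normalized :class:`Structure`.

    Keeps standard amino-acid residues of the selected ``chains`` (all chains
    when ``None``), heavy atoms only, one conformer per atom (highest
    occupancy, ties by altloc code). Waters and other hetero groups are
    dropped unless ``include_hetero`` is set, in which case hetero residues
    with a standard amino-acid name are kept too. Only the first model of a
    multi-model file is read.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EmptyStructureError
        If no standard residues remain after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chains = set(chains) if chains is not None else None

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())

    residues: list[Residue] = []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetflag, seqnum, icode = res.get_id()
            is_hetero = hetflag.strip() != ""
            if is_hetero and not include_hetero:
                continue
            resname = res.get_resname().strip()
            if resname not in THREE_TO_ONE:
                if not is_hetero:
                    logger.warning("skipping unknown residue %s %s%d", resname, chain.id, seqnum)
                continue
            atoms = []
            for atom in res.get_list():
                atom = _pick_conformer(atom)
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                occ = atom.get_occupancy()
                atoms.append(
                    AtomRecord(
                        name=atom.get_name(),
                        element=element,
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        occupancy=min(max(occ if occ is not None else 1.0, 0.0), 1.0),
                        altloc=atom.get_altloc().strip(),
                    )
                )
            if not atoms:
                continue
            rid = ResidueId(chain.id, seqnum, icode.strip())
            residues.append(Residue(rid, THREE_TO_ONE[resname], atoms))

    if not residues:
        raise EmptyStructureError(f"no standard amino-acid residues in {path} (chains={chains})")
    return Structure(residues, label if label is not None else path.stem)


def _to_biopdb(structure: Structure):
    """Convert to a Biopython entity (used for writing and for SASA)."""
    builder = StructureBuilder()
    builder.init_structure(structure.label or "s")
    builder.init_model(0)
    current_chain = None
    serial = 1
    for res in structure:
        if res.id.chain != current_chain:
            builder.init_chain(res.id.chain)
            current_chain = res.id.chain
        builder.init_seg("    ")
        builder.init_residue(ONE_TO_THREE[res.aa_type], " ", res.id.seqnum, res.id.icode or " ")
        for atom in res.atoms:
            builder.init_atom(
                atom.name,
                np.asarray(atom.coords, dtype=np.float32),
                0.0,
                atom.occupancy,
                atom.altloc or " ",
                atom.name.center(4) if len(atom.name) < 4 else atom.name,
                serial,
                atom.element or None,
            )
            serial += 1
    return builder.get_structure()


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as a PDB file; coordinates keep 3-decimal precision.

    Round-trip guarantee: ``read_pdb(write_pdb(s))`` reproduces residue ids,
    types and coordinates to 3 decimals.
    """
    if len(structure) == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    io = PDBIO()
    io.set_structure(_to_biopdb(structure))
    io.save(str(path))
    return path
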