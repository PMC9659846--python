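"""Saturation-mutagenesis design and mutant-structure providers.

The scan design is fixed: every position is mutated to each of the 19
non-wild-type standard amino acids, 19·N mutants for N residues. Mutant
structures come from one of two providers:

* ``load_external_mutants`` reads a directory of PDB files produced by an
  external mutator (FoldX-style naming) and validates the single-
  substitution and fixed-backbone contract.
* ``naive_mutate`` is a built-in geometric side-chain substitution engine:
  it swaps the side chain at the mutation site for an idealized template
  (CCD ideal coordinates) placed on the wild-type N/CA/C frame, copying the
  first side-chain torsion (chi-1) from the wild type when both types have
  one. It is a structural stand-in, not an energy model: no repacking, no
  minimization, and atoms outside the mutated side chain never move.
  Published GCAT results built on energy-minimized mutants are therefore
  not reproducible with this engine; it exists so the full pipeline runs
  and is testable without licensed third-party software.

``make_synthetic_structure`` builds reproducible pseudo-structures for
tests and examples.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure.info as _ccd

from gcatnet.structure_io import (
    BACKBONE_ATOMS,
    ONE_TO_THREE,
    STANDARD_AA,
    AtomRecord,
    Residue,
    ResidueId,
    Structure,
    read_pdb,
)

#: Atom defining the chi-1 torsion (N-CA-CB-*gamma*), by priority.
_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")

#: Default external-directory filename pattern: e.g. ``LA312G.pdb``
#: = Leu at chain A position 312 mutated to Gly (FoldX individual-list style).
DEFAULT_NAMING = (
    r"^(?P<from_aa>[A-Z])(?P<chain>[A-Za-z0-9])(?P<seqnum>-?\d+)(?P<to_aa>[A-Z])\.pdb$"
)


@dataclass(frozen=True, order=True)
class MutationSpec:
    """One point mutation: position, wild-type type, target type."""

    position: ResidueId
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.from_aa not in ONE_TO_THREE or self.to_aa not in ONE_TO_THREE:
            raise ValueError(f"non-standard amino acid in {self.from_aa}->{self.to_aa}")
        if self.from_aa == self.to_aa:
            raise ValueError(f"mutation at {self.position} must change the type")

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass
class MutantSet:
    """A wild type plus its single-point mutant structures.

    ``rejected`` and ``missing`` record validation failures / absent files
    for external providers; built-in providers leave them empty.
    """

    wildtype: Structure
    entries: dict[MutationSpec, Structure]
    provider: str
    rejected: list[tuple[str, str]] = field(default_factory=list)
    missing: list[MutationSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def coverage(self) -> dict[ResidueId, int]:
        """Number of available mutants per position (19 when complete)."""
        cov = {rid: 0 for rid in self.wildtype.ids}
        for spec in self.entries:
            cov[spec.position] += 1
        return cov


def enumerate_mutations(structure: Structure) -> list[MutationSpec]:
    """All 19·N mutation specs, ordered by (position, target type)."""
    if len(structure) == 0:
        raise ValueError("cannot enumerate mutations of an empty structure")
    specs = []
    for res in structure:
        for to_aa in STANDARD_AA:
            if to_aa != res.aa_type:
                specs.append(MutationSpec(res.id, res.aa_type, to_aa))
    return specs


# ---------------------------------------------------------------------------
# Naive side-chain substitution engine
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _template(aa: str) -> tuple[tuple[str, str], ...]:
    """Idealized heavy-atom template for a residue type.

    Returns ``((name, element), ...)`` paired with coordinates via
    :func:`_template_coords`; sourced from the Chemical Component
    Dictionary's ideal coordinates, hydrogens and the terminal OXT dropped.
    """
    arr = _ccd.residue(ONE_TO_THREE[aa])
    keep = [
        k
        for k in range(arr.array_length())
        if arr.element[k] not in ("H", "D") and arr.atom_name[k] != "OXT"
    ]
    return tuple((arr.atom_name[k], arr.element[k]) for k in keep)


@lru_cache(maxsize=None)
def _template_coords(aa: str) -> np.ndarray:
    arr = _ccd.residue(ONE_TO_THREE[aa])
    keep = [
        k
        for k in range(arr.array_length())
        if arr.element[k] not in ("H", "D") and arr.atom_name[k] != "OXT"
    ]
    return np.asarray(arr.coord[keep], dtype=float)


def _rigid_fit(src: np.ndarray, dst: np.ndarray):
    """Least-squares rigid transform mapping point set ``src`` onto ``dst``."""
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dst_c, src - src_c)

    def apply(points: np.ndarray) -> np.ndarray:
        return rot.apply(points - src_c) + dst_c

    return apply


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) of four points."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _gamma_atom(names: set[str]) -> str | None:
    for g in _GAMMA_ATOMS:
        if g in names:
            return g
    return None


def naive_mutate(wildtype: Structure, spec: MutationSpec) -> Structure:
    """Replace the side chain at ``spec.position`` with an idealized template.

    The backbone of every residue and all atoms of non-mutated residues are
    untouched. The template side chain is placed by superposing its N/CA/C
    frame onto the wild-type residue's N/CA/C; chi-1 is copied from the wild
    type when both the old and new types have one (glycine/alanine have
    none; proline's ring torsion is never copied). Fully deterministic.
    """
    if spec.position not in wildtype:
        raise KeyError(f"position {spec.position} not in wild type")
    wt_res = wildtype[spec.position]
    if wt_res.aa_type != spec.from_aa:
        raise ValueError(
            f"wild type has {wt_res.aa_type} at {spec.position}, spec says {spec.from_aa}"
        )
    for name in ("N", "CA", "C"):
        if not wt_res.has_atom(name):
            raise ValueError(f"{spec.position}: backbone atom {name} missing")

    wt_frame = np.array([wt_res.atom(n).coords for n in ("N", "CA", "C")])

    meta = _template(spec.to_aa)
    coords = _template_coords(spec.to_aa).copy()
    names = [m[0] for m in meta]
    t_idx = {n: k for k, n in enumerate(names)}
    t_frame = np.array([coords[t_idx[n]] for n in ("N", "CA", "C")])
    coords = _rigid_fit(t_frame, wt_frame)(coords)

    sidechain_idx = [k for k, n in enumerate(names) if n not in BACKBONE_ATOMS]

    # chi-1 copy: rotate distal side-chain atoms about the CA->CB axis.
    wt_names = {a.name for a in wt_res.atoms}
    wt_gamma = _gamma_atom(wt_names)
    new_gamma = _gamma_atom(set(names))
    copy_chi = (
        "P" not in (spec.from_aa, spec.to_aa)
        and wt_gamma is not None
        and "CB" in wt_names
        and new_gamma is not None
        and "CB" in t_idx
    )
    if copy_chi:
        n_xyz, ca_xyz = wt_frame[0], wt_frame[1]
        chi_wt = _dihedral(n_xyz, ca_xyz, wt_res.atom("CB").coords, wt_res.atom(wt_gamma).coords)
        cb_xyz = coords[t_idx["CB"]]
        chi_new = _dihedral(n_xyz, ca_xyz, cb_xyz, coords[t_idx[new_gamma]])
        axis = cb_xyz - ca_xyz
        axis = axis / np.linalg.norm(axis)
        spin = Rotation.from_rotvec(axis * (chi_wt - chi_new))
        distal = [k for k in sidechain_idx if names[k] != "CB"]
        coords[distal] = spin.apply(coords[distal] - cb_xyz) + cb_xyz

    # Assemble: wild-type backbone atoms in place, then the new side chain.
    new_atoms = [
        AtomRecord(a.name, a.element, a.coords.copy(), a.occupancy, a.altloc)
        for a in wt_res.atoms
        if a.name in BACKBONE_ATOMS
    ]
    for k in sidechain_idx:
        new_atoms.append(AtomRecord(names[k], meta[k][1], coords[k]))

    mutant = wildtype.copy(label=str(spec))
    mutated = mutant[spec.position]
    mutated.aa_type = spec.to_aa
    mutated.atoms = new_atoms
    return mutant


def naive_mutant_set(
    wildtype: Structure, specs: list[MutationSpec] | None = None
) -> MutantSet:
    """All (or the given) mutants of ``wildtype`` via the naive engine."""
    if specs is None:
        specs = enumerate_mutations(wildtype)
    entries = {spec: naive_mutate(wildtype, spec) for spec in specs}
    return MutantSet(wildtype, entries, provider="naive-engine")


# ---------------------------------------------------------------------------
# External mutant directories (FoldX-style output)
# ---------------------------------------------------------------------------

def load_external_mutants(
    wildtype: Structure,
    directory: str | Path,
    naming: str = DEFAULT_NAMING,
    backbone_tol: float = 0.0,
    chains: list[str] | None = None,
) -> MutantSet:
    """Read single-mutant PDBs from ``directory`` into a validated MutantSet.

    Filenames must match the ``naming`` regex, whose named groups
    ``from_aa``, ``chain``, ``seqnum`` (and optionally ``icode``, ``to_aa``)
    encode the mutation. Each file is checked against the contract: same
    residue-id set as the wild type, exactly one residue of changed type (at
    the encoded position), and backbone N/CA/C/O coordinates identical to
    the wild type within ``backbone_tol`` Å (0 = exact at file precision).
    Violating files are rejected and listed in ``MutantSet.rejected``;
    mutations with no file are listed in ``MutantSet.missing`` with a
    warning (partial sets are allowed).
    """
    directory = Path(directory)
    pattern = re.compile(naming)
    entries: dict[MutationSpec, Structure] = {}
    rejected: list[tuple[str, str]] = []

    for path in sorted(directory.iterdir()):
        if not path.is_file() or not path.name.endswith(".pdb"):
            continue
        m = pattern.match(path.name)
        if m is None:
            raise ValueError(f"filename {path.name!r} does not match naming pattern {naming!r}")
        groups = m.groupdict()
        rid = ResidueId(groups["chain"], int(groups["seqnum"]), groups.get("icode") or "")
        spec = MutationSpec(rid, groups["from_aa"], groups["to_aa"])
        structure = read_pdb(path, chains=chains, label=str(spec))
        reason = _validate_mutant(wildtype, structure, spec, backbone_tol)
        if reason is not None:
            rejected.append((path.name, reason))
            continue
        entries[spec] = structure

    expected = set(enumerate_mutations(wildtype))
    missing = sorted(expected - set(entries))
    if missing:
        warnings.warn(
            f"mutant directory {directory} is missing {len(missing)} of "
            f"{len(expected)} expected mutants (e.g. {missing[0]})",
            stacklevel=2,
        )
    if rejected:
        for name, reason in rejected:
            warnings.warn(f"rejected {name}: {reason}", stacklevel=2)
    return MutantSet(wildtype, entries, provider="external-dir", rejected=rejected, missing=missing)


def _validate_mutant(
    wildtype: Structure, mutant: Structure, spec: MutationSpec, backbone_tol: float
) -> str | None:
    """Return a rejection reason, or None if the mutant honors the contract."""
    if set(mutant.ids) != set(wildtype.ids):
        return "residue-id set differs from wild type"
    changed = [rid for rid in wildtype.ids if mutant[rid].aa_type != wildtype[rid].aa_type]
    if changed != [spec.position]:
        return f"substituted residues {[str(c) for c in changed]} != [{spec.position}]"
    if mutant[spec.position].aa_type != spec.to_aa:
        return (
            f"type at {spec.position} is {mutant[spec.position].aa_type}, expected {spec.to_aa}"
        )
    for rid in wildtype.ids:
        wt_res, mut_res = wildtype[rid], mutant[rid]
        for name in ("N", "CA", "C", "O"):
            if not (wt_res.has_atom(name) and mut_res.has_atom(name)):
                continue
            delta = np.abs(wt_res.atom(name).coords - mut_res.atom(name).coords).max()
            if delta > backbone_tol:
                return f"backbone atom {name} of {rid} moved by {delta:.4f} Å"
    return None


# ---------------------------------------------------------------------------
# Synthetic fixture structures
# ---------------------------------------------------------------------------

def make_synthetic_structure(
    n_residues: int,
    geometry: str = "chain-walk",
    seed: int = 0,
    spacing: float = 3.8,
    cluster_size: int = 8,
    cluster_gap: float = 40.0,
    chain: str = "A",
    start_seqnum: int = 1,
    aa_types: str | None = None,
) -> Structure:
    """Reproducible pseudo-structure for tests and examples.

    Each residue is an idealized full-heavy-atom template given a random
    orientation and anchored by its CA position. ``geometry`` controls CA
    placement:

    * ``"chain-walk"`` — a self-avoiding random walk with step ``spacing``
      (Å); consecutive residues are contact-network neighbors at the 5 Å
      cutoff, giving a connected chain with extra random contacts.
    * ``"cluster"`` — residues grouped into clusters of ``cluster_size`` on
      a local lattice with constant ``spacing``, cluster centers
      ``cluster_gap`` Å apart; yields isolated connected regions.

    Identical arguments (including ``seed``) produce bit-identical output.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    aa_pool = aa_types if aa_types is not None else STANDARD_AA
    types = [aa_pool[rng.integers(len(aa_pool))] for _ in range(n_residues)]

    if geometry == "chain-walk":
        ca = _walk_positions(n_residues, spacing, rng)
    elif geometry == "cluster":
        ca = _cluster_positions(n_residues, spacing, cluster_size, cluster_gap)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    residues = []
    for i, (aa, pos) in enumerate(zip(types, ca)):
        meta = _template(aa)
        coords = _template_coords(aa).copy()
        ca_idx = [m[0] for m in meta].index("CA")
        coords -= coords[ca_idx]
        rotvec = rng.normal(size=3)
        rotvec = rotvec / np.linalg.norm(rotvec) * rng.uniform(0, np.pi)
        coords = Rotation.from_rotvec(rotvec).apply(coords) + pos
        atoms = [AtomRecord(name, elem, xyz) for (name, elem), xyz in zip(meta, coords)]
        residues.append(Residue(ResidueId(chain, start_seqnum + i), aa, atoms))
    return Structure(residues, label=f"synthetic-{geometry}-{seed}")


def _walk_positions(n: int, step: float, rng: np.random.Generator) -> np.ndarray:
    positions = [np.zeros(3)]
    while len(positions) < n:
        for _ in range(200):
            direction = rng.normal(size=3)
            candidate = positions[-1] + direction / np.linalg.norm(direction) * step
            if all(np.linalg.norm(candidate - p) > 0.75 * step for p in positions[:-1]):
                break
        positions.append(candidate)
    return np.asarray(positions)


def _cluster_positions(n: int, spacing: float, cluster_size: int, gap: float) -> np.ndarray:
    side = int(np.ceil(cluster_size ** (1 / 3)))
    lattice = sorted(itertools.product(range(side + 1), repeat=3), key=lambda t: (sum(t), t))
    positions = []
    for i in range(n):
        center = np.array([(i // cluster_size) * gap, 0.0, 0.0])
        offset = spacing * np.asarray(lattice[i % cluster_size], dtype=float)
        positions.append(center + offset)
    return np.asarray(positions)
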