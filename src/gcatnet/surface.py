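"""Relative accessible surface area (rASA) and surface-exposed/buried calls.

Absolute per-residue ASA is computed with a rolling-probe method (Shrake-
Rupley by default, probe radius 1.4 Å; an external DSSP binary can be used
instead when available) and normalized by a published per-residue-type
maximum (Sander-Rost by default; Wilke/Tien or Miller scales selectable).
A residue is surface exposed (SE) iff rASA > threshold, strictly; the
default threshold is 0.2.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio.PDB.DSSP import DSSP, residue_max_acc
from Bio.PDB.SASA import ShrakeRupley

from gcatnet.structure_io import ONE_TO_THREE, ResidueId, Structure, _to_biopdb, write_pdb

#: Published maximum-ASA reference sets (Å²) keyed by scale name.
MAX_ASA_SCALES = residue_max_acc

SE = "SE"
BURIED = "buried"


@dataclass
class RasaTable:
    """Per-residue rASA fractions plus the SE/buried threshold."""

    values: dict[ResidueId, float]
    threshold: float = 0.2
    scale: str = "Sander"
    backend: str = "shrake-rupley"

    def __post_init__(self) -> None:
        bad = [str(r) for r, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative rASA for {bad}")

    def classification(self, rid: ResidueId) -> str:
        return SE if self.values[rid] > self.threshold else BURIED


def compute_rasa(
    structure: Structure,
    max_asa_scale: str = "Sander",
    threshold: float = 0.2,
    backend: str = "shrake-rupley",
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> RasaTable:
    """Compute per-residue rASA for ``structure``.

    rASA = (absolute ASA of the residue) / (reference maximum ASA for its
    type). Values may exceed 1 for highly exposed residues and are not
    clamped.

    ``backend`` is ``"shrake-rupley"`` (pure-Python rolling probe, default)
    or ``"dssp"`` (requires the ``mkdssp`` executable on PATH; this is the
    backend whose absolute ASA values published DSSP-based analyses use).
    """
    if len(structure) == 0:
        raise ValueError("cannot compute rASA of an empty structure")
    try:
        scale = MAX_ASA_SCALES[max_asa_scale]
    except KeyError:
        raise ValueError(
            f"unknown max-ASA scale {max_asa_scale!r}; choose from {sorted(MAX_ASA_SCALES)}"
        ) from None
    for res in structure:
        if ONE_TO_THREE[res.aa_type] not in scale:
            raise ValueError(f"no reference maximum ASA for residue {res.id} ({res.aa_type})")

    if backend == "shrake-rupley":
        asa = _asa_shrake_rupley(structure, probe_radius, n_points)
    elif backend == "dssp":
        asa = _asa_dssp(structure)
    else:
        raise ValueError(f"unknown ASA backend {backend!r}")

    values = {
        res.id: asa[res.id] / scale[ONE_TO_THREE[res.aa_type]] for res in structure
    }
    return RasaTable(values, threshold=threshold, scale=max_asa_scale, backend=backend)


def _asa_shrake_rupley(structure: Structure, probe_radius: float, n_points: int) -> dict[ResidueId, float]:
    model = next(_to_biopdb(structure).get_models())
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(model, level="R")
    out: dict[ResidueId, float] = {}
    for chain in model:
        for res in chain:
            _, seqnum, icode = res.get_id()
            out[ResidueId(chain.id, seqnum, icode.strip())] = float(res.sasa)
    return out


def _asa_dssp(structure: Structure) -> dict[ResidueId, float]:
    # DSSP reports relative accessibility (normalized by the Sander maxima);
    # convert back to absolute Å² so one normalization path serves both backends.
    sander = MAX_ASA_SCALES["Sander"]
    model = next(_to_biopdb(structure).get_models())
    with tempfile.TemporaryDirectory() as tmp:
        pdb_path = Path(tmp) / "model.pdb"
        write_pdb(structure, pdb_path)
        dssp = DSSP(model, str(pdb_path), acc_array="Sander")
        out: dict[ResidueId, float] = {}
        for key in dssp.keys():
            chain_id, (_, seqnum, icode) = key
            record = dssp[key]
            rel_asa, resname = record[3], record[1]
            if rel_asa == "NA":
                continue
            three = ONE_TO_THREE.get(resname, None)
            if three is None:
                continue
            out[ResidueId(chain_id, seqnum, icode.strip())] = float(rel_asa) * sander[three]
    missing = set(structure.ids) - set(out)
    if missing:
        raise RuntimeError(f"DSSP returned no ASA for {sorted(map(str, missing))}")
    return out


def classify_se(rasa: RasaTable) -> dict[ResidueId, str]:
    """Map every residue to ``"SE"`` (rASA > threshold, strictly) or ``"buried"``."""
    if not rasa.values:
        raise ValueError("empty rASA table")
    return {rid: rasa.classification(rid) for rid in rasa.values}


def rasa_table_frame(rasa: RasaTable):
    """CSV-ready table: residue id, rASA, SE/buried flag."""
    import pandas as pd

    rows = [
        {"residue_id": str(rid), "rasa": rasa.values[rid], "class": rasa.classification(rid)}
        for rid in sorted(rasa.values)
    ]
    return pd.DataFrame(rows)
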