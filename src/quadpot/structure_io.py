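"""Read PDB files into Cα coarse-grained structures.

The potential and mutagenesis machinery operates on a one-point-per-residue
model: each residue is represented by its Cα coordinate, a one-letter amino
acid code, and a 3-state secondary-structure label (H helix, S strand,
C coil) taken from the PDB entry's HELIX/SHEET records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: one-letter codes, ascending alphabetical — the canonical 20-letter alphabet
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # nonstandard residues mapped onto the 20-letter alphabet
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine
}


@dataclass(frozen=True)
class Residue:
    """One coarse-grained residue: author numbering, identity, Cα, SS label."""

    seq_number: int
    aa: str
    ca_xyz: tuple[float, float, float]
    ss: str = "C"
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_number, self.icode)


@dataclass(frozen=True)
class ProteinStructure:
    """An ordered chain of Cα-represented residues."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (seq_number, icode) within chain")
        for r in self.residues:
            if r.aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino acid code {r.aa!r}")
            if r.ss not in "HSC":
                raise ValueError(f"invalid secondary-structure label {r.ss!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def positions(self) -> list[int]:
        """Author sequence numbers, in file order."""
        return [r.seq_number for r in self.residues]

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in Å, in file order."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def residue_at(self, seq_number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_number == seq_number and r.icode == icode:
                return r
        raise KeyError(f"no residue {seq_number}{icode!r} in chain {self.chain_id}")

    def index_of(self, seq_number: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.seq_number == seq_number and r.icode == icode:
                return i
        raise KeyError(f"no residue {seq_number}{icode!r} in chain {self.chain_id}")


def _load_gemmi(pdb_text_or_path: str | Path) -> gemmi.Structure:
    s = str(pdb_text_or_path)
    if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "HEADER", "HELIX",
                                           "SHEET", "MODEL", "REMARK", "CRYST1")):
        return gemmi.read_pdb_string(s)
    return gemmi.read_structure(s, format=gemmi.CoorFormat.Pdb)


def _pick_ca(res: gemmi.Residue) -> gemmi.Atom | None:
    """Cα after altloc resolution: highest occupancy, ties → first in file."""
    best = None
    for atom in res:
        if atom.name != "CA" or atom.element.name not in ("C", ""):
            continue
        if best is None or atom.occ > best.occ + 1e-9:
            best = atom
    return best


def read_structure(pdb_text_or_path: str | Path, chain_id: str | None = None,
                   assign_ss: bool = True) -> ProteinStructure:
    """Parse one chain of a PDB entry into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text_or_path
        PDB file path or the raw text of a PDB entry.
    chain_id
        Chain to extract; ``None`` selects the first chain in the file.
    assign_ss
        Label residues H/S/C from the entry's HELIX/SHEET records
        (default); otherwise every residue is labeled C.

    Raises
    ------
    ValueError
        If the chain is missing or holds fewer than 4 Cα residues
        (a tessellation needs at least one tetrahedron).
    """
    st = _load_gemmi(pdb_text_or_path)
    if len(st) == 0:
        raise ValueError("PDB input contains no model")
    model = st[0]
    if chain_id is None:
        if len(model) == 0:
            raise ValueError("PDB input contains no chain")
        chain = model[0]
        chain_id = chain.name
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise ValueError(f"chain {chain_id!r} not found in PDB input")

    residues: list[Residue] = []
    seen: set[tuple[int, str]] = set()
    for res in chain:
        aa = _THREE_TO_ONE.get(res.name)
        if aa is None:
            if res.is_amino_acid():
                logger.warning("dropping nonstandard residue %s %d%s",
                               res.name, res.seqid.num, res.seqid.icode.strip())
            continue
        ca = _pick_ca(res)
        if ca is None:
            logger.warning("dropping residue %s %d: no CA atom",
                           res.name, res.seqid.num)
            continue
        key = (res.seqid.num, res.seqid.icode.strip())
        if key in seen:  # altloc split across residue records
            continue
        seen.add(key)
        residues.append(Residue(seq_number=res.seqid.num, aa=aa,
                                ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                                icode=key[1]))
    if len(residues) < 4:
        raise ValueError(
            f"chain {chain_id!r} has {len(residues)} Cα residues; "
            "at least 4 are required for tessellation")
    structure = ProteinStructure(chain_id=chain_id, residues=tuple(residues))
    if assign_ss:
        structure = assign_secondary_structure(structure, st)
    return structure


def _record_ranges(st: gemmi.Structure, chain_id: str
                   ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    helices, sheets = [], []
    for h in st.helices:
        if h.start.chain_name == chain_id:
            helices.append((h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain_id:
                sheets.append((strand.start.res_id.seqid.num,
                               strand.end.res_id.seqid.num))
    return helices, sheets


def assign_secondary_structure(
    structure: ProteinStructure,
    pdb_source: str | Path | gemmi.Structure | None = None,
    labels: dict[int, str] | None = None,
) -> ProteinStructure:
    """Attach H/S/C labels from HELIX/SHEET records or an external map.

    Residues within a HELIX range become H, within a SHEET strand range S,
    and everything else C. ``labels`` (seq_number → H/S/C) overrides record
    lookup and supports external assignments (e.g. a DSSP run reduced to
    3 states). With no records and no labels, all residues are C and a
    warning is logged.
    """
    if labels is not None:
        new = tuple(replace(r, ss=labels.get(r.seq_number, "C"))
                    for r in structure.residues)
        return ProteinStructure(structure.chain_id, new)
    if pdb_source is None:
        raise ValueError("either pdb_source or labels is required")
    st = pdb_source if isinstance(pdb_source, gemmi.Structure) \
        else _load_gemmi(pdb_source)
    helices, sheets = _record_ranges(st, structure.chain_id)
    if not helices and not sheets:
        logger.warning("no HELIX/SHEET records for chain %s: all residues "
                       "labeled C", structure.chain_id)

    def label(num: int) -> str:
        if any(a <= num <= b for a, b in helices):
            return "H"
        if any(a <= num <= b for a, b in sheets):
            return "S"
        return "C"

    new = tuple(replace(r, ss=label(r.seq_number)) for r in structure.residues)
    return ProteinStructure(structure.chain_id, new)


def write_pdb(structure: ProteinStructure) -> str:
    """Render a structure as minimal PDB text (CA-only ATOM records)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if k not in ("MSE", "SEC")}
    lines = []
    for i, r in enumerate(structure.residues, start=1):
        x, y, z = r.ca_xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {one_to_three[r.aa]} {structure.chain_id:1.1s}"
            f"{r.seq_number:4d}{r.icode:1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C")
    lines.append("END")
    return "\n".join(lines) + "\n"


def structure_table(structure: ProteinStructure) -> "pd.DataFrame":
    """Tabular view (seq_number, aa, x, y, z, ss) used by the CLI."""
    import pandas as pd

    return pd.DataFrame(
        {"seq_number": [r.seq_number for r in structure.residues],
         "aa": list(structure.sequence),
         "x": structure.coords[:, 0],
         "y": structure.coords[:, 1],
         "z": structure.coords[:, 2],
         "ss": [r.ss for r in structure.residues]})
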