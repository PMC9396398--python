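"""Parsing and representation of macromolecular structures and sequences.

Thin domain layer on top of Bio.PDB: structures are flattened into plain
dataclasses carrying author residue numbering (so residue 1202 in the file
is residue 1202 here), per-atom van der Waals radii from a configurable
table, and a polar/apolar flag used by the interface detectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Default van der Waals radii (Å), protein-atom set in the PISA/NACCESS family.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70  # fallback for unknown elements

#: Elements whose heavy atoms count as polar (H-bond capable chemistry).
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, modelled as Met
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """A single atom with coordinates and derived chemistry flags."""

    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float
    is_polar: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be > 0")


@dataclass
class Residue:
    """A residue keyed by author numbering, e.g. F1202 of the Nfasc peptide."""

    chain_id: str
    number: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    resname: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.aa}{self.number}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Residue {self.chain_id}/{self.label} ({len(self.atoms)} atoms)>"


@dataclass
class Structure:
    """Ordered chains of residues; hetero groups and waters kept separately."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hetero: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for residues in self.chains.values():
            for r in residues:
                if r.key in seen:
                    raise ValueError(f"duplicate residue key {r.key}")
                seen.add(r.key)

    def residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        ids = set(chain_ids) if chain_ids is not None else None
        for cid, residues in self.chains.items():
            if ids is None or cid in ids:
                yield from residues

    def atoms(self, chain_ids: Iterable[str] | None = None) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues(chain_ids):
            for atom in res.atoms:
                yield res, atom

    def select(
        self,
        chain_ids: Iterable[str] | None = None,
        residue_range: tuple[int, int] | None = None,
    ) -> "Structure":
        """Sub-structure restricted to chains and an author-number range."""
        out: dict[str, list[Residue]] = {}
        for res in self.residues(chain_ids):
            if residue_range is not None:
                lo, hi = residue_range
                if not (lo <= res.number <= hi):
                    continue
            out.setdefault(res.chain_id, []).append(res)
        return Structure(id=self.id, chains=out)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # 4-char names starting with a digit (e.g. 1HG1) are hydrogens
    if stripped[0].isdigit():
        return "H"
    if len(atom_name) == 4 and atom_name[0] not in (" ", ""):
        # two-letter element only if the first column is occupied in a 4-wide name
        cand = stripped[:2].upper()
        if cand in DEFAULT_VDW_RADII:
            return cand
    return stripped[0].upper()


def _radius_for(element: str, radii: dict[str, float]) -> float:
    try:
        return radii[element.upper()]
    except KeyError:
        log.warning("unknown element %r: using default radius %.2f Å", element, DEFAULT_RADIUS)
        return DEFAULT_RADIUS


def parse_structure(
    path: str | Path,
    format: str = "auto",
    radii: dict[str, float] | None = None,
    keep_waters: bool = False,
    keep_hetero: bool = False,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Author residue numbering is preserved verbatim.  Waters and hetero
    groups are excluded from chains by default (kept in ``Structure.hetero``).
    For alternate locations only the highest-occupancy conformer is kept.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension).
    radii:
        Van der Waals radii table overriding :data:`DEFAULT_VDW_RADII`.
    """
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")

    radii_table = dict(DEFAULT_VDW_RADII)
    if radii:
        radii_table.update({k.upper(): v for k, v in radii.items()})

    parser = PDBParser(QUIET=True) if format == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError, KeyError) as exc:
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc

    model = next(iter(bio_structure), None)
    if model is None:
        raise StructureParseError(f"{path}: no model records found")

    structure = Structure(id=path.stem)
    for bio_chain in model:
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            is_water = hetflag == "W" or resname == "HOH"
            is_het = hetflag.startswith("H_") and resname not in THREE_TO_ONE
            residue = Residue(
                chain_id=bio_chain.id,
                number=int(resseq),
                insertion_code=icode.strip(),
                aa=THREE_TO_ONE.get(resname, "X"),
                resname=resname,
            )
            for bio_atom in bio_res:
                # DisorderedAtom: Bio.PDB pre-selects the highest-occupancy altloc
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                element = (bio_atom.element or "").strip() or infer_element(bio_atom.get_fullname())
                residue.atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=element.upper(),
                        coord=np.array(bio_atom.coord, dtype=float),
                        vdw_radius=_radius_for(element, radii_table),
                        is_polar=element.upper() in POLAR_ELEMENTS,
                    )
                )
            if is_water:
                if keep_waters:
                    structure.hetero.append(residue)
            elif is_het:
                if keep_hetero:
                    structure.hetero.append(residue)
            else:
                structure.chains.setdefault(bio_chain.id, []).append(residue)

    if not structure.chains:
        raise StructureParseError(f"{path}: no polymer residues found")
    return structure


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a normalized PDB file (fixtures / round-trips only)."""
    ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
    lines: list[str] = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            resname = res.resname or ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:<3s} {chain_id:1s}"
                    f"{res.number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` pairs."""
    from Bio import SeqIO

    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
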