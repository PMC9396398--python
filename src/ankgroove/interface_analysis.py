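"""Solvent accessibility, buried area, hydrogen bonds and hydrophobic contacts.

SASA is computed with deterministic quasi-uniform sphere sampling (Fibonacci
lattice, no RNG) so results are exactly reproducible for a fixed point count.
Buried surface area of a two-component complex is the per-component SASA loss
on complexation; ``interface_area`` is half the two-sided sum (the common
interface-area convention).

Hydrogen bonds are detected geometrically.  The structure may or may not
carry hydrogens: with hydrogens present the D-H...A angle criterion is used,
otherwise the antecedent-donor-acceptor angle stands in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, Structure

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_HB_DISTANCE = 3.5
DEFAULT_HB_ANGLE_NOH = 90.0   # antecedent-donor-acceptor, no hydrogens in model
DEFAULT_HB_ANGLE_H = 120.0    # D-H...A, hydrogens present
DEFAULT_CONTACT_DISTANCE = 4.5

# ---------------------------------------------------------------------------
# donor / acceptor chemistry (heavy atoms, standard protein sidechains)

_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

SIDECHAIN_DONORS: dict[str, set[str]] = {
    "R": {"NE", "NH1", "NH2"},
    "K": {"NZ"},
    "W": {"NE1"},
    "H": {"ND1", "NE2"},
    "N": {"ND2"},
    "Q": {"NE2"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
    "C": {"SG"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "D": {"OD1", "OD2"},
    "E": {"OE1", "OE2"},
    "N": {"OD1"},
    "Q": {"OE1"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
    "H": {"ND1", "NE2"},
    "M": {"SD"},
    "C": {"SG"},
}

#: covalently bonded heavy-atom antecedent used for the no-hydrogen angle test
ANTECEDENT: dict[str, str] = {
    "N": "CA", "O": "C", "OXT": "C",
    "NE": "CD", "NH1": "CZ", "NH2": "CZ", "NZ": "CE", "NE1": "CD1",
    "ND1": "CG", "NE2": "CD2", "ND2": "CG", "OG": "CB", "OG1": "CB",
    "OH": "CZ", "SG": "CB", "OD1": "CG", "OD2": "CG", "OE1": "CD",
    "OE2": "CD", "SD": "CG",
}
# Gln NE2 antecedent differs from His NE2
_ANTECEDENT_BY_AA: dict[tuple[str, str], str] = {
    ("Q", "NE2"): "CD",
    ("H", "NE2"): "CD2",
    ("H", "ND1"): "CG",
}


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (Å²)."""

    per_atom: dict[tuple[tuple[str, int, str], str], float]
    per_residue: dict[tuple[str, int, str], float]
    total: float


@dataclass
class HBond:
    donor: tuple[Residue, Atom]
    acceptor: tuple[Residue, Atom]
    distance: float
    angle: float

    @property
    def label(self) -> str:
        d_res, d_atom = self.donor
        a_res, a_atom = self.acceptor
        return (
            f"{d_res.chain_id}/{d_res.label}:{d_atom.name}"
            f"--{a_res.chain_id}/{a_res.label}:{a_atom.name}"
        )


@dataclass
class ContactPair:
    residue_a: Residue
    residue_b: Residue
    min_heavy_atom_distance: float
    n_atom_pairs: int

    @property
    def label(self) -> str:
        return (
            f"{self.residue_a.chain_id}/{self.residue_a.label}"
            f"--{self.residue_b.chain_id}/{self.residue_b.label}"
        )


@dataclass
class InterfaceReport:
    bsa_component_a: float
    bsa_component_b: float
    hbonds: list[HBond] = field(default_factory=list)
    hydrophobic_contacts: list[ContactPair] = field(default_factory=list)

    @property
    def bsa_total(self) -> float:
        return self.bsa_component_a + self.bsa_component_b

    @property
    def interface_area(self) -> float:
        return self.bsa_total / 2.0


# ---------------------------------------------------------------------------
# SASA

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def compute_sasa(
    structure: Structure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    selection: Iterable[str] | None = None,
) -> SasaResult:
    """Shrake-Rupley-style SASA over the selected chains.

    Each atom's sphere of radius ``vdw + probe`` is sampled with ``n_points``
    lattice points; a point is accessible when outside every neighbouring
    expanded sphere.  Deterministic: no random number generation involved.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_points < 64:
        raise ValueError("n_points must be >= 64")

    items = list(structure.atoms(selection))
    if not items:
        raise ValueError("empty selection: no atoms to compute SASA for")

    coords = np.array([a.coord for _, a in items])
    radii = np.array([a.vdw_radius + probe_radius for _, a in items])
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom: dict[tuple[tuple[str, int, str], str], float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    total = 0.0

    for i, (res, atom) in enumerate(items):
        r_i = radii[i]
        pts = coords[i] + r_i * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], r_i + max_r) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        area = 4.0 * np.pi * r_i**2 * accessible.sum() / n_points
        per_atom[(res.key, atom.name)] = area
        per_residue[res.key] = per_residue.get(res.key, 0.0) + area
        total += area

    return SasaResult(per_atom=per_atom, per_residue=per_residue, total=total)


def buried_surface_area(
    structure: Structure,
    component_a: Iterable[str],
    component_b: Iterable[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> InterfaceReport:
    """Per-component SASA loss on complexation (areas only).

    ``bsa_component_x = SASA(x alone) - SASA(x within the complex)``.
    """
    set_a, set_b = set(component_a), set(component_b)
    if not set_a or not set_b:
        raise ValueError("both components must be non-empty")
    if set_a & set_b:
        raise ValueError(f"components overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(structure.chains)
    if missing:
        raise ValueError(f"chains not in structure: {sorted(missing)}")

    complex_sasa = compute_sasa(structure, probe_radius, n_points, selection=set_a | set_b)
    alone_a = compute_sasa(structure, probe_radius, n_points, selection=set_a)
    alone_b = compute_sasa(structure, probe_radius, n_points, selection=set_b)

    def _component_total(sasa: SasaResult, chains: set[str]) -> float:
        return sum(v for (key, _), v in sasa.per_atom.items() if key[0] in chains)

    bsa_a = alone_a.total - _component_total(complex_sasa, set_a)
    bsa_b = alone_b.total - _component_total(complex_sasa, set_b)
    return InterfaceReport(bsa_component_a=bsa_a, bsa_component_b=bsa_b)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _donor_atoms(res: Residue) -> list[Atom]:
    names = set(_BACKBONE_DONOR) | SIDECHAIN_DONORS.get(res.aa, set())
    if res.aa == "P":
        names -= {"N"}  # proline backbone N has no H
    return [a for a in res.atoms if a.name in names]


def _acceptor_atoms(res: Residue) -> list[Atom]:
    names = set(_BACKBONE_ACCEPTOR) | SIDECHAIN_ACCEPTORS.get(res.aa, set())
    return [a for a in res.atoms if a.name in names]


def _antecedent_atom(res: Residue, donor: Atom) -> Atom | None:
    name = _ANTECEDENT_BY_AA.get((res.aa, donor.name), ANTECEDENT.get(donor.name))
    return res.atom(name) if name else None


def _attached_hydrogens(res: Residue, donor: Atom, max_bond: float = 1.3) -> list[Atom]:
    out = []
    for a in res.atoms:
        if a.element == "H" and np.linalg.norm(a.coord - donor.coord) <= max_bond:
            out.append(a)
    return out


def _angle(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p1 - vertex, p2 - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hydrogen_bonds(
    structure: Structure,
    component_a: Iterable[str],
    component_b: Iterable[str],
    max_da_distance: float = DEFAULT_HB_DISTANCE,
    min_angle: float | None = None,
) -> list[HBond]:
    """Inter-component hydrogen bonds by distance + angle criteria.

    Donor-acceptor heavy-atom distance <= ``max_da_distance``; when the donor
    carries modelled hydrogens the D-H...A angle must reach ``min_angle``
    (default 120°), otherwise the antecedent-donor-acceptor angle must reach
    90° (or ``min_angle`` if given).  Both directions (a donates to b, b
    donates to a) are scanned; results sorted by donor residue number.
    """
    set_a, set_b = set(component_a), set(component_b)
    if set_a & set_b:
        raise ValueError("components overlap")

    res_a = list(structure.residues(set_a))
    res_b = list(structure.residues(set_b))

    bonds: list[HBond] = []
    for donors_side, acceptors_side in ((res_a, res_b), (res_b, res_a)):
        acc_items = [(r, a) for r in acceptors_side for a in _acceptor_atoms(r)]
        if not acc_items:
            continue
        acc_coords = np.array([a.coord for _, a in acc_items])
        tree = cKDTree(acc_coords)
        for d_res in donors_side:
            for d_atom in _donor_atoms(d_res):
                for j in tree.query_ball_point(d_atom.coord, max_da_distance):
                    a_res, a_atom = acc_items[j]
                    dist = float(np.linalg.norm(d_atom.coord - a_atom.coord))
                    hydrogens = _attached_hydrogens(d_res, d_atom)
                    if hydrogens:
                        threshold = DEFAULT_HB_ANGLE_H if min_angle is None else min_angle
                        angle = max(
                            _angle(d_atom.coord, h.coord, a_atom.coord) for h in hydrogens
                        )
                    else:
                        threshold = DEFAULT_HB_ANGLE_NOH if min_angle is None else min_angle
                        ante = _antecedent_atom(d_res, d_atom)
                        if ante is None:
                            angle = 180.0  # lone donor (fixture without antecedent)
                        else:
                            angle = _angle(ante.coord, d_atom.coord, a_atom.coord)
                    if angle >= threshold:
                        bonds.append(
                            HBond(donor=(d_res, d_atom), acceptor=(a_res, a_atom),
                                  distance=dist, angle=angle)
                        )
    bonds.sort(key=lambda b: (b.donor[0].number, b.donor[1].name, b.acceptor[0].number))
    return bonds


# ---------------------------------------------------------------------------
# hydrophobic contacts

def _apolar_atoms(res: Residue, include_sulfur: bool = False) -> list[Atom]:
    atoms = [a for a in res.atoms if a.element == "C"]
    if include_sulfur and res.aa in {"M", "C"}:
        atoms += [a for a in res.atoms if a.element == "S"]
    return atoms


def find_hydrophobic_contacts(
    structure: Structure,
    component_a: Iterable[str],
    component_b: Iterable[str],
    cutoff: float = DEFAULT_CONTACT_DISTANCE,
    include_sulfur: bool = False,
) -> list[ContactPair]:
    """Residue-level apolar contacts across the interface.

    A pair is reported when any two apolar heavy atoms (carbons; optionally
    Met/Cys sulfurs) from the two components lie within ``cutoff`` Å.
    """
    res_a = list(structure.residues(set(component_a)))
    res_b = list(structure.residues(set(component_b)))

    b_items = [(r, a) for r in res_b for a in _apolar_atoms(r, include_sulfur)]
    if not b_items:
        return []
    b_coords = np.array([a.coord for _, a in b_items])
    tree = cKDTree(b_coords)

    pairs: dict[tuple, ContactPair] = {}
    for r_a in res_a:
        apolar_a = _apolar_atoms(r_a, include_sulfur)
        for atom in apolar_a:
            for j in tree.query_ball_point(atom.coord, cutoff):
                r_b, atom_b = b_items[j]
                d = float(np.linalg.norm(atom.coord - atom_b.coord))
                key = (r_a.key, r_b.key)
                if key in pairs:
                    c = pairs[key]
                    c.n_atom_pairs += 1
                    c.min_heavy_atom_distance = min(c.min_heavy_atom_distance, d)
                else:
                    pairs[key] = ContactPair(
                        residue_a=r_a, residue_b=r_b,
                        min_heavy_atom_distance=d, n_atom_pairs=1,
                    )
    out = list(pairs.values())
    out.sort(key=lambda c: (c.residue_a.number, c.residue_b.number))
    return out


def analyze_interface(
    structure: Structure,
    component_a: Iterable[str],
    component_b: Iterable[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    hb_distance: float = DEFAULT_HB_DISTANCE,
    hb_angle: float | None = None,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
) -> InterfaceReport:
    """Full interface inventory: areas, hydrogen bonds, hydrophobic contacts."""
    report = buried_surface_area(structure, component_a, component_b, probe_radius, n_points)
    report.hbonds = find_hydrogen_bonds(structure, component_a, component_b, hb_distance, hb_angle)
    report.hydrophobic_contacts = find_hydrophobic_contacts(
        structure, component_a, component_b, contact_distance
    )
    return report
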