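"""Fixture generators with machine-readable ground truth.

Everything the pipeline consumes can be generated here with known answers:
periodic repeat sequences with controlled residue-class composition at the
layer positions, minimal two-residue coordinate sets realizing prescribed
hydrogen-bond / hydrophobic-contact geometries, two-sphere SASA fixtures
with the analytic cap-formula areas, and noisy one-site titrations
(delegating the isotherm itself to :mod:`ankgroove.itc_binding`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .itc_binding import OneSiteParams, TitrationExperiment, simulate_titration
from .preference_stats import DEFAULT_SCHEME, ResidueClassScheme
from .repeat_layers import (
    DEFAULT_PERIOD,
    LayerScheme,
    RepeatFrame,
    SequenceRecord,
    canonical_layer,
)
from .structure_io import Atom, Residue, Structure

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# idealized covalent geometry used by the coordinate fixtures
NH_BOND = 1.0
CO_BOND = 1.23
CA_N_BOND = 1.46


@dataclass
class LayerCompositionSpec:
    """Per-layer probability that the drawn residue is in-class."""

    probabilities: Mapping[str, float]
    n_repeats: int = 10
    seed: int = 0
    period: int = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        self.probabilities = {
            canonical_layer(k): float(v) for k, v in self.probabilities.items()
        }
        for layer, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {layer} must be in [0, 1], got {p}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class GeometryFixtureSpec:
    pair_type: str  # {"hbond", "hydrophobic", "none"}
    distance: float = 2.9
    angle: float = 165.0

    def __post_init__(self) -> None:
        if self.pair_type not in {"hbond", "hydrophobic", "none"}:
            raise ValueError(f"unknown pair type {self.pair_type!r}")
        if self.distance <= 0:
            raise ValueError("distance must be > 0")


@dataclass
class RepeatSequenceTruth:
    record: SequenceRecord
    frames: list[RepeatFrame]
    class_labels: dict[str, list[bool]] = field(default_factory=dict)
    # class_labels[layer][i]: whether repeat i's residue was drawn in-class

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein": self.record.protein_id,
                "frames": [
                    {"start": f.start, "period": f.period, "label": f.index}
                    for f in self.frames
                ],
                "class_labels": self.class_labels,
            },
            indent=2,
        )


def make_repeat_sequences(
    spec: LayerCompositionSpec,
    scheme: LayerScheme | None = None,
    class_scheme: ResidueClassScheme = DEFAULT_SCHEME,
    protein_id: str = "synthetic",
) -> RepeatSequenceTruth:
    """Periodic sequence with controlled class composition at layer positions.

    At each layer offset the residue is drawn uniformly from the layer's
    conventional class set with the given probability, and uniformly from
    the complement otherwise; all non-layer positions are uniform over the
    20 standard residues.
    """
    scheme = scheme if scheme is not None else LayerScheme.canonical()
    rng = np.random.default_rng(spec.seed)
    period = scheme.period
    seq = [rng.choice(list(AA20)) for _ in range(spec.n_repeats * period)]

    class_labels: dict[str, list[bool]] = {layer: [] for layer in spec.probabilities}
    for rep in range(spec.n_repeats):
        for layer, p in spec.probabilities.items():
            offset = scheme.offsets[layer]
            target = class_scheme.class_for(layer)
            in_class_set = sorted(getattr(class_scheme, target))
            out_class_set = sorted(set(AA20) - set(in_class_set))
            in_class = bool(rng.random() < p)
            pool = in_class_set if in_class else out_class_set
            seq[rep * period + offset] = rng.choice(pool)
            class_labels[layer].append(in_class)

    record = SequenceRecord(protein_id=protein_id, sequence="".join(seq), first_residue_number=1)
    frames = [
        RepeatFrame(protein_id=protein_id, start=1 + i * period, period=period, index=f"R{i+1}")
        for i in range(spec.n_repeats)
    ]
    return RepeatSequenceTruth(record=record, frames=frames, class_labels=class_labels)


# ---------------------------------------------------------------------------
# coordinate fixtures


def _residue(chain: str, number: int, aa: str, resname: str, atoms: list[Atom]) -> Residue:
    return Residue(chain_id=chain, number=number, aa=aa, resname=resname, atoms=atoms)


def _atom(name: str, element: str, coord, radius: float | None = None) -> Atom:
    from .structure_io import DEFAULT_VDW_RADII, DEFAULT_RADIUS, POLAR_ELEMENTS

    r = radius if radius is not None else DEFAULT_VDW_RADII.get(element, DEFAULT_RADIUS)
    return Atom(name=name, element=element, coord=np.asarray(coord, float),
                vdw_radius=r, is_polar=element in POLAR_ELEMENTS)


def make_geometry_fixture(spec: GeometryFixtureSpec) -> Structure:
    """Two residues in two chains realizing the requested pair geometry.

    hbond: backbone amide donor (chain B, Gly) against a backbone carbonyl
    acceptor (chain A, Gly) at the given N...O distance with the given
    antecedent(CA)-N...O angle.  hydrophobic: two Leu CD1 carbons at the
    given separation, polar atoms pushed out of H-bond range.  none: same
    as hydrophobic but meant to be placed beyond all cutoffs.
    """
    d = spec.distance
    if spec.pair_type == "hbond":
        if not (0.0 < spec.angle <= 180.0):
            raise ValueError("hbond angle must be in (0, 180]")
        # acceptor carbonyl at origin; C antecedent of O along -x
        acc = _residue("A", 1, "G", "GLY", [
            _atom("C", "C", [-CO_BOND, 0.0, 0.0]),
            _atom("O", "O", [0.0, 0.0, 0.0]),
            _atom("CA", "C", [-CO_BOND - 1.52, 0.0, 0.0]),
        ])
        # donor N at distance d along +x; CA placed to realize angle CA-N-O
        # acceptor direction from N is -x; put CA at the requested angle from it
        theta = np.pi - np.radians(spec.angle)
        n_pos = np.array([d, 0.0, 0.0])
        ca_pos = n_pos + CA_N_BOND * np.array([np.cos(theta), np.sin(theta), 0.0])
        don = _residue("B", 2, "G", "GLY", [
            _atom("N", "N", n_pos),
            _atom("CA", "C", ca_pos),
        ])
        return Structure(id="hbond_fixture", chains={"A": [acc], "B": [don]})

    # hydrophobic / none: Leu sidechain tips facing each other, backbones apart
    res_a = _residue("A", 1, "L", "LEU", [
        _atom("CD1", "C", [0.0, 0.0, 0.0]),
        _atom("CG", "C", [-1.53, 0.0, 0.0]),
        _atom("CB", "C", [-2.3, 1.3, 0.0]),
        _atom("CA", "C", [-3.8, 1.3, 0.0]),
        _atom("N", "N", [-4.5, 2.5, 0.0]),
        _atom("C", "C", [-4.5, 0.05, 0.0]),
        _atom("O", "O", [-5.7, 0.05, 0.0]),
    ])
    # mirror res_a through the plane x = d/2: CD1 tips face each other at
    # separation d while the polar backbone atoms sit ~ d + 9 A apart
    res_b = _residue("B", 2, "L", "LEU", [
        _atom(a.name, a.element, np.array([d - a.coord[0], a.coord[1], a.coord[2]]))
        for a in res_a.atoms
    ])
    return Structure(id=f"{spec.pair_type}_fixture", chains={"A": [res_a], "B": [res_b]})


@dataclass
class TwoSphereFixture:
    structure: Structure
    analytic_area_1: float
    analytic_area_2: float

    @property
    def analytic_total(self) -> float:
        return self.analytic_area_1 + self.analytic_area_2


def two_sphere_exposed_areas(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> tuple[float, float]:
    """Closed-form exposed areas of two probe-expanded intersecting spheres.

    With expanded radii ``R = r + probe``: disjoint spheres are fully
    exposed; a sphere engulfed by the other is fully buried; otherwise the
    spherical cap inside the partner (height ``h = R - x`` where ``x`` is
    the signed distance from the centre to the intersection plane) is
    removed: ``exposed = 4 pi R^2 - 2 pi R h``.
    """
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4.0 * np.pi * R1**2, 4.0 * np.pi * R2**2
    if d >= R1 + R2:
        return full1, full2
    if d <= abs(R1 - R2):
        # smaller sphere entirely inside the larger
        return (full1, 0.0) if R1 >= R2 else (0.0, full2)
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    x2 = d - x1
    h1, h2 = R1 - x1, R2 - x2
    return full1 - 2.0 * np.pi * R1 * h1, full2 - 2.0 * np.pi * R2 * h2


def make_two_sphere_fixture(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> TwoSphereFixture:
    """Two isolated atoms at separation ``d`` plus their analytic SASA.

    Full-overlap convention (d = 0, r1 = r2): the analytic areas assign the
    whole single-sphere area to atom 1 and zero to atom 2 (matching the
    engulfed-sphere branch, which keeps the larger/first sphere exposed).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    a1, a2 = two_sphere_exposed_areas(r1, r2, d, probe)
    res_a = _residue("A", 1, "X", "UNK", [_atom("X1", "C", [0.0, 0.0, 0.0], radius=r1)])
    res_b = _residue("B", 2, "X", "UNK", [_atom("X2", "C", [d, 0.0, 0.0], radius=r2)])
    structure = Structure(id="two_sphere", chains={"A": [res_a], "B": [res_b]})
    return TwoSphereFixture(structure=structure, analytic_area_1=a1, analytic_area_2=a2)


# ---------------------------------------------------------------------------
# titrations


def make_titration(
    kd: float = 0.22e-6,
    n: float = 1.0,
    dH: float = -8000.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    protocol: TitrationExperiment | None = None,
) -> tuple[TitrationExperiment, OneSiteParams]:
    """Noisy titration under the default protocol, truth returned alongside."""
    params = OneSiteParams(n=n, Ka=1.0 / kd, dH=dH)
    exp = simulate_titration(params, protocol=protocol, noise_sd=noise_sd, seed=seed)
    return exp, params


# ---------------------------------------------------------------------------
# bundle writer (CLI backend)


def write_fixture_bundle(kind: str, out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write a self-describing fixture set (data + truth JSON) to ``out_dir``."""
    from . import structure_io
    from .itc_binding import write_titration_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind == "repeats":
        spec = LayerCompositionSpec(
            probabilities={"phi1": 0.9, "phi2": 0.8, "rho1": 0.8, "rho2": 0.7},
            n_repeats=20, seed=seed,
        )
        truth = make_repeat_sequences(spec)
        fasta = out / "repeats.fasta"
        structure_io.write_fasta([(truth.record.protein_id, truth.record.sequence)], fasta)
        truth_path = out / "repeats_truth.json"
        truth_path.write_text(truth.to_json() + "\n")
        written += [fasta, truth_path]
    elif kind == "geometry":
        for name, spec in {
            "hbond": GeometryFixtureSpec("hbond", 2.9, 165.0),
            "hydrophobic": GeometryFixtureSpec("hydrophobic", 4.0),
            "none": GeometryFixtureSpec("none", 12.0),
        }.items():
            path = out / f"{name}.pdb"
            structure_io.write_pdb(make_geometry_fixture(spec), path)
            written.append(path)
        truth_path = out / "geometry_truth.json"
        truth_path.write_text(json.dumps(
            {"hbond": {"distance": 2.9, "angle": 165.0, "n_hbonds": 1},
             "hydrophobic": {"distance": 4.0, "n_contacts": 1},
             "none": {"distance": 12.0, "n_hbonds": 0, "n_contacts": 0}},
            indent=2) + "\n")
        written.append(truth_path)
    elif kind == "itc":
        exp, params = make_titration(seed=seed)
        csv_path = out / "titration.csv"
        write_titration_csv(exp, csv_path)
        truth_path = out / "titration_truth.json"
        truth_path.write_text(json.dumps(
            {"n": params.n, "Kd": params.Kd, "dH": params.dH,
             "noise_sd": 0.2, "seed": seed}, indent=2) + "\n")
        written += [csv_path, truth_path]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
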