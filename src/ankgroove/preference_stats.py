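"""Residue-class composition at the inner-groove layer positions.

The statistic of interest: the fraction of hydrophobic residues at the two
hydrophobic layer positions (phi1, phi2) and of polar residues at the two
polar positions (rho1, rho2), compared across cohorts (target-binding
repeats, all ANK repeats, whole-proteome background), with a one-sided
exact binomial enrichment test against the background fraction.

Class membership follows the study's convention: hydrophobic
A/C/F/I/L/M/V/W/Y, polar D/E/H/K/N/Q/R/S/T; everything else (G, P,
non-standard letters) is "neither".  Note Y and C sit in the hydrophobic
set here even though other schemes call them polar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .repeat_layers import LayerAssignment, canonical_layer

HYDROPHOBIC = frozenset("ACFILMVWY")
POLAR = frozenset("DEHKNQRST")


@dataclass(frozen=True)
class ResidueClassScheme:
    hydrophobic: frozenset[str] = HYDROPHOBIC
    polar: frozenset[str] = POLAR

    def __post_init__(self) -> None:
        if self.hydrophobic & self.polar:
            raise ValueError(
                f"classes overlap: {sorted(self.hydrophobic & self.polar)}"
            )

    @property
    def neither(self) -> frozenset[str]:
        standard = frozenset("ACDEFGHIKLMNPQRSTVWY")
        return standard - self.hydrophobic - self.polar

    def class_for(self, layer: str) -> str:
        """Target class conventionally scored at a layer position."""
        return "hydrophobic" if canonical_layer(layer) in ("phi1", "phi2") else "polar"


DEFAULT_SCHEME = ResidueClassScheme()


@dataclass
class EnrichmentResult:
    position: str
    k: int
    n: int
    p0: float
    p_value: float


@dataclass
class PreferenceTable:
    """Per (layer x cohort) class counts and fractions."""

    rows: list[dict] = field(default_factory=list)
    # row: {"position", "cohort", "k", "n", "fraction", "p_value" (optional)}

    def to_tsv(self) -> str:
        lines = ["position\tcohort\tk\tn\tfraction\tp_value"]
        for r in self.rows:
            p = f"{r['p_value']:.3g}" if r.get("p_value") is not None else "NA"
            lines.append(
                f"{r['position']}\t{r['cohort']}\t{r['k']}\t{r['n']}\t{r['fraction']:.4f}\t{p}"
            )
        return "\n".join(lines) + "\n"


def classify_residue(aa: str, scheme: ResidueClassScheme = DEFAULT_SCHEME) -> str:
    """Classify a one-letter code as hydrophobic / polar / neither."""
    if len(aa) != 1:
        raise ValueError(f"expected a single letter, got {aa!r}")
    aa = aa.upper()
    if aa in scheme.hydrophobic:
        return "hydrophobic"
    if aa in scheme.polar:
        return "polar"
    if aa not in "ACDEFGHIKLMNPQRSTVWY":
        warnings.warn(f"non-standard residue letter {aa!r} classified as neither")
    return "neither"


def layer_fraction(
    assignments: Iterable[LayerAssignment],
    position: str,
    target_class: str = None,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
) -> tuple[int, int, float]:
    """(k, n, fraction) of in-class residues at one layer position.

    Pools all assignments; absent positions are excluded from ``n``.
    ``target_class`` defaults to the class conventionally scored at that
    position (hydrophobic for phi, polar for rho).
    """
    position = canonical_layer(position)
    if target_class is None:
        target_class = scheme.class_for(position)
    residues = [aa for a in assignments for (_, aa) in a.residues_at(position)]
    if not residues:
        raise ValueError(f"no residues assigned at {position}")
    k = sum(1 for aa in residues if classify_residue(aa, scheme) == target_class)
    n = len(residues)
    return k, n, k / n


def proteome_background(
    sequences: Sequence[tuple[str, str]],
    target_class: str = "hydrophobic",
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
) -> float:
    """Residue-weighted in-class fraction over all positions of all records."""
    if not sequences:
        raise ValueError("no sequences supplied")
    class_set = getattr(scheme, target_class) if target_class != "neither" else scheme.neither
    k = total = 0
    for _, seq in sequences:
        seq = seq.upper()
        total += len(seq)
        k += sum(1 for aa in seq if aa in class_set)
    if total == 0:
        raise ValueError("sequences are empty")
    return k / total


def enrichment_test(k: int, n: int, p0: float) -> EnrichmentResult:
    """One-sided exact binomial tail P(X >= k | n, p0)."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"background fraction must be in (0, 1), got {p0}")
    p_value = float(stats.binom.sf(k - 1, n, p0))
    # tail probabilities below the smallest subnormal underflow to 0.0;
    # clamp so the contract p in (0, 1] holds
    p_value = max(p_value, float(np.finfo(float).smallest_subnormal))
    return EnrichmentResult(position="", k=k, n=n, p0=p0, p_value=p_value)


def build_preference_table(
    cohorts: dict[str, list[LayerAssignment]],
    background_fraction: dict[str, float] | None = None,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    positions: Sequence[str] = ("phi1", "phi2", "rho1", "rho2"),
) -> PreferenceTable:
    """Assemble the per-position, per-cohort table with optional enrichment.

    ``background_fraction`` maps class name -> proteome fraction; when given,
    each cohort row carries the one-sided binomial p-value against it.
    """
    table = PreferenceTable()
    for position in positions:
        position = canonical_layer(position)
        target_class = scheme.class_for(position)
        for cohort_name, assignments in cohorts.items():
            k, n, fraction = layer_fraction(assignments, position, target_class, scheme)
            p_value = None
            if background_fraction and target_class in background_fraction:
                p0 = background_fraction[target_class]
                p_value = enrichment_test(k, n, p0).p_value
            table.rows.append(
                {"position": position, "cohort": cohort_name, "k": k, "n": n,
                 "fraction": fraction, "p_value": p_value}
            )
        if background_fraction and target_class in background_fraction:
            p0 = background_fraction[target_class]
            table.rows.append(
                {"position": position, "cohort": "proteome_background", "k": 0,
                 "n": 0, "fraction": p0, "p_value": None}
            )
    return table
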