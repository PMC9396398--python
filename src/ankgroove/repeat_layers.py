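"""ANK-repeat frames and the four inner-groove layer positions.

An ANK repeat is modelled as a frame of fixed period (default 33 residues)
anchored at the hairpin-tip hydrophobic position ("phi1").  The other three
inner-groove positions are expressed as offsets from that anchor:

    phi1  hairpin tip            offset  0   (hydrophobic layer)
    phi2  helix-A belly          offset +5   (hydrophobic layer)
    rho2  helix-A bottom         offset +8   (polar layer)
    rho1  inter-repeat upper loop offset +31 (polar layer)

Offsets are not hard-coded: :func:`derive_layer_offsets` recovers them from
lists of annotated residue numbers, and the canonical values above are what
it returns for the AnkG R8-R14 annotation shipped in ``data/``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import gcd
from pathlib import Path
from typing import Iterable, Mapping, Sequence

LAYER_NAMES = ("phi1", "phi2", "rho2", "rho1")
DEFAULT_PERIOD = 33

#: aliases accepted in user-facing inputs (JSON keys, CLI)
_LAYER_ALIASES = {
    "phi1": "phi1", "Φ1": "phi1", "f1": "phi1",
    "phi2": "phi2", "Φ2": "phi2", "f2": "phi2",
    "rho1": "rho1", "ρ1": "rho1", "r1": "rho1",
    "rho2": "rho2", "ρ2": "rho2", "r2": "rho2",
}


def canonical_layer(name: str) -> str:
    try:
        return _LAYER_ALIASES[name]
    except KeyError:
        raise ValueError(f"unknown layer name {name!r}") from None


class FrameError(ValueError):
    """Inconsistent repeat-frame or layer annotation."""


@dataclass(frozen=True)
class RepeatFrame:
    """One repeat's frame: origin (phi1 anchor, author numbering) + period."""

    protein_id: str
    start: int
    period: int = DEFAULT_PERIOD
    index: str = ""

    def __post_init__(self) -> None:
        if not (30 <= self.period <= 36):
            raise FrameError(f"period {self.period} outside [30, 36]")


@dataclass(frozen=True)
class LayerScheme:
    """Layer offsets relative to the frame origin, plus the common period."""

    offsets: Mapping[str, int]
    period: int = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        offs = dict(self.offsets)
        if len(set(offs.values())) != len(offs):
            raise FrameError("layer offsets must be distinct")
        for layer, off in offs.items():
            if not (0 <= off < self.period):
                raise FrameError(f"offset {layer}={off} outside [0, {self.period})")
        object.__setattr__(self, "offsets", offs)

    @classmethod
    def canonical(cls) -> "LayerScheme":
        """The scheme derived from the AnkG annotation (period 33)."""
        return cls(offsets={"phi1": 0, "phi2": 5, "rho2": 8, "rho1": 31}, period=33)


@dataclass
class SequenceRecord:
    """A protein sequence with author numbering of its first residue."""

    protein_id: str
    sequence: str
    first_residue_number: int = 1

    def residue(self, number: int) -> str | None:
        idx = number - self.first_residue_number
        if 0 <= idx < len(self.sequence):
            return self.sequence[idx]
        return None


@dataclass
class LayerAssignment:
    """Per-repeat residues at each layer position; None marks absent."""

    protein_id: str
    source: str  # "sequence" or "structure"
    rows: list[dict] = field(default_factory=list)
    # each row: {"index": "R8", "start": 277,
    #            "layers": {"phi1": (277, "I") or None, ...}}

    def residues_at(self, layer: str) -> list[tuple[int, str]]:
        layer = canonical_layer(layer)
        out = []
        for row in self.rows:
            entry = row["layers"].get(layer)
            if entry is not None:
                out.append(entry)
        return out


# ---------------------------------------------------------------------------

def derive_layer_offsets(residue_lists: Mapping[str, Sequence[int]]) -> LayerScheme:
    """Recover period and per-layer offsets from annotated residue numbers.

    Each layer's residue numbers must form an arithmetic-progression-like
    series with a common spacing; the period is the GCD of all consecutive
    spacings and the offsets are taken modulo the period, anchored so that
    phi1 has offset 0.
    """
    lists = {canonical_layer(k): sorted(v) for k, v in residue_lists.items()}
    if "phi1" not in lists or not lists["phi1"]:
        raise FrameError("phi1 residue list required as the anchor layer")

    # infer the period from the anchor layer's spacings, so a single
    # phase-shifted annotation elsewhere is reported as the offender rather
    # than silently collapsing the GCD
    period = 0
    for a, b in zip(lists["phi1"], lists["phi1"][1:]):
        period = gcd(period, b - a)
    if period == 0:
        for layer, numbers in lists.items():
            for a, b in zip(numbers, numbers[1:]):
                period = gcd(period, b - a)
    if period == 0:
        raise FrameError("need at least two residues in some layer to infer a period")
    if not (30 <= period <= 36):
        raise FrameError(f"inferred period {period} outside the ANK range [30, 36]")

    anchor = lists["phi1"][0]
    offsets: dict[str, int] = {}
    offenders: list[str] = []
    for layer, numbers in lists.items():
        offs = {(n - anchor) % period for n in numbers}
        if len(offs) != 1:
            offenders.extend(f"{layer}:{n}" for n in numbers)
            continue
        offsets[layer] = offs.pop()
    if offenders:
        raise FrameError(f"phase-inconsistent annotations: {', '.join(offenders)}")
    return LayerScheme(offsets=offsets, period=period)


def assign_frames(
    target: SequenceRecord,
    boundaries: Sequence[int] | None = None,
    period: int = DEFAULT_PERIOD,
    first_label: str = "R1",
    motif_scan: bool = False,
) -> list[RepeatFrame]:
    """Enumerate repeat frames over a sequence.

    Either explicit ``boundaries`` (strictly increasing phi1-anchor residue
    numbers) are supplied, or ``motif_scan=True`` detects the dominant exact
    periodicity of the sequence (suitable for engineered/synthetic repeat
    proteins; no external repeat profile is used).
    """
    if boundaries is None and not motif_scan:
        raise ValueError("supply explicit boundaries or set motif_scan=True")

    if boundaries is not None:
        if any(b >= c for b, c in zip(boundaries, boundaries[1:])):
            raise FrameError("boundaries must be strictly increasing")
        last = target.first_residue_number + len(target.sequence) - 1
        for b in boundaries:
            if not (target.first_residue_number <= b <= last):
                raise FrameError(f"boundary {b} outside sequence [{target.first_residue_number}, {last}]")
        starts = list(boundaries)
    else:
        starts = _scan_periodicity(target, period_range=(30, 36))

    base = _parse_label_index(first_label)
    return [
        RepeatFrame(protein_id=target.protein_id, start=s,
                    period=(starts[i + 1] - s) if i + 1 < len(starts) and 30 <= starts[i + 1] - s <= 36 else period,
                    index=f"R{base + i}")
        for i, s in enumerate(starts)
    ]


def _parse_label_index(label: str) -> int:
    if label.upper().startswith("R") and label[1:].isdigit():
        return int(label[1:])
    raise ValueError(f"repeat label {label!r} not of the form R<n>")


def _scan_periodicity(target: SequenceRecord, period_range: tuple[int, int]) -> list[int]:
    """Find the period maximizing exact self-similarity, phase 0 frames."""
    seq = target.sequence
    best_p, best_score = None, -1.0
    for p in range(period_range[0], period_range[1] + 1):
        if len(seq) < 2 * p:
            continue
        matches = sum(1 for i in range(len(seq) - p) if seq[i] == seq[i + p])
        score = matches / (len(seq) - p)
        if score > best_score:
            best_p, best_score = p, score
    if best_p is None:
        raise FrameError("sequence too short for periodicity scan")
    n_frames = len(seq) // best_p
    return [target.first_residue_number + i * best_p for i in range(n_frames)]


def extract_layers(
    frames: Sequence[RepeatFrame],
    scheme: LayerScheme,
    target: SequenceRecord,
    source: str = "sequence",
) -> LayerAssignment:
    """Read off the residue at each layer position of each frame.

    Positions outside the sequence (truncated terminal repeats) are marked
    absent (``None``), never guessed.
    """
    assignment = LayerAssignment(protein_id=target.protein_id, source=source)
    for frame in frames:
        layers: dict[str, tuple[int, str] | None] = {}
        for layer, offset in scheme.offsets.items():
            number = frame.start + offset
            aa = target.residue(number)
            layers[layer] = (number, aa) if aa is not None else None
        assignment.rows.append({"index": frame.index, "start": frame.start, "layers": layers})
    return assignment


# ---------------------------------------------------------------------------
# built-in annotation

def load_builtin_annotation(name: str = "ankg_inner_groove") -> dict:
    """Load a packaged inner-groove annotation.

    Returns a dict with keys ``record`` (a :class:`SequenceRecord` whose
    unannotated positions are 'X'), ``frames`` (list of
    :class:`RepeatFrame`), and ``layer_lists`` (layer -> sorted residue
    numbers, usable directly by :func:`derive_layer_offsets`).
    """
    from importlib.resources import files

    payload = json.loads(files("ankgroove.data").joinpath(f"{name}.json").read_text())
    first = payload["first_residue_number"]
    last = payload["last_residue_number"]
    seq = ["X"] * (last - first + 1)
    for table in payload["layers"].values():
        for number, aa in table.items():
            seq[int(number) - first] = aa
    record = SequenceRecord(
        protein_id=payload["protein"], sequence="".join(seq), first_residue_number=first
    )
    frames = [
        RepeatFrame(protein_id=payload["protein"], start=f["start"],
                    period=f.get("period", DEFAULT_PERIOD), index=f["label"])
        for f in payload["frames"]
    ]
    layer_lists = {
        canonical_layer(layer): sorted(int(n) for n in table)
        for layer, table in payload["layers"].items()
    }
    return {"record": record, "frames": frames, "layer_lists": layer_lists}


# ---------------------------------------------------------------------------
# serialization

def load_frames_json(path: str | Path) -> tuple[str, list[RepeatFrame]]:
    """Read ``{"protein": ..., "frames": [{"start":..,"period":..,"label":..}]}``."""
    payload = json.loads(Path(path).read_text())
    protein = payload["protein"]
    frames = [
        RepeatFrame(protein_id=protein, start=int(f["start"]),
                    period=int(f.get("period", DEFAULT_PERIOD)), index=f.get("label", f"R{i+1}"))
        for i, f in enumerate(payload["frames"])
    ]
    _check_frame_order(frames)
    return protein, frames


def load_frames_tsv(path: str | Path) -> list[RepeatFrame]:
    """3+ column TSV: protein, start, label[, period]."""
    frames = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        protein, start, label = parts[0], int(parts[1]), parts[2]
        period = int(parts[3]) if len(parts) > 3 else DEFAULT_PERIOD
        frames.append(RepeatFrame(protein_id=protein, start=start, period=period, index=label))
    _check_frame_order(frames)
    return frames


def _check_frame_order(frames: Sequence[RepeatFrame]) -> None:
    by_protein: dict[str, list[RepeatFrame]] = {}
    for f in frames:
        by_protein.setdefault(f.protein_id, []).append(f)
    for protein, fs in by_protein.items():
        for a, b in zip(fs, fs[1:]):
            if b.start < a.start + a.period:
                raise FrameError(f"{protein}: frames {a.index} and {b.index} overlap")


def assignment_to_tsv(assignments: Iterable[LayerAssignment]) -> str:
    """TSV rows: protein, repeat, layer, resnum, aa (absent positions skipped)."""
    lines = ["protein\trepeat\tlayer\tresnum\taa"]
    for assignment in assignments:
        for row in assignment.rows:
            for layer in LAYER_NAMES:
                entry = row["layers"].get(layer)
                if entry is None:
                    continue
                number, aa = entry
                lines.append(f"{assignment.protein_id}\t{row['index']}\t{layer}\t{number}\t{aa}")
    return "\n".join(lines) + "\n"
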