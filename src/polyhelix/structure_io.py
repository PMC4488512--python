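"""Cα-trace I/O: PDB reading, chain-break splitting, result serialization.

Reading goes through gemmi (first model only).  Per residue exactly one Cα
is retained: alternate locations are resolved by highest occupancy, ties by
lowest altloc letter.  HETATM Cα atoms of standard modified amino acids
(MSE etc.) are kept; waters, ligands and calcium ions are ignored.

Chains are split into contiguous segments wherever a consecutive Cα–Cα
distance falls outside a window covering trans (~3.8 Å) and cis (~2.9 Å)
peptides; numbering gaps alone do not split — distance is the authority.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .assignment import HelixAnnotation

__all__ = [
    "CalphaResidue",
    "CalphaChain",
    "ChainSegment",
    "ProfileRow",
    "EmptyInputError",
    "PDBFormatError",
    "ConsistencyError",
    "read_calpha_chains",
    "split_on_breaks",
    "write_assignments",
    "read_annotations_json",
    "parse_helix_records",
    "write_calpha_pdb",
    "DEFAULT_BREAK_WINDOW",
    "HELIX_CLASS_CODES",
]

DEFAULT_BREAK_WINDOW = (2.5, 4.3)

# HETATM residues treated as polymer amino acids (Cα retained)
MODIFIED_AA = {
    "MSE", "SEC", "PYL", "MLY", "HYP", "SEP", "TPO", "PTR", "CSO", "KCX",
    "CME", "MLE", "FME", "CSD", "OCS", "ALY", "M3L",
}

# helix-record class codes: (type, handedness) -> helixClass
HELIX_CLASS_CODES = {
    ("alpha", "right"): 1,
    ("pi", "right"): 3,
    ("310", "right"): 5,
    ("alpha", "left"): 6,
    ("310", "left"): 8,
    ("pi", "left"): 10,
}
_CODE_TO_TYPE = {v: k for k, v in HELIX_CLASS_CODES.items()}


class EmptyInputError(ValueError):
    """Input document contains no Cα records."""


class PDBFormatError(ValueError):
    """Input document could not be parsed as PDB."""


class ConsistencyError(ValueError):
    """Annotations violate a structural contract (e.g. overlap)."""


@dataclass(frozen=True)
class CalphaResidue:
    """One retained Cα atom with its residue identity."""

    residue_number: int
    insertion_code: str
    residue_name: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def residue_id(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass
class CalphaChain:
    """Ordered Cα trace of one chain, in file order."""

    chain_id: str
    residues: list[CalphaResidue] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([r.position for r in self.residues]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ChainSegment:
    """Contiguous (break-free) sub-run of a chain."""

    chain_id: str
    residues: list[CalphaResidue]
    start_offset: int = 0  # index of residues[0] within the parent chain

    def coords(self) -> np.ndarray:
        return np.array([r.position for r in self.residues]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProfileRow:
    """One per-residue output row (profile values plus assignment)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    r: float = math.nan
    p: float = math.nan
    t: float = math.nan
    delta: float = math.nan
    a: float = math.nan
    small_delta: float = math.nan
    h: float = math.inf
    g: float = math.inf
    pi: float = math.inf
    assigned: str = "-"
    handedness: str = "-"


def _keep_residue(residue: gemmi.Residue) -> bool:
    if residue.is_water():
        return False
    if residue.het_flag == "A":
        return True
    return residue.name in MODIFIED_AA


def _validate_coordinate_fields(document: str) -> None:
    # gemmi is lenient about malformed numeric fields; fail loudly instead
    for lineno, line in enumerate(document.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")) or len(line) < 54:
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            field = line[lo:hi]
            try:
                float(field)
            except ValueError:
                raise PDBFormatError(
                    f"unparsable coordinate field {field!r} on line {lineno}: {line!r}"
                ) from None


def read_calpha_chains(document: str) -> list[CalphaChain]:
    """Parse PDB-format text into one :class:`CalphaChain` per chain id.

    First model only.  Raises :class:`EmptyInputError` when no Cα records
    survive filtering and :class:`PDBFormatError` on unparsable input (the
    gemmi message names the offending line).
    """
    _validate_coordinate_fields(document)
    try:
        structure = gemmi.read_pdb_string(document)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB document: {exc}") from exc
    chains: dict[str, CalphaChain] = {}
    seen: dict[str, set[tuple[int, str]]] = {}
    if len(structure) == 0:
        raise EmptyInputError("no Cα records found")
    model = structure[0]
    for chain in model:
        for residue in chain:
            if not _keep_residue(residue):
                continue
            cas = [
                atom
                for atom in residue
                if atom.name == "CA" and atom.element.name in ("C", "X")
            ]
            if not cas:
                continue
            # altloc resolution: highest occupancy, ties -> lowest letter
            best = min(cas, key=lambda a: (-a.occ, a.altloc or " "))
            icode = residue.seqid.icode if residue.seqid.icode.strip() else " "
            rid = (residue.seqid.num, icode)
            if rid in seen.setdefault(chain.name, set()):
                continue
            seen[chain.name].add(rid)
            occ = best.occ if best.occ is not None else 1.0
            chains.setdefault(chain.name, CalphaChain(chain_id=chain.name)).residues.append(
                CalphaResidue(
                    residue_number=residue.seqid.num,
                    insertion_code=icode,
                    residue_name=residue.name,
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    occupancy=min(max(occ, 0.0), 1.0),
                )
            )
    result = [c for c in chains.values() if c.residues]
    if not result:
        raise EmptyInputError("no Cα records found")
    return result


def split_on_breaks(
    chain: CalphaChain,
    window: tuple[float, float] = DEFAULT_BREAK_WINDOW,
) -> list[ChainSegment]:
    """Split a chain into maximal runs of in-window consecutive Cα distances.

    Segments shorter than 4 residues are still returned (assignment skips
    them); the concatenated segments always equal the input residue sequence.
    """
    lo, hi = window
    segments: list[ChainSegment] = []
    current: list[CalphaResidue] = []
    start = 0
    for i, res in enumerate(chain.residues):
        if current:
            d = float(np.linalg.norm(res.position - current[-1].position))
            if not lo <= d <= hi:
                segments.append(
                    ChainSegment(chain.chain_id, current, start_offset=start)
                )
                current = []
                start = i
        current.append(res)
    if current:
        segments.append(ChainSegment(chain.chain_id, current, start_offset=start))
    return segments


# ---------------------------------------------------------------------------
# Output writers

_TSV_HEADER = (
    "chain\tresnum\ticode\th\tg\tpi\ta\tdelta\tsmall_delta\tassigned\thandedness"
)


def _fmt(x: float, prec: int = 4) -> str:
    if math.isnan(x):
        return "nan"
    if math.isinf(x):
        return "inf"
    return f"{x:.{prec}f}"


def _check_no_overlap(
    annotations: Sequence[HelixAnnotation], rows: Sequence[ProfileRow]
) -> dict[tuple[str, tuple[int, str]], int]:
    order: dict[tuple[str, tuple[int, str]], int] = {}
    for idx, row in enumerate(rows):
        order[(row.chain_id, (row.residue_number, row.insertion_code))] = idx
    claimed: dict[int, HelixAnnotation] = {}
    for ann in annotations:
        key_s = (ann.chain_id, tuple(ann.start))
        key_e = (ann.chain_id, tuple(ann.end))
        if key_s not in order or key_e not in order:
            raise ConsistencyError(f"annotation {ann} references unknown residues")
        for idx in range(order[key_s], order[key_e] + 1):
            if idx in claimed:
                raise ConsistencyError(
                    f"annotations overlap at residue index {idx}: {claimed[idx]} / {ann}"
                )
            claimed[idx] = ann
    return order


def write_assignments(
    annotations: Sequence[HelixAnnotation],
    rows: Sequence[ProfileRow],
    style: str = "tsv",
    config_echo: dict | None = None,
) -> str:
    """Serialize annotations (+ per-residue rows) as tsv, json or
    helix-records.

    Annotation ``start``/``end`` must be (residue_number, insertion_code)
    pairs resolvable in ``rows``.  Overlapping annotations raise
    :class:`ConsistencyError`.
    """
    order = _check_no_overlap(annotations, rows)
    if style == "tsv":
        lines = [_TSV_HEADER]
        for row in rows:
            lines.append(
                "\t".join(
                    [
                        row.chain_id,
                        str(row.residue_number),
                        row.insertion_code.strip() or ".",
                        _fmt(row.h, 2),
                        _fmt(row.g, 2),
                        _fmt(row.pi, 2),
                        _fmt(row.a, 2),
                        _fmt(row.delta),
                        _fmt(row.small_delta),
                        row.assigned,
                        row.handedness,
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    if style == "json":
        payload = {
            "annotations": [
                {
                    "chain_id": ann.chain_id,
                    "start": list(ann.start),
                    "end": list(ann.end),
                    "helix_type": ann.helix_type,
                    "handedness": ann.handedness,
                }
                for ann in annotations
            ],
            "config": config_echo or {},
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if style == "helix-records":
        by_res = {
            (row.chain_id, (row.residue_number, row.insertion_code)): row
            for row in rows
        }
        lines = []
        for serial, ann in enumerate(annotations, start=1):
            start_row = by_res[(ann.chain_id, tuple(ann.start))]
            end_row = by_res[(ann.chain_id, tuple(ann.end))]
            key_s = (ann.chain_id, tuple(ann.start))
            key_e = (ann.chain_id, tuple(ann.end))
            length = order[key_e] - order[key_s] + 1
            cls = HELIX_CLASS_CODES[(ann.helix_type, ann.handedness)]
            lines.append(_format_helix_record(serial, start_row, end_row, cls, length))
        return "\n".join(lines) + ("\n" if lines else "")
    raise ValueError(f"unknown style {style!r}")


def _format_helix_record(
    serial: int, start: ProfileRow, end: ProfileRow, helix_class: int, length: int
) -> str:
    # PDB v3.3 HELIX record, column-exact (76 columns)
    line = (
        f"HELIX  {serial:>3} {serial:>3} "
        f"{start.residue_name:>3} {start.chain_id:1.1}{start.residue_number:>5}"
        f"{start.insertion_code:1.1} "
        f"{end.residue_name:>3} {end.chain_id:1.1}{end.residue_number:>5}"
        f"{end.insertion_code:1.1}{helix_class:>2}{'':30} {length:>5}"
    )
    assert len(line) == 76
    return line


def parse_helix_records(document: str) -> list[HelixAnnotation]:
    """Strict fixed-column reader for PDB HELIX records."""
    annotations = []
    for line in document.splitlines():
        if not line.startswith("HELIX "):
            continue
        if len(line) < 76:
            raise PDBFormatError(f"short HELIX record: {line!r}")
        chain_s = line[19]
        seq_s = int(line[21:25])
        icode_s = line[25] or " "
        chain_e = line[31]
        seq_e = int(line[33:37])
        icode_e = line[37] or " "
        cls = int(line[38:40])
        if chain_s != chain_e:
            raise PDBFormatError("HELIX record spans two chains")
        if cls not in _CODE_TO_TYPE:
            raise PDBFormatError(f"unsupported helix class {cls}")
        helix_type, handedness = _CODE_TO_TYPE[cls]
        annotations.append(
            HelixAnnotation(
                chain_id=chain_s,
                start=(seq_s, icode_s),
                end=(seq_e, icode_e),
                helix_type=helix_type,
                handedness=handedness,
            )
        )
    return annotations


def read_annotations_json(document: str) -> list[HelixAnnotation]:
    """Inverse of the json style of :func:`write_assignments`."""
    payload = json.loads(document)
    return [
        HelixAnnotation(
            chain_id=item["chain_id"],
            start=tuple(item["start"]),
            end=tuple(item["end"]),
            helix_type=item["helix_type"],
            handedness=item["handedness"],
        )
        for item in payload["annotations"]
    ]


def write_calpha_pdb(
    coords: np.ndarray,
    chain_id: str = "A",
    residue_name: str = "ALA",
    start_number: int = 1,
    remarks: Iterable[str] = (),
) -> str:
    """Serialize an (n, 3) Cα trace as a minimal PDB document."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    lines = [f"REMARK 999 {text}" for text in remarks]
    for i, (x, y, z) in enumerate(coords):
        serial = i + 1
        resnum = start_number + i
        lines.append(
            f"ATOM  {serial:>5}  CA  {residue_name:>3} {chain_id:1.1}{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
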