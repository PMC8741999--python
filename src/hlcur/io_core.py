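"""Readers and writers for the formats the pipeline touches.

PDB coordinate files are parsed at fixed columns (wwPDB v3.3 dialect):
only the first MODEL block is read, HETATM records are kept with a flag,
and alternate locations are resolved to the highest-occupancy conformer
(ties keep the first encountered).  Variant tables are TSV with a
configurable column map; ΔΔG tables accept either replica lists or a
published mean±SD summary pair.

Every reader logs input/kept/flagged counts so that row-count
conservation is assertable downstream.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import acmg_engine
from .variant_domain import (
    Consequence,
    PriorAssertion,
    VariantRecord,
    Zygosity,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    coords: np.ndarray  # (3,) float, Angstrom
    element: str
    hetatm: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ParseError(
                f"atom {self.serial} {self.atom_name}: coordinates must be 3 finite floats"
            )
        self.atom_name = self.atom_name.strip()

    @property
    def residue_id(self) -> tuple[int, str]:
        """Author residue number plus insertion code."""
        return (self.residue_seq, self.icode)


class StructureModel:
    """Parsed coordinates with chain/residue addressing.

    ``model.residue(chain, seq)`` returns that residue's atoms in file
    order; every (chain, residue_seq+icode, atom_name) triple is unique.
    """

    def __init__(self, atoms: Sequence[AtomRecord], model_id: str = "") -> None:
        if not atoms:
            raise ParseError(f"structure {model_id!r} contains no atoms")
        self.atoms: list[AtomRecord] = list(atoms)
        self.id = model_id
        self._index: dict[str, dict[tuple[int, str], list[AtomRecord]]] = {}
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            triple = (a.chain_id, a.residue_seq, a.icode, a.atom_name)
            if triple in seen:
                raise ParseError(
                    f"duplicate atom {a.atom_name!r} in residue "
                    f"{a.chain_id}{a.residue_seq}{a.icode.strip()}"
                )
            seen.add(triple)
            self._index.setdefault(a.chain_id, {}).setdefault(a.residue_id, []).append(a)

    # -- addressing ----------------------------------------------------
    @property
    def chains(self) -> list[str]:
        return list(self._index)

    def residues(self, chain_id: str) -> list[tuple[int, str]]:
        if chain_id not in self._index:
            raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")
        return list(self._index[chain_id])

    def residue(self, chain_id: str, residue_seq: int, icode: str = "") -> list[AtomRecord]:
        try:
            return self._index[chain_id][(residue_seq, icode)]
        except KeyError:
            raise KeyError(
                f"residue {chain_id}:{residue_seq}{icode} not in structure {self.id!r}"
            ) from None

    def has_residue(self, chain_id: str, residue_seq: int, icode: str = "") -> bool:
        return (residue_seq, icode) in self._index.get(chain_id, {})

    def n_residues(self, chain_id: str) -> int:
        return len(self._index[chain_id])


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        return AtomRecord(
            serial=int(line[6:11]),
            atom_name=line[12:16].strip(),
            residue_name=line[17:20].strip(),
            chain_id=line[21],
            residue_seq=int(line[22:26]),
            icode=line[26].strip(),
            coords=np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            ),
            element=line[76:78].strip() if len(line) >= 78 else "",
            hetatm=line.startswith("HETATM"),
            occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
        )
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc


def read_pdb(path: PathLike) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    First MODEL block only; altlocs resolved to highest occupancy (tie:
    first encountered); HETATM kept with ``hetatm=True``.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    # altloc resolution: (chain, resseq, icode, atom_name) -> (index, occupancy)
    placed: dict[tuple[str, int, str, str], int] = {}
    in_later_model = False
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                n_models += 1
                in_later_model = n_models > 1
            elif rec == "ENDMDL":
                continue
            if in_later_model:
                continue
            if rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"truncated ATOM/HETATM record at line {lineno}")
                altloc = line[16].strip()
                atom = _parse_atom_line(line, lineno)
                key = (atom.chain_id, atom.residue_seq, atom.icode, atom.atom_name)
                if altloc and key in placed:
                    prev = atoms[placed[key]]
                    if atom.occupancy > prev.occupancy:
                        atoms[placed[key]] = atom
                    continue
                placed[key] = len(atoms)
                atoms.append(atom)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if n_models > 1:
        log.info("%s: %d MODEL blocks, keeping the first", path.name, n_models)
    log.info("%s: read %d atoms, %d chains", path.name, len(atoms),
             len({a.chain_id for a in atoms}))
    return StructureModel(atoms, model_id=path.stem)


def write_pdb(model: StructureModel, path: PathLike) -> None:
    """Write a model in fixed-column PDB format (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for a in model.atoms:
            rec = "HETATM" if a.hetatm else "ATOM  "
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"{rec}{a.serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id}{a.residue_seq:>4d}{a.icode or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "patient_id": "patient_id",
    "gene": "gene",
    "transcript": "transcript",
    "cdna": "cdna",
    "protein": "protein",
    "consequence": "consequence",
    "zygosity": "zygosity",
    "dbsnp": "dbsnp",
    "af_global": "af_global",
    "prior_assertion": "prior_assertion",
    "evidence": "evidence",
    "reference": "reference",
    "phase_partner": "phase_partner",
}

REQUIRED_COLUMNS = ("patient_id", "gene", "transcript", "cdna", "consequence", "zygosity")

_MISSING = {"", "-", "–", "NA", "na", "None", "."}


@dataclass
class VariantTable:
    rows: list[VariantRecord]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.patient_id)
        return list(seen)

    def subset(self, rows: Iterable[VariantRecord]) -> "VariantTable":
        return VariantTable(list(rows), self.source_path)


def _opt(value: Optional[str]) -> Optional[str]:
    if value is None or value.strip() in _MISSING:
        return None
    return value.strip()


def read_variant_table(
    path: PathLike,
    column_map: Optional[dict[str, str]] = None,
) -> VariantTable:
    """Read an annotated variant TSV into a :class:`VariantTable`.

    ``column_map`` maps logical field names to header names so annotator
    exports with different headers can be adapted without code changes.
    Missing optional fields become None, never zeros; evidence strings
    are parsed via :func:`hlcur.acmg_engine.parse_codes`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    path = Path(path)
    rows: list[VariantRecord] = []
    keys: dict[tuple, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [cmap[f] for f in REQUIRED_COLUMNS if cmap[f] not in header]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        for i, raw in enumerate(reader, start=2):
            def get(field: str) -> Optional[str]:
                return _opt(raw.get(cmap[field]))

            af_text = get("af_global")
            prior_text = get("prior_assertion")
            evidence_text = get("evidence")
            record = VariantRecord(
                patient_id=get("patient_id") or "",
                gene=get("gene") or "",
                transcript=get("transcript") or "",
                cdna_change=get("cdna") or "",
                protein_change=get("protein"),
                consequence=Consequence(get("consequence")),
                zygosity=Zygosity(get("zygosity") or "het"),
                phase_partner=get("phase_partner"),
                dbsnp=get("dbsnp"),
                af_global=float(af_text) if af_text is not None else None,
                prior_assertion=(
                    PriorAssertion(prior_text) if prior_text is not None else None
                ),
                evidence=(
                    acmg_engine.parse_codes(evidence_text) if evidence_text else []
                ),
                reference=get("reference"),
            )
            record.novel = record.reference == "This work"
            k = record.key()
            if k in keys:
                raise ParseError(
                    f"{path}: duplicate (patient, gene, cdna) key {k} "
                    f"at rows {keys[k]} and {i}"
                )
            keys[k] = i
            rows.append(record)
    log.info("%s: read %d variant rows, %d patients", path.name, len(rows),
             len({r.patient_id for r in rows}))
    return VariantTable(rows, str(path))


def write_variant_table(table: VariantTable, path: PathLike) -> None:
    fields = list(DEFAULT_COLUMN_MAP)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(fields)
        for r in table.rows:
            writer.writerow([
                r.patient_id, r.gene, r.transcript, r.cdna_change,
                r.protein_change or "-",
                r.consequence.value, r.zygosity.value,
                r.dbsnp or "-",
                "" if r.af_global is None else repr(r.af_global),
                r.prior_assertion.value if r.prior_assertion else "-",
                " ".join(c.token() for c in r.evidence) or "-",
                r.reference or "-",
                r.phase_partner or "-",
            ])


# ---------------------------------------------------------------------------
# ddG tables
# ---------------------------------------------------------------------------

@dataclass
class DdgReplicateSet:
    """Per-variant folding free-energy change replicas (kcal/mol).

    Either ``replicas`` holds the raw per-replica values, or — when a
    source publishes only mean±SD — the set is stored in summary form
    and replica-level operations degrade to the summary.
    """

    variant_label: str
    replicas: Optional[list[float]] = None
    summary_mean: Optional[float] = None
    summary_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicas is not None:
            if len(self.replicas) == 0:
                raise ParseError(f"{self.variant_label}: empty replica list")
            if not all(math.isfinite(v) for v in self.replicas):
                raise ParseError(f"{self.variant_label}: non-finite replica value")
        elif self.summary_mean is None:
            raise ParseError(f"{self.variant_label}: neither replicas nor summary given")
        if self.summary_sd is not None and self.summary_sd < 0:
            raise ParseError(f"{self.variant_label}: negative SD")

    @property
    def n(self) -> int:
        return len(self.replicas) if self.replicas is not None else 0

    @property
    def mean(self) -> float:
        if self.replicas is not None:
            return float(np.mean(self.replicas))
        return float(self.summary_mean)  # type: ignore[arg-type]

    @property
    def sd(self) -> float:
        """Sample (n-1) standard deviation of the replicas."""
        if self.replicas is not None:
            if len(self.replicas) == 1:
                return 0.0
            return float(np.std(self.replicas, ddof=1))
        return float(self.summary_sd if self.summary_sd is not None else 0.0)

    @property
    def is_summary(self) -> bool:
        return self.replicas is None


@dataclass
class DdgTable:
    rows: dict[str, DdgReplicateSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, label: str) -> DdgReplicateSet:
        return self.rows[label]

    def get(self, label: str) -> Optional[DdgReplicateSet]:
        return self.rows.get(label)


def read_ddg_table(path: PathLike) -> DdgTable:
    """Read a ΔΔG table: ``label <sep> v1 v2 ...`` or ``label, mean, sd``.

    A row with exactly two numeric cells is interpreted as a published
    mean±SD summary; three or more numerics are raw replicas.  Comma,
    tab and whitespace separators are accepted; lines starting with '#'
    are comments.
    """
    path = Path(path)
    table = DdgTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace(",", "\t").split("\t") if p.strip()]
            if len(parts) == 1:
                parts = line.split()
            label, cells = parts[0], parts[1:]
            # label may itself contain spaces if tab/comma separated
            values = []
            for cell in cells:
                for token in cell.split():
                    try:
                        values.append(float(token))
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric ΔΔG cell {token!r} "
                            f"in row {label!r}"
                        ) from None
            if not values:
                raise ParseError(f"{path}:{lineno}: row {label!r} has no values")
            if len(values) == 2:
                entry = DdgReplicateSet(label, summary_mean=values[0], summary_sd=values[1])
            else:
                entry = DdgReplicateSet(label, replicas=values)
            table.rows[label] = entry
    log.info("%s: read %d ΔΔG rows", path.name, len(table))
    return table
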