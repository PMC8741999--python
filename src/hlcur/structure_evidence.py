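"""Geometry and stability evidence for missense variants.

Implements the structure-based arm of the curation workflow: rigid
least-squares superposition of two conformations of a protein model
(Kabsch, reflections excluded), per-residue backbone RMSD profiles and
detection of motile regions, side-chain distance shells around a
residue, ligand-interface residue detection at a distance cutoff,
FoldX-style ΔΔG replicate thresholding (destabilizing above
1.6 kcal/mol, twice the force field's standard deviation), a
formal-charge heuristic for electrostatic-surface changes, and the
precedence rules that triage a missense variant into a structural
mechanism (LoF / stability / electrostatic surface / interface /
nonconclusive).  A conclusive mechanism verdict feeds back into the
evidence combiner as a supporting in-silico criterion (PP3).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .acmg_engine import EvidenceCode, code
from .io_core import AtomRecord, DdgReplicateSet, StructureModel
from .variant_domain import (
    Consequence,
    VariantRecord,
    parse_protein_change,
)

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: ΔΔG significance threshold, kcal/mol: twice the force-field SD.
DDG_THRESHOLD = 1.6

#: formal side-chain charges at physiological pH (His counted neutral)
FORMAL_CHARGE = {
    "D": -1, "E": -1, "K": +1, "R": +1, "H": 0,
    **{aa: 0 for aa in "ACFGILMNPQSTVWY"},
}


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueSelector:
    chain_id: str
    residue_seq: int
    icode: str = ""

    def atoms(self, model: StructureModel) -> list[AtomRecord]:
        try:
            return model.residue(self.chain_id, self.residue_seq, self.icode)
        except KeyError as exc:
            raise GeometryError(str(exc)) from exc

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_seq}{self.icode}"


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray           # (3,3), det +1
    translation: np.ndarray        # (3,)
    global_rmsd: float
    per_residue_rmsd: dict[int, float]
    n_paired_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _paired_backbone(
    mobile: StructureModel,
    reference: StructureModel,
    chain_mobile: str,
    chain_reference: str,
    atom_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pair atoms by (residue_seq, atom_name) over shared residues."""
    xs, ys, owners = [], [], []
    shared = [r for r in reference.residues(chain_reference)
              if (r in set(mobile.residues(chain_mobile)))]
    for resid in shared:
        ref_atoms = {a.atom_name: a for a in reference.residue(chain_reference, *resid)}
        mob_atoms = {a.atom_name: a for a in mobile.residue(chain_mobile, *resid)}
        for name in atom_names:
            if name in ref_atoms and name in mob_atoms:
                xs.append(mob_atoms[name].coords)
                ys.append(ref_atoms[name].coords)
                owners.append(resid[0])
    if not xs:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.array(xs), np.array(ys), owners


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid transform (R, t) minimizing |R x + t - y|^2.

    Proper rotation only: a reflection in the SVD solution is corrected
    by negating the smallest singular direction.  Degenerate (collinear
    or coincident) point sets, for which the rotation about the
    degenerate axis is not identifiable, raise :class:`GeometryError`.
    """
    x = np.asarray(mobile_xyz, float)
    y = np.asarray(reference_xyz, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise GeometryError("paired coordinate arrays must both be (n, 3)")
    if len(x) < 3:
        raise GeometryError(f"need >= 3 paired atoms, got {len(x)}")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # rank < 2 => points are collinear/coincident: rotation underdetermined
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set: superposition undefined")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - rot @ xc
    return rot, t


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    chain_mobile: Optional[str] = None,
    chain_reference: Optional[str] = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` over paired backbone atoms.

    Residues are paired by author residue number (the deposited
    conformation pairs share numbering; no alignment is performed);
    residues present in only one model are skipped.  Per-residue RMSD is
    computed over that residue's paired backbone atoms after applying
    the global transform.
    """
    cm = chain_mobile or mobile.chains[0]
    cr = chain_reference or reference.chains[0]
    x, y, owners = _paired_backbone(mobile, reference, cm, cr, atom_names)
    rot, t = kabsch(x, y)
    moved = x @ rot.T + t
    sq = np.sum((moved - y) ** 2, axis=1)
    global_rmsd = float(np.sqrt(sq.mean()))
    per_res: dict[int, list[float]] = {}
    for owner, s in zip(owners, sq):
        per_res.setdefault(owner, []).append(s)
    per_residue = {r: float(np.sqrt(np.mean(v))) for r, v in per_res.items()}
    return SuperpositionResult(rot, t, global_rmsd, per_residue, len(x))


def detect_motile_regions(
    per_residue_rmsd: dict[int, float],
    min_len: int = 5,
    threshold: float | str = "auto",
) -> list[tuple[int, int]]:
    """Find maximal runs of >=min_len consecutive residues above threshold.

    ``threshold='auto'`` uses profile mean + 2*SD, which flags regions
    standing out of the overall inter-conformation deviation.  Returned
    ranges are inclusive (first_residue, last_residue), ascending.
    """
    if not per_residue_rmsd:
        raise GeometryError("empty per-residue RMSD profile")
    values = np.array(list(per_residue_rmsd.values()))
    if threshold == "auto":
        threshold = float(values.mean() + 2.0 * values.std())
    regions: list[tuple[int, int]] = []
    run: list[int] = []
    for resid in sorted(per_residue_rmsd):
        above = per_residue_rmsd[resid] > threshold
        contiguous = bool(run) and resid == run[-1] + 1
        if above and (not run or contiguous):
            run.append(resid)
        else:
            if len(run) >= min_len:
                regions.append((run[0], run[-1]))
            run = [resid] if above else []
    if len(run) >= min_len:
        regions.append((run[0], run[-1]))
    return regions


# ---------------------------------------------------------------------------
# distances and shells
# ---------------------------------------------------------------------------

def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if not a.atom_name.startswith("H") and a.element != "H"]


def _sidechain(atoms: Iterable[AtomRecord]) -> tuple[list[AtomRecord], bool]:
    """Side-chain heavy atoms; GLY (or CA-only models) fall back to CA.

    Returns (atoms, used_fallback).
    """
    heavy = _heavy(atoms)
    side = [a for a in heavy if a.atom_name not in BACKBONE_ATOMS]
    if side:
        return side, False
    ca = [a for a in heavy if a.atom_name == "CA"]
    if not ca:
        raise GeometryError("residue has neither side-chain heavy atoms nor CA")
    return ca, True


def sidechain_min_distance(
    model: StructureModel, a: ResidueSelector, b: ResidueSelector
) -> float:
    """Minimum heavy-atom distance between two residues' side chains (Å).

    The side chain is every heavy atom beyond the backbone (N, CA, C, O);
    glycine falls back to CA (logged).
    """
    atoms_a, fb_a = _sidechain(a.atoms(model))
    atoms_b, fb_b = _sidechain(b.atoms(model))
    if fb_a or fb_b:
        log.debug("sidechain distance %s-%s used CA fallback", a, b)
    pa = np.array([at.coords for at in atoms_a])
    pb = np.array([at.coords for at in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def neighbor_shell(
    model: StructureModel,
    center: ResidueSelector,
    cutoff: float = 5.0,
) -> list[tuple[ResidueSelector, float]]:
    """Residues with side chains within ``cutoff`` Å of the center's.

    Sequence neighbors (i±1 in the same chain) and the center itself are
    excluded; results ascend by distance.
    """
    center.atoms(model)  # raises early if unresolvable
    shell = []
    for chain in model.chains:
        for resid in model.residues(chain):
            sel = ResidueSelector(chain, resid[0], resid[1])
            if sel == center:
                continue
            if chain == center.chain_id and abs(resid[0] - center.residue_seq) <= 1:
                continue
            d = sidechain_min_distance(model, center, sel)
            if d < cutoff:
                shell.append((sel, d))
    shell.sort(key=lambda item: item[1])
    return shell


def avg_shell_distance(
    model: StructureModel,
    center: ResidueSelector,
    partners: Sequence[ResidueSelector],
) -> float:
    """Arithmetic mean of side-chain minimum distances center->partner."""
    if not partners:
        raise GeometryError("avg_shell_distance requires at least one partner")
    return float(np.mean([sidechain_min_distance(model, center, p) for p in partners]))


def interface_residues(
    model: StructureModel,
    ligand_chain: str,
    cutoff: float = 5.0,
) -> set[ResidueSelector]:
    """Protein residues with any heavy atom within ``cutoff`` of the ligand chain."""
    if ligand_chain not in model.chains:
        raise GeometryError(f"ligand chain {ligand_chain!r} not in structure {model.id!r}")
    ligand_xyz = np.array([
        a.coords for a in model.atoms
        if a.chain_id == ligand_chain and a in _heavy([a])
    ])
    result: set[ResidueSelector] = set()
    for chain in model.chains:
        if chain == ligand_chain:
            continue
        for resid in model.residues(chain):
            atoms = _heavy(model.residue(chain, *resid))
            if not atoms:
                continue
            xyz = np.array([a.coords for a in atoms])
            d = np.linalg.norm(xyz[:, None, :] - ligand_xyz[None, :, :], axis=-1)
            if d.min() < cutoff:
                result.add(ResidueSelector(chain, resid[0], resid[1]))
    return result


def burial_proxy(
    model: StructureModel,
    center: ResidueSelector,
    shell_radius: float = 8.0,
) -> int:
    """Heavy-atom contact count around the side-chain centroid.

    Counts heavy atoms of *other* residues within ``shell_radius`` of
    the center residue's side-chain centroid; higher means more buried.
    A crude but monotone surface/core separator for formal-charge
    mechanism gating.
    """
    side, _ = _sidechain(center.atoms(model))
    centroid = np.mean([a.coords for a in side], axis=0)
    count = 0
    for a in _heavy(model.atoms):
        if a.chain_id == center.chain_id and (a.residue_seq, a.icode) == (
            center.residue_seq, center.icode
        ):
            continue
        if np.linalg.norm(a.coords - centroid) <= shell_radius:
            count += 1
    return count


# ---------------------------------------------------------------------------
# ddG, charge, mechanism
# ---------------------------------------------------------------------------

def ddg_classify(ddg: DdgReplicateSet, threshold: float = DDG_THRESHOLD) -> bool:
    """True iff the mean ΔΔG significantly destabilizes (strictly above threshold)."""
    return ddg.mean > threshold


def charge_delta(aa_from: str, aa_to: str) -> int:
    """Formal side-chain charge change charge(to) - charge(from)."""
    try:
        return FORMAL_CHARGE[aa_to.upper()] - FORMAL_CHARGE[aa_from.upper()]
    except KeyError as exc:
        raise GeometryError(f"nonstandard amino acid code: {exc}") from exc


class Mechanism(enum.Enum):
    LOF = "LoF"
    STABILITY = "stability"
    ELECTROSTATIC_SURFACE = "electrostatic_surface"
    INTERFACE_INTERACTION = "interface_interaction"
    NONCONCLUSIVE = "nonconclusive"


@dataclass
class MechanismVerdict:
    label: Mechanism
    measurements: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MechanismConfig:
    """Thresholds for mechanism triage.

    ``burial_surface_cutoff`` is the contact count at or below which a
    side chain counts as surface-exposed (calibrated on a synthetic
    globule so that a core residue fails the electrostatic gate);
    ``ddg_threshold`` in kcal/mol.
    """

    ddg_threshold: float = DDG_THRESHOLD
    burial_surface_cutoff: int = 40
    min_abs_charge_delta: int = 1


@dataclass
class ResidueAnnotation:
    """Per-position structural annotation for a protein.

    ``interface``: positions contacting the ligand (tRNA) within 5 Å;
    ``helix``: positions inside annotated alpha-helices (used by the
    proline rule); ``exposed``: surface-exposed positions, either
    annotated directly or derivable from a model via burial_proxy.
    """

    interface: set[int] = field(default_factory=set)
    helix: set[int] = field(default_factory=set)
    exposed: set[int] = field(default_factory=set)
    buried: set[int] = field(default_factory=set)

    def is_exposed(self, position: int) -> Optional[bool]:
        if position in self.exposed:
            return True
        if position in self.buried:
            return False
        return None


def assign_mechanism(
    variant: VariantRecord,
    ddg: Optional[DdgReplicateSet] = None,
    model: Optional[StructureModel] = None,
    annotation: Optional[ResidueAnnotation] = None,
    config: MechanismConfig = MechanismConfig(),
    chain_id: Optional[str] = None,
) -> MechanismVerdict:
    """Triage a variant into a structural mechanism.

    Precedence: (1) LoF for truncating consequences; (2) interface
    interaction when the position lies in the ligand-interface set; (3)
    electrostatic surface when the formal charge changes and the side
    chain is surface-exposed; (4) stability when mean ΔΔG exceeds the
    significance threshold or the substitution introduces/removes a
    proline inside an annotated helix; (5) nonconclusive.

    Surface exposure comes from the annotation when present, otherwise
    from :func:`burial_proxy` on the model; with neither available the
    electrostatic gate is conservatively closed.
    """
    annotation = annotation or ResidueAnnotation()
    meas: dict = {}
    if variant.consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT):
        return MechanismVerdict(Mechanism.LOF, {"consequence": variant.consequence.value})
    if variant.consequence is not Consequence.MISSENSE:
        return MechanismVerdict(Mechanism.NONCONCLUSIVE,
                                {"consequence": variant.consequence.value})
    aa_from, position, aa_to = parse_protein_change(variant.protein_change or "")
    meas["position"] = position
    if ddg is not None:
        meas["ddg_mean"], meas["ddg_sd"] = ddg.mean, ddg.sd

    if position in annotation.interface:
        meas["interface"] = True
        return MechanismVerdict(Mechanism.INTERFACE_INTERACTION, meas)

    dq = charge_delta(aa_from, aa_to)
    meas["charge_delta"] = dq
    if abs(dq) >= config.min_abs_charge_delta:
        exposed = annotation.is_exposed(position)
        if exposed is None and model is not None:
            chain = chain_id or model.chains[0]
            if model.has_residue(chain, position):
                burial = burial_proxy(model, ResidueSelector(chain, position))
                meas["burial_proxy"] = burial
                exposed = burial <= config.burial_surface_cutoff
        meas["exposed"] = exposed
        if exposed:
            return MechanismVerdict(Mechanism.ELECTROSTATIC_SURFACE, meas)

    destabilizing = ddg is not None and ddg_classify(ddg, config.ddg_threshold)
    proline_in_helix = ("P" in (aa_from, aa_to)) and position in annotation.helix
    meas["destabilizing"] = destabilizing
    meas["proline_in_helix"] = proline_in_helix
    if destabilizing or proline_in_helix:
        return MechanismVerdict(Mechanism.STABILITY, meas)
    return MechanismVerdict(Mechanism.NONCONCLUSIVE, meas)


def pp3_from_structure(verdict: MechanismVerdict) -> Optional[EvidenceCode]:
    """Supporting in-silico evidence (PP3) from a conclusive mechanism.

    LoF verdicts yield no code: truncating evidence is PVS1 territory,
    supplied upstream, and must not be double counted.  Nonconclusive
    verdicts yield no code either; a benign-direction BP4 is never
    emitted automatically.
    """
    if verdict.label in (
        Mechanism.STABILITY,
        Mechanism.ELECTROSTATIC_SURFACE,
        Mechanism.INTERFACE_INTERACTION,
    ):
        return code("PP3")
    return None


def template_screen(
    candidates: Iterable[tuple[str, float, float]],
    min_identity: float = 0.36,
    max_resolution: float = 2.5,
) -> list[tuple[str, float, float]]:
    """Rank homology-modeling template candidates.

    Keeps (id, identity, resolution) entries with identity strictly
    above ``min_identity`` and resolution strictly below
    ``max_resolution``; sorts by identity descending, resolution
    ascending as tiebreak.
    """
    accepted = []
    for tid, identity, resolution in candidates:
        if not 0.0 <= identity <= 1.0:
            raise GeometryError(f"template {tid}: identity {identity} outside [0, 1]")
        if resolution <= 0:
            raise GeometryError(f"template {tid}: nonpositive resolution")
        if identity > min_identity and resolution < max_resolution:
            accepted.append((tid, identity, resolution))
    accepted.sort(key=lambda c: (-c[1], c[2]))
    return accepted
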