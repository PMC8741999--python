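"""Seeded generators for every pipeline input, plus transcribed fixtures.

The generators emulate the study conditions: a 32-proband deafness
cohort screened against a 183-gene panel with rare spiked causal alleles
on a background of common/benign decoys; two-conformation toy helices
with a known motile (hinge) interval standing in for the two motor
domain states; and Gaussian five-replica ΔΔG sets mimicking FoldX
output.  Every generator is a pure function of its spec and seed.

``load_fixture`` serves the verbatim transcriptions of the curation
table (28 variants, 20 patients), the synthetase variant-modeling table
(20 variants with ΔΔG summaries and structural annotations), the domain
architecture, and the stand-in gene panel.  Fixture checksums are pinned
in a manifest; edits without a manifest update fail loudly.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import acmg_engine
from .acmg_engine import combine, parse_codes
from .filter_engine import GenePanel
from .io_core import (
    AtomRecord,
    DdgReplicateSet,
    DdgTable,
    StructureModel,
    VariantTable,
    read_variant_table,
)
from .structure_evidence import ResidueAnnotation
from .variant_domain import (
    Consequence,
    InheritanceMode,
    InheritanceModel,
    PedigreeMember,
    Tier,
    VariantRecord,
    Zygosity,
)


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXDIR = resources.files("hlcur") / "fixtures"

_TIERS = {t.value: t for t in Tier}


def _fixture_path(filename: str) -> Path:
    p = Path(str(_FIXDIR / filename))
    if not p.exists():
        raise FixtureError(f"fixture file missing: {filename}")
    return p


def _verify_checksum(filename: str) -> None:
    manifest = json.loads(_fixture_path("manifest.json").read_text())
    digest = hashlib.sha256(_fixture_path(filename).read_bytes()).hexdigest()
    if manifest.get(filename) != digest:
        raise FixtureError(
            f"fixture {filename} does not match its pinned checksum; "
            "update fixtures/manifest.json deliberately if the edit is intended"
        )


@dataclass
class Table3Fixture:
    """The synthetase variant-modeling table as pipeline-ready objects."""

    variants: VariantTable
    ddg: DdgTable
    annotation: ResidueAnnotation
    expected_mechanism: dict[str, str]      # protein change -> label
    expected_tier: dict[str, Tier]          # protein change -> classification


@dataclass
class DomainRegion:
    name: str
    start: int
    end: int


def load_fixture(name: str) -> Union[VariantTable, Table3Fixture, list[DomainRegion], GenePanel]:
    """Load a named fixture: table2 | table3 | lars2_domains | panel."""
    if name == "table2":
        return _load_table2()
    if name == "table3":
        return _load_table3()
    if name == "lars2_domains":
        return _load_domains()
    if name == "panel":
        _verify_checksum("panel183.txt")
        return GenePanel.from_file(_fixture_path("panel183.txt"), name="deafness-183")
    raise FixtureError(f"unknown fixture {name!r}")


def _load_table2() -> VariantTable:
    _verify_checksum("table2.tsv")
    path = _fixture_path("table2.tsv")
    table = read_variant_table(path)
    with open(path, newline="") as fh:
        extras = list(csv.DictReader(fh, delimiter="\t"))
    for row, raw in zip(table.rows, extras):
        row.extra["after_curation"] = _TIERS[raw["after_curation"]]
        row.extra["phenotype"] = raw["phenotype"]
        row.extra["segregation_note"] = raw["segregation"]
    return table


def _load_table3() -> Table3Fixture:
    _verify_checksum("table3.tsv")
    path = _fixture_path("table3.tsv")
    table = read_variant_table(path)
    ddg = DdgTable()
    annotation = ResidueAnnotation()
    expected_mechanism: dict[str, str] = {}
    expected_tier: dict[str, Tier] = {}
    with open(path, newline="") as fh:
        raws = list(csv.DictReader(fh, delimiter="\t"))
    for row, raw in zip(table.rows, raws):
        p = row.protein_change or row.cdna_change
        row.extra["effect_printed"] = raw["effect_printed"]
        row.extra["mechanism_label"] = raw["mechanism_label"]
        expected_mechanism[p] = raw["mechanism_label"]
        expected_tier[p] = _TIERS[raw["classification"]]
        row.extra["classification"] = _TIERS[raw["classification"]]
        if raw["ddg_mean"] != "-":
            ddg.rows[p] = DdgReplicateSet(
                p, summary_mean=float(raw["ddg_mean"]), summary_sd=float(raw["ddg_sd"])
            )
        if row.consequence is Consequence.MISSENSE:
            from .variant_domain import parse_protein_change

            _, pos, _ = parse_protein_change(p)
            if raw["interface"] == "1":
                annotation.interface.add(pos)
            if raw["helix"] == "1":
                annotation.helix.add(pos)
            if raw["exposed"] == "1":
                annotation.exposed.add(pos)
            elif raw["exposed"] == "0":
                annotation.buried.add(pos)
    return Table3Fixture(table, ddg, annotation, expected_mechanism, expected_tier)


def _load_domains() -> list[DomainRegion]:
    _verify_checksum("lars2_domains.tsv")
    regions = []
    with open(_fixture_path("lars2_domains.tsv")) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for raw in reader:
            regions.append(DomainRegion(raw["name"], int(raw["start"]), int(raw["end"])))
    return regions


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: evidence templates whose combined tier is the planned tier (checked at
#: generation time, so a combiner change cannot silently invalidate spikes)
_TIER_EVIDENCE = {
    Tier.PATHOGENIC: "PVS1 PM2 PM3",
    Tier.LIKELY_PATHOGENIC: "PM2 PM3 PP1 PP4",
    Tier.VUS: "PM2 PP3",
    Tier.BENIGN: "BA1",
}

_DECOY_CONSEQUENCES = [
    (Consequence.SYNONYMOUS, 0.30),
    (Consequence.INTRONIC, 0.25),
    (Consequence.MISSENSE, 0.30),
    (Consequence.OTHER, 0.05),
    (Consequence.SPLICE_SITE, 0.05),
    (Consequence.INFRAME_INDEL, 0.05),
]


@dataclass
class SpikePlan:
    patient_id: str
    gene: str
    tier: Tier
    zygosity: Zygosity
    inheritance: InheritanceModel
    cdna: str
    partner_cdna: Optional[str] = None
    segregation_consistent_plan: bool = True


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 32 probands, a 183-gene panel,
    a 62.5% fraction of patients carrying a reportable (spiked) variant,
    background MAFs drawn from Beta(0.2, 5) so most decoys are rare but
    a controlled fraction violates the frequency thresholds.
    """

    n_patients: int = 32
    panel: Optional[GenePanel] = None
    fraction_with_findings: float = 0.625
    fraction_ar: float = 0.5
    background_variants_per_patient: int = 30
    maf_beta: tuple[float, float] = (0.2, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = load_fixture("panel")


@dataclass
class SyntheticCohort:
    tables: dict[str, VariantTable]
    pedigrees: dict[str, list[PedigreeMember]]
    truth: list[SpikePlan]
    inheritance: dict[str, InheritanceModel]


_OFFPANEL_GENES = [f"OFFPANEL{i:02d}" for i in range(1, 21)]


def _background_record(rng: np.random.Generator, patient: str, spec: CohortSpec,
                       serial: int) -> VariantRecord:
    in_panel = rng.random() < 0.5
    if in_panel:
        gene = str(rng.choice(sorted(spec.panel.genes)))
    else:
        gene = str(rng.choice(_OFFPANEL_GENES))
    kinds, weights = zip(*_DECOY_CONSEQUENCES)
    consequence = kinds[rng.choice(len(kinds), p=np.array(weights) / sum(weights))]
    af = float(rng.beta(*spec.maf_beta))
    return VariantRecord(
        patient_id=patient,
        gene=gene,
        transcript=f"NM_{serial:06d}.1",
        cdna_change=f"c.{serial}A>G",
        protein_change=None,
        consequence=consequence,
        zygosity=Zygosity.HET,
        af_global=af,
    )


def _trio(patient: str, key: str, inheritance: InheritanceModel,
          biallelic_keys: tuple[str, ...] = (),
          consistent: bool = True) -> list[PedigreeMember]:
    """Proband + parents genotyped for the spiked variant(s)."""
    ar = inheritance.mode is InheritanceMode.AUTOSOMAL_RECESSIVE
    proband = PedigreeMember(f"{patient}-proband", affected=True, is_proband=True,
                             relationship="proband")
    mother = PedigreeMember(f"{patient}-mother", affected=False, relationship="mother")
    father = PedigreeMember(f"{patient}-father", affected=not ar, relationship="father")
    for k in (key, *biallelic_keys):
        proband.carries_variant[k] = True
        proband.biallelic[k] = True
        if ar:
            mother.carries_variant[k] = True       # healthy carrier
            father.carries_variant[k] = True
        else:
            mother.carries_variant[k] = False
            father.carries_variant[k] = consistent  # affected parent carries it
            if not consistent:
                # carrier parent unaffected: contradicts dominant model
                father.affected = False
                father.carries_variant[k] = True
    return [proband, mother, father]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate per-patient variant tables, pedigrees and a truth table.

    Spiked causal variants satisfy all three filters by construction
    (panel gene, kept consequence, MAF drawn below the relevant
    threshold) and carry evidence whose combined tier equals the
    planned tier (asserted at generation).
    """
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, VariantTable] = {}
    pedigrees: dict[str, list[PedigreeMember]] = {}
    truth: list[SpikePlan] = []
    inheritance_map: dict[str, InheritanceModel] = {}
    panel_genes = sorted(spec.panel.genes)
    serial = 1000

    for i in range(spec.n_patients):
        patient = f"S{i + 1:03d}"
        ar = rng.random() < spec.fraction_ar
        model = InheritanceModel(
            InheritanceMode.AUTOSOMAL_RECESSIVE if ar else InheritanceMode.AUTOSOMAL_DOMINANT
        )
        inheritance_map[patient] = model
        rows: list[VariantRecord] = []
        for _ in range(spec.background_variants_per_patient):
            serial += 1
            rows.append(_background_record(rng, patient, spec, serial))

        if rng.random() < spec.fraction_with_findings:
            gene = str(rng.choice(panel_genes))
            maf_cap = 0.01 if ar else 0.005
            tier = Tier.PATHOGENIC if rng.random() < 0.7 else Tier.LIKELY_PATHOGENIC
            evidence = parse_codes(_TIER_EVIDENCE[tier])
            assert combine(evidence) is tier, "spike evidence must combine to plan"
            serial += 1
            cdna = f"c.{serial}C>T"
            if ar:
                serial += 1
                cdna2 = f"c.{serial}G>A"
                key1, key2 = f"{gene}:{cdna}", f"{gene}:{cdna2}"
                rows.append(VariantRecord(
                    patient_id=patient, gene=gene, transcript="NM_000001.1",
                    cdna_change=cdna, consequence=Consequence.MISSENSE,
                    zygosity=Zygosity.HET, phase_partner=key2,
                    af_global=float(rng.uniform(0, maf_cap * 0.5)),
                    evidence=list(evidence),
                ))
                rows.append(VariantRecord(
                    patient_id=patient, gene=gene, transcript="NM_000001.1",
                    cdna_change=cdna2, consequence=Consequence.MISSENSE,
                    zygosity=Zygosity.HET, phase_partner=key1,
                    af_global=float(rng.uniform(0, maf_cap * 0.5)),
                    evidence=list(evidence),
                ))
                plan = SpikePlan(patient, gene, tier, Zygosity.HET, model, cdna,
                                 partner_cdna=cdna2)
                pedigrees[patient] = _trio(patient, key1, model, (key2,))
            else:
                rows.append(VariantRecord(
                    patient_id=patient, gene=gene, transcript="NM_000001.1",
                    cdna_change=cdna, consequence=Consequence.MISSENSE,
                    zygosity=Zygosity.HET,
                    af_global=float(rng.uniform(0, maf_cap * 0.5)),
                    evidence=list(evidence),
                ))
                plan = SpikePlan(patient, gene, tier, Zygosity.HET, model, cdna)
                pedigrees[patient] = _trio(patient, f"{gene}:{cdna}", model)
            truth.append(plan)
        else:
            pedigrees[patient] = [
                PedigreeMember(f"{patient}-proband", affected=True, is_proband=True,
                               relationship="proband")
            ]
        tables[patient] = VariantTable(rows, source_path=f"synthetic:{patient}")
    return SyntheticCohort(tables, pedigrees, truth, inheritance_map)


# ---------------------------------------------------------------------------
# two-conformation helix generator
# ---------------------------------------------------------------------------

@dataclass
class HingeHelixSpec:
    """Toy two-conformation helix with a known motile interval.

    An ideal alpha-helix backbone (1.5 Å rise, 100°/residue twist) with
    CB pseudo-side-chains; the second conformation rigidly rotates the
    hinge residues about the helix axis by ``hinge_angle`` and adds
    Gaussian coordinate noise, so the inter-conformation deviation is a
    step localized to the hinge.
    """

    n_residues: int = 100
    hinge_start: int = 20
    hinge_end: int = 30
    hinge_angle_deg: float = 30.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.hinge_start <= self.hinge_end <= self.n_residues):
            raise ValueError("hinge interval must lie within [1, n_residues]")
        if self.n_residues < (self.hinge_end - self.hinge_start + 1) + 10:
            raise ValueError("helix must exceed hinge length by at least 10 residues")


_HELIX_ATOMS = (
    # (atom_name, radius Å, phase offset deg, z offset Å, element)
    ("N", 1.6, -28.0, -0.55, "N"),
    ("CA", 2.3, 0.0, 0.0, "C"),
    ("C", 2.0, 26.0, 0.55, "C"),
    ("O", 2.0, 26.0, 1.75, "O"),
    ("CB", 3.3, -15.0, -0.3, "C"),
)


def _helix_coords(i: int, name_spec: tuple) -> np.ndarray:
    _, radius, dphase, dz, _ = name_spec
    phase = np.deg2rad(i * 100.0 + dphase)
    return np.array([radius * np.cos(phase), radius * np.sin(phase), i * 1.5 + dz])


def generate_helix_pair(spec: HingeHelixSpec) -> tuple[StructureModel, StructureModel]:
    """Return (reference, mobile) conformations of the toy helix."""
    rng = np.random.default_rng(spec.seed)
    theta = np.deg2rad(spec.hinge_angle_deg)
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    ref_atoms, mob_atoms = [], []
    serial = 0
    for i in range(1, spec.n_residues + 1):
        in_hinge = spec.hinge_start <= i <= spec.hinge_end
        for atom_spec in _HELIX_ATOMS:
            serial += 1
            xyz = _helix_coords(i, atom_spec)
            moved = rot @ xyz if in_hinge else xyz.copy()
            moved = moved + rng.normal(0.0, spec.noise_sd, size=3)
            name, _, _, _, element = atom_spec
            common = dict(atom_name=name, residue_name="ALA", chain_id="A",
                          residue_seq=i, icode="", element=element)
            ref_atoms.append(AtomRecord(serial=serial, coords=xyz, **common))
            mob_atoms.append(AtomRecord(serial=serial, coords=moved, **common))
    return (
        StructureModel(ref_atoms, model_id="helix-ref"),
        StructureModel(mob_atoms, model_id="helix-mobile"),
    )


# ---------------------------------------------------------------------------
# ddG replica generator
# ---------------------------------------------------------------------------

def generate_ddg_sets(
    truth: list[tuple[str, float, float]],
    n_replicas: int = 5,
    seed: int = 0,
) -> DdgTable:
    """Draw Normal(mu, sd) replica sets (five per variant, FoldX-style)."""
    rng = np.random.default_rng(seed)
    table = DdgTable()
    for label, mu, sd in truth:
        if sd < 0:
            raise ValueError(f"{label}: negative SD")
        replicas = [float(mu + sd * rng.standard_normal()) for _ in range(n_replicas)]
        table.rows[label] = DdgReplicateSet(label, replicas=replicas)
    return table
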