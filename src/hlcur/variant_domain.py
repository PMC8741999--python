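"""Core data model: variants, inheritance, pedigrees, classification tiers.

The unit of analysis is one annotated variant observed in one patient
(:class:`VariantRecord`).  Evidence codes attached to a record are the
ACMG/AMP criteria with optional strength modifiers; they are parsed and
combined by :mod:`hlcur.acmg_engine`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .acmg_engine import EvidenceCode


class Consequence(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


class Zygosity(enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class InheritanceMode(enum.Enum):
    AUTOSOMAL_RECESSIVE = "AR"
    AUTOSOMAL_DOMINANT = "AD"
    X_LINKED = "XL"


class PriorAssertion(enum.Enum):
    """Assertion previously recorded in ClinVar for a variant."""

    P = "P"
    LP = "LP"
    P_LP = "P/LP"  # dual assertion "Pathogenic/Likely pathogenic"
    VUS = "VUS"
    CONFLICTING = "ConflictingInterpretation"
    LB = "LB"
    B = "B"


class Tier(enum.Enum):
    """Five-tier classification outcome."""

    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "LikelyBenign"
    BENIGN = "Benign"


#: ordering used for monotonicity checks: benign end low, pathogenic end high
TIER_ORDER = {
    Tier.BENIGN: 0,
    Tier.LIKELY_BENIGN: 1,
    Tier.VUS: 2,
    Tier.LIKELY_PATHOGENIC: 3,
    Tier.PATHOGENIC: 4,
}


class VariantDomainError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One annotated variant in one patient.

    ``af_global`` is the single population allele frequency used for
    filtering; ``None`` means "not observed in the frequency databases"
    and is never silently treated as zero (the filter logs it).
    """

    patient_id: str
    gene: str
    transcript: str
    cdna_change: str
    protein_change: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    zygosity: Zygosity = Zygosity.HET
    phase_partner: Optional[str] = None
    dbsnp: Optional[str] = None
    af_global: Optional[float] = None
    prior_assertion: Optional[PriorAssertion] = None
    evidence: list["EvidenceCode"] = field(default_factory=list)
    novel: bool = False
    reference: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene = self.gene.upper()
        self._check_hgvs_consistency()

    def _check_hgvs_consistency(self) -> None:
        p = self.protein_change or ""
        if ("fs" in p) and self.consequence not in (
            Consequence.FRAMESHIFT,
        ):
            raise VariantDomainError(
                f"{self.key()}: protein change {p!r} implies frameshift, "
                f"got consequence {self.consequence.value}"
            )
        # "*" or "Ter" at the end of the substitution implies a stop gain,
        # but only when it is not part of an fs*N extension
        stop_gain = ("fs" not in p) and (p.rstrip(")").endswith("*") or "Ter" in p)
        if stop_gain and self.consequence is not Consequence.NONSENSE:
            raise VariantDomainError(
                f"{self.key()}: protein change {p!r} implies nonsense, "
                f"got consequence {self.consequence.value}"
            )

    def key(self) -> tuple[str, str, str]:
        """Row identity: (patient_id, gene, cdna_change)."""
        return (self.patient_id, self.gene, self.cdna_change)

    def variant_key(self) -> tuple[str, str]:
        """Variant identity independent of carrier: (gene, cdna_change)."""
        return (self.gene, self.cdna_change)


@dataclass(frozen=True)
class InheritanceModel:
    mode: InheritanceMode


@dataclass
class PedigreeMember:
    """One family member with affection status and per-variant carrier data.

    ``carries_variant`` maps a variant key (``gene:cdna``) to one of
    ``True`` (carrier, heterozygous unless ``biallelic``), ``False``
    (tested negative) or is absent (not genotyped).  ``biallelic`` marks
    homozygous / compound-het carriers for recessive reasoning.
    """

    member_id: str
    affected: bool
    relationship: str = ""
    is_proband: bool = False
    carries_variant: dict[str, bool] = field(default_factory=dict)
    biallelic: dict[str, bool] = field(default_factory=dict)

    def genotyped_for(self, key: str) -> bool:
        return key in self.carries_variant


class SegregationResult(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    INDETERMINATE = "indeterminate"


def _validate_pedigree(pedigree: list[PedigreeMember]) -> PedigreeMember:
    probands = [m for m in pedigree if m.is_proband]
    if len(probands) != 1:
        raise VariantDomainError(
            f"pedigree must contain exactly one proband, found {len(probands)}"
        )
    return probands[0]


def segregation_consistent(
    pedigree: list[PedigreeMember],
    variant: VariantRecord,
    model: InheritanceModel,
) -> SegregationResult:
    """Check family segregation of ``variant`` under an inheritance model.

    Returns CONSISTENT when no genotyped member's (affected, carrier)
    pair contradicts the model, INCONSISTENT on any contradiction, and
    INDETERMINATE when no non-proband member is genotyped (distinct from
    a refutation).

    Autosomal recessive: affected members must be biallelic, unaffected
    members must not be.  Autosomal dominant: among genotyped members,
    affected <=> carrier.  X-linked is handled as dominant-style
    carrier/affection matching with hemizygotes counting as carriers.
    """
    _validate_pedigree(pedigree)
    key = "%s:%s" % variant.variant_key()
    genotyped = [m for m in pedigree if not m.is_proband and m.genotyped_for(key)]
    if not genotyped:
        return SegregationResult.INDETERMINATE

    for m in pedigree:
        if not m.genotyped_for(key):
            continue
        carrier = m.carries_variant[key]
        biallelic = m.biallelic.get(key, False)
        if model.mode is InheritanceMode.AUTOSOMAL_RECESSIVE:
            if m.affected and not biallelic:
                return SegregationResult.INCONSISTENT
            if not m.affected and biallelic:
                return SegregationResult.INCONSISTENT
        else:  # AD and XL: affected <=> carrier among genotyped members
            if m.affected != carrier:
                return SegregationResult.INCONSISTENT
    return SegregationResult.CONSISTENT


def parse_protein_change(p: str) -> tuple[str, int, str]:
    """Parse a missense HGVS p. string into (aa_from, position, aa_to).

    Accepts ``p.(Glu638Lys)``, ``p.Thr629Met`` and one-letter forms such
    as ``p.E638K``.  Raises :class:`VariantDomainError` when the string is
    not a simple substitution.
    """
    import re

    s = p.strip()
    s = s.removeprefix("p.").strip("()")
    m = re.fullmatch(r"([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})", s)
    if m:
        try:
            return (
                THREE_TO_ONE[m.group(1)],
                int(m.group(2)),
                THREE_TO_ONE[m.group(3)],
            )
        except KeyError as exc:
            raise VariantDomainError(f"unknown amino acid in {p!r}") from exc
    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", s)
    if m and m.group(1) in ONE_LETTER and m.group(3) in ONE_LETTER:
        return (m.group(1), int(m.group(2)), m.group(3))
    raise VariantDomainError(f"not a parseable missense protein change: {p!r}")


THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_LETTER = set(THREE_TO_ONE.values())
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
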