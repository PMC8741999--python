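"""Case orchestration and cohort summary reports.

A case runs filter -> structural evidence (PP3 merge) -> evidence
combination -> segregation check -> diagnostic call.  The diagnostic
flag for a recessive case requires a biallelic genotype (hom, hemi, or
two heterozygous variants in one gene established in trans); a dominant
case requires one het P/LP variant.  A cohort summary reproduces the
curation headline tallies: patients with findings, novel variants,
prior database assertions and the reclassification rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import acmg_engine, filter_engine, structure_evidence
from .acmg_engine import classify_record, reclassification_report
from .io_core import DdgTable, VariantTable
from .structure_evidence import (
    Mechanism,
    MechanismConfig,
    MechanismVerdict,
    ResidueAnnotation,
    assign_mechanism,
    pp3_from_structure,
)
from .variant_domain import (
    Consequence,
    InheritanceMode,
    InheritanceModel,
    PedigreeMember,
    SegregationResult,
    Tier,
    VariantRecord,
    segregation_consistent,
)

log = logging.getLogger(__name__)


@dataclass
class CaseConfig:
    patient_id: str
    inheritance: Optional[InheritanceModel] = None
    panel: Optional[filter_engine.GenePanel] = None
    filter_config: filter_engine.FilterConfig = field(
        default_factory=filter_engine.FilterConfig
    )
    pedigree: list[PedigreeMember] = field(default_factory=list)
    ddg: Optional[DdgTable] = None
    annotation: Optional[ResidueAnnotation] = None
    mechanism_config: MechanismConfig = field(default_factory=MechanismConfig)


@dataclass
class CaseResult:
    patient_id: str
    reported_variants: list[tuple[VariantRecord, Tier, Optional[MechanismVerdict]]]
    diagnostic: bool
    inheritance: Optional[InheritanceModel]
    notes: list[str] = field(default_factory=list)

    @property
    def has_findings(self) -> bool:
        return bool(self.reported_variants)


def _biallelic_configuration(variants: list[tuple[VariantRecord, Tier]]) -> bool:
    """Hom/hemi P-LP variant, or two in-trans het P/LP variants in one gene."""
    plp = [(v, t) for v, t in variants
           if t in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)]
    for v, _ in plp:
        if v.zygosity.value in ("hom", "hemi"):
            return True
    by_gene: dict[str, list[VariantRecord]] = {}
    for v, _ in plp:
        if v.zygosity.value == "het":
            by_gene.setdefault(v.gene, []).append(v)
    for gene, vs in by_gene.items():
        keys = {f"{v.gene}:{v.cdna_change}" for v in vs}
        for v in vs:
            if v.phase_partner and v.phase_partner in keys - {f"{v.gene}:{v.cdna_change}"}:
                return True
    return False


def run_case(table: VariantTable, config: CaseConfig) -> CaseResult:
    """Run one patient's variants through the full workflow."""
    rows = table.subset([r for r in table.rows if r.patient_id == config.patient_id])
    notes: list[str] = []

    if config.panel is not None:
        rows = filter_engine.filter_by_panel(rows, config.panel)
    rows = filter_engine.filter_by_consequence(rows, config.filter_config)
    rows = filter_engine.filter_by_maf(rows, config.inheritance, config.filter_config)

    reported: list[tuple[VariantRecord, Tier, Optional[MechanismVerdict]]] = []
    for record in rows.rows:
        verdict: Optional[MechanismVerdict] = None
        if record.consequence is Consequence.MISSENSE and config.ddg is not None:
            ddg = config.ddg.get(record.protein_change or "")
            if ddg is not None or config.annotation is not None:
                verdict = assign_mechanism(
                    record, ddg=ddg, annotation=config.annotation,
                    config=config.mechanism_config,
                )
                pp3 = pp3_from_structure(verdict)
                bases = {c.base for c in record.evidence}
                if pp3 is not None and pp3.base not in bases:
                    record.evidence.append(pp3)
                    notes.append(f"{record.cdna_change}: PP3 merged from structure")
        tier = classify_record(record)
        record.extra["tier"] = tier

        if config.pedigree:
            seg = segregation_consistent(config.pedigree, record, config.inheritance
                                         or InheritanceModel(InheritanceMode.AUTOSOMAL_RECESSIVE))
            record.extra["segregation"] = seg
            if seg is SegregationResult.INCONSISTENT:
                notes.append(f"{record.cdna_change}: failed segregation, not reported")
                continue
        reported.append((record, tier, verdict))

    diagnostic = _diagnostic_call(reported, config, notes)
    log.info("case %s: %d reported variants, diagnostic=%s",
             config.patient_id, len(reported), diagnostic)
    return CaseResult(config.patient_id, reported, diagnostic, config.inheritance, notes)


def _diagnostic_call(
    reported: list[tuple[VariantRecord, Tier, Optional[MechanismVerdict]]],
    config: CaseConfig,
    notes: list[str],
) -> bool:
    pairs = [(v, t) for v, t, _ in reported]
    plp = [(v, t) for v, t in pairs if t in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)]
    if not plp:
        return False
    mode = config.inheritance.mode if config.inheritance else None
    if mode is InheritanceMode.AUTOSOMAL_RECESSIVE:
        if _biallelic_configuration(pairs):
            return True
        notes.append("AR case without a biallelic P/LP configuration: undiagnosed")
        return False
    return True


@dataclass
class CohortSummary:
    n_patients: int
    n_with_findings: int
    findings_rate_percent: float  # full precision; render rounds to 1 decimal
    n_diagnostic: int
    n_variants: int
    n_novel: int
    n_prior_clinvar: int
    n_reclassified: int
    reclassified_percent: Optional[float]
    mechanism_breakdown: dict[str, tuple[int, float]] = field(default_factory=dict)

    def rendered(self) -> dict:
        """Counts plus percentages rounded to reporting precision."""
        return {
            "n_patients": self.n_patients,
            "n_with_findings": self.n_with_findings,
            "findings_rate_percent": round(self.findings_rate_percent, 1),
            "n_diagnostic": self.n_diagnostic,
            "n_variants": self.n_variants,
            "n_novel": self.n_novel,
            "n_prior_clinvar": self.n_prior_clinvar,
            "n_reclassified": self.n_reclassified,
            "reclassified_percent": (
                None if self.reclassified_percent is None
                else round(self.reclassified_percent)
            ),
            "mechanism_breakdown": {
                label: {"count": n, "percent": round(pct)}
                for label, (n, pct) in self.mechanism_breakdown.items()
            },
        }


def summarize_cohort(
    results: list[CaseResult],
    table: VariantTable,
    n_patients: Optional[int] = None,
    mechanisms: Optional[list[MechanismVerdict]] = None,
) -> CohortSummary:
    """Aggregate per-case results and the curated variant table.

    ``n_patients`` is the size of the studied cohort (it may exceed the
    number of cases with findings, e.g. undiagnosed patients carry no
    table rows).  ``mechanisms`` optionally adds a structural-mechanism
    breakdown over missense verdicts.
    """
    n = n_patients if n_patients is not None else len(results)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    with_findings = [r for r in results if r.has_findings]
    distinct: dict[tuple[str, str], VariantRecord] = {}
    for r in table.rows:
        distinct.setdefault(r.variant_key(), r)
    reclass = reclassification_report(table)
    mech_breakdown: dict[str, tuple[int, float]] = {}
    if mechanisms:
        missense = [m for m in mechanisms if m.label is not Mechanism.LOF]
        for label in Mechanism:
            if label is Mechanism.LOF:
                continue
            k = sum(1 for m in missense if m.label is label)
            mech_breakdown[label.value] = (k, 100.0 * k / len(missense) if missense else 0.0)
    return CohortSummary(
        n_patients=n,
        n_with_findings=len(with_findings),
        findings_rate_percent=100.0 * len(with_findings) / n,
        n_diagnostic=sum(1 for r in results if r.diagnostic),
        n_variants=len(distinct),
        n_novel=sum(1 for v in distinct.values() if v.novel),
        n_prior_clinvar=sum(1 for v in distinct.values() if v.prior_assertion is not None),
        n_reclassified=reclass.n_changed,
        reclassified_percent=reclass.percent_changed,
        mechanism_breakdown=mech_breakdown,
    )
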