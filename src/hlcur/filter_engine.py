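"""Candidate-variant filtering: gene panel, consequence class, MAF.

Reduces an annotated variant list to candidate disease variants the way
a deafness in-silico panel screen does: keep variants in panel genes,
keep protein-relevant consequence classes (missense, nonsense,
frameshift, in-frame indel, splice site), and apply inheritance-aware
minor-allele-frequency cutoffs — MAF <= 0.01 for recessive and <= 0.005
for dominant candidate alleles (both inclusive).  Variants with no
population frequency cannot be excluded on frequency and are kept with
a flag.  All three filters are order-independent and idempotent; every
exclusion is logged with a reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .io_core import VariantTable
from .variant_domain import Consequence, InheritanceModel, InheritanceMode

log = logging.getLogger(__name__)

DEFAULT_KEPT_CONSEQUENCES = frozenset({
    Consequence.MISSENSE,
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.INFRAME_INDEL,
    Consequence.SPLICE_SITE,
})


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class GenePanel:
    genes: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    @classmethod
    def from_file(cls, path: Union[str, Path], name: Optional[str] = None) -> "GenePanel":
        """Load a one-symbol-per-line panel file ('#' comments allowed)."""
        path = Path(path)
        genes = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    genes.add(line.upper())
        return cls(frozenset(genes), name or path.stem)


@dataclass(frozen=True)
class FilterConfig:
    maf_recessive: float = 0.01
    maf_dominant: float = 0.005
    kept_consequences: frozenset[Consequence] = DEFAULT_KEPT_CONSEQUENCES

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_dominant <= self.maf_recessive <= 1.0:
            raise FilterError(
                "require 0 <= maf_dominant <= maf_recessive <= 1, got "
                f"{self.maf_dominant} / {self.maf_recessive}"
            )


def _log_stage(stage: str, n_in: int, n_kept: int, reasons: Iterable[str]) -> None:
    excluded = n_in - n_kept
    log.info("%s: %d in, %d kept, %d excluded%s", stage, n_in, n_kept, excluded,
             f" ({'; '.join(sorted(set(reasons)))})" if excluded else "")


def filter_by_panel(table: VariantTable, panel: GenePanel) -> VariantTable:
    """Keep rows whose gene is in the panel."""
    if panel.size == 0:
        raise FilterError("refusing to filter with an empty gene panel")
    kept = [r for r in table.rows if r.gene in panel]
    _log_stage(f"panel[{panel.name}]", len(table.rows), len(kept),
               (f"gene not in {panel.name}" for _ in range(1)))
    return table.subset(kept)


def filter_by_consequence(
    table: VariantTable, config: FilterConfig = FilterConfig()
) -> VariantTable:
    """Keep rows whose consequence class is in the kept set."""
    kept = [r for r in table.rows if r.consequence in config.kept_consequences]
    _log_stage("consequence", len(table.rows), len(kept), ["consequence class"])
    return table.subset(kept)


def filter_by_maf(
    table: VariantTable,
    model: Optional[InheritanceModel],
    config: FilterConfig = FilterConfig(),
) -> VariantTable:
    """Keep rows at or below the inheritance-appropriate MAF threshold.

    When the case's inheritance model is unknown the looser recessive
    threshold is applied (logged), to avoid false exclusion.  Rows with
    no frequency are kept and flagged ``af_absent``.
    """
    if model is None:
        log.info("maf: inheritance model unknown, applying recessive threshold")
        threshold = config.maf_recessive
    elif model.mode is InheritanceMode.AUTOSOMAL_DOMINANT:
        threshold = config.maf_dominant
    else:
        threshold = config.maf_recessive
    kept = []
    n_absent = 0
    for r in table.rows:
        if r.af_global is None:
            r.extra["af_absent"] = True
            n_absent += 1
            kept.append(r)
        elif r.af_global <= threshold:
            kept.append(r)
    _log_stage(f"maf<= {threshold}", len(table.rows), len(kept), ["MAF above threshold"])
    if n_absent:
        log.info("maf: %d rows kept with AF absent flag", n_absent)
    return table.subset(kept)


def apply_all(
    table: VariantTable,
    panel: GenePanel,
    model: Optional[InheritanceModel],
    config: FilterConfig = FilterConfig(),
) -> VariantTable:
    """panel ∘ consequence ∘ MAF (order-invariant by construction)."""
    return filter_by_maf(
        filter_by_consequence(filter_by_panel(table, panel), config), model, config
    )
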