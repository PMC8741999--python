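"""ACMG/AMP evidence parsing and five-tier rule combination.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) carry a
default strength given by their family (VeryStrong, Strong, Moderate,
Supporting, Standalone) and may be re-weighted with a suffix modifier,
the mechanism the ClinGen Hearing Loss Expert Panel uses to tune the
generic rules to deafness genes (e.g. ``PM3_VS`` counts the in-trans
criterion at VeryStrong, ``BS1_Sup`` downgrades the frequency criterion
to Supporting).

:func:`combine` applies categorical rule combination, Richards-style,
with the hearing-loss panel's additional Likely-Pathogenic combination
(1 Moderate + >=3 Supporting).  The point-based (Tavtigian) system is
deliberately not used: the inputs are criteria strings, not points.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .variant_domain import PriorAssertion, Tier, VariantRecord

log = logging.getLogger(__name__)


class EvidenceStrength(enum.IntEnum):
    """Ordered evidence weights (Standalone is the BA1-only top weight)."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STANDALONE = 5


class Direction(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


_BASES_PATHOGENIC = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
_BASES_BENIGN = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
VALID_BASES = frozenset(_BASES_PATHOGENIC + _BASES_BENIGN)

_FAMILY_DEFAULTS = {
    "PVS": EvidenceStrength.VERY_STRONG,
    "PS": EvidenceStrength.STRONG,
    "PM": EvidenceStrength.MODERATE,
    "PP": EvidenceStrength.SUPPORTING,
    "BA": EvidenceStrength.STANDALONE,
    "BS": EvidenceStrength.STRONG,
    "BP": EvidenceStrength.SUPPORTING,
}

# Modifier dialects seen in curation tables.  "_S" always means Strong
# (PVS1_S is a downgrade to Strong, PP1_S an upgrade), never Supporting.
_MODIFIERS = {
    "SUP": EvidenceStrength.SUPPORTING,
    "SUPPORTING": EvidenceStrength.SUPPORTING,
    "P": EvidenceStrength.SUPPORTING,
    "M": EvidenceStrength.MODERATE,
    "MOD": EvidenceStrength.MODERATE,
    "MODERATE": EvidenceStrength.MODERATE,
    "S": EvidenceStrength.STRONG,
    "STRONG": EvidenceStrength.STRONG,
    "VS": EvidenceStrength.VERY_STRONG,
    "VERYSTRONG": EvidenceStrength.VERY_STRONG,
}


class EvidenceParseError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceCode:
    base: str
    applied_strength: EvidenceStrength

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise EvidenceParseError(f"unknown evidence base {self.base!r}")

    @property
    def direction(self) -> Direction:
        return Direction.PATHOGENIC if self.base.startswith("P") else Direction.BENIGN

    @property
    def default_strength(self) -> EvidenceStrength:
        return _FAMILY_DEFAULTS[_family(self.base)]

    def with_strength(self, strength: EvidenceStrength) -> "EvidenceCode":
        return replace(self, applied_strength=strength)

    def token(self) -> str:
        if self.applied_strength == self.default_strength:
            return self.base
        suffix = {
            EvidenceStrength.SUPPORTING: "Sup",
            EvidenceStrength.MODERATE: "M",
            EvidenceStrength.STRONG: "S",
            EvidenceStrength.VERY_STRONG: "VS",
            EvidenceStrength.STANDALONE: "SA",
        }[self.applied_strength]
        return f"{self.base}_{suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def _family(base: str) -> str:
    m = re.match(r"([A-Z]+)", base)
    assert m is not None
    return m.group(1)


def code(base: str, strength: Optional[EvidenceStrength] = None) -> EvidenceCode:
    """Build an EvidenceCode at default or explicit strength."""
    c = EvidenceCode(base, _FAMILY_DEFAULTS[_family(base)] if base in VALID_BASES else EvidenceStrength.SUPPORTING)
    return c if strength is None else c.with_strength(strength)


def parse_code(token: str) -> EvidenceCode:
    """Parse one evidence token such as ``PM3_VS`` or ``PP1_Supporting``.

    A bare base takes its family's default strength.  Unknown bases or
    modifiers raise :class:`EvidenceParseError` naming the token.
    """
    tok = token.strip()
    if not tok:
        raise EvidenceParseError("empty evidence token")
    parts = tok.split("_", 1)
    base = parts[0].upper()
    if base not in VALID_BASES:
        raise EvidenceParseError(f"unknown evidence code {token!r}")
    if len(parts) == 1:
        return code(base)
    modifier = parts[1].strip().upper().replace("_", "")
    if modifier not in _MODIFIERS:
        raise EvidenceParseError(f"unknown strength modifier in {token!r}")
    return code(base, _MODIFIERS[modifier])


def parse_codes(text: str) -> list[EvidenceCode]:
    """Parse a comma/space/semicolon-separated evidence string."""
    tokens = [t for t in re.split(r"[,;\s]+", text.strip()) if t and t != "-"]
    return [parse_code(t) for t in tokens]


def _bucket(codes: Iterable[EvidenceCode]) -> tuple[Counter, Counter]:
    path: Counter = Counter()
    benign: Counter = Counter()
    for c in codes:
        (path if c.direction is Direction.PATHOGENIC else benign)[c.applied_strength] += 1
    return path, benign


def _pathogenic_combination(vs: int, s: int, m: int, p: int) -> bool:
    if vs >= 2:
        return True
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2):
        return True
    if s >= 2:
        return True
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return True
    return False


def _likely_pathogenic_combination(vs: int, s: int, m: int, p: int) -> bool:
    # last clause (1 Moderate + >=3 Supporting) is the hearing-loss
    # panel's addition to the generic rule set
    return (
        (vs >= 1 and m >= 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 3)
    )


def combine(codes: Iterable[EvidenceCode]) -> Tier:
    """Combine evidence codes into a five-tier classification.

    Each code counts at its *applied* strength, so panel-modified codes
    (PM3_VS, PP1_S, BS1_Sup, ...) move between buckets.  BA1 is
    stand-alone Benign and overrides everything.  Benign evidence whose
    combined weight does not itself reach LikelyBenign/Benign does not
    force VUS; when both a pathogenic and a benign combination are
    satisfied the result is VUS (conflict), except under BA1.
    """
    codes = list(codes)
    path, benign = _bucket(codes)

    if benign[EvidenceStrength.STANDALONE] >= 1:  # BA1: absolute
        return Tier.BENIGN

    vs = path[EvidenceStrength.VERY_STRONG] + path[EvidenceStrength.STANDALONE]
    s = path[EvidenceStrength.STRONG]
    m = path[EvidenceStrength.MODERATE]
    p = path[EvidenceStrength.SUPPORTING]
    bs = benign[EvidenceStrength.STRONG] + benign[EvidenceStrength.VERY_STRONG]
    bp = benign[EvidenceStrength.SUPPORTING] + benign[EvidenceStrength.MODERATE]

    pathogenic = _pathogenic_combination(vs, s, m, p)
    likely_pathogenic = pathogenic or _likely_pathogenic_combination(vs, s, m, p)
    benign_tier = bs >= 2
    likely_benign = benign_tier or (bs == 1 and bp >= 1) or bp >= 2

    if likely_pathogenic and likely_benign:
        return Tier.VUS
    if pathogenic:
        return Tier.PATHOGENIC
    if likely_pathogenic:
        return Tier.LIKELY_PATHOGENIC
    if benign_tier:
        return Tier.BENIGN
    if likely_benign:
        return Tier.LIKELY_BENIGN
    return Tier.VUS


def classify_record(record: VariantRecord) -> Tier:
    if not record.evidence:
        record.extra["no_evidence"] = True
        return Tier.VUS
    return combine(record.evidence)


def classify_table(table) -> None:
    """Attach a curated tier to every row of a VariantTable (in place).

    Rows without evidence codes become VUS with a ``no_evidence`` flag.
    The tier is stored in ``row.extra['tier']``.
    """
    n_no_evidence = 0
    for row in table.rows:
        tier = classify_record(row)
        row.extra["tier"] = tier
        n_no_evidence += int(row.extra.get("no_evidence", False))
    log.info(
        "classified %d rows (%d without evidence -> VUS)",
        len(table.rows),
        n_no_evidence,
    )


_PRIOR_SINGLE = {
    PriorAssertion.P: Tier.PATHOGENIC,
    PriorAssertion.LP: Tier.LIKELY_PATHOGENIC,
    PriorAssertion.VUS: Tier.VUS,
    PriorAssertion.LB: Tier.LIKELY_BENIGN,
    PriorAssertion.B: Tier.BENIGN,
}


@dataclass
class ReclassificationReport:
    n_prior_asserted: int
    n_changed: int
    percent_changed: Optional[float]  # full precision; render rounds
    changed_keys: list[tuple[str, str, str]]

    @property
    def percent_changed_printed(self) -> Optional[int]:
        if self.percent_changed is None:
            return None
        return round(self.percent_changed)


def reclassification_report(table) -> ReclassificationReport:
    """Compare curated tiers against prior database assertions.

    A prior single tier counts as changed iff the curated tier differs.
    Dual assertions (Pathogenic/Likely pathogenic) and Conflicting
    Interpretations count as changed whenever curation yields any single
    tier, since curation resolves them.
    """
    n_prior = 0
    changed: list[tuple[str, str, str]] = []
    for row in table.rows:
        if row.prior_assertion is None:
            continue
        n_prior += 1
        tier = row.extra.get("tier") or classify_record(row)
        prior = row.prior_assertion
        if prior in _PRIOR_SINGLE:
            if _PRIOR_SINGLE[prior] is not tier:
                changed.append(row.key())
        else:  # dual or conflicting: resolved by curation
            changed.append(row.key())
    pct = 100.0 * len(changed) / n_prior if n_prior else None
    if pct is None:
        log.info("reclassification: no prior assertions present")
    return ReclassificationReport(n_prior, len(changed), pct, changed)
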