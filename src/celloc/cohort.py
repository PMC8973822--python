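"""Rare-variant carrier arithmetic for a case/control cohort.

Implements the descriptive statistics layer of a rare-variant screen:
minor-allele-frequency rarity filtering, HGVS-string-driven variant
classification (missense / indel / splice / premature-termination),
carrier-frequency reporting, 2x2 contingency testing (Fisher exact with
Woolf confidence interval) and compound-carrier counting.

Counting convention: per-class tallies count variant-carriage occurrences
(an individual carrying two missense variants contributes two), which is
how screened-cohort variant frequencies are conventionally reported;
``multi_variant_carriers`` counts individuals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "VariantRecord",
    "CarrierTable",
    "ContingencyResult",
    "filter_rare",
    "classify_variant",
    "carrier_frequency",
    "contingency_test",
    "multi_variant_carriers",
    "tally_carriers",
]

VARIANT_CLASSES = ("missense", "indel", "splice", "ptc")


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    cdna_hgvs: str
    protein_hgvs: str = ""
    variant_class: str = ""
    maf_gnomad_nfe: Optional[float] = None  # percent
    maf_evs: Optional[float] = None
    maf_1kg: Optional[float] = None
    in_excluded_region: bool = False  # segmental dup / repeat / homopolymer
    predictor_scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf_gnomad_nfe", "maf_evs", "maf_1kg"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] percent")

    @property
    def mafs(self) -> list[float]:
        return [v for v in (self.maf_gnomad_nfe, self.maf_evs, self.maf_1kg)
                if v is not None]


@dataclass
class CarrierTable:
    cohort: str  # "patients" or "controls"
    cohort_size: int
    carriers_by_class: dict[str, int]
    carriers_any: int  # total variant-carriage occurrences across classes
    multi_variant_carriers: int  # individuals with >= 2 distinct variants

    def __post_init__(self) -> None:
        if self.carriers_any > sum(self.carriers_by_class.values()):
            raise ValueError("carriers_any exceeds per-class total")


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    ci95: tuple[float, float]
    p_two_sided: float
    method: str
    continuity_corrected: bool = False


# ---------------------------------------------------------------------------
# rarity filter

def filter_rare(variants: Iterable[VariantRecord],
                maf_cutoff: float = 1.0) -> list[VariantRecord]:
    """Keep variants rare in every population database they appear in.

    A variant passes when it is not in an excluded (segmental-duplication /
    repeat / homopolymer) region and every available MAF is <= the cutoff
    (inclusive); variants absent from all databases pass — absence is itself
    evidence of rarity.
    """
    if not (0.0 < maf_cutoff <= 100.0):
        raise ValueError("maf_cutoff must be in (0, 100] percent")
    return [v for v in variants
            if not v.in_excluded_region
            and all(m <= maf_cutoff for m in v.mafs)]


# ---------------------------------------------------------------------------
# HGVS classification

_INTRONIC = re.compile(r"c\.[*\d]+([+-])(\d+)")
_CDNA_INDEL = re.compile(r"(del|dup|ins)", re.IGNORECASE)
_CDNA_SUB = re.compile(r"c\.[*\d+-]+\s*[ACGT]\s*>\s*[ACGT]", re.IGNORECASE)
_PROT_STOP = re.compile(r"(\*|\bTer\b|X$)")
_PROT_MISSENSE = re.compile(
    r"p\.\(?([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])\)?$")


def classify_variant(cdna_hgvs: str, protein_hgvs: str = "") -> str:
    """Assign a variant class from its HGVS strings alone.

    Rules: intronic offset beyond the canonical +/-1,2 dinucleotide ->
    ``splice`` (canonical-site changes are ``ptc``-class, as splice-site
    disruption truncates the product); del/dup/ins -> ``indel`` (including
    frameshifts); a substitution creating a stop -> ``ptc``; a substitution
    with an amino-acid exchange -> ``missense``.
    """
    cdna = (cdna_hgvs or "").replace(" ", "")
    prot = (protein_hgvs or "").replace(" ", "")

    m = _INTRONIC.match(cdna)
    if m and not _CDNA_INDEL.search(cdna):
        offset = int(m.group(2))
        return "ptc" if offset <= 2 else "splice"
    if _CDNA_INDEL.search(cdna):
        return "indel"
    if _CDNA_SUB.match(cdna):
        if prot and _PROT_STOP.search(prot):
            return "ptc"
        if _PROT_MISSENSE.match(prot):
            mm = _PROT_MISSENSE.match(prot)
            if mm.group(1) != mm.group(3):
                return "missense"
        raise ValueError(
            f"cannot classify substitution {cdna_hgvs!r} / {protein_hgvs!r}")
    raise ValueError(f"unparsable HGVS: {cdna_hgvs!r}")


# ---------------------------------------------------------------------------
# frequencies

def round_half_up(x: float, decimals: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{decimals}"),
                                           rounding=ROUND_HALF_UP))


def carrier_frequency(carriers: int, cohort_size: int,
                      decimals: int = 2) -> tuple[float, Fraction]:
    """Carrier frequency as a percentage (rounded half-up) + the exact ratio."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be > 0")
    if not (0 <= carriers <= cohort_size):
        raise ValueError("carriers must be in [0, cohort_size]")
    exact = Fraction(100 * carriers, cohort_size)
    return round_half_up(carriers * 100.0 / cohort_size, decimals), exact


# ---------------------------------------------------------------------------
# contingency

def contingency_test(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Fisher exact test (two-sided, minimum-likelihood rule) on
    [[a, b], [c, d]] with odds ratio and Woolf logit 95% CI.

    A 0.5 Haldane–Anscombe correction is applied to the OR and CI (flagged)
    when any cell is zero; the p-value is always exact.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be >= 0")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("zero margin: test undefined")

    p = _fisher_two_sided(a, b, c, d)

    corrected = any(x == 0 for x in cells)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = map(float, cells)
    orr = (a_ * d_) / (b_ * c_)
    se_log = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    lo = float(np.exp(np.log(orr) - 1.959963984540054 * se_log))
    hi = float(np.exp(np.log(orr) + 1.959963984540054 * se_log))
    return ContingencyResult(table=cells, odds_ratio=float(orr),
                             ci95=(lo, hi), p_two_sided=p,
                             method="fisher-exact-two-sided",
                             continuity_corrected=corrected)


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum hypergeometric probabilities <= that of the observed table."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = sps.hypergeom(n, row1, col1)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    # tolerance for ties, as in the standard minimum-likelihood convention
    p = probs[probs <= p_obs * (1 + 1e-7)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# rosters

def multi_variant_carriers(roster: Mapping[str, Sequence[str]]) -> int:
    """Number of individuals carrying >= 2 distinct variants."""
    for ind, vs in roster.items():
        if not vs:
            raise ValueError(f"individual {ind!r} has an empty variant list")
    return sum(1 for vs in roster.values() if len(set(vs)) >= 2)


def tally_carriers(
    roster: Mapping[str, Sequence[str]],
    variant_classes: Mapping[str, str],
    cohort: str,
    cohort_size: int,
    count_classes: Sequence[str] = ("missense", "splice", "indel"),
) -> CarrierTable:
    """Build a CarrierTable from an individual -> variants roster.

    ``variant_classes`` maps variant_id to class. Classes outside
    ``count_classes`` (e.g. ptc partners of compound carriers) appear in the
    roster but are excluded from the occurrence tallies.
    """
    by_class = {cls: 0 for cls in count_classes}
    for vs in roster.values():
        for v in set(vs):
            cls = variant_classes[v]
            if cls in by_class:
                by_class[cls] += 1
    any_count = sum(by_class.values())
    return CarrierTable(cohort=cohort, cohort_size=cohort_size,
                        carriers_by_class=by_class, carriers_any=any_count,
                        multi_variant_carriers=multi_variant_carriers(roster))
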