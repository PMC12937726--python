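"""Per-carrier modifier lookup, phenotype-reliability calls and cohort
description arithmetic (carrier frequencies, APOE summaries)."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .matrix import GenotypeMatrix
from .phenotyping import ACEPhenotype, HIGH_BINS, LOW_BINS
from .pqtl_screen import SummaryStatRecord

CALLS = ("concordant", "possible_false_positive", "possible_false_negative", "indeterminate")

APOE_GENOTYPES = ("ε2/ε2", "ε2/ε3", "ε2/ε4", "ε3/ε3", "ε3/ε4", "ε4/ε4", "unknown")
_E4_HET = frozenset({"ε2/ε4", "ε3/ε4"})
_E4_HOM = "ε4/ε4"
# ascii spellings tolerated on input
_APOE_ALIASES = {g.replace("ε", "e"): g for g in APOE_GENOTYPES}


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_apoe(genotype: str) -> str:
    """Canonical ε-spelling; unrecognized strings become ``unknown``."""
    g = genotype.strip()
    g = _APOE_ALIASES.get(g, g)
    return g if g in APOE_GENOTYPES else "unknown"


@dataclass
class ModifierHit:
    variant_id: str
    gene: str
    beta: float


@dataclass
class CarrierProfile:
    sample_id: str
    phenotype: ACEPhenotype | None = None
    modifier_hits: list[ModifierHit] = field(default_factory=list)
    apoe_genotype: str = "unknown"

    def __post_init__(self) -> None:
        self.apoe_genotype = normalize_apoe(self.apoe_genotype)


@dataclass
class ReliabilityCall:
    call: str
    evidence: list[ModifierHit] = field(default_factory=list)


def find_modifier_hits(
    matrix: GenotypeMatrix,
    sample_id: str,
    refined_list: Sequence[SummaryStatRecord],
) -> list[ModifierHit]:
    """Every refined-list variant this sample carries (het or hom), with its
    effect size.  Variants not on the list are never reported; variants on
    the list but absent from the matrix contribute nothing."""
    calls = matrix.sample_calls(sample_id)
    return [
        ModifierHit(variant_id=r.variant_id, gene=r.gene, beta=r.beta)
        for r in refined_list
        if calls.get(r.variant_id, 0) > 0
    ]


def call_phenotype_reliability(profile: CarrierProfile) -> ReliabilityCall:
    """Classify whether modifier carriage undermines the measured phenotype.

    No hits -> concordant.  A positive-effect hit in a sample binned normal
    or high means the measurement may overstate the subject's intrinsic
    level (possible false positive); a negative-effect hit in a low bin may
    understate it (possible false negative).  Hits whose sign does not
    oppose the observed bin -> indeterminate, as is an unknown bin.

    When both signs are present in an extreme bin, the call matching the
    bin-opposing sign wins and all hits are attached as evidence.
    """
    hits = profile.modifier_hits
    if not hits:
        return ReliabilityCall(call="concordant")
    bin_label = profile.phenotype.bin if profile.phenotype is not None else None
    if bin_label in HIGH_BINS and any(h.beta > 0 for h in hits):
        return ReliabilityCall(call="possible_false_positive", evidence=list(hits))
    if bin_label in LOW_BINS and any(h.beta < 0 for h in hits):
        return ReliabilityCall(call="possible_false_negative", evidence=list(hits))
    return ReliabilityCall(call="indeterminate", evidence=list(hits))


def carrier_frequency(n_carriers: float, n_subjects: float) -> int:
    """Carriers per 100,000 subjects, rounded half away from zero."""
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if n_carriers < 0 or n_carriers > n_subjects:
        raise ValueError("n_carriers must be in [0, n_subjects]")
    return int(_round_half_up(n_carriers / n_subjects * 100_000))


@dataclass
class ApoeSummary:
    n: int
    n_e4_hom: int
    n_e4_het: int
    n_neutral: int
    n_unknown: int
    pct_e4_hom: float
    pct_e4_het: float
    pct_neutral: float


def apoe_percent(count: int, total: int) -> float:
    """Percent of cohort at one-decimal half-up rounding; 0.0 on empty."""
    if total <= 0:
        return 0.0
    return _round_half_up(count / total * 100.0, 1)


def apoe_summary(profiles: Sequence[CarrierProfile]) -> ApoeSummary:
    """Counts and percents of ε4 homozygotes, ε4 heterozygotes and neutral
    genotypes (ε2/ε2, ε2/ε3, ε3/ε3) in the cohort."""
    n = len(profiles)
    hom = sum(1 for p in profiles if p.apoe_genotype == _E4_HOM)
    het = sum(1 for p in profiles if p.apoe_genotype in _E4_HET)
    unknown = sum(1 for p in profiles if p.apoe_genotype == "unknown")
    neutral = n - hom - het - unknown
    return ApoeSummary(
        n=n,
        n_e4_hom=hom,
        n_e4_het=het,
        n_neutral=neutral,
        n_unknown=unknown,
        pct_e4_hom=apoe_percent(hom, n),
        pct_e4_het=apoe_percent(het, n),
        pct_neutral=apoe_percent(neutral, n),
    )
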