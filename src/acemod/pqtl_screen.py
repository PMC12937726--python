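"""Filtering cascade over plasma-protein GWAS summary statistics.

The cascade: nominal significance + coding consequence + minimum absolute
effect size ("candidate filter"), an exome-wide Bonferroni short list, a
large-effect sublist, and refinement against control carriers with normal
phenotype.  Thresholds follow the source conventions: the effect-size floor
is inclusive, the Bonferroni and large-effect cuts are strict.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

CONSEQUENCES = (
    "missense",
    "stop_gained",
    "inframe_indel",
    "frameshift",
    "synonymous",
    "intronic",
    "other",
)

#: Consequence classes counted as protein-coding for the candidate filter.
DEFAULT_CODING_CLASSES = frozenset(
    {"missense", "stop_gained", "inframe_indel", "frameshift"}
)


@dataclass
class SummaryStatRecord:
    """One variant's pQTL statistics.

    ``beta`` is the per-allele effect on standardized blood protein level;
    negative means lower measured level.  ``maf`` is the folded minor allele
    frequency.  ``annotations`` is pass-through text (e.g. predictor scores).
    """

    variant_id: str
    gene: str
    consequence: str
    beta: float
    p_value: float
    maf: float
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ScreenThresholds:
    nominal_p: float = 0.05
    beta_abs_min: float = 0.350
    bonferroni_p: float = 3e-7
    large_beta_abs: float = 1.000
    coding_classes: frozenset[str] = DEFAULT_CODING_CLASSES

    def __post_init__(self) -> None:
        if not 0 < self.bonferroni_p < self.nominal_p <= 1:
            raise ValueError("need 0 < bonferroni_p < nominal_p <= 1")
        if not self.large_beta_abs > self.beta_abs_min > 0:
            raise ValueError("need large_beta_abs > beta_abs_min > 0")


def _well_formed(record: SummaryStatRecord) -> bool:
    try:
        return math.isfinite(record.beta) and math.isfinite(record.p_value) and (
            0 < record.p_value <= 1
        )
    except TypeError:
        return False


def filter_candidates(
    records: Sequence[SummaryStatRecord],
    thresholds: ScreenThresholds | None = None,
) -> list[SummaryStatRecord]:
    """Retain coding variants with p below nominal and |beta| at or above the
    floor.  Malformed records (non-finite beta or p) are skipped with a
    logged count.  Order-preserving and idempotent.
    """
    t = thresholds or ScreenThresholds()
    skipped = sum(1 for r in records if not _well_formed(r))
    if skipped:
        logger.warning("skipped %d malformed summary-stat records", skipped)
    return [
        r
        for r in records
        if _well_formed(r)
        and r.p_value < t.nominal_p
        and r.consequence in t.coding_classes
        and abs(r.beta) >= t.beta_abs_min
    ]


def bonferroni_select(
    records: Sequence[SummaryStatRecord],
    thresholds: ScreenThresholds | None = None,
) -> list[SummaryStatRecord]:
    """Exome-wide short list: strict ``p < bonferroni_p``."""
    t = thresholds or ScreenThresholds()
    selected = [r for r in records if _well_formed(r) and r.p_value < t.bonferroni_p]
    logger.info(
        "bonferroni_select: %d variants in %d genes",
        len(selected),
        len({r.gene for r in selected}),
    )
    return selected


def large_effect_subset(
    records: Sequence[SummaryStatRecord],
    thresholds: ScreenThresholds | None = None,
) -> list[SummaryStatRecord]:
    """Sublist with strictly ``|beta| > large_beta_abs``."""
    t = thresholds or ScreenThresholds()
    return [r for r in records if _well_formed(r) and abs(r.beta) > t.large_beta_abs]


@dataclass
class RefinementReport:
    retained: list[SummaryStatRecord]
    removed: list[SummaryStatRecord]
    #: variant id -> control sample ids whose carriage triggered removal
    evidence: dict[str, list[str]]
    n_controls_without_phenotype: int = 0


def refine_by_controls(
    records: Sequence[SummaryStatRecord],
    control_matrix: GenotypeMatrix,
    control_percents: Mapping[str, float],
    normal_range: tuple[float, float] = (50.0, 150.0),
) -> RefinementReport:
    """Drop every variant carried by at least one control whose corrected
    level lies inside ``normal_range`` (inclusive): such carriage means the
    variant does not perturb the level and its listing is an artifact.

    Controls missing from ``control_percents`` contribute no evidence and are
    counted in the report.  Missing genotypes are not carriage.  The retained
    list is a subset of the input, and re-applying the refinement is a no-op.
    """
    low, high = normal_range
    if not low < high:
        raise ValueError("normal_range must satisfy low < high")

    no_pheno = [s for s in control_matrix.sample_ids if s not in control_percents]
    if no_pheno:
        logger.warning(
            "%d control samples lack phenotype and are excluded as evidence",
            len(no_pheno),
        )
    informative = [
        i
        for i, s in enumerate(control_matrix.sample_ids)
        if s in control_percents and low <= control_percents[s] <= high
    ]

    carrier = control_matrix.carrier_mask()
    present = set(control_matrix.variant_ids)
    retained, removed, evidence = [], [], {}
    for rec in records:
        if rec.variant_id not in present:
            retained.append(rec)
            continue
        j = control_matrix.variant_index(rec.variant_id)
        hits = [control_matrix.sample_ids[i] for i in informative if carrier[i, j]]
        if hits:
            removed.append(rec)
            evidence[rec.variant_id] = hits
        else:
            retained.append(rec)
    return RefinementReport(
        retained=retained,
        removed=removed,
        evidence=evidence,
        n_controls_without_phenotype=len(no_pheno),
    )


@dataclass
class GeneSummary:
    n_variants: int
    n_genes: int
    per_gene: dict[str, int]
    n_cis: int
    n_singleton_trans: int
    cis_gene: str = "ACE"


def summarize_genes(
    records: Sequence[SummaryStatRecord], cis_gene: str = "ACE"
) -> GeneSummary:
    """Unique-gene count, per-gene variant counts, cis count and the number
    of non-cis genes represented by exactly one variant."""
    counts = Counter(r.gene for r in records)
    return GeneSummary(
        n_variants=len(records),
        n_genes=len(counts),
        per_gene=dict(counts),
        n_cis=counts.get(cis_gene, 0),
        n_singleton_trans=sum(
            1 for g, c in counts.items() if g != cis_gene and c == 1
        ),
        cis_gene=cis_gene,
    )
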