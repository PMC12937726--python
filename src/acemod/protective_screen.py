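"""High-vs-low group exclusive-variant screen with association statistics.

Genotype QC (call rate then folded MAF), the basic 1-df allelic chi-square
on 2x2 allele-count tables, a median-based genomic-inflation estimate,
Bonferroni adjustment, set-difference exclusivity, and the carrier-count
recurrence window that discards singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1DF_MEDIAN: float = 0.4549364


@dataclass
class AssociationResult:
    variant_id: str
    chi_square: float
    p_value: float
    odds_ratio: float | None = None
    adjusted_p: float | None = None


@dataclass(frozen=True)
class RecurrenceWindow:
    min_carriers: int = 3
    max_carriers: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.min_carriers <= self.max_carriers:
            raise ValueError("need 1 <= min_carriers <= max_carriers")


class RecurrentVariant(NamedTuple):
    variant_id: str
    carrier_count: int
    gene: str


@dataclass
class QCReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_retained: int


def variant_qc(
    matrix: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants with missing fraction above ``max_missing``, then
    variants whose folded MAF (over non-missing calls, two alleles per
    sample) is below ``min_maf`` — the MAF cut is inclusive at the bound.

    An all-removed result is an empty matrix with a warning, not an error.
    """
    if matrix.n_variants == 0:
        raise ValueError("empty matrix")
    miss = matrix.missing_fraction()
    pass_call = miss <= max_missing
    after_call = matrix.subset_variants(
        [v for v, ok in zip(matrix.variant_ids, pass_call) if ok]
    )
    maf = after_call.minor_allele_freq()
    pass_maf = maf >= min_maf
    retained = after_call.subset_variants(
        [v for v, ok in zip(after_call.variant_ids, pass_maf) if ok]
    )
    report = QCReport(
        n_input=matrix.n_variants,
        n_removed_call_rate=int((~pass_call).sum()),
        n_removed_maf=int((~pass_maf).sum()),
        n_retained=retained.n_variants,
    )
    if retained.n_variants == 0:
        logger.warning("variant_qc removed every variant")
    return retained, report


def chi_square_allelic(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """1-df chi-square without continuity correction for the allele table

        minor major
    high   a     b
    low    c     d

    Returns ``(chi_square, p_value)``; any zero margin gives (0, 1).
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _allele_tables(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant folded minor/major allele counts in the high and low groups."""
    hi = matrix.group_rows("high")
    lo = matrix.group_rows("low")
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both 'high' and 'low' groups must be non-empty")
    called = matrix.calls != -1
    dosage = np.where(called, np.maximum(matrix.calls, 0), 0).astype(np.int64)

    alt_hi = dosage[hi, :].sum(axis=0)
    alt_lo = dosage[lo, :].sum(axis=0)
    tot_hi = 2 * called[hi, :].sum(axis=0, dtype=np.int64)
    tot_lo = 2 * called[lo, :].sum(axis=0, dtype=np.int64)

    # fold on the pooled frequency so both groups count the same allele
    alt_all = alt_hi + alt_lo
    tot_all = tot_hi + tot_lo
    flip = alt_all * 2 > tot_all
    a = np.where(flip, tot_hi - alt_hi, alt_hi)
    c = np.where(flip, tot_lo - alt_lo, alt_lo)
    return a, tot_hi - a, c, tot_lo - c


def allelic_test(matrix: GenotypeMatrix) -> list[AssociationResult]:
    """Basic allelic association per variant: 2x2 minor/major x high/low
    allele-count table, chi-square without continuity correction, odds ratio
    ``ad/bc`` (undefined on zero cells).  Monomorphic variants and zero
    margins give chi-square 0, p 1."""
    a, b, c, d = _allele_tables(matrix)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.maximum(denom, 1), 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(denom > 0, pvals, 1.0)

    results = []
    for j, vid in enumerate(matrix.variant_ids):
        orr: float | None = None
        if min(a[j], b[j], c[j], d[j]) > 0:
            orr = float(a[j] * d[j] / (b[j] * c[j]))
        results.append(
            AssociationResult(
                variant_id=vid,
                chi_square=float(chi2[j]),
                p_value=float(pvals[j]),
                odds_ratio=orr,
            )
        )
    return results


def genomic_inflation(results: Sequence[AssociationResult]) -> float:
    """Genomic inflation factor: median observed chi-square over the 1-df
    null median.  Warns below 100 statistics, errors on an empty input."""
    if len(results) == 0:
        raise ValueError("no association results")
    if len(results) < 100:
        logger.warning(
            "genomic inflation estimated from only %d statistics", len(results)
        )
    med = float(np.median([r.chi_square for r in results]))
    return med / CHI2_1DF_MEDIAN


def bonferroni_adjust(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Attach ``adjusted_p = min(1, p * m)`` for ``m`` tests."""
    m = len(results)
    if m < 1:
        raise ValueError("need at least one test")
    return [replace(r, adjusted_p=min(1.0, r.p_value * m)) for r in results]


def exclusive_variants(matrix: GenotypeMatrix) -> list[str]:
    """Variants with at least one carrier in the high group and none in the
    low group.  Missing calls are not carriage."""
    hi = matrix.group_rows("high")
    lo = matrix.group_rows("low")
    carrier = matrix.carrier_mask()
    hi_any = carrier[hi, :].any(axis=0) if hi.size else np.zeros(matrix.n_variants, bool)
    lo_any = carrier[lo, :].any(axis=0) if lo.size else np.zeros(matrix.n_variants, bool)
    keep = hi_any & ~lo_any
    return [v for v, k in zip(matrix.variant_ids, keep) if k]


def recurrence_filter(
    matrix: GenotypeMatrix,
    exclusive: Sequence[str],
    window: RecurrenceWindow | None = None,
) -> list[RecurrentVariant]:
    """Keep exclusive variants whose high-group carrier count (individuals;
    a homozygote counts once) lies inside the window."""
    window = window or RecurrenceWindow()
    hi = matrix.group_rows("high")
    counts = matrix.carrier_counts(rows=hi)
    by_id = dict(zip(matrix.variant_ids, counts))
    out = []
    for vid in exclusive:
        k = int(by_id[vid])
        if window.min_carriers <= k <= window.max_carriers:
            out.append(
                RecurrentVariant(
                    variant_id=vid,
                    carrier_count=k,
                    gene=matrix.gene_of.get(vid, ""),
                )
            )
    return out


@dataclass
class ProtectiveScreenReport:
    qc: QCReport
    n_tested: int
    lambda_gc: float
    n_exclusive: int
    n_recurrent: int
    n_recurrent_genes: int
    maf_before_exclusive: bool


def run_protective_screen(
    matrix: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
    window: RecurrenceWindow | None = None,
    maf_before_exclusive: bool = False,
) -> tuple[list[AssociationResult], list[RecurrentVariant], ProtectiveScreenReport]:
    """Full chain: QC -> allelic test (+ inflation, adjustment) on the
    MAF-filtered matrix, exclusivity + recurrence on either the call-rate-
    filtered matrix (default: rare exclusives survive) or the MAF-filtered
    one (``maf_before_exclusive=True``)."""
    window = window or RecurrenceWindow()

    call_rate_only, _ = variant_qc(matrix, max_missing=max_missing, min_maf=0.0)
    qcd, report = variant_qc(matrix, max_missing=max_missing, min_maf=min_maf)

    results = bonferroni_adjust(allelic_test(qcd)) if qcd.n_variants else []
    lam = genomic_inflation(results) if results else float("nan")

    screen_matrix = qcd if maf_before_exclusive else call_rate_only
    exclusive = exclusive_variants(screen_matrix)
    recurrent = recurrence_filter(screen_matrix, exclusive, window)

    screen_report = ProtectiveScreenReport(
        qc=report,
        n_tested=len(results),
        lambda_gc=lam,
        n_exclusive=len(exclusive),
        n_recurrent=len(recurrent),
        n_recurrent_genes=len({r.gene for r in recurrent}),
        maf_before_exclusive=maf_before_exclusive,
    )
    return results, recurrent, screen_report
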