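"""Synthetic cohorts, assay panels, summary-statistic tables and genotype
matrices with the statistical structure the downstream screens assume.

The level model is multiplicative: a Hardy-Weinberg I/D genotype factor,
a linear allele-dosage term for the damaging mutation (one mutant allele
contributes ``mutant_allele_expr`` of a wild-type allele's output), and
mean-one log-normal assay noise.  With noise off every quantity is exact
closed-form arithmetic, which the unit tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .matrix import GenotypeMatrix, HET, HOM, MISSING, REF
from .phenotyping import DEFAULT_GENOTYPE_FACTORS, GENOTYPES, hwe_genotype_frequencies
from .pqtl_screen import SummaryStatRecord

__all__ = [
    "CohortConfig",
    "SimulatedIndividual",
    "PlantedEffect",
    "generate_cohort",
    "generate_assay_panel",
    "generate_pqtl_table",
    "generate_genotype_matrix",
]


@dataclass(frozen=True)
class CohortConfig:
    """All simulation parameters for one synthetic cohort.

    ``mutant_allele_expr`` (default 0.24) is calibrated so a noise-free
    heterozygote sits at 62% of the population mean after genotype
    correction; ``mutant_5b3_multiplier`` (default 4.6) puts the noise-free
    heterozygote marker ratio at ~170% of control.
    """

    n_individuals: int = 1000
    d_allele_freq: float = 0.5
    genotype_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FACTORS)
    )
    mutant_allele_expr: float = 0.24
    carrier_freq: float = 0.015
    assay_cv: float = 0.12
    mutant_5b3_multiplier: float = 4.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for name in ("d_allele_freq", "mutant_allele_expr", "carrier_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.assay_cv < 0:
            raise ValueError("assay_cv must be non-negative")
        if self.mutant_5b3_multiplier <= 0:
            raise ValueError("mutant_5b3_multiplier must be positive")
        if any(self.genotype_factors.get(g, 0) <= 0 for g in GENOTYPES):
            raise ValueError("genotype_factors must be positive for II, ID, DD")

    @property
    def mean_factor(self) -> float:
        """HWE-weighted mean genotype factor at ``d_allele_freq``."""
        freqs = hwe_genotype_frequencies(self.d_allele_freq)
        return sum(freqs[g] * self.genotype_factors[g] for g in GENOTYPES)


@dataclass
class SimulatedIndividual:
    """One simulated subject: genotypes, latent level and assay activities."""

    sample_id: str
    id_genotype: str
    y215c_copies: int
    true_level: float
    assay_9b9: float | None = None
    assay_1g12: float | None = None
    assay_5b3: float | None = None


@dataclass(frozen=True)
class PlantedEffect:
    """A variant with a known signed effect on standardized protein level."""

    variant_id: str
    gene: str
    beta: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must be in (0, 1)")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _structural_level(ind: SimulatedIndividual, config: CohortConfig) -> float:
    """Noise-free level: genotype factor over mean factor times allele dosage."""
    wt = 2 - ind.y215c_copies
    dosage = (wt + config.mutant_allele_expr * ind.y215c_copies) / 2.0
    return 100.0 * config.genotype_factors[ind.id_genotype] / config.mean_factor * dosage


def generate_cohort(config: CohortConfig) -> list[SimulatedIndividual]:
    """Draw a cohort of ``config.n_individuals`` subjects.

    Genotypes follow Hardy-Weinberg at ``d_allele_freq``; mutant copies are
    drawn with ``carrier_freq`` as the allele frequency (so homozygotes occur
    at its square).  ``true_level`` is the structural level times one noise
    draw.  Identical seeds give byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    freqs = hwe_genotype_frequencies(config.d_allele_freq)
    genotypes = rng.choice(GENOTYPES, size=n, p=[freqs[g] for g in GENOTYPES])

    q = config.carrier_freq
    copies = rng.choice([0, 1, 2], size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])

    noise = _lognormal_noise(rng, config.assay_cv, n)

    width = max(4, len(str(n)))
    cohort = []
    for i in range(n):
        ind = SimulatedIndividual(
            sample_id=f"S{i + 1:0{width}d}",
            id_genotype=str(genotypes[i]),
            y215c_copies=int(copies[i]),
            true_level=0.0,
        )
        ind.true_level = _structural_level(ind, config) * float(noise[i])
        cohort.append(ind)
    return cohort


def generate_assay_panel(
    individuals: Sequence[SimulatedIndividual], config: CohortConfig
) -> list[SimulatedIndividual]:
    """Fill in the three antibody activities for every individual.

    9B9 and 1G12 read total protein (wild-type and mutant weighted equally);
    5B3 weights the mutant contribution by ``mutant_5b3_multiplier``.  Each
    assay gets an independent noise draw; noise streams are seeded one step
    away from the cohort stream so the two generators never collide.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(individuals)
    noise = {
        name: _lognormal_noise(rng, config.assay_cv, n)
        for name in ("assay_9b9", "assay_1g12", "assay_5b3")
    }
    out = []
    for i, ind in enumerate(individuals):
        base = _structural_level(ind, config)
        wt = 2 - ind.y215c_copies
        mutant_term = config.mutant_allele_expr * ind.y215c_copies
        factor = config.genotype_factors[ind.id_genotype] / config.mean_factor
        base_5b3 = 100.0 * factor * (wt + config.mutant_5b3_multiplier * mutant_term) / 2.0
        out.append(
            replace(
                ind,
                assay_9b9=base * float(noise["assay_9b9"][i]),
                assay_1g12=base * float(noise["assay_1g12"][i]),
                assay_5b3=base_5b3 * float(noise["assay_5b3"][i]),
            )
        )
    return out


_NULL_CONSEQUENCES = (
    "missense",
    "synonymous",
    "intronic",
    "other",
    "stop_gained",
    "inframe_indel",
    "frameshift",
)


def _effect_se(maf: float, n_samples: int) -> float:
    """Standard error of a per-allele effect at the given allele frequency."""
    return 1.0 / math.sqrt(2.0 * n_samples * maf * (1.0 - maf))


def generate_pqtl_table(
    n_null: int,
    planted: Sequence[PlantedEffect],
    n_samples: int,
    seed: int,
) -> list[SummaryStatRecord]:
    """Summary-statistic table mixing uniform-p null variants with planted
    effects whose p-values are consistent with beta, carrier fraction and
    sample size.

    Null betas are drawn as ``z * se`` with ``z ~ N(0,1)``, which makes the
    null p-value distribution exactly uniform.  The output order is a
    deterministic shuffle of nulls and planted records.
    """
    if n_null < 0:
        raise ValueError("n_null must be non-negative")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    records: list[SummaryStatRecord] = []

    mafs = rng.uniform(0.05, 0.5, size=n_null)
    zs = rng.standard_normal(n_null)
    for i in range(n_null):
        se = _effect_se(float(mafs[i]), n_samples)
        z = float(zs[i])
        records.append(
            SummaryStatRecord(
                variant_id=f"null{i + 1:06d}",
                gene=f"NULLG{i + 1:05d}",
                consequence=_NULL_CONSEQUENCES[i % len(_NULL_CONSEQUENCES)],
                beta=z * se,
                p_value=float(stats.chi2.sf(z * z, df=1)),
                maf=float(mafs[i]),
            )
        )

    for eff in planted:
        maf = min(eff.carrier_fraction / 2.0, 0.5)
        se = _effect_se(maf, n_samples)
        z = eff.beta / se
        # strong effects underflow chi2.sf to exactly 0; keep p in (0, 1]
        p = max(float(stats.chi2.sf(z * z, df=1)), 5e-324)
        records.append(
            SummaryStatRecord(
                variant_id=eff.variant_id,
                gene=eff.gene,
                consequence="missense",
                beta=eff.beta,
                p_value=p,
                maf=maf,
            )
        )

    order = rng.permutation(len(records))
    return [records[i] for i in order]


def generate_genotype_matrix(
    n_high: int,
    n_low: int,
    n_background_variants: int,
    planted_exclusive: int,
    recurrence_range: tuple[int, int] = (3, 5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Grouped genotype matrix with planted high-group-exclusive variants.

    Background variants are guaranteed at least one carrier in each group so
    that, with no missingness, the exclusivity screen recovers exactly the
    planted set.  Each planted variant is carried by ``k`` high-group
    individuals with ``k`` uniform in ``recurrence_range`` (mostly het, the
    occasional hom, matching real recurrence grids).
    """
    if n_high <= 0 or n_low <= 0:
        raise ValueError("both groups must be non-empty")
    lo, hi = recurrence_range
    if not 1 <= lo <= hi:
        raise ValueError("recurrence_range must satisfy 1 <= min <= max")
    if hi > n_high:
        raise ValueError(
            f"recurrence max {hi} exceeds the high-group size {n_high}"
        )
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    sample_ids = [f"H{i + 1:03d}" for i in range(n_high)] + [
        f"L{i + 1:03d}" for i in range(n_low)
    ]
    group = {s: ("high" if s.startswith("H") else "low") for s in sample_ids}
    n_samples = n_high + n_low

    variant_ids: list[str] = []
    gene_of: dict[str, str] = {}
    columns: list[np.ndarray] = []

    for b in range(n_background_variants):
        vid = f"bg{b + 1:05d}"
        freq = rng.uniform(0.15, 0.5)
        col = rng.binomial(2, freq, size=n_samples).astype(np.int8)
        # force carriage in both groups so nothing background is exclusive
        if not (col[:n_high] > 0).any():
            col[rng.integers(0, n_high)] = HET
        if not (col[n_high:] > 0).any():
            col[n_high + rng.integers(0, n_low)] = HET
        variant_ids.append(vid)
        gene_of[vid] = f"BGENE{b + 1:05d}"
        columns.append(col)

    for e in range(planted_exclusive):
        vid = f"ex{e + 1:05d}"
        k = int(rng.integers(lo, hi + 1))
        carriers = rng.choice(n_high, size=k, replace=False)
        col = np.zeros(n_samples, dtype=np.int8)
        states = np.where(rng.random(k) < 0.1, HOM, HET).astype(np.int8)
        col[carriers] = states
        variant_ids.append(vid)
        gene_of[vid] = f"EGENE{e + 1:05d}"
        columns.append(col)

    if columns:
        calls = np.column_stack(columns)
    else:
        calls = np.zeros((n_samples, 0), dtype=np.int8)

    if missing_rate > 0 and calls.size:
        drop = rng.random(calls.shape) < missing_rate
        calls = np.where(drop, np.int8(MISSING), calls)

    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        calls=calls,
        group=group,
        gene_of=gene_of,
    )
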