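"""Normalization, genotype correction and bin classification of blood ACE levels.

Raw immunoprecipitated activities are expressed as percent of a control pool,
rescaled for the intronic insertion/deletion (I/D) genotype, and bucketed into
five level classes.  A ratio of two N-domain antibody signals serves as a
marker for the circulating mutant enzyme.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

GENOTYPES = ("II", "ID", "DD")

#: Default multiplicative genotype effects on blood ACE level.  The DD/II
#: ratio of 1.66 encodes the reported 66% excess in DD carriers.
DEFAULT_GENOTYPE_FACTORS: Mapping[str, float] = {"II": 1.00, "ID": 1.33, "DD": 1.66}

#: Left-closed bin edges; values below 50 are "blue", 200 and above are "red".
BIN_EDGES: tuple[float, ...] = (50.0, 80.0, 120.0, 200.0)
BIN_LABELS: tuple[str, ...] = ("blue", "yellow", "gray", "orange", "red")
LOW_BINS = frozenset({"blue", "yellow"})
HIGH_BINS = frozenset({"gray", "orange", "red"})

#: Binding-ratio percent at or above which a sample is called mutant-marker
#: positive: midway between the control ratio (100%) and the lowest ratio
#: observed in mutant pools (~170%).
DEFAULT_MARKER_THRESHOLD: float = 150.0


def hwe_genotype_frequencies(d_allele_freq: float) -> dict[str, float]:
    """Hardy-Weinberg genotype frequencies for the I/D polymorphism.

    ``d_allele_freq`` is the frequency of the D allele; returns frequencies
    for II, ID and DD.
    """
    if not 0.0 <= d_allele_freq <= 1.0:
        raise ValueError(f"d_allele_freq must be in [0, 1], got {d_allele_freq}")
    p = d_allele_freq
    return {"II": (1 - p) ** 2, "ID": 2 * p * (1 - p), "DD": p**2}


@dataclass(frozen=True)
class GenotypeModel:
    """Multiplicative I/D genotype model with an HWE-weighted reference mean."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FACTORS)
    )
    d_allele_freq: float = 0.5

    def __post_init__(self) -> None:
        missing = [g for g in GENOTYPES if g not in self.factors]
        if missing:
            raise ValueError(f"factors missing genotypes: {missing}")
        if any(self.factors[g] <= 0 for g in GENOTYPES):
            raise ValueError("genotype factors must be positive")
        if not self.factors["DD"] > self.factors["ID"] > self.factors["II"]:
            raise ValueError("factors must satisfy DD > ID > II")
        if not 0.0 <= self.d_allele_freq <= 1.0:
            raise ValueError("d_allele_freq must be in [0, 1]")

    @property
    def reference_mean(self) -> float:
        """HWE-weighted mean factor (the population anchor for correction)."""
        freqs = hwe_genotype_frequencies(self.d_allele_freq)
        return sum(freqs[g] * self.factors[g] for g in GENOTYPES)


@dataclass
class PhenotypeRecord:
    """One individual's genotypes and raw assay activities.

    Activities are in arbitrary fluorometric units; they only become
    comparable across samples after normalization to a control pool.
    """

    sample_id: str
    id_genotype: str = "unknown"
    y215c_copies: int = 0
    assay_9b9: float | None = None
    assay_1g12: float | None = None
    assay_5b3: float | None = None

    def __post_init__(self) -> None:
        if self.y215c_copies not in (0, 1, 2):
            raise ValueError("y215c_copies must be 0, 1 or 2")
        for name in ("assay_9b9", "assay_1g12", "assay_5b3"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass
class ACEPhenotype:
    """Normalized, genotype-corrected level with bin and marker annotations."""

    sample_id: str
    percent_of_control: float
    corrected_percent: float
    bin: str
    binding_ratio_percent: float | None = None
    mutant_marker_positive: bool = False
    genotype_corrected: bool = True


def normalize_to_control(activity: float, control_activities: Sequence[float]) -> float:
    """Express one activity as percent of the control-pool mean.

    Raises ``ValueError`` on an empty control set or non-positive values.
    """
    if len(control_activities) == 0:
        raise ValueError("control set is empty")
    if any(c <= 0 for c in control_activities):
        raise ValueError("control activities must all be positive")
    if activity <= 0:
        raise ValueError("activity must be positive")
    return activity / (sum(control_activities) / len(control_activities)) * 100.0


def correct_for_genotype(
    percent: float, genotype: str, model: GenotypeModel | None = None
) -> float:
    """Rescale a percent-of-control level for the I/D genotype.

    An individual exactly at its genotype-expected mean maps to 100.  Unknown
    genotypes are returned unchanged with a logged warning so that the sample
    can be flagged as uncorrected.
    """
    model = model or GenotypeModel()
    if genotype not in model.factors:
        logger.warning("unknown I/D genotype %r: level left uncorrected", genotype)
        return percent
    return percent * model.reference_mean / model.factors[genotype]


def classify_bin(corrected_percent: float) -> str:
    """Assign a corrected level to one of the five bins.

    Intervals are half-open, left-closed: [0,50) blue, [50,80) yellow,
    [80,120) gray, [120,200) orange, [200,inf) red.
    """
    if not math.isfinite(corrected_percent) or corrected_percent <= 0:
        raise ValueError(f"corrected percent must be positive, got {corrected_percent}")
    return BIN_LABELS[bisect.bisect_right(BIN_EDGES, corrected_percent)]


def compute_binding_ratio(
    assay_5b3_percent: float,
    assay_1g12_percent: float,
    threshold: float = DEFAULT_MARKER_THRESHOLD,
) -> tuple[float, bool]:
    """Mutant-marker ratio of two antibody signals, each already in percent
    of its own control.

    Returns ``(ratio_percent, flagged)`` where the flag is True at or above
    ``threshold``.
    """
    if assay_5b3_percent <= 0 or assay_1g12_percent <= 0:
        raise ValueError("both assay percents must be positive")
    ratio = assay_5b3_percent / assay_1g12_percent * 100.0
    return ratio, ratio >= threshold


def phenotype_record(
    record: PhenotypeRecord,
    controls: Mapping[str, Sequence[float]],
    model: GenotypeModel | None = None,
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD,
) -> ACEPhenotype:
    """Full per-sample phenotyping: normalize, correct, bin, marker ratio.

    ``controls`` maps assay name ("assay_9b9", ...) to the list of control
    activities for that antibody.  The 9B9 signal defines the level; the
    5B3/1G12 ratio is computed when both signals and controls are present.
    """
    model = model or GenotypeModel()
    if record.assay_9b9 is None:
        raise ValueError(f"sample {record.sample_id}: missing 9B9 activity")
    percent = normalize_to_control(record.assay_9b9, controls["assay_9b9"])
    corrected_flag = record.id_genotype in model.factors
    corrected = correct_for_genotype(percent, record.id_genotype, model)

    ratio: float | None = None
    flagged = False
    if (
        record.assay_5b3 is not None
        and record.assay_1g12 is not None
        and "assay_5b3" in controls
        and "assay_1g12" in controls
    ):
        p5b3 = normalize_to_control(record.assay_5b3, controls["assay_5b3"])
        p1g12 = normalize_to_control(record.assay_1g12, controls["assay_1g12"])
        ratio, flagged = compute_binding_ratio(p5b3, p1g12, marker_threshold)

    return ACEPhenotype(
        sample_id=record.sample_id,
        percent_of_control=percent,
        corrected_percent=corrected,
        bin=classify_bin(corrected),
        binding_ratio_percent=ratio,
        mutant_marker_positive=flagged,
        genotype_corrected=corrected_flag,
    )


def phenotype_cohort(
    records: Sequence[PhenotypeRecord],
    controls: Mapping[str, Sequence[float]],
    model: GenotypeModel | None = None,
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD,
) -> list[ACEPhenotype]:
    """Phenotype every record against a shared control set."""
    model = model or GenotypeModel()
    return [phenotype_record(r, controls, model, marker_threshold) for r in records]
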