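"""Sample-by-variant genotype matrix used by the carrier and protective screens.

Calls are stored as a compact int8 array with the encoding

    0  homozygous reference
    1  heterozygous
    2  homozygous alternate
   -1  missing call

Carriage (het or hom) is the unit of evidence everywhere downstream; allele
dosage only enters the allelic association test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

REF: int = 0
HET: int = 1
HOM: int = 2
MISSING: int = -1

_VALID_CALLS = frozenset({REF, HET, HOM, MISSING})


@dataclass
class GenotypeMatrix:
    """Carrier states for a set of samples across a set of variants.

    Parameters
    ----------
    sample_ids :
        Ordered, unique sample identifiers (rows of ``calls``).
    variant_ids :
        Ordered, unique variant identifiers (columns of ``calls``).
    calls :
        ``(n_samples, n_variants)`` int8 array with the module-level encoding.
    group :
        Optional map sample id -> ``"high"`` | ``"low"`` for case/control
        style screens.
    gene_of :
        Optional map variant id -> gene symbol.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    calls: np.ndarray
    group: dict[str, str] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D sample x variant array")
        if self.calls.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid call codes: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def variant_index(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def group_rows(self, label: str) -> np.ndarray:
        """Row indices of samples assigned to ``label``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group.get(s) == label],
            dtype=np.intp,
        )

    # -- per-variant summaries ------------------------------------------

    def carrier_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_variants)``: het or hom, missing is False."""
        return self.calls > REF

    def missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per variant."""
        return (self.calls == MISSING).mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        """Folded minor allele frequency per variant over non-missing calls.

        Each called sample contributes two alleles; variants with no called
        samples get MAF 0.
        """
        called = self.calls != MISSING
        dosage = np.where(called, np.maximum(self.calls, 0), 0)
        alt = dosage.sum(axis=0, dtype=np.int64)
        total = 2 * called.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        return np.minimum(freq, 1.0 - freq)

    def carrier_counts(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Number of carrier individuals per variant, optionally within rows."""
        mask = self.carrier_mask()
        if rows is not None:
            mask = mask[rows, :]
        return mask.sum(axis=0)

    # -- subsetting ------------------------------------------------------

    def subset_variants(self, keep: Sequence[str] | Iterable[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``keep`` variant ids (order preserved)."""
        keep_set = set(keep)
        idx = [j for j, v in enumerate(self.variant_ids) if v in keep_set]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[j] for j in idx],
            calls=self.calls[:, idx].copy(),
            group=dict(self.group),
            gene_of={v: g for v, g in self.gene_of.items() if v in keep_set},
        )

    def sample_calls(self, sample_id: str) -> Mapping[str, int]:
        """Call per variant for one sample."""
        row = self.calls[self.sample_index(sample_id), :]
        return dict(zip(self.variant_ids, (int(c) for c in row)))
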