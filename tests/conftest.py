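import numpy as np
import pytest

from acemod.matrix import GenotypeMatrix


@pytest.fixture
def default_model():
    from acemod import GenotypeModel

    return GenotypeModel()


def random_grouped_matrix(rng, n_samples=None, n_variants=None, missing=True):
    """Random grouped genotype matrix for oracle comparisons."""
    n_samples = n_samples or int(rng.integers(2, 65))
    n_variants = n_variants or int(rng.integers(1, 257))
    codes = [-1, 0, 1, 2] if missing else [0, 1, 2]
    probs = [0.05, 0.65, 0.2, 0.1] if missing else [0.7, 0.2, 0.1]
    calls = rng.choice(codes, size=(n_samples, n_variants), p=probs).astype(np.int8)
    sample_ids = [f"s{i}" for i in range(n_samples)]
    n_high = int(rng.integers(1, n_samples))
    group = {s: ("high" if i < n_high else "low") for i, s in enumerate(sample_ids)}
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=[f"v{j}" for j in range(n_variants)],
        calls=calls,
        group=group,
    )


def brute_force_exclusive(matrix):
    """Double-loop set-difference oracle for the exclusivity screen."""
    out = []
    for j, vid in enumerate(matrix.variant_ids):
        in_high = in_low = False
        for i, s in enumerate(matrix.sample_ids):
            if matrix.calls[i, j] > 0:
                if matrix.group.get(s) == "high":
                    in_high = True
                elif matrix.group.get(s) == "low":
                    in_low = True
        if in_high and not in_low:
            out.append(vid)
    return out
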