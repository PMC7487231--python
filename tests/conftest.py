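import numpy as np
import pytest

from trophicniche import FecalItemRecord, IsotopeRecord


@pytest.fixture
def two_sample_feces():
    """Two samples of one species: S1 = {A: 3 items/3 mm3, B: 1/1},
    S2 = {A: 1/1}."""
    return [
        FecalItemRecord("S1", "sp", "A", "fruit", 3, 3.0),
        FecalItemRecord("S1", "sp", "B", "insect", 1, 1.0),
        FecalItemRecord("S2", "sp", "A", "fruit", 1, 1.0),
    ]


@pytest.fixture
def random_feces():
    """A larger random fecal table for invariant checks (two species,
    several taxa, positive counts and volumes)."""
    rng = np.random.default_rng(42)
    taxa = [("figs", "fruit"), ("ants", "insect"), ("beetles", "insect"),
            ("seeds", "fruit"), ("spiders", "other")]
    records = []
    for sp, n_samples in [("sp1", 12), ("sp2", 7)]:
        for s in range(n_samples):
            k = rng.integers(1, len(taxa) + 1)
            for idx in rng.choice(len(taxa), size=k, replace=False):
                taxon, cat = taxa[idx]
                records.append(
                    FecalItemRecord(
                        f"{sp}-{s}", sp, taxon, cat,
                        int(rng.integers(1, 8)),
                        float(rng.uniform(0.2, 9.0)),
                    )
                )
    return records


@pytest.fixture
def gaussian_blood():
    """30 bivariate-normal individuals of one species in delta space."""
    rng = np.random.default_rng(7)
    vals = rng.multivariate_normal([-24.0, 10.0], [[1.5, 0.4], [0.4, 1.0]], 30)
    return [
        IsotopeRecord(f"b{i}", "sp", float(c), float(n))
        for i, (c, n) in enumerate(vals)
    ]
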