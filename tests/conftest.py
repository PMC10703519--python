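import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wfscape as w

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flat_landscape(L: int) -> w.FitnessLandscape:
    """Landscape with fitness 1.0 for every genotype (neutral evolution)."""
    return w.gen_hoc(L, dist=lambda rng, size: np.zeros(size), rng=0)


def epistasis_circuits(raw: np.ndarray, L: int) -> np.ndarray:
    """All pairwise epistasis circuits F(g)+F(g|m1|m2)-F(g|m1)-F(g|m2) on raw
    scores, brute-forced over every locus pair and every background genotype
    with both focal loci at 0."""
    circuits = []
    for b1 in range(L):
        for b2 in range(b1 + 1, L):
            m1, m2 = 1 << b1, 1 << b2
            for g in range(1 << L):
                if g & m1 or g & m2:
                    continue
                circuits.append(raw[g] + raw[g | m1 | m2] - raw[g | m1] - raw[g | m2])
    return np.asarray(circuits)


def hamming_neighbor_correlation(make_landscape, n_landscapes: int) -> float:
    """Pearson correlation of raw scores between Hamming-distance-1 genotype
    pairs, pooled over replicate landscapes."""
    xs, ys = [], []
    for rep in range(n_landscapes):
        ls = make_landscape(rep)
        raw = ls.raw_scores
        for b in range(ls.L):
            neighbor = np.arange(1 << ls.L) ^ (1 << b)
            xs.append(raw)
            ys.append(raw[neighbor])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])
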