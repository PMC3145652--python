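import numpy as np
import pandas as pd
import pytest

from barrex.expression_io import CohortExpression, build_annotation


def make_cohort(rng, name="toy", n_probes=30, group_sizes=(4, 4, 4),
                scale="linear"):
    """Small well-formed cohort with clean annotation, for unit tests."""
    n = sum(group_sizes)
    probes = [f"{name}_p{i}" for i in range(n_probes)]
    samples = [f"{name}_s{i}" for i in range(n)]
    labels = pd.Series(
        ["S"] * group_sizes[0] + ["BE"] * group_sizes[1] + ["EAC"] * group_sizes[2],
        index=samples, name="tissue")
    log2 = rng.normal(7, 1, size=(n_probes, 1)) + rng.normal(0, 0.5, size=(n_probes, n))
    values = np.power(2.0, log2) if scale == "linear" else log2
    matrix = pd.DataFrame(values, index=probes, columns=samples)
    annotation = build_annotation(probes, list(range(1, n_probes + 1)),
                                  [f"G{i}" for i in range(1, n_probes + 1)])
    return CohortExpression(name=name, matrix=matrix, labels=labels,
                            annotation=annotation, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cohort(rng):
    return make_cohort(rng)


def profile_matrix(rng, n_per_class=8, n_genes=40, noise_sd=0.125):
    """Three tissue classes with random centroid profiles in general position.

    With noise_sd = 0.125 and unit-scale centroids the classes sit roughly
    8 noise-sd apart, a widely separated regime.
    """
    centroids = rng.normal(0, 1, (3, n_genes))
    X = np.vstack([centroids[k] + rng.normal(0, noise_sd, (n_per_class, n_genes))
                   for k in range(3)])
    samples = [f"s{i}" for i in range(3 * n_per_class)]
    matrix = pd.DataFrame(X, index=samples, columns=[f"g{i}" for i in range(n_genes)])
    labels = pd.Series(["S"] * n_per_class + ["BE"] * n_per_class
                       + ["EAC"] * n_per_class, index=samples, name="tissue")
    return matrix, labels
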