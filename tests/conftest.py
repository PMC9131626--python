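import numpy as np
import pytest

from llfrailty.simulate import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20160118)


def two_covariate_config(
    G=60, n_i=200, theta=0.5, seed=1, shape_k=6.0, median=16.5
) -> SyntheticConfig:
    """Small generating design used across recovery tests: two binary
    covariates with AFT effects (0.3, -0.2)."""
    return SyntheticConfig(
        cluster_sizes={f"c{i:03d}": n_i for i in range(G)},
        covariate_schema={
            "grp": {"a": 0.5, "b": 0.5},
            "exposure": {"lo": 0.6, "hi": 0.4},
        },
        true_beta={"grp:b": 0.3, "exposure:hi": -0.2},
        true_intercept=float(np.log(median)),
        true_shape_k=shape_k,
        true_theta=theta,
        seed=seed,
    )


def null_config(G=40, n_i=15, seed=1) -> SyntheticConfig:
    """No-frailty (theta = 0), no-covariate design for null-size studies."""
    return SyntheticConfig(
        cluster_sizes={f"c{i:03d}": n_i for i in range(G)},
        covariate_schema={},
        true_beta={},
        true_intercept=float(np.log(16.5)),
        true_shape_k=6.0,
        true_theta=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One mid-sized simulated cohort with frailty, reused across tests."""
    from llfrailty.simulate import generate_population

    cfg = two_covariate_config(G=30, n_i=60, theta=0.5, seed=42)
    df, truth = generate_population(cfg)
    return cfg, df, truth
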