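import numpy as np
import pytest

from storystates.reliability import StatePattern
from storystates.simulate import stationary_distribution


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def zspace_means(state_means: np.ndarray, cov: np.ndarray, A: np.ndarray) -> np.ndarray:
    """True state means projected into the per-subject z-scored space.

    The generator z-scores each subject's series, so the fitted means live on
    the scale (mu_k - E[x]) / SD[x] with mixture moments taken under the
    chain's stationary distribution.
    """
    pi = stationary_distribution(A)
    grand = pi @ state_means
    between = pi @ (state_means - grand) ** 2
    sd = np.sqrt(np.diag(cov) + between)
    return (state_means - grand) / sd


def make_pattern(
    mean,
    occupancy=0.1,
    group="combined",
    model_k=2,
    state_index=0,
    split_half_r=0.9,
) -> StatePattern:
    return StatePattern(
        mean=np.asarray(mean, dtype=float),
        occupancy=occupancy,
        group=group,
        model_k=model_k,
        state_index=state_index,
        max_abs_activation=float(np.max(np.abs(mean))),
        ci_widths=np.full(len(mean), 0.1),
        split_half_r=split_half_r,
    )
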