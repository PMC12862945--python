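"""Synthetic data with the statistical structure the analysis assumes.

Generates Markov state paths with multivariate-Gaussian network emissions,
bursty binary annotation streams, feature-coupled binary state occupancy with
AR(2) terms and subject random intercepts, and behavioral button presses
driven by the same logistic mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .annotations import build_composites
from .prep import NetworkSeries


class FeatureRate(BaseModel):
    """Marginal statistics of one bursty binary annotation stream."""

    rate: float = Field(ge=0.0, lt=1.0)  # rate 0 yields an all-zero column
    mean_run_length: float = Field(ge=1.0)

    @model_validator(mode="after")
    def _feasible(self) -> "FeatureRate":
        # off->on probability must stay <= 1 under the two-state chain
        if self.rate / (1.0 - self.rate) > self.mean_run_length:
            raise ValueError(
                f"rate {self.rate} with mean run length {self.mean_run_length} "
                "implies an off->on probability > 1"
            )
        return self


class SimSpec(BaseModel):
    """Parameters of the Markov-Gaussian network time-series generator."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_subjects_per_group: int = Field(ge=1, default=19)
    n_trs: int = Field(ge=1, default=451)
    n_networks: int = Field(ge=1, default=17)
    tr_seconds: float = Field(gt=0.0, default=1.5)
    n_states: int = Field(ge=1, default=3)
    state_means: list[list[float]] | None = None
    covariance_scale: float = Field(gt=0.0, default=1.0)
    covariance: list[list[float]] | None = None  # optional full emission covariance
    expected_dwell_trs: float = Field(ge=1.0, default=7.0 / 1.5)
    seed: int = 0

    @model_validator(mode="after")
    def _check_means(self) -> "SimSpec":
        if self.state_means is not None:
            m = np.asarray(self.state_means, dtype=float)
            if m.shape != (self.n_states, self.n_networks):
                raise ValueError(
                    f"state_means shape {m.shape} != ({self.n_states}, {self.n_networks})"
                )
            if self.n_states > 1:
                for i in range(self.n_states):
                    for j in range(i + 1, self.n_states):
                        if np.allclose(m[i], m[j]):
                            raise ValueError(f"state means {i} and {j} are not distinct")
        if self.covariance is not None:
            c = np.asarray(self.covariance, dtype=float)
            if c.shape != (self.n_networks, self.n_networks):
                raise ValueError("covariance must be n_networks x n_networks")
        return self

    def means_matrix(self, rng: np.random.Generator) -> np.ndarray:
        if self.state_means is not None:
            return np.asarray(self.state_means, dtype=float)
        return rng.standard_normal((self.n_states, self.n_networks))

    def covariance_matrix(self) -> np.ndarray:
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
        else:
            cov = self.covariance_scale * np.eye(self.n_networks)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("requested emission covariance is singular or not positive-definite") from exc
        return cov


class CouplingSpec(BaseModel):
    """Logistic coupling from annotation features to a binary outcome stream."""

    feature_rates: dict[str, FeatureRate] = Field(default_factory=dict)
    beta0: float = 0.0
    beta_group: float = 0.0
    beta_feature: dict[str, float] = Field(default_factory=dict)
    beta_interaction: dict[str, float] = Field(default_factory=dict)
    gamma_ar: tuple[float, float] = (0.0, 0.0)
    sigma_u: float = Field(ge=0.0, default=0.0)
    seed: int = 0


@dataclass
class GroundTruth:
    """True parameters and per-subject state paths behind a synthetic dataset."""

    state_paths: dict[str, np.ndarray]
    transition_matrix: np.ndarray
    state_means: np.ndarray
    covariance: np.ndarray

    def to_jsonable(self) -> dict:
        return {
            "state_paths": {k: v.tolist() for k, v in self.state_paths.items()},
            "transition_matrix": self.transition_matrix.tolist(),
            "state_means": self.state_means.tolist(),
            "covariance": self.covariance.tolist(),
        }


def dwell_transition_matrix(n_states: int, expected_dwell_trs: float) -> np.ndarray:
    """Row-stochastic matrix with self-transition ``a = 1 - 1/dwell`` and
    uniform off-diagonal mass, so mean dwell is geometric with mean ``dwell``."""
    if expected_dwell_trs < 1.0:
        raise ValueError("expected_dwell_trs must be >= 1")
    a = 1.0 - 1.0 / expected_dwell_trs
    if n_states == 1:
        return np.array([[1.0]])
    off = (1.0 - a) / (n_states - 1)
    A = np.full((n_states, n_states), off)
    np.fill_diagonal(A, a)
    return A


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary row vector of a transition matrix, by eigen-analysis."""
    vals, vecs = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_path(A: np.ndarray, n_steps: int, rng: np.random.Generator, start: np.ndarray | None = None) -> np.ndarray:
    pi = stationary_distribution(A) if start is None else np.asarray(start)
    cum = np.cumsum(A, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(n_steps)
    path = np.empty(n_steps, dtype=int)
    path[0] = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    for t in range(1, n_steps):
        path[t] = int(np.searchsorted(cum[path[t - 1]], u[t], side="right"))
    return path


def dwell_segments(path: np.ndarray) -> np.ndarray:
    """Lengths of maximal constant runs in a state path."""
    path = np.asarray(path)
    if path.size == 0:
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(path) != 0)
    bounds = np.concatenate([[-1], change, [path.size - 1]])
    return np.diff(bounds)


def generate_hmm_dataset(spec: SimSpec, groups: tuple[str, str] = ("affair", "paranoia")) -> tuple[list[NetworkSeries], GroundTruth]:
    """Simulate per-subject z-scored network series from a Gaussian HMM.

    Subjects are split evenly between the two group labels. Each subject gets
    an independent stationary Markov state path and Gaussian emissions around
    the active state's mean; the series is z-scored per subject (population
    SD) before return, matching the analysis-side convention.
    """
    rng = np.random.default_rng(spec.seed)
    means = spec.means_matrix(rng)
    cov = spec.covariance_matrix()
    chol = np.linalg.cholesky(cov)
    A = dwell_transition_matrix(spec.n_states, spec.expected_dwell_trs)

    series: list[NetworkSeries] = []
    paths: dict[str, np.ndarray] = {}
    for g, group in enumerate(groups):
        for s in range(spec.n_subjects_per_group):
            sid = f"{group}_{s + 1:02d}"
            path = sample_markov_path(A, spec.n_trs, rng)
            noise = rng.standard_normal((spec.n_trs, spec.n_networks)) @ chol.T
            data = means[path] + noise
            mu = data.mean(axis=0)
            sd = data.std(axis=0)
            if np.any(sd == 0):
                raise ValueError("degenerate simulated series: zero-variance column")
            data = (data - mu) / sd
            paths[sid] = path
            series.append(
                NetworkSeries(subject_id=sid, data=data, tr_seconds=spec.tr_seconds, group=group)
            )
    return series, GroundTruth(paths, A, means, cov)


def _two_state_chain(rate: float, mean_run_length: float) -> tuple[float, float]:
    """(P(on->off), P(off->on)) for a stationary two-state chain with the
    requested on-rate and mean on-run length."""
    d = 1.0 / mean_run_length
    b = d * rate / (1.0 - rate)
    return d, b


def generate_feature_streams(coupling: CouplingSpec, n_trs: int, composites: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Simulate bursty binary annotation columns as two-state Markov chains.

    One column per entry of ``coupling.feature_rates``; composite columns are
    appended as products when both parents are present.
    """
    if n_trs < 1:
        raise ValueError("n_trs must be >= 1")
    rng = np.random.default_rng(coupling.seed)
    table = pd.DataFrame({"tr_index": np.arange(n_trs, dtype=int)})
    for name, fr in coupling.feature_rates.items():
        d, b = _two_state_chain(fr.rate, fr.mean_run_length)
        col = np.empty(n_trs, dtype=int)
        col[0] = int(rng.random() < fr.rate)
        u = rng.random(n_trs - 1) if n_trs > 1 else np.array([])
        for t in range(1, n_trs):
            p_on = 1.0 - d if col[t - 1] == 1 else b
            col[t] = int(u[t - 1] < p_on)
        table[name] = col
    if composites:
        present = {
            k: v for k, v in composites.items() if v[0] in table.columns and v[1] in table.columns
        }
        table = build_composites(table, present)
    return table


def zero_rate_column(n_trs: int) -> np.ndarray:
    """All-zero annotation column (rate-0 feature)."""
    return np.zeros(n_trs, dtype=int)


def _logistic_series(
    features: pd.DataFrame,
    coupling: CouplingSpec,
    group_code: int,
    n_subjects: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-subject Bernoulli series from the logistic model with AR(2)
    outcome lags and subject random intercepts. Lags before t=0 are 0."""
    if group_code not in (1, -1):
        raise ValueError("group_code must be +1 or -1")
    n_trs = len(features)
    fixed = np.full(n_trs, coupling.beta0 + coupling.beta_group * group_code)
    for name, beta in coupling.beta_feature.items():
        fixed = fixed + beta * features[name].to_numpy()
    for name, beta in coupling.beta_interaction.items():
        fixed = fixed + beta * group_code * features[name].to_numpy()
    g1, g2 = coupling.gamma_ar

    out = np.empty((n_subjects, n_trs), dtype=int)
    u = rng.normal(0.0, coupling.sigma_u, size=n_subjects) if coupling.sigma_u > 0 else np.zeros(n_subjects)
    for i in range(n_subjects):
        draws = rng.random(n_trs)
        y1 = y2 = 0
        for t in range(n_trs):
            eta = fixed[t] + g1 * y1 + g2 * y2 + u[i]
            y = int(draws[t] < 1.0 / (1.0 + np.exp(-eta)))
            out[i, t] = y
            y2, y1 = y1, y
    return out


def generate_state_occupancy(
    features: pd.DataFrame, coupling: CouplingSpec, group_code: int, n_subjects: int = 1
) -> np.ndarray:
    """Binary state-occupancy sequences, one row per subject."""
    rng = np.random.default_rng(coupling.seed)
    return _logistic_series(features, coupling, group_code, n_subjects, rng)


def generate_button_presses(
    features: pd.DataFrame, coupling: CouplingSpec, group_code: int, n_subjects: int = 1
) -> np.ndarray:
    """Binary per-TR button-press indicators, one row per subject."""
    rng = np.random.default_rng(coupling.seed)
    return _logistic_series(features, coupling, group_code, n_subjects, rng)


def presses_to_times(press_matrix: np.ndarray, tr_seconds: float) -> list[np.ndarray]:
    """Convert binary per-TR press rows into press times at bin centers."""
    out = []
    for row in np.asarray(press_matrix):
        bins = np.flatnonzero(row)
        out.append((bins + 0.5) * tr_seconds)
    return out
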