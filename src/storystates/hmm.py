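"""Gaussian-observation HMM fitting with dwell-time-prior initialization,
multiple restarts, decoding, leave-one-subject-out CV, and Hungarian state
matching.

The EM itself is delegated to :mod:`hmmlearn`; this module owns the
initialization scheme (dwell-prior transitions, uniform starts, standard-normal
mean draws, identity-plus-ridge covariances), restart selection by
log-likelihood, a per-M-step covariance ridge, and monotonicity checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from scipy.optimize import linear_sum_assignment

from .simulate import dwell_transition_matrix

RIDGE_DEFAULT = 1e-6
MAX_STATES = 20


@dataclass
class HmmParams:
    """Parameters of a K-state Gaussian HMM."""

    means: np.ndarray  # (K, D)
    covars: np.ndarray  # (K, D, D)
    transmat: np.ndarray  # (K, K) row-stochastic
    startprob: np.ndarray  # (K,)
    ridge: float = RIDGE_DEFAULT

    def __post_init__(self) -> None:
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-10):
            raise ValueError("start probabilities must sum to 1")
        for k, cov in enumerate(self.covars):
            if np.linalg.eigvalsh(cov).min() < self.ridge / 2:
                raise ValueError(f"state {k} covariance below ridge floor")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]


@dataclass
class FittedHMM:
    """Best-of-restarts EM solution with full restart provenance."""

    params: HmmParams
    log_likelihood: float
    restart_seeds: list[int]
    restart_log_likelihoods: list[float]
    n_iter: int
    tol: float
    converged: bool
    ll_history: list[float] = field(default_factory=list)
    model: GaussianHMM | None = None  # fitted backend model for decoding/scoring

    def __post_init__(self) -> None:
        finite = [ll for ll in self.restart_log_likelihoods if np.isfinite(ll)]
        if finite and not np.isclose(self.log_likelihood, max(finite)):
            raise ValueError("reported log-likelihood must be the max over restarts")


@dataclass
class StateSequence:
    """Viterbi path and posterior state probabilities for one subject."""

    subject_id: str
    path: np.ndarray  # (T,) ints in [0, K)
    posteriors: np.ndarray  # (T, K), rows sum to 1


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def _reset(self):
        super()._reset()
        self.full_history = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


class _RidgedGaussianHMM(GaussianHMM):
    """GaussianHMM with an epsilon diagonal ridge re-applied every M-step."""

    def __init__(self, *args, ridge: float = RIDGE_DEFAULT, **kwargs):
        super().__init__(*args, **kwargs)
        self.ridge = ridge

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        if "c" in self.params and self.covariance_type == "full":
            cov = self._covars_
            cov += self.ridge * np.eye(cov.shape[-1])[None, :, :]
        elif "c" in self.params and self.covariance_type == "diag":
            self._covars_ = np.maximum(self._covars_, self.ridge)


def init_model(
    K: int,
    n_networks: int,
    expected_dwell_s: float = 7.0,
    tr_s: float = 1.5,
    seed: int = 0,
    ridge: float = RIDGE_DEFAULT,
) -> HmmParams:
    """Initial HMM parameters: dwell-favoring transitions, uniform starts,
    standard-normal mean draws, identity-plus-ridge covariances.

    The transition diagonal is ``1 - tr_s/expected_dwell_s``, which under the
    geometric dwell law gives an expected dwell of ``expected_dwell_s`` seconds.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if expected_dwell_s < tr_s:
        raise ValueError(f"expected dwell {expected_dwell_s}s shorter than one TR ({tr_s}s)")
    rng = np.random.default_rng(seed)
    A = dwell_transition_matrix(K, expected_dwell_s / tr_s)
    return HmmParams(
        means=rng.standard_normal((K, n_networks)),
        covars=np.repeat(((1.0 + ridge) * np.eye(n_networks))[None], K, axis=0),
        transmat=A,
        startprob=np.full(K, 1.0 / K),
        ridge=ridge,
    )


def implied_dwell_seconds(params: HmmParams, tr_s: float) -> np.ndarray:
    """Per-state expected dwell in seconds, ``tr_s / (1 - a_kk)``."""
    diag = np.diag(params.transmat)
    return tr_s / (1.0 - diag)


def _build_backend(params: HmmParams, tol: float, max_iter: int, covariance_type: str) -> _RidgedGaussianHMM:
    model = _RidgedGaussianHMM(
        n_components=params.n_states,
        covariance_type=covariance_type,
        min_covar=0.0,
        covars_prior=0.0,
        covars_weight=0.0,
        init_params="",
        params="stmc",
        tol=tol,
        n_iter=max_iter,
        ridge=params.ridge,
    )
    model.startprob_ = params.startprob.copy()
    model.transmat_ = params.transmat.copy()
    model.means_ = params.means.copy()
    if covariance_type == "full":
        model.covars_ = params.covars.copy()
    else:
        model.covars_ = np.array([np.diag(c) for c in params.covars])
    return model


def _extract_params(model: GaussianHMM, ridge: float) -> HmmParams:
    if model.covariance_type == "full":
        covars = np.array(model.covars_)
    else:
        covars = np.array([np.diag(c) for c in model.covars_])
    return HmmParams(
        means=np.array(model.means_),
        covars=covars,
        transmat=np.array(model.transmat_),
        startprob=np.array(model.startprob_),
        ridge=ridge,
    )


def check_monotone(history: list[float], rel_tol: float = 1e-8) -> None:
    """Raise if the EM log-likelihood trace decreases beyond numerical noise."""
    h = np.asarray(history)
    if h.size < 2:
        return
    drops = np.diff(h)
    floor = -rel_tol * np.maximum(1.0, np.abs(h[:-1]))
    if (drops < floor).any():
        i = int(np.argmin(drops - floor))
        raise RuntimeError(f"EM log-likelihood decreased at iteration {i + 1}: {h[i]} -> {h[i + 1]}")


def fit_hmm(
    stacked: np.ndarray,
    subject_ranges: list[tuple[str, int, int]],
    K: int,
    n_restarts: int = 5,
    base_seed: int = 0,
    expected_dwell_s: float = 7.0,
    tr_s: float = 1.5,
    tol: float = 1e-4,
    max_iter: int = 500,
    covariance_type: str = "full",
    ridge: float = RIDGE_DEFAULT,
) -> FittedHMM:
    """Fit a K-state Gaussian HMM with ``n_restarts`` seeded restarts and
    return the highest-log-likelihood solution.

    Restart ``r`` is initialized by :func:`init_model` with seed
    ``base_seed + r`` (the seed drives only the mean draws; EM is otherwise
    deterministic given the initialization). Restarts that fail numerically
    are flagged with ``-inf`` log-likelihood and excluded.
    """
    if K < 1 or K > MAX_STATES:
        raise ValueError(f"K must be in [1, {MAX_STATES}]")
    lengths = [b - a for _, a, b in subject_ranges]
    if sum(lengths) != stacked.shape[0]:
        raise ValueError("subject ranges do not cover the stacked matrix")

    seeds = [base_seed + r for r in range(n_restarts)]
    best: tuple[float, GaussianHMM, list[float]] | None = None
    restart_lls: list[float] = []
    for seed in seeds:
        init = init_model(K, stacked.shape[1], expected_dwell_s, tr_s, seed, ridge)
        model = _build_backend(init, tol, max_iter, covariance_type)
        model.monitor_ = _HistoryMonitor(model.tol, model.n_iter, model.verbose)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(stacked, lengths=lengths)
            history = list(model.monitor_.full_history)
            ll = history[-1]
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log-likelihood")
            check_monotone(history)
        except (FloatingPointError, ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"restart seed {seed} failed: {exc}", stacklevel=2)
            restart_lls.append(-np.inf)
            continue
        restart_lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, model, history)
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed for K={K}")

    ll, model, history = best
    return FittedHMM(
        params=_extract_params(model, ridge),
        log_likelihood=ll,
        restart_seeds=seeds,
        restart_log_likelihoods=restart_lls,
        n_iter=len(history),
        tol=tol,
        converged=model.monitor_.converged,
        ll_history=history,
        model=model,
    )


def decode(fit: FittedHMM, data: np.ndarray, subject_id: str = "") -> StateSequence:
    """Viterbi path plus forward-backward posteriors for one subject's series."""
    if fit.model is None:
        raise ValueError("fit has no backend model attached")
    data = np.asarray(data, dtype=float)
    if data.shape[1] != fit.params.means.shape[1]:
        raise ValueError(
            f"series has {data.shape[1]} channels, model expects {fit.params.means.shape[1]}"
        )
    _, path = fit.model.decode(data, algorithm="viterbi")
    post = fit.model.predict_proba(data)
    return StateSequence(subject_id=subject_id, path=path, posteriors=post)


def decode_all(fit: FittedHMM, stacked: np.ndarray, subject_ranges: list[tuple[str, int, int]]) -> dict[str, StateSequence]:
    return {sid: decode(fit, stacked[a:b], sid) for sid, a, b in subject_ranges}


def match_states(means_a: np.ndarray, means_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of state mean patterns between two equal-K models.

    Returns ``(perm, corrs)`` where state ``i`` of model A matches state
    ``perm[i]`` of model B, maximizing the total Pearson correlation.
    """
    means_a = np.asarray(means_a)
    means_b = np.asarray(means_b)
    if means_a.shape != means_b.shape:
        raise ValueError(f"state count/shape mismatch: {means_a.shape} vs {means_b.shape}")
    K = means_a.shape[0]
    C = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            C[i, j] = np.corrcoef(means_a[i], means_b[j])[0, 1]
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm, C[rows, cols]


@dataclass
class LoocvResult:
    heldout_log_likelihoods: dict[str, float]
    mean_heldout_log_likelihood: float
    pattern_reliability: float  # mean Hungarian-matched correlation over fold pairs
    fold_means: dict[str, np.ndarray]


def loocv(
    stacked: np.ndarray,
    subject_ranges: list[tuple[str, int, int]],
    K: int,
    n_restarts: int = 5,
    base_seed: int = 0,
    **fit_kwargs,
) -> LoocvResult:
    """Leave-one-subject-out CV: held-out log-likelihood per fold and
    cross-fold mean-pattern reliability averaged over all fold pairs."""
    n_subj = len(subject_ranges)
    if n_subj < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    heldout: dict[str, float] = {}
    fold_means: dict[str, np.ndarray] = {}
    for held_idx, (sid, a, b) in enumerate(subject_ranges):
        keep = [r for i, r in enumerate(subject_ranges) if i != held_idx]
        train = np.vstack([stacked[x:y] for _, x, y in keep])
        ranges = []
        start = 0
        for s2, x, y in keep:
            ranges.append((s2, start, start + (y - x)))
            start += y - x
        fit = fit_hmm(train, ranges, K, n_restarts=n_restarts, base_seed=base_seed, **fit_kwargs)
        heldout[sid] = float(fit.model.score(stacked[a:b]))
        fold_means[sid] = fit.params.means

    sids = [sid for sid, _, _ in subject_ranges]
    pair_scores = []
    for i in range(n_subj):
        for j in range(i + 1, n_subj):
            _, corrs = match_states(fold_means[sids[i]], fold_means[sids[j]])
            pair_scores.append(float(np.mean(corrs)))
    return LoocvResult(
        heldout_log_likelihoods=heldout,
        mean_heldout_log_likelihood=float(np.mean(list(heldout.values()))),
        pattern_reliability=float(np.mean(pair_scores)),
        fold_means=fold_means,
    )
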