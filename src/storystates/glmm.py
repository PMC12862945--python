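"""MAP-estimated Bayesian logistic mixed models for binary TR series.

The design couples per-TR story features to a binary outcome (brain-state
occupancy or button presses) with a deviation-coded group term (+1 affair,
-1 paranoia), group x feature interactions, AR(2) lags of the outcome, and
subject random intercepts. Estimation maximizes the joint posterior

    Bernoulli log-likelihood
    + log Normal(beta; 0, tau^2 I)          (fixed effects)
    + sum_i log Normal(u_i; 0, sigma_u^2)   (random intercepts)
    + log InvGamma(sigma_u^2; a0, b0)

by block alternation: damped Newton steps on (beta, u) given sigma_u^2, then
a closed-form sigma_u^2 update. Posterior uncertainty is Gaussian from the
inverse curvature of the penalized objective at the optimum; direction
probabilities, a Bayesian FDR rule on them, odds-ratio conversion, and
deviation-coding group decompositions complete the reporting surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

GROUP_CODES = {"affair": 1, "paranoia": -1}
SEPARATION_BOUND = 15.0


@dataclass
class PriorSpec:
    """Normal(0, tau^2) fixed-effect prior and InvGamma(a0, b0) prior on the
    random-intercept variance. ``tau=None`` means flat fixed-effect priors."""

    tau: float | None = 2.5
    a0: float = 2.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive (or None for flat)")
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("a0 and b0 must be positive")


@dataclass
class GlmmDesign:
    """Stacked (subject, TR) design for the logistic mixed model."""

    X: np.ndarray  # (n_obs, p) fixed-effect columns
    y: np.ndarray  # (n_obs,) binary outcome
    subject_idx: np.ndarray  # (n_obs,) int codes into subject_ids
    subject_ids: list[str]
    columns: list[str]
    feature_names: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_design(
    features: pd.DataFrame,
    outcomes: dict[str, np.ndarray],
    groups: dict[str, str],
    n_lags: int = 2,
    feature_names: list[str] | None = None,
) -> GlmmDesign:
    """Assemble the stacked design matrix.

    Column order: intercept, group, features, group x features, AR lags.
    AR lag columns are the outcome shifted within subject, padded with 0 at
    each subject's first ``n_lags`` TRs.
    """
    if feature_names is None:
        feature_names = [c for c in features.columns if c != "tr_index"]
    F = features[feature_names].to_numpy(dtype=float)
    n_trs = F.shape[0]

    blocks_X, blocks_y, blocks_sub = [], [], []
    subject_ids = sorted(outcomes)
    for si, sid in enumerate(subject_ids):
        y = np.asarray(outcomes[sid], dtype=float).ravel()
        if y.size != n_trs:
            raise ValueError(f"subject {sid}: outcome length {y.size} != feature rows {n_trs}")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"subject {sid}: outcome is not binary")
        label = groups[sid]
        if label not in GROUP_CODES:
            raise KeyError(f"subject {sid}: unknown group label {label!r}")
        g = GROUP_CODES[label]
        cols = [np.ones(n_trs), np.full(n_trs, float(g))]
        cols.extend(F[:, j] for j in range(F.shape[1]))
        cols.extend(g * F[:, j] for j in range(F.shape[1]))
        for lag in range(1, n_lags + 1):
            lagged = np.zeros(n_trs)
            lagged[lag:] = y[:-lag]
            cols.append(lagged)
        blocks_X.append(np.column_stack(cols))
        blocks_y.append(y)
        blocks_sub.append(np.full(n_trs, si, dtype=int))

    columns = (
        ["intercept", "group"]
        + list(feature_names)
        + [f"group:{f}" for f in feature_names]
        + [f"ar{lag}" for lag in range(1, n_lags + 1)]
    )
    return GlmmDesign(
        X=np.vstack(blocks_X),
        y=np.concatenate(blocks_y),
        subject_idx=np.concatenate(blocks_sub),
        subject_ids=subject_ids,
        columns=columns,
        feature_names=list(feature_names),
    )


@dataclass
class GlmmFit:
    """MAP point estimates with Laplace-style posterior uncertainty."""

    columns: list[str]
    coef: np.ndarray  # (p,) fixed effects, log-odds
    sd: np.ndarray  # (p,) approximate posterior SDs
    cov: np.ndarray  # (p, p) approximate posterior covariance of beta
    u: np.ndarray  # (n_subj,) random intercepts
    sigma_u2: float
    subject_ids: list[str]
    feature_names: list[str]
    n_iter: int
    converged: bool
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.columns.index(name)])

    def sd_of(self, name: str) -> float:
        return float(self.sd[self.columns.index(name)])

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def or_intervals(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + level / 2.0)
        return np.exp(self.coef - z * self.sd), np.exp(self.coef + z * self.sd)


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit_map(
    design: GlmmDesign,
    priors: PriorSpec | None = None,
    include_random: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> GlmmFit:
    """Fit the logistic mixed model by MAP estimation.

    Convergence is declared when the max-abs parameter change over a full
    outer cycle falls below ``tol``. With ``include_random=False`` the model
    reduces to a penalized (or, with flat priors, plain ML) logistic
    regression, which serves as the oracle-comparison mode.
    """
    priors = priors or PriorSpec()
    y = design.y
    if y.min() == y.max():
        raise ValueError("outcome is all-0 or all-1; model is not identifiable")
    X = design.X
    n_obs, p = X.shape
    n_subj = design.n_subjects if include_random else 0

    beta = np.zeros(p)
    u = np.zeros(n_subj)
    sigma_u2 = 1.0
    prior_prec_beta = 0.0 if priors.tau is None else 1.0 / priors.tau**2

    sub = design.subject_idx

    def objective(beta, u, sigma_u2):
        eta = X @ beta + (u[sub] if n_subj else 0.0)
        ll = float(y @ eta - _log1pexp(eta).sum())
        ll -= 0.5 * prior_prec_beta * float(beta @ beta)
        if n_subj:
            ll -= 0.5 * float(u @ u) / sigma_u2 + 0.5 * n_subj * np.log(sigma_u2)
            ll -= (priors.a0 + 1.0) * np.log(sigma_u2) + priors.b0 / sigma_u2
        return ll

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta_old, u_old, s_old = beta.copy(), u.copy(), sigma_u2

        # Newton steps on (beta, u) given sigma_u2, with step halving
        for _ in range(50):
            eta = X @ beta + (u[sub] if n_subj else 0.0)
            mu = _sigmoid(eta)
            w = mu * (1.0 - mu)
            resid = y - mu
            g_beta = X.T @ resid - prior_prec_beta * beta
            H_bb = X.T @ (X * w[:, None]) + prior_prec_beta * np.eye(p)
            if n_subj:
                g_u = np.bincount(sub, weights=resid, minlength=n_subj) - u / sigma_u2
                H_uu = np.bincount(sub, weights=w, minlength=n_subj) + 1.0 / sigma_u2
                H_bu = np.zeros((p, n_subj))
                for j in range(p):
                    H_bu[j] = np.bincount(sub, weights=w * X[:, j], minlength=n_subj)
                H = np.block([[H_bb, H_bu], [H_bu.T, np.diag(H_uu)]])
                g = np.concatenate([g_beta, g_u])
            else:
                H, g = H_bb, g_beta
            gnorm = np.max(np.abs(g))
            if gnorm < tol:
                break
            step = np.linalg.solve(H, g)
            f0 = objective(beta, u, sigma_u2)
            scale = 1.0
            for _ in range(30):
                beta_new = beta + scale * step[:p]
                u_new = u + scale * step[p:] if n_subj else u
                if objective(beta_new, u_new, sigma_u2) >= f0 - 1e-12:
                    break
                scale *= 0.5
            beta, u = beta_new, (u_new if n_subj else u)

        if n_subj:
            sigma_u2 = (float(u @ u) + 2.0 * priors.b0) / (n_subj + 2.0 * priors.a0 + 2.0)

        delta = max(
            np.max(np.abs(beta - beta_old)),
            np.max(np.abs(u - u_old)) if n_subj else 0.0,
            abs(sigma_u2 - s_old),
        )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"MAP estimation did not converge in {max_iter} outer iterations "
            f"(last max-abs change {delta:.3g})"
        )

    if priors.tau is None and np.max(np.abs(beta)) > SEPARATION_BOUND:
        warnings.warn(
            "possible separation: |coefficient| > 15 under flat priors; "
            "consider a proper normal prior for regularization",
            stacklevel=2,
        )

    # Laplace covariance from the penalized curvature at the MAP
    eta = X @ beta + (u[sub] if n_subj else 0.0)
    w = _sigmoid(eta) * (1.0 - _sigmoid(eta))
    H_bb = X.T @ (X * w[:, None]) + prior_prec_beta * np.eye(p)
    if n_subj:
        H_uu = np.bincount(sub, weights=w, minlength=n_subj) + 1.0 / sigma_u2
        H_bu = np.zeros((p, n_subj))
        for j in range(p):
            H_bu[j] = np.bincount(sub, weights=w * X[:, j], minlength=n_subj)
        # marginalize u: Schur complement of the u-block
        H_marg = H_bb - H_bu @ (H_bu.T / H_uu[:, None])
        cov = np.linalg.inv(H_marg)
    else:
        cov = np.linalg.inv(H_bb)

    return GlmmFit(
        columns=list(design.columns),
        coef=beta,
        sd=np.sqrt(np.diag(cov)),
        cov=cov,
        u=u,
        sigma_u2=float(sigma_u2) if n_subj else 0.0,
        subject_ids=list(design.subject_ids),
        feature_names=list(design.feature_names),
        n_iter=it,
        converged=converged,
        priors=priors,
    )


def direction_probability(coef: np.ndarray | float, sd: np.ndarray | float) -> np.ndarray | float:
    """Gaussian-approximation P(effect > 0) = Phi(coef / sd).

    A zero SD collapses to 0/1 by the sign of the estimate (0.5 at zero).
    """
    coef = np.asarray(coef, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, coef / np.where(sd > 0, sd, 1.0), np.sign(coef) * np.inf)
    z = np.where((sd == 0) & (coef == 0), 0.0, z)
    out = norm.cdf(z)
    return float(out) if out.ndim == 0 else out


@dataclass
class FdrResult:
    credible: np.ndarray  # bool flags, original order
    adjusted_probability: np.ndarray  # 1 - running mean of sorted error probs
    error_probability: np.ndarray  # 1 - max(P(>0), 1 - P(>0))


def bayesian_fdr(direction_probs: np.ndarray, alpha: float = 0.05) -> FdrResult:
    """Bayesian FDR on posterior direction probabilities.

    With ``p* = max(P(>0), 1-P(>0))`` and error probabilities ``e = 1 - p*``
    sorted ascending, the largest prefix whose running mean stays <= alpha is
    flagged credible; each coefficient's adjusted probability is 1 minus the
    running mean at its rank.
    """
    probs = np.asarray(direction_probs, dtype=float)
    p_star = np.maximum(probs, 1.0 - probs)
    e = 1.0 - p_star
    order = np.argsort(e, kind="stable")
    running_mean = np.cumsum(e[order]) / np.arange(1, e.size + 1)
    ok = running_mean <= alpha
    cutoff = int(np.max(np.flatnonzero(ok))) + 1 if ok.any() else 0
    credible = np.zeros(e.size, dtype=bool)
    credible[order[:cutoff]] = True
    adjusted = np.empty(e.size)
    adjusted[order] = 1.0 - running_mean
    return FdrResult(credible=credible, adjusted_probability=adjusted, error_probability=e)


@dataclass
class GroupEffect:
    feature: str
    group: str  # affair | paranoia
    log_odds: float
    sd: float
    odds_ratio: float
    p_positive: float


def group_effects(fit: GlmmFit) -> list[GroupEffect]:
    """Deviation-coding decomposition: affair effect = beta_j + beta_gj,
    paranoia effect = beta_j - beta_gj, with variances from the posterior
    covariance (var_j + var_gj +/- 2 cov)."""
    out: list[GroupEffect] = []
    for feat in fit.feature_names:
        j = fit.columns.index(feat)
        gj = fit.columns.index(f"group:{feat}")
        vj, vgj, cjg = fit.cov[j, j], fit.cov[gj, gj], fit.cov[j, gj]
        for group, sign in (("affair", 1.0), ("paranoia", -1.0)):
            lo = fit.coef[j] + sign * fit.coef[gj]
            var = vj + vgj + 2.0 * sign * cjg
            sd = float(np.sqrt(max(var, 0.0)))
            out.append(
                GroupEffect(
                    feature=feat,
                    group=group,
                    log_odds=float(lo),
                    sd=sd,
                    odds_ratio=float(np.exp(lo)),
                    p_positive=float(direction_probability(lo, sd)),
                )
            )
    return out


def main_or_from_group_ors(or_affair: float, or_paranoia: float) -> float:
    """Invert the deviation coding: the main-effect OR is the geometric mean
    of the two group-specific ORs."""
    return float(np.exp(0.5 * (np.log(or_affair) + np.log(or_paranoia))))


def interaction_or_from_group_ors(or_affair: float, or_paranoia: float) -> float:
    """Interaction OR = exp of half the difference of the group log-odds."""
    return float(np.exp(0.5 * (np.log(or_affair) - np.log(or_paranoia))))


def representative_occupancy(paths: dict[str, np.ndarray], state_index: int) -> dict[str, np.ndarray]:
    """Binary on/off outcome per subject: 1 iff the decoded state equals the
    representative state at that TR."""
    out = {}
    for sid, path in paths.items():
        ind = (np.asarray(path) == state_index).astype(int)
        if ind.sum() == 0:
            warnings.warn(f"subject {sid}: representative state never visited", stacklevel=2)
        out[sid] = ind
    return out


def summary_table(fit: GlmmFit, alpha: float = 0.05) -> pd.DataFrame:
    """One row per coefficient: estimate, SD, OR with 95% interval, direction
    probability, FDR-adjusted probability, credible flag; plus group-specific
    rows for each feature."""
    p_pos = direction_probability(fit.coef, fit.sd)
    feat_mask = [c in fit.feature_names or c.startswith("group:") for c in fit.columns]
    fdr = bayesian_fdr(np.asarray(p_pos)[np.asarray(feat_mask)], alpha=alpha)
    lo, hi = fit.or_intervals()

    rows = []
    fi = 0
    for i, name in enumerate(fit.columns):
        is_feat = feat_mask[i]
        rows.append(
            {
                "term": name,
                "scope": "main",
                "estimate": fit.coef[i],
                "sd": fit.sd[i],
                "odds_ratio": np.exp(fit.coef[i]),
                "or_low": lo[i],
                "or_high": hi[i],
                "p_positive": np.asarray(p_pos)[i],
                "fdr_adjusted_probability": fdr.adjusted_probability[fi] if is_feat else np.nan,
                "credible": bool(fdr.credible[fi]) if is_feat else False,
            }
        )
        if is_feat:
            fi += 1
    z = norm.ppf(0.975)
    for ge in group_effects(fit):
        rows.append(
            {
                "term": ge.feature,
                "scope": ge.group,
                "estimate": ge.log_odds,
                "sd": ge.sd,
                "odds_ratio": ge.odds_ratio,
                "or_low": np.exp(ge.log_odds - z * ge.sd),
                "or_high": np.exp(ge.log_odds + z * ge.sd),
                "p_positive": ge.p_positive,
                "fdr_adjusted_probability": np.nan,
                "credible": False,
            }
        )
    return pd.DataFrame(rows)
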