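"""Run configuration: every threshold and default used by the pipeline, with
a stable hash embedded in all outputs for provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field

from .simulate import CouplingSpec, FeatureRate, SimSpec


def default_feature_rates() -> dict[str, FeatureRate]:
    # placeholder marginals for the eight base annotation streams; set per
    # experiment when real annotations are available
    return {
        "arthur_speaking": FeatureRate(rate=0.30, mean_run_length=6.0),
        "lee_speaking": FeatureRate(rate=0.25, mean_run_length=5.0),
        "girl_speaking": FeatureRate(rate=0.10, mean_run_length=3.0),
        "lee_girl_together": FeatureRate(rate=0.20, mean_run_length=8.0),
        "verb": FeatureRate(rate=0.55, mean_run_length=3.0),
        "noun": FeatureRate(rate=0.60, mean_run_length=3.0),
        "adjective": FeatureRate(rate=0.30, mean_run_length=2.0),
        "adverb": FeatureRate(rate=0.25, mean_run_length=2.0),
    }


def default_coupling() -> CouplingSpec:
    return CouplingSpec(
        feature_rates=default_feature_rates(),
        beta0=-1.0,
        beta_group=0.1,
        beta_feature={"arthur_speaking": 0.5, "verb": 0.2},
        beta_interaction={"arthur_speaking": -0.5},
        gamma_ar=(1.0, 0.3),
        sigma_u=0.3,
        seed=0,
    )


class RunConfig(BaseModel):
    """All analysis constants, serialized with every output."""

    # timing / trimming
    tr_seconds: float = 1.5
    shift_trs: int = 3
    onset_exclude_trs: int = 14  # 18 s music + 3 s silence at TR 1.5 s
    offset_exclude_trs: int = 10  # 15 s tail at TR 1.5 s
    n_trs: int = 451

    # HMM
    k_min: int = 2
    k_max: int = 20
    n_restarts: int = 5
    expected_dwell_s: float = 7.0
    ridge: float = 1e-6
    em_tol: float = 1e-4
    em_max_iter: int = 500
    covariance_type: str = "full"

    # state reliability
    theta_act: float = 0.1
    theta_ci: float = 0.3
    theta_sh: float = 0.5
    n_boot: int = 1000

    # clustering
    similarity_threshold: float = 0.8
    sweep_thresholds: list[float] = Field(
        default_factory=lambda: [0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90]
    )
    top_n_clusters: int = 4

    # GLMM
    prior_tau: float = 2.5
    prior_a0: float = 2.0
    prior_b0: float = 1.0
    fdr_alpha: float = 0.05
    n_ar_lags: int = 2

    # permutation
    n_perm: int = 10_000

    # balanced constructed group: 9 affair + 10 paranoia
    balanced_n_affair: int = 9
    balanced_n_paranoia: int = 10

    seed: int = 0

    # synthetic data
    sim: SimSpec = Field(default_factory=SimSpec)
    coupling: CouplingSpec = Field(default_factory=default_coupling)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2, sort_keys=True)
            fh.write("\n")
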