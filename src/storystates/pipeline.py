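"""End-to-end driver: simulate -> fit HMMs per group -> filter states ->
cluster -> representative-state GLMMs -> behavioral GLMM -> permutation.

Every stage is seeded from the run config, so a rerun with the same config
produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import behavior, clustering, glmm, hmm, io, permutation, reliability, simulate
from .annotations import COMPOSITES
from .config import RunConfig
from .prep import NetworkSeries, concatenate_subjects

logger = logging.getLogger(__name__)

ANALYSIS_GROUPS = ("affair", "paranoia", "combined", "balanced")


def build_analysis_groups(series: list[NetworkSeries], config: RunConfig) -> dict[str, list[NetworkSeries]]:
    """The two experimental groups plus the combined and balanced constructed
    groups (balanced: seeded subsample of 9 affair + 10 paranoia)."""
    affair = [s for s in series if s.group == "affair"]
    paranoia = [s for s in series if s.group == "paranoia"]
    rng = np.random.default_rng(config.seed + 1)
    n_a = min(config.balanced_n_affair, len(affair))
    n_p = min(config.balanced_n_paranoia, len(paranoia))
    balanced = [affair[i] for i in sorted(rng.choice(len(affair), n_a, replace=False))] + [
        paranoia[i] for i in sorted(rng.choice(len(paranoia), n_p, replace=False))
    ]
    return {
        "affair": affair,
        "paranoia": paranoia,
        "combined": affair + paranoia,
        "balanced": balanced,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full simulate-then-analyze pipeline and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.seed
    config.to_json(out / "config.json")

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    sim = config.sim.model_copy(update={"seed": config.seed})
    coupling = config.coupling.model_copy(update={"seed": config.seed + 2})
    try:
        series, truth = simulate.generate_hmm_dataset(sim)
        features = simulate.generate_feature_streams(coupling, sim.n_trs, COMPOSITES)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    for s in series:
        io.write_network_series(s, out / "series" / f"{s.subject_id}.tsv", chash, seed)
    io.write_tsv(features, out / "features.tsv", chash, seed)
    io.write_json(truth.to_jsonable(), out / "ground_truth.json", chash, seed)

    groups = build_analysis_groups(series, config)

    # --- fit HMMs and filter states --------------------------------------
    stage("fit-hmm + filter-states")
    pool: list[reliability.StatePattern] = []
    rejections = []
    combined_fits: dict[int, hmm.FittedHMM] = {}
    combined_stacked = None
    combined_ranges = None
    thresholds = reliability.ReliabilityThresholds(
        activation=config.theta_act, ci_width=config.theta_ci, split_half=config.theta_sh
    )
    hmm_summaries = {}
    for gi, gname in enumerate(ANALYSIS_GROUPS):
        stacked, ranges = concatenate_subjects(groups[gname])
        if gname == "combined":
            combined_stacked, combined_ranges = stacked, ranges
        for K in range(config.k_min, config.k_max + 1):
            try:
                fit = hmm.fit_hmm(
                    stacked,
                    ranges,
                    K,
                    n_restarts=config.n_restarts,
                    base_seed=config.seed + 1000 * gi + K,
                    expected_dwell_s=config.expected_dwell_s,
                    tr_s=config.tr_seconds,
                    tol=config.em_tol,
                    max_iter=config.em_max_iter,
                    covariance_type=config.covariance_type,
                    ridge=config.ridge,
                )
            except Exception as exc:
                raise RuntimeError(f"stage fit-hmm failed for {gname} K={K}: {exc}") from exc
            if gname == "combined":
                combined_fits[K] = fit
            seqs = hmm.decode_all(fit, stacked, ranges)
            paths = [seqs[sid].path for sid, _, _ in ranges]
            result = reliability.filter_states(
                fit.params.means,
                paths,
                stacked,
                gname,
                thresholds,
                n_boot=config.n_boot,
                seed=config.seed + 7000 + 1000 * gi + K,
            )
            pool.extend(result.passed)
            rejections.extend(result.rejected)
            hmm_summaries[f"{gname}_K{K}"] = {
                "log_likelihood": fit.log_likelihood,
                "restart_log_likelihoods": fit.restart_log_likelihoods,
                "restart_seeds": fit.restart_seeds,
                "n_iter": fit.n_iter,
                "converged": fit.converged,
                "n_states_passed": len(result.passed),
            }
    io.write_json(hmm_summaries, out / "hmm_summaries.json", chash, seed)
    io.write_tsv(io.patterns_to_frame(pool), out / "patterns.tsv", chash, seed)

    # --- cluster ----------------------------------------------------------
    stage("cluster-states")
    if not pool:
        raise RuntimeError("stage cluster-states failed: no states passed the reliability filters")
    solution = clustering.cluster_states(pool, config.similarity_threshold, config.theta_act)
    stability = clustering.threshold_stability(
        pool, config.sweep_thresholds, theta_act=config.theta_act
    )
    io.write_json(
        {
            "similarity_threshold": solution.similarity_threshold,
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "total_occupancy": c.total_occupancy,
                    "provenance": c.provenance,
                    "consensus": c.consensus,
                    "n_members": len(c.members),
                    "members": [
                        {"group": m.group, "model_k": m.model_k, "state_index": m.state_index}
                        for m in c.members
                    ],
                }
                for c in solution.clusters
            ],
            "stability": {
                "thresholds": stability.thresholds,
                "mean_similarity": stability.mean_similarity,
                "fraction_high": stability.fraction_high,
            },
        },
        out / "clusters.json",
        chash,
        seed,
    )

    # --- brain GLMMs + permutation per top cluster ------------------------
    stage("glmm-brain + permute")
    subject_groups = {s.subject_id: s.group for s in groups["combined"]}
    labels_order = [sid for sid, _, _ in combined_ranges]
    priors = glmm.PriorSpec(tau=config.prior_tau, a0=config.prior_a0, b0=config.prior_b0)
    brain_results = {}
    for c in solution.top(config.top_n_clusters):
        try:
            rep = clustering.select_representative(c)
        except ValueError as exc:
            logger.warning("cluster %d skipped: %s", c.cluster_id, exc)
            continue
        fit_c = combined_fits[rep.model_k]
        seqs = hmm.decode_all(fit_c, combined_stacked, combined_ranges)
        paths = {sid: seqs[sid].path for sid in labels_order}
        occupancy = glmm.representative_occupancy(paths, rep.state_index)
        design = glmm.build_design(features, occupancy, subject_groups, config.n_ar_lags)
        gfit = glmm.fit_map(design, priors)
        io.write_tsv(
            glmm.summary_table(gfit, config.fdr_alpha),
            out / f"glmm_brain_cluster{c.cluster_id}.tsv",
            chash,
            seed,
        )
        occ_matrix = np.vstack([occupancy[sid] for sid in labels_order])
        labels = np.array([subject_groups[sid] for sid in labels_order])
        perm = permutation.permutation_test(
            occ_matrix, labels, n_perm=config.n_perm, seed=config.seed + 5000 + c.cluster_id
        )
        brain_results[f"cluster_{c.cluster_id}"] = {
            "representative": {"model_k": rep.model_k, "state_index": rep.state_index},
            "permutation_p": perm.p_value,
            "observed_difference": perm.observed,
            "sigma_u2": gfit.sigma_u2,
        }
    io.write_json(brain_results, out / "brain_results.json", chash, seed)

    # --- behavioral GLMM --------------------------------------------------
    stage("glmm-behavior")
    press_times: dict[str, np.ndarray] = {}
    press_groups: dict[str, str] = {}
    press_outcomes: dict[str, np.ndarray] = {}
    for gname, code in (("affair", 1), ("paranoia", -1)):
        c2 = coupling.model_copy(update={"seed": config.seed + 3 + (code < 0)})
        presses = simulate.generate_button_presses(
            features, c2, code, n_subjects=sim.n_subjects_per_group
        )
        for i, times in enumerate(simulate.presses_to_times(presses, config.tr_seconds)):
            sid = f"beh_{gname}_{i + 1:02d}"
            press_times[sid] = times
            press_groups[sid] = gname
    io.write_tsv(io.presses_to_frame(press_times, press_groups), out / "presses.tsv", chash, seed)
    for sid, times in press_times.items():
        ps = behavior.align_presses(times, config.tr_seconds, sim.n_trs, sid, press_groups[sid])
        press_outcomes[sid] = ps.responses
    beh_design = glmm.build_design(features, press_outcomes, press_groups, config.n_ar_lags)
    beh_fit = glmm.fit_map(beh_design, priors)
    io.write_tsv(glmm.summary_table(beh_fit, config.fdr_alpha), out / "glmm_behavior.tsv", chash, seed)

    agreement = {
        gname: behavior.group_agreement(
            [
                behavior.PressSeries(sid, gname, press_outcomes[sid])
                for sid in press_outcomes
                if press_groups[sid] == gname
            ]
        )
        for gname in ("affair", "paranoia")
    }
    io.write_json({k: v for k, v in agreement.items()}, out / "agreement.json", chash, seed)

    logger.info("pipeline complete: %s", out)
    return {
        "config_hash": chash,
        "n_patterns": len(pool),
        "n_clusters": len(solution.clusters),
        "brain_results": brain_results,
        "out_dir": str(out),
    }
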