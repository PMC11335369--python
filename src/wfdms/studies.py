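"""Canned validation studies on synthetic data.

Each study runs the full pipeline — simulate, sample reads, build
trajectories, fit, score — under the package's default study
conditions, and returns plain numbers. They back both the test suite
and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import minimize

from .epistasis import build_extended_features, infer_epistasis
from .evaluate import (
    consistency_report,
    enrichment_ratios,
    naive_epistasis_scores,
    replicate_correlation,
)
from .frequencies import counts_to_frequencies
from .model import SelectionModel, infer_selection, integrated_covariance
from .frequencies import FrequencyTrajectory
from .simulate import SimulationConfig, sample_reads, simulate_wf

__all__ = [
    "oracle_equivalence_study",
    "recovery_study",
    "consistency_study",
    "sparsity_study",
]

#: Default single-mutant study conditions: 10 sites x 5 alleles,
#: effects ~ Normal(0, 0.1^2), N = 1e4, 5 rounds, depth 1e5, NB
#: dispersion 10, 3 replicates.
RECOVERY_CONDITIONS = SimulationConfig()


def oracle_equivalence_study(seed: int = 0, n_instances: int = 100) -> float:
    """Worst per-coordinate gap between the closed form and a numerical optimizer.

    Random small single-site instances (2-5 alleles, 1-3 intervals,
    Dirichlet frequencies) with ridge penalties cycling through
    {0.01, 0.1, 1}; the oracle maximizes the regularized quadratic
    objective directly with BFGS.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for trial in range(n_instances):
        n_alleles = int(rng.integers(2, 6))
        n_intervals = int(rng.integers(1, 4))
        z = rng.dirichlet(np.ones(n_alleles), size=n_intervals + 1).T
        traj = FrequencyTrajectory(
            replicate_id="r", times=np.arange(n_intervals + 1, dtype=float),
            sites=[1], alleles={1: [f"a{i}" for i in range(n_alleles)]},
            wildtype={1: "a0"}, z={1: z},
            depth={1: np.full(n_intervals + 1, 1000.0)})
        stats = integrated_covariance(traj)
        gamma = (0.01, 0.1, 1.0)[trial % 3]
        closed = infer_selection([stats], gamma=gamma).params.to_numpy()
        M = stats.A + gamma * np.eye(len(stats.b))
        opt = minimize(lambda s: 0.5 * s @ M @ s - s @ stats.b,
                       np.zeros(len(stats.b)), jac=lambda s: M @ s - stats.b,
                       method="BFGS", options={"gtol": 1e-12, "maxiter": 1000})
        worst = max(worst, float(np.max(np.abs(opt.x - closed))))
    return worst


def _simulate_and_fit(seed: int):
    config = replace(RECOVERY_CONDITIONS, seed=seed)
    dataset = sample_reads(simulate_wf(config))
    trajectories = {rep: counts_to_frequencies(dataset.to_aa_count_tables(rep))
                    for rep in dataset.replicate_ids}
    model = SelectionModel(list(trajectories.values()))
    return dataset, trajectories, model


def recovery_study(seed: int = 0, n_seeds: int = 10) -> list[float]:
    """Joint-inference Pearson R against the true selection coefficients.

    One value per simulated dataset; seeds are ``seed .. seed+n_seeds-1``.
    """
    results = []
    for s in range(seed, seed + n_seeds):
        dataset, _, model = _simulate_and_fit(s)
        fit = model.fit().gauge_to_reference()
        results.append(replicate_correlation(
            dataset.true_s, fit.params, "pearson",
            exclude_wt=True, wildtype=dataset.wildtype))
    return results


def consistency_study(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Mean inter-replicate Pearson R: WF MAP vs enrichment ratios."""
    wf_r, ratio_r, wf_r2, ratio_r2 = [], [], [], []
    for s in range(seed, seed + n_seeds):
        dataset, trajectories, model = _simulate_and_fit(s)
        wf = {rep: model.fit_single(rep).params for rep in model.replicate_ids}
        ratios = {rep: enrichment_ratios(traj)
                  for rep, traj in trajectories.items()}
        wf_report = consistency_report(wf, "wf_map", wildtype=dataset.wildtype)
        ratio_report = consistency_report(ratios, "enrichment",
                                          wildtype=dataset.wildtype)
        wf_r.append(wf_report.mean_pearson)
        ratio_r.append(ratio_report.mean_pearson)
        wf_r2.append(wf_report.mean_r_squared)
        ratio_r2.append(ratio_report.mean_r_squared)
    return {
        "wf_map": float(np.mean(wf_r)),
        "enrichment": float(np.mean(ratio_r)),
        "wf_map_r2": float(np.mean(wf_r2)),
        "enrichment_r2": float(np.mean(ratio_r2)),
    }


def sparsity_study(seed: int = 0, n_seeds: int = 10) -> list[float]:
    """Shrinkage sparsity of pair coefficients under zero true epistasis.

    Double-mutant libraries (5 sites, 3 alleles, 10% doubles) with no
    true interactions: for each seed, returns the fraction of
    regularized |pair coefficients| exceeding the 90th percentile of the
    naive log-ratio epistasis |values| on the same data (the naive
    estimate's own fraction is 0.10 by construction).
    """
    fractions = []
    for s in range(seed, seed + n_seeds):
        config = replace(RECOVERY_CONDITIONS, seed=s, n_sites=5,
                         alleles_per_site=3, fraction_double=0.10)
        dataset = sample_reads(simulate_wf(config))
        rep = dataset.replicate_ids[0]
        ext = build_extended_features(dataset.to_variant_tables(rep),
                                      pseudocount=0.5)
        fitted = infer_epistasis(ext)
        naive = naive_epistasis_scores(ext)
        threshold = float(np.percentile(np.abs(naive.to_numpy()), 90))
        fractions.append(float(np.mean(
            np.abs(fitted.pairs.to_numpy()) > threshold)))
    return fractions
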