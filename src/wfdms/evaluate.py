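"""Baselines and consistency metrics.

Contains the classic log enrichment-ratio estimator of mutation
effects, replicate-consistency correlations (Pearson and Spearman), a
truth-recovery report for simulated data, and a naive log-ratio
epistasis estimate used as the comparison point for the regularized
pairwise estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .epistasis import ExtendedTrajectory
from .frequencies import FrequencyTrajectory

__all__ = [
    "ConsistencyReport",
    "enrichment_ratios",
    "replicate_correlation",
    "consistency_report",
    "recovery_report",
    "naive_epistasis_scores",
]


def enrichment_ratios(
    traj: FrequencyTrajectory, pseudocount: float = 0.5
) -> pd.Series:
    """Log2 enrichment of each allele relative to wild type.

    ``score(site, a) = log2[(z_a(t_K)/z_WT(t_K)) / (z_a(t_0)/z_WT(t_0))]``
    computed from pseudocount-smoothed counts at the first and last
    timepoints only (the classic ratio estimator); the wild-type score
    is identically zero.
    """
    if traj.counts is None:
        raise ValueError("trajectory carries no raw counts")
    scores: dict[tuple[int, str], float] = {}
    for site in traj.sites:
        counts = traj.counts[site]
        alleles = traj.alleles[site]
        n = len(alleles)
        wt = traj.wildtype[site]
        idx = traj.allele_index(site)
        smoothed = (counts + pseudocount) / (
            counts.sum(axis=0) + pseudocount * n)
        z0, zK = smoothed[:, 0], smoothed[:, -1]
        if z0[idx[wt]] == 0 or zK[idx[wt]] == 0:
            raise ValueError(f"site {site}: wild-type frequency is zero after smoothing")
        for a in alleles:
            if a == wt:
                scores[(site, a)] = 0.0
                continue
            i = idx[a]
            if z0[i] == 0 or zK[i] == 0:
                raise ValueError(
                    f"site {site}, allele {a}: zero frequency with zero pseudocount")
            scores[(site, a)] = float(
                np.log2((zK[i] / zK[idx[wt]]) / (z0[i] / z0[idx[wt]])))
    return pd.Series(scores)


def _drop_wt(scores: pd.Series, wildtype: Mapping[int, str]) -> pd.Series:
    keep = [key for key in scores.index if wildtype.get(key[0]) != key[1]]
    return scores.loc[keep]


def replicate_correlation(
    a: pd.Series,
    b: pd.Series,
    method: str = "pearson",
    exclude_wt: bool = True,
    wildtype: Mapping[int, str] | None = None,
) -> float:
    """Correlation between two score vectors over their shared index.

    Wild-type entries are excluded by default (they are reference
    constants under ratio methods and would inflate agreement); at least
    three shared entries with nonzero variance are required.
    """
    if exclude_wt:
        if wildtype is None:
            raise ValueError("exclude_wt requires a wild-type mapping")
        a = _drop_wt(a, wildtype)
        b = _drop_wt(b, wildtype)
    shared = [key for key in a.index if key in set(b.index)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared entries; need >= 3")
    x = a.loc[shared].to_numpy(float)
    y = b.loc[shared].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a score vector; correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass
class ConsistencyReport:
    """Pairwise replicate-consistency correlations for one method."""

    method: str
    pair_labels: list[tuple[str, str]]
    pearson: list[float]
    spearman: list[float]

    @property
    def r_squared(self) -> list[float]:
        return [r**2 for r in self.pearson]

    @property
    def mean_pearson(self) -> float:
        return float(np.mean(self.pearson))

    @property
    def mean_spearman(self) -> float:
        return float(np.mean(self.spearman))

    @property
    def mean_r_squared(self) -> float:
        return float(np.mean(self.r_squared))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.method,
            "replicate_a": [a for a, _ in self.pair_labels],
            "replicate_b": [b for _, b in self.pair_labels],
            "pearson_r": self.pearson,
            "spearman_rho": self.spearman,
            "r_squared": self.r_squared,
        })

    def summary(self) -> str:
        return (f"{self.method}: mean R = {self.mean_pearson:.4f}, "
                f"mean rho = {self.mean_spearman:.4f}, "
                f"mean R^2 = {self.mean_r_squared:.4f} "
                f"over {len(self.pearson)} replicate pair(s)")


def consistency_report(
    scores_by_replicate: Mapping[str, pd.Series],
    method: str = "scores",
    wildtype: Mapping[int, str] | None = None,
    exclude_wt: bool = True,
) -> ConsistencyReport:
    """All pairwise replicate correlations of one method's score vectors."""
    labels = list(scores_by_replicate)
    if len(labels) < 2:
        raise ValueError("need at least two replicates")
    pairs, pearson, spearman = [], [], []
    for a, b in combinations(labels, 2):
        kwargs = dict(exclude_wt=exclude_wt, wildtype=wildtype)
        pearson.append(replicate_correlation(
            scores_by_replicate[a], scores_by_replicate[b], "pearson", **kwargs))
        spearman.append(replicate_correlation(
            scores_by_replicate[a], scores_by_replicate[b], "spearman", **kwargs))
        pairs.append((a, b))
    return ConsistencyReport(method=method, pair_labels=pairs,
                             pearson=pearson, spearman=spearman)


@dataclass
class RecoveryReport:
    """Truth-recovery and replicate-consistency comparison on simulated data."""

    truth_pearson_inferred: float
    truth_spearman_inferred: float
    truth_pearson_baseline: float
    truth_spearman_baseline: float
    inferred_consistency: ConsistencyReport | None
    baseline_consistency: ConsistencyReport | None

    @property
    def mean_r2_improvement(self) -> float:
        """Mean replicate R^2 of the WF estimator minus the baseline's."""
        if self.inferred_consistency is None or self.baseline_consistency is None:
            raise ValueError("replicate consistency unavailable (single replicate)")
        return (self.inferred_consistency.mean_r_squared
                - self.baseline_consistency.mean_r_squared)

    def summary(self) -> str:
        lines = [
            "Recovery vs ground truth",
            f"  WF MAP:     R = {self.truth_pearson_inferred:.4f}, "
            f"rho = {self.truth_spearman_inferred:.4f}",
            f"  enrichment: R = {self.truth_pearson_baseline:.4f}, "
            f"rho = {self.truth_spearman_baseline:.4f}",
        ]
        if self.inferred_consistency is not None:
            lines += [self.inferred_consistency.summary(),
                      self.baseline_consistency.summary(),
                      f"mean R^2 improvement: {self.mean_r2_improvement:+.4f}"]
        return "\n".join(lines)


def recovery_report(
    truth: pd.Series,
    inferred: pd.Series,
    baseline: pd.Series,
    wildtype: Mapping[int, str],
    inferred_by_replicate: Mapping[str, pd.Series] | None = None,
    baseline_by_replicate: Mapping[str, pd.Series] | None = None,
) -> RecoveryReport:
    """Compare inferred and baseline scores against simulation ground truth.

    ``truth`` is indexed by (site, mutant allele); wild-type entries of
    the score vectors are excluded throughout.
    """
    kwargs = dict(exclude_wt=True, wildtype=wildtype)
    inf_cons = base_cons = None
    if inferred_by_replicate is not None and len(inferred_by_replicate) >= 2:
        inf_cons = consistency_report(inferred_by_replicate, "wf_map",
                                      wildtype=wildtype)
        base_cons = consistency_report(baseline_by_replicate, "enrichment",
                                       wildtype=wildtype)
    return RecoveryReport(
        truth_pearson_inferred=replicate_correlation(truth, inferred, "pearson", **kwargs),
        truth_spearman_inferred=replicate_correlation(truth, inferred, "spearman", **kwargs),
        truth_pearson_baseline=replicate_correlation(truth, baseline, "pearson", **kwargs),
        truth_spearman_baseline=replicate_correlation(truth, baseline, "spearman", **kwargs),
        inferred_consistency=inf_cons,
        baseline_consistency=base_cons,
    )


def naive_epistasis_scores(
    ext: ExtendedTrajectory, pseudocount: float = 0.5
) -> pd.Series:
    """Naive log-ratio epistasis: double enrichment minus single enrichments.

    For each pair feature, ``eps = logE(ab) - logE(a) - logE(b)`` where
    ``logE(f)`` is the log2 enrichment of feature-carriage counts
    relative to the wild-type variant between the first and last
    timepoints, with pseudocount smoothing. This is the unregularized
    baseline the shrinkage estimator is compared against.
    """
    z_counts = ext.carriage.T @ ext.counts
    wt_counts = ext.counts[ext.wt_index]
    if wt_counts[0] + pseudocount <= 0 or wt_counts[-1] + pseudocount <= 0:
        raise ValueError("wild-type count is zero and pseudocount is zero")

    def log_enrichment(row: np.ndarray) -> float:
        return float(
            np.log2((row[-1] + pseudocount) / (wt_counts[-1] + pseudocount))
            - np.log2((row[0] + pseudocount) / (wt_counts[0] + pseudocount)))

    f_index = {f: i for i, f in enumerate(ext.features)}
    scores: dict = {}
    for f in ext.features:
        if len(f) != 2:
            continue
        eps = (log_enrichment(z_counts[f_index[f]])
               - log_enrichment(z_counts[f_index[(f[0],)]])
               - log_enrichment(z_counts[f_index[(f[1],)]]))
        scores[f] = eps
    return pd.Series(scores, dtype=float)
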