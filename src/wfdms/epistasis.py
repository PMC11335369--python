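"""Pairwise epistasis inference from variant-level (haplotype) counts.

The additive model is extended with pair features: the fitness of a
sequence is the sum of its single-substitution coefficients plus a
pairwise coefficient for every pair of substitutions it carries at
different sites. Features are indicator functions on variants, so the
instantaneous covariance between features f and g is

    C_fg(t) = z_fg(t) - z_f(t) z_g(t)

where ``z_fg`` is the frequency of sequences carrying both features.
The same ridge-regularized MAP solve as for single mutations is applied
to the extended feature vector. Pair features are created only for
substitution pairs observed together in at least one library variant:
an unobserved pair is "no evidence", not an inferred zero.

With pair features disabled this machinery is exactly the
haplotype-linkage route for single-mutation inference — covariance
between substitutions at different sites is estimated from variant
co-occurrence instead of being zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ConfigError, Substitution, VariantCountTable
from .model import (
    InferenceConfig,
    IntegratedStatistics,
    SelectionResults,
    infer_selection,
    select_gamma,
)

__all__ = [
    "ExtendedTrajectory",
    "EpistasisResults",
    "build_extended_features",
    "infer_epistasis",
    "selection_from_variants",
    "site_pair_scores",
]

#: A feature is a sorted tuple of substitutions: length 1 = single,
#: length 2 = pair (distinct sites, site_i < site_j).
Feature = tuple


@dataclass
class ExtendedTrajectory:
    """Variant frequencies and feature carriage for one replicate.

    ``counts`` is (n_variants, n_times) raw read counts; ``freqs`` the
    (optionally pseudocount-smoothed) variant frequencies; ``carriage``
    the boolean variant-by-feature indicator matrix.
    """

    replicate_id: str
    times: np.ndarray
    variants: list[tuple[Substitution, ...]]
    counts: np.ndarray
    freqs: np.ndarray
    features: list[Feature]
    carriage: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        z = self.feature_frequencies()
        singles = {f[0]: i for i, f in enumerate(self.features) if len(f) == 1}
        for i, f in enumerate(self.features):
            if len(f) == 2:
                bound = np.minimum(z[singles[f[0]]], z[singles[f[1]]])
                if np.any(z[i] > bound + 1e-12):
                    raise ValueError(f"pair frequency exceeds a marginal for {f!r}")

    def feature_frequencies(self) -> np.ndarray:
        """(n_features, n_times) carriage frequencies ``z_f(t)``."""
        return self.carriage.T @ self.freqs

    @property
    def wt_index(self) -> int:
        return self.variants.index(())


def _variant_features(
    subs: tuple[Substitution, ...], include_pairs: bool
) -> list[Feature]:
    feats: list[Feature] = [(s,) for s in subs]
    if include_pairs:
        feats.extend(tuple(sorted(p)) for p in combinations(sorted(subs), 2))
    return feats


def build_extended_features(
    tables: Sequence[VariantCountTable],
    include_pairs: bool = True,
    pseudocount: float = 0.0,
    features: Sequence[Feature] | None = None,
) -> ExtendedTrajectory:
    """Build the extended (single + pair) feature trajectory of a replicate.

    Feature frequencies are carriage fractions: the frequency of a
    single feature is the total frequency of variants carrying that
    substitution; a pair feature counts variants carrying both. With
    ``features`` given, that index is used (e.g. the union across
    replicates for a joint fit); otherwise features observed in this
    replicate's library define it.
    """
    if len(tables) < 2:
        raise ValueError("need at least two timepoints")
    reps = {t.sample.replicate_id for t in tables}
    if len(reps) != 1:
        raise ValueError(f"tables span multiple replicates: {sorted(reps)}")
    tables = sorted(tables, key=lambda t: t.sample.time)
    times = np.array([t.sample.time for t in tables], dtype=float)

    variants = sorted({subs for t in tables for subs, _ in t.variants})
    if () not in variants:
        variants.insert(0, ())
    v_index = {v: i for i, v in enumerate(variants)}
    counts = np.zeros((len(variants), len(tables)))
    for k, t in enumerate(tables):
        for subs, c in t.variants:
            counts[v_index[subs], k] = c
    totals = counts.sum(axis=0)
    if np.any(totals + pseudocount * len(variants) <= 0):
        raise ValueError("zero total count at a timepoint")
    freqs = (counts + pseudocount) / (totals + pseudocount * len(variants))

    if features is None:
        feats: set[Feature] = set()
        for v in variants:
            feats.update(_variant_features(v, include_pairs))
        features = sorted(feats)
    else:
        features = list(features)

    f_index = {f: i for i, f in enumerate(features)}
    carriage = np.zeros((len(variants), len(features)))
    for vi, v in enumerate(variants):
        vset = set(v)
        for f in features:
            if set(f) <= vset:
                carriage[vi, f_index[f]] = 1.0
    return ExtendedTrajectory(
        replicate_id=tables[0].sample.replicate_id, times=times,
        variants=variants, counts=counts, freqs=freqs,
        features=features, carriage=carriage,
    )


def extended_statistics(
    ext: ExtendedTrajectory, config: InferenceConfig | None = None
) -> IntegratedStatistics:
    """Integrated covariance and net change over extended features."""
    config = config or InferenceConfig()
    X = ext.carriage
    z = ext.feature_frequencies()
    n = len(ext.features)
    A = np.zeros((n, n))
    dts = np.diff(ext.times) * config.time_unit

    def instantaneous(k: int) -> np.ndarray:
        p = ext.freqs[:, k]
        zk = z[:, k]
        return (X.T * p) @ X - np.outer(zk, zk)

    cs = [instantaneous(k) for k in range(ext.times.size)]
    for k, dt in enumerate(dts):
        if config.integration == "trapezoid":
            A += dt * 0.5 * (cs[k] + cs[k + 1])
        else:
            A += dt * cs[k]
    A = 0.5 * (A + A.T)  # symmetrize away round-off
    b = z[:, -1] - z[:, 0]
    return IntegratedStatistics(index=list(ext.features), A=A, b=b,
                                replicate_id=ext.replicate_id)


@dataclass
class EpistasisResults:
    """Single and pairwise coefficients from an extended-feature fit."""

    params: pd.Series
    gamma: float
    scope: str
    config: InferenceConfig
    n_replicates: int = 1

    @property
    def singles(self) -> pd.Series:
        """Coefficients of single substitutions, indexed by Substitution."""
        keys = [f for f in self.params.index if len(f) == 1]
        return pd.Series([self.params[f] for f in keys],
                         index=pd.Index([f[0] for f in keys], tupleize_cols=False))

    @property
    def pairs(self) -> pd.Series:
        """Pairwise coefficients, indexed by (substitution, substitution)."""
        keys = [f for f in self.params.index if len(f) == 2]
        return pd.Series([self.params[f] for f in keys],
                         index=pd.Index(keys, tupleize_cols=False), dtype=float)

    def site_pair_scores(self, normalize: bool = True) -> pd.DataFrame:
        return site_pair_scores(self, normalize=normalize)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), value in self.pairs.items():
            rows.append({"site_i": a.site, "aa_i": a.mut_aa,
                         "site_j": b.site, "aa_j": b.mut_aa,
                         "epistatic_coefficient": value})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pair_vals = self.pairs.to_numpy(float)
        lines = [
            "Pairwise epistasis estimates (extended WF MAP fit)",
            "=" * 50,
            f"single features:  {len(self.singles)}",
            f"pair features:    {len(pair_vals)}",
            f"replicate scope:  {self.scope} (n={self.n_replicates})",
            f"ridge penalty γ:  {self.gamma:.6g}",
        ]
        if len(pair_vals):
            lines.append(f"mean |pair s|:    {np.abs(pair_vals).mean():.6g}")
        return "\n".join(lines)


def infer_epistasis(
    ext: ExtendedTrajectory | Sequence[ExtendedTrajectory],
    config: InferenceConfig | None = None,
    gamma: float | None = None,
) -> EpistasisResults:
    """MAP fit of single + pairwise coefficients.

    Accepts one extended trajectory or a list (joint across replicates;
    all must share the feature index). The extended system is always
    rank-deficient in practice, so a strictly positive penalty is
    required.
    """
    config = config or InferenceConfig()
    exts = [ext] if isinstance(ext, ExtendedTrajectory) else list(ext)
    stats = [extended_statistics(e, config) for e in exts]
    if gamma is None:
        gamma = select_gamma(stats, config)
    if gamma <= 0:
        raise ConfigError("epistasis inference requires gamma > 0")
    res = infer_selection(stats, config, gamma=gamma)
    return EpistasisResults(params=res.params, gamma=res.gamma, scope=res.scope,
                            config=config, n_replicates=len(stats))


def selection_from_variants(
    tables_by_replicate: Sequence[Sequence[VariantCountTable]],
    config: InferenceConfig | None = None,
    gamma: float | None = None,
    pseudocount: float = 0.0,
) -> SelectionResults:
    """Haplotype-linkage single-mutation inference from variant tables.

    Covariance between substitutions at different sites is computed from
    variant co-occurrence (pair features disabled): this is
    :func:`infer_epistasis` restricted to single features.
    """
    model = EpistasisModel(tables_by_replicate, config,
                           pseudocount=pseudocount, include_pairs=False)
    stats = [extended_statistics(e, model.config) for e in model.trajectories]
    return infer_selection(stats, model.config, gamma=gamma)


class EpistasisModel:
    """Extended-feature (single + pair) MAP estimator over variant tables.

    Parameters
    ----------
    tables_by_replicate : sequence of sequences of VariantCountTable
        One inner sequence per replicate, each covering that
        replicate's timepoints. Features are the union across
        replicates, so joint fits share one index.
    config : InferenceConfig, optional
    pseudocount : float
        Variant-frequency smoothing (per variant).
    """

    def __init__(
        self,
        tables_by_replicate: Sequence[Sequence[VariantCountTable]],
        config: InferenceConfig | None = None,
        pseudocount: float = 0.0,
        include_pairs: bool = True,
    ) -> None:
        self.config = config or InferenceConfig()
        feats: set[Feature] = set()
        for tables in tables_by_replicate:
            feats.update(build_extended_features(
                tables, include_pairs=include_pairs,
                pseudocount=pseudocount).features)
        self.features = sorted(feats)
        self.trajectories = [
            build_extended_features(tables, include_pairs=include_pairs,
                                    pseudocount=pseudocount,
                                    features=self.features)
            for tables in tables_by_replicate
        ]

    def fit(self, gamma: float | None = None) -> EpistasisResults:
        return infer_epistasis(self.trajectories, self.config, gamma=gamma)


def site_pair_scores(
    result: EpistasisResults, normalize: bool = True
) -> pd.DataFrame:
    """Sum of squared pairwise coefficients for each pair of sites.

    Returns a symmetric non-negative site-by-site matrix; with
    ``normalize`` the scores are scaled to [0, 1] by dividing by the
    maximum (skipped, with a warning, when all scores are zero).
    """
    pairs = result.pairs
    sites = sorted({s.site for f in result.params.index for s in f})
    mat = pd.DataFrame(0.0, index=sites, columns=sites)
    for (a, b), value in pairs.items():
        mat.loc[a.site, b.site] += value**2
        mat.loc[b.site, a.site] += value**2
    if normalize:
        top = float(mat.to_numpy().max())
        if top > 0:
            mat /= top
        else:
            warnings.warn("all site-pair scores are zero; normalization skipped")
    return mat
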