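"""Wright-Fisher path-likelihood MAP estimation of selection coefficients.

The model treats each selection round of a deep mutational scanning
experiment as one generation of a Wright-Fisher population. Under the
Gaussian (diffusion) approximation of the WF path likelihood, the
log-likelihood of an observed frequency trajectory is quadratic in the
selection coefficients ``s``, with sufficient statistics

* ``A`` — the time-integrated allele-frequency covariance matrix, and
* ``b`` — the net frequency change ``z(t_K) - z(t_0)``.

Adding a zero-mean Gaussian prior of precision ``gamma`` (an L2 /
ridge penalty), the maximum-a-posteriori estimate is the solution of
the symmetric positive-definite linear system::

    (sum_r A_r + gamma * I) s_hat = sum_r b_r

where the sum runs over replicates: joint inference pools evidence by
summing sufficient statistics, which weights replicates by the
information they carry rather than averaging their point estimates.

De novo mutation during selection rounds is not modelled: the variant
library is fixed at the first timepoint, so the mutational-flux term of
the full WF path likelihood vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .frequencies import FrequencyTrajectory
from .io import ConfigError

__all__ = [
    "InferenceConfig",
    "IntegratedStatistics",
    "SelectionResults",
    "SelectionModel",
    "NumericalError",
    "integrated_covariance",
    "infer_selection",
    "select_gamma",
    "gauge_to_reference",
]


class NumericalError(RuntimeError):
    """The linear solve failed; typically the system needs gamma > 0."""


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for the MAP estimator.

    Parameters
    ----------
    gamma : float
        Ridge penalty (prior precision scale); ignored unless
        ``gamma_mode="fixed"``. Must be >= 0.
    gamma_mode : {"adaptive", "fixed"}
        ``"adaptive"`` sets gamma from the data as the mean diagonal of
        the pooled integrated covariance, a heuristic that scales the
        prior with the overall information in the experiment;
        ``"fixed"`` uses ``gamma`` as given.
    linkage_mode : {"site", "haplotype"}
        ``"site"`` treats sites as independent (block-diagonal ``A``),
        appropriate for single-mutant libraries; ``"haplotype"``
        requires variant-level count tables and is handled by the
        epistasis machinery.
    time_unit : float
        Generations per unit of the sample times (default 1: times are
        selection rounds).
    integration : {"trapezoid", "left"}
        Quadrature rule for the covariance integral.
    include_stop : bool
        Whether stop-codon alleles participate in inference.
    """

    gamma: float = 1.0
    gamma_mode: str = "adaptive"
    linkage_mode: str = "site"
    time_unit: float = 1.0
    integration: str = "trapezoid"
    include_stop: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.time_unit <= 0:
            raise ValueError("time_unit must be > 0")
        if self.gamma_mode not in ("adaptive", "fixed"):
            raise ValueError(f"unknown gamma_mode {self.gamma_mode!r}")
        if self.linkage_mode not in ("site", "haplotype"):
            raise ValueError(f"unknown linkage_mode {self.linkage_mode!r}")
        if self.integration not in ("trapezoid", "left"):
            raise ValueError(f"unknown integration rule {self.integration!r}")


@dataclass
class IntegratedStatistics:
    """Sufficient statistics of one replicate's trajectory.

    ``A`` is the integrated covariance, ``b`` the net frequency change,
    and ``index`` the ordered (site, allele) — or extended feature —
    labels of the rows.
    """

    index: list
    A: np.ndarray
    b: np.ndarray
    replicate_id: str

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.A.shape != (n, n) or self.b.shape != (n,):
            raise ValueError("statistics shape mismatch")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) < -1e-12):
            raise ValueError("A must have a non-negative diagonal")


def _covariance_block(z: np.ndarray) -> np.ndarray:
    """Multinomial covariance of one site's allele frequencies at one time."""
    return np.diag(z) - np.outer(z, z)


def integrated_covariance(
    traj: FrequencyTrajectory, config: InferenceConfig | None = None
) -> IntegratedStatistics:
    """Compute the integrated covariance ``A`` and net change ``b``.

    Within each site, the instantaneous covariance is the multinomial
    form ``C_aa = z_a (1 - z_a)``, ``C_ab = -z_a z_b``; the integral
    over time uses the trapezoid rule by default. Site-factorized mode
    leaves cross-site blocks at zero.
    """
    config = config or InferenceConfig()
    if config.linkage_mode == "haplotype":
        raise ConfigError(
            "haplotype linkage requires variant-level count tables; "
            "build extended features from VariantCountTable records instead"
        )
    index = [(site, a) for site in traj.sites for a in traj.alleles[site]]
    n = len(index)
    A = np.zeros((n, n))
    b = np.zeros(n)
    dts = np.diff(traj.times) * config.time_unit
    offset = 0
    for site in traj.sites:
        zs = traj.z[site]
        m = zs.shape[0]
        block = np.zeros((m, m))
        for k, dt in enumerate(dts):
            if config.integration == "trapezoid":
                c = 0.5 * (_covariance_block(zs[:, k]) + _covariance_block(zs[:, k + 1]))
            else:
                c = _covariance_block(zs[:, k])
            block += dt * c
        sl = slice(offset, offset + m)
        A[sl, sl] = block
        b[sl] = zs[:, -1] - zs[:, 0]
        offset += m
    return IntegratedStatistics(index=index, A=A, b=b,
                                replicate_id=traj.replicate_id)


def select_gamma(
    stats: Sequence[IntegratedStatistics], config: InferenceConfig
) -> float:
    """Resolve the ridge penalty for a set of replicate statistics.

    Fixed mode returns ``config.gamma``. Adaptive mode returns the mean
    diagonal of the pooled integrated covariance — a data-scaled default
    that keeps the prior comparable to the typical information content
    per coefficient. Falls back to 1 (with a warning) if the pooled
    covariance is identically zero.
    """
    if not stats:
        raise ValueError("no statistics supplied")
    if config.gamma_mode == "fixed":
        return float(config.gamma)
    diag = sum(np.diag(s.A) for s in stats)
    gamma = float(np.mean(diag))
    if gamma <= 0.0:
        warnings.warn("pooled integrated covariance is zero; using gamma = 1")
        return 1.0
    return gamma


def infer_selection(
    stats: Sequence[IntegratedStatistics],
    config: InferenceConfig | None = None,
    gamma: float | None = None,
) -> "SelectionResults":
    """Solve the regularized MAP system for selection coefficients.

    Statistics from multiple replicates are pooled by summation before
    the solve; a single replicate is the list-of-one case. The solve
    uses a Cholesky factorization and fails loudly (advising
    ``gamma > 0``) if the system is singular.
    """
    config = config or InferenceConfig()
    stats = list(stats)
    if not stats:
        raise ValueError("no statistics supplied")
    index = stats[0].index
    for s in stats[1:]:
        if s.index != index:
            raise ValueError(
                f"replicate {s.replicate_id!r} has a different feature index"
            )
    if gamma is None:
        gamma = select_gamma(stats, config)
    A = sum(s.A for s in stats)
    b = sum(s.b for s in stats)
    M = A + gamma * np.eye(len(index))
    if gamma == 0.0:
        # Cholesky can slip through an exactly singular PSD matrix on
        # round-off alone; reject it explicitly instead of returning noise
        eigs = np.linalg.eigvalsh(M)
        if eigs[0] <= 1e-12 * max(eigs[-1], 1.0):
            raise NumericalError(
                "normal matrix is singular at gamma=0; use gamma > 0 to "
                "regularize")
    try:
        c, low = linalg.cho_factor(M, check_finite=False)
        s_hat = linalg.cho_solve((c, low), b, check_finite=False)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            f"normal matrix is not positive definite (gamma={gamma}); "
            "use gamma > 0 to regularize"
        ) from exc
    scope = stats[0].replicate_id if len(stats) == 1 else "joint"
    return SelectionResults(
        params=pd.Series(s_hat, index=pd.Index(index, tupleize_cols=False)),
        gauge="raw", gamma=float(gamma), scope=scope, config=config,
        n_replicates=len(stats),
    )


@dataclass
class SelectionResults:
    """Inferred selection coefficients and the settings that produced them.

    ``params`` is indexed by (site, allele) — or by extended feature for
    haplotype fits. ``gauge`` is ``"raw"`` as estimated, or ``"wt-zero"``
    after :meth:`gauge_to_reference`, in which case ``params_raw`` keeps
    the original values.
    """

    params: pd.Series
    gauge: str
    gamma: float
    scope: str
    config: InferenceConfig
    n_replicates: int = 1
    wildtype: Mapping[int, str] | None = None
    params_raw: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.params.to_numpy(float))):
            raise ValueError("selection coefficients must be finite")

    @property
    def sites(self) -> list[int]:
        return sorted({site for site, _ in self.params.index})

    def gauge_to_reference(
        self, wildtype: Mapping[int, str] | None = None
    ) -> "SelectionResults":
        """Report coefficients relative to the wild-type allele per site."""
        return gauge_to_reference(self, wildtype or self.wildtype)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        wt = self.wildtype or {}
        for (site, allele), value in self.params.items():
            rows.append({"site": site, "wildtype_aa": wt.get(site, ""),
                         "amino_acid": allele, "selection_coefficient": value})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        p = self.params.to_numpy(float)
        lines = [
            "Wright-Fisher MAP selection-coefficient estimates",
            "=" * 49,
            f"coefficients:      {len(p)}",
            f"sites:             {len(self.sites)}",
            f"replicate scope:   {self.scope} (n={self.n_replicates})",
            f"gauge:             {self.gauge}",
            f"ridge penalty γ:   {self.gamma:.6g} ({self.config.gamma_mode})",
            f"mean |s|:          {np.abs(p).mean():.6g}",
            f"max s:             {p.max():.6g}  min s: {p.min():.6g}",
        ]
        return "\n".join(lines)


def gauge_to_reference(
    result: SelectionResults, wildtype: Mapping[int, str] | None
) -> SelectionResults:
    """Shift each site's coefficients so the wild-type allele is zero.

    The shift is a per-site gauge transformation: differences between
    alleles at a site — and hence correlations computed over non-WT
    alleles — are unchanged. Raw-gauge input is required; the raw
    coefficients are retained on the returned object.
    """
    if result.gauge != "raw":
        raise ValueError(f"expected a raw-gauge result, got {result.gauge!r}")
    if wildtype is None:
        raise ValueError("a per-site wild-type mapping is required")
    shifted = result.params.copy()
    for site in result.sites:
        wt = wildtype[site]
        if (site, wt) not in result.params.index:
            raise KeyError(f"wild-type allele {wt!r} absent at site {site}")
        ref = result.params[(site, wt)]
        for key in result.params.index:
            if key[0] == site:
                shifted[key] = result.params[key] - ref
    return replace(result, params=shifted, gauge="wt-zero",
                   wildtype=dict(wildtype), params_raw=result.params)


class SelectionModel:
    """MAP estimator of per-mutation selection coefficients.

    Parameters
    ----------
    trajectories : sequence of FrequencyTrajectory
        One trajectory per replicate, sharing site and allele sets.
    config : InferenceConfig, optional

    Examples
    --------
    >>> model = SelectionModel(trajectories)          # doctest: +SKIP
    >>> res = model.fit()                             # joint across replicates
    >>> res.gauge_to_reference().params               # WT-zero coefficients
    """

    def __init__(
        self,
        trajectories: Sequence[FrequencyTrajectory],
        config: InferenceConfig | None = None,
    ) -> None:
        trajectories = list(trajectories)
        if not trajectories:
            raise ValueError("at least one trajectory is required")
        self.trajectories = trajectories
        self.config = config or InferenceConfig()
        self.statistics = [integrated_covariance(t, self.config)
                           for t in trajectories]
        self.wildtype = dict(trajectories[0].wildtype)

    @property
    def replicate_ids(self) -> list[str]:
        return [t.replicate_id for t in self.trajectories]

    def fit(self, gamma: float | None = None) -> SelectionResults:
        """Joint fit pooling the sufficient statistics of all replicates."""
        res = infer_selection(self.statistics, self.config, gamma=gamma)
        res.wildtype = self.wildtype
        return res

    def fit_single(
        self, replicate_id: str, gamma: float | None = None
    ) -> SelectionResults:
        """Fit one replicate alone (for replicate-consistency analyses)."""
        for stat in self.statistics:
            if stat.replicate_id == replicate_id:
                res = infer_selection([stat], self.config, gamma=gamma)
                res.wildtype = self.wildtype
                return res
        raise KeyError(f"unknown replicate {replicate_id!r}")
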