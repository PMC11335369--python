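"""Allele-frequency trajectories from count tables.

Counts flow through three steps before inference:

1. codon counts are aggregated to amino-acid counts with the standard
   genetic code (:func:`aggregate_codons_to_aa`);
2. amino-acid counts across the timepoints of a replicate become a
   :class:`FrequencyTrajectory` with optional pseudocount smoothing
   (:func:`counts_to_frequencies`);
3. when a wild-type-only control sample is available, sequencing errors
   are subtracted from the observed frequencies (:func:`error_correct`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._codon import AA_ALPHABET, CODON_TO_AA
from .io import CodonCountTable, SampleKey

__all__ = [
    "AminoAcidCountTable",
    "FrequencyTrajectory",
    "aggregate_codons_to_aa",
    "counts_to_frequencies",
    "error_correct",
]


@dataclass
class AminoAcidCountTable:
    """Per-site amino-acid counts for one sample."""

    sites: list[int]
    wildtype_aa: dict[int, str]
    counts: dict[int, dict[str, int]]
    sample: SampleKey

    def depth(self, site: int) -> int:
        return sum(self.counts[site].values())


def aggregate_codons_to_aa(
    table: CodonCountTable, include_stop: bool = True
) -> AminoAcidCountTable:
    """Sum codon counts over synonymous codons.

    With ``include_stop=False``, stop-codon reads are dropped entirely:
    they appear neither as an allele nor in the per-site depth.
    """
    alleles = AA_ALPHABET if include_stop else AA_ALPHABET[:-1]
    counts: dict[int, dict[str, int]] = {}
    wildtype: dict[int, str] = {}
    for site in table.sites:
        aa_counts = {aa: 0 for aa in alleles}
        for codon, n in table.counts[site].items():
            aa = CODON_TO_AA[codon]
            if aa in aa_counts:
                aa_counts[aa] += n
        counts[site] = aa_counts
        wildtype[site] = CODON_TO_AA[table.wildtype_codon[site]]
    return AminoAcidCountTable(
        sites=list(table.sites), wildtype_aa=wildtype, counts=counts,
        sample=table.sample,
    )


@dataclass
class FrequencyTrajectory:
    """Per-site allele frequencies over the ordered timepoints of a replicate.

    ``z[site]`` is an ``(n_alleles, n_times)`` array of frequencies that
    sum to one over alleles at every timepoint; ``depth[site]`` holds
    total counts per timepoint and ``counts[site]`` the raw per-allele
    counts (kept so ratio-based baselines can re-smooth with their own
    pseudocount).
    """

    replicate_id: str
    times: np.ndarray
    sites: list[int]
    alleles: dict[int, list[str]]
    wildtype: dict[int, str]
    z: dict[int, np.ndarray]
    depth: dict[int, np.ndarray]
    counts: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least two timepoints")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for site in self.sites:
            zs = self.z[site]
            if zs.shape != (len(self.alleles[site]), self.times.size):
                raise ValueError(f"site {site}: frequency array shape mismatch")
            if np.any(zs < 0) or np.any(zs > 1):
                raise ValueError(f"site {site}: frequencies outside [0, 1]")
            if not np.allclose(zs.sum(axis=0), 1.0, atol=1e-12, rtol=0):
                raise ValueError(f"site {site}: frequencies do not sum to 1")

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def allele_index(self, site: int) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.alleles[site])}


def counts_to_frequencies(
    tables: Sequence[AminoAcidCountTable],
    pseudocount: float = 0.5,
) -> FrequencyTrajectory:
    """Build a frequency trajectory from one replicate's count tables.

    Frequencies are ``(count + a) / (depth + a * n_alleles)`` with
    pseudocount ``a >= 0`` applied uniformly per allele (Haldane–Anscombe
    half-count by default). All tables must belong to the same replicate
    and share site and allele sets.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if len(tables) < 2:
        raise ValueError("need at least two timepoints")
    reps = {t.sample.replicate_id for t in tables}
    if len(reps) != 1:
        raise ValueError(f"tables span multiple replicates: {sorted(reps)}")
    tables = sorted(tables, key=lambda t: t.sample.time)
    times = np.array([t.sample.time for t in tables], dtype=float)

    first = tables[0]
    sites = list(first.sites)
    for t in tables[1:]:
        missing = set(sites).symmetric_difference(t.sites)
        if missing:
            raise ValueError(
                f"site set differs across timepoints; mismatched sites {sorted(missing)}"
            )

    alleles: dict[int, list[str]] = {}
    z: dict[int, np.ndarray] = {}
    depth: dict[int, np.ndarray] = {}
    counts: dict[int, np.ndarray] = {}
    for site in sites:
        allele_list = list(first.counts[site])
        for t in tables[1:]:
            if set(t.counts[site]) != set(allele_list):
                raise ValueError(f"site {site}: allele set differs across timepoints")
        c = np.array(
            [[t.counts[site][a] for t in tables] for a in allele_list], dtype=float
        )
        d = c.sum(axis=0)
        denom = d + pseudocount * len(allele_list)
        if np.any(denom == 0):
            raise ValueError(f"site {site}: zero depth and zero pseudocount")
        alleles[site] = allele_list
        counts[site] = c
        depth[site] = d
        z[site] = (c + pseudocount) / denom
    return FrequencyTrajectory(
        replicate_id=first.sample.replicate_id, times=times, sites=sites,
        alleles=alleles, wildtype=dict(first.wildtype_aa), z=z, depth=depth,
        counts=counts,
    )


def error_correct(
    traj: FrequencyTrajectory, error_control: FrequencyTrajectory
) -> FrequencyTrajectory:
    """Subtract sequencing-error frequencies estimated from a WT-only sample.

    For every non-wild-type allele the corrected frequency is
    ``max(0, observed - control)``, where the control frequency is the
    mean over the control sample's timepoints; the wild-type frequency
    absorbs the remainder so columns still sum to one. Raises if the
    corrected non-WT mass exceeds one (a pathological control).
    """
    corrected_z: dict[int, np.ndarray] = {}
    for site in traj.sites:
        if site not in error_control.z:
            raise ValueError(f"site {site} absent from the error control")
        ctrl_alleles = error_control.allele_index(site)
        missing = [a for a in traj.alleles[site] if a not in ctrl_alleles]
        if missing:
            raise ValueError(f"site {site}: control lacks allele(s) {missing}")
        ctrl_mean = error_control.z[site].mean(axis=1)
        wt = traj.wildtype[site]
        idx = traj.allele_index(site)
        zs = traj.z[site].copy()
        for a in traj.alleles[site]:
            if a == wt:
                continue
            zs[idx[a]] = np.maximum(0.0, zs[idx[a]] - ctrl_mean[ctrl_alleles[a]])
        nonwt = np.array([i for a, i in idx.items() if a != wt], dtype=int)
        nonwt_sum = zs[nonwt].sum(axis=0) if nonwt.size else np.zeros(traj.n_times)
        if np.any(nonwt_sum > 1.0 + 1e-12):
            raise ValueError(
                f"site {site}: corrected non-WT frequencies exceed 1 "
                "(pathological error control)"
            )
        zs[idx[wt]] = 1.0 - np.minimum(nonwt_sum, 1.0)
        corrected_z[site] = zs
    return FrequencyTrajectory(
        replicate_id=traj.replicate_id, times=traj.times.copy(),
        sites=list(traj.sites), alleles={s: list(a) for s, a in traj.alleles.items()},
        wildtype=dict(traj.wildtype), z=corrected_z,
        depth={s: d.copy() for s, d in traj.depth.items()},
        counts=None if traj.counts is None
        else {s: c.copy() for s, c in traj.counts.items()},
    )
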