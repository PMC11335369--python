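"""Forward Wright-Fisher simulation of deep mutational scanning rounds.

The simulator generates a variant library (wild type, single mutants,
optionally double mutants), evolves it through multinomial selection
rounds with additive fitness, and samples sequencing reads with
negative-binomial noise. It provides the ground truth against which the
inference modules are validated, and can emit fixture files in either
supported input dialect.

Selection acts multiplicatively on counts through a linear fitness
``w(g) = 1 + sum_i s_i(g) + sum_{ij} s_ij(g)`` (an ``exponential``
option uses ``exp(sum s)`` instead); each round the next population is
a single multinomial draw of size N with probabilities proportional to
``n_g w_g``. No new variants arise during selection: library diversity
is fixed at round zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._codon import AA_ALPHABET, CANONICAL_CODON, CODONS
from .frequencies import AminoAcidCountTable
from .io import (
    SampleKey,
    Substitution,
    VariantCountTable,
    write_dms_tools_codon_counts,
    write_mavedb_counts,
)
from .io import CodonCountTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_wf",
    "replicator_update",
    "sample_reads",
    "write_fixture",
    "error_control_tables",
]

_CANONICAL_AAS = AA_ALPHABET[:-1]  # simulated libraries use the 20 residues


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a simulated DMS experiment.

    Defaults describe a moderate-size screen: 10 sites with 5 alleles
    each (wild type + 4 mutants), effect sizes drawn from
    ``Normal(0, 0.1^2)``, a population of 10^4 sequences carried through
    5 selection rounds, 10^5 reads per sample with negative-binomial
    dispersion 10, and 3 replicates.
    """

    n_sites: int = 10
    alleles_per_site: int = 5
    population_size: int = 10_000
    rounds: int = 5
    depth: int = 100_000
    dispersion: float = 10.0
    replicates: int = 3
    fraction_wt: float = 0.2
    fraction_double: float = 0.0
    s_std: float = 0.1
    true_s: Mapping[tuple[int, str], float] | None = None
    true_pair_s: Mapping[tuple, float] | None = None
    fitness_model: str = "linear"
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (use inf for Poisson)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.alleles_per_site < 2:
            raise ValueError("alleles_per_site must be >= 2 (WT + mutants)")
        fd = self.fraction_double
        if not (0 <= self.fraction_wt and 0 <= fd
                and self.fraction_wt + fd <= 1):
            raise ValueError("library fractions must be in [0, 1] and sum <= 1")
        if self.fitness_model not in ("linear", "exponential"):
            raise ValueError(f"unknown fitness_model {self.fitness_model!r}")


def _library_alleles(config: SimulationConfig) -> tuple[dict[int, str], dict[int, list[str]]]:
    """Deterministic wild-type and mutant amino acids per site."""
    wildtype: dict[int, str] = {}
    mutants: dict[int, list[str]] = {}
    n_mut = config.alleles_per_site - 1
    for site in range(1, config.n_sites + 1):
        w = (site - 1) % len(_CANONICAL_AAS)
        wildtype[site] = _CANONICAL_AAS[w]
        mutants[site] = [_CANONICAL_AAS[(w + 1 + j) % len(_CANONICAL_AAS)]
                         for j in range(n_mut)]
    return wildtype, mutants


@dataclass
class SyntheticDataset:
    """Ground truth plus simulated populations and sampled reads."""

    config: SimulationConfig
    variants: list[tuple[Substitution, ...]]
    wildtype: dict[int, str]
    true_s: pd.Series
    true_pair_s: pd.Series
    population_freqs: dict[str, np.ndarray]
    population_counts: dict[str, np.ndarray] | None = None
    read_counts: dict[str, np.ndarray] | None = None

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.population_freqs)

    @property
    def times(self) -> np.ndarray:
        k = next(iter(self.population_freqs.values())).shape[1]
        return np.arange(k, dtype=float)

    def sites(self) -> list[int]:
        return sorted(self.wildtype)

    def site_alleles(self) -> dict[int, list[str]]:
        """Library allele set per site (wild type first)."""
        alleles: dict[int, list[str]] = {s: [wt] for s, wt in self.wildtype.items()}
        for subs in self.variants:
            for sub in subs:
                if sub.mut_aa not in alleles[sub.site]:
                    alleles[sub.site].append(sub.mut_aa)
        return alleles

    def _require_reads(self) -> dict[str, np.ndarray]:
        if self.read_counts is None:
            raise ValueError("no sampled reads; call sample_reads first")
        return self.read_counts

    def to_variant_tables(self, replicate_id: str) -> list[VariantCountTable]:
        """Sampled reads of one replicate as per-timepoint variant tables."""
        reads = self._require_reads()[replicate_id]
        tables = []
        for k in range(reads.shape[1]):
            sample = SampleKey(replicate_id, f"t{k}", float(k))
            variants = [(subs, int(reads[i, k]))
                        for i, subs in enumerate(self.variants)]
            tables.append(VariantCountTable(variants=variants, sample=sample))
        return tables

    def to_aa_count_tables(self, replicate_id: str) -> list[AminoAcidCountTable]:
        """Per-site amino-acid marginal counts of one replicate's reads."""
        reads = self._require_reads()[replicate_id]
        sites = self.sites()
        alleles = self.site_alleles()
        tables = []
        for k in range(reads.shape[1]):
            sample = SampleKey(replicate_id, f"t{k}", float(k))
            counts = {s: {a: 0 for a in alleles[s]} for s in sites}
            for i, subs in enumerate(self.variants):
                n = int(reads[i, k])
                mutated = {sub.site: sub.mut_aa for sub in subs}
                for s in sites:
                    counts[s][mutated.get(s, self.wildtype[s])] += n
            tables.append(AminoAcidCountTable(
                sites=list(sites), wildtype_aa=dict(self.wildtype),
                counts=counts, sample=sample))
        return tables

    def truth_frame(self) -> pd.DataFrame:
        rows = [{"site": site, "wildtype_aa": self.wildtype[site],
                 "amino_acid": aa, "true_s": value}
                for (site, aa), value in self.true_s.items()]
        return pd.DataFrame(rows)


def replicator_update(freqs: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Deterministic (infinite-population) selection update.

    ``z' = z * w / sum(z * w)``; for two variants with fitnesses
    ``1 + s`` and ``1`` this is the classic ``z(1+s) / (1 + z s)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    w = np.asarray(fitness, dtype=float)
    mean_w = float(freqs @ w)
    if mean_w <= 0:
        raise ValueError("mean fitness must be positive")
    return freqs * w / mean_w


def _build_library(config: SimulationConfig, truth_rng: np.random.Generator):
    wildtype, mutants = _library_alleles(config)
    singles = [Substitution(site, wildtype[site], m)
               for site in sorted(wildtype) for m in mutants[site]]

    if config.true_s is not None:
        true_s = pd.Series({(s.site, s.mut_aa): float(config.true_s[(s.site, s.mut_aa)])
                            for s in singles})
    else:
        draws = truth_rng.normal(0.0, config.s_std, size=len(singles))
        true_s = pd.Series({(s.site, s.mut_aa): float(v)
                            for s, v in zip(singles, draws)})

    variants: list[tuple[Substitution, ...]] = [()]
    variants.extend((s,) for s in singles)
    doubles: list[tuple[Substitution, ...]] = []
    if config.fraction_double > 0:
        for i, a in enumerate(singles):
            for b in singles[i + 1:]:
                if a.site != b.site:
                    doubles.append(tuple(sorted((a, b))))
        variants.extend(doubles)

    pair_index = [(a, b) for (a, b) in doubles]
    if config.true_pair_s is not None:
        true_pair_s = pd.Series({p: float(config.true_pair_s.get(p, 0.0))
                                 for p in pair_index}, dtype=float)
    else:
        true_pair_s = pd.Series(0.0, index=pd.Index(pair_index, tupleize_cols=False),
                                dtype=float)

    f_single = 1.0 - config.fraction_wt - config.fraction_double
    p0 = np.empty(len(variants))
    p0[0] = config.fraction_wt
    p0[1:1 + len(singles)] = f_single / len(singles)
    if doubles:
        p0[1 + len(singles):] = config.fraction_double / len(doubles)
    return wildtype, variants, true_s, true_pair_s, p0


def _fitness_vector(
    variants: Sequence[tuple[Substitution, ...]],
    true_s: pd.Series,
    true_pair_s: pd.Series,
    model: str,
) -> np.ndarray:
    totals = np.zeros(len(variants))
    pair_lookup = dict(true_pair_s.items())
    for i, subs in enumerate(variants):
        total = sum(true_s[(s.site, s.mut_aa)] for s in subs)
        if len(subs) >= 2:
            ordered = sorted(subs)
            for a_idx in range(len(ordered)):
                for b_idx in range(a_idx + 1, len(ordered)):
                    total += pair_lookup.get((ordered[a_idx], ordered[b_idx]), 0.0)
        totals[i] = total
    if model == "exponential":
        return np.exp(totals)
    w = 1.0 + totals
    if np.any(w < 0):
        warnings.warn("selection too strong for linear fitness; flooring at 0")
        w = np.maximum(w, 0.0)
    return w


def simulate_wf(config: SimulationConfig) -> SyntheticDataset:
    """Run the forward simulation for every replicate.

    Deterministic given ``config.seed``: the truth draw and each
    replicate's trajectory use independent child streams of the seed, so
    the ground truth does not depend on the number of replicates.
    """
    root = np.random.SeedSequence(config.seed)
    truth_ss, *rep_ss = root.spawn(1 + config.replicates)
    truth_rng = np.random.default_rng(truth_ss)
    wildtype, variants, true_s, true_pair_s, p0 = _build_library(config, truth_rng)
    w = _fitness_vector(variants, true_s, true_pair_s, config.fitness_model)

    population_freqs: dict[str, np.ndarray] = {}
    population_counts: dict[str, np.ndarray] | None = (
        None if config.deterministic else {}
    )
    n_times = config.rounds + 1
    for r, ss in enumerate(rep_ss):
        rep_id = f"rep{r + 1}"
        if config.deterministic:
            z = np.empty((len(variants), n_times))
            z[:, 0] = p0
            for k in range(config.rounds):
                z[:, k + 1] = replicator_update(z[:, k], w)
            population_freqs[rep_id] = z
        else:
            rng = np.random.default_rng(ss)
            counts = np.empty((len(variants), n_times), dtype=np.int64)
            counts[:, 0] = rng.multinomial(config.population_size, p0)
            for k in range(config.rounds):
                weights = counts[:, k] * w
                total = weights.sum()
                if total <= 0:
                    raise RuntimeError("population fitness collapsed to zero")
                counts[:, k + 1] = rng.multinomial(
                    config.population_size, weights / total)
            population_counts[rep_id] = counts
            population_freqs[rep_id] = counts / config.population_size
    return SyntheticDataset(
        config=config, variants=variants, wildtype=wildtype,
        true_s=true_s, true_pair_s=true_pair_s,
        population_freqs=population_freqs, population_counts=population_counts,
    )


def sample_reads(
    dataset: SyntheticDataset,
    depth: int | None = None,
    dispersion: float | None = None,
    seed: int | None = None,
) -> SyntheticDataset:
    """Sample sequencing reads for every replicate and timepoint.

    Each variant's read count is drawn independently from a negative
    binomial with mean ``depth * z`` and variance
    ``mean + mean^2 / dispersion``; ``dispersion = inf`` gives the
    Poisson limit. Returns the dataset with ``read_counts`` populated.
    """
    config = dataset.config
    depth = config.depth if depth is None else depth
    r = config.dispersion if dispersion is None else dispersion
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    read_counts: dict[str, np.ndarray] = {}
    for rep_id, ss in zip(dataset.replicate_ids,
                          root.spawn(len(dataset.replicate_ids))):
        rng = np.random.default_rng(ss)
        z = dataset.population_freqs[rep_id]
        mean = depth * z
        if np.isinf(r):
            counts = rng.poisson(mean)
        else:
            counts = np.where(mean > 0,
                              rng.negative_binomial(r, r / (r + mean)), 0)
        read_counts[rep_id] = counts.astype(np.int64)
    dataset.read_counts = read_counts
    return dataset


def _codon_table_from_aa(table: AminoAcidCountTable) -> CodonCountTable:
    """Place amino-acid counts on canonical codons (first lexicographic)."""
    counts = {}
    wt_codon = {}
    for site in table.sites:
        row = {c: 0 for c in CODONS}
        for aa, n in table.counts[site].items():
            row[CANONICAL_CODON[aa]] += n
        counts[site] = row
        wt_codon[site] = CANONICAL_CODON[table.wildtype_aa[site]]
    return CodonCountTable(sites=list(table.sites), wildtype_codon=wt_codon,
                           counts=counts, sample=table.sample)


def write_fixture(
    dataset: SyntheticDataset,
    directory: str | Path,
    format: str = "dms_tools",
) -> dict:
    """Write the sampled dataset as parseable fixture files.

    dms_tools format emits one codon-count file per replicate and
    timepoint (amino-acid counts are assigned to the first lexicographic
    codon encoding each residue); MaveDB format emits one CSV with a
    count column per sample. A truth table and a YAML manifest mapping
    files/columns to replicates and times are always written.
    """
    if format not in ("dms_tools", "mavedb"):
        raise ValueError(f"unknown fixture format {format!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": format, "samples": []}
    paths: dict = {"samples": []}

    if format == "dms_tools":
        for rep_id in dataset.replicate_ids:
            for table in dataset.to_aa_count_tables(rep_id):
                name = f"counts_{rep_id}_{table.sample.timepoint_label}.csv"
                path = directory / name
                write_dms_tools_codon_counts(_codon_table_from_aa(table), path)
                paths["samples"].append(path)
                manifest["samples"].append({
                    "path": name, "replicate": table.sample.replicate_id,
                    "timepoint": table.sample.timepoint_label,
                    "time": table.sample.time,
                })
    else:
        tables = []
        columns = []
        for rep_id in dataset.replicate_ids:
            for table in dataset.to_variant_tables(rep_id):
                tables.append(table)
                col = f"{rep_id}_{table.sample.timepoint_label}"
                columns.append(col)
                manifest["samples"].append({
                    "path": "counts.csv", "column": col,
                    "replicate": table.sample.replicate_id,
                    "timepoint": table.sample.timepoint_label,
                    "time": table.sample.time,
                })
        path = directory / "counts.csv"
        write_mavedb_counts(tables, path, column_names=columns)
        paths["samples"].append(path)

    truth_path = directory / "truth.csv"
    dataset.truth_frame().to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    if len(dataset.true_pair_s):
        pair_rows = [{"site_i": a.site, "aa_i": a.mut_aa,
                      "site_j": b.site, "aa_j": b.mut_aa, "true_pair_s": v}
                     for (a, b), v in dataset.true_pair_s.items()]
        pair_path = directory / "truth_pairs.csv"
        pd.DataFrame(pair_rows).to_csv(pair_path, index=False)
        paths["truth_pairs"] = pair_path

    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = manifest_path
    return paths


def error_control_tables(
    dataset: SyntheticDataset,
    miscall_rate: float,
    depth: int | None = None,
    seed: int | None = None,
) -> tuple[list[AminoAcidCountTable], dict[str, list[AminoAcidCountTable]]]:
    """Simulate uniform per-read miscalls plus a WT-only control sample.

    Returns ``(control_tables, corrupted)`` where the control is a
    sequencing run of a pure wild-type sample through the same miscall
    process (two timepoints, so it forms a valid trajectory), and
    ``corrupted`` maps each replicate to its miscall-corrupted
    amino-acid count tables. Each read is miscalled with probability
    ``miscall_rate`` to a uniform different allele at that site.
    """
    if not (0 <= miscall_rate < 1):
        raise ValueError("miscall_rate must be in [0, 1)")
    config = dataset.config
    depth = config.depth if depth is None else depth
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))

    def corrupt(table: AminoAcidCountTable) -> AminoAcidCountTable:
        counts = {}
        for site in table.sites:
            alleles = list(table.counts[site])
            row = {a: 0 for a in alleles}
            for a in alleles:
                n = table.counts[site][a]
                miscalled = rng.binomial(n, miscall_rate)
                row[a] += n - miscalled
                if miscalled and len(alleles) > 1:
                    others = [x for x in alleles if x != a]
                    spread = rng.multinomial(miscalled,
                                             np.full(len(others), 1 / len(others)))
                    for other, m in zip(others, spread):
                        row[other] += m
            counts[site] = row
        return AminoAcidCountTable(sites=list(table.sites),
                                   wildtype_aa=dict(table.wildtype_aa),
                                   counts=counts, sample=table.sample)

    sites = dataset.sites()
    alleles = dataset.site_alleles()
    control = []
    for k in range(2):
        sample = SampleKey("control", f"t{k}", float(k))
        counts = {s: {a: depth if a == dataset.wildtype[s] else 0
                      for a in alleles[s]} for s in sites}
        control.append(corrupt(AminoAcidCountTable(
            sites=list(sites), wildtype_aa=dict(dataset.wildtype),
            counts=counts, sample=sample)))

    corrupted = {rep: [corrupt(t) for t in dataset.to_aa_count_tables(rep)]
                 for rep in dataset.replicate_ids}
    return control, corrupted
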