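"""Reading and writing count tables and result tables.

Two input dialects are supported:

* **dms_tools codon counts** — delimited text with one row per site, a
  ``wildtype`` codon column and one count column for each of the 64 DNA
  codons. Comma- and whitespace-separated files are both accepted;
  lines starting with ``#`` are comments. Output is always
  comma-separated.
* **MaveDB variant counts** — comma-separated text with an ``hgvs_pro``
  column keying variants by HGVS protein strings (``_wt``,
  ``p.Gly5Ala``, ``p.[Trp17Cys;Pro19Ser]``) plus named per-sample count
  columns.

Result tables (selection coefficients) are written as comma-separated
text with a deterministic row order: site ascending, then the fixed
amino-acid alphabet order ``ACDEFGHIKLMNPQRSTVWY*``.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from ._codon import AA_ALPHABET, CODONS, THREE_TO_ONE

__all__ = [
    "FormatError",
    "HgvsParseError",
    "ConfigError",
    "SampleKey",
    "Substitution",
    "CodonCountTable",
    "VariantCountTable",
    "read_dms_tools_codon_counts",
    "write_dms_tools_codon_counts",
    "read_mavedb_counts",
    "write_mavedb_counts",
    "parse_hgvs_pro",
    "format_hgvs_pro",
    "write_selection_coefficients",
    "read_selection_coefficients",
]


class FormatError(ValueError):
    """A file does not conform to the expected table format."""


class HgvsParseError(ValueError):
    """An HGVS protein string does not match the supported grammar."""


class ConfigError(ValueError):
    """A run configuration is inconsistent with the data it references."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identifies one sequencing sample: a replicate at a timepoint.

    ``time`` is the experimental time of the sample in generations or
    selection-round units; within a replicate, samples are ordered by it.
    """

    replicate_id: str
    timepoint_label: str
    time: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError(f"sample time must be finite, got {self.time!r}")


class Substitution(NamedTuple):
    """A single amino-acid substitution at one site (one-letter codes)."""

    site: int
    wt_aa: str
    mut_aa: str


@dataclass
class CodonCountTable:
    """Per-site codon counts for one sample (dms_tools layout)."""

    sites: list[int]
    wildtype_codon: dict[int, str]
    counts: dict[int, dict[str, int]]
    sample: SampleKey

    def __post_init__(self) -> None:
        for site in self.sites:
            row = self.counts[site]
            if set(row) != set(CODONS):
                raise FormatError(f"site {site}: counts must cover all 64 codons")
            if any(c < 0 for c in row.values()):
                raise ValueError(f"site {site}: negative codon count")
            wt = self.wildtype_codon[site]
            if wt not in row:
                raise FormatError(f"site {site}: wildtype codon {wt!r} not a DNA codon")

    def depth(self, site: int) -> int:
        """Total read count at ``site``."""
        return sum(self.counts[site].values())


@dataclass
class VariantCountTable:
    """Variant (haplotype) read counts for one sample.

    Each variant is a tuple of :class:`Substitution` records; the empty
    tuple is the wild-type sequence, which is always present explicitly.
    """

    variants: list[tuple[tuple[Substitution, ...], int]]
    sample: SampleKey

    def __post_init__(self) -> None:
        seen: set[tuple[Substitution, ...]] = set()
        for subs, count in self.variants:
            if count < 0:
                raise ValueError(f"variant {subs!r}: negative count")
            sites = [s.site for s in subs]
            if len(sites) != len(set(sites)):
                raise FormatError(f"variant {subs!r}: a site appears twice")
            if any(s.wt_aa == s.mut_aa for s in subs):
                raise FormatError(f"variant {subs!r}: synonymous substitution retained")
            if subs in seen:
                raise FormatError(f"variant {subs!r}: duplicate record")
            seen.add(subs)
        if () not in seen:
            self.variants.insert(0, ((), 0))

    def as_dict(self) -> dict[tuple[Substitution, ...], int]:
        return dict(self.variants)

    @property
    def total(self) -> int:
        return sum(c for _, c in self.variants)


# --- dms_tools codon counts -------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comment-tolerant table, sniffing comma vs whitespace separation."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no data lines")
    sep = "," if "," in lines[0] else r"\s+"
    header = re.split(r",|\s+", lines[0].strip())
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate columns {sorted(dupes)}")
    return pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep)


def read_dms_tools_codon_counts(path: str | Path, sample: SampleKey) -> CodonCountTable:
    """Read a dms_tools-format codon-count table.

    The header must contain ``site``, ``wildtype`` and all 64 codon
    columns; every cell must be a non-negative integer.
    """
    df = _read_delimited(path)
    for col in ("site", "wildtype"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    missing = [c for c in CODONS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing codon column(s) {missing}")

    sites: list[int] = []
    wildtype: dict[int, str] = {}
    counts: dict[int, dict[str, int]] = {}
    for idx, row in df.iterrows():
        site = int(row["site"])
        if site in counts:
            raise FormatError(f"{path}: duplicate site {site} at row {idx}")
        wt = str(row["wildtype"]).upper()
        if wt not in CODONS:
            raise FormatError(f"{path}: row {idx}: wildtype {wt!r} is not a DNA codon")
        site_counts: dict[str, int] = {}
        for codon in CODONS:
            value = row[codon]
            if pd.isna(value):
                raise ValueError(f"{path}: row {idx}: missing count for codon {codon}")
            fval = float(value)
            if fval < 0 or fval != int(fval):
                raise ValueError(
                    f"{path}: row {idx}: count for codon {codon} is not a "
                    f"non-negative integer ({value!r})"
                )
            site_counts[codon] = int(fval)
        sites.append(site)
        wildtype[site] = wt
        counts[site] = site_counts
    return CodonCountTable(sites=sites, wildtype_codon=wildtype, counts=counts,
                           sample=sample)


def write_dms_tools_codon_counts(table: CodonCountTable, path: str | Path) -> Path:
    """Write a codon-count table in canonical comma-separated form."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("site,wildtype," + ",".join(CODONS) + "\n")
        for site in table.sites:
            row = table.counts[site]
            fh.write(f"{site},{table.wildtype_codon[site]},"
                     + ",".join(str(row[c]) for c in CODONS) + "\n")
    return path


# --- HGVS protein strings ---------------------------------------------------

_AA3 = "|".join(THREE_TO_ONE)
_AA1 = "[" + re.escape(AA_ALPHABET) + "]"
_SUB_RE = re.compile(rf"^(?P<wt>{_AA3}|{_AA1})(?P<site>[1-9][0-9]*)(?P<mut>{_AA3}|{_AA1})$")


def _decode_aa(token: str) -> str:
    return THREE_TO_ONE.get(token, token)


def parse_hgvs_pro(s: str) -> list[Substitution]:
    """Parse an HGVS protein string into a list of substitutions.

    Supported grammar: ``_wt``, ``p.<sub>`` and ``p.[<sub>;<sub>;...]``
    with three-letter or one-letter amino-acid codes (``Ter`` and ``*``
    both denote the stop symbol). Returns one-letter codes.
    """
    if not isinstance(s, str):
        raise HgvsParseError(f"expected a string, got {type(s).__name__}")
    if s == "_wt":
        return []
    if not s.startswith("p."):
        raise HgvsParseError(f"unsupported HGVS string {s!r}")
    body = s[2:]
    if body.startswith("["):
        if not body.endswith("]"):
            raise HgvsParseError(f"unbalanced brackets in {s!r}")
        parts = body[1:-1].split(";")
        if any(not p for p in parts):
            raise HgvsParseError(f"empty substitution in {s!r}")
    else:
        parts = [body]
    subs: list[Substitution] = []
    for part in parts:
        m = _SUB_RE.match(part)
        if m is None:
            raise HgvsParseError(f"cannot parse substitution {part!r} in {s!r}")
        subs.append(Substitution(int(m["site"]), _decode_aa(m["wt"]),
                                 _decode_aa(m["mut"])))
    return subs


def format_hgvs_pro(subs: Sequence[Substitution]) -> str:
    """Format substitutions as an HGVS protein string (one-letter codes)."""
    if not subs:
        return "_wt"
    parts = [f"{s.wt_aa}{s.site}{s.mut_aa}" for s in subs]
    if len(parts) == 1:
        return "p." + parts[0]
    return "p.[" + ";".join(parts) + "]"


# --- MaveDB variant counts --------------------------------------------------

def read_mavedb_counts(
    path: str | Path,
    sample_columns: Mapping[str, SampleKey],
) -> list[VariantCountTable]:
    """Read a MaveDB-format variant count file.

    ``sample_columns`` maps count-column names to :class:`SampleKey`
    records (the file itself carries no replicate/timepoint metadata).
    Returns one :class:`VariantCountTable` per requested column, in
    mapping order. Synonymous substitutions are dropped from variant
    definitions; rows whose substitutions all drop out count as
    wild type.
    """
    df = pd.read_csv(path, comment="#")
    if "hgvs_pro" not in df.columns:
        raise FormatError(f"{path}: missing required column 'hgvs_pro'")
    absent = [c for c in sample_columns if c not in df.columns]
    if absent:
        raise ConfigError(f"{path}: count column(s) {absent} not present")

    parsed: list[tuple[Substitution, ...]] = []
    for idx, raw in enumerate(df["hgvs_pro"]):
        try:
            subs = parse_hgvs_pro(raw)
        except HgvsParseError as exc:
            raise HgvsParseError(f"{path}: row {idx}: {exc}") from exc
        subs = tuple(s for s in subs if s.wt_aa != s.mut_aa)
        sites = [s.site for s in subs]
        if len(sites) != len(set(sites)):
            raise FormatError(f"{path}: row {idx}: a site appears twice in {raw!r}")
        parsed.append(tuple(sorted(subs)))

    tables: list[VariantCountTable] = []
    for col, sample in sample_columns.items():
        agg: dict[tuple[Substitution, ...], int] = {(): 0}
        for subs, value in zip(parsed, df[col]):
            if pd.isna(value):
                raise ValueError(f"{path}: missing count in column {col!r}")
            fval = float(value)
            if fval < 0 or fval != int(fval):
                raise ValueError(
                    f"{path}: column {col!r}: count {value!r} is not a "
                    "non-negative integer"
                )
            agg[subs] = agg.get(subs, 0) + int(fval)
        tables.append(VariantCountTable(variants=sorted(agg.items()), sample=sample))
    return tables


def write_mavedb_counts(
    tables: Sequence[VariantCountTable],
    path: str | Path,
    column_names: Sequence[str] | None = None,
) -> Path:
    """Write variant count tables as one MaveDB-format CSV.

    All tables must describe the same experiment; the union of their
    variants becomes the row set (missing counts are written as 0).
    """
    if not tables:
        raise ValueError("no tables to write")
    if column_names is None:
        column_names = [f"{t.sample.replicate_id}_{t.sample.timepoint_label}"
                        for t in tables]
    all_variants = sorted({subs for t in tables for subs, _ in t.variants})
    dicts = [t.as_dict() for t in tables]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("hgvs_pro," + ",".join(column_names) + "\n")
        for subs in all_variants:
            counts = ",".join(str(d.get(subs, 0)) for d in dicts)
            fh.write(f"{format_hgvs_pro(subs)},{counts}\n")
    return path


# --- result tables ----------------------------------------------------------

_AA_ORDER = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def write_selection_coefficients(
    result,
    path: str | Path,
    float_format: str = "%.17g",
) -> Path:
    """Write a selection-coefficient table as CSV.

    Columns: ``site, wildtype_aa, amino_acid, selection_coefficient,
    scope``. Rows are ordered by site ascending then by the fixed
    amino-acid alphabet, so output is deterministic; the default float
    format round-trips IEEE doubles exactly.
    """
    items = list(result.params.items())
    if not items:
        raise ValueError("refusing to write an empty result")
    wildtype = getattr(result, "wildtype", {}) or {}
    scope = getattr(result, "scope", "joint")
    items.sort(key=lambda kv: (kv[0][0], _AA_ORDER.get(kv[0][1], 99)))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("site,wildtype_aa,amino_acid,selection_coefficient,scope\n")
        for (site, aa), value in items:
            wt = wildtype.get(site, "")
            fh.write(f"{site},{wt},{aa},{float_format % value},{scope}\n")
    return path


def read_selection_coefficients(path: str | Path) -> pd.Series:
    """Read a coefficient table back as a Series indexed by (site, aa)."""
    df = pd.read_csv(path, comment="#")
    for col in ("site", "amino_acid", "selection_coefficient"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    index = [(int(s), str(a)) for s, a in zip(df["site"], df["amino_acid"])]
    return pd.Series(df["selection_coefficient"].to_numpy(float), index=index)
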