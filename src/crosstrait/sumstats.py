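"""GWAS summary-statistics containers, readers, QC and cross-trait harmonization.

The in-memory currency of the whole pipeline is :class:`SumStats`, a thin
validated wrapper around a :class:`pandas.DataFrame` with one row per SNP.
Conventions:

* coordinates are 1-based, closed intervals;
* ``a1`` is the effect allele, ``a2`` the other allele;
* ``beta`` is the per-allele effect (trait units for quantitative traits,
  log-odds for binary traits), ``se`` its standard error;
* ``z`` is derived as ``beta / se`` when not supplied;
* missing p-values are recomputed from ``|z|`` under the two-sided normal.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("rsid", "chrom", "pos", "a1", "a2", "beta", "se", "pval", "n")
OPTIONAL_COLUMNS = ("z", "eaf")

#: default column-name mapping for the canonical delimited dialect
DEFAULT_COLUMN_MAP = {
    "SNP": "rsid",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "a1",
    "A2": "a2",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
    "Z": "z",
    "EAF": "eaf",
}

_RSID_RE = re.compile(r"^rs\d+$")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: MHC region used for exclusion before LDSC (chr6, standard convention)
MHC_REGION = (6, 25_000_000, 34_000_000)


class SumStatsError(ValueError):
    """Raised for invalid summary-statistics inputs."""


class ConfigError(ValueError):
    """Raised when the column map does not cover the mandatory fields."""


@dataclass
class SumStats:
    """Per-SNP association records for one trait.

    Parameters
    ----------
    data
        DataFrame with columns ``rsid, chrom, pos, a1, a2, beta, se, pval, n``
        and optionally ``z`` and ``eaf``.
    trait_label
        Human-readable trait name.
    trait_type
        ``"quantitative"`` or ``"binary"``.
    """

    data: pd.DataFrame
    trait_label: str = "trait"
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SumStatsError(f"unknown trait_type {self.trait_type!r}")
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "pval"]
        if missing:
            raise SumStatsError(f"missing mandatory columns: {missing}")
        if "z" not in df.columns:
            df["z"] = df["beta"] / df["se"]
        else:
            absent = df["z"].isna()
            if absent.any():
                df.loc[absent, "z"] = df.loc[absent, "beta"] / df.loc[absent, "se"]
        if "pval" not in df.columns:
            df["pval"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
        else:
            absent = df["pval"].isna()
            if absent.any():
                df.loc[absent, "pval"] = 2.0 * stats.norm.sf(np.abs(df.loc[absent, "z"]))
        self.data = df.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:  # tolerated (e.g. aggressive region exclusion)
            return
        if (df["se"] <= 0).any():
            raise SumStatsError("non-positive standard errors present")
        if (df["a1"] == df["a2"]).any():
            raise SumStatsError("a1 == a2 for some SNPs")
        z = df["beta"] / df["se"]
        if not np.allclose(z, df["z"], atol=1e-6):
            raise SumStatsError("z inconsistent with beta/se beyond 1e-6")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> pd.Series:
        return self.data["rsid"]

    def replace_data(self, df: pd.DataFrame) -> "SumStats":
        return SumStats(df.reset_index(drop=True), self.trait_label, self.trait_type)


@dataclass
class GeneAnnotation:
    """A gene's genomic interval and member SNPs (1-based closed interval)."""

    gene_id: str
    chrom: int
    start: int
    end: int
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SumStatsError(f"gene {self.gene_id}: start > end")


@dataclass
class QCReport:
    n_input: int = 0
    n_no_rsid: int = 0
    n_duplicated: int = 0
    n_output: int = 0


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _open_maybe_gzip(path, mode="rt"):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)


def read_sumstats(path, column_map: dict | None = None,
                  trait_type: str = "quantitative",
                  trait_label: str | None = None) -> SumStats:
    """Read whitespace/tab-delimited summary statistics into a :class:`SumStats`.

    ``column_map`` maps file column names to canonical field names; the
    default covers the ``SNP CHR BP A1 A2 BETA SE P N [Z EAF]`` dialect.
    Rows with unparseable numeric fields are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    with _open_maybe_gzip(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", dtype=str)
    if df.empty:
        raise SumStatsError(f"{path}: empty summary-statistics file")
    present = {src: dst for src, dst in cmap.items() if src in df.columns}
    mandatory = set(REQUIRED_COLUMNS) - {"pval"}
    if not mandatory <= set(present.values()):
        missing = mandatory - set(present.values())
        raise ConfigError(f"{path}: column map does not cover {sorted(missing)}")
    df = df[list(present)].rename(columns=present)

    numeric = [c for c in ("chrom", "pos", "beta", "se", "pval", "n", "z", "eaf")
               if c in df.columns]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[numeric].isna().any(axis=1)
    # a missing optional z/eaf cell is tolerated, not a parse failure
    for c in ("z", "eaf"):
        if c in df.columns:
            bad &= ~(df[numeric].drop(columns=[c]).notna().all(axis=1)
                     & df[c].isna())
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with unparseable numerics", path, n_bad)
        df = df[~bad]
    df = df[df["se"] > 0]
    if df.empty:
        raise SumStatsError(f"{path}: no valid rows after parsing")
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    for c in ("a1", "a2"):
        df[c] = df[c].str.upper()
    label = trait_label if trait_label is not None else str(path)
    return SumStats(df.reset_index(drop=True), label, trait_type)


def write_sumstats(s: SumStats, path) -> None:
    """Write in the canonical tab-delimited dialect (round-trips with
    :func:`read_sumstats`)."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = s.data.rename(columns=inv)
    cols = [c for c in DEFAULT_COLUMN_MAP if c in out.columns]
    with _open_maybe_gzip(path, "wt") as fh:
        out[cols].to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_gene_annotation(path, snp_map_path=None) -> list[GeneAnnotation]:
    """Read a BED-like ``chrom  start  end  gene_id`` table (1-based closed),
    optionally with an explicit two-column ``rsid  gene_id`` SNP map."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "gene_id"], dtype=str)
    snp_map: dict[str, list[str]] = {}
    if snp_map_path is not None:
        sm = pd.read_csv(snp_map_path, sep=r"\s+", header=None,
                         names=["rsid", "gene_id"], dtype=str)
        for gid, grp in sm.groupby("gene_id"):
            snp_map[gid] = list(grp["rsid"])
    genes = []
    for _, row in df.iterrows():
        genes.append(GeneAnnotation(
            gene_id=row["gene_id"], chrom=int(row["chrom"]),
            start=int(row["start"]), end=int(row["end"]),
            snp_ids=snp_map.get(row["gene_id"], []),
        ))
    return genes


# ----------------------------------------------------------------------
# QC and harmonization
# ----------------------------------------------------------------------

def qc_sumstats(s: SumStats) -> tuple[SumStats, QCReport]:
    """Quality control: drop SNPs without an ``rs`` label and remove every
    copy of a duplicated rsID (duplicates cannot be adjudicated, so all
    copies go).  Idempotent."""
    df = s.data
    report = QCReport(n_input=len(df))
    has_rs = df["rsid"].astype(str).str.match(_RSID_RE)
    report.n_no_rsid = int((~has_rs).sum())
    df = df[has_rs]
    dup = df["rsid"].duplicated(keep=False)
    report.n_duplicated = int(dup.sum())
    df = df[~dup]
    report.n_output = len(df)
    if len(df) == 0:
        raise SumStatsError("QC removed all SNPs")
    if report.n_no_rsid or report.n_duplicated:
        logger.info("QC %s: removed %d without rsID, %d duplicated",
                    s.trait_label, report.n_no_rsid, report.n_duplicated)
    return s.replace_data(df), report


def is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return pd.Series(
        [(x, y) in _PALINDROMIC for x, y in zip(a1, a2)], index=a1.index
    )


def harmonize_pair(exposure: SumStats, outcome: SumStats,
                   keep_palindromic: bool = False,
                   eaf_margin: float = 0.08) -> tuple[SumStats, SumStats]:
    """Align two traits' summary statistics to a common SNP set and the
    exposure's allele coding.

    Outcome records whose alleles are swapped relative to the exposure
    (direct or on the opposite strand) have ``beta`` and ``z`` sign-flipped
    and alleles rewritten.  Strand-ambiguous palindromic SNPs (A/T, C/G)
    are removed unless ``keep_palindromic`` and both traits carry an allele
    frequency clearly away from 0.5 (``|eaf - 0.5| > eaf_margin``), in which
    case frequency-based alignment is used.  SNPs with irreconcilable
    alleles are removed.  Both outputs have identical SNP order.
    """
    e = exposure.data.set_index("rsid")
    o = outcome.data.set_index("rsid")
    common = e.index.intersection(o.index)
    if len(common) == 0:
        raise SumStatsError("no SNPs shared between the two traits")
    e = e.loc[common]
    o = o.loc[common].copy()

    pal = is_palindromic(e["a1"], e["a2"])
    same = (o["a1"] == e["a1"]) & (o["a2"] == e["a2"])
    swapped = (o["a1"] == e["a2"]) & (o["a2"] == e["a1"])
    o_a1c = o["a1"].map(_COMPLEMENT)
    o_a2c = o["a2"].map(_COMPLEMENT)
    same_flip = (o_a1c == e["a1"]) & (o_a2c == e["a2"]) & ~pal
    swapped_flip = (o_a1c == e["a2"]) & (o_a2c == e["a1"]) & ~pal

    keep = same | swapped | same_flip | swapped_flip
    if keep_palindromic and "eaf" in e.columns and "eaf" in o.columns:
        informative = ((e["eaf"] - 0.5).abs() > eaf_margin) & \
                      ((o["eaf"] - 0.5).abs() > eaf_margin)
        pal_keep = pal & same & informative
        # frequency mismatch at a palindromic same-coded SNP implies the
        # outcome reports the other strand's allele: flip
        pal_flip = pal_keep & (
            np.sign(e["eaf"] - 0.5) != np.sign(o["eaf"] - 0.5))
        keep = keep & (~pal | pal_keep)
        flip_sign = swapped | swapped_flip | pal_flip
    else:
        keep = keep & ~pal
        flip_sign = swapped | swapped_flip

    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("harmonize: removed %d SNPs (palindromic/irreconcilable)",
                    n_removed)

    for col in ("beta", "z"):
        o.loc[flip_sign, col] = -o.loc[flip_sign, col]
    if "eaf" in o.columns:
        o.loc[flip_sign, "eaf"] = 1.0 - o.loc[flip_sign, "eaf"]
    o.loc[flip_sign | same_flip | swapped_flip, "a1"] = e["a1"]
    o.loc[flip_sign | same_flip | swapped_flip, "a2"] = e["a2"]

    e_out = e[keep].reset_index()
    o_out = o[keep].reset_index()
    if len(e_out) == 0:
        raise SumStatsError("harmonization removed all SNPs")
    return (exposure.replace_data(e_out), outcome.replace_data(o_out))


def exclude_region(s: SumStats, chrom: int, start: int, end: int) -> SumStats:
    """Remove SNPs with ``chrom`` matching and ``start <= pos <= end``
    (1-based closed).  Used for MHC exclusion before LDSC."""
    if start > end:
        raise SumStatsError("start > end")
    df = s.data
    inside = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
    out = df[~inside]
    if len(out) == 0:
        logger.warning("exclude_region removed every SNP")
    return s.replace_data(out)


def exclude_mhc(s: SumStats) -> SumStats:
    return exclude_region(s, *MHC_REGION)
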