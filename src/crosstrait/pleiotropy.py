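"""Composite-null pleiotropy test over paired gene p-values.

A gene is pleiotropic when it is associated with BOTH traits (H11).  The
composite null is the union of H00 (both null), H01 (trait 1 null only)
and H10 (trait 2 null only).  The test statistic is the intersection-union
max statistic ``t = max(p1, p2)``; its null distribution is a
three-component mixture, giving the p-value

    p = [ (pi01 + pi10) * t + pi00 * t^2 ] / (pi00 + pi01 + pi10)

which is exact under independent uniform null p-values within each
mixture component.  Mixture weights are estimated from the two marginal
Storey null proportions under a product (independence) decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import GeneAnnotation, SumStats

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


class PleiotropyError(ValueError):
    pass


@dataclass
class NullComposition:
    """Mixture proportions of the four hypothesis states."""

    pi00: float
    pi01: float
    pi10: float
    pi11: float

    def __post_init__(self) -> None:
        total = self.pi00 + self.pi01 + self.pi10 + self.pi11
        if abs(total - 1.0) > 1e-9:
            raise PleiotropyError("mixture proportions must sum to 1")
        for v in (self.pi00, self.pi01, self.pi10, self.pi11):
            if v < -1e-12:
                raise PleiotropyError("negative mixture proportion")


@dataclass
class PleiotropyResult:
    gene_id: str
    p1: float
    p2: float
    t: float
    p_pleio: float
    q: float
    effect_corr: float = np.nan
    n_local_snps: int = 0


def _storey_pi0(p: np.ndarray, grid: np.ndarray) -> float:
    """Storey null-proportion estimate smoothed over the lambda grid with
    a cubic polynomial and read off at lambda = 0.5 (the endpoint
    extrapolation is far noisier); falls back to the raw estimate at
    lambda = 0.5 if the smoother leaves (0, 1]."""
    G = len(p)
    raw = np.array([(p > lam).sum() / ((1 - lam) * G) for lam in grid])
    coef = np.polyfit(grid, raw, 3)
    pi0 = float(np.polyval(coef, 0.5))
    if not (0 < pi0 <= 1):
        pi0 = float(raw[np.argmin(np.abs(grid - 0.5))])
    return float(np.clip(pi0, 1.0 / G, 1.0))


def estimate_null_proportions(p1, p2,
                              lambda_grid: np.ndarray | None = None,
                              ) -> NullComposition:
    """Estimate the four-state mixture from the two marginal Storey null
    proportions under the product decomposition
    ``pi00 = pi0(1) pi0(2)``, ``pi01 = pi0(1) (1 - pi0(2))``,
    ``pi10 = (1 - pi0(1)) pi0(2)``, ``pi11`` the remainder."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise PleiotropyError("p-value vectors must have equal length")
    for p in (p1, p2):
        if ((p <= 0) | (p > 1)).any():
            raise PleiotropyError("p-values must lie in (0, 1]")
    if len(p1) < 100:
        logger.warning("null-proportion estimation on only %d genes", len(p1))
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    pi0_1 = _storey_pi0(p1, grid)
    pi0_2 = _storey_pi0(p2, grid)
    pi00 = pi0_1 * pi0_2
    pi01 = pi0_1 * (1 - pi0_2)
    pi10 = (1 - pi0_1) * pi0_2
    comp = np.clip([pi00, pi01, pi10], 0.0, 1.0)
    pi11 = max(0.0, 1.0 - comp.sum())
    total = comp.sum() + pi11
    return NullComposition(pi00=comp[0] / total, pi01=comp[1] / total,
                           pi10=comp[2] / total, pi11=pi11 / total)


def maiup_test(p1, p2, composition: NullComposition) -> np.ndarray:
    """Mixture-adjusted intersection-union p-values for ``t = max(p1, p2)``.

    Monotone in t; reduces to the independent-null closed form ``t^2``
    when ``pi00 = 1``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    c = composition
    null_mass = c.pi00 + c.pi01 + c.pi10
    if null_mass <= 0:
        raise PleiotropyError("null mixture mass is zero")
    t = np.maximum(p1, p2)
    return ((c.pi01 + c.pi10) * t + c.pi00 * t ** 2) / null_mass


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise PleiotropyError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_effect_correlation(s1: SumStats, s2: SumStats,
                            gene: GeneAnnotation,
                            min_snps: int = 3) -> tuple[float, int]:
    """Pearson correlation of the two traits' per-SNP effect sizes over the
    gene's local SNPs (harmonized inputs assumed).  Returns ``(nan, n)``
    when fewer than ``min_snps`` shared SNPs or a constant beta vector."""
    d1 = s1.data.set_index("rsid")
    d2 = s2.data.set_index("rsid")
    if gene.snp_ids:
        members = [r for r in gene.snp_ids if r in d1.index and r in d2.index]
    else:
        sel = (d1["chrom"] == gene.chrom) & (d1["pos"] >= gene.start) & \
              (d1["pos"] <= gene.end)
        members = [r for r in d1.index[sel] if r in d2.index]
    n = len(members)
    if n < min_snps:
        logger.info("gene %s: only %d shared SNPs, correlation undefined",
                    gene.gene_id, n)
        return np.nan, n
    b1 = d1.loc[members, "beta"].to_numpy(dtype=float)
    b2 = d2.loc[members, "beta"].to_numpy(dtype=float)
    if np.ptp(b1) == 0 or np.ptp(b2) == 0:
        logger.warning("gene %s: constant effect vector", gene.gene_id)
        return np.nan, n
    r, _ = stats.pearsonr(b1, b2)
    return float(r), n


def pleiotropy_scan(gene_pvals1: pd.DataFrame, gene_pvals2: pd.DataFrame,
                    fdr: float = 0.05,
                    composition: NullComposition | None = None,
                    ) -> tuple[pd.DataFrame, NullComposition]:
    """Full pleiotropy stage over two gene p-value tables (columns
    ``gene_id`` and ``pval``); returns per-gene results sorted by q and the
    estimated mixture.  Genes missing from either table are excluded."""
    m = pd.merge(gene_pvals1, gene_pvals2, on="gene_id",
                 suffixes=("_1", "_2"))
    if m.empty:
        raise PleiotropyError("no genes shared between the two traits")
    dropped = (len(gene_pvals1) - len(m), len(gene_pvals2) - len(m))
    if any(dropped):
        logger.info("pleiotropy universe: dropped %d / %d unmatched genes",
                    *dropped)
    p1 = m["pval_1"].to_numpy()
    p2 = m["pval_2"].to_numpy()
    if composition is None:
        composition = estimate_null_proportions(p1, p2)
    p_pleio = maiup_test(p1, p2, composition)
    q = bh_fdr(p_pleio)
    out = pd.DataFrame({
        "gene_id": m["gene_id"], "p1": p1, "p2": p2,
        "t": np.maximum(p1, p2), "p_pleio": p_pleio, "q": q,
        "significant": q < fdr,
    })
    return out.sort_values("q", kind="stable").reset_index(drop=True), composition


@dataclass
class SetComparison:
    shared_genes: list[str]
    corr_effect_corr: float
    frac_positive_1: float
    frac_positive_2: float


def compare_pleiotropic_sets(set1: list[PleiotropyResult],
                             set2: list[PleiotropyResult]) -> SetComparison:
    """Compare two pleiotropic gene sets (e.g. fetal- vs maternal-specific):
    intersection, correlation of local effect-size correlations on shared
    genes, and each set's fraction of positive effect correlations."""
    d1 = {r.gene_id: r for r in set1}
    d2 = {r.gene_id: r for r in set2}
    shared = sorted(set(d1) & set(d2))
    if len(shared) >= 3:
        v1 = np.array([d1[g].effect_corr for g in shared])
        v2 = np.array([d2[g].effect_corr for g in shared])
        valid = ~(np.isnan(v1) | np.isnan(v2))
        if valid.sum() >= 3:
            corr = float(stats.pearsonr(v1[valid], v2[valid])[0])
        else:
            corr = np.nan
    else:
        corr = np.nan

    def frac_pos(rs):
        vals = np.array([r.effect_corr for r in rs])
        vals = vals[~np.isnan(vals)]
        return float((vals > 0).mean()) if len(vals) else np.nan

    return SetComparison(shared_genes=shared, corr_effect_corr=corr,
                         frac_positive_1=frac_pos(set1),
                         frac_positive_2=frac_pos(set2))
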