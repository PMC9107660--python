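"""Cross-trait LD score regression.

Univariate model:   E[z_j^2]      = n * h2 * l_j / M + 1 + a
Bivariate model:    E[z1_j z2_j]  = sqrt(n1*n2) * rho_g * l_j / M + c

where ``l_j`` is SNP j's LD score, ``M`` the number of regression SNPs,
``h2`` the SNP heritability, ``rho_g`` the genetic covariance, and the
free intercepts absorb confounding and (for the bivariate fit) sample
overlap.  Genetic correlation is ``rg = rho_g / sqrt(h2_1 * h2_2)``.

Estimation is two-step weighted least squares: a first pass with weights
``1/l_j`` (over-counting correction), then a second pass whose weights
also divide by the fitted conditional variance of the response
(``2 (n h2 l/M + 1 + a)^2`` for z^2; the product-moment variance for
z1 z2).  High-LD SNPs carry both most of the leverage and most of the
noise, so the variance term is essential for a well-behaved slope.
Standard errors come from a delete-one-block jackknife over contiguous
SNP blocks; for rg the jackknife re-solves the full three-regression
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import LDReference

logger = logging.getLogger(__name__)

DEFAULT_N_BLOCKS = 200

#: floor on fitted response variances in the second-step weights
_VARIANCE_FLOOR = 0.5


class LdscError(ValueError):
    pass


def compute_ld_scores(ld: LDReference) -> pd.Series:
    """Per-SNP LD score ``l_j = sum_k r_jk^2`` over the SNP's block (self
    included, so ``l_j >= 1``)."""
    return ld.ld_scores()


def _effective_n_blocks(m: int, n_blocks: int | None) -> int:
    if n_blocks is not None:
        nb = n_blocks
    else:
        nb = min(DEFAULT_N_BLOCKS, max(2, m // 50))
    if m < 2 * nb:
        raise LdscError(f"{m} SNPs is fewer than 2 x {nb} jackknife blocks")
    return nb


def _block_suffstats(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                     nb: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sufficient statistics of the weighted regression of y on
    [1, x]: normal matrices A (nb, 2, 2) and moment vectors b (nb, 2)."""
    splits = np.array_split(np.arange(len(x)), nb)
    A = np.empty((nb, 2, 2))
    B = np.empty((nb, 2))
    for i, idx in enumerate(splits):
        wi, xi, yi = w[idx], x[idx], y[idx]
        sw, swx, swxx = wi.sum(), (wi * xi).sum(), (wi * xi * xi).sum()
        A[i] = [[sw, swx], [swx, swxx]]
        B[i] = [(wi * yi).sum(), (wi * xi * yi).sum()]
    return A, B


def _solve(A: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of the 2x2 weighted normal equations."""
    sol = np.linalg.solve(A, b)
    return float(sol[0]), float(sol[1])


@dataclass
class _Regression:
    """One weighted LDSC regression with cached block sufficient stats."""

    intercept: float
    slope: float
    A: np.ndarray
    B: np.ndarray

    @property
    def totals(self):
        return self.A.sum(axis=0), self.B.sum(axis=0)

    def delete_block(self, i: int) -> tuple[float, float]:
        At, Bt = self.totals
        return _solve(At - self.A[i], Bt - self.B[i])


def _wls(x, y, w, nb) -> _Regression:
    A, B = _block_suffstats(x, y, w, nb)
    intercept, slope = _solve(A.sum(axis=0), B.sum(axis=0))
    return _Regression(intercept=intercept, slope=slope, A=A, B=B)


def _two_step(x, y, ell, nb, variance) -> _Regression:
    """Second-pass fit with weights ``1 / (l * variance)``."""
    w = 1.0 / (np.maximum(ell, 1.0) * variance)
    return _wls(x, y, w, nb)


@dataclass
class H2Fit:
    h2: float
    se: float
    intercept: float
    n_snps: int
    n_blocks: int


@dataclass
class LdscFit:
    """Bivariate LDSC fit.  ``ok`` is False (with ``reason``) when rg is
    undefined, e.g. a non-positive heritability estimate."""

    h2_1: float
    h2_2: float
    gencov: float
    rg: float
    se_rg: float
    pval_rg: float
    intercept_1: float
    intercept_2: float
    intercept_biv: float
    n_snps_used: int
    n_blocks: int
    ok: bool = True
    reason: str = ""

    @property
    def rg_clipped(self) -> float:
        """rg clipped to [-1, 1] for reporting; the raw value is kept."""
        return float(np.clip(self.rg, -1.0, 1.0))


def _align(s1, s2, ld_scores: pd.Series) -> pd.DataFrame:
    d1 = s1.data.set_index("rsid")
    d2 = s2.data.set_index("rsid")
    shared = set(d1.index) & set(d2.index) & set(ld_scores.index)
    if not shared:
        raise LdscError("no SNPs shared between traits and LD scores")
    common = [r for r in d1.index if r in shared]  # keep s1 order
    return pd.DataFrame({
        "z1": d1.loc[common, "z"].to_numpy(),
        "z2": d2.loc[common, "z"].to_numpy(),
        "n1": d1.loc[common, "n"].to_numpy(dtype=float),
        "n2": d2.loc[common, "n"].to_numpy(dtype=float),
        "ell": ld_scores.loc[common].to_numpy(),
        "chrom": d1.loc[common, "chrom"].to_numpy(),
    }, index=common)


def _fit_univariate(z, n, ell, nb, M,
                    pass1: _Regression | None = None) -> _Regression:
    x = ell * n / M
    if pass1 is None:
        pass1 = _wls(x, z ** 2, 1.0 / np.maximum(ell, 1.0), nb)
    v = pass1.slope * x + pass1.intercept
    var = np.maximum(2.0 * v ** 2, _VARIANCE_FLOOR)
    return _two_step(x, z ** 2, ell, nb, var)


def ldsc_h2(s, ld_scores: pd.Series, n_blocks: int | None = None,
            M: int | None = None) -> H2Fit:
    """SNP heritability: two-step weighted regression of z^2 on
    ``l * n / M`` with a free intercept; jackknife SE over contiguous SNP
    blocks."""
    d = s.data.set_index("rsid")
    shared = set(ld_scores.index)
    common = [r for r in d.index if r in shared]
    if not common:
        raise LdscError("no SNPs shared with the LD scores")
    z = d.loc[common, "z"].to_numpy()
    n = d.loc[common, "n"].to_numpy(dtype=float)
    ell = ld_scores.loc[common].to_numpy()
    m = len(z)
    nb = _effective_n_blocks(m, n_blocks)
    M_eff = m if M is None else M
    reg = _fit_univariate(z, n, ell, nb, M_eff)
    dels = np.array([reg.delete_block(i)[1] for i in range(nb)])
    se = float(np.sqrt((nb - 1) / nb * ((dels - dels.mean()) ** 2).sum()))
    return H2Fit(h2=reg.slope, se=se, intercept=reg.intercept,
                 n_snps=m, n_blocks=nb)


def ldsc_rg(s1, s2, ld_scores: pd.Series, n_blocks: int | None = None,
            M: int | None = None) -> LdscFit:
    """Cross-trait LDSC: regress ``z1*z2`` on ``l * sqrt(n1*n2) / M`` with
    a free intercept (absorbing sample overlap); ``rg = gencov /
    sqrt(h2_1 * h2_2)``; jackknife SE of the full ratio via
    delete-one-block refits of all three regressions."""
    df = _align(s1, s2, ld_scores)
    m = len(df)
    nb = _effective_n_blocks(m, n_blocks)
    M_eff = m if M is None else M
    ell = df["ell"].to_numpy()
    n1 = df["n1"].to_numpy()
    n2 = df["n2"].to_numpy()
    z1 = df["z1"].to_numpy()
    z2 = df["z2"].to_numpy()
    x1 = ell * n1 / M_eff
    x2 = ell * n2 / M_eff
    xc = ell * np.sqrt(n1 * n2) / M_eff
    w0 = 1.0 / np.maximum(ell, 1.0)

    p1 = _wls(x1, z1 ** 2, w0, nb)
    p2 = _wls(x2, z2 ** 2, w0, nb)
    pc = _wls(xc, z1 * z2, w0, nb)
    r1 = _fit_univariate(z1, n1, ell, nb, M_eff, pass1=p1)
    r2 = _fit_univariate(z2, n2, ell, nb, M_eff, pass1=p2)
    v1 = p1.slope * x1 + p1.intercept
    v2 = p2.slope * x2 + p2.intercept
    vc = np.maximum(v1 * v2 + (pc.slope * xc + pc.intercept) ** 2,
                    _VARIANCE_FLOOR)
    rc = _two_step(xc, z1 * z2, ell, nb, vc)

    h2_1, h2_2, gencov = r1.slope, r2.slope, rc.slope
    if h2_1 <= 0 or h2_2 <= 0:
        return LdscFit(h2_1=h2_1, h2_2=h2_2, gencov=gencov,
                       rg=np.nan, se_rg=np.nan, pval_rg=np.nan,
                       intercept_1=r1.intercept, intercept_2=r2.intercept,
                       intercept_biv=rc.intercept, n_snps_used=m,
                       n_blocks=nb, ok=False,
                       reason="non-positive heritability estimate")

    rg = gencov / np.sqrt(h2_1 * h2_2)
    dels = np.empty(nb)
    for i in range(nb):
        h1_i = r1.delete_block(i)[1]
        h2_i = r2.delete_block(i)[1]
        gc_i = rc.delete_block(i)[1]
        denom = np.sqrt(h1_i * h2_i) if h1_i > 0 and h2_i > 0 else np.nan
        dels[i] = gc_i / denom
    if np.isnan(dels).any():
        logger.warning("ldsc_rg: %d jackknife blocks with non-positive h2",
                       int(np.isnan(dels).sum()))
        dels = dels[~np.isnan(dels)]
    k = len(dels)
    if k < 2:
        return LdscFit(h2_1=h2_1, h2_2=h2_2, gencov=gencov, rg=float(rg),
                       se_rg=np.nan, pval_rg=np.nan, intercept_1=r1.intercept,
                       intercept_2=r2.intercept, intercept_biv=rc.intercept,
                       n_snps_used=m, n_blocks=nb, ok=False,
                       reason="jackknife degenerate (non-positive h2 in "
                              "nearly all delete-one fits)")
    se = float(np.sqrt((k - 1) / k * ((dels - dels.mean()) ** 2).sum()))
    # jackknife t-statistic referred to t_{k-1}: with few blocks the
    # normal reference is measurably anti-conservative (t -> normal as
    # the block count grows)
    pval = float(2 * stats.t.sf(abs(rg) / se, k - 1)) if se > 0 else np.nan
    return LdscFit(h2_1=h2_1, h2_2=h2_2, gencov=gencov, rg=float(rg),
                   se_rg=se, pval_rg=pval, intercept_1=r1.intercept,
                   intercept_2=r2.intercept, intercept_biv=rc.intercept,
                   n_snps_used=m, n_blocks=nb)


def ldsc_rg_by_chromosome(s1, s2, ld_scores: pd.Series,
                          n_blocks: int | None = None,
                          min_snps: int = 100) -> pd.DataFrame:
    """Per-chromosome genetic correlation with 95% CIs (the chromosome-wise
    decomposition of the overall rg).  Chromosomes with fewer than
    ``min_snps`` shared SNPs are skipped with a warning."""
    df = _align(s1, s2, ld_scores)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        m = len(grp)
        if m < min_snps:
            logger.warning("chromosome %s skipped (%d SNPs < %d)",
                           chrom, m, min_snps)
            continue
        idx = grp.index
        sub1 = s1.replace_data(s1.data[s1.data["rsid"].isin(idx)])
        sub2 = s2.replace_data(s2.data[s2.data["rsid"].isin(idx)])
        nb = min(n_blocks or DEFAULT_N_BLOCKS, max(2, m // 50))
        try:
            fit = ldsc_rg(sub1, sub2, ld_scores, n_blocks=nb)
        except (np.linalg.LinAlgError, LdscError) as exc:
            logger.warning("chromosome %s skipped: %s", chrom, exc)
            continue
        rows.append({
            "chrom": chrom, "rg": fit.rg, "se": fit.se_rg,
            "ci_low": fit.rg - 1.96 * fit.se_rg,
            "ci_high": fit.rg + 1.96 * fit.se_rg,
            "pval": fit.pval_rg, "n_snps": m, "ok": fit.ok,
        })
    return pd.DataFrame(rows)
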