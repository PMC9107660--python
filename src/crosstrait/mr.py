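"""Two-sample Mendelian-randomization engine.

Instrument selection (LD clumping, fetal/maternal classification,
Bonferroni screening), the univariable estimator suite (IVW, MR-Egger,
weighted median, maximum likelihood, MR-PRESSO) the multivariable IVW, and
a binary-outcome power approximation.

All estimators consume an :class:`InstrumentSet` of per-SNP exposure and
outcome effect estimates with standard errors; the exposure may be a
matrix for multivariable fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldref import LDReference
from .sumstats import SumStats

logger = logging.getLogger(__name__)

CLASS_LABELS = ("fetal_specific", "maternal_specific", "both_same_direction",
                "both_opposite_direction", "unclassified")

#: instrument thresholds used for the birthweight exposure
BW_P_THRESHOLD = 6.60e-9
BW_R2_THRESHOLD = 0.10

#: default clumping thresholds for the other exposures
CLUMP_P = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 1_000_000


class MRError(ValueError):
    pass


@dataclass
class InstrumentSet:
    """Per-SNP instrument-level effect estimates.

    ``bx``/``sx`` have shape (J,) for univariable MR or (J, K) for K
    exposures; ``by``/``sy`` are (J,).
    """

    rsid: np.ndarray
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    exposure_labels: list[str] = field(default_factory=lambda: ["exposure"])
    outcome_label: str = "outcome"
    class_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rsid = np.asarray(self.rsid)
        self.bx = np.atleast_1d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_1d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        if len(self.rsid) == 0:
            raise MRError("empty instrument set")
        if (self.sy <= 0).any() or (self.sx <= 0).any():
            raise MRError("non-positive standard errors")

    @property
    def n_instruments(self) -> int:
        return len(self.rsid)

    @property
    def n_exposures(self) -> int:
        return 1 if self.bx.ndim == 1 else self.bx.shape[1]

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(
            rsid=self.rsid[mask], bx=self.bx[mask], sx=self.sx[mask],
            by=self.by[mask], sy=self.sy[mask],
            exposure_labels=list(self.exposure_labels),
            outcome_label=self.outcome_label,
            class_labels=None if self.class_labels is None
            else self.class_labels[mask])


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    n_instruments: int
    exposure: str = "exposure"
    outcome: str = "outcome"
    extras: dict = field(default_factory=dict)


def make_instrument_set(exposure: SumStats, outcome: SumStats,
                        rsids, exposure2: SumStats | None = None,
                        ) -> InstrumentSet:
    """Assemble an instrument set from (harmonized) per-trait summary
    statistics at the given rsIDs; rsIDs absent from any trait are dropped
    with a warning."""
    dx = exposure.data.set_index("rsid")
    dy = outcome.data.set_index("rsid")
    frames = [dx, dy]
    if exposure2 is not None:
        frames.append(exposure2.data.set_index("rsid"))
    keep = [r for r in rsids if all(r in f.index for f in frames)]
    if len(keep) < len(list(rsids)):
        logger.warning("instrument set: dropped %d rsIDs missing from "
                       "some trait", len(list(rsids)) - len(keep))
    if not keep:
        raise MRError("no instruments present in all traits")
    if exposure2 is None:
        bx = dx.loc[keep, "beta"].to_numpy()
        sx = dx.loc[keep, "se"].to_numpy()
        labels = [exposure.trait_label]
    else:
        d2 = frames[2]
        bx = np.column_stack([dx.loc[keep, "beta"], d2.loc[keep, "beta"]])
        sx = np.column_stack([dx.loc[keep, "se"], d2.loc[keep, "se"]])
        labels = [exposure.trait_label, exposure2.trait_label]
    return InstrumentSet(rsid=np.array(keep), bx=bx, sx=sx,
                         by=dy.loc[keep, "beta"].to_numpy(),
                         sy=dy.loc[keep, "se"].to_numpy(),
                         exposure_labels=labels,
                         outcome_label=outcome.trait_label)


def make_mv_instrument_set(exposures: list[SumStats], outcome: SumStats,
                           rsids) -> InstrumentSet:
    """Multi-exposure instrument set: exposure betas/SEs stacked as
    columns in the order given."""
    frames = [e.data.set_index("rsid") for e in exposures]
    dy = outcome.data.set_index("rsid")
    keep = [r for r in rsids
            if r in dy.index and all(r in f.index for f in frames)]
    if not keep:
        raise MRError("no instruments present in all traits")
    bx = np.column_stack([f.loc[keep, "beta"] for f in frames])
    sx = np.column_stack([f.loc[keep, "se"] for f in frames])
    return InstrumentSet(rsid=np.array(keep), bx=bx, sx=sx,
                         by=dy.loc[keep, "beta"].to_numpy(),
                         sy=dy.loc[keep, "se"].to_numpy(),
                         exposure_labels=[e.trait_label for e in exposures],
                         outcome_label=outcome.trait_label)


# ----------------------------------------------------------------------
# instrument selection
# ----------------------------------------------------------------------

def clump_instruments(s: SumStats, ld: LDReference,
                      p_thresh: float = CLUMP_P,
                      r2_thresh: float = CLUMP_R2,
                      window_bp: int = CLUMP_WINDOW_BP) -> list[str]:
    """Greedy LD clumping: candidates below ``p_thresh`` sorted by
    ascending p; a SNP is accepted iff its r-squared with every
    already-accepted SNP on the same chromosome within ``window_bp`` is
    below ``r2_thresh``.  SNPs absent from the LD reference are treated as
    independent (logged)."""
    d = s.data[s.data["pval"] <= p_thresh]
    if d.empty:
        return []
    d = d.sort_values(["pval", "rsid"], kind="stable")
    n_uncovered = int((~d["rsid"].isin([r for r in d["rsid"] if r in ld])).sum())
    if n_uncovered:
        logger.info("clumping: %d candidate SNPs not in LD reference "
                    "(treated as independent)", n_uncovered)
    accepted: list[tuple[str, int, int]] = []
    for rsid, chrom, pos in zip(d["rsid"], d["chrom"], d["pos"]):
        ok = True
        for a_rsid, a_chrom, a_pos in accepted:
            if chrom == a_chrom and abs(pos - a_pos) <= window_bp:
                if ld.r2(rsid, a_rsid) >= r2_thresh:
                    ok = False
                    break
        if ok:
            accepted.append((rsid, chrom, pos))
    return [a[0] for a in accepted]


def classify_bw_instruments(fetal: SumStats, maternal: SumStats,
                            rsids, sig_thresh: float = 5e-8) -> pd.Series:
    """Classify birthweight instruments by which genetic component drives
    them: ``fetal_specific`` (fetal effect significant, maternal not),
    ``maternal_specific`` (the converse), ``both_same_direction`` /
    ``both_opposite_direction`` (both significant, by beta sign agreement),
    else ``unclassified``.

    The fetal instrument set is fetal_specific plus both_*; the maternal
    set is maternal_specific plus both_*; unclassified SNPs enter neither.
    """
    df = fetal.data.set_index("rsid")
    dm = maternal.data.set_index("rsid")
    labels = {}
    for r in rsids:
        if r not in df.index or r not in dm.index:
            logger.warning("classify: %s missing from an input, "
                           "unclassified", r)
            labels[r] = "unclassified"
            continue
        sig_f = df.loc[r, "pval"] < sig_thresh
        sig_m = dm.loc[r, "pval"] < sig_thresh
        if sig_f and not sig_m:
            labels[r] = "fetal_specific"
        elif sig_m and not sig_f:
            labels[r] = "maternal_specific"
        elif sig_f and sig_m:
            same = np.sign(df.loc[r, "beta"]) == np.sign(dm.loc[r, "beta"])
            labels[r] = "both_same_direction" if same \
                else "both_opposite_direction"
        else:
            labels[r] = "unclassified"
    return pd.Series(labels, name="class_label")


def instrument_sets_from_labels(labels: pd.Series) -> dict[str, list[str]]:
    """Fetal / maternal instrument rsID sets implied by the class labels."""
    fetal = labels[labels.isin(["fetal_specific", "both_same_direction",
                                "both_opposite_direction"])].index
    maternal = labels[labels.isin(["maternal_specific", "both_same_direction",
                                   "both_opposite_direction"])].index
    return {"fetal": list(fetal), "maternal": list(maternal)}


def bonferroni_filter(inst: InstrumentSet, screening_pvals,
                      m: int | None = None,
                      alpha: float = 0.05) -> tuple[InstrumentSet, list[str]]:
    """Remove instruments whose screening p-value (association with the
    outcome or a competing trait) is below ``alpha / m`` (``m`` defaults to
    the candidate count) — a conservative horizontal-pleiotropy screen."""
    p = np.asarray(screening_pvals, dtype=float)
    if len(p) != inst.n_instruments:
        raise MRError("screening p-values must match instrument count")
    m_eff = len(p) if m is None else m
    remove = p < alpha / m_eff
    removed = list(inst.rsid[remove])
    if removed:
        logger.info("Bonferroni screen removed %d instruments", len(removed))
    if remove.all():
        raise MRError("Bonferroni screen removed every instrument")
    return inst.subset(~remove), removed


# ----------------------------------------------------------------------
# univariable estimators
# ----------------------------------------------------------------------

def _require_univariable(inst: InstrumentSet) -> None:
    if inst.n_exposures != 1:
        raise MRError("univariable estimator given a multi-exposure set")


def ivw(inst: InstrumentSet, model: str = "multiplicative_random",
        ) -> MREstimate:
    """Inverse-variance weighted estimate: weighted regression of outcome
    betas on exposure betas through the origin with weights ``1/se_y^2``.
    Under the multiplicative random-effects model the SE is inflated by
    ``sqrt(Q / (J - 1))`` when Cochran's Q exceeds its df."""
    _require_univariable(inst)
    if model not in ("fixed", "multiplicative_random"):
        raise MRError(f"unknown IVW model {model!r}")
    bx, by, sy = inst.bx, inst.by, inst.sy
    if np.all(bx == 0):
        raise MRError("all exposure betas are zero (irrelevant instruments)")
    w = 1.0 / sy ** 2
    sxx = np.sum(w * bx ** 2)
    beta = np.sum(w * bx * by) / sxx
    se = np.sqrt(1.0 / sxx)
    J = inst.n_instruments
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if model == "multiplicative_random" and J >= 2:
        se *= np.sqrt(max(1.0, q / (J - 1)))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(method="IVW", beta=float(beta), se=float(se),
                      pval=pval, n_instruments=J,
                      exposure=inst.exposure_labels[0],
                      outcome=inst.outcome_label,
                      extras={"cochran_q": q, "q_df": J - 1, "model": model})


def mr_egger(inst: InstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression ``by = a + b * bx`` with weights
    ``1/se_y^2`` after re-orienting each SNP so exposure betas are
    non-negative.  The intercept tests directional pleiotropy; inference
    uses a t-distribution with J - 2 df and the residual variance floored
    at 1 (multiplicative overdispersion)."""
    _require_univariable(inst)
    J = inst.n_instruments
    if J < 3:
        raise MRError("MR-Egger needs at least 3 instruments")
    flip = np.sign(inst.bx)
    flip[flip == 0] = 1.0
    bx = inst.bx * flip
    by = inst.by * flip
    w = 1.0 / inst.sy ** 2
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    scale = max(1.0, float(np.sum(w * resid ** 2) / (J - 2)))
    cov = np.linalg.inv(A) * scale
    alpha, beta = coef
    se_alpha, se_beta = np.sqrt(np.diag(cov))
    p_beta = float(2 * stats.t.sf(abs(beta) / se_beta, J - 2))
    p_alpha = float(2 * stats.t.sf(abs(alpha) / se_alpha, J - 2))
    return MREstimate(method="Egger", beta=float(beta), se=float(se_beta),
                      pval=p_beta, n_instruments=J,
                      exposure=inst.exposure_labels[0],
                      outcome=inst.outcome_label,
                      extras={"intercept": float(alpha),
                              "intercept_se": float(se_alpha),
                              "intercept_pval": p_alpha})


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, r))


def weighted_median(inst: InstrumentSet, n_boot: int = 1000,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> MREstimate:
    """Weighted-median estimator: the weighted empirical median of per-SNP
    Wald ratios (weights = first-order inverse ratio variances), consistent
    when valid instruments carry more than half the weight.  SE by seeded
    parametric bootstrap."""
    _require_univariable(inst)
    if inst.n_instruments < 3:
        raise MRError("weighted median needs at least 3 instruments")
    keep = inst.bx != 0
    if not keep.all():
        logger.warning("weighted median: dropped %d instruments with "
                       "zero exposure beta", int((~keep).sum()))
        inst = inst.subset(keep)
    bx, sx, by, sy = inst.bx, inst.sx, inst.by, inst.sy
    ratios = by / bx
    weights = bx ** 2 / sy ** 2  # 1 / Var(ratio), first-order
    est = _weighted_median(ratios, weights)

    if rng is None:
        rng = np.random.default_rng(seed)
    J = len(bx)
    bxb = rng.normal(bx, sx, size=(n_boot, J))
    byb = rng.normal(by, sy, size=(n_boot, J))
    bxb[bxb == 0] = np.finfo(float).tiny
    rb = byb / bxb
    wb = bxb ** 2 / sy ** 2
    order = np.argsort(rb, axis=1)
    rb = np.take_along_axis(rb, order, axis=1)
    wb = np.take_along_axis(wb, order, axis=1)
    wb = wb / wb.sum(axis=1, keepdims=True)
    sb = np.cumsum(wb, axis=1) - wb / 2
    boots = np.array([np.interp(0.5, sb[i], rb[i]) for i in range(n_boot)])
    se = float(boots.std(ddof=1))
    pval = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else np.nan
    return MREstimate(method="weighted_median", beta=est, se=se, pval=pval,
                      n_instruments=J, exposure=inst.exposure_labels[0],
                      outcome=inst.outcome_label,
                      extras={"n_boot": n_boot})


def max_likelihood(inst: InstrumentSet) -> MREstimate:
    """Maximum-likelihood estimator: joint normal likelihood of
    ``(bx_j, by_j)`` around ``(xi_j, beta * xi_j)``, profiled over the
    per-SNP nuisance effects ``xi_j``; SE from the observed information of
    the profile likelihood.  Starts at the IVW estimate."""
    _require_univariable(inst)
    if inst.n_instruments < 1:
        raise MRError("no instruments")
    bx, sx, by, sy = inst.bx, inst.sx, inst.by, inst.sy
    wx, wy = 1.0 / sx ** 2, 1.0 / sy ** 2

    def nll(beta: float) -> float:
        xi = (bx * wx + beta * by * wy) / (wx + beta ** 2 * wy)
        return 0.5 * float(np.sum((bx - xi) ** 2 * wx
                                  + (by - beta * xi) ** 2 * wy))

    start = ivw(inst).beta if inst.n_instruments > 1 and np.any(bx != 0) \
        else float(by[0] / bx[0])
    res = optimize.minimize(lambda b: nll(b[0]), x0=[start], method="BFGS")
    if not res.success and abs(res.jac[0]) > 1e-4:
        raise MRError(f"ML estimator did not converge: {res.message}")
    beta = float(res.x[0])
    h = 1e-5 * max(1.0, abs(beta))
    info = (nll(beta + h) - 2 * nll(beta) + nll(beta - h)) / h ** 2
    if info <= 0:
        raise MRError("non-positive observed information")
    se = float(1.0 / np.sqrt(info))
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(method="max_likelihood", beta=beta, se=se, pval=pval,
                      n_instruments=inst.n_instruments,
                      exposure=inst.exposure_labels[0],
                      outcome=inst.outcome_label)


# ----------------------------------------------------------------------
# MR-PRESSO
# ----------------------------------------------------------------------

@dataclass
class PressoResult:
    global_p: float
    global_rss: float
    outlier_pvals: pd.Series | None
    outlier_rsids: list[str]
    corrected: MREstimate
    uncorrected: MREstimate


def _loo_slopes(bx, by, w):
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx ** 2)
    return (s_xy - w * bx * by) / (s_xx - w * bx ** 2)


def mr_presso(inst: InstrumentSet, n_sim: int = 1000,
              seed: int | None = None,
              rng: np.random.Generator | None = None,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO residual-sum-of-squares test for horizontal pleiotropy.

    The observed RSS uses leave-one-out IVW slopes; its null distribution
    comes from parametric simulation of the no-pleiotropy model.  Per-SNP
    outlier p-values (Bonferroni-adjusted) come from each SNP's simulated
    residual distribution; the corrected estimate is IVW after removing
    flagged outliers (identical to the uncorrected IVW when nothing is
    flagged).  With fewer than 4 instruments only the global test runs.
    """
    _require_univariable(inst)
    J = inst.n_instruments
    if J < 3:
        raise MRError("MR-PRESSO needs at least 3 instruments")
    if rng is None:
        rng = np.random.default_rng(seed)
    bx, sx, by, sy = inst.bx, inst.sx, inst.by, inst.sy
    w = 1.0 / sy ** 2

    slopes = _loo_slopes(bx, by, w)
    resid2 = w * (by - slopes * bx) ** 2
    rss_obs = float(resid2.sum())

    bxs = rng.normal(bx, sx, size=(n_sim, J))
    bys = rng.normal(slopes * bx, sy, size=(n_sim, J))
    ws = np.broadcast_to(w, (n_sim, J))
    s_xy = np.sum(ws * bxs * bys, axis=1, keepdims=True)
    s_xx = np.sum(ws * bxs ** 2, axis=1, keepdims=True)
    loo = (s_xy - ws * bxs * bys) / (s_xx - ws * bxs ** 2)
    sim_resid2 = ws * (bys - loo * bxs) ** 2
    rss_sim = sim_resid2.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    uncorrected = ivw(inst)
    if J < 4:
        logger.warning("MR-PRESSO: <4 instruments, outlier test skipped")
        return PressoResult(global_p=global_p, global_rss=rss_obs,
                            outlier_pvals=None, outlier_rsids=[],
                            corrected=uncorrected, uncorrected=uncorrected)

    p_snp = (1 + np.sum(sim_resid2 >= resid2, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_snp * J, 1.0)
    outliers = p_adj < outlier_alpha
    outlier_rsids = list(inst.rsid[outliers])
    corrected = ivw(inst.subset(~outliers)) if outliers.any() else uncorrected
    return PressoResult(global_p=global_p, global_rss=rss_obs,
                        outlier_pvals=pd.Series(p_adj, index=inst.rsid),
                        outlier_rsids=outlier_rsids,
                        corrected=corrected, uncorrected=uncorrected)


# ----------------------------------------------------------------------
# multivariable IVW
# ----------------------------------------------------------------------

def mvmr_ivw(inst: InstrumentSet) -> list[MREstimate]:
    """Multivariable IVW: weighted multiple regression of outcome betas on
    all exposure beta columns, no intercept, weights ``1/se_y^2``; returns
    per-exposure conditional effects.  Reduces exactly to IVW with a
    single exposure."""
    X = inst.bx if inst.bx.ndim == 2 else inst.bx[:, None]
    J, K = X.shape
    if J < K + 1:
        raise MRError("need more instruments than exposures")
    w = 1.0 / inst.sy ** 2
    XtW = X.T * w
    A = XtW @ X
    if np.linalg.matrix_rank(X) < K:
        # name the collinear exposures for the error message
        bad = [inst.exposure_labels[k] if k < len(inst.exposure_labels)
               else f"exposure{k}" for k in range(K)
               if np.all(X[:, k] == 0)]
        raise MRError("exposure beta matrix is rank deficient"
                      + (f" (degenerate: {bad})" if bad else ""))
    coef = np.linalg.solve(A, XtW @ inst.by)
    resid = inst.by - X @ coef
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, q / (J - K)) if J > K else 1.0
    cov = np.linalg.inv(A) * scale
    ses = np.sqrt(np.diag(cov))
    out = []
    for k in range(K):
        label = inst.exposure_labels[k] if k < len(inst.exposure_labels) \
            else f"exposure{k}"
        pval = float(2 * stats.norm.sf(abs(coef[k]) / ses[k]))
        out.append(MREstimate(
            method="MVMR_IVW", beta=float(coef[k]), se=float(ses[k]),
            pval=pval, n_instruments=J, exposure=label,
            outcome=inst.outcome_label,
            extras={"adjusted_for": [l for i, l in
                                     enumerate(inst.exposure_labels)
                                     if i != k],
                    "cochran_q": q, "q_df": J - K}))
    return out


# ----------------------------------------------------------------------
# power
# ----------------------------------------------------------------------

def mr_power_binary(n: float, case_fraction: float, r2_instruments: float,
                    odds_ratio: float, alpha: float = 0.05) -> float:
    """Approximate power of a two-sample MR Wald test with a binary
    outcome: ``Phi( sqrt(n * r2 * K * (1-K)) * |log OR| - z_{1-alpha/2} )``
    with K the case fraction and r2 the variance of the exposure explained
    by the instruments."""
    if not (0 < case_fraction < 1):
        raise MRError("case_fraction must be in (0, 1)")
    if not (0 < r2_instruments < 1):
        raise MRError("r2_instruments must be in (0, 1)")
    if n <= 0 or odds_ratio <= 0 or not (0 < alpha < 1):
        raise MRError("invalid power parameters")
    ncp = np.sqrt(n * r2_instruments * case_fraction * (1 - case_fraction)) \
        * abs(np.log(odds_ratio))
    return float(stats.norm.cdf(ncp - stats.norm.isf(alpha / 2)))
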