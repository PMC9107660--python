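"""Synthetic GWAS data with the statistical structure each analysis stage
assumes.

Everything downstream of this module consumes only summary statistics, so
the generators work directly on that scale:

* genome-wide paired traits follow the LD-score-regression moment model
  ``E[z1_j z2_j] = sqrt(n1*n2) * rho_g * l_j / M + rho * n_overlap / sqrt(n1*n2)``
  with within-block noise correlated according to the block LD matrix;
* fetal- and maternal-specific birthweight effects are drawn jointly with a
  configurable (typically negative) correlation, emitted as if already
  decomposed into the two components;
* pleiotropic genes are planted with controlled local effect-size
  correlation and per-gene truth labels (H00/H01/H10/H11);
* the mediation chain X -> M1 -> M2 -> Y is simulated at the instrument
  level on the standardized summary-statistic scale, with optional
  horizontal pleiotropy and outlier instruments.

Every generator is a pure function of its config and an explicit
``numpy.random.Generator``; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import LDBlock, LDReference, ar1_correlation
from .sumstats import GeneAnnotation, SumStats


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generative parameters for the genome-wide paired-trait simulation.

    Defaults give two polygenic quantitative traits with h2 = 0.3 each,
    genetic correlation 0.5, 50 LD blocks of 100 SNPs (AR(1) rho = 0.5) and
    50,000 samples per GWAS with no overlap.
    """

    m_snps: int = 5000
    n_blocks: int = 50
    #: AR(1) LD parameter; a scalar applies to every block, a (low, high)
    #: pair gives an equally spaced per-block grid emulating regional LD
    #: variability (which also spreads the LD scores, keeping the LDSC
    #: regression well identified)
    block_rho: float | tuple[float, float] = (0.0, 0.95)
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg_true: float = 0.5
    n1: int = 50_000
    n2: int = 50_000
    n_overlap: int = 0
    rho_pheno: float = 0.0
    #: correlation between fetal- and maternal-specific true effects;
    #: negative by default (the two components pull in opposite directions)
    fm_corr: float = -0.6
    fm_effect_sd: float = 0.02
    n_fetal: int = 264_498
    n_maternal: int = 179_360
    #: per-SNP effect scale and planted local effect correlation magnitude
    #: for pleiotropic genes
    gene_effect_sd: float = 0.05
    gene_effect_corr: float = 0.8
    frac_t1_only: float = 0.07
    frac_t2_only: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        rhos = np.atleast_1d(np.asarray(self.block_rho, dtype=float))
        if ((rhos < 0) | (rhos >= 1)).any():
            raise SimulationError("block_rho must be in [0, 1)")
        for h in (self.h2_1, self.h2_2):
            if not (0 <= h <= 1):
                raise SimulationError("heritabilities must be in [0, 1]")
        if not (-1 <= self.rg_true <= 1):
            raise SimulationError("rg_true must be in [-1, 1]")
        if not (-1 <= self.fm_corr <= 1):
            raise SimulationError("fm_corr must be in [-1, 1]")
        if self.n_overlap > min(self.n1, self.n2):
            raise SimulationError("n_overlap exceeds the smaller sample")
        if not (-1 <= self.rho_pheno <= 1):
            raise SimulationError("rho_pheno must be in [-1, 1]")


@dataclass
class ChainConfig:
    """Instrument-level causal-chain generative model
    X (birthweight) -> M1 (age at menarche) -> M2 (age at menopause)
    -> Y (breast cancer, log-odds scale).

    Path coefficients default to the magnitudes of the fitted chain
    (0.09, 0.11, 0.10) with no direct X -> Y effect; GWAS sample sizes
    default to the source studies' (264,498 / 329,345 / 69,360 / 266,081).
    """

    theta_xm1: float = 0.09
    theta_m1m2: float = 0.11
    theta_m2y: float = 0.10
    theta_xy: float = 0.0
    theta_xm2: float = 0.0
    n_inst_x: int = 100
    n_inst_m1: int = 100
    n_inst_m2: int = 100
    inst_sd_x: float = 0.02
    inst_sd_m1: float = 0.02
    inst_sd_m2: float = 0.03
    n_x: int = 264_498
    n_m1: int = 329_345
    n_m2: int = 69_360
    n_y: int = 266_081
    #: horizontal pleiotropy of X instruments acting directly on M1
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    #: planted outlier instruments with inflated effects on Y
    outlier_frac: float = 0.0
    outlier_scale: float = 10.0

    def __post_init__(self) -> None:
        if min(self.n_inst_x, self.n_inst_m1, self.n_inst_m2) < 3:
            raise SimulationError("need at least 3 instruments per exposure")


# ----------------------------------------------------------------------
# LD reference
# ----------------------------------------------------------------------

def simulate_ld_reference(m_snps: int, n_blocks: int,
                          block_rho: float | tuple[float, float],
                          seed: int | None = None) -> LDReference:
    """AR(1) within-block LD, zero across blocks; 22 pseudo-chromosomes
    assigned round-robin to blocks.  ``block_rho`` may be a scalar (every
    block identical) or a (low, high) pair giving an equally spaced
    per-block grid of AR(1) parameters (regional LD variability).
    Remainder SNPs go to the last block.  The reference is deterministic;
    ``seed`` is accepted for interface symmetry."""
    if n_blocks < 1 or m_snps < n_blocks:
        raise SimulationError("need m_snps >= n_blocks >= 1")
    if np.isscalar(block_rho):
        rhos = np.full(n_blocks, float(block_rho))
    else:
        lo, hi = block_rho
        rhos = np.linspace(lo, hi, n_blocks)
    base = m_snps // n_blocks
    sizes = [base] * n_blocks
    sizes[-1] += m_snps - base * n_blocks
    blocks = []
    counter = 0
    pos_within_chrom: dict[int, int] = {}
    for b in range(n_blocks):
        m = sizes[b]
        chrom = (b % 22) + 1
        start = pos_within_chrom.get(chrom, 0)
        rsids = [f"rs{counter + j + 1}" for j in range(m)]
        positions = (np.arange(m) + start + 1) * 1000
        pos_within_chrom[chrom] = start + m
        R = ar1_correlation(m, float(rhos[b]))
        blocks.append(LDBlock(chrom=chrom, rsids=rsids,
                              positions=positions, R=R))
        counter += m
    return LDReference(blocks)


# ----------------------------------------------------------------------
# paired genome-wide traits (LDSC target)
# ----------------------------------------------------------------------

def _bivariate_sqrt(h1: float, h2: float, rg: float) -> np.ndarray:
    """Symmetric square root of the 2x2 per-SNP effect covariance (handles
    the singular |rg| = 1 case)."""
    c = rg * np.sqrt(h1 * h2)
    C = np.array([[h1, c], [c, h2]])
    w, V = np.linalg.eigh(C)
    if np.min(w) < -1e-10:
        raise SimulationError("effect covariance not PSD")
    w = np.clip(w, 0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def _emit_sumstats(ld: LDReference, z: np.ndarray, n: int, eaf: np.ndarray,
                   label: str, trait_type: str = "quantitative") -> SumStats:
    tab = ld.snp_table()
    scale = np.sqrt(n * 2.0 * eaf * (1.0 - eaf))
    df = pd.DataFrame({
        "rsid": tab["rsid"], "chrom": tab["chrom"], "pos": tab["pos"],
        "a1": "A", "a2": "G",
        "beta": z / scale, "se": 1.0 / scale,
        "pval": 2.0 * stats.norm.sf(np.abs(z)),
        "n": n, "z": z, "eaf": eaf,
    })
    return SumStats(df, trait_label=label, trait_type=trait_type)


def simulate_paired_sumstats(ld: LDReference, cfg: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[SumStats, SumStats]:
    """Two traits' Z-statistics following the cross-trait LDSC moment model.

    True standardized effects are drawn i.i.d. per SNP from a bivariate
    normal with per-SNP covariance ``[[h2_1, c], [c, h2_2]] / M`` where
    ``c = rg_true * sqrt(h2_1 * h2_2)``; observed Z-vectors are
    ``z_t = sqrt(n_t) R beta_t + e_t`` with block noise ``e ~ N(0, R)``
    correlated across traits by ``rho_pheno * n_overlap / sqrt(n1 n2)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    M = ld.n_snps
    A = _bivariate_sqrt(cfg.h2_1, cfg.h2_2, cfg.rg_true) / np.sqrt(M)
    r0 = cfg.rho_pheno * cfg.n_overlap / np.sqrt(cfg.n1 * cfg.n2)

    z1_parts, z2_parts = [], []
    for blk in ld.blocks:
        m = len(blk.rsids)
        L = blk.cholesky()
        b = rng.standard_normal((m, 2)) @ A.T  # true effects (beta1, beta2)
        u1 = rng.standard_normal(m)
        u2 = rng.standard_normal(m)
        e1 = L @ u1
        e2 = L @ (r0 * u1 + np.sqrt(1 - r0 ** 2) * u2)
        Rb = blk.R @ b
        z1_parts.append(np.sqrt(cfg.n1) * Rb[:, 0] + e1)
        z2_parts.append(np.sqrt(cfg.n2) * Rb[:, 1] + e2)
    z1 = np.concatenate(z1_parts)
    z2 = np.concatenate(z2_parts)
    eaf1 = rng.uniform(0.05, 0.95, M)
    eaf2 = eaf1  # same reference population
    s1 = _emit_sumstats(ld, z1, cfg.n1, eaf1, "trait1")
    s2 = _emit_sumstats(ld, z2, cfg.n2, eaf2, "trait2")
    return s1, s2


def simulate_fetal_maternal(ld: LDReference, cfg: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[SumStats, SumStats]:
    """Fetal- and maternal-specific birthweight summary statistics, emitted
    as if already decomposed.  Per-SNP true effects are bivariate normal
    with correlation ``cfg.fm_corr`` and standard deviation
    ``cfg.fm_effect_sd``; observation noise uses the two components'
    sample sizes."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    M = ld.n_snps
    r = cfg.fm_corr
    u1 = rng.standard_normal(M)
    u2 = rng.standard_normal(M)
    bf = cfg.fm_effect_sd * u1
    bm = cfg.fm_effect_sd * (r * u1 + np.sqrt(1 - r ** 2) * u2)
    eaf = rng.uniform(0.05, 0.95, M)
    out = []
    for b, n, label in ((bf, cfg.n_fetal, "bw_fetal"),
                        (bm, cfg.n_maternal, "bw_maternal")):
        beta_std = b + rng.standard_normal(M) / np.sqrt(n)
        z = beta_std * np.sqrt(n)
        out.append(_emit_sumstats(ld, z, n, eaf, label))
    return out[0], out[1]


# ----------------------------------------------------------------------
# planted pleiotropic genes
# ----------------------------------------------------------------------

@dataclass
class PlantedGenes:
    """Truth table and true per-SNP effects for a planted-gene simulation."""

    truth: pd.DataFrame           # gene_id, label in {H00,H01,H10,H11}
    beta1: pd.Series              # true standardized effects, indexed by rsid
    beta2: pd.Series

    def to_observed_sumstats(self, ld: LDReference, n1: int, n2: int,
                             rng: np.random.Generator,
                             ) -> tuple[SumStats, SumStats]:
        """Observed Z = sqrt(n) R beta + N(0, R) per block."""
        tab = ld.snp_table()
        b1 = self.beta1.reindex(tab["rsid"]).fillna(0.0).to_numpy()
        b2 = self.beta2.reindex(tab["rsid"]).fillna(0.0).to_numpy()
        z1, z2 = [], []
        off = 0
        for blk in ld.blocks:
            m = len(blk.rsids)
            L = blk.cholesky()
            z1.append(np.sqrt(n1) * blk.R @ b1[off:off + m]
                      + L @ rng.standard_normal(m))
            z2.append(np.sqrt(n2) * blk.R @ b2[off:off + m]
                      + L @ rng.standard_normal(m))
            off += m
        eaf = rng.uniform(0.05, 0.95, ld.n_snps)
        s1 = _emit_sumstats(ld, np.concatenate(z1), n1, eaf, "trait1")
        s2 = _emit_sumstats(ld, np.concatenate(z2), n2, eaf, "trait2")
        return s1, s2


def plant_pleiotropic_genes(genes: list[GeneAnnotation], frac_shared: float,
                            effect_corr_sign: int, cfg: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            ) -> PlantedGenes:
    """Assign hypothesis-state labels to genes and draw true SNP effects.

    ``frac_shared`` genes are H11 (associated with both traits) with local
    SNP effect correlation ``effect_corr_sign * cfg.gene_effect_corr``;
    ``cfg.frac_t1_only`` / ``cfg.frac_t2_only`` genes carry an effect on a
    single trait (H10 / H01); the rest are H00.  Labels partition the gene
    set.
    """
    if not (0 <= frac_shared <= 1):
        raise SimulationError("frac_shared must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    G = len(genes)
    n11 = int(round(frac_shared * G))
    n10 = int(round(cfg.frac_t1_only * G))
    n01 = int(round(cfg.frac_t2_only * G))
    # H11 takes precedence; single-trait classes are capped by what remains
    n10 = min(n10, G - n11)
    n01 = min(n01, G - n11 - n10)
    order = rng.permutation(G)
    labels = np.array(["H00"] * G, dtype=object)
    labels[order[:n11]] = "H11"
    labels[order[n11:n11 + n10]] = "H10"
    labels[order[n11 + n10:n11 + n10 + n01]] = "H01"

    rho = float(np.clip(effect_corr_sign, -1, 1)) * cfg.gene_effect_corr \
        if effect_corr_sign in (-1, 1) else cfg.gene_effect_corr
    sd = cfg.gene_effect_sd
    b1: dict[str, float] = {}
    b2: dict[str, float] = {}
    for g, lab in zip(genes, labels):
        m = len(g.snp_ids)
        if m == 0:
            continue
        if lab == "H11":
            u = rng.standard_normal(m)
            v = rng.standard_normal(m)
            e1 = sd * u
            e2 = sd * (rho * u + np.sqrt(1 - rho ** 2) * v)
        elif lab == "H10":
            e1 = sd * rng.standard_normal(m)
            e2 = np.zeros(m)
        elif lab == "H01":
            e1 = np.zeros(m)
            e2 = sd * rng.standard_normal(m)
        else:
            e1 = e2 = np.zeros(m)
        for rsid, x, y in zip(g.snp_ids, e1, e2):
            b1[rsid] = b1.get(rsid, 0.0) + float(x)
            b2[rsid] = b2.get(rsid, 0.0) + float(y)
    truth = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                          "label": labels})
    return PlantedGenes(truth=truth,
                        beta1=pd.Series(b1, dtype=float),
                        beta2=pd.Series(b2, dtype=float))


def simulate_mixture_pvalues(n_genes: int, pis: tuple[float, float, float, float],
                             signal_mu: float = 4.0,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired gene p-values from the four-state mixture (H00, H01, H10,
    H11 with proportions ``pis``): null p-values are U(0,1); non-null
    p-values are two-sided normal tails of ``|N(signal_mu, 1)|``.
    Returns (p1, p2, labels) with labels in {0: H00, 1: H01, 2: H10,
    3: H11}."""
    if rng is None:
        rng = np.random.default_rng(0)
    pis = np.asarray(pis, dtype=float)
    if abs(pis.sum() - 1) > 1e-9 or (pis < 0).any():
        raise SimulationError("mixture proportions must be a distribution")
    lab = rng.choice(4, n_genes, p=pis)
    p1 = rng.uniform(size=n_genes)
    p2 = rng.uniform(size=n_genes)
    nn1 = (lab == 2) | (lab == 3)   # trait 1 non-null
    nn2 = (lab == 1) | (lab == 3)   # trait 2 non-null
    p1[nn1] = 2 * stats.norm.sf(np.abs(rng.normal(signal_mu, 1, nn1.sum())))
    p2[nn2] = 2 * stats.norm.sf(np.abs(rng.normal(signal_mu, 1, nn2.sum())))
    tiny = np.finfo(float).tiny
    return np.clip(p1, tiny, 1.0), np.clip(p2, tiny, 1.0), lab


# ----------------------------------------------------------------------
# causal chain at the instrument level
# ----------------------------------------------------------------------

@dataclass
class ChainData:
    """Instrument-level summary statistics for the four chain traits plus
    generative truth."""

    x: SumStats
    m1: SumStats
    m2: SumStats
    y: SumStats
    truth: dict = field(default_factory=dict)


def simulate_causal_chain(cfg: ChainConfig,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> ChainData:
    """Simulate instrument-level effects through the chain
    ``beta_M1 = theta_XM1 beta_X + gamma``,
    ``beta_M2 = theta_M1M2 beta_M1 + theta_XM2 beta_X + d2``,
    ``beta_Y = theta_M2Y beta_M2 + theta_XY beta_X`` (log-odds scale),
    with standardized observation noise ``1/sqrt(n_trait)`` per trait.

    Three instrument groups are generated: SNPs affecting X directly, SNPs
    affecting M1 directly, and SNPs affecting M2 directly, so every
    exposure in the chain has its own instruments.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    jx, j1, j2 = cfg.n_inst_x, cfg.n_inst_m1, cfg.n_inst_m2
    J = jx + j1 + j2
    group = np.repeat(["X", "M1", "M2"], [jx, j1, j2])

    beta_x = np.zeros(J)
    beta_x[:jx] = rng.normal(0, cfg.inst_sd_x, jx)
    d1 = np.zeros(J)
    d1[jx:jx + j1] = rng.normal(0, cfg.inst_sd_m1, j1)
    d2 = np.zeros(J)
    d2[jx + j1:] = rng.normal(0, cfg.inst_sd_m2, j2)

    gamma = np.zeros(J)
    if cfg.pleiotropy_frac > 0:
        n_pleio = int(round(cfg.pleiotropy_frac * jx))
        idx = rng.choice(jx, n_pleio, replace=False)
        gamma[idx] = rng.normal(cfg.pleiotropy_mean, max(cfg.pleiotropy_sd, 0),
                                n_pleio)

    beta_m1 = cfg.theta_xm1 * beta_x + gamma + d1
    beta_m2 = cfg.theta_m1m2 * beta_m1 + cfg.theta_xm2 * beta_x + d2
    beta_y = cfg.theta_m2y * beta_m2 + cfg.theta_xy * beta_x

    se = {"x": 1 / np.sqrt(cfg.n_x), "m1": 1 / np.sqrt(cfg.n_m1),
          "m2": 1 / np.sqrt(cfg.n_m2), "y": 1 / np.sqrt(cfg.n_y)}
    outlier_rsids: list[str] = []
    rsids = [f"rs9%06d" % (i + 1) for i in range(J)]
    if cfg.outlier_frac > 0:
        n_out = max(1, int(round(cfg.outlier_frac * jx)))
        idx = rng.choice(jx, n_out, replace=False)
        shift = cfg.outlier_scale * se["y"] * rng.choice([-1, 1], n_out)
        beta_y = beta_y.copy()
        beta_y[idx] += shift
        outlier_rsids = [rsids[i] for i in idx]

    chrom = (np.arange(J) % 22) + 1
    pos = (np.arange(J) // 22 + 1) * 2_000_000

    def emit(beta_true, key, n, label, trait_type="quantitative"):
        obs = beta_true + rng.normal(0, se[key], J)
        z = obs / se[key]
        df = pd.DataFrame({
            "rsid": rsids, "chrom": chrom, "pos": pos,
            "a1": "A", "a2": "G",
            "beta": obs, "se": se[key],
            "pval": 2.0 * stats.norm.sf(np.abs(z)),
            "n": n, "z": z,
        })
        return SumStats(df, trait_label=label, trait_type=trait_type)

    truth = {
        "group": pd.Series(group, index=rsids),
        "beta_x": pd.Series(beta_x, index=rsids),
        "beta_m1": pd.Series(beta_m1, index=rsids),
        "beta_m2": pd.Series(beta_m2, index=rsids),
        "beta_y": pd.Series(beta_y, index=rsids),
        "gamma": pd.Series(gamma, index=rsids),
        "outlier_rsids": outlier_rsids,
        "total_effect_xy": (cfg.theta_xy
                            + cfg.theta_xm1 * cfg.theta_m1m2 * cfg.theta_m2y
                            + cfg.theta_xm2 * cfg.theta_m2y),
    }
    return ChainData(
        x=emit(beta_x, "x", cfg.n_x, "birthweight"),
        m1=emit(beta_m1, "m1", cfg.n_m1, "age_at_menarche"),
        m2=emit(beta_m2, "m2", cfg.n_m2, "age_at_menopause"),
        y=emit(beta_y, "y", cfg.n_y, "breast_cancer", "binary"),
        truth=truth,
    )


# ----------------------------------------------------------------------
# birthweight instrument panel with a planted classification composition
# ----------------------------------------------------------------------

#: composition of the fetal/maternal birthweight instrument panel used for
#: classification bookkeeping: fetal-specific, maternal-specific, shared
#: same-direction, shared opposite-direction, unclassified
DEFAULT_PANEL_COMPOSITION = {
    "fetal_specific": 63,
    "maternal_specific": 31,
    "both_same_direction": 26,
    "both_opposite_direction": 15,
    "unclassified": 71,
}


def simulate_bw_instrument_panel(composition: dict[str, int] | None = None,
                                 rng: np.random.Generator | None = None,
                                 n_fetal: int = 264_498,
                                 n_maternal: int = 179_360,
                                 sig_thresh: float = 5e-8,
                                 ) -> tuple[SumStats, SumStats, pd.Series]:
    """Fetal and maternal birthweight summary statistics for a candidate
    instrument panel whose true class composition is ``composition``
    (default: :data:`DEFAULT_PANEL_COMPOSITION` — 63 fetal-specific,
    31 maternal-specific, 26 shared same-direction, 15 shared
    opposite-direction SNPs, plus 71 SNPs with unclassifiable effect
    direction).  Returns the two SumStats plus the planted truth labels
    indexed by rsid."""
    if composition is None:
        composition = dict(DEFAULT_PANEL_COMPOSITION)
    if rng is None:
        rng = np.random.default_rng(0)
    z_crit = stats.norm.isf(sig_thresh / 2)

    rows_f, rows_m, labels, rsids = [], [], [], []

    def z_sig(sign=None):
        z = z_crit + 2.0 + rng.exponential(3.0)
        s = rng.choice([-1, 1]) if sign is None else sign
        return s * z

    def z_null():
        # comfortably inside the acceptance region
        return rng.uniform(-2.0, 2.0)

    i = 0
    for label, count in composition.items():
        for _ in range(count):
            i += 1
            rsids.append(f"rs8%06d" % i)
            labels.append(label)
            if label == "fetal_specific":
                zf, zm = z_sig(), z_null()
            elif label == "maternal_specific":
                zf, zm = z_null(), z_sig()
            elif label == "both_same_direction":
                s = rng.choice([-1, 1])
                zf, zm = z_sig(s), z_sig(s)
            elif label == "both_opposite_direction":
                s = rng.choice([-1, 1])
                zf, zm = z_sig(s), z_sig(-s)
            elif label == "unclassified":
                zf, zm = z_null(), z_null()
            else:
                raise SimulationError(f"unknown class {label}")
            rows_f.append(zf)
            rows_m.append(zm)

    J = len(rsids)
    chrom = (np.arange(J) % 22) + 1
    pos = (np.arange(J) // 22 + 1) * 2_000_000

    def emit(zs, n, label):
        z = np.asarray(zs, dtype=float)
        se = 1.0 / np.sqrt(n)
        df = pd.DataFrame({
            "rsid": rsids, "chrom": chrom, "pos": pos,
            "a1": "A", "a2": "G",
            "beta": z * se, "se": se,
            "pval": 2.0 * stats.norm.sf(np.abs(z)),
            "n": n, "z": z,
        })
        return SumStats(df, trait_label=label)

    fetal = emit(rows_f, n_fetal, "bw_fetal")
    maternal = emit(rows_m, n_maternal, "bw_maternal")
    return fetal, maternal, pd.Series(labels, index=rsids, name="true_class")
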