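"""Block-structured LD reference: per-block SNP correlation matrices.

LD between SNPs in different blocks is taken as exactly zero, the usual
approximately-independent-blocks abstraction.  The per-SNP LD score
``l_j = sum_k r_jk**2`` (self-correlation included, so ``l_j >= 1``) is
derived from the block matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LDError(ValueError):
    pass


@dataclass
class LDBlock:
    chrom: int
    rsids: list[str]
    positions: np.ndarray
    R: np.ndarray  # correlation matrix, unit diagonal, symmetric PSD

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.rsids)
        if self.R.shape != (m, m):
            raise LDError("R shape does not match SNP count")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise LDError("R diagonal must be 1")
        if np.max(np.abs(self.R)) > 1 + 1e-8:
            raise LDError("|r| > 1 in LD block")

    @property
    def ld_scores(self) -> np.ndarray:
        return (self.R ** 2).sum(axis=1)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of R (tiny jitter for PSD boundary),
        cached on the instance."""
        if not hasattr(self, "_chol"):
            self._chol = np.linalg.cholesky(self.R + 1e-12 * np.eye(len(self.R)))
        return self._chol


@dataclass
class LDReference:
    blocks: list[LDBlock]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for b_i, blk in enumerate(self.blocks):
            for j, rsid in enumerate(blk.rsids):
                if rsid in self._index:
                    raise LDError(f"rsid {rsid} appears in two blocks")
                self._index[rsid] = (b_i, j)

    @property
    def n_snps(self) -> int:
        return len(self._index)

    def ld_scores(self) -> pd.Series:
        """Per-SNP LD scores, indexed by rsid."""
        ids, vals = [], []
        for blk in self.blocks:
            ids.extend(blk.rsids)
            vals.append(blk.ld_scores)
        return pd.Series(np.concatenate(vals), index=ids, name="ld_score")

    def snp_table(self) -> pd.DataFrame:
        rows = []
        for blk in self.blocks:
            for rsid, pos in zip(blk.rsids, blk.positions):
                rows.append((rsid, blk.chrom, pos))
        return pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])

    def r2(self, rsid_a: str, rsid_b: str) -> float:
        """Squared correlation between two SNPs (0 across blocks or when a
        SNP is absent from the reference)."""
        a = self._index.get(rsid_a)
        b = self._index.get(rsid_b)
        if a is None or b is None or a[0] != b[0]:
            return 0.0
        return float(self.blocks[a[0]].R[a[1], b[1]] ** 2)

    def submatrix(self, rsids: list[str]) -> np.ndarray:
        """Block-diagonal correlation submatrix for the given SNPs (order
        preserved).  SNPs absent from the reference raise."""
        m = len(rsids)
        out = np.eye(m)
        locs = []
        for r in rsids:
            if r not in self._index:
                raise LDError(f"rsid {r} not in LD reference")
            locs.append(self._index[r])
        for i in range(m):
            bi, ji = locs[i]
            for k in range(i + 1, m):
                bk, jk = locs[k]
                if bi == bk:
                    out[i, k] = out[k, i] = self.blocks[bi].R[ji, jk]
        return out

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index


def save_ld_reference(ld: LDReference, out_dir) -> None:
    """Write one tab-delimited file per block: columns ``rsid, chrom, pos``
    followed by the correlation matrix rows."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for i, blk in enumerate(ld.blocks):
        df = pd.DataFrame({"rsid": blk.rsids,
                           "chrom": blk.chrom,
                           "pos": blk.positions})
        rmat = pd.DataFrame(blk.R, columns=[f"r{j}" for j in range(len(blk.R))])
        pd.concat([df, rmat], axis=1).to_csv(
            os.path.join(out_dir, f"block_{i:05d}.tsv"),
            sep="\t", index=False, float_format="%.17g")


def load_ld_reference(in_dir) -> LDReference:
    import glob
    import os

    paths = sorted(glob.glob(os.path.join(str(in_dir), "block_*.tsv")))
    if not paths:
        raise LDError(f"no LD block files in {in_dir}")
    blocks = []
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        rcols = [c for c in df.columns if c.startswith("r") and c[1:].isdigit()]
        blocks.append(LDBlock(
            chrom=int(df["chrom"].iloc[0]),
            rsids=list(df["rsid"]),
            positions=df["pos"].to_numpy(),
            R=df[rcols].to_numpy(dtype=float)))
    return LDReference(blocks)


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix ``R_jk = rho**|j-k|`` (always PSD for
    ``0 <= rho < 1``)."""
    if not 0 <= rho < 1:
        raise LDError("AR(1) parameter must satisfy 0 <= rho < 1")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])
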