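"""Per-SNP regression statistics and pairwise LD structure of an ROI.

For each SNP the expression vector is regressed on the coded genotype; the
resulting sample coefficient of determination equals the squared Pearson
correlation, and the slope t-test supplies a nominal two-sided p-value.
Pairwise signed Pearson correlations between coded genotype vectors give
the r² LD estimates used downstream for model prediction and family
parsing.  Missing dosages are mean-imputed per SNP before any correlation
is computed, keeping all statistics on a common sample set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import ROIDataset

logger = logging.getLogger(__name__)


@dataclass
class AssociationProfile:
    """Per-SNP single-variable statistics plus the genotype correlation matrix.

    ``r2_est = r_y**2`` elementwise; ``geno_corr`` is symmetric with unit
    diagonal; monomorphic SNPs carry ``r_y = 0, p_val = 1`` and are flagged
    in ``monomorphic``.  ``n_samples`` and ``sst`` (total sum of squares of
    expression) are retained so downstream model scores (R²_M-based
    likelihoods) need no second pass over the data.
    """

    snp_ids: list[str]
    r_y: np.ndarray
    r2_est: np.ndarray
    p_val: np.ndarray
    geno_corr: np.ndarray
    monomorphic: np.ndarray
    n_samples: int
    sst: float
    snps: pd.DataFrame = field(repr=False)
    genotypes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def r2_ld(self) -> np.ndarray:
        return self.geno_corr**2

    def index_of(self, snp_ids: list[str] | str) -> np.ndarray:
        """Positional indices of the given SNP ids (order preserved)."""
        if isinstance(snp_ids, str):
            snp_ids = [snp_ids]
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from exc

    def to_frame(self) -> pd.DataFrame:
        out = self.snps[["snp_id", "chrom", "pos"]].copy()
        out["r_y"] = self.r_y
        out["r2_est"] = self.r2_est
        out["p_val"] = self.p_val
        return out

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def _impute_mean(genotypes: np.ndarray) -> np.ndarray:
    """Mean-dosage imputation per SNP; returns a dense copy."""
    g = np.array(genotypes, dtype=float, copy=True)
    n_missing = int(np.isnan(g).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotype entries", n_missing)
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = col_mean[idx[1]]
    return g


def pairwise_ld(dataset: ROIDataset) -> tuple[np.ndarray, np.ndarray]:
    """Signed genotype correlation matrix and its elementwise square (r² LD).

    Monomorphic SNPs (zero genotype variance) get correlation 0 to every
    other SNP, with a warning; the diagonal stays 1.
    """
    g = _impute_mean(dataset.genotypes)
    sd = g.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s): pairwise correlation set to 0",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(mono, 1.0, sd)
    z = (g - g.mean(axis=0)) / safe
    corr = z.T @ z / g.shape[0]
    corr[mono, :] = 0.0
    corr[:, mono] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return corr, corr**2


def estimate_per_snp(dataset: ROIDataset) -> AssociationProfile:
    """Single-variable OLS of expression on each SNP's coded genotype.

    The per-SNP coefficient of determination is the squared Pearson r of
    expression with genotype; the two-sided p-value comes from the slope
    t-statistic ``t = r sqrt((n-2)/(1-r²))`` with n-2 degrees of freedom.
    """
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples")
    g = _impute_mean(dataset.genotypes)
    y = dataset.expression
    n = dataset.n_samples
    sd_g = g.std(axis=0)
    mono = sd_g == 0
    if not (sd_g > 0).any() and y.std() == 0:
        raise ValueError("all SNPs monomorphic and expression constant")
    yc = y - y.mean()
    sy = yc.std()
    if sy == 0:
        raise ValueError("expression vector is constant")
    safe = np.where(mono, 1.0, sd_g)
    r = (yc / sy) @ ((g - g.mean(axis=0)) / safe) / n
    r = np.clip(np.where(mono, 0.0, r), -1.0, 1.0)
    r2 = r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(mono, 1.0, p)
    if mono.any():
        logger.info(
            "%d monomorphic SNP(s) flagged (r2_est=0, p=1)", int(mono.sum())
        )
    corr, _ = pairwise_ld(dataset)
    return AssociationProfile(
        snp_ids=dataset.snp_ids,
        r_y=r,
        r2_est=r2,
        p_val=p,
        geno_corr=corr,
        monomorphic=mono,
        n_samples=n,
        sst=float((yc**2).sum()),
        snps=dataset.snps,
        genotypes=g,
    )
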