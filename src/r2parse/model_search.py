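"""Exhaustive enumeration and scoring of 1-4 index-SNP (iSNP) models.

Each candidate model picks 1-4 ROI SNPs as proxies for unknown regulatory
variants and predicts, from the constraint matrix equations, the
coefficient of determination every other ROI SNP should show if it merely
tags those proxies through LD.  Agreement between the predicted and the
estimated (single-variable regression) R² values across the whole ROI is
the model's score; the default ranking criterion is minimum NRMSE, with
maximum adjusted R²_model, maximum R²_M, maximum summed iSNP R², minimum
AIC and minimum BIC available as alternatives.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import corrmath
from .association import AssociationProfile

logger = logging.getLogger(__name__)

#: ranking criteria: name -> (attribute, direction); +1 means larger is better
CRITERIA: dict[str, tuple[str, int]] = {
    "nrmse": ("nrmse", -1),
    "adj_r2_model": ("adj_r2_model", +1),
    "r2_m": ("r2_m", +1),
    "sum_isnp_r2": ("sum_isnp_r2", +1),
    "aic": ("aic", -1),
    "bic": ("bic", -1),
}


@dataclass
class ISNPModel:
    """One scored iSNP model over the full ROI."""

    isnp_ids: list[str]
    predicted_r2: np.ndarray | None
    nrmse: float = math.nan
    adj_r2_model: float = math.nan
    r2_m: float = math.nan
    sum_isnp_r2: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    loglik: float = math.nan
    valid: bool = True
    message: str = ""
    n_warn_gt1: int = field(default=0, repr=False)

    @property
    def size(self) -> int:
        return len(self.isnp_ids)


def reduce_candidates(
    profile: AssociationProfile, p_threshold: float = 0.05
) -> list[str]:
    """Shortlist candidate iSNPs: significant, one per duplicate-genotype group.

    Keeps SNPs with nominal p below ``p_threshold``; among SNPs with
    byte-identical coded genotype vectors only the one at the lowest genomic
    position survives.  The full ROI SNP list is untouched elsewhere — it
    remains the prediction target set.
    """
    keep = (profile.p_val < p_threshold) & ~profile.monomorphic
    if not keep.any():
        raise ValueError(
            f"no SNP passes p < {p_threshold}; relax the threshold"
        )
    if profile.genotypes is None:
        raise ValueError("profile lacks genotype matrix for duplicate check")
    pos = profile.snps["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    seen: dict[bytes, str] = {}
    survivors = []
    for j in order:
        if not keep[j]:
            continue
        key = profile.genotypes[:, j].tobytes()
        if key in seen:
            logger.info(
                "dropping %s: duplicate genotypes of %s",
                profile.snp_ids[j],
                seen[key],
            )
            continue
        seen[key] = profile.snp_ids[j]
        survivors.append(j)
    survivors.sort()
    return [profile.snp_ids[j] for j in survivors]


def evaluate_model(
    isnp_ids: list[str], profile: AssociationProfile
) -> ISNPModel:
    """Score one iSNP set: predicted R² over every ROI SNP plus fit metrics.

    A collinear iSNP pair marks the model invalid (logged, not fatal) so the
    surrounding search can skip it.  AIC/BIC come from the Gaussian
    likelihood of the multiple OLS of expression on the iSNP genotypes,
    computed analytically from R²_M, the expression total sum of squares
    and n; the parameter count includes the intercept and the residual
    variance.
    """
    isnp_ids = list(isnp_ids)
    if not 1 <= len(isnp_ids) <= 4:
        raise ValueError("models use 1-4 iSNPs")
    if len(set(isnp_ids)) != len(isnp_ids):
        model = ISNPModel(isnp_ids, None, valid=False,
                          message="duplicate iSNP in set")
        logger.info("invalid model %s: %s", isnp_ids, model.message)
        return model
    idx = profile.index_of(isnp_ids)
    c = profile.r_y[idx]
    r_mat = profile.geno_corr[np.ix_(idx, idx)]
    a_mat = profile.geno_corr[:, idx]
    try:
        r2_m = corrmath.multiple_r2(c, r_mat)
        predicted = corrmath.predict_r2_profile(c, r_mat, a_mat)
    except corrmath.CollinearityError as exc:
        model = ISNPModel(isnp_ids, None, valid=False, message=str(exc))
        logger.info("invalid model %s: %s", isnp_ids, model.message)
        return model
    est = profile.r2_est
    resid = est - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    spread = float(est.max() - est.min())
    nrmse = rmse / spread if spread > 0 else rmse
    adj = _adjusted_r2_of_fit(est, predicted)
    n, k = profile.n_samples, len(isnp_ids)
    ssr = profile.sst * max(1.0 - r2_m, 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * ssr / n) + 1.0)
    n_par = k + 2  # slopes + intercept + residual variance
    return ISNPModel(
        isnp_ids=isnp_ids,
        predicted_r2=predicted,
        nrmse=nrmse,
        adj_r2_model=adj,
        r2_m=float(r2_m),
        sum_isnp_r2=float(est[idx].sum()),
        aic=2.0 * n_par - 2.0 * loglik,
        bic=n_par * math.log(n) - 2.0 * loglik,
        loglik=loglik,
        n_warn_gt1=int(np.sum(predicted > 1.0)),
    )


def _adjusted_r2_of_fit(est: np.ndarray, pred: np.ndarray) -> float:
    """Adjusted R² of the OLS of estimated on predicted R² (one predictor)."""
    n = est.shape[0]
    if n < 3 or np.std(pred) == 0 or np.std(est) == 0:
        return math.nan
    r2 = float(np.corrcoef(est, pred)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def search(
    profile: AssociationProfile,
    *,
    max_isnps: int = 3,
    criterion: str = "nrmse",
    top_k: int | None = None,
    p_threshold: float = 0.05,
    candidates: list[str] | None = None,
    max_models: int = 200_000,
) -> list[ISNPModel]:
    """Exhaustively enumerate and rank all 1..max_isnps iSNP models.

    Deterministic given input order; ties broken lexicographically on the
    iSNP id list.  Raises if the combinatorial budget ``max_models`` would
    be exceeded (tighten ``p_threshold`` in that case).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; one of {sorted(CRITERIA)}")
    if not 1 <= max_isnps <= 4:
        raise ValueError("max_isnps must be 1-4")
    if candidates is None:
        candidates = reduce_candidates(profile, p_threshold)
    if not candidates:
        raise ValueError("empty candidate list")
    n_models = sum(
        math.comb(len(candidates), k)
        for k in range(1, min(max_isnps, len(candidates)) + 1)
    )
    if n_models > max_models:
        raise ValueError(
            f"{n_models} models exceed the budget of {max_models}; "
            "use a stricter p_threshold"
        )
    models = []
    for k in range(1, min(max_isnps, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, k):
            models.append(evaluate_model(list(combo), profile))
    n_invalid = sum(not m.valid for m in models)
    if n_invalid:
        logger.info("skipped %d collinear/invalid models", n_invalid)
    return rank_models([m for m in models if m.valid], criterion, top_k)


def rank_models(
    models: list[ISNPModel], criterion: str = "nrmse", top_k: int | None = None
) -> list[ISNPModel]:
    attr, direction = CRITERIA[criterion]

    def key(m: ISNPModel):
        v = getattr(m, attr)
        v = math.inf if math.isnan(v) else v
        return (-direction * v, tuple(m.isnp_ids))

    ranked = sorted(models, key=key)
    return ranked if top_k is None else ranked[:top_k]


def models_to_frame(models: list[ISNPModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "isnp_ids": [",".join(m.isnp_ids) for m in models],
            "n_isnps": [m.size for m in models],
            "nrmse": [m.nrmse for m in models],
            "adj_r2_model": [m.adj_r2_model for m in models],
            "r2_m": [m.r2_m for m in models],
            "sum_isnp_r2": [m.sum_isnp_r2 for m in models],
            "aic": [m.aic for m in models],
            "bic": [m.bic for m in models],
        }
    )


def write_models_tsv(models: list[ISNPModel], path: str) -> None:
    models_to_frame(models).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_best_model_json(
    model: ISNPModel, profile: AssociationProfile, path: str
) -> None:
    payload = {
        "isnp_ids": model.isnp_ids,
        "nrmse": model.nrmse,
        "adj_r2_model": model.adj_r2_model,
        "r2_m": model.r2_m,
        "sum_isnp_r2": model.sum_isnp_r2,
        "aic": model.aic,
        "bic": model.bic,
        "predicted_r2": {
            s: float(v) for s, v in zip(profile.snp_ids, model.predicted_r2)
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
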