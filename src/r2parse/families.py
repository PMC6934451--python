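"""Parsing ROI SNPs into semi-independent families around the chosen iSNPs.

Once a best iSNP model is selected, every ROI SNP is assigned to the iSNP
with which it shares the largest genotype-based r² LD, provided that r²
clears a membership threshold; otherwise it stays unassigned.  The scaled
line heights for the R²-Δ² diagnostic plot are the per-iSNP r² profiles
multiplied by that iSNP's estimated R², so each line touches its iSNP's own
bar exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationProfile
from .model_search import ISNPModel

UNASSIGNED = "unassigned"

#: Default membership threshold on r²; the visual grouping in typical data
#: corresponds to roughly this level, and it is configurable everywhere.
DEFAULT_R2_THRESHOLD = 0.2


@dataclass
class FamilyAssignment:
    snp_id: str
    family_label: str
    r2_to_isnp: np.ndarray


def assign_families(
    profile: AssociationProfile,
    model: ISNPModel,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """Assign each ROI SNP to the iSNP family with maximal r² LD.

    Returns a DataFrame with one row per ROI SNP: family label (an iSNP id
    or ``"unassigned"``) plus the r² to each iSNP.  Each iSNP belongs to its
    own family (r² = 1 with itself).  Ties at the maximum are broken toward
    the iSNP with the larger estimated R².
    """
    if not model.valid:
        raise ValueError("cannot parse families from an invalid model")
    idx = profile.index_of(model.isnp_ids)
    r2 = profile.r2_ld[:, idx]  # (n_snps, p)
    isnp_r2_est = profile.r2_est[idx]
    labels = []
    for i in range(profile.n_snps):
        row = r2[i]
        best = row.max()
        if best < r2_threshold:
            labels.append(UNASSIGNED)
            continue
        tied = np.flatnonzero(np.isclose(row, best, rtol=0, atol=1e-12))
        j = tied[np.argmax(isnp_r2_est[tied])]
        labels.append(model.isnp_ids[j])
    out = profile.snps[["snp_id", "chrom", "pos"]].copy()
    out["family_label"] = labels
    for k, isnp in enumerate(model.isnp_ids):
        out[f"r2_to_{isnp}"] = r2[:, k]
    return out


def scale_plot_lines(
    profile: AssociationProfile, model: ISNPModel
) -> np.ndarray:
    """Per-iSNP line heights for the R²-Δ² plot.

    Height of iSNP j's line at SNP i is ``r²(i, j) * r2_est(j)``, so at the
    iSNP's own position the line height equals its estimated R².
    """
    if not model.valid:
        raise ValueError("cannot plot an invalid model")
    idx = profile.index_of(model.isnp_ids)
    return profile.r2_ld[:, idx] * profile.r2_est[idx][None, :]


def write_families_tsv(families: pd.DataFrame, path: str) -> None:
    families.to_csv(path, sep="\t", index=False, float_format="%.8g")
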