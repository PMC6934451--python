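"""Top-level modelling API: fit an iSNP family model to an ROI dataset.

Follows the familiar model/results split: :class:`SNPFamilyModel` wraps the
aligned data and the analysis settings; ``fit()`` runs the per-SNP
association scan, the exhaustive iSNP model search and the family parsing,
returning a :class:`SNPFamilyResults` that carries the ranked models, the
best model's predictions, the family assignments, a ``summary()`` table and
the two diagnostic plots.

Example
-------
>>> from r2parse import SNPFamilyModel, simulate
>>> dataset, truth = simulate.simulate_roi(
...     n_blocks=4, block_size=5, causal={0: 0.25, 10: 0.10}, seed=7)
>>> res = SNPFamilyModel(dataset).fit(max_isnps=2)
>>> res.best_model.isnp_ids  # doctest: +SKIP
['snp001', 'snp011']
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import association, families, model_search
from .dataset_io import ROIDataset, assemble, load_dataset


class SNPFamilyModel:
    """Multiple-R²-based parsing of ROI SNPs into iSNP families.

    Parameters
    ----------
    dataset
        An assembled :class:`~r2parse.dataset_io.ROIDataset` (aligned
        expression vector + coded genotype matrix).
    """

    def __init__(self, dataset: ROIDataset):
        self.dataset = dataset
        self.profile = association.estimate_per_snp(dataset)

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.Series,
        genotypes: pd.DataFrame,
        snps: pd.DataFrame | None = None,
        *,
        min_maf: float = 0.0,
        max_missing: float = 1.0,
    ) -> "SNPFamilyModel":
        """Build from a sample-indexed expression Series and dosage frame."""
        if snps is None:
            snps = pd.DataFrame(
                {
                    "snp_id": genotypes.columns,
                    "chrom": "NA",
                    "pos": np.arange(1, genotypes.shape[1] + 1),
                    "ref": "N",
                    "alt": "N",
                    "minor_allele": "",
                }
            )
        dataset = assemble(
            snps, genotypes, expression, min_maf=min_maf, max_missing=max_missing
        )
        return cls(dataset)

    @classmethod
    def from_files(
        cls,
        genotype_path: str,
        expression_path: str,
        region: str | None = None,
        *,
        min_maf: float = 0.05,
        max_missing: float = 0.1,
    ) -> "SNPFamilyModel":
        return cls(
            load_dataset(
                genotype_path,
                expression_path,
                region,
                min_maf=min_maf,
                max_missing=max_missing,
            )
        )

    def fit(
        self,
        *,
        p_threshold: float = 0.05,
        max_isnps: int = 3,
        criterion: str = "nrmse",
        top_k: int | None = 100,
        family_r2_threshold: float = families.DEFAULT_R2_THRESHOLD,
        max_models: int = 200_000,
    ) -> "SNPFamilyResults":
        """Run candidate reduction, exhaustive model search and family parsing."""
        candidates = model_search.reduce_candidates(self.profile, p_threshold)
        ranked = model_search.search(
            self.profile,
            max_isnps=max_isnps,
            criterion=criterion,
            top_k=top_k,
            candidates=candidates,
            max_models=max_models,
        )
        best = ranked[0]
        fam = families.assign_families(
            self.profile, best, r2_threshold=family_r2_threshold
        )
        return SNPFamilyResults(
            model=self,
            profile=self.profile,
            candidates=candidates,
            ranked_models=ranked,
            best_model=best,
            families=fam,
            criterion=criterion,
            settings={
                "p_threshold": p_threshold,
                "max_isnps": max_isnps,
                "criterion": criterion,
                "top_k": top_k,
                "family_r2_threshold": family_r2_threshold,
            },
        )


@dataclass
class SNPFamilyResults:
    """Fit results: ranked iSNP models, best-model predictions, families."""

    model: SNPFamilyModel
    profile: association.AssociationProfile
    candidates: list[str]
    ranked_models: list[model_search.ISNPModel]
    best_model: model_search.ISNPModel
    families: pd.DataFrame
    criterion: str
    settings: dict = field(default_factory=dict)

    @property
    def models_frame(self) -> pd.DataFrame:
        return model_search.models_to_frame(self.ranked_models)

    def family_sizes(self) -> pd.Series:
        return self.families["family_label"].value_counts()

    def summary(self) -> SimpleTable:
        """Text summary of the selected model, statsmodels-table style."""
        b = self.best_model
        sizes = self.family_sizes()
        rows = [
            ("ROI SNPs", f"{self.profile.n_snps}"),
            ("samples", f"{self.profile.n_samples}"),
            ("candidate iSNPs", f"{len(self.candidates)}"),
            ("models evaluated", f"{len(self.ranked_models)} (top kept)"),
            ("criterion", self.criterion),
            ("selected iSNPs", ", ".join(b.isnp_ids)),
            ("NRMSE", f"{b.nrmse:.4f}"),
            ("adj R2 (model)", f"{b.adj_r2_model:.4f}"),
            ("R2_M (iSNP set)", f"{b.r2_m:.4f}"),
            ("sum iSNP R2", f"{b.sum_isnp_r2:.4f}"),
            ("AIC", f"{b.aic:.2f}"),
            ("BIC", f"{b.bic:.2f}"),
        ] + [
            (f"family {label}", f"{count} SNPs")
            for label, count in sizes.items()
        ]
        return SimpleTable(
            [[v] for _, v in rows],
            headers=[""],
            stubs=[k for k, _ in rows],
            title="iSNP family model (multiple-R² parsing)",
        )

    def plot_r2_r2(self, path: str | None = None, **kwargs):
        from . import plotting

        return plotting.plot_r2_r2(self.profile, self.best_model, path, **kwargs)

    def plot_r2_delta2(self, path: str | None = None, **kwargs):
        from . import plotting

        return plotting.plot_r2_delta2(
            self.profile, self.best_model, self.families, path, **kwargs
        )

    def save(self, outdir: str) -> dict[str, str]:
        """Write the association, model-ranking, best-model and family files."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "association": os.path.join(outdir, "association.tsv"),
            "models": os.path.join(outdir, "models.tsv"),
            "best_model": os.path.join(outdir, "best_model.json"),
            "families": os.path.join(outdir, "families.tsv"),
        }
        self.profile.to_tsv(paths["association"])
        model_search.write_models_tsv(self.ranked_models, paths["models"])
        model_search.write_best_model_json(
            self.best_model, self.profile, paths["best_model"]
        )
        families.write_families_tsv(self.families, paths["families"])
        return paths
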