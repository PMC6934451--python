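"""Reading, aligning and coding genotype/expression inputs for an ROI.

Genotypes arrive as a VCF (GT or DS fields) or a dosage TSV (header row =
SNP ids, first column = sample id); expression as a two-column TSV
(sample_id, value).  :func:`assemble` intersects samples, recodes dosages to
minor-allele counts within the analyzed sample set, applies MAF and
missingness filters, and returns the aligned :class:`ROIDataset` the rest of
the package consumes.  Positions are 1-based as in VCF; region filters use
half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "minor_allele"]


@dataclass
class ROIDataset:
    """Aligned expression vector + coded genotype matrix for one ROI.

    Attributes
    ----------
    sample_ids : list of str
    snps : DataFrame
        Columns ``snp_id, chrom, pos, ref, alt, minor_allele``, sorted by
        (chrom, pos).
    genotypes : ndarray, shape (n_samples, n_snps)
        Minor-allele dosages in [0, 2]; NaN marks missing calls prior to
        imputation.  Fractional dosages (imputed genotypes) are accepted.
    expression : ndarray, shape (n_samples,)
        One expression value per sample, in the units provided.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    genotypes: np.ndarray
    expression: np.ndarray
    assembled: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or self.expression.shape != (n,):
            raise ValueError("sample dimension mismatch")
        if len(self.snps) != m:
            raise ValueError("SNP dimension mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.genotypes, initial=0) < -1e-9 or np.nanmax(
                self.genotypes, initial=0
            ) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` into its parts (1-based, half-open)."""
    m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", region.replace(",", ""))
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if end <= start:
        raise ValueError(f"empty region {region!r}")
    return chrom, start, end


def _read_vcf(path: str, region: str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)  # gt_types: 0/1/2 = alt count, 3 = missing
    samples = list(vcf.samples)
    records, columns = [], []
    sel = parse_region(region) if region else None
    for var in vcf:
        if sel is not None:
            chrom, start, end = sel
            if var.CHROM != chrom or not (start <= var.POS < end):
                continue
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d", var.CHROM, var.POS
            )
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom ref, 1=het, 2=hom alt (when gts012), 3=missing
            gt = np.asarray(var.gt_types, dtype=float)
            dose = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        records.append(
            {
                "snp_id": snp_id,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
                "minor_allele": "",
            }
        )
        columns.append(dose)
    if not records:
        raise ValueError(f"zero SNPs in region {region!r} of {path}")
    snp_df = pd.DataFrame(records)
    geno = pd.DataFrame(
        np.column_stack(columns), index=samples, columns=snp_df["snp_id"]
    )
    return snp_df, geno


def _read_dosage_tsv(
    path: str, region: str | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    try:
        geno = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed dosage TSV {path}: {exc}") from exc
    geno.index = geno.index.astype(str)
    snp_df = pd.DataFrame(
        {
            "snp_id": geno.columns,
            "chrom": "NA",
            "pos": np.arange(1, geno.shape[1] + 1),
            "ref": "N",
            "alt": "N",
            "minor_allele": "",
        }
    )
    # a companion .snps.tsv sidecar may carry real coordinates
    sidecar = re.sub(r"\.tsv$", "", str(path)) + ".snps.tsv"
    try:
        meta = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
        meta = meta.set_index("snp_id").reindex(geno.columns)
        for col in ("chrom", "pos", "ref", "alt"):
            if col in meta:
                snp_df[col] = meta[col].values
    except FileNotFoundError:
        pass
    if region:
        chrom, start, end = parse_region(region)
        keep = (snp_df["chrom"] == chrom) & (
            (snp_df["pos"] >= start) & (snp_df["pos"] < end)
        )
        if not keep.any():
            raise ValueError(f"zero SNPs in region {region!r} of {path}")
        snp_df = snp_df[keep.values].reset_index(drop=True)
        geno = geno.loc[:, snp_df["snp_id"]]
    return snp_df, geno


def read_genotypes(
    path: str, region: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read SNP records and a raw (uncoded) sample x SNP dosage frame.

    VCF input yields ALT-allele dosages; TSV input is taken as-is.  Coding
    to minor-allele counts happens in :func:`assemble`.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path, region)
    return _read_dosage_tsv(path, region)


def read_expression(path: str) -> pd.Series:
    """Read a two-column (sample_id, value) expression TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"expression TSV {path} needs >= 2 columns")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        bad = df.iloc[int(values.isna().idxmax()), 1]
        raise ValueError(f"non-numeric expression value {bad!r} in {path}")
    return pd.Series(values.values, index=df.iloc[:, 0].astype(str).values)


def assemble(
    snp_df: pd.DataFrame,
    genotypes: pd.DataFrame,
    expression: pd.Series,
    *,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
) -> ROIDataset:
    """Intersect samples, code to minor-allele dosage, filter, sort.

    Sample order follows the expression input.  Within the intersected
    sample set, a SNP whose mean dosage exceeds 1 (allele frequency > 0.5)
    is flipped to ``2 - dosage`` so the coded allele is the minor one; ties
    at frequency 0.5 are broken by alphabetical allele order.  SNPs with
    MAF below ``min_maf`` or missingness above ``max_missing`` are dropped
    (logged).
    """
    shared = [s for s in expression.index if s in set(genotypes.index)]
    if not shared:
        raise ValueError("no shared sample ids between genotypes and expression")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    geno = genotypes.loc[shared].to_numpy(dtype=float)
    expr = expression.loc[shared].to_numpy(dtype=float)

    snp_df = snp_df.reset_index(drop=True).copy()
    keep, minor = [], []
    for j, row in snp_df.iterrows():
        col = geno[:, j]
        miss = np.isnan(col).mean()
        freq = np.nanmean(col) / 2.0 if miss < 1.0 else np.nan
        flip = False
        if np.isnan(freq):
            pass
        elif freq > 0.5:
            flip = True
        elif freq == 0.5:
            # code the alphabetically-first allele at the MAF = 0.5 tie
            flip = str(row["ref"]) < str(row["alt"])
        if flip:
            geno[:, j] = 2.0 - col
            freq = 1.0 - freq
        minor.append(
            (row["ref"] if flip else row["alt"]) if row["alt"] != "N" else ""
        )
        maf = freq if not np.isnan(freq) else 0.0
        if miss > max_missing:
            logger.info("dropping %s: missingness %.3f", row["snp_id"], miss)
            keep.append(False)
        elif maf < min_maf:
            logger.info("dropping %s: MAF %.4f < %.4f", row["snp_id"], maf, min_maf)
            keep.append(False)
        else:
            keep.append(True)
    snp_df["minor_allele"] = minor
    snp_df = snp_df[keep].reset_index(drop=True)
    geno = geno[:, np.asarray(keep, dtype=bool)]
    if snp_df.empty:
        raise ValueError("no SNPs survive MAF/missingness filters")
    order = snp_df.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    snp_df = snp_df.loc[order].reset_index(drop=True)
    geno = geno[:, order]
    return ROIDataset(
        sample_ids=list(shared),
        snps=snp_df,
        genotypes=geno,
        expression=expr,
        assembled=True,
    )


def assemble_dataset(
    dataset: ROIDataset, *, min_maf: float = 0.05, max_missing: float = 0.1
) -> ROIDataset:
    """Run :func:`assemble` on an existing dataset (idempotent on output)."""
    geno = pd.DataFrame(
        dataset.genotypes, index=dataset.sample_ids, columns=dataset.snp_ids
    )
    expr = pd.Series(dataset.expression, index=dataset.sample_ids)
    return assemble(
        dataset.snps, geno, expr, min_maf=min_maf, max_missing=max_missing
    )


def load_dataset(
    genotype_path: str,
    expression_path: str,
    region: str | None = None,
    *,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
) -> ROIDataset:
    """Convenience wrapper: read both inputs and assemble the ROI dataset."""
    snp_df, geno = read_genotypes(genotype_path, region)
    expr = read_expression(expression_path)
    return assemble(snp_df, geno, expr, min_maf=min_maf, max_missing=max_missing)


def write_dosage_tsv(dataset: ROIDataset, path: str) -> None:
    """Write the coded genotype matrix as a dosage TSV plus a SNP sidecar."""
    pd.DataFrame(
        dataset.genotypes, index=dataset.sample_ids, columns=dataset.snp_ids
    ).rename_axis("sample_id").to_csv(path, sep="\t")
    sidecar = re.sub(r"\.tsv$", "", str(path)) + ".snps.tsv"
    dataset.snps.to_csv(sidecar, sep="\t", index=False)


def write_expression_tsv(dataset: ROIDataset, path: str) -> None:
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "value": dataset.expression}
    ).to_csv(path, sep="\t", index=False)


def write_vcf(
    dataset: ROIDataset,
    path: str,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Write genotypes as a minimal VCF 4.2 text file.

    When the per-sample haplotype pair is known (simulated data),
    ``haplotypes`` with shape (n_samples, 2, n_snps) preserves phase via
    ``a|b`` GT fields; otherwise unphased genotypes are written from the
    rounded dosage.  The coded (minor) allele is written as ALT so dosages
    round-trip.
    """
    lines = [
        "##fileformat=VCFv4.2",
        *(
            f"##contig=<ID={c}>"
            for c in dict.fromkeys(dataset.snps["chrom"].astype(str))
        ),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dataset.sample_ids),
    ]
    for j, row in dataset.snps.iterrows():
        ref = row["ref"] if row["ref"] not in ("", "N") else "A"
        alt = row["alt"] if row["alt"] not in ("", "N") else "T"
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["snp_id"]),
            ref,
            alt,
            ".",
            "PASS",
            ".",
            "GT",
        ]
        for i in range(dataset.n_samples):
            if haplotypes is not None:
                a, b = haplotypes[i, 0, j], haplotypes[i, 1, j]
                fields.append(f"{int(a)}|{int(b)}")
            else:
                g = dataset.genotypes[i, j]
                if np.isnan(g):
                    fields.append("./.")
                else:
                    g = int(round(g))
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[g])
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
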