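"""Haplotype-based simulation of genotype/expression datasets.

Populations are generated from a haplotype frequency vector over 2-5 SNPs:
each individual draws two haplotypes independently (Hardy-Weinberg
equilibrium) and genotypes are coded as minor-allele counts.  Expression is
assigned from the genotypes of the designated regulatory SNPs under Fisher's
genotypic-value framework with purely additive allelic effects (genotypic
values -a, 0, +a; no dominance), plus Gaussian noise.

Two ways of specifying the haplotype distribution are supported, mirroring
the two validation designs the method was checked against:

* random frequencies from a Dirichlet draw over all 2^m haplotypes, giving
  a wide spread of allele frequencies and pairwise r² LD values;
* an explicit LD parameterization — per-SNP minor allele frequencies plus
  pairwise D and (for three loci) third-order D_ABC coefficients — converted
  to haplotype frequencies through the Bennett-style decomposition.

Multi-block ROIs (tens of SNPs) are built by concatenating independent
haplotype blocks, so cross-block LD is zero by construction and the block
label of each SNP is a usable ground truth for family parsing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import ROIDataset

__all__ = [
    "HaplotypeSpec",
    "SimulationSpec",
    "GroundTruth",
    "random_haplotype_spec",
    "ld_to_haplotype_freqs",
    "haplotype_freqs_to_ld",
    "simulate_dataset",
    "simulate_roi",
    "effects_for_target_r2",
]


def _haplotype_alleles(n_snps: int) -> np.ndarray:
    """(2^n, n) matrix; entry 1 means the haplotype carries the minor allele.

    Haplotype index h carries the minor allele at SNP j iff bit j of h is
    set (SNP 0 = least significant bit).
    """
    h = np.arange(2**n_snps)
    return ((h[:, None] >> np.arange(n_snps)[None, :]) & 1).astype(float)


@dataclass
class HaplotypeSpec:
    """Haplotype frequency vector over all 2^n_snps haplotypes of an LD block."""

    n_snps: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not 2 <= self.n_snps <= 5:
            raise ValueError("supported block sizes are 2-5 SNPs")
        if self.freqs.shape != (2**self.n_snps,):
            raise ValueError("need one frequency per haplotype")
        if np.any(self.freqs < -1e-12):
            raise ValueError("negative haplotype frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the designated (minor) allele at each SNP."""
        return _haplotype_alleles(self.n_snps).T @ self.freqs

    def genotype_cov(self) -> np.ndarray:
        """Population covariance of the 0/1/2 genotype vector under HWE."""
        alle = _haplotype_alleles(self.n_snps)
        p = alle.T @ self.freqs
        second = alle.T @ (alle * self.freqs[:, None])
        # genotype = sum of two iid haplotype draws
        return 2.0 * (second - np.outer(p, p))

    def genotype_corr(self) -> np.ndarray:
        cov = self.genotype_cov()
        sd = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        return corr


def random_haplotype_spec(
    n_snps: int,
    seed: int | np.random.Generator,
    *,
    alpha: float = 1.0,
    min_maf: float | None = None,
    max_r2: float | None = None,
    max_tries: int = 10_000,
) -> HaplotypeSpec:
    """Dirichlet-random haplotype frequencies summing to 1.

    ``alpha`` is the (flat) Dirichlet concentration: 1 gives uniform random
    frequency vectors, values below 1 concentrate mass on few haplotypes and
    hence raise typical pairwise LD.  Optional rejection constraints keep
    every implied minor-allele frequency at or above ``min_maf`` and every
    implied pairwise genotype r² at or below ``max_r2``.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    for _ in range(max_tries):
        freqs = rng.dirichlet(np.full(2**n_snps, alpha))
        spec = HaplotypeSpec(n_snps=n_snps, freqs=freqs)
        p = spec.allele_freqs()
        if min_maf is not None and np.any(np.minimum(p, 1 - p) < min_maf):
            continue
        if max_r2 is not None:
            corr = spec.genotype_corr() ** 2
            np.fill_diagonal(corr, 0.0)
            if corr.max() > max_r2:
                continue
        return spec
    raise RuntimeError("could not draw a haplotype spec under the constraints")


def ld_to_haplotype_freqs(
    maf: np.ndarray,
    d2: float | np.ndarray,
    d3: float | None = None,
) -> np.ndarray:
    """Haplotype frequencies from MAFs plus pairwise D (and D_ABC for 3 loci).

    Uses the Bennett-style decomposition with D defined with respect to the
    minor alleles (D_AB = f(minor, minor) - p_A p_B).  For a haplotype with
    sign e_j = +1 when it carries the minor allele at locus j and -1
    otherwise, and marginal factor P_j = p_j or 1 - p_j accordingly:

        2 loci:  f = P_A P_B + e_A e_B D_AB
        3 loci:  f = P_A P_B P_C + P_A e_B e_C D_BC + P_B e_A e_C D_AC
                     + P_C e_A e_B D_AB + e_A e_B e_C D_ABC

    Any parameter set implying a frequency outside [0, 1] is rejected with a
    range error naming the offending haplotype.
    """
    p = np.atleast_1d(np.asarray(maf, dtype=float))
    m = p.shape[0]
    if m not in (2, 3):
        raise ValueError("LD parameterization supports 2 or 3 loci")
    if np.any((p <= 0) | (p > 0.5)):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    if m == 2:
        d_ab = float(np.atleast_1d(np.asarray(d2, dtype=float))[0])
        pair_d = {(0, 1): d_ab}
        if d3 is not None:
            raise ValueError("d3 applies to 3 loci only")
        d_abc = 0.0
    else:
        d2 = np.asarray(d2, dtype=float)
        if d2.shape == (3, 3):
            d2 = np.array([d2[0, 1], d2[0, 2], d2[1, 2]])
        if d2.shape != (3,):
            raise ValueError("3 loci need D_AB, D_AC, D_BC")
        pair_d = {(0, 1): d2[0], (0, 2): d2[1], (1, 2): d2[2]}
        d_abc = float(d3) if d3 is not None else 0.0

    freqs = np.empty(2**m)
    for h in range(2**m):
        carries = [(h >> j) & 1 for j in range(m)]
        e = np.where(carries, 1.0, -1.0)
        marg = np.where(carries, p, 1.0 - p)
        f = float(np.prod(marg))
        for (i, j), d in pair_d.items():
            others = [k for k in range(m) if k not in (i, j)]
            f += float(np.prod(marg[others])) * e[i] * e[j] * d
        if m == 3:
            f += e[0] * e[1] * e[2] * d_abc
        if f < -1e-12 or f > 1 + 1e-12:
            alleles = "".join("m" if c else "M" for c in carries)
            raise ValueError(
                f"infeasible LD parameters: haplotype {alleles} "
                f"(minor=m) has frequency {f:.6f}"
            )
        freqs[h] = min(max(f, 0.0), 1.0)
    return freqs


def haplotype_freqs_to_ld(
    freqs: np.ndarray,
) -> tuple[np.ndarray, dict[tuple[int, int], float], float | None]:
    """Recover MAFs, pairwise D and (3 loci) D_ABC from haplotype frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    m = int(np.log2(freqs.shape[0]))
    alle = _haplotype_alleles(m)
    p = alle.T @ freqs
    pair_d = {}
    for i, j in itertools.combinations(range(m), 2):
        f_both = float(freqs @ (alle[:, i] * alle[:, j]))
        pair_d[(i, j)] = f_both - p[i] * p[j]
    d_abc = None
    if m == 3:
        f_all = float(freqs @ (alle[:, 0] * alle[:, 1] * alle[:, 2]))
        d_abc = (
            f_all
            - p[0] * pair_d[(1, 2)]
            - p[1] * pair_d[(0, 2)]
            - p[2] * pair_d[(0, 1)]
            - p[0] * p[1] * p[2]
        )
    return p, pair_d, d_abc


@dataclass
class SimulationSpec:
    """One simulated population: haplotype block(s) + effect structure.

    ``haplotypes`` may be a single :class:`HaplotypeSpec` or a list of
    independent blocks; ``causal_idx`` indexes SNPs in the concatenated
    order.  ``effects`` are additive genotypic values *a* (expression units
    per minor allele); ``noise_sd`` the residual standard deviation.
    """

    haplotypes: HaplotypeSpec | list[HaplotypeSpec]
    causal_idx: list[int]
    effects: list[float]
    noise_sd: float = 1.0
    n_individuals: int = 1000
    n_replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if len(self.causal_idx) != len(self.effects):
            raise ValueError("one effect per causal SNP")
        n_snps = sum(b.n_snps for b in self.blocks)
        if any(not 0 <= i < n_snps for i in self.causal_idx):
            raise ValueError("causal_idx out of range")

    @property
    def blocks(self) -> list[HaplotypeSpec]:
        h = self.haplotypes
        return list(h) if isinstance(h, (list, tuple)) else [h]

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)


@dataclass
class GroundTruth:
    """What the generator knows that an analyst would not."""

    causal_ids: list[str]
    effects: list[float]
    noise_sd: float
    block_labels: list[int]
    haplotype_counts: list[np.ndarray]
    haplotypes: np.ndarray = field(repr=False)  # (n, 2, n_snps) minor-allele


def _snp_table(n_snps: int, block_labels: list[int]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:03d}" for j in range(n_snps)],
            "chrom": "1",
            "pos": 1000 * (np.arange(n_snps) + 1),
            "ref": "A",
            "alt": "T",
            "minor_allele": "T",
        }
    )


def simulate_dataset(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ROIDataset, GroundTruth]:
    """Draw one population: HWE genotypes + additive expression + noise.

    Per individual, two haplotypes are drawn independently from each block's
    frequency vector; per-SNP genotype is the minor-allele count.
    Expression is ``sum_j a_j g_j + Normal(0, noise_sd)``.  Monomorphic
    realized SNPs (possible at small n) trigger a warning downstream, not a
    redraw, so replicate streams stay aligned.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    geno_parts, hap_parts, counts, labels = [], [], [], []
    for b, block in enumerate(spec.blocks):
        alle = _haplotype_alleles(block.n_snps)
        draws = rng.choice(len(block.freqs), size=(n, 2), p=block.freqs)
        hap = alle[draws]  # (n, 2, block_snps)
        geno_parts.append(hap.sum(axis=1))
        hap_parts.append(hap)
        counts.append(np.bincount(draws.ravel(), minlength=len(block.freqs)))
        labels.extend([b] * block.n_snps)
    geno = np.concatenate(geno_parts, axis=1)
    haps = np.concatenate(hap_parts, axis=2)
    expr = np.zeros(n)
    for idx, a in zip(spec.causal_idx, spec.effects):
        expr += a * geno[:, idx]
    if spec.noise_sd > 0:
        expr += rng.normal(0.0, spec.noise_sd, size=n)
    snps = _snp_table(spec.n_snps, labels)
    dataset = ROIDataset(
        sample_ids=[f"s{i + 1:04d}" for i in range(n)],
        snps=snps,
        genotypes=geno,
        expression=expr,
        assembled=True,
    )
    truth = GroundTruth(
        causal_ids=[snps["snp_id"][i] for i in spec.causal_idx],
        effects=list(spec.effects),
        noise_sd=spec.noise_sd,
        block_labels=labels,
        haplotype_counts=counts,
        haplotypes=haps,
    )
    return dataset, truth


def effects_for_target_r2(
    genotype_vars: np.ndarray,
    target_r2: np.ndarray,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Additive effects giving designed population R² for independent causals.

    For mutually unlinked causal SNPs with genotype variances v_j, solving
    ``a_j² v_j = R_j · Var(Y)`` with ``Var(Y) = noise_sd² / (1 - sum R)``
    yields the effect sizes that realize per-SNP population coefficients of
    determination ``R_j``.
    """
    v = np.atleast_1d(np.asarray(genotype_vars, dtype=float))
    r2 = np.atleast_1d(np.asarray(target_r2, dtype=float))
    total = r2.sum()
    if total >= 1.0:
        raise ValueError("target R² values must sum to < 1")
    var_y = noise_sd**2 / (1.0 - total)
    return np.sqrt(r2 * var_y / v)


def validation_experiment(
    n_regulatory: int,
    n_datasets: int,
    *,
    n_individuals: int = 1000,
    noise_sd: float = 1.0,
    effect_range: tuple[float, float] = (0.8, 2.0),
    alpha: float = 0.3,
    seed: int | np.random.Generator = 0,
    ld_parameterized: bool = False,
) -> pd.DataFrame:
    """Estimated vs predicted R²_A over many simulated populations.

    Each replicate simulates one non-regulatory SNP (SNP_A) jointly with
    ``n_regulatory`` regulatory variants from a random haplotype
    distribution (Dirichlet by default; with ``ld_parameterized`` and 2-3
    total loci, from a random feasible MAF/D/D_ABC parameter set instead),
    assigns expression additively with Gaussian noise, then compares the
    single-variable regression R² of SNP_A against the value predicted from
    the constraint matrix equations using the same sample's correlations.
    Draws whose sample iSNP correlation matrix is degenerate are skipped.

    Defaults emulate strong cis-eQTL architectures: additive genotypic
    values drawn uniformly from ``effect_range`` (expression units per
    minor allele) against unit residual noise, and a sparse Dirichlet
    (``alpha`` < 1) over haplotypes so pairwise r² LD — and hence the true
    R²_A — spans a wide range instead of piling up near zero.

    Returns a DataFrame with columns ``estimated`` and ``predicted``, one
    row per retained replicate.
    """
    from . import corrmath

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_snps = n_regulatory + 1  # SNP_A occupies index 0
    rows = []
    while len(rows) < n_datasets:
        if ld_parameterized and n_snps in (2, 3):
            block = _random_ld_parameterized_spec(n_snps, rng)
        else:
            block = random_haplotype_spec(
                n_snps, rng, alpha=alpha, min_maf=0.05, max_r2=0.95
            )
        effects = list(rng.uniform(*effect_range, size=n_regulatory))
        spec = SimulationSpec(
            haplotypes=block,
            causal_idx=list(range(1, n_snps)),
            effects=effects,
            noise_sd=noise_sd,
            n_individuals=n_individuals,
        )
        dataset, _ = simulate_dataset(spec, rng)
        g = dataset.genotypes
        if np.any(g.std(axis=0) == 0):
            continue
        full = np.corrcoef(np.column_stack([dataset.expression, g]), rowvar=False)
        c_vec = full[0, 2:]
        r_mat = full[2:, 2:]
        a_vec = full[1, 2:]
        est = full[0, 1] ** 2
        try:
            bundle = corrmath.CorrelationBundle(c_vec, r_mat, a_vec)
            pred = corrmath.predict_r2_general(bundle)
        except corrmath.CollinearityError:
            continue
        rows.append((est, pred))
    return pd.DataFrame(rows, columns=["estimated", "predicted"])


def _random_ld_parameterized_spec(
    n_snps: int, rng: np.random.Generator, max_tries: int = 10_000
) -> HaplotypeSpec:
    """Random feasible MAF/D(/D_ABC) parameter set -> haplotype spec."""
    for _ in range(max_tries):
        p = rng.uniform(0.1, 0.5, size=n_snps)
        bound = np.array(
            [
                min(p[i] * (1 - p[j]), p[j] * (1 - p[i]))
                for i, j in itertools.combinations(range(n_snps), 2)
            ]
        )
        d2 = rng.uniform(-1.0, 1.0, size=bound.shape[0]) * bound
        d3 = float(rng.uniform(-0.02, 0.02)) if n_snps == 3 else None
        try:
            freqs = ld_to_haplotype_freqs(
                p, d2 if n_snps == 3 else d2[0], d3
            )
        except ValueError:
            continue
        spec = HaplotypeSpec(n_snps=n_snps, freqs=freqs / freqs.sum())
        corr2 = spec.genotype_corr() ** 2
        np.fill_diagonal(corr2, 0.0)
        if corr2.max() > 0.95:
            continue
        return spec
    raise RuntimeError("no feasible LD parameter set found")


def simulate_roi(
    n_blocks: int,
    block_size: int,
    causal: dict[int, float],
    *,
    noise_sd: float = 1.0,
    n_individuals: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.6,
    min_maf: float = 0.05,
) -> tuple[ROIDataset, GroundTruth]:
    """A multi-block ROI with designed per-causal population R² values.

    ``causal`` maps a SNP index (in concatenated order) to its target
    population coefficient of determination; each causal SNP should live in
    a distinct block so the designed values are exact (cross-block LD is
    zero).  Blocks are independent Dirichlet draws with a minimum implied
    MAF, emulating a region of semi-independent LD blocks.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    blocks = [
        random_haplotype_spec(
            block_size, rng, alpha=alpha, min_maf=min_maf, max_r2=0.995
        )
        for _ in range(n_blocks)
    ]
    causal_idx = sorted(causal)
    gvars = []
    for idx in causal_idx:
        block, offset = divmod(idx, block_size)
        gvars.append(blocks[block].genotype_cov()[offset, offset])
    effects = effects_for_target_r2(
        np.array(gvars), np.array([causal[i] for i in causal_idx]), noise_sd
    )
    spec = SimulationSpec(
        haplotypes=blocks,
        causal_idx=causal_idx,
        effects=list(effects),
        noise_sd=noise_sd,
        n_individuals=n_individuals,
    )
    return simulate_dataset(spec, rng)
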