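"""Matrix-equation machinery for multiple coefficients of determination.

The central quantity is the multiple coefficient of determination of an
outcome (mRNA expression) on a set of predictor genotypes,

    R2_M = C^T R^{-1} C,

where ``C`` holds the signed Pearson correlations between the outcome and
each predictor and ``R`` is the predictor correlation matrix.  For a
non-regulatory SNP (conventionally "SNP_A") that merely sits in linkage
disequilibrium with a set of index SNPs (iSNPs), the constraint that adding
SNP_A to the predictor set must not raise R2_M (R2_AB = R2_B,
R2_ABC = R2_BC, ...) pins down its coefficient of determination in closed
form.  Writing the (p+1)x(p+1) correlation matrix of [SNP_A, iSNP_1..iSNP_p]
as M, with first-row adjugate entries b_11, b_12, ..., the predicted value is

    R2_A = (sum_k r_{Y,iSNP_k} * b_{1,k+1})^2 / b_11^2,

the square of the unique root r_YA = -beta/(2*alpha) of the constraint
quadratic (its discriminant vanishes under the constraint, so the root is
unique).  ``predict_r2_general`` implements this for 1-4 iSNPs;
``predict_r2_closed_form`` evaluates the explicit printed 1- and 2-iSNP
formulas as an independent cross-check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CollinearityError",
    "NonPSDWarning",
    "CorrelationBundle",
    "adjugate",
    "multiple_r2",
    "predict_r2_general",
    "predict_r2_profile",
    "predict_r2_closed_form",
    "constrained_r_y",
    "count_expansion_terms",
]

#: Reciprocal-condition threshold below which an iSNP correlation matrix is
#: treated as degenerate (near-perfect LD between two iSNPs).
RCOND_THRESHOLD = 1e-10

#: |det| threshold (relative to matrix scale) below which the iSNP block is
#: treated as exactly collinear.
DET_THRESHOLD = 1e-12


class CollinearityError(ValueError):
    """Raised when an iSNP set is (near-)collinear, i.e. degenerate LD."""


class NonPSDWarning(UserWarning):
    """A predicted R2 exceeded 1: the correlation configuration is not PSD."""


def _worst_pair(r_mat: np.ndarray) -> tuple[int, int, float]:
    """Off-diagonal entry with the largest |r| — the usual degeneracy culprit."""
    m = np.abs(np.asarray(r_mat, dtype=float).copy())
    np.fill_diagonal(m, 0.0)
    i, j = np.unravel_index(np.argmax(m), m.shape)
    return int(i), int(j), float(r_mat[i, j])


def adjugate(m: np.ndarray) -> np.ndarray:
    """Adjugate (transpose of the cofactor matrix) of a square matrix.

    Defined for singular matrices as well; satisfies
    ``m @ adjugate(m) == det(m) * I``.  Intended for the small (<= 5 x 5)
    correlation matrices this method works with.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("adjugate requires a square matrix")
    n = m.shape[0]
    if n == 1:
        return np.array([[1.0]])
    cof = np.empty((n, n))
    rows = np.arange(n)
    for i in range(n):
        for j in range(n):
            minor = m[np.ix_(rows != i, rows != j)]
            cof[i, j] = (-1.0) ** (i + j) * np.linalg.det(minor)
    return cof.T


def multiple_r2(
    c_vec: np.ndarray,
    r_mat: np.ndarray,
    *,
    rcond_threshold: float = RCOND_THRESHOLD,
) -> float:
    """Multiple coefficient of determination ``C^T R^{-1} C``.

    Parameters
    ----------
    c_vec
        Signed Pearson correlations between the outcome and each predictor.
    r_mat
        Symmetric predictor correlation matrix with unit diagonal.
    rcond_threshold
        Reject ``r_mat`` whose reciprocal condition number falls below this,
        naming the worst-correlated predictor pair.
    """
    c = np.atleast_1d(np.asarray(c_vec, dtype=float))
    r = np.atleast_2d(np.asarray(r_mat, dtype=float))
    if r.shape[0] != r.shape[1] or c.shape[0] != r.shape[0]:
        raise ValueError("c_vec length must match the dimension of r_mat")
    if r.shape[0] > 1:
        # singular values give the reciprocal condition number robustly
        sv = np.linalg.svd(r, compute_uv=False)
        rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
        if rcond < rcond_threshold:
            i, j, rij = _worst_pair(r)
            raise CollinearityError(
                "degenerate LD among iSNPs: correlation matrix is "
                f"near-singular (rcond={rcond:.2e}); worst pair "
                f"({i}, {j}) with r={rij:+.6f}"
            )
    return float(c @ np.linalg.solve(r, c))


@dataclass
class CorrelationBundle:
    """Correlation inputs for predicting one target SNP's R2 from p iSNPs.

    Attributes
    ----------
    c_vec : array, shape (p,)
        Signed correlations between expression and each iSNP genotype
        (r_YB, r_YC, ...).
    r_mat : array, shape (p, p)
        Pairwise signed correlations among iSNP genotypes (unit diagonal).
    a_vec : array, shape (p,)
        Signed correlations between the target SNP's genotype and each
        iSNP genotype (r_AB, r_AC, ...).
    """

    c_vec: np.ndarray
    r_mat: np.ndarray
    a_vec: np.ndarray

    def __post_init__(self) -> None:
        self.c_vec = np.atleast_1d(np.asarray(self.c_vec, dtype=float))
        self.r_mat = np.atleast_2d(np.asarray(self.r_mat, dtype=float))
        self.a_vec = np.atleast_1d(np.asarray(self.a_vec, dtype=float))
        p = self.r_mat.shape[0]
        if self.r_mat.shape != (p, p):
            raise ValueError("r_mat must be square")
        if self.c_vec.shape != (p,) or self.a_vec.shape != (p,):
            raise ValueError("c_vec and a_vec must match r_mat dimension")
        if not np.allclose(self.r_mat, self.r_mat.T, atol=1e-8):
            raise ValueError("r_mat must be symmetric")
        if not np.allclose(np.diag(self.r_mat), 1.0, atol=1e-8):
            raise ValueError("r_mat must have unit diagonal")
        for name, v in (("c_vec", self.c_vec), ("a_vec", self.a_vec),
                        ("r_mat", self.r_mat)):
            if np.any(np.abs(v) > 1.0 + 1e-8):
                raise ValueError(f"{name} contains entries outside [-1, 1]")

    @property
    def p(self) -> int:
        return self.r_mat.shape[0]

    def augmented(self) -> np.ndarray:
        """(p+1)x(p+1) correlation matrix of [SNP_A, iSNP_1..iSNP_p]."""
        p = self.p
        m = np.empty((p + 1, p + 1))
        m[0, 0] = 1.0
        m[0, 1:] = self.a_vec
        m[1:, 0] = self.a_vec
        m[1:, 1:] = self.r_mat
        return m


def _first_adjugate_row(bundle: CorrelationBundle) -> np.ndarray:
    """First row (b_11, b_12, ..., b_1,p+1) of the augmented adjugate."""
    return adjugate(bundle.augmented())[0]


def constrained_r_y(bundle: CorrelationBundle) -> float:
    """Signed correlation r_YA implied by the constraint equations.

    Returns the unique quadratic root -beta/(2*alpha) =
    -(sum_k c_k b_{1,k+1}) / b_11: the value of r_YA at which adding the
    target SNP to the iSNP set leaves R2_M unchanged.
    """
    b = _first_adjugate_row(bundle)
    if abs(b[0]) < DET_THRESHOLD * max(1.0, float(np.abs(b).max())):
        i, j, rij = _worst_pair(bundle.r_mat)
        raise CollinearityError(
            f"collinear iSNP set: b_11 (det of iSNP block) ~ 0; worst pair "
            f"({i}, {j}) with r={rij:+.6f}"
        )
    return float(-(bundle.c_vec @ b[1:]) / b[0])


def predict_r2_general(bundle: CorrelationBundle) -> float:
    """Predicted R2 for the target SNP under the constraint equations.

    Builds the augmented correlation matrix with the target SNP in
    row/column 1, takes its adjugate, and returns
    ``(sum_k c_k b_{1,k+1})^2 / b_11^2``.  Supports 1-4 iSNPs.  A result
    above 1 signals a non-positive-semidefinite correlation configuration
    and is returned as-is with a :class:`NonPSDWarning`.
    """
    if not 1 <= bundle.p <= 4:
        raise ValueError("predict_r2_general supports 1 to 4 iSNPs")
    b = _first_adjugate_row(bundle)
    if abs(b[0]) < DET_THRESHOLD * max(1.0, float(np.abs(b).max())):
        i, j, rij = _worst_pair(bundle.r_mat)
        raise CollinearityError(
            f"collinear iSNP set: b_11 (det of iSNP block) ~ 0; worst pair "
            f"({i}, {j}) with r={rij:+.6f}"
        )
    r2 = float((bundle.c_vec @ b[1:]) ** 2 / b[0] ** 2)
    if r2 > 1.0:
        warnings.warn(
            f"predicted R2 = {r2:.6f} > 1: correlation configuration is not "
            "positive semidefinite",
            NonPSDWarning,
            stacklevel=2,
        )
    return r2


def predict_r2_profile(
    c_vec: np.ndarray, r_mat: np.ndarray, a_mat: np.ndarray
) -> np.ndarray:
    """Predicted R2 for many target SNPs against one iSNP set, vectorized.

    ``a_mat`` has one row per target SNP (its correlations with the p
    iSNPs).  Uses the identity that the first adjugate row of the augmented
    matrix is linear in the target column: b_{1,k+1} = -(adj(R) a)_k and
    b_11 = det(R), so each prediction equals ``(a^T adj(R) c)^2 / det(R)^2``
    — exactly the per-target augmented-adjugate computation, done in one
    matrix product.
    """
    c = np.atleast_1d(np.asarray(c_vec, dtype=float))
    r = np.atleast_2d(np.asarray(r_mat, dtype=float))
    a = np.atleast_2d(np.asarray(a_mat, dtype=float))
    det = float(np.linalg.det(r))
    adj = adjugate(r)
    if abs(det) < DET_THRESHOLD * max(1.0, float(np.abs(adj).max())):
        i, j, rij = _worst_pair(r)
        raise CollinearityError(
            f"collinear iSNP set: det of iSNP block ~ 0; worst pair "
            f"({i}, {j}) with r={rij:+.6f}"
        )
    s = a @ adj @ c
    return (s / det) ** 2


def predict_r2_closed_form(bundle: CorrelationBundle) -> float:
    """Explicit 1- and 2-iSNP closed forms; cross-check of the general path.

    1 iSNP:  R2_A = R2_B * r2_AB
    2 iSNPs: R2_A = [R_B (r_AB - r_BC r_AC) + R_C (r_AC - r_AB r_BC)]^2
                    / (1 - r_BC^2)^2
    """
    c, a = bundle.c_vec, bundle.a_vec
    if bundle.p == 1:
        return float(c[0] ** 2 * a[0] ** 2)
    if bundle.p == 2:
        r_bc = float(bundle.r_mat[0, 1])
        if abs(abs(r_bc) - 1.0) < 1e-12:
            raise CollinearityError(
                f"collinear iSNP pair: |r_BC| = {abs(r_bc):.6f}"
            )
        num = (
            c[0] * (a[0] - r_bc * a[1]) + c[1] * (a[1] - a[0] * r_bc)
        ) ** 2
        return float(num / (1.0 - r_bc**2) ** 2)
    raise ValueError("closed forms are printed for 1 and 2 iSNPs only")


def _leibniz_terms(entries: list[list[object]]) -> list[object]:
    """All signed permutation products of a symbolic matrix, uncollected."""
    n = len(entries)
    terms = []
    for perm in itertools.permutations(range(n)):
        sign = _perm_sign(perm)
        prod = sign
        for i, j in enumerate(perm):
            prod = prod * entries[i][j]
        if prod != 0:
            terms.append(prod)
    return terms


def _perm_sign(perm: tuple[int, ...]) -> int:
    inversions = sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )
    return -1 if inversions % 2 else 1


def count_expansion_terms(p: int) -> int:
    """Number of additive terms in the fully distributed R2_A numerator.

    For p iSNPs the numerator is ``(sum_k R_k b_{1,k+1})^2`` with each
    adjugate entry written out as its cofactor determinant.  Expanding every
    determinant by the Leibniz permutation sum and distributing the square
    fully, WITHOUT collecting like terms, gives the term count — e.g. 16 for
    the 3-SNP system (p=2) and 324 for the 4-SNP system (p=3).  Exists for
    verification; the numeric code never expands these polynomials.
    """
    if p not in (1, 2, 3):
        raise ValueError("term counting is supported for 1-3 iSNPs")
    import sympy

    n = p + 1  # augmented system size including the target SNP
    labels = "ABCDE"[:n]
    sym = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                sym[i, j] = sympy.Integer(1)
            else:
                a, b = sorted((labels[i], labels[j]))
                sym[i, j] = sympy.Symbol(f"r_{a}{b}")
    total = 0
    for k in range(1, n):  # cofactor b_{1,k+1}: delete row 0, column k
        rows = [r for r in range(n) if r != 0]
        cols = [c for c in range(n) if c != k]
        minor = [[sym[r, c] for c in cols] for r in rows]
        terms = _leibniz_terms(minor)
        total += len(terms)
    return total**2


def random_psd_bundle(
    p: int,
    rng: np.random.Generator,
    *,
    max_abs_r: float = 0.98,
) -> tuple[CorrelationBundle, np.ndarray]:
    """Draw a random valid joint correlation structure for [Y, A, iSNPs].

    Samples a full (p+2)-dimensional positive-definite correlation matrix
    from a random Gram construction and slices out the bundle pieces plus
    the actual r_YA (returned separately; the constraint equations replace
    it).  Rejects draws with near-collinear predictors.
    """
    m = p + 2  # Y, A, p iSNPs
    while True:
        g = rng.normal(size=(m, m + 2))
        s = g @ g.T
        d = np.sqrt(np.diag(s))
        corr = s / np.outer(d, d)
        off = corr[~np.eye(m, dtype=bool)]
        if np.abs(off).max() > max_abs_r:
            continue
        sv = np.linalg.svd(corr, compute_uv=False)
        if sv[-1] / sv[0] < 1e-6:
            continue
        bundle = CorrelationBundle(
            c_vec=corr[0, 2:], r_mat=corr[2:, 2:], a_vec=corr[1, 2:]
        )
        return bundle, corr
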