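"""Gram-matrix construction for genomic-prediction kernels.

A kernel k(x, y) measures genetic similarity between two accessions from
their SNP dosage vectors.  The n x n Gram matrix K = [k(X_i, X_j)] is the
covariance structure of the genetic values in the kernel mixed model
(see :mod:`kernelgp.mixed_model`).  Supported families:

========== =====================================  ==========================
family     k(x, y)                                hyperparameters
========== =====================================  ==========================
linear     <x, y>                                 none
polynomial (<x, y> + c)^d                         offset c >= 0, degree d
gaussian   exp(-h * ||x - y||_2^2)                rate of decay h > 0
laplacian  exp(-h * ||x - y||_1)                  rate of decay h > 0
anova      (sum_j exp(-h (x_j - y_j)^2))^d        rate of decay h, degree d
========== =====================================  ==========================

The linear kernel gives GBLUP; the polynomial kernel with c = 0, d = 2 is
the quadratic kernel whose feature space contains all pairwise marker
interactions; the Gaussian kernel is universal and implicitly models all
interaction orders.  Every valid kernel yields a positive semi-definite
Gram matrix (Mercer's condition), which :func:`check_psd` verifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GenotypeMatrix",
    "KernelSpec",
    "GramMatrix",
    "FeatureMap",
    "gram_matrix",
    "cross_gram",
    "quadratic_feature_map",
    "check_psd",
]

KERNEL_FAMILIES = ("linear", "polynomial", "gaussian", "laplacian", "anova")

#: markers processed per block when the ANOVA kernel accumulates its sum
_ANOVA_BLOCK = 256


class KernelError(ValueError):
    """Invalid kernel specification or incompatible inputs."""


@dataclass
class GenotypeMatrix:
    """n accessions x p markers dosage matrix.

    Dosages count copies of the alternate allele (0, 1 or 2 for a diploid).
    ``coding`` records whether columns are raw counts or have been centered;
    centering constants always come from a training set so that new
    accessions can be placed on the same scale (``center_means`` holds them
    when the matrix was centered with external means).
    """

    values: np.ndarray
    coding: str = "raw_012"
    accession_ids: list[str] | None = None
    marker_ids: list[str] | None = None
    center_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise KernelError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise KernelError(f"need n >= 2 accessions and p >= 1 markers, got {n} x {p}")
        if not np.all(np.isfinite(self.values)):
            raise KernelError("genotype matrix contains missing or non-finite entries; "
                              "impute before constructing a GenotypeMatrix")
        if self.coding == "raw_012":
            if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
                raise KernelError("raw_012 coding requires dosages in {0, 1, 2}")
        elif self.coding == "centered":
            if self.center_means is None:
                col_means = self.values.mean(axis=0)
                if np.abs(col_means).max() >= 1e-10:
                    raise KernelError("centered coding requires zero column means "
                                      "(or explicit center_means from a training set)")
        else:
            raise KernelError(f"unknown coding {self.coding!r}")
        if self.accession_ids is None:
            self.accession_ids = [f"acc{i}" for i in range(n)]
        if self.marker_ids is None:
            self.marker_ids = [f"m{j}" for j in range(p)]
        if len(self.accession_ids) != n:
            raise KernelError("accession_ids length does not match row count")
        if len(self.marker_ids) != p:
            raise KernelError("marker_ids length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def centered(self, means: np.ndarray | None = None) -> "GenotypeMatrix":
        """Center columns, by own column means or by training-set ``means``."""
        if self.coding == "centered" and means is None:
            return self
        m = self.column_means() if means is None else np.asarray(means, dtype=float)
        if m.shape != (self.p,):
            raise KernelError("centering means length does not match marker count")
        return GenotypeMatrix(
            self.values - m,
            coding="centered",
            accession_ids=list(self.accession_ids),
            marker_ids=list(self.marker_ids),
            center_means=None if means is None else m,
        )

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency (raw_012 coding only)."""
        if self.coding != "raw_012":
            raise KernelError("MAF is defined on raw dosage coding")
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters.

    ``decay_h`` is the rate of decay of the gaussian/laplacian/anova
    kernels: similarity between two accessions decreases with genotype
    distance at rate h.  ``degree_d`` and ``offset_c`` parameterize the
    polynomial kernel (<x,y> + c)^d; d = 2, c = 0 is the quadratic kernel.
    """

    family: str
    decay_h: float | None = None
    degree_d: int | None = None
    offset_c: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise KernelError(f"unknown kernel family {self.family!r}; "
                              f"choose one of {KERNEL_FAMILIES}")
        if self.family in ("gaussian", "laplacian", "anova"):
            if self.decay_h is None or not (self.decay_h > 0):
                raise KernelError(f"{self.family} kernel requires decay_h > 0")
        if self.family == "linear" and (
            self.decay_h is not None or self.degree_d is not None or self.offset_c != 0.0
        ):
            raise KernelError("linear kernel takes no hyperparameters")
        if self.family == "polynomial":
            d = 2 if self.degree_d is None else self.degree_d
            if d < 1 or int(d) != d:
                raise KernelError("polynomial degree_d must be a positive integer")
            if self.offset_c < 0:
                raise KernelError("polynomial offset_c must be non-negative")
        if self.family == "anova":
            d = 1 if self.degree_d is None else self.degree_d
            if d < 1 or int(d) != d:
                raise KernelError("anova degree_d must be a positive integer")

    @property
    def degree(self) -> int:
        """Effective degree (defaults: polynomial 2, anova 1)."""
        if self.degree_d is not None:
            return int(self.degree_d)
        return {"polynomial": 2, "anova": 1}.get(self.family, 1)


@dataclass
class GramMatrix:
    """Symmetric PSD matrix of pairwise kernel evaluations."""

    values: np.ndarray
    spec: KernelSpec
    accession_ids: list[str] | None = None
    min_eigenvalue: float = field(default=math.nan)
    jitter_applied: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise KernelError("Gram matrix must be square")
        asym = np.abs(K - K.T).max()
        if asym >= 1e-12 * max(1.0, np.abs(K).max()):
            raise KernelError(f"Gram matrix is not symmetric (max asymmetry {asym:.3g})")
        if math.isnan(self.min_eigenvalue):
            self.min_eigenvalue = float(np.linalg.eigvalsh(K)[0])
        scale = max(1.0, float(np.diag(K).max(initial=0.0)))
        if self.min_eigenvalue < -1e-8 * scale:
            raise KernelError(
                f"Gram matrix is not PSD: min eigenvalue {self.min_eigenvalue:.3g} "
                f"below tolerance for scale {scale:.3g}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_jitter(self) -> "GramMatrix":
        """Return a copy with delta * I added, delta = 1e-8 * mean(diag).

        Used when downstream linear algebra needs strict positive
        definiteness; the amount is recorded in ``jitter_applied`` so the
        perturbation is never silent.
        """
        delta = 1e-8 * float(np.diag(self.values).mean())
        return GramMatrix(
            self.values + delta * np.eye(self.n),
            spec=self.spec,
            accession_ids=self.accession_ids,
            min_eigenvalue=self.min_eigenvalue + delta,
            jitter_applied=self.jitter_applied + delta,
        )


@dataclass
class FeatureMap:
    """Explicit map phi(X) into a kernel's feature space (verification-scale)."""

    values: np.ndarray
    source_spec: KernelSpec
    column_labels: list[str] | None = None


def _as_values(X) -> np.ndarray:
    v = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(v)):
        raise KernelError("non-finite entries in genotype input")
    return v


def _kernel_block(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Raw kernel evaluations between rows of A (m x p) and B (n x p)."""
    if A.shape[1] != B.shape[1]:
        raise KernelError(
            f"marker-count mismatch: {A.shape[1]} vs {B.shape[1]} columns"
        )
    fam = spec.family
    if fam == "linear":
        return A @ B.T
    if fam == "polynomial":
        return (A @ B.T + spec.offset_c) ** spec.degree
    if fam == "gaussian":
        return np.exp(-spec.decay_h * cdist(A, B, metric="sqeuclidean"))
    if fam == "laplacian":
        return np.exp(-spec.decay_h * cdist(A, B, metric="cityblock"))
    if fam == "anova":
        # accumulate sum_j exp(-h (a_j - b_j)^2) in marker blocks to bound memory
        out = np.zeros((A.shape[0], B.shape[0]))
        h = spec.decay_h
        for start in range(0, A.shape[1], _ANOVA_BLOCK):
            a = A[:, start:start + _ANOVA_BLOCK]
            b = B[:, start:start + _ANOVA_BLOCK]
            diff = a[:, None, :] - b[None, :, :]
            out += np.exp(-h * diff**2).sum(axis=2)
        return out ** spec.degree
    raise KernelError(f"unknown kernel family {fam!r}")  # pragma: no cover


def gram_matrix(X, spec: KernelSpec, jitter: bool = False) -> GramMatrix:
    """Build the n x n Gram matrix K_ij = k(X_i, X_j).

    The gaussian and laplacian kernels have an exactly unit diagonal, which
    is enforced after the distance computation.  ``jitter`` adds
    delta * I with delta = 1e-8 * mean(diag) for downstream factorizations
    that need strict positive definiteness; the amount is recorded.
    """
    V = _as_values(X)
    K = _kernel_block(V, V, spec)
    K = (K + K.T) / 2.0
    if spec.family in ("gaussian", "laplacian"):
        np.fill_diagonal(K, 1.0)
    ids = list(X.accession_ids) if isinstance(X, GenotypeMatrix) else None
    g = GramMatrix(K, spec=spec, accession_ids=ids)
    return g.with_jitter() if jitter else g


def cross_gram(X_new, X_train, spec: KernelSpec) -> np.ndarray:
    """m x n block of kernel evaluations between new and training accessions.

    ``X_new`` must share the marker set with ``X_train`` and, when centered
    coding is used, must have been centered with the training column means;
    stacking [train; new] and calling :func:`gram_matrix` yields the same
    block.
    """
    A = _as_values(X_new)
    B = _as_values(X_train)
    return _kernel_block(A, B, spec)


def quadratic_feature_map(X, max_p: int = 50) -> FeatureMap:
    """Explicit feature map of the quadratic kernel (<x, y>)^2.

    Columns are the p squared terms x_j^2 followed by the p(p-1)/2 pairwise
    interaction terms sqrt(2) * x_j * x_k in lexicographic (j, k) order, so
    q = p(p+1)/2 in total and phi(X) phi(X)' equals the polynomial
    (d=2, c=0) Gram matrix.  Verification-scale only: the point of the
    kernel trick is that this expansion is never needed, so p is capped
    (use :func:`gram_matrix` with the polynomial kernel for real data).
    """
    V = _as_values(X)
    n, p = V.shape
    if p > max_p:
        raise KernelError(
            f"explicit quadratic expansion with p={p} markers would have "
            f"{p * (p + 1) // 2} columns; use gram_matrix(X, "
            f"KernelSpec('polynomial', degree_d=2)) instead"
        )
    squares = V**2
    ju, ku = np.triu_indices(p, k=1)
    pairs = math.sqrt(2.0) * V[:, ju] * V[:, ku]
    marker_ids = (list(X.marker_ids) if isinstance(X, GenotypeMatrix)
                  else [f"m{j}" for j in range(p)])
    labels = [f"{m}^2" for m in marker_ids]
    labels += [f"{marker_ids[j]}*{marker_ids[k]}" for j, k in zip(ju, ku)]
    spec = KernelSpec("polynomial", degree_d=2, offset_c=0.0)
    return FeatureMap(np.hstack([squares, pairs]), source_spec=spec, column_labels=labels)


def check_psd(K, tol: float = 1e-8) -> tuple[bool, float]:
    """Smallest eigenvalue test of Mercer's PSD condition.

    Returns ``(is_psd, min_eigenvalue)`` where ``is_psd`` is true iff the
    smallest eigenvalue is >= -tol * max(1, max diagonal).  Rejects
    asymmetric input.
    """
    M = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise KernelError("PSD check requires a square matrix")
    if np.abs(M - M.T).max() >= 1e-12 * max(1.0, np.abs(M).max()):
        raise KernelError("PSD check requires a symmetric matrix")
    min_eig = float(np.linalg.eigvalsh(M)[0])
    scale = max(1.0, float(np.diag(M).max(initial=0.0)))
    return bool(min_eig >= -tol * scale), min_eig
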