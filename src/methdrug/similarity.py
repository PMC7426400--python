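"""Kernel similarity matrices over cell lines and drugs.

Heterogeneous omics are made comparable by replacing each raw
features x samples matrix with a samples x samples similarity matrix:
binary mutation profiles through an exponentiated Hamming distance,
S(i,j) = exp(-HD(c_i, c_j)), and real-valued profiles (copy number,
expression, methylation beta, chemical descriptors) through an RBF kernel,
S(i,j) = exp(-alpha * ||c_i - c_j||^2).

Bandwidths. The conventional alphas are 1e-3 for copy number and drug
descriptors and 1e-4 for expression and methylation; these are calibrated
to genome-scale profiles (tens of thousands of features). On smaller
matrices a fixed alpha leaves every off-diagonal entry near 1, so
``alpha="median"`` applies the standard median heuristic
(alpha = 1 / median of pairwise squared distances). Likewise the raw
exponentiated Hamming distance underflows to exactly 0 for genome-scale
non-identical profiles (exponents below -746); a ``normalized`` mode
(exp(-scale * HD / len)) is provided, and underflow triggers a warning
rather than an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .io import Modality, OmicsMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "SimilarityMatrix",
    "DEFAULT_KERNELS",
    "hamming_kernel",
    "rbf_kernel",
    "build_similarity",
    "cross_similarity",
    "resolve_alpha",
    "load_similarity",
    "write_similarity",
]

#: exp(x) underflows to exactly 0.0 in IEEE double below this exponent
UNDERFLOW_EXPONENT = -746.0


@dataclass(frozen=True)
class KernelSpec:
    """How to turn profile columns into pairwise similarities.

    kind
        ``"hamming"`` (binary profiles) or ``"rbf"`` (real profiles).
    alpha
        RBF bandwidth; a number >= 0 or ``"median"`` for the median
        heuristic (resolved against the data at build time).
    normalized / scale
        Hamming options: when ``normalized``, the exponent is
        ``-scale * HD / len`` instead of the raw ``-HD``.
    """

    kind: str
    alpha: Union[float, str] = 0.0
    normalized: bool = False
    scale: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("hamming", "rbf"):
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        if isinstance(self.alpha, str):
            if self.alpha != "median":
                raise ValidationError(f"alpha must be a number or 'median', got {self.alpha!r}")
        elif self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")
        if self.scale < 0:
            raise ValidationError(f"scale must be >= 0, got {self.scale}")


#: Conventional kernel per modality (bandwidths as used on genome-scale data).
DEFAULT_KERNELS: dict[Modality, KernelSpec] = {
    Modality.MUTATION: KernelSpec("hamming"),
    Modality.COPY_NUMBER: KernelSpec("rbf", alpha=1e-3),
    Modality.EXPRESSION: KernelSpec("rbf", alpha=1e-4),
    Modality.METHYLATION: KernelSpec("rbf", alpha=1e-4),
    Modality.DESCRIPTOR: KernelSpec("rbf", alpha=1e-3),
}


@dataclass
class SimilarityMatrix:
    """Symmetric entity x entity kernel matrix with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    kernel_spec: KernelSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValidationError("similarity matrix diagonal must be 1")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValidationError("similarity entries must lie in [0,1]")

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.values[self.ids.index(entity_id)]
        except ValueError as exc:
            raise ValidationError(f"unknown entity ID {entity_id!r}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _check_binary(x: np.ndarray, what: str) -> None:
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValidationError(f"{what}: Hamming kernel requires binary entries")


def hamming_kernel(a, b, normalized: bool = False, scale: float = 100.0) -> float:
    """exp(-HD(a,b)) for binary vectors; normalized: exp(-scale*HD/len)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    _check_binary(a, "a")
    _check_binary(b, "b")
    hd = float(np.sum(a != b))
    exponent = -scale * hd / a.size if normalized else -hd
    _warn_underflow(exponent)
    return float(np.exp(exponent))


def rbf_kernel(a, b, alpha: float) -> float:
    """exp(-alpha * ||a-b||^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if alpha < 0:
        raise ValidationError(f"alpha must be >= 0, got {alpha}")
    d2 = float(np.sum((a - b) ** 2))
    exponent = -alpha * d2
    _warn_underflow(exponent)
    return float(np.exp(exponent))


def _warn_underflow(min_exponent: float) -> None:
    if min_exponent <= UNDERFLOW_EXPONENT:
        msg = (
            f"kernel exponent {min_exponent:.3g} underflows exp() to exactly 0; "
            "consider the normalized Hamming mode or a smaller alpha"
        )
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)


def _squared_distances(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between rows of X and rows of Y.

    Float cancellation in the Gram-matrix expansion can produce tiny
    negative values; those are clamped to 0 before exponentiation.
    """
    sq = (X * X).sum(axis=1)[:, None] + (Y * Y).sum(axis=1)[None, :] - 2.0 * X @ Y.T
    np.maximum(sq, 0.0, out=sq)
    return sq


def resolve_alpha(spec: KernelSpec, X: np.ndarray) -> KernelSpec:
    """Resolve ``alpha="median"`` against reference profiles (rows of X)."""
    if spec.kind != "rbf" or spec.alpha != "median":
        return spec
    d2 = _squared_distances(X, X)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(off)) if off.size else 0.0
    alpha = 1.0 / med if med > 0 else 1.0
    log.info("median-heuristic bandwidth: alpha = %.6g", alpha)
    return replace(spec, alpha=alpha)


def _entity_profiles(data) -> tuple[list[str], np.ndarray]:
    """Columns of an OmicsMatrix / DataFrame are the entities; rows of a
    descriptor table indexed by drug would be passed transposed by callers."""
    if isinstance(data, OmicsMatrix):
        return list(data.cell_ids), data.values.T.copy()
    if isinstance(data, pd.DataFrame):
        return [str(c) for c in data.columns], data.to_numpy(dtype=float).T
    raise ValidationError(f"cannot build similarity from {type(data).__name__}")


def build_similarity(data, spec: KernelSpec) -> SimilarityMatrix:
    """Apply the pairwise kernel over the columns (entities) of ``data``.

    Symmetric by construction; diagonal exactly 1.
    """
    ids, X = _entity_profiles(data)
    if len(ids) < 2:
        raise ValidationError("need at least 2 entities to build a similarity matrix")
    spec = resolve_alpha(spec, X)
    if spec.kind == "hamming":
        _check_binary(X, "profiles")
        hd = X @ (1.0 - X).T + (1.0 - X) @ X.T
        exponents = -spec.scale * hd / X.shape[1] if spec.normalized else -hd
    else:
        exponents = -float(spec.alpha) * _squared_distances(X, X)
    _warn_underflow(float(exponents.min()))
    S = np.exp(exponents)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids, S, spec)


def cross_similarity(query, reference, spec: KernelSpec) -> pd.DataFrame:
    """Kernel rows of query entities against reference entities.

    This is how held-out cohorts are featurized: each new cell line (or
    drug) gets a row of similarities to the *training* entities, keeping
    the feature length anchored to the training cohort. ``alpha="median"``
    is resolved on the reference profiles, matching
    :func:`build_similarity` on the same reference.
    """
    q_ids, Q = _entity_profiles(query)
    r_ids, R = _entity_profiles(reference)
    if Q.shape[1] != R.shape[1]:
        raise ValidationError(
            f"feature-length mismatch: query has {Q.shape[1]}, reference has {R.shape[1]}"
        )
    spec = resolve_alpha(spec, R)
    if spec.kind == "hamming":
        _check_binary(Q, "query")
        _check_binary(R, "reference")
        hd = Q @ (1.0 - R).T + (1.0 - Q) @ R.T
        exponents = -spec.scale * hd / Q.shape[1] if spec.normalized else -hd
    else:
        exponents = -float(spec.alpha) * _squared_distances(Q, R)
    _warn_underflow(float(exponents.min()))
    return pd.DataFrame(np.exp(exponents), index=q_ids, columns=r_ids)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(path, sep="\t")


def load_similarity(path: str | Path, spec: KernelSpec | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if spec is None:
        spec = KernelSpec("rbf", alpha=0.0)
    return SimilarityMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), spec)
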