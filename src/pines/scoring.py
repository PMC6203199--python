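"""Angle-based scoring in the decorrelated annotation space.

The background annotation matrix has mean vector μ and covariance Σ.
Σ is a noisy estimate of the true correlation structure, so scoring
uses the rank-k approximation Σ̂ = Σᵢ≤k λᵢuᵢuᵢᵀ from its spectral
decomposition (default k = 30), whose Moore–Penrose pseudo-inverse is
Σ̂⁺ = Σᵢ≤k λᵢ⁻¹uᵢuᵢᵀ.  With a diagonal weight matrix W (identity in
the unweighted analysis), a variant's annotation vector x projects to
the whitened coordinates

    zᵢ = λᵢ^(−1/2) · uᵢᵀ W (x − μ),   i = 1..k,

so that ‖z‖² = (x−μ)ᵀ W Σ̂⁺ W (x−μ): the reweighted Mahalanobis
distance to μ.  The score is the angle between z and the whitened
image of the all-1 vector 𝟙 (the maximal-annotation-load direction),
scaled by the two whitened lengths:

    score(x) = acos( cos∠(z, z_𝟙) ) / ( ‖z‖ · ‖z_𝟙‖ ).

Smaller scores indicate greater evidence of regulatory function; the
all-1 vector attains the global minimum 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pines.annotation_io import POOLED, AnnotationMatrix

DEFAULT_RANK = 30
EIGENVALUE_FLOOR_RATIO = 1e-10  # eigenvalues below this fraction of λ₁ are dropped
COSINE_CLIP_TOL = 1e-12
ZERO_LENGTH_TOL = 1e-12


class DegenerateModelError(ValueError):
    """Background covariance has no usable positive eigenvalues."""


class UndefinedAngleError(ValueError):
    """A whitened projection has zero length; the angle is undefined."""


@dataclass
class WeightVector:
    """Diagonal annotation weights W; all entries non-negative."""

    weights: np.ndarray
    source: str = "unweighted"  # unweighted | manual | enrichment

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if not np.all(self.weights >= 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.weights)


def unweighted(n_columns: int) -> WeightVector:
    return WeightVector(np.ones(n_columns), source="unweighted")


@dataclass
class BackgroundModel:
    """Per-class background mean and top-k eigenpairs of the covariance."""

    variant_class: str
    mu: np.ndarray  # (d,)
    eigenvalues: np.ndarray  # (k,) descending, strictly positive
    eigenvectors: np.ndarray  # (d, k) orthonormal columns
    variance_explained: float
    n_background: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        k = len(self.eigenvalues)
        if self.eigenvectors.shape != (len(self.mu), k):
            raise ValueError("eigenvector matrix must be d x k")
        if k == 0 or not np.all(self.eigenvalues > 0):
            raise DegenerateModelError("eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("eigenvectors not orthonormal to 1e-8")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_columns(self) -> int:
        return len(self.mu)


def _imputed_values(matrix: AnnotationMatrix | np.ndarray) -> np.ndarray:
    """Raw float matrix; NaNs imputed to the column mean (0 if all-NaN)."""
    X = matrix.values if isinstance(matrix, AnnotationMatrix) else np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        X = X.copy()
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(X, axis=0)
        col_means = np.nan_to_num(col_means)  # all-NaN column -> 0
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_means[nan_c]
    return X


def estimate_background_model(
    background: AnnotationMatrix | np.ndarray,
    variant_class: str = POOLED,
    k: int = DEFAULT_RANK,
    variance_target: float | None = None,
) -> BackgroundModel:
    """Estimate μ and the top-k eigenpairs of the background covariance.

    Missing entries are imputed to the column mean before covariance
    estimation.  Eigenvalues that are non-positive or below
    ``EIGENVALUE_FLOOR_RATIO``·λ₁ are dropped, reducing k.  If
    ``variance_target`` is given, k is instead the smallest rank whose
    eigenvalues account for that fraction of the total variance (capped
    at ``k``).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(background, AnnotationMatrix) and variant_class != POOLED:
        background = background.for_class(variant_class)
    X = _imputed_values(background)
    n, d = X.shape
    if n < 2:
        raise ValueError(f"need >= 2 background rows, got {n}")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(np.sum(np.clip(evals, 0.0, None)))
    if total <= 0 or evals[0] <= 0:
        raise DegenerateModelError("background covariance is zero (all-constant matrix)")
    keep = evals > EIGENVALUE_FLOOR_RATIO * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    if variance_target is not None:
        frac = np.cumsum(evals) / total
        k_eff = min(int(np.searchsorted(frac, variance_target) + 1), k, len(evals))
    else:
        k_eff = min(k, len(evals))
    evals, evecs = evals[:k_eff], evecs[:, :k_eff]
    return BackgroundModel(
        variant_class=variant_class,
        mu=mu,
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_explained=float(np.sum(evals) / total),
        n_background=n,
    )


def _as_weights(W: WeightVector | np.ndarray | None, d: int) -> np.ndarray:
    if W is None:
        return np.ones(d)
    w = W.weights if isinstance(W, WeightVector) else np.asarray(W, dtype=float)
    if w.shape != (d,):
        raise ValueError(f"weight vector length {w.shape} does not match {d} columns")
    return w


def _prepare_x(x: np.ndarray, model: BackgroundModel) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_columns:
        raise ValueError(f"annotation vector length {x.shape[-1]} != {model.n_columns} columns")
    if np.isnan(x).any():
        x = np.where(np.isnan(x), model.mu, x)  # missing -> background mean
    return x


def whiten(x: np.ndarray, model: BackgroundModel, W: WeightVector | np.ndarray | None = None) -> np.ndarray:
    """Whitened coordinates z with zᵢ = λᵢ^(−1/2)·uᵢᵀW(x−μ).

    Accepts a single annotation vector (returns shape (k,)) or a matrix
    of row vectors (returns shape (n, k)).  Missing entries are imputed
    to μ, contributing zero deviation.
    """
    x = _prepare_x(x, model)
    w = _as_weights(W, model.n_columns)
    dev = (x - model.mu) * w
    return (dev @ model.eigenvectors) / np.sqrt(model.eigenvalues)


def mahalanobis(x: np.ndarray, model: BackgroundModel, W: WeightVector | np.ndarray | None = None) -> float | np.ndarray:
    """Reweighted Mahalanobis length sqrt((x−μ)ᵀWΣ̂⁺W(x−μ))."""
    z = whiten(x, model, W)
    norm = np.linalg.norm(z, axis=-1)
    return float(norm) if norm.ndim == 0 else norm


def _ones_projection(model: BackgroundModel, w: np.ndarray) -> np.ndarray:
    ones = np.ones(model.n_columns)
    dev = (ones - model.mu) * w
    z1 = (dev @ model.eigenvectors) / np.sqrt(model.eigenvalues)
    if np.linalg.norm(z1) <= ZERO_LENGTH_TOL:
        raise UndefinedAngleError("all-1 vector has zero-length projection")
    return z1


def _snap_cosine(cos):
    """Absorb floating-point drift: values within 1e-12 of ±1 become exact.

    Parallel whitened vectors otherwise pick up an O(sqrt(eps)) angle
    from acos near its endpoints."""
    cos = np.clip(cos, -1.0, 1.0)
    return np.where(np.abs(cos) > 1.0 - COSINE_CLIP_TOL, np.sign(cos), cos)


def cosine_to_ones(x: np.ndarray, model: BackgroundModel, W: WeightVector | np.ndarray | None = None) -> float:
    """Cosine of the angle between the whitened x and the whitened 𝟙.

    Clipped to [−1, 1] to absorb floating-point drift before acos.
    """
    w = _as_weights(W, model.n_columns)
    z = whiten(x, model, w)
    if z.ndim != 1:
        raise ValueError("cosine_to_ones expects a single annotation vector")
    nz = np.linalg.norm(z)
    if nz <= ZERO_LENGTH_TOL:
        raise UndefinedAngleError("annotation vector has zero-length projection")
    z1 = _ones_projection(model, w)
    cos = float(z @ z1 / (nz * np.linalg.norm(z1)))
    return float(_snap_cosine(cos))


def pines_score(x: np.ndarray, model: BackgroundModel, W: WeightVector | np.ndarray | None = None) -> float:
    """Angle to the maximal-load direction scaled by the whitened lengths.

    score = acos(cos∠(z, z_𝟙)) / (‖z‖·‖z_𝟙‖); non-negative, and 0 iff
    the whitened x is a positive multiple of the whitened 𝟙.
    """
    w = _as_weights(W, model.n_columns)
    z = whiten(x, model, w)
    nz = np.linalg.norm(z)
    if nz <= ZERO_LENGTH_TOL:
        raise UndefinedAngleError("annotation vector has zero-length projection")
    z1 = _ones_projection(model, w)
    n1 = np.linalg.norm(z1)
    cos = float(_snap_cosine(float(z @ z1) / (nz * n1)))
    return float(np.arccos(cos) / (nz * n1))


def score_matrix(
    X: AnnotationMatrix | np.ndarray,
    model: BackgroundModel,
    W: WeightVector | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scores for a matrix of annotation row vectors.

    Returns ``(scores, undefined)``: variants whose whitened projection
    has zero length get score NaN and ``undefined=True`` (reported
    downstream with empirical p = 1 and a flag).
    """
    Xv = X.values if isinstance(X, AnnotationMatrix) else np.asarray(X, dtype=float)
    w = _as_weights(W, model.n_columns)
    Z = whiten(Xv, model, w)
    if Z.ndim == 1:
        Z = Z[None, :]
    norms = np.linalg.norm(Z, axis=1)
    z1 = _ones_projection(model, w)
    n1 = np.linalg.norm(z1)
    undefined = norms <= ZERO_LENGTH_TOL
    safe = np.where(undefined, 1.0, norms)
    cos = _snap_cosine((Z @ z1) / (safe * n1))
    scores = np.arccos(cos) / (safe * n1)
    scores[undefined] = np.nan
    return scores, undefined


# --- model persistence -----------------------------------------------------


def save_model(model: BackgroundModel, path, schema_hash: str | None = None) -> None:
    """Persist a background model as a single .npz archive."""
    np.savez_compressed(
        path,
        variant_class=np.array(model.variant_class),
        mu=model.mu,
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
        variance_explained=np.array(model.variance_explained),
        n_background=np.array(model.n_background),
        schema_hash=np.array(schema_hash or ""),
    )


def load_model(path) -> BackgroundModel:
    with np.load(path, allow_pickle=False) as z:
        return BackgroundModel(
            variant_class=str(z["variant_class"]),
            mu=z["mu"],
            eigenvalues=z["eigenvalues"],
            eigenvectors=z["eigenvectors"],
            variance_explained=float(z["variance_explained"]),
            n_background=int(z["n_background"]),
        )
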