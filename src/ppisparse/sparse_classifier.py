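"""Sparse representation classification (SRC) and its Gaussian-weighted
variant (WSRC).

A query vector y is encoded as a sparse linear combination of the training
columns by solving the basis pursuit denoising (BPDN) program

    min ||alpha||_1   s.t.  ||y - X' alpha||_2 <= epsilon,

where X' is the column-wise unit-normalized training matrix, additionally
scaled per column by the Gaussian kernel similarity w_j = exp(-||x_j -
y||^2 / (2 sigma^2)) in WSRC mode.  The query is assigned to the class
whose columns alone reconstruct it with the smallest residual
g_k = ||y - X' delta_k(alpha)||_2 (ties broken by lowest class index).

The weighting makes nearby training samples cheap to use in the l1
objective (coefficient beta_j on the original column costs |beta_j| / w_j),
which is what lets the method work in low-dimensional feature spaces.

The BPDN program is solved exactly via the piecewise-linear lasso homotopy
path: coefficients are linear in the penalty within each path segment, so
the residual norm is a quadratic along the segment and the epsilon
constraint boundary can be located in closed form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import lars_path

from .errors import DataValidationError, ParameterError, SolverError

#: Default Gaussian kernel width.
DEFAULT_SIGMA: float = 50.0
#: Default BPDN residual tolerance.
DEFAULT_EPSILON: float = 0.05

_FORMAT_VERSION = 1

# All weights below this are treated as numerically dead; the classifier
# falls back to unweighted SRC rather than solving on a ~zero dictionary.
_WEIGHT_UNDERFLOW = 1e-12


def gaussian_weight(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian kernel similarity exp(-||x - y||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DataValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def solve_l1(X: np.ndarray, y: np.ndarray, epsilon: float) -> np.ndarray:
    """Solve min ||alpha||_1 s.t. ||y - X alpha||_2 <= epsilon.

    Parameters
    ----------
    X : ndarray, shape (d, n)
        Dictionary with columns as training atoms (callers pass unit-norm,
        possibly weight-scaled columns; no normalization happens here).
    y : ndarray, shape (d,)
        Query vector.
    epsilon : float
        Positive residual tolerance.

    Returns
    -------
    alpha : ndarray, shape (n,)
        Minimum-l1 coefficient vector feasible for the constraint.

    Raises
    ------
    SolverError
        If no feasible point exists on the homotopy path (residual floor of
        the dictionary exceeds ``epsilon``).

    Notes
    -----
    Uses the exact LARS/lasso homotopy: the lasso solution alpha(lambda) is
    piecewise linear in the penalty lambda, and the BPDN optimum is the
    lasso solution at the lambda where the residual constraint becomes
    active.  The crossing is found by solving the per-segment quadratic
    ||(1-t) r_prev + t r_next||^2 = epsilon^2.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[1] == 0:
        raise DataValidationError("dictionary X must be a non-empty 2-D array")
    if X.shape[0] != y.size:
        raise DataValidationError(
            f"dimension mismatch: dictionary rows {X.shape[0]} vs query {y.size}"
        )

    n_cols = X.shape[1]
    if float(np.linalg.norm(y)) <= epsilon:
        return np.zeros(n_cols)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, coefs = lars_path(X, y, method="lasso")
    except Exception as exc:  # degenerate dictionaries
        raise SolverError(f"lasso homotopy failed: {exc}") from exc

    resid = y[:, None] - X @ coefs  # (d, n_nodes)
    norms = np.linalg.norm(resid, axis=0)

    feasible = np.flatnonzero(norms <= epsilon)
    if feasible.size == 0:
        raise SolverError(
            f"constraint infeasible on path: best residual {norms.min():.3g} "
            f"> epsilon={epsilon:.3g}"
        )
    j = int(feasible[0])
    if j == 0:
        return coefs[:, 0].copy()

    # residual is linear in t along the segment [j-1, j]; find the crossing
    r_prev, r_next = resid[:, j - 1], resid[:, j]
    dr = r_next - r_prev
    a = float(dr @ dr)
    b = 2.0 * float(r_prev @ dr)
    c = float(r_prev @ r_prev) - epsilon**2
    if a <= 0:
        t = 1.0
    else:
        disc = max(b * b - 4 * a * c, 0.0)
        t = (-b - np.sqrt(disc)) / (2 * a)
        t = float(np.clip(t, 0.0, 1.0))
        # convex quadratic: the smaller root is the downward crossing; if it
        # fell outside [0, 1] numerically, take the segment endpoint
        if np.linalg.norm(r_prev + t * dr) > epsilon * (1 + 1e-9):
            t = 1.0
    return (1.0 - t) * coefs[:, j - 1] + t * coefs[:, j]


@dataclass(frozen=True)
class SparseCode:
    """Outcome of classifying one query: code, residuals, decision."""

    alpha: np.ndarray
    residuals: np.ndarray
    predicted_class: int
    weights: np.ndarray


class SparseRepresentationClassifier:
    """SRC / WSRC classifier over a unit-normalized training dictionary.

    Parameters
    ----------
    mode : {"wsrc", "src"}
        ``"wsrc"`` scales each dictionary column by its Gaussian similarity
        to the query before sparse coding; ``"src"`` uses unit weights.
    sigma : float
        Gaussian kernel width (WSRC only). Default 50.
    epsilon : float
        BPDN residual tolerance. Default 0.05.

    Notes
    -----
    ``fit`` only stores and column-normalizes the training data; all the
    work happens per query.  Similarities and residuals are computed on the
    unit-normalized columns, and the weighted dictionary is used both in
    the l1 program and in the class residuals, so the weights actually
    shape the decision.
    """

    def __init__(
        self,
        mode: str = "wsrc",
        sigma: float = DEFAULT_SIGMA,
        epsilon: float = DEFAULT_EPSILON,
    ) -> None:
        if mode not in ("wsrc", "src"):
            raise ParameterError(f"mode must be 'wsrc' or 'src', got {mode!r}")
        if sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {sigma}")
        if epsilon <= 0:
            raise ParameterError(f"epsilon must be positive, got {epsilon}")
        self.mode = mode
        self.sigma = float(sigma)
        self.epsilon = float(epsilon)

    # -- fitting -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SparseRepresentationClassifier":
        """Store the training set; columns are scaled to unit l2 norm.

        Parameters
        ----------
        X : ndarray, shape (n_samples, d)
            Training feature rows.
        y : ndarray, shape (n_samples,)
            Integer class labels.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] == 0:
            raise DataValidationError(
                f"bad training shapes: X {X.shape}, y {y.shape}"
            )
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise DataValidationError(f"training sample {bad} is all zeros")
        self.classes_ = np.unique(y)
        self._col_class = np.searchsorted(self.classes_, y)
        self.dictionary_ = (X / norms[:, None]).T  # (d, n) unit columns
        return self

    @property
    def n_classes_(self) -> int:
        return self.classes_.size

    def _check_fitted(self) -> None:
        if not hasattr(self, "dictionary_"):
            raise DataValidationError("classifier is not fitted")

    # -- per-query pipeline ------------------------------------------------

    def _weights(self, y: np.ndarray) -> np.ndarray:
        if self.mode == "src":
            return np.ones(self.dictionary_.shape[1])
        d2 = np.sum((self.dictionary_ - y[:, None]) ** 2, axis=0)
        w = np.exp(-d2 / (2.0 * self.sigma**2))
        if w.max() < _WEIGHT_UNDERFLOW:
            warnings.warn(
                "all Gaussian weights underflowed (query far from training "
                "set); falling back to unweighted SRC for this query",
                RuntimeWarning,
                stacklevel=3,
            )
            return np.ones_like(w)
        return w

    def class_residuals(self, alpha: np.ndarray, y: np.ndarray,
                        weights: np.ndarray | None = None) -> np.ndarray:
        """Residuals g_k = ||y - X' delta_k(alpha)||_2, one per class.

        ``weights`` must be the column weights used when solving for
        ``alpha`` so the same dictionary X' enters both stages (all ones
        for SRC).
        """
        self._check_fitted()
        alpha = np.asarray(alpha, dtype=np.float64).ravel()
        if alpha.size != self.dictionary_.shape[1]:
            raise DataValidationError(
                f"alpha length {alpha.size} != dictionary width "
                f"{self.dictionary_.shape[1]}"
            )
        Xw = self.dictionary_ if weights is None else self.dictionary_ * weights
        g = np.empty(self.n_classes_)
        for k in range(self.n_classes_):
            mask = self._col_class == k
            g[k] = np.linalg.norm(y - Xw[:, mask] @ alpha[mask])
        return g

    def classify_one(self, y: np.ndarray) -> SparseCode:
        """Run the full pipeline on a single query vector."""
        self._check_fitted()
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != self.dictionary_.shape[0]:
            raise DataValidationError(
                f"query dimension {y.size} != dictionary rows "
                f"{self.dictionary_.shape[0]}"
            )
        w = self._weights(y)
        Xw = self.dictionary_ * w
        alpha = solve_l1(Xw, y, self.epsilon)
        g = self.class_residuals(alpha, y, weights=w)
        k = int(np.argmin(g))  # argmin takes the lowest index on ties
        return SparseCode(
            alpha=alpha,
            residuals=g,
            predicted_class=int(self.classes_[k]),
            weights=w,
        )

    # -- batch API ---------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels for feature rows X."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.array([self.classify_one(row).predicted_class for row in X])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Residual-margin score g_neg - g_pos for binary problems.

        Higher means more confidently the larger class label (the positive
        class); the argmin decision is recovered at threshold 0.
        """
        self._check_fitted()
        if self.n_classes_ != 2:
            raise DataValidationError(
                "decision_function requires a binary problem, got "
                f"{self.n_classes_} classes"
            )
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            g = self.classify_one(row).residuals
            out[i] = g[0] - g[1]
        return out

    def predict_detail(self, X: np.ndarray) -> list[SparseCode]:
        """Per-query :class:`SparseCode` objects (code, residuals, weights)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return [self.classify_one(row) for row in X]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Persist as a single ``.npz`` archive with a format-version tag."""
        self._check_fitted()
        np.savez_compressed(
            Path(path),
            format_version=_FORMAT_VERSION,
            mode=self.mode,
            sigma=self.sigma,
            epsilon=self.epsilon,
            dictionary=self.dictionary_,
            classes=self.classes_,
            col_class=self._col_class,
            metadata=json.dumps(metadata or {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> tuple["SparseRepresentationClassifier", dict]:
        """Load a model archive; returns (classifier, metadata dict)."""
        with np.load(Path(path), allow_pickle=False) as z:
            version = int(z["format_version"])
            if version != _FORMAT_VERSION:
                raise DataValidationError(
                    f"unsupported model format version {version}"
                )
            clf = cls(
                mode=str(z["mode"]),
                sigma=float(z["sigma"]),
                epsilon=float(z["epsilon"]),
            )
            clf.dictionary_ = z["dictionary"]
            clf.classes_ = z["classes"]
            clf._col_class = z["col_class"]
            metadata = json.loads(str(z["metadata"]))
        return clf, metadata
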