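"""RBF-SVM model for DNA-binding-protein prediction.

Organised as a model/results pair: :class:`ProfileSVM` holds the training
features and labels (built directly or via :meth:`ProfileSVM.from_dataset`,
which applies one of the profile transformations); ``fit`` returns a
:class:`ProfileSVMResults` carrying the support expansion, the per-sample
dual weights, the feature-scaling record and the discriminant-weight
analysis.  Hyperparameters can be chosen with
:meth:`ProfileSVM.grid_search` (exhaustive, stratified 5-fold CV over
power-of-two grids).

The per-sample weight vector ``A = [a_1 .. a_N]`` contains the signed dual
coefficients ``a_i = y_i * alpha_i`` of the trained machine (zero for
non-support samples).  The discriminant weight of each feature is
``W = A . M`` where ``M`` is the (scaled) training feature matrix; summing
the ``d >= 1`` blocks of ``W`` per ordered residue pair gives the
aggregated bigram weights used for feature analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .profile_io import CANONICAL_ORDER, LabeledDataset
from .transforms import DEFAULT_D, PAPER_PRESETS, feature_matrix, feature_names

DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16))
DEFAULT_G_GRID = tuple(2.0**k for k in range(-15, 6))


class ModelError(ValueError):
    """Raised for invalid model inputs or mismatched dimensions."""


# ---------------------------------------------------------------------------
# Feature scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingRecord:
    """Per-feature linear map onto [-1, 1] learned from training data.

    Constant features (max == min) are mapped to 0.  The record is stored
    with the model and reused verbatim at prediction time.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.mins.size:
            raise ModelError(
                f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match scaling record ({self.mins.size})"
            )
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = -1.0 + 2.0 * (X[:, nz] - self.mins[nz]) / span[nz]
        return out

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingRecord":
        return cls(np.asarray(d["mins"], float), np.asarray(d["maxs"], float))


def scale_fit_transform(X: np.ndarray) -> tuple[np.ndarray, ScalingRecord]:
    """Fit a [-1, 1] min-max scaling on X and return (scaled X, record)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ModelError("scaling requires a 2-D matrix with at least 2 samples")
    record = ScalingRecord(X.min(axis=0), X.max(axis=0))
    return record.transform(X), record


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Exhaustive CV grid with the chosen operating point."""

    grid: list[tuple[float, float, float]]  # (c, g, mean CV accuracy)
    c: float
    g: float
    folds: int
    seed: int

    @property
    def best_accuracy(self) -> float:
        return max(acc for _, _, acc in self.grid)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    g_grid: tuple[float, ...] = DEFAULT_G_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Pick (c, g) by stratified k-fold CV accuracy over an exhaustive grid.

    Scaling is refit inside every fold.  Ties are broken toward the
    smallest c, then the smallest g (the simpler machine), skipping tied
    candidates whose full-data machine has no free support vector: with
    every dual coefficient at the box bound the bias is pinned by the
    class counts alone and the machine degenerates to a majority vote as
    soon as the training classes are off-balance by a single sample (as
    they are in every leave-one-out fit).  With a fixed seed the result is
    fully deterministic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ModelError("grid search requires samples from both classes")
    if folds < 2:
        raise ModelError("grid search requires folds >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    grid: list[tuple[float, float, float]] = []
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            correct = 0
            for tr, va in splits:
                Xs, rec = scale_fit_transform(X[tr])
                svc = SVC(C=c, gamma=g, kernel="rbf")
                svc.fit(Xs, y[tr])
                correct += int((svc.predict(rec.transform(X[va])) == y[va]).sum())
            grid.append((c, g, correct / len(y)))
    best_acc = max(acc for _, _, acc in grid)
    tied = [(c, g) for c, g, acc in grid if acc == best_acc]
    Xs, _ = scale_fit_transform(X)
    chosen = tied[0]
    for c, g in tied:
        svc = SVC(C=c, gamma=g, kernel="rbf")
        svc.fit(Xs, y)
        if not np.isclose(np.abs(svc.dual_coef_[0]), c, rtol=1e-8).all():
            chosen = (c, g)
            break
    return GridSearchResult(
        grid=grid, c=chosen[0], g=chosen[1], folds=folds, seed=seed
    )


# ---------------------------------------------------------------------------
# Discriminant weights
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantWeights:
    """Per-feature discriminant weights W = A . M and their aggregations."""

    W: np.ndarray
    method: str | None = None
    D: int | None = None

    @property
    def names(self) -> list[str] | None:
        if self.method is None:
            return None
        return feature_names(self.method, self.D)

    def block(self, d: int) -> np.ndarray:
        """The 20 x 20 weight matrix of the separation-d features."""
        if self.method not in ("dbt", "edt"):
            raise ModelError("per-distance blocks exist only for dbt/edt features")
        d0 = 0 if self.method == "dbt" else 1
        if not d0 <= d <= self.D:
            raise ModelError(f"distance {d} outside [{d0}, {self.D}]")
        k = (d - d0) * 400
        return self.W[k : k + 400].reshape(20, 20)

    def aggregated_bigram_weights(self) -> np.ndarray:
        """20 x 20 matrix: entry (x, y) sums W over the d >= 1 blocks.

        This is the bigram-importance table of the feature analysis: the
        weight of pair (x, y) pooled over all separations at which the
        bigram was counted.
        """
        if self.method not in ("dbt", "edt"):
            raise ModelError("bigram aggregation applies to dbt/edt features")
        return sum(self.block(d) for d in range(1, self.D + 1))

    def composition_weights(self) -> np.ndarray:
        """The 20 amino-acid-composition weights (diagonal of the d=0 block)."""
        if self.method != "dbt":
            raise ModelError("composition weights live in the dbt d=0 block")
        return np.diag(self.block(0)).copy()

    def bigram_weight(self, x: str, y: str) -> float:
        i, j = CANONICAL_ORDER.index(x), CANONICAL_ORDER.index(y)
        return float(self.aggregated_bigram_weights()[i, j])


def discriminant_weights(
    A: np.ndarray,
    M: np.ndarray,
    method: str | None = None,
    D: int | None = None,
) -> DiscriminantWeights:
    """Compute W = A . M for sample weights A and training feature matrix M."""
    A = np.asarray(A, float)
    M = np.asarray(M, float)
    if M.shape[0] != A.size:
        raise ModelError(
            f"training matrix has {M.shape[0]} rows but A has {A.size} entries"
        )
    return DiscriminantWeights(W=A @ M, method=method, D=D)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ProfileSVM:
    """Soft-margin RBF-SVM over profile-derived feature vectors.

    Parameters
    ----------
    X : ndarray (N, j)
        Raw (unscaled) feature vectors.
    y : ndarray (N,)
        Binary labels, 1 = DNA-binding.
    ids : list of str, optional
    method, D :
        Which transformation produced X; recorded for feature naming.
    """

    def __init__(self, X, y, ids=None, method=None, D=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ModelError("X must be (N, j) with one label per row")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ModelError("labels must be 0/1")
        self.ids = list(ids) if ids is not None else None
        self.method = method
        self.D = D

    @classmethod
    def from_dataset(
        cls, dataset: LabeledDataset, method: str = "dbt", D: int | None = None
    ) -> "ProfileSVM":
        if D is None:
            D = DEFAULT_D.get(method)
        X, y, ids = feature_matrix(dataset, method, D)
        return cls(X, y, ids=ids, method=method, D=D)

    @property
    def nobs(self) -> int:
        return int(self.y.size)

    def grid_search(
        self,
        c_grid: tuple[float, ...] = DEFAULT_C_GRID,
        g_grid: tuple[float, ...] = DEFAULT_G_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> GridSearchResult:
        return grid_search(self.X, self.y, c_grid, g_grid, folds, seed)

    def fit(self, c: float | None = None, g: float | None = None) -> "ProfileSVMResults":
        """Train at fixed (c, g); defaults come from the method's preset."""
        if len(np.unique(self.y)) < 2:
            raise ModelError("training requires samples from both classes")
        preset = PAPER_PRESETS.get(self.method or "", {})
        c = float(c if c is not None else preset.get("c", 1.0))
        g = float(g if g is not None else preset.get("g", 1.0 / self.X.shape[1]))
        Xs, record = scale_fit_transform(self.X)
        svc = SVC(C=c, gamma=g, kernel="rbf")
        svc.fit(Xs, self.y)
        A = np.zeros(self.nobs)
        A[svc.support_] = svc.dual_coef_[0]
        return ProfileSVMResults(
            model=self,
            c=c,
            g=g,
            scaling=record,
            support_vectors=Xs[svc.support_].copy(),
            sv_coef=svc.dual_coef_[0].copy(),
            bias=float(svc.intercept_[0]),
            dual_weights=A,
            scaled_train=Xs,
        )


@dataclass
class ProfileSVMResults:
    """A fitted RBF-SVM: support expansion, scaling record, dual weights.

    ``predict`` evaluates the decision function explicitly over the stored
    support vectors, so a saved-and-reloaded results object reproduces the
    in-memory predictions bit for bit.  A decision value of exactly 0 is
    resolved to the positive class.
    """

    c: float
    g: float
    scaling: ScalingRecord
    support_vectors: np.ndarray
    sv_coef: np.ndarray
    bias: float
    dual_weights: np.ndarray
    model: ProfileSVM | None = None
    scaled_train: np.ndarray | None = field(default=None, repr=False)
    method: str | None = None
    D: int | None = None
    train_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.model is not None:
            self.method = self.model.method
            self.D = self.model.D
            self.train_ids = self.model.ids

    # -- prediction --------------------------------------------------------

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaling.transform(np.asarray(X, float))
        sq = (
            (Xs**2).sum(axis=1)[:, None]
            - 2.0 * Xs @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.g * np.maximum(sq, 0.0))
        return K @ self.sv_coef + self.bias

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (labels, decision values); label = 1 iff decision >= 0."""
        dec = self.decision_function(X)
        return (dec >= 0).astype(int), dec

    # -- analysis ----------------------------------------------------------

    def discriminant_weights(
        self, M: np.ndarray | None = None
    ) -> DiscriminantWeights:
        """W = A . M; by default M is the scaled training feature matrix."""
        if M is None:
            M = self.scaled_train
        if M is None:
            raise ModelError(
                "no training matrix available; pass M (scaled features) explicitly"
            )
        return discriminant_weights(self.dual_weights, M, self.method, self.D)

    def summary(self) -> str:
        n_sv = int(self.sv_coef.size)
        lines = [
            "Profile RBF-SVM results",
            "=" * 40,
            f"Feature method:     {self.method or 'unspecified'}"
            + (f" (D={self.D})" if self.D is not None else ""),
            f"Features:           {self.support_vectors.shape[1]}",
            f"Training samples:   {self.dual_weights.size}",
            f"Support vectors:    {n_sv}",
            f"Cost c:             {self.c:g}",
            f"RBF gamma g:        {self.g:g}",
            f"Bias:               {self.bias:.6g}",
            f"Sum of dual weights: {self.dual_weights.sum():.3e}",
        ]
        if self.model is not None:
            labels, _ = self.predict(self.model.X)
            acc = float((labels == self.model.y).mean())
            lines.append(f"Training accuracy:  {acc:.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "c": self.c,
            "g": self.g,
            "bias": self.bias,
            "method": self.method,
            "D": self.D,
            "scaling": self.scaling.to_dict(),
            "support_vectors": self.support_vectors.tolist(),
            "sv_coef": self.sv_coef.tolist(),
            "dual_weights": self.dual_weights.tolist(),
            "train_ids": self.train_ids,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ProfileSVMResults":
        d = json.loads(Path(path).read_text())
        return cls(
            c=d["c"],
            g=d["g"],
            bias=d["bias"],
            scaling=ScalingRecord.from_dict(d["scaling"]),
            support_vectors=np.asarray(d["support_vectors"], float),
            sv_coef=np.asarray(d["sv_coef"], float),
            dual_weights=np.asarray(d["dual_weights"], float),
            method=d.get("method"),
            D=d.get("D"),
            train_ids=d.get("train_ids"),
        )


def train(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    g: float,
    ids=None,
    method=None,
    D=None,
) -> ProfileSVMResults:
    """Functional entry point: scale, fit, and return results."""
    return ProfileSVM(X, y, ids=ids, method=method, D=D).fit(c=c, g=g)
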