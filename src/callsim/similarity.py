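"""Caller classification by linear DFA and centroid-based call similarity.

A linear discriminant model (shared within-class covariance, priors
proportional to training counts) classifies calls to bats.  Individuality
is quantified by leave-one-out cross-validated accuracy (computed exactly
via rank-one downdates, not by refitting) and by a permutation null that
refits the non-cross-validated DFA under randomized caller labels.

Pairwise caller similarity is derived from the Mahalanobis distance
between class centroids under the pooled within-class covariance:

    S = 1 - D / max(D)

normalized per analysis, with any exact-zero similarity replaced by a
small floor (default 0.001) so that a beta-distributed outcome model can
be applied downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

ID_COLUMNS = ("bat_id", "source", "call_index", "site", "epoch")


def _split(table: pd.DataFrame):
    if "bat_id" not in table.columns:
        raise ValueError("feature table must have a bat_id column")
    feat_cols = [c for c in table.columns if c not in ID_COLUMNS]
    X = table[feat_cols].to_numpy(dtype=float)
    y = table["bat_id"].to_numpy()
    return X, y, feat_cols


def filter_bats_min_calls(table: pd.DataFrame, min_calls: int = 100) -> pd.DataFrame:
    """Keep only bats contributing at least ``min_calls`` rows."""
    counts = table["bat_id"].value_counts()
    keep = counts.index[counts >= min_calls]
    out = table[table["bat_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no bats meet the minimum-call threshold", stacklevel=2)
    return out


@dataclass
class DfaModel:
    """Fitted linear discriminant model for caller classification."""

    classes: np.ndarray
    centroids: np.ndarray  # (K, p) class means
    pooled_cov: np.ndarray  # (p, p) pooled within-class covariance
    priors: np.ndarray  # proportional to training counts
    counts: np.ndarray
    feature_names: list

    def _discriminant_terms(self):
        c, low = cho_factor(self.pooled_cov)
        A = cho_solve((c, low), self.centroids.T).T  # (K, p) = mu_k' Sigma^-1
        b = -0.5 * np.einsum("kp,kp->k", A, self.centroids) + np.log(self.priors)
        return A, b

    def predict(self, X: np.ndarray) -> np.ndarray:
        A, b = self._discriminant_terms()
        scores = X @ A.T + b
        return self.classes[np.argmax(scores, axis=1)]

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


def _pooled_fit(X, y, classes, reg=1e-8):
    K, p = len(classes), X.shape[1]
    centroids = np.empty((K, p))
    counts = np.empty(K, dtype=int)
    W = np.zeros((p, p))
    for k, cls in enumerate(classes):
        Xi = X[y == cls]
        counts[k] = len(Xi)
        centroids[k] = Xi.mean(axis=0)
        d = Xi - centroids[k]
        W += d.T @ d
    dof = len(X) - K
    if dof <= 0:
        raise ValueError("need more calls than bats")
    cov = W / dof
    # regularize if numerically singular
    try:
        cholesky(cov, lower=True)
    except LinAlgError:
        diag = np.mean(np.diag(cov))
        cov = cov + reg * max(diag, 1.0) * np.eye(p)
        try:
            cholesky(cov, lower=True)
        except LinAlgError:
            v = np.diag(cov)
            bad = [n for n, ok in zip(range(p), v > 0) if not ok]
            raise ValueError(
                f"pooled within-class covariance is singular (degenerate columns {bad})"
            ) from None
    return centroids, counts, W, cov


def fit_dfa(table: pd.DataFrame) -> DfaModel:
    """Fit the linear DFA on all features; invariant to row order."""
    X, y, feat_cols = _split(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two bats")
    centroids, counts, _, cov = _pooled_fit(X, y, classes)
    priors = counts / counts.sum()
    return DfaModel(classes, centroids, cov, priors, counts, feat_cols)


def classify_loocv(table: pd.DataFrame) -> dict:
    """Exact leave-one-out cross-validated caller classification.

    For each held-out call the class mean and the pooled covariance are
    downdated analytically (rank-one Sherman–Morrison update of the pooled
    scatter inverse), which reproduces refitting the DFA without the call.
    Returns overall and per-bat accuracy.
    """
    X, y, _ = _split(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two bats")
    class_idx = {c: k for k, c in enumerate(classes)}
    yi = np.array([class_idx[v] for v in y])
    centroids, counts, W, _ = _pooled_fit(X, y, classes)
    # mirror the covariance regularization on the raw scatter (collinear
    # features such as IQRs make W rank-deficient by construction)
    try:
        cholesky(W, lower=True)
    except LinAlgError:
        W = W + 1e-8 * max(np.mean(np.diag(W)), 1.0) * np.eye(W.shape[1])
    if counts.min() < 2:
        bad = classes[np.argmin(counts)]
        raise ValueError(f"bat {bad!r} has a single call; cannot hold out")
    N, p = X.shape
    K = len(classes)
    dof = N - 1 - K  # after removing one observation
    if dof <= 0:
        raise ValueError("too few calls for leave-one-out")

    Winv = np.linalg.inv(W)
    correct = np.zeros(K)
    for i in range(N):
        k = yi[i]
        n_k = counts[k]
        x = X[i]
        mu_k = (n_k * centroids[k] - x) / (n_k - 1)
        # scatter downdate: W' = W - c v v^T with v = x - mu_full, c = n_k/(n_k-1)
        v = x - centroids[k]
        c = n_k / (n_k - 1)
        Wv = Winv @ v
        denom = 1.0 - c * (v @ Wv)
        Winv_i = Winv + (c / denom) * np.outer(Wv, Wv)
        Sigma_inv = Winv_i * dof  # (W'/dof)^-1

        mus = centroids.copy()
        mus[k] = mu_k
        cnts = counts.astype(float).copy()
        cnts[k] -= 1
        priors = cnts / cnts.sum()
        A = mus @ Sigma_inv
        b = -0.5 * np.einsum("kp,kp->k", A, mus) + np.log(priors)
        pred = int(np.argmax(A @ x + b))
        if pred == k:
            correct[k] += 1

    per_bat = correct / counts
    return {
        "overall": float(correct.sum() / N),
        "per_bat": pd.Series(per_bat, index=classes),
    }


def permutation_null_accuracy(
    table: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Permutation null for caller information: randomized-label DFA.

    The observed statistic is the non-cross-validated classification
    accuracy; the null distribution refits the DFA ``n_perm`` times with
    caller labels randomly permuted across calls.  Reports
    p = (1 + #{null >= observed}) / (1 + n_perm) and the null's 2.5/97.5%
    quantiles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y, _ = _split(table)
    rng = np.random.default_rng(seed)

    def _noncv_accuracy(labels):
        classes = np.unique(labels)
        centroids, counts, _, cov = _pooled_fit(X, labels, classes)
        model = DfaModel(classes, centroids, cov, counts / counts.sum(), counts, [])
        return model.accuracy(X, labels)

    observed = _noncv_accuracy(y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _noncv_accuracy(rng.permutation(y))
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return {
        "observed": observed,
        "null": null,
        "p_value": float(p),
        "null_q025": float(np.quantile(null, 0.025)),
        "null_q975": float(np.quantile(null, 0.975)),
    }


def compare_cv_noncv(table: pd.DataFrame) -> dict:
    """Per-bat LOOCV vs non-CV accuracies and their Pearson correlation."""
    model = fit_dfa(table)
    X, y, _ = _split(table)
    pred = model.predict(X)
    noncv = pd.Series(
        [np.mean(pred[y == c] == c) for c in model.classes], index=model.classes
    )
    cv = classify_loocv(table)["per_bat"]
    degenerate = len(model.classes) < 3
    if np.std(cv) == 0 or np.std(noncv) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(cv, noncv)[0, 1])
    return {"loocv": cv, "noncv": noncv, "pearson_r": r, "degenerate": degenerate}


def centroid_mahalanobis_matrix(model: DfaModel) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between class centroids.

    D_ij = sqrt((mu_i - mu_j)^T Sigma_pooled^-1 (mu_i - mu_j)) via Cholesky
    whitening of the pooled within-class covariance.
    """
    try:
        L = cholesky(model.pooled_cov, lower=True)
    except LinAlgError as e:
        raise ValueError("pooled covariance is singular") from e
    Z = np.linalg.solve(L, model.centroids.T).T  # whitened centroids
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=model.classes, columns=model.classes)


@dataclass
class SimilarityMatrix:
    """Normalized dyadic caller similarity in (0, 1] with its raw distances."""

    bat_ids: list
    S: pd.DataFrame
    D: pd.DataFrame
    max_d: float
    floor: float

    def pairs(self) -> pd.DataFrame:
        """Long-format unordered pairs with similarity values."""
        ids = list(self.bat_ids)
        rows = [
            {"bat_i": ids[i], "bat_j": ids[j], "similarity": self.S.iloc[i, j]}
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        return pd.DataFrame(rows)


def similarity_from_distances(
    D: pd.DataFrame | np.ndarray, floor: float = 0.001
) -> SimilarityMatrix:
    """Normalize distances to similarities: S = 1 - D/max(D), floored.

    The pair attaining the maximum distance would map to exactly 0, which a
    beta outcome model cannot represent, so exact zeros are replaced by
    ``floor``.  The diagonal is 1 (D = 0).
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        Dm = D.to_numpy(dtype=float)
    else:
        Dm = np.asarray(D, dtype=float)
        ids = list(range(Dm.shape[0]))
    if not np.allclose(Dm, Dm.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(Dm < 0):
        raise ValueError("distances must be nonnegative")
    dmax = float(Dm.max())
    if dmax <= 0:
        raise ValueError("no variation among bats: max distance is zero")
    S = 1.0 - Dm / dmax
    S[S == 0.0] = floor
    Sdf = pd.DataFrame(S, index=ids, columns=ids)
    Ddf = pd.DataFrame(Dm, index=ids, columns=ids)
    return SimilarityMatrix(ids, Sdf, Ddf, dmax, floor)


def similarity_from_table(table: pd.DataFrame, floor: float = 0.001) -> SimilarityMatrix:
    """Convenience: DFA fit -> centroid distances -> similarity matrix."""
    model = fit_dfa(table)
    D = centroid_mahalanobis_matrix(model)
    return similarity_from_distances(D, floor=floor)
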