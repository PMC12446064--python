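"""Consensus NMF for one dataset.

NMF with the Frobenius objective and multiplicative updates is run many
times from distinct random initializations; the replicate spectra are
L2-normalized, outlier components are removed by a local-density filter
(mean Euclidean distance to the nearest ``int(local_neighborhood_size *
n_iter)`` neighbors above ``density_threshold``), the survivors are k-means
clustered into k groups, and per-cluster median spectra become the
consensus. Usages are then refit against the consensus spectra by
nonnegative least squares, and final spectra are refit over *all* retained
features (including ADTs) in TPM units and in per-feature z-score units.

Component stability across replicates (silhouette of the clustered spectra)
vs reconstruction error guides the choice of k; the choice itself is left
to the user.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment  # noqa: F401  (used by callers)
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import non_negative_factorization
from sklearn.metrics import silhouette_score

from .preprocess import NormalizedMatrix


def _as_array(x) -> np.ndarray:
    if isinstance(x, NormalizedMatrix):
        return np.asarray(x.values, dtype=float)
    if hasattr(x, "values") and hasattr(x, "gene_ids"):  # CorrectedMatrix
        return np.asarray(x.values, dtype=float)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def nnls_fixed_spectra(
    X: np.ndarray,
    spectra: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 1000,
    random_state: int = 0,
    solver: str = "mu",
) -> np.ndarray:
    """Solve ``min_U ||X - U S||_F, U >= 0`` with S fixed."""
    kwargs = {} if solver == "cd" else {"beta_loss": "frobenius"}
    U, _, _ = non_negative_factorization(
        np.asarray(X, dtype=float),
        H=np.ascontiguousarray(spectra, dtype=float),
        n_components=spectra.shape[0],
        update_H=False,
        solver=solver,
        tol=tol,
        max_iter=max_iter,
        random_state=random_state,
        **kwargs,
    )
    return U


def run_replicates(
    xc,
    k: int,
    n_iter: int = 20,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> list[np.ndarray]:
    """Run ``n_iter`` seeded NMF factorizations; returns the k x H spectra."""
    X = _as_array(xc)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(cells, genes)={min(X.shape)}")
    spectra = []
    for i in range(n_iter):
        _, H, _ = non_negative_factorization(
            X,
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            tol=tol,
            max_iter=max_iter,
            random_state=seed + i,
        )
        spectra.append(H)
    return spectra


def combine_replicates(
    replicates: list[np.ndarray],
    X: np.ndarray,
    k: int,
    local_neighborhood_size: float = 0.3,
    density_threshold: float = 0.15,
    seed: int = 0,
    refit_tol: float = 1e-4,
    refit_max_iter: int = 1000,
) -> dict:
    """Filter, cluster and average replicate spectra into a consensus.

    Returns a dict with ``spectra`` (k x H consensus, rows unit-L2),
    ``usages`` (refit by NNLS), ``stability`` (silhouette of the clustered
    components), ``error`` (relative Frobenius reconstruction error) and
    ``n_filtered``.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    stacked = np.vstack(replicates)  # (n_iter*k) x H
    norms = np.linalg.norm(stacked, axis=1, keepdims=True)
    l2 = stacked / np.maximum(norms, 1e-12)
    n_neighbors = max(1, int(local_neighborhood_size * len(replicates)))
    # squared Euclidean on unit vectors = 2 - 2*cosine; its maximum for
    # nonnegative spectra is 2, which is why a threshold of 2 is inert
    D = np.clip(2.0 - 2.0 * (l2 @ l2.T), 0.0, None)
    # mean distance to the nearest n_neighbors components (excluding self)
    part = np.sort(D, axis=1)[:, 1 : n_neighbors + 1]
    local_density = part.mean(axis=1)
    keep = local_density <= density_threshold
    if keep.sum() < k:
        raise ValueError(
            f"density filter at {density_threshold} left {keep.sum()} components "
            f"for k={k} clusters; consider a lower density_threshold"
        )
    surv = l2[keep]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(surv)
    labels = km.labels_
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ValueError("empty consensus cluster; consider a lower density_threshold")
    medians = np.vstack([np.median(surv[labels == j], axis=0) for j in range(k)])
    medians /= np.maximum(np.linalg.norm(medians, axis=1, keepdims=True), 1e-12)
    stability = (
        float(silhouette_score(surv, labels, metric="euclidean"))
        if k > 1 and len(surv) > k
        else 1.0
    )
    X = np.asarray(X, dtype=float)
    usages = nnls_fixed_spectra(
        X, medians, tol=refit_tol, max_iter=refit_max_iter, random_state=seed
    )
    error = float(np.linalg.norm(X - usages @ medians) / np.linalg.norm(X))
    return {
        "spectra": medians,
        "usages": usages,
        "stability": stability,
        "error": error,
        "n_filtered": int((~keep).sum()),
    }


def k_selection_stats(
    xc,
    k_values: list[int],
    n_iter: int = 20,
    seed: int = 0,
    local_neighborhood_size: float = 0.3,
    density_threshold: float = 0.15,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Stability / reconstruction-error table over a scan of k values."""
    X = _as_array(xc)
    rows = []
    for k in k_values:
        reps = run_replicates(X, k, n_iter=n_iter, seed=seed, tol=tol, max_iter=max_iter)
        res = combine_replicates(
            reps, X, k,
            local_neighborhood_size=local_neighborhood_size,
            density_threshold=density_threshold,
            seed=seed,
        )
        rows.append(
            {"k": k, "stability": res["stability"], "error": res["error"],
             "n_filtered": res["n_filtered"]}
        )
    return pd.DataFrame(rows)


def suggest_k(table: pd.DataFrame, stability_fraction: float = 0.9) -> int:
    """Largest k whose stability exceeds ``stability_fraction`` of the
    maximum observed stability. A suggestion only — the final choice of k is
    the user's."""
    thr = stability_fraction * table["stability"].max()
    ok = table.loc[table["stability"] >= thr, "k"]
    return int(ok.max())


def refit_spectra(
    usages: np.ndarray | pd.DataFrame,
    tpm,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Refit consensus spectra over all retained features.

    ``spectra_tpm``: nonnegative least squares of the TPM matrix on the
    usages, rows renormalized to sum to 1e6. ``spectra_zscore``: ordinary
    least squares of per-feature standardized TPM (population SD) on the
    usages — coefficients in z units, used to define marker genes.
    """
    U = usages.to_numpy(dtype=float) if isinstance(usages, pd.DataFrame) else np.asarray(usages, float)
    T = _as_array(tpm)
    if np.linalg.matrix_rank(U) < U.shape[1]:
        raise ValueError("rank-deficient usage matrix; cannot refit spectra")
    # NNLS per feature with U fixed: factorize T^T with H = U^T fixed.
    Wt, _, _ = non_negative_factorization(
        np.ascontiguousarray(T.T),
        H=np.ascontiguousarray(U.T),
        n_components=U.shape[1],
        update_H=False,
        solver="mu",
        beta_loss="frobenius",
        tol=1e-6,
        max_iter=2000,
        random_state=seed,
    )
    spectra_tpm = Wt.T  # k x features
    rowsum = spectra_tpm.sum(axis=1, keepdims=True)
    spectra_tpm = spectra_tpm / np.maximum(rowsum, 1e-300) * 1e6
    mu = T.mean(axis=0)
    sd = T.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (T - mu) / sd
    spectra_z, *_ = np.linalg.lstsq(U, Z, rcond=None)
    return spectra_tpm, spectra_z


class ConsensusNMF(BaseEstimator, TransformerMixin):
    """Consensus NMF decomposition with a scikit-learn estimator surface.

    ``fit(X)`` learns ``components_`` (k x H consensus spectra, unit L2
    rows) plus ``usages_``, ``stability_`` and ``reconstruction_err_``;
    ``transform(X)`` refits usages against the learned spectra by NNLS.
    """

    def __init__(
        self,
        n_components: int = 10,
        n_iter: int = 20,
        local_neighborhood_size: float = 0.3,
        density_threshold: float = 0.15,
        tol: float = 1e-4,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_iter = n_iter
        self.local_neighborhood_size = local_neighborhood_size
        self.density_threshold = density_threshold
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        A = _as_array(X)
        reps = run_replicates(
            A,
            self.n_components,
            n_iter=self.n_iter,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        res = combine_replicates(
            reps,
            A,
            self.n_components,
            local_neighborhood_size=self.local_neighborhood_size,
            density_threshold=self.density_threshold,
            seed=self.random_state,
            refit_tol=self.tol,
            refit_max_iter=self.max_iter,
        )
        self.components_ = res["spectra"]
        self.usages_ = res["usages"]
        self.stability_ = res["stability"]
        self.reconstruction_err_ = res["error"]
        self.n_filtered_ = res["n_filtered"]
        return self

    def transform(self, X):
        return nnls_fixed_spectra(
            _as_array(X),
            self.components_,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
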