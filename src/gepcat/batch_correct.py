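"""Batch correction of nonnegative gene-level matrices.

The corrector learns diversity-penalized soft clusters on principal
components of the TP10K-scaled matrix ``X^norm`` (soft k-means with an
entropy term at temperature ``sigma`` and a penalty ``theta`` against
clusters dominated by a single batch), then applies a per-cluster
mixture-of-experts linear model to remove the batch component from the
gene-level unit-variance matrix ``X^raw`` — rather than from the embedding —
and floors the result at zero so it remains a valid input for NMF.

With a single batch level the diversity penalty is inert and the clustering
reduces to plain soft k-means; the correction then subtracts nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data_model import ValidationError
from .preprocess import NormalizedMatrix


@dataclass
class SoftClusterModel:
    """Converged soft cluster responsibilities and the batch design."""

    responsibilities: np.ndarray  # cells x clusters, rows sum to 1
    batch_design: np.ndarray  # cells x batch-levels indicator
    batch_levels: list[str]
    n_clusters: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        R = self.responsibilities
        if not np.allclose(R.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("responsibility rows must sum to 1")


@dataclass
class CorrectedMatrix:
    """Gene-level batch-corrected matrix X^c, floored at zero."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    floored_fraction: float

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def _design(batch: pd.Series) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(pd.Series(batch).astype(str))
    return d.to_numpy(dtype=float), list(d.columns)


class HarmonyCorrector(BaseEstimator):
    """Diversity-penalized soft clustering + mixture-of-experts correction.

    Parameters
    ----------
    n_clusters : int or None
        soft cluster count; default ``min(100, round(n_cells / 30))``.
    theta : float
        diversity penalty per batch covariate.
    sigma : float
        soft-assignment temperature.
    n_pcs : int
        principal components of X^norm used for clustering.
    ridge_lambda : float
        ridge penalty on batch columns of the per-cluster linear model
        (the intercept is unpenalized).
    block_size : float
        fraction of cells updated per within-round block.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        theta: float = 2.0,
        sigma: float = 0.1,
        n_pcs: int = 50,
        max_rounds: int = 10,
        max_inner: int = 20,
        tol: float = 1e-4,
        ridge_lambda: float = 1.0,
        block_size: float = 0.05,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.theta = theta
        self.sigma = sigma
        self.n_pcs = n_pcs
        self.max_rounds = max_rounds
        self.max_inner = max_inner
        self.tol = tol
        self.ridge_lambda = ridge_lambda
        self.block_size = block_size
        self.random_state = random_state

    # -- clustering -----------------------------------------------------
    def fit(self, xnorm, batch: pd.Series):
        """Learn soft clusters from PCs of ``xnorm`` (a NormalizedMatrix or
        a dense array already in embedding space)."""
        if isinstance(xnorm, NormalizedMatrix):
            X = xnorm.values
            n_pcs = min(self.n_pcs, min(X.shape) - 1)
            Z = PCA(n_components=n_pcs, random_state=self.random_state).fit_transform(X)
        else:
            Z = np.asarray(xnorm, dtype=float)
        self.model_ = self._fit_soft_clusters(Z, pd.Series(batch))
        return self

    def _fit_soft_clusters(self, Z: np.ndarray, batch: pd.Series) -> SoftClusterModel:
        n = Z.shape[0]
        Phi, levels = _design(batch)
        K = self.n_clusters or max(2, min(100, int(round(n / 30))))
        K = min(K, n)
        rng = np.random.default_rng(self.random_state)
        # cosine geometry: operate on L2-normalized cells and centroids
        Zc = Z / np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), 1e-12)
        km = KMeans(n_clusters=K, n_init=10, random_state=self.random_state).fit(Zc)
        Y = km.cluster_centers_
        Y = Y / np.maximum(np.linalg.norm(Y, axis=1, keepdims=True), 1e-12)
        Pr_b = Phi.mean(axis=0)  # batch frequencies
        theta = self.theta if Phi.shape[1] > 1 else 0.0

        def distances(Yc):
            return 2.0 * (1.0 - Zc @ Yc.T)  # cells x K

        def assign_all(D):
            R = np.exp(-D / self.sigma)
            return R / R.sum(axis=1, keepdims=True)

        D = distances(Y)
        R = assign_all(D)
        trace = []
        converged = False
        block = max(1, int(np.ceil(self.block_size * n)))
        for _ in range(self.max_rounds):
            for _ in range(self.max_inner):
                order = rng.permutation(n)
                for start in range(0, n, block):
                    idx = order[start : start + block]
                    O = R.T @ Phi  # K x B co-occurrence
                    E = np.outer(R.sum(axis=0), Pr_b)
                    O -= R[idx].T @ Phi[idx]
                    E -= np.outer(R[idx].sum(axis=0), Pr_b)
                    penalty = np.power((E + 1.0) / (O + 1.0), theta)  # K x B
                    Rnew = np.exp(-D[idx] / self.sigma) * (Phi[idx] @ penalty.T)
                    R[idx] = Rnew / Rnew.sum(axis=1, keepdims=True)
                # centroid update
                Y = R.T @ Zc
                Y = Y / np.maximum(np.linalg.norm(Y, axis=1, keepdims=True), 1e-12)
                D = distances(Y)
                O = R.T @ Phi
                E = np.outer(R.sum(axis=0), Pr_b)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ent = np.where(R > 0, R * np.log(R), 0.0).sum()
                    div = (O * np.log((O + 1.0) / (E + 1.0))).sum()
                obj = (R * D).sum() + self.sigma * ent + self.sigma * theta * div
                trace.append(float(obj))
                if len(trace) > 1 and abs(trace[-2] - trace[-1]) < self.tol * abs(trace[-2]):
                    converged = True
                    break
            if converged:
                break
        if not converged:
            warnings.warn("soft clustering did not converge within max_rounds")
        return SoftClusterModel(
            responsibilities=R,
            batch_design=Phi,
            batch_levels=levels,
            n_clusters=K,
            converged=converged,
            objective_trace=trace,
            hyperparams={
                "theta": theta,
                "sigma": self.sigma,
                "n_pcs": self.n_pcs,
                "max_rounds": self.max_rounds,
                "tol": self.tol,
            },
        )

    # -- correction -----------------------------------------------------
    def _moe_residual(self, X: np.ndarray, model: SoftClusterModel) -> np.ndarray:
        """Mixture-of-experts batch component of X (to be subtracted)."""
        R, Phi = model.responsibilities, model.batch_design
        n, B = Phi.shape
        if B < 2:
            # a single batch level carries no batch signal: nothing to subtract
            return np.zeros_like(X, dtype=float)
        design = np.hstack([np.ones((n, 1)), Phi])  # intercept first
        lam = np.diag([0.0] + [self.ridge_lambda] * B)
        batch_part = np.zeros_like(X, dtype=float)
        for k in range(model.n_clusters):
            w = R[:, k]
            Dw = design * w[:, None]  # n x (B+1)
            G = design.T @ Dw + lam
            W = np.linalg.solve(G, Dw.T @ X)  # (B+1) x genes
            W[0, :] = 0.0  # keep the intercept (cluster expression)
            batch_part += (Dw @ W)
        return batch_part

    def correct(self, xraw) -> CorrectedMatrix:
        """Subtract the per-cluster batch component from gene-level values
        and floor at zero. ``xraw`` is a NormalizedMatrix (raw_scaled) whose
        cells align with the fitted responsibilities."""
        model = self.model_
        if isinstance(xraw, NormalizedMatrix):
            X, genes, cells = xraw.values, xraw.gene_ids, xraw.cell_ids
        else:
            X = np.asarray(xraw, dtype=float)
            genes = [str(i) for i in range(X.shape[1])]
            cells = [str(i) for i in range(X.shape[0])]
        if X.shape[0] != model.responsibilities.shape[0]:
            raise ValidationError(
                f"{X.shape[0]} cells in xraw vs "
                f"{model.responsibilities.shape[0]} in the cluster model"
            )
        corrected = X - self._moe_residual(X, model)
        floored = corrected < 0
        corrected[floored] = 0.0
        return CorrectedMatrix(
            values=corrected,
            gene_ids=list(genes),
            cell_ids=list(cells),
            floored_fraction=float(floored.mean()),
        )

    def fit_correct_embedding(self, Z: np.ndarray, batch: pd.Series) -> np.ndarray:
        """Fit on an embedding and return the corrected embedding (no floor);
        used for ADT smoothing where the correction target is the PCs."""
        self.fit(np.asarray(Z), batch)
        return np.asarray(Z) - self._moe_residual(np.asarray(Z, dtype=float), self.model_)


# -- functional wrappers ----------------------------------------------------


def fit_soft_clusters(xnorm, batch: pd.Series, **hyperparams) -> SoftClusterModel:
    """Thin wrapper over :meth:`HarmonyCorrector.fit`."""
    hc = HarmonyCorrector(**hyperparams)
    hc.fit(xnorm, batch)
    return hc.model_


def correct_gene_level(
    xraw, model: SoftClusterModel, ridge_lambda: float = 1.0
) -> CorrectedMatrix:
    """Thin wrapper over :meth:`HarmonyCorrector.correct`."""
    hc = HarmonyCorrector(ridge_lambda=ridge_lambda)
    hc.model_ = model
    return hc.correct(xraw)
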