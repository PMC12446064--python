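"""Normalization pipelines feeding consensus NMF and catalog projection.

From a filtered :class:`~gepcat.data_model.CountMatrix` three matrices are
derived:

* ``X^raw``  — counts on the overdispersed genes, each gene scaled to unit
  variance (no centering, so values stay nonnegative), with a global
  high-quantile ceiling against outliers;
* ``X^norm`` — the same genes after per-cell TP10K library-size
  normalization, again gene-scaled to unit variance (used only for the PCs
  that drive batch soft-clustering);
* ``TPM``    — per-cell TP10K over all retained features, with RNA and ADT
  blocks normalized separately so each block sums to 10,000 (used for the
  final spectra refit).

ADT surface proteins get their own pipeline (CLR, scaling, ceiling, kNN
diffusion smoothing) for manual gating.

Standard deviations are population SDs (ddof 0) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import CountMatrix, ValidationError


@dataclass
class NormalizedMatrix:
    """A dense cells x genes matrix in one of the pipeline's units."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    variant: str  # raw_scaled | norm_scaled | tp10k
    ceiling_value: float | None = None

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class SmoothedADT:
    """Diffusion-smoothed, CLR-normalized surface-protein estimates."""

    values: pd.DataFrame  # cells x proteins
    k_neighbors: int
    diffusion_t: int
    ceiling: float


# ---------------------------------------------------------------------------


def filter_counts(
    counts: CountMatrix,
    min_cells_per_gene: int = 10,
    min_umis_per_cell: int = 500,
    drop_adt: bool = False,
    drop_dotted_genes: bool = False,
) -> CountMatrix:
    """Remove rarely detected genes, low-UMI cells and (optionally) ADT
    features and genes whose id contains a period.

    The gene filter (detected in fewer than ``min_cells_per_gene`` cells) is
    computed before the cell filter (total counts below
    ``min_umis_per_cell``); both boundaries are inclusive at the threshold
    (a 500-UMI cell is kept). Each filter is applied once, without iteration.
    """
    X = counts.values
    feature_keep = np.asarray((X > 0).sum(axis=0)).ravel() >= min_cells_per_gene
    if drop_adt:
        feature_keep &= counts.is_rna
    if drop_dotted_genes:
        dotted = np.array(["." in f for f in counts.feature_ids])
        feature_keep &= ~(dotted & counts.is_rna)
    if not feature_keep.any():
        raise ValidationError("gene filter removed every feature")
    out = counts.subset(feature_mask=feature_keep)
    cell_keep = np.asarray(out.values.sum(axis=1)).ravel() >= min_umis_per_cell
    if not cell_keep.any():
        raise ValidationError("UMI filter removed every cell")
    return out.subset(cell_mask=cell_keep)


def _vst_standardized_variance(
    X: sp.spmatrix, span: float = 0.3
) -> np.ndarray:
    """Variance-stabilizing dispersion statistic (vst / 'seurat_v3' style).

    Fits a lowess trend of log10(variance) on log10(mean), standardizes
    counts by the trend SD with clipping at sqrt(N), and returns the variance
    of the clipped standardized values per gene. Genes with zero variance
    get statistic 0.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    X = sp.csc_matrix(X)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    stat = np.zeros(X.shape[1])
    ok = (var > 0) & (mean > 0)
    if not ok.any():
        return stat
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    fit = lowess(ly, lx, frac=span, return_sorted=False)
    reg_sd = np.sqrt(10**fit)
    clip = np.sqrt(n)
    Xd = np.asarray(X[:, ok].todense())
    z = (Xd - mean[ok]) / reg_sd
    np.clip(z, -clip, clip, out=z)
    # variance of clipped standardized values, without re-centering
    stat[ok] = np.square(z).sum(axis=0) / (n - 1)
    return stat


def select_overdispersed(
    counts: CountMatrix, n_genes: int = 2000, span: float = 0.3
) -> list[str]:
    """Rank genes by the vst standardized-variance statistic and return the
    top ``n_genes`` gene ids (RNA features only). Deterministic; invariant to
    cell order. If fewer genes are available, all are returned with a
    warning."""
    rna = counts.subset(feature_mask=counts.is_rna)
    stat = _vst_standardized_variance(rna.values, span=span)
    order = np.argsort(-stat, kind="stable")
    ids = [rna.feature_ids[i] for i in order]
    if n_genes > len(ids):
        warnings.warn(
            f"requested {n_genes} overdispersed genes but only {len(ids)} available"
        )
        n_genes = len(ids)
    return ids[:n_genes]


def _subset_dense(counts: CountMatrix, genes: list[str]) -> np.ndarray:
    idx = {f: i for i, f in enumerate(counts.feature_ids)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise ValidationError(f"genes not in counts: {missing[:5]}")
    cols = [idx[g] for g in genes]
    return np.asarray(counts.values[:, cols].todense(), dtype=float)


def _scale_unit_variance(M: np.ndarray, genes) -> np.ndarray:
    sd = M.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        bad = [g for g, z in zip(genes, zero) if z][:10]
        raise ValidationError(f"zero-variance genes cannot be scaled: {bad}")
    return M / sd


def build_xraw(
    counts: CountMatrix, genes: list[str], ceiling_quantile: float = 0.9999
) -> NormalizedMatrix:
    """Counts on ``genes`` scaled to unit variance per gene (no centering),
    then clipped at the ``ceiling_quantile`` quantile computed over all
    entries of the scaled matrix."""
    M = _scale_unit_variance(_subset_dense(counts, genes), genes)
    ceiling = None
    if ceiling_quantile < 1.0:
        ceiling = float(np.quantile(M, ceiling_quantile))
        np.minimum(M, ceiling, out=M)
    return NormalizedMatrix(M, list(genes), list(counts.cell_ids), "raw_scaled", ceiling)


def build_xnorm(
    counts: CountMatrix, genes: list[str], target_sum: float = 1e4
) -> NormalizedMatrix:
    """TP10K per cell computed on the full filtered gene set, then subset to
    ``genes`` and per-gene unit-variance scaling (no centering)."""
    totals = np.asarray(counts.values.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValidationError("zero-count cell encountered; run filter_counts first")
    M = _subset_dense(counts, genes) * (target_sum / totals)[:, None]
    M = _scale_unit_variance(M, genes)
    return NormalizedMatrix(M, list(genes), list(counts.cell_ids), "norm_scaled")


def tp10k_with_adt(counts: CountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """Per-cell TP10K with the RNA block and the ADT block normalized to
    ``target_sum`` separately, then concatenated in the original feature
    order. Cells with no ADT counts get zeros in the ADT block."""
    X = np.asarray(counts.values.todense(), dtype=float)
    out = np.zeros_like(X)
    for mask in (counts.is_rna, counts.is_adt):
        if not mask.any():
            continue
        block = X[:, mask]
        tot = block.sum(axis=1)
        nz = tot > 0
        block[nz] *= (target_sum / tot[nz])[:, None]
        out[:, mask] = block
    return NormalizedMatrix(out, list(counts.feature_ids), list(counts.cell_ids), "tp10k")


# ---------------------------------------------------------------------------
# ADT smoothing
# ---------------------------------------------------------------------------


def knn_diffusion_operator(embedding: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic diffusion operator from a symmetrized kNN graph.

    Directed kNN edges (excluding self) are symmetrized by union, self-loops
    added, and the adjacency row-normalized.
    """
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be below the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    A = nn.kneighbors_graph(embedding, mode="connectivity")
    A = ((A + A.T) > 0).astype(float)
    A = A.toarray()
    np.fill_diagonal(A, 1.0)
    return A / A.sum(axis=1, keepdims=True)


class ADTSmoother:
    """CLR-normalize and diffusion-smooth ADT protein counts.

    Pipeline: per-cell TP10K -> per-cell CLR on pseudocounted values
    (log(x+1) minus the mean of logs across proteins) -> per-protein unit
    variance -> ceiling clip -> PCA -> optional batch correction of PCs ->
    kNN diffusion operator powered to ``t`` applied to the scaled protein
    matrix.
    """

    def __init__(
        self,
        k: int = 5,
        t: int = 3,
        ceiling: float = 15.0,
        n_pcs: int = 20,
        random_state: int = 0,
    ):
        self.k = k
        self.t = t
        self.ceiling = ceiling
        self.n_pcs = n_pcs
        self.random_state = random_state

    def fit_transform(
        self, adt_counts: pd.DataFrame, batch: pd.Series | None = None
    ) -> SmoothedADT:
        from sklearn.decomposition import PCA

        X = adt_counts.to_numpy(dtype=float)
        n, p = X.shape
        if p < 2:
            raise ValidationError("ADT smoothing needs at least 2 proteins")
        if self.k >= n:
            raise ValidationError(f"k={self.k} >= n_cells={n}")
        tot = X.sum(axis=1)
        tp10k = np.divide(X * 1e4, tot[:, None], out=np.zeros_like(X), where=tot[:, None] > 0)
        logs = np.log(tp10k + 1.0)
        clr = logs - logs.mean(axis=1, keepdims=True)
        sd = clr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        scaled = np.minimum(clr / sd, self.ceiling)
        n_pcs = min(self.n_pcs, n - 1, p)
        pcs = PCA(n_components=n_pcs, random_state=self.random_state).fit_transform(scaled)
        if batch is not None and pd.Series(batch).nunique() > 1:
            from .batch_correct import HarmonyCorrector

            hc = HarmonyCorrector(n_pcs=n_pcs, random_state=self.random_state)
            pcs = hc.fit_correct_embedding(pcs, pd.Series(batch))
        P = knn_diffusion_operator(pcs, self.k)
        smoothed = scaled.copy()
        for _ in range(self.t):
            smoothed = P @ smoothed
        self.operator_ = P
        return SmoothedADT(
            pd.DataFrame(smoothed, index=adt_counts.index, columns=adt_counts.columns),
            self.k,
            self.t,
            self.ceiling,
        )


def adt_clr_smooth(
    adt_counts: pd.DataFrame,
    batch: pd.Series | None = None,
    k: int = 5,
    t: int = 3,
    ceiling: float = 15.0,
) -> SmoothedADT:
    """Functional wrapper over :class:`ADTSmoother`."""
    return ADTSmoother(k=k, t=t, ceiling=ceiling).fit_transform(adt_counts, batch)
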