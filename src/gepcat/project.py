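"""Fixed-catalog projection and per-cell annotation scores.

Given a catalog of GEP spectra G* and a query count matrix, per-cell usages
solve ``min_U ||X_query - U G*||_F`` with U >= 0, where the query columns
are the genes shared between query and catalog, each divided by its
standard deviation across query cells (no centering, no ceiling). Usage
rows are then normalized to sum to 1; cells with all-zero raw usage are
flagged and left at zero rather than renormalized.

Derived annotations are linear functionals of the normalized usage with
thresholds applied strictly (">"): the antigen-specific activation (ASA)
score sums its named component programs (default positivity threshold
0.0625; 0.065 matches some published figure panels), the cell-cycle score
sums the three cell-cycle programs (proliferating above 0.1), doublets are
flagged by summed usage of doublet-class programs, and subset labels come
from a multinomial logistic classifier on standardized usages with
balanced class weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .cnmf import nnls_fixed_spectra
from .data_model import CountMatrix, GEPCatalog, UsageMatrix, ValidationError

ASA_THRESHOLD_METHODS = 0.0625  #: default positivity threshold
ASA_THRESHOLD_FIGURES = 0.065  #: alternative threshold used in figure panels


@dataclass
class ProjectionResult:
    usage: UsageMatrix  # normalized
    raw_usage: UsageMatrix
    genes_used: list[str]
    dropped_catalog_genes: list[str]
    zero_rows: list[str] = field(default_factory=list)


class CatalogProjector(BaseEstimator, TransformerMixin):
    """Project query cells onto a fixed GEP catalog by nonnegative least
    squares.

    Parameters
    ----------
    catalog : GEPCatalog
        fixed spectra G* (programs x genes, SD-normalized TPM units).
    min_shared_genes : int
        floor on the query/catalog gene intersection.
    sd_on : {"counts", "tp10k"}
        whether per-gene SDs normalizing the query are computed on raw
        counts (default) or TP10K values.
    solver, tol, max_iter
        optimizer for the per-cell convex NNLS problem. The default
        coordinate-descent solver at tol 1e-10 reaches the unique optimum
        (it matches an exact active-set solve to ~1e-8 per entry);
        ``solver="mu"`` with tol 1e-4 / max_iter 1000 reproduces the slower
        multiplicative-update variant some published pipelines use.

    After ``fit(query)`` the projection is in ``result_``;
    ``transform(query)`` returns the normalized usage array.
    """

    def __init__(
        self,
        catalog: GEPCatalog | None = None,
        min_shared_genes: int = 20,
        sd_on: str = "counts",
        solver: str = "cd",
        tol: float = 1e-10,
        max_iter: int = 10000,
        random_state: int = 0,
        zero_eps: float = 1e-10,
    ):
        self.catalog = catalog
        self.min_shared_genes = min_shared_genes
        self.sd_on = sd_on
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.zero_eps = zero_eps

    def _query_frame(self, query) -> pd.DataFrame:
        if isinstance(query, CountMatrix):
            return pd.DataFrame(
                np.asarray(query.values.todense(), dtype=float),
                index=query.cell_ids,
                columns=query.feature_ids,
            )
        if isinstance(query, pd.DataFrame):
            return query.astype(float)
        raise TypeError("query must be a CountMatrix or DataFrame")

    def fit(self, query, y=None):
        cat = self.catalog
        if cat is None:
            raise ValidationError("CatalogProjector needs a catalog")
        Q = self._query_frame(query)
        if self.sd_on == "tp10k":
            tot = Q.sum(axis=1).to_numpy()
            Q = Q.mul(1e4 / np.maximum(tot, 1e-300), axis=0)
        sd = Q.std(axis=0, ddof=0)
        usable = pd.Index([g for g in Q.columns if sd[g] > 0])
        genes = [g for g in cat.gene_ids if g in set(usable)]
        if len(genes) < self.min_shared_genes:
            raise ValidationError(
                f"only {len(genes)} genes shared between query and catalog "
                f"(floor {self.min_shared_genes})"
            )
        dropped = [g for g in cat.gene_ids if g not in set(genes)]
        X = Q[genes].to_numpy() / sd[genes].to_numpy()
        G = cat.spectra[genes].to_numpy(dtype=float)
        raw = nnls_fixed_spectra(
            X, G, tol=self.tol, max_iter=self.max_iter,
            random_state=self.random_state, solver=self.solver,
        )
        sums = raw.sum(axis=1)
        zero = sums <= self.zero_eps
        norm = np.zeros_like(raw)
        norm[~zero] = raw[~zero] / sums[~zero, None]
        cells = list(Q.index)
        zero_rows = [c for c, z in zip(cells, zero) if z]
        cols = cat.program_names
        self.result_ = ProjectionResult(
            usage=UsageMatrix(
                pd.DataFrame(norm, index=cells, columns=cols),
                normalized=True,
                zero_rows=zero_rows,
            ),
            raw_usage=UsageMatrix(pd.DataFrame(raw, index=cells, columns=cols)),
            genes_used=genes,
            dropped_catalog_genes=dropped,
            zero_rows=zero_rows,
        )
        return self

    def transform(self, query):
        self.fit(query)
        return self.result_.usage.values.to_numpy()


def fit_usage(query, catalog: GEPCatalog, **kwargs) -> ProjectionResult:
    """Thin wrapper over :class:`CatalogProjector`."""
    return CatalogProjector(catalog=catalog, **kwargs).fit(query).result_


# ---------------------------------------------------------------------------
# derived scores
# ---------------------------------------------------------------------------


def _component_sum(usage: pd.DataFrame, catalog: GEPCatalog, score_name: str) -> pd.Series:
    if score_name not in catalog.score_components:
        raise ValidationError(f"catalog has no score component set {score_name!r}")
    comps = catalog.score_components[score_name]
    missing = [c for c in comps if c not in usage.columns]
    if missing:
        raise ValidationError(f"usage lacks programs {missing} for score {score_name!r}")
    return usage[comps].sum(axis=1)


def score_asa(
    usage: pd.DataFrame | UsageMatrix,
    catalog: GEPCatalog,
    threshold: float = ASA_THRESHOLD_METHODS,
) -> tuple[pd.Series, pd.Series]:
    """Per-cell sum of the catalog's "ASA" component usages; positive iff
    strictly above ``threshold``."""
    u = usage.values if isinstance(usage, UsageMatrix) else usage
    score = _component_sum(u, catalog, "ASA").rename("asa_score")
    return score, (score > threshold).rename("asa_positive")


def score_cellcycle(
    usage: pd.DataFrame | UsageMatrix,
    catalog: GEPCatalog,
    threshold: float = 0.1,
) -> tuple[pd.Series, pd.Series]:
    """Per-cell sum of the "CellCycle" components; proliferating iff
    strictly above ``threshold``."""
    u = usage.values if isinstance(usage, UsageMatrix) else usage
    score = _component_sum(u, catalog, "CellCycle").rename("cellcycle_score")
    return score, (score > threshold).rename("proliferating")


def flag_doublets(
    usage: pd.DataFrame | UsageMatrix,
    catalog: GEPCatalog,
    threshold: float = 0.1,
) -> pd.Series:
    """Flag cells whose summed usage of doublet-class programs exceeds
    ``threshold``. With no doublet programs in the catalog every flag is
    False and a warning is issued."""
    u = usage.values if isinstance(usage, UsageMatrix) else usage
    doublet_programs = [p for p in catalog.programs_of_class("doublet") if p in u.columns]
    if not doublet_programs:
        warnings.warn("catalog has no doublet-class programs; no cells flagged")
        return pd.Series(False, index=u.index, name="doublet_flag")
    return (u[doublet_programs].sum(axis=1) > threshold).rename("doublet_flag")


def score_table(
    usage: pd.DataFrame | UsageMatrix,
    catalog: GEPCatalog,
    asa_threshold: float = ASA_THRESHOLD_METHODS,
    cc_threshold: float = 0.1,
    doublet_threshold: float = 0.1,
    classifier: "SubsetClassifier | None" = None,
) -> pd.DataFrame:
    """Assemble the per-cell annotation table."""
    u = usage.values if isinstance(usage, UsageMatrix) else usage
    cols = {}
    if "ASA" in catalog.score_components:
        cols["asa_score"], cols["asa_positive"] = score_asa(u, catalog, asa_threshold)
    if "CellCycle" in catalog.score_components:
        cols["cellcycle_score"], cols["proliferating"] = score_cellcycle(
            u, catalog, cc_threshold
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cols["doublet_flag"] = flag_doublets(u, catalog, doublet_threshold)
    if classifier is not None:
        cols["subset_label"] = pd.Series(classifier.predict(u), index=u.index)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# subset classifier
# ---------------------------------------------------------------------------


class SubsetClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression on standardized usages.

    Usage columns are scaled to zero mean and unit variance; observations
    are weighted by the inverse of their class size (``class_weight=
    'balanced'``) so small subsets contribute equally; lbfgs solver with L2
    regularization.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 2000, random_state: int = 0,
                 min_cells_per_class: int = 10):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state
        self.min_cells_per_class = min_cells_per_class

    def fit(self, usage: pd.DataFrame | UsageMatrix, labels):
        X = (usage.values if isinstance(usage, UsageMatrix) else usage)
        self.feature_names_ = list(X.columns)
        y = pd.Series(labels).to_numpy()
        counts = pd.Series(y).value_counts()
        if len(counts) < 2:
            raise ValidationError("need at least 2 classes")
        small = counts[counts < self.min_cells_per_class]
        if len(small):
            raise ValidationError(
                f"classes below {self.min_cells_per_class} cells: {small.to_dict()}"
            )
        self.scaler_ = StandardScaler().fit(X.to_numpy())
        self.model_ = LogisticRegression(
            solver="lbfgs",
            C=self.C,
            class_weight="balanced",
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(self.scaler_.transform(X.to_numpy()), y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, usage: pd.DataFrame | UsageMatrix) -> np.ndarray:
        X = (usage.values if isinstance(usage, UsageMatrix) else usage)
        if list(X.columns) != self.feature_names_:
            raise ValidationError(
                "usage programs at predict time differ from the training programs"
            )
        return self.model_.predict(self.scaler_.transform(X.to_numpy()))


def train_subset_classifier(usage, labels, **kwargs) -> SubsetClassifier:
    """Thin wrapper over :class:`SubsetClassifier`."""
    return SubsetClassifier(**kwargs).fit(usage, labels)


def predict_subsets(model: SubsetClassifier, usage) -> np.ndarray:
    return model.predict(usage)


def balanced_accuracy(pred, truth) -> float:
    """Mean per-class recall over the classes present in ``truth``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    recalls = [
        np.mean(pred[truth == c] == c) for c in pd.unique(truth)
    ]
    return float(np.mean(recalls))
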