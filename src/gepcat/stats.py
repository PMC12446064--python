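"""Downstream inference on program usages.

Pseudobulk associations (OLS per program with Benjamini-Hochberg FDR),
paired proliferation tests with Fisher-method meta-analysis, greedy forward
AUC-based selection of activation-score components, and Fisher-exact marker
gene-set enrichment.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import fdrcorrection


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values (the 'indep' variant)."""
    p = np.asarray(pvals, dtype=float)
    _, q = fdrcorrection(p, method="indep")
    return q


def make_pseudobulk(
    usage: pd.DataFrame, cell_meta: pd.DataFrame, group_cols: list[str]
) -> pd.DataFrame:
    """Mean usage per (group) unit with a cell count column."""
    joined = usage.join(cell_meta[group_cols])
    out = joined.groupby(group_cols, observed=True).mean()
    out["n_cells"] = joined.groupby(group_cols, observed=True).size()
    return out.reset_index()


def _ols_table(pseudobulk: pd.DataFrame, usage_cols, design: pd.DataFrame) -> pd.DataFrame:
    X = sm.add_constant(design.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a redundant column for the error message
        for col in design.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                raise ValueError(f"collinear design: column {col!r} is redundant")
        raise ValueError("collinear design matrix")
    rows = []
    for prog in usage_cols:
        fit = sm.OLS(pseudobulk[prog].astype(float).to_numpy(), X.to_numpy()).fit()
        for k, col in enumerate(X.columns):
            if col == "const":
                continue
            rows.append(
                {"program": prog, "term": col, "coef": fit.params[k], "p": fit.pvalues[k]}
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for term, idx in table.groupby("term").groups.items():
        table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"])
    return table


def aim_association(
    pseudobulk: pd.DataFrame,
    usage_cols: list[str],
    stim_col: str = "stim",
    aimpos_col: str = "aim_pos",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-program OLS of pseudobulk mean usage on an intercept, a
    stimulated-vs-mock dummy and a stimulated-and-AIM-positive dummy.

    Programs positively associated with the stimulation dummy at q<alpha
    are classified "milieu-associated"; programs positively associated with
    the AIM-positive dummy are "AIM-associated".
    """
    table = _ols_table(pseudobulk, usage_cols, pseudobulk[[stim_col, aimpos_col]])
    wide = table.pivot(index="program", columns="term", values=["coef", "p", "q"])
    cls = pd.Series("none", index=wide.index, dtype=object)
    milieu = (wide[("coef", stim_col)] > 0) & (wide[("q", stim_col)] < alpha)
    aim = (wide[("coef", aimpos_col)] > 0) & (wide[("q", aimpos_col)] < alpha)
    cls[milieu] = "milieu-associated"
    cls[aim] = "AIM-associated"  # AIM label wins when both
    table = table.set_index(["program", "term"])
    table["classification"] = cls.reindex(
        table.index.get_level_values("program")
    ).to_numpy()
    return table.reset_index()


def disease_association(
    pseudobulk: pd.DataFrame,
    usage_cols: list[str],
    condition_col: str,
    covariate_cols: list[str] | None = None,
    donor_col: str | None = None,
    cells_col: str = "n_cells",
) -> pd.DataFrame:
    """Per-program OLS of mean usage on a binary condition, controlling for
    dummy-encoded categorical covariates; BH across programs. When
    ``donor_col`` is given, duplicate donors keep only the sample with the
    most cells."""
    pb = pseudobulk.copy()
    if donor_col is not None and pb[donor_col].duplicated().any():
        pb = (
            pb.sort_values(cells_col, ascending=False)
            .drop_duplicates(subset=[donor_col], keep="first")
            .sort_index()
        )
    design = pd.DataFrame({condition_col: pb[condition_col].astype(float)}, index=pb.index)
    for cov in covariate_cols or []:
        dummies = pd.get_dummies(pb[cov].astype(str), prefix=cov, drop_first=True)
        design = pd.concat([design, dummies], axis=1)
    table = _ols_table(pb, usage_cols, design)
    return table[table["term"] == condition_col].reset_index(drop=True)


def proliferation_association(
    usage: pd.DataFrame,
    cellcycle_score: pd.Series,
    sample_ids: pd.Series,
    cc_threshold: float = 0.1,
    min_high: int = 10,
    min_low: int = 100,
) -> pd.DataFrame:
    """Paired t-test per program between per-sample mean usage in high
    cell-cycle (score > threshold) vs low cell-cycle cells, over samples
    with at least ``min_high`` high and ``min_low`` low cells."""
    high = cellcycle_score > cc_threshold
    rows = []
    per_sample_high, per_sample_low = {}, {}
    for s, idx in usage.groupby(sample_ids.to_numpy()).groups.items():
        h = idx[high.loc[idx]]
        l = idx[~high.loc[idx]]
        if len(h) < min_high or len(l) < min_low:
            continue
        per_sample_high[s] = usage.loc[h].mean()
        per_sample_low[s] = usage.loc[l].mean()
    if len(per_sample_high) < 2:
        raise ValueError(
            f"only {len(per_sample_high)} samples pass the high/low cell filters"
        )
    H = pd.DataFrame(per_sample_high).T
    L = pd.DataFrame(per_sample_low).T
    for prog in usage.columns:
        t, p = scipy.stats.ttest_rel(H[prog], L[prog])
        rows.append(
            {"program": prog, "t": float(t), "p": float(p),
             "mean_diff": float((H[prog] - L[prog]).mean()),
             "n_samples": len(H)}
        )
    return pd.DataFrame(rows)


def fisher_combine(pvals) -> tuple[float, float]:
    """Fisher's method: statistic -2*sum(log p) ~ ChiSq(2k) under the null."""
    stat, p = scipy.stats.combine_pvalues(np.asarray(pvals, float), method="fisher")
    return float(stat), float(p)


def proliferation_meta(per_dataset_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fisher-combined p per program across per-dataset paired-t tables."""
    programs = sorted(
        set.intersection(*(set(t["program"]) for t in per_dataset_tables.values()))
    )
    rows = []
    for prog in programs:
        ps = [
            float(t.loc[t["program"] == prog, "p"].iloc[0])
            for t in per_dataset_tables.values()
        ]
        stat, p = fisher_combine(ps)
        rows.append({"program": prog, "fisher_stat": stat, "fisher_p": p,
                     "n_datasets": len(ps)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward stepwise selection of ASA components
# ---------------------------------------------------------------------------


def stepwise_asa_selection(
    candidates: list[str],
    targets: dict[str, pd.Series],
    usages: dict[str, pd.DataFrame],
    exclude: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection of programs whose summed usage best
    predicts a per-cell binary target, scored by mean AUC across datasets.

    At each step the candidate giving the best mean AUC is considered; it
    is added if the mean improves, and selection stops when the best
    candidate reduces the AUC in *every* dataset. Datasets whose target has
    a single class are excluded with a warning. Deterministic: ties broken
    by candidate order.
    """
    exclude = set(exclude or [])
    cands = [c for c in candidates if c not in exclude]
    ds = []
    for name in targets:
        y = pd.Series(targets[name]).astype(int)
        if y.nunique() < 2:
            warnings.warn(f"dataset {name!r} target has one class; excluded")
            continue
        ds.append(name)
    if not ds:
        raise ValueError("no dataset with a two-class target")

    def aucs(selected: list[str]) -> dict[str, float]:
        out = {}
        for name in ds:
            score = usages[name][selected].sum(axis=1)
            out[name] = float(roc_auc_score(targets[name].astype(int), score))
        return out

    selected: list[str] = []
    current = {name: 0.5 for name in ds}
    trajectory = []
    remaining = list(cands)
    while remaining:
        best, best_auc, best_mean = None, None, -np.inf
        for c in remaining:
            a = aucs(selected + [c])
            m = float(np.mean(list(a.values())))
            if m > best_mean:
                best, best_auc, best_mean = c, a, m
        worse_everywhere = all(best_auc[n] < current[n] for n in ds)
        if worse_everywhere:
            break
        if selected and best_mean <= float(np.mean(list(current.values()))):
            break
        selected.append(best)
        remaining.remove(best)
        current = best_auc
        trajectory.append(
            {"step": len(selected), "added": best, "mean_auc": best_mean, **best_auc}
        )
    return selected, pd.DataFrame(trajectory)


# ---------------------------------------------------------------------------
# marker gene-set enrichment
# ---------------------------------------------------------------------------


def marker_enrichment(
    zscores: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    z_threshold: float = 0.015,
) -> pd.DataFrame:
    """Fisher's exact test of gene-set membership against per-program
    marker genes (z score strictly above ``z_threshold``), on the shared
    gene universe. The odds ratio is the sample OR ``ad/bc`` (inf when
    ``bc`` is 0)."""
    universe = list(zscores.columns)
    rows = []
    for set_name, genes in gene_sets.items():
        in_set = pd.Index(universe).isin(set(genes))
        if not in_set.any():
            raise ValueError(f"gene set {set_name!r} does not intersect the catalog genes")
        for prog in zscores.index:
            above = (zscores.loc[prog] > z_threshold).to_numpy()
            a = int((in_set & above).sum())
            b = int((~in_set & above).sum())
            c = int((in_set & ~above).sum())
            d = int((~in_set & ~above).sum())
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"program": prog, "gene_set": set_name, "odds_ratio": odds,
                 "p": float(p), "n_overlap": a}
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"])
    return table
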