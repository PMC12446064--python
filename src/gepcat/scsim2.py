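"""Gamma-Poisson single-cell count simulator with GEP mixtures (scsim2).

Counts follow the Splatter generative model: gamma-distributed baseline gene
means with rare lognormal expression outliers, lognormal library sizes, and
per-entry BCV (biological coefficient of variation) inflation turning
Poisson sampling into negative-binomial-like counts.

On top of the count model, every cell expresses exactly one *subset* GEP
(identity program, drawn uniformly) plus zero or more additive *activity*
GEPs: each activity program switches on independently with probability
``p_activity`` and, when on, draws a usage uniformly in
``(activity_low, activity_high)``. If a cell's total activity usage exceeds
``activity_cap`` it is rescaled to sum to exactly the cap, so the subset
program always retains usage above ``1 - activity_cap``. A GEP is a vector
of multiplicative differential-expression factors over genes; a cell's mean
profile is the baseline means times the usage-weighted average of its GEP
factor vectors, rescaled so the cell's expected depth equals its library
size.

Defaults reproduce the published Splatter parameterization of real
single-cell data (median library size exp(7.64) ~ 2079 UMIs, ~5% DE genes
per program).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import CountMatrix


@dataclass
class SimParams:
    """Simulator parameters (Splatter-style count model + GEP mixing)."""

    mean_rate: float = 7.68
    mean_shape: float = 0.34
    libloc: float = 7.64
    libscale: float = 0.78
    expoutprob: float = 0.00286
    expoutloc: float = 6.15
    expoutscale: float = 0.49
    diffexpprob: float = 0.025
    diffexpdownprob: float = 0.025
    diffexploc: float = 1.0
    diffexpscale: float = 1.0
    bcv_dispersion: float = 0.448
    bcv_dof: float = 22.087
    n_genes: int = 10000
    n_subset_geps: int = 10
    n_activity_geps: int = 10
    p_activity: float = 0.3
    activity_low: float = 0.1
    activity_high: float = 0.7
    activity_cap: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_activity <= 1.0:
            raise ValueError("p_activity must be in [0, 1]")
        if not (self.activity_low < self.activity_high <= self.activity_cap < 1.0):
            raise ValueError(
                "require activity_low < activity_high <= activity_cap < 1"
            )

    @property
    def gep_names(self) -> list[str]:
        return [f"Subset{i}" for i in range(self.n_subset_geps)] + [
            f"Activity{i}" for i in range(self.n_activity_geps)
        ]


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator."""

    usage: pd.DataFrame  # cells x GEPs, rows sum to 1
    subset_assignment: pd.Series  # per-cell GEP name
    gep_profiles: pd.DataFrame  # GEPs x genes multiplicative DE factors
    gene_means: pd.Series  # baseline per-gene means
    library_sizes: pd.Series | None = None

    @property
    def subset_names(self) -> list[str]:
        return [g for g in self.usage.columns if g.startswith("Subset")]

    @property
    def activity_names(self) -> list[str]:
        return [g for g in self.usage.columns if g.startswith("Activity")]


def simulate_geps(
    params: SimParams, rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame]:
    """Draw baseline gene means and per-GEP multiplicative factor profiles.

    Gene means are Gamma(shape, rate); with probability ``expoutprob`` a
    gene's mean is replaced by ``median(means) * LogNormal(loc, scale)``.
    Per GEP, each gene is up-regulated with probability ``diffexpprob`` by a
    LogNormal(diffexploc, diffexpscale) factor, or down-regulated with
    probability ``diffexpdownprob`` by its reciprocal; other genes keep
    factor 1.
    """
    g = params.n_genes
    genes = [f"gene{i}" for i in range(g)]
    means = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate, size=g)
    is_out = rng.random(g) < params.expoutprob
    if is_out.any():
        means[is_out] = np.median(means) * rng.lognormal(
            params.expoutloc, params.expoutscale, size=is_out.sum()
        )
    names = params.gep_names
    profiles = np.ones((len(names), g))
    u = rng.random((len(names), g))
    up = u < params.diffexpprob
    down = (u >= params.diffexpprob) & (u < params.diffexpprob + params.diffexpdownprob)
    factors = rng.lognormal(params.diffexploc, params.diffexpscale, size=(len(names), g))
    profiles[up] = factors[up]
    profiles[down] = 1.0 / factors[down]
    return (
        pd.Series(means, index=genes, name="gene_mean"),
        pd.DataFrame(profiles, index=names, columns=genes),
    )


def sample_usages(
    n_cells: int,
    params: SimParams,
    rng: np.random.Generator,
    subset_geps: list[str] | None = None,
    activity_geps: list[str] | None = None,
    cell_prefix: str = "cell",
) -> pd.DataFrame:
    """Sample the per-cell ground-truth usage matrix.

    Returns a cells x GEPs DataFrame whose rows sum to 1 exactly. Columns
    default to all of ``params.gep_names`` but can be restricted (e.g. for
    benchmark datasets that include only part of the GEP universe).
    """
    subset_geps = subset_geps or [f"Subset{i}" for i in range(params.n_subset_geps)]
    activity_geps = (
        activity_geps
        if activity_geps is not None
        else [f"Activity{i}" for i in range(params.n_activity_geps)]
    )
    n_act = len(activity_geps)
    subset_idx = rng.integers(0, len(subset_geps), size=n_cells)
    act = np.zeros((n_cells, n_act))
    if n_act:
        on = rng.random((n_cells, n_act)) < params.p_activity
        vals = rng.uniform(params.activity_low, params.activity_high, size=(n_cells, n_act))
        act = np.where(on, vals, 0.0)
        tot = act.sum(axis=1)
        over = tot > params.activity_cap
        if over.any():
            act[over] *= (params.activity_cap / tot[over])[:, None]
    subset_usage = 1.0 - act.sum(axis=1)
    usage = np.zeros((n_cells, len(subset_geps) + n_act))
    usage[np.arange(n_cells), subset_idx] = subset_usage
    usage[:, len(subset_geps) :] = act
    # one compensation step so row sums are exactly 1 in floating point
    resid = usage.sum(axis=1) - 1.0
    usage[np.arange(n_cells), subset_idx] -= resid
    cells = [f"{cell_prefix}{i}" for i in range(n_cells)]
    return pd.DataFrame(usage, index=cells, columns=list(subset_geps) + list(activity_geps))


def simulate_counts(
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator,
    chunk_size: int = 1000,
) -> CountMatrix:
    """Draw BCV-inflated gamma-Poisson counts for the cells in ``truth``.

    Per cell: the mean profile ``gene_means * (usage @ gep_profiles)`` is
    rescaled so its sum equals the cell's LogNormal library size; per entry
    the dispersion ``b = (bcv_dispersion + 1/sqrt(mean)) * sqrt(dof / chi2)``
    inflates a Gamma mean that a Poisson draw is taken from. Generated in
    cell chunks and stored sparse.
    """
    genes = list(truth.gep_profiles.columns)
    means = truth.gene_means.reindex(genes).to_numpy()
    profiles = truth.gep_profiles.to_numpy()
    usage = truth.usage.to_numpy()
    n = usage.shape[0]
    if truth.library_sizes is None:
        lib = rng.lognormal(params.libloc, params.libscale, size=n)
        truth.library_sizes = pd.Series(lib, index=truth.usage.index, name="library_size")
    lib = truth.library_sizes.to_numpy()
    blocks = []
    for start in range(0, n, chunk_size):
        end = min(start + chunk_size, n)
        mix = usage[start:end] @ profiles  # cells x genes factor mixture
        mean = mix * means[None, :]
        rowsum = mean.sum(axis=1, keepdims=True)
        mean *= lib[start:end, None] / np.maximum(rowsum, 1e-300)
        with np.errstate(divide="ignore"):
            bcv = (params.bcv_dispersion + 1.0 / np.sqrt(np.maximum(mean, 1e-300))) * np.sqrt(
                params.bcv_dof / rng.chisquare(params.bcv_dof, size=mean.shape)
            )
        if params.bcv_dispersion <= 0 and params.bcv_dof == np.inf:
            lam = mean
        else:
            shape = 1.0 / np.square(bcv)
            lam = rng.gamma(shape=shape, scale=mean * np.square(bcv))
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
    X = sp.vstack(blocks, format="csr")
    return CountMatrix(
        values=X,
        feature_ids=genes,
        cell_ids=list(truth.usage.index),
        feature_kind=np.array(["RNA"] * len(genes)),
        cell_meta=pd.DataFrame(
            {
                "batch": "sim",
                "sample": "sim",
                "subset": truth.subset_assignment.to_numpy(),
            },
            index=truth.usage.index,
        ),
    )


def simulate_dataset(
    n_cells: int,
    params: SimParams,
    rng: np.random.Generator | None = None,
    subset_geps: list[str] | None = None,
    activity_geps: list[str] | None = None,
    genes: list[str] | None = None,
    shared: tuple[pd.Series, pd.DataFrame] | None = None,
    cell_prefix: str = "cell",
) -> tuple[CountMatrix, SimTruth]:
    """Convenience: draw GEPs (or reuse ``shared``), sample usages, draw
    counts, optionally restricted to a gene subset."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    gene_means, gep_profiles = shared if shared is not None else simulate_geps(params, rng)
    usage = sample_usages(
        n_cells, params, rng, subset_geps=subset_geps, activity_geps=activity_geps,
        cell_prefix=cell_prefix,
    )
    if genes is not None:
        gene_means = gene_means.loc[genes]
        gep_profiles = gep_profiles.loc[:, genes]
    subset_cols = [c for c in usage.columns if c.startswith("Subset")]
    assignment = usage[subset_cols].idxmax(axis=1)
    truth = SimTruth(
        usage=usage,
        subset_assignment=assignment,
        gep_profiles=gep_profiles.loc[usage.columns],
        gene_means=gene_means,
    )
    counts = simulate_counts(truth, params, rng)
    return counts, truth


@dataclass
class Benchmark:
    """Three datasets from one GEP universe for projection benchmarking."""

    ref_extra: CountMatrix
    ref_missing: CountMatrix
    query: CountMatrix
    truths: dict[str, SimTruth] = field(default_factory=dict)
    gene_subsets: dict[str, list[str]] = field(default_factory=dict)
    gep_sets: dict[str, list[str]] = field(default_factory=dict)


def make_benchmark(
    params: SimParams | None = None,
    n_ref_cells: int = 100_000,
    n_query_cells: int = 20_000,
    gene_keep: int = 9000,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> Benchmark:
    """Build the extra-GEP / missing-GEP projection benchmark.

    From a shared universe of ``n_subset_geps + n_activity_geps`` GEPs over
    ``n_genes`` genes, three datasets are simulated: an *extra-GEP*
    reference containing all GEPs, a *missing-GEP* reference with 6 subset
    and 6 activity GEPs, and a query with 8 subset and 8 activity GEPs; the
    GEP sets are nested (missing c query c extra). Each dataset keeps an
    independent random ``gene_keep``-gene subset of the universe. ``scale``
    shrinks the cell counts proportionally for desk-size runs.
    """
    params = params or SimParams()
    if gene_keep > params.n_genes:
        raise ValueError(f"gene_keep={gene_keep} exceeds n_genes={params.n_genes}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_ref = max(1, int(round(n_ref_cells * scale)))
    n_query = max(1, int(round(n_query_cells * scale)))
    shared = simulate_geps(params, rng)
    subs = [f"Subset{i}" for i in rng.permutation(params.n_subset_geps)]
    acts = [f"Activity{i}" for i in rng.permutation(params.n_activity_geps)]
    gep_sets = {
        "ref_extra": sorted(subs) + sorted(acts),
        "query": sorted(subs[:8]) + sorted(acts[:8]),
        "ref_missing": sorted(subs[:6]) + sorted(acts[:6]),
    }
    all_genes = list(shared[0].index)
    datasets = {}
    truths = {}
    gene_subsets = {}
    for name, n_cells in (
        ("ref_extra", n_ref),
        ("ref_missing", n_ref),
        ("query", n_query),
    ):
        keep_idx = np.sort(rng.choice(params.n_genes, size=gene_keep, replace=False))
        genes = [all_genes[i] for i in keep_idx]
        gene_subsets[name] = genes
        geps = gep_sets[name]
        counts, truth = simulate_dataset(
            n_cells,
            params,
            rng,
            subset_geps=[g for g in geps if g.startswith("Subset")],
            activity_geps=[g for g in geps if g.startswith("Activity")],
            genes=genes,
            shared=shared,
            cell_prefix=f"{name}_cell",
        )
        datasets[name] = counts
        truths[name] = truth
    return Benchmark(
        ref_extra=datasets["ref_extra"],
        ref_missing=datasets["ref_missing"],
        query=datasets["query"],
        truths=truths,
        gene_subsets=gene_subsets,
        gep_sets=gep_sets,
    )
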