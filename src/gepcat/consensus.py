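"""Merging GEPs discovered in multiple datasets into consensus GEPs.

Each dataset contributes its final GEP spectra (TPM units). Spectra are
renormalized to sum to 1e6 and divided gene-wise by that dataset's TP10K
standard deviation; the resulting vectors become graph nodes. Edges connect
pairs that (1) come from different datasets, (2) correlate at Pearson
R > 0.5 on the union of the two datasets' overdispersed genes, and (3) are
mutually among each other's top-7 most correlated GEPs. Edges are then
replayed in decreasing R and sets merged greedily, accepting a merge only
when at least two-thirds of all node pairs in the merged set are connected.
Merged sets (and explicitly retained singletons) are averaged element-wise
on the common gene universe into the final catalog.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import GEPCatalog

logger = logging.getLogger(__name__)


@dataclass
class GEPNode:
    """One dataset-level GEP as a node of the reproducibility graph."""

    vector: pd.Series  # normalized spectrum over that dataset's genes
    dataset_id: str
    name: str
    zscore: pd.Series | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.dataset_id, self.name)


@dataclass
class CorrelationEdge:
    i: int
    j: int
    r: float


@dataclass
class ConsensusSet:
    members: list[int]
    supported_datasets: set = field(default_factory=set)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def normalize_spectra(
    spectra_tpm: pd.DataFrame, tpm_gene_sd: pd.Series, dataset_id: str,
    zscores: pd.DataFrame | None = None,
) -> list[GEPNode]:
    """Renormalize each spectra row to sum to 1e6, then divide each gene by
    its TP10K standard deviation; genes with zero SD are dropped from the
    node vector."""
    nodes = []
    sd = tpm_gene_sd.reindex(spectra_tpm.columns)
    ok = sd.to_numpy() > 0
    for name, row in spectra_tpm.iterrows():
        v = row.to_numpy(dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError(f"all-zero spectrum {dataset_id}/{name}")
        v = v / total * 1e6
        vec = pd.Series(v[ok] / sd.to_numpy()[ok], index=spectra_tpm.columns[ok])
        z = None
        if zscores is not None:
            z = zscores.loc[name]
        nodes.append(GEPNode(vector=vec, dataset_id=dataset_id, name=str(name), zscore=z))
    return nodes


def _pairwise_r(
    nodes: list[GEPNode],
    overdispersed: dict[str, list[str]] | None,
    min_shared_genes: int,
) -> np.ndarray:
    """Pearson correlations for every node pair on the union of the two
    datasets' overdispersed genes, restricted to genes present in both
    vectors. NaN marks pairs with insufficient shared genes (or self)."""
    n = len(nodes)
    R = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = nodes[i], nodes[j]
            shared = gi.vector.index.intersection(gj.vector.index)
            if overdispersed is not None:
                union_od = pd.Index(
                    sorted(
                        set(overdispersed.get(gi.dataset_id, []))
                        | set(overdispersed.get(gj.dataset_id, []))
                    )
                )
                shared = shared.intersection(union_od)
            if len(shared) < min_shared_genes:
                logger.info(
                    "pair (%s/%s, %s/%s) shares %d genes (<%d); no edge possible",
                    gi.dataset_id, gi.name, gj.dataset_id, gj.name,
                    len(shared), min_shared_genes,
                )
                continue
            a = gi.vector.loc[shared].to_numpy()
            b = gj.vector.loc[shared].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            R[i, j] = R[j, i] = float(np.corrcoef(a, b)[0, 1])
    return R


def build_graph(
    nodes: list[GEPNode],
    r_min: float = 0.5,
    top_n: int = 7,
    overdispersed: dict[str, list[str]] | None = None,
    min_shared_genes: int = 20,
    top_pool: str = "all",
) -> list[CorrelationEdge]:
    """Edges between cross-dataset GEP pairs with R above ``r_min`` that are
    mutually within each other's ``top_n`` most correlated GEPs.

    ``top_pool`` controls whether the top-n ranking is computed over all
    other nodes (``"all"``, default) or only cross-dataset candidates
    (``"cross_dataset_only"``); ranking ties are broken by node index.
    """
    n = len(nodes)
    R = _pairwise_r(nodes, overdispersed, min_shared_genes)
    top = []
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i or np.isnan(R[i, j]):
                continue
            if top_pool == "cross_dataset_only" and nodes[j].dataset_id == nodes[i].dataset_id:
                continue
            cand.append(j)
        cand.sort(key=lambda j: (-R[i, j], j))
        top.append(set(cand[:top_n]))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(R[i, j]) or R[i, j] <= r_min:
                continue
            if nodes[i].dataset_id == nodes[j].dataset_id:
                continue
            if j in top[i] and i in top[j]:
                edges.append(CorrelationEdge(i, j, float(R[i, j])))
    return edges


def greedy_merge(
    nodes: list[GEPNode],
    edges: list[CorrelationEdge],
    connectivity_min: float = 2.0 / 3.0,
) -> list[ConsensusSet]:
    """Single greedy pass over edges in decreasing R: merge the two
    containing sets iff at least ``connectivity_min`` of all unordered node
    pairs in the candidate union are connected by an edge. The output is a
    partition of the nodes; failed merges are not retried."""
    def sort_key(e: CorrelationEdge):
        ki = (nodes[e.i].dataset_id, nodes[e.i].name)
        kj = (nodes[e.j].dataset_id, nodes[e.j].name)
        return (-e.r, min(ki, kj), max(ki, kj))

    adj = {(min(e.i, e.j), max(e.i, e.j)) for e in edges}
    parent = {i: i for i in range(len(nodes))}
    members: dict[int, set[int]] = {i: {i} for i in range(len(nodes))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for e in sorted(edges, key=sort_key):
        ri, rj = find(e.i), find(e.j)
        if ri == rj:
            continue
        union = members[ri] | members[rj]
        pairs = len(union) * (len(union) - 1) // 2
        connected = sum(
            1 for a, b in itertools.combinations(sorted(union), 2) if (a, b) in adj
        )
        if connected / pairs >= connectivity_min:
            parent[rj] = ri
            members[ri] = union
            del members[rj]
    out = []
    for root in sorted(members, key=lambda r: min(members[r])):
        ms = sorted(members[root])
        out.append(
            ConsensusSet(
                members=ms,
                supported_datasets={nodes[i].dataset_id for i in ms},
            )
        )
    return out


def finalize_catalog(
    sets: list[ConsensusSet],
    nodes: list[GEPNode],
    overdispersed: dict[str, list[str]],
    full_gene_lists: dict[str, list[str]],
    retain_singletons: list[str] | None = None,
) -> GEPCatalog:
    """Average member vectors of each retained set on the catalog universe.

    The gene universe is the union of per-dataset overdispersed genes
    intersected with every dataset's full gene list. Merged sets are always
    retained; singletons only when named (as ``dataset/name``) in
    ``retain_singletons``. Genes missing from a member vector (zero-SD
    drops) are averaged over the members that carry them.
    """
    retain_singletons = retain_singletons or []
    universe = set().union(*overdispersed.values())
    for genes in full_gene_lists.values():
        universe &= set(genes)
    universe = sorted(universe)
    singleton_names = {
        f"{nodes[s.members[0]].dataset_id}/{nodes[s.members[0]].name}"
        for s in sets
        if s.is_singleton
    }
    unknown = set(retain_singletons) - singleton_names
    if unknown:
        raise ValueError(f"retain_singletons not found among singletons: {sorted(unknown)}")
    spectra_rows, z_rows, names = [], [], []
    for idx, s in enumerate(sets):
        if s.is_singleton:
            node = nodes[s.members[0]]
            if f"{node.dataset_id}/{node.name}" not in retain_singletons:
                continue
            name = f"{node.dataset_id}/{node.name}"
        else:
            name = f"cGEP{len(names)}"
        vecs = pd.DataFrame(
            {i: nodes[i].vector.reindex(universe) for i in s.members}
        )
        spectra_rows.append(vecs.mean(axis=1, skipna=True).fillna(0.0))
        zs = [
            nodes[i].zscore.reindex(universe)
            for i in s.members
            if nodes[i].zscore is not None
        ]
        z_rows.append(
            pd.concat(zs, axis=1).mean(axis=1) if zs else pd.Series(np.nan, index=universe)
        )
        names.append(name)
    spectra = pd.DataFrame(spectra_rows, index=names)
    zscores = pd.DataFrame(z_rows, index=names)
    return GEPCatalog(spectra=spectra, zscores=zscores)


def membership_report(
    sets: list[ConsensusSet], nodes: list[GEPNode], edges: list[CorrelationEdge]
) -> pd.DataFrame:
    """Which dataset GEPs formed each consensus set, with pairwise r."""
    rmap = {(min(e.i, e.j), max(e.i, e.j)): e.r for e in edges}
    rows = []
    for si, s in enumerate(sets):
        rs = [
            rmap[(a, b)]
            for a, b in itertools.combinations(sorted(s.members), 2)
            if (a, b) in rmap
        ]
        rows.append(
            {
                "set": si,
                "n_members": len(s.members),
                "members": ";".join(
                    f"{nodes[i].dataset_id}/{nodes[i].name}" for i in s.members
                ),
                "n_datasets": len(s.supported_datasets),
                "mean_r": float(np.mean(rs)) if rs else np.nan,
            }
        )
    return pd.DataFrame(rows)
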