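"""Core containers and on-disk formats.

Three objects travel through the whole pipeline:

``CountMatrix``
    cells x features nonnegative integer counts (RNA and, optionally, ADT
    surface proteins) plus a per-cell metadata table.
``GEPCatalog``
    a fixed set of gene expression programs (GEPs): an expression-scale
    spectra matrix (programs x genes, SD-normalized TPM units), its z-score
    twin used for marker genes, per-program class labels and named component
    sets for derived scores (e.g. "ASA", "CellCycle").
``UsageMatrix``
    cells x programs nonnegative usages; after normalization every non-zero
    row sums to 1.

Everywhere in this package matrices are cells-in-rows, features-in-columns.
On disk, Matrix Market files follow the CellRanger convention
(features x cells) and are transposed on load; loading never reorders cells
or features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

RNA = "RNA"
ADT = "ADT"
FEATURE_KINDS = (RNA, ADT)

#: legal program classes for a catalog
PROGRAM_CLASSES = (
    "subset",
    "functional",
    "activation",
    "technical",
    "doublet",
    "unassigned",
)

#: default feature-id prefix marking surface proteins
ADT_PREFIX = "AB_"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Cells x features nonnegative integer counts with cell metadata.

    Parameters
    ----------
    values
        ``(n_cells, n_features)`` sparse or dense matrix of nonnegative
        integers.
    feature_ids, cell_ids
        unique string identifiers, order preserved from file.
    feature_kind
        per-feature flag, ``"RNA"`` or ``"ADT"``.
    cell_meta
        table indexed by ``cell_id``; must cover every cell. Conventional
        columns: ``batch``, ``sample``, plus optional condition/label columns.
    """

    values: sp.spmatrix | np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    feature_kind: np.ndarray | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.feature_kind is None:
            self.feature_kind = np.array(
                [ADT if f.startswith(ADT_PREFIX) else RNA for f in self.feature_ids]
            )
        else:
            self.feature_kind = np.asarray(self.feature_kind, dtype=object)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, m = self.values.shape
        if n != len(self.cell_ids) or m != len(self.feature_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.cell_ids, "cell_ids")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integral")
        unknown = set(self.feature_kind) - set(FEATURE_KINDS)
        if unknown:
            raise ValidationError(f"unknown feature kinds: {sorted(unknown)}")
        missing = set(self.cell_ids) - set(self.cell_meta.index.astype(str))
        if missing:
            raise ValidationError(
                f"cell_meta missing {len(missing)} cells, e.g. {sorted(missing)[:3]}"
            )

    # -- conveniences ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_rna(self) -> np.ndarray:
        return np.asarray(self.feature_kind) == RNA

    @property
    def is_adt(self) -> np.ndarray:
        return np.asarray(self.feature_kind) == ADT

    def subset(self, cell_mask=None, feature_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given boolean masks."""
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        fm = (
            np.ones(self.n_features, bool)
            if feature_mask is None
            else np.asarray(feature_mask)
        )
        cells = [c for c, keep in zip(self.cell_ids, cm) if keep]
        return CountMatrix(
            values=self.values[cm][:, fm],
            feature_ids=[f for f, keep in zip(self.feature_ids, fm) if keep],
            cell_ids=cells,
            feature_kind=self.feature_kind[fm],
            cell_meta=self.cell_meta.loc[cells],
        )

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.values.copy(),
            obs=self.cell_meta.loc[self.cell_ids].copy(),
            var=pd.DataFrame(
                {"kind": self.feature_kind}, index=pd.Index(self.feature_ids, name="feature_id")
            ),
        )


@dataclass
class UsageMatrix:
    """Cells x programs nonnegative usage matrix.

    ``values`` is a DataFrame indexed by cell_id with program columns. When
    ``normalized`` every row sums to 1 within 1e-8, except rows listed in
    ``zero_rows`` (cells whose raw usage was all ~0; these are reported, never
    silently renormalized).
    """

    values: pd.DataFrame
    normalized: bool = False
    zero_rows: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = self.values.to_numpy()
        if v.size and v.min() < -1e-12:
            raise ValidationError("usages must be nonnegative")
        if self.normalized and len(self.values):
            sums = v.sum(axis=1)
            ok = np.isclose(sums, 1.0, atol=1e-8) | self.values.index.isin(self.zero_rows)
            if not ok.all():
                bad = self.values.index[~ok][:3].tolist()
                raise ValidationError(f"normalized usage rows do not sum to 1: {bad}")


@dataclass
class GEPCatalog:
    """A fixed catalog of consensus gene expression programs.

    ``spectra`` rows are programs in SD-normalized TPM units (nonnegative);
    ``zscores`` is the marker-gene representation on the same programs/genes.
    ``score_components`` maps a score name (e.g. ``"ASA"``) to the list of
    program names whose summed usage defines the score.
    """

    spectra: pd.DataFrame
    zscores: pd.DataFrame | None = None
    program_class: pd.Series | None = None
    score_components: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.zscores is None:
            self.zscores = pd.DataFrame(
                np.nan, index=self.spectra.index, columns=self.spectra.columns
            )
        if self.program_class is None:
            self.program_class = pd.Series(
                "unassigned", index=self.spectra.index, dtype=object
            )
        self.validate()

    def validate(self) -> None:
        _check_unique(self.spectra.columns, "gene_ids")
        _check_unique(self.spectra.index, "program_names")
        if (self.spectra.to_numpy() < -1e-12).any():
            raise ValidationError("catalog spectra must be nonnegative")
        if not self.zscores.index.equals(self.spectra.index) or not self.zscores.columns.equals(
            self.spectra.columns
        ):
            raise ValidationError("zscores must share spectra's programs and genes")
        bad = set(self.program_class) - set(PROGRAM_CLASSES)
        if bad:
            raise ValidationError(f"program_class outside vocabulary: {sorted(bad)}")
        known = set(self.spectra.index)
        for name, members in self.score_components.items():
            missing = set(members) - known
            if missing:
                raise ValidationError(
                    f"score_components[{name!r}] names unknown programs: {sorted(missing)}"
                )

    @property
    def program_names(self) -> list[str]:
        return list(self.spectra.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.spectra.columns)

    def programs_of_class(self, cls: str) -> list[str]:
        return list(self.program_class.index[self.program_class == cls])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _load_mtx(path: Path, adt_prefix: str) -> CountMatrix:
    # CellRanger layout: matrix.mtx is features x cells with sibling
    # barcodes.tsv and features.tsv; features.tsv may carry a third "kind"
    # column which wins over the prefix heuristic.
    d = path if path.is_dir() else path.parent
    mtx = path if path.suffix == ".mtx" else d / "matrix.mtx"
    feats_f, bcs_f = d / "features.tsv", d / "barcodes.tsv"
    for f in (mtx, feats_f, bcs_f):
        if not f.exists():
            raise FileNotFoundError(f"expected file {f}")
    try:
        values = sp.csr_matrix(scipy.io.mmread(mtx).T)
    except Exception as e:  # malformed MatrixMarket header/body
        raise FormatError(f"cannot parse {mtx}: {e}") from None
    feats = pd.read_csv(feats_f, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bcs_f, sep="\t", header=None, dtype=str)[0].tolist()
    feature_ids = feats[0].tolist()
    if feats.shape[1] >= 3:
        kind = feats[2].to_numpy(dtype=object)
        bad = set(kind) - set(FEATURE_KINDS)
        if bad:
            raise FormatError(f"features.tsv kind column has unknown values: {sorted(bad)}")
    else:
        kind = np.array([ADT if f.startswith(adt_prefix) else RNA for f in feature_ids])
    meta = None
    cells_f = d / "cells.tsv"
    if cells_f.exists():
        meta = pd.read_csv(cells_f, sep="\t", index_col=0, dtype={0: str})
        meta.index = meta.index.astype(str)
    return CountMatrix(values, feature_ids, barcodes, kind, meta)


def _load_tsv(path: Path, adt_prefix: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError("duplicate cell or feature ids in TSV")
    kind = np.array(
        [ADT if str(f).startswith(adt_prefix) else RNA for f in df.columns]
    )
    meta = None
    cells_f = path.parent / "cells.tsv"
    if cells_f.exists():
        meta = pd.read_csv(cells_f, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()), df.columns.tolist(), df.index.astype(str).tolist(), kind, meta
    )


def _load_h5(path: Path, adt_prefix: str) -> CountMatrix:
    with h5py.File(path, "r") as f:
        X = f["X"][...]
        cells = [c.decode() if isinstance(c, bytes) else str(c) for c in f["obs"][...]]
        feats = [g.decode() if isinstance(g, bytes) else str(g) for g in f["var"][...]]
        kind = None
        if "var_kind" in f:
            kind = np.array([k.decode() for k in f["var_kind"][...]], dtype=object)
    if kind is None:
        kind = np.array([ADT if g.startswith(adt_prefix) else RNA for g in feats])
    return CountMatrix(sp.csr_matrix(X), feats, cells, kind)


def load_counts(path, format: str | None = None, adt_prefix: str = ADT_PREFIX) -> CountMatrix:
    """Load a :class:`CountMatrix` from ``mtx`` (CellRanger triple), dense
    ``tsv`` (cells in rows) or an ``h5`` container with /X, /obs, /var.

    A sibling ``cells.tsv`` (first column cell_id) is joined as metadata when
    present. ADT features are recognized by the ``kind`` column of
    features.tsv when available, else by ``adt_prefix``.
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix in (".h5", ".hdf5"):
            format = "h5"
        else:
            format = "tsv"
    loaders = {"mtx": _load_mtx, "tsv": _load_tsv, "h5": _load_h5}
    if format not in loaders:
        raise ValueError(f"unknown format {format!r}")
    return loaders[format](path, adt_prefix)


def save_counts(counts: CountMatrix, path, format: str = "mtx") -> Path:
    """Write a CountMatrix; inverse of :func:`load_counts`."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(counts.values.T))
        pd.DataFrame(
            {0: counts.feature_ids, 1: counts.feature_ids, 2: counts.feature_kind}
        ).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        if counts.cell_meta.shape[1]:
            counts.cell_meta.to_csv(path / "cells.tsv", sep="\t")
        return path
    if format == "tsv":
        df = pd.DataFrame(
            counts.values.toarray(), index=counts.cell_ids, columns=counts.feature_ids
        )
        df.to_csv(path, sep="\t")
        return path
    if format == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=counts.values.toarray())
            f.create_dataset("obs", data=np.array(counts.cell_ids, dtype="S"))
            f.create_dataset("var", data=np.array(counts.feature_ids, dtype="S"))
            f.create_dataset("var_kind", data=np.array(counts.feature_kind, dtype="S"))
        return path
    raise ValueError(f"unknown format {format!r}")


def save_catalog(catalog: GEPCatalog, path) -> Path:
    """Write a catalog as a directory of spectra.tsv + zscores.tsv + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    catalog.spectra.to_csv(path / "spectra.tsv", sep="\t")
    catalog.zscores.to_csv(path / "zscores.tsv", sep="\t")
    meta = {
        "program_class": catalog.program_class.to_dict(),
        "score_components": catalog.score_components,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_catalog(path) -> GEPCatalog:
    """Inverse of :func:`save_catalog`.

    A missing meta.json sidecar raises; a sidecar without score_components
    loads with an empty mapping and a warning.
    """
    path = Path(path)
    spectra_f, z_f, meta_f = path / "spectra.tsv", path / "zscores.tsv", path / "meta.json"
    if not spectra_f.exists():
        raise FileNotFoundError(f"expected catalog spectra at {spectra_f}")
    if not meta_f.exists():
        raise FileNotFoundError(f"expected catalog sidecar at {meta_f}")
    spectra = pd.read_csv(spectra_f, sep="\t", index_col=0)
    zscores = pd.read_csv(z_f, sep="\t", index_col=0) if z_f.exists() else None
    meta = json.loads(meta_f.read_text())
    if "score_components" not in meta:
        warnings.warn(f"{meta_f} lacks score_components; loading with empty mapping")
    return GEPCatalog(
        spectra=spectra,
        zscores=zscores,
        program_class=pd.Series(meta.get("program_class", {})).reindex(spectra.index).fillna(
            "unassigned"
        ),
        score_components=meta.get("score_components", {}),
    )
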