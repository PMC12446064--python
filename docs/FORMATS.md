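# On-disk formats

## Count matrices

* **MTX triple** (directory): `matrix.mtx` in MatrixMarket coordinate
  format, features-by-cells (CellRanger orientation; transposed to
  cells-by-features on load); `features.tsv` with columns id, name and an
  optional third `kind` column (`RNA`/`ADT`) that overrides the `AB_`
  prefix heuristic; `barcodes.tsv` with one cell id per line. An optional
  `cells.tsv` (first column cell id) is joined as cell metadata.
* **Dense TSV**: cells in rows, features in columns, first column cell id.
* **HDF5**: datasets `/X` (cells x features), `/obs` (cell ids), `/var`
  (feature ids), optional `/var_kind`.

Order is always preserved exactly as on disk; integer round-trips are
bitwise.

## Catalogs

A directory with `spectra.tsv` (programs x genes, SD-normalized TPM
units), `zscores.tsv` (same shape, marker-gene z units) and `meta.json`
holding `program_class` (subset / functional / activation / technical /
doublet / unassigned) and `score_components` (score name -> program list,
e.g. `ASA`, `CellCycle`).

## Pipeline outputs

`cnmf finalize` writes `spectra_hvg.tsv`, `spectra_tpm.tsv` (rows sum to
1e6), `spectra_zscore.tsv`, `usages.tsv`, `overdispersed.tsv` and
`tpm_gene_sd.tsv`; `consensus` consumes those directories and writes a
catalog plus `membership.tsv` (which dataset GEPs formed each consensus
program, with mean pairwise correlation). `project` writes a cells x
programs usage TSV (rows sum to 1) and an optional per-cell score table.
Every command writes a `manifest.json` (command, seed, inputs, package
version, wall time) next to its outputs.
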