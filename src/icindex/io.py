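"""Reading, filtering and normalizing single-cell qPCR expression data.

The raw measurement is a quantification cycle (Cq) per (cell, gene, technical
replicate); lower Cq means more transcript.  Preprocessing follows the standard
single-cell qPCR workflow: per-assay limit-of-detection (LOD) cutoffs applied at
the replicate level, median collapse of technical triplicates, per-cell ΔCq
normalization against housekeeping (control) genes, and a detection floor for
non-detects so the resulting matrix is complete.  The product is an
:class:`ExpressionMatrix` — the n cells × m genes log2-scale data matrix X(t)
that every downstream statistic consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a reaction that never crossed the amplification threshold.
NON_DETECT = float("nan")

_CQ_COLUMNS = ("cell", "gene", "replicate", "cq")

META_COLUMNS = ("time_point", "treatment", "fraction")


class FormatError(ValueError):
    """A delimited input file does not have the expected structure."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


@dataclass
class CqTable:
    """Raw quantification cycles with per-assay LOD cutoffs.

    Parameters
    ----------
    records
        One row per (cell, gene, replicate) with columns
        ``cell, gene, replicate, cq``; ``cq`` is NaN for a non-detect.
    lod
        Map gene -> limit-of-detection Cq (the cutoff cycle; replicates at or
        beyond it are treated as non-detects).
    control_genes
        Housekeeping genes used as the per-cell ΔCq reference.
    """

    records: pd.DataFrame
    lod: dict[str, float]
    control_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = [c for c in _CQ_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"Cq table missing required column(s): {missing}")
        rec = self.records
        if (rec["replicate"] < 1).any():
            raise ValidationError("replicate_index must be >= 1")
        cq = rec["cq"].to_numpy(dtype=float)
        detected = ~np.isnan(cq)
        if np.any(cq[detected] <= 0) or np.any(~np.isfinite(cq[detected])):
            raise ValidationError("detected Cq values must be finite and > 0")
        genes = set(rec["gene"])
        absent = genes - set(self.lod)
        if absent:
            raise ValidationError(
                f"gene(s) present in records but absent from LOD map: {sorted(absent)}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.records["gene"]))

    @property
    def cells(self) -> list[str]:
        return sorted(set(self.records["cell"]))


def read_cq_table(path: str | Path, lod_path: str | Path) -> CqTable:
    """Read a delimited Cq table and its LOD sidecar.

    The Cq file needs columns ``cell, gene, replicate, cq`` (case-insensitive;
    an empty ``cq`` field is a non-detect).  The LOD file needs ``gene, lod``.
    An optional ``control`` column in the LOD file (1/0 or true/false) marks
    the housekeeping genes.
    """
    rec = _read_table(path)
    missing = [c for c in _CQ_COLUMNS if c not in rec.columns]
    if missing:
        raise FormatError(f"Cq table {path} missing required column(s): {missing}")
    rec = rec.loc[:, list(_CQ_COLUMNS)].copy()
    rec["cell"] = rec["cell"].astype(str)
    rec["gene"] = rec["gene"].astype(str)
    rec["replicate"] = rec["replicate"].astype(int)
    rec["cq"] = pd.to_numeric(rec["cq"], errors="coerce")

    lod_df = _read_table(lod_path)
    for col in ("gene", "lod"):
        if col not in lod_df.columns:
            raise FormatError(f"LOD file {lod_path} missing required column: {col}")
    lod_df["gene"] = lod_df["gene"].astype(str)
    known = set(rec["gene"])
    unknown = sorted(set(lod_df["gene"]) - known)
    if unknown:
        logger.warning("LOD file lists %d gene(s) absent from the Cq table: %s",
                       len(unknown), unknown)
    lod = dict(zip(lod_df["gene"], lod_df["lod"].astype(float)))
    controls: set[str] = set()
    if "control" in lod_df.columns:
        flags = lod_df["control"].astype(str).str.strip().str.lower()
        controls = set(lod_df.loc[flags.isin({"1", "true", "yes"}), "gene"]) & known
    return CqTable(records=rec, lod=lod, control_genes=controls)


def collapse_replicates(cq: CqTable) -> CqTable:
    """Collapse technical replicates to one Cq per (cell, gene).

    Replicates whose Cq is strictly below (better than) the gene's LOD cutoff
    are kept and their median taken; if no replicate passes, the collapsed
    value is a non-detect.  Idempotent.
    """
    rec = cq.records
    lod = rec["gene"].map(cq.lod).to_numpy(dtype=float)
    vals = rec["cq"].to_numpy(dtype=float)
    passing = rec.assign(cq=np.where(~np.isnan(vals) & (vals < lod), vals, np.nan))
    collapsed = (
        passing.groupby(["cell", "gene"], sort=True)["cq"]
        .median()  # NaN-skipping median over passing replicates
        .reset_index()
    )
    collapsed.insert(2, "replicate", 1)
    return CqTable(records=collapsed, lod=dict(cq.lod), control_genes=set(cq.control_genes))


def normalize_delta_cq(cq: CqTable, floor_margin: float = 1.0) -> "ExpressionMatrix":
    """ΔCq-normalize a replicate-collapsed Cq table into log2 expression.

    Per cell the reference level is the mean Cq of its detected control genes;
    a target gene's expression is ``reference − Cq`` (one cycle ≈ one log2
    unit, higher = more transcript).  Non-detects are imputed just below the
    least detectable level, at ``reference − (LOD + floor_margin)``, and
    flagged in the detect mask.  Cells detecting no target gene and cells with
    no detected control gene are dropped.
    """
    if not cq.control_genes:
        raise ValidationError("ΔCq normalization requires non-empty control_genes")
    rec = cq.records
    if rec.duplicated(["cell", "gene"]).any():
        raise ValidationError("Cq table is not replicate-collapsed (duplicate cell/gene)")

    wide = rec.pivot(index="cell", columns="gene", values="cq")
    controls = sorted(set(cq.control_genes) & set(wide.columns))
    targets = [g for g in wide.columns if g not in cq.control_genes]
    if not controls:
        raise ValidationError("no control gene column present in the Cq table")

    reference = wide[controls].mean(axis=1, skipna=True)
    no_control = reference.isna()
    if no_control.any():
        logger.warning("dropping %d cell(s) with no detected control gene: %s",
                       int(no_control.sum()), list(wide.index[no_control]))
    all_nd = wide[targets].isna().all(axis=1)
    if all_nd.any():
        logger.warning("dropping %d cell(s) expressing no target gene", int(all_nd.sum()))
    keep = ~(no_control | all_nd)
    wide, reference = wide.loc[keep], reference.loc[keep]

    lod = pd.Series({g: cq.lod[g] for g in wide.columns})
    detect = wide.notna()
    expr = reference.to_numpy()[:, None] - wide.to_numpy()
    floor = reference.to_numpy()[:, None] - (lod.to_numpy()[None, :] + floor_margin)
    values = pd.DataFrame(np.where(detect, expr, floor),
                          index=wide.index, columns=wide.columns)

    roles = pd.Series(["control" if g in cq.control_genes else "target" for g in wide.columns],
                      index=wide.columns, name="role")
    meta = pd.DataFrame({c: "" for c in META_COLUMNS}, index=wide.index)
    return ExpressionMatrix(values=values, cell_meta=meta, gene_roles=roles,
                            detect_mask=detect)


@dataclass
class ExpressionMatrix:
    """The n × m log2-scale expression matrix X(t) with cell/gene annotation.

    Rows are cell state vectors S^k, columns are gene vectors g_i.
    ``cell_meta`` carries (time_point, treatment, fraction) per cell;
    ``gene_roles`` marks each gene as ``target`` or ``control``;
    ``detect_mask`` distinguishes measured from floor-imputed entries.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame
    gene_roles: pd.Series
    detect_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(f"expression matrix must be at least 2x2, got {v.shape}")
        if v.index.duplicated().any():
            raise ValidationError("duplicate cell_ids")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate gene_ids")
        if v.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        orphans = [c for c in v.index if c not in self.cell_meta.index]
        if orphans:
            raise ValidationError(f"cell_meta missing cell(s): {orphans}")
        self.cell_meta = self.cell_meta.loc[v.index, :]
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = ""
        missing_roles = [g for g in v.columns if g not in self.gene_roles.index]
        if missing_roles:
            raise ValidationError(f"gene_roles missing gene(s): {missing_roles}")
        self.gene_roles = self.gene_roles.loc[v.columns]
        bad = set(self.gene_roles) - {"target", "control"}
        if bad:
            raise ValidationError(f"invalid gene role(s): {sorted(bad)}")
        if self.detect_mask is None:
            self.detect_mask = pd.DataFrame(True, index=v.index, columns=v.columns)
        else:
            self.detect_mask = self.detect_mask.loc[v.index, v.columns]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def target_genes(self) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == "target"])

    @property
    def control_genes(self) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == "control"])

    def subset(self, cells=None, genes=None) -> "ExpressionMatrix":
        cells = self.cell_ids if cells is None else list(cells)
        genes = self.gene_ids if genes is None else list(genes)
        return ExpressionMatrix(
            values=self.values.loc[cells, genes].copy(),
            cell_meta=self.cell_meta.loc[cells].copy(),
            gene_roles=self.gene_roles.loc[genes].copy(),
            detect_mask=self.detect_mask.loc[cells, genes].copy(),
        )


def _sidecar(path: Path, tag: str) -> Path:
    return path.with_name(path.stem + f".{tag}" + path.suffix)


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix plus metadata/roles/detect sidecars as CSV.

    ``<base>.csv`` holds cells × genes values; sidecars ``<base>.meta.csv``,
    ``<base>.genes.csv`` and ``<base>.detect.csv`` hold the per-cell metadata,
    gene roles and detection mask.  Full float precision is preserved so
    write→read is the identity.
    """
    path = Path(path)
    x.values.to_csv(path, index_label="cell_id", float_format="%.17g")
    x.cell_meta.to_csv(_sidecar(path, "meta"), index_label="cell_id")
    x.gene_roles.rename("role").to_csv(_sidecar(path, "genes"), index_label="gene_id")
    x.detect_mask.astype(int).to_csv(_sidecar(path, "detect"), index_label="cell_id")


def read_expression_matrix(path: str | Path, meta_path: str | Path | None = None,
                           genes_path: str | Path | None = None,
                           detect_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression_matrix`."""
    path = Path(path)
    values = pd.read_csv(path, index_col=0, sep=_sniff_delimiter(path),
                         float_precision="round_trip")
    values.index = values.index.astype(str)

    meta_path = Path(meta_path) if meta_path else _sidecar(path, "meta")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta = pd.read_csv(meta_path, index_col=0, dtype=str, keep_default_na=False)
    meta.index = meta.index.astype(str)
    orphans = [c for c in values.index if c not in meta.index]
    if orphans:
        raise ValidationError(f"metadata rows missing for cell(s): {orphans}")

    genes_path = Path(genes_path) if genes_path else _sidecar(path, "genes")
    if genes_path.exists():
        roles = pd.read_csv(genes_path, index_col=0)["role"].astype(str)
        roles.index = roles.index.astype(str)
    else:
        roles = pd.Series("target", index=values.columns)

    detect_path = Path(detect_path) if detect_path else _sidecar(path, "detect")
    detect = None
    if detect_path.exists():
        detect = pd.read_csv(detect_path, index_col=0).astype(bool)
        detect.index = detect.index.astype(str)
    return ExpressionMatrix(values=values, cell_meta=meta, gene_roles=roles,
                            detect_mask=detect)
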