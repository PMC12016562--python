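"""Trans and cis predictor construction and data-cleaning rules.

Expression matrices are genes x cells DataFrames; feature matrices handed to
the models are observations x features.  Transformers follow the sklearn
estimator contract (``fit``/``transform``, fitted attributes with a trailing
underscore) so they compose in pipelines; the module-level functions are thin
wrappers for one-shot use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MissingValueFilter",
    "CellQCFilter",
    "ExpressionNormalizer",
    "TransFeatureSelector",
    "CisFeatureEncoder",
    "OrthologMapper",
    "filter_missing",
    "qc_filter_cells",
    "normalize_expression",
    "build_trans_features",
    "build_cis_features",
    "map_orthologs",
    "read_regulator_list",
]


class MissingValueFilter(BaseEstimator, TransformerMixin):
    """Drop rows, then columns, whose missing fraction exceeds ``max_frac``.

    Fractions are computed on the matrix seen at ``fit`` time, before any
    dropping, so the row and column decisions are symmetric; the boundary is
    strict (exactly ``max_frac`` missing is retained).  The operation is
    idempotent.
    """

    def __init__(self, max_frac: float = 0.10):
        self.max_frac = max_frac

    def fit(self, X: pd.DataFrame, y=None):
        if X.empty:
            raise ValueError("matrix is empty")
        na = X.isna()
        row_frac = na.mean(axis=1)
        col_frac = na.mean(axis=0)
        self.dropped_rows_ = list(X.index[row_frac > self.max_frac])
        self.dropped_cols_ = list(X.columns[col_frac > self.max_frac])
        if len(self.dropped_rows_) == len(X.index) or \
                len(self.dropped_cols_) == len(X.columns):
            raise ValueError("missing-value filter would drop everything")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.drop(index=[r for r in self.dropped_rows_ if r in X.index],
                      columns=[c for c in self.dropped_cols_ if c in X.columns])


class CellQCFilter(BaseEstimator, TransformerMixin):
    """Single-cell QC on a genes x cells raw count matrix.

    Cells are kept only when strictly inside the detected-gene and total-count
    windows and strictly below the mitochondrial-percentage cap; genes seen in
    fewer than ``min_cells_per_gene`` remaining cells are then removed.
    Mitochondrial genes default to those named with an ``MT-`` prefix.
    """

    def __init__(self, min_features: int = 200, max_features: int = 4000,
                 min_counts: int = 200, max_counts: int = 20000,
                 max_pct_mito: float = 25.0, min_cells_per_gene: int = 3,
                 min_genes_per_cell: int = 200, mito_genes=None):
        self.min_features = min_features
        self.max_features = max_features
        self.min_counts = min_counts
        self.max_counts = max_counts
        self.max_pct_mito = max_pct_mito
        self.min_cells_per_gene = min_cells_per_gene
        self.min_genes_per_cell = min_genes_per_cell
        self.mito_genes = mito_genes

    def fit(self, X: pd.DataFrame, y=None):
        if (X.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        mito = (list(self.mito_genes) if self.mito_genes is not None
                else [g for g in X.index if str(g).upper().startswith("MT-")])
        n_features = (X > 0).sum(axis=0)
        n_counts = X.sum(axis=0)
        totals = n_counts.replace(0, np.nan)
        pct_mito = 100.0 * X.loc[X.index.intersection(mito)].sum(axis=0) / totals
        pct_mito = pct_mito.fillna(0.0)
        keep = ((n_features > self.min_features)
                & (n_features < self.max_features)
                & (n_features >= self.min_genes_per_cell)
                & (n_counts > self.min_counts)
                & (n_counts < self.max_counts)
                & (pct_mito < self.max_pct_mito))
        self.kept_cells_ = list(X.columns[keep])
        if not self.kept_cells_:
            raise ValueError("QC removed every cell")
        expressed = (X[self.kept_cells_] > 0).sum(axis=1)
        self.kept_genes_ = list(X.index[expressed >= self.min_cells_per_gene])
        if not self.kept_genes_:
            raise ValueError("QC removed every gene")
        self.qc_metrics_ = pd.DataFrame(
            {"n_features": n_features, "n_counts": n_counts,
             "pct_mito": pct_mito, "kept": keep})
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.kept_genes_, self.kept_cells_]


class ExpressionNormalizer(BaseEstimator, TransformerMixin):
    """Per-cell library-size normalization to ``scale_factor`` plus log1p.

    Each cell's counts are scaled to sum to ``scale_factor`` (10,000 by
    default) and natural-log1p transformed, preserving within-cell gene
    rank order.
    """

    def __init__(self, scale_factor: float = 1e4):
        self.scale_factor = scale_factor

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.sum(axis=0)
        if (totals == 0).any():
            bad = list(X.columns[totals == 0])
            raise ValueError(f"zero-total cells cannot be normalized: {bad[:5]}")
        return np.log1p(X / totals * self.scale_factor)


class TransFeatureSelector(BaseEstimator, TransformerMixin):
    """Restrict a genes x cells matrix to a regulator panel, as cells x panel.

    Columns follow the panel's order.  Regulators absent from the expression
    matrix become zero columns and are recorded in ``missing_regulators_`` so
    the imputation stays auditable.
    """

    def __init__(self, regulators=()):
        self.regulators = regulators

    def fit(self, X: pd.DataFrame, y=None):
        regs = list(self.regulators)
        if not regs:
            raise ValueError("regulator set is empty")
        if len(set(regs)) != len(regs):
            raise ValueError("regulator ids must be unique")
        present = [r for r in regs if r in X.index]
        if not present:
            raise ValueError("no regulator from the panel found in expression")
        self.missing_regulators_ = [r for r in regs if r not in X.index]
        self.feature_names_ = regs
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.reindex(self.feature_names_).fillna(0.0).T
        out.columns.name = None
        return out


class CisFeatureEncoder(BaseEstimator, TransformerMixin):
    """Encode per-site sequence context from position probability matrices.

    ``mode='flatten'`` emits each site's 4 x L PPM as a row-major 4L vector
    (all PPMs must share L).  ``mode='score'`` scans each site's sequence with
    every motif PPM and emits the maximum log2 likelihood ratio against a
    uniform background, one feature per motif.
    """

    BASES = ("A", "C", "G", "U")

    def __init__(self, mode: str = "flatten", ppms=None, floor: float = 1e-6):
        self.mode = mode
        self.ppms = ppms
        self.floor = floor

    def fit(self, X=None, y=None):
        if self.mode not in ("flatten", "score"):
            raise ValueError("mode must be 'flatten' or 'score'")
        if self.mode == "score":
            if not self.ppms:
                raise ValueError("score mode requires motif PPMs")
            self.motif_ids_ = [p.attrs.get("motif_id", f"motif_{i:03d}")
                               for i, p in enumerate(self.ppms)]
        return self

    def transform(self, X) -> pd.DataFrame:
        """``X``: dict site_id -> PPM (flatten) or site_id -> sequence (score)."""
        if self.mode == "flatten":
            lengths = {ppm.shape[1] for ppm in X.values()}
            if len(lengths) > 1:
                raise ValueError(f"ragged PPM lengths in flatten mode: {lengths}")
            L = lengths.pop()
            cols = [f"{b}{i}" for b in self.BASES for i in range(L)]
            rows = {site: np.asarray(ppm, float).ravel()
                    for site, ppm in X.items()}
            return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        rows = {site: [self.scan_score(seq, ppm) for ppm in self.ppms]
                for site, seq in X.items()}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=self.motif_ids_)

    def scan_score(self, seq: str, ppm: pd.DataFrame) -> float:
        """Best log2 likelihood-ratio of the motif over a uniform background."""
        seq = seq.upper().replace("T", "U")
        p = np.maximum(np.asarray(ppm, float), self.floor)
        L = p.shape[1]
        if len(seq) < L:
            raise ValueError(f"sequence shorter than motif length {L}")
        idx = np.array([self.BASES.index(b) if b in self.BASES else -1
                        for b in seq])
        llr = np.log2(p / 0.25)
        best = -np.inf
        for o in range(len(seq) - L + 1):
            window = idx[o:o + L]
            if (window < 0).any():
                continue
            best = max(best, float(llr[window, np.arange(L)].sum()))
        if not np.isfinite(best):
            raise ValueError("sequence contains no scannable window")
        return best


class OrthologMapper(BaseEstimator, TransformerMixin):
    """Relabel a genes x cells matrix through a many-to-one ortholog table.

    Unmapped source genes are dropped (ids kept in ``dropped_genes_``);
    several sources mapping to one target are aggregated (sum by default,
    counts being additive; max by flag).  With ``log_transform`` the result
    is log1p-harmonized so matrices from different quantification scales can
    be compared.
    """

    def __init__(self, mapping: pd.DataFrame | None = None,
                 agg: str = "sum", log_transform: bool = True):
        self.mapping = mapping
        self.agg = agg
        self.log_transform = log_transform

    def fit(self, X: pd.DataFrame, y=None):
        if self.mapping is None or len(self.mapping) == 0:
            raise ValueError("ortholog mapping is empty")
        if self.agg not in ("sum", "max"):
            raise ValueError("agg must be 'sum' or 'max'")
        m = self.mapping.iloc[:, :2]
        m.columns = ["source", "target"]
        if m["source"].duplicated().any():
            raise ValueError("mapping must be many-to-one (duplicate sources)")
        self.map_ = dict(zip(m["source"], m["target"]))
        self.dropped_genes_ = [g for g in X.index if g not in self.map_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept = X.loc[[g for g in X.index if g in self.map_]]
        targets = [self.map_[g] for g in kept.index]
        out = kept.groupby(pd.Index(targets, name=None), sort=True)
        out = out.sum() if self.agg == "sum" else out.max()
        if self.log_transform:
            out = np.log1p(out)
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers


def filter_missing(matrix: pd.DataFrame, max_frac: float = 0.10):
    """Drop rows/columns with > ``max_frac`` missing; return (matrix, report)."""
    f = MissingValueFilter(max_frac).fit(matrix)
    return f.transform(matrix), {"dropped_rows": f.dropped_rows_,
                                 "dropped_cols": f.dropped_cols_}


def qc_filter_cells(counts: pd.DataFrame, mito_genes=None, cfg=None):
    """Apply single-cell QC; ``cfg`` is a :class:`scm6a.config.QCConfig`."""
    from .config import QCConfig

    cfg = cfg or QCConfig()
    f = CellQCFilter(mito_genes=mito_genes,
                     **{k: getattr(cfg, k) for k in (
                         "min_features", "max_features", "min_counts",
                         "max_counts", "max_pct_mito", "min_cells_per_gene",
                         "min_genes_per_cell")}).fit(counts)
    return f.transform(counts)


def normalize_expression(counts: pd.DataFrame,
                         scale_factor: float = 1e4) -> pd.DataFrame:
    return ExpressionNormalizer(scale_factor).fit(counts).transform(counts)


def build_trans_features(expr: pd.DataFrame, regulators) -> pd.DataFrame:
    """Cells x regulators feature matrix; missing regulators imputed as 0."""
    sel = TransFeatureSelector(regulators).fit(expr)
    out = sel.transform(expr)
    if sel.missing_regulators_:
        warnings.warn(f"{len(sel.missing_regulators_)} regulators absent from "
                      "expression; filled with 0", stacklevel=2)
    return out


def build_cis_features(ppms_per_site=None, mode: str = "flatten",
                       site_sequences=None, motif_ppms=None) -> pd.DataFrame:
    """Per-site cis features: flattened PPMs or motif-scan scores."""
    enc = CisFeatureEncoder(mode=mode, ppms=motif_ppms).fit()
    return enc.transform(ppms_per_site if mode == "flatten" else site_sequences)


def map_orthologs(expr: pd.DataFrame, mapping: pd.DataFrame,
                  agg: str = "sum", log_transform: bool = True):
    """Convert gene ids across species; return (matrix, report)."""
    m = OrthologMapper(mapping, agg=agg, log_transform=log_transform).fit(expr)
    return m.transform(expr), {"dropped_genes": m.dropped_genes_}


def read_regulator_list(path) -> list[str]:
    """One regulator id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    if not out:
        raise ValueError(f"regulator list {path} is empty")
    return out
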