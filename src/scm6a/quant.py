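"""Winscore-based m6A quantification from paired IP/input window counts.

The pipeline: tile each transcript with overlapping sliding windows, compute
RPKM per window in the IP and input libraries, add a pseudo-count of 1 RPKM to
both (guarding against unreliable ratios in poorly covered windows), take the
IP/input ratio (the winscore), call windows whose winscore strictly exceeds
the cutoff, merge consecutive significant windows within a gene into peaks,
and split merged peaks so none spans more than ``max_windows_per_peak``
windows.  Peak-level m6A is the mean (or max) winscore over member windows.

Coordinates are 0-based half-open throughout; BED on disk.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QuantConfig

__all__ = [
    "WindowCountTable",
    "Peak",
    "make_windows",
    "rpkm",
    "winscore",
    "call_merge_split",
    "peak_levels",
    "quantify_sample",
    "tpm_quantile_normalize",
    "match_windows",
    "peaks_to_bed",
    "parse_site_id",
]

WINDOW_COLS = ["chrom", "start", "end", "gene_id", "strand"]


@dataclass
class WindowCountTable:
    """Per-window read counts plus the library's total mapped reads.

    ``df`` has columns chrom, start, end, gene_id, strand, count and an
    integer ``window_index`` giving each window's ordinal position in its
    transcript's sliding grid (consecutiveness is defined on this index).
    """

    df: pd.DataFrame
    library_size: int

    def __post_init__(self) -> None:
        missing = [c for c in WINDOW_COLS + ["count"] if c not in self.df.columns]
        if missing:
            raise ValueError(f"window table missing columns: {missing}")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(self.df) and int(self.df["count"].max()) > self.library_size:
            raise ValueError("library_size smaller than a window count")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# library_size={self.library_size}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WindowCountTable":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            m = re.match(r"#\s*library_size=(\d+)", first)
            if not m:
                raise ValueError(
                    f"{path}: expected '# library_size=N' header line")
            df = pd.read_csv(fh, sep="\t")
        return cls(df, int(m.group(1)))


@dataclass
class Peak:
    """A run of consecutive significant windows within one gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    window_rows: np.ndarray  # positional row indices into the window grid
    strand: str = "+"

    @property
    def site_id(self) -> str:
        return f"{self.gene_id}:{self.start}-{self.end}"


def make_windows(annotation: pd.DataFrame, cfg: QuantConfig | None = None,
                 ) -> pd.DataFrame:
    """Sliding-window grid over each annotated transcript.

    Full windows start at offsets 0, step, 2*step, ...; a trailing partial
    window is appended when the full grid does not reach the transcript end
    and the partial is at least ``step`` wide.  A 300-bp transcript therefore
    yields exactly five 100/50 windows whose union spans it.
    """
    cfg = cfg or QuantConfig()
    if annotation.empty:
        raise ValueError("annotation has no transcripts")
    if "length" in annotation.columns:
        lengths = annotation["length"].astype(int)
    else:
        lengths = annotation[["utr5_len", "cds_len", "utr3_len"]].sum(axis=1)
    rows = []
    for (_, tx), length in zip(annotation.iterrows(), lengths):
        length = int(length)
        if length < cfg.step:
            raise ValueError(
                f"transcript {tx.transcript_id} (length {length}) shorter "
                f"than step {cfg.step}")
        strand = tx.get("strand", "+")
        tx_rows = []
        offset = 0
        while offset + cfg.window_size <= length:
            tx_rows.append((tx.transcript_id, offset, offset + cfg.window_size,
                            tx.gene_id, strand, len(tx_rows)))
            offset += cfg.step
        last_end = tx_rows[-1][2] if tx_rows else 0
        if last_end < length and length - offset >= cfg.step:
            # trailing partial window reaching the transcript end
            tx_rows.append((tx.transcript_id, offset, length,
                            tx.gene_id, strand, len(tx_rows)))
        elif not tx_rows:
            # transcript shorter than one window but >= step: single window
            tx_rows.append((tx.transcript_id, 0, length, tx.gene_id, strand, 0))
        rows.extend(tx_rows)
    return pd.DataFrame(rows, columns=WINDOW_COLS + ["window_index"])


def rpkm(table: WindowCountTable) -> np.ndarray:
    """Reads per kilobase per million mapped reads, per window."""
    width = (table.df["end"] - table.df["start"]).to_numpy(float)
    if (width <= 0).any():
        raise ValueError("zero-width window")
    return table.df["count"].to_numpy(float) / (
        (width / 1_000.0) * (table.library_size / 1_000_000.0))


def winscore(ip_rpkm: np.ndarray, input_rpkm: np.ndarray,
             cfg: QuantConfig | None = None,
             gene_ids: np.ndarray | None = None) -> np.ndarray:
    """Pseudo-count-adjusted IP/input RPKM ratio per window.

    With ``gene_median_norm`` each library's adjusted RPKM is first divided
    by its within-gene median (the original winscore normalization); the
    default is the plain adjusted ratio.
    """
    cfg = cfg or QuantConfig()
    ip_rpkm = np.asarray(ip_rpkm, float)
    input_rpkm = np.asarray(input_rpkm, float)
    if ip_rpkm.shape != input_rpkm.shape:
        raise ValueError("IP and input RPKM vectors are misaligned")
    ip_adj = ip_rpkm + cfg.pseudo_rpkm
    in_adj = input_rpkm + cfg.pseudo_rpkm
    if cfg.gene_median_norm:
        if gene_ids is None:
            raise ValueError("gene_median_norm requires gene_ids")
        gene_ids = np.asarray(gene_ids)
        s = pd.Series(ip_adj)
        ip_adj = (s / s.groupby(gene_ids).transform("median")).to_numpy()
        s = pd.Series(in_adj)
        in_adj = (s / s.groupby(gene_ids).transform("median")).to_numpy()
    return ip_adj / in_adj


def call_merge_split(windows: pd.DataFrame, winscores: np.ndarray,
                     cfg: QuantConfig | None = None) -> list[Peak]:
    """Call significant windows, merge consecutive runs, split long peaks.

    Windows with winscore strictly above ``winscore_cutoff`` are grouped into
    maximal runs of consecutive grid positions within the same transcript;
    runs longer than ``max_windows_per_peak`` are chunked greedily left to
    right, so a run of k windows yields ceil(k / max) peaks.
    """
    cfg = cfg or QuantConfig()
    winscores = np.asarray(winscores, float)
    if len(winscores) != len(windows):
        raise ValueError("winscores misaligned with window grid")
    sig = winscores > cfg.winscore_cutoff
    peaks: list[Peak] = []
    if not sig.any():
        return peaks
    df = windows.reset_index(drop=True)
    sig_rows = np.flatnonzero(sig)
    sub = df.iloc[sig_rows]
    for chrom, grp in sub.groupby("chrom", sort=False):
        rows_grp = grp.index.to_numpy()
        order = np.argsort(grp["window_index"].to_numpy(), kind="stable")
        rows = rows_grp[order]
        widx = grp["window_index"].to_numpy()[order]
        # maximal consecutive runs in the sliding grid
        breaks = np.flatnonzero(np.diff(widx) != 1) + 1
        for run in np.split(np.arange(len(widx)), breaks):
            members = rows[run]
            for i in range(0, len(members), cfg.max_windows_per_peak):
                chunk = members[i:i + cfg.max_windows_per_peak]
                peaks.append(Peak(
                    gene_id=df.at[chunk[0], "gene_id"],
                    chrom=chrom,
                    start=int(df.loc[chunk, "start"].min()),
                    end=int(df.loc[chunk, "end"].max()),
                    window_rows=chunk,
                    strand=df.at[chunk[0], "strand"],
                ))
    return peaks


def peak_levels(peaks: list[Peak], winscore_matrix: pd.DataFrame,
                cfg: QuantConfig | None = None) -> pd.DataFrame:
    """Peak x sample m6A-level matrix from per-window winscores.

    ``winscore_matrix`` is windows x samples, rows positionally aligned with
    the window grid the peaks were called on.  The peak level is the mean
    (default) or max of its member windows' winscores, per sample.
    """
    cfg = cfg or QuantConfig()
    n_windows = winscore_matrix.shape[0]
    values = winscore_matrix.to_numpy(float)
    rows = []
    ids = []
    for pk in peaks:
        if pk.window_rows.max(initial=-1) >= n_windows:
            raise ValueError(f"peak {pk.site_id} references unknown windows")
        member = values[pk.window_rows]
        rows.append(member.max(axis=0) if cfg.peak_level_stat == "max"
                    else member.mean(axis=0))
        ids.append(pk.site_id)
    return pd.DataFrame(rows, index=ids, columns=winscore_matrix.columns)


def quantify_sample(ip: WindowCountTable, input_: WindowCountTable,
                    cfg: QuantConfig | None = None):
    """One-sample winscore pipeline: counts -> (peaks, peak levels, winscores)."""
    cfg = cfg or QuantConfig()
    if not ip.df[WINDOW_COLS].reset_index(drop=True).equals(
            input_.df[WINDOW_COLS].reset_index(drop=True)):
        raise ValueError("IP and input tables use different window grids")
    ws = winscore(rpkm(ip), rpkm(input_), cfg,
                  gene_ids=ip.df["gene_id"].to_numpy())
    peaks = call_merge_split(ip.df, ws, cfg)
    ws_mat = pd.DataFrame({"sample": ws})
    levels = peak_levels(peaks, ws_mat, cfg)
    return peaks, levels, ws


def tpm_quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    After normalization every column's sorted values equal the per-rank means
    of the sorted input columns; ties map to the average of their ranks'
    reference values (limma's normalizeQuantiles behaviour).
    """
    if expr.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning "
                      "input unchanged", stacklevel=2)
        return expr.copy()
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    x = expr.to_numpy(float)
    ref = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = pd.Series(x[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = ref[lo] * (1 - frac) + ref[np.minimum(hi, n - 1)] * frac
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


_SITE_RE = re.compile(r"^(?P<gene>.+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_site_id(site_id: str) -> tuple[str, int, int]:
    """Split a 'gene:start-end' row id into its parts."""
    m = _SITE_RE.match(site_id)
    if not m:
        raise ValueError(f"malformed site id {site_id!r}")
    return m.group("gene"), int(m.group("start")), int(m.group("end"))


def match_windows(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                  min_overlap_frac: float = 0.0,
                  ) -> list[tuple[str, str, int]]:
    """Greedily pair rows of two peak matrices by genomic overlap.

    Row ids must be 'gene:start-end'.  Candidate pairs share a gene and
    overlap by more than ``min_overlap_frac`` of the shorter span (0 = any
    positive overlap).  Pairs are accepted in decreasing overlap length, each
    row used at most once; ties break on lexicographic id order.

    Returns ``(row_a, row_b, overlap_bp)`` tuples.
    """
    parsed_a = [parse_site_id(r) for r in matrix_a.index]
    parsed_b = [parse_site_id(r) for r in matrix_b.index]
    by_gene_b: dict[str, list[int]] = {}
    for j, (g, _, _) in enumerate(parsed_b):
        by_gene_b.setdefault(g, []).append(j)
    candidates = []
    for i, (g, sa, ea) in enumerate(parsed_a):
        for j in by_gene_b.get(g, ()):
            _, sb, eb = parsed_b[j]
            ov = min(ea, eb) - max(sa, sb)
            if ov <= 0:
                continue
            shorter = min(ea - sa, eb - sb)
            if shorter > 0 and ov / shorter <= min_overlap_frac and \
                    min_overlap_frac > 0:
                continue
            candidates.append((ov, matrix_a.index[i], matrix_b.index[j]))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for ov, ra, rb in candidates:
        if ra in used_a or rb in used_b:
            continue
        used_a.add(ra)
        used_b.add(rb)
        pairs.append((ra, rb, ov))
    return pairs


def peaks_to_bed(peaks: list[Peak], levels: pd.DataFrame,
                 path: str | Path) -> None:
    """Write peaks as BED6; score = mean winscore x 100 capped at 1000."""
    with open(path, "w") as fh:
        for pk in peaks:
            mean_ws = float(levels.loc[pk.site_id].mean())
            score = min(int(round(mean_ws * 100)), 1000)
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.site_id}\t"
                     f"{score}\t{pk.strand}\n")
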