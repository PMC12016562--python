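"""Synthetic data with the statistical structure the predictor assumes.

The generators plant a sparse regulator-to-site network: each m6A site is
driven by a handful of trans regulators through an affine model on log1p
expression, with Gaussian noise and clipping at zero (methylation levels are
nonnegative enrichment scores).  A parallel arm emulates m6A-seq: Poisson read
counts per sliding window in paired IP/input libraries, with the IP rate
multiplied by a fold factor inside planted peak spans.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .quant import make_windows
from .config import QuantConfig

__all__ = [
    "PlantedNetwork",
    "make_planted_network",
    "gen_regulator_expression",
    "gen_m6a_levels",
    "gen_annotation",
    "gen_peak_spans",
    "gen_window_counts",
    "gen_ppms",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "U", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
BASES = ("A", "C", "G", "U")


@dataclass
class PlantedNetwork:
    """Sparse ground-truth map from regulators to m6A sites.

    ``regulators[s]`` lists the column indices of the regulators driving site
    ``s``; ``coefs[s]`` the matching coefficients on log1p expression;
    ``intercepts[s]`` the site baseline.  Intercepts carry an offset
    proportional to the negative-coefficient mass so that simulated levels
    stay positive (the zero clip in :func:`gen_m6a_levels` is a safeguard,
    essentially never active at default settings).
    """

    regulators: list[np.ndarray]
    coefs: list[np.ndarray]
    intercepts: np.ndarray
    noise_sd: float

    @property
    def n_sites(self) -> int:
        return len(self.regulators)

    def max_regulator_index(self) -> int:
        return max(int(r.max()) for r in self.regulators if r.size)


def make_planted_network(cfg: SimConfig) -> PlantedNetwork:
    """Draw a sparse planted network under ``cfg``."""
    rng = np.random.default_rng(cfg.seed + 1)
    regulators, coefs = [], []
    intercepts = np.empty(cfg.n_sites)
    for s in range(cfg.n_sites):
        regs = rng.choice(cfg.n_regulators, size=cfg.regulators_per_site,
                          replace=False)
        c = rng.normal(0.0, cfg.effect_size_sd, size=cfg.regulators_per_site)
        # offset baseline by the negative-effect mass times a high-typical
        # log1p expression value (~mean + 1.4 sd) to keep levels positive
        offset = 3.0 * np.maximum(0.0, -c).sum()
        intercepts[s] = rng.uniform(1.0, 3.0) + offset
        regulators.append(np.sort(regs))
        coefs.append(c[np.argsort(regs)])
    return PlantedNetwork(regulators, coefs, intercepts, cfg.noise_sd)


def gen_regulator_expression(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a cells x regulators expression matrix.

    Marginals are log-normal (``exp(Normal(log_mean, log_sd))``), emulating
    the heavy right tail of TPM-scale expression.  Optional dropout zeroes a
    Bernoulli(``dropout_rate``) subset of entries (off by default).
    """
    rng = np.random.default_rng(cfg.seed)
    expr = rng.lognormal(cfg.log_mean, cfg.log_sd,
                         size=(cfg.n_cells, cfg.n_regulators))
    if cfg.dropout_rate > 0:
        expr *= rng.random(expr.shape) >= cfg.dropout_rate
    cells = [f"cell_{i:05d}" for i in range(cfg.n_cells)]
    regs = [f"REG{j:04d}" for j in range(cfg.n_regulators)]
    return pd.DataFrame(expr, index=cells, columns=regs)


def linear_predictor(expr: pd.DataFrame | np.ndarray,
                     net: PlantedNetwork) -> np.ndarray:
    """Noise-free site x cell linear part: intercept + sum coef * log1p(expr)."""
    x = np.log1p(np.asarray(expr, dtype=float))
    n_cells = x.shape[0]
    y = np.empty((net.n_sites, n_cells))
    for s in range(net.n_sites):
        if net.regulators[s].size and net.regulators[s].max() >= x.shape[1]:
            raise IndexError(
                f"site {s} references regulator index {net.regulators[s].max()} "
                f"but expression has {x.shape[1]} regulators"
            )
        y[s] = net.intercepts[s] + x[:, net.regulators[s]] @ net.coefs[s]
    return y


def gen_m6a_levels(expr: pd.DataFrame, net: PlantedNetwork,
                   seed: int = 0) -> pd.DataFrame:
    """Ground-truth m6A levels: planted linear model plus noise, clipped at 0.

    Returns a sites x cells DataFrame aligned with ``expr``'s rows (cells).
    """
    rng = np.random.default_rng(seed + 2)
    y = linear_predictor(expr, net)
    if net.noise_sd > 0:
        y = y + rng.normal(0.0, net.noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)
    sites = [f"site_{s:04d}" for s in range(net.n_sites)]
    cells = list(expr.index) if isinstance(expr, pd.DataFrame) else [
        f"cell_{i:05d}" for i in range(y.shape[1])]
    return pd.DataFrame(y, index=sites, columns=cells)


def gen_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Per-transcript 5'UTR/CDS/3'UTR lengths (transcript coordinates).

    Region lengths are drawn around typical mRNA proportions (short 5'UTR,
    long CDS, intermediate 3'UTR) and rounded to multiples of the default
    50-bp step so that planted peaks align with window boundaries.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n = cfg.n_transcripts
    u5 = 50 * np.maximum(2, rng.poisson(4, n))          # ~200 bp
    cds = 50 * np.maximum(6, rng.poisson(20, n))        # ~1000 bp
    u3 = 50 * np.maximum(4, rng.poisson(12, n))         # ~600 bp
    return pd.DataFrame({
        "transcript_id": [f"tx_{i:04d}" for i in range(n)],
        "gene_id": [f"GENE{i:04d}" for i in range(n)],
        "utr5_len": u5,
        "cds_len": cds,
        "utr3_len": u3,
        "strand": rng.choice(["+", "-"], n),
    })


def gen_peak_spans(annotation: pd.DataFrame, cfg: SimConfig,
                   peak_len: int = 300, frac_transcripts: float = 0.4,
                   ) -> pd.DataFrame:
    """Plant one peak span per selected transcript, biased toward the CDS end.

    Spans are aligned to 50-bp boundaries and clipped to the transcript.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    rows = []
    for _, tx in annotation.iterrows():
        if rng.random() > frac_transcripts:
            continue
        total = int(tx.utr5_len + tx.cds_len + tx.utr3_len)
        if total < peak_len + 100:
            continue
        # centre near the stop codon, the canonical m6A hotspot
        centre = int(tx.utr5_len + tx.cds_len)
        centre += int(rng.normal(0, 150))
        start = 50 * ((centre - peak_len // 2) // 50)
        start = min(max(start, 0), total - peak_len)
        rows.append({"transcript_id": tx.transcript_id,
                     "gene_id": tx.gene_id,
                     "start": int(start), "end": int(start + peak_len)})
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "start", "end"])


def gen_window_counts(annotation: pd.DataFrame, peak_spans: pd.DataFrame,
                      cfg: SimConfig, quant_cfg: QuantConfig | None = None,
                      seed_offset: int = 0):
    """Paired IP/input window count tables for one m6A-seq sample.

    Input counts are Poisson with rate proportional to a per-transcript
    log-normal expression weight times window width, scaled so the expected
    input library totals ``cfg.seq_depth`` reads.  IP rates are multiplied by
    ``cfg.enrichment_fold`` in proportion to each window's overlap with a
    planted span.  Library sizes report the realized totals.

    Returns ``(ip_table, input_table)`` as :class:`scm6a.quant.WindowCountTable`.
    """
    from .quant import WindowCountTable

    quant_cfg = quant_cfg or QuantConfig()
    rng = np.random.default_rng(cfg.seed + 5 + seed_offset)
    windows = make_windows(annotation, quant_cfg)

    total_len = annotation[["utr5_len", "cds_len", "utr3_len"]].sum(axis=1)
    tx_ids = annotation["transcript_id"].tolist()
    weight = pd.Series(rng.lognormal(cfg.log_mean, cfg.log_sd, len(tx_ids)),
                       index=tx_ids)

    for _, span in peak_spans.iterrows():
        tx_len = int(total_len[annotation.transcript_id == span.transcript_id].iloc[0])
        if span.start < 0 or span.end > tx_len:
            raise ValueError(
                f"planted span {span.start}-{span.end} outside transcript "
                f"{span.transcript_id} (length {tx_len})")

    width = (windows["end"] - windows["start"]).to_numpy(float)
    base = weight.reindex(windows["chrom"]).to_numpy(float) * width
    base *= cfg.seq_depth / base.sum()

    # per-window planted-span overlap fraction
    enrich = np.ones(len(windows))
    spans_by_tx = {tx: df for tx, df in peak_spans.groupby("transcript_id")}
    chrom = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    for i in range(len(windows)):
        spans = spans_by_tx.get(chrom[i])
        if spans is None:
            continue
        ov = np.minimum(ends[i], spans["end"].to_numpy()) - \
            np.maximum(starts[i], spans["start"].to_numpy())
        frac = np.clip(ov, 0, None).sum() / (ends[i] - starts[i])
        enrich[i] = 1.0 + (cfg.enrichment_fold - 1.0) * min(frac, 1.0)

    input_counts = rng.poisson(base)
    ip_counts = rng.poisson(base * enrich)
    wdf = windows.copy()
    ip = WindowCountTable(wdf.assign(count=ip_counts), int(ip_counts.sum()))
    inp = WindowCountTable(wdf.assign(count=input_counts), int(input_counts.sum()))
    return ip, inp


def gen_ppms(n_motifs: int, consensus: str = "GGACU", seed: int = 0,
             perturbation: float = 0.1) -> list[pd.DataFrame]:
    """Position probability matrices perturbed around an IUPAC consensus.

    Each PPM is 4 x L (rows A, C, G, U) with columns summing to one.  At zero
    perturbation each column is uniform over the consensus letter's allowed
    bases, so for a concrete consensus the argmax recovers it exactly.
    """
    if not consensus:
        raise ValueError("consensus must be nonempty")
    consensus = consensus.upper()
    for ch in consensus:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r}")
    rng = np.random.default_rng(seed)
    ppms = []
    for m in range(n_motifs):
        cols = []
        for ch in consensus:
            p = np.full(4, 1e-12)
            allowed = IUPAC[ch]
            for b in allowed:
                p[BASES.index(b)] = 1.0 / len(allowed)
            if perturbation > 0:
                p = p + rng.gamma(1.0, perturbation, 4)
            cols.append(p / p.sum())
        ppm = pd.DataFrame(np.column_stack(cols), index=list(BASES),
                           columns=[f"pos{i}" for i in range(len(consensus))])
        ppm.attrs["motif_id"] = f"motif_{m:03d}"
        ppms.append(ppm)
    return ppms
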