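"""Stage orchestration: plain-file artifacts wired by a single RunConfig.

Every stage reads and writes ordinary files (TSV/BED/JSON) inside the run
directory so intermediate results stay inspectable, and a run manifest
records the config hash, seed and stage history.  Reruns with an identical
config reproduce identical artifacts for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .evaluate import correlate, evaluate_predictions, permutation_null
from .features import read_regulator_list
from .io import (read_annotation, read_matrix_tsv, read_ppms, write_annotation,
                 write_matrix_tsv, write_ppms)
from .models import Scm6ARegressor, load_models, save_models, split_train_test
from .quant import (WindowCountTable, make_windows, peak_levels, peaks_to_bed,
                    call_merge_split, rpkm, winscore)
from .simulate import (gen_annotation, gen_m6a_levels, gen_peak_spans, gen_ppms,
                       gen_regulator_expression, gen_window_counts,
                       make_planted_network)

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "quantify", "build-features", "train", "predict",
          "evaluate", "metagene")

log = logging.getLogger("scm6a")
if not log.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[scm6a %(levelname)s] %(message)s"))
    log.addHandler(h)
    log.setLevel(logging.INFO)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name} (run the '{produced_by}' "
            f"stage first or provide it at {path})")
    return path


def _config_hash(cfg: RunConfig) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _update_manifest(outdir: Path, cfg: RunConfig, stage: str,
                     artifacts: list[str], elapsed: float) -> None:
    mpath = outdir / "run_manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": _config_hash(cfg), "seed": cfg.seed,
        "version": __version__, "stages": {}}
    manifest["stages"][stage] = {"artifacts": sorted(artifacts),
                                 "seconds": round(elapsed, 3)}
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    sim = cfg.sim
    expr = gen_regulator_expression(sim)            # cells x regulators
    net = make_planted_network(sim)
    truth = gen_m6a_levels(expr, net, seed=sim.seed)
    ann = gen_annotation(sim)
    spans = gen_peak_spans(ann, sim)
    ip, inp = gen_window_counts(ann, spans, sim, cfg.quant)
    ppms = gen_ppms(sim.n_motifs, sim.motif_consensus, seed=sim.seed)

    write_matrix_tsv(expr.T, outdir / "expression.tsv", index_label="gene_id")
    (outdir / "regulators.txt").write_text("\n".join(expr.columns) + "\n")
    write_matrix_tsv(truth, outdir / "truth_m6a.tsv", index_label="site_id")
    write_annotation(ann, outdir / "annotation.tsv")
    spans.to_csv(outdir / "planted_spans.tsv", sep="\t", index=False)
    ip.to_tsv(outdir / "ip_counts.tsv")
    inp.to_tsv(outdir / "input_counts.tsv")
    write_ppms(ppms, outdir / "ppms.txt")
    network = [{"site": f"site_{s:04d}",
                "regulators": [int(r) for r in net.regulators[s]],
                "coefs": [float(c) for c in net.coefs[s]],
                "intercept": float(net.intercepts[s])}
               for s in range(net.n_sites)]
    (outdir / "planted_network.json").write_text(
        json.dumps({"noise_sd": net.noise_sd, "sites": network}, indent=1))
    return ["expression.tsv", "regulators.txt", "truth_m6a.tsv",
            "annotation.tsv", "planted_spans.tsv", "ip_counts.tsv",
            "input_counts.tsv", "ppms.txt", "planted_network.json"]


def _stage_quantify(cfg: RunConfig, outdir: Path) -> list[str]:
    ip = WindowCountTable.from_tsv(
        _require(outdir / "ip_counts.tsv", "quantify", "simulate"))
    inp = WindowCountTable.from_tsv(
        _require(outdir / "input_counts.tsv", "quantify", "simulate"))
    ws = winscore(rpkm(ip), rpkm(inp), cfg.quant,
                  gene_ids=ip.df["gene_id"].to_numpy())
    peaks = call_merge_split(ip.df, ws, cfg.quant)
    levels = peak_levels(peaks, pd.DataFrame({"sample_1": ws}), cfg.quant)
    peaks_to_bed(peaks, levels, outdir / "peaks.bed")
    write_matrix_tsv(levels, outdir / "m6a_winscore_matrix.tsv",
                     index_label="site_id")
    wdf = ip.df[["chrom", "start", "end", "gene_id", "strand"]].copy()
    wdf["winscore"] = ws
    wdf.to_csv(outdir / "window_winscores.tsv", sep="\t", index=False)
    log.info("quantify: %d peaks from %d windows", len(peaks), len(wdf))
    return ["peaks.bed", "m6a_winscore_matrix.tsv", "window_winscores.tsv"]


def _stage_build_features(cfg: RunConfig, outdir: Path) -> list[str]:
    expr = read_matrix_tsv(
        _require(outdir / "expression.tsv", "build-features", "simulate"))
    regs = read_regulator_list(
        _require(outdir / "regulators.txt", "build-features", "simulate"))
    panel = expr.reindex(regs).fillna(0.0)
    features = np.log1p(panel).T      # cells x regulators, log1p-harmonized
    write_matrix_tsv(features, outdir / "features.tsv", index_label="cell_id")
    return ["features.tsv"]


def _stage_train(cfg: RunConfig, outdir: Path) -> list[str]:
    features = read_matrix_tsv(
        _require(outdir / "features.tsv", "train", "build-features"))
    truth = read_matrix_tsv(
        _require(outdir / "truth_m6a.tsv", "train", "simulate"))
    train_ids, test_ids = split_train_test(list(features.index), cfg.train)
    model = Scm6ARegressor(
        family=cfg.train.family, mode=cfg.train.mode,
        param_grid=None if cfg.train.grid_search else {},
        cv_folds=cfg.train.cv_folds,
        target_transform=cfg.train.target_transform, seed=cfg.train.seed)
    cis = None
    if cfg.train.mode == "global":
        from .features import build_cis_features

        ppms = read_ppms(_require(outdir / "ppms.txt", "train", "simulate"))
        # per-site PPM assignment: motif m for site s chosen round-robin
        per_site = {s: ppms[i % len(ppms)] for i, s in enumerate(truth.index)}
        cis = build_cis_features(per_site, mode="flatten")
    model.fit(features.loc[train_ids], truth[train_ids], cis=cis)
    save_models(model, outdir / "model")
    (outdir / "split.json").write_text(json.dumps(
        {"train": train_ids, "test": test_ids}, indent=1))
    log.info("train: %s/%s fitted on %d cells (%d sites)", cfg.train.family,
             cfg.train.mode, len(train_ids), len(model.sites_))
    return ["model/manifest.json", "model/models.joblib", "split.json"]


def _stage_predict(cfg: RunConfig, outdir: Path) -> list[str]:
    features = read_matrix_tsv(
        _require(outdir / "features.tsv", "predict", "build-features"))
    model = load_models(_require(outdir / "model", "predict", "train"))
    cis = None
    if model.mode == "global":
        from .features import build_cis_features

        ppms = read_ppms(_require(outdir / "ppms.txt", "predict", "simulate"))
        per_site = {s: ppms[i % len(ppms)] for i, s in enumerate(model.sites_)}
        cis = build_cis_features(per_site, mode="flatten")
    pred = model.predict(features, cis=cis)
    write_matrix_tsv(pred, outdir / "predictions.tsv", index_label="site_id")
    return ["predictions.tsv"]


def _stage_evaluate(cfg: RunConfig, outdir: Path) -> list[str]:
    pred = read_matrix_tsv(
        _require(outdir / "predictions.tsv", "evaluate", "predict"))
    truth = read_matrix_tsv(
        _require(outdir / "truth_m6a.tsv", "evaluate", "simulate"))
    split_path = outdir / "split.json"
    if split_path.exists():
        test_ids = json.loads(split_path.read_text())["test"]
        cells = [c for c in test_ids if c in pred.columns]
        pred = pred[cells]
    report = evaluate_predictions(truth, pred, cfg.eval)
    # pooled permutation null of the truth/prediction correlation
    common = [c for c in pred.columns if c in truth.columns]
    yt = truth.loc[pred.index, common].to_numpy(float).ravel()
    yp = pred[common].to_numpy(float).ravel()
    obs, null, p = permutation_null(
        lambda a, b: correlate(a, b, cfg.eval)[0], yt, yp, cfg.eval)
    report.nulls["pooled_correlation"] = list(null)
    report.correlations["pooled"] = {
        "R": round(float(obs), 10), "P_permutation": round(float(p), 10),
        "n": int(yt.size)}
    report.to_json(outdir / "eval_report.json")
    report.to_tsv(outdir / "eval_per_site.tsv")
    log.info("evaluate: median R²=%.3f AUROC=%.3f",
             report.summary["r2"]["median"],
             report.summary["auroc"]["median"])
    return ["eval_report.json", "eval_per_site.tsv"]


def _stage_metagene(cfg: RunConfig, outdir: Path) -> list[str]:
    from .evaluate import metagene_profile

    bed = _require(outdir / "peaks.bed", "metagene", "quantify")
    peaks = pd.read_csv(bed, sep="\t", header=None,
                        names=["chrom", "start", "end", "name", "score",
                               "strand"])
    ann = read_annotation(
        _require(outdir / "annotation.tsv", "metagene", "simulate"))
    profile, skipped = metagene_profile(peaks, ann)
    regions = ["utr5"] * 10 + ["cds"] * 10 + ["utr3"] * 10
    pd.DataFrame({"bin": range(1, 31), "region": regions,
                  "density": profile}).to_csv(
        outdir / "metagene.tsv", sep="\t", index=False)
    log.info("metagene: %d peaks binned, %d skipped", len(peaks) - skipped,
             skipped)
    return ["metagene.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "build-features": _stage_build_features,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "metagene": _stage_metagene,
}


def run_pipeline(cfg: RunConfig, stages=STAGES, outdir: str | Path | None = None,
                 ) -> Path:
    """Run the requested stages in canonical order; returns the run directory."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; choose from {STAGES}")
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        artifacts = _STAGE_FN[stage](cfg, outdir)
        elapsed = time.perf_counter() - t0
        log.info("stage %-14s done in %.2fs", stage, elapsed)
        _update_manifest(outdir, cfg, stage, artifacts, elapsed)
    return outdir
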