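"""End-to-end orchestration: synthesize -> normalize -> map -> rank ->
aggregate -> consense -> evaluate, with a run directory, manifest and
reproducibility guarantees (bit-identical reruns under a fixed seed).

Defaults scale the reference workflow down to desk size: 30 studies of 2,000
genes, first-round cut N = 500, per-track top-K = 50, four normalization
tracks, consensus threshold 3.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import evalmetrics, genemap, normtracks, rankagg, stabrank, synthgen

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Serializable configuration covering every pipeline stage."""

    seed: int = 1
    tracks: tuple[str, ...] = ("RMA", "MAS5", "LiWong", "VSN")
    # synthetic collection
    n_studies: int = 30
    n_genes: int = 2000
    frac_housekeeping: float = 0.02
    frac_responsive: float = 0.30
    probes_per_set: int = 11
    n_samples_range: tuple[int, int] = (4, 24)
    #: overrides for synthgen.NoiseParams fields (None = generator defaults)
    noise: dict | None = None
    # first-round ranking
    stab_N: int = 500
    detect_floor: float | None = None
    fold_limit: float = 1.0
    # second-round aggregation
    agg_K: int = 50
    ce_rho: float = 0.1
    ce_nu: float = 0.7
    ce_max_iter: int = 500
    ce_conv_window: int = 15
    # consensus + evaluation
    consensus_threshold: int = 3
    validation_n_samples: int = 24
    validation_dispersion: float = 0.05
    n_compare: int = 13
    mas5_target: float = 500.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tracks"] = list(self.tracks)
        d["n_samples_range"] = list(self.n_samples_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tracks" in d:
            d["tracks"] = tuple(d["tracks"])
        if "n_samples_range" in d:
            d["n_samples_range"] = tuple(d["n_samples_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(cfg: RunConfig, *tags: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the run seed and a tag."""
    digest = hashlib.sha256("/".join(tags).encode()).digest()
    entropy = int.from_bytes(digest[:4], "big") % (2 ** 31)
    return np.random.SeedSequence([cfg.seed, entropy])


# ---------------------------------------------------------------------------
# stage functions (file-based, so the CLI can run them independently)


def stage_synth(cfg: RunConfig, run_dir: Path) -> None:
    noise_kwargs = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in (cfg.noise or {}).items()}
    mats, ann, truth, manifests = synthgen.generate_collection(
        noise=synthgen.NoiseParams(**noise_kwargs),
        n_studies=cfg.n_studies,
        n_genes=cfg.n_genes,
        frac_housekeeping=cfg.frac_housekeeping,
        frac_responsive=cfg.frac_responsive,
        probes_per_set=cfg.probes_per_set,
        n_samples_range=cfg.n_samples_range,
        seed=_child_seed(cfg, "synth"),
    )
    synthgen.write_collection(run_dir / "synth", mats, ann, truth, manifests)
    log.info("synth: %d studies, %d genes, %d probesets", len(mats),
             cfg.n_genes, len(ann.mapping))


def _kept_studies(run_dir: Path) -> list[synthgen.StudyManifest]:
    manifests = synthgen.read_manifests(run_dir / "synth" / "manifest.tsv")
    return synthgen.filter_studies(manifests)


def stage_normalize(cfg: RunConfig, run_dir: Path) -> None:
    """Normalize every kept study under every track and collapse to GEMs."""
    ann = synthgen.read_annotation(run_dir / "synth" / "annotation.tsv")
    kept = _kept_studies(run_dir)
    census_rows = []
    for m in kept:
        raw = synthgen.read_probe_matrix(run_dir / "synth" / "studies" / m.study_id)
        for track in cfg.tracks:
            cfg_kwargs = {"target": cfg.mas5_target} if track == "MAS5" else {}
            mat = normtracks.run_track(track, raw, **cfg_kwargs)
            tdir = run_dir / "normalized" / track
            tdir.mkdir(parents=True, exist_ok=True)
            mat.values.rename_axis("probeset_id").to_csv(
                tdir / f"{m.study_id}.tsv", sep="\t", float_format=FLOAT_FMT)
            gem = genemap.build_gem(mat, ann)
            gdir = run_dir / "gems" / track
            gdir.mkdir(parents=True, exist_ok=True)
            gem.values.rename_axis("gene_id").to_csv(
                gdir / f"{m.study_id}.tsv", sep="\t", float_format=FLOAT_FMT)
            census_rows.append(gem)
    census = genemap.gem_census(census_rows)
    census.to_csv(run_dir / "gems" / "census.tsv", sep="\t", index=False)
    log.info("normalize: %d studies x %d tracks", len(kept), len(cfg.tracks))


def _read_gem(run_dir: Path, track: str, study_id: str) -> genemap.GeneExpressionMatrix:
    df = pd.read_csv(run_dir / "gems" / track / f"{study_id}.tsv", sep="\t",
                     index_col="gene_id")
    return genemap.GeneExpressionMatrix(study_id, track, df)


def stage_rank(cfg: RunConfig, run_dir: Path) -> None:
    kept = _kept_studies(run_dir)
    for track in cfg.tracks:
        tdir = run_dir / "gls" / track
        tdir.mkdir(parents=True, exist_ok=True)
        for m in kept:
            gem = _read_gem(run_dir, track, m.study_id)
            gl = stabrank.rank_first_round(
                gem, N=cfg.stab_N, detect_floor=cfg.detect_floor,
                fold_limit=cfg.fold_limit)
            gl.to_frame().to_csv(tdir / f"{m.study_id}.tsv", sep="\t",
                                 index=False, float_format=FLOAT_FMT)


def _read_gl(path: Path) -> list[str]:
    return list(pd.read_csv(path, sep="\t", dtype={"gene_id": str})["gene_id"])


def stage_aggregate(cfg: RunConfig, run_dir: Path) -> None:
    """Per track, aggregate the top-K truncations of the first-round lists."""
    kept = _kept_studies(run_dir)
    (run_dir / "sgls").mkdir(exist_ok=True)
    for track in cfg.tracks:
        gls = [
            _read_gl(run_dir / "gls" / track / f"{m.study_id}.tsv")[:cfg.agg_K]
            for m in kept
        ]
        sgl = rankagg.aggregate_ce(
            gls, k=cfg.agg_K, rho=cfg.ce_rho, nu=cfg.ce_nu,
            max_iter=cfg.ce_max_iter, conv_window=cfg.ce_conv_window,
            seed=_child_seed(cfg, "aggregate", track), track=track,
        )
        pd.DataFrame({"rank": np.arange(1, len(sgl.items) + 1),
                      "gene_id": sgl.items}).to_csv(
            run_dir / "sgls" / f"{track}.tsv", sep="\t", index=False)
        diag = {k: v for k, v in sgl.diagnostics.items() if k != "trace"}
        diag["objective"] = sgl.objective
        diag["objective_trace_tail"] = [round(v, 6) for v in
                                        sgl.diagnostics["trace"][-5:]]
        with open(run_dir / "sgls" / f"{track}_diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
        log.info("aggregate %s: objective %.3f after %d iterations", track,
                 sgl.objective, sgl.diagnostics["iterations"])


def _read_sgls(cfg: RunConfig, run_dir: Path) -> list[rankagg.AggregatedList]:
    sgls = []
    for track in cfg.tracks:
        items = _read_gl(run_dir / "sgls" / f"{track}.tsv")
        sgls.append(rankagg.AggregatedList(track, items, 0.0))
    return sgls


def stage_consensus(cfg: RunConfig, run_dir: Path) -> None:
    sgls = _read_sgls(cfg, run_dir)
    if len(sgls) == 1:
        # degenerate single-track run: the SGL is the candidate set
        table = pd.DataFrame(
            {"count": 1, "tracks": sgls[0].track, "candidate": True},
            index=pd.Index(sorted(sgls[0].items), name="gene_id"))
        report = consensus_mod.ConsensusReport(table, 1, 1)
    else:
        report = consensus_mod.intersect_sgls(sgls, cfg.consensus_threshold)
    (run_dir / "consensus").mkdir(exist_ok=True)
    report.table.to_csv(run_dir / "consensus" / "report.tsv", sep="\t")
    hist = consensus_mod.sharing_histogram(report)
    hist.to_frame().to_csv(run_dir / "consensus" / "sharing_histogram.tsv",
                           sep="\t")
    with open(run_dir / "consensus" / "candidates.json", "w") as fh:
        json.dump({"threshold": report.threshold,
                   "candidates": report.candidates}, fh, indent=1)
    log.info("consensus: %d candidates at threshold %d",
             len(report.candidates), report.threshold)


def stage_evaluate(cfg: RunConfig, run_dir: Path) -> dict:
    """Recovery metrics vs truth plus a held-out count-based comparison."""
    truth = synthgen.read_truth(run_dir / "synth")
    metrics = validate_run(run_dir, truth)

    # held-out RNA-seq-style validation matrix
    rng = np.random.default_rng(_child_seed(cfg, "evaluate", "libs"))
    lib_sizes = rng.integers(800_000, 1_200_000, cfg.validation_n_samples)
    counts = synthgen.generate_counts(
        truth, cfg.validation_n_samples, lib_sizes,
        seed=_child_seed(cfg, "evaluate", "counts"),
        dispersion=cfg.validation_dispersion,
    )
    expr = evalmetrics.log2_cpm(counts)

    t = truth.table.sort_values(["noise_sd"], kind="stable")
    stable_set = list(t.index[t["archetype"] == "housekeeping"][:cfg.n_compare])
    common_set = list(t.index[t["archetype"] == "responsive"][:cfg.n_compare])
    comp = evalmetrics.compare_gene_sets(
        expr, stable_set, common_set, top_n=10,
        labels=("embedded_stable", "common_style"))

    edir = run_dir / "evaluation"
    edir.mkdir(exist_ok=True)
    comp.table.to_csv(edir / "comparison.tsv", sep="\t", float_format=FLOAT_FMT)
    metrics["occupancy_stable_sd"] = comp.occupancy["embedded_stable"]["sd"]
    metrics["occupancy_stable_gc"] = comp.occupancy["embedded_stable"]["gc"]
    with open(edir / "validation.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
    return metrics


STAGES = ("synth", "normalize", "rank", "aggregate", "consensus", "evaluate")
_STAGE_FNS = {
    "synth": stage_synth,
    "normalize": stage_normalize,
    "rank": stage_rank,
    "aggregate": stage_aggregate,
    "consensus": stage_consensus,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage into ``out_dir`` and write a run manifest.

    Rerunning with the same config and seed produces a bit-identical output
    tree.  Any stage error aborts with the stage name attached.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    metrics: dict = {}
    for stage in STAGES:
        try:
            result = _STAGE_FNS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        if isinstance(result, dict):
            metrics.update(result)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": list(STAGES),
        "n_studies_kept": len(_kept_studies(run_dir)),
        "metrics": metrics,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return run_dir


def validate_run(run_dir: str | Path,
                 truth: synthgen.SyntheticTruth | None = None) -> dict:
    """Precision/recall of the candidate set against the embedded truth."""
    run_dir = Path(run_dir)
    if truth is None:
        truth = synthgen.read_truth(run_dir / "synth")
    report = pd.read_csv(run_dir / "consensus" / "report.tsv", sep="\t",
                         index_col="gene_id")
    candidates = set(report.index[report["candidate"]])
    unknown = candidates - set(truth.table.index)
    if unknown:
        raise ValueError(f"candidate genes absent from truth: {sorted(unknown)[:5]}")
    hk = set(truth.genes_of("housekeeping"))
    tp = len(candidates & hk)
    precision = tp / len(candidates) if candidates else float("nan")
    recall = tp / len(hk) if hk else float("nan")

    cfg = RunConfig.from_yaml(run_dir / "config.yaml")
    sgl_recall = {}
    for track in cfg.tracks:
        items = set(_read_gl(run_dir / "sgls" / f"{track}.tsv"))
        sgl_recall[track] = len(items & hk) / len(hk)
    metrics = {
        "n_candidates": len(candidates),
        "n_housekeeping": len(hk),
        "true_positives": tp,
        "precision": precision,
        "precision_defined": bool(candidates),
        "recall": recall,
        "sgl_recall": sgl_recall,
    }
    pd.DataFrame([
        {"metric": "precision", "value": precision},
        {"metric": "recall", "value": recall},
        {"metric": "n_candidates", "value": len(candidates)},
    ]).to_csv(run_dir / "validation_metrics.tsv", sep="\t", index=False)
    return metrics
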