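"""End-to-end orchestration: simulate -> saturate/classify/gestalt/kinetics
-> report, with a checksummed run manifest.

Stages hand data to each other through plain files only, so every stage is
independently scriptable; deterministic stages reproduce identical
checksums when rerun with the same manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from nmascope import io as nio
from nmascope.biophys_kinetics import FitError, FitRejectedError, fit_half_time, melt_tm
from nmascope.cohort_classifier import classify_cohort
from nmascope.gestalt_stats import (
    DEFAULT_THRESHOLD,
    cohesion,
    compare_cohorts,
)
from nmascope.synthetic_data import (
    CohortSpec,
    EmbeddingSpec,
    GeneratorConfig,
    MeltSpec,
    PopulationSpec,
    TraceSpec,
    TranscriptSpec,
    make_cohort,
    make_embeddings,
    make_melts,
    make_population,
    make_traces,
    make_transcript,
)
from nmascope.transcript_saturation import enumerate_snvs, summarize, variants_to_frame

logger = logging.getLogger("nmascope.pipeline")

__all__ = ["RunManifest", "StageResult", "run_all", "load_config"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageResult:
    name: str
    status: str  # ok | failed | skipped
    wall_time_s: float = 0.0
    outputs: Dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    error: Optional[str] = None


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    out_dir: str
    stages: List[StageResult] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(s.status == "failed" for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": [
                {
                    "name": s.name,
                    "status": s.status,
                    "wall_time_s": round(s.wall_time_s, 3),
                    "outputs": s.outputs,
                    "error": s.error,
                }
                for s in self.stages
            ],
        }


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _build_generator_config(cfg: dict) -> GeneratorConfig:
    return GeneratorConfig(
        seed=int(cfg.get("seed", 0)),
        transcript=TranscriptSpec(**cfg.get("transcript", {})),
        population=PopulationSpec(**cfg.get("population", {})),
        cohort=CohortSpec(**cfg.get("cohort", {})),
        embedding=EmbeddingSpec(**cfg.get("embedding", {})),
        trace=TraceSpec(**cfg.get("trace", {})),
        melt=MeltSpec(**cfg.get("melt", {})),
    )


def run_all(config: dict, out_dir: Path) -> RunManifest:
    """Execute all stages in dependency order.

    A stage failure is recorded in the manifest and downstream stages are
    skipped; callers should exit nonzero when ``manifest.failed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canon = json.dumps(config, sort_keys=True).encode()
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon).hexdigest(),
        seed=seed,
        out_dir=str(out_dir),
    )
    gen = _build_generator_config(config)
    ctx: dict = {"gen": gen, "threshold": config.get("threshold", DEFAULT_THRESHOLD)}

    stages: List[tuple] = [
        ("simulate", _stage_simulate),
        ("saturate", _stage_saturate),
        ("classify", _stage_classify),
        ("gestalt", _stage_gestalt),
        ("kinetics", _stage_kinetics),
        ("report", _stage_report),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            manifest.stages.append(StageResult(name, "skipped"))
            continue
        t0 = time.perf_counter()
        try:
            outputs = fn(ctx, out_dir)
            dt = time.perf_counter() - t0
            checks = {str(p.relative_to(out_dir)): _sha256(p) for p in outputs}
            manifest.stages.append(StageResult(name, "ok", dt, checks))
            logger.info("stage %s ok (%.2fs, seed %d)", name, dt, seed)
        except Exception as exc:  # recorded, not raised: manifest carries it
            dt = time.perf_counter() - t0
            manifest.stages.append(
                StageResult(name, "failed", dt, error=f"{type(exc).__name__}: {exc}")
            )
            logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
            failed = True

    nio.dump_json(manifest.to_dict(), out_dir / "manifest.json")
    return manifest


# -- stages -----------------------------------------------------------------

def _stage_simulate(ctx: dict, out: Path) -> List[Path]:
    gen: GeneratorConfig = ctx["gen"]
    seed = gen.seed
    paths = []

    model = make_transcript(gen.transcript, seed=seed)
    ctx["model"] = model
    fa, iv = out / "transcript.fa", out / "transcript_intervals.tsv"
    nio.write_transcript(model, fa, iv)
    paths += [fa, iv]

    pop, pop_truth = make_population(gen.population, model, seed=seed + 1)
    ppath = out / "population.tsv"
    nio.write_population_tsv(pop, ppath)
    nio.dump_json(pop_truth, out / "population_truth.json")
    paths += [ppath, out / "population_truth.json"]

    records, truth = make_cohort(gen.cohort, seed=seed + 2)
    cpath = out / "cohort.tsv"
    nio.write_cohort(records, cpath)
    truth.to_csv(out / "cohort_truth.tsv", sep="\t", index=False)
    paths += [cpath, out / "cohort_truth.tsv"]

    es, es_truth = make_embeddings(gen.embedding, seed=seed + 3)
    epath = out / "embeddings.csv"
    nio.write_embeddings_csv(es, epath)
    nio.dump_json(
        {k: v for k, v in es_truth.items() if k != "directions"},
        out / "embeddings_truth.json",
    )
    paths += [epath, out / "embeddings_truth.json"]

    traces, tr_truth = make_traces(gen.trace, seed=seed + 4)
    tpath = out / "traces.csv"
    nio.write_traces_csv(traces, tpath)
    nio.dump_json(tr_truth, out / "traces_truth.json")
    paths += [tpath, out / "traces_truth.json"]

    melts, m_truth = make_melts(gen.melt, seed=seed + 5)
    mpath = out / "melts.csv"
    nio.write_melts_csv(melts, mpath)
    nio.dump_json(m_truth, out / "melts_truth.json")
    paths += [mpath, out / "melts_truth.json"]
    ctx["trace_mode"] = gen.trace.mode
    return paths


def _stage_saturate(ctx: dict, out: Path) -> List[Path]:
    model = nio.read_transcript(out / "transcript.fa", out / "transcript_intervals.tsv")
    population = nio.read_population(out / "population.tsv")
    variants = enumerate_snvs(model, "coding_only")
    summary = summarize(variants, population)
    vpath = out / "saturation_variants.tsv"
    variants_to_frame(variants).to_csv(vpath, sep="\t", index=False)
    spath = out / "saturation_summary.json"
    nio.dump_json(summary.to_dict(), spath)
    return [vpath, spath]


def _stage_classify(ctx: dict, out: Path) -> List[Path]:
    records = nio.read_cohort(out / "cohort.tsv")
    report = classify_cohort(records)
    apath = out / "assignments.tsv"
    report.assignments.to_csv(apath, sep="\t", index=False)
    cpath = out / "classification_counts.json"
    nio.dump_json(report.to_dict(), cpath)
    return [apath, cpath]


def _stage_gestalt(ctx: dict, out: Path) -> List[Path]:
    es = nio.read_embeddings_csv(out / "embeddings.csv")
    gen: GeneratorConfig = ctx["gen"]
    threshold = ctx["threshold"]
    labels = sorted(set(es.cohort))
    results = {"threshold": threshold, "comparisons": [], "cohesion": []}
    big = [l for l in labels if (es.cohort == l).sum() >= 2]
    for i, a in enumerate(big):
        for b in big[i + 1 :]:
            cmp_ = compare_cohorts(
                es.cohort_vectors(a),
                es.cohort_vectors(b),
                threshold=threshold,
                seed=gen.seed + 10,
                names=(a, b),
            )
            results["comparisons"].append(cmp_.to_dict())
    for a in big:
        res = cohesion(
            es.cohort_vectors(a),
            es,
            n_batches=200,
            seed=gen.seed + 11,
            cohort_name=a,
        )
        results["cohesion"].append(res.to_dict())
    gpath = out / "gestalt_report.json"
    nio.dump_json(results, gpath)
    return [gpath]


def _stage_kinetics(ctx: dict, out: Path) -> List[Path]:
    traces = nio.read_traces_csv(out / "traces.csv", mode=ctx.get("trace_mode", "polymerization"))
    rows = []
    for tr in traces:
        tid = tr.metadata.get("trace_id")
        try:
            fit = fit_half_time(tr)
            rows.append({"trace_id": tid, "status": "ok", **fit.to_dict()})
        except (FitError, FitRejectedError) as exc:
            rows.append({"trace_id": tid, "status": f"rejected: {exc}"})
    import pandas as pd

    kpath = out / "kinetic_fits.tsv"
    pd.DataFrame(rows).to_csv(kpath, sep="\t", index=False)

    melts = nio.read_melts_csv(out / "melts.csv")
    mrows = []
    for cv in melts:
        res = melt_tm(cv)
        mrows.append({"curve_id": cv.metadata.get("curve_id"), **res.to_dict()})
    mpath = out / "melt_tms.tsv"
    pd.DataFrame(mrows).to_csv(mpath, sep="\t", index=False)
    return [kpath, mpath]


def _stage_report(ctx: dict, out: Path) -> List[Path]:
    summary = json.loads((out / "saturation_summary.json").read_text())
    counts = json.loads((out / "classification_counts.json").read_text())
    gestalt = json.loads((out / "gestalt_report.json").read_text())

    lines = ["# nmascope run report", ""]
    lines.append("## Saturation")
    lines.append(
        f"- enumerated {summary['total_enumerated']} alternate alleles over "
        f"{summary['n_reference_positions']} reference positions"
    )
    for cls, n in summary["class_counts"].items():
        if n:
            lines.append(f"  - {cls}: {n} (observed in population: "
                         f"{summary['observed_counts'][cls]})")
    lines.append("")
    lines.append("## Classification")
    lines.append(f"- {counts['n_subjects']} subjects")
    for lab, n in counts["label_counts"].items():
        if n:
            lines.append(f"  - {lab}: {n}")
    lines.append("")
    lines.append("## Gestalt")
    for c in gestalt["comparisons"]:
        lines.append(
            f"- {c['cohort1']} vs {c['cohort2']}: d={c['distance']:.3f}, "
            f"fraction_above={c['fraction_above']:.2f} -> {c['decision']}"
        )
    for c in gestalt["cohesion"]:
        lines.append(
            f"- cohesion {c['cohort']}: d={c['within_distance']:.3f}, "
            f"percentile={c['left_tail_percentile']:.2f}"
        )
    rpath = out / "report.md"
    rpath.write_text("\n".join(lines) + "\n")
    return [rpath]
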