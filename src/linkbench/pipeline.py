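"""End-to-end experiment orchestration.

One experiment = one graph, one slicing regime, several scoring methods,
``n_runs`` repeats. Per run r (seeded ``base_seed + r``) the pipeline
slices the graph, samples 1:1 negatives, hands the *identical* split to
every method, scores the test pairs, computes the five metrics and the
no-common-neighbour diagnostic, and finally aggregates runs with the
mean ± sd / t-test protocol. A manifest records every seed, fraction and
default so a run is reproducible byte-for-byte.

Method specifications: plain heuristic names ``CN`` / ``AA`` / ``JI``, or
``<walker>:<combine_op>`` where walker is ``deepwalk`` (uniform walks) or
``node2vec`` (p/q-biased walks) and combine_op is one of the five node
combination operators, e.g. ``deepwalk:average`` or ``node2vec:hadamard``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import heuristics as heur
from .embedding import WalkConfig, complete_table, generate_walks, train_embeddings
from .graph_io import TemporalGraph
from .metrics import METRIC_NAMES, MetricReport, aggregate_runs, compute_metrics
from .nocn import NoCnReport, no_cn_report
from .predictor import PredictorConfig, combine_pairs, predict, train_predictor
from .ranking import ScoredRanking, merge_labelled_pairs
from .slicing import LinkSplit, random_slice, time_slice

WALK_MODES = {"deepwalk": "uniform", "node2vec": "biased"}


@dataclass
class MethodSpec:
    """A single scoring route: heuristic, or embedding × combiner × predictor."""

    name: str
    kind: str  # "heuristic" | "embedding"
    heuristic: str | None = None
    walk_mode: str | None = None  # "uniform" | "biased"
    combine_op: str | None = None

    @classmethod
    def parse(cls, spec: str) -> "MethodSpec":
        if spec in heur.METHODS:
            return cls(name=spec, kind="heuristic", heuristic=spec)
        if ":" in spec:
            walker, op = spec.split(":", 1)
            if walker in WALK_MODES:
                from .predictor import COMBINE_OPS

                if op not in COMBINE_OPS:
                    raise ValueError(f"unknown combine op {op!r} in {spec!r}")
                return cls(name=spec, kind="embedding",
                           walk_mode=WALK_MODES[walker], combine_op=op)
        raise ValueError(
            f"cannot parse method {spec!r}: expected CN/AA/JI or "
            f"<deepwalk|node2vec>:<combine_op>"
        )


@dataclass
class ExperimentConfig:
    methods: list[str]
    slicing: str = "random"  # "random" | "time"
    frac_induction: float = 0.60
    frac_train: float = 0.10
    induction_end: int | None = None
    train_start: int | None = None
    test_end: int | None = None
    k_ratio: float = 0.3
    n_runs: int = 3
    base_seed: int = 0
    walk: WalkConfig = field(default_factory=WalkConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        self.specs = [MethodSpec.parse(m) for m in self.methods]
        if self.slicing not in ("random", "time"):
            raise ValueError("slicing must be 'random' or 'time'")
        if self.slicing == "time" and None in (
            self.induction_end, self.train_start, self.test_end
        ):
            raise ValueError("time slicing needs induction_end, train_start, test_end")


@dataclass
class RunResult:
    split: LinkSplit
    rankings: dict[str, ScoredRanking]
    metrics: dict[str, dict[str, float]]
    nocn: NoCnReport
    random_init_fraction: dict[str, float]
    seed: int


@dataclass
class ExperimentResult:
    report: MetricReport
    runs: list[RunResult]
    manifest: dict[str, Any]

    @property
    def nocn_reports(self) -> list[NoCnReport]:
        return [r.nocn for r in self.runs]

    def mean_nocn_fraction(self) -> float:
        runs = self.nocn_reports
        return sum(r.frac_no_cn for r in runs) / len(runs)

    def mean_top_half(self, method: str) -> float:
        runs = self.nocn_reports
        return sum(r.per_method[method] for r in runs) / len(runs)


def _pairs_digest(pairs) -> str:
    h = hashlib.sha256()
    for u, v in sorted(pairs):
        h.update(f"{u}|{v};".encode())
    return h.hexdigest()[:16]


def run_single(
    g: TemporalGraph, cfg: ExperimentConfig, seed: int, stage_prefix: str = ""
) -> RunResult:
    """One seeded run: slice, score every method on the same split, measure."""
    try:
        if cfg.slicing == "random":
            split = random_slice(g, cfg.frac_induction, cfg.frac_train, seed=seed)
        else:
            split = time_slice(
                g, cfg.induction_end, cfg.train_start, cfg.test_end, seed=seed
            )
    except Exception as exc:
        raise RuntimeError(f"{stage_prefix}slicing failed: {exc}") from exc

    induction = split.induction_graph(g)  # all nodes kept; some isolated
    bipartite = g.partition is not None
    test_pairs, test_labels = merge_labelled_pairs(split.test_pos, split.test_neg)

    # embeddings shared across combine ops within a run
    emb_cache: dict[str, Any] = {}

    def embedding_for(mode: str):
        if mode not in emb_cache:
            walk_graph = g.subgraph_of_links(split.induction_links)  # linked nodes only
            wcfg = WalkConfig(**{**cfg.walk.__dict__, "seed": seed})
            walks = generate_walks(walk_graph, wcfg, mode=mode)
            table = train_embeddings(walks, wcfg)
            emb_cache[mode] = complete_table(
                table, g.nodes, wcfg.dimensions, seed=seed
            )
        return emb_cache[mode]

    rankings: dict[str, ScoredRanking] = {}
    metric_values: dict[str, dict[str, float]] = {}
    random_init_fraction: dict[str, float] = {}
    for spec in cfg.specs:
        try:
            if spec.kind == "heuristic":
                ranking = heur.score_all(
                    induction, test_pairs, spec.heuristic,
                    labels=test_labels, bipartite=bipartite,
                )
            else:
                emb = embedding_for(spec.walk_mode)
                random_init_fraction[spec.name] = emb.random_init_fraction()
                pcfg = PredictorConfig(**{**cfg.predictor.__dict__, "seed": seed})
                train_pairs_pos = sorted(split.train_pos)
                train_pairs_neg = sorted(split.train_neg)
                model = train_predictor(
                    combine_pairs(train_pairs_pos, emb, spec.combine_op),
                    combine_pairs(train_pairs_neg, emb, spec.combine_op),
                    pcfg,
                )
                ranking = predict(
                    model, test_pairs, emb, spec.combine_op,
                    labels=test_labels, method=spec.name,
                )
            ranking.method = spec.name
            rankings[spec.name] = ranking
            metric_values[spec.name] = compute_metrics(ranking, cfg.k_ratio)
        except Exception as exc:
            raise RuntimeError(f"{stage_prefix}method {spec.name!r} failed: {exc}") from exc

    nocn = no_cn_report(induction, split.test_pos, rankings, bipartite=bipartite)
    return RunResult(
        split=split,
        rankings=rankings,
        metrics=metric_values,
        nocn=nocn,
        random_init_fraction=random_init_fraction,
        seed=seed,
    )


def run_experiment(g: TemporalGraph, cfg: ExperimentConfig) -> ExperimentResult:
    """The full protocol: n_runs seeded repeats plus aggregation."""
    runs: list[RunResult] = []
    for r in range(cfg.n_runs):
        seed = cfg.base_seed + r
        runs.append(run_single(g, cfg, seed, stage_prefix=f"run {r}: "))

    per_method = {
        spec.name: [run.metrics[spec.name] for run in runs] for spec in cfg.specs
    }
    if cfg.n_runs >= 2:
        report = aggregate_runs(per_method, k_ratio=cfg.k_ratio)
    else:
        report = MetricReport(runs=per_method, k_ratio=cfg.k_ratio)
        for method, run_list in per_method.items():
            report.mean[method] = dict(run_list[0])
            report.sd[method] = {m: 0.0 for m in METRIC_NAMES}
        for metric in METRIC_NAMES:
            best = max(per_method, key=lambda m: report.mean[m][metric])
            report.best[metric] = best
            report.significance[metric] = {
                m: "not-different" for m in per_method
            }

    manifest = {
        "config": {
            "methods": cfg.methods,
            "slicing": cfg.slicing,
            "frac_induction": cfg.frac_induction,
            "frac_train": cfg.frac_train,
            "induction_end": cfg.induction_end,
            "train_start": cfg.train_start,
            "test_end": cfg.test_end,
            "k_ratio": cfg.k_ratio,
            "n_runs": cfg.n_runs,
            "base_seed": cfg.base_seed,
            "walk": dict(cfg.walk.__dict__),
            "predictor": dict(cfg.predictor.__dict__),
        },
        "graph": {"n_nodes": len(g.nodes), "n_links": len(g.links),
                  "bipartite": g.partition is not None},
        "runs": [
            {
                "seed": run.seed,
                "n_induction": len(run.split.induction_links),
                "n_train_pos": len(run.split.train_pos),
                "n_test_pos": len(run.split.test_pos),
                "test_digest": _pairs_digest(
                    sorted(run.split.test_pos) + sorted(run.split.test_neg)
                ),
                "no_cn_fraction": run.nocn.frac_no_cn,
                "random_init_fraction": run.random_init_fraction,
            }
            for run in runs
        ],
    }
    return ExperimentResult(report=report, runs=runs, manifest=manifest)


def write_result(result: ExperimentResult, outdir) -> None:
    from .metrics import write_report_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report_tsv(result.report, outdir / "metrics.tsv")
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write(result.report.summary_table() + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    for i, run in enumerate(result.runs):
        with open(outdir / f"nocn_run{i}.tsv", "w") as fh:
            fh.write(run.nocn.to_tsv() + "\n")
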