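"""End-to-end orchestration: inputs -> HAPs -> CSHANs -> epicenter lists.

`run_stages` is the in-memory workhorse (used by the sensitivity
protocol and the tests); `run_pipeline` wraps it with file I/O and a
serialized run configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .centrality import (EpicenterRanking, LSCCReport, get_epicenters,
                         lscc_report, write_ranking)
from .core import (BaseNetwork, ConditionNetwork, ExpressionProfile,
                   build_condition_network, fold_changes, load_base_network,
                   load_expression, write_graphml)
from .cshan import CSHAN, condition_specific_paths, induce_cshan, write_cshan_edges
from .errors import EpitracerError, ParameterError
from .paths import HAPSet, extract_hap_set, write_hap_set

logger = logging.getLogger("epitracer")

__all__ = ["RunConfig", "PipelineResult", "run_stages", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated run configuration, serialized into the output directory."""

    network_path: str
    expression_path: str
    control_columns: list[str] = field(default_factory=list)
    perturbed_columns: list[str] = field(default_factory=list)
    percentile: float = 0.1
    top_k: int = 10
    analyze: str = "perturbed"  # perturbed | control | both
    outdir: str = "epitracer_out"
    seed: int = 0
    unlog2: bool = False
    fc_cutoff: float = 1.5
    stream_threshold: int = 400

    def validate(self) -> None:
        if not (0 < self.percentile <= 100):
            raise ParameterError(
                f"percentile must lie in (0, 100], got {self.percentile}")
        if self.top_k < 1:
            raise ParameterError(f"top_k must be >= 1, got {self.top_k}")
        if self.analyze not in ("perturbed", "control", "both"):
            raise ParameterError(
                f"analyze must be perturbed/control/both, got {self.analyze!r}")
        if self.fc_cutoff <= 1:
            raise ParameterError(
                f"fc_cutoff must be > 1, got {self.fc_cutoff}")


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one run, in memory."""

    networks: dict[str, ConditionNetwork]
    hap_sets: dict[str, HAPSet]
    unique_hap_sets: dict[str, HAPSet]
    cshans: dict[str, CSHAN]
    #: analyzed condition -> (specific ranking, global ranking)
    rankings: dict[str, tuple[EpicenterRanking, EpicenterRanking]]
    lscc: dict[str, LSCCReport]
    timings: dict[str, float] = field(default_factory=dict)


def run_stages(base: BaseNetwork, control: ExpressionProfile,
               perturbed: ExpressionProfile, *, q: float = 0.1,
               top_k: int = 10, analyze: str = "perturbed",
               stream_threshold: int = 400) -> PipelineResult:
    """Run the full workflow in memory.

    Stages: map each profile onto the base network; extract each
    condition's highest-activity paths at percentile ``q``; discard paths
    common to both conditions; induce the condition-specific networks;
    rank by ripple centrality and split into specific/global lists for
    each analyzed condition; annotate with LSCC membership.
    """
    if analyze not in ("perturbed", "control", "both"):
        raise ParameterError(f"analyze must be perturbed/control/both, got {analyze!r}")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    networks = {
        "control": build_condition_network(base, control),
        "perturbed": build_condition_network(base, perturbed),
    }
    timings["map_profiles"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hap_sets = {c: extract_hap_set(net, q, stream_threshold=stream_threshold)
                for c, net in networks.items()}
    timings["extract_haps"] = time.perf_counter() - t0
    logger.info("HAPs retained: control=%d perturbed=%d (q=%g)",
                len(hap_sets["control"]), len(hap_sets["perturbed"]), q)

    t0 = time.perf_counter()
    unique_control, unique_perturbed = condition_specific_paths(
        hap_sets["control"], hap_sets["perturbed"])
    unique = {"control": unique_control, "perturbed": unique_perturbed}
    cshans = {c: induce_cshan(unique[c], networks[c]) for c in networks}
    timings["cshan"] = time.perf_counter() - t0
    logger.info("condition-specific HAPs: control=%d perturbed=%d; "
                "CSHAN sizes: control=%d/%d perturbed=%d/%d (nodes/edges)",
                len(unique_control), len(unique_perturbed),
                cshans["control"].number_of_nodes(),
                cshans["control"].number_of_edges(),
                cshans["perturbed"].number_of_nodes(),
                cshans["perturbed"].number_of_edges())

    t0 = time.perf_counter()
    to_analyze = ["perturbed", "control"] if analyze == "both" else [analyze]
    rankings: dict[str, tuple[EpicenterRanking, EpicenterRanking]] = {}
    lscc: dict[str, LSCCReport] = {}
    for cond in to_analyze:
        other = "control" if cond == "perturbed" else "perturbed"
        specific, global_ = get_epicenters(cshans[cond], cshans[other], top_k=top_k)
        rankings[cond] = (specific, global_)
        lscc[cond] = lscc_report(cshans[cond], specific)
    timings["rank"] = time.perf_counter() - t0

    return PipelineResult(networks=networks, hap_sets=hap_sets,
                          unique_hap_sets=unique, cshans=cshans,
                          rankings=rankings, lscc=lscc, timings=timings)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per ``config``, run all stages, write artifacts to disk.

    Outputs (TSV/GraphML/JSON under ``config.outdir``): the run config,
    per-condition HAP sets, CSHAN edge lists + GraphML, and for each
    analyzed condition the specific and global rankings (annotated with
    LSCC membership and fold change) plus an LSCC summary.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "wt", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    try:
        base = load_base_network(config.network_path)
    except EpitracerError as exc:
        raise EpitracerError(f"stage load_network: {exc} "
                             "(check the TSV edge list)") from exc
    try:
        control = load_expression(config.expression_path, "control",
                                  config.control_columns or None,
                                  unlog2=config.unlog2)
        perturbed = load_expression(config.expression_path, "perturbed",
                                    config.perturbed_columns or None,
                                    unlog2=config.unlog2)
    except EpitracerError as exc:
        raise EpitracerError(f"stage load_expression: {exc} "
                             "(check column names and scale)") from exc

    result = run_stages(base, control, perturbed, q=config.percentile,
                        top_k=config.top_k, analyze=config.analyze,
                        stream_threshold=config.stream_threshold)
    fc = fold_changes(control, perturbed, cutoff=config.fc_cutoff)

    for cond, hs in result.hap_sets.items():
        write_hap_set(hs, outdir / f"haps_{cond}.tsv")
    for cond, cshan in result.cshans.items():
        write_cshan_edges(cshan, outdir / f"cshan_{cond}.tsv")
        write_graphml(cshan.graph, outdir / f"cshan_{cond}.graphml")
    for cond, (specific, global_) in result.rankings.items():
        lscc_nodes = result.lscc[cond].lscc if result.lscc[cond].lscc_size > 1 else set()
        write_ranking(specific, outdir / f"ranking_{cond}_specific.tsv",
                      lscc=lscc_nodes, fold_change_table=fc)
        write_ranking(global_, outdir / f"ranking_{cond}_global.tsv",
                      lscc=lscc_nodes, fold_change_table=fc)
        rep = result.lscc[cond]
        with open(outdir / f"lscc_{cond}.json", "wt", encoding="utf-8") as fh:
            json.dump({"condition": rep.condition, "lscc_size": rep.lscc_size,
                       "cshan_size": rep.graph_size,
                       "members": sorted(rep.lscc)}, fh, indent=2)
            fh.write("\n")
    with open(outdir / "timings.json", "wt", encoding="utf-8") as fh:
        json.dump(result.timings, fh, indent=2)
        fh.write("\n")
    return result
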