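"""End-to-end orchestration: summaries, NBS stages, and the JSON report.

``run_summary`` computes the headline analyses (per-timepoint lateralization
paired t tests; LMEs over time on left/right/interhemispheric strengths and
the lateralization index with all period contrasts; behavioral improvement
LME and the vocabulary-proficiency correlation).  ``run_full_pipeline``
chains read -> threshold -> summary -> omnibus NBS -> post-hoc localization
-> score NBS -> optional vocabulary-subgroup analysis, and writes a
deterministic JSON report plus TSV tables.  A single global seed fans out
to per-stage seeds through a SeedSequence so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    EdgeMask,
    LongitudinalConnectomes,
    group_threshold,
    read_connectomes,
    strength_table,
)
from .models import ModelSpec, lme_time_contrasts, paired_t, pearson
from .nbs import (
    NBSConfig,
    PeriodSubnetwork,
    SubnetworkResult,
    edgewise_stats,
    nbs_score,
    nbs_test,
    posthoc_adjacent,
    subgroup_split,
)
from .regions import read_region_table

log = logging.getLogger("plastconn")


@dataclass(frozen=True)
class PipelineConfig:
    region_table: str
    connectomes: str
    output_dir: str
    scores: str | None = None
    vocabulary: str | None = None
    threshold_fraction: float = 0.30
    p_threshold: float = 0.01
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    component_statistic: str = "extent"
    run_lateralization: bool = True
    run_interhemispheric: bool = True
    run_omnibus_nbs: bool = True
    run_posthoc: bool = True
    run_score_nbs: bool = True
    run_subgroup: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: int) -> int:
        """Per-stage seed derived from the global seed (documented fan-out:
        SeedSequence(seed).generate_state, entry ``stage``, mod 2**31)."""
        state = np.random.SeedSequence(self.seed).generate_state(stage + 1)
        return int(state[stage] % (2**31))


def _ttest_dict(res) -> dict:
    return {"t": _num(res.t), "df": res.df, "p": _num(res.p), "n": res.n}


def _num(x) -> float | str:
    x = float(x)
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x


def _contrast_rows(frame: pd.DataFrame) -> list[dict]:
    return [
        {"contrast": r["contrast"], "estimate": _num(r["estimate"]),
         "se": _num(r["se"]), "t": _num(r["t"]), "df": int(r["df"]),
         "p": _num(r["p"])}
        for _, r in frame.iterrows()
    ]


def _subnetwork_dict(s: SubnetworkResult) -> dict:
    return {
        "direction": s.direction,
        "extent": s.extent,
        "statistic": s.component_statistic,
        "statistic_value": _num(s.statistic_value),
        "p_fwe": _num(s.p_fwe),
        "significant": bool(s.significant),
        "mean_t": _num(s.mean_t),
        "member_regions": list(s.member_regions),
        "edges": [list(e) for e in s.edges],
    }


def _period_dict(s: PeriodSubnetwork) -> dict:
    return {
        "period": f"{s.period[0]}->{s.period[1]}",
        "direction": s.direction,
        "extent": s.extent,
        "mean_estimate": _num(s.mean_estimate),
        "mean_t": _num(s.mean_t),
        "edges": [list(e) for e in s.edges],
    }


def run_summary(data: LongitudinalConnectomes, mask: EdgeMask,
                scores: pd.DataFrame | None = None,
                vocabulary: pd.Series | None = None) -> dict:
    """Hemispheric/lateralization summaries and behavioral statistics."""
    strengths = strength_table(data, mask)
    out: dict = {}

    later = {}
    for tp in data.timepoints():
        sub = strengths.loc[strengths["timepoint"] == tp]
        later[str(tp)] = _ttest_dict(paired_t(sub["left"], sub["right"]))
    out["lateralization"] = later

    spec = ModelSpec("time")
    traj = {}
    for meas in ("left", "right", "interhemispheric", "lateralization_index"):
        frame = strengths.rename(columns={meas: "value"})[
            ["participant", "timepoint", "value"]]
        traj[meas] = _contrast_rows(lme_time_contrasts(frame, spec))
    out["trajectories"] = traj

    if scores is not None:
        frame = scores.rename(columns={"score": "value"})
        rows = lme_time_contrasts(frame, spec)
        out["behavior"] = {"improvement": _contrast_rows(rows)}
        if vocabulary is not None:
            s6 = scores.loc[scores["timepoint"] == 6].set_index("participant")["score"]
            common = sorted(set(s6.index) & set(vocabulary.index))
            res = pearson(vocabulary.loc[common], s6.loc[common])
            out["behavior"]["vocabulary_correlation"] = {
                "r": _num(res.r), "p": _num(res.p), "n": res.n}
    else:
        out["behavior"] = "skipped"
    return out


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write report.json + TSV artifacts.

    Deterministic for a fixed config (including seed): rerunning writes
    byte-identical artifacts.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "plastconn",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        }
    }

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    try:
        t0 = stage("read")
        regions = read_region_table(config.region_table)
        data = read_connectomes(config.connectomes, regions)
        scores = vocab = None
        if config.scores:
            scores = pd.read_csv(config.scores)
            scores["participant"] = scores["participant"].astype(str)
        if config.vocabulary:
            vf = pd.read_csv(config.vocabulary)
            vocab = vf.set_index(vf["participant"].astype(str))["vocabulary"]
        log.info("read done in %.2fs (%d matrices)", time.time() - t0, len(data))

        t0 = stage("threshold")
        mask = group_threshold(data, config.threshold_fraction)
        mask.write(outdir / "edge_mask.tsv")

        t0 = stage("summary")
        report["summary"] = run_summary(data, mask, scores, vocab)
        strength_table(data, mask).to_csv(outdir / "strengths.tsv",
                                          sep="\t", index=False)

        nbs_cfg = NBSConfig(
            p_threshold=config.p_threshold,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=config.stage_seed(1),
            component_statistic=config.component_statistic,
        )
        subnets: list[SubnetworkResult] = []
        if config.run_omnibus_nbs:
            t0 = stage("omnibus-nbs")
            spec = ModelSpec("time")
            stats = edgewise_stats(data, mask, spec)
            stats.to_frame().to_csv(outdir / "edgewise_time.tsv",
                                    sep="\t", index=False)
            subnets = nbs_test(data, mask, spec, nbs_cfg)
            report["omnibus_nbs"] = [_subnetwork_dict(s) for s in subnets]
            log.info("omnibus NBS done in %.2fs (%d components)",
                     time.time() - t0, len(subnets))
        else:
            report["omnibus_nbs"] = "skipped"

        if config.run_posthoc and config.run_omnibus_nbs:
            t0 = stage("posthoc")
            sig = [s for s in subnets if s.significant] or subnets
            period = posthoc_adjacent(data, mask, sig, alpha=0.05)
            report["posthoc"] = [_period_dict(s) for s in period]
        else:
            report["posthoc"] = "skipped"

        if config.run_score_nbs and scores is not None:
            t0 = stage("score-nbs")
            score_cfg = dataclasses.replace(nbs_cfg, seed=config.stage_seed(2))
            score_nets = nbs_score(data, scores, mask, score_cfg)
            report["score_nbs"] = [_subnetwork_dict(s) for s in score_nets]
        else:
            report["score_nbs"] = "skipped"

        if (config.run_subgroup and scores is not None
                and vocab is not None):
            t0 = stage("subgroup")
            above, below = subgroup_split(vocab)
            sub_report = {"above_mean": {"participants": above},
                          "at_or_below_mean": {"participants": below}}
            for name, group in (("above_mean", above),
                                ("at_or_below_mean", below)):
                cfg_g = dataclasses.replace(nbs_cfg, seed=config.stage_seed(3))
                try:
                    nets = nbs_score(data, scores, mask, cfg_g,
                                     participants=group)
                    sub_report[name]["score_nbs"] = [
                        _subnetwork_dict(s) for s in nets]
                except Exception as exc:  # small groups may be degenerate
                    sub_report[name]["score_nbs"] = f"failed: {exc}"
            report["subgroup"] = sub_report
        else:
            report["subgroup"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {exc}") from exc

    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


REPORT_SCHEMA = {
    "provenance": dict,
    "summary": dict,
    "omnibus_nbs": (list, str),
    "posthoc": (list, str),
    "score_nbs": (list, str),
    "subgroup": (dict, str),
}


def validate_report(report: dict) -> None:
    """Check the report against the published top-level schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} has wrong type")
    prov = report["provenance"]
    for key in ("package", "version", "config", "config_hash", "seed"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")
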