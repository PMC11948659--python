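"""Pipeline orchestration: ingest → score → survival → fit, with manifests.

All figure-oriented exports are data-only (CSV/JSON): transition-plot edge
lists, outcome histograms and Kaplan–Meier curve/at-risk tables.  Reruns
with an identical configuration and seed produce identical data outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path as FsPath
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .citation_graph import (
    CitationNetwork,
    Location,
    TargetKind,
    read_network,
    validate_network,
)
from .impact_scoring import (
    DEFAULT_CONFIG,
    ImpactConfig,
    enumerate_paths,
    flow_summary,
    score_network,
)
from .stats_models import (
    DegenerateFitError,
    SpecError,
    Outcome,
    RegressionSpec,
    build_analysis_frame,
    fit_cox,
    fit_count_model,
    km_fit,
)
from .synthetic_data import (
    GeneratorConfig,
    exemplar_fixture,
    generate_network,
    reference_fixture,
)
from .time_to_impact import DEFAULT_CENSOR_DATE

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input selection plus run parameters for :func:`run_pipeline`.

    Exactly one of ``network_dir``, ``fixture`` ("reference" or "exemplar")
    or ``generator`` must be set.
    """

    out_dir: str
    network_dir: str | None = None
    fixture: str | None = None
    generator: GeneratorConfig | None = None
    seed: int = 0
    censor_date: date = DEFAULT_CENSOR_DATE
    direct_citation_impactful: bool = True

    @classmethod
    def from_yaml(cls, path: str | FsPath) -> "PipelineConfig":
        raw = yaml.safe_load(FsPath(path).read_text())
        gen = raw.get("generator")
        if gen is not None:
            gen = GeneratorConfig(**gen)
        censor = raw.get("censor_date", DEFAULT_CENSOR_DATE)
        if isinstance(censor, str):
            censor = date.fromisoformat(censor)
        return cls(
            out_dir=raw["out_dir"],
            network_dir=raw.get("network_dir"),
            fixture=raw.get("fixture"),
            generator=gen,
            seed=int(raw.get("seed", 0)),
            censor_date=censor,
            direct_citation_impactful=bool(raw.get("direct_citation_impactful", True)),
        )

    def config_hash(self) -> str:
        """Hash of the analysis inputs (the output destination is excluded
        so reruns to different directories compare equal)."""
        def _default(o: Any):
            if isinstance(o, date):
                return o.isoformat()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)
        payload = json.dumps(fields, default=_default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_network(cfg: PipelineConfig) -> CitationNetwork:
    chosen = [x is not None for x in (cfg.network_dir, cfg.fixture, cfg.generator)]
    if sum(chosen) != 1:
        raise StageError("ingest: set exactly one of network_dir, fixture, generator")
    if cfg.network_dir:
        return read_network(cfg.network_dir)
    if cfg.fixture:
        if cfg.fixture == "reference":
            return reference_fixture()
        if cfg.fixture == "exemplar":
            return exemplar_fixture()
        raise StageError(f"ingest: unknown fixture {cfg.fixture!r}")
    return generate_network(cfg.generator, seed=cfg.seed)


def export_transitions(network: CitationNetwork, trial_id: str) -> dict:
    """Layered edge list for a transition plot of one trial's literature
    footprint (registry → articles → SRs → guidelines).

    Edge ``status`` carries the inclusion semantics (solid vs. dotted);
    guideline edges carry the route kind (article vs. SR vs. registry).
    """
    trial = network.trial(trial_id)
    nodes = [{"id": trial_id, "layer": "registry", "kind": "trial"}]
    edges: list[dict] = []

    article_ids = network.articles_by_trial.get(trial_id, [])
    for aid in article_ids:
        art = network.articles[aid]
        nodes.append({"id": aid, "layer": "article", "kind": "article",
                      "is_method_article": art.is_method_article})
        edges.append({"source": aid, "target": trial_id, "type": "publication",
                      "status": "included"})

    sr_ids: list[str] = []
    for aid in article_ids:
        for sr_id, status in network.srs_by_article.get(aid, []):
            if sr_id not in sr_ids:
                sr_ids.append(sr_id)
            edges.append({"source": sr_id, "target": aid, "type": "sr_citation",
                          "status": status.value})
    for sr_id in sorted(sr_ids):
        nodes.append({"id": sr_id, "layer": "sr", "kind": "sr"})

    cpg_ids: list[str] = []
    paths = enumerate_paths(network, trial_id)
    seen_edges: set[tuple] = set()
    for p in paths:
        kind, ref = p.terminal_reference
        key = (p.cpg_id, kind.value, ref)
        if key in seen_edges:
            continue
        seen_edges.add(key)
        if p.cpg_id not in cpg_ids:
            cpg_ids.append(p.cpg_id)
        edges.append({
            "source": p.cpg_id, "target": ref, "type": "cpg_citation",
            "route": kind.value,
            "status": p.reference_in_cpg.value,
            "main_count": network.ref_main_count(p.cpg_id, kind, ref),
            "supp_count": network.ref_supp_count(p.cpg_id, kind, ref),
        })
    for cpg in sorted(cpg_ids):
        nodes.append({"id": cpg, "layer": "cpg", "kind": "guideline"})

    return {"trial_id": trial_id, "nodes": nodes, "edges": edges}


def _write_json(path: FsPath, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig | str | FsPath) -> FsPath:
    """Run ingest → validate → score → flow → survival → models and write
    every output plus a run manifest to ``config.out_dir``.

    Any stage failure raises :class:`StageError` naming the stage.  An
    empty network yields all-empty outputs and succeeds.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = FsPath(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    impact_cfg = ImpactConfig(direct_citation_impactful=config.direct_citation_impactful)

    def stage(name, fn, *args, **kw):
        try:
            result = fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc
        return result

    network = stage("ingest", _load_network, config)
    diagnostics = stage("validate", validate_network, network)
    if diagnostics:
        logger.warning("validate: %d diagnostic(s); first: %s",
                       len(diagnostics), diagnostics[0])
    logger.info("ingest: %d trials, %d articles, %d SRs, %d guidelines",
                len(network.trials), len(network.articles),
                len(network.srs), len(network.guidelines))

    impacts = stage("score", score_network, network, impact_cfg)
    pd.DataFrame([{
        "trial_id": ti.trial_id,
        "impact_on_cpgs": ti.impact_on_cpgs,
        "impacted_cpgs": ti.impacted_cpgs,
        "guideline_impact": ti.guideline_impact,
        "associated_cpgs": ti.associated_cpgs,
    } for ti in impacts.values()]).to_csv(out / "trial_impact.csv", index=False)

    fs = stage("flow", flow_summary, network, impact_cfg)
    _write_json(out / "flow_summary.json", fs.to_dict())
    logger.info("flow: %d/%d trials impactful, %d/%d guidelines impacted",
                fs.n_trials_impactful, fs.n_trials,
                fs.n_cpgs_impacted, fs.n_cpgs_associated)

    df = stage("survival", build_analysis_frame, network,
               config.censor_date, config.seed, impact_cfg)
    df.to_csv(out / "survival.csv", index=False)

    # histogram data for the two count outcomes
    for col in ("impact_on_cpgs", "impacted_cpgs"):
        if len(df):
            vc = df[col].value_counts().sort_index()
            hist = pd.DataFrame({col: vc.index, "n_trials": vc.to_numpy()})
        else:
            hist = pd.DataFrame(columns=[col, "n_trials"])
        hist.to_csv(out / f"histogram_{col}.csv", index=False)

    # models (skipped, with empty placeholders, when the data is degenerate)
    results_cols = ["term", "level", "estimate", "ci_low", "ci_high", "p"]
    for outcome in (Outcome.IMPACT_ON_CPGS, Outcome.IMPACTED_CPGS):
        fname = out / f"model_nb_{outcome.value}.csv"
        try:
            res = stage(f"fit-nb-{outcome.value}", fit_count_model, df,
                        RegressionSpec(outcome=outcome))
            res.to_frame().to_csv(fname, index=False)
        except StageError as err:
            if _degenerate(err):
                logger.warning("%s; writing empty results", err)
                pd.DataFrame(columns=results_cols).to_csv(fname, index=False)
            else:
                raise
    try:
        cox = stage("fit-cox", fit_cox, df, RegressionSpec())
        cox.to_frame().to_csv(out / "model_cox.csv", index=False)
    except StageError as err:
        if _degenerate(err):
            logger.warning("%s; writing empty results", err)
            pd.DataFrame(columns=results_cols).to_csv(out / "model_cox.csv", index=False)
        else:
            raise

    # KM curve data and yearly at-risk table
    try:
        km = stage("km", km_fit, df)
        curves = pd.DataFrame({"time_years": km.times,
                               **{g: c for g, c in km.cumulative_incidence.items()}})
        curves.to_csv(out / "km_curves.csv", index=False)
        km.at_risk.to_csv(out / "km_risk_table.csv")
        logrank_p = km.logrank_p
    except StageError as err:
        if _degenerate(err):
            pd.DataFrame(columns=["time_years"]).to_csv(out / "km_curves.csv", index=False)
            pd.DataFrame().to_csv(out / "km_risk_table.csv")
            logrank_p = float("nan")
        else:
            raise

    manifest = {
        "command": "run_pipeline",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "censor_date": config.censor_date.isoformat(),
        "software_version": __version__,
        "inputs": {"network_dir": config.network_dir, "fixture": config.fixture,
                   "generator": config.generator is not None},
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "n_trials": len(network.trials),
        "logrank_p": None if np.isnan(logrank_p) else logrank_p,
        "ci_method": "wald",
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    _write_json(out / "manifest.json", manifest)
    return out


def _degenerate(err: StageError) -> bool:
    """Model stages skip (with empty outputs) when the data cannot support
    the fit: no events/counts, or a covariate without contrast."""
    cause = err.__cause__
    return (isinstance(cause, (DegenerateFitError, SpecError))
            or "no records" in str(err))
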