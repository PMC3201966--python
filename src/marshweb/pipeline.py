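"""Pipeline orchestration: run every analysis stage from one config.

All stochastic stages derive their streams from a single master seed
via named substreams, so a run manifest (inputs, versions, seeds) is
sufficient to reproduce every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import MinresCorePeriphery, centrality_suite
from .diversity import (build_predictor_table, fit_random_forest,
                        fit_regression_tree, importance_report)
from .groups import scan_group_sizes
from .metrics import (basic_metrics, cumulative_degree_distribution,
                      fit_degree_models, generality_vulnerability)
from .nestedness import nestedness_analysis
from .parasites import (filter_viable_parasites, host_richness,
                        infer_trophic_links, read_parasite_table)
from .synthetic import (SyntheticParasiteConfig, SyntheticWebConfig,
                        generate_parasites, generate_web)
from .webio import FoodWeb, read_adjacency

__all__ = ["PipelineConfig", "run_pipeline", "substream_seed"]

log = logging.getLogger("marshweb")

REPORT_FILES = ("web_metrics.csv", "degree_fits.csv", "nestedness.csv",
                "centrality.csv", "partitions.csv", "incidence.csv",
                "model_report.csv")


def substream_seed(master: int, name: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Exactly one of ``web_paths`` (file mode) or ``synthetic`` set."""

    seed: int
    out_dir: str
    web_paths: list[str] | None = None
    parasite_table: str | None = None
    transpose: bool = False
    synthetic: dict | None = None        # SyntheticWebConfig fields
    synthetic_parasites: dict | None = None
    replicates: int = 1000
    g_range: tuple[int, int] = (2, 12)
    restarts: int = 10
    anneal_steps: int | None = None
    n_trees: int = 1000
    cv_folds: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config missing required field 'seed'")
        if "out_dir" not in raw:
            raise ValueError("config missing required field 'out_dir'")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "g_range" in raw:
            raw["g_range"] = tuple(raw["g_range"])
        return cls(**raw)

    def validate(self) -> None:
        file_mode = self.web_paths is not None
        synth_mode = self.synthetic is not None
        if file_mode == synth_mode:
            raise ValueError(
                "exactly one of 'web_paths' (file mode) or 'synthetic' "
                "(simulation mode) must be set")
        if file_mode:
            missing = [p for p in self.web_paths if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"web files not found: {missing}")
            if self.parasite_table and not Path(self.parasite_table).exists():
                raise FileNotFoundError(
                    f"parasite table not found: {self.parasite_table}")


def _load_inputs(cfg: PipelineConfig):
    if cfg.web_paths is not None:
        webs = [read_adjacency(p, transpose=cfg.transpose) for p in cfg.web_paths]
        records = (read_parasite_table(cfg.parasite_table)
                   if cfg.parasite_table else [])
        planted = {w.name: None for w in webs}
        return webs, {w.name: records for w in webs}, planted
    wcfg = SyntheticWebConfig(**{**cfg.synthetic,
                                 "seed": substream_seed(cfg.seed, "web")})
    web, groups = generate_web(wcfg)
    pk = cfg.synthetic_parasites or {}
    pcfg = SyntheticParasiteConfig(
        **{**pk, "seed": substream_seed(cfg.seed, "parasites")})
    records = generate_parasites(web, pcfg)
    return [web], {web.name: records}, {web.name: groups}


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and emit the CSV reports plus a manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "marshweb_version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "inputs": ({p: _checksum(p) for p in cfg.web_paths}
                   if cfg.web_paths else {"synthetic": cfg.synthetic}),
        "status": "running",
    }
    try:
        webs, records_by_web, planted = _load_inputs(cfg)
        log.info("loaded %d web(s)", len(webs))

        # stage: web metrics + degree fits
        metric_rows, fit_rows = [], []
        for w in webs:
            metric_rows.append(basic_metrics(w).to_row())
            dist = cumulative_degree_distribution(w)
            for f in fit_degree_models(dist):
                fit_rows.append({"web": w.name, **f.to_row()})
        pd.DataFrame(metric_rows).to_csv(out / "web_metrics.csv", index=False)
        pd.DataFrame(fit_rows).to_csv(out / "degree_fits.csv", index=False)
        manifest["stages"]["metrics"] = "ok"
        log.info("web metrics done")

        # stage: nestedness
        nest_rows = []
        for w in webs:
            res = nestedness_analysis(
                w, replicates=cfg.replicates,
                seed=substream_seed(cfg.seed, f"nestedness:{w.name}"))
            nest_rows.append(res.to_row())
        pd.DataFrame(nest_rows).to_csv(out / "nestedness.csv", index=False)
        manifest["stages"]["nestedness"] = "ok"
        log.info("nestedness done")

        # stage: centrality + coreness
        cent_frames, core_frames = [], []
        for w in webs:
            cent_frames.append(centrality_suite(w).table.assign(web=w.name))
            est = MinresCorePeriphery().fit(w)
            core_frames.append(pd.DataFrame(
                {"web": w.name, "label": list(w.labels),
                 "coreness": est.coreness_}))
        centrality_df = pd.concat(cent_frames, ignore_index=True)
        coreness_df = pd.concat(core_frames, ignore_index=True)
        centrality_df.merge(coreness_df, on=["web", "label"]).to_csv(
            out / "centrality.csv", index=False)
        manifest["stages"]["centrality"] = "ok"
        log.info("centrality done")

        # stage: group model
        part_frames, scan_frames = [], []
        group_results = {}
        for w in webs:
            gs = substream_seed(cfg.seed, f"groups:{w.name}")
            best_g, scan, results = scan_group_sizes(
                w, range(cfg.g_range[0], cfg.g_range[1] + 1),
                n_steps=cfg.anneal_steps, restarts=cfg.restarts, seed=gs)
            group_results[w.name] = results[best_g]
            scan_frames.append(scan)
            part_frames.append(pd.DataFrame(
                {"web": w.name, "label": list(w.labels),
                 "group": results[best_g].partition}))
            log.info("group scan %s: best g = %d", w.name, best_g)
        pd.concat(part_frames, ignore_index=True).to_csv(
            out / "partitions.csv", index=False)
        pd.concat(scan_frames, ignore_index=True).to_csv(
            out / "group_scan.csv", index=False)
        manifest["stages"]["groups"] = "ok"

        # stage: parasites
        inc_frames = []
        viable_by_web = {}
        for w in webs:
            viable = filter_viable_parasites(w, records_by_web[w.name])
            viable_by_web[w.name] = viable
            inc_frames.append(host_richness(w, viable))
        incidence = pd.concat(inc_frames, ignore_index=True)
        incidence.to_csv(out / "incidence.csv", index=False)
        manifest["stages"]["parasites"] = "ok"
        log.info("parasite overlay done")

        # stage: diversity models
        grp_df = pd.concat(part_frames, ignore_index=True)
        gv_df = pd.concat(
            [generality_vulnerability(w).assign(web=w.name) for w in webs],
            ignore_index=True)
        table = build_predictor_table(webs, centrality_df, coreness_df,
                                      grp_df, gv_df, incidence)
        models = {}
        ms = substream_seed(cfg.seed, "models")
        models[("regression_tree", "all")] = fit_regression_tree(
            table, cv_folds=cfg.cv_folds, seed=ms)
        models[("random_forest", "all")] = fit_random_forest(
            table, n_trees=cfg.n_trees, seed=ms)
        report = importance_report(models)
        report.to_csv(out / "model_report.csv", index=False)
        manifest["stages"]["models"] = "ok"
        log.info("diversity models done")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        raise
    finally:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        log.removeHandler(handler)
        handler.close()
    return out
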