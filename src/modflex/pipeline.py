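"""End-to-end pipeline: simulate -> DEGs -> network/modules -> preservation
(DEM calling) -> module graph -> responder analysis (METM) -> flexibility.

A run is driven by a single nested key-value config (YAML on disk).
Unknown keys are errors.  Every run writes a ``run_report.json`` embedding
the fully resolved config, per-stage wall times and the headline numbers,
so a run is reproducible from its report alone.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import __version__
from .expression import ExpressionMatrix, call_degs, filter_variance, read_expression, read_metadata
from .flexibility import (
    flexibility_profiles,
    flexibility_regression,
    profiles_table,
)
from .modgraph import build_module_graph, connectivity_matrix, graph_topology
from .network import build_network, detect_modules, export_edge_list, module_eigengene
from .preservation import preservation_table, preservation_z
from .responders import module_trait_correlation, select_metm, stratify
from .simulate import ARM_CONTROL, ARM_TREATED, SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "DEFAULT_CONFIG", "load_config", "resolve_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        # any SimulationConfig field may appear here
    },
    "input": {
        "dir": None,  # directory with expr_<arm>_<tp>.tsv + metadata.tsv when not simulating
    },
    "deg": {
        "contrast": "arm_at_timepoint",
        "timepoint": "Day30",
        "adjust": None,
    },
    "network": {
        "power": 6,  # integer, or "auto" for scale-free selection
        "signed": False,
        "top_n": None,
        "min_module_size": 30,
        "cut_height": 0.95,
        "merge_height": 0.25,
    },
    "preserve": {
        "reference": "control_Day30",
        "test": "DHI_Day30",
        "n_permutations": 100,
    },
    "modnet": {
        "edge_threshold": 0.3,
        "cs_method": "eigengene",
        "small_world_random": 20,
    },
    "respond": {
        "mode": "project",  # or "redetect"
        "trait_timepoints": ("Day0", "Day30"),
    },
    "flex": {
        "n_bins": 6,
        "tau_g": None,  # None => reference-complete calibration
        "min_bin_size": 3,
    },
}

_SIM_FIELDS = set(SimulationConfig.__dataclass_fields__)


def _check_keys(config: dict, defaults: dict, path: str = "") -> None:
    for key, value in config.items():
        here = f"{path}{key}"
        if path == "simulate." and key in _SIM_FIELDS:
            continue
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            _check_keys(value, defaults[key], here + ".")


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge user overrides onto the defaults, rejecting unknown keys."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _check_keys(overrides, DEFAULT_CONFIG)
        for key, value in overrides.items():
            if isinstance(value, dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve_config(raw)


def _dataset_key(arm: str, tp: str) -> str:
    return f"{arm}_{tp}"


def _load_datasets(config: dict, outdir: Path, seed: int):
    """Either simulate a study or read matrices from the input directory."""
    if config["simulate"]["enabled"]:
        sim_kwargs = {k: v for k, v in config["simulate"].items() if k != "enabled"}
        for key in ("module_sizes", "timepoints", "dissolved_modules", "af_range"):
            if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_kwargs.setdefault("seed", seed)
        study = simulate_study(SimulationConfig(**sim_kwargs))
        write_study(study, outdir / "sim")
        datasets = {_dataset_key(arm, tp): em for (arm, tp), em in study.expression.items()}
        return datasets, study.metadata, study.truth
    indir = config["input"]["dir"]
    if indir is None:
        raise ConfigError("simulate.enabled is false but input.dir is not set")
    indir = Path(indir)
    datasets = {}
    for path in sorted(indir.glob("expr_*.tsv")):
        key = path.stem[len("expr_"):]
        datasets[key] = read_expression(path)
    if not datasets:
        raise ConfigError(f"no expr_*.tsv matrices found in {indir}")
    meta = read_metadata(indir / "metadata.tsv")
    return datasets, meta, None


def _subject_of(sample_id: str, meta: pd.DataFrame) -> dict[str, str]:
    return dict(zip(meta["sample_id"], meta["subject_id"]))


def run_pipeline(
    config: dict,
    outdir: str | Path,
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    config = resolve_config(config if config else None)
    if seed is not None:
        config["seed"] = seed
    seed = int(config["seed"])
    outdir = Path(outdir)
    report_path = outdir / "run_report.json"
    if report_path.exists() and not force:
        raise RuntimeError(f"{report_path} exists; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"modflex_version": __version__, "config": _jsonable(config), "stages": {}}
    summary: dict = {}

    def _stage(name):
        logger.info("stage %s ...", name)
        return _StageTimer(name, report)

    try:
        with _stage("simulate"):
            datasets, meta, truth = _load_datasets(config, outdir, seed)

        with _stage("deg"):
            deg_cfg = config["deg"]
            tp = deg_cfg["timepoint"]
            both = pd.concat(
                [datasets[_dataset_key(ARM_TREATED, tp)].data, datasets[_dataset_key(ARM_CONTROL, tp)].data],
                axis=1,
            )
            degs = call_degs(
                ExpressionMatrix(both), meta,
                contrast=deg_cfg["contrast"], timepoint=tp, adjust=deg_cfg["adjust"],
            )
            (outdir / "deg").mkdir(exist_ok=True)
            degs.to_csv(outdir / "deg" / "degs.tsv", sep="\t", index=False)
            summary["n_degs"] = int(degs["is_deg"].sum())

        with _stage("network"):
            net_cfg = config["network"]
            ref_key = config["preserve"]["reference"]
            test_key = config["preserve"]["test"]
            ref_x = datasets[ref_key]
            if net_cfg["top_n"]:
                ref_x = filter_variance(ref_x, int(net_cfg["top_n"]))
            test_x = datasets[test_key].subset_genes(ref_x.gene_ids)
            power = net_cfg["power"]
            ref_net = build_network(ref_x, None if power == "auto" else float(power),
                                    signed=net_cfg["signed"])
            test_net = build_network(test_x, ref_net.power, signed=net_cfg["signed"], with_tom=False)
            partition = detect_modules(
                ref_net.tom,
                expression=ref_x,
                min_module_size=int(net_cfg["min_module_size"]),
                cut_height=float(net_cfg["cut_height"]),
                merge_height=float(net_cfg["merge_height"]),
            )
            (outdir / "network").mkdir(exist_ok=True)
            partition.to_frame().to_csv(outdir / "network" / "modules.tsv", sep="\t", index=False)
            if partition.eigengenes is not None:
                partition.eigengenes.to_csv(outdir / "network" / "eigengenes.tsv", sep="\t",
                                            index_label="sample_id")
            export_edge_list(ref_net, outdir / "network" / "edges.tsv")
            summary["power"] = ref_net.power
            summary["n_modules"] = len(partition.module_labels)

        with _stage("preserve"):
            results = preservation_z(
                ref_net, test_net, partition,
                n_permutations=int(config["preserve"]["n_permutations"]),
                seed=seed,
            )
            pres = preservation_table(results)
            (outdir / "preserve").mkdir(exist_ok=True)
            pres.to_csv(outdir / "preserve" / "preservation.tsv", sep="\t", index=False)
            dems = list(pres.loc[pres["is_dem"], "module_label"])
            summary["n_dems"] = len(dems)
            summary["dems"] = dems

        with _stage("modnet"):
            mod_cfg = config["modnet"]
            (outdir / "modnet").mkdir(exist_ok=True)
            if len(dems) >= 2:
                # CS over eigengenes of the DEMs in the *test* data (the treated network)
                test_mes = pd.DataFrame(
                    {lab: module_eigengene(test_x, partition.genes_in(lab)) for lab in dems}
                )
                cs = connectivity_matrix(test_mes, dems, method=mod_cfg["cs_method"],
                                         network=test_net, partition=partition)
                sizes = {lab: len(partition.genes_in(lab)) for lab in dems}
                mg = build_module_graph(dems, cs, float(mod_cfg["edge_threshold"]), sizes)
                mg.edge_list().to_csv(outdir / "modnet" / "edges.tsv", sep="\t", index=False)
                nx.write_graphml(mg.graph, outdir / "modnet" / "module_graph.graphml")
                features = graph_topology(mg, small_world=True,
                                          n_random=int(mod_cfg["small_world_random"]), seed=seed)
                with open(outdir / "modnet" / "features.json", "w") as fh:
                    json.dump(features.to_dict(), fh, indent=1)
                summary["module_graph"] = features.to_dict()
            else:
                logger.warning("fewer than 2 DEMs; module graph skipped")
                summary["module_graph"] = None

        with _stage("respond"):
            summary.update(
                _respond_stage(config, outdir, datasets, meta, partition, ref_net, seed)
            )

        with _stage("flex"):
            summary.update(
                _flex_stage(config, outdir, datasets, meta, partition,
                            summary.get("metm"), ref_net)
            )
    except Exception as exc:
        report["failed_stage"] = getattr(exc, "_stage_name", None)
        report["error"] = f"{type(exc).__name__}: {exc}"
        report["summary"] = _jsonable(summary)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
        raise

    report["summary"] = _jsonable(summary)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)
    return report


class _StageTimer:
    def __init__(self, name: str, report: dict):
        self.name = name
        self.report = report

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report["stages"][self.name] = {
            "seconds": round(time.perf_counter() - self.t0, 3),
            "ok": exc_type is None,
        }
        if exc is not None and not hasattr(exc, "_stage_name"):
            try:
                exc._stage_name = self.name
            except Exception:
                pass
        logger.info("stage %s done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def _respond_stage(config, outdir, datasets, meta, partition, ref_net, seed):
    """Stratify treated subjects, call per-stratum DEMs, correlate with delta-AF, pick METM."""
    mode = config["respond"]["mode"]
    tp0, tp1 = config["respond"]["trait_timepoints"]
    net_cfg = config["network"]
    strata = stratify(meta)
    out = outdir / "respond"
    out.mkdir(exist_ok=True)
    daf = meta.drop_duplicates("subject_id").set_index("subject_id")["delta_af"]
    sample_of = {
        (r["subject_id"], r["timepoint"]): r["sample_id"] for _, r in meta.iterrows()
    }
    result = {"strata": {s.name: s.n for s in strata}, "stratum_dems": {}, "metm": None}
    best_corr = None
    genes = ref_net.gene_ids

    change_all = None
    if mode == "project":
        # module scores per treated subject from the full treated data
        # (stable eigengene estimates); correlations are taken within strata
        x30_all = datasets[f"DHI_{tp1}"].subset_genes(genes)
        x0_all = datasets[f"DHI_{tp0}"].subset_genes(genes)
        subj30 = {s: meta.loc[meta["sample_id"] == s, "subject_id"].iloc[0]
                  for s in x30_all.sample_ids}
        subj0 = {s: meta.loc[meta["sample_id"] == s, "subject_id"].iloc[0]
                 for s in x0_all.sample_ids}
        cols = {}
        for lab in partition.module_labels:
            g = [g for g in partition.genes_in(lab) if g in x30_all.gene_ids]
            if len(g) < 2:
                continue
            me30 = module_eigengene(x30_all, g).rename(index=subj30)
            me0 = module_eigengene(x0_all, g).rename(index=subj0)
            cols[lab] = (me30 - me0.loc[me30.index]).astype(float)
        change_all = pd.DataFrame(cols)

    for stratum in strata:
        s30 = [sample_of[(s, tp1)] for s in stratum.subjects if (s, tp1) in sample_of]
        if len(s30) < 4:
            logger.warning("stratum %s has %d Day-30 samples; skipped", stratum.name, len(s30))
            continue
        x30 = datasets[f"DHI_{tp1}"].subset_samples(s30).subset_genes(genes)
        if mode == "redetect":
            net_s = build_network(x30, ref_net.power, signed=net_cfg["signed"])
            part_s = detect_modules(
                net_s.tom, expression=x30,
                min_module_size=int(net_cfg["min_module_size"]),
                cut_height=float(net_cfg["cut_height"]),
                merge_height=float(net_cfg["merge_height"]),
            )
            candidate_part = part_s
        elif mode == "project":
            net_s = build_network(x30, ref_net.power, signed=net_cfg["signed"], with_tom=False)
            candidate_part = partition
        else:
            raise ConfigError(f"unknown respond.mode: {mode!r}")
        if not candidate_part.module_labels:
            logger.warning("stratum %s: no modules; skipped", stratum.name)
            continue
        res = preservation_z(ref_net, net_s, candidate_part,
                             n_permutations=int(config["preserve"]["n_permutations"]), seed=seed)
        pres = preservation_table(res)
        pres.to_csv(out / f"dems_{stratum.name}.tsv", sep="\t", index=False)
        dems_s = list(pres.loc[pres["is_dem"], "module_label"])
        result["stratum_dems"][stratum.name] = len(dems_s)
        if not dems_s:
            continue
        # eigengene change Day0 -> Day30 per subject, correlated with delta-AF
        if mode == "project":
            cols = [l for l in dems_s if l in change_all.columns]
            if not cols:
                continue
            mes = change_all.loc[stratum.subjects, cols]
        else:
            s0 = [sample_of[(s, tp0)] for s in stratum.subjects if (s, tp0) in sample_of]
            x0 = datasets[f"DHI_{tp0}"].subset_samples(s0).subset_genes(genes)
            cols = {}
            for lab in dems_s:
                g = [g for g in candidate_part.genes_in(lab) if g in x30.gene_ids]
                if len(g) < 2:
                    continue
                me30 = module_eigengene(x30, g)
                me0 = module_eigengene(x0, g)
                me30.index = [sid.rsplit("_", 1)[0] for sid in me30.index]
                me0.index = [sid.rsplit("_", 1)[0] for sid in me0.index]
                cols[lab] = (me30 - me0.loc[me30.index]).astype(float)
            if not cols:
                continue
            mes = pd.DataFrame(cols)
        corr = module_trait_correlation(mes, daf)
        corr.to_csv(out / f"correlations_{stratum.name}.tsv", sep="\t", index=False)
        if stratum.name == "best":
            best_corr = corr
    if best_corr is not None:
        result["metm"] = select_metm(best_corr)
    return result


def _flex_stage(config, outdir, datasets, meta, partition, metm, ref_net):
    flex_cfg = config["flex"]
    out = outdir / "flex"
    out.mkdir(exist_ok=True)
    if metm is None or metm not in partition.module_labels:
        logger.warning("no METM available; flexibility stage skipped")
        return {"flexibility": None}
    genes = partition.genes_in(metm)
    daf = meta.drop_duplicates("subject_id").set_index("subject_id")["delta_af"]
    treated = meta[(meta["arm"] == ARM_TREATED) & (meta["timepoint"] == "Day30")]
    n_bins = int(flex_cfg["n_bins"])
    values = daf.loc[treated["subject_id"]].to_numpy()
    edges = np.linspace(values.min(), values.max() + 1e-9, n_bins + 1)
    nets, means = {}, {}
    for b in range(n_bins):
        members = treated[(values >= edges[b]) & (values < edges[b + 1])]
        if len(members) < int(flex_cfg["min_bin_size"]):
            continue
        x = datasets["DHI_Day30"].subset_samples(list(members["sample_id"])).subset_genes(genes)
        name = f"bin{b + 1}"
        nets[name] = build_network(x, ref_net.power, signed=False, with_tom=False)
        means[name] = float(daf.loc[members["subject_id"]].mean())
    if len(nets) < 3:
        logger.warning("fewer than 3 usable delta-AF bins; flexibility regression skipped")
        return {"flexibility": None}
    reference = max(means, key=means.get)
    profiles = flexibility_profiles(genes, nets, means, reference, tau_g=flex_cfg["tau_g"])
    profiles_table(profiles).to_csv(out / "profiles.tsv", sep="\t", index=False)
    fit_d, fit_edges = flexibility_regression(profiles)
    payload = {
        "metm": metm,
        "reference_stratum": reference,
        "d_regression": fit_d.to_dict(),
        "edges_regression": fit_edges.to_dict(),
    }
    payload = _jsonable(payload)
    with open(out / "regression.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"flexibility": payload}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    return obj
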