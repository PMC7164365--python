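"""Configuration-driven orchestration of the full analysis graph.

A YAML (or dict) run configuration names the inputs (tree, trait tables,
occurrence and abundance tables), the thresholds, and per-stage toggles;
``run_all`` executes the enabled stages in dependency order - diversity
extrapolation, occurrence/size/larval trait coding, birth-death and
BiSSE diversification fits, phylogenetic signal and PD, and the
stochastic-mapping + OU stage - writing JSON/TSV artifacts, a manifest
with seeds and input checksums, and a markdown summary.  A stage failure
halts its dependents but independent stages still run.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bdfit import fit_bd_suite, rates_through_time
from .bisse import bisse_model_lattice, fit_bisse
from .modelsel import select_model
from .occurrence import (chao1, code_depth_binary, code_size_binary,
                         classify_protoconch, depth_ranges_from_table,
                         diversity_sample_from_counts,
                         estimate_total_diversity, state_sampling_fractions)
from .regimes import fit_mk, fit_ou_suite, stochastic_map
from .signal import fritz_purvis_d, pagels_lambda, ses_metric
from .tables import read_occurrence_table, read_trait_table, write_trait_table
from .tree import read_newick, write_simmap

__all__ = ["RunConfig", "run_all", "load_config"]

STAGES = ("diversity", "traits", "bdfit", "bisse", "signal", "pd", "ou")
TREE_STAGES = ("bdfit", "bisse", "signal", "pd", "ou")


class RunConfig(dict):
    """Validated run configuration (a thin dict wrapper)."""

    @property
    def seed(self) -> int:
        return int(self.get("seed", 0))

    def stage_enabled(self, name: str) -> bool:
        toggles = self.get("stages", {})
        return bool(toggles.get(name, name in self))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


def _checksum(path) -> str:
    h = hashlib.sha256(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k)
                          for k in obj.__dataclass_fields__})
    if hasattr(obj, "params") and hasattr(obj, "loglik"):  # ModelFit
        return {"name": obj.name, "params": _jsonable(obj.params),
                "loglik": obj.loglik, "k": obj.k, "aic": obj.aic,
                "aicc": obj.aicc, "converged": obj.converged}
    return obj


def _validate(config: RunConfig):
    """Fail fast: every enabled stage's inputs must resolve."""
    errors = []
    tree_path = config.get("tree")
    if tree_path and not Path(tree_path).exists():
        errors.append(f"tree file not found: {tree_path}")
    for stage in STAGES:
        if not config.stage_enabled(stage):
            continue
        section = config.get(stage, {})
        for key in ("abundance_counts", "occurrences", "sizes", "whorls",
                    "traits"):
            p = section.get(key)
            if p and not Path(p).exists():
                errors.append(f"{stage}.{key} not found: {p}")
        if stage in TREE_STAGES and not tree_path:
            continue  # stage will be skipped, not an error
    if errors:
        raise FileNotFoundError("; ".join(errors))


def run_all(config, output_dir=None) -> dict:
    """Execute the enabled stages; returns the report bundle (also
    written under the output directory)."""
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    _validate(config)
    outdir = Path(output_dir or config.get("output_dir", "terebra_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report = {"stages": {}, "errors": {}}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dict(config),
        "inputs": {},
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    tree = None
    if config.get("tree"):
        manifest["inputs"]["tree"] = _checksum(config["tree"])
        tree = read_newick(Path(config["tree"]).read_text())

    traits_df = None
    if config.get("traits_table"):
        manifest["inputs"]["traits_table"] = _checksum(config["traits_table"])
        traits_df = read_trait_table(config["traits_table"])

    def run_stage(name, fn):
        if not config.stage_enabled(name):
            return
        if name in TREE_STAGES and tree is None:
            report["errors"][name] = "skipped: no tree input"
            return
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # halt dependents, keep independents running
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    # -- diversity ---------------------------------------------------------
    def stage_diversity():
        sec = config["diversity"]
        counts = pd.read_csv(sec["abundance_counts"], sep="\t")
        sample = diversity_sample_from_counts(
            dict(zip(counts["species"], counts["count"])),
            region=sec.get("region", ""))
        result = estimate_total_diversity(
            sample, int(sec["worms_described"]),
            int(sec.get("newly_delimited", 0)))
        (outdir / "diversity.json").write_text(
            json.dumps(_jsonable(result), indent=2))
        return result

    run_stage("diversity", stage_diversity)

    # -- trait coding ------------------------------------------------------
    def stage_traits():
        nonlocal traits_df
        sec = config["traits"]
        frames = {}
        if sec.get("occurrences"):
            occ = read_occurrence_table(sec["occurrences"])
            ranges = depth_ranges_from_table(occ)
            thr = float(sec.get("depth_threshold", 100.0))
            ranges["depth_state"] = [
                code_depth_binary((lo, hi), thr) for lo, hi in
                zip(ranges["depth_min_m"], ranges["depth_max_m"])]
            frames["depth"] = ranges
        if sec.get("sizes"):
            sizes = pd.read_csv(sec["sizes"], sep="\t").set_index("species")
            states, size_report = code_size_binary(
                sizes["size_mm"], float(sec.get("size_threshold", 25.0)))
            frames["size"] = pd.DataFrame(
                {"size_mm": sizes["size_mm"], "size_state": states})
            frames["size_report"] = size_report
        if sec.get("whorls"):
            wh = pd.read_csv(sec["whorls"], sep="\t").set_index("species")
            nuc = wh["nucleus_small"] if "nucleus_small" in wh else None
            cls = [classify_protoconch(
                w, None if nuc is None or pd.isna(nuc.iloc[i])
                else bool(nuc.iloc[i]))
                for i, w in enumerate(wh["whorls"])]
            frames["larval"] = pd.DataFrame(
                {"whorls": wh["whorls"],
                 "larval_class": cls,
                 "larval_state": [
                     {"planktotrophic": 0, "lecithotrophic": 1}.get(c)
                     for c in cls]}, index=wh.index)
        coded = None
        for key in ("depth", "size", "larval"):
            if key in frames:
                coded = (frames[key] if coded is None
                         else coded.join(frames[key], how="outer"))
        if coded is not None:
            write_trait_table(coded, outdir / "coded_traits.tsv")
            if traits_df is None:
                traits_df = coded
            else:  # user-supplied columns win over recoded duplicates
                new_cols = [c for c in coded.columns
                            if c not in traits_df.columns]
                traits_df = traits_df.join(coded[new_cols], how="outer")
        out = {k: (v if isinstance(v, dict) else f"{len(v)} species")
               for k, v in frames.items()}
        return out

    run_stage("traits", stage_traits)

    # -- birth-death suite -------------------------------------------------
    def stage_bdfit():
        sec = config.get("bdfit", {})
        f = float(sec.get("f", 1.0))
        suite = fit_bd_suite(tree, f=f, seed=seed,
                             n_starts=int(sec.get("n_starts", 3)))
        pd.DataFrame([{k: v for k, v in row.items() if k != "params"}
                      for row in suite["table"]]).to_csv(
            outdir / "bd_model_table.tsv", sep="\t", index=False)
        grid_step = float(sec.get("grid_step", 1.0))
        T = tree.ages()[tree.root]
        grid = np.arange(0, T + grid_step / 2, grid_step)
        best_fit = suite["fits"][suite["best"]]
        rtt = rates_through_time(best_fit, grid, crown_age=T, tree=tree)
        pd.DataFrame(rtt).to_csv(outdir / "bd_rates_through_time.tsv",
                                 sep="\t", index=False)
        out = {"best": suite["best"], "table": _jsonable(suite["table"])}
        (outdir / "bdfit.json").write_text(json.dumps(out, indent=2))
        return out

    run_stage("bdfit", stage_bdfit)

    # -- BiSSE -------------------------------------------------------------
    def stage_bisse():
        sec = config["bisse"]
        col = sec["trait_column"]
        states = traits_df[col].dropna().astype(int)
        f = (float(sec.get("f0", 1.0)), float(sec.get("f1", 1.0)))
        lattice = sec.get("models") or list(bisse_model_lattice())
        all_models = bisse_model_lattice()
        fits = [fit_bisse(tree, states, all_models[m], f=f, name=m,
                          seed=seed, n_starts=int(sec.get("n_starts", 3)))
                for m in lattice]
        decision = select_model(fits)
        out = _jsonable({"decision": decision,
                         "sampling_fractions": f})
        (outdir / "bisse.json").write_text(json.dumps(out, indent=2))
        return out

    run_stage("bisse", stage_bisse)

    # -- phylogenetic signal ----------------------------------------------
    def stage_signal():
        sec = config.get("signal", {})
        out = {}
        for col in sec.get("continuous", []):
            res = pagels_lambda(tree, traits_df[col].dropna())
            out[f"lambda[{col}]"] = _jsonable(res)
        for col in sec.get("binary", []):
            res = fritz_purvis_d(tree, traits_df[col].dropna().astype(int),
                                 n_null=int(sec.get("n_null", 1000)),
                                 seed=seed)
            out[f"D[{col}]"] = _jsonable(res)
        (outdir / "signal.json").write_text(json.dumps(out, indent=2))
        return out

    run_stage("signal", stage_signal)

    # -- phylogenetic diversity -------------------------------------------
    def stage_pd():
        sec = config.get("pd", {})
        out = {}
        for col in sec.get("binary", []):
            states = traits_df[col].dropna().astype(int)
            communities = {f"{col}={s}": states.index[states == s].tolist()
                           for s in (0, 1)}
            for metric in sec.get("metrics", ["PD", "MPD", "MNTD"]):
                res = ses_metric(tree, communities, metric=metric,
                                 n_rand=int(sec.get("n_rand", 999)),
                                 seed=seed)
                out[f"{metric}[{col}]"] = _jsonable(res)
        (outdir / "pd.json").write_text(json.dumps(out, indent=2))
        return out

    run_stage("pd", stage_pd)

    # -- stochastic mapping + OU ------------------------------------------
    def stage_ou():
        sec = config["ou"]
        discrete = traits_df[sec["discrete"]].dropna().astype(int)
        continuous = traits_df[sec["continuous"]].dropna()
        mk = fit_mk(tree, discrete, method=sec.get("mk_method", "ML"),
                    seed=seed)
        maps = stochastic_map(tree, discrete,
                              mk, n_maps=int(sec.get("n_maps", 100)),
                              seed=seed)
        with open(outdir / "simmaps.nwk", "w") as fh:
            for m in maps:
                fh.write(write_simmap(m) + "\n")
        suite = fit_ou_suite(maps, continuous,
                             models=sec.get("models"), seed=seed,
                             n_starts=int(sec.get("n_starts", 2)))
        rows = []
        for i, pm in enumerate(suite["per_map"]):
            for name, fit in pm["fits"].items():
                rows.append({"map": i, "model": name, "logL": fit.loglik,
                             "k": fit.k, "aicc": fit.aicc,
                             "weight": pm["weights"][name]})
        pd.DataFrame(rows).to_csv(outdir / "ou_per_map.tsv", sep="\t",
                                  index=False)
        out = {"mk_q": mk.q, "summary": _jsonable(suite["summary"])}
        (outdir / "ou.json").write_text(json.dumps(out, indent=2))
        return out

    run_stage("ou", stage_ou)

    manifest["stages_run"] = sorted(report["stages"])
    manifest["stage_errors"] = report["errors"]
    (outdir / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2))
    _write_summary(outdir, report)
    report["manifest"] = manifest
    report["output_dir"] = str(outdir)
    return report


def _write_summary(outdir: Path, report: dict):
    lines = ["# Run summary", ""]
    for name, result in report["stages"].items():
        lines.append(f"## {name}")
        lines.append("```json")
        lines.append(json.dumps(_jsonable(result), indent=2, default=str)[:4000])
        lines.append("```")
        lines.append("")
    if report["errors"]:
        lines.append("## Errors / skipped")
        for k, v in report["errors"].items():
            lines.append(f"- {k}: {v}")
    (outdir / "summary.md").write_text("\n".join(lines))
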