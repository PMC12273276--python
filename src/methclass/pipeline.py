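"""End-to-end orchestration: data → discover → classify → integrate → score →
survive, from a single config, with a run manifest and stage-output caching.

Every stage writes plain TSV/JSON under the run directory; the manifest
records the config hash, per-stage input/output checksums, wall-clock time
and captured warnings.  Re-running with an identical config and seed reuses
cached stage outputs; a cached output whose checksum no longer matches the
manifest raises an error naming the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .integration import (
    aggregate_to_regions,
    differential_expression,
    differential_methylation,
    overrepresentation_test,
    quadrant_assignment,
)
from .signatures import class_association, dichotomize, score_signatures, zscore_normalize
from .simulate import SimulationConfig, make_fixture_bundle
from .subtypes import CLASS_ORDER, CentroidModel, MethylationClassModel, classify_samples
from .survival import km_estimate, logrank_test, median_followup, progression_analysis

logger = logging.getLogger(__name__)

STAGE_ORDER = ["data", "discover", "classify", "integrate", "score", "survive"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _WarningCatcher(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "methclass_run",
    "simulate": {"enabled": True},
    "inputs": {},
    "discover": {"fraction": 0.01, "k_min": 2, "k_max": 6,
                 "n_resamples": 200, "subsample_frac": 0.8,
                 "max_missing_frac": 0.2},
    "classify": {"enabled": False, "beta": None, "min_shared_sites": None},
    "integrate": {"enabled": True, "group": "CIMP", "delta": 0.1,
                  "alpha": 0.05, "n_perm": 1000, "min_sites": 1},
    "score": {"enabled": True, "min_genes": 3},
    "survive": {"enabled": True},
}


def load_config(source) -> dict:
    """Merge a YAML file / dict over the defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


@dataclasses.dataclass
class RunManifest:
    package_version: str
    config_hash: str
    seed: int
    stages: dict

    def to_json(self, path: Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            path.write_text(text)
        return text


def _verify_or_invalidate(prev: dict | None, key: str, out_dir: Path) -> dict | None:
    """Return the previous stage record if it is reusable, else None.

    A matching key with an existing-but-altered output is an integrity
    failure, reported with the offending file name.
    """
    if not prev or prev.get("key") != key or prev.get("status") not in ("ok", "cached"):
        return None
    for rel, sha in prev.get("outputs", {}).items():
        p = out_dir / rel
        if not p.exists():
            return None
        if _sha256(p) != sha:
            raise ValueError(f"checksum mismatch for {rel}")
    return prev


def run_pipeline(config, seed: int | None = None) -> RunManifest:
    """Execute all enabled stages in dependency order; returns the manifest."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = _hash_obj(cfg)

    manifest_path = out_dir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}

    manifest = RunManifest(package_version=__version__, config_hash=config_hash,
                           seed=int(cfg["seed"]), stages={})
    paths: dict[str, Path] = {}
    failed = False

    for stage in STAGE_ORDER:
        record = {"status": "skipped", "outputs": {}, "seconds": 0.0, "warnings": []}
        manifest.stages[stage] = record
        runner = _STAGES[stage]
        enabled = cfg.get(stage, {}).get("enabled", True) if stage in (
            "classify", "integrate", "score", "survive") else True
        if failed or not enabled:
            continue
        key = _hash_obj({"config": cfg.get(stage, {}), "seed": cfg["seed"],
                         "inputs": {k: str(v) for k, v in paths.items()}})
        record["key"] = key
        catcher = _WarningCatcher()
        logging.getLogger("methclass").addHandler(catcher)
        t0 = time.perf_counter()
        try:
            prev = _verify_or_invalidate(previous.get(stage), key, out_dir)
            if prev is not None:
                record.update(status="cached", outputs=prev["outputs"])
                _register_outputs(stage, out_dir, prev["outputs"], paths)
            else:
                outputs = runner(cfg, out_dir, paths)
                record["outputs"] = {str(p.relative_to(out_dir)): _sha256(p)
                                     for p in outputs}
                _register_outputs(stage, out_dir, record["outputs"], paths)
                record["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest must record any failure
            record["status"] = "failed"
            record["error"] = str(exc)
            logger.error("stage %s failed: %s", stage, exc)
            failed = True
        finally:
            record["seconds"] = round(time.perf_counter() - t0, 3)
            record["warnings"] = catcher.messages
            logging.getLogger("methclass").removeHandler(catcher)

    manifest.to_json(manifest_path)
    if failed:
        bad = [s for s, r in manifest.stages.items() if r["status"] == "failed"][0]
        raise PipelineError(bad, manifest.stages[bad].get("error", "unknown"))
    return manifest


def _register_outputs(stage: str, out_dir: Path, outputs: dict, paths: dict) -> None:
    for rel in outputs:
        paths[Path(rel).stem] = out_dir / rel


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_data(cfg, out_dir: Path, paths) -> list[Path]:
    if cfg["simulate"].get("enabled", True):
        sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
        sim_cfg = SimulationConfig.from_dict(sim_kwargs)
        bundle = make_fixture_bundle(sim_cfg, out_dir / "data", seed=cfg["seed"])
        return list(bundle.values())
    inputs = cfg["inputs"]
    needed = ["beta"]
    for name in needed:
        if not inputs.get(name):
            raise ValueError(f"inputs.{name} is required when simulation is disabled")
    data_dir = out_dir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    written = []
    mapping = {"beta": ("beta.tsv", mio.read_beta_matrix, mio.write_beta_matrix),
               "expression": ("expression.tsv", mio.read_expression_matrix,
                              mio.write_expression_matrix),
               "sample_sheet": ("sample_sheet.csv", mio.read_sample_sheet,
                                mio.write_sample_sheet)}
    for name, (fname, reader, writer) in mapping.items():
        if inputs.get(name):
            obj = reader(inputs[name])
            writer(obj, data_dir / fname)
            written.append(data_dir / fname)
    for name, fname in (("promoters", "promoters.bed"), ("gmt", "signatures.gmt")):
        if inputs.get(name):
            src = Path(inputs[name])
            (data_dir / fname).write_text(src.read_text())
            written.append(data_dir / fname)
    return written


def _stage_discover(cfg, out_dir: Path, paths) -> list[Path]:
    dcfg = cfg["discover"]
    beta = mio.read_beta_matrix(paths["beta"])
    model = MethylationClassModel(beta, fraction=dcfg["fraction"],
                                  max_missing_frac=dcfg["max_missing_frac"])
    res = model.fit(
        k_range=range(int(dcfg["k_min"]), int(dcfg["k_max"]) + 1),
        n_resamples=int(dcfg["n_resamples"]),
        subsample_frac=float(dcfg["subsample_frac"]),
        seed=int(cfg["seed"]),
    )
    d = out_dir / "discover"
    d.mkdir(parents=True, exist_ok=True)
    labels = res.labels.to_frame()
    if res.k == 4:
        labels["merged"] = res.merged_labels
    labels.to_csv(d / "labels.tsv", sep="\t")
    pd.DataFrame({"site_id": res.panel.site_ids,
                  "variance": res.panel.statistic.to_numpy()}).to_csv(
        d / "panel.tsv", sep="\t", index=False, float_format="%.10g")
    (d / "consensus.json").write_text(json.dumps({
        "chosen_k": res.k,
        "areas": {str(k): v for k, v in res.consensus.areas.items()},
        "delta_areas": {str(k): v for k, v in res.consensus.delta_areas.items()},
        "weak_structure": res.consensus.weak_structure,
    }, indent=1, sort_keys=True))
    (d / "summary.txt").write_text(res.summary() + "\n")
    out = [d / "labels.tsv", d / "panel.tsv", d / "consensus.json", d / "summary.txt"]
    if res.centroid_model is not None:
        res.centroid_model.to_json(d / "centroid_model.json")
        out.append(d / "centroid_model.json")
    return out


def _stage_classify(cfg, out_dir: Path, paths) -> list[Path]:
    ccfg = cfg["classify"]
    model_path = paths.get("centroid_model")
    if model_path is None:
        raise ValueError("no centroid model from discovery (k != 4?)")
    model = CentroidModel.from_json(model_path)
    beta_new = mio.read_beta_matrix(ccfg["beta"])
    calls = classify_samples(model, beta_new,
                             min_shared_sites=ccfg.get("min_shared_sites"))
    d = out_dir / "classify"
    d.mkdir(parents=True, exist_ok=True)
    calls.to_csv(d / "transfer_labels.tsv", sep="\t", float_format="%.10g")
    return [d / "transfer_labels.tsv"]


def _read_labels(paths) -> pd.Series:
    df = pd.read_csv(paths["labels"], sep="\t", index_col=0)
    return df["class"]


def _stage_integrate(cfg, out_dir: Path, paths) -> list[Path]:
    icfg = cfg["integrate"]
    if "expression" not in paths or "promoters" not in paths:
        raise ValueError("integration needs expression and promoter inputs")
    beta = mio.read_beta_matrix(paths["beta"])
    expr = mio.read_expression_matrix(paths["expression"])
    regions = mio.read_region_bed(paths["promoters"])
    labels = _read_labels(paths)
    group = icfg["group"]
    region_beta = aggregate_to_regions(beta, regions, min_sites=int(icfg["min_sites"]))
    dm = differential_methylation(region_beta, labels, group,
                                  delta=float(icfg["delta"]),
                                  alpha=float(icfg["alpha"]))
    de = differential_expression(expr.values, labels, group,
                                 n_perm=int(icfg["n_perm"]), seed=int(cfg["seed"]))
    prom_to_gene = {r.region_id: r.region_id.removeprefix("prom_") for r in regions}
    quad = quadrant_assignment(dm, de, prom_to_gene)
    d = out_dir / "integrate"
    d.mkdir(parents=True, exist_ok=True)
    dm.to_csv(d / "differential_methylation.tsv", sep="\t", float_format="%.10g")
    de.to_csv(d / "differential_expression.tsv", sep="\t", float_format="%.10g")
    quad.to_frame().to_csv(d / "quadrants.tsv", sep="\t")
    out = [d / "differential_methylation.tsv", d / "differential_expression.tsv",
           d / "quadrants.tsv"]
    if "signatures" in paths:
        sets = mio.read_gmt(paths["signatures"])
        background = list(expr.values.index)
        target = quad.index[quad == "down_hyper"]
        ora = overrepresentation_test(target, sets, background)
        ora.to_csv(d / "overrepresentation_down_hyper.tsv", sep="\t",
                   float_format="%.10g")
        out.append(d / "overrepresentation_down_hyper.tsv")
    return out


def _stage_score(cfg, out_dir: Path, paths) -> list[Path]:
    scfg = cfg["score"]
    if "expression" not in paths or "signatures" not in paths:
        raise ValueError("scoring needs expression and a GMT file")
    expr = mio.read_expression_matrix(paths["expression"])
    sets = mio.read_gmt(paths["signatures"])
    labels = _read_labels(paths)
    z = zscore_normalize(expr.values)
    scores = score_signatures(z, sets, min_genes=int(scfg["min_genes"]))
    d = out_dir / "score"
    d.mkdir(parents=True, exist_ok=True)
    scores.to_csv(d / "scores.tsv", sep="\t", float_format="%.10g")
    dich = scores.apply(dichotomize)
    dich.to_csv(d / "dichotomy.tsv", sep="\t")
    rows = []
    for sig in scores.columns:
        try:
            chi2, dof, p, _ = class_association(dich[sig], labels)
            rows.append((sig, chi2, dof, p))
        except ValueError as exc:
            logger.warning("association for %s not computed: %s", sig, exc)
    assoc = pd.DataFrame(rows, columns=["signature", "chi2", "df", "p"])
    assoc.to_csv(d / "associations.tsv", sep="\t", index=False, float_format="%.10g")
    return [d / "scores.tsv", d / "dichotomy.tsv", d / "associations.tsv"]


def _stage_survive(cfg, out_dir: Path, paths) -> list[Path]:
    if "sample_sheet" not in paths:
        raise ValueError("survival stage needs a sample sheet")
    sheet = mio.read_sample_sheet(paths["sample_sheet"])
    labels = _read_labels(paths)
    pat = sheet.set_index("sample_id").join(labels.rename("class"), how="inner")
    times = pat["survival_months"].to_numpy(dtype=float)
    events = pat["event"].to_numpy(dtype=int)
    groups = pat["class"].to_numpy()
    curves = km_estimate(times, events, groups)
    lr = logrank_test(times, events, groups)
    fu = median_followup(times)
    prog = progression_analysis(sheet, labels)
    d = out_dir / "survive"
    d.mkdir(parents=True, exist_ok=True)
    km_rows = []
    for g, curve in curves.items():
        t = curve.table.copy()
        t.insert(0, "group", g)
        km_rows.append(t)
    pd.concat(km_rows).to_csv(d / "km_curves.tsv", sep="\t", index=False,
                              float_format="%.10g")
    medians = {g: curves[g].median for g in curves}
    stats_payload = {
        "logrank": {"statistic": lr.statistic, "df": lr.df, "p": lr.p},
        "median_followup": fu,
        "km_median_months": medians,
        "progression": {
            "counts": {c: {k: int(v) for k, v in row.items()}
                       for c, row in prog.counts.iterrows()},
            "chi2": prog.statistic, "df": prog.df, "p": prog.p,
            "pct_of_nonprogressors": prog.pct_of_nonprogressors.round(4).to_dict(),
            "degenerate": prog.degenerate,
        },
    }
    if prog.cns_counts is not None:
        stats_payload["progression"]["cns_counts"] = {
            k: int(v) for k, v in prog.cns_counts.items()}
    (d / "survival_stats.json").write_text(
        json.dumps(stats_payload, indent=1, sort_keys=True))
    return [d / "km_curves.tsv", d / "survival_stats.json"]


_STAGES = {
    "data": _stage_data,
    "discover": _stage_discover,
    "classify": _stage_classify,
    "integrate": _stage_integrate,
    "score": _stage_score,
    "survive": _stage_survive,
}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(run_dir) -> tuple[str, dict]:
    """Human-readable markdown report plus a machine-readable summary dict.

    Missing stage outputs produce sections marked absent rather than errors.
    Writes ``report.md`` and ``summary.json`` into the run directory.
    """
    run_dir = Path(run_dir)
    summary: dict = {}
    lines = ["# methclass run report", ""]

    manifest_file = run_dir / "manifest.json"
    if manifest_file.exists():
        man = json.loads(manifest_file.read_text())
        summary["seed"] = man.get("seed")
        lines.append(f"seed: {man.get('seed')}  |  config hash: "
                     f"`{man.get('config_hash', '')[:12]}`")
        warn = {s: r.get("warnings", []) for s, r in man.get("stages", {}).items()
                if r.get("warnings")}
        if warn:
            lines.append("\n## Warnings")
            for s, msgs in warn.items():
                for m in msgs:
                    lines.append(f"- [{s}] {m}")

    lines.append("\n## Methylation classes")
    labels_file = run_dir / "discover" / "labels.tsv"
    if labels_file.exists():
        labels = pd.read_csv(labels_file, sep="\t", index_col=0)["class"]
        sizes = labels.value_counts().to_dict()
        summary["class_sizes"] = {str(k): int(v) for k, v in sizes.items()}
        cons = json.loads((run_dir / "discover" / "consensus.json").read_text())
        summary["chosen_k"] = cons["chosen_k"]
        lines.append(f"chosen k = {cons['chosen_k']}; class sizes: "
                     + ", ".join(f"{c}={sizes.get(c, 0)}"
                                 for c in (CLASS_ORDER if cons['chosen_k'] == 4
                                           else sorted(sizes))))
        beta_file = run_dir / "data" / "beta.tsv"
        panel_file = run_dir / "discover" / "panel.tsv"
        if beta_file.exists() and panel_file.exists():
            beta = mio.read_beta_matrix(beta_file).beta
            panel = pd.read_csv(panel_file, sep="\t")["site_id"]
            pb = beta.loc[panel]
            means = {c: float(np.nanmean(pb[labels.index[labels == c]].to_numpy()))
                     for c in labels.unique()}
            order = [c for c in CLASS_ORDER if c in means] or sorted(means)
            summary["class_mean_beta"] = {c: round(means[c], 4) for c in order}
            lines.append("mean panel β by class: "
                         + ", ".join(f"{c}={means[c]:.3f}" for c in order))
            increasing = all(means[a] < means[b] for a, b in zip(order, order[1:]))
            summary["global_beta_ordered"] = bool(increasing)
            lines.append(f"global β strictly increasing across classes: {increasing}")
    else:
        lines.append("*absent*")

    lines.append("\n## Signature associations")
    assoc_file = run_dir / "score" / "associations.tsv"
    if assoc_file.exists():
        assoc = pd.read_csv(assoc_file, sep="\t")
        summary["signature_associations"] = assoc.round(6).to_dict(orient="records")
        for _, row in assoc.iterrows():
            lines.append(f"- {row['signature']}: chi2={row['chi2']:.2f} "
                         f"(df={int(row['df'])}), p={row['p']:.3g}")
    else:
        lines.append("*absent*")

    lines.append("\n## Survival and progression")
    surv_file = run_dir / "survive" / "survival_stats.json"
    if surv_file.exists():
        sv = json.loads(surv_file.read_text())
        summary["survival"] = sv
        lines.append(f"log-rank chi2={sv['logrank']['statistic']:.2f} "
                     f"(df={sv['logrank']['df']}), p={sv['logrank']['p']:.3g}")
        lines.append("KM median months by class: "
                     + ", ".join(f"{c}={v:.1f}" if v == v else f"{c}=NR"
                                 for c, v in sv["km_median_months"].items()))
        lines.append("non-progressor share by class (%): "
                     + ", ".join(f"{c}={v:.1f}"
                                 for c, v in sv["progression"]
                                 ["pct_of_nonprogressors"].items()))
    else:
        lines.append("*absent*")

    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return text, summary
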