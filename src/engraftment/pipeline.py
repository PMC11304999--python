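"""Config-driven end-to-end analysis runner.

One flat YAML config fully determines a run: the study source (TSV paths or
a named simulation scenario), the comparison plan, and every analysis knob.
The config is hashed into the report so each emitted number is traceable to
the settings that produced it, and a run is byte-for-byte reproducible from
its config + seed. Step wall times are logged to the console; the on-disk
report carries only deterministic provenance (hash, version, seed,
checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffab import pairwise_group_tests, top_taxa_summary
from .diversity import distance_matrix, pcoa, permanova, shannon
from .io_tables import StudyBundle, align, read_count_table, read_metadata, read_taxonomy
from .normalization import normalize_counts
from .synthetic import simulate_study
from .transfer import (
    abundance_histogram,
    between_group_efficiency,
    classify_asvs,
    stratified_efficiency,
    within_group_consistency,
)

__all__ = ["PipelineError", "load_config", "validate_config", "load_bundle", "run"]

logger = logging.getLogger("engraftment.pipeline")

_KNOB_DEFAULTS = {
    "zero_policy": "drop_joint_zeros",
    "input_mode": "average_replicates",
    "level": "asv",
    "metric": "bray_curtis",
    "n_perm": 999,
    "prevalence": 0.10,
    "fdr": 0.1,
    "bin_width": 0.5,
    "top_n": 8,
    "diffab_rank": "genus",
}


class PipelineError(RuntimeError):
    """A pipeline step failed; carries the step name."""

    def __init__(self, step: str, cause: Exception):
        super().__init__(f"step {step!r} failed: {cause}")
        self.step = step
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _knobs(cfg: dict) -> dict:
    knobs = dict(_KNOB_DEFAULTS)
    knobs.update(cfg.get("knobs") or {})
    return knobs


def validate_config(cfg: dict, bundle: StudyBundle | None = None) -> list[str]:
    """Cross-check a parsed config; returns a list of problems (empty = valid)."""
    problems: list[str] = []
    inputs = cfg.get("inputs") or {}
    has_paths = all(k in inputs for k in ("counts", "metadata"))
    has_scenario = "scenario" in inputs
    if not (has_paths or has_scenario):
        problems.append("inputs must name counts+metadata paths or a scenario")
    if has_scenario and "seed" not in cfg:
        problems.append("seed is mandatory when simulating")
    knobs = _knobs(cfg)
    if not (0 < float(knobs["prevalence"]) <= 1):
        problems.append(f"prevalence {knobs['prevalence']} outside (0, 1]")
    if not (0 < float(knobs["fdr"]) <= 1):
        problems.append(f"fdr {knobs['fdr']} outside (0, 1]")
    if int(knobs["n_perm"]) < 99:
        problems.append(f"n_perm {knobs['n_perm']} below the minimum of 99")
    if float(knobs["bin_width"]) <= 0:
        problems.append("bin_width must be positive")
    if knobs["zero_policy"] not in ("drop_joint_zeros", "keep_all"):
        problems.append(f"unknown zero_policy {knobs['zero_policy']!r}")
    if int(knobs["n_perm"]) >= 99 and "seed" not in cfg and _wants_permanova(cfg):
        problems.append("seed is mandatory when permanova is enabled")

    plan = cfg.get("plan") or {}
    if not plan:
        problems.append("empty comparison plan: nothing to do")
    if bundle is not None:
        known = set(bundle.metadata.groups)
        for pair in plan.get("efficiency") or []:
            for key in ("input_group", "recipient_group"):
                g = pair.get(key)
                if g not in known:
                    problems.append(f"efficiency: unknown group {g!r}")
        for g in plan.get("consistency") or []:
            if g not in known:
                problems.append(f"consistency: unknown group {g!r}")
        for g in (plan.get("diffab") or {}).get("groups") or []:
            if g not in known:
                problems.append(f"diffab: unknown group {g!r}")
    return problems


def _wants_permanova(cfg: dict) -> bool:
    return "permanova" in (cfg.get("plan") or {})


def load_bundle(cfg: dict) -> StudyBundle:
    """Materialize the study bundle a config points at (files or simulation)."""
    inputs = cfg.get("inputs") or {}
    if "scenario" in inputs:
        study = simulate_study(inputs["scenario"], int(cfg["seed"]))
        return study.bundle
    counts = read_count_table(inputs["counts"], inputs.get("dialect", "tsv"))
    taxonomy = read_taxonomy(inputs["taxonomy"]) if "taxonomy" in inputs else None
    metadata = read_metadata(inputs["metadata"])
    return align(counts, taxonomy, metadata)


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6f", **kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the full analysis battery; returns the run report (also written).

    Steps: normalize, efficiency, consistency, classification (+histograms),
    stratified efficiency, diversity, ordination, permanova, diffab,
    summaries — each controlled by the config's plan. A step failure aborts
    with the step name; the report of completed steps is still written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    bundle = load_bundle(cfg)
    problems = validate_config(cfg, bundle)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    knobs = _knobs(cfg)
    plan = cfg.get("plan") or {}
    seed = int(cfg.get("seed", 0))
    report: dict = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": seed,
        "knobs": knobs,
        "steps": [],
        "warnings": [],
    }
    steps_done = report["steps"]

    def step(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except Exception as exc:  # abort with step name, keep partial report
                report["failed_step"] = name
                (out / "report.json").write_text(json.dumps(report, indent=2))
                raise PipelineError(name, exc) from exc
            elapsed = time.perf_counter() - t0
            logger.info("step %s finished in %.2fs", name, elapsed)
            steps_done.append(
                {
                    "name": name,
                    "outputs": [str(p.relative_to(out)) for p in outputs],
                    "checksums": {
                        str(p.relative_to(out)): _checksum(p) for p in outputs
                    },
                }
            )

        return wrap

    norm = normalize_counts(bundle.counts)

    @step("normalize")
    def _():
        p = out / "normalized" / "normalized.tsv"
        p.parent.mkdir(parents=True, exist_ok=True)
        norm.to_tsv(p)
        return [p]

    @step("efficiency")
    def _():
        paths = []
        rows = []
        for pair in plan.get("efficiency") or []:
            res = between_group_efficiency(
                bundle,
                pair["input_group"],
                pair["recipient_group"],
                level=pair.get("level", knobs["level"]),
                input_mode=knobs["input_mode"],
                zero_policy=knobs["zero_policy"],
            )
            tag = f"{pair['input_group']}__{pair['recipient_group']}__{res.level}"
            p = out / "efficiency" / f"between_{tag}.tsv"
            _write_tsv(res.pairs, p, index=False)
            paths.append(p)
            rows.append(res.summary())
        if rows:
            p = out / "efficiency" / "between_summary.tsv"
            _write_tsv(pd.DataFrame(rows), p, index=False)
            paths.append(p)
        return paths

    @step("consistency")
    def _():
        paths = []
        rows = []
        for group in plan.get("consistency") or []:
            res = within_group_consistency(
                bundle, group, level=knobs["level"], zero_policy=knobs["zero_policy"]
            )
            p = out / "efficiency" / f"within_{group}.tsv"
            _write_tsv(res.pairs, p, index=False)
            paths.append(p)
            rows.append(res.summary())
        if rows:
            p = out / "efficiency" / "within_summary.tsv"
            _write_tsv(pd.DataFrame(rows), p, index=False)
            paths.append(p)
        return paths

    @step("classification")
    def _():
        paths = []
        for pair in plan.get("classify") or []:
            in_g = pair["input_group"]
            for rec in bundle.samples_in_group(pair["recipient_group"]):
                cls = classify_asvs(bundle, in_g, rec, input_mode=knobs["input_mode"])
                p = out / "classification" / f"cls_{in_g}__{rec}.tsv"
                _write_tsv(cls.table, p, index_label="feature_id")
                paths.append(p)
                for which in ("non_transferring", "newly_detected"):
                    hist = abundance_histogram(cls, which, float(knobs["bin_width"]))
                    hp = out / "classification" / f"hist_{which}_{in_g}__{rec}.tsv"
                    _write_tsv(hist, hp, index=False)
                    paths.append(hp)
        return paths

    @step("stratified_efficiency")
    def _():
        paths = []
        for pair in plan.get("stratified") or []:
            res = stratified_efficiency(
                bundle,
                pair["input_group"],
                pair["recipient_group"],
                input_mode=knobs["input_mode"],
                zero_policy=knobs["zero_policy"],
            )
            rows = []
            for stratum, eff in res.items():
                if eff is None:
                    rows.append(
                        {"stratum": stratum, "estimable": False, "mean_r": None,
                         "sd_r": None, "n_pairs": 0}
                    )
                    report["warnings"].append(f"stratum {stratum} not estimable")
                else:
                    rows.append(
                        {"stratum": stratum, "estimable": True, "mean_r": eff.mean_r,
                         "sd_r": eff.sd_r, "n_pairs": eff.n_pairs}
                    )
            tag = f"{pair['input_group']}__{pair['recipient_group']}"
            p = out / "efficiency" / f"stratified_{tag}.tsv"
            _write_tsv(pd.DataFrame(rows), p, index=False)
            paths.append(p)
        return paths

    @step("diversity")
    def _():
        rows = [
            {
                "sample_id": s,
                "group": bundle.metadata.table.loc[s, "group"],
                "shannon_nats": shannon(bundle.counts.counts[s]),
            }
            for s in bundle.counts.sample_ids
        ]
        p = out / "diversity" / "shannon.tsv"
        _write_tsv(pd.DataFrame(rows), p, index=False)
        return [p]

    @step("ordination")
    def _():
        step_cfg = plan.get("ordination")
        if step_cfg is None:
            return []
        dm = distance_matrix(norm.values, step_cfg.get("metric", knobs["metric"]))
        ord_res = pcoa(dm)
        p = out / "ordination" / "pcoa_coordinates.tsv"
        _write_tsv(ord_res.to_frame(), p, index_label="sample_id")
        ev = pd.DataFrame(
            {"eigenvalue": ord_res.eigenvalues}
        )
        p2 = out / "ordination" / "pcoa_eigenvalues.tsv"
        _write_tsv(ev, p2, index_label="axis")
        return [p, p2]

    @step("permanova")
    def _():
        step_cfg = plan.get("permanova")
        if step_cfg is None:
            return []
        term = step_cfg.get("term", "group")
        roles = bundle.metadata.table["role"]
        recipients = [s for s in bundle.counts.sample_ids if roles[s] == "recipient"]
        sub = normalize_counts(bundle.counts.subset_samples(recipients))
        dm = distance_matrix(sub.values, step_cfg.get("metric", knobs["metric"]))
        labels = bundle.metadata.table.loc[recipients, term].to_numpy()
        res = permanova(dm, labels, n_perm=int(knobs["n_perm"]), seed=seed)
        p = out / "ordination" / "permanova.tsv"
        _write_tsv(pd.DataFrame([res.as_dict()]), p, index=False)
        return [p]

    @step("diffab")
    def _():
        step_cfg = plan.get("diffab")
        if step_cfg is None:
            return []
        res = pairwise_group_tests(
            bundle,
            step_cfg["groups"],
            rank=step_cfg.get("rank", knobs["diffab_rank"]),
            threshold=float(knobs["prevalence"]),
            fdr_cutoff=float(knobs["fdr"]),
        )
        paths = []
        for (ga, gb), r in res.items():
            p = out / "diffab" / f"diffab_{ga}__{gb}.tsv"
            _write_tsv(r.table, p, index_label="taxon")
            paths.append(p)
        return paths

    @step("summary")
    def _():
        step_cfg = plan.get("summary")
        if step_cfg is None:
            return []
        table = top_taxa_summary(
            bundle,
            rank=step_cfg.get("rank", knobs["diffab_rank"]),
            n_top=int(step_cfg.get("top", knobs["top_n"])),
        )
        p = out / "diffab" / "top_taxa_summary.tsv"
        _write_tsv(table, p, index_label="group")
        return [p]

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
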