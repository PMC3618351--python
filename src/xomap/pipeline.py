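"""End-to-end driver: simulate (or load) -> QC -> call -> stats -> summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, datasets, model, qc, simulate, stats

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Exactly one of ``genotypes_path`` (with ``panel_path``/``chrom_sizes_path``)
    or ``sim`` must be provided."""

    out_dir: str = "xomap_out"
    panel_path: str | None = None
    chrom_sizes_path: str | None = None
    genotypes_path: str | None = None
    sim: simulate.SimConfig | None = None
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    regions: list[stats.RegionSpec] = field(default_factory=lambda: [stats.centromeric_region(),
                                                                     stats.telomeric_region()])
    comparisons: tuple = stats.DEFAULT_COMPARISONS
    proportion_cutoff: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.genotypes_path is None) == (self.sim is None):
            raise ValueError("provide exactly one of genotypes_path or a simulation config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("out_dir", "panel_path", "chrom_sizes_path", "genotypes_path",
                    "proportion_cutoff", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "qc" in raw:
            kwargs["qc"] = qc.QcConfig(**raw["qc"])
        if "sim" in raw:
            s = dict(raw["sim"])
            if kwargs.get("panel_path"):
                panel = model.read_panel(kwargs["panel_path"], kwargs["chrom_sizes_path"])
            else:
                panel = datasets.reference_panel()
            scale = s.pop("map_scale", None)
            if scale is not None:
                s["map_cm"] = {sex: simulate.default_chrom_map(sex, scale=scale)
                               for sex in ("female", "male")}
            kwargs["sim"] = simulate.SimConfig(panel=panel, seed=raw.get("seed", 0), **s)
        if "regions" in raw:
            kwargs["regions"] = [stats.RegionSpec(r["name"], [(int(c), str(sel)) for c, sel in r["members"]])
                                 for r in raw["regions"]]
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write stage TSVs plus ``summary.json``, return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.sim is not None:
        panel = config.sim.panel
        matrix, truth = simulate.simulate_offspring(config.sim)
        model.write_genotypes(matrix, out / "genotypes.tsv")
        truth.write(out / "truth.tsv")
    else:
        panel = model.read_panel(config.panel_path, config.chrom_sizes_path)
        matrix = model.read_genotypes(config.genotypes_path, panel)

    # --- qc ---------------------------------------------------------------
    qc_result = qc.run_qc(matrix, panel, config.qc)
    qc_result.report.dropped_markers.to_csv(out / "dropped_markers.tsv", sep="\t", index=False)
    qc_result.report.dropped_samples.to_csv(out / "dropped_samples.tsv", sep="\t", index=False)
    model.write_genotypes(qc_result.matrix, out / "genotypes_qc.tsv")

    scenarios = [config.qc.scenario] if config.qc.scenario != "both" else list(qc.SCENARIOS)
    per_scenario = {}
    for scen in scenarios:
        per_scenario[scen] = _run_analysis(qc_result, config, scen, truth, out)

    primary = per_scenario[scenarios[0]]
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "qc": {
            "n_markers_in": qc_result.report.n_markers_in,
            "n_markers_out": qc_result.report.n_markers_out,
            "n_samples_in": qc_result.report.n_samples_in,
            "n_samples_out": qc_result.report.n_samples_out,
            "n_residual_missing": qc_result.report.n_residual_missing,
        },
        "panel_summary": _panel_summary_doc(qc_result.panel),
        "scenarios": per_scenario,
    }
    if len(per_scenario) == 2:
        summary["scenario_bracket"] = (per_scenario["liberal"]["grand_total"]
                                       - per_scenario["conservative"]["grand_total"])
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _panel_summary_doc(panel: model.MarkerPanel) -> dict:
    s = model.summarize_panel(panel)
    return {
        "n_markers": s.n_markers,
        "n_chromosomes": s.n_chromosomes,
        "n_intervals": s.n_intervals,
        "total_length_mbp": model.round_half_up(s.total_length_mbp, 1),
        "mean_distance_mbp": model.round_half_up(s.mean_distance_mbp, 2),
        "mean_max_distance_mbp": model.round_half_up(s.mean_max_distance_mbp, 2),
        "per_chrom": s.to_frame().reset_index().to_dict(orient="records"),
    }


def _run_analysis(qc_result: qc.QcResult, config: PipelineConfig, scenario: str,
                  truth, out: Path) -> dict:
    tag = f".{scenario}"
    scen = qc.apply_missing_scenario(qc_result.matrix, qc_result.panel, scenario)
    calls = calling.call_events(scen, qc_result.panel)
    calls.to_frame().to_csv(out / f"events{tag}.tsv", sep="\t", index=False)

    cstats = calling.chrom_stats(calls, qc_result.panel)
    cstats.to_csv(out / f"chrom_stats{tag}.tsv", sep="\t", index=False)
    means = calling.group_means(calls)
    means.reset_index().to_csv(out / f"group_means{tag}.tsv", sep="\t", index=False)

    sample_totals = pd.DataFrame({"sample_id": calls.sample_ids, "group": calls.groups,
                                  "total": calls.per_sample_total()})
    sample_totals.to_csv(out / f"sample_totals{tag}.tsv", sep="\t", index=False)

    comparisons = []
    totals = calls.per_sample_total()
    mw_pairs = [("FWT", "MWT"), ("FKO", "MKO"), ("FWT", "FKO"), ("MWT", "MKO")]
    present = set(calls.groups)
    mw_pairs = [p for p in mw_pairs if set(p) <= present]
    for a, b in mw_pairs:
        r = stats.mann_whitney_groups(totals[calls.group_mask(a)], totals[calls.group_mask(b)],
                                      family_size=len(mw_pairs), labels=(a, b))
        comparisons.append(_comparison_doc(r))

    region_docs = []
    for region in config.regions:
        try:
            r, summ = stats.region_compare(calls, region)
        except ValueError as exc:
            logger.warning("region %s skipped: %s", region.name, exc)
            continue
        region_docs.append({"region": region.name, "comparison": _comparison_doc(r),
                            "means": summ.to_dict(orient="records")})

    pairs = [p for p in config.comparisons if set(p) <= present]
    interval_doc = None
    if pairs:
        itab = stats.fisher_intervals(calls, comparisons=pairs,
                                      proportion_cutoff=config.proportion_cutoff)
        itab.to_csv(out / f"interval_stats{tag}.tsv", sep="\t", index=False)
        interval_doc = {
            "family_size": itab.attrs["family_size"],
            "threshold": itab.attrs["threshold"],
            "n_significant": int(itab["significant"].sum()),
        }

    doc = {
        "scenario": scenario,
        "grand_total": calls.grand_total(),
        "group_means": means.reset_index().to_dict(orient="records"),
        "chrom_table": calling.chrom_stats_table(cstats).reset_index().to_dict(orient="records"),
        "comparisons": comparisons,
        "regions": region_docs,
        "interval_tests": interval_doc,
    }
    fm = {r["group"]: r["mean"] for r in doc["group_means"]}
    if "FWT" in fm and "MWT" in fm:
        doc["sex_averaged_wt"] = calling.sex_averaged(fm["FWT"], fm["MWT"])
    if truth is not None and set(truth.sample_ids) >= set(calls.sample_ids):
        sub_truth = truth if set(truth.sample_ids) == set(calls.sample_ids) else None
        if sub_truth is not None:
            power = stats.detection_power(calls, sub_truth, qc_result.panel)
            doc["detection_power"] = {
                "fraction": power.fraction, "n_called": power.n_called, "n_true": power.n_true,
                "n_true_out_of_span": power.n_true_out_of_span,
                "n_cancelled_in_span": power.n_cancelled_in_span,
                "residual": power.residual,
            }
    return doc


def _comparison_doc(r: stats.ComparisonResult) -> dict:
    return {"test": r.test, "groups": list(r.groups), "statistic": r.statistic,
            "p": r.p_value, "family_size": r.family_size, "threshold": r.threshold,
            "significant": bool(r.significant)}
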