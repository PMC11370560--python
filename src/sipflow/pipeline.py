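"""End-to-end orchestration: simulate/ingest -> metrics -> statistics.

``run_pipeline`` executes the full analysis battery on either simulated or
on-disk input streams and writes every intermediate table plus a single
``report.json`` holding the sex-wise analyses, the behavioural clustering,
and the cluster-wise reruns.  Each stage logs one structured line with its
input/output row counts, which doubles as the run's audit trail.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, intake_metrics, phenotype_clustering, polysubstance, preference, stats_engine
from . import stream_io, synthetic_data

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "export_report", "validate_report"]

log = logging.getLogger("sipflow")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration (mirrors the YAML run file).

    Exactly one of ``simulate`` (a SimConfig) or ``inputs`` (paths to
    animals/stations/rfid/vdm/behavior CSVs) must be provided.
    """

    out_dir: str = "sipflow_out"
    simulate: synthetic_data.SimConfig | None = None
    inputs: dict | None = None
    lights_on_hour: float = 6.0
    window_minutes: float = 60.0
    max_gap: float = 1.0
    tolerance: float = 2.0
    cluster_k: int | str = "auto"
    cluster_boot: int = 100
    cluster_n_init: int = 10
    cluster_k_range: tuple = (3, 6)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulate", None)
        cfg = cls(**{k: v for k, v in doc.items() if k != "inputs"})
        cfg.inputs = doc.get("inputs")
        if sim is not None:
            cfg.simulate = synthetic_data.SimConfig(**sim)
        if cfg.window_minutes <= 0:
            raise ValueError("window_minutes must be positive")
        return cfg


def _load_inputs(cfg: RunConfig):
    if (cfg.simulate is None) == (cfg.inputs is None):
        raise PipelineError("ingest", "config must set exactly one of simulate/inputs")
    if cfg.simulate is not None:
        fixture = synthetic_data.simulate_cohort(cfg.simulate)
        return (
            fixture.animals,
            fixture.stations,
            fixture.rfid,
            fixture.vdm,
            fixture.behavior,
            fixture.truth,
        )
    paths = cfg.inputs
    for key in ("animals", "stations", "rfid", "vdm", "behavior"):
        if key not in paths:
            raise PipelineError("ingest", f"missing input path for {key!r}")
        if not Path(paths[key]).exists():
            raise PipelineError("ingest", f"input file not found: {paths[key]}")
    animals = stream_io.read_animals(paths["animals"])
    stations = stream_io.read_stations(paths["stations"])
    rfid = stream_io.read_rfid_stream(paths["rfid"])
    vdm = stream_io.read_vdm_stream(paths["vdm"])
    behavior = pd.read_csv(paths["behavior"])
    return animals, stations, rfid, vdm, behavior, None


def _poly_section(windows, group_labels, n_days, mode):
    """Distributions and chi-square contrasts for one mode and one grouping."""
    dists_all = polysubstance.combination_distribution(windows, mode, group_labels, scope="all")
    tests = {}
    for ring in ("outer", "inner"):
        try:
            res = polysubstance.compare_distributions(dists_all, ring)
            tests[f"all_days_{ring}"] = res.to_dict()
        except stats_engine.DegenerateTableError as exc:
            tests[f"all_days_{ring}"] = {"error": str(exc)}
    # first vs last day within each group
    for g in dists_all:
        d1 = polysubstance.combination_distribution(windows, mode, group_labels, day=1)
        d7 = polysubstance.combination_distribution(windows, mode, group_labels, day=n_days)
        if g in d1 and g in d7:
            for ring in ("outer", "inner"):
                try:
                    res = polysubstance.compare_distributions([d1[g], d7[g]], ring)
                    tests[f"{g}_day1_vs_day{n_days}_{ring}"] = res.to_dict()
                except stats_engine.DegenerateTableError as exc:
                    tests[f"{g}_day1_vs_day{n_days}_{ring}"] = {"error": str(exc)}
    frames = [d.to_frame() for d in dists_all.values()]
    return {
        "distributions": pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(),
        "tests": tests,
    }


def _group_analyses(intake_total, intake_day, events, windows_by_mode,
                    roster, group_labels, group_name, n_days):
    """The per-substance ANOVA battery and preference tests for one grouping."""
    section = {}
    # group x substance mixed ANOVA on total normalised intake
    tot = intake_total.copy()
    tot["category"] = tot["substance"] + ":" + tot["dose_label"]
    tot["group"] = tot["tag"].map(group_labels)
    long = tot.rename(columns={"tag": "subject", "category": "within",
                               "normalized_ml_per_kg": "value"})
    try:
        fit = stats_engine.mixed_rm_anova(long[["subject", "group", "within", "value"]])
        section["intake_group_by_substance"] = fit.to_dict()
    except ValueError as exc:
        section["intake_group_by_substance"] = {"error": str(exc)}

    # group x day mixed ANOVA per substance category
    per_substance = {}
    day = intake_day.copy()
    day["category"] = day["substance"] + ":" + day["dose_label"]
    day["group"] = day["tag"].map(group_labels)
    for cat, sub in day.groupby("category"):
        long = sub.rename(columns={"tag": "subject", "day": "within",
                                   "normalized_ml_per_kg": "value"})
        try:
            fit = stats_engine.mixed_rm_anova(long[["subject", "group", "within", "value"]])
            per_substance[cat] = fit.to_dict()
        except ValueError as exc:
            per_substance[cat] = {"error": str(exc)}
    section["intake_group_by_day_per_substance"] = per_substance
    return section


def _preference_tests(intake_total, group_labels):
    """Between-group tests on each total-scope preference index.

    Two groups -> Student's t; three or more -> one-way ANOVA.  Undefined
    (NaN) indices are excluded pairwise.
    """
    out = {}
    for substance in ("ethanol", "fentanyl"):
        for fn, kind in (
            (preference.substance_preference, f"{substance}/water"),
            (preference.dose_preference, f"{substance}-dose"),
        ):
            pref = fn(intake_total, substance, scope="total")
            pref["group"] = pref["tag"].map(group_labels)
            defined = pref[pref["defined"]]
            groups = [g["value"].to_numpy() for _, g in defined.groupby("group")]
            try:
                if len(groups) == 2:
                    res = stats_engine.t_test(groups[0], groups[1])
                else:
                    res = stats_engine.oneway_anova(groups)
                out[kind] = res.to_dict()
            except ValueError as exc:
                out[kind] = {"error": str(exc)}
            out[kind + "_n_undefined"] = int((~pref["defined"]).sum())
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the bundle (all tables + report doc).

    Writes the CSV/JSON interfaces into ``cfg.out_dir``.  Raises
    :class:`PipelineError` naming the failing stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"counts": {}}

    log.info("stage=ingest starting")
    animals, stations, rfid, vdm, behavior, truth = _load_inputs(cfg)
    n_days = (
        cfg.simulate.n_days
        if cfg.simulate is not None
        else (int(rfid["t_sec"].max() // 86400) + 1 if len(rfid) else 1)
    )
    bundle["counts"].update(
        {"animals": len(animals), "rfid_reads": len(rfid), "vdm_rows": len(vdm)}
    )
    log.info("stage=ingest animals=%d rfid=%d vdm=%d", len(animals), len(rfid), len(vdm))

    try:
        bouts = stream_io.collapse_visits(rfid, max_gap=cfg.max_gap)
        assignment = stream_io.assign_drinks(vdm, bouts, animals, stations, tolerance=cfg.tolerance)
    except (ValueError, KeyError) as exc:
        raise PipelineError("integrate", str(exc)) from exc
    events = assignment.events
    bundle["counts"].update(
        {
            "bouts": len(bouts),
            "events": len(events),
            "unassigned": assignment.n_unassigned,
            "overlap_drinks": assignment.n_overlap,
        }
    )
    log.info(
        "stage=integrate bouts=%d events=%d unassigned=%d",
        len(bouts), len(events), assignment.n_unassigned,
    )

    try:
        intake_total = intake_metrics.aggregate_intake(events, animals, "total", stations, n_days)
        intake_day = intake_metrics.aggregate_intake(events, animals, "day", stations, n_days)
        intake_phase = intake_metrics.aggregate_intake(events, animals, "phase", stations, n_days)
        intake_dz = intake_metrics.aggregate_intake(events, animals, "day_zt", stations, n_days)
        occupancy = intake_metrics.chamber_occupancy(bouts, "day_zt", n_days)
        heat_sex = intake_metrics.heatmap_matrix(intake_dz, animals, "sex")
    except ValueError as exc:
        raise PipelineError("intake", str(exc)) from exc
    log.info("stage=intake rows_total=%d rows_day_zt=%d", len(intake_total), len(intake_dz))

    try:
        pref_long = preference.preference_long(intake_total, intake_day)
    except ValueError as exc:
        raise PipelineError("preference", str(exc)) from exc
    log.info("stage=preference rows=%d", len(pref_long))

    try:
        windows = {m: polysubstance.classify_windows(events, m, cfg.window_minutes)
                   for m in polysubstance.MODES}
    except ValueError as exc:
        raise PipelineError("poly", str(exc)) from exc
    bundle["counts"]["windows_collapsed"] = len(windows["collapsed"])
    log.info("stage=poly windows=%d", len(windows["collapsed"]))

    try:
        clust = phenotype_clustering.phenotype_pipeline(
            behavior,
            k=cfg.cluster_k,
            k_range=range(cfg.cluster_k_range[0], cfg.cluster_k_range[1] + 1),
            n_boot=cfg.cluster_boot,
            n_init=cfg.cluster_n_init,
            seed=cfg.seed,
        )
        cluster_table, cluster_sex_chi2 = phenotype_clustering.cluster_by_group_table(
            clust["labels"], animals
        )
    except ValueError as exc:
        raise PipelineError("cluster", str(exc)) from exc
    labels = clust["labels"]
    log.info("stage=cluster k=%d", clust["model"].k)

    sex_labels = animals.set_index("tag")["sex"]
    cluster_labels = labels.astype(str)

    report = {
        "meta": {
            "version": __version__,
            "seed": cfg.seed,
            "n_days": n_days,
            "counts": bundle["counts"],
        },
        "sex_intake": _group_analyses(
            intake_total, intake_day, events, windows, animals, sex_labels, "sex", n_days
        ),
        "sex_preference": _preference_tests(intake_total, sex_labels),
        "sex_polysubstance": {
            m: _poly_section(windows[m], sex_labels, n_days, m)["tests"]
            for m in polysubstance.MODES
        },
        "clustering": {
            "explained_variance_ratio": clust["pca"].explained_variance_ratio.tolist(),
            "n_components": clust["n_components"],
            "k": clust["model"].k,
            "stability": clust["stability"].table.reset_index().to_dict(orient="records"),
            "recommended_k": clust["stability"].recommended_k,
            "cluster_by_sex_table": cluster_table.to_dict(),
            "cluster_by_sex_chi2": cluster_sex_chi2.to_dict(),
        },
        "cluster_intake": _group_analyses(
            intake_total, intake_day, events, windows, animals, cluster_labels, "cluster", n_days
        ),
        "cluster_preference": _preference_tests(intake_total, cluster_labels),
        "cluster_polysubstance": {
            m: _poly_section(windows[m], cluster_labels, n_days, m)["tests"]
            for m in polysubstance.MODES
        },
    }
    if truth is not None:
        report["meta"]["simulated"] = True

    # ---- write the bundle ------------------------------------------------
    intake_dz.to_csv(out / "intake_long.csv", index=False)
    occupancy.to_csv(out / "occupancy_long.csv", index=False)
    heat_sex.to_csv(out / "heatmap_long.csv", index=False)
    pref_long.to_csv(out / "preference_long.csv", index=False)
    pd.concat(
        [w.assign(mode=m) for m, w in windows.items()], ignore_index=True
    ).to_csv(out / "poly_windows.csv", index=False)
    poly_frames = []
    for m in polysubstance.MODES:
        for lab_name, labs in (("sex", sex_labels), ("cluster", cluster_labels)):
            sec = _poly_section(windows[m], labs, n_days, m)
            poly_frames.append(sec["distributions"].assign(grouping=lab_name))
    pd.concat(poly_frames, ignore_index=True).to_csv(out / "poly_distributions.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    with open(out / "pca_model.json", "w") as fh:
        json.dump(clust["pca"].to_dict(), fh, indent=1)
    labels.rename("label").reset_index().to_csv(out / "clusters.csv", index=False)
    clust["stability"].table.to_csv(out / "stability.csv")
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    doc = export_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(doc, fh, indent=1, default=str)

    bundle.update(
        {
            "animals": animals,
            "stations": stations,
            "bouts": bouts,
            "events": events,
            "intake_total": intake_total,
            "intake_day": intake_day,
            "intake_phase": intake_phase,
            "intake_day_zt": intake_dz,
            "occupancy": occupancy,
            "preference": pref_long,
            "windows": windows,
            "clustering": clust,
            "labels": labels,
            "report": doc,
            "truth": truth,
            "out_dir": str(out),
        }
    )
    log.info("stage=report sections=%d out=%s", len(doc), out)
    return bundle


REQUIRED_SECTIONS = (
    "meta",
    "sex_intake",
    "sex_preference",
    "sex_polysubstance",
    "clustering",
    "cluster_intake",
    "cluster_preference",
    "cluster_polysubstance",
)


def validate_report(doc: dict) -> None:
    """Check the report against the shipped schema; raise listing gaps."""
    with resources.files("sipflow").joinpath("report_schema.json").open() as fh:
        schema = json.load(fh)
    missing = [s for s in schema["required_sections"] if s not in doc]
    if missing:
        raise PipelineError("report", f"missing report sections: {missing}")


def export_report(report: dict) -> dict:
    """Validate and return the single-document summary."""
    validate_report(report)
    return report
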