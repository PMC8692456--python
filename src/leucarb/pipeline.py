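"""Run orchestration: configuration, table I/O, staged execution, logging.

A run is described by a :class:`RunConfig` (YAML-loadable).  Stages execute
in method order — simulate, estimate-cf, php-model, correlate, community,
predict-cf — each reading the delimited-text outputs of its predecessors
from the run directory, so any stage can also be pointed at real data laid
out in the same schemas.  Every output file carries the config hash in a
comment header; a per-run log records seeds, filters and exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cf_estimator as cfe
from . import community_composition as cc
from . import php_depth_models as php
from .cf_predictor import fit_cf_model
from .dom_optics import StationDepthRecord, correlation_screen, screen_to_frame
from .synthetic_data import (
    CommunitySimParams,
    IncubationSimParams,
    ProfileSimParams,
    DEFAULT_ANCHORS,
    simulate_asv_table,
    simulate_depth_profiles,
    simulate_incubation,
    simulate_lir_profile,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "estimate_cf", "php_model", "correlate", "community", "predict_cf")

EXPERIMENT_SCHEMA = {
    "station": str, "depth_m": float, "sample_id": str, "curve_id": str,
    "time_d": float, "biomass_ugc_per_l": float, "lir_pmol_per_l_h": float,
}
PROFILE_SCHEMA = {
    "station": str, "depth_m": float, "tpot": float, "sal": float, "oxy": float,
    "doc": float, "peak_m": float, "peak_t": float, "a254": float,
    "a340": float, "a365": float, "s275_295": float,
}
LIR_SCHEMA = {"station": str, "depth_m": float, "lir_pmol_per_l_h": float}


class UserInputError(ValueError):
    """Bad configuration or input data (CLI exit code 1)."""


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 1
    alpha: float = 0.1
    stages: tuple = ALL_STAGES
    rarefaction_depth: int = 0  # 0: rarefy to the smallest sample
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise UserInputError("seed must be an integer")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise UserInputError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise UserInputError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise UserInputError(f"bad config: {exc}") from exc

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# table I/O

def write_table(path, df: pd.DataFrame, comments: dict | None = None) -> None:
    """Write a CSV with '#' comment header lines, 12-significant-digit
    floats and 'NA' for missing values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, float_format="%.12g", na_rep="NA")


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a schema-checked CSV written by :func:`write_table`.

    The header must carry exactly the schema's columns (missing/extra are
    listed in the error); 'NA' cells become missing values.  Depth columns
    must be non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise UserInputError(f"input file not found: {path}")
    df = pd.read_csv(path, comment="#", na_values=["NA"], keep_default_na=False)
    missing = set(schema) - set(df.columns)
    extra = set(df.columns) - set(schema)
    if missing or extra:
        raise UserInputError(
            f"{path.name}: schema mismatch (missing: {sorted(missing)}, "
            f"extra: {sorted(extra)})"
        )
    for col, dtype in schema.items():
        df[col] = df[col].astype(dtype)
        if col.startswith("depth") and (df[col].dropna() < 0).any():
            raise UserInputError(f"{path.name}: negative values in column {col!r}")
    return df


# --------------------------------------------------------------------------
# stages

# Campaign-shaped experiment design: (station, depth, sample_id, n_curves,
# true conversion factor).  Truths follow the published depth gradient.
_EXPERIMENT_DESIGN = (
    ("FIN111", 50.0, "50", 1, 3.91),
    ("FIN111", 100.0, "100", 1, 4.00),
    ("FIN11", 500.0, "500", 1, 2.12),
    ("FIN11", 1000.0, "1000_a", 3, 1.19),
    ("FIN11", 1000.0, "1000_b", 3, 1.59),
    ("FIN11", 2000.0, "2000", 3, 1.50),
    ("SAN115", 500.0, "500", 3, 0.31),
    ("SAN115", 1000.0, "1000", 3, 0.31),
    ("SAN115", 2000.0, "2000", 2, 0.10),
)


def _stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    rows = []
    k = 0
    for station, depth, sample, n_curves, true_cf in _EXPERIMENT_DESIGN:
        for c in range(n_curves):
            k += 1
            crash = (3.0,) if c == 1 else ()  # second curve of each sample crashes
            params = IncubationSimParams(
                true_cf=true_cf, biomass_cv=cfg.noise_cv, lir_cv=cfg.noise_cv,
                crash_times=crash, crash_fraction=0.6,
                seed=cfg.seed * 10_000 + k, station=station, depth=depth,
                curve_id=f"{sample}.{c + 1}",
            )
            tc = simulate_incubation(params)
            for t, b, l in zip(tc.times, tc.biomass, tc.lir):
                rows.append((station, depth, sample, tc.curve_id, t, b, l))
    exp = pd.DataFrame(rows, columns=list(EXPERIMENT_SCHEMA))
    meta = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    write_table(outdir / "experiments.csv", exp, meta)

    frames = []
    for i, station in enumerate(("FIN", "SAN")):
        anchors = dict(DEFAULT_ANCHORS)
        if station == "SAN":  # slightly DOM-richer at surface, as observed
            anchors.update(doc=(81.0, 50.0), peak_m=(0.63, 0.91), a254=(1.90, 0.93))
        recs = simulate_depth_profiles(ProfileSimParams(
            anchors=anchors, noise_cv=cfg.noise_cv, station=station,
            seed=cfg.seed * 100 + i,
        ))
        frames.append(pd.DataFrame([
            {"station": r.station, "depth_m": r.depth,
             **{k: getattr(r, k) for k in PROFILE_SCHEMA if k not in ("station", "depth_m")}}
            for r in recs
        ]))
    write_table(outdir / "profiles.csv", pd.concat(frames, ignore_index=True), meta)

    lir_frames = [
        simulate_lir_profile(
            depths=np.geomspace(50, 2000, 20), surface_lir=20.0, deep_lir=0.1,
            noise_cv=max(cfg.noise_cv, 0.2), station=st, seed=cfg.seed * 100 + 7 + i,
        ).rename(columns={"depth_m": "depth_m"})
        for i, st in enumerate(("FIN", "SAN"))
    ]
    write_table(outdir / "lir_profiles.csv", pd.concat(lir_frames, ignore_index=True), meta)

    table = simulate_asv_table(CommunitySimParams(seed=cfg.seed * 100 + 13))
    table.counts.to_csv(outdir / "asv_counts.tsv", sep="\t")
    table.taxonomy.rename("taxon").to_csv(outdir / "asv_taxonomy.tsv", sep="\t")
    table.metadata.to_csv(outdir / "sample_metadata.csv")
    logger.info("simulate: %d curves, %d profile rows", k, 2 * 6)


def _stage_estimate_cf(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    exp = read_table(outdir / "experiments.csv", EXPERIMENT_SCHEMA)
    curve_rows, sample_aggs = [], {}
    for (station, depth, sample), grp in exp.groupby(
        ["station", "depth_m", "sample_id"], sort=True
    ):
        fits = []
        for curve_id, cg in grp.groupby("curve_id", sort=True):
            cg = cg.sort_values("time_d")
            tc = cfe.IncubationTimeCourse(
                station=station, depth=depth, curve_id=curve_id,
                times=tuple(cg["time_d"]), biomass=tuple(cg["biomass_ugc_per_l"]),
                lir=tuple(cg["lir_pmol_per_l_h"]),
            )
            series = cfe.accumulate_curve(tc)
            if series.excluded:
                logger.info("curve %s/%s: excluded timepoints %s",
                            station, curve_id, [i for i, _ in series.excluded])
            fit = cfe.fit_curve(series)
            fits.append(fit)
            curve_rows.append((station, depth, sample, curve_id, "curve",
                               fit.ecf, fit.se, fit.p_value, fit.n_points))
        agg = cfe.aggregate_sample(fits, alpha=cfg.alpha)
        sample_aggs.setdefault((station, depth), []).append(agg)
        curve_rows.append((station, depth, sample, "", "sample",
                           agg.mean_ecf, agg.sem, np.nan, agg.n))
    for (station, depth), aggs in sorted(sample_aggs.items()):
        usable = [a for a in aggs if a.has_estimate]
        if not usable:
            logger.warning("no significant curves at %s %gm", station, depth)
            continue
        dep = cfe.aggregate_depth(usable)
        curve_rows.append((station, depth, "", "", "depth",
                           dep.mean_ecf, dep.sem, np.nan, dep.n))
    out = pd.DataFrame(curve_rows, columns=[
        "station", "depth_m", "sample_id", "curve_id", "level",
        "ecf", "se", "p_value", "n",
    ])
    write_table(outdir / "cf_table.csv", out,
                {"config_hash": cfg.config_hash, "alpha": cfg.alpha})
    return out


def _depth_ecfs(outdir: Path) -> pd.DataFrame:
    cf = read_table(outdir / "cf_table.csv", {
        "station": str, "depth_m": float, "sample_id": str, "curve_id": str,
        "level": str, "ecf": float, "se": float, "p_value": float, "n": float,
    })
    dep = cf[cf["level"] == "depth"][["station", "depth_m", "ecf"]].copy()
    dep["section"] = dep["station"].str.extract(r"^([A-Z]+)")
    return dep


def _stage_php_model(cfg: RunConfig, outdir: Path) -> dict:
    lir = read_table(outdir / "lir_profiles.csv", LIR_SCHEMA)
    dep = _depth_ecfs(outdir)
    # per-layer mean empirical CF by section, applied to in situ LIR profiles
    dep["layer"] = dep["depth_m"].map(php.assign_layer)
    layer_cf = dep.groupby(["section", "layer"])["ecf"].mean()
    section_default = dep.groupby("section")["ecf"].mean()

    rows = []
    for _, r in lir.iterrows():
        layer = php.assign_layer(r["depth_m"])
        section = r["station"][:3]
        ecf = layer_cf.get((section, layer), section_default.get(section, np.nan))
        for variant, cf_val in (("empirical", ecf), ("theoretical", cfe.THEORETICAL_CF)):
            est = php.make_php_estimate(r["depth_m"], r["lir_pmol_per_l_h"], cf_val, variant)
            rows.append((r["station"], est.depth, est.layer, variant, cf_val, est.php))
    out = pd.DataFrame(rows, columns=["station", "depth_m", "layer", "variant",
                                      "cf_used", "php_umol_m3_d"])
    write_table(outdir / "php.csv", out, {"config_hash": cfg.config_hash})

    report = {}
    for variant in ("empirical", "theoretical"):
        sub = out[out["variant"] == variant]
        linear, quad, sel = php.fit_depth_model(sub["depth_m"], sub["php_umol_m3_d"])
        report[variant] = {
            "linear": {"coefficients": list(linear.coefficients), "r2": linear.r2,
                       "aic": linear.aic},
            "quadratic": {"coefficients": list(quad.coefficients), "r2": quad.r2,
                          "aic": quad.aic},
            "selected": sel.model,
        }
    e = out[out["variant"] == "empirical"]
    groups = {lay: g["php_umol_m3_d"].to_numpy()
              for lay, g in e.groupby("layer") if len(g) >= 2}
    sections = {st: g["php_umol_m3_d"].to_numpy()
                for st, g in e.groupby("station") if len(g) >= 2}
    comp = php.layer_comparisons(groups, sections if len(sections) == 2 else None)
    report["layer_anova"] = {"f": comp.anova_f, "p": comp.anova_p}
    if comp.section_p is not None:
        report["section_ttest"] = {"t": comp.section_t, "p": comp.section_p}
    with open(outdir / "depth_models.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _stage_correlate(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    prof = read_table(outdir / "profiles.csv", PROFILE_SCHEMA)
    dep = _depth_ecfs(outdir)
    prof["section"] = prof["station"].str.extract(r"^([A-Z]+)")
    merged = dep.merge(prof, on=["section", "depth_m"], how="inner",
                       suffixes=("", "_prof"))
    if len(merged) < 3:
        raise UserInputError("fewer than 3 eCF/profile matches; cannot correlate")
    records = [
        StationDepthRecord(
            station=r["station_prof"], depth=r["depth_m"], tpot=r["tpot"],
            sal=r["sal"], oxy=r["oxy"], doc=r["doc"], peak_m=r["peak_m"],
            peak_t=r["peak_t"], a254=r["a254"], a340=r["a340"], a365=r["a365"],
            s275_295=r["s275_295"],
        )
        for _, r in merged.iterrows()
    ]
    results = correlation_screen(merged["ecf"].tolist(), records, alpha=cfg.alpha)
    out = screen_to_frame(results)
    write_table(outdir / "correlations.csv", out,
                {"config_hash": cfg.config_hash, "alpha": cfg.alpha})
    return out


def _stage_community(cfg: RunConfig, outdir: Path) -> dict:
    counts = pd.read_csv(outdir / "asv_counts.tsv", sep="\t", index_col=0)
    taxonomy = pd.read_csv(outdir / "asv_taxonomy.tsv", sep="\t", index_col=0)["taxon"]
    metadata = pd.read_csv(outdir / "sample_metadata.csv", index_col=0)
    table = cc.ASVTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
    table = cc.remove_singletons(table)
    depth = cfg.rarefaction_depth or int(table.sample_sums.min())
    table = cc.rarefy(table, depth, seed=cfg.seed)

    div = pd.DataFrame([
        {"sample": s, "shannon_h": m.shannon_h, "chao1": m.chao1,
         "observed_asvs": m.observed_asvs}
        for s, m in ((s, cc.diversity(row)) for s, row in table.counts.iterrows())
    ])
    write_table(outdir / "diversity.csv", div, {"config_hash": cfg.config_hash,
                                                "rarefaction_depth": depth})

    layers = metadata.loc[table.counts.index, "depth_m"].map(php.assign_layer)
    agg = cc.aggregate_phylotypes(table)
    res = cc.anosim(cc.bray_curtis(agg), layers.to_numpy(), seed=cfg.seed)
    clr_mat = cc.zero_replace_clr(table)
    write_table(outdir / "clr_matrix.csv", clr_mat.reset_index(names="sample"),
                {"config_hash": cfg.config_hash})

    dep = _depth_ecfs(outdir)
    layer_ecf = dep.assign(layer=dep["depth_m"].map(php.assign_layer)) \
                   .groupby("layer")["ecf"].mean()
    clr_layer = clr_mat.groupby(layers.to_numpy()).mean()
    common = [l for l in clr_layer.index if l in layer_ecf.index]
    fits = {}
    if len(common) >= 4:
        for asv in clr_layer.columns[:20]:  # top ASV columns suffice for the report
            fit = cc.fit_clr_vs_cf(clr_layer.loc[common, asv], layer_ecf[common], asv)
            fits[asv] = {"model": fit.model, "r2": fit.r2, "p_value": fit.p_value}
    report = {
        "rarefaction_depth": depth,
        "anosim_r": res.r,
        "anosim_p": res.p_value,
        "n_phylotypes": int(agg.shape[1]),
        "clr_vs_cf": fits,
    }
    with open(outdir / "community_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _stage_predict_cf(cfg: RunConfig, outdir: Path) -> None:
    prof = read_table(outdir / "profiles.csv", PROFILE_SCHEMA)
    dep = _depth_ecfs(outdir)
    prof["section"] = prof["station"].str.extract(r"^([A-Z]+)")
    merged = dep.merge(prof, on=["section", "depth_m"], how="inner",
                       suffixes=("", "_prof"))
    model = fit_cf_model(merged["ecf"], merged["tpot"], merged["peak_m"],
                         merged["peak_t"])
    model.to_json(outdir / "cf_model.json")
    logger.info("predict_cf: R2=%.3f n=%d", model.r2, model.n)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "estimate_cf": _stage_estimate_cf,
    "php_model": _stage_php_model,
    "correlate": _stage_correlate,
    "community": _stage_community,
    "predict_cf": _stage_predict_cf,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages in order; returns a small run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
    ))
    root = logging.getLogger("leucarb")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report = {"config_hash": config.config_hash, "stages_run": []}
    try:
        logger.info("run start: hash=%s seed=%d", config.config_hash, config.seed)
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            try:
                _STAGE_FUNCS[stage](config, outdir)
            except UserInputError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            report["stages_run"].append(stage)
            logger.info("stage %s done", stage)
    finally:
        root.removeHandler(handler)
        handler.close()
    return report
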