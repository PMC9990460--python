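"""End-to-end orchestration: simulate -> quantify -> QC -> hits -> integrate.

The pipeline is a pure function of (inputs, config, seed): reruns write
byte-identical outputs, and a manifest records digests, row counts per
stage and the QC summary for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ASSAYS, GeneSetCollection, ScreenDesign, validate_well_table
from .enrichment import enrichment_ora, hit_sets_from_stats, phenotype_overlap
from .errors import ConfigError
from .hits import Thresholds, dual_flashlight_table, score_genes
from .qc import QCReport, interassay_cv, replicate_correlation, run_plate_qc
from .quantify import (
    QuantificationWarning,
    fit_nitrite_standard_curve,
    nitrite_concentration,
    percent_cytotoxicity,
)
from .simulate import SimulationConfig, simulate_screen

logger = logging.getLogger(__name__)


@dataclass
class QuantifyParams:
    """Constants needed to turn raw readouts into phenotype values."""

    griess_standards: list[tuple[float, float]]
    ldh_max: float
    phago_background: float = 0.0

    @classmethod
    def from_simulation(cls, cfg: SimulationConfig) -> "QuantifyParams":
        return cls(
            griess_standards=cfg.griess_standards(),
            ldh_max=cfg.ldh_max,
            phago_background=cfg.phago_background,
        )


def quantify_wells(wells: pd.DataFrame, params: QuantifyParams) -> pd.DataFrame:
    """Convert a raw well table into a per-well phenotype value table.

    NO: Griess OD inverted through the fitted standard curve (uM nitrite).
    LDH: percent cytotoxicity against the lysis-control maximum.
    Wound: per-well migration velocity from the width time series (um/h).
    Phagocytosis: fold over the same-plate nontargeting-control mean.
    """
    wells = validate_well_table(wells)
    keys = ["plate_id", "well", "role", "gene_id", "condition", "screen_repeat", "assay"]
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QuantificationWarning)
        for assay, sub in wells.groupby("assay"):
            if assay == "no":
                curve = fit_nitrite_standard_curve(params.griess_standards)
                out = sub[keys].copy()
                out["value"] = nitrite_concentration(sub["readout"].to_numpy(), curve)
            elif assay == "ldh":
                out = sub[keys].copy()
                out["value"] = percent_cytotoxicity(sub["readout"].to_numpy(), params.ldh_max)
            elif assay == "phago":
                out = sub[keys].copy()
                neg_mean = (
                    sub[sub["role"] == "neg_control_siRNA"]
                    .groupby("plate_id")["readout"]
                    .mean()
                )
                if ((neg_mean - params.phago_background) <= 0).any():
                    raise ValueError("phagocytosis control mean at or below background")
                out["value"] = (sub["readout"].to_numpy() - params.phago_background) / (
                    sub["plate_id"].map(neg_mean).to_numpy() - params.phago_background
                )
            else:  # wound: velocity from the first/last width of each well's series
                sub = sub.sort_values(["plate_id", "well", "timepoint_h"], kind="mergesort")
                g = sub.groupby(["plate_id", "well"], sort=False)
                first = g.first()
                last = g.last()
                vel = (first["readout"] - last["readout"]) / (
                    2.0 * (last["timepoint_h"] - first["timepoint_h"])
                )
                out = first[
                    ["role", "gene_id", "condition", "screen_repeat", "assay"]
                ].reset_index()
                out["value"] = vel.to_numpy()
                out = out[keys + ["value"]]
            frames.append(out)
    values = pd.concat(frames, ignore_index=True)
    logger.info("quantified %d wells across %d assays", len(values), values["assay"].nunique())
    return values


def per_repeat_gene_fc(values: pd.DataFrame, condition: str = "LPS") -> dict[str, dict[int, pd.Series]]:
    """Per-assay, per-screen-repeat series of per-gene mean log2 fold changes."""
    out: dict[str, dict[int, pd.Series]] = {}
    sub = values[values["condition"] == condition]
    for (assay, repeat), grp in sub.groupby(["assay", "screen_repeat"]):
        neg_mean = (
            grp[grp["role"] == "neg_control_siRNA"].groupby("plate_id")["value"].mean()
        )
        lib = grp[grp["role"] == "library"].copy()
        lib["log2_ratio"] = np.log2(
            lib["value"].to_numpy() / lib["plate_id"].map(neg_mean).to_numpy()
        )
        out.setdefault(assay, {})[int(repeat)] = lib.groupby("gene_id")["log2_ratio"].mean()
    return out


def run_qc(
    values: pd.DataFrame,
    plate_ssmd_threshold: float = 1.0,
    replicate_r_threshold: float = 0.8,
    cv_threshold: float = 20.0,
) -> tuple[QCReport, pd.DataFrame]:
    """All three QC layers; returns the report and the plate-filtered values."""
    report, kept = run_plate_qc(values, threshold=plate_ssmd_threshold)
    report.thresholds["replicate_r"] = replicate_r_threshold
    report.thresholds["interassay_cv"] = cv_threshold

    fc = per_repeat_gene_fc(kept)
    for assay, by_rep in fc.items():
        reps = sorted(by_rep)
        if len(reps) >= 2:
            try:
                r, ok = replicate_correlation(
                    by_rep[reps[0]], by_rep[reps[1]], replicate_r_threshold
                )
                report.replicate_r[assay] = r
                report.replicate_pass[assay] = ok
            except ValueError:
                pass

    # CV across screen repeats of the per-repeat mean library phenotype
    # (controls are plate-normalised for some assays, which would degenerate to 0)
    lps = kept[(kept["condition"] == "LPS") & (kept["role"] == "library")]
    for assay, grp in lps.groupby("assay"):
        per_rep = grp.groupby("screen_repeat")["value"].mean()
        if len(per_rep) >= 2:
            cv, ok = interassay_cv(per_rep.to_numpy(), cv_threshold)
            report.interassay_cv[assay] = cv
            report.cv_pass[assay] = ok
    return report, kept


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    """Load and minimally validate a pipeline YAML config."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    for section in ("thresholds",):
        if section not in cfg:
            raise ConfigError(f"config missing required section {section!r}")
    return cfg


def _build_objects(cfg: Mapping, seed: int | None) -> tuple[SimulationConfig, Thresholds, dict]:
    try:
        design = ScreenDesign(**cfg.get("design", {}))
        sim_kwargs = dict(cfg.get("simulation", {}))
        if seed is not None:
            sim_kwargs["seed"] = seed
        if "effect_range" in sim_kwargs:
            sim_kwargs["effect_range"] = tuple(sim_kwargs["effect_range"])
        if "assays" in sim_kwargs:
            sim_kwargs["assays"] = tuple(sim_kwargs["assays"])
        sim = SimulationConfig(design=design, **sim_kwargs)
        th = Thresholds(**cfg.get("thresholds") or {})
        qc_cfg = {
            "plate_ssmd_threshold": 1.0,
            "replicate_r_threshold": 0.8,
            "cv_threshold": 20.0,
            **cfg.get("qc", {}),
        }
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return sim, th, qc_cfg


def run_pipeline(
    config: Mapping | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    wells: pd.DataFrame | None = None,
    gene_sets: GeneSetCollection | None = None,
    sep: str = "\t",
) -> dict:
    """Run the full screen analysis and write all outputs under *out_dir*.

    When *wells* is None a synthetic screen is generated from the config's
    design/simulation sections; otherwise the provided well table is
    analysed.  Returns the run manifest (also written as manifest.json).
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    sim_cfg, th, qc_cfg = _build_objects(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"

    counts = {}
    truth = None
    if wells is None:
        wells, truth = simulate_screen(sim_cfg)
    wells = validate_well_table(wells)
    counts["wells_in"] = len(wells)

    values = quantify_wells(wells, QuantifyParams.from_simulation(sim_cfg))
    counts["values"] = len(values)

    report, kept = run_qc(
        values,
        plate_ssmd_threshold=qc_cfg["plate_ssmd_threshold"],
        replicate_r_threshold=qc_cfg["replicate_r_threshold"],
        cv_threshold=qc_cfg["cv_threshold"],
    )
    counts["values_after_qc"] = len(kept)
    counts["plates_failed_qc"] = len(report.failing_plates)
    if len(kept) == 0:
        logger.warning("all plates failed QC; hit tables will be empty")

    stats = score_genes(kept, th)
    counts["gene_assay_stats"] = len(stats)

    outputs: list[Path] = []

    def write_df(df: pd.DataFrame, name: str) -> None:
        p = out / f"{name}.{ext}"
        with open(p, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# fc_log2={th.fc_log2} ssmd={th.ssmd} lps_ratio={th.lps_ratio}\n")
            df.to_csv(fh, sep=sep, index=False)
        outputs.append(p)

    for assay in sorted(stats["assay"].unique()) if len(stats) else []:
        sub = stats[stats["assay"] == assay].sort_values("gene_id", kind="mergesort")
        write_df(sub, f"hits_{assay}")
        write_df(dual_flashlight_table(sub), f"dual_flashlight_{assay}")

    qc_tsv = out / f"qc_report.{ext}"
    report.write_tsv(qc_tsv)
    outputs.append(qc_tsv)
    qc_json = out / "qc_report.json"
    report.to_json(qc_json)
    outputs.append(qc_json)

    if len(stats):
        hit_sets = hit_sets_from_stats(stats)
        if hit_sets:
            universe = sorted(stats["gene_id"].unique())
            overlap = phenotype_overlap(hit_sets, universe)
            p = out / "phenotype_overlap.json"
            p.write_text(json.dumps(overlap, indent=2, sort_keys=True), encoding="utf-8")
            outputs.append(p)
            if gene_sets is not None:
                all_hits = set().union(*hit_sets.values())
                if all_hits:
                    ora = enrichment_ora(all_hits, gene_sets)
                    write_df(ora, "enrichment")

    if truth is not None:
        p = out / f"truth.{ext}"
        truth.to_csv(p, sep=sep, index=False)
        outputs.append(p)

    cfg_digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "seed": sim_cfg.seed,
        "config_digest": cfg_digest,
        "row_counts": counts,
        "qc_summary": {
            "failing_plates": report.failing_plates,
            "replicate_r": report.replicate_r,
            "interassay_cv": report.interassay_cv,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
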