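"""Synthetic multiplexed screen generator with ground truth.

Emulates the statistical structure the analysis assumes: a gene-knockdown
well's phenotype is the assay/condition baseline scaled by
``2^(true effect + plate effect + edge effect + well noise)`` — spiked
log2 effects for a configurable fraction of genes, multiplicative
log-normal well noise, plate-level factors shared by all wells of a plate
(including its controls, so in-plate normalization cancels them), and an
optional additive edge-well bias.  Phenotype values are then pushed
through the forward observation model of each assay to produce raw
plate-reader readouts: Griess optical density, LDH absorbance, a wound
width time series sampled every 2 h for 48 h, and phagocytosis
fluorescence over background.

Randomness comes from one master seed expanded into per-plate substreams
(``SeedSequence(seed, spawn_key=(1, plate_index))``), so enlarging the
design appends plates without reshuffling existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    ASSAYS,
    WELL_COLUMNS,
    ScreenDesign,
    build_screen_design,
)
from .errors import ConfigError

DEFAULT_BASELINES: dict[str, dict[str, float]] = {
    # assay -> condition -> phenotype-scale baseline (native units)
    "no": {"LPS": 20.0, "PBS": 2.0},  # nitrite uM: LPS strongly induces NO
    "ldh": {"LPS": 0.9, "PBS": 0.3},  # LDH absorbance AU
    "wound": {"LPS": 2.5, "PBS": 5.0},  # migration velocity um/h (LPS-primed glia move slower)
    "phago": {"LPS": 1000.0, "PBS": 500.0},  # fluorescence AU over background
}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic screen.

    Defaults mirror the screened library (623 genes, 7 master plates,
    triplicate wells, two conditions, duplicate screens) with roughly 10%
    spiked genes per assay, |log2 effect| in 0.5-2.0, well noise SD 0.25
    log2 units and plate factor SD 0.1 log2 units.
    """

    design: ScreenDesign = field(default_factory=ScreenDesign)
    seed: int = 0
    assays: tuple[str, ...] = ASSAYS
    hit_fraction: float | Mapping[str, float] = 0.1
    effect_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.25
    plate_sd: float = 0.1
    edge_effect: float = 0.0
    lps_dependent_fraction: float = 0.3
    baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(v) for a, v in DEFAULT_BASELINES.items()}
    )
    # forward observation model constants
    griess_slope: float = 0.02  # OD per uM
    griess_intercept: float = 0.05  # OD of the blank
    ldh_max: float = 6.0  # lysis-control (100% kill) absorbance AU
    wound_initial_width: float = 2000.0  # um
    wound_duration_h: float = 48.0
    wound_interval_h: float = 2.0
    phago_background: float = 100.0  # AU

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.plate_sd < 0:
            raise ConfigError("noise SDs must be nonnegative")
        lo, hi = self.effect_range
        if not (0 < lo <= hi):
            raise ConfigError("effect magnitude range must be positive")
        for a in self.assays:
            if a not in ASSAYS:
                raise ConfigError(f"unknown assay {a!r}")
        for frac in self._hit_fractions().values():
            if not 0 <= frac <= 1:
                raise ConfigError("hit_fraction must lie in [0, 1]")
        if not 0 <= self.lps_dependent_fraction <= 1:
            raise ConfigError("lps_dependent_fraction must lie in [0, 1]")

    def _hit_fractions(self) -> dict[str, float]:
        if isinstance(self.hit_fraction, Mapping):
            return {a: float(self.hit_fraction.get(a, 0.0)) for a in self.assays}
        return {a: float(self.hit_fraction) for a in self.assays}

    def griess_standards(self) -> list[tuple[float, float]]:
        """Sodium-nitrite standards (uM, OD) generated by the forward curve."""
        concs = [0.0, 6.25, 12.5, 25.0, 50.0, 100.0]
        return [(c, self.griess_slope * c + self.griess_intercept) for c in concs]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["design"] = asdict(self.design)
        d["design"]["control_wells"] = dict(self.design.control_wells)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _is_edge(well: str) -> bool:
    return well[0] in "AH" or well[1:] in ("01", "12")


def simulate_truth(config: SimulationConfig, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Draw the per-gene per-assay true log2 effects and LPS-dependency flags."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n = len(gene_ids)
    lps_dep = rng.random(n) < config.lps_dependent_fraction
    lo, hi = config.effect_range
    fracs = config._hit_fractions()
    frames = []
    for assay in config.assays:
        is_hit = rng.random(n) < fracs[assay]
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        mag = rng.uniform(lo, hi, n)
        effect = np.where(is_hit, sign * mag, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "assay": assay,
                    "true_log2_effect": effect,
                    "lps_dependent": lps_dep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_screen(
    config: SimulationConfig, gene_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic screen: (well table, ground truth).

    The well table is the standard long format (one row per well per assay,
    one row per timepoint for the wound series).  Identical config and seed
    give bit-identical output.
    """
    design = config.design
    if gene_ids is None:
        gene_ids = design.default_gene_ids()
    expanded = build_screen_design(design, gene_ids)
    truth = simulate_truth(config, list(gene_ids))

    effect_lookup = {
        (r.gene_id, r.assay): r.true_log2_effect for r in truth.itertuples()
    }
    lps_dep = dict(zip(truth["gene_id"], truth["lps_dependent"]))

    plate_ids = list(dict.fromkeys(expanded["plate_id"]))
    out_frames: list[pd.DataFrame] = []
    n_tp = int(round(config.wound_duration_h / config.wound_interval_h)) + 1
    timepoints = np.arange(n_tp) * config.wound_interval_h

    for i, plate_id in enumerate(plate_ids):
        plate = expanded[expanded["plate_id"] == plate_id]
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        wells = plate["well"].to_numpy()
        roles = plate["role"].to_numpy()
        genes = plate["gene_id"].to_numpy()
        plate_condition = plate.loc[plate["role"] != "untreated_control", "condition"]
        plate_condition = plate_condition.iloc[0] if len(plate_condition) else "PBS"
        cond = np.where(roles == "untreated_control", "PBS", plate_condition)
        repeat = int(plate["screen_repeat"].iloc[0])
        edge = np.fromiter((_is_edge(w) for w in wells), dtype=bool, count=len(wells))

        for assay in config.assays:
            plate_eff = rng.normal(0.0, config.plate_sd) if config.plate_sd > 0 else 0.0
            noise = (
                rng.normal(0.0, config.noise_sd, len(wells))
                if config.noise_sd > 0
                else np.zeros(len(wells))
            )
            eff = np.zeros(len(wells))
            for j, (role, gene, c) in enumerate(zip(roles, genes, cond)):
                if role == "library":
                    e = effect_lookup[(gene, assay)]
                    if c == "PBS" and lps_dep[gene]:
                        e = 0.0
                    eff[j] = e
            base = np.asarray([config.baselines[assay][c] for c in cond])
            log2v = (
                np.log2(base)
                + eff
                + plate_eff
                + np.where(edge, config.edge_effect, 0.0)
                + noise
            )
            value = np.exp2(log2v)

            common = dict(
                plate_id=plate_id,
                well=wells,
                role=roles,
                gene_id=genes,
                condition=cond,
                screen_repeat=repeat,
                assay=assay,
            )
            if assay == "no":
                readout = config.griess_slope * value + config.griess_intercept
                out_frames.append(
                    pd.DataFrame({**common, "readout": readout, "timepoint_h": np.nan})
                )
            elif assay == "ldh":
                out_frames.append(
                    pd.DataFrame({**common, "readout": value, "timepoint_h": np.nan})
                )
            elif assay == "phago":
                out_frames.append(
                    pd.DataFrame(
                        {**common, "readout": config.phago_background + value,
                         "timepoint_h": np.nan}
                    )
                )
            else:  # wound: linear closure at 2 * v per hour (both edges advance)
                widths = np.maximum(
                    config.wound_initial_width - 2.0 * value[:, None] * timepoints[None, :],
                    0.0,
                )
                df = pd.DataFrame(
                    {
                        **{k: np.repeat(v, n_tp) if isinstance(v, np.ndarray) else v
                           for k, v in common.items()},
                        "readout": widths.ravel(),
                        "timepoint_h": np.tile(timepoints, len(wells)),
                    }
                )
                out_frames.append(df)

    wells_df = pd.concat(out_frames, ignore_index=True)[WELL_COLUMNS]
    return wells_df, truth


def evaluate_recovery(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    fc_threshold: float = 0.5,
    condition: str = "LPS",
) -> dict:
    """Score hit calls against simulation ground truth.

    ``calls`` is a stats table with gene_id, assay, condition and category.
    Sensitivity is measured over genes with |true effect| >= fc_threshold,
    the false-positive rate over true-null genes, and direction
    correctness over the called true-effect genes.  Returns per-assay and
    pooled summaries.
    """
    sub = calls[calls["condition"] == condition]
    per_assay = {}
    tp = fp = n_eff = n_null = n_dir = n_called_eff = 0
    for assay, t in truth.groupby("assay"):
        c = sub[sub["assay"] == assay]
        merged = t.merge(c[["gene_id", "category"]], on="gene_id", how="left", validate="1:1")
        if merged["category"].isna().any() or len(c) != len(t):
            missing = merged.loc[merged["category"].isna(), "gene_id"].tolist()[:5]
            raise ValueError(f"calls and truth cover different genes (assay={assay}, e.g. {missing})")
        effect = merged["true_log2_effect"].to_numpy()
        called = (merged["category"] != "none").to_numpy()
        up = (merged["category"] == "increased").to_numpy()
        is_eff = np.abs(effect) >= fc_threshold
        is_null = effect == 0.0
        a_tp = int((is_eff & called).sum())
        a_fp = int((is_null & called).sum())
        dir_ok = int((is_eff & called & (up == (effect > 0))).sum())
        per_assay[assay] = {
            "sensitivity": a_tp / is_eff.sum() if is_eff.sum() else float("nan"),
            "fpr": a_fp / is_null.sum() if is_null.sum() else float("nan"),
            "direction_accuracy": dir_ok / a_tp if a_tp else float("nan"),
            "n_true_effects": int(is_eff.sum()),
            "n_nulls": int(is_null.sum()),
        }
        tp += a_tp
        fp += a_fp
        n_eff += int(is_eff.sum())
        n_null += int(is_null.sum())
        n_dir += dir_ok
        n_called_eff += a_tp
    return {
        "sensitivity": tp / n_eff if n_eff else float("nan"),
        "fpr": fp / n_null if n_null else float("nan"),
        "direction_accuracy": n_dir / n_called_eff if n_called_eff else float("nan"),
        "per_assay": per_assay,
    }
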