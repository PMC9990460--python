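"""Control-based normalization and the screen's three quality-control layers.

1. Per-plate control SSMD: on each plate a positive/negative control
   contrast must clear a minimum |SSMD| (default 1.0, the conventional
   boundary of a "moderate" standardized effect) or the plate's wells are
   excluded from hit selection.
2. Replicate-screen reproducibility: Pearson correlation of per-gene mean
   log2 fold changes between the two full screen repeats (pass at r >= 0.8).
3. Interassay coefficient of variation across repeated runs (pass below 20%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hits import compute_ssmd


def compute_log2_fc(treated_values, control_values) -> float:
    """log2 of the ratio of group means: log2(mean(treated) / mean(control)).

    Controls are the same-plate nontargeting-siRNA wells measured under the
    same condition; their mean must be positive.
    """
    t = np.asarray(treated_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("empty input to compute_log2_fc")
    cm = c.mean()
    if cm <= 0:
        raise ValueError("control mean must be positive")
    tm = t.mean()
    if tm <= 0:
        raise ValueError("treated mean must be positive")
    return float(np.log2(tm / cm))


def plate_qc_ssmd(positive_wells, negative_wells, threshold: float = 1.0) -> tuple[float, bool]:
    """Per-plate QC: SSMD of the positive-vs-negative control contrast.

    The plate passes when |SSMD| >= threshold, i.e. the plate resolved at
    least a moderate standardized separation between its controls.
    """
    ssmd = compute_ssmd(positive_wells, negative_wells)
    return ssmd, bool(abs(ssmd) >= threshold)


def replicate_correlation(
    screen1: pd.Series | dict, screen2: pd.Series | dict, threshold: float = 0.8
) -> tuple[float, bool]:
    """Pearson correlation of per-gene values between two replicate screens.

    The series are matched on their gene index; at least three shared genes
    and nonconstant values in both screens are required.  Passes at
    r >= threshold (default 0.8, a strong correlation).
    """
    s1 = pd.Series(screen1, dtype=float)
    s2 = pd.Series(screen2, dtype=float)
    common = s1.index.intersection(s2.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes shared between replicate screens")
    a = s1.loc[common].to_numpy()
    b = s2.loc[common].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series; correlation undefined")
    if np.array_equal(a, b):
        r = 1.0  # duplicated screens correlate exactly; skip float round-off
    else:
        r = float(sps.pearsonr(a, b).statistic)
    return r, bool(r >= threshold)


def interassay_cv(repeat_values, threshold: float = 20.0) -> tuple[float, bool]:
    """Interassay coefficient of variation: 100 * sample SD / mean (percent).

    Passes when the CV is strictly below the threshold (default 20%).
    """
    v = np.asarray(repeat_values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 repeat values for a CV")
    m = v.mean()
    if m == 0:
        raise ValueError("zero mean; CV undefined")
    cv = float(100.0 * v.std(ddof=1) / abs(m))
    return cv, bool(cv < threshold)


@dataclass
class QCReport:
    """Machine-readable QC summary across plates, replicates and assays."""

    plate_ssmd: dict[str, float] = field(default_factory=dict)
    plate_pass: dict[str, bool] = field(default_factory=dict)
    replicate_r: dict[str, float] = field(default_factory=dict)
    replicate_pass: dict[str, bool] = field(default_factory=dict)
    interassay_cv: dict[str, float] = field(default_factory=dict)
    cv_pass: dict[str, bool] = field(default_factory=dict)
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"plate_ssmd": 1.0, "replicate_r": 0.8, "interassay_cv": 20.0}
    )

    @property
    def failing_plates(self) -> list[str]:
        return sorted(p for p, ok in self.plate_pass.items() if not ok)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def plate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": sorted(self.plate_ssmd),
                "control_ssmd": [self.plate_ssmd[p] for p in sorted(self.plate_ssmd)],
                "plate_pass": [self.plate_pass[p] for p in sorted(self.plate_ssmd)],
            }
        )

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# plate_ssmd_threshold={self.thresholds['plate_ssmd']}\n")
            fh.write(f"# replicate_r_threshold={self.thresholds['replicate_r']}\n")
            fh.write(f"# interassay_cv_threshold={self.thresholds['interassay_cv']}\n")
            self.plate_table().to_csv(fh, sep="\t", index=False)


def run_plate_qc(
    values: pd.DataFrame,
    positive_role: str = "untreated_control",
    negative_role: str = "neg_control_siRNA",
    threshold: float = 1.0,
    qc_assay: str | None = None,
) -> tuple[QCReport, pd.DataFrame]:
    """Apply the per-plate control-SSMD gate and drop failing plates.

    The positive control is the LPS-untreated wells carried on every plate:
    on LPS-stimulated plates they should separate sharply from the
    nontargeting (LPS-stimulated) control wells, so a plate that fails to
    resolve them is discarded.  Plates of the untreated (PBS) condition
    carry no built-in separation contrast, so they are gated by the paired
    LPS plate of the same position when present, and pass by default
    otherwise.

    Returns the QC report and the filtered values table (all wells of
    failing plates removed — they contribute nothing downstream).
    """
    report = QCReport()
    report.thresholds["plate_ssmd"] = threshold

    if qc_assay is None:
        # gate on one assay so the control contrast is in homogeneous units;
        # the NO readout carries the sharpest LPS-vs-untreated separation
        present = values["assay"].unique().tolist()
        qc_assay = "no" if "no" in present else present[0]

    # plate condition from stimulated wells (untreated_control wells are PBS by role)
    stim = values[values["role"] != "untreated_control"]
    plate_cond = stim.groupby("plate_id")["condition"].first()
    for plate_id, sub in values.groupby("plate_id"):
        sub = sub[sub["assay"] == qc_assay]
        if plate_cond.get(plate_id) != "LPS":
            continue
        pos = sub.loc[sub["role"] == positive_role, "value"].to_numpy()
        neg = sub.loc[sub["role"] == negative_role, "value"].to_numpy()
        if pos.size < 2 or neg.size < 2:
            raise ValueError(f"plate {plate_id}: need >= 2 wells per control group")
        ssmd, ok = plate_qc_ssmd(pos, neg, threshold)
        report.plate_ssmd[plate_id] = ssmd
        report.plate_pass[plate_id] = ok

    # PBS plates inherit the verdict of the positionally paired LPS plate.
    for plate_id in plate_cond.index:
        if plate_cond[plate_id] == "LPS":
            continue
        partner = plate_id.replace("_PBS_", "_LPS_")
        report.plate_pass[plate_id] = report.plate_pass.get(partner, True)

    keep = values["plate_id"].map(lambda p: report.plate_pass.get(p, True))
    return report, values[keep].reset_index(drop=True)
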