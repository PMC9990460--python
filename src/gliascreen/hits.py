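"""Hit selection: SSMD, average log2 fold change, dual-flashlight calls.

The screen's core statistic is the strictly standardized mean difference

    SSMD = (mean(sample) - mean(control)) / sqrt(var(sample) + var(control))

computed with unbiased (n-1) group variances.  A gene is a hit in an assay
when its average log2 fold change and its SSMD jointly clear symmetric
cutoffs (|log2 FC| >= 0.5 and |SSMD| >= 1.65 by default), the joint rule
visualised by a dual-flashlight plot.  Hits are further classified as
LPS-dependent when the fold change under LPS exceeds the fold change in
the untreated condition by more than a ratio threshold, and effect sizes
are summarised with the bias-corrected Hedges' g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

CATEGORIES = ("increased", "decreased", "none")


class HitSelectionWarning(UserWarning):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Joint hit-calling cutoffs, applied symmetrically around zero.

    fc_log2 and ssmd define the dual-flashlight acceptance regions;
    lps_ratio the LPS-dependence fold-change ratio; g_* the Hedges' g
    magnitude labels (large/moderate/small).
    """

    fc_log2: float = 0.5
    ssmd: float = 1.65
    lps_ratio: float = 1.5
    g_large: float = 0.8
    g_moderate: float = 0.5
    g_small: float = 0.2

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all thresholds must be positive")


@dataclass
class GeneAssayStat:
    """Aggregated per-gene per-assay statistics feeding the dual-flashlight plot."""

    gene_id: str
    assay: str
    condition: str
    mean_log2fc: float
    ssmd: float
    n_wells: int
    category: str
    lps_dependent: bool | None = None
    hedges_g: float | None = None


def _check_groups(sample, control) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(sample, dtype=float)
    c = np.asarray(control, dtype=float)
    if s.size < 2 or c.size < 2:
        raise ValueError("need >= 2 values in each group")
    if not (np.isfinite(s).all() and np.isfinite(c).all()):
        raise ValueError("non-finite values in input")
    return s, c


def compute_ssmd(sample, control, umvue: bool = False) -> float:
    """Strictly standardized mean difference between two well groups.

    Method-of-moments estimator: mean difference over the square root of the
    summed unbiased group variances.  When both variances are zero the
    statistic degenerates: equal means give 0, unequal means give a signed
    infinity sentinel (flagged with a warning) so that a perfectly separated
    noiseless contrast still counts as an extreme effect.

    ``umvue=True`` applies the uniformly-minimum-variance-unbiased variant,
    which rescales by Gamma(K/2)/Gamma((K-1)/2) * sqrt(2/K) with
    K = n1 + n2 - 2 degrees of freedom.
    """
    s, c = _check_groups(sample, control)
    diff = s.mean() - c.mean()
    var_sum = s.var(ddof=1) + c.var(ddof=1)
    if var_sum == 0:
        if diff == 0:
            return 0.0
        warnings.warn(
            "zero variance with unequal means; returning signed infinity",
            HitSelectionWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, diff)
    if umvue:
        # unbiased under equal group variances: E[gamma-ratio / sqrt(SS)] = 1/(sqrt(2)*sigma)
        k = s.size + c.size - 2
        ss = (s.size - 1) * s.var(ddof=1) + (c.size - 1) * c.var(ddof=1)
        corr = math.exp(gammaln(k / 2.0) - gammaln((k - 1) / 2.0))
        return float(corr * diff / math.sqrt(ss))
    return float(diff / math.sqrt(var_sum))


def call_hits(mean_log2fc: float, ssmd: float, th: Thresholds = Thresholds()) -> str:
    """Dual-flashlight category for one gene: increased / decreased / none.

    'increased' requires mean log2 FC >= +fc_log2 AND SSMD >= +ssmd;
    'decreased' the mirrored rule; boundaries are inclusive.  Infinite SSMD
    (the zero-variance sentinel) is a legitimate extreme; NaN is rejected.
    """
    if math.isnan(mean_log2fc) or math.isnan(ssmd):
        raise ValueError("NaN input to call_hits")
    if mean_log2fc >= th.fc_log2 and ssmd >= th.ssmd:
        return "increased"
    if mean_log2fc <= -th.fc_log2 and ssmd <= -th.ssmd:
        return "decreased"
    return "none"


def classify_lps_dependence(
    fc_lps: float, fc_untreated: float, th: Thresholds = Thresholds()
) -> bool:
    """Whether a hit's phenotype shift depends on LPS stimulation.

    Both inputs are linear-scale fold changes.  For phenotype-increasing
    hits (fc_lps >= 1) the criterion is fc_lps / fc_untreated > lps_ratio.
    For phenotype-decreasing hits the knockdown pushes both fold changes
    below 1, so the same ratio is taken on the magnitudes, i.e.
    fc_untreated / fc_lps > lps_ratio: the shift away from 1 must be
    lps_ratio-fold stronger under LPS either way.
    """
    if fc_lps <= 0 or fc_untreated <= 0:
        raise ValueError("linear fold changes must be positive")
    if fc_lps >= 1.0:
        ratio = fc_lps / fc_untreated
    else:
        ratio = fc_untreated / fc_lps
    return ratio > th.lps_ratio


def hedges_g(
    sample, control, th: Thresholds = Thresholds()
) -> tuple[float, str]:
    """Bias-corrected standardized mean difference and its magnitude label.

    g = J * (mean(sample) - mean(control)) / s_pooled with the df-weighted
    pooled SD and the small-sample correction J = 1 - 3 / (4*df - 1),
    df = n1 + n2 - 2.  Labels follow the conventional |g| bands:
    >= 0.8 large, >= 0.5 moderate, >= 0.2 small, else negligible.
    """
    s, c = _check_groups(sample, control)
    df = s.size + c.size - 2
    pooled_var = ((s.size - 1) * s.var(ddof=1) + (c.size - 1) * c.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = float(j * (s.mean() - c.mean()) / math.sqrt(pooled_var))
    mag = abs(g)
    if mag >= th.g_large:
        label = "large"
    elif mag >= th.g_moderate:
        label = "moderate"
    elif mag >= th.g_small:
        label = "small"
    else:
        label = "negligible"
    return g, label


def validation_concordance(
    screen_calls: Mapping[str, str], validation_calls: Mapping[str, str]
) -> tuple[float, float, int]:
    """Concordance and false-positive rate of screen hits against a validation assay.

    Over genes called non-'none' in the screen and present in the validation
    table: FPR = 100 * disagreements / compared, concordance = 100 - FPR.
    Returns (concordance %, FPR %, n compared).
    """
    compared = [
        g
        for g, cat in screen_calls.items()
        if cat != "none" and g in validation_calls
    ]
    if not compared:
        raise ValueError("no screen hits present in the validation table")
    disagree = sum(1 for g in compared if validation_calls[g] != screen_calls[g])
    fpr = 100.0 * disagree / len(compared)
    return 100.0 - fpr, fpr, len(compared)


def hit_percentages(
    category_counts: Mapping[str, int], library_size: int
) -> dict[str, float]:
    """Hit counts as percentages of the library, to one decimal (round-half-even)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    out = {}
    for name, count in category_counts.items():
        if count < 0 or count > library_size:
            raise ValueError(f"count {count} for {name!r} outside [0, {library_size}]")
        pct = Decimal(100 * count) / Decimal(library_size)
        out[name] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))
    return out


def score_genes(
    values: pd.DataFrame,
    th: Thresholds = Thresholds(),
    umvue: bool = False,
    with_hedges_g: bool = True,
) -> pd.DataFrame:
    """Aggregate per-well phenotype values into per-gene per-assay statistics.

    Parameters
    ----------
    values
        Well-level phenotype table with columns plate_id, well, role,
        gene_id, condition, screen_repeat, assay, value (the output of the
        quantification stage).  Wells from QC-failing plates must already
        have been removed.
    th
        Hit-calling thresholds.

    Every well is first normalised to the mean of the nontargeting-siRNA
    (neg_control_siRNA) wells of its own plate, which cancels plate-level
    multiplicative effects.  Per gene, assay and condition the replicate
    wells of both screen repeats are pooled: the average of the per-well
    log2 ratios is the reported fold change, and the SSMD contrasts the
    gene's wells against the pooled same-plate control wells.  LPS
    dependence is evaluated on hits by comparing linear fold changes
    between conditions.

    Returns a dual-flashlight table: one row per (gene, assay, condition)
    with mean_log2fc, ssmd, n_wells, category, hedges_g, lps_dependent.
    """
    required = {"plate_id", "role", "gene_id", "condition", "screen_repeat", "assay", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"values table missing columns: {sorted(missing)}")

    rows: list[dict] = []
    for (assay, condition), sub in values.groupby(["assay", "condition"], sort=True):
        neg = sub[sub["role"] == "neg_control_siRNA"]
        if neg.empty:
            raise ValueError(f"no neg_control_siRNA wells for assay={assay}, condition={condition}")
        ctrl_mean = neg.groupby("plate_id")["value"].mean()
        if (ctrl_mean <= 0).any():
            bad = ctrl_mean[ctrl_mean <= 0].index.tolist()
            raise ValueError(f"non-positive control mean on plates {bad}")

        norm = sub["value"].to_numpy() / sub["plate_id"].map(ctrl_mean).to_numpy()
        with np.errstate(divide="ignore"):
            log2r = np.log2(norm)
        sub = sub.assign(log2_ratio=log2r)

        lib = sub[sub["role"] == "library"]
        ctrl_by_plate = sub[sub["role"] == "neg_control_siRNA"].groupby("plate_id")[
            "log2_ratio"
        ]
        ctrl_ratios = {pid: grp.to_numpy() for pid, grp in ctrl_by_plate}

        for gene, g in lib.groupby("gene_id", sort=True):
            svals = g["log2_ratio"].to_numpy()
            cvals = np.concatenate([ctrl_ratios[p] for p in g["plate_id"].unique()])
            mean_fc = float(svals.mean())
            ssmd = compute_ssmd(svals, cvals, umvue=umvue) if svals.size >= 2 else np.nan
            cat = call_hits(mean_fc, ssmd, th) if not math.isnan(ssmd) else "none"
            hg = None
            if with_hedges_g and svals.size >= 2:
                try:
                    hg, _ = hedges_g(svals, cvals, th)
                except ValueError:
                    hg = None
            rows.append(
                dict(
                    gene_id=gene,
                    assay=assay,
                    condition=condition,
                    mean_log2fc=mean_fc,
                    ssmd=ssmd,
                    n_wells=int(svals.size),
                    category=cat,
                    hedges_g=hg,
                )
            )

    stats = pd.DataFrame(rows)
    if stats.empty:
        return stats

    # LPS dependence: compare linear fold changes of LPS hits against the
    # untreated condition, where both conditions were screened.
    stats["lps_dependent"] = pd.NA
    if {"LPS", "PBS"} <= set(stats["condition"].unique()):
        pbs = stats[stats["condition"] == "PBS"].set_index(["gene_id", "assay"])["mean_log2fc"]
        for idx, row in stats[stats["condition"] == "LPS"].iterrows():
            key = (row["gene_id"], row["assay"])
            if row["category"] == "none" or key not in pbs.index:
                continue
            fc_lps = 2.0 ** row["mean_log2fc"]
            fc_unt = 2.0 ** float(pbs.loc[key])
            stats.loc[idx, "lps_dependent"] = classify_lps_dependence(fc_lps, fc_unt, th)
    return stats


def dual_flashlight_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready projection of a stats table: x = mean log2 FC, y = SSMD."""
    cols = ["gene_id", "assay", "condition", "mean_log2fc", "ssmd", "category"]
    return stats[cols].rename(columns={"mean_log2fc": "x_log2fc", "ssmd": "y_ssmd"})
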