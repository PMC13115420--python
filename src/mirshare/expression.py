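"""Efficiency-adjusted qPCR quantification, ELISA normalization and group
statistics.

Relative expression follows the efficiency-adjusted (Pfaffl-type) model

    ratio = E_target^(ΔCt_target) / E_ref^(ΔCt_ref),   ΔCt = Ct_calibrator − Ct_sample

where E is the per-assay amplification efficiency (ideally 2, i.e. perfect
doubling; with both efficiencies at 2 the ratio reduces exactly to
2^(−ΔΔCt)).  The calibrator is the mean Ct of a designated reference group
(plasma: control/discopathy; tissue: peritumoral).  Targets with
Ct above the detectability cutoff (40 cycles) are reported as missing, not
zero, so group means are not biased downward.

Group comparisons use one-way fixed-effects ANOVA computed from the between
and within mean squares, followed by Fisher's LSD pairwise t-tests on the
pooled within-group error term without multiplicity adjustment (the LSD
definition), plus a pooled-variance two-sample t-test for the two-compartment
tissue contrast.  Fold-changes are ratios of group means of relative
expression, rounded half-up for reporting.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CT_UNDETECTABLE, ELISA_RANGE_PG_PER_ML

logger = logging.getLogger("mirshare.expression")


@dataclass(frozen=True)
class CtMeasurement:
    """A raw Ct observation with its amplification efficiency."""

    sample_id: str
    group: str
    analyte: str
    ct: float
    efficiency: float = 2.0
    compartment: str = "plasma"

    @property
    def undetectable(self) -> bool:
        return self.ct > CT_UNDETECTABLE


@dataclass(frozen=True)
class RelativeExpression:
    """Pfaffl-type normalized expression ratio for one sample."""

    sample_id: str
    analyte: str
    ratio: float  # NaN when the target was undetectable
    reference_analyte: str
    calibrator_definition: str


@dataclass
class GroupComparison:
    """One-way ANOVA with LSD pairwise tests and fold-changes of group means."""

    analyte: str
    group_means: dict[str, float]
    F: float
    p_overall: float
    pairwise_p: dict[tuple[str, str], float]
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class ElisaMeasurement:
    """ELISA concentration normalized to total protein (pg analyte / ng protein)."""

    sample_id: str
    compartment: str
    concentration_pg_per_ml: float
    total_protein_ng: float
    normalized_pg_per_ng: float
    in_range: bool


@dataclass(frozen=True)
class FoldChange:
    """Ratio of group means with its half-up-rounded reported value."""

    value: float
    reported: float
    numerator: str
    denominator: str


def _validate_efficiency(e: float) -> None:
    if not (1.0 < e <= 2.2):
        raise ValueError(f"amplification efficiency must lie in (1, 2.2], got {e}")


def relative_expression(
    ct_target: float,
    ct_ref: float,
    E_target: float,
    E_ref: float,
    calibrator_cts: tuple[float, float],
    ct_cutoff: float = CT_UNDETECTABLE,
) -> float:
    """Efficiency-adjusted expression ratio for one sample.

    ``calibrator_cts`` is the (target, reference) calibrator mean Ct pair.
    Returns NaN (missing, not zero) when the target Ct exceeds the
    detectability cutoff.
    """
    _validate_efficiency(E_target)
    _validate_efficiency(E_ref)
    if not (math.isfinite(ct_ref) and math.isfinite(ct_target)):
        raise ValueError("Ct values must be finite")
    if ct_target > ct_cutoff:
        return math.nan
    cal_target, cal_ref = calibrator_cts
    delta_target = cal_target - ct_target
    delta_ref = cal_ref - ct_ref
    return E_target**delta_target / E_ref**delta_ref


def quantify_dataset(
    ct_table: pd.DataFrame,
    reference_analyte: str = "U6",
    calibrator_groups: Mapping[str, str] | None = None,
    exclude_analytes: Sequence[str] = ("cel-miR-39-3p",),
    ct_cutoff: float = CT_UNDETECTABLE,
) -> pd.DataFrame:
    """Per-sample relative expression for every target analyte in a Ct table.

    ``calibrator_groups`` maps compartment -> the group (plasma) or the
    compartment (tissue) whose mean Ct defines the calibrator; defaults to
    control for plasma and peritumoral for tissue.
    """
    calibrator_groups = dict(calibrator_groups or {"plasma": "control", "tissue": "peritumoral"})
    required = {"sample_id", "group", "compartment", "analyte", "ct", "efficiency"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    is_plasma = ct_table["compartment"] == "plasma"
    for scope, table in (("plasma", ct_table[is_plasma]), ("tissue", ct_table[~is_plasma])):
        if table.empty:
            continue
        cal_key = calibrator_groups[scope]
        cal_col = "group" if scope == "plasma" else "compartment"
        ref = table[table["analyte"] == reference_analyte].set_index("sample_id")
        cal_rows = table[table[cal_col] == cal_key]
        if cal_rows.empty:
            raise ValueError(f"calibrator {cal_key!r} absent from the {scope} data")
        cal_means = cal_rows.groupby("analyte")["ct"].mean()
        for analyte, sub in table.groupby("analyte"):
            if analyte == reference_analyte or analyte in exclude_analytes:
                continue
            for row in sub.itertuples(index=False):
                if row.sample_id not in ref.index:
                    continue
                ratio = relative_expression(
                    ct_target=row.ct,
                    ct_ref=float(ref.loc[row.sample_id, "ct"]),
                    E_target=float(row.efficiency),
                    E_ref=float(ref.loc[row.sample_id, "efficiency"]),
                    calibrator_cts=(
                        float(cal_means[analyte]),
                        float(cal_means[reference_analyte]),
                    ),
                    ct_cutoff=ct_cutoff,
                )
                rows.append(
                    (row.sample_id, row.group, row.compartment, analyte, ratio)
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "compartment", "analyte", "ratio"]
    )


def spike_in_qc(
    spike_cts: Mapping[str, float] | pd.Series, max_sd: float = 2.0
) -> pd.DataFrame:
    """Flag samples whose spike-in Ct deviates > ``max_sd`` SDs from the
    cohort mean.  Flagged samples are reported, not dropped.  With fewer
    than 3 samples the QC is skipped (all pass, with a warning)."""
    cts = pd.Series(dict(spike_cts), dtype=float)
    if len(cts) < 3:
        warnings.warn("spike-in QC skipped: fewer than 3 samples", stacklevel=2)
        return pd.DataFrame({"sample_id": cts.index, "ct": cts.values, "qc_pass": True})
    mean, sd = cts.mean(), cts.std(ddof=1)
    deviation = (cts - mean).abs()
    passed = deviation <= max_sd * sd if sd > 0 else pd.Series(True, index=cts.index)
    flagged = (~passed).sum()
    if flagged:
        logger.info("spike_in_qc: %d of %d samples flagged", flagged, len(cts))
    return pd.DataFrame(
        {"sample_id": cts.index, "ct": cts.values, "qc_pass": passed.values}
    )


def anova_lsd(groups: Mapping[str, Sequence[float]], analyte: str = "") -> GroupComparison:
    """One-way fixed-effects ANOVA followed by Fisher's LSD pairwise tests.

    F and p come from the between/within mean squares; the LSD tests are
    pairwise t-tests on the pooled within-group MSE with its df, with no
    multiplicity adjustment (that is the LSD definition).
    """
    arrays = {g: np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
              for g, vals in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} needs at least 2 finite values")
    grand = np.concatenate(list(arrays.values()))
    n_total, k = len(grand), len(arrays)
    grand_mean = grand.mean()
    ss_between = sum(len(a) * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between, df_within = k - 1, n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-group variance everywhere; F is undefined")
    f_stat = (ss_between / df_between) / ms_within
    p_overall = float(stats.f.sf(f_stat, df_between, df_within))
    pairwise = {}
    for g1, g2 in combinations(sorted(arrays), 2):
        a, b = arrays[g1], arrays[g2]
        se = math.sqrt(ms_within * (1 / len(a) + 1 / len(b)))
        t = (a.mean() - b.mean()) / se
        pairwise[(g1, g2)] = float(2 * stats.t.sf(abs(t), df_within))
    means = {g: float(a.mean()) for g, a in arrays.items()}
    folds = {}
    for g1, g2 in combinations(sorted(arrays), 2):
        if means[g2] > 0:
            folds[(g1, g2)] = means[g1] / means[g2]
        if means[g1] > 0:
            folds[(g2, g1)] = means[g2] / means[g1]
    return GroupComparison(
        analyte=analyte,
        group_means=means,
        F=float(f_stat),
        p_overall=p_overall,
        pairwise_p=pairwise,
        fold_changes=folds,
    )


def two_sample_t(
    tumor_values: Sequence[float],
    peritumoral_values: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Pooled-variance independent t by default; paired mode available."""
    a = np.asarray([v for v in tumor_values if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in peritumoral_values if np.isfinite(v)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per arm")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length arms")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def round_half_up(value: float, decimals: int = 2) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def group_fold_change(
    group_means: Mapping[str, float],
    numerator_group: str,
    denominator_group: str,
    round_to: int = 2,
) -> FoldChange:
    """Ratio of group means, with a half-up-rounded reported value."""
    num = group_means[numerator_group]
    den = group_means[denominator_group]
    if den <= 0:
        raise ValueError(f"denominator group mean must be > 0, got {den}")
    value = num / den
    return FoldChange(
        value=value,
        reported=round_half_up(value, round_to),
        numerator=numerator_group,
        denominator=denominator_group,
    )


def elisa_normalize(
    concentration_pg_per_ml: float,
    assay_volume_ml: float,
    total_protein_ng: float,
    sample_id: str = "",
    compartment: str = "",
) -> ElisaMeasurement:
    """Analyte mass in the assayed volume divided by total protein (pg/ng).

    Concentrations outside the kit detection range are flagged, not dropped.
    """
    if total_protein_ng <= 0:
        raise ValueError("total protein must be > 0 ng")
    if assay_volume_ml <= 0:
        raise ValueError("assay volume must be > 0 mL")
    lo, hi = ELISA_RANGE_PG_PER_ML
    normalized = concentration_pg_per_ml * assay_volume_ml / total_protein_ng
    return ElisaMeasurement(
        sample_id=sample_id,
        compartment=compartment,
        concentration_pg_per_ml=concentration_pg_per_ml,
        total_protein_ng=total_protein_ng,
        normalized_pg_per_ng=normalized,
        in_range=lo <= concentration_pg_per_ml <= hi,
    )


def boxplot_summary(values: Sequence[float]) -> dict[str, float | list[float]]:
    """Median, quartiles, 1.5·IQR whiskers and outliers (Tukey convention)."""
    a = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if a.size == 0:
        raise ValueError("no finite values to summarize")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = a[(a >= lo_fence) & (a <= hi_fence)]
    return {
        "mean": float(a.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(v) for v in a[(a < lo_fence) | (a > hi_fence)]),
        "n": int(a.size),
    }
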