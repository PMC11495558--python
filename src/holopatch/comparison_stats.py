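"""Method-comparison statistics for patch measurement tables.

Operates on a long-format table of records (patient, evaluator, method,
area, diameters): per-patient aggregation across evaluators, paired
differences and ratios between methods, Bland–Altman limits of
agreement, the one-sample (paired) Student t-test, and the rule that a
shunt-position change above 90° between modalities counts as relevant.

Pairing conventions
-------------------
Reference methods measured once per patient (DRP, CT) carry no
evaluator id; when paired against an evaluator-replicated method, the
single reference record broadcasts across that patient's evaluators, so
each evaluator's patch is compared with the patient's reference.
Pairing ``level`` is either ``"per_record"`` (all patient x evaluator
pairs — the default, matching pooled analyses over every created patch)
or ``"per_patient_median"`` (one pair per patient after taking the
median across evaluators).

Percentiles (medians, IQRs) use linear interpolation between order
statistics throughout; IQRs depend on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MeshContentError, ParameterError

REFERENCE_METHODS = ("DRP", "CT")

REQUIRED_COLUMNS = ("patient_id", "evaluator_id", "method", "area_mm2")


@dataclass
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


@dataclass
class RatioSummary:
    """Median and IQR of per-pair measurement ratios."""

    median_ratio: float
    iqr: tuple
    n: int


@dataclass
class PairedTestResult:
    """One-sample Student t-test of paired differences against zero."""

    mean_diff: float
    ci95: tuple
    t_statistic: float
    dof: int
    p_value: float
    degenerate: bool = False


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MeshContentError(f"table is missing columns: {missing}")
    if (table["area_mm2"] <= 0).any():
        raise MeshContentError("areas must be positive")


def summarize_per_patient(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-patient median and SD of one method's areas across evaluators.

    Returns a frame indexed by patient with columns ``median_area``,
    ``sd_area`` and ``n``; its ``.attrs["averaged_sd"]`` holds the mean
    of the per-patient SDs (the table-wide "averaged SD").  The SD of a
    single record is undefined and reported as NaN.
    """
    _check_table(table)
    sub = table[table["method"] == method]
    if sub.empty:
        raise MeshContentError(f"method {method!r} absent from table")
    grouped = sub.groupby("patient_id")["area_mm2"]
    out = pd.DataFrame(
        {
            "median_area": grouped.median(),
            "sd_area": grouped.std(ddof=1),
            "n": grouped.count(),
        }
    )
    out.attrs["averaged_sd"] = float(out["sd_area"].mean())
    return out


def _paired_frame(
    table: pd.DataFrame, method_a: str, method_b: str, level: str
) -> pd.DataFrame:
    """Inner helper: one row per matched (A, B) measurement pair."""
    _check_table(table)
    for m in (method_a, method_b):
        if not (table["method"] == m).any():
            raise MeshContentError(f"method {m!r} absent from table")
    if level == "per_patient_median":
        a = table[table["method"] == method_a].groupby("patient_id")["area_mm2"].median()
        b = table[table["method"] == method_b].groupby("patient_id")["area_mm2"].median()
        merged = pd.concat([a.rename("area_a"), b.rename("area_b")], axis=1, join="inner")
        merged = merged.reset_index()
        merged["evaluator_id"] = pd.NA
        return merged
    if level != "per_record":
        raise ParameterError(f"unknown pairing level {level!r}")

    def side(m, name):
        sub = table[table["method"] == m][["patient_id", "evaluator_id", "area_mm2"]]
        return sub.rename(columns={"area_mm2": name})

    a = side(method_a, "area_a")
    b = side(method_b, "area_b")
    a_ref = method_a in REFERENCE_METHODS or a["evaluator_id"].isna().all()
    b_ref = method_b in REFERENCE_METHODS or b["evaluator_id"].isna().all()
    if a_ref and not b_ref:
        merged = b.merge(a.drop(columns="evaluator_id"), on="patient_id")
    elif b_ref and not a_ref:
        merged = a.merge(b.drop(columns="evaluator_id"), on="patient_id")
    elif a_ref and b_ref:
        merged = a.drop(columns="evaluator_id").merge(
            b.drop(columns="evaluator_id"), on="patient_id"
        )
        merged["evaluator_id"] = pd.NA
    else:
        merged = a.merge(b, on=["patient_id", "evaluator_id"])
    return merged


def pairwise_differences(
    table: pd.DataFrame, method_a: str, method_b: str, level: str = "per_record"
) -> pd.DataFrame:
    """Signed (and absolute) A − B area differences for matched pairs.

    Columns: patient_id, evaluator_id, area_a, area_b, diff, abs_diff.
    Unmatched records are simply excluded by the inner join.
    """
    merged = _paired_frame(table, method_a, method_b, level)
    merged = merged.copy()
    merged["diff"] = merged["area_a"] - merged["area_b"]
    merged["abs_diff"] = merged["diff"].abs()
    return merged


def bland_altman(differences) -> BlandAltmanResult:
    """Bland–Altman agreement statistics of a difference sample.

    Mean, SD (n−1 denominator) and limits of agreement mean ± 1.96 SD.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        d = d.ravel()
    if len(d) < 2:
        raise MeshContentError("need at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, len(d))


def ratio_summary(
    table: pd.DataFrame, method_a: str, method_b: str, level: str = "per_record"
) -> RatioSummary:
    """Median and IQR of per-pair A/B area ratios."""
    merged = _paired_frame(table, method_a, method_b, level)
    ratios = merged["area_a"].to_numpy(dtype=float) / merged["area_b"].to_numpy(dtype=float)
    q25, q75 = np.percentile(ratios, [25, 75])
    return RatioSummary(float(np.median(ratios)), (float(q25), float(q75)), len(ratios))


def paired_t(differences) -> PairedTestResult:
    """One-sample Student t-test of differences against zero, two-sided,
    with the 95% confidence interval from the t quantile.

    A zero-variance sample is degenerate: the CI collapses to the mean
    and the p-value is reported as 0 (mean ≠ 0) or 1 (mean = 0), with
    the ``degenerate`` flag set.
    """
    d = np.asarray(differences, dtype=float).ravel()
    if len(d) < 2:
        raise MeshContentError("need at least 2 differences")
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    if sd == 0.0:
        return PairedTestResult(
            mean,
            (mean, mean),
            np.inf if mean != 0 else 0.0,
            dof,
            0.0 if mean != 0 else 1.0,
            degenerate=True,
        )
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    tq = stats.t.ppf(0.975, dof)
    return PairedTestResult(mean, (mean - tq * se, mean + tq * se), float(t_stat), dof, float(p))


def shunt_position_change(angle_between_modalities: float) -> bool:
    """True when the residual-shunt position differs by strictly more
    than 90° between modalities (the relevance threshold)."""
    a = float(angle_between_modalities)
    if not (0.0 <= a <= 180.0):
        raise ParameterError(f"angle must be in [0, 180] degrees, got {a}")
    return a > 90.0


def bland_altman_plot(table, method_a, method_b, path, level: str = "per_record"):
    """Write a Bland–Altman scatter (mean vs difference with limit lines)
    to ``path`` (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = pairwise_differences(table, method_a, method_b, level)
    res = bland_altman(merged["diff"])
    means = (merged["area_a"] + merged["area_b"]) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, merged["diff"], s=18, alpha=0.8)
    for y, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel(f"mean of {method_a} and {method_b} (mm²)")
    ax.set_ylabel(f"{method_a} − {method_b} (mm²)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return res
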