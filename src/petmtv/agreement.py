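"""Observer-agreement and accuracy statistics.

The battery applied to every method x threshold cell of a measurement
table: Pearson correlation against the reference volume with qualitative
effect-size bands (|r| 0.1-0.29 small, 0.3-0.49 medium, 0.5-1.0 large),
two-tailed paired t test with 95% CI, mean percentage difference from
the reference, ICC(2,1) - two-way random effects, absolute agreement,
single measures - with exact F-based 95% confidence bounds
(McGraw-Wong) and reliability bands (< 0.5 poor, 0.5-0.75 moderate,
0.75-0.9 good, > 0.9 excellent), and Bland-Altman analysis with a
regression test for proportional bias.

``summarize`` assembles the full agreement report from a long-format
measurement table; rows with too few measurable cases carry absent
statistics rather than raising, and unmeasured cases are dropped
pairwise with the drop count reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PearsonResult",
    "PairedTResult",
    "IccResult",
    "BlandAltmanResult",
    "AgreementReport",
    "pearson_with_band",
    "paired_t_ci",
    "mean_pct_diff",
    "icc_2_1",
    "bland_altman",
    "summarize",
    "TABLE_COLUMNS",
    "validate_table",
]

#: long-format measurement table columns (one row per case/reader/method/threshold)
TABLE_COLUMNS = [
    "case_id",
    "reader",
    "method",
    "threshold",
    "mtv_ml",
    "measured",
    "reference_ml",
    "masking_required",
    "adjustment_grade",
    "affected_slices",
]


class PearsonResult(NamedTuple):
    r: float
    p: float
    band: str


class PairedTResult(NamedTuple):
    mean_diff: float
    ci95: tuple[float, float]
    p: float


class IccResult(NamedTuple):
    icc: float
    ci95: tuple[float, float]
    band: str


class BlandAltmanResult(NamedTuple):
    bias: float
    loa95: tuple[float, float]
    slope: float
    slope_p: float
    proportional_bias: bool


def _as_1d(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def pearson_band(r: float) -> str:
    a = abs(r)
    if a < 0.1:
        return "none"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "medium"
    return "large"


def icc_band(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def pearson_with_band(x, y) -> PearsonResult:
    """Sample Pearson r with two-sided p and qualitative band."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p), pearson_band(float(r)))


def paired_t_ci(x, y, alpha: float = 0.05) -> PairedTResult:
    """Two-tailed paired t test on x - y with a t-based 95% CI."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical: degenerate but well-defined limits
        return PairedTResult(mean, (mean, mean), 1.0 if mean == 0.0 else 0.0)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    half = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1) * se
    return PairedTResult(mean, (mean - half, mean + half), float(p))


def mean_pct_diff(mtv, ref) -> float:
    """Mean over cases of 100 * (mtv_i - ref_i) / ref_i (per-case ratios)."""
    mtv, ref = _as_1d(mtv, "mtv"), _as_1d(ref, "ref")
    if len(mtv) != len(ref):
        raise ValueError("mtv and ref must be paired")
    if np.any(ref <= 0):
        raise ValueError("reference volumes must be positive")
    return float(np.mean(100.0 * (mtv - ref) / ref))


def icc_2_1(readings, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``readings`` is an (n x k) array of n cases rated by k readers
    (k = 2 in this pipeline).  The estimate is
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` from the
    two-way ANOVA decomposition, with exact F-distribution confidence
    bounds in the McGraw-Wong convention.
    """
    x = np.asarray(readings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("readings must be an n x k array with k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("readings contain non-finite values")
    n, k = x.shape
    if n < 5:
        raise ValueError("ICC needs at least 5 complete cases")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))

    if msr + (k - 1) * mse + k * (msc - mse) / n <= 0:
        raise ValueError("no between-case variance: ICC undefined")

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse == 0.0:
        if msc == 0.0:
            return IccResult(1.0, (1.0, 1.0), icc_band(1.0))
        # limiting F bounds as the residual mean square vanishes
        v = float(k - 1)
        f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * msr / (f_upper * k * msc + n * msr)
        upper = n * f_lower * msr / (k * msc + n * f_lower * msr)
        return IccResult(float(icc), (float(lower), float(upper)), icc_band(float(icc)))

    # exact F-based bounds (McGraw & Wong 1996, ICC(A,1))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return IccResult(float(icc), (float(lower), float(upper)), icc_band(float(icc)))


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurements.

    Differences ``d = x - y`` against means ``m = (x + y) / 2``; bias is
    the mean difference, the 95% limits of agreement are
    ``bias +/- 1.96 sd(d)``, and proportional bias is flagged when the
    least-squares slope of d on m differs from zero at ``alpha``.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("Bland-Altman needs n >= 3")
    d = x - y
    m = (x + y) / 2.0
    if np.var(m) == 0:
        raise ValueError("zero variance of the pair means")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if np.allclose(d, d[0]):
        slope, slope_p = 0.0, 1.0
    else:
        fit = stats.linregress(m, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(bias, loa, slope, slope_p, bool(slope_p < alpha))


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns {missing}")
    if len(table) == 0:
        raise ValueError("measurement table is empty")
    key = ["case_id", "reader", "method", "threshold"]
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (case, reader, method, threshold) rows")
    ref = table["reference_ml"].to_numpy(float)
    if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
        raise ValueError("reference_ml must be positive and finite")
    return table


def _reader_row(method, threshold, reader, group, alpha) -> dict:
    meas = group[group["measured"] & group["mtv_ml"].notna()]
    mtv = meas["mtv_ml"].to_numpy(float)
    ref = meas["reference_ml"].to_numpy(float)
    n = len(meas)
    row = {
        "method": method,
        "threshold": threshold,
        "reader": reader,
        "n": n,
        "n_not_measured": int(len(group) - n),
        "mean_ml": float(mtv.mean()) if n else np.nan,
        "sd_ml": float(mtv.std(ddof=1)) if n >= 2 else np.nan,
        "median_ml": float(np.median(mtv)) if n else np.nan,
        "pearson_r": np.nan,
        "pearson_p": np.nan,
        "r_band": "",
        "mean_diff_ml": np.nan,
        "diff_ci95_low": np.nan,
        "diff_ci95_high": np.nan,
        "paired_t_p": np.nan,
        "significant": False,
        "mean_pct_diff": np.nan,
        "ba_bias": np.nan,
        "ba_loa_low": np.nan,
        "ba_loa_high": np.nan,
        "ba_slope": np.nan,
        "ba_slope_p": np.nan,
        "ba_prop_bias": False,
    }
    if n >= 3 and np.var(mtv) > 0 and np.var(ref) > 0:
        pr = pearson_with_band(mtv, ref)
        tt = paired_t_ci(mtv, ref, alpha=alpha)
        ba = bland_altman(mtv, ref, alpha=alpha)
        row.update(
            pearson_r=pr.r,
            pearson_p=pr.p,
            r_band=pr.band,
            mean_diff_ml=tt.mean_diff,
            diff_ci95_low=tt.ci95[0],
            diff_ci95_high=tt.ci95[1],
            paired_t_p=tt.p,
            significant=bool(tt.p < alpha),
            mean_pct_diff=mean_pct_diff(mtv, ref),
            ba_bias=ba.bias,
            ba_loa_low=ba.loa95[0],
            ba_loa_high=ba.loa95[1],
            ba_slope=ba.slope,
            ba_slope_p=ba.slope_p,
            ba_prop_bias=ba.proportional_bias,
        )
    elif n >= 1:
        row["mean_pct_diff"] = mean_pct_diff(mtv, ref) if np.all(ref > 0) else np.nan
    return row


def _icc_row(method, threshold, group) -> dict:
    wide = group[group["measured"] & group["mtv_ml"].notna()].pivot_table(
        index="case_id", columns="reader", values="mtv_ml", aggfunc="first"
    )
    n_cases = group["case_id"].nunique()
    complete = wide.dropna()
    readers = sorted(group["reader"].unique())
    row = {
        "method": method,
        "threshold": threshold,
        "n_pairs": int(len(complete)) if len(readers) >= 2 else 0,
        "n_dropped": int(n_cases - len(complete)) if len(readers) >= 2 else n_cases,
        "icc": np.nan,
        "icc_ci95_low": np.nan,
        "icc_ci95_high": np.nan,
        "icc_band": "",
    }
    if len(readers) >= 2 and len(complete) >= 5:
        mat = complete.to_numpy(float)
        try:
            res = icc_2_1(mat)
        except ValueError:
            return row
        row.update(
            icc=res.icc,
            icc_ci95_low=res.ci95[0],
            icc_ci95_high=res.ci95[1],
            icc_band=res.band,
        )
    return row


def _tally_row(method, threshold, reader, group) -> dict:
    grades = group["adjustment_grade"].fillna("")
    return {
        "method": method,
        "threshold": threshold,
        "reader": reader,
        "n": int(len(group)),
        "masking_required": int(group["masking_required"].fillna(False).sum()),
        "adjust_none": int((grades == "none").sum()),
        "adjust_minor": int((grades == "minor").sum()),
        "adjust_major": int((grades == "major").sum()),
        "adjust_too_difficult": int((grades == "too_difficult").sum()),
    }


@dataclass
class AgreementReport:
    """Per-reader accuracy, inter-reader ICC and masking/adjustment tallies."""

    per_reader: pd.DataFrame
    inter_reader: pd.DataFrame
    tallies: pd.DataFrame

    def to_json(self, path=None) -> str:
        payload = {
            "per_reader": self.per_reader.to_dict(orient="records"),
            "inter_reader": self.inter_reader.to_dict(orient="records"),
            "tallies": self.tallies.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_csvs(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in [
            ("per_reader", self.per_reader),
            ("inter_reader", self.inter_reader),
            ("tallies", self.tallies),
        ]:
            p = out_dir / f"agreement_{name}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        return paths


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")  # pragma: no cover


def summarize(table: pd.DataFrame, alpha: float = 0.05) -> AgreementReport:
    """Compute the full agreement report from a long measurement table."""
    table = validate_table(table)
    per_reader, inter, tallies = [], [], []
    for (method, threshold), g in table.groupby(["method", "threshold"], sort=True):
        for reader, gr in g.groupby("reader", sort=True):
            per_reader.append(_reader_row(method, threshold, reader, gr, alpha))
            tallies.append(_tally_row(method, threshold, reader, gr))
        inter.append(_icc_row(method, threshold, g))
    return AgreementReport(
        per_reader=pd.DataFrame(per_reader),
        inter_reader=pd.DataFrame(inter),
        tallies=pd.DataFrame(tallies),
    )
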