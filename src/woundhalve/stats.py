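"""Reliability statistics for wound-halving ratings.

Implements the evaluation protocol of a split-wound rater study:

* medians with interquartile ranges under the SPSS weighted-average
  (HAVERAGE, R type-6) quantile convention,
* ICC(A,1) — two-way random effects, single measure, absolute agreement —
  with a McGraw–Wong F-based 95% confidence interval,
* the Wilcoxon signed-rank test (exact for small tie-free samples, normal
  approximation with tie and continuity corrections otherwise),
* builders for the two summary tables of the study design: inter-rater
  agreement by assessment type, and before/after intra-rater agreement.

The ICC can be negative when between-rater disagreement exceeds
between-image variance; negative estimates are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import IncompleteDesignError, UndefinedICCError

_QUANTILE_METHODS = {"haverage": "weibull", "linear": "linear"}

__all__ = [
    "SummaryRow",
    "ICCResult",
    "WilcoxonResult",
    "median_iqr",
    "icc_a1",
    "interpret_icc",
    "wilcoxon_signed_rank",
    "build_table1",
    "build_table2",
    "compare_manual_vs_algorithm",
    "table1_to_frame",
    "table2_to_frame",
]


@dataclass(frozen=True)
class SummaryRow:
    label: str
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    msr: float  # between-rows (images) mean square
    msc: float  # between-columns (raters) mean square
    mse: float  # residual mean square
    n: int
    k: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n_effective: int  # pairs with nonzero difference
    p_two_sided: float
    method: str  # "exact" or "normal-approx"
    degenerate: bool = False  # all differences were zero


def median_iqr(values, label: str = "", convention: str = "haverage") -> SummaryRow:
    """Median and quartiles of a sample of percentages.

    ``haverage`` is the SPSS default weighted-average quantile (position
    (n+1)p, R type 6); ``linear`` is the usual numpy default.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("median_iqr needs at least one value")
    method = _QUANTILE_METHODS[convention]
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    return SummaryRow(label=label, median=float(med), q1=float(q1), q3=float(q3))


def icc_a1(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is n images (rows) x k raters (columns), complete.  The
    estimate is (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)); the 95%
    CI follows the McGraw–Wong F-based procedure with Satterthwaite degrees
    of freedom.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("rating matrix must be 2-D (images x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 images and 2 raters")
    if np.isnan(x).any():
        raise ValueError(
            "rating matrix has missing cells; apply listwise deletion upstream"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if sst <= 0 or denom == 0:
        raise UndefinedICCError("zero total variance; ICC undefined")
    r = (msr - mse) / denom

    if mse <= 0 and msc <= 0:
        # perfect absolute agreement: degenerate CI
        lo = hi = r
    else:
        a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
        b = 1.0 + (k * r * (n - 1)) / (n * (1.0 - r)) if r < 1.0 else np.inf
        if not np.isfinite(a):
            lo = hi = r
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            if np.isfinite(f_l):
                lo = (
                    n * (msr - f_l * mse)
                    / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
            else:
                # limit of the bound as the F quantile diverges (v -> 0)
                lo = -n * mse / (k * msc + (k * n - k - n) * mse)
            if np.isfinite(f_u):
                hi = (
                    n * (f_u * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
                )
            else:
                hi = 1.0
    return ICCResult(
        estimate=float(r),
        ci_low=float(min(lo, r)),
        ci_high=float(max(hi, r)),
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n=n,
        k=k,
    )


def interpret_icc(estimate: float) -> str:
    """Qualitative agreement band for an ICC estimate."""
    if estimate > 1.0 + 1e-12:
        raise ValueError("ICC estimate cannot exceed 1")
    if estimate >= 0.80:
        return "excellent"
    if estimate >= 0.60:
        return "good"
    if estimate >= 0.40:
        return "moderate"
    if estimate >= 0.20:
        return "fair"
    return "poor"


def _exact_wplus_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per W+ value (generating-function DP)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y, method: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classical Wilcoxon / SPSS default); tied
    absolute differences get mid-ranks.  The exact two-sided p enumerates all
    sign assignments (valid only without rank ties) and is used for
    n_effective <= 12; otherwise the normal approximation with tie and
    continuity corrections applies.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0, 1.0, "exact", degenerate=True)
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    has_ties = len(np.unique(absd)) < n
    w_plus = float(ranks[d > 0].sum())
    if method == "exact" and has_ties:
        raise ValueError("exact p is only defined without rank ties")
    use_exact = method == "exact" or (method == "auto" and n <= 12 and not has_ties)
    if use_exact:
        counts = _exact_wplus_counts(ranks)
        total = int(ranks.sum())
        w = int(round(w_plus))
        lo, hi = min(w, total - w), max(w, total - w)
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / 2.0**n
        return WilcoxonResult(w_plus, n, float(min(p, 1.0)), "exact")
    mu = n * (n + 1) / 4.0
    tie_sizes = np.unique(absd, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes**3 - tie_sizes).sum()) / 48.0
    dev = w_plus - mu
    dev -= 0.5 * np.sign(dev)  # continuity correction toward the mean
    z = dev / np.sqrt(var)
    p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    return WilcoxonResult(w_plus, n, max(p, np.finfo(float).tiny), "normal-approx")


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Row:
    label: str
    value: SummaryRow  # one-side wound-surface percentage
    icc: ICCResult  # inter-rater ICC on the percentage matrix
    deviation: SummaryRow  # |percentage - 50|


@dataclass(frozen=True)
class Table2Entry:
    assessor: str
    round1_value: SummaryRow
    round1_deviation: SummaryRow
    round2_value: SummaryRow
    round2_deviation: SummaryRow
    icc: ICCResult | None  # round-2 vs round-1 (None only if a round is absent)


def _pivot(df: pd.DataFrame, index: str, columns: str, values: str) -> pd.DataFrame:
    wide = df.pivot(index=index, columns=columns, values=values)
    if wide.isna().any().any():
        cells = [
            (i, c) for i in wide.index for c in wide.columns if pd.isna(wide.loc[i, c])
        ]
        raise IncompleteDesignError(f"missing rating cells: {cells}")
    return wide


def build_table1(
    rating: pd.DataFrame,
    reference_assessor: str | None = None,
    convention: str = "haverage",
) -> dict[str, Table1Row]:
    """Inter-rater agreement by assessment type.

    Rows: Algorithm (grounded on each assessor's round-1 outline for the ICC,
    on the reference assessor's outlines for the pooled median/IQR), then
    manual rounds 1 and 2 pooled over all assessors.
    """
    assessors = sorted(rating["assessor_id"].unique())
    if reference_assessor is None:
        reference_assessor = assessors[0]
    if reference_assessor not in assessors:
        raise ValueError(f"unknown reference assessor {reference_assessor!r}")
    rows: dict[str, Table1Row] = {}

    alg = rating[rating["source"] == "algorithm"]
    ref = alg[alg["assessor_id"] == reference_assessor]
    if ref.empty:
        raise IncompleteDesignError("no algorithm rows for the reference assessor")
    wide = _pivot(alg, "image_id", "assessor_id", "fraction_side1")
    rows["Algorithm"] = Table1Row(
        label="Algorithm",
        value=median_iqr(ref["fraction_side1"], "Algorithm", convention),
        icc=icc_a1(wide.to_numpy()),
        deviation=median_iqr(ref["abs_deviation"], "Algorithm", convention),
    )
    for rnd, label in ((1, "Manual 1st round"), (2, "Manual 2nd round")):
        man = rating[(rating["source"] == "manual") & (rating["round"] == rnd)]
        if man.empty:
            raise IncompleteDesignError(f"no manual ratings for round {rnd}")
        wide = _pivot(man, "image_id", "assessor_id", "fraction_side1")
        rows[label] = Table1Row(
            label=label,
            value=median_iqr(man["fraction_side1"], label, convention),
            icc=icc_a1(wide.to_numpy()),
            deviation=median_iqr(man["abs_deviation"], label, convention),
        )
    return rows


def build_table2(
    rating: pd.DataFrame, convention: str = "haverage"
) -> dict[str, Table2Entry]:
    """Before/after intra-rater agreement, per assessor and overall.

    Per assessor: round-wise median/IQR of the percentage and its deviation,
    plus ICC(A,1) on the images x {round 1, round 2} matrix.  The "All" entry
    pools the per-assessor (round-1, round-2) pairs by stacking the matrices.
    """
    man = rating[rating["source"] == "manual"]
    entries: dict[str, Table2Entry] = {}
    stacked = []
    for assessor in sorted(man["assessor_id"].unique()):
        sub = man[man["assessor_id"] == assessor]
        r1 = sub[sub["round"] == 1]
        r2 = sub[sub["round"] == 2]
        if r1.empty or r2.empty:
            raise IncompleteDesignError(
                f"assessor {assessor!r} is missing a round"
            )
        wide = _pivot(sub, "image_id", "round", "fraction_side1")[[1, 2]]
        stacked.append(wide.to_numpy())
        entries[assessor] = Table2Entry(
            assessor=assessor,
            round1_value=median_iqr(r1["fraction_side1"], assessor, convention),
            round1_deviation=median_iqr(r1["abs_deviation"], assessor, convention),
            round2_value=median_iqr(r2["fraction_side1"], assessor, convention),
            round2_deviation=median_iqr(r2["abs_deviation"], assessor, convention),
            icc=icc_a1(wide.to_numpy()),
        )
    r1 = man[man["round"] == 1]
    r2 = man[man["round"] == 2]
    entries["All"] = Table2Entry(
        assessor="All",
        round1_value=median_iqr(r1["fraction_side1"], "All", convention),
        round1_deviation=median_iqr(r1["abs_deviation"], "All", convention),
        round2_value=median_iqr(r2["fraction_side1"], "All", convention),
        round2_deviation=median_iqr(r2["abs_deviation"], "All", convention),
        icc=icc_a1(np.vstack(stacked)),
    )
    return entries


def compare_manual_vs_algorithm(
    rating: pd.DataFrame, pairing: str = "per-assessor-image"
) -> dict[str, WilcoxonResult]:
    """Wilcoxon signed-rank: manual vs algorithmic absolute deviation.

    ``per-assessor-image`` pairs each (assessor, image) manual deviation with
    that assessor's algorithm deviation on the same image;
    ``per-image-mean`` first averages both across assessors per image.
    Returns results per round plus the pooled pairs.
    """
    if pairing not in ("per-assessor-image", "per-image-mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    alg = rating[rating["source"] == "algorithm"]
    out: dict[str, WilcoxonResult] = {}
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for rnd in sorted(rating.loc[rating["source"] == "manual", "round"].unique()):
        man = rating[(rating["source"] == "manual") & (rating["round"] == rnd)]
        if pairing == "per-assessor-image":
            merged = man.merge(
                alg[["image_id", "assessor_id", "abs_deviation"]],
                on=["image_id", "assessor_id"],
                suffixes=("_manual", "_algorithm"),
            )
        else:
            mm = man.groupby("image_id")["abs_deviation"].mean()
            aa = alg.groupby("image_id")["abs_deviation"].mean()
            merged = pd.DataFrame(
                {"abs_deviation_manual": mm, "abs_deviation_algorithm": aa}
            ).dropna()
        x = merged["abs_deviation_manual"].to_numpy()
        y = merged["abs_deviation_algorithm"].to_numpy()
        pooled_x.extend(x)
        pooled_y.extend(y)
        out[f"round{rnd}"] = wilcoxon_signed_rank(x, y)
    out["pooled"] = wilcoxon_signed_rank(pooled_x, pooled_y)
    return out


# ---------------------------------------------------------------------------
# display frames (paper-style rounding; CSVs keep full precision elsewhere)
# ---------------------------------------------------------------------------


def _fmt(x: float, decimals: int) -> float:
    return float(np.round(x, decimals))


def table1_to_frame(rows: dict[str, Table1Row]) -> pd.DataFrame:
    """Render the type-of-assessment table with display rounding.

    Manual percentages print as integers, the algorithm's deviation to one
    decimal, mirroring the headline tables.
    """
    recs = []
    for label, row in rows.items():
        dec = 1 if label == "Algorithm" else 0
        recs.append(
            {
                "type": label,
                "value_median": _fmt(row.value.median, 0),
                "value_q1": _fmt(row.value.q1, 0),
                "value_q3": _fmt(row.value.q3, 0),
                "icc": _fmt(row.icc.estimate, 2),
                "icc_ci_low": _fmt(row.icc.ci_low, 2),
                "icc_ci_high": _fmt(row.icc.ci_high, 2),
                "deviation_median": _fmt(row.deviation.median, dec),
                "deviation_q1": _fmt(row.deviation.q1, dec),
                "deviation_q3": _fmt(row.deviation.q3, dec),
            }
        )
    return pd.DataFrame(recs)


def table2_to_frame(entries: dict[str, Table2Entry]) -> pd.DataFrame:
    recs = []
    for name, e in entries.items():
        recs.append(
            {
                "assessor": name,
                "round1_value_median": _fmt(e.round1_value.median, 0),
                "round1_value_q1": _fmt(e.round1_value.q1, 0),
                "round1_value_q3": _fmt(e.round1_value.q3, 0),
                "round1_deviation_median": _fmt(e.round1_deviation.median, 0),
                "round1_deviation_q1": _fmt(e.round1_deviation.q1, 0),
                "round1_deviation_q3": _fmt(e.round1_deviation.q3, 0),
                "round2_value_median": _fmt(e.round2_value.median, 0),
                "round2_value_q1": _fmt(e.round2_value.q1, 0),
                "round2_value_q3": _fmt(e.round2_value.q3, 0),
                "round2_deviation_median": _fmt(e.round2_deviation.median, 0),
                "round2_deviation_q1": _fmt(e.round2_deviation.q1, 0),
                "round2_deviation_q3": _fmt(e.round2_deviation.q3, 0),
                "icc": _fmt(e.icc.estimate, 1) if e.icc else None,
                "icc_ci_low": _fmt(e.icc.ci_low, 1) if e.icc else None,
                "icc_ci_high": _fmt(e.icc.ci_high, 1) if e.icc else None,
            }
        )
    return pd.DataFrame(recs)
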