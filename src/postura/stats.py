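"""Agreement validation between two measurement sources.

Implements the software-vs-software comparison protocol: per feature,
the normality of each source's sample is assessed with Shapiro–Wilk; the
paired difference is then tested with a paired t test when both samples
look normal and a Wilcoxon signed-rank test otherwise.  Features that
come out significantly different at both significance levels (0.05 and
0.1) get a Tukey-rule outlier removal on the differences and a repeat
analysis.  Finally a paired-TOST equivalence test is run along a ladder
of widening bounds (±0.01 → ±0.05 → ±0.06 by default), stopping at the
first rung that establishes equivalence.

All tests are evaluated at both α = 0.05 and α = 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, MismatchedTablesError

ALPHAS = (0.05, 0.1)
DEFAULT_TOST_LADDER = ((-0.01, 0.01), (-0.05, 0.05), (-0.06, 0.06))


@dataclass(frozen=True)
class PairedFeatureSample:
    """Same-subject measurements of one feature from two sources."""

    feature: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length vectors")
        if len(a) < 3:
            raise ValueError("at least 3 pairs are required")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing entries must be resolved before pairing")

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    decisions: dict            # alpha -> bool (reject / declare)
    extra: dict = field(default_factory=dict)


def _decisions(p: float, reject_when_below: bool = True) -> dict:
    return {a: (p < a if reject_when_below else p >= a) for a in ALPHAS}


def shapiro_wilk(sample, alphas=ALPHAS) -> TestResult:
    """Shapiro–Wilk normality test; ``decisions[α]`` is True when the
    sample is *compatible with* normality (p ≥ α)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("zero variance sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p),
                      {a: p >= a for a in alphas})


def paired_compare(pair: PairedFeatureSample, alpha: float = 0.05) -> TestResult:
    """Normality-gated paired comparison.

    Both sources normal at ``alpha`` (Shapiro–Wilk) → paired t test;
    otherwise Wilcoxon signed-rank on the differences (zeros discarded,
    exact null for ≤ 25 nonzero differences, normal approximation with
    continuity correction above).
    """
    d = pair.differences
    if np.all(d == 0):
        raise DegenerateSampleError("no nonzero differences")
    sw_a = shapiro_wilk(pair.a)
    sw_b = shapiro_wilk(pair.b)
    both_normal = sw_a.p_value >= alpha and sw_b.p_value >= alpha
    gate = {"normal_A_p": sw_a.p_value, "normal_B_p": sw_b.p_value,
            "gate_alpha": alpha, "both_normal": both_normal}
    if both_normal:
        stat, p = sps.ttest_rel(pair.a, pair.b)
        name = "paired_t"
    else:
        nz = int(np.count_nonzero(d))
        method = "exact" if nz <= 25 else "approx"
        res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                           method=method)
        stat, p = res.statistic, res.pvalue
        name = "wilcoxon_signed_rank"
        gate["wilcoxon_method"] = method
    return TestResult(name, float(stat), float(p), _decisions(float(p)),
                      extra=gate)


def tost_equivalence(pair: PairedFeatureSample, lower: float, upper: float,
                     alphas=ALPHAS) -> TestResult:
    """Paired two-one-sided-tests equivalence test on the t distribution
    with n−1 degrees of freedom; ``decisions[α]`` is True when
    equivalence is declared (p < α).

    Zero-variance differences are handled exactly: equivalent iff the
    constant difference lies strictly inside (lower, upper).
    """
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    d = pair.differences
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        inside = lower < mean < upper
        p = 0.0 if inside else 1.0
        return TestResult("tost", float("nan"), p,
                          {a: inside for a in alphas},
                          extra={"bounds": (lower, upper), "mean_diff": mean,
                                 "degenerate": True})
    se = sd / np.sqrt(n)
    t_low = (mean - lower) / se
    t_high = (mean - upper) / se
    p_low = float(sps.t.sf(t_low, n - 1))    # H1: mean > lower
    p_high = float(sps.t.cdf(t_high, n - 1))  # H1: mean < upper
    p = max(p_low, p_high)
    return TestResult("tost", float(max(abs(t_low), abs(t_high))), p,
                      _decisions(p),
                      extra={"bounds": (lower, upper), "mean_diff": mean,
                             "sd_diff": sd, "p_lower": p_low, "p_upper": p_high})


def remove_outlier_pairs(pair: PairedFeatureSample,
                         iqr_factor: float = 1.5) -> PairedFeatureSample:
    """Drop pairs whose difference falls outside the Tukey fences
    [Q1 − k·IQR, Q3 + k·IQR] of the differences; both sources lose the
    same subjects."""
    if pair.n < 5:
        raise ValueError("outlier removal requires at least 5 pairs")
    d = pair.differences
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    keep = (d >= q1 - iqr_factor * iqr) & (d <= q3 + iqr_factor * iqr)
    if keep.sum() < 3:
        raise DegenerateSampleError(
            "outlier removal would leave fewer than 3 pairs")
    return PairedFeatureSample(pair.feature, pair.a[keep], pair.b[keep])


# ---------------------------------------------------------------------------
# full per-table protocol


@dataclass
class ValidationConfig:
    alphas: tuple = ALPHAS
    gate_alpha: float = 0.05
    tost_ladder: tuple = DEFAULT_TOST_LADDER
    iqr_factor: float = 1.5
    standardize: bool = False  # run TOST on differences / sd(differences)


@dataclass
class ValidationReport:
    per_feature: dict
    config: ValidationConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat, rec in self.per_feature.items():
            rows.append({
                "feature": feat,
                "n": rec["n"],
                "mean_diff": rec["mean_diff"],
                "sd_diff": rec["sd_diff"],
                "gate": rec.get("gate"),
                "test": rec.get("test"),
                "p": rec.get("p"),
                "outliers_removed": rec.get("outliers_removed", 0),
                "tost_bounds_used": str(rec.get("tost_bounds_used")),
                "tost_p": rec.get("tost_p"),
                "equivalent_at_0.05": rec.get("equivalent", {}).get(0.05),
                "equivalent_at_0.1": rec.get("equivalent", {}).get(0.1),
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, float) and np.isnan(o):
                return None
            return o
        return json.dumps(clean(self.per_feature), indent=2)


def validate_feature_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                            config: ValidationConfig | None = None) -> ValidationReport:
    """Run the full agreement protocol feature by feature.

    Both tables must be indexed by subject and share columns.  The
    outlier re-analysis is triggered only when a feature's difference
    test is significant at *both* significance levels; the TOST ladder
    stops at the first rung equivalent at α = 0.05.
    """
    config = config or ValidationConfig()
    if not table_a.index.equals(table_b.index):
        raise MismatchedTablesError(
            "subject mismatch between tables",
            {"only_a": sorted(set(table_a.index) - set(table_b.index)),
             "only_b": sorted(set(table_b.index) - set(table_a.index))})
    if sorted(table_a.columns) != sorted(table_b.columns):
        raise MismatchedTablesError(
            "feature mismatch between tables",
            {"only_a": sorted(set(table_a.columns) - set(table_b.columns)),
             "only_b": sorted(set(table_b.columns) - set(table_a.columns))})

    report = {}
    for feat in table_a.columns:
        pair = PairedFeatureSample(feat, table_a[feat].to_numpy(),
                                   table_b[feat].to_numpy())
        d = pair.differences
        rec = {"n": pair.n, "mean_diff": float(d.mean()),
               "sd_diff": float(d.std(ddof=1))}

        if np.all(d == 0):
            rec["exact_agreement"] = True
            rec["test"] = None
            rec["gate"] = None
            rec["p"] = None
            eq_pair = pair
        else:
            rec["exact_agreement"] = False
            res = paired_compare(pair, alpha=config.gate_alpha)
            rec["gate"] = ("parametric" if res.extra["both_normal"]
                           else "nonparametric")
            rec["test"] = res.test
            rec["p"] = res.p_value
            rec["significant"] = dict(res.decisions)
            if all(res.decisions[a] for a in config.alphas):
                cleaned = remove_outlier_pairs(pair, config.iqr_factor)
                rec["outliers_removed"] = pair.n - cleaned.n
                res2 = paired_compare(cleaned, alpha=config.gate_alpha)
                rec["post_outlier"] = {
                    "n": cleaned.n, "test": res2.test, "p": res2.p_value,
                    "significant": dict(res2.decisions)}
            eq_pair = pair

        if config.standardize and rec["sd_diff"] > 0:
            scale = rec["sd_diff"]
            eq_pair = PairedFeatureSample(feat, eq_pair.a / scale,
                                          eq_pair.b / scale)

        ladder = []
        equivalent = {a: False for a in config.alphas}
        bounds_used = None
        tost_p = None
        for (lo, hi) in config.tost_ladder:
            t = tost_equivalence(eq_pair, lo, hi, alphas=config.alphas)
            ladder.append({"bounds": (lo, hi), "p": t.p_value,
                           "equivalent": dict(t.decisions)})
            if bounds_used is None and t.decisions[0.05]:
                bounds_used = (lo, hi)
                tost_p = t.p_value
                equivalent = dict(t.decisions)
                break
        if bounds_used is None and ladder:
            tost_p = ladder[-1]["p"]
            equivalent = dict(ladder[-1]["equivalent"])
            bounds_used = ladder[-1]["bounds"]
        rec["tost_ladder"] = ladder
        rec["tost_bounds_used"] = bounds_used
        rec["tost_p"] = tost_p
        rec["equivalent"] = equivalent
        report[feat] = rec
    return ValidationReport(report, config)
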