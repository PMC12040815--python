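"""Statistical layer: Welch's t, paired t, one-sample t, 95% CIs, cohort tables.

Two-sided p-values are reported for the Welch and paired comparisons; the
one-sided variant exists for the profile-peak visibility test. Zero-variance
samples follow a documented convention instead of raising: the t statistic is
signed infinity and p is 0 or 1 depending on the direction of the mean. No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ARM_VOCABULARY = ("previous", "new", "simulated", "clinical")


@dataclass
class TestResult:
    statistic: float
    df: float
    pvalue: float
    mean_diff: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    kind: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("CI lower bound exceeds upper bound")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def welch_t(sample_a, sample_b, alpha: float = 0.05) -> TestResult:
    """Welch's unequal-variance two-sample t-test with two-sided p.

    Degrees of freedom follow Welch–Satterthwaite; the CI is on the mean
    difference a − b.
    """
    a = _as_sample(sample_a, "sample_a")
    b = _as_sample(sample_b, "sample_b")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; Welch's test undefined")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    diff = a.mean() - b.mean()
    hw = tc * np.sqrt(se2)
    return TestResult(float(t), float(df), float(p), float(diff),
                      float(diff - hw), float(diff + hw), alpha, "welch")


def one_sample_t(sample, popmean: float = 0.0, alternative: str = "two-sided",
                 alpha: float = 0.05) -> TestResult:
    """One-sample t-test against ``popmean`` (two-sided, greater, or less)."""
    x = _as_sample(sample, "sample")
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    diff = mean - popmean
    df = n - 1
    if sd == 0.0:
        # zero-variance convention
        t = np.inf * np.sign(diff) if diff != 0 else 0.0
        if alternative == "greater":
            p = 0.0 if diff > 0 else 1.0
        elif alternative == "less":
            p = 0.0 if diff < 0 else 1.0
        else:
            p = 0.0 if diff != 0 else 1.0
        return TestResult(float(t), float(df), float(p), float(diff),
                          float(diff), float(diff), alpha, "one_sample")
    se = sd / np.sqrt(n)
    t = diff / se
    if alternative == "greater":
        p = sps.t.sf(t, df)
    elif alternative == "less":
        p = sps.t.cdf(t, df)
    elif alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return TestResult(float(t), float(df), float(p), float(diff),
                      float(diff - tc * se), float(diff + tc * se), alpha, "one_sample")


def paired_t(before, after, alpha: float = 0.05) -> TestResult:
    """Paired two-sample t-test (one-sample t on after − before), two-sided."""
    b = _as_sample(before, "before")
    a = _as_sample(after, "after")
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length ({b.size} vs {a.size})")
    res = one_sample_t(a - b, popmean=0.0, alternative="two-sided", alpha=alpha)
    return TestResult(res.statistic, res.df, res.pvalue, res.mean_diff,
                      res.ci_low, res.ci_high, alpha, "paired")


def mean_ci95(sample, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample mean with its t-based confidence interval."""
    x = _as_sample(sample, "sample")
    n = x.size
    mean = float(x.mean())
    se = x.std(ddof=1) / np.sqrt(n)
    tc = sps.t.ppf(0.5 + confidence / 2.0, n - 1)
    return mean, (mean - tc * se, mean + tc * se)


def compare_cohorts(
    records: pd.DataFrame,
    pairing: str = "cohort",
    metrics=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metric comparison table of a two-arm dosimetric record set.

    ``pairing='cohort'`` applies Welch's t-test between the two arms;
    ``pairing='paired'`` matches records by patient id and applies the paired
    t-test. Reports mean, SD, range and 95% CI per arm plus the test result,
    mirroring the reporting style of the clinical comparison (means ± SD with
    ranges and CIs, no multiplicity correction).
    """
    if pairing not in ("cohort", "paired"):
        raise ValueError("pairing must be 'cohort' or 'paired'")
    arms = list(pd.unique(records["arm"]))
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 arms, found {arms}")
    for arm in arms:
        if arm not in ARM_VOCABULARY:
            raise ValueError(f"arm {arm!r} not in {ARM_VOCABULARY}")
    if metrics is None:
        reserved = {"patient_id", "arm"}
        metrics = [c for c in records.columns if c not in reserved]
    rows = []
    for metric in metrics:
        if metric not in records.columns:
            raise KeyError(f"metric column {metric!r} missing from the records")
        a = records.loc[records["arm"] == arms[0], [metric, "patient_id"]]
        b = records.loc[records["arm"] == arms[1], [metric, "patient_id"]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 records per arm")
        if pairing == "paired":
            a = a.sort_values("patient_id")
            b = b.sort_values("patient_id")
            if len(a) != len(b):
                raise ValueError("paired mode requires equal arm sizes")
            res = paired_t(a[metric].to_numpy(), b[metric].to_numpy(), alpha)
            # mean_diff is arm2 − arm1 in paired_t(before=arm1, after=arm2)
            diff = res.mean_diff
        else:
            res = welch_t(a[metric].to_numpy(), b[metric].to_numpy(), alpha)
            diff = -res.mean_diff  # report arm2 − arm1 uniformly
        row = {"metric": metric, "test": res.kind, "statistic": res.statistic,
               "df": res.df, "pvalue": res.pvalue,
               f"mean_diff_{arms[1]}_minus_{arms[0]}": diff,
               "significant": res.significant}
        for arm, sub in ((arms[0], a), (arms[1], b)):
            vals = sub[metric].to_numpy()
            mean, (lo, hi) = mean_ci95(vals)
            row.update({
                f"{arm}_mean": mean,
                f"{arm}_sd": float(vals.std(ddof=1)),
                f"{arm}_min": float(vals.min()),
                f"{arm}_max": float(vals.max()),
                f"{arm}_ci_low": lo,
                f"{arm}_ci_high": hi,
            })
        rows.append(row)
    return pd.DataFrame(rows)
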