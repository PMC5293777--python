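"""The study's statistical battery and derived summary quantities.

Routing follows the published scheme: two-group comparisons use a two-sided
t-test after both samples pass Shapiro-Wilk at alpha = 0.05, otherwise the
Mann-Whitney rank-sum test; multi-group comparisons use one-way ANOVA with
Holm-Sidak-adjusted pairwise follow-ups; a sample mean is compared to a
hypothesized value with a one-sided t-test.  All group summaries are
mean +/- SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import Eye


class TestName(str, Enum):
    T_TWO_SIDED = "t_two_sided"
    T_PAIRED = "t_paired"
    MANN_WHITNEY = "mann_whitney"
    WILCOXON = "wilcoxon"
    T_ONE_SIDED_VS_VALUE = "t_one_sided_vs_value"
    ANOVA = "anova"
    HOLM_SIDAK_PAIRWISE = "holm_sidak_pairwise"
    SHAPIRO_WILK = "shapiro_wilk"


@dataclass
class TestResult:
    test_name: TestName
    statistic: float
    p_value: float
    n: tuple[int, ...]
    normality_pass: bool | None = None  # None = not applicable
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value out of range: {self.p_value}")


@dataclass
class IOPRecord:
    animal_id: str
    eye: Eye
    day: int  # <= 0 is pre-injection; injection happens on day 0
    iop_mmHg: float

    def __post_init__(self) -> None:
        if self.iop_mmHg <= 0:
            raise ValueError("iop_mmHg must be > 0")


def baseline_iop(readings) -> float:
    """Mean of an eye's pre-injection readings (2-3 days expected; warn
    outside that range)."""
    vals = np.asarray(list(readings), dtype=float)
    if vals.size == 0:
        raise ValueError("no pre-injection readings")
    if not 2 <= vals.size <= 3:
        warnings.warn(
            f"{vals.size} pre-injection readings (expected 2-3)", stacklevel=2
        )
    return float(vals.mean())


def baseline_iop_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per animal/eye baseline from a long-format IOP table (day <= 0)."""
    pre = df[df["day"] <= 0]
    if pre.empty:
        raise ValueError("no pre-injection records")
    out = (
        pre.groupby(["animal_id", "eye"], sort=True)["iop_mmHg"]
        .mean()
        .rename("baseline_mmHg")
        .reset_index()
    )
    return out


def percent_change(
    reference_mean: float, comparison_mean: float, decimals: int | None = None
) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    ``decimals`` applies the report's rounding convention (1 for IOP
    elevations, 0 for marker-ratio changes); None returns the raw value.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    change = 100.0 * (comparison_mean - reference_mean) / reference_mean
    if decimals is not None:
        change = round(change, decimals)
        if decimals == 0:
            change = float(int(change))
    return change


def test_vs_unity(
    ratios, value: float = 1.0, alternative: str = "auto"
) -> TestResult:
    """One-sided one-sample t-test of the ratios against ``value``
    (default unity).

    With ``alternative="auto"`` the one-sided direction is taken from the
    observed side of ``value`` (the study tests departure from unity in the
    per-panel known direction); ``"two-sided"``, ``"greater"`` and ``"less"``
    are available explicitly.
    """
    x = np.asarray(list(ratios), dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 ratios")
    mean = x.mean()
    if alternative == "auto":
        if mean == value:
            alternative = "greater"  # t = 0 -> one-sided p = 0.5 either way
        else:
            alternative = "greater" if mean > value else "less"
    if x.std(ddof=1) == 0.0:
        if mean == value:
            return TestResult(TestName.T_ONE_SIDED_VS_VALUE, 0.0, 0.5, (x.size,))
        # zero variance off the hypothesized value: p -> 0, flagged
        return TestResult(
            TestName.T_ONE_SIDED_VS_VALUE,
            float(np.inf if mean > value else -np.inf),
            0.0,
            (x.size,),
            details={"zero_variance": True, "alternative": alternative},
        )
    res = stats.ttest_1samp(x, popmean=value, alternative=alternative)
    return TestResult(
        TestName.T_ONE_SIDED_VS_VALUE,
        float(res.statistic),
        float(res.pvalue),
        (x.size,),
        details={"alternative": alternative, "hypothesized": value},
    )


def _shapiro_ok(x: np.ndarray, alpha: float) -> tuple[bool, float]:
    if np.ptp(x) == 0.0:
        return True, float("nan")  # constant sample: gate cannot run; pass through
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(x)
    return res.pvalue > alpha, float(res.pvalue)


def compare_groups(a, b, paired: bool = False, alpha: float = 0.05) -> TestResult:
    """Two-group comparison with the Shapiro-Wilk normality gate.

    Both samples normal at ``alpha`` -> two-sided t-test (paired or
    independent); otherwise the rank-based fallback (Mann-Whitney, or the
    Wilcoxon signed-rank test when paired).  The route taken is recorded.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError(
            "Shapiro-Wilk normality gate needs n >= 3 per group "
            f"(got {x.size}, {y.size})"
        )
    if paired and x.size != y.size:
        raise ValueError("paired comparison requires equal sample sizes")
    ok_x, p_x = _shapiro_ok(x, alpha)
    ok_y, p_y = _shapiro_ok(y, alpha)
    normal = ok_x and ok_y
    details = {"shapiro_p": (p_x, p_y), "paired": paired}
    if normal:
        if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
            # degenerate: identical constants compare equal with certainty
            stat = 0.0 if x.mean() == y.mean() else float("inf")
            p = 1.0 if x.mean() == y.mean() else 0.0
            name = TestName.T_PAIRED if paired else TestName.T_TWO_SIDED
            return TestResult(name, stat, p, (x.size, y.size), True, details)
        if paired:
            res = stats.ttest_rel(x, y)
            name = TestName.T_PAIRED
        else:
            res = stats.ttest_ind(x, y)
            name = TestName.T_TWO_SIDED
        return TestResult(
            name, float(res.statistic), float(res.pvalue), (x.size, y.size), True, details
        )
    if paired:
        res = stats.wilcoxon(x, y)
        name = TestName.WILCOXON
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = TestName.MANN_WHITNEY
    return TestResult(
        name, float(res.statistic), float(res.pvalue), (x.size, y.size), False, details
    )


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment; monotone in the raw p-values."""
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running_max = max(running_max, val)
        adj[idx] = min(running_max, 1.0)
    return adj


def anova_holm_sidak(groups, labels=None, alpha: float = 0.05) -> list[TestResult]:
    """One-way ANOVA followed by Holm-Sidak-adjusted pairwise t-tests.

    Returns the omnibus result first, then one TestResult per pair with the
    adjusted p-value (raw p in ``details``).
    """
    samples = [np.asarray(list(g), dtype=float) for g in groups]
    if len(samples) < 3:
        raise ValueError("need >= 3 groups; use compare_groups for two")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(samples))]
    f_res = stats.f_oneway(*samples)
    results = [
        TestResult(
            TestName.ANOVA,
            float(f_res.statistic),
            float(f_res.pvalue),
            tuple(s.size for s in samples),
        )
    ]
    pairs = [
        (i, j) for i in range(len(samples)) for j in range(i + 1, len(samples))
    ]
    raw = []
    stats_ = []
    for i, j in pairs:
        r = stats.ttest_ind(samples[i], samples[j])
        raw.append(float(r.pvalue))
        stats_.append(float(r.statistic))
    adj = holm_sidak_adjust(raw)
    for (i, j), t, p_raw, p_adj in zip(pairs, stats_, raw, adj):
        results.append(
            TestResult(
                TestName.HOLM_SIDAK_PAIRWISE,
                t,
                float(p_adj),
                (samples[i].size, samples[j].size),
                details={
                    "pair": (labels[i], labels[j]),
                    "p_raw": p_raw,
                    "reject": bool(p_adj <= alpha),
                },
            )
        )
    return results


def observed_power_t(a, b, alpha: float = 0.05) -> float:
    """Post-hoc observed power for a two-sample t-test (reported for parity
    with the study; never used for inference)."""
    from statsmodels.stats.power import TTestIndPower

    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    sp = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    if sp == 0:
        return 1.0
    d = abs(x.mean() - y.mean()) / sp
    return float(
        TTestIndPower().power(
            effect_size=d, nobs1=x.size, ratio=y.size / x.size, alpha=alpha
        )
    )


def iop_elevation_summary(
    df: pd.DataFrame, decimals: int = 1
) -> pd.DataFrame:
    """Per-group per-eye post-injection summary (days >= 1): animal means,
    then group mean +/- SEM, plus the microbead-vs-saline percent elevation.

    ``df`` is long-format with columns animal_id, eye, day, iop_mmHg and an
    optional group column.  Animals missing an eye are flagged in the output
    (excluded from the elevation figure); single-animal groups carry an
    undefined (NaN) SEM.
    """
    required = {"animal_id", "eye", "day", "iop_mmHg"}
    if not required <= set(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    post = df[df["day"] >= 1]
    if post.empty:
        raise ValueError("no post-injection records (day >= 1)")
    if "group" not in post.columns:
        post = post.assign(group="ALL")
    animal_means = (
        post.groupby(["group", "animal_id", "eye"], sort=True)["iop_mmHg"]
        .mean()
        .reset_index()
    )
    rows = []
    for group, sub in animal_means.groupby("group", sort=True):
        eyes = {}
        flagged = []
        for eye in (Eye.SALINE.value, Eye.MICROBEAD.value):
            vals = sub.loc[sub["eye"] == eye, "iop_mmHg"].to_numpy()
            eyes[eye] = vals
        per_eye_animals = {
            eye: set(sub.loc[sub["eye"] == eye, "animal_id"]) for eye in eyes
        }
        both = per_eye_animals[Eye.SALINE.value] & per_eye_animals[Eye.MICROBEAD.value]
        flagged = sorted(
            (per_eye_animals[Eye.SALINE.value] ^ per_eye_animals[Eye.MICROBEAD.value])
        )
        for eye, vals in eyes.items():
            n = vals.size
            rows.append(
                {
                    "group": group,
                    "eye": eye,
                    "n": n,
                    "mean_mmHg": float(vals.mean()) if n else float("nan"),
                    "sem_mmHg": float(vals.std(ddof=1) / np.sqrt(n))
                    if n > 1
                    else float("nan"),
                    "flagged_animals": ";".join(flagged),
                }
            )
        sal = eyes[Eye.SALINE.value]
        mb = eyes[Eye.MICROBEAD.value]
        elev = (
            percent_change(float(sal.mean()), float(mb.mean()), decimals=decimals)
            if sal.size and mb.size
            else float("nan")
        )
        rows.append(
            {
                "group": group,
                "eye": "ELEVATION_%",
                "n": len(both),
                "mean_mmHg": elev,
                "sem_mmHg": float("nan"),
                "flagged_animals": ";".join(flagged),
            }
        )
    return pd.DataFrame(rows)
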