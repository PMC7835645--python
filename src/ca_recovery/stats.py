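"""Outcome statistics: survival curves and group comparisons.

Covers every procedure the analysis pipeline needs:

* Kaplan-Meier product-limit estimate and the Mantel-Cox log-rank test,
  implemented from first principles (observed-vs-expected accumulation
  over risk sets, hypergeometric variance for ties);
* Welch's unequal-variance t test and the Mann-Whitney U test (exact null
  distribution for small tie-free samples, midrank/tie-corrected normal
  approximation otherwise);
* a Kolmogorov-Smirnov normality gate (Lilliefors correction by default,
  since location and scale are estimated from the sample);
* two-way mixed-design repeated-measures ANOVA (between-subject group x
  within-subject timepoint) with Sidak-adjusted post hoc comparisons.

Every test returns a :class:`TestResult` that serializes losslessly to
JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "SurvivalDataset",
    "TestResult",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "welch_t",
    "mann_whitney_u",
    "ks_normality",
    "rm_anova_two_way",
    "sidak_posthoc",
    "SidakResult",
]


@dataclass
class SurvivalDataset:
    """Per-animal survival records: time (h), event flag, group label.

    ``event`` is True for a death and False for censoring.  A death
    occurring exactly at the censoring horizon is still an event.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.group = np.asarray(self.group, dtype=object)
        if not (self.time.shape == self.event.shape == self.group.shape):
            raise ValueError("time/event/group must have identical shapes")
        if self.time.size == 0:
            raise ValueError("survival dataset is empty")
        if (self.time < 0).any():
            raise ValueError("times must be non-negative")

    @property
    def groups(self) -> list:
        return sorted(set(self.group.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": [f"a{i}" for i in range(self.time.size)],
             "group": self.group, "time_h": self.time,
             "event": self.event.astype(int)}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalDataset":
        return cls(
            time=frame["time_h"].to_numpy(dtype=float),
            event=frame["event"].to_numpy(dtype=bool),
            group=frame["group"].to_numpy(dtype=object),
        )


@dataclass
class TestResult:
    """A named statistic with df, p value and procedure metadata."""

    __test__ = False  # not a pytest collectable despite the name

    name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    direction: str | None = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p value must lie in [0, 1]")

    def to_json(self) -> str:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "direction": self.direction,
            "metadata": _jsonable(self.metadata),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TestResult":
        d = json.loads(text)
        df = d["df"]
        if isinstance(df, list):
            df = tuple(df)
        return cls(
            name=d["name"],
            statistic=d["statistic"],
            p_value=d["p_value"],
            df=df,
            direction=d["direction"],
            metadata=d["metadata"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


@dataclass
class KMCurve:
    """Right-continuous product-limit survival step function."""

    times: np.ndarray       # distinct event times
    survival: np.ndarray    # S(t) just after each event time
    n_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(data: SurvivalDataset) -> dict:
    """Kaplan-Meier product-limit estimate per group.

    S starts at 1, is non-increasing and drops only at event times:
    S(t) = prod_{t_i <= t} (1 - d_i / n_i).
    """
    out: dict = {}
    for g in data.groups:
        sel = data.group == g
        t, e = data.time[sel], data.event[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        event_times = np.unique(t[e])
        surv, n_risk, n_ev = [], [], []
        s = 1.0
        for et in event_times:
            n = int((t >= et).sum())
            d = int(((t == et) & e).sum())
            s *= 1.0 - d / n
            surv.append(s)
            n_risk.append(n)
            n_ev.append(d)
        out[g] = KMCurve(
            times=event_times,
            survival=np.asarray(surv),
            n_risk=np.asarray(n_risk),
            n_events=np.asarray(n_ev),
        )
    return out


def logrank_test(data: SurvivalDataset) -> TestResult:
    """Two-group Mantel-Cox log-rank test.

    Accumulates observed and expected events for group 1 over the distinct
    event times, with the hypergeometric variance handling ties:
    chi2 = (O1 - E1)^2 / V on 1 df.  Censoring at an event time keeps the
    censored subject in that time's risk set (standard convention:
    censored after events at equal times).
    """
    groups = data.groups
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups}")
    g1 = groups[0]
    t, e = data.time, data.event
    in1 = data.group == g1
    event_times = np.unique(t[e])
    if event_times.size == 0:
        raise ValueError("no events in either group: log-rank statistic undefined")
    O1 = E1 = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        dmask = (t == et) & e
        d = int(dmask.sum())
        d1 = int((dmask & in1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    if V <= 0:
        raise ValueError("log-rank variance is zero: statistic undefined")
    chi2 = (O1 - E1) ** 2 / V
    p = float(sst.chi2.sf(chi2, df=1))
    direction = "more_events" if O1 > E1 else ("fewer_events" if O1 < E1 else "equal")
    return TestResult(
        name="logrank_mantel_cox",
        statistic=float(chi2),
        p_value=p,
        df=1,
        direction=f"{g1}:{direction}",
        metadata={
            "groups": groups,
            "observed_group1": O1,
            "expected_group1": E1,
            "variance": V,
        },
    )


def welch_t(x, y, labels: tuple[str, str] = ("group1", "group2")) -> TestResult:
    """Unpaired t test with Welch's correction (unequal variances).

    t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y), with the
    Welch-Satterthwaite df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t test needs >= 2 observations per group")
    res = sst.ttest_ind(x, y, equal_var=False)
    diff = float(x.mean() - y.mean())
    direction = (
        f"{labels[0]}:" + ("higher" if diff > 0 else "lower" if diff < 0 else "equal")
    )
    return TestResult(
        name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        direction=direction,
        metadata={
            "labels": list(labels),
            "mean_diff": diff,
            "n": [int(x.size), int(y.size)],
        },
    )


def mann_whitney_u(x, y, labels: tuple[str, str] = ("group1", "group2")) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The exact null distribution is used when the combined sample size is
    <= 20 and there are no ties; otherwise the normal approximation with
    tie correction.  The reported statistic is U for the first group; U2
    and the method used are in the metadata.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= 20 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return TestResult(
        name="mann_whitney_u",
        statistic=u1,
        p_value=float(res.pvalue),
        df=None,
        direction=f"{labels[0]}:" + ("higher" if u1 > u2 else "lower" if u1 < u2 else "equal"),
        metadata={
            "labels": list(labels),
            "U1": u1,
            "U2": u2,
            "method": method,
            "ties_present": bool(has_ties),
        },
    )


def ks_normality(values, alpha: float = 0.05, variant: str = "lilliefors") -> TestResult:
    """Normality gate via the Kolmogorov-Smirnov statistic.

    ``variant='lilliefors'`` (default) corrects the null distribution for
    mean and SD estimated from the sample; ``variant='plain'`` compares
    against a fixed normal with the sample moments (anti-conservative,
    provided for parity with naive usage).  The gate decision
    (``metadata['gate_passes']``) is p >= alpha.  Constant or tiny samples
    are degenerate: the gate fails with an explicit flag.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4 or np.std(v) == 0:
        return TestResult(
            name=f"ks_normality_{variant}",
            statistic=float("nan"),
            p_value=0.0,
            df=None,
            metadata={"gate_passes": False, "degenerate": True, "n": int(v.size)},
        )
    if variant == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(v, dist="norm", pvalmethod="table")
    elif variant == "plain":
        stat, p = sst.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    else:
        raise ValueError("variant must be 'lilliefors' or 'plain'")
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(
        name=f"ks_normality_{variant}",
        statistic=float(stat),
        p_value=p,
        df=None,
        metadata={
            "gate_passes": bool(p >= alpha),
            "degenerate": False,
            "alpha": alpha,
            "n": int(v.size),
        },
    )


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "timepoint",
    between: str = "group",
    subject: str = "animal",
) -> dict[str, TestResult]:
    """Two-way mixed-design repeated-measures ANOVA.

    Between-subject factor ``between`` (e.g. diet group) x within-subject
    factor ``within`` (e.g. timepoint), keyed by ``subject``.  Subjects
    missing any within level are excluded listwise (recorded in the
    metadata); no sphericity correction is applied by default (a 2-level
    within factor is unaffected).  Returns TestResults keyed "group",
    "time" and "interaction".
    """
    df = data[[subject, between, within, dv]].dropna()
    levels = sorted(df[within].unique())
    if len(levels) < 2 or df[between].nunique() < 2:
        raise ValueError("need >= 2 levels of both factors")
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == len(levels)].index
    excluded = sorted(set(df[subject]) - set(complete))
    df = df[df[subject].isin(complete)]
    if df[between].nunique() < 2:
        raise ValueError("listwise exclusion left fewer than 2 groups")

    if df.groupby([between, within])[dv].var(ddof=1).fillna(0).max() == 0:
        flag = {"degenerate": True, "excluded_subjects": excluded}
        return {
            k: TestResult(
                name=f"rm_anova_{k}", statistic=float("nan"), p_value=1.0,
                df=None, metadata=flag,
            )
            for k in ("group", "time", "interaction")
        }

    import pingouin as pg

    aov = pg.mixed_anova(
        data=df, dv=dv, within=within, subject=subject, between=between
    )
    aov = aov.set_index("Source")
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    mapping = {"group": between, "time": within, "interaction": "Interaction"}
    out: dict[str, TestResult] = {}
    for key, source in mapping.items():
        row = aov.loc[source]
        out[key] = TestResult(
            name=f"rm_anova_{key}",
            statistic=float(row["F"]),
            p_value=float(row[pcol]),
            df=(float(row["DF1"]), float(row["DF2"])),
            metadata={
                "excluded_subjects": excluded,
                "n_subjects": int(df[subject].nunique()),
                "df_convention": "listwise-complete mixed ANOVA",
            },
        )
    return out


@dataclass
class SidakResult:
    alpha: float
    m: int
    alpha_adjusted: float
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray


def sidak_posthoc(p_values, alpha: float = 0.05, m: int | None = None) -> SidakResult:
    """Sidak multiple-comparison adjustment for a family of m comparisons.

    alpha' = 1 - (1 - alpha)^(1/m); adjusted p = 1 - (1 - p)^m, clipped to
    [0, 1].  Adjusted p values are never smaller than the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    fam = int(m) if m is not None else p.size
    if fam < 1:
        raise ValueError("family size must be >= 1")
    alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / fam)
    p_adj = np.clip(1.0 - (1.0 - p) ** fam, 0.0, 1.0)
    return SidakResult(
        alpha=alpha,
        m=fam,
        alpha_adjusted=float(alpha_adj),
        p_raw=p,
        p_adjusted=p_adj,
        reject=p_adj <= alpha,
    )
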