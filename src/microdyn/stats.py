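"""Test selection, hypothesis testing and power analysis for cell-level
metrics.

Two-group comparisons follow a fixed decision tree: normality of each group is
assessed with both Shapiro-Wilk and Anderson-Darling tests (a group counts as
normal only if both pass at α = 0.05); when both groups are normal, a
two-sided F test decides between Student's t (equal variances) and Welch's t,
while any normality failure routes to the Mann-Whitney U test (independent
samples) or the Wilcoxon signed-rank test (paired samples).  Multi-group
comparisons route analogously to one-way ANOVA + Tukey, Welch's ANOVA +
Games-Howell, or Kruskal-Wallis + Dunn.  Sample-size planning uses the
noncentral-t formulation of the two-sided two-sample t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as ss
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA_BRANCH = 0.05  # level for the normality and variance pre-tests


@dataclass
class SampleGroup:
    """One group of real-valued per-cell measurements."""

    values: np.ndarray
    label: str = ""
    pairing_key: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) < 2:
            raise ValueError(f"group {self.label!r}: need at least 2 values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestDecision:
    """Outcome of the decision tree: the chosen test plus the full branch trace."""

    test_name: str
    statistic: float
    p_value: float
    branch_trace: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "branch_trace": self.branch_trace,
        }
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.to_dict(orient="records")
        return out


def _is_normal(values: np.ndarray) -> tuple[bool, dict]:
    """Normality = Shapiro-Wilk AND Anderson-Darling both pass at 0.05."""
    if len(values) < 3:
        raise ValueError("normality testing requires n >= 3")
    sw_stat, sw_p = ss.shapiro(values)
    ad_stat, ad_p = normal_ad(np.asarray(values, dtype=float))
    passed = (sw_p >= ALPHA_BRANCH) and (ad_p >= ALPHA_BRANCH)
    return passed, {
        "shapiro_p": float(sw_p),
        "anderson_darling_p": float(ad_p),
        "normal": bool(passed),
    }


def _f_test_equal_var(a: np.ndarray, b: np.ndarray) -> tuple[bool, dict]:
    """Two-sided F test for equality of variances at 0.05."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(ss.f.cdf(f, dfa, dfb), ss.f.sf(f, dfa, dfb))
    p = min(p, 1.0)
    equal = p >= ALPHA_BRANCH
    return equal, {"f_statistic": float(f), "f_p": float(p), "equal_variances": bool(equal)}


def decide_and_test(group_a: SampleGroup, group_b: SampleGroup, paired: bool = False) -> TestDecision:
    """Compare two groups via the normality → variance decision tree.

    Both groups normal → F test → Student's t (equal variances) or Welch's t;
    any normality failure → Mann-Whitney U (independent) or Wilcoxon
    signed-rank (paired).  Paired normal data use the paired t test (a
    variance pre-test is meaningless for differences); this is recorded in the
    branch trace.  All tests are two-sided.
    """
    a, b = group_a.values, group_b.values
    if paired and len(a) != len(b):
        raise ValueError("paired groups must have equal n")
    norm_a, trace_a = _is_normal(a)
    norm_b, trace_b = _is_normal(b)
    trace = {"group_a": trace_a, "group_b": trace_b, "paired": paired}

    if norm_a and norm_b:
        if paired:
            stat, p = ss.ttest_rel(a, b)
            name = "paired t"
            trace["variance_test"] = "skipped (paired design)"
        else:
            equal, vtrace = _f_test_equal_var(a, b)
            trace["variance_test"] = vtrace
            if equal:
                stat, p = ss.ttest_ind(a, b, equal_var=True)
                name = "Student's t"
            else:
                stat, p = ss.ttest_ind(a, b, equal_var=False)
                name = "Welch's t"
    else:
        if paired:
            stat, p = ss.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        else:
            stat, p = ss.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    trace["chosen_test"] = name
    return TestDecision(test_name=name, statistic=float(stat), p_value=float(p), branch_trace=trace)


def multi_group_test(groups: list[SampleGroup]) -> TestDecision:
    """Compare ≥3 independent groups.

    All groups normal and equal variances (Bartlett) → one-way ANOVA with
    Tukey's post hoc; all normal but unequal variances → Welch's ANOVA with
    Games-Howell; any normality failure → Kruskal-Wallis with Dunn's post hoc
    (Bonferroni-adjusted).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = [g.values for g in groups]
    labels = [g.label or f"group{i}" for i, g in enumerate(groups)]
    norm_flags, traces = zip(*(_is_normal(a) for a in arrays))
    trace: dict = {"normality": dict(zip(labels, traces))}

    if all(norm_flags):
        bart_stat, bart_p = ss.bartlett(*arrays)
        equal = bart_p >= ALPHA_BRANCH
        trace["variance_test"] = {"bartlett_statistic": float(bart_stat), "bartlett_p": float(bart_p), "equal_variances": bool(equal)}
        df = pd.DataFrame(
            {"value": np.concatenate(arrays), "group": np.repeat(labels, [len(a) for a in arrays])}
        )
        if equal:
            stat, p = ss.f_oneway(*arrays)
            tk = pairwise_tukeyhsd(df["value"], df["group"], alpha=0.05)
            posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            name = "one-way ANOVA + Tukey"
        else:
            aov = pg.welch_anova(data=df, dv="value", between="group")
            stat, p = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])
            posthoc = pg.pairwise_gameshowell(data=df, dv="value", between="group")
            name = "Welch's ANOVA + Games-Howell"
    else:
        stat, p = ss.kruskal(*arrays)
        posthoc = dunn_posthoc(arrays, labels)
        name = "Kruskal-Wallis + Dunn"
    trace["chosen_test"] = name
    return TestDecision(test_name=name, statistic=float(stat), p_value=float(p), branch_trace=trace, posthoc=posthoc)


def dunn_posthoc(arrays: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc with Bonferroni adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt(V·(1/n_i + 1/n_j)) on joint ranks, with the
    standard tie correction V = (N(N+1)/12) · (1 − Σ(t³−t)/(N³−N)).
    """
    all_vals = np.concatenate(arrays)
    n_total = len(all_vals)
    ranks = ss.rankdata(all_vals)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total) if n_total > 1 else 0.0
    variance = n_total * (n_total + 1) / 12.0 * (1.0 - tie_term)
    mean_ranks, ns = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        ns.append(len(a))
        start += len(a)
    m = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(variance * (1 / ns[i] + 1 / ns[j]))
        p = 2 * ss.norm.sf(abs(z))
        rows.append(
            {"A": labels[i], "B": labels[j], "z": float(z), "p_unc": float(p), "p_adj": float(min(1.0, p * m))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power / sample size
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """Design parameters for a two-sample t-test sample-size calculation.

    ``effect_percent`` is the between-group difference as a percentage of the
    control mean; ``sd`` is on the same scale as the control mean, so the
    standardized effect is d = (effect_percent/100·control_mean)/sd.
    """

    control_mean: float = 100.0
    sd: float = 25.0
    effect_percent: float = 50.0
    alpha: float = 0.05
    power: float = 0.80
    sides: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")

    @property
    def cohens_d(self) -> float:
        return abs(self.effect_percent / 100.0 * self.control_mean) / self.sd


def achieved_power(n: int, d: float, alpha: float = 0.05, sides: int = 2) -> float:
    """Power of the two-sample t-test with ``n`` per group at standardized
    effect ``d``, via the noncentral t with df = 2n−2 and noncentrality
    d·√(n/2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    if sides == 2:
        tcrit = ss.t.ppf(1 - alpha / 2, df)
        return float(ss.nct.sf(tcrit, df, nc) + ss.nct.cdf(-tcrit, df, nc))
    tcrit = ss.t.ppf(1 - alpha, df)
    return float(ss.nct.sf(tcrit, df, nc))


def sample_size_two_sample_t(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest per-group n whose achieved power meets the target.

    With the standard planning defaults (control 100%, SD 25%, 50% effect,
    80% power, α = 0.05 two-sided) this returns six cells per group.
    """
    if spec.effect_percent == 0:
        raise ValueError("effect size must be non-zero")
    d = spec.cohens_d
    n = 2
    while n <= max_n:
        if achieved_power(n, d, spec.alpha, spec.sides) >= spec.power:
            return n
        n += 1
    raise ValueError(f"target power not reachable with n <= {max_n}")
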