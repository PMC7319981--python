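"""Clinical and immunohistochemistry comparison statistics.

Wilcoxon-Mann-Whitney tests for continuous comparisons, Fisher exact tests
for categorical ones, Kaplan-Meier curves with log-rank tests for survival,
two-reader IHC score averaging, and a grouped summary table in the style of
a clinical "Table 1". All tests are two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GROUPS = ("FA", "LGP", "HGP")
MARKERS = ("Ki67", "p53", "beta_catenin", "E_cadherin")


@dataclass
class ClinicalRecord:
    """Per-patient outcome record.

    ``time_to_event`` is the event time for recurrences/deaths and the
    censoring time (last follow-up) otherwise; it can never exceed the
    follow-up time.
    """

    case_id: str
    group: str
    age: float
    tumor_size: float
    followup_months: float | None
    recurrence: bool
    death_from_disease: bool
    time_to_event: float | None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.followup_months is not None and self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if (
            self.time_to_event is not None
            and self.followup_months is not None
            and self.time_to_event > self.followup_months + 1e-9
        ):
            raise ValueError("time_to_event cannot exceed followup_months")
        if (self.recurrence or self.death_from_disease) and self.time_to_event is None:
            raise ValueError("events require a recorded time_to_event")

    @property
    def has_event(self) -> bool:
        return self.recurrence or self.death_from_disease


@dataclass
class IHCRecord:
    """Two-reader IHC percent positivity; the analysis value is the average
    of the two readers' estimates."""

    case_id: str
    group: str
    marker: str
    reader1_pct: float
    reader2_pct: float
    mean_pct: float = field(init=False)

    def __post_init__(self) -> None:
        for v in (self.reader1_pct, self.reader2_pct):
            if not (0 <= v <= 100):
                raise ValueError("reader percentages must lie in [0, 100]")
        self.mean_pct = (self.reader1_pct + self.reader2_pct) / 2.0


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate: a right-continuous step function that
    starts at 1 and drops only at event times."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12) or np.any(self.survival < 0) or self.survival[0] > 1:
            raise ValueError("survival must be non-increasing within [0, 1]")


def wmw_test(x, y):
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U, p).

    U is the statistic for ``x`` (number of (x, y) pairs with x > y, ties
    counted half). The p-value is exact when min(n) <= 8 and there are no
    ties, and otherwise uses the normal approximation with tie and continuity
    corrections. Fully degenerate input (every value identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table):
    """Two-sided Fisher exact test on a 2x2 count table; returns (OR, p, flags).

    The p-value is the conditional hypergeometric "probability at most
    observed" sum. The odds ratio is the sample OR, with 0.5 added to every
    cell when any cell is zero (continuity applied to the OR only, never to
    the p-value). A zero margin gives p = 1 with the OR flagged undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    flags = []
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return float("nan"), 1.0, ("zero_margin", "or_undefined")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    if np.any(t == 0):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        flags.append("or_continuity_corrected")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), tuple(flags)


def km_curve(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve.

    Ties between an event and a censoring at the same time follow the
    standard convention: the event is processed first (the censored subject
    counts as at risk at that time). Censoring decrements the risk set
    without a drop in survival. The curve starts at (0, 1).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if len(times) == 0:
        raise ValueError("km_curve needs at least one subject")
    if len(times) != len(flags) or np.any(times < 0):
        raise ValueError("times and event_flags must match, with times >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=flags)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    out_times, out_surv, out_risk = [], [], []
    for t in table.index:
        if table.loc[t, "observed"] > 0:
            out_times.append(float(t))
            out_surv.append(float(sf.loc[t]))
            out_risk.append(int(table.loc[t, "at_risk"]))
    if not out_times or out_times[0] > 0.0:
        out_times.insert(0, 0.0)
        out_surv.insert(0, 1.0)
        out_risk.insert(0, len(times))
    return SurvivalCurve(
        times=np.array(out_times),
        survival=np.array(out_surv),
        n_at_risk=np.array(out_risk),
    )


def logrank_test(group_a, group_b):
    """Two-group log-rank test; returns (chi2, p) with 1 degree of freedom.

    ``group_a`` and ``group_b`` are (times, event_flags) pairs. With no
    events in either group the test is vacuous: chi2 = 0, p = 1.
    """
    from lifelines.statistics import logrank_test as _lr

    (ta, fa), (tb, fb) = group_a, group_b
    ta, fa = np.asarray(ta, float), np.asarray(fa, bool)
    tb, fb = np.asarray(tb, float), np.asarray(fb, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if fa.sum() + fb.sum() == 0:
        return 0.0, 1.0
    res = _lr(ta, tb, event_observed_A=fa, event_observed_B=fb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        return 0.0, 1.0
    return chi2, p


def proportion_pct(numerator: int, denominator: int) -> float:
    """A count proportion as a percentage, rounded to one decimal — the
    convention used for reporting rates like recurrence or re-excision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def _pairwise_wmw(values_by_group: dict) -> dict:
    out = {}
    names = [g for g in GROUPS if g in values_by_group]
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            v1, v2 = values_by_group[g1], values_by_group[g2]
            if len(v1) == 0 or len(v2) == 0:
                out[f"{g1}_vs_{g2}"] = None
                continue
            _, p = wmw_test(v1, v2)
            out[f"{g1}_vs_{g2}"] = p
    return out


def summarize_groups(clinical: list, ihc: list) -> dict:
    """Grouped clinical + IHC summary in the style of a clinical Table 1.

    Per group and marker: mean / median / range of the two-reader average
    positivity, with pairwise WMW p-values across groups (degenerate all-equal
    markers, e.g. uniformly negative stromal E-cadherin, render p = 1 rather
    than failing). Clinical age / tumor size comparisons and the
    disease-free Kaplan-Meier / log-rank comparison cover the FA and LGP
    groups when both are present.
    """
    report: dict = {"ihc": {}, "clinical": {}}

    by_marker: dict[str, dict] = {}
    for rec in ihc:
        by_marker.setdefault(rec.marker, {}).setdefault(rec.group, []).append(rec.mean_pct)
    for marker, groups in by_marker.items():
        cells = {}
        for g, vals in groups.items():
            arr = np.asarray(vals)
            cells[g] = {
                "n": len(arr),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
                "range": (float(arr.min()), float(arr.max())),
            }
        for g in GROUPS:
            if g not in cells:
                cells[g] = "unavailable"
        entry = {"groups": cells}
        if sum(isinstance(v, dict) for v in cells.values()) >= 2:
            entry["p_values"] = _pairwise_wmw(groups)
        report["ihc"][marker] = entry

    by_group: dict[str, list] = {}
    for rec in clinical:
        by_group.setdefault(rec.group, []).append(rec)
    for g, recs in by_group.items():
        ages = np.array([r.age for r in recs])
        sizes = np.array([r.tumor_size for r in recs])
        report["clinical"][g] = {
            "n": len(recs),
            "age": {"mean": float(ages.mean()), "median": float(np.median(ages)),
                    "range": (float(ages.min()), float(ages.max()))},
            "tumor_size": {"mean": float(sizes.mean()), "median": float(np.median(sizes)),
                           "range": (float(sizes.min()), float(sizes.max()))},
            "n_recurrence": int(sum(r.recurrence for r in recs)),
            "recurrence_pct": proportion_pct(sum(r.recurrence for r in recs), len(recs)),
        }
    if "FA" in by_group and "LGP" in by_group:
        fa, lgp = by_group["FA"], by_group["LGP"]
        _, p_age = wmw_test([r.age for r in lgp], [r.age for r in fa])
        _, p_size = wmw_test([r.tumor_size for r in lgp], [r.tumor_size for r in fa])
        report["clinical"]["comparisons"] = {"age_p": p_age, "tumor_size_p": p_size}
        with_fu = [r for r in fa + lgp if r.time_to_event is not None]
        fa_fu = [(r.time_to_event, r.has_event) for r in with_fu if r.group == "FA"]
        lgp_fu = [(r.time_to_event, r.has_event) for r in with_fu if r.group == "LGP"]
        if fa_fu and lgp_fu:
            fa_t, fa_e = zip(*fa_fu)
            lgp_t, lgp_e = zip(*lgp_fu)
            chi2, p_lr = logrank_test((fa_t, fa_e), (lgp_t, lgp_e))
            report["clinical"]["disease_free_survival"] = {
                "logrank_chi2": chi2,
                "logrank_p": p_lr,
                "km_FA": km_curve(fa_t, fa_e),
                "km_LGP": km_curve(lgp_t, lgp_e),
            }
    return report


def km_plot(curves: dict, path) -> None:
    """Write a step plot of one or more labeled SurvivalCurves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
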