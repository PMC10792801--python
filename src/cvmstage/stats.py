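"""Cohort statistics: normality triage, three-group comparisons, letters, ICC.

Reproduces the analysis pipeline used to characterise the maturational
stages: each outcome is triaged for normality (Shapiro–Wilk and a
Kolmogorov–Smirnov test with estimated parameters, i.e. Lilliefors, per
group; one rejection at alpha routes the outcome non-parametrically),
then compared across the three stages with either

* one-way ANOVA + Bonferroni-adjusted pairwise t tests (pooled error
  term), effect size eta² = SS_between / SS_total; or
* Kruskal–Wallis + Dunn's z tests with Bonferroni adjustment, effect
  size via the H-based approximation eta²_H = (H − k + 1) / (n − k).

Pairwise significance is condensed into a compact letter display
(A = highest location; stages sharing a letter do not differ) by the
standard insert-and-absorb sweep.  Bonferroni correction spans the three
pairwise comparisons within an outcome only — no cross-outcome
correction is applied, matching the source protocol.

Reliability uses the intraclass correlation coefficient in single-rater
two-way forms: absolute agreement ICC(2,1) (default — the conventional
model for inter-observer agreement across a fixed panel) and consistency
ICC(3,1), both with 95% CIs by the F-distribution method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .landmarks import STAGES
from .measures import OUTCOMES

__all__ = [
    "OutcomeComparison",
    "ComparisonReport",
    "ICCResult",
    "normality_triage",
    "compare_three_groups",
    "compare_cohort",
    "letter_grouping",
    "icc",
]

_ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality triage


def normality_triage(groups: Mapping[str, Sequence[float]], alpha: float = _ALPHA) -> str:
    """Route an outcome: ``"parametric"`` or ``"non-parametric"``.

    Non-parametric when Shapiro–Wilk or Lilliefors rejects at ``alpha``
    in *any* group (the conservative OR reading), or when a group is
    degenerate (constant values, e.g. the flat pre-pubertal inferior
    border producing a point mass at 0).
    """
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            raise ValueError(f"group {name!r} has {x.size} values; need >= 3")
        if np.ptp(x) < 1e-12:
            return "non-parametric"
        if sps.shapiro(x).pvalue < alpha:
            return "non-parametric"
        if x.size >= 4 and lilliefors(x, dist="norm")[1] < alpha:
            return "non-parametric"
    return "parametric"


# ---------------------------------------------------------------------------
# compact letter display


def letter_grouping(
    locations: Mapping[str, float],
    significant: Mapping[frozenset, bool],
) -> dict[str, str]:
    """Compact letter display from locations and pairwise significance.

    Groups are ranked by location descending; the group with the largest
    location receives 'A'.  Non-significant pairs share a letter.  Uses
    the insert-and-absorb sweep, which resolves non-transitive
    significance chains without error.
    """
    order = sorted(locations, key=lambda g: -locations[g])  # stable: ties keep input order
    columns: list[set] = [set(order)]
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            if not significant.get(frozenset((gi, gj)), False):
                continue
            new_cols: list[set] = []
            for col in columns:
                if gi in col and gj in col:
                    new_cols.append(col - {gi})
                    new_cols.append(col - {gj})
                else:
                    new_cols.append(col)
            # absorb: drop empties, duplicates and strict subsets
            columns = []
            for col in new_cols:
                if not col or any(col < other for other in new_cols):
                    continue
                if col not in columns:
                    columns.append(col)
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "ABCDEFGH"
    return {
        g: "".join(alphabet[k] for k, col in enumerate(columns) if g in col)
        for g in locations
    }


# ---------------------------------------------------------------------------
# three-group comparison


@dataclass(frozen=True)
class OutcomeComparison:
    """The comparison summary for one outcome across the three stages."""

    test_used: str                      #: "anova" or "kruskal-wallis"
    statistic: float                    #: F or H
    p_value: float
    effect_size: float                  #: eta squared (or its H-based analogue)
    descriptives: Mapping[str, Mapping[str, float]]  #: per-stage cells
    letters: Mapping[str, str]
    pairwise: pd.DataFrame              #: columns a, b, statistic, p_adj, significant

    def cell(self, stage: str) -> str:
        """Render a per-stage cell the way the reference table prints it."""
        d = self.descriptives[stage]
        if "mean" in d:
            return f"{d['mean']:.2f} ({d['sd']:.2f}) {self.letters[stage]}"
        return f"{d['median']:g} ({d['min']:g}–{d['max']:g}) {self.letters[stage]}"


def _sum_of_squares(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    allx = np.concatenate(groups)
    grand = allx.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    sst = float(((allx - grand) ** 2).sum())
    return float(ssb), sst - float(ssb), sst


def _anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    k = len(groups)
    n = sum(len(g) for g in groups)
    ssb, ssw, sst = _sum_of_squares(groups)
    eta2 = ssb / sst if sst > 0 else 0.0
    if ssw <= 1e-300 * max(sst, 1.0):
        # zero within-group variance: F is unbounded unless the means agree too
        return (math.inf, 0.0, eta2) if ssb > 0 else (0.0, 1.0, eta2)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(sps.f.sf(f, k - 1, n - k))
    return f, p, eta2


def _bonferroni_t_pairs(
    names: Sequence[str], groups: Sequence[np.ndarray]
) -> pd.DataFrame:
    k = len(groups)
    n = sum(len(g) for g in groups)
    _, ssw, _ = _sum_of_squares(groups)
    df = n - k
    mse = ssw / df
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            if mse <= 0:
                t = math.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                se = math.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
                t = diff / se
                p = 2.0 * float(sps.t.sf(abs(t), df))
            p_adj = min(1.0, p * m)
            rows.append({"a": names[i], "b": names[j], "statistic": t,
                         "p_adj": p_adj, "significant": p_adj < _ALPHA})
    return pd.DataFrame(rows)


def _kruskal(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    allx = np.concatenate(groups)
    if np.ptp(allx) < 1e-12:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _dunn_pairs(names: Sequence[str], groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based z tests with tie correction, Bonferroni-adjusted."""
    sizes = [len(g) for g in groups]
    allx = np.concatenate(groups)
    n = allx.size
    ranks = sps.rankdata(allx)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(allx, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
                p = 2.0 * float(sps.norm.sf(abs(z)))
            p_adj = min(1.0, p * m)
            rows.append({"a": names[i], "b": names[j], "statistic": z,
                         "p_adj": p_adj, "significant": p_adj < _ALPHA})
    return pd.DataFrame(rows)


def compare_three_groups(
    groups: Mapping[str, Sequence[float]],
    route: str = "auto",
) -> OutcomeComparison:
    """Compare one outcome across three groups.

    ``route`` is ``"auto"`` (normality triage decides), ``"anova"`` or
    ``"kw"``.  Returns the omnibus test, eta-squared effect size,
    per-stage descriptive cells, Bonferroni-adjusted pairwise results
    and the compact letter display.
    """
    if len(groups) != 3:
        raise ValueError(f"expected exactly three groups, got {len(groups)}")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, x in zip(names, arrays):
        if x.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    if route == "auto":
        route = "anova" if normality_triage(groups) == "parametric" else "kw"
    if route not in ("anova", "kw"):
        raise ValueError(f"unknown route {route!r}")

    if route == "anova":
        stat, p, eta2 = _anova(arrays)
        pairwise = _bonferroni_t_pairs(names, arrays)
        locations = {g: float(x.mean()) for g, x in zip(names, arrays)}
        descr = {
            g: {"n": int(x.size), "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
            for g, x in zip(names, arrays)
        }
        test_used = "anova"
    else:
        stat, p = _kruskal(arrays)
        k = len(arrays)
        n = sum(x.size for x in arrays)
        eta2 = min(1.0, max(0.0, (stat - k + 1) / (n - k)))
        pairwise = _dunn_pairs(names, arrays)
        locations = {g: float(np.median(x)) for g, x in zip(names, arrays)}
        descr = {
            g: {"n": int(x.size), "median": float(np.median(x)),
                "min": float(x.min()), "max": float(x.max())}
            for g, x in zip(names, arrays)
        }
        test_used = "kruskal-wallis"

    significant = {
        frozenset((r.a, r.b)): bool(r.significant) for r in pairwise.itertuples()
    }
    letters = letter_grouping(locations, significant)
    return OutcomeComparison(
        test_used=test_used, statistic=stat, p_value=p, effect_size=eta2,
        descriptives=descr, letters=letters, pairwise=pairwise,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Per-outcome comparison results for a whole cohort."""

    outcomes: Mapping[str, OutcomeComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, comp in self.outcomes.items():
            row = {"outcome": key, "test": comp.test_used,
                   "statistic": comp.statistic, "p_value": comp.p_value,
                   "eta_squared": comp.effect_size}
            for stage in comp.descriptives:
                row[stage] = comp.cell(stage)
            rows.append(row)
        return pd.DataFrame(rows).set_index("outcome")

    def to_dict(self) -> dict:
        out = {}
        for key, comp in self.outcomes.items():
            out[key] = {
                "test": comp.test_used,
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "eta_squared": comp.effect_size,
                "stages": {s: dict(d) for s, d in comp.descriptives.items()},
                "letters": dict(comp.letters),
                "pairwise": comp.pairwise.to_dict(orient="records"),
            }
        return out


def compare_cohort(table: pd.DataFrame, route: str = "auto") -> ComparisonReport:
    """Run the three-stage comparison for every outcome in a long-format cohort.

    ``table`` columns: subject_id, stage, outcome, vertebra, value (the
    format produced by the synthetic generator and the CLI).
    """
    df = table.assign(key=lambda d: d["outcome"] + "_" + d["vertebra"].str.lower())
    results = {}
    for key in OUTCOMES:
        sub = df[df["key"] == key]
        if sub.empty:
            continue
        groups = {s: sub.loc[sub["stage"] == s, "value"].to_numpy() for s in STAGES}
        results[key] = compare_three_groups(groups, route=route)
    return ComparisonReport(outcomes=results)


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    """A single-rater ICC with its 95% confidence interval."""

    model: str
    value: float
    ci95: tuple[float, float]


def icc(ratings, model: str = "icc2_1", confidence: float = 0.95) -> ICCResult:
    """Intraclass correlation for a complete subjects x raters matrix.

    ``model`` is ``"icc2_1"`` (two-way random, absolute agreement,
    single rater — the default reliability index for agreement across a
    fixed rater panel) or ``"icc3_1"`` (two-way mixed, consistency).
    Confidence limits use the F-distribution method.
    """
    y = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        y = ratings.to_numpy(dtype=float)
    if y.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = y.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    if not np.isfinite(y).all():
        raise ValueError("ratings matrix is incomplete (missing values are not imputed)")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    alpha = 1.0 - confidence

    if model == "icc3_1":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse <= 0:
            lo, hi = 1.0, 1.0
        else:
            f = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse <= 0 and msc <= 0:
            lo, hi = 1.0, 1.0
        else:
            # Shrout & Fleiss F-based limits via the Satterthwaite df
            fj = msc / mse if mse > 0 else math.inf
            r = value
            vn = (k - 1) * (n - 1) * (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
            vd = (n - 1) * (k * r * fj) ** 2 + (n * (1 + (k - 1) * r) - k * r) ** 2
            v = vn / vd if vd > 0 else 1.0
            f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr
            )
    else:
        raise ValueError(f"unknown ICC model {model!r} (use 'icc2_1' or 'icc3_1')")

    lo = max(-1.0, min(lo, value))
    hi = min(1.0, max(hi, value))
    return ICCResult(model=model, value=float(value), ci95=(float(lo), float(hi)))
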