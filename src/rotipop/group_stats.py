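"""One-way ANOVA, post-hoc letter displays and nonparametric group tests.

The ANOVA layer exists twice on purpose: ``anova_oneway`` decomposes raw
replicate values, while ``anova_from_summary`` rebuilds the same table
from published group means with SE (or SD) and n — the form in which
culture experiments are usually reported.  Post-hoc multiple comparisons
(Student-Newman-Keuls, Duncan, Games-Howell) are rendered as compact
letter displays: groups sharing a letter are not significantly different.

Nonparametric companions: tie-corrected Kruskal-Wallis (with exact
enumeration for tiny samples) and the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import isfinite

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_oneway",
    "anova_from_summary",
    "posthoc_letters",
    "assumption_checks",
    "kruskal_wallis",
    "rank_sum",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean with dispersion (SE or SD) and n."""

    label: str
    mean: float
    dispersion: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2")
        if self.dispersion < 0:
            raise ValueError(f"group {self.label!r}: negative dispersion")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA decomposition (the machine twin of a printed table)."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within if self.df_within else np.nan

    def to_dict(self) -> dict:
        return {
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "ss_total": self.ss_total,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "ms_between": self.ms_between,
            "ms_within": self.ms_within,
            "F": self.F,
            "p": self.p,
        }


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(out):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    return out


def anova_oneway(groups) -> AnovaResult:
    """Standard one-way decomposition with p from the F distribution.

    Zero within-group variance with distinct means yields F = +inf, p = 0.
    """
    gs = _as_groups(groups)
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    ms_b = ss_between / df_b
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 0.0, df_b, df_w, 0.0, 1.0)
        return AnovaResult(ss_between, 0.0, df_b, df_w, float("inf"), 0.0)
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(ss_between, ss_within, df_b, df_w, float(F), p)


def anova_from_summary(summaries, se_mode: bool = True) -> AnovaResult:
    """Rebuild the one-way table from group means, dispersions and n.

    With ``se_mode=True`` the dispersion is a standard error and the group
    variance is ``n * SE^2``; otherwise it is a standard deviation.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    disp = np.array([s.dispersion for s in summaries], dtype=float)
    variances = ns * disp**2 if se_mode else disp**2
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * variances).sum())
    df_b = len(summaries) - 1
    df_w = int(ns.sum()) - len(summaries)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 0.0, df_b, df_w, 0.0, 1.0)
        return AnovaResult(ss_between, 0.0, df_b, df_w, float("inf"), 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(ss_between, ss_within, df_b, df_w, float(F), p)


def _pairwise_significance(gs, labels, method: str, alpha: float):
    """True/False significance per unordered label pair."""
    k = len(gs)
    means = np.array([g.mean() for g in gs])
    ns = np.array([g.size for g in gs], dtype=float)
    order = np.argsort(means)  # ascending
    sig: dict[frozenset, bool] = {}
    if method in ("snk", "duncan"):
        aov = anova_oneway(gs)
        ms_w, df_w = aov.ms_within, aov.df_within
        if not isfinite(ms_w) or ms_w == 0:
            # degenerate: any mean difference is significant
            for i, j in combinations(range(k), 2):
                sig[frozenset((labels[i], labels[j]))] = means[i] != means[j]
            return sig
        # step-down range ladder on ordered means; a pair inside a span
        # already declared non-significant is never declared significant
        nonsig_spans: list[tuple[int, int]] = []
        for span in range(k, 1, -1):
            for start in range(0, k - span + 1):
                end = start + span - 1
                if any(a <= start and end <= b for a, b in nonsig_spans):
                    nonsig_spans.append((start, end))
                    continue
                i, j = order[start], order[end]
                n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
                q = abs(means[j] - means[i]) / np.sqrt(ms_w / n_h)
                if method == "duncan":
                    a_eff = 1.0 - (1.0 - alpha) ** (span - 1)
                else:
                    a_eff = alpha
                q_crit = stats.studentized_range.ppf(1.0 - a_eff, span, df_w)
                if q <= q_crit:
                    nonsig_spans.append((start, end))
        for a, b in combinations(range(k), 2):
            pa, pb = int(np.where(order == a)[0][0]), int(np.where(order == b)[0][0])
            lo, hi = min(pa, pb), max(pa, pb)
            covered = any(s <= lo and hi <= e for s, e in nonsig_spans)
            sig[frozenset((labels[a], labels[b]))] = not covered
        return sig
    if method == "games-howell":
        variances = np.array([g.var(ddof=1) for g in gs])
        for i, j in combinations(range(k), 2):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            se = np.sqrt(vi + vj)
            if se == 0:
                sig[frozenset((labels[i], labels[j]))] = means[i] != means[j]
                continue
            df = (vi + vj) ** 2 / (vi**2 / (ns[i] - 1) + vj**2 / (ns[j] - 1))
            q = abs(means[i] - means[j]) / np.sqrt((vi + vj) / 2.0)
            q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df)
            sig[frozenset((labels[i], labels[j]))] = q > q_crit
        return sig
    raise ValueError(f"unknown post-hoc method: {method!r}")


def posthoc_letters(
    groups,
    method: str = "snk",
    alpha: float = 0.05,
    labels=None,
) -> dict[str, str]:
    """Compact letter display from a post-hoc multiple-comparison method.

    ``method`` is one of ``snk`` (Student-Newman-Keuls), ``duncan`` or
    ``games-howell``.  Groups sharing any letter are not significantly
    different at ``alpha``.  Letters are assigned by the insert-and-absorb
    algorithm so the display is transitive-consistent with the pairwise
    non-significance relation.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(gs))]
    labels = list(labels)
    sig = _pairwise_significance(gs, labels, method.lower().replace("_", "-"), alpha)
    # insert-and-absorb: start from one letter covering everything, split on
    # each significant pair, drop letter sets contained in others
    letter_sets: list[set[str]] = [set(labels)]
    for pair, is_sig in sorted(sig.items(), key=lambda kv: sorted(kv[0])):
        if not is_sig:
            continue
        a, b = sorted(pair)
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = [
            s
            for s in new_sets
            if s and not any(s < t for t in new_sets if t is not s)
        ]
        # dedupe
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    means = {lab: g.mean() for lab, g in zip(labels, gs)}
    letter_sets.sort(key=lambda s: -max(means[l] for l in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out


def assumption_checks(groups, center: str = "median") -> dict:
    """Normality (one-sample KS against the fitted normal) and Levene's test.

    ``center='median'`` gives the Brown-Forsythe variant of Levene's
    statistic (deviations from the group median); ``'mean'`` the classic
    form.  Constant data in every group yields a zero statistic with p = 1.
    """
    gs = _as_groups(groups)
    normality = []
    for g in gs:
        sd = g.std(ddof=1)
        if sd == 0:
            normality.append(np.nan)
        else:
            normality.append(float(stats.kstest(g, "norm", args=(g.mean(), sd)).pvalue))
    if all(g.std(ddof=1) == 0 for g in gs):
        return {"normality_p": normality, "levene_stat": 0.0, "levene_p": 1.0}
    stat, p = stats.levene(*gs, center=center)
    return {"normality_p": normality, "levene_stat": float(stat), "levene_p": float(p)}


def _kruskal_h(groups_flat: np.ndarray, sizes: list[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for pre-concatenated values."""
    n = groups_flat.size
    ranks = stats.rankdata(groups_flat)
    h = 0.0
    start = 0
    for sz in sizes:
        r = ranks[start : start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(groups_flat, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(groups, exact: str = "auto") -> dict:
    """Tie-corrected Kruskal-Wallis test across >= 2 groups.

    ``exact='auto'`` enumerates the permutation distribution of H when the
    total sample size is <= 10; otherwise (or with ``exact='never'``) the
    chi-square approximation is used.  All-identical data give H = 0, p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate(gs)
    sizes = [g.size for g in gs]
    if np.all(flat == flat[0]):
        return {"H": 0.0, "p": 1.0, "method": "degenerate"}
    n = flat.size
    h_obs = _kruskal_h(flat, sizes)
    if exact == "always" or (exact == "auto" and n <= 10):
        count = 0
        total = 0
        for perm in permutations(range(n)):
            h = _kruskal_h(flat[list(perm)], sizes)
            if h >= h_obs - 1e-12:
                count += 1
            total += 1
        return {"H": float(h_obs), "p": count / total, "method": "exact"}
    p = float(stats.chi2.sf(h_obs, len(gs) - 1))
    return {"H": float(h_obs), "p": p, "method": "chi2"}


def rank_sum(a, b, alternative: str = "two-sided", method: str = "auto") -> dict:
    """Wilcoxon rank-sum test via the Mann-Whitney U statistic.

    Returns the rank-sum ``W`` of the first sample together with U and the
    (exact where feasible) p-value.  Two identical samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)
    return {"W": w, "U": float(res.statistic), "p": float(res.pvalue)}
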