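"""Gated many-to-one multiple comparisons and significance tiers.

The workflow mirrors common practice for day-course comparisons against a
reference day: each group family is first gated on normality (Shapiro, per
group) and equal variance (Bartlett); when neither is rejected the
parametric Dunnett many-to-one test is used, otherwise the nonparametric
Steel test (pairwise rank sums against the reference with a familywise
max-statistic adjustment).  Two-group morphology contrasts use the
Mann-Whitney rank-sum test.  Significance tiers: * p<0.1, ** p<0.05,
*** p<0.01.

The Steel test is implemented here directly.  Its statistics are pairwise
Wilcoxon rank sums of each treatment against the shared reference,
standardized with the tie-corrected null variance.  Under the null the
vector of standardized statistics is asymptotically multivariate normal
with the one-factor correlation rho_ij = lambda_i * lambda_j,
lambda_i = sqrt(n_i / (n_i + n0)) — the shared control is the common
factor — so the familywise p-value is an exact 1-D integral over that
factor, evaluated by dense quadrature (deterministic, no MC error).  For
very small groups the normal approximation is poor and a conservative
Bonferroni-adjusted exact rank-sum fallback is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: gate level for the Shapiro and Bartlett pre-tests
GATE_ALPHA = 0.05
#: minimum per-group size for the Steel normal approximation; below this the
#: Bonferroni-adjusted exact rank-sum fallback is used
STEEL_MIN_N_FOR_MVN = 6

_TIERS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def significance_tier(p: float) -> str:
    """Map a p-value to its tier: * p<0.1, ** p<0.05, *** p<0.01, else ns."""
    if not (0 <= p <= 1 or np.isnan(p)):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for cut, stars in _TIERS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    test: str  # Dunnett | Steel | Mann-Whitney
    statistic: float
    p_value: float

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p_value,
                "tier": r.tier,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Gate


def gate_test_choice(groups, alpha_gate: float = GATE_ALPHA) -> str:
    """Choose "Dunnett" or "Steel" from Shapiro + Bartlett pre-tests.

    Dunnett only when no group rejects normality and Bartlett does not
    reject equal variances, both at ``alpha_gate``.  Degenerate
    (zero-variance) groups fail the gate and route to Steel.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 3:
            raise ValueError("every group needs n >= 3")
    if any(np.ptp(g) == 0 for g in groups):
        return "Steel"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_ps = [sps.shapiro(g).pvalue for g in groups]
        bartlett_p = sps.bartlett(*groups).pvalue
    if min(shapiro_ps) < alpha_gate or bartlett_p < alpha_gate:
        return "Steel"
    return "Dunnett"


# ---------------------------------------------------------------------------
# Dunnett (parametric many-to-one)


def dunnett_many_to_one(
    groups,
    reference_index: int = 0,
    alternative: str = "two-sided",
    labels=None,
) -> list[ComparisonResult]:
    """Dunnett many-to-one mean comparisons against the reference group."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = groups[reference_index]
    if control.size == 0:
        raise ValueError("reference group is empty")
    treatments = [g for i, g in enumerate(groups) if i != reference_index]
    if labels is None:
        labels = [f"group {i} vs reference" for i in range(len(groups))
                  if i != reference_index]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # identical constants: no evidence of difference
        return [ComparisonResult(lab, "Dunnett", 0.0, 1.0) for lab in labels]
    res = sps.dunnett(*treatments, control=control, alternative=alternative)
    return [
        ComparisonResult(lab, "Dunnett", float(s), float(p))
        for lab, s, p in zip(labels, res.statistic, res.pvalue)
    ]


# ---------------------------------------------------------------------------
# Steel (nonparametric many-to-one)


def _rank_sum_z(treatment: np.ndarray, control: np.ndarray) -> float:
    """Tie-corrected standardized Wilcoxon rank-sum statistic (treatment)."""
    n1, n0 = treatment.size, control.size
    pooled = np.concatenate([control, treatment])
    ranks = sps.rankdata(pooled)
    w = ranks[n0:].sum()
    mean = n1 * (n0 + n1 + 1) / 2.0
    n = n0 + n1
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return 0.0
    return (w - mean) / np.sqrt(var)


def _one_factor_rectangle(lams: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> float:
    """P(lower_j <= Z_j <= upper_j) for Z_j = lam_j*X0 + sqrt(1-lam_j^2)*X_j.

    Deterministic dense-quadrature evaluation of the one-factor integral.
    """
    x = np.linspace(-8.0, 8.0, 4001)
    s = np.sqrt(1.0 - lams**2)
    up = sps.norm.cdf((upper[:, None] - lams[:, None] * x[None, :]) / s[:, None])
    lo = sps.norm.cdf((lower[:, None] - lams[:, None] * x[None, :]) / s[:, None])
    integrand = sps.norm.pdf(x) * np.prod(up - lo, axis=0)
    return float(np.trapezoid(integrand, x))


def steel_many_to_one(
    groups,
    reference_index: int = 0,
    alternative: str = "two-sided",
    labels=None,
    method: str = "auto",
) -> list[ComparisonResult]:
    """Steel many-to-one rank comparisons against the reference group.

    ``method``: "mvn" (one-factor multivariate-normal familywise
    adjustment), "bonferroni" (exact pairwise rank-sum p-values times the
    number of contrasts, conservative), or "auto" (mvn unless any group is
    smaller than :data:`STEEL_MIN_N_FOR_MVN`).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    control = groups[reference_index]
    if control.size == 0:
        raise ValueError("reference group is empty")
    treatments = [g for i, g in enumerate(groups) if i != reference_index]
    if labels is None:
        labels = [f"group {i} vs reference" for i in range(len(groups))
                  if i != reference_index]
    k = len(treatments)
    if method == "auto":
        small = min(g.size for g in groups) < STEEL_MIN_N_FOR_MVN
        method = "bonferroni" if small else "mvn"

    if method == "bonferroni":
        out = []
        for lab, t in zip(labels, treatments):
            mw = sps.mannwhitneyu(t, control, alternative=alternative)
            out.append(
                ComparisonResult(lab, "Steel", float(mw.statistic),
                                 min(1.0, k * float(mw.pvalue)))
            )
        return out

    z = np.array([_rank_sum_z(t, control) for t in treatments])
    n0 = control.size
    lams = np.array([np.sqrt(t.size / (t.size + n0)) for t in treatments])
    out = []
    for lab, zi in zip(labels, z):
        if alternative == "greater":
            c = np.full(k, zi)
            p = 1.0 - _one_factor_rectangle(lams, np.full(k, -np.inf), c)
        elif alternative == "less":
            c = np.full(k, zi)
            p = 1.0 - _one_factor_rectangle(lams, c, np.full(k, np.inf))
        elif alternative == "two-sided":
            c = np.full(k, abs(zi))
            p = 1.0 - _one_factor_rectangle(lams, -c, c)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        out.append(ComparisonResult(lab, "Steel", float(zi),
                                    float(np.clip(p, 0.0, 1.0))))
    return out


# ---------------------------------------------------------------------------
# Two-group rank test


def mann_whitney_two_group(a, b, alternative: str = "two-sided") -> ComparisonResult:
    """Mann-Whitney rank-sum test (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return ComparisonResult("a vs b", "Mann-Whitney", float(res.statistic),
                            float(res.pvalue))


# ---------------------------------------------------------------------------
# Study-level contrast runner


def run_paper_contrasts(
    table: pd.DataFrame,
    index: str,
    scheme: str = "days1to4",
    alternative: str = "two-sided",
    alpha_gate: float = GATE_ALPHA,
) -> list[ComparisonResult]:
    """Run the study's many-to-one contrast scheme on one index column.

    scheme "days1to4": within each condition, Days 2-4 are compared against
    the Day 1 reference.  scheme "day5": the Day-5 manipulation groups
    (cutoff / horizontal / reverse) are compared against the intact group.
    The Shapiro/Bartlett gate picks Dunnett or Steel per family.
    """
    if index not in table.columns:
        raise ValueError(f"table has no column {index!r}")
    results: list[ComparisonResult] = []
    if scheme == "days1to4":
        for cond, sub in table.groupby("condition", sort=False):
            days = sorted(sub["day"].unique())
            if 1 not in days:
                raise ValueError(f"condition {cond!r} is missing the Day 1 reference")
            groups = [sub.loc[sub["day"] == d, index].to_numpy() for d in days]
            labels = [f"{cond}: Day {d} vs Day 1" for d in days if d != 1]
            results.extend(
                _gated_many_to_one(groups, labels, alternative, alpha_gate)
            )
    elif scheme == "day5":
        sub = table[table["day"] == 5]
        conds = [c for c in sub["condition"].unique()]
        if "day5_intact" not in conds:
            raise ValueError("day5 scheme needs the day5_intact reference group")
        order = ["day5_intact"] + sorted(c for c in conds if c != "day5_intact")
        groups = [sub.loc[sub["condition"] == c, index].to_numpy() for c in order]
        labels = [f"{c} vs day5_intact" for c in order[1:]]
        results.extend(_gated_many_to_one(groups, labels, alternative, alpha_gate))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return results


def _gated_many_to_one(groups, labels, alternative, alpha_gate):
    choice = gate_test_choice(groups, alpha_gate=alpha_gate)
    if choice == "Dunnett":
        return dunnett_many_to_one(groups, 0, alternative=alternative, labels=labels)
    return steel_many_to_one(groups, 0, alternative=alternative, labels=labels)
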