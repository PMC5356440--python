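"""Group-comparison decision tree and organoid bud-distribution summaries.

The decision tree mirrors common practice for microscopy measurement
tables: each group is first assessed with the D'Agostino-Pearson omnibus
normality test; if every group passes (and is large enough for the test to
be valid), a parametric unpaired t-test (two groups) or one-way ANOVA
(more) is applied; otherwise the nonparametric Mann-Whitney U (two groups)
or Kruskal-Wallis test with Dunn's multiple-comparison post-test is used.
The full decision trace (normality p-values, chosen branch) is recorded in
the result so every routed test is auditable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

MIN_N_FOR_NORMALITY = 8  # the omnibus skew/kurtosis test is invalid below
BUD_CATEGORIES = ("0", "1", "2", "3", "4+")


@dataclass
class GroupComparison:
    labels: list[str]
    n_per_group: list[int]
    normality_p: dict[str, float]
    test: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None
    trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError("p-value outside [0, 1]")


def _dunn(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise post-test after Kruskal-Wallis.

    Uses the pooled-rank z statistic with tie correction
    ``sum(t^3 - t) / (12 (N - 1))`` and two-sided normal p-values, adjusted
    over all pairs (Bonferroni by default, the classic form of the test).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in labels:
        n = len(groups[g])
        mean_ranks[g] = float(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    rows = []
    pairs = list(itertools.combinations(labels, 2))
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    elif adjust == "none":
        out["p_adj"] = out["p_raw"]
    else:
        raise InvalidParameterError(f"unknown adjustment {adjust!r}")
    out.attrs["adjustment"] = adjust
    return out


def choose_and_run_test(groups: dict[str, np.ndarray],
                        alpha_normality: float = 0.05,
                        posthoc_adjust: str = "bonferroni") -> GroupComparison:
    """Route labelled value lists through the normality decision tree.

    Parametric branch (all groups pass D'Agostino-Pearson at
    ``alpha_normality`` *and* every n >= 8, the smallest sample the omnibus
    test accepts): unpaired t-test for two groups, one-way ANOVA for more.
    Otherwise: Mann-Whitney U for two groups, Kruskal-Wallis with Dunn's
    post-test for more.  Groups smaller than 3 are refused outright.
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise InvalidParameterError(
                f"group {name!r} has n={len(vals)} < 3: too small to compare")
    trace: list[str] = []
    normality_p: dict[str, float] = {}
    parametric = True
    for name, vals in groups.items():
        if len(vals) < MIN_N_FOR_NORMALITY:
            normality_p[name] = float("nan")
            trace.append(f"group {name}: n={len(vals)} < {MIN_N_FOR_NORMALITY}, "
                         "too small for the normality test -> nonparametric branch")
            parametric = False
        elif np.ptp(vals) == 0.0:
            normality_p[name] = 0.0
            trace.append(f"group {name}: constant values -> nonparametric branch")
            logger.warning("group %s contains ties only", name)
            parametric = False
        else:
            p = float(sps.normaltest(vals).pvalue)
            normality_p[name] = p
            verdict = "passes" if p > alpha_normality else "fails"
            trace.append(f"group {name}: D'Agostino-Pearson p={p:.4g} "
                         f"({verdict} at alpha={alpha_normality})")
            if p <= alpha_normality:
                parametric = False
    vals = list(groups.values())
    labels = list(groups)
    posthoc = None
    if parametric:
        if len(groups) == 2:
            res = sps.ttest_ind(vals[0], vals[1])
            test = "t-test"
        else:
            res = sps.f_oneway(*vals)
            test = "one-way ANOVA"
    else:
        if len(groups) == 2:
            res = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
            test = "Mann-Whitney U"
        else:
            res = sps.kruskal(*vals)
            test = "Kruskal-Wallis"
            posthoc = _dunn(groups, posthoc_adjust)
            trace.append(f"Dunn's post-test over all pairs "
                         f"({posthoc_adjust} adjustment)")
    trace.append(f"routed to {test}")
    return GroupComparison(
        labels=labels, n_per_group=[len(v) for v in vals],
        normality_p=normality_p, test=test,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        posthoc=posthoc, trace=trace)


# ---------------------------------------------------------------------------
# organoid bud distributions
# ---------------------------------------------------------------------------

def bud_distribution(buds: pd.DataFrame) -> pd.DataFrame:
    """Percentage of organoids with 0 / 1 / 2 / 3 / 4+ buds.

    ``buds`` holds one row per organoid with columns ``genotype``, ``day``,
    ``region`` and ``n_buds`` (non-negative integer).  Percentages are
    computed per region (each region's categories sum to 100) and then
    averaged over regions within genotype x day — the region, not the
    organoid, is the unit of replication.
    """
    required = {"genotype", "day", "region", "n_buds"}
    if not required.issubset(buds.columns):
        raise InvalidParameterError(f"bud table needs columns {sorted(required)}")
    if (buds.n_buds < 0).any():
        raise InvalidParameterError("bud counts must be >= 0")
    work = buds.copy()
    work["category"] = np.where(work.n_buds >= 4, "4+",
                                work.n_buds.astype(int).astype(str))
    rows = []
    for (genotype, day, region), g in work.groupby(["genotype", "day", "region"]):
        if len(g) == 0:
            logger.warning("region %s (%s day %s) empty; excluded", region, genotype, day)
            continue
        counts = g.category.value_counts()
        for cat in BUD_CATEGORIES:
            rows.append({"genotype": genotype, "day": day, "region": region,
                         "category": cat,
                         "percentage": 100.0 * counts.get(cat, 0) / len(g)})
    per_region = pd.DataFrame(rows)
    out = (per_region.groupby(["genotype", "day", "category"], sort=False)
           .percentage.mean().reset_index())
    out["category"] = pd.Categorical(out.category, BUD_CATEGORIES, ordered=True)
    return out.sort_values(["genotype", "day", "category"]).reset_index(drop=True)


def bud_two_way_anova(buds: pd.DataFrame, category: str = "0") -> pd.DataFrame:
    """Optional genotype x day two-way ANOVA on per-region percentages.

    Runs on the per-region percentage of one bud category (default: the
    no-bud class, the most sensitive read-out of delayed development).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    work = buds.copy()
    work["category"] = np.where(work.n_buds >= 4, "4+",
                                work.n_buds.astype(int).astype(str))
    rows = []
    for (genotype, day, region), g in work.groupby(["genotype", "day", "region"]):
        rows.append({"genotype": genotype, "day": day, "region": region,
                     "pct": 100.0 * (g.category == category).mean()})
    table = pd.DataFrame(rows)
    model = ols("pct ~ C(genotype) * C(day)", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)


def percent_change(control: np.ndarray, treated: np.ndarray) -> dict:
    """Percent change of the treated mean relative to control.

    Negative change is a reduction; ``percent_reduction`` reports it with
    the customary positive sign.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise DegenerateInputError("both value lists must be non-empty")
    if control.mean() == 0:
        raise ZeroDivisionError("control mean is zero: percent change undefined")
    change = 100.0 * (treated.mean() - control.mean()) / control.mean()
    return {"percent_change": float(change),
            "percent_reduction": float(-change)}
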