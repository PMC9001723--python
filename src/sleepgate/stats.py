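"""Block-wise mixed models and behavioral statistics.

The EEG analysis treats the 8 s before / during / after each presentation as
separate blocks and fits, per block, a linear mixed model of normalized
band power with sound type, time (1-8 s) and their interaction (optionally
sleep phase) as fixed effects, and random intercepts for animals and for
sessions nested within animals.  Behavioral analyses cover the
avoidance-learning criterion, Audiobox per-sound avoidance rates, 4-parameter
logistic generalization fits, and one-way ANOVA with Tukey-Kramer post-hoc
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sp_stats
from scipy.stats import studentized_range
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


# ---------------------------------------------------------------------------
# Block-wise linear mixed model
# ---------------------------------------------------------------------------

class BlockPowerModel:
    """Linear mixed model of normalized band power within one block.

    Built from the long-format power table (one row per epoch-second).
    Fixed effects default to sound type, time and their interaction, plus
    sleep phase when both states are present; random effects are intercepts
    for animal and for session nested in animal.

    Examples
    --------
    >>> model = BlockPowerModel.from_table(table, block=2)
    >>> res = model.fit()
    >>> res.anova_table()          # per-term F tests
    >>> res.lrt_random_effects()   # LRT vs the fixed-effects-only model
    """

    def __init__(
        self,
        table: pd.DataFrame,
        block: int,
        include_phase: bool | None = None,
    ) -> None:
        if block not in (1, 2, 3):
            raise ValueError("block must be 1, 2 or 3")
        data = table[table["block"] == block].copy()
        if data.empty:
            raise ValueError(f"no rows for block {block}")
        if include_phase is None:
            include_phase = data["phase"].nunique() > 1
        self.block = block
        self.include_phase = include_phase
        self.data = data.reset_index(drop=True)
        terms = []
        if include_phase:
            terms.append("C(phase)")
        multi_sound = data["sound_type"].nunique() > 1
        if multi_sound:
            terms.append("C(sound_type)")
        terms.append("time")
        if multi_sound:
            terms.append("C(sound_type):time")
        self.formula = "normalized_power ~ " + " + ".join(terms)
        self._terms = terms

    @classmethod
    def from_table(cls, table: pd.DataFrame, block: int, **kw) -> "BlockPowerModel":
        return cls(table, block, **kw)

    @classmethod
    def from_epochs(cls, epochs, block: int, **kw) -> "BlockPowerModel":
        from .power import to_long_table

        return cls(to_long_table(epochs), block, **kw)

    def _mixed(self, reml: bool):
        model = smf.mixedlm(
            self.formula,
            self.data,
            groups=self.data["animal_id"],
            re_formula="1",
            vc_formula={"session": "0 + C(session_id)"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=["lbfgs", "powell"])

    def fit(self, reml: bool = True) -> "BlockPowerResult":
        """REML fit (ML refits are performed internally for the LRT)."""
        res = self._mixed(reml=reml)
        singular = bool(getattr(res, "converged", True) is False)
        return BlockPowerResult(self, res, singular=singular)


@dataclass
class FixedEffectTest:
    term: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    effect_size: float  # coefficient (or mean coefficient for multi-df terms)


@dataclass
class BlockPowerResult:
    """Fitted block model: per-term F tests, coefficients, LRT, summary."""

    model: BlockPowerModel
    mixed_result: object
    singular: bool = False
    _lrt: dict | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.mixed_result.params

    @property
    def llf(self) -> float:
        return float(self.mixed_result.llf)

    @property
    def random_effect_variances(self) -> dict:
        res = self.mixed_result
        out = {"animal": float(np.asarray(res.cov_re).ravel()[0])}
        vcomp = getattr(res, "vcomp", None)
        if vcomp is not None and len(vcomp):
            out["session"] = float(vcomp[0])
        out["residual"] = float(res.scale)
        return out

    def _term_columns(self, term: str) -> list[str]:
        exog_names = self.mixed_result.model.exog_names
        if term == "time":
            return [n for n in exog_names if n == "time"]
        if term.startswith("C(") and ":" not in term:
            fac = term[2:-1]
            return [n for n in exog_names if n.startswith(f"C({fac})[") and ":" not in n]
        if ":" in term:
            return [n for n in exog_names if ":" in n]
        return [n for n in exog_names if n == term]

    @property
    def df_resid(self) -> int:
        k = len(self.mixed_result.fe_params)
        return int(self.mixed_result.model.nobs - k)

    def f_test_term(self, term: str) -> FixedEffectTest:
        """Wald F test of all coefficients belonging to one fixed-effect term.

        The denominator df is the residual-style n - rank(X); with the
        design sizes used here this is effectively equivalent to a
        Satterthwaite approximation.
        """
        cols = self._term_columns(term)
        if not cols:
            raise KeyError(f"no coefficients found for term {term!r}")
        exog_names = self.mixed_result.model.exog_names
        k_all = len(self.mixed_result.params)
        contrast = np.zeros((len(cols), k_all))
        for i, c in enumerate(cols):
            contrast[i, exog_names.index(c)] = 1.0
        wt = self.mixed_result.wald_test(contrast, scalar=True)
        chi2 = float(wt.statistic)
        q = len(cols)
        f_stat = chi2 / q
        p = float(sp_stats.f.sf(f_stat, q, self.df_resid))
        coefs = self.mixed_result.fe_params[cols]
        return FixedEffectTest(
            term=term,
            f_stat=f_stat,
            df_num=q,
            df_den=self.df_resid,
            p_value=p,
            effect_size=float(np.mean(coefs)),
        )

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for term in self.model._terms:
            t = self.f_test_term(term)
            rows.append(
                {
                    "term": term,
                    "F": t.f_stat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.p_value,
                    "effect_size": t.effect_size,
                }
            )
        return pd.DataFrame(rows)

    def lrt_random_effects(self) -> dict:
        """Likelihood-ratio test of the random effects vs plain OLS.

        Both models are refit by ML; the chi-square df equals the number of
        variance parameters removed (animal intercept + session component).
        """
        if self._lrt is None:
            ml = self.model._mixed(reml=False)
            ols = smf.ols(self.model.formula, self.model.data).fit()
            k_var = len(np.asarray(ml.cov_re).ravel()) + len(
                getattr(ml, "vcomp", []) or []
            )
            chi2 = max(0.0, 2.0 * (float(ml.llf) - float(ols.llf)))
            self._lrt = {
                "chi2": chi2,
                "df": int(k_var),
                "p": float(sp_stats.chi2.sf(chi2, max(k_var, 1))),
            }
        return self._lrt

    def interaction_p(self) -> float:
        """P value of the sound x time interaction (the gating signature)."""
        return self.f_test_term("C(sound_type):time").p_value

    def summary(self) -> str:
        lines = [
            f"Block {self.model.block} linear mixed model "
            f"({self.model.data.shape[0]} epoch-seconds)",
            f"  formula: {self.model.formula}",
            "  random: ~1 | animal_id + ~1 | session_id (nested)",
        ]
        if self.singular:
            lines.append("  WARNING: fit did not converge (singular fit?)")
        lines.append("")
        tab = self.anova_table()
        for _, r in tab.iterrows():
            lines.append(
                f"  {r['term']:<24s} F({r['df_num']:.0f}, {r['df_den']:.0f}) = "
                f"{r['F']:8.2f}   p = {r['p']:.3g}   EES = {r['effect_size']:+.3f}"
            )
        var = self.random_effect_variances
        lines.append("")
        lines.append(
            "  variance components: "
            + ", ".join(f"{k} = {v:.4f}" for k, v in var.items())
        )
        lrt = self.lrt_random_effects()
        lines.append(
            f"  LRT vs fixed-effects-only: chi2({lrt['df']}) = {lrt['chi2']:.1f}, "
            f"p = {lrt['p']:.3g}"
        )
        return "\n".join(lines)


def fit_block_lmm(
    table: pd.DataFrame, block: int, include_phase: bool | None = None
) -> BlockPowerResult:
    """Convenience wrapper: build and fit the block model in one call."""
    return BlockPowerModel(table, block, include_phase=include_phase).fit()


# ---------------------------------------------------------------------------
# Behavioral analyses
# ---------------------------------------------------------------------------

def classify_learner(trials: pd.DataFrame, animal_id: str | None = None) -> str:
    """Learner classification from conditioning trials.

    Learner iff day-2 avoidance is strictly above 80% AND the animal has
    accumulated at least 15 conditioning trials by the end of day 2.
    Returns 'learner', 'nonlearner', or 'unknown' when day 2 is absent.
    """
    t = trials if animal_id is None else trials[trials["animal_id"] == animal_id]
    day2 = t[t["day"] == 2]
    if day2.empty:
        return "unknown"
    avoidance = 100.0 * day2["avoided"].mean()
    n_cum = int((t["day"] <= 2).sum())
    return "learner" if (avoidance > 80.0 and n_cum >= 15) else "nonlearner"


def classify_learners(trials: pd.DataFrame) -> pd.Series:
    """Per-animal learner classification over a multi-animal trial table."""
    return pd.Series(
        {a: classify_learner(trials, a) for a in sorted(trials["animal_id"].unique())},
        name="cohort",
    )


def avoidance_by_sound(visits: pd.DataFrame, phase: str = "early") -> pd.DataFrame:
    """Per-animal per-sound avoidance percentage in the early or late phase.

    'early' keeps the first two distinct training days present in the table,
    'late' the last two.  Avoidance % = 100 x visits without a nose poke /
    visits; (animal, sound) cells without visits are omitted.
    """
    days = np.sort(visits["day"].unique())
    if phase == "early":
        keep = days[:2]
    elif phase == "late":
        keep = days[-2:]
    else:
        raise ValueError("phase must be 'early' or 'late'")
    sub = visits[visits["day"].isin(keep)]
    if sub.empty:
        raise ValueError("no visits in the requested phase")
    out = (
        sub.groupby(["animal_id", "sound"])
        .agg(n_visits=("nosepoked", "size"), avoidance_pct=("nosepoked", lambda s: 100.0 * (~s.astype(bool)).mean()))
        .reset_index()
    )
    out["phase"] = phase
    return out


def _four_pl(x, floor, ceiling, midpoint, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (x - midpoint)))


@dataclass
class SigmoidFit:
    """4-parameter logistic fit of avoidance vs sound-frequency rank."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _four_pl(np.asarray(x, float), self.floor, self.ceiling, self.midpoint, self.slope)


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Least-squares 4PL fit (floor, ceiling, midpoint, slope).

    Non-convergence is reported through ``converged`` with residuals from
    the best attempt (a flat fallback when no fit is possible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a 4PL fit")
    span = max(np.ptp(y), 1e-6)
    p0 = [float(np.min(y)), float(np.max(y)), float(np.median(x)), 4.0 / max(np.ptp(x), 1e-6)]
    bounds = (
        [np.min(y) - span, np.min(y) - span, np.min(x) - np.ptp(x), -200.0],
        [np.max(y) + span, np.max(y) + span, np.max(x) + np.ptp(x), 200.0],
    )
    try:
        popt, _ = optimize.curve_fit(_four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        popt = [float(np.mean(y)), float(np.mean(y)), float(np.median(x)), 0.0]
        converged = False
    fitted = _four_pl(x, *popt)
    return SigmoidFit(
        floor=float(popt[0]),
        ceiling=float(popt[1]),
        midpoint=float(popt[2]),
        slope=float(popt[3]),
        fitted=fitted,
        residuals=y - fitted,
        converged=converged,
    )


@dataclass
class AnovaTukeyResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_stat:.2f}, p = {self.p_value:.3g}",
            "Tukey-Kramer pairwise comparisons:",
        ]
        for _, r in self.tukey.iterrows():
            lines.append(
                f"  {r['group1']} vs {r['group2']}: diff = {r['meandiff']:+.2f}, "
                f"p = {r['p_adj']:.4f}{' *' if r['reject'] else ''}"
            )
        return "\n".join(lines)


def anova_tukey(
    table: pd.DataFrame, value_col: str = "avoidance_pct", group_col: str = "sound"
) -> AnovaTukeyResult:
    """One-way ANOVA across sounds with Tukey-Kramer post-hoc comparisons.

    The Tukey-Kramer procedure (studentized-range based, supporting unequal
    group sizes) adjusts the pairwise p values.
    """
    groups = [g[value_col].to_numpy(float) for _, g in table.groupby(group_col)]
    if len(groups) < 2:
        raise ValueError("need at least two sound groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    f_stat, p = sp_stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    res = pairwise_tukeyhsd(
        endog=table[value_col].to_numpy(float),
        groups=table[group_col].to_numpy(),
    )
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.replace("-", "_") for c in res.summary().data[0]],
    ).rename(columns={"p_adj": "p_adj", "meandiff": "meandiff"})
    tukey.columns = ["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
    return AnovaTukeyResult(
        f_stat=float(f_stat),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        p_value=float(p),
        tukey=tukey,
    )


def tukey_hsd_pvalue(mean_a, mean_b, mse, n_per_group, k_groups, df_within) -> float:
    """Closed-form equal-n Tukey HSD p value (studentized-range oracle)."""
    q = abs(mean_a - mean_b) / np.sqrt(mse / n_per_group)
    return float(studentized_range.sf(q, k_groups, df_within))
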