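"""Statistical analysis chain for factorial no-choice mating trials.

The chain mirrors a classical quantitative-genetic analysis of a fully
factorial isogenic-line mating study:

* log-transformed **general linear models** for the male-controlled
  channels (courtship latency, copulation duration), with Type-III
  effect tests for male genotype, female genotype, ages, and the
  male x female genotype interaction ("base model");
* a **Cox proportional-hazards model** for copulation latency, which is
  right-censored at the recording limit, with per-effect likelihood-
  ratio chi-squares obtained by drop-one nested refits;
* **Levene's test** for heterogeneity of response variance among chooser
  lines (genetic variation in choosiness);
* **Benjamini-Hochberg FDR** adjustment across effect p-values;
* an OLS regression of female-line choosiness on male-line (inverse)
  global attractiveness — the line-level **genetic correlation**;
* **Kendall's coefficient of concordance (W)** across chooser lines'
  partner rankings, with a permutation null, which discriminates
  preference-function classes: open-ended (or shared-peak unimodal)
  preferences force identical rankings (W near 1), while variable-peak
  unimodal preferences produce discordant rankings (W below 1) and a
  genotype x genotype interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import patsy
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .components import CHOOSER_ROLE, cell_means

__all__ = [
    "EffectTable",
    "LeveneResult",
    "CorrelationResult",
    "ConcordanceResult",
    "DiscriminationResult",
    "fit_courtship_model",
    "fit_copulation_model",
    "fit_duration_model",
    "levene_choosiness",
    "fdr_adjust",
    "genetic_correlation",
    "kendalls_w",
    "rank_concordance",
    "discriminate_models",
]

logger = logging.getLogger(__name__)

BASE_EFFECTS = ("male_line", "female_line", "male_age", "female_age",
                "male_line:female_line")


@dataclass
class EffectTable:
    """Per-effect test statistics from one fitted stage.

    ``table`` has one row per model effect with columns
    ``effect, df, statistic, stat_type, p_value`` (stat_type is ``F`` or
    ``LR_chi2``); ``metadata`` records the channel, formula, and the
    number of rows used, for audit.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def pvalues(self) -> pd.Series:
        return self.table.set_index("effect")["p_value"]

    def to_json_dict(self) -> dict:
        return {"metadata": self.metadata,
                "effects": self.table.to_dict(orient="records")}


class LeveneResult(tuple):
    """(statistic, df1, df2, p_value) from Levene's test."""

    def __new__(cls, statistic, df1, df2, p_value):
        return super().__new__(cls, (statistic, df1, df2, p_value))

    statistic = property(lambda self: self[0])
    df1 = property(lambda self: self[1])
    df2 = property(lambda self: self[2])
    p_value = property(lambda self: self[3])


@dataclass(frozen=True)
class CorrelationResult:
    """Line-level regression summary (genetic correlation estimate)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_lines: int


@dataclass
class ConcordanceResult:
    """Kendall's W across chooser lines' partner rankings."""

    kendall_w: float
    p_value: float
    n_choosers: int
    n_partners: int
    rankings: pd.DataFrame  # one row per chooser line, columns = partner lines
    n_permutations: int = 0

    def to_json_dict(self) -> dict:
        return {
            "kendall_w": self.kendall_w, "p_value": self.p_value,
            "n_choosers": self.n_choosers, "n_partners": self.n_partners,
            "n_permutations": self.n_permutations,
            "rankings": self.rankings.to_dict(orient="index"),
        }


@dataclass
class DiscriminationResult:
    """Preference-function class label plus its supporting statistics."""

    label: str
    interaction_p: float
    interaction_statistic: float
    kendall_w: float
    concordance_p: float
    levene: LeveneResult
    alpha: float
    w_high: float

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "interaction_p": self.interaction_p,
            "interaction_statistic": self.interaction_statistic,
            "kendall_w": self.kendall_w,
            "concordance_p": self.concordance_p,
            "levene_F": self.levene.statistic,
            "levene_p": self.levene.p_value,
            "alpha": self.alpha, "w_high": self.w_high,
        }


# ---------------------------------------------------------------------------
# linear models


def _check_factorial(df: pd.DataFrame, context: str) -> None:
    """Every male x female line cell must be occupied, else the factorial
    interaction is rank-deficient."""
    for col in ("male_line", "female_line"):
        if df[col].nunique() < 2:
            raise ValueError(f"{context}: factor {col!r} has fewer than two levels; "
                             "no contrast can be estimated")
    present = set(zip(df["male_line"], df["female_line"]))
    expected = {(m, f) for m in df["male_line"].unique()
                for f in df["female_line"].unique()}
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"{context}: design is rank-deficient; empty cells: {missing}")


def _base_terms(df: pd.DataFrame) -> list[str]:
    """Base-model terms, dropping age factors without contrast."""
    terms = ["C(male_line, Sum)", "C(female_line, Sum)"]
    for col in ("male_age", "female_age"):
        if df[col].nunique() >= 2:
            terms.append(f"C({col}, Sum)")
        else:
            logger.info("dropping %s: single level", col)
    terms.append("C(male_line, Sum):C(female_line, Sum)")
    return terms


_PRETTY = {
    "C(male_line, Sum)": "male_line",
    "C(female_line, Sum)": "female_line",
    "C(male_age, Sum)": "male_age",
    "C(female_age, Sum)": "female_age",
    "C(male_line, Sum):C(female_line, Sum)": "male_line:female_line",
    "np.log(courtship_latency)": "courtship_latency",
    "copulation_latency": "copulation_latency",
}


def _ols_effect_table(df: pd.DataFrame, response: str, terms: Sequence[str],
                      channel: str) -> EffectTable:
    """Type-III effect tests (sum-to-zero coding) for an OLS fit."""
    formula = f"np.log({response}) ~ " + " + ".join(terms)
    res = ols(formula, data=df).fit()
    aov = anova_lm(res, typ=3)
    rows = []
    for term in terms:
        if term not in aov.index:  # pragma: no cover - defensive
            raise RuntimeError(f"term {term} missing from ANOVA table")
        rows.append({
            "effect": _PRETTY.get(term, term),
            "df": int(aov.loc[term, "df"]),
            "statistic": float(aov.loc[term, "F"]),
            "stat_type": "F",
            "p_value": float(aov.loc[term, "PR(>F)"]),
        })
    meta = {"channel": channel, "formula": formula, "n_used": int(res.nobs),
            "df_resid": int(res.df_resid), "model": "ols_type3_sum"}
    return EffectTable(pd.DataFrame(rows), meta)


def fit_courtship_model(trials: pd.DataFrame) -> EffectTable:
    """General linear model for log courtship latency (male-controlled).

    Effects: male genotype, female genotype, male age, female age, and
    the male x female genotype interaction, tested with Type-III F tests
    under sum-to-zero coding.  Uses trials in which courtship occurred.
    """
    df = trials[trials["courted"].astype(bool)].dropna(subset=["courtship_latency"]).copy()
    df = _drop_missing(df, ["male_age", "female_age"], "courtship model")
    _check_factorial(df, "courtship model")
    return _ols_effect_table(df, "courtship_latency", _base_terms(df),
                             "courtship_latency")


def fit_duration_model(trials: pd.DataFrame) -> EffectTable:
    """General linear model for log copulation duration (mated pairs only).

    Base-model effects plus log courtship latency and copulation latency
    as covariates controlling for precopulatory timing.
    """
    df = trials[trials["mated"].astype(bool)].dropna(
        subset=["copulation_duration", "courtship_latency", "copulation_latency"]).copy()
    df = _drop_missing(df, ["male_age", "female_age"], "duration model")
    _check_factorial(df, "duration model")
    terms = _base_terms(df) + ["np.log(courtship_latency)", "copulation_latency"]
    return _ols_effect_table(df, "copulation_duration", terms, "copulation_duration")


def _drop_missing(df: pd.DataFrame, cols: list[str], context: str) -> pd.DataFrame:
    n0 = len(df)
    out = df.dropna(subset=[c for c in cols if c in df.columns])
    if len(out) < n0:
        logger.info("%s: dropped %d row(s) with missing covariates", context, n0 - len(out))
    return out


def fit_copulation_model(trials: pd.DataFrame,
                         effects: Sequence[str] | None = None,
                         penalizer: float = 0.0) -> EffectTable:
    """Cox proportional-hazards model for right-censored copulation latency.

    The event is successful mating; unmated (courted) pairs are censored
    at the recording limit.  Covariates are the base model (sum-coded
    genotype and age factors plus the factorial genotype interaction)
    and log courtship latency.  Each effect's likelihood-ratio
    chi-square comes from a drop-one nested refit (Efron tie handling).

    ``effects`` limits which effects are tested (all by default), saving
    the corresponding reduced fits.
    """
    df = trials[trials["courted"].astype(bool)].dropna(
        subset=["copulation_latency", "courtship_latency"]).copy()
    df = _drop_missing(df, ["male_age", "female_age"], "copulation model")
    _check_factorial(df, "copulation model")

    terms = _base_terms(df) + ["np.log(courtship_latency)"]
    formula = " + ".join(terms)
    design = patsy.dmatrix(formula, df, return_type="dataframe")
    info = design.design_info
    design = design.drop(columns="Intercept")

    fit_df = design.copy()
    fit_df["_duration"] = df["copulation_latency"].to_numpy(dtype=float)
    fit_df["_event"] = df["mated"].to_numpy(dtype=bool)

    def _fit_newton(frame: pd.DataFrame, pen: float) -> float:
        cph = CoxPHFitter(penalizer=pen)
        cph.fit(frame, duration_col="_duration", event_col="_event")
        return float(cph.log_likelihood_)

    def _fit_ridge(frame: pd.DataFrame, pen: float) -> float:
        """Strictly concave ridge-penalized partial likelihood via a
        line-searched quasi-Newton optimizer.

        Under a monotone partial likelihood the unpenalized MLE is at
        infinity and pure Newton iterations (lifelines) can stall or
        falsely report convergence; the ridge objective has a unique
        finite optimum that L-BFGS finds reliably.  Returns the
        unpenalized partial log-likelihood at the ridge solution, like
        the primary fitter.
        """
        import statsmodels.api as sm
        from scipy.optimize import minimize
        x = frame.drop(columns=["_duration", "_event"]).to_numpy(dtype=float)
        model = sm.PHReg(frame["_duration"].to_numpy(dtype=float), x,
                         status=frame["_event"].to_numpy(dtype=int), ties="efron")
        n = x.shape[0]

        def negobj(b):
            return -(model.loglike(b) - 0.5 * pen * n * float(b @ b))

        def neggrad(b):
            return -(model.score(b) - pen * n * b)

        res = minimize(negobj, np.zeros(x.shape[1]), jac=neggrad,
                       method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-7})
        if not np.all(np.isfinite(res.x)):
            raise ConvergenceError("ridge fallback produced non-finite coefficients")
        return float(model.loglike(res.x))

    def _fit(frame: pd.DataFrame, pen: float, use_ridge: bool) -> float:
        return _fit_ridge(frame, pen) if use_ridge else _fit_newton(frame, pen)

    if effects is None:
        tested = terms
    else:
        rev = {v: k for k, v in _PRETTY.items()}
        tested = [rev.get(e, e) for e in effects]
        unknown = [t for t in tested if t not in terms]
        if unknown:
            raise ValueError(f"unknown effect(s) {unknown}; model terms are "
                             f"{[_PRETTY.get(t, t) for t in terms]}")

    # A monotone partial likelihood (a factor level perfectly ordering the
    # events) sends coefficients to infinity and defeats the Newton
    # fitter; escalate a small ridge penalizer until all nested fits
    # converge, using the same penalizer and optimizer for full and
    # reduced fits so the LR comparison remains valid.  The ladder stays
    # gentle: a heavy ridge would shrink the very contrasts the LR
    # measures.  Ridged fits go through the line-searched fallback
    # optimizer, which cannot falsely converge on the strictly concave
    # penalized objective.
    attempts = [(penalizer, False)] + [
        (p, True) for p in (1e-5, 1e-4, 1e-3) if p > penalizer]
    last_err: Exception | None = None
    for pen, use_ridge in attempts:
        try:
            ll_full = _fit(fit_df, pen, use_ridge)
            lrs = []
            for term in tested:
                cols = info.column_names[info.term_name_slices[term]]
                cols = [c for c in cols if c != "Intercept"]
                ll_red = _fit(fit_df.drop(columns=cols), pen, use_ridge)
                if ll_full < ll_red - 1e-4:
                    # nested models: the full fit must dominate; a lower
                    # full-model likelihood means it stalled short of its
                    # optimum, so this penalizer level is unusable
                    raise ConvergenceError(
                        f"full-model likelihood below nested model by "
                        f"{ll_red - ll_full:.3g} at penalizer {pen:g}")
                lrs.append((term, len(cols), max(0.0, 2.0 * (ll_full - ll_red))))
            break
        except ConvergenceError as err:
            last_err = err
            logger.info("Cox fit failed at penalizer %g; escalating", pen)
    else:
        raise last_err
    if pen > penalizer:
        logger.warning("Cox model required ridge penalizer %g to converge", pen)

    rows = [{
        "effect": _PRETTY.get(term, term),
        "df": dof,
        "statistic": lr,
        "stat_type": "LR_chi2",
        "p_value": float(stats.chi2.sf(lr, dof)),
    } for term, dof, lr in lrs]
    all_events = bool(fit_df["_event"].all())
    meta = {"channel": "copulation_latency", "formula": formula,
            "n_used": int(len(fit_df)), "n_events": int(fit_df["_event"].sum()),
            "all_events": all_events, "ties": "efron", "penalizer": pen,
            "model": "cox_ph_drop_one_lr"}
    if all_events:
        meta["note"] = "no censored observations"
    return EffectTable(pd.DataFrame(rows), meta)


# ---------------------------------------------------------------------------
# variance heterogeneity, FDR, genetic correlation


def levene_choosiness(trials: pd.DataFrame, channel: str = "copulation_latency",
                      center: str = "mean", mated_only: bool | None = None,
                      log_scale: bool = False) -> LeveneResult:
    """Levene's test for unequal response variance among chooser lines.

    A significant result means lines differ in the spread of their
    responses across partners — genetic variation in choosiness.
    ``center='mean'`` is the classic Levene statistic (an ANOVA on
    absolute deviations from group means); ``center='median'`` gives the
    Brown-Forsythe variant.  For copulation latency, ``mated_only=False``
    (default) keeps censored trials at the censor time so every trial
    informs the variance, matching the full-design degrees of freedom;
    ``mated_only=True`` restricts to mated pairs.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    if channel == "copulation_latency" and mated_only is None:
        mated_only = False
    from .components import _channel_values  # shared filtering rules
    vals = _channel_values(trials, channel, mated_only)
    if log_scale:
        vals = vals.assign(value=np.log(vals["value"]))
    groups = [g.to_numpy(dtype=float)
              for _, g in vals.groupby("chooser_line", observed=True)["value"]]
    if len(groups) < 2:
        raise ValueError("Levene's test needs at least two chooser lines")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every chooser line needs at least two observations")
    stat, p = stats.levene(*groups, center=center)
    n_total = sum(len(g) for g in groups)
    return LeveneResult(float(stat), len(groups) - 1, n_total - len(groups), float(p))


def fdr_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genetic_correlation(choosiness: pd.Series, attractiveness: pd.Series,
                        inverse_transform: bool = True) -> CorrelationResult:
    """OLS regression of female-line choosiness on male-line attractiveness.

    Both series must be indexed by the same shared-genotype line ids
    (each isogenic line contributes its males' global attractiveness and
    its females' choosiness).  With ``inverse_transform`` (default) the
    attractiveness axis is 1 / mean latency, so a positive slope reads
    "lines with more attractive males have choosier females".
    """
    c = pd.Series(choosiness).dropna()
    a = pd.Series(attractiveness).dropna()
    if set(c.index) != set(a.index):
        raise ValueError(
            f"line sets differ: choosiness has {sorted(set(c.index) - set(a.index))} "
            f"extra, attractiveness has {sorted(set(a.index) - set(c.index))} extra")
    if len(c) < 3:
        raise ValueError("need at least three shared lines")
    a = a.reindex(c.index)
    x = (1.0 / a) if inverse_transform else a
    res = stats.linregress(x.to_numpy(dtype=float), c.to_numpy(dtype=float))
    return CorrelationResult(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             p_value=float(res.pvalue), n_lines=len(c))


# ---------------------------------------------------------------------------
# rank concordance


def kendalls_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ranks`` is an (m choosers x n objects) matrix of within-row ranks
    (ties as average ranks).  W = 12 S / (m^2 (n^3 - n) - m sum(T)),
    with S the sum of squared deviations of column rank sums and T the
    standard tie correction per row.
    """
    r = np.asarray(ranks, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least 2 choosers and 2 objects")
    m, n = r.shape
    col_sums = r.sum(axis=0)
    s = float(np.sum((col_sums - col_sums.mean()) ** 2))
    tie_term = 0.0
    for row in r:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = m ** 2 * (n ** 3 - n) - m * tie_term
    if denom <= 0:
        # every row fully tied: no information; define W = 0
        return 0.0
    return 12.0 * s / denom


def rank_concordance(cells: pd.DataFrame, n_permutations: int = 2000,
                     seed: int = 0,
                     rng: np.random.Generator | None = None) -> ConcordanceResult:
    """Concordance of partner rankings across chooser lines.

    Each chooser line ranks partner lines by its cell-mean response
    (ties averaged).  Kendall's W is 1 when all chooser lines agree.
    The p-value is the permutation probability of a W at least as large
    under independently shuffled rankings per chooser (the null of no
    shared ranking), so a *small* p indicates significant concordance.
    """
    mat = cells.pivot(index="chooser_line", columns="partner_line", values="mean")
    if mat.isna().any().any():
        missing = [(i, j) for i in mat.index for j in mat.columns
                   if pd.isna(mat.loc[i, j])]
        raise ValueError(f"incomplete chooser x partner matrix; missing cells: {missing}")
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 chooser lines and 2 partner lines")
    ranks = np.apply_along_axis(stats.rankdata, 1, mat.to_numpy(dtype=float))
    w_obs = kendalls_w(ranks)

    if rng is None:
        rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permuted(ranks, axis=1)
        if kendalls_w(perm) >= w_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    rankings = pd.DataFrame(ranks, index=mat.index, columns=mat.columns)
    return ConcordanceResult(kendall_w=float(w_obs), p_value=float(p),
                             n_choosers=mat.shape[0], n_partners=mat.shape[1],
                             rankings=rankings, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# model discrimination


def discriminate_models(trials: pd.DataFrame, alpha: float = 0.05,
                        w_high: float = 0.9, n_permutations: int = 2000,
                        seed: int = 0,
                        mated_only: bool | None = None) -> DiscriminationResult:
    """Classify the female preference-function regime from trial data.

    Open-ended preferences (or unimodal ones sharing a peak) force every
    chooser genotype to rank partner genotypes identically, so Kendall's
    W stays near 1.  Variable-peak unimodal preferences produce
    discordant rankings: W drops below 1 and a genotype x genotype
    interaction appears in the copulation-latency model.  The label is

    * ``open_ended_or_shared_peak`` — rankings concordant: W >= w_high
      and the concordance permutation test is significant at alpha;
    * ``variable_peak_unimodal`` — rankings discordant and the
      discordance statistically supported: W < w_high and the
      interaction LR test significant at alpha;
    * ``inconclusive`` — otherwise.

    W < w_high stands in for "W significantly below 1", which admits no
    exact test under cell-mean sampling noise.  The interaction test
    alone cannot separate the classes: variation in open-ended steepness
    produces a genuine magnitude (non-rank) G x G interaction even when
    every chooser ranks partners identically, so a high, significant W
    overrides a significant interaction.
    """
    eff = fit_copulation_model(trials, effects=("male_line:female_line",))
    inter = eff.table.loc[eff.table["effect"] == "male_line:female_line"].iloc[0]
    cells = cell_means(trials, "copulation_latency", mated_only=mated_only)
    conc = rank_concordance(cells, n_permutations=n_permutations, seed=seed)
    lev = levene_choosiness(trials, "copulation_latency", mated_only=mated_only)

    interaction_sig = inter["p_value"] < alpha
    w_is_high = conc.kendall_w >= w_high
    if w_is_high and conc.p_value < alpha:
        label = "open_ended_or_shared_peak"
    elif (not w_is_high) and interaction_sig:
        label = "variable_peak_unimodal"
    else:
        label = "inconclusive"
    return DiscriminationResult(
        label=label,
        interaction_p=float(inter["p_value"]),
        interaction_statistic=float(inter["statistic"]),
        kendall_w=conc.kendall_w,
        concordance_p=conc.p_value,
        levene=lev,
        alpha=alpha,
        w_high=w_high,
    )
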