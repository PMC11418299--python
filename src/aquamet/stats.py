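"""Staged statistical workflow for cohort endpoint tables.

The stages mirror standard practice in comparative physiology:

1. assumption gate — Shapiro-Wilk normality and Levene homoscedasticity;
   endpoints failing normality are log10-transformed and retested;
2. two-way factorial ANOVA (treatment x sex) with type III sums of squares
   under sum-to-zero coding; when the interaction is not significant the
   model is refit additively and main effects are reported with type II;
3. repeated-measures endpoints: linear mixed model with a per-fish random
   intercept, fixed-effect structure chosen by BIC over all candidate sets
   containing the main effects; Wald chi-square tests (with an F version)
   per term;
4. Tukey-HSD-adjusted contrasts on estimated marginal means, with the
   compact letter display used in figures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from scipy.stats import studentized_range
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ALPHA_DEFAULT = 0.05


@dataclass
class EndpointTable:
    """Tidy endpoint values: one row per fish (or fish x time point)."""

    data: pd.DataFrame  # columns: fish_id, sex, treatment, [time_point], value
    endpoint: str
    transform: str = "none"  # "none" | "log10"

    def with_log10(self) -> "EndpointTable":
        if (self.data["value"] <= 0).any():
            raise ValueError("log10 transform impossible: non-positive values")
        out = self.data.copy()
        out["value"] = np.log10(out["value"])
        return EndpointTable(out, self.endpoint, "log10")


@dataclass
class GateResult:
    shapiro_p: float
    levene_p: float
    transform: str
    shapiro_p_after: float
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class TermTest:
    term: str
    statistic: float
    df_num: float
    df_den: float
    p: float
    kind: str  # "F" | "chi2"


@dataclass
class StatResult:
    model: str
    anova_type: str
    terms: list[TermTest]
    transform: str = "none"
    alpha: float = ALPHA_DEFAULT
    contrasts: pd.DataFrame | None = None
    letters: dict[str, str] | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)
    _fit: object = None  # statsmodels results, kept for contrast computation
    _df_den: float = float("nan")

    def term(self, name: str) -> TermTest:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def assumption_gate(
    values: np.ndarray,
    groups: np.ndarray | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> GateResult:
    """Normality / homoscedasticity gate with log10 fallback.

    Returns Shapiro-Wilk (and, when ``groups`` is given, Levene) p-values;
    if normality fails at ``alpha`` and all values are positive the values
    are log10-transformed and retested, and the final transform recorded.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        return GateResult(np.nan, np.nan, "none", np.nan, ("degenerate: zero variance",))

    def levene_p(vals):
        if groups is None:
            return np.nan
        g = np.asarray(groups)
        samples = [vals[g == lv] for lv in np.unique(g)]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            return np.nan
        return float(sps.levene(*samples).pvalue)

    p_sw = float(sps.shapiro(x).pvalue)
    p_lev = levene_p(x)
    if p_sw >= alpha:
        return GateResult(p_sw, p_lev, "none", p_sw)
    if np.any(x <= 0):
        return GateResult(
            p_sw, p_lev, "none", np.nan, ("transform impossible: non-positive values",)
        )
    xl = np.log10(x)
    p_after = float(sps.shapiro(xl).pvalue)
    flags = () if p_after >= alpha else ("normality fails after log10",)
    return GateResult(p_sw, levene_p(xl), "log10", p_after, flags)


def apply_gate(table: EndpointTable, alpha: float = ALPHA_DEFAULT) -> tuple[EndpointTable, GateResult]:
    """Run the gate on an endpoint table and apply the chosen transform.

    The gate is applied per endpoint across all observations (a single
    transform decision per metric), with Levene groups formed from the
    treatment factor.
    """
    gate = assumption_gate(
        table.data["value"].to_numpy(),
        groups=table.data["treatment"].to_numpy(),
        alpha=alpha,
    )
    if gate.transform == "log10":
        return table.with_log10(), gate
    return table, gate


def _clean_term(name: str) -> str:
    parts = name.split(":")
    out = []
    for p in parts:
        p = p.strip()
        if p.startswith("C("):
            p = p[2:].split(",")[0].strip()
        out.append(p)
    return ":".join(out)


def _terms_from_anova(tab: pd.DataFrame, kind: str = "F") -> list[TermTest]:
    terms = []
    df_den = float(tab.loc["Residual", "df"]) if "Residual" in tab.index else np.nan
    for name, row in tab.iterrows():
        if name in ("Residual", "Intercept"):
            continue
        f = row["F"]
        p = row["PR(>F)"]
        if not np.isfinite(f) and abs(row["sum_sq"]) < 1e-12:
            f, p = 0.0, 1.0  # no effect variance at all
        terms.append(TermTest(_clean_term(name), float(f), float(row["df"]), df_den, float(p), kind))
    return terms


def factorial_anova(
    table: EndpointTable,
    factors: tuple[str, str] = ("treatment", "sex"),
    alpha: float = ALPHA_DEFAULT,
) -> StatResult:
    """Two-way factorial ANOVA with the interaction drop rule.

    Fits the full interaction model with type III sums of squares under
    sum-to-zero coding; if the interaction is not significant at ``alpha``
    the additive model is refit and main effects are reported with type II.
    On balanced designs the two types coincide exactly.
    """
    df = table.data
    a, b = factors
    for f in factors:
        counts = df.groupby(f, observed=True)["value"].count()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(f"factor {f!r} needs >=2 levels with >=2 observations")
    if (df.groupby([a, b], observed=True)["value"].count() == 0).any() or len(
        df.groupby([a, b], observed=True)
    ) < len(df[a].unique()) * len(df[b].unique()):
        raise ValueError("empty cell: type III ANOVA undefined")

    if np.ptp(df["value"].to_numpy(float)) == 0.0:
        # a constant response carries no effect variance at all: every F is 0
        nul = [
            TermTest(t, 0.0, np.nan, np.nan, 1.0, "F")
            for t in (a, b, f"{a}:{b}")
        ]
        return StatResult(
            model=f"value ~ {a} + {b}", anova_type="II", terms=nul,
            transform=table.transform, alpha=alpha,
            flags=("degenerate: zero response variance",),
        )

    full = smf.ols(f"value ~ C({a}, Sum) * C({b}, Sum)", data=df).fit()
    tab3 = anova_lm(full, typ=3)
    inter_name = [n for n in tab3.index if ":" in n][0]
    inter_row = tab3.loc[inter_name]
    inter_p = float(inter_row["PR(>F)"])
    inter_f = float(inter_row["F"])
    if not np.isfinite(inter_f) and abs(inter_row["sum_sq"]) < 1e-12:
        inter_f, inter_p = 0.0, 1.0
    inter_term = TermTest(
        _clean_term(inter_name), inter_f, float(inter_row["df"]),
        float(tab3.loc["Residual", "df"]), inter_p, "F",
    )

    if np.isfinite(inter_p) and inter_p < alpha:
        terms = _terms_from_anova(tab3.rename(columns={"sum_sq": "sum_sq"}))
        return StatResult(
            model=f"value ~ {a} * {b}", anova_type="III", terms=terms,
            transform=table.transform, alpha=alpha, _fit=full,
            _df_den=float(full.df_resid),
        )
    additive = smf.ols(f"value ~ C({a}, Sum) + C({b}, Sum)", data=df).fit()
    tab2 = anova_lm(additive, typ=2)
    tab2 = tab2.assign(df=tab2["df"])
    terms = _terms_from_anova(tab2)
    terms.append(inter_term)
    return StatResult(
        model=f"value ~ {a} + {b}", anova_type="II", terms=terms,
        transform=table.transform, alpha=alpha,
        flags=(f"interaction dropped (p={inter_p:.3f})",) if np.isfinite(inter_p) else ("interaction dropped",),
        _fit=additive, _df_den=float(additive.df_resid),
    )


def one_way_anova(table: EndpointTable, factor: str = "treatment",
                  alpha: float = ALPHA_DEFAULT) -> StatResult:
    """One-way ANOVA (used where small cells force dropping a factor)."""
    fit = smf.ols(f"value ~ C({factor}, Sum)", data=table.data).fit()
    tab = anova_lm(fit, typ=2)
    return StatResult(
        model=f"value ~ {factor}", anova_type="II",
        terms=_terms_from_anova(tab), transform=table.transform, alpha=alpha,
        _fit=fit, _df_den=float(fit.df_resid),
    )


# ---------------------------------------------------------------------------
# repeated-measures linear mixed model
# ---------------------------------------------------------------------------

_MAIN = "C(treatment, Sum) + C(sex, Sum) + C(time_point, Sum)"
_TWOWAY = (
    "C(treatment, Sum):C(time_point, Sum)",
    "C(sex, Sum):C(time_point, Sum)",
    "C(treatment, Sum):C(sex, Sum)",
)


def _candidate_formulas() -> list[str]:
    """All fixed-effect structures containing the three main effects plus any
    subset of the two-way interactions, and the full factorial."""
    out = []
    for r in range(len(_TWOWAY) + 1):
        for combo in itertools.combinations(_TWOWAY, r):
            out.append(" + ".join(("value ~ " + _MAIN,) + combo))
    out.append("value ~ C(treatment, Sum) * C(sex, Sum) * C(time_point, Sum)")
    return out


def _wald_terms(res, design_info, df_den: float) -> list[TermTest]:
    """Per-term Wald chi-square (type III under sum coding) on the fixed
    effects, with an F-statistic version at ``df_den`` denominator df."""
    k_fe = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    beta = np.asarray(res.fe_params)
    terms = []
    for name, sl in design_info.term_name_slices.items():
        if name == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        q = len(idx)
        p_chi2 = float(sps.chi2.sf(stat, q))
        terms.append(TermTest(_clean_term(name), stat, q, np.nan, p_chi2, "chi2"))
        terms.append(
            TermTest(
                _clean_term(name) + " [F]", stat / q, q, df_den,
                float(sps.f.sf(stat / q, q, df_den)), "F",
            )
        )
    return terms


def repeated_measures_lmm(
    table: EndpointTable,
    alpha: float = ALPHA_DEFAULT,
    candidates: list[str] | None = None,
) -> StatResult:
    """Linear mixed model with a per-fish random intercept.

    Candidate fixed-effect structures (all containing the treatment, sex and
    time-point main effects) are fit by maximum likelihood and ranked by
    BIC; the winner is refit by REML and its terms tested with Wald
    chi-square statistics (an F version with containment-style denominator
    df is emitted alongside, since software conventions differ).  A singular
    random-intercept fit is flagged and the model falls back to ordinary
    least squares.
    """
    df = table.data.dropna(subset=["value"]).copy()
    if df["time_point"].nunique() < 2:
        raise ValueError("repeated-measures model needs >=2 time points")
    candidates = candidates or _candidate_formulas()

    bics = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in candidates:
            try:
                m = smf.mixedlm(f, data=df, groups=df["fish_id"])
                r = m.fit(reml=False)
                bics.append((r.bic if np.isfinite(r.bic) else np.inf, f))
            except Exception:
                bics.append((np.inf, f))
    bics.sort(key=lambda t: t[0])
    best_formula = bics[0][1]

    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(best_formula, data=df, groups=df["fish_id"])
        res = model.fit(reml=True)
    var_resid = float(res.scale)
    var_re = float(np.asarray(res.cov_re).ravel()[0])
    # a between-fish variance below 0.1% of the residual variance is an
    # effectively boundary (singular) fit
    singular = var_re < 1e-3 * max(var_resid, 1e-12)
    n_groups = df["fish_id"].nunique()
    k_fe = len(res.fe_params)
    df_den = max(len(df) - k_fe - n_groups + 1, 1)

    if singular:
        flags.append("singular random-intercept fit; fixed-effects fallback")
        ols_res = smf.ols(best_formula, data=df).fit()
        design_info = ols_res.model.data.design_info
        terms = []
        for name, sl in design_info.term_name_slices.items():
            if name == "Intercept":
                continue
            idx = np.arange(len(ols_res.params))[sl]
            L = np.eye(len(ols_res.params))[idx]
            ft = ols_res.f_test(L)
            q = len(idx)
            terms.append(TermTest(_clean_term(name), float(ft.fvalue) * q, q, np.nan,
                                  float(sps.chi2.sf(float(ft.fvalue) * q, q)), "chi2"))
            terms.append(TermTest(_clean_term(name) + " [F]", float(ft.fvalue), q,
                                  float(ols_res.df_resid), float(ft.pvalue), "F"))
        return StatResult(
            model=best_formula + " (OLS fallback)", anova_type="III (Wald)",
            terms=terms, transform=table.transform, alpha=alpha,
            flags=tuple(flags), _fit=ols_res, _df_den=float(ols_res.df_resid),
        )

    design_info = model.data.design_info
    terms = _wald_terms(res, design_info, df_den)
    return StatResult(
        model=best_formula + " + (1|fish_id)", anova_type="III (Wald)",
        terms=terms, transform=table.transform, alpha=alpha,
        flags=tuple(flags), _fit=res, _df_den=float(df_den),
    )


# ---------------------------------------------------------------------------
# Tukey-adjusted contrasts on estimated marginal means
# ---------------------------------------------------------------------------


def _emm_rows(fit, data: pd.DataFrame, margin: str) -> tuple[list[str], np.ndarray]:
    """Contrast rows producing estimated marginal means of ``margin``:
    for each level, the design row averaged over the observed levels of the
    other factors (equally weighted reference grid)."""
    model = fit.model
    design_info = model.data.design_info
    factor_cols = [c for c in ("treatment", "sex", "time_point") if c in data.columns]
    levels = {c: sorted(data[c].astype(str).unique()) for c in factor_cols}
    if margin not in levels:
        raise ValueError(f"margin {margin!r} not among model factors")
    margin_levels = levels[margin]
    others = [c for c in factor_cols if c != margin]
    rows = []
    for lv in margin_levels:
        combos = list(itertools.product(*[levels[c] for c in others])) or [()]
        grid = pd.DataFrame(
            [{margin: lv, **dict(zip(others, combo))} for combo in combos]
        )
        X = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
        rows.append(X.mean(axis=0))
    return margin_levels, np.vstack(rows)


def tukey_contrasts(result: StatResult, margin: str, data: pd.DataFrame | None = None,
                    alpha: float | None = None) -> StatResult:
    """All pairwise differences between the estimated marginal means of
    ``margin``, with family-wise Tukey-HSD adjustment (studentized range)
    and a compact letter display.

    With two levels the adjusted p equals the unadjusted pairwise p.
    Returns a copy of ``result`` with ``contrasts`` and ``letters`` filled.
    """
    fit = result._fit
    if fit is None:
        raise ValueError("result carries no fitted model")
    alpha = result.alpha if alpha is None else alpha
    if data is None:
        data = fit.model.data.frame
    levels, L = _emm_rows(fit, data, margin)
    if len(levels) < 2:
        raise ValueError(f"margin {margin!r} has a single level: no contrasts")
    beta = np.asarray(getattr(fit, "fe_params", fit.params))
    k = len(beta)
    V = np.asarray(fit.cov_params())[:k, :k]
    L = L[:, :k]
    est = L @ beta
    df_den = result._df_den if np.isfinite(result._df_den) else 1e6
    kk = len(levels)
    rows = []
    sig = np.zeros((kk, kk), dtype=bool)
    for i, j in itertools.combinations(range(kk), 2):
        c = L[i] - L[j]
        diff = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        q = abs(diff) / se * np.sqrt(2.0) if se > 0 else np.inf
        p = float(studentized_range.sf(q, kk, df_den)) if se > 0 else 0.0
        sig[i, j] = sig[j, i] = p < alpha
        rows.append(
            {
                "contrast": f"{levels[i]} - {levels[j]}",
                "estimate": diff,
                "se": se,
                "df": df_den,
                "p_tukey": p,
            }
        )
    letters = letter_display(levels, sig)
    out = StatResult(
        model=result.model, anova_type=result.anova_type, terms=result.terms,
        transform=result.transform, alpha=result.alpha,
        contrasts=pd.DataFrame(rows),
        letters=letters, flags=result.flags, _fit=fit, _df_den=result._df_den,
    )
    return out


def letter_display(levels: list[str], sig: np.ndarray) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different (insert-and-absorb algorithm)."""
    sets: list[set[int]] = [set(range(len(levels)))]
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            if not sig[i, j]:
                continue
            new_sets = []
            for s in sets:
                if i in s and j in s:
                    new_sets.extend([s - {i}, s - {j}])
                else:
                    new_sets.append(s)
            # absorb subsets and drop empties
            new_sets = [s for s in new_sets if s]
            sets = [
                s
                for s in new_sets
                if not any(s < t for t in new_sets)
            ]
            # deduplicate
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    sets.sort(key=lambda s: (min(s), -len(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, s in zip(alphabet, sets):
        for i in sorted(s):
            out[levels[i]] += letter
    return out


def group_summary(
    df: pd.DataFrame, value: str = "value", by: tuple[str, ...] = ("treatment",)
) -> pd.DataFrame:
    """Cell means with standard errors, 'mean ± s.e.m.' style.

    Cells with a single observation get an undefined (NaN) s.e.m. and a flag.
    """
    g = df.groupby(list(by), observed=True)[value]
    out = g.agg(n="count", mean="mean", sem="sem").reset_index()
    out["flag"] = np.where(out["n"] < 2, "sem undefined (n=1)", "")
    return out


def format_stat_result(name: str, result: StatResult) -> str:
    lines = [f"[{name}] model: {result.model}  (ANOVA type {result.anova_type}, "
             f"transform: {result.transform})"]
    for t in result.terms:
        stat = "chi2" if t.kind == "chi2" else "F"
        dd = "" if not np.isfinite(t.df_den) else f",{t.df_den:.0f}"
        lines.append(
            f"    {t.term}: {stat}({t.df_num:.0f}{dd}) = {t.statistic:.3f}, p = {t.p:.4f}"
        )
    for fl in result.flags:
        lines.append(f"    note: {fl}")
    if result.letters:
        disp = ", ".join(f"{k}: {v}" for k, v in result.letters.items())
        lines.append(f"    letters: {disp}")
    return "\n".join(lines)
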