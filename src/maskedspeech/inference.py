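"""Linear mixed-effects analysis of RAU accuracy scores.

The statistical stage mirrors the analysis convention of closed-set
speech-perception studies: RAU-transformed accuracy is modeled with fixed
effects and interactions of mask condition, modality and listener group,
plus a random intercept per subject.  Non-significant interactions are
eliminated backward (least-significant highest-order term first) until all
retained interactions are significant; reference levels are re-set as
needed for post hoc contrasts; between-group accuracy comparisons outside
the factorial design use Welch's unequal-variance t-test.

Models are fitted by REML via ``statsmodels`` MixedLM.  Term-level F
statistics are Wald tests on the term's coefficient block; the denominator
degrees of freedom use a residual-style approximation,
``n_obs - rank(X) - (n_subjects - 1)``, which for designs of this size is
within a few counts of the Satterthwaite value and is documented as
approximate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_accuracy_model",
    "posthoc_contrasts",
    "welch_group_test",
]

DEFAULT_REFERENCES = {"mask": "none", "modality": "AO", "group": "CNH"}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit.

    ``factors`` enter as a full factorial (all interactions up to the full
    order); ``covariates`` enter as additive terms; ``extra_terms`` are
    patsy-style term strings appended verbatim (e.g. stated three-way
    interactions with age).  ``references`` pins the reference level of each
    categorical factor.
    """

    response: str = "rau"
    factors: tuple[str, ...] = ("mask", "modality", "group")
    covariates: tuple[str, ...] = ()
    extra_terms: tuple[str, ...] = ()
    subject: str = "subject_id"
    alpha: float = 0.05
    references: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    eliminate: bool = True
    max_order: int | None = None  # cap interaction order; None = full factorial


def _factor_code(name: str, references: dict) -> str:
    ref = references.get(name)
    if ref is None:
        return f"C({name})"
    return f"C({name}, Treatment('{ref}'))"


def _all_terms(spec: ModelSpec) -> list[tuple[str, ...]]:
    """Factorial terms as sorted tuples of factor names, mains first."""
    top = len(spec.factors) if spec.max_order is None else spec.max_order
    terms = []
    for order in range(1, min(top, len(spec.factors)) + 1):
        terms.extend(itertools.combinations(spec.factors, order))
    return terms


def _term_string(term: tuple[str, ...], spec: ModelSpec) -> str:
    return ":".join(_factor_code(f, spec.references) for f in term)


def _build_formula(terms: list[tuple[str, ...]], spec: ModelSpec) -> str:
    parts = [_term_string(t, spec) for t in terms]
    parts += list(spec.covariates)
    parts += list(spec.extra_terms)
    return f"{spec.response} ~ " + " + ".join(parts)


@dataclass
class FittedModel:
    """A fitted mixed model plus its term tests and elimination history."""

    spec: ModelSpec
    formula: str
    terms: list[tuple[str, ...]]
    coefficients: pd.DataFrame  # term, estimate, se, t, df, p
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    random_intercept_var: float
    residual_var: float
    elimination_trace: list[tuple[str, float]]
    converged: bool
    data: pd.DataFrame
    result: object = None  # statsmodels MixedLMResults

    def term_pvalue(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["p"].iloc[0])


def _fit_mixedlm(formula: str, data: pd.DataFrame, subject: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(formula, data, groups=data[subject],
                                        re_formula="1")
        try:
            res = model.fit(reml=True, method="lbfgs")
            if not res.converged:
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            res = model.fit(reml=True, method="powell", maxiter=500)
    return model, res


def _term_tests(model, res, data: pd.DataFrame, subject: str,
                spec: ModelSpec) -> pd.DataFrame:
    """Wald F test per model term, with approximate denominator df."""
    design_info = model.data.design_info
    k_fe = len(res.fe_params)
    n_obs = len(data)
    n_subj = data[subject].nunique()
    ddf = max(n_obs - k_fe - (n_subj - 1), 1)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    beta = np.asarray(res.fe_params)
    rows = []
    for term_name in design_info.term_names:
        if term_name == "Intercept":
            continue
        sl = design_info.term_name_slices[term_name]
        idx = np.arange(k_fe)[sl]
        b = beta[idx]
        v = cov[np.ix_(idx, idx)]
        q = len(idx)
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            chi2 = float(b @ np.linalg.pinv(v) @ b)
        fstat = chi2 / q
        rows.append({
            "term": term_name,
            "F": fstat,
            "df_num": q,
            "df_den": ddf,
            "p": float(_st.f.sf(fstat, q, ddf)),
        })
    return pd.DataFrame(rows)


def _coef_table(res, data: pd.DataFrame, subject: str) -> pd.DataFrame:
    k_fe = len(res.fe_params)
    n_obs = len(data)
    n_subj = data[subject].nunique()
    ddf = max(n_obs - k_fe - (n_subj - 1), 1)
    est = np.asarray(res.fe_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # exact-fit cov can hit 0
        se = np.asarray(res.bse_fe)
    t = est / se
    return pd.DataFrame({
        "term": list(res.fe_params.index),
        "estimate": est,
        "se": se,
        "t": t,
        "df": ddf,
        "p": 2 * _st.t.sf(np.abs(t), ddf),
    })


def fit_accuracy_model(scores: pd.DataFrame, spec: ModelSpec | None = None) -> FittedModel:
    """REML mixed-model fit with backward elimination of interactions.

    Elimination considers only interaction terms that are not nested inside
    a retained higher-order interaction; at each step the least significant
    such term of the highest order present is dropped if its p-value
    exceeds ``spec.alpha``, and the model is refitted.  Main effects are
    never removed.  The path is deterministic given the data.
    """
    spec = spec or ModelSpec()
    for col in (spec.response, spec.subject, *spec.factors, *spec.covariates):
        if col not in scores.columns:
            raise ValueError(f"score table is missing column {col!r}")
    if scores.groupby(spec.subject).ngroups < 2:
        raise ValueError("need at least 2 subjects")
    data = scores.copy()

    terms = [t for t in _all_terms(spec)
             if all(data[f].nunique() > 1 for f in t)]
    trace: list[tuple[str, float]] = []
    while True:
        formula = _build_formula(terms, spec)
        model, res = _fit_mixedlm(formula, data, spec.subject)
        anova = _term_tests(model, res, data, spec.subject, spec)
        if not spec.eliminate:
            break
        interactions = [t for t in terms if len(t) > 1]
        # only terms not nested within a retained higher-order interaction
        maximal = [t for t in interactions
                   if not any(set(t) < set(u) for u in interactions)]
        if not maximal:
            break
        candidates = []
        for t in maximal:
            p = anova.loc[anova["term"] == _term_string(t, spec), "p"]
            if len(p) and float(p.iloc[0]) > spec.alpha:
                candidates.append((t, float(p.iloc[0])))
        if not candidates:
            break
        top_order = max(len(t) for t, _ in candidates)
        drop, p_drop = max(((t, p) for t, p in candidates if len(t) == top_order),
                           key=lambda tp: tp[1])
        trace.append((_term_string(drop, spec), p_drop))
        terms = [t for t in terms if t != drop]

    var_re = float(np.asarray(res.cov_re).ravel()[0])
    return FittedModel(
        spec=spec,
        formula=formula,
        terms=terms,
        coefficients=_coef_table(res, data, spec.subject),
        anova=anova,
        random_intercept_var=var_re,
        residual_var=float(res.scale),
        elimination_trace=trace,
        converged=bool(res.converged),
        data=data,
        result=res,
    )


def posthoc_contrasts(model: FittedModel, references: dict) -> pd.DataFrame:
    """Coefficient table of the retained model refitted under new references.

    Re-leveling changes which simple effects the coefficients express (the
    fit itself is equivalent); this reproduces the convention of varying
    the reference condition for post hoc comparisons.  No multiplicity
    correction is applied by default, matching the source analyses; apply
    one downstream if desired.
    """
    spec = model.spec
    for factor, level in references.items():
        if factor not in spec.factors:
            raise ValueError(f"unknown factor {factor!r}")
        if level not in set(model.data[factor]):
            raise ValueError(f"factor {factor!r} has no level {level!r}")
    new_refs = dict(spec.references)
    new_refs.update(references)
    new_spec = ModelSpec(
        response=spec.response, factors=spec.factors,
        covariates=spec.covariates, extra_terms=spec.extra_terms,
        subject=spec.subject, alpha=spec.alpha, references=new_refs,
        eliminate=False, max_order=spec.max_order,
    )
    formula = _build_formula(model.terms, new_spec)
    _, res = _fit_mixedlm(formula, model.data, spec.subject)
    return _coef_table(res, model.data, spec.subject)


def welch_group_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and
    a two-sided p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2 * _st.t.sf(abs(t), df)
    return float(t), float(df), float(p)
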