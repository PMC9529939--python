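"""Burden regressions: case-control, sleep duration, and insomnia traits.

Four model families are fit over per-individual burden profiles joined to
phenotypes on sample id. All share the same four burden predictors —
DEL_target, DUP_target, DEL_other, DUP_other — built from one of three
weightings (gene count, sum 1/LOEUF, sum DS) for one target gene set
(circadian, insomnia, or their union):

* Model 1: logistic regression of case status on gene-count burden.
* Model 2: the same with 1/LOEUF- (or DS-) weighted burden.
* Model 3: linear regression of sleep duration in minutes.
* Model 4: proportional-odds (cumulative-logit) regression of the 0-2
  insomnia-trait count.

Case-control fits offer a flat prior (plain maximum likelihood, useful
for closed-form checks) and a weakly-informative mode: a MAP fit under
independent zero-centered Student-t priors (df 3, scale 2.5) on
standardized coefficients, which keeps estimates finite under the sparse
carrier counts and complete separation that rare-CNV designs produce.
Within-family correlation is handled by cluster-robust standard errors,
a GEE exchangeable fit, or a variational random-intercept fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, SeparationError
from .io_tables import is_missing

BURDEN_TERMS = ("DEL_target", "DUP_target", "DEL_other", "DUP_other")
_METRIC_OF_WEIGHTING = {"count": "n_genes", "inv_loeuf": "inv_loeuf", "ds": "ds"}
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, burden weighting, target set, covariates."""

    model_id: int = 1
    outcome: str = "case_status"
    weighting: str = "count"
    target_set: str = "union"
    covariates: tuple[str, ...] = ()
    cluster_by: str | None = None
    cluster_method: str = "robust"  # robust | gee_exchangeable | random_intercept
    prior_mode: str = "flat"        # flat | weakly_informative
    outcome_scale: str = "minutes"  # minutes | z (model 3 only)

    def __post_init__(self):
        if self.model_id not in (1, 2, 3, 4):
            raise ConfigError(f"model_id must be 1-4, got {self.model_id}")
        if self.weighting not in _METRIC_OF_WEIGHTING:
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.target_set not in ("circadian", "insomnia", "union"):
            raise ConfigError(f"unknown target_set {self.target_set!r}")
        if self.prior_mode not in ("flat", "weakly_informative"):
            raise ConfigError(f"unknown prior_mode {self.prior_mode!r}")
        if self.cluster_method not in ("robust", "gee_exchangeable", "random_intercept"):
            raise ConfigError(f"unknown cluster_method {self.cluster_method!r}")
        expected = {1: "case_status", 2: "case_status", 3: "sleep_duration_min", 4: "insomnia_traits"}
        if self.outcome != expected[self.model_id]:
            raise ConfigError(
                f"model {self.model_id} requires outcome {expected[self.model_id]!r}, got {self.outcome!r}"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted coefficient with Wald 95% interval.

    beta is in log-odds (models 1/2), minutes per unit burden (model 3),
    or log cumulative-odds (model 4); or_value = exp(beta) where the
    scale is a log-odds.
    """

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    or_value: float | None = None
    significant: bool | None = None


def score_insomnia(item_falling_asleep, item_awakenings):
    """Count of endorsed insomnia items; None unless both items answered."""

    def parse(v):
        if is_missing(v):
            return None
        s = str(v).strip().lower()
        if s in ("yes", "y", "1", "true"):
            return 1
        if s in ("no", "n", "0", "false"):
            return 0
        return None

    a, b = parse(item_falling_asleep), parse(item_awakenings)
    if a is None or b is None:
        return None
    return a + b


def score_insomnia_frame(phenotypes: pd.DataFrame) -> pd.Series:
    """Vectorized insomnia-trait scoring from the two item columns."""
    vals = [
        score_insomnia(a, b)
        for a, b in zip(phenotypes["item_falling_asleep"], phenotypes["item_awakenings"])
    ]
    return pd.Series(pd.array(vals, dtype="Int64"), index=phenotypes.index, name="insomnia_traits")


def _wald(term, beta, se, or_scale: bool):
    z = beta / se if se > 0 else math.inf * np.sign(beta) if beta else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return EffectEstimate(
        term=term,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        p=float(p),
        or_value=float(np.exp(beta)) if or_scale else None,
    )


def build_design(
    profiles: pd.DataFrame, phenotypes: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, pd.Series | None]:
    """Join profiles to phenotypes and assemble (y, X, cluster groups).

    X carries the four burden terms (named by their role, not the raw
    profile column) followed by covariates; no constant column. Rows with
    a missing outcome or covariate are dropped. Zero-variance columns are
    dropped with a warning.
    """
    ph = phenotypes.copy()
    ph["sample_id"] = ph["sample_id"].astype(str)
    missing = set(ph["sample_id"]) ^ set(profiles.index.astype(str))
    if missing:
        raise ConfigError(
            f"profiles and phenotypes must cover the same samples; mismatched ids: {sorted(missing)[:5]}"
        )
    metric = _METRIC_OF_WEIGHTING[spec.weighting]
    df = ph.set_index("sample_id")
    for term in BURDEN_TERMS:
        df[term] = profiles[f"{term}_{metric}"].reindex(df.index)

    if spec.outcome == "insomnia_traits" and "insomnia_traits" not in df.columns:
        df["insomnia_traits"] = score_insomnia_frame(ph).to_numpy()

    cols = list(BURDEN_TERMS) + list(spec.covariates)
    for c in cols + [spec.outcome]:
        if c not in df.columns:
            raise ConfigError(f"column {c!r} absent from the joined table")
    keep = df[[spec.outcome] + cols].apply(pd.to_numeric, errors="coerce")
    mask = keep[spec.outcome].notna() & keep[list(spec.covariates)].notna().all(axis=1) if spec.covariates else keep[spec.outcome].notna()
    keep = keep[mask]
    y = keep[spec.outcome].astype(float)
    X = keep[cols].astype(float)
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            warnings.warn(f"predictor {c!r} has zero variance; dropped", stacklevel=2)
            X = X.drop(columns=[c])
    groups = None
    if spec.cluster_by:
        groups = df.loc[keep.index, spec.cluster_by]
    return y, X, groups


# ---------------------------------------------------------------- logistic


def _map_logistic(y: np.ndarray, X: np.ndarray, scale=2.5, intercept_scale=10.0, df=3.0):
    """MAP logistic fit under independent Student-t priors on standardized
    coefficients. Returns (coef, cov) on the standardized-with-intercept
    scale; column 0 of X must be the constant."""
    n, k = X.shape
    s = np.full(k, scale)
    s[0] = intercept_scale

    def neg_post(b):
        eta = X @ b
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        lp = -0.5 * (df + 1.0) * np.log1p(b**2 / (df * s**2)).sum()
        return -(ll + lp)

    def grad(b):
        p = 1.0 / (1.0 + np.exp(-(X @ b)))
        g_ll = X.T @ (y - p)
        g_lp = -(df + 1.0) * b / (df * s**2 + b**2)
        return -(g_ll + g_lp)

    res = optimize.minimize(neg_post, np.zeros(k), jac=grad, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    b = res.x
    p = 1.0 / (1.0 + np.exp(-(X @ b)))
    w = p * (1 - p)
    h_prior = (df + 1.0) * (df * s**2 - b**2) / (df * s**2 + b**2) ** 2
    H = X.T @ (X * w[:, None]) + np.diag(h_prior)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return b, cov


def fit_case_control(
    profiles: pd.DataFrame, phenotypes: pd.DataFrame, spec: ModelSpec
) -> list[EffectEstimate]:
    """Models 1 and 2: logistic regression of case status on burden terms.

    prior_mode "flat" is the maximum-likelihood fit (and raises
    SeparationError under complete separation); "weakly_informative" is a
    MAP fit under Student-t(3, 2.5) priors on standardized predictors.
    When cluster_by is set, within-family correlation is handled per
    cluster_method.
    """
    import statsmodels.api as sm

    if spec.model_id not in (1, 2):
        raise ConfigError("fit_case_control requires model_id 1 or 2")
    y, X, groups = build_design(profiles, phenotypes, spec)
    uniq = set(np.unique(y))
    if not uniq <= {0.0, 1.0}:
        raise ConfigError(f"case_status must be binary 0/1, found values {sorted(uniq)[:5]}")

    if X.shape[1] == 0:
        frac = float(y.mean())
        beta0 = math.log(frac / (1 - frac))
        se0 = math.sqrt(1.0 / (len(y) * frac * (1 - frac)))
        return [_wald("intercept", beta0, se0, or_scale=True)]

    Xc = sm.add_constant(X, prepend=True, has_constant="raise")
    terms = ["intercept"] + list(X.columns)

    if spec.prior_mode == "weakly_informative":
        mu = X.mean(axis=0).to_numpy()
        sd = X.std(axis=0, ddof=0).to_numpy()
        Z = np.column_stack([np.ones(len(y)), (X.to_numpy() - mu) / sd])
        b_std, cov_std = _map_logistic(y.to_numpy(), Z)
        # back-transform: orig = T @ std
        k = X.shape[1]
        T = np.zeros((k + 1, k + 1))
        T[0, 0] = 1.0
        T[0, 1:] = -mu / sd
        for j in range(k):
            T[j + 1, j + 1] = 1.0 / sd[j]
        b = T @ b_std
        cov = T @ cov_std @ T.T
        ses = np.sqrt(np.diag(cov))
        return [_wald(t, bi, si, or_scale=True) for t, bi, si in zip(terms, b, ses)]

    if groups is not None and spec.cluster_method == "gee_exchangeable":
        model = sm.GEE(y, Xc, groups=groups, family=sm.families.Binomial(),
                       cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit()
        return [
            _wald(t, res.params.iloc[i], res.bse.iloc[i], or_scale=True)
            for i, t in enumerate(terms)
        ]
    if groups is not None and spec.cluster_method == "random_intercept":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        codes, _ = pd.factorize(groups)
        vc = pd.get_dummies(codes).to_numpy(dtype=float)
        model = BinomialBayesMixedGLM(
            y.to_numpy(), Xc.to_numpy(), exog_vc=vc, ident=np.zeros(vc.shape[1], dtype=int)
        )
        res = model.fit_vb()
        b = res.fe_mean
        ses = res.fe_sd
        return [_wald(t, b[i], ses[i], or_scale=True) for i, t in enumerate(terms)]

    model = sm.Logit(y, Xc)
    try:
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    except Exception as e:  # statsmodels raises PerfectSeparation* or fails to converge
        raise SeparationError(
            "flat-prior logistic fit failed (likely complete separation); "
            "retry with prior_mode='weakly_informative'"
        ) from e
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 25:
        raise SeparationError(
            "flat-prior logistic estimates diverged (complete separation); "
            "retry with prior_mode='weakly_informative'"
        )
    if groups is not None:  # cluster-robust sandwich standard errors
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10,
                        cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
    return [
        _wald(t, res.params.iloc[i], res.bse.iloc[i], or_scale=True)
        for i, t in enumerate(terms)
    ]


# ------------------------------------------------------------------ linear


def fit_sleep_duration(
    profiles: pd.DataFrame, phenotypes: pd.DataFrame, spec: ModelSpec
) -> list[EffectEstimate]:
    """Model 3: ordinary least squares on sleep duration.

    Coefficients are minutes per unit burden; with outcome_scale="z" the
    outcome is standardized first and coefficients are z-units.
    """
    import statsmodels.api as sm

    if spec.model_id != 3:
        raise ConfigError("fit_sleep_duration requires model_id 3")
    y, X, groups = build_design(profiles, phenotypes, spec)
    if spec.outcome_scale == "z":
        sd = y.std(ddof=0)
        y = (y - y.mean()) / (sd if sd > 0 else 1.0)
    if len(y) <= X.shape[1] + 1:
        raise ConfigError(f"n={len(y)} too small for {X.shape[1]} predictors")
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    terms = ["intercept"] + list(X.columns)
    if groups is not None:
        res = sm.OLS(y, Xc).fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
    else:
        res = sm.OLS(y, Xc).fit()
    return [
        _wald(t, res.params.iloc[i], res.bse.iloc[i], or_scale=False)
        for i, t in enumerate(terms)
    ]


# ----------------------------------------------------------------- ordinal


def fit_insomnia(
    profiles: pd.DataFrame, phenotypes: pd.DataFrame, spec: ModelSpec
) -> list[EffectEstimate]:
    """Model 4: proportional-odds regression of the 0-2 insomnia count.

    Cumulative-logit with two thresholds and slopes shared across levels;
    individuals with a missing score are excluded. Thresholds are
    reported as terms "threshold_1" and "threshold_2" on the cumulative
    log-odds scale; slope or_value is the per-unit cumulative odds ratio.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if spec.model_id != 4:
        raise ConfigError("fit_insomnia requires model_id 4")
    y, X, groups = build_design(profiles, phenotypes, spec)
    if groups is not None:
        warnings.warn(
            "family clustering is not supported for the proportional-odds model; "
            "fitting observations as independent", stacklevel=2
        )
    levels = np.unique(y)
    if not set(levels) <= {0.0, 1.0, 2.0}:
        raise ConfigError(f"insomnia_traits must be 0/1/2, found {sorted(set(levels))[:5]}")
    if len(levels) < 3:
        warnings.warn(
            f"outcome levels {sorted(set(levels))} only; the cumulative model "
            "collapses toward a binary logistic", stacklevel=2
        )

    if X.shape[1] == 0:
        # intercept-only MLE: thresholds are logits of cumulative frequencies
        n = len(y)
        out = []
        cum = 0.0
        for j, lev in enumerate(sorted(levels)[:-1], start=1):
            cum += float((y == lev).mean())
            tau = math.log(cum / (1 - cum))
            se = math.sqrt(1.0 / (n * cum * (1 - cum)))
            out.append(_wald(f"threshold_{j}", tau, se, or_scale=False))
        return out

    model = OrderedModel(y.astype(int), X, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=0)
    k = X.shape[1]
    out = [
        _wald(term, res.params.iloc[i], res.bse.iloc[i], or_scale=True)
        for i, term in enumerate(X.columns)
    ]
    # thresholds: first is the raw parameter; later ones add exp(increment)
    cov = np.asarray(res.cov_params())
    tau = float(res.params.iloc[k])
    out.append(_wald("threshold_1", tau, float(res.bse.iloc[k]), or_scale=False))
    for j in range(1, len(np.unique(y)) - 1):
        inc = float(res.params.iloc[k + j])
        tau = tau + math.exp(inc)
        grad = np.zeros(len(res.params))
        grad[k] = 1.0
        for m in range(1, j + 1):
            grad[k + m] = math.exp(float(res.params.iloc[k + m]))
        se = float(np.sqrt(grad @ cov @ grad))
        out.append(_wald(f"threshold_{j + 1}", tau, se, or_scale=False))
    return out


# --------------------------------------------------------------- dispatch


def fit_model(
    profiles: pd.DataFrame, phenotypes: pd.DataFrame, spec: ModelSpec
) -> list[EffectEstimate]:
    """Fit whichever of the four models the ModelSpec selects."""
    if spec.model_id in (1, 2):
        return fit_case_control(profiles, phenotypes, spec)
    if spec.model_id == 3:
        return fit_sleep_duration(profiles, phenotypes, spec)
    return fit_insomnia(profiles, phenotypes, spec)


def bonferroni_gate(
    estimates: list[EffectEstimate], alpha: float = 0.05, n_tests: int = 3
) -> list[EffectEstimate]:
    """Flag estimates significant at the Bonferroni-corrected level.

    The default corrects for the three burden weightings tested per model
    family (count, 1/LOEUF, DS): alpha/n = 0.05/3, i.e. p < 0.017.
    """
    cut = alpha / n_tests
    return [
        EffectEstimate(
            term=e.term, beta=e.beta, se=e.se, ci_low=e.ci_low, ci_high=e.ci_high,
            p=e.p, or_value=e.or_value, significant=bool(e.p < cut),
        )
        for e in estimates
    ]


def estimates_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy one-row-per-term table (term, beta, se, or, ci, p, significant)."""
    return pd.DataFrame(
        {
            "term": [e.term for e in estimates],
            "beta": [e.beta for e in estimates],
            "se": [e.se for e in estimates],
            "or": [e.or_value for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "p": [e.p for e in estimates],
            "significant": [e.significant for e in estimates],
        }
    )
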