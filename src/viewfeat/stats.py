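"""Correlation and stepwise-regression inference for the view-feature study.

The analysis table has one row per participant: averaged low-level
visual features, subjective view ratings, demographics, and the two
behavioral outcomes.  Inference proceeds in the study's order:

* Spearman rank correlations (tie-corrected, t-based two-sided p) among
  features and ratings;
* bidirectional stepwise OLS selection by AIC, with optional forced
  terms that are never dropped;
* two hierarchical designs: (A) ratings explained by the 12 usable
  features, robustness-checked by a second stepwise pass over control
  variables with the stage-1 features forced; (B) each behavioral
  outcome on a forced block of 7 controls plus stepwise selection over
  subjective ratings and features.

Objective brightness (mean and SD) is excluded from the candidate
feature set by default: brightness of uncontrolled photographs varies
with camera settings and is unreliable as an exposure measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

#: features entering the models ("usable" = the 14 minus objective brightness)
BRIGHTNESS_FEATURES = ("bright_mean", "bright_sd")
LLVF_USABLE = (
    "hue_mean",
    "hue_sd",
    "sat_mean",
    "sat_sd",
    "green_ratio",
    "blue_ratio",
    "sky_ratio",
    "edge_density",
    "straight_edge_density",
    "nonstraight_edge_density",
    "entropy",
    "fractal_dim",
)

#: forced control block of the outcome models (design B block 1)
CONTROL_VARS = (
    "age",
    "sex",
    "income",
    "time_home_pre",
    "time_home_covid",
    "living_space",
    "image_count",
)

#: subjective window-view ratings offered to design B's stepwise block
RATING_VARS = (
    "pct_nature",
    "pct_manmade",
    "quality",
    "brightness_rating",
    "green_visibility",
    "vegetation_rooms",
    "long_distance_view",
)

_AIC_TIE_TOL = 1e-8


class RankDeficientError(ValueError):
    """Raised when the design matrix is collinear."""


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Encode sex as a binary indicator (female = 1) for modeling.

    Must be applied after the diverse-sex exclusion; any remaining
    non-binary level raises.
    """
    table = table.copy()
    if "sex" in table.columns and table["sex"].dtype == object:
        levels = set(table["sex"].dropna().unique())
        if not levels <= {"male", "female"}:
            raise ValueError(
                f"sex must be binary after exclusions, found levels {sorted(levels)}"
            )
        table["sex"] = (table["sex"] == "female").astype(float)
    return table


def exclude_participants(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Apply the study's exclusion rules.

    Participants with diverse sex are removed (a factor level with one
    member would distort the models); when ``columns`` is given, rows
    with missing data on any of those columns are dropped (per-analysis
    listwise deletion).
    """
    out = table
    if "sex" in out.columns and out["sex"].dtype == object:
        out = out[out["sex"] != "diverse"]
    if columns:
        out = out.dropna(subset=list(columns))
    return out.copy()


@dataclass
class SpearmanMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    undefined: set = field(default_factory=set)


def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> SpearmanMatrix:
    """Tie-corrected Spearman correlation matrix with two-sided p-values.

    p-values come from the t approximation t = rho * sqrt((n-2)/(1-rho^2))
    on n - 2 degrees of freedom.  Zero-variance variables yield NaN
    entries and are reported in ``undefined``.
    """
    data = table[list(variables)].dropna()
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 complete rows for correlation")
    k = len(variables)
    rho = np.ones((k, k))
    pval = np.zeros((k, k))
    undefined: set = set()
    for i in range(k):
        for j in range(i + 1, k):
            x = data.iloc[:, i].to_numpy(float)
            y = data.iloc[:, j].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                if np.ptp(x) == 0:
                    undefined.add(variables[i])
                if np.ptp(y) == 0:
                    undefined.add(variables[j])
                continue
            r, p = scipy.stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = list(variables)
    return SpearmanMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pval, index=idx, columns=idx),
        n=n,
        undefined=undefined,
    )


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """Full Gaussian-likelihood AIC of an OLS fit with k predictors.

    Counts k + 2 parameters (slopes, intercept, residual variance);
    model ordering is invariant to the additive constant.
    """
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + 2 * (k + 2) + n * (np.log(2 * np.pi) + 1)


def _rss(y: np.ndarray, X: np.ndarray) -> float | None:
    """Residual sum of squares of y on [1, X]; None if rank-deficient."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return None
    if res.size:
        return float(res[0])
    return float(((y - design @ beta) ** 2).sum())


@dataclass
class OLSFit:
    """One fitted linear model in the study's reporting layout."""

    outcome: str
    terms: tuple[str, ...]
    table: pd.DataFrame  # rows: const + terms; columns B, SE, beta, t, p
    aic: float
    adj_r2: float
    n: int
    r2: float
    fvalue: float
    f_pvalue: float


def fit_ols(table: pd.DataFrame, outcome: str, terms) -> OLSFit:
    """OLS of ``outcome`` on ``terms`` with the study's summary statistics.

    Reports raw coefficients B with their SEs, t and two-sided p, the
    standardized beta B * sd(x)/sd(y) (sample SDs on the analysis rows),
    adjusted R-squared, and the Gaussian AIC of :func:`gaussian_aic`.
    """
    terms = tuple(terms)
    cols = [outcome, *terms]
    data = table[cols].dropna().astype(float)
    y = data[outcome].to_numpy()
    n = len(data)
    k = len(terms)
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for {k} predictors")
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    X = data[list(terms)].to_numpy() if terms else np.empty((n, 0))
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(data, terms)
        raise RankDeficientError(f"collinear predictors: {bad}")
    model = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    rows = []
    names = ["const", *terms]
    for i, name in enumerate(names):
        beta = np.nan
        if name != "const":
            beta = model.params[i] * data[name].std(ddof=1) / sd_y
        rows.append(
            {
                "variable": name,
                "B": model.params[i],
                "SE": model.bse[i],
                "beta": beta,
                "t": model.tvalues[i],
                "p": model.pvalues[i],
            }
        )
    return OLSFit(
        outcome=outcome,
        terms=terms,
        table=pd.DataFrame(rows),
        aic=gaussian_aic(float(model.ssr), n, k),
        adj_r2=float(model.rsquared_adj),
        n=n,
        r2=float(model.rsquared),
        fvalue=float(model.fvalue) if k else float("nan"),
        f_pvalue=float(model.f_pvalue) if k else float("nan"),
    )


def _collinear_columns(data: pd.DataFrame, terms) -> list[str]:
    """Name the smallest suffix of terms whose removal restores full rank."""
    bad = []
    kept: list[str] = []
    n = len(data)
    for t in terms:
        design = np.column_stack(
            [np.ones(n)] + [data[c].to_numpy(float) for c in kept + [t]]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad.append(t)
        else:
            kept.append(t)
    return bad


@dataclass
class StepwiseResult:
    """Final model of a bidirectional stepwise search plus its trace."""

    fit: OLSFit
    forced: tuple[str, ...]
    selected: tuple[str, ...]  # stepwise-chosen terms, in inclusion order
    trace: list  # dicts: step, action, term, aic

    @property
    def terms(self) -> tuple[str, ...]:
        return self.fit.terms

    @property
    def aic(self) -> float:
        return self.fit.aic


def stepwise_bidirectional(
    table: pd.DataFrame,
    outcome: str,
    candidates,
    forced=(),
) -> StepwiseResult:
    """Greedy bidirectional model selection by AIC.

    Starting from the forced-only model, each iteration scores every
    single addition from the remaining candidates and every single drop
    of a non-forced current term, applies the best move if it lowers the
    current AIC, and stops at a local minimum.  Forced terms are never
    dropped.  At (numerically) tied AIC the smaller model wins, then the
    candidate listed earliest.  Rank-deficient moves are skipped.
    """
    candidates = tuple(candidates)
    forced = tuple(forced)
    if set(candidates) & set(forced):
        raise ValueError("candidates must be disjoint from forced terms")
    data = table[[outcome, *forced, *candidates]].dropna().astype(float)
    y = data[outcome].to_numpy()
    n = len(data)
    if n <= len(forced) + 1:
        raise ValueError(f"n = {n} too small for the forced block")
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    cols = {c: data[c].to_numpy() for c in forced + candidates}
    order = {c: i for i, c in enumerate(candidates)}

    def model_aic(terms: tuple[str, ...]) -> float | None:
        if n <= len(terms) + 1:
            return None
        X = (
            np.column_stack([cols[t] for t in terms])
            if terms
            else np.empty((n, 0))
        )
        rss = _rss(y, X)
        return None if rss is None else gaussian_aic(rss, n, len(terms))

    current = forced
    current_aic = model_aic(current)
    if current_aic is None:
        raise RankDeficientError("forced block is collinear")
    trace = [{"step": 0, "action": "start", "term": None, "aic": current_aic}]
    selected: list[str] = []
    step = 0
    while True:
        moves = []  # (aic, size, tiebreak order, action, term)
        for t in candidates:
            if t in current:
                continue
            a = model_aic(current + (t,))
            if a is not None:
                moves.append((a, len(current) + 1, order[t], "add", t))
        for t in current:
            if t in forced:
                continue
            reduced = tuple(x for x in current if x != t)
            a = model_aic(reduced)
            if a is not None:
                moves.append((a, len(reduced), order[t], "drop", t))
        if not moves:
            break
        best_aic = min(m[0] for m in moves)
        tied = [m for m in moves if m[0] <= best_aic + _AIC_TIE_TOL]
        a, _, _, action, term = min(tied, key=lambda m: (m[1], m[2]))
        if a >= current_aic - _AIC_TIE_TOL:
            break
        step += 1
        if action == "add":
            current = current + (term,)
            selected.append(term)
        else:
            current = tuple(x for x in current if x != term)
            selected.remove(term)
        current_aic = a
        trace.append({"step": step, "action": action, "term": term, "aic": a})

    fit = fit_ols(data, outcome, current)
    return StepwiseResult(
        fit=fit, forced=forced, selected=tuple(selected), trace=trace
    )


def design_A_feature_models(
    table: pd.DataFrame,
    outcomes=("pct_nature", "pct_manmade", "quality"),
    features=LLVF_USABLE,
    controls=CONTROL_VARS,
) -> dict:
    """Ratings explained by features, robustness-checked with controls.

    For each rating outcome: stage 1 selects among the 12 usable
    features by bidirectional stepwise AIC; stage 2 forces the stage-1
    terms and offers the control variables to the same stepwise search.
    Returns ``{outcome: (stage1, stage2)}``.
    """
    table = encode_covariates(exclude_participants(table))
    results = {}
    for outcome in outcomes:
        sub = exclude_participants(
            table, columns=[outcome, *features, *controls]
        )
        stage1 = stepwise_bidirectional(sub, outcome, candidates=features)
        stage2 = stepwise_bidirectional(
            sub, outcome, candidates=controls, forced=stage1.terms
        )
        results[outcome] = (stage1, stage2)
    return results


def design_B_outcome_models(
    table: pd.DataFrame,
    outcomes=("negative_affect", "auc"),
    features=LLVF_USABLE,
    ratings=RATING_VARS,
    controls=CONTROL_VARS,
) -> dict:
    """Behavioral outcomes on forced controls + stepwise view parameters.

    Block 1 (forced entry): the 7 control variables.  Block 2
    (stepwise): the 7 subjective ratings and 12 usable features.
    Returns ``{outcome: StepwiseResult}``.
    """
    table = encode_covariates(exclude_participants(table))
    results = {}
    for outcome in outcomes:
        sub = exclude_participants(
            table, columns=[outcome, *controls, *ratings, *features]
        )
        results[outcome] = stepwise_bidirectional(
            sub,
            outcome,
            candidates=tuple(ratings) + tuple(features),
            forced=tuple(controls),
        )
    return results
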