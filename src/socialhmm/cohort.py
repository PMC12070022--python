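"""Cohort splitting and the regression analyses linking dwell time to clinical
measures.

The training / validation split mirrors reference-group training: healthy
controls (HC) with at least 90% overall data availability form the training
set, except a seeded random subset retained in the validation set; every
participant from a clinical group (schizophrenia SZ, Alzheimer disease AD,
subjective cognitive complaints SCC) is always validation.

Analyses: OLS models of social/clinical scores on total dwell time, age,
diagnostic group and group x dwell interactions; a multinomial logistic model
of group membership (HC reference) on dwell time and age, reported as odds
ratios with Wald intervals; age-matched sensitivity filters with cutoffs
computed from the table; and multiplicity adjustment, either a per-family
min(1, m*p) multiplication or Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

GROUPS = ("HC", "SZ", "AD", "SCC")


class CohortError(ValueError):
    pass


@dataclass
class RegressionResult:
    """Per-term estimates in a tidy frame.

    ``table`` columns: term, coef, se, stat, df, p, p_adj (NaN until
    :meth:`adjust` is called), and for logistic fits odds_ratio, ci_low,
    ci_high.
    """

    model: str
    response: str
    table: pd.DataFrame

    def adjust(self, method: str = "times_m", m: int | None = None) -> "RegressionResult":
        self.table["p_adj"] = adjust_pvalues(self.table["p"].to_numpy(), method, m)
        return self

    def coef(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        if len(row) != 1:
            raise CohortError(f"term {term!r} not found in results")
        return float(row["coef"].iloc[0])


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "group", "age"}
    missing = required - set(table.columns)
    if missing:
        raise CohortError(f"cohort table is missing column(s) {sorted(missing)}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise CohortError(f"unknown group label(s) {sorted(bad)}")
    if "overall_availability" in table.columns:
        av = table["overall_availability"]
        if ((av < 0) | (av > 1)).any():
            raise CohortError("overall_availability must lie in [0, 1]")
    if "total_dwell_time" in table.columns:
        dw = table["total_dwell_time"].dropna()
        if ((dw < 0) | (dw > 100)).any():
            raise CohortError("total_dwell_time must lie in [0, 100]")
    return table


def split_cohort(
    table: pd.DataFrame,
    availability_threshold: float = 0.90,
    n_retain: int = 15,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """(train ids, validation ids) by the reference-group availability rule.

    Training = HCs with availability >= threshold, minus ``n_retain`` of them
    drawn without replacement (seeded) and retained in the validation set.
    All clinical-group participants and low-availability HCs are validation.
    """
    validate_cohort(table)
    if "overall_availability" not in table.columns:
        raise CohortError("cohort table lacks overall_availability")
    hc = table[table["group"] == "HC"]
    if hc.empty:
        raise CohortError("cohort contains no HCs")
    eligible = sorted(
        hc.loc[hc["overall_availability"] >= availability_threshold, "participant_id"]
    )
    if len(eligible) < n_retain:
        raise CohortError(
            f"only {len(eligible)} HCs meet the availability criterion; "
            f"cannot retain {n_retain}"
        )
    rng = np.random.default_rng(seed)
    retained = set(rng.choice(eligible, size=n_retain, replace=False)) if n_retain else set()
    train = [pid for pid in eligible if pid not in retained]
    if not train:
        raise CohortError("training set is empty after retention")
    train_set = set(train)
    validation = [p for p in table["participant_id"] if p not in train_set]
    return train, validation


def _design_terms(terms: list[str], reference_group: str) -> str:
    group_term = f"C(group, Treatment({reference_group!r}))"
    out = []
    for t in terms:
        out.append(t.replace("group", group_term) if "group" in t else t)
    return " + ".join(out)


def _check_full_rank(exog: pd.DataFrame | np.ndarray, names: list[str]) -> None:
    X = np.asarray(exog, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, cols = [], []
        for j, name in enumerate(names):
            cand = X[:, cols + [j]]
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(j)
        raise CohortError(f"design is rank deficient; collinear term(s): {bad}")


def fit_linear_model(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    reference_group: str = "HC",
) -> RegressionResult:
    """OLS of ``response`` on ``terms`` with two-sided t tests per coefficient.

    ``terms`` use column names, with ``group`` expanded to treatment coding
    against ``reference_group`` and ``a:b`` denoting an interaction — e.g.
    ``["total_dwell_time", "age", "group", "group:total_dwell_time"]`` is the
    full social-functioning model.
    """
    cols = {response} | {c for t in terms for c in t.split(":")}
    data = table.dropna(subset=[c for c in cols if c in table.columns]).copy()
    n_terms = len(terms)
    if len(data) < n_terms + 2:
        raise CohortError(
            f"only {len(data)} complete rows for response {response!r}; "
            f"need at least {n_terms + 2}"
        )
    formula = f"{response} ~ {_design_terms(terms, reference_group)}"
    model = smf.ols(formula, data=data)
    _check_full_rank(model.exog, list(model.exog_names))
    res = model.fit()
    out = pd.DataFrame(
        {
            "term": _clean_names(res.params.index, reference_group),
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "stat": res.tvalues.to_numpy(),
            "df": float(res.df_resid),
            "p": res.pvalues.to_numpy(),
            "p_adj": np.nan,
        }
    )
    return RegressionResult(model="ols", response=response, table=out)


def _clean_names(names, reference_group: str) -> list[str]:
    out = []
    for n in names:
        n = n.replace(f"C(group, Treatment({reference_group!r}))", "group")
        n = n.replace("[T.", "[").replace("]", "]")
        out.append(n)
    return out


def fit_group_logistic(
    table: pd.DataFrame,
    reference_group: str = "HC",
    predictors: tuple[str, ...] = ("total_dwell_time", "age"),
    level: float = 0.95,
) -> RegressionResult:
    """Multinomial logistic regression of diagnostic group on the predictors.

    HC is the reference outcome; each contrast row reports the Wald z test,
    OR = exp(coef) and the Wald CI.  With exactly two categories present the
    fit coincides with binomial logistic regression.
    """
    data = table.dropna(subset=[*predictors, "group"]).copy()
    counts = data["group"].value_counts()
    empty = [g for g in set(data["group"].unique()) if counts.get(g, 0) == 0]
    present = [g for g in GROUPS if counts.get(g, 0) > 0]
    if reference_group not in present:
        raise CohortError(f"reference group {reference_group!r} has no members")
    if len(present) < 2:
        raise CohortError("need at least 2 outcome categories")
    dropped = [g for g in GROUPS if g not in present and (table["group"] == g).any()]
    if dropped or empty:
        warnings.warn(f"dropping empty group(s): {sorted(set(dropped) | set(empty))}")
    categories = [reference_group] + [g for g in present if g != reference_group]
    endog = pd.Categorical(data["group"], categories=categories).codes
    exog = sm.add_constant(data[list(predictors)].astype(float))
    _check_full_rank(exog, list(exog.columns))
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.MNLogit(endog, exog).fit(method="newton", maxiter=200, disp=False)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise CohortError("perfect separation: model did not converge") from exc
    if not res.mle_retvals.get("converged", False):
        raise CohortError("multinomial logistic fit did not converge")
    if not (np.isfinite(res.params).all().all() and np.isfinite(res.bse).all().all()):
        raise CohortError(
            "multinomial logistic estimates are not finite "
            "(quasi-separation or too few participants per group)"
        )
    zcrit = sps.norm.ppf(0.5 + level / 2)
    rows = []
    params = np.asarray(res.params)  # (k_exog, n_cat - 1)
    bse = np.asarray(res.bse)
    for j, cat in enumerate(categories[1:]):
        for i, name in enumerate(exog.columns):
            coef, se = params[i, j], bse[i, j]
            z = coef / se
            rows.append(
                {
                    "term": f"{cat}:{name}",
                    "coef": coef,
                    "se": se,
                    "stat": z,
                    "df": np.nan,
                    "p": 2 * sps.norm.sf(abs(z)),
                    "p_adj": np.nan,
                    "odds_ratio": np.exp(coef),
                    "ci_low": np.exp(coef - zcrit * se),
                    "ci_high": np.exp(coef + zcrit * se),
                }
            )
    return RegressionResult(
        model="multinomial_logistic", response="group", table=pd.DataFrame(rows)
    )


def age_match_filter(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Restrict to one clinical group plus HCs inside its age range.

    Cutoffs come from the table itself: for SZ, HCs older than the oldest SZ
    participant are dropped; for AD and SCC, HCs younger than the youngest
    group member are dropped.
    """
    if group not in ("SZ", "AD", "SCC"):
        raise CohortError(f"age matching is defined for SZ/AD/SCC, not {group!r}")
    sub = table[table["group"] == group]
    if sub.empty:
        raise CohortError(f"group {group!r} absent from table")
    hc = table[table["group"] == "HC"]
    if group == "SZ":
        hc = hc[hc["age"] <= sub["age"].max()]
    else:
        hc = hc[hc["age"] >= sub["age"].min()]
    return pd.concat([hc, sub]).sort_index()


def adjust_pvalues(
    p, method: str = "times_m", m: int | None = None
) -> np.ndarray:
    """Multiplicity adjustment.

    ``times_m`` multiplies each p by the family size m (default: len(p)) and
    caps at 1 — this is the closed form behind every printed adjusted value in
    the source tables.  ``benjamini_hochberg`` is the standard FDR step-up.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise CohortError("p-values must lie in [0, 1]")
    if method == "times_m":
        m_eff = len(p) if m is None else m
        return np.minimum(1.0, m_eff * p)
    if method == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    raise CohortError(f"unknown adjustment method {method!r}")


def odds_ratio(coefficient: float, se: float, level: float = 0.95):
    """(OR, (ci_low, ci_high)) with a Wald interval exp(coef +/- z * se)."""
    if not (np.isfinite(coefficient) and np.isfinite(se)):
        raise CohortError("coefficient and se must be finite")
    if se <= 0:
        raise CohortError("se must be positive")
    z = sps.norm.ppf(0.5 + level / 2)
    return float(np.exp(coefficient)), (
        float(np.exp(coefficient - z * se)),
        float(np.exp(coefficient + z * se)),
    )


def format_p(p: float) -> str:
    """Report-style p value: 2 decimals, '<.001' floor, '>.99' ceiling."""
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    return f"{p:.2f}".lstrip("0")
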