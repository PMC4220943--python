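"""Stepwise multiple linear regression of reorientation error.

The response is the reorientation error Y (mm) of each non-reference
landmark; candidate predictors are the locating error Db (mm), the
distance DX of the averaged landmark from the reoriented x axis (mm), the
reference-shift angle sum A3r (degrees), and — as deliberately testable
alternatives — the distances from the y axis (DY), z axis (DZ) and origin
(D0).  Selection is forward entry / backward removal on ordinary least
squares with an intercept: the candidate with the smallest partial p-value
enters while p < entry threshold; selected predictors with p > removal
threshold are dropped.  Collinearity is diagnosed with variance inflation
factors, VIF_j = 1 / (1 - R²_j), from regressing each selected predictor
on the others.

Marginal effects are linear: a ``delta`` change in a selected predictor
changes the predicted error by B * delta, with no intercept contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    InsufficientDataError,
    UnknownPredictorError,
)
from .landmarks import ANALYSIS_LANDMARKS
from .metrics import ErrorRecord, records_to_frame

logger = logging.getLogger(__name__)

#: Default candidate predictors, in evaluation order.
DEFAULT_CANDIDATES: tuple = ("Db", "DX", "A3r", "DY", "DZ", "D0")

DEFAULT_ENTRY_P = 0.05
DEFAULT_REMOVAL_P = 0.10


@dataclass
class RegressionResult:
    """Selected model for one scope (a trial pair or the pooled total)."""

    scope: str
    predictors: List[str]
    coefficients: Dict[str, float]
    std_errors: Dict[str, float]
    p_values: Dict[str, float]
    vif: Dict[str, float]
    intercept: float
    adj_r_squared: float
    r_squared: float
    n_rows: int
    n_excluded_outliers: int
    #: The intercept of the error model has no published counterpart; it is
    #: estimated and reported but should not be compared across systems.
    intercept_comparable: bool = False

    @property
    def selected(self) -> bool:
        return bool(self.predictors)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "predictors": list(self.predictors),
            "coefficients": dict(self.coefficients),
            "std_errors": dict(self.std_errors),
            "p_values": dict(self.p_values),
            "p_values_3dp": {k: round(v, 3) for k, v in self.p_values.items()},
            "vif": dict(self.vif),
            "intercept": self.intercept,
            "intercept_comparable": self.intercept_comparable,
            "adj_r_squared": self.adj_r_squared,
            "r_squared": self.r_squared,
            "n_rows": self.n_rows,
            "n_excluded_outliers": self.n_excluded_outliers,
        }


#: Coefficients of the error model as fitted on the original human
#: repeated-digitization study (20 patients, three trials), per scope.
#: Units: mm of reorientation error per mm of Db, per mm of DX and per
#: degree of A3r.  Usable for marginal-effect prediction when no local
#: fit is available; intercepts were not reported.
REFERENCE_FIT_COEFFICIENTS: Dict[str, Dict[str, float]] = {
    "T1-T2": {"Db": 0.412, "DX": 0.015, "A3r": 0.242},
    "T1-T3": {"Db": 0.677, "DX": 0.018, "A3r": 0.614},
    "T2-T3": {"Db": 0.866, "DX": 0.022, "A3r": 0.657},
    "Total": {"Db": 0.758, "DX": 0.018, "A3r": 0.545},
}

REFERENCE_FIT_ADJ_R2: Dict[str, float] = {
    "T1-T2": 0.230, "T1-T3": 0.153, "T2-T3": 0.297, "Total": 0.233,
}


def reference_total_model() -> RegressionResult:
    """The pooled-scope reference error model as a
    :class:`RegressionResult` (coefficients only; intercept unknown and
    set to NaN)."""
    coefs = REFERENCE_FIT_COEFFICIENTS["Total"]
    nan = float("nan")
    return RegressionResult(
        scope="Total",
        predictors=list(coefs),
        coefficients=dict(coefs),
        std_errors={k: nan for k in coefs},
        p_values={k: 0.0 for k in coefs},
        vif={"Db": 1.016, "DX": 1.409, "A3r": 1.397},
        intercept=nan,
        adj_r_squared=REFERENCE_FIT_ADJ_R2["Total"],
        r_squared=nan,
        n_rows=0,
        n_excluded_outliers=0,
    )


# ---------------------------------------------------------------------------
# dataset assembly and outlier rule


def assemble_rows(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    """One regression row per (patient, pair, analysis landmark).

    The four reference landmarks are excluded: their errors define the
    frame rather than being measured against it.  Columns: identifiers,
    response ``Y`` and the candidate predictors ``Db``, ``DX``, ``A3r``,
    ``DY``, ``DZ``, ``D0``.
    """
    df = records_to_frame(records)
    df = df[df["landmark"].isin(ANALYSIS_LANDMARKS)].copy()
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "pair": df["pair"],
        "landmark": df["landmark"],
        "Y": df["Y_mm"],
        "Db": df["Db_mm"],
        "DX": df["DX_mm"],
        "A3r": df["A3r_deg"],
        "DY": df["DY_mm"],
        "DZ": df["DZ_mm"],
        "D0": df["D0_mm"],
    })
    bad = ~np.isfinite(out[["Y", "Db", "DX", "A3r"]]).all(axis=1)
    if bad.any():
        raise InsufficientDataError(
            f"{int(bad.sum())} regression rows have non-finite values"
        )
    return out.reset_index(drop=True)


def exclude_outliers(
    rows: pd.DataFrame, n_sd: float = 3.0, column: str = "Y"
) -> Tuple[pd.DataFrame, int]:
    """Drop rows whose response lies more than ``n_sd`` sample standard
    deviations from the scope mean.  Single pass, no re-iteration; with
    zero (or undefined) SD nothing is excluded."""
    if len(rows) < 10:
        raise InsufficientDataError("outlier screening needs at least 10 rows")
    y = rows[column].to_numpy(dtype=float)
    sd = float(np.std(y, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        return rows.reset_index(drop=True), 0
    keep = np.abs(y - float(np.mean(y))) <= n_sd * sd
    return rows[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# stepwise fit


def _design(rows: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    X = rows[list(names)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("design matrix is rank-deficient within a step")


def _fit(rows: pd.DataFrame, names: Sequence[str]):
    X = _design(rows, names)
    _check_rank(X)
    return sm.OLS(rows["Y"].to_numpy(dtype=float), X).fit()


def _vif(rows: pd.DataFrame, names: Sequence[str]) -> Dict[str, float]:
    """VIF_j = 1 / (1 - R²_j) from regressing predictor j on the other
    selected predictors (with intercept); 1.0 for a lone predictor."""
    vifs = {}
    for name in names:
        others = [n for n in names if n != name]
        if not others:
            vifs[name] = 1.0
            continue
        aux = sm.OLS(
            rows[name].to_numpy(dtype=float), _design(rows, others)
        ).fit()
        r2 = min(float(aux.rsquared), 1.0 - 1e-15)
        vifs[name] = 1.0 / (1.0 - r2)
    return vifs


def stepwise_fit(
    rows: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
    scope: str = "Total",
    n_excluded_outliers: int = 0,
) -> RegressionResult:
    """Forward-entry / backward-removal stepwise OLS of Y on ``candidates``.

    Candidates enter one at a time by smallest partial p-value while that
    p-value is below ``entry_p``; after each entry, any selected predictor
    whose p-value rises above ``removal_p`` is removed (worst first).  An
    empty model (no candidate meets entry) is returned as a
    :class:`RegressionResult` with no predictors, not an error.

    Raises
    ------
    CollinearityError
        If duplicated candidates are supplied or the design matrix at any
        step is rank-deficient.
    InsufficientDataError
        If there are fewer than 10 rows per candidate.
    """
    candidates = list(candidates)
    if len(set(candidates)) != len(candidates):
        raise CollinearityError("duplicated candidate predictors")
    unknown = [c for c in candidates if c not in rows.columns]
    if unknown:
        raise UnknownPredictorError(f"unknown candidate(s) {unknown}")
    if len(rows) < 10 * len(candidates):
        raise InsufficientDataError(
            f"stepwise fit needs >= {10 * len(candidates)} rows for "
            f"{len(candidates)} candidates, got {len(rows)}"
        )
    if not (0.0 < entry_p <= removal_p < 1.0):
        raise ValueError("need 0 < entry_p <= removal_p < 1")

    y = rows["Y"].to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    selected: List[str] = []
    just_entered: Optional[str] = None

    while True:
        # stop early once the fit is numerically exact: partial p-values on
        # a zero residual are meaningless
        if selected:
            res = _fit(rows, selected)
            if sst > 0 and float(res.ssr) <= 1e-12 * sst:
                break

        best_name, best_p = None, np.inf
        for cand in [c for c in candidates if c not in selected]:
            res = _fit(rows, selected + [cand])
            p = float(res.pvalues[-1])
            if np.isfinite(p) and p < best_p:
                best_name, best_p = cand, p
        if best_name is None or best_p >= entry_p:
            break
        selected.append(best_name)
        just_entered = best_name

        # backward removal (never the variable just entered, to avoid cycling)
        while len(selected) > 1:
            res = _fit(rows, selected)
            pvals = dict(zip(selected, res.pvalues[1:]))
            removable = {
                n: p for n, p in pvals.items()
                if n != just_entered and np.isfinite(p) and p > removal_p
            }
            if not removable:
                break
            worst = max(removable, key=removable.get)
            logger.debug("stepwise[%s]: removing %s (p=%.3g)", scope, worst,
                         removable[worst])
            selected.remove(worst)

    if not selected:
        return RegressionResult(
            scope=scope, predictors=[], coefficients={}, std_errors={},
            p_values={}, vif={}, intercept=float(np.mean(y)),
            adj_r_squared=0.0, r_squared=0.0, n_rows=len(rows),
            n_excluded_outliers=n_excluded_outliers,
        )

    res = _fit(rows, selected)
    coefs = dict(zip(selected, map(float, res.params[1:])))
    return RegressionResult(
        scope=scope,
        predictors=selected,
        coefficients=coefs,
        std_errors=dict(zip(selected, map(float, res.bse[1:]))),
        p_values=dict(zip(selected, map(float, res.pvalues[1:]))),
        vif=_vif(rows, selected),
        intercept=float(res.params[0]),
        adj_r_squared=float(res.rsquared_adj),
        r_squared=float(res.rsquared),
        n_rows=len(rows),
        n_excluded_outliers=n_excluded_outliers,
    )


def predict_marginal(
    result: RegressionResult | Mapping[str, float], predictor: str, delta: float
) -> float:
    """Marginal change in predicted reorientation error (mm) for a
    ``delta`` change in ``predictor``: B * delta, no intercept."""
    coefs = (
        result.coefficients if isinstance(result, RegressionResult) else result
    )
    if predictor not in coefs:
        raise UnknownPredictorError(
            f"predictor {predictor!r} not in model {sorted(coefs)}"
        )
    return float(coefs[predictor]) * float(delta)


def fit_all_scopes(
    rows: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
    outlier_sd: float = 3.0,
) -> Dict[str, RegressionResult]:
    """Outlier exclusion and stepwise fit per trial-pair scope plus the
    pooled ``Total`` scope.

    Each scope is screened for outliers and fitted independently.  Scopes
    without rows are logged and omitted from the returned mapping.
    """
    scopes = sorted(rows["pair"].unique())
    results: Dict[str, RegressionResult] = {}
    for scope in scopes + ["Total"]:
        sub = rows if scope == "Total" else rows[rows["pair"] == scope]
        if sub.empty:
            logger.warning("scope %s has no rows; skipped", scope)
            continue
        kept, n_excl = exclude_outliers(sub, n_sd=outlier_sd)
        results[scope] = stepwise_fit(
            kept, candidates, entry_p, removal_p,
            scope=scope, n_excluded_outliers=n_excl,
        )
    return results
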