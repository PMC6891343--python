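"""Linear calibration of tau*L_A against water mass, and its inversion.

The calibration regresses the product of optical depth and leaf area on the
gravimetric water mass, tau*L_A = C1*M_w + C0, per species, by ordinary
least squares. Neither tau alone nor L_A alone correlates reliably with
M_w across leaves — the forward model tau = K*M_w/L_A shows why: tau
confounds water mass with area — but their product is linear in M_w, which
is what makes the nondestructive inversion

    M_w_hat = (tau * L_A - C0) / C1

possible on leaves that are never detached. Prediction uncertainty comes
from first-order (delta-method) propagation of the slope/intercept standard
errors, their covariance, and the residual scatter of a new observation.

Species comparison utilities mirror the usual summary-table workflow:
Tukey–Kramer all-pairs tests with a compact letter display, and a table of
adjusted R^2 for the three candidate regressions (tau vs M_w, tau vs L_A,
tau*L_A vs M_w).
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import LeafRecord
from .errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    NegativePredictionWarning,
    NonInvertibleCalibrationError,
)

__all__ = [
    "CalibrationModel",
    "PredictionResult",
    "fit_line",
    "fit_calibration",
    "fit_zero_intercept",
    "adjusted_r2",
    "pearson_test",
    "predict_water_mass",
    "tukey_letters",
    "correlation_table",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted tau*L_A = C1*M_w + C0 line with diagnostics.

    C1 is in cm^2 mg^-1 (physically alpha/rho_w less dry-matter losses),
    C0 in cm^2 (residual absorption). cov_C1_C0 is needed for the
    delta-method prediction variance; residual_sd is the root mean squared
    error with n-2 degrees of freedom.
    """

    species_code: str | None
    C1: float
    C0: float
    se_C1: float
    se_C0: float
    cov_C1_C0: float
    r2: float
    adj_r2: float
    pearson_r: float
    pearson_p: float
    n: int
    residual_sd: float


@dataclass(frozen=True)
class PredictionResult:
    """Inverted water-mass estimate with its uncertainty."""

    M_w_hat: float
    se: float
    interval: tuple[float, float]
    confidence: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.M_w_hat <= hi):
            raise DomainError("interval must bracket the point estimate")


def _validate_xy(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("x and y must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in the predictor")


def fit_line(x: Iterable[float], y: Iterable[float], species_code: str | None = None) -> CalibrationModel:
    """OLS of y on x with an intercept, packaged as a CalibrationModel."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    _validate_xy(x, y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    c0, c1 = res.params
    se_c0, se_c1 = res.bse
    cov = res.cov_params()
    if np.ptp(y) == 0:
        r, p = 0.0, 1.0  # flat response: correlation undefined, report null
    else:
        r, p = pearson_test(x, y)
    return CalibrationModel(
        species_code=species_code,
        C1=float(c1),
        C0=float(c0),
        se_C1=float(se_c1),
        se_C0=float(se_c0),
        cov_C1_C0=float(np.asarray(cov)[0, 1]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        pearson_r=float(r),
        pearson_p=float(p),
        n=int(x.size),
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def _records_xy(records: Sequence[LeafRecord]) -> tuple[np.ndarray, np.ndarray]:
    usable = [
        r
        for r in records
        if r.tau is not None
        and r.leaf_area is not None
        and np.isfinite(r.tau)
        and np.isfinite(r.leaf_area)
    ]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >=3 records with finite tau, L_A and M_w; got {len(usable)}"
        )
    x = np.array([r.water_mass for r in usable])
    y = np.array([r.tau * r.leaf_area for r in usable])
    return x, y


def fit_calibration(records: Sequence[LeafRecord], species_code: str | None = None) -> CalibrationModel:
    """Fit tau*L_A = C1*M_w + C0 by OLS over a set of leaves."""
    if species_code is None:
        codes = {r.species_code for r in records}
        species_code = codes.pop() if len(codes) == 1 else None
    x, y = _records_xy(records)
    return fit_line(x, y, species_code=species_code)


def fit_zero_intercept(records: Sequence[LeafRecord]) -> float:
    """Least squares through the origin, K = sum(xy)/sum(x^2).

    The pure water-slab model tau*L_A = K*M_w has no intercept; this is the
    one-parameter fit of that form.
    """
    x, y = _records_xy(records)
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateDesignError("all water masses are zero")
    return float(np.dot(x, y) / denom)


def adjusted_r2(r2: float, n: int, p: int = 1) -> float:
    """Adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1); may be negative."""
    if not 0 <= r2 <= 1:
        raise DomainError(f"R^2 must lie in [0, 1], got {r2}")
    if n <= p + 1:
        raise DomainError(f"need n > p+1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def pearson_test(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p (t-transform, n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("need equal-length vectors of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("zero variance in x or y")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def predict_water_mass(
    tau: float,
    l_a: float,
    model: CalibrationModel,
    confidence: float = 0.95,
) -> PredictionResult:
    """Invert a fitted calibration to estimate a leaf's water mass (mg).

    The point estimate is the algebraic inverse (tau*L_A - C0)/C1. The
    variance combines, to first order, the new observation's residual
    scatter with the sampling covariance of (C0, C1); the interval uses the
    t quantile with n-2 degrees of freedom. Negative estimates (possible
    when tau*L_A < C0) are reported as-is with a warning — truncation would
    bias validation statistics.
    """
    if not 0 < confidence < 1:
        raise DomainError("confidence must be in (0, 1)")
    if model.C1 <= 0:
        raise NonInvertibleCalibrationError(
            f"calibration slope C1={model.C1} is not positive"
        )
    y = tau * l_a
    m_hat = (y - model.C0) / model.C1
    # d m/dy = 1/C1, d m/dC0 = -1/C1, d m/dC1 = -m/C1
    var = (
        model.residual_sd**2
        + model.se_C0**2
        + m_hat**2 * model.se_C1**2
        + 2.0 * m_hat * model.cov_C1_C0
    ) / model.C1**2
    se = float(np.sqrt(max(var, 0.0)))
    df = model.n - 2
    tq = float(scipy.stats.t.ppf(0.5 + confidence / 2.0, df)) if se > 0 else 0.0
    if m_hat < 0:
        warnings.warn(
            f"predicted water mass is negative ({m_hat:.3g} mg)",
            NegativePredictionWarning,
            stacklevel=2,
        )
    return PredictionResult(
        M_w_hat=float(m_hat),
        se=se,
        interval=(float(m_hat - tq * se), float(m_hat + tq * se)),
        confidence=confidence,
    )


def _tukey_significant_pairs(
    groups: Mapping[str, np.ndarray], alpha: float
) -> set[frozenset[str]]:
    """All-pairs Tukey–Kramer comparisons; returns the significant pairs."""
    names = list(groups)
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    n_total = sum(v.size for v in groups.values())
    sse = sum(float(np.sum((v - means[k]) ** 2)) for k, v in groups.items())
    if sse == 0.0:
        # Degenerate: no within-group scatter. Any mean difference is then
        # infinitely many standard errors away; equal means never differ.
        return {
            frozenset((a, b))
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if means[a] != means[b]
        }
    values = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    labels = np.concatenate([np.repeat(k, groups[k].size) for k in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = [str(g) for g in res.groupsunique]
    out: set[frozenset[str]] = set()
    # pvalues follow itertools.combinations order over the sorted groups
    for (i, j), p in zip(itertools.combinations(range(len(uniq)), 2), res.pvalues):
        if p <= alpha:
            out.add(frozenset((uniq[i], uniq[j])))
    return out


def tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from Tukey–Kramer all-pairs tests.

    Groups sharing no letter differ significantly at level ``alpha``; the
    Tukey–Kramer studentized-range test handles unequal group sizes.
    Letters are assigned by the insert-and-absorb algorithm, ordered by
    descending group mean (letter 'a' contains the largest mean).
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrs = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    sig = _tukey_significant_pairs(arrs, alpha)
    means = {k: float(np.mean(v)) for k, v in arrs.items()}
    order = sorted(arrs, key=lambda k: -means[k])

    # Insert-and-absorb: start with one column holding every group; each
    # significant pair splits any column containing both; subset columns
    # are absorbed.
    columns: list[set[str]] = [set(order)]
    for pair in sig:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for dropped in (a, b):
                new = col - {dropped}
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        columns = [
            c
            for i, c in enumerate(columns)
            if not any(c < other or (c == other and i > j) for j, other in enumerate(columns))
        ]

    columns.sort(key=lambda c: -max(means[g] for g in c))
    if len(columns) > len(string.ascii_lowercase):
        raise DomainError("more letter classes than available letters")
    letters: dict[str, list[str]] = {k: [] for k in arrs}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in col:
            letters[g].append(letter)
    return {k: "".join(sorted(v)) for k, v in letters.items()}


#: The three candidate regressions reported per species.
_RELATIONS = ("tau_vs_Mw", "tau_vs_LA", "tauLA_vs_Mw")


def correlation_table(
    records: Sequence[LeafRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Adjusted R^2 of the three candidate regressions, per species.

    Rows: one per (species, relation) with relation in
    ``tau_vs_Mw``, ``tau_vs_LA``, ``tauLA_vs_Mw``. ``significant`` flags a
    two-sided Pearson p <= alpha (no multiplicity correction across the
    three rows). Only the product tau*L_A is expected to track M_w across
    species; the simple correlations confound water mass with area.
    """
    by_species: dict[str, list[LeafRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_code, []).append(r)
    rows = []
    for code in sorted(by_species):
        recs = by_species[code]
        if len(recs) < 3:
            raise InsufficientDataError(f"species {code} has fewer than 3 leaves")
        mw = np.array([r.water_mass for r in recs])
        la = np.array([r.leaf_area for r in recs], dtype=float)
        tau = np.array([r.tau for r in recs], dtype=float)
        for relation, (x, y) in zip(
            _RELATIONS, ((mw, tau), (la, tau), (mw, tau * la))
        ):
            m = fit_line(x, y, species_code=code)
            rows.append(
                {
                    "species": code,
                    "relation": relation,
                    "adj_r2": m.adj_r2,
                    "pearson_r": m.pearson_r,
                    "pearson_p": m.pearson_p,
                    "significant": bool(m.pearson_p <= alpha),
                }
            )
    return pd.DataFrame(rows)
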