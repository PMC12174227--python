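"""Diversity-invasibility fits and persistence-surface summaries.

The diversity-invasibility relationship is estimated by a binomial GAM:
invasion success regressed on native diversity through a penalized cubic
B-spline smooth (10 basis functions, penalty weight chosen by generalized
cross-validation), with the smooth term's significance assessed by a Wald
test at its effective degrees of freedom.  A first-difference sign-pattern
rule turns the fitted curve into one of the qualitative labels used to
describe such relationships: negative, positive, U-shape or flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = ["DiversityInvasibilityFit", "PersistenceSurface",
           "fit_diversity_gam", "classify_shape",
           "summarize_persistence_surface"]


@dataclass
class DiversityInvasibilityFit:
    """Penalized-smooth estimate of invasion probability vs native diversity."""

    grid: np.ndarray        # diversity values the smooth is evaluated on
    predicted: np.ndarray   # predicted invasion probabilities on the grid
    edf: float              # effective degrees of freedom of the smooth
    p_value: float          # Wald p-value of the smooth term
    significant: bool       # p_value < 0.05
    n: int                  # number of records fitted
    alpha: float            # selected penalty weight


def fit_diversity_gam(diversity, success, n_grid: int = 100,
                      df: int = 10, degree: int = 3) -> DiversityInvasibilityFit:
    """Fit the binomial diversity-invasibility smooth.

    Parameters
    ----------
    diversity, success
        Paired records: total native richness and the binary invasion
        outcome of each simulated community.
    n_grid
        Number of evaluation points for the returned smooth curve.
    df, degree
        B-spline basis dimension and polynomial degree.

    Raises
    ------
    ValueError
        On degenerate designs: fewer than 30 records, fewer than 3 distinct
        diversity values, or no variation in the outcome.
    """
    x = np.asarray(diversity, dtype=float)
    y = np.asarray(success, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("diversity and success must be equal-length 1-D")
    n = len(x)
    if n < 30:
        raise ValueError(f"refusing to fit: only {n} records (need >= 30)")
    n_unique = len(np.unique(x))
    if n_unique < 3:
        raise ValueError(
            f"refusing to fit: only {n_unique} distinct diversity values "
            "(no diversity variation)")
    if y.min() == y.max():
        raise ValueError("refusing to fit: no outcome variation "
                         f"(all outcomes = {y.min():g})")

    df_eff = int(min(df, max(4, n_unique - 1)))
    basis = BSplines(x, df=[df_eff], degree=[degree])
    exog = np.ones((n, 1))
    family = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # GCV over a log-spaced penalty grid: n * deviance / (n - edf)^2
        best = None
        for a in np.logspace(-2, 4, 7):
            try:
                r = GLMGam(y, exog, smoother=basis, family=family,
                           alpha=[a]).fit()
            except Exception:
                continue
            edf_t = float(np.sum(r.edf))
            if not (0.0 < edf_t < 0.9 * n) or not np.isfinite(r.deviance):
                continue  # diverged IRLS / separation artefact
            gcv = n * r.deviance / (n - edf_t) ** 2
            if np.isfinite(gcv) and (best is None or gcv < best[0]):
                best = (gcv, a, r)
        if best is None:
            raise ValueError("refusing to fit: penalized fit did not converge")
        _, alpha, res = best
        test = res.test_significance(0)

    p_value = float(np.squeeze(test.pvalue))
    edf = float(np.sum(res.edf[1:]))  # first entry is the intercept
    grid = np.linspace(x.min(), x.max(), n_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = res.predict(np.ones((n_grid, 1)), exog_smooth=grid)
    pred = np.clip(np.asarray(pred), 0.0, 1.0)
    return DiversityInvasibilityFit(
        grid=grid, predicted=pred, edf=edf, p_value=p_value,
        significant=bool(p_value < 0.05), n=n,
        alpha=float(np.squeeze(alpha)))


def classify_shape(fit: DiversityInvasibilityFit) -> str:
    """Qualitative label of the fitted curve from its first differences.

    Nonsignificant fits are ``flat`` by definition; otherwise the sign
    pattern of consecutive differences (with near-zero differences ignored)
    decides: all negative -> ``negative``, all positive -> ``positive``, one
    negative-to-positive change -> ``U-shape``, anything else -> ``flat``.
    """
    if not fit.significant:
        return "flat"
    diffs = np.diff(fit.predicted)
    span = float(fit.predicted.max() - fit.predicted.min())
    eps = 1e-12 + 1e-3 * span
    signs = np.sign(diffs[np.abs(diffs) > eps])
    if len(signs) == 0:
        return "flat"
    if np.all(signs < 0):
        return "negative"
    if np.all(signs > 0):
        return "positive"
    change = np.flatnonzero(np.diff(signs) != 0)
    if len(change) == 1 and signs[0] < 0 and signs[-1] > 0:
        return "U-shape"
    return "flat"


@dataclass
class PersistenceSurface:
    """Mean persistence over the (F1, F2) grid for one (rule, adaptive) pair."""

    rule: str
    adaptive: bool
    matrix: pd.DataFrame          # index F1, columns F2, values mean persistence
    marginal_F1: pd.DataFrame     # mean over F2 per F1 (and vice versa below)
    marginal_F2: pd.DataFrame


def summarize_persistence_surface(grid_table: pd.DataFrame
                                  ) -> dict[tuple[str, bool], PersistenceSurface]:
    """Aggregate a grid table into per-(rule, adaptive) persistence surfaces.

    Accepts either the per-run table (column ``persistence``) or the
    cell-mean table (column ``mean_persistence``) produced by ``run_grid``.
    Pure aggregation: missing cells stay missing (NaN), nothing is
    interpolated, and row order of the input is irrelevant.
    """
    df = grid_table
    if "persistence" in df.columns:
        if "failed" in df.columns:
            df = df[~df["failed"]]
        value = "persistence"
    elif "mean_persistence" in df.columns:
        value = "mean_persistence"
    else:
        raise ValueError("grid table needs a 'persistence' or "
                         "'mean_persistence' column")
    out: dict[tuple[str, bool], PersistenceSurface] = {}
    for (rule, adaptive), sub in df.groupby(["rule", "adaptive"]):
        cells = (sub.groupby(["F1", "F2"])[value].mean().reset_index())
        matrix = cells.pivot(index="F1", columns="F2", values=value).sort_index()
        marg1 = cells.groupby("F1")[value].mean().reset_index()
        marg2 = cells.groupby("F2")[value].mean().reset_index()
        out[(rule, bool(adaptive))] = PersistenceSurface(
            rule=rule, adaptive=bool(adaptive), matrix=matrix,
            marginal_F1=marg1, marginal_F2=marg2)
    return out
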