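"""Linear models with permutation-of-residuals inference, and plate-reader
expression processing.

The permutation scheme is the reduced-model (Freedman-Lane) construction:
to test a term, the model *without* that term is fitted, its residuals are
shuffled and added back to its fitted values, and the full model is refitted
on each pseudo-response; the permutation p-value compares the observed |t|
of the term with the shuffled ones (add-one convention).  Permuting the raw
response instead is available via ``scheme="raw"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermutationOLS",
    "PermutationOLSResults",
    "ExpressionRecord",
    "permlm",
    "process_expression",
    "expression_fitness_regression",
    "group_ttest",
]


@dataclass
class PermutationOLSResults:
    """OLS estimates plus permutation p-values per tested term."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    r_squared: float
    adj_r_squared: float
    perm_pvalues: dict[str, float]
    exog_names: list[str]
    n_obs: int
    B: int
    seed: int | None
    scheme: str

    def summary(self) -> str:
        lines = [
            f"Permutation OLS ({self.scheme} scheme, B={self.B}, seed={self.seed})",
            f"  n = {self.n_obs}, R2 = {self.r_squared:.4f}, "
            f"adj R2 = {self.adj_r_squared:.4f}",
            f"  {'term':<20}{'coef':>12}{'se':>12}{'t':>10}{'perm p':>10}",
        ]
        for i, name in enumerate(self.exog_names):
            p = self.perm_pvalues.get(name)
            lines.append(f"  {name:<20}{self.params[i]:>12.5g}{self.bse[i]:>12.5g}"
                         f"{self.tvalues[i]:>10.3f}"
                         f"{(f'{p:.4g}' if p is not None else '-'):>10}")
        return "\n".join(lines)


class PermutationOLS:
    """Ordinary least squares with permutation inference.

    Parameters
    ----------
    endog : 1-d response.
    exog : 2-d predictor matrix *without* intercept (one is prepended
        unless ``add_constant=False``).
    exog_names : names for the predictor columns.
    """

    def __init__(self, endog, exog, exog_names: Sequence[str] | None = None,
                 add_constant: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(X.shape[1])]
        exog_names = list(exog_names)
        if len(exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        if len(set(exog_names)) != len(exog_names):
            raise ValueError("duplicate predictor names")
        if add_constant:
            X = np.column_stack([np.ones(len(y)), X])
            exog_names = ["const"] + exog_names
        mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
        dropped = int((~mask).sum())
        if dropped:
            warnings.warn(f"dropping {dropped} rows with missing values (listwise)")
        y, X = y[mask], X[mask]
        if len(y) < X.shape[1] + 2:
            raise ValueError(f"need at least p+2={X.shape[1] + 2} complete rows, "
                             f"have {len(y)}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.endog, self.exog, self.exog_names = y, X, exog_names
        self.n_dropped = dropped

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "PermutationOLS":
        """Build from an R-style formula (via patsy), e.g. ``"w_mean ~ delta_cai"``."""
        import patsy

        y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe",
                                     NA_action="drop")
        names = list(X_dm.columns)
        has_const = "Intercept" in names
        if has_const:
            X = X_dm.drop(columns="Intercept").to_numpy()
            names = [n for n in names if n != "Intercept"]
        else:
            X = X_dm.to_numpy()
        return cls(y_dm.to_numpy().ravel(), X, exog_names=names,
                   add_constant=has_const)

    # ------------------------------------------------------------------
    def _ols(self, y: np.ndarray):
        X = self.exog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return beta, resid

    def fit(self, B: int = 10_000, seed: int | None = 0,
            scheme: str = "freedman_lane",
            test_terms: Sequence[str] | None = None) -> PermutationOLSResults:
        """Fit and attach permutation p-values for each non-intercept term."""
        if scheme not in ("freedman_lane", "raw"):
            raise ValueError(f"unknown scheme {scheme!r}")
        y, X, names = self.endog, self.exog, self.exog_names
        n, p = X.shape
        XtX_inv = np.linalg.inv(X.T @ X)
        pinv = XtX_inv @ X.T
        beta = pinv @ y
        resid = y - X @ beta
        dof = n - p
        # residual variance indistinguishable from floating-point fuzz is
        # treated as zero: t is 0 for null coefficients, +-inf for a perfect
        # fit (degenerate but well-defined edge cases)
        scale = float(np.abs(y).max()) or 1.0
        tol = (1e-10 * scale) ** 2 * n
        sigma2 = float(resid @ resid) / dof
        degenerate = float(resid @ resid) <= tol
        with np.errstate(divide="ignore", invalid="ignore"):
            bse = np.sqrt(sigma2 * np.diag(XtX_inv))
            tvals = beta / bse
        if degenerate:
            tvals = np.where(np.abs(beta) < 1e-10 * scale, 0.0,
                             np.sign(beta) * np.inf)
            bse = np.zeros_like(bse)
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float(resid @ resid)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if tss > 0 else 0.0

        if test_terms is None:
            test_terms = [nm for nm in names if nm != "const"]
        rng = np.random.default_rng(seed)
        pvals: dict[str, float] = {}
        diag = np.diag(XtX_inv)
        for term in test_terms:
            j = names.index(term)
            if scheme == "raw":
                base_fit = np.zeros(n)
                base_resid = y.copy()
            else:
                Z = np.delete(X, j, axis=1)
                bz, *_ = np.linalg.lstsq(Z, y, rcond=None)
                base_fit = Z @ bz
                base_resid = y - base_fit
            # (n, B) matrix of permuted pseudo-responses, fitted in one shot
            idx = np.argsort(rng.random((B, n)), axis=1)
            Ystar = base_fit[:, None] + base_resid[idx].T
            Bstar = pinv @ Ystar                        # (p, B)
            Rstar = Ystar - X @ Bstar
            s2 = np.einsum("ij,ij->j", Rstar, Rstar) / dof
            with np.errstate(divide="ignore", invalid="ignore"):
                tstar = Bstar[j] / np.sqrt(s2 * diag[j])
            rss_star = np.einsum("ij,ij->j", Rstar, Rstar)
            deg = rss_star <= tol
            if np.any(deg):
                tstar[deg] = np.where(np.abs(Bstar[j, deg]) < 1e-10 * scale,
                                      0.0, np.inf)
            tstar = np.nan_to_num(tstar, nan=0.0)
            exceed = int(np.sum(np.abs(tstar) >= abs(tvals[j]) - 1e-12))
            pvals[term] = (1 + exceed) / (B + 1)
        return PermutationOLSResults(
            params=beta, bse=bse, tvalues=tvals, r_squared=r2,
            adj_r_squared=float(adj_r2), perm_pvalues=pvals,
            exog_names=names, n_obs=n, B=B, seed=seed, scheme=scheme)


def permlm(data: pd.DataFrame, formula: str, B: int = 10_000,
           seed: int | None = 0, scheme: str = "freedman_lane") -> PermutationOLSResults:
    """Formula front end: ``permlm(df, "w_mean ~ delta_cai + distance")``."""
    return PermutationOLS.from_formula(formula, data).fit(B=B, seed=seed,
                                                          scheme=scheme)


# ---------------------------------------------------------------------------
# plate-reader expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """Background- and OD-corrected maximum reporter signal, relative to WT."""

    strain: str
    max_signal: float              # (F - F_background) / (OD - OD_blank) at peak
    max_relative_expression: float  # divided by the WT value
    peak_index: int
    rejected: bool = False
    reason: str = ""


def _max_corrected(fluor: np.ndarray, od: np.ndarray,
                   bg_fluor: np.ndarray, blank_od: np.ndarray):
    signal = fluor - bg_fluor
    i = int(np.argmax(signal))
    denom = od[i] - blank_od[i]
    if denom <= 0:
        return None, i
    return float(signal[i] / denom), i


def process_expression(timeseries: pd.DataFrame, background_strain: str,
                       blank_strain: str, wt_strain: str) -> list[ExpressionRecord]:
    """Relative expression per strain from long plate-reader series.

    ``timeseries`` has columns strain, time, od, fluorescence; one series
    per strain (average replicate wells upstream).  The reporter signal is
    background-subtracted fluorescence at its maximum over the series,
    divided by blank-corrected OD at that time, then standardised by the
    wild-type value.  Strains whose OD correction is non-positive at the
    peak are rejected with a reason.
    """
    req = {"strain", "time", "od", "fluorescence"}
    if not req <= set(timeseries.columns):
        raise ValueError(f"timeseries missing columns: {sorted(req - set(timeseries.columns))}")
    series = {}
    for strain, grp in timeseries.groupby("strain"):
        g = grp.sort_values("time")
        series[str(strain)] = (g["fluorescence"].to_numpy(dtype=float),
                               g["od"].to_numpy(dtype=float))
    for needed in (background_strain, blank_strain, wt_strain):
        if needed not in series:
            raise ValueError(f"strain {needed!r} absent from the timeseries")
    bg_fluor = series[background_strain][0]
    blank_od = series[blank_strain][1]

    wt_val, _ = _max_corrected(series[wt_strain][0], series[wt_strain][1],
                               bg_fluor, blank_od)
    if wt_val is None or wt_val <= 0:
        raise ValueError("wild-type series yields non-positive corrected signal")

    records = []
    for strain, (fluor, od) in series.items():
        if strain in (background_strain, blank_strain):
            continue
        val, i = _max_corrected(fluor, od, bg_fluor, blank_od)
        if val is None:
            records.append(ExpressionRecord(
                strain=strain, max_signal=float("nan"),
                max_relative_expression=float("nan"), peak_index=i,
                rejected=True, reason="blank-corrected OD <= 0 at peak"))
        else:
            records.append(ExpressionRecord(
                strain=strain, max_signal=val,
                max_relative_expression=val / wt_val, peak_index=i))
    return records


def expression_fitness_regression(fitness: pd.DataFrame,
                                  expression: pd.DataFrame,
                                  synonymous_only: bool = True,
                                  B: int = 10_000,
                                  seed: int | None = 0) -> PermutationOLSResults:
    """OLS of relative fitness on relative transcript level.

    Joins on ``mutation_id``; by default restricted to synonymous mutations
    (the subset for which transcript level is the candidate mechanism).
    """
    df = fitness.merge(expression, on="mutation_id", how="inner")
    if synonymous_only and "class" in df.columns:
        df = df[df["class"].astype(str) == "synonymous"]
    df = df.dropna(subset=["w_mean", "relative_expression"])
    if len(df) < 3:
        raise ValueError(f"join produced only {len(df)} usable rows")
    model = PermutationOLS(df["w_mean"].to_numpy(),
                           df["relative_expression"].to_numpy()[:, None],
                           exog_names=["relative_expression"])
    return model.fit(B=B, seed=seed)


def group_ttest(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance (equal-variance) two-sample t-test.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give (inf-signed t, 0), the documented edge case.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math_inf_signed(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def math_inf_signed(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")
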