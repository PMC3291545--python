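"""All-subsets linear-model mining with AIC ranking and grouped CV.

The water energy model was found by fitting every non-empty subset of a
library of docking scoring-function terms (8 terms -> 255 linear models)
to calculated water binding free energies, ranking the fits by AIC,
keeping the 30 lowest-AIC models, and picking the one with the smallest
mean absolute error under leave-group-out cross-validation, where a group
is all the measurements of one conserved water molecule.  The winner on
the original data was the single hydrogen-bond term with intercept 1.77
and slope -2.58 kcal/mol.

AIC here is the Gaussian profile form n*ln(RSS/n) + 2*(k+1) with
k = |subset| + 1 counting the coefficients and the intercept, and the +1
the profiled-out noise variance; the full-likelihood form (adds the
n*ln(2*pi) + n constant) is available via ``aic_dialect="full"`` and does
not change any ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

#: Default 8-term library: the docking engine's five non-torsional empirical
#: terms plus the force-field vdW, electrostatic and desolvation terms
#: (the force-field hydrogen-bond term duplicates the empirical one and the
#: torsional terms do not apply to a rigid water).
DEFAULT_TERMS = (
    "vina_gauss1", "vina_gauss2", "vina_repulsion", "vina_hydrophobic",
    "vina_hbond", "ad4_vdw", "ad4_electrostatic", "ad4_desolvation",
)


@dataclass
class TermMatrix:
    """Per-water term values, the response energy and a group id per row."""

    X: pd.DataFrame            # columns = term names
    y: pd.Series               # calculated binding free energy, kcal/mol
    groups: pd.Series          # conserved-water / protein group id per row

    def __post_init__(self):
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("term matrix contains missing values")
        if len(self.X) != len(self.y) or len(self.X) != len(self.groups):
            raise ValueError("X, y and groups must have equal length")
        if self.groups.nunique() < 2:
            raise ValueError("need at least 2 groups for cross-validation")

    @property
    def terms(self) -> list:
        return list(self.X.columns)

    @classmethod
    def from_csv(cls, path, response: str = "energy", group: str = "group") -> "TermMatrix":
        df = pd.read_csv(path)
        term_cols = [c for c in df.columns if c not in (response, group)]
        return cls(X=df[term_cols], y=df[response], groups=df[group])


@dataclass
class LinearModelFit:
    subset: tuple
    coefficients: dict          # term -> coefficient
    intercept: float
    rss: float
    aic: float
    n: int
    k: int = 0                  # parameter count excluding the variance
    cv_error: float | None = None

    def __post_init__(self):
        self.k = self.k or len(self.subset) + 1

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for term, coef in self.coefficients.items():
            out = out + coef * X[term].to_numpy()
        return out


def enumerate_subsets(terms: Sequence[str]) -> list:
    """All non-empty subsets, smallest first, name order within a size."""
    terms = sorted(terms)
    if not terms:
        raise ValueError("need at least one term")
    return [subset for size in range(1, len(terms) + 1)
            for subset in combinations(terms, size)]


def _design(X: pd.DataFrame, subset) -> np.ndarray:
    return np.column_stack([np.ones(len(X))] + [X[t].to_numpy() for t in subset])


def _ols(A: np.ndarray, y: np.ndarray, subset):
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for subset {tuple(subset)}: collinear terms"
        )
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def fit_ols_aic(data: TermMatrix, subset, aic_dialect: str = "profile") -> LinearModelFit:
    """OLS with intercept on one term subset, with its AIC."""
    subset = tuple(subset)
    n = len(data.X)
    k = len(subset) + 1
    if n <= k:
        raise ValueError(f"need more than {k} rows to fit {k} parameters, have {n}")
    A = _design(data.X, subset)
    y = data.y.to_numpy(dtype=float)
    beta, rss = _ols(A, y, subset)
    # floor RSS at machine-precision scale so exact fits share one AIC base
    # and rank by the parameter penalty alone
    floor = n * (1e-12 * max(1.0, float(np.linalg.norm(y)))) ** 2
    aic = n * np.log(max(rss, floor) / n) + 2 * (k + 1)
    if aic_dialect == "full":
        aic += n * np.log(2 * np.pi) + n
    elif aic_dialect != "profile":
        raise ValueError(f"unknown AIC dialect {aic_dialect!r}")
    return LinearModelFit(
        subset=subset,
        coefficients=dict(zip(subset, beta[1:])),
        intercept=float(beta[0]),
        rss=rss, aic=float(aic), n=n, k=k,
    )


def leave_group_out_cv(data: TermMatrix, subset) -> float:
    """Mean over groups of the held-out group's mean absolute prediction error."""
    subset = tuple(subset)
    y = data.y.to_numpy(dtype=float)
    group_errors = []
    for g in data.groups.unique():
        held = (data.groups == g).to_numpy()
        n_train = int((~held).sum())
        if n_train <= len(subset) + 1:
            raise ValueError(
                f"fold for group {g!r} leaves only {n_train} training rows"
            )
        A = _design(data.X, subset)
        beta, _ = _ols(A[~held], y[~held], subset)
        pred = A[held] @ beta
        group_errors.append(float(np.mean(np.abs(pred - y[held]))))
    return float(np.mean(group_errors))


def select_model(data: TermMatrix, top_k: int = 30,
                 aic_dialect: str = "profile") -> LinearModelFit:
    """AIC-rank all subsets, CV the top ``top_k``, return the lowest-CV-error fit.

    The returned model is refit on the full data; ties in CV error break
    to the smaller subset, then name order.
    """
    fits = [fit_ols_aic(data, s, aic_dialect) for s in enumerate_subsets(data.terms)]
    fits.sort(key=lambda f: (f.aic, len(f.subset), f.subset))
    candidates = fits[:min(top_k, len(fits))]
    for fit in candidates:
        fit.cv_error = leave_group_out_cv(data, fit.subset)
    # CV errors equal to within numerical noise count as ties, which break
    # to the smaller subset, then name order
    best = min(candidates,
               key=lambda f: (round(f.cv_error, 9), len(f.subset), f.subset))
    return best


def mean_predictor_error(data: TermMatrix) -> float:
    """Grouped-CV error of the no-model baseline (predict the training mean)."""
    y = data.y.to_numpy(dtype=float)
    errs = []
    for g in data.groups.unique():
        held = (data.groups == g).to_numpy()
        errs.append(float(np.mean(np.abs(y[held] - y[~held].mean()))))
    return float(np.mean(errs))
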