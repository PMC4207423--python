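"""Affinity-model fitting, best-subset search and outlier iteration.

The affinity model is an ordinary least-squares fit of observed log K on
a chosen subset of descriptor columns, reported with the full diagnostic
panel used in model-based QSAR work: multiple R, R^2, adjusted R^2, the
F statistic with (k, n-k-1) degrees of freedom, the residual standard
deviation SD = sqrt(SS_res/(n-k-1)), standardized (beta) coefficients,
per-coefficient t tests, the matrix of squared pairwise predictor
correlations, standardized residuals (residual/SD) and the molecules
whose standardized residual exceeds 2 in magnitude.

Model search is best-subset: subsets of sizes 1 and 2 are enumerated
exhaustively via closed-form normal equations, the best survivors are
extended column-by-column (a small beam) up to k_max, and the visited
pool is re-enumerated exhaustively when it has at most 20 columns.
Every visited subset then faces two admissibility screens: a
pairwise-collinearity cap on squared predictor correlations and an
all-coefficients significance screen whose per-coefficient level is
Bonferroni-corrected for the number of size-k subsets by default.
Without that correction, the best of ~50 noise columns would clear a
nominal 0.05 threshold almost every time, and jointly selected subsets
at small n can interpolate the noise so well that every coefficient of
a pure-overfit model looks significant.

The outlier protocol refits after removing, one at a time, the molecule
with the largest standardized residual beyond the 2-sigma limit, and
records the full trace; a run that exhausts its removal budget is
labelled "no acceptable model".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .errors import ConfigError, SingularityError
from .matrix import DescriptorMatrix

OUTLIER_SIGMA = 2.0


def _frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, DescriptorMatrix):
        return matrix.values
    return matrix


@dataclass
class RegressionReport:
    """Fitted affinity model with the complete diagnostic panel."""

    selected_columns: list[str]
    coefficients: pd.Series  # includes "intercept"
    std_errors: pd.Series
    n: int
    k: int
    R: float
    R2: float
    R2_adj: float
    F: float
    F_dof: tuple[int, int]
    F_p: float
    SD: float
    standardized_betas: pd.Series  # predictors only
    t_values: pd.Series
    p_values: pd.Series
    predictor_r2_matrix: pd.DataFrame
    fitted: pd.Series
    residuals: pd.Series
    standardized_residuals: pd.Series
    outliers: list  # molecule ids with |standardized residual| > 2

    def summary_frame(self) -> pd.DataFrame:
        """Per-predictor table mirroring a beta/t/p diagnostics layout."""
        return pd.DataFrame(
            {
                "coefficient": self.coefficients.drop("intercept"),
                "std_error": self.std_errors.drop("intercept"),
                "beta": self.standardized_betas,
                "t": self.t_values.drop("intercept"),
                "p": self.p_values.drop("intercept"),
            }
        )

    def to_dict(self) -> dict:
        return {
            "selected_columns": list(self.selected_columns),
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "n": self.n,
            "k": self.k,
            "R": self.R,
            "R2": self.R2,
            "R2_adj": self.R2_adj,
            "F": self.F,
            "F_dof": list(self.F_dof),
            "F_p": self.F_p,
            "SD": self.SD,
            "standardized_betas": self.standardized_betas.to_dict(),
            "t_values": self.t_values.to_dict(),
            "p_values": self.p_values.to_dict(),
            "outliers": [str(o) for o in self.outliers],
        }


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, piv = qr(design, mode="economic", pivoting=True)
        dependent = sorted(
            columns[j - 1] for j in piv[rank:] if j > 0
        )
        raise SingularityError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{design.shape[1]}); linearly dependent column(s): "
            f"{dependent}",
            dependent_columns=dependent,
        )


def fit(
    matrix,
    columns: Sequence[str],
    activities: pd.Series,
) -> RegressionReport:
    """OLS of log K on ``columns`` with intercept, full diagnostics.

    ``matrix`` is a DescriptorMatrix or a plain DataFrame indexed by
    molecule_id; ``activities`` must cover its rows.

    Raises
    ------
    SingularityError
        If the design matrix is rank deficient; names the dependent
        columns.
    """
    frame = _frame(matrix)
    columns = list(columns)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise KeyError(f"columns not in matrix: {missing}")
    X = frame[columns]
    y = activities.loc[X.index].astype(float)
    n, k = len(y), len(columns)
    if n <= k + 1:
        raise ConfigError(
            f"n = {n} rows cannot support k = {k} predictors plus "
            "intercept (need n > k + 1)"
        )
    _check_rank(X.to_numpy(dtype=float), columns)

    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y.to_numpy(dtype=float), design).fit()

    names = ["intercept"] + columns
    coefs = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    tvals = pd.Series(res.tvalues, index=names)
    pvals = pd.Series(res.pvalues, index=names)

    fitted = pd.Series(res.fittedvalues, index=X.index)
    residuals = y - fitted
    ss_res = float(residuals.pow(2).sum())
    dof = n - k - 1
    sd = math.sqrt(ss_res / dof)
    r2 = float(res.rsquared)
    with np.errstate(divide="ignore", invalid="ignore"):
        std_resid = residuals / sd if sd > 0 else residuals * 0.0

    y_sd = float(y.std(ddof=1))
    betas = pd.Series(
        {
            c: coefs[c] * float(X[c].std(ddof=1)) / y_sd
            for c in columns
        }
    )

    r_value = (
        float(np.corrcoef(fitted, y)[0, 1]) if fitted.std() > 0 else 0.0
    )
    outliers = std_resid.index[std_resid.abs() > OUTLIER_SIGMA].tolist()
    return RegressionReport(
        selected_columns=columns,
        coefficients=coefs,
        std_errors=bse,
        n=n,
        k=k,
        R=r_value,
        R2=r2,
        R2_adj=float(res.rsquared_adj),
        F=float(res.fvalue),
        F_dof=(k, dof),
        F_p=float(res.f_pvalue),
        SD=sd,
        standardized_betas=betas,
        t_values=tvals,
        p_values=pvals,
        predictor_r2_matrix=X.corr() ** 2,
        fitted=fitted,
        residuals=residuals,
        standardized_residuals=std_resid,
        outliers=outliers,
    )


@dataclass(frozen=True)
class SearchConfig:
    """Model-search settings.

    ``alpha`` is the familywise level of the all-coefficients
    significance screen. With ``bonferroni_screen`` (default) the
    per-coefficient threshold in a k-variable model is
    alpha / C(p, k), p the number of candidate columns: a Bonferroni
    correction over the family of size-k subsets the best-subset search
    selects from (the same multiplicity the risk-inflation criterion
    penalizes). Without it, the best of ~50 noise columns clears a
    nominal 0.05 threshold almost every time, and small subsets chosen
    from hundreds of columns can interpolate the noise so well that
    every coefficient of a pure-overfit model looks significant.
    ``collinearity_cap`` bounds the squared pairwise correlation allowed
    among selected predictors. ``beam_width`` controls how many
    subsets survive each size during the best-subset beam extension.
    """

    strategy: str = "forward-stepwise"  # or "exhaustive"
    k_max: int = 5
    min_rows_per_predictor: int = 3
    collinearity_cap: float = 0.5
    alpha: float = 0.05
    bonferroni_screen: bool = True
    max_models: int = 10
    beam_width: int = 10

    def __post_init__(self):
        if self.strategy not in ("forward-stepwise", "exhaustive"):
            raise ConfigError(f"unknown search strategy {self.strategy!r}")
        if self.k_max < 1:
            raise ConfigError("k_max must be at least 1")


@dataclass
class SearchResult:
    """Ranked admissible models plus a diagnostic summary of the search."""

    models: list[RegressionReport] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.models)

    @property
    def best(self) -> RegressionReport | None:
        return self.models[0] if self.models else None


def _adj_r2(rss: float, tss: float, n: int, k: int) -> float:
    if tss == 0 or n - k - 1 <= 0:
        return -math.inf
    return 1.0 - (rss / (n - k - 1)) / (tss / (n - 1))


class _FastScan:
    """Closed-form OLS statistics on centered data, for subset scanning.

    Built once per search: the Gram matrix of the centered candidate
    columns and their covariance with centered y give RSS, slope
    estimates and slope t-tests for any small subset without touching
    the raw design again. statsmodels reproduces these numbers exactly
    for the reported models; this path exists because best-subset
    scanning evaluates thousands of subsets.
    """

    def __init__(self, frame: pd.DataFrame, y: pd.Series):
        self.columns = list(frame.columns)
        self.n = len(y)
        X = frame.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        yv = y.to_numpy(dtype=float)
        yc = yv - yv.mean()
        self.C = Xc.T @ Xc
        self.c = Xc.T @ yc
        self.tss = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt(np.diag(self.C))
            self.r2 = (self.C / np.outer(d, d)) ** 2
        np.fill_diagonal(self.r2, 1.0)

    def rss(self, idx: tuple[int, ...]) -> float:
        G = self.C[np.ix_(idx, idx)]
        g = self.c[list(idx)]
        try:
            beta = np.linalg.solve(G, g)
        except np.linalg.LinAlgError:
            return math.inf
        return max(float(self.tss - g @ beta), 0.0)

    def stats(
        self, idx: tuple[int, ...]
    ) -> tuple[float, np.ndarray] | None:
        """(RSS, |t| of each slope) for one subset; None if singular or
        under-determined. A perfect fit reports infinite |t|."""
        lst = list(idx)
        G = self.C[np.ix_(lst, lst)]
        g = self.c[lst]
        dof = self.n - len(idx) - 1
        if dof <= 0:
            return None
        try:
            Ginv = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            return None
        # guard near-singular Gram matrices that inv() tolerates
        if np.linalg.cond(G) > 1e12:
            return None
        beta = Ginv @ g
        rss = max(float(self.tss - g @ beta), 0.0)
        sigma2 = rss / dof
        if sigma2 == 0:
            return rss, np.full(len(idx), np.inf)
        se = np.sqrt(sigma2 * np.diag(Ginv))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(beta / se)
        return rss, t

    def collinear(self, idx: Sequence[int], cap: float) -> bool:
        for a, b in itertools.combinations(idx, 2):
            if self.r2[a, b] > cap:
                return True
        return False

    def best_pairs_and_singles(
        self, cap: float, keep: int
    ) -> list[tuple[float, tuple[int, ...]]]:
        """Exhaustive sizes 1 and 2 by closed-form RSS; (rss, idx)
        pairs for the ``keep`` best of each size."""
        p = len(self.columns)
        diag = np.diag(self.C).copy()
        ok = diag > 0
        singles = []
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = self.tss - np.where(ok, self.c**2 / diag, -math.inf)
        order = np.argsort(rss1)
        singles = [
            (float(rss1[j]), (int(j),)) for j in order[:keep] if ok[j]
        ]
        # pairs: 2x2 normal equations, vectorized over the upper triangle
        Cii = diag[:, None]
        Cjj = diag[None, :]
        Cij = self.C
        det = Cii * Cjj - Cij**2
        ci = self.c[:, None]
        cj = self.c[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            b1 = (Cjj * ci - Cij * cj) / det
            b2 = (Cii * cj - Cij * ci) / det
            rss2 = self.tss - (ci * b1 + cj * b2)
        bad = (
            (det <= 1e-12 * np.maximum(Cii * Cjj, 1e-300))
            | (self.r2 > cap)
            | ~np.isfinite(rss2)
        )
        iu = np.triu_indices(p, k=1)
        vals = np.where(bad[iu], math.inf, rss2[iu])
        order = np.argsort(vals)[:keep]
        pairs = [
            (float(vals[m]), (int(iu[0][m]), int(iu[1][m])))
            for m in order
            if math.isfinite(vals[m])
        ]
        return singles + pairs


def search(
    matrix,
    activities: pd.Series,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Find the best-ranked admissible affinity models.

    Best-subset search: subsets of sizes 1 and 2 are enumerated
    exhaustively by closed-form least squares; the best survivors are
    extended one column at a time (beam of ``beam_width``) up to
    ``k_max``. When the union of visited columns has at most 20
    members, every subset of that pool is enumerated as a refinement
    pass. Every visited subset then faces the collinearity cap and the
    all-coefficients significance screen; admissible models are ranked
    by adjusted R^2 (ties broken lexicographically on sorted column
    labels) and the top ``max_models`` are refit for full diagnostics.
    With ``strategy="exhaustive"`` all subsets of the whole candidate
    set are enumerated instead (at most 25 candidate columns).

    Returns an empty :class:`SearchResult` with diagnostics, never an
    exception, when no admissible model exists.
    """
    config = config or SearchConfig()
    frame = _frame(matrix)
    y = activities.loc[frame.index].astype(float)
    n = len(y)
    candidates = list(frame.columns)
    if config.k_max * config.min_rows_per_predictor > n:
        raise ConfigError(
            f"k_max ({config.k_max}) x min_rows_per_predictor "
            f"({config.min_rows_per_predictor}) exceeds n = {n}"
        )
    k_cap = min(config.k_max, n - 2)
    p_cand = max(len(candidates), 1)

    def alpha_for(k: int) -> float:
        if not config.bonferroni_screen:
            return config.alpha
        return config.alpha / float(math.comb(p_cand, min(k, p_cand)))

    scan = _FastScan(frame, y)
    cap = config.collinearity_cap

    visited: set[tuple[int, ...]] = set()
    if config.strategy == "exhaustive":
        if len(candidates) > 25:
            raise ConfigError(
                "exhaustive strategy limited to 25 candidate columns; "
                f"got {len(candidates)}"
            )
        for size in range(1, k_cap + 1):
            for combo in itertools.combinations(range(len(candidates)), size):
                visited.add(combo)
        pool = list(range(len(candidates)))
    else:
        seeds = [
            s
            for s in scan.best_pairs_and_singles(cap, keep=config.beam_width)
            if len(s[1]) <= k_cap
        ]
        beam = []
        for rss, idx in seeds:
            visited.add(idx)
            beam.append((rss, idx))
        beam.sort()
        beam = beam[: config.beam_width]
        size = 2
        while size < k_cap and beam:
            extensions: list[tuple[float, tuple[int, ...]]] = []
            for _, idx in beam:
                if len(idx) != size:
                    continue
                for j in range(len(candidates)):
                    if j in idx:
                        continue
                    new = tuple(sorted((*idx, j)))
                    if new in visited:
                        continue
                    if scan.collinear(new, cap):
                        continue
                    rss = scan.rss(new)
                    if math.isfinite(rss):
                        visited.add(new)
                        extensions.append((rss, new))
            extensions.sort()
            beam = extensions[: config.beam_width]
            size += 1
        pool_cols: list[int] = []
        ranked = sorted(
            visited, key=lambda idx: _rank_key(scan, n, idx)
        )
        for idx in ranked:
            for j in idx:
                if j not in pool_cols:
                    pool_cols.append(j)
            if len(pool_cols) >= 20:
                break
        pool = pool_cols[:20]
        if len(pool) <= 20:
            for size in range(1, min(k_cap, len(pool)) + 1):
                for combo in itertools.combinations(sorted(pool), size):
                    visited.add(tuple(sorted(combo)))

    from scipy import stats as _st

    t_threshold = {
        k: float(_st.t.isf(alpha_for(k) / 2.0, n - k - 1))
        for k in range(1, k_cap + 1)
        if n - k - 1 > 0
    }
    admissible: list[tuple[float, tuple[str, ...], tuple[int, ...]]] = []
    rejected = {"collinear": 0, "screen": 0, "singular": 0}
    for idx in visited:
        if scan.collinear(idx, cap):
            rejected["collinear"] += 1
            continue
        out = scan.stats(idx)
        if out is None:
            rejected["singular"] += 1
            continue
        rss, tvals = out
        if not np.all(tvals >= t_threshold[len(idx)]):
            rejected["screen"] += 1
            continue
        adj = _adj_r2(rss, scan.tss, n, len(idx))
        labels = tuple(sorted(scan.columns[j] for j in idx))
        admissible.append((-adj, labels, idx))
    admissible.sort()

    models = []
    for _, _, idx in admissible[: config.max_models]:
        try:
            models.append(
                fit(frame, [scan.columns[j] for j in sorted(idx)], y)
            )
        except SingularityError:
            continue
    return SearchResult(
        models=models,
        diagnostics={
            "n_candidates": len(candidates),
            "pool": sorted(scan.columns[j] for j in pool),
            "models_examined": len(visited),
            "n_admissible": len(admissible),
            "rejected": rejected,
            "alpha_per_coefficient": {
                k: alpha_for(k) for k in range(1, k_cap + 1)
            },
        },
    )


def _rank_key(scan: _FastScan, n: int, idx: tuple[int, ...]):
    return -_adj_r2(scan.rss(idx), scan.tss, n, len(idx))


@dataclass
class OutlierStep:
    report: RegressionReport
    flagged: list
    removed: object | None  # molecule id removed after this fit


@dataclass
class OutlierTrace:
    """Full record of the iterative >2-sigma outlier protocol."""

    steps: list[OutlierStep]
    status: str  # "clean" | "no acceptable model" | "under-determined"
    removed: list

    @property
    def final_report(self) -> RegressionReport:
        return self.steps[-1].report


def outlier_protocol(
    matrix,
    activities: pd.Series,
    columns: Sequence[str],
    max_removals: int = 3,
    sigma: float = OUTLIER_SIGMA,
) -> OutlierTrace:
    """Iteratively refit after removing the worst >sigma outlier.

    Each step fits on the remaining molecules and flags those whose
    standardized residual magnitude exceeds ``sigma``. If any are
    flagged, the single worst one is removed and the model refit. The
    trace ends "clean" (no molecule flagged), "no acceptable model"
    (removal budget exhausted with outliers still flagged) or
    "under-determined" (too few molecules would remain to refit).
    """
    frame = _frame(matrix)
    keep = list(frame.index)
    k = len(columns)
    steps: list[OutlierStep] = []
    removed: list = []
    while True:
        report = fit(frame.loc[keep], columns, activities)
        std = report.standardized_residuals
        flagged = std.index[std.abs() > sigma].tolist()
        if not flagged:
            steps.append(OutlierStep(report, [], None))
            return OutlierTrace(steps, "clean", removed)
        worst = std.abs().idxmax()
        if len(removed) >= max_removals:
            steps.append(OutlierStep(report, flagged, None))
            return OutlierTrace(steps, "no acceptable model", removed)
        if len(keep) - 1 <= k + 2:
            steps.append(OutlierStep(report, flagged, None))
            return OutlierTrace(steps, "under-determined", removed)
        steps.append(OutlierStep(report, flagged, worst))
        removed.append(worst)
        keep.remove(worst)
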