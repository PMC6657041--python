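"""Exploratory factor analysis of the weekly mobility-indicator matrix.

Covers the full analysis chain: per-column normalizing transformation
(original / log / square root, chosen by skewness), Kaiser-Meyer-Olkin
sampling adequacy, Bartlett's sphericity test, non-graphical scree
estimation of the number of factors (Kaiser rule, parallel analysis,
optimal coordinates, acceleration factor, combined by a mode-else-median
rule), maximum-likelihood factor extraction with varimax rotation, and the
pair matrix that counts how often indicator pairs co-load across repeated
runs of the random day selection.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor import Factor

__all__ = [
    "TransformResult",
    "FactorSolution",
    "PairMatrix",
    "transform_columns",
    "kmo",
    "bartlett_sphericity",
    "estimate_n_factors",
    "fit_efa",
    "pair_matrix",
    "run_study",
]

LOADING_THRESHOLD = 0.4


@dataclass
class TransformResult:
    """Transformed indicator matrix plus the per-column transform tags."""

    data: pd.DataFrame
    transforms: dict[str, str]  # column -> {original, log, sqrt}


@dataclass
class FactorSolution:
    """One ML factor-analysis result after varimax rotation."""

    n_factors: int
    loadings: pd.DataFrame  # variables x factors
    variance_share: np.ndarray  # per factor, fraction of total variance
    cumulative_variance: float
    fit_p: float | None  # likelihood-ratio sufficiency test
    rotation: str = "varimax"
    suggestions: dict[str, int] = field(default_factory=dict)
    loadings_unrotated: pd.DataFrame | None = None

    @property
    def primary_factor(self) -> pd.Series:
        """Per variable, the factor it loads on most strongly (by |loading|)."""
        return self.loadings.abs().idxmax(axis=1)


@dataclass
class PairMatrix:
    """Indicator x indicator co-assignment counts over repeated EFA runs."""

    counts: pd.DataFrame
    n_runs: int
    threshold: float = LOADING_THRESHOLD


# ---------------------------------------------------------------------------
# transformation


def transform_columns(df: pd.DataFrame) -> TransformResult:
    """Choose per column among original / log / sqrt by minimal |skewness|.

    The log candidate uses a machine-small offset when zeros are present;
    candidates are skipped for columns with negative values. Ties keep the
    least aggressive transform (original before sqrt before log).
    """
    def abs_skew(v: np.ndarray) -> float:
        if np.std(v) < 1e-9 * (1.0 + float(np.abs(v).max(initial=0.0))):
            return math.inf  # (near-)constant: skewness meaningless
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = float(stats.skew(v, bias=False))
        return abs(s) if np.isfinite(s) else math.inf

    out = {}
    tags = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        order = {"original": 0, "sqrt": 1, "log": 2}
        candidates: list[tuple[float, str, np.ndarray]] = [(abs_skew(x), "original", x)]
        if np.all(x >= 0.0):
            candidates.append((abs_skew(np.sqrt(x)), "sqrt", np.sqrt(x)))
            offset = np.finfo(float).tiny if np.any(x == 0.0) else 0.0
            lx = np.log(x + offset)
            if np.all(np.isfinite(lx)):
                candidates.append((abs_skew(lx), "log", lx))
        skw, tag, xt = min(candidates, key=lambda c: (c[0], order[c[1]]))
        out[col] = xt
        tags[col] = tag
    return TransformResult(pd.DataFrame(out, index=df.index), tags)


# ---------------------------------------------------------------------------
# sampling adequacy


def _corr(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        bad = [str(c) for c, s in zip(df.columns, sd) if s == 0.0]
        raise ValueError(f"constant column(s), correlation undefined: {bad}")
    return np.corrcoef(x, rowvar=False)


def kmo(df: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1].

    Compares summed squared correlations against summed squared partial
    correlations (from the inverse correlation matrix); values above 0.5
    are conventionally considered adequate for factor analysis.
    """
    r = _corr(df)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    if np.any(np.diag(rinv) <= 0.0):
        raise ValueError(
            "correlation matrix is not positive definite "
            "(fewer observations than variables?)"
        )
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    np.fill_diagonal(partial, 0.0)
    np.fill_diagonal(r, 0.0)
    ssq_r = float(np.sum(r**2))
    ssq_p = float(np.sum(partial**2))
    return ssq_r / (ssq_r + ssq_p)


def bartlett_sphericity(df: pd.DataFrame) -> tuple[float, float]:
    """Bartlett's test of sphericity against an identity correlation matrix.

    Returns (chi-square statistic, p-value); df = p(p-1)/2.
    """
    n, p = df.shape
    r = _corr(df)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    ddof = p * (p - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, ddof))


# ---------------------------------------------------------------------------
# number of factors


def _parallel_mean_eigenvalues(n: int, p: int, n_rep: int, rng: np.random.Generator) -> np.ndarray:
    acc = np.zeros(p)
    for _ in range(n_rep):
        x = rng.standard_normal((n, p))
        acc += np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    return acc / n_rep


def estimate_n_factors(
    df: pd.DataFrame,
    rng_seed: int = 0,
    n_parallel: int = 100,
) -> tuple[dict[str, int], int]:
    """Non-graphical scree estimation of the number of factors.

    Four estimators on the correlation eigenvalues: Kaiser rule (count > 1),
    parallel analysis (count exceeding the mean eigenvalues of ``n_parallel``
    seeded random normal data sets of the same shape), optimal coordinates
    (observed eigenvalue above its value extrapolated from the next
    eigenvalue and the last one), and acceleration factor (elbow = maximal
    second difference of the scree). The chosen count is the mode of the
    four suggestions; with exactly two modes — or no repeated value — the
    median is used.
    """
    n, p = df.shape
    eig = np.sort(np.linalg.eigvalsh(_corr(df)))[::-1]
    suggestions = scree_suggestions(eig, n, rng_seed=rng_seed, n_parallel=n_parallel)
    chosen = _mode_else_median(list(suggestions.values()))
    return suggestions, chosen


def scree_suggestions(
    eig: np.ndarray, n_obs: int, rng_seed: int = 0, n_parallel: int = 100
) -> dict[str, int]:
    """The four non-graphical scree counts for a correlation spectrum.

    ``eig`` must be the correlation eigenvalues in decreasing order;
    ``n_obs`` the number of observations behind them (used by parallel
    analysis to size its random data sets).
    """
    eig = np.asarray(eig, dtype=float)
    p = eig.size

    kaiser = int(np.sum(eig > 1.0))  # strictly greater than 1

    rng = np.random.default_rng(rng_seed)
    mean_rand = _parallel_mean_eigenvalues(n_obs, p, n_parallel, rng)
    parallel = int(np.argmin(eig > mean_rand)) if not np.all(eig > mean_rand) else p

    # optimal coordinates: predict eigenvalue i by the line through
    # (i+1, eig[i+1]) and (p, eig[p-1]); count leading eigenvalues above
    # their prediction
    oc = 0
    for i in range(p - 2):
        slope = (eig[p - 1] - eig[i + 1]) / ((p - 1) - (i + 1))
        pred = eig[i + 1] + slope * (i - (i + 1))
        if eig[i] >= pred:
            oc = i + 1
        else:
            break
    oc = max(oc, 1)

    # acceleration factor: the elbow is where the scree bends most sharply
    second_diff = eig[2:] - 2.0 * eig[1:-1] + eig[:-2]
    af = int(np.argmax(second_diff)) + 1  # factors before the elbow
    af = max(af, 1)

    return {
        "kaiser": kaiser,
        "parallel": parallel,
        "optimal_coordinates": oc,
        "acceleration": af,
    }


def _mode_else_median(values: Sequence[int]) -> int:
    counts = Counter(values)
    top = counts.most_common()
    modes = [v for v, c in top if c == top[0][1]]
    if top[0][1] > 1 and len(modes) == 1:
        return modes[0]
    # two modes, or no repeated value: median of the suggestions
    return int(round(float(np.median(values))))


# ---------------------------------------------------------------------------
# maximum-likelihood factor analysis


def fit_efa(df: pd.DataFrame, n_factors: int) -> FactorSolution:
    """ML factor analysis with varimax rotation on standardized columns.

    Variance shares are per-factor sums of squared rotated loadings divided
    by the number of variables; the fit p-value is the Bartlett-corrected
    likelihood-ratio test that ``n_factors`` factors are sufficient.
    """
    n, p = df.shape
    if not 1 <= n_factors < p:
        raise ValueError(f"n_factors={n_factors} inadmissible for p={p}")
    x = (df - df.mean()) / df.std(ddof=1)
    fa = Factor(x.to_numpy(), n_factor=n_factors, method="ml")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Fitting did not converge")
            res = fa.fit(maxiter=500)
    except Exception as exc:  # statsmodels raises generic errors on Heywood cases
        raise RuntimeError(f"ML factor analysis failed to converge: {exc}") from exc
    uniqueness = np.asarray(res.uniqueness, dtype=float)
    if np.any(uniqueness <= 1e-6):
        raise RuntimeError(
            "Heywood case: zero uniqueness for "
            f"{list(df.columns[uniqueness <= 1e-6])}"
        )
    unrotated = pd.DataFrame(
        np.asarray(res.loadings, dtype=float).copy(),
        index=df.columns,
        columns=[f"F{i + 1}" for i in range(n_factors)],
    )
    if n_factors > 1:
        res.rotate("varimax")
    loadings = pd.DataFrame(
        np.asarray(res.loadings, dtype=float),
        index=df.columns,
        columns=[f"F{i + 1}" for i in range(n_factors)],
    )
    # order factors by explained variance, flip signs so each factor's
    # largest loading is positive (rotation leaves both arbitrary)
    ssq = (loadings**2).sum(axis=0).to_numpy()
    order = np.argsort(ssq)[::-1]
    loadings = loadings.iloc[:, order]
    loadings.columns = [f"F{i + 1}" for i in range(n_factors)]
    for c in loadings.columns:
        if loadings[c].loc[loadings[c].abs().idxmax()] < 0:
            loadings[c] = -loadings[c]
    variance_share = (loadings**2).sum(axis=0).to_numpy() / p
    fit_p = _sufficiency_p(_corr(df), loadings.to_numpy(), uniqueness, n)
    return FactorSolution(
        n_factors=n_factors,
        loadings=loadings,
        variance_share=variance_share,
        cumulative_variance=float(variance_share.sum()),
        fit_p=fit_p,
        loadings_unrotated=unrotated,
    )


def _sufficiency_p(r: np.ndarray, loadings: np.ndarray, uniqueness: np.ndarray, n: int) -> float | None:
    """Likelihood-ratio test that k factors are sufficient (factanal-style)."""
    p, k = loadings.shape
    dof = ((p - k) ** 2 - p - k) / 2.0
    if dof <= 0:
        return None
    sigma = loadings @ loadings.T + np.diag(uniqueness)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(r)
    if sign_s <= 0 or sign_r <= 0:
        return None
    objective = logdet_s + np.trace(r @ np.linalg.inv(sigma)) - logdet_r - p
    stat = (n - 1 - (2 * p + 5) / 6.0 - 2.0 * k / 3.0) * objective
    return float(stats.chi2.sf(max(stat, 0.0), dof))


# ---------------------------------------------------------------------------
# multi-run summary


def pair_matrix(solutions: Sequence[FactorSolution], threshold: float = LOADING_THRESHOLD) -> PairMatrix:
    """Count co-appearances of indicator pairs in the same factor across runs.

    Per run, an indicator belongs to every factor where |loading| >=
    ``threshold``; a pair is counted once per run if the two indicators
    share at least one factor. The diagonal counts the runs in which the
    indicator loaded anywhere at all.
    """
    if not solutions:
        raise ValueError("no solutions")
    cols = list(solutions[0].loadings.index)
    counts = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for sol in solutions:
        if list(sol.loadings.index) != cols:
            raise ValueError("solutions must share the indicator set")
        a = sol.loadings.abs().to_numpy() >= threshold
        co = (a @ a.T) > 0  # share at least one factor
        counts += np.where(co, 1, 0)
    return PairMatrix(counts=counts, n_runs=len(solutions), threshold=threshold)


def run_study(
    matrix_source: Callable[[tuple[int, float], int], pd.DataFrame],
    conditions: Sequence[tuple[int, float]],
    n_runs: int = 10,
    base_seed: int = 0,
) -> dict:
    """Repeated EFA over data conditions and random day selections.

    ``matrix_source(condition, run_seed)`` must return the weekly indicator
    matrix (participants x indicators, no missing cells) for the given
    (min_days, min_hours) condition and run seed. For each condition,
    ``n_runs`` runs re-draw the study days, re-transform, re-estimate the
    factor count and refit; failing runs are recorded and skipped. Returns
    per-condition run summaries plus a pair matrix.
    """
    report: dict = {"conditions": {}}
    for ci, cond in enumerate(conditions):
        runs = []
        solutions = []
        for r in range(n_runs):
            seed = base_seed + 1000 * ci + r
            try:
                raw = matrix_source(cond, seed)
                raw = raw.dropna()
                tr = transform_columns(raw)
                suggestions, chosen = estimate_n_factors(tr.data, rng_seed=seed)
                sol = fit_efa(tr.data, chosen)
                sol.suggestions = suggestions
                solutions.append(sol)
                runs.append(
                    {
                        "seed": seed,
                        "n_obs": int(len(raw)),
                        "n_factors": chosen,
                        "suggestions": suggestions,
                        "transforms": tr.transforms,
                        "variance_shares": sol.variance_share.tolist(),
                        "cumulative_variance": sol.cumulative_variance,
                        "fit_p": sol.fit_p,
                        "kmo": kmo(tr.data),
                        "bartlett_p": bartlett_sphericity(tr.data)[1],
                        "loadings": sol.loadings.round(4).to_dict(),
                    }
                )
            except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
                runs.append({"seed": seed, "error": str(exc)})
        key = f"{cond[0]}d_{cond[1]:g}h"
        report["conditions"][key] = {
            "runs": runs,
            "pair_matrix": pair_matrix(solutions).counts.to_dict() if solutions else None,
            "n_ok": len(solutions),
        }
    return report
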