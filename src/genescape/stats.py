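"""Matrix correlation and curve-fitting statistics.

Mantel tests relate pairwise genetic similarity (Dps) to pairwise
resistance distance; the permutation null jointly permutes rows and
columns of one matrix. Distance-decay and connectivity-diversity
relationships are compared across three forms — linear, logarithmic and
exponential — fitted by (transformed) ordinary least squares and ranked
by adjusted R^2 evaluated on the original response scale so the forms
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["MantelResult", "FitResult", "mantel_test", "fit_three_forms", "relate_diversity_to_connectivity"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_pairs: int


@dataclass
class FitResult:
    form: str  # linear | logarithmic | exponential
    a: float
    b: float
    adjusted_r2: float
    p: float
    n: int
    best: bool = False


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two symmetric matrices.

    r is the Pearson correlation of the vectorized strict upper triangles;
    pairs where either matrix is non-finite are dropped (the mask is
    recomputed under each permutation). The two-sided permutation p-value
    uses the add-one correction (count(|r_perm| >= |r_obs|) + 1) /
    (n_perm + 1). With n_perm=0 only r is computed (p is NaN).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = m1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes for a Mantel test")

    def corr(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            return np.nan, int(ok.sum())
        return float(np.corrcoef(a[ok], b[ok])[0, 1]), int(ok.sum())

    v1 = _upper(m1)
    r_obs, n_pairs = corr(v1, _upper(m2))
    if n_perm <= 0:
        return MantelResult(r=r_obs, p=float("nan"), n_permutations=0, n_pairs=n_pairs)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p, _ = corr(v1, _upper(m2[np.ix_(perm, perm)]))
        if np.isnan(r_p) or abs(r_p) >= abs(r_obs):
            count += 1
    return MantelResult(r=r_obs, p=(count + 1) / (n_perm + 1), n_permutations=n_perm, n_pairs=n_pairs)


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    n = len(y)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_three_forms(x: np.ndarray, y: np.ndarray) -> list[FitResult]:
    """Fit linear, logarithmic and exponential models and flag the best.

    linear: y = a + b x (OLS); logarithmic: y = a + b ln x (OLS on ln x,
    points with x <= 0 dropped); exponential: y = a e^(bx) (OLS of ln y on
    x, points with y <= 0 dropped). Adjusted R^2 is computed from
    predictions on the original y scale for all three; p is the slope
    test of the fitting-scale regression. Best = highest adjusted R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")

    fits: list[FitResult] = []

    res = sps.linregress(x, y)
    fits.append(FitResult("linear", float(res.intercept), float(res.slope),
                          _adjusted_r2(y, res.intercept + res.slope * x), float(res.pvalue), len(x)))

    pos_x = x > 0
    if pos_x.sum() >= 3 and np.std(np.log(x[pos_x])) > 0:
        lx, ly = np.log(x[pos_x]), y[pos_x]
        res = sps.linregress(lx, ly)
        fits.append(FitResult("logarithmic", float(res.intercept), float(res.slope),
                              _adjusted_r2(ly, res.intercept + res.slope * lx), float(res.pvalue),
                              int(pos_x.sum())))

    pos_y = y > 0
    if pos_y.sum() >= 3 and np.std(x[pos_y]) > 0:
        xe, lye = x[pos_y], np.log(y[pos_y])
        res = sps.linregress(xe, lye)
        a, b = float(np.exp(res.intercept)), float(res.slope)
        fits.append(FitResult("exponential", a, b,
                              _adjusted_r2(y[pos_y], a * np.exp(b * xe)), float(res.pvalue),
                              int(pos_y.sum())))

    valid = [f for f in fits if np.isfinite(f.adjusted_r2)]
    if valid:
        max(valid, key=lambda f: f.adjusted_r2).best = True
    return fits


def relate_diversity_to_connectivity(
    summaries: pd.DataFrame,
    connectivity: np.ndarray,
    indices: tuple[str, ...] = ("n_s", "a_r", "h_o", "h_e"),
) -> dict[str, list[FitResult]]:
    """Fit the three forms of each diversity index against connectivity.

    ``summaries`` rows must align with ``connectivity`` (same node order);
    NaN summary rows are dropped per index.
    """
    connectivity = np.asarray(connectivity, dtype=float)
    if len(summaries) != len(connectivity):
        raise ValueError("summaries and connectivity must cover the same nodes")
    out: dict[str, list[FitResult]] = {}
    for name in indices:
        y = summaries[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        out[name] = fit_three_forms(connectivity[ok], y[ok])
    return out


def fits_to_frame(fits_by_key: dict[str, list[FitResult]], **extra: str) -> pd.DataFrame:
    """Flatten fit results to a tidy table (one row per form per key)."""
    rows = []
    for key, fits in fits_by_key.items():
        for f in fits:
            rows.append({**extra, "relationship": key, "form": f.form, "a": f.a, "b": f.b,
                         "adjusted_r2": f.adjusted_r2, "p": f.p, "n": f.n, "best": f.best})
    return pd.DataFrame(rows)
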