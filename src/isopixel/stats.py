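"""Spatial C-N coupling statistics.

The centrepiece is the continuous two-segment ("breakpoint") linear
regression

    y = b0 + a_low * x + (a_high - a_low) * max(0, x - BP),

fitted by an exhaustive profile search of the residual sum of squares over
interior x-quantile candidates, refined by iterative linearization (the
working-model update of Muggeo 2003) to a configurable tolerance on BP.
Breakpoint existence is screened by a Davies-type maximum-score test; when
it is non-significant the fit falls back to a plain line and the breakpoint
is reported as undefined. The breakpoint standard error comes from a seeded
nonparametric pairs bootstrap (a delta-method variant is available).

Also here: information-criterion model selection across linear / log-x /
log-y / log-log / segmented candidates with the log-Jacobian correction
that makes transformed-response likelihoods comparable on the original
scale, Spearman rank correlation (exact permutation p at small n),
line-scan profiles binned at a fixed number of pixels per data point, and
per-side weighted means plus OLS fits for split-root bulk tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SegmentedFit",
    "ModelSelectionResult",
    "SideResult",
    "fit_segmented",
    "grid_search_breakpoint",
    "davies_test",
    "select_model",
    "spearman_correlation",
    "line_scan_profile",
    "root_side_analysis",
]


@dataclass
class SegmentedFit:
    """Result of a breakpoint regression of y on x.

    When the breakpoint-existence test is non-significant the model falls
    back to a single line: ``segmented`` is False, ``breakpoint`` is NaN and
    ``slope_low`` holds the single slope.
    """

    breakpoint: float
    se_breakpoint: float
    slope_low: float
    slope_high: float
    intercept: float
    r2: float
    r2_low: float
    r2_high: float
    p_low: float
    p_high: float
    p_existence: float
    n: int
    segmented: bool
    converged: bool
    rss: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not self.segmented:
            return self.intercept + self.slope_low * x
        return (self.intercept + self.slope_low * x
                + (self.slope_high - self.slope_low) * np.maximum(0.0, x - self.breakpoint))


def _design(x: np.ndarray, bp: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - bp)])


def _rss_for_candidates(x: np.ndarray, y: np.ndarray, cands: np.ndarray) -> np.ndarray:
    """RSS of the 3-parameter segmented fit at each candidate breakpoint.

    Vectorized over candidates through batched normal equations.
    """
    n = x.size
    u = np.maximum(0.0, x[None, :] - cands[:, None])  # (k, n)
    s1 = float(n)
    sx = x.sum()
    sxx = (x * x).sum()
    sy = y.sum()
    sxy = (x * y).sum()
    su = u.sum(axis=1)
    sxu = u @ x
    suu = (u * u).sum(axis=1)
    suy = u @ y
    k = cands.size
    ata = np.empty((k, 3, 3))
    ata[:, 0, 0] = s1
    ata[:, 0, 1] = ata[:, 1, 0] = sx
    ata[:, 0, 2] = ata[:, 2, 0] = su
    ata[:, 1, 1] = sxx
    ata[:, 1, 2] = ata[:, 2, 1] = sxu
    ata[:, 2, 2] = suu
    aty = np.empty((k, 3))
    aty[:, 0] = sy
    aty[:, 1] = sxy
    aty[:, 2] = suy
    # guard singular systems (candidate beyond data range)
    rss = np.full(k, np.inf)
    for i in range(k):
        try:
            beta = np.linalg.solve(ata[i], aty[i])
        except np.linalg.LinAlgError:
            continue
        resid = y - (beta[0] + beta[1] * x + beta[2] * u[i])
        rss[i] = float(resid @ resid)
    return rss


def grid_search_breakpoint(
    x: np.ndarray, y: np.ndarray, candidates: np.ndarray
) -> tuple[float, float]:
    """Exhaustive RSS profile over candidate breakpoints; (best bp, rss)."""
    rss = _rss_for_candidates(np.asarray(x, float), np.asarray(y, float),
                              np.asarray(candidates, float))
    i = int(np.argmin(rss))
    return float(candidates[i]), float(rss[i])


def _muggeo_refine(
    x: np.ndarray, y: np.ndarray, bp0: float, lo: float, hi: float,
    tol: float, max_iter: int,
) -> tuple[float, bool]:
    """Iterative-linearization refinement of the breakpoint estimate."""
    bp = bp0
    for _ in range(max_iter):
        u = np.maximum(0.0, x - bp)
        v = -(x > bp).astype(float)
        a = np.column_stack([np.ones_like(x), x, u, v])
        beta, *_ = np.linalg.lstsq(a, y, rcond=None)
        d = beta[2]
        if abs(d) < 1e-12:
            return bp, False
        step = beta[3] / d
        new = bp + step
        if not (lo <= new <= hi) or not np.isfinite(new):
            return bp, False
        if abs(new - bp) < tol:
            return new, True
        bp = new
    return bp, False


def davies_test(x: np.ndarray, y: np.ndarray, k: int = 50,
                quantile_range: tuple[float, float] = (0.05, 0.95)) -> float:
    """Approximate p-value for the existence of a breakpoint.

    Score-type test: the maximum |t| of the hinge term added to the linear
    model over k interior candidates, with the Davies upper bound for the
    correlated maximum. Degenerate (zero-residual) linear fits return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    lo, hi = np.quantile(x, quantile_range)
    cands = np.linspace(lo, hi, k)
    tvals = np.empty(k)
    ok = np.zeros(k, dtype=bool)
    for i, c in enumerate(cands):
        a = _design(x, c)
        beta, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ beta
        dof = n - 3
        if dof <= 0:
            return 1.0
        s2 = float(resid @ resid) / dof
        if s2 <= 0 or not np.isfinite(s2):
            # segmented model fits exactly: a kink trivially exists if the
            # linear model does not also fit exactly
            lin = np.column_stack([np.ones_like(x), x])
            bl, *_ = np.linalg.lstsq(lin, y, rcond=None)
            rl = y - lin @ bl
            return 1.0 if float(rl @ rl) < 1e-12 else 0.0
        try:
            cov = s2 * np.linalg.inv(a.T @ a)
        except np.linalg.LinAlgError:
            continue
        se = np.sqrt(cov[2, 2])
        if se > 0:
            tvals[i] = beta[2] / se
            ok[i] = True
    if not ok.any():
        return 1.0
    tvals = tvals[ok]
    m = float(np.max(np.abs(tvals)))
    # Davies (1987) bound for the supremum of a Gaussian process
    p_point = 2.0 * sps.norm.sf(m)
    v = float(np.sum(np.abs(np.diff(tvals))))
    p = p_point + v * np.exp(-m * m / 2.0) / np.sqrt(8.0 * np.pi)
    return float(min(1.0, p))


def _sub_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R2, slope p-value) of a per-segment line; NaN when degenerate."""
    if x.size < 3 or np.unique(x).size < 2:
        return float("nan"), float("nan")
    res = sps.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    *,
    grid: int = 200,
    quantile_range: tuple[float, float] = (0.05, 0.95),
    tol: float = 1e-8,
    max_iter: int = 100,
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    force_segmented: bool = False,
) -> SegmentedFit:
    """Fit the continuous two-segment regression of y on x.

    Profile grid search over ``grid`` interior x-quantile candidates,
    refined by iterative linearization to ``tol`` on the breakpoint.
    Breakpoint existence is tested at level ``alpha`` (Davies-type); a
    non-significant test triggers the plain-linear fallback unless
    ``force_segmented``. SE(BP) by pairs bootstrap with ``n_boot``
    resamples (0 skips it).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 points, got {n}")
    if np.unique(x).size < 5:
        raise ValueError("x must have at least 5 distinct values")

    lin = sps.linregress(x, y)
    lin_rss = float(np.sum((y - (lin.intercept + lin.slope * x)) ** 2))
    p_exist = davies_test(x, y, quantile_range=quantile_range)

    if not force_segmented and not (p_exist < alpha):
        sst = float(np.sum((y - y.mean()) ** 2))
        return SegmentedFit(
            breakpoint=float("nan"), se_breakpoint=float("nan"),
            slope_low=float(lin.slope), slope_high=float(lin.slope),
            intercept=float(lin.intercept),
            r2=float(lin.rvalue**2), r2_low=float("nan"), r2_high=float("nan"),
            p_low=float(lin.pvalue), p_high=float("nan"), p_existence=p_exist,
            n=n, segmented=False, converged=True, rss=lin_rss,
        )

    bp, rss = _fit_bp(x, y, grid, quantile_range, tol, max_iter)
    beta, *_ = np.linalg.lstsq(_design(x, bp), y, rcond=None)
    resid = y - _design(x, bp) @ beta
    rss = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    low = x <= bp
    r2_low, p_low = _sub_fit(x[low], y[low])
    r2_high, p_high = _sub_fit(x[~low], y[~low])

    se_bp = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        coarse = max(25, grid // 4)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if np.unique(xb).size < 5:
                boots[b] = np.nan
                continue
            boots[b], _ = _fit_bp(xb, yb, coarse, quantile_range, max(tol, 1e-6), 30)
        boots = boots[np.isfinite(boots)]
        se_bp = float(np.std(boots, ddof=1)) if boots.size > 1 else float("nan")

    return SegmentedFit(
        breakpoint=float(bp), se_breakpoint=se_bp,
        slope_low=float(beta[1]), slope_high=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        r2=float(1.0 - rss / sst) if sst > 0 else float("nan"),
        r2_low=r2_low, r2_high=r2_high, p_low=p_low, p_high=p_high,
        p_existence=p_exist, n=n, segmented=True, converged=True, rss=rss,
    )


def _fit_bp(x, y, grid, quantile_range, tol, max_iter) -> tuple[float, float]:
    lo, hi = np.quantile(x, quantile_range)
    cands = np.linspace(lo, hi, grid)
    bp0, rss0 = grid_search_breakpoint(x, y, cands)
    span = (hi - lo) / max(grid - 1, 1)
    bp, ok = _muggeo_refine(x, y, bp0, max(lo, bp0 - 2 * span), min(hi, bp0 + 2 * span),
                            tol, max_iter)
    _, rss_ref = grid_search_breakpoint(x, y, np.array([bp]))
    if not np.isfinite(rss_ref) or rss_ref > rss0:
        # linearization left the RSS valley; fall back to a bounded profile search
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda c: _rss_for_candidates(x, y, np.array([c]))[0],
            bounds=(max(lo, bp0 - 2 * span), min(hi, bp0 + 2 * span)), method="bounded",
            options={"xatol": tol},
        )
        if res.fun <= rss0:
            return float(res.x), float(res.fun)
        return bp0, rss0
    return float(bp), float(rss_ref)


@dataclass
class ModelSelectionResult:
    """Candidate table and the information-criterion winner."""

    table: pd.DataFrame
    selected: str
    criterion: str
    jacobian_corrected: bool = True


def _gauss_loglik(rss: float, n: int) -> float:
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def select_model(
    x: np.ndarray,
    y: np.ndarray,
    criterion: str = "AIC",
    jacobian_correction: bool = True,
    seed: int | None = None,
) -> ModelSelectionResult:
    """Choose among linear / log-x / log-y / log-log / segmented by AIC or BIC.

    Log-transformed-response candidates are corrected by the log-Jacobian
    (sum of log y) so all likelihoods refer to the original response scale;
    the uncorrected values are reported alongside. Candidates needing a log
    of non-positive data are excluded and recorded. Ties break toward fewer
    parameters.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    rows = []

    def add(name, k, rss, log_response):
        ll_raw = _gauss_loglik(rss, n)
        jac = float(np.sum(np.log(y))) if log_response else 0.0
        ll = ll_raw - jac
        rows.append({
            "model": name, "k": k,
            "loglik": ll, "loglik_uncorrected": ll_raw,
            "aic": 2 * k - 2 * ll, "bic": k * np.log(n) - 2 * ll,
            "aic_uncorrected": 2 * k - 2 * ll_raw,
            "bic_uncorrected": k * np.log(n) - 2 * ll_raw,
            "note": "",
        })

    res = sps.linregress(x, y)
    add("linear", 3, float(np.sum((y - res.intercept - res.slope * x) ** 2)), False)

    if (x > 0).all():
        lx = np.log(x)
        r = sps.linregress(lx, y)
        add("log-x", 3, float(np.sum((y - r.intercept - r.slope * lx) ** 2)), False)
    else:
        rows.append({"model": "log-x", "note": "excluded: non-positive x"})
    if (y > 0).all():
        ly = np.log(y)
        r = sps.linregress(x, ly)
        add("log-y", 3, float(np.sum((ly - r.intercept - r.slope * x) ** 2)), True)
        if (x > 0).all():
            lx = np.log(x)
            r = sps.linregress(lx, ly)
            add("log-log", 3, float(np.sum((ly - r.intercept - r.slope * lx) ** 2)), True)
        else:
            rows.append({"model": "log-log", "note": "excluded: non-positive x"})
    else:
        rows.append({"model": "log-y", "note": "excluded: non-positive y"})
        rows.append({"model": "log-log", "note": "excluded: non-positive y"})

    try:
        seg = fit_segmented(x, y, n_boot=0, force_segmented=True, seed=seed)
        add("segmented", 5, seg.rss, False)
    except (ValueError, np.linalg.LinAlgError):
        rows.append({"model": "segmented", "note": "excluded: fit failed"})

    table = pd.DataFrame(rows)
    evaluable = table[table["note"] == ""].copy()
    if evaluable.empty:
        raise ValueError("no evaluable model candidate")
    col = criterion.lower() if jacobian_correction else criterion.lower() + "_uncorrected"
    best = evaluable.sort_values([col, "k"], kind="stable").iloc[0]
    return ModelSelectionResult(table=table, selected=str(best["model"]),
                                criterion=criterion, jacobian_corrected=jacobian_correction)


def spearman_correlation(
    x: np.ndarray, y: np.ndarray, p_method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    ``p_method='auto'`` uses the exact permutation p-value (two-sided) for
    n <= 10 on untied data and the asymptotic t-distribution otherwise;
    'exact'/'asymptotic' force one path. Constant input is undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = np.unique(x).size < n or np.unique(y).size < n
    use_exact = (p_method == "exact") or (p_method == "auto" and n <= 10 and not has_ties)
    if p_method == "exact" and (n > 10 or has_ties):
        raise ValueError("exact p-value limited to n <= 10 without ties")
    if use_exact:
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(range(1, n + 1))),
            dtype=np.int8,
        ).reshape(-1, n).astype(np.float64)
        ry_c = ry - ry.mean()
        denom = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum(ry_c**2))
        rs_all = ((perms - rx.mean()) @ ry_c) / denom
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
    else:
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rs, p


def line_scan_profile(
    image: np.ndarray,
    polyline: np.ndarray,
    bin_px: int = 3,
    pixel_size_um: float = 1.0,
    se_image: np.ndarray | None = None,
) -> pd.DataFrame:
    """Profile along a polyline, aggregated at ``bin_px`` pixels per point.

    Pixels are sampled along each polyline segment (Bresenham chain,
    consecutive duplicates dropped), then consecutive runs of ``bin_px``
    pixels are pooled into one data point: mean value, SE (propagated from
    ``se_image`` when given, otherwise the within-bin SE of the mean), and
    the distance (micrometres) of the bin centre along the path.
    """
    from skimage.draw import line as sk_line

    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    pts = np.asarray(polyline, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (k, 2) array of (row, col) vertices")
    h, w = image.shape
    if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() or (pts[:, 1] < 0).any() or (pts[:, 1] >= w).any():
        raise ValueError("polyline exits the image")
    rr_all, cc_all = [], []
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = sk_line(r0, c0, r1, c1)
        if rr_all:
            rr, cc = rr[1:], cc[1:]  # avoid doubling shared vertices
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    steps = np.hypot(np.diff(rr.astype(float)), np.diff(cc.astype(float)))
    dist = np.concatenate([[0.0], np.cumsum(steps)]) * pixel_size_um
    vals = image[rr, cc].astype(float)
    ses = se_image[rr, cc].astype(float) if se_image is not None else None

    rows = []
    for start in range(0, vals.size - bin_px + 1, bin_px):
        sl = slice(start, start + bin_px)
        v = vals[sl]
        fin = np.isfinite(v)
        if not fin.any():
            continue
        m = float(v[fin].mean())
        if ses is not None:
            s = ses[sl][fin]
            se = float(np.sqrt(np.sum(s**2)) / fin.sum())
        else:
            se = float(v[fin].std(ddof=1) / np.sqrt(fin.sum())) if fin.sum() > 1 else float("nan")
        rows.append({
            "distance_um": float(dist[sl][fin].mean()),
            "value": m, "se": se, "n_px": int(fin.sum()),
        })
    return pd.DataFrame(rows, columns=["distance_um", "value", "se", "n_px"])


@dataclass
class SideResult:
    """Weighted means and OLS fit for one root-system half."""

    side: str
    n_segments: int
    weighted_mean_ape13c: float
    weighted_mean_ape15n: float
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    p_value: float = float("nan")
    regression_available: bool = False


def root_side_analysis(
    records: pd.DataFrame, weight_col: str = "mass_mg"
) -> dict[str, SideResult]:
    """Per-side mass-weighted mean APE and OLS fit of APE15N on APE13C.

    ``records`` needs columns side, ape13c, ape15n and the weight column;
    root-tip rows (kind == 'tip') are excluded when a ``kind`` column is
    present. Sides with fewer than 2 segments get means only.
    """
    df = records
    if "kind" in df.columns:
        df = df[df["kind"] == "segment"]
    if df.empty:
        raise ValueError("no segment records")
    out: dict[str, SideResult] = {}
    for side, grp in df.groupby("side"):
        w = grp[weight_col].to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValueError("segment masses must be > 0")
        x = grp["ape13c"].to_numpy(dtype=float)
        y = grp["ape15n"].to_numpy(dtype=float)
        res = SideResult(
            side=str(side), n_segments=len(grp),
            weighted_mean_ape13c=float(np.average(x, weights=w)),
            weighted_mean_ape15n=float(np.average(y, weights=w)),
        )
        if len(grp) >= 2 and np.unique(x).size > 1:
            fit = sps.linregress(x, y)
            res.slope = float(fit.slope)
            res.intercept = float(fit.intercept)
            res.r2 = float(fit.rvalue**2)
            res.p_value = float(fit.pvalue)
            res.regression_available = True
        out[str(side)] = res
    return out
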