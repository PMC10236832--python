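"""Normalization and count-model inference for variant abundance changes.

A selection experiment asks, per variant, whether its relative abundance
changes between conditions (input vs output libraries, or between groups of
replicates).  Counts are modeled per variant with either

* a negative-binomial generalized linear model with log link, trended
  dispersion and a quasi-likelihood F-test (the ``nbql`` path), or
* a normal model on log2-CPM with mean–variance precision weights and an
  empirical-Bayes moderated t-statistic (the ``voom``-style path).

Per-sample scale enters through offsets: trimmed-mean-of-M-values (TMM)
effective library sizes give "absolute" log-fold changes, while the sum or
geometric mean of wild-type counts as offsets gives log-fold changes
relative to the wild-type (enrichment scores).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, gammaln, polygamma, xlogy
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)

TEST_RESULT_COLUMNS = ("logFC", "aveAbundance", "stat", "pvalue", "fdr")


# ----------------------------------------------------------- normalization


def _counts_frame(counts) -> pd.DataFrame:
    if hasattr(counts, "assay"):  # Experiment
        counts = counts.assay("reads")
    if isinstance(counts, pd.DataFrame):
        return counts
    return pd.DataFrame(np.asarray(counts))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed, precision-weighted mean of M-values of one sample against
    the reference sample.  Zero-count features are excluded pairwise."""
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask] / lib_obs, ref[mask] / lib_ref
    if o.size == 0:
        return 1.0
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method precision weights (binomial sampling variance)
    w = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (lib_ref - ref[mask]) / (
        lib_ref * ref[mask]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts, ref_sample: str | int | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, M-values against a reference sample are trimmed (30% on
    log-ratios, 5% on abundance) and averaged with precision weights; the
    factors are rescaled to geometric mean 1.  The reference defaults to
    the sample whose 75th count-percentile (library-size-scaled) is closest
    to the mean of those percentiles.
    """
    df = _counts_frame(counts)
    y = df.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    if ref_sample is None:
        f75 = np.array(
            [np.quantile(y[:, j], 0.75) / lib[j] for j in range(y.shape[1])]
        )
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    elif isinstance(ref_sample, str):
        ref = list(df.columns).index(ref_sample)
    else:
        ref = int(ref_sample)
    factors = np.array(
        [_tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref]) for j in range(y.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def wt_offsets(counts, wt_row_ids, method: str = "sum") -> np.ndarray:
    """Per-sample log-scale offsets from wild-type counts.

    Substituting these for the log library sizes in either model makes
    every log-fold change relative to the wild-type aggregate (``sum`` or
    ``geomean`` of the wild-type rows).
    """
    df = _counts_frame(counts)
    wt_row_ids = list(wt_row_ids) if not isinstance(wt_row_ids, str) else [wt_row_ids]
    if not wt_row_ids:
        raise ValueError("wt_row_ids must be non-empty")
    missing = [w for w in wt_row_ids if w not in df.index]
    if missing:
        raise KeyError(f"wild-type rows not in matrix: {missing}")
    sub = df.loc[wt_row_ids].to_numpy(dtype=float)
    if method == "sum":
        agg = sub.sum(axis=0)
    elif method == "geomean":
        if (sub <= 0).any():
            raise ValueError("geometric mean requires positive wild-type counts")
        agg = np.exp(np.mean(np.log(sub), axis=0))
    else:
        raise ValueError("method must be 'sum' or 'geomean'")
    if (agg <= 0).any():
        raise ValueError("wild-type aggregate must be positive in every sample")
    return np.log(agg)


def _offsets(counts: pd.DataFrame, normalization: str, wt_rows) -> np.ndarray:
    lib = counts.to_numpy(dtype=float).sum(axis=0)
    if normalization == "tmm":
        return np.log(lib * tmm_factors(counts).to_numpy())
    if normalization == "libsize":
        return np.log(lib)
    if normalization in ("wtsum", "wtgeomean"):
        if wt_rows is None:
            raise ValueError(f"normalization {normalization!r} needs wt_rows")
        return wt_offsets(counts, wt_rows, "sum" if normalization == "wtsum" else "geomean")
    raise ValueError(f"unknown normalization {normalization!r}")


# ------------------------------------------------------- design & contrast


def _design_matrix(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    return X, names


def _contrast_vector(contrast, names: list[str]) -> np.ndarray:
    if isinstance(contrast, str):
        if contrast not in names:
            raise ValueError(f"contrast {contrast!r} not a design column")
        c = np.zeros(len(names))
        c[names.index(contrast)] = 1.0
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(names),) or not c.any():
        raise ValueError("contrast vector must be non-zero, one entry per column")
    return c


def filter_by_min_count(
    counts: pd.DataFrame, min_count: int, samples=None
) -> pd.DataFrame:
    """Keep variants whose count is at least `min_count` in every one of
    `samples` (default: all samples)."""
    if min_count <= 0:
        return counts
    sub = counts if samples is None else counts[list(samples)]
    return counts.loc[(sub >= min_count).all(axis=1)]


def _ave_log_cpm(y: np.ndarray, lib: np.ndarray) -> np.ndarray:
    cpm = (y + 0.5) / (lib + 1.0) * 1e6
    return np.log2(cpm.mean(axis=1))


# ------------------------------------------------- NB GLM machinery (nbql)


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray | float,
    maxit: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-variant NB GLMs with a shared design.

    y: (G, n) counts; X: (n, p); offset: (n,) or (G, n) log-scale;
    phi: dispersion, scalar or (G,).  Returns (beta (G, p), mu (G, n)).
    """
    G, n = y.shape
    p = X.shape[1]
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    mu = np.maximum(y.astype(float), 1e-4) + 1e-4
    eta = np.log(mu) - off
    beta = np.zeros((G, p))
    for _ in range(maxit):
        mu = np.exp(np.clip(eta + off, -60.0, 60.0))
        w = mu / (1.0 + phi[:, None] * mu)
        z = eta + (y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        b = np.einsum("gn,gn,ni->gi", w, z, X, optimize=True)
        A[:, np.arange(p), np.arange(p)] += 1e-10
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = beta @ X.T
        if delta < tol:
            break
    mu = np.exp(np.clip(eta + off, -60.0, 60.0))
    return beta, mu


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        pois = xlogy(y, y / mu) - (y - mu)
        r = 1.0 / np.maximum(phi, 1e-12)
        nb = xlogy(y, y / mu) - (y + r) * np.log((y + r) / (mu + r))
        unit = np.where(phi < 1e-10, pois, nb)
    return 2.0 * unit.sum(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-variant NB log-likelihood (phi floored away from 0)."""
    phi = np.maximum(np.broadcast_to(np.asarray(phi, float), (y.shape[0],)), 1e-8)
    r = (1.0 / phi)[:, None]
    mu = np.maximum(mu, 1e-10)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + xlogy(y, mu)
        - (y + r) * np.log(mu + r)
        + r * np.log(r)
    )
    return ll.sum(axis=1)


def _cox_reid(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """0.5 * log det(X'WX) per variant (Cox–Reid adjustment)."""
    A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
    p = X.shape[1]
    A[:, np.arange(p), np.arange(p)] += 1e-10
    sign, logdet = np.linalg.slogdet(A)
    return 0.5 * logdet


def _interp_argmax(loglik: np.ndarray, log_grid: np.ndarray) -> float:
    """Continuous argmax of a concave-ish profile sampled on a grid, by
    quadratic interpolation around the discrete maximum."""
    i = int(np.argmax(loglik))
    if i == 0 or i == len(log_grid) - 1:
        return float(log_grid[i])
    y0, y1, y2 = loglik[i - 1], loglik[i], loglik[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(log_grid[i])
    step = log_grid[i + 1] - log_grid[i]
    return float(log_grid[i] + 0.5 * step * (y0 - y2) / denom)


def estimate_dispersion(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    grid: np.ndarray | None = None,
    n_bins: int | None = None,
) -> dict:
    """Common and abundance-trended NB dispersion.

    Adjusted profile likelihoods (Cox–Reid) are evaluated on a dispersion
    grid with the means refitted at each grid value; the common dispersion
    maximizes the pooled profile, and the trend interpolates per-bin maxima
    (bins of similar average abundance) on the log scale.
    """
    G, n = y.shape
    if grid is None:
        grid = np.logspace(-4, 1, 18)
    log_grid = np.log(grid)
    lib = np.exp(np.broadcast_to(np.asarray(offset, float), (n,)))
    a = _ave_log_cpm(y, y.sum(axis=0))
    apl = np.empty((G, len(grid)))
    for k, phi in enumerate(grid):
        beta, mu = _nb_irls(y, X, offset, phi, maxit=40, tol=1e-8)
        w = mu / (1.0 + phi * mu)
        apl[:, k] = _nb_loglik(y, mu, np.full(G, phi)) - _cox_reid(X, w)
    common = float(np.exp(_interp_argmax(apl.sum(axis=0), log_grid)))
    if n_bins is None:
        n_bins = int(np.clip(G // 100, 1, 10))
    if n_bins < 2 or G < 50:
        trended = np.full(G, common)
    else:
        order = np.argsort(a)
        bins = np.array_split(order, n_bins)
        xs, ys = [], []
        for idx in bins:
            xs.append(float(a[idx].mean()))
            ys.append(_interp_argmax(apl[idx].sum(axis=0), log_grid))
        trended = np.exp(np.interp(a, np.array(xs), np.array(ys)))
    return {"common": common, "trended": trended, "ave_log_cpm": a}


def _lowess_trend(x: np.ndarray, y: np.ndarray, frac: float = 0.5):
    """Lowess fit returning a callable predictor with constant
    extrapolation outside the fitted range."""
    fit = lowess(y, x, frac=frac, it=3, return_sorted=True)
    xf, yf = fit[:, 0], fit[:, 1]
    xu, inv = np.unique(xf, return_inverse=True)
    yu = np.zeros_like(xu)
    cnt = np.zeros_like(xu)
    np.add.at(yu, inv, yf)
    np.add.at(cnt, inv, 1.0)
    yu /= cnt

    def predict(x0: np.ndarray) -> np.ndarray:
        return np.interp(x0, xu, yu)

    return predict


def fit_nb_ql(
    counts,
    design,
    contrast,
    normalization: str = "tmm",
    wt_rows=None,
    min_count: int = 0,
    filter_samples=None,
    assay: str = "reads",
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Negative-binomial quasi-likelihood test for one contrast.

    Per variant, an NB GLM with log link and per-sample offsets is fitted
    with abundance-trended dispersion; residual quasi-dispersions are shrunk
    toward their abundance trend with a fixed prior df, and the contrast is
    tested with a quasi-likelihood F-test.

    Returns a DataFrame indexed by variant with columns
    ``logFC`` (log2), ``aveAbundance`` (average log2 CPM), ``stat`` (F),
    ``pvalue`` and ``fdr`` (Benjamini–Hochberg).
    """
    df = _counts_frame(counts if not hasattr(counts, "assay") else counts.assay(assay))
    df = filter_by_min_count(df, min_count, filter_samples)
    y = df.to_numpy(dtype=float)
    G, n = y.shape
    X, names = _design_matrix(design)
    if X.shape[0] != n:
        raise ValueError("design rows must match samples")
    c = _contrast_vector(contrast, names)
    p = X.shape[1]
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    offset = _offsets(df, normalization, wt_rows)

    disp = estimate_dispersion(y, X, offset)
    phi = disp["trended"]
    a = disp["ave_log_cpm"]

    B = linalg.null_space(c.reshape(1, -1))  # (p, p-1)
    beta_full, mu_full = _nb_irls(y, X, offset, phi)
    dev_full = _nb_deviance(y, mu_full, phi)
    _, mu_red = _nb_irls(y, X @ B, offset, phi)
    dev_red = _nb_deviance(y, mu_red, phi)

    df_res = float(n - p)
    s2 = dev_full / df_res
    if G >= 50:
        trend = _lowess_trend(a, s2)
        s2_0 = np.maximum(trend(a), 1e-8)
    else:
        s2_0 = np.full(G, max(float(np.mean(s2)), 1e-8))
    s2_post = (prior_df * s2_0 + df_res * s2) / (prior_df + df_res)
    lr = np.maximum(dev_red - dev_full, 0.0)
    fstat = lr / s2_post
    pval = stats.f.sf(fstat, 1.0, prior_df + df_res)
    logfc = (beta_full @ c) / LOG2

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "aveAbundance": a,
            "stat": fstat,
            "pvalue": pval,
            "fdr": adjust_fdr(pval),
        },
        index=df.index,
    )
    return out


# -------------------------------------------------- precision-weights path


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment fit of a scaled F-distribution to sample variances; returns
    (prior df d0, prior variance s0^2).  d0 = inf for under-dispersed
    moments."""
    x = np.maximum(s2, 1e-12)
    z = np.log(x)
    e = z - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df1 / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return d0, float(s0)


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Per-variant weighted least squares with a shared design.

    y, w: (G, n); X: (n, p).  Returns (coef (G,p), s2 (G,), XtWX_inv)."""
    p = X.shape[1]
    A = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
    b = np.einsum("gn,gn,ni->gi", w, y, X, optimize=True)
    A[:, np.arange(p), np.arange(p)] += 1e-12
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    fitted = coef @ X.T
    resid = y - fitted
    df_res = y.shape[1] - p
    s2 = np.einsum("gn,gn->g", w, resid**2) / df_res
    Ainv = np.linalg.inv(A)
    return coef, s2, Ainv


def fit_voom(
    counts,
    design,
    contrast,
    normalization: str = "tmm",
    wt_rows=None,
    min_count: int = 0,
    filter_samples=None,
    assay: str = "reads",
) -> pd.DataFrame:
    """Precision-weighted linear model with moderated t-statistics.

    Counts are transformed to log2 CPM with a 0.5 pseudocount; the
    mean–variance relation (sqrt residual sd vs mean log2 count) is fitted
    by lowess and inverted into observation weights; per-variant weighted
    least squares is followed by empirical-Bayes moderation of the residual
    variances.  Output columns as in :func:`fit_nb_ql` (``stat`` is the
    moderated t).
    """
    df = _counts_frame(counts if not hasattr(counts, "assay") else counts.assay(assay))
    df = filter_by_min_count(df, min_count, filter_samples)
    y_counts = df.to_numpy(dtype=float)
    G, n = y_counts.shape
    X, names = _design_matrix(design)
    if X.shape[0] != n:
        raise ValueError("design rows must match samples")
    c = _contrast_vector(contrast, names)
    p = X.shape[1]
    df_res = n - p
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    offset = _offsets(df, normalization, wt_rows)
    lib = np.exp(offset)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    y = np.log2((y_counts + 0.5) / (lib + 1.0) * 1e6)
    ones = np.ones((G, n))
    coef0, s2_0, _ = _wls(y, X, ones)
    sigma0 = np.sqrt(s2_0)
    sx = y.mean(axis=1) + float(np.mean(np.log2(lib + 1.0))) - np.log2(1e6)
    sy = np.sqrt(sigma0)
    if G >= 10:
        trend = _lowess_trend(sx, sy, frac=0.5)
    else:
        mval = float(np.mean(sy))
        trend = lambda x0: np.full_like(np.asarray(x0, dtype=float), mval)
    fitted_logcpm = coef0 @ X.T
    lam = fitted_logcpm + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    w = 1.0 / np.maximum(trend(lam), 1e-4) ** 4

    coef, s2, Ainv = _wls(y, X, w)
    d0, s0 = _fit_f_dist(s2, float(df_res))
    if np.isinf(d0):
        s2_post = np.full(G, s0)
        df_total = 1e6
    else:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    u = np.einsum("i,gij,j->g", c, Ainv, c)
    logfc = coef @ c
    tstat = logfc / np.sqrt(np.maximum(s2_post * u, 1e-300))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "aveAbundance": _ave_log_cpm(y_counts, y_counts.sum(axis=0)),
            "stat": tstat,
            "pvalue": pval,
            "fdr": adjust_fdr(pval),
        },
        index=df.index,
    )
    return out


def test_variants(counts, design, contrast, method: str = "nbql", **kwargs) -> pd.DataFrame:
    """Dispatch to :func:`fit_nb_ql` (``nbql``) or :func:`fit_voom`
    (``voom``)."""
    if method == "nbql":
        return fit_nb_ql(counts, design, contrast, **kwargs)
    if method == "voom":
        return fit_voom(counts, design, contrast, **kwargs)
    raise ValueError("method must be 'nbql' or 'voom'")


# -------------------------------------------------------------- PPI scores


def ppi_scores(
    counts,
    input_samples,
    output_samples,
    wt_row: str,
    pseudocount: float = 0.0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-variant, per-replicate wild-type-normalized enrichment scores.

    score(v, r) = log2((out_v + p) / (in_v + p))
                − log2((out_wt + p) / (in_wt + p)),
    optionally multiplied by `scale` (e.g. a growth-rate constant).  Input
    and output samples are paired by position (replicate order); the
    wild-type row scores 0 in every replicate.
    """
    df = _counts_frame(counts)
    input_samples = list(input_samples)
    output_samples = list(output_samples)
    if len(input_samples) != len(output_samples) or not input_samples:
        raise ValueError("input and output samples must pair up by replicate")
    if wt_row not in df.index:
        raise KeyError(f"wild-type row {wt_row!r} not in matrix")
    out = {}
    for i, (s_in, s_out) in enumerate(zip(input_samples, output_samples), start=1):
        vin = df[s_in].to_numpy(dtype=float) + pseudocount
        vout = df[s_out].to_numpy(dtype=float) + pseudocount
        wt_in = df.at[wt_row, s_in] + pseudocount
        wt_out = df.at[wt_row, s_out] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            score = (np.log2(vout) - np.log2(vin)) - (
                np.log2(wt_out) - np.log2(wt_in)
            )
        out[f"rep{i}"] = scale * score
    return pd.DataFrame(out, index=df.index)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
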