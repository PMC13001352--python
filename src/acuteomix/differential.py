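"""Per-feature difference-in-changes mixed models.

A cell-means model (one mean per group x timepoint cell) with a participant
random intercept is fit per feature by profiled REML; the delta-delta
contrast compares the change from pre in an exercise group to the same
change in control.  Count omes get precision weights from the mean-variance
trend; residual variances are moderated with an empirical-Bayes scaled
inverse-chi-squared prior, and BH is applied separately per (contrast, ome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import AcuteomixError, OmicsMatrix, POST_TIMEPOINTS, bh_adjust
from .preprocess import log_cpm, tmm_factors

log = logging.getLogger(__name__)


class FeatureSkipped(AcuteomixError):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class ModelSpec:
    """Fixed cell-means terms plus covariates and the random grouping."""

    covariates: tuple = ("sex", "age", "batch")
    random: str = "participant_id"
    groups: tuple = ("CON", "EE", "RE")
    timepoints: tuple = ("pre",) + POST_TIMEPOINTS


def cell_name(group: str, timepoint: str) -> str:
    return f"cell.{group}.{timepoint}"


def build_design_matrix(design: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Cell-means design matrix with covariate columns, indexed by sample."""
    d = design.set_index("sample_id")
    cols = {}
    cells = sorted(
        set(zip(d["group"], d["timepoint"])),
        key=lambda gt: (spec.groups.index(gt[0]), spec.timepoints.index(gt[1])),
    )
    for g, t in cells:
        cols[cell_name(g, t)] = ((d["group"] == g) & (d["timepoint"] == t)).astype(float)
    for cov in spec.covariates:
        if cov not in d.columns:
            raise AcuteomixError(f"covariate {cov!r} not in design")
        vals = d[cov]
        if vals.dtype.kind in "ifu":
            cols[cov] = vals.astype(float) - float(vals.mean())
        else:
            levels = sorted(vals.unique())
            for lv in levels[1:]:
                cols[f"{cov}.{lv}"] = (vals == lv).astype(float)
    return pd.DataFrame(cols, index=d.index)


def eligibility_filter(
    design: pd.DataFrame,
    m: OmicsMatrix,
    min_paired: int = 3,
    groups: tuple = ("CON", "EE", "RE"),
    timepoints: tuple = POST_TIMEPOINTS,
) -> pd.DataFrame:
    """Paired pre/post participant counts per (group, timepoint) per feature.

    Returns a DataFrame with one boolean column per (group, timepoint) cell
    plus an ``eligible`` column that is True only when every cell has at
    least ``min_paired`` participants with observed pre AND post values.
    """
    d = design.set_index("sample_id")
    obs = m.values.notna()
    out = {}
    for g in groups:
        pre_ids = d[(d["group"] == g) & (d["timepoint"] == "pre")]
        pre_by_part = {}
        for sid, row in pre_ids.iterrows():
            pre_by_part[row["participant_id"]] = sid
        for t in timepoints:
            post = d[(d["group"] == g) & (d["timepoint"] == t)]
            pairs = [
                (pre_by_part[row["participant_id"]], sid)
                for sid, row in post.iterrows()
                if row["participant_id"] in pre_by_part
            ]
            if pairs:
                count = sum(
                    (obs[pre_sid] & obs[post_sid]).to_numpy().astype(int)
                    for pre_sid, post_sid in pairs
                )
                count = pd.Series(count, index=obs.index)
            else:
                count = pd.Series(0, index=obs.index)
            out[f"{g}.{t}"] = count >= min_paired
    table = pd.DataFrame(out, index=obs.index)
    table["eligible"] = table.all(axis=1)
    return table


def voom_weights(
    counts: OmicsMatrix,
    design: pd.DataFrame,
    spec: ModelSpec = None,
    factors: pd.Series = None,
) -> tuple:
    """limma-voom style precision weights for a count ome.

    Returns (log_cpm DataFrame, weights DataFrame).  Weights are the inverse
    fourth power of the lowess sqrt-standard-deviation trend evaluated at
    each observation's fitted log-count.
    """
    spec = spec or ModelSpec()
    vals = counts.values.fillna(0)
    if factors is None:
        factors = tmm_factors(vals)
    lib = (vals.sum(axis=0) * factors).to_numpy(dtype=float)
    y = log_cpm(vals, factors)
    x = build_design_matrix(design, spec).loc[y.columns].to_numpy()
    yv = y.to_numpy()
    n, p = x.shape[0], np.linalg.matrix_rank(x)
    if n - p < 2:
        log.warning("voom: fewer than 2 residual df; using unit weights")
        ones = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        return y, ones
    pinv = np.linalg.pinv(x)
    beta = yv @ pinv.T
    fitted = beta @ x.T
    resid = yv - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    # mean log2-count per feature and fitted log2-count per observation
    mean_lib = np.mean(np.log2(lib + 1.0))
    sx = yv.mean(axis=1) + mean_lib - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=0.5, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    trend = np.interp(fitted_count, lx, ly, left=ly[0], right=ly[-1])
    trend = np.clip(trend, 1e-6, None)
    w = trend**-4
    return y, pd.DataFrame(w, index=y.index, columns=y.columns)


@dataclass
class FeatureFit:
    beta: pd.Series            # cell means + covariate effects
    cov_unscaled: pd.DataFrame # (X' V^-1 X)^-1 ; multiply by sigma2 for cov(beta)
    sigma2: float              # residual variance
    df_resid: int
    lambda_ratio: float        # random-intercept variance / residual variance
    n_used: int

    @property
    def random_intercept_var(self) -> float:
        return self.lambda_ratio * self.sigma2


def _reml_quantities(y, x, w, pidx, n_participants, lam):
    """Woodbury-based GLS pieces for V = W^-1 + lam * Z Z'."""
    wy = w * y
    wx = w[:, None] * x
    s = np.bincount(pidx, weights=w, minlength=n_participants)
    t = np.bincount(pidx, weights=wy, minlength=n_participants)
    g = np.vstack(
        [np.bincount(pidx, weights=wx[:, j], minlength=n_participants) for j in range(x.shape[1])]
    ).T  # participants x p
    if lam > 0:
        dinv = 1.0 / (1.0 / lam + s)
        a = x.T @ wx - g.T @ (dinv[:, None] * g)
        b = x.T @ wy - g.T @ (dinv * t)
        yvy = y @ wy - t @ (dinv * t)
        logdet_v = -np.sum(np.log(w)) + np.sum(np.log1p(lam * s))
    else:
        a = x.T @ wx
        b = x.T @ wy
        yvy = y @ wy
        logdet_v = -np.sum(np.log(w))
    return a, b, yvy, logdet_v


def _reml_criterion(y, x, w, pidx, n_participants, lam):
    a, b, yvy, logdet_v = _reml_quantities(y, x, w, pidx, n_participants, lam)
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return 1e300, None
    beta = np.linalg.solve(a, b)
    rss = yvy - b @ beta
    n, p = len(y), x.shape[1]
    if rss <= 0:
        return 1e300, None
    crit = (n - p) * np.log(rss) + logdet_v + logdet_a
    return crit, (a, beta, rss)


def fit_cell_means(
    y: pd.Series,
    design: pd.DataFrame,
    spec: ModelSpec = None,
    weights: pd.Series = None,
) -> FeatureFit:
    """Profiled-REML fit of the cell-means mixed model for one feature.

    The random-intercept-to-residual variance ratio is profiled on a log
    grid via bounded scalar minimization; a boundary estimate of zero
    collapses the fit to weighted least squares.
    """
    spec = spec or ModelSpec()
    obs = y.dropna()
    if len(obs) == 0:
        raise FeatureSkipped("no observed values")
    d = design.set_index("sample_id").loc[obs.index]
    xdf = build_design_matrix(design.loc[design["sample_id"].isin(obs.index)], spec)
    xdf = xdf.loc[obs.index]
    # drop all-zero cell columns (cells unobserved for this feature);
    # covariate columns are kept so their collinearity is still detected
    drop = [c for c in xdf.columns if c.startswith("cell.") and not (xdf[c] != 0).any()]
    xdf = xdf.drop(columns=drop)
    x = xdf.to_numpy()
    n, p = x.shape
    if n <= p or np.linalg.matrix_rank(x) < p:
        raise FeatureSkipped("singular design for observed cells")
    w = np.ones(n) if weights is None else weights.loc[obs.index].to_numpy(dtype=float)
    participants = d[spec.random].unique()
    pidx = d[spec.random].map({q: i for i, q in enumerate(participants)}).to_numpy()

    yv = obs.to_numpy(dtype=float)
    crit0, sol0 = _reml_criterion(yv, x, w, pidx, len(participants), 0.0)
    best_lam, best = 0.0, (crit0, sol0)
    if len(participants) < n:  # replication exists: profile lambda
        res = optimize.minimize_scalar(
            lambda ll: _reml_criterion(yv, x, w, pidx, len(participants), np.exp(ll))[0],
            bounds=(-8.0, 8.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        lam = float(np.exp(res.x))
        crit, sol = _reml_criterion(yv, x, w, pidx, len(participants), lam)
        if crit < best[0] and sol is not None:
            best_lam, best = lam, (crit, sol)
    _, (a, beta, rss) = best
    df_resid = n - p
    sigma2 = rss / df_resid
    cov_unscaled = pd.DataFrame(np.linalg.inv(a), index=xdf.columns, columns=xdf.columns)
    return FeatureFit(
        beta=pd.Series(beta, index=xdf.columns),
        cov_unscaled=cov_unscaled,
        sigma2=float(sigma2),
        df_resid=int(df_resid),
        lambda_ratio=float(best_lam),
        n_used=int(n),
    )


def delta_delta_contrast(fit: FeatureFit, group: str, timepoint: str, control: str = "CON"):
    """(group change from pre) minus (control change from pre); returns
    (estimate, se) with se = sigma * sqrt(c' (X'V^-1X)^-1 c)."""
    needed = [
        cell_name(group, timepoint),
        cell_name(group, "pre"),
        cell_name(control, timepoint),
        cell_name(control, "pre"),
    ]
    for cell in needed:
        if cell not in fit.beta.index:
            raise AcuteomixError(f"missing cell {cell!r} for contrast {group}/{timepoint}")
    c = pd.Series(0.0, index=fit.beta.index)
    c[needed[0]] += 1.0
    c[needed[1]] -= 1.0
    c[needed[2]] -= 1.0
    c[needed[3]] += 1.0
    est = float(c @ fit.beta)
    var = float(c @ fit.cov_unscaled @ c) * fit.sigma2
    return est, float(np.sqrt(var))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y (Newton iterations, limma-style)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: np.ndarray):
    """Empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse-chi-squared prior (d0, s0^2) by matching moments of
    log residual variances via digamma/trigamma equations; returns
    (post_var, d0, s0sq).  d0 may be inf (full shrinkage to a common value).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        log.warning("squeeze_var: <2 usable variances; no shrinkage applied")
        return s2.copy(), 0.0, float("nan")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    emean = e.mean()
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df[ok] / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        # degenerate prior: no excess spread beyond sampling noise; shrink
        # fully to the geometric mean (equal inputs stay exactly equal)
        d0 = np.inf
        s0sq = float(np.exp(np.mean(z)))
        post = np.full_like(s2, s0sq)
    post = np.where(ok, post, s2)
    return post, float(d0), float(s0sq)


def moderate_and_adjust(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Moderated t + BH per (contrast, ome) stratum.

    ``results`` needs columns: feature, ome, contrast, estimate, se, sigma2,
    df_resid.  Emits t (moderated), df, p, adj_p, significant.
    """
    out = results.copy()
    out["t"] = np.nan
    out["df"] = np.nan
    out["p"] = np.nan
    for ome, idx in out.groupby("ome").groups.items():
        sub = out.loc[idx]
        per_feat = sub.drop_duplicates("feature").set_index("feature")
        feats = per_feat.index
        if len(feats) < 2:
            log.warning("moderation skipped for ome %s: single feature, raw t used", ome)
            post = per_feat["sigma2"].to_numpy()
            d0 = 0.0
        else:
            post, d0, _ = squeeze_var(
                per_feat["sigma2"].to_numpy(), per_feat["df_resid"].to_numpy()
            )
        post_map = dict(zip(feats, post))
        sigma2 = sub["sigma2"].to_numpy()
        postv = sub["feature"].map(post_map).to_numpy()
        unscaled_se = sub["se"].to_numpy() / np.sqrt(sigma2)
        tval = sub["estimate"].to_numpy() / (unscaled_se * np.sqrt(postv))
        dft = sub["df_resid"].to_numpy() + (d0 if np.isfinite(d0) else 1e6)
        out.loc[idx, "t"] = tval
        out.loc[idx, "df"] = dft
        out.loc[idx, "p"] = 2.0 * stats.t.sf(np.abs(tval), dft)
    for (_, _), idx in out.groupby(["ome", "contrast"]).groups.items():
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out


def run_differential(
    m: OmicsMatrix,
    design: pd.DataFrame,
    spec: ModelSpec = None,
    groups: tuple = ("EE", "RE"),
    min_paired: int = 3,
    normalized: bool = False,
) -> pd.DataFrame:
    """Full per-ome differential pipeline: eligibility, (voom), per-feature
    REML cell-means fits, delta-delta contrasts, moderation, BH.

    Count omes are taken as raw counts unless ``normalized`` is True.
    """
    spec = spec or ModelSpec()
    design = design[design["sample_id"].isin(m.samples)]
    timepoints = [t for t in POST_TIMEPOINTS if (design["timepoint"] == t).any()]
    elig = eligibility_filter(design, m, min_paired=min_paired, timepoints=tuple(timepoints))
    weights = None
    if m.is_count_ome and not normalized:
        values, weights = voom_weights(m, design, spec)
    else:
        values = m.values

    rows = []
    fits = {}
    for feat in values.index[elig["eligible"].reindex(values.index, fill_value=False)]:
        wrow = None if weights is None else weights.loc[feat]
        try:
            fit = fit_cell_means(values.loc[feat], design, spec, wrow)
        except FeatureSkipped as exc:
            log.info("feature %s skipped: %s", feat, exc.reason)
            continue
        fits[feat] = fit
        for g in groups:
            for t in timepoints:
                try:
                    est, se = delta_delta_contrast(fit, g, t)
                except AcuteomixError:
                    continue
                rows.append(
                    {
                        "feature": feat,
                        "ome": m.ome,
                        "group": g,
                        "timepoint": t,
                        "contrast": f"{g}.{t}",
                        "estimate": est,
                        "se": se,
                        "sigma2": fit.sigma2,
                        "df_resid": fit.df_resid,
                        "n_used": fit.n_used,
                    }
                )
    if not rows:
        return pd.DataFrame(
            columns=[
                "feature", "ome", "group", "timepoint", "contrast", "estimate",
                "se", "sigma2", "df_resid", "n_used", "t", "df", "p", "adj_p",
                "significant",
            ]
        )
    return moderate_and_adjust(pd.DataFrame(rows))
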