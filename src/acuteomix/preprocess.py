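"""Ome-specific preprocessing: feature filters, normalization, imputation,
PCA outlier flagging, and batch-effect residualization.

Filter thresholds are applied literally as stated and are configurable
through :class:`FilterRule`; every applied threshold is logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AcuteomixError, OmicsMatrix, RankDeficientError

log = logging.getLogger(__name__)

DEFAULT_RULES = {
    # literal reading: REMOVE genes with CPM <= 0.5 in at least 10% of samples
    "rna": {"cpm_threshold": 0.5, "sample_fraction": 0.10, "mode": "literal"},
    "atac": {"min_count": 10, "min_samples": 6},
    "protein": {"min_quantified_fraction": 0.30},
    "phospho": {"min_quantified_fraction": 0.30},
    "metab": {"max_missing_fraction": 0.20},
}


@dataclass
class FilterRule:
    ome: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ome not in DEFAULT_RULES:
            raise AcuteomixError(f"unknown ome label {self.ome!r}")
        merged = dict(DEFAULT_RULES[self.ome])
        merged.update(self.params)
        for key, val in merged.items():
            if key == "mode":
                continue
            if "fraction" in key and not 0 <= val <= 1:
                raise AcuteomixError(f"{key} must be in [0, 1]")
            if val < 0:
                raise AcuteomixError(f"{key} must be nonnegative")
        self.params = merged


def cpm(counts: pd.DataFrame, lib_sizes=None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return counts.div(lib, axis=1) * 1e6


def filter_features(m: OmicsMatrix, rule: FilterRule = None) -> pd.Series:
    """Boolean keep-mask over features, applying the ome's rule literally."""
    if rule is None:
        rule = FilterRule(m.ome)
    if rule.ome != m.ome:
        raise AcuteomixError(f"rule for {rule.ome!r} applied to {m.ome!r} matrix")
    p = rule.params
    vals = m.values
    if m.ome == "rna":
        c = cpm(vals.fillna(0))
        low = (c <= p["cpm_threshold"]).mean(axis=1)
        if p.get("mode", "literal") == "literal":
            keep = low < p["sample_fraction"]
        else:
            # alternative reading: keep genes with CPM > threshold in > fraction
            keep = (c > p["cpm_threshold"]).mean(axis=1) > p["sample_fraction"]
    elif m.ome == "atac":
        keep = (vals.fillna(0) >= p["min_count"]).sum(axis=1) >= p["min_samples"]
    elif m.ome in ("protein", "phospho"):
        keep = vals.notna().mean(axis=1) >= p["min_quantified_fraction"]
    elif m.ome == "metab":
        keep = vals.isna().mean(axis=1) <= p["max_missing_fraction"]
    else:  # pragma: no cover - guarded in FilterRule
        raise AcuteomixError(f"unknown ome label {m.ome!r}")
    log.info("filter_features[%s]: %s -> kept %d/%d", m.ome, p, int(keep.sum()), len(keep))
    return keep.rename("keep")


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    Doubly-trimmed (30% on M, 5% on A), precision-weighted mean of log-ratios
    against a reference library, with factors centered to a product of 1.
    """
    counts = counts.astype(float)
    lib = counts.sum(axis=0).to_numpy()
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise AcuteomixError(f"all-zero library for samples: {bad}")
    y = counts.to_numpy()
    # reference: library whose upper quartile of scaled counts is closest to mean
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref, nref = y[:, ref_j], lib[ref_j]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        obs, nobs = y[:, j], lib[j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            continue
        o, rf = obs[ok], ref[ok]
        m_val = np.log2((o / nobs) / (rf / nref))
        a_val = 0.5 * np.log2((o / nobs) * (rf / nref))
        w = (nobs - o) / (nobs * o) + (nref - rf) / (nref * rf)
        n = m_val.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = stats.rankdata(m_val, method="average")
        rank_a = stats.rankdata(a_val, method="average")
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and np.sum(w[keep]) > 0:
            f = np.sum(w[keep] * m_val[keep]) / np.sum(w[keep])
            if np.isfinite(f):
                factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric-mean centering
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series = None, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with offset ``prior`` (voom convention)."""
    lib = counts.sum(axis=0)
    if factors is not None:
        lib = lib * factors
    return np.log2((counts + prior).div(lib + 1.0, axis=1) * 1e6)


def median_mad_normalize(values: pd.DataFrame, scale_constant: float = 1.4826) -> pd.DataFrame:
    med = values.median(axis=0, skipna=True)
    mad = (values - med).abs().median(axis=0, skipna=True) * scale_constant
    mad = mad.replace(0, 1.0)
    return (values - med) / mad


def _kruskal_assoc(stat_per_sample: pd.Series, labels: pd.Series) -> float:
    groups = [stat_per_sample[labels == lv].dropna().to_numpy() for lv in labels.unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all identical
        return 1.0


def should_median_mad(values: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.01) -> bool:
    """Apply median-MAD scaling only when neither sample medians nor upper
    quartiles are associated (Kruskal-Wallis p < alpha) with sex or group."""
    d = design.set_index("sample_id").loc[values.columns]
    med = values.median(axis=0, skipna=True)
    uq = values.quantile(0.75, axis=0)
    for stat in (med, uq):
        for col in ("sex", "group"):
            if _kruskal_assoc(stat, d[col]) < alpha:
                return False
    return True


def normalize(m: OmicsMatrix, design: pd.DataFrame = None, median_mad: str = "auto") -> OmicsMatrix:
    """Ome-appropriate normalization.

    Counts: TMM factors then log2-CPM.  Proteomics/phospho: per-sample median
    centering to zero.  Metabolomics: log2(x+1), then median-MAD scaling when
    ``median_mad`` is "always" or ("auto" and the association test passes).
    """
    if m.is_count_ome:
        factors = tmm_factors(m.values.fillna(0))
        out = log_cpm(m.values.fillna(0), factors)
    elif m.ome in ("protein", "phospho"):
        out = m.values - m.values.median(axis=0, skipna=True)
    elif m.ome == "metab":
        out = np.log2(m.values + 1.0)
        do = median_mad == "always" or (
            median_mad == "auto" and design is not None and should_median_mad(out, design)
        )
        if do:
            log.info("normalize[metab]: applying median-MAD scaling")
            out = median_mad_normalize(out)
    else:
        raise AcuteomixError(f"unknown ome label {m.ome!r}")
    return m.with_values(out)


def impute_metabolites(m: OmicsMatrix, n_neighbors: int = 5) -> OmicsMatrix:
    """KNN imputation across features when >12 features, else half-minimum."""
    vals = m.values
    fully_missing = vals.isna().all(axis=1)
    if fully_missing.any():
        raise AcuteomixError(
            f"features entirely missing (should have been filtered): "
            f"{list(vals.index[fully_missing])[:5]}"
        )
    if not vals.isna().any().any():
        return m.with_values(vals.copy())
    if vals.shape[0] > 12:
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=min(n_neighbors, vals.shape[0] - 1))
        # rows are features, so neighbors are the most similar features
        out = pd.DataFrame(imp.fit_transform(vals.to_numpy()), index=vals.index, columns=vals.columns)
    else:
        half_min = vals.min(axis=1, skipna=True) / 2.0
        out = vals.apply(lambda row: row.fillna(half_min[row.name]), axis=1)
    return m.with_values(out)


def detect_pca_outliers(
    m: OmicsMatrix,
    iqr_mult: float = 5.0,
    var_explained: float = 0.95,
    n_components: int = None,
) -> list:
    """Flag samples whose score on any retained PC lies outside
    [Q1 - k*IQR, Q3 + k*IQR]."""
    vals = m.values.dropna(axis=0, how="any")
    n = vals.shape[1]
    if n < 3:
        raise AcuteomixError("PCA outlier detection requires at least 3 samples")
    if n_components is not None and n_components > min(n, vals.shape[0]):
        raise AcuteomixError("more components requested than samples/features")
    x = vals.to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    if n_components is None:
        n_components = int(np.searchsorted(frac, var_explained) + 1)
    scores = u[:, :n_components] * s[:n_components]
    flagged = set()
    for k in range(scores.shape[1]):
        col = scores[:, k]
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        out = (col < q1 - iqr_mult * iqr) | (col > q3 + iqr_mult * iqr)
        flagged.update(vals.columns[out])
    return sorted(flagged)


def _check_full_rank(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via greedy QR-style elimination
        bad, kept = [], []
        for j in range(x.shape[1]):
            cand = x[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise RankDeficientError(bad)


def remove_batch_effects(
    m: OmicsMatrix,
    batch_covariates: pd.DataFrame,
    protected_design: pd.DataFrame,
) -> OmicsMatrix:
    """Regress out batch covariates while protecting the design of interest.

    Per feature, values are fit on [protected | batch] jointly and only the
    fitted batch component is subtracted.
    """
    prot = protected_design.loc[m.samples].to_numpy(dtype=float)
    prot = np.hstack([np.ones((prot.shape[0], 1)), prot])  # protected intercept
    batch = batch_covariates.loc[m.samples].to_numpy(dtype=float)
    names = ["intercept"] + list(protected_design.columns) + list(batch_covariates.columns)
    x = np.hstack([prot, batch])
    _check_full_rank(x, names)
    y = m.values.to_numpy(dtype=float)
    pb = prot.shape[1]
    if not np.isnan(y).any():
        beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
        adj = y - (batch @ beta[pb:]).T
    else:
        adj = y.copy()
        for i in range(y.shape[0]):
            ok = ~np.isnan(y[i])
            if ok.sum() <= x.shape[1]:
                continue
            beta, *_ = np.linalg.lstsq(x[ok], y[i, ok], rcond=None)
            adj[i, ok] = y[i, ok] - batch[ok] @ beta[pb:]
    out = pd.DataFrame(adj, index=m.features, columns=m.samples)
    return m.with_values(out)
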