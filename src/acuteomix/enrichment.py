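"""Contrast z-score matrices and set-level enrichment statistics.

Moderated t-statistics are converted to signed normal z-scores; collections
are size/coverage filtered; set statistics come from CAMERA-PR (competitive
mean-difference t with a VIF for inter-feature correlation), hypergeometric
over-representation, and a PTM signature running-sum test with permutation
NES (weight-0 area statistic).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

from .core import AcuteomixError, bh_adjust

log = logging.getLogger(__name__)

_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<sites>[STY]\d+(?:;[STY]\d+)*)$")


def t_to_z(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Signed normal-quantile transform of the t CDF at the fitted df."""
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    p_one = stats.t.sf(np.abs(t), df)
    p_one = np.clip(p_one, 1e-300, 1.0)
    z = stats.norm.isf(p_one)
    return np.sign(t) * np.where(t == 0, 0.0, z)


def build_zscore_matrix(
    results: pd.DataFrame, feature_id_map: dict = None
) -> pd.DataFrame:
    """Pivot contrast results into an identifier x contrast z matrix.

    Multi-feature identifiers are collapsed to the entry with maximum
    absolute z (ties broken toward the first feature in sorted id order);
    unmapped features are dropped with a logged count.
    """
    df = results.copy()
    if feature_id_map is not None:
        df["identifier"] = df["feature"].map(feature_id_map)
        dropped = df["identifier"].isna().sum()
        if dropped:
            log.info("build_zscore_matrix: dropped %d unmapped rows", int(dropped))
        df = df.dropna(subset=["identifier"])
    else:
        df["identifier"] = df["feature"]
    df["z"] = t_to_z(df["t"].to_numpy(), df["df"].to_numpy())
    df = df.sort_values("feature", kind="mergesort")
    df["_absz"] = df["z"].abs()
    best = (
        df.sort_values("_absz", kind="mergesort", ascending=False)
        .drop_duplicates(subset=["identifier", "contrast"], keep="first")
    )
    mat = best.pivot(index="identifier", columns="contrast", values="z")
    return mat.sort_index()


def split_multisite(phospho_results: pd.DataFrame, site_col: str = "feature") -> pd.DataFrame:
    """Split multi-site phospho ids into single sites with duplicated rows.

    ``protein_S1;S2`` becomes rows ``protein_S1`` and ``protein_S2``.
    Duplicated single sites within a contrast resolve to the entry of
    maximum absolute z (or t when no z column exists).
    """
    offenders = []
    rows = []
    for _, row in phospho_results.iterrows():
        match = _SITE_RE.match(str(row[site_col]))
        if not match:
            offenders.append(row[site_col])
            continue
        protein = match.group("protein")
        for site in match.group("sites").split(";"):
            new = row.copy()
            new[site_col] = f"{protein}_{site}"
            rows.append(new)
    if offenders:
        raise AcuteomixError(f"unparseable site ids: {sorted(set(offenders))}")
    out = pd.DataFrame(rows).reset_index(drop=True)
    value_col = "z" if "z" in out.columns else "t"
    key = ["contrast"] if "contrast" in out.columns else []
    out["_abs"] = out[value_col].abs()
    out = (
        out.sort_values("_abs", kind="mergesort", ascending=False)
        .drop_duplicates(subset=[site_col, *key], keep="first")
        .drop(columns="_abs")
        .sort_values(site_col, kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def _members_ids(members):
    return [m[0] if isinstance(m, tuple) else m for m in members]


def filter_sets(
    sets: dict,
    universe,
    min_size: int = 5,
    min_coverage: float = 0.70,
    coverage_applies: bool = True,
) -> dict:
    """Intersect sets with the universe; drop sets with <5 survivors and
    (for gene collections) <70% retention of original members."""
    if not len(universe):
        raise AcuteomixError("empty universe")
    uni = set(universe)
    out = {}
    for name, members in sets.items():
        surv = [m for m in members if (m[0] if isinstance(m, tuple) else m) in uni]
        if len(surv) < min_size:
            continue
        if coverage_applies and members and len(surv) / len(members) < min_coverage:
            continue
        out[name] = surv
    return out


def camera_pr(
    z: pd.Series,
    sets: dict,
    rho: float = 0.01,
    kinase_sets: set = frozenset(),
    alpha: float = 0.05,
    kinase_alpha: float = 0.10,
) -> pd.DataFrame:
    """Pre-ranked CAMERA: standardized set-vs-rest mean difference with a
    variance inflation factor 1 + (m-1)*rho, two-sided t p at G-2 df."""
    zz = z.dropna()
    g = len(zz)
    rows = []
    for name, members in sets.items():
        ids = [m for m in _members_ids(members) if m in zz.index]
        m_size = len(ids)
        n_out = g - m_size
        if m_size < 2 or n_out < 2:
            rows.append({"set": name, "size": m_size, "stat": np.nan, "direction": "NA", "p": np.nan})
            continue
        in_mask = zz.index.isin(ids)
        zin, zout = zz[in_mask].to_numpy(), zz[~in_mask].to_numpy()
        s2p = ((m_size - 1) * zin.var(ddof=1) + (n_out - 1) * zout.var(ddof=1)) / (g - 2)
        vif = 1.0 + (m_size - 1) * rho
        denom = np.sqrt(s2p * (vif / m_size + 1.0 / n_out))
        tval = 0.0 if denom == 0 else (zin.mean() - zout.mean()) / denom
        p = 2.0 * stats.t.sf(abs(tval), g - 2) if denom > 0 else 1.0
        rows.append(
            {
                "set": name,
                "size": m_size,
                "stat": tval,
                "direction": "Up" if tval > 0 else ("Down" if tval < 0 else "NA"),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        thresh = out["set"].map(lambda s: kinase_alpha if s in kinase_sets else alpha)
        out["significant"] = out["adj_p"] < thresh
    return out


def ora(hits, universe, sets: dict) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH across sets."""
    universe = set(universe)
    if not universe:
        raise AcuteomixError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise AcuteomixError("hits must be a subset of the universe")
    big_n, n_draw = len(universe), len(hits)
    rows = []
    for name, members in sets.items():
        ids = set(_members_ids(members)) & universe
        k_set = len(ids)
        overlap = len(ids & hits)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, k_set, n_draw)) if k_set else 1.0
        rows.append({"set": name, "set_size": k_set, "overlap": overlap, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def _area_es(positions: np.ndarray, g: int, m: int) -> float:
    """Mean running enrichment score: +1/m at member ranks, -1/(G-m)
    elsewhere; closed form via per-position weights (G - i)/G."""
    w = (g - np.arange(g)) / g  # weight of position i in the RES average
    total_out = w.sum() / (g - m)
    inc = 1.0 / m + 1.0 / (g - m)
    return float(inc * w[positions].sum() - total_out)


def ptm_sea(
    z_sites: pd.Series,
    signatures: dict,
    weight: int = 0,
    nperm: int = 1000,
    min_overlap: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """PTM signature enrichment: weight-0 running-sum area statistic with
    feature-label permutation NES and +1-smoothed permutation p.

    Members tagged "d" have the feature statistic sign-flipped before the
    per-signature ranking.  Signatures with overlap < ``min_overlap`` are
    skipped.
    """
    if nperm < 1:
        raise AcuteomixError("nperm must be >= 1")
    if weight != 0:
        raise AcuteomixError("only weight=0 (rank-only running sum) is implemented")
    zz = z_sites.dropna()
    g = len(zz)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in signatures.items():
        directions = {}
        for mem in members:
            if isinstance(mem, tuple):
                directions[mem[0]] = mem[1]
            else:
                directions[mem] = "u"
        ids = [s for s in directions if s in zz.index]
        m_size = len(ids)
        if m_size < min_overlap or g - m_size < 1:
            continue
        stat = zz.copy()
        flip = [s for s in ids if directions[s] == "d"]
        stat.loc[flip] = -stat.loc[flip]
        order = np.argsort(-stat.to_numpy(), kind="mergesort")
        ranked_ids = stat.index.to_numpy()[order]
        member_pos = np.flatnonzero(np.isin(ranked_ids, ids))
        es = _area_es(member_pos, g, m_size)

        null = np.empty(nperm)
        for b in range(nperm):
            pos = rng.choice(g, size=m_size, replace=False)
            null[b] = _area_es(pos, g, m_size)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same):
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
        else:
            nes, p = np.nan, 1.0 / (1 + nperm)
        rows.append({"signature": name, "size": m_size, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows, columns=["signature", "size", "es", "nes", "p"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def localization_filter(
    results: pd.DataFrame, scores: pd.Series, min_score: float = 17.0
) -> pd.DataFrame:
    """Keep only confidently localized sites (score strictly above the cut)."""
    ok = results["feature"].map(scores) > min_score
    return results[ok.fillna(False)].reset_index(drop=True)
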