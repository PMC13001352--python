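"""Nearest-neighbor phosphosite analysis.

Each site's difference-in-changes estimates over (EE, RE) x (15min, 3.5h,
24h) form a fold-change profile; neighbors of an anchor site are profiles
with Pearson r at or above a threshold that are also differentially abundant
at one or more cells; neighbor proteins feed a hypergeometric ORA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import AcuteomixError
from .enrichment import ora

log = logging.getLogger(__name__)

PROFILE_ORDER = (
    ("EE", "15min"), ("EE", "3.5h"), ("EE", "24h"),
    ("RE", "15min"), ("RE", "3.5h"), ("RE", "24h"),
)


def profile_fold_changes(results: pd.DataFrame, site_ids=None) -> pd.DataFrame:
    """Site x profile-cell matrix of delta-delta estimates in fixed order.

    Missing cells are NaN (masked in downstream correlations).
    """
    df = results if site_ids is None else results[results["feature"].isin(set(site_ids))]
    cols = [f"{g}.{t}" for g, t in PROFILE_ORDER]
    mat = df.pivot_table(index="feature", columns="contrast", values="estimate", aggfunc="first")
    return mat.reindex(columns=cols)


def _pairwise_r(a: np.ndarray, b: np.ndarray, min_overlap: int = 3) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_overlap:
        return np.nan
    x, y = a[ok], b[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def find_neighbors(
    anchor: str,
    profiles: pd.DataFrame,
    da_table: pd.DataFrame = None,
    r_min: float = 0.8,
    require_da: bool = True,
    min_overlap: int = 3,
) -> pd.Series:
    """Sites whose profile correlates with the anchor at r >= ``r_min``.

    With ``require_da``, a neighbor must be significant (adj_p < 0.05) at
    one or more (modality, timepoint) cells.  The anchor is excluded from
    its own neighbor set; all-constant profiles are skipped with a log entry.
    """
    if anchor not in profiles.index:
        raise AcuteomixError(f"anchor site {anchor!r} not in profiles")
    av = profiles.loc[anchor].to_numpy(dtype=float)
    da_sites = None
    if require_da:
        if da_table is None:
            raise AcuteomixError("require_da needs the differential results table")
        da_sites = set(da_table.loc[da_table["adj_p"] < 0.05, "feature"])
    rs = {}
    for site in profiles.index:
        if site == anchor:
            continue
        r = _pairwise_r(av, profiles.loc[site].to_numpy(dtype=float), min_overlap)
        if np.isnan(r):
            log.info("find_neighbors: site %s skipped (constant or sparse profile)", site)
            continue
        rs[site] = r
    rs = pd.Series(rs, dtype=float).sort_values(ascending=False)
    neigh = rs[rs >= r_min]
    if require_da:
        neigh = neigh[neigh.index.isin(da_sites)]
    return neigh.rename("r")


def neighbor_ora(
    neighbors,
    site_protein: dict,
    universe_sites,
    sets: dict,
    min_proteins: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Protein-level ORA of the neighbor set.

    Sites collapse to proteins; only sets with >= ``min_proteins``
    contributing proteins and BH adj_p < ``alpha`` are reported.  An empty
    neighbor set yields an empty table.
    """
    neighbor_ids = list(neighbors.index) if isinstance(neighbors, pd.Series) else list(neighbors)
    universe = sorted({site_protein[s] for s in universe_sites if s in site_protein})
    hits = sorted({site_protein[s] for s in neighbor_ids if s in site_protein})
    if not hits:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "p", "adj_p"])
    res = ora(hits, universe, sets)
    return res[(res["overlap"] >= min_proteins) & (res["adj_p"] < alpha)].reset_index(drop=True)
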