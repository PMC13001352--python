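"""Coverage-based CpG filtering and MCL merging of nearby correlated sites.

The merge follows a four-step decision algorithm: (a) per-sample nCpG10
(sites at >=10x coverage), (b) exclusion of samples below the 20th
percentile of nCpG10 from clustering, (c) MCL over sites with >=10x
coverage in all remaining samples, edges between sites within the window
weighted by the Pearson correlation of methylation fractions (negatives
zeroed), and (d) application of the resulting region assignments to all
samples including the excluded ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcuteomixError

log = logging.getLogger(__name__)


@dataclass
class CpGCoverage:
    """Per-site counts: ``sites`` has chrom + pos (1-based); ``methylated``
    and ``total`` are site x sample count matrices sharing the site index."""

    sites: pd.DataFrame
    methylated: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self):
        if (self.methylated.to_numpy() > self.total.to_numpy()).any():
            raise AcuteomixError("methylated counts exceed totals")
        for chrom, grp in self.sites.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise AcuteomixError(f"positions not strictly increasing on {chrom}")

    def subset(self, keep) -> "CpGCoverage":
        return CpGCoverage(
            self.sites.loc[keep], self.methylated.loc[keep], self.total.loc[keep]
        )


def read_bismark_coverage(paths: dict) -> CpGCoverage:
    """Combine bismark-style coverage TSVs (chrom, pos, methylated,
    unmethylated), one file per sample keyed by sample id."""
    meth, tot = {}, {}
    for sample, path in paths.items():
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "methylated", "unmethylated"]
        )
        df = df.set_index(["chrom", "pos"])
        meth[sample] = df["methylated"]
        tot[sample] = df["methylated"] + df["unmethylated"]
    meth = pd.DataFrame(meth).fillna(0).astype(int)
    tot = pd.DataFrame(tot).fillna(0).astype(int)
    sites = meth.index.to_frame(index=False)
    idx = pd.RangeIndex(len(sites))
    sites.index = idx
    meth.index = idx
    tot.index = idx
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort")
    return CpGCoverage(sites, meth.loc[sites.index], tot.loc[sites.index])


def filter_cpg_coverage(cov: CpGCoverage, min_cov: int = 5, min_fraction: float = 0.5) -> pd.Series:
    """Keep sites with >= ``min_cov`` coverage in at least ``min_fraction``
    of samples (boundary retained: removal applies to 'less than')."""
    if cov.total.shape[1] < 1:
        raise AcuteomixError("no samples in coverage table")
    frac = (cov.total >= min_cov).mean(axis=1)
    return (frac >= min_fraction).rename("keep")


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
    self_loops: bool = True,
) -> list:
    """Markov Cluster Algorithm on a nonnegative weighted graph.

    Returns a list of clusters (lists of node indices); deterministic.
    """
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any():
        raise AcuteomixError("adjacency weights must be nonnegative")
    n = a.shape[0]
    if n == 0:
        return []
    m = a.copy()
    if self_loops:
        np.fill_diagonal(m, np.maximum(np.diag(m), m.max(axis=0) if m.max() > 0 else 1.0))
        np.fill_diagonal(m, np.where(np.diag(m) == 0, 1.0, np.diag(m)))
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    m = m / col
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune] = 0.0
        col = m.sum(axis=0)
        col[col == 0] = 1.0
        m = m / col
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    if not converged:
        log.warning("mcl: not converged at %d iterations; best-iterate clusters", max_iter)
    # attractor graph: i attracts j when M[i, j] > 0; weak components
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rows, cols = np.nonzero(m > prune)
    for i, j in zip(rows, cols):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


@dataclass
class CpGRegionSet:
    regions: pd.DataFrame        # region_id, chrom, start_pos, end_pos, n_sites
    assignment: pd.Series        # site index -> region_id
    pooled_methylated: pd.DataFrame
    pooled_total: pd.DataFrame
    clustering_samples: list     # samples used in step (c)


def merge_cpg_regions(
    cov: CpGCoverage,
    window_bp: int = 1000,
    inflation: float = 2.0,
    ncpg10_cov: int = 10,
    percentile: float = 20.0,
) -> CpGRegionSet:
    """Merge nearby correlated CpG sites into regions via MCL (steps a-d)."""
    if window_bp <= 0:
        raise AcuteomixError("window_bp must be positive")
    # (a) per-sample nCpG10
    ncpg10 = (cov.total >= ncpg10_cov).sum(axis=0)
    # (b) exclude samples strictly below the 20th percentile
    cut = np.percentile(ncpg10.to_numpy(), percentile)
    keep_samples = ncpg10.index[ncpg10 >= cut].tolist()
    log.info(
        "merge_cpg_regions: %d/%d samples retained for clustering (nCpG10 cut %.1f)",
        len(keep_samples), cov.total.shape[1], cut,
    )
    # (c) cluster sites with >=10x coverage in all remaining samples
    tot_k = cov.total[keep_samples]
    clusterable = (tot_k >= ncpg10_cov).all(axis=1)
    frac = cov.methylated[keep_samples] / tot_k.replace(0, np.nan)

    cluster_of = pd.Series(-1, index=cov.sites.index, dtype=int)
    next_cluster = 0
    for chrom, grp in cov.sites.groupby("chrom"):
        idx = grp.index[clusterable.loc[grp.index]]
        if len(idx) == 0:
            continue
        pos = cov.sites.loc[idx, "pos"].to_numpy()
        f = frac.loc[idx].to_numpy(dtype=float)
        n = len(idx)
        adj = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if pos[j] - pos[i] > window_bp:
                    break
                a, b = f[i], f[j]
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 3 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
                    r = np.corrcoef(a[ok], b[ok])[0, 1]
                    adj[i, j] = adj[j, i] = max(0.0, r)
        for members in mcl(adj, inflation=inflation):
            for mi in members:
                cluster_of[idx[mi]] = next_cluster
            next_cluster += 1

    # regions: maximal runs of consecutive same-cluster sites (contiguity),
    # unclustered sites become singletons; (d) pooled counts over ALL samples
    region_rows, assign = [], {}
    region_id = 0
    for chrom, grp in cov.sites.groupby("chrom"):
        prev_cluster = None
        run = []
        ordered = grp.sort_values("pos").index
        for si in ordered:
            cl = cluster_of[si]
            if cl >= 0 and cl == prev_cluster:
                run.append(si)
            else:
                if run:
                    region_rows.append((region_id, chrom, run))
                    region_id += 1
                run = [si]
            prev_cluster = cl if cl >= 0 else None
            if cl < 0:  # singleton: close immediately
                region_rows.append((region_id, chrom, run))
                region_id += 1
                run = []
        if run:
            region_rows.append((region_id, chrom, run))
            region_id += 1

    meta, pooled_m, pooled_t = [], {}, {}
    for rid, chrom, members in region_rows:
        name = f"region_{rid + 1:06d}"
        for si in members:
            assign[si] = name
        meta.append(
            {
                "region_id": name,
                "chrom": chrom,
                "start_pos": int(cov.sites.loc[members, "pos"].min()),
                "end_pos": int(cov.sites.loc[members, "pos"].max()),
                "n_sites": len(members),
            }
        )
        pooled_m[name] = cov.methylated.loc[members].sum(axis=0)
        pooled_t[name] = cov.total.loc[members].sum(axis=0)
    regions = pd.DataFrame(meta).set_index("region_id")
    return CpGRegionSet(
        regions=regions,
        assignment=pd.Series(assign).sort_index(),
        pooled_methylated=pd.DataFrame(pooled_m).T.loc[regions.index],
        pooled_total=pd.DataFrame(pooled_t).T.loc[regions.index],
        clustering_samples=keep_samples,
    )
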