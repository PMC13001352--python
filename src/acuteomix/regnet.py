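"""Phospho-TF -> transcript regulatory network inference.

Regulators are TF phosphosites (<=40% missing, chained-equations imputation
averaged over 15 runs); features are fuzzy-c-means clustered on stacked
z-profiles; per-target tree-ensemble importances give edge weights; a
column-shuffle permutation null trims edges; a simplified cis-regulatory
circuit linker adds TF->gene edges; the integrated multiset union is scored
per node by motif participation (FFL, diamond, 3-chain).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core import AcuteomixError, bh_adjust

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["regulator", "target", "weight", "modality", "provenance", "p", "adj_p"]


def prepare_regulators(
    phospho_values: pd.DataFrame,
    tf_list,
    site_gene: dict,
    max_missing: float = 0.40,
    n_imputations: int = 15,
) -> pd.DataFrame:
    """TF phosphosite regulator matrix, complete after averaged MICE.

    Sites must map to a TF gene and have at most 40% missing values; missing
    cells are the mean of ``n_imputations`` chained-equations imputations
    run with seeds 1..n_imputations.
    """
    if not len(tf_list):
        raise AcuteomixError("tf_list is empty")
    tfs = set(tf_list)
    keep = [
        s
        for s in phospho_values.index
        if site_gene.get(s) in tfs
        and phospho_values.loc[s].isna().mean() <= max_missing
    ]
    if not keep:
        raise AcuteomixError("no TF phosphosites pass the missingness filter")
    sub = phospho_values.loc[keep]
    if not sub.isna().any().any():
        return sub.copy()
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    x = sub.to_numpy(dtype=float).T  # samples x sites for column-wise imputation
    acc = np.zeros_like(x)
    for s in range(1, n_imputations + 1):
        imp = IterativeImputer(sample_posterior=True, random_state=s, max_iter=10)
        acc += imp.fit_transform(x)
    return pd.DataFrame((acc / n_imputations).T, index=sub.index, columns=sub.columns)


def mfuzz_fuzzifier(n_features: int, dim: int) -> float:
    """Fuzzy c-means fuzzifier from the feature count N and profile length D."""
    n, d = float(n_features), float(dim)
    return (
        1.0
        + (1418.0 / n + 22.05) * d**-2
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


def _fcm(x: np.ndarray, c: int, m: float, seed: int, max_iter: int = 200, tol: float = 1e-6):
    """Standard fuzzy c-means; returns (memberships N x c, centroids c x D)."""
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    for _ in range(max_iter):
        um = u**m
        cent = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        new_u = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    um = u**m
    cent = (um.T @ x) / um.sum(axis=0)[:, None]
    return u, cent


@dataclass
class ClusteringResult:
    memberships: pd.DataFrame  # features x clusters
    centroids: np.ndarray
    c: int
    fuzzifier: float

    @property
    def hard_labels(self) -> pd.Series:
        return pd.Series(
            self.memberships.to_numpy().argmax(axis=1), index=self.memberships.index
        )


def cluster_features(
    profiles: pd.DataFrame,
    c_range=range(2, 13),
    seed: int = 0,
    validity_fraction: float = 0.1,
) -> ClusteringResult:
    """Fuzzy c-means over stacked regulator/target z-profiles.

    Rows are scaled by standard deviations computed with two temporary zero
    columns appended (pre-exercise placeholders).  The chosen c is the
    largest one whose minimum pairwise centroid distance exceeds
    ``validity_fraction`` of the c=2 minimum distance.
    """
    x = profiles.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise AcuteomixError("profiles must be finite")
    n, d = x.shape
    c_range = [c for c in c_range]
    if any(c < 2 or c > n - 1 for c in c_range):
        raise AcuteomixError(f"c_range must lie in [2, {n - 1}]")
    padded = np.hstack([x, np.zeros((n, 2))])
    sd = padded.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    x = x / sd[:, None]
    m = mfuzz_fuzzifier(n, d)

    results = {}
    min_dist = {}
    for c in sorted(c_range):
        u, cent = _fcm(x, c, m, seed)
        dists = [
            np.linalg.norm(cent[i] - cent[j])
            for i, j in itertools.combinations(range(c), 2)
        ]
        results[c] = (u, cent)
        min_dist[c] = min(dists)
    ref = min_dist[min(min_dist)]
    chosen = max((c for c in min_dist if min_dist[c] > validity_fraction * ref), default=min(min_dist))
    u, cent = results[chosen]
    memberships = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster{i + 1}" for i in range(chosen)]
    )
    return ClusteringResult(memberships=memberships, centroids=cent, c=chosen, fuzzifier=m)


def infer_edges(
    regulators: pd.DataFrame,
    targets: pd.DataFrame,
    memberships: ClusteringResult = None,
    site_gene: dict = None,
    target_gene: dict = None,
    n_trees: int = 100,
    seed: int = 0,
    modality: str = "EE",
) -> pd.DataFrame:
    """Per-target random-forest regression on candidate regulators.

    Candidates are regulators sharing the target's argmax-membership cluster
    (falling back to all regulators when none co-cluster); phosphosites on
    the target's own gene are excluded.  Edge weight = impurity importance.
    """
    if list(regulators.columns) != list(targets.columns):
        raise AcuteomixError("regulator and target matrices must share sample columns")
    labels = memberships.hard_labels if memberships is not None else None
    rows = []
    rng = np.random.default_rng(seed)
    reg_ids = list(regulators.index)
    for tgt in targets.index:
        y = targets.loc[tgt].to_numpy(dtype=float)
        if np.std(y) == 0:
            log.info("infer_edges: zero-variance target %s skipped", tgt)
            continue
        cands = reg_ids
        if labels is not None and tgt in labels.index:
            cl = labels[tgt]
            cands = [r for r in reg_ids if labels.get(r) == cl]
            if not cands:
                cands = reg_ids
        if site_gene is not None:
            own = target_gene.get(tgt, tgt) if target_gene else tgt
            cands = [r for r in cands if site_gene.get(r) != own]
        if not cands:
            continue
        x = regulators.loc[cands].to_numpy(dtype=float).T
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(x, y)
        for reg, w in zip(cands, rf.feature_importances_):
            rows.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "weight": float(w),
                    "modality": modality,
                    "provenance": "edge-inference",
                }
            )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS[:5])


def permutation_trim(
    regulators: pd.DataFrame,
    targets: pd.DataFrame,
    memberships: ClusteringResult = None,
    n_perm: int = 100,
    weight_floor: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
    **infer_kwargs,
) -> pd.DataFrame:
    """Permutation-null edge trimming.

    Regulator sample columns are shuffled relative to targets ``n_perm``
    times; the pooled null of importances gives a +1-smoothed p per edge,
    BH-adjusted; retained edges need adj_p < alpha AND weight > floor.
    """
    if n_perm < 1:
        raise AcuteomixError("n_perm must be >= 1")
    edges = infer_edges(regulators, targets, memberships, seed=seed, **infer_kwargs)
    rng = np.random.default_rng(seed)
    null_weights = []
    for b in range(n_perm):
        perm = rng.permutation(regulators.shape[1])
        shuffled = pd.DataFrame(
            regulators.to_numpy()[:, perm], index=regulators.index, columns=regulators.columns
        )
        null = infer_edges(
            shuffled, targets, memberships, seed=seed + b + 1, **infer_kwargs
        )
        null_weights.append(null["weight"].to_numpy())
    pooled = np.sort(np.concatenate(null_weights)) if null_weights else np.array([])
    n_null = pooled.size
    w = edges["weight"].to_numpy()
    ge = n_null - np.searchsorted(pooled, w, side="left")
    edges = edges.copy()
    edges["p"] = (1.0 + ge) / (1.0 + n_null)
    edges["adj_p"] = bh_adjust(edges["p"].to_numpy())
    kept = edges[(edges["adj_p"] < alpha) & (edges["weight"] > weight_floor)]
    return kept.reset_index(drop=True)


def infer_circuits(
    atac_results: pd.DataFrame,
    atac_values: pd.DataFrame,
    rna_results: pd.DataFrame,
    rna_values: pd.DataFrame,
    peak_tss: pd.DataFrame,
    motif_occupancy: pd.DataFrame,
    tf_activity: pd.DataFrame = None,
    window_bp: int = 100_000,
    peak_p: float = 0.005,
    gene_adj_p: float = 0.05,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simplified cis-regulatory circuit linking.

    Candidate (TF, peak, gene) triplets: peak differential at raw p < 0.005,
    gene differential at adj p < 0.05, |peak center - TSS| <= 100 kb, TF
    motif present in the peak.  Linking statistic = corr(peak, gene) x
    corr(TF activity proxy, peak); significance by sample-permutation null
    with BH.  TF activity defaults to the TF's transcript values.
    """
    da_peaks = set(atac_results.loc[atac_results["p"] < peak_p, "feature"])
    da_genes = set(rna_results.loc[rna_results["adj_p"] < gene_adj_p, "feature"])
    shared = [s for s in atac_values.columns if s in set(rna_values.columns)]
    if len(shared) < 3:
        raise AcuteomixError("need >=3 shared samples for circuit linking")
    if tf_activity is None:
        tf_activity = rna_values

    cands = []
    for _, row in peak_tss.iterrows():
        peak, gene, dist = row["peak"], row["gene"], row["tss_distance"]
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            log.info("infer_circuits: missing TSS for a candidate gene; skipped")
            continue
        if abs(dist) > window_bp or peak not in da_peaks or gene not in da_genes:
            continue
        if peak not in motif_occupancy.index or gene not in rna_values.index:
            continue
        for tf in motif_occupancy.columns[motif_occupancy.loc[peak].astype(bool)]:
            if tf in tf_activity.index:
                cands.append((tf, peak, gene, int(dist)))
    if not cands:
        return pd.DataFrame(
            columns=["tf", "peak", "gene", "tss_distance", "stat", "p", "adj_p"]
        )

    def zrows(df, ids):
        x = df.loc[ids, shared].to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        sd[sd == 0] = 1.0
        return x / sd[:, None]

    tfs = [c[0] for c in cands]
    peaks = [c[1] for c in cands]
    genes = [c[2] for c in cands]
    n = len(shared)
    pz = zrows(atac_values, peaks)
    gz = zrows(rna_values, genes)
    az = zrows(tf_activity, tfs)
    stat = (pz * gz).sum(axis=1) / n * ((az * pz).sum(axis=1) / n)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(cands))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null = (pz * gz[:, perm]).sum(axis=1) / n * ((az[:, perm] * pz).sum(axis=1) / n)
        exceed += np.abs(null) >= np.abs(stat)
    p = (1.0 + exceed) / (1.0 + n_perm)
    out = pd.DataFrame(
        {
            "tf": tfs, "peak": peaks, "gene": genes,
            "tss_distance": [c[3] for c in cands],
            "stat": stat, "p": p, "adj_p": bh_adjust(p),
        }
    )
    return out[out["adj_p"] < alpha].reset_index(drop=True)


def circuits_to_edges(circuits: pd.DataFrame) -> pd.DataFrame:
    """Emit circuit TF->gene records as network edges."""
    if not len(circuits):
        return pd.DataFrame(columns=EDGE_COLUMNS[:5])
    return pd.DataFrame(
        {
            "regulator": circuits["tf"],
            "target": circuits["gene"],
            "weight": circuits["stat"].abs(),
            "modality": "circuit",
            "provenance": "circuit-linking",
        }
    )


def integrate(*networks: pd.DataFrame) -> pd.DataFrame:
    """Multiset union of edge tables: duplicates across methods are kept as
    separate records with their provenance intact."""
    frames = [n for n in networks if n is not None and len(n)]
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS[:5])
    return pd.concat(frames, ignore_index=True)


def filter_validated_targets(edges: pd.DataFrame, regulator: str, validated) -> pd.DataFrame:
    """Generic edge filter: keep a regulator's edges whose target appears in a
    user-supplied validated-target list (e.g. ChIP-supported targets)."""
    validated = set(validated)
    mine = edges[edges["regulator"] == regulator]
    return mine[mine["target"].isin(validated)].reset_index(drop=True)


def _simple_digraph(edges: pd.DataFrame):
    adj, radj, nodes = {}, {}, set()
    for _, row in edges.iterrows():
        a, b = row["regulator"], row["target"]
        if a == b:
            raise AcuteomixError(f"self-loop rejected: {a}")
        nodes.update((a, b))
        adj.setdefault(a, set()).add(b)
        radj.setdefault(b, set()).add(a)
    for v in nodes:
        adj.setdefault(v, set())
        radj.setdefault(v, set())
    return adj, radj, sorted(nodes)


def count_motifs(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node participation counts in FFL, 3-chain and diamond instances.

    Parallel records are collapsed to a simple digraph before counting;
    instances are enumerated exhaustively.
    """
    adj, radj, nodes = _simple_digraph(edges)
    counts = {v: {"ffl": 0, "chain3": 0, "diamond": 0} for v in nodes}

    # FFL: A->B, A->C, B->C
    for b in nodes:
        for c in adj[b]:
            for a in radj[b] & radj[c]:
                if a != c:
                    counts[a]["ffl"] += 1
                    counts[b]["ffl"] += 1
                    counts[c]["ffl"] += 1
    # 3-chain: A->B->C with A != C
    for b in nodes:
        for a in radj[b]:
            for c in adj[b]:
                if a != c:
                    counts[a]["chain3"] += 1
                    counts[b]["chain3"] += 1
                    counts[c]["chain3"] += 1
    # diamond: A->B, A->C, B->D, C->D; unordered middle pair, all 4 distinct
    for b, c in itertools.combinations(nodes, 2):
        common_pred = radj[b] & radj[c]
        common_succ = adj[b] & adj[c]
        if not common_pred or not common_succ:
            continue
        for a in common_pred:
            if a in (b, c):
                continue
            for d in common_succ:
                if d in (a, b, c):
                    continue
                counts[a]["diamond"] += 1
                counts[b]["diamond"] += 1
                counts[c]["diamond"] += 1
                counts[d]["diamond"] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").astype(int)
    out.index.name = "node"
    return out.sort_index()


def network_motif_score(counts: pd.DataFrame) -> pd.Series:
    """NMS per node: sum over motif types of the min-max-normalized
    participation count; a constant-count type contributes 0."""
    if not len(counts):
        return pd.Series(dtype=float, name="nms")
    nms = pd.Series(0.0, index=counts.index, name="nms")
    for col in counts.columns:
        x = counts[col].astype(float)
        rng_ = x.max() - x.min()
        if rng_ > 0:
            nms += (x - x.min()) / rng_
    return nms


def write_graphml(edges: pd.DataFrame, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(edges), path)


def to_networkx(edges: pd.DataFrame):
    import networkx as nx

    g = nx.MultiDiGraph()
    for _, row in edges.iterrows():
        g.add_edge(
            row["regulator"], row["target"],
            weight=row.get("weight", 1.0),
            modality=row.get("modality", ""),
            provenance=row.get("provenance", ""),
        )
    return g
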