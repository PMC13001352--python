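"""Cross-omic pathway-guided latent-variable decomposition.

Per-ome matrices are reduced to a shared protein/gene row space (cumulative
promoter-accessibility and cumulative phosphorylation scores), row-z-scored
per ome block, and concatenated column-wise.  The decomposition minimizes

    ||Y - Z B||^2 + l1 ||Z - C U||^2 + l2 ||B||^2 + l3 |U|_1,  U >= 0

by block coordinate descent with ridge closed forms for Z and B and
nonnegative coordinate descent for U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AcuteomixError, bh_adjust

log = logging.getLogger(__name__)


@dataclass
class CrossOmicMatrix:
    y: pd.DataFrame          # rows: shared genes/proteins; columns: (ome, sample)
    blocks: dict             # ome -> list of column labels

    @property
    def omes(self):
        return list(self.blocks)


@dataclass
class PlierModel:
    z: pd.DataFrame          # features x K loadings
    b: pd.DataFrame          # K x (ome, sample) LV scores
    u: pd.DataFrame          # pathways x K prior weights (nonnegative)
    c: pd.DataFrame          # features x pathways binary prior
    lambdas: tuple
    objective_trace: list
    blocks: dict


def _row_zscore(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def promoter_peaks(peak_meta: pd.DataFrame, gene_tss: dict, promoter_bp: int = 1000) -> pd.DataFrame:
    """Annotate peaks whose center is within ``promoter_bp`` of a gene TSS.

    Returns rows (peak, gene, tss_distance) for Promoter (<=1kb) peaks, each
    peak assigned to its nearest gene.
    """
    rows = []
    genes = list(gene_tss)
    tss = np.array([gene_tss[g] for g in genes])
    for peak, row in peak_meta.iterrows():
        center = (row["start"] + row["end"]) // 2
        i = int(np.argmin(np.abs(tss - center)))
        dist = int(center - tss[i])
        if abs(dist) <= promoter_bp:
            rows.append({"peak": peak, "gene": genes[i], "tss_distance": dist})
    return pd.DataFrame(rows, columns=["peak", "gene", "tss_distance"])


def cumulative_scores(
    values: pd.DataFrame, feature_gene: pd.Series, agg: str = "sum"
) -> pd.DataFrame:
    """Per-gene cumulative score: sum (default) of member feature rows."""
    joined = values.join(feature_gene.rename("_gene"), how="inner")
    grouped = joined.groupby("_gene")
    return grouped.sum() if agg == "sum" else grouped.mean()


def build_cross_omic_matrix(
    matrices: dict,
    feature_gene_maps: dict,
    omes: tuple,
    agg: str = "sum",
) -> CrossOmicMatrix:
    """Stack z-scored per-ome blocks over the genes present in all omes.

    ``matrices`` maps ome -> normalized feature x sample DataFrame;
    ``feature_gene_maps`` maps ome -> Series(feature -> gene) for omes whose
    features need collapsing (atac promoter peaks, phospho sites); rna and
    protein rows are assumed keyed by gene already.
    """
    per_gene = {}
    for ome in omes:
        vals = matrices[ome]
        fmap = feature_gene_maps.get(ome)
        per_gene[ome] = cumulative_scores(vals, fmap, agg=agg) if fmap is not None else vals
    shared = None
    for ome in omes:
        idx = set(per_gene[ome].index)
        shared = idx if shared is None else shared & idx
    if not shared:
        raise AcuteomixError("no shared genes across requested omes")
    shared = sorted(shared)
    blocks, parts = {}, []
    for ome in omes:
        block = _row_zscore(per_gene[ome].loc[shared])
        block.columns = pd.MultiIndex.from_product([[ome], block.columns])
        blocks[ome] = list(block.columns)
        parts.append(block)
    return CrossOmicMatrix(y=pd.concat(parts, axis=1), blocks=blocks)


def estimate_num_pc(y: np.ndarray, n_perm: int = 20, quantile: float = 0.95, seed: int = 0) -> int:
    """Parallel analysis: number of singular values of Y exceeding the
    ``quantile`` of column-permuted singular values, component-wise."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise AcuteomixError("Y must be finite")
    sv = np.linalg.svd(y, compute_uv=False)
    if sv.max() == 0:
        raise AcuteomixError("degenerate (rank-0) matrix")
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(sv)))
    for b in range(n_perm):
        perm = np.empty_like(y)
        for j in range(y.shape[1]):
            perm[:, j] = y[rng.permutation(y.shape[0]), j]
        null[b] = np.linalg.svd(perm, compute_uv=False)
    cut = np.quantile(null, quantile, axis=0)
    exceeds = sv > cut
    k = int(np.argmin(exceeds)) if not exceeds.all() else len(sv)
    return max(k, 0)


def choose_lv_count(y: np.ndarray, fallback: int = 100, **kwargs) -> int:
    """Double the significant-PC count; fall back when estimation fails."""
    try:
        k = estimate_num_pc(y, **kwargs)
    except AcuteomixError:
        return fallback
    return 2 * k if k > 0 else fallback


def _objective(y, z, b, c, u, l1, l2, l3):
    r = y - z @ b
    obj = np.sum(r * r) + l2 * np.sum(b * b)
    if l1 > 0:
        d = z - c @ u
        obj += l1 * np.sum(d * d) + l3 * np.sum(np.abs(u))
    return float(obj)


def _update_u(z, c, u, l1, l3, n_pass: int = 5):
    """Nonnegative coordinate descent for each LV column of U."""
    ctc = c.T @ c
    ctz = c.T @ z
    diag = np.diag(ctc).copy()
    diag[diag == 0] = 1.0
    shrink = l3 / (2.0 * l1)
    for _ in range(n_pass):
        for j in range(u.shape[0]):
            # residual excluding pathway j's contribution
            r = ctz[j] - ctc[j] @ u + diag[j] * u[j]
            u[j] = np.maximum(0.0, (r - shrink) / diag[j])
    return u


def fit_plier(
    y,
    c=None,
    k: int = 10,
    l1: float = None,
    l2: float = None,
    l3: float = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> PlierModel:
    """Block-coordinate minimization with SVD initialization.

    Penalty defaults are 0.1 x mean singular value of Y.  LV loadings are
    normalized to unit columns (with compensating B scaling) only on output.
    """
    ydf = y.y if isinstance(y, CrossOmicMatrix) else y
    blocks = y.blocks if isinstance(y, CrossOmicMatrix) else {}
    yv = ydf.to_numpy(dtype=float) if isinstance(ydf, pd.DataFrame) else np.asarray(ydf, dtype=float)
    n_feat, n_samp = yv.shape
    if c is None:
        cdf = None
        cv = np.zeros((n_feat, 0))
    else:
        cdf = c if isinstance(c, pd.DataFrame) else pd.DataFrame(c)
        if isinstance(ydf, pd.DataFrame) and isinstance(c, pd.DataFrame):
            cdf = cdf.reindex(ydf.index, fill_value=0)
        cv = cdf.to_numpy(dtype=float)
        if cv.shape[0] != n_feat:
            raise AcuteomixError("prior matrix rows must align with Y rows")
    sv = np.linalg.svd(yv, compute_uv=False)
    default = 0.1 * float(sv.mean())
    l1 = default if l1 is None else l1
    l2 = default if l2 is None else l2
    l3 = default if l3 is None else l3

    uu, ss, vt = np.linalg.svd(yv, full_matrices=False)
    kk = min(k, len(ss))
    z = uu[:, :kk] * np.sqrt(ss[:kk])
    b = (np.sqrt(ss[:kk])[:, None] * vt[:kk])
    if kk < k:  # pad with small random columns for over-complete requests
        rng = np.random.default_rng(seed)
        z = np.hstack([z, rng.normal(0, 1e-3, (n_feat, k - kk))])
        b = np.vstack([b, rng.normal(0, 1e-3, (k - kk, n_samp))])
    u = np.zeros((cv.shape[1], k))

    trace = [_objective(yv, z, b, cv, u, l1, l2, l3)]
    for it in range(max_iter):
        # B: ridge closed form
        a = z.T @ z + l2 * np.eye(k)
        b = np.linalg.solve(a, z.T @ yv)
        # Z: ridge toward CU
        lhs = b @ b.T + l1 * np.eye(k)
        rhs = yv @ b.T + (l1 * (cv @ u) if l1 > 0 and cv.shape[1] else 0.0)
        if l1 == 0:
            lhs = b @ b.T
            rhs = yv @ b.T
            z = np.linalg.lstsq(lhs, rhs.T, rcond=None)[0].T
        else:
            z = np.linalg.solve(lhs.T, rhs.T).T
        # U: nonnegative lasso columns, with per-LV sign selection (the
        # nonnegative prior cannot match sign-flipped loadings, so each LV
        # may flip Z/B signs jointly when that lowers the prior term)
        if l1 > 0 and cv.shape[1]:
            u_pos = _update_u(z, cv, u.copy(), l1, l3)
            u_neg = _update_u(-z, cv, u.copy(), l1, l3)
            rp = z - cv @ u_pos
            rn = -z - cv @ u_neg
            cost_p = l1 * (rp**2).sum(axis=0) + l3 * u_pos.sum(axis=0)
            cost_n = l1 * (rn**2).sum(axis=0) + l3 * u_neg.sum(axis=0)
            flip = cost_n < cost_p
            z[:, flip] *= -1.0
            b[flip, :] *= -1.0
            u = np.where(flip[None, :], u_neg, u_pos)
        obj = _objective(yv, z, b, cv, u, l1, l2, l3)
        if not np.isfinite(obj):
            raise AcuteomixError(f"non-finite objective at iteration {it}: {trace[-5:]}")
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            break

    # scale identifiability: unit-norm LV loadings, compensate B (and U)
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = 1.0
    z = z / norms
    b = b * norms[:, None]
    u = u / norms[None, :] if u.size else u

    lv_names = [f"LV{i + 1}" for i in range(k)]
    feat_idx = ydf.index if isinstance(ydf, pd.DataFrame) else pd.RangeIndex(n_feat)
    col_idx = ydf.columns if isinstance(ydf, pd.DataFrame) else pd.RangeIndex(n_samp)
    pw_idx = cdf.columns if cdf is not None else pd.Index([], dtype=object)
    return PlierModel(
        z=pd.DataFrame(z, index=feat_idx, columns=lv_names),
        b=pd.DataFrame(b, index=lv_names, columns=col_idx),
        u=pd.DataFrame(u, index=pw_idx, columns=lv_names),
        c=pd.DataFrame(cv, index=feat_idx, columns=pw_idx),
        lambdas=(l1, l2, l3),
        objective_trace=trace,
        blocks=blocks,
    )


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def lv_significance(
    model: PlierModel,
    design: pd.DataFrame,
    modalities: tuple = ("EE", "RE"),
    control: str = "CON",
) -> pd.DataFrame:
    """Within-subject LV delta (post - pre) tested per (LV, ome, modality,
    timepoint) against control with Welch's t; BH over the full grid."""
    d = design.set_index("sample_id")
    rows = []
    for ome, cols in model.blocks.items():
        scores = model.b[[c for c in model.b.columns if c in cols or (isinstance(c, tuple) and c[0] == ome)]]
        samp = [c[1] if isinstance(c, tuple) else c for c in scores.columns]
        meta = d.loc[samp]
        for lv in model.b.index:
            vals = pd.Series(scores.loc[lv].to_numpy(), index=samp)
            pre = {}
            for sid, row in meta[meta["timepoint"] == "pre"].iterrows():
                pre[row["participant_id"]] = vals[sid]
            for tp in sorted(meta.loc[meta["timepoint"] != "pre", "timepoint"].unique()):
                sub = meta[meta["timepoint"] == tp]
                deltas = {}
                for sid, row in sub.iterrows():
                    pid = row["participant_id"]
                    if pid not in pre:
                        log.info("lv_significance: %s lacks a pre sample; dropped", pid)
                        continue
                    deltas[pid] = vals[sid] - pre[pid]
                grp = {pid: meta.loc[meta["participant_id"] == pid, "group"].iloc[0] for pid in deltas}
                ctrl = np.array([deltas[p] for p in deltas if grp[p] == control])
                for mod in modalities:
                    ex = np.array([deltas[p] for p in deltas if grp[p] == mod])
                    rows.append(
                        {
                            "lv": lv, "ome": ome, "modality": mod, "timepoint": tp,
                            "effect": ex.mean() - ctrl.mean() if len(ex) and len(ctrl) else np.nan,
                            "p": _welch_p(ex, ctrl),
                        }
                    )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def cross_ome_correlation(model: PlierModel, ome_a: str, ome_b: str) -> pd.Series:
    """Pearson correlation of each LV's scores between two ome blocks,
    matched on sample id."""
    cols_a = {c[1]: c for c in model.b.columns if isinstance(c, tuple) and c[0] == ome_a}
    cols_b = {c[1]: c for c in model.b.columns if isinstance(c, tuple) and c[0] == ome_b}
    shared = sorted(set(cols_a) & set(cols_b))
    if len(shared) < 3:
        raise AcuteomixError("need >=3 shared samples for cross-ome correlation")
    out = {}
    for lv in model.b.index:
        a = model.b.loc[lv, [cols_a[s] for s in shared]].to_numpy(dtype=float)
        b = model.b.loc[lv, [cols_b[s] for s in shared]].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            out[lv] = np.nan
        else:
            out[lv] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name=f"cor_{ome_a}_{ome_b}")
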