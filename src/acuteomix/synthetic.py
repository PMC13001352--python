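"""Synthetic multi-omic cohort generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a
three-group (CON/EE/RE) design with pre plus arm-dependent post-exercise
timepoints, negative-binomial count omes with participant random intercepts,
Gaussian log-ratio omes, injected group-by-time (difference-in-changes)
effects, a planted TF-phosphosite -> target-gene regulatory network,
peak -> gene links on one synthetic chromosome, and pathway priors.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .core import (
    ARM_TIMEPOINTS,
    ARMS,
    GROUPS,
    POST_TIMEPOINTS,
    InvalidConfigError,
    OmicsMatrix,
    validate_design,
)

GAUSSIAN_OMES = ("protein", "phospho", "metab")


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``group_counts`` overrides largest-remainder rounding of
    ``allocation_ratio`` when realized group sizes are supplied directly.
    ``sex_counts`` optionally fixes the number of female participants per
    group (CON, EE, RE); otherwise sex is drawn with ``female_fraction``.
    """

    n_participants: int = 19
    allocation_ratio: tuple = (3, 8, 8)
    group_counts: tuple = None
    arm_probs: dict = field(
        default_factory=lambda: {a: 0.25 for a in ARMS}
    )
    sex_counts: tuple = None
    female_fraction: float = 0.72

    n_genes: int = 200
    n_tfs: int = 10
    n_peaks: int = 300
    n_phosphosites: int = 150
    n_metabolites: int = 60
    n_proteins: int = None  # default: all genes have a measured protein

    # planted effects: per-ome number of perturbed features and the grid of
    # |delta-delta| magnitudes cycled over them (log2 units / normalized units)
    n_perturbed: dict = field(default_factory=dict)
    effect_size_grid: dict = field(
        default_factory=lambda: {o: (1.0, 1.5, 2.0) for o in ("rna", "atac", "protein", "phospho", "metab")}
    )
    missingness: dict = field(
        default_factory=lambda: {"protein": 0.1, "phospho": 0.2, "metab": 0.1}
    )
    missing_mode: str = "mcar"  # or "censor" (intensity-dependent)

    # regulatory truth
    n_regulators: int = 5
    regulator_out_degree: float = 4.0
    regulator_coupling: float = 0.8

    # genome layout (0-based half-open, one synthetic chromosome)
    chrom: str = "chrS"
    gene_spacing: int = 20_000
    link_window_bp: int = 100_000
    peak_width: int = 200

    # pathway priors
    n_pathways: int = 20
    pathway_size: int = 15

    # noise model
    intercept_sd: float = 0.3
    nb_dispersion: float = 0.1
    feature_var_logmean: float = -1.2
    feature_var_logsd: float = 0.5
    time_effect_sd: float = 0.15
    n_batches: int = 2

    seed: int = 0

    def validate(self) -> "CohortConfig":
        if len(self.allocation_ratio) != 3 or any(r <= 0 for r in self.allocation_ratio):
            raise InvalidConfigError("allocation_ratio must be three positive integers")
        if self.group_counts is None and self.n_participants < sum(self.allocation_ratio):
            raise InvalidConfigError(
                "n_participants smaller than the sum of allocation ratio entries"
            )
        probs = np.array([self.arm_probs.get(a, 0.0) for a in ARMS], dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise InvalidConfigError("arm probabilities must be nonnegative and sum to 1")
        for name in ("n_genes", "n_tfs", "n_peaks", "n_phosphosites", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_tfs > self.n_genes:
            raise InvalidConfigError("n_tfs must not exceed n_genes")
        for ome, frac in self.missingness.items():
            if not 0 <= frac < 1:
                raise InvalidConfigError(f"missingness[{ome}] must be in [0, 1)")
        return self

    @property
    def proteins_count(self) -> int:
        return self.n_genes if self.n_proteins is None else self.n_proteins


@dataclass
class SyntheticTruth:
    genes: list
    tfs: list
    proteins: list
    metabolites: list
    phosphosite_gene: dict           # site id -> gene
    gene_tss: dict                   # gene -> TSS coordinate
    peaks: pd.DataFrame              # chrom, start, end, name
    peak_gene_links: pd.DataFrame    # peak, gene, tss_distance, tf
    motif_occupancy: pd.DataFrame    # peaks x TFs binary
    regulatory_edges: set            # {(regulator site, target gene)}
    pathway_memberships: dict        # set name -> [genes]
    perturbed_features: pd.DataFrame # ome, feature, group, timepoint, delta

    def validate(self, config: CohortConfig) -> "SyntheticTruth":
        if not set(self.tfs) <= set(self.genes):
            raise InvalidConfigError("TF list not a subset of gene list")
        for reg, _tgt in self.regulatory_edges:
            gene = self.phosphosite_gene.get(reg)
            if gene not in self.tfs:
                raise InvalidConfigError(f"regulator {reg} does not map to a TF gene")
        if len(self.peak_gene_links):
            if (self.peak_gene_links["tss_distance"].abs() > config.link_window_bp).any():
                raise InvalidConfigError("true peak-gene link outside the link window")
        if (self.perturbed_features["group"] == "CON").any():
            raise InvalidConfigError("CON must never carry injected effects")
        return self


@dataclass
class SyntheticBundle:
    omes: dict          # ome label -> OmicsMatrix
    design: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig


def _largest_remainder(n: int, ratio) -> list:
    ratio = np.asarray(ratio, dtype=float)
    quota = n * ratio / ratio.sum()
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    short = n - counts.sum()
    for i in np.argsort(-rem, kind="mergesort")[:short]:
        counts[i] += 1
    return counts.tolist()


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the sample design table (one row per collected sample)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.group_counts is not None:
        counts = list(config.group_counts)
        n = sum(counts)
    else:
        n = config.n_participants
        counts = _largest_remainder(n, config.allocation_ratio)

    groups = np.repeat(GROUPS, counts)
    arm_p = [config.arm_probs.get(a, 0.0) for a in ARMS]
    arms = rng.choice(ARMS, size=n, p=arm_p)
    ages = np.clip(np.round(rng.normal(41, 15, size=n)), 18, 75).astype(int)

    if config.sex_counts is not None:
        sexes = []
        for gi, cnt in enumerate(counts):
            nf = config.sex_counts[gi]
            if nf > cnt:
                raise InvalidConfigError("sex_counts exceed group size")
            sexes.extend(["F"] * nf + ["M"] * (cnt - nf))
        sexes = np.array(sexes)
    else:
        sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")

    rows = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        batch = f"B{(i % config.n_batches) + 1}"
        for tp in ("pre", *ARM_TIMEPOINTS[arms[i]]):
            rows.append(
                {
                    "sample_id": f"{pid}_{tp}",
                    "participant_id": pid,
                    "group": groups[i],
                    "timepoint": tp,
                    "sex": sexes[i],
                    "age": ages[i],
                    "batch": batch,
                    "arm": arms[i],
                }
            )
    design = pd.DataFrame(rows)
    return validate_design(design)


def generate_truth(config: CohortConfig) -> SyntheticTruth:
    """Plant the regulatory/genomic/pathway ground truth for one cohort."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    tfs = genes[: config.n_tfs]
    proteins = genes[: config.proteins_count]
    metabolites = [f"M{i + 1:04d}" for i in range(config.n_metabolites)]

    # phosphosites: the first n_regulators sit on TF genes (the regulators),
    # the rest are scattered over measured proteins
    if config.n_regulators > config.n_phosphosites:
        raise InvalidConfigError("n_regulators exceeds n_phosphosites")
    site_gene = {}
    sites = []
    for i in range(config.n_regulators):
        gene = tfs[i % len(tfs)]
        sid = f"{gene}_S{100 + i}"
        sites.append(sid)
        site_gene[sid] = gene
    host = rng.choice(proteins, size=config.n_phosphosites - config.n_regulators)
    for i, gene in enumerate(host):
        sid = f"{gene}_S{i + 1}"
        if sid in site_gene:  # same gene drawn twice: bump position
            sid = f"{gene}_T{i + 1}"
        sites.append(sid)
        site_gene[sid] = gene

    # regulatory edges: TF-phosphosite -> non-self target gene
    non_tf_genes = [g for g in genes if g not in set(tfs)]
    edges = set()
    for sid in sites[: config.n_regulators]:
        deg = max(1, rng.poisson(config.regulator_out_degree))
        if config.regulator_out_degree > len(non_tf_genes):
            raise InvalidConfigError("requested edge density infeasible")
        deg = min(deg, len(non_tf_genes))
        targets = rng.choice(non_tf_genes, size=deg, replace=False)
        for t in targets:
            edges.add((sid, str(t)))

    # genome: genes laid down one synthetic chromosome, TSS every gene_spacing
    gene_tss = {g: (i + 1) * config.gene_spacing for i, g in enumerate(genes)}

    # peaks: one promoter peak per gene for the first min(n_peaks, n_genes)
    # genes; remaining peaks placed within +/- link window of a random TSS
    peak_rows, link_rows = [], []
    n_promoter = min(config.n_peaks, config.n_genes)
    half = config.peak_width // 2
    for i in range(config.n_peaks):
        name = f"peak_{i + 1:05d}"
        if i < n_promoter:
            gene = genes[i]
            center = gene_tss[gene] + int(rng.integers(-500, 501))
        else:
            gene = str(rng.choice(genes))
            offset = int(rng.integers(-config.link_window_bp, config.link_window_bp + 1))
            center = max(half, gene_tss[gene] + offset)
        tf = str(rng.choice(tfs))
        peak_rows.append(
            {"chrom": config.chrom, "start": center - half, "end": center + half, "name": name}
        )
        link_rows.append(
            {"peak": name, "gene": gene, "tss_distance": center - gene_tss[gene], "tf": tf}
        )
    peaks = pd.DataFrame(peak_rows)
    links = pd.DataFrame(link_rows)

    occ = pd.DataFrame(
        rng.random((config.n_peaks, config.n_tfs)) < 0.15,
        index=peaks["name"], columns=tfs,
    )
    for _, row in links.iterrows():  # the linking TF always has its motif
        occ.loc[row["peak"], row["tf"]] = True

    pathways = {}
    for i in range(config.n_pathways):
        size = min(config.pathway_size, config.n_genes)
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{i + 1:03d}"] = sorted(map(str, members))

    # planted difference-in-changes effects; never in CON
    features_by_ome = {
        "rna": genes,
        "atac": list(peaks["name"]),
        "protein": proteins,
        "phospho": sites,
        "metab": metabolites,
    }
    pert_rows = []
    for ome, n_pert in sorted(config.n_perturbed.items()):
        pool = features_by_ome[ome]
        if n_pert > len(pool):
            raise InvalidConfigError(f"n_perturbed[{ome}] exceeds feature count")
        chosen = rng.choice(pool, size=n_pert, replace=False)
        grid = config.effect_size_grid.get(ome, (1.0,))
        for j, feat in enumerate(chosen):
            delta = grid[j % len(grid)] * (1 if rng.random() < 0.5 else -1)
            pert_rows.append(
                {
                    "ome": ome,
                    "feature": str(feat),
                    "group": ("EE", "RE")[int(rng.integers(2))],
                    "timepoint": POST_TIMEPOINTS[int(rng.integers(3))],
                    "delta": delta,
                }
            )
    perturbed = pd.DataFrame(
        pert_rows, columns=["ome", "feature", "group", "timepoint", "delta"]
    )

    truth = SyntheticTruth(
        genes=genes,
        tfs=tfs,
        proteins=proteins,
        metabolites=metabolites,
        phosphosite_gene=site_gene,
        gene_tss=gene_tss,
        peaks=peaks,
        peak_gene_links=links,
        motif_occupancy=occ,
        regulatory_edges=edges,
        pathway_memberships=pathways,
        perturbed_features=perturbed,
    )
    return truth.validate(config)


def _effect_matrix(features, design, truth, ome):
    """Per-(feature, sample) injected delta: applied at the perturbed
    (group, timepoint) cell only, so it shows up purely as a
    (group - CON) change-from-pre shift."""
    eff = np.zeros((len(features), len(design)))
    pert = truth.perturbed_features
    pert = pert[pert["ome"] == ome]
    if not len(pert):
        return eff
    fidx = {f: i for i, f in enumerate(features)}
    for _, row in pert.iterrows():
        i = fidx.get(row["feature"])
        if i is None:
            continue
        cols = (design["group"] == row["group"]) & (design["timepoint"] == row["timepoint"])
        eff[i, cols.to_numpy()] += row["delta"]
    return eff


def simulate_omics(design: pd.DataFrame, truth: SyntheticTruth, config: CohortConfig) -> SyntheticBundle:
    """Simulate all five omes for a design/truth pair."""
    config.validate()
    if set(truth.phosphosite_gene.values()) - set(truth.genes):
        raise InvalidConfigError("truth does not match config gene universe")
    if (
        len(truth.genes) != config.n_genes
        or len(truth.peaks) != config.n_peaks
        or len(truth.phosphosite_gene) != config.n_phosphosites
        or len(truth.metabolites) != config.n_metabolites
    ):
        raise InvalidConfigError("truth dimensions do not match config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_samp = len(design)
    participants = design["participant_id"].unique()
    p_index = design["participant_id"].map(
        {p: i for i, p in enumerate(participants)}
    ).to_numpy()

    # participant random intercepts (log2 scale), shared time trends per ome
    intercepts = {
        ome: rng.normal(0, config.intercept_sd, size=len(participants))
        for ome in ("rna", "atac", "protein", "phospho", "metab")
    }
    tp_codes = design["timepoint"].map({t: i for i, t in enumerate(("pre",) + POST_TIMEPOINTS)}).to_numpy()
    time_effects = {
        ome: np.concatenate([[0.0], rng.normal(0, config.time_effect_sd, size=3)])
        for ome in ("rna", "atac", "protein", "phospho", "metab")
    }

    def base_signal(ome, features):
        sig = intercepts[ome][p_index][None, :] + time_effects[ome][tp_codes][None, :]
        return np.broadcast_to(sig, (len(features), n_samp)).copy()

    def feature_sds(n):
        return np.exp(rng.normal(config.feature_var_logmean, config.feature_var_logsd, size=n))

    omes = {}

    # --- phospho first: regulators feed the transcriptome ---
    sites = sorted(truth.phosphosite_gene)
    sig = base_signal("phospho", sites)
    sig += _effect_matrix(sites, design, truth, "phospho")
    sds = feature_sds(len(sites))
    phospho_vals = sig + rng.normal(0, 1, sig.shape) * sds[:, None]
    site_pos = {s: i for i, s in enumerate(sites)}

    # --- RNA: NB counts; targets coupled to their regulator sites ---
    genes = truth.genes
    log_mu = base_signal("rna", genes)
    log_mu += _effect_matrix(genes, design, truth, "rna")
    gidx = {g: i for i, g in enumerate(genes)}
    gene_latent = log_mu.copy()  # retained for linked-peak coupling
    for reg, tgt in sorted(truth.regulatory_edges):
        x = phospho_vals[site_pos[reg]]
        xs = np.std(x)
        if xs > 0:
            z = (x - np.mean(x)) / xs
            log_mu[gidx[tgt]] += config.regulator_coupling * z
            gene_latent[gidx[tgt]] += config.regulator_coupling * z

    base_expr = rng.uniform(3, 9, size=len(genes))  # log2 mean expression
    mu = 2.0 ** (base_expr[:, None] + log_mu)
    r = 1.0 / config.nb_dispersion
    rna_counts = rng.negative_binomial(r, r / (r + mu))

    # --- ATAC: NB counts; linked peaks track their gene's latent signal ---
    peak_names = list(truth.peaks["name"])
    log_mu_a = base_signal("atac", peak_names)
    log_mu_a += _effect_matrix(peak_names, design, truth, "atac")
    for i, (_, row) in enumerate(truth.peak_gene_links.iterrows()):
        g = gidx.get(row["gene"])
        if g is not None:
            dev = gene_latent[g] - gene_latent[g].mean()
            log_mu_a[i] += 0.9 * dev
    base_acc = rng.uniform(3, 7, size=len(peak_names))
    mu_a = 2.0 ** (base_acc[:, None] + log_mu_a)
    atac_counts = rng.negative_binomial(r, r / (r + mu_a))

    # --- protein / metabolite: Gaussian on log scale ---
    prot = truth.proteins
    sig_p = base_signal("protein", prot) * 0.5
    sig_p += _effect_matrix(prot, design, truth, "protein")
    prot_vals = sig_p + rng.normal(0, 1, sig_p.shape) * feature_sds(len(prot))[:, None]

    mets = truth.metabolites
    base_met = rng.uniform(4, 12, size=len(mets))
    sig_m = base_signal("metab", mets) + base_met[:, None]
    sig_m += _effect_matrix(mets, design, truth, "metab")
    met_vals = 2.0 ** (sig_m + rng.normal(0, 1, sig_m.shape) * feature_sds(len(mets))[:, None])

    cols = design["sample_id"].tolist()

    def apply_missing(values: np.ndarray, ome: str) -> np.ndarray:
        frac = config.missingness.get(ome, 0.0)
        if frac <= 0:
            return values
        vals = values.astype(float).copy()
        if config.missing_mode == "censor":
            # intensity-dependent: low values preferentially censored
            ranks = np.argsort(np.argsort(vals, axis=None)).reshape(vals.shape)
            pmiss = frac * 2 * (1 - ranks / vals.size)
            mask = rng.random(vals.shape) < np.clip(pmiss, 0, 1)
        else:
            mask = rng.random(vals.shape) < frac
        vals[mask] = np.nan
        return vals

    pk = truth.peaks.set_index("name")
    atac_meta = pd.DataFrame(
        {"chrom": pk["chrom"], "start": pk["start"], "end": pk["end"]}
    )
    phospho_meta = pd.DataFrame(
        {
            "gene": [truth.phosphosite_gene[s] for s in sites],
            "confident_score": rng.integers(10, 41, size=len(sites)),
        },
        index=pd.Index(sites, name="feature_id"),
    )

    omes["rna"] = OmicsMatrix(
        pd.DataFrame(apply_missing(rna_counts, "rna"), index=genes, columns=cols),
        "rna",
        pd.DataFrame({"gene": genes}, index=pd.Index(genes, name="feature_id")),
    )
    omes["atac"] = OmicsMatrix(
        pd.DataFrame(apply_missing(atac_counts, "atac"), index=peak_names, columns=cols),
        "atac", atac_meta,
    )
    omes["protein"] = OmicsMatrix(
        pd.DataFrame(apply_missing(prot_vals, "protein"), index=prot, columns=cols),
        "protein",
        pd.DataFrame({"gene": prot}, index=pd.Index(prot, name="feature_id")),
    )
    omes["phospho"] = OmicsMatrix(
        pd.DataFrame(apply_missing(phospho_vals, "phospho"), index=sites, columns=cols),
        "phospho", phospho_meta,
    )
    omes["metab"] = OmicsMatrix(
        pd.DataFrame(apply_missing(met_vals, "metab"), index=mets, columns=cols),
        "metab",
    )
    return SyntheticBundle(omes=omes, design=design, truth=truth, config=config)


def generate_bundle(config: CohortConfig) -> SyntheticBundle:
    """Convenience: design + truth + simulated omes in one call."""
    design = generate_cohort(config)
    truth = generate_truth(config)
    return simulate_omics(design, truth, config)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ome, m in bundle.omes.items():
        aio.write_matrix_tsv(m, outdir / f"{ome}.tsv")
    aio.write_design_tsv(bundle.design, outdir / "design.tsv")
    aio.write_bed(bundle.truth.peaks, outdir / "peaks.bed")
    ann = pd.DataFrame(
        {
            "gene_id": bundle.truth.genes,
            "chrom": bundle.config.chrom,
            "tss": [bundle.truth.gene_tss[g] for g in bundle.truth.genes],
            "strand": "+",
        }
    )
    aio.write_annotation_tsv(ann, outdir / "annotation.tsv")
    aio.write_gmt(bundle.truth.pathway_memberships, outdir / "pathways.gmt")
    bundle.truth.motif_occupancy.astype(int).to_csv(
        outdir / "motif_occupancy.tsv", sep="\t", index_label="peak"
    )
    truth = bundle.truth
    aio.write_json(
        {
            "genes": truth.genes,
            "tfs": truth.tfs,
            "proteins": truth.proteins,
            "metabolites": truth.metabolites,
            "phosphosite_gene": truth.phosphosite_gene,
            "gene_tss": truth.gene_tss,
            "regulatory_edges": sorted(map(list, truth.regulatory_edges)),
            "peak_gene_links": truth.peak_gene_links.to_dict(orient="records"),
            "perturbed_features": truth.perturbed_features.to_dict(orient="records"),
            "pathway_memberships": truth.pathway_memberships,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(bundle.config).items()
            },
        },
        outdir / "truth.json",
    )


def bundle_digest(bundle: SyntheticBundle) -> str:
    """SHA256 over serialized matrices + design; used for determinism checks."""
    h = hashlib.sha256()
    for ome in sorted(bundle.omes):
        h.update(bundle.omes[ome].values.to_csv().encode())
    h.update(bundle.design.to_csv(index=False).encode())
    return h.hexdigest()
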