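import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from acuteomix.core import AcuteomixError
from acuteomix.regnet import (
    circuits_to_edges,
    cluster_features,
    count_motifs,
    filter_validated_targets,
    infer_circuits,
    infer_edges,
    integrate,
    mfuzz_fuzzifier,
    network_motif_score,
    permutation_trim,
    prepare_regulators,
)


class TestPrepareRegulators:
    def _phospho(self, rng, missing_first=0.45):
        vals = pd.DataFrame(
            rng.normal(0, 1, (4, 20)),
            index=["TF1_S1", "TF1_S2", "TF2_S3", "G9_S4"],
            columns=[f"s{i}" for i in range(20)],
        )
        n_miss = int(missing_first * 20)
        vals.iloc[0, :n_miss] = np.nan
        return vals

    def test_heavy_missing_site_dropped(self, rng):
        vals = self._phospho(rng, 0.45)
        out = prepare_regulators(vals, ["TF1", "TF2"], {"TF1_S1": "TF1", "TF1_S2": "TF1", "TF2_S3": "TF2", "G9_S4": "G9"})
        assert "TF1_S1" not in out.index
        assert "G9_S4" not in out.index  # not on a TF
        assert not out.isna().any().any()

    def test_no_missing_identity(self, rng):
        vals = self._phospho(rng, 0.0)
        out = prepare_regulators(vals, ["TF1", "TF2"], {"TF1_S1": "TF1", "TF1_S2": "TF1", "TF2_S3": "TF2", "G9_S4": "G9"})
        pd.testing.assert_frame_equal(out, vals.loc[out.index])

    def test_mice_beats_column_mean(self, rng):
        # correlated sites: MICE exploits correlation; mean imputation cannot
        base = rng.normal(0, 1, 60)
        vals = pd.DataFrame(
            [base + rng.normal(0, 0.2, 60) for _ in range(6)],
            index=[f"TF1_S{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(60)],
        )
        truth = vals.copy()
        holes = rng.random(vals.shape) < 0.15
        vals = vals.mask(holes)
        out = prepare_regulators(
            vals, ["TF1"], {f"TF1_S{i}": "TF1" for i in range(6)}
        )
        mice_rmse = np.sqrt(np.nanmean((out.to_numpy()[holes] - truth.to_numpy()[holes]) ** 2))
        row_means = vals.mean(axis=1)
        mean_filled = vals.apply(lambda r: r.fillna(row_means[r.name]), axis=1)
        mean_rmse = np.sqrt(np.nanmean((mean_filled.to_numpy()[holes] - truth.to_numpy()[holes]) ** 2))
        assert mice_rmse < mean_rmse

    def test_empty_filter_rejected(self, rng):
        vals = self._phospho(rng)
        with pytest.raises(AcuteomixError):
            prepare_regulators(vals, ["TFX"], {})


class TestClustering:
    def test_fuzzifier_formula_direct_evaluation(self):
        n, d = 100, 8
        expected = (
            1
            + (1418 / n + 22.05) * d**-2
            + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
        )
        assert mfuzz_fuzzifier(n, d) == pytest.approx(expected, rel=1e-12)

    def test_two_blobs_confident_membership(self, rng):
        a = rng.normal(0, 0.2, (25, 6)) + 3
        b = rng.normal(0, 0.2, (25, 6)) - 3
        profiles = pd.DataFrame(
            np.vstack([a, b]), index=[f"f{i}" for i in range(50)]
        )
        res = cluster_features(profiles, c_range=[2], seed=0)
        mx = res.memberships.to_numpy().max(axis=1)
        assert (mx > 0.95).all()
        labels = res.hard_labels
        assert labels.iloc[:25].nunique() == 1 and labels.iloc[25:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_memberships_sum_to_one(self, rng):
        profiles = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        res = cluster_features(profiles, c_range=[2, 3, 4], seed=1)
        np.testing.assert_allclose(res.memberships.sum(axis=1).to_numpy(), 1.0, atol=1e-9)

    def test_bad_c_range_rejected(self, rng):
        profiles = pd.DataFrame(rng.normal(0, 1, (10, 4)))
        with pytest.raises(AcuteomixError):
            cluster_features(profiles, c_range=[1], seed=0)

    def test_row_scaling_uses_two_zero_columns(self, rng):
        # the SD denominator includes two appended zeros (ddof=1)
        profiles = pd.DataFrame(rng.normal(0, 1, (20, 6)))
        row = profiles.iloc[0].to_numpy()
        sd = np.std(np.concatenate([row, [0.0, 0.0]]), ddof=1)
        assert sd != np.std(row, ddof=1)  # the appended zeros matter


class TestInferEdges:
    def test_linear_truth_top_importance(self, rng):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, (5, 50))
            y = 2 * x[0] + r.normal(0, 0.3, 50)
            regulators = pd.DataFrame(x, index=[f"TF{i}_S1" for i in range(5)],
                                      columns=[f"s{j}" for j in range(50)])
            targets = pd.DataFrame([y], index=["G1"], columns=regulators.columns)
            edges = infer_edges(regulators, targets, n_trees=50, seed=seed)
            top = edges.sort_values("weight").iloc[-1]["regulator"]
            hits += top == "TF0_S1"
        assert hits >= 95

    def test_null_target_importances_low(self, rng):
        x = rng.normal(0, 1, (5, 60))
        regulators = pd.DataFrame(x, index=[f"TF{i}_S1" for i in range(5)],
                                  columns=[f"s{j}" for j in range(60)])
        y_signal = 2 * x[0] + rng.normal(0, 0.3, 60)
        y_null = rng.normal(0, 1, 60)
        targets = pd.DataFrame([y_signal, y_null], index=["G1", "G2"], columns=regulators.columns)
        edges = infer_edges(regulators, targets, n_trees=100, seed=0)
        signal_w = edges[(edges.target == "G1") & (edges.regulator == "TF0_S1")]["weight"].iloc[0]
        null_max = edges[edges.target == "G2"]["weight"].max()
        assert null_max < signal_w

    def test_importances_nonnegative_finite(self, rng):
        regulators = pd.DataFrame(rng.normal(0, 1, (4, 30)), index=[f"TF{i}_S1" for i in range(4)])
        targets = pd.DataFrame(rng.normal(0, 1, (3, 30)), index=["G1", "G2", "G3"])
        edges = infer_edges(regulators, targets, n_trees=20, seed=1)
        w = edges["weight"].to_numpy()
        assert np.isfinite(w).all() and (w >= 0).all()

    def test_own_gene_site_excluded(self, rng):
        regulators = pd.DataFrame(rng.normal(0, 1, (2, 30)), index=["TF1_S1", "TF2_S1"])
        targets = pd.DataFrame(rng.normal(0, 1, (1, 30)), index=["TF1"])
        edges = infer_edges(
            regulators, targets,
            site_gene={"TF1_S1": "TF1", "TF2_S1": "TF2"}, seed=0, n_trees=10,
        )
        assert "TF1_S1" not in set(edges["regulator"])

    def test_mismatched_columns_rejected(self, rng):
        regulators = pd.DataFrame(rng.normal(0, 1, (2, 5)), columns=list("abcde"))
        targets = pd.DataFrame(rng.normal(0, 1, (2, 5)), columns=list("fghij"))
        with pytest.raises(AcuteomixError):
            infer_edges(regulators, targets)


class TestPermutationTrim:
    def test_defaults(self):
        import inspect

        sig = inspect.signature(permutation_trim)
        assert sig.parameters["n_perm"].default == 100
        assert sig.parameters["weight_floor"].default == 0.1

    def test_retained_edges_above_floor_and_nonzero_p(self, rng):
        x = rng.normal(0, 1, (4, 50))
        regulators = pd.DataFrame(x, index=[f"TF{i}_S1" for i in range(4)],
                                  columns=[f"s{j}" for j in range(50)])
        y = 3 * x[0] + rng.normal(0, 0.2, 50)
        targets = pd.DataFrame([y], index=["G1"], columns=regulators.columns)
        kept = permutation_trim(regulators, targets, n_perm=20, n_trees=30, seed=0)
        assert (kept["weight"] > 0.1).all()
        assert (kept["p"] > 0).all() and (kept["p"] <= 1).all()

    def test_null_calibration_scaled(self, rng):
        regulators = pd.DataFrame(rng.normal(0, 1, (5, 40)),
                                  index=[f"TF{i}_S1" for i in range(5)],
                                  columns=[f"s{j}" for j in range(40)])
        targets = pd.DataFrame(rng.normal(0, 1, (15, 40)),
                               index=[f"G{i}" for i in range(15)],
                               columns=regulators.columns)
        kept = permutation_trim(regulators, targets, n_perm=20, n_trees=30, seed=1)
        frac = len(kept) / (5 * 15)
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 75)

    def test_zero_perm_rejected(self, rng):
        regulators = pd.DataFrame(rng.normal(0, 1, (2, 10)))
        with pytest.raises(AcuteomixError):
            permutation_trim(regulators, regulators, n_perm=0)


class TestCircuits:
    def _setup(self, rng, n_samp=40):
        samples = [f"s{i}" for i in range(n_samp)]
        latent = rng.normal(0, 1, n_samp)
        tf_act = latent + rng.normal(0, 0.4, n_samp)
        peak = latent + rng.normal(0, 0.4, n_samp)
        gene = latent + rng.normal(0, 0.4, n_samp)
        atac_values = pd.DataFrame(
            [peak, rng.normal(0, 1, n_samp), rng.normal(0, 1, n_samp)],
            index=["pk1", "pk2", "pk3"], columns=samples,
        )
        rna_values = pd.DataFrame(
            [gene, rng.normal(0, 1, n_samp), tf_act],
            index=["G1", "G2", "TF1"], columns=samples,
        )
        atac_results = pd.DataFrame(
            {"feature": ["pk1", "pk2", "pk3"], "p": [0.001, 0.01, 0.001]}
        )
        rna_results = pd.DataFrame({"feature": ["G1", "G2"], "adj_p": [0.01, 0.01]})
        peak_tss = pd.DataFrame(
            {
                "peak": ["pk1", "pk2", "pk3"],
                "gene": ["G1", "G1", "G2"],
                "tss_distance": [5_000, 50_000, 150_000],
            }
        )
        occ = pd.DataFrame(
            {"TF1": [1, 1, 1]}, index=["pk1", "pk2", "pk3"]
        )
        return atac_results, atac_values, rna_results, rna_values, peak_tss, occ

    def test_far_peak_and_weak_peak_excluded(self, rng):
        args = self._setup(rng)
        out = infer_circuits(*args, n_perm=200, seed=0)
        # pk3 is 150 kb away; pk2 has raw p = 0.01 >= 0.005
        assert "pk3" not in set(out["peak"])
        assert "pk2" not in set(out["peak"])

    def test_planted_circuit_recovered(self, rng):
        args = self._setup(rng)
        out = infer_circuits(*args, n_perm=200, seed=0)
        assert ("TF1", "pk1", "G1") in set(zip(out["tf"], out["peak"], out["gene"]))

    def test_circuit_edges_provenance(self, rng):
        args = self._setup(rng)
        out = infer_circuits(*args, n_perm=100, seed=0)
        edges = circuits_to_edges(out)
        assert (edges["provenance"] == "circuit-linking").all()


class TestIntegrate:
    def _edges(self, reg, tgt, prov, modality="EE"):
        return pd.DataFrame(
            [{"regulator": reg, "target": tgt, "weight": 1.0,
              "modality": modality, "provenance": prov}]
        )

    def test_same_edge_reported_twice(self):
        a = self._edges("TF1_S1", "G1", "edge-inference")
        b = self._edges("TF1_S1", "G1", "circuit-linking", "circuit")
        combined = integrate(a, b)
        assert len(combined) == 2
        assert set(combined["provenance"]) == {"edge-inference", "circuit-linking"}

    def test_disjoint_sizes_add(self):
        a = self._edges("TF1_S1", "G1", "edge-inference")
        b = self._edges("TF2_S1", "G2", "edge-inference")
        assert len(integrate(a, b)) == 2

    def test_order_invariant_up_to_record_order(self):
        a = self._edges("TF1_S1", "G1", "edge-inference")
        b = self._edges("TF2_S1", "G2", "circuit-linking")
        ab = integrate(a, b).sort_values(["regulator"]).reset_index(drop=True)
        ba = integrate(b, a).sort_values(["regulator"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(ab, ba)


def brute_force_motifs(edges: pd.DataFrame):
    """Exhaustive enumeration over node triples/quadruples (oracle)."""
    adj = set(zip(edges["regulator"], edges["target"]))
    nodes = sorted({n for e in adj for n in e})
    counts = {v: {"ffl": 0, "chain3": 0, "diamond": 0} for v in nodes}
    for a, b, c in itertools.permutations(nodes, 3):
        if (a, b) in adj and (a, c) in adj and (b, c) in adj:
            for v in (a, b, c):
                counts[v]["ffl"] += 1
        if (a, b) in adj and (b, c) in adj:
            for v in (a, b, c):
                counts[v]["chain3"] += 1
    for a, d in itertools.permutations(nodes, 2):
        for b, c in itertools.combinations(nodes, 2):
            if len({a, b, c, d}) < 4:
                continue
            if (a, b) in adj and (a, c) in adj and (b, d) in adj and (c, d) in adj:
                for v in (a, b, c, d):
                    counts[v]["diamond"] += 1
    return pd.DataFrame.from_dict(counts, orient="index").sort_index()


def _edge_df(pairs):
    return pd.DataFrame(
        [{"regulator": a, "target": b, "weight": 1.0, "modality": "EE",
          "provenance": "edge-inference"} for a, b in pairs]
    )


class TestMotifs:
    def test_triangle_cycle(self):
        edges = _edge_df([("A", "B"), ("B", "C"), ("C", "A")])
        counts = count_motifs(edges)
        assert (counts["ffl"] == 0).all()
        assert (counts["chain3"] == 3).all()

    def test_minimal_ffl(self):
        edges = _edge_df([("A", "B"), ("A", "C"), ("B", "C")])
        counts = count_motifs(edges)
        assert counts.loc["A", "ffl"] == 1
        assert counts["ffl"].sum() == 3  # one instance, three participants

    def test_minimal_diamond(self):
        edges = _edge_df([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
        counts = count_motifs(edges)
        assert (counts["diamond"] == 1).all()

    def test_matches_brute_force_on_random_digraphs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            nodes = [f"n{i}" for i in range(8)]
            pairs = [
                (a, b)
                for a in nodes
                for b in nodes
                if a != b and rng.random() < 0.25
            ]
            if not pairs:
                continue
            edges = _edge_df(pairs)
            got = count_motifs(edges)
            expected = brute_force_motifs(edges)
            pd.testing.assert_frame_equal(
                got, expected, check_names=False, check_dtype=False
            )

    def test_self_loop_rejected(self):
        with pytest.raises(AcuteomixError):
            count_motifs(_edge_df([("A", "A")]))


class TestNms:
    def test_isolated_node_zero(self):
        edges = _edge_df([("A", "B"), ("A", "C"), ("B", "C"), ("D", "E")])
        counts = count_motifs(edges)
        nms = network_motif_score(counts)
        assert nms["E"] == 0.0

    def test_maximal_node_scores_three(self):
        # star-of-FFLs: make one node dominate every motif type
        edges = _edge_df(
            [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D"), ("C", "E"), ("E", "F")]
        )
        counts = count_motifs(edges)
        nms = network_motif_score(counts)
        best = counts.idxmax()
        if len(set(best)) == 1:  # a single node tops all three types
            assert nms[best.iloc[0]] == pytest.approx(3.0)
        assert (nms <= 3.0 + 1e-12).all()

    def test_relabeling_invariance(self, rng):
        nodes = [f"n{i}" for i in range(7)]
        pairs = [(a, b) for a in nodes for b in nodes if a != b and rng.random() < 0.3]
        edges = _edge_df(pairs)
        nms = network_motif_score(count_motifs(edges))
        mapping = {n: f"x{9 - i}" for i, n in enumerate(nodes)}
        edges2 = _edge_df([(mapping[a], mapping[b]) for a, b in pairs])
        nms2 = network_motif_score(count_motifs(edges2))
        for n in nms.index:
            assert nms[n] == pytest.approx(nms2[mapping[n]])

    def test_empty_graph_empty_table(self):
        counts = count_motifs(_edge_df([]))
        assert len(network_motif_score(counts)) == 0


class TestValidatedTargets:
    def test_fraction_retained(self):
        edges = _edge_df([("MEF2A", f"G{i}") for i in range(10)])
        kept = filter_validated_targets(edges, "MEF2A", [f"G{i}" for i in range(3)])
        assert len(kept) == 3
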