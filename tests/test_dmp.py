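import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spatialmeth as sm
from spatialmeth.annotation import ProbeAnnotation
from spatialmeth.cluster import ClusterAssignment
from spatialmeth.dmp import pairwise_dmp, summarize_genes, venn_overlap
from spatialmeth.matrices import BetaMatrix


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up q values: q_i = min over j>=rank(i) of m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def welch_by_formula(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def _assignment(labels):
    return ClusterAssignment(labels=labels, k=len(set(labels.values())), method={})


def _beta_matrix(rows, samples):
    return BetaMatrix(pd.DataFrame(rows, index=samples).T)


class TestPairwiseDMP:
    def test_welch_t_and_bh_match_direct_formulas(self):
        rows = {
            "cg1": [0.10, 0.20, 0.15, 0.70, 0.80, 0.75],
            "cg2": [0.50, 0.52, 0.48, 0.49, 0.51, 0.50],
            "cg3": [0.30, 0.35, 0.32, 0.45, 0.40, 0.42],
        }
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        beta = _beta_matrix(rows, samples)
        assignment = _assignment({s: 1 if s.startswith("a") else 2 for s in samples})
        out = pairwise_dmp(beta, assignment, (1, 2), space="beta").set_index("probe_id")

        ps = []
        for probe, vals in rows.items():
            a, b = np.array(vals[:3]), np.array(vals[3:])
            t, p = welch_by_formula(a, b)
            assert out.loc[probe, "statistic"] == pytest.approx(t, rel=1e-9)
            assert out.loc[probe, "p_value"] == pytest.approx(p, rel=1e-9)
            assert out.loc[probe, "delta_beta"] == pytest.approx(a.mean() - b.mean())
            ps.append(p)
        np.testing.assert_allclose(
            out["q_value"].to_numpy(), brute_force_bh(np.array(ps)), rtol=1e-12
        )

    def test_identical_clusters_yield_no_signal(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0.1, 0.9, 100)
        beta = BetaMatrix(
            pd.DataFrame({s: col for s in ["a1", "a2", "b1", "b2"]},
                         index=[f"cg{i}" for i in range(100)])
        )
        assignment = _assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        out = pairwise_dmp(beta, assignment, (1, 2))
        assert (out["delta_beta"] == 0).all()
        assert not out["significant"].any()

    def test_singleton_cluster_uses_floored_z(self):
        rows = {"cg1": [0.9, 0.30, 0.32, 0.31, 0.29]}
        samples = ["lone", "b1", "b2", "b3", "b4"]
        beta = _beta_matrix(rows, samples)
        assignment = _assignment({"lone": 1, "b1": 2, "b2": 2, "b3": 2, "b4": 2})
        out = pairwise_dmp(beta, assignment, (1, 2), space="beta", sd_floor=0.1)
        group = np.array(rows["cg1"][1:])
        z = (0.9 - group.mean()) / max(group.std(ddof=1), 0.1)  # floor binds here
        assert out.loc[0, "statistic"] == pytest.approx(z)
        assert out.loc[0, "p_value"] == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert out.loc[0, "method"] == "z_vs_cluster"

    def test_flipping_comparison_flips_directions_not_q(self):
        rng = np.random.default_rng(2)
        beta = BetaMatrix(
            pd.DataFrame(
                rng.uniform(0.1, 0.9, size=(50, 6)),
                index=[f"cg{i}" for i in range(50)],
                columns=["a1", "a2", "a3", "b1", "b2", "b3"],
            )
        )
        assignment = _assignment(
            {"a1": 1, "a2": 1, "a3": 1, "b1": 2, "b2": 2, "b3": 2}
        )
        fwd = pairwise_dmp(beta, assignment, (1, 2))
        rev = pairwise_dmp(beta, assignment, (2, 1))
        np.testing.assert_allclose(fwd["q_value"], rev["q_value"], rtol=1e-12)
        np.testing.assert_allclose(fwd["delta_beta"], -rev["delta_beta"], rtol=1e-12)
        nonzero = fwd["delta_beta"] != 0
        assert (
            fwd.loc[nonzero, "direction"].to_numpy()
            != rev.loc[nonzero, "direction"].to_numpy()
        ).all()

    def test_empty_cluster_rejected(self):
        beta = _beta_matrix({"cg1": [0.1, 0.2]}, ["a", "b"])
        assignment = _assignment({"a": 1, "b": 2})
        with pytest.raises(ValueError, match="cluster 3 not in assignment"):
            pairwise_dmp(beta, assignment, (1, 3))

    def test_planted_drift_probes_found_with_controlled_fdp(self):
        """Welch comparison of the two recurrent clones where drift is the
        only planted between-clone signal (full purity, uniform MGMT state):
        most drift probes are detected and the false-discovery proportion
        against the planted truth stays at the nominal target."""
        from dataclasses import replace

        uniform_mgmt = {"C1": "methylated", "C2": "methylated", "C3": "methylated"}
        fdps, recalls = [], []
        for seed in range(5):
            cfg = replace(
                sm.default_cohort_config(seed=100 + seed, n_probes=10_000),
                purity=1.0,
                mgmt_state=uniform_mgmt,
            )
            beta, _, _, _, truth = sm.simulate_cohort(cfg)
            assignment = _assignment(truth.clone_tree.partition())
            out = pairwise_dmp(beta, assignment, (2, 3))
            sig = set(out.loc[out["significant"], "probe_id"])
            drift = set(truth.drift_probes)
            # drift magnitudes are Gaussian around zero and extreme-beta
            # probes saturate, so score recall on probes whose noiseless
            # clone difference on the observed (offset-M) scale is clearly
            # detectable at this group size
            base_m = np.log2(truth.baseline_beta.loc[truth.drift_probes])
            base_m -= np.log2(1 - truth.baseline_beta.loc[truth.drift_probes])

            def observable_m(shift):
                b = 2.0 ** (base_m + shift) / (1 + 2.0 ** (base_m + shift))
                return np.log2((b + 0.01) / (1 - b + 0.01))

            delta = (
                observable_m(truth.drift_shifts["C2"])
                - observable_m(truth.drift_shifts["C3"])
            ).abs()
            strong = set(delta.index[delta > 2.5])
            fdps.append(len(sig - drift) / max(len(sig), 1))
            recalls.append(len(sig & strong) / len(strong))
        assert np.mean(recalls) > 0.9
        assert np.mean(fdps) <= 0.01

    def test_null_simulation_is_clean(self):
        """With no drift and no other planted between-clone differences the
        fraction of discoveries stays at the FDR target."""
        from dataclasses import replace

        uniform_mgmt = {"C1": "methylated", "C2": "methylated", "C3": "methylated"}
        fracs = []
        for seed in range(20):
            cfg = replace(
                sm.default_cohort_config(seed=200 + seed, n_probes=3000),
                fraction_drift_probes=0.0,
                purity=1.0,
                mgmt_state=uniform_mgmt,
            )
            beta, _, _, _, truth = sm.simulate_cohort(cfg)
            assignment = _assignment(truth.clone_tree.partition())
            out = pairwise_dmp(beta, assignment, (2, 3))
            fracs.append(out["significant"].mean())
        assert np.mean(fracs) <= 0.01


def _annotation(genes: dict[str, str], classes: dict[str, str] | None = None):
    probes = list(genes)
    classes = classes or {}
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probes,
                "chrom": "1",
                "pos": np.arange(1, len(probes) + 1) * 100,
                "gene": [genes[p] for p in probes],
                "tss": 1.0,
                "strand": "+",
                "region_class": [classes.get(p, "gene_body") for p in probes],
                "dist_to_tss": 0.0,
            }
        )
    )


def _records(rows):
    df = pd.DataFrame(rows, columns=["probe_id", "delta_beta", "significant"])
    df["comparison"] = "C1_vs_C2"
    return df


class TestSummarizeGenes:
    def test_gene_means_and_ranking_match_hand_computation(self):
        ann = _annotation(
            {"p1": "GA", "p2": "GA", "p3": "GB", "p4": "GC", "p5": "GC", "p6": "GD"}
        )
        rec = _records(
            [
                ("p1", 0.30, True),
                ("p2", 0.10, True),   # GA mean +0.20
                ("p3", 0.25, True),   # GB mean +0.25
                ("p4", -0.40, True),
                ("p5", -0.20, True),  # GC mean -0.30
                ("p6", -0.05, False), # GD has no significant probe: excluded
            ]
        )
        hyper, hypo = summarize_genes(rec, ann, top_n=50)
        assert hyper["gene"].tolist() == ["GB", "GA"]
        assert hyper["mean_delta_beta"].tolist() == pytest.approx([0.25, 0.20])
        assert hypo["gene"].tolist() == ["GC"]
        assert "GD" not in set(hyper["gene"]) | set(hypo["gene"])

    def test_intergenic_probes_never_contribute(self):
        ann = _annotation({"p1": "GA", "p2": ""}, {"p2": "intergenic"})
        rec = _records([("p1", 0.2, True), ("p2", 0.9, True)])
        hyper, _ = summarize_genes(rec, ann)
        assert hyper["gene"].tolist() == ["GA"]

    @pytest.mark.parametrize(("available", "expected"), [(500, 50), (10, 10)])
    def test_truncation_to_top_n(self, available, expected):
        genes = {f"p{i}": f"G{i:04d}" for i in range(available)}
        ann = _annotation(genes)
        rng = np.random.default_rng(0)
        rec = _records(
            [(f"p{i}", float(rng.uniform(0.05, 0.5)), True) for i in range(available)]
        )
        hyper, hypo = summarize_genes(rec, ann, top_n=50)
        assert len(hyper) == expected
        assert len(hypo) == 0


class TestVennOverlap:
    def test_identical_lists_fill_triple_intersection(self):
        lists = {"A": {"g1", "g2"}, "B": {"g1", "g2"}, "C": {"g1", "g2"}}
        counts = venn_overlap(lists)
        assert counts["A&B&C"] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_lists_populate_unique_regions_only(self):
        counts = venn_overlap({"A": {"g1"}, "B": {"g2"}, "C": {"g3"}})
        assert (counts["A"], counts["B"], counts["C"]) == (1, 1, 1)
        assert counts["A&B"] == counts["A&C"] == counts["B&C"] == counts["A&B&C"] == 0

    def test_pairwise_chain_example(self):
        counts = venn_overlap({"L1": {"A", "B"}, "L2": {"B", "C"}, "L3": {"C", "D"}})
        assert counts == {
            "L1": 1, "L2": 0, "L3": 1,
            "L1&L2": 1, "L1&L3": 0, "L2&L3": 1,
            "L1&L2&L3": 0,
        }
        assert sum(counts.values()) == 4  # |union| = {A,B,C,D}
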