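import numpy as np
import pandas as pd
import pytest

import spatialmeth as sm
from spatialmeth.cluster import ClusterAssignment
from spatialmeth.deconv import call_mgmt, compare_fractions, estimate_fractions
from spatialmeth.matrices import BetaMatrix


def _assignment(labels):
    return ClusterAssignment(labels=labels, k=len(set(labels.values())), method={})


def _signature(seed=0, n_probes=60, types=("tumor", "endothelial", "fibroblast")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0.02, 0.98, size=(n_probes, len(types))),
        index=[f"cg{i:04d}" for i in range(n_probes)],
        columns=list(types),
    )


class TestCallMGMT:
    def test_fully_methylated_promoter(self):
        beta = BetaMatrix(pd.DataFrame({"s1": [1.0, 1.0]}, index=["cgA", "cgB"]))
        out = call_mgmt(beta, ["cgA", "cgB"])
        assert out.loc[0, "status"] == "methylated"

    def test_mean_exactly_at_threshold_is_methylated(self):
        beta = BetaMatrix(pd.DataFrame({"s1": [0.3, 0.4]}, index=["cgA", "cgB"]))
        out = call_mgmt(beta, ["cgA", "cgB"], threshold=0.35)
        assert out.loc[0, "mean_promoter_beta"] == pytest.approx(0.35)
        assert out.loc[0, "status"] == "methylated"

    def test_absent_probes_skipped_but_all_absent_rejected(self):
        beta = BetaMatrix(pd.DataFrame({"s1": [0.9]}, index=["cgA"]))
        out = call_mgmt(beta, ["cgA", "cgMissing"])
        assert out.loc[0, "n_probes"] == 1
        with pytest.raises(ValueError, match="none of the listed"):
            call_mgmt(beta, ["cgMissing"])

    def test_call_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        beta = BetaMatrix(
            pd.DataFrame(
                rng.uniform(0, 1, size=(5, 8)),
                index=[f"cg{i}" for i in range(5)],
                columns=[f"s{i}" for i in range(8)],
            )
        )
        previous = None
        for thr in np.linspace(0.0, 1.0, 21):
            called = set(
                call_mgmt(beta, beta.probe_ids, threshold=thr)
                .query("status == 'methylated'")["sample_id"]
            )
            if previous is not None:
                assert called <= previous  # raising threshold only removes calls
            previous = called

    def test_default_cohort_c3_lost_promoter_methylation(self, default_cohort):
        beta, _, _, _, truth = default_cohort
        out = call_mgmt(beta, truth.mgmt_probes).set_index("sample_id")
        for s, state in truth.mgmt_state.items():
            assert out.loc[s, "status"] == state
        unmeth = {s for s, st in truth.mgmt_state.items() if st == "unmethylated"}
        assert unmeth == {"s5", "s6", "s7", "s8"}


class TestEstimateFractions:
    def test_pure_signature_column_recovered(self):
        sig = _signature()
        beta = BetaMatrix(pd.DataFrame({"s1": sig["fibroblast"]}))
        out = estimate_fractions(beta, sig)
        assert out.loc["s1", "fibroblast"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc["s1", "tumor"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["s1", "residual"] <= 1e-9

    def test_noiseless_mixture_recovered_to_1e6(self):
        sig = _signature(seed=1)
        f_true = np.array([0.5, 0.3, 0.2])
        beta = BetaMatrix(pd.DataFrame({"s1": sig.to_numpy() @ f_true}, index=sig.index))
        out = estimate_fractions(beta, sig)
        np.testing.assert_allclose(
            out.loc["s1", list(sig.columns)].to_numpy(), f_true, atol=1e-6
        )
        assert out.loc["s1", "residual"] <= 1e-9

    def test_fractions_sum_to_one_and_nonnegative(self):
        sig = _signature(seed=2)
        rng = np.random.default_rng(4)
        beta = BetaMatrix(
            pd.DataFrame(
                rng.uniform(0, 1, size=(len(sig), 3)),
                index=sig.index,
                columns=["s1", "s2", "s3"],
            )
        )
        out = estimate_fractions(beta, sig)
        fr = out[list(sig.columns)].to_numpy()
        assert (fr >= -1e-12).all()
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self):
        sig = _signature(seed=5)
        rng = np.random.default_rng(6)
        beta = BetaMatrix(
            pd.DataFrame({"s1": rng.uniform(0, 1, len(sig))}, index=sig.index)
        )
        base = estimate_fractions(beta, sig)
        permuted_cols = ["fibroblast", "tumor", "endothelial"]
        perm = estimate_fractions(beta, sig[permuted_cols])
        for ct in sig.columns:
            assert perm.loc["s1", ct] == pytest.approx(base.loc["s1", ct], abs=1e-9)

    def test_rank_deficient_signature_warns(self):
        sig = _signature(seed=7)
        sig["fibroblast"] = sig["tumor"]  # duplicate column
        beta = BetaMatrix(pd.DataFrame({"s1": sig["tumor"]}))
        with pytest.warns(UserWarning, match="rank-deficient"):
            estimate_fractions(beta, sig)

    def test_planted_fractions_recovered_on_simulated_cohort(self, default_cohort):
        beta, _, _, _, truth = default_cohort
        out = estimate_fractions(beta, truth.signature)
        est = out[truth.cell_fractions.columns].loc[truth.cell_fractions.index]
        mae = (est - truth.cell_fractions).abs().mean(axis=0)
        assert (mae <= 0.05).all()


class TestCompareFractions:
    def test_constant_fractions_give_p_one(self):
        fr = pd.DataFrame(
            {"tumor": [0.7] * 4, "fibroblast": [0.3] * 4},
            index=["a1", "a2", "b1", "b2"],
        )
        assignment = _assignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        out = compare_fractions(fr, assignment).set_index("cell_type")
        assert (out["p_value"] == 1.0).all()

    def test_two_cluster_exact_mann_whitney_matches_enumeration(self):
        # x = [1,2,3] all below y = [4,5,6]: U = 0; exact two-sided
        # p = 2 * P(U <= 0) = 2 * 1/C(6,3) = 2/20 = 0.1
        fr = pd.DataFrame(
            {"tumor": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]},
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        fr["other"] = 1 - fr["tumor"]
        assignment = _assignment(
            {"a1": 1, "a2": 1, "a3": 1, "b1": 2, "b2": 2, "b3": 2}
        )
        out = compare_fractions(fr, assignment).set_index("cell_type")
        assert out.loc["tumor", "p_value"] == pytest.approx(0.1)
        assert out.loc["tumor", "test"] == "mannwhitney_u"

    def test_planted_fibroblast_enrichment_detected(self):
        """With only fibroblast admixture tilted in one clone, fibroblast
        attains the smallest between-cluster p among the stromal signatures
        in most seeds (fractions are compositional, so the complementary
        types also shift and can tie in any single run), and the constant
        tumor purity never does."""
        from dataclasses import replace

        stromal = ["endothelial", "fibroblast", "immune"]
        fibro_wins, tumor_wins = 0, 0
        for seed in range(1, 11):
            cfg = replace(
                sm.default_cohort_config(seed=seed, n_probes=5000),
                stromal_weights={
                    "C1": (1.0, 1.0, 1.0),
                    "C2": (1.0, 1.0, 1.0),
                    "C3": (1.0, 3.0, 1.0),
                },
                stromal_concentration=15.0,
            )
            beta, _, _, _, truth = sm.simulate_cohort(cfg)
            fractions = estimate_fractions(beta, truth.signature)
            assignment = _assignment(truth.clone_tree.partition())
            out = compare_fractions(fractions, assignment).set_index("cell_type")
            fibro_wins += int(
                out.loc["fibroblast", "p_value"] == out.loc[stromal, "p_value"].min()
            )
            tumor_wins += int(
                out.loc["tumor", "p_value"] < out.loc["fibroblast", "p_value"]
            )
        assert fibro_wins >= 7
        assert tumor_wins <= 2

    def test_requires_two_clusters(self):
        fr = pd.DataFrame({"tumor": [0.5, 0.6]}, index=["a", "b"])
        with pytest.raises(ValueError, match="2 clusters"):
            compare_fractions(fr, _assignment({"a": 1, "b": 1}))
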