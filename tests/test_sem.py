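"""Piecewise SEM: d-separation basis sets (with a brute-force oracle),
Fisher's C, stratified resampling, mediation rules and recovery behaviour."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import befmeta as b
from befmeta.sem import SEMResult
from conftest import null_truth


def brute_force_claims(edges, exogenous):
    """Independent enumerator of the d-separation basis set.

    For every missing edge between nodes that are not both exogenous, emit
    (x, y | parents of y) with y the later node in a topological order.
    """
    nodes = sorted({n for e in edges for n in e})
    parents = {n: sorted({a for a, c in edges if c == n}) for n in nodes}
    # Kahn's algorithm with lexicographic tie-break
    remaining = {n: set(parents[n]) for n in nodes}
    order = []
    while remaining:
        ready = sorted(n for n, ps in remaining.items() if not ps)
        order.append(ready[0])
        del remaining[ready[0]]
        for ps in remaining.values():
            ps.discard(order[-1])
    pos = {n: i for i, n in enumerate(order)}
    claims = []
    adjacent = {frozenset(e) for e in edges}
    for i, a in enumerate(nodes):
        for c in nodes[i + 1:]:
            if frozenset((a, c)) in adjacent:
                continue
            if a in exogenous and c in exogenous:
                continue
            x, y = (a, c) if pos[a] < pos[c] else (c, a)
            if y in exogenous:
                x, y = y, x
            claims.append((x, y, tuple(sorted(set(parents[y]) - {x}))))
    return sorted(claims)


FULL_EDGES = [
    ("intensity", "zB"), ("study_type", "zB"), ("taxon_group", "zB"),
    ("zB", "zLD"), ("intensity", "zLD"), ("study_type", "zLD"),
]
EXO = {"intensity", "study_type", "taxon_group", "diversity_metric"}


class TestBasisSet:
    def test_full_graph_single_claim(self):
        claims = b.basis_set(b.full_dag("abundance"))
        assert claims == [
            ("taxon_group", "zLD", ("intensity", "study_type", "zB"))
        ]
        assert claims == brute_force_claims(FULL_EDGES, EXO)

    def test_reduced_graph_two_claims(self):
        claims = b.basis_set(b.reduced_dag("abundance"))
        edges = [e for e in FULL_EDGES if e != ("zB", "zLD")]
        assert claims == brute_force_claims(edges, EXO)
        assert ("zB", "zLD", ("intensity", "study_type")) in claims
        assert ("taxon_group", "zLD", ("intensity", "study_type")) in claims
        assert len(claims) == 2

    def test_diversity_graph_adds_metric_claim(self):
        claims = b.basis_set(b.full_dag("diversity"))
        edges = FULL_EDGES + [("diversity_metric", "zB")]
        assert claims == brute_force_claims(edges, EXO)
        assert len(claims) == 2

    def test_saturated_graph_empty_basis(self):
        g = b.full_dag("abundance")
        g.add_edge("taxon_group", "zLD")
        assert b.basis_set(g) == []
        assert b.fishers_c([])[0] == 0.0

    def test_cyclic_graph_rejected(self):
        g = b.full_dag("abundance")
        g.add_edge("zLD", "intensity")
        with pytest.raises(ValueError, match="acyclic"):
            b.basis_set(g)


class TestFishersC:
    def test_worked_examples(self):
        c, df, p = b.fishers_c([1.0])
        assert (c, df, p) == (0.0, 2, 1.0)
        c, df, p = b.fishers_c([0.05, 0.05])
        assert c == pytest.approx(-4 * math.log(0.05), abs=1e-9)
        assert c == pytest.approx(11.983, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_monotone_nonincreasing_in_each_p(self):
        base = b.fishers_c([0.5, 0.5])[0]
        assert b.fishers_c([0.4, 0.5])[0] > base
        assert b.fishers_c([0.5, 0.6])[0] < base

    def test_zero_p_gives_infinite_c(self):
        c, df, p = b.fishers_c([0.0, 0.5])
        assert math.isinf(c) and p == 0.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            b.fishers_c([1.2])

    def test_chi_square_calibration(self):
        # C over k independent uniforms follows chi2(2k)
        rng = np.random.default_rng(17)
        k = 3
        c = -2.0 * np.log(rng.random((4000, k))).sum(axis=1)
        assert stats.kstest(c, "chi2", args=(2 * k,)).pvalue > 0.01


def make_pairs(frame, family="abundance"):
    return b.pair_effects(frame, response_family=family)


class TestStratifiedResample:
    def test_identity_without_duplicates(self):
        cfg = null_truth(n_studies=12, dup_range=(1, 1), seed=3)
        eff = b.generate_effect_table(cfg).effects
        pairs = make_pairs(eff)
        t1 = b.stratified_resample(pairs, seed=1)
        t2 = b.stratified_resample(pairs, seed=99)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == len(pairs)

    def test_uniform_selection(self):
        pair = b.PairedEffect(
            link_key="l", decomposition={"obs_id": "d", "z": 0.1, "var_z": 0.05},
            biodiversity=[
                {"obs_id": f"b{i}", "z": 0.1 * i, "var_z": 0.05,
                 "taxon_group": "animal", "diversity_metric": "not_applicable"}
                for i in range(3)
            ],
            intensity=0.5, case_study_id="s", driver="stressor",
            study_type="experimental",
        )
        counts = {f"b{i}": 0 for i in range(3)}
        for seed in range(3000):
            t = b.stratified_resample([pair], seed=seed)
            counts[t["obs_id_b"].iloc[0]] += 1
        for v in counts.values():
            assert v / 3000 == pytest.approx(1 / 3, abs=0.03)

    def test_seed_determinism(self, effects_dataset):
        pairs = make_pairs(effects_dataset.effects)
        pd.testing.assert_frame_equal(
            b.stratified_resample(pairs, seed=7), b.stratified_resample(pairs, seed=7)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            b.stratified_resample([], seed=0)


class TestMediationRule:
    def _res(self, c_p, aic):
        return SEMResult(
            paths=pd.DataFrame(), fisher_C=0.0, C_df=2, C_p=c_p, AIC=aic,
            indirect_effect=0.1, direct_effect=0.2, n_iterations=10, n_failed=0,
            seed=0, data_hash="h", dataset_kind="abundance",
        )

    def test_poor_reduced_fit_and_worse_aic_supports(self):
        rep = b.mediation_test(self._res(0.2, 100.0), self._res(0.01, 105.0))
        assert rep.supported and not rep.criterion_conflict

    def test_good_reduced_fit_never_supports(self):
        rep = b.mediation_test(self._res(0.2, 100.0), self._res(0.50, 200.0))
        assert not rep.supported

    def test_better_reduced_aic_flags_conflict(self):
        rep = b.mediation_test(self._res(0.2, 100.0), self._res(0.01, 97.0))
        assert not rep.supported and rep.criterion_conflict

    def test_mismatched_data_rejected(self):
        full = self._res(0.2, 100.0)
        red = self._res(0.01, 105.0)
        red.data_hash = "other"
        with pytest.raises(ValueError, match="different data"):
            b.mediation_test(full, red)


class TestPathHelpers:
    def test_standardize_path(self):
        assert b.standardize_path(0.42, 0.8, 1.0) == pytest.approx(0.336)
        assert b.standardize_path(-0.3, 2.0, 2.0) == -0.3
        with pytest.raises(ValueError):
            b.standardize_path(1.0, 0.0, 1.0)

    def test_indirect_effect(self):
        assert b.indirect_effect(-0.3, 0.4) == pytest.approx(-0.12)
        assert b.indirect_effect(0.0, 5.0) == 0.0


class TestResampledSEM:
    def test_no_duplicates_equals_deterministic_fit(self):
        cfg = null_truth(n_studies=25, dup_range=(1, 1), path_b=0.4,
                         tau_study=0.2, sigma_obs=0.2, seed=9)
        eff = b.generate_effect_table(cfg).effects
        pairs = make_pairs(eff)
        r1 = b.run_resampled_sem(pairs, dataset_kind="abundance", iterations=1, seed=0)
        r5 = b.run_resampled_sem(pairs, dataset_kind="abundance", iterations=5, seed=42)
        pd.testing.assert_frame_equal(r1.paths, r5.paths, atol=1e-9)
        assert r1.fisher_C == pytest.approx(r5.fisher_C, abs=1e-9)

        # and matches the pandas-path sub-model fits
        table = b.stratified_resample(pairs, seed=0)
        fits = b.fit_submodels(table, dataset_kind="abundance")
        zb_row = r1.paths.set_index("edge").loc["zB->zLD"]
        assert zb_row["coef"] == pytest.approx(fits["zLD"].coefficients["z_b"],
                                               abs=2e-4)
        assert zb_row["se"] == pytest.approx(fits["zLD"].se["z_b"], abs=2e-4)

    def test_engine_consistency_with_fused_mediation(self):
        cfg = b.TruthConfig(n_studies=25, seed=13)
        pairs = make_pairs(b.generate_effect_table(cfg).effects)
        solo = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                   iterations=15, seed=5)
        full, red, rep = b.mediation_analysis(pairs, dataset_kind="abundance",
                                              iterations=15, seed=5)
        pd.testing.assert_frame_equal(solo.paths, full.paths, atol=1e-9)
        assert solo.fisher_C == pytest.approx(full.fisher_C, abs=1e-9)
        assert solo.AIC == pytest.approx(full.AIC, abs=1e-7)

    def test_seed_stability_of_averages(self):
        cfg = b.TruthConfig(n_studies=40, path_b=0.42, seed=19)
        pairs = make_pairs(b.generate_effect_table(cfg).effects)
        r1 = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                 iterations=120, seed=1)
        r2 = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                 iterations=120, seed=2)
        a = r1.paths.set_index("edge")
        c = r2.paths.set_index("edge")
        for edge in a.index:
            assert abs(a.loc[edge, "coef"] - c.loc[edge, "coef"]) < (
                0.5 * a.loc[edge, "se"]
            )

    def test_indirect_is_product_of_standardized_paths(self):
        cfg = b.TruthConfig(n_studies=30, seed=23)
        pairs = make_pairs(b.generate_effect_table(cfg).effects)
        res = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                  iterations=10, seed=3)
        std = res.paths.set_index("edge")["std_coef"]
        assert res.indirect_effect == pytest.approx(
            std["intensity->zB"] * std["zB->zLD"], abs=1e-12
        )
        assert res.direct_effect == pytest.approx(std["intensity->zLD"], abs=1e-12)

    def test_null_path_coefficient_near_zero(self):
        hits = 0
        for r in range(15):
            cfg = null_truth(n_studies=60, tau_study=0.2, sigma_obs=0.2,
                             seed=800 + r)
            pairs = make_pairs(b.generate_effect_table(cfg).effects)
            res = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                      iterations=25, seed=r)
            row = res.paths.set_index("edge").loc["zB->zLD"]
            hits += abs(row["coef"]) < 2 * row["se"]
        assert hits >= 13  # ~95% nominal over 15 replicates

    def test_full_model_c_p_roughly_uniform(self):
        # under the correctly specified full graph, rejection at 5% is rare
        rejections = 0
        for r in range(20):
            cfg = b.TruthConfig(n_studies=50, seed=1200 + r)
            pairs = make_pairs(b.generate_effect_table(cfg).effects)
            res = b.run_resampled_sem(pairs, dataset_kind="abundance",
                                      iterations=20, seed=r)
            rejections += res.C_p < 0.05
        assert rejections <= 4
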