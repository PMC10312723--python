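"""Gene aggregation: Drop-First geometric means, amalgams, empirical FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from craave import (
    aggregate_genes,
    aggregate_phenotype,
    analyze_sgrnas,
    build_amalgam,
    call_hits,
    empirical_fdr,
    gene_score,
    make_truth,
    simulate_library,
    simulate_screen_counts,
    weighted_geomean_fdr,
)
from craave.geopagg import drop_first_weights

from conftest import hand_stepped_delta


class TestWeightedGeomean:
    @pytest.mark.parametrize("n", [1, 2, 5, 11])
    def test_constant_members_return_constant(self, n):
        assert weighted_geomean_fdr([0.37] * n) == pytest.approx(0.37, abs=1e-12)

    def test_single_member_weight_cancels(self):
        assert weighted_geomean_fdr([0.042]) == pytest.approx(0.042, abs=1e-12)

    def test_worked_three_member_example(self):
        # q = exp((0.5 ln 0.01 + ln 0.04 + ln 0.25) / 2.5)
        expected = math.exp(
            (0.5 * math.log(0.01) + math.log(0.04) + math.log(0.25)) / 2.5
        )
        assert expected == pytest.approx(0.0631, abs=5e-4)
        assert weighted_geomean_fdr([0.01, 0.04, 0.25]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bounded_by_member_extremes_and_order_invariant(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = rng.random(rng.integers(1, 8)) * 0.999 + 1e-4
            q = weighted_geomean_fdr(x)
            assert x.min() - 1e-12 <= q <= x.max() + 1e-12
            perm = rng.permutation(x)
            assert weighted_geomean_fdr(perm) == pytest.approx(q, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_geomean_fdr([])

    def test_drop_first_unique_winner_and_tiebreak(self):
        w = drop_first_weights([0.5, 0.01, 0.3])
        assert list(w) == [1.0, 0.5, 1.0]
        # FDR tie: under-abundance favors the most negative phenotype
        w = drop_first_weights([0.01, 0.01], phis=[-2.0, -0.5], direction="under")
        assert list(w) == [0.5, 1.0]
        w = drop_first_weights([0.01, 0.01], phis=[-2.0, -0.5], direction="over")
        assert list(w) == [1.0, 0.5]
        # full tie: lexicographic sgrna_id
        w = drop_first_weights(
            [0.01, 0.01], phis=[1.0, 1.0], direction="under", sgrna_ids=["b", "a"]
        )
        assert list(w) == [1.0, 0.5]
        assert (w == 0.5).sum() == 1


class TestAggregatePhenotype:
    @pytest.mark.parametrize(
        "phis,expected",
        [([-2, -2, -2], -2.0), ([-3, 0, 0], -1.0), ([-1.5, -0.5, 0.2, 0.4, -0.6], -0.4)],
    )
    def test_arithmetic_mean(self, phis, expected):
        assert aggregate_phenotype(phis) == pytest.approx(expected, abs=1e-12)


class TestBuildAmalgam:
    def test_all_ntcs_when_size_equals_pool(self):
        groups = build_amalgam([f"n{i}" for i in range(5)], [5], seed=0)
        (members,) = groups.values()
        assert sorted(members) == [f"n{i}" for i in range(5)]

    def test_matches_membership_distribution_no_duplicates(self):
        ntcs = [f"ntc{i}" for i in range(250)]
        groups = build_amalgam(ntcs, [5] * 50, seed=1)
        assert len(groups) == 50
        for members in groups.values():
            assert len(members) == 5
            assert len(set(members)) == 5  # without replacement within a gene

    def test_seed_determinism(self):
        ntcs = [f"n{i}" for i in range(40)]
        a = build_amalgam(ntcs, [4] * 10, seed=7)
        b = build_amalgam(ntcs, [4] * 10, seed=7)
        c = build_amalgam(ntcs, [4] * 10, seed=8)
        assert a == b
        assert a != c

    def test_factor_multiplies_count(self):
        groups = build_amalgam([f"n{i}" for i in range(30)], [3, 4], seed=0, factor=3)
        assert len(groups) == 6

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds the NTC pool"):
            build_amalgam(["n1", "n2"], [3], seed=0)


class TestGeneScore:
    def test_product_form(self):
        assert gene_score(-2.0, 0.01) == pytest.approx(-4.0, abs=1e-12)

    def test_zero_cases(self):
        assert gene_score(5.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert gene_score(0.0, 1e-8) == pytest.approx(0.0, abs=1e-12)

    def test_additive_variant(self):
        # phi - log10(q): the paper's literal typeset reading
        assert gene_score(-2.0, 0.01, variant="additive") == pytest.approx(0.0)
        assert gene_score(0.5, 0.1, variant="additive") == pytest.approx(1.5)


class TestEmpiricalFdr:
    def test_hand_steppable_example(self):
        # ranks: real(q=0.001), amalgam, real(q=0.01)
        # delta_1 = max(0/1, 0.001) = 0.001; delta_3 = max(1/3, 0.01) = 1/3
        delta = empirical_fdr(
            gamma=[-5.0, -3.0, -1.0],
            q=[0.001, 0.5, 0.01],
            is_amalgam=[False, True, False],
            direction="under",
        )
        assert delta[0] == pytest.approx(0.001)
        assert delta[2] == pytest.approx(1 / 3)
        assert delta[2] >= delta[0]
        # the amalgam's own diagnostic delta: max(c_2/2, q_2) = 0.5
        assert delta[1] == pytest.approx(0.5)

    def test_all_amalgams_first(self):
        n_am = 4
        gamma = list(range(-10, -10 + n_am)) + [-1.0, 0.0]
        q = [0.9] * n_am + [0.001, 0.002]
        am = [True] * n_am + [False, False]
        delta = empirical_fdr(gamma, q, am, direction="under")
        for i in (n_am, n_am + 1):
            assert delta[i] >= n_am / (i + 1)

    def test_early_amalgam_does_not_erase_later_genes(self):
        # An amalgam at rank 1 has c/i = 1; real genes after it must not
        # inherit delta = 1 through the monotone chain.
        delta = empirical_fdr(
            gamma=[-9.0, -5.0, -4.0],
            q=[0.2, 0.001, 0.002],
            is_amalgam=[True, False, False],
            direction="under",
        )
        assert delta[0] == pytest.approx(1.0)
        assert delta[1] == pytest.approx(0.5)
        assert delta[2] == pytest.approx(0.5)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            empirical_fdr([0.0, -1.0], [0.1, 0.1], [False, False], direction="under")
        with pytest.raises(ValueError, match="not sorted"):
            empirical_fdr([0.0, 1.0], [0.1, 0.1], [False, False], direction="over")

    def test_matches_hand_stepped_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_real = rng.integers(1, 11)
            n_am = rng.integers(0, 11)
            n = n_real + n_am
            gamma = np.sort(rng.normal(size=n))
            q = rng.random(n)
            am = np.zeros(n, bool)
            am[rng.choice(n, size=n_am, replace=False)] = True
            delta = empirical_fdr(gamma, q, am, direction="under")
            np.testing.assert_array_equal(delta, hand_stepped_delta(q, am))
            assert np.all(np.diff(delta[~am]) >= 0)  # monotone over real genes
            assert np.all(delta >= q - 1e-15)
            assert np.all(delta <= 1.0)


def sgrna_table(rows):
    """rows: (sgrna_id, gene_group, phi, fdr_under, fdr_over)."""
    df = pd.DataFrame(
        rows, columns=["sgrna_id", "gene_group", "phi", "fdr_under", "fdr_over"]
    ).set_index("sgrna_id")
    return df


def toy_table(seed=0, n_genes=6, n_ntc=10, depleted=("g1",)):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        gene = f"g{g}"
        for j in range(3):
            if gene in depleted:
                phi, fu = -2 + rng.normal(0, 0.1), 10 ** -rng.uniform(3, 6)
            else:
                phi, fu = rng.normal(0, 0.2), rng.uniform(0.2, 1)
            rows.append((f"{gene}_sg{j}", gene, phi, fu, rng.uniform(0.2, 1)))
    for k in range(n_ntc):
        rows.append(
            (f"ntc_{k}", "non-targeting", rng.normal(0, 0.2),
             rng.uniform(0.2, 1), rng.uniform(0.2, 1))
        )
    return sgrna_table(rows)


class TestAggregateGenes:
    def test_depleted_gene_reported_and_hit(self):
        res = aggregate_genes(toy_table(), ntc_groups="non-targeting", seed=5)
        row = res.genes.loc["g1"]
        assert row["direction"] == "depleted"
        assert row["is_hit"]
        assert res.hit_genes == {"g1"}
        assert "non-targeting" not in res.genes.index

    def test_direction_symmetry(self):
        """Negating phenotypes and swapping directional FDRs swaps outputs."""
        tbl = toy_table(seed=3)
        mirrored = tbl.copy()
        mirrored["phi"] = -tbl["phi"]
        mirrored[["fdr_under", "fdr_over"]] = tbl[["fdr_over", "fdr_under"]].to_numpy()
        a = aggregate_genes(tbl, "non-targeting", seed=9)
        b = aggregate_genes(mirrored, "non-targeting", seed=9)
        np.testing.assert_allclose(a.genes["q_under"], b.genes["q_over"], rtol=1e-12)
        np.testing.assert_allclose(a.genes["phi"], -b.genes["phi"], rtol=1e-12)
        np.testing.assert_allclose(
            a.genes["empirical_fdr"], b.genes["empirical_fdr"], rtol=1e-12
        )
        swap = {"depleted": "enriched", "enriched": "depleted"}
        assert list(b.genes["direction"]) == [swap[d] for d in a.genes["direction"]]

    def test_delta_dominates_q_and_membership_reported(self):
        res = aggregate_genes(toy_table(seed=11), "non-targeting", seed=2)
        g = res.genes
        q_reported = np.where(g["direction"] == "depleted", g["q_under"], g["q_over"])
        assert (g["empirical_fdr"].to_numpy() >= q_reported - 1e-15).all()
        assert (g["n_sgrnas"] == 3).all()

    def test_dual_tss_groups_independent(self):
        rows = [
            ("a_p1_sg1", "geneA_P1", -2.0, 1e-4, 0.9),
            ("a_p1_sg2", "geneA_P1", -1.8, 1e-3, 0.9),
            ("a_p2_sg1", "geneA_P2", 0.1, 0.8, 0.4),
            ("a_p2_sg2", "geneA_P2", -0.1, 0.7, 0.6),
            ("b_sg1", "geneB", 0.0, 0.9, 0.9),
            ("ntc_1", "non-targeting", 0.0, 0.5, 0.5),
            ("ntc_2", "non-targeting", 0.1, 0.6, 0.4),
        ]
        res = aggregate_genes(sgrna_table(rows), "non-targeting", seed=1)
        assert {"geneA_P1", "geneA_P2", "geneB"} == set(res.genes.index)
        p1, p2 = res.genes.loc["geneA_P1"], res.genes.loc["geneA_P2"]
        assert p1["q_under"] == pytest.approx(
            weighted_geomean_fdr([1e-4, 1e-3]), rel=1e-12
        )
        assert p2["q_under"] == pytest.approx(
            weighted_geomean_fdr([0.8, 0.7]), rel=1e-12
        )
        assert p1["is_hit"] and not p2["is_hit"]

    def test_call_hits_threshold(self):
        res = aggregate_genes(toy_table(), "non-targeting", seed=5)
        assert set(call_hits(res).index) == {"g1"}
        assert len(call_hits(res, threshold=1e-12)) == 0

    def test_amalgam_determinism(self):
        tbl = toy_table(seed=8)
        a = aggregate_genes(tbl, "non-targeting", seed=4)
        b = aggregate_genes(tbl, "non-targeting", seed=4)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.diagnostics, b.diagnostics)


class TestAmalgamExchangeability:
    def test_null_ranks_indistinguishable(self):
        """Under a fully null screen, real and amalgam genes interleave:
        a rank test must not separate them (allow 1 failure in 20 seeds)."""
        # 50 genes vs 250 NTCs: each NTC lands in ~1 amalgam, so amalgam
        # ranks are close to independent and the rank test is valid. With
        # heavy pool reuse (many more amalgams than NTCs) amalgam ranks
        # are correlated through shared members and the independence
        # assumption of the test itself breaks down.
        failures = 0
        for seed in range(20):
            lib = simulate_library(50, 5, 250, seed=500 + seed)
            truth = make_truth(lib, essential_fraction=0.0, seed=600 + seed)
            counts, _ = simulate_screen_counts(
                lib, truth, n_mice=3, control_reps=3, depth=300, seed=700 + seed
            )
            sg = analyze_sgrnas(counts)
            res = aggregate_genes(sg.table, "non-targeting", seed=800 + seed)
            under = res.diagnostics[res.diagnostics["direction"] == "under"]
            real_ranks = under.loc[~under["is_amalgam"], "rank"]
            am_ranks = under.loc[under["is_amalgam"], "rank"]
            p = mannwhitneyu(real_ranks, am_ranks).pvalue
            if p <= 0.01:
                failures += 1
        assert failures <= 1
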