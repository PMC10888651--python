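import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_compendium
from connexsig.connectivity import (
    ConnectivityConfig,
    build_touchstone,
    es_score,
    heatmap_matrix,
    normalize_ncs,
    query_compendium,
    tau_score,
    top_k,
    wtcs,
)
from connexsig.errors import QueryError, ValidationError
from connexsig.signature import GeneSignature
from connexsig.synthetic_data import CompendiumSpec, simulate_compendium


def brute_force_es(ranks, n):
    """Literal evaluation of the a/b maxima, plain Python."""
    v = sorted(ranks)
    t = len(v)
    a = max((j + 1) / t - v[j] / n for j in range(t))
    b = max(v[j] / n - j / t for j in range(t))
    return a if a > b else -b


def ranking(n):
    return [f"g{i}" for i in range(1, n + 1)]


class TestEsScore:
    def test_single_gene_at_top(self):
        assert es_score(["g1"], ranking(10)) == pytest.approx(0.9)

    def test_single_gene_at_bottom(self):
        assert es_score(["g10"], ranking(10)) == pytest.approx(-1.0)

    def test_pair_at_top(self):
        assert es_score(["g1", "g2"], ranking(10)) == pytest.approx(0.8)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            es_score([], ranking(10))

    def test_gene_absent_from_ranking_rejected(self):
        with pytest.raises(ValidationError):
            es_score(["nope"], ranking(5))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        t = int(rng.integers(1, n + 1))
        ranks = rng.choice(n, size=t, replace=False) + 1
        genes = [f"g{r}" for r in ranks]
        es = es_score(genes, ranking(n))
        assert -1.0 <= es <= 1.0
        assert es == pytest.approx(brute_force_es(ranks, n), abs=1e-12)

    def test_reversed_ranking_flips_extreme_sets(self):
        fwd = ranking(20)
        rev = fwd[::-1]
        top = fwd[:4]
        assert es_score(top, fwd) > 0
        assert es_score(top, rev) < 0


class TestWtcs:
    def test_perfect_connection(self):
        assert wtcs(1.0, -1.0) == 1.0

    def test_same_sign_is_null(self):
        assert wtcs(0.8, 0.5) == 0.0
        assert wtcs(-0.3, -0.9) == 0.0

    def test_opposite_signs_average(self):
        assert wtcs(0.8, -0.6) == pytest.approx(0.7)


class TestNormalizeNcs:
    def test_single_positive_record_self_normalizes(self):
        records = pd.DataFrame({"cell_id": ["A"], "wtcs": [0.42]})
        assert normalize_ncs(records)["ncs"].iloc[0] == pytest.approx(1.0)

    def test_same_sign_group_mean(self):
        records = pd.DataFrame({"cell_id": ["A", "A"], "wtcs": [0.2, 0.4]})
        np.testing.assert_allclose(normalize_ncs(records)["ncs"], [2 / 3, 4 / 3])

    def test_all_zero_group_stays_zero(self):
        records = pd.DataFrame({"cell_id": ["A", "A"], "wtcs": [0.0, 0.0]})
        np.testing.assert_array_equal(normalize_ncs(records)["ncs"], [0.0, 0.0])

    def test_groups_normalized_independently(self):
        records = pd.DataFrame(
            {"cell_id": ["A", "A", "B"], "wtcs": [0.2, -0.4, 0.5]}
        )
        out = normalize_ncs(records)
        np.testing.assert_allclose(out["ncs"], [1.0, -1.0, 1.0])


class TestTauScore:
    def test_above_all_references(self):
        assert tau_score(2.0, np.array([0.5, 1.0, 1.5])) == 100.0

    def test_below_all_references(self):
        assert tau_score(0.1, np.array([0.5, 1.0, 1.5])) == 0.0

    def test_exceeds_seven_of_ten(self):
        bank = np.arange(1.0, 11.0)  # 1..10
        assert tau_score(7.5, bank) == pytest.approx(70.0)

    def test_negative_ncs_gets_negative_tau(self):
        assert tau_score(-2.0, np.array([0.5, 1.0])) == -100.0

    def test_empty_bank_rejected(self):
        with pytest.raises(ValidationError):
            tau_score(1.0, np.array([]))

    def test_monotone_in_abs_ncs(self, rng):
        bank = rng.normal(size=50)
        values = np.sort(rng.uniform(0, 3, size=20))
        taus = [tau_score(v, bank) for v in values]
        assert all(b >= a for a, b in zip(taus, taus[1:]))
        assert all(abs(t) <= 100 for t in taus)


def planted_compendium(seed, strength=1.0, n_genes=500, n_compounds=15):
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    draw = rng.choice(n_genes, size=100, replace=False)
    sig = GeneSignature(
        f"q{seed}",
        tuple(genes[i] for i in draw[:50]),
        tuple(genes[i] for i in draw[50:]),
    )
    spec = CompendiumSpec(
        n_landmark=100,
        n_nonlandmark=n_genes - 100,
        compounds=[(f"P{i:03d}", f"cpd-{i}") for i in range(n_compounds)],
        cell_ids=("A375", "MCF7"),
        profiles_per_pair=2,
        planted_connections=[
            (sig.signature_id, f"P{min(7, n_compounds - 1):03d}", strength)
        ],
        seed=seed + 1000,
    )
    ref, _ = simulate_compendium(spec, [sig])
    return sig, ref


class TestQueryCompendium:
    def test_planted_compound_ranks_first(self):
        sig, ref = planted_compendium(seed=1)
        table = query_compendium(sig, ref)
        assert table.iloc[0]["pert_id"] == "P007"
        assert table.iloc[0]["connected"]

    def test_null_connection_rate_bounded(self):
        """No planted signal: on average few compounds pass |tau| > 90."""
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"G{i + 1:05d}" for i in range(300)]
            draw = rng.choice(300, size=60, replace=False)
            sig = GeneSignature(
                "null", tuple(genes[i] for i in draw[:30]), tuple(genes[i] for i in draw[30:])
            )
            spec = CompendiumSpec(
                n_landmark=300, n_nonlandmark=0,
                compounds=[(f"P{i:03d}", f"c{i}") for i in range(50)],
                cell_ids=("A375",), profiles_per_pair=1, seed=seed + 77,
            )
            ref, _ = simulate_compendium(spec, [])
            table = query_compendium(sig, ref)
            fractions.append(table["connected"].mean())
        assert np.mean(fractions) <= 0.15

    def test_all_tags_absent_is_query_error(self):
        sig, ref = planted_compendium(seed=2)
        ghost = GeneSignature("ghost", ("X1", "X2"), ("X3",))
        with pytest.raises(QueryError):
            query_compendium(ghost, ref)

    def test_records_are_per_compound_cell_pair(self):
        sig, ref = planted_compendium(seed=3)
        table = query_compendium(sig, ref)
        assert len(table) == 15 * 2  # compounds x cell lines
        assert not table.duplicated(["pert_id", "cell_id"]).any()

    def test_sorted_by_tau_descending(self):
        sig, ref = planted_compendium(seed=4)
        taus = query_compendium(sig, ref)["tau"].to_numpy()
        assert (np.diff(taus) <= 1e-12).all()

    def test_median_aggregator_runs(self):
        sig, ref = planted_compendium(seed=5)
        table = query_compendium(sig, ref, ConnectivityConfig(aggregator="median"))
        assert table.iloc[0]["pert_id"] == "P007"

    def test_external_touchstone_used(self):
        sig, ref = planted_compendium(seed=6)
        ref.touchstone = build_touchstone(ref, n_probes=5, tags_per_direction=20, seed=0)
        table = query_compendium(sig, ref)
        assert table.iloc[0]["pert_id"] == "P007"
        assert (table["tau"].abs() <= 100).all()


class TestTopK:
    def make_table(self, n):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "query_id": "q",
                "pert_id": [f"P{i:03d}" for i in range(n)],
                "pert_iname": [f"c{i}" for i in range(n)],
                "cell_id": "A375",
                "sig_id": [f"s{i}" for i in range(n)],
                "es_up": 0.5,
                "es_down": -0.5,
                "wtcs": 0.5,
                "ncs": rng.normal(size=n),
                "tau": rng.uniform(-100, 100, size=n),
                "connected": False,
            }
        )

    def test_default_selects_ten(self):
        assert len(top_k(self.make_table(50))) == 10

    def test_short_table_returned_whole(self):
        assert len(top_k(self.make_table(4), k=10)) == 4

    def test_tau_tie_broken_by_abs_ncs(self):
        table = self.make_table(3)
        table["tau"] = [50.0, 50.0, 10.0]
        table["ncs"] = [0.2, -0.9, 2.0]
        out = top_k(table, k=2)
        assert list(out["pert_id"]) == ["P001", "P000"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValidationError):
            top_k(self.make_table(5), k=0)


class TestHeatmapMatrix:
    def test_shared_top_lists_are_dense(self):
        sig, ref = planted_compendium(seed=7)
        t1 = query_compendium(sig, ref)
        tables = {"q1": t1.assign(query_id="q1"), "q2": t1.assign(query_id="q2")}
        m = heatmap_matrix(tables, k=5)
        assert not np.isnan(m.values).any()
        assert list(m.col_meta["signature"]) == ["q1", "q1", "q2", "q2"]
        assert set(m.col_meta["cell_line"]) == {"A375", "MCF7"}

    def test_disjoint_tables_have_na_blocks(self):
        def table(pert, tau):
            return pd.DataFrame(
                {
                    "query_id": ["q"], "pert_id": [pert], "pert_iname": [pert.lower()],
                    "cell_id": ["A375"], "sig_id": ["s"], "es_up": [0.5],
                    "es_down": [-0.5], "wtcs": [0.5], "ncs": [1.0], "tau": [tau],
                    "connected": [False],
                }
            )
        m = heatmap_matrix({"q1": table("PA", 95.0), "q2": table("PB", 80.0)}, k=1)
        assert m.shape == (2, 2)
        assert np.isnan(m.values).sum() == 2

    def test_planted_row_holds_matrix_maximum(self):
        sig, ref = planted_compendium(seed=8)
        m = heatmap_matrix({sig.signature_id: query_compendium(sig, ref)}, k=10)
        top_row = m.row_ids.index("P007")
        assert np.nanmax(m.values) == np.nanmax(m.values[top_row])


class TestCompendiumIO:
    def test_save_load_round_trip_with_touchstone(self, tmp_path):
        sig, ref = planted_compendium(seed=9, n_genes=120, n_compounds=4)
        ref.touchstone = build_touchstone(ref, n_probes=3, tags_per_direction=10, seed=1)
        ref.save(tmp_path / "ref")
        from connexsig.connectivity import ReferenceCompendium

        back = ReferenceCompendium.load(tmp_path / "ref")
        np.testing.assert_allclose(back.zscores.values, ref.zscores.values, rtol=1e-9)
        assert set(back.touchstone) == set(ref.touchstone)
        for cell in ref.touchstone:
            np.testing.assert_allclose(
                np.sort(back.touchstone[cell]), np.sort(ref.touchstone[cell]), rtol=1e-9
            )
        t1 = query_compendium(sig, ref)
        t2 = query_compendium(sig, back)
        assert list(t1["pert_id"]) == list(t2["pert_id"])
        np.testing.assert_allclose(t1["tau"], t2["tau"])
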