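from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ks_running_sum
from comireg.data_model import CoMiProfile, DrugInstance, RankedDrugList
from comireg.drug_screen import (
    connectivity_score,
    default_k_values,
    discriminative_features,
    dsp_pvalue,
    dsp_sweep,
    ks_score,
    make_signature,
    rank_library,
)

from conftest import profile_from_stats


def stats_profile(values, condition="disease"):
    return profile_from_stats(
        {(f"m{i:02d}", f"t{i:02d}"): v for i, v in enumerate(values)},
        condition_id=condition,
    )


def make_instance(instance_id, disease: CoMiProfile, transform, positive=False):
    stats = {k: transform(v) for k, v in disease.statistics().items()}
    return DrugInstance(
        instance_id=instance_id,
        drug_name=instance_id,
        cell_line="CL",
        concentration="1uM",
        profile=profile_from_stats(stats, condition_id=instance_id),
        is_positive=positive,
    )


class TestMakeSignature:
    def test_tags_are_extremes_and_disjoint(self):
        prof = stats_profile([3, 2, 1, 0, -1, -2, -3] + [0.1 * i for i in range(8)])
        sig = make_signature(prof, k=5)
        stats = prof.statistics()
        up_vals = sorted((stats[k] for k in sig.up_tags), reverse=True)
        assert up_vals == sorted(stats.values(), reverse=True)[:5]
        down_vals = sorted(stats[k] for k in sig.down_tags)
        assert down_vals == sorted(stats.values())[:5]
        assert not set(sig.up_tags) & set(sig.down_tags)

    def test_window_boundaries(self):
        prof = stats_profile(np.linspace(-1, 1, 18))
        assert make_signature(prof, k=6).k == 6  # floor(18/3)
        with pytest.raises(ValueError):
            make_signature(prof, k=7)
        with pytest.raises(ValueError):
            make_signature(prof, k=4)

    def test_tie_break_is_deterministic(self):
        prof = stats_profile([1.0] * 20)
        sigs = [make_signature(prof, k=5) for _ in range(3)]
        assert all(s.up_tags == sigs[0].up_tags for s in sigs)
        assert all(s.down_tags == sigs[0].down_tags for s in sigs)


class TestConnectivityScore:
    def test_identity_gives_plus_one(self):
        disease = stats_profile(np.linspace(-2, 2, 20))
        sig = make_signature(disease, k=5)
        drug = make_instance("d", disease, lambda v: v)
        assert connectivity_score(sig, disease, drug.profile) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        disease = stats_profile(np.linspace(-2, 2, 20))
        sig = make_signature(disease, k=5)
        drug = make_instance("d", disease, lambda v: -v)
        assert connectivity_score(sig, disease, drug.profile) == pytest.approx(-1.0)

    def test_random_drug_scores_center_at_zero(self):
        rng = np.random.default_rng(12)
        disease = stats_profile(rng.normal(size=30))
        sig = make_signature(disease, k=6)
        rhos = []
        for _ in range(1000):
            perm = rng.normal(size=30)
            drug = stats_profile(perm, condition="rnd")
            rhos.append(connectivity_score(sig, disease, drug))
        assert abs(np.mean(rhos)) < 0.05

    def test_insufficient_shared_patterns_is_none(self):
        disease = stats_profile(np.linspace(-2, 2, 20))
        sig = make_signature(disease, k=5)
        tiny = profile_from_stats({("m00", "t00"): 1.0}, condition_id="tiny")
        assert connectivity_score(sig, disease, tiny) is None


class TestRankLibrary:
    def test_orders_by_score(self):
        disease = stats_profile(np.linspace(-2, 2, 20))
        sig = make_signature(disease, k=5)
        lib = [
            make_instance("b_mid", disease, lambda v: 0.1 * v),
            make_instance("a_anti", disease, lambda v: -v, positive=True),
            make_instance("c_same", disease, lambda v: v),
        ]
        ranked = rank_library(sig, disease, lib)
        assert [i.instance_id for i in ranked.instances] == ["a_anti", "b_mid", "c_same"]
        assert ranked.positive_positions == [1]

    def test_exact_negation_ranks_first_among_random(self):
        rng = np.random.default_rng(13)
        disease = stats_profile(rng.normal(size=30))
        sig = make_signature(disease, k=6)
        for _ in range(20):
            lib = [make_instance("zz_neg", disease, lambda v: -v, positive=True)]
            for i in range(20):
                stats = rng.normal(size=30)
                lib.append(
                    DrugInstance(
                        instance_id=f"r{i:02d}", drug_name=f"r{i:02d}",
                        cell_line="CL", concentration="1uM",
                        profile=stats_profile(stats, condition=f"r{i}"),
                        is_positive=False,
                    )
                )
            ranked = rank_library(sig, disease, lib)
            assert ranked.instances[0].instance_id == "zz_neg"

    def test_rank_invariant_to_input_order(self):
        rng = np.random.default_rng(14)
        disease = stats_profile(rng.normal(size=24))
        sig = make_signature(disease, k=5)
        lib = [
            make_instance(f"d{i}", disease, lambda v, a=a: a * v)
            for i, a in enumerate(rng.normal(size=8))
        ]
        r1 = rank_library(sig, disease, lib)
        r2 = rank_library(sig, disease, list(reversed(lib)))
        assert [i.instance_id for i in r1.instances] == [i.instance_id for i in r2.instances]


class TestKsScore:
    def test_hand_enumerated_top(self):
        assert ks_score((1, 2), 2, 10) == pytest.approx(0.8)

    def test_hand_enumerated_bottom(self):
        assert ks_score((9, 10), 2, 10) == pytest.approx(-0.9)

    @pytest.mark.parametrize("n_pos", [1, 2, 3])
    def test_matches_running_sum_oracle_exhaustively(self, n_pos):
        N = 10
        for positions in combinations(range(1, N + 1), n_pos):
            got = ks_score(positions, n_pos, N)
            assert got == pytest.approx(ks_running_sum(positions, N), abs=1e-12)

    def test_positive_score_flips_sign_under_reversal(self):
        N = 10
        for positions in combinations(range(1, N + 1), 2):
            score = ks_score(positions, 2, N)
            reversed_pos = tuple(sorted(N + 1 - v for v in positions))
            if score > 0:
                rev = ks_score(reversed_pos, 2, N)
                assert rev < 0
                assert abs(rev) == pytest.approx(score + 1 / N, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounds_and_oracle_on_arbitrary_position_sets(self, data):
        N = data.draw(st.integers(min_value=1, max_value=40))
        n_pos = data.draw(st.integers(min_value=1, max_value=N))
        positions = tuple(
            sorted(
                data.draw(
                    st.sets(
                        st.integers(min_value=1, max_value=N),
                        min_size=n_pos, max_size=n_pos,
                    )
                )
            )
        )
        score = ks_score(positions, n_pos, N)
        assert -1 <= score <= 1
        assert score == pytest.approx(ks_running_sum(positions, N), abs=1e-12)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            ks_score((2, 2), 2, 10)
        with pytest.raises(ValueError):
            ks_score((0, 3), 2, 10)
        with pytest.raises(ValueError):
            ks_score((3, 11), 2, 10)


def ranked_with_positions(positions, N):
    return RankedDrugList(
        instances=[None] * N,
        scores=list(np.linspace(-1, 1, N)),
        positive_positions=list(positions),
        N=N,
        n_pos=len(positions),
    )


class TestDspPvalue:
    def test_top_block_reaches_floor(self):
        ranked = ranked_with_positions(range(1, 11), 100)
        res = dsp_pvalue(ranked, n_perm=1000, seed=1)
        assert res.ks_score == pytest.approx(0.9)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_seeded_determinism(self):
        ranked = ranked_with_positions([3, 17, 40], 60)
        r1 = dsp_pvalue(ranked, n_perm=500, seed=9)
        r2 = dsp_pvalue(ranked, n_perm=500, seed=9)
        assert r1 == r2
        r3 = dsp_pvalue(ranked, n_perm=500, seed=10)
        p = r1.p_value
        assert abs(r3.p_value - p) < 4 * np.sqrt(p * (1 - p) / 500) + 1e-9

    def test_all_positive_warns_p_one(self, caplog):
        ranked = ranked_with_positions(range(1, 6), 5)
        with caplog.at_level("WARNING"):
            res = dsp_pvalue(ranked, n_perm=100, seed=0)
        assert res.p_value == 1.0


class TestSweepAndFeatures:
    def _screen(self, seed=15):
        rng = np.random.default_rng(seed)
        disease = stats_profile(rng.normal(size=36))
        lib = [
            make_instance(f"true{i}", disease, lambda v: -v + rng.normal(0, 0.3),
                          positive=True)
            for i in range(4)
        ]
        for i in range(20):
            lib.append(
                DrugInstance(
                    instance_id=f"dec{i:02d}", drug_name=f"dec{i:02d}",
                    cell_line="CL", concentration="1uM",
                    profile=stats_profile(rng.normal(size=36), condition=f"dec{i}"),
                    is_positive=False,
                )
            )
        return disease, lib

    def test_single_k_sweep_matches_dsp_pvalue(self):
        disease, lib = self._screen()
        sig = make_signature(disease, k=5)
        ranked = rank_library(sig, disease, lib)
        single = dsp_pvalue(ranked, n_perm=200, seed=3)
        table, _ = dsp_sweep(disease, lib, [5], n_perm=200, seed=3)
        assert table.ks_score.iloc[0] == pytest.approx(single.ks_score)
        assert table.p_value.iloc[0] == pytest.approx(single.p_value)

    def test_sweep_summary_and_detection(self):
        disease, lib = self._screen()
        ks = default_k_values(36)
        table, summary = dsp_sweep(disease, lib, ks, n_perm=200, seed=4)
        assert len(table) == len(ks)
        assert summary["q1_ks"] <= summary["median_ks"] <= summary["q3_ks"]
        assert (table.ks_score > 0).all()

    def test_discriminative_features_top_fraction(self):
        disease, lib = self._screen()
        table, _ = dsp_sweep(disease, lib, [5, 6], n_perm=50, seed=5)
        all_feats = discriminative_features(table, top_fraction=1.0)
        best_row = table.sort_values("ks_score", ascending=False).iloc[0]
        top_feats = discriminative_features(table, top_fraction=0.5)
        assert top_feats == set(best_row["signature"].patterns)
        assert top_feats <= all_feats

    def test_single_signature_full_fraction_is_its_tags(self):
        disease, lib = self._screen()
        table, _ = dsp_sweep(disease, lib, [7], n_perm=50, seed=6)
        feats = discriminative_features(table, top_fraction=1.0)
        assert feats == set(table.signature.iloc[0].patterns)
        assert len(feats) == 14

    def test_bad_top_fraction_rejected(self):
        disease, lib = self._screen()
        table, _ = dsp_sweep(disease, lib, [5], n_perm=20, seed=7)
        with pytest.raises(ValueError):
            discriminative_features(table, top_fraction=0.0)
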