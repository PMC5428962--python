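import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soyquefts import (
    InsufficientDataError,
    NutrientTriple,
    Observation,
    UndefinedEfficiencyError,
    compute_ie_rie,
    compute_nutrient_hi,
    compute_uptake,
    filter_by_hi,
    read_observations,
    resolve_uptake,
    seed_dry_matter,
    summarize,
    write_observations,
)


def obs(**kw):
    base = dict(site_id="s", year=2010)
    base.update(kw)
    return Observation(**base)


class TestComputeUptake:
    @pytest.mark.parametrize("seed_dm,cs,straw,cstr,expected_n", [
        # seed 2000 kg @ 50 g/kg + straw 2000 kg @ 10 g/kg = 120 kg/ha
        (2000.0, 50.0, 2000.0, 10.0, 120.0),
        # single-term product: 1000 kg seed at the mean seed-N concentration
        (1000.0, 53.5, 0.0, 99.0, 53.5),
        (1500.0, 0.0, 800.0, 0.0, 0.0),
    ])
    def test_hand_arithmetic(self, seed_dm, cs, straw, cstr, expected_n):
        o = obs(seed_yield=seed_dm, straw_dm=straw,
                conc_seed=NutrientTriple(cs, 0, 0),
                conc_straw=NutrientTriple(cstr, 0, 0))
        u = compute_uptake(o, moisture_fraction=0.0)
        assert u.n == pytest.approx(expected_n, abs=1e-9)
        assert u.p == u.k == 0.0

    def test_moisture_correction_applied_to_seed_only(self):
        o = obs(seed_yield=1000.0, straw_dm=1000.0,
                conc_seed=NutrientTriple(10.0, 0, 0),
                conc_straw=NutrientTriple(10.0, 0, 0))
        # seed contributes on a dry-matter basis: 1000*0.865*0.010 = 8.65
        assert compute_uptake(o).n == pytest.approx(8.65 + 10.0)
        assert seed_dry_matter(o) == pytest.approx(865.0)

    def test_missing_inputs_never_silently_zero(self):
        with pytest.raises(InsufficientDataError):
            compute_uptake(obs(seed_yield=1000.0, straw_dm=500.0,
                               conc_seed=NutrientTriple(50, 7, 13)))
        with pytest.raises(InsufficientDataError):
            compute_uptake(obs(seed_yield=1000.0,
                               conc_seed=NutrientTriple(50, 7, 13),
                               conc_straw=NutrientTriple(9, 3, 8)))

    @given(scale=st.floats(0.1, 10))
    def test_linear_in_concentrations(self, scale, ):
        base = obs(seed_yield=2000.0, straw_dm=1500.0,
                   conc_seed=NutrientTriple(50, 7, 13),
                   conc_straw=NutrientTriple(9, 3, 8))
        scaled = obs(seed_yield=2000.0, straw_dm=1500.0,
                     conc_seed=NutrientTriple(50 * scale, 7 * scale, 13 * scale),
                     conc_straw=NutrientTriple(9 * scale, 3 * scale, 8 * scale))
        u0, u1 = compute_uptake(base), compute_uptake(scaled)
        for x in "npk":
            assert u1[x] == pytest.approx(scale * u0[x], rel=1e-12)


class TestInternalEfficiency:
    def test_round_numbers(self):
        ie, rie = compute_ie_rie(obs(seed_yield=1000.0,
                                     uptake=NutrientTriple(50, 10, 20)))
        assert ie.n == pytest.approx(20.0)
        assert rie.n == pytest.approx(50.0)

    def test_ratio_of_dataset_means(self):
        # dividing the dataset-mean yield by dataset-mean uptakes
        # (intentionally different from the mean of per-plot ratios)
        ie, _ = compute_ie_rie(obs(seed_yield=2472.0,
                                   uptake=NutrientTriple(131.5, 21.8, 47.6)))
        assert ie.n == pytest.approx(18.80, abs=0.01)
        assert ie.p == pytest.approx(113.4, abs=0.1)
        assert ie.k == pytest.approx(51.9, abs=0.1)

    def test_ie_rie_reciprocal_identity(self):
        ie, rie = compute_ie_rie(obs(seed_yield=2731.0,
                                     uptake=NutrientTriple(147.2, 19.3, 55.8)))
        for x in "npk":
            assert ie[x] * rie[x] == pytest.approx(1000.0, rel=1e-12)

    def test_zero_yield_flags_rie(self):
        ie, rie = compute_ie_rie(obs(seed_yield=0.0,
                                     uptake=NutrientTriple(50, 10, 20)))
        assert list(ie) == [0.0, 0.0, 0.0]
        assert all(math.isnan(v) for v in rie)

    def test_zero_uptake_is_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            compute_ie_rie(obs(seed_yield=1000.0, uptake=NutrientTriple(50, 0, 20)))


class TestNutrientHarvestIndex:
    def test_seed_share(self):
        # 84 kg N in seed of a 100 kg total -> HI_N = 0.84
        o = obs(seed_yield=1000.0, straw_dm=1000.0,
                conc_seed=NutrientTriple(84, 10, 10),
                conc_straw=NutrientTriple(16, 0, 10))
        nhi = compute_nutrient_hi(o, moisture_fraction=0.0)
        assert nhi.hi_n == pytest.approx(0.84)
        assert nhi.hi_p == 1.0          # no P in straw
        assert nhi.hi_k == pytest.approx(0.5)

    def test_zero_seed_content_boundary(self):
        o = obs(seed_yield=1000.0, straw_dm=1000.0,
                conc_seed=NutrientTriple(0, 1, 1),
                conc_straw=NutrientTriple(10, 1, 1))
        assert compute_nutrient_hi(o, moisture_fraction=0.0).hi_n == 0.0


class TestHiFilter:
    def test_threshold_inclusive(self):
        table = [obs(hi=v) for v in (0.26, 0.40, 0.47, 0.66)]
        kept = filter_by_hi(table, 0.4)
        assert [o.hi for o in kept] == [0.40, 0.47, 0.66]

    def test_zero_threshold_is_identity(self):
        table = [obs(hi=v) for v in (0.26, 0.47)]
        assert filter_by_hi(table, 0.0) == table
        assert filter_by_hi([], 0.4) == []

    def test_missing_hi_excluded_unless_flagged(self):
        table = [obs(hi=0.5), obs(hi=None)]
        assert len(filter_by_hi(table)) == 1
        assert len(filter_by_hi(table, keep_missing=True)) == 2

    @given(st.lists(st.floats(0.01, 0.99), max_size=30),
           st.floats(0.05, 0.9))
    def test_idempotent_and_order_preserving(self, his, threshold):
        table = [obs(hi=round(v, 6)) for v in his]
        once = filter_by_hi(table, threshold)
        assert filter_by_hi(once, threshold) == once
        assert [o.hi for o in once] == [o.hi for o in table if o.hi >= threshold]


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.mean, s.median, s.minimum, s.maximum) == (3, 3, 1, 5)
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        assert (s.q25, s.q75) == (2, 4)

    def test_single_and_constant(self):
        s = summarize([7.0])
        assert s.mean == s.median == s.minimum == s.maximum == 7.0
        assert s.sd == 0.0
        c = summarize([3.2] * 10)
        assert c.sd == 0.0 and c.q25 == c.q75 == 3.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a, b = summarize(values), summarize(shuffled)
        assert a.n_obs == b.n_obs
        for fld in ("mean", "sd", "minimum", "q25", "median", "q75", "maximum"):
            # summation order may differ in the last ulp
            assert getattr(a, fld) == pytest.approx(getattr(b, fld), abs=1e-9)


class TestResolveUptake:
    def test_consistent_record_passes(self, full_observation):
        u = resolve_uptake(full_observation)
        recomputed = compute_uptake(full_observation)
        for x in "npk":
            assert u[x] == pytest.approx(recomputed[x])

    def test_inconsistent_record_rejected(self, full_observation):
        import dataclasses
        good = compute_uptake(full_observation)
        bad = dataclasses.replace(
            full_observation,
            uptake=NutrientTriple(good.n * 1.01, good.p, good.k))
        with pytest.raises(ValueError, match="inconsistent"):
            resolve_uptake(bad)


def test_csv_round_trip(tmp_path, full_observation):
    partial = Observation(site_id="s2", year=2012, treatment="FP",
                          seed_yield=1800.0, uptake=NutrientTriple(90, 14, 33))
    path = tmp_path / "obs.csv"
    write_observations([full_observation, partial], path)
    back = read_observations(path)
    assert back[0] == full_observation
    assert back[1] == partial
    assert back[1].conc_seed is None
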