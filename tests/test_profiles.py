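"""Modified-Z standardization, feature selection statistics and treatment
profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoprofiler.catalogue import build_catalogue
from autoprofiler.profiles import (
    MODIFIED_Z_SCALE,
    bh_adjust,
    build_profile,
    compute_reference,
    drop_nan_features,
    mann_whitney_u,
    modified_z,
    select_significant,
    variable_feature_timecourse,
)
from autoprofiler.synthgen import generate_feature_table


def _table(dmso_vals, treated_vals, feature="area"):
    rows = []
    for i, v in enumerate(dmso_vals):
        rows.append({"cell_id": f"d{i}", "time": 0.5, "treatment": "DMSO",
                     "plate": "p1", "well": "A01", "position": 1, feature: v})
    for i, v in enumerate(treated_vals):
        rows.append({"cell_id": f"t{i}", "time": 0.5, "treatment": "drug",
                     "plate": "p1", "well": "B01", "position": 1, feature: v})
    return pd.DataFrame(rows)


class TestModifiedZ:
    def test_hand_example(self):
        # DMSO {1..5}: median 3, mean abs deviation 1.2 -> z(6) = 1.995
        tab = _table([1, 2, 3, 4, 5], [6])
        std = modified_z(tab)
        z = std.loc[std.treatment == "drug", "area"].iloc[0]
        assert z == pytest.approx(3 / (MODIFIED_Z_SCALE * 1.2), abs=1e-9)
        assert std.loc[std.area == 0.0].shape[0] == 1  # the DMSO median row

    def test_centering_at_dmso_median(self):
        tab = _table([1, 2, 3, 4, 5], [3])
        std = modified_z(tab)
        assert std.loc[std.treatment == "drug", "area"].iloc[0] == 0.0

    def test_normal_scale_recovers_unit_sd(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.normal(10, 2, 200_000), [10])
        std = modified_z(tab)
        sd = std.loc[std.treatment == "DMSO", "area"].std()
        assert sd == pytest.approx(1.0, rel=0.01)

    def test_zero_mad_feature_excluded_with_warning(self):
        tab = _table([5, 5, 5, 5], [7])
        with pytest.warns(UserWarning, match="zero DMSO MAD"):
            std = modified_z(tab)
        assert "area" not in std.columns

    @given(scale=st.floats(min_value=0.01, max_value=100),
           shift=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_equivariance(self, scale, shift):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 40)
        z1 = modified_z(_table(vals[:30], vals[30:]))
        z2 = modified_z(_table(vals[:30] * scale + shift, vals[30:] * scale + shift))
        assert np.allclose(z1["area"], z2["area"], atol=1e-6)


class TestDropNan:
    def test_clean_table_unchanged(self):
        tab = _table([1, 2, 3], [4])
        assert drop_nan_features(tab).equals(tab)

    def test_column_wise_never_row_wise(self):
        tab = _table([1, 2, 3], [4])
        tab["other"] = [np.nan, 1.0, 2.0, 3.0]
        out = drop_nan_features(tab)
        assert len(out) == len(tab)
        assert "other" not in out.columns and "area" in out.columns


class TestMannWhitney:
    def test_identical_samples(self):
        U, p = mann_whitney_u([1.0, 2, 3], [1.0, 2, 3])
        assert U == 4.5  # |a||b|/2
        assert p == 1.0

    def test_exact_small_sample(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 * 1/20

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_p_equals_full_enumeration(self):
        # independent oracle: enumerate all C(10,5) group assignments
        rng = np.random.default_rng(3)
        for _ in range(30):
            pooled = rng.normal(size=10)
            a, b = pooled[:5], pooled[5:]
            U_obs, p_obs = mann_whitney_u(a, b)
            us = []
            for idx in itertools.combinations(range(10), 5):
                sel = np.zeros(10, bool)
                sel[list(idx)] = True
                aa, bb = pooled[sel], pooled[~sel]
                us.append(sum((x > y) + 0.5 * (x == y) for x in aa for y in bb))
            us = np.array(us)
            p_le = (us <= U_obs).mean()
            p_ge = (us >= U_obs).mean()
            p_exact = min(1.0, 2 * min(p_le, p_ge))
            assert p_obs == pytest.approx(p_exact, abs=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()


class TestSelectSignificant:
    def test_identical_arms_nothing_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=60)
        tab = _table(vals[:30], vals[:30])
        rec = select_significant(modified_z(tab), "drug", 0.5)
        assert rec["significant"].sum() == 0

    def test_planted_shift_is_flagged(self):
        tab = generate_feature_table({"drug": {"area": 2.0}}, 300, 1, seed=9,
                                     features=build_catalogue().names[:100])
        rec = select_significant(modified_z(tab), "drug", 0.5)
        flagged = set(rec.loc[rec.significant, "feature"])
        assert flagged == {"area"}

    def test_missing_control_rejected(self):
        tab = _table([1, 2, 3], [4, 5])
        tab = tab[tab.treatment != "DMSO"]
        with pytest.raises(ValueError):
            select_significant(tab, "drug", 0.5)

    def test_flag_is_conjunction_of_rules(self):
        tab = generate_feature_table({"drug": {"area": 2.0}}, 100, 1, seed=9,
                                     features=build_catalogue().names[:50])
        rec = select_significant(modified_z(tab), "drug", 0.5)
        should = (rec["median_z"].abs() >= 0.5) & (rec["q"] < 0.05)
        assert (rec["significant"] == should).all()
        assert (rec["q"] >= rec["p"] - 1e-12).all()


class TestTimecourse:
    def test_transient_effect_window_recovered(self):
        eff = {"drug": {"area": np.array([3.0, 0.0, 0.0]),
                        "perimeter": np.array([3.0, 3.0, 0.0])}}
        tab = generate_feature_table(eff, 200, 3, seed=4,
                                     features=build_catalogue().names[:40])
        counts = variable_feature_timecourse(modified_z(tab))["drug"]
        assert counts.tolist() == [2, 1, 0]

    def test_counts_bounded_by_catalogue(self):
        tab = generate_feature_table({"d": {}}, 50, 2, seed=0,
                                     features=build_catalogue().names[:30])
        counts = variable_feature_timecourse(modified_z(tab))
        assert (counts <= 30).all().all()


class TestBuildProfile:
    def test_single_cell_profile_is_its_vector(self):
        tab = _table([1, 2, 3, 4, 5], [6])
        std = modified_z(tab)
        prof = build_profile(std, "drug", ["area"])
        assert prof[("area", 0.5)] == std.loc[std.treatment == "drug", "area"].iloc[0]

    def test_dmso_profile_near_zero(self):
        tab = generate_feature_table({"d": {}}, 300, 1, seed=2,
                                     features=build_catalogue().names[:60])
        std = modified_z(tab)
        prof = build_profile(std, "DMSO", build_catalogue().names[:60])
        assert prof.abs().max() < 3 / np.sqrt(300)

    def test_split_half_reproducibility(self):
        feats = build_catalogue().names[:60]
        eff = {"d": {f: s for f, s in zip(feats, np.linspace(-2, 2, 60))}}
        tab = generate_feature_table(eff, 300, 1, seed=8, features=feats)
        std = modified_z(tab)
        treated = std[std.treatment == "d"]
        dmso = std[std.treatment == "DMSO"]
        half_profiles = []
        for half in (slice(0, 150), slice(150, 300)):
            sub = pd.concat([treated.iloc[half], dmso])
            half_profiles.append(build_profile(sub, "d", feats))
        r = np.corrcoef(half_profiles[0], half_profiles[1])[0, 1]
        assert r > 0.95

    def test_missing_timepoint_error_lists_gaps(self):
        tab = _table([1, 2, 3], [4])
        with pytest.raises(ValueError, match="1.5"):
            build_profile(modified_z(tab), "drug", ["area"], timepoints=[0.5, 1.5])
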