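"""Normalization, distance scoring, p-values, viability, and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lucihits.hit_selection import (
    DegenerateNullError,
    HitCaller,
    NullModel,
    UndefinedRLUError,
    build_null,
    compute_rlu,
    normalize_plate,
    p_value,
    score_compound,
    select_hits,
    viability_filter,
    z_prime_factor,
)
from lucihits.synthetic_screen import SyntheticScreenConfig, generate_screen

from conftest import make_mini_dataset


class TestComputeRlu:
    @pytest.mark.parametrize(
        "firefly,renilla,expected", [(2000, 1000, 2.0), (0, 500, 0.0)]
    )
    def test_ratio(self, firefly, renilla, expected):
        assert compute_rlu(firefly, renilla) == expected

    def test_zero_renilla_raises(self):
        with pytest.raises(UndefinedRLUError):
            compute_rlu(100, 0)


class TestNormalizePlate:
    @staticmethod
    def _plate(tnfa_rlus, lib_rlu=None):
        rows = []
        for i, r in enumerate(tnfa_rlus):
            rows.append(
                dict(plate_id="P1", replicate=1, row="A", col=i + 1,
                     role="TNFA", compound_id="", concentration_M=np.nan,
                     firefly=r * 100.0, renilla=100.0)
            )
        if lib_rlu is not None:
            rows.append(
                dict(plate_id="P1", replicate=1, row="B", col=1,
                     role="LIBRARY", compound_id="X", concentration_M=1e-5,
                     firefly=lib_rlu * 100.0, renilla=100.0)
            )
        return pd.DataFrame(rows)

    def test_library_activity_against_tnfa_mean(self):
        out = normalize_plate(self._plate([4, 4, 4, 4], lib_rlu=2.0))
        lib = out[out["role"] == "LIBRARY"]
        assert lib["normalized_activity"].iloc[0] == pytest.approx(0.5)

    def test_tnfa_self_normalization(self):
        out = normalize_plate(self._plate([3, 5]))
        acts = sorted(out["normalized_activity"])
        assert acts == pytest.approx([0.75, 1.25])
        assert out["normalized_activity"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_no_tnfa_wells_is_error(self):
        df = self._plate([4.0])
        df["role"] = "DMSO"
        with pytest.raises(ValueError, match="TNFA"):
            normalize_plate(df)

    def test_mixed_groups_rejected(self):
        df = pd.concat([self._plate([4.0]), self._plate([4.0]).assign(replicate=2)])
        with pytest.raises(ValueError, match="one .plate_id, replicate."):
            normalize_plate(df)

    def test_tnfa_mean_exactly_one_on_generated_screens(self, small_screen):
        dataset, _ = small_screen
        for _, grp in dataset.wells.groupby(["plate_id", "replicate"]):
            out = normalize_plate(grp)
            tnfa_mean = out.loc[out["role"] == "TNFA", "normalized_activity"].mean()
            assert abs(tnfa_mean - 1.0) < 1e-12


class TestScoreCompound:
    @pytest.mark.parametrize(
        "activities,expected",
        [((0.5, 0.6, 0.55), 1.35), ((1.0, 1.0, 1.0), 0.0), ((0.2,), 0.8)],
    )
    def test_manhattan_distance(self, activities, expected):
        assert score_compound(activities) == pytest.approx(expected)

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            score_compound([])

    def test_nan_replicates_are_ignored(self):
        assert score_compound([0.5, np.nan, 0.6]) == pytest.approx(0.9)

    @given(
        delta=st.floats(-2, 2, allow_nan=False),
        n_rep=st.integers(1, 6),
    )
    def test_translation_consistency(self, delta, n_rep):
        """Shifting every replicate by delta from the control mean gives R|delta|."""
        d = score_compound([1.0 + delta] * n_rep)
        assert d == pytest.approx(n_rep * abs(delta), abs=1e-9)


class TestNullModel:
    def test_empirical_pool_is_sorted(self):
        acts = pd.DataFrame(
            {
                "row": ["A", "B", "C", "D"] * 2,
                "col": [1] * 8,
                "replicate": [1] * 4 + [2] * 4,
                "normalized_activity": [1.05, 0.9, 1.2, 0.8, 0.95, 1.1, 0.8, 1.2],
            }
        )
        null = build_null(acts, "empirical", plate_id="P1")
        assert null.n == 4
        assert (np.diff(null.null_distances) >= 0).all()
        # each well's distance is the L1 deviation over its two replicates
        assert null.null_distances[0] == pytest.approx(abs(1.05 - 1) + abs(0.95 - 1))

    def test_degenerate_null_raises(self):
        acts = pd.DataFrame(
            {
                "row": list("ABC"),
                "col": [1, 1, 1],
                "replicate": [1, 1, 1],
                "normalized_activity": [1.0, 1.0, 1.0],
            }
        )
        with pytest.raises(DegenerateNullError):
            build_null(acts, "empirical")

    def test_half_normal_sigma_is_rms(self):
        null = NullModel("P1", "half_normal", np.array([1.0, 1.0, 1.0, 1.0]))
        assert null.sigma == pytest.approx(1.0)

    def test_too_few_controls_names_plate(self):
        acts = pd.DataFrame(
            {
                "row": ["A", "B"],
                "col": [1, 1],
                "replicate": [1, 1],
                "normalized_activity": [0.9, 1.1],
            }
        )
        with pytest.raises(ValueError, match="P9"):
            build_null(acts, "empirical", plate_id="P9")


class TestPValue:
    def test_distance_zero_gives_p_one(self):
        null = NullModel("P1", "empirical", np.array([0.1, 0.2, 0.3, 0.4]))
        assert p_value(0.0, null) == pytest.approx(1.0)

    def test_empirical_rank_example(self):
        null = NullModel("P1", "empirical", np.array([0.1, 0.2, 0.3, 0.4]))
        # two null distances >= 0.25, add-one: (2+1)/5
        assert p_value(0.25, null) == pytest.approx(0.6)

    def test_half_normal_at_one_sigma(self):
        null = NullModel("P1", "half_normal", np.array([1.0, 1.0, 1.0, 1.0]))
        assert p_value(1.0, null) == pytest.approx(2 * stats.norm.sf(1.0), rel=1e-12)
        assert p_value(1.0, null) == pytest.approx(0.3173, abs=5e-5)

    @given(
        pool=st.lists(st.floats(0.001, 5.0), min_size=3, max_size=60),
        d=st.floats(0.0, 6.0),
    )
    def test_empirical_matches_brute_force_count(self, pool, d):
        """The add-one estimator equals direct counting over the pool."""
        null = NullModel("P1", "empirical", np.array(pool))
        expected = (sum(x >= d for x in pool) + 1) / (len(pool) + 1)
        assert p_value(d, null) == expected

    @given(
        pool=st.lists(st.floats(0.001, 5.0), min_size=3, max_size=30),
        d1=st.floats(0.0, 6.0),
        d2=st.floats(0.0, 6.0),
        method=st.sampled_from(["empirical", "half_normal"]),
    )
    def test_monotone_nonincreasing_in_distance(self, pool, d1, d2, method):
        null = NullModel("P1", method, np.array(pool))
        lo, hi = sorted([d1, d2])
        assert p_value(lo, null) >= p_value(hi, null)

    def test_negative_distance_rejected(self):
        null = NullModel("P1", "empirical", np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            p_value(-0.1, null)


class TestViabilityFilter:
    @pytest.mark.parametrize(
        "renilla,expected",
        [
            ([40, 45, 38], False),   # clearly cytotoxic
            ([60, 70, 65], True),    # healthy
            ([50, 50, 50], True),    # boundary: >= is retained
        ],
    )
    def test_median_threshold(self, renilla, expected):
        assert viability_filter(renilla, 100.0, 0.5) is expected

    def test_zero_renilla_fails_filter(self):
        assert viability_filter([0.0, 0.0, 0.0], 100.0, 0.5) is False

    def test_nonpositive_plate_median_rejected(self):
        with pytest.raises(ValueError):
            viability_filter([50], 0.0, 0.5)


class TestSelectHits:
    def test_compound_at_control_mean_is_not_a_hit(self):
        """A compound sitting exactly on the per-replicate TNFa mean has
        distance 0 and p = 1."""
        tnfa = [[3.0, 5.0], [5.0, 3.0], [4.5, 3.5], [3.5, 4.5]]  # means 4.0, 4.0
        ds = make_mini_dataset(
            lib_rlu={"AT-MEAN": [4.0, 4.0], "LOW": [0.4, 0.4]}, tnfa_rlu=tnfa
        )
        scores, _ = select_hits(ds)
        at_mean = scores.set_index("compound_id").loc["AT-MEAN"]
        assert at_mean["distance"] == pytest.approx(0.0, abs=1e-12)
        assert at_mean["p_value"] == pytest.approx(1.0)
        assert not at_mean["hit"]

    def test_alpha_one_makes_every_compound_significant(self):
        cfg = SyntheticScreenConfig(
            n_library_plates=1, n_replicates=2, compounds_per_plate=30, seed=2
        )
        ds, _ = generate_screen(cfg)
        scores, report = select_hits(ds, alpha=1.0)
        assert report.n_significant == report.n_tested == 30
        assert scores["significant"].all()

    def test_flowchart_counts_are_consistent(self, small_screen):
        dataset, _ = small_screen
        _, report = select_hits(dataset)
        assert report.n_hits == (
            report.n_significant
            - report.n_removed_by_direction
            - report.n_removed_by_viability
        )
        assert report.n_tested == 80

    def test_zero_renilla_well_drops_one_replicate(self):
        """A dead well is routed out of scoring; the compound is judged on
        its remaining replicates against a matching-dimension null."""
        tnfa = [[3.0, 5.0], [5.0, 3.0], [4.5, 3.5], [3.5, 4.5]]
        ds = make_mini_dataset(
            lib_rlu={"DEAD1": [4.0, 4.0], "OK": [4.0, 4.0]},
            tnfa_rlu=tnfa,
            renilla_overrides={("DEAD1", 1): 0.0},
        )
        scores, _ = select_hits(ds)
        s = scores.set_index("compound_id")
        assert s.loc["DEAD1", "n_replicates"] == 1
        assert s.loc["OK", "n_replicates"] == 2
        assert np.isfinite(s.loc["DEAD1", "p_value"])

    def test_all_replicates_dead_is_viability_excluded(self):
        tnfa = [[3.0, 5.0], [5.0, 3.0], [4.5, 3.5], [3.5, 4.5]]
        ds = make_mini_dataset(
            lib_rlu={"DEAD2": [4.0, 4.0], "OK": [4.0, 4.0]},
            tnfa_rlu=tnfa,
            renilla_overrides={("DEAD2", 1): 0.0, ("DEAD2", 2): 0.0},
        )
        scores, _ = select_hits(ds)
        s = scores.set_index("compound_id")
        assert not s.loc["DEAD2", "renilla_ok"]
        assert not s.loc["DEAD2", "hit"]
        assert s.loc["DEAD2", "n_replicates"] == 0

    def test_strong_inhibitor_is_called(self):
        tnfa = [[1.05, 0.95], [0.9, 1.1], [1.0, 1.0], [1.05, 0.95]]
        ds = make_mini_dataset(
            lib_rlu={"STRONG": [0.2, 0.25], "NULL": [1.0, 1.0]}, tnfa_rlu=tnfa
        )
        # the mini plate's 4-well null resolves p only down to 1/5
        scores, report = select_hits(ds, alpha=0.25)
        s = scores.set_index("compound_id")
        assert s.loc["STRONG", "hit"]
        assert s.loc["STRONG", "inhibits"]
        assert not s.loc["NULL", "hit"]
        assert report.n_hits == 1

    def test_spike_in_recovery_single_screen(self):
        """Strong inhibitors are recovered and cytotoxic compounds flagged."""
        cfg = SyntheticScreenConfig(seed=123)
        ds, truth = generate_screen(cfg)
        scores, _ = select_hits(ds)
        merged = scores.merge(truth, on="compound_id")
        true_pos = merged[
            (merged["true_inhibition_fraction"] > 0) & ~merged["is_cytotoxic"]
        ]
        assert true_pos["hit"].mean() >= 0.95
        cyto = merged[merged["is_cytotoxic"]]
        assert (~cyto["renilla_ok"]).mean() >= 0.95

    def test_bh_option_never_adds_hits(self, small_screen):
        dataset, _ = small_screen
        raw, _ = select_hits(dataset)
        adj, _ = select_hits(dataset, bh=True)
        assert adj["hit"].sum() <= raw["hit"].sum()
        assert "p_adjusted" in adj.columns

    def test_half_normal_null_method_runs(self, small_screen):
        dataset, _ = small_screen
        scores, _ = select_hits(dataset, null_method="half_normal")
        assert scores["p_value"].between(0, 1).all()

    def test_pooled_null_option(self, small_screen):
        dataset, _ = small_screen
        caller = HitCaller(pool_plates=True).fit(dataset)
        pooled_n = {m.n for m in caller.null_models_.values()}
        assert pooled_n == {80}  # 40 TNFa wells x 2 plates


class TestZPrime:
    def test_separated_controls_give_positive_z_prime(self):
        cfg = SyntheticScreenConfig(n_library_plates=1, measurement_cv=0.05, seed=1)
        ds, _ = generate_screen(cfg)
        caller = HitCaller().fit(ds)
        z = z_prime_factor(caller.normalized_)
        assert 0.0 < z < 1.0
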