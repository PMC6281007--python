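"""Construct derivation: dual-period splitting, window containment,
eligibility, the response-coverage rule and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acekit as ak
from acekit.derivation import DerivationError, ItemTable, merge_dual_period
from conftest import brute_force_constructs, random_item_table


def _dual_table(codes):
    data = pd.DataFrame({"d": codes}, index=range(len(codes)), dtype=float)
    meta = pd.DataFrame.from_dict(
        {
            "d": {
                "ace_category": "bullying", "window_start": 6, "window_end": 7,
                "report_age": 10, "reporter": "mother", "timing": "prospective",
                "dual_period": True, "second_window_start": 8,
                "second_window_end": 9,
            }
        },
        orient="index",
    )
    return ItemTable(data=data, meta=meta)


class TestDualPeriodSplit:
    @pytest.mark.parametrize(
        "code,expected",
        [(1, (1.0, 0.0)), (2, (0.0, 1.0)), (3, (1.0, 1.0)), (4, (0.0, 0.0))],
    )
    def test_four_level_mapping(self, code, expected):
        """first-only/second-only/both/neither map to the dummy pairs."""
        split = ak.split_dual_period(_dual_table([code]))
        assert (split.data.iloc[0]["d__p1"], split.data.iloc[0]["d__p2"]) == expected

    def test_missing_propagates_to_both_dummies(self):
        split = ak.split_dual_period(_dual_table([np.nan]))
        assert split.data.iloc[0].isna().all()

    def test_split_windows_and_meta(self):
        split = ak.split_dual_period(_dual_table([3]))
        assert split.meta.at["d__p1", "window_start"] == 6
        assert split.meta.at["d__p1", "window_end"] == 7
        assert split.meta.at["d__p2", "window_start"] == 8
        assert split.meta.at["d__p2", "window_end"] == 9
        assert not split.meta["dual_period"].any()

    def test_bad_coding_names_item(self):
        with pytest.raises(DerivationError, match="'d'"):
            ak.split_dual_period(_dual_table([7]))

    def test_full_dictionary_gives_582_columns(self, complete_cohort):
        """541 questions with 41 dual-period split into 582 analysis vars."""
        items = ak.apply_dictionary(complete_cohort.responses, complete_cohort.dictionary)
        assert items.n_items == 541
        split = ak.split_dual_period(items)
        assert split.n_items == 582

    @given(st.lists(st.sampled_from([1, 2, 3, 4]), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=50)
    def test_split_merge_roundtrip(self, codes):
        """The four-level coding is exactly recoverable from the dummy pair."""
        split = ak.split_dual_period(_dual_table(codes))
        merged = merge_dual_period(split.data["d__p1"], split.data["d__p2"])
        assert merged.tolist() == [float(c) for c in codes]


class TestSelectWindow:
    def _items(self, windows):
        cols = {f"i{k}": [1.0] for k in range(len(windows))}
        meta = {
            f"i{k}": {
                "ace_category": "bullying", "window_start": ws, "window_end": we,
                "report_age": 10, "reporter": "mother", "timing": "prospective",
                "dual_period": False, "second_window_start": None,
                "second_window_end": None,
            }
            for k, (ws, we) in enumerate(windows)
        }
        return ItemTable(
            data=pd.DataFrame(cols, index=[1]),
            meta=pd.DataFrame.from_dict(meta, orient="index"),
        )

    @pytest.mark.parametrize(
        "window,target,kept",
        [
            ((0, 11), (0, 8), False),  # spans wider than the target -> excluded
            ((6, 7), (0, 8), True),
            ((0, 16), (0, 16), True),  # boundary containment
            ((16, 18), (0, 16), False),
        ],
    )
    def test_containment(self, window, target, kept):
        out = ak.select_window(self._items([window]), *target)
        assert out.n_items == (1 if kept else 0)

    def test_monotone_in_target_window(self):
        """Enlarging the target never drops a retained item."""
        rng = np.random.default_rng(2)
        windows = [
            tuple(sorted(rng.integers(0, 19, 2).tolist())) for _ in range(40)
        ]
        items = self._items(windows)
        prev: set = set()
        for end in range(0, 19):
            kept = set(ak.select_window(items, 0, end).data.columns)
            assert prev <= kept
            prev = kept

    def test_rejects_unsplit_dual(self):
        with pytest.raises(DerivationError, match="split"):
            ak.select_window(_dual_table([1]), 0, 16)


class TestEligibility:
    def _items(self, answered, total):
        vals = [1.0] * answered + [np.nan] * (total - answered)
        data = pd.DataFrame([vals], columns=[f"i{k}" for k in range(total)], index=[1])
        meta = pd.DataFrame.from_dict(
            {
                f"i{k}": {
                    "ace_category": "bullying", "window_start": 0, "window_end": 16,
                    "report_age": 10, "reporter": "mother", "timing": "prospective",
                    "dual_period": False, "second_window_start": None,
                    "second_window_end": None,
                }
                for k in range(total)
            },
            orient="index",
        )
        return ItemTable(data=data, meta=meta)

    def test_55_of_541_retained(self):
        assert ak.eligibility_filter(self._items(55, 541)).n_participants == 1

    def test_54_of_541_dropped_exact_rational(self):
        """54/541 = 0.0998... < 1/10, decided in exact arithmetic."""
        from fractions import Fraction

        assert Fraction(54, 541) < Fraction(1, 10)
        assert ak.eligibility_filter(self._items(54, 541)).n_participants == 0

    def test_full_coverage_threshold(self):
        assert ak.eligibility_filter(self._items(9, 10), min_fraction=1.0).n_participants == 0
        assert ak.eligibility_filter(self._items(10, 10), min_fraction=1.0).n_participants == 1


class TestDeriveConstruct:
    def _items(self, rows, n_items):
        data = pd.DataFrame(rows, columns=[f"i{k}" for k in range(n_items)], dtype=float)
        meta = pd.DataFrame.from_dict(
            {
                f"i{k}": {
                    "ace_category": "sexual_abuse", "window_start": 0,
                    "window_end": 16, "report_age": 10, "reporter": "mother",
                    "timing": "prospective", "dual_period": False,
                    "second_window_start": None, "second_window_end": None,
                }
                for k in range(n_items)
            },
            orient="index",
        )
        return ItemTable(data=data, meta=meta)

    def test_half_coverage_is_enough(self):
        """Twelve items, six answered all-negative: derivable, construct 0."""
        row = [0.0] * 6 + [np.nan] * 6
        col, info = ak.derive_construct(self._items([row], 12), "sexual_abuse")
        assert col.iloc[0] == 0.0
        assert info["answered"].iloc[0] == 6

    def test_below_half_coverage_is_missing(self):
        """Five of twelve answered: construct missing even with a positive."""
        row = [1.0, 0.0, 0.0, 0.0, 0.0] + [np.nan] * 7
        col, _ = ak.derive_construct(self._items([row], 12), "sexual_abuse")
        assert np.isnan(col.iloc[0])

    def test_any_positive_coding(self):
        row = [0.0] * 5 + [1.0] + [np.nan] * 4
        col, _ = ak.derive_construct(self._items([row], 10), "sexual_abuse")
        assert col.iloc[0] == 1.0

    def test_majority_coding_option(self):
        row = [0.0] * 5 + [1.0] + [np.nan] * 4
        col, _ = ak.derive_construct(
            self._items([row], 10), "sexual_abuse", coding="majority"
        )
        assert col.iloc[0] == 0.0  # 1 of 6 answered positive is not a majority

    def test_zero_items_flagged_all_missing(self):
        items = self._items([[0.0]], 1)
        col, info = ak.derive_construct(items, "bullying")
        assert col.isna().all()
        assert info["empty"]


class TestDeriveAll:
    def test_matches_bruteforce_on_random_tables(self):
        """Vectorised derivation equals the explicit loop oracle."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            items, aces = random_item_table(rng, n_participants=15)
            got = ak.derive_all(items, window=(0, 16), categories=aces)
            expected = brute_force_constructs(items, aces)
            pd.testing.assert_frame_equal(got.data, expected)

    def test_complete_input_no_missing_constructs(self, complete_cohort):
        items = ak.split_dual_period(
            ak.apply_dictionary(complete_cohort.responses, complete_cohort.dictionary)
        )
        cons = ak.derive_all(items, window=(0, 16))
        assert not cons.data.isna().any().any()

    def test_all_missing_input_all_missing_constructs(self):
        rng = np.random.default_rng(0)
        items, aces = random_item_table(rng, n_participants=5, missing=1.0)
        items.data[:] = np.nan
        cons = ak.derive_all(items, window=(0, 16), categories=aces)
        assert cons.data.isna().all().all()

    def test_prevalence_on_complete_data_is_any_positive_fraction(self):
        rng = np.random.default_rng(3)
        items, aces = random_item_table(rng, n_participants=60, missing=0.0)
        cons = ak.derive_all(items, window=(0, 18), categories=aces)
        for ace in aces:
            ids = [c for c in items.data.columns if items.meta.at[c, "ace_category"] == ace]
            direct = (items.data[ids].sum(axis=1) >= 1).mean()
            assert cons.data[ace].mean() == pytest.approx(direct)

    def test_non_missing_counts_reported(self, mar_constructs):
        n = mar_constructs.non_missing_n()
        assert (n <= len(mar_constructs.data)).all()
        assert (n > 0).all()
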