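"""OKS scoring, severity bands, EQ-5D-5L profiles and value-set machinery."""

import numpy as np
import pandas as pd
import pytest

from oksmap.instruments import (
    DOMAINS,
    EQProfile,
    ValueSet,
    bundled_value_set_path,
    bundled_value_sets,
    classify_severity,
    enumerate_profiles,
    read_value_set,
    total_oks,
    utility,
    write_value_set,
)


class TestOKSScoring:
    @pytest.mark.parametrize(
        "items, expected",
        [([0] * 12, 0), ([4] * 12, 48), ([4] * 11 + [0], 44), ([2] * 12, 24)],
    )
    def test_total(self, items, expected):
        assert total_oks(items) == expected

    @pytest.mark.parametrize("bad", [[5] + [0] * 11, [-1] + [0] * 11, [0] * 11, [0] * 13])
    def test_invalid_responses_rejected(self, bad):
        with pytest.raises(ValueError):
            total_oks(bad)

    def test_severity_bands_partition_full_range(self):
        expected = {
            range(0, 20): "severe",
            range(20, 30): "moderate",
            range(30, 40): "mild",
            range(40, 49): "very_mild",
        }
        for band, name in expected.items():
            for score in band:
                assert classify_severity(score) == name

    @pytest.mark.parametrize("score, band", [(45, "very_mild"), (20, "moderate"), (19, "severe")])
    def test_severity_examples(self, score, band):
        assert classify_severity(score) == band

    @pytest.mark.parametrize("bad", [-1, 49])
    def test_severity_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_severity(bad)


class TestProfiles:
    def test_enumeration_covers_all_states(self):
        profiles = enumerate_profiles()
        assert len(profiles) == 3125
        assert profiles[0].code == "11111"
        assert profiles[-1].code == "55555"
        codes = [p.code for p in profiles]
        assert codes == sorted(codes)

    def test_code_level_bijection(self):
        for p in enumerate_profiles():
            assert EQProfile.from_code(p.code).levels == p.levels

    @pytest.mark.parametrize("bad", [(0, 1, 1, 1, 1), (1, 1, 1, 1, 6), (1, 1, 1, 1)])
    def test_invalid_levels_rejected(self, bad):
        with pytest.raises(ValueError):
            EQProfile(tuple(bad))


class TestValueSets:
    def test_full_health_is_one_for_bundled_sets(self, toy_value_sets):
        full = EQProfile((1, 1, 1, 1, 1))
        for vs in toy_value_sets:
            assert utility(full, vs) == pytest.approx(1.0)

    def test_single_decrement_example(self):
        dec = {d: {l: 0.1 * (l - 1) for l in (2, 3, 4, 5)} for d in DOMAINS}
        vs = ValueSet(country="uniform", decrements=dec)
        assert utility(EQProfile((2, 1, 1, 1, 1)), vs) == pytest.approx(0.9)

    def test_additive_lookup_round_trip(self, toy_value_sets):
        additive = toy_value_sets[0]
        lookup = additive.to_lookup()
        for p in enumerate_profiles():
            assert utility(p, lookup) == pytest.approx(utility(p, additive), abs=1e-12)

    def test_zero_decrement_tariff_is_flat(self, tmp_path):
        dec_rows = [{"domain": "constant", "level": 0, "decrement": 1.0}]
        for d in DOMAINS:
            for l in (2, 3, 4, 5):
                dec_rows.append({"domain": d, "level": l, "decrement": 0.0})
        path = tmp_path / "flat.csv"
        pd.DataFrame(dec_rows).to_csv(path, index=False)
        vs = read_value_set(path, "additive")
        assert all(utility(p, vs) == pytest.approx(1.0) for p in enumerate_profiles())

    def test_additive_monotone_under_nonnegative_decrements(self, toy_value_sets):
        vs = toy_value_sets[0]
        rng = np.random.default_rng(3)
        for _ in range(300):
            levels = list(rng.integers(1, 6, size=5))
            base = utility(EQProfile(tuple(levels)), vs)
            for d in range(5):
                if levels[d] < 5:
                    worse = levels.copy()
                    worse[d] += 1
                    assert utility(EQProfile(tuple(worse)), vs) <= base + 1e-12

    def test_truncated_lookup_names_missing_code(self, tmp_path, toy_value_sets):
        lookup = toy_value_sets[0].to_lookup()
        rows = [{"profile_code": c, "utility": u} for c, u in lookup.table.items()]
        dropped = rows.pop(1234)
        path = tmp_path / "truncated.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(ValueError, match=dropped["profile_code"]):
            read_value_set(path, "lookup")

    def test_duplicate_lookup_rows_rejected(self, tmp_path, toy_value_sets):
        lookup = toy_value_sets[0].to_lookup()
        rows = [{"profile_code": c, "utility": u} for c, u in lookup.table.items()]
        rows[10] = rows[11]
        path = tmp_path / "dup.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_value_set(path, "lookup")

    def test_non_numeric_utilities_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = [{"profile_code": p.code, "utility": "x"} for p in enumerate_profiles()]
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-numeric"):
            read_value_set(path, "lookup")

    def test_write_read_round_trip(self, tmp_path, toy_value_sets):
        for vs in toy_value_sets:
            path = tmp_path / f"{vs.country}.csv"
            write_value_set(vs, path)
            back = read_value_set(path, vs.dialect, country=vs.country, tariff_type=vs.tariff_type)
            for p in enumerate_profiles():
                assert utility(p, back) == pytest.approx(utility(p, vs), abs=1e-9)

    def test_missing_profile_in_lookup_errors(self, toy_value_sets):
        lookup = dict(toy_value_sets[0].to_lookup().table)
        vs = ValueSet(country="x", dialect="lookup", table=lookup)
        vs.table = {k: v for k, v in lookup.items() if k != "23451"}
        with pytest.raises(KeyError, match="23451"):
            utility(EQProfile.from_code("23451"), vs)
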