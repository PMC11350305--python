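import pandas as pd
import pytest

from foodenv.environments import (
    EnvironmentAssembler,
    category_share,
    cuisine_frequencies,
    density_by_postcode,
    format_accessibility,
    online_accessibility,
    pct_change,
)
from foodenv.types import MainCategory, MatchResult, NormalizedOutlet, Source

C = MainCategory


class TestPctChange:
    # printed regional (local, hybrid) pairs pin the rounding convention
    @pytest.mark.parametrize("n_local,n_hybrid,expected", [
        (10069, 13758, 137),
        (893, 905, 101),
        (299, 300, 100),
        (8684, 12282, 141),
        (36967, 51470, 139),
    ])
    def test_regional_values(self, n_local, n_hybrid, expected):
        assert pct_change(n_local, n_hybrid) == expected

    def test_round_half_up(self):
        assert pct_change(200, 301) == 151  # 150.5 rounds up

    def test_zero_local_undefined(self):
        assert pct_change(0, 5) is None


class TestCategoryShare:
    def test_printed_shares(self):
        shares = category_share({C.INDEPENDENT_RESTAURANT_CAFE: 17437}, 36967)
        assert shares[C.INDEPENDENT_RESTAURANT_CAFE] == 47.2
        shares = category_share({C.INDEPENDENT_RESTAURANT_CAFE: 8369}, 16158)
        assert shares[C.INDEPENDENT_RESTAURANT_CAFE] == 51.8

    def test_single_category_is_100(self):
        assert category_share({C.BAKERY: 7}, 7) == {C.BAKERY: 100.0}

    def test_shares_sum_to_100_within_rounding(self):
        by_cat = {C.BAKERY: 313, C.SWEETS_EXTRA: 211, C.FRESH_PRODUCE: 97}
        shares = category_share(by_cat, sum(by_cat.values()))
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.5)


class TestAccessibility:
    def test_printed_cells(self):
        assert format_accessibility(online_accessibility(2734, 3273), 1) == "83.5"
        assert format_accessibility(online_accessibility(97, 45), 0) == "216"
        assert format_accessibility(online_accessibility(16158, 36967), 1) == "43.7"

    def test_zero_online(self):
        assert online_accessibility(0, 50) == 0.0
        assert online_accessibility(0, 0) == 0.0


class TestSmallHelpers:
    def test_density_max_maps_to_one(self):
        d = density_by_postcode({"2148": 50, "2000": 10, "2500": 10})
        assert d["2148"] == 1.0
        assert d["2000"] == 0.0

    def test_density_degenerate_all_equal(self):
        assert density_by_postcode({"a": 3, "b": 3}) == {"a": 1.0, "b": 1.0}

    def test_density_hand_scaled(self):
        d = density_by_postcode({"a": 2, "b": 6, "c": 10})
        assert d == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_cuisine_frequencies_ordering(self):
        outlets = [
            _outlet("a", descriptors=["burger"]),
            _outlet("b", descriptors=["burger"]),
            _outlet("c", descriptors=["burger", "sushi"]),
            _outlet("d", descriptors=["asian"]),
        ]
        freqs = cuisine_frequencies(outlets)
        assert freqs == [("burger", 3), ("asian", 1), ("sushi", 1)]

    def test_cuisine_frequencies_empty(self):
        assert cuisine_frequencies([]) == []


def _outlet(sid, suburb="oakvale", postcode="2000", source=Source.LOCAL,
            descriptors=()):
    return NormalizedOutlet(
        source=source, source_id=sid, name_norm=f"outlet {sid}",
        street_number="1", street_name="king", street_type="road",
        suburb_norm=suburb, postcode_norm=postcode,
        descriptors=list(descriptors),
    )


def _match(online_id, local_id):
    return MatchResult(online_id=online_id, local_id=local_id, step=1,
                       name_similarity_jaro=1.0, name_similarity_ratio=100.0,
                       address_similarity_ratio=100.0)


GEO = pd.DataFrame([
    {"suburb": "oakvale", "postcode": "2000", "region": "metro",
     "region_population": 400000, "urban": True, "lat": -33.0, "lon": 150.5},
    {"suburb": "fernwood", "postcode": "2001", "region": "metro",
     "region_population": 400000, "urban": True, "lat": -33.0, "lon": 150.52},
    {"suburb": "riverbend", "postcode": "2800", "region": "plains",
     "region_population": 100000, "urban": False, "lat": -35.0, "lon": 150.5},
])


class TestAssembler:
    def _assembler(self):
        local = [_outlet("g1"), _outlet("g2"), _outlet("g3"),
                 _outlet("g4", suburb="riverbend", postcode="2800")]
        online = [_outlet("u1", source=Source.ONLINE),
                  _outlet("u2", source=Source.ONLINE)]
        # u1 and u2 deliver to oakvale; u1 is the online twin of g1
        delivery = [("u1", "oakvale"), ("u2", "oakvale"), ("u2", "fernwood")]
        return EnvironmentAssembler(local, online, delivery, [_match("u1", "g1")],
                                    GEO)

    def test_hybrid_counts_matched_pair_once(self):
        views = self._assembler().unit_views("2000")
        assert views["local"].n_outlets == 3
        assert views["online"].n_outlets == 2
        # 3 local + 2 online - 1 matched = 4
        assert views["hybrid"].n_outlets == 4

    def test_unit_without_delivery_hybrid_equals_local(self):
        views = self._assembler().unit_views("2800")
        assert views["online"].n_outlets == 0
        assert views["hybrid"].outlet_ids == views["local"].outlet_ids

    def test_hybrid_dominates_local_and_online(self):
        asm = self._assembler()
        for unit in asm.all_units():
            v = asm.unit_views(unit)
            assert v["hybrid"].n_outlets >= v["local"].n_outlets
            assert v["hybrid"].n_outlets >= v["online"].n_outlets

    def test_unknown_postcode_goes_to_reserved_unit(self):
        local = [_outlet("g1", suburb="empty", postcode="0000")]
        asm = EnvironmentAssembler(local, [], [], [], GEO)
        assert asm.unit_views("unknown")["local"].n_outlets == 1

    def test_region_summary_counts_and_pct(self):
        summaries = {s.region: s for s in self._assembler().region_summaries()}
        metro = summaries["metro"]
        assert (metro.n_local, metro.n_online, metro.n_hybrid) == (3, 2, 4)
        assert metro.pct_change == pct_change(3, 4) == 133
        plains = summaries["plains"]
        assert plains.pct_change == 100

    def test_unique_totals(self):
        totals = self._assembler().unique_totals()
        assert totals == {"local": 4, "online": 2, "hybrid": 5}

    def test_category_conservation_per_view(self, noisy_world, geography,
                                            norm_config):
        from foodenv.categorize import CategoryLexicon, categorize_all
        from foodenv.linkage import run_cascade
        from foodenv.normalize import normalize_dataset
        online, local = normalize_dataset(noisy_world["online_rows"],
                                          noisy_world["local_rows"], norm_config)
        matches, _, _ = run_cascade(online, local)
        lex = CategoryLexicon()
        assignments, _ = categorize_all(online, local, matches, lex, lex)
        delivery = [(r.source_id, str(r.extra.get("delivery_suburb", "")).lower())
                    for r in noisy_world["online_rows"]
                    if r.extra.get("delivery_suburb")]
        asm = EnvironmentAssembler(local, online, delivery, matches, geography,
                                   assignments)
        for unit in asm.all_units():
            for view in asm.unit_views(unit).values():
                assert sum(view.by_category.values()) == view.n_outlets

    def test_hybrid_union_equals_truth_oracle(self, zero_noise_world, geography,
                                              norm_config):
        # on the zero-noise world the per-unit hybrid sets must equal a
        # brute-force union computed straight from the truth maps
        from foodenv.linkage import run_cascade
        from foodenv.normalize import normalize_dataset
        from foodenv.synthetic import delivery_suburbs, truth_by_source_id

        online, local = normalize_dataset(zero_noise_world["online_rows"],
                                          zero_noise_world["local_rows"],
                                          norm_config)
        matches, _, _ = run_cascade(online, local)
        delivery = [(r.source_id, str(r.extra.get("delivery_suburb", "")).lower())
                    for r in zero_noise_world["online_rows"]
                    if r.extra.get("delivery_suburb")]
        asm = EnvironmentAssembler(local, online, delivery, matches, geography)

        local_truth = truth_by_source_id(zero_noise_world["local_truth"])
        online_truth = truth_by_source_id(zero_noise_world["online_truth"])
        by_truth = {o.truth_id: o for o in zero_noise_world["universe"]}
        pc_of_suburb = dict(zip(geography["suburb"], geography["postcode"]))
        kept_local_ids = {o.source_id for o in local}

        for pc in geography["postcode"]:
            truth_local = {
                local_truth[rid] for rid in local_truth
                if rid in kept_local_ids and by_truth[local_truth[rid]].postcode == pc
            }
            truth_online = {
                online_truth[pid] for pid in online_truth
                if any(pc_of_suburb[s["suburb"]] == pc
                       for s in delivery_suburbs(by_truth[online_truth[pid]],
                                                 geography))
            }
            expected_hybrid = len(truth_local | truth_online)
            got = asm.unit_views(pc)["hybrid"].n_outlets
            assert got == expected_hybrid, pc
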