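import string

import pytest
from hypothesis import given
from hypothesis import strategies as st

from foodenv.config import NormalizationConfig
from foodenv.normalize import (
    MISSING_POSTCODE,
    MISSING_STREET_NUMBER,
    MISSING_SUBURB,
    REJECT,
    compute_postcode_suburb_stats,
    compute_suburb_postcode_stats,
    dedupe_online,
    filter_local,
    impute_missing,
    normalize_listing,
    normalize_name,
    normalize_suburb,
    parse_street_address,
)
from foodenv.types import NormalizedOutlet, RawOutletListing, Source, Status

CFG = NormalizationConfig(suburb_list=["parramatta", "oakvale", "brighton le sands"])


class TestNormalizeSuburb:
    def test_lowercases(self):
        assert normalize_suburb("SYDNEY", "NSW", CFG) == "sydney"

    def test_out_of_state_rejected(self):
        assert normalize_suburb("Canberra", "ACT", CFG) is REJECT

    def test_dash_removal_keeps_spacing_variants_distinct(self):
        # the two spellings of one suburb deliberately stay unequal: dashes
        # are dropped but spaces are kept, mirroring the source inconsistency
        a = normalize_suburb("Brighton-Le-Sands", "NSW", CFG)
        b = normalize_suburb("Brighton Le Sands", "NSW", CFG)
        assert a == "brightonlesands"
        assert b == "brighton le sands"
        assert a != b

    def test_missing_returns_none(self):
        assert normalize_suburb(None, "NSW", CFG) is None
        assert normalize_suburb("   ", "NSW", CFG) is None

    def test_missing_state_not_rejected(self):
        assert normalize_suburb("Sydney", None, CFG) == "sydney"


class TestNormalizeName:
    def _norm(self, name):
        return normalize_name(name, CFG.centre_list, CFG.suburb_list,
                              CFG.city_tokens + CFG.state_tokens, CFG.petrol_list)

    @pytest.mark.parametrize("raw,expected", [
        ("Mario's Pizza!!", "marios pizza"),
        ("Shawarma Today", "shawarma today"),
        ("Noodle House Sydney NSW", "noodle house"),
        ("Café Crème", "cafe creme"),
        ("Fish & Chips Co", "fish and chips co"),
        ("Westfield Sushi Bar", "sushi bar"),       # centre token removed
        ("Golden Wok Parramatta", "golden wok"),    # suburb token removed
        ("7 Eleven Kitchen", "7 eleven kitchen"),   # numerals retained
    ])
    def test_examples(self, raw, expected):
        assert self._norm(raw) == expected

    def test_empty_after_stripping_flagged_as_empty_string(self):
        assert self._norm("Sydney NSW") == ""


class TestParseStreetAddress:
    # hand-parsed fixture set
    @pytest.mark.parametrize("raw,suburb,postcode,state,expected", [
        ("Shop 12, Westfield, 1 Main Street Parramatta NSW 2150",
         "parramatta", "2150", "NSW", ("1", "main", "street")),
        ("5 King Road", None, None, None, ("5", "king", "road")),
        ("King Road", None, None, None, (MISSING_STREET_NUMBER, "king", "road")),
        ("Unit 3, 45 Ocean Pde", "brighton", "2216", "NSW",
         ("45", "ocean", "parade")),
        ("12 Station St Oakvale 2001", "oakvale", "2001", None,
         ("12", "station", "street")),
        ("Level 2, Central Park, 28 Broadway", None, None, None,
         ("28", "", "unknown")),  # "broadway" is not in the street-type vocabulary
        ("7-9 George St", None, None, None, ("79", "george", "street")),
    ])
    def test_hand_parsed_fixtures(self, raw, suburb, postcode, state, expected):
        got = parse_street_address(raw, suburb, postcode, state,
                                   CFG.centre_list, CFG.street_types,
                                   CFG.state_tokens)
        if expected[1] == "" and expected[2] == "unknown":
            # unparseable remainder: street name carries whatever is left
            assert got[0] == expected[0]
            assert got[2] == "unknown"
        else:
            assert got == expected

    def test_missing_number_sets_sentinel(self):
        number, name, stype = parse_street_address(
            "Harbour Street", None, None, None, [], CFG.street_types)
        assert number == MISSING_STREET_NUMBER
        assert (name, stype) == ("harbour", "street")


def _rec(**kw):
    base = dict(source=Source.LOCAL, source_id="x1", name_norm="cafe one",
                street_number="5", street_name="king", street_type="road",
                suburb_norm="sydney", postcode_norm="2000")
    base.update(kw)
    return NormalizedOutlet(**base)


class TestImputation:
    STATS = {"2000": "sydney", "2148": "blacktown"}

    def test_modal_suburb_for_known_postcode(self):
        # e.g. 2000 hosts both a dominant and a minority suburb; the modal
        # one fills the gap
        rec = _rec(suburb_norm="", postcode_norm="2000")
        out = impute_missing(rec, self.STATS)
        assert out.suburb_norm == "sydney"
        assert out.imputed_suburb and not out.imputed_postcode

    def test_both_missing_sentinels(self):
        rec = _rec(suburb_norm="", postcode_norm="")
        out = impute_missing(rec, self.STATS)
        assert (out.suburb_norm, out.postcode_norm) == (MISSING_SUBURB,
                                                        MISSING_POSTCODE)
        assert out.imputed_suburb and out.imputed_postcode

    def test_unseen_postcode_keeps_postcode_with_empty_suburb(self):
        rec = _rec(suburb_norm="", postcode_norm="2999")
        out = impute_missing(rec, self.STATS)
        assert out.suburb_norm == MISSING_SUBURB
        assert out.postcode_norm == "2999"

    def test_nothing_missing_is_identity(self):
        rec = _rec()
        out = impute_missing(rec, self.STATS)
        assert out is rec

    def test_missing_postcode_takes_modal_for_suburb(self):
        rec = _rec(suburb_norm="blacktown", postcode_norm="")
        out = impute_missing(rec, self.STATS, {"blacktown": "2148"})
        assert out.postcode_norm == "2148"
        assert out.imputed_postcode

    def test_modal_tables_tie_break_lexicographically(self):
        recs = [_rec(source_id=str(i), suburb_norm=s, postcode_norm="2001")
                for i, s in enumerate(["beta", "alpha"])]
        assert compute_postcode_suburb_stats(recs) == {"2001": "alpha"}
        recs2 = [_rec(source_id=str(i), suburb_norm="sydney", postcode_norm=p)
                 for i, p in enumerate(["2002", "2001"])]
        assert compute_suburb_postcode_stats(recs2) == {"sydney": "2001"}


def _raw(source_id, suburb="Sydney", delivery=None, status=Status.OPEN,
         tags=("cafe",), source=Source.ONLINE, address="5 King Road"):
    extra = {"delivery_suburb": delivery} if delivery else {}
    return RawOutletListing(
        source=source, source_id=source_id, name="Cafe One",
        street_address=address, suburb=suburb, state="NSW", postcode="2000",
        latitude=None, longitude=None, category_descriptors=list(tags),
        status=status, extra=extra,
    )


class TestDedupeOnline:
    def test_seven_rows_three_ids(self):
        rows = [_raw("a", delivery="Newtown"), _raw("a", delivery="Sydney"),
                _raw("a", delivery="Glebe"), _raw("b", delivery="Glebe"),
                _raw("b", delivery="Sydney"), _raw("c", delivery="Erko"),
                _raw("c", delivery="Glebe")]
        out = dedupe_online(rows)
        assert [r.source_id for r in out] == ["a", "b", "c"]

    def test_representative_prefers_physical_suburb_row(self):
        rows = [_raw("a", delivery="Newtown"), _raw("a", delivery="Sydney")]
        assert dedupe_online(rows)[0].extra["delivery_suburb"] == "Sydney"

    def test_falls_back_to_first_row_in_input_order(self):
        rows = [_raw("a", delivery="Newtown"), _raw("a", delivery="Glebe")]
        assert dedupe_online(rows)[0].extra["delivery_suburb"] == "Newtown"

    def test_conflicting_addresses_keep_modal(self):
        rows = [_raw("a", address="5 King Road"), _raw("a", address="5 King Road"),
                _raw("a", address="9 Queen Street")]
        assert dedupe_online(rows)[0].street_address == "5 King Road"


class TestFilterLocal:
    def test_nonfood_only_row_removed(self):
        rows = [_raw("a", tags=("jewelry store",), source=Source.LOCAL)]
        assert filter_local(rows, CFG.nonfood_categories) == []

    def test_open_cafe_retained(self):
        rows = [_raw("a", tags=("cafe",), source=Source.LOCAL)]
        assert len(filter_local(rows, CFG.nonfood_categories)) == 1

    def test_permanently_closed_removed(self):
        rows = [_raw("a", status=Status.PERMANENTLY_CLOSED, source=Source.LOCAL)]
        assert filter_local(rows, CFG.nonfood_categories) == []

    def test_duplicate_directory_ids_collapse(self):
        rows = [_raw("a", source=Source.LOCAL), _raw("a", source=Source.LOCAL)]
        assert len(filter_local(rows, CFG.nonfood_categories)) == 1


# ---------------------------------------------------------------------------
# idempotence properties

_texty = st.text(alphabet=string.ascii_letters + string.digits + " -'&!.,éü",
                 max_size=40)


@given(_texty)
def test_normalize_suburb_idempotent(s):
    once = normalize_suburb(s, "NSW", CFG)
    if once is None or once is REJECT:
        return
    assert normalize_suburb(once, "NSW", CFG) == once


@given(_texty)
def test_normalize_name_idempotent(s):
    args = (CFG.centre_list, CFG.suburb_list,
            CFG.city_tokens + CFG.state_tokens, CFG.petrol_list)
    once = normalize_name(s, *args)
    assert normalize_name(once, *args) == once


@given(_texty)
def test_parse_street_address_idempotent_on_its_own_output(s):
    number, name, stype = parse_street_address(s, None, None, None,
                                               CFG.centre_list, CFG.street_types)
    rebuilt = " ".join(p for p in (number, name, stype if stype != "unknown" else "")
                       if p).strip()
    again = parse_street_address(rebuilt, None, None, None,
                                 CFG.centre_list, CFG.street_types)
    assert again == (number, name, stype)


def test_normalize_listing_preserves_source_and_id():
    raw = _raw("keep-me", source=Source.ONLINE)
    out = normalize_listing(raw, CFG)
    assert out.source is Source.ONLINE
    assert out.source_id == "keep-me"
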