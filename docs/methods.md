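# Methods

This note documents the procedures implemented in `foodenv`, the parameters
that matter, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## Record representations

Rows move through four representations: the synthetic ground truth
(`GroundTruthOutlet`), the as-scraped row (`RawOutletListing`), the cleaned
record (`NormalizedOutlet`) and the analysis outputs (`MatchResult`,
`CategoryAssignment`, `EnvironmentView`, `RegionSummary`). Normalization never
alters `source` or `source_id`, and every cleaning operation is idempotent —
both properties are enforced by tests.

## Cleaning and imputation

* **Suburbs** are lowercased with dashes/quotes (and other specials) removed
  but spaces kept, so differently spaced spellings of one suburb remain
  distinct. This is deliberate: it reproduces a real failure mode of listing
  data, and the unmatched audit reports such pairs as `suburb_inconsistency`
  rather than silently merging them. Rows whose state lies outside the target
  state list are rejected outright; a missing state is not grounds for
  rejection.
* **Names** are reduced to lowercase alphanumerics and single spaces, after
  de-accenting (`café → cafe`) and rewriting `&` to `and` (so "Fish & Chips"
  meets "Fish and Chips"). Numerals are retained. Whole-word tokens are then
  removed in the fixed order centre → petrol station → suburb → city → state;
  the order is a convention (it is not derivable from first principles) and
  longer phrases are removed before shorter ones within each group. A name
  that strips to nothing is kept as an empty string and logged for review.
* **Street addresses** drop embedded suburb/postcode/state copies, then
  shopping-centre/building phrases, then leading unit designators
  (`shop 12`, `level 3`, …), and the remainder is split into a leading number
  token, a street name, and a trailing street-type token from a closed
  vocabulary that maps common abbreviations to full words (`st → street`,
  `rd → road`). An unrecognized trailing token leaves `street_type` as
  `unknown` with the remainder as the street name. A missing leading number is
  imputed as the sentinel `12345`.
* **Missing suburb/postcode**: the modal suburb per postcode (ties broken
  lexicographically) is computed over the *combined* dataset and fills missing
  suburbs; both missing become `empty` / `0000`. The symmetric case — postcode
  missing with suburb present — is not covered by the cleaning rules the
  pipeline descends from, so the package applies the mirrored rule (modal
  postcode per suburb, falling back to `0000` for a suburb seen nowhere else).
* **Deduplication**: the online view carries one row per delivery suburb; one
  representative per platform ID is kept, preferring the row whose delivery
  suburb equals the physical suburb, else the first row in input order.
  Conflicting physical addresses under one ID keep the modal address and log a
  warning. The directory view drops permanently closed rows and rows whose
  category tags all belong to the non-food list.

## Matching cascade

The 15 steps require the equality sets listed in `linkage._STEP_FIELDS`.
Numbered choices:

* **One-to-one greedy order.** The sources do not dictate whether matching is
  one-to-one; the package imposes one-to-one greedy matching in stable sorted
  order of (online id, local id), because matched-count semantics implicitly
  pair each outlet once and reproducibility requires a total order. Ties among
  equally eligible locals break by higher name edit-ratio, then smaller local
  id. Consequences verified by tests: permuting input rows never changes the
  match set, and deleting later steps never changes earlier matches.
* **Thresholds.** Steps 10–11 demand a name edit-ratio ≥ 83 (0–100 scale).
  Steps 12–15, read literally ("same postcode", "same suburb", …), would match
  nearly arbitrary pairs; they are therefore additionally constrained to the
  dual similarity thresholds (name and address, Jaro ≥ 0.90 *and* edit ratio
  ≥ 90), the same pair of constraints applied by the final similarity pass
  that runs after step 15.
* **Similarity measures.** Jaro similarity (0–1) and a normalized edit ratio
  (0–100) computed from the Levenshtein distance with substitution cost 2,
  i.e. `ratio = 200·LCS/(|a|+|b|)`. Equal strings score (1, 100); an empty
  string against a non-empty one scores (0, 0). Both are implemented in
  `foodenv.similarity` and validated against hand-computed values and an
  independent LCS oracle in the tests.
* **Address string** for similarity purposes is
  `"{street_number} {street_name} {street_type}"`.

The cascade is checked for exact equality against a brute-force reference
implementation (all pairs, all steps, no blocking) on synthetic instances with
several hundred outlets per side.

## Categorization

A franchise is a brand — identical normalized name — with **strictly more
than 10** distinct physical locations (distinct street number + street name +
suburb) across both datasets, matched pairs counted once. The boundary is
exercised in tests: 10 locations is not a franchise, 11 is. Franchise outlets
take the `takeaway_franchise` category plus a subtype (dessert, bakery, juice,
healthy, unhealthy) from a config lexicon; brands absent from the lexicon are
subtyped from their pooled descriptors with keyword precedence dessert →
bakery → juice → healthy, defaulting to unhealthy.

Non-franchise outlets are scored from a descriptor → (category, weight)
lexicon. Weights default to 2, with prominence adjustments (e.g. `fast food`
= 4) and niche demotions (e.g. `japanese set item` = 1); multi-category
descriptors (`grocer`, `hotel`, `restaurant`) contribute to every mapped
category. The shipped lexicon contains every explicitly documented mapping
plus the descriptor vocabulary used by the synthetic generator; real
deployments are expected to extend it via config, since full source
vocabularies run to hundreds of descriptors.

Score ties go to the category that is rarer globally. The global frequency
table is computed once, up front, from unique-maximum assignments only (tied
outlets contribute nothing), then frozen; a residual tie falls back to a fixed
category order. Matched local outlets inherit their online twin's category
(`assignment_source = transferred`); an all-zero score yields the `NA`
sentinel.

## Environments and statistics

Per unit: local = physically located outlets; online = unique platform outlets
deliverable into the unit (membership comes from delivery rows, not physical
location); hybrid = union with matched online outlets collapsed onto their
local twin, hence `|hybrid| ≥ max(|local|, |online|)` always. Outlets whose
postcode imputed to `0000` land in a reserved `unknown` unit so totals stay
conserved. Regional counts union their postcodes' sets; state-wide unique
totals deduplicate by outlet id, so per-unit online counts may legitimately
sum to more than the unique online total (delivery duplication).

Rounding conventions, pinned by tests against published cell values: integer
percents are round-half-up (`pct_change(10069, 13758) = 137`); category shares
are half-up at one decimal (`17437/36967 → 47.2`); accessibility is computed
exactly and exposed at both printed precisions (`83.5` at one decimal, `216`
as an integer) because the published table mixes the two. Densities are
min-max scaled per postcode; the degenerate all-equal case maps every postcode
to 1.0.

## Synthetic data

The generator emulates the *structure* of scraped listing data, not any real
place:

* a deterministic geography of urban and rural regions, suburbs on planar
  grids (2 km spacing urban, 8 km rural, regions ~110 km apart so delivery
  radii never straddle regions), one postcode per suburb;
* distances via the equirectangular approximation
  `d = R·sqrt(Δφ² + (cos φ̄ · Δλ)²)`, R = 6371.0088 km — centimetre-exactness
  is irrelevant at suburb scale and the approximation keeps the delivery-list
  oracle exact;
* franchise brands planted at exact configured location counts (defaults
  straddle the >10 boundary), independents drawn from a category mix dominated
  by independent restaurants/cafes as observed in real directories;
* platform participation Bernoulli per outlet, 0.6 urban vs 0.1 rural by
  default, radius 3 km (platforms extend reach roughly three times the
  traditional 1 km neighborhood); delivery suburb lists are *derived* from the
  radius, never sampled, so expected row counts are exactly checkable;
* noise modes per row: missing suburb/postcode/both/street-number,
  shopping-centre prefixes, suburb/city/state tokens embedded in names and
  addresses, case shuffles, punctuation; contaminant non-food and
  permanently-closed rows injected into the directory view (defaults 0.30 and
  0.10, emulating directories where roughly a third of raw rows fall outside
  the food environment);
* one global seed drives per-row substreams keyed by row index
  (`numpy.random.SeedSequence` spawn keys), so outputs are byte-identical for
  a fixed seed and insertion order cannot affect noise;
* food outlets are generated with unique (name, suburb, street) triples —
  realistic (a chain does not open two branches on one street of one suburb)
  and necessary for distinct physical locations to remain distinguishable at
  the granularity the matching steps use.

What it does **not** emulate: real suburb/brand names, search-term coverage
artifacts, partial scrapes, geocoding error, menu content, or malformed
column shifts (the audit detects the latter, and tests construct such rows
directly). Passing tests on this generator therefore demonstrate the
*pipeline logic* — linkage correctness, filter recovery, statistic arithmetic
— not the field accuracy of any particular scrape.

## Numerical and degenerate-input choices

* Percent rounding uses `decimal` with ROUND_HALF_UP, never binary-float
  `round`.
* `pct_change` with zero local outlets is undefined and reported missing.
* Empty match inputs return empty results; duplicate ids in match inputs are a
  hard error (upstream dedupe violated).
* An outlet whose delivery radius covers no suburb midpoint emits exactly one
  row for its home suburb.
* Modal-table ties (suburb per postcode, postcode per suburb, modal address in
  dedupe) always break lexicographically.

## Known limitations

* The shipped centre list, street-type vocabulary and category lexicon are
  stand-ins sized for the synthetic world; production use requires the
  region-specific lists.
* Self-reported descriptors can mislead the scorer (a fast-food chain tagging
  itself "Healthy"); no correction is attempted.
* The matching cascade is deterministic by design — no probabilistic
  (Fellegi–Sunter) linkage model is provided.
* Suburb-spacing inconsistencies ("brighton le sands" vs "brightonlesands")
  are surfaced by the audit, not repaired.
* Only point-geometry GeoJSON is exported (postcode centroids); boundary
  polygons are out of scope.
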