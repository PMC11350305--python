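# foodenv

Online food delivery platforms let outlets serve customers far beyond their
street address, so the food environment a resident can actually reach is no
longer just the outlets physically nearby. `foodenv` is a Python package for
public-health nutrition surveillance that quantifies this *digitalization of
local food environments*: it takes noisy business-listing data from two
sources — a local directory view (outlets physically located somewhere) and a
delivery-platform view (outlets that deliver into a suburb) — and produces,
per postcode and region, the **local**, **online**, and **hybrid** food
environments together with their healthfulness composition.

It is aimed at researchers who work with scraped outlet listings and need the
whole chain to be reproducible and testable: cleaning rules, record linkage,
category assignment, and the summary statistics.

## What it computes

Given listings from the two sources, the pipeline:

1. **Cleans and parses** each row: lowercasing and punctuation stripping,
   removal of shopping-centre/petrol/suburb/city/state tokens from names,
   street-address parsing into (number, name, type), and imputation of missing
   fields (modal suburb per postcode; sentinels `empty` / `0000` / `12345`).
2. **Deduplicates**: one row per platform outlet ID on the online side
   (platform listings repeat once per delivery suburb); drops permanently
   closed and non-food rows on the directory side.
3. **Links** the two sources with a deterministic 15-step matching cascade.
   Steps 1–9 require exact equality of the normalized name plus a shrinking
   set of address fields; steps 10–11 relax the name to an edit-ratio
   similarity of at least 83 (0–100 scale); steps 12–15 and a final pass
   require name *and* address similarity to clear dual thresholds on both the
   Jaro scale (≥ 0.90) and the edit-ratio scale (≥ 90). Matching is one-to-one
   and order-independent, and every unmatched online outlet is classified into
   an error taxonomy (centre-address residue, malformed fields, suburb-naming
   inconsistencies, near-miss names, no candidate).
4. **Categorizes** outlets into nine main categories (takeaway franchise,
   independent takeaway, independent restaurant/cafe, supermarket/grocer,
   fresh produce, sandwich/salad, sweets/extra, bakery, convenience/petrol,
   plus an alcohol-retailer auxiliary). A *franchise* is a brand with more
   than 10 distinct locations across both datasets. Non-franchise outlets are
   scored from their category descriptors: descriptor *d* contributes weight
   w(d, c) to each mapped category c (base weight 2, prominent descriptors 4,
   niche ones 1), and the outlet takes the category with the highest
   cumulative score, `argmax_c Σ_d w(d, c)`; ties go to the globally rarer
   category. Matched local outlets inherit their online twin's category.
5. **Assembles environments** per geographic unit *u*: local(u) = outlets
   located in *u*; online(u) = unique platform outlets deliverable into *u*;
   hybrid(u) = local(u) ∪ online(u) with matched pairs counted once. The
   headline statistic is the percent change `round(100 · |hybrid| / |local|)`,
   plus one-decimal category shares, per-category online accessibility
   (`100 · n_online / n_local`, legitimately above 100 at times), cuisine
   descriptor frequencies (word-cloud payload), and min-max scaled outlet
   densities per postcode (choropleth payload).

Because scraped sources are ephemeral, the package ships a first-class
**synthetic-data module**: it generates a ground-truth outlet universe on a
synthetic geography and renders both noisy views (missing fields,
shopping-centre prefixes, embedded suburb/state/postcode tokens, case and
punctuation noise, non-food and closed contaminant rows, urban-skewed
platform participation, one online row per delivery suburb) together with a
truth map, so linkage precision/recall and every filter can be verified
exactly.

## Worked example

```python
from foodenv import CategoryLexicon, score_categories, assign_main_category, pct_change

scores = score_categories(["comfort food", "burger", "salad"], CategoryLexicon())
print({c.value: s for c, s in scores.items()})
# {'independent_takeaway': 4, 'sandwich_salad': 2}

category, tie_broken = assign_main_category(scores, {})
print(category.value)       # independent_takeaway

print(pct_change(10069, 13758))  # 137
```

The first two descriptors each add 2 points to *independent takeaway* while
*salad* adds 2 to *sandwich/salad*; 4 beats 2, so the outlet is an independent
takeaway. The last line is the percent-change statistic for a region with
10,069 local and 13,758 hybrid outlets: delivery platforms expanded that
region's accessible outlets to 137% of the local count.

An end-to-end run on synthetic data:

```bash
foodenv run --seed 42 --outdir out/
```

writes the simulated views, cleaned tables, matches, audit, category
assignments, region summaries, density GeoJSON, word-cloud JSON and a
`manifest.json`. With the default configuration (1,040 ground-truth outlets
over 4 regions) the run reports 944 directory outlets kept after filtering,
463 unique platform outlets, and 461 matches — the platform view is almost
entirely a subset of the directory view, so regional hybrid counts exceed
local counts only where platform-only outlets deliver in. Each stage is also
available as its own CLI verb (`simulate`, `clean`, `match`, `categorize`,
`summarize`, `export`).

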