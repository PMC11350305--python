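"""Configuration models and built-in vocabularies.

Everything the cleaning and matching rules treat as a lookup table — the
shopping-centre list, the street-type vocabulary, the non-food category list,
the city/state tokens — is configuration, editable from a YAML file. The
built-in defaults target New South Wales, Australia, matching the study
setting, but nothing else in the pipeline is state-specific.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


def _prob(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"probability out of [0,1]: {v}")
    return v


class NoiseConfig(BaseModel):
    """Rates of the listing-noise modes injected into the scraped views.

    Each rate is an independent per-row Bernoulli probability. The defaults
    emulate a heavily contaminated directory view (roughly a third of raw
    directory rows are non-food businesses and a tenth are permanently closed,
    so that the cleaned set is well under the raw row count) and moderate
    field-level noise on both views.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    p_missing_suburb: float = 0.05
    p_missing_postcode: float = 0.05
    p_missing_both: float = 0.02
    p_missing_street_number: float = 0.05
    p_centre_prefix: float = 0.08
    p_name_decoration: float = 0.10
    p_address_embed: float = 0.20
    p_case_shuffle: float = 0.50
    p_punctuation: float = 0.15
    p_nonfood_rows: float = 0.30
    p_closed_rows: float = 0.10
    #: nominal mean delivery-suburb count per online outlet; informational —
    #: delivery suburb lists are derived from the delivery radius, not sampled.
    n_delivery_suburbs_mean: float = 4.0

    _v = field_validator(
        "p_missing_suburb", "p_missing_postcode", "p_missing_both",
        "p_missing_street_number", "p_centre_prefix", "p_name_decoration",
        "p_address_embed", "p_case_shuffle", "p_punctuation",
        "p_nonfood_rows", "p_closed_rows",
    )(_prob)

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseConfig":
        """A configuration with every noise rate at zero (identity noise)."""
        return cls(
            seed=seed,
            p_missing_suburb=0, p_missing_postcode=0, p_missing_both=0,
            p_missing_street_number=0, p_centre_prefix=0, p_name_decoration=0,
            p_address_embed=0, p_case_shuffle=0, p_punctuation=0,
            p_nonfood_rows=0, p_closed_rows=0,
        )


class BrandSpec(BaseModel):
    """A franchise brand planted in the synthetic universe."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_locations: int = Field(gt=0)
    subtype: str = "unhealthy"  # FranchiseSubtype value
    descriptors: list[str] = Field(default_factory=lambda: ["fast food", "burger"])


class SimulationConfig(BaseModel):
    """Shape of the synthetic outlet universe.

    ``outlets_per_region`` counts ground-truth outlets (franchise locations
    included) per region id. Participation on the delivery platform is
    region-dependent: urban regions participate more than rural ones.
    """

    model_config = ConfigDict(extra="forbid")

    outlets_per_region: dict[str, int]
    franchise_brands: list[BrandSpec] = Field(default_factory=list)
    #: independent-outlet category mix (echoing the observed dominance of
    #: independent restaurants/cafes); normalised internally
    category_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "independent_restaurant_cafe": 0.51,
            "independent_takeaway": 0.12,
            "supermarket_grocer": 0.07,
            "alcohol_retailer": 0.06,
            "convenience_petrol": 0.06,
            "fresh_produce": 0.06,
            "sweets_extra": 0.05,
            "bakery": 0.04,
            "sandwich_salad": 0.03,
        }
    )
    urban_participation: float = 0.6
    rural_participation: float = 0.1
    delivery_radius_km: float = 3.0
    closed_fraction: float = 0.05
    nonfood_fraction: float = 0.05

    _v = field_validator(
        "urban_participation", "rural_participation",
        "closed_fraction", "nonfood_fraction",
    )(_prob)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if any(n < 0 for n in self.outlets_per_region.values()):
            raise ValueError("outlet counts must be non-negative")
        if self.urban_participation <= self.rural_participation:
            raise ValueError("urban participation must exceed rural participation")
        if self.delivery_radius_km < 0:
            raise ValueError("delivery radius must be non-negative")
        return self


#: street-type vocabulary with common abbreviations mapped to full words
DEFAULT_STREET_TYPES: dict[str, str] = {
    "street": "street", "st": "street",
    "road": "road", "rd": "road",
    "avenue": "avenue", "ave": "avenue", "av": "avenue",
    "drive": "drive", "dr": "drive",
    "lane": "lane", "ln": "lane",
    "parade": "parade", "pde": "parade",
    "highway": "highway", "hwy": "highway",
    "place": "place", "pl": "place",
    "court": "court", "ct": "court",
    "crescent": "crescent", "cres": "crescent",
    "boulevard": "boulevard", "blvd": "boulevard",
    "terrace": "terrace", "tce": "terrace",
    "circuit": "circuit", "cct": "circuit",
    "way": "way",
    "esplanade": "esplanade",
    "square": "square",
}

#: stand-in for the manually identified shopping centres / buildings / plazas
DEFAULT_CENTRE_LIST: list[str] = [
    "westfield", "central park", "spice alley", "harbourside plaza",
    "market square", "civic arcade", "grand central", "the galleria",
    "riverside centre", "town hall arcade",
]

DEFAULT_PETROL_LIST: list[str] = [
    "bp", "shell", "caltex", "ampol", "united petroleum", "metro fuel",
]

#: category tags that mark a business as outside the food environment
DEFAULT_NONFOOD_CATEGORIES: list[str] = [
    "appliance store", "corporate office", "jewelry store", "hardware store",
    "hair salon", "pharmacy", "bank", "gym", "car wash", "florist",
]

DEFAULT_CITY_TOKENS: list[str] = ["sydney"]
DEFAULT_STATE_TOKENS: list[str] = ["nsw", "new south wales"]

#: state/territory spellings accepted as in-scope
DEFAULT_TARGET_STATES: list[str] = ["nsw", "new south wales"]


class NormalizationConfig(BaseModel):
    """Token lists and vocabularies driving the cleaning rules."""

    model_config = ConfigDict(extra="forbid")

    target_states: list[str] = Field(default_factory=lambda: list(DEFAULT_TARGET_STATES))
    centre_list: list[str] = Field(default_factory=lambda: list(DEFAULT_CENTRE_LIST))
    petrol_list: list[str] = Field(default_factory=lambda: list(DEFAULT_PETROL_LIST))
    city_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_CITY_TOKENS))
    state_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_STATE_TOKENS))
    street_types: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_STREET_TYPES))
    nonfood_categories: list[str] = Field(
        default_factory=lambda: list(DEFAULT_NONFOOD_CATEGORIES)
    )
    #: suburb names removable from outlet names; filled from geography at run time
    suburb_list: list[str] = Field(default_factory=list)


class SimilarityThresholds(BaseModel):
    """Cut-offs for the fuzzy passes of the matching cascade."""

    model_config = ConfigDict(extra="forbid")

    jaro_min: float = 0.90
    levenshtein_ratio_min: float = 90.0
    step10_11_name_min: float = 83.0

    @model_validator(mode="after")
    def _scales(self) -> "SimilarityThresholds":
        if not 0 <= self.jaro_min <= 1:
            raise ValueError("jaro_min must be on [0,1]")
        for v in (self.levenshtein_ratio_min, self.step10_11_name_min):
            if not 0 <= v <= 100:
                raise ValueError("ratio thresholds must be on [0,100]")
        return self


class GeographySpec(BaseModel):
    """Parameters of the built-in synthetic geography."""

    model_config = ConfigDict(extra="forbid")

    n_urban_regions: int = 2
    n_rural_regions: int = 2
    suburbs_per_urban_region: int = 12
    suburbs_per_rural_region: int = 6
    urban_spacing_km: float = 2.0
    rural_spacing_km: float = 8.0


class PipelineConfig(BaseModel):
    """Everything one end-to-end run needs, round-trippable through YAML."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    geography: GeographySpec = Field(default_factory=GeographySpec)
    simulation: Optional[SimulationConfig] = None
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)
    thresholds: SimilarityThresholds = Field(default_factory=SimilarityThresholds)
    #: strict > 10 locations by default, i.e. at least 11
    franchise_min_locations: int = 11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def default_simulation_config(geography_regions: dict[str, bool],
                              n_per_urban: int = 400,
                              n_per_rural: int = 120) -> SimulationConfig:
    """A demo-scale universe: a few hundred outlets per region and a handful
    of franchise brands straddling the >10-location threshold."""
    per_region = {
        r: (n_per_urban if urban else n_per_rural)
        for r, urban in geography_regions.items()
    }
    brands = [
        BrandSpec(name="burger barn", n_locations=24, subtype="unhealthy",
                  descriptors=["fast food", "burger"]),
        BrandSpec(name="crispy cluck", n_locations=16, subtype="unhealthy",
                  descriptors=["fried chicken", "fast food"]),
        BrandSpec(name="scoop city", n_locations=12, subtype="dessert",
                  descriptors=["ice cream", "desserts"]),
        BrandSpec(name="daily crust", n_locations=11, subtype="bakery",
                  descriptors=["bakery", "bread"]),
        BrandSpec(name="green squeeze", n_locations=11, subtype="juice",
                  descriptors=["juice", "smoothies"]),
        BrandSpec(name="leaf and grain", n_locations=12, subtype="healthy",
                  descriptors=["salad", "sandwich"]),
        # deliberately at the threshold boundary: 10 locations is NOT a franchise
        BrandSpec(name="corner pide", n_locations=10, subtype="unhealthy",
                  descriptors=["kebab", "comfort food"]),
    ]
    return SimulationConfig(outlets_per_region=per_region, franchise_brands=brands)
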