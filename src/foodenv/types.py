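"""Core record types shared across the pipeline.

The pipeline moves outlet records through four representations: the synthetic
ground truth (:class:`GroundTruthOutlet`), the as-scraped row
(:class:`RawOutletListing`), the cleaned and parsed record
(:class:`NormalizedOutlet`), and the analysis outputs
(:class:`MatchResult`, :class:`CategoryAssignment`, :class:`EnvironmentView`,
:class:`RegionSummary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union


class Source(str, Enum):
    """Which scraped view a row came from."""

    LOCAL = "local"
    ONLINE = "online"


class Status(str, Enum):
    OPEN = "open"
    PERMANENTLY_CLOSED = "permanently_closed"
    UNKNOWN = "unknown"


class MainCategory(str, Enum):
    """The nine main outlet categories, plus the alcohol-retailer auxiliary
    category and the NA sentinel for outlets whose descriptors carry no
    food-category signal.

    Enum definition order doubles as the fixed tie-break order used when both
    cumulative scores and global frequencies are tied.
    """

    TAKEAWAY_FRANCHISE = "takeaway_franchise"
    INDEPENDENT_TAKEAWAY = "independent_takeaway"
    INDEPENDENT_RESTAURANT_CAFE = "independent_restaurant_cafe"
    SUPERMARKET_GROCER = "supermarket_grocer"
    FRESH_PRODUCE = "fresh_produce"
    SANDWICH_SALAD = "sandwich_salad"
    SWEETS_EXTRA = "sweets_extra"
    BAKERY = "bakery"
    CONVENIENCE_PETROL = "convenience_petrol"
    ALCOHOL_RETAILER = "alcohol_retailer"
    NA = "na"


#: The nine categories an outlet can be scored into (excludes the sentinel).
SCOREABLE_CATEGORIES = tuple(c for c in MainCategory if c is not MainCategory.NA)


class FranchiseSubtype(str, Enum):
    DESSERT = "dessert"
    BAKERY = "bakery"
    JUICE = "juice"
    HEALTHY = "healthy"
    UNHEALTHY = "unhealthy"
    UNASSIGNED = "unassigned"


class AssignmentSource(str, Enum):
    SCORED = "scored"
    TRANSFERRED = "transferred"
    FRANCHISE = "franchise"


@dataclass(frozen=True)
class GroundTruthOutlet:
    """One outlet in the synthetic ground-truth universe."""

    truth_id: str
    brand: Optional[str]
    canonical_name: str
    street_number: int
    street_name: str
    street_type: str
    suburb: str
    postcode: str
    region: str
    latitude: float
    longitude: float
    true_category: MainCategory
    descriptors: tuple[str, ...]
    is_food_business: bool
    is_open: bool
    on_delivery_platform: bool
    delivery_radius_km: float


@dataclass
class RawOutletListing:
    """An as-scraped outlet row from either source, before any cleaning."""

    source: Source
    source_id: str
    name: str
    street_address: str
    suburb: Optional[str]
    state: Optional[str]
    postcode: Optional[str]
    latitude: Optional[float]
    longitude: Optional[float]
    category_descriptors: list[str]
    status: Status = Status.UNKNOWN
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source_id:
            raise ValueError("source_id must be non-empty")


@dataclass
class NormalizedOutlet:
    """A cleaned, parsed outlet with structured address components.

    ``name_norm`` and ``suburb_norm`` contain only lowercase alphanumerics and
    single spaces. Imputation sentinels: suburb ``"empty"``, postcode
    ``"0000"``, street number ``"12345"``, each paired with its flag.
    """

    source: Source
    source_id: str
    name_norm: str
    street_number: str
    street_name: str
    street_type: str
    suburb_norm: str
    postcode_norm: str
    imputed_suburb: bool = False
    imputed_postcode: bool = False
    imputed_street_number: bool = False
    descriptors: list[str] = field(default_factory=list)
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def address_string(self) -> str:
        """Canonical address form used for address-similarity comparisons."""
        parts = [self.street_number, self.street_name, self.street_type]
        return " ".join(p for p in parts if p)


@dataclass(frozen=True)
class MatchResult:
    """A linked (online, local) outlet pair and the cascade step that made it."""

    online_id: str
    local_id: str
    step: Union[int, str]  # 1-15 or "similarity_pass"
    name_similarity_jaro: float
    name_similarity_ratio: float
    address_similarity_ratio: float


@dataclass
class CategoryAssignment:
    outlet_id: str
    scores: dict[MainCategory, int]
    main_category: MainCategory
    tie_broken: bool = False
    assignment_source: AssignmentSource = AssignmentSource.SCORED
    franchise_subtype: Optional[FranchiseSubtype] = None


@dataclass
class EnvironmentView:
    """The outlet set visible from one geographic unit under one scope."""

    scope: str  # "local" | "online" | "hybrid"
    geography_unit: str  # postcode, region id, or "unknown"
    outlet_ids: frozenset[str]
    by_category: dict[MainCategory, int] = field(default_factory=dict)
    cuisine_frequencies: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_outlets(self) -> int:
        return len(self.outlet_ids)


@dataclass
class RegionSummary:
    region: str
    n_postcodes: int
    population: int
    n_local: int
    n_online: int
    n_hybrid: int
    pct_change: Optional[int]  # round-half-up integer percent; None if no local outlets
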