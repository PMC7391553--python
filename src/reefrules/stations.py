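"""Station-level habitat observations: domain types, aggregation, CSV I/O.

A *station* is one rotating-video deployment observing roughly 78.5 m**2
(a 5-m radius disc) of sea floor.  Its habitat is described by thirteen
base attributes: depth (m), two ordinal scores (topography, complexity,
each on a 1-5 scale, fractional after frame averaging), five substrate
percent covers that partition the observed area (sand, debris, boulder,
rock, slab -- they sum to 100), and five biotic percent covers overlaid
on the substrate (live coral, dead coral, erect algae, algal turf,
seagrass).  Three composite covers are derived, never stored:

* ``algae``          = erect_algae + algal_turf
* ``hard_coral``     = live_coral + dead_coral
* ``hard_substrate`` = debris + boulder + rock + slab

Raw annotations arrive per frame (six 60-degree frames per rotation) for
habitat, and per rotation (three rotations) for fish counts; this module
holds the arithmetic that reduces them to station level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HABITATS: tuple[str, ...] = ("Seagrass", "Macroalgae", "Sandy", "Debris", "Live Coral")

SUBSTRATE_ATTRIBUTES: tuple[str, ...] = ("sand", "debris", "boulder", "rock", "slab")
BIOTIC_ATTRIBUTES: tuple[str, ...] = (
    "live_coral",
    "dead_coral",
    "erect_algae",
    "algal_turf",
    "seagrass",
)
ORDINAL_ATTRIBUTES: tuple[str, ...] = ("topography", "complexity")
COVER_ATTRIBUTES: tuple[str, ...] = SUBSTRATE_ATTRIBUTES + BIOTIC_ATTRIBUTES
BASE_ATTRIBUTES: tuple[str, ...] = ("depth",) + ORDINAL_ATTRIBUTES + COVER_ATTRIBUTES

#: Named composite covers, each a sum of base covers.
COMPOSITE_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "algae": ("erect_algae", "algal_turf"),
    "hard_coral": ("live_coral", "dead_coral"),
    "hard_substrate": ("debris", "boulder", "rock", "slab"),
}

#: Annotation rounding slack on the substrate partition, percentage points.
SUBSTRATE_SUM_TOLERANCE = 0.5

#: Observed surface area of one station, m**2 (5-m radius disc).
DEFAULT_OBSERVED_AREA = 78.5

FRAMES_PER_ROTATION = 6
ROTATIONS_PER_STATION = 3


class ValidationError(ValueError):
    """A station violates a structural invariant of the attribute schema."""


class SchemaError(ValueError):
    """Tabular input does not match the documented column dictionary."""


@dataclass(frozen=True)
class AttributeProfile:
    """The thirteen station-level habitat attributes.

    Covers are percentages in [0, 100]; ordinal scores live in [1, 5] and
    may be fractional because they are means over six frames.  Composite
    covers are computed on demand through :meth:`value`.
    """

    depth: float
    topography: float
    complexity: float
    sand: float
    debris: float
    boulder: float
    rock: float
    slab: float
    live_coral: float
    dead_coral: float
    erect_algae: float
    algal_turf: float
    seagrass: float

    def value(self, attribute: str) -> float:
        """Resolve a base or composite attribute to its numeric value."""
        if attribute in COMPOSITE_ATTRIBUTES:
            return float(sum(getattr(self, a) for a in COMPOSITE_ATTRIBUTES[attribute]))
        if attribute in BASE_ATTRIBUTES:
            return float(getattr(self, attribute))
        raise KeyError(f"unknown attribute {attribute!r}")

    def substrate_sum(self) -> float:
        return float(sum(getattr(self, a) for a in SUBSTRATE_ATTRIBUTES))

    def as_dict(self) -> dict[str, float]:
        return {a: float(getattr(self, a)) for a in BASE_ATTRIBUTES}

    def validate(self, *, strict: bool = False, station_id: str = "?") -> list[str]:
        """Check range and partition invariants.

        Returns a list of human-readable issues.  Hard violations (a cover
        outside [0, 100], an ordinal outside [1, 5], negative depth) raise
        :class:`ValidationError` immediately; the soft substrate-sum check
        (tolerance 0.5 points, visual-estimate rounding) is reported as a
        warning unless ``strict`` is set.
        """
        if self.depth < 0:
            raise ValidationError(f"station {station_id}: negative depth {self.depth}")
        for a in ORDINAL_ATTRIBUTES:
            v = getattr(self, a)
            if not 1.0 <= v <= 5.0:
                raise ValidationError(f"station {station_id}: {a}={v} outside [1, 5]")
        for a in COVER_ATTRIBUTES:
            v = getattr(self, a)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"station {station_id}: {a}={v} outside [0, 100]")
        issues: list[str] = []
        s = self.substrate_sum()
        if abs(s - 100.0) > SUBSTRATE_SUM_TOLERANCE:
            msg = f"station {station_id}: substrate covers sum to {s:.2f}, not 100"
            if strict:
                raise ValidationError(msg)
            issues.append(msg)
        return issues


@dataclass
class StationFishSummary:
    """Station-level fish metrics derived from the three rotations.

    ``abundance`` is the per-species mean count over rotations; ``density``
    rescales it to individuals per 100 m**2; ``species_richness`` counts
    species seen in *any* rotation; ``family_presence`` flags families with
    at least one individual.
    """

    abundance: dict[str, float]
    density: dict[str, float]
    species_richness: int
    family_presence: dict[str, bool]

    @property
    def total_density(self) -> float:
        """Overall abundance density, all species pooled (ind/100 m**2)."""
        return float(sum(self.density.values()))


@dataclass
class StationRecord:
    """One station observation: attributes, optional label, optional fish."""

    station_id: str
    profile: AttributeProfile
    site: str = ""
    zone: str = "coastal"  # "coastal" or "remote"
    habitat: str | None = None
    fish: StationFishSummary | None = None
    degraded: bool = False  # fewer rotations/frames than nominal
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat is not None and self.habitat not in HABITATS:
            raise ValidationError(
                f"station {self.station_id}: habitat {self.habitat!r} "
                f"not one of {HABITATS}"
            )

    def with_habitat(self, habitat: str | None) -> "StationRecord":
        return replace(self, habitat=habitat)


@dataclass
class FrameAnnotationSet:
    """Per-frame attribute values for one rotation (six frames expected)."""

    station_id: str
    frames: list[dict[str, float]]


@dataclass
class RotationFishCounts:
    """Per-species counts for each rotation of one station.

    ``counts`` maps species to a list of per-rotation counts (three
    rotations expected, fewer tolerated with a warning); ``families`` maps
    species to family.
    """

    station_id: str
    counts: dict[str, list[float]]
    families: dict[str, str]
    observed_area: float = DEFAULT_OBSERVED_AREA


def aggregate_habitat_frames(frames: FrameAnnotationSet) -> AttributeProfile:
    """Average per-frame habitat annotations into a station profile.

    Each of the thirteen attributes is the arithmetic mean of its six frame
    values; the substrate partition is re-checked after averaging (a mean of
    valid partitions is a valid partition, but annotation errors are not).
    """
    if len(frames.frames) != FRAMES_PER_ROTATION:
        raise ValidationError(
            f"station {frames.station_id}: expected {FRAMES_PER_ROTATION} "
            f"frames, got {len(frames.frames)}"
        )
    values: dict[str, float] = {}
    for a in BASE_ATTRIBUTES:
        try:
            values[a] = float(np.mean([f[a] for f in frames.frames]))
        except KeyError:
            raise ValidationError(
                f"station {frames.station_id}: attribute {a!r} missing from a frame"
            ) from None
    profile = AttributeProfile(**values)
    profile.validate(station_id=frames.station_id)
    return profile


def summarize_fish(counts: RotationFishCounts) -> StationFishSummary:
    """Reduce rotation counts to abundance, density, richness and presence.

    Abundance is the mean count over the available rotations; density is
    abundance / observed_area * 100 (ind/100 m**2).  Richness counts the
    species recorded at least once in any rotation.
    """
    n_rot = {len(v) for v in counts.counts.values()}
    if n_rot and max(n_rot) > ROTATIONS_PER_STATION:
        raise ValidationError(
            f"station {counts.station_id}: more than "
            f"{ROTATIONS_PER_STATION} rotations"
        )
    if n_rot and min(n_rot) < ROTATIONS_PER_STATION:
        warnings.warn(
            f"station {counts.station_id}: fewer than "
            f"{ROTATIONS_PER_STATION} rotations; metrics computed on "
            "available rotations",
            stacklevel=2,
        )
    abundance: dict[str, float] = {}
    density: dict[str, float] = {}
    richness = 0
    family_presence: dict[str, bool] = {}
    for species, per_rot in counts.counts.items():
        arr = np.asarray(per_rot, dtype=float)
        if (arr < 0).any():
            raise ValidationError(
                f"station {counts.station_id}: negative count for {species}"
            )
        mean = float(arr.mean()) if arr.size else 0.0
        abundance[species] = mean
        density[species] = mean / counts.observed_area * 100.0
        present = bool(arr.size and arr.max() > 0)
        if present:
            richness += 1
        fam = counts.families.get(species, "Unknown")
        family_presence[fam] = family_presence.get(fam, False) or present
    return StationFishSummary(
        abundance=abundance,
        density=density,
        species_richness=richness,
        family_presence=family_presence,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = (
    "station_id",
    "depth_m",
    "topography",
    "complexity",
    "sand_pc",
    "debris_pc",
    "boulder_pc",
    "rock_pc",
    "slab_pc",
    "live_coral_pc",
    "dead_coral_pc",
    "erect_algae_pc",
    "algal_turf_pc",
    "seagrass_pc",
)
_OPTIONAL_COLUMNS = ("site", "zone", "habitat")

_COLUMN_TO_ATTR = {
    "depth_m": "depth",
    "topography": "topography",
    "complexity": "complexity",
    **{f"{a}_pc": a for a in COVER_ATTRIBUTES},
}
_ATTR_TO_COLUMN = {v: k for k, v in _COLUMN_TO_ATTR.items()}


def read_stations(path, *, strict: bool = False) -> list[StationRecord]:
    """Read stations from CSV (one row per station, documented columns).

    Unknown columns are kept verbatim in ``record.extras``.  Missing
    mandatory columns raise :class:`SchemaError`; a non-numeric or
    out-of-range value raises :class:`ValidationError` naming the station.
    Substrate sums off by more than the tolerance warn (error if
    ``strict``).
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    extra_cols = [
        c for c in df.columns if c not in _MANDATORY_COLUMNS + _OPTIONAL_COLUMNS
    ]
    records: list[StationRecord] = []
    for _, row in df.iterrows():
        sid = str(row["station_id"])
        values = {}
        for col, attr in _COLUMN_TO_ATTR.items():
            try:
                values[attr] = float(row[col])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"station {sid}: non-numeric value {row[col]!r} in {col}"
                ) from None
        profile = AttributeProfile(**values)
        for issue in profile.validate(strict=strict, station_id=sid):
            warnings.warn(issue, stacklevel=2)
        habitat = row.get("habitat")
        if habitat is not None and (pd.isna(habitat) or habitat == ""):
            habitat = None
        records.append(
            StationRecord(
                station_id=sid,
                profile=profile,
                site=str(row.get("site", "") or ""),
                zone=str(row.get("zone", "coastal") or "coastal"),
                habitat=habitat,
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_stations(records: list[StationRecord], path) -> None:
    """Write stations to CSV; inverse of :func:`read_stations`."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "station_id": r.station_id,
            "site": r.site,
            "zone": r.zone,
        }
        for attr, col in _ATTR_TO_COLUMN.items():
            row[col] = round(getattr(r.profile, attr), 6)
        row["habitat"] = r.habitat if r.habitat is not None else ""
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_stations(records: list[StationRecord]) -> dict[str, list[str]]:
    """Run the invariant checks over a collection; map station_id -> issues."""
    report: dict[str, list[str]] = {}
    for r in records:
        issues = r.profile.validate(station_id=r.station_id)
        if issues:
            report[r.station_id] = issues
    return report


def read_fish_counts(path, *, observed_area: float = DEFAULT_OBSERVED_AREA
                     ) -> dict[str, RotationFishCounts]:
    """Read long-form fish counts (station_id, species, family, rotation,
    count) into per-station :class:`RotationFishCounts`."""
    df = pd.read_csv(path, dtype={"station_id": str})
    needed = {"station_id", "species", "family", "rotation", "count"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"missing fish-count columns: {sorted(missing)}")
    out: dict[str, RotationFishCounts] = {}
    for sid, grp in df.groupby("station_id"):
        rotations = sorted(grp["rotation"].unique())
        counts: dict[str, list[float]] = {}
        families: dict[str, str] = {}
        for sp, sp_grp in grp.groupby("species"):
            per_rot = sp_grp.set_index("rotation")["count"]
            counts[str(sp)] = [float(per_rot.get(r, 0.0)) for r in rotations]
            families[str(sp)] = str(sp_grp["family"].iloc[0])
        out[str(sid)] = RotationFishCounts(
            station_id=str(sid),
            counts=counts,
            families=families,
            observed_area=observed_area,
        )
    return out


def attach_fish(records: list[StationRecord],
                fish: dict[str, RotationFishCounts]) -> list[StationRecord]:
    """Return records with fish summaries attached where counts exist."""
    out = []
    for r in records:
        if r.station_id in fish:
            out.append(replace(r, fish=summarize_fish(fish[r.station_id])))
        else:
            out.append(r)
    return out
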