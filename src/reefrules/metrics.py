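"""Descriptive fish-community summaries by habitat.

Station-level inputs come from :mod:`reefrules.stations`: overall
abundance density (all species pooled, ind/100 m**2) and species
richness per station.  Quartiles use linear interpolation.  The
habitat-effect tests (GLM with gamma / negative-binomial families,
Tukey comparisons) are deliberately not re-implemented here; a thin
convenience wrapper over statsmodels is provided for completeness and is
not part of the core method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stations import StationRecord


class MetricsError(ValueError):
    pass


@dataclass
class HabitatMetricSummary:
    """0.25/0.5/0.75 quartiles of overall density and species richness,
    per habitat and over all habitats pooled."""

    density_quartiles: dict[str, tuple[float, float, float]]
    richness_quartiles: dict[str, tuple[float, float, float]]
    overall_density_quartiles: tuple[float, float, float]
    overall_richness_quartiles: tuple[float, float, float]


@dataclass
class FamilyFrequencyTable:
    """Family x habitat frequency matrix (% of stations where present)."""

    frequencies: pd.DataFrame  # index family, columns habitats
    overall: pd.Series  # overall frequency per family


def _with_fish(stations: list[StationRecord]) -> list[StationRecord]:
    out = [s for s in stations if s.fish is not None and s.habitat is not None]
    if not out:
        raise MetricsError("no labeled stations with fish summaries")
    return out


def _quartiles(values) -> tuple[float, float, float]:
    q = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
    return (float(q[0]), float(q[1]), float(q[2]))


def summarize_metrics(stations: list[StationRecord]) -> HabitatMetricSummary:
    """Quartiles of overall density and richness per habitat and pooled."""
    usable = _with_fish(stations)
    df = pd.DataFrame(
        {
            "habitat": [s.habitat for s in usable],
            "density": [s.fish.total_density for s in usable],
            "richness": [s.fish.species_richness for s in usable],
        }
    )
    dq, rq = {}, {}
    for habitat, grp in df.groupby("habitat"):
        dq[habitat] = _quartiles(grp["density"])
        rq[habitat] = _quartiles(grp["richness"])
    return HabitatMetricSummary(
        density_quartiles=dq,
        richness_quartiles=rq,
        overall_density_quartiles=_quartiles(df["density"]),
        overall_richness_quartiles=_quartiles(df["richness"]),
    )


def family_frequencies(stations: list[StationRecord],
                       min_overall_pct: float = 1.0) -> FamilyFrequencyTable:
    """Per-habitat presence frequency per family.

    A family's frequency in a habitat is the percentage of that habitat's
    stations where the family was present; families whose overall
    (all-station) frequency is at or below ``min_overall_pct`` are
    dropped.
    """
    usable = _with_fish(stations)
    rows = []
    for s in usable:
        for family, present in s.fish.family_presence.items():
            rows.append((s.station_id, s.habitat, family, present))
    presence = pd.DataFrame(
        rows, columns=["station_id", "habitat", "family", "present"]
    )
    n_total = len(usable)
    n_by_habitat = pd.Series([s.habitat for s in usable]).value_counts()
    # A family absent from a station simply has no row; count presences.
    present = presence[presence["present"]]
    overall = (
        present.groupby("family")["station_id"].nunique() / n_total * 100.0
    )
    keep = overall[overall > min_overall_pct].index
    freq = (
        present[present["family"].isin(keep)]
        .groupby(["family", "habitat"])["station_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    freq = freq.div(n_by_habitat, axis=1).fillna(0.0) * 100.0
    return FamilyFrequencyTable(
        frequencies=freq.sort_index(), overall=overall.loc[keep].sort_index()
    )


def habitat_effect_glm(stations: list[StationRecord], metric: str = "density"):
    """Convenience (non-core): GLM of a metric on habitat via statsmodels.

    ``metric`` is "density" (gamma family, log link) or "richness"
    (negative binomial).  Returns the fitted statsmodels results object.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    usable = _with_fish(stations)
    df = pd.DataFrame(
        {
            "habitat": [s.habitat for s in usable],
            "density": [max(s.fish.total_density, 1e-9) for s in usable],
            "richness": [s.fish.species_richness for s in usable],
        }
    )
    if metric == "density":
        family = sm.families.Gamma(link=sm.families.links.Log())
    elif metric == "richness":
        family = sm.families.NegativeBinomial()
    else:
        raise MetricsError(f"unknown metric {metric!r}")
    return smf.glm(f"{metric} ~ C(habitat)", data=df, family=family).fit()


def summary_frame(summary: HabitatMetricSummary) -> pd.DataFrame:
    rows = []
    for habitat in sorted(summary.density_quartiles):
        d = summary.density_quartiles[habitat]
        r = summary.richness_quartiles[habitat]
        rows.append((habitat, *d, *r))
    rows.append(
        (
            "Overall",
            *summary.overall_density_quartiles,
            *summary.overall_richness_quartiles,
        )
    )
    return pd.DataFrame(
        rows,
        columns=[
            "habitat",
            "density_q25", "density_q50", "density_q75",
            "richness_q25", "richness_q50", "richness_q75",
        ],
    )
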