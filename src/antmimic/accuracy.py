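"""Per-pair mimetic-accuracy distances and category scores.

Mimetic accuracy is distance: for each mimic–ant (and mimic–control) pair,
every trait contributes a non-negative distance between the species-level
summaries — Euclidean distance for the 800-value reflectance vectors and the
40-point standardized outline vectors, absolute difference of SD-scaled
species means for scalar traits.  Member-trait distances are averaged within
the four categories

    color    = {color}
    shape    = {circularity, outline}
    size     = {body_length, thickness}
    movement = {velocity, locomotion, mobility, angular_velocity}

and each category is finally scaled to unit SD across mimic–ant pairs so the
categories are comparable despite their different native scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORY_MEMBERS: dict[str, tuple[str, ...]] = {
    "color": ("color",),
    "shape": ("circularity", "outline"),
    "size": ("body_length", "thickness"),
    "movement": ("velocity", "locomotion", "mobility", "angular_velocity"),
}
CATEGORIES = tuple(CATEGORY_MEMBERS)
SCALAR_TRAITS = (
    "circularity",
    "body_length",
    "thickness",
    "velocity",
    "locomotion",
    "mobility",
    "angular_velocity",
)
ROLES = ("mimic", "ant", "control")
MAJOR_TAXA = ("insect", "spider")


@dataclass
class TripletRecord:
    """One mimic–ant–control triplet with its taxonomic assignment."""

    triplet_id: str
    mimic: str
    ant: str
    control: str
    group: str
    major_taxon: str

    def __post_init__(self) -> None:
        if len({self.mimic, self.ant, self.control}) != 3:
            raise ValueError(f"triplet {self.triplet_id}: roles must be distinct species")
        if self.major_taxon not in MAJOR_TAXA:
            raise ValueError(f"major_taxon must be one of {MAJOR_TAXA}")


@dataclass
class SpeciesSummary:
    """Species-level trait summary for one role instance of a triplet.

    A model or control species shared by several triplets keeps a separate
    measurement set per triplet, so summaries are keyed by (triplet, role).
    """

    species_id: str
    spectrum: np.ndarray | None = None  # 800-vector species mean
    outline: np.ndarray | None = None  # 40-vector standardized species mean
    scalars: dict[str, float] = field(default_factory=dict)


def scalar_trait_distance(mimic_mean: float, other_mean: float, trait_sd: float) -> float:
    """|difference| of species means on the per-trait SD scale."""
    if trait_sd <= 0:
        raise ValueError("trait_sd must be > 0")
    return abs(mimic_mean - other_mean) / trait_sd


def category_accuracy(distances: dict[str, float], category: str) -> float | None:
    """Mean of member-trait distances; None when a member is missing."""
    members = CATEGORY_MEMBERS[category]
    vals = [distances.get(t) for t in members]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return None
    return float(sum(vals)) / len(members)


def scale_by_sd(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide by the sample SD; returns (scaled values, the SD used)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values to scale by SD")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("SD is zero; cannot scale a constant vector")
    return v / sd, sd


def pooled_trait_sds(summaries: dict[tuple[str, str], SpeciesSummary]) -> dict[str, float]:
    """Sample SD of each scalar trait pooled across every species summary."""
    sds = {}
    for trait in SCALAR_TRAITS:
        vals = np.array(
            [
                s.scalars[trait]
                for s in summaries.values()
                if trait in s.scalars and np.isfinite(s.scalars[trait])
            ]
        )
        sds[trait] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
    return sds


def _pair_trait_distances(
    mimic: SpeciesSummary, other: SpeciesSummary, sds: dict[str, float]
) -> dict[str, float | None]:
    from .spectra import spectral_distance  # local import to avoid cycles

    d: dict[str, float | None] = {}
    if mimic.spectrum is not None and other.spectrum is not None:
        d["color"] = spectral_distance(mimic.spectrum, other.spectrum)
    else:
        d["color"] = None
    if mimic.outline is not None and other.outline is not None:
        d["outline"] = float(np.linalg.norm(np.asarray(mimic.outline) - np.asarray(other.outline)))
    else:
        d["outline"] = None
    for trait in SCALAR_TRAITS:
        if trait == "outline":
            continue
        a = mimic.scalars.get(trait, np.nan)
        b = other.scalars.get(trait, np.nan)
        if np.isfinite(a) and np.isfinite(b) and np.isfinite(sds.get(trait, np.nan)):
            d[trait] = scalar_trait_distance(a, b, sds[trait])
        else:
            d[trait] = None
    return d


def build_pair_tables(
    triplets: list[TripletRecord] | pd.DataFrame,
    summaries: dict[tuple[str, str], SpeciesSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-pair trait distances and category accuracies.

    Returns ``(trait_table, category_table)``.  ``trait_table`` has one row
    per pair × trait; ``category_table`` one row per pair × category with the
    raw mean-member distance and, for rows with a defined category value, the
    value scaled by the SD over mimic–ant pairs of that category (the
    comparative analysis runs on mimic–ant rows; mimic–control rows are
    scaled by the same divisor so pair types stay comparable).

    Raises
    ------
    KeyError
        If a triplet references a (triplet, role) with no species summary.
    """
    if isinstance(triplets, pd.DataFrame):
        triplets = [
            TripletRecord(
                str(r.triplet_id), str(r.mimic_id), str(r.ant_id), str(r.control_id),
                str(r.group), str(r.major_taxon),
            )
            for r in triplets.itertuples()
        ]
    sds = pooled_trait_sds(summaries)
    trait_rows, cat_rows = [], []
    for tr in triplets:
        key_m = (tr.triplet_id, "mimic")
        if key_m not in summaries:
            raise KeyError(f"no species summary for {key_m}")
        mimic = summaries[key_m]
        for role, species in (("ant", tr.ant), ("control", tr.control)):
            key = (tr.triplet_id, role)
            if key not in summaries:
                raise KeyError(f"no species summary for {key}")
            other = summaries[key]
            pair_id = f"{tr.triplet_id}:{role}"
            dists = _pair_trait_distances(mimic, other, sds)
            for trait, val in dists.items():
                trait_rows.append(
                    dict(
                        pair_id=pair_id,
                        triplet_id=tr.triplet_id,
                        pair_type=f"mimic-{role}",
                        mimic_id=tr.mimic,
                        other_id=species,
                        group=tr.group,
                        major_taxon=tr.major_taxon,
                        trait=trait,
                        distance=val,
                    )
                )
            for cat in CATEGORIES:
                raw = category_accuracy(dists, cat)
                if raw is None:
                    logger.warning(
                        "pair %s: category %s missing (incomplete member traits)", pair_id, cat
                    )
                cat_rows.append(
                    dict(
                        pair_id=pair_id,
                        triplet_id=tr.triplet_id,
                        pair_type=f"mimic-{role}",
                        mimic_id=tr.mimic,
                        group=tr.group,
                        major_taxon=tr.major_taxon,
                        category=cat,
                        raw=raw,
                        missing=raw is None,
                    )
                )
    trait_table = pd.DataFrame(trait_rows)
    category_table = pd.DataFrame(cat_rows)
    category_table["scaled"] = np.nan
    for cat in CATEGORIES:
        ma = category_table.query("category == @cat and pair_type == 'mimic-ant'")["raw"].dropna()
        if len(ma) >= 2 and float(np.std(ma, ddof=1)) > 0:
            sd = float(np.std(ma, ddof=1))
            sel = category_table["category"] == cat
            category_table.loc[sel, "scaled"] = category_table.loc[sel, "raw"] / sd
    return trait_table, category_table
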