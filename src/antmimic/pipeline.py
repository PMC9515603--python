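"""End-to-end orchestration: raw inputs → trait summaries → analyses.

Glue between the measurement modules and the statistical modules; consumed by
the command-line interface and usable directly from Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import morphometry, movement
from .accuracy import CATEGORIES, SpeciesSummary, build_pair_tables
from .mixed_models import LMEFit, compare_categories_lme, fit_pairtype_lme
from .morphometry import SilhouetteMask
from .movement import MotionParams, Trajectory
from .phylo_gls import (
    AncovaFit,
    SignalEstimate,
    bonferroni,
    lambda_signal,
    pgls_ancova,
    tree_to_vcv,
)
from .spectra import SpecimenSpectra, species_mean_spectrum
from .synthetic_data import StudyBundle

logger = logging.getLogger(__name__)


def summarize_species(
    masks: dict[tuple[str, str], list],
    spectra: dict[tuple[str, str], list[SpecimenSpectra]],
    trajectories: dict[tuple[str, str], list],
    species_ids: dict[tuple[str, str], str] | None = None,
    motion_params: MotionParams | None = None,
) -> dict[tuple[str, str], SpeciesSummary]:
    """Species-level trait summaries per (triplet, role) measurement set.

    Masks and trajectories may come as bare objects or as (object, truth)
    tuples straight from the generator.  Scalar traits are averaged across
    specimens; outlines are averaged pointwise then standardized; spectra are
    averaged pointwise.
    """
    motion_params = motion_params or MotionParams()
    keys = set(masks) | set(spectra) | set(trajectories)
    out: dict[tuple[str, str], SpeciesSummary] = {}
    for key in sorted(keys):
        sid = species_ids.get(key, f"{key[0]}:{key[1]}") if species_ids else f"{key[0]}:{key[1]}"
        summary = SpeciesSummary(species_id=sid)
        if key in spectra and spectra[key]:
            summary.spectrum = species_mean_spectrum(spectra[key])
        scalars: dict[str, list[float]] = {}
        if key in masks and masks[key]:
            profiles = []
            for item in masks[key]:
                mask: SilhouetteMask = item[0] if isinstance(item, tuple) else item
                shape, size = morphometry.shape_and_size_traits(mask)
                profiles.append(shape.outline)
                scalars.setdefault("circularity", []).append(shape.circularity)
                scalars.setdefault("body_length", []).append(size.body_length)
                if np.isfinite(size.mean_thickness):
                    scalars.setdefault("thickness", []).append(size.mean_thickness)
            summary.outline = morphometry.species_mean_outline(profiles).distances
        if key in trajectories and trajectories[key]:
            for item in trajectories[key]:
                traj: Trajectory = item[0] if isinstance(item, tuple) else item
                traits = movement.movement_traits(traj, motion_params)
                scalars.setdefault("velocity", []).append(traits.mean_velocity)
                scalars.setdefault("locomotion", []).append(traits.locomotion_prop)
                scalars.setdefault("angular_velocity", []).append(traits.angular_velocity)
                if traits.mobility_pct is not None:
                    scalars.setdefault("mobility", []).append(traits.mobility_pct)
        summary.scalars = {k: float(np.mean(v)) for k, v in scalars.items() if v}
        out[key] = summary
    return out


@dataclass
class ComparativeResults:
    """Phylogenetic comparative analysis of mimic–ant category accuracies."""

    signal: dict[str, SignalEstimate]  # Pagel's λ per category
    ancova: dict[tuple[str, str], AncovaFit]  # pairwise category relationships
    correlations: dict[tuple[str, str], float]
    bonferroni_m: int

    def significant(self, alpha: float = 0.05) -> dict[tuple[str, str], bool]:
        pairs = list(self.ancova)
        pvals = [self.ancova[p].slope_F[3] for p in pairs]
        dec = bonferroni(pvals, self.bonferroni_m, alpha)
        return dict(zip(pairs, (bool(d) for d in dec)))


def comparative_analysis(
    category_table: pd.DataFrame,
    tree,
    bonferroni_m: int = 6,
) -> ComparativeResults:
    """λ signal per category plus taxon-split ANCOVA for each category pair.

    Runs on mimic–ant rows only.  Species with a missing category (e.g. no
    behavioral recordings) are dropped pairwise, mirroring how incomplete
    species are handled in practice.
    """
    ma = category_table[category_table.pair_type == "mimic-ant"]
    wide = ma.pivot_table(index="mimic_id", columns="category", values="scaled", aggfunc="mean")
    taxon = ma.drop_duplicates("mimic_id").set_index("mimic_id")["major_taxon"]
    C_full = tree_to_vcv(tree)

    signal: dict[str, SignalEstimate] = {}
    for cat in CATEGORIES:
        if cat not in wide:
            continue
        vals = wide[cat].dropna()
        if len(vals) < 4:
            continue
        C = C_full.reorder(list(vals.index))
        signal[cat] = lambda_signal(vals.to_numpy(), C)

    ancova: dict[tuple[str, str], AncovaFit] = {}
    correlations: dict[tuple[str, str], float] = {}
    cats = [c for c in CATEGORIES if c in wide]
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1 :]:
            sub = wide[[c1, c2]].dropna()
            if len(sub) < 6:
                continue
            C = C_full.reorder(list(sub.index))
            tax = taxon.loc[sub.index].to_numpy()
            try:
                ancova[(c1, c2)] = pgls_ancova(sub[c1].to_numpy(), sub[c2].to_numpy(), tax, C)
            except ValueError as e:
                logger.warning("ANCOVA %s~%s skipped: %s", c1, c2, e)
            from .phylo_gls import phylo_correlation

            correlations[(c1, c2)] = phylo_correlation(
                sub[c1].to_numpy(), sub[c2].to_numpy(), C
            )
    return ComparativeResults(signal, ancova, correlations, bonferroni_m)


@dataclass
class StudyResults:
    trait_table: pd.DataFrame
    category_table: pd.DataFrame
    pairtype_fits: dict[str, LMEFit]  # per category
    category_fit: LMEFit | None
    comparative: ComparativeResults


def analyze_bundle(
    bundle: StudyBundle,
    motion_params: MotionParams | None = None,
    run_comparative: bool = True,
) -> StudyResults:
    """Full pipeline on a generated (or loaded) study bundle."""
    species_ids = {}
    for t in bundle.triplets:
        species_ids[(t.triplet_id, "mimic")] = t.mimic
        species_ids[(t.triplet_id, "ant")] = t.ant
        species_ids[(t.triplet_id, "control")] = t.control
    summaries = summarize_species(
        bundle.masks, bundle.spectra, bundle.trajectories, species_ids, motion_params
    )
    # key pair tables by mimic species id for the comparative step
    trait_table, category_table = build_pair_tables(bundle.triplets, summaries)

    pairtype_fits: dict[str, LMEFit] = {}
    for cat in CATEGORIES:
        sub = category_table[(category_table.category == cat) & category_table.raw.notna()]
        sub = sub.rename(columns={"raw": "distance"})
        if sub.pair_type.nunique() == 2:
            pairtype_fits[cat] = fit_pairtype_lme(
                sub.assign(pair_id=sub.triplet_id), response="distance"
            )
    ma = category_table[(category_table.pair_type == "mimic-ant") & category_table.scaled.notna()]
    category_fit = compare_categories_lme(ma) if ma.category.nunique() == 4 else None
    comparative = (
        comparative_analysis(category_table, bundle.tree) if run_comparative else None
    )
    return StudyResults(trait_table, category_table, pairtype_fits, category_fit, comparative)
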