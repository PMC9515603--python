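"""File formats for study inputs and outputs.

Masks are 8-bit grayscale PNGs (foreground > 127) with a per-specimen
metadata CSV carrying the mm/px scale and a landmark CSV
(specimen_id, appendage_id, segment, x_px, y_px, axis_dx, axis_dy).
Spectra, trajectories and the triplet table are tidy CSVs; the phylogeny is
Newick; configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from PIL import Image

from .morphometry import Landmark, SilhouetteMask
from .movement import Trajectory
from .spectra import WAVELENGTH_GRID, SpecimenSpectra
from .synthetic_data import StudyBundle


def write_mask_png(path: Path, pixels: np.ndarray) -> None:
    Image.fromarray((np.asarray(pixels) > 0).astype(np.uint8) * 255, mode="L").save(path)


def read_mask_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def read_mask(
    mask_path: Path,
    scale: float,
    body_only_path: Path | None = None,
    landmarks: pd.DataFrame | None = None,
) -> SilhouetteMask:
    pixels = read_mask_png(mask_path)
    body = read_mask_png(body_only_path) if body_only_path else None
    lms = []
    if landmarks is not None and len(landmarks):
        for r in landmarks.itertuples():
            lms.append(Landmark(int(r.appendage_id), str(r.segment), float(r.x_px),
                                float(r.y_px), float(r.axis_dx), float(r.axis_dy)))
    return SilhouetteMask(pixels, scale, lms, body)


def write_study(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Write a generated study to disk in the formats the pipeline reads."""
    out = Path(outdir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    bundle.tree.write(path=str(out / "tree.nwk"), schema="newick", suppress_rooting=True)

    pd.DataFrame(
        [
            dict(triplet_id=t.triplet_id, mimic_id=t.mimic, ant_id=t.ant,
                 control_id=t.control, group=t.group, major_taxon=t.major_taxon)
            for t in bundle.triplets
        ]
    ).to_csv(out / "triplets.csv", index=False)

    meta_rows, lm_rows, spec_rows, traj_rows = [], [], [], []
    for (trip, role), mask_list in bundle.masks.items():
        for i, (mask, _truth) in enumerate(mask_list):
            sid = f"{trip}_{role}_{i + 1}"
            write_mask_png(out / "masks" / f"{sid}.png", mask.pixels)
            write_mask_png(out / "masks" / f"{sid}_body.png", mask.body_only_pixels)
            meta_rows.append(dict(specimen_id=sid, triplet_id=trip, role=role,
                                  scale_mm_per_px=mask.scale))
            for lm in mask.appendage_landmarks:
                lm_rows.append(dict(specimen_id=sid, appendage_id=lm.appendage_id,
                                    segment=lm.segment, x_px=lm.x, y_px=lm.y,
                                    axis_dx=lm.axis_dx, axis_dy=lm.axis_dy))
    for (trip, role), specs in bundle.spectra.items():
        for i, sp in enumerate(specs):
            sid = f"{trip}_{role}_{i + 1}"
            for part, sl in (("anterior", slice(0, 400)), ("posterior", slice(400, 800))):
                spec_rows.append(
                    pd.DataFrame(dict(specimen_id=sid, triplet_id=trip, role=role,
                                      body_part=part, wavelength_nm=WAVELENGTH_GRID,
                                      reflectance=sp.vector[sl]))
                )
    for (trip, role), trajs in bundle.trajectories.items():
        for i, (traj, _truth) in enumerate(trajs):
            sid = f"{trip}_{role}_{i + 1}"
            traj_rows.append(
                pd.DataFrame(dict(specimen_id=sid, triplet_id=trip, role=role, t_s=traj.t,
                                  x_cm=traj.x, y_cm=traj.y, body_change=traj.body_change))
            )
    pd.DataFrame(meta_rows).to_csv(out / "specimens.csv", index=False)
    pd.DataFrame(lm_rows).to_csv(out / "landmarks.csv", index=False)
    pd.concat(spec_rows, ignore_index=True).to_csv(out / "spectra.csv", index=False)
    pd.concat(traj_rows, ignore_index=True).to_csv(out / "trajectories.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(_jsonable(bundle.ground_truth), fh, indent=1)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_study(indir: str | Path):
    """Read a study directory back into in-memory objects.

    Returns (tree, triplets_df, specimens_df, masks, spectra, trajectories)
    where the last three are keyed by (triplet_id, role) like a StudyBundle.
    """
    ind = Path(indir)
    tree = dendropy.Tree.get(path=str(ind / "tree.nwk"), schema="newick")
    triplets = pd.read_csv(ind / "triplets.csv")
    specimens = pd.read_csv(ind / "specimens.csv")
    landmarks = pd.read_csv(ind / "landmarks.csv")
    spectra_df = pd.read_csv(ind / "spectra.csv")
    traj_df = pd.read_csv(ind / "trajectories.csv")

    masks: dict[tuple[str, str], list[SilhouetteMask]] = {}
    for r in specimens.itertuples():
        key = (str(r.triplet_id), str(r.role))
        lm = landmarks[landmarks.specimen_id == r.specimen_id]
        mask = read_mask(
            ind / "masks" / f"{r.specimen_id}.png",
            float(r.scale_mm_per_px),
            ind / "masks" / f"{r.specimen_id}_body.png",
            lm,
        )
        masks.setdefault(key, []).append(mask)

    spectra: dict[tuple[str, str], list[SpecimenSpectra]] = {}
    for (sid, trip, role), g in spectra_df.groupby(["specimen_id", "triplet_id", "role"], sort=True):
        ant = g[g.body_part == "anterior"].sort_values("wavelength_nm")["reflectance"].to_numpy()
        post = g[g.body_part == "posterior"].sort_values("wavelength_nm")["reflectance"].to_numpy()
        spectra.setdefault((str(trip), str(role)), []).append(
            SpecimenSpectra(str(sid), np.concatenate([ant, post]))
        )

    trajectories: dict[tuple[str, str], list[Trajectory]] = {}
    for (sid, trip, role), g in traj_df.groupby(["specimen_id", "triplet_id", "role"], sort=True):
        g = g.sort_values("t_s")
        trajectories.setdefault((str(trip), str(role)), []).append(
            Trajectory(g.t_s.to_numpy(), g.x_cm.to_numpy(), g.y_cm.to_numpy(),
                       g.body_change.to_numpy() if "body_change" in g else None)
        )
    return tree, triplets, specimens, masks, spectra, trajectories
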