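"""Synthetic study generator with known ground truth.

Emulates the structure of a multi-trait ant-mimicry study: mimic–ant–control
triplets nested in eight taxonomic groups (six spider, two insect), mimic
species related by a pure-birth phylogeny, and every raw input the pipeline
consumes — silhouette masks with appendage landmarks, reflectance spectra,
centroid trajectories — generated from role-level phenotype parameters.

The key dial is the mimic position θ ∈ [0, 1]: each mimic phenotype is the
convex combination θ·ant + (1−θ)·control of its model and control phenotypes
plus noise, so θ = 1 is a perfect mimic and θ = 0 is indistinguishable from
the control.  Per-category mimic positions carry phylogenetic signal: their
deviations evolve on the tree with a tunable Pagel λ.  Color accuracy is
coupled to shape accuracy with a slope whose sign depends on the major taxon
(positive for insects, negative for spiders), mirroring the contrasting
co-evolution the analysis is designed to detect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .accuracy import CATEGORIES, TripletRecord
from .morphometry import Landmark, SilhouetteMask
from .movement import Trajectory
from .phylo_gls import PhyloCovariance, apply_lambda, tree_to_vcv
from .spectra import N_POINTS, WAVELENGTH_GRID, SpecimenSpectra

MM_PER_PX = 0.05

#: Role-level phenotype presets.  Ants are elongated and articulated (deep
#: constrictions, thin appendages) and move fast; controls are rounder,
#: thicker-limbed and slower.  Lengths/widths in px, speeds in cm/s.
ANT_PRESET = dict(
    length=150.0,
    halfwidth=11.0,
    constriction=0.72,
    curvature=0.05,
    leg_len=16.0,
    leg_widths=(4.0, 3.2, 2.4),
    speed=2.0,
    go_prob=0.60,
    turn_sd=6.0,
    mobility_p=0.45,
    spectra_bumps=((360.0, 35.0, 0.25), (560.0, 60.0, 0.20)),
)
CONTROL_PRESET = dict(
    length=180.0,
    halfwidth=20.0,
    constriction=0.18,
    curvature=0.10,
    leg_len=16.0,
    leg_widths=(7.5, 6.5, 5.5),
    speed=0.8,
    go_prob=0.30,
    turn_sd=18.0,
    mobility_p=0.12,
    spectra_bumps=((420.0, 45.0, 0.45), (640.0, 50.0, 0.40)),
)

SPIDER_GROUPS = ("Corinnidae", "Gnaphosidae", "Salticidae", "Myrmarachne", "Zodariidae", "OtherSpiders")
INSECT_GROUPS = ("Hemiptera", "OtherInsects")
GROUPS = SPIDER_GROUPS + INSECT_GROUPS


@dataclass
class StudyScenario:
    """Conditions of one synthetic study; defaults mirror the field design."""

    n_triplets: int = 72
    n_groups: int = 8
    n_specimens: int = 3
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    theta: float = 0.8  # mimic position: 0 = at control, 1 = at ant
    theta_sd: float = 0.10  # SD of per-category mimic-position deviations
    lambda_true: dict[str, float] = field(
        default_factory=lambda: {"color": 0.0, "movement": 0.30, "shape": 0.36, "size": 0.48}
    )
    color_shape_slope: dict[str, float] = field(
        default_factory=lambda: {"insect": 0.8, "spider": -0.8}
    )
    specimen_jitter: float = 0.03  # multiplicative phenotype noise per specimen
    spectra_noise_sd: float = 0.02
    duration_s: float = 60.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if min(self.theta_sd, self.specimen_jitter, self.spectra_noise_sd) <= 0:
            raise ValueError("all noise SDs must be > 0")
        if self.n_groups != len(GROUPS):
            raise ValueError(f"n_groups must be {len(GROUPS)} (the taxonomic group design)")


# ---------------------------------------------------------------------------
# tree and trait simulation


def gen_tree(n_tips: int, rate: float = 1.0, seed: int = 0, depth: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` tips labelled mimic_001..., depth-normalized."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    prng = random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=prng,
    )
    # the simulator stops at the n-th birth, leaving a zero-length cherry and
    # a singular covariance; run the clock on to the next (memoryless) event
    extra = prng.expovariate(n_tips * rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # relabel tips deterministically and scale depth
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(f"mimic_{i + 1:03d}")
    tree.taxon_namespace = taxa
    max_depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / max_depth * depth
    return tree


def sim_traits_lambda(
    C: PhyloCovariance | np.ndarray,
    lam: float,
    sigma2: float,
    mean: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw from N(mean, σ²·C(λ)) — the simulation inverse of λ estimation."""
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    n = M.shape[0]
    mu = np.broadcast_to(np.asarray(mean, float), (n,))
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return mu.copy()
    V = apply_lambda(M, lam) * sigma2
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    return mu + L @ rng.standard_normal(n)


def sim_ancova_data(
    C: PhyloCovariance | np.ndarray,
    slopes: dict[str, float],
    rng: np.random.Generator,
    lam_x: float = 0.3,
    lam_resid: float = 0.3,
    resid_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariate, taxon factor and response for a taxon-split regression.

    Tips are assigned to the eight taxonomic groups round-robin (six spider,
    two insect groups, as in the study design); x evolves on the tree with
    signal ``lam_x`` and unit variance, and y = slope_taxon·x + ε with ε
    evolving with signal ``lam_resid`` and SD ``resid_sd``.  Returns
    (y, x, taxon).
    """
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    n = M.shape[0]
    taxon = np.array(
        ["insect" if GROUPS[i % len(GROUPS)] in INSECT_GROUPS else "spider" for i in range(n)]
    )
    x = sim_traits_lambda(M, lam_x, 1.0, 0.0, rng)
    x = (x - x.mean()) / x.std()
    beta = np.array([slopes[t] for t in taxon])
    eps = sim_traits_lambda(M, lam_resid, resid_sd**2, 0.0, rng)
    y = beta * x + eps
    return y, x, taxon


# ---------------------------------------------------------------------------
# silhouettes


def _body_params(role_params: dict, rng: np.random.Generator, jitter: float) -> dict:
    out = dict(role_params)
    for key in ("length", "halfwidth", "constriction", "curvature", "leg_len"):
        out[key] = role_params[key] * (1 + jitter * rng.standard_normal())
    out["leg_widths"] = tuple(
        w * (1 + jitter * rng.standard_normal()) for w in role_params["leg_widths"]
    )
    out["constriction"] = float(np.clip(out["constriction"], 0.0, 0.9))
    return out


def _capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, halfwidth: float) -> None:
    """Rasterize a thick line segment (capsule) into a boolean mask, in place."""
    lo = np.floor(np.minimum(p0, p1) - halfwidth - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + halfwidth + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [mask.shape[1], mask.shape[0]])
    if np.any(hi <= lo):
        return
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    gx, gy = np.meshgrid(xs, ys)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = (gx - p0[0]) ** 2 + (gy - p0[1]) ** 2
    else:
        t = np.clip(((gx - p0[0]) * d[0] + (gy - p0[1]) * d[1]) / L2, 0, 1)
        dist2 = (gx - p0[0] - t * d[0]) ** 2 + (gy - p0[1] - t * d[1]) ** 2
    mask[lo[1] : hi[1], lo[0] : hi[0]] |= dist2 <= halfwidth**2


def gen_silhouette(
    role: str,
    params: dict | None = None,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.03,
) -> tuple[SilhouetteMask, dict]:
    """Render one specimen silhouette and its generating ground truth.

    The body is a tube of varying half-width around a (possibly curved)
    spine: an elliptical envelope with Gaussian constrictions at 1/3 and 2/3
    of the body length whose depth is the ``constriction`` parameter.  Four
    appendage pairs are attached as tapered three-segment bars; landmarks
    record each segment midpoint and axis direction for one side.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params is None:
        if role == "ant":
            base = ANT_PRESET
        elif role == "control":
            base = CONTROL_PRESET
        else:  # mimic defaults halfway
            base = {
                k: (
                    tuple((a + b) / 2 for a, b in zip(ANT_PRESET[k], CONTROL_PRESET[k]))
                    if isinstance(ANT_PRESET[k], tuple)
                    else (ANT_PRESET[k] + CONTROL_PRESET[k]) / 2
                )
                for k in ANT_PRESET
                if k != "spectra_bumps"
            }
        params = {k: v for k, v in base.items() if k != "spectra_bumps"}
    p = _body_params(params, rng, jitter)

    L = p["length"]
    hw = p["halfwidth"]
    curve_amp = p["curvature"] * L * 0.5
    leg_reach = p["leg_len"] * 2.2 + max(p["leg_widths"])
    margin = int(np.ceil(hw + leg_reach + 4))
    width_px = int(np.ceil(L)) + 2 * 12
    height_px = 2 * margin + int(np.ceil(2 * curve_amp)) + 8
    x0, yc = 12.0, height_px / 2.0

    s = np.linspace(0.0, L, 220)
    u = s / L
    spine_x = x0 + s
    spine_y = yc + curve_amp * np.sin(np.pi * u) - curve_amp * 0.5
    # half-width profile: superelliptical envelope with two constrictions
    envelope = np.sqrt(np.clip(1 - (2 * u - 1) ** 4, 0, 1))
    w = hw * envelope
    for pos in (1.0 / 3.0, 2.0 / 3.0):
        w = w * (1 - p["constriction"] * np.exp(-(((u - pos) / 0.055) ** 2)))
    w = np.clip(w, 1.2, None)

    # the spine is x-monotonic with gentle curvature, so the body tube is
    # rasterized column-wise as a vertical extent around the spine
    body = np.zeros((height_px, width_px), dtype=bool)
    cols = np.arange(width_px, dtype=float)
    inside = (cols >= spine_x[0]) & (cols <= spine_x[-1])
    cy = np.interp(cols, spine_x, spine_y)
    cw = np.where(inside, np.interp(cols, spine_x, w), -1.0)
    rows_grid = np.arange(height_px, dtype=float)[:, None]
    body = np.abs(rows_grid - cy[None, :]) <= cw[None, :]

    # appendages: 4 pairs attached along the anterior half of the spine
    full = body.copy()
    landmarks: list[Landmark] = []
    seg_fracs = (0.18, 0.30, 0.42, 0.54)
    seg_lens = (p["leg_len"], p["leg_len"] * 0.9, p["leg_len"] * 0.8)
    truth_widths = []
    for k, frac in enumerate(seg_fracs):
        i = int(frac * (len(s) - 1))
        base_pt = np.array([spine_x[i], spine_y[i]])
        # local spine normal
        tang = np.array([spine_x[min(i + 1, len(s) - 1)] - spine_x[max(i - 1, 0)],
                         spine_y[min(i + 1, len(s) - 1)] - spine_y[max(i - 1, 0)]])
        tang /= np.hypot(*tang)
        normal = np.array([-tang[1], tang[0]])
        for side in (+1, -1):
            ang0 = np.arctan2(side * normal[1], side * normal[0])
            sweep = np.deg2rad(-35 + 18 * k)  # fan the legs out along the body
            start = base_pt + side * normal * max(w[i] - 2.0, 0.0)
            pos0 = start
            for j, (slen, swid) in enumerate(zip(seg_lens, p["leg_widths"])):
                ang = ang0 + sweep + side * np.deg2rad(12.0 * j)
                direction = np.array([np.cos(ang), np.sin(ang)])
                pos1 = pos0 + direction * slen
                _capsule(full, pos0, pos1, swid / 2.0)
                if side == +1:
                    mid = (pos0 + pos1) / 2
                    landmarks.append(
                        Landmark(k + 1, ("femur", "tibia", "tarsus")[j], mid[0], mid[1],
                                 direction[0], direction[1])
                    )
                    if k == 0:
                        pass
                    truth_widths.append(swid)
                pos0 = pos1

    mask = SilhouetteMask(
        pixels=full,
        scale=MM_PER_PX,
        appendage_landmarks=landmarks,
        body_only_pixels=body,
    )
    truth = dict(
        spine=np.column_stack([spine_x, spine_y]),
        length_px=float(L),
        length_mm=float(L * MM_PER_PX),
        halfwidth_px=float(hw),
        constriction=float(p["constriction"]),
        constriction_positions=(1.0 / 3.0, 2.0 / 3.0),
        segment_widths_px=np.array(truth_widths),
        segment_widths_mm=np.array(truth_widths) * MM_PER_PX,
        params=p,
    )
    return mask, truth


# ---------------------------------------------------------------------------
# trajectories


def gen_trajectory(
    profile: dict | None = None,
    duration: float = 60.0,
    fps: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Trajectory, dict]:
    """Correlated random walk with stop/go switching and a body-change channel.

    ``profile`` keys: speed (cm/s in the go state), go_prob (stationary
    fraction of time spent moving), turn_sd (deg per frame heading noise),
    mobility_p (probability a stationary frame shows body movement).
    Returns the trajectory and its realized ground-truth metrics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = profile or dict(speed=1.5, go_prob=0.5, turn_sd=10.0, mobility_p=0.3)
    n = int(round(duration * fps)) + 1
    dt = 1.0 / fps
    # two-state Markov chain with mean bout length ~3 s and stationary go_prob
    mean_bout = 3.0 * fps
    g = float(np.clip(profile["go_prob"], 0.0, 1.0))
    p_go_to_stop = min(1.0, (1.0 / mean_bout) * (1 - g) * 2) if g > 0 else 1.0
    p_stop_to_go = min(1.0, (1.0 / mean_bout) * g * 2)
    state = np.empty(n, dtype=bool)
    state[0] = rng.random() < g
    r = rng.random(n)
    for i in range(1, n):
        if state[i - 1]:
            state[i] = r[i] >= p_go_to_stop
        else:
            state[i] = r[i] < p_stop_to_go
    if g == 0:
        state[:] = False
    heading = np.cumsum(np.deg2rad(profile["turn_sd"]) * rng.standard_normal(n))
    speed = np.where(state, np.clip(profile["speed"] * (1 + 0.1 * rng.standard_normal(n)), 0, None), 0.0)
    vx = speed * np.cos(heading) * dt
    vy = speed * np.sin(heading) * dt
    x = np.concatenate([[0.0], np.cumsum(vx[1:])])
    y = np.concatenate([[0.0], np.cumsum(vy[1:])])
    body_change = np.where(
        state,
        rng.uniform(0.2, 0.8, n),
        (rng.random(n) < profile["mobility_p"]) * rng.uniform(0.1, 0.6, n),
    )
    t = np.arange(n) * dt
    traj = Trajectory(t=t, x=x, y=y, body_change=body_change)

    disp = np.hypot(np.diff(x), np.diff(y))
    go_steps = state[1:]
    # heading change between successive steps, counted where both steps moved
    dh = np.diff(heading)[1:]
    both = go_steps[1:] & go_steps[:-1]
    dheads = dh[both]
    truth = dict(
        mean_velocity=float(disp.sum() / (t[-1] - t[0])),
        locomotion_prop=float(go_steps.mean()),
        angular_velocity=float(np.mean(np.abs(np.rad2deg(dheads))) * fps) if len(dheads) else 0.0,
        mobility_pct=float(100.0 * np.mean(~state & (body_change > 0.05))),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# spectra


def _bump_curve(bumps: tuple, grid: np.ndarray) -> np.ndarray:
    c = np.full_like(grid, 0.05)
    for center, width, height in bumps:
        c = c + height * np.exp(-(((grid - center) / width) ** 2))
    return c


def gen_spectra(
    ant_bumps: tuple,
    control_bumps: tuple,
    theta: float,
    noise_sd: float,
    n_specimens: int,
    rng: np.random.Generator,
    prefix: str = "sp",
) -> dict[str, list[SpecimenSpectra]]:
    """Specimen spectra per role; the mimic curve is θ·ant + (1−θ)·control."""
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    grid = WAVELENGTH_GRID
    curves = {
        "ant": _bump_curve(ant_bumps, grid),
        "control": _bump_curve(control_bumps, grid),
    }
    curves["mimic"] = theta * curves["ant"] + (1 - theta) * curves["control"]
    out: dict[str, list[SpecimenSpectra]] = {}
    for role, curve in curves.items():
        specs = []
        for i in range(n_specimens):
            vec = np.empty(2 * N_POINTS)
            for part in range(2):
                shift = 1 + 0.05 * rng.standard_normal()  # posterior slightly differs
                jitter = noise_sd * rng.standard_normal(N_POINTS)
                vec[part * N_POINTS : (part + 1) * N_POINTS] = np.clip(
                    curve * shift + jitter, 0, None
                )
            specs.append(SpecimenSpectra(f"{prefix}_{role}_{i + 1}", vec))
        out[role] = specs
    return out


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus generating ground truth."""

    scenario: StudyScenario
    tree: dendropy.Tree
    triplets: list[TripletRecord]
    masks: dict[tuple[str, str], list[tuple[SilhouetteMask, dict]]]
    spectra: dict[tuple[str, str], list[SpecimenSpectra]]
    trajectories: dict[tuple[str, str], list[tuple[Trajectory, dict]]]
    ground_truth: dict


def _interp_params(ant: dict, control: dict, theta_shape: float, theta_size: float) -> dict:
    """Mimic silhouette parameters as a per-category convex combination."""
    mix = {}
    shape_keys = ("halfwidth", "constriction", "curvature")
    size_keys = ("length",)
    for k in shape_keys:
        mix[k] = theta_shape * ant[k] + (1 - theta_shape) * control[k]
    for k in size_keys:
        mix[k] = theta_size * ant[k] + (1 - theta_size) * control[k]
    mix["leg_len"] = 0.5 * (ant["leg_len"] + control["leg_len"])
    mix["leg_widths"] = tuple(
        theta_size * a + (1 - theta_size) * c for a, c in zip(ant["leg_widths"], control["leg_widths"])
    )
    return mix


def gen_study(scenario: StudyScenario) -> StudyBundle:
    """Generate one full synthetic study from a scenario.

    Per triplet the ant and control phenotypes are drawn around the presets;
    the mimic phenotype sits at the per-category mimic position θ_c between
    them.  θ_c deviations evolve on the mimic tree under the scenario's λ per
    category, and the color position is additionally coupled to the shape
    position with a taxon-signed slope.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    tree = gen_tree(sc.n_triplets, sc.birth_rate, seed=int(rng.integers(2**31 - 1)), depth=sc.tree_depth)
    C = tree_to_vcv(tree)
    tip_order = C.tip_labels

    # per-category mimic-position deviations with phylogenetic signal
    theta_dev: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        lam = sc.lambda_true.get(cat, 0.0)
        theta_dev[cat] = sim_traits_lambda(C, lam, sc.theta_sd**2, 0.0, rng)

    triplets: list[TripletRecord] = []
    masks = {}
    spectra = {}
    trajectories = {}
    group_of: dict[str, str] = {}
    taxon_of: dict[str, str] = {}
    theta_used: dict[str, dict[str, float]] = {}

    for t_idx, mimic_id in enumerate(tip_order):
        group = GROUPS[t_idx % sc.n_groups]
        major = "spider" if group in SPIDER_GROUPS else "insect"
        trip_id = f"T{t_idx + 1:03d}"
        trip = TripletRecord(
            triplet_id=trip_id,
            mimic=mimic_id,
            ant=f"ant_{t_idx + 1:03d}",
            control=f"ctrl_{t_idx + 1:03d}",
            group=group,
            major_taxon=major,
        )
        triplets.append(trip)
        group_of[mimic_id] = group
        taxon_of[mimic_id] = major

        i = tip_order.index(mimic_id)
        th = {cat: float(np.clip(sc.theta + theta_dev[cat][i], 0.05, 0.95)) for cat in CATEGORIES}
        # couple color to shape: inaccuracy_color = base + slope * shape deviation
        slope = sc.color_shape_slope["insect" if major == "insect" else "spider"]
        dev_shape = sc.theta - th["shape"]  # positive when the mimic is a worse shape mimic
        th["color"] = float(np.clip(sc.theta + theta_dev["color"][i] - slope * dev_shape, 0.05, 0.95))
        theta_used[mimic_id] = th

        # triplet-level phenotype draws around the presets
        ant_p = _body_params({k: v for k, v in ANT_PRESET.items() if k != "spectra_bumps"}, rng, 0.05)
        ctrl_p = _body_params(
            {k: v for k, v in CONTROL_PRESET.items() if k != "spectra_bumps"}, rng, 0.05
        )
        mimic_p = _interp_params(ant_p, ctrl_p, th["shape"], th["size"])
        sil_params = {"ant": ant_p, "control": ctrl_p, "mimic": mimic_p}

        move_profiles = {}
        for role in ("ant", "control"):
            preset = ANT_PRESET if role == "ant" else CONTROL_PRESET
            move_profiles[role] = dict(
                speed=preset["speed"] * (1 + 0.05 * rng.standard_normal()),
                go_prob=float(np.clip(preset["go_prob"] * (1 + 0.05 * rng.standard_normal()), 0.05, 0.95)),
                turn_sd=preset["turn_sd"] * (1 + 0.05 * rng.standard_normal()),
                mobility_p=float(np.clip(preset["mobility_p"] * (1 + 0.05 * rng.standard_normal()), 0.02, 0.95)),
            )
        tm = th["movement"]
        move_profiles["mimic"] = {
            k: tm * move_profiles["ant"][k] + (1 - tm) * move_profiles["control"][k]
            for k in move_profiles["ant"]
        }

        # spectra base curves per triplet (jittered presets)
        ant_bumps = tuple(
            (c * (1 + 0.02 * rng.standard_normal()), wdt, h * (1 + 0.05 * rng.standard_normal()))
            for c, wdt, h in ANT_PRESET["spectra_bumps"]
        )
        ctrl_bumps = tuple(
            (c * (1 + 0.02 * rng.standard_normal()), wdt, h * (1 + 0.05 * rng.standard_normal()))
            for c, wdt, h in CONTROL_PRESET["spectra_bumps"]
        )
        spec_by_role = gen_spectra(
            ant_bumps, ctrl_bumps, th["color"], sc.spectra_noise_sd, sc.n_specimens, rng, prefix=trip_id
        )

        for role in ("mimic", "ant", "control"):
            key = (trip_id, role)
            masks[key] = [
                gen_silhouette(role, sil_params[role], rng, jitter=sc.specimen_jitter)
                for _ in range(sc.n_specimens)
            ]
            spectra[key] = spec_by_role[role]
            trajectories[key] = [
                gen_trajectory(move_profiles[role], sc.duration_s, sc.fps, rng)
                for _ in range(sc.n_specimens)
            ]

    ground_truth = dict(
        lambda_true=dict(sc.lambda_true),
        theta=sc.theta,
        theta_per_mimic=theta_used,
        color_shape_slope=dict(sc.color_shape_slope),
        group_of=group_of,
        taxon_of=taxon_of,
    )
    return StudyBundle(
        scenario=sc,
        tree=tree,
        triplets=triplets,
        masks=masks,
        spectra=spectra,
        trajectories=trajectories,
        ground_truth=ground_truth,
    )
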