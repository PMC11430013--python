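"""Synthetic carboxysome pose populations and QconCAT peptide tables.

The pose generator emulates the organization seen in cryoET of
beta-carboxysomes: Rubiscos arranged in concentric layers spaced 120 A
apart, a single complex at the core, each layer filled quasi-uniformly at
a density calibrated so the fourth layer holds 174 particles, every
particle's 4-fold axis pointing radially (plus alignment noise). The
peptide generator emulates the isotope-dilution design: for each protein,
two Q-peptides per replicate, with the light/heavy area ratio carrying
the protein's molar amount relative to a spiked heavy standard.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .config import PoseSimConfig, QuantSimConfig

POSE_COLUMNS = ["carboxysome_id", "x_A", "y_A", "z_A",
                "rot_deg", "tilt_deg", "psi_deg"]
TRUTH_COLUMNS = ["carboxysome_id", "diameter_nm", "layer", "true_radius_A",
                 "centre_x_A", "centre_y_A", "centre_z_A"]
QUANT_COLUMNS = ["protein", "peptide", "replicate",
                 "light_area", "heavy_area", "spike_pmol"]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def golden_spiral(n: int, balance: bool = True) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (Fibonacci lattice).

    With ``balance`` the lattice is nudged (subtract centroid,
    renormalize, iterated) so its centroid is the origin to ~1e-12; the
    raw spiral has a small azimuthal imbalance that would otherwise
    shift a noiseless carboxysome's centre of mass off its centre.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    if balance and n >= 2:
        for _ in range(100):
            centroid = pts.mean(axis=0)
            if np.abs(centroid).max() < 1e-13:
                break
            pts = pts - centroid
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def layer_radii(config: PoseSimConfig, diameter_nm: float) -> np.ndarray:
    """Lattice radii r_l = (l-1)*d that fit inside the lumen.

    The usable lumen radius is ``inradius_factor * (D/2) - shell_clearance``;
    layers are kept while their radius does not exceed it.
    """
    d = config.lattice_spacing_A
    lumen = config.inradius_factor * (diameter_nm * 10.0 / 2.0) \
        - config.shell_clearance_A
    if lumen < 0.0:
        raise ValueError(
            "diameter too small for a single Rubisco layer: "
            f"{diameter_nm:.1f} nm < minimum feasible "
            f"{config.min_feasible_diameter_nm:.1f} nm")
    n_layers = int(lumen // d) + 1
    return d * np.arange(n_layers)


def layer_capacity(radius_A: float, area_per_particle_A2: float) -> int:
    """Particles a spherical layer holds: round(4*pi*r^2 / a); 1 at r=0."""
    if radius_A == 0.0:
        return 1
    return int(round(4.0 * math.pi * radius_A**2 / area_per_particle_A2))


def _rotations_to(axes: np.ndarray) -> Rotation:
    """Minimal rotations taking the lab z-axis onto each row of ``axes``."""
    z = np.array([0.0, 0.0, 1.0])
    c = np.clip(axes @ z, -1.0, 1.0)
    rv = np.cross(np.broadcast_to(z, axes.shape), axes)
    s = np.linalg.norm(rv, axis=1)
    angle = np.arctan2(s, c)
    unit = np.zeros_like(axes)
    ok = s > 1e-12
    unit[ok] = rv[ok] / s[ok, None]
    unit[~ok] = [1.0, 0.0, 0.0]  # at the poles any transverse axis works
    return Rotation.from_rotvec(unit * angle[:, None])


def _perpendicular_axes(axes: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """One uniformly random unit vector perpendicular to each row."""
    phi = rng.uniform(0.0, 2.0 * math.pi, len(axes))
    helper = np.tile([1.0, 0.0, 0.0], (len(axes), 1))
    helper[np.abs(axes[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    e1 = np.cross(axes, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    return np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2


def simulate_carboxysome(config: PoseSimConfig, diameter_nm: float,
                         seed: int | np.random.Generator,
                         carboxysome_id: str = "cb_000",
                         centre: np.ndarray | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one carboxysome's Rubisco poses plus its ground truth.

    Returns ``(poses, truth)``: poses carry coordinates (A) and intrinsic
    ZYZ Euler angles (deg), truth the per-particle layer index and the
    noiseless lattice radius.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    centre = np.zeros(3) if centre is None else np.asarray(centre, float)
    radii = layer_radii(config, diameter_nm)

    positions, axes, layers, true_r = [], [], [], []
    for layer_idx, r in enumerate(radii, start=1):
        if r == 0.0:
            positions.append(np.zeros((1, 3)))
            axes.append(golden_spiral(1))  # arbitrary; angle undefined at core
            layers.append(np.ones(1, dtype=int))
            true_r.append(np.zeros(1))
            continue
        n = layer_capacity(r, config.area_per_particle_A2)
        unit = golden_spiral(n)
        positions.append(r * unit)
        axes.append(unit)
        layers.append(np.full(n, layer_idx, dtype=int))
        true_r.append(np.full(n, r))
    positions = np.vstack(positions)
    axes = np.vstack(axes)
    layers = np.concatenate(layers)
    true_r = np.concatenate(true_r)

    if config.position_jitter_sd_A > 0:
        positions = positions + rng.normal(
            0.0, config.position_jitter_sd_A, positions.shape)

    sigma = math.radians(config.orientation_noise_sd_deg)
    n_total = len(positions)
    inplane = Rotation.from_euler(
        "z", rng.uniform(0.0, 2.0 * math.pi, (n_total, 1)))
    rot = _rotations_to(axes) * inplane
    if sigma > 0:
        tilt = np.abs(rng.normal(0.0, sigma, n_total))
        perp = _perpendicular_axes(axes, rng)
        rot = Rotation.from_rotvec(perp * tilt[:, None]) * rot
    eulers = rot.as_euler("ZYZ", degrees=True)

    poses = pd.DataFrame({
        "carboxysome_id": carboxysome_id,
        "x_A": centre[0] + positions[:, 0],
        "y_A": centre[1] + positions[:, 1],
        "z_A": centre[2] + positions[:, 2],
        "rot_deg": eulers[:, 0],
        "tilt_deg": eulers[:, 1],
        "psi_deg": eulers[:, 2],
    })
    truth = pd.DataFrame({
        "carboxysome_id": carboxysome_id,
        "diameter_nm": diameter_nm,
        "layer": layers,
        "true_radius_A": true_r,
        "centre_x_A": centre[0],
        "centre_y_A": centre[1],
        "centre_z_A": centre[2],
    })
    return poses, truth


def simulate_population(n: int, config: PoseSimConfig,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n`` carboxysomes with Normal(mean, sd) diameters.

    Diameters below the feasibility minimum are redrawn rather than
    clipped, so no degenerate zero-layer organelle is emitted. Each
    carboxysome is dropped at a random centre inside a 1-um box, as in a
    tomogram's coordinate frame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(n + 1)[1:]

    min_d = config.min_feasible_diameter_nm
    poses_parts, truth_parts = [], []
    for i in range(n):
        diameter = float(master.normal(config.diameter_mean_nm,
                                       config.diameter_sd_nm))
        while diameter < min_d:
            diameter = float(master.normal(config.diameter_mean_nm,
                                           config.diameter_sd_nm))
        centre = master.uniform(-5000.0, 5000.0, 3)
        poses, truth = simulate_carboxysome(
            config, diameter, np.random.default_rng(children[i]),
            carboxysome_id=f"cb_{i:03d}", centre=centre)
        poses_parts.append(poses)
        truth_parts.append(truth)
    return (pd.concat(poses_parts, ignore_index=True),
            pd.concat(truth_parts, ignore_index=True))


def simulate_peptide_quant(config: QuantSimConfig) -> pd.DataFrame:
    """Simulate a QconCAT peptide quantification table.

    For protein *i*, peptide *p*, replicate *r* the light/heavy area ratio is

        (copies_i / copies_anchor) * anchor_pmol / spike_pmol * exp(eps)

    with eps ~ Normal(0, noise_cv); the heavy area is proportional to the
    spiked amount times a per-peptide response factor (which cancels in
    the ratio, as in the real measurement).
    """
    copies = dict(config.true_monomer_copies)
    if config.anchor not in copies or copies[config.anchor] <= 0:
        raise ValueError(
            f"anchor protein {config.anchor!r} missing or has zero copies")
    rng = np.random.default_rng(config.seed)
    anchor_copies = float(copies[config.anchor])

    rows = []
    for protein in copies:
        for p in range(1, config.peptides_per_protein + 1):
            # ionization-efficiency spread; identical for light and heavy
            response = 10.0 ** rng.uniform(-0.5, 0.5)
            for rep in range(1, config.n_replicates + 1):
                heavy = 1.0e6 * response * config.spike_pmol
                ratio = (copies[protein] / anchor_copies
                         * config.anchor_pmol / config.spike_pmol)
                if config.noise_cv > 0:
                    ratio *= math.exp(rng.normal(0.0, config.noise_cv))
                rows.append((protein, f"{protein}_pep{p}", f"rep{rep}",
                             ratio * heavy, heavy, config.spike_pmol))
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)
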