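"""Per-carboxysome spatial statistics of Rubisco poses.

Given particle centres and orientations for one or more carboxysomes,
these functions reproduce the standard cryoET post-processing of cargo
organization: the organelle core (mean particle position), radial
distances, concentric-layer assignment, neighbour distances, the angle
between each particle's 4-fold axis and its radial vector, and
population-level summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

DEFAULT_SPACING_A = 120.0
NEIGHBOUR_CUTOFF_A = 160.0
#: carboxysomes with fewer particles are summarized but kept out of
#: layer-count histograms
MIN_INTACT_PARTICLES = 4


@dataclass
class LayerProfile:
    """Radial structure of one carboxysome."""

    carboxysome_id: str
    core: np.ndarray
    particles: pd.DataFrame = field(repr=False)  # radius_A, layer, theta_deg
    layers: pd.DataFrame = field(repr=False)     # layer, mean_radius_A, count

    @property
    def n_layers(self) -> int:
        return int(self.layers["layer"].max())


def pose_axes(poses: pd.DataFrame) -> np.ndarray:
    """Unit 4-fold axes from intrinsic ZYZ Euler angles (degrees).

    The 4-fold axis is the body z-axis of the reference orientation.
    """
    rot = Rotation.from_euler(
        "ZYZ", poses[["rot_deg", "tilt_deg", "psi_deg"]].to_numpy(),
        degrees=True)
    return rot.apply(np.array([0.0, 0.0, 1.0]))


def estimate_core(positions: np.ndarray) -> np.ndarray:
    """Carboxysome core: the arithmetic mean of all particle positions."""
    positions = np.asarray(positions, float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("need at least one particle position")
    return positions.mean(axis=0)


def radial_distances(positions: np.ndarray, core: np.ndarray) -> np.ndarray:
    core = np.asarray(core, float)
    if not np.all(np.isfinite(core)):
        raise ValueError("core must be finite")
    return np.linalg.norm(np.asarray(positions, float) - core, axis=1)


def assign_layers(radii: np.ndarray, spacing: float = DEFAULT_SPACING_A,
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign each radial distance to a concentric layer (1 = innermost).

    Layer radii are located as peaks of a Gaussian kernel-density
    estimate of the radii (bandwidth ``spacing / 4``); peaks closer than
    ``spacing / 2`` are merged and each particle joins its nearest peak.
    With fewer than 20 particles (or degenerate radii) the lattice rule
    ``layer = round(r / spacing) + 1`` is used instead.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    radii = np.asarray(radii, float)
    if radii.size == 0:
        raise ValueError("no radii supplied")

    peaks = _kde_layer_peaks(radii, spacing) if radii.size >= 20 else None
    if peaks is None:
        # lattice rule keeps physical indices, so an empty shell leaves a gap
        layers = np.rint(radii / spacing).astype(int) + 1
    else:
        # a 1-particle layer (the core) can hide under a neighbouring
        # peak's slope: particles far from every peak seed a new one at
        # their nearest lattice radius before the final assignment
        resid = np.abs(radii[:, None] - peaks[None, :]).min(axis=1)
        orphans = radii[resid > spacing / 2.0]
        if orphans.size:
            extra = np.unique(np.rint(orphans / spacing)) * spacing
            peaks = np.sort(np.concatenate([peaks, extra]))
        # label peaks by their core-anchored lattice index (layer l sits
        # near (l-1)*spacing): a mislocated single-particle core layer
        # then costs one particle, not a whole-carboxysome label shift
        if len(peaks) > 1:
            d_hat = float(np.median(np.diff(peaks)))
            if not d_hat > 0:
                d_hat = spacing
        else:
            d_hat = spacing
        labels = np.rint(peaks / d_hat).astype(int) + 1
        for _ in range(len(peaks)):  # merge peaks landing on one index
            dup = np.flatnonzero(np.diff(labels) == 0)
            if dup.size == 0:
                break
            k = dup[0]
            peaks = np.concatenate([
                peaks[:k], [0.5 * (peaks[k] + peaks[k + 1])], peaks[k + 2:]])
            labels = np.rint(peaks / d_hat).astype(int) + 1
        nearest = np.abs(radii[:, None] - peaks[None, :]).argmin(axis=1)
        layers = labels[nearest]

    summary = (pd.DataFrame({"layer": layers, "radius_A": radii})
               .groupby("layer")["radius_A"].agg(["mean", "size"])
               .reset_index())
    summary = pd.DataFrame({
        "layer": summary["layer"].to_numpy(int),
        "mean_radius_A": summary["mean"].to_numpy(),
        "count": summary["size"].to_numpy(int),
    })
    return layers, summary


def _kde_layer_peaks(radii: np.ndarray, spacing: float) -> np.ndarray | None:
    bandwidth = spacing / 4.0
    sd = radii.std()
    if sd == 0.0:
        return None
    # per-layer particle counts grow like r^2, so an unweighted KDE
    # drowns the sparse inner layers (the core layer is one particle);
    # inverse-shell-area weights give every layer comparable mass
    weights = 1.0 / (radii**2 + bandwidth**2)
    # gaussian_kde scales its factor by the weighted data SD
    weighted_sd = math.sqrt(float(np.cov(radii, aweights=weights)))
    if weighted_sd == 0.0:
        return None
    kde = gaussian_kde(radii, bw_method=bandwidth / weighted_sd,
                       weights=weights)
    # extend past 0 so a central particle forms an interior peak
    grid = np.arange(-spacing, radii.max() + spacing, spacing / 50.0)
    density = kde(grid)
    idx, _ = find_peaks(density)
    peaks = grid[idx]
    peaks = peaks[peaks > -spacing / 2.0]
    if peaks.size == 0:
        return None
    merged = [peaks[0]]
    for p in peaks[1:]:
        if p - merged[-1] < spacing / 2.0:
            merged[-1] = 0.5 * (merged[-1] + p)
        else:
            merged.append(p)
    return np.array(merged)


def nearest_neighbour_distances(positions: np.ndarray) -> np.ndarray:
    """Distance from each particle to its closest companion."""
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two particles")
    dist, _ = cKDTree(positions).query(positions, k=2)
    return dist[:, 1]


def neighbour_pair_distances(positions: np.ndarray,
                             cutoff: float = NEIGHBOUR_CUTOFF_A,
                             ) -> np.ndarray:
    """Centre-to-centre distances of all particle pairs within ``cutoff``.

    This is the statistic behind the 'distance between neighbouring
    Rubiscos': every contact pair counted once, not just the single
    closest companion.
    """
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two particles")
    pairs = cKDTree(positions).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0)
    return np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]],
                          axis=1)


def axis_radial_angles(axes: np.ndarray, positions: np.ndarray,
                       core: np.ndarray) -> np.ndarray:
    """Angle (deg) between each particle's 4-fold axis and its radial vector.

    Folded to [0, 90] because the axis is undirected; radially aligned
    particles score 0. Particles at the core have no radial direction and
    get NaN.
    """
    vec = np.asarray(positions, float) - np.asarray(core, float)
    r = np.linalg.norm(vec, axis=1)
    theta = np.full(len(vec), np.nan)
    ok = r > 1e-9
    cosang = np.abs(np.einsum("ij,ij->i", axes[ok], vec[ok]) / r[ok])
    theta[ok] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return theta


def layer_profile(poses: pd.DataFrame,
                  spacing: float = DEFAULT_SPACING_A) -> LayerProfile:
    """Full radial analysis of a single carboxysome's pose table."""
    ids = poses["carboxysome_id"].unique()
    if len(ids) != 1:
        raise ValueError("layer_profile expects a single carboxysome")
    positions = poses[["x_A", "y_A", "z_A"]].to_numpy()
    core = estimate_core(positions)
    radii = radial_distances(positions, core)
    layers, summary = assign_layers(radii, spacing)
    theta = axis_radial_angles(pose_axes(poses), positions, core)
    particles = pd.DataFrame({
        "carboxysome_id": ids[0],
        "radius_A": radii,
        "layer": layers,
        "theta_deg": theta,
    }, index=poses.index)
    return LayerProfile(str(ids[0]), core, particles, summary)


def summarize_population(poses: pd.DataFrame,
                         spacing: float = DEFAULT_SPACING_A,
                         cutoff: float = NEIGHBOUR_CUTOFF_A,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Analyse every carboxysome in a pose table.

    Returns ``(particle_table, per_carboxysome, population)`` where the
    population dict carries the layer-count histogram (intact
    carboxysomes only), the fraction with 4-6 layers, particle-count
    moments and the pooled neighbour statistics.
    """
    particle_parts, rows = [], []
    nn_pool, pair_pool = [], []
    for cid, group in poses.groupby("carboxysome_id", sort=True):
        prof = layer_profile(group, spacing)
        particle_parts.append(prof.particles)
        positions = group[["x_A", "y_A", "z_A"]].to_numpy()
        n = len(group)
        nn = nearest_neighbour_distances(positions) if n >= 2 else np.empty(0)
        pairs = neighbour_pair_distances(positions, cutoff) if n >= 2 \
            else np.empty(0)
        nn_pool.append(nn)
        pair_pool.append(pairs)
        rows.append({
            "carboxysome_id": cid,
            "n_particles": n,
            "n_layers": prof.n_layers,
            "radial_extent_A": 2.0 * prof.particles["radius_A"].max(),
            "nn_mean_A": nn.mean() if nn.size else np.nan,
            "neighbour_mean_A": pairs.mean() if pairs.size else np.nan,
            "theta_mean_deg": prof.particles["theta_deg"].mean(),
        })
    per_carb = pd.DataFrame(rows)
    nn_pool = np.concatenate(nn_pool) if nn_pool else np.empty(0)
    pair_pool = np.concatenate(pair_pool) if pair_pool else np.empty(0)

    intact = per_carb[per_carb["n_particles"] >= MIN_INTACT_PARTICLES]
    hist = intact["n_layers"].value_counts().sort_index()
    frac_4_6 = float(intact["n_layers"].between(4, 6).mean()) \
        if len(intact) else math.nan
    population = {
        "n_carboxysomes": int(len(per_carb)),
        "layer_count_histogram": {int(k): int(v) for k, v in hist.items()},
        "modal_layer_count": int(hist.idxmax()) if len(hist) else None,
        "fraction_4_to_6_layers": frac_4_6,
        "particle_count_mean": float(per_carb["n_particles"].mean()),
        "particle_count_sd": float(per_carb["n_particles"].std(ddof=1))
        if len(per_carb) > 1 else 0.0,
        "nn_mean_A": float(nn_pool.mean()) if nn_pool.size else None,
        "nn_sd_A": float(nn_pool.std()) if nn_pool.size else None,
        "neighbour_mean_A": float(pair_pool.mean()) if pair_pool.size
        else None,
        "neighbour_sd_A": float(pair_pool.std()) if pair_pool.size else None,
        "neighbour_cutoff_A": float(cutoff),
    }
    particle_table = pd.concat(particle_parts, ignore_index=True)
    return particle_table, per_carb, population
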