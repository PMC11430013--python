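"""Configuration objects for the simulators and the pipeline.

All lengths at the interface follow the conventions of the cryoET
literature: particle coordinates and spacings in Angstrom, organelle
diameters in nanometres. Angles are degrees everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

# Layer-4 calibration: a sphere of radius 360 A (the fourth concentric
# layer at 120 A spacing) must hold 174 Rubiscos, so the effective
# surface area per particle is 4*pi*360^2/174 ~ 9360 A^2.
DEFAULT_AREA_PER_PARTICLE = 4.0 * math.pi * 360.0**2 / 174.0


@dataclass
class PoseSimConfig:
    """Parameters of the concentric-layer Rubisco pose generator.

    Attributes
    ----------
    diameter_mean_nm, diameter_sd_nm:
        Population distribution of carboxysome diameters (vertex-to-vertex),
        Normal(169.0, 11.8) nm by default.
    lattice_spacing_A:
        Radial distance between consecutive Rubisco layers (120 A).
    area_per_particle_A2:
        Effective sphere-surface area claimed by one Rubisco; sets in-layer
        density. Default calibrated so layer 4 holds 174 particles.
    position_jitter_sd_A:
        Isotropic Gaussian displacement applied to every lattice site.
    orientation_noise_sd_deg:
        SD of the tilt of the 4-fold axis away from the radial direction.
    shell_clearance_A:
        Gap between the outermost usable layer radius and the shell lumen
        (shell thickness plus Rubisco half-height).
    inradius_factor:
        Inscribed/circumscribed radius ratio converting the polyhedral
        diameter into the usable lumen radius (0.76 ~ icosahedron).
    """

    diameter_mean_nm: float = 169.0
    diameter_sd_nm: float = 11.8
    lattice_spacing_A: float = 120.0
    area_per_particle_A2: float = DEFAULT_AREA_PER_PARTICLE
    position_jitter_sd_A: float = 15.0
    orientation_noise_sd_deg: float = 10.0
    shell_clearance_A: float = 90.0
    inradius_factor: float = 0.76
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diameter_mean_nm", "lattice_spacing_A",
                     "area_per_particle_A2", "shell_clearance_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("diameter_sd_nm", "position_jitter_sd_A",
                     "orientation_noise_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.inradius_factor <= 1.0:
            raise ValueError("inradius_factor must lie in (0, 1]")

    @property
    def min_feasible_diameter_nm(self) -> float:
        """Smallest diameter that admits at least the central particle."""
        return 2.0 * self.shell_clearance_A / self.inradius_factor / 10.0


def _default_true_copies() -> dict[str, float]:
    from .stoichiometry import reference_composition

    ref = reference_composition()
    return dict(zip(ref["protein"], ref["monomer_copies"].astype(float)))


@dataclass
class QuantSimConfig:
    """Parameters of the QconCAT peptide-table generator.

    ``true_monomer_copies`` defaults to the reference carboxysome
    composition (13 proteins, RbcL = 5112 monomers). ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal measurement
    noise applied to each light/heavy ratio. ``anchor_pmol`` fixes the
    molar amount of the anchor protein in the (simulated) digest; only
    ratios of amounts survive the downstream arithmetic, so its value is
    a free scale.
    """

    true_monomer_copies: Mapping[str, float] = field(
        default_factory=_default_true_copies)
    peptides_per_protein: int = 2
    n_replicates: int = 4
    noise_cv: float = 0.2
    spike_pmol: float = 0.6
    anchor: str = "RbcL"
    anchor_pmol: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.spike_pmol <= 0 or self.anchor_pmol <= 0:
            raise ValueError("spike_pmol and anchor_pmol must be > 0")
        if any(v < 0 for v in self.true_monomer_copies.values()):
            raise ValueError("true_monomer_copies must be non-negative")


def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    if "true_monomer_copies" in d:
        d["true_monomer_copies"] = dict(d["true_monomer_copies"])
    return d


def config_to_yaml(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_asdict(cfg), sort_keys=True))


def config_from_yaml(cls, path: str | Path):
    data = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**data)


def config_hash(cfg) -> str:
    """Short stable digest of a config, echoed into output headers."""
    blob = json.dumps(_asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
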