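"""Sphere-surface-area packing model for concentric Rubisco layers.

Layers sit at radii r_l = (l-1)*d. With a reference layer's measured
count, every other layer's capacity follows from the ratio of sphere
surface areas, N_l = N_ref * (r_l / r_ref)^2 — the layer-1 "layer" is the
single central particle. Totals and the capacity of larger organelles
follow by summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PackingModel:
    """4*pi*r^2 layer-count predictor anchored at a reference layer."""

    spacing_A: float = 120.0
    ref_layer: int = 4
    ref_count: float = 174.0

    def __post_init__(self) -> None:
        if self.spacing_A <= 0:
            raise ValueError("spacing must be > 0")
        if self.ref_layer < 2:
            raise ValueError(
                "reference layer must be >= 2 (layer 1 has zero radius)")
        if self.ref_count <= 0:
            raise ValueError("reference count must be > 0")

    def layer_radius(self, layer: int) -> float:
        return (layer - 1) * self.spacing_A


def predict_layer_count(model: PackingModel, layer: int) -> float:
    """Predicted Rubisco count of ``layer``; exactly 1 for the core layer."""
    if layer < 1:
        raise ValueError("layer index must be >= 1")
    if layer == 1:
        return 1.0
    return model.ref_count * ((layer - 1) / (model.ref_layer - 1)) ** 2


def fit_spacing(mean_radii: Sequence[float]) -> float:
    """Inter-layer spacing: mean of consecutive layer-radius differences."""
    radii = np.asarray(mean_radii, float)
    if radii.size < 2:
        raise ValueError("need at least two layers to fit a spacing")
    return float(np.diff(radii).mean())


def extrapolate_total(model: PackingModel, n_layers: int) -> float:
    """Total Rubiscos in an organelle with ``n_layers`` concentric layers."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    return 1.0 + sum(predict_layer_count(model, l)
                     for l in range(2, n_layers + 1))


def predictions_table(model: PackingModel, layers: Iterable[int],
                      measured: dict[int, float] | None = None,
                      ) -> pd.DataFrame:
    """Per-layer predictions, optionally against measured counts."""
    measured = measured or {}
    rows = []
    for layer in layers:
        pred = predict_layer_count(model, layer)
        meas = measured.get(layer)
        rows.append({
            "layer": layer,
            "radius_A": model.layer_radius(layer),
            "predicted": pred,
            "measured": meas,
            "relative_error": (pred - meas) / meas if meas else np.nan,
        })
    return pd.DataFrame(rows)


def layers_for_diameter(diameter_nm: float, spacing_A: float,
                        inradius_factor: float = 0.76,
                        clearance_A: float = 90.0) -> int:
    """Number of layers that fit in an organelle of the given diameter."""
    lumen = inradius_factor * diameter_nm * 10.0 / 2.0 - clearance_A
    if lumen < 0:
        return 0
    return int(lumen // spacing_A) + 1


def capacity_curve(model: PackingModel, diameters_nm: Sequence[float],
                   inradius_factor: float = 0.76,
                   clearance_A: float = 90.0) -> pd.DataFrame:
    """Rubisco capacity vs organelle diameter (nm).

    Applies the layer predictor through the outermost layer that fits;
    the outermost layers of real organelles are less regular, so the
    curve is an idealized, upper-bound-style estimate.
    """
    rows = []
    for d in diameters_nm:
        n_layers = layers_for_diameter(d, model.spacing_A,
                                       inradius_factor, clearance_A)
        total = extrapolate_total(model, n_layers) if n_layers >= 1 else 0.0
        rows.append({"diameter_nm": d, "n_layers": n_layers, "total": total})
    return pd.DataFrame(rows)
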