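"""Exposure-to-bioactivity comparison: Css vs modeled EC50 potencies.

Steady-state plasma concentrations (Css, uM, externally computed under
a standardized 1 mg/kg/day oral dose) are compared against the potency
of modeled concentration-response curves at the assay, protein, and
pathway layers.  Each curve's EC50 — the concentration at half of its
own maximal absolute response, located by log-linear interpolation on
the grid — is compared with the compound's 95th-percentile Css (the
slow-clearance, sensitive subpopulation).  A compound is flagged
exposure-relevant when any modeled target responds at or below that
internal concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hill import ConcentrationGrid
from .tensor_model import LayerTensor

logger = logging.getLogger(__name__)

__all__ = ["CssRecord", "LayerPotency", "ec50_from_curve", "layer_potencies",
           "exposure_flags"]

M_PER_UM = 1e-6


@dataclass(frozen=True)
class CssRecord:
    """Population Css percentiles for one compound (uM at 1 mg/kg/day)."""

    chemical_id: str
    css_p5: float
    css_p50: float
    css_p95: float

    def __post_init__(self) -> None:
        if not 0 < self.css_p5 <= self.css_p50 <= self.css_p95:
            raise ValueError(
                f"{self.chemical_id}: Css percentiles must be positive and ordered"
            )


@dataclass(frozen=True)
class LayerPotency:
    chemical_id: str
    layer: str       # assay | prot | path
    target_id: str
    ec50: float | None  # uM; None when the curve never reaches half-max


def ec50_from_curve(
    responses: np.ndarray,
    grid: ConcentrationGrid,
    noise_floor: float = 1.0,
) -> float | None:
    """EC50 of a modeled curve: first crossing of half its own max |response|.

    Located by linear interpolation of |response| against log10
    concentration between the bracketing grid points, and returned in
    uM.  Returns None for curves whose maximal absolute response stays
    below ``noise_floor`` (percent of scale): no meaningful potency.
    """
    r = np.asarray(responses, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("non-finite responses")
    if r.shape != (grid.n,):
        raise ValueError("responses not on the given grid")
    mag = np.abs(r)
    peak = mag.max()
    if peak < noise_floor:
        return None
    half = peak / 2.0
    logc = grid.log10_points
    above = mag >= half
    i = int(np.argmax(above))  # first grid point at/above half-max
    if i == 0:
        return float(grid.points[0] / M_PER_UM)
    x0, x1 = logc[i - 1], logc[i]
    y0, y1 = mag[i - 1], mag[i]
    t = (half - y0) / (y1 - y0)
    return float(10 ** (x0 + t * (x1 - x0)) / M_PER_UM)


def layer_potencies(layer: LayerTensor, layer_name: str,
                    noise_floor: float = 1.0) -> list[LayerPotency]:
    """EC50 for every observed (target, chemical) fiber of a layer tensor."""
    out = []
    for j, chem in enumerate(layer.chemical_ids):
        for i, target in enumerate(layer.entity_ids):
            if not layer.mask[i, :, j].all():
                continue
            ec50 = ec50_from_curve(layer.values[i, :, j], layer.grid,
                                   noise_floor=noise_floor)
            out.append(LayerPotency(chemical_id=chem, layer=layer_name,
                                    target_id=target, ec50=ec50))
    return out


def exposure_flags(css: CssRecord, potencies: list[LayerPotency]) -> dict:
    """Per-layer exposure comparison for one compound.

    For each layer: median and minimum EC50 (uM) over targets with a
    defined potency, the count and fraction of targets responding at or
    below the 95th-percentile Css, and an overall flag that is True iff
    any EC50 <= css_p95 (the modeled effect falls inside plausible
    internal exposure).
    """
    mine = [p for p in potencies if p.chemical_id == css.chemical_id]
    if not mine:
        raise ValueError(f"no potency records for compound {css.chemical_id}")
    result: dict = {"chemical_id": css.chemical_id, "css_p95_uM": css.css_p95,
                    "layers": {}, "exposure_relevant": False}
    for layer in ("assay", "prot", "path"):
        recs = [p for p in mine if p.layer == layer]
        if not recs:
            continue
        ec50s = np.array([p.ec50 for p in recs if p.ec50 is not None], dtype=float)
        n_total = len(recs)
        if ec50s.size == 0:
            summary = {"n_targets": n_total, "n_with_ec50": 0, "median_ec50_uM": None,
                       "min_ec50_uM": None, "n_below_css": 0, "frac_below_css": 0.0}
        else:
            below = int((ec50s <= css.css_p95).sum())
            summary = {
                "n_targets": n_total,
                "n_with_ec50": int(ec50s.size),
                "median_ec50_uM": float(np.median(ec50s)),
                "min_ec50_uM": float(ec50s.min()),
                "n_below_css": below,
                "frac_below_css": below / n_total,
            }
            if below:
                result["exposure_relevant"] = True
        result["layers"][layer] = summary
    return result
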