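"""Hill-curve evaluation and harmonization onto a standard concentration grid.

Quantitative HTS pipelines deliver each compound-assay pair as a fitted
Hill model R(C) = Top * C^s / (C^s + AC50^s).  This module evaluates
those fits on a shared logarithmic grid (45 points, 1 pM - 100 uM by
default), rescales each curve to a bounded 0-100% activity scale while
preserving direction and shape, classifies assays by the sign pattern
of their fitted Top values, reconciles replicate profiles, and stacks
the harmonized curves into the (assays x concentrations x chemicals)
input tensor of the hierarchical model.

Concentrations are molar internally; micromolar is accepted at I/O with
an explicit unit column (see :mod:`aoptox.io`).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .tensor_model import LayerTensor

__all__ = [
    "HillParams",
    "ConcentrationGrid",
    "AssayTopSummary",
    "NormalizedCurve",
    "hill_response",
    "build_grid",
    "normalize_curve",
    "merge_replicates",
    "summarize_assay_tops",
    "classify_assay",
    "build_assay_tensor",
]


@dataclass(frozen=True)
class HillParams:
    """Fitted Hill parameters for one compound-assay pair.

    ac50 is molar and must be positive; slope is dimensionless and
    positive; top is the signed asymptotic percent response (negative =
    inhibition).
    """

    ac50: float
    slope: float
    top: float

    def __post_init__(self) -> None:
        if not self.ac50 > 0:
            raise ValueError(f"ac50 must be > 0, got {self.ac50}")
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


@dataclass(frozen=True)
class ConcentrationGrid:
    """Strictly increasing, log10-uniform concentration grid (molar)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(pts <= 0) or np.any(np.diff(pts) <= 0):
            raise ValueError("grid must be positive and strictly increasing")
        logs = np.log10(pts)
        steps = np.diff(logs)
        if not np.allclose(steps, steps[0], rtol=1e-12, atol=1e-12):
            raise ValueError("grid must be uniform in log10 concentration")

    @property
    def n(self) -> int:
        return self.points.size

    @property
    def log10_points(self) -> np.ndarray:
        return np.log10(self.points)


@dataclass(frozen=True)
class AssayTopSummary:
    assay_id: str
    min_top: float
    max_top: float
    category: str  # positive | mixed | negative | excluded


@dataclass(frozen=True)
class NormalizedCurve:
    """A Hill curve rescaled to 0-100% of its own Top on the grid.

    ``top`` keeps the signed Top so response units can be restored
    (responses * top / 100); ``direction`` records whether the original
    fit was an activation (top > 0) or inhibition (top < 0).
    """

    responses: np.ndarray
    direction: str  # activation | inhibition
    source: tuple[str, str]  # (assay_id, chemical_id)
    top: float


def hill_response(params: HillParams, conc) -> np.ndarray | float:
    """Signed percent response of a Hill model at concentration(s) ``conc``.

    R(C) = Top * C^s / (C^s + AC50^s); 0 at C=0, approaching Top as
    C -> inf.  Evaluated in log space as Top * expit(s*(ln C - ln AC50))
    for numerical stability over the 8-decade grid.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, expit(params.slope * (np.log(np.maximum(c, 1e-300)) - np.log(params.ac50))), 0.0)
    out = params.top * frac
    return float(out) if np.isscalar(conc) else out


def build_grid(n: int = 45, c_min: float = 1e-12, c_max: float = 1e-4) -> ConcentrationGrid:
    """Standard grid: ``n`` log10-uniform points from ``c_min`` to ``c_max`` molar.

    Defaults reproduce the 45-point 1 pM - 100 uM harmonization grid.
    """
    if n < 2:
        raise ValueError("grid needs n >= 2")
    if not 0 < c_min < c_max:
        raise ValueError("require 0 < c_min < c_max")
    return ConcentrationGrid(points=np.logspace(np.log10(c_min), np.log10(c_max), n))


def normalize_curve(params: HillParams, grid: ConcentrationGrid,
                    source: tuple[str, str] = ("", "")) -> NormalizedCurve:
    """Rescale a fitted curve so baseline is 0% and its own Top is 100%.

    Responses become 100 * R(C)/Top, a monotone nondecreasing trace in
    [0, 100] regardless of the sign of Top; direction is carried in the
    flag rather than the values.
    """
    if params.top == 0:
        raise ValueError("top = 0: uninformative curve cannot be normalized")
    resp = 100.0 * expit(params.slope * (grid.log10_points * np.log(10) - np.log(params.ac50)))
    return NormalizedCurve(
        responses=resp,
        direction="activation" if params.top > 0 else "inhibition",
        source=source,
        top=float(params.top),
    )


def merge_replicates(curves: Sequence[NormalizedCurve]) -> NormalizedCurve:
    """Select the most reproducible replicate profile.

    With one curve it is returned unchanged; otherwise the curve with
    the smallest mean squared deviation from the pointwise median of
    all replicates is retained (selection, not averaging).  Ties go to
    the earliest replicate.
    """
    if len(curves) == 0:
        raise ValueError("merge_replicates: empty replicate list")
    if len(curves) == 1:
        return curves[0]
    if len({c.responses.shape for c in curves}) > 1:
        raise ValueError("replicates must share a grid")
    stack = np.stack([c.responses for c in curves])
    med = np.median(stack, axis=0)
    msd = np.mean((stack - med) ** 2, axis=1)
    return curves[int(np.argmin(msd))]


def classify_assay(min_top: float, max_top: float, eps: float = 1.0) -> str:
    """Directionality category of an assay from its Top range.

    positive: both tops above +eps (agonist-like); negative: both below
    -eps (antagonist-like); mixed: range straddles the +-eps band;
    excluded: near-zero Top values with minimal modeled activity.  The
    min <= max constraint makes the (min > 0, max < 0) quadrant
    unreachable.
    """
    if min_top > max_top:
        raise ValueError(f"min_top {min_top} > max_top {max_top}")
    if min_top > eps and max_top > eps:
        return "positive"
    if min_top < -eps and max_top < -eps:
        return "negative"
    if min_top < -eps and max_top > eps:
        return "mixed"
    return "excluded"


def summarize_assay_tops(
    assay_id: str,
    params_by_chemical: Mapping[str, HillParams],
    eps: float = 1.0,
) -> AssayTopSummary:
    """Min/max fitted Top over an assay's tested compounds, with category."""
    tops = [p.top for p in params_by_chemical.values() if p is not None]
    if not tops:
        return AssayTopSummary(assay_id=assay_id, min_top=np.nan, max_top=np.nan,
                               category="excluded")
    lo, hi = float(min(tops)), float(max(tops))
    return AssayTopSummary(assay_id=assay_id, min_top=lo, max_top=hi,
                           category=classify_assay(lo, hi, eps=eps))


def build_assay_tensor(
    curves: Mapping[tuple[str, str], NormalizedCurve] | Iterable[tuple[tuple[str, str], NormalizedCurve]],
    grid: ConcentrationGrid,
    assay_ids: Sequence[str],
    chemical_ids: Sequence[str],
    scale: str = "percent",
) -> LayerTensor:
    """Stack merged curves into the (assays x concentrations x chemicals) tensor.

    The observed mask is True exactly where a merged curve exists;
    untested pairs stay flagged rather than zero-filled.  ``scale``
    selects the harmonized 0-100% values ("percent") or response units
    restored by each curve's signed Top ("response").
    """
    if scale not in ("percent", "response"):
        raise ValueError("scale must be 'percent' or 'response'")
    items = curves.items() if isinstance(curves, Mapping) else list(curves)
    a_idx = {a: i for i, a in enumerate(assay_ids)}
    k_idx = {k: i for i, k in enumerate(chemical_ids)}
    values = np.zeros((len(assay_ids), grid.n, len(chemical_ids)))
    mask = np.zeros_like(values, dtype=bool)
    for (aid, kid), curve in items:
        i, j = a_idx[aid], k_idx[kid]
        if mask[i, 0, j]:
            raise ValueError(f"duplicate curve for pair ({aid}, {kid}) after merging")
        resp = curve.responses
        if resp.shape != (grid.n,):
            raise ValueError(f"curve for ({aid}, {kid}) not on the shared grid")
        if scale == "response":
            resp = resp * curve.top / 100.0
        values[i, :, j] = resp
        mask[i, :, j] = True
    return LayerTensor(values=values, mask=mask, entity_ids=list(assay_ids),
                       chemical_ids=list(chemical_ids), grid=grid)
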