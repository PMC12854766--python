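"""Compound toxicity scoring, quartile stratification, and dose-band classes.

Summarized Tox-tensor scores are min-max normalized within each
endpoint, ranked into quartiles (Q4 = highest predicted toxicity), and
compared against regulatory dose bands: GHS acute-oral categories for
LD50 and a three-band NOAEL scheme for repeated-dose endpoints.
Cluster-level profiles standardize each structural cluster's median
endpoint value against the all-compound distribution, so clusters can
be compared on a common z-score scale where higher always means more
toxic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ToxClass",
    "ClusterToxProfile",
    "assign_quartiles",
    "ghs_acute_class",
    "noael_band_class",
    "cluster_z_scores",
    "score_table",
]


@dataclass(frozen=True)
class ToxClass:
    scheme: str  # GHS_acute | NOAEL_band | binary
    label: str   # low | moderate | high | unclassified | nontoxic | toxic


@dataclass(frozen=True)
class ClusterToxProfile:
    cluster_id: int
    endpoint_id: str
    median_value: float
    z_score: float


def assign_quartiles(scores: pd.Series) -> pd.Series:
    """Rank-based quartile labels Q1..Q4 (Q4 = highest scores).

    Edges fall at ranks ceil(n/4), ceil(n/2), ceil(3n/4); ties are
    broken by stable chemical-id order so the stratification is
    deterministic.
    """
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n < 4:
        raise ValueError("quartile stratification needs at least 4 compounds")
    order = s.sort_values(kind="stable").index  # stable: ties keep id order
    ranks = pd.Series(np.arange(1, n + 1), index=order)
    edges = (np.ceil(n / 4), np.ceil(n / 2), np.ceil(3 * n / 4))
    labels = np.where(ranks <= edges[0], "Q1",
             np.where(ranks <= edges[1], "Q2",
             np.where(ranks <= edges[2], "Q3", "Q4")))
    return pd.Series(labels, index=order).reindex(s.index)


def ghs_acute_class(ld50_mg_per_kg: float) -> ToxClass:
    """GHS acute-oral toxicity band for an LD50 in mg/kg.

    high: LD50 <= 50; moderate: 50 < LD50 <= 2000; low: LD50 > 2000.
    """
    if not ld50_mg_per_kg > 0:
        raise ValueError("LD50 must be positive")
    if ld50_mg_per_kg <= 50:
        label = "high"
    elif ld50_mg_per_kg <= 2000:
        label = "moderate"
    else:
        label = "low"
    return ToxClass(scheme="GHS_acute", label=label)


def noael_band_class(noael_mg_per_kg_day: float) -> ToxClass:
    """NOAEL severity band in mg/kg bw/day.

    high: <= 15; moderate: 15 < NOAEL <= 300; low: > 1000.  The scheme
    leaves (300, 1000] unassigned; such doses return "unclassified"
    rather than being forced into a neighboring band.
    """
    if not noael_mg_per_kg_day > 0:
        raise ValueError("NOAEL must be positive")
    x = noael_mg_per_kg_day
    if x <= 15:
        label = "high"
    elif x <= 300:
        label = "moderate"
    elif x > 1000:
        label = "low"
    else:
        label = "unclassified"
    return ToxClass(scheme="NOAEL_band", label=label)


def cluster_z_scores(
    assignments: pd.Series,
    endpoint_values: pd.Series,
    endpoint_id: str,
    kind: str = "continuous",
    ddof: int = 0,
) -> list[ClusterToxProfile]:
    """Standardized median endpoint value per structural cluster.

    z = (cluster median - mean of all compound values) / sd of all
    compound values (population sd by default).  Continuous endpoints
    are expected on the -log10 dose scale.  Binary endpoints are coded
    toxic = 1; standardizing the reversed (nontoxic = 1) coding and
    negating — the directional-consistency recipe — is algebraically
    identical to standardizing the toxic = 1 coding directly, which is
    what is computed.  Either way, higher z means more toxic.
    """
    joined = pd.concat([assignments.rename("cluster"),
                        pd.Series(endpoint_values, dtype=float).rename("y")],
                       axis=1, join="inner").dropna()
    y = joined["y"].to_numpy()
    if y.size == 0:
        raise ValueError("no compounds with both a cluster and an endpoint value")
    mu = float(np.mean(y))
    sd = float(np.std(y, ddof=ddof))
    if sd == 0:
        raise ValueError(f"endpoint {endpoint_id}: zero variance, z-scores undefined")
    out = []
    for cid, grp in joined.groupby("cluster", sort=True):
        if pd.isna(cid):
            continue
        med = float(grp["y"].median())
        out.append(ClusterToxProfile(cluster_id=int(cid), endpoint_id=endpoint_id,
                                     median_value=med, z_score=(med - mu) / sd))
    return out


def score_table(
    normalized_scores: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format score/quartile table from an endpoints x chemicals matrix."""
    rows = []
    for endpoint_id, row in normalized_scores.iterrows():
        vals = row.dropna()
        quart = assign_quartiles(vals)
        for chem in vals.index:
            rows.append({"chemical_id": chem, "endpoint_id": endpoint_id,
                         "normalized_score": vals[chem], "quartile": quart[chem]})
    return pd.DataFrame(rows, columns=["chemical_id", "endpoint_id",
                                       "normalized_score", "quartile"])
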