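"""Structural clustering of compounds by MACCS fingerprints.

Compounds are grouped with the Taylor-Butina sphere-exclusion algorithm
at a fixed Tanimoto similarity threshold (0.7 by default): compounds
are ranked by how many neighbors they have at the threshold, the
highest-ranked unassigned compound becomes a centroid and claims its
unassigned neighbors, and the process repeats.  Clusters below the
minimum size (5) are reported but flagged as not retained.  The largest
substructure shared by a retained cluster's members is encoded as a
SMARTS pattern via maximum-common-substructure search.

Fingerprinting, similarity, and MCS are delegated to RDKit; the sphere
exclusion loop is implemented here so tie-breaking (by chemical-id
order) is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSet",
    "ClusterAssignment",
    "maccs_fingerprints",
    "tanimoto",
    "taylor_butina",
    "cluster_mcs_smarts",
]


@dataclass
class FingerprintSet:
    """chemical_id -> fixed-length binary fingerprint (166-bit MACCS keys)."""

    bits: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.bits.values()}
        if len(lengths) > 1:
            raise ValueError("fingerprints must share a length")

    @property
    def ids(self) -> list[str]:
        return list(self.bits)


@dataclass
class ClusterAssignment:
    """cluster id per compound; None marks singletons/sub-minimum clusters."""

    labels: dict[str, int | None]
    retained: list[int] = field(default_factory=list)
    centroids: dict[int, str] = field(default_factory=dict)


def maccs_fingerprints(smiles_by_id: dict[str, str]) -> FingerprintSet:
    """166-bit MACCS keys from SMILES; invalid structures are dropped with a warning."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    bits: dict[str, np.ndarray] = {}
    for cid, smi in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("invalid SMILES for %s dropped: %r", cid, smi)
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        arr = np.zeros(167, dtype=np.uint8)
        for b in fp.GetOnBits():
            arr[b] = 1
        bits[cid] = arr[1:]
    return FingerprintSet(bits=bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints differ in length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return float(np.logical_and(a, b).sum() / union)


def taylor_butina(
    fps: FingerprintSet,
    threshold: float = 0.7,
    min_size: int = 5,
) -> ClusterAssignment:
    """Sphere-exclusion clustering at a Tanimoto threshold.

    Deterministic: candidate centroids are ranked by neighbor count with
    ties broken by chemical-id sort order; members of clusters smaller
    than ``min_size`` get a null cluster id so downstream joins stay
    total.
    """
    ids = sorted(fps.ids)
    n = len(ids)
    if n == 0:
        raise ValueError("no fingerprints to cluster")
    mat = np.stack([fps.bits[i].astype(bool) for i in ids])
    # pairwise Tanimoto on the bit matrix
    inter = (mat.astype(np.int32) @ mat.T.astype(np.int32)).astype(float)
    counts = mat.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    neighbors = (sim >= threshold) & ~np.eye(n, dtype=bool)

    unassigned = np.ones(n, dtype=bool)
    labels: dict[str, int | None] = {}
    centroids: dict[int, str] = {}
    retained: list[int] = []
    next_id = 0
    while unassigned.any():
        counts_now = (neighbors & unassigned[None, :]).sum(axis=1)
        counts_now[~unassigned] = -1
        # highest neighbor count wins; ties fall to the lowest index = id order
        c = int(np.argmax(counts_now))
        members = np.flatnonzero(neighbors[c] & unassigned)
        cluster = [c, *members.tolist()]
        size = len(cluster)
        cid = next_id if size >= min_size else None
        for m in cluster:
            labels[ids[m]] = cid
            unassigned[m] = False
        if cid is not None:
            centroids[cid] = ids[c]
            retained.append(cid)
            next_id += 1
    logger.info("taylor_butina: %d compounds, %d retained clusters (>= %d members)",
                n, len(retained), min_size)
    return ClusterAssignment(labels=labels, retained=retained, centroids=centroids)


def cluster_mcs_smarts(members_smiles: list[str], timeout: int = 10) -> tuple[str, bool]:
    """SMARTS for the maximum common substructure of a cluster.

    Returns (pattern, ok); ok is False when no shared substructure of
    more than one atom exists, in which case the pattern is empty.  The
    search is bounded by ``timeout`` seconds with the best-so-far result
    returned.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFMCS

    mols = [m for m in (Chem.MolFromSmiles(s) for s in members_smiles) if m is not None]
    if len(mols) < 2:
        raise ValueError("MCS needs at least 2 valid structures")
    res = rdFMCS.FindMCS(mols, timeout=timeout)
    if res.numAtoms <= 1 or not res.smartsString:
        return ("", False)
    return (res.smartsString, True)
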