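"""Supervised statistical filtering of pathway-endpoint associations.

The pathway->toxicity mapping M3 is not learned by gradient descent: a
pathway is linked to an in vivo endpoint only when its summarized
concentration-response score associates with the observed outcome.

Continuous endpoints (LD50, NOAEL; stored as -log10 of the mg/kg dose,
so higher = more potent) use Pearson correlation; a pair is retained
when r >= r_min, BH-FDR q < q_max, and r >= 2/sqrt(n) (the sample-size-
dependent floor).  Only positive correlations qualify.  Binary
endpoints (hepatotoxicity labels) use a two-group rank comparison: the
Wilcoxon rank-sum test when the pooled sample has no ties, otherwise
the tie-robust Brunner-Munzel test; effect size is the rank-biserial
correlation, and a pair is retained when r_rb > 0 and q < q_max.

95% confidence intervals come from the Fisher z-transformation, with an
optional nonparametric bootstrap for dose endpoints whose measurement
variability is poorly captured by the normal approximation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EndpointTable",
    "AssociationRecord",
    "transform_continuous_endpoint",
    "pearson_r",
    "sample_size_threshold",
    "bh_fdr",
    "fisher_z_ci",
    "bootstrap_ci",
    "rank_group_test",
    "rank_biserial",
    "retain_pair",
    "associate",
    "build_m3",
]


@dataclass
class EndpointTable:
    """Per-compound outcomes for one in vivo endpoint.

    ``values`` is indexed by chemical id; continuous endpoints hold
    -log10(dose mg/kg), binary endpoints hold {0, 1} with 1 = toxic.
    """

    endpoint_id: str
    kind: str  # "continuous" | "binary"
    values: pd.Series

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown endpoint kind {self.kind!r}")
        v = pd.Series(self.values, dtype=float)
        if self.kind == "binary" and not v.dropna().isin((0.0, 1.0)).all():
            raise ValueError("binary endpoint values must be 0/1")
        if self.kind == "continuous" and not np.isfinite(v.dropna()).all():
            raise ValueError("continuous endpoint values must be finite")
        self.values = v


@dataclass
class AssociationRecord:
    """Statistics for one pathway-endpoint pair."""

    pathway_id: str
    endpoint_id: str
    n: int
    stat: float            # Pearson r or rank-biserial r_rb
    p: float
    test_used: str         # pearson | wilcoxon | brunner_munzel
    kind: str              # continuous | binary
    q: float = math.nan
    ci95: tuple[float, float] = (math.nan, math.nan)
    boot_ci95: tuple[float, float] | None = None
    retained: bool = False
    extras: dict = field(default_factory=dict)


def transform_continuous_endpoint(dose_mg_per_kg: float) -> float:
    """Potency score of a dose endpoint: -log10(dose in mg/kg)."""
    if not dose_mg_per_kg > 0:
        raise ValueError(f"dose must be > 0 mg/kg, got {dose_mg_per_kg}")
    return -math.log10(dose_mg_per_kg)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def sample_size_threshold(n: int) -> float:
    """Minimum |r| considered interpretable at sample size n: 2/sqrt(n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 / math.sqrt(n)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_z_ci(stat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform CI for a correlation-type statistic.

    atanh(stat) +- z_crit / sqrt(n-3), mapped back by tanh.  |stat| = 1
    yields a degenerate interval with a warning.
    """
    if n < 4:
        raise ValueError("fisher_z_ci needs n >= 4")
    if abs(stat) >= 1:
        warnings.warn("degenerate correlation |r| = 1: returning a point interval")
        return (float(stat), float(stat))
    z = math.atanh(stat)
    half = stats.norm.ppf(0.5 + level / 2) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def bootstrap_ci(
    values_x,
    values_y,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Pearson r over paired resamples.

    Degenerate (constant) resamples are redrawn; their count is logged.
    Deterministic for a fixed seed.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    n = x.size
    if n < 5 or y.size != n:
        raise ValueError("bootstrap_ci needs paired vectors of length >= 5")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) > 0 and np.ptp(yb) > 0:
                break
            n_redrawn += 1
            if n_redrawn > 100 * n_boot:
                raise RuntimeError("bootstrap: data too degenerate to resample")
        # resamples of perfectly collinear data are still r = +-1
        rs[b] = np.corrcoef(xb, yb)[0, 1]
    if n_redrawn:
        logger.info("bootstrap_ci: redrew %d degenerate resamples", n_redrawn)
    alpha = 1 - level
    lo, hi = np.quantile(rs, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def _has_ties(pooled: np.ndarray) -> bool:
    # float-safe tie detection: equality after rounding to 12 significant digits
    rounded = np.array([float(f"{v:.12g}") for v in pooled])
    return np.unique(rounded).size < pooled.size


def rank_group_test(toxic, nontoxic) -> tuple[float, str]:
    """Two-sided rank comparison of toxic vs nontoxic score distributions.

    Wilcoxon rank-sum (exact for small tie-free samples) when the pooled
    sample has no tied values; otherwise Brunner-Munzel with the
    Satterthwaite t-approximated degrees of freedom.
    """
    a = np.asarray(toxic, dtype=float)
    b = np.asarray(nontoxic, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    if _has_ties(pooled):
        if min(a.size, b.size) < 5:
            warnings.warn("Brunner-Munzel t-approximation is unreliable below ~5 per group")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.brunnermunzel(a, b, alternative="two-sided")
        p = float(res.pvalue)
        if not np.isfinite(p):
            # the BM statistic degenerates (0/0) when the rank variance is zero:
            # identical distributions (no evidence) or complete separation
            auc = (rank_biserial(a, b) + 1.0) / 2.0
            p = 1.0 if abs(auc - 0.5) < 1e-12 else 0.0
        return p, "brunner_munzel"
    method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), "wilcoxon"


def rank_biserial(toxic, nontoxic) -> float:
    """Rank-biserial correlation r_rb = 2*A - 1.

    A is the probability that a toxic compound outscores a nontoxic one
    (ties credited 1/2); positive r_rb means toxic scores are
    stochastically larger.
    """
    a = np.asarray(toxic, dtype=float)
    b = np.asarray(nontoxic, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_biserial: empty group")
    # U1 from the rank formulation already carries the half-tie credit
    u1 = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic
    auc = u1 / (a.size * b.size)
    return float(2.0 * auc - 1.0)


def retain_pair(
    record: AssociationRecord,
    r_min: float = 0.1,
    q_max: float = 0.05,
    use_n_threshold: bool = True,
) -> bool:
    """Retention rule for one pathway-endpoint pair.

    Continuous: r >= r_min AND q < q_max AND (r >= 2/sqrt(n) when the
    sample-size floor is enabled); only positive correlations pass.
    Binary: r_rb > 0 AND q < q_max.
    """
    if not np.isfinite(record.q):
        raise ValueError("record has no q-value; run FDR adjustment first")
    if record.kind == "continuous":
        ok = record.stat >= r_min and record.q < q_max
        if use_n_threshold:
            ok = ok and record.stat >= sample_size_threshold(record.n)
        return bool(ok)
    return bool(record.stat > 0 and record.q < q_max)


def associate(
    path_scores: pd.DataFrame,
    endpoints: list[EndpointTable],
    boot_endpoints: tuple[str, ...] = (),
    n_boot: int = 2000,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Score every (pathway, endpoint) pair.

    ``path_scores`` is pathways x chemicals (summarized over
    concentration).  Compounds missing either the score or the outcome
    are dropped pairwise.  Endpoints named in ``boot_endpoints``
    additionally get a bootstrap CI (the dose endpoints whose in vivo
    measurements are highly variable).
    """
    records: list[AssociationRecord] = []
    for ep in endpoints:
        for pathway_id, row in path_scores.iterrows():
            joined = pd.concat([row.rename("score"), ep.values.rename("y")],
                               axis=1, join="inner").dropna()
            n = len(joined)
            rec = AssociationRecord(pathway_id=str(pathway_id), endpoint_id=ep.endpoint_id,
                                    n=n, stat=math.nan, p=math.nan, test_used="",
                                    kind=ep.kind)
            try:
                if ep.kind == "continuous":
                    r, p = pearson_r(joined["score"], joined["y"])
                    rec.stat, rec.p, rec.test_used = r, p, "pearson"
                    rec.ci95 = fisher_z_ci(r, n) if n >= 4 else (math.nan, math.nan)
                    if ep.endpoint_id in boot_endpoints and n >= 5:
                        rec.boot_ci95 = bootstrap_ci(joined["score"], joined["y"],
                                                     n_boot=n_boot, seed=seed)
                else:
                    tox = joined.loc[joined["y"] == 1, "score"].to_numpy()
                    non = joined.loc[joined["y"] == 0, "score"].to_numpy()
                    rec.p, rec.test_used = rank_group_test(tox, non)
                    rec.stat = rank_biserial(tox, non)
                    if n >= 4 and abs(rec.stat) <= 1:
                        rec.ci95 = fisher_z_ci(min(max(rec.stat, -1.0), 1.0), n)
            except ValueError as exc:
                logger.warning("pair (%s, %s) not testable: %s", pathway_id,
                               ep.endpoint_id, exc)
                continue
            records.append(rec)
    return records


def build_m3(
    records: list[AssociationRecord],
    pathway_ids: list[str],
    endpoint_ids: list[str],
    r_min: float = 0.1,
    q_max: float = 0.05,
    use_n_threshold: bool = True,
    fdr_scope: str = "per_endpoint",
) -> np.ndarray:
    """Binarized M3 (pathways x endpoints) from association records.

    BH-FDR adjustment is applied within each endpoint across its
    candidate pathways by default (``fdr_scope="per_endpoint"``), or
    across all pairs at once (``"global"``).  Records are mutated in
    place with their q-values and retained flags.
    """
    if fdr_scope not in ("per_endpoint", "global"):
        raise ValueError("fdr_scope must be 'per_endpoint' or 'global'")
    groups: dict[str | None, list[AssociationRecord]] = {}
    for rec in records:
        key = rec.endpoint_id if fdr_scope == "per_endpoint" else None
        groups.setdefault(key, []).append(rec)
    for recs in groups.values():
        qs = bh_fdr([r.p for r in recs])
        for rec, q in zip(recs, qs):
            rec.q = float(q)
    m3 = np.zeros((len(pathway_ids), len(endpoint_ids)), dtype=int)
    p_idx = {p: i for i, p in enumerate(pathway_ids)}
    e_idx = {e: j for j, e in enumerate(endpoint_ids)}
    for rec in records:
        rec.retained = retain_pair(rec, r_min=r_min, q_max=q_max,
                                   use_n_threshold=use_n_threshold)
        if rec.retained:
            m3[p_idx[rec.pathway_id], e_idx[rec.endpoint_id]] = 1
    for e, j in e_idx.items():
        logger.info("endpoint %s: %d pathways retained", e, int(m3[:, j].sum()))
    return m3
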