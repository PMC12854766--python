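"""End-to-end benchmark computations on synthetic studies.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns measured quantities: statistical oracle
deviations, type-I/power rates of the association filter, tensor
recovery quality, quartile enrichment, and run determinism.  They back
both the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .assoc_filter import associate, bh_fdr, build_m3, rank_biserial, rank_group_test
from .hill import HillParams, classify_assay, hill_response
from .io import EndpointSpec, PipelineConfig, harmonize_stage, run_pipeline
from .synthetic_data import (SynthConfig, generate_pathway_endpoint_data,
                             generate_study, write_study)
from .tensor_model import (TrainConfig, fit_pathway_layer, fit_protein_layer,
                           fit_tox_layer, minmax_normalize,
                           summarize_over_concentration)
from .tox_scoring import assign_quartiles, ghs_acute_class

__all__ = [
    "hill_half_max_max_error",
    "classification_examples_correct",
    "bh_fdr_oracle_max_dev",
    "rank_biserial_oracle_max_dev",
    "wilcoxon_exact_p",
    "null_retention",
    "power_retention_rate",
    "tensor_recovery",
    "threshold_sensitivity_identical",
    "quartile_high_fractions",
    "pipeline_determinism",
]


# -- statistical oracles ------------------------------------------------------

def hill_half_max_max_error(n_draws: int = 1000, seed: int = 0) -> float:
    """Max |R(AC50) - Top/2| over random Hill parameter draws."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        p = HillParams(ac50=10 ** rng.uniform(-11, -5), slope=rng.uniform(0.1, 10),
                       top=rng.uniform(-200, 200) or 1.0)
        worst = max(worst, abs(hill_response(p, p.ac50) - p.top / 2))
    return worst


def classification_examples_correct() -> bool:
    """The three printed assay-directionality examples."""
    return (classify_assay(37.3, 116.0) == "positive"
            and classify_assay(-120.0, 120.0) == "mixed"
            and classify_assay(-120.0, -16.9) == "negative")


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order, start=1):
        q[idx] = min(1.0, min(p[order[j - 1]] * m / j for j in range(pos, m + 1)))
    return q


def bh_fdr_oracle_max_dev(n_vectors: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 30)) ** rng.uniform(0.5, 3)
        worst = max(worst, float(np.abs(bh_fdr(p) - _bh_oracle(p)).max()))
    return worst


def rank_biserial_oracle_max_dev(seed: int = 0, n_cases: int = 500) -> float:
    """Max deviation from pairwise enumeration over random groups of size <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        a = rng.integers(0, 5, rng.integers(1, 7)).astype(float)
        b = rng.integers(0, 5, rng.integers(1, 7)).astype(float)
        wins = sum(x > y for x in a for y in b)
        ties = sum(x == y for x in a for y in b)
        oracle = 2 * (wins + 0.5 * ties) / (a.size * b.size) - 1
        worst = max(worst, abs(rank_biserial(a, b) - oracle))
    return worst


def wilcoxon_exact_p() -> float:
    """Two-sided rank-sum p for complete separation at n1 = n2 = 3."""
    p, used = rank_group_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert used == "wilcoxon"
    return p


# -- association filter operating characteristics ----------------------------

def null_retention(n_seeds: int = 50, n_pathways: int = 100, n_endpoints: int = 5,
                   n_chemicals: int = 500, seed: int = 0) -> dict:
    """Fraction of pathway-endpoint pairs retained under the global null."""
    fracs = []
    for i in range(n_seeds):
        s = (seed * 1009 + i) % (2**31)
        scores, eps, _ = generate_pathway_endpoint_data(
            n_pathways, n_chemicals, n_endpoints, [], seed=s)
        recs = associate(scores, eps, seed=s)
        m3 = build_m3(recs, list(scores.index), [e.endpoint_id for e in eps])
        fracs.append(m3.mean())
    fracs = np.asarray(fracs)
    return {"mean_fraction": float(fracs.mean()),
            "mc_se": float(fracs.std(ddof=1) / math.sqrt(n_seeds)),
            "n": n_seeds * n_pathways * n_endpoints}


def power_retention_rate(n_seeds: int = 50, r_true: float = 0.3,
                         n_chemicals: int = 500, n_pathways: int = 12,
                         seed: int = 0) -> dict:
    """How often a single true association is retained across seeded repeats."""
    hits = 0
    for i in range(n_seeds):
        s = (seed * 2003 + i) % (2**31)
        scores, eps, _ = generate_pathway_endpoint_data(
            n_pathways, n_chemicals, 3, [(0, 0, r_true)], seed=s)
        recs = associate(scores, eps, seed=s)
        m3 = build_m3(recs, list(scores.index), [e.endpoint_id for e in eps])
        hits += int(m3[0, 0])
    return {"rate": hits / n_seeds, "n": n_seeds}


def threshold_sensitivity_identical(seed: int = 0, r_true: float = 0.4,
                                    n_chemicals: int = 500) -> dict:
    """Is the retained set identical across r-cutoffs 0.05 / 0.1 / 0.2?"""
    scores, eps, _ = generate_pathway_endpoint_data(
        12, n_chemicals, 3, [(0, 0, r_true)], seed=seed % (2**31))
    recs = associate(scores, eps, seed=seed)
    sets = []
    for r_min in (0.05, 0.1, 0.2):
        m3 = build_m3(recs, list(scores.index), [e.endpoint_id for e in eps],
                      r_min=r_min)
        sets.append(m3.copy())
    identical = all(np.array_equal(s, sets[0]) for s in sets[1:])
    return {"identical": identical, "n_retained": int(sets[0].sum()),
            "n": sets[0].size}


# -- hierarchical model recovery ---------------------------------------------

def _staged_fit(study, truth, seed):
    records = [(a, k, p) for (a, k), p in truth.hill_params.items()]
    tensor, _ = harmonize_stage(records, study.grid)
    a_idx = {a: i for i, a in enumerate(study.assay_ids)}
    m1_mask = truth.M1_true.structure_mask[[a_idx[a] for a in tensor.entity_ids]]
    tc = TrainConfig(seed=seed % (2**31))
    m1, prot, _ = fit_protein_layer(tensor, m1_mask, tc,
                                    protein_ids=study.protein_ids)
    m2, path, _ = fit_pathway_layer(prot, truth.M2_true.structure_mask, tc,
                                    pathway_ids=study.pathway_ids)
    return tensor, m1, prot, m2, path, tc


def _masked_r2(pred, obs, mask):
    p, o = pred[mask], obs[mask]
    return float(1.0 - np.sum((p - o) ** 2) / np.sum((o - o.mean()) ** 2))


def tensor_recovery(seed: int = 0) -> dict:
    """Staged training on the default study (20 assays x 45 x 300 chemicals,
    8 proteins, 5 pathways, noise sd 0.05): per-layer reconstruction R^2 and
    per-pathway correlation of recovered vs ground-truth summarized scores."""
    cfg = SynthConfig(seed=seed % (2**31))
    study, truth = generate_study(cfg)
    tensor, m1, prot, m2, path, _ = _staged_fit(study, truth, seed)
    rec1 = np.einsum("ap,pck->ack", m1.weights, prot.values)
    rec2 = np.einsum("pq,qck->pck", m2.weights, path.values)
    s_hat = summarize_over_concentration(path)
    s_true = truth.path_scores.to_numpy()
    corrs = []
    for q in range(cfg.n_pathways):
        ok = np.isfinite(s_hat[q])
        corrs.append(pearsonr(s_hat[q][ok], s_true[q][ok]).statistic)
    return {
        "r2_assay": _masked_r2(rec1, tensor.values, tensor.mask),
        "r2_prot": _masked_r2(rec2, prot.values, prot.mask),
        "min_pathway_corr": float(min(corrs)),
        "pathway_corrs": [float(c) for c in corrs],
        "n": int(tensor.mask.sum()),
    }


# -- scoring and determinism --------------------------------------------------

def quartile_high_fractions(n_seeds: int = 20, seed: int = 0) -> dict:
    """Mean fraction of GHS high-toxicity compounds per Tox-score quartile,
    on studies where one pathway drives a continuous (LD50-like) endpoint."""
    fracs = np.full((n_seeds, 4), np.nan)
    for i in range(n_seeds):
        s = (seed * 4001 + i) % (2**31)
        cfg = SynthConfig(seed=s, n_assays=8, n_proteins=5, n_pathways=3,
                          n_chemicals=150, n_endpoints=1,
                          endpoint_kinds=("continuous",), true_assoc=[(0, 0, 0.6)])
        study, truth = generate_study(cfg)
        tensor, m1, prot, m2, path, tc = _staged_fit(study, truth, s)
        ps = pd.DataFrame(summarize_over_concentration(path),
                          index=study.pathway_ids, columns=study.chemical_ids)
        recs = associate(ps, truth.endpoint_values, seed=s)
        m3 = build_m3(recs, study.pathway_ids, study.endpoint_ids)
        if m3.sum() == 0:
            continue
        tox, _ = fit_tox_layer(path, m3, tc, endpoint_ids=study.endpoint_ids)
        scores = pd.Series(summarize_over_concentration(tox)[0],
                           index=study.chemical_ids).dropna()
        norm = pd.Series(minmax_normalize(scores.to_numpy()), index=scores.index)
        quart = assign_quartiles(norm)
        doses = 10.0 ** (-truth.endpoint_values[0].values)
        is_high = doses.map(lambda d: ghs_acute_class(d).label == "high")
        for j, lab in enumerate(("Q1", "Q2", "Q3", "Q4")):
            members = quart[quart == lab].index
            fracs[i, j] = float(is_high[members].mean())
    mean_fracs = np.nanmean(fracs, axis=0)
    return {"mean_high_fraction": [float(f) for f in mean_fracs],
            "nondecreasing": bool(np.all(np.diff(mean_fracs) >= -1e-12)),
            "n": n_seeds}


def _study_pipeline_config(cfg: SynthConfig, in_dir: FsPath) -> PipelineConfig:
    study, truth = generate_study(cfg)
    paths = write_study(study, truth, in_dir)
    schemes = {"continuous": "GHS_acute", "binary": "binary"}
    return PipelineConfig(
        assay_table=paths["assay_table.csv"],
        assay_protein_map=paths["assay_protein_map.csv"],
        genesets=paths["pathways.gmt"],
        endpoints=[EndpointSpec(endpoint_id=eid, kind=kind,
                                path=paths[f"endpoint_{eid}.csv"], scheme=schemes[kind])
                   for eid, kind in zip(study.endpoint_ids, cfg.endpoint_kinds)],
        css_table=paths["css_table.csv"],
        smiles=paths["compounds.smi"],
        seed=cfg.seed, train=TrainConfig(seed=cfg.seed),
    )


def pipeline_determinism(work_dir: str | FsPath, seed: int = 0) -> dict:
    """Run the full pipeline twice with one seed; compare score tables bytewise."""
    work = FsPath(work_dir)
    cfg = SynthConfig(seed=seed % (2**31), n_assays=10, n_proteins=6, n_pathways=4,
                      n_chemicals=120, n_endpoints=4,
                      true_assoc=[(0, 0, 0.5), (1, 1, 0.5), (2, 2, 0.5), (3, 3, 0.5)])
    pc = _study_pipeline_config(cfg, work / "inputs")
    digests = []
    for run in ("run1", "run2"):
        run_pipeline(pc, work / run)
        digests.append(hashlib.sha256(
            (work / run / "tox_scores.csv").read_bytes()).hexdigest())
    return {"identical": digests[0] == digests[1], "n": 2}
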