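"""Synthetic study generator with known ground truth.

Emulates the complete set of inputs the pipeline consumes — a
Hill-parameter assay table, assay->protein and protein->pathway
mappings, continuous (LD50/NOAEL-style) and binary (hepatotoxicity-
style) endpoint tables, a Css table, and a SMILES list — from a known
generative model, so every downstream stage can be tested against the
truth without any external download.

Generative model
----------------
Latent pathway activity is Hill-shaped per (pathway, chemical): AC50
log-uniform over the interior of the standard grid, slope uniform in
[0.5, 3], and a fixed amplitude.  The amplitude is deliberately held
constant: per-curve Top normalization during harmonization rescales
every observed curve to its own plateau, so cross-chemical amplitude
variation in the latent profiles would be erased by preprocessing and
no method could recover it.  With fixed amplitude, normalization
reduces to a per-assay scaling and the bilinear structure
Assay = M1 . M2 . Path survives harmonization intact.

Protein and assay tensors follow by the mapping products with sparse
positive matrices (every row and column of each mapping covered).
Assay-level profiles (plus optional Gaussian noise) are converted back
to Hill parameters by least-squares fits — the form in which real
screening data arrives.  When each assay chains to a single pathway
(mapping densities at or below one entry per row) the assay profiles
are exactly Hill and the round trip is exact to numerical precision;
mixed chains are sums of Hill curves and round-trip only approximately.

Continuous endpoints are linear in the standardized ground-truth
pathway score with Gaussian noise calibrated so the population
correlation equals the requested r_true; binary endpoints come from a
logistic link on the same score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from .assoc_filter import EndpointTable
from .hill import ConcentrationGrid, HillParams, build_grid
from .tensor_model import LayerTensor, MappingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_study",
    "generate_pathway_endpoint_data",
    "write_study",
    "SCAFFOLD_FAMILIES",
]

M_PER_UM = 1e-6

# ---------------------------------------------------------------------------
# packaged SMILES library: ~90 small valid molecules in scaffold families so
# fingerprint clustering has known structure (family = expected cluster)
# ---------------------------------------------------------------------------

SCAFFOLD_FAMILIES: dict[str, list[str]] = {
    "phenothiazine": [
        "CN1c2ccccc2Sc2ccccc21",
        "CCN1c2ccccc2Sc2ccccc21",
        "CCCN1c2ccccc2Sc2ccccc21",
        "CCCCN1c2ccccc2Sc2ccccc21",
        "CN(C)CCN1c2ccccc2Sc2ccccc21",
        "CN(C)CCCN1c2ccccc2Sc2ccccc21",
        "OCCN1c2ccccc2Sc2ccccc21",
        "CC(C)N1c2ccccc2Sc2ccccc21",
    ],
    "organophosphate": [
        "COP(=O)(OC)OC",
        "CCOP(=O)(OCC)OCC",
        "CCCOP(=O)(OCCC)OCCC",
        "COP(=S)(OC)OC",
        "CCOP(=S)(OCC)OCC",
        "COP(=O)(OC)Oc1ccccc1",
        "CCOP(=O)(OCC)Oc1ccccc1",
        "COP(=S)(OC)Oc1ccccc1",
    ],
    "alkanol": [
        "CCO", "CCCO", "CCCCO", "CCCCCO",
        "CCCCCCO", "CCCCCCCO", "CCCCCCCCO", "CCCCCCCCCO",
    ],
    "aniline": [
        "Nc1ccccc1", "Nc1ccc(C)cc1", "Nc1ccc(CC)cc1", "Nc1ccc(Cl)cc1",
        "Nc1ccc(Br)cc1", "Nc1ccc(O)cc1", "Nc1ccc(OC)cc1", "Nc1ccc(F)cc1",
    ],
    "benzoate": [
        "OC(=O)c1ccccc1", "COC(=O)c1ccccc1", "CCOC(=O)c1ccccc1",
        "OC(=O)c1ccc(C)cc1", "OC(=O)c1ccc(Cl)cc1", "OC(=O)c1ccc(O)cc1",
        "COC(=O)c1ccc(N)cc1", "OC(=O)c1ccc(OC)cc1",
    ],
    "alkane": [
        "CCCCCC", "CCCCCCC", "CCCCCCCC", "CCCCCCCCC",
        "CCCCCCCCCC", "CCCCCCCCCCC", "CCCCCCCCCCCC", "CCCCCCCCCCCCC",
    ],
    "chlorophenol": [
        "Oc1ccccc1Cl", "Oc1ccc(Cl)cc1", "Oc1cccc(Cl)c1", "Oc1ccc(Cl)cc1Cl",
        "Oc1cc(Cl)cc(Cl)c1", "Oc1c(Cl)cccc1Cl", "Oc1ccc(Cl)c(Cl)c1", "Oc1cc(Cl)ccc1Cl",
    ],
    "pyridine": [
        "c1ccncc1", "Cc1ccncc1", "CCc1ccncc1", "Cc1cccnc1",
        "Cc1ccccn1", "Nc1ccncc1", "Oc1ccncc1", "COc1ccncc1",
    ],
    "phthalate": [
        "COC(=O)c1ccccc1C(=O)OC", "CCOC(=O)c1ccccc1C(=O)OCC",
        "CCCOC(=O)c1ccccc1C(=O)OCCC", "CCCCOC(=O)c1ccccc1C(=O)OCCCC",
        "CC(C)OC(=O)c1ccccc1C(=O)OC(C)C", "CCCCCOC(=O)c1ccccc1C(=O)OCCCCC",
        "CCCCCCOC(=O)c1ccccc1C(=O)OCCCCCC", "CCCCCCCCOC(=O)c1ccccc1C(=O)OCCCCCCCC",
    ],
    "alkylbenzene": [
        "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1", "CCCCc1ccccc1",
        "Cc1ccccc1C", "Cc1cccc(C)c1", "Cc1ccc(C)cc1", "CCc1ccc(C)cc1",
    ],
    "misc": [
        "CO", "CC(=O)O", "CC(C)=O", "C1CCOC1", "C1CCCCC1", "c1ccccc1",
        "OCCO", "CC#N", "CS(C)=O", "O=S(=O)(O)O",
    ],
}

_FAMILY_OF: list[tuple[str, str]] = [
    (smi, fam) for fam, smis in SCAFFOLD_FAMILIES.items() for smi in smis
]


# ---------------------------------------------------------------------------
# configuration / outputs
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Generating conditions for one synthetic study."""

    n_assays: int = 20
    n_proteins: int = 8
    n_pathways: int = 5
    n_chemicals: int = 300
    n_endpoints: int = 5
    grid: ConcentrationGrid = field(default_factory=build_grid)
    assay_protein_density: float = 0.2
    protein_pathway_density: float = 0.3
    true_assoc: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 0, 0.5), (1, 1, 0.4), (2, 2, 0.4),
                                 (3, 3, 0.5), (4, 4, 0.5)]
    )
    noise_sd: float = 0.05
    missing_frac: float = 0.1
    endpoint_kinds: tuple[str, ...] | None = None
    binary_prevalence: float = 0.5
    path_amplitude: float = 100.0
    ac50_coherence_sd: float | None = 0.5  # decades; None = independent AC50s
    css_frac: float = 0.15
    dose_loc: float = -2.5   # mean of -log10(dose mg/kg); ~300 mg/kg
    dose_scale: float = 0.8  # sd of -log10(dose mg/kg)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_assays", "n_proteins", "n_pathways", "n_chemicals", "n_endpoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("assay_protein_density", "protein_pathway_density"):
            d = getattr(self, name)
            if not 0 < d <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        for p, e, r in self.true_assoc:
            if not -1 < r < 1:
                raise ValueError(f"r_true must lie in (-1, 1), got {r}")
            if not (0 <= p < self.n_pathways and 0 <= e < self.n_endpoints):
                raise ValueError(f"true_assoc index ({p}, {e}) out of range")
        if self.endpoint_kinds is None:
            n_cont = math.ceil(0.6 * self.n_endpoints)
            self.endpoint_kinds = tuple(
                "continuous" if j < n_cont else "binary" for j in range(self.n_endpoints)
            )
        if len(self.endpoint_kinds) != self.n_endpoints:
            raise ValueError("endpoint_kinds length must equal n_endpoints")

    @property
    def assay_ids(self) -> list[str]:
        return [f"A{i:03d}" for i in range(self.n_assays)]

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i:03d}" for i in range(self.n_proteins)]

    @property
    def pathway_ids(self) -> list[str]:
        return [f"PW{i:03d}" for i in range(self.n_pathways)]

    @property
    def chemical_ids(self) -> list[str]:
        return [f"C{i:05d}" for i in range(self.n_chemicals)]

    @property
    def endpoint_ids(self) -> list[str]:
        return [f"EP{j}_{k}" for j, k in enumerate(self.endpoint_kinds)]


@dataclass
class GroundTruth:
    """The generating quantities every downstream stage is tested against."""

    M1_true: MappingMatrix
    M2_true: MappingMatrix
    M3_true: np.ndarray
    path_true: LayerTensor
    path_scores: pd.DataFrame          # pathways x chemicals, mean over conc
    endpoint_values: list[EndpointTable]
    hill_params: dict[tuple[str, str], HillParams]
    assay_true: LayerTensor | None = None
    smiles_families: pd.Series | None = None


@dataclass
class SyntheticStudy:
    """File-shaped study inputs (what the pipeline readers consume)."""

    assay_table: pd.DataFrame
    assay_protein_map: pd.DataFrame
    genesets: dict[str, list[str]]
    endpoint_tables: dict[str, pd.DataFrame]
    css_table: pd.DataFrame
    smiles_table: pd.DataFrame
    grid: ConcentrationGrid
    assay_ids: list[str]
    protein_ids: list[str]
    pathway_ids: list[str]
    chemical_ids: list[str]
    endpoint_ids: list[str]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _mapping_mask(rng: np.random.Generator, n_rows: int, n_cols: int,
                  density: float, what: str) -> np.ndarray:
    """Sparse boolean mask with >= 1 True per row and per column.

    Every column receives one dedicated ("anchor") row mapping only to
    it — the structure of curated annotation maps, where each target has
    at least one selective assay and each pathway at least one dedicated
    member, and the condition under which the factorization is
    identifiable up to per-entity scale.  Remaining rows draw
    independent Bernoulli(density) entries (empty rows are repaired with
    one random entry), so degrees vary.  Densities well below 1/n_cols
    leave every row with a single entry — the single-chain regime in
    which assay profiles stay exactly Hill.
    """
    if n_rows < n_cols:
        raise ValueError(
            f"{what}: cannot cover {n_cols} columns with {n_rows} rows; "
            "the first uncoverable column would have zero allowed entries"
        )
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    anchor_rows = rng.permutation(n_rows)[:n_cols]
    for c, i in enumerate(anchor_rows):
        mask[i, c] = True
    free = np.setdiff1d(np.arange(n_rows), anchor_rows)
    mask[free] = rng.random((free.size, n_cols)) < density
    for i in free[~mask[free].any(axis=1)]:
        mask[i, rng.integers(n_cols)] = True
    return mask


def _fit_hill(responses: np.ndarray, grid: ConcentrationGrid) -> HillParams:
    """Least-squares Hill fit of a response profile on the grid."""
    logc = grid.log10_points
    r = np.asarray(responses, dtype=float)

    def model(x, top, m, s):
        return top * expit(s * np.log(10.0) * (x - m))

    top0 = r[-1] if abs(r[-1]) >= abs(r[0]) else r[0]
    if top0 == 0:
        top0 = r[np.argmax(np.abs(r))]
    if top0 == 0:
        top0 = 1e-6
    # initial midpoint: first crossing of half the plateau
    half = abs(top0) / 2
    above = np.abs(r) >= half
    m0 = logc[int(np.argmax(above))] if above.any() else logc[len(logc) // 2]
    try:
        popt, _ = curve_fit(
            model, logc, r, p0=(top0, m0, 1.0),
            bounds=([-np.inf, logc[0] - 3, 1e-3], [np.inf, logc[-1] + 3, 20.0]),
            maxfev=20000,
        )
        top, m, s = popt
    except RuntimeError:  # fall back to the direct initial estimates
        top, m, s = top0, m0, 1.0
    return HillParams(ac50=float(10 ** m), slope=float(s), top=float(top))


def _endpoint_from_score(
    rng: np.random.Generator,
    z: np.ndarray,
    kind: str,
    r_true: float,
    cfg: SynthConfig,
) -> np.ndarray:
    """Endpoint values with population correlation r_true to the score z."""
    n = z.size
    if kind == "continuous":
        eps = rng.standard_normal(n)
        y = r_true * z + math.sqrt(1 - r_true**2) * eps
        return cfg.dose_loc + cfg.dose_scale * y  # on the -log10(mg/kg) scale
    beta = 2.0 * r_true / math.sqrt(1 - r_true**2)
    alpha = float(logit(cfg.binary_prevalence))
    p = expit(alpha + beta * z)
    return (rng.random(n) < p).astype(float)


def generate_pathway_endpoint_data(
    n_pathways: int,
    n_chemicals: int,
    n_endpoints: int,
    true_assoc: list[tuple[int, int, float]],
    seed: int = 0,
    endpoint_kinds: tuple[str, ...] | None = None,
    grid: ConcentrationGrid | None = None,
) -> tuple[pd.DataFrame, list[EndpointTable], np.ndarray]:
    """Pathway-score matrix + endpoint tables only (no assay layer).

    The statistical sub-generator behind :func:`generate_study`, useful
    when only the association-filtering stage is under study: pathway
    scores are the concentration means of Hill-shaped latent profiles
    with independent per-pathway potencies (the least favorable regime
    for the filter — no cross-pathway correlation to lean on), and
    endpoints are tied to them exactly as in the full generator.
    Returns (path_scores pathways x chemicals, endpoint tables, M3_true).
    """
    cfg = SynthConfig(
        n_assays=1, n_proteins=1, n_pathways=n_pathways,
        n_chemicals=n_chemicals, n_endpoints=n_endpoints,
        true_assoc=true_assoc, endpoint_kinds=endpoint_kinds,
        grid=grid or build_grid(), seed=seed, ac50_coherence_sd=None,
    )
    rng = np.random.default_rng(seed)
    path_vals = _latent_path_tensor(rng, cfg)
    scores = path_vals.mean(axis=1)  # pathways x chemicals
    path_scores = pd.DataFrame(scores, index=cfg.pathway_ids, columns=cfg.chemical_ids)
    endpoints, m3_true = _draw_endpoints(rng, cfg, scores)
    return path_scores, endpoints, m3_true


def _latent_path_tensor(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Hill-shaped latent profiles, (n_pathways x n_conc x n_chemicals).

    With ``ac50_coherence_sd`` set (the default), each chemical draws a
    compound-level log10 potency uniform over the grid interior and
    pathway AC50s scatter around it with that many decades of spread —
    compounds act on their pathways at related concentrations, so
    assay-level mixtures of pathway curves remain close to Hill-shaped.
    ``None`` draws every (pathway, chemical) AC50 independently.
    """
    logc = cfg.grid.log10_points
    lo, hi = logc[0] + 1.0, logc[-1] - 1.0  # one-decade interior margin
    if cfg.ac50_coherence_sd is None:
        m = rng.uniform(lo, hi, size=(cfg.n_pathways, cfg.n_chemicals))
    else:
        base = rng.uniform(lo, hi, size=cfg.n_chemicals)
        m = base[None, :] + rng.normal(0.0, cfg.ac50_coherence_sd,
                                       size=(cfg.n_pathways, cfg.n_chemicals))
        m = np.clip(m, logc[0], logc[-1])
    s = rng.uniform(0.5, 3.0, size=(cfg.n_pathways, cfg.n_chemicals))
    frac = expit(s[:, None, :] * np.log(10.0) * (logc[None, :, None] - m[:, None, :]))
    return cfg.path_amplitude * frac


def _draw_endpoints(
    rng: np.random.Generator, cfg: SynthConfig, scores: np.ndarray
) -> tuple[list[EndpointTable], np.ndarray]:
    m3_true = np.zeros((cfg.n_pathways, cfg.n_endpoints), dtype=int)
    assoc_for: dict[int, tuple[int, float]] = {}
    for p, e, r in cfg.true_assoc:
        m3_true[p, e] = 1
        assoc_for.setdefault(e, (p, r))
    endpoints = []
    for j, (eid, kind) in enumerate(zip(cfg.endpoint_ids, cfg.endpoint_kinds)):
        if j in assoc_for:
            p, r = assoc_for[j]
            s = scores[p]
            z = (s - s.mean()) / s.std()
        else:
            r, z = 0.0, rng.standard_normal(cfg.n_chemicals)
        vals = _endpoint_from_score(rng, z, kind, r, cfg)
        endpoints.append(EndpointTable(
            endpoint_id=eid, kind=kind,
            values=pd.Series(vals, index=cfg.chemical_ids),
        ))
    return endpoints, m3_true


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(config: SynthConfig) -> tuple[SyntheticStudy, GroundTruth]:
    """Generate a complete synthetic study and its ground truth.

    Deterministic for a fixed ``config.seed``.  See the module docstring
    for the generative model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid

    m1_mask = _mapping_mask(rng, cfg.n_assays, cfg.n_proteins,
                            cfg.assay_protein_density, "assay->protein map")
    m2_mask = _mapping_mask(rng, cfg.n_proteins, cfg.n_pathways,
                            cfg.protein_pathway_density, "protein->pathway map")
    m1_w = np.where(m1_mask, rng.uniform(0.5, 1.5, m1_mask.shape), 0.0)
    m2_w = np.where(m2_mask, rng.uniform(0.5, 1.5, m2_mask.shape), 0.0)

    path_vals = _latent_path_tensor(rng, cfg)                     # (q, c, k)
    prot_vals = np.einsum("pq,qck->pck", m2_w, path_vals)         # (p, c, k)
    assay_vals = np.einsum("ap,pck->ack", m1_w, prot_vals)        # (a, c, k)

    observed = rng.random((cfg.n_assays, cfg.n_chemicals)) >= cfg.missing_frac
    noisy = assay_vals
    if cfg.noise_sd > 0:
        noisy = assay_vals + rng.normal(0.0, cfg.noise_sd, assay_vals.shape)

    hill_params: dict[tuple[str, str], HillParams] = {}
    rows = []
    for i, aid in enumerate(cfg.assay_ids):
        for j, kid in enumerate(cfg.chemical_ids):
            if not observed[i, j]:
                continue
            params = _fit_hill(noisy[i, :, j], grid)
            hill_params[(aid, kid)] = params
            rows.append({
                "assay_id": aid, "chemical_id": kid,
                "ac50": params.ac50 / M_PER_UM, "slope": params.slope,
                "top": params.top, "unit": "uM",
            })
    assay_table = pd.DataFrame(rows, columns=["assay_id", "chemical_id",
                                              "ac50", "slope", "top", "unit"])

    scores = path_vals.mean(axis=1)
    path_scores = pd.DataFrame(scores, index=cfg.pathway_ids, columns=cfg.chemical_ids)
    endpoints, m3_true = _draw_endpoints(rng, cfg, scores)

    endpoint_tables = {}
    for ep in endpoints:
        if ep.kind == "continuous":
            df = pd.DataFrame({"chemical_id": ep.values.index,
                               "dose_mg_per_kg": 10.0 ** (-ep.values.to_numpy())})
        else:
            df = pd.DataFrame({"chemical_id": ep.values.index,
                               "label": ep.values.astype(int).to_numpy()})
        endpoint_tables[ep.endpoint_id] = df

    # Css table for a subset of compounds (externally modeled in real studies)
    n_css = max(1, int(round(cfg.css_frac * cfg.n_chemicals)))
    css_chems = sorted(rng.choice(cfg.chemical_ids, size=n_css, replace=False))
    p50 = 10.0 ** rng.uniform(-1.5, 1.5, size=n_css)
    spread = 10.0 ** rng.uniform(0.2, 0.6, size=n_css)
    css_table = pd.DataFrame({
        "chemical_id": css_chems,
        "css_p5_uM": p50 / spread, "css_p50_uM": p50, "css_p95_uM": p50 * spread,
    })

    fam_idx = np.arange(cfg.n_chemicals) % len(_FAMILY_OF)
    smiles_table = pd.DataFrame({
        "chemical_id": cfg.chemical_ids,
        "smiles": [_FAMILY_OF[i][0] for i in fam_idx],
    })
    families = pd.Series([_FAMILY_OF[i][1] for i in fam_idx], index=cfg.chemical_ids)

    study = SyntheticStudy(
        assay_table=assay_table,
        assay_protein_map=pd.DataFrame(
            [{"assay_id": cfg.assay_ids[i], "protein_id": cfg.protein_ids[p]}
             for i, p in zip(*np.nonzero(m1_mask))],
        ),
        genesets={cfg.pathway_ids[q]: [cfg.protein_ids[p]
                                       for p in np.flatnonzero(m2_mask[:, q])]
                  for q in range(cfg.n_pathways)},
        endpoint_tables=endpoint_tables,
        css_table=css_table,
        smiles_table=smiles_table,
        grid=grid,
        assay_ids=cfg.assay_ids, protein_ids=cfg.protein_ids,
        pathway_ids=cfg.pathway_ids, chemical_ids=cfg.chemical_ids,
        endpoint_ids=cfg.endpoint_ids,
    )
    mask3 = np.ones_like(path_vals, dtype=bool)
    truth = GroundTruth(
        M1_true=MappingMatrix(weights=m1_w, structure_mask=m1_mask, layer="M1",
                              row_ids=cfg.assay_ids, col_ids=cfg.protein_ids),
        M2_true=MappingMatrix(weights=m2_w, structure_mask=m2_mask, layer="M2",
                              row_ids=cfg.protein_ids, col_ids=cfg.pathway_ids),
        M3_true=m3_true,
        path_true=LayerTensor(values=path_vals, mask=mask3,
                              entity_ids=cfg.pathway_ids,
                              chemical_ids=cfg.chemical_ids, grid=grid),
        path_scores=path_scores,
        endpoint_values=endpoints,
        hill_params=hill_params,
        assay_true=LayerTensor(
            values=assay_vals,
            mask=np.broadcast_to(observed[:, None, :], assay_vals.shape).copy(),
            entity_ids=cfg.assay_ids, chemical_ids=cfg.chemical_ids, grid=grid),
        smiles_families=families,
    )
    logger.info("generated study: %d assays x %d chemicals (%d pairs observed)",
                cfg.n_assays, cfg.n_chemicals, len(hill_params))
    return study, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_study(study: SyntheticStudy, truth: GroundTruth, out_dir: str | FsPath) -> dict[str, str]:
    """Write the study in the file formats the pipeline readers consume.

    CSV for tables, GMT for gene sets, SMI for structures, plus a JSON
    ground-truth sidecar for tests.  Returns {name: path}.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[name] = str(p)

    _csv(study.assay_table, "assay_table.csv")
    _csv(study.assay_protein_map, "assay_protein_map.csv")
    _csv(study.css_table, "css_table.csv")
    for eid, df in study.endpoint_tables.items():
        _csv(df, f"endpoint_{eid}.csv")

    gmt = out / "pathways.gmt"
    with gmt.open("w") as fh:
        for pw, members in study.genesets.items():
            fh.write("\t".join([pw, "synthetic", *members]) + "\n")
    paths["pathways.gmt"] = str(gmt)

    smi = out / "compounds.smi"
    with smi.open("w") as fh:
        for _, row in study.smiles_table.iterrows():
            fh.write(f"{row['smiles']}\t{row['chemical_id']}\n")
    paths["compounds.smi"] = str(smi)

    sidecar = {
        "M1_true": truth.M1_true.weights.tolist(),
        "M2_true": truth.M2_true.weights.tolist(),
        "M3_true": truth.M3_true.tolist(),
        "path_scores": truth.path_scores.to_dict(orient="split"),
        "grid": study.grid.points.tolist(),
        "assay_ids": study.assay_ids,
        "protein_ids": study.protein_ids,
        "pathway_ids": study.pathway_ids,
        "chemical_ids": study.chemical_ids,
        "endpoint_ids": study.endpoint_ids,
    }
    gt = out / "ground_truth.json"
    gt.write_text(json.dumps(sidecar, sort_keys=True))
    paths["ground_truth.json"] = str(gt)
    return paths
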