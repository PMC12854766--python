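"""File I/O, configuration, and the end-to-end pipeline driver.

All tables are plain CSV/TSV; gene sets use the tab-separated GMT
format; structures use one-per-line SMI.  Floats are written with 12
significant digits so every writer round-trips losslessly through its
paired reader.  Tensors go to ``.npz`` with a JSON axis sidecar.

``run_pipeline`` chains the stages: harmonize -> fit M1/Prot -> fit
M2/Path -> summarize -> associate/filter (M3) -> fit Tox -> score ->
(optional) cluster -> (optional) exposure, writing a machine-readable
manifest; everything is deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from . import assoc_filter, chem_cluster, exposure, tox_scoring
from .assoc_filter import EndpointTable
from .hill import (ConcentrationGrid, HillParams, build_grid, build_assay_tensor,
                   merge_replicates, normalize_curve, summarize_assay_tops)
from .tensor_model import (LayerTensor, TrainConfig, fit_pathway_layer,
                           fit_protein_layer, fit_tox_layer, minmax_normalize,
                           summarize_over_concentration)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
M_PER_UM = 1e-6

__all__ = [
    "PipelineConfig", "EndpointSpec",
    "read_assay_table", "read_genesets", "read_endpoint_table",
    "read_css_table", "read_smiles",
    "write_tensor", "read_tensor",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EndpointSpec:
    endpoint_id: str
    kind: str          # continuous | binary
    path: str
    scheme: str = "none"  # GHS_acute | NOAEL_band | binary | none
    bootstrap: bool = False


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the YAML config file."""

    assay_table: str
    assay_protein_map: str
    genesets: str
    endpoints: list[EndpointSpec]
    css_table: str | None = None
    smiles: str | None = None
    grid_n: int = 45
    grid_c_min: float = 1e-12
    grid_c_max: float = 1e-4
    train: TrainConfig = field(default_factory=TrainConfig)
    r_min: float = 0.1
    q_max: float = 0.05
    use_n_threshold: bool = True
    fdr_scope: str = "per_endpoint"
    cluster_threshold: float = 0.7
    cluster_min_size: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | FsPath) -> "PipelineConfig":
        raw = yaml.safe_load(FsPath(path).read_text())
        raw["endpoints"] = [EndpointSpec(**e) for e in raw.get("endpoints", [])]
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        return cls(**raw)

    def to_yaml(self, path: str | FsPath) -> None:
        FsPath(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def grid(self) -> ConcentrationGrid:
        return build_grid(self.grid_n, self.grid_c_min, self.grid_c_max)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_REQUIRED_ASSAY_COLS = ("assay_id", "chemical_id", "ac50", "slope", "top")


def read_assay_table(path: str | FsPath) -> tuple[list[tuple[str, str, HillParams]], int]:
    """Read a Hill-parameter table (CSV/TSV).

    Required columns: assay_id, chemical_id, ac50, slope, top; optional
    ``unit`` for ac50 ("uM" default, or "M").  Rows with missing or
    invalid parameters (ac50 <= 0, slope <= 0, top == 0 or any
    non-finite) are dropped and counted.  Duplicate (assay, chemical)
    rows are all kept for replicate reconciliation.
    Returns (records, n_dropped).
    """
    p = FsPath(path)
    df = pd.read_csv(p, sep="\t" if p.suffix.lower() in (".tsv", ".tab") else ",")
    for col in _REQUIRED_ASSAY_COLS:
        if col not in df.columns:
            raise ValueError(f"assay table {p} is missing required column {col!r}")
    units = df["unit"] if "unit" in df.columns else pd.Series("uM", index=df.index)
    records: list[tuple[str, str, HillParams]] = []
    dropped = 0
    for idx, row in df.iterrows():
        ac50, slope, top = row["ac50"], row["slope"], row["top"]
        unit = str(units.loc[idx]).strip()
        ok = (np.isfinite([ac50, slope, top]).all() and ac50 > 0 and slope > 0
              and top != 0 and unit in ("uM", "M"))
        if not ok:
            dropped += 1
            continue
        ac50_m = float(ac50) * (M_PER_UM if unit == "uM" else 1.0)
        records.append((str(row["assay_id"]), str(row["chemical_id"]),
                        HillParams(ac50=ac50_m, slope=float(slope), top=float(top))))
    if dropped:
        logger.info("read_assay_table: dropped %d invalid rows of %d", dropped, len(df))
    return records, dropped


def read_genesets(path: str | FsPath, protein_roster: list[str]) -> tuple[np.ndarray, list[str]]:
    """Read a GMT gene-set file into a protein x pathway boolean mask.

    Standard GMT: name <tab> description <tab> member...; membership is
    intersected with the protein roster.  Empty sets and sets with no
    known members are dropped with a warning.
    """
    idx = {pid: i for i, pid in enumerate(protein_roster)}
    names: list[str] = []
    cols: list[np.ndarray] = []
    dropped = 0
    with FsPath(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name<TAB>description)")
            name, _desc, *members = fields
            col = np.zeros(len(protein_roster), dtype=bool)
            for m in members:
                if m in idx:
                    col[idx[m]] = True
            if not col.any():
                logger.warning("%s:%d: gene set %s has no members on the roster; dropped",
                               path, lineno, name)
                dropped += 1
                continue
            names.append(name)
            cols.append(col)
    if not names:
        raise ValueError(f"{path}: no usable gene sets")
    if dropped:
        logger.info("read_genesets: dropped %d sets", dropped)
    return np.stack(cols, axis=1), names


def read_endpoint_table(path: str | FsPath, endpoint_id: str, kind: str) -> EndpointTable:
    """Read one endpoint CSV into an EndpointTable.

    Continuous files carry (chemical_id, dose_mg_per_kg) and are
    transformed to the -log10 potency scale; binary files carry
    (chemical_id, label) with 1 = toxic.
    """
    df = pd.read_csv(path)
    if "chemical_id" not in df.columns:
        raise ValueError(f"endpoint table {path} is missing column 'chemical_id'")
    if kind == "continuous":
        if "dose_mg_per_kg" not in df.columns:
            raise ValueError(f"endpoint table {path} is missing column 'dose_mg_per_kg'")
        vals = df["dose_mg_per_kg"].map(assoc_filter.transform_continuous_endpoint)
    elif kind == "binary":
        if "label" not in df.columns:
            raise ValueError(f"endpoint table {path} is missing column 'label'")
        vals = df["label"].astype(float)
    else:
        raise ValueError(f"unknown endpoint kind {kind!r}")
    return EndpointTable(endpoint_id=endpoint_id, kind=kind,
                         values=pd.Series(vals.to_numpy(), index=df["chemical_id"].astype(str)))


def read_css_table(path: str | FsPath) -> list[exposure.CssRecord]:
    df = pd.read_csv(path)
    need = ("chemical_id", "css_p5_uM", "css_p50_uM", "css_p95_uM")
    for col in need:
        if col not in df.columns:
            raise ValueError(f"Css table {path} is missing column {col!r}")
    return [exposure.CssRecord(chemical_id=str(r["chemical_id"]),
                               css_p5=float(r["css_p5_uM"]),
                               css_p50=float(r["css_p50_uM"]),
                               css_p95=float(r["css_p95_uM"]))
            for _, r in df.iterrows()]


def read_smiles(path: str | FsPath) -> dict[str, str]:
    """Read an SMI file (SMILES <whitespace> id per line)."""
    out: dict[str, str] = {}
    with FsPath(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: SMI line needs 'SMILES id'")
            out[parts[1]] = parts[0]
    return out


# ---------------------------------------------------------------------------
# tensor round trip
# ---------------------------------------------------------------------------

def write_tensor(t: LayerTensor, stem: str | FsPath) -> None:
    """Write a LayerTensor to <stem>.npz plus <stem>.axes.json metadata."""
    stem = FsPath(stem)
    np.savez(stem.with_suffix(".npz"), values=t.values, mask=t.mask)
    meta = {"entity_ids": t.entity_ids, "chemical_ids": t.chemical_ids,
            "grid": None if t.grid is None else list(map(float, t.grid.points))}
    stem.with_suffix(".axes.json").write_text(json.dumps(meta))


def read_tensor(stem: str | FsPath) -> LayerTensor:
    stem = FsPath(stem)
    arrs = np.load(stem.with_suffix(".npz"))
    meta = json.loads(stem.with_suffix(".axes.json").read_text())
    grid = None if meta["grid"] is None else ConcentrationGrid(points=np.asarray(meta["grid"]))
    return LayerTensor(values=arrs["values"], mask=arrs["mask"],
                       entity_ids=meta["entity_ids"],
                       chemical_ids=meta["chemical_ids"], grid=grid)


def _write_csv(df: pd.DataFrame, path: FsPath, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def harmonize_stage(records: list[tuple[str, str, HillParams]],
                    grid: ConcentrationGrid) -> tuple[LayerTensor, pd.DataFrame]:
    """Normalize, reconcile replicates, classify assays, and stack the tensor."""
    by_pair: dict[tuple[str, str], list] = {}
    by_assay: dict[str, dict[str, HillParams]] = {}
    for aid, kid, params in records:
        by_pair.setdefault((aid, kid), []).append(
            normalize_curve(params, grid, source=(aid, kid)))
        by_assay.setdefault(aid, {})[kid] = params
    summaries = [summarize_assay_tops(aid, chems) for aid, chems in sorted(by_assay.items())]
    summary_df = pd.DataFrame([{"assay_id": s.assay_id, "min_top": s.min_top,
                                "max_top": s.max_top, "category": s.category}
                               for s in summaries])
    keep = {s.assay_id for s in summaries if s.category != "excluded"}
    logger.info("harmonize: %d/%d assays retained after Top classification",
                len(keep), len(summaries))
    merged = {pair: merge_replicates(curves) for pair, curves in by_pair.items()
              if pair[0] in keep}
    assay_ids = sorted(keep)
    chem_ids = sorted({kid for (_aid, kid) in merged})
    tensor = build_assay_tensor(merged, grid, assay_ids, chem_ids)
    return tensor, summary_df


def run_pipeline(config: PipelineConfig, out_dir: str | FsPath) -> dict:
    """Execute the full workflow and write all artifact tables.

    Returns the run manifest (also written to manifest.json).  A stage
    failure writes a FAILED marker naming the stage and re-raises.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": [], "counts": {}}
    stage = "init"
    try:
        # 1 — harmonize
        stage = "harmonize"
        grid = config.grid()
        records, n_dropped = read_assay_table(config.assay_table)
        assay_tensor, top_summary = harmonize_stage(records, grid)
        _write_csv(top_summary, out / "assay_top_summary.csv")
        write_tensor(assay_tensor, out / "assay_tensor")
        manifest["stages"].append(stage)
        manifest["counts"]["assay_rows_dropped"] = n_dropped
        manifest["counts"]["assays_retained"] = len(assay_tensor.entity_ids)

        # 2 — protein layer
        stage = "fit_protein_layer"
        ap = pd.read_csv(config.assay_protein_map)
        protein_ids = sorted(ap["protein_id"].astype(str).unique())
        p_idx = {p: i for i, p in enumerate(protein_ids)}
        a_idx = {a: i for i, a in enumerate(assay_tensor.entity_ids)}
        m1_mask = np.zeros((len(a_idx), len(protein_ids)), dtype=bool)
        for _, r in ap.iterrows():
            aid = str(r["assay_id"])
            if aid in a_idx:
                m1_mask[a_idx[aid], p_idx[str(r["protein_id"])]] = True
        cfg_train = config.train
        m1, prot, trace1 = fit_protein_layer(assay_tensor, m1_mask, cfg_train,
                                             protein_ids=protein_ids)
        _write_csv(pd.DataFrame(m1.weights, index=m1.row_ids, columns=m1.col_ids),
                   out / "M1.csv", index=True)
        write_tensor(prot, out / "prot_tensor")
        manifest["stages"].append(stage)
        manifest["counts"]["proteins_mapped"] = len(protein_ids)

        # 3 — pathway layer
        stage = "fit_pathway_layer"
        m2_mask, pathway_ids = read_genesets(config.genesets, protein_ids)
        m2, path, trace2 = fit_pathway_layer(prot, m2_mask, cfg_train,
                                             pathway_ids=pathway_ids)
        _write_csv(pd.DataFrame(m2.weights, index=m2.row_ids, columns=m2.col_ids),
                   out / "M2.csv", index=True)
        write_tensor(path, out / "path_tensor")
        manifest["stages"].append(stage)

        # 4 — summarize + associate + build M3
        stage = "filter_associations"
        path_scores = pd.DataFrame(summarize_over_concentration(path),
                                   index=path.entity_ids, columns=path.chemical_ids)
        _write_csv(path_scores, out / "path_scores.csv", index=True)
        endpoints = [read_endpoint_table(e.path, e.endpoint_id, e.kind)
                     for e in config.endpoints]
        boot = tuple(e.endpoint_id for e in config.endpoints if e.bootstrap)
        recs = assoc_filter.associate(path_scores, endpoints, boot_endpoints=boot,
                                      seed=config.seed)
        m3 = assoc_filter.build_m3(recs, pathway_ids,
                                   [e.endpoint_id for e in config.endpoints],
                                   r_min=config.r_min, q_max=config.q_max,
                                   use_n_threshold=config.use_n_threshold,
                                   fdr_scope=config.fdr_scope)
        assoc_df = pd.DataFrame([{
            "pathway_id": r.pathway_id, "endpoint_id": r.endpoint_id, "n": r.n,
            "stat": r.stat, "p": r.p, "q": r.q, "test_used": r.test_used,
            "ci95_lo": r.ci95[0], "ci95_hi": r.ci95[1],
            "boot_ci95_lo": r.boot_ci95[0] if r.boot_ci95 else np.nan,
            "boot_ci95_hi": r.boot_ci95[1] if r.boot_ci95 else np.nan,
            "retained": r.retained} for r in recs])
        _write_csv(assoc_df, out / "associations.csv")
        _write_csv(pd.DataFrame(m3, index=pathway_ids,
                                columns=[e.endpoint_id for e in config.endpoints]),
                   out / "M3.csv", index=True)
        manifest["stages"].append(stage)
        manifest["counts"]["pathway_endpoint_pairs_retained"] = int(m3.sum())

        # 5 — toxicity layer + scoring
        stage = "fit_tox_layer"
        endpoint_ids = [e.endpoint_id for e in config.endpoints]
        tox, trace3 = fit_tox_layer(path, m3, cfg_train, endpoint_ids=endpoint_ids)
        write_tensor(tox, out / "tox_tensor")
        raw_scores = pd.DataFrame(summarize_over_concentration(tox),
                                  index=endpoint_ids, columns=tox.chemical_ids)
        norm_scores = raw_scores.apply(lambda row: pd.Series(
            minmax_normalize(row.to_numpy()), index=row.index), axis=1)
        scores = tox_scoring.score_table(norm_scores)
        # dose-band classes where a scheme applies
        ep_by_id = {e.endpoint_id: e for e in config.endpoints}
        ep_values = {t.endpoint_id: t for t in endpoints}
        cls_col = []
        for _, row in scores.iterrows():
            spec = ep_by_id[row["endpoint_id"]]
            tbl = ep_values[spec.endpoint_id]
            val = tbl.values.get(row["chemical_id"], np.nan)
            if pd.isna(val):
                cls_col.append("")
            elif spec.scheme == "GHS_acute":
                cls_col.append(tox_scoring.ghs_acute_class(10.0 ** (-val)).label)
            elif spec.scheme == "NOAEL_band":
                cls_col.append(tox_scoring.noael_band_class(10.0 ** (-val)).label)
            elif spec.kind == "binary":
                cls_col.append("toxic" if val == 1 else "nontoxic")
            else:
                cls_col.append("")
        scores["observed_class"] = cls_col
        _write_csv(scores, out / "tox_scores.csv")
        manifest["stages"].append(stage)

        # 6 — structural clustering (optional)
        stage = "cluster"
        if config.smiles:
            smiles = read_smiles(config.smiles)
            fps = chem_cluster.maccs_fingerprints(smiles)
            assign = chem_cluster.taylor_butina(fps, threshold=config.cluster_threshold,
                                                min_size=config.cluster_min_size)
            labels = pd.Series(assign.labels, name="cluster_id")
            _write_csv(labels.rename_axis("chemical_id").reset_index(),
                       out / "clusters.csv")
            profiles = []
            for t in endpoints:
                try:
                    profiles.extend(tox_scoring.cluster_z_scores(
                        labels, t.values, t.endpoint_id, kind=t.kind))
                except ValueError as exc:
                    logger.warning("cluster z-scores skipped for %s: %s",
                                   t.endpoint_id, exc)
            _write_csv(pd.DataFrame([vars(p) for p in profiles]),
                       out / "cluster_tox_profiles.csv")
            smarts_rows = []
            for cid in assign.retained:
                members = [smiles[c] for c, l in assign.labels.items() if l == cid]
                pattern, ok = chem_cluster.cluster_mcs_smarts(members)
                smarts_rows.append({"cluster_id": cid, "n_members": len(members),
                                    "smarts": pattern, "mcs_found": ok})
            _write_csv(pd.DataFrame(smarts_rows), out / "cluster_smarts.csv")
            manifest["counts"]["clusters_retained"] = len(assign.retained)
        manifest["stages"].append(stage)

        # 7 — exposure comparison (optional)
        stage = "exposure"
        if config.css_table:
            css_records = read_css_table(config.css_table)
            pots = (exposure.layer_potencies(assay_tensor, "assay")
                    + exposure.layer_potencies(prot, "prot")
                    + exposure.layer_potencies(path, "path"))
            have = {p.chemical_id for p in pots}
            rows = []
            for css in css_records:
                if css.chemical_id not in have:
                    logger.warning("no modeled potency for %s; skipped", css.chemical_id)
                    continue
                flags = exposure.exposure_flags(css, pots)
                for layer, summ in flags["layers"].items():
                    rows.append({"chemical_id": css.chemical_id, "layer": layer,
                                 "css_p95_uM": css.css_p95, **summ,
                                 "exposure_relevant": flags["exposure_relevant"]})
            _write_csv(pd.DataFrame(rows), out / "exposure_flags.csv")
            manifest["counts"]["compounds_with_css"] = len({r["chemical_id"] for r in rows})
        manifest["stages"].append(stage)

        manifest["loss_final"] = {"M1": float(trace1.loss_trace[-1]),
                                  "M2": float(trace2.loss_trace[-1]),
                                  "Tox": float(trace3.loss_trace[-1])}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
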