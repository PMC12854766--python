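"""Three-layer hierarchical factorization of harmonized bioassay tensors.

The model decomposes a harmonized concentration-response tensor
``Assay`` (n_assays x n_concentrations x n_chemicals) through a cascade
of bilinear maps,

    Assay = M1 . Prot        (assay  -> protein)
    Prot  = M2 . Path        (protein -> pathway)
    Path  = M3 . Tox         (pathway -> toxicity endpoint)

where M1/M2 are learnable mapping matrices constrained to the sparsity
pattern of curated assay->protein and protein->pathway annotations, and
M3 is a fixed binary matrix produced by supervised statistical filtering
(see :mod:`aoptox.assoc_filter`).  Each stage minimizes the mean squared
error between the reconstruction and its target over *observed* tensor
entries only; untested compound-assay pairs carry an explicit mask and
never enter the loss.

Training follows the protocol of adaptive-moment gradient descent
(Adam, initial step size 1e-3) with a plateau-triggered step-size decay
and early stopping, applied after a deterministic warm start computed by
masked alternating least squares.  Factor scale is not identifiable, so
downstream consumers work with reconstructions and summarized scores,
never raw weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LayerTensor",
    "MappingMatrix",
    "TrainConfig",
    "TrainResult",
    "fit_protein_layer",
    "fit_pathway_layer",
    "fit_tox_layer",
    "summarize_over_concentration",
    "minmax_normalize",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LayerTensor:
    """A 3-way (entities x concentrations x chemicals) activity tensor.

    ``mask`` is True exactly where an entry is observed (or modeled);
    masked-out entries are never consumed by any loss or summary.
    """

    values: np.ndarray
    mask: np.ndarray
    entity_ids: list[str]
    chemical_ids: list[str]
    grid: object | None = None  # ConcentrationGrid, kept by reference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"LayerTensor values must be 3-way, got ndim={self.values.ndim}")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        n_e, _, n_k = self.values.shape
        if len(self.entity_ids) != n_e:
            raise ValueError("entity_ids length does not match first axis")
        if len(self.chemical_ids) != n_k:
            raise ValueError("chemical_ids length does not match last axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class MappingMatrix:
    """A structurally masked mapping matrix (M1, M2 or M3).

    ``weights`` are identically zero wherever ``structure_mask`` is
    False.  For M3 the binarized 0/1 form used as the fixed supervised
    transformation is held in ``binarized``.
    """

    weights: np.ndarray
    structure_mask: np.ndarray
    layer: str  # "M1" | "M2" | "M3"
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    binarized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.structure_mask = np.asarray(self.structure_mask, dtype=bool)
        if self.weights.shape != self.structure_mask.shape:
            raise ValueError("weights and structure_mask shapes differ")
        if np.any(self.weights[~self.structure_mask] != 0.0):
            raise ValueError(f"{self.layer}: nonzero weight outside structure mask")
        if self.binarized is not None:
            b = np.asarray(self.binarized)
            if not np.isin(b, (0, 1)).all():
                raise ValueError("binarized entries must be 0/1")
            if np.any(b.astype(bool) & ~self.structure_mask):
                raise ValueError("binarized entry outside structure mask")


@dataclass
class TrainConfig:
    """Gradient-training hyperparameters shared by all three layers."""

    lr0: float = 1e-3
    plateau_factor: float = 0.1
    plateau_patience: int = 20
    max_epochs: int = 1000
    converge_tol: float = 1e-6
    converge_window: int = 20
    init_sd: float = 0.01
    als_sweeps: int = 50
    nonneg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0,1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    loss_trace: np.ndarray
    lr_trace: np.ndarray
    n_epochs: int
    converged: bool


# ---------------------------------------------------------------------------
# masked bilinear trainer
# ---------------------------------------------------------------------------

_RIDGE = 1e-4  # relative Tikhonov damping in the alternating solves


def _ridge_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """min ||A x - B||^2 + ridge, scale-free: damps cancellation blow-ups."""
    G = A.T @ A
    lam = _RIDGE * max(np.trace(G) / max(G.shape[0], 1), 1e-30)
    return np.linalg.solve(G + lam * np.eye(G.shape[0]), A.T @ B)


def _masked_lstsq_rows(T: np.ndarray, W: np.ndarray, X: np.ndarray,
                       struct: np.ndarray, nonneg: bool) -> np.ndarray:
    """Solve rows of M in min ||W*(T - M X)||^2 subject to the structure mask.

    Each row is an independent least-squares problem over its allowed
    columns, restricted to that row's observed entries.
    """
    n_rows, n_cols = struct.shape
    M = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        cols = np.flatnonzero(struct[i])
        obs = W[i]
        if cols.size == 0 or not obs.any():
            continue
        A = X[cols][:, obs].T  # (n_obs, n_allowed)
        b = T[i, obs]
        sol = _ridge_solve(A, b)
        if nonneg:
            sol = np.maximum(sol, 0.0)
        M[i, cols] = sol
    return M


def _masked_lstsq_cols(T: np.ndarray, W: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve X in min ||W*(T - M X)||^2 column by column (unconstrained)."""
    n_cols = T.shape[1]
    X = np.zeros((M.shape[1], n_cols))
    # group columns by identical observation pattern to batch the solves
    patterns: dict[bytes, list[int]] = {}
    for j in range(n_cols):
        patterns.setdefault(W[:, j].tobytes(), []).append(j)
    for key, js in patterns.items():
        rows = np.frombuffer(key, dtype=bool)
        if not rows.any():
            continue
        X[:, js] = _ridge_solve(M[rows], T[np.ix_(rows, js)])
    return X


def _fit_masked_product(
    target: np.ndarray,
    obs_mask: np.ndarray,
    struct: np.ndarray,
    cfg: TrainConfig,
    *,
    fixed_map: np.ndarray | None = None,
    layer_name: str = "M",
) -> tuple[np.ndarray, np.ndarray, TrainResult]:
    """Minimize masked MSE between ``map @ latent`` and a 2-D target.

    ``target`` is (entities x q) with q = n_concentrations*n_chemicals
    flattened; ``obs_mask`` marks observed entries.  When ``fixed_map``
    is given only the latent factor is trained (the supervised M3
    stage); otherwise both the structurally masked mapping matrix and
    the latent factor are trained.

    Returns (mapping weights, latent factor, trace).  Deterministic for
    a fixed ``cfg.seed``.
    """
    target = np.asarray(target, dtype=float)
    W = np.asarray(obs_mask, dtype=bool)
    n_rows = target.shape[0]
    rng = np.random.default_rng(cfg.seed)

    row_ok = struct.any(axis=1)
    if fixed_map is None and not row_ok.all():
        bad = int(np.flatnonzero(~row_ok)[0])
        raise ValueError(f"{layer_name}: row {bad} has no allowed entries in the structure mask")

    n_obs = int(W.sum())
    if n_obs == 0:
        raise ValueError("no observed entries to fit")

    # ----- warm start: masked alternating least squares -------------------
    def _rebalance(M: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # fold latent row scales into the mapping columns (loss-invariant);
        # keeps alternating solves well conditioned across layers
        scale = np.sqrt(np.mean(X * X, axis=1))
        ok = scale > 1e-12
        X = np.where(ok[:, None], X / np.where(ok, scale, 1.0)[:, None], X)
        M = M * np.where(ok, scale, 1.0)[None, :]
        return M, X

    if fixed_map is not None:
        M = np.asarray(fixed_map, dtype=float)
        X = _masked_lstsq_cols(target, W, M)
    else:
        M = struct.astype(float)  # unit weights on allowed entries
        X = _masked_lstsq_cols(target, W, M)
        best_pair = (M, X)
        best_loss = float(np.mean(((M @ X - target)[W]) ** 2))
        prev = best_loss
        for _ in range(cfg.als_sweeps):
            M, X = _rebalance(M, X)
            M = _masked_lstsq_rows(target, W, X, struct, cfg.nonneg)
            # guard against rows collapsing to zero under the nonneg clip
            dead = ~M.any(axis=1) & struct.any(axis=1)
            M[dead] = struct[dead].astype(float)
            X = _masked_lstsq_cols(target, W, M)
            cur = float(np.mean(((M @ X - target)[W]) ** 2))
            if cur < best_loss:
                best_loss, best_pair = cur, (M, X)
            if abs(prev - cur) <= 1e-12 * max(prev, 1.0):
                break
            prev = cur
        M, X = _rebalance(*best_pair)
        # seeded jitter so repeated trainings explore distinct basins
        X = X + rng.normal(0.0, cfg.init_sd, size=X.shape)

    # ----- Adam refinement with plateau decay and early stopping ----------
    train_map = fixed_map is None
    lr = cfg.lr0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mX = np.zeros_like(X)
    vX = np.zeros_like(X)
    if train_map:
        mM = np.zeros_like(M)
        vM = np.zeros_like(M)

    def loss_of(Mc: np.ndarray, Xc: np.ndarray) -> float:
        R = (Mc @ Xc - target)[W]
        return float(np.mean(R * R))

    losses = [loss_of(M, X)]
    lrs = [lr]
    best = losses[0]
    since_plateau = 0
    flat_epochs = 0
    converged = False

    for epoch in range(1, cfg.max_epochs + 1):
        R = np.where(W, M @ X - target, 0.0)
        gX = (2.0 / n_obs) * (M.T @ R)
        mX = beta1 * mX + (1 - beta1) * gX
        vX = beta2 * vX + (1 - beta2) * gX * gX
        bc1 = 1 - beta1 ** epoch
        bc2 = 1 - beta2 ** epoch
        X = X - lr * (mX / bc1) / (np.sqrt(vX / bc2) + eps)
        if train_map:
            gM = (2.0 / n_obs) * (R @ X.T)
            gM[~struct] = 0.0
            mM = beta1 * mM + (1 - beta1) * gM
            vM = beta2 * vM + (1 - beta2) * gM * gM
            M = M - lr * (mM / bc1) / (np.sqrt(vM / bc2) + eps)
            M[~struct] = 0.0
            if cfg.nonneg:
                np.maximum(M, 0.0, out=M)

        cur = loss_of(M, X)
        if not np.isfinite(cur):
            raise ArithmeticError(f"{layer_name}: non-finite loss at epoch {epoch}")
        losses.append(cur)
        lrs.append(lr)

        # plateau-triggered decay of the step size
        if cur < best * (1 - 1e-12):
            since_plateau = 0
        else:
            since_plateau += 1
            if since_plateau >= cfg.plateau_patience:
                lr *= cfg.plateau_factor
                since_plateau = 0
        # early stopping on sustained relative-improvement collapse
        rel = (best - cur) / max(best, 1e-300)
        if rel < cfg.converge_tol:
            flat_epochs += 1
            if flat_epochs >= cfg.converge_window:
                converged = True
        else:
            flat_epochs = 0
        best = min(best, cur)
        if converged:
            break

    trace = TrainResult(
        loss_trace=np.asarray(losses),
        lr_trace=np.asarray(lrs),
        n_epochs=len(losses) - 1,
        converged=converged,
    )
    logger.info(
        "%s: %d epochs, final masked MSE %.3e (converged=%s)",
        layer_name, trace.n_epochs, losses[-1], converged,
    )
    return M, X, trace


def _flatten(t: LayerTensor) -> tuple[np.ndarray, np.ndarray, int, int]:
    n_e, n_c, n_k = t.shape
    return t.values.reshape(n_e, n_c * n_k), t.mask.reshape(n_e, n_c * n_k), n_c, n_k


# ---------------------------------------------------------------------------
# layer fits
# ---------------------------------------------------------------------------

def fit_protein_layer(
    assay: LayerTensor,
    m1_mask: np.ndarray,
    cfg: TrainConfig | None = None,
    protein_ids: list[str] | None = None,
) -> tuple[MappingMatrix, LayerTensor, TrainResult]:
    """Learn M1 and the latent protein tensor from the harmonized assay tensor.

    ``m1_mask`` (n_assays x n_proteins) is the structural sparsity
    pattern from the curated assay->protein map; every assay must map to
    at least one protein.
    """
    cfg = cfg or TrainConfig()
    m1_mask = np.asarray(m1_mask, dtype=bool)
    if m1_mask.shape[0] != assay.shape[0]:
        raise ValueError("m1_mask rows must equal n_assays")
    T, W, n_c, n_k = _flatten(assay)
    M, X, trace = _fit_masked_product(T, W, m1_mask, cfg, layer_name="M1")
    n_p = m1_mask.shape[1]
    # a latent protein fiber is modeled only where at least one mapped assay
    # was observed for that chemical; everything else is unidentifiable
    observed_ak = assay.mask.any(axis=1)                      # (assays x chems)
    modeled_pk = m1_mask.T.astype(int) @ observed_ak.astype(int) > 0
    prot = LayerTensor(
        values=X.reshape(n_p, n_c, n_k),
        mask=np.broadcast_to(modeled_pk[:, None, :], (n_p, n_c, n_k)).copy(),
        entity_ids=list(protein_ids) if protein_ids is not None else [f"P{i}" for i in range(n_p)],
        chemical_ids=assay.chemical_ids,
        grid=assay.grid,
    )
    m1 = MappingMatrix(weights=M, structure_mask=m1_mask, layer="M1",
                       row_ids=assay.entity_ids, col_ids=prot.entity_ids)
    return m1, prot, trace


def fit_pathway_layer(
    prot: LayerTensor,
    m2_mask: np.ndarray,
    cfg: TrainConfig | None = None,
    pathway_ids: list[str] | None = None,
) -> tuple[MappingMatrix, LayerTensor, TrainResult]:
    """Learn M2 and the latent pathway tensor from the protein tensor."""
    cfg = cfg or TrainConfig()
    m2_mask = np.asarray(m2_mask, dtype=bool)
    if m2_mask.shape[0] != prot.shape[0]:
        raise ValueError("m2_mask rows must equal n_proteins")
    T, W, n_c, n_k = _flatten(prot)
    M, X, trace = _fit_masked_product(T, W, m2_mask, cfg, layer_name="M2")
    n_q = m2_mask.shape[1]
    modeled_pk = prot.mask.any(axis=1)
    modeled_qk = m2_mask.T.astype(int) @ modeled_pk.astype(int) > 0
    path = LayerTensor(
        values=X.reshape(n_q, n_c, n_k),
        mask=np.broadcast_to(modeled_qk[:, None, :], (n_q, n_c, n_k)).copy(),
        entity_ids=list(pathway_ids) if pathway_ids is not None else [f"PW{i}" for i in range(n_q)],
        chemical_ids=prot.chemical_ids,
        grid=prot.grid,
    )
    m2 = MappingMatrix(weights=M, structure_mask=m2_mask, layer="M2",
                       row_ids=prot.entity_ids, col_ids=path.entity_ids)
    return m2, path, trace


def fit_tox_layer(
    path: LayerTensor,
    m3_binary: np.ndarray,
    cfg: TrainConfig | None = None,
    endpoint_ids: list[str] | None = None,
) -> tuple[LayerTensor, TrainResult]:
    """Fit the toxicity tensor against the pathway tensor through fixed M3.

    M3 is the binarized (n_pathways x n_endpoints) supervised filter;
    only the Tox tensor is trainable.  Every endpoint column must retain
    at least one pathway, otherwise that endpoint is unmodelable.
    """
    cfg = cfg or TrainConfig()
    m3 = np.asarray(m3_binary, dtype=float)
    if m3.shape[0] != path.shape[0]:
        raise ValueError("m3 rows must equal n_pathways")
    empty = np.flatnonzero(~m3.astype(bool).any(axis=0))
    if empty.size:
        ids = endpoint_ids or [f"E{i}" for i in range(m3.shape[1])]
        raise ValueError(
            "endpoint(s) with zero retained pathways cannot be modeled: "
            + ", ".join(ids[i] for i in empty)
        )
    T, W, n_c, n_k = _flatten(path)
    _, X, trace = _fit_masked_product(T, W, m3.astype(bool), cfg,
                                      fixed_map=m3, layer_name="Tox")
    n_e = m3.shape[1]
    modeled_qk = path.mask.any(axis=1)
    modeled_ek = m3.astype(bool).T.astype(int) @ modeled_qk.astype(int) > 0
    tox = LayerTensor(
        values=X.reshape(n_e, n_c, n_k),
        mask=np.broadcast_to(modeled_ek[:, None, :], (n_e, n_c, n_k)).copy(),
        entity_ids=list(endpoint_ids) if endpoint_ids is not None else [f"E{i}" for i in range(n_e)],
        chemical_ids=path.chemical_ids,
        grid=path.grid,
    )
    return tox, trace


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_over_concentration(layer: LayerTensor, how: str = "mean") -> np.ndarray:
    """Collapse a layer tensor to an (entities x chemicals) score matrix.

    The concentration axis is reduced by the arithmetic mean (default)
    or maximum over observed grid points; fully masked fibers yield NaN.
    """
    if layer.shape[1] < 1:
        raise ValueError("layer has no concentration axis")
    counts = layer.mask.sum(axis=1)
    if how == "mean":
        sums = np.where(layer.mask, layer.values, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    elif how == "max":
        out = np.where(layer.mask, layer.values, -np.inf).max(axis=1)
        out = np.where(counts > 0, out, np.nan)
    else:
        raise ValueError(f"unknown summary {how!r}")
    return out


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """Min-max scale a score vector to [0, 1] (NaNs propagate).

    A constant vector maps to 0.5 everywhere: with no spread there is no
    basis for ranking, and the midpoint avoids manufacturing extremes.
    """
    x = np.asarray(scores, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("minmax_normalize: no finite values")
    lo = x[finite].min()
    hi = x[finite].max()
    if hi == lo:
        out = np.full_like(x, 0.5)
        out[~finite] = np.nan
        return out
    return (x - lo) / (hi - lo)
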