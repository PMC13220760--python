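"""Three-stage training: embedding, temporal refinement, kinetic experts.

Stage 1 pretrains the graph-attention autoencoder on highly variable genes
and clusters the embedding coarsely (Leiden on a z-kNN graph) to obtain the
groups used for gene filtering and tendency estimation.  Stage 2 retrains
the encoder on the informative gene set together with the kinetic-time
encoder under smoothness and directionality regularization.  Stage 3
activates the mixture-of-experts and optimizes the full objective, adding
the MinCUT routing regularizer and the forward-difference dynamical
consistency loss that ties learned rates to observed expression changes
along latent time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor, gather_rows
from . import io_data
from .gaae import GAAE, edge_arrays
from .graph import (
    CellGraph,
    build_expression_graph,
    build_spatial_graph,
    pca_features,
    smooth_moments,
    unify_graphs,
)
from .moe_kinetics import (
    ExpertNetwork,
    GatingNetwork,
    cell_representation,
    expert_labels,
    mincut_loss,
    mixture_rates,
)
from .temporal import (
    TimeEncoder,
    directionality_agreement,
    directionality_loss,
    local_tendency,
    minmax_normalize,
    smoothness_loss,
)


@dataclasses.dataclass
class TrainConfig:
    """All tunables of a training run (defaults are desk-scale)."""

    # preprocessing / graph
    n_hvg: int = 2000
    pca_dim: int = 30
    k_expr: int = 30
    k_expr_spatial: int = 15
    k_spatial: int = 8
    use_spatial: bool = True
    normalize: str = "size_factor"
    min_cells_frac: float = 0.03
    min_u: float = 10.0
    r_min: float = 0.1
    quantile: float = 0.05
    leiden_resolution: float = 1.0
    z_knn: int = 15
    # architecture
    hidden: int = 128
    d_z: int = 32
    heads: int = 2
    time_hidden: int = 64
    gate_hidden: int = 64
    expert_hidden: int = 64
    K: int = 8
    tau: float = 1.0
    # optimization
    epochs: tuple = (150, 300, 250)
    lr: float = 1e-3
    lambda_recon: float = 1.0
    lambda_smooth: float = 0.1
    lambda_dir: float = 1.0
    lambda_cut: float = 0.5
    lambda_dyn: float = 1.0
    sign_scale: float = 5.0
    dt_max: float = 0.2
    max_pairs: int = 20000
    balance_genes: bool = False
    # stage 3 trains routing + kinetics on the frozen stage-2 embedding by
    # default; set True to fine-tune encoder and time encoder end-to-end
    stage3_finetune_embedding: bool = False
    # hard-EM refinement after the gradient stage: cells are reassigned to
    # the expert whose kinetics fit their forward differences best (residual
    # profiles smoothed over the graph for topological consistency), experts
    # refit on their cells, and the gate distilled to the final assignment
    em_iters: int = 6
    em_m_epochs: int = 60
    em_smooth_rounds: int = 2
    em_lr: float = 3e-4
    em_distill_epochs: int = 300
    # latent-time gauge for kinetic fitting: "rank" spreads cells uniformly
    # along [0,1] (ordering preserved); "raw" keeps the encoder output
    time_gauge: str = "rank"
    # what the expert nets condition on: "t" (rates are per-regime functions
    # of latent time, the kinetic law's form) or "zt" (latent-conditioned)
    expert_inputs: str = "t"
    # routing initialization: random ("none", the default), K-means on
    # [z‖t] ("kmeans"), or the stage-1 coarse groups ("coarse")
    gate_init: str = "none"
    gate_init_epochs: int = 200
    routing: str = "hard"  # inference-time routing
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_recon", "lambda_smooth", "lambda_dir",
                     "lambda_cut", "lambda_dyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.epochs = tuple(int(e) for e in self.epochs)


@dataclasses.dataclass
class SteerModel:
    """A fitted model plus the cached outputs for the training data."""

    config: TrainConfig
    gene_names: np.ndarray  # informative genes the kinetic model uses
    hvg_names: np.ndarray
    gaae: GAAE
    time_encoder: TimeEncoder
    gating: GatingNetwork
    experts: list
    flip_time: bool
    coarse_groups: np.ndarray
    stage_flags: tuple = (False, False, False)
    log: list = dataclasses.field(default_factory=list)
    # cached training-data outputs
    graph: CellGraph | None = None
    z: np.ndarray | None = None
    t: np.ndarray | None = None  # min–max normalized
    W: np.ndarray | None = None
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    U_kin: np.ndarray | None = None
    S_kin: np.ndarray | None = None

    @property
    def experts_of_cells(self) -> np.ndarray:
        return expert_labels(self.W)

    def velocity(self):
        from .velocity_analysis import compute_velocity

        return compute_velocity(self.alpha, self.beta, self.gamma,
                                self.U_kin, self.S_kin)


# -- forward neighborhoods and dynamical loss ---------------------------------

def forward_pairs(graph: CellGraph, t: np.ndarray, dt_max: float = 0.2):
    """All directed edges (i, j) with t_j > t_i and t_j − t_i ≤ dt_max."""
    src, dst = graph.directed_edges()  # dst=i, src=j
    t = np.asarray(t, dtype=float)
    dt = t[src] - t[dst]
    keep = (dt > 0) & (dt <= dt_max)
    return dst[keep], src[keep]


def forward_neighbors(graph: CellGraph, t, i: int, dt_max: float = 0.2) -> set:
    """Forward neighborhood of one cell (set of cell indices)."""
    ii, jj = forward_pairs(graph, t, dt_max)
    return set(jj[ii == i].tolist())


def dynamical_loss_pairs(U, S, alpha, beta, gamma, t, pair_i, pair_j,
                         gene_weights=None):
    """Forward-difference residual loss over given (i, j) pairs.

    r_U = (U_j−U_i) − (α_i − β_i U_i)·Δt,  r_S = (S_j−S_i) − (β_i U_i − γ_i S_i)·Δt,
    loss = mean over pairs and genes of w_g·(r_U² + r_S²).  Differentiable in
    the rates and in t.  ``gene_weights`` (optional, per gene) balance the
    contribution of high- and low-abundance genes.
    """
    if len(pair_i) == 0:
        return Tensor(0.0)
    t = Tensor.as_tensor(t)
    dt = (gather_rows(t, pair_j) - gather_rows(t, pair_i)).reshape(-1, 1)
    Ui, Si = Tensor(U[pair_i]), Tensor(S[pair_i])
    dU, dS = Tensor(U[pair_j] - U[pair_i]), Tensor(S[pair_j] - S[pair_i])
    a_i = gather_rows(alpha, pair_i) if isinstance(alpha, Tensor) else Tensor(np.asarray(alpha)[pair_i])
    b_i = gather_rows(beta, pair_i) if isinstance(beta, Tensor) else Tensor(np.asarray(beta)[pair_i])
    g_i = gather_rows(gamma, pair_i) if isinstance(gamma, Tensor) else Tensor(np.asarray(gamma)[pair_i])
    r_u = dU - (a_i - b_i * Ui) * dt
    r_s = dS - (b_i * Ui - g_i * Si) * dt
    sq = r_u * r_u + r_s * r_s
    if gene_weights is not None:
        sq = sq * Tensor(np.asarray(gene_weights, dtype=float).reshape(1, -1))
    return sq.mean()


def abundance_gene_weights(U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Inverse-variance gene weights (normalized to mean 1) so that sparse
    and abundant genes contribute comparably to the dynamical loss."""
    v = U.var(axis=0) + S.var(axis=0)
    w = 1.0 / np.maximum(v, 1e-8)
    return w / w.mean()


def dynamical_loss(U, S, alpha, beta, gamma, t, graph: CellGraph,
                   dt_max: float = 0.2) -> float:
    """Plain-number wrapper over all forward pairs (warning-free API)."""
    pair_i, pair_j = forward_pairs(graph, np.asarray(t, float), dt_max)
    if len(pair_i) == 0:
        import warnings

        warnings.warn("no forward pairs; dynamical loss is 0")
        return 0.0
    return float(dynamical_loss_pairs(np.asarray(U, float), np.asarray(S, float),
                                      alpha, beta, gamma, t,
                                      pair_i, pair_j).data)


def total_objective(terms: dict, config: TrainConfig, stage: int):
    """Weighted sum of the active stage terms plus a per-term breakdown."""
    weights = {
        "recon": config.lambda_recon,
        "smooth": config.lambda_smooth,
        "dir": config.lambda_dir,
        "cut": config.lambda_cut,
        "dyn": config.lambda_dyn,
    }
    active = {1: ("recon",), 2: ("recon", "smooth", "dir"),
              3: ("recon", "smooth", "dir", "cut", "dyn")}[stage]
    total = None
    breakdown = {}
    for name in active:
        if name not in terms:
            continue
        term = terms[name] * weights[name]
        breakdown[name] = float(term.data)
        total = term if total is None else total + term
    if total is None:
        total = Tensor(0.0)
    return total, breakdown


def rank_uniform(t: np.ndarray) -> np.ndarray:
    """Map per-cell times to uniform ranks on [0, 1] (average ties)."""
    from scipy.stats import rankdata

    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        return np.zeros_like(t)
    return (rankdata(t, method="average") - 1) / (len(t) - 1)


def ls_constant_rates(U, S, t, pair_i, pair_j, eps: float = 1e-4):
    """Per-gene least-squares constant rates from forward differences.

    The residuals are linear in (α, β, γ), so the global single-regime fit
    has a closed form (3×3 normal equations per gene).  Used to initialize
    the expert output layers at a sensible operating point; also a useful
    baseline in its own right.
    """
    dt = (t[pair_j] - t[pair_i])[:, None]
    Ui, Si = U[pair_i], S[pair_i]
    dU, dS = U[pair_j] - U[pair_i], S[pair_j] - S[pair_i]
    g = U.shape[1]
    out = np.empty((3, g))
    # rows: r_U uses [dt, -U dt, 0]; r_S uses [0, U dt, -S dt]
    a1, b1 = dt * np.ones_like(Ui), -Ui * dt
    b2, c2 = Ui * dt, -Si * dt
    A11 = (a1 * a1).sum(0)
    A12 = (a1 * b1).sum(0)
    A22 = (b1 * b1).sum(0) + (b2 * b2).sum(0)
    A23 = (b2 * c2).sum(0)
    A33 = (c2 * c2).sum(0)
    y1 = (a1 * dU).sum(0)
    y2 = (b1 * dU).sum(0) + (b2 * dS).sum(0)
    y3 = (c2 * dS).sum(0)
    for j in range(g):
        A = np.array([[A11[j], A12[j], 0.0],
                      [A12[j], A22[j], A23[j]],
                      [0.0, A23[j], A33[j]]])
        y = np.array([y1[j], y2[j], y3[j]])
        try:
            out[:, j] = np.linalg.solve(A + 1e-9 * np.eye(3), y)
        except np.linalg.LinAlgError:
            out[:, j] = eps
    return np.clip(out[0], eps, None), np.clip(out[1], eps, None), \
        np.clip(out[2], eps, None)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    y = np.clip(y, 1e-6, None)
    return np.where(y > 30, y, np.log(np.expm1(y)))


def _em_refine(experts, U, S, t, graph, pair_i, pair_j, config):
    """Hard-EM refinement of the expert mixture.

    E-step: per-cell mean forward-difference residual under each expert,
    smoothed over the graph (topological consistency), argmin assignment.
    M-step: each expert refit on the forward pairs of its own cells.
    Returns the final per-cell labels.
    """
    from .graph import smooth_moments

    n = U.shape[0]
    K = len(experts)
    t_in = Tensor(t.reshape(-1, 1))
    dU, dS = U[pair_j] - U[pair_i], S[pair_j] - S[pair_i]
    dt = (t[pair_j] - t[pair_i])[:, None]
    counts = np.bincount(pair_i, minlength=n).astype(float)
    labels = np.zeros(n, dtype=int)

    for it in range(config.em_iters):
        resid = np.zeros((n, K))
        for k in range(K):
            a, b, c = (r.data for r in experts[k](t_in))
            ru = dU - (a[pair_i] - b[pair_i] * U[pair_i]) * dt
            rs = dS - (b[pair_i] * U[pair_i] - c[pair_i] * S[pair_i]) * dt
            per_pair = (ru ** 2 + rs ** 2).mean(axis=1)
            acc = np.zeros(n)
            np.add.at(acc, pair_i, per_pair)
            resid[:, k] = acc / np.maximum(counts, 1)
        resid[counts == 0] = resid[counts == 0].mean(axis=1, keepdims=True)
        sm = resid
        for _ in range(config.em_smooth_rounds):
            sm = smooth_moments(graph, sm)
        new_labels = sm.argmin(axis=1)
        changed = (new_labels != labels).mean()
        labels = new_labels
        for k in range(K):
            mask = labels[pair_i] == k if K > 1 else np.ones(len(pair_i), bool)
            if mask.sum() < 20:
                continue
            pik = pair_i[mask]
            opt = Adam(experts[k].parameters(), lr=config.em_lr)
            Ui, Si = Tensor(U[pik]), Tensor(S[pik])
            dUk, dSk = Tensor(dU[mask]), Tensor(dS[mask])
            dtk = Tensor(dt[mask])
            tik = Tensor(t[pik].reshape(-1, 1))
            for _ in range(config.em_m_epochs):
                opt.zero_grad()
                a, b, c = experts[k](tik)
                ru = dUk - (a - b * Ui) * dtk
                rs = dSk - (b * Ui - c * Si) * dtk
                ((ru * ru + rs * rs).mean()).backward()
                opt.step()
        if changed < 0.01 and it > 0:
            break
    return labels


def _prior_targets(groups: np.ndarray, K: int) -> np.ndarray:
    """Map coarse group labels onto expert indices (largest groups keep
    distinct experts; surplus groups wrap around)."""
    uniq, counts = np.unique(groups, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {g: i % K for i, g in enumerate(order)}
    return np.array([mapping[g] for g in groups])


# -- coarse grouping -----------------------------------------------------------

def coarse_cluster(z: np.ndarray, k: int = 15, resolution: float = 1.0,
                   seed: int = 0) -> np.ndarray:
    """Leiden community detection on a kNN graph of the embedding."""
    import igraph
    import leidenalg

    g_z = build_expression_graph(z, k=min(k, z.shape[0] - 1))
    edges = [tuple(e) for e in g_z.edges()]
    graph = igraph.Graph(n=z.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


# -- the fit procedure ---------------------------------------------------------

def _train_loop(params, build_loss, epochs, lr, log, stage, config):
    opt = Adam(params, lr=lr)
    for epoch in range(epochs):
        opt.zero_grad()
        terms = build_loss(epoch)
        total, breakdown = total_objective(terms, config, stage)
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite objective at stage {stage}")
        total.backward()
        opt.step()
        log.append({"stage": stage, "epoch": epoch,
                    "total": float(total.data), **breakdown})


def fit(data: io_data.VelocityDataset, config: TrainConfig | None = None) -> SteerModel:
    """Run the full three-stage training and return a fitted model."""
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    log: list = []

    # preprocessing
    norm, _factors, _zero = io_data.normalize_dataset(data, config.normalize)
    n = norm.n_cells
    hvg = io_data.select_hvg(norm, min(config.n_hvg, norm.n_genes))
    logS = np.log1p(norm.S[:, hvg])
    pcs = pca_features(logS, d=config.pca_dim, seed=config.seed)
    has_spatial = config.use_spatial and data.spatial_coords is not None
    k_expr = min(config.k_expr_spatial if has_spatial else config.k_expr, n - 1)
    g_expr = build_expression_graph(pcs, k=k_expr)
    g_spatial = (
        build_spatial_graph(data.spatial_coords, k=min(config.k_spatial, n - 1))
        if has_spatial else None
    )
    graph = unify_graphs(g_expr, g_spatial)
    src, dst = edge_arrays(graph)

    # ---- stage 1: GAAE pretraining on HVGs ----------------------------------
    X1 = Tensor(io_data.log_features(norm, hvg))
    gaae1 = GAAE(rng, d_in=X1.shape[1], hidden=config.hidden, d_z=config.d_z,
                 heads=config.heads)

    def stage1_loss(_epoch):
        recon, _z, _a = gaae1.reconstruction_loss(X1, src, dst, n)
        return {"recon": recon}

    _train_loop(gaae1.parameters(), stage1_loss, config.epochs[0], config.lr,
                log, 1, config)
    z1, _ = gaae1.encode(X1, src, dst, n)
    groups = coarse_cluster(z1.data, k=config.z_knn,
                            resolution=config.leiden_resolution, seed=config.seed)

    # informative genes + tendency on smoothed kinetic layers
    informative = io_data.filter_informative_genes(
        norm, groups, min_cells_frac=config.min_cells_frac,
        min_u=config.min_u, r_min=config.r_min)
    U_kin = smooth_moments(graph, norm.U[:, informative])
    S_kin = smooth_moments(graph, norm.S[:, informative])
    tendency, _k = local_tendency(U_kin, S_kin, groups, q=config.quantile)

    # ---- stage 2: temporal refinement on the informative set ----------------
    X2 = Tensor(io_data.log_features(norm, informative))
    gaae2 = GAAE(rng, d_in=X2.shape[1], hidden=config.hidden, d_z=config.d_z,
                 heads=config.heads)
    time_enc = TimeEncoder(rng, config.d_z, hidden=config.time_hidden)

    def stage2_loss(_epoch):
        recon, z, _a = gaae2.reconstruction_loss(X2, src, dst, n)
        t = time_enc(z)
        return {
            "recon": recon,
            "smooth": smoothness_loss(t, graph),
            "dir": directionality_loss(t, graph, tendency, S_kin,
                                       sign_scale=config.sign_scale),
        }

    _train_loop(gaae2.parameters() + time_enc.parameters(), stage2_loss,
                config.epochs[1], config.lr, log, 2, config)

    # orientation: the temporal losses fix ordering only up to reflection
    z2, _ = gaae2.encode(X2, src, dst, n)
    t2 = time_enc(z2).data
    flip = directionality_agreement(t2, graph, tendency, S_kin) < 0

    # ---- stage 3: mixture-of-experts kinetics -------------------------------
    # Gauge fixing: latent time is defined only up to a monotone
    # reparameterization; the sigmoid output compresses its ends, which makes
    # rate curves ill-conditioned.  Rank-uniformizing t keeps the ordering
    # (Spearman-invariant) while spreading cells evenly along [0, 1].
    t2f = (1.0 - t2) if flip else t2
    if config.time_gauge == "rank":
        t2f = rank_uniform(t2f)
    pair_all = forward_pairs(graph, t2f, config.dt_max)

    gating = GatingNetwork(rng, config.d_z + 1, config.K,
                           hidden=config.gate_hidden, tau=config.tau)
    d_expert = 1 if config.expert_inputs == "t" else config.d_z + 1
    # rate magnitudes scale inversely with the typical forward time step
    pi0, pj0 = pair_all
    med_dt = np.median(t2f[pj0] - t2f[pi0]) if len(pi0) else 0.1
    rate_scale = 1.0 / max(float(med_dt), 1e-3)
    experts = [ExpertNetwork(rng, d_expert, len(informative),
                             hidden=config.expert_hidden, out_scale=rate_scale)
               for _ in range(config.K)]
    if len(pi0):
        # start every expert at the global single-regime least-squares fit;
        # routing and refinement differentiate them from this operating point
        a0, b0, g0 = ls_constant_rates(U_kin, S_kin, t2f, pi0, pj0)
        bias = _softplus_inv(np.concatenate([a0, b0, g0]) / rate_scale)
        for ex in experts:
            ex.net.layers[-1].b.data = bias.copy()
            ex.net.layers[-1].W.data[:] = 0.0  # start exactly at the LS fit
    A = graph.adjacency
    pair_rng = np.random.default_rng(config.seed + 1)
    gene_w = (abundance_gene_weights(U_kin, S_kin)
              if config.balance_genes else None)

    # Routing initialization.  MoE gates are initialization-sensitive: from a
    # random start the MinCUT optimum is an arbitrary balanced partition.
    # Anchoring each expert to a distinct region of the model's own latent
    # space (K-means on [z‖t]) before kinetic refinement makes routing follow
    # the learned geometry instead.
    if config.K > 1 and config.gate_init != "none" and config.gate_init_epochs > 0:
        rep_np = np.column_stack([z2.data, (1 - t2) if flip else t2])
        if config.gate_init == "kmeans":
            from sklearn.cluster import KMeans

            targets = KMeans(n_clusters=config.K, n_init=10,
                             random_state=config.seed).fit_predict(rep_np)
        elif config.gate_init == "coarse":
            targets = _prior_targets(groups, config.K)
        else:
            raise ValueError(f"unknown gate_init {config.gate_init!r}")
        rep0 = cell_representation(Tensor(z2.data), Tensor(t2 if not flip else 1 - t2))
        rows = np.arange(n)
        opt = Adam(gating.parameters(), lr=config.lr)
        for _ in range(config.gate_init_epochs):
            opt.zero_grad()
            W = gating(rep0)
            nll = -(W[rows, targets] + 1e-12).log().mean()
            nll.backward()
            opt.step()

    finetune = config.stage3_finetune_embedding
    # under the frozen-embedding default these are stage-3 constants
    rep_const = cell_representation(Tensor(z2.data), Tensor(t2f))

    def stage3_loss(_epoch):
        if finetune:
            recon, z, _a = gaae2.reconstruction_loss(X2, src, dst, n)
            t_raw = time_enc(z)
            t = (1.0 - t_raw) if flip else t_raw
            rep = cell_representation(z, t)
            terms = {
                "recon": recon,
                "smooth": smoothness_loss(t, graph),
                "dir": directionality_loss(t, graph, tendency, S_kin,
                                           sign_scale=config.sign_scale),
            }
            pair_i, pair_j = forward_pairs(graph, t.data, config.dt_max)
        else:
            rep, t = rep_const, Tensor(t2f)
            terms = {}
            pair_i, pair_j = pair_all
        W = gating(rep)
        # kinetics are fit conditional on time: stage 2 pinned the ordering,
        # so the dynamical residual must not warp t through its gradient
        t_fixed = t.detach()
        e_rep = (t_fixed.reshape(-1, 1) if config.expert_inputs == "t"
                 else cell_representation(rep[:, :config.d_z], t_fixed))
        rates = [ex(e_rep) for ex in experts]
        alpha, beta, gamma = mixture_rates(W, rates, mode="soft")
        if len(pair_i) > config.max_pairs:
            sel = pair_rng.choice(len(pair_i), config.max_pairs, replace=False)
            pair_i, pair_j = pair_i[sel], pair_j[sel]
        terms["dyn"] = dynamical_loss_pairs(U_kin, S_kin, alpha, beta, gamma,
                                            t_fixed, pair_i, pair_j,
                                            gene_weights=gene_w)
        if config.K > 1:
            terms["cut"] = mincut_loss(W, A)
        return terms

    params3 = gating.parameters() + sum((e.parameters() for e in experts), [])
    if finetune:
        params3 = gaae2.parameters() + time_enc.parameters() + params3
    _train_loop(params3, stage3_loss, config.epochs[2], config.lr, log, 3, config)

    # ---- hard-EM refinement of the mixture ----------------------------------
    if config.em_iters > 0 and config.expert_inputs == "t":
        if finetune:
            z_cur, _ = gaae2.encode(X2, src, dst, n)
            t_cur = time_enc(z_cur).data
            t_cur = (1.0 - t_cur) if flip else t_cur
            if config.time_gauge == "rank":
                t_cur = rank_uniform(t_cur)
            z_data = z_cur.data
            pi_all, pj_all = forward_pairs(graph, t_cur, config.dt_max)
        else:
            t_cur, z_data = t2f, z2.data
            pi_all, pj_all = pair_all
        labels = _em_refine(experts, U_kin, S_kin, t_cur, graph,
                            pi_all, pj_all, config)
        if config.K > 1 and config.em_distill_epochs > 0:
            # distill the gate so W reflects the refined assignment
            rep_d = cell_representation(Tensor(z_data), Tensor(t_cur))
            rows = np.arange(n)
            opt = Adam(gating.parameters(), lr=config.lr * 3)
            for _ in range(config.em_distill_epochs):
                opt.zero_grad()
                Wd = gating(rep_d)
                nll = -(Wd[rows, labels] + 1e-12).log().mean()
                nll.backward()
                opt.step()

    # ---- final forward pass --------------------------------------------------
    z_f, _ = gaae2.encode(X2, src, dst, n)
    t_raw = time_enc(z_f).data
    t_f = (1.0 - t_raw) if flip else t_raw
    if config.time_gauge == "rank":
        t_f = rank_uniform(t_f)
    rep = cell_representation(Tensor(z_f.data), Tensor(t_f))
    W = gating(rep).data
    e_rep = Tensor(t_f.reshape(-1, 1)) if config.expert_inputs == "t" else rep
    rates = [tuple(r.data for r in ex(e_rep)) for ex in experts]
    alpha, beta, gamma = mixture_rates(W, rates, mode=config.routing)

    model = SteerModel(
        config=config,
        gene_names=data.gene_names[informative],
        hvg_names=data.gene_names[hvg],
        gaae=gaae2,
        time_encoder=time_enc,
        gating=gating,
        experts=experts,
        flip_time=bool(flip),
        coarse_groups=groups,
        stage_flags=(True, True, True),
        log=log,
        graph=graph,
        z=z_f.data,
        t=minmax_normalize(t_f),
        W=W,
        alpha=np.asarray(alpha),
        beta=np.asarray(beta),
        gamma=np.asarray(gamma),
        U_kin=U_kin,
        S_kin=S_kin,
    )
    return model


def predict(model: SteerModel, data: io_data.VelocityDataset) -> SteerModel:
    """Apply a fitted model to a new dataset with the same gene set.

    The graph is rebuilt from the new data; all network parameters are
    reused.  Returns a shallow copy of the model carrying the new outputs.
    """
    config = model.config
    name_to_idx = {g: i for i, g in enumerate(data.gene_names)}
    missing = [g for g in model.gene_names if g not in name_to_idx]
    missing += [g for g in model.hvg_names if g not in name_to_idx]
    if missing:
        raise ValueError(f"dataset lacks genes required by the model: "
                         f"{sorted(set(map(str, missing)))[:10]}")
    informative = np.array([name_to_idx[g] for g in model.gene_names])
    hvg = np.array([name_to_idx[g] for g in model.hvg_names])

    norm, _f, _z = io_data.normalize_dataset(data, config.normalize)
    n = norm.n_cells
    logS = np.log1p(norm.S[:, hvg])
    pcs = pca_features(logS, d=config.pca_dim, seed=config.seed)
    has_spatial = config.use_spatial and data.spatial_coords is not None
    k_expr = min(config.k_expr_spatial if has_spatial else config.k_expr, n - 1)
    g_expr = build_expression_graph(pcs, k=k_expr)
    g_spatial = (build_spatial_graph(data.spatial_coords,
                                     k=min(config.k_spatial, n - 1))
                 if has_spatial else None)
    graph = unify_graphs(g_expr, g_spatial)
    src, dst = edge_arrays(graph)

    X2 = Tensor(io_data.log_features(norm, informative))
    z_f, _ = model.gaae.encode(X2, src, dst, n)
    t_raw = model.time_encoder(z_f).data
    t_f = (1.0 - t_raw) if model.flip_time else t_raw
    if config.time_gauge == "rank":
        t_f = rank_uniform(t_f)
    rep = cell_representation(Tensor(z_f.data), Tensor(t_f))
    W = model.gating(rep).data
    e_rep = Tensor(t_f.reshape(-1, 1)) if config.expert_inputs == "t" else rep
    rates = [tuple(r.data for r in ex(e_rep)) for ex in model.experts]
    alpha, beta, gamma = mixture_rates(W, rates, mode=config.routing)
    U_kin = smooth_moments(graph, norm.U[:, informative])
    S_kin = smooth_moments(graph, norm.S[:, informative])

    return dataclasses.replace(
        model,
        graph=graph,
        z=z_f.data,
        t=minmax_normalize(t_f),
        W=W,
        alpha=np.asarray(alpha),
        beta=np.asarray(beta),
        gamma=np.asarray(gamma),
        U_kin=U_kin,
        S_kin=S_kin,
    )


# -- persistence ---------------------------------------------------------------

def save_model(model: SteerModel, path) -> None:
    """Checkpoint all learnable parameters plus config to ``path`` (dir)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    modules = {"gaae": model.gaae, "time": model.time_encoder,
               "gating": model.gating}
    for name, mod in modules.items():
        for i, arr in enumerate(mod.state_arrays()):
            arrays[f"{name}_{i}"] = arr
    for k, ex in enumerate(model.experts):
        for i, arr in enumerate(ex.state_arrays()):
            arrays[f"expert{k}_{i}"] = arr
    np.savez(path / "params.npz", **arrays)
    meta = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(model.config).items()},
        "gene_names": model.gene_names.tolist(),
        "hvg_names": model.hvg_names.tolist(),
        "flip_time": model.flip_time,
        "d_in": model.gaae.d_in,
        "rate_scale": model.experts[0].out_scale if model.experts else 1.0,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> SteerModel:
    """Load a checkpoint written by :func:`save_model`."""
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["epochs"] = tuple(cfg_dict["epochs"])
    config = TrainConfig(**cfg_dict)
    rng = np.random.default_rng(config.seed)
    gene_names = np.array(meta["gene_names"])
    hvg_names = np.array(meta["hvg_names"])
    gaae = GAAE(rng, d_in=int(meta["d_in"]), hidden=config.hidden,
                d_z=config.d_z, heads=config.heads)
    time_enc = TimeEncoder(rng, config.d_z, hidden=config.time_hidden)
    gating = GatingNetwork(rng, config.d_z + 1, config.K,
                           hidden=config.gate_hidden, tau=config.tau)
    d_expert = 1 if config.expert_inputs == "t" else config.d_z + 1
    experts = [ExpertNetwork(rng, d_expert, len(gene_names),
                             hidden=config.expert_hidden,
                             out_scale=float(meta.get("rate_scale", 1.0)))
               for _ in range(config.K)]
    arrays = np.load(path / "params.npz")

    def load(mod, prefix):
        keys = sorted((k for k in arrays.files if k.startswith(prefix + "_")
                       and k[len(prefix) + 1:].isdigit()),
                      key=lambda k: int(k.rsplit("_", 1)[1]))
        mod.load_state_arrays([arrays[k] for k in keys])

    load(gaae, "gaae")
    load(time_enc, "time")
    load(gating, "gating")
    for k, ex in enumerate(experts):
        load(ex, f"expert{k}")
    return SteerModel(
        config=config,
        gene_names=gene_names,
        hvg_names=hvg_names,
        gaae=gaae,
        time_encoder=time_enc,
        gating=gating,
        experts=experts,
        flip_time=bool(meta["flip_time"]),
        coarse_groups=np.array([]),
        stage_flags=(True, True, True),
    )
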