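"""Per-cell single-sample gene set scoring functions and the full pipeline.

Each scoring function maps one (smoothed) expression profile and a gene set
to a single number.  Rank-based scores (singscore, ssGSEA, rank-biased
overlap, summed_up) see only the ordering of genes within a cell, which
makes them invariant to any strictly monotone transform of expression;
value-based scores (average, median, mean z) see the values themselves.
Ties always receive the average of their positions, so every score is
invariant to the input order of genes.

Directionality: a two-part set scores its down-genes in opposition to its
up-genes — by subtraction (ssGSEA, summed_up, average, median, mean z) or
by re-scoring the down half against the reversed ranking (singscore,
rank-biased overlap).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .datamodel import ExpressionDataset, GeneSet
from .geneset_io import RestrictedSet, restrict_to_universe
from .grouping import MIN_SMOOTH_GROUP_SIZE, split_by_groupby
from .neighbors import (
    binary_adjacency,
    build_knn,
    embed_cells,
    gaussian_connectivities,
    identity_adjacency,
)
from .smoothing import smooth_counts

__all__ = [
    "METHODS",
    "RankedProfile",
    "rank_profile",
    "score_summed_up",
    "score_average",
    "score_median",
    "score_mean_z",
    "score_geneset_overlap",
    "score_singscore",
    "score_ssgsea",
    "score_rbo",
    "score_cells",
    "ScoreResult",
    "auc_separation",
]

logger = logging.getLogger(__name__)

#: Methods whose scale sensitivity makes the row-mean smoothing variant the
#: sensible default (rank-based methods are unaffected by a global row scale).
SCALE_SENSITIVE_METHODS = frozenset({"average_score", "median_score", "mean_z_score"})

METHODS = (
    "singscore",
    "ssgsea",
    "rank_biased_overlap",
    "mean_z_score",
    "average_score",
    "median_score",
    "summed_up",
    "geneset_overlap",
)


# ---------------------------------------------------------------------------
# Ranked profiles


@dataclass
class RankedProfile:
    """One cell's expression vector with ascending average-tie ranks.

    Rank 1 is the lowest expression; tied values share the average of the
    positions they span, so the rank sum is always N(N+1)/2.
    """

    gene_ids: list[str]
    values: np.ndarray
    ranks: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array(sorted(pos[g] for g in genes if g in pos), dtype=int)


def rank_profile(values, gene_ids=None) -> RankedProfile:
    """Rank one expression vector ascending with average-tie handling."""
    values = np.asarray(values, dtype=float).ravel()
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.size)]
    return RankedProfile(list(gene_ids), values, rankdata(values, method="average"))


# ---------------------------------------------------------------------------
# Batch scorers: V is (cells x genes) dense, R its ascending rank matrix.


def _batch_summed_up(R, up, dn):
    s = np.zeros(R.shape[0])
    if up.size:
        s += R[:, up].sum(axis=1)
    if dn.size:
        s -= R[:, dn].sum(axis=1)
    return s


def _batch_average(V, up, dn, stat=np.mean):
    s = np.zeros(V.shape[0])
    if up.size:
        s += stat(V[:, up], axis=1)
    if dn.size:
        s -= stat(V[:, dn], axis=1)
    return s


def _batch_mean_z(V, up, dn, gene_mean, gene_sd):
    ok = gene_sd > 0
    s = np.zeros(V.shape[0])
    any_term = False
    for idx, sign in ((up, 1.0), (dn, -1.0)):
        if idx.size == 0:
            continue
        keep = idx[ok[idx]]
        if keep.size == 0:
            continue
        any_term = True
        z = (V[:, keep] - gene_mean[keep]) / gene_sd[keep]
        s += sign * z.mean(axis=1)
    return s if any_term else np.full(V.shape[0], np.nan)


def _batch_overlap(V, members, threshold, as_fraction):
    counts = (V[:, members] > threshold).sum(axis=1).astype(float)
    return counts / members.size if as_fraction else counts


def _singscore_centered(R, idx, reverse):
    """Normalized mean-rank score for one direction, centered to [-0.5, 0.5]."""
    N = R.shape[1]
    n = idx.size
    if n == N:
        warnings.warn("gene set covers every measured gene: singscore degenerate, 0")
        return np.zeros(R.shape[0])
    ranks = (N + 1 - R) if reverse else R
    mean_rank = ranks[:, idx].mean(axis=1)
    return (mean_rank - (n + 1) / 2) / (N - n) - 0.5


def _batch_singscore(R, up, dn):
    s = np.zeros(R.shape[0])
    if up.size:
        s += _singscore_centered(R, up, reverse=False)
    if dn.size:
        s += _singscore_centered(R, dn, reverse=True)
    return s


def _desc_order(V):
    # stable: ties fall back to the lower gene index, deterministically
    return np.argsort(-V, axis=1, kind="stable")


def _ssgsea_direction(V, idx, alpha, order=None):
    n_cells, N = V.shape
    n = idx.size
    if n == 0 or n == N:
        return np.full(n_cells, np.nan)
    if order is None:
        order = _desc_order(V)
    member = np.zeros(N, dtype=bool)
    member[idx] = True
    member_sorted = member[order]  # (cells, N) membership along the ranking
    pos_weight = (N - np.arange(N)).astype(float) ** alpha  # |N - pos + 1|^alpha
    hit = member_sorted * pos_weight
    p_hit = np.cumsum(hit, axis=1) / hit.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~member_sorted, axis=1) / (N - n)
    return (p_hit - p_miss).sum(axis=1)


def _batch_ssgsea(V, up, dn, alpha):
    order = _desc_order(V)
    if up.size and dn.size:
        return _ssgsea_direction(V, up, alpha, order) - _ssgsea_direction(V, dn, alpha, order)
    if up.size:
        return _ssgsea_direction(V, up, alpha, order)
    return -_ssgsea_direction(V, dn, alpha, order)


def _rbo_direction(V, idx, p, depth, order):
    n_cells, N = V.shape
    n = idx.size
    if n == 0:
        return np.full(n_cells, np.nan)
    D = min(depth if depth is not None else n, N)
    member = np.zeros(N, dtype=bool)
    member[idx] = True
    hits = member[order[:, :D]]
    agreement = np.cumsum(hits, axis=1) / np.arange(1, D + 1)
    wts = p ** np.arange(D)
    return (agreement @ wts) / wts.sum()


def _batch_rbo(V, up, dn, p, depth):
    # both halves are scored against the same descending ranking and
    # subtracted, so swapping up and down negates the score exactly
    order = _desc_order(V)
    s = np.zeros(V.shape[0])
    if up.size:
        s += _rbo_direction(V, up, p, depth, order)
    if dn.size:
        s -= _rbo_direction(V, dn, p, depth, order)
    return s


# ---------------------------------------------------------------------------
# Per-profile wrappers (the single-cell view of the batch scorers)


def _split_idx(p: RankedProfile, gs: GeneSet):
    return p.index_of(gs.up_genes), p.index_of(gs.down_genes)


def score_summed_up(p: RankedProfile, gs: GeneSet) -> float:
    """Sum of ranks of up-genes minus sum of ranks of down-genes."""
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_summed_up(p.ranks[None, :], up, dn)[0])


def score_average(p: RankedProfile, gs: GeneSet) -> float:
    """Mean expression over up-genes minus mean over down-genes."""
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_average(p.values[None, :], up, dn, stat=np.mean)[0])


def score_median(p: RankedProfile, gs: GeneSet) -> float:
    """Median expression over up-genes minus median over down-genes."""
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_average(p.values[None, :], up, dn, stat=np.median)[0])


def score_mean_z(p: RankedProfile, gs: GeneSet, gene_mean, gene_sd) -> float:
    """Mean z-score of up-genes minus that of down-genes.

    ``gene_mean`` / ``gene_sd`` are per-gene statistics across the scored
    population; genes with zero standard deviation are excluded.
    """
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(
        _batch_mean_z(
            p.values[None, :], up, dn, np.asarray(gene_mean, float), np.asarray(gene_sd, float)
        )[0]
    )


def score_geneset_overlap(
    p: RankedProfile, gs: GeneSet, threshold: float = 0.0, as_fraction: bool = False
) -> float:
    """How many set genes are expressed above ``threshold`` in this cell."""
    members = p.index_of(gs.all_genes)
    if not members.size:
        return float("nan")
    return float(_batch_overlap(p.values[None, :], members, threshold, as_fraction)[0])


def score_singscore(p: RankedProfile, gs: GeneSet) -> float:
    """Normalized mean-rank score (bounded, direction-aware).

    The up-score is the mean rank of the up-genes rescaled to [0, 1] by its
    attainable extremes; down-genes are scored the same way against the
    reversed ranking.  Two-part totals lie in [-1, 1]; one-directional sets
    report the centered score in [-0.5, 0.5].
    """
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_singscore(p.ranks[None, :], up, dn)[0])


def score_ssgsea(p: RankedProfile, gs: GeneSet, alpha: float = 0.75) -> float:
    """Single-sample GSEA: integrated weighted running-sum statistic.

    Genes are walked in decreasing expression order; in-set genes step the
    running sum up by their normalized rank weight ``(N - pos + 1)^alpha``,
    out-of-set genes step it down by ``1/(N - n)``; the score integrates the
    running sum over all N positions.  Two-part sets score up minus down on
    the same ordering.
    """
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_ssgsea(p.values[None, :], up, dn, alpha)[0])


def score_rbo(
    p: RankedProfile, gs: GeneSet, persistence: float = 0.9, depth: int | None = None
) -> float:
    """Rank-biased overlap between the cell's top genes and the set.

    Agreement at depth d is the fraction of the top-d genes that belong to
    the set; depths are weighted geometrically by ``persistence`` and the
    sum is normalized so a perfect prefix scores exactly 1.  The default
    depth is the measured set size.  Down-genes are scored against the same
    descending ranking and subtracted, penalizing cells that still express
    their supposedly suppressed genes.
    """
    up, dn = _split_idx(p, gs)
    if not up.size and not dn.size:
        return float("nan")
    return float(_batch_rbo(p.values[None, :], up, dn, persistence, depth)[0])


# ---------------------------------------------------------------------------
# Separation metric


def auc_separation(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive cell outscores random negative).

    Computed as U/(n1*n0) from average ranks, which applies the standard tie
    correction; constant scores therefore give exactly 0.5.  Cells with
    missing scores are dropped; degenerate inputs (one class empty) return
    0.5 rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        return 0.5
    r = rankdata(scores, method="average")
    u = r[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# The full pipeline


@dataclass
class ScoreResult:
    """Scores plus a machine-readable report of how they were produced."""

    scores: pd.DataFrame
    report: dict = field(default_factory=dict)


def _batch_scores(method, V, R, rset, params, stats):
    gs = rset.geneset
    up = np.asarray(sorted(params["col_of"][g] for g in gs.up_genes), dtype=int)
    dn = np.asarray(sorted(params["col_of"][g] for g in gs.down_genes), dtype=int)
    if method == "summed_up":
        return _batch_summed_up(R, up, dn)
    if method == "singscore":
        return _batch_singscore(R, up, dn)
    if method == "ssgsea":
        return _batch_ssgsea(V, up, dn, params["alpha"])
    if method == "rank_biased_overlap":
        return _batch_rbo(V, up, dn, params["rbo_p"], params["rbo_depth"])
    if method == "average_score":
        return _batch_average(V, up, dn, stat=np.mean)
    if method == "median_score":
        return _batch_average(V, up, dn, stat=np.median)
    if method == "mean_z_score":
        return _batch_mean_z(V, up, dn, stats[0], stats[1])
    if method == "geneset_overlap":
        members = np.union1d(up, dn)
        return _batch_overlap(V, members, params["threshold"], params["as_fraction"])
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _group_smoothed(X_g, smooth_mode, knn, n_components, seed, row_normalize, report):
    """Smoothed matrix for one group, or X itself when smoothing is off."""
    n_g = X_g.shape[0]
    if smooth_mode == "off" or knn == 0 or n_g == 1:
        report["K_used"] = 0
        return X_g
    K_eff = min(knn, n_g - 1)
    if n_g < 3:
        # too few cells to embed: all-pairs graph on raw profiles
        emb = np.asarray(X_g.todense())
        report.setdefault("notes", []).append("group < 3 cells: all-pairs graph, no embedding")
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = embed_cells(X_g, n_components=n_components, seed=seed)
        except ValueError as exc:
            report.setdefault("notes", []).append(f"embedding failed ({exc}); smoothing skipped")
            report["K_used"] = 0
            return X_g
    g = build_knn(emb, K_eff, seed=seed)
    A = binary_adjacency(g) if smooth_mode == "binary" else gaussian_connectivities(g)
    report["K_used"] = K_eff
    return smooth_counts(A, X_g, row_normalize=row_normalize).M


def score_cells(
    ds: ExpressionDataset,
    genesets,
    method: str = "singscore",
    *,
    groupby: list[str] | None = None,
    smooth_mode: str = "connectivity",
    knn: int = 32,
    n_components: int = 50,
    row_normalize: str = "auto",
    min_group_size: int = MIN_SMOOTH_GROUP_SIZE,
    seed: int = 0,
    case_insensitive: bool = False,
    alpha: float = 0.75,
    rbo_p: float = 0.9,
    rbo_depth: int | None = None,
    threshold: float = 0.0,
    as_fraction: bool = False,
    append_to_annotations: bool = True,
) -> ScoreResult:
    """Run the full per-group pipeline and score every cell against each set.

    Per group: restrict sets to the measured universe, embed, build the KNN
    graph, form the adjacency (``smooth_mode`` in binary/connectivity/off),
    smooth ``M = A X``, and apply the chosen scoring function.  Groups below
    ``min_group_size`` are scored unsmoothed and flagged; a failing group
    yields missing values without affecting the others.  Row normalization
    ``auto`` uses the row-mean variant for scale-sensitive methods
    (average/median/mean z) and plain sums otherwise.

    Returns the score table (one column per gene set, named
    ``<set>__<method>``) and a report with effective parameters and
    per-group diagnostics; columns are also appended to
    ``ds.cell_annotations`` unless disabled.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if smooth_mode not in ("binary", "connectivity", "off"):
        raise ValueError(f"unknown smooth_mode {smooth_mode!r}")
    if isinstance(genesets, GeneSet):
        genesets = [genesets]
    if not genesets:
        raise ValueError("no gene sets supplied")

    restricted = [
        gs if isinstance(gs, RestrictedSet) else restrict_to_universe(gs, ds.gene_ids, case_insensitive)
        for gs in genesets
    ]
    col_of = {g: i for i, g in enumerate(ds.gene_ids)}
    row_norm_flag = (row_normalize == "mean") or (
        row_normalize == "auto" and method in SCALE_SENSITIVE_METHODS
    )
    if row_normalize not in ("auto", "sum", "mean"):
        raise ValueError(f"unknown row_normalize {row_normalize!r}")
    params = {
        "col_of": col_of,
        "alpha": alpha,
        "rbo_p": rbo_p,
        "rbo_depth": rbo_depth,
        "threshold": threshold,
        "as_fraction": as_fraction,
    }

    groups = split_by_groupby(ds, groupby)
    group_reports: list[dict] = []
    smoothed: list = []
    for key, idx in groups:
        rep = {"key": key, "size": int(len(idx)), "error": None}
        allow = len(idx) >= min_group_size
        if not allow:
            rep.setdefault("notes", []).append(
                f"group below minimum size {min_group_size}: smoothing forced off"
            )
        X_g = ds.counts[idx].astype(float)
        try:
            M_g = _group_smoothed(
                X_g,
                smooth_mode if allow else "off",
                knn,
                n_components,
                seed,
                row_norm_flag,
                rep,
            )
        except Exception as exc:  # per-group isolation
            rep["error"] = f"{type(exc).__name__}: {exc}"
            logger.error("group %s failed: %s", key, rep["error"])
            M_g = None
        smoothed.append((idx, M_g))
        group_reports.append(rep)

    stats = (None, None)
    if method == "mean_z_score":
        ok = [M for _, M in smoothed if M is not None]
        if ok:
            full = sp.vstack([sp.csr_matrix(M) for M in ok])
            mean = np.asarray(full.mean(axis=0)).ravel()
            sq = np.asarray(full.multiply(full).mean(axis=0)).ravel()
            stats = (mean, np.sqrt(np.maximum(sq - mean**2, 0.0)))

    columns = [f"{r.name}__{method}" for r in restricted]
    out = np.full((ds.n_cells, len(restricted)), np.nan)
    for (idx, M_g), rep in zip(smoothed, group_reports):
        if M_g is None:
            continue
        V = np.asarray(sp.csr_matrix(M_g).todense())
        R = rankdata(V, method="average", axis=1)
        try:
            for j, rset in enumerate(restricted):
                if not rset.scorable:
                    continue
                out[idx, j] = _batch_scores(method, V, R, rset, params, stats)
        except Exception as exc:
            rep["error"] = f"{type(exc).__name__}: {exc}"
            logger.error("group %s scoring failed: %s", rep["key"], rep["error"])
            out[idx, :] = np.nan

    scores = pd.DataFrame(out, index=pd.Index(ds.cell_ids, name="cell_id"), columns=columns)
    if append_to_annotations:
        for c in columns:
            ds.cell_annotations[c] = scores[c]
    report = {
        "method": method,
        "smooth_mode": smooth_mode,
        "knn": knn,
        "n_components": n_components,
        "row_normalize": "mean" if row_norm_flag else "sum",
        "groupby": list(groupby) if groupby else [],
        "min_group_size": min_group_size,
        "seed": seed,
        "method_params": {
            "alpha": alpha,
            "rbo_p": rbo_p,
            "rbo_depth": rbo_depth,
            "threshold": threshold,
            "as_fraction": as_fraction,
        },
        "groups": group_reports,
        "gene_sets": [
            {"name": r.name, "coverage": r.coverage, "scorable": r.scorable} for r in restricted
        ],
        "n_failed_groups": sum(1 for r in group_reports if r["error"]),
    }
    return ScoreResult(scores, report)
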