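"""Co-expression module detection around eGenes.

Per tissue the workflow is: (1) collect the eGenes plus every gene whose
Spearman correlation with at least one eGene reaches |rho| >= 0.90;
(2) cluster that gene set hierarchically (average linkage) on the
correlation distance 1 - rho; (3) choose the number of modules with the
gap statistic under the globalSEmax rule, comparing observed within-module
dispersion to reference datasets drawn uniformly over the feature ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix
from .errors import InputError

GAP_RULES = ("globalSEmax", "firstSEmax", "globalmax")


@dataclass
class GapCurve:
    """Gap(k) and its simulation error s_k over k = 1..Kmax."""

    k_values: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    B: int
    selected_k: int = 0
    rule: str = "globalSEmax"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "gap": self.gap, "se": self.se})


@dataclass
class ModuleSet:
    """Gene-to-module assignment for one tissue plus selection diagnostics."""

    tissue_id: str
    assignment: dict[str, int]
    n_modules: int
    egenes_per_module: dict[int, list[str]]
    dendrogram: np.ndarray = field(repr=False)
    gap: GapCurve | None = None

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module]

    def as_frame(self) -> pd.DataFrame:
        egene_lookup = {
            g for genes in self.egenes_per_module.values() for g in genes
        }
        rows = [
            (self.tissue_id, g, m, g in egene_lookup)
            for g, m in self.assignment.items()
        ]
        return pd.DataFrame(rows, columns=["tissue_id", "gene_id", "module", "is_egene"])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average-rank ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need two equal-length vectors with >= 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise InputError("Spearman correlation undefined for a constant vector")
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Column-wise mid-ranks centred and scaled to unit norm (constant
    columns become NaN so their correlations propagate as NaN)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.linalg.norm(ranks, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return ranks / norms


def coexpression_set(
    expr: ExpressionMatrix,
    egenes: list[str],
    rho_min: float = 0.90,
    signed: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """eGenes plus genes co-expressed with at least one eGene.

    A gene joins the set when |rho| >= rho_min with some eGene (Spearman);
    with ``signed=True`` the literal one-sided reading rho >= rho_min is
    applied instead.  Returns the selected genes (expression-matrix order)
    and their Spearman correlation matrix.
    """
    present = [g for g in egenes if g in expr.values.columns]
    if not present:
        raise InputError("none of the eGenes are present in the expression matrix")
    Z = _rank_standardize(expr.values.to_numpy(dtype=float))
    cols = {g: i for i, g in enumerate(expr.gene_ids)}
    e_idx = [cols[g] for g in present]
    C = Z[:, e_idx].T @ Z  # eGenes x all genes Spearman correlations
    with np.errstate(invalid="ignore"):
        strength = C.max(axis=0) if signed else np.abs(C).max(axis=0)
    selected_mask = strength >= rho_min
    for i in e_idx:
        selected_mask[i] = True
    selected = [g for g in expr.gene_ids if selected_mask[cols[g]]]
    s_idx = [cols[g] for g in selected]
    corr = pd.DataFrame(Z[:, s_idx].T @ Z[:, s_idx], index=selected, columns=selected)
    np.fill_diagonal(corr.values, 1.0)
    return selected, corr


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _cut_to_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into exactly k clusters, labels 1..k contiguous in
    order of first appearance (stable under relabeling)."""
    raw = cut_tree(Z, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[i] = relabel[lab]
    return out


def cluster_genes(corr: pd.DataFrame, K: int) -> dict[str, int]:
    """Average-linkage agglomerative clustering on distance 1 - rho, cut to
    exactly K modules.  Returns gene -> module index (1..K)."""
    genes = list(corr.index)
    n = len(genes)
    if not 1 <= K <= n:
        raise InputError(f"K must lie in 1..{n}")
    M = corr.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise InputError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-8):
        raise InputError("correlation matrix must have unit diagonal")
    D = 1.0 - (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    if n == 1:
        return {genes[0]: 1}
    Z = linkage(squareform(D, checks=False), method="average")
    labels = _cut_to_k(Z, K)
    return dict(zip(genes, labels))


def linkage_from_corr(corr: pd.DataFrame) -> np.ndarray:
    M = corr.to_numpy(dtype=float)
    D = 1.0 - (M + M.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of pairwise squared Euclidean
    distances) / (2 * cluster size) — equivalently the within-cluster sum
    of squares around centroids."""
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        centroid = pts.mean(axis=0)
        total += float(((pts - centroid) ** 2).sum())
    return total


def _hierarchical_labels(X: np.ndarray, kmax: int) -> list[np.ndarray]:
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return [_cut_to_k(Z, k) for k in range(1, kmax + 1)]


def gap_statistic(
    data: np.ndarray | pd.DataFrame,
    kmax: int | None = None,
    B: int = 100,
    seed: int = 0,
    rule: str = "globalSEmax",
) -> GapCurve:
    """Gap statistic over k = 1..kmax for hierarchically clustered rows.

    Gap(k) = mean_b log W*_kb - log W_k with W the within-cluster
    dispersion; the B reference datasets are drawn uniformly over the
    observed per-feature ranges and clustered with the same average-linkage
    routine.  s_k = sd_b(log W*_kb) * sqrt(1 + 1/B).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("gap statistic needs a 2-D matrix with >= 2 rows")
    if np.ptp(X, axis=0).max() == 0:
        raise InputError("degenerate data: all observations identical")
    n = X.shape[0]
    if kmax is None:
        kmax = min(10, n - 1)
    if not 1 <= kmax <= n:
        raise InputError(f"kmax must lie in 1..{n}")
    if B < 1:
        raise InputError("B must be >= 1")
    if rule not in GAP_RULES:
        raise InputError(f"unknown selection rule {rule!r}")
    rng = np.random.default_rng(seed)
    log_w_obs = np.array(
        [np.log(max(_within_dispersion(X, lab), np.finfo(float).tiny))
         for lab in _hierarchical_labels(X, kmax)]
    )
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    log_w_ref = np.empty((B, kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k_idx, lab in enumerate(_hierarchical_labels(ref, kmax)):
            log_w_ref[b, k_idx] = np.log(max(_within_dispersion(ref, lab), np.finfo(float).tiny))
    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B) if B > 1 else np.zeros(kmax)
    curve = GapCurve(
        k_values=np.arange(1, kmax + 1), gap=gap, se=se, B=B, rule=rule
    )
    curve.selected_k = select_k(curve, rule)
    return curve


def select_k_globalSEmax(curve: GapCurve) -> int:
    """Smallest k with Gap(k) >= Gap(k_gm) - s_{k_gm}, k_gm the global max."""
    if curve.gap.size == 0:
        raise InputError("empty gap curve")
    k_gm = int(np.argmax(curve.gap))
    threshold = curve.gap[k_gm] - curve.se[k_gm]
    for i, g in enumerate(curve.gap):
        if g >= threshold:
            return int(curve.k_values[i])
    return int(curve.k_values[k_gm])


def select_k(curve: GapCurve, rule: str = "globalSEmax") -> int:
    if rule == "globalSEmax":
        return select_k_globalSEmax(curve)
    if rule == "globalmax":
        return int(curve.k_values[int(np.argmax(curve.gap))])
    if rule == "firstSEmax":
        g = curve.gap
        local = next(
            (i for i in range(len(g)) if (i == len(g) - 1) or g[i] >= g[i + 1]),
            len(g) - 1,
        )
        threshold = g[local] - curve.se[local]
        for i in range(local + 1):
            if g[i] >= threshold:
                return int(curve.k_values[i])
        return int(curve.k_values[local])
    raise InputError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# per-tissue orchestration
# ---------------------------------------------------------------------------

def detect_modules(
    expr: ExpressionMatrix,
    egenes: list[str],
    rho_min: float = 0.90,
    kmax: int | None = None,
    B: int = 100,
    seed: int = 0,
    signed: bool = False,
    rule: str = "globalSEmax",
) -> ModuleSet:
    """Full per-tissue module detection: co-expression set, gap-statistic
    model selection on the gene expression profiles, final cut on
    correlation distance."""
    selected, corr = coexpression_set(expr, egenes, rho_min=rho_min, signed=signed)
    if len(selected) == 1:
        assignment = {selected[0]: 1}
        curve = None
        n_modules = 1
        dendrogram = np.empty((0, 4))
    else:
        profiles = expr.values[selected].to_numpy(dtype=float).T  # genes x samples
        if kmax is None:
            kmax = 10
        # k = n is degenerate (zero dispersion on both data and reference)
        kmax = min(kmax, len(selected) - 1)
        curve = gap_statistic(profiles, kmax=kmax, B=B, seed=seed, rule=rule)
        n_modules = curve.selected_k
        assignment = cluster_genes(corr, n_modules)
        dendrogram = linkage_from_corr(corr)
    egene_set = {g for g in egenes if g in assignment}
    egenes_per_module: dict[int, list[str]] = {m: [] for m in range(1, n_modules + 1)}
    for g in egene_set:
        egenes_per_module[assignment[g]].append(g)
    for m in egenes_per_module:
        egenes_per_module[m].sort()
    return ModuleSet(
        tissue_id=expr.tissue_id,
        assignment=assignment,
        n_modules=n_modules,
        egenes_per_module=egenes_per_module,
        dendrogram=dendrogram,
        gap=curve,
    )
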