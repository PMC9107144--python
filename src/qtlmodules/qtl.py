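"""Additive-model cis/trans QTL mapping with permutation-based empirical
significance.

The mapping model is ordinary least squares of expression on allele dosage
with an intercept (slope = the normalized effect size for the effect
allele).  Per-gene significance follows the empirical-permutation scheme:
expression is permuted across samples B times, the minimum nominal p over
the gene's cis variants is recorded per permutation, and the empirical p is
the +1-corrected rank of the observed minimum.  Gene-level discoveries are
controlled with Benjamini-Hochberg on the empirical p-values; the boundary
gene (the rejected gene closest to the FDR threshold) sets the probability
level at which each eGene's permutation null is cut into a per-gene nominal
p threshold for calling individual variant-gene pairs significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenotypeMatrix, SummaryStatSet
from .errors import InputError, MonomorphicVariantError

logger = logging.getLogger(__name__)

QTL_COLUMNS = ["variant_id", "gene_id", "tissue_id", "beta", "se", "p_nominal", "df", "kind"]

_P_FLOOR = np.finfo(float).tiny  # p never exactly 0 even when se underflows


@dataclass
class QtlRecord:
    """One variant-gene-tissue association under the additive model."""

    variant_id: str
    gene_id: str
    tissue_id: str
    beta: float
    se: float
    p_nominal: float
    df: int
    kind: str = "cis"
    significant: bool | None = None


@dataclass
class GeneEmpirical:
    """Permutation summary for one gene in one tissue."""

    gene_id: str
    tissue_id: str
    p_min_observed: float
    empirical_p: float
    perm_min_ps: np.ndarray = field(repr=False)
    nominal_threshold: float | None = None

    @property
    def summary(self) -> dict[str, float]:
        qs = np.quantile(self.perm_min_ps, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "count": float(self.perm_min_ps.size),
            "q0": qs[0], "q25": qs[1], "q50": qs[2], "q75": qs[3], "q100": qs[4],
        }


# ---------------------------------------------------------------------------
# core OLS
# ---------------------------------------------------------------------------

def ols_scan(G: np.ndarray, y: np.ndarray):
    """OLS slope/se/p of y on each column of G (with intercept), vectorized.

    Missing dosages are handled by pairwise-complete deletion.  Columns with
    zero variance yield NaN results (callers decide whether to error or
    drop).  Returns (beta, se, p, df) arrays, df = n_complete - 2.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[0] != y.shape[0]:
        raise InputError("dosage and expression lengths differ")
    if np.isnan(G).any() or np.isnan(y).any():
        return _ols_scan_pairwise(G, y)
    n = G.shape[0]
    if n < 3:
        raise InputError("need at least 3 paired observations")
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc * Gc).sum(axis=0)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(sse / df / sxx)
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR, 1.0)
    bad = sxx <= 0
    beta[bad] = se[bad] = p[bad] = np.nan
    return beta, se, p, np.full(G.shape[1], df)


def _ols_scan_pairwise(G: np.ndarray, y: np.ndarray):
    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    df = np.zeros(m, dtype=int)
    for j in range(m):
        mask = ~(np.isnan(G[:, j]) | np.isnan(y))
        if mask.sum() < 3:
            continue
        b, s, pv, d = ols_scan(G[mask, j][:, None], y[mask])
        beta[j], se[j], p[j], df[j] = b[0], s[0], pv[0], d[0]
    return beta, se, p, df


def fit_additive(dosage: np.ndarray, expr: np.ndarray) -> tuple[float, float, float, int]:
    """Single-pair additive fit; raises on degenerate input.

    Returns (beta, se, p_nominal, df).
    """
    dosage = np.asarray(dosage, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if dosage.shape != expr.shape:
        raise InputError("dosage and expression lengths differ")
    mask = ~(np.isnan(dosage) | np.isnan(expr))
    if mask.sum() < 3:
        raise InputError("need at least 3 paired observations")
    d, e = dosage[mask], expr[mask]
    if np.var(d) == 0:
        raise MonomorphicVariantError("dosage vector has zero variance")
    beta, se, p, df = ols_scan(d[:, None], e)
    return float(beta[0]), float(se[0]), float(p[0]), int(df[0])


# ---------------------------------------------------------------------------
# cis / trans scans
# ---------------------------------------------------------------------------

def _shared_samples(geno: GenotypeMatrix, expr: ExpressionMatrix) -> pd.Index:
    shared = geno.dosages.index.intersection(expr.values.index)
    if len(shared) < 3:
        raise InputError("fewer than 3 samples shared between genotypes and expression")
    return shared


def cis_variants(
    geno: GenotypeMatrix, genes: pd.DataFrame, gene_id: str, window_bp: int
) -> list[str]:
    """Variants on the gene's chromosome with |pos - tss| <= window_bp."""
    if gene_id not in genes.index:
        raise InputError(f"gene {gene_id!r} missing from annotation")
    chrom, tss = genes.loc[gene_id, "chrom"], int(genes.loc[gene_id, "tss"])
    v = geno.variants
    mask = (v["chrom"] == chrom) & ((v["pos"] - tss).abs() <= window_bp)
    return list(v.index[mask])


def map_cis(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Test every variant against every gene whose TSS lies within
    window_bp on the same chromosome.  Returns a QTL table (one row per
    tested pair); monomorphic variants are dropped with a log message."""
    shared = _shared_samples(geno, expr)
    dosages = geno.dosages.loc[shared]
    values = expr.values.loc[shared]
    rows = []
    for gene_id in expr.gene_ids:
        if gene_id not in genes.index:
            continue
        vids = cis_variants(geno, genes, gene_id, window_bp)
        if not vids:
            continue
        G = dosages[vids].to_numpy(dtype=float)
        beta, se, p, df = ols_scan(G, values[gene_id].to_numpy(dtype=float))
        for k, vid in enumerate(vids):
            if np.isnan(beta[k]):
                logger.debug("dropping monomorphic variant %s for gene %s", vid, gene_id)
                continue
            rows.append((vid, gene_id, expr.tissue_id, beta[k], se[k], p[k], df[k], "cis"))
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


def map_trans(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: pd.DataFrame,
    interactions: pd.DataFrame,
    cis_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Test each variant against genes whose TSS falls inside the union of
    interaction target ranges anchored at the variant's locus.

    Only same-chromosome targets are tested (distant-but-same-chromosome
    convention) and genes already covered by the cis window are excluded.
    BEDPE coordinates are 0-based half-open; TSSs are 1-based.
    """
    shared = _shared_samples(geno, expr)
    dosages = geno.dosages.loc[shared]
    values = expr.values.loc[shared]
    rows = []
    if interactions.empty:
        return pd.DataFrame(rows, columns=QTL_COLUMNS)
    for vid, vrow in geno.variants.iterrows():
        pos0 = int(vrow["pos"]) - 1
        anchors = interactions[
            (interactions["chrom1"] == vrow["chrom"])
            & (interactions["start1"] <= pos0)
            & (pos0 < interactions["end1"])
        ]
        if anchors.empty:
            continue
        target_genes: list[str] = []
        for _, irow in anchors.iterrows():
            if irow["chrom2"] != vrow["chrom"]:
                continue  # inter-chromosomal targets are out of scope
            g = genes[
                (genes["chrom"] == irow["chrom2"])
                & (genes["tss"] - 1 >= irow["start2"])
                & (genes["tss"] - 1 < irow["end2"])
            ]
            target_genes.extend(g.index)
        for gene_id in sorted(set(target_genes)):
            if gene_id not in values.columns:
                continue
            if abs(int(genes.loc[gene_id, "tss"]) - int(vrow["pos"])) <= cis_window_bp:
                continue  # already tested in cis
            d = dosages[vid].to_numpy(dtype=float)
            beta, se, p, df = ols_scan(d[:, None], values[gene_id].to_numpy(dtype=float))
            if np.isnan(beta[0]):
                continue
            rows.append((vid, gene_id, expr.tissue_id, beta[0], se[0], p[0], df[0], "trans"))
    return pd.DataFrame(rows, columns=QTL_COLUMNS)


# ---------------------------------------------------------------------------
# permutation empirical p-values and the eGene threshold rule
# ---------------------------------------------------------------------------

def _min_p_from_corr(r: np.ndarray, df: int) -> np.ndarray:
    """Minimum two-sided p over variants from a (variants x draws) matrix of
    dosage-expression correlations; min-p corresponds to max |r| at common df."""
    rmax = np.minimum(np.max(np.abs(r), axis=0), 1.0 - 1e-15)
    t = rmax * np.sqrt(df / (1.0 - rmax**2))
    return np.clip(2.0 * stats.t.sf(t, df), _P_FLOOR, 1.0)


def empirical_gene_p(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: pd.DataFrame,
    gene_id: str,
    B: int = 1000,
    seed: int = 0,
    window_bp: int = 1_000_000,
) -> GeneEmpirical | None:
    """Permutation empirical p for one gene's best cis association.

    empirical_p = (1 + #{permutation min-p <= observed min-p}) / (B + 1).
    Genes with no (polymorphic) cis variants are skipped with a warning.
    """
    if B < 1:
        raise InputError("permutation count B must be >= 1")
    shared = _shared_samples(geno, expr)
    vids = cis_variants(geno, genes, gene_id, window_bp)
    G = geno.dosages.loc[shared, vids].to_numpy(dtype=float) if vids else np.empty((len(shared), 0))
    G = G[:, G.std(axis=0) > 0]
    if G.shape[1] == 0:
        logger.warning("gene %s has no polymorphic cis variants; skipped", gene_id)
        return None
    y = expr.values.loc[shared, gene_id].to_numpy(dtype=float)
    n = len(y)
    df = n - 2
    Gz = (G - G.mean(axis=0)) / np.linalg.norm(G - G.mean(axis=0), axis=0)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise InputError(f"gene {gene_id!r} has constant expression")
    yz = yc / ynorm
    p_obs = float(_min_p_from_corr((Gz.T @ yz)[:, None], df)[0])
    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(B)])
    Y = yz[perm_idx].T  # n x B, each column a permuted standardized y
    perm_min_ps = _min_p_from_corr(Gz.T @ Y, df)
    empirical = (1.0 + np.sum(perm_min_ps <= p_obs)) / (B + 1.0)
    return GeneEmpirical(
        gene_id=gene_id,
        tissue_id=expr.tissue_id,
        p_min_observed=p_obs,
        empirical_p=float(empirical),
        perm_min_ps=perm_min_ps,
    )


def egene_threshold(
    empiricals: list[GeneEmpirical], fdr: float = 0.05
) -> pd.DataFrame:
    """Benjamini-Hochberg on gene empirical p-values and per-eGene nominal
    thresholds.

    The boundary gene is the BH-rejected gene with the largest empirical p
    (the gene closest to the FDR threshold); its empirical p, p*, is the
    probability level at which each eGene's permutation min-p distribution
    is cut to give that gene's nominal threshold.  If nothing is rejected
    no eQTLs are called.  Returns a frame with is_egene and
    nominal_threshold columns; the boundary level is stored in
    ``frame.attrs['p_star']``.
    """
    if not empiricals:
        raise InputError("no gene empirical p-values supplied")
    emp_p = np.array([e.empirical_p for e in empiricals])
    reject, _, _, _ = multipletests(emp_p, alpha=fdr, method="fdr_bh")
    p_star = float(emp_p[reject].max()) if reject.any() else np.nan
    rows = []
    for e, rej in zip(empiricals, reject):
        threshold = float(np.quantile(e.perm_min_ps, p_star)) if rej else np.nan
        e.nominal_threshold = threshold if rej else None
        rows.append(
            (e.gene_id, e.tissue_id, e.p_min_observed, e.empirical_p, bool(rej), threshold)
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue_id", "p_min_observed", "empirical_p",
            "is_egene", "nominal_threshold",
        ],
    )
    frame.attrs["p_star"] = p_star
    return frame


def mark_significant(qtls: pd.DataFrame, egenes: pd.DataFrame) -> pd.DataFrame:
    """Flag variant-gene pairs: significant iff the gene is an eGene and the
    pair's nominal p is at or below the gene's nominal threshold."""
    merged = qtls.merge(
        egenes[["gene_id", "tissue_id", "is_egene", "nominal_threshold"]],
        on=["gene_id", "tissue_id"],
        how="left",
    )
    merged["is_egene"] = merged["is_egene"].astype("boolean").fillna(False).astype(bool)
    merged["significant"] = merged["is_egene"] & (
        merged["p_nominal"] <= merged["nominal_threshold"]
    )
    return merged.drop(columns=["is_egene"])


def filter_fixed_threshold(stats_set: SummaryStatSet, alpha: float = 5e-8) -> SummaryStatSet:
    """Retain records with p strictly below alpha (genome-wide significance
    convention for protein/metabolite QTLs)."""
    if "p" not in stats_set.table.columns:
        raise InputError("summary statistics lack a p column")
    kept = stats_set.table[stats_set.table["p"] < alpha].reset_index(drop=True)
    return SummaryStatSet(trait_id=stats_set.trait_id, table=kept)
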