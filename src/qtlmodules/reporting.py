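"""Cross-tissue synthesis of QTL and enrichment results.

Answers the sharing questions: in how many tissues is each eGene, each
eQTL-eGene pair and each enriched pathway detected, are effect directions
consistent across tissues, and which QTL modalities (expression, protein,
metabolite) does each lead variant belong to.
"""

from __future__ import annotations

from itertools import chain

import pandas as pd

SHARING_COLUMNS = ["entity_id", "tissues_detected", "n_tissues", "direction_consistent"]


def _sharing_frame(groups: dict[str, tuple[list[str], bool]]) -> pd.DataFrame:
    rows = [
        (entity, ",".join(tissues), len(tissues), consistent)
        for entity, (tissues, consistent) in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=SHARING_COLUMNS)


def summarize_sharing(
    qtls: pd.DataFrame,
    enrichments: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, object]:
    """Tissue-sharing summaries from a significance-flagged QTL table.

    Returns a dict with frames ``egenes``, ``pairs``, ``pathways`` (each
    entity, its tissues, tissue count and beta sign consistency) and a
    ``totals`` dict: distinct eQTL variants, distinct eGenes and
    (variant, gene, tissue) triples.
    """
    sig = qtls[qtls["significant"].fillna(False)] if "significant" in qtls.columns else qtls
    egene_groups: dict[str, tuple[list[str], bool]] = {}
    for gene, sub in sig.groupby("gene_id"):
        tissues = sorted(sub["tissue_id"].unique())
        consistent = bool((sub["beta"] > 0).all() or (sub["beta"] < 0).all())
        egene_groups[str(gene)] = (tissues, consistent)
    pair_groups: dict[str, tuple[list[str], bool]] = {}
    for (variant, gene), sub in sig.groupby(["variant_id", "gene_id"]):
        tissues = sorted(sub["tissue_id"].unique())
        consistent = bool((sub["beta"] > 0).all() or (sub["beta"] < 0).all())
        pair_groups[f"{variant}:{gene}"] = (tissues, consistent)
    pathway_groups: dict[str, tuple[list[str], bool]] = {}
    if enrichments is not None and not enrichments.empty:
        enriched = enrichments[enrichments["p_adj"] <= alpha]
        for pathway, sub in enriched.groupby("pathway"):
            tissues = sorted(sub["tissue_id"].unique())
            pathway_groups[str(pathway)] = (tissues, True)
    totals = {
        "n_eqtl_variants": int(sig["variant_id"].nunique()),
        "n_egenes": int(sig["gene_id"].nunique()),
        "n_pair_tissue_triples": int(
            sig[["variant_id", "gene_id", "tissue_id"]].drop_duplicates().shape[0]
        ),
    }
    return {
        "egenes": _sharing_frame(egene_groups),
        "pairs": _sharing_frame(pair_groups),
        "pathways": _sharing_frame(pathway_groups),
        "totals": totals,
    }


def qtl_overlap_classes(
    eqtl_variants: list[str],
    pqtl_variants: list[str],
    mqtl_variants: list[str],
) -> pd.DataFrame:
    """Label each variant with the QTL modalities it belongs to (Venn/upset
    membership).  Variants in no modality are excluded."""
    modalities = {
        "eQTL": set(eqtl_variants),
        "pQTL": set(pqtl_variants),
        "mQTL": set(mqtl_variants),
    }
    rows = []
    for variant in sorted(set(chain.from_iterable(modalities.values()))):
        member = [name for name, vs in modalities.items() if variant in vs]
        rows.append((variant, "+".join(member), len(member)))
    return pd.DataFrame(rows, columns=["variant_id", "qtl_class", "n_modalities"])
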