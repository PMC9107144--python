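"""Pathway over-representation of co-expression modules (Fisher's exact
test) and the module-retention filter.

Each (module, pathway) pair is summarized by the 2x2 table

                 in pathway   not in pathway
    in module        a              b
    not in module    c              d

over a configurable gene universe.  Odds ratio is the sample OR a*d/(b*c);
p-values are two-sided Fisher exact by default and Benjamini-Hochberg
adjusted within tissue.  A module is retained only when it contains at
least one eGene and is enriched for at least one pathway.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .modules import ModuleSet

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "tissue_id", "module", "pathway", "a", "b", "c", "d", "odds_ratio", "p", "p_adj",
]


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on a 2x2 table of counts.

    Returns (odds_ratio, p).  OR conventions: +inf when b*c = 0 and
    a*d > 0, 0 when a*d = 0 and b*c > 0, NaN when both products vanish.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise InputError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d < 1:
        raise InputError("table total must be >= 1")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return odds, float(min(max(p, np.finfo(float).tiny), 1.0))


def enrich_modules(
    modules: ModuleSet,
    catalog: dict[str, list[str]],
    universe: list[str],
    alternative: str = "two-sided",
    adjust: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of every (module, pathway) pair with >= 1 shared
    gene; BH adjustment across all tests within the tissue.

    Genes outside the universe are dropped (count logged).
    """
    uni = set(universe)
    if not uni:
        raise InputError("empty gene universe")
    rows = []
    for module in sorted({m for m in modules.assignment.values()}):
        mod_genes = {g for g, m in modules.assignment.items() if m == module}
        dropped = len(mod_genes - uni)
        if dropped:
            logger.info("module %d: %d genes outside universe dropped", module, dropped)
        mod_genes &= uni
        for pathway, genes in catalog.items():
            pw = set(genes) & uni
            if len(set(genes)) > len(pw):
                logger.info(
                    "pathway %s: %d genes outside universe dropped",
                    pathway, len(set(genes)) - len(pw),
                )
            a = len(mod_genes & pw)
            if a == 0:
                continue
            b = len(mod_genes) - a
            c = len(pw) - a
            d = len(uni) - a - b - c
            odds, p = fisher_exact(a, b, c, d, alternative=alternative)
            rows.append((modules.tissue_id, module, pathway, a, b, c, d, odds, p))
    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if frame.empty:
        frame["p_adj"] = pd.Series(dtype=float)
        return frame
    if adjust:
        frame["p_adj"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["p_adj"] = frame["p"]
    return frame


def filter_modules(
    modules: ModuleSet,
    enrichments: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> list[int]:
    """Module indices retained under the rule: keep a module only if it
    contains >= 1 eGene and has >= 1 pathway with (adjusted) p <= alpha."""
    pcol = "p_adj" if use_adjusted else "p"
    retained = []
    for module in range(1, modules.n_modules + 1):
        has_egene = bool(modules.egenes_per_module.get(module))
        sub = enrichments[enrichments["module"] == module]
        enriched = bool((sub[pcol] <= alpha).any()) if not sub.empty else False
        if has_egene and enriched:
            retained.append(module)
        else:
            reason = []
            if not has_egene:
                reason.append("no eGene")
            if not enriched:
                reason.append(f"no pathway at alpha={alpha}")
            logger.info(
                "tissue %s module %d dropped: %s",
                modules.tissue_id, module, "; ".join(reason),
            )
    return retained
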