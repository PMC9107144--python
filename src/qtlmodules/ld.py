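"""Pairwise linkage disequilibrium from dosages and lead-SNP proxy expansion.

LD is measured as the squared Pearson correlation of allele-dosage vectors
(phase-free, so no haplotype inference is needed); a variant is a proxy of
a lead SNP when r2 >= 0.80 within a window around the lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import InputError, MonomorphicVariantError


@dataclass
class LdExpansion:
    """A lead variant and its proxies (the lead itself included at r2=1)."""

    lead_variant_id: str
    proxies: list[tuple[str, float]]
    window_bp: int

    @property
    def proxy_ids(self) -> list[str]:
        return [vid for vid, _ in self.proxies]


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("dosage vectors differ in length")
    if a.size < 2:
        raise InputError("need at least 2 samples to compute r2")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0 or vb == 0:
        raise MonomorphicVariantError("r2 undefined for a monomorphic variant")
    cov = float(ac @ bc)
    return cov * cov / (va * vb)


def expand_leads(
    leads: list[str],
    geno: GenotypeMatrix,
    r2_min: float = 0.80,
    window_bp: int = 1_000_000,
) -> list[LdExpansion]:
    """For each lead, find same-chromosome variants within window_bp whose
    dosage r2 with the lead is >= r2_min.

    Proxies are sorted by descending r2, ties broken by position; the lead
    itself is always first with r2 = 1.  Monomorphic candidates are
    skipped; a monomorphic or absent lead raises.
    """
    if not 0.0 <= r2_min <= 1.0:
        raise InputError("r2_min must lie in [0, 1]")
    expansions = []
    variants = geno.variants
    D = geno.dosages.to_numpy(dtype=float)
    Dc = D - D.mean(axis=0)
    norms = np.linalg.norm(Dc, axis=0)
    col = {vid: j for j, vid in enumerate(geno.variant_ids)}
    for lead in leads:
        if lead not in col:
            raise InputError(f"lead variant {lead!r} not in genotype matrix")
        j = col[lead]
        if norms[j] == 0:
            raise MonomorphicVariantError(f"lead variant {lead!r} is monomorphic")
        chrom = variants.loc[lead, "chrom"]
        pos = int(variants.loc[lead, "pos"])
        in_window = (variants["chrom"] == chrom) & (
            (variants["pos"] - pos).abs() <= window_bp
        )
        cand = [col[v] for v in variants.index[in_window]]
        cand = [k for k in cand if norms[k] > 0]
        r = (Dc[:, cand].T @ Dc[:, j]) / (norms[cand] * norms[j])
        rsq = r * r
        pairs = []
        for k, value in zip(cand, rsq):
            vid = geno.variant_ids[k]
            if vid == lead:
                pairs.append((vid, 1.0))
            elif value >= r2_min:
                pairs.append((vid, float(value)))
        pairs.sort(key=lambda it: (-it[1], int(variants.loc[it[0], "pos"])))
        expansions.append(LdExpansion(lead_variant_id=lead, proxies=pairs, window_bp=window_bp))
    return expansions


def expansions_to_frame(expansions: list[LdExpansion]) -> pd.DataFrame:
    rows = [
        (e.lead_variant_id, vid, val)
        for e in expansions
        for vid, val in e.proxies
    ]
    return pd.DataFrame(rows, columns=["lead_variant_id", "proxy_variant_id", "r2"])
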