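"""Synthetic genotype-expression panels with planted, machine-readable truth.

The generator emulates the data regime of a multi-tissue eQTL resource:

* Hardy-Weinberg genotypes organised in LD blocks.  Within a block every
  variant is a per-haplotype copy of its left neighbour with a calibrated
  "recombination" flip probability, so the expected adjacent-pair dosage
  r-squared equals a target value; variants in different blocks are
  independent.
* Per-tissue expression built from latent co-expression module factors,
  additive allele-dosage eQTL effects and Gaussian noise, followed by a
  per-gene rank-based inverse-normal transform (disable-able for
  exact-recovery experiments).
* Disease/analyte summary statistics for colocalization scenarios in which
  two traits share, or do not share, a causal variant.
* GMT pathway catalogs that coincide with, partially overlap, or avoid the
  planted modules.

Everything is a pure function of (spec, seed): one master seed is split
into fixed, purpose-keyed child streams so that e.g. adding a tissue never
perturbs the genotypes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, SummaryStatSet
from .errors import SpecError

# Fixed spawn keys for child RNG streams (never reorder: determinism contract).
_STREAM_GENOTYPES = 0
_STREAM_EXPRESSION = 1  # sub-keyed by tissue index
_STREAM_SUMMARY = 2  # sub-keyed by scenario index
_STREAM_PATHWAYS = 3

POS_SPACING_BP = 10_000  # variant grid spacing on the synthetic chromosome
TRANS_OFFSET_BP = 3_000_000  # TSS offset placing a planted trans gene out of cis range
CIS_OFFSET_BP = 1_000  # TSS offset for a planted cis gene relative to its variant


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class PlantedEffect:
    """One planted additive eQTL: beta is the expression shift per copy of
    the effect allele, in pre-transform expression SD units."""

    variant_id: str
    gene_id: str
    tissue_ids: list[str]
    beta: float
    kind: str = "cis"  # cis | trans

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise SpecError("planted beta must be finite")
        if not self.tissue_ids:
            raise SpecError("planted effect needs at least one tissue")
        if self.kind not in ("cis", "trans"):
            raise SpecError(f"unknown effect kind {self.kind!r}")


@dataclass
class ColocScenario:
    """A region with 0-2 causal variants across two traits (hypotheses H0-H4)."""

    name: str
    region_variants: list[str]
    causal_variant_trait1: str | None = None
    causal_variant_trait2: str | None = None
    shared: bool = False
    beta1: float = 0.0
    beta2: float = 0.0
    n1: int = 1000
    n2: int = 1000
    trait2_kind: str = "protein"  # protein | metabolite (reporting modality)

    def __post_init__(self) -> None:
        if self.shared and self.causal_variant_trait1 != self.causal_variant_trait2:
            raise SpecError("shared scenario must name one common causal variant")
        for causal in (self.causal_variant_trait1, self.causal_variant_trait2):
            if causal is not None and causal not in self.region_variants:
                raise SpecError(f"causal variant {causal!r} outside region")
        if min(self.n1, self.n2) < 3:
            raise SpecError("scenario sample sizes must be >= 3")

    @property
    def hypothesis(self) -> str:
        c1, c2 = self.causal_variant_trait1, self.causal_variant_trait2
        if c1 is None and c2 is None:
            return "H0"
        if c2 is None:
            return "H1"
        if c1 is None:
            return "H2"
        return "H4" if c1 == c2 else "H3"


@dataclass
class PathwaySpec:
    """How one synthetic gene set relates to the planted modules.

    mode "module": exact copy of planted module ``module_index``;
    mode "partial": ``round(size*overlap)`` genes from the module, rest from
    outside it; mode "random": uniform draw from the universe.
    """

    name: str
    mode: str = "random"
    module_index: int = 0
    size: int = 20
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("module", "partial", "random"):
            raise SpecError(f"unknown pathway mode {self.mode!r}")


@dataclass
class SimulationSpec:
    """Full description of one synthetic study."""

    n_samples: int = 300
    n_variants: int = 50
    ld_block_size: int = 5
    within_block_r2: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_tissues: int = 2
    n_genes: int = 60
    n_modules: int = 2
    module_size: int = 15
    module_factor_sd: float = 2.0
    noise_sd: float = 1.0
    inverse_normal: bool = True
    planted_eqtls: list[PlantedEffect] = field(default_factory=list)
    coloc_scenarios: list[ColocScenario] = field(default_factory=list)
    pathways: list[PathwaySpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf_range = tuple(self.maf_range)  # type: ignore[assignment]
        self.validate()

    # -- naming ----------------------------------------------------------
    def variant_id(self, i: int) -> str:
        return f"v{i + 1:04d}"

    def gene_id(self, i: int) -> str:
        return f"g{i + 1:04d}"

    def tissue_id(self, i: int) -> str:
        return f"tissue{i + 1:02d}"

    @property
    def variant_ids(self) -> list[str]:
        return [self.variant_id(i) for i in range(self.n_variants)]

    @property
    def gene_ids(self) -> list[str]:
        return [self.gene_id(i) for i in range(self.n_genes)]

    @property
    def tissue_ids(self) -> list[str]:
        return [self.tissue_id(i) for i in range(self.n_tissues)]

    def module_assignment(self) -> dict[str, int]:
        """Planted module membership: modules 1..n_modules occupy consecutive
        leading gene blocks; unassigned genes are absent from the map."""
        out: dict[str, int] = {}
        for m in range(self.n_modules):
            for j in range(self.module_size):
                out[self.gene_id(m * self.module_size + j)] = m + 1
        return out

    def validate(self) -> None:
        if min(self.n_samples, self.n_variants, self.n_tissues, self.n_genes) <= 0:
            raise SpecError("all dimensions must be positive")
        if self.ld_block_size <= 0:
            raise SpecError("ld_block_size must be positive")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise SpecError("within_block_r2 must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_modules < 0 or self.module_size < 0:
            raise SpecError("module counts must be non-negative")
        if self.n_modules * self.module_size > self.n_genes:
            raise SpecError("n_modules * module_size exceeds n_genes")
        if self.module_factor_sd < 0:
            raise SpecError("module_factor_sd must be >= 0")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        variant_ids = set(self.variant_ids)
        gene_ids = set(self.gene_ids)
        tissue_ids = set(self.tissue_ids)
        for eff in self.planted_eqtls:
            if eff.variant_id not in variant_ids:
                raise SpecError(f"planted effect references unknown variant {eff.variant_id!r}")
            if eff.gene_id not in gene_ids:
                raise SpecError(f"planted effect references unknown gene {eff.gene_id!r}")
            unknown = set(eff.tissue_ids) - tissue_ids
            if unknown:
                raise SpecError(f"planted effect references unknown tissues {sorted(unknown)}")
        for sc in self.coloc_scenarios:
            if set(sc.region_variants) - variant_ids:
                raise SpecError(f"scenario {sc.name!r} references unknown variants")
            if max(sc.n1, sc.n2) > self.n_samples:
                raise SpecError(f"scenario {sc.name!r} needs more samples than simulated")
        for pw in self.pathways:
            if pw.size > self.n_genes:
                raise SpecError(f"pathway {pw.name!r} larger than the gene universe")
            if pw.mode in ("module", "partial") and not (
                1 <= pw.module_index <= self.n_modules
            ):
                raise SpecError(f"pathway {pw.name!r} references unknown module")


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    planted_eqtls: list[PlantedEffect]
    module_assignment: dict[str, int]
    scenario_labels: dict[str, str]
    variant_freqs: dict[str, float]
    pathway_overlaps: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_eqtls": [dataclasses.asdict(e) for e in self.planted_eqtls],
            "module_assignment": self.module_assignment,
            "scenario_labels": self.scenario_labels,
            "variant_freqs": self.variant_freqs,
            "pathway_overlaps": self.pathway_overlaps,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_eqtls=[PlantedEffect(**e) for e in payload["planted_eqtls"]],
            module_assignment={k: int(v) for k, v in payload["module_assignment"].items()},
            scenario_labels=payload["scenario_labels"],
            variant_freqs=payload["variant_freqs"],
            pathway_overlaps=payload["pathway_overlaps"],
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages in LD blocks.

    Within a block all variants share one population allele frequency drawn
    from ``maf_range``.  Haplotype alleles of variant j+1 copy variant j
    with probability ``sqrt(within_block_r2)`` and are redrawn fresh at the
    block frequency otherwise, giving expected adjacent-pair dosage
    r-squared ~= within_block_r2 (copy correlation enters squared).
    """
    spec.validate()
    rng = _rng(spec.seed, _STREAM_GENOTYPES)
    n, m = spec.n_samples, spec.n_variants
    copy_prob = float(np.sqrt(spec.within_block_r2))
    haplotypes = np.empty((n, 2, m), dtype=np.int8)
    freqs = np.empty(m)
    for start in range(0, m, spec.ld_block_size):
        stop = min(start + spec.ld_block_size, m)
        p = rng.uniform(*spec.maf_range)
        haplotypes[:, :, start] = rng.random((n, 2)) < p
        freqs[start:stop] = p
        for j in range(start + 1, stop):
            fresh = rng.random((n, 2)) < p
            keep = rng.random((n, 2)) < copy_prob
            haplotypes[:, :, j] = np.where(keep, haplotypes[:, :, j - 1], fresh)
    dosages = haplotypes.sum(axis=1, dtype=np.int16)
    sample_ids = [f"s{i + 1:05d}" for i in range(n)]
    frame = pd.DataFrame(dosages, index=sample_ids, columns=spec.variant_ids)
    eaf = frame.to_numpy(dtype=float).mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1 + np.arange(m) * POS_SPACING_BP,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": np.minimum(eaf, 1.0 - eaf),
        },
        index=spec.variant_ids,
    )
    return GenotypeMatrix(dosages=frame, variants=variants)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def gene_annotation(spec: SimulationSpec, geno: GenotypeMatrix) -> pd.DataFrame:
    """Place gene TSSs on the synthetic chromosome.

    Genes are spread evenly over the variant coordinate range; genes with a
    planted cis effect are moved next to their variant, genes with a
    planted trans effect far beyond the default cis window.
    """
    pos = geno.variants["pos"]
    lo, hi = int(pos.min()), int(pos.max())
    tss = np.linspace(lo, hi, spec.n_genes).round().astype(int)
    genes = pd.DataFrame({"chrom": "1", "tss": tss}, index=spec.gene_ids)
    for eff in spec.planted_eqtls:
        vpos = int(geno.variants.loc[eff.variant_id, "pos"])
        offset = CIS_OFFSET_BP if eff.kind == "cis" else TRANS_OFFSET_BP
        genes.loc[eff.gene_id, "tss"] = vpos + offset
    return genes


def trans_interaction_ranges(
    spec: SimulationSpec, geno: GenotypeMatrix, genes: pd.DataFrame, pad_bp: int = 50_000
) -> pd.DataFrame:
    """BEDPE interaction ranges anchoring each planted trans variant to a
    window around its target gene's TSS (0-based half-open)."""
    rows = []
    for eff in spec.planted_eqtls:
        if eff.kind != "trans":
            continue
        vpos = int(geno.variants.loc[eff.variant_id, "pos"])
        tss = int(genes.loc[eff.gene_id, "tss"])
        rows.append(
            (
                "1",
                max(0, vpos - 1 - 5_000),
                vpos - 1 + 5_000,
                "1",
                max(0, tss - 1 - pad_bp),
                tss - 1 + pad_bp,
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Per-column rank-based inverse-normal transform (Blom offset 3/8)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def simulate_expression(
    geno: GenotypeMatrix, spec: SimulationSpec
) -> tuple[list[ExpressionMatrix], TruthTable]:
    """Per-tissue expression: module latent factor + planted additive dosage
    effects + Gaussian noise, then (by default) inverse-normal transformed."""
    spec.validate()
    n = geno.n_samples
    assignment = spec.module_assignment()
    gene_index = {g: i for i, g in enumerate(spec.gene_ids)}
    tissues: list[ExpressionMatrix] = []
    for t, tissue in enumerate(spec.tissue_ids):
        rng = _rng(spec.seed, _STREAM_EXPRESSION, t)
        factors = rng.normal(0.0, spec.module_factor_sd, size=(n, max(spec.n_modules, 1)))
        expr = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
        for gene, module in assignment.items():
            expr[:, gene_index[gene]] += factors[:, module - 1]
        for eff in spec.planted_eqtls:
            if tissue in eff.tissue_ids:
                expr[:, gene_index[eff.gene_id]] += eff.beta * geno.dosage(eff.variant_id)
        if spec.inverse_normal:
            expr = inverse_normal_transform(expr)
        tissues.append(
            ExpressionMatrix(
                values=pd.DataFrame(expr, index=geno.dosages.index, columns=spec.gene_ids),
                tissue_id=tissue,
            )
        )
    truth = TruthTable(
        planted_eqtls=list(spec.planted_eqtls),
        module_assignment=assignment,
        scenario_labels={sc.name: sc.hypothesis for sc in spec.coloc_scenarios},
        variant_freqs={
            spec.variant_id(i): float(f)
            for i, f in enumerate(_population_freqs(spec))
        },
    )
    return tissues, truth


def _population_freqs(spec: SimulationSpec) -> np.ndarray:
    """Replay the genotype stream to recover the drawn block frequencies."""
    rng = _rng(spec.seed, _STREAM_GENOTYPES)
    n, m = spec.n_samples, spec.n_variants
    freqs = np.empty(m)
    for start in range(0, m, spec.ld_block_size):
        stop = min(start + spec.ld_block_size, m)
        p = rng.uniform(*spec.maf_range)
        rng.random((n, 2))
        freqs[start:stop] = p
        for _ in range(start + 1, stop):
            rng.random((n, 2))
            rng.random((n, 2))
    return freqs


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    geno: GenotypeMatrix, scenario: ColocScenario, seed: int, scenario_index: int = 0
) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Single-variant association summaries for the two traits of a scenario.

    Each trait is causal-dosage x beta + standard normal noise over its own
    leading sample subset; every region variant is then regressed on the
    trait with an intercept, yielding aligned (variant, beta, se, p) sets.
    """
    from .qtl import ols_scan  # local import to avoid a cycle

    sets = []
    rng = _rng(seed, _STREAM_SUMMARY, scenario_index)
    region = scenario.region_variants
    dosage_block = geno.dosages[region].to_numpy(dtype=float)
    for trait_idx, (causal, beta, n_sub) in enumerate(
        [
            (scenario.causal_variant_trait1, scenario.beta1, scenario.n1),
            (scenario.causal_variant_trait2, scenario.beta2, scenario.n2),
        ]
    ):
        X = dosage_block[:n_sub]
        y = rng.normal(0.0, 1.0, size=n_sub)
        if causal is not None:
            y = y + beta * X[:, region.index(causal)]
        betas, ses, ps, _ = ols_scan(X, y)
        eaf = X.mean(axis=0) / 2.0
        table = pd.DataFrame(
            {
                "variant_id": region,
                "beta": betas,
                "se": ses,
                "p": ps,
                "n": n_sub,
                "maf": np.minimum(eaf, 1.0 - eaf),
                "effect_allele": geno.variants.loc[region, "effect_allele"].to_numpy(),
                "other_allele": geno.variants.loc[region, "other_allele"].to_numpy(),
            }
        )
        sets.append(
            SummaryStatSet(trait_id=f"{scenario.name}_trait{trait_idx + 1}", table=table)
        )
    return sets[0], sets[1]


# ---------------------------------------------------------------------------
# pathway catalogs
# ---------------------------------------------------------------------------

def build_pathway_catalog(
    spec: SimulationSpec, truth: TruthTable | None = None
) -> dict[str, list[str]]:
    """Emit a gene-set catalog whose sets coincide with, partially overlap,
    or avoid the planted modules; Jaccard overlaps versus every planted
    module are recorded in the truth table when one is supplied."""
    spec.validate()
    if not spec.pathways:
        raise SpecError("empty pathway catalog requested")
    rng = _rng(spec.seed, _STREAM_PATHWAYS)
    assignment = spec.module_assignment()
    modules: dict[int, list[str]] = {}
    for gene, module in assignment.items():
        modules.setdefault(module, []).append(gene)
    universe = spec.gene_ids
    catalog: dict[str, list[str]] = {}
    for pw in spec.pathways:
        if pw.mode == "module":
            genes = list(modules[pw.module_index])
        elif pw.mode == "partial":
            members = modules[pw.module_index]
            n_in = int(round(pw.size * pw.overlap))
            n_in = min(n_in, len(members), pw.size)
            inside = list(rng.choice(members, size=n_in, replace=False))
            outside_pool = [g for g in universe if g not in set(members)]
            n_out = min(pw.size - n_in, len(outside_pool))
            outside = list(rng.choice(outside_pool, size=n_out, replace=False))
            genes = inside + outside
        else:
            genes = list(rng.choice(universe, size=pw.size, replace=False))
        catalog[pw.name] = sorted(genes)
    if truth is not None:
        overlaps: dict[str, dict[str, float]] = {}
        for name, genes in catalog.items():
            gset = set(genes)
            overlaps[name] = {
                str(m): len(gset & set(members)) / len(gset | set(members))
                for m, members in modules.items()
            }
        truth.pathway_overlaps = overlaps
    return catalog
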