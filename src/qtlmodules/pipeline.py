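"""End-to-end orchestration: simulate -> map-qtl -> ld -> coloc -> modules
-> enrich -> report, with a JSON run manifest.

Every stage writes its table(s) as TSV under the output directory; the
manifest records the config hash, seed, per-stage row counts and wall
clock.  Identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import enrichment as enrich_mod
from . import ld as ld_mod
from . import modules as modules_mod
from . import qtl as qtl_mod
from . import reporting as report_mod
from . import synthetic
from .containers import SummaryStatSet, write_gene_annotation
from .errors import SpecError
from .io import write_bedpe, write_gmt, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and sizes of one pipeline run."""

    simulation: synthetic.SimulationSpec = field(default_factory=synthetic.SimulationSpec)
    cis_window_bp: int = 1_000_000
    permutations: int = 200
    fdr: float = 0.05
    r2_min: float = 0.80
    ld_window_bp: int = 1_000_000
    rho_min: float = 0.90
    signed_coexpression: bool = False
    gap_kmax: int | None = None
    gap_B: int = 50
    gap_rule: str = "globalSEmax"
    fixed_alpha: float = 5e-8
    h4_threshold: float = 0.9
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_prior_sd: float = 0.15
    enrich_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("fdr", self.fdr, 0.0, 1.0),
            ("r2_min", self.r2_min, 0.0, 1.0),
            ("rho_min", self.rho_min, 0.0, 1.0),
            ("h4_threshold", self.h4_threshold, 0.0, 1.0),
            ("enrich_alpha", self.enrich_alpha, 0.0, 1.0),
            ("fixed_alpha", self.fixed_alpha, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise SpecError(f"{name}={value} outside [{lo}, {hi}]")
        if self.permutations < 1:
            raise SpecError("permutations must be >= 1")
        if self.gap_rule not in modules_mod.GAP_RULES:
            raise SpecError(f"unknown gap rule {self.gap_rule!r}")
        self.simulation.validate()

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        sim = out["simulation"]
        sim["maf_range"] = list(sim["maf_range"])
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = dict(payload.pop("simulation", {}))
        sim["planted_eqtls"] = [
            synthetic.PlantedEffect(**e) for e in sim.get("planted_eqtls", [])
        ]
        sim["coloc_scenarios"] = [
            synthetic.ColocScenario(**s) for s in sim.get("coloc_scenarios", [])
        ]
        sim["pathways"] = [synthetic.PathwaySpec(**p) for p in sim.get("pathways", [])]
        return cls(simulation=synthetic.SimulationSpec(**sim), **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def demo_config(seed: int = 11) -> RunConfig:
    """Bundled demonstration study: 3 tissues, 80 variants in 16 LD blocks,
    90 genes with 3 planted co-expression modules, planted cis/trans eQTLs,
    three colocalization scenarios and a 5-set pathway catalog."""
    from importlib.resources import files

    cfg = RunConfig.from_yaml(files("qtlmodules.data").joinpath("demo_config.yaml"))
    cfg.seed = seed
    cfg.simulation.seed = seed
    return cfg


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "stages": {},
        "timing_s": {},
    }

    def _stage(name: str):
        manifest["stages"][name] = {"rows": {}}
        return time.perf_counter()

    def _done(name: str, t0: float) -> None:
        manifest["timing_s"][name] = round(time.perf_counter() - t0, 3)

    def _write(stage: str, filename: str, frame: pd.DataFrame) -> None:
        write_tsv(frame, outdir / filename)
        manifest["stages"][stage]["rows"][filename] = int(frame.shape[0])

    spec = config.simulation

    # -- simulate --------------------------------------------------------
    t0 = _stage("simulate")
    geno = synthetic.simulate_genotypes(spec)
    genes = synthetic.gene_annotation(spec, geno)
    tissues, truth = synthetic.simulate_expression(geno, spec)
    geno.write(outdir / "genotypes.tsv", outdir / "variants.tsv")
    manifest["stages"]["simulate"]["rows"]["genotypes.tsv"] = geno.n_samples
    write_gene_annotation(genes, outdir / "genes.tsv")
    manifest["stages"]["simulate"]["rows"]["genes.tsv"] = genes.shape[0]
    for expr in tissues:
        expr.write(outdir / f"expression_{expr.tissue_id}.tsv")
        manifest["stages"]["simulate"]["rows"][
            f"expression_{expr.tissue_id}.tsv"
        ] = expr.n_samples
    interactions = synthetic.trans_interaction_ranges(spec, geno, genes)
    write_bedpe(interactions, outdir / "interactions.bedpe")
    manifest["stages"]["simulate"]["rows"]["interactions.bedpe"] = interactions.shape[0]
    scenario_stats: dict[str, tuple[SummaryStatSet, SummaryStatSet]] = {}
    for i, scenario in enumerate(spec.coloc_scenarios):
        s1, s2 = synthetic.simulate_summary_stats(geno, scenario, spec.seed, i)
        s1.write(outdir / f"sumstats_{s1.trait_id}.tsv")
        s2.write(outdir / f"sumstats_{s2.trait_id}.tsv")
        scenario_stats[scenario.name] = (s1, s2)
        manifest["stages"]["simulate"]["rows"][f"sumstats_{s1.trait_id}.tsv"] = len(
            s1.table
        )
        manifest["stages"]["simulate"]["rows"][f"sumstats_{s2.trait_id}.tsv"] = len(
            s2.table
        )
    catalog = synthetic.build_pathway_catalog(spec, truth) if spec.pathways else {}
    if catalog:
        write_gmt(catalog, outdir / "pathways.gmt")
        manifest["stages"]["simulate"]["rows"]["pathways.gmt"] = len(catalog)
    truth.to_json(outdir / "truth.json")
    _done("simulate", t0)

    # -- map-qtl ---------------------------------------------------------
    t0 = _stage("map_qtl")
    qtl_frames = []
    egene_frames = []
    module_sets: dict[str, modules_mod.ModuleSet] = {}
    for t_idx, expr in enumerate(tissues):
        cis = qtl_mod.map_cis(geno, expr, genes, window_bp=config.cis_window_bp)
        trans = qtl_mod.map_trans(
            geno, expr, genes, interactions, cis_window_bp=config.cis_window_bp
        )
        empiricals = []
        for gene_id in expr.gene_ids:
            emp = qtl_mod.empirical_gene_p(
                geno,
                expr,
                genes,
                gene_id,
                B=config.permutations,
                seed=_child_seed(config.seed, 10, t_idx, expr.gene_ids.index(gene_id)),
                window_bp=config.cis_window_bp,
            )
            if emp is not None:
                empiricals.append(emp)
        egenes = qtl_mod.egene_threshold(empiricals, fdr=config.fdr)
        tested = pd.concat([f for f in (cis, trans) if not f.empty], ignore_index=True)
        flagged = qtl_mod.mark_significant(tested, egenes)
        qtl_frames.append(flagged)
        egene_frames.append(egenes)
    qtls = pd.concat(qtl_frames, ignore_index=True)
    egene_table = pd.concat(egene_frames, ignore_index=True)
    _write("map_qtl", "qtls.tsv", qtls)
    _write("map_qtl", "egenes.tsv", egene_table)
    _done("map_qtl", t0)

    # -- ld --------------------------------------------------------------
    t0 = _stage("ld")
    leads = sorted(qtls.loc[qtls["significant"], "variant_id"].unique())
    expansions = ld_mod.expand_leads(
        leads, geno, r2_min=config.r2_min, window_bp=config.ld_window_bp
    )
    _write("ld", "ld.tsv", ld_mod.expansions_to_frame(expansions))
    _done("ld", t0)

    # -- coloc -----------------------------------------------------------
    t0 = _stage("coloc")
    priors = coloc_mod.ColocPriors(
        p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12
    )
    coloc_rows = []
    for scenario in spec.coloc_scenarios:
        s1, s2 = scenario_stats[scenario.name]
        result = coloc_mod.coloc_region(
            s1,
            s2,
            priors=priors,
            prior_sd1=config.coloc_prior_sd,
            prior_sd2=config.coloc_prior_sd,
            h4_threshold=config.h4_threshold,
        )
        coloc_rows.append(
            {
                "scenario": scenario.name,
                "n_variants": result.n_variants,
                **result.as_dict(),
                "h4_call": result.h4_call,
            }
        )
    _write("coloc", "coloc.tsv", pd.DataFrame(coloc_rows))
    _done("coloc", t0)

    # -- modules ---------------------------------------------------------
    t0 = _stage("modules")
    module_frames = []
    gap_frames = []
    for t_idx, expr in enumerate(tissues):
        tissue_egenes = sorted(
            egene_table.loc[
                (egene_table["tissue_id"] == expr.tissue_id) & egene_table["is_egene"],
                "gene_id",
            ]
        )
        if not tissue_egenes:
            logger.info("tissue %s has no eGenes; skipping modules", expr.tissue_id)
            continue
        mset = modules_mod.detect_modules(
            expr,
            tissue_egenes,
            rho_min=config.rho_min,
            kmax=config.gap_kmax,
            B=config.gap_B,
            seed=_child_seed(config.seed, 20, t_idx),
            signed=config.signed_coexpression,
            rule=config.gap_rule,
        )
        module_sets[expr.tissue_id] = mset
        module_frames.append(mset.as_frame())
        if mset.gap is not None:
            gf = mset.gap.as_frame()
            gf.insert(0, "tissue_id", expr.tissue_id)
            gap_frames.append(gf)
    modules_table = (
        pd.concat(module_frames, ignore_index=True)
        if module_frames
        else pd.DataFrame(columns=["tissue_id", "gene_id", "module", "is_egene"])
    )
    gap_table = (
        pd.concat(gap_frames, ignore_index=True)
        if gap_frames
        else pd.DataFrame(columns=["tissue_id", "k", "gap", "se"])
    )
    _write("modules", "modules.tsv", modules_table)
    _write("modules", "gap_curves.tsv", gap_table)
    _done("modules", t0)

    # -- enrich ----------------------------------------------------------
    t0 = _stage("enrich")
    enrich_frames = []
    retained_rows = []
    for tissue_id, mset in module_sets.items():
        expr = next(e for e in tissues if e.tissue_id == tissue_id)
        enr = enrich_mod.enrich_modules(mset, catalog, universe=expr.gene_ids)
        enrich_frames.append(enr)
        for module in enrich_mod.filter_modules(mset, enr, alpha=config.enrich_alpha):
            retained_rows.append((tissue_id, module, len(mset.module_genes(module))))
    enrichment_table = (
        pd.concat(enrich_frames, ignore_index=True)
        if enrich_frames
        else pd.DataFrame(columns=enrich_mod.ENRICHMENT_COLUMNS)
    )
    retained_table = pd.DataFrame(
        retained_rows, columns=["tissue_id", "module", "n_genes"]
    )
    _write("enrich", "enrichment.tsv", enrichment_table)
    _write("enrich", "modules_retained.tsv", retained_table)
    _done("enrich", t0)

    # -- report ----------------------------------------------------------
    t0 = _stage("report")
    retained_enr = enrichment_table.merge(
        retained_table[["tissue_id", "module"]], on=["tissue_id", "module"]
    ) if not enrichment_table.empty else enrichment_table
    sharing = report_mod.summarize_sharing(
        qtls, retained_enr, alpha=config.enrich_alpha
    )
    _write("report", "sharing_egenes.tsv", sharing["egenes"])
    _write("report", "sharing_pairs.tsv", sharing["pairs"])
    _write("report", "sharing_pathways.tsv", sharing["pathways"])
    pqtl_variants: list[str] = []
    mqtl_variants: list[str] = []
    for scenario in spec.coloc_scenarios:
        _, s2 = scenario_stats[scenario.name]
        sig = qtl_mod.filter_fixed_threshold(s2, alpha=config.fixed_alpha)
        target = pqtl_variants if scenario.trait2_kind == "protein" else mqtl_variants
        target.extend(sig.variant_ids)
    overlap = report_mod.qtl_overlap_classes(leads, pqtl_variants, mqtl_variants)
    _write("report", "qtl_overlap.tsv", overlap)
    manifest["stages"]["report"]["totals"] = sharing["totals"]
    _done("report", t0)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _child_seed(seed: int, *key: int) -> int:
    """Derive a deterministic 31-bit child seed from the master seed."""
    digest = hashlib.sha256(("/".join(map(str, (seed, *key)))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def manifest_core(manifest: dict) -> dict:
    """Manifest minus wall-clock timing (the determinism contract)."""
    return {k: v for k, v in manifest.items() if k != "timing_s"}
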