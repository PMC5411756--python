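"""End-to-end orchestration: simulate -> QC -> map -> prune -> replicate -> enrich.

A :class:`PipelineConfig` (usually loaded from YAML) names every input and
threshold.  ``run_pipeline`` executes the requested stages in dependency
order, writes fixed-format TSV outputs into a run directory, and records a
manifest (config hash, seed, package version, row counts per output) so
re-runs are verifiably bit-stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cis, genesets, gwas as gwas_mod, io, ld, replicate as rep
from .config import SimulationConfig
from .exceptions import AnalysisError, ConfigurationError, DataConsistencyError
from .simulate import simulate_cohort, simulate_gene_sets, simulate_validation_study


@dataclass
class PipelineConfig:
    out_dir: str = "epiqtl_run"
    seed: int = 0
    # either a simulation block or explicit input paths
    simulate: dict | None = None
    genotypes_vcf: str | None = None
    genotypes_tsv: str | None = None
    variants_tsv: str | None = None  # required alongside genotypes_tsv (positions)
    genes_bed: str | None = None
    expression_tsv: str | None = None
    probe_map_tsv: str | None = None
    gwas_tsv: str | None = None
    validation_tsv: str | None = None
    epilepsy_genes_txt: str | None = None
    other_genes_txt: str | None = None
    # analysis constants
    cis_window_bp: int = 20_000
    eqtl_fdr_cut: float = 0.05
    ld_r2_threshold: float = 0.8
    proxy_r2_threshold: float = 0.8
    ld_window_bp: int = 1_000_000
    gwas_p_grid: tuple[float, ...] = gwas_mod.DEFAULT_GWAS_THRESHOLDS
    fdr_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2)
    perm_gwas_threshold: float = 1e-3
    n_permutations: int = 10_000
    min_bin: int = 10
    # per-SNP QC
    qc_maf_min: float = 0.05
    qc_call_rate_min: float = 0.95
    qc_hwe_p_min: float = 1e-6
    run_qc: bool = True

    def __post_init__(self) -> None:
        for name in ("eqtl_fdr_cut", "ld_r2_threshold", "proxy_r2_threshold", "qc_maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.cis_window_bp < 0:
            raise ConfigurationError("cis_window_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gwas_p_grid", "fdr_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> dict:
    """Pre-flight check of file existence and schemas.

    Returns {"errors": [...], "warnings": [...]}; any error is fatal and
    ``run_pipeline`` refuses to start.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    if config.simulate is not None:
        try:
            SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulate block: {exc}")
        return {"errors": errors, "warnings": warnings_}

    paths = {
        "genes_bed": config.genes_bed,
        "expression_tsv": config.expression_tsv,
        "probe_map_tsv": config.probe_map_tsv,
    }
    if config.genotypes_vcf:
        paths["genotypes_vcf"] = config.genotypes_vcf
    elif config.genotypes_tsv:
        paths["genotypes_tsv"] = config.genotypes_tsv
        if config.variants_tsv:
            paths["variants_tsv"] = config.variants_tsv
        else:
            errors.append("genotypes_tsv needs a variants_tsv with SNP coordinates")
    else:
        errors.append("no genotype input: set genotypes_vcf or genotypes_tsv")
    for key in ("gwas_tsv", "validation_tsv", "epilepsy_genes_txt", "other_genes_txt"):
        if getattr(config, key):
            paths[key] = getattr(config, key)
    for name, p in paths.items():
        if p is None:
            errors.append(f"missing required input path: {name}")
        elif not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    # schema checks
    if config.gwas_tsv:
        head = pd.read_csv(config.gwas_tsv, sep="\t", nrows=5)
        missing = {"SNP", "CHR", "BP", "P"} - set(head.columns)
        if missing:
            errors.append(f"gwas_tsv: missing columns {sorted(missing)}")
    try:
        bed = pd.read_csv(config.genes_bed, sep="\t", header=None)
        bad = bed[bed[1] > bed[2]]
        for line_no in bad.index:
            errors.append(f"genes_bed line {line_no + 1}: start > end")
    except Exception as exc:  # malformed file
        errors.append(f"genes_bed: {exc}")

    if config.genotypes_tsv and config.expression_tsv:
        gsamp = pd.read_csv(config.genotypes_tsv, sep="\t", usecols=["sample_id"])["sample_id"]
        esamp = pd.read_csv(config.expression_tsv, sep="\t", usecols=["sample_id"])["sample_id"]
        extra = sorted(set(esamp.astype(str)) - set(gsamp.astype(str)))
        if extra:
            errors.append(f"expression samples absent from genotypes: {extra[:5]}")
    return {"errors": errors, "warnings": warnings_}


def _load_inputs(config: PipelineConfig) -> dict:
    if config.simulate is not None:
        sim_cfg = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        data = simulate_cohort(sim_cfg)
        data["sim_config"] = sim_cfg
        return data
    if config.genotypes_vcf:
        geno, variants = io.read_vcf(config.genotypes_vcf)
    else:
        geno = io.read_dosage_tsv(config.genotypes_tsv)
        variants = io.read_variants_tsv(config.variants_tsv)
        missing = set(geno.snp_ids) - set(variants["snp_id"])
        if missing:
            raise DataConsistencyError(
                f"SNPs in dosage TSV without coordinates: {sorted(missing)[:5]}"
            )
    annotation = io.read_bed(config.genes_bed)
    expr = io.read_expression_tsv(config.expression_tsv, config.probe_map_tsv)
    data = {"geno": geno, "variants": variants, "annotation": annotation, "expr": expr,
            "truth": None, "sim_config": None}
    data["gwas"] = io.read_gwas_tsv(config.gwas_tsv) if config.gwas_tsv else None
    return data


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all runnable stages; returns {stage results, manifest path}.

    Fails fast on input validation problems; any stage exception aborts the
    run with the stage name recorded in the manifest as invalid.
    """
    report = validate_inputs(config)
    if report["errors"]:
        raise DataConsistencyError("input validation failed: " + "; ".join(report["errors"]))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "valid": False,
    }
    results: dict = {}
    stage = "load"
    try:
        data = _load_inputs(config)
        geno, variants = data["geno"], data["variants"]
        annotation, expr = data["annotation"], data["expr"]
        truth = data.get("truth")

        if config.run_qc:
            stage = "qc"
            from .qc import snp_qc

            geno, variants = snp_qc(
                geno, variants, config.qc_maf_min, config.qc_call_rate_min, config.qc_hwe_p_min
            )
            manifest["stages"]["qc"] = {"n_snps_kept": geno.n_snps}

        stage = "map"
        expr_sel = cis.select_probes(expr)
        pairs = cis.enumerate_cis_pairs(variants, annotation, window=config.cis_window_bp)
        eqtl = cis.fit_cis_model(geno, expr_sel, pairs)
        io.write_eqtl_tsv(eqtl, variants, out / "eqtl.tsv")
        results["eqtl"] = eqtl
        manifest["stages"]["map"] = {
            "n_pairs": len(eqtl),
            "n_tested": int(eqtl["tested"].sum()),
            "n_significant": int((eqtl.loc[eqtl["tested"], "fdr"] < config.eqtl_fdr_cut).sum()),
        }

        stage = "ld"
        proxies = ld.build_proxy_map(
            geno, variants, r2_threshold=config.proxy_r2_threshold, window_bp=config.ld_window_bp
        )
        proxy_df = ld.proxy_map_to_frame(proxies)
        io.write_tsv(proxy_df, out / "ld_proxies.tsv")
        results["proxies"] = proxies
        manifest["stages"]["ld"] = {"n_proxy_pairs": len(proxy_df)}

        stage = "replicate"
        validation = None
        if config.simulate is not None:
            validation = simulate_validation_study(
                truth, eqtl, data["sim_config"], fdr_threshold=config.eqtl_fdr_cut
            )
            io.write_validation_tsv(validation, out / "validation.tsv")
        elif config.validation_tsv:
            validation = io.read_validation_tsv(config.validation_tsv)
        if validation is not None:
            pruned = ld.ld_prune(
                sorted(set(eqtl.loc[eqtl["tested"], "snp_id"])),
                geno,
                variants,
                r2_threshold=config.ld_r2_threshold,
                window_bp=config.ld_window_bp,
            )
            disc = eqtl[eqtl["snp_id"].isin(pruned)].reset_index(drop=True)
            repl = rep.replicate_study(
                disc,
                validation,
                proxies,
                fdr_threshold=config.eqtl_fdr_cut,
                n_perm=config.n_permutations,
                seed=config.seed,
            )
            io.write_tsv(repl.to_frame(), out / "replication.tsv")
            results["replication"] = repl
            manifest["stages"]["replicate"] = {
                "n_sig_pairs": repl.n_sig_pairs,
                "n_sig_replicated": repl.n_sig_replicated,
            }

        gwas_df = data.get("gwas")
        if gwas_df is not None:
            stage = "enrich-gwas"
            shared = gwas_mod.shared_pruned_snps(
                gwas_df, eqtl, geno, variants,
                r2_threshold=config.ld_r2_threshold, window_bp=config.ld_window_bp,
            )
            curve = gwas_mod.enrichment_curve(
                shared, eqtl_fdr_cut=config.eqtl_fdr_cut, thresholds=config.gwas_p_grid
            )
            io.write_tsv(curve.table, out / "enrichment_curve.tsv")
            thr, fold = gwas_mod.max_enrichment(curve, min_bin=config.min_bin)
            perm = gwas_mod.permute_enrichment(
                shared,
                eqtl_fdr_cut=config.eqtl_fdr_cut,
                threshold=config.perm_gwas_threshold,
                n_perm=config.n_permutations,
                seed=config.seed,
            )
            grid = gwas_mod.reverse_enrichment_grid(shared, config.gwas_p_grid, config.fdr_grid)
            io.write_tsv(grid.table, out / "reverse_enrichment_grid.tsv")
            results["enrichment"] = {
                "shared": shared, "curve": curve, "max_threshold": thr, "max_fold": fold,
                "perm": perm, "grid": grid,
            }
            manifest["stages"]["enrich-gwas"] = {
                "n_shared_pruned": len(shared),
                "max_fold": fold,
                "max_fold_threshold": thr,
                "perm_p": perm.p_value,
            }

        stage = "enrich-genes"
        epi = other = None
        if config.simulate is not None:
            cis_set = genesets.classify_cis_genes(eqtl, config.eqtl_fdr_cut)
            epi, other = simulate_gene_sets(annotation, truth, data["sim_config"])
            io.write_gene_list(epi, out / "epilepsy_genes.txt")
            io.write_gene_list(other, out / "other_genes.txt")
        elif config.epilepsy_genes_txt and config.other_genes_txt:
            cis_set = genesets.classify_cis_genes(eqtl, config.eqtl_fdr_cut)
            epi = io.read_gene_list(config.epilepsy_genes_txt)
            other = io.read_gene_list(config.other_genes_txt) - io.read_gene_list(
                config.epilepsy_genes_txt
            )
        if epi is not None:
            gres = genesets.mendelian_enrichment(cis_set, epi, other)
            results["gene_enrichment"] = gres
            manifest["stages"]["enrich-genes"] = {
                "table2x2": [list(r) for r in gres.table2x2],
                "ratio": gres.ratio if np.isfinite(gres.ratio) else str(gres.ratio),
                "fisher_p": gres.fisher_p,
            }

        manifest["valid"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise AnalysisError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    results["out_dir"] = str(out)
    return results
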