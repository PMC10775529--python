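"""End-to-end orchestration: simulate/read -> filter -> scan -> LD/blocks ->
PCA/polygons -> candidate genes, from one YAML config with one global seed.

Every stage writes its table under the output directory and the run ends
with a consolidated machine-readable report (JSON) plus a manifest recording
input hashes, parameters and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .drift import POPULATION_PAIRS, build_drift_bank, intersect_significant, scan_all_pairs
from .genes import genes_near_snps, read_gff
from .linkage import block_summary, blocks_frame, gabriel_blocks, ld_decay
from .pca import compare_variance, genomic_pca, population_areas
from .simulate import SimulationParams, merged_matrix, simulate_experiment
from .variant_io import (
    FilterConfig,
    allele_frequencies,
    apply_site_filters,
    read_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (see ``from_yaml``)."""

    outdir: Path
    seed: int = 0
    vcf: Path | None = None
    sample_map: Path | None = None
    gff: Path | None = None
    simulate: dict | None = None
    filter: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    ld: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    stages: tuple = ("filter", "scan", "ld", "blocks", "pca", "genes")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["outdir"] = Path(raw.get("outdir", "driftscan_out"))
        for key in ("vcf", "sample_map", "gff"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            if self.vcf is None or self.sample_map is None:
                raise ValidationError(
                    "either a simulate section or vcf + sample_map paths are required"
                )
            for key, p in (("vcf", self.vcf), ("sample_map", self.sample_map)):
                if not Path(p).exists():
                    raise ValidationError(f"{key} path does not exist: {p}")
        if "genes" in self.stages and self.gff is not None and not Path(self.gff).exists():
            raise ValidationError(f"gff path does not exist: {self.gff}")
        if "genes" in self.stages and self.simulate is None and self.gff is None:
            pass  # genes stage is silently skipped without an annotation


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the report."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "inputs": {}}
    report: dict = {}

    # --- input stage: simulate or read -------------------------------------
    truth = None
    if cfg.simulate is not None:
        params = SimulationParams(**{**cfg.simulate, "seed": _stage_seed(cfg.seed, "simulate")})
        study = simulate_experiment(params)
        gm = merged_matrix(study)
        pop_map = study.sample_map
        truth = study.truth
        study.sample_map.to_csv(out / "samples.tsv", sep="\t", index=False)
        study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        report["simulate"] = {
            "n_snps": gm.n_snps,
            "n_samples": gm.n_samples,
            "n_selected_loci": len(study.truth),
        }
    else:
        gm, pop_map = read_vcf(cfg.vcf, cfg.sample_map)
        manifest["inputs"]["vcf"] = _sha256(cfg.vcf)
        manifest["inputs"]["sample_map"] = _sha256(cfg.sample_map)

    # --- filter ------------------------------------------------------------
    if "filter" in cfg.stages:
        fcfg = FilterConfig(**cfg.filter)
        gm, freport = apply_site_filters(gm, fcfg)
        freport.as_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        report["filter"] = {
            "n_input": freport.n_input,
            "n_survivors": freport.n_survivors,
            "steps": freport.steps,
            "min_calls_tool": freport.min_calls_tool,
            "min_calls_floor": freport.min_calls_floor,
        }

    af_table = allele_frequencies(gm, pop_map)
    af_table.to_csv(out / "allele_frequencies.tsv", sep="\t", index=False)

    # --- drift scan --------------------------------------------------------
    scan_df = None
    if "scan" in cfg.stages:
        scan_opts = dict(cfg.scan)
        bank = build_drift_bank(
            n_sim=scan_opts.pop("n_sim", 10_000),
            ne=scan_opts.pop("ne", 16),
            transitions=scan_opts.pop("transitions", 8),
            seed=_stage_seed(cfg.seed, "bank"),
        )
        bank.save(out / "drift_bank.npz")
        pairs = scan_opts.pop("pairs", None)
        pairs = POPULATION_PAIRS if pairs is None else tuple(tuple(p) for p in pairs)
        scan_df = scan_all_pairs(af_table, bank, pairs=pairs, **scan_opts)
        scan_df.to_csv(out / "scan.tsv", sep="\t", index=False)
        sig_sets = {
            label: {
                (r.chrom, r.pos)
                for r in scan_df[(scan_df["population"] == label) & scan_df["significant"]].itertuples()
            }
            for label, _, _ in pairs
        }
        inter = intersect_significant(sig_sets)
        inter.to_csv(out / "intersections.tsv", sep="\t", index=False)
        report["scan"] = {
            "significant_per_population": {k: len(v) for k, v in sig_sets.items()},
            "strong_and_significant": {
                label: int(
                    (
                        (scan_df["population"] == label)
                        & scan_df["significant"]
                        & scan_df["strong"]
                    ).sum()
                )
                for label, _, _ in pairs
            },
            "intersections": inter.to_dict("records"),
        }

    # --- LD decay ----------------------------------------------------------
    if "ld" in cfg.stages:
        decay = ld_decay(gm, pop_map, **cfg.ld)
        decay.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        report["ld"] = {
            "populations": sorted(decay["population"].unique().tolist()),
            "n_bins": int(decay.groupby("population").size().max()) if len(decay) else 0,
        }

    # --- haplotype blocks --------------------------------------------------
    if "blocks" in cfg.stages:
        per_pop = {}
        for pop, grp in pop_map.groupby("population", sort=False):
            per_pop[pop] = gabriel_blocks(gm, samples=list(grp["sample_id"]), **cfg.blocks)
        blocks_frame(per_pop).to_csv(out / "blocks.tsv", sep="\t", index=False)
        summary = block_summary(per_pop)
        summary.to_csv(out / "block_summary.tsv", sep="\t", index=False)
        report["blocks"] = summary.set_index("population").to_dict("index")

    # --- PCA / polygon areas / variance tests ------------------------------
    if "pca" in cfg.stages:
        pca_opts = dict(cfg.pca)
        k_pairs = pca_opts.pop("k_pairs", 6)
        emb = genomic_pca(gm, n_components=pca_opts.pop("n_components", 15))
        emb.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": emb.eigenvalues, "explained_frac": emb.explained_frac}
        ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
        areas = population_areas(emb, pop_map, k=k_pairs)
        areas.to_csv(out / "polygon_areas.tsv", sep="\t", index=False)
        comparisons = pca_opts.pop(
            "comparisons",
            [
                {"label": "bumblebee_gen9_vs_gen1", "baseline": ["A1", "B1"], "target": ["B9A", "B9B"]},
                {"label": "control_gen9_vs_gen1", "baseline": ["A1", "B1"], "target": ["C9A", "C9B"]},
            ],
        )
        tests = []
        for comp in comparisons:
            try:
                res = compare_variance(areas, comp["baseline"], comp["target"], k=k_pairs)
            except ValidationError as exc:
                logger.warning("comparison %s skipped: %s", comp.get("label"), exc)
                continue
            tests.append(
                {
                    "comparison": comp.get("label", "?"),
                    "V": res.v_statistic,
                    "n": res.n_pairs,
                    "p_two_sided": res.p_two_sided,
                    "exact": res.exact,
                }
            )
        pd.DataFrame(tests).to_csv(out / "polygon_tests.tsv", sep="\t", index=False)
        report["pca"] = {
            "explained_frac_first6": float(emb.explained_frac[:6].sum()),
            "tests": tests,
        }

    # --- candidate genes ---------------------------------------------------
    if "genes" in cfg.stages and cfg.gff is not None and scan_df is not None:
        manifest["inputs"]["gff"] = _sha256(cfg.gff)
        gene_records = read_gff(cfg.gff)
        sig = scan_df[scan_df["significant"]][["chrom", "pos"]]
        candidates = genes_near_snps(sig, gene_records, **cfg.genes)
        candidates.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
        report["genes"] = {
            "n_significant_snps": int(len(sig.drop_duplicates())),
            "n_candidate_genes": int(len(candidates)),
        }

    if truth is not None and scan_df is not None and len(truth):
        sig_pos = set(
            map(tuple, scan_df[scan_df["significant"]][["chrom", "pos"]].to_numpy())
        )
        truth_pos = set(map(tuple, truth[["chrom", "pos"]].to_numpy()))
        report["truth_recovery"] = {
            "n_truth_loci": len(truth_pos),
            "n_truth_flagged": len(truth_pos & sig_pos),
        }

    report = make_report(report, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return report


def make_report(artifacts: dict, outdir: Path | None = None) -> dict:
    """Serialize the consolidated run report (JSON + plain-text summary)."""
    if not artifacts:
        raise ValidationError("no stage artifacts to report")
    report = json.loads(json.dumps(artifacts, default=_jsonable))
    if outdir is not None:
        out = Path(outdir)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        lines = ["er-driftscan run report", "======================="]
        for stage, payload in report.items():
            lines.append(f"\n[{stage}]")
            lines.append(json.dumps(payload, indent=2, sort_keys=True))
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
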