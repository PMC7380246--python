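"""Configured, logged, resumable orchestration of the full analysis.

``run_pipeline`` executes simulate -> DMR calling -> DEG calling ->
integration from a single :class:`RunConfig`, writing every stage's output
as TSV/JSON plus a manifest of parameters and SHA-256 hashes.  Reruns with
an identical config are byte-identical; completed stages whose recorded
output hashes still match are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import dmr as dmrmod
from . import expression as exprmod
from . import integrate as intmod
from .io import read_cytosine_report
from .simulate import SimulationDesign, simulate_experiment, write_experiment

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_CONFIG, EXIT_STAGE = 0, 2, 3


@dataclass
class RunConfig:
    """All thresholds and design parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "chillmeth_run"
    design: SimulationDesign | None = None
    # methylome thresholds
    min_coverage: int = 5
    window: int = 100
    step: int | None = None
    min_meth_cytosines: int = 20
    dmr_q_max: float = 0.01
    dmr_min_delta: float = 3.0
    pseudocount: float = 0.5
    # expression thresholds
    deg_q_max: float = 0.01
    deg_min_abs_log2fc: float = 1.0
    dispersion_mode: str = "common"
    # integration thresholds
    flank: int = 2000
    r_max: float = -0.5
    closest_only: bool = False
    enrichment_q_max: float = 0.01
    # clustering
    k_dmr: int = 16
    k_expr: int = 10
    threads: int = 1  # accepted for interface compatibility; results never depend on it

    def validate(self) -> None:
        if not (0 <= self.dmr_q_max <= 1 and 0 <= self.deg_q_max <= 1):
            raise ValueError("FDR thresholds must lie in [0, 1]")
        if self.window < 1 or self.flank < 0 or self.min_coverage < 0:
            raise ValueError("window/flank/min_coverage out of range")
        if self.r_max > 1 or self.r_max < -1:
            raise ValueError("r_max must lie in [-1, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"]["conditions"] = {
                k: list(v) for k, v in self.design.conditions.items()
            }
            d["design"]["chrom_sizes"] = dict(self.design.chrom_sizes)
            d["design"]["baselines"] = dict(self.design.baselines)
            d["design"]["gene_length"] = list(self.design.gene_length)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (keys as in the dataclass)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design_raw = raw.pop("design", None)
    cfg = RunConfig(**raw)
    if design_raw is not None:
        if "conditions" in design_raw:
            design_raw["conditions"] = {
                k: tuple(v) for k, v in design_raw["conditions"].items()
            }
        if "gene_length" in design_raw:
            design_raw["gene_length"] = tuple(design_raw["gene_length"])
        cfg.design = SimulationDesign(**design_raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    """Stage ledger; paths stored relative to the run directory so that two
    runs in different directories produce byte-identical manifests."""

    def __init__(self, path: Path, root: Path):
        self.path = path
        self.root = root
        self.data: dict[str, Any] = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_current(self, name: str, params: dict) -> bool:
        st = self.data["stages"].get(name)
        if not st or st.get("params") != params:
            return False
        return all(
            (self.root / p).exists() and _sha256(self.root / p) == h
            for p, h in st["outputs"].items()
        )

    def record(self, name: str, params: dict, outputs: list[Path]) -> None:
        self.data["stages"][name] = {
            "params": params,
            "outputs": {
                str(p.relative_to(self.root)): _sha256(p) for p in outputs
            },
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig, force: bool = False) -> dict[str, Any]:
    """Run simulate -> dmr -> deg -> integrate; return the run report.

    The report summarises counts per stage (windows tested, DMRs by
    direction and context, DEGs by contrast, quadrant tables, conserved
    genes, retained correlations) and is also written as ``report.json``.
    """
    config.validate()
    if config.design is None:
        config.design = SimulationDesign(seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json", outdir)
    params = _jsonable(config.to_dict())
    # location and thread count must not affect results or manifest identity
    params.pop("outdir", None)
    params.pop("threads", None)
    logger.info("pipeline start: seed=%s outdir=%s", config.seed, outdir)
    logger.info("parameters: %s", json.dumps(params, sort_keys=True))

    # --- stage: simulate -------------------------------------------------
    sim_dir = outdir / "inputs"
    exp = simulate_experiment(config.design)
    if force or not manifest.stage_current("simulate", params["design"]):
        paths = write_experiment(exp, sim_dir)
        manifest.record(
            "simulate", params["design"],
            [p for p in paths.values() if p.is_file()],
        )
        logger.info("stage simulate: wrote %d artefacts", len(paths))
    genotypes = list(config.design.conditions)

    report: dict[str, Any] = {"seed": config.seed, "genotypes": genotypes}
    windows = dmrmod.tile_windows(
        config.design.chrom_sizes, width=config.window, step=config.step
    )
    genome_length = config.design.genome_length

    dmr_results: dict[str, dmrmod.DMRResults] = {}
    context_results: dict[str, dict[str, dmrmod.DMRResults]] = {}
    deg_results: dict[str, dict[str, exprmod.DEGResults]] = {}

    for g in genotypes:
        conds = [f"{ch}CH" for ch in config.design.conditions[g]]
        baseline = conds[0]

        # --- stage: dmr --------------------------------------------------
        calls = {
            sid: read_cytosine_report(
                sim_dir / "methylome" / g / f"{sid}.cx.tsv",
                min_coverage=config.min_coverage,
            )
            for sid in exp.calls[g]
        }
        design_map = exp.sample_design(g)
        wq = dmrmod.quantify_windows(
            calls, windows, genome_length, pseudocount=config.pseudocount
        )
        wq = dmrmod.filter_windows(wq, config.min_meth_cytosines)
        res = dmrmod.call_dmrs(
            wq, design_map, baseline,
            q_max=config.dmr_q_max, min_delta=config.dmr_min_delta,
        )
        dmr_results[g] = res
        ctx_res = dmrmod.split_by_context(
            calls, windows, design_map, baseline, genome_length,
            min_meth_cytosines=config.min_meth_cytosines,
            q_max=config.dmr_q_max, min_delta=config.dmr_min_delta,
            pseudocount=config.pseudocount,
        )
        context_results[g] = ctx_res
        dmr_path = outdir / f"dmrs_{g}.tsv"
        res.table.to_csv(dmr_path, sep="\t", index=False, float_format="%.6g")
        bed_path = outdir / f"dmrs_{g}.bed"
        res.to_bed(bed_path)
        manifest.record(f"dmr:{g}", params, [dmr_path, bed_path])
        logger.info("stage dmr[%s]: %d windows tested, %d DMRs", g, len(res.table), res.n_dmrs)

        report[f"dmr:{g}"] = {
            "windows_tested": len(res.table),
            "n_dmrs": res.n_dmrs,
            "directions": {
                cond: res.direction_counts(cond).to_dict()
                for cond in res.conditions[1:]
            },
            "per_context": {c: r.n_dmrs for c, r in ctx_res.items()},
        }

        # --- stage: deg --------------------------------------------------
        model = exprmod.DEGModel(exp.counts[g], design_map)
        fits = model.fit_all(
            baseline,
            q_max=config.deg_q_max,
            min_abs_log2fc=config.deg_min_abs_log2fc,
            dispersion_mode=config.dispersion_mode,
        )
        deg_results[g] = fits
        deg_paths = []
        for cond, fit in fits.items():
            p = outdir / f"degs_{g}_{cond}.tsv"
            fit.to_tsv(p)
            deg_paths.append(p)
        manifest.record(f"deg:{g}", params, deg_paths)
        report[f"deg:{g}"] = {
            cond: {"up": fit.n_up, "down": fit.n_down} for cond, fit in fits.items()
        }
        logger.info("stage deg[%s]: %s", g, report[f"deg:{g}"])

    # --- stage: integrate -----------------------------------------------
    quadrant_tables: dict[str, list[intmod.QuadrantTable]] = {}
    int_paths = []
    for g in genotypes:
        res = dmr_results[g]
        links = intmod.link_dmrs_to_genes(res.dmrs, exp.genes, flank=config.flank)
        links_path = outdir / f"links_{g}.tsv"
        links.to_csv(links_path, sep="\t", index=False)
        int_paths.append(links_path)
        quadrant_tables[g] = []
        qrows = []
        for cond in res.conditions[1:]:
            dirs = dict(
                zip(res.dmrs["window_id"], res.dmrs[f"direction_{cond}"])
            )
            qt = intmod.quadrant_overlap(
                links, dirs, deg_results[g][cond].table, cond
            )
            quadrant_tables[g].append(qt)
            for qd, n in qt.counts.items():
                qrows.append((cond, qd, n))
            qrows.append((cond, "no_test", len(qt.no_test)))
        qpath = outdir / f"quadrants_{g}.tsv"
        pd.DataFrame(qrows, columns=["contrast", "quadrant", "n"]).to_csv(
            qpath, sep="\t", index=False
        )
        int_paths.append(qpath)
        report[f"quadrants:{g}"] = {
            qt.contrast: qt.counts for qt in quadrant_tables[g]
        }

        # correlations on condition means
        meth_prof = res.dmr_profiles()
        meth_prof.columns = [str(c) for c in meth_prof.columns]
        cpm = exprmod.DEGModel(exp.counts[g], exp.sample_design(g)).cpm()
        sheet = exp.sample_sheets[g]
        cond_of = dict(zip(sheet["sample_id"], sheet["condition"]))
        # per-condition mean log2 expression
        log2cpm = np.log2(cpm + 0.5)
        expr_prof = log2cpm.T.groupby(pd.Series(cond_of)).mean().T
        conds = [f"{ch}CH" for ch in config.design.conditions[g]]
        expr_prof = expr_prof[conds]
        meth_prof = meth_prof[conds]
        corr = intmod.methylation_expression_correlation(
            links, meth_prof, expr_prof,
            r_max=config.r_max, closest_only=config.closest_only,
        )
        cpath = outdir / f"correlations_{g}.tsv"
        corr.to_csv(cpath, sep="\t", index=False, float_format="%.6g")
        int_paths.append(cpath)
        report[f"correlations:{g}"] = {
            "n_links": len(corr),
            "n_retained": int(corr["retained"].sum()),
        }

    if len(genotypes) >= 2:
        a, b = genotypes[:2]
        conserved = intmod.conserved_patterns(
            quadrant_tables[a], quadrant_tables[b]
        )
        cons_path = outdir / "conserved_genes.tsv"
        conserved.to_csv(cons_path, sep="\t", index=False)
        int_paths.append(cons_path)
        report["conserved_genes"] = len(conserved)
    manifest.record("integrate", params, int_paths)
    logger.info("stage integrate: done")

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", report_path)
    return report
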