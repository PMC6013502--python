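"""End-to-end orchestration: simulate -> eQTL scan -> theta clustering ->
DAP matching -> rare-variant burden, driven by one serialisable config.

Every stage consumes a child random generator spawned from the config
seed, so a config (including its seed) determines the full report
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import coloc, crm, eqtl, nullsim, synth
from .containers import GenomicInterval
from .theta import ThetaParams

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "eqtl", "cluster", "coloc", "burden")


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline, with its standard default.

    Paths/stages are plain scalars and lists so the config round-trips
    losslessly through YAML.
    """

    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # cohort
    n_samples: int = 300
    n_variants: int = 300
    block_len: int = 20
    block_r2: float = 0.8
    tissues: list = field(default_factory=lambda: ["T1", "T2", "T3"])
    # planted cis-eQTL: probe_id, causal position (fraction of locus), h2, tissues
    planted: list = field(
        default_factory=lambda: [
            {"probe_id": "probe0", "causal_frac": 0.5, "h2": 0.3, "tissues": ["T1", "T2"]},
            {"probe_id": "probe1", "causal_frac": 0.5, "h2": 0.3, "tissues": ["T1"]},
        ]
    )
    n_null_probes: int = 3
    # eQTL scan
    n_perm: int = 1000
    window_half_width: int = 1_000_000
    corrected_p_max: float = 0.05
    # theta / clustering
    informative_threshold: float = 1.3
    weight_exponent: float = 1.0
    steepness: float = 30.0
    midpoint: float = 0.3
    theta_threshold: float = 0.6
    pairing_radius: float = 2_000_000.0
    prune: list = field(default_factory=list)
    # disease simulation / matching
    disease_F: float = 0.01
    n_cases: int = 2000
    n_controls: int = 2000
    # rare variants / burden
    maf_max: float = 0.005
    rare_relative_risk: float = 3.0
    n_rare_cases: int = 1500
    n_rare_controls: int = 1500
    burden_n_perm: int = 500

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def theta_params(self) -> ThetaParams:
        return ThetaParams(
            weight_exponent=self.weight_exponent,
            steepness=self.steepness,
            midpoint=self.midpoint,
            threshold=self.informative_threshold,
        )


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    stages_run: list
    n_patterns: int = 0
    n_modules: int = 0
    class_percent: dict = field(default_factory=dict)
    module_table: pd.DataFrame | None = None
    match_table: pd.DataFrame | None = None
    best_theta: float = np.nan
    n_matching_modules: int = 0
    burden_table: pd.DataFrame | None = None
    module_burden: pd.DataFrame | None = None
    shift_p: float = np.nan
    lambda_gc: float = np.nan

    def summary(self) -> dict:
        return {
            "config": self.config_hash,
            "seed": self.seed,
            "stages": list(self.stages_run),
            "patterns": self.n_patterns,
            "modules": self.n_modules,
            "class_percent": dict(self.class_percent),
            "matching_modules": self.n_matching_modules,
            "best_theta": None if np.isnan(self.best_theta) else round(self.best_theta, 3),
            "shift_p": None if np.isnan(self.shift_p) else self.shift_p,
        }


def demo_config(seed: int = 0) -> PipelineConfig:
    """Small configuration that completes quickly on one CPU."""
    return PipelineConfig(seed=seed, n_perm=300, burden_n_perm=300)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the toggled stages in order; later stages require earlier
    ones.  An empty stage list validates the config and returns."""
    report = PipelineReport(config.config_hash(), config.seed, list(config.stages))
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    if not config.stages:
        return report
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    # -- simulate ---------------------------------------------------------
    sim = synth.SimulationConfig(
        n_samples=config.n_samples,
        n_variants=config.n_variants,
        block_len=config.block_len,
        block_r2=config.block_r2,
        seed=config.seed,
    )
    geno = synth.simulate_genotypes(sim)
    sim.planted_eqtl = [
        synth.PlantedEqtl(
            p["probe_id"],
            int(p["causal_frac"] * (geno.n_variants - 1)),
            p["h2"],
            tuple(p["tissues"]),
        )
        for p in config.planted
    ]
    expr_by_tissue = synth.simulate_expression(
        geno, sim, tissues=tuple(config.tissues),
        n_null_probes=config.n_null_probes, rng=rngs[0],
    )
    if "eqtl" not in config.stages:
        return report

    # -- eQTL scans and association patterns ------------------------------
    patterns, meta = {}, {}
    for tissue, expr in expr_by_tissue.items():
        summary, results = eqtl.run_tissue_scan(
            expr, geno, n_perm=config.n_perm, rng=rngs[1],
            window_half_width=config.window_half_width,
        )
        for res in results.values():
            if res.empty or res.corrected_p is None:
                continue
            if res.corrected_p > config.corrected_p_max:
                continue
            pos = int(expr.probes.set_index("probe_id").loc[res.probe_id, "pos"])
            pat = eqtl.pattern_from_result(res, probe_pos=pos)
            patterns[pat.trait] = pat
            gene = str(expr.probes.set_index("probe_id").loc[res.probe_id, "gene"])
            meta[pat.trait] = crm.PatternMeta(pat.trait, gene, tissue)
    report.n_patterns = len(patterns)
    if "cluster" not in config.stages:
        return report

    # -- clustering into cRM ----------------------------------------------
    modules, theta_table = crm.cluster_patterns(
        patterns, meta,
        threshold=config.theta_threshold,
        params=config.theta_params(),
        pairing_radius=config.pairing_radius,
        removal_list=[tuple(e) for e in config.prune],
    )
    report.n_modules = len(modules)
    report.class_percent = crm.class_composition(modules) if modules else {}
    report.module_table = pd.DataFrame(
        {
            "module_id": [m.module_id for m in modules],
            "n_members": [len(m.members) for m in modules],
            "n_genes": [len(m.genes) for m in modules],
            "n_tissues": [len(m.tissues) for m in modules],
            "class": [m.label for m in modules],
        }
    )
    if "coloc" not in config.stages:
        return report

    # -- disease pattern and module matching ------------------------------
    causal_index = int(config.planted[0]["causal_frac"] * (geno.n_variants - 1))
    dap, design = nullsim.simulate_dap(
        geno, causal_index, config.disease_F, config.n_cases, config.n_controls, rngs[2]
    )
    locus = GenomicInterval.from_1based(
        str(geno.variants["chrom"].iloc[0]),
        int(geno.variants["pos"].min()),
        int(geno.variants["pos"].max()),
        name="locus1",
    )
    match_table = coloc.match_dap_to_modules(
        dap, modules, patterns, locus,
        threshold=config.theta_threshold, params=config.theta_params(),
    )
    report.match_table = match_table
    if not match_table.empty:
        report.best_theta = float(
            match_table.loc[match_table["theta"].abs().idxmax(), "theta"]
        )
        report.n_matching_modules = int(
            match_table.loc[match_table["matched"], "module_id"].nunique()
        )
    if "burden" not in config.stages:
        return report

    # -- rare-variant burden ----------------------------------------------
    planted_genes = {p["probe_id"].replace("probe", "GENE") for p in config.planted}
    null_genes = [f"NULLG{k}" for k in range(config.n_null_probes)]
    theta_by_gene = {}
    if report.match_table is not None and not report.match_table.empty:
        for gene, grp in report.match_table.groupby("gene"):
            theta_by_gene[gene] = float(grp.loc[grp["theta"].abs().idxmax(), "theta"])
    var_frames, geno_cols = [], []
    for gene in sorted(planted_genes) + null_genes:
        # the planted burden acts in the direction implied by the gene's
        # theta: reduced-expression-risk genes (theta < 0) accumulate
        # disruptive carriers in cases, protective genes in controls
        if gene in planted_genes:
            rr = (
                config.rare_relative_risk
                if theta_by_gene.get(gene, -1.0) < 0
                else 1.0 / config.rare_relative_risk
            )
        else:
            rr = 1.0
        spec = synth.RareVariantSpec(relative_risk={"LoF": rr, "damaging": rr})
        v, g = synth.simulate_rare_variants(
            config.n_rare_cases, config.n_rare_controls, spec, rngs[3], gene=gene
        )
        var_frames.append(v)
        geno_cols.append(g)
    variants = pd.concat(var_frames, ignore_index=True)
    genotypes = np.column_stack(geno_cols)
    status = np.r_[
        np.ones(config.n_rare_cases, dtype=int), np.zeros(config.n_rare_controls, dtype=int)
    ]
    scan = burden_mod.gene_burden_scan(
        variants, genotypes, status, theta_by_gene,
        n_perm=config.burden_n_perm, rng=rngs[4], maf_max=config.maf_max,
    )
    report.burden_table = scan.table()
    report.lambda_gc = scan.lambda_gc
    shift = burden_mod.global_shift_test(scan)
    report.shift_p = shift["shift_p"]
    modules_genes = {
        m.module_id: sorted(m.genes & set(scan.genes))
        for m in modules
        if m.genes & set(scan.genes)
    }
    if modules_genes:
        report.module_burden = burden_mod.module_burden_test(scan, modules_genes)
    return report
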