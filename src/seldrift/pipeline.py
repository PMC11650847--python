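"""End-to-end workflow: simulate -> qc -> Ne -> GWAS -> gene drop -> change analytics.

One root seed drives everything; each stage derives its own stream from the
root seed and the stage name, so reruns with the same config are bit-identical
and stages can be re-run in isolation. All tested quantities are emitted as
TSV/JSON; figures are SVG artifacts of the report stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afdynamics, genedrop, gwas, simulate
from .genotypes import (
    AfTable,
    allele_freq_by_cohort,
    concat_af_tables,
    impute_mean,
    qc_genotypes,
    read_dosage_tsv,
    read_phenotypes,
)
from .pedigree import estimate_ne, generation_interval, mean_kinship_by_year, read_pedigree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the root seed and the stage name."""
    return (int(root_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def record(self, stage: str, status: str, outputs: list[str] | None = None) -> None:
        self.stages[stage] = {"status": status, "outputs": outputs or []}
        self.outputs.extend(outputs or [])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "stages": self.stages, "outputs": sorted(set(self.outputs))},
                fh, indent=2,
            )


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {},  # SimConfig field overrides; omit entirely to use 'inputs'
    "qc": {"animal_miss_max": 0.05, "marker_miss_max": 0.05, "mendel_conflict_max": 0.02},
    "gwas": {"traits": None, "alpha": 0.05},  # traits None = all simulated traits
    "genedrop": {"maf_grid": [round(0.05 * k, 2) for k in range(1, 11)], "n_reps": 200},
    "afchange": {"baseline_year": None},  # None = first simulated year
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, raw)


def run_pipeline(config, out_dir) -> RunManifest:
    """Run all stages in dependency order; abort names the failing stage."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    seed = int(cfg["seed"])
    manifest = RunManifest(chash, seed)
    manifest_path = out / "manifest.json"

    def run_stage(name, fn):
        try:
            outputs = fn()
        except Exception as e:
            manifest.record(name, "failed")
            manifest.write(manifest_path)
            raise PipelineError(name, e) from e
        manifest.record(name, "ok", outputs)
        manifest.write(manifest_path)
        return outputs

    state: dict = {}

    # -- simulate (or load provided inputs)
    def do_simulate():
        if "inputs" in cfg:
            state["paths"] = dict(cfg["inputs"])
            return []
        sim_cfg_kwargs = dict(cfg.get("simulate") or {})
        if "traits" in sim_cfg_kwargs:
            sim_cfg_kwargs["traits"] = tuple(
                simulate.TraitSpec(**t) for t in sim_cfg_kwargs["traits"]
            )
        if "years" in sim_cfg_kwargs:
            sim_cfg_kwargs["years"] = tuple(sim_cfg_kwargs["years"])
        sim_cfg = simulate.SimConfig(**sim_cfg_kwargs)
        rng = np.random.default_rng(stage_seed(seed, "simulate"))
        res = simulate.simulate_population(sim_cfg, rng)
        paths = simulate.write_dataset(res, out / "data")
        state["paths"] = paths
        state["sim_years"] = sim_cfg.years
        return list(paths.values())

    run_stage("simulate", do_simulate)

    # -- load + qc
    def do_qc():
        paths = state["paths"]
        ped, _ = read_pedigree(paths["pedigree"])
        if not Path(paths["phenotypes"]).exists():
            raise FileNotFoundError(paths["phenotypes"])
        pheno = read_phenotypes(paths["phenotypes"])
        geno = read_dosage_tsv(paths["genotypes"], marker_map=paths.get("marker_map"))
        qc_kwargs = dict(cfg["qc"])
        lines = {r.animal_id: r.line for r in ped.records}
        geno_qc, report = qc_genotypes(geno, ped, lines=lines, **qc_kwargs)
        geno_qc = impute_mean(geno_qc)
        state.update(ped=ped, pheno=pheno, geno=geno_qc)
        rpt = out / "qc_report.json"
        report.to_json(rpt)
        return [str(rpt)]

    run_stage("qc", do_qc)

    # -- effective population size
    def do_ne():
        ped = state["ped"]
        rows = []
        for line in ped.lines or [None]:
            series = mean_kinship_by_year(ped, line=line)
            L, _ = generation_interval(ped, ped.genotyped_ids(line))
            rows.append(estimate_ne(series, L).to_dict())
        path = out / "ne.json"
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
        state["ne"] = rows
        return [str(path)]

    run_stage("ne", do_ne)

    # -- allele frequencies per cohort
    def do_af():
        ped, geno = state["ped"], state["geno"]
        geno_set = set(geno.animal_ids)
        tables = []
        for line in ped.lines or [""]:
            cohorts = {
                y: [i for i in ids if i in geno_set]
                for y, ids in ped.cohorts(line=line).items()
            }
            cohorts = {y: ids for y, ids in cohorts.items() if ids}
            tables.append(
                allele_freq_by_cohort(
                    geno, cohorts, line=line,
                    counted_alleles={m: "ALT" for m in geno.marker_ids},
                )
            )
        af = concat_af_tables(tables)
        state["af"] = af
        path = out / "allele_freqs.tsv"
        af.write_tsv(path)
        return [str(path)]

    run_stage("allele_freqs", do_af)

    # -- GWAS per line and trait (all years pooled)
    def do_gwas():
        ped, pheno, geno = state["ped"], state["pheno"], state["geno"]
        traits = cfg["gwas"].get("traits")
        if traits is None:
            reserved = {"animal_id", "line", "year", "sex", "batch", "litter", "index"}
            traits = [
                c for c in pheno.columns
                if c not in reserved and not c.startswith("tbv_") and pheno[c].dtype.kind == "f"
            ]
        outputs = []
        state["gwas"] = {}
        for line in ped.lines or [""]:
            line_ids = [a for a in geno.animal_ids if not line or ped.records[ped.index[a]].line == line]
            g_line = geno.subset(animals=line_ids)
            # drop markers monomorphic within the line (not estimable, break the GRM)
            freqs = g_line.allele_frequencies()
            poly = [m for m, p in zip(g_line.marker_ids, freqs) if 0 < p < 1]
            g_line = g_line.subset(markers=poly)
            grm = gwas.compute_grm(g_line)
            ph_line = pheno[pheno["animal_id"].isin(line_ids)] if line else pheno
            for trait in traits:
                design = gwas.build_design(
                    ph_line, trait, g_line.animal_ids,
                    fixed=cfg["gwas"].get("fixed", ["sex"]) if trait != "index" else [],
                    random=cfg["gwas"].get("random", []),
                )
                vc = gwas.reml_null(design, grm)
                res = gwas.snp_scan(design, grm, vc, g_line)
                path = out / f"gwas_{line or 'all'}_{trait}.tsv"
                res.write_tsv(path)
                outputs.append(str(path))
                state["gwas"][(line, trait)] = res
        state["bonferroni"] = gwas.bonferroni_threshold(
            cfg["gwas"].get("alpha", 0.05), geno.n_markers
        )
        return outputs

    run_stage("gwas", do_gwas)

    # -- gene dropping drift envelopes
    def do_genedrop():
        ped, af = state["ped"], state["af"]
        baseline = cfg["afchange"].get("baseline_year") or min(
            y for line in af.lines for y in af.years(line)
        )
        geno_set = set(state["geno"].animal_ids)
        cohorts = {}
        for line in ped.lines or [""]:
            for y, ids in ped.cohorts(line=line).items():
                ids = [i for i in ids if i in geno_set]
                if ids:
                    cohorts[(line, y)] = ids
        gd_cfg = genedrop.GeneDropConfig(
            cohorts=cohorts,
            baseline_year=baseline,
            maf_grid=np.asarray(cfg["genedrop"]["maf_grid"]),
            n_reps=int(cfg["genedrop"]["n_reps"]),
            seed=stage_seed(seed, "genedrop"),
        )
        traj = genedrop.run_gene_dropping(ped, gd_cfg)
        env = genedrop.drift_change_distribution(traj)
        path = out / "drift_envelope.tsv"
        env.write_tsv(path)
        state["envelope"] = env
        state["baseline"] = baseline
        return [str(path)]

    run_stage("genedrop", do_genedrop)

    # -- allele-frequency-change analytics
    def do_afchange():
        af, env = state["af"], state["envelope"]
        baseline = state["baseline"]
        chg = afdynamics.abs_change_vs_baseline(af, baseline)
        outputs = []
        p1 = out / "af_change.tsv"
        chg.write_tsv(p1)
        outputs.append(str(p1))
        strat = afdynamics.maf_stratified_summary(chg)
        p2 = out / "af_change_by_maf.tsv"
        strat.to_csv(p2, sep="\t", index=False)
        outputs.append(str(p2))
        cmp_rpt = genedrop.compare_to_drift(chg, env)
        p3 = out / "drift_comparison.json"
        with open(p3, "w") as fh:
            json.dump(cmp_rpt.summary, fh, indent=2)
        outputs.append(str(p3))
        regs = []
        for (line, trait), res in state["gwas"].items():
            for year in af.years(line)[:-1]:
                try:
                    nyc = afdynamics.consecutive_year_change(af, line, year)
                    regs.append(
                        afdynamics.change_vs_gwas_regression(nyc, res, line=line, year=year).to_dict()
                    )
                except ValueError:
                    continue
        p4 = out / "change_vs_gwas.json"
        with open(p4, "w") as fh:
            json.dump(regs, fh, indent=2)
        outputs.append(str(p4))
        lines = af.lines
        if len(lines) == 2:
            chg_by_line = {
                ln: afdynamics.AfChangeTable(chg.for_line(ln), baseline, chg.counted_alleles)
                for ln in lines
            }
            last = max(af.years(lines[0]))
            r2 = afdynamics.between_line_correlation(
                chg_by_line[lines[0]], chg_by_line[lines[1]], last
            )
            p5 = out / "between_line_r2.json"
            with open(p5, "w") as fh:
                json.dump({"year": last, "r2_signed_dp": r2}, fh, indent=2)
            outputs.append(str(p5))
        state["chg"] = chg
        return outputs

    run_stage("afchange", do_afchange)

    # -- report
    def do_report():
        outputs = [str(p) for p in _render_report(state, cfg, out)]
        return outputs

    run_stage("report", do_report)
    manifest.write(manifest_path)
    return manifest


def _render_report(state, cfg, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = []
    chg = state["chg"]
    thr = state["bonferroni"]
    for line in chg.frame["line"].unique():
        last = chg.frame[chg.frame["line"] == line]["year"].max()
        sub = chg.frame[(chg.frame["line"] == line) & (chg.frame["year"] == last)]
        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.scatter(range(len(sub)), sub["abs_dp"], s=2, c="steelblue")
        ax.set(xlabel="marker", ylabel=f"|dp| {state['baseline']}->{last}",
               title=f"line {line}: absolute allele-frequency change")
        p = out / f"af_change_{line}.svg"
        fig.savefig(p)
        plt.close(fig)
        outputs.append(p)
    for (line, trait), res in state["gwas"].items():
        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.scatter(range(len(res.frame)), res.frame["neglog10p"], s=2, c="darkslategray")
        ax.axhline(thr, ls=":", c="red")
        ax.set(xlabel="marker", ylabel="-log10 p", title=f"line {line}, {trait}")
        p = out / f"manhattan_{line or 'all'}_{trait}.svg"
        fig.savefig(p)
        plt.close(fig)
        outputs.append(p)
    # markdown summary
    md = out / "report.md"
    with open(md, "w") as fh:
        fh.write("# seldrift run summary\n\n")
        fh.write(f"Bonferroni threshold (-log10 p): {thr:.2f}\n\n")
        fh.write("## Effective population size\n\n")
        for row in state["ne"]:
            fh.write(
                f"- line {row['line']}: dF/year = {row['delta_f_year']:.4f}, "
                f"L = {row['generation_interval_L']:.2f} y, Ne = {row['ne_rounded']}\n"
            )
        fh.write("\n## Figures\n\n")
        for p in outputs:
            fh.write(f"- {p.name}\n")
    outputs.append(md)
    return outputs
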