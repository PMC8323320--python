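"""Stage orchestration: simulate, estimate, evaluate, design schemes.

Each stage reads its inputs from the output directory of the previous
stage (or from user-supplied files), writes its artifacts, and records
seeds and content hashes in ``manifest.json`` so that a run is fully
reproducible from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .breeding import BreedingConfig, run_breeding_program, sample_genotyped_sets
from .config import RunConfig
from .genome import (
    GenomeSpec,
    HaplotypePanel,
    assign_qtl_effects,
    filter_loci_by_maf,
    simulate_historical_panel,
)
from .genomic import run_analysis
from .metrics import evaluate_analysis
from .schemes import SchemeGrid, enumerate_and_optimize

__all__ = ["run_pipeline", "STAGES"]

STAGES = (
    "simulate-historical",
    "simulate-breeding",
    "estimate-ebv",
    "evaluate",
    "design-schemes",
)


class StageDependencyError(FileNotFoundError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(
            f"stage {stage!r} needs missing artifact {path.name!r}; "
            "run the upstream stage first"
        )
    return path


def _genome_spec(g: dict) -> GenomeSpec:
    return GenomeSpec.uniform(
        n_loci=g["n_loci"],
        n_chromosomes=g["n_chromosomes"],
        total_length_mb=g["total_length_mb"],
        recombination_rate=g["recombination_rate"],
        mutation_rate=g["mutation_rate"],
    )


def run_pipeline(
    config: RunConfig,
    stages: list[str] | tuple[str, ...] = STAGES,
    outdir: str | Path = "beegs_run",
    accuracy_csv: str | Path | None = None,
) -> dict:
    """Execute the requested stages, returning the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("seed", config.seed)
    manifest.setdefault("stages", {})
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(STAGES, root.spawn(len(STAGES)))}
    artifacts: dict[str, Path] = {}

    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        rng = np.random.default_rng(stage_seeds[stage])
        written: list[Path] = []

        if stage == "simulate-historical":
            g = config.genome
            spec = _genome_spec(g)
            panel = simulate_historical_panel(
                spec,
                g["historical_queens"],
                g["historical_years"],
                seed=rng,
                expansion_size=g.get("expansion_size"),
                expansion_years=g.get("expansion_years", 0),
            )
            panel, kept = filter_loci_by_maf(panel, g["maf_threshold"])
            np.save(out / "panel_haplotypes.npy", panel.haplotypes)
            sidecar = {
                "n_queens": panel.n_queens,
                "n_loci": panel.spec.n_loci,
                "kept_loci": kept.tolist(),
                "generation_label": panel.generation_label,
                "genome": {k: v for k, v in g.items()},
            }
            (out / "panel_meta.json").write_text(json.dumps(sidecar, indent=1))
            with open(out / "panel.pkl", "wb") as fh:
                pickle.dump(panel, fh)
            written = [out / "panel_haplotypes.npy", out / "panel_meta.json"]

        elif stage == "simulate-breeding":
            with open(_require(out / "panel.pkl", stage), "rb") as fh:
                panel: HaplotypePanel = pickle.load(fh)
            qtl = assign_qtl_effects(
                panel, config.genome["n_qtl"], config.trait_base.V_a, seed=rng
            )
            cfg = BreedingConfig(**config.population)
            history = run_breeding_program(
                cfg, panel, qtl, config.trait_base, seed=rng
            )
            with open(out / "history.pkl", "wb") as fh:
                pickle.dump(history, fh)
            history.pedigree().to_frame().to_csv(out / "pedigree.csv", index=False)
            history.phenotype_frame().to_csv(out / "phenotypes.csv", index=False)
            written = [out / "pedigree.csv", out / "phenotypes.csv"]

        elif stage == "estimate-ebv":
            with open(_require(out / "history.pkl", stage), "rb") as fh:
                history = pickle.load(fh)
            ev = config.evaluation
            tables = []
            ebv_pblup = run_analysis(history, "PBLUP", config.trait_base)
            ebv_pblup.to_csv(out / "ebv_PBLUP.csv", index=False)
            tables.append(("PBLUP", None, None, ebv_pblup))
            for p_ref in ev["p_ref_grid"]:
                geno = sample_genotyped_sets(
                    history, p_ref, include_dpq=True, seed=rng,
                    bq_years=(4, history.config.years - 3),
                    extra_years=(history.config.years - 2, history.config.years - 1),
                    dpq_deploy_years=(4, history.config.years - 1),
                )
                for mode in ev["modes"]:
                    if mode == "PBLUP":
                        continue
                    ebv = run_analysis(
                        history, mode, config.trait_base, genotyped=geno
                    )
                    tag = f"{mode}_pref{p_ref}".replace("+", "")
                    ebv.to_csv(out / f"ebv_{tag}.csv", index=False)
                    tables.append((mode, p_ref, geno, ebv))
            with open(out / "ebv_tables.pkl", "wb") as fh:
                pickle.dump(tables, fh)
            written = sorted(out.glob("ebv_*.csv"))

        elif stage == "evaluate":
            with open(_require(out / "ebv_tables.pkl", stage), "rb") as fh:
                tables = pickle.load(fh)
            with open(_require(out / "history.pkl", stage), "rb") as fh:
                history = pickle.load(fh)
            rows = []
            for mode, p_ref, geno, ebv in tables:
                rep = evaluate_analysis(
                    ebv,
                    history,
                    genotyped_bq=geno["bq"] if geno else None,
                )
                row = rep.as_dict()
                row["p_ref"] = p_ref if p_ref is not None else 0.0
                rows.append(row)
            acc = pd.DataFrame(rows)
            acc.to_csv(out / "accuracy.csv", index=False)
            (out / "accuracy.json").write_text(
                json.dumps(rows, indent=1, default=float)
            )
            written = [out / "accuracy.csv", out / "accuracy.json"]

        elif stage == "design-schemes":
            if accuracy_csv is not None:
                acc = pd.read_csv(accuracy_csv)
            else:
                acc = pd.read_csv(_require(out / "accuracy.csv", stage))
            sigma_pW = float(acc.sigma_pW.iloc[0])
            sigma_uQ = float(acc.sigma_uQ.iloc[0])
            grid = SchemeGrid(budgets=tuple(config.scheme["budgets"]))
            optima = enumerate_and_optimize(acc, sigma_pW, sigma_uQ, grid=grid)
            optima.to_csv(out / "scheme_optima.csv", index=False)
            (out / "scheme_optima.json").write_text(
                optima.to_json(orient="records", indent=1)
            )
            written = [out / "scheme_optima.csv", out / "scheme_optima.json"]

        manifest["stages"][stage] = {
            "seed_entropy": int(stage_seeds[stage].entropy),
            "spawn_key": [int(k) for k in stage_seeds[stage].spawn_key],
            "duration_s": round(time.time() - t0, 3),
            "artifacts": {p.name: _sha256(p) for p in written},
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))

    return manifest
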