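"""End-to-end pipeline over simulated panels.

``run_pipeline`` chains the stages simulate -> fit -> effect estimation ->
imputation -> prediction -> permutation baseline on a YAML/dict
configuration, writing every artifact as TSV/JSON under an output directory
together with a run manifest (config snapshot, master seed, artifact
digests). Outputs are a pure function of the configuration and seed, so a
rerun regenerates bit-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._errors import InputError
from ._rng import spawn_seeds
from . import io as hio
from .effects import hare_from_panel, impute_expression
from .haplo import panel_summary
from .permtest import PermutationScheme, run_permutation_study
from .popsim import (
    FounderSet,
    SimScenario,
    simulate_diverse_panel,
    simulate_expression,
    simulate_nam_panel,
    simulate_phenotype,
)
from .predict import evaluate_within_panel
from .varcomp import fit_panel

log = logging.getLogger("hare.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "panel": "diverse",  # "nam" or "diverse"
        "n_founders": 26,
        "n_ranges": 40,
        "n_lines": 150,
        "n_families": 25,
        "rils_per_family": 200,
        "crossovers_per_range_set": 30.0,
        "mosaic_block_mean": 20.0,
        "n_genes": 30,
        "cis_share": 1.0 / 3.0,
        "heritability": 0.55,
        "n_tissues": 1,
        "trans_tissue_corr": 0.5,
        "n_causal_genes": 8,
        "trait_noise": 0.5,
    },
    "fit": {"model": 3},
    "predict": {"n_repeats": 20, "train_frac": 0.8},
    "permute": {"k": 100},
}


def load_config(path_or_dict: str | Path | dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    s_sim, s_trait, s_eval, s_perm = spawn_seeds(seed, 4)
    sim_cfg = cfg["simulate"]
    artifacts: dict[str, Path] = {}

    founders = FounderSet(
        n_founders=int(sim_cfg["n_founders"]), n_ranges=int(sim_cfg["n_ranges"])
    )
    log.info("simulating %s panel", sim_cfg["panel"])
    if sim_cfg["panel"] == "nam":
        panel = simulate_nam_panel(
            founders,
            n_families=int(sim_cfg["n_families"]),
            rils_per_family=int(sim_cfg["rils_per_family"]),
            crossovers_per_range_set=float(sim_cfg["crossovers_per_range_set"]),
            seed=s_sim,
        )
    elif sim_cfg["panel"] == "diverse":
        panel = simulate_diverse_panel(
            founders,
            n_lines=int(sim_cfg["n_lines"]),
            mosaic_block_mean=float(sim_cfg["mosaic_block_mean"]),
            seed=s_sim,
        )
    else:
        raise InputError(f"unknown panel type: {sim_cfg['panel']}")

    scenario = SimScenario(
        n_genes=int(sim_cfg["n_genes"]),
        cis_share=float(sim_cfg["cis_share"]),
        heritability=float(sim_cfg["heritability"]),
        n_tissues=int(sim_cfg["n_tissues"]),
        trans_tissue_corr=float(sim_cfg["trans_tissue_corr"]),
        seed=s_sim,
    )
    sim = simulate_expression(panel, scenario)
    pheno = simulate_phenotype(
        sim.truth,
        n_causal_genes=int(sim_cfg["n_causal_genes"]),
        trait_noise=float(sim_cfg["trait_noise"]),
        seed=s_trait,
    )

    hio.write_haplotypes_tsv(panel, out / "haplotypes.tsv")
    hio.write_ranges_bed(panel.ranges, out / "ranges.bed")
    artifacts["haplotypes"] = out / "haplotypes.tsv"
    artifacts["ranges"] = out / "ranges.bed"
    for t, mat in sim.expression.items():
        p = out / f"expression_{t}.tsv"
        hio.write_expression_tsv(mat, p)
        artifacts[f"expression_{t}"] = p
    hio.write_phenotypes_tsv(pheno.values.to_frame(), out / "phenotypes.tsv")
    artifacts["phenotypes"] = out / "phenotypes.tsv"

    summary = panel_summary(panel)
    pd.DataFrame(
        {"entropy": summary.entropy}
    ).to_csv(out / "entropy.tsv", sep="\t", index_label="range_id")
    artifacts["entropy"] = out / "entropy.tsv"

    model = int(cfg["fit"]["model"])
    tissue0 = sim.tissues[0]
    log.info("fitting model %d for %d genes", model, scenario.n_genes)
    fits = fit_panel(sim.expression[tissue0], panel, model=model)
    fits.to_csv(out / "varcomp.tsv", sep="\t")
    artifacts["varcomp"] = out / "varcomp.tsv"

    hare = hare_from_panel(
        sim.expression[tissue0], panel, founders.haplotype_universe,
        model=model, tissue=tissue0,
    )
    hio.write_hare_tsv(hare, out / f"hare_{tissue0}.tsv")
    artifacts["hare"] = out / f"hare_{tissue0}.tsv"

    imputed = impute_expression(hare, panel)
    hio.write_matrix_tsv(imputed.values, out / f"imputed_{tissue0}.tsv")
    artifacts["imputed"] = out / f"imputed_{tissue0}.tsv"

    pred_cfg = cfg["predict"]
    result = evaluate_within_panel(
        imputed.values, pheno.values,
        n_repeats=int(pred_cfg["n_repeats"]),
        train_frac=float(pred_cfg["train_frac"]),
        seed=s_eval,
    )
    pd.DataFrame(
        {"repeat": range(len(result.accuracies)), "accuracy": result.accuracies}
    ).to_csv(out / "prediction.tsv", sep="\t", index=False)
    artifacts["prediction"] = out / "prediction.tsv"

    perm_cfg = cfg["permute"]
    outcome = run_permutation_study(
        hare, panel, pheno.values,
        scheme=PermutationScheme(k=int(perm_cfg["k"]), seed=s_perm),
        protocol="within",
        n_repeats=int(pred_cfg["n_repeats"]),
        train_frac=float(pred_cfg["train_frac"]),
    )
    perm_path = out / "permutation.json"
    pd.Series(
        {
            "observed_mean_accuracy": outcome.observed_mean,
            "permuted_mean_accuracy": float(outcome.permuted_means.mean()),
            "p_high": outcome.p_high,
            "p_low": outcome.p_low,
            "k": int(perm_cfg["k"]),
        }
    ).to_json(perm_path, indent=2)
    artifacts["permutation"] = perm_path

    manifest = hio.write_manifest(
        out / "manifest.json", cfg, seed, artifacts,
        extra={
            "median_haplotype_frequency": summary.median_frequency,
            "median_entropy": summary.median_entropy,
        },
    )
    return manifest
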