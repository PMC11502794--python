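"""Model-validation experiments: null calibration and planted-signal recovery.

These run the package's own generator and tests against each other: null
simulations measure the raw type-I error of the two Wald tests, and planted
simulations measure sensitivity / empirical FDR against the recorded truth.
All experiments are deterministic given their seed. Group size defaults to
three replicates per group for the module-level experiments; the end-to-end
switch experiment runs the full pipeline at the study design (two replicates
per cell).
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .counts import call_dhml, nb_wald_test
from .design import make_design, samples_for
from .dml import dml_test
from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimulationConfig, simulate_rnaseq, simulate_rrbs, simulate_rrhp

RECOVERY_COMPARISON = "glial_undiff_vs_MacCM"


def _groups(design, n_per_group, condition_b="MacCM"):
    a = samples_for(design, line="glial", condition="undiff")[:n_per_group]
    b = samples_for(design, line="glial", condition=condition_b)[:n_per_group]
    return a, b


def null_calibration_bb(n_loci: int = 5000, n_per_group: int = 3,
                        seed: int = 0) -> dict:
    """Fraction of raw beta-binomial Wald p-values below 0.05 under the null."""
    if n_loci % 4:
        raise ValueError("n_loci must be a multiple of cpgs_per_gene=4")
    config = SimulationConfig(
        n_genes=n_loci // 4, frac_true=0.0, planted_delta=0.0,
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000}, seed=seed,
    )
    design = make_design(n_replicates=n_per_group)
    table, _ = simulate_rrbs(config, design)
    a, b = _groups(design, n_per_group, condition_b="DM")  # both null
    res = dml_test(table, a, b)
    p = res["p"].to_numpy()
    return {"fraction_p_below_0.05": float((p < 0.05).mean()),
            "n_tests": int(len(p))}


def null_calibration_nb(n_features: int = 1000, n_per_group: int = 3,
                        seed: int = 0) -> dict:
    """Fraction of raw NB Wald p-values below 0.05 under the null."""
    config = SimulationConfig(
        n_genes=n_features, frac_true=0.0, planted_lfc=0.0,
        mean_log_sigma_rna=0.0,
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000}, seed=seed,
    )
    design = make_design(n_replicates=n_per_group)
    table, _ = simulate_rnaseq(config, design)
    a, b = _groups(design, n_per_group, condition_b="DM")
    res = nb_wald_test(table, a, b)
    p = res["p"].to_numpy()
    return {"fraction_p_below_0.05": float((p < 0.05).mean()),
            "n_tests": int(len(p))}


def _score(called: set, truth: set) -> dict:
    tp = len(called & truth)
    return {
        "sensitivity": tp / len(truth) if truth else None,
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_true": len(truth),
        "n_called": len(called),
    }


def dml_recovery(n_genes: int = 500, n_per_group: int = 3,
                 seed: int = 0) -> dict:
    """Recovery of planted methylation differences (delta = planted_delta,
    coverage = mean_coverage) by the beta-binomial test."""
    config = SimulationConfig(n_genes=n_genes, seed=seed)
    design = make_design(n_replicates=n_per_group)
    table, truth = simulate_rrbs(config, design)
    a, b = _groups(design, n_per_group)
    res = dml_test(table, a, b)
    called = {
        f"{c}:{p}:{s}" for c, p, s in zip(
            res.loc[res["significant"], "chrom"],
            res.loc[res["significant"], "pos"],
            res.loc[res["significant"], "strand"])
    }
    return _score(called, truth.feature_ids(RECOVERY_COMPARISON))


def nb_recovery(modality: str = "RNA", n_genes: int = 2000,
                n_per_group: int = 3, seed: int = 0) -> dict:
    """Recovery of planted log2 fold changes by the NB test (RNA genes or
    strand-specific 5hmC tag counts)."""
    if modality == "RNA":
        config = SimulationConfig(
            n_genes=n_genes, mean_log_sigma_rna=0.0,
            chrom_lengths={"chr1": 12_000_000, "chr2": 12_000_000}, seed=seed)
        design = make_design(n_replicates=n_per_group)
        table, truth = simulate_rnaseq(config, design)
        test = nb_wald_test
    elif modality == "5hmC":
        config = SimulationConfig(
            n_genes=n_genes, mean_log_sigma_tags=0.0,
            chrom_lengths={"chr1": 12_000_000, "chr2": 12_000_000}, seed=seed)
        design = make_design(n_replicates=n_per_group)
        table, truth = simulate_rrhp(config, design)
        test = call_dhml
    else:
        raise ValueError("modality must be 'RNA' or '5hmC'")
    a, b = _groups(design, n_per_group)
    res = test(table, a, b)
    called = set(res.loc[res["significant"], "feature_id"])
    return _score(called, truth.feature_ids(RECOVERY_COMPARISON))


def switch_recovery(seed: int = 0, n_genes: int = 300,
                    out_dir: str | None = None) -> dict:
    """End-to-end reciprocal-switch recovery at the full study design."""
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return switch_recovery(seed=seed, n_genes=n_genes, out_dir=tmp)
    cfg = PipelineConfig(simulation=SimulationConfig(n_genes=n_genes),
                         seed=seed, out_dir=str(Path(out_dir)))
    summary = run_pipeline(cfg)
    return dict(summary["recovery"]["switch"])


def summary_determinism(seed: int = 0, n_genes: int = 40) -> bool:
    """True iff two pipeline runs at the same seed write byte-identical
    summaries."""
    payloads = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as tmp:
            cfg = PipelineConfig(simulation=SimulationConfig(n_genes=n_genes),
                                 seed=seed, out_dir=tmp)
            run_pipeline(cfg)
            payloads.append((Path(tmp) / "summary.json").read_bytes())
    return payloads[0] == payloads[1]
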