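"""End-to-end orchestration: simulate -> differential calls -> annotation ->
patterns -> summary, plus exploratory utilities (PCA, hierarchical
clustering, delta-delta-Ct).

The study's pairwise design is encoded in :func:`epipattern.simulate.study_comparisons`:
per cell line, undifferentiated vs each differentiation environment (normal
medium DM, inflammatory Mac-CM), plus the undifferentiated line contrast.
Patterns at the undifferentiated stage come from the line contrast; patterns
at the differentiated stage, per environment, from the union of the
undiff-vs-environment comparisons over lines.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import annotate as ann
from . import io as epio
from . import patterns as pat
from .counts import NegativeBinomialDE, size_factors
from .design import make_design
from .dml import BetaBinomialDML
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("epipattern")


@dataclass
class PipelineConfig:
    """Thresholds, simulation parameters and output location."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    min_delta: float = 0.10
    lfc_threshold: float = 1.0
    min_coverage: int = 5
    flank: int = 2000
    out_dir: str = "epipattern_out"
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "min_delta", "lfc_threshold", "flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _recovery(called: set, truth: set, universe_size: int) -> dict:
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    return {
        "n_called": len(called),
        "n_true": len(truth),
        "sensitivity": tp / len(truth) if truth else None,
        "fdr": fp / len(called) if called else 0.0,
        "n_false_negative": fn,
        "n_features": universe_size,
    }


def run_pipeline(config: PipelineConfig, dataset: dict | None = None) -> dict:
    """Run the full analysis; writes stage outputs under ``config.out_dir``
    and returns the machine-readable summary (also written as JSON)."""
    t0 = time.time()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        logger.info("simulating dataset (seed=%d)", config.seed)
        dataset = simulate_dataset(config.simulation)
    genes = dataset["genes"]
    comps = dataset["comparisons"]
    chrom_lengths = config.simulation.chrom_lengths

    epio.write_methylation_table(dataset["rrbs"], out / "rrbs_counts.tsv")
    epio.write_count_matrix(dataset["rrhp"], out / "rrhp_counts.tsv")
    epio.write_count_matrix(dataset["rna"], out / "rna_counts.tsv")
    epio.write_annotation_bed(genes, out / "annotation.bed")
    for key in ("rrbs_truth", "rrhp_truth", "rna_truth"):
        dataset[key].write(out / f"{key}.json")

    summary: dict = {"comparisons": {}, "recovery": {}, "patterns": {},
                     "seed": config.seed}
    all_hits = []
    rrhp_ids = list(dataset["rrhp"].index)
    locus_of_tag = {
        fid: tuple(fid.split(":")) for fid in rrhp_ids
    }

    for comp in comps:
        label = comp["label"]
        stage_t = time.time()
        # --- 5mC -----------------------------------------------------------
        dml_model = BetaBinomialDML.from_table(
            dataset["rrbs"], comp["group_a"], comp["group_b"])
        dml_res = dml_model.fit(alpha=config.alpha, min_delta=config.min_delta,
                                min_coverage=config.min_coverage)
        dml_res.to_tsv(out / f"dml_{label}.tsv")
        sig_dml = dml_res.significant
        dml_loci = list(zip(sig_dml["chrom"], sig_dml["pos"], sig_dml["strand"]))
        dml_dirs = {tuple(l): d for l, d in zip(dml_loci, sig_dml["delta"])}
        regions = ann.extend_and_merge(dml_loci, flank=config.flank,
                                       chrom_lengths=chrom_lengths)
        ann.regions_to_bed(regions).to_csv(
            out / f"dml_regions_{label}.bed", sep="\t", index=False, header=False)
        hits_5mc = ann.assign_regions_to_genes(
            regions, genes, "5mC", label, directions=dml_dirs)

        # --- 5hmC ----------------------------------------------------------
        dhml_model = NegativeBinomialDE.from_table(
            dataset["rrhp"], comp["group_a"], comp["group_b"])
        dhml_res = dhml_model.fit(alpha=config.alpha,
                                  lfc_threshold=config.lfc_threshold)
        dhml_res.to_tsv(out / f"dhml_{label}.tsv")
        sig_dhml = dhml_res.significant
        dhml_loci = [
            (locus_of_tag[f][0], int(locus_of_tag[f][1]), locus_of_tag[f][2])
            for f in sig_dhml["feature_id"]
        ]
        dhml_dirs = {l: v for l, v in zip(dhml_loci, sig_dhml["log2fc"])}
        regions_h = ann.extend_and_merge(dhml_loci, flank=config.flank,
                                         chrom_lengths=chrom_lengths)
        hits_5hmc = ann.assign_regions_to_genes(
            regions_h, genes, "5hmC", label, directions=dhml_dirs)

        # --- RNA -----------------------------------------------------------
        deg_model = NegativeBinomialDE.from_table(
            dataset["rna"], comp["group_a"], comp["group_b"])
        deg_res = deg_model.fit(alpha=config.alpha,
                                lfc_threshold=config.lfc_threshold)
        deg_res.to_tsv(out / f"deg_{label}.tsv")
        hits_rna = ann.rna_gene_hits(deg_res.frame, label)

        n_up = int((deg_res.significant["log2fc"] > 0).sum())
        n_down = int((deg_res.significant["log2fc"] < 0).sum())
        if n_up + n_down != len(deg_res.significant):
            raise AssertionError("DEG direction partition violated")

        hits = pd.concat([hits_5mc, hits_5hmc, hits_rna], ignore_index=True)
        all_hits.append(hits)
        summary["comparisons"][label] = {
            "n_loci_tested_5mC": dml_res.n_retained,
            "n_dml": int(len(sig_dml)),
            "n_dhml": int(len(sig_dhml)),
            "n_deg": int(len(deg_res.significant)),
            "n_deg_up": n_up,
            "n_deg_down": n_down,
            "n_merged_regions_5mC": len(regions),
            "n_gene_hits": int(len(hits)),
        }
        logger.info("comparison %s done in %.1fs", label, time.time() - stage_t)

    gene_hits = pd.concat(all_hits, ignore_index=True)
    gene_hits.to_csv(out / "gene_hits.tsv", sep="\t", index=False)
    tf_hits = ann.filter_tfs(gene_hits, genes)
    tf_hits.to_csv(out / "tf_hits.tsv", sep="\t", index=False)

    # --- patterns / trackability / switching ------------------------------
    undiff_hits = gene_hits[gene_hits["comparison"] == "undiff_glial_vs_neural"]
    undiff_patterns = pat.patterns_from_hits(undiff_hits, "undiff")
    track_records = []
    env_hits = {}
    for env in ("DM", "MacCM"):
        labels = [c["label"] for c in comps if c["environment"] == env]
        hits_env = gene_hits[gene_hits["comparison"].isin(labels)]
        env_hits[env] = hits_env
        diff_patterns = pat.patterns_from_hits(hits_env, f"diff_{env}")
        track_records.extend(
            pat.classify_trackability(undiff_patterns, diff_patterns, env))
        summary["patterns"][env] = {
            "n_genes_detected": len(diff_patterns),
            "pattern_counts": {
                str(pid): sum(1 for p in diff_patterns.values()
                              if p.pattern_id == pid)
                for pid in range(1, pat.N_PATTERNS + 1)
            },
        }
    switch_calls = pat.detect_switch(env_hits["DM"], env_hits["MacCM"])
    pat.track_records_frame(track_records).to_csv(
        out / "track_records.tsv", sep="\t", index=False)
    pd.DataFrame([(c.gene_id, c.switch_class) for c in switch_calls],
                 columns=["gene_id", "switch_class"]).to_csv(
        out / "switch_calls.tsv", sep="\t", index=False)
    summary_table = pat.summarize_patterns(track_records, switch_calls)
    summary_table.to_csv(out / "pattern_summary.tsv", sep="\t", index=False)
    summary["patterns"]["undiff_n_genes"] = len(undiff_patterns)
    summary["patterns"]["track_status"] = {
        f"{r.environment}:{r.status}": 0 for r in track_records}
    for r in track_records:
        summary["patterns"]["track_status"][f"{r.environment}:{r.status}"] += 1
    summary["patterns"]["switch_counts"] = {
        cls: sum(1 for c in switch_calls if c.switch_class == cls)
        for cls in ("gain5mC_loss5hmC", "gain5hmC_loss5mC", "none")
    }

    # --- recovery against planted truth ------------------------------------
    truths = {"5mC": dataset["rrbs_truth"], "5hmC": dataset["rrhp_truth"],
              "RNA": dataset["rna_truth"]}
    results_files = {"5mC": "dml", "5hmC": "dhml", "RNA": "deg"}
    for modality, truth in truths.items():
        per_comp = {}
        for comp in comps:
            label = comp["label"]
            res = pd.read_csv(out / f"{results_files[modality]}_{label}.tsv",
                              sep="\t")
            if modality == "5mC":
                called = {
                    f"{c}:{p}:{s}" for c, p, s in zip(
                        res.loc[res["significant"], "chrom"],
                        res.loc[res["significant"], "pos"],
                        res.loc[res["significant"], "strand"])
                }
                universe = dataset["rrbs"].shape[0]
            else:
                called = set(res.loc[res["significant"], "feature_id"])
                universe = (dataset["rrhp"] if modality == "5hmC"
                            else dataset["rna"]).shape[0]
            per_comp[label] = _recovery(called, truth.feature_ids(label), universe)
        summary["recovery"][modality] = per_comp

    truth_switch = dataset["rrbs_truth"].switch_genes
    called_switch = {c.gene_id: c.switch_class for c in switch_calls
                     if c.switch_class != "none"}
    tp = sum(1 for g, cls in truth_switch.items()
             if called_switch.get(g) == cls)
    false_calls = {g for g in called_switch if g not in truth_switch}
    summary["recovery"]["switch"] = {
        "n_true": len(truth_switch),
        "n_recovered": tp,
        "sensitivity": tp / len(truth_switch) if truth_switch else None,
        "n_false_switch_calls": len(false_calls),
    }

    summary["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(_det(summary), fh, indent=1, sort_keys=True)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary


def _det(obj):
    """JSON-stable copy: numpy scalars to Python, wall-clock fields dropped
    so identical seeds give byte-identical summary files."""
    if isinstance(obj, dict):
        return {k: _det(v) for k, v in obj.items() if k != "runtime_s"}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# exploratory utilities
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance: np.ndarray


def log2_normalized(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) of size-factor-normalised counts."""
    sf = size_factors(counts)
    return np.log2(counts / sf + 1.0)


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> EmbeddingResult:
    """PCA of samples (columns) from a features x samples matrix.

    Features are centred and the sample scores taken from the singular value
    decomposition; coordinates are reproducible up to a sign per component.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    Y = X.T - X.T.mean(axis=0)  # samples x features, feature-centred
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    ev = S**2
    evr = ev / ev.sum() if ev.sum() > 0 else np.zeros_like(ev)
    cols = [f"PC{i+1}" for i in range(n_components)]
    idx = matrix.columns if isinstance(matrix, pd.DataFrame) else range(X.shape[1])
    return EmbeddingResult(pd.DataFrame(scores, index=idx, columns=cols),
                           evr[:n_components])


def hierarchical_cluster(matrix: pd.DataFrame):
    """Average-linkage agglomeration of samples (columns) on Euclidean
    distances; returns (leaf order, scipy linkage matrix)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-numeric or non-finite input")
    Z = hierarchy.linkage(pdist(X.T), method="average")
    order = hierarchy.leaves_list(Z)
    return order, Z


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative quantification by the delta-delta-Ct method:
    2**-((Ct_tgt,s - Ct_ref,s) - (Ct_tgt,cal - Ct_ref,cal))."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator,
           ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
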