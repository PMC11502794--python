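"""Synthetic RRBS / RRHP / RNA-seq count tables with planted differential effects.

Counts are simulated directly at the per-locus level (read alignment is
upstream of this package's scope): RRBS CpG coverage is negative-binomial and
methylated reads beta-binomial; RRHP strand-specific CCGG tag counts and RNA
gene counts are negative-binomial. Planted effects are condition-specific
shifts in methylation level (``planted_delta``) or log2 fold changes in mean
count (``planted_lfc``), recorded in a machine-readable :class:`PlantedTruth`
so that recovery of the planted signal can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import SampleDesign, make_design, samples_for


@dataclass
class SimulationConfig:
    """Generator parameters.

    ``mean_coverage`` is the expected RRBS total read count per CpG and also
    the baseline scale for RRHP tag and RNA gene means. ``bb_dispersion`` is
    the beta-binomial dispersion phi in (0,1) (variance inflation
    1+(c-1)*phi); ``nb_dispersion`` the negative-binomial dispersion d
    (variance mu + d*mu^2). ``planted_delta`` / ``planted_lfc`` are the true
    effect sizes given to differential features; ``frac_true`` the fraction
    of features planted differential per comparison.
    """

    n_genes: int = 300
    tf_fraction: float = 0.3
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 4_000_000, "chr2": 4_000_000}
    )
    cpgs_per_gene: int = 4
    ccgg_per_gene: int = 2
    mean_coverage: float = 30.0
    nb_dispersion: float = 0.1
    bb_dispersion: float = 0.1
    baseline_mu: float = 0.4
    planted_delta: float = 0.30
    planted_lfc: float = 2.0
    frac_true: float = 0.1
    seed: int = 0
    mean_log_sigma_tags: float = 0.5  # log-normal spread of CCGG tag means
    mean_log_sigma_rna: float = 1.0  # log-normal spread of gene expression means
    gene_length: int = 2000
    gene_gap: int = 8000  # keeps +/-2 kb extensions of neighbours disjoint

    def validate(self) -> None:
        for name in ("n_genes", "cpgs_per_gene", "ccgg_per_gene", "gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.tf_fraction < 1:
            raise ValueError("tf_fraction must be in (0, 1)")
        if not 0 < self.bb_dispersion < 1:
            raise ValueError("bb_dispersion must be in (0, 1)")
        if self.mean_coverage <= 0 or self.nb_dispersion < 0:
            raise ValueError("mean_coverage must be > 0 and nb_dispersion >= 0")
        lo = self.baseline_mu - abs(self.planted_delta)
        hi = self.baseline_mu + abs(self.planted_delta)
        if lo < 0.02 or hi > 0.98:
            raise ValueError(
                "baseline_mu +/- planted_delta must stay within [0.02, 0.98]"
            )
        if not 0 <= self.frac_true <= 1:
            raise ValueError("frac_true must be in [0, 1]")


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential effect: ``effect`` is the signed delta-mu
    (5mC) or signed log2 fold change (5hmC / RNA) applied to ``sample_ids``."""

    feature_id: str
    comparison: str
    effect: float
    gene_id: str
    sample_ids: tuple


class PlantedTruth:
    """Ground-truth record of planted effects, JSON round-trippable."""

    def __init__(self, modality: str):
        self.modality = modality
        self.records: list[PlantedEffect] = []
        self.size_factors: dict[str, float] = {}
        self.switch_genes: dict[str, str] = {}

    def add(self, eff: PlantedEffect) -> None:
        if eff.effect != 0:
            self.records.append(eff)

    def feature_ids(self, comparison: str | None = None) -> set:
        return {
            r.feature_id
            for r in self.records
            if comparison is None or r.comparison == comparison
        }

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "records": [asdict(r) for r in self.records],
            "size_factors": self.size_factors,
            "switch_genes": self.switch_genes,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        t = cls(d["modality"])
        for r in d["records"]:
            t.records.append(
                PlantedEffect(
                    r["feature_id"], r["comparison"], r["effect"], r["gene_id"],
                    tuple(r["sample_ids"]),
                )
            )
        t.size_factors = dict(d.get("size_factors", {}))
        t.switch_genes = dict(d.get("switch_genes", {}))
        return t

    @classmethod
    def read(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        return isinstance(other, PlantedTruth) and self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig):
    """Place non-overlapping genes, their CpG and strand-specific CCGG loci.

    Returns ``(genes, cpgs, ccggs)``: a BED-like gene frame with an ``is_tf``
    flag, and per-gene locus frames. Raises if the chromosomes cannot hold
    ``n_genes`` without overlap.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    slot = config.gene_length + config.gene_gap
    capacity = {c: L // slot for c, L in config.chrom_lengths.items()}
    if sum(capacity.values()) < config.n_genes:
        raise ValueError(
            f"chromosomes hold {sum(capacity.values())} genes of length "
            f"{config.gene_length} (gap {config.gene_gap}); {config.n_genes} requested"
        )

    rows = []
    gi = 0
    for chrom in sorted(config.chrom_lengths):
        for k in range(capacity[chrom]):
            if gi >= config.n_genes:
                break
            start = k * slot + int(rng.integers(0, config.gene_gap // 2))
            rows.append((f"gene{gi:05d}", chrom, start, start + config.gene_length))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    genes["strand"] = rng.choice(["+", "-"], size=len(genes))
    n_tf = int(round(config.tf_fraction * config.n_genes))
    tf_idx = rng.choice(config.n_genes, size=n_tf, replace=False)
    genes["is_tf"] = False
    genes.loc[tf_idx, "is_tf"] = True

    def _loci(per_gene: int, stranded: bool) -> pd.DataFrame:
        recs = []
        for g in genes.itertuples():
            pos = np.sort(
                rng.choice(np.arange(g.start, g.end), size=per_gene, replace=False)
            )
            for p in pos:
                strand = rng.choice(["+", "-"]) if stranded else "+"
                recs.append((g.chrom, int(p), strand, g.gene_id))
        return pd.DataFrame(recs, columns=["chrom", "pos", "strand", "gene_id"])

    cpgs = _loci(config.cpgs_per_gene, stranded=False)
    ccggs = _loci(config.ccgg_per_gene, stranded=True)
    return genes, cpgs, ccggs


# ---------------------------------------------------------------------------
# count generators
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _betabin_draw(rng, total: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Beta-binomial: p ~ Beta with mean mu and dispersion phi, then binomial."""
    mu = np.clip(mu, 1e-6, 1 - 1e-6)
    if phi <= 0:
        return rng.binomial(total, mu)
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    p = rng.beta(a, b)
    return rng.binomial(total, p)


def _default_effects(
    config: SimulationConfig,
    design: list[SampleDesign],
    feature_ids: list[str],
    gene_of: dict[str, str],
    effect_size: float,
    rng,
    comparison: str = "glial_undiff_vs_MacCM",
) -> list[PlantedEffect]:
    """Plant ``frac_true`` of features differential in the Mac-CM group of
    one line, with random effect sign."""
    target = tuple(samples_for(design, line="glial", condition="MacCM"))
    n_true = int(round(config.frac_true * len(feature_ids)))
    chosen = rng.choice(len(feature_ids), size=n_true, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_true)
    return [
        PlantedEffect(feature_ids[i], comparison, s * effect_size,
                      gene_of[feature_ids[i]], target)
        for i, s in zip(chosen, signs)
    ]


def simulate_rrbs(
    config: SimulationConfig,
    design: list[SampleDesign],
    truth_spec: list[PlantedEffect] | None = None,
    loci: pd.DataFrame | None = None,
    rng=None,
):
    """RRBS methylation count table.

    Per locus and sample, total reads are negative binomial around
    ``mean_coverage`` and methylated reads beta-binomial with locus/sample
    mean mu (baseline shifted by the planted delta in affected samples) and
    dispersion ``bb_dispersion``. Returns ``(table, truth)`` where the table
    holds columns chrom, pos, strand and per-sample ``meth_<id>``,
    ``total_<id>``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if loci is None:
        _, loci, _ = simulate_annotation(config)
    sample_ids = [s.sample_id for s in design]
    n_loci = len(loci)
    feature_ids = [
        f"{c}:{p}:{s}" for c, p, s in zip(loci["chrom"], loci["pos"], loci["strand"])
    ]
    gene_of = dict(zip(feature_ids, loci["gene_id"]))
    if truth_spec is None:
        truth_spec = _default_effects(
            config, design, feature_ids, gene_of, config.planted_delta, rng
        )

    mu = np.full((n_loci, len(design)), config.baseline_mu)
    idx = {f: i for i, f in enumerate(feature_ids)}
    col = {s: j for j, s in enumerate(sample_ids)}
    truth = PlantedTruth("5mC")
    for eff in truth_spec:
        truth.add(eff)
        if eff.effect != 0:
            cols = [col[s] for s in eff.sample_ids]
            mu[idx[eff.feature_id], cols] += eff.effect
    mu = np.clip(mu, 0.02, 0.98)

    total = _nb_draw(rng, np.full(mu.shape, config.mean_coverage), config.nb_dispersion)
    meth = _betabin_draw(rng, total, mu, config.bb_dispersion)

    table = loci[["chrom", "pos", "strand"]].copy()
    for j, s in enumerate(sample_ids):
        table[f"meth_{s}"] = meth[:, j]
        table[f"total_{s}"] = total[:, j]
    return table, truth


def _simulate_nb_table(
    config, design, truth_spec, feature_ids, gene_of, baseline_means, rng,
    modality, size_factor_range=None,
):
    sample_ids = [s.sample_id for s in design]
    n = len(feature_ids)
    if truth_spec is None:
        truth_spec = _default_effects(
            config, design, feature_ids, gene_of, config.planted_lfc, rng
        )
    mean = np.tile(baseline_means[:, None], (1, len(sample_ids))).astype(float)
    idx = {f: i for i, f in enumerate(feature_ids)}
    col = {s: j for j, s in enumerate(sample_ids)}
    truth = PlantedTruth(modality)
    for eff in truth_spec:
        truth.add(eff)
        if eff.effect != 0:
            cols = [col[s] for s in eff.sample_ids]
            mean[idx[eff.feature_id], cols] *= 2.0 ** eff.effect
    if size_factor_range is not None:
        lo, hi = size_factor_range
        sf = rng.uniform(lo, hi, size=len(sample_ids))
        mean = mean * sf[None, :]
        truth.size_factors = dict(zip(sample_ids, map(float, sf)))
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    table = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                         columns=sample_ids)
    return table, truth


def simulate_rrhp(
    config: SimulationConfig,
    design: list[SampleDesign],
    truth_spec: list[PlantedEffect] | None = None,
    loci: pd.DataFrame | None = None,
    rng=None,
):
    """RRHP strand-specific CCGG tag counts.

    Each locus is keyed by (chrom, pos, strand); strands are never merged.
    True differential loci have their group mean multiplied by
    ``2**planted_lfc``. Returns ``(table, truth)`` with the table indexed by
    ``chrom:pos:strand``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if loci is None:
        _, _, loci = simulate_annotation(config)
    feature_ids = [
        f"{c}:{p}:{s}" for c, p, s in zip(loci["chrom"], loci["pos"], loci["strand"])
    ]
    gene_of = dict(zip(feature_ids, loci["gene_id"]))
    base = np.exp(rng.normal(np.log(config.mean_coverage),
                             config.mean_log_sigma_tags, size=len(feature_ids)))
    return _simulate_nb_table(
        config, design, truth_spec, feature_ids, gene_of, base, rng, "5hmC"
    )


def simulate_rnaseq(
    config: SimulationConfig,
    design: list[SampleDesign],
    truth_spec: list[PlantedEffect] | None = None,
    genes: pd.DataFrame | None = None,
    rng=None,
):
    """RNA gene-count matrix with per-sample library-size factors.

    Size factors are drawn uniformly from [0.5, 2] and recorded in the truth;
    gene baseline means are log-normal around ``mean_coverage``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if genes is None:
        genes, _, _ = simulate_annotation(config)
    feature_ids = list(genes["gene_id"])
    gene_of = {g: g for g in feature_ids}
    base = np.exp(rng.normal(np.log(config.mean_coverage),
                             config.mean_log_sigma_rna, size=len(feature_ids)))
    return _simulate_nb_table(
        config, design, truth_spec, feature_ids, gene_of, base, rng, "RNA",
        size_factor_range=(0.5, 2.0),
    )


# ---------------------------------------------------------------------------
# full coordinated dataset
# ---------------------------------------------------------------------------

def study_comparisons(design: list[SampleDesign]) -> list[dict]:
    """The study's pairwise comparisons: per line, undifferentiated vs each
    differentiation environment, plus the undifferentiated line contrast."""
    comps = []
    lines = sorted({s.line for s in design})
    for line in lines:
        for env in ("DM", "MacCM"):
            comps.append(
                {
                    "label": f"{line}_undiff_vs_{env}",
                    "group_a": samples_for(design, line=line, condition="undiff"),
                    "group_b": samples_for(design, line=line, condition=env),
                    "line": line,
                    "environment": env,
                }
            )
    comps.append(
        {
            "label": "undiff_glial_vs_neural",
            "group_a": samples_for(design, line="glial", condition="undiff"),
            "group_b": samples_for(design, line="neural", condition="undiff"),
            "line": None,
            "environment": None,
        }
    )
    return comps


def simulate_dataset(
    config: SimulationConfig,
    design: list[SampleDesign] | None = None,
    switch_fraction: float = 0.5,
):
    """Generate the full coordinated multi-omic dataset.

    Plants, per pairwise comparison, ``frac_true`` differential features in
    each modality (random sign), on disjoint gene sets so recovery is
    unambiguous. A ``switch_fraction`` of the TF genes is reserved for
    reciprocal 5mC/5hmC switching: under Mac-CM these genes gain 5mC and
    lose 5hmC (or the mirror image), with the opposite pairing under DM, in
    both cell lines.

    Returns a dict with the annotation, the three count tables, their truth
    records, the design and the comparison list.
    """
    config.validate()
    if design is None:
        design = make_design()
    rng = np.random.default_rng(config.seed)
    genes, cpgs, ccggs = simulate_annotation(config)
    comps = study_comparisons(design)

    cpg_ids = [f"{c}:{p}:{s}" for c, p, s in
               zip(cpgs["chrom"], cpgs["pos"], cpgs["strand"])]
    ccgg_ids = [f"{c}:{p}:{s}" for c, p, s in
                zip(ccggs["chrom"], ccggs["pos"], ccggs["strand"])]
    cpg_gene = dict(zip(cpg_ids, cpgs["gene_id"]))
    ccgg_gene = dict(zip(ccgg_ids, ccggs["gene_id"]))
    cpgs_by_gene = cpgs.groupby("gene_id").indices
    ccggs_by_gene = ccggs.groupby("gene_id").indices

    tf_genes = list(genes.loc[genes["is_tf"], "gene_id"])
    n_switch = int(round(switch_fraction * len(tf_genes)))
    switch = list(rng.choice(tf_genes, size=n_switch, replace=False))
    switch_class = {
        g: ("gain5mC_loss5hmC" if i % 2 == 0 else "gain5hmC_loss5mC")
        for i, g in enumerate(switch)
    }
    free_genes = [g for g in genes["gene_id"] if g not in switch_class]

    rrbs_spec: list[PlantedEffect] = []
    rrhp_spec: list[PlantedEffect] = []
    rna_spec: list[PlantedEffect] = []

    # reciprocal switch genes: opposite-signed 5mC / 5hmC effects in the two
    # environments, in every line
    for comp in comps:
        if comp["environment"] is None:
            continue
        env_sign = 1.0 if comp["environment"] == "MacCM" else -1.0
        grp = tuple(comp["group_b"])
        for g, cls in switch_class.items():
            cls_sign = 1.0 if cls == "gain5mC_loss5hmC" else -1.0
            d5mc = env_sign * cls_sign * config.planted_delta
            l5hmc = -env_sign * cls_sign * config.planted_lfc
            for i in cpgs_by_gene[g]:
                rrbs_spec.append(
                    PlantedEffect(cpg_ids[i], comp["label"], d5mc, g, grp))
            for i in ccggs_by_gene[g]:
                rrhp_spec.append(
                    PlantedEffect(ccgg_ids[i], comp["label"], l5hmc, g, grp))

    # ordinary planted effects per comparison on disjoint non-switch genes
    n_per_comp = int(round(config.frac_true * len(free_genes) / len(comps)))
    pool = list(rng.permutation(free_genes))
    for comp in comps:
        if comp["environment"] is None:
            # line contrast: shift every sample of the second line so that
            # within-line comparisons stay null for these genes
            grp = tuple(samples_for(design, line="neural"))
        else:
            grp = tuple(comp["group_b"])
        for modality, spec in (("5mC", rrbs_spec), ("5hmC", rrhp_spec),
                               ("RNA", rna_spec)):
            take, pool = pool[:n_per_comp], pool[n_per_comp:]
            signs = rng.choice([-1.0, 1.0], size=len(take))
            for g, s in zip(take, signs):
                if modality == "5mC":
                    for i in cpgs_by_gene[g]:
                        spec.append(PlantedEffect(
                            cpg_ids[i], comp["label"],
                            s * config.planted_delta, g, grp))
                elif modality == "5hmC":
                    for i in ccggs_by_gene[g]:
                        spec.append(PlantedEffect(
                            ccgg_ids[i], comp["label"],
                            s * config.planted_lfc, g, grp))
                else:
                    spec.append(PlantedEffect(
                        g, comp["label"], s * config.planted_lfc, g, grp))

    rrbs, rrbs_truth = simulate_rrbs(config, design, rrbs_spec, cpgs, rng)
    rrhp, rrhp_truth = simulate_rrhp(config, design, rrhp_spec, ccggs, rng)
    rna, rna_truth = simulate_rnaseq(config, design, rna_spec, genes, rng)
    for t in (rrbs_truth, rrhp_truth, rna_truth):
        t.switch_genes = dict(switch_class)

    return {
        "config": config,
        "design": design,
        "comparisons": comps,
        "genes": genes,
        "cpgs": cpgs,
        "ccggs": ccggs,
        "rrbs": rrbs,
        "rrbs_truth": rrbs_truth,
        "rrhp": rrhp,
        "rrhp_truth": rrhp_truth,
        "rna": rna,
        "rna_truth": rna_truth,
    }
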