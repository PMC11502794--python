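"""Map significant loci to genes by flank extension and interval merging.

Each significant point locus is extended by +/- ``flank`` bp (default 2 kb),
overlapping or book-ended extensions are merged, and a gene receives a hit
when any merged region overlaps its body by at least one base. Coordinates
are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenomicRegion:
    chrom: str
    start: int
    end: int
    source_loci: list = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end (half-open)")


def extend_and_merge(
    loci,
    flank: int = 2000,
    chrom_lengths: dict | None = None,
) -> list[GenomicRegion]:
    """Extend point loci by ``flank`` and merge overlapping/book-ended spans.

    ``loci`` is an iterable of (chrom, pos) or (chrom, pos, strand); a point
    locus at ``pos`` becomes ``[max(0, pos - flank), pos + flank + 1)``.
    Output regions are disjoint, sorted, and carry their source loci. Loci
    extending past a supplied chromosome length are clipped with a warning.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    recs = []
    for loc in loci:
        chrom, pos = loc[0], int(loc[1])
        start = max(0, pos - flank)
        end = pos + flank + 1
        if chrom_lengths is not None and chrom in chrom_lengths:
            L = chrom_lengths[chrom]
            if end > L:
                warnings.warn(f"locus {chrom}:{pos} extends past chromosome end; clipped")
                end = L
                start = min(start, end - 1)
        recs.append((chrom, start, end, tuple(loc)))

    out: list[GenomicRegion] = []
    recs.sort(key=lambda r: (r[0], r[1], r[2]))
    for chrom, start, end, src in recs:
        if out and out[-1].chrom == chrom and start <= out[-1].end:
            out[-1].end = max(out[-1].end, end)
            out[-1].source_loci.append(src)
        else:
            out.append(GenomicRegion(chrom, start, end, [src]))
    return out


def regions_to_bed(regions: list[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, len(r.source_loci)) for r in regions],
        columns=["chrom", "start", "end", "n_loci"],
    )


def assign_regions_to_genes(
    regions: list[GenomicRegion],
    annotation: pd.DataFrame,
    modality: str,
    comparison: str,
    directions: dict | None = None,
) -> pd.DataFrame:
    """Gene hits: one row per (gene, modality, comparison, direction).

    A gene is hit iff a merged region overlaps its [start, end) by >= 1 bp.
    ``directions`` maps a source locus key (chrom, pos[, strand]) to a signed
    effect; a gene's direction is the majority sign over its overlapping
    source loci ('gain' / 'loss'), and an exact tie records both. Without
    ``directions`` every hit is direction 'na'.
    """
    known = set(annotation["chrom"])
    for r in regions:
        if r.chrom not in known:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")

    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in annotation.groupby("chrom")}
    for chrom, genes in by_chrom.items():
        gstart = genes["start"].to_numpy()
        gend = genes["end"].to_numpy()
        gids = genes["gene_id"].to_numpy()
        for r in regions:
            if r.chrom != chrom:
                continue
            hit = (gstart < r.end) & (gend > r.start)
            for gid in gids[hit]:
                rows.append((gid, r.source_loci))

    hits: dict[tuple, int] = {}
    for gid, sources in rows:
        if directions is None:
            key = (gid, "na")
            hits[key] = hits.get(key, 0) + len(sources)
            continue
        signs = [np.sign(directions[tuple(s)]) for s in sources
                 if tuple(s) in directions]
        pos = sum(1 for s in signs if s > 0)
        neg = sum(1 for s in signs if s < 0)
        if pos > neg:
            dirs = ["gain"]
        elif neg > pos:
            dirs = ["loss"]
        else:
            dirs = ["gain", "loss"]  # exact tie: both recorded
        n_each = max(pos, neg) if pos != neg else pos
        for d in dirs:
            key = (gid, d)
            hits[key] = hits.get(key, 0) + max(n_each, 1)

    frame = pd.DataFrame(
        [(g, modality, comparison, d, n) for (g, d), n in sorted(hits.items())],
        columns=["gene_id", "modality", "comparison", "direction", "n_loci"],
    )
    return frame


def rna_gene_hits(nb_frame: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Gene hits from a DEG result frame (no extension: already gene-level)."""
    sig = nb_frame[nb_frame["significant"]]
    return pd.DataFrame(
        {
            "gene_id": sig["feature_id"].to_numpy(),
            "modality": "RNA",
            "comparison": comparison,
            "direction": np.where(sig["log2fc"] > 0, "gain", "loss"),
            "n_loci": 1,
        }
    )


def filter_tfs(hits: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Restrict gene hits to transcription-factor genes."""
    tf = set(annotation.loc[annotation["is_tf"], "gene_id"])
    return hits[hits["gene_id"].isin(tf)].reset_index(drop=True)
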