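"""Combinatorial epigenetic patterns, trackability and 5mC/5hmC switching.

A gene detected at a stage carries one of seven patterns — the non-empty
subsets of {RNA, 5mC, 5hmC} in canonical order. A gene with a pattern both
undifferentiated and differentiated (within one environment) is *trackable*;
a gene seen at only one stage is *untrackable*. A reciprocal switch is a
gene whose 5mC and 5hmC changes point in opposite directions under the
inflammatory medium (Mac-CM) with the mirrored pairing under normal medium
(DM): gain of 5mC with loss of 5hmC, or the converse.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MODALITIES = ("RNA", "5mC", "5hmC")

# canonical single-stage pattern numbering
PATTERN_TABLE: dict[frozenset, int] = {
    frozenset({"RNA"}): 1,
    frozenset({"5mC"}): 2,
    frozenset({"5hmC"}): 3,
    frozenset({"RNA", "5mC"}): 4,
    frozenset({"RNA", "5hmC"}): 5,
    frozenset({"5mC", "5hmC"}): 6,
    frozenset({"RNA", "5mC", "5hmC"}): 7,
}
N_PATTERNS = len(PATTERN_TABLE)


@dataclass(frozen=True)
class PatternCode:
    gene_id: str
    stage: str
    modalities: frozenset
    pattern_id: int


@dataclass(frozen=True)
class TrackRecord:
    gene_id: str
    environment: str
    undiff_pattern: PatternCode | None
    diff_pattern: PatternCode | None
    status: str  # trackable | untrackable_undiff_only | untrackable_diff_only
    transition_id: int


@dataclass(frozen=True)
class SwitchCall:
    gene_id: str
    switch_class: str  # gain5mC_loss5hmC | gain5hmC_loss5mC | none


def modality_pattern(gene_id: str, modalities, stage: str) -> PatternCode | None:
    """Pattern of one gene at one stage from the set of assays with >= 1
    significant hit; ``None`` when the gene is undetected at the stage."""
    mset = frozenset(modalities)
    if not mset:
        return None
    unknown = mset - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    return PatternCode(gene_id, stage, mset, PATTERN_TABLE[mset])


def patterns_from_hits(hits: pd.DataFrame, stage: str) -> dict[str, PatternCode]:
    """Per-gene patterns from a GeneHit frame (one stage's comparisons)."""
    out = {}
    if len(hits) == 0:
        return out
    for gene_id, grp in hits.groupby("gene_id"):
        pc = modality_pattern(gene_id, set(grp["modality"]), stage)
        if pc is not None:
            out[gene_id] = pc
    return out


def transition_id(undiff: PatternCode | None, diff: PatternCode | None) -> int:
    """Deterministic transition numbering.

    Undiff-only genes keep their single-stage id 1-7; trackable transitions
    occupy 8..56 as 7 + (undiff_id - 1)*7 + diff_id; diff-only genes occupy
    the reserved range 57..63 as 56 + diff_id.
    """
    if undiff is not None and diff is not None:
        return 7 + (undiff.pattern_id - 1) * 7 + diff.pattern_id
    if undiff is not None:
        return undiff.pattern_id
    if diff is not None:
        return 56 + diff.pattern_id
    raise ValueError("at least one pattern required")


def classify_trackability(
    undiff_patterns: dict[str, PatternCode],
    diff_patterns: dict[str, PatternCode],
    environment: str,
) -> list[TrackRecord]:
    """Trackable / untrackable status per gene for one environment."""
    records = []
    for gene in sorted(set(undiff_patterns) | set(diff_patterns)):
        u = undiff_patterns.get(gene)
        d = diff_patterns.get(gene)
        if u is not None and d is not None:
            status = "trackable"
        elif u is not None:
            status = "untrackable_undiff_only"
        else:
            status = "untrackable_diff_only"
        records.append(
            TrackRecord(gene, environment, u, d, status, transition_id(u, d))
        )
    return records


def _gene_directions(hits: pd.DataFrame) -> dict[str, dict[str, set]]:
    """gene -> modality -> set of directions seen in the hit frame."""
    out: dict[str, dict[str, set]] = {}
    for row in hits.itertuples():
        if row.direction not in ("gain", "loss"):
            continue
        out.setdefault(row.gene_id, {}).setdefault(row.modality, set()).add(
            row.direction
        )
    return out


def detect_switch(hits_dm: pd.DataFrame, hits_maccm: pd.DataFrame) -> list[SwitchCall]:
    """Reciprocal 5mC/5hmC switch calls between the two environments.

    ``gain5mC_loss5hmC``: under Mac-CM the gene gains 5mC and loses 5hmC
    while under DM it loses 5mC and gains 5hmC; ``gain5hmC_loss5mC`` is the
    mirror image. A gene with any other combination — or absent from either
    environment — is classed ``none``. Classes are mutually exclusive.
    """
    dm = _gene_directions(hits_dm)
    mac = _gene_directions(hits_maccm)
    calls = []
    for gene in sorted(set(dm) | set(mac)):
        cls = "none"
        d, m = dm.get(gene, {}), mac.get(gene, {})
        needed = {"5mC", "5hmC"}
        if needed <= set(d) and needed <= set(m):
            if (m["5mC"] == {"gain"} and m["5hmC"] == {"loss"}
                    and d["5mC"] == {"loss"} and d["5hmC"] == {"gain"}):
                cls = "gain5mC_loss5hmC"
            elif (m["5mC"] == {"loss"} and m["5hmC"] == {"gain"}
                    and d["5mC"] == {"gain"} and d["5hmC"] == {"loss"}):
                cls = "gain5hmC_loss5mC"
        calls.append(SwitchCall(gene, cls))
    return calls


def summarize_patterns(
    track_records: list[TrackRecord],
    switch_calls: list[SwitchCall],
) -> pd.DataFrame:
    """Per-environment counts by trackability status and switch class.

    The status counts partition the pattern-bearing genes of each
    environment; switch-class counts partition the switch-call genes.
    """
    rows = []
    by_env: dict[str, list[TrackRecord]] = {}
    for r in track_records:
        by_env.setdefault(r.environment, []).append(r)
    for env in sorted(by_env):
        recs = by_env[env]
        for status in ("trackable", "untrackable_undiff_only",
                       "untrackable_diff_only"):
            rows.append((env, "status", status,
                         sum(1 for r in recs if r.status == status)))
    for cls in ("gain5mC_loss5hmC", "gain5hmC_loss5mC", "none"):
        rows.append(("DM_vs_MacCM", "switch", cls,
                     sum(1 for c in switch_calls if c.switch_class == cls)))
    return pd.DataFrame(rows, columns=["environment", "kind", "category", "count"])


def track_records_frame(records: list[TrackRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.gene_id,
                r.environment,
                r.undiff_pattern.pattern_id if r.undiff_pattern else 0,
                r.diff_pattern.pattern_id if r.diff_pattern else 0,
                r.status,
                r.transition_id,
            )
            for r in records
        ],
        columns=["gene_id", "environment", "undiff_pattern_id",
                 "diff_pattern_id", "status", "transition_id"],
    )
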