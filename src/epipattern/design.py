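"""Sample design: cell lines, differentiation conditions and replicates.

The study design is two neural-stem-cell derivative lines (a glial-biased
and a neural-biased line), each profiled undifferentiated and after 14 days
in either normal differentiation medium (DM) or macrophage-conditioned,
inflammatory medium (Mac-CM), with two biological replicates per
(line, condition) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LINES = ("glial", "neural")
CONDITIONS = ("undiff", "DM", "MacCM")


@dataclass(frozen=True)
class SampleDesign:
    """One sequenced sample: a (line, condition, replicate) cell of the design."""

    sample_id: str
    line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.line not in LINES:
            raise ValueError(f"unknown line {self.line!r}; expected one of {LINES}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def make_design(n_replicates: int = 2) -> list[SampleDesign]:
    """Full-factorial design: every line x condition with ``n_replicates`` each."""
    if n_replicates < 2:
        raise ValueError("each (line, condition) needs at least 2 replicates")
    design = []
    for line in LINES:
        for condition in CONDITIONS:
            for rep in range(1, n_replicates + 1):
                design.append(
                    SampleDesign(f"{line}_{condition}_r{rep}", line, condition, rep)
                )
    return design


def design_frame(design: list[SampleDesign]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s.sample_id, s.line, s.condition, s.replicate) for s in design],
        columns=["sample_id", "line", "condition", "replicate"],
    )
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    if df.duplicated(["line", "condition", "replicate"]).any():
        raise ValueError("duplicate (line, condition, replicate) triples")
    counts = df.groupby(["line", "condition"]).size()
    if (counts < 2).any():
        raise ValueError("every (line, condition) needs >=2 replicates")
    return df


def write_design(design: list[SampleDesign], path) -> None:
    design_frame(design).to_csv(path, sep="\t", index=False)


def read_design(path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleDesign(r.sample_id, r.line, r.condition, int(r.replicate))
        for r in df.itertuples()
    ]


def samples_for(design: list[SampleDesign], line: str | None = None,
                condition: str | None = None) -> list[str]:
    """Sample ids matching the given line and/or condition."""
    return [
        s.sample_id
        for s in design
        if (line is None or s.line == line)
        and (condition is None or s.condition == condition)
    ]
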