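"""Prominin transmembrane-topology curation filter.

The operational prominin definition: exactly five transmembrane helices in
a 2+2+1 arrangement — with an extracellular N-terminus the four inter-TM
loops alternate intracellular / extracellular / intracellular /
extracellular, the two extracellular loops are large (> 300 residues) and
the two intracellular loops small (< 25 residues). Termini are not counted
as loops. Thresholds are configurable; inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class TopologyRecord:
    seq_id: str
    sequence: str
    tm_spans: list[tuple[int, int]]  # 1-based inclusive residue intervals, ascending
    n_term_side: str = "extracellular"  # "extracellular" | "intracellular" | "unknown"

    def __post_init__(self) -> None:
        if self.n_term_side not in ("extracellular", "intracellular", "unknown"):
            raise ValueError(f"bad n_term_side {self.n_term_side!r}")
        prev_end = 0
        for start, end in self.tm_spans:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"{self.seq_id}: span ({start}, {end}) outside sequence of length {len(self.sequence)}"
                )
            if start <= prev_end:
                raise ValueError(f"{self.seq_id}: spans must be non-overlapping and ascending")
            prev_end = end


@dataclass
class PromininVerdict:
    seq_id: str
    passes: bool
    reasons: list[str] = field(default_factory=list)
    loop_lengths: list[tuple[int, str]] = field(default_factory=list)  # (length, compartment)
    warning: str = ""

    def __post_init__(self) -> None:
        if self.passes != (not self.reasons):
            raise ValueError("passes must be equivalent to an empty reasons list")


@dataclass
class TopologyParams:
    n_tm: int = 5
    ec_loop_min_aa: int = 300  # extracellular loops strictly greater
    ic_loop_max_aa: int = 25  # intracellular loops strictly smaller
    ec_mode: str = "per_loop"  # "per_loop" | "combined"


def classify_prominin_topology(
    r: TopologyRecord, params: TopologyParams | None = None
) -> PromininVerdict:
    """Evaluate one topology-annotated sequence against the prominin definition.

    An unknown N-terminus side is evaluated under the extracellular
    assumption (the prominin convention) with a warning recorded.
    """
    params = params or TopologyParams()
    reasons: list[str] = []
    warning = ""
    n_term = r.n_term_side
    if n_term == "unknown":
        n_term = "extracellular"
        warning = "n_term_side unknown; evaluated assuming extracellular N-terminus"

    loops: list[tuple[int, str]] = []
    sides = ("intracellular", "extracellular") if n_term == "extracellular" else (
        "extracellular",
        "intracellular",
    )
    for i in range(len(r.tm_spans) - 1):
        length = r.tm_spans[i + 1][0] - r.tm_spans[i][1] - 1
        loops.append((length, sides[i % 2]))

    if len(r.tm_spans) != params.n_tm:
        reasons.append("tm_count")
    else:
        ec = [length for length, side in loops if side == "extracellular"]
        ic = [length for length, side in loops if side == "intracellular"]
        if params.ec_mode == "per_loop":
            if not all(length > params.ec_loop_min_aa for length in ec):
                reasons.append("ec_loop_min")
        elif params.ec_mode == "combined":
            if not sum(ec) > params.ec_loop_min_aa:
                reasons.append("ec_loop_min")
        else:
            raise ValueError(f"unknown ec_mode {params.ec_mode!r}")
        if not all(length < params.ic_loop_max_aa for length in ic):
            reasons.append("ic_loop_max")

    return PromininVerdict(
        seq_id=r.seq_id,
        passes=not reasons,
        reasons=reasons,
        loop_lengths=loops,
        warning=warning,
    )


def filter_records(
    records: list[TopologyRecord], params: TopologyParams | None = None
) -> tuple[list[TopologyRecord], pd.DataFrame]:
    """Order-preserving curation filter; one verdict row per input record."""
    params = params or TopologyParams()
    passed: list[TopologyRecord] = []
    rows = []
    for r in records:
        verdict = classify_prominin_topology(r, params)
        if verdict.passes:
            passed.append(r)
        rows.append(
            {
                "seq_id": r.seq_id,
                "passes": verdict.passes,
                "reasons": ";".join(verdict.reasons),
                "n_tm": len(r.tm_spans),
                "loop_lengths": ";".join(f"{n}:{side[:2]}" for n, side in verdict.loop_lengths),
                "warning": verdict.warning,
            }
        )
    table = pd.DataFrame(
        rows, columns=["seq_id", "passes", "reasons", "n_tm", "loop_lengths", "warning"]
    )
    return passed, table


# ---------------------------------------------------------------------------
# I/O: FASTA + TM-span table (as produced by external topology predictors)


def read_topology_records(
    fasta_path: str | Path, spans_path: str | Path, n_term_side: str = "extracellular"
) -> list[TopologyRecord]:
    """Join a FASTA file with a CSV span table (columns seq_id, start, end)."""
    spans = pd.read_csv(spans_path)
    for col in ("seq_id", "start", "end"):
        if col not in spans.columns:
            raise ValueError(f"span table missing column {col!r}")
    grouped = {
        str(seq_id): sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        for seq_id, grp in spans.groupby("seq_id")
    }
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        side = n_term_side
        records.append(
            TopologyRecord(
                seq_id=rec.id,
                sequence=str(rec.seq),
                tm_spans=grouped.get(rec.id, []),
                n_term_side=side,
            )
        )
    return records


def write_curated_fasta(records: list[TopologyRecord], path: str | Path) -> Path:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return Path(path)
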