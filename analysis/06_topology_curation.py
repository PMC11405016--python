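#!/usr/bin/env python
"""Prominin topology curation on a constructed panel of annotated sequences.

The panel spans the decision boundaries of the rule (five TM helices,
extracellular loops > 300 aa, intracellular loops < 25 aa) plus both
boundary values, which must fail under the strict inequalities.
"""

from pathlib import Path

from evquant import topology

results = Path("results")
results.mkdir(exist_ok=True)


def record(loops, seq_id):
    spans, pos = [], 10
    for i in range(len(loops) + 1):
        spans.append((pos + 1, pos + 20))
        pos += 20 + (loops[i] if i < len(loops) else 0)
    return topology.TopologyRecord(seq_id=seq_id, sequence="A" * (pos + 10), tm_spans=spans)


panel = [
    record([15, 350, 20, 400], "prominin_like"),
    record([24, 301, 24, 301], "boundary_pass"),
    record([15, 250, 20, 400], "short_ec_loop"),
    record([15, 300, 20, 400], "ec_loop_at_300"),
    record([25, 350, 20, 400], "ic_loop_at_25"),
    record([30, 350, 20, 400], "long_ic_loop"),
    record([15, 350, 20], "four_tm"),
    record([15, 120, 20, 130], "ttyh_like_short_ecds"),
]

passed, verdicts = topology.filter_records(panel)
verdicts.to_csv(results / "topology_verdicts.csv", index=False)

print(f"{len(passed)}/{len(panel)} sequences pass the prominin definition:")
for row in verdicts.itertuples(index=False):
    status = "PASS" if row.passes else f"fail ({row.reasons})"
    print(f"  {row.seq_id:22s} loops {row.loop_lengths:28s} {status}")
print(f"-> {results/'topology_verdicts.csv'}")
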