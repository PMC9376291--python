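"""Per-node support values over replicate reconciliations.

Mirrors the role of AggregateRanger: given R sampled optimal
reconciliations of one gene tree, tally how often each internal gene-tree
node carries each event type, maps to each species node, and (for
transfers) receives from each donor.  Node identity across replicates is
the gene tree's stable post-order index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reconcile import Reconciliation, TRANSFER
from .trees import write_newick

__all__ = ["NodeSupport", "NodeSupportTable", "aggregate", "support_report"]


@dataclass
class NodeSupport:
    event_freq: dict[str, float] = field(default_factory=dict)
    mapping_freq: dict[int, float] = field(default_factory=dict)
    donor_freq: dict[int, float] = field(default_factory=dict)

    @property
    def top_event(self) -> str:
        return max(sorted(self.event_freq), key=lambda k: self.event_freq[k])

    @property
    def top_mapping(self) -> int:
        return max(sorted(self.mapping_freq), key=lambda k: self.mapping_freq[k])

    @property
    def top_donor(self):
        if not self.donor_freq:
            return None
        return max(sorted(self.donor_freq), key=lambda k: self.donor_freq[k])


@dataclass
class NodeSupportTable:
    """Support values per internal gene-tree node over R replicates."""

    replicates: int
    rows: dict[int, NodeSupport]
    sidx_names: dict[int, str]

    def to_json_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "nodes": {
                str(g): {
                    "event_freq": row.event_freq,
                    "mapping_freq": {self.sidx_names[s]: f for s, f in row.mapping_freq.items()},
                    "top_mapping": self.sidx_names[row.top_mapping],
                    "donor_freq": {self.sidx_names[s]: f for s, f in row.donor_freq.items()},
                }
                for g, row in sorted(self.rows.items())
            },
        }


def aggregate(replicates: list[Reconciliation]) -> NodeSupportTable:
    """Exact per-node frequencies (counts / R) over the replicates.

    All replicates must reconcile the same gene tree against the same
    species tree; frequencies in every map sum to 1 per node, and the
    donor map is populated only from replicates whose node is a transfer.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    ref = write_newick(replicates[0].gene)
    for rec in replicates[1:]:
        if write_newick(rec.gene) != ref:
            raise ValueError("replicates aggregate different gene trees")
    R = len(replicates)
    gidx = replicates[0].gidx
    sidx = replicates[0].sidx
    rows: dict[int, NodeSupport] = {}
    internal = [g for g in range(len(gidx.nodes)) if not gidx.is_leaf(g)]
    for g in internal:
        ev_counts: dict[str, int] = {}
        map_counts: dict[int, int] = {}
        donor_counts: dict[int, int] = {}
        for rec in replicates:
            ev = rec.events[g]
            ev_counts[ev.type] = ev_counts.get(ev.type, 0) + 1
            s = rec.mapping[g]
            map_counts[s] = map_counts.get(s, 0) + 1
            if ev.type == TRANSFER:
                donor_counts[ev.donor] = donor_counts.get(ev.donor, 0) + 1
        rows[g] = NodeSupport(
            event_freq={k: v / R for k, v in ev_counts.items()},
            mapping_freq={k: v / R for k, v in map_counts.items()},
            donor_freq={k: v / R for k, v in donor_counts.items()},
        )
    names = {s: sidx.name(s) for s in range(len(sidx.nodes))}
    return NodeSupportTable(replicates=R, rows=rows, sidx_names=names)


def support_report(table: NodeSupportTable) -> str:
    """TSV: one row per internal gene node with its top event/mapping/donor."""
    lines = ["#node\ttop_event\tevent_support\ttop_mapping\tmapping_support\ttop_donor\tdonor_support"]
    for g, row in sorted(table.rows.items()):
        ev = row.top_event
        mp = row.top_mapping
        dn = row.top_donor
        donor_cell = "-\t-"
        if dn is not None:
            donor_cell = f"{table.sidx_names[dn]}\t{row.donor_freq[dn]:.3f}"
        lines.append(
            f"{g}\t{ev}\t{row.event_freq[ev]:.3f}"
            f"\t{table.sidx_names[mp]}\t{row.mapping_freq[mp]:.3f}\t{donor_cell}"
        )
    return "\n".join(lines) + "\n"
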