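"""Per-family origin classification and the cross-family HGT tally.

For a focal species group (e.g. the Dissulfurispiraceae-like clade) and
one gene family, each replicate reconciliation votes on how the focal
group acquired the gene: the vote is HGT when, walking rootward from the
gene-tree MRCA of the focal leaves, the first transfer event in which the
focal lineage is the recipient exists before the root, and VERTICAL
otherwise.  The donor group of an HGT vote is the group shared by all
descendant leaves of the donor species node ("mixed" when they disagree).
Votes are combined by strict majority across replicates, and calls are
tallied across gene families into the headline percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .reconcile import Reconciliation, TRANSFER
from .trees import LabeledTree, TreeIndex

__all__ = [
    "HGT",
    "VERTICAL",
    "ABSENT",
    "AMBIGUOUS",
    "OriginCall",
    "GroupSummary",
    "classify_origin",
    "summarize",
    "format_percent",
    "calls_tsv",
    "markdown_report",
]

HGT = "HGT"
VERTICAL = "VERTICAL"
ABSENT = "ABSENT"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class OriginCall:
    family: str
    focal_group: str
    verdict: str
    donor_group: str = ""
    support: float = 0.0
    replicate_breakdown: dict = field(default_factory=dict)  # (verdict, donor) -> count
    warning: str = ""

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "focal_group": self.focal_group,
            "verdict": self.verdict,
            "donor_group": self.donor_group,
            "support": self.support,
            "replicate_breakdown": {
                f"{v}|{d}": c for (v, d), c in sorted(self.replicate_breakdown.items())
            },
            "warning": self.warning,
        }


@dataclass
class GroupSummary:
    focal_group: str
    n_families: int
    n_hgt: int
    n_vertical: int
    n_ambiguous: int
    pct_hgt: float
    pct_vertical: float
    pct_ambiguous: float
    donor_breakdown: dict  # donor group -> (count, percent of HGT calls)
    per_family: list

    def to_json_dict(self) -> dict:
        return {
            "focal_group": self.focal_group,
            "n_families": self.n_families,
            "n_hgt": self.n_hgt,
            "n_vertical": self.n_vertical,
            "n_ambiguous": self.n_ambiguous,
            "pct_hgt": self.pct_hgt,
            "pct_vertical": self.pct_vertical,
            "pct_ambiguous": self.pct_ambiguous,
            "donor_breakdown": {d: list(v) for d, v in sorted(self.donor_breakdown.items())},
            "per_family": [c.to_json_dict() for c in self.per_family],
        }


def format_percent(k: int, n: int) -> str:
    """``100*k/n`` rounded half-up to one decimal, with a ``%`` suffix."""
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0 or k > n:
        raise ValueError("k must satisfy 0 <= k <= n")
    pct = (Decimal(k) * 100 / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


def _group_of_species_node(sidx: TreeIndex, s: int, groups: dict[str, str]) -> str:
    seen = {groups.get(sidx.nodes[j].label, "other") for j in sidx.leaves_under(s)}
    return seen.pop() if len(seen) == 1 else "mixed"


def _maximal_focal_clades(gidx: TreeIndex, focal_leaves: set[int]) -> list[int]:
    n = len(gidx.nodes)
    all_focal = [False] * n
    for g in range(n):  # post-order
        if gidx.is_leaf(g):
            all_focal[g] = g in focal_leaves
        else:
            all_focal[g] = all(all_focal[c] for c in gidx.children[g])
    return [
        g for g in range(n)
        if all_focal[g] and (gidx.parent[g] < 0 or not all_focal[gidx.parent[g]])
    ]


def _clade_vote(rec: Reconciliation, clade_root: int, groups: dict[str, str]):
    """Walk rootward; first transfer received by the lineage decides."""
    gidx = rec.gidx
    cur = clade_root
    while gidx.parent[cur] >= 0:
        p = gidx.parent[cur]
        ev = rec.events[p]
        if ev.type == TRANSFER and ev.moved_child == cur:
            return HGT, _group_of_species_node(rec.sidx, ev.donor, groups)
        cur = p
    return VERTICAL, ""


def classify_origin(
    gene: LabeledTree,
    species: LabeledTree,
    leafmap: dict[str, str],
    groups: dict[str, str],
    focal_group: str,
    replicates: list[Reconciliation],
    family: str = "",
) -> OriginCall:
    """Majority-vote origin call for one gene family.

    Per replicate the focal-group leaves' gene-tree MRCA lineage votes HGT
    or VERTICAL (see module docstring); when the focal leaves are not
    monophyletic in the gene tree, each maximal all-focal clade votes and
    the replicate takes the within-replicate majority (ties lean HGT --
    an acquisition signal in any sub-clade is evidence of transfer), with
    a warning recorded on the call.
    """
    if focal_group not in set(groups.values()):
        raise ValueError(f"focal group {focal_group!r} not present in the group map")
    if not replicates:
        raise ValueError("need at least one replicate")
    gidx = replicates[0].gidx
    focal_leaves = {
        g for lab, g in gidx.leaf_index.items()
        if groups.get(leafmap.get(lab, ""), "other") == focal_group
    }
    if not focal_leaves:
        return OriginCall(family, focal_group, ABSENT, support=1.0)
    clades = _maximal_focal_clades(gidx, focal_leaves)
    warning = "" if len(clades) == 1 else (
        f"focal leaves not monophyletic in gene tree ({len(clades)} clades)"
    )
    R = len(replicates)
    breakdown: dict[tuple[str, str], int] = {}
    for rec in replicates:
        votes = [_clade_vote(rec, x, groups) for x in clades]
        hgt_votes = [v for v in votes if v[0] == HGT]
        # within-replicate combination: majority over clades, ties -> HGT
        if 2 * len(hgt_votes) >= len(votes) and hgt_votes:
            donors = sorted(d for _, d in hgt_votes)
            donor = min(set(donors), key=lambda d: (-donors.count(d), d))
            key = (HGT, donor)
        else:
            key = (VERTICAL, "")
        breakdown[key] = breakdown.get(key, 0) + 1
    n_hgt = sum(c for (v, _), c in breakdown.items() if v == HGT)
    n_vert = R - n_hgt
    if n_hgt * 2 > R:
        donor_counts: dict[str, int] = {}
        for (v, d), c in breakdown.items():
            if v == HGT:
                donor_counts[d] = donor_counts.get(d, 0) + c
        donor = max(sorted(donor_counts), key=lambda d: donor_counts[d])
        verdict, support = HGT, n_hgt / R
    elif n_vert * 2 > R:
        verdict, donor, support = VERTICAL, "", n_vert / R
    else:
        verdict, donor, support = AMBIGUOUS, "", n_hgt / R
    return OriginCall(family, focal_group, verdict, donor, support, breakdown, warning)


def summarize(calls: list[OriginCall], focal_group: str) -> GroupSummary:
    """Cross-family tally; ABSENT families are excluded from the denominator."""
    if not calls:
        raise ValueError("no origin calls to summarize")
    for c in calls:
        if c.focal_group != focal_group:
            raise ValueError("all calls must share the focal group")
    present = [c for c in calls if c.verdict != ABSENT]
    if not present:
        raise ValueError("all families are ABSENT for this focal group")
    n = len(present)
    n_hgt = sum(1 for c in present if c.verdict == HGT)
    n_vert = sum(1 for c in present if c.verdict == VERTICAL)
    n_amb = sum(1 for c in present if c.verdict == AMBIGUOUS)
    donors: dict[str, int] = {}
    for c in present:
        if c.verdict == HGT:
            donors[c.donor_group] = donors.get(c.donor_group, 0) + 1
    donor_breakdown = {
        d: (k, 100.0 * k / n_hgt) for d, k in sorted(donors.items())
    }
    return GroupSummary(
        focal_group=focal_group,
        n_families=n,
        n_hgt=n_hgt,
        n_vertical=n_vert,
        n_ambiguous=n_amb,
        pct_hgt=100.0 * n_hgt / n,
        pct_vertical=100.0 * n_vert / n,
        pct_ambiguous=100.0 * n_amb / n,
        donor_breakdown=donor_breakdown,
        per_family=list(calls),
    )


def calls_tsv(calls: list[OriginCall]) -> str:
    lines = ["#family\tverdict\tdonor_group\tsupport\treplicates\twarning"]
    for c in calls:
        R = sum(c.replicate_breakdown.values())
        lines.append(
            f"{c.family}\t{c.verdict}\t{c.donor_group or '-'}"
            f"\t{c.support:.3f}\t{R}\t{c.warning or '-'}"
        )
    return "\n".join(lines) + "\n"


def markdown_report(summary: GroupSummary, label: str = "") -> str:
    """Markdown summary in the 'X% (k of n trees)' phrasing."""
    n = summary.n_families
    head = label or f"Origin of gene families in the {summary.focal_group} group"
    lines = [f"## {head}", ""]
    lines.append(
        f"- Acquired horizontally in {format_percent(summary.n_hgt, n)} of cases "
        f"({summary.n_hgt} of {n} trees)."
    )
    lines.append(
        f"- Inherited vertically in {format_percent(summary.n_vertical, n)} of cases "
        f"({summary.n_vertical} of {n} trees)."
    )
    if summary.n_ambiguous:
        lines.append(
            f"- Ambiguous in {format_percent(summary.n_ambiguous, n)} of cases "
            f"({summary.n_ambiguous} of {n} trees)."
        )
    if summary.donor_breakdown:
        lines.append("")
        lines.append("Donor attribution among the HGT calls:")
        lines.append("")
        for d, (k, _pct) in summary.donor_breakdown.items():
            lines.append(
                f"- from the {d} group: {format_percent(k, summary.n_hgt)} "
                f"({k} of {summary.n_hgt} trees)"
            )
    return "\n".join(lines) + "\n"
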