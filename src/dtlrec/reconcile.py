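"""Maximum-parsimony duplication-transfer-loss (DTL) reconciliation.

Maps a rooted binary gene tree onto a rooted binary species tree, charging
per-event costs for duplications (D), transfers (T) and losses (L), with
speciations free.  The model is the undated one: a transfer may join any
two species branches that are not in an ancestor-descendant relation, and
temporal feasibility is checked per reconciliation afterwards rather than
constrained during the search.

Beyond the optimal cost, the dynamic program carries exact solution counts
(arbitrary-precision integers), which enables (a) counting all optimal
reconciliations, (b) drawing one uniformly at random -- the replicate
mechanism used by the rest of the pipeline -- and (c) exhaustively listing
the optimum set.  A brute-force enumerator over all consistent histories
serves as an independent oracle for small instances.

Cost tables use exact ``Fraction`` arithmetic internally so that
co-optimality ties are detected exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional

import networkx as nx

from .trees import LabeledTree, TreeError, TreeIndex

__all__ = [
    "SPECIATION",
    "DUPLICATION",
    "TRANSFER",
    "CostScheme",
    "NOTUNG",
    "RANGER",
    "Event",
    "Reconciliation",
    "DTLReconciler",
    "reconcile_cost",
    "count_optimal",
    "sample_reconciliation",
    "enumerate_optimal",
    "brute_force_reconcile",
    "check_temporal_feasibility",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
TRANSFER = "transfer"

INF = math.inf


@dataclass(frozen=True)
class CostScheme:
    """Per-event costs; speciation is free by convention."""

    dup_cost: float = 2.0
    transfer_cost: float = 3.0
    loss_cost: float = 1.0

    def __post_init__(self):
        for name in ("dup_cost", "transfer_cost", "loss_cost"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def scaled(self, lam: float) -> "CostScheme":
        return CostScheme(self.dup_cost * lam, self.transfer_cost * lam, self.loss_cost * lam)


#: Notung's standard parameters.
NOTUNG = CostScheme(1.5, 3.0, 1.0)
#: Ranger-DTL's default parameters.
RANGER = CostScheme(2.0, 3.0, 1.0)

PRESETS = {"NOTUNG": NOTUNG, "RANGER": RANGER}


@dataclass(frozen=True)
class Event:
    """Event annotation at an internal gene-tree node.

    ``donor``/``recipient`` are species post-order indices (transfers only);
    ``moved_child`` is the gene post-order index of the transferred child.
    """

    type: str
    donor: Optional[int] = None
    recipient: Optional[int] = None
    moved_child: Optional[int] = None

    def as_tuple(self):
        return (self.type, self.donor, self.recipient, self.moved_child)


@dataclass
class Reconciliation:
    """One full annotation of a gene tree against a species tree."""

    gene: LabeledTree
    species: LabeledTree
    gidx: TreeIndex
    sidx: TreeIndex
    mapping: dict[int, int]
    events: dict[int, Event]
    loss_count: int
    total_cost: float

    def n_events(self) -> dict[str, int]:
        out = {SPECIATION: 0, DUPLICATION: 0, TRANSFER: 0}
        for ev in self.events.values():
            out[ev.type] += 1
        return out

    def recomputed_cost(self, costs: CostScheme) -> float:
        n = self.n_events()
        return (
            costs.dup_cost * n[DUPLICATION]
            + costs.transfer_cost * n[TRANSFER]
            + costs.loss_cost * self.loss_count
        )

    def canonical(self):
        """Hashable identity: (mapping, events, losses); used to compare
        reconciliation sets against the brute-force oracle."""
        return (
            tuple(sorted(self.mapping.items())),
            tuple(sorted((g, ev.as_tuple()) for g, ev in self.events.items())),
            self.loss_count,
        )

    def transfers(self) -> list[Event]:
        return [ev for ev in self.events.values() if ev.type == TRANSFER]

    def to_json_dict(self) -> dict:
        return {
            "total_cost": self.total_cost,
            "loss_count": self.loss_count,
            "mapping": {str(g): s for g, s in sorted(self.mapping.items())},
            "events": {
                str(g): {
                    "type": ev.type,
                    "donor": ev.donor,
                    "recipient": ev.recipient,
                    "moved_child": ev.moved_child,
                }
                for g, ev in sorted(self.events.items())
            },
        }

    @classmethod
    def from_json_dict(
        cls, d: dict, gene: LabeledTree, species: LabeledTree,
        gidx: Optional[TreeIndex] = None, sidx: Optional[TreeIndex] = None,
    ) -> "Reconciliation":
        gidx = gidx or TreeIndex(gene)
        sidx = sidx or TreeIndex(species)
        mapping = {int(g): s for g, s in d["mapping"].items()}
        events = {
            int(g): Event(e["type"], e["donor"], e["recipient"], e["moved_child"])
            for g, e in d["events"].items()
        }
        return cls(gene, species, gidx, sidx, mapping, events,
                   d["loss_count"], d["total_cost"])

    def to_tsv(self) -> str:
        """Per-node report: gene node, event, mapped/donor/recipient species."""
        lines = ["#gene_node\tevent\tmapping\tdonor\trecipient"]
        for g in sorted(self.events):
            ev = self.events[g]
            donor = self.sidx.name(ev.donor) if ev.donor is not None else "-"
            recip = self.sidx.name(ev.recipient) if ev.recipient is not None else "-"
            lines.append(
                f"{g}\t{ev.type}\t{self.sidx.name(self.mapping[g])}\t{donor}\t{recip}"
            )
        return "\n".join(lines) + "\n"


def _leafmap_indices(gidx: TreeIndex, sidx: TreeIndex, leafmap: dict[str, str]) -> dict[int, int]:
    out = {}
    for lab, i in gidx.leaf_index.items():
        if lab not in leafmap:
            raise TreeError(f"leafmap is missing gene leaf {lab!r}")
        sp = leafmap[lab]
        if sp not in sidx.leaf_index:
            raise TreeError(f"leafmap image {sp!r} is not a species-tree leaf")
        out[i] = sidx.leaf_index[sp]
    return out


def _require_rooted_binary(tree: LabeledTree, what: str) -> None:
    if tree.n_leaves() == 0:
        raise TreeError(f"{what} tree is empty")
    if not tree.is_binary():
        raise TreeError(
            f"{what} tree is not binary; resolve polytomies explicitly "
            "(trees.resolve_polytomies) before reconciling"
        )


class DTLReconciler:
    """DTL dynamic program over one (gene tree, species tree) pair.

    Tables are computed once at construction; ``optimal_cost``, ``count``,
    ``sample`` and ``enumerate`` all reuse them, so drawing many replicates
    is cheap.
    """

    def __init__(self, gene: LabeledTree, species: LabeledTree,
                 leafmap: dict[str, str], costs: CostScheme):
        _require_rooted_binary(gene, "gene")
        _require_rooted_binary(species, "species")
        self.gene, self.species, self.costs = gene, species, costs
        self.gidx = TreeIndex(gene)
        self.sidx = TreeIndex(species)
        self.lmap = _leafmap_indices(self.gidx, self.sidx, leafmap)
        self._D = Fraction(costs.dup_cost)
        self._T = Fraction(costs.transfer_cost)
        self._L = Fraction(costs.loss_cost)
        self._run_dp()

    # -- dynamic program -------------------------------------------------

    def _run_dp(self) -> None:
        gidx, sidx = self.gidx, self.sidx
        nG, nS = len(gidx.nodes), len(sidx.nodes)
        D, T, L = self._D, self._T, self._L
        # per (gene, species): exact-mapping cost, at-or-below cost with
        # per-edge loss charge, subtree minimum (no charge), and the best
        # over incomparable nodes; each with exact solution counts.
        self.c = [[INF] * nS for _ in range(nG)]
        self.cc = [[0] * nS for _ in range(nG)]
        self.inb = [[INF] * nS for _ in range(nG)]
        self.cin = [[0] * nS for _ in range(nG)]
        self.bm = [[INF] * nS for _ in range(nG)]
        self.cbm = [[0] * nS for _ in range(nG)]
        self.out = [[INF] * nS for _ in range(nG)]
        self.cout = [[0] * nS for _ in range(nG)]

        for g in range(nG):  # post-order
            if gidx.is_leaf(g):
                s0 = self.lmap[g]
                self.c[g][s0] = Fraction(0)
                self.cc[g][s0] = 1
            else:
                g1, g2 = gidx.children[g]
                for s in range(nS):
                    for val, cnt, _tag in self._options(g, s, g1, g2):
                        if cnt == 0:
                            continue
                        if val < self.c[g][s]:
                            self.c[g][s], self.cc[g][s] = val, cnt
                        elif val == self.c[g][s]:
                            self.cc[g][s] += cnt
            # at-or-below and subtree-min rows (species post-order)
            for s in range(nS):
                best, cnt = self.c[g][s], self.cc[g][s]
                bbest, bcnt = best, cnt
                for t in sidx.children[s]:
                    v = L + self.inb[g][t]
                    if v < best:
                        best, cnt = v, self.cin[g][t]
                    elif v == best:
                        cnt += self.cin[g][t]
                    bv = self.bm[g][t]
                    if bv < bbest:
                        bbest, bcnt = bv, self.cbm[g][t]
                    elif bv == bbest:
                        bcnt += self.cbm[g][t]
                self.inb[g][s], self.cin[g][s] = best, cnt
                self.bm[g][s], self.cbm[g][s] = bbest, bcnt
            # incomparable row (species pre-order = reversed post-order)
            for s in reversed(range(nS)):
                p = sidx.parent[s]
                if p < 0:
                    continue
                best, cnt = self.out[g][p], self.cout[g][p]
                for sib in sidx.children[p]:
                    if sib == s:
                        continue
                    v = self.bm[g][sib]
                    if v < best:
                        best, cnt = v, self.cbm[g][sib]
                    elif v == best:
                        cnt += self.cbm[g][sib]
                self.out[g][s], self.cout[g][s] = best, cnt

        root = gidx.root
        self._best = INF
        self._count = 0
        for s in range(nS):
            v = self.c[root][s]
            if v < self._best:
                self._best, self._count = v, self.cc[root][s]
            elif v == self._best:
                self._count += self.cc[root][s]
        if self._count == 0:  # pragma: no cover - total leafmap => feasible
            raise TreeError("no valid reconciliation exists")

    def _options(self, g: int, s: int, g1: int, g2: int):
        """Co-optimal candidate (cost, count) pairs for mapping g exactly at s."""
        sidx = self.sidx
        D, T = self._D, self._T
        opts = []
        kids = sidx.children[s]
        if kids:
            s1, s2 = kids
            opts.append((self.inb[g1][s1] + self.inb[g2][s2],
                         self.cin[g1][s1] * self.cin[g2][s2], ("spec", s1, s2)))
            opts.append((self.inb[g1][s2] + self.inb[g2][s1],
                         self.cin[g1][s2] * self.cin[g2][s1], ("spec", s2, s1)))
        opts.append((D + self.inb[g1][s] + self.inb[g2][s],
                     self.cin[g1][s] * self.cin[g2][s], ("dup",)))
        opts.append((T + self.inb[g1][s] + self.out[g2][s],
                     self.cin[g1][s] * self.cout[g2][s], ("tr", g2)))
        opts.append((T + self.inb[g2][s] + self.out[g1][s],
                     self.cin[g2][s] * self.cout[g1][s], ("tr", g1)))
        return opts

    # -- public results --------------------------------------------------

    @property
    def optimal_cost(self) -> float:
        return float(self._best)

    @property
    def count(self) -> int:
        return self._count

    # -- uniform sampling ------------------------------------------------

    def sample(self, rng: random.Random) -> Reconciliation:
        """One optimal reconciliation, uniform over the full optimum set.

        Every traceback choice is weighted by the exact number of optimal
        completions downstream, so the draw is exactly uniform.
        """
        state = _TracebackState()
        root = self.gidx.root
        s = _weighted_pick(
            rng,
            [(self.cc[root][s], s) for s in range(len(self.sidx.nodes))
             if self.c[root][s] == self._best],
        )
        self._trace_exact(root, s, rng, state)
        rec = Reconciliation(
            self.gene, self.species, self.gidx, self.sidx,
            state.mapping, state.events, state.losses, float(self._best),
        )
        assert rec.recomputed_cost(self.costs) == float(self._best)
        return rec

    def _trace_exact(self, g: int, s: int, rng, state) -> None:
        state.mapping[g] = s
        if self.gidx.is_leaf(g):
            return
        g1, g2 = self.gidx.children[g]
        target = self.c[g][s]
        choices = [(cnt, tag) for v, cnt, tag in self._options(g, s, g1, g2)
                   if cnt > 0 and v == target]
        tag = _weighted_pick(rng, choices)
        if tag[0] == "spec":
            _, s1, s2 = tag
            state.events[g] = Event(SPECIATION)
            self._trace_inbelow(g1, s1, rng, state)
            self._trace_inbelow(g2, s2, rng, state)
        elif tag[0] == "dup":
            state.events[g] = Event(DUPLICATION)
            self._trace_inbelow(g1, s, rng, state)
            self._trace_inbelow(g2, s, rng, state)
        else:
            moved = tag[1]
            stay = g1 if moved == g2 else g2
            x = _weighted_pick(
                rng,
                [(self.cc[moved][t], t) for t in range(len(self.sidx.nodes))
                 if not self.sidx.comparable(t, s) and self.c[moved][t] == self.out[moved][s]],
            )
            state.events[g] = Event(TRANSFER, donor=s, recipient=x, moved_child=moved)
            self._trace_inbelow(stay, s, rng, state)
            self._trace_exact(moved, x, rng, state)

    def _trace_inbelow(self, g: int, s: int, rng, state) -> None:
        L = self._L
        while True:
            target = self.inb[g][s]
            choices = []
            if self.c[g][s] == target and self.cc[g][s] > 0:
                choices.append((self.cc[g][s], None))
            for t in self.sidx.children[s]:
                if L + self.inb[g][t] == target and self.cin[g][t] > 0:
                    choices.append((self.cin[g][t], t))
            step = _weighted_pick(rng, choices)
            if step is None:
                self._trace_exact(g, s, rng, state)
                return
            state.losses += 1
            s = step

    # -- exhaustive enumeration of the optimum set -----------------------

    def enumerate(self, limit: int = 10000) -> list[Reconciliation]:
        if self._count > limit:
            raise ValueError(
                f"optimum set has {self._count} reconciliations, over the limit {limit}"
            )
        root = self.gidx.root
        out = []
        for s in range(len(self.sidx.nodes)):
            if self.c[root][s] != self._best:
                continue
            for mapping, events, losses in self._enum_exact(root, s):
                out.append(Reconciliation(
                    self.gene, self.species, self.gidx, self.sidx,
                    dict(mapping), dict(events), losses, float(self._best),
                ))
        assert len(out) == self._count
        return out

    def _enum_exact(self, g: int, s: int):
        if self.gidx.is_leaf(g):
            return [(((g, s),), (), 0)]
        g1, g2 = self.gidx.children[g]
        target = self.c[g][s]
        results = []
        for v, cnt, tag in self._options(g, s, g1, g2):
            if cnt == 0 or v != target:
                continue
            if tag[0] == "spec":
                _, s1, s2 = tag
                ev = (g, Event(SPECIATION))
                for m1, e1, l1 in self._enum_inbelow(g1, s1):
                    for m2, e2, l2 in self._enum_inbelow(g2, s2):
                        results.append((((g, s),) + m1 + m2, (ev,) + e1 + e2, l1 + l2))
            elif tag[0] == "dup":
                ev = (g, Event(DUPLICATION))
                for m1, e1, l1 in self._enum_inbelow(g1, s):
                    for m2, e2, l2 in self._enum_inbelow(g2, s):
                        results.append((((g, s),) + m1 + m2, (ev,) + e1 + e2, l1 + l2))
            else:
                moved = tag[1]
                stay = g1 if moved == g2 else g2
                for x in range(len(self.sidx.nodes)):
                    if self.sidx.comparable(x, s) or self.c[moved][x] != self.out[moved][s]:
                        continue
                    ev = (g, Event(TRANSFER, donor=s, recipient=x, moved_child=moved))
                    for m1, e1, l1 in self._enum_inbelow(stay, s):
                        for m2, e2, l2 in self._enum_exact(moved, x):
                            results.append((((g, s),) + m1 + m2, (ev,) + e1 + e2, l1 + l2))
        return results

    def _enum_inbelow(self, g: int, s: int):
        target = self.inb[g][s]
        results = []
        stack = [(s, 0)]
        while stack:
            cur, losses = stack.pop()
            here = target - losses * self._L
            if self.c[g][cur] == here and self.cc[g][cur] > 0:
                for m, e, l in self._enum_exact(g, cur):
                    results.append((m, e, l + losses))
            for t in self.sidx.children[cur]:
                if self._L + self.inb[g][t] == here and self.cin[g][t] > 0:
                    stack.append((t, losses + 1))
        return results


class _TracebackState:
    __slots__ = ("mapping", "events", "losses")

    def __init__(self):
        self.mapping: dict[int, int] = {}
        self.events: dict[int, Event] = {}
        self.losses = 0


def _weighted_pick(rng: random.Random, choices):
    """Exact big-integer weighted choice among (weight, payload) pairs."""
    total = sum(w for w, _ in choices)
    if total <= 0:
        raise AssertionError("no positive-weight choices")  # pragma: no cover
    r = rng.randrange(total)
    for w, payload in choices:
        if r < w:
            return payload
        r -= w
    raise AssertionError  # pragma: no cover


# -- module-level convenience wrappers -----------------------------------


def reconcile_cost(gene, species, leafmap, costs: CostScheme) -> float:
    """Minimal DTL cost of reconciling ``gene`` with ``species``."""
    return DTLReconciler(gene, species, leafmap, costs).optimal_cost


def count_optimal(gene, species, leafmap, costs: CostScheme) -> int:
    """Exact number of distinct optimal reconciliations."""
    return DTLReconciler(gene, species, leafmap, costs).count


def sample_reconciliation(gene, species, leafmap, costs: CostScheme, seed: int) -> Reconciliation:
    rec = DTLReconciler(gene, species, leafmap, costs)
    return rec.sample(random.Random(seed))


def enumerate_optimal(gene, species, leafmap, costs: CostScheme, limit: int = 10000):
    return DTLReconciler(gene, species, leafmap, costs).enumerate(limit)


# -- independent brute-force oracle --------------------------------------


def brute_force_reconcile(gene: LabeledTree, species: LabeledTree,
                          leafmap: dict[str, str], costs: CostScheme):
    """Exhaustive enumeration of every consistent DTL history (no cost DP).

    Recursively generates, for each gene node mapped exactly at each
    species node, all event assignments and child mappings allowed by the
    DTL semantics, then takes the true minimum over the complete list.
    Only intended as a test oracle; both trees must have <= 7 leaves.

    Returns ``(min_cost, optima)`` where optima is a list of canonical
    history tuples in the same shape as ``Reconciliation.canonical()``.
    """
    if gene.n_leaves() > 7 or species.n_leaves() > 7:
        raise ValueError("brute_force_reconcile is limited to trees with <= 7 leaves")
    _require_rooted_binary(gene, "gene")
    _require_rooted_binary(species, "species")
    gidx, sidx = TreeIndex(gene), TreeIndex(species)
    lmap = _leafmap_indices(gidx, sidx, leafmap)
    nS = len(sidx.nodes)
    depth = sidx.depth
    sub = {s: [x for x in range(nS) if sidx.is_ancestor(s, x)] for s in range(nS)}
    incomp = {s: [x for x in range(nS) if not sidx.comparable(s, x)] for s in range(nS)}

    @lru_cache(maxsize=None)
    def hist(g: int, s: int):
        """All histories of the g-subtree with g mapped exactly at s:
        tuples of (mapping items, event items, loss count)."""
        if gidx.is_leaf(g):
            return (((((g, s),), (), 0),) if lmap[g] == s else ())
        g1, g2 = gidx.children[g]
        results = []

        def combine(x1, x2, ev, local_losses):
            for m1, e1, l1 in hist(g1, x1):
                for m2, e2, l2 in hist(g2, x2):
                    results.append(
                        (((g, s),) + m1 + m2, ((g, ev),) + e1 + e2,
                         local_losses + l1 + l2)
                    )

        kids = sidx.children[s]
        if kids:
            s1, s2 = kids
            for x1 in sub[s1]:
                for x2 in sub[s2]:
                    combine(x1, x2, (SPECIATION, None, None, None),
                            (depth[x1] - depth[s1]) + (depth[x2] - depth[s2]))
            for x1 in sub[s2]:
                for x2 in sub[s1]:
                    combine(x1, x2, (SPECIATION, None, None, None),
                            (depth[x1] - depth[s2]) + (depth[x2] - depth[s1]))
        for x1 in sub[s]:
            for x2 in sub[s]:
                combine(x1, x2, (DUPLICATION, None, None, None),
                        (depth[x1] - depth[s]) + (depth[x2] - depth[s]))
        for xs in sub[s]:
            for xm in incomp[s]:
                combine(xs, xm, (TRANSFER, s, xm, g2), depth[xs] - depth[s])
                combine(xm, xs, (TRANSFER, s, xm, g1), depth[xs] - depth[s])
        return tuple(results)

    best = INF
    optima = []
    for s in range(nS):
        for mapping, events, losses in hist(gidx.root, s):
            nd = sum(1 for _, ev in events if ev[0] == DUPLICATION)
            nt = sum(1 for _, ev in events if ev[0] == TRANSFER)
            cost = (Fraction(costs.dup_cost) * nd + Fraction(costs.transfer_cost) * nt
                    + Fraction(costs.loss_cost) * losses)
            if cost < best:
                best = cost
                optima = []
            if cost == best:
                optima.append((tuple(sorted(mapping)),
                               tuple(sorted(events)), losses))
    hist.cache_clear()
    return float(best), optima


# -- temporal feasibility -------------------------------------------------


def check_temporal_feasibility(rec: Reconciliation, species: Optional[LabeledTree] = None):
    """Check that the transfers of ``rec`` admit a consistent time order.

    Builds the standard constraint digraph over species nodes: ancestry
    edges parent -> child, plus for each transfer donor d -> recipient r the
    coexistence constraints parent(d) -> r and parent(r) -> d.  The history
    is feasible iff the digraph is acyclic; otherwise a witness cycle is
    returned as a sequence of species node names.
    """
    sidx = rec.sidx if species is None else TreeIndex(species)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(sidx.nodes)))
    for s in range(len(sidx.nodes)):
        for t in sidx.children[s]:
            graph.add_edge(s, t)
    for ev in rec.transfers():
        d, r = ev.donor, ev.recipient
        pd, pr = sidx.parent[d], sidx.parent[r]
        if pd >= 0:
            graph.add_edge(pd, r)
        if pr >= 0:
            graph.add_edge(pr, d)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return True, []
    return False, [sidx.name(u) for u, _ in cycle]
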