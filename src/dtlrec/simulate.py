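"""Forward simulation of gene families under a DTL process.

Generates ultrametric (Yule) species trees with labeled clades and gene
families evolved along them with duplication, transfer and loss events at
given rates, recording the ground-truth history.  A planted-transfer mode
emulates the scenario of interest for gene-cluster evolution studies: a
gene family carried by a donor clade is transferred exactly once into the
stem of a recipient clade, which carries no native copy beforehand.

Transfers are simulated on the dated tree (donor and recipient branches
coexist at the event time), so every simulated history is temporally
feasible by construction even though downstream inference is undated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trees import LabeledTree, Node, TreeError, TreeIndex, mrca

__all__ = [
    "SimulationError",
    "SimParams",
    "TruthEvent",
    "SimulatedFamily",
    "Study",
    "simulate_species_tree",
    "simulate_family",
    "plant_clade_transfer",
    "perturb_tree",
    "make_study",
    "write_study",
    "DEFAULT_FAMILY_NAMES",
]

#: Gene-cluster style family names used by default in synthetic studies.
DEFAULT_FAMILY_NAMES = (
    "Mad26", "Mad25", "Mad24", "Mad23", "MamO-Cter", "Man6", "Man5", "Man4",
    "MamQ", "MamE", "MamI", "MamA", "Mad2", "MamB", "MamQ-2", "Mad31",
    "MamM", "MamP", "Man3", "Mad10", "Man2", "MamK", "Man1",
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Simulation settings.

    Rates are events per gene lineage per unit branch time; the species
    tree height is set by the Yule ``birth_rate``.
    """

    n_species: int = 30
    birth_rate: float = 1.0
    dup_rate: float = 0.0
    transfer_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 0
    nni_moves: int = 0
    planted: Optional[tuple[str, str]] = None  # (donor group, recipient group)

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        for name in ("dup_rate", "transfer_rate", "loss_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.nni_moves < 0:
            raise ValueError("nni_moves must be >= 0")


@dataclass(frozen=True)
class TruthEvent:
    type: str  # "D" | "T" | "L"
    species: str  # branch (named by its child-end species node)
    time: float
    donor: str = ""
    recipient: str = ""
    planted: bool = False

    def to_json_dict(self) -> dict:
        return {
            "type": self.type, "species": self.species, "time": self.time,
            "donor": self.donor, "recipient": self.recipient, "planted": self.planted,
        }


@dataclass
class SimulatedFamily:
    gene_tree: Optional[LabeledTree]  # None when the family went extinct
    leafmap: dict[str, str]
    truth: list[TruthEvent]


# -- species tree ---------------------------------------------------------


def simulate_species_tree(n_species: int, birth_rate: float, seed: int) -> LabeledTree:
    """Ultrametric Yule tree with leaves labeled S1..Sn; deterministic per seed."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.children = [a, b]
    active: list[tuple[Node, float]] = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = t - born
        c1, c2 = Node(), Node()
        node.children = [c1, c2]
        active.extend([(c1, t), (c2, t)])
    height = t + rng.exponential(1.0 / (len(active) * birth_rate))
    for node, born in active:
        node.length = height - born
    k = 0
    for node in root.postorder():
        if node.is_leaf():
            k += 1
            node.label = f"S{k}"
    return LabeledTree(root)


def _node_ages(sidx: TreeIndex) -> list[float]:
    """Time from the root (age 0) to each node; requires branch lengths."""
    ages = [0.0] * len(sidx.nodes)
    for s in reversed(range(len(sidx.nodes))):  # pre-order
        p = sidx.parent[s]
        if p >= 0:
            ln = sidx.nodes[s].length
            if ln is None:
                raise TreeError("species tree must have branch lengths")
            ages[s] = ages[p] + ln
    return ages


def _check_ultrametric(sidx: TreeIndex, ages: list[float]) -> float:
    tips = [ages[s] for s in range(len(sidx.nodes)) if sidx.is_leaf(s)]
    height = max(tips)
    if height <= 0 or (height - min(tips)) > 1e-6 * height:
        raise TreeError("species tree is not ultrametric")
    return height


# -- gene genealogy -------------------------------------------------------


class _GN:
    """Genealogy node: full record including extinct lineages."""

    __slots__ = ("kind", "time", "sp", "children")

    def __init__(self, kind: str, time: float, sp: int):
        self.kind = kind  # "spec" | "dup" | "tr" | "loss" | "leaf"
        self.time = time
        self.sp = sp
        self.children: list["_GN"] = []


class _Genealogy:
    def __init__(self, species: LabeledTree, params: SimParams, rng,
                 blocked: Optional[int] = None, no_transfer_into: Optional[int] = None):
        self.sidx = TreeIndex(species)
        self.ages = _node_ages(self.sidx)
        _check_ultrametric(self.sidx, self.ages)
        self.params = params
        self.rng = rng
        self.blocked = blocked
        self.no_transfer_into = no_transfer_into
        self.truth: list[TruthEvent] = []
        self.segments: list[tuple[int, float, float, _GN]] = []
        self._branches = [s for s in range(len(self.sidx.nodes)) if self.sidx.parent[s] >= 0]

    def _alive(self, t: float, exclude: int) -> list[int]:
        out = []
        for v in self._branches:
            if v == exclude:
                continue
            if self.no_transfer_into is not None and self.sidx.is_ancestor(self.no_transfer_into, v):
                continue
            if self.ages[self.sidx.parent[v]] < t < self.ages[v]:
                out.append(v)
        return out

    def _name(self, s: int) -> str:
        return self.sidx.name(s)

    def run(self) -> _GN:
        root = self.sidx.root
        gn = _GN("spec", 0.0, root)
        for c in self.sidx.children[root]:
            if c == self.blocked:
                continue
            gn.children.append(self.evolve(c, 0.0))
        return gn

    def evolve(self, v: int, t0: float) -> _GN:
        """One gene lineage on the branch of species node v from time t0."""
        p = self.params
        total = p.dup_rate + p.transfer_rate + p.loss_rate
        t_end = self.ages[v]
        dt = self.rng.exponential(1.0 / total) if total > 0 else math.inf
        if t0 + dt >= t_end:
            if self.sidx.is_leaf(v):
                gn = _GN("leaf", t_end, v)
            else:
                gn = _GN("spec", t_end, v)
                for c in self.sidx.children[v]:
                    if c == self.blocked:
                        continue
                    gn.children.append(self.evolve(c, t_end))
            self.segments.append((v, t0, t_end, gn))
            return gn
        t = t0 + dt
        u = self.rng.random() * total
        if u < p.dup_rate:
            gn = _GN("dup", t, v)
            self.truth.append(TruthEvent("D", self._name(v), t))
            self.segments.append((v, t0, t, gn))
            gn.children = [self.evolve(v, t), self.evolve(v, t)]
            return gn
        if u < p.dup_rate + p.transfer_rate:
            recipients = self._alive(t, exclude=v)
            if recipients:
                r = recipients[int(self.rng.integers(len(recipients)))]
                gn = _GN("tr", t, v)
                self.truth.append(
                    TruthEvent("T", self._name(v), t,
                               donor=self._name(v), recipient=self._name(r))
                )
                self.segments.append((v, t0, t, gn))
                gn.children = [self.evolve(v, t), self.evolve(r, t)]
                return gn
            # no coexisting recipient: the attempt lapses, lineage continues
            return self.evolve(v, t)
        gn = _GN("loss", t, v)
        self.truth.append(TruthEvent("L", self._name(v), t))
        self.segments.append((v, t0, t, gn))
        return gn


def _genealogy_to_family(root_gn: _GN, sidx: TreeIndex,
                         truth: list[TruthEvent]) -> SimulatedFamily:
    """Prune extinct lineages, suppress unary nodes, label leaves."""
    copy_counter: dict[int, int] = {}
    leafmap: dict[str, str] = {}

    def build(gn: _GN, parent_time: float) -> Optional[Node]:
        if gn.kind == "loss":
            return None
        if gn.kind == "leaf":
            sp_label = sidx.nodes[gn.sp].label
            copy_counter[gn.sp] = copy_counter.get(gn.sp, 0) + 1
            label = f"{sp_label}|g{copy_counter[gn.sp]}"
            leafmap[label] = sp_label
            return Node(label, gn.time - parent_time)
        kids = [k for k in (build(c, gn.time) for c in gn.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + (gn.time - parent_time)
            return kids[0]
        node = Node("", gn.time - parent_time)
        node.children = kids
        return node

    root = build(root_gn, 0.0)
    truth = sorted(truth, key=lambda e: e.time)
    if root is None:
        return SimulatedFamily(None, {}, truth)
    root.length = None
    return SimulatedFamily(LabeledTree(root), leafmap, truth)


def simulate_family(species: LabeledTree, params: SimParams) -> SimulatedFamily:
    """One gene family evolved forward along the dated species tree.

    A single gene lineage enters at the species root; along every species
    branch, duplications, transfers and losses arrive as a Poisson process
    at the given rates.  A transfer's recipient is drawn uniformly among
    the species branches alive at the event time (excluding the donor).
    Fully extinct families are returned with ``gene_tree=None``.
    """
    rng = np.random.default_rng(params.seed)
    sim = _Genealogy(species, params, rng)
    root_gn = sim.run()
    return _genealogy_to_family(root_gn, sim.sidx, sim.truth)


# -- planted ancestral transfer ------------------------------------------


def _clade_node(tree: LabeledTree, sidx: TreeIndex, labels: set[str], what: str) -> int:
    node = mrca(tree, labels)
    i = sidx.index[id(node)]
    under = {sidx.nodes[j].label for j in sidx.leaves_under(i)}
    if under != labels:
        raise SimulationError(
            f"{what} clade {sorted(labels)} is not monophyletic "
            f"(its MRCA also spans {sorted(under - labels)})"
        )
    return i


def plant_clade_transfer(species: LabeledTree, donor_clade: set[str],
                         recipient_clade: set[str], params: SimParams) -> SimulatedFamily:
    """Family with one forced ancestral transfer donor-clade -> recipient stem.

    The family evolves vertically (with the background rates) everywhere
    except that no native copy enters the recipient clade; instead, all
    recipient-clade copies descend from a single transfer out of a branch
    inside (or the stem of) the donor clade into the recipient clade's
    stem branch.  Background transfers are not allowed to land inside the
    recipient clade, preserving the single-origin guarantee.
    """
    donor_clade, recipient_clade = set(donor_clade), set(recipient_clade)
    if donor_clade & recipient_clade:
        raise SimulationError("donor and recipient clades overlap")
    rng = np.random.default_rng(params.seed)
    pre_sidx = TreeIndex(species)
    d_node = _clade_node(species, pre_sidx, donor_clade, "donor")
    r_node = _clade_node(species, pre_sidx, recipient_clade, "recipient")
    if pre_sidx.comparable(d_node, r_node):
        raise SimulationError("donor and recipient clades are nested")

    sim = _Genealogy(species, params, rng, blocked=r_node, no_transfer_into=r_node)
    sidx, ages = sim.sidx, sim.ages
    root_gn = sim.run()

    # branches of the donor clade, stem included
    donor_branches = {v for v in range(len(sidx.nodes))
                      if sidx.parent[v] >= 0 and sidx.is_ancestor(d_node, v)}
    donor_branches.add(d_node)
    r_parent = sidx.parent[r_node]
    stem_lo, stem_hi = ages[r_parent], ages[r_node]
    candidates = []
    for v, s0, s1, gn in sim.segments:
        if v not in donor_branches:
            continue
        lo, hi = max(s0, stem_lo), min(s1, stem_hi)
        if hi > lo:
            candidates.append((v, lo, hi, gn))
    if not candidates:
        raise SimulationError(
            "no surviving donor-clade gene lineage coexists with the "
            "recipient clade's stem branch; cannot place the planted transfer"
        )
    v, lo, hi, target = candidates[int(rng.integers(len(candidates)))]
    t_star = float(rng.uniform(lo, hi))

    # the transferred lineage evolves from the recipient stem at t*
    sim.no_transfer_into = None
    sim.blocked = None
    moved = sim.evolve(r_node, t_star)

    # splice the transfer node above `target` in the genealogy
    tr_node = _GN("tr", t_star, v)
    tr_node.children = [target, moved]
    spliced = False
    stack = [root_gn]
    while stack:
        gn = stack.pop()
        for i, ch in enumerate(gn.children):
            if ch is target:
                gn.children[i] = tr_node
                spliced = True
                break
            stack.append(ch)
        if spliced:
            break
    if not spliced:  # pragma: no cover - target is always reachable
        raise SimulationError("internal error: transfer splice point not found")
    sim.truth.append(
        TruthEvent("T", sidx.name(v), t_star, donor=sidx.name(v),
                   recipient=sidx.name(r_node), planted=True)
    )
    return _genealogy_to_family(root_gn, sidx, sim.truth)


# -- topology noise -------------------------------------------------------


def perturb_tree(tree: LabeledTree, nni_moves: int, seed: int) -> LabeledTree:
    """Apply random nearest-neighbor interchanges; models inference error."""
    if not tree.is_binary():
        raise TreeError("NNI perturbation requires a binary tree")
    if tree.n_leaves() < 4:
        raise TreeError("NNI perturbation requires at least 4 leaves")
    rng = np.random.default_rng(seed)
    new = tree.copy()
    for _ in range(nni_moves):
        idx = TreeIndex(new)
        # internal edges of the *unrooted* topology: (u, v) with an internal
        # non-root parent, plus the edge joining two internal root children
        edges: list[tuple[str, int, int]] = [
            ("cross", idx.parent[v], v)
            for v in range(len(idx.nodes))
            if not idx.is_leaf(v)
            and idx.parent[v] >= 0 and idx.parent[v] != idx.root
        ]
        rc = idx.children[idx.root]
        if len(rc) == 2 and not idx.is_leaf(rc[0]) and not idx.is_leaf(rc[1]):
            edges.append(("root", rc[0], rc[1]))
        if not edges:
            raise TreeError("tree has no internal edge eligible for NNI")
        kind, x, y = edges[int(rng.integers(len(edges)))]
        i = int(rng.integers(2))
        if kind == "cross":
            # swap the chosen child of y with y's sibling under x
            xnode, ynode = idx.nodes[x], idx.nodes[y]
            sib = next(c for c in xnode.children if c is not ynode)
            child = ynode.children[i]
            xnode.children[xnode.children.index(sib)] = child
            ynode.children[i] = sib
        else:
            # NNI across the edge between the two root children
            xnode, ynode = idx.nodes[x], idx.nodes[y]
            xnode.children[i], ynode.children[0] = ynode.children[0], xnode.children[i]
        new = LabeledTree(new.root)
    return new


# -- complete synthetic study ---------------------------------------------


@dataclass
class Study:
    """A synthetic dataset shaped like a gene-cluster reconciliation study."""

    species_tree: LabeledTree
    groups: dict[str, str]  # species leaf -> group name
    group_clades: dict[str, set[str]]  # group name -> leaf set
    donor_group: str
    recipient_group: str
    families: dict[str, SimulatedFamily] = field(default_factory=dict)
    seed: int = 0


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31 - 1)


def _pick_group_clades(sidx: TreeIndex, ages: list[float], n_species: int):
    """Three disjoint clades (donor, recipient, third) of moderate size with
    donor/recipient temporal overlap so the planted transfer is datable."""
    lo = 4 if n_species >= 20 else 3
    hi = max(lo + 1, n_species // 3)
    cands = [
        s for s in range(len(sidx.nodes))
        if not sidx.is_leaf(s) and sidx.parent[s] >= 0
        and lo <= len(sidx.leaves_under(s)) <= hi
    ]
    for a in cands:  # donor
        for b in cands:  # recipient
            if b == a or sidx.comparable(a, b):
                continue
            if ages[sidx.parent[a]] >= ages[b]:
                continue  # donor clade arises after the recipient stem ends
            for c in cands:
                if c in (a, b) or sidx.comparable(c, a) or sidx.comparable(c, b):
                    continue
                return a, b, c
    return None


def make_study(
    seed: int,
    n_species: int = 30,
    n_families: int = 22,
    birth_rate: float = 1.0,
    dup_rate: float = 0.0,
    transfer_rate: float = 0.0,
    loss_rate: float = 0.0,
    nni_moves: int = 0,
    group_names: tuple[str, str, str] = (
        "Magnetobacteriaceae", "Dissulfurispiraceae", "Thermodesulfobacteriota_man",
    ),
    family_names: Optional[list[str]] = None,
) -> Study:
    """Species tree with three labeled groups + gene families, each carrying
    one planted ancestral transfer from the first group into the second.

    The defaults mirror a gene-cluster study: ~30 genomes, 22 families,
    pure vertical descent apart from the planted transfer, with optional
    NNI noise standing in for tree-inference error.
    """
    if family_names is None:
        family_names = list(DEFAULT_FAMILY_NAMES[:n_families])
    if len(family_names) != n_families:
        raise ValueError("family_names length must equal n_families")
    donor_name, recip_name, third_name = group_names

    species = None
    for attempt in range(64):
        cand = simulate_species_tree(n_species, birth_rate, _derive_seed(seed, attempt))
        sidx = TreeIndex(cand)
        ages = _node_ages(sidx)
        picked = _pick_group_clades(sidx, ages, n_species)
        if picked is not None:
            species = cand
            a, b, c = picked
            break
    if species is None:  # pragma: no cover - 64 Yule draws always suffice
        raise SimulationError("could not find three suitable group clades")

    clades = {
        donor_name: {sidx.nodes[j].label for j in sidx.leaves_under(a)},
        recip_name: {sidx.nodes[j].label for j in sidx.leaves_under(b)},
        third_name: {sidx.nodes[j].label for j in sidx.leaves_under(c)},
    }
    groups = {}
    for leaf in species.leaf_labels():
        groups[leaf] = "other"
        for gname, members in clades.items():
            if leaf in members:
                groups[leaf] = gname
    study = Study(species, groups, clades, donor_name, recip_name, seed=seed)
    for i, name in enumerate(family_names):
        params = SimParams(
            n_species=n_species, birth_rate=birth_rate, dup_rate=dup_rate,
            transfer_rate=transfer_rate, loss_rate=loss_rate,
            seed=_derive_seed(seed, 10_000 + i), nni_moves=nni_moves,
            planted=(donor_name, recip_name),
        )
        fam = plant_clade_transfer(species, clades[donor_name], clades[recip_name], params)
        if nni_moves > 0 and fam.gene_tree is not None and fam.gene_tree.n_leaves() >= 4:
            fam.gene_tree = perturb_tree(
                fam.gene_tree, nni_moves, _derive_seed(seed, 20_000 + i)
            )
        study.families[name] = fam
    return study


def write_study(study: Study, outdir) -> None:
    """Write a synthetic study directory: Newick trees, maps, truth JSONs."""
    import json
    from pathlib import Path

    from .trees import write_newick, write_tsv_map

    out = Path(outdir)
    (out / "families").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    (out / "species.nwk").write_text(write_newick(study.species_tree), encoding="utf-8")
    write_tsv_map(out / "groups.tsv", study.groups, header="species\tgroup")
    leafmap: dict[str, str] = {}
    for name, fam in study.families.items():
        if fam.gene_tree is None:
            continue
        (out / "families" / f"{name}.nwk").write_text(
            write_newick(fam.gene_tree), encoding="utf-8"
        )
        leafmap.update(fam.leafmap)
        (out / "truth" / f"{name}.json").write_text(
            json.dumps([e.to_json_dict() for e in fam.truth], indent=1),
            encoding="utf-8",
        )
    write_tsv_map(out / "leafmap.tsv", leafmap, header="gene_leaf\tspecies")
    meta = {
        "seed": study.seed,
        "donor_group": study.donor_group,
        "recipient_group": study.recipient_group,
        "families": sorted(study.families),
    }
    (out / "study.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
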