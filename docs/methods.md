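# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `dtlrec`, in the order the pipeline uses them.

## Trees and input conventions

All stages operate on rooted trees with uniquely labeled leaves
(`dtlrec.trees.LabeledTree`). Newick parsing is delegated to dendropy;
square-bracket comments are stripped, quoted labels and underscores are
preserved verbatim, and only bare numbers after `:` are accepted as
branch lengths. Parse errors report a character offset. Writing is done
by the package itself with full-precision (`repr`) lengths so that
parse–write round-trips are exact.

Reconciliation requires binary trees. Polytomies are rejected with an
explicit error rather than silently resolved — maximum-likelihood tree
inference produces binary trees, so a multifurcation in the input usually
indicates an upstream problem. A seeded random resolution
(`resolve_polytomies`) is available as an explicit opt-in.

Rooting follows the conventions of phylogenomic practice: species trees
are rooted on an outgroup (`outgroup_root` places the root at the
midpoint of the edge realizing the outgroup bipartition and reports the
offending split when the outgroup is not monophyletic), while protein
trees without a reliable outgroup are midpoint-rooted. Midpoint ties
between equally long leaf-to-leaf paths are broken by lexicographic order
of the sorted endpoint-label pair; this keeps the operation deterministic
(the choice is otherwise arbitrary and the paper trail of any real
dataset rarely records it). `prune_to` restricts a tree to a leaf subset,
suppressing unary nodes with branch lengths summed, so pairwise path
lengths among kept leaves are preserved.

When no leaf-to-species map is supplied, gene-tree leaf labels are split
on the first `|` as `species|gene_id`; labels without `|` map to
themselves. An explicit 2-column TSV map always takes precedence.

Internal species nodes are reported as `mrca(a,b)` where `a` and `b` are
the smallest leaf labels of the node's two child subtrees — a pair whose
MRCA identifies the node uniquely (naming by a subtree's extreme leaves
alone can collide between nested nodes).

## DTL parsimony engine

The engine implements undated duplication–transfer–loss parsimony with
free speciations, the model shared by the Ranger-DTL default and by
Notung's DTL mode. Transfers may connect any two species nodes that are
not in an ancestor–descendant relation. Losses are charged implicitly,
one per skipped species edge, through the "at-or-below" table; the loss
count of a concrete reconciliation is reconstructed during traceback.
The gene root may map to any species node with no loss charged above it.
Cost presets: `NOTUNG` (D=1.5, T=3, L=1) and `RANGER` (D=2, T=3, L=1);
custom non-negative triples are accepted.

Cost arithmetic uses exact `Fraction` values internally. This matters
because counting and uniform sampling hinge on detecting *exact*
co-optimality ties; binary floats would be safe for the built-in presets
but not for arbitrary user-supplied costs.

Alongside each cost table the engine stores the exact number of optimal
completions as an arbitrary-precision integer. Three consumers build on
the counts:

- `count_optimal` — the size of the optimum set (distinct
  mapping-plus-event annotations at minimal cost).
- `sample_reconciliation` — traceback in which every tie is resolved by
  a big-integer weighted draw over the counts of the competing options,
  giving an exactly uniform sample over all optima. Replicate variation
  in the pipeline comes solely from this sampling; costs are never
  perturbed.
- `enumerate_optimal` — exhaustive expansion of the optimum set, guarded
  by a limit checked against the count first.

A transfer's recipient is the species node the moved child maps to; no
losses are charged above a transfer landing. Consequently the three event
options can tie on the same mapping (e.g. a speciation and a duplication
explaining the same child placements) and are counted as distinct
reconciliations, matching how the brute-force enumerator counts
histories.

### Independent oracle

`brute_force_reconcile` recursively generates *every* history consistent
with the DTL semantics — all event assignments and child mappings, not
just optimal ones — and takes the minimum at the end. It shares no
recurrence with the dynamic program (it never forms the `in`/`out`
minimization tables; per-node enumeration lists are memoized purely to
avoid recomputation). It is restricted to trees of at most 7 leaves and
exists for validation: the test suite checks cost, count and optimum-set
equality on hundreds of random instances.

### Temporal feasibility

Feasibility of a reconciliation's transfer set is decided on the standard
constraint digraph over species nodes: ancestry edges `parent → child`,
plus `parent(d) → r` and `parent(r) → d` for each transfer `d → r`. The
history is feasible iff the digraph is acyclic (cycle detection via
networkx); an infeasible history comes with a witness cycle. Feasibility
is a post-hoc annotation, not a search constraint: the pipeline reports
the feasible fraction of replicates and keeps infeasible ones by default
(Ranger-like undated behavior), with a `--feasibility-filter` flag to
drop them (Notung-strict behavior).

## Replicate aggregation

`aggregate` tallies, per internal gene-tree node over R replicates, the
frequency of each event type, each species mapping, and each transfer
donor. Frequencies are exact counts divided by R. Node identity across
replicates is the gene tree's stable post-order index — not the species
mapping, which varies between replicates. Events live on internal nodes
only; leaves carry none in the DTL model, so aggregation is over internal
nodes even though per-tool output formats sometimes speak of "leaf"
rows.

## Origin classification

For a focal species group and one family, each replicate votes:

1. Collect the gene leaves whose species belong to the focal group; no
   leaves means the family is ABSENT for that group.
2. Take their gene-tree MRCA `m` and walk rootward from `m`. The first
   event in which the walked lineage is a transfer *recipient* (the
   transferred child is the lineage itself) makes the replicate vote
   HGT, with the donor group read off the transfer's donor species node.
   Reaching the root without such an event votes VERTICAL.

The "first transfer walking rootward" rule reflects that the most recent
transfer into a lineage determines the clade's proximate origin, which is
what donor statements in comparative studies refer to. A donor species
node's group is the unanimous group of its descendant leaves, else
`"mixed"` (reported and counted as such).

If the focal leaves are not monophyletic in the gene tree (common under
topology noise), each maximal all-focal clade votes and the replicate
takes the within-replicate majority, with ties leaning HGT — an
acquisition signal in any sub-clade is evidence of transfer — and a
warning is attached to the call.

Per-family calls are strict majorities over replicates (> R/2); exact
ties yield AMBIGUOUS. Support is the winning fraction. Cross-family
summaries exclude ABSENT families from the denominator; percentages are
formatted by half-up rounding to one decimal (`format_percent`), the
style used in published tallies such as "90.9% (20 of 22 trees)".

## Simulator

`simulate_species_tree` draws a Yule (pure-birth) tree: starting from two
lineages at the root, each of `k` lineages splits after an exponential
wait with rate `k·birth_rate`; after the (n−1)-th split a final
exponential interval sets the present, making the tree ultrametric.
Leaves are labeled `S1..Sn`.

`simulate_family` runs a forward DTL process on the dated tree: one gene
lineage enters at the species root, and along each species branch events
arrive as a Poisson process with the per-lineage rates `dup_rate`,
`transfer_rate`, `loss_rate` (events per unit branch time). A transfer's
recipient branch is drawn uniformly among species branches alive at the
event time, excluding the donor — so simulated histories are temporally
feasible by construction, and the feasibility checker must never flag
them (tested). Duplications fork the lineage in place, losses end it,
and lineages surviving to the present become leaves labeled
`Sk|g1, Sk|g2, …`. Extinct subtrees are pruned and unary nodes
suppressed before output; a fully extinct family returns no gene tree.
Ground truth records every event with its time and branches.

`plant_clade_transfer` forces the scenario of interest: the family
evolves vertically everywhere except that no native copy enters the
recipient clade's stem; instead a single transfer is placed at a seeded
uniform time in the overlap between the recipient stem's interval and a
surviving donor-clade gene lineage (stem included), and the transferred
lineage then evolves normally inside the recipient clade. Background
transfers are barred from landing inside the recipient clade so that all
recipient copies descend from the one planted event. With nonzero
background rates it is possible for the realized history to leave no
donor lineage coexisting with the recipient stem; this raises an error
rather than silently resampling.

Note a consequence of the "no native copy" construction: the parsimony
explanation of a planted family is one transfer *plus one loss on the
recipient stem* (the vertical backbone must skip the stem), so the
optimal cost is `T + L`, not `T`, whenever the recipient clade is not a
child of the species root. The planted donor/recipient pair is still
recovered in every optimal reconciliation (tested against the oracle).

`perturb_tree` models tree-inference error with random
nearest-neighbor interchanges on internal edges of the *unrooted*
topology (including the edge joining two internal root children); leaf
sets are preserved and moves are seeded.

`make_study` assembles a complete synthetic study: a Yule tree whose
three labeled groups are disjoint clades (size 4–12 at the default 30
species) chosen deterministically subject to the donor clade's lifespan
overlapping the recipient clade's stem (so the planted transfer is
datable), plus one planted-transfer family per gene-cluster-style family
name (`Mad26 … Man1`, 22 by default). Per-family seeds derive from the
study seed, so regenerating with more families never changes existing
ones.

### What the simulator does and does not emulate

The generator reproduces the *structure* of a gene-cluster
reconciliation study — a genome tree with labeled groups, per-family
gene trees shaped by shared vertical descent plus one ancestral
interphylum-style transfer, and reconstruction noise via NNI moves. It
does not simulate sequences (no alignment or inference step; noise is
injected directly into topologies), rate heterogeneity across branches,
incomplete lineage sorting, or genome sampling biases. Passing the
recovery tests therefore demonstrates that the inference chain is
correct and robust to modest topological error, not that any particular
empirical dataset's percentages would be reproduced.

## Pipeline defaults and numerical choices

- Replicates: 100 per family (the convention of sampling-based
  reconciliation runs); per-family seed = master seed XOR CRC32 of the
  family name.
- Both cost presets are intended to be run side by side, mirroring the
  two-tool practice; the acceptance script does so.
- Study scale for validation runs: 30 species, 3 groups, 22 families,
  R=100, with 0 or 2 NNI noise moves per gene tree. These sizes keep the
  full validation suite fast while matching the shape of a real
  gene-cluster study.
- Ultrametricity is checked with relative tolerance 1e-6; midpoint path
  comparisons use an absolute 1e-12 slack to make tie detection robust
  to float summation order.
- Degenerate inputs: single-leaf gene trees reconcile at cost 0 with no
  events; empty trees, non-binary trees, and incomplete leaf maps are
  errors.

## Known limitations

- Undated parsimony only: no time-sliced/dated reconciliation and no
  likelihood model (ALE-style sampling is out of scope).
- No reconciliation-aware gene-tree correction: input topologies are
  taken as fixed (no rearrangement mode, no bootstrap-threshold
  collapsing beyond the explicit polytomy-resolution helper).
- The origin classifier attributes a donor *group*, not a donor branch;
  when both transfer directions between two groups are supported by
  different families, deciding which group was the ultimate donor is
  left to the analyst.
- Uniform replicate sampling explores co-optimal histories only;
  near-optimal histories carry no weight.
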