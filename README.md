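# dtlrec

Gene-tree/species-tree reconciliation for detecting horizontal transfer of
gene clusters, built around the kind of question raised by the magnetosome
gene cluster (MGC) of magnetotactic bacteria: did a focal group of genomes
(say, a *Dissulfurispiraceae*-like clade) inherit its cluster vertically
from its ancestors, or acquire it horizontally — and if so, from which
donor group?

The package is aimed at phylogenomics practitioners who already have a
genome ("species") tree and per-gene protein trees in Newick format and
want a reproducible, scriptable version of the classic two-tool workflow
(Notung-style and Ranger-DTL-style parsimony reconciliation, replicate
aggregation, and per-family origin tallies), plus a simulator that
generates families with known histories so every stage can be validated.

## The model

A rooted binary gene tree `G` is mapped onto a rooted binary species tree
`S` under **duplication–transfer–loss (DTL) parsimony**: each internal
gene node is annotated as a speciation (free), duplication (cost `D`),
or transfer (cost `T`), and each skipped species edge is charged a loss
(cost `L`). The model is *undated*: a transfer may connect any two
species branches that are not ancestor and descendant, and temporal
feasibility is checked per reconciliation afterwards via the standard
constraint digraph (species ancestry plus, for each transfer `d → r`, the
coexistence constraints `parent(d) → r` and `parent(r) → d`; the history
is feasible iff this digraph is acyclic).

With `c(g,s)` the minimal cost of mapping gene node `g` exactly at
species node `s`, `in(g,s)` the minimum of `c(g,x) + L·|path(s,x)|` over
descendants-or-self `x` of `s`, and `out(g,s)` the minimum of `c(g,x)`
over `x` incomparable to `s`, the recurrence for internal `g` with
children `g1, g2` and internal `s` with children `s1, s2` is

```
c(g,s) = min(  in(g1,s1) + in(g2,s2),  in(g1,s2) + in(g2,s1),      # speciation
               D + in(g1,s) + in(g2,s),                            # duplication
               T + in(g1,s) + out(g2,s),  T + in(g2,s) + out(g1,s) # transfer
            )
```

with the optimum taken over all species nodes for the gene root. Two cost
presets are built in: `NOTUNG` (D=1.5, T=3, L=1) and `RANGER`
(D=2, T=3, L=1).

The dynamic program also carries **exact solution counts** (big
integers), so the package can count all optimal reconciliations, draw one
*uniformly at random* (the replicate mechanism standing in for a tool's
"100 simulations"), or list the whole optimum set. Replicates are
aggregated into per-node event/mapping/donor support values, and a
per-family **origin classifier** votes HGT vs vertical for a focal
species group: walking rootward from the gene-tree MRCA of the focal
leaves, the first transfer received by that lineage decides the vote and
names the donor group. Majority votes across replicates become per-family
calls, and calls are tallied across families into statements like
"acquired horizontally in 90.9% of cases (20 of 22 trees)".

## Worked example

Generate a synthetic study (20 genomes in three labeled groups, 5 gene
families, each with one planted ancestral transfer from the
`Magnetobacteriaceae`-like group into the `Dissulfurispiraceae`-like
clade, one NNI noise move per gene tree), reconcile, and classify:

```
dtlrec simulate --seed 42 --out study --n-species 20 --n-families 5 --nni-moves 1
dtlrec reconcile --species study/species.nwk --genes study/families/Mad26.nwk \
    [...one --genes per family...] --leafmap study/leafmap.tsv \
    --preset RANGER --replicates 100 --seed 42 --out run
dtlrec classify --run-dir run --groups study/groups.tsv \
    --focal-group Dissulfurispiraceae
```

which prints

```
Dissulfurispiraceae: HGT 3/5, vertical 2/5, ambiguous 0/5
```

and writes `run/report.Dissulfurispiraceae.md`:

```
- Acquired horizontally in 60.0% of cases (3 of 5 trees).
- Inherited vertically in 40.0% of cases (2 of 5 trees).

Donor attribution among the HGT calls:

- from the Magnetobacteriaceae group: 100.0% (3 of 3 trees)
```

Three of the five noisy families keep a clear transfer signal and all
three name the true donor group; the one NNI move per tree was enough to
blur the other two into vertical-looking histories — exactly the failure
mode the noise model is meant to exercise. Per-family detail lives in the
support tables, e.g. `run/Mad26.support.tsv`:

```
#node  top_event   event_support  top_mapping  mapping_support  top_donor  donor_support
2      speciation  1.000          mrca(S1,S2)  1.000            -          -
5      transfer    1.000          S3           0.540            S3         0.540
```

(node 5 is a transfer in all 100 replicates, with several co-optimal
donor placements), and `run/manifest.json` records, per family, the
optimal cost, the exact number of co-optimal reconciliations, and the
fraction of replicates that are temporally feasible. Without noise
(`--nni-moves 0`) the same pipeline recovers HGT with the correct donor
for 5 of 5 families at support 1.0.

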