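# indelopt

Globally optimal maximum-parsimony reconstruction of insertion/deletion
(indel) histories on rooted phylogenetic trees.

Insertions and deletions leave gap patterns in a multiple sequence
alignment (MSA) that substitutions-only ancestral reconstruction
ignores or treats column by column. `indelopt` infers, for every
ancestor in a tree, a complete gap/non-gap pattern, by solving **one**
mixed-integer program (MIP) over all branch points jointly — so indel
calls at neighbouring sites, which belong to the same multi-site event,
are never made independently. It is aimed at people doing ancestral
sequence reconstruction and protein-family evolution analysis who want
indel placements that are provably optimal and internally consistent
across the whole tree.

## The model

Input: an aligned FASTA (only its gap structure is used: entries become
`a_ki ∈ {0,1}`, 1 = residue) and a rooted Newick tree whose leaf labels
match the alignment. The alignment columns are reduced (all-gap columns
removed, maximal runs of all-occupied columns collapsed), and a
partial-order alignment graph (POAG) `P` is built: directed edges
between consecutive occupied sites of each sequence, plus dummy start
(0) and end (m+1) sites, so each sequence is a start→end path — its
*indel footprint*.

For each internal node `k` the MIP chooses binary site states `a_ki`
and edge indicators `y_kp` (p ∈ P) tied together by network-flow
constraints, so each ancestor is exactly one POAG path. For every
branch `b = (k,l)` and site `i`, `d_bi = |a_ki − a_li|` marks a state
difference and `g_bi` marks the opening of a run of differences
(including the case where the gap orientation reverses mid-run, i.e.
an insertion abuts a deletion). The objective is the affine gap
penalty

    min Σ_b Σ_i ( d_bi + α · g_bi ),          α = 2 by default

Tied optima are enumerated exactly with no-good cuts (each found
solution is excluded by `Σ_{y*=1} y ≤ Q−1` while the objective is
pinned to the optimum). The solver is HiGHS via `scipy.optimize.milp`.

Also included: an indel-event score and per-branch event counts,
evolutionary-cohesiveness and footprint-conformity diagnostics, a
per-column Fitch parsimony baseline (PSP), and a seeded indel-evolution
simulator (Gamma branch lengths, Poisson indel events, geometric
lengths) that records the true gap pattern of every ancestor.

## A worked example

The scoring that drives the objective, for an ancestor `10011` and a
descendant `00101` (`examples/01_affine_gap_scoring.py`):

```
ancestor          : 10011
child             : 00101
differences d     : 10110
openings g (basic): 10100
openings g (full) : 10110
branch cost at alpha=2: 9
indel events on branch: 3
```

`d` marks the three differing sites. A run of differences opens at
sites 1 and 3; site 4 also opens an event because the gap orientation
reverses there (the child's insertion at site 3 abuts its deletion at
site 4), giving `g = 10110` and a branch cost of 3 + 2·3 = 9.

Inference end to end (`examples/03_alternative_histories.py`): two
cherries with footprints `101` and `110` leave the root genuinely
ambiguous, and enumeration finds both optimal histories:

```
2 optimal histories at objective 6.0
  solution 1: root=101 N2=101 N3=110
  solution 2: root=110 N2=101 N3=110
```

The CLI mirrors the API:

```
indelopt simulate --n 50 --delta 0.5 --seed 7 -o data/
indelopt infer data/extants.fasta data/tree.nwk -o run/anc
indelopt alternatives data/extants.fasta data/tree.nwk -o run/anc
indelopt compare data/ --methods mip,psp
```

`infer` writes a solution JSON (patterns in original MSA coordinates),
an ancestors FASTA (`X` residue / `-` gap) and a metrics TSV.

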