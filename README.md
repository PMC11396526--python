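# zzfullerene

Topological invariants of (5,6)-fullerenes and related pentagon/hexagon
polycyclic molecules: ring-spiral isomer generation, Zhang–Zhang (Clar
covering) polynomials, the derived Kekulé/Clar invariants, Pauling bond
orders, and isomer-stability analyses over externally supplied energy tables.

## Who this is for

A (5,6)-fullerene C*n* is a cubic polyhedral carbon cage whose faces are
exactly 12 pentagons and *n*/2 − 10 hexagons. The placement of the 12
pentagons among the hexagons generates large isomer families (1812 cages for
C60, 8149 for C70), and a long line of work asks whether purely
graph-theoretic invariants — resonance-structure counts, aromatic-sextet
counts — can predict which isomer is the thermodynamically stable one.
This package gives computational chemists and graph theorists exact, tested
implementations of that invariant machinery; quantum-chemical energies are
deliberately out of scope and are consumed as plain TSV tables.

## The mathematics at the core

For a plane molecular graph **B**, a *Kekulé structure* is a spanning
subgraph whose components are single edges K₂ (a perfect matching: alternating
double bonds), and a *Clar cover* additionally allows 6-cycle components C₆
(aromatic sextets). With cₖ the number of Clar covers containing exactly *k*
sextets, the Zhang–Zhang (Clar covering) polynomial is

    ZZ(B, x) = Σₖ cₖ xᵏ ,

and it bundles the classical invariants:

* Kekulé count  K = c₀ = ZZ(B, 0),
* Clar count   C = Σₖ cₖ = ZZ(B, 1),
* Clar number  Cl = deg ZZ(B, x),
* Clar formula count c_Cl (the leading coefficient).

The engine computes ZZ exactly (arbitrary-precision integers) by a memoized
vertex-branching decomposition: the pivot vertex is covered either by a double
bond to a neighbour or by a sextet ring through it, and every recursion state
is an induced subgraph, so the memo key is a bit-set of live vertices.
Independent oracles (exhaustive Clar-cover backtracking; memo-free
edge-branching matching counts) cross-check the engine in the test suite.

Isomers are generated with the classic ring-spiral algorithm: a cage is
encoded by the 12 positions of its pentagons in a face spiral, codes are wound
up into cages by dual-triangulation bookkeeping, and each cage is kept only if
its code equals its canonical (lexicographically smallest) spiral — giving the
familiar *n*:*m* labels (e.g. 60:1 is the tubular C60 cage with K = 16,501).

Pauling π bond orders average bond character over resonance structures:
pK(e) = K(G−u−v)/K(G) over Kekulé structures, and the Clar-cover variant
weights sextet membership ½. Orders are exact rationals, and the built-in
linear bond-length models are 1.5096 − 0.2016·p (Clar) and 1.5708 − 0.3851·p
(Kekulé), in Å.

## Worked example

Corannulene (C20H10), a pentagon fused to five hexagons, is the standard
pencil-and-paper example:

```
$ zzfullerene fixtures --name corannulene --out cor.adj
$ zzfullerene zz --adj cor.adj
11 15 5
11 + 15 x + 5 x^2
K=11 C=31 Cl=2 cCl=5
```

Read: corannulene has 11 Kekulé structures (covers with no sextet), 15 Clar
covers with one sextet, and 5 Clar formulas with the maximal Cl = 2 sextets —
31 Clar covers in all.

Enumerate fullerene isomers and tabulate their invariants (columns are
n, m, K, C, Cl, c_Cl, then the full ZZ coefficient vector):

```
$ zzfullerene invariants --n 30
30	1	151	241	1	90	151 90
30	2	117	183	2	8	117 58 8
30	3	107	165	2	6	107 52 6
```

C30 has three isomers; the first has 151 perfect matchings and can host at
most one aromatic sextet (90 ways). Bond orders with length predictions, here
for the C20 dodecahedral cage where every edge is equivalent (p = 1/3):

```
$ zzfullerene bondorders --spiral "20 1 2 3 4 5 6 7 8 9 10 11 12" | head -2
u	v	pK	len_pred_K	pC	len_pred_C
1	2	0.333333	1.4424	0.333333	1.4424
```

The `analyze` subcommand consumes an invariants TSV (plus an optional energy
table `n m energy unit`) and writes Clar-number populations, C-vs-K wedge
statistics, ZZ-vector uniqueness checks, and the K/C stability-hypothesis
verdicts.

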