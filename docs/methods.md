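# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `zzfullerene`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself recompute.

## Graph model

A molecule is a `PlaneMolecularGraph`: contiguous 0-based vertex ids, degrees
2 or 3 (degree-2 vertices are CH positions with implicit hydrogens, as in
corannulene), 2-connected, and a rotation system — the cyclic order of
neighbours around each vertex — that fixes the plane embedding. Faces are
traced by the standard dart-walking rule on the rotation system; every
directed edge is used exactly once and Euler's relation V − E + F = 2 is
asserted after every trace. Fullerene cages use the sphere convention: all
12 + (n/2 − 10) faces are ordinary faces, none is an "outer" face. For
disk-shaped polycyclics one face larger than a hexagon is tolerated and
treated as the boundary rim (corannulene's 15-ring).

Embeddings are computed with networkx's planarity algorithm for *every*
input, including cages built by the spiral windup. The windup's dual
triangulation would also induce a rotation system, but fullerene graphs are
3-connected, so their embedding is unique up to reflection and recomputing it
keeps one code path; all face-dependent quantities are reflection-invariant.

Bond perception from XYZ files uses a distance cutoff, default 1.70 Å:
C–C bonds in these cages span roughly 1.37–1.48 Å while next-nearest
distances exceed 2.2 Å, so any cutoff in between works and the choice is
exposed as a flag (`--cutoff`). Hydrogens in XYZ input are ignored.
`naive_spherical_layout` (top three non-Perron adjacency eigenvectors,
projected to the sphere) exists solely so XYZ round-trip tests can exercise
bond perception on small cages; it is not a geometry optimizer and large
cages may self-intersect under it.

## ZZ polynomial engine

The recurrence branches on a pivot vertex u of the live induced subgraph S:
u is covered either by a double bond to a live neighbour v, or by a candidate
sextet ring through u that is fully live,

    ZZ(S) = Σ_v ZZ(S − {u,v}) + x · Σ_{h ∋ u} ZZ(S − V(h)).

Correctness is immediate (each Clar cover assigns u to exactly one
component), and because every state is an induced subgraph of the input, the
memo key is the bit-set of live vertices — collision-free with no graph
canonicalization. Coefficients are Python integers, hence exact at any size
(C70-scale Kekulé counts overflow 32-bit arithmetic).

Sextet candidates are *all* simple 6-cycles, found once upfront
(`networkx.simple_cycles` with a length bound), not just hexagonal faces; for
fullerene cages the two sets coincide (girth 5 forbids non-facial 6-cycles),
which the test suite verifies on every generated cage it touches, and the
broader definition keeps non-fullerene inputs honest.

The pivot is the live vertex with the fewest live neighbours, ties broken by
smallest index — deterministic and quick to kill dead branches. A
`min_index` policy is also implemented; the two give identical polynomials
(tested), which guards against branch-order bugs. The memo lives per engine
instance; cross-isomer fragment caching is deliberately not attempted — a
single C60 polynomial takes well under a second, and batch runs over
thousands of isomers stay in minutes.

Degenerate inputs: the empty graph has ZZ = 1 (empty product); odd-vertex
graphs have ZZ = 0; a graph with no cover at all gets the zero polynomial and
reports Clar number −1 ("no cover") instead of raising, so batch tabulations
never abort. The engine guards at 120 vertices by default.

Two independent oracles exist purely for testing: exhaustive Clar-cover
backtracking (guarded to ≤ 32 vertices; covers the lowest-index uncovered
vertex by each incident edge or ring) and a memo-free edge-branching perfect
matching counter M(G) = M(G−e) + M(G−u−v), which shares no code or idea with
the decomposition engine. The icosahedral C60 Kekulé count is cross-checked
through the matching oracle rather than the cover enumerator, which its size
guard excludes.

## Ring-spiral machinery

The windup works in the dual (the sphere triangulation whose vertices are
faces). Faces are attached in spiral order; each new face connects to the
spiral head and to the oldest boundary face (tail), then absorbs saturated
boundary faces at both ends; the final face must pick up exactly one open
valence from every remaining boundary face. Any mismatch aborts with the
1-based index of the offending face (`WindupFailure`). The primal cage is
recovered as the triangle graph of the dual: every 3-clique of a fullerene
dual is a face (cyclic 5-edge-connectivity forbids non-facial triangles), so
triangles are atoms and triangles sharing a dual edge are bonded.

Canonicalization unwinds the spiral from every start (each face, each
adjacent face, both winding directions): the next face is forced as the
unused common neighbour of head and tail, every forced boundary connection
is verified against the true adjacency, and the canonical code is the
lexicographically smallest pentagon-position tuple over all successful
starts. This is invariant under vertex relabelling by construction and is
tested as such.

Exhaustive generation DFS-walks face-size sequences (pentagon before
hexagon, giving lexicographic emission order) with the incremental windup
pruning failing prefixes; a completed spiral is kept only if it equals its
own canonical form, which deduplicates isomorphism classes without storing
graphs. The hot loop ships twice: a pure-Python reference implementation and
a numba-compiled version flattened onto integer arrays; tests assert
identical output and the JIT path is used when numba imports. Exhaustive
counts through C70 (8149 isomers) take about a minute compiled.

Isomer numbering: *n*:*m* means the m-th canonical code in ascending
lexicographic order. The reference anchors 36:14 (K = 288), 50:271
(K = 2343, Cl = 5), 60:1 (K = 16,501) and 60:44 (K = 11,259, Cl = 8) all land
at their published ranks under this rule, and the C60 Clar-number census
matches the published populations class by class. One known divergence: C60
contains a single cage whose every successful spiral starts with eight
hexagons (canonical code 9 10 13 14 17 18 21 22 25 26 29 30). Plain
lexicographic comparison ranks it 1812, which pushes the icosahedral cage to
1811, whereas the Atlas-style numbering prints the icosahedral cage as
60:1812. The historical rule for ranking hexagon-start spirals is not
restated in the sources this package follows, so the package keeps its
self-consistent ordering and documents the discrepancy rather than
special-casing one cage. No shipped invariant or reference check depends on
the rank of that cage. For n > 70 a warning notes that face spirals are not
guaranteed complete (cages without spirals exist from C380 on); top-down
generation is out of scope.

## Bond orders and length models

Pauling–Kekulé orders are pK(e) = K(G−u−v)/K(G); Pauling–Clar orders count a
bond as double (1), sextet member (½) or single (0) across all Clar covers:
pC(e) = [C(G−u−v) + ½ Σ_h∋e C(G−V(h))]/C(G), where h runs over candidate
6-cycles traversing e (a 6-cycle merely containing both endpoints does not
count). All per-edge counts reuse one memoized engine per parent graph, and
orders are `fractions.Fraction`s, so the vertex sum rule Σ_e∋v p(e) = 1
holds exactly — the tests assert equality, not approximation.

The shipped length models, length = 1.5096 − 0.2016·p and
1.5708 − 0.3851·p Å for the Clar and Kekulé flavours, are fits over
DFTB-optimized cage geometries reported with the reference tabulation; the
package ships them as constants and provides ordinary least squares
(`regress_orders_vs_lengths`, R² as squared sample correlation) for
user-supplied geometries. The regression is length-on-order, matching the
form in which the fits are quoted. Reproducing the published R² values would
require the DFTB geometries of all 30,579 isomers and is out of scope.

## Analysis conventions

Energies enter as TSV rows `n m energy unit` with unit ∈ {hartree, kcal/mol}
(1 hartree = 627.5094740631 kcal/mol); verdicts are invariant under unit
choice and any positive affine transformation of the energy. The
Zhang–Ye–Liu hypothesis check finds the argmax of K (or C, in the modified
variant) within the maximal-Clar-number class and compares against the
global energy argmin; ties are reported as sets and never broken silently.
The lower boundary of the C-vs-K wedge is summarized as the minimum C/K
ratio over the set — the simplest reading of a linear lower bound, flagged
as an interpretation in the report header. Percentages in Clar-population
tables round half away from zero to integers, matching the reference
formatting.

## Problem sizes and what the tests do (and do not) show

The default suite exercises: all isomers of C20–C40 for oracle equivalence,
uniqueness and sum rules; exhaustive censuses of C36, C50, C52, C60 and C70;
and the corannulene and icosahedral-C60 worked examples. These are exact
integer checks, so passing them demonstrates combinatorial correctness at
those sizes. They do not validate anything about real molecular energetics:
energy-dependent analyses are only as good as the supplied energy table, and
the shipped bond-length models are used as constants, not re-derived.
Synthetic energy tables in the tests are constructed to exercise verdict
logic (including deliberate counterexamples), not to mimic DFTB physics.

## Known limitations

* No spiral-jump ("general spiral") encoding: cages beyond C70 lacking face
  spirals cannot be generated or canonicalized.
* The Atlas rank of the one hexagon-start C60 cage differs by one (above).
* `enumerate_clar_covers` is exponential by design and guarded to 32
  vertices; use the engine for anything larger.
* Symmetry groups, IPR-only generation filters, and 3D geometry generation
  beyond the naive spectral layout are not provided.
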