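# Methods

## Graph model and labelings

Molecular graphs are hydrogen-suppressed: vertices are heavy atoms, edges
are bonds, with no bond orders, charges or geometry.  Graphs are simple and
undirected; self-loops are rejected at construction and duplicate edges
collapse.  Disconnected graphs are admissible — nothing in the edge-sum
formalism requires connectivity — and the maximum degree Δ(G) is always
taken over the whole input graph, exactly as the reduced-reverse definition
RR(v) = Δ(G) − d(v) + 2 states.  This is a deliberate choice: for a
*family* of related molecules one could instead fix Δ per family, and the
two conventions disagree on fused systems.  The published descriptor column
for the 26-molecule benzenoid study is consistent with a plain
degree-product Randić-type sum rather than the per-graph labeling for some
fused members (e.g. the value 2.2778 for the MW-128.17 molecule), so the
package implements the definition literally, ships the published column as
data, and does not attempt to regenerate it from guessed structures (the
study never names the 26 molecules).

Edge-partition label pairs are canonicalized larger-label-first.  Vertex
identifiers are opaque; all quantities are invariant under relabeling
(property-tested).

## Index catalog

26 specs: 10 reduced-reverse (RRM1, RRM2, RRHM1, RRHM2, RRF, RRABC, RRGA,
RRR_α for α = −1, ½, −½) and 16 degree-based comparators (M1, M2, HM1, HM2,
F, ABC, R, GA, H, R_−1, R_½, R_−½, GO1, GO2, HGO1, HGO2), using the
standard literature definitions of the Zagreb, hyper-Zagreb, forgotten,
atom-bond-connectivity, Randić, geometric–arithmetic, harmonic, Gourava and
hyper-Gourava families.  The plain Randić index R uses α = −½ by
convention.  RRR with α = 1 coincides with RRM2 identically, so it is not a
separate catalog entry; `randic_spec` builds a spec for any exponent and
the identity is asserted in the tests.  ABC-type weights at the degenerate
label pair (1, 1) evaluate to 0 (the numerator vanishes): defined, not an
error.

## Closed forms for repeat-unit families

If the edge-class counts of a family G_n are linear forms c_i(n) = s_i·n +
t_i, any edge-sum index is Σ_i c_i(n)·w(a_i, b_i) = (Σ s_i w_i)·n +
(Σ t_i w_i).  Slopes and intercepts are accumulated in double precision;
for integer-valued weights the results are exact.  The packaged nine-class
partition of the conjugate polymer sums to 96n edges; back-mapping labels
to degrees (d = Δ + 2 − a with Δ = 4) and summing count·(1/d(a) + 1/d(b))
in exact rational arithmetic gives the implied vertex count 87n + 1.  The
published vertex count is the pure 87n; the +1 constant is the partition's
own implication (the boundary classes carry constants ±1) and is reported,
not reconciled — only the per-unit coefficient 87 is asserted.

Two published closed forms do not follow from the published partition by
direct summation: RRGA (computed 94.4586n + 0.0041 vs printed
93.9919881117n + 1.9836) and RRR_−½ (computed 28.8590n − 0.1484 vs printed
26.1823n − 0.0075).  The package reports the computed forms; the
independent check is the numeric route (instantiate the partition at n and
sum), which agrees with the symbolic route to 1e−9 for every index — so
the discrepancy lies between the print and the partition, not in the
summation.  These two forms are exactly the reason the symbolic and
numeric evaluation paths are kept separate rather than collapsed.

## Benzenoid builder

Hexagonal systems are assembled from axial cell coordinates on a doubled
integer grid (pointy-top orientation); shared corners of adjacent cells get
identical integer keys, so merging is exact with no floating-point
rounding.  Degrees are always in {2, 3}; disconnected cell sets are
rejected.  Catafused (tree-like) arrangements of h cells obey
|V| = 4h + 2, |E| = 5h + 1, which the tests check for chains h = 1…6 plus
bent and branched fusions.

## Random fixture graphs

`random_molecular_graph(n, max_deg, seed)` grows a uniform-attachment random
tree under a degree cap, then adds up to n random chords that respect the
cap.  It is a test oracle generator, not a sampler of chemical space: it
emulates sparse connected molecular skeletons with bounded valence and
nothing else (no rings statistics, no element identities).  Passing the
direct-sum vs partition-sum equivalence on 200 such graphs shows the two
evaluation routes agree on arbitrary bounded-degree topology; it says
nothing about descriptor quality on real molecules.

## Regression and diagnostics

Models are OLS fits of P = α₁·TI + γ or P = α₁·TI² + α₂·TI + γ via
statsmodels; `PolynomialQSPR.fit()` returns a results object carrying
coefficients, standard errors and the study's diagnostics computed from the
unrounded fit:

* **R²** — ordinary coefficient of determination.
* **χ²** = Σ(obs − pred)²/obs, a residual-based statistic (not a Pearson
  counts test), screened against the packaged 5%-level critical value
  37.652, i.e. 25 degrees of freedom for the 26-record study (records − 1,
  the source study's usage).  Undefined (None) when any observation is ≤ 0.
* **RMSE** under both √(SSR/n) and √(SSR/(n − p)) conventions.  On the
  published-coefficient boiling-point predictions these give 22.3818 and
  23.2957 respectively; the published table prints 23.2957, i.e. the n − p
  convention.  Both remain exposed since the convention is not stated in
  the source.
* **average residual %** — mean of 100·|obs − pred|/obs.

Reproduction of the published prediction tables uses the published
(rounded) coefficients; R²-based claims use freshly fitted models.  Both
paths are exposed and both are exercised in the tests.

Descriptor screening (`select_best_models`) fits every supplied descriptor
per property, discards fits with R² < 0.8 (the IAMC recommendation,
configurable), and keeps the maximum-R² survivor; ties break toward fewer
coefficients, then lexicographic descriptor name.  Properties with no
survivor, or with constant values (R² undefined), are flagged entries
rather than exceptions.  No multiple-testing correction is applied, matching
the study design.

## Numerical choices and degenerate inputs

* Closed-form accumulation: double precision; implied vertex counts:
  `fractions.Fraction` (exact, so the 87 slope is exact, not ≈87).
* Symbolic partitions must instantiate to non-negative integer counts for
  n ≥ 1 (checked to 1e−9 when instantiating).
* Rank-deficient designs (all descriptor values equal) and too-short inputs
  are rejected at model construction.
* Property values are treated as unitless reals (the source states no
  units for BP/CT/CV/CP); GE and PI are carried as opaque column names.
* The 26 study molecules are keyed by ordinal only.

## Problem sizes

The default test run uses graphs of ≤ 60 vertices, 200 random graphs for
the oracle-equivalence sweep, and repeat counts n = 1…5 for
symbolic/numeric agreement; the whole suite runs in a few seconds.  These
sizes were chosen because the equivalences being checked are exact
identities — agreement at small, varied topology plus exact arithmetic
implies nothing further is gained from larger instances.

## Known limitations

* The benzenoid study's descriptor columns other than the published
  RRR_−1 column cannot be regenerated (molecule structures unnamed), so
  R² values for other property/descriptor pairings are not reproduction
  targets; the toolkit computes them for user-supplied descriptor matrices.
* The conjugate polymer is represented only by its edge partition; no
  attempt is made to rebuild its molecular graph from the structure
  drawing.
* Degree-1/2 polynomial models of a single descriptor only — no
  multivariate regression, cross-validation or applicability-domain
  analysis.
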