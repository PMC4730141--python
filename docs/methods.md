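# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `hyscav`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what
the code demonstrates on its own synthetic data.

## Selection profiling (Nei–Gojobori)

Site counts follow the NG86 convention with stop exclusion: at each of
the three codon positions the synonymous fraction is the number of
single-nucleotide changes preserving the amino acid divided by the
number of changes not producing a stop codon, so S + N = 3 exactly for
every sense codon. Difference counts between two codons average the
synonymous/nonsynonymous step classification over all orderings of the
differing positions, discarding orderings that pass through a stop
codon and weighting the survivors equally; when every ordering is
blocked the pair is flagged inadmissible rather than given an invented
value. Two genetic codes are supported: the standard code and an
opal-as-Sec variant in which TGA encodes selenocysteine (U) and only
TAA/TAG terminate — under the Sec code TGA is a sense codon with its
own site counts.

Pairwise statistics use p-distances pS = ΣSd/ΣS̄, pN = ΣNd/ΣN̄ with
site counts averaged between the two sequences, the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) (returned uncorrected with a
saturation flag when p ≥ 3/4), and bootstrap variances over codon
columns (seeded, 1000 replicates by default).

The per-column profile accumulates Sd, Nd and averaged site counts over
every branch of the rooted tree, comparing each parent sequence
(reconstructed, or true in simulations) with its child; per column,
δS = ΣSd/ΣS̄ and δN = ΣNd/ΣN̄. Columns with no informative branch (or
with a zero site-count denominator, e.g. an invariant Met column has no
synonymous site) are flagged NaN, never zero-filled. The one-tailed
Z-test for positive selection uses variances from a bootstrap over
branches (200 replicates by default); with zero total variance the
statistic is 0 (δN = δS) or flagged infinite. A `branches="root_to_tip"`
mode compares the root directly against each extant leaf instead.

**A subtlety worth knowing.** Equal-weight pathway averaging can
attribute fractional nonsynonymous differences to branch endpoint pairs
produced by two *synonymous* events, when the alternative ordering of
the two changes passes through a different amino acid (the arginine
codon family is the main case: CGC → CGA → AGA is purely synonymous,
but the endpoint pair CGC/AGA averages that pathway with
CGC → AGC(Ser) → AGA to Sd = 1, Nd = 1). Consequently a column evolved
with ω = 0 can show δN > 0 at a low rate (~0.25% of conserved columns
at 8 taxa and tree length 1.5 in our simulations). δN − δS remains
strictly negative for such columns — each ambiguous pair contributes
Sd ≥ Nd against a smaller synonymous site denominator — so conserved
columns never score as positively selected; the profile's *sign* is
reliable even where the raw δN is not exactly zero.

## Likelihood machinery and ancestral reconstruction

The substitution model is GTR at the nucleotide level: six
exchangeabilities (AC, AG, AT, CG, CT, GT; GT fixed to 1 when fitting)
and empirical base frequencies, with the generator scaled to one
expected substitution per site per unit branch length. Rate variation
uses the discrete gamma with equal-probability bins and bin-mean rates
(4 categories by default; category means average to 1 to 1e-9 for any
shape in [0.1, 10]), plus an optional invariant-sites class; with
p_inv > 0 the variable-class rates are rescaled by 1/(1 − p_inv) so the
mixture mean rate stays 1 and branch lengths keep their units.
Transition matrices come from the eigendecomposition of the
π-symmetrized generator (real spectrum by reversibility).

The pruning likelihood uses per-node rescaling (log-scale bookkeeping
per site pattern) and site-pattern compression; it matches brute-force
summation over all ancestral assignments on trees of ≤5 leaves to
better than 1e-10 and is invariant to re-rooting along a branch of the
same unrooted tree (reversibility). Marginal ancestral posteriors
combine the inside (subtree) partials with an outside pass, are
mixture-weighted over rate categories, and normalize to 1 per node and
site. MAP ties break by the fixed base order A < C < G < T. MAP bases
are assembled into codons; an assembled stop codon (possible because
per-site argmaxes are taken independently) is replaced by the sense
codon with the highest product of per-base posteriors, alphabetical
order breaking ties, and the repair is recorded. Branch lengths are
taken from the input tree and not re-optimized during reconstruction.

Tree construction, when no tree is supplied, is neighbor joining
(scikit-bio) on pairwise maximum-likelihood distances (bounded scalar
optimization per pair under the same mixture model), midpoint-rooted,
with negative NJ branch lengths clamped to zero. Bootstrap supports
resample nucleotide columns with replacement and report the percentage
of replicate NJ trees containing each non-trivial split of the
point-estimate tree. Model fitting maximizes the pruning likelihood
over log-exchangeabilities, log gamma shape and logit p_inv with
L-BFGS-B; non-convergence is flagged, returning the best point found.

Internal nodes carry stable post-order labels (`N0`, `N1`, …) assigned
once and used consistently by ancestors, cavity tables and lineages;
the numbering is arbitrary but deterministic.

## Synthetic data

The codon simulator evolves each column independently down the tree by
a Gillespie walk: single-nucleotide changes are proposed under an
F81-style generator (target-frequency proportional, normalized to one
expected proposal per site per unit branch length at neutrality),
synonymous proposals are always accepted, proposals creating stops are
always rejected, and nonsynonymous proposals are accepted with
probability ω when ω ≤ 1. For ω > 1 thinning cannot raise a rate, so
the nonsynonymous proposal rate itself is scaled by ω — the same
dN/dS law by a different construction. Root codons are drawn from the
sense codons with probability proportional to the product of base
frequencies. True internal-node sequences and the full event log
(accepted and rejected proposals, with their synonymy) are retained as
ground truth. Default regime: ω = 0.2 background, ω = 5 hotspots,
ω = 0 conserved; 8 leaves; total tree length 1.5 expected proposals
per site (spread over the whole tree) — a moderately diverged family
in which ancestral states are still confidently recoverable. Trees are
Yule-grown (random tip splitting, exponential branch lengths) or
balanced, then rescaled to the requested total length.

Synthetic structures use united-atom geometry: 1.8 Å atom radius, 1.4 Å
water probe, both configurable. The sealed cage places atoms on a
deterministic Fibonacci lattice of radius R (void volume ≈
(4/3)π(R − r_atom − r_probe)³); the aperture cage removes the atoms
inside a cone of given solid angle (0.8 sr in the fixtures, a ~4 Å
mouth); the surface dent is a dense lattice ball with a spherical scoop
(centred at 0.6 R with radius 0.6 R — centring the scoop on the surface
would leave its probe-free core outside the convex hull, and with the
default radii a cage radius of at least ~8 Å is needed for a nonempty
pocket); the convex blob is a dense lattice ball with no void.

The independent volume oracle declares a point void iff it is inside
the convex hull of atom centers, clears every probe-inflated atom
sphere, and cannot reach the outside: connectivity is resolved on a
0.3 Å voxel grid by flood fill from the bounding-box border (the
enclosed mask is dilated by one voxel so free sample points in blocked
boundary voxels are attributed correctly), and the volume is a
Monte-Carlo estimate at ≥10⁶ samples with a fixed oracle seed. The
oracle shares no code with the cavity detector.

What the generator does *not* emulate: real protein packing
heterogeneity, side-chain shapes, gaps/indels in alignments, rate
correlation between sites, and MD-relaxed geometry. Passing tests
therefore demonstrate algorithmic correctness and calibration under
idealized geometry and site-independent evolution, not performance on
experimental structures.

## Cavity detection

A tetrahedron of the Delaunay triangulation is *empty* (probe-scale
space) when its circumsphere radius exceeds the mean radius of its four
atoms plus the probe radius; a shared triangular facet is *open*
(probe-passable) when its circumradius exceeds the analogous facet
threshold. Cavities are connected components of empty tetrahedra joined
across open facets. A component's open facets on the convex hull are
its mouths, counted as edge-connected patches; a component with none is
an insulated internal cavity. Two screens remove artifacts: components
whose boundary has more open hull facets than closed boundary facets
are exterior space (the gap amid a handful of atoms), and components
with zero probe-free measure (flat slivers between atoms; checked by a
short seeded stratified sample) are discarded, as are components below
5 Å³ of summed tetrahedron volume.

This is an unweighted alpha-complex variant with a probe-augmented mean
radius, a deliberate simplification of the weighted-triangulation /
discrete-flow computation used by pocket servers: with near-uniform
radii it recovers the same pocket topology, and only relative and
threshold behavior is claimed for volumes — no absolute agreement with
solvent-accessible pocket measures. Per-element van der Waals radii
(C 1.7, N 1.55, O 1.52, S 1.8, Se 1.9 Å) are applied when PDB elements
are present, a uniform 1.8 Å otherwise.

Volumes are probe-excluded measures of the tetrahedron union minus the
inflated atom spheres, estimated by Monte-Carlo sampling stratified
over member tetrahedra by volume (2×10⁵ points by default; below 10⁴
the measurement is refused), with a binomial standard error; areas sum
the sphere-free fraction of boundary facets by the same sampler. The
detector agrees with the independent oracle to within ~1% on sealed
cages of radius 6–12 Å (5% is the acceptance tolerance). Degenerate
(coplanar) inputs raise with guidance to enable the seeded 1e-6 Å
jitter. Classification of mouth-bearing cavities is by volume: dent
< 500 Å³ ≤ crack < 1000 Å³ ≤ crevice, both boundaries inclusive on the
upper class; mouthless components are internal regardless of volume.

## Lineages, cavity score and overlay

Cavity identity across structures is residue overlap: lining residues
(owners of any vertex atom of a member tetrahedron) are mapped to
alignment columns and compared by Jaccard; greedy best-first matching
with a 0.3 threshold and lowest-id tie-breaks makes the pairing
deterministic and symmetric up to transposition. Lineages are numbered
in order of first appearance during a preorder walk (ancestors before
descendants); nodes without structures are transparent (matching is
against the nearest structured ancestor). Per-node compositions render
as lineage-number + class-letter strings ("3k + 5i").

The cavity score of a column is the number of structures in which the
residue at that column lines any cavity (the alternative reading —
summing lining residues — is available behind a flag). The overlay
joins this score with δN − δS and reports four counts: columns under
positive selection pressure, cavity-lining columns, their intersection,
and cavity-forming-but-conserved columns (score > 0 yet δN − δS < 0).
On the wired synthetic scenario (cavity linings planted onto hotspot,
conserved and background columns) the overlay flags ≥90% of the
planted cavity-opening hotspots and consistently finds
cavity-forming-but-conserved columns.

## Readthrough and SECIS scanning

The readthrough detector reports the first in-frame TGA, provided no
TAA/TAG precedes it (the ORF would genuinely end there), translates the
CDS with U at the opal position, and ends at the next in-frame stop
when one exists. The SECIS scan is a minimal hairpin maximizer, not a
thermodynamic folder: it enumerates all perfect-stem geometries
(Watson–Crick plus G·U wobble, loop length 3–8, no bulges) and returns
the highest-scoring one, ties broken by leftmost start then longer
stem. The default window is the 60 nt immediately 3′ of the opal codon
(bacterial SECIS elements are proximal; the window is configurable).
It matches a brute-force enumerator exactly and separates planted 8-bp
stems from shuffled controls, but it is a transparent heuristic — no
covariance-model search, no free energies.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give
  bit-identical outputs, including pipeline output checksums.
- Coordinates are 1-based codon columns and 1-based nucleotide
  positions throughout; column maps are TSVs with `residue` and
  `column` headers.
- The pipeline (`hyscav run`) validates inputs first (parse checks,
  leaf↔row binding, codon divisibility, map coverage; errors vs
  warnings), then runs ASR → selection profile → cavities → lineages →
  overlay, writing per-stage TSVs and a manifest with input/output
  checksums, seeds and timings.
- Problem sizes in tests and the acceptance script (tens of replicate
  simulations, 8-taxon trees, 10⁵–10⁶ Monte-Carlo samples) were chosen
  as the smallest runs at which the measured rates and tolerances are
  stable; all complete in seconds.

## Known limitations

- The nucleotide-level model ignores codon structure during
  reconstruction; ancestral codons are assembled from independent
  per-site MAP bases (with stop repair) rather than from a 61-state
  codon model.
- The cavity detector's exterior/pocket boundary rule (open-hull-facet
  dominance) is a heuristic; highly concave surfaces could be
  misclassified. Discrete-flow sink analysis would be the upgrade path.
- Absolute cavity volumes depend on the radius set and probe; only
  oracle-relative accuracy and classification thresholds are validated.
- NG86 pathway averaging is an estimator, not an event count; see the
  δN > 0 subtlety above.
- No gap handling in simulated alignments (real-data mode accepts `-`
  by skipping affected codon columns pairwise).
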