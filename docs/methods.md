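# Methods

## The scoring model

`xlscore` scores a model of a protein complex against crosslinking
mass-spectrometry (XL-MS) restraints.  A crosslink between two lysines
constrains them in three ways: the crosslinker has a maximum span, the
observed distances between crosslinked residues follow a characteristic
distribution, and both residues must have been solvent accessible when
the crosslinker reacted.  The cMNXL score combines the three:

```
cMNXL = ExSASD + NoV + 3 × (NoNA_inter + NoNA_intra)
```

* **ExSASD** — for each inter-subunit crosslink whose solvent-accessible
  surface distance (SASD) in the model is at most 32 Å, the value of the
  normal density N(μ = 21.92 Å, σ = 4.87 Å) at that distance.  The
  density is used unnormalised (its maximum is ≈ 0.0819); the penalty
  constants below are calibrated on that scale, so the default is not a
  probability but a score.
* **NoV** — each inter-subunit crosslink whose SASD exceeds 32 Å is
  penalised by −0.1.  A pair that is accessible but has no solvent path
  under the bounded search cap is treated the same way.
* **NoNA** — each crosslink (inter- or intra-subunit) with at least one
  solvent-inaccessible residue is penalised by −0.1, and these counts
  carry weight 3 in the total.

A distance exactly at the bound scores under ExSASD (the inequalities
are ≤ / >).  Accessible intra-subunit crosslinks contribute exactly
zero: only their non-accessibility is informative about the assembly.
The Euclidean variant replaces the SASD density and bound with
N(18.35 Å, 4.11 Å) and 30 Å; accessibility remains grid-determined, so
the non-accessibility information is retained even when straight-line
distances are scored.

Chain-ambiguous crosslinks on homo-oligomers are resolved against the
native structure by evaluating every chain-copy combination and keeping
the lowest SASD (even when it exceeds the bound, in which case the link
will score as a violation), then emitting the reciprocal combination
under swapping the assigned chains.

## The surface-distance engine

SASD is computed on a cubic voxel grid (default spacing 1.0 Å,
configurable in [0.5, 2.0] Å) enclosing the structure plus a solvent
margin of 12 Å (at least the 11.4 Å linker arm).  A voxel is *protein*
if its centre lies within the van der Waals radius (C 1.7, N 1.55,
O 1.52, S 1.8 Å) plus a 1.4 Å water-probe radius of any atom.  Empty
voxels 26-connected to the box boundary are *solvent*; enclosed empty
voxels are *buried cavities* and are excluded from paths.

The distance anchor of a residue is lysine Nζ when present, else Cβ,
else Cα — the amine nitrogen is the chemically reactive site.  A
residue is accessible when at least one solvent voxel centre lies
within `vdW + probe + √3·spacing` of its anchor; those voxels are also
the path entry points, with the exact anchor-to-centre Euclidean offset
added to the path length.  Paths run over solvent voxels with
26-connectivity and Euclidean edge weights (diagonal steps cost √2 or
√3 times the spacing), searched by Dijkstra with one virtual exit node
and one virtual entry node per residue, so one multi-source run yields
all pairwise distances without routes short-cutting through a third
residue's anchor.  The search is capped (default 60 Å); an accessible
pair with no path under the cap is reported as `no_path` and scored as
a violation.

Two engine options trade exactness for speed at ensemble scale and are
used by the benchmark harness (they are off by default):

* a *tight cap* just above the scoring bound — any path longer than the
  bound scores identically as a violation, so its exact length is not
  needed;
* a *solvent corridor* restricting path voxels to within 8 Å of the
  protein surface — geodesics around a body hug its surface, so the
  corridor reproduces the unrestricted result except across gaps wider
  than 16 Å, which then report `no_path` (and would usually be
  violations regardless).

Discretisation gives `SASD ≥ ED` exactly (triangle inequality on the
entry offsets) and `SASD ≈ ED` within about two grid spacings for
unobstructed pairs.

## Model accuracy

`meanRMSD` superposes the model onto the native once per subunit —
least-squares (Kabsch) on that subunit's Cα atoms only — computes the
whole-model Cα RMSD after each fit, and averages over subunits.  `fnat`
is the fraction of native inter-subunit residue contacts (any-atom
distance ≤ 5 Å, inclusive) maintained by the model.  A model is a
*positive* when meanRMSD ≤ 4 Å **and** fnat ≥ 0.3 (the CAPRI
medium-quality-equivalent criterion).  Residue correspondence is by
chain and author residue number; no alignment is attempted, as decoys
share the native's sequence.

## Benchmark statistics

Precision is TP/(TP+FP) over the 10 top-scoring models; the
false-positive rate is FP/(FP+TN), with TN the negatives outside the
top 10 (equivalently FP over all negatives).  When a block of tied
scores straddles the rank-10 boundary, the slots left after taking all
strictly-higher models are filled by uniform draws from the tied block,
and the statistic is averaged over 1000 draws.  ROC curves sweep the
score threshold; AUC is the trapezoidal integral and equals the
Mann–Whitney rank statistic (asserted in tests to 1e−9).

Crosslink recovery is emulated by drawing `round(rate × N)` links
(round-half-up) uniformly without replacement from the theoretical set,
redrawing until at least 2 inter-subunit links are present.  Because
the score is additive over crosslinks, the harness precomputes one
contribution matrix (models × links) per benchmark and evaluates any
recovery subset by a column sum; recovery curves average precision and
AUC over repeated draws per rate.

The weight scan enumerates per-term weights on a grid from 0 to 1
(default step 0.1), maximising mean top-10 precision across benchmark
cases; ties break toward the lexicographically smallest weight vector,
and weight vectors producing constant scores are flagged degenerate.
Score comparisons between methods use a one-sided paired t-test (pairs
are benchmark cases); zero-variance differences return p = 0.5, 0 or 1
by the sign of the common difference.

## Simulated 3D-EM fitness

A structure is blurred into a density map by summing per-atom isotropic
Gaussians with FWHM equal to the nominal resolution (σ = resolution /
2√(2 ln 2)), weighted by atomic number, on a cubic grid (default 3 Å
voxels, valid down to resolution = 2 × voxel size).  Fit between maps
is the mutual information of their joint intensity histogram (20 × 20
equal-width bins, natural log), after trilinear resampling onto the
coarser grid.  The clash penalty PS is the fraction of atoms involved
in inter-subunit contacts closer than half the sum of van der Waals
radii.  The fitness of an n-subunit model is `F = n × MI − PS`, and the
combined crosslink + EM score is `F + 0.5 × cMNXL`.  The blur, binning
and penalty forms are deliberately simple, config-exposed choices; only
their roles are contractual.

## Synthetic fixtures

No public decoy benchmark is small enough to regenerate at desk scale,
so all tests run on generated fixtures:

* **Toy complexes** — poly-alanine α-helices wound around seeded
  irregular space curves (a small random drift of the axis direction
  per residue).  The irregularity is essential: ideal straight helices
  have flip pseudo-symmetries that let completely wrong poses reproduce
  native crosslink geometry.  Subunits are docked side by side at van
  der Waals contact, choosing each subunit's spin about its axis to
  maximise interface breadth.  Lysines are substituted at accessible
  positions outside the interface core, selected greedily (with local
  swap refinement) so that the inter-subunit anchor distances cluster
  near the 21.92 Å reference mean — mirroring the fact that observed
  crosslink distances on native structures follow that distribution.
  A homo-oligomer mode reuses one geometry and lysine set per chain.
* **Decoys** — per subunit, a geometric number of perturbation
  iterations (mean 3), each a per-axis translation uniform in ±5 Å and
  a rotation of uniform 0–180° about a random axis through the subunit
  centroid; a per-decoy magnitude factor uniform in (0, 1] scales both
  ranges so the ensemble spans near-native to wrecked.  Candidates with
  more than 20 inter-subunit main-chain atom pairs closer than 2.0 Å
  are rejected; survivors are selected round-robin from 10 equal-width
  meanRMSD bins to flatten the quality histogram.
* **The canonical benchmark fixture** (`make_benchmark_complex`) uses
  two 60-residue subunits with 30 surface lysines and requires at least
  40 inter-subunit theoretical links — the lysine-rich regime in which
  crosslink-driven model discrimination is reported to work; complexes
  with few surface lysines, or small relative to the 32 Å span, are
  documented failure cases of the approach.
* **The occlusion fixture** (`make_occlusion_fixture`) is a shell
  subunit with a lysine caged at its centre plus exposed partners,
  realising all three crosslink fates (reward, non-accessible,
  violation) deterministically.  Thin helical subunits cannot bury an
  anchor — solvent is never more than a few Å away — so burial-specific
  behaviour is exercised on this purpose-built geometry.

What the fixtures do not emulate: side-chain packing and flexibility,
sequence diversity, realistic interface chemistry, and experimental
noise in crosslink identification.  Passing tests therefore demonstrate
the internal correctness and qualitative behaviour of the scoring
machinery, not its measured performance on real benchmarks.

## Problem sizes and numerical choices

Ensemble-scale suites (20 seeded benchmarks × 100 decoys) run the
engine at 1.5 Å spacing with the 8 Å corridor and tight cap; analytic
and oracle checks run at 1.0–2.0 Å without approximations.  Voxel
labelling uses flood fill over 26-connectivity; grid memory is capped
(configurable) with a clear error suggesting coarser spacing.
Tie-breaking among equal-length paths is irrelevant by construction
(only lengths are contractual).  Random draws always flow from
explicitly passed seeds; every stochastic report carries its seed.

## Known limitations

* The native-top property — the native outscoring every decoy of
  meanRMSD > 4 Å — holds only in a fraction of seeds (about 40% under
  the default benchmark fixture; see the test suite's benchmark
  property).
  Two structural reasons: uniform recovery sampling of an all-pairs
  theoretical set leaves some sampled links at the admissible range's
  tails, where near-boundary decoys (4–9 Å) can gain by first-order
  distance reshuffles; and the main-chain-only clash filter does not
  block small compressions of the interface, which move above-mean link
  lengths toward the density mean.  This mirrors the method's reported
  behaviour on real dimer benchmarks, where average per-case precision
  is well below 1: cMNXL reliably enriches near-native models in the
  top ranks but does not guarantee the native the single top rank.
* SASD accuracy is limited by grid discretisation (≈ ±2 spacings) and
  by the rigid anchor convention (no side-chain conformer sampling).
* The corridor approximation misclassifies links across solvent gaps
  wider than twice the corridor as `no_path`; such poses are almost
  always heavy violators anyway.
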