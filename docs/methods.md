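# Methods

## Scope and model

`kturn` treats kink-turn structural integrity as a per-frame
classification problem.  Each frame of an ensemble (MD frames exported as
multi-model PDB, or a single crystal structure) is reduced to a feature
vector over the motif's characteristic interactions; ensemble-level
results are fractional occupancies of those features, optionally
conditioned on frames where the signature interaction (SI) is intact.
The package does not simulate dynamics, estimate kinetics or free
energies, and does not call unkinking/stem-disruption events; SI presence
is the integrity proxy.

## Geometric criteria

**H-bonds.**  A catalogued H-bond is present when the donor–acceptor
heavy-atom distance is < 4.0 Å and the donor–hydrogen–acceptor angle is
> 120°, maximized over the donor's hydrogens (N6→H61/H62, N2→H21/H22,
G N1→H1, C N4→H41/H42, U N3→H3, O2′→HO2′).  The angle condition is waived
when either partner is an O2′-group atom: hydroxyl rotational freedom
makes the angle test produce false negatives.  The 4.0 Å cutoff is
deliberately lenient; occupancies near 90 % should be read as "fully
stable".  Frames lacking a required hydrogen raise an error unless the
distance-only fallback is enabled (intended for H-free crystal
structures; each use is warned).

**SI.**  Native = G_L1(O2′)–A_1n(N1), non-native = G_L1(O2′)–A_1n(N6);
both involve O2′ and are therefore distance-only.  If both pass the
cutoff the shorter distance wins.  The tie-break is this package's
choice: the shorter heavy-atom distance is the natural proxy for which
arrangement is occupied, and the two distances are never equal in
floating point in practice.

**A-minor.**  Type I is assigned when AMI_A and AMI_C hold; AMI_B
(C_−1b(O2′)–A_2b(O2′)) is optional because a transient water insertion
into that bond is part of the motif's natural dynamics.  Otherwise type 0
is assigned when AM0_A holds; AM0_B is reported as an auxiliary flag and
is never decisive.  Type I therefore outranks type 0 when both bond sets
are satisfied.

**χ window.**  syn iff χ ∈ (−90°, +90°) on the quadruple O4′–C1′–N9–C4
(purine) or O4′–C1′–N1–C2 (pyrimidine).  The boundary values ±90° are
assigned to *anti*: the window is stated as an open range and a closed
convention is required for determinism.

**Stacking.**  Distances between geometric centers of the endocyclic
nitrogens (purine N1/N3/N7/N9, pyrimidine N1/N3); A_L2/A_1n passes below
4.0 Å, A_L2/G_L1 below 4.5 Å.  If both pass, the smaller distance/cutoff
ratio wins — comparing raw distances would bias toward the pair with the
looser cutoff.

**Sugar pucker.**  Altona–Sundaralingam pseudorotation from the five
endocyclic torsions ν0 = C4′–O4′–C1′–C2′ … ν4 = C3′–C4′–O4′–C1′:
P = atan2(ν4 + ν1 − ν3 − ν0, 2ν2(sin 36° + sin 72°)), amplitude
τm = ν2 / cos P (numerator form when cos P is small).  Classes are the
ten 36° bins of P anchored at 0° (C3′-endo [0°, 36°), …, C2′-endo
[144°, 180°), …).  The bin edges are this package's convention; only the
class names C3′-endo / O4′-endo / C2′-endo are externally fixed.

**Torsions.**  IUPAC right-hand convention, cis = 0°, values in
(−180°, +180]; degrees everywhere across module boundaries.  The torsion
is invariant under full atom-order reversal and negated by mirror
reflection; the implementation is cross-checked against MDAnalysis in the
tests.  Gauche bins: g+ = [0°, 120°), g− = [−120°, 0°), t otherwise, so
the canonical ±60°/180° centers sit mid-bin and boundary values fall in
the half-open interval that contains them.

**Suites.**  The three monitored suites are named by residue pairs
(A_1n/G_−1n, G_L1/A_L2, A_L2/A_L3) with native α/γ combinations g+/t,
g+/g−, g+/g+.  α and γ are measured on the 3′ residue of each pair
(α: O3′(i−1)–P–O5′–C5′, γ: O5′–C5′–C4′–C3′); the annotation's `suites`
section can override the quadruples if a different assignment is wanted.

**Ions.**  K⁺/Na⁺ bind an acceptor within 3.5 Å; Mg²⁺ shells are inner
< 3.5 Å, outer [3.5, 4.8) Å.  Ions are recognized by element or residue
name (K, NA, MG and common variants).

**Coordinates** are assumed whole/imaged (no periodic-boundary
reconstruction); a guard warns when any monitored pair exceeds 50 Å.
Missing atoms propagate as an explicit `Unresolvable` sentinel — never a
silent default — and sentinel frames are excluded from both numerator and
denominator of occupancies, because a missing atom is a data problem,
not a structural observation.

## Occupancy statistics

"Combined" occupancies pool frames across replicates, so the combined
value equals the frame-weighted mean of the replicate values as an exact
identity (asserted in tests).  SI-conditioned analyses restrict to frames
with SI ∈ {native, non-native}.  Convergence uses standard block
averaging: for block size b the series is cut into ⌊n/b⌋ contiguous
blocks (tail discarded) and the SE is the standard deviation of block
means over √(#blocks); the reported plateau is the SE at the largest
usable block.  A constant series reports exactly zero SE (round-off from
summation is suppressed).  No multiple-testing machinery is used: the
outputs are descriptive populations, not hypothesis tests.

## Synthetic ensembles

The generator exists to validate the classifiers and statistics, not to
imitate physics.

**Templates.**  `build_template` places only the atoms the classifiers
touch, using internal-coordinate (NeRF) construction, so that the
classifier outputs equal the declared targets exactly at zero noise.
Formed H-bonds are realized at 2.9 Å (broken: 5.5 Å), giving ≥ 1.0 Å of
margin to the 4.0 Å cutoff; torsion targets sit at bin centers (≥ 60°
margins, ≥ 20° for χ at its default states); pucker targets sit mid-bin
(18°, the maximum possible for 36° bins).  Internal frames use enlarged
bond lengths (~2–2.8 Å; sugar-ring circumradius 2.4 Å) and an
exaggerated pucker amplitude (τm ≈ 90° vs ~40° in real sugars) because
per-atom coordinate noise propagates into torsions and into the
pseudorotation phase inversely with those scales; with these choices the
default noise of σ = 0.1 Å sits ≥ ~6 SD from every decision boundary and
the measured flip rate is zero at the simulated sample sizes.  The
builder emits a margin report and rejects contradictory targets (e.g.
SI native with the G_L1 O2′ atom deleted) with an error naming the
conflict.

**State switching.**  Each categorical feature follows an independent
stationary Markov chain with transition matrix
(1 − a)·**1**πᵀ + a·I, which has stationary distribution π exactly and
second eigenvalue a.  The default persistence a = 0.2 emulates fast
reversible switching relative to the frame stride, as the monitored
interactions show in MD.  Default stationary fractions: SI
(native/non-native/absent) = 0.7/0.2/0.1, A-minor (AM0/AMI/none) =
0.8/0.15/0.05, χ (syn/anti) = 0.6/0.4, stacking (A_1n/G_L1/none) =
0.5/0.4/0.1, pucker (C2′-endo/O4′-endo/C3′-endo) = 0.5/0.3/0.2 (echoing
the coupled C2′-endo → O4′-endo → C3′-endo sequence), suites 0.7/0.3,
0.3/0.7 and 0.9/0.1 (the G_L1/A_L2 suite preferring canonical A-RNA),
4BPh on = 0.4, sugar–phosphate on = 0.3, sugar–base on = 0.9.  Optional
coupling rules force a target feature's state when a trigger feature is
in given states; contradictory rules are rejected at spec validation.

**Randomness.**  Every stream derives from `SeedSequence(seed,
spawn_key=(replicate, feature_code))` with fixed per-feature codes, so
adding a feature never perturbs the draws of the others, and the full
output is bit-for-bit reproducible under a fixed seed.  Ground truth is
recorded before noise.

**Statistical checks.**  `recovery_report` compares classified
occupancies with the *realized* ground-truth fractions using the plain
binomial SE √(p(1−p)/n) and a 3-SE pass criterion; at the default noise
the classification error is exactly zero, so this mainly guards the
pipeline plumbing.  The generator's own chain consistency (empirical vs
stationary fractions) is checked with the Markov-corrected SE, inflated
by √((1+a)/(1−a)) — the statistically appropriate error for an
autocorrelated chain; using the iid SE there would produce spurious
failures at a rate independent of n.

**What the generator does not emulate:** force-field physics, solvent,
concerted backbone motion, chemically complete nucleotides, realistic
transition kinetics, or correlations between features beyond the
explicit coupling rules.  Passing the recovery tests therefore
demonstrates correctness of the classification and statistics pipeline,
not the fidelity of any MD force field; the occupancy tables of real
μs-scale studies are not reproducible at desk scale and are not targets
of this package's tests.

## Problem sizes

The test suite and the acceptance script use 5 replicates × 2000 frames
at σ = 0.1 Å for recovery (≈ 10⁴ frames, ~25 s on one CPU), the full
~245-combination repertoire for zero-noise enumeration, 500 randomized
internal-coordinate round-trips, and dense 1.7°-step grids for the
pseudorotation inverse.  These sizes were chosen so each statistical
criterion has ample resolving power while the whole suite stays
interactive.

## Known limitations

* PDB is the only structure format (no mmCIF, DCD/XTC/NetCDF); frames
  must fit the PDB coordinate field and share one atom table.
* The annotation must be supplied by the user for real structures; no
  automatic kink-turn detection or numbering inference is attempted.
* The suite classification monitors α/γ only (the motif's discriminating
  pair), not the full seven-torsion suite alphabet.
* Water-mediated bridges are not detected explicitly; the AMI_B
  exemption stands in for the known water insertion at that position.
* The stacking tie-break (distance/cutoff ratio) and the SI shorter-
  distance tie-break are conventions of this package for the rare
  double-pass frames; alternative conventions would differ only there.
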