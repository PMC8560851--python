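# Methods

This note documents the models, numerical choices and limitations behind
`h3graft`. The package reproduces the *logic* of an H3 loop-replacement
screen — stage order, retention counts, filter rules, stratified consensus
ranking — with small, fully documented internal components standing in for
the large third-party engines such a protocol normally calls (Rosetta,
AMBER, Loopy, dDFIRE, SCWRL, ProCheck, ProPOSE). The substitutions are
design decisions of this package: each stand-in preserves the role and the
contract of the step it replaces, not the numerical output of the original
program.

## Structure model

Structures are handled heavy-atom-only; polar hydrogens are implied and
enter only through geometric hydrogen-bond terms. PDB input is parsed with
gemmi (first MODEL only; highest-occupancy altloc, ties broken by altloc
identifier). Regions come from a user or fixture annotation table with the
fixed vocabulary {FR, H1, H2, H3, L1, L2, L3, ANTIGEN}; CDR boundaries are
IMGT by convention and numbering is supplied externally — the package does
not implement Kabat/IMGT numbering itself. The H3 loop uses the internal
convention s[1] ↔ H93 … s[L] ↔ H102 with insertion codes on residue 100
beyond length 10; the last two loop positions are always 101 and 102, so
both anchors are stable across lengths.

Preparation removes waters and single-atom metal/halogen residues, drops
chains absent from the annotation (extra biomolecular copies; the annotation
is the arbiter of the relevant copy), records disulfides (SG–SG < 2.5 Å),
completes missing side-chain heavy atoms at ideal geometry without
repacking, and flags chain breaks (C–N > 2.0 Å) and termini as capped;
caps are terminal flags, not atoms.

Ideal residue geometry — side-chain templates, bond graphs and the
reference bond lengths/angles of the internal force field — comes from the
Chemical Component Dictionary shipped with biotite. Side chains are built by
rigidly fitting the template on the actual (N, CA, C) triad and applying chi
rotations; the rotamer set is a small backbone-independent list of the most
frequent chi combinations per residue type (1–5 rotamers). Placement is
greedy and clash-minimal (clash: non-bonded pair closer than 0.6× the sum
of van der Waals radii), ties going to the most frequent rotamer.

## Internal force field

Terms: harmonic bonds (300 kcal/mol/Å², reference = template geometry),
harmonic angles (80 kcal/mol/rad²), omega planarity (15 kcal/mol/rad²,
target 180° or 0° for pre-existing cis peptides), Lennard-Jones
(ε = 0.15 kcal/mol, r_min = sum of vdW radii, linearly continued below
0.6·r_min), screened Coulomb with distance-dependent dielectric ε = 4r and
coarse partial charges (neutral backbone and polar-group dipoles; ±1 formal
charges smeared over terminal heavy atoms of Asp/Glu/Lys/Arg), a
distance-Gaussian hydrogen-bond well (depth 2 kcal/mol at 2.9 Å,
σ = 0.35 Å) between donor/acceptor heavy atoms, and harmonic positional
restraints. Gradients are analytic; minimization is L-BFGS with the
environment fixed; nonbonded pair lists are built once from the input
coordinates (10 Å cutoff + 1.5 Å skin) and frozen during a minimization.
The restraint constants exposed in the interfaces (5 kcal/mol/Å² for
post-graft regularization, 1 kcal/mol/Å² for pre-scoring minimization)
mirror the protocol structure they come from.

"Regularize" (post-graft) uses bonded terms plus soft-sphere repulsion only,
with backbone restraints; convergence is max gradient < 0.1 or 500
iterations. Loop minimization adds the LJ/Coulomb/HB terms.

## Sampling and closure

Loop tips are resampled from a mixture-of-Gaussians Ramachandran model with
separate maps for Gly, Pro and all other residues; the propensity term used
in scoring is the log density relative to each map's mean density, so the
term carries no residue-composition bias. Closure is cyclic coordinate
descent over the tip φ/ψ dihedrals onto the fixed anchor triad (N, CA, C of
the residue after the window), accepting a closure gap (RMSD over the three
anchor atoms) of at most 0.5 Å; the CCD kernel is numba-compiled. Omega is
fixed trans during rebuilds. Conformations with hard clashes (pair closer
than 0.55× radius sum) are discarded and resampled; a closure success rate
below 1% is treated as a geometrically impossible graft. Every ensemble is
seeded with the grafted conformation itself as conformer 0.

Stem templates reuse the cluster representative's own loop at its native
length; other lengths keep the grafted stems (first 2 / last 3 loop
residues) and bridge the remainder with an extended backbone closed by CCD.
Where a short linker cannot meet the rigid C-stem at ideal geometry, a small
Cartesian relaxation lets bond angles flex (bonds held within 0.08 Å of
ideal); linkers that still cannot close within 0.5 Å raise an error, and
cluster/length combinations that fail are skipped with a warning when a
library is expanded.

The statistical rescoring potential is an atom-typed (C/N/O/S),
distance-binned (0.5 Å bins to 8 Å) pair table built from a soft 8-4
well on the radius sum plus an attractive polar (N/O) band near 2.9 Å,
summed over loop–environment pairs and loop–loop pairs at residue
separation ≥ 2.

## Scores

The total-energy track is the internal force-field energy of the loop
region (bonded strain + loop-self and loop-environment nonbonded terms)
plus the backbone propensity term. The interaction track is
`α(E_vdW + E_Coul(D_in) + E_RF + γ·ΔSASA) + C` over the antibody/antigen
partition, with α = 0.1048, D_in = 2.25, γ = 0.0129 kcal/mol/Å²,
C = −2.89 kcal/mol following the published SIE parameterization lineage;
these are configuration, not contract. ΔSASA is the (negative) surface area
buried on binding from an in-package Shrake–Rupley computation (probe
1.4 Å, 100 sphere points by default, verified against the closed-form
two-sphere buried-area formula); the reaction-field desolvation is
approximated as a per-atom penalty proportional to |charge| × buried area
of polar atoms (β = 0.02 kcal/mol/Å²). Burial bookkeeping is restricted to
interface atoms (within 7 Å of the other body); atoms farther away have
identical exposure in bound and free states and cancel exactly.

Boltzmann averages use weights exp(−(E − E_min)/kT) from the total-energy
track for both score averages; kT defaults to 1 energy unit (the protocol
this mirrors does not state a temperature). The same-weight rule means the
interaction average is conditioned on conformations the total energy
considers plausible.

## Ranking and selection

Z-scores are computed per H3 length stratum with the robust scale
1.4826·MAD (configurable to the standard deviation); a stratum of size 1 is
flagged unscorable and excluded. The composite is the unweighted mean of
the two tracks' Z's; ranks are dense (ties share the smaller rank). The
−1.5 cutoff uses ≤ semantics. The Ramachandran filter classifies each
residue of the extracted H92–H103 segment against relative-density
thresholds on the propensity maps (core > 0.30, allowed > 0.03, generous >
0.003 of the map peak; below that, disallowed); terminal residues with
undefined φ or ψ are skipped. The hydrogen-bond screen compares
intermolecular HB energy (distance well × angular factor at the donor) and
a flaw count (buried interface donors/acceptors without a partner within
3.5 Å) against the parental complex as two independent one-sided tests at
+1 unit — the stricter reading of the rule. Curation rules are codified
visual inspection: shared-epitope fraction ≥ 0.25, the stem Arg(s2)/Asp(s
[L−1]) salt bridge (≤ 4 Å) when that pair is present, and no buried
(SASA < 5 Å²) charged side-chain group in the loop without an opposite
charge within 4.5 Å; charge pairing is evaluated per charged group, since a
guanidinium hydrogen-bonded through one nitrogen is paired.

## Synthetic fixtures

The toy complex is a ~90-residue scaffold: a heavy chain whose framework
strands flank a compact hairpin H3 carrying the parental bH1 sequence
SRWGGDGFYAMDY, a light-chain hairpin, and a 14-residue helical antigen.
The antigen is placed against the loop tip, the azimuth is chosen among
contact-compatible placements by a LJ + screened-Coulomb energy proxy, and
the pose is then settled by a rigid-body optimization including
hydrogen-bond wells — the epitope is thereby genuinely complementary to the
parental loop, which is the premise a loop-replacement screen needs. The
parental stem Arg/Asp pair is swung into its salt bridge by a deterministic
chi sweep (the same step runs after every graft, so a self-graft is exactly
idempotent). Construction guarantees: chemically sane backbone geometry
(NeRF-built), ≥ 5 parental H3–antigen heavy-atom contacts at 4.5 Å,
bit-for-bit determinism under the seed, and H3 coordinates that vary with
the seed. Generated H3 libraries draw residues from the frequency profile
of the experimentally characterized design panel (cysteine-free), include
the parental sequence and the minimal-H3 control (first 3 + Gly + last 3),
and cycle lengths through the requested range. Synthetic score tables
implement the size-bias phenomenon directly:
score = base − slope·length + N(0, σ), with slope 1 score unit per residue
and σ = 1 by default.

What the fixtures do **not** emulate: real antibody topology (no β-sheet
pairing or disulfides), solvent, crystallographic noise, or — most
importantly — the discriminating power of mature force fields. Passing
tests on these fixtures demonstrates that the protocol machinery (grafting
geometry, stage bookkeeping, filters, stratified ranking) is correct, not
that the internal potentials would rank real binders as the original
engines do.

## Problem sizes and determinism

Default stage counts are the protocol's (5000 samples, rescore 1000, keep
250, 100 per stem, 5 then 25 expansions). Tests and the acceptance script
run scaled-down screens (60/40/12/6 with 1/2 expansions in the suite;
200/100/25/10 with 2/5 in the acceptance run) on libraries of ~13
candidates over three length strata — sizes chosen so the full protocol
executes end to end while remaining a desk-scale computation. All
randomness flows through explicit integer seeds (per-candidate streams are
derived by hashing the candidate id), and the full pipeline is deterministic
under a fixed seed and configuration.

## Known limitations

- The stand-in potentials reproduce the protocol's structure, not the
  ranking fidelity of Talaris/SIE. On the synthetic screen the parental
  binder typically scores better than its stratum median consensus
  (composite Z < 0 under the suite's reference seed) but its exact Z is
  seed-dependent and it is not a robust ≤ −1.5 outlier among
  composition-matched decoys; the planted-binder recovery property is
  therefore demonstrated at the selection layer, where a strong binder
  planted in the synthetic score table must survive the stratified-Z
  cutoff.
- Cross-length H3 RMSD comparisons are refused rather than aligned; the
  per-region RMSD table compares like with like.
- The retrospective graft assumes the design crystal shares the parent's
  framework labeling for the superposition and residue correspondence.
- Stem matching uses BLOSUM62 log-odds in place of an unspecified HMM; the
  1.7 retention window is preserved numerically but its scale is the
  profile's, and it is configurable.
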