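# Methods

`gofold` implements a structure-based ("Gō") model of RNA folding: a potential
in which only atom pairs that touch in the folded reference structure attract,
so the energy landscape is funnelled toward the native state.  This note
documents the model, its parameters, the numerical choices, what the synthetic
fixtures emulate, and the known limitations.

## The potential

For a native structure with heavy-atom coordinates, the non-bonded energy is

    V = 4 ε Σ_(i,j) ∈ native [ (σ_ij / r_ij)^12 − (σ_ij / r_ij)^10 ]
      + 4 ε′ Σ_(i,j) ∉ native (σ_rep,ij / r_ij)^12

where σ_ij is the pair distance in the native structure.  This printed 12-10
form has V(σ) = 0 and its minimum −0.26792 ε at r = σ·√(6/5) ≈ 1.09545 σ.
The conventional structure-based weighting ε[5(σ/r)^12 − 6(σ/r)^10], whose
minimum is −ε at exactly σ, is available as `GoParameters(form="sbm")`; it is
what established RNA structure-based studies that quote ε = 0.14 / ε′ = 0.01
actually integrate, and it is the default of `desk_parameters()` (below).

**Native contacts** are heavy-atom pairs within 4.0 Å in the native state,
excluding covalently coupled pairs (1-2/1-3) and pairs closer than
`min_residue_separation = 3` residues in sequence.  The separation rule is the
common structure-based-model practice, and here it is also a correctness
requirement: with bonds, angles and dihedrals restrained to native geometry,
atom pairs in the same or adjacent residues remain within 1.2 σ in essentially
every accessible conformation, so counting them would make the protocol's
"unfolded configurations with no native contacts" (Q = 0) unreachable.
Settings of 0/1 restore the literal any-pair/no-intra-residue definitions.

**Excluded volume.**  Non-native pairs repel with per-pair radius
σ_rep,ij = min(σ_rep, 0.8 · d_native,ij), σ_rep = 2.5 Å.  The cap matters:
pairs dropped from the contact map by the separation rule sit closer than
2.5 Å in the native state, and a uniform radius strained the native structure
apart (the native mini-tRNA lost most of its contacts within picoseconds even
at 200 K).  Capping at the native separation is the strain-free choice used by
structure-based toolchains.

**Bonded terms** use uniform constants with equilibria measured from the
native structure, so the native state is the exact bonded minimum:

| term      | form                    | constant | units        |
|-----------|-------------------------|----------|--------------|
| bond      | k (r − r₀)²             | 100      | kcal/mol/Å²  |
| angle     | k (θ − θ₀)²             | 20       | kcal/mol/rad²|
| dihedral  | k (1 − cos(φ − φ₀))     | 1        | kcal/mol     |

Two regularisations keep the forces integrable:

* Angles whose native value is within ~15° of linear (|sin θ₀| < 0.26) use a
  cosine-harmonic k_c (cos θ − cos θ₀)² with k_c capped at 4 k_angle.  The
  harmonic form's force carries a 1/sin θ factor that diverges at the colinear
  geometry such angles visit constantly; before this change trajectories of
  systems with near-linear linker angles heated without bound.  The native
  geometry remains the exact minimum, and the analytic force is the exact
  gradient everywhere.
* No dihedral is built across a flanking native angle within ~17° of linear
  (sin < 0.3): the torsion force diverges as a flanking triple goes colinear.
  This is the standard "no torsion across linear angles" rule.

Units throughout: kcal/mol, Å, amu, ps, K, with k_B = 0.0019872041
kcal/(mol·K) and 1 kcal/mol = 418.4 amu·Å²/ps².

## Sampling

Dynamics are BAOAB-split Langevin (half kick, half drift, exact
Ornstein-Uhlenbeck velocity refresh, half drift, half kick) at a default
timestep of 2 fs with heavy-atom masses and friction 1 ps⁻¹ — the friction is
purely a thermostat, as the model has no solvent.  With friction 0 and noise
off the scheme reduces to velocity Verlet; the energy-conservation check runs
at 0.2 fs, where the drift over 10⁴ steps is below 10⁻⁴ relative.  Measured
kinetic temperature is within 1% of target at 2 fs.  Velocities initialise
from the Maxwell-Boltzmann distribution at the run temperature.

Every run is seeded; identical (seed, parameters, platform) gives
bit-identical trajectories.  A master seed spawns independent per-trajectory
seeds through `numpy.random.SeedSequence.spawn`, all below 2³¹.

**Unfolded ensembles** are generated two ways: (i) the study protocol —
high-temperature runs (550–700 K, sampled uniformly) from the native state
until not a single native contact satisfies the formation criterion; and (ii)
`randomize_unfolded`, a fast geometric stand-in applying seeded pivot moves
(random rotations of all downstream residues about an inter-residue backbone
bond).  Pivot moves change backbone dihedrals only — bond lengths and bond
angles keep their native values exactly — and moves that bring any non-bonded
pair closer than 2 Å are rejected, so the result is a self-avoiding coil with
Q = 0.

**Folding runs** start from unfolded configurations (Q < 0.2 enforced) and
terminate at the first observation of Q > 0.8.  The termination condition is
checked every 10 steps even though frames are stored every 100: with
100-step checks, short-lived threshold crossings between samples are missed
and folding events undercounted.

## Analyses

* **Q** — fraction of native contacts with r_ij < λ σ_ij, λ = 1.2 (standard
  native-contact practice; Q(native) = 1 for any λ ≥ 1).  Per-domain Q uses
  intra-domain contacts only; domains without intra-domain contacts carry no
  Q series and are skipped by the pipeline with a log note.
* **F(Q) = −k_B T ln P(Q)** from the pooled histogram of all frames of all
  trajectories of a system, equally weighted, 20 bins, empty bins masked
  rather than smoothed, minimum shifted to zero.
* **Pathways** — a domain folds at the first frame where its Q exceeds 0.8
  and stays above for 5 consecutive analysis frames (persistence suppresses
  transient crossings); the trajectory's label is the arrow-joined order of
  those events, with exact ties broken by domain name and flagged.
* **Q_tsl × Q_dsl density** — pooled 2-D histogram; "corner mass" is the
  density with one stem-loop folded and the other not (Q > 0.8 vs Q < 0.2),
  "diagonal mass" the concerted band |Q_tsl − Q_dsl| < 0.2 with both mid-range.
  Stepwise folding puts more mass in the corners than on the diagonal.
* **Residue-interaction maps** — fraction of frames in which any native atom
  contact between two residues is formed.
* **Δd** — mass-weighted base center-of-mass distance between a focus residue
  and a neighbour, averaged over frames passing a per-domain Q gate, compared
  between modified and unmodified systems (negative Δd = closer when
  modified).
* **N_HB** — heavy-atom hydrogen-bond count: donor/acceptor pairs from fixed
  per-base lists within 3.5 Å, no hydrogens and no angle criterion (the model
  carries no hydrogens; the threshold is configurable).  N2,N2-dimethylation
  removes N2 from the donor list.

## The m2,2G edit

`apply_m22g` converts a guanosine to N2,N2-dimethylguanosine by adding two
carbons bonded to N2 at 1.45 Å in idealised trigonal in-plane geometry (120°
from the C2–N2 bond, in the best-fit base plane).  All other atoms are
untouched, and because bonded equilibria and the contact map are rebuilt from
the modified structure, the modified native state is still the potential's
reference minimum.  The edit is applied before any simulation; requesting it
on a non-guanosine fails the pipeline at the prepare stage.

## Synthetic fixtures and desk-scale parameters

The generators build reduced pseudo-atom RNAs (3–5 heavy atoms per residue:
phosphate proxy P, sugar proxy C4', and 1–3 base atoms with real nucleobase
atom names, so base-atom selections and H-bond chemistry resolve):

* `make_hairpin` — an idealised stem-loop; paired residues place their
  innermost base atoms 2.5 Å apart so both the direct and the diagonal
  (next-rung) cross-strand pairs fall inside the 4 Å cutoff, and stems rise
  3.1 Å per residue.
* `make_mini_trna` — four stem-loop arms labelled asl, dsl, tsl, aas plus a
  variable-loop linker (vl), with the tsl stacked 3.6 Å above the dsl and the
  vl routed over the dsl through a compact 2 Å-radius curl, so dsl–tsl and
  dsl–vl inter-domain native contacts exist — a toy analogue of the L-shaped
  tertiary fold.  Arm placement is collision-checked at build time (minimum
  non-bonded clearance 2.05 Å).
* `make_scripted_trajectory` — frames in which each domain snaps from an
  expanded geometry to native at a prescribed frame; a complete, independent
  oracle for the pathway classifier.
* `make_nucleotide` / `make_base_pair` — full-geometry planar purines for
  tests of the m2,2G edit and hydrogen-bond counting.

**Why `desk_parameters()` exists.**  ε = 0.14 kcal/mol is calibrated for full
heavy-atom RNA, where the 4 Å map yields tens of contacts per residue
(≈2 kcal/mol of native stabilisation per residue).  A 3–5-atom-per-residue
model has ~2–3 contacts per residue; at ε = 0.14 its native basin is more
than an order of magnitude too shallow relative to k_B T and no folding
transition exists anywhere between 200 K and 600 K.  `desk_parameters()`
restores the full-atom per-residue stabilisation with the conventional SBM
weighting and ε = 1 kcal/mol — the canonical structure-based well depth.
Under these parameters the mini-tRNA fixture is folded at 200 K, sits near
its folding transition at 353 K (mirroring the rationale for simulating at
the upper end of the tRNA melting range), and unfolds at 600 K; the 12-nt
hairpin folds from randomized coils at 300 K within 5·10⁵ steps in 10/10
seeds and melts at 600 K in 10/10.

What passing tests on these fixtures shows: the potential, integrator,
termination logic, order parameters and classifiers behave correctly on
systems with the same *structure* of the problem (multiple domains, tertiary
packing, two-state-like behaviour).  What they do not show: quantitative
agreement with any real tRNA's folding thermodynamics or pathway fractions —
reduced geometry, compensated ε and a ~50-residue chain cannot reproduce
those numbers, and no attempt is made to mimic the real molecule's contact
count or sequence.

## Problem sizes

The test suite and the acceptance script run entirely on the fixtures:
hairpin 4 bp + 4 loop (36 atoms), mini-tRNA at 3 atoms/residue (~145 atoms)
or 5 for the modification analyses (~250 atoms); folding ensembles of 4–10
trajectories with 4–5·10⁵-step budgets; thermal checks over 10⁵ steps; the
equipartition check over 4·10⁵ steps of a single stiff bond.  These sizes
were chosen so a full verification pass completes in a few minutes on one
CPU core while every statistic quoted is still computed, not asserted.

## Known limitations

* No electrostatics, solvent or sequence-dependent energetics; ionic effects
  enter only implicitly through ε, as in the underlying model class.
* The printed 12-10 form leaves the native state on the attractive term's
  zero crossing rather than at its minimum; equilibrium bond/angle terms then
  balance a small outward pull of 8ε/σ per contact pair at r = σ.
* Near-linear angles are weakly confined near equilibrium (quartic in the
  deviation) by the capped cosine-harmonic term.
* The classifier reports first-passage order only; no kinetic modelling
  (rates, Markov state models) is attempted.
* Pipeline analyses hold trajectory frames in memory; per-trajectory frame
  PDBs are written only with `save_frames`.
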