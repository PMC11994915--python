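# Methods

## Free-energy model

The package estimates alchemical free-energy differences with forward
Zwanzig exponential averaging over a λ-window ladder. For each window
transition λ → λ+Δλ,

    ΔG_λ = −kB·T · ln ⟨ exp(−β·[V(λ+Δλ; x) − V(λ; x)]) ⟩_λ ,

with configurations x Boltzmann-distributed under the mixed potential
V(λ) = (1−λ)V₁ + λV₂, and ΔG = Σ_λ ΔG_λ. The relative binding free
energy of a mutation is the thermodynamic-cycle difference
ΔΔG = ΔG_bound − ΔG_free, where both legs apply the identical
transformation. The sign convention is positive = weakened binding.

The exponential average is evaluated with log-sum-exp, so arbitrarily
large |β·ΔV| cannot overflow. The estimator is single-ended (forward, as
the accumulation formula is written); the test suite uses the reverse
estimate as a double-ended consistency oracle rather than exposing it as
a second production estimator.

Constants: kB = 0.0019872 kcal/(mol·K), T = 300 K by default; energies
are uniformly kcal/mol and distances Å.

### λ schedule

The default ladder is the production 46-window soft-core schedule: 47 λ
values from 0.00 to 1.00, spaced down to Δλ = 10⁻⁵ at both end points
(where soft-core atoms appear or vanish and the perturbation is
stiffest) and Δλ = 0.04 through the middle. Custom schedules are
accepted anywhere a schedule is taken; they must be strictly increasing
from exactly 0 to exactly 1.

### Decomposition

Electrostatic and van der Waals components are obtained by applying the
same window estimator to the component perturbation energies
(V = V_elec + V_vdW) collected in the same configurational ensembles as
the total. Because exponential averaging is nonlinear the components do
not add exactly; the residual is reported explicitly as a coupling term,
and total = elec + vdW + coupling holds identically by construction.
When one component's perturbation is identically zero its term — and the
coupling — are exactly zero.

### Errors

Each window × replica is an independent Markov chain; per-replica totals
give a sample standard error (n−1 denominator, /√n) over the default 6
replicas. For ΔΔG the bound- and free-leg errors are combined in
quadrature; both per-leg errors remain available on the cycle object.
The quadrature combination is this package's explicit convention (the
alternative — reporting legs only — loses the headline uncertainty).

### Soft-core pair potential

A Beutler-style form with α = 0.5 and λ-power 1 for van der Waals,

    V_vdw(r, λ) = (1−λ)·4ε·[(αλ + (r/σ)⁶)⁻² − (αλ + (r/σ)⁶)⁻¹],

and linear charge scaling (1−λ)·C·q₁q₂/r for electrostatics. At λ = 0
this is exactly Lennard-Jones + Coulomb; at λ = 1 the pair is fully
decoupled; for λ > 0 the vdW term is bounded as r → 0. These are the de
facto standard choices in FEP practice; α and the λ-power are arguments,
not constants.

## Synthetic data

### Toy alchemical systems

The Monte Carlo engine samples two families of end states:

* **Harmonic wells** V = ½k|x−c|² (1–3 dimensions). The exact
  transformation free energy is (d/2)·kB·T·ln(k₂/k₁). By package
  convention harmonic energies are booked entirely as van der Waals,
  giving decomposition tests an exactly-zero electrostatic leg.
* **A soft-core LJ particle** among fixed neighbour sites in a hard-wall
  box, with optional Coulomb term — exercises the soft-core form and
  produces transformations with a genuine (small) coupling term.

Sampling is Metropolis Monte Carlo with Gaussian proposals: acceptance
min(1, e^(−βΔE)), step size adapted toward ~40% acceptance during
equilibration and then frozen, so detailed balance holds exactly for all
production samples. One independent chain per (window × replica), no
sample reuse across windows; per-chain seeds are spawned
deterministically from (seed, window index, replica), so identical
inputs are bit-reproducible. Defaults: 1000 production samples and 200
equilibration steps per window, 6 replicas.

Two independent ground truths check the estimator: the harmonic closed
form, and direct quadrature of −kB·T·ln(Z₂/Z₁) on a trapezoidal grid
(1-D/2-D), which reports its own grid-refinement error.

### Synthetic trajectories

Two bead chains (one "peptide", one "receptor") on 5 Å-spaced lines; each
peptide residue sits at a prescribed contact distance from its partner
bead during scheduled frame intervals (half-open, 1-based) and at the
separated distance otherwise, plus optional isotropic Gaussian noise.
Defaults: contact 4 Å (just inside the 4.5 Å contact cutoff), separation
30 Å (far outside it). This gives every trajectory statistic a
constructed truth — e.g. a residue scheduled in contact for 7 of 10
frames must yield contact probability 0.70 exactly at zero noise.

What the synthetic data does **not** emulate: solvent, realistic
side-chain geometry and packing, correlated inter-residue motion,
secondary structure, or force-field energetics. Passing tests therefore
demonstrate the correctness of the estimators and statistics as
algorithms, not the accuracy of any particular force field or sampling
protocol on real complexes.

## Trajectory statistics

* **Contact probability**: fraction of analysed frames in which the
  minimum heavy-atom distance between two selections is below the
  cutoff, pooled over replicas (total contact frames / total frames).
  The cutoff defaults to 4.5 Å — a common residue-contact convention,
  explicitly configurable because no universal value exists. Analysis
  restricted to the final `tail_fraction` of frames (default 10%,
  half-open window), the dimensionless stand-in for "the last portion of
  the production run".
* **Key-residue filter**: residues with contact probability strictly
  above a threshold, default 50%.
* **SASA**: Shrake–Rupley with probe 1.4 Å and 960 deterministic
  golden-spiral sphere points per atom; Bondi-style element radii from a
  built-in table. Accuracy is discretization-limited at the ~1–2% level
  at 960 points (tests verify convergence toward a 10⁵-point brute-force
  burial oracle).
* **Contact-area ratio**: (isolated-peptide residue SASA − in-complex
  residue SASA) / isolated SASA, clamped to [0, 1]; a residue with zero
  isolated SASA reports NaN rather than a fabricated ratio. Computed on
  a caller-chosen frame (reported in CLI outputs), since averaging over
  frames versus using a representative frame are both legitimate.
* **Hydrogen bonds**: geometric criterion, donor–acceptor distance
  < 3.5 Å and D–H…A deviation from linearity < 30°; hydrogens are
  associated to donors by same-residue proximity (< 1.3 Å in the first
  frame), and donors with no hydrogen are a hard error.
* **RMSD**: Kabsch superposition via SVD with determinant correction (no
  reflections); at least three non-collinear atoms required, degenerate
  geometry is an error rather than a silent answer.

## Mutation bookkeeping

Mutation labels follow `<wild><site><target>` with `+` for simultaneous
multi-site compounds; `sY` is a two-character code on either side, so
desulfation (sY→Y) and sulfation (Y→sY) parse uniformly. Sites are
1-based. Malformed labels, out-of-range sites and wild-type mismatches
raise three distinct exception types.

Average molecular weight = Σ standard average residue masses + 18.02 Da
water (free termini) + 80.06 Da SO₃ per sulfation. The average-mass
convention (rather than monoisotopic) is used because it reproduces the
measured variant weights of the reference peptide within print rounding
(±0.2 Da).

Experimental conversion: ΔΔG_exp = −kB·T·ln(Kd_wt/Kd_mut), unit-free in
Kd. Classification uses the replica standard error as the neutrality
band: enhancing if ΔΔG + SE < 0, weakening if ΔΔG − SE > 0, else
neutral — i.e. a call is made only when the error bar clears zero. This
band is an explicit package convention; no quantitative threshold for
"promising" exists beyond it.

The relative root-growth statistic for phenotyping assays is
100 × mean(treated root lengths) / mean(control root lengths); the
sampling-budget helper multiplies per-run time × replicas × cycle legs
(18.4 ns × 6 × 2 = 220.8 ns at production scale).

## Problem sizes and numerical choices

The validation suite runs at desk scale: 10³ samples/window × 6 replicas
over the 46-window ladder for the headline recovery test (the estimate
lands within 3× its replica standard error of the closed form), 21–41
linear windows × 600–1000 samples for cycle-closure and antisymmetry
properties, and 10-frame bead trajectories for the statistics. These
sizes were chosen so the whole suite completes in about a minute while
keeping every stochastic check at ≥3σ headroom; all stochastic tests fix
their seeds and are exactly reproducible.

Degenerate inputs are errors, not warnings: empty sample sets,
non-finite energies or coordinates, zero-length tail windows, empty
selections, donors without hydrogens, collinear RMSD geometry.
Under-sampled windows (fewer than 50 samples by default) warn but
proceed, since short windows are legitimate in smoke tests.

## Known limitations

* Forward-only exponential averaging is biased at poor window overlap;
  the ladder must be fine enough (the asymmetric-overlap direction of a
  well-narrowing transformation is the worst case, visible in the
  antisymmetry test's need for 41 windows at small sample counts).
* Replica standard errors capture stochastic spread, not residual
  systematic bias from finite window spacing.
* The toy sampler is a single-particle Metropolis walk: no molecular
  degrees of freedom, no solvent, no long-range electrostatics.
* SASA and burial values are discretization-limited at the stated point
  counts; tighten `n_points` where 1% matters.
* The PDB reader handles standard fixed-column ATOM/HETATM records
  (first altloc kept) and nothing more exotic; trajectories are
  multi-frame XYZ with a PDB topology, by design.
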