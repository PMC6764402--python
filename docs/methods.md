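# Methods

## The model

`synagg` studies how a proline-binding chaperone (FKBP12) changes the
aggregation of an amphiphilic, intrinsically disordered protein
(alpha-synuclein), and how a tight competitive inhibitor (ElteN378)
reverses that change.  Three model layers are involved.

### Coarse-grained monomer and force field

Each alpha-synuclein monomer is a linear chain of 15 beads in three
5-bead blocks: a hydrophilic N-terminal block, the hydrophobic central
NAC block that drives amyloid stacking, and a hydrophilic C-terminal
block.  An FKBP12-bound ("doped") monomer replaces the last C-terminal
bead with a hydrophobic SEED bead — FKBP12 binds a proline in the
C-terminus and, in this picture, presents an extra sticky patch there.
SEED interacts exactly like a NAC bead.

The solvent is implicit.  All units are reduced Lennard-Jones units
(epsilon = sigma = m = 1, tau = sigma sqrt(m/epsilon)).

| term | form | default | why |
| --- | --- | --- | --- |
| hydrophobic pair (H-H, H-S, S-S) | 12-6 LJ, truncated and shifted | eps 1.0, cutoff 2.5 sigma | attraction mimicking hydration-renormalised hydrophobic contact |
| any pair with a PHILIC bead | WCA (LJ cut at 2^(1/6) sigma) | eps 1.0 | good-solvent excluded volume: hydrophilic groups stay solvated |
| bond (14 per chain) | harmonic | k = 500 eps/sigma^2, r0 = 1 sigma | stiff but integrable at dt = 0.005 tau |
| angle (13 per chain) | harmonic in theta | k = 2 eps, theta0 = pi | semiflexible chain |

1-2 bonded pairs are excluded from the non-bonded sum; 1-3 pairs are
kept (the angle term dominates them).  The default system is dilute:
512 chains in a 60 sigma periodic cube (bead volume fraction about 2%),
scaled as N^(1/3) for smaller systems.  Doping: round-half-away-from-
zero of phi x N monomers, chosen uniformly at random with the build
seed.

### Dynamics

BAOAB Langevin integration (half-kick, half-drift, Ornstein-Uhlenbeck
refresh, half-drift, half-kick) with dt = 0.005 tau, friction
1 tau^-1 and k_B T = 0.60 eps by default.  With zero friction the
scheme is exactly velocity Verlet, which is how the energy-conservation
tests run.  The temperature is a calibration knob, not a reproduction
of any published protocol: 0.60 eps puts the hydrophobic contact energy
at ~1.7 k_B T so the undoped system aggregates slowly rather than
instantly.

Implementation notes (all verified by oracle tests):

* Production forces come from a Verlet neighbour list (cutoff + 0.6
  sigma skin) rebuilt whenever any bead has moved half a skin; a
  cell-list and an all-pairs path exist independently and agree with
  the production path to 1e-10 eps/sigma.
* Langevin noise is drawn from a 256-layer ziggurat over a splitmix64
  stream compiled into the integrator kernel.  The sampler was checked
  against the normal distribution by moments and a Kolmogorov-Smirnov
  test (n = 2e5).  Runs are bit-reproducible for a fixed seed and fixed
  run settings; changing the frame-reporting interval changes
  floating-point summation order and, through Lyapunov growth, the
  microscopic trajectory (not the statistics).
* Desk preset: 128 chains, 2e5 steps (1000 tau).  Production preset:
  512 chains, 2e6 steps.  Replica protocol: three independent seeds per
  condition, averaged with standard errors.

### Aggregate kinetics

Two monomers are in contact when at least `min_contacts` (default 2)
of their hydrophobic bead pairs are within 1.5 sigma (minimum image);
aggregates are single-linkage clusters (union-find) of that relation.
The kinetics observable n_mol(t) is the mean monomers per aggregate.
Singletons count (a dispersed system starts at n_mol = 1); number
weighting is the default and mass weighting (sum s^2 / sum s) is also
reported, since either convention is defensible for "average aggregate
size".  The total inter-monomer hydrophobic contact count is logged as
a rough ThT-like reporter (both count packed hydrophobic material) and
correlates positively with n_mol in aggregating runs.

"Final" size = mean over the trailing 10% of frames.  The
doped-fraction crossover is estimated as the smallest phi whose final
n_mol exceeds 3x the phi = 0 value (factor configurable; the rule is a
ratio and is scale-invariant).

### Morphology

Branching is measured on the monomer-level contact graph: branch nodes
have degree >= 3 (in-register fibril stacking gives interior monomers
degree 2), ends have degree 1.  Geometry is measured after unwrapping
the aggregate across periodic boundaries (BFS over the contact graph,
minimum-image shift per edge): gyration-tensor eigenvalues, relative
shape anisotropy kappa^2 (1 = collinear, 0 = isotropic), asphericity,
and a mass-radius fractal dimension fit of log N(<r) vs log r between
2 sigma and the 90%-mass radius.  The fractal dimension of an
aggregate is computed on monomer centres: at bead level even an ideal
fibril is a ribbon 14 sigma wide and the slope saturates near 1.5; the
centre backbone recovers d_f = 1 for a stack, 3 for a ball.

Classification defaults (all configurable, always reported next to the
raw metrics): linear when branch_fraction < 0.05 and kappa^2 > 0.7;
branched when branch_fraction >= 0.05, size >= 20 monomers and the
contact graph is sparse (mean degree < 2.8 — ideal fibrils and trees
sit near 2); otherwise globular/star-like.  The mean-degree guard
exists because a densely packed ball has many degree->=3 contacts that
have nothing to do with dendritic branching.

### Binding equilibrium

The doped fraction phi fed into the simulations is the equilibrium
fraction of alpha-synuclein carrying FKBP12.  Two-species case: the
standard quadratic solution of S + F <-> SF mass balance.  Competitive
case (inhibitor I occupying the FKBP12 pocket): bisection on free F in
[0, F_tot] of

    F + S_tot F/(Kd_s + F) + I_tot F/(Kd_i + F) = F_tot,

which is monotone, so the bracket is guaranteed; phi = F/(Kd_s + F).
Tolerance 1e-12 uM; residuals verified below 1e-10.  Defaults:
Kd_s = 1.2 uM (the complex is only characterised as "micromolar"; 1.2
is the documented package default because it satisfies both qualitative
bounds simultaneously — equimolar 1 uM gives phi = 0.351 in [0.3, 0.4],
and adding 0.2 uM of a tight inhibitor gives phi = 0.297 < 0.3) and
Kd_i = 0.01 uM (FK506-like affinity).  Both are configuration
parameters, not claims about the real complex.  Concentrations are
micromolar throughout; `nm()` converts nanomolar inputs.

### ThT kinetics fitting

Fluorescence curves are fit with the logistic nucleation-elongation
surrogate F(t) = f0 + A/(1 + exp(-k(t - t_half))), with the standard
lag-time convention t_lag = t_half - 2/k (reported only when
non-negative).  Mixed samples that overshoot and relax are handled by a
phenomenological post-midpoint decay factor
[1 - d(1 - exp(-(t - t_half)+/tau_d))]; d = 0 recovers the plain
sigmoid, and the decay model is only adopted when AICc prefers it.
Fitting is `scipy.optimize.least_squares` with five seeded starts; best
residual wins, ties break to the smallest rate.  A fitted amplitude
below five times the residual RMS is flagged "no transition".  Recovery
performance (measured by the test suite): exact to 1e-4 relative on
noiseless data; median |t_half error| < 0.5 day at 2% amplitude noise.

## Synthetic data

The generators provide every input the analysis stages need, with
ground truth attached:

* ThT curves from the same sigmoid(-decay) family, on a uniform grid
  with seeded Gaussian noise.  The three-condition dataset emulates the
  experimental phenomenology qualitatively (pure protein slowest;
  equimolar chaperone faster, larger amplitude, overshooting; inhibited
  intermediate); its parameters are illustrative and none is read off
  a measurement.
* Ideal aggregates built from the standard 15-bead monomer at
  force-field spacing, so clustering cutoffs transfer unchanged:
  linear stacks (contact graph = path), branched trees (arms attached
  at 1.2 sigma so the hub is the only extra contact), globules
  (collapsed chains packed in a ball), and dispersed gases.

What the generators do *not* emulate: photophysics (no spectra, no
probe redistribution mechanism), instrument drift, heteroscedastic
noise, or any real aggregate geometry — passing the recovery tests
shows the estimators are correct on model-generated data, not that the
model describes any particular experiment.

## Numerical and design choices

* Overlap floor 0.9 sigma and up to 1e5 placement attempts at build
  time; boxes below 15 sigma are rejected (a straight chain would
  self-overlap through the periodic boundary).
* Angle forces guard the 1/sin(theta) prefactor (clamped at 1e-8; the
  (theta - pi) factor cancels the singularity analytically).
* Pair energies are truncated-and-shifted, so energies are continuous
  at the cutoffs; the LJ shift is reported separately and can be
  disabled.
* Crossover and classification thresholds are package definitions,
  validated on ideal fixtures; published imaging of such aggregates is
  qualitative, so there are no external numeric morphology values to
  calibrate against.

## Desk-scale behaviour and known limitations

The desk preset (128 chains, 1000 tau, three replicas per condition,
k_B T = 0.60) is what the test suite and the acceptance script run.
Its measured behaviour, which the heavier paper-scale preset may or
may not share:

* Final n_mol rises monotonically with phi (about 3.7 at phi = 0 to
  about 4.5 at phi = 0.6, SE about 0.1-0.25) and no condition reaches
  3x the undoped baseline within 1000 tau: the crossover estimate is
  right-censored at the top of the grid.  The cluster-cluster
  coagulation time at this dilution exceeds the run length, so the
  "few macro-aggregates" regime is out of reach at desk scale; the
  data do establish that nothing at phi <= 0.3 leaves the baseline,
  the direction the threshold statement requires.
* At this scale the aggregates of *all* conditions are compact
  micelles (largest clusters ~8-18 monomers, branch_fraction near 1,
  kappa^2 < 0.1 at phi = 0): with isotropic hydrophobic attraction and
  a 2:1 corona/core ratio, the spherical micelle is the preferred
  local packing, and chain stiffness (angle_k up to 20 eps) or 5x
  longer runs do not change that.  Genuine in-register fibrils need
  the directionality of beta-sheet hydrogen bonding, which an
  isotropic bead-bead potential cannot supply; the package measures
  and reports the morphology honestly rather than presupposing the
  fibril/dendrite contrast.  The morphology metrics themselves are
  validated on ideal fixtures where the expected answers are known
  exactly.
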