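# Methods

This note documents the models, algorithms, numerical choices and
limitations of `stringfe`. Units are fixed package-wide: energies in
kcal/mol, lengths in Å, masses in amu, temperatures in K, times in ps
(timesteps given in fs); k_B = 0.0019872 kcal/(mol·K). Defaults follow the
simulation conventions of the enzyme studies this workflow mirrors: 310 K,
Langevin collision frequency 2.0 ps⁻¹, 1 fs timestep, transferred-proton
CV masses of 2 amu in the mass-weighted metric.

## Synthetic landscapes (what they emulate, and what they do not)

`make_reaction_landscape` builds a potential V(x) over a low-dimensional CV
space from an ordered list of stationary free energies (minima alternating
with saddles). A curve is embedded in CV space — a straight segment by
default, optionally with a sinusoidal bend to exercise path curvature —
and the prescribed energies are placed at equally spaced arc-length
stations. Longitudinally the potential follows a cubic Hermite interpolant
with zero slope clamped at every station: each station is exactly
stationary, each inter-station branch is monotone, and the station energies
are reproduced to machine precision (exactly, for the line geometry; to the
dense-polyline resolution for the bend). Transverse to the curve the
potential is uniformly harmonic (default 50 kcal/mol/Å²); because the
confinement is uniform, the transverse free-energy term is a constant and
the exact PMF along the curve equals the prescribed profile plus an
additive constant — this is the property that makes the generator a valid
oracle for the whole pipeline, and it is tested both by transverse
Gaussian quadrature and by invariance of relative station energies under a
4× change of the transverse stiffness. Beyond the terminal stations the
longitudinal profile continues as a quadratic wall so sampling cannot
escape.

These landscapes emulate the *topography* a reaction PMF presents to the
string/umbrella-sampling machinery — multiple basins, saddles up to
~21 kcal/mol, curvature, a mass-weighted metric. They do not emulate basin
anharmonicity or position-dependent transverse widths of a real enzyme
surface (the calibration tables only prescribe stationary values, not
shapes), nor the cost and noise structure of QM/MM forces. Passing the
recovery tests therefore validates the estimators and their coupling, not
the electronic-structure layer.

The packaged calibration tables carry the three catalytic stages of the
asparaginase cycle. The acylation stage lists the on-path states R…ACE+NH₃
relative to an *external* zero (the Michaelis complex, R = 1.4 including
the nucleophile-activation penalty); the Michaelis reference is carried as
an offset rather than as a station because two consecutive minima would
violate the minimum/saddle alternation the generator requires. The
regeneration stage prints only its barrier (5.2) in the main text; its
product station is set to −11.23 relative to the stage reactant so that
the assembled cycle ends at the printed overall reaction free energy
(−7.2 relative to the Michaelis complex).

## Sampling engine

Underdamped Langevin dynamics with the BAOAB splitting; one force
evaluation per step; velocities initialized from Maxwell-Boltzmann. BAOAB
was chosen for its near-exact configurational sampling at practical
timesteps: the leading configurational bias for a harmonic mode scales as
(ωΔt)²/4, which is <1% for every fixture at the timesteps used (0.1–1 fs
depending on the stiffest mode present). All stochastic entry points take
an explicit seed; per-window and per-node streams are derived from
(seed, index) spawn keys, so batched and sequential execution are
bit-identical and independent of scheduling. Friction is a pure efficiency
parameter (the stationary distribution does not depend on it); production
umbrella sampling uses 5–10 ps⁻¹, which decorrelates window coordinates
fastest for the force constants that arise here, while the documented
default of 2.0 ps⁻¹ matches the thermostat setting of the mirrored
workflow.

`equilibrium_moment` is the deterministic oracle: trapezoid Boltzmann
quadrature on a grid (dimension ≤ 3) with the discretization error
reported as the difference against a half-resolution grid, and a warning
when the boundary density exceeds 1e-10 of the maximum.

## Adaptive string method

The free-energy gradient at a node is estimated from the harmonic
identity ∇G(c) ≈ −k(⟨x⟩ − c), which is unbiased for harmonic restraints
and avoids instantaneous-force estimators. Nodes move along the negative
gradient component transverse to the local tangent, computed in the
mass-weighted metric; tangents are taken from a lightly smoothed copy of
the string (one binomial pass) because raw node noise would leak the large
longitudinal gradient into the transverse move. Per-iteration node
displacement is capped (default 0.01 Å): on stiff surfaces the raw
gradient would otherwise throw nodes across ridges in a single move — with
the cap the deterministic limit of the update recovers both saddles of the
standard three-well test surface to <0.01 units. Reparametrization is
piecewise-linear resampling to equal mass-weighted arc length, swept until
segment lengths agree to 1e-6 relative (a single sweep cuts corners on
bent strings). Endpoints are not restrained; they relax by steepest
descent to their basin minima each iteration. Hamiltonian exchange between
neighbor nodes is attempted every 50 sampler steps with alternating
even/odd pairing; swapping positions only is valid because velocities are
i.i.d. Maxwellian. Convergence is declared when the mass-weighted RMSD
against the running-average string stays at or below the threshold
(default 0.1 amu^1/2·Å) over a trailing window equivalent to 2 ps of
sampling. After convergence the node positions of a trailing block of
iterations (default 15) are averaged and lightly smoothed before the
path-CV is built — single-iteration strings carry Monte-Carlo jitter of
the order of the convergence threshold, which would otherwise contaminate
the projection-based s.

The choice of the transverse-only move (rather than the full gradient) and
the projection-based path-CV (rather than an exponential-weighted form)
are documented substitutes for the original formulations, adequate for
landscapes of this scale; on-path s values are exact and the s-gradient is
piecewise constant.

## Umbrella sampling and WHAM

Windows are equally spaced interior centers cᵢ = (i+½)/n on s ∈ [0,1]
(default n = 48). The initial force constant 4k_BT/Δs² makes the biased
Gaussian width half the spacing; a short pilot run rescales each window by
(σ_obs/σ_target)², clipped to [¼, 4]× — the on-the-fly calibration that
keeps the s-density homogeneous. The path is extended ~8% beyond the
terminal minima (linear tangent continuation, end tangents averaged over
three segments) so both stage endpoints sit in the window interior rather
than at the clamped s = 0/1 edges. WHAM solves the standard
self-consistent equations on a fixed grid (default 200 bins) as a
stabilized matrix iteration in probability space — exponent shifts per
iteration make it numerically equivalent to the log-space form while
allowing the bootstrap to re-solve quickly from warm starts; convergence
requires the maximum relative change of window free energies below 1e-10.
Profiles are referenced to the first minimum along s (the stage-reactant
analog of referencing to the Michaelis complex). Uncertainties are a
seeded block bootstrap (20 contiguous blocks per window, 100 resamples by
default; per-block histograms are precomputed so each resample is a sum):
reported ± values of this kind rarely state their estimator, so the
block bootstrap is this package's documented choice. Stationary points are
extracted from the (moving-average smoothed, window 5) profile with a
prominence filter (default 0.5 kcal/mol) and alternation enforced by
keeping the more extreme of same-kind neighbors.

Default problem sizes for the end-to-end pipeline — 25 string nodes,
~100 iterations of 400 steps, 48 windows × 100k production steps at 0.5 fs
— were chosen so a full stage reconstruction runs in about a minute on one
CPU while recovering the calibrated stationary energies to ~0.1–0.3
kcal/mol (a few bootstrap standard errors). Reconstruction error is
dominated by the statistical bridge error between adjacent windows and
shrinks as 1/√(steps).

## Thermodynamic integration and cycles

Alchemical toys mix two everywhere-finite end states linearly in λ, so no
soft-core treatment is needed; dU/dλ = V_B − V_A. The default schedule is
11 equidistant λ points with 5 replicas, the leg ΔG is the mean of the
replica trapezoid integrals, and the reported error combines the replica
standard error with a Richardson-type quadrature estimate
|I_fine − I_half|/3 in quadrature (independent sources). The two-leg
"release toy" softens both environments by the same stiffness ratio, so
the analytic leg difference equals the requested target exactly and the
trapezoid truncation cancels between legs. The pKa cycle applies
pKa = pKa_aq + ΔΔG/(RT ln10) (aqueous reference 9.1) and the penalty
RT ln10 (pKa − pH); at 310 K the formula gives 1.418 kcal/mol for
pKa 8.5 at pH 7.5 — the printed penalty 1.38 evidently derives from the
unrounded cycle pKa, so the cycle used for recovery is calibrated to the
penalty itself rather than to the rounded pKa.

## Cycle assembly and the effective barrier

Stages are joined by continuity: each stage's reactant is anchored at the
previous stage's product energy plus any corrections attached to that
product, so the corrected acyl-enzyme resting state appears as its own
state (2.7 − 4.47 = −1.77 relative to the Michaelis complex) distinct from
the in-site product. Irreversibility is an explicit user mark, never
inferred. The effective barrier is the maximum G(TS) − G(resting
intermediate) over pairs not separated by an irreversible mark, computed
in a single pass with a running minimum that resets at each mark; the
tests pin it against exhaustive pair enumeration. The deprotonation
penalty may arrive either folded into the first stage's energies (as the
packaged acylation table has it) or as an explicit correction — a flag
records which, and supplying both is rejected.

## Trajectory descriptors

RMSF, weighted CV-space RMSD to a reference frame (no Cartesian
superposition — these are collective variables), and normalized 2-D state
densities with a time-resolved track. Angular coordinates use degrees in
[−180, 180) and wrap periodically. Conformational ON/OFF-state assignment
is deliberately not hard-coded: the 2-D density plus a user-supplied
classifier is exposed instead, because no numeric boundary is prescribed.

## Known limitations

- The generator's basin curvatures are free parameters; only relative
  stationary energies are meaningful, and only those are asserted.
- The projection-based s is non-smooth at Voronoi boundaries between path
  segments; with ~25–50 nodes and the landscapes used here this is
  invisible in the reconstructed profiles, but a strongly kinked path
  would need the exponential-weighted path-CV.
- WHAM bins the bias at bin centers; with the default 200 bins the
  associated bias is well below the statistical error, but very stiff
  windows with few bins per σ would need finer grids.
- The string update assumes the restraint is stiff enough that the
  harmonic gradient identity holds across the sampled cloud; on surfaces
  with curvature varying strongly over sqrt(k_BT/k), node stiffness must
  be raised (the three-well test surface uses 4000 kcal/mol/Å²).
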