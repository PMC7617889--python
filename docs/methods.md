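# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions that shape the results.

## Grand canonical Monte Carlo

Water exchange with the pocket is sampled in the Adams formulation: the
dimensionless control parameter *B* plays the role of chemical potential,
with `B = βμ′ + ln(ρ_bulk·V_region)` connecting it to the excess chemical
potential of a bulk reservoir (helper `adams_from_mu`). Acceptance is

    P_insert = min(1, e^B/(N+1) · e^(−βΔU)),
    P_delete = min(1, N·e^(−B) · e^(−βΔU)),

evaluated in log space so large |B| cannot overflow.

Two system flavours share this rule:

* **Unbounded cell** (`IdealGasCell`): *N* is the global particle count.
  Detailed balance gives a Poisson stationary law with mean `e^(B−βU)`,
  so a non-interacting cell obeys ⟨N⟩ = e^B — the engine's analytic
  control.
* **Lattice-site pocket** (`ToyPocketSystem`): each of 1–3 discrete sites
  holds at most one water, and the acceptance rule is applied with the
  *site-local* count (N ∈ {0, 1} for the chosen site, insert/delete
  proposed with equal probability on a uniformly chosen site). This is
  the Adams rule specialised to a single-site subvolume and is the
  formulation whose stationary distribution is exactly the
  independent-site grand-canonical law `⟨n_i⟩ = e^(B−βU_i)/(1+e^(B−βU_i))`
  (and, with pairwise coupling, the enumerated 2^k-state law). A global-N
  variant with uniform empty-site insertion proposals would instead pick
  up a spurious `−ln k` shift per site and was rejected for that reason.

Defaults: equilibration 10% of production; thinning every 100 steps;
temperature 298.15 K for hydration toys and 310 K where a proton-transfer
thermostat is being emulated; titration grid −9.0 → −24.0 in steps of
0.5 with five independently seeded repeats. Per-(repeat, grid-point)
seeds are spawned from one base seed, so titrations are bit-reproducible.
Statistical checks in the tests compare means against closed forms within
3 standard errors over repeats, with a small absolute floor (10⁻³
occupancy units) on the SE so saturated grid points — where every repeat
returns exactly 0 or 1 and the repeat SD collapses — are compared at a
meaningful resolution rather than at zero tolerance.

## Transfer free energies and the solvation cycle

Grand-canonical integration turns a titration curve into a per-water
transfer free energy. For a logistic site, `∫⟨N⟩dB` between the empty and
occupied plateaus equals `n_w·(B_max − B̄½)` up to exponentially small
edge terms, so the mean half-occupancy point is recovered from a
trapezoid on the measured grid and converted to energy against a bulk
reference:

    ΔG_solv = k_BT · (B̄½ − B_bulk).

**Sign convention.** `ΔG_solv` is the free energy of bringing a water
from bulk into the pocket: negative = more stable in the pocket. This
makes ΔΔG = ΔG_solv(bound) − ΔG_solv(apo) negative exactly when the
bound peptide stabilises the water network, which is the interpretation
the cycle is designed to report. The quantity is per transferred water,
so pocket sites that never titrate (e.g. the third apo site excluded by
the ligand) cannot move it — the reason solvation is defined against
bulk rather than vacuum.

`B_bulk` defaults to the bulk-equivalence Adams value of the standard
pocket region (3.23 × 3.38 × 5.78 Å box around the two bridging waters),
computed from the excess hydration free energy of water (−6.2 kcal/mol)
and bulk density 0.0334 Å⁻³; it is configurable because the reference is
a convention, not a measurement. Integration is plain trapezoid on the
0.5-step grid — reproducible and assumption-light; no smoothing is
applied. Errors are the standard deviation of repeat-level integrals
(independent repeats), propagated into the cycle as the root sum of
variances. Recovery experiments plant transfer free energies of
{−4, 0, +4} kcal/mol; around the default bulk reference those transitions
sit at B½ ≈ {−16.5, −9.7, −3.0}, so the recovery grid keeps the 0.5 step
but spans +4.0 → −24.0 to bracket all three.

## Umbrella sampling and WHAM

`wham_solve` iterates the standard self-consistent equations on pooled
histograms (default 100 bins over the sampled range, tolerance 10⁻⁷
kcal/mol on the window constants, max 10⁵ iterations — none of these are
protocol facts, all are configurable). Two numerical choices matter:

* The Boltzmann factor of each window's bias is **averaged over each bin**
  with 5-point Gauss–Legendre quadrature rather than evaluated at the bin
  center. The solver then estimates the bin-averaged unbiased density,
  which is also what a quadrature reference computes; with center-point
  evaluation a systematic offset of ~0.01–0.03 k_BT per bin survives even
  at large sample counts.
* Interior bins with no samples are masked (NaN) with a warning; empty
  bins at the profile edges are trimmed. Samples outside an explicit
  `bin_range` are dropped with a logged count.

Profiles are anchored with their global minimum at zero and always
reported in kcal/mol; force constants declared in kJ/mol (the
proton-transfer protocol's 20000 kJ/mol/nm²) are converted on input and
the conversion logged. Repeat-based errors (`pmf_from_repeats`) solve
each independently seeded repeat on a common binning, align repeats by
their mean over jointly finite bins (the single anchor bin of one repeat
is itself noisy), and report the per-bin SD.

The solver's output is exactly invariant under window reordering and
under duplicating the entire window set, and the tests assert both.
Duplicating a *single* window is not an invariance of maximum-likelihood
WHAM — it doubles that window's weight and moves the fixed point by a
statistical-sized amount — so it is deliberately not asserted.

Unbinding free energy is the mean PMF over a user-chosen dissociated
plateau (at least three bins, excluded from containing the global
minimum); for the 1.8–3.3 nm pulling schedule the natural plateau is the
outermost windows. Barriers between two disjoint state ranges use the
maximum strictly between them, ties broken toward the bin nearest the
midpoint of the gap.

## Collective variables

The unbinding coordinate is the distance from the mass-weighted center of
five pocket Cα atoms (residues 9, 44, 64, 124, 162) to the peptide
N-terminal nitrogen, reported in nm. With no masses supplied an
equal-mass center is used (exact for an all-Cα selection) and flagged in
the debug log.

The CEC proton-transfer coordinate is the signed sum of three
donor/acceptor distance differences (His12 Nδ/its proton; bridging-water
oxygen/each water hydrogen against the Asp9 carboxylate oxygen). The
printed form of the coordinate does not parenthesise its distance
arguments; the grouping implemented here — three hydrogen-wise difference
pairs — is the only reading in which each term tracks one proton's
progress between a donor-side and an acceptor-side reference. The His
nitrogen is taken as Nδ (the solvent-facing nitrogen, the plausible exit
route for the proton at low pH). W:H1 vs W:H2 is fixed once per
trajectory by first-frame proximity to the Asp oxygen (tie → lower atom
index) so the series cannot jump from relabeling. Which numeric endpoint
of the 0.1 → −0.4 nm axis corresponds to the His- vs Asp-protonated
state is carried as metadata on the window schedule, not assumed by the
math.

## Water-network occupancy and RMSF

Hydrogen bonds are geometric: donor–acceptor ≤ 3.5 Å and donor–H–acceptor
deviation from linearity ≤ 30°, the community defaults; a distance-only
mode exists for hydrogen-free fixtures and for chain links with no
explicit hydrogen (the water→C-terminus link in the default chain). The
network statistic counts a frame only when every link of the
His12→W1→W2→C-terminus chain holds *and* both water oxygens are inside
the pocket region; waters are identity-tracked by role, matching the
crystallographic W1/W2 framing, rather than re-identified per frame.
RMSF is the per-atom root-mean-square deviation from the time-mean
position, optionally after least-squares superposition of each frame
onto the first.

## Structure comparison

PDB files are parsed with gemmi; alternate locations collapse to the
highest-occupancy conformer (tie → 'A'), waters are retained, residue
numbering is kept 1-based as deposited. Superposition is Kabsch via SVD
with a reflection guard (det = +1 enforced by flipping the smallest
singular direction). Atoms are paired by (mapped chain, residue number,
atom name); unmatched residues are dropped and reported, and the matched
count is returned beside the RMSD because published Cα counts rarely come
with a selection recipe — discrepancies should be visible, not silent.
B-factor aggregation defaults to the mean over all residue atoms, with a
max mode and a side-chain-only option, since the aggregation behind
published per-residue values is typically unstated.

## Assay statistics

Group effects are reported as bootstrap mean differences with percentile
95% CIs: resampling within group, with replacement, at the original group
sizes; 5000 resamples by default with a hard floor of 1000. The
percentile interval (rather than BCa) matches the plot semantics of
estimation-statistics figures; under extreme skew a percentile interval
can exclude the point estimate, in which case it is widened to include it
so the invariant `ci_low ≤ diff ≤ ci_high` always holds. Coverage on
Gaussian data is verified at 95% ± 3% over 500 simulated repetitions.

## What the synthetic generators emulate — and what they do not

The toy pocket reproduces the *shape* of grand-canonical titration data:
logistic per-site occupancy in B, an optional site–site coupling standing
in for the W1–W2 hydrogen bond, and a ligand that excludes the third
site. It does not model water–water energetics, protein flexibility or
any force field, so passing recovery tests demonstrates the correctness
of the estimators, not the realism of the energies. Umbrella samples are
exact draws (inverse-CDF on a fine, adaptively widened grid) from the
biased density of a stated 1D potential: WHAM results are therefore free
of autocorrelation and equilibration artifacts that real trajectories
carry. Network trajectories plant occupancy by construction (a seeded
permutation of bonded/broken frames; W2 displaced 6 Å out of the region
when broken) and RMSF by isotropic Gaussian displacement with per-axis
σ = a/√3; they contain no solvent exchange, so residence-time kinetics
are out of reach by design.

Problem sizes in the tests and the acceptance script (10⁴–10⁵ MC steps
per state point, 1.5×10⁵ samples per window, 500 bootstrap repetitions)
were chosen so each statistical assertion is comfortably powered while a
full run completes in well under a minute on one CPU.

## Known limitations

* The GCMC engine has no continuous-space moves with a protein
  environment; the optional translate weight exists only for the
  trajectory-producing continuous variant of the toys.
* WHAM is 1D; no MBAR generalisation, no 2D profiles, no
  replica-exchange bookkeeping.
* The CEC implementation covers the single-proton, single-bridging-water
  coordinate only — no multi-proton or Voronoi-weighted generalisations,
  and no quantum engine: only the coordinate, bias and profile analysis
  layer.
* Published structure-comparison numbers can only be recomputed when the
  deposited coordinate files are supplied locally; the package ships no
  download client.
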