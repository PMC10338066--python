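# Methods

## Scope and model

`rdcfit` treats a set of same-sequence protein conformers (crystal chains,
models of a multi-MODEL file, or synthetic fixtures) as a weighted
conformational ensemble and asks how well measured residual dipolar couplings
(RDCs) agree with it. The physical model is the standard rank-2 dipolar
interaction: a coupling for bond vector **u** under Saupe matrix **S** is
D = **u**ᵀ**S****u**, and fast exchange between conformers averages the
*interaction*, not the vector, so the ensemble prediction is
Σᵢ wᵢ **u**ᵢᵀ**S****u**ᵢ. All couplings are expressed on the amide N–H scale.

## Conventions and units

- **Saupe matrix**: 3×3 symmetric traceless, in Hz on the NH scale. Fit
  parameterization is the 5-vector (Sxx, Syy, Sxy, Sxz, Syz) with design rows
  [ux²−uz², uy²−uz², 2uxuy, 2uxuz, 2uyuz]; ensemble rows are weight-averaged
  quadratic terms, so a single-member fit is bitwise identical to a static fit.
- **Da, Rh**: eigenvalues ordered |λz| ≥ |λy| ≥ |λx|; Da = λz/2 (Hz, signed),
  Rh = 2(λx−λy)/(3λz). This ordering pins Rh into [0, 2/3] automatically. In
  the principal frame D(θ,φ) = Da[(3cos²θ−1) + (3/2)Rh sin²θ cos2φ].
  Orientation is reported as z-y-z Euler angles of the principal-axis frame
  (right-handed, det +1).
- **Q factor**: Q = rms(D_pred−D_meas)/sqrt(Da²(4+3Rh²)/5). The denominator
  is the rms of a coupling drawn from an isotropically distributed bond under
  the same tensor, which is what makes Q comparable across media. Q is
  undefined at Da = 0 and reported as NaN with a warning on the fit result.
  The square root covers the numerator rms and denominator separately (the
  "normalized rms deviation" reading); this is stated here because typeset
  versions of the formula are often ambiguous.
- **Per-type scaling**: default factors map each coupling type onto the NH
  scale as (γNγH/r³NH)/(γAγB/r³AB) with standard distances (N–H 1.02 Å,
  Cα–Hα 1.09 Å, C′–N 1.329 Å, C′–Cα 1.525 Å, two-bond C′–H 2.05 Å). The
  factors are *signed* — the γ products carry sign — which is what allows one
  tensor to fit several coupling types jointly. Literature often quotes
  magnitude factors calibrated on real data (e.g. ≈3.09 for two-bond C′–H,
  which also absorbs small alignment-strength differences between
  experiments); such values can be supplied as literal overrides and take
  precedence.

## Structure preparation

Coordinates are read with gemmi (PDB, mmCIF, gzipped accepted). One conformer
is produced per matching chain and per model; author residue numbering is
retained and residues are matched across members by number + name (name
mismatches are excluded with a warning). Alternate locations resolve to the
highest-occupancy copy, ties to altloc 'A'. Entries whose recorded resolution
exceeds the cutoff are dropped; entries without a recorded resolution are
kept.

Missing amide hydrogens are built in the C′(i−1)–N(i)–Cα(i) plane, opposite
the bisector of the C′→N and Cα→N directions, 1.02 Å from N. The N–H distance
does not affect RDC directions; it is fixed for reproducibility. Prolines,
chain-initial residues and residues without a preceding carbonyl are skipped;
experimentally present hydrogens are never moved.

Superposition uses the Kabsch algorithm on Cα atoms of a residue interval
minus an exclusion set, with proper rotations enforced (det +1; reflections
are never returned). The reference is member 1 by default; a two-pass mode
re-fits to the unweighted mean structure. Rank-deficient (collinear)
selections and selections of fewer than 3 shared Cα raise errors rather than
returning a degenerate frame.

## Order parameters and disorder diagnostics

The "ensemble-averaged orientation" of a bond is the renormalized weighted
mean vector. This matches the notion of a single averaged orientation per
bond and keeps the excursion angle β well-defined; the principal axis of
⟨uuᵀ⟩ is a defensible alternative but differs only at large amplitudes, where
the mean-vector convention is the one the excursion-angle definition of S
assumes. Residues whose mean vector has zero norm (antipodal members) are
flagged undefined and excluded from ranking. S from excursions satisfies
−0.5 ≤ S ≤ 1; both S and S² are always emitted, since relaxation experiments
report S².

Disorder ranking uses rms β (configurable to 1−S; the two orderings agree
except for exotic bimodal cases). The ranked list splits at the median into
H50%/L50%; ties break by residue number (lower → L50%), and with an odd count
the extra residue goes to L50%. Separate tensor fits to the two halves give
the Da(H50)/Da(L50) consistency ratio: a rigid ensemble scoring its own
noiseless couplings yields exactly 1, and exaggerating the motional
amplitudes of the mobile half inflates the ratio above 1 (the fit compensates
for over-averaged vectors by scaling up the tensor).

The averaged-orientation comparison model replaces each bond by its
renormalized mean vector and refits. On data generated by ensemble averaging,
the ensemble fit can match the generator exactly while the averaged model
cannot, so Q(ensemble) ≤ Q(averaged) on such fixtures; the gap grows with
motional amplitude and vanishes for rigid ensembles. This comparison is what
distinguishes "the ensemble's distribution matters" from "averaging many
structures cancels coordinate noise".

## Sparse weight optimization

The objective for region [P, R] is

    F(w) = sqrt(Σⱼ (Σᵢ wᵢ Dᵢⱼ − Dⱼ)²/n) / sqrt(Da²(4+3Rh²)/5) − C·Σᵢ(wᵢ+ε)²

with ε = 10⁻⁴ and Da/Rh frozen from a tensor fit that excludes the region (or
from a fixed reference structure; both sources are supported). The misfit
term is exactly the regional Q of the weighted prediction, tying the module
to the scoring used everywhere else. The penalty is *subtracted*: Σ(wᵢ+ε)² is
maximal at a simplex vertex, so minimizing F rewards concentrating weight on
few members. An alternative reading that weights each member's own misfit,
Σᵢ wᵢ(Dᵢⱼ−Dⱼ)², is available behind `per_member_misfit=True`; it corresponds
to slow-exchange averaging of squared deviations and is not the default
because the observable being fit is the averaged coupling.

Minimization runs Metropolis simulated annealing with pairwise weight
transfers (move δ ~ U(0, 0.2)·T/T0 from member i to j, clamped at 0), which
preserves the simplex exactly at every step. Defaults: T0 = 10× the F spread
over 100 random simplex points, geometric cooling 0.95, 200 moves per
temperature, T_min = 10⁻⁴·T0. Because the transfer amplitude shrinks with
temperature, the stochastic phase ends diffuse; a deterministic greedy
pairwise-transfer descent (transfer sizes 0.2 → 10⁻⁴, sweeping all pairs until
no improvement) finishes the search from the annealed point. The misfit term
is quadratic in w, so this coordinate descent converges to the basin optimum;
on well-conditioned recovery problems the result matches the non-negative
least-squares optimum to ~10⁻³ in each weight. An exhaustive simplex-grid
search (default resolution 0.01) serves as an independent oracle for N ≤ 4.
All randomness flows from a single integer seed; identical seeds give
bitwise-identical solutions.

"Member of the minimal ensemble" means weight > 0.01 (configurable). The C
scan anneals at each grid value (ascending) and reports the largest C whose
regional rms misfit stays within the supplied noise estimate σ̄, plus the full
trade-off curve. σ̄ is a caller decision: the acceptance script passes the
generator noise with a 2-sigma χ² allowance, σ·sqrt(1 + 2·sqrt(2/n)), because
the realized rms of n noisy records fluctuates about σ and a bound at exactly
σ would reject the true solution for a sizable fraction of noise draws.

Cross-validation freezes all tensor parameters, refits weights on a random
train split, and evaluates the free Q on the held-out records; repeats use
disjoint sub-seeds. Free Q far above training Q flags overfitting (e.g. many
members against few couplings).

## Synthetic data

The generators are pure functions of (spec, seed) and define the test
conditions for the whole package. Defaults: Da = 10 Hz, Rh = 0.3 (a typical
phage/gel alignment for a mid-size protein on the NH scale), Gaussian noise
0.2 Hz = 2% of Da (the precision regime of good backbone amide measurements),
10 members, rigid bonds unless a residue is given cone wobble (uniform over
the cone's solid angle, semi-angle θ0, analytic S = cosθ0(1+cosθ0)/2),
two-state jumps (deterministic population split), or fully scattered
per-member orientations emulating discrete conformers.

PDB fixtures place each residue as an internally rigid, idealized peptide
unit on a regular lattice (6 Å spacing), oriented so the N→H vector equals
the requested one, with CA/C/O completing the unit; units are intentionally
not bonded into a chain, since exact realization of arbitrary N–H directions
is incompatible with chain closure. The fixtures therefore exercise parsing,
hydrogen handling, vector extraction, superposition and fitting — not
protein-like backbone topology.

What passing on these fixtures does **not** show: robustness to real
crystallographic pathologies (missing density, correlated coordinate errors,
lattice-contact distortions, per-entry refinement biases), to imperfect
residue correspondence across homologous entries, or to alignment-medium
effects (the generator assumes one exact tensor per medium). Real
superensembles also violate the generators' independence assumptions —
crystal structures cluster by space group and ligation state.

## Numerical choices and edge cases

- Least squares via `numpy.linalg.lstsq`; the design-matrix condition number
  is reported, with an `IllConditionedWarning` above 10⁶.
- Fits require ≥5 usable records; fewer raise an under-determined error.
- A zero fitted tensor (all-zero measurements) reports Da = 0 and Q = NaN.
- Records lacking a vector in any ensemble member are dropped, mirroring the
  common-residue policy of vector extraction; media are always fit with
  independent tensors, and multi-medium scores are reported per medium plus
  the rms over media.
- β is computed after global superposition of the ensemble (a local,
  per-region superposition can be emulated by superposing on the region of
  interest before extracting vectors).
- arccos arguments are clipped to [−1, 1]; unit-vector invariants are enforced
  to 1e-9 at container construction.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic data at
desk scale: ≤100 residues, ≤50-member ensembles for fitting and diagnostics,
10⁴-member ensembles only for Monte-Carlo order-parameter checks, and
annealing problems of ≤50 members × ≤30 records. These sizes make every check
exact or statistically sharp while keeping the full suite under a minute of
compute, and they are the regime the method targets (local regions, tens of
candidate conformers). Production-scale optimization of hundreds of weights
with convergence guarantees is explicitly out of scope.

## Known limitations

- No sequence alignment across homologs: residues correspond by number+name.
- No steric/electrostatic prediction of alignment tensors from molecular
  shape; tensors always come from fits to data.
- No side-chain protons beyond Hα; no dynamic corrections to effective r³;
  no conversion of S to relaxation observables (the systematic ~0.1 offset
  between ensemble-derived S² and relaxation-derived S² expected from fast
  N–H librations is a known feature of comparing the two, not computed here).
- The annealer is a local stochastic search with a deterministic polish; for
  N ≤ 4 it is verified against exhaustive search, for larger N against
  recovery of known generating weights, but global optimality is not
  guaranteed in general.
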