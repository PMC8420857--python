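# Methods

This note records the models, algorithms and numerical choices behind
`cd2struct`, and what the synthetic test bed does and does not demonstrate.

## Problem setting

Circular dichroism (CD) spectroscopy, and in particular synchrotron
vacuum-UV CD reaching below 190 nm, carries enough information to estimate
the secondary-structure composition of a protein in solution. The pipeline
implemented here goes from a measured spectrum to a per-residue structure
string in four steps:

1. **Unit handling** — raw ellipticity θ (millidegrees) is converted to the
   molar circular dichroism per mean residue,
   Δε = θ·MRW / (32980 · l · c) (M⁻¹ cm⁻¹), where l is the cell path length
   (cm), c the protein concentration (mg/mL) and MRW the mean residue weight
   (g/mol). The constant folds the mean-residue-ellipticity convention
   [θ] = θ·MRW/(10·l·c) with Δε = [θ]/3298. Concentration can be derived
   from A280 via the E 1 % convention: c = 10·A280/(E1%·l).
2. **Deconvolution** — a self-consistent SVD method estimates six fraction
   classes: ordered/distorted α-helix, ordered/distorted β-strand, turn, and
   unordered.
3. **Segment counts** — distorted fractions convert to segment numbers:
   N_helix = round(h_d·N_res/4), N_strand = round(s_d·N_res/2), because a
   helix carries ≈4 distorted (terminal) residues and a strand ≈2. Rounding
   is half-away-from-zero; the convention at exact .5 is a documented choice
   the published integer tables cannot discriminate.
4. **Positional assignment** — per-residue helix/strand scores are combined
   with the residue- and segment-count targets from steps 2–3 to produce an
   H/E/C string.

## Self-consistent deconvolution

Let C be the (wavelengths × proteins) matrix of reference spectra and F the
(6 × proteins) matrix of their known fractions. The query spectrum q is
prepended to C and the current guess of its fractions to F. From the SVD
C = U S Vᵀ, each truncation order k = 1..K yields a candidate

    f_k = F V_k S_k⁻¹ U_kᵀ q,      K = min(k_max, n_proteins+1, rank),

with singular values below 1e-10·s₁ treated as rank-deficient. Four
selection rules screen candidates: sum of fractions in 1 ± `tol_sum`
(default 0.05); every fraction ≥ −0.025; RMSD between the rank-k
reconstruction of q and q itself ≤ `fit_max` (0.25 Δε); helix total within
`helix_tol` (0.03) of the highest-order solution. The guess is replaced by
the mean of surviving candidates (falling back to the highest-order
solution when none survives) and the loop repeats until the guess moves by
less than `tol_sc` (1e-3) in any class.

Numerical choices:

* the update is damped (guess ← ½(guess + new)); feeding back the raw
  top-order solution lets the solution scale drift until the sum rule
  rejects every order,
* a candidate order sitting exactly on a rule boundary can flip in and out
  of the survivor set, producing a period-2 limit cycle rather than a fixed
  point; a detected two-cycle is resolved to its midpoint, followed by one
  final selection pass,
* the averaged survivor solution is cleaned up (negatives clipped, vector
  renormalized to sum 1) only at the very end, so the small-negative floor
  stays observable to the fraction rule,
* the initial guess is the fractions of the nearest reference spectrum by
  RMSD (ties to the lower index),
* the analysis range defaults to 175–240 nm on a 1 nm grid, intersected
  with the available data; at least 40 nm of overlap is required.

No solution surviving the rules is reported as an explicit error carrying
per-rule rejection counts (a flat zero spectrum fails the sum rule at every
order, pinned by a regression test). In leave-one-out evaluation such
members are skipped with a warning, as is standard for reference-set
self-checks; δ is the RMSD pooled over all (protein, class) pairs and r the
Pearson correlation over the same pairs, one scalar each. The 5 % spectral
error typical of the measurement is **not** propagated into fraction
uncertainties; users should treat fraction differences of a point or two as
within method error.

## Constrained assignment

The discrepancy between a labeling and the targets is

    D = |n_H − t_H| + |n_E − t_E| + λ·(|seg_H − t_sH| + |seg_E − t_sE|),

with λ = 1 by default (one segment mismatch weighs like one residue
mismatch). Phase 1 labels residues greedily in descending score order until
the residue targets are met; a residue claimed by both classes goes to the
higher score (exact ties to helix, then to the lower index).

Phase 2 exploits the fact that D depends on the labeling only through the
tuple (n_H, seg_H, n_E, seg_E). A tuple is realizable on a chain of n
residues iff each segment count is positive exactly when its residue count
is, no segment count exceeds its residue count, and
n_H + n_E + max(0, |seg_H − seg_E| − 1) ≤ n (the last term counts the
single-C separators needed once alternation between the two classes is
exhausted). The minimum of D over realizable tuples is found exactly — the
residue subproblem at fixed segment counts has a closed form, and segment
counts are enumerated — and a labeling with the optimal tuple is
constructed: segment sizes split as evenly as possible, majority-class
segments interleaved with minority-class ones, then score-improving
one-position shifts (deterministic, capped by `max_polish`). If the phase-1
labeling already attains the optimum it is returned unchanged, which is what
makes a clean, high-margin profile recover its planted labeling exactly.
The output is therefore globally optimal in D: realizable targets are met
exactly, unrealizable ones yield the minimal-difference compromise. When
the profile carries little signal (e.g. bare single-residue propensities on
a random sequence), many labelings tie near the optimum and the constructed
layout is left-leaning; positions are then driven by the constraints, not
the sequence.

Comparison utilities report 1-based positions, optionally shifted by a tag
offset so a fusion construct can be read in the numbering of the untagged
protein (offset 129 maps construct position 219 to protein residue 90).

## Propensity providers

The assignment stage consumes arbitrary real scores; only ranks matter, so
no normalization is imposed. The bundled provider applies a centered moving
average (default window 5, shrinking at the chain ends) to Chou–Fasman
helix/strand propensities — a deliberately simple, clearly labeled stand-in
for profile-based predictors, useful for exercising the machinery, not for
state-of-the-art accuracy. Externally computed per-residue scores in the
common `.ss2` layout (index, residue, label, C/H/E columns) are read and
cross-checked against the FASTA sequence.

## Synthetic data

The generators produce the full input universe for testing:

* **Basis curves** — one sum-of-Gaussians curve per fraction class with
  literature-standard band positions (helix: +192/−208/−222 nm; strand:
  +197/−216 nm; unordered: −198 nm; weak turn features). Amplitudes are in
  plausible Δε ranges and the six curves are linearly independent.
* **Reference sets** — fraction vectors drawn from three Dirichlet
  archetypes (helix-rich, strand-rich, mixed) over the four observable
  totals; distorted sub-fractions are fixed shares of the class totals
  (40 % of helix, 45 % of strand, config-exposed). Spectra are
  fraction-weighted basis sums plus white noise expressed as a fraction of
  each member's peak |Δε| (default 2 %). Chain lengths are uniform on
  80–350 residues. Defaults: 30 members, matching the size of real VUVCD
  reference databases.
* **Planted profiles** — in-class residues score base + margin + noise,
  out-of-class residues base + noise, so recovery difficulty is controlled
  by margin/noise.

What passing tests show — and do not. Because the fixed distorted shares
put every reference fraction vector on a rank-4 manifold, the deconvolution
can only identify compositions that manifold spans; synthetic queries are
therefore drawn from the same distribution. The same caveat applies to real
reference databases: a query protein whose composition lies far outside the
database's span (e.g. an intrinsically disordered protein against a
globular-protein basis) is not identifiable, however good the fit. The
Gaussian bands also make the linear mixing model exact, so synthetic
leave-one-out δ (≈0.005 at 2 % noise, bounded at 0.06 in the acceptance
tests) is flattering relative to the ≈0.06 achieved by real databases,
where band shapes themselves vary between proteins. Recovered accuracy on
synthetic data demonstrates correctness of the algorithms, not expected
accuracy on measurements.

## Problem sizes and determinism

Test and acceptance runs use 30-member reference sets, 20 recovery seeds,
200 random small-chain assignment instances checked against a full 3ⁿ
enumeration (n ≤ 12), and 100 feasibility instances — sizes chosen so the
whole suite runs in well under a minute on one CPU while exercising every
guarantee. Every stochastic component takes an explicit seed and the
end-to-end pipeline is a pure function of (inputs, config, seed); reruns
are byte-identical.

## Known limitations

* Six classes are fixed; no CONTIN/CDSSTR-style variants and no
  IDP-specific reference handling.
* Thresholds default to literature-standard values; a different reference
  database may warrant retuning via the config surface.
* The bundled propensity table is not a trained predictor; positional
  accuracy inherits the quality of whatever scores are supplied.
* Measurement-error propagation into fraction uncertainties is not
  modeled.
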