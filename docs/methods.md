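# Methods

## Observable model

All quantitative analysis rests on the fast-exchange approximation: a
residue's amide cross peak sits at the population-weighted average of its
free and bound positions, so its combined chemical-shift perturbation

    CSP = sqrt(Δδ_H² + (α·Δδ_N)²)

grows as Δδ_max·θ, with θ the equilibrium occupancy of the site the residue
reports on. The ¹⁵N weighting α defaults to 0.14 (the community standard
that rescales the wider ¹⁵N dispersion onto the ¹H scale; 0.20 is
conventional for glycine and available as an option). Residues whose
intensity collapses during the titration (ratio to the free state below
0.3 at any point) are in intermediate exchange — their apparent shifts are
not population averages — and are flagged and excluded from fitting;
residues whose peaks vanish entirely are flagged lost. Missing intensity
data degrades gracefully: everything is treated as fast exchange, with a
warning.

## Equilibria

Binding models are parameterized by dissociation constants in mol/L.
Stepwise constants of the sequential two-site model are **macroscopic**
concentration quotients (K_d1 = [P][L]/[PL], K_d2 = [PL][L]/[PL₂]); the
identical-sites model carries one **microscopic** per-site constant, so
"K_d = 4.5 μM" reads "both sites at this affinity". The two conventions
meet at the statistical-factor identity: two identical independent sites
of microscopic k are exactly the sequential model (k/2, 2k), which the
test suite asserts as an oracle identity. K_d2/K_d1 = 4 therefore marks
the non-cooperative baseline and larger ratios negative cooperativity.

Free-ligand concentrations come from the scalar mass balance
L + bound(L) = L_tot. Since bound(L) is monotone the root in [0, L_tot] is
unique; it is found by bracketed bisection (100 halvings, i.e. far beyond
1e-12 relative), vectorized across titration points. One uniform code
path serves every model — no closed-form quadratic shortcuts — which keeps
tolerances and behaviour identical across families and mixtures.
Activity coefficients are ignored (sub-mM regime). Site-filling
convention: site 1 is the high-affinity, first-filling site (the
M416–M419-type cluster in the SilB-p geometry), site 2 the weaker
R405–H408-type cluster whose occupancy f_PL2 is what produces the observed
sigmoidal titration curve.

## Global fitting

The fit minimizes Σ[(CSP_obs − Δδ_max,r·θ_s(r))/σ]² over the shared log₁₀
dissociation constants and per-residue amplitudes. Design choices:

* **Log-space constants with bounds** (default 1e-9…1e-1 M): the
  affinities of interest span 4–571 μM; linear-space optimization stalls.
* **Variable projection**: for fixed constants the amplitudes are linear
  and solved in closed form per residue (clamped at zero), so the
  nonlinear search is 1–2 dimensional. The projected functional has the
  same minimizers as the joint problem and is far better conditioned.
* **Multistart** (default 10) from log-uniform draws of the constants,
  seeded; ties within 1e-10 in χ² resolve to the lowest first constant.
* **Noise scale** σ = 0.003 ppm combined-CSP units by default,
  overridable; it matches the default generator noise
  (σ_H = 0.002 ppm, σ_N = 0.02 ppm combine to ≈ 0.0034 via α = 0.14).
* **Uncertainties both ways**: Gauss-Newton covariance SEs at the optimum
  (scaled by reduced χ²) and residual-resampling bootstrap percentile
  intervals (default 200 refits warm-started from the optimum), because
  the convention behind a published "±" is rarely stated.
* **AICc** = χ² + 2k + 2k(k+1)/(n−k−1) with k = constants + amplitudes and
  n the number of beyond-free-state residuals; candidates with n ≤ k+1 are
  unrankable. For model selection all candidates are restricted to one
  shared residue set (the two strongest CSP clusters) so their likelihoods
  are comparable.

Significance of a residue's response uses mean + k·SD (k = 1) of the
final-point CSPs over fast-exchange residues with one trimming round;
clusters are maximal runs of significant residues tolerating one-residue
gaps. The assignment of clusters to sequential sites is data-driven: the
cluster whose mean normalized curve crosses half-saturation at the lower
molar ratio is site 1.

Stoichiometry is estimated per residue as the breakpoint of a continuous
two-segment fit y = s·min(ratio, b) (rising limb through the origin plus
plateau), median across residues; residues whose final slope exceeds 10%
of their initial slope have not saturated and are excluded. The estimate
is meaningful only in the tight-binding regime (P_tot ≫ K_d); visible
corner rounding triggers a warning.

## Competition replay

Assay protocols are sequences of ligand/receptor additions with
concentrations on a post-mixing basis. After each step the full mixture
equilibrium is re-solved, so the replay is purely thermodynamic and
path-independent by construction. Displacement is summarized per site by
the shift-back fraction (relative occupancy loss when the competitor is
added) and the recovery ratio (final vs pre-competitor occupancy).

A known limitation follows directly: at the fitted constants the SilB-type
first site (stepwise 4 μM) and the SilE-type sites (microscopic 4.5 μM,
i.e. first-event 2.25 μM) are nearly equal in affinity, so the equilibrium
model necessarily lets the competitor strip a substantial part of the
first site — whereas the experiments show that site essentially immobile.
The replay reports the model's prediction; reconciling this ordering would
need kinetics or interactions outside a thermodynamic mixture model, and
one acceptance check records the discrepancy rather than hiding it. The
weak-site behaviour (nearly complete displacement, recovery at high
ligand) is reproduced.

## Synthetic data

The generator emulates the study design: an 11-residue peptide at 1 mM
(identical-two-site truth, ratios 0–4 in 13 points), a 30-residue peptide
at 0.92 mM (sequential truth, ratios 0–8 in 13 points with denser sampling
below 2 equivalents, where the first site titrates), two ~15-residue
fragments at 1 mM (one-site truths; the fragment concentration is not
printed in the source study, so the same ~1 mM regime was adopted), and an
equimolar 0.88 mM mixture for competition assays. Free-state shifts are
uniform in the random-coil amide window (¹H 7.6–8.8, ¹⁵N 105–130 ppm);
site residues get combined amplitudes log-uniform in 0.02–0.25 ppm split
into ¹H/¹⁵N components of random direction, background residues 0–0.005
ppm; shift noise is Gaussian (σ_H = 0.002, σ_N = 0.02 ppm — typical HSQC
precision, no figure is printed in the source). Intermediate-exchange
residues get a phenomenological Lorentzian-like intensity attenuation
bottoming at 0.05 near half-saturation of their site — it exists to
exercise the flagging logic and is never fitted. Everything derives from
one integer seed.

What the generator does **not** emulate: peak overlap and crowding,
baseline/phasing artifacts, lineshape changes short of the intermediate-
exchange flags, concentration errors between points, and any structural
response (helicity) of the bound state. Passing recovery tests therefore
demonstrate the statistical machinery under the stated noise model, not
robustness to every pathology of real spectra.

## Problem sizes

Recovery studies use 50 independent noise realizations per condition and
report medians — per-realization estimates in the tight-binding regime
(K_d/P_tot < 0.01) scatter widely by design, since the data only weakly
identify constants far below the receptor concentration; the median is
the honest summary. Model-selection rates use 100 replicates per
direction with 4 multistarts per fit; bootstrap coverage uses 100
datasets × 200 refits on a one-site design.

## Numerical conventions

Bisection depth 100 (deterministic cost, bracket ~1e-30 relative);
fit tolerances xtol = ftol = gtol = 1e-12; bootstrap refits 1e-10;
breakpoint search: 201-point grid scan refined by bounded scalar
minimization to 1e-10. Degenerate inputs: an empty peak list parses with
a warning; ¹⁵N shifts outside 90–140 ppm warn but load; fewer than four
residues make the significance threshold undefined (error); a sequential
fit with an empty site is a specification error; θ_before = 0 makes
displacement metrics undefined (reported as missing, not zero).
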