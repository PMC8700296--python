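# Methods

## The two-state activation model

The model treats a receptor's transmembrane domain as equilibrating between
one inactive (R) and one active (R\*) conformation. Constitutive activity is
the unitless ratio α = [R]/[R\*] at rest, so the basal active fraction is
1/(1+α): α = 0 is a fully active receptor, α = 100 a nearly silent one. An
allosteric ligand A occupies a single modulator site with dissociation
constant K_inact on the inactive state and K_act = K_inact/β on the active
state; β = K_inact/K_act is the state-selectivity ratio. With ligand in
excess (free ≈ total concentration) the four species R, R\*, AR, AR\* obey
mass action, giving the closed-form active fraction

    f(c) = (1 + βc) / (1 + α + c(β + α)),   c = [A] / K_inact,

which runs from 1/(1+α) at c = 0 to β/(α+β) at saturation, with midpoint
concentration (1+α)·K_inact/(β+α). The difference of the two plateaus — the
*agonism window* — is the model-level intrinsic agonist activity of the
ligand. Its two limits carry the model's whole message: the window is zero
exactly at β = 1 (a neutral ligand cannot shift an equilibrium), and it
decays to zero as α → ∞ at fixed β (with almost no spontaneously active
receptor, state-selective binding has nothing to amplify). As a function of
α it is unimodal with its maximum at α = √β; in the suppressed-activity
regime α > √β, lowering constitutive activity lowers the window, which is
the predicted — and panel-observed — positive correlation between basal
activity and ago-PAM agonism.

Deliberate simplifications: one modulator site, exactly two conformations,
no extracellular-domain species (their influence is absorbed into α), and a
readout that is affine in the active fraction (`signal_floor +
signal_span·f`), i.e. no receptor-reserve or amplification stage. With
amplification, a transient readout can hide a small window that an
accumulating readout still shows; that distinction is handled downstream by
the profile classifier (below), not inside the model. Orthosteric
potentiation (PAM + agonist cooperativity) is outside the model's scope and
is simulated phenomenologically (below). Closed-form evaluation switches to
the saturating limit above c = 10⁹ to avoid pointless extreme-ratio
arithmetic.

## Dose–response fitting

Curves are fitted in the log10-concentration domain to

    Y = Bottom + (Top − Bottom) / (1 + 10^((LogEC50 − X)·Hill)),

all four parameters free, by least squares (Levenberg–Marquardt) from a
deterministic 3×3 start grid: LogEC50 at the data range's ends and middle,
Hill at −1, 1, 2, plateaus seeded at the response extremes. The best start
wins by lowest residual sum of squares, ties by lowest |Hill|. The 4PL is
exactly invariant under (Bottom, Top, Hill) → (Top, Bottom, −Hill); fits are
reported in the canonical orientation Top ≥ Bottom, so Top is always the
upper plateau and doubles as Emax, and a descending curve shows as
Hill < 0. Zero-dose rows (log10 undefined) are excluded from fitting.
Standard errors come from the Gauss–Newton covariance at the optimum. A fit
is "converged" only if the optimizer succeeded *and* LogEC50 lies within the
fitted concentration range ± 2 log units; midpoints that escape the data are
reported but flagged untrusted. Zero response variance or fewer than two
distinct concentrations raise a degenerate-fit error.

Derived quantities:

* EC_p = 10^(LogEC50 + log10(p/(1−p))/Hill), the concentration reaching
  Bottom + p·(Top−Bottom); EC20 (p = 0.2) is EC50/4 at Hill = 1. The form is
  valid for negative Hill as well.
* Percent normalization divides by the *mean* of the designated reference
  replicates and multiplies by 100, so the reference maps to 100; figure
  conventions of this kind use a single reference response scale, and the
  mean is the natural estimator of it.
* Kinetic endpoints subtract the mean of all samples strictly before the
  stimulus time (the baseline window is otherwise unspecified in common
  practice) from the linearly interpolated signal at stimulus + delay.
* Potentiation is summarized as EC50(without)/EC50(with) — > 1 means a left
  shift — and Top(with)/Top(without).

## Panel statistics

Construct endpoints are normalized so the wild-type mean is exactly 100;
SEMs scale identically. The basal-vs-agonism association is a Pearson
correlation with a Fisher-z 95% CI (degenerate at |r| = 1 or n = 3). The
many-to-one contract is one-way ANOVA followed by Dunnett's test against the
wild-type group (scipy's exact multivariate-t implementation, seeded;
adjusted p-values therefore carry ~10⁻⁴-level quasi-Monte-Carlo integration
noise, which never moves a significance decision in practice). Significance
tiers follow the star convention p < 0.05 / 0.005 / 0.0005 / 0.0001 — tier
labels are reporting metadata, not effect sizes. Constructs expressed below
20% of wild type (configurable) are flagged, never dropped, since low
expression confounds interpretation but is itself a result.

The modulator-profile classifier operationalizes the qualitative ago-PAM /
pure-PAM distinction: a compound is an ago-PAM if its response exceeds
vehicle (one-sided Dunnett-adjusted p < 0.05) in *every* supplied assay,
pure-PAM-like if only in the equilibrium (accumulating, IP1-type) assays —
weak intrinsic efficacy that integration amplifies — and inactive otherwise.

## Grid volumetrics

All volumes are counted on a regular Cartesian grid of spacing h (default
0.5 Å) as N·h³.

*Molecular (vdW) volume*: grid points strictly inside at least one atomic
van-der-Waals sphere, overlaps counted once. Radii are the Bondi set
(fallback 1.7 Å with a warning for unknown elements). The single-sphere
discretization error is ~2% at h = r/8. Two conventions exist for ligands:
all-atom (explicit hydrogens, the API default) and heavy-atom (crystal-pose
convention — deposited structures carry no hydrogens, so published volumes
computed from them are heavy-atom unions). The package's reference values
for the two PAM chemotypes use the heavy-atom convention; the all-atom
volumes run ~15–18% larger. Conformers are embedded from SMILES with ETKDG
at a fixed seed and MMFF94-minimized; file-supplied (SDF) coordinates are
used as-is.

*Pocket volume*: the site-point procedure. A grid point is a cavity point if
it is (a) outside every protein atom's vdW sphere, (b) inside a focus sphere
around the ligand centroid, and (c) buried — at least 2/3 of 26 rays
(cube-neighbour directions) cast from it hit protein within the site-opening
distance (default 8 Å). Rays are marched in steps of h/2; a sample hits when
it falls inside the vdW sphere of its nearest protein atom (nearest-atom
test; exact for uniform radii, a ≤0.1 Å approximation otherwise). Cavity
points within the cutoff (default 4.5 Å, strict "less than") of any atom of
any supplied ligand are retained; pocket volume is their count × h³. The
procedure this replaces ran in proprietary software whose site-point
definition is not public; only the grid spacing, site opening, and proximity
cutoff are shared, so agreement on real receptor pockets is approximate by
construction, and the hollow-shell fixture (analytic interior volume,
recovered within 5%) is the method's controlled validation.

*Superposition*: Kabsch via SVD on shared Cα atoms matched by (chain,
residue number), with the smallest singular direction flipped when needed so
the rotation determinant is +1 — a reflection is never returned even when it
would fit better. Fewer than three pairs, or a collinear selection, raises a
geometry error rather than returning an underdetermined rotation.

## Synthetic data: what it emulates, what it does not

The panel generator forward-simulates the two-state model per construct and
perturbs responses with multiplicative log-normal noise (unit mean, chosen
because assay noise scales with signal), at a default CV of 5% and 5
replicates. Default conditions: wild-type α = 9, putting basal signalling at
10% of the readout span — a receptor with clear but non-saturating
constitutive activity; mutant α multipliers 0.6–25×, mimicking a panel
dominated by constitutive-activity-suppressing mutations plus one mild
enhancer; ago-PAM β = 10 with K_inact = 10 µM. β = 10 places the panel in
the α > √β regime where basal activity and agonism window co-vary strongly
(model-level Pearson r ≈ 0.96 for this panel); far larger β would bend the
relationship until the linear correlation degrades, which is a real property
of the model, not of the assay. The intrinsic-agonism endpoint is the
saturating PAM response minus the construct's mean basal.

Potentiation families are generated *phenomenologically* — the agonist
curve's LogEC50 shifts left by (max shift)·(modulator occupancy) and its Top
scales likewise — deliberately decoupled from the two-state model so that
fit-recovery tests do not validate the model with its own output. Kinetic
traces are baseline-then-exponential with additive Gaussian noise. Geometry
fixtures provide a hollow-shell pseudo-protein (two dense Fibonacci-lattice
layers; inner vdW surface at radius 4 Å, so the cavity volume is exactly
(4/3)π·4³ ≈ 268.1 Å³), a rigid 5-atom pseudo-ligand, and an exactly known
rigid motion of it.

Not emulated: day-to-day (hierarchical) variance structure, plate effects,
readout-specific mechanics (HTRF ratios, fluorescence kinetics), receptor
expression entering the signal, and real protein surface texture. Passing
tests therefore demonstrate correctness of the estimators and procedures
under a clean noise model, not robustness to every real-world artifact.

## Numerical choices and problem sizes

Model-vs-equilibrium agreement is checked on 1,000 random parameter draws
against an independent numerical solve of the four-species system (equations
rescaled to O(1); agreement to 10⁻⁹ relative, observed ~10⁻¹⁴). 4PL recovery
uses 100 Monte-Carlo seeds at 5% CV and 3 replicates (median |ΔlogEC50|
≈ 0.02, documented bound 0.1). The Dunnett family-wise error is estimated on
2,000 simulated null panels of 6 groups × 5 replicates (observed ≈ 0.051
against the nominal 0.05 ± 0.02 band). Cavity detection on the shell fixture
uses a 0.5 Å grid and a 6 Å focus radius. All generators and the test suite
derive randomness from fixed or CLI-provided seeds.

## Known limitations

* The two-state model is an equilibrium description; kinetic experiments
  (association/dissociation of modulators) are outside its scope.
* The pocket method's agreement with proprietary cavity detectors on real
  receptors is approximate and unbounded a priori; treat real-structure
  pocket volumes as reproducible-by-convention numbers, not ground truth.
* EC_p extraction assumes a converged, non-flat fit; it extrapolates poorly
  when p lies far outside the observed response range.
* The profile classifier inherits the power of the underlying comparisons:
  with few replicates, "inactive" may simply mean "underpowered".
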