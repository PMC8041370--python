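# Methods

## Scope and model

The package implements the statistical and arithmetic layer of an
NMR-based configurational assignment, together with the mass-spectrometric
and SPR bookkeeping that accompanies a natural-product isolation study.
The quantum-chemistry stages that normally feed it — conformational
searching, DFT geometry optimisation, GIAO shielding calculation — are
external: the package consumes their outputs (multi-frame XYZ geometries
with relative energies, per-atom isotropic shieldings) or substitutes
them with its synthetic generator.

### Shift prediction and ranking

For a candidate diastereomer with conformers *i*, populations are
Boltzmann weights w_i = exp(−(E_i − E_min)/RT)/Σ_j exp(−(E_j − E_min)/RT)
with R = 8.314462618 J mol⁻¹ K⁻¹ and T = 298.15 K by default (the
temperature of the shielding calculation is rarely reported with the
ensemble; it is configurable per `Ensemble`).  Shieldings are referenced
against TMS computed at the same level of theory, δ = σ_TMS − σ.  An
optional per-nucleus linear scaling δ = (intercept − σ)/(−slope) is
provided but off by default: direct TMS referencing is the simplest
defensible reading of "scaled to TMS", and the choice only shifts/scales
all candidates identically, so it cannot change a ranking.

Referencing and Boltzmann weighting are both affine, so they commute;
the implementation averages shieldings first and references once, and a
property test checks the commutation.

Before comparison, magnetically equivalent sets (methyl protons) are
collapsed to their unweighted arithmetic mean — free methyl rotation
makes the three protons one resonance — and the collapsed row takes the
group label, which is also how the experimental tables index such
resonances.  sp² **carbons** are excluded from the ¹³C comparison;
protons attached to sp² carbons are retained in the ¹H comparison (the
exclusion rule names carbon atoms only; retaining olefinic protons is the
conservative reading, and the synthetic studies show the ¹H channel is
secondary anyway).  A methyl counts as one entry of n, not three,
matching the single experimental resonance.

MAE = Σ(Δδ)/n is computed separately per nucleus and candidates are
ordered lexicographically by (¹³C MAE rank, ¹H MAE rank).  ¹³C leads
because its shift dispersion (~200 ppm) dwarfs ¹H's (~10 ppm); in the
packaged reference cases both nuclei agree, so the tie-break is
unexercised there.  If the two nuclei disagree on the top candidate the
result sets `disagreement_flag` rather than resolving it silently.
Labels present in only one table are excluded and enumerated in the
result — never imputed.  Exact-MAE ties keep input order and are
reported as ties.

### Conformer elimination

Pruning applies the energy window first (13.0 kJ/mol above the global
minimum, the window being defined relative to the most favoured
conformation), then a greedy sweep in ascending energy keeps a conformer
iff its RMSD to every kept conformer is ≥ 1.0 Å.  The greedy order is a
design choice — the reference workflow's internal algorithm is not
published — and guarantees the global minimum always survives.  A
conformer at exactly the cutoff RMSD or exactly the window edge is kept.

RMSD is the Kabsch minimal RMSD over proper rotations and translations
(reflections excluded), computed over heavy atoms by default, since
hydrogen positions are noise for dedup purposes; a flag includes them.
Atom correspondence is positional: identical ordering is assumed and no
molecular-graph symmetry correction is attempted (a known limitation —
symmetric rotors can inflate RMSD between genuinely identical
structures).  The superposition itself is delegated to
`scipy.spatial.transform.Rotation.align_vectors` and is cross-checked in
the tests against a brute-force rotation-grid search.

Energies are carried in kJ/mol; the XYZ reader converts `E=<value>
hartree|kcal/mol` comment lines at the boundary (1 hartree =
2625.4996 kJ/mol, 1 kcal = 4.184 kJ thermochemical).

### Mass arithmetic

Monoisotopic masses use NIST values (¹²C ≡ 12 exactly, ¹H 1.00782503,
¹⁶O 15.99491462, ²³Na 22.98976928, …).  Adduct m/z is the plain sum of
neutral + adduct atoms with **no electron-mass subtraction**: this is the
convention under which all nine packaged printed "calcd" values
reproduce exactly at 4 decimal places (subtracting m_e breaks several of
them at the fourth decimal).  Reported masses are rounded half-up at
4 dp.

RDBE = (2C + 2 + N − H − halogens)/2; oxygen is ignored.  A half-integer
result is returned with a warning instead of raising, since it is the
standard signal of an odd-electron species or a typo in the formula.
One packaged compound (C₃₀H₄₆O₉) is described inconsistently in its
source — stated once as 12 and once as 8 hydrogen deficiencies; the
formula arithmetic gives 8 and that is what the package returns.

Neutral-loss annotation compares the observed Δm = precursor − fragment
against a small library (CO₂ 43.9898, acetic 60.0211, methacrylic
86.0368, tiglic 100.0524, 2-hydroxyisovaleric 118.0630, 2×acetic
120.0423 Da) and returns the closest candidate within a relative
tolerance, default 15 ppm **of the loss mass** — deliberately generous
because the loss difference inherits the absolute error of two ion
measurements while being numerically small.  Ties are reported, not
broken.

### Langmuir kinetics

The 1:1 model is fitted globally: one (k_a, k_d, R_max) across all
concentrations of a series, matching single-K_D reporting.  The fit runs
in log-parameter space (positivity for free) with
`scipy.optimize.least_squares`; starting values come from standard SPR
heuristics — k_d from the log-linear slope of the dissociation tail,
k_a from the slope of the observed rate k_obs = k_aC + k_d versus C,
R_max from the largest end-of-association response divided by the
implied fractional occupancy.  Standard errors derive from the
Gauss–Newton covariance at the optimum; the K_D error uses the delta
method on log k_d − log k_a.  A series spanning ≤ one order of magnitude
in concentration triggers an identifiability warning (k_a and R_max
become strongly correlated).  Mass-transport limitation, baseline drift
and bulk refractive-index jumps are not modelled.

The closed-form association/dissociation solution is validated against
direct ODE integration (`scipy.integrate.solve_ivp` at rtol 1e-10) to
better than 1e-6 RU across the packaged five-point assay design
(25 nM – 4 µM, 60 s / 300 s phases).

## Synthetic data: what it emulates, what it does not

`generate_stereo_case` builds per-conformer shieldings as
σ = σ_TMS − (δ_exp + offset + ε): the true candidate has zero offset, so
its Boltzmann average differs from experiment only through the Gaussian
per-conformer noise ε; each wrong candidate additionally carries a
systematic ±offset on a contiguous block of sp³ carbons, mimicking the
stereocentre-proximal shift sensitivity that the method exploits.  The
proton offset is one tenth of the carbon offset, reflecting the roughly
ten-fold narrower ¹H shift range.  Defaults: 20 carbons (20 % sp²,
chosen away from the perturbed block so the decoy signal survives the
sp² exclusion), 24 protons with a third in methyl triples, 4 candidates,
8 conformers at an exponential energy scale of 3 kJ/mol — the population
structure of a post-QM ensemble that keeps a handful of conformers
within a few kJ/mol — noise 2.0 ppm (¹³C) / 0.2 ppm (¹H), offset 3.0 ppm
on 5 atoms.  The noise magnitudes sit at the scale of the MAEs real
assignments produce, so the synthetic difficulty mirrors the real case.

What the generator does **not** emulate: correlated (systematic) DFT
errors shared across candidates, conformation-dependent shift surfaces,
solvent effects, rotamer-dependent methyl averaging.  Passing recovery
tests therefore shows the *statistical machinery* discriminates a
localised systematic offset from unbiased noise at realistic magnitudes;
it does not validate any quantum-chemistry protocol.

`generate_toy_conformers` produces a base geometry plus Gaussian
displacements with energies equal to the RMS displacement magnitude —
just enough structure for RMSD/pruning tests, with no chemistry implied.

All generators are pure functions of their spec including its mandatory
seed; a spec with zero noise **and** zero decoy offset is rejected as
degenerate (all candidates identical).

The packaged experimental tables assign carbon hybridization by a shift
threshold (δ_C ≥ 105 ppm → sp²).  For these oxygen-rich terpenoids the
heuristic is checked against the structural assignments: acetal/hemiacetal
carbons at 97–100 ppm stay sp³ and olefinic CH at 109–110 ppm are sp².
It is not a general-purpose perception rule; user-supplied tables carry
their own flags.

## Problem sizes and numerics

The validation studies run at: 100 seeded synthetic assignment cases for
the recovery rate; 50 seeded noisy assays (SNR 100, i.e. noise sd =
R_max/100) for the K_D recovery study, each fitted over 5 curves × 361
1-second samples; pruning oracles on 8-conformer, 5-atom toys.  These
sizes give stable medians and rates while keeping the whole suite fast.
Published MAE values ship as a documentation fixture for the ranking
logic only: regenerating them would require the original shielding
ensembles, which were never deposited, and the published K_D values
(e.g. 18.2 ± 1.9 nM) likewise cannot be re-derived without the raw
sensorgrams — the SPR validation surface is parameter recovery on
synthetic data using the published assay design.  Whether reported
± values on such constants are replicate SDs or fit SEs is ambiguous in
general; for simulated data the fit reports its own SE and leaves
replicate statistics to the caller.

Degenerate inputs are errors, not silent defaults: empty ensembles,
empty Δδ collections, zero overlapping labels, non-finite data, charge-0
adducts, negative losses.  Ties (RMSD at cutoff, equal MAEs, equal loss
errors) are resolved by explicit documented rules.
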