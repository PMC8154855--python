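# Methods

This note records the models implemented in `spinpath`, the assumptions
behind them, the parameter choices that matter, and the numerical details a
user would need to judge what the results do and do not show.

## Tunneling-pathway analysis

The pathway picture treats the donor–acceptor electronic coupling as a
product of per-step decay factors along a chain of contacts. Defaults are
the canonical literature values: ε_C = 0.6 per covalent bond;
ε_H = ε_C²·exp(−β(R − 2.8 Å)) per hydrogen bond;
ε_S = 0.5·ε_C·exp(−β(R − 1.4 Å)) per through-space jump, with
β = 1.7 Å⁻¹ in both exponential terms. All values are config-overridable;
every ε is clamped to ≤ 1.

Hydrogen bonds are detected geometrically (N/O/S heavy-atom pairs within
3.5 Å; donor–H–acceptor angle ≥ 120° when an H is present, distance-only
otherwise), because the structures handled here — toy templates and
multi-model PDB ensembles — carry no force-field topology. Through-space
edges connect non-bonded heavy atoms within 6 Å; hydrogens are excluded
from through-space jumps to bound graph size. Covalent bonds come from
CONECT records when present, else from a distance rule (heavy pairs
≤ 1.9 Å, H pairs ≤ 1.2 Å).

The strongest pathway is the max-product route, found by Dijkstra on edge
weights −ln ε. Path costs equal within 1×10⁻¹² relative are tied; ties are
broken by fewer edges, then by the lexicographically smallest atom-id
sequence, so the ensemble census is deterministic. Census identity is the
residue-level signature (consecutive duplicates collapsed): residue routes,
not atom-level variants, are the objects being counted. Waters are ordinary
residues and may appear in signatures. Snapshots whose donor and acceptor
are disconnected are counted and reported separately, never dropped.

The cross-condition observable is the ratio of mean-square decay products
⟨ε²_total⟩₁/⟨ε²_total⟩₂, the golden-rule estimate of the rate ratio; it can
be pushed into the kinetic model by scaling k_DA with the same factor.

Open choices made here: reported donor–acceptor distances are
metal-to-metal (consistent in magnitude with the measured 1.7/2.05/2.58 nm
values); pathway search anchors are the metal ions themselves, overridable
through the site-tag config. The Cu out-of-plane displacement uses the
plane through exactly the two His nitrogens and the Cys thiolate sulfur
(not a least-squares fit over more atoms), signed positive toward the Met
sulfur.

## Photocycle kinetics

Four states per protein: ground Ru(II)/Cu(II); excited Ru(II)*/Cu(II);
charge-separated Ru(III)/Cu(I); and Ru(II)/Cu(I) after the electrode
refills the Ru(III) hole. First-order rates k_exc = k_I·I, k_DA, k_refill,
k_AAg close the cycle; k_quench (energy/electron transfer of the excited
donor to the metal) is a parasitic excited→ground loss competing with
k_DA. Electrode processes are plain first-order rates — no electronic
structure of the metal is modelled, because the observable of interest is
the per-protein steady-state flux to the electrode and, ultimately, only
its ratio between temperatures. The proportionality constant between that
flux and a measured photovoltage (surface coverage, device geometry) is
deliberately not modelled.

The stationary distribution is the normalized null vector of the
column-sum-zero rate matrix (`scipy.linalg.null_space`, singular-value
tolerance 1×10⁻¹⁰ relative); a null space of dimension ≠ 1 — a reducible or
degenerate scheme, including pathologically stiff rate sets whose smallest
nonzero singular value falls below the tolerance — is rejected rather than
silently pseudo-inverted. No Marcus-type temperature dependence is built
into k_DA (the transfer step being modelled is nearly activationless);
temperature enters only through the rate values supplied per condition.
The shipped `examples/kinetics_290_250.yaml` is an illustrative
parameterization of the quench-dominated regime — a k_DA drop of 1.88× (a
"less than 2-fold" coupling-squared decrease) yielding an accumulation
ratio of 1.80 — not a transcription of measured rates.

## Vibronic spin polarization

The implemented model is deliberately reduced: Morse thermal anharmonic
displacement → linear effective field → Brillouin moment → spin-weighted
current. It is the minimal chain that reproduces the behaviors the full
vibronic transport theory is invoked for: an effective field that grows
steeply (≥100-fold between 50 K and room temperature), an ionic moment
whose sign follows the external selection field, a polarization of ~20% at
290 K rising over 150–290 K, and the loss of polarization in the cold,
harmonic regime. A full many-body/Green's-function treatment is out of
scope.

Parameters (units, defaults, rationale):

| parameter | default | why |
|---|---|---|
| ħω (from a, D, m) | 21.945 meV | the 177 cm⁻¹ Cu–Met stretch |
| m | 21.2008 amu | Cu–S reduced mass |
| D | 500 meV | deep enough that level spacings stay near ħω, which keeps the 50 K level population — and hence B_vib(50 K) — small; see calibration |
| a | 1.562857 Å⁻¹ | fixed by ħω, D, m |
| κ | 10622.7 T/Å | calibrated: maps Δx(290 K) to the field giving P(290 K) = 20% |
| S, g | 1/2, 2.0 | Cu(II), d⁹ |
| B_ext | 0.35 T | the external selection field of the simulated sweep |
| I₀, G1 | 1, 1 | equal bypass and through-copper flux scales |
| n_levels | 24 | populations above level 23 are negligible below 400 K |

`scripts/calibrate_vibronic.py` performs the calibration and prints the
constants; they live in the `VibronicParams` defaults, never hard-coded in
formulas. The calibrated set gives B_vib(290)/B_vib(50) = 114.8 and
P(290 K) = 20.000%.

Numerical choices. Thermal averages are quantum (Boltzmann over
eigenstates), not classical: ħω ≈ 22 meV ≫ k_BT at 50 K, where a classical
integral would be badly wrong. Eigenpairs come from finite-difference grid
diagonalization with 2048 uniform points. The domain is at most
[x_eq − 5/a, x_eq + 20/a] but is capped at the classical turning points of
the highest retained level plus ten ground-state lengths — the bare 1/a
rule degenerates for very deep (nearly harmonic) wells, whose 1/a length
diverges while the wavefunctions do not. Closed-form Morse energies agree
with the grid to better than 0.1% over the levels used. The default sweep
is 80 points on 5–400 K, the range the model is meant to describe; grids
outside it warn rather than fail.

Two model facts worth stating plainly. First, ⟨S_z⟩ entering P is the
thermal ionic moment, not a transport-weighted quantity; the distinction
cannot be resolved from the observables modelled here, so the simpler
choice is implemented and flagged. Second, at fixed B_ext the polarization
does not go identically to zero in the harmonic or low-temperature limits:
what vanishes is the vibration-driven part. A Zeeman background
P = 100·S·B_S(gμ_B S B_ext/k_BT) remains (≈0.04% at 290 K, ≈2% at 5 K,
where the 1/T Curie growth of the argument partly offsets the vanishing
field). The harmonic-potential reference (`potential="harmonic"`)
reproduces exactly this background, which is the operational statement of
the "no anharmonicity → no chiral-induced polarization" null.

## Device observables and Arrhenius fits

The two-filter MR curve is MR(H) = −100·(1 − leak)·p_protein·tanh(H/H_sat):
a field-independent chiral filter in series with a hysteresis-free Ni
magnetization, diluted by the pinhole leak fraction. The tanh choice keeps
the antisymmetry MR(−H) = −MR(H) exact, which is the property the curve
shape is used for; hysteresis and absolute MR magnitudes are out of scope.
All public outputs are percentages.

Activation energies are ordinary least squares on ln(signal) vs 1/(k_BT),
E_act = −slope in meV, optional weights. Non-positive signal points are
excluded from the log fit and recorded on the fit object — a 0%
polarization floor is a detection floor, not an Arrhenius datum. The
phonon-quenching correction applied to the measured polarization data is a
device-specific procedure not reproduced here; the
`exclude_quench_correction` hook is a documented identity pass-through
that logs a notice, keeping the composition point explicit.

## Synthetic data: what it emulates, and what passing tests show

The toy template emulates the His83-labelled system's geometry at the level
the analyses need: a 1.7 nm donor–acceptor separation; a Cu site with two
His nitrogens and a Cys thiolate defining the equatorial plane, the Cu
0.04 Å out of plane toward an axial Met sulfur at 3.5 Å; a 22-bond
meandering covalent bridge; and a two-water pocket offering an almost
straight, through-space/H-bond-assisted shortcut. The geometry is tuned so
the two route classes genuinely compete under moderate jitter (the
shortcut wins in roughly 10–20% of 290 K snapshots at the default
σ_ref = 0.35 Å).

Ensemble jitter is isotropic, per-atom, uncorrelated Gaussian noise with
σ(T) = σ_ref·√(T/T_ref) — the equipartition scaling of harmonic positional
fluctuations. Noise is drawn as standard normals and scaled afterwards, so
seed-matched ensembles at two temperatures share their underlying
displacements; paired (common-random-number) comparisons of, e.g., the
shortcut occurrence at 290 vs 250 K are then stable enough for a seeded
regression test.

What this generator does *not* emulate: correlated protein modes, real
force-field energetics, solvent, anisotropic site stiffness, or the actual
conformational distributions of the protein. Consequently, passing the
ensemble tests shows that the census, geometry and ratio machinery is
correct and that the qualitative hot-favors-direct-routes tendency emerges
from variance alone; it does not reproduce — and is not meant to
reproduce — the real occurrence percentages, out-of-plane averages or
coupling ratios, which require genuine MD sampling.

Problem sizes used in the shipped tests and scripts (chosen as the
package's own working scale): ensembles of 40–400 snapshots of the
~35-atom template; random pathway graphs of ≤ 10 nodes against exhaustive
enumeration (500 cases); 1000 random 4-state kinetic models against an
independent linear solve; 2048-point oscillator grids; Arrhenius recovery
over 100 seeds at 20 points per curve.

## Known limitations

* The pathway model is semi-empirical; no Hamiltonian or curve-crossing
  corrections, and spin does not enter the pathway search.
* The kinetic model is a single-protein cycle with first-order electrode
  steps; absolute fluxes are not comparable across devices.
* The vibronic model's κ compresses all exchange physics into one linear
  coefficient; its value is a calibration, not a prediction, so B_vib's
  absolute scale inherits that status (its temperature *dependence* is the
  model content).
* Measured activation energies (tens of meV for the photoinduced spin
  polarization, ~13 meV for dark MR) are figure-level data; the thermal
  module is validated on synthetic ground truth instead.
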