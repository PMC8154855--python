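# spinpath

Analysis toolkit for temperature-dependent **charge and spin transfer in
Ru-modified azurin films**: electron-tunneling pathway statistics over
structure ensembles, steady-state photocycle kinetics at a metal electrode,
a vibronically activated spin-polarization model of the Cu(II) site, and the
observable algebra of magnetic-tunnel-junction measurements
(magnetoresistance, photovoltage, Arrhenius activation energies).

It is written for people modelling chiral-induced spin selectivity (CISS)
and long-range electron transfer in metalloproteins who want the individual
analysis steps as tested, composable library functions rather than
one-off scripts.

## What it computes

**Tunneling pathways** (`spinpath.structures`, `spinpath.pathways`).
A conformational snapshot becomes a weighted graph whose edges carry
per-step decay factors in the semi-empirical pathway model:

    covalent bond     ε_C = 0.6
    hydrogen bond     ε_H = ε_C² · exp(−1.7 (R − 2.8 Å))
    through-space     ε_S = 0.5 · ε_C · exp(−1.7 (R − 1.4 Å))

The strongest donor→acceptor pathway maximizes Π ε (Dijkstra on −ln ε,
verified against exhaustive enumeration), and an ensemble census reports
how often each residue-level route wins, together with the mean-square
decay product ⟨ε²⟩ whose cross-temperature ratio estimates the golden-rule
rate ratio |H_DA(T₁)|²/|H_DA(T₂)|². Cu-site geometry observables (Ru–Cu
distance, Cu out-of-equatorial-plane displacement, Cu–S(Met) distance) come
from the same snapshots.

**Photocycle kinetics** (`spinpath.kinetics`). A four-state master equation
— ground → excited (k_I·I) → charge-separated (k_DA) → Cu(I)-reduced
(k_refill) → ground (k_AAg), with parasitic quenching k_quench — is solved
for its stationary distribution (null space of the rate matrix); the
steady-state electron flux to the electrode per protein is the model
quantity proportional to the photovoltage-derived charge-transfer yield.

**Vibronic spin polarization** (`spinpath.vibronic`). The Cu–ligand
coordinate sits in a Morse potential (ħω = 177 cm⁻¹ Cu–Met mode); grid
diagonalization gives level energies and per-level ⟨x⟩ₙ, thermal population
of anharmonic levels shifts the mean position Δx(T), and a linear map
κ·Δx(T) produces the effective exchange field **B**_vib(T). The ionic
moment follows the Brillouin function,
⟨S_z⟩ = S·B_S(gμ_B S (B_vib·sign B + B)/(k_B T)), and the chiral-induced
spin polarization of the junction current I = I₀ + I₁ is

    P = 100% · |⟨S_z⟩ · I₁ / I₀|

**Device observables** (`spinpath.transport`, `spinpath.thermal`).
MR(%) = 100·(R(H)−R(0))/R(0); the antisymmetric two-filter MR curve of a
chiral filter in series with a Ni electrode; ΔMR = MR(−H_max) − MR(+H_max);
photovoltage summaries V↑↓ = (V↑+V↓)/2, P = (V↑−V↓)/V↑↓; and Arrhenius
activation energies from ln(signal) vs 1/(k_B T).

**Synthetic data** (`spinpath.synthetic`). A toy His83-like template
(donor–acceptor separation 1.7 nm, tagged Cu ligand shell, a 22-bond
meandering bridge and a two-water shortcut) with seeded √T-scaled jitter,
plus Arrhenius curves with known activation energy — every pipeline input,
generated with known ground truth.

## Worked example

Generate a 100-snapshot ensemble at 290 K, run the pathway census, then the
photocycle and vibronic models:

```sh
$ spinpath synth --seed 1 --out demo
wrote demo/ensemble.pdb (100 snapshots, T=290.0 K)

$ spinpath pathways --pdb demo/ensemble.pdb --out demo
wrote demo/census.csv
wrote demo/pathways.csv
mean-square decay: 9.344761e-10 (0 disconnected snapshot(s))
```

`demo/census.csv` ranks the winning residue routes; with this seed the
meandering covalent bridge (RU201→HIS83→GLY84…GLY101→CYS112→CU130) wins
most snapshots, and shorter routes that jump through-space to the His46
ligand or through the internal waters take the rest.

```sh
$ spinpath kinetics --config examples/kinetics_290_250.yaml --out demo
 temperature_K  flux_to_electrode  accumulation_ratio_vs_ref
           290          90.899918                   1.800047
           250          50.498632                   1.000000
```

With the illustrative rate sets of `examples/kinetics_290_250.yaml`
(a less-than-2-fold k_DA drop in a quench-dominated regime) the
steady-state charge accumulation at 290 vs 250 K comes out in the ratio
1.80 — the magnitude of the measured cross-temperature yield ratio.

```sh
$ spinpath vibronic --out demo     # writes demo/vibronic_sweep.csv
 temperature_K    B_vib_T      S_z   P_percent
            50   1.590157 0.013029    1.302935
           150  55.512780 0.122534   12.253391
           290 182.553364 0.200001   20.000076
```

Under the default calibrated parameters the vibrational field grows
~115-fold from 50 K to 290 K and the room-temperature spin polarization is
20%, rising monotonically over the measured 150–290 K window.

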