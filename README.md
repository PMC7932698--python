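# condensate-quant

Quantification pipeline for single-molecule and condensate experiments on
protein-driven DNA compaction — the kind of data produced when a
chromatin protein such as HP1α condenses DNA on a curtain assay, forms
liquid-like droplets with DNA in solution, exchanges in and out of those
droplets (FRAP), and resists mechanical disruption in an optical trap.

It is written for experimentalists who have image stacks and
force-extension records and need the bespoke analyses these assays
require, with every step validated by parameter recovery on a built-in
synthetic-data generator.

## What it computes

**Curtain compaction tracking** (`tracking`). Kymograms are built per DNA
strand by averaging the three pixel columns local to the strand. The free
DNA end is the per-frame minimum of the positional derivative of the
Gaussian-smoothed kymogram; positions near the image edge are excluded
and positions off a Savitzky–Golay-smoothed trajectory are rejected as
outliers. The compaction rate *v* is the slope of end position vs time.

**Binding kinetics** (`kinetics`). On uncompacted DNA the protein
fluorescence density grows linearly, ρ(t) = κt. Two limiting models for
the compacted segment follow: if protein binds compacted and uncompacted
DNA equally, I_a(t) = κvt²; if binding to compacted DNA is blocked, each
captured element keeps its capture-time density and
I_b(t) = v∫₀ᵗκs ds = ½κvt² — exactly half. Normalizing the measured
compacted intensity by ρ(t)·l_c(t) therefore centers on 1 (equal) or 0.5
(blocked). A dye-conservation statistic, (I_c − I_u,fit)/max(I_c),
spans [−1, 1] and crosses zero at the compaction midpoint when the
intercalator signal is conserved.

**Droplet morphology** (`droplets`). Brightfield condensates are
segmented edge-first (Fourier high-pass, Canny over a sigma ladder,
closing + hole filling, scale-aware union), then filtered: area > 3 px
and eccentricity ≤ 0.94. Radius statistics per condition: the
complementary cumulative distribution CCD(r) = P(R ≥ r) with
percentile-bootstrap bands, the expected radius E[R] = ∫CCD dr, and a
power-law fit E[R] = A·c^b across concentrations.

**FRAP** (`frap`). Line FRAP is double-normalized,
(I_FRAP(t)/I_FRAP(0)) / (I_unb(t)/I_unb(0)), and fit to a biexponential
to extract t½. Whole-droplet FRAP over minutes corrects photobleaching
with a spatially varying decay,
ȳ(t) = ⟨a⟩e^(−k₁(x,y)t) + ⟨b⟩e^(−k₂(x,y)t) with
k_i(x,y) = k_i0 + αᵢx + βᵢy fitted by regressing per-droplet decay rates
on droplet position.

**Force analysis** (`force`). Marko–Siggia worm-like-chain reference
curves, F = (k_BT/L_p)[¼(1−x/L₀)⁻² − ¼ + x/L₀]; the energy stored in
compacted DNA as the area between protein and bare-DNA stretch curves
(pN·µm → k_BT, divided by compacted base pairs); compacted length from
the extension deficit at a query force; binding-site size from a protein
dimer span at 0.34 nm/bp.

**Synthetic data** (`synthetic`). Seeded generators for every input —
kymograms, curtain movies, brightfield droplet fields, FRAP movies,
force-extension pairs — each returning its ground truth.

## Worked example

The numbered scripts under `analysis/` run the full chain on simulated
inputs and write tables under `results/`:

```
python analysis/01_simulate_inputs.py
python analysis/02_track_compaction.py
python analysis/03_binding_kinetics.py
python analysis/04_droplet_morphology.py
python analysis/05_frap_recovery.py
python analysis/06_force_energetics.py
```

Output of the chain (seed 0):

```
accepted frames: 49/100
max per-frame tracking error: 1.00 px
fitted rate: 1.9942 px/frame (truth 2.0; 0.29% off)

conservation statistic spans [-1.02, 0.96] (ideal [-1, 1])
equal binding: kappa = 0.0500/frame, normalized Ic centers at 1.020 (expected ~1.0)
blocked binding: kappa = 0.0500/frame, normalized Ic centers at 0.521 (expected ~0.5)

detection precision 1.000, recall 1.000
power law: r = 0.519 * c^0.401 (+/- 0.005); generative exponent 0.4

line FRAP: t_half = 2.33 s (truth 2.32 s)
whole-drop: fitted k1 gradient (4.99e-04, 2.01e-04) vs truth (5.00e-04, 2.00e-04)
corrected plateau (last 20 frames): 0.999 (1.0 = full recovery)

extension deficit at 20 pN -> 4994 bp sequestered (truth 5000)
area between curves: 9.628 pN um (truth 9.567)
energy barrier: 0.469 kBT/bp
binding site of open dimer (22.2 nm span): 65 bp; sites per 2.7 kbp DNA: 45
```

Each number is a recovery of a known generative parameter: the tracker
recovers the 2 px/frame compaction rate to 0.3%, the blocked-binding
kymogram centers on ½ as the model predicts, segmentation finds every
droplet and the radius-vs-concentration exponent to ±0.005, FRAP
recovers the half-time and photobleach gradients, and the trap analysis
recovers the sequestered length and enclosed area.

A `condensate-quant` CLI wraps the same library for real data:

```
condensate-quant track --movie movie.tif --pixel-size 0.16 --frame-interval 0.1
condensate-quant droplets --image field.tif
condensate-quant frap --movie frap.tif --mode whole --bleach-frame 10 --roi 54 54 75 75
condensate-quant force --curves curves.csv --deficit-force 20
condensate-quant demo --seed 1        # everything end-to-end on synthetic data
```

## Layout

```
src/condensate_quant/   library (synthetic, tracking, kinetics, droplets, frap, force, io, cli)
analysis/               numbered narrative drivers writing results/
tests/                  pytest suite (unit, property, end-to-end recovery)
scripts/acceptance.py   deterministic recomputation of the headline quantity
docs/methods.md         models, assumptions, parameter choices, limitations
```
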