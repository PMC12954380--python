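# Methods

## Titration model and processing chain

A one-electron cofactor poised at electrode potential E (mV vs SHE) is
oxidised to fraction f_ox(E) = 1/(1 + exp(−zF(E − Em)/RT)). The observable —
absorbance averaged over a band where the oxidised and reduced species
differ — is therefore a Nernstian sigmoid in E:

    Y(E) = a / (exp(zF(E − Em)/RT) + 1) + c

with amplitude a, offset c and midpoint Em. Constants: F = 96485.34
J mol⁻¹ V⁻¹, R = 8.3145 J mol⁻¹ K⁻¹, T = 293 K, z = 1 (fixed in fits).
The thermal width RT/zF ≈ 25.25 mV sets the 10 %→90 % span at
2·ln 9·RT/F ≈ 111 mV; a fitted curve that violates this closed form would
indicate a broken fit, and a test checks it.

The processing chain, in run order:

1. **Baseline correction.** The mean absorbance over 650–700 nm (a region
   without redox-linked features for these chromophores) is subtracted per
   spectrum. This absorbs any wavelength-independent offset, so constant
   spectral shifts cannot move Em (property-tested).
2. **Band averaging.** Arithmetic mean over 465–485 nm. Window membership
   is inclusive on both ends and tested on the recorded wavelength grid; no
   interpolation, the simplest reproducible rule.
3. **Drift correction.** The thin-layer cell's optical path can shrink
   during a run; re-measuring the first potential at the end exposes this
   as unequal band values at equal potential. A ramp linear in acquisition
   index, anchored so the first/last repeated-potential entries coincide,
   is subtracted. Acquisition index is the drift abscissa (wall-clock
   timestamps are not part of the data model, and index is a faithful proxy
   for measurement order). An additive linear drift is thereby removed
   exactly; the generator's multiplicative path-length drift is only
   approximately linear after band averaging and leaves a sub-mV residual
   at 5 % total drift — consistent with the correction mattering more for
   plots than for Em.
4. **Normalisation.** Min-max scaling to [0, 1], then re-zeroed at the
   lowest-potential (most-reduced) spectrum so Y = A − A_red starts at 0.
   Em is invariant under any affine rescaling of the trace, so this choice
   is cosmetic for the headline number; it makes amplitudes comparable
   across replicates.
5. **Scale conversion.** Applied potentials (vs Ag/AgCl) + 280 mV → SHE.

Replicates are processed independently; per-potential means and standard
deviations across replicates are then formed, the means fitted, the SDs fed
to the bootstrap. Oxidising and reducing sweep branches are fitted jointly
by default (one Em per protein); `branch_mode="split"` fits them separately
and reports the difference as hysteresis.

## Fitting and bootstrap

The fit minimises Σ(Y − model)² with scipy's Levenberg–Marquardt. Because
the model is linear in (a, c) at fixed Em, initialisation scans a 1 mV Em
grid solving the 2×2 normal equations in closed form at each candidate,
then refines all three parameters (xtol = ftol = 1e-12). The sign of a is
unconstrained so the same form covers rising and falling traces. A fitted
Em outside the sampled potential range sets a warning flag rather than
failing. The test suite holds this fitter against an independent
brute-force oracle (exhaustive 0.1 mV grid search) on noiseless data.

Uncertainty: a parametric Gaussian bootstrap. 1000 datasets are drawn
around the per-point means with SD = 3 × the per-point experimental SDs,
each refit (initialised from the point-estimate fit, which is what makes
1000 refits cheap), and the SD of the Em distribution is reported. The ×3
inflation makes the estimate deliberately conservative; calibration-wise,
the *unscaled* bootstrap SD tracks the replicate-to-replicate scatter of
per-replicate fits within a factor of two on synthetic data. Replicates
whose refit fails are dropped and counted, with a 10 % failure ceiling to
avoid silent bias. One seeded generator stream per bootstrap call gives
exact reproducibility.

## Synthetic data: what it emulates, what it does not

`simulate_titration` builds each spectrum as
(baseline + f_red·reduced + f_ox·oxidized) · (1 − drift_total·i/(N−1)) +
Gaussian noise, on a 250–800 nm grid at 0.5 nm spacing. Component spectra
are sums of Gaussian bands (defaults: oxidised peaks at 350, 475 and 560 nm;
reduced at 420 nm) — band-level caricatures, not digitised spectra of any
real protein. The drift is multiplicative because it models path length.
Defaults are the study conditions: −50…+550 mV vs SHE in 20 mV steps with
the first potential repeated at the end, triplicates, noise SD 0.02 AU
(~2 % of the ~0.85 AU band amplitude), 5 % total drift.

Not emulated: iR drop and double-layer effects, equilibration kinetics,
wavelength-correlated noise, multi-cofactor spectra, pH drift. Passing the
recovery tests therefore shows the *pipeline* is unbiased and correctly
seeded under its own assumptions, not that real OTTLE data are this clean.

Toy structures place rigid minimal templates (a [2Fe2S] rhombus, [4Fe4S]
cubane, porphyrin core, isoalloxazine and nicotinamide fragments) at chosen
centroids on one chain. Planar templates stacked along z give edge-to-edge
distances exactly equal to the centroid spacing, which the fixtures exploit.

## Geometry

Edge-to-edge distance = minimum Euclidean distance over heavy-atom pairs;
the default atom set is *all* heavy atoms of the heterogroup (including
heme propionates and FAD/NADP tails). An optional `mode="conjugated"`
restricts hemes to the porphyrin core + Fe, FAD to the isoalloxazine and
NADP to the nicotinamide (FeS clusters are their own core), since
Moser–Dutton practice often excludes substituents; atom-name lists are in
`redoxpath.geometry.CONJUGATED_ATOMS`. Only the first MODEL of a file is
read; alternate conformations keep the highest-occupancy copy (ties: first
encountered). Distances are in Å with no periodicity.

Cofactor recognition is by residue code (HEM→heme_b, HEC→heme_c, FES, SF4,
F3S, FAD, NAP/NDP) through a user-overridable registry — predicted models
are known to mislabel b- vs c-type hemes, so the code-to-kind mapping must
not be hard-wired.

Transfer-graph edges exist at distance ≤ cutoff (default 20 Å) and are
classified efficient (≤ 15 Å) or possible (> 15 Å). Pathfinding is
bottleneck-optimal — minimise the maximum step, since tunneling rate decays
exponentially with the longest hop — with ties broken by fewer steps, then
lexicographic label order (implemented by scanning edge-weight thresholds
and taking the lexicographically smallest unweighted shortest path in the
thresholded subgraph). Disconnection is an explicit result, not an error.

Checks against deposited crystal structures or AlphaFold3 complex models
(e.g. the 26–28 Å soluble-to-membrane-domain heme distances) require
downloading those coordinate files; the generic machinery
(`min_group_distance`) is provided and tested on synthetic structures, and
no test in the suite needs network access.

## Energetics

Potentials are mV vs SHE throughout; "favorable" means a positive
acceptor-minus-donor difference. The ledger is closed-form: favorable =
E(high acceptor) − E(quinone); required = E(quinone) − E(low acceptor);
net = favorable − required, feasible when net ≥ 0. Proton-motive-force
contributions are deliberately not modeled — feasibility here is purely
redox bookkeeping. The heme estimates encode two family regularities:
b_P = 2·E(quinone) − E(Rieske) (Rieske and b_P symmetric around the
quinone) and b_N = b_P + offset with the offset a parameter defaulting to
+130 mV (it is a trend, not a constant). The Rieske potential at 303 mV
gives b_N = −313 mV by exact arithmetic; the implementation reports the
exact value rather than a rounded one. ΔG = −nFΔE converts to kJ/mol when
an energy is wanted.

Default couples table: MK-7 −70 mV, NAD(P)+/NAD(P)H −320 mV, NO₂⁻/NO
+380 mV, Kuste4569 303 mV, Kustd1480 335 mV.

## Problem sizes and numerical choices

The recovery studies use 50 simulations of triplicate 32-point ladders with
full 1000-replicate bootstraps in the acceptance-style test (≈40 s) and a
2-replicate bootstrap in the script's recovery study, where only the median
|Em_fit − Em_true| is reported. Exponent arguments are clipped at ±500
before `exp` to avoid overflow at extreme potentials; fit tolerances are
xtol = ftol = 1e-12; drift correction and baseline subtraction are exact
arithmetic. Degenerate inputs fail loudly: constant traces (no transition),
missing repeated potentials (skip-correction advice), potential spans below
2·RT/F, empty spectral windows, hemes without iron.

## Known limitations

- Single-transition fits only; overlapping multi-cofactor transitions and
  pH dependence of Em are out of scope.
- The drift model is linear in acquisition index; strongly nonlinear path
  loss would leave a residual the repeated-potential anchor cannot see.
- Edge classification uses sharp 15/20 Å thresholds; no rate model
  (Moser–Dutton log-rate, packing density β) is computed.
- The bifurcation ledger ignores membrane potential, pH gradients and
  short-circuit kinetics; it answers "is the redox arithmetic favorable",
  nothing more.
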