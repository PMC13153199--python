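# Methods

`foulcast` re-implements, as a tested library, the computational core of a
bench-scale reverse-osmosis (RO) fouling comparison between three
coagulation pretreatment scenarios — no coagulant (Ctrl), AlCl₃ (Al) and
FeCl₃ (Fe), the latter two leaving residual metal in the RO feed.  Real
membrane and sequencing data are not required: a synthetic-data module
generates every input stream with known ground truth, so each analysis
stage is validated by recovery.  This note records the models, the defaults
and why, and what the synthetic conditions do and do not establish.

## Flux and resistance analytics (`hydraulics`)

Flux is J = ΔV/(A·ΔT) in L m⁻² h⁻¹ (LMH); resistances follow the
resistance-in-series picture R_T = ΔP/(μ·J_SI) and R_f = R_T − R_m, with J
converted to m s⁻¹ (÷3.6×10⁶) only inside these formulas.  Percent flux
decline is 100·(J_first − J_last)/J_first with configurable head/tail
averaging windows (default: single endpoints; the averaging choice is
exposed because endpoint-vs-window conventions differ between labs).
Concentration polarization uses the film model EF = exp(J_SI/k); the
mass-transfer coefficient k is an input.  A helper derives k from a generic
laminar Sherwood correlation (Sh = 1.85·(Re·Sc·d_h/L)^⅓, L = 100·d_h) for a
rectangular crossflow cell; that correlation choice is an assumption
suitable for order-of-magnitude estimates only.  At the nominal operating
point (25 LMH, k = 4.7×10⁻⁵ m s⁻¹) EF ≈ 1.16, i.e. polarization enriches
the wall concentration by only ~15–20 % and cannot by itself explain
scenario-sized fouling differences.

### Synthetic flux curves

Noiseless flux follows J(t) = J_end + (J₀ − J_end)·e^(−t/τ) with
J_end = J₀(1 − f).  Defaults: J₀ = 25 LMH for every scenario; 20-d decline
fractions f = 0.255 (Ctrl), 0.493 (Al), 0.712 (Fe); τ = 2 d (1.6 d for Fe)
so the sharp decline is over within the first ~6 days, followed by a
pseudo-stable plateau.  The Fe scenario adds a bounded sinusoid
(amplitude 1.2 LMH, period 4 d) switched on after day 8 to emulate foulant
detachment/regrowth events; its period divides the remaining 12 days, so
the 20-d endpoint is unaffected.  Measurement noise is Gaussian with
sd 0.1 LMH, which reproduces replicate scatter of a few tenths of a percent
in the decline.  The exponential-plus-oscillation form is a modelling
choice: only its endpoints and time scales are constrained by the emulated
study.

## 2D correlation spectroscopy (`cos2d`)

Dynamic spectra subtract a reference (default: the time mean, the standard
choice).  The synchronous map is Φ = ỸỸᵀ/(m−1); the asynchronous map is
Ψ = ỸNỸᵀ/(m−1) with the Hilbert–Noda matrix N_jk = 1/(π(k−j)), zero
diagonal.  Φ symmetry, Ψ antisymmetry and the zero Ψ diagonal are exact up
to rounding; the implementation is verified against closed forms on sampled
full-period sinusoids (Φ₁₂ = m·cosφ/(2(m−1)), Ψ₁₂ = m·sinφ/(2(m−1)) up to
discretization error that shrinks with m).  The discrete transform presumes
even time sampling; non-uniform series are rejected with advice to
resample.

Auto-peaks are local maxima of the Φ diagonal above 5 % of the largest
auto-peak (no detection rule is standard; 5 % is conservative for the
band-over-baseline contrast the generator produces).  Band ordering applies
the sign rule — |Ψ| ≤ tol: simultaneous; Φ·Ψ > 0: first band leads;
otherwise lags — with tol defaulting to 1 % of max|Ψ|, floored at 1e-10 of
the top auto-peak so exactly-synchronized bands read as ties.  Pairwise
verdicts aggregate to dense ranks by win counting, and non-transitive
triads are reported rather than hidden.

### Synthetic FTIR series

Spectra are sums of Gaussian bands on a 600–4000 cm⁻¹ grid (2 cm⁻¹ step)
at 11 evenly spaced time points over 20 d.  Band centres use conventional
foulant assignments (3290 O–H/N–H, 2925/2855 C–H, 1720 C=O, 1645 Amide I,
1585 Amide II, 1450/1400 CH/COO⁻, 1240 phospholipid >P=O, 1150/1080/1040
polysaccharide C–O–C, 980); the Fe scenario carries 13 bands (adds 2855 and
1720) versus 11 for Ctrl/Al, and its microbial signatures (>P=O, Amide II)
appear first.  Appearance order is planted through sigmoid amplitude
profiles with staggered onset days (one deliberate tie per scenario); each
band's dynamic amplitude is normalized to unit temporal variance so every
band yields a comparable auto-peak.  Recovery of both the counts (13/11)
and the full planted order is exact under the default noise (sd 0.004).

## EEM fluorescence quotients (`eemfq`)

Each sample's EEM is min–max normalized into [0.01, 0.10]
(FI′ = 0.01 + 0.09·(FI − FI_min)/(FI_max − FI_min)); normalization is per
sample, making the comparison robust to lamp-intensity scale.  The
fluorescence quotient is FQ_A/B = log₁₀(FI′_A/FI′_B) per paired sample,
aggregated across the 11 pairs by the pixelwise median (log base and
aggregator are package choices; log₁₀ makes FQ = 1 exactly one normalized
decade).  Significance uses a one-tailed paired Wilcoxon signed-rank test
per pixel (p < 0.1, alternative toward the observed median difference).
Differences below 1e-9 on the normalized scale count as zeros and are
dropped — they are numerical residue, not evidence.  Pixels without tied
magnitudes go through a vectorized exact null (the signed-rank distribution
is precomputed per effective n); ties fall back to `scipy.stats.wilcoxon`,
and the two routes are cross-checked in the tests.  Optional diagonal
Rayleigh/Raman scatter masking is available but off by default.

The three-way classifier labels a pixel Al-prominent when FQ_Ctrl/Al < 0
and FQ_Al/Fe > 0, Fe-prominent when FQ_Ctrl/Fe < 0 and FQ_Al/Fe < 0, and
Ctrl-prominent when FQ_Ctrl/Al > 0 and FQ_Ctrl/Fe > 0, each gated on the
two relevant significance masks.  The three sign patterns are mutually
exclusive; a residual-conflict counter is kept as a guard and is zero by
construction.

### Synthetic EEM cubes

Ex 200–450 × Em 250–550 nm at 5 nm spacing (a typical spectrometer export),
default 11 samples per scenario.  All scenarios share base peaks, including
one tall anchor peak that is every sample's maximum — with a common
normalization anchor, far-from-peak pixels carry no systematic
between-scenario differences and prominence localizes at the scenario
boosts: Ctrl boosted in Em 300–330 nm (tryptophan-like/SMP), Fe in
Em 330–450 nm (humic- and marine-humic-like), Al in a low-Stokes-shift
band.  Noise is multiplicative (lognormal whole-map scale sd 0.15, pixel
sd 0.05), keeping intensities positive.

## Commonality variance partitioning (`varpart`)

Flux decline is regressed on three predictor blocks (biological B,
inorganic I, organic O); the seven subset R²s yield the classical three-set
commonality components, e.g. U_B = R²(BIO) − R²(IO) and
C_BIO = R²(B)+R²(I)+R²(O) − R²(BI)−R²(BO)−R²(IO) + R²(BIO).  The components
sum to R²(BIO) identically; negative components (suppression) are reported,
not truncated (truncation is available as an explicit presentation choice).
Percentages use the explained-variance baseline by default (÷R²_full, sums
to 100) with the total-variance baseline as an option.

Blocks enter with all their columns by default (`raw_multicolumn`).  The
single-component reduction (`pca_first_component`, sign-aligned to the
response) is provided, but it is not the default for a structural reason:
once each block is one column, the partition is a function of the 4×4
correlation matrix of (B, I, O, y) alone, and a numerical search over that
entire family cannot reach partitions that combine a dominant pairwise
commonality near 50 % of explained variance with a triadic share near 40 %
and small uniques — the profile this pipeline is built to quantify.  Shared
variance of that shape exists only when blocks keep ≥ 2 indicators, which
is also how the underlying measurements come (multiple elements, multiple
organic assays).

### Calibrated fouling datasets

The generator builds seven iid standard-normal latents (one per
commonality component), two columns per block as weighted sums of the
block's four latents (unique, two pairwise, triadic) plus measurement noise
(variance 0.1), and the response as a weighted latent sum.  For a requested
fraction target the weights are found by least squares against the
*analytic* population partition (closed-form covariance → subset R² →
components), so the population fractions match the target to ~1e-14;
calibrated weights for the three scenario targets ship frozen in
`foulcast._calibrated` (regenerable via `calibrate_fouling_weights`).
Each scenario target fixes its two headline fractions (Ctrl: U_O = 18.3,
C_BI = 42.0; Al: U_B = 15.1, C_BI = 28.9; Fe: C_IO = 49.1, C_BIO = 39.0 —
percent of explained variance) and completes the remaining five so the set
sums to 100 while preserving the qualitative ordering (triadic largest in
Fe; the B–I pair dominant among Ctrl/Al binaries).

Defaults: n = 500 observations (the emulated study's ~33 membrane
observations are available via `n=33`, but component estimates are then
very noisy), total R² = 0.9 set by added response noise.  The high R²
reflects a bench study whose flux decline is strongly determined by the
measured foulant loads, and it keeps the per-seed spread of recovered
fractions (sd ≈ 2.5–3 points, dominated by latent sampling) small enough
that 20-seed medians sit within ~1.5 points of target.  Sample-level
recovery carries a small finite-sample bias that vanishes by n ≈ 2000.

## Co-occurrence networks and roles (`micronet`)

Edges connect taxa whose |Spearman ρ| (default; Pearson available) meets a
threshold (default 0.8 for user data); signs are kept as edge attributes,
constant taxa are excluded with a warning, isolated nodes dropped.  Modules
come from Clauset–Newman–Moore greedy modularity maximization
(deterministic given node order).  Roles use the within-module degree
z-score Zi = (κᵢ − mean)/sd (population sd per module; Zi = 0 where the sd
vanishes) and participation coefficient Pi = 1 − Σ_s(κᵢs/kᵢ)², with the
conventional thresholds: module hub Zi > 2.5 with Pi ≤ 0.62, connector
Pi > 0.62 with Zi ≤ 2.5, network hub both, boundary values peripheral.

The random-matrix threshold scan is a deliberately simplified stand-in for
the full external network pipeline: for each candidate cutoff the
thresholded correlation matrix is reduced to its connected rows, the
eigenvalue staircase is unfolded with a least-squares polynomial, and the
nearest-neighbour spacing histogram is compared with the Poisson form
e^(−s) by a χ²/dof distance; the smallest cutoff within tolerance is
suggested.  Networks below 10 connected nodes are treated as trivially
compatible — an empty network has no level statistics to test.

### Synthetic abundance tables

Every taxon is a unit-norm row over an orthonormal basis (module factors +
per-taxon idiosyncratic coordinates), so population correlations are exact
row dot products; data are the rows times iid normal samples (default 150),
exponentiated to lognormal abundances (rank correlations therefore equal
the Gaussian ones).  Regular members load their module factor with
loadings in [0.5, 0.62]; a planted module hub is the normalized module sum
(strongly correlated with every member, so modules are hub-centred stars
plus sparse member–member edges — exactly the degree profile that makes Zi
single out the hub); a planted connector is the balanced sum of the module
hub signals.  The ground truth includes the planted graph: population
Spearman correlations thresholded at 0.42, chosen to sit between the
connector–member (~0.33) and connector–hub (~0.56) correlations.  The
default user-facing build threshold of 0.8 is intentionally not used here —
with k mutually independent module factors a unit-variance taxon's
correlation with any one of them is at most 1/√k, so balanced connectors
are only expressible at a lower cutoff.

Limits worth knowing: with 3 modules a balanced connector's participation
ceiling is 2/3, barely above the 0.62 convention, so on finite samples the
recovered connector sometimes slips below the line (the planted-graph
classification is exact; recovered-graph tests assert the robust
properties — hubs above Zi = 2.5, connectors touching ≥ 2 modules, module
recovery with adjusted Rand > 0.9).

## Pipeline and reproducibility

`run_pipeline` executes flux → FTIR/2DCoS → EEM → variance partitioning →
network per scenario, then the cross-scenario FQ comparison and an OTU-set
Venn, writing per-stage CSV/JSON artifacts, a `summary.json`, the
serialized config and a timing log.  A single global seed fans out to
per-stage sub-seeds via `SeedSequence([seed, stage_index, scenario_index])`
so any stage can be re-run in isolation; fixed-seed runs are byte-identical.
All generators are bit-reproducible for fixed seeds and parameters.

What passing on synthetic data shows — and what it does not: the analyses
recover planted structure under the stated noise models (Gaussian flux
noise, Gaussian band profiles, lognormal EEM noise, Gaussian latents,
Gaussian copula abundances).  Real foulant spectra have baselines and band
overlap the generator omits (baseline/ATR correction is declared out of
scope), real EEMs have scatter ridges (masking is optional), real
abundances are compositional counts, and real predictor tables are small
(n ≈ 33) where commonality estimates are far noisier than at the default
n = 500.  The package validates the machinery, not the field study.
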