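# Methods

Exact definitions and conventions used by `boldvar`, in the order a study
flows through them.

## Local variability (rMSSD)

Each run (regions × timepoints) is first centered to a whole-brain mean of
zero — a single scalar shift that standardizes baselines without touching any
temporal structure. Local variability of a regional series x₁…xₙ is

    rMSSD = sqrt( Σᵢ (xᵢ₊₁ − xᵢ)² / (n − 1) ),

the root of the mean squared first difference. For iid noise of standard
deviation σ, E[(xᵢ₊₁ − xᵢ)²] = 2σ², so rMSSD → √2·σ; positive lag-1
autocorrelation lowers it (rMSSD = √(2σ²(1 − ρ₁)) for stationary series).
Lag-1/lag-2 autocorrelation maps use the plain product-moment correlation of
the series with its shifted copy. Group maps are element-wise means;
z-scoring uses the population SD (divide by R).

## Global variability (covSTATIS hull areas)

1. **High-pass filter** at 1/window-length Hz (order-4 Butterworth, zero-phase
   forward–backward, after mean removal). A window of length w seconds cannot
   resolve fluctuations slower than 1/w Hz; left in, they inflate every
   windowed correlation.
2. **Sliding windows**: square shape, step 1 TR. Width in TRs is the nearest
   integer to window_s/TR with halves rounded away from zero
   (`floor(x + 0.5)`); the number of windows is `(T − w)//step + 1`. Window
   lengths of 45–100 s are accepted silently, others with a warning.
3. **Windowed connectivity**: the product-moment correlation table of each
   window, clipped to [−1, 1]; a zero-variance region within a window gets
   zero correlations (with a warning) and a unit diagonal.
4. **covSTATIS compromise**: all Y tables of all subjects are vectorized. The
   Rv coefficient between two symmetric tables is tr(AB)/√(tr(AA)·tr(BB)) —
   the classical trace form; a `squared=True` variant is available. The Y×Y Rv
   matrix equals W·Wᵀ for Frobenius-normalized vectorized tables W, so its
   leading eigenvector is found by Lanczos iteration without forming the
   matrix. That eigenvector is non-negative (Perron–Frobenius; Rv of PSD
   tables is non-negative) and, normalized to sum 1, gives the table weights.
   The compromise is the weighted sum of the tables; it is eigendecomposed,
   non-positive eigenvalues dropped, eigenvector signs fixed (largest loading
   positive), and factor scores defined as U·Λ^½ (so F·Fᵀ reconstructs the
   compromise).
5. **Back-projection**: window table Xₜ maps to Xₜ·U·Λ^(−½); projecting the
   compromise itself returns the factor scores.
6. **Hull area**: per region, take the T window coordinates on the first two
   components, drop the `ceil(0.05·T)` points farthest from the cloud
   centroid (95% peel, guarding against single-window outliers), and compute
   the convex-hull area. Degenerate clouds (fewer than 3 distinct points,
   collinear) score 0 — as does any perfectly stationary stack.

## Validation statistics

- **ICC(3,k)** (two-way mixed, consistency, average measures) from the ANOVA
  decomposition: (MS_subjects − MS_error)/MS_subjects, with the confidence
  interval from the F ratio with (n−1) and (n−1)(k−1) degrees of freedom.
  For single-measure reliability ρ the expected value is kρ/(1 + (k−1)ρ).
- **Test-retest**: group-level Pearson correlation of group-mean maps, plus
  within-subject Spearman correlations Fisher-z transformed (clipped at
  atanh(1 − 1e−12)), averaged, back-transformed, and tested against zero with
  a one-sample t (Cohen's d = mean z / SD z).
- **Welch reliability**: per-region (or per-network, pooling regions) Welch
  t-tests between two samples; a unit is *reliable* when the samples do not
  differ (p > α).
- **Behavioral PLS**: within each group, correlate age with every region's
  score; stack the group correlation rows and decompose by SVD. Covariance
  explained per latent variable is s²/Σs². Permutations shuffle age within
  group (p with +1 smoothing); bootstraps resample subjects within group,
  align resampled saliences to the original basis by orthogonal Procrustes,
  and form bootstrap ratios (salience / bootstrap SE, stable when |BSR| ≥ 2).

## Multiscale association

- **Receptor composites** on max-normalized densities d (each receptor scaled
  by its across-region maximum): entropy H = −Σ d·log d / log L with
  0·log 0 = 0 (L = 13 receptors; base-invariant; 0 when every d is 1), E/I
  ratio (mean excitatory / mean inhibitory), and mean ionotropic /
  metabotropic density. The panel annotates 13 receptors: 8 excitatory, 5
  inhibitory; 4 ionotropic (a4b2, GABAa, GABAa-bz, NMDA), 9 metabotropic.
- **Hungarian spin test**: each hemisphere's parcel centroids live on their
  own full registration sphere (as in surface-based alignment). Per spin, a
  uniform random rotation is applied to the left hemisphere and its sagittal
  mirror conjugate to the right, and rotated parcels are re-assigned to
  original slots by minimum-total-distance Hungarian matching — a bijective,
  hemisphere-preserving permutation that preserves spatial autocorrelation.
  Because the generator evaluates spatial kernels on mirror-aligned
  coordinates, the mirrored rotation is an exact isometry of the map
  covariance up to matching error; measured rejection at α = 0.05 on
  independent smooth maps is ≈ 0.055. Two-sided p-values use +1 smoothing:
  (1 + #{|r_null| ≥ |r_obs|})/(1 + n_spins).
- **Participation coefficient** on absolute correlation weights, self-loops
  removed: PCᵢ = 1 − Σ_s (k_is/kᵢ)²; isolated nodes score 0 with a warning.
- **Dominance analysis**: the incremental R² of each predictor over every
  subset of the others, averaged within subset size then across sizes (all
  2^p − 1 submodels, computed from a cached normal-equation solve per
  subset). General dominance weights sum to the full-model R²; for orthogonal
  predictors they equal the squared correlations.

## Spectral simulation arm

Simulated series combine an aperiodic component — white noise shaped in the
frequency domain so power ∝ f^χ, normalized to unit variance — with rhythmic
components whose log₁₀-power spectra are Gaussian bumps relative to the
aperiodic level (α: 10 Hz, 0.7 a.u., 2 Hz bandwidth; β: 19 Hz, 0.4 a.u.,
5 Hz; σ = bandwidth/2), each realized as independently phase-randomized
shaped noise with total power P_aperiodic·(10^bump − 1). Spectra are
estimated by Welch's method (Hann, 2-s windows, 50% overlap → 0.5 Hz
resolution) and parameterized over 1–40 Hz in fixed (no-knee) mode: robust
log-log line fit, iterative Gaussian peak extraction from the residual (a
peak must exceed 2 residual SDs *and* 0.3 a.u.; bandwidths clipped to
[0.5, 12] Hz; peaks within 2σ of a larger one merged), then an aperiodic
refit on the peak-subtracted spectrum; the exponent is the negative slope.

The exponent sweep simulates 10 series per exponent (−0.7 to −1.5, step
−0.1; 150 s at 500 Hz; n = 90) and regresses rMSSD on exponent steepness
|χ|: steeper spectra carry relatively less high-frequency power, so rMSSD
falls and the slope is negative; R² ≈ 0.97.

## Synthetic ground truth

- **Parcellation**: right-hemisphere centroids on a randomly rotated
  Fibonacci sphere lattice (quasi-uniform); the left hemisphere mirrors
  jittered homologs onto its own sphere. Networks come from k-means on
  mirror-aligned coordinates (bilateral, spatially compact), with A/B
  subnetworks emulating a finer granularity that merges back by name prefix.
- **BOLD generator**: hidden-Markov Gaussian model. State covariances are
  low-rank-plus-diagonal, C_k = A_k·A_kᵀ + 0.05·I, where region i's unit
  loading row in state k mixes a shared baseline direction with a
  state-specific one: u_ki = normalize((1 − sᵢ)·u0ᵢ + sᵢ·w_ki). The
  per-region spread sᵢ is the planted quantity hull areas should recover;
  every region keeps unit signal variance, so local amplitude is not
  confounded with connectivity dynamics. States switch with exponential
  dwell (default mean 45 s, 8 states); observation noise is white (SD 0.5).
  Age dampening shrinks state covariances toward their mean:
  C_k(age) = λ·C_k + (1 − λ)·C̄ with λ decreasing linearly over the age span.
- **Regional maps / receptor panel**: Gaussian processes with exponential
  kernel exp(−geodesic/ℓ) on the mirror-aligned centroids (homotopic regions
  correlate); densities are log-normal transforms, positive by construction.

## Acquisition profiles

Post-discard volume counts and TRs of the four simulated designs:
`young1` 200 × 3.0 s, `young2` 399 × 1.4 s, `lifespan1` 297 × 2.0 s,
`lifespan2` 399 × 1.4 s; young ages 18–34, lifespan 20–86.
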