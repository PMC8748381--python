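# Methods

This note documents the models, algorithms, defaults and limits of
chromforge, module by module, the way a maintainer would want them stated.

## Retention model and gradient simulation (`gradsim`)

Retention of a reversed-phase solute follows the linear solvent strength
(LSS) relation

    log10 k = log k0 − S·φ + a_T·(T − T_ref)

with `k` the retention factor, `φ` the volume fraction of organic modifier,
`S` the solute-specific slope (positive in reversed phase; a non-positive
value warns but does not fail), and an optional van't Hoff-like linear
temperature correction about the design-center reference `T_ref`.

Under a time-varying program `φ(t)` the solute's fractional migration in a
small isocratic step `dt` is `dt/(t0·k(φ(t)))`, where `t0` is the column
dead time; elution occurs when the accumulated migration reaches 1, so
`tR = t0 + t_g` with `∫₀^{t_g} dt/(t0·k) = 1`. The program is piecewise
linear between nodes, held constant outside them, and delayed by the dwell
time `t_dwell` as seen by the column inlet. The integral is accumulated with
the trapezoid rule on a uniform grid (default step `t0/50`), in blocks, with
the crossing interpolated inside the final step. Against closed forms this
gives the isocratic `tR = t0(1+k)` to machine precision and the
linear-gradient LSS solution to ~0.003 % at `dt = t0/100`; halving the step
changes `tR` by well under 0.1 %.

Peak width uses the isocratic plate expression `σ_t = t0(1+k_e)/√N` with
`k_e` the local retention factor at elution and `N` the plate count (default
8000, typical of a modern 5 cm–7.5 cm column). Gradient peak compression is
deliberately not modelled: widths are used to *rank* separations, and the
compression factor is close to common across candidates. Resolution uses the
4σ convention `Rs = (tR_j − tR_i)/(2(σ_i + σ_j))` over adjacent pairs; the
critical Rs is their minimum (infinite sentinel for a single component).
Solutes still on column at the last node continue isocratically for
3× the program span (configurable) before being flagged non-eluting.

## Screening designs (`design`)

Calibration designs are economical irregular second-order (Hoke-type)
matrices with 2, 6, 8 and 18 runs for 1–4 factors, levels in {−1, 0, +1}.
The 6-run (2-factor) and 18-run (4-factor) realizations support the full
second-order polynomial with full column rank (the 18-run matrix was chosen
by D-optimal coordinate exchange over the 3⁴ grid). The 8-run 3-factor
design is *supersaturated* for the 10-term full quadratic — its model matrix
has the maximal possible rank of 8 — which is precisely why the empirical
retention mode uses PLS rather than ordinary least squares.

Gradient time must span at least a 3:1 level ratio, otherwise `S` and
`log k0` are poorly separable; a narrower range is rejected (or widened on
request, with a warning — never silently accepted). pH is refused as a
factor under UV-only detection because pH shifts the spectra on which
cross-run component correlation relies; with MS present it is allowed with a
warning. Validation rows are appended outside the calibration set, either at
the range extremes (stress-testing the model) or at interior points
(friendlier to discovery); they never coincide with a calibration row.

## Synthetic campaigns (`synthgen`)

The generator emulates a multi-run DAD-UV (optionally MS) screening
campaign with full ground truth. Each latent component has a unit-maximum UV
spectrum (sums of Gaussian absorption bands), an optional sparse MS spectrum
(base peak 100), LSS parameters, and an injected amount. Per run, the
component elutes as an **area-normalized** Gaussian centred at the retention
time computed by the same gradient integrator the rest of the package uses
(so ground truth and simulation agree exactly), with the plate-model width;
the recorded matrix is the bilinear sum of profile ⊗ spectrum terms plus a
polynomial baseline drift, an optional broad early "injection" hump (to
exercise the artifact filter), an optional negative autozero offset, and iid
Gaussian noise. Identical seeds give bit-identical matrices.

The packaged six-component campaign screens gradient time 5–15 min, initial
modifier 0.05–0.20 and temperature 25–45 °C on the 8-run design plus one
intermediate validation run, at 5 points/s sampling. Components have
pairwise spectral |r| < 0.9, `log k0` 1.6–3.5, `S` 3.2–5.8 (typical of small
phenolic solutes), amounts spanning 10-fold, and noise giving the weakest
peak an apex S/N of roughly 200. These conditions make discovery nontrivial
(all six peaks overlap heavily in the fast runs) but solvable (each
component is baseline-resolved somewhere).

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: peak tailing/fronting, gradient peak
compression, detector saturation, wavelength-dependent noise, spectral
drift with temperature, and retention behaviour outside the LSS model.

## Trace processing and segmentation (`clusters`)

Peak picking runs on the maxplot (per-time max over wavelengths, clipped at
zero) or TIC (per-scan sum). The trace is smoothed by Savitzky–Golay
(window 11 points, order 3 — appropriate at the advised ≥ 5 points/s).
The baseline level and noise are estimated robustly from the smoothed trace:
level = median, noise = 1.4826 × median absolute *negative* deviation (the
lower side is peak-free; note a maxplot has a positive noise floor, which
the level term absorbs). Points at or below `level + 3·noise` (noise_k
default 3) for at least 5 consecutive samples (min_points) are baseline;
the non-baseline stretches in between become clusters, except stretches
shorter than min_points, which are noise blips. A relative floor of 1e−4 of
the trace range keeps smoothing ripple out of noiseless data. Apexes are
local maxima of the smoothed trace with negative second derivative.
Composite clusters are split at interior minima falling below 0.5× the
smaller adjacent apex (valley_ratio; no published value exists, 0.5 is a
conservative "half-height valley" choice). Pieces tile the parent exactly.

## Curve resolution (`mcr`)

Each cluster matrix (negatives clipped to zero first — baseline noise and
autozero offsets otherwise violate the model) is decomposed as `X = C Sᵀ + E`
by alternating least squares:

* **C-step**: per-time-point non-negative least squares against the current
  spectra, followed by projection of each profile onto the unimodal cone
  (isotonic increase up to the column maximum, antitonic decrease after,
  by pool-adjacent-violators).
* **S-step**: per-channel non-negative least squares against the profiles;
  spectra columns are unit-normalized with the scale pushed into C.

For the small ranks involved (≤ 6) each NNLS is solved exactly by
enumerating the 2^r − 1 support sets on the Gram system, batched over all
right-hand sides — verified against the classical active-set solver and
orders of magnitude faster on long clusters. Iteration stops when the lack
of fit changes by less than 1e−6 (relative, with an absolute floor of 1e−6
percentage points so near-perfect fits terminate), after 500 sweeps, or
after 10 consecutive lof increases (flagged non-converged).

Initialization is SIMPLISMA: row purity `p_i = σ_i/(μ_i + α)` with the
offset `α` = 3 % (literature-typical 1–5 %) of the maximum of the mean
spectrum, and determinant-based down-weighting of directions already
selected (computed incrementally, never materializing the full
correlation-around-origin matrix).

The number of components per cluster is chosen automatically: an SVD
candidate count (singular values above the iid-noise floor
`σ(√m + √n)`, with signal presence requiring the matrix maximum to clear
the expected noise extreme `σ√(2 ln 2mn)` by three Gumbel scales), then the
smallest rank whose lof drops below 2 % — capped at six components per
cluster, a deliberate guard against noise-driven overfitting.

Extraction screens are deliberately lenient (false negatives are worse than
false positives, which later diagnostics can still remove): components keep
their place if their SIMPLISMA purity exceeds 5 % of the cluster's best, and
— when MS spectra are attached — if the count of non-base signals above
0.1 % of the base peak stays at or below the configured maximum. A component
is flagged **pure** if it eluted alone (rank-1 cluster) or if its profile
carries ≥ 95 % of the fitted signal around its own apex; profiles peaking on
a cluster boundary are kept but flagged truncated.

## Discovery, assignment, diagnostics (`discovery`)

Pure-flagged components are merged across runs into catalog entries when
their unit spectra correlate at `r ≥ 0.95` (Pearson; the standard
chemometric spectral-match metric), processed in decreasing purity order;
the consensus spectrum is the renormalized member mean. With MS evidence,
entries whose UV spectra match but whose base peaks differ by more than
0.5 m/z stay separate (MS cosine ≥ 0.9 required to merge, on unit bins).

Never-pure spectra unexplained by the catalog are promoted to provisional
entries only if (a) they recur in at least two runs (a real component's
spectrum repeats; one-off deformed extractions do not) and (b) they carry
new spectral information — a candidate whose spectrum is reproduced at
`r ≥ 0.95` by a non-negative combination of the co-eluting entries' spectra
is the classic "sum spectrum" false positive and stays in the mixed set for
reporting.

Assignment is per run, greedy by descending correlation, one-to-one (no
extracted component is consumed twice); ties within 1e−9 go to the candidate
nearest the entry's median assigned retention time. `r ≥ 0.95` assigns;
`0.8 < r < 0.95` issues an alert and leaves the cell empty; below 0.8 the
cell is unassigned. Retention fitting refuses to run over outstanding alert
cells unless explicitly waived — an alert is an unverified assignment, and
modelling around it silently would defeat the whole diagnostic design.

Entries whose spectrum correlates, positively or negatively, at |r| ≥ 0.95
with any run's background spectrum (mean spectrum over non-cluster points)
are flagged artifacts and excluded from modelling — flagged, never deleted.
The diagnostics report is likewise advisory: redundant entry pairs (spectra
matching and retention agreeing within 2 sampling intervals in every
co-assigned run), sum-spectrum candidates, and per-column inconsistency
(assigned on one column, never on the other). User edits (merge, delete,
set_tR) are applied by `resolve`, with manual provenance recorded.

## Retention fitting (`retention`)

Two modes:

* **lss** (default): fit `(log k0, S[, a_T])` by nonlinear least squares on
  observed vs simulated retention times under each calibration run's actual
  program (coarse 4×3 grid start, then bounded trust-region refinement).
  This is the physically structured mode and the only one usable by the
  optimizer, since it permits simulating arbitrary candidate programs.
* **pls**: PLS regression of tR on the second-order expansion of the coded
  factors, latent-variable count by leave-one-out PRESS on the calibration
  runs, capped at (calibration runs − 2). Useful as a purely empirical
  interpolator and on supersaturated designs.

Validation-role runs never enter either fit; their predictions are reported
separately, and per-run standardized residuals flag |z| > 3 as suspect
assignments. Temperature enters only when the design varies it.

## Optimization (`optimize`)

Single-objective: DE/rand/1/bin (`v = a + F(b−c)`, binomial crossover with a
forced gene, greedy replacement), F = 0.7, CR = 0.9, population 40 —
standard robust settings. Bounds are handled by reflection; non-finite
objective values reject the trial. Fully seeded and reproducible.

Multi-objective (recommended): objectives (−critical Rs, runtime), where
runtime is the simulated elution time of the *last component*, not the
programmed gradient time. A trial vector replaces its parent only when it
dominates it (GDE3-style greedy rule), and every evaluated point feeds an
external archive pruned to the non-dominated set, which is returned as the
Pareto front. The resolution objective is capped (default Rs = 10) so the
search does not spend evaluations inflating resolution far beyond utility;
the cap is configurable (set it to infinity to compare raw optima). On the
packaged six-component mixture the front's best critical Rs reaches within
5 % of an exhaustive 50×50 grid over the same space in 60 generations.

Program encoding is a single linear segment (φ_initial, φ_final, t_G,
temperature) by default, with an optional mid-node (t_mid fraction, φ_mid)
for two-segment profiles; any in-bounds vector decodes to a valid program
(φ clipped to [0, 1], node times sorted).

## Interfaces

UV matrices are delimited text (channels in row 1, times in column 1,
sniffed delimiter, shortest-roundtrip float formatting — read∘write is the
identity). MS scans are long-format `time,mz,intensity` CSV, accumulated
into half-open left-inclusive bins (default 1 Da, matching unit-resolution
quadrupoles); binning conserves total ion current exactly. Metadata is a
JSON sidecar per run (program nodes, t0, dwell, temperature, flow, column,
role); times are minutes everywhere, with `time_unit: s` converted on load.
The CLI (`chromforge design|simulate|discover|fit|optimize|report`) wraps
the library per stage, writes the resolved config and seed next to the
outputs, and exits with code 2 from `discover`/`fit` while unresolved alerts
remain (unless `--allow-alerts`).

## Numerical and degenerate-input choices

* All-zero cluster matrices are rejected before SIMPLISMA; all-baseline
  traces segment to an empty list (not an error).
* Bilinear permutation/scale ambiguity: all comparisons to truth use best
  column matching on unit-normalized spectra.
* Zero-variance spectra correlate to 0 by convention (undefined Pearson).
* Unretained solutes (k → 0) elute at the dead time; the migration rate is
  clamped at k = 1e−12 to avoid division blow-ups.
* Seeds are masked to 31 bits before use; every stochastic component
  (generator, DE, noise) takes an explicit seed.

## Known limitations

* Retention outside the LSS model (strongly curved log k vs φ) biases both
  fitting and optimization; only the linear model is implemented.
* The plate-model width underestimates gradient peak compression, so
  absolute Rs values are conservative for steep gradients.
* Discovery assumes each real component elutes pure — or at least dominates
  its apex — in at least one run; a component that co-elutes exactly
  everywhere is found only via the mixed-set pass, and a component fully
  co-eluting with the *same* partner in every run is indistinguishable from
  a sum-spectrum artifact (the chromatographer-in-the-loop case).
* Enantiomers and other components with identical UV *and* MS spectra
  cannot be distinguished.
* The background filter models drift as a stable spectral shape per run;
  structured, time-varying backgrounds may evade it.
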