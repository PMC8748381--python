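# chromforge

Computer-assisted reversed-phase LC method development for mixtures of
**unknown composition**: discover what is in the sample from a handful of
screening chromatograms, model each component's retention, and optimize the
gradient elution program — without ever identifying the compounds.

## Who this is for

Separation scientists (and the software that serves them) facing the
"unnamed peaks" problem: classical method-development tools need to know the
mixture's components up front so each peak can be tracked across calibration
runs. When the sample is unknown, peaks cannot be tracked by position —
selectivity changes reorder and merge them between runs — so no retention
model can be built. chromforge tracks components by their **spectra**
instead, extracted from second-order detector data (DAD-UV time × wavelength
matrices, optionally full-scan MS).

## The method

1. **Screening design.** Economical irregular second-order designs (2/6/8/18
   runs for 1–4 factors) over gradient time (levels spanning at least a 3:1
   ratio), modifier fraction, temperature. A validation run is held out.
2. **Peak clusters.** Each run's maxplot (or TIC) is smoothed
   (Savitzky–Golay), segmented at baseline stretches, and split at deep
   valleys into small time × channel sections.
3. **Curve resolution.** Every cluster `X` is decomposed by MCR-ALS under
   non-negativity and unimodality, `X = C Sᵀ + E`, with SIMPLISMA
   purest-variable initialization, at most six components per cluster, and a
   lack of fit `lof = 100·√(ΣE²/ΣX²)` as the convergence metric.
4. **Component discovery.** Spectra that eluted pure somewhere are
   correlated across runs (Pearson r on unit spectra) into a catalog of
   unique components; MS base peaks separate UV-identical components.
   Background-correlated entries are flagged as artifacts.
5. **Assignment.** Each catalog component takes, per run, the retention time
   of its best-correlating extracted component if `r ≥ 0.95`; a significant
   but insufficient correlation (`0.8 < r < 0.95`) raises an **alert** for
   chromatographer review. Fitting refuses to proceed over unresolved alerts.
6. **Retention model.** Per component, the linear solvent strength (LSS)
   relation `log k = log k₀ − S·φ` (plus a linear temperature term) is
   fitted by nonlinear least squares through the gradient simulator; a PLS
   regression on the second-order design expansion is available as an
   empirical alternative.
7. **Optimization.** Any elution program is simulated as a series of small
   isocratic steps (migration `Δx = dt/(t₀·k(φ(t)))`, elution at `Σ Δx = 1`);
   differential evolution with Pareto bookkeeping trades the critical
   resolution `Rs = Δt_R/(2(σᵢ+σⱼ))` against analysis time.

## Worked example

`examples/03_discover_and_fit.py` simulates a 9-run screening campaign of a
six-component mixture (known ground truth), then discovers and models it
blind:

```
catalog: 6 components (0 artifact-flagged, 0 alert cells)

entry  log k0     S      a_T      r2        val residual (min)
    1   3.438  5.796  -0.0060  1.000000  +0.0018
    2   2.340  4.301  -0.0060  1.000000  +0.0018
    3   1.559  3.196  -0.0040  1.000000  +0.0006
    4   2.748  4.895  -0.0050  1.000000  -0.0003
    5   1.952  3.804  -0.0050  1.000000  +0.0003
    6   3.030  5.300  -0.0070  1.000000  -0.0011
```

All six latent components are recovered (true `S` values 3.2–5.8 match to
three figures), every run is assigned with no alerts, and the held-out
validation run is predicted to a few thousandths of a minute — the
diagnostic that would expose a mis-assigned peak as a large residual.
`examples/04_optimize_program.py` then searches gradient programs:

```
Pareto front: 232 non-dominated programs (2440 simulations)

  phi_0   phi_f    t_G    critical Rs   runtime (min)
  0.267   0.989    3.1        0.89          2.80
  0.293   0.844    4.0        1.61          3.59
  0.297   0.955    8.0        2.54          4.83
  0.298   0.974   12.8        3.45          6.30
  ...
```

reading as the resolution/time trade-off: baseline separation (Rs ≥ 1.5) of
all six components is available from ~3.6 min upward.

The other examples cover design + simulation (`01`) and the curve-resolution
core on a strongly overlapped peak (`02`). A thin CLI wraps the same
pipeline for shell use: `chromforge simulate|discover|fit|optimize|report
--seed N --outdir DIR` (stages are individually re-runnable; `discover` and
`fit` exit non-zero while alert cells remain unless `--allow-alerts`).

## Scope and limits

Reversed-phase LC only (the LSS model is the retention backbone); exported
text data, not vendor formats; no pH factor under UV-only detection; peak
widths from the isocratic plate model (no gradient compression); robustness
assessment of the chosen optimum is out of scope. See `docs/methods.md` for
the full model description, parameter defaults and known limitations.
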