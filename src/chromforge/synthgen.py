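"""Synthetic multi-run screening campaigns with known ground truth.

Emulates what a diode-array (and optionally single-quadrupole MS) detector
records during a gradient screening campaign: each latent mixture component
has a fixed UV spectrum, an optional sparse MS spectrum, and LSS retention
parameters.  Under each run's elution program the component elutes as a
Gaussian centred at the retention time predicted by the stepwise gradient
integrator, with time-domain width from the isocratic plate expression
``sigma_t = t0 (1 + k_e) / sqrt(N)``.  The recorded matrix is the bilinear
sum of profile (x) spectrum outer products plus polynomial baseline drift, an
optional broad early "injection" hump (emulating the maxplot artifacts real
diode-array data shows at the start of runs), and iid Gaussian noise.

What it does not emulate: peak tailing/fronting, gradient peak compression,
detector saturation, and spectral shifts with temperature or pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromio import ChannelAxis, ChannelKind, Chromatogram, Detector, RunMeta, RunRole
from .design import DesignMatrix, FactorRole
from .gradsim import ElutionProgram, LSSParams, peak_sigma, simulate_gradient

__all__ = [
    "TrueComponent",
    "BaselineModel",
    "CampaignSpec",
    "GroundTruth",
    "program_for_run",
    "simulate_run",
    "simulate_campaign",
    "gaussian_spectrum",
    "example_six_component_spec",
]


def gaussian_spectrum(
    axis_values: np.ndarray, bands: list[tuple[float, float, float]]
) -> np.ndarray:
    """Unit-maximum UV spectrum as a sum of Gaussian absorption bands
    ``(center_nm, width_nm, relative_height)``."""
    axis_values = np.asarray(axis_values, dtype=float)
    s = np.zeros_like(axis_values)
    for center, width, height in bands:
        s += height * np.exp(-0.5 * ((axis_values - center) / width) ** 2)
    m = s.max()
    if m <= 0:
        raise ValueError("spectrum must have positive maximum")
    return s / m


@dataclass(frozen=True)
class TrueComponent:
    """A latent mixture component the pipeline should rediscover."""

    name: str
    lss: LSSParams
    uv_spectrum: np.ndarray  # unit-maximum, on the campaign's UV axis
    amount: float = 1.0
    ms_spectrum: dict[float, float] | None = None  # m/z -> rel. intensity, base = 100

    def __post_init__(self) -> None:
        s = np.asarray(self.uv_spectrum, dtype=float)
        object.__setattr__(self, "uv_spectrum", s)
        if np.any(s < 0) or not np.isclose(s.max(), 1.0):
            raise ValueError(f"{self.name}: uv_spectrum must be >= 0 with unit maximum")
        if self.amount <= 0:
            raise ValueError(f"{self.name}: amount must be positive")
        if self.ms_spectrum is not None:
            vals = list(self.ms_spectrum.values())
            if not vals or not np.isclose(max(vals), 100.0) or min(vals) <= 0:
                raise ValueError(
                    f"{self.name}: MS relative intensities must be in (0, 100] "
                    "with base peak 100"
                )


@dataclass(frozen=True)
class BaselineModel:
    """Low-order polynomial drift plus an optional broad injection hump.

    ``drift_coeffs`` are polynomial coefficients in normalized time (t/t_end),
    lowest order first, applied to every channel through ``drift_spectrum``
    (unit-maximum; defaults to a flat spectrum).  The hump is a wide Gaussian
    at ``hump_time`` minutes.  Default amplitudes are zero (clean baseline).
    """

    drift_coeffs: tuple[float, ...] = (0.0,)
    hump_amplitude: float = 0.0
    hump_time: float = 0.5
    hump_sigma: float = 0.3
    drift_spectrum: np.ndarray | None = None

    def evaluate(self, time: np.ndarray, axis_values: np.ndarray) -> np.ndarray:
        u = time / max(time[-1], 1e-12)
        drift = np.polynomial.polynomial.polyval(u, np.asarray(self.drift_coeffs))
        if self.hump_amplitude:
            drift = drift + self.hump_amplitude * np.exp(
                -0.5 * ((time - self.hump_time) / self.hump_sigma) ** 2
            )
        spec = (
            np.ones_like(axis_values, dtype=float)
            if self.drift_spectrum is None
            else np.asarray(self.drift_spectrum, dtype=float)
        )
        return np.outer(drift, spec)


@dataclass
class CampaignSpec:
    """Everything needed to generate a reproducible screening campaign."""

    components: list[TrueComponent]
    design: DesignMatrix
    uv_axis: ChannelAxis
    plates: float = 8000.0
    noise_sd: float = 0.0  # detector units, iid per cell
    baseline: BaselineModel = field(default_factory=BaselineModel)
    sampling_rate: float = 5.0  # points per second
    seed: int = 0
    t0: float = 1.0  # min
    t_dwell: float = 0.0
    flow: float = 1.0
    phi_final_default: float = 0.95
    post_hold: float = 3.0  # min of isocratic hold recorded after the gradient
    column_id: str = "colA"
    ms_axis: ChannelAxis | None = None
    ms_noise_sd: float = 0.0
    autozero_offset: float = 0.0  # constant offset, may be negative

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for c in self.components:
            if len(c.uv_spectrum) != len(self.uv_axis):
                raise ValueError(f"{c.name}: spectrum length != UV axis length")


@dataclass
class GroundTruth:
    """True per-run retention of every component, for testing recovery."""

    table: pd.DataFrame  # columns: component, run_id, tR_true, sigma, k_e, truncated

    def tR(self, component: str, run_id: str) -> float:
        row = self.table[
            (self.table.component == component) & (self.table.run_id == run_id)
        ]
        return float(row.tR_true.iloc[0])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def program_for_run(spec: CampaignSpec, run_index: int) -> ElutionProgram:
    """Translate one design row into an elution program.

    Recognized factor roles: gradient_time (ramp duration), phi_initial,
    phi_final and temperature.  Missing roles fall back to campaign defaults
    (phi_initial 0.05, phi_final ``phi_final_default``, 25 degC, and a 10 min
    ramp if gradient time is not a factor).
    """
    real = spec.design.real_values[run_index]
    by_role = {f.role: real[j] for j, f in enumerate(spec.design.factors)}
    t_g = float(by_role.get(FactorRole.gradient_time, 10.0))
    phi0 = float(by_role.get(FactorRole.phi_initial, 0.05))
    phi1 = float(by_role.get(FactorRole.phi_final, spec.phi_final_default))
    temp = float(by_role.get(FactorRole.temperature, 25.0))
    return ElutionProgram(
        nodes=((0.0, phi0), (t_g, phi1)),
        temperature=temp,
        t0=spec.t0,
        t_dwell=spec.t_dwell,
        flow=spec.flow,
    )


def _run_truth(
    spec: CampaignSpec, run_index: int
) -> tuple[ElutionProgram, list[dict]]:
    program = program_for_run(spec, run_index)
    t_end = program.span + spec.post_hold + spec.t0
    rows = []
    for comp in spec.components:
        tR, k_e = simulate_gradient(comp.lss, program)
        truncated = not np.isfinite(tR) or tR > t_end
        sigma = (
            peak_sigma(tR, k_e, spec.t0, spec.plates) if np.isfinite(tR) else np.nan
        )
        rows.append(
            {
                "component": comp.name,
                "run_id": f"run{run_index + 1}",
                "tR_true": tR,
                "sigma": sigma,
                "k_e": k_e,
                "truncated": truncated,
            }
        )
    return program, rows


def simulate_run(
    spec: CampaignSpec, run_index: int, detector: Detector = Detector.UV
) -> Chromatogram:
    """Generate one run's chromatogram (UV by default, MS if requested)."""
    if not 0 <= run_index < spec.design.coded.shape[0]:
        raise IndexError("run_index outside the design")
    program, truth_rows = _run_truth(spec, run_index)
    t_end = program.span + spec.post_hold + spec.t0
    dt_min = 1.0 / (spec.sampling_rate * 60.0)
    time = np.arange(0.0, t_end + dt_min / 2, dt_min)

    if detector is Detector.MS:
        if spec.ms_axis is None:
            raise ValueError("campaign has no MS axis configured")
        axis = spec.ms_axis
        noise_sd = spec.ms_noise_sd
    else:
        axis = spec.uv_axis
        noise_sd = spec.noise_sd

    X = np.zeros((time.size, len(axis)))
    for comp, row in zip(spec.components, truth_rows):
        tR, sigma = row["tR_true"], row["sigma"]
        if not np.isfinite(tR):
            continue
        # area-normalized Gaussian: the same injected amount gives the same
        # flow-corrected peak area in every run, whatever the width
        height = comp.amount / (spec.flow * sigma * np.sqrt(2.0 * np.pi))
        profile = height * np.exp(-0.5 * ((time - tR) / sigma) ** 2)
        if detector is Detector.MS:
            if comp.ms_spectrum is None:
                continue
            spectrum = np.zeros(len(axis))
            for mz, rel in comp.ms_spectrum.items():
                j = int(np.argmin(np.abs(axis.values - mz)))
                spectrum[j] += rel / 100.0
        else:
            spectrum = comp.uv_spectrum
        X += np.outer(profile, spectrum)

    if detector is Detector.UV:
        X += spec.baseline.evaluate(time, axis.values)
        X += spec.autozero_offset
    # one independent stream per (run, detector) so UV and MS runs are
    # individually reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, run_index, int(detector is Detector.MS)])
    )
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)

    meta = RunMeta(
        program=program,
        temperature=program.temperature,
        flow=spec.flow,
        column_id=spec.column_id,
        role=RunRole(spec.design.roles[run_index]),
    )
    return Chromatogram(
        run_id=f"run{run_index + 1}",
        time=time,
        axis=axis,
        intensity=X,
        detector=detector,
        meta=meta,
    )


def simulate_campaign(
    spec: CampaignSpec, with_ms: bool = False
) -> tuple[list[Chromatogram], GroundTruth, list[Chromatogram] | None]:
    """Generate the whole campaign: one chromatogram per design row.

    Returns (uv_runs, ground_truth, ms_runs-or-None).
    """
    uv_runs = []
    ms_runs: list[Chromatogram] | None = [] if with_ms else None
    truth_rows: list[dict] = []
    for i in range(spec.design.coded.shape[0]):
        uv_runs.append(simulate_run(spec, i, Detector.UV))
        if with_ms:
            ms_runs.append(simulate_run(spec, i, Detector.MS))
        _, rows = _run_truth(spec, i)
        truth_rows.extend(rows)
    return uv_runs, GroundTruth(pd.DataFrame(truth_rows)), ms_runs


def example_six_component_spec(
    seed: int = 0,
    noise_sd: float = 5e-4,
    n_validation: int = 1,
    amounts: tuple[float, ...] | None = None,
) -> CampaignSpec:
    """A six-component, three-factor (8 + 1 run) campaign used throughout the
    documentation and tests.

    Components have pairwise-distinct UV spectra (|r| < 0.9) and LSS
    parameters in the range typical of small phenolic solutes; amounts span a
    10-fold range and the default noise gives an apex signal-to-noise of
    roughly 100 for the weakest component.
    """
    from .design import FactorDef, add_validation_runs, build_design

    factors = [
        FactorDef("t_G", FactorRole.gradient_time, 5.0, 15.0),
        FactorDef("phi_0", FactorRole.phi_initial, 0.05, 0.20),
        FactorDef("T", FactorRole.temperature, 25.0, 45.0),
    ]
    dm = build_design(factors)
    if n_validation:
        dm = add_validation_runs(dm, n=n_validation, strategy="intermediate")
    axis = ChannelAxis(ChannelKind.wavelength_nm, np.arange(210.0, 400.0, 2.0))
    band_sets = [
        [(225.0, 9.0, 1.0), (275.0, 12.0, 0.55)],
        [(240.0, 10.0, 1.0), (320.0, 15.0, 0.40)],
        [(218.0, 7.0, 0.8), (255.0, 10.0, 1.0)],
        [(230.0, 8.0, 0.5), (300.0, 14.0, 1.0)],
        [(262.0, 11.0, 1.0), (350.0, 18.0, 0.35)],
        [(222.0, 8.0, 1.0), (238.0, 6.0, 0.9), (290.0, 10.0, 0.25)],
    ]
    lss = [
        LSSParams(1.6, 3.2, a_temp=-0.004),
        LSSParams(2.0, 3.8, a_temp=-0.005),
        LSSParams(2.4, 4.3, a_temp=-0.006),
        LSSParams(2.8, 4.9, a_temp=-0.005),
        LSSParams(3.1, 5.3, a_temp=-0.007),
        LSSParams(3.5, 5.8, a_temp=-0.006),
    ]
    if amounts is None:
        # 10-fold spread; with area-normalized peaks these give apex heights
        # of roughly 0.1-1.5 AU and apex S/N of ~200 for the weakest peak
        amounts = (0.10, 0.035, 0.08, 0.015, 0.055, 0.010)
    ms_spectra = [
        {137.0: 100.0, 93.0: 32.0},
        {153.0: 100.0, 109.0: 21.0},
        {163.0: 100.0, 119.0: 45.0, 91.0: 12.0},
        {179.0: 100.0, 135.0: 28.0},
        {181.0: 100.0, 166.0: 55.0},
        {193.0: 100.0, 178.0: 40.0, 149.0: 15.0},
    ]
    comps = [
        TrueComponent(
            name=f"C{i + 1}",
            lss=lss[i],
            uv_spectrum=gaussian_spectrum(axis.values, band_sets[i]),
            amount=amounts[i],
            ms_spectrum=ms_spectra[i],
        )
        for i in range(6)
    ]
    ms_axis = ChannelAxis(ChannelKind.mz, np.arange(50.0, 650.0) + 0.5)
    return CampaignSpec(
        components=comps,
        design=dm,
        uv_axis=axis,
        plates=8000.0,
        noise_sd=noise_sd,
        sampling_rate=5.0,
        seed=seed,
        ms_axis=ms_axis,
        ms_noise_sd=noise_sd * 0.1,
    )
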