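"""Per-component retention models from assigned retention times.

Two fitting modes are offered:

* ``lss`` (default): the physically structured fit.  The LSS parameters
  (log k0, S, and a linear temperature coefficient when temperature is a
  design factor) are estimated by nonlinear least squares, minimizing the
  squared difference between observed retention times and those produced by
  the stepwise gradient simulator under each calibration run's program.
  This is the mode the optimizer needs, because only LSS parameters let an
  arbitrary candidate program be simulated.

* ``pls``: direct empirical interpolation.  Retention time is regressed on
  the second-order expansion of the coded design factors by partial least
  squares, with the latent-variable count chosen by leave-one-out
  cross-validation on the calibration runs.  PLS tolerates the
  supersaturated 3-factor design (8 runs for 10 model terms).

Validation-role runs never enter either fit; their predictions are reported
separately so a bad assignment shows up as a large residual rather than
being absorbed into the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.cross_decomposition import PLSRegression

from .design import DesignMatrix, second_order_matrix
from .discovery import AssignmentTable, UnresolvedAlertError
from .gradsim import ElutionProgram, LSSParams, simulate_gradient

__all__ = [
    "RetentionModel",
    "InsufficientDataError",
    "fit_component",
    "fit_all",
    "goodness_of_fit",
    "invert_to_lss",
]


class InsufficientDataError(ValueError):
    """Fewer assigned calibration runs than model parameters."""


@dataclass
class RetentionModel:
    component_id: str
    column_id: str
    mode: str  # "lss" | "pls"
    lss: LSSParams | None
    coefficients: np.ndarray | None  # pls coefficients on expanded factors
    latent_variables: int | None
    r2_cal: float
    rmse_cal: float
    residuals: dict[str, float]  # calibration run -> observed - predicted (min)
    predictions_cal: dict[str, tuple[float, float]]  # run -> (obs, pred)
    predictions_val: dict[str, tuple[float, float]]  # validation run -> (obs, pred)
    pls_state: tuple | None = None  # (model, x_mean-free expansion cache)

    def predict_program(self, program: ElutionProgram, dt: float | None = None) -> float:
        if self.mode != "lss" or self.lss is None:
            raise ValueError("program prediction requires an lss-mode model")
        tR, _ = simulate_gradient(self.lss, program, dt=dt)
        return tR


def fit_component(
    component_id: str,
    tR_by_run: dict[str, float],
    design: DesignMatrix,
    programs: dict[str, ElutionProgram],
    mode: str = "lss",
    column_id: str = "",
    dt: float | None = None,
) -> RetentionModel:
    """Fit one component's retention model from its assigned retention times.

    ``tR_by_run`` maps run ids (matching the design's ``run1..runN`` naming)
    to assigned retention times in minutes; unassigned or alert cells are
    simply absent.  Runs with role "validation" are held out and predicted.
    """
    run_ids = [f"run{i + 1}" for i in range(design.coded.shape[0])]
    roles = dict(zip(run_ids, design.roles))
    cal_runs = [r for r in run_ids if r in tR_by_run and roles[r] == "calibration"]
    val_runs = [r for r in run_ids if r in tR_by_run and roles[r] == "validation"]

    if mode == "lss":
        return _fit_lss(
            component_id, tR_by_run, cal_runs, val_runs, programs, column_id, dt
        )
    if mode == "pls":
        return _fit_pls(
            component_id, tR_by_run, cal_runs, val_runs, design, run_ids, column_id
        )
    raise ValueError(f"unknown mode {mode!r}")


def _fit_lss(
    component_id: str,
    tR_by_run: dict[str, float],
    cal_runs: list[str],
    val_runs: list[str],
    programs: dict[str, ElutionProgram],
    column_id: str,
    dt: float | None,
) -> RetentionModel:
    temps = {programs[r].temperature for r in cal_runs}
    with_temp = len(temps) > 1
    n_par = 3 if with_temp else 2
    if len(cal_runs) < n_par:
        raise InsufficientDataError(
            f"component {component_id}: {len(cal_runs)} assigned calibration "
            f"runs but the LSS model needs {n_par}"
        )
    t_ref = float(np.mean(sorted(temps)))
    obs = np.array([tR_by_run[r] for r in cal_runs])
    progs = [programs[r] for r in cal_runs]

    def residual(theta: np.ndarray) -> np.ndarray:
        lk0, S = theta[0], theta[1]
        aT = theta[2] if with_temp else 0.0
        p = LSSParams(lk0, max(S, 1e-6), a_temp=aT, t_ref=t_ref)
        sim = np.array([simulate_gradient(p, pr, dt=dt)[0] for pr in progs])
        sim[~np.isfinite(sim)] = 1e3
        return sim - obs

    # coarse grid start, then refine
    best = None
    for lk0 in (1.0, 2.0, 3.0, 4.0):
        for S in (2.0, 4.0, 6.0):
            theta0 = np.array([lk0, S] + ([0.0] if with_temp else []))
            sse = float(np.sum(residual(theta0) ** 2))
            if best is None or sse < best[0]:
                best = (sse, theta0)
    lo = [-1.0, 0.05] + ([-0.2] if with_temp else [])
    hi = [8.0, 30.0] + ([0.2] if with_temp else [])
    sol = least_squares(residual, best[1], bounds=(lo, hi), xtol=1e-10, ftol=1e-12)
    theta = sol.x
    lss = LSSParams(
        theta[0], theta[1], a_temp=(theta[2] if with_temp else 0.0), t_ref=t_ref
    )

    pred_cal = {
        r: (tR_by_run[r], simulate_gradient(lss, programs[r], dt=dt)[0])
        for r in cal_runs
    }
    pred_val = {
        r: (tR_by_run[r], simulate_gradient(lss, programs[r], dt=dt)[0])
        for r in val_runs
    }
    residuals = {r: o - p for r, (o, p) in pred_cal.items()}
    r2, rmse = _r2_rmse(pred_cal)
    return RetentionModel(
        component_id=component_id,
        column_id=column_id,
        mode="lss",
        lss=lss,
        coefficients=None,
        latent_variables=None,
        r2_cal=r2,
        rmse_cal=rmse,
        residuals=residuals,
        predictions_cal=pred_cal,
        predictions_val=pred_val,
    )


def _fit_pls(
    component_id: str,
    tR_by_run: dict[str, float],
    cal_runs: list[str],
    val_runs: list[str],
    design: DesignMatrix,
    run_ids: list[str],
    column_id: str,
) -> RetentionModel:
    idx = {r: i for i, r in enumerate(run_ids)}
    Xfull = second_order_matrix(design.coded)[:, 1:]  # drop intercept, PLS centers
    Xcal = Xfull[[idx[r] for r in cal_runs]]
    y = np.array([tR_by_run[r] for r in cal_runs])
    n = len(cal_runs)
    if n < 3:
        raise InsufficientDataError(
            f"component {component_id}: PLS needs at least 3 assigned "
            f"calibration runs, got {n}"
        )
    max_lv = max(1, min(n - 2, Xcal.shape[1]))
    best_lv, best_press = 1, np.inf
    import warnings as _warnings

    with _warnings.catch_warnings():
        # sklearn warns when a latent variable exhausts the y residual; here
        # that just means fewer useful components than requested
        _warnings.filterwarnings("ignore", message="y residual is constant")
        for lv in range(1, max_lv + 1):
            press = 0.0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                m = PLSRegression(n_components=lv, scale=False)
                m.fit(Xcal[mask], y[mask])
                press += float((m.predict(Xcal[[i]]).ravel()[0] - y[i]) ** 2)
            if press < best_press - 1e-12:
                best_press, best_lv = press, lv
        model = PLSRegression(n_components=best_lv, scale=False)
        model.fit(Xcal, y)

    def predict(rs: list[str]) -> dict[str, tuple[float, float]]:
        if not rs:
            return {}
        P = model.predict(Xfull[[idx[r] for r in rs]]).ravel()
        return {r: (tR_by_run[r], float(p)) for r, p in zip(rs, P)}

    pred_cal = predict(cal_runs)
    pred_val = predict(val_runs)
    residuals = {r: o - p for r, (o, p) in pred_cal.items()}
    r2, rmse = _r2_rmse(pred_cal)
    return RetentionModel(
        component_id=component_id,
        column_id=column_id,
        mode="pls",
        lss=None,
        coefficients=np.asarray(model.coef_).ravel(),
        latent_variables=best_lv,
        r2_cal=r2,
        rmse_cal=rmse,
        residuals=residuals,
        predictions_cal=pred_cal,
        predictions_val=pred_val,
        pls_state=(model,),
    )


def _r2_rmse(pred: dict[str, tuple[float, float]]) -> tuple[float, float]:
    obs = np.array([o for o, _ in pred.values()])
    est = np.array([p for _, p in pred.values()])
    ss_res = float(np.sum((obs - est) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / len(obs)))
    return r2, rmse


def fit_all(
    table: AssignmentTable,
    design: DesignMatrix,
    programs: dict[str, ElutionProgram],
    mode: str = "lss",
    column_id: str = "",
    allow_alerts: bool = False,
    dt: float | None = None,
) -> dict[int, RetentionModel]:
    """Fit every catalog entry in an assignment table.

    Refuses to run while unresolved alert cells remain, unless waived: an
    alert marks an assignment the chromatographer has not yet verified, and
    silently modelling around it defeats the diagnostics.
    """
    alerts = table.alert_cells()
    if alerts and not allow_alerts:
        raise UnresolvedAlertError(
            f"{len(alerts)} unresolved alert cell(s) remain "
            f"(e.g. entry {alerts[0][0]} in {alerts[0][1]}); resolve them or "
            "pass allow_alerts=True"
        )
    models: dict[int, RetentionModel] = {}
    for eid in table.entries:
        tRs = table.tR_row(eid)
        try:
            models[eid] = fit_component(
                str(eid), tRs, design, programs, mode=mode, column_id=column_id, dt=dt
            )
        except InsufficientDataError:
            continue
    return models


def goodness_of_fit(model: RetentionModel) -> dict:
    """Observed-vs-predicted summary with flagged outlier runs.

    Calibration and validation pairs are kept separate; runs whose
    standardized residual exceeds 3 in magnitude are flagged as suspect
    assignments.
    """
    res = np.array(list(model.residuals.values()))
    sd = float(res.std(ddof=1)) if res.size > 1 else 0.0
    standardized = {
        r: (v / sd if sd > 0 else 0.0) for r, v in model.residuals.items()
    }
    rmse_check = float(np.sqrt(np.mean(res**2))) if res.size else 0.0
    return {
        "component_id": model.component_id,
        "mode": model.mode,
        "r2": model.r2_cal,
        "rmse": rmse_check,
        "calibration": model.predictions_cal,
        "validation": model.predictions_val,
        "standardized_residuals": standardized,
        "flagged_runs": [r for r, z in standardized.items() if abs(z) > 3.0],
    }


def invert_to_lss(
    model_or_points: RetentionModel | list[tuple[float, float]],
    t0: float | None = None,
) -> LSSParams:
    """Recover (log k0, S) usable by the gradient simulator.

    For an lss-mode model this is the identity.  Alternatively a list of
    isocratic observations ``(phi, k)`` is accepted and fitted by a straight
    line in (phi, log10 k); at least two distinct phi values are required.
    """
    if isinstance(model_or_points, RetentionModel):
        if model_or_points.lss is not None:
            return model_or_points.lss
        raise ValueError(
            "pls-mode models carry no LSS parameters; refit in lss mode or "
            "supply isocratic (phi, k) points"
        )
    pts = list(model_or_points)
    phis = np.array([p for p, _ in pts])
    ks = np.array([k for _, k in pts])
    if np.ptp(phis) == 0:
        raise ValueError("phi does not vary; S is not identifiable")
    slope, intercept = np.polyfit(phis, np.log10(ks), 1)
    return LSSParams(log_k0=float(intercept), S=float(-slope))
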