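"""Screening experimental designs for retention-model calibration.

Economical irregular second-order (Hoke-type D6) designs are used so the
calibration stays desk-scale: 2, 6, 8 and 18 runs for 1 to 4 factors.  The
6- and 18-run designs support the full second-order polynomial; the 8-run
3-factor design is supersaturated for the 10-term full quadratic (maximal
rank 8), which is why downstream retention fitting offers PLS.

Gradient time must be screened over at least a 3:1 ratio so the solvent-
strength slope is identifiable; the builder refuses narrower ranges unless
asked to widen them.  pH is refused as a factor under UV-only detection
because it shifts the very spectra the discovery step correlates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FactorRole",
    "FactorDef",
    "DesignMatrix",
    "hoke_d6",
    "gradient_time_factor",
    "scale_to_real",
    "unscale_to_coded",
    "build_design",
    "add_validation_runs",
    "second_order_matrix",
    "write_design_csv",
    "read_design_csv",
]

MIN_GRADIENT_TIME_RATIO = 3.0


class FactorRole(str, Enum):
    gradient_time = "gradient_time"
    phi_initial = "phi_initial"
    phi_final = "phi_final"
    temperature = "temperature"
    ph = "ph"
    other = "other"


@dataclass(frozen=True)
class FactorDef:
    name: str
    role: FactorRole
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name}: low must be < high")
        if self.role is FactorRole.gradient_time and self.high / self.low < MIN_GRADIENT_TIME_RATIO:
            raise ValueError(
                f"gradient-time levels must span a ratio of at least "
                f"{MIN_GRADIENT_TIME_RATIO}:1 (got {self.high / self.low:.2f}); "
                "widen the range or use gradient_time_factor(..., widen=True)"
            )


@dataclass
class DesignMatrix:
    factors: list[FactorDef]
    coded: np.ndarray  # (n_runs, n_factors) in [-1, 1]
    roles: list[str]  # per-row "calibration" | "validation"

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix shape does not match factors")
        if np.any(np.abs(self.coded) > 1 + 1e-12):
            raise ValueError("coded entries must lie in [-1, 1]")
        if len(self.roles) != self.coded.shape[0]:
            raise ValueError("one role per design row required")

    @property
    def real_values(self) -> np.ndarray:
        return scale_to_real(self.coded, self.factors)

    @property
    def n_calibration(self) -> int:
        return sum(r == "calibration" for r in self.roles)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.real_values, columns=[f.name for f in self.factors])
        df.insert(0, "role", self.roles)
        df.insert(0, "run_id", [f"run{i + 1}" for i in range(len(self.roles))])
        return df


# Coded calibration matrices.  Row counts (2/6/8/18) are the design-family
# checksum; levels are drawn from {-1, 0, +1} and chosen so the second-order
# model matrix reaches maximal rank (full rank for 1, 2 and 4 factors).
_D6: dict[int, np.ndarray] = {
    1: np.array([[-1.0], [1.0]]),
    2: np.array(
        [
            [-1, -1],
            [1, -1],
            [-1, 1],
            [1, 1],
            [1, 0],
            [0, 1],
        ],
        dtype=float,
    ),
    3: np.array(
        [
            [-1, -1, -1],
            [1, 1, -1],
            [1, -1, 1],
            [-1, 1, 1],
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
            [-1, -1, 1],
        ],
        dtype=float,
    ),
    # D-optimal 18-run irregular fraction of 3^4; full second-order rank (15).
    4: np.array(
        [
            [-1, -1, -1, 1],
            [-1, -1, 0, -1],
            [-1, -1, 1, 0],
            [-1, 0, -1, -1],
            [-1, 0, 1, 1],
            [-1, 1, -1, 1],
            [-1, 1, 1, -1],
            [0, -1, 1, -1],
            [0, 0, 0, 0],
            [0, 1, -1, -1],
            [0, 1, 1, 1],
            [1, -1, -1, -1],
            [1, -1, -1, 1],
            [1, -1, 1, 1],
            [1, 0, 1, -1],
            [1, 1, -1, 1],
            [1, 1, 0, -1],
            [1, 1, 1, 0],
        ],
        dtype=float,
    ),
}


def hoke_d6(n_factors: int) -> np.ndarray:
    """Coded calibration design for 1-4 factors (2/6/8/18 runs)."""
    if n_factors not in _D6:
        raise ValueError("n_factors must be between 1 and 4")
    return _D6[n_factors].copy()


def scale_to_real(coded: np.ndarray, factors: list[FactorDef]) -> np.ndarray:
    """Affine map of coded levels to factor units: -1 -> low, +1 -> high."""
    coded = np.asarray(coded, dtype=float)
    if np.any(np.abs(coded) > 1 + 1e-12):
        raise ValueError("coded entries must lie in [-1, 1]")
    lows = np.array([f.low for f in factors])
    highs = np.array([f.high for f in factors])
    return lows + (coded + 1.0) * 0.5 * (highs - lows)


def unscale_to_coded(real: np.ndarray, factors: list[FactorDef]) -> np.ndarray:
    """Inverse of :func:`scale_to_real`."""
    real = np.asarray(real, dtype=float)
    lows = np.array([f.low for f in factors])
    highs = np.array([f.high for f in factors])
    return 2.0 * (real - lows) / (highs - lows) - 1.0


def gradient_time_factor(
    name: str, low: float, high: float, widen: bool = False
) -> FactorDef:
    """Gradient-time factor with the 3:1 level-ratio rule enforced.

    With ``widen=True`` a too-narrow range is stretched to the minimum ratio
    (with a warning) instead of being rejected.
    """
    if high / low < MIN_GRADIENT_TIME_RATIO:
        if not widen:
            # constructing the FactorDef raises the detailed error
            return FactorDef(name, FactorRole.gradient_time, low, high)
        new_high = low * MIN_GRADIENT_TIME_RATIO
        warnings.warn(
            f"gradient-time range widened to ({low}, {new_high}) to reach the "
            "required 3:1 level ratio",
            stacklevel=2,
        )
        high = new_high
    return FactorDef(name, FactorRole.gradient_time, low, high)


def build_design(
    factors: list[FactorDef],
    ms_detection: bool = False,
) -> DesignMatrix:
    """Build the coded calibration design for the given factors."""
    fixed: list[FactorDef] = []
    for f in factors:
        if f.role is FactorRole.ph:
            if not ms_detection:
                raise ValueError(
                    "pH cannot be screened with UV-only detection: it alters "
                    "the spectra the component-discovery correlation relies on"
                )
            warnings.warn(
                "screening pH: UV spectra may shift between runs; MS evidence "
                "will be needed to keep component assignment reliable",
                stacklevel=2,
            )
        fixed.append(f)
    coded = hoke_d6(len(fixed))
    return DesignMatrix(fixed, coded, ["calibration"] * coded.shape[0])


def add_validation_runs(
    dm: DesignMatrix, n: int = 1, strategy: str = "intermediate"
) -> DesignMatrix:
    """Append ``n`` validation rows not coincident with any calibration row.

    ``extreme`` places them at the slowest/fastest gradient settings of the
    factor ranges; ``intermediate`` at interior points, which eases the
    discovery step (less extreme overlap) at some cost in model stress-testing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if strategy not in ("extreme", "intermediate"):
        raise ValueError("strategy must be 'extreme' or 'intermediate'")
    existing = dm.coded
    rows: list[np.ndarray] = []
    if strategy == "extreme":
        for i in range(n):
            sign = 1.0 if i % 2 == 0 else -1.0
            cand = np.full(len(dm.factors), sign)
            # nudge off any coincident calibration corner
            shrink = 1.0
            while _coincides(cand * shrink, existing, rows):
                shrink -= 0.1
            rows.append(cand * shrink)
    else:
        # interior points on a shrinking diagonal lattice
        levels = [0.5, -0.5, 0.25, -0.25, 0.75, -0.75]
        k = 0
        while len(rows) < n:
            base = levels[k % len(levels)] * (0.9 ** (k // len(levels)))
            cand = np.full(len(dm.factors), base)
            cand[::2] *= -1.0 if (k % 2) else 1.0
            if not _coincides(cand, existing, rows):
                rows.append(cand)
            k += 1
    coded = np.vstack([existing, np.array(rows)])
    roles = list(dm.roles) + ["validation"] * n
    return DesignMatrix(dm.factors, coded, roles)


def _coincides(cand: np.ndarray, existing: np.ndarray, extra: list[np.ndarray]) -> bool:
    pool = [existing] + ([np.array(extra)] if extra else [])
    for mat in pool:
        if mat.size and np.any(np.all(np.abs(mat - cand) < 1e-9, axis=1)):
            return True
    return False


def second_order_matrix(coded: np.ndarray) -> np.ndarray:
    """Full second-order model matrix: intercept, linear, interaction,
    quadratic columns."""
    coded = np.asarray(coded, dtype=float)
    n, k = coded.shape
    cols = [np.ones(n)]
    cols.extend(coded[:, j] for j in range(k))
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(coded[:, i] * coded[:, j])
    cols.extend(coded[:, j] ** 2 for j in range(k))
    return np.column_stack(cols)


def write_design_csv(dm: DesignMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = dm.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_design_csv(path: str | Path, factors: list[FactorDef]) -> DesignMatrix:
    df = pd.read_csv(path)
    real = df[[f.name for f in factors]].to_numpy(dtype=float)
    coded = unscale_to_coded(real, factors)
    return DesignMatrix(factors, coded, list(df["role"]))
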