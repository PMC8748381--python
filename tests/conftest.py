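import numpy as np
import pytest

from chromforge.discovery import discover
from chromforge.synthgen import example_six_component_spec, simulate_campaign


@pytest.fixture(scope="session")
def campaign():
    """The packaged six-component screening campaign (8 calibration runs +
    1 intermediate validation run), simulated once per session."""
    spec = example_six_component_spec(seed=1)
    runs, truth, _ = simulate_campaign(spec)
    return spec, runs, truth


@pytest.fixture(scope="session")
def discovered(campaign):
    """Full discovery output for the session campaign."""
    _, runs, _ = campaign
    return discover(runs)


@pytest.fixture(scope="session")
def entry_truth_map(campaign, discovered):
    """Best-matching true component for every active catalog entry."""
    spec, _, _ = campaign
    catalog, _, _ = discovered
    out = {}
    for e in catalog.active_entries:
        rs = {
            c.name: float(np.corrcoef(c.uv_spectrum, e.spectrum)[0, 1])
            for c in spec.components
        }
        name = max(rs, key=rs.get)
        out[e.entry_id] = (name, rs[name])
    return out


def two_component_cluster(
    sep_sigma: float = 2.0,
    n_t: int = 80,
    amp2: float = 0.6,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Noise-free (or noisy) bilinear rank-2 cluster with unimodal profiles
    and moderately correlated spectra; returns (X, C_true, S_true)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_t, dtype=float)
    sigma = 6.0
    c1 = np.exp(-0.5 * ((t - (n_t / 2 - sep_sigma * sigma / 2)) / sigma) ** 2)
    c2 = amp2 * np.exp(-0.5 * ((t - (n_t / 2 + sep_sigma * sigma / 2)) / sigma) ** 2)
    lam = np.linspace(210, 400, 60)
    s1 = np.exp(-0.5 * ((lam - 240) / 15) ** 2) + 0.4 * np.exp(-0.5 * ((lam - 300) / 20) ** 2)
    s2 = np.exp(-0.5 * ((lam - 262) / 12) ** 2) + 0.3 * np.exp(-0.5 * ((lam - 350) / 18) ** 2)
    X = np.outer(c1, s1) + np.outer(c2, s2)
    if noise_sd:
        X = X + rng.normal(0, noise_sd, X.shape)
    return X, np.column_stack([c1, c2]), np.column_stack([s1, s2])


def spectrum_with_correlation(base: np.ndarray, r: float, seed: int = 0) -> np.ndarray:
    """Non-negative spectrum whose Pearson correlation with ``base`` is
    exactly ``r`` (Pearson is shift-invariant, so a positive offset keeps
    non-negativity without changing r)."""
    rng = np.random.default_rng(seed)
    a = base - base.mean()
    a = a / np.linalg.norm(a)
    u = rng.normal(size=base.size)
    u = u - u.mean()
    u = u - (u @ a) * a
    u = u / np.linalg.norm(u)
    z = r * a + np.sqrt(max(1.0 - r * r, 0.0)) * u
    z = z - z.min() + 0.05
    assert abs(np.corrcoef(z, base)[0, 1] - r) < 1e-9
    return z
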