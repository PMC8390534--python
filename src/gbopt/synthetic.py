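"""Synthetic yield surfaces and simulated experiments for pipeline validation.

Real gardenia-blue yields come from a chemistry whose true response surface
is unknown; to test the analysis end-to-end we generate surfaces with the
qualitative structure the study observed — a unimodal temperature optimum in
the 80–95 °C range, saturating dose–response in both substrates, and a
rise-then-plateau time effect — plus additive Gaussian measurement noise.
Because the ground-truth optimum of a generated surface is known (by dense
grid search), the full design → simulate → train → optimize pipeline can be
scored on how well it recovers that optimum.

Per-factor effects are normalized to peak at 1 and combined multiplicatively
by default, so yield collapses whenever any single factor is unfavourable
(no substrate → no pigment); an additive combination is available for
robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import DesignTable
from .ga import GAConfig, run_ga
from .surrogate import TrainConfig, train_gdx

#: Experimental box of the reference study (temperature, geniposide, glycine, time).
DEFAULT_BOUNDS = ((40.0, 100.0), (240.0, 480.0), (2.0, 14.0), (5.0, 180.0))


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a synthetic ground-truth yield surface.

    Defaults emulate the reference study's observed single-factor shapes:
    temperature bump centred at 87 °C, substrate half-saturation well inside
    the dose range, time constant of 60 min, and a peak yield amplitude of
    20 μg/mL with ~0.5 μg/mL measurement noise.
    """

    temp_peak: float = 87.0  # °C, centre of the Gaussian temperature effect
    temp_width: float = 18.0  # °C, scale of the bump
    geni_half: float = 120.0  # μg/mL, Michaelis half-saturation dose
    glyc_half: float = 3.0  # μg/mL, half-saturation dose
    time_scale: float = 60.0  # min, saturating-rise time constant
    amplitude: float = 20.0  # μg/mL, yield at the joint optimum
    combine: str = "product"  # "product" or "additive"
    noise_sd: float = 0.5  # μg/mL, additive Gaussian noise
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.combine not in ("product", "additive"):
            raise ValueError("combine must be 'product' or 'additive'")


@dataclass(frozen=True)
class Surface:
    """A deterministic yield function with its grid-searched true optimum."""

    spec: SurfaceSpec
    true_argmax: np.ndarray
    true_peak: float

    def __call__(self, x) -> np.ndarray:
        return _evaluate_surface(self.spec, x)


def _factor_effects(spec: SurfaceSpec, X: np.ndarray) -> np.ndarray:
    """Per-factor effects in [0, 1]; each attains 1 inside/at the box edge."""
    (t_lo, t_hi), (g_lo, g_hi), (y_lo, y_hi), (m_lo, m_hi) = spec.bounds
    T, G, Y, M = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    eff = np.empty_like(X, dtype=float)
    eff[:, 0] = np.exp(-(((T - spec.temp_peak) / spec.temp_width) ** 2))
    # saturating doses, normalized so the upper bound maps to 1
    eff[:, 1] = (G / (spec.geni_half + G)) / (g_hi / (spec.geni_half + g_hi))
    eff[:, 2] = (Y / (spec.glyc_half + Y)) / (y_hi / (spec.glyc_half + y_hi))
    eff[:, 3] = (1.0 - np.exp(-M / spec.time_scale)) / (
        1.0 - np.exp(-m_hi / spec.time_scale)
    )
    return eff


def _evaluate_surface(spec: SurfaceSpec, x) -> np.ndarray:
    X = np.atleast_2d(np.asarray(x, dtype=float))
    eff = _factor_effects(spec, X)
    if spec.combine == "product":
        out = spec.amplitude * eff.prod(axis=1)
    else:
        out = spec.amplitude * eff.mean(axis=1)
    out = np.maximum(out, 0.0)
    return out if np.ndim(x) == 2 else out[0]


def make_surface(spec: SurfaceSpec, grid_points: int = 25) -> Surface:
    """Build the surface and record its dense-grid argmax as ground truth.

    A ``grid_points``⁴ lattice over the box (default 25⁴ ≈ 391k points) is
    evaluated vectorized; the best lattice point is the reference optimum,
    accurate to one grid step per axis.
    """
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in spec.bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = _evaluate_surface(spec, pts)
    best = int(np.argmax(vals))
    return Surface(spec=spec, true_argmax=pts[best].copy(), true_peak=float(vals[best]))


def simulate_runs(
    design: DesignTable, surface: Surface, noise_sd: float | None = None, seed: int = 0
) -> np.ndarray:
    """Noisy yields for a design: surface(x) + N(0, σ²), truncated at zero."""
    X = design.values
    for f, (lo, hi) in enumerate(surface.spec.bounds):
        if X[:, f].min() < lo or X[:, f].max() > hi:
            raise ValueError(f"design column {f} leaves the surface box [{lo}, {hi}]")
    sd = surface.spec.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    y = surface(X) + rng.normal(0.0, sd, size=X.shape[0]) if sd > 0 else surface(X)
    return np.maximum(np.asarray(y, dtype=float), 0.0)


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered a known synthetic optimum."""

    estimated_x: np.ndarray
    estimated_peak: float
    true_x: np.ndarray
    true_peak: float
    argmax_error_frac: np.ndarray  # |Δx| per factor, as a fraction of its span
    peak_rel_error: float


def recovery_experiment(
    spec: SurfaceSpec,
    design: DesignTable,
    hidden: int = 8,
    train_config: TrainConfig | None = None,
    ga_config: GAConfig | None = None,
    seed: int = 0,
) -> RecoveryReport:
    """Run design → simulate → train → optimize against a known surface.

    All stage seeds derive from ``seed``.  The report compares the GA's
    condition estimate and predicted peak with the surface's grid-searched
    truth; argmax errors are normalized by each factor's box span.
    """
    rng = np.random.default_rng(seed)
    s_sim, s_train, s_ga = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    surface = make_surface(spec)
    y = simulate_runs(design, surface, seed=s_sim)

    t_cfg = train_config or TrainConfig()
    t_cfg = replace(t_cfg, seed=s_train)
    model, _ = train_gdx(design.values, y, hidden, t_cfg)

    lo = tuple(b[0] for b in spec.bounds)
    hi = tuple(b[1] for b in spec.bounds)
    g_cfg = ga_config or GAConfig()
    g_cfg = replace(g_cfg, lower_bounds=lo, upper_bounds=hi, seed=s_ga)
    result = run_ga(lambda x: float(model.predict(x)[0]), g_cfg)

    span = np.array(hi) - np.array(lo)
    argmax_err = np.abs(result.best_x - surface.true_argmax) / span
    peak_err = abs(result.best_fitness - surface.true_peak) / surface.true_peak
    return RecoveryReport(
        estimated_x=result.best_x,
        estimated_peak=result.best_fitness,
        true_x=surface.true_argmax,
        true_peak=surface.true_peak,
        argmax_error_frac=argmax_err,
        peak_rel_error=peak_err,
    )
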