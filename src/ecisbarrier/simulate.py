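"""Synthetic ECIS experiments: culture growth, RD damage, and stress metrics.

Two generator tiers are provided. The mechanistic tier drives the
Giaever-Keese forward model with time- or cycle-dependent parameters and
produces full spectra (exercising the whole inversion pipeline); the
phenomenological tier writes the surrogate traces directly from the two-phase
damage law (a confluent plateau followed by R0 exp(-lambda (N-N_P1)) + R_F),
which is exact and fast and is what the fitting layers are tested against.

Randomness is fully deterministic: every stream derives from
(seed, node_id), so adding nodes never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gk import GKParams, NakedElectrodeParams, default_naked, extract_surrogates, gk_forward
from .io import DEFAULT_FREQUENCIES, SpectrumSeries, SurrogateTrace, node_area_cm2

__all__ = [
    "SimConfig",
    "TrajectorySpec",
    "StressInputs",
    "simulate_culture",
    "simulate_rd_experiment",
    "make_phenomenological_traces",
    "simulate_case_cohort",
    "stress_metrics",
]

REFERENCE_SEEDING_DENSITY = 160_000.0  # cells/cm^2


@dataclass
class SimConfig:
    """Shared generator settings.

    noise_cv is the multiplicative magnitude-noise coefficient of variation
    per spectrum point; node_heterogeneity_cv bounds the node-to-node spread
    of layer properties (the instrument shows up to ~15% spread between
    nodes, so the default 0.10 stays inside that cap).
    """

    seed: int
    n_nodes: int = 8
    epoch_size: int = 10
    n_max_cycles: int = 500
    noise_cv: float = 0.03
    node_heterogeneity_cv: float = 0.10
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_FREQUENCIES.copy())
    naked: NakedElectrodeParams | None = None
    area: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must lie in [0, 1)")
        if not 0.0 <= self.node_heterogeneity_cv < 1.0:
            raise ValueError("node_heterogeneity_cv must lie in [0, 1)")
        if self.epoch_size < 1:
            raise ValueError("epoch_size must be >= 1")
        if self.naked is None:
            self.naked = default_naked()
        if self.area is None:
            self.area = node_area_cm2()

    def node_rng(self, node_id: int) -> np.random.Generator:
        """Independent substream for one node, stable under added nodes."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), int(node_id))))


@dataclass
class TrajectorySpec:
    """Mechanistic two-phase damage trajectory in GK-parameter space.

    Phase 1 (N <= N_P1): coverage stays 1, the tight-junction resistance
    declines linearly to exactly 0 at N_P1 while alpha rises by
    ``alpha_rise_frac`` (sub-cellular gap compression); Phase 2 (N > N_P1):
    Rb = 0 and coverage decays as exp(-lambda_cov (N - N_P1)).
    """

    rb_init: float = 10.0
    alpha_init: float = 6.0
    cm: float = 1.0
    n_p1_mean: float = 200.0
    n_p1_sd: float = 15.0
    lambda_cov: float = 0.01
    alpha_rise_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rb_init", "alpha_init", "cm", "lambda_cov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_p1_mean < 0:
            raise ValueError("n_p1_mean must be >= 0")


@dataclass
class StressInputs:
    """Scalar inputs of the interfacial stress metrics.

    gamma: surface tension, mN/m; radius: air-liquid interface radius
    (airway caliber), mm; viscosity: lining-fluid viscosity, mPa*s;
    velocity: interface speed, mm/s; length: travel amplitude, mm.
    """

    gamma: float = 70.0
    radius: float = 0.175
    viscosity: float = 1.0
    velocity: float = 0.5
    length: float = 50.0

    def __post_init__(self) -> None:
        for name in ("gamma", "radius", "viscosity", "velocity", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _noisy_spectrum(z: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative magnitude noise plus a small phase jitter."""
    if cv == 0.0:
        return z
    mag = 1.0 + cv * rng.standard_normal(z.shape)
    phase = np.exp(1j * 0.1 * cv * rng.standard_normal(z.shape))
    return z * mag * phase


def _node_multiplier(rng: np.random.Generator, cv: float) -> float:
    # uniform in [1-cv, 1+cv]: keeps the node spread strictly inside the cap
    return 1.0 + cv * rng.uniform(-1.0, 1.0)


def simulate_culture(
    config: SimConfig,
    seeding_density: float = REFERENCE_SEEDING_DENSITY,
    culture_time_h: float = 36.0,
    rb_plateau: float = 20.0,
    alpha_plateau: float = 3.0,
    cm: float = 1.0,
    sample_every_h: float = 2.0,
) -> SpectrumSeries:
    """Impedance spectra of a growing layer over culture time.

    Coverage rises logistically during the attachment/spreading period and is
    essentially complete by ~12 h at the reference density; tight-junction
    resistance rises logistically afterwards with a half-time inversely
    proportional to seeding density, so halving the density roughly doubles
    the time needed to reach a given barrier level.
    """
    density_factor = REFERENCE_SEEDING_DENSITY / seeding_density
    t_half_phi = 6.0 * density_factor
    tau_phi = 1.5 * density_factor
    t_half_rb = 20.0 * density_factor
    tau_rb = 3.0 * density_factor
    times = np.arange(0.0, culture_time_h + 1e-9, sample_every_h)
    records = []
    for node in range(1, config.n_nodes + 1):
        rng = config.node_rng(node)
        mult = _node_multiplier(rng, config.node_heterogeneity_cv)
        for t in times:
            phi = 1.0 / (1.0 + np.exp(-(t - t_half_phi) / tau_phi))
            rb = mult * rb_plateau / (1.0 + np.exp(-(t - t_half_rb) / tau_rb))
            alpha = alpha_plateau / (1.0 + np.exp(-(t - t_half_phi) / tau_phi))
            p = GKParams(rb=rb, alpha=alpha, cm=cm, coverage=phi)
            z = gk_forward(p, config.naked, config.frequencies, config.area)
            z = _noisy_spectrum(z, config.noise_cv, rng)
            records.extend(
                (node, t, f, zv) for f, zv in zip(config.frequencies, z)
            )
    return SpectrumSeries.from_records(records, obs_axis="culture_hours")


def simulate_rd_experiment(
    config: SimConfig, trajectory: TrajectorySpec
) -> tuple[SpectrumSeries, list[SurrogateTrace]]:
    """Mechanistic RD damage experiment: spectra and surrogate traces per node.

    Each node draws its Phase-1 length from Normal(n_p1_mean, n_p1_sd),
    snapped to the epoch grid and truncated at 0 (immediate-failure layers).
    Spectra are sampled at epoch boundaries only, since impedance can only be
    read with the chamber refilled between RD epochs.
    """
    n_grid = np.arange(0.0, config.n_max_cycles + 1e-9, config.epoch_size)
    records = []
    traces = []
    for node in range(1, config.n_nodes + 1):
        rng = config.node_rng(node)
        mult = _node_multiplier(rng, config.node_heterogeneity_cv)
        draw = rng.normal(trajectory.n_p1_mean, trajectory.n_p1_sd)
        np1 = max(round(draw / config.epoch_size) * config.epoch_size, 0.0)
        rb_i = trajectory.rb_init * mult
        r1k, c64k = [], []
        for n in n_grid:
            if np1 > 0 and n <= np1:
                frac = n / np1
                rb = rb_i * (1.0 - frac)
                alpha = trajectory.alpha_init * (1.0 + trajectory.alpha_rise_frac * frac)
                phi = 1.0
            else:
                rb = 0.0
                alpha = trajectory.alpha_init * (1.0 + trajectory.alpha_rise_frac)
                phi = float(np.exp(-trajectory.lambda_cov * (n - np1)))
            p = GKParams(rb=rb, alpha=alpha, cm=trajectory.cm, coverage=phi)
            z = gk_forward(p, config.naked, config.frequencies, config.area)
            z = _noisy_spectrum(z, config.noise_cv, rng)
            records.extend((node, n, f, zv) for f, zv in zip(config.frequencies, z))
            pair = extract_surrogates(config.frequencies, z)
            r1k.append(pair.r1k)
            c64k.append(pair.c64k)
        traces.append(
            SurrogateTrace(
                node_id=node,
                n=n_grid.copy(),
                r1k=np.array(r1k),
                c64k=np.array(c64k),
                epoch_size=config.epoch_size,
            )
        )
    series = SpectrumSeries.from_records(records, obs_axis="cumulative_rd_cycles")
    return series, traces


def make_phenomenological_traces(
    r_plateau: float = 8020.0,
    n_p1: float = 208.0,
    lam: float = 0.0107,
    r_f: float = 1200.0,
    c_base: float = 3.0,
    c_free: float = 12.0,
    c_rate: float | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    epoch_size: int = 10,
    n_max: int = 500,
    node_id: int = 1,
) -> SurrogateTrace:
    """Direct two-phase surrogate trace from the damage law (fast path).

    R(1K) holds ``r_plateau`` through Phase 1 and then follows
    (r_plateau - r_f) exp(-lam (N - n_p1)) + r_f; C(64K) holds ``c_base``
    and then relaxes toward the cell-free ``c_free`` with rate ``c_rate``
    (default: the same lam), sharing the changepoint. Noise is multiplicative
    Gaussian with the given CV, drawn from a (seed, node_id) substream.
    """
    if c_rate is None:
        c_rate = lam
    n = np.arange(0.0, n_max + 1e-9, epoch_size)
    phase2 = n > n_p1
    r = np.full_like(n, float(r_plateau))
    r[phase2] = (r_plateau - r_f) * np.exp(-lam * (n[phase2] - n_p1)) + r_f
    c = np.full_like(n, float(c_base))
    c[phase2] = c_free + (c_base - c_free) * np.exp(-c_rate * (n[phase2] - n_p1))
    if noise_cv > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(node_id))))
        r = r * (1.0 + noise_cv * rng.standard_normal(r.shape))
        c = c * (1.0 + noise_cv * rng.standard_normal(c.shape))
    return SurrogateTrace(node_id=node_id, n=n, r1k=r, c64k=c, epoch_size=epoch_size)


def simulate_case_cohort(
    config: SimConfig,
    n_p1_mean: float,
    n_p1_sd: float,
    lam: float,
    r_plateau: float = 8020.0,
    r_f: float = 1200.0,
    c_base: float = 3.0,
    c_free: float = 12.0,
) -> tuple[list[SurrogateTrace], np.ndarray]:
    """Phenomenological cohort of one culture condition.

    Each node draws its true Phase-1 length from Normal(n_p1_mean, n_p1_sd),
    snapped to the epoch grid and truncated at 0, then emits the two-phase
    damage law with R(1K) decay constant ``lam`` and multiplicative noise at
    the configured CV. Returns the traces together with the true per-node
    Phase-1 lengths (the recovery oracle).
    """
    traces, truth = [], []
    for node in range(1, config.n_nodes + 1):
        rng = config.node_rng(node)
        mult = _node_multiplier(rng, config.node_heterogeneity_cv)
        draw = rng.normal(n_p1_mean, n_p1_sd)
        np1 = max(round(draw / config.epoch_size) * config.epoch_size, 0.0)
        traces.append(
            make_phenomenological_traces(
                r_plateau=r_plateau * mult,
                n_p1=np1,
                lam=lam,
                r_f=r_f,
                c_base=c_base,
                c_free=c_free,
                noise_cv=config.noise_cv,
                seed=config.seed,
                epoch_size=config.epoch_size,
                n_max=config.n_max_cycles,
                node_id=node,
            )
        )
        truth.append(np1)
    return traces, np.array(truth)


def stress_metrics(inputs: StressInputs) -> dict:
    """Scalar stress metrics of one RD maneuver.

    Returns the Laplace pressure drop dP = gamma / R across the air-liquid
    interface (Pa), the capillary number Ca = mu U / gamma (dimensionless
    ratio of viscous to surface-tension forces), and the cycle period 2L/U
    (s) of one full forward-and-back traverse.
    """
    dp_pa = inputs.gamma / inputs.radius  # (mN/m) / mm = Pa
    ca = (inputs.viscosity * 1e-3) * (inputs.velocity * 1e-3) / (inputs.gamma * 1e-3)
    period_s = 2.0 * inputs.length / inputs.velocity
    return {"delta_p_pa": dp_pa, "capillary_number": ca, "cycle_period_s": period_s}
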