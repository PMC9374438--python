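"""Synthetic turbulent-plume signal generator.

Emulates the statistical structure of odor concentration sampled on a
horizontal plane downwind of a concentrated source: inside a cone-shaped
detection region the signal is intermittent — discrete whiffs of odor
separated by blanks — with whiff intensity decaying and intermittency
varying monotonically with distance from the source.

Each in-cone grid cell carries an independent alternating-renewal
("telegraph") process: blank durations are exponential with mean
``tau_b(r)``, whiff durations exponential with mean ``tau_w(r)``, and each
whiff is assigned a log-normal amplitude around a deterministic power-law
envelope ``C(r)``. Intensity decay (via the exponent ``alpha``) and sparsity
(via the duration laws) are independently tunable, which is the property the
downstream feature-ranking analysis needs. The generator is a statistical
stand-in for a resolved turbulent-transport simulation; it reproduces
renewal statistics, not fluid dynamics.

Time is measured in units of the smallest turbulent timescale (one
Kolmogorov time per snapshot by default); lengths in grid-cell units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PlumeConfig",
    "PlumeRealization",
    "GroundTruthLaws",
    "generate_plume",
    "ground_truth_laws",
    "concentrated_config",
    "dilute_config",
]

SparsityProfile = Literal["concentrated", "dilute", "custom"]

#: duration-law distance exponents (whiff, blank) implied by each profile tag
_PROFILE_EXPONENTS = {
    # weak blank-duration decay: sparsity eases slightly downwind (the
    # near-source signal is the most intermittent), but the intensity
    # envelope carries most of the distance signal
    "concentrated": (0.0, -0.35),
    # blanks shorten downwind at fixed whiff duration: the signal is
    # sparsest near the source and fills in with distance, while the cycle
    # time stays short relative to the analysis window; the -1 exponent
    # keeps the relative blank-duration gradient constant in r
    "dilute": (0.0, -1.0),
}


class ConfigurationError(ValueError):
    """Raised when a plume configuration violates its invariants."""


@dataclass(frozen=True)
class PlumeConfig:
    """Parameters of the synthetic plume.

    Parameters
    ----------
    domain_length : float
        Downwind extent ``R`` of the simulated domain (cone length upper
        bound), in grid-cell length units.
    cone_half_angle : float
        Half-opening angle of the emission cone, radians, in ``(0, pi/2)``.
    grid_shape : (int, int)
        Number of cells downwind x crosswind.
    n_frames : int
        Number of snapshots in the record.
    dt : float
        Time per snapshot; one Kolmogorov time by convention.
    source_intensity : float
        Concentration scale ``c0`` of the envelope at the source.
    intensity_decay_exponent : float
        ``alpha >= 0``; the in-whiff envelope is
        ``C(r) = c0 (max(r, r_min)/r_min)^(-alpha) / (1 + height_factor)``.
    whiff_duration_law, blank_duration_law : (float, float)
        ``(baseline, distance_exponent)``: the mean duration at distance
        ``r`` is ``baseline * (max(r, r_min)/r_min)**exponent`` (time units).
        The exponents are overridden by ``sparsity_profile`` unless the
        profile is ``"custom"``.
    lognormal_dispersion : float
        ``sigma_ln`` of the per-whiff log-normal amplitude factor.
    sparsity_profile : {"concentrated", "dilute", "custom"}
        Selects the duration-law distance exponents (see above).
    height_factor : float
        ``>= 0``; scales blank durations up and the intensity envelope down,
        emulating sampling planes progressively further from the substrate
        where the odor is more sparse and less intense.
    within_whiff_ramp : float
        Optional linear ramp amplitude inside each whiff (fraction of the
        whiff amplitude, 0 disables); whiffs are otherwise internally flat.
    r_min : float or None
        Source regularization radius; defaults to one downwind cell so the
        envelope has no singularity at the origin.
    seed : int
        Base seed; identical config + seed reproduces the realization
        bit for bit.
    """

    domain_length: float = 64.0
    cone_half_angle: float = 0.35
    grid_shape: tuple[int, int] = (64, 17)
    n_frames: int = 2700
    dt: float = 1.0
    source_intensity: float = 1.0
    intensity_decay_exponent: float = 1.0
    whiff_duration_law: tuple[float, float] = (8.0, 0.0)
    blank_duration_law: tuple[float, float] = (12.0, 0.0)
    lognormal_dispersion: float = 0.3
    sparsity_profile: SparsityProfile = "custom"
    height_factor: float = 0.0
    within_whiff_ramp: float = 0.0
    r_min: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_length <= 0:
            raise ConfigurationError("domain_length must be > 0")
        if not 0 < self.cone_half_angle < math.pi / 2:
            raise ConfigurationError("cone_half_angle must lie in (0, pi/2)")
        nz, nx = self.grid_shape
        if nz < 1 or nx < 1:
            raise ConfigurationError("grid_shape entries must be >= 1")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.intensity_decay_exponent < 0:
            raise ConfigurationError("intensity_decay_exponent must be >= 0")
        if self.whiff_duration_law[0] <= 0 or self.blank_duration_law[0] < 0:
            raise ConfigurationError("duration-law baselines must be positive")
        if self.lognormal_dispersion < 0:
            raise ConfigurationError("lognormal_dispersion must be >= 0")
        if self.height_factor < 0:
            raise ConfigurationError("height_factor must be >= 0")
        if self.sparsity_profile not in ("concentrated", "dilute", "custom"):
            raise ConfigurationError(
                f"unknown sparsity_profile {self.sparsity_profile!r}"
            )
        if self.r_min is not None and self.r_min <= 0:
            raise ConfigurationError("r_min must be > 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def cell_size(self) -> float:
        return self.domain_length / self.grid_shape[0]

    @property
    def effective_r_min(self) -> float:
        return self.r_min if self.r_min is not None else self.cell_size

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates: downwind ``z1 > 0``, crosswind ``z2``
        symmetric about the source axis."""
        nz, nx = self.grid_shape
        dx = self.cell_size
        z1 = (np.arange(nz) + 0.5) * dx
        z2 = (np.arange(nx) - (nx - 1) / 2.0) * dx
        return z1, z2

    def cone_mask(self) -> np.ndarray:
        """Geometric emission cone: |z2| <= z1 tan(half angle)."""
        z1, z2 = self.coordinates()
        return np.abs(z2)[None, :] <= np.tan(self.cone_half_angle) * z1[:, None]

    # -- distance laws ------------------------------------------------------

    def _radial(self, r: np.ndarray | float) -> np.ndarray:
        return np.maximum(np.asarray(r, dtype=float), self.effective_r_min) / self.effective_r_min

    def duration_exponents(self) -> tuple[float, float]:
        if self.sparsity_profile == "custom":
            return self.whiff_duration_law[1], self.blank_duration_law[1]
        return _PROFILE_EXPONENTS[self.sparsity_profile]

    def whiff_mean(self, r: np.ndarray | float) -> np.ndarray:
        """Mean (continuous) whiff duration at distance r, time units."""
        ew, _ = self.duration_exponents()
        return self.whiff_duration_law[0] * self._radial(r) ** ew

    def blank_mean(self, r: np.ndarray | float) -> np.ndarray:
        """Mean (continuous) blank duration at distance r, time units."""
        _, eb = self.duration_exponents()
        return (
            self.blank_duration_law[0]
            * self._radial(r) ** eb
            * (1.0 + self.height_factor)
        )

    def envelope(self, r: np.ndarray | float) -> np.ndarray:
        """In-whiff concentration envelope C(r)."""
        return (
            self.source_intensity
            * self._radial(r) ** (-self.intensity_decay_exponent)
            / (1.0 + self.height_factor)
        )

    # discretized renewal means: durations are drawn exponential and rounded
    # up to whole samples, so the realized mean (time units) is
    # dt / (1 - exp(-dt/tau)), not tau.

    def discrete_whiff_mean(self, r: np.ndarray | float) -> np.ndarray:
        return _discrete_mean(self.whiff_mean(r), self.dt)

    def discrete_blank_mean(self, r: np.ndarray | float) -> np.ndarray:
        tb = self.blank_mean(r)
        return np.where(tb > 0, _discrete_mean(np.maximum(tb, 1e-300), self.dt), 0.0)

    def intermittency(self, r: np.ndarray | float) -> np.ndarray:
        """Long-run fraction of time above zero (telegraph duty cycle)."""
        mw = self.discrete_whiff_mean(r)
        mb = self.discrete_blank_mean(r)
        return mw / (mw + mb)


def _discrete_mean(tau: np.ndarray | float, dt: float) -> np.ndarray:
    """Mean of ceil(Exp(tau)/dt) samples, expressed in time units.

    The ceiling makes the sample count geometric with success probability
    p = 1 - exp(-dt/tau), whose mean is 1/p samples.
    """
    tau = np.asarray(tau, dtype=float)
    with np.errstate(over="ignore"):
        return dt / -np.expm1(-dt / tau)


def _discrete_sd(tau: np.ndarray | float, dt: float) -> np.ndarray:
    """Standard deviation of the discretized duration, time units."""
    p = -np.expm1(-dt / np.asarray(tau, dtype=float))
    return dt * np.sqrt((1.0 - p)) / p


@dataclass(frozen=True)
class PlumeRealization:
    """One generated plume record.

    ``concentration`` has shape ``grid_shape + (n_frames,)``; cells outside
    the emission cone hold the all-zero series. ``z1``/``z2`` are the cell
    center coordinates with the source at the origin.
    """

    concentration: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    config: PlumeConfig

    @property
    def n_frames(self) -> int:
        return self.concentration.shape[-1]

    @property
    def dt(self) -> float:
        return self.config.dt

    def cell_series(self, i: int, j: int) -> np.ndarray:
        return self.concentration[i, j]

    def distances(self) -> np.ndarray:
        return np.hypot(self.z1[:, None], self.z2[None, :])


def _telegraph_series(
    rng: np.random.Generator,
    n: int,
    tau_w: float,
    tau_b: float,
    amp: float,
    sigma_ln: float,
    dt: float,
    ramp: float,
) -> np.ndarray:
    """One alternating-renewal series of length n samples."""
    out = np.zeros(n)
    if tau_b <= 0:  # no blanks: a single whiff covering the record
        n_whiffs = max(1, int(math.ceil(n * dt / max(tau_w, dt))))
        lengths = np.maximum(1, np.ceil(rng.exponential(tau_w, n_whiffs) / dt)).astype(int)
        while lengths.sum() < n:
            extra = np.maximum(1, np.ceil(rng.exponential(tau_w, n_whiffs) / dt)).astype(int)
            lengths = np.concatenate([lengths, extra])
        xi = np.exp(rng.normal(0.0, sigma_ln, size=lengths.size)) if sigma_ln > 0 else np.ones(lengths.size)
        out[:] = np.repeat(amp * xi, lengths)[:n]
        if ramp:
            out *= 1.0 + ramp * _ramp_profile(lengths)[:n]
        return out

    phi = tau_w / (tau_w + tau_b)
    start_whiff = rng.random() < phi
    mean_cycle = _discrete_mean(tau_w, dt) + _discrete_mean(tau_b, dt)
    # draw cycles in batches until the record is covered
    n_cyc = int(n * dt / mean_cycle * 1.5) + 8
    state: list[np.ndarray] = []
    covered = 0
    whiff_first = start_whiff
    while covered < n:
        w = np.maximum(1, np.ceil(rng.exponential(tau_w, n_cyc) / dt)).astype(int)
        b = np.maximum(1, np.ceil(rng.exponential(tau_b, n_cyc) / dt)).astype(int)
        if whiff_first:
            lengths = np.empty(2 * n_cyc, dtype=int)
            lengths[0::2], lengths[1::2] = w, b
            is_whiff = np.zeros(2 * n_cyc, dtype=bool)
            is_whiff[0::2] = True
        else:
            lengths = np.empty(2 * n_cyc, dtype=int)
            lengths[0::2], lengths[1::2] = b, w
            is_whiff = np.zeros(2 * n_cyc, dtype=bool)
            is_whiff[1::2] = True
        xi = (
            np.exp(rng.normal(0.0, sigma_ln, size=n_cyc))
            if sigma_ln > 0
            else np.ones(n_cyc)
        )
        amps = np.zeros(2 * n_cyc)
        amps[is_whiff] = amp * xi
        seg = np.repeat(amps, lengths)
        if ramp:
            prof = _ramp_profile(lengths) * np.repeat(is_whiff.astype(float), lengths)
            seg = seg * (1.0 + ramp * prof)
        state.append(seg)
        covered += seg.size
        whiff_first = not bool(is_whiff[-1])  # next batch starts opposite
    return np.concatenate(state)[:n]


def _ramp_profile(lengths: np.ndarray) -> np.ndarray:
    """Per-segment linear ramp from -1/2 to +1/2, concatenated."""
    parts = [
        (np.arange(L) - (L - 1) / 2.0) / max(L - 1, 1) for L in lengths
    ]
    return np.concatenate(parts) if parts else np.zeros(0)


def generate_plume(config: PlumeConfig) -> PlumeRealization:
    """Generate a plume realization from a configuration.

    In-cone cells receive independent telegraph processes whose whiff/blank
    means and amplitude envelope follow the configured distance laws;
    out-of-cone cells are exactly zero.
    """
    nz, nx = config.grid_shape
    z1, z2 = config.coordinates()
    mask = config.cone_mask()
    conc = np.zeros((nz, nx, config.n_frames))
    r = np.hypot(z1[:, None], z2[None, :])

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(nz * nx)
    for i in range(nz):
        for j in range(nx):
            if not mask[i, j]:
                continue
            rng = np.random.default_rng(children[i * nx + j])
            conc[i, j] = _telegraph_series(
                rng,
                config.n_frames,
                float(config.whiff_mean(r[i, j])),
                float(config.blank_mean(r[i, j])),
                float(config.envelope(r[i, j])),
                config.lognormal_dispersion,
                config.dt,
                config.within_whiff_ramp,
            )
    return PlumeRealization(concentration=conc, z1=z1, z2=z2, config=config)


# ---------------------------------------------------------------------------
# Ground-truth feature laws


@dataclass(frozen=True)
class GroundTruthLaws:
    """Analytic mean/sd curves of the five features vs downwind distance.

    The curves describe features computed on the *true* telegraph state
    (detection threshold -> 0); adaptive-threshold estimates acquire a small
    selection bias discussed in the package docs. Mean curves for features
    1, 3, 4, 5 are exact under the renewal model; dispersion curves use a
    delta-method approximation with the effective number of renewal cycles
    per window, or a Monte-Carlo estimate when requested.
    """

    config: PlumeConfig
    memory: float
    monte_carlo: bool = False

    def _n_cycles(self, y: np.ndarray | float) -> np.ndarray:
        cyc = self.config.discrete_whiff_mean(y) + self.config.discrete_blank_mean(y)
        return np.maximum(np.asarray(self.memory / cyc, dtype=float), 1.0)

    def g(self, k: int, y: np.ndarray | float) -> np.ndarray:
        """Expected feature k at centerline downwind distance y."""
        c = self.config
        y = np.asarray(y, dtype=float)
        s2 = c.lognormal_dispersion**2
        if k == 1:
            return c.envelope(y) * np.exp(s2 / 2.0)
        if k == 2:  # onset step dominates for internally flat whiffs
            return c.envelope(y) * np.exp(s2 / 2.0) / c.dt
        if k == 3:
            return c.discrete_blank_mean(y)
        if k == 4:
            return c.discrete_whiff_mean(y)
        if k == 5:
            return c.intermittency(y)
        raise ValueError(f"feature index must be 1..5, got {k}")

    def s(self, k: int, y: np.ndarray | float) -> np.ndarray:
        """Approximate sd of feature k across windows of the stated memory."""
        c = self.config
        y = np.asarray(y, dtype=float)
        n = self._n_cycles(y)
        cv_xi = math.sqrt(math.expm1(c.lognormal_dispersion**2))
        if k in (1, 2):
            return self.g(k, y) * cv_xi / np.sqrt(n)
        if k == 3:
            return _discrete_sd(np.maximum(c.blank_mean(y), 1e-12), c.dt) / np.sqrt(n)
        if k == 4:
            return _discrete_sd(c.whiff_mean(y), c.dt) / np.sqrt(n)
        if k == 5:
            phi = c.intermittency(y)
            return np.sqrt(phi * (1.0 - phi) / n)
        raise ValueError(f"feature index must be 1..5, got {k}")


def ground_truth_laws(config: PlumeConfig, memory: float) -> GroundTruthLaws:
    """Analytic feature laws implied by a configuration.

    ``memory`` is the window duration (time units) the features are computed
    over; it sets the effective averaging in the dispersion curves.
    """
    if memory < config.dt:
        raise ConfigurationError("memory must be at least one sampling interval")
    return GroundTruthLaws(config=config, memory=float(memory))


# ---------------------------------------------------------------------------
# Study-condition presets


def concentrated_config(**overrides) -> PlumeConfig:
    """Near-substrate conditions: strong intensity decay, flat sparsity.

    The distance signal lives in the whiff amplitudes; the on/off pattern is
    statistically homogeneous, so intensity features dominate.
    """
    base = dict(
        sparsity_profile="concentrated",
        intensity_decay_exponent=1.5,
        lognormal_dispersion=0.3,
        whiff_duration_law=(8.0, 0.0),
        blank_duration_law=(12.0, 0.0),
    )
    base.update(overrides)
    return PlumeConfig(**base)


def dilute_config(**overrides) -> PlumeConfig:
    """Elevated / dilute conditions: weak intensity decay, strong sparsity
    gradient.

    Whiff amplitudes barely depend on distance and fluctuate strongly, while
    the duty cycle rises steeply downwind, so timing features dominate.
    """
    base = dict(
        sparsity_profile="dilute",
        intensity_decay_exponent=0.05,
        lognormal_dispersion=0.5,
        whiff_duration_law=(6.0, 0.0),
        blank_duration_law=(9.0, 0.0),
        # spread the sparsity gradient over the bulk of the cone rather
        # than the first few cells
        r_min=6.0,
    )
    base.update(overrides)
    return PlumeConfig(**base)
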