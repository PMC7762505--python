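"""Synthetic resting-state recordings and cohorts with known ground truth.

The signal model captures the three spectral alterations that matter for
dementia-related slowing: a 1/f^beta background, a Gaussian alpha bump whose
center and mass are controllable, and a multiplicative boost of power below
8 Hz (the "slowing" knob).  Signals are synthesised in the frequency domain:
the one-sided amplitude spectrum is shaped to the analytic target and phases
are randomised, so the periodogram of every realisation matches the analytic
spectrum exactly and downstream estimators can be checked against a closed
form.

The cohort generator couples a latent per-participant slowing factor to both
the low-frequency boost of that participant's recording and the cognitive
score trajectory, so the correlation between the spectral median frequency
and the score change is known by construction and tunable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfftfreq

from .spectral import Recording

__all__ = [
    "SignalSpec",
    "CohortSpec",
    "CohortInfo",
    "simulate_recording",
    "simulate_cohort",
    "analytic_psd",
    "analytic_normalized_psd",
    "analytic_median_frequency",
]

# below this frequency the 1/f curve is clamped to avoid the DC divergence
_F_CLAMP = 0.5

# study-scale cohort constants: initial-score distribution (mean, sd, floor,
# ceiling of the plausible draw range) and group-level change (mean, sd)
_INSTRUMENTS = ("mmse", "adas")
_INITIAL_SCORE = {"mmse": (25.8, 2.9, 20.0, 30.0), "adas": (8.0, 3.4, 0.8, 13.7)}
_SCORE_CHANGE = {"mmse": (1.0, 2.7), "adas": (-1.8, 2.1)}
_AGE = (77.3, 6.4, 64.0, 88.0)


def _derive_seed(master: int, *parts: object) -> int:
    """Stable sub-seed from a master seed and string parts (< 2**31)."""
    tag = ":".join(str(p) for p in parts)
    return zlib.crc32(f"{master}:{tag}".encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic multi-channel recording.

    ``one_over_f_exponent`` (beta) sets the background slope,
    ``alpha_relative_power`` the fraction of 1–70 Hz power carried by the
    Gaussian alpha bump (``alpha_bandwidth`` is its full width at half
    maximum), ``low_band_boost`` multiplies power below 8 Hz, and
    ``line_noise_amplitude`` adds a 50-Hz sinusoid of that amplitude.
    Test-scale defaults (200 Hz, 60 s, 8 channels) keep simulations fast;
    study-scale acquisition is 2,000 Hz, 300 s, 160 channels.
    """

    n_channels: int = 8
    duration: float = 60.0
    fs: float = 200.0
    one_over_f_exponent: float = 1.0
    alpha_center: float = 10.0
    alpha_bandwidth: float = 2.0
    alpha_relative_power: float = 0.3
    low_band_boost: float = 1.0
    line_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 140.0:
            raise ValueError("fs must exceed 140 Hz (2 x 70 Hz normalisation band)")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x fs must be an integer number of samples")
        if self.one_over_f_exponent < 0:
            raise ValueError("one_over_f_exponent must be >= 0")
        if self.alpha_relative_power > 0 and not (8.0 <= self.alpha_center <= 12.0):
            raise ValueError("alpha_center must lie in [8, 12] Hz when a bump is requested")
        if self.alpha_bandwidth <= 0:
            raise ValueError("alpha_bandwidth must be positive")
        if not 0.0 <= self.alpha_relative_power < 1.0:
            raise ValueError("alpha_relative_power must be in [0, 1)")
        if self.low_band_boost < 0:
            raise ValueError("low_band_boost must be >= 0")
        if self.line_noise_amplitude < 0:
            raise ValueError("line_noise_amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def analytic_psd(spec: SignalSpec, freqs: np.ndarray) -> np.ndarray:
    """Expected one-sided PSD of the generative model on ``freqs`` (density units).

    ``C * f^-beta * boost(f) + bump(f)`` with the bump scaled so it carries
    ``alpha_relative_power`` of the total 1–70 Hz mass.  The 50-Hz line, being
    a spectral delta, is not part of this density.  The overall scale is fixed
    so the 1–70 Hz integral is 1 (spectral statistics are scale-free).
    """
    f = np.asarray(freqs, dtype=float)
    base = np.power(np.maximum(f, _F_CLAMP), -spec.one_over_f_exponent)
    base = np.where(f < 8.0, base * spec.low_band_boost, base)
    band = (f >= 1.0) & (f <= 70.0)
    if not np.any(band):
        raise ValueError("frequency grid does not cover the 1-70 Hz band")
    base_mass = float(np.trapezoid(np.where(band, base, 0.0), f))
    psd = base.copy()
    r = spec.alpha_relative_power
    if r > 0:
        sigma = spec.alpha_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        bump = np.exp(-0.5 * ((f - spec.alpha_center) / sigma) ** 2)
        bump_mass = float(np.trapezoid(np.where(band, bump, 0.0), f))
        if bump_mass > 0:
            psd = psd + bump * (r / (1.0 - r)) * base_mass / bump_mass
    total = float(np.trapezoid(np.where(band, psd, 0.0), f))
    return psd / total


def analytic_normalized_psd(
    spec: SignalSpec, grid_df: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth PSDn of the generative model on a uniform 1–70 Hz grid."""
    freqs = np.arange(1.0, 70.0 + grid_df / 2, grid_df)
    psd = analytic_psd(spec, freqs)
    mass = psd / psd.sum()
    return freqs, mass


def analytic_median_frequency(spec: SignalSpec, grid_df: float = 0.1) -> float:
    """Median frequency implied by the analytic generative spectrum."""
    freqs, mass = analytic_normalized_psd(spec, grid_df)
    idx = int(np.searchsorted(np.cumsum(mass), 0.5))
    return float(freqs[idx])


def simulate_recording(spec: SignalSpec) -> Recording:
    """Synthesise one recording whose periodogram equals the analytic spectrum.

    Fourier amplitudes are set deterministically to ``sqrt(S(f))`` and phases
    drawn uniformly per channel and bin, then inverse-transformed; channels
    are independent realisations.  Identical ``spec`` (including seed) yields
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    freqs = rfftfreq(n, 1.0 / spec.fs)
    s = analytic_psd(spec, freqs)
    s[0] = 0.0  # zero-mean signal
    amp = np.sqrt(s * spec.fs * n / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, freqs.size))
    coeffs = amp[None, :] * np.exp(1j * phases)
    coeffs[:, 0] = 0.0
    if n % 2 == 0:
        # Nyquist coefficient must be real; above 70 Hz its power is irrelevant
        coeffs[:, -1] = 0.0
    samples = irfft(coeffs, n, axis=1)
    if spec.line_noise_amplitude > 0:
        t = np.arange(n) / spec.fs
        line_phase = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, 1))
        samples = samples + spec.line_noise_amplitude * np.sin(
            2.0 * np.pi * 50.0 * t[None, :] + line_phase
        )
    return Recording(samples=samples, fs=spec.fs)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic treatment cohort.

    Defaults emulate the study scale: 16 participants, treatment periods of
    126–245 days with 14–29 sessions, recordings delayed 0–76 days after the
    initial assessment, MMSE-like scores near 20–30 and ADAS-like scores near
    0–14.  ``target_mf_outcome_corr`` sets the built-in correlation between
    the recording's median frequency and the score change;
    ``noise_sd_scores`` overrides the per-instrument change SDs when given.
    """

    n_participants: int = 16
    score_ranges: dict = field(
        default_factory=lambda: {"mmse": (0.0, 30.0), "adas": (0.0, 70.0)}
    )
    npt_period_range: tuple[int, int] = (126, 245)
    session_count_range: tuple[int, int] = (14, 29)
    meg_delay_range: tuple[int, int] = (0, 76)
    target_mf_outcome_corr: float = -0.5
    noise_sd_scores: float | None = None
    slowing_sd: float = 0.5
    alpha_center_jitter: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        for name in ("npt_period_range", "session_count_range", "meg_delay_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if self.npt_period_range[0] <= 0:
            raise ValueError("npt_period_range must be positive")
        for inst, (lo, hi) in self.score_ranges.items():
            if lo > hi:
                raise ValueError(f"score_ranges[{inst!r}] must be ordered (lo <= hi)")
        if abs(self.target_mf_outcome_corr) >= 1.0:
            raise ValueError("target_mf_outcome_corr magnitude must be < 1")
        if self.noise_sd_scores is not None and self.noise_sd_scores < 0:
            raise ValueError("noise_sd_scores must be >= 0")
        if self.slowing_sd < 0:
            raise ValueError("slowing_sd must be >= 0")
        if self.alpha_center_jitter < 0:
            raise ValueError("alpha_center_jitter must be >= 0")


@dataclass
class CohortInfo:
    """Ground-truth bookkeeping returned with a simulated cohort."""

    realized_latent_corr: dict  # instrument -> corr(expected MF, score change)
    n_clipped: dict  # instrument -> clipping events at the instrument range
    latent_slowing: np.ndarray
    expected_mf: np.ndarray


def simulate_cohort(
    cspec: CohortSpec, signal_template: SignalSpec | None = None
) -> tuple[pd.DataFrame, list[SignalSpec], CohortInfo]:
    """Generate a cohort table and per-participant recording specs.

    A latent slowing factor ``z ~ N(0, 1)`` drives the low-frequency boost of
    each participant's signal (``boost = exp(slowing_sd * z)``) and, through
    the analytic median frequency it implies, the score change: per
    instrument, ``change = mu + sd * (rho * u + sqrt(1 - rho^2) * eps)`` with
    ``u`` the standardised expected MF, so corr(MF, change) approximates
    ``target_mf_outcome_corr``.  Scores are clipped to the instrument range
    and clipping events counted — heavy clipping attenuates the realised
    correlation, and calibration analyses should avoid such regimes.

    Returns the long-format cohort table (one row per participant and
    instrument), the signal specs, and a :class:`CohortInfo` with the
    realised latent correlations (NaN when undefined, e.g. n = 1).
    """
    rng = np.random.default_rng(_derive_seed(cspec.seed, "cohort"))
    n = cspec.n_participants
    template = signal_template or SignalSpec()

    z = rng.standard_normal(n)
    boosts = np.exp(cspec.slowing_sd * z)
    # independent per-participant alpha-peak jitter, kept clear of the band
    # edges so IAF varies across the cohort without coupling to the latent
    centers = np.clip(
        template.alpha_center
        + rng.uniform(-cspec.alpha_center_jitter, cspec.alpha_center_jitter, size=n),
        8.25,
        11.75,
    )
    specs = [
        replace(
            template,
            low_band_boost=float(boosts[i]),
            alpha_center=float(centers[i]),
            seed=_derive_seed(cspec.seed, "signal", i),
        )
        for i in range(n)
    ]
    expected_mf = np.array([analytic_median_frequency(s) for s in specs])
    if n > 1 and np.std(expected_mf) > 0:
        u = (expected_mf - expected_mf.mean()) / expected_mf.std()
    else:
        u = np.zeros(n)

    age = np.clip(rng.normal(_AGE[0], _AGE[1], size=n), _AGE[2], _AGE[3])
    day_initial = np.zeros(n, dtype=int)
    day_first_npt = day_initial + rng.integers(5, 43, size=n)
    periods = rng.integers(
        cspec.npt_period_range[0], cspec.npt_period_range[1] + 1, size=n
    )
    day_last = day_first_npt + periods
    meg_delay = rng.integers(
        cspec.meg_delay_range[0], cspec.meg_delay_range[1] + 1, size=n
    )
    day_meg = np.minimum(day_initial + meg_delay, day_last)
    n_sessions = rng.integers(
        cspec.session_count_range[0], cspec.session_count_range[1] + 1, size=n
    )

    rho = cspec.target_mf_outcome_corr
    rows = []
    realized: dict[str, float] = {}
    clipped: dict[str, int] = {}
    for inst in _INSTRUMENTS:
        mu0, sd0, lo0, hi0 = _INITIAL_SCORE[inst]
        mu_c, sd_c = _SCORE_CHANGE[inst]
        if cspec.noise_sd_scores is not None:
            sd_c = cspec.noise_sd_scores
        floor, ceil = cspec.score_ranges.get(inst, (0.0, np.inf))
        initial = np.clip(rng.normal(mu0, sd0, size=n), lo0, hi0)
        initial = np.clip(initial, floor, ceil)
        eps = rng.standard_normal(n)
        change = mu_c + sd_c * (rho * u + np.sqrt(1.0 - rho**2) * eps)
        last_raw = initial + change
        last = np.clip(last_raw, floor, ceil)
        clipped[inst] = int(np.sum(last != last_raw))
        realized_change = last - initial
        if n > 1 and np.std(realized_change) > 0 and np.std(expected_mf) > 0:
            realized[inst] = float(np.corrcoef(expected_mf, realized_change)[0, 1])
        else:
            realized[inst] = float("nan")
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"p{i:03d}",
                    "instrument": inst,
                    "initial_score": float(initial[i]),
                    "last_score": float(last[i]),
                    "day_initial": int(day_initial[i]),
                    "day_first_npt": int(day_first_npt[i]),
                    "day_meg": int(day_meg[i]),
                    "day_last": int(day_last[i]),
                    "n_sessions": int(n_sessions[i]),
                    "age": float(age[i]),
                }
            )
    table = pd.DataFrame(rows)
    info = CohortInfo(
        realized_latent_corr=realized,
        n_clipped=clipped,
        latent_slowing=z,
        expected_mf=expected_mf,
    )
    return table, specs, info
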