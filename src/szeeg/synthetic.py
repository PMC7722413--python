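"""Synthetic two-class EEG cohort generator and analytic fixture signals.

The generator emulates the data geometry of a resting-state clinical EEG
study: 19 scalp channels in the 10-20 layout, 15 minutes at 250 Hz
(225,000 samples per channel), cut into non-overlapping 5000-sample
stationary segments (45 per channel).  Two diagnostic classes ("normal"
vs "schizophrenia") are separated only through the *nonlinear statistics*
of the signals -- scaling exponent, sample entropy, Lempel-Ziv
complexity -- by mixing

* 1/f^beta colored background noise with a class-dependent spectral
  exponent beta,
* band-limited alpha/beta-band oscillations, and
* a class-dependent fraction of a chaotic (logistic-map) component,

then applying a random full-rank channel-mixing matrix.  ``effect_size``
scales the between-class difference of the generating parameters; at
``effect_size=0`` both classes are drawn from identical parameters.

No attempt is made to mimic clinical EEG morphology; the generator only
guarantees the statistical structure the downstream pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import OptimizationError, ParameterError

__all__ = [
    "CLASS_LABELS",
    "EEGRecording",
    "GeneratorConfig",
    "SegmentMatrix",
    "generate_recording",
    "generate_cohort",
    "segment_channel",
    "make_fixture",
    "TEN_TWENTY_19",
]

CLASS_LABELS = ("normal", "schizophrenia")

#: Standard 10-20 labels for a 19-channel montage.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# Per-unit-effect-size shifts applied to the schizophrenia class only:
# whiter background noise (lower beta) and a larger chaotic fraction both
# raise sample entropy / LZC and lower the DFA exponent.  The direction is
# chosen only to create separation; it carries no clinical claim.
_BETA_SHIFT_PER_EFFECT = -0.25
_MIX_SHIFT_PER_EFFECT = 0.15


def _channel_names(n: int) -> tuple[str, ...]:
    if n <= len(TEN_TWENTY_19):
        return TEN_TWENTY_19[:n]
    extra = tuple(f"EXG{i}" for i in range(1, n - len(TEN_TWENTY_19) + 1))
    return TEN_TWENTY_19 + extra


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level parameters of a synthetic cohort.

    Parameters
    ----------
    n_subjects_per_class : int
        Subjects simulated per diagnostic class (study default 14).
    n_channels : int
        Scalp channels (default 19, 10-20 montage labels).
    fs : float
        Sampling rate in Hz (default 250; 15 min * 250 Hz = 225,000 samples).
    duration_s : float
        Recording length in seconds (default 900).
    effect_size : float
        Non-negative scale of the between-class difference in the
        generating parameters; 0 makes the classes identical in law.
    noise_spectral_exponent : mapping class -> beta
        Baseline 1/f^beta exponent per class (defaults equal).
    chaotic_mix : mapping class -> fraction in [0, 1]
        Baseline fraction of chaotic component per class (defaults equal).
    seed : int
        Master seed; equal seeds give bit-identical cohorts.
    """

    n_subjects_per_class: int = 14
    n_channels: int = 19
    fs: float = 250.0
    duration_s: float = 900.0
    effect_size: float = 1.0
    noise_spectral_exponent: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 1.2, "schizophrenia": 1.2}
    )
    chaotic_mix: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 0.05, "schizophrenia": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ParameterError("n_subjects_per_class must be >= 1")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        for label in CLASS_LABELS:
            if label not in self.noise_spectral_exponent:
                raise ParameterError(f"noise_spectral_exponent missing class {label!r}")
            if label not in self.chaotic_mix:
                raise ParameterError(f"chaotic_mix missing class {label!r}")
            mix = self.chaotic_mix[label]
            if not 0.0 <= mix <= 1.0:
                raise ParameterError("chaotic_mix must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        n = self.duration_s * self.fs
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ParameterError("duration_s * fs must be an integer sample count")
        return n_int

    def class_params(self, class_label: str) -> tuple[float, float]:
        """Effective (beta, chaotic_mix) for one class, after the effect-size shift.

        Only the schizophrenia class is shifted; with ``effect_size=0`` and
        the default (equal) baselines both classes share identical parameters.
        """
        if class_label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {class_label!r}")
        beta = float(self.noise_spectral_exponent[class_label])
        mix = float(self.chaotic_mix[class_label])
        if class_label == "schizophrenia":
            beta = beta + _BETA_SHIFT_PER_EFFECT * self.effect_size
            mix = float(np.clip(mix + _MIX_SHIFT_PER_EFFECT * self.effect_size, 0.0, 1.0))
        return beta, mix

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class EEGRecording:
    """One subject's multichannel signal with label and sampling metadata."""

    subject_id: str
    class_label: str
    data: np.ndarray  # channels x samples, microvolts
    fs: float
    channel_names: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ParameterError("data must be a channels x samples matrix")
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {self.class_label!r}")
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        if len(self.channel_names) != self.data.shape[0]:
            raise ParameterError("channel_names length must match channel count")
        if not np.isfinite(self.data).all():
            raise ParameterError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentMatrix:
    """Non-overlapping, contiguous fixed-length segments of one channel.

    ``values`` is segment_length x n_segments; column k holds the k-th
    segment in temporal order.
    """

    channel: int
    segment_length: int
    n_segments: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.segment_length, self.n_segments):
            raise ParameterError("values shape must be (segment_length, n_segments)")

    def segment(self, k: int) -> np.ndarray:
        return self.values[:, k]


# ---------------------------------------------------------------------------
# primitive signal sources
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def colored_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^beta noise via spectral shaping, unit variance."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return _standardize(x)


def logistic_series(n: int, r: float = 3.99, x0: float | None = None,
                    rng: np.random.Generator | None = None, burn: int = 200) -> np.ndarray:
    """Orbit of the logistic map x <- r x (1 - x), transient discarded."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if x0 is None:
        if rng is None:
            raise ParameterError("x0 or rng required")
        x0 = float(rng.uniform(0.1, 0.9))
    x = np.empty(n + burn)
    x[0] = x0
    for i in range(1, n + burn):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x[burn:]


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """fGn with Hurst exponent ``hurst`` via Davies-Harte circulant embedding."""
    if not 0.0 < hurst < 1.0:
        raise ParameterError("fgn Hurst exponent must lie in (0, 1)")
    if n < 2:
        raise ParameterError("n must be >= 2")
    m = n
    k = np.arange(m + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2.0 * k ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2m
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # tiny negatives from roundoff
    size = 2 * m
    z = rng.standard_normal(size) + 1j * rng.standard_normal(size)
    x = np.fft.fft(z * np.sqrt(lam / (4.0 * m))).real[:n]
    return x


def lorenz_x(n: int, rng: np.random.Generator, dt: float = 0.01,
             sample_every: int = 1, burn: int = 1000) -> np.ndarray:
    """x-coordinate of the Lorenz system (sigma=10, rho=28, beta=8/3), RK4."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    sigma, rho, b = 10.0, 28.0, 8.0 / 3.0

    def deriv(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - b * z])

    state = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
    total = burn + n * sample_every
    out = np.empty(n)
    j = 0
    for i in range(total):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= burn and (i - burn) % sample_every == 0 and j < n:
            out[j] = state[0]
            j += 1
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, n: int, seed: int = 0, **params) -> np.ndarray:
    """Deterministic test signals with known nonlinear statistics.

    Supported kinds: ``constant`` (value), ``sine`` (omega rad/sample,
    amplitude, phase), ``white_noise`` (sigma), ``fgn`` (hurst),
    ``pink_noise``, ``logistic_map`` (r, x0, burn), ``lorenz_x``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(n, float(params.get("value", 0.0)))
    if kind == "sine":
        omega = float(params.get("omega", 2.0 * np.pi * 0.01))
        amplitude = float(params.get("amplitude", 1.0))
        phase = float(params.get("phase", 0.0))
        return amplitude * np.sin(omega * np.arange(n) + phase)
    if kind == "white_noise":
        return float(params.get("sigma", 1.0)) * rng.standard_normal(n)
    if kind == "fgn":
        return fractional_gaussian_noise(n, float(params.get("hurst", 0.5)), rng)
    if kind == "pink_noise":
        return colored_noise(n, 1.0, rng)
    if kind == "logistic_map":
        return logistic_series(
            n,
            r=float(params.get("r", 4.0)),
            x0=params.get("x0"),
            rng=rng,
            burn=int(params.get("burn", 0 if "x0" in params else 200)),
        )
    if kind == "lorenz_x":
        return lorenz_x(
            n, rng,
            dt=float(params.get("dt", 0.01)),
            sample_every=int(params.get("sample_every", 1)),
        )
    raise ParameterError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# recordings and cohorts
# ---------------------------------------------------------------------------

def _mixing_matrix(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Near-identity random full-rank mixing matrix."""
    for _ in range(16):
        m = np.eye(n_channels) + 0.15 * rng.standard_normal((n_channels, n_channels)) / max(
            1.0, np.sqrt(n_channels)
        )
        if np.linalg.matrix_rank(m) == n_channels:
            return m
    raise OptimizationError("could not draw a full-rank mixing matrix")  # pragma: no cover


def generate_recording(class_label: str, config: GeneratorConfig,
                       subject_seed: int | np.random.SeedSequence,
                       subject_id: str | None = None) -> EEGRecording:
    """Simulate one subject.

    Each channel source is ``(1 - mix) * colored-noise(beta) + mix * chaotic
    component`` plus weak 10 Hz / 20 Hz oscillations; channels are then
    combined through a random full-rank mixing matrix and scaled to a
    plausible microvolt range.
    """
    beta, mix = config.class_params(class_label)
    n = config.n_samples
    if isinstance(subject_seed, np.random.SeedSequence):
        ss = subject_seed
    else:
        ss = np.random.SeedSequence(int(subject_seed))
    rng = np.random.default_rng(ss)

    t = np.arange(n) / config.fs
    sources = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        noise = colored_noise(n, beta, rng)
        chaos = _standardize(logistic_series(n, r=3.99, rng=rng))
        osc = (
            0.4 * np.sin(2.0 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
            + 0.15 * np.sin(2.0 * np.pi * 20.0 * t + rng.uniform(0, 2 * np.pi))
        )
        sources[c] = (1.0 - mix) * noise + mix * chaos + osc
    mixed = _mixing_matrix(config.n_channels, rng) @ sources
    data = 20.0 * mixed  # microvolt scale
    if subject_id is None:
        subject_id = f"{class_label[:3]}-{int(np.random.default_rng(ss.spawn(1)[0]).integers(1 << 30)):08d}"
    return EEGRecording(
        subject_id=subject_id,
        class_label=class_label,
        data=data,
        fs=config.fs,
        channel_names=_channel_names(config.n_channels),
    )


def subject_seed_sequence(config: GeneratorConfig, class_label: str,
                          subject_index: int) -> np.random.SeedSequence:
    """Stable per-subject seed: SeedSequence(config.seed, (class_index, subject_index))."""
    class_index = CLASS_LABELS.index(class_label)
    return np.random.SeedSequence(entropy=int(config.seed),
                                  spawn_key=(class_index, int(subject_index)))


def generate_cohort(config: GeneratorConfig) -> list[EEGRecording]:
    """Simulate ``2 * n_subjects_per_class`` recordings, deterministically."""
    recs: list[EEGRecording] = []
    for class_label in CLASS_LABELS:
        for j in range(config.n_subjects_per_class):
            ss = subject_seed_sequence(config, class_label, j)
            recs.append(
                generate_recording(
                    class_label, config, ss, subject_id=f"{class_label[:3]}{j:02d}"
                )
            )
    return recs


def segment_channel(recording: EEGRecording, channel: int,
                    segment_length: int = 5000) -> SegmentMatrix:
    """Cut one channel into non-overlapping contiguous segments.

    The trailing remainder (``n_samples mod segment_length`` samples) is
    discarded.
    """
    if segment_length <= 0:
        raise ParameterError("segment_length must be > 0")
    if not 0 <= channel < recording.n_channels:
        raise ParameterError(f"channel {channel} out of range")
    x = recording.data[channel]
    if segment_length > x.size:
        raise ParameterError("segment_length exceeds channel sample count")
    n_segments = x.size // segment_length
    values = x[: n_segments * segment_length].reshape(n_segments, segment_length).T
    return SegmentMatrix(
        channel=channel,
        segment_length=segment_length,
        n_segments=n_segments,
        values=np.ascontiguousarray(values),
    )
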