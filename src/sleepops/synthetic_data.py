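"""Synthetic sleep-EEG generation with stage-dependent spectral structure.

Each sleep stage is described by a :class:`StageArchetype`: a 1/f-colored
noise floor, relative power in the five classical EEG bands (delta, theta,
alpha, sigma, beta), an overall amplitude scale in microvolts, and rates for
transient events (sigma-band spindle bursts and K-complex-like biphasic
waves).  Epochs are synthesized in the frequency domain with seeded random
phases, so spectral content is controlled exactly; transients are added in
the time domain.

The defaults mirror textbook stage physiology: N3 is delta-dominated and
high-amplitude (slow waves make monotone ordinal patterns likely), N2 carries
spindles and sparse K-complexes over a theta background, N1 is
theta-dominated at intermediate amplitude, REM mixes theta and beta with
inflated variability, and wake is low-amplitude alpha/beta.  A small Markov
chain over stages produces plausible hypnograms with geometric-ish run
lengths.

``make_benchmark_dataset`` builds a separate two-class benchmark in which the
classes share ordinal-pattern frequencies but differ in which event type
carries the large amplitudes, so unweighted pattern features are
uninformative while amplitude-weighted (q != 0) features separate the
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sleep_io import STAGES, LabeledEpoch, Recording

#: Classical EEG frequency bands, Hz.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}

#: Raw hypnogram labels written for synthetic recordings (Sleep-EDF dialect).
RAW_LABELS = {
    "W": "Sleep stage W",
    "N1": "Sleep stage 1",
    "N2": "Sleep stage 2",
    "N3": "Sleep stage 3",
    "R": "Sleep stage R",
}


@dataclass(frozen=True)
class StageArchetype:
    """Generator parameters for one sleep stage.

    band_powers are relative PSD boosts per band (dimensionless);
    amplitude_scale is the target signal standard deviation in microvolts;
    noise_exponent is the 1/f^slope of the background; spindle_rate and
    kcomplex_rate are expected event counts per 30-s epoch.
    """

    stage: str
    band_powers: dict[str, float] = field(default_factory=dict)
    amplitude_scale: float = 10.0
    noise_exponent: float = 1.0
    spindle_rate: float = 0.0
    kcomplex_rate: float = 0.0
    spindle_freq: float = 13.5
    spindle_seconds: float = 1.0
    spindle_amplitude: float = 1.5
    kcomplex_seconds: float = 0.8
    kcomplex_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if any(v < 0 for v in self.band_powers.values()):
            raise ValueError("band powers must be non-negative")
        if self.spindle_rate < 0 or self.kcomplex_rate < 0:
            raise ValueError("event rates must be non-negative")
        unknown = set(self.band_powers) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")


#: Default archetypes: relative band powers chosen so that at 100 Hz the
#: q=0 entropy ordering is H(N3) < H(N2) < H(R), H(W), and monotone patterns
#: dominate in N3.  All parameters are plain data and user-overridable.
DEFAULT_ARCHETYPES: dict[str, StageArchetype] = {
    "W": StageArchetype(
        stage="W",
        band_powers={"alpha": 3.0, "beta": 2.0},
        amplitude_scale=10.0,
        noise_exponent=0.8,
    ),
    "N1": StageArchetype(
        stage="N1",
        band_powers={"theta": 4.0, "alpha": 1.0},
        amplitude_scale=15.0,
        noise_exponent=1.2,
    ),
    "N2": StageArchetype(
        stage="N2",
        band_powers={"theta": 3.0, "delta": 2.0, "sigma": 1.0},
        amplitude_scale=20.0,
        noise_exponent=1.5,
        spindle_rate=3.0,
        kcomplex_rate=1.0,
    ),
    "N3": StageArchetype(
        stage="N3",
        band_powers={"delta": 8.0, "theta": 1.0},
        amplitude_scale=30.0,
        noise_exponent=2.2,
    ),
    "R": StageArchetype(
        stage="R",
        band_powers={"theta": 2.5, "beta": 1.5},
        amplitude_scale=12.0,
        noise_exponent=1.0,
    ),
}


def _colored_spectrum(freqs: np.ndarray, archetype: StageArchetype) -> np.ndarray:
    """Target amplitude spectrum: 1/f^slope floor plus band boosts."""
    psd = np.zeros_like(freqs)
    nonzero = freqs > 0
    psd[nonzero] = freqs[nonzero] ** (-archetype.noise_exponent)
    for band, power in archetype.band_powers.items():
        lo, hi = BANDS[band]
        in_band = (freqs >= lo) & (freqs < hi)
        psd[in_band] += power / max(hi - lo, 1.0)
    return np.sqrt(psd)


def _spindle(t: np.ndarray, center: float, archetype: StageArchetype, phase: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / (archetype.spindle_seconds / 4)) ** 2)
    return env * np.sin(2 * np.pi * archetype.spindle_freq * t + phase)


def _kcomplex(t: np.ndarray, center: float, archetype: StageArchetype) -> np.ndarray:
    # Biphasic sharp-then-slow wave: derivative-of-Gaussian shape.
    s = archetype.kcomplex_seconds / 4
    u = (t - center) / s
    return -u * np.exp(-0.5 * u**2) * np.sqrt(np.e)  # peak amplitude 1


def generate_epoch(
    archetype: StageArchetype,
    sampling_rate: float = 100.0,
    seconds: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One synthetic epoch (3000 samples at the defaults), zero-mean, in uV."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(sampling_rate * seconds))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)

    amp = _colored_spectrum(freqs, archetype)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    x *= archetype.amplitude_scale / max(x.std(), 1e-12)

    t = np.arange(n) / sampling_rate
    for _ in range(rng.poisson(archetype.spindle_rate)):
        center = rng.uniform(1.0, seconds - 1.0)
        x += (
            archetype.spindle_amplitude
            * archetype.amplitude_scale
            * _spindle(t, center, archetype, rng.uniform(0, 2 * np.pi))
        )
    for _ in range(rng.poisson(archetype.kcomplex_rate)):
        center = rng.uniform(1.0, seconds - 1.0)
        x += archetype.kcomplex_amplitude * archetype.amplitude_scale * _kcomplex(t, center, archetype)

    return x - x.mean()


@dataclass(frozen=True)
class HypnogramModel:
    """Markov chain over the five stages at epoch granularity.

    ``transition_matrix`` rows/columns follow ``STAGES`` order and each row
    sums to 1; self-transition probabilities set the mean run lengths.
    """

    transition_matrix: np.ndarray
    initial_stage: str = "W"

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        object.__setattr__(self, "transition_matrix", tm)
        if self.initial_stage not in STAGES:
            raise ValueError(f"initial_stage must be one of {STAGES}")

    @classmethod
    def from_run_lengths(
        cls,
        mean_run_lengths: dict[str, float],
        neighbor_weights: dict[str, dict[str, float]] | None = None,
        initial_stage: str = "W",
    ) -> "HypnogramModel":
        """Build a chain with given mean run lengths (epochs) per stage.

        Self-transition probability is ``1 - 1/run_length``; the remaining
        mass is spread over plausible successor stages.
        """
        default_weights = {
            "W": {"N1": 1.0},
            "N1": {"N2": 0.6, "W": 0.25, "R": 0.15},
            "N2": {"N3": 0.45, "R": 0.25, "N1": 0.15, "W": 0.15},
            "N3": {"N2": 0.8, "W": 0.2},
            "R": {"N1": 0.3, "N2": 0.3, "W": 0.4},
        }
        weights = neighbor_weights or default_weights
        tm = np.zeros((5, 5))
        for i, stage in enumerate(STAGES):
            run = max(float(mean_run_lengths.get(stage, 1.0)), 1.0)
            stay = 1.0 - 1.0 / run
            tm[i, i] = stay
            w = weights[stage]
            total = sum(w.values())
            for nxt, frac in w.items():
                tm[i, STAGES.index(nxt)] += (1.0 - stay) * frac / total
        return cls(transition_matrix=tm, initial_stage=initial_stage)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        return pi / pi.sum()

    def sample_stages(self, n_epochs: int, rng: np.random.Generator) -> list[str]:
        idx = STAGES.index(self.initial_stage)
        out = []
        for _ in range(n_epochs):
            out.append(STAGES[idx])
            idx = rng.choice(5, p=self.transition_matrix[idx])
        return out


#: Default hypnogram: run lengths loosely matching overnight stage bouts
#: (brief awakenings, short N1 transitions, long N2 stretches).
DEFAULT_HYPNOGRAM = HypnogramModel.from_run_lengths(
    {"W": 3, "N1": 3, "N2": 15, "N3": 10, "R": 10}, initial_stage="N2"
)


def generate_recording(
    hypnogram_model: HypnogramModel = DEFAULT_HYPNOGRAM,
    archetypes: dict[str, StageArchetype] | None = None,
    n_epochs: int = 100,
    seed: int = 0,
    sampling_rate: float = 100.0,
    epoch_seconds: float = 30.0,
    subject_id: str | None = None,
) -> tuple[Recording, list[LabeledEpoch]]:
    """Sample a hypnogram, synthesize the continuous signal, emit annotations.

    Returns the Recording (with Sleep-EDF-style raw stage labels as
    annotation runs) and the matching list of LabeledEpoch.
    """
    archetypes = archetypes or DEFAULT_ARCHETYPES
    missing = [s for s in STAGES if s not in archetypes]
    if missing:
        raise ValueError(f"archetype missing for stages {missing}")
    rng = np.random.default_rng(seed)
    subject_id = subject_id or f"synth-{seed}"
    n_per = int(round(sampling_rate * epoch_seconds))

    stages = hypnogram_model.sample_stages(n_epochs, rng)
    signal = np.empty(n_epochs * n_per)
    epochs: list[LabeledEpoch] = []
    for i, stage in enumerate(stages):
        x = generate_epoch(archetypes[stage], sampling_rate, epoch_seconds, seed=rng)
        signal[i * n_per : (i + 1) * n_per] = x
        epochs.append(
            LabeledEpoch(
                samples=x, stage=stage, subject_id=subject_id, start_sample=i * n_per
            )
        )

    # Compress the stage sequence into annotation runs.
    annotations: list[tuple[float, float, str]] = []
    run_start = 0
    for i in range(1, n_epochs + 1):
        if i == n_epochs or stages[i] != stages[run_start]:
            annotations.append(
                (
                    run_start * epoch_seconds,
                    (i - run_start) * epoch_seconds,
                    RAW_LABELS[stages[run_start]],
                )
            )
            run_start = i

    rec = Recording(
        signal=signal,
        sampling_rate=sampling_rate,
        channel="EEG Fpz-Cz",
        annotations=annotations,
        subject_id=subject_id,
    )
    return rec, epochs


# ---------------------------------------------------------------------------
# Planted amplitude-structure benchmark
# ---------------------------------------------------------------------------


def _place_events(
    x: np.ndarray,
    rng: np.random.Generator,
    n_ramps: int,
    n_zigzags: int,
    ramp_amp: float,
    zigzag_amp: float,
    event_len: int = 6,
) -> None:
    """Insert monotone ramps and alternating zigzags at random disjoint spots."""
    n_events = n_ramps + n_zigzags
    starts = rng.choice(x.size // (2 * event_len) - 1, size=n_events, replace=False)
    starts = starts * 2 * event_len + rng.integers(0, event_len)
    kinds = np.array(["ramp"] * n_ramps + ["zig"] * n_zigzags)
    rng.shuffle(kinds)
    ramp = np.linspace(-1.0, 1.0, event_len)
    zigzag = np.array([1.0 if i % 2 else -1.0 for i in range(event_len)])
    for start, kind in zip(starts, kinds):
        shape, amp = (ramp, ramp_amp) if kind == "ramp" else (zigzag, zigzag_amp)
        x[start : start + event_len] = amp * shape * (1 + 0.1 * rng.standard_normal(event_len))


def make_benchmark_dataset(
    n_epochs_per_class: int = 150,
    n_events: int = 4,
    strong_amp: float = 12.0,
    weak_amp: float = 1.5,
    epoch_samples: int = 3000,
    seed: int = 0,
    class_stages: tuple[str, str] = ("W", "N1"),
) -> list[LabeledEpoch]:
    """Two epoch families separable by amplitude structure only.

    Every epoch is unit-variance white noise carrying ``n_events`` monotone
    ramps and ``n_events`` zigzag transients.  In the first class the ramps
    are large-amplitude and the zigzags small; in the second class the roles
    are swapped.  Both classes therefore share ordinal-pattern frequencies at
    q = 0 (same event counts, same noise), while any q != 0 weights the
    high-variance event segments up and separates the classes.  Class labels
    reuse two stage names so the tables plug into the standard pipeline.
    """
    rng = np.random.default_rng(seed)
    epochs: list[LabeledEpoch] = []
    for cls_i, stage in enumerate(class_stages):
        for j in range(n_epochs_per_class):
            x = rng.standard_normal(epoch_samples)
            if cls_i == 0:
                _place_events(x, rng, n_events, n_events, strong_amp, weak_amp)
            else:
                _place_events(x, rng, n_events, n_events, weak_amp, strong_amp)
            epochs.append(
                LabeledEpoch(
                    samples=x - x.mean(),
                    stage=stage,
                    subject_id=f"bench-{seed}",
                    start_sample=(cls_i * n_epochs_per_class + j) * epoch_samples,
                )
            )
    return epochs
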