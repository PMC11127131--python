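"""Synthetic multimodal affect cohorts.

Generates cohorts of annotated multichannel recordings that emulate a
chest-worn sensor study: 8 modalities (ECG-, EDA-, EMG-, respiration-,
temperature- and 3-axis-acceleration-like channels) sampled at a common
rate, with a per-sample affective-state annotation in
{neutral, stress, amusement} arranged in contiguous state blocks.

The generative model for participant ``p``, modality ``m``, at sample ``t``
in state ``s(t)`` is::

    x[m, t] = base_mean[s, m] + eta * delta[p, s, m]
              + amp[s, m] * sin(2*pi*f[m]*t/fs + phi[p, m])
              + AR(1) noise (coefficient ``ar_coefficient``,
                             stationary SD ``noise_sd``)

``delta[p, s, m]`` is the subject-specific state signature, drawn once per
participant; ``eta`` (the ``heterogeneity`` knob) scales it and is the
single dial separating between-subject variance from sensor noise. Each
entry of ``delta`` is marginally standard normal, but the entries are
correlated across modalities: a fraction ``signature_alignment`` of the
signature variance lies along one fixed "reactivity axis" shared by all
participants (real between-subject physiological variance is dominated by
a common low-dimensional factor — overall autonomic reactivity — rather
than independent per-channel offsets). Concentrating subject shifts along
a shared axis means different participants' state clusters genuinely
overlap once ``eta`` rivals the class separation, so a generalized model
must reconcile conflicting mappings in every cohort realization, while the
class contrasts orthogonal to the axis keep each participant's own task
separable. At ``eta = 0`` all participants share the same state-conditional
expectations and a generalized model has nothing to lose relative to a
personalized one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

NEUTRAL, STRESS, AMUSEMENT = 0, 1, 2
STATE_NAMES = ("neutral", "stress", "amusement")
N_STATES = 3

#: modality roles, in channel order
MODALITY_NAMES = ("ecg", "eda", "emg", "resp", "temp", "acc_x", "acc_y", "acc_z")

# State-conditional baseline means per modality (rows: neutral, stress,
# amusement). Magnitudes ~1 set the class separation that `heterogeneity`
# is measured against. Stress elevates the arousal-linked channels (EDA,
# ECG, EMG, respiration) and drops skin temperature; amusement is a milder
# arousal shift with more motion.
BASE_MEAN = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.9, 1.2, 0.8, 0.6, -0.4, 0.3, 0.3, 0.2],
        [0.4, 0.5, 0.2, 0.3, 0.1, 0.8, 0.6, 0.7],
    ]
)

# Oscillation frequency (Hz) per modality: cardiac ~1.1 Hz, slow EDA drift,
# EMG tremor band, respiration ~0.25 Hz, near-static temperature, gait-range
# accelerations.
PERIODIC_HZ = np.array([1.1, 0.05, 8.0, 0.25, 0.01, 2.0, 1.7, 2.3])
PERIODIC_AMP = np.array([0.3, 0.1, 0.25, 0.4, 0.05, 0.3, 0.3, 0.3])
#: state modulation of oscillation amplitude (neutral, stress, amusement)
AMP_MOD = np.array([1.0, 1.4, 1.2])

# Fixed unit "reactivity axis": the shared direction in modality space that
# carries most between-subject signature variance (arousal-linked channels
# load heaviest).
_w = np.array([0.5, 0.6, 0.4, 0.4, -0.2, 0.1, 0.1, 0.1])
REACTIVITY_AXIS = _w / np.linalg.norm(_w)


class CohortSizingError(ValueError):
    """Recording too short to host the requested state blocks."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the source study's scale: 15 participants, 700 Hz,
    ~36 minutes each, 8 modalities, and class fractions inside the
    per-participant ranges observed in the real protocol
    (neutral 51.8-54.0%, stress 29.0-31.8%, amusement 16.3-17.4%).
    """

    n_participants: int = 15
    sampling_rate: float = 700.0
    duration: float = 36.0 * 60.0  # seconds per participant
    n_modalities: int = 8
    class_fractions: tuple[float, float, float] = (0.53, 0.30, 0.17)
    heterogeneity: float = 1.0  # eta: SD of subject state-signature shifts
    signature_alignment: float = 0.9  # fraction of signature SD on the shared axis
    noise_sd: float = 0.5  # stationary SD of the AR(1) noise
    ar_coefficient: float = 0.8
    n_blocks_per_state: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.class_fractions, dtype=float)
        if fr.shape != (N_STATES,):
            raise ValueError("class_fractions must have one entry per state")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {fr.sum()!r}")
        if np.any(fr <= 0):
            raise ValueError("every class fraction must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity (eta) must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_participants < 1 or self.n_modalities < 1:
            raise ValueError("n_participants and n_modalities must be >= 1")
        if self.n_blocks_per_state < 1:
            raise ValueError("n_blocks_per_state must be >= 1")
        if not 0 <= self.signature_alignment <= 1:
            raise ValueError("signature_alignment must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Recording:
    """One participant's synchronized signals plus per-sample state labels."""

    participant_id: str
    signals: np.ndarray  # [n_modalities, n_samples]
    labels: np.ndarray  # [n_samples], values in {0, 1, 2}
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.signals.ndim != 2:
            raise ValueError("signals must be a [n_modalities, n_samples] matrix")
        if self.signals.shape[1] != self.labels.shape[0]:
            raise ValueError(
                "signals and labels disagree on n_samples: "
                f"{self.signals.shape[1]} vs {self.labels.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def n_modalities(self) -> int:
        return self.signals.shape[0]


@dataclass
class Cohort:
    recordings: list[Recording]
    config: CohortConfig

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids must be unique")
        rates = {r.sampling_rate for r in self.recordings}
        if len(rates) > 1:
            raise ValueError("all recordings must share one sampling_rate")

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.recordings]


def _class_sample_counts(n_samples: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n_samples across states."""
    exact = fractions * n_samples
    counts = np.floor(exact).astype(int)
    short = n_samples - counts.sum()
    order = np.argsort(-(exact - counts))  # biggest remainders first
    counts[order[:short]] += 1
    return counts


def make_state_schedule(
    config: CohortConfig,
    rng: np.random.Generator,
    min_block_samples: int = 64,
) -> np.ndarray:
    """Per-sample label vector of contiguous state blocks.

    Each state's total sample count follows ``config.class_fractions``
    (largest-remainder rounding, so realized fractions are exact to one
    sample), split into ``n_blocks_per_state`` near-equal contiguous blocks
    whose order is a deterministic shuffle of ``rng``. By default every
    block must be able to host at least one 64-sample window; pass a
    smaller ``min_block_samples`` for schedules that will not be windowed.
    """
    n = config.n_samples
    counts = _class_sample_counts(n, np.asarray(config.class_fractions, float))
    k = config.n_blocks_per_state
    min_block = min(int(c) // k for c in counts)
    if min_block < min_block_samples:
        worst = int(np.argmin(counts))
        need = int(np.ceil(min_block_samples * k / config.class_fractions[worst]))
        raise CohortSizingError(
            f"duration too short: state '{STATE_NAMES[worst]}' blocks would have "
            f"{min_block} samples (< {min_block_samples}); need at least "
            f"{need} total samples ({need / config.sampling_rate:.1f} s at "
            f"{config.sampling_rate:g} Hz)"
        )
    blocks: list[tuple[int, int]] = []  # (state, length)
    for s in range(N_STATES):
        base, extra = divmod(int(counts[s]), k)
        for b in range(k):
            blocks.append((s, base + (1 if b < extra else 0)))
    order = rng.permutation(len(blocks))
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for i in order:
        s, length = blocks[i]
        labels[pos : pos + length] = s
        pos += length
    assert pos == n
    return labels


def subject_signature(
    delta_stream: np.random.SeedSequence, config: CohortConfig
) -> np.ndarray:
    """Draw one participant's state-signature matrix delta, [3, n_modalities].

    delta[s] = a*sqrt(m) * u[s] * w + sqrt(1 - a^2) * eps[s] with u, eps
    standard normal and w the fixed unit reactivity axis. The expected
    squared norm per state is m, matching an i.i.d. standard-normal draw,
    but a fraction ``a^2`` (a = ``signature_alignment``) of that variance
    is concentrated along the shared axis; ``a = 0`` recovers fully
    independent standard-normal signatures.
    """
    m = config.n_modalities
    rng = np.random.default_rng(delta_stream)
    u = rng.standard_normal(N_STATES)
    eps = rng.standard_normal((N_STATES, m))
    a = config.signature_alignment
    axis = REACTIVITY_AXIS[:m]
    axis = axis / np.linalg.norm(axis)
    return a * np.sqrt(m) * u[:, None] * axis[None, :] + np.sqrt(1 - a * a) * eps


def generate_recording(
    participant_index: int, config: CohortConfig, rng_stream: np.random.SeedSequence
) -> Recording:
    """One participant's recording under the generative model above.

    ``rng_stream`` is a SeedSequence; independent substreams are spawned for
    the state schedule, the subject perturbations ``delta``, the oscillation
    phases, and the noise, so that e.g. two participants can share a noise
    substream while differing in ``delta``.
    """
    sched_ss, delta_ss, phase_ss, noise_ss = rng_stream.spawn(4)
    labels = make_state_schedule(config, np.random.default_rng(sched_ss))

    m = config.n_modalities
    delta = subject_signature(delta_ss, config)
    phases = np.random.default_rng(phase_ss).uniform(0, 2 * np.pi, size=m)

    n = config.n_samples
    t = np.arange(n, dtype=np.float64) / config.sampling_rate

    state_mean = BASE_MEAN[:, :m] + config.heterogeneity * delta  # [3, m]
    signals = state_mean[labels].T.copy()  # [m, n]

    amp = (PERIODIC_AMP[:m][None, :] * AMP_MOD[:, None]).astype(np.float64)  # [3, m]
    per_sample_amp = amp[labels].T  # [m, n]
    signals += per_sample_amp * np.sin(
        2 * np.pi * PERIODIC_HZ[:m, None] * t[None, :] + phases[:, None]
    )

    if config.noise_sd > 0:
        a = config.ar_coefficient
        nrng = np.random.default_rng(noise_ss)
        innov_sd = config.noise_sd * np.sqrt(1.0 - a * a)
        e = nrng.standard_normal((m, n)) * innov_sd
        # start each channel from the stationary distribution
        e[:, 0] = nrng.standard_normal(m) * config.noise_sd
        if a > 0:
            noise = lfilter([1.0], [1.0, -a], e, axis=1)
        else:
            noise = e
        signals += noise

    return Recording(
        participant_id=f"P{participant_index + 1:02d}",
        signals=signals,
        labels=labels,
        sampling_rate=config.sampling_rate,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministically generate ``config.n_participants`` recordings.

    The global seed spawns one child stream per participant, so regeneration
    with the same config is bit-identical and adding participants does not
    disturb earlier ones.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_participants)
    recordings = [
        generate_recording(i, config, streams[i]) for i in range(config.n_participants)
    ]
    return Cohort(recordings=recordings, config=config)


def state_conditional_means(recording: Recording) -> np.ndarray:
    """Empirical mean of each modality within each state, [3, n_modalities]."""
    out = np.full((N_STATES, recording.n_modalities), np.nan)
    for s in range(N_STATES):
        mask = recording.labels == s
        if mask.any():
            out[s] = recording.signals[:, mask].mean(axis=1)
    return out
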