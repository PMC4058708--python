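"""Synthetic multichannel EEG with known shared-frequency network structure.

The simulator plants sinusoidal oscillators on chosen subsets of the 19
montage channels, superposed on independent Gaussian noise, and reports the
adjacency matrix those oscillators imply as ground truth.  Five ICU-EEG
archetypes gate the temporal envelope:

normal
    continuous oscillatory activity (used both for non-encephalopathic
    background and, with fewer/more clustered oscillators, diffuse slowing).
low_voltage
    severely attenuated continuous activity (oscillators below ~10 uV).
iso_electric
    no cortical activity; near-zero noise only (<= 2 uV).
burst_suppression
    oscillators multiplied by an alternating on/off envelope (default 2 s
    on / 8 s off at duty cycle 0.2).
gpd
    generalized periodic discharges: a biphasic sharp transient (difference
    of Gaussians) repeated at the discharge rate, identical on all channels,
    on top of any oscillators.

The cohort generator assembles whole synthetic study populations: survivors
carry rich, spatially distributed oscillator sets; non-survivors carry a
clinically motivated mixture of sparser, spatially clustered patterns
(slowed-background, burst-suppression, low-voltage and iso-electric), with
CPC, SSEP and visual-EEG labels assigned accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording, TARGET_SFREQ
from .montage import CHANNELS_1020, N_CHANNELS, neighbourhood

ARCHETYPES = ("normal", "low_voltage", "iso_electric", "burst_suppression", "gpd")

#: frequency pool for planted oscillators: 0.5 Hz grid values spaced 1.5 Hz
#: apart, so no two oscillators interfere within one Hann window's
#: three-bin main lobe and every planted peak survives criterion (c)
FREQ_POOL = tuple(np.arange(2.0, 23.5, 1.5))

BURST_PERIOD_S = 10.0
GPD_AMPLITUDE_UV = 80.0
#: per-epoch probabilities of transient EEG state changes in continuous
#: records, two-sided so that group means are approximately preserved:
#: suppression (much of the oscillatory repertoire drops out, as under
#: sedation), arousal (transient enrichment), and topology events in which
#: the spatial organisation transiently fragments into local clusters or,
#: conversely, integrates across regions.  They give every metric a heavy
#: within-group tail, as ICU EEG state changes do.
SUPPRESSION_P = 0.15
AROUSAL_P = 0.15
FRAGMENTATION_P = 0.07
INTEGRATION_P = 0.07


class ConfigurationError(ValueError):
    """Invalid archetype/parameter combination."""


@dataclass(frozen=True)
class OscillatorSpec:
    """One sinusoidal oscillator shared by a set of channels."""

    frequency: float  # Hz, multiple of 0.5 in [1, 25]
    amplitude: float  # uV
    phase: float = 0.0  # radians
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        f = self.frequency
        if not (1.0 <= f <= 25.0) or abs(f * 2 - round(f * 2)) > 1e-9:
            raise ConfigurationError(
                f"frequency {f} not on the 0.5 Hz grid within [1, 25]"
            )
        if not self.channels:
            raise ConfigurationError("oscillator needs a non-empty channel set")
        bad = [ch for ch in self.channels if ch not in CHANNELS_1020]
        if bad:
            raise ConfigurationError(f"unknown montage channel(s): {bad}")


@dataclass(frozen=True)
class PatternSpec:
    """Recipe for one synthetic epoch."""

    archetype: str = "normal"
    oscillators: tuple[OscillatorSpec, ...] = ()
    noise_sd: float = 5.0  # uV
    burst_duty_cycle: float | None = None  # burst_suppression only
    discharge_rate: float | None = None  # gpd only, Hz
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if self.duration < 4.0:
            raise ConfigurationError("epoch duration must be at least 4 s")
        if self.archetype == "iso_electric":
            if self.oscillators:
                raise ConfigurationError("iso_electric admits no oscillators")
            if self.noise_sd > 2.0:
                raise ConfigurationError("iso_electric noise_sd must be <= 2 uV")
        if (self.burst_duty_cycle is not None) != (
            self.archetype == "burst_suppression"
        ):
            raise ConfigurationError(
                "burst_duty_cycle is required for burst_suppression and "
                "invalid elsewhere"
            )
        if self.burst_duty_cycle is not None and not 0.0 <= self.burst_duty_cycle <= 1.0:
            raise ConfigurationError("burst_duty_cycle must lie in [0, 1]")
        if (self.discharge_rate is not None) != (self.archetype == "gpd"):
            raise ConfigurationError(
                "discharge_rate is required for gpd and invalid elsewhere"
            )


@dataclass
class GroundTruth:
    """Adjacency structure implied by the planted oscillators."""

    expected_adjacency: np.ndarray  # (19, 19) bool
    expected_present_channels: tuple[str, ...]


def expected_adjacency(oscillators: tuple[OscillatorSpec, ...]) -> np.ndarray:
    """Pairwise 'share >= 1 oscillator frequency' relation, plus diagonal."""
    adj = np.zeros((N_CHANNELS, N_CHANNELS), dtype=bool)
    freq_channels: dict[float, set[int]] = {}
    for osc in oscillators:
        freq_channels.setdefault(osc.frequency, set()).update(
            CHANNELS_1020.index(ch) for ch in osc.channels
        )
    for chans in freq_channels.values():
        idx = sorted(chans)
        for i in idx:
            adj[i, idx] = True
    return adj


def generate_epoch(spec: PatternSpec) -> tuple[EEGRecording, GroundTruth]:
    """Render one synthetic epoch and its ground-truth network.

    Each oscillator appears as a sinusoid of its stated frequency, amplitude
    and phase in exactly its channel set, on independent Gaussian noise of
    ``noise_sd`` per channel.  The archetype gates the temporal envelope of
    the oscillatory part.  Identical spec (including seed) gives identical
    samples.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * TARGET_SFREQ))
    t = np.arange(n) / TARGET_SFREQ

    data = rng.normal(0.0, spec.noise_sd, size=(N_CHANNELS, n))

    osc_part = np.zeros((N_CHANNELS, n))
    for osc in spec.oscillators:
        wave = osc.amplitude * np.sin(2 * np.pi * osc.frequency * t + osc.phase)
        for ch in osc.channels:
            osc_part[CHANNELS_1020.index(ch)] += wave

    if spec.archetype == "burst_suppression":
        on_len = spec.burst_duty_cycle * BURST_PERIOD_S
        envelope = (np.mod(t, BURST_PERIOD_S) < on_len).astype(float)
        osc_part *= envelope
    elif spec.archetype == "gpd" and spec.discharge_rate > 0:
        period = 1.0 / spec.discharge_rate
        centers = np.arange(0.5 * period, spec.duration, period)
        transient = np.zeros(n)
        for c in centers:
            transient += GPD_AMPLITUDE_UV * (
                np.exp(-((t - c) ** 2) / (2 * 0.02**2))
                - 0.6 * np.exp(-((t - c) ** 2) / (2 * 0.05**2))
            )
        osc_part += transient[None, :]

    data += osc_part

    adj = expected_adjacency(spec.oscillators)
    present = tuple(
        CHANNELS_1020[i] for i in range(N_CHANNELS) if adj[i, i]
    )
    rec = EEGRecording(CHANNELS_1020, TARGET_SFREQ, data)
    return rec, GroundTruth(expected_adjacency=adj, expected_present_channels=present)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SubjectEpoch:
    start_hour: float
    spec: PatternSpec
    recording: EEGRecording
    truth: GroundTruth


@dataclass
class CohortSubject:
    subject_id: str
    cpc: int
    ssep_status: str  # "bilateral_absent" | "present"
    visual_eeg: str  # iso_electric | low_voltage | burst_suppression | diffuse_slowing | other
    epochs: list[SubjectEpoch] = field(default_factory=list)

    @property
    def survivor(self) -> bool:
        return self.cpc < 5


#: group-wise archetype frequencies of the default cohort.  Non-survivor
#: composition mirrors the clinical mixture seen in post-anoxic coma: most
#: non-survivors retain continuous but slowed, spatially clustered activity,
#: with burst suppression, low-voltage and iso-electric records making up
#: the remainder.
DEFAULT_EFFECT_PROFILE: dict[str, dict[str, float]] = {
    "survivor": {"normal": 1.0},
    "non_survivor": {
        "normal": 0.6,
        "burst_suppression": 0.2,
        "low_voltage": 0.16,
        "iso_electric": 0.04,
    },
}

#: CPC distribution among survivors (normal function through severe
#: disability), matching the skew typical of resuscitated cohorts
_SURVIVOR_CPC = (1, 2, 3, 4)
_SURVIVOR_CPC_P = (19 / 29, 8 / 29, 1 / 29, 1 / 29)

DEFAULT_EPOCH_HOURS = (1.0, 30.0, 60.0)


def _pick_channels(rng: np.random.Generator, size: int, clustered: bool) -> tuple[str, ...]:
    if clustered:
        center = CHANNELS_1020[rng.integers(N_CHANNELS)]
        return neighbourhood(center, size)
    idx = rng.choice(N_CHANNELS, size=size, replace=False)
    return tuple(CHANNELS_1020[i] for i in sorted(idx))


def _oscillators(
    rng: np.random.Generator,
    n_osc: int,
    set_sizes: tuple[int, int],
    amp_range: tuple[float, float],
    clustered_frac: float,
) -> tuple[OscillatorSpec, ...]:
    freqs = rng.choice(FREQ_POOL, size=min(n_osc, len(FREQ_POOL)), replace=False)
    oscs = []
    for f in freqs:
        size = int(rng.integers(set_sizes[0], set_sizes[1] + 1))
        clustered = rng.random() < clustered_frac
        oscs.append(
            OscillatorSpec(
                frequency=float(f),
                amplitude=float(rng.uniform(*amp_range)),
                phase=float(rng.uniform(0, 2 * np.pi)),
                channels=_pick_channels(rng, size, clustered),
            )
        )
    return tuple(oscs)


def _subject_spec_factory(
    archetype: str, survivor: bool, rng: np.random.Generator
):
    """Subject-level pattern parameters, drawn once per subject.

    Survivors carry more oscillators on larger, mostly random (spatially
    distributed) channel sets; non-survivors carry fewer oscillators on
    tight spatial clusters, so their networks are smaller with higher
    relative clustering and shorter relative paths.
    """
    if archetype == "iso_electric":
        def make(seed: int) -> PatternSpec:
            return PatternSpec("iso_electric", (), noise_sd=1.0, seed=seed)
        return make

    if archetype == "low_voltage":
        n_osc = int(rng.integers(2, 5))

        def make(seed: int) -> PatternSpec:
            sub = np.random.default_rng(seed)
            oscs = _oscillators(sub, n_osc, (3, 4), (6.0, 9.5), 0.9)
            return PatternSpec("low_voltage", oscs, noise_sd=2.0, seed=seed)
        return make

    if archetype == "burst_suppression":
        n_osc = int(rng.integers(3, 6))
        duty = float(rng.uniform(0.35, 0.5))

        def make(seed: int) -> PatternSpec:
            sub = np.random.default_rng(seed)
            oscs = _oscillators(sub, n_osc, (3, 4), (25.0, 40.0), 0.9)
            return PatternSpec(
                "burst_suppression", oscs, noise_sd=5.0,
                burst_duty_cycle=duty, seed=seed,
            )
        return make

    # Continuous background.  The group differences are spread over
    # several subject-level axes with independent within-group variation,
    # so that each single metric overlaps between the groups while the
    # composite of all four ranked metrics separates:
    #   - number of oscillator "cores" (local rhythm generators) -> size
    #   - number of spatially distributed "bridge" oscillators joining the
    #     cores into one component -> relative path length
    #   - spatial placement of cores: survivors mix distributed and
    #     clustered sets (cross-linked, lower relative clustering);
    #     non-survivor cores are almost purely local cliques.
    # Channel-set widths are drawn from the same range in both groups, so
    # connection count separates only through size and bridging.
    amp = (25.0, 40.0)
    if survivor:
        n_core = int(rng.integers(5, 7))
        base = int(rng.integers(4, 6))
        n_bridge = int(rng.integers(2, 4))
        clustered_frac = float(rng.uniform(0.25, 0.45))
    else:
        n_core = int(rng.integers(4, 6))
        base = int(rng.integers(4, 6))
        n_bridge = int(rng.integers(0, 2))
        clustered_frac = float(rng.uniform(0.85, 1.0))
    core_sizes = (base - 2, base + 1)

    def make(seed: int) -> PatternSpec:
        sub = np.random.default_rng(seed)
        n_c, n_b = n_core, n_bridge
        # Two-sided transient state excursions (see the module constants)
        # give every metric a heavy within-group tail while approximately
        # preserving the group means.
        u = sub.random()
        if u < SUPPRESSION_P:
            keep = sub.uniform(0.3, 0.5)
            n_c = max(1, int(np.ceil(n_c * keep)))
            n_b = int(np.ceil(n_b * keep))
        elif u < SUPPRESSION_P + AROUSAL_P:
            boost = sub.uniform(1.7, 2.2)
            n_c = int(np.round(n_c * boost))
            n_b = int(np.round(n_b * boost))
        elif u < SUPPRESSION_P + AROUSAL_P + FRAGMENTATION_P:
            n_c, n_b = n_c + n_b, 0
        elif u < SUPPRESSION_P + AROUSAL_P + FRAGMENTATION_P + INTEGRATION_P:
            shift = min(n_c - 1, 2)
            n_c, n_b = n_c - shift, n_b + shift
        n_total = min(n_c + n_b, len(FREQ_POOL))
        n_c = min(n_c, n_total)
        freqs = sub.choice(FREQ_POOL, size=n_total, replace=False)
        oscs = []
        for i, f in enumerate(freqs):
            if i < n_c:  # core
                size = int(sub.integers(core_sizes[0], core_sizes[1] + 1))
                clustered = sub.random() < clustered_frac
            else:  # bridge: distributed across the scalp
                size = int(sub.integers(4, 6))
                clustered = False
            oscs.append(
                OscillatorSpec(
                    frequency=float(f),
                    amplitude=float(sub.uniform(*amp)),
                    phase=float(sub.uniform(0, 2 * np.pi)),
                    channels=_pick_channels(sub, size, clustered),
                )
            )
        return PatternSpec("normal", tuple(oscs), noise_sd=5.0, seed=seed)
    return make


def _archetype_counts(n: int, profile: dict[str, float]) -> list[str]:
    """Deterministically allocate n subjects to archetypes by frequency."""
    items = sorted(profile.items())
    counts = {a: int(np.floor(f * n)) for a, f in items}
    remainder = n - sum(counts.values())
    # hand leftovers to the most frequent archetypes
    for a, _ in sorted(items, key=lambda kv: -kv[1]):
        if remainder == 0:
            break
        counts[a] += 1
        remainder -= 1
    out: list[str] = []
    for a, _ in items:
        out.extend([a] * counts[a])
    return out


def generate_cohort(
    n_survivors: int,
    n_nonsurvivors: int,
    effect_profile: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    epoch_hours: tuple[float, ...] = DEFAULT_EPOCH_HOURS,
    epoch_duration: float = 300.0,
) -> list[CohortSubject]:
    """Generate a labelled synthetic cohort with recordings.

    Survivors (CPC 1-4) receive continuous, spatially distributed
    oscillatory activity; non-survivors (CPC 5) receive the archetype
    mixture of ``effect_profile['non_survivor']``.  Each subject gets one
    epoch per entry of ``epoch_hours``.  Reproducible under a fixed seed.
    """
    if n_survivors < 2 or n_nonsurvivors < 2:
        raise ConfigurationError("need at least 2 subjects per outcome group")
    profile = effect_profile or DEFAULT_EFFECT_PROFILE
    rng = np.random.default_rng(seed)

    plan: list[tuple[bool, str]] = []
    for arch in _archetype_counts(n_survivors, profile["survivor"]):
        plan.append((True, arch))
    for arch in _archetype_counts(n_nonsurvivors, profile["non_survivor"]):
        plan.append((False, arch))

    subjects: list[CohortSubject] = []
    for i, (survivor, arch) in enumerate(plan):
        if survivor:
            cpc = int(rng.choice(_SURVIVOR_CPC, p=_SURVIVOR_CPC_P))
            ssep = "present"
            visual = "diffuse_slowing" if rng.random() < 0.8 else "other"
        else:
            cpc = 5
            ssep = (
                "bilateral_absent"
                if arch in ("iso_electric", "low_voltage")
                else "present"
            )
            visual = {"normal": "diffuse_slowing"}.get(arch, arch)
        make_spec = _subject_spec_factory(arch, survivor, rng)
        subject = CohortSubject(
            subject_id=f"S{i:03d}", cpc=cpc, ssep_status=ssep, visual_eeg=visual
        )
        for hour in epoch_hours:
            epoch_seed = int(rng.integers(0, 2**31 - 1))
            spec = make_spec(epoch_seed)
            if spec.duration != epoch_duration:
                spec = PatternSpec(
                    spec.archetype, spec.oscillators, spec.noise_sd,
                    spec.burst_duty_cycle, spec.discharge_rate,
                    duration=epoch_duration, seed=spec.seed,
                )
            rec, truth = generate_epoch(spec)
            rec.t0_offset_hours = hour
            subject.epochs.append(
                SubjectEpoch(start_hour=hour, spec=spec, recording=rec, truth=truth)
            )
        subjects.append(subject)
    return subjects
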