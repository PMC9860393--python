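"""Synthetic recordings with ground truth.

CSF-contacting neurons fire Ca²⁺ spikes sparsely (a homogeneous Poisson
process near 0.148 Hz) with a bimodal amplitude distribution: small spikes
from low-voltage-activated T-type channels and large spikes that additionally
recruit high-voltage-activated (HVA) channels.  In cell-attached recordings
each action potential appears as an extracellular waveform (EAP) whose
depolarizing phase carries a primary peak and a variably recruited secondary
peak (median ~23 % of the primary); the running integral of the EAP tracks
the intracellular action potential, and the Ca²⁺ spike amplitude scales
linearly with its peak.

This module is a phenomenological forward model of those recordings: Poisson
event times, a two-class log-normal amplitude mixture, a double-exponential
GCaMP6f-like transient kernel, a three-lobe Gaussian EAP template, linear
Ca↔∫EAP coupling, and the pharmacological / stimulation transforms used in
the study (TTx, Cd²⁺, ML218, electrode placement, ACh/ATP ejection).  Every
output is reproducible from one integer seed, and every drawn quantity is
returned as :class:`GroundTruth` so downstream detectors can be scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import Trace

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeClassParams",
    "KernelParams",
    "EapTemplateParams",
    "GroundTruth",
    "EffectConfig",
    "PairedConfig",
    "CONDITIONS",
    "generate_spike_train",
    "draw_secondary_scales",
    "assign_amplitudes",
    "render_ca_trace",
    "render_eap_train",
    "eap_template_waveform",
    "template_integral_peak",
    "generate_paired_recording",
    "coupling_noise_for_variance_ratio",
    "apply_condition",
]

# Spontaneous firing rate: population median reported for 127 cells.
DEFAULT_RATE_HZ = 0.148

# z-score of the 75th percentile of a standard normal; converts a quartile
# ratio into a log-normal sigma.
_Z75 = 0.6744897501960817


def _sigma_from_quartiles(q25: float, q75: float) -> float:
    """Log-normal sigma whose quartile ratio matches (q25, q75) geometrically."""
    return math.log(math.sqrt(q75 / q25)) / _Z75


@dataclass
class SpikeClassParams:
    """Two-class (small T-type / large HVA) amplitude mixture.

    Amplitudes are log-normal within each class; ``p_large`` is the
    probability that an event recruits the HVA current.  ``coupling_slope``
    and ``coupling_noise_sd`` define the linear map from the peak of the
    noise-free ∫EAP to the Ca²⁺ spike amplitude in paired recordings.
    """

    p_large: float = 0.5
    small_amp_mu: float = math.log(0.3)   # log ΔF/F, median 0.3
    small_amp_sigma: float = 0.3
    large_amp_mu: float = math.log(1.5)   # log ΔF/F, median 1.5
    large_amp_sigma: float = 0.3
    coupling_slope: float = 12.0          # ΔF/F per pA·s
    coupling_noise_sd: float = 0.05       # ΔF/F

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_large <= 1.0:
            raise ValueError(f"p_large must be in [0,1], got {self.p_large}")
        if self.small_amp_sigma < 0 or self.large_amp_sigma < 0:
            raise ValueError("amplitude sigmas must be >= 0")
        if math.exp(self.large_amp_mu) <= math.exp(self.small_amp_mu):
            raise ValueError("large-class median must exceed small-class median")
        if self.coupling_noise_sd < 0:
            raise ValueError("coupling_noise_sd must be >= 0")


@dataclass
class KernelParams:
    """GCaMP6f-like transient kernel and imaging-noise parameters.

    The transient is a unit-peak double exponential
    ``exp(-t/decay_tau) - exp(-t/rise_tau)``; defaults are literature-typical
    GCaMP6f kinetics (the recordings themselves do not constrain them).
    """

    rise_tau: float = 0.05    # s
    decay_tau: float = 0.4    # s
    frame_rate: float = 30.0  # Hz; acquisitions ran at 30-120 Hz
    noise_sd: float = 0.05    # ΔF/F, additive white noise

    def __post_init__(self) -> None:
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class EapTemplateParams:
    """Three-lobe EAP template (depolarizing-positive convention).

    The waveform is a sum of Gaussian lobes: a primary depolarizing lobe, a
    repolarizing lobe, and a secondary depolarizing lobe whose amplitude is a
    per-event fraction (``scale``) of the primary.  The secondary fraction is
    log-normal with median ``secondary_rel_median`` (0.23 by default, with
    quartiles matching 0.11–0.37).
    """

    sample_rate: float = 25_000.0  # Hz
    primary_amp: float = 50.0      # pA
    primary_width: float = 0.0005  # s (Gaussian sigma)
    repol_amp: float = 30.0        # pA (magnitude of the negative lobe)
    repol_delay: float = 0.0015    # s, centre of the repolarizing lobe
    repol_width: float = 0.0006    # s
    secondary_delay: float = 0.003  # s, centre of the secondary lobe
    secondary_width: float = 0.0008  # s
    secondary_rel_median: float = 0.23
    secondary_rel_iqr: tuple[float, float] = (0.11, 0.37)
    noise_sd: float = 1.0          # pA

    def __post_init__(self) -> None:
        if self.sample_rate < 10_000:
            raise ValueError("EAP traces must be sampled at >= 10 kHz")
        for name in ("primary_width", "repol_width", "secondary_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.secondary_rel_median <= 1.5:
            raise ValueError("secondary_rel_median must be in [0, 1.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def secondary_rel_sigma(self) -> float:
        q25, q75 = self.secondary_rel_iqr
        return _sigma_from_quartiles(q25, q75)


@dataclass
class GroundTruth:
    """Oracle record of a synthetic recording.

    One entry per event: time (s), class label (``"small"``/``"large"``),
    true Ca²⁺ amplitude (ΔF/F) and secondary-lobe scale (fraction of the
    primary EAP peak).
    """

    event_times: np.ndarray
    class_labels: np.ndarray
    true_amplitudes: np.ndarray
    true_secondary_scales: np.ndarray
    rate: float
    seed: int | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.true_amplitudes = np.asarray(self.true_amplitudes, dtype=float)
        self.true_secondary_scales = np.asarray(self.true_secondary_scales, dtype=float)
        n = self.event_times.size
        for name in ("class_labels", "true_amplitudes", "true_secondary_scales"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have one entry per event")
        if n > 1 and not np.all(np.diff(self.event_times) > 0):
            raise ValueError("event_times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.event_times.size


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for (seed, key...) — one explicit root, no global state."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))


def generate_spike_train(rate: float, duration: float, seed) -> np.ndarray:
    """Homogeneous Poisson event times on [0, duration).

    Inter-event intervals are i.i.d. exponential at ``rate``; the train is
    truncated at ``duration``.  ``seed`` may be an int or a Generator.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0 Hz, got {rate}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    if rate == 0:
        return np.empty(0)
    rng = _rng(seed)
    # Draw in blocks until past the end; expected count + 10 sigma headroom.
    expected = rate * duration
    block = max(16, int(expected + 10.0 * math.sqrt(expected + 1.0)))
    times: list[np.ndarray] = []
    t_end = 0.0
    while t_end < duration:
        isis = rng.exponential(1.0 / rate, size=block)
        chunk = t_end + np.cumsum(isis)
        times.append(chunk)
        t_end = chunk[-1]
    all_times = np.concatenate(times)
    return all_times[all_times < duration]


def draw_secondary_scales(
    n: int,
    seed,
    median: float = 0.23,
    iqr: tuple[float, float] = (0.11, 0.37),
) -> np.ndarray:
    """Per-event secondary-lobe scales, log-normal with the given median/IQR."""
    rng = _rng(seed)
    sigma = _sigma_from_quartiles(*iqr)
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=n)


def assign_amplitudes(
    event_times: np.ndarray,
    params: SpikeClassParams,
    seed,
    *,
    rate: float | None = None,
    duration: float | None = None,
    scale_median: float = 0.23,
    scale_iqr: tuple[float, float] = (0.11, 0.37),
) -> GroundTruth:
    """Label events small/large and draw their amplitudes and secondary scales.

    Each event draws a secondary scale from one log-normal (median
    ``scale_median``); events in the top ``p_large`` quantile of that
    distribution are the "large" class (strong HVA recruitment), so labels are
    Bernoulli(``p_large``) marginally and class correlates with the secondary
    current, as in paired recordings.  Amplitudes are then log-normal within
    class.
    """
    rng = _rng(seed)
    event_times = np.asarray(event_times, dtype=float)
    n = event_times.size
    scales = draw_secondary_scales(n, rng, median=scale_median, iqr=scale_iqr)
    if params.p_large <= 0:
        large = np.zeros(n, dtype=bool)
    elif params.p_large >= 1:
        large = np.ones(n, dtype=bool)
    else:
        sigma = _sigma_from_quartiles(*scale_iqr)
        from scipy.stats import norm

        cut = math.exp(math.log(scale_median) + sigma * norm.ppf(1.0 - params.p_large))
        large = scales > cut
    amps = np.where(
        large,
        rng.lognormal(params.large_amp_mu, params.large_amp_sigma, size=n),
        rng.lognormal(params.small_amp_mu, params.small_amp_sigma, size=n),
    )
    labels = np.where(large, "large", "small").astype(object)
    if rate is None:
        rate = n / duration if duration else float("nan")
    return GroundTruth(event_times, labels, amps, scales, rate=rate, duration=duration)


def ca_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak double-exponential transient, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    out = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    return out / peak


def render_ca_trace(
    truth: GroundTruth,
    kernel: KernelParams,
    duration: float | None = None,
    seed=None,
) -> Trace:
    """ΔF/F trace: sum of per-event unit-peak transients plus white noise.

    Overlapping transients add linearly.  Events outside [0, duration) are
    dropped with a warning.  Noise requires a seed (or Generator); with
    ``noise_sd == 0`` the trace is deterministic.
    """
    if duration is None:
        duration = truth.duration
    if duration is None:
        raise ValueError("duration must be given (or set on the GroundTruth)")
    fs = kernel.frame_rate
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("trace would be shorter than 2 samples")
    sig = np.zeros(n)
    inside = (truth.event_times >= 0) & (truth.event_times < duration)
    if not np.all(inside):
        logger.warning(
            "dropping %d event(s) outside the trace window [0, %.3f s)",
            int((~inside).sum()), duration,
        )
    # Per-event support: until the transient has decayed to <1e-4 of its peak.
    support = int(math.ceil(kernel.decay_tau * math.log(1e4) * fs)) + 1
    for t_e, amp in zip(truth.event_times[inside], truth.true_amplitudes[inside]):
        i0 = int(math.floor(t_e * fs))
        i1 = min(n, i0 + support)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - t_e
        sig[i0:i1] += amp * ca_kernel(t_rel, kernel.rise_tau, kernel.decay_tau)
    if kernel.noise_sd > 0:
        sig = sig + _rng(seed).normal(0.0, kernel.noise_sd, size=n)
    return Trace(sig, fs, units="dff")


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def eap_template_waveform(
    t: np.ndarray, template: EapTemplateParams, scale: float
) -> np.ndarray:
    """Closed-form noise-free EAP at times ``t`` (s, event at t=0), in pA.

    Primary depolarizing lobe (+), repolarizing lobe (−), then a secondary
    depolarizing lobe at ``scale`` × primary amplitude.  Depolarizing phase is
    rendered positive.
    """
    p = template
    wf = p.primary_amp * _gauss(t, 0.0, p.primary_width)
    wf -= p.repol_amp * _gauss(t, p.repol_delay, p.repol_width)
    wf += scale * p.primary_amp * _gauss(t, p.secondary_delay, p.secondary_width)
    return wf


def template_integral_peak(template: EapTemplateParams, scale: float) -> float:
    """Peak of the running integral of the noise-free template (pA·s).

    Evaluated on a dense grid spanning the template support; used as the
    noise-free ∫EAP in the Ca↔∫EAP coupling and as an analytic oracle.
    """
    t_hi = template.secondary_delay + 8 * template.secondary_width
    t_lo = -8 * template.primary_width
    t = np.linspace(t_lo, t_hi, 4001)
    wf = eap_template_waveform(t, template, scale)
    from scipy.integrate import cumulative_trapezoid

    integ = cumulative_trapezoid(wf, t, initial=0.0)
    return float(integ.max())


def render_eap_train(
    event_times: np.ndarray,
    template: EapTemplateParams,
    secondary_scales: np.ndarray,
    seed,
    duration: float | None = None,
) -> Trace:
    """Current trace (pA): one stereotyped waveform per event plus white noise."""
    event_times = np.asarray(event_times, dtype=float)
    secondary_scales = np.asarray(secondary_scales, dtype=float)
    if secondary_scales.size != event_times.size:
        raise ValueError(
            f"need one secondary scale per event: {secondary_scales.size} scales "
            f"for {event_times.size} events"
        )
    if np.any(secondary_scales < 0):
        raise ValueError("secondary scales must be >= 0")
    if duration is None:
        duration = (event_times.max() if event_times.size else 0.0) + 0.05
    fs = template.sample_rate
    n = int(round(duration * fs))
    sig = np.zeros(n)
    pre = 6 * template.primary_width
    post = template.secondary_delay + 8 * template.secondary_width
    for t_e, s in zip(event_times, secondary_scales):
        i0 = max(0, int(math.floor((t_e - pre) * fs)))
        i1 = min(n, int(math.ceil((t_e + post) * fs)))
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - t_e
        sig[i0:i1] += eap_template_waveform(t_rel, template, s)
    if template.noise_sd > 0:
        sig = sig + _rng(seed).normal(0.0, template.noise_sd, size=n)
    return Trace(sig, fs, units="pA")


@dataclass
class PairedConfig:
    """Configuration of a simultaneous Ca²⁺-imaging + cell-attached recording."""

    rate: float = 3 * DEFAULT_RATE_HZ  # electrode placement elevates activity
    duration: float = 120.0
    classes: SpikeClassParams = field(default_factory=SpikeClassParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    template: EapTemplateParams = field(default_factory=EapTemplateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel.frame_rate <= 0 or self.template.sample_rate <= 0:
            raise ValueError("both Ca and EAP sample rates must be specified and > 0")


def generate_paired_recording(config: PairedConfig) -> tuple[Trace, Trace, GroundTruth]:
    """Simultaneous Ca²⁺ and EAP traces driven by identical event times.

    The true Ca²⁺ amplitude of each event is
    ``coupling_slope × (noise-free ∫EAP peak) + N(0, coupling_noise_sd)``,
    so every EAP has a Ca²⁺ spike and vice versa, and the two amplitudes are
    linearly coupled up to the configured noise.
    """
    cfg = config
    times = generate_spike_train(cfg.rate, cfg.duration, spawn_rng(cfg.seed, 0))
    truth = assign_amplitudes(
        times, cfg.classes, spawn_rng(cfg.seed, 1), rate=cfg.rate, duration=cfg.duration,
        scale_median=cfg.template.secondary_rel_median, scale_iqr=cfg.template.secondary_rel_iqr,
    )
    ipeaks = np.array(
        [template_integral_peak(cfg.template, s) for s in truth.true_secondary_scales]
    )
    amp_noise = spawn_rng(cfg.seed, 2).normal(
        0.0, cfg.classes.coupling_noise_sd, size=truth.n_events
    )
    amps = cfg.classes.coupling_slope * ipeaks + amp_noise
    truth = replace(truth, true_amplitudes=np.clip(amps, 0.0, None))
    ca = render_ca_trace(truth, cfg.kernel, cfg.duration, seed=spawn_rng(cfg.seed, 3))
    eap = render_eap_train(
        truth.event_times, cfg.template, truth.true_secondary_scales,
        spawn_rng(cfg.seed, 4), duration=cfg.duration,
    )
    return ca, eap, truth


def coupling_noise_for_variance_ratio(
    integral_peaks: np.ndarray, slope: float, ratio: float
) -> float:
    """Coupling noise SD giving signal-variance / noise-variance = ``ratio``."""
    if ratio <= 0:
        raise ValueError("variance ratio must be > 0")
    sig_var = float(np.var(slope * np.asarray(integral_peaks, dtype=float)))
    return math.sqrt(sig_var / ratio)


@dataclass
class EffectConfig:
    """Tunables of the condition transforms (see :func:`apply_condition`)."""

    ml218_survival: float = 0.05     # fraction of events that survive T-type block
    electrode_factor: float = 3.0    # firing-rate multiplier from pipette contact
    stim_windows: tuple[tuple[float, float], ...] = ()  # (start, end) s, evoked trials
    evoked_rate: float = 2.0         # Hz inside a stimulus window
    classes: SpikeClassParams = field(default_factory=SpikeClassParams)


CONDITIONS = ("TTx", "Cd", "ML218", "electrode", "ACh", "ATP")


def apply_condition(
    truth: GroundTruth,
    condition: str,
    effect_config: EffectConfig | None = None,
    seed=None,
) -> GroundTruth:
    """Transform a ground truth according to a pharmacological/stimulus condition.

    - ``TTx``: identity — spikes are Ca²⁺-based, Na⁺-channel block has no effect.
    - ``Cd``: HVA block — large-class events are re-labelled small with
      amplitudes redrawn from the small class; all secondary scales drop to 0.
    - ``ML218``: T-type block — events thinned to ``ml218_survival``.
    - ``electrode``: mechanical activation — rate multiplied by
      ``electrode_factor`` (independent Poisson superposition).
    - ``ACh`` / ``ATP``: agonist ejection — evoked events inside the declared
      stimulus windows, large-class-only (ACh) or small-class-only (ATP).

    Transforms never create events outside declared stimulus windows and
    preserve event-time ordering.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; valid conditions: {', '.join(CONDITIONS)}"
        )
    eff = effect_config or EffectConfig()
    rng = _rng(seed)

    if condition == "TTx":
        return replace(truth)

    if condition == "Cd":
        large = truth.class_labels == "large"
        amps = truth.true_amplitudes.copy()
        amps[large] = rng.lognormal(
            eff.classes.small_amp_mu, eff.classes.small_amp_sigma, size=int(large.sum())
        )
        labels = np.full(truth.n_events, "small", dtype=object)
        scales = np.zeros(truth.n_events)
        return replace(
            truth, class_labels=labels, true_amplitudes=amps, true_secondary_scales=scales
        )

    if condition == "ML218":
        keep = rng.random(truth.n_events) < eff.ml218_survival
        return replace(
            truth,
            event_times=truth.event_times[keep],
            class_labels=truth.class_labels[keep],
            true_amplitudes=truth.true_amplitudes[keep],
            true_secondary_scales=truth.true_secondary_scales[keep],
            rate=truth.rate * eff.ml218_survival,
        )

    if condition == "electrode":
        if truth.duration is None:
            raise ValueError("electrode condition needs truth.duration to add events")
        extra_rate = (eff.electrode_factor - 1.0) * truth.rate
        extra_times = generate_spike_train(extra_rate, truth.duration, rng)
        extra = assign_amplitudes(extra_times, eff.classes, rng, rate=extra_rate,
                                  duration=truth.duration)
        order = np.argsort(np.concatenate([truth.event_times, extra.event_times]))
        cat = lambda a, b: np.concatenate([a, b])[order]  # noqa: E731
        return replace(
            truth,
            event_times=cat(truth.event_times, extra.event_times),
            class_labels=cat(truth.class_labels, extra.class_labels),
            true_amplitudes=cat(truth.true_amplitudes, extra.true_amplitudes),
            true_secondary_scales=cat(
                truth.true_secondary_scales, extra.true_secondary_scales
            ),
            rate=truth.rate * eff.electrode_factor,
        )

    # ACh / ATP evoked trials
    if not eff.stim_windows:
        raise ValueError(f"{condition} requires stim_windows in the EffectConfig")
    new_times = []
    for start, end in eff.stim_windows:
        if end <= start:
            raise ValueError(f"bad stimulus window ({start}, {end})")
        w = generate_spike_train(eff.evoked_rate, end - start, rng) + start
        new_times.append(w)
    times = np.sort(np.concatenate(new_times)) if new_times else np.empty(0)
    n = times.size
    if condition == "ACh":
        amps = rng.lognormal(eff.classes.large_amp_mu, eff.classes.large_amp_sigma, size=n)
        labels = np.full(n, "large", dtype=object)
        scales = draw_secondary_scales(n, rng)
    else:  # ATP: small, T-type-only events
        amps = rng.lognormal(eff.classes.small_amp_mu, eff.classes.small_amp_sigma, size=n)
        labels = np.full(n, "small", dtype=object)
        scales = np.zeros(n)
    merged = np.argsort(np.concatenate([truth.event_times, times]), kind="stable")
    cat = lambda a, b: np.concatenate([a, b])[merged]  # noqa: E731
    return replace(
        truth,
        event_times=cat(truth.event_times, times),
        class_labels=cat(truth.class_labels, labels),
        true_amplitudes=cat(truth.true_amplitudes, amps),
        true_secondary_scales=cat(truth.true_secondary_scales, scales),
    )
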