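"""Synthetic 64-channel EEG with planted early visual components.

The generator emulates the two experimental designs this package analyzes:

* Experiment 1 — spider and wheel silhouettes at five screen locations
  (fixation plus four quadrants), 200 trials per category x location,
  150 ms stimulus, fixed 850 ms inter-trial interval, eight blocks.
* Experiment 2 — both categories at fixation only, 500 trials each,
  jittered ITI drawn from {750, 800, 850, 900, 950} ms (mean 850 ms),
  four blocks.

Each stimulus plants a negative posterior deflection near 40 ms and a
later positive deflection (~80 ms in design 1, ~105 ms in design 2) with
Gaussian temporal profile and spherical-Gaussian scalp topography.
Spider trials receive an extra peak-to-peak separation split between the
two deflections. Background activity is white plus 1/f-shaped noise, a
10 Hz alpha rhythm (optionally phase-locked to stimulus onset, emulating
entrainment by a strictly periodic stimulus train), a common-mode slow
drift removed by nose-reference subtraction, and stereotyped blinks
loading on frontal channels and the EOG derivations.

``noise_scale`` supports variance-preserving scaled-down runs: simulating
n' trials per condition with stochastic amplitudes scaled by
sqrt(n' / n_full) leaves the sampling law of per-condition *averages*
unchanged for the Gaussian background components. Deterministic parts
(evoked templates, phase-locked alpha) are never scaled.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ContinuousRecording
from .layout import ChannelLayout

LOCATIONS = ("FIX", "UL", "UR", "LL", "LR")
CATEGORIES = ("spider", "wheel")

#: auxiliary channels appended after the 64 scalp channels
AUX_CHANNELS = ("Nose", "VEOG", "HEOG")

STIMULUS_DURATION_MS = 150.0
EXP2_ITI_SET_MS = (750.0, 800.0, 850.0, 900.0, 950.0)


# ---------------------------------------------------------------------------
# trial plans
# ---------------------------------------------------------------------------

def design_sequence(
    experiment: int,
    seed: int,
    trials_per_condition: int | None = None,
    locations: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Build a randomized trial plan for one participant.

    Parameters
    ----------
    experiment : {1, 2}
        Design 1: both categories at all five locations, fixed 850 ms ITI,
        eight blocks. Design 2: fixation only, jittered ITI, four blocks.
    seed : int
        Seeds the presentation-order permutation, the ITI draw (design 2)
        and the fixation-dot task trials.
    trials_per_condition : int, optional
        Override the per-condition trial count (200 for design 1,
        500 for design 2). Used for scaled-down runs.
    locations : tuple of str, optional
        Restrict design 1 to a subset of stimulus locations (scaled-down
        runs analyzing fixation only). Ignored for design 2.

    Returns
    -------
    DataFrame with columns trial_index, category, location, onset_time_ms,
    iti_ms, block, dot_change, stimulus_ms.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), experiment]))

    if experiment == 1:
        full = 200
        npc = full if trials_per_condition is None else int(trials_per_condition)
        locs = LOCATIONS if locations is None else tuple(locations)
        if any(l not in LOCATIONS for l in locs):
            raise ValueError(f"unknown locations in {locs!r}")
        cells = [(c, l) for c in CATEGORIES for l in locs]
        n_blocks = max(1, round(8 * npc / full))
    else:
        full = 500
        npc = full if trials_per_condition is None else int(trials_per_condition)
        cells = [(c, "FIX") for c in CATEGORIES]
        n_blocks = max(1, round(4 * npc / full))

    cats, locs = zip(*[cell for cell in cells for _ in range(npc)])
    order = rng.permutation(len(cats))
    cats = np.asarray(cats)[order]
    locs = np.asarray(locs)[order]
    n = len(cats)

    if experiment == 1:
        iti = np.full(n, 850.0)
    else:
        iti = rng.choice(EXP2_ITI_SET_MS, size=n)
    soa = STIMULUS_DURATION_MS + iti
    onset = 2000.0 + np.concatenate([[0.0], np.cumsum(soa[:-1])])

    blocks = np.concatenate(
        [np.full(len(ix), b) for b, ix in enumerate(np.array_split(np.arange(n), n_blocks))]
    )
    dot = np.zeros(n, dtype=bool)
    for b in range(n_blocks):
        members = np.flatnonzero(blocks == b)
        # 1-5 dot trials per full-size (250-trial) block; scaled-down blocks
        # keep the ~1-2% task-trial rate rather than the absolute count
        k = int(rng.integers(1, 6))
        k = max(1, min(k, max(1, len(members) // 50)))
        dot[rng.choice(members, size=min(k, len(members)), replace=False)] = True

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "category": cats,
            "location": locs,
            "onset_time_ms": onset,
            "iti_ms": iti,
            "block": blocks,
            "dot_change": dot,
            "stimulus_ms": STIMULUS_DURATION_MS,
        }
    )


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentTemplate:
    """A planted deflection: Gaussian in time, spherical Gaussian on the scalp.

    ``peak_latency_ms`` may be a scalar or a per-location mapping;
    ``center`` likewise names the channel on which the topography peaks
    (per location for contralateral components). ``effect_share`` is the
    fraction of the category peak-to-peak effect carried by this
    deflection. ``topography`` may override the spherical Gaussian with an
    explicit weight vector (length = number of scalp channels).
    """

    name: str
    polarity: int  # -1 negative, +1 positive
    amplitude_uv: float
    width_ms: float  # FWHM of the temporal Gaussian
    peak_latency_ms: float | dict
    center: str | dict = "Oz"
    spread: float = 0.5
    effect_share: float = 0.5
    topography: tuple | None = None

    def latency(self, location: str) -> float:
        if isinstance(self.peak_latency_ms, dict):
            return float(self.peak_latency_ms[location])
        return float(self.peak_latency_ms)

    def center_channel(self, location: str) -> str:
        if isinstance(self.center, dict):
            return self.center[location]
        return self.center

    def topo_weights(self, layout: ChannelLayout, location: str) -> np.ndarray:
        if self.topography is not None:
            w = np.asarray(self.topography, dtype=float)
            if w.shape != (layout.n_channels,):
                raise ValueError(
                    f"topography length {w.shape} does not match layout "
                    f"({layout.n_channels} channels)"
                )
            if w.min() < 0 or w.max() > 1:
                raise ValueError("topography weights must lie in [0, 1]")
            return w
        c = layout.positions[layout.index(self.center_channel(location))]
        d2 = np.sum((layout.positions - c) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * self.spread**2))

    def waveform(self, times_ms: np.ndarray, location: str) -> np.ndarray:
        """Unit-amplitude temporal profile on the given time axis (ms)."""
        sigma = self.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((times_ms - self.latency(location)) / sigma) ** 2)


def default_templates(experiment: int) -> tuple[ComponentTemplate, ...]:
    """Planted components for each design (latencies follow the designs)."""
    if experiment == 1:
        return (
            ComponentTemplate(
                name="N40", polarity=-1, amplitude_uv=3.5, width_ms=20.0,
                peak_latency_ms=39.0,
                center={"FIX": "Oz", "UL": "PO8", "UR": "PO7", "LL": "PO8", "LR": "PO7"},
                spread=0.5, effect_share=0.5,
            ),
            ComponentTemplate(
                name="P80", polarity=+1, amplitude_uv=4.0, width_ms=30.0,
                peak_latency_ms={"FIX": 80.0, "LL": 88.0, "LR": 86.0, "UL": 90.0, "UR": 101.0},
                center={"FIX": "POz", "UL": "PO8", "UR": "PO7", "LL": "PO8", "LR": "PO7"},
                spread=0.55, effect_share=0.5,
            ),
        )
    return (
        ComponentTemplate(
            name="N40", polarity=-1, amplitude_uv=3.5, width_ms=20.0,
            peak_latency_ms=45.0, center="Oz", spread=0.5, effect_share=0.5,
        ),
        ComponentTemplate(
            name="P100", polarity=+1, amplitude_uv=4.0, width_ms=36.0,
            peak_latency_ms=105.0, center="POz", spread=0.55, effect_share=0.5,
        ),
    )


@dataclass(frozen=True)
class SimParams:
    """Signal-model parameters. Amplitudes in microvolts, latencies in ms.

    The defaults are the package's stated synthetic world: evoked
    amplitudes of a few microvolts over posterior sites against a much
    larger single-trial background, a 1.2 uV category effect on
    peak-to-peak amplitude with a 1.0 uV between-participant SD, and 30%
    amplitude for peripheral stimuli (peripheral under-representation).
    The effect parameters are calibrated so that at the full design's
    trial counts the fixation peak-to-peak contrast has a population
    effect size of d ~ 0.75 once measurement noise (~1.2 uV on factor
    scores) is included. The 8 ms trigger-to-screen lag is corrected
    during preprocessing.
    """

    n_participants: int = 36
    sampling_rate: float = 512.0
    component_templates: tuple = field(default_factory=lambda: default_templates(1))
    category_effect_ptp: float = 1.2
    participant_effect_sd: float = 1.0
    peripheral_scale: float = 0.3
    alpha_amplitude: float = 3.0      # random-phase per-trial alpha, uV
    prestim_alpha_uv: float = 2.0     # anticipatory baseline alpha burst, uV
    alpha_phase_locked: bool = True
    alpha_freq: float = 10.0
    noise_sd: float = 8.0             # white broadband, uV
    pink_sd: float = 4.0              # 1/f-shaped, uV RMS
    drift_amplitude: float = 20.0     # common-mode slow drift, uV
    drift_freq: float = 0.2
    blink_rate: float = 8.0           # per minute
    blink_amplitude: float = 150.0    # on the vertical EOG derivation
    amplitude_scale_sd: float = 0.15  # participant-level multiplicative spread
    trigger_lag_ms: float = 8.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        amps = [t.amplitude_uv for t in self.component_templates]
        if not np.all(np.isfinite(amps)):
            raise ValueError("component amplitudes must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def scaled_params(params: SimParams, full_trials: int, scaled_trials: int) -> SimParams:
    """Variance-preserving reduction: fewer trials, proportionally less noise.

    For Gaussian stationary background (white, 1/f, random-phase alpha) the
    per-condition trial average from ``scaled_trials`` trials with
    amplitudes scaled by sqrt(scaled/full) has exactly the law of the
    full-size average. Deterministic signal content is untouched.
    """
    if not (0 < scaled_trials <= full_trials):
        raise ValueError("need 0 < scaled_trials <= full_trials")
    return replace(params, noise_scale=params.noise_scale * np.sqrt(scaled_trials / full_trials))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth implied by the parameters (population-level).

    ``true_effect_size_d`` is the noise-free effect size (category effect
    over between-participant SD), an upper bound on the realized contrast
    effect size; measurement noise at the full design's trial counts
    attenuates it to ~0.75 under the default parameters.
    """

    true_amplitude: dict        # (category, component name) -> uV at topo peak, FIX
    true_ptp_difference: float  # spider - wheel peak-to-peak, uV
    true_effect_size_d: float   # ptp difference / between-participant SD


def make_truth(params: SimParams) -> SimTruth:
    amp = {}
    for t in params.component_templates:
        for cat in CATEGORIES:
            extra = t.effect_share * params.category_effect_ptp if cat == "spider" else 0.0
            amp[(cat, t.name)] = t.polarity * (t.amplitude_uv + extra)
    d = (
        params.category_effect_ptp / params.participant_effect_sd
        if params.participant_effect_sd > 0
        else (np.inf if params.category_effect_ptp > 0 else 0.0)
    )
    return SimTruth(
        true_amplitude=amp,
        true_ptp_difference=params.category_effect_ptp,
        true_effect_size_d=d,
    )


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def _background_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, white_sd: float, pink_sd: float
) -> np.ndarray:
    """White + 1/f-shaped Gaussian noise, channels independent.

    Synthesized directly in the frequency domain (one inverse FFT) with
    analytic normalization, so the white and pink parts have exactly the
    requested time-domain standard deviations in expectation.
    """
    n = n_samples
    nf = n // 2 + 1
    k = np.arange(nf, dtype=float)
    s2 = np.zeros(nf)
    if white_sd > 0:
        s2 += white_sd**2 * n / 2.0
    if pink_sd > 0:
        inv_f = np.zeros(nf)
        inv_f[1:] = 1.0 / k[1:]
        inv_f[-1] = 0.0 if n % 2 == 0 else inv_f[-1]
        tot = inv_f.sum()
        if tot > 0:
            s2 += pink_sd**2 * (n**2 / 4.0) * inv_f / tot
    s = np.sqrt(s2)
    s[0] = 0.0
    if n % 2 == 0:
        s[-1] = 0.0
    z = rng.standard_normal((n_channels, nf)) + 1j * rng.standard_normal((n_channels, nf))
    return np.fft.irfft(z * s[None, :], n=n, axis=-1)


def _alpha_series(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    onsets: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """Ongoing 10 Hz activity with a random phase per trial segment."""
    t = np.arange(n_samples) / rate
    w = 2.0 * np.pi * params.alpha_freq
    out = np.zeros(n_samples)
    bounds = np.concatenate([[0], onsets, [n_samples]]).astype(int)
    a_rand = params.alpha_amplitude * params.noise_scale
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            continue
        phi = rng.uniform(0, 2 * np.pi)
        out[lo:hi] += a_rand * np.sin(w * t[lo:hi] + phi)
    return out


def _prestim_burst(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    onsets: np.ndarray,
    params: SimParams,
) -> np.ndarray:
    """Anticipatory alpha burst filling the 100 ms before each stimulus.

    Emulates pre-stimulus alpha synchronization that desynchronizes at
    stimulus onset (event-related desynchronization): exactly one 10 Hz
    cycle spanning the baseline window, zero at both ends, hence zero mean
    over the baseline and no content after onset. Under a strictly
    periodic stimulus train (``alpha_phase_locked``) the burst phase is
    locked trial to trial and survives averaging in full, dominating the
    baseline variability of averaged waveforms; with a jittered train the
    phase is random per trial and averages out.
    """
    out = np.zeros(n_samples)
    if params.prestim_alpha_uv <= 0:
        return out
    nb = int(round(0.100 * rate))
    k = np.arange(nb)
    base_phase = 2.0 * np.pi * params.alpha_freq * (k - nb) / rate
    for s in onsets:
        lo = int(s) - nb
        if lo < 0:
            continue
        phi = 0.0 if params.alpha_phase_locked else rng.uniform(0, 2 * np.pi)
        # taper guarantees zero endpoints even with a random phase
        taper = np.sin(np.pi * k / nb) ** 2 if not params.alpha_phase_locked else 1.0
        out[lo : int(s)] += params.prestim_alpha_uv * np.sin(base_phase + phi) * taper
    return out


def simulate_recording(
    plan: pd.DataFrame,
    layout: ChannelLayout,
    params: SimParams,
    participant: int = 0,
) -> tuple[ContinuousRecording, SimTruth]:
    """Synthesize one participant's continuous recording from a trial plan.

    The recorded trigger marks *precede* the actual screen onset by
    ``trigger_lag_ms``; planted components are time-locked to the actual
    onset, so downstream lag correction is required (and exercised).

    Returns the recording (64 scalp channels + Nose reference + VEOG/HEOG)
    and the parameter-implied ground truth.
    """
    if len(plan) == 0:
        raise ValueError("empty trial plan")
    rate = params.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 7919, int(participant)]))

    n_scalp = layout.n_channels
    names = list(layout.names) + list(AUX_CHANNELS)
    last_onset = float(plan["onset_time_ms"].iloc[-1])
    n_samples = int(np.ceil((last_onset + 1500.0) * rate / 1000.0))
    data = np.zeros((len(names), n_samples))

    # participant-level heterogeneity
    u_p = rng.normal(0.0, params.participant_effect_sd)
    pscale = max(0.5, 1.0 + params.amplitude_scale_sd * rng.standard_normal())

    # --- background -------------------------------------------------------
    if params.noise_sd > 0 or params.pink_sd > 0:
        data[:n_scalp] += _background_noise(
            rng,
            n_scalp,
            n_samples,
            params.noise_sd * params.noise_scale,
            params.pink_sd * params.noise_scale,
        )

    trig_recorded = np.round(plan["onset_time_ms"].to_numpy() * rate / 1000.0).astype(int)
    onset_samples = np.round(
        (plan["onset_time_ms"].to_numpy() + params.trigger_lag_ms) * rate / 1000.0
    ).astype(int)

    topo_alpha = np.where(layout.posterior_mask(), 0.85, 0.2)
    if params.alpha_amplitude > 0:
        alpha = _alpha_series(rng, n_samples, rate, onset_samples, params)
        data[:n_scalp] += topo_alpha[:, None] * alpha[None, :]
    if params.prestim_alpha_uv > 0:
        burst = _prestim_burst(rng, n_samples, rate, onset_samples, params)
        topo_burst = np.where(layout.posterior_mask(), 0.9, 0.3)
        data[:n_scalp] += topo_burst[:, None] * burst[None, :]

    if params.drift_amplitude > 0:
        t = np.arange(n_samples) / rate
        drift = params.drift_amplitude * np.sin(
            2 * np.pi * params.drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
        data += drift[None, :]  # common mode on every channel incl. Nose

    # --- evoked components ------------------------------------------------
    spider_extra = params.category_effect_ptp + u_p
    for tmpl in params.component_templates:
        sigma = tmpl.width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sig_samp = sigma * rate / 1000.0
        for loc in plan["location"].unique():
            topo = tmpl.topo_weights(layout, loc)
            lat_samp = tmpl.latency(loc) * rate / 1000.0
            klo = int(np.floor(lat_samp - 4.0 * sig_samp))
            khi = int(np.ceil(lat_samp + 4.0 * sig_samp))
            k = np.arange(klo, khi + 1)
            bump = np.exp(-0.5 * ((k - lat_samp) / sig_samp) ** 2)
            s_loc = 1.0 if loc == "FIX" else params.peripheral_scale
            for cat in CATEGORIES:
                mag = tmpl.amplitude_uv * pscale
                if cat == "spider":
                    mag = mag + tmpl.effect_share * spider_extra
                signal = tmpl.polarity * s_loc * mag * np.outer(topo, bump)
                rows = plan[(plan["location"] == loc) & (plan["category"] == cat)]
                for s in onset_samples[rows.index.to_numpy()]:
                    lo, hi = s + klo, s + khi + 1
                    a, b = max(lo, 0), min(hi, n_samples)
                    data[:n_scalp, a:b] += signal[:, a - lo : (a - lo) + (b - a)]

    # --- blinks and EOG ---------------------------------------------------
    i_nose = names.index("Nose")
    i_veog = names.index("VEOG")
    i_heog = names.index("HEOG")
    data[i_veog] += rng.normal(0, 3.0, n_samples)
    data[i_heog] += rng.normal(0, 3.0, n_samples)
    data[i_nose] += rng.normal(0, 1.0, n_samples)
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * n_samples / rate / 60.0)
        blen = int(0.4 * rate)
        prof = np.sin(np.pi * np.arange(blen) / blen) ** 2
        w_blink = np.clip(layout.positions[:, 1], 0.0, None) ** 2 * 0.6
        for s in np.sort(rng.integers(0, max(1, n_samples - blen), n_blinks)):
            seg = slice(s, s + blen)
            data[i_veog, seg] += params.blink_amplitude * prof
            data[i_heog, seg] += 0.25 * params.blink_amplitude * prof
            data[:n_scalp, seg] += params.blink_amplitude * np.outer(w_blink, prof)

    triggers = pd.DataFrame(
        {
            "sample": trig_recorded,
            "category": plan["category"].to_numpy(),
            "location": plan["location"].to_numpy(),
            "dot_change": plan["dot_change"].to_numpy(),
        }
    )
    rec = ContinuousRecording(
        data=data,
        sampling_rate=rate,
        channel_names=names,
        triggers=triggers,
        participant=participant,
    )
    return rec, make_truth(params)


def evoked_template(
    params: SimParams,
    layout: ChannelLayout,
    location: str,
    category: str,
    times_ms: np.ndarray,
    participant_dev: float = 0.0,
    pscale: float = 1.0,
) -> np.ndarray:
    """Population evoked waveform (channels x samples) implied by the model.

    ``times_ms`` is relative to actual stimulus onset. Used as the oracle
    in noiseless-limit checks and recovery tests.
    """
    out = np.zeros((layout.n_channels, len(times_ms)))
    s_loc = 1.0 if location == "FIX" else params.peripheral_scale
    for tmpl in params.component_templates:
        mag = tmpl.amplitude_uv * pscale
        if category == "spider":
            mag = mag + tmpl.effect_share * (params.category_effect_ptp + participant_dev)
        out += (
            tmpl.polarity
            * s_loc
            * mag
            * np.outer(tmpl.topo_weights(layout, location), tmpl.waveform(times_ms, location))
        )
    return out
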