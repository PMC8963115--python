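"""Synthetic study generator.

Emulates a complete cybersickness evaluation study — a participant panel,
per-scene ordinal sickness ratings, rendered frame sequences with exact
ground-truth motion, questionnaire responses, and physiological recordings —
with the statistical structure the downstream analyses assume, so the whole
pipeline is testable end to end without any recorded data.

The rating model is a thresholded-latent (cumulative-link) ordinal model:
each (participant, scene) cell has a latent severity

    latent = baseline + motion term + factor modifiers
             + susceptibility * z(MSSQ) + age-controllability interaction
             + Gaussian noise,

and the emitted 1-5 score counts how many of four increasing cut points the
noisy latent exceeds.  The motion term pools the per-component severity
weights sublinearly (dominant component plus a scaled sum of the rest),
reflecting that complex motion is worse than simple motion but not
additively so.  Default weights are calibrated so that condition means fall
in the 1.1-3.0 range typical of scene-level opinion scores, with the
factor directions of the severity literature: roll > pitch > yaw rotation,
backward > lateral > forward translation, vertical > forward, faster and
accelerating motion worse, small field of view / frame reference /
controllability protective, longer exposure worse, and higher-susceptibility
and (for controllable scenes) older participants sicker.

EEG epochs are sums of band-limited noise whose relative band powers follow
channel-specific linear trends in the sickness level; by default the six
frontal/temporal features known to track cybersickness severity are active
(Fp1 and Fp2 and T4 delta share increasing, Fp1 and T4 beta and Fp2 gamma
share decreasing).  ECG is a QRS template train with configurable rate and
RR jitter; GSR is a slow tonic drift plus phasic bumps scaled by level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import ndimage

from .biosignals import EEG_CHANNELS, SignalEpoch
from .scenes import Scene, SPEED_MPS

__all__ = [
    "ParticipantProfile",
    "EffectConfig",
    "gen_panel",
    "gen_scores",
    "gen_ssq",
    "render_scene_motion",
    "gen_eeg",
    "gen_ecg",
    "gen_gsr",
    "PANEL_GROUP_MIX",
]

# Panel composition of the emulated study: (young men, young women,
# middle-aged men, middle-aged women) out of 154 valid participants.
PANEL_GROUP_COUNTS = {
    ("young", "man"): 43,
    ("young", "woman"): 63,
    ("middle_aged", "man"): 28,
    ("middle_aged", "woman"): 20,
}
PANEL_GROUP_MIX = {k: v / 154 for k, v in PANEL_GROUP_COUNTS.items()}

AGE_BOUNDARY = 30  # years; "young" is strictly under 30


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    sex: str  # "man" | "woman"
    age_years: int
    mssq_a: float
    mssq_b: float

    def __post_init__(self) -> None:
        if self.sex not in ("man", "woman"):
            raise ValueError(f"unknown sex token {self.sex!r}")
        if self.age_years < 14:
            raise ValueError("participants are at least 14 years old")
        if self.mssq_a < 0 or self.mssq_b < 0:
            raise ValueError("susceptibility scores are nonnegative")

    @property
    def group(self) -> str:
        return "young" if self.age_years < AGE_BOUNDARY else "middle_aged"

    @property
    def mssq_total(self) -> float:
        return self.mssq_a + self.mssq_b


def _default_component_weights() -> dict:
    return {
        "ry": 1.13, "rr": 2.04, "rp": 1.90,
        "tf": 0.11, "tb": 0.28, "tl": 0.15, "tu": 0.31, "td": 0.26,
    }


def _default_eeg_slopes() -> dict:
    # share change per sickness level for the six severity-tracking features
    return {
        ("Fp1", "delta"): 0.020,
        ("Fp1", "beta"): -0.012,
        ("Fp2", "delta"): 0.020,
        ("Fp2", "gamma"): -0.008,
        ("T4", "delta"): 0.015,
        ("T4", "beta"): -0.012,
    }


def _default_band_baseline() -> dict:
    return {"delta": 0.30, "theta": 0.15, "alpha": 0.25, "beta": 0.20, "gamma": 0.10}


@dataclass(frozen=True)
class EffectConfig:
    """All knobs of the generative study model.

    Severity weights are on the latent 1-5 scale.  ``secondary_scale``
    pools multi-component motion sublinearly: the motion term is the largest
    component weight plus ``secondary_scale`` times the sum of the others.
    Relief weights are negative.  ``susceptibility_weight`` multiplies the
    panel-standardized overall MSSQ score; ``age_controllability_weight`` is
    added for middle-aged participants on controllable scenes (control
    proficiency interaction).  ``thresholds`` are the four ordinal cut
    points on the latent scale.
    """

    component_weights: dict = field(default_factory=_default_component_weights)
    secondary_scale: float = 0.15
    speed_fast_weight: float = 0.42
    acceleration_weight: float = 0.30
    duration_long_weight: float = 0.55
    fov_small_relief: float = -0.10
    fov_middle_relief: float = 0.0
    frame_reference_relief: float = -0.28
    controllability_relief: float = -0.45
    susceptibility_weight: float = 0.25
    age_controllability_weight: float = 0.50
    baseline: float = 1.0
    noise_sd: float = 0.75
    thresholds: tuple = (1.5, 2.5, 3.5, 4.5)
    # EEG generative model
    band_baseline: dict = field(default_factory=_default_band_baseline)
    eeg_slopes: dict = field(default_factory=_default_eeg_slopes)
    blink_rate_hz: float = 0.0  # blink bursts per second on frontal channels
    blink_amplitude: float = 8.0  # in units of the clean-signal s.d.
    # ECG / GSR
    rr_jitter_s: float = 0.02
    resting_bpm: float = 72.0
    gsr_drift_period_s: float = 60.0
    gsr_phasic_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("latent noise s.d. must be positive")
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("ordinal thresholds must be strictly increasing")

    def with_(self, **kwargs) -> "EffectConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# panel and ratings
# ---------------------------------------------------------------------------

def gen_panel(n: int, group_mix: dict | None = None, seed: int = 0) -> list:
    """Draw a reproducible participant panel.

    ``group_mix`` maps (group, sex) pairs to proportions (summing to 1);
    group sizes follow a largest-remainder apportionment, so the default mix
    at n=154 reproduces the (43, 63, 28, 20) composition exactly.  Ages are
    uniform on [14, 29] for the young group and [30, 59] otherwise; the two
    MSSQ section scores are independent truncated normals.
    """
    if n < 1:
        raise ValueError("panel size must be at least 1")
    mix = dict(group_mix) if group_mix is not None else dict(PANEL_GROUP_MIX)
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng(seed)

    keys = list(mix)
    quotas = np.array([mix[k] * n for k in keys])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    for idx in np.argsort(-(quotas - counts), kind="stable")[:remainder]:
        counts[idx] += 1

    panel = []
    pid = 0
    for (group, sex), count in zip(keys, counts):
        lo, hi = (14, AGE_BOUNDARY - 1) if group == "young" else (AGE_BOUNDARY, 59)
        for _ in range(count):
            pid += 1
            age = int(rng.integers(lo, hi + 1))
            mssq_a = float(np.clip(rng.normal(10.0, 6.0), 0.0, None))
            mssq_b = float(np.clip(rng.normal(8.0, 5.0), 0.0, None))
            panel.append(
                ParticipantProfile(f"P{pid:03d}", sex, age, mssq_a, mssq_b)
            )
    return panel


def _motion_term(scene: Scene, config: EffectConfig) -> float:
    weights = sorted(
        (config.component_weights[c] for c in scene.components), reverse=True
    )
    if not weights:
        return 0.0
    return weights[0] + config.secondary_scale * sum(weights[1:])


def scene_severity(scene: Scene, config: EffectConfig) -> float:
    """Deterministic (participant-independent) part of the latent severity."""
    latent = config.baseline + _motion_term(scene, config)
    if scene.translation_speed == "fast_9.2mps":
        latent += config.speed_fast_weight
    if scene.acceleration:
        latent += config.acceleration_weight
    if scene.duration_s >= 24:
        latent += config.duration_long_weight
    if scene.fov_deg == 30:
        latent += config.fov_small_relief
    elif scene.fov_deg == 45:
        latent += config.fov_middle_relief
    if scene.frame_reference:
        latent += config.frame_reference_relief
    if scene.controllable:
        latent += config.controllability_relief
    return latent


def gen_scores(panel, scenes, config: EffectConfig | None = None, seed: int = 0):
    """Generate the participants x scenes ordinal rating matrix.

    Returns ``(scores, latent)`` as two DataFrames indexed by participant id
    with one column per scene id: the emitted 1-5 ratings and the noisy
    latent severities they were thresholded from (for oracle tests).
    """
    if not panel or not scenes:
        raise ValueError("panel and scene list must be nonempty")
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)

    mssq = np.array([p.mssq_total for p in panel])
    sd = mssq.std()
    z = (mssq - mssq.mean()) / sd if sd > 0 else np.zeros_like(mssq)

    base = np.array([scene_severity(s, config) for s in scenes])  # per scene
    latent = base[None, :] + config.susceptibility_weight * z[:, None]
    middle = np.array([p.group == "middle_aged" for p in panel], dtype=float)
    ctrl = np.array([s.controllable for s in scenes], dtype=float)
    latent = latent + config.age_controllability_weight * np.outer(middle, ctrl)
    latent = latent + rng.normal(0.0, config.noise_sd, size=latent.shape)

    cuts = np.asarray(config.thresholds)
    scores = 1 + (latent[:, :, None] > cuts[None, None, :]).sum(axis=2)

    index = pd.Index([p.participant_id for p in panel], name="participant_id")
    columns = pd.Index([s.scene_id for s in scenes], name="scene_id")
    return (
        pd.DataFrame(scores, index=index, columns=columns),
        pd.DataFrame(latent, index=index, columns=columns),
    )


def gen_ssq(panel, scenes, config: EffectConfig | None = None, seed: int = 0,
            item_gain: float = 0.5) -> pd.DataFrame:
    """Generate 16-item SSQ responses at rest and after each scene category.

    Each participant's post-category symptom load is driven by the mean
    latent severity of that category's scenes for that participant (same
    latent model as :func:`gen_scores`, including susceptibility and the
    age-controllability interaction); the rest-state load is a small
    baseline.  Item levels are independent clipped Poisson draws whose mean
    is ``item_gain`` times the (nonnegative) load, so every subscale
    inherits the group structure.

    Returns a tidy DataFrame: participant_id, timepoint, item_1..item_16.
    """
    if not panel or not scenes:
        raise ValueError("panel and scene list must be nonempty")
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)

    mssq = np.array([p.mssq_total for p in panel])
    sd = mssq.std()
    z = (mssq - mssq.mean()) / sd if sd > 0 else np.zeros_like(mssq)

    rows = []
    for i, p in enumerate(panel):
        loads = {"rest": 0.3 + 0.1 * max(z[i], 0.0)}
        for cat in ("CCU", "CUA", "CUU"):
            cat_scenes = [s for s in scenes if s.category == cat]
            if not cat_scenes:
                continue
            sev = np.mean([scene_severity(s, config) for s in cat_scenes])
            sev += config.susceptibility_weight * z[i]
            if p.group == "middle_aged" and any(s.controllable for s in cat_scenes):
                sev += config.age_controllability_weight
            loads[f"post_{cat}"] = max(sev - 1.0, 0.05)
        for timepoint, load in loads.items():
            items = np.clip(rng.poisson(item_gain * load, size=16), 0, 3)
            rows.append(
                {"participant_id": p.participant_id, "timepoint": timepoint,
                 **{f"item_{j + 1}": int(v) for j, v in enumerate(items)}}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frames and ground-truth motion
# ---------------------------------------------------------------------------

# Pixel-displacement gains per unit of normalized image coordinate, chosen so
# flows stay within a few pixels per frame on the default 64x64 grid.
_TRANSLATION_GAIN = 0.35   # px per (m/s) for in-plane translations
_RADIAL_GAIN = 0.50        # px per (m/s) at the image border for tf/tb
_ROTATION_GAIN = 2.0       # px at the border for yaw/pitch, and roll tangential


def _analytic_flow(scene: Scene, shape, speed_scale: float = 1.0) -> np.ndarray:
    """One frame's ground-truth (H, W, 2) flow field implied by the camera motion."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    # normalized coordinates in [-1, 1], FOV scales the projection
    fov_scale = scene.fov_deg / 90.0
    xn = (2.0 * xs / (w - 1) - 1.0) * fov_scale
    yn = (2.0 * ys / (h - 1) - 1.0) * fov_scale
    u = np.zeros(shape)
    v = np.zeros(shape)
    speed = scene.translation_speed_mps * speed_scale
    for comp in scene.components:
        if comp == "ry":      # yaw: near-uniform lateral flow
            u += _ROTATION_GAIN
        elif comp == "rp":    # pitch: near-uniform vertical flow
            v += _ROTATION_GAIN
        elif comp == "rr":    # roll: rotation about the image center
            u += -_ROTATION_GAIN * yn
            v += _ROTATION_GAIN * xn
        elif comp == "tf":    # forward: divergent expansion
            u += _RADIAL_GAIN * speed * xn
            v += _RADIAL_GAIN * speed * yn
        elif comp == "tb":    # backward: contraction
            u += -_RADIAL_GAIN * speed * xn
            v += -_RADIAL_GAIN * speed * yn
        elif comp == "tl":
            u += _TRANSLATION_GAIN * speed
        elif comp == "tu":
            v += -_TRANSLATION_GAIN * speed
        elif comp == "td":
            v += _TRANSLATION_GAIN * speed
    return np.stack([u, v], axis=-1)


def render_scene_motion(scene: Scene, frames: int = 30, grid=(64, 64), seed: int = 0):
    """Render a moving random-dot texture plus its exact motion fields.

    Returns ``(frame_stack, fields)``: a (T, H, W) float image stack and a
    list of T-1 ground-truth (H, W, 2) flow fields, where ``fields[t]`` is
    the displacement of content from frame t to frame t+1 in pixels (dx,
    dy).  Translational flow scales with the scene's speed; under
    acceleration the per-frame speed ramps linearly from the initial value
    to ``acceleration_rate`` times it by the final field.  A scene with no
    motion components yields identical frames and all-zero fields.
    """
    if frames < 2:
        raise ValueError("need at least two frames")
    h, w = grid
    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=1.2, mode="wrap")

    n_fields = frames - 1
    fields = []
    for t in range(n_fields):
        if scene.acceleration and n_fields > 1:
            ramp = 1.0 + (scene.acceleration_rate - 1.0) * t / (n_fields - 1)
        else:
            ramp = 1.0
        fields.append(_analytic_flow(scene, (h, w), speed_scale=ramp))

    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    stack = np.empty((frames, h, w))
    stack[0] = texture
    cum_x = np.zeros((h, w))
    cum_y = np.zeros((h, w))
    for t in range(1, frames):
        cum_x += fields[t - 1][..., 0]
        cum_y += fields[t - 1][..., 1]
        # inverse warp: frame t samples the base texture back along the
        # accumulated displacement (exact for spatially uniform flow, a
        # small-displacement approximation otherwise)
        stack[t] = ndimage.map_coordinates(
            texture, [ys - cum_y, xs - cum_x], order=3, mode="grid-wrap"
        )
    return stack, fields


# ---------------------------------------------------------------------------
# physiological signals
# ---------------------------------------------------------------------------

def _band_noise(rng, n, fs, low, high):
    """Unit-variance Gaussian noise band-limited to [low, high) Hz."""
    x = rng.standard_normal(n + 2 * int(fs))
    sos = sps.butter(4, (low, min(high, fs / 2 - 1e-6)), btype="bandpass",
                     fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)[int(fs):int(fs) + n]
    return y / y.std()


def eeg_band_shares(channel: str, score_level: int, config: EffectConfig) -> dict:
    """Target relative band powers for one channel at one sickness level.

    A configured (channel, band) slope moves that band's share linearly in
    the level (centered at level 3); the remaining free bands are rescaled
    to keep the five disjoint shares summing to one, so configured shares
    are realized exactly.
    """
    from .biosignals import DISJOINT_BANDS

    shares = dict(config.band_baseline)
    configured = set()
    for (ch, band), slope in config.eeg_slopes.items():
        if ch == channel:
            shares[band] = shares[band] + slope * (score_level - 3)
            configured.add(band)
    for band in shares:
        shares[band] = max(shares[band], 0.01)
    fixed = sum(shares[b] for b in configured)
    free = [b for b in DISJOINT_BANDS if b not in configured]
    free_sum = sum(shares[b] for b in free)
    target_free = max(1.0 - fixed, 0.01 * len(free))
    for b in free:
        shares[b] = shares[b] * target_free / free_sum
    return shares


def gen_eeg(score_level: int, duration_s: float = 13.0,
            config: EffectConfig | None = None, seed: int = 0,
            fs: float = 256.0) -> SignalEpoch:
    """Synthesize one 8-channel EEG epoch at a given sickness level.

    Each channel sums independent band-limited noise components scaled so
    the relative band powers match :func:`eeg_band_shares`.  If
    ``config.blink_rate_hz`` is positive, correlated low-frequency
    high-amplitude bursts (an eye-blink surrogate) are added to the two
    frontal channels so that ICA-based artifact rejection has a target.
    """
    if not 1 <= score_level <= 5:
        raise ValueError("score level must be in 1..5")
    if duration_s < 4:
        raise ValueError("epoch must be at least 4 s for spectral estimation")
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    from .biosignals import EEG_BANDS, DISJOINT_BANDS

    samples = np.zeros((len(EEG_CHANNELS), n))
    for i, ch in enumerate(EEG_CHANNELS):
        shares = eeg_band_shares(ch, score_level, config)
        for band in DISJOINT_BANDS:
            low, high = EEG_BANDS[band]
            samples[i] += np.sqrt(shares[band]) * _band_noise(rng, n, fs, low, high)

    if config.blink_rate_hz > 0:
        n_blinks = rng.poisson(config.blink_rate_hz * duration_s)
        t = np.arange(n) / fs
        burst = np.zeros(n)
        sigma = 0.06  # s; ~0.3 s visible burst width
        for t0 in rng.uniform(0.5, duration_s - 0.5, size=n_blinks):
            burst += np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        amp = config.blink_amplitude * samples[0].std()
        samples[0] += amp * burst
        samples[1] += 0.9 * amp * burst
    return SignalEpoch(samples, fs, EEG_CHANNELS)


def _qrs_template(fs: float) -> np.ndarray:
    """A stylized QRS complex: sharp R wave with small Q/S side lobes.

    Sampled on a grid centered exactly on the R peak so that a jitter-free
    beat train has sample-exact, equidistant maxima.
    """
    half = int(0.06 * fs)
    t = np.arange(-half, half + 1) / fs
    r = np.exp(-0.5 * (t / 0.012) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.030) / 0.010) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.030) / 0.010) ** 2)
    return r + q + s


def gen_ecg(bpm: float, rr_jitter_s: float = 0.0, duration_s: float = 13.0,
            seed: int = 0, fs: float = 256.0,
            baseline_wander: float = 0.1, noise_sd: float = 0.01) -> SignalEpoch:
    """Synthesize a single-channel ECG as a jittered QRS template train.

    RR intervals are ``60/bpm`` plus zero-mean Gaussian jitter; beats are
    placed at the nearest sample.  A slow sinusoidal baseline wander and a
    small white-noise floor are added so detrending and peak detection are
    exercised.
    """
    if not 30 <= bpm <= 220:
        raise ValueError("bpm must be in [30, 220]")
    if rr_jitter_s < 0:
        raise ValueError("RR jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    x = noise_sd * rng.standard_normal(n)
    t = np.arange(n) / fs
    x += baseline_wander * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))

    template = _qrs_template(fs)
    half = len(template) // 2
    beat_t = 0.3
    while beat_t < duration_s - 0.3:
        idx = int(round(beat_t * fs))
        lo, hi = idx - half, idx - half + len(template)
        if 0 <= lo and hi <= n:
            x[lo:hi] += template
        rr = 60.0 / bpm + (rng.normal(0.0, rr_jitter_s) if rr_jitter_s > 0 else 0.0)
        beat_t += max(rr, 0.25)
    return SignalEpoch(x, fs, ("ECG",))


def gen_gsr(level: int, duration_s: float = 13.0, seed: int = 0,
            fs: float = 256.0, config: EffectConfig | None = None) -> SignalEpoch:
    """Synthesize a skin-conductance trace: tonic drift plus phasic bumps.

    The tonic level and the phasic bump amplitude both scale with the
    sickness level, giving downstream mean-amplitude features a monotone
    target.
    """
    if not 1 <= level <= 5:
        raise ValueError("level must be in 1..5")
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    tonic = 2.0 + 0.5 * level
    x = tonic + 0.2 * np.sin(2 * np.pi * t / config.gsr_drift_period_s
                             + rng.uniform(0, 2 * np.pi))
    n_bumps = rng.poisson(config.gsr_phasic_rate_hz * duration_s)
    for t0 in rng.uniform(0, duration_s, size=n_bumps):
        rise = 0.75
        x += 0.1 * level * np.exp(-0.5 * ((t - t0) / rise) ** 2) * (t > t0 - 2 * rise)
    x += 0.02 * rng.standard_normal(n)
    return SignalEpoch(x, fs, ("GSR",))
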