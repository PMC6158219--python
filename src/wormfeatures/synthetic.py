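"""Synthetic worms, labelled feature tables and pulse experiments.

The worm model is a travelling sinusoidal wave — tangent angle
theta(s, t) = A sin(2 pi (s / lambda - f t)) — advected along its body axis
at a scheduled speed.  It is not a biomechanical simulation, but it drives
every feature operator with known ground truth: length, widths, undulation
amplitude and frequency, speed, and the forward / backward / paused
schedule are all recoverable by the corresponding pipeline stage.

Feature tables are class-conditional Gaussians with planted informative
columns, and pulse experiments add a stimulus-locked mean shift on chosen
features with worm-level random effects (so frames within a worm are
correlated, which is what makes frame-level permutation anticonservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, PulseProtocol, WormTrajectory


@dataclass
class WormModelParams:
    """Ground-truth parameters of one synthetic worm."""

    length: float = 1000.0  # um
    max_width: float = 80.0  # um
    width_taper: float = 0.5
    amplitude: float = 0.6  # rad, undulation amplitude of the tangent angle
    wave_frequency: float = 0.5  # Hz
    wavelength_bl: float = 1.0  # spatial wavelength in body lengths
    speed: float = 300.0  # um/s while moving
    paused_wave_scale: float = 0.1  # wave-phase rate while paused
    schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [("forward", 30.0)]
    )
    noise_um: float = 0.0  # coordinate noise sd
    fps: float = 25.0
    n_points: int = 49
    ventral_side: str = "left"
    seed: int = 0

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.schedule)


def generate_worm(params: WormModelParams, worm_id: str = "sim", strain: str = "N2") -> WormTrajectory:
    """Simulate a travelling-wave worm following its state schedule."""
    rng = np.random.default_rng(params.seed)
    n_frames = max(2, int(round(params.duration * params.fps)))
    dt = 1.0 / params.fps
    times = np.arange(n_frames) * dt
    # signed centroid speed and wave-phase rate per frame from the schedule
    speed = np.zeros(n_frames)
    phase_rate = np.full(n_frames, params.wave_frequency)
    t0 = 0.0
    for state, dur in params.schedule:
        lo = int(round(t0 * params.fps))
        hi = int(round((t0 + dur) * params.fps))
        if state == "forward":
            speed[lo:hi] = params.speed
        elif state == "backward":
            speed[lo:hi] = -params.speed
        elif state == "paused":
            # a paused worm holds its posture: the body wave (almost) stops
            speed[lo:hi] = 0.0
            phase_rate[lo:hi] *= params.paused_wave_scale
        else:
            raise ValueError(f"unknown state {state!r}")
        t0 += dur
    head_x = np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])
    phase = np.concatenate([[0.0], np.cumsum(phase_rate[:-1] * dt)])

    P = params.n_points
    s = np.linspace(0.0, params.length, P)  # arc length from head tip
    ds = s[1] - s[0]
    lam = params.wavelength_bl * params.length
    skeleton = np.empty((n_frames, P, 2))
    for i in range(n_frames):
        theta = params.amplitude * np.sin(2 * np.pi * (s / lam + phase[i]))
        # head leads in +x; the body extends in -x behind the head, and the
        # shape is anchored at its centroid so the scheduled speed is the
        # actual centroid speed
        tang = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        body = -np.cumsum(tang * ds, axis=0) + tang * ds
        body -= body.mean(axis=0)
        skeleton[i, :, 0] = head_x[i] + body[:, 0]
        skeleton[i, :, 1] = body[:, 1]
    if params.noise_um > 0:
        skeleton += rng.normal(0.0, params.noise_um, size=skeleton.shape)
    frac = s / params.length
    width_profile = params.max_width * (4 * frac * (1 - frac)) ** params.width_taper
    widths = np.tile(width_profile, (n_frames, 1))
    return WormTrajectory(
        worm_id=worm_id,
        strain=strain,
        skeleton=skeleton,
        widths=widths,
        timestamps=times,
        fps=params.fps,
        ventral_side=params.ventral_side,
    )


@dataclass
class TableModelParams:
    """Ground truth for a labelled worms x features table."""

    n_strains: int = 4
    worms_per_strain: int = 50
    n_features: int = 125
    informative: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_sd: float = 2.0
    nan_rate: float = 0.0
    nan_columns: tuple[int, ...] = ()
    seed: int = 0


def generate_table(params: TableModelParams) -> FeatureTable:
    """Class-conditional Gaussian feature table with planted informative columns.

    Informative columns get a per-strain mean drawn from N(0, effect_sd^2);
    every other column is standard normal in all strains.  NaNs are injected
    at ``nan_rate`` into ``nan_columns``.
    """
    if max(params.informative, default=-1) >= params.n_features:
        raise ValueError("informative indices must be < n_features")
    rng = np.random.default_rng(params.seed)
    offsets = np.zeros((params.n_strains, params.n_features))
    offsets[:, list(params.informative)] = rng.normal(
        0.0, params.effect_sd, size=(params.n_strains, len(params.informative))
    )
    rows, worm_ids, strains = [], [], []
    for s in range(params.n_strains):
        x = rng.standard_normal((params.worms_per_strain, params.n_features))
        rows.append(x + offsets[s])
        strains += [f"strain_{s}"] * params.worms_per_strain
        worm_ids += [f"worm_{s}_{i}" for i in range(params.worms_per_strain)]
    values = np.concatenate(rows, axis=0)
    for col in params.nan_columns:
        mask = rng.random(values.shape[0]) < params.nan_rate
        values[mask, col] = np.nan
    names = [f"feature_{j:03d}" for j in range(params.n_features)]
    return FeatureTable(
        values=values, feature_names=names, worm_ids=worm_ids, strain_labels=strains
    )


@dataclass
class PulseModelParams:
    """Ground truth for a two-arm stimulation experiment."""

    n_features: int = 40
    n_worms_per_arm: int = 30
    effect_features: tuple[int, ...] = ()
    effect_sd: float = 0.0  # shift (in sd units) during pulses, treatment arm
    worm_sd: float = 0.5  # worm-level random intercept sd
    fps: float = 4.0
    strain: str = "simulated"
    seed: int = 0


def generate_pulse_experiment(
    params: PulseModelParams, protocol: PulseProtocol | None = None
) -> tuple[pd.DataFrame, PulseProtocol]:
    """Per-frame feature values for a treatment and a control arm.

    Returns a long-ish DataFrame with columns ``worm_id``, ``strain``,
    ``condition``, ``time_s`` and one column per feature.  Frames of the
    treatment arm have their ``effect_features`` shifted by ``effect_sd``
    whenever the frame lies inside a stimulation pulse.  Worm-level random
    intercepts make frames within a worm correlated.
    """
    if protocol is None:
        protocol = PulseProtocol.default()
    rng = np.random.default_rng(params.seed)
    end = max(stop for _, stop in protocol.short_pulses + protocol.long_pulses) + 30.0
    times = np.arange(0.0, end, 1.0 / params.fps)
    in_pulse = np.zeros(times.shape, dtype=bool)
    for start, stop in protocol.short_pulses + protocol.long_pulses:
        in_pulse |= (times >= start) & (times < stop)
    names = [f"feature_{j:03d}" for j in range(params.n_features)]
    frames = []
    for condition, n in (("treatment", params.n_worms_per_arm), ("control", params.n_worms_per_arm)):
        for w in range(n):
            base = rng.normal(0.0, params.worm_sd, size=params.n_features)
            values = base + rng.standard_normal((times.size, params.n_features))
            if condition == "treatment" and params.effect_features:
                values[np.ix_(in_pulse, list(params.effect_features))] += params.effect_sd
            df = pd.DataFrame(values, columns=names)
            df.insert(0, "time_s", times)
            df.insert(0, "condition", condition)
            df.insert(0, "strain", params.strain)
            df.insert(0, "worm_id", f"{condition}_{w}")
            frames.append(df)
    return pd.concat(frames, ignore_index=True), protocol
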