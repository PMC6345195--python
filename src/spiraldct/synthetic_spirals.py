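"""Simulated Archimedes'-spiral drawings with controllable kinetic tremor.

The generator emulates what a digitizing tablet records while a subject
traces a spiral template over tens of seconds: a smooth base trajectory
x = p*theta*cos(theta), y = p*theta*sin(theta) with monotone angular
progress, plus three disturbance terms —

* a sinusoidal kinetic tremor in the 4–12 Hz band, injected along the radial
  direction or (default) perpendicular to the instantaneous pen path,
* slow low-pass-filtered drift (posture/arm wander), and
* white sensor jitter.

Cohorts mimic the clinical study design: ET-like subjects draw with a tremor
amplitude drawn from a range well above the control range, both classes share
the 4–12 Hz frequency band.  Ground-truth parameters go to a separate
manifest so downstream feature code cannot see them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .ingest import DrawingSample, Label, ParameterError

DEFAULT_PITCH = 3.0  # length units per radian of spiral growth

#: Tremor-amplitude presets, in length units, relative to DEFAULT_PITCH.
#: Disjoint ranges with min(ET)/max(control) = 5.
ET_AMP_RANGE = (0.4 * DEFAULT_PITCH, 1.2 * DEFAULT_PITCH)
CONTROL_AMP_RANGE = (0.02 * DEFAULT_PITCH, 0.08 * DEFAULT_PITCH)


@dataclass
class SpiralParams:
    """Defaults: a 3-turn spiral over 15 s at 100 Hz with the pen easing in
    and out of the stroke (zero start/end velocity), so the tremor-free
    template is almost entirely captured by the first ~17 DCT coefficients
    of each axis — the premise of the residue method."""

    turns: float = 3.0
    duration_s: float = 15.0
    fs: float = 100.0
    pitch: float = DEFAULT_PITCH
    tremor_freq_hz: float = 8.0
    tremor_amp: float = 0.0
    tremor_mode: str = "PERPENDICULAR"  # or "RADIAL"
    drift_amp: float = 0.1 * DEFAULT_PITCH
    drift_cutoff_hz: float = 0.5
    jitter_sd: float = 0.05 * DEFAULT_PITCH
    angular_profile: str = "EASE_IN_OUT"  # or "CONSTANT"
    ease_fraction: float = 0.15  # fraction of the record spent ramping speed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be positive")
        if not 0 <= self.tremor_freq_hz < self.fs / 2:
            raise ParameterError("tremor_freq_hz must lie in [0, fs/2)")
        if min(self.tremor_amp, self.drift_amp, self.jitter_sd) < 0:
            raise ParameterError("amplitudes must be non-negative")
        if self.tremor_mode not in ("RADIAL", "PERPENDICULAR"):
            raise ParameterError(f"unknown tremor_mode {self.tremor_mode!r}")
        if self.angular_profile not in ("CONSTANT", "EASE_IN_OUT"):
            raise ParameterError(f"unknown angular_profile {self.angular_profile!r}")
        if not 0 < self.ease_fraction <= 0.5:
            raise ParameterError("ease_fraction must be in (0, 0.5]")


@dataclass
class CohortSpec:
    n_et: int = 24
    n_control: int = 27
    et_amp_range: tuple = ET_AMP_RANGE
    control_amp_range: tuple = CONTROL_AMP_RANGE
    freq_range: tuple = (4.0, 12.0)
    seed: int = 0
    spiral: SpiralParams = field(default_factory=SpiralParams)

    def __post_init__(self) -> None:
        if self.n_et < 1 or self.n_control < 1:
            raise ParameterError("each class needs at least one sample")
        if min(*self.et_amp_range, *self.control_amp_range) < 0:
            raise ParameterError("amplitude ranges must be non-negative")


def _lowpass_noise(rng, n: int, fs: float, cutoff_hz: float, amp: float) -> np.ndarray:
    """White noise low-passed below ``cutoff_hz``, rescaled to RMS ``amp``."""
    if amp == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz / (fs / 2), btype="low")
    x = signal.filtfilt(b, a, w)
    rms = np.sqrt(np.mean(x**2))
    return x * (amp / rms) if rms > 0 else np.zeros(n)


def generate_spiral(p: SpiralParams) -> DrawingSample:
    """One deterministic simulated drawing (label UNKNOWN)."""
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs
    u = t / t[-1]
    if p.angular_profile == "EASE_IN_OUT":
        # trapezoidal speed: cosine ramps at both ends, constant in between;
        # zero boundary velocity keeps the DCT spectrum compact
        a = p.ease_fraction
        w = np.ones(n)
        lo = u < a
        w[lo] = 0.5 * (1 - np.cos(np.pi * u[lo] / a))
        hi = u > 1 - a
        w[hi] = 0.5 * (1 - np.cos(np.pi * (1 - u[hi]) / a))
        u = np.cumsum(w)
        u /= u[-1]
    theta = 2 * np.pi * p.turns * u
    x = p.pitch * theta * np.cos(theta)
    y = p.pitch * theta * np.sin(theta)

    if p.tremor_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        osc = p.tremor_amp * np.sin(2 * np.pi * p.tremor_freq_hz * t + phase)
        if p.tremor_mode == "RADIAL":
            ux, uy = np.cos(theta), np.sin(theta)
        else:
            dx, dy = np.gradient(x), np.gradient(y)
            norm = np.hypot(dx, dy)
            norm[norm == 0] = 1.0
            ux, uy = -dy / norm, dx / norm  # unit normal to the pen path
        x = x + osc * ux
        y = y + osc * uy

    x = x + _lowpass_noise(rng, n, p.fs, p.drift_cutoff_hz, p.drift_amp)
    y = y + _lowpass_noise(rng, n, p.fs, p.drift_cutoff_hz, p.drift_amp)
    x = x + rng.normal(0, p.jitter_sd, n) if p.jitter_sd > 0 else x
    y = y + rng.normal(0, p.jitter_sd, n) if p.jitter_sd > 0 else y

    return DrawingSample(
        subject_id=f"sim{p.seed}",
        x_raw=x,
        y_raw=y,
        label=Label.UNKNOWN,
        t_raw=t,
        fs_nominal=p.fs,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[DrawingSample], pd.DataFrame]:
    """Labelled cohort plus a ground-truth manifest (one row per drawing).

    Tremor frequency ~ U(freq_range) and amplitude ~ U(class amp range);
    per-sample sub-seeds are derived from ``spec.seed`` so the cohort is
    reproducible as a whole.
    """
    rng = np.random.default_rng(spec.seed)
    plan = [(Label.ET, spec.et_amp_range)] * spec.n_et + [
        (Label.CONTROL, spec.control_amp_range)
    ] * spec.n_control
    samples, rows = [], []
    for i, (label, amp_range) in enumerate(plan):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        freq = float(rng.uniform(*spec.freq_range))
        amp = float(rng.uniform(*amp_range))
        p = SpiralParams(
            **{
                **asdict(spec.spiral),
                "tremor_freq_hz": freq,
                "tremor_amp": amp,
                "seed": sub_seed,
            }
        )
        s = generate_spiral(p)
        s.subject_id = f"{label.value.lower()}_{i:03d}"
        s.label = label
        samples.append(s)
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": label.value,
                "tremor_freq_hz": freq,
                "tremor_amp": amp,
                "tremor_mode": p.tremor_mode,
                "drift_amp": p.drift_amp,
                "jitter_sd": p.jitter_sd,
                "fs": p.fs,
                "duration_s": p.duration_s,
                "turns": p.turns,
                "pitch": p.pitch,
                "seed": sub_seed,
            }
        )
    return samples, pd.DataFrame(rows)


def write_cohort(
    samples: list[DrawingSample], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write one CSV per drawing plus ``manifest.csv``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        np.savetxt(
            out / f"{s.subject_id}.csv",
            np.column_stack([s.x_raw, s.y_raw]),
            fmt="%.10g",
            delimiter=",",
            header="x,y",
            comments="",
        )
    manifest.to_csv(out / "manifest.csv", index=False)
    return out
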