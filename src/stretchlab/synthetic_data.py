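"""Deterministic generators for every input the analysis chain needs.

The study's actual stimulus recording and sequencing data are not
distributed, so the pipeline is exercised on synthetic stand-ins: music-like
audio with the stimulus's documented spectral character (content within
0-20 kHz, most power below 1 kHz), noisy calibration tables on the standard
voltage grid, drifting cyclic strain traces, and qPCR Ct tables encoding
chosen effect directions.  Every generator is a pure function of its
parameters and a seed; per-generator substreams are derived by stable
hashing of the generator name, so adding a generator never perturbs the
fixtures of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actuation import DriftModel
from .measurement import CalibrationLine, StrainTrace
from .transduction import AudioSignal

__all__ = [
    "MusicProfile",
    "EffectSpec",
    "STANDARD_VOLTAGE_GRID_KV",
    "gen_music_like_audio",
    "gen_calibration_table",
    "gen_drifting_trace",
    "gen_ct_table",
]

#: The characterization voltage grid, kV.
STANDARD_VOLTAGE_GRID_KV = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent substream: seed combined with a stable hash of the name."""
    digest = hashlib.sha256(stream.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class MusicProfile:
    """Parameters of the music-like generator.

    Notes have fundamentals drawn log-uniformly from ``f0_range`` (Hz),
    ``n_partials`` harmonics with 1/k^rolloff amplitudes, and exponential
    note durations around ``note_duration_s``.  Fundamentals below 1 kHz
    with a rolloff >= 1 keep well over half the power below 1 kHz, matching
    the stimulus's documented spectral balance.
    """

    f0_range: tuple[float, float] = (110.0, 880.0)
    n_partials: int = 8
    rolloff: float = 1.5
    note_duration_s: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not 0 < lo < hi <= 20000:
            raise ValueError(f"f0_range must lie within (0, 20000], got {self.f0_range}")
        if self.n_partials < 1:
            raise ValueError("n_partials must be >= 1")
        if self.rolloff < 0:
            raise ValueError("rolloff must be non-negative")
        if self.note_duration_s <= 0:
            raise ValueError("note_duration_s must be positive")


def gen_music_like_audio(
    profile: MusicProfile = MusicProfile(),
    duration: float = 10.0,
    sample_rate: float = 44100.0,
    seed: int = 0,
) -> AudioSignal:
    """Music-like harmonic note sequence, peak-normalized, deterministic per seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    rng = _rng(seed, "music")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    lo, hi = profile.f0_range
    t0 = 0.0
    while t0 < duration:
        dur = max(0.05, rng.exponential(profile.note_duration_s))
        f0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        i0 = int(t0 * sample_rate)
        i1 = min(n, int((t0 + dur) * sample_rate))
        if i1 <= i0:
            break
        tt = t[i0:i1] - t0
        # raised-cosine envelope avoids clicks at note boundaries
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.minimum(tt / dur, 1.0)))
        note = np.zeros_like(tt)
        for k in range(1, profile.n_partials + 1):
            fk = k * f0
            if fk > min(20000.0, sample_rate / 2):
                break
            phase = rng.uniform(0, 2 * np.pi)
            note += np.sin(2 * np.pi * fk * tt + phase) / k**profile.rolloff
        out[i0:i1] += env * note
        t0 += dur
    peak = np.max(np.abs(out))
    if peak > 0:
        out /= peak
    return AudioSignal(samples=out, sample_rate=sample_rate)


def gen_calibration_table(
    line: CalibrationLine = CalibrationLine(),
    voltages_kv=STANDARD_VOLTAGE_GRID_KV,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Strain measurements on a voltage grid: line(V) plus Gaussian noise (%).

    Returns columns ``voltage_kV, strain_percent``; the noiseless strain is
    the raw line value (no clamping), since this emulates the fitting data
    the line was estimated from.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    v = np.asarray(list(voltages_kv), dtype=float)
    rng = _rng(seed, "calibration")
    strain = line.slope * v + line.intercept
    if noise_sd > 0:
        strain = strain + rng.normal(0.0, noise_sd, size=v.shape)
    return pd.DataFrame({"voltage_kV": v, "strain_percent": strain})


def gen_drifting_trace(
    drift: DriftModel,
    base_cycle: tuple[float, float] = (5.0, 13.0),
    freq: float = 1.0,
    duration: float = 10.0,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Square-wave strain trace (%) between creeping envelopes.

    The high and low levels approach the configured asymptotes
    ``base_cycle = (low, high)`` through the drift model's Prony kernel,
    1 - sum g_k exp(-t / tau_k); with zero drift the trace is an exact
    square wave.  Optional Gaussian noise, deterministic per seed.
    Returns a percent-unit :class:`~stretchlab.measurement.StrainTrace`.
    """
    low, high = base_cycle
    if not low < high:
        raise ValueError("base_cycle must satisfy low < high")
    if freq <= 0:
        raise ValueError("freq must be positive")
    if sample_rate <= 2 * freq:
        raise ValueError("sample_rate cannot resolve the cycle frequency")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    g = np.asarray(drift.g, dtype=float)
    tau = np.asarray(drift.tau, dtype=float)
    if g.size:
        envelope = 1.0 - np.exp(-t[:, None] / tau[None, :]) @ g
    else:
        envelope = np.ones_like(t)
    phase = (t * freq) % 1.0
    level = np.where(phase < 0.5, high, low)
    strain = level * envelope
    if noise_sd > 0:
        strain = strain + _rng(seed, "trace").normal(0.0, noise_sd, size=n)
    return StrainTrace(time=t, strain=strain, sample_rate=sample_rate, unit="percent")


@dataclass(frozen=True)
class EffectSpec:
    """Expected log2 fold changes per gene and group, plus Ct replicate noise.

    ``log2fc[group][gene]`` is the expected log2 fold change against the
    control group; ``noise_sd`` is the per-replicate Ct standard deviation
    in cycles.  The default encodes the study's qualitative directions:
    stemness markers (Sox2, Nanog) down in both stretched groups;
    osteogenic Runx2 up under nonuniform microstretching (NUMS) only;
    chondrogenic Sox9 and adipogenic PPARg up under uniform stretch (US)
    and down under NUMS.
    """

    log2fc: dict = field(
        default_factory=lambda: {
            "NUMS": {"Sox2": -1.0, "Nanog": -1.0, "Sox9": -0.7, "PPARg": -0.7, "Runx2": 1.0},
            "US": {"Sox2": -1.0, "Nanog": -1.0, "Sox9": 0.7, "PPARg": 0.7, "Runx2": 0.0},
        }
    )
    noise_sd: float = 0.0
    reference_ct: float = 18.0
    baseline_dct: float = 6.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bad = set(self.log2fc) - {"NUMS", "US", "control"}
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")


def gen_ct_table(spec: EffectSpec = EffectSpec(), n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Synthetic qPCR Ct table with the specified expected fold changes.

    Columns ``group, gene, ct_target, ct_reference, replicate``; includes a
    control group.  With zero noise, 2^-ddCt against the control recovers
    each specified fold change exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(seed, "ct")
    genes = sorted({g for d in spec.log2fc.values() for g in d})
    groups = ["control"] + [g for g in spec.log2fc if g != "control"]
    rows = []
    for group in groups:
        for gene in genes:
            log2fc = spec.log2fc.get(group, {}).get(gene, 0.0)
            for rep in range(n_replicates):
                ref = spec.reference_ct + (
                    rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                )
                tgt = ref + spec.baseline_dct - log2fc + (
                    rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                )
                rows.append(
                    {
                        "group": group,
                        "gene": gene,
                        "ct_target": tgt,
                        "ct_reference": ref,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)
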