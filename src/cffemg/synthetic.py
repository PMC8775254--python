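"""Synthetic multichannel sEMG-like recordings with controllable class structure.

Surface EMG during a steady contraction is well approximated by amplitude-
modulated zero-mean noise, so a gesture class is modeled as a per-channel
amplitude envelope multiplying unit-variance Gaussian noise, on top of a
background noise floor set by the requested SNR.  Recordings follow the
repetition protocol of the NinaPro benchmarks: each gesture is repeated
``reps`` times, movements separated by rest, labels 0 (rest) or the gesture
id per sample, with a per-movement repetition counter.

``make_confusable_pair`` builds the dataset at the heart of the fusion
argument: two classes whose windows contain the *same amplitude values* in a
different *temporal order* (a rising vs falling ramp).  Any purely amplitude-
based statistic (window max, MAV) is distributionally identical between the
two, while a model that reads temporal order can separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import scipy.io

from .windowing import RawRecording

ENVELOPE_SHAPES = ("flat", "ramp_up", "ramp_down", "burst")

# ramps run between RAMP_LO*peak and peak so the quiet end stays above rest
RAMP_LO = 0.2


@dataclass
class EnvelopeSpec:
    shape: str = "flat"
    peak: float = 1.0

    def __post_init__(self):
        if self.shape not in ENVELOPE_SHAPES:
            raise ValueError(f"unknown envelope shape {self.shape!r}")
        if self.peak <= 0:
            raise ValueError("envelope peak must be positive")

    def sample(self, n: int) -> np.ndarray:
        """Envelope values over a movement block of ``n`` samples."""
        t = np.arange(n) / max(n - 1, 1)
        if self.shape == "flat":
            return np.full(n, self.peak)
        if self.shape == "ramp_up":
            return self.peak * (RAMP_LO + (1 - RAMP_LO) * t)
        if self.shape == "ramp_down":
            return self.peak * (RAMP_LO + (1 - RAMP_LO) * t)[::-1]
        # burst: Gaussian bump centered mid-block
        return self.peak * (RAMP_LO + (1 - RAMP_LO) * np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2))


def default_envelopes(G: int, C: int) -> list[list[EnvelopeSpec]]:
    """Flat envelopes with a distinct pair of strong channels per class.

    Classes cycle through the ``C choose 2`` channel pairs, so any two classes
    differ in at least one strong channel as long as ``G <= C*(C-1)/2``.
    """
    pairs = list(combinations(range(C), 2)) or [(0, 0)]
    out = []
    for g in range(G):
        strong = set(pairs[g % len(pairs)])
        out.append([
            EnvelopeSpec("flat", 2.0 if c in strong else 0.5) for c in range(C)
        ])
    return out


@dataclass
class SyntheticSpec:
    """Generator configuration.

    The defaults (6 classes, 4 channels, 200 Hz, 6 repetitions of 1 s
    movements with 0.5 s rests, 20 dB SNR) give a recording a full
    segment/train/compare cycle can process in minutes on one CPU.
    """

    G: int = 6
    C: int = 4
    fs: float = 200.0
    reps: int = 6
    movement_ms: float = 1000.0
    rest_ms: float = 500.0
    envelopes: list | None = None  # [class][channel] -> EnvelopeSpec
    snr_db: float = 20.0
    seed: int = 0
    subject: int = 1

    def __post_init__(self):
        if self.G < 2 or self.C < 1 or self.fs <= 0:
            raise ValueError("need G >= 2, C >= 1, fs > 0")
        if self.movement_ms <= 0 or self.rest_ms < 0:
            raise ValueError("durations must be positive")
        if self.envelopes is None:
            self.envelopes = default_envelopes(self.G, self.C)
        if len(self.envelopes) != self.G or any(len(e) != self.C for e in self.envelopes):
            raise ValueError("envelopes must be a G x C table")


def generate(spec: SyntheticSpec) -> RawRecording:
    """Generate one recording.  Pure: identical spec (incl. seed) gives a
    bit-identical recording.

    Blocks are class-major — for each gesture, ``reps`` repetitions of
    (movement, rest) — preceded by one leading rest block.  Movement samples
    are ``envelope * n1 + sigma_bg * n2`` with iid standard normal ``n1, n2``;
    rest samples are pure background noise.  ``sigma_bg`` is set from
    ``snr_db`` relative to the RMS of all movement envelopes.
    """
    rng = np.random.default_rng(spec.seed)
    n_mov = int(round(spec.movement_ms * spec.fs / 1000.0))
    n_rest = int(round(spec.rest_ms * spec.fs / 1000.0))
    env_table = [
        np.stack([spec.envelopes[g][c].sample(n_mov) for c in range(spec.C)], axis=1)
        for g in range(spec.G)
    ]  # each (n_mov, C)
    env_rms = np.sqrt(np.mean([np.mean(e**2) for e in env_table]))
    sigma_bg = env_rms * 10 ** (-spec.snr_db / 20.0)

    sig_parts, lab_parts, rep_parts = [], [], []

    def rest_block():
        if n_rest == 0:
            return
        sig_parts.append(sigma_bg * rng.standard_normal((n_rest, spec.C)))
        lab_parts.append(np.zeros(n_rest, dtype=int))
        rep_parts.append(np.zeros(n_rest, dtype=int))

    rest_block()
    for g in range(spec.G):
        for r in range(spec.reps):
            env = env_table[g]
            block = env * rng.standard_normal((n_mov, spec.C)) \
                + sigma_bg * rng.standard_normal((n_mov, spec.C))
            sig_parts.append(block)
            lab_parts.append(np.full(n_mov, g + 1, dtype=int))
            rep_parts.append(np.full(n_mov, r + 1, dtype=int))
            rest_block()
    return RawRecording(
        signal=np.concatenate(sig_parts),
        fs=spec.fs,
        labels=np.concatenate(lab_parts),
        repetition=np.concatenate(rep_parts),
        subject=spec.subject,
    )


def make_confusable_pair(base: SyntheticSpec, peak: float = 1.5) -> SyntheticSpec:
    """Two classes with identical amplitude content in opposite temporal order.

    Class 1 ramps up, class 2 ramps down, with the same peak on every channel;
    the sorted envelope values of any window of one class appear (mirrored) in
    the other, so amplitude-only statistics carry no class information while
    the within-window slope does.
    """
    env = [
        [EnvelopeSpec("ramp_up", peak) for _ in range(base.C)],
        [EnvelopeSpec("ramp_down", peak) for _ in range(base.C)],
    ]
    return replace(base, G=2, envelopes=env)


def perturb_subject(spec: SyntheticSpec, subject: int, jitter: float = 0.2,
                    seed: int | None = None) -> SyntheticSpec:
    """A per-subject variant: envelope peaks scaled by ``1 ± jitter`` (seeded),
    emulating inter-subject amplitude variability on pooled data."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    env = [
        [EnvelopeSpec(e.shape, e.peak * float(1 + rng.uniform(-jitter, jitter)))
         for e in row]
        for row in spec.envelopes
    ]
    return replace(spec, envelopes=env, subject=subject,
                   seed=(spec.seed * 1000003 + subject) % (2**31))


def export_mat(path, rec: RawRecording):
    """Write a recording in the NinaPro-style field layout (emg / stimulus /
    repetition / subject) so it can round-trip through the ``.mat`` reader."""
    scipy.io.savemat(str(path), {
        "emg": rec.signal,
        "stimulus": rec.labels[:, None].astype(float),
        "repetition": rec.repetition[:, None].astype(float),
        "subject": np.array([[float(rec.subject) if not isinstance(rec.subject, str) else 0.0]]),
    })
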