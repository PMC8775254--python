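"""Sliding-window segmentation of labeled multichannel sEMG recordings.

A recording is a ``T x C`` sample-by-channel matrix with per-sample gesture
labels (0 = rest) and repetition ids.  Segmentation cuts it into fixed-length
overlapping windows, each window is reshaped into a 3-D frame ``(W, H, C_out)``
for the convolutional front end, frames are z-scored with statistics estimated
on the training split only, and labels are one-hot encoded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.io


class WindowingError(ValueError):
    """Raised for invalid segmentation configs or inputs."""


@dataclass
class RawRecording:
    """A sample-by-channel signal with per-sample metadata.

    Parameters
    ----------
    signal : ndarray, shape (T, C)
        Amplitude in arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of int, shape (T,)
        0 for rest, ``1..G`` for gesture ids.
    repetition : ndarray of int, shape (T,)
        Repetition counter (0 during rest).
    subject : int or str
        Subject identifier.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    repetition: np.ndarray
    subject: object = 0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.repetition = np.asarray(self.repetition, dtype=int)
        if self.signal.ndim != 2:
            raise WindowingError("signal must be a T x C matrix")
        T = self.signal.shape[0]
        if self.labels.shape != (T,) or self.repetition.shape != (T,):
            raise WindowingError(
                "labels and repetition must have exactly one entry per sample"
            )
        if not np.all(np.isfinite(self.signal)):
            raise WindowingError("signal contains non-finite values")
        if self.fs <= 0:
            raise WindowingError("sampling rate must be positive")
        if self.labels.min(initial=0) < 0:
            raise WindowingError("labels must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class WindowConfig:
    """Sliding-window geometry.

    ``window_ms``/``overlap_ms`` are durations; the window length in samples is
    ``N = round(window_ms * fs / 1000)`` and the hop is
    ``N - round(overlap_ms * fs / 1000)`` (integer sample arithmetic, no
    drift).  ``W`` and ``H`` give the frame reshape; ``c_out`` defaults to the
    channel count (set it to fold channels into the spatial axes, e.g. the
    ``(5, 25, 2)`` layout for 10-channel 100 Hz data).
    """

    window_ms: float = 250.0
    overlap_ms: float = 200.0
    W: int = 5
    H: int = 100
    c_out: int | None = None

    def __post_init__(self):
        if not (0 <= self.overlap_ms < self.window_ms):
            raise WindowingError("need 0 <= overlap_ms < window_ms")

    def n_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def hop(self, fs: float) -> int:
        h = self.n_samples(fs) - int(round(self.overlap_ms * fs / 1000.0))
        if h < 1:
            raise WindowingError("hop must be at least one sample")
        return h


@dataclass
class Frame:
    """One reshaped window with its label and provenance."""

    data: np.ndarray  # (W, H, C_out)
    label: int
    start_sample: int
    repetition: int
    subject: object = 0


def sliding_windows(
    rec: RawRecording,
    cfg: WindowConfig,
    *,
    min_purity: float = 0.5,
    drop_impure: bool = False,
):
    """Cut ``rec`` into overlapping ``N x C`` windows.

    Windows start at ``0, hop, 2*hop, ...``; the count over a span of ``T``
    samples is ``floor((T - N)/hop) + 1``.  Each window is labeled by the
    majority per-sample label (ties broken toward the smaller id).  If
    ``drop_impure`` is set, windows whose majority fraction is below
    ``min_purity`` are discarded.

    Yields ``(window, label, start, repetition)`` tuples.
    """
    N = cfg.n_samples(rec.fs)
    hop = cfg.hop(rec.fs)
    T = rec.n_samples
    if T < N:
        raise WindowingError(
            f"recording too short: {T} samples < one {N}-sample window"
        )
    for start in range(0, T - N + 1, hop):
        sl = slice(start, start + N)
        win_labels = rec.labels[sl]
        counts = np.bincount(win_labels)
        label = int(np.argmax(counts))
        if drop_impure and counts[label] < min_purity * N:
            continue
        reps = rec.repetition[sl]
        rep_counts = np.bincount(reps)
        yield rec.signal[sl].copy(), label, start, int(np.argmax(rep_counts))


def reshape_frame(window: np.ndarray, W: int, H: int, c_out: int | None = None) -> np.ndarray:
    """Reshape an ``N x C`` window into a ``(W, H, C_out)`` frame.

    Two layouts are supported, both fixed bijections:

    * channel-preserving (``c_out == C``, requires ``W*H == N``): the time
      axis is folded row-major into ``(W, H)``, channels untouched —
      ``frame[w, h, c] = window[w*H + h, c]``;
    * channel-folding (``c_out != C``, requires ``W*H*c_out == N*C``): the
      window is flattened time-major (channel fastest) and refolded row-major
      into ``(W, H, c_out)``.
    """
    window = np.asarray(window)
    N, C = window.shape
    if c_out is None:
        c_out = C
    if W * H * c_out != N * C:
        raise WindowingError(
            f"cannot reshape: W*H*C_out = {W * H * c_out} but N*C = {N * C}"
        )
    if c_out == C and W * H == N:
        return window.reshape(W, H, C)
    return window.reshape(-1).reshape(W, H, c_out)


def inverse_reshape(frame: np.ndarray, N: int, C: int) -> np.ndarray:
    """Invert :func:`reshape_frame`, recovering the original ``N x C`` window."""
    frame = np.asarray(frame)
    W, H, c_out = frame.shape
    if W * H * c_out != N * C:
        raise WindowingError(
            f"cannot invert: frame has {W * H * c_out} elements, window needs {N * C}"
        )
    if c_out == C and W * H == N:
        return frame.reshape(N, C)
    return frame.reshape(-1).reshape(N, C)


@dataclass
class ChannelStats:
    """Per-channel normalization statistics, estimated on training data only."""

    mean: np.ndarray
    std: np.ndarray
    minmax: bool = False
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def apply(self, frames: np.ndarray) -> np.ndarray:
        out = (frames - self.mean) / self.std
        if self.minmax:
            span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
            out = (out - self.lo) / span
        return out

    def invert(self, frames: np.ndarray) -> np.ndarray:
        out = frames
        if self.minmax:
            span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
            out = out * span + self.lo
        return out * self.std + self.mean

    def to_dict(self) -> dict:
        d = {"mean": self.mean.tolist(), "std": self.std.tolist(), "minmax": self.minmax}
        if self.minmax:
            d["lo"] = self.lo.tolist()
            d["hi"] = self.hi.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(
            mean=np.asarray(d["mean"]),
            std=np.asarray(d["std"]),
            minmax=d.get("minmax", False),
            lo=np.asarray(d["lo"]) if d.get("lo") is not None else None,
            hi=np.asarray(d["hi"]) if d.get("hi") is not None else None,
        )


def standardize(
    train_frames: np.ndarray,
    *other_sets: np.ndarray,
    minmax: bool = False,
):
    """Per-channel z-scoring fitted on the training set and applied unchanged.

    ``train_frames`` has shape ``(n, W, H, C)`` (or ``(n, N, C)``); statistics
    are taken over all but the last (channel) axis.  Channels with zero spread
    get unit scale and a warning.  With ``minmax=True`` a second min-max
    rescaling to the training [0, 1] range is composed after the z-score.

    Returns ``(train_norm, *others_norm, stats)``.
    """
    train_frames = np.asarray(train_frames, dtype=float)
    if train_frames.size == 0:
        raise WindowingError("training set is empty")
    axes = tuple(range(train_frames.ndim - 1))
    mean = train_frames.mean(axis=axes)
    std = train_frames.std(axis=axes)
    bad = std == 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-variance channel(s); using unit scale",
            RuntimeWarning,
            stacklevel=2,
        )
        std = np.where(bad, 1.0, std)
    stats = ChannelStats(mean=mean, std=std)
    if minmax:
        z = (train_frames - mean) / std
        stats.minmax = True
        stats.lo = z.min(axis=axes)
        stats.hi = z.max(axis=axes)
    out = [stats.apply(train_frames)]
    out.extend(stats.apply(np.asarray(s, dtype=float)) for s in other_sets)
    out.append(stats)
    return tuple(out)


def one_hot(labels: Sequence[int], G: int) -> np.ndarray:
    """Encode integer labels in ``[0, G)`` as an ``n x G`` indicator matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= G):
        raise IndexError(f"labels must lie in [0, {G})")
    out = np.zeros((labels.size, G))
    out[np.arange(labels.size), labels] = 1.0
    return out


def frame_dataset(
    rec: RawRecording,
    cfg: WindowConfig,
    *,
    drop_rest: bool = False,
    min_purity: float = 0.5,
    drop_impure: bool = False,
):
    """Segment + reshape a recording into a frame stack.

    Returns ``(frames (n, W, H, C_out), labels (n,), starts (n,), reps (n,))``.
    With ``drop_rest`` windows whose majority label is 0 are discarded.
    """
    frames, labels, starts, reps = [], [], [], []
    for win, lab, start, rep in sliding_windows(
        rec, cfg, min_purity=min_purity, drop_impure=drop_impure
    ):
        if drop_rest and lab == 0:
            continue
        frames.append(reshape_frame(win, cfg.W, cfg.H, cfg.c_out))
        labels.append(lab)
        starts.append(start)
        reps.append(rep)
    if not frames:
        raise WindowingError("no windows survived segmentation")
    return (
        np.stack(frames),
        np.asarray(labels),
        np.asarray(starts),
        np.asarray(reps),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NINAPRO_LABEL_FIELDS = ("restimulus", "stimulus")
_NINAPRO_REP_FIELDS = ("rerepetition", "repetition")


def load_ninapro_mat(path, fs: float, subject=None) -> RawRecording:
    """Read a NinaPro-style ``.mat`` file into a :class:`RawRecording`.

    Expects an ``emg`` (T x C) array, a label vector (``restimulus``
    preferred, else ``stimulus``) and a repetition vector (``rerepetition``
    preferred, else ``repetition``).  The refined (``re``-prefixed) fields are
    the relabeled versions shipped with the databases.  Missing fields are
    reported by name.
    """
    mat = scipy.io.loadmat(str(path))
    missing = []
    if "emg" not in mat:
        missing.append("emg")
    lab_key = next((k for k in _NINAPRO_LABEL_FIELDS if k in mat), None)
    if lab_key is None:
        missing.append("stimulus/restimulus")
    rep_key = next((k for k in _NINAPRO_REP_FIELDS if k in mat), None)
    if rep_key is None:
        missing.append("repetition/rerepetition")
    if missing:
        raise KeyError(f"NinaPro file {path} is missing fields: {', '.join(missing)}")
    if subject is None:
        subject = int(np.ravel(mat["subject"])[0]) if "subject" in mat else 0
    return RawRecording(
        signal=np.asarray(mat["emg"], dtype=float),
        fs=fs,
        labels=np.ravel(mat[lab_key]).astype(int),
        repetition=np.ravel(mat[rep_key]).astype(int),
        subject=subject,
    )


def save_frames(path, frames, labels, cfg: WindowConfig, stats: ChannelStats | None = None, **meta):
    """Serialize a frame set to ``<path>.npz`` with a JSON sidecar.

    The sidecar records the window config and normalization statistics so a
    saved set can be re-normalized or inverted later.
    """
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             frames=frames, labels=labels)
    sidecar = {
        "window_config": {
            "window_ms": cfg.window_ms,
            "overlap_ms": cfg.overlap_ms,
            "W": cfg.W,
            "H": cfg.H,
            "c_out": cfg.c_out,
        },
        "stats": stats.to_dict() if stats is not None else None,
        **meta,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_frames(path):
    """Load a frame set saved by :func:`save_frames`.

    Returns ``(frames, labels, WindowConfig, ChannelStats | None)``.
    """
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    arrs = np.load(base + ".npz")
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    wc = sidecar["window_config"]
    cfg = WindowConfig(
        window_ms=wc["window_ms"], overlap_ms=wc["overlap_ms"],
        W=wc["W"], H=wc["H"], c_out=wc["c_out"],
    )
    stats = ChannelStats.from_dict(sidecar["stats"]) if sidecar.get("stats") else None
    return arrs["frames"], arrs["labels"], cfg, stats
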