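"""Preprocessing pipeline: notch filtering, rest removal, windowing,
sEMG-image construction, augmentation and dataset splitting.

The raw labelled session is notch-filtered to suppress powerline
interference, rest samples are discarded, and each contraction is cut into
fixed-length windows — either disjoint tiles or overlapping slides.  A
window of ``n_channels x w_samples`` values is the "sEMG image" fed to the
CNN.  Windows never cross a contraction boundary, so no image mixes
gestures or contains rest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import AllRestError, ConfigError, DataError
from .synth import REST, RecordingSession

# ---------------------------------------------------------------------------
# specs

#: Segment-size grid (ms) and overlap-size grid studied in the sweep.
SEGMENT_SIZE_GRID_MS: tuple[int, ...] = (100, 150, 200, 250, 300, 350)
OVERLAP_GRID: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class SegmentationSpec:
    """Windowing scheme: disjoint tiling or overlapped sliding."""

    mode: str = "overlap"  # {"disjoint", "overlap"}
    window_ms: float = 200.0
    overlap_frac: float = 0.8  # ignored for disjoint

    def __post_init__(self) -> None:
        if self.mode not in ("disjoint", "overlap"):
            raise ConfigError(f"unknown segmentation mode {self.mode!r}")
        if self.window_ms <= 0:
            raise ConfigError("window_ms must be > 0")
        if self.mode == "overlap" and not 0.0 <= self.overlap_frac < 1.0:
            raise ConfigError("overlap_frac must be in [0, 1)")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        w = self.window_samples(fs)
        if self.mode == "disjoint":
            return w
        return max(1, int(round(w * (1.0 - self.overlap_frac))))


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (defaults 70/20/10, stratified)."""

    train_frac: float = 0.70
    val_frac: float = 0.20
    test_frac: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if any(not 0.0 < f < 1.0 for f in fracs):
            raise ConfigError("split fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass(frozen=True)
class AugmentationSpec:
    """Random flips and integer translations applied to training images.

    ``shift_axes='time'`` restricts translations to the horizontal (time)
    axis; channel-axis shifts displace the per-channel amplitude pattern,
    which on synthetic channel-coded data removes the class information.
    """

    flip_prob: float = 0.5
    max_shift_px: int = 4
    flip_axis: str = "time"  # {"time", "channel"}
    shift_axes: str = "both"  # {"both", "time"}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ConfigError("flip_prob must be in [0, 1]")
        if self.max_shift_px < 0:
            raise ConfigError("max_shift_px must be >= 0")
        if self.flip_axis not in ("time", "channel"):
            raise ConfigError(f"unknown flip_axis {self.flip_axis!r}")
        if self.shift_axes not in ("both", "time"):
            raise ConfigError(f"unknown shift_axes {self.shift_axes!r}")


# ---------------------------------------------------------------------------
# containers


@dataclass
class WindowSet:
    """Stack of equally sized windows with per-window class labels."""

    windows: np.ndarray  # N x n_channels x w_samples
    labels: np.ndarray  # N
    sources: list = field(default_factory=list)  # (contraction idx, start sample)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.windows):
            raise DataError("window/label count mismatch")

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class SEMGImageSet:
    """Stack of channels x samples images, the CNN input."""

    images: np.ndarray  # N x n_channels x w_samples
    labels: np.ndarray  # N

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if not np.issubdtype(self.images.dtype, np.floating):
            self.images = self.images.astype(float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.images):
            raise DataError("image/label count mismatch")
        if len(self.images) and not np.all(np.isfinite(self.images)):
            raise DataError("images contain non-finite values")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: np.ndarray) -> "SEMGImageSet":
        return SEMGImageSet(self.images[idx], self.labels[idx])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.images).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# operations


def notch_filter(
    session: RecordingSession, f0: float = 50.0, bandwidth: float = 4.0
) -> RecordingSession:
    """Second-order Butterworth band-stop centred at ``f0``.

    Causal single-pass filtering (no zero-phase compensation), matching a
    real-time myoelectric-control constraint.  The -3 dB stop band is
    ``f0 +/- bandwidth/2``; labels and length are unchanged.
    """
    if not 0 < f0 < session.fs / 2.0:
        raise ConfigError(f"notch frequency {f0} Hz must lie in (0, fs/2)")
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be > 0")
    edges = [f0 - bandwidth / 2.0, f0 + bandwidth / 2.0]
    if edges[0] <= 0 or edges[1] >= session.fs / 2.0:
        raise ConfigError("stop band must lie strictly inside (0, fs/2)")
    sos = sps.butter(2, edges, btype="bandstop", fs=session.fs, output="sos")
    out = session.copy()
    out.signal = sps.sosfilt(sos, out.signal, axis=1)
    return out


def notch_sos(fs: float, f0: float = 50.0, bandwidth: float = 4.0) -> np.ndarray:
    """The second-order sections of the notch filter (for response analysis)."""
    edges = [f0 - bandwidth / 2.0, f0 + bandwidth / 2.0]
    return sps.butter(2, edges, btype="bandstop", fs=fs, output="sos")


def extract_contractions(
    session: RecordingSession,
) -> list[tuple[int, np.ndarray]]:
    """Split a session into maximal contraction runs, dropping rest.

    Returns one ``(class_id, channels x length signal)`` entry per maximal
    non-rest run, in temporal order.  Raises :class:`AllRestError` when the
    session holds no contraction samples.
    """
    labels = session.labels
    if not np.any(labels != REST):
        raise AllRestError("session contains only rest samples")
    # boundaries where the label changes
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    out: list[tuple[int, np.ndarray]] = []
    for s, e in zip(starts, ends):
        k = int(labels[s])
        if k != REST:
            out.append((k, session.signal[:, s:e]))
    return out


def window_count(L: int, w: int, mode: str, overlap_frac: float = 0.0) -> int:
    """Closed-form number of windows of length ``w`` in a segment of length ``L``."""
    if w < 1:
        raise ConfigError("window length must be >= 1 sample")
    if L < w:
        return 0
    if mode == "disjoint":
        return L // w
    s = max(1, int(round(w * (1.0 - overlap_frac))))
    return (L - w) // s + 1


def segment_windows(
    segment: np.ndarray,
    class_id: int,
    spec: SegmentationSpec,
    fs: float,
    contraction_index: int = 0,
) -> WindowSet:
    """Cut one contraction into windows; never crosses the segment boundary.

    Start indices are ``0, s, 2s, ...`` while ``start + w <= L`` where the
    step ``s`` equals ``w`` for disjoint mode and
    ``max(1, round(w * (1 - overlap_frac)))`` for overlap mode.  A segment
    shorter than one window yields an empty set.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise DataError("segment must be n_channels x L")
    w = spec.window_samples(fs)
    if w < 1:
        raise ConfigError("window shorter than one sample at this fs")
    L = segment.shape[1]
    n = window_count(L, w, spec.mode, spec.overlap_frac)
    if n == 0:
        return WindowSet(
            np.empty((0, segment.shape[0], w)), np.empty(0, dtype=int), []
        )
    s = spec.step_samples(fs)
    starts = np.arange(n) * s
    windows = np.stack([segment[:, st : st + w] for st in starts])
    labels = np.full(n, class_id, dtype=int)
    sources = [(contraction_index, int(st)) for st in starts]
    return WindowSet(windows, labels, sources)


def windows_to_images(ws: WindowSet) -> SEMGImageSet:
    """Identity mapping from windows to the image container."""
    if len(ws) == 0:
        return SEMGImageSet(ws.windows.copy(), ws.labels.copy())
    shapes = {w.shape for w in ws.windows}
    if len(shapes) > 1:
        raise DataError(f"heterogeneous window shapes: {sorted(shapes)}")
    return SEMGImageSet(ws.windows.copy(), ws.labels.copy())


def session_to_images(
    session: RecordingSession,
    spec: SegmentationSpec,
    *,
    notch: bool = True,
    notch_hz: float = 50.0,
    notch_bandwidth: float = 4.0,
) -> SEMGImageSet:
    """Full per-session pipeline: notch -> rest removal -> windows -> images."""
    if notch:
        session = notch_filter(session, notch_hz, notch_bandwidth)
    parts = []
    for i, (k, seg) in enumerate(extract_contractions(session)):
        ws = segment_windows(seg, k, spec, session.fs, contraction_index=i)
        if len(ws):
            parts.append(ws)
    if not parts:
        w = spec.window_samples(session.fs)
        return SEMGImageSet(
            np.empty((0, session.n_channels, w)), np.empty(0, dtype=int)
        )
    windows = np.concatenate([p.windows for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    return SEMGImageSet(windows, labels)


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys1 > ys0 and xs1 > xs0:
        out[
            max(0, dy) : max(0, dy) + (ys1 - ys0),
            max(0, dx) : max(0, dx) + (xs1 - xs0),
        ] = img[ys0:ys1, xs0:xs1]
    return out


def augment_images(imgs: SEMGImageSet, spec: AugmentationSpec) -> SEMGImageSet:
    """Random flip plus random integer translation with zero fill.

    "Vertical-axis" flipping is interpreted as reversal of the time axis
    (mirror about the vertical axis); ``flip_axis='channel'`` selects the
    alternative reading.  Each image is treated independently; labels and
    cardinality are preserved and the result is deterministic given the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(imgs)
    out = imgs.images.copy()
    if n == 0:
        return SEMGImageSet(out, imgs.labels.copy())
    flips = rng.random(n) < spec.flip_prob
    m = spec.max_shift_px
    shifts = rng.integers(-m, m + 1, size=(n, 2)) if m > 0 else np.zeros((n, 2), int)
    if spec.shift_axes == "time":
        shifts[:, 0] = 0
    axis = 1 if spec.flip_axis == "time" else 0
    for i in range(n):
        img = out[i]
        if flips[i]:
            img = np.flip(img, axis=axis)
        dy, dx = int(shifts[i, 0]), int(shifts[i, 1])
        if dy or dx:
            img = _shift2d(img, dy, dx)
        out[i] = img
    return SEMGImageSet(out, imgs.labels.copy())


def _allocate(n: int, fracs: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder allocation of n items to three fractions."""
    raw = np.array(fracs) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def split_dataset(
    imgs: SEMGImageSet, spec: SplitSpec
) -> tuple[SEMGImageSet, SEMGImageSet, SEMGImageSet]:
    """Random (optionally class-stratified) partition into train/val/test.

    The three parts are disjoint and jointly exhaustive; sizes follow the
    fractions by largest-remainder rounding, per class when stratified.
    """
    n = len(imgs)
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_frac, spec.val_frac, spec.test_frac)
    tr_idx: list[np.ndarray] = []
    va_idx: list[np.ndarray] = []
    te_idx: list[np.ndarray] = []
    if spec.stratified:
        classes = np.unique(imgs.labels)
        if n < len(classes):
            raise DataError("fewer images than classes in stratified split")
        for k in classes:
            idx = np.flatnonzero(imgs.labels == k)
            idx = rng.permutation(idx)
            a, b, _ = _allocate(len(idx), fracs)
            tr_idx.append(idx[:a])
            va_idx.append(idx[a : a + b])
            te_idx.append(idx[a + b :])
    else:
        idx = rng.permutation(n)
        a, b, _ = _allocate(n, fracs)
        tr_idx, va_idx, te_idx = [idx[:a]], [idx[a : a + b]], [idx[a + b :]]
    tr = np.sort(np.concatenate(tr_idx)) if tr_idx else np.empty(0, int)
    va = np.sort(np.concatenate(va_idx)) if va_idx else np.empty(0, int)
    te = np.sort(np.concatenate(te_idx)) if te_idx else np.empty(0, int)
    return imgs.subset(tr), imgs.subset(va), imgs.subset(te)
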