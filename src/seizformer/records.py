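"""Core in-memory containers: continuous recordings and windowed segments.

Conventions used throughout the package:

* signal values are in microvolts, shaped ``(n_channels, n_samples)``;
* time is in seconds; seizure intervals are half-open ``[start, end)``;
* window ``k`` of a sliding segmentation covers ``[k*step, k*step + window_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ShapeError

Interval = tuple[float, float]


def canonical_label(label: str) -> str:
    """Canonicalize a bipolar-montage channel label: uppercase, no whitespace.

    Clinical EDF headers are inconsistent about spacing and case
    ("FP 1- F 7" vs "FP1-F7"); comparisons in this package always go
    through this canonical form.
    """
    return "".join(label.split()).upper()


@dataclass
class EEGRecord:
    """A continuous multi-channel EEG recording with seizure annotations.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling frequency in Hz.
    channel_labels
        One bipolar-montage label per row of ``data`` (e.g. ``"FP1-F7"``).
    seizure_intervals
        Sorted, disjoint half-open ``[start_s, end_s)`` intervals in seconds.
    subject_id
        Free-form identifier, carried through windowing and reports.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    seizure_intervals: list[Interval] = field(default_factory=list)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D (channels, samples), got {self.data.shape}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ShapeError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        canon = [canonical_label(c) for c in self.channel_labels]
        if len(set(canon)) != len(canon):
            raise ShapeError("channel labels must be unique")
        if not self.fs > 0:
            raise ShapeError(f"fs must be positive, got {self.fs}")
        ivs = sorted((float(a), float(b)) for a, b in self.seizure_intervals)
        for (a, b) in ivs:
            if not (0.0 <= a < b <= self.duration_s + 1e-9):
                raise ShapeError(f"interval [{a}, {b}) outside record of {self.duration_s} s")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ShapeError("seizure intervals must be disjoint")
        self.seizure_intervals = ivs

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecord":
        """Copy of this record with ``data`` replaced (same metadata)."""
        return replace(self, data=data)


@dataclass
class Window:
    """One fixed-length labeled segment of a recording."""

    data: np.ndarray          # (n_channels, samples_per_window)
    label: int                # 0 = non-seizure, 1 = seizure
    start_s: float
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("window data must be finite")
        if self.label not in (0, 1):
            raise ShapeError(f"label must be 0 or 1, got {self.label}")


@dataclass
class WindowSet:
    """An ordered collection of equally shaped windows from one montage.

    ``norm_stats`` holds per-channel ``(mean, std)`` once :func:`zscore_fit`
    has been applied; it is ``None`` for raw windows.
    """

    windows: list[Window]
    fs: float
    channel_labels: list[str]
    norm_stats: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {w.data.shape for w in self.windows}
        if len(shapes) > 1:
            raise ShapeError(f"windows have mixed shapes: {sorted(shapes)}")
        if self.norm_stats is not None:
            mean, std = self.norm_stats
            if np.any(np.asarray(std) <= 0):
                raise ShapeError("norm_stats std must be positive")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)

    @property
    def starts(self) -> np.ndarray:
        return np.array([w.start_s for w in self.windows], dtype=np.float64)

    def stacked(self) -> np.ndarray:
        """All window data as one ``(n_windows, n_channels, samples)`` array."""
        return np.stack([w.data for w in self.windows], axis=0)
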