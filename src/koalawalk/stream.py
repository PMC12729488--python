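"""In-memory container for labelled collar accelerometer streams."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Standard gravity used for g <-> m/s^2 conversion throughout the package.
GRAVITY = 9.81

#: Logger clip range (the collar records at +/- 4 g).
CLIP_G = 4.0


@dataclass
class LabelledStream:
    """Uniformly sampled multi-axis accelerometer stream with per-sample labels.

    Acceleration is held in m/s^2 in collar body axes (heave, surge, sway).
    Labels are stored as integer codes into ``classes``; code -1 marks an
    unlabelled sample. ``gaps`` records known recording gaps as
    ``(start_s, end_s)`` pairs relative to ``start_time`` — gaps are metadata,
    the sample grid itself is always uniform.
    """

    sample_rate: float
    acc: np.ndarray  # (n, 3) m/s^2
    label_codes: np.ndarray  # (n,) int16, -1 = unlabelled
    classes: tuple[str, ...]
    gyro: np.ndarray | None = None  # (n, 3) deg/s, optional
    start_time: np.datetime64 = field(
        default_factory=lambda: np.datetime64("2023-05-15T00:00:00")
    )
    individual_id: str = "unknown"
    sex: str = "U"
    habitat: str = "patch"
    mass_kg: float = float("nan")
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.label_codes = np.asarray(self.label_codes, dtype=np.int16)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if len(self.label_codes) != len(self.acc):
            raise ValueError("labels and acceleration must have equal length")
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
            if self.gyro.shape != self.acc.shape:
                raise ValueError("gyro must match acc shape")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.acc)

    @property
    def n_axes(self) -> int:
        return 3 if self.gyro is None else 6

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds since ``start_time``."""
        return np.arange(len(self)) / self.sample_rate

    @property
    def labels(self) -> np.ndarray:
        """Per-sample labels decoded to strings ('' where unlabelled)."""
        lut = np.array(("",) + self.classes, dtype=object)
        return lut[self.label_codes + 1]

    def axes_matrix(self) -> np.ndarray:
        """All channels as one (n, 3) or (n, 6) matrix (acc first)."""
        if self.gyro is None:
            return self.acc
        return np.hstack([self.acc, self.gyro])

    @classmethod
    def from_labels(
        cls,
        sample_rate: float,
        acc: np.ndarray,
        labels,
        **kwargs,
    ) -> "LabelledStream":
        """Build a stream from string labels, factorising them to codes."""
        labels = np.asarray(labels, dtype=object)
        classes = tuple(sorted({str(l) for l in labels if l != ""}))
        index = {c: i for i, c in enumerate(classes)}
        codes = np.array([index.get(l, -1) for l in labels], dtype=np.int16)
        return cls(sample_rate=sample_rate, acc=acc, label_codes=codes,
                   classes=classes, **kwargs)

    def copy(self) -> "LabelledStream":
        return replace(
            self,
            acc=self.acc.copy(),
            label_codes=self.label_codes.copy(),
            gyro=None if self.gyro is None else self.gyro.copy(),
            gaps=list(self.gaps),
        )


def clip_acceleration(acc: np.ndarray) -> np.ndarray:
    """Clip acceleration to the logger's +/- 4 g range (in m/s^2)."""
    lim = CLIP_G * GRAVITY
    return np.clip(acc, -lim, lim)
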