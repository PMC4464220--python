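"""Umbrella-sampling experimental design: windows, restraints, CV series I/O.

Windows are harmonic restraints U(L) = 1/2 k (L - L0)^2 on the loop--loop
distance; a :class:`WindowSet` additionally records the initialization
direction (forward = increasing centers, backward = decreasing) and the
stiffness used during sequential initialization, which matter only as
metadata for hysteresis bookkeeping.

CV series are stored as plain text, one file per window::

    # center_angstrom: 13.0
    # stiffness_kcal_mol_A2: 20.0
    0.0 12.984
    1.0 13.107
    ...
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "UmbrellaWindow",
    "WindowSet",
    "CvSeries",
    "make_windows",
    "make_windows_spacing",
    "bias_energy",
    "discard_equilibration",
    "read_cv",
    "write_cv",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic restraint: center L_i (Å), stiffness k ((kcal/mol)/Å^2)."""

    index: int
    center: float
    stiffness: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError(f"window {self.index}: stiffness must be positive")
        if self.center <= 0:
            raise ValueError(f"window {self.index}: center must be positive")


@dataclass(frozen=True)
class WindowSet:
    windows: tuple[UmbrellaWindow, ...]
    direction: Literal["forward", "backward"] = "forward"
    init_stiffness: float | None = None

    def __post_init__(self) -> None:
        centers = [w.center for w in self.iter_in_order()]
        diffs = np.diff(centers)
        if len(centers) > 1:
            if self.direction == "forward" and not np.all(diffs > 0):
                raise ValueError("forward window centers must be strictly increasing")
            if self.direction == "backward" and not np.all(diffs < 0):
                raise ValueError("backward window centers must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.windows)

    def iter_in_order(self) -> Iterator[UmbrellaWindow]:
        """Windows in initialization order (reversed for backward sets)."""
        return iter(self.windows if self.direction == "forward"
                    else tuple(reversed(self.windows)))

    def with_direction(self, direction: Literal["forward", "backward"]) -> "WindowSet":
        return replace(self, direction=direction)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "direction": self.direction,
            "init_stiffness_kcal_mol_A2": self.init_stiffness,
            "windows": [
                {"index": w.index, "center_angstrom": w.center,
                 "stiffness_kcal_mol_A2": w.stiffness}
                for w in self.windows
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WindowSet":
        doc = yaml.safe_load(Path(path).read_text())
        windows = tuple(
            UmbrellaWindow(w["index"], w["center_angstrom"],
                           w["stiffness_kcal_mol_A2"])
            for w in doc["windows"]
        )
        return cls(windows=windows, direction=doc.get("direction", "forward"),
                   init_stiffness=doc.get("init_stiffness_kcal_mol_A2"))


@dataclass
class CvSeries:
    """Biased samples of the CV from one window: times (ps), values (Å)."""

    window: UmbrellaWindow
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("empty series")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def make_windows(
    l_min: float,
    l_max: float,
    n: int,
    stiffness: float,
    direction: Literal["forward", "backward"] = "forward",
    init_stiffness: float | None = None,
) -> WindowSet:
    """Place ``n`` uniformly spaced window centers on [l_min, l_max].

    The first center equals ``l_min`` and the last ``l_max``; spacing is
    (l_max - l_min)/(n - 1).
    """
    if n < 1:
        raise ValueError("need at least one window")
    if l_max < l_min:
        raise ValueError(f"l_max ({l_max}) must be >= l_min ({l_min})")
    if n == 1:
        if l_max != l_min:
            raise ValueError("a single window requires l_min == l_max")
        centers = np.array([l_min])
    else:
        centers = np.linspace(l_min, l_max, n)
    windows = tuple(
        UmbrellaWindow(index=i, center=float(c), stiffness=stiffness)
        for i, c in enumerate(centers)
    )
    return WindowSet(windows=windows, direction=direction,
                     init_stiffness=init_stiffness)


def make_windows_spacing(
    l_min: float,
    l_max: float,
    spacing: float,
    stiffness: float,
    direction: Literal["forward", "backward"] = "forward",
    init_stiffness: float | None = None,
) -> WindowSet:
    """Uniform windows at a given spacing, endpoints included.

    (l_max - l_min) must be an integer multiple of ``spacing`` (to float
    tolerance); the window count follows as the number of grid points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    steps = (l_max - l_min) / spacing
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"range {l_max - l_min} is not an integer multiple of spacing {spacing}"
        )
    n = int(round(steps)) + 1
    return make_windows(l_min, l_max, n, stiffness, direction, init_stiffness)


def bias_energy(
    l_value: float | np.ndarray, window: UmbrellaWindow, full_k: bool = False
) -> float | np.ndarray:
    """Harmonic restraint energy (kcal/mol) at CV value ``l_value``.

    Default convention is U = 1/2 k (L - L0)^2; ``full_k=True`` switches to
    U = k (L - L0)^2 for cross-checks against tools using that convention.
    """
    prefactor = window.stiffness if full_k else 0.5 * window.stiffness
    return prefactor * (np.asarray(l_value) - window.center) ** 2


def discard_equilibration(series: CvSeries, keep_last: float) -> CvSeries:
    """Keep only the samples in the final ``keep_last`` ps of the series."""
    if keep_last <= 0:
        raise ValueError("keep_last must be positive")
    if series.duration < keep_last:
        raise ValueError(
            f"series duration {series.duration} ps is shorter than "
            f"keep_last {keep_last} ps"
        )
    if keep_last >= series.duration:
        return CvSeries(series.window, series.times.copy(), series.values.copy())
    cutoff = series.times[-1] - keep_last
    mask = series.times > cutoff
    return CvSeries(series.window, series.times[mask], series.values[mask])


def write_cv(series: CvSeries, path: str | Path) -> None:
    """Write one window's CV series in the documented text dialect."""
    with open(path, "w") as fh:
        fh.write(f"# center_angstrom: {series.window.center:.17g}\n")
        fh.write(f"# stiffness_kcal_mol_A2: {series.window.stiffness:.17g}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.17g} {v:.17g}\n")


def read_cv(path: str | Path, index: int = 0) -> CvSeries:
    """Read one CV series file; the header must carry center and stiffness."""
    path = Path(path)
    meta: dict[str, float] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                key = key.strip()
                if key in ("center_angstrom", "stiffness_kcal_mol_A2"):
                    meta[key] = float(val)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path.name}: line {lineno}: expected two columns")
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    missing = {"center_angstrom", "stiffness_kcal_mol_A2"} - set(meta)
    if missing:
        raise ValueError(f"{path.name}: missing metadata header: {sorted(missing)}")
    if not times:
        raise ValueError(f"{path.name}: empty series")
    window = UmbrellaWindow(index=index, center=meta["center_angstrom"],
                            stiffness=meta["stiffness_kcal_mol_A2"])
    return CvSeries(window=window, times=np.array(times), values=np.array(values))


def read_cv_glob(paths: Sequence[str | Path]) -> list[CvSeries]:
    """Read many CV files, assigning window indices in sorted-path order."""
    return [read_cv(p, index=i) for i, p in enumerate(sorted(map(str, paths)))]
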