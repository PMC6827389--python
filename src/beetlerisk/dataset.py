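"""Build training examples from a landscape series.

Each example describes one focal host cell in one target year by a 19x19
moving window of small-integer codes around the cell — local host
distribution plus attack activity in the two preceding years — together
with two auxiliary variables (mean annual temperature at the focal cell
and the regional outbreak stage of the previous year). Flattened, an
example has exactly 361 + 2 = 363 input variables. The label is whether
the focal cell was attacked in the target year.

Cell codes
----------
0  non-host (or outside the landscape, or host killed by an old attack)
1  host, not attacked in the two preceding years
2  attacked two years before the target year
3  attacked one year before the target year (wins over code 2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import LandscapeSeries

__all__ = [
    "WINDOW_SIZE",
    "STAGES",
    "Example",
    "ExampleSet",
    "StageSeries",
    "classify_outbreak_stages",
    "encode_window",
    "build_examples",
    "split_by_years",
    "split_random",
]

WINDOW_SIZE = 19
_HALF = WINDOW_SIZE // 2

#: outbreak stages by regional-volume tercile, lowest to highest:
#: endemic background, gradation (build-up), culmination (peak)
STAGES = ("background", "gradation", "culmination")


@dataclass(frozen=True)
class Example:
    """A single focal cell-year (mainly for inspection; bulk work uses ExampleSet)."""

    window: np.ndarray  # (19, 19) int8 cell codes
    temperature: float
    stage: str
    label: int
    focal: tuple[int, int, int]  # (row, col, year)

    def flatten(self) -> np.ndarray:
        """The 363-variable input vector: 361 window codes + temperature + stage code."""
        return np.concatenate(
            [
                self.window.ravel().astype(np.float64),
                [self.temperature, float(STAGES.index(self.stage))],
            ]
        )


@dataclass
class StageSeries:
    """Per-year outbreak-stage labels with the tercile cutoffs that produced them."""

    years: np.ndarray
    labels: list[str]
    cutoffs: tuple[float, float]  # (33rd, 66th percentile of the fitted volumes)

    def stage_of(self, year: int) -> str:
        return self.labels[int(np.flatnonzero(self.years == year)[0])]

    def code_of(self, year: int) -> int:
        return STAGES.index(self.stage_of(year))


@dataclass
class ExampleSet:
    """Columnar example collection.

    windows hold int8 cell codes with shape (n, 19, 19); stage is the
    integer code into STAGES; focal rows are (row, col, year).
    """

    windows: np.ndarray
    temperature: np.ndarray
    stage: np.ndarray
    labels: np.ndarray
    focal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        assert self.windows.shape == (n, WINDOW_SIZE, WINDOW_SIZE)
        assert self.focal.shape == (n, 3)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def years(self) -> np.ndarray:
        return self.focal[:, 2]

    @property
    def class_counts(self) -> tuple[int, int]:
        n_pos = int(self.labels.sum())
        return n_pos, len(self) - n_pos

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean()) if len(self) else float("nan")

    def year_index(self) -> dict[int, np.ndarray]:
        return {int(y): np.flatnonzero(self.years == y) for y in np.unique(self.years)}

    def subset(self, idx) -> "ExampleSet":
        idx = np.asarray(idx)
        return ExampleSet(
            windows=self.windows[idx],
            temperature=self.temperature[idx],
            stage=self.stage[idx],
            labels=self.labels[idx],
            focal=self.focal[idx],
            meta=dict(self.meta),
        )

    def example(self, i: int) -> Example:
        return Example(
            window=self.windows[i],
            temperature=float(self.temperature[i]),
            stage=STAGES[int(self.stage[i])],
            label=int(self.labels[i]),
            focal=tuple(int(v) for v in self.focal[i]),
        )

    def flat_inputs(self) -> np.ndarray:
        """(n, 363) float matrix: 361 window codes + temperature + stage code."""
        n = len(self)
        return np.column_stack(
            [
                self.windows.reshape(n, -1).astype(np.float64),
                self.temperature.astype(np.float64),
                self.stage.astype(np.float64),
            ]
        )

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            windows=self.windows,
            temperature=self.temperature,
            stage=self.stage,
            labels=self.labels,
            focal=self.focal,
        )

    @classmethod
    def load(cls, path) -> "ExampleSet":
        with np.load(path) as z:
            return cls(
                windows=z["windows"],
                temperature=z["temperature"],
                stage=z["stage"],
                labels=z["labels"],
                focal=z["focal"],
            )


def classify_outbreak_stages(regional_volume, years=None) -> StageSeries:
    """Assign each year an outbreak stage by terciles of disturbed volume.

    Cutoffs are the 33rd and 66th percentiles (linear interpolation) of
    the volume series; a year at or below the lower cutoff is background,
    at or below the upper cutoff gradation, above it culmination. Ties at
    a cutoff therefore resolve to the lower class.
    """
    try:
        import pandas as pd

        if isinstance(regional_volume, pd.Series):
            if years is None:
                years = regional_volume.index.to_numpy()
            regional_volume = regional_volume.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    volumes = np.asarray(regional_volume, dtype=np.float64)
    if years is None:
        raise ValueError("years required when volumes are a bare array")
    years = np.asarray(years, dtype=np.int64)
    if volumes.size < 3:
        raise ValueError("need at least 3 years of volume data to form terciles")
    q33, q66 = np.percentile(volumes, [33, 66])
    labels = [
        STAGES[0] if v <= q33 else (STAGES[1] if v <= q66 else STAGES[2]) for v in volumes
    ]
    return StageSeries(years=years, labels=labels, cutoffs=(float(q33), float(q66)))


def _code_grid(series: LandscapeSeries, year: int, mortality: bool = True) -> np.ndarray:
    """Cell codes for one target year over the whole landscape."""
    yi = int(np.flatnonzero(series.years == year)[0])
    if yi < 2:
        raise ValueError(f"target year {year} lacks two preceding years in the series")
    a1 = series.attacks[yi - 1].astype(bool)
    a2 = series.attacks[yi - 2].astype(bool)
    host = series.host.astype(bool)
    if mortality and yi > 2:
        killed_before = series.attacks[: yi - 2].any(axis=0)
        host = host & ~killed_before
    codes = np.zeros(series.shape, dtype=np.int8)
    codes[host] = 1
    codes[a2] = 2
    codes[a1] = 3  # more recent attack wins
    return codes


def encode_window(
    series: LandscapeSeries, row: int, col: int, year: int, mortality: bool = True
) -> np.ndarray:
    """The 19x19 code window centred on (row, col) for a target year.

    Cells outside the landscape boundary are coded 0 (zero padding).
    """
    h, w = series.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"focal cell ({row}, {col}) outside {h}x{w} landscape")
    codes = _code_grid(series, year, mortality=mortality)
    padded = np.zeros((h + 2 * _HALF, w + 2 * _HALF), dtype=np.int8)
    padded[_HALF : _HALF + h, _HALF : _HALF + w] = codes
    return padded[row : row + WINDOW_SIZE, col : col + WINDOW_SIZE].copy()


def build_examples(
    series: LandscapeSeries,
    stages: StageSeries | None = None,
    mortality: bool = True,
) -> ExampleSet:
    """One example per eligible focal cell per target year.

    Target years are all years with two predecessors in the series.
    Eligible focal cells are host cells; with ``mortality`` (default) a
    cell attacked in any earlier year is removed from the host set for
    later target years (beetle-killed trees are no longer hosts). The
    stage covariate is the outbreak stage of the year before the target
    year; stages are fitted to the series' own volume data if not given.
    """
    if stages is None:
        stages = classify_outbreak_stages(series.regional_volume)
    if series.n_years < 3:
        raise ValueError("need at least 3 years (two predecessors plus a target year)")
    h, w = series.shape
    windows, temps, stage_codes, labels, focal = [], [], [], [], []
    # attacked in any year before the current target year
    ever_attacked = (series.attacks[0] | series.attacks[1]).astype(bool)
    host = series.host.astype(bool)
    finite_temp = np.isfinite(series.temperature)
    for yi in range(2, series.n_years):
        year = int(series.years[yi])
        if yi > 2:
            ever_attacked |= series.attacks[yi - 1].astype(bool)
        eligible = host & finite_temp
        if mortality:
            eligible = eligible & ~ever_attacked
        rows, cols = np.nonzero(eligible)
        if rows.size == 0:
            continue
        codes = _code_grid(series, year, mortality=mortality)
        padded = np.zeros((h + 2 * _HALF, w + 2 * _HALF), dtype=np.int8)
        padded[_HALF : _HALF + h, _HALF : _HALF + w] = codes
        s0, s1 = padded.strides
        views = np.lib.stride_tricks.as_strided(
            padded, (h, w, WINDOW_SIZE, WINDOW_SIZE), (s0, s1, s0, s1)
        )
        windows.append(views[rows, cols])
        temps.append(series.temperature[rows, cols])
        stage_codes.append(np.full(rows.size, stages.code_of(year - 1), dtype=np.int8))
        labels.append(series.attacks[yi][rows, cols])
        focal.append(
            np.column_stack([rows, cols, np.full(rows.size, year)]).astype(np.int32)
        )
    if not windows:
        raise ValueError("no eligible focal cells in any target year")
    return ExampleSet(
        windows=np.concatenate(windows).astype(np.int8),
        temperature=np.concatenate(temps).astype(np.float32),
        stage=np.concatenate(stage_codes),
        labels=np.concatenate(labels).astype(np.int8),
        focal=np.concatenate(focal),
        meta={
            "cell_size_m": series.cell_size_m,
            "mortality": mortality,
            "stage_cutoffs": stages.cutoffs,
        },
    )


def split_by_years(example_set: ExampleSet, holdout_years) -> tuple[ExampleSet, ExampleSet]:
    """Year-holdout split: test = examples whose target year is held out."""
    holdout = {int(y) for y in np.atleast_1d(holdout_years)}
    present = set(int(y) for y in np.unique(example_set.years))
    missing = holdout - present
    if missing:
        raise KeyError(f"holdout years {sorted(missing)} not in the example set")
    mask = np.isin(example_set.years, list(holdout))
    if mask.all():
        raise ValueError("holdout covers every target year; training set would be empty")
    return example_set.subset(np.flatnonzero(~mask)), example_set.subset(np.flatnonzero(mask))


def split_random(
    example_set: ExampleSet, fraction: float, seed: int
) -> tuple[ExampleSet, ExampleSet]:
    """Random unstratified holdout of round(fraction * N) examples."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    n = len(example_set)
    n_test = int(round(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return example_set.subset(train_idx), example_set.subset(test_idx)
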