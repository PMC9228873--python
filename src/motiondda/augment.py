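"""Artificial-database construction via stretch/rotation schedules plus noise.

Seven database codes (X, Y, R, XY, XR, YR, XYR) define ranges for three
augmentation parameters: a horizontal-stretch start percentage p_h, a
vertical-stretch start percentage p_v, and a starting rotation theta (deg).
For one source motion, 20 parameter triples are sampled along a schedule that
progresses monotonically toward neutral (stretch ratio 1, rotation 0); each
transformed matrix is replicated 3 times with Gaussian coordinate noise,
giving 60 matrices per label, 360 per dataset, and 20 datasets per database.

Schedule index 0 is the farthest from neutral and index 19 is neutral, so a
label's latent trajectory shrinks toward its target as the index grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from motiondda.shapes import LABELS, MotionMatrix, bbox_diagonal

#: Augmentation-parameter ranges per database code:
#: (p_h % interval, p_v % interval, theta degree interval).
TABLE1_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "X": ((10, 50), (90, 100), (-5, 5)),
    "Y": ((90, 100), (10, 50), (-5, 5)),
    "R": ((90, 100), (90, 100), (-45, 45)),
    "XY": ((10, 50), (10, 50), (-5, 5)),
    "XR": ((10, 50), (90, 100), (-45, 45)),
    "YR": ((90, 100), (10, 50), (-45, 45)),
    "XYR": ((10, 50), (10, 50), (-45, 45)),
}

ScheduleBehavior = Literal["linear", "random_staircase"]
BEHAVIORS: tuple[str, ...] = ("linear", "random_staircase")


@dataclass
class AugmentationConfig:
    """Configuration of one artificial database build.

    ``range_ph``/``range_pv`` are percent intervals for the stretch start
    values (converted to ratios internally); ``range_theta`` is in degrees.
    ``noise_sigma`` is the replicate-noise std. dev. as a fraction of the
    transformed matrix's bounding-box diagonal.
    """

    database_code: str = "XYR"
    range_ph: tuple[float, float] | None = None
    range_pv: tuple[float, float] | None = None
    range_theta: tuple[float, float] | None = None
    n_schedule: int = 20
    n_noise_copies: int = 3
    noise_sigma: float = 0.02
    n_datasets: int = 20
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.database_code not in TABLE1_RANGES:
            raise ValueError(
                f"unknown database code {self.database_code!r}; "
                f"expected one of {sorted(TABLE1_RANGES)}"
            )
        defaults = TABLE1_RANGES[self.database_code]
        if self.range_ph is None:
            self.range_ph = defaults[0]
        if self.range_pv is None:
            self.range_pv = defaults[1]
        if self.range_theta is None:
            self.range_theta = defaults[2]
        if self.n_schedule < 2 or self.n_noise_copies < 1 or self.n_datasets < 1:
            raise ValueError("n_schedule >= 2, n_noise_copies >= 1, n_datasets >= 1 required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def dataset_size(self) -> int:
        return self.n_schedule * self.n_noise_copies * len(LABELS)


@dataclass
class AnnotatedMotion:
    """A transformed motion plus its schedule/noise annotations.

    ``ph``/``pv`` are the stretch ratios and ``theta`` the rotation (deg)
    actually applied at this schedule index.
    """

    motion: MotionMatrix
    schedule_index: int
    noise_index: int
    ph: float
    pv: float
    theta: float

    @property
    def label(self) -> str:
        return self.motion.label


@dataclass
class ArtificialDataset:
    """360 annotated motions (60 per label) built from one source per label."""

    items: list[AnnotatedMotion]
    dataset_index: int = 0

    def __len__(self) -> int:
        return len(self.items)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened inputs (n, 64) and integer label indices (n,)."""
        X = np.stack([it.motion.flattened() for it in self.items])
        y = np.array([LABELS.index(it.label) for it in self.items])
        return X, y


@dataclass
class DatabaseSplit:
    """Held-out test datasets plus a 5-fold cross-validation pool.

    Each fold is a (train_indices, validation_indices) pair with 12 and 3
    dataset indices respectively; the validation sets partition the 15-dataset
    pool.  Two datasets remain unused (the printed 12/3/3 counts do not fill
    all 20).
    """

    test: tuple[int, ...]
    folds: list[tuple[tuple[int, ...], tuple[int, ...]]]
    unused: tuple[int, ...]


@dataclass
class ArtificialDatabase:
    """20 artificial datasets built under one augmentation configuration."""

    datasets: list[ArtificialDataset]
    config: AugmentationConfig
    split: DatabaseSplit | None = None

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def code(self) -> str:
        return self.config.database_code


def sample_schedule(
    start_value: float,
    end_value: float,
    n: int,
    behavior: str,
    rng_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample n ordered values from start_value to end_value.

    ``linear`` gives an arithmetic progression.  ``random_staircase`` gives a
    monotone piecewise-constant sequence: a random number of plateaus (2-10)
    with random change-points, plateau values taken from the linear schedule
    at the plateau's start, and the final plateau pinned to ``end_value``.
    """
    if n < 2:
        raise ValueError(f"schedule length must be >= 2, got {n}")
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown schedule behavior {behavior!r}; expected one of {BEHAVIORS}")
    linear = np.linspace(start_value, end_value, n)
    if behavior == "linear":
        return linear
    rng = np.random.default_rng(rng_seed)
    if start_value == end_value:
        return linear
    n_plateaus = int(rng.integers(2, 11))
    n_plateaus = min(n_plateaus, n)
    # change-points partition 0..n-1 into n_plateaus contiguous runs
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_plateaus - 1, replace=False))
    starts = np.concatenate([[0], cuts])
    values = np.empty(n)
    for i, s in enumerate(starts):
        stop = starts[i + 1] if i + 1 < len(starts) else n
        values[s:stop] = linear[s]
    values[starts[-1]:] = end_value
    values[0] = start_value
    return values


def apply_transform(
    points: np.ndarray, ratio_h: float, ratio_v: float, theta_deg: float
) -> np.ndarray:
    """Stretch by (ratio_h, ratio_v) then rotate by theta_deg about the centroid."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    if ratio_h <= 0 or ratio_v <= 0:
        raise ValueError(f"stretch ratios must be positive, got ({ratio_h}, {ratio_v})")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    stretched = centred * np.array([ratio_h, ratio_v])
    theta = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return stretched @ rot.T + centroid


def build_label_set(
    source_motion: MotionMatrix,
    config: AugmentationConfig,
    rng_seed: int | np.random.Generator | None = None,
) -> list[AnnotatedMotion]:
    """Build the 60 artificial matrices for one label from one source motion.

    Start values p_h, p_v, theta are drawn uniformly from the configured
    ranges; each parameter independently gets a linear or random-staircase
    schedule of length 20 toward neutral; every schedule point is then
    replicated ``n_noise_copies`` times with Gaussian coordinate noise.
    """
    rng = np.random.default_rng(rng_seed)
    ph0 = rng.uniform(*config.range_ph) / 100.0
    pv0 = rng.uniform(*config.range_pv) / 100.0
    th0 = rng.uniform(*config.range_theta)
    schedules = {}
    for name, (start, end) in (("ph", (ph0, 1.0)), ("pv", (pv0, 1.0)), ("theta", (th0, 0.0))):
        behavior = BEHAVIORS[rng.integers(0, 2)]
        schedules[name] = sample_schedule(start, end, config.n_schedule, behavior, rng)
    out: list[AnnotatedMotion] = []
    for i in range(config.n_schedule):
        ph, pv, th = schedules["ph"][i], schedules["pv"][i], schedules["theta"][i]
        transformed = apply_transform(source_motion.points, ph, pv, th)
        sigma = config.noise_sigma * bbox_diagonal(transformed)
        for j in range(config.n_noise_copies):
            noisy = transformed + rng.normal(0.0, sigma, size=transformed.shape)
            out.append(
                AnnotatedMotion(
                    MotionMatrix(noisy, source_motion.label, dict(source_motion.meta)),
                    schedule_index=i,
                    noise_index=j,
                    ph=float(ph),
                    pv=float(pv),
                    theta=float(th),
                )
            )
    return out


def build_database(
    source_per_label: Mapping[str, MotionMatrix | Sequence[MotionMatrix]],
    config: AugmentationConfig,
    rng_seed: int | None = None,
) -> ArtificialDatabase:
    """Build one database: ``config.n_datasets`` datasets of 360 motions each.

    ``source_per_label`` maps each label to either a single source motion or a
    pool of candidates; pools are re-drawn afresh for every dataset (a new
    random source selection per repetition of the build step).
    """
    missing = [lab for lab in LABELS if lab not in source_per_label]
    if missing:
        raise ValueError(f"missing source motion for label(s): {', '.join(missing)}")
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    datasets = []
    for d in range(config.n_datasets):
        items: list[AnnotatedMotion] = []
        for label in LABELS:
            src = source_per_label[label]
            if isinstance(src, MotionMatrix):
                chosen = src
            else:
                chosen = src[rng.integers(0, len(src))]
            items.extend(build_label_set(chosen, config, rng))
        datasets.append(ArtificialDataset(items, dataset_index=d))
    return ArtificialDatabase(datasets, config)


def split_database(
    database: ArtificialDatabase,
    rng_seed: int | np.random.Generator | None = None,
    n_test: int = 3,
    n_folds: int = 5,
    fold_val: int = 3,
) -> DatabaseSplit:
    """Assign datasets to test / 5-fold cross-validation pool.

    3 datasets go to the test set; 15 of the remaining 17 form the CV pool,
    partitioned into 5 folds of 3 validation datasets (12 train each); the
    last 2 datasets are unused.  The assignment is recorded on the database.
    """
    n = len(database.datasets)
    pool_size = n_folds * fold_val
    if n < n_test + pool_size:
        raise ValueError(f"database needs >= {n_test + pool_size} datasets, has {n}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    test = tuple(int(i) for i in sorted(perm[:n_test]))
    pool = perm[n_test : n_test + pool_size]
    unused = tuple(int(i) for i in sorted(perm[n_test + pool_size :]))
    folds = []
    for k in range(n_folds):
        val = pool[k * fold_val : (k + 1) * fold_val]
        train = np.setdiff1d(pool, val)
        folds.append((tuple(int(i) for i in sorted(train)), tuple(int(i) for i in sorted(val))))
    split = DatabaseSplit(test=test, folds=folds, unused=unused)
    database.split = split
    return split


def dataset_arrays(
    database: ArtificialDatabase, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the flattened inputs and label indices of the given datasets."""
    Xs, ys = [], []
    for i in indices:
        X, y = database.datasets[i].arrays()
        Xs.append(X)
        ys.append(y)
    return np.concatenate(Xs), np.concatenate(ys)
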