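"""Cone of detection and regression-dataset assembly.

The analysis is restricted to the region where odor is detected often
enough to carry statistics: the cone of detection, defined as the cells
whose long-run detection probability exceeds a threshold (0.35 by default).
Training and test examples are short windows cut from the record at
locations drawn uniformly over the cone, with training start times in the
first half of the record and test start times in the second half, so the
two sets never overlap in time. Windows that never exceed their adaptive
detection threshold carry no feature and are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, features_from_values
from .synthetic import PlumeRealization

__all__ = [
    "DetectionCone",
    "RegressionDataset",
    "detection_probability_map",
    "build_cone",
    "sample_dataset",
    "count_windows",
    "DEFAULT_CONE_THRESHOLD",
]

DEFAULT_CONE_THRESHOLD = 0.35

#: oversampling cap when redrawing windows that never exceed threshold
_RETRY_FACTOR = 100


class EmptyConeError(RuntimeError):
    """No cell exceeds the detection-probability threshold."""


@dataclass(frozen=True)
class DetectionCone:
    """Boolean mask of detectable cells plus the cone length R.

    ``R`` is the largest downwind coordinate of any masked cell; it sets the
    support of the distance prior used by the expected-error model.
    """

    mask: np.ndarray
    p_det: np.ndarray
    R: float
    threshold: float

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def detection_probability_map(stack: PlumeRealization) -> np.ndarray:
    """Fraction of snapshots above each cell's own adaptive threshold.

    Each cell's threshold is half the mean of its strictly positive samples
    over the full record — the same adaptive rule used everywhere in the
    pipeline. Cells with no positive sample get probability 0.
    """
    c = stack.concentration
    pos = c > 0
    counts = pos.sum(axis=-1)
    sums = np.where(pos, c, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cthr = 0.5 * sums / counts
    p = np.zeros(c.shape[:-1])
    has_pos = counts > 0
    p[has_pos] = (c[has_pos] > cthr[has_pos, None]).mean(axis=-1)
    return p


def build_cone(
    p_det: np.ndarray,
    stack: PlumeRealization,
    threshold: float = DEFAULT_CONE_THRESHOLD,
) -> DetectionCone:
    """Threshold the detection-probability map into a cone mask."""
    if np.any((p_det < 0) | (p_det > 1)):
        raise ValueError("p_det must lie in [0, 1]")
    mask = p_det > threshold
    if not mask.any():
        raise EmptyConeError("no detectable region: empty cone mask")
    iz = np.nonzero(mask.any(axis=1))[0]
    R = float(stack.z1[iz.max()])
    return DetectionCone(mask=mask, p_det=p_det, R=R, threshold=float(threshold))


def count_windows(n_frames: int, M: int) -> int:
    """Number of disjoint M-sample windows in a record of n_frames."""
    if M < 1:
        raise ValueError("window length M must be >= 1")
    return n_frames // M


@dataclass(frozen=True)
class RegressionDataset:
    """Feature rows paired with distance outputs and train/test tags.

    ``table`` holds one row per sampled window: location, start time, the
    five features and the output; every row derives from a valid feature
    vector. ``X(subset)`` returns the design matrix for a feature subset.
    """

    table: pd.DataFrame
    output_axis: str
    memory: int
    dt: float
    cone_R: float
    seed: int

    def rows(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role]

    def X(self, subset, role: str) -> np.ndarray:
        subset = list(subset)
        bad = [f for f in subset if f not in FEATURE_NAMES]
        if bad:
            raise ValueError(f"unknown features {bad}")
        return self.rows(role)[subset].to_numpy()

    def y(self, role: str) -> np.ndarray:
        return self.rows(role)["y"].to_numpy()

    @property
    def n_train(self) -> int:
        return int((self.table["role"] == "train").sum())

    @property
    def n_test(self) -> int:
        return int((self.table["role"] == "test").sum())


def _draw_rows(
    stack: PlumeRealization,
    cells: np.ndarray,
    n_rows: int,
    t_lo: int,
    t_hi: int,
    memory: int,
    output_axis: str,
    rng: np.random.Generator,
    role: str,
) -> list[dict]:
    """Draw windows until n_rows valid feature vectors are collected."""
    rows: list[dict] = []
    attempts = 0
    conc = stack.concentration
    dt = stack.dt
    while len(rows) < n_rows:
        if attempts >= _RETRY_FACTOR * max(n_rows, 1):
            raise RuntimeError(
                f"could not draw {n_rows} valid windows within "
                f"{_RETRY_FACTOR}x oversampling (got {len(rows)})"
            )
        attempts += 1
        i, j = cells[rng.integers(cells.shape[0])]
        t0 = int(rng.integers(t_lo, t_hi + 1))
        feats = features_from_values(conc[i, j, t0 : t0 + memory], dt)
        if not np.all(np.isfinite(feats)):
            continue
        if output_axis == "downwind":
            y = abs(float(stack.z1[i]))
        elif output_axis == "crosswind":
            y = float(stack.z2[j])
        else:
            raise ValueError("output_axis must be 'downwind' or 'crosswind'")
        rows.append(
            {
                "z1": float(stack.z1[i]),
                "z2": float(stack.z2[j]),
                "t0": t0 * dt,
                **dict(zip(FEATURE_NAMES, feats)),
                "y": y,
                "role": role,
            }
        )
    return rows


def sample_dataset(
    stack: PlumeRealization,
    cone: DetectionCone,
    N: int,
    Nt: int,
    memory: int,
    output_axis: str = "downwind",
    seed: int = 0,
) -> RegressionDataset:
    """Sample a train/test regression dataset from a plume record.

    Locations are drawn uniformly (with replacement) over the cone mask;
    start times uniformly over admissible window starts, training from the
    first half of the record and test from the second half. ``memory`` is
    the window length in samples.
    """
    n_frames = stack.n_frames
    half = n_frames // 2
    if memory > half:
        raise ValueError(
            f"memory ({memory} samples) exceeds half the record ({half})"
        )
    cells = np.argwhere(cone.mask)
    rng = np.random.default_rng(seed)
    train = _draw_rows(
        stack, cells, N, 0, half - memory, memory, output_axis, rng, "train"
    )
    test = _draw_rows(
        stack, cells, Nt, half, n_frames - memory, memory, output_axis, rng, "test"
    )
    table = pd.DataFrame(train + test)
    if table.empty:
        table = pd.DataFrame(
            columns=["z1", "z2", "t0", *FEATURE_NAMES, "y", "role"]
        )
    return RegressionDataset(
        table=table,
        output_axis=output_axis,
        memory=memory,
        dt=stack.dt,
        cone_R=cone.R,
        seed=seed,
    )
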