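"""Data splitting, evaluation metrics, and the configuration grid search.

The evaluation protocol: of 45 samples, 35 are drawn at random as the
calibration set — itself split 7:3 into training and validation to guard
against over-fitting — and the remaining 10 are held out for testing.
Every candidate configuration (algorithm x learning rate x layer sizes x
activations) is trained on the training set with validation-based early
stopping, then scored on the held-out test samples by R² (squared
Pearson correlation of predicted vs measured) and RMSEP,
``sqrt(sum (k_E - k_P)^2 / N)``.  Models are ranked by R² descending
with RMSEP ascending as tie-breaker.  RMSEP is also expressed as a
percentage of the observed target range ("RMSEP percentile").
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .neuralnet import (
    ACTIVATION_KINDS,
    AnnConfig,
    AnnModel,
    TrainingDivergedError,
    fit_regressor,
    predict,
)

__all__ = [
    "SplitPlan",
    "EvalReport",
    "make_split",
    "rmsep",
    "r_squared",
    "r_squared_identity",
    "rmsep_percentile",
    "table2_full_grid",
    "best_model_configs",
    "restricted_grid",
    "grid_search",
]

logger = logging.getLogger(__name__)

#: Grid values swept in the original configuration study.
GRID_LEARNING_RATES = (0.5, 0.7, 0.9)
GRID_HIDDEN1_SIZES = (9, 11, 13)
GRID_HIDDEN2_SIZES = (0, 9, 11, 13)
GRID_ALGORITHMS = ("incremental", "batch", "rprop", "quickprop")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation/test index sets."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    @property
    def calibration(self) -> tuple[int, ...]:
        return self.train + self.validation

    def __post_init__(self) -> None:
        all_ids = self.train + self.validation + self.test
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split groups overlap")
        if not (self.train and self.validation and self.test):
            raise ValueError("every split group must be non-empty")


def make_split(n: int, seed: int) -> SplitPlan:
    """Seeded shuffle into calibration (train + validation, 7:3) and test.

    For the canonical 45-sample panel the calibration set has exactly 35
    samples; for other n it holds ceil(0.78 n).
    """
    if n < 5:
        raise ValueError(f"need n >= 5 to populate all three groups, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_cal = 35 if n == 45 else math.ceil(0.78 * n)
    n_cal = min(n_cal, n - 1)
    cal, test = order[:n_cal], order[n_cal:]
    n_train = int(round(0.7 * n_cal))
    n_train = min(max(n_train, 1), n_cal - 1)
    return SplitPlan(
        train=tuple(int(i) for i in cal[:n_train]),
        validation=tuple(int(i) for i in cal[n_train:]),
        test=tuple(int(i) for i in test),
        seed=seed,
    )


def rmsep(predicted, expected) -> float:
    """Root mean square error of prediction."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(expected, dtype=float)
    if p.shape != e.shape or p.size == 0:
        raise ValueError("predicted/expected must be equal-length, non-empty")
    return float(np.sqrt(np.mean((e - p) ** 2)))


def r_squared(predicted, expected) -> float:
    """Squared Pearson correlation of predicted against expected."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(expected, dtype=float)
    if p.shape != e.shape or p.size < 3:
        raise ValueError("need >= 3 equal-length pairs")
    if np.ptp(e) == 0:
        raise ValueError("expected values are constant; R² undefined")
    if np.ptp(p) == 0:
        return 0.0  # constant prediction carries no correlation
    r, _ = stats.pearsonr(p, e)
    return float(r**2)


def r_squared_identity(predicted, expected) -> float:
    """Coefficient of determination about the identity line, 1 - SSres/SStot."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(expected, dtype=float)
    if np.ptp(e) == 0:
        raise ValueError("expected values are constant; R² undefined")
    ss_res = float(np.sum((e - p) ** 2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def rmsep_percentile(rmsep_value: float, target_min: float, target_max: float) -> float:
    """RMSEP as a percentage of the observed target range."""
    if target_max <= target_min:
        raise ValueError("degenerate target range")
    return 100.0 * rmsep_value / (target_max - target_min)


# ---------------------------------------------------------------------------
# configuration grids
# ---------------------------------------------------------------------------

def table2_full_grid(
    activations: tuple[str, ...] = ACTIVATION_KINDS,
    max_epochs: int = 1000,
) -> list[AnnConfig]:
    """Enumerate the full sweep grid (very large; filter before training)."""
    configs = []
    for algo, lr, h1, h2 in itertools.product(
        GRID_ALGORITHMS, GRID_LEARNING_RATES, GRID_HIDDEN1_SIZES, GRID_HIDDEN2_SIZES
    ):
        layer_acts = (
            itertools.product(activations, activations)
            if h2 == 0
            else itertools.product(activations, activations, activations)
        )
        for acts in layer_acts:
            if h2 == 0:
                a1, out = acts
                a2 = "sigmoid"
            else:
                a1, a2, out = acts
            configs.append(
                AnnConfig(
                    algorithm=algo,
                    learning_rate=lr,
                    hidden1_size=h1,
                    hidden1_activation=a1,
                    hidden2_size=h2,
                    hidden2_activation=a2,
                    output_activation=out,
                    max_epochs=max_epochs,
                )
            )
    return configs


def best_model_configs(max_epochs: int = 2000) -> dict[str, AnnConfig]:
    """The three winning configurations of the original sweep, per taste."""
    return {
        "sweetness": AnnConfig(
            algorithm="incremental",
            learning_rate=0.9,
            hidden1_size=9,
            hidden1_activation="sigmoid",
            hidden2_size=11,
            hidden2_activation="sigmoid",
            output_activation="sin",
            max_epochs=max_epochs,
        ),
        "sourness": AnnConfig(
            algorithm="quickprop",
            learning_rate=0.9,
            hidden1_size=9,
            hidden1_activation="sigmoid",
            hidden2_size=11,
            hidden2_activation="gaussian",
            output_activation="sin",
            max_epochs=max_epochs,
        ),
        "astringency": AnnConfig(
            algorithm="batch",
            learning_rate=0.7,
            hidden1_size=13,
            hidden1_activation="sigmoid",
            hidden2_size=11,
            hidden2_activation="gaussian",
            output_activation="cos",
            max_epochs=max_epochs,
        ),
    }


def restricted_grid(max_epochs: int = 2000) -> list[AnnConfig]:
    """Fast grid: the three historical best-model patterns."""
    return list(best_model_configs(max_epochs).values())


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Outcome of one grid search on one taste target."""

    best_config: AnnConfig
    best_model: AnnModel
    r2_test: float
    rmsep_test: float
    rmsep_pct: float
    r2_identity_test: float
    leaderboard: pd.DataFrame = field(repr=False)
    predictions_test: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "best_config": self.best_config.describe(),
            "r2_test": self.r2_test,
            "rmsep_test": self.rmsep_test,
            "rmsep_pct": self.rmsep_pct,
            "r2_identity_test": self.r2_identity_test,
        }


def grid_search(
    features: np.ndarray,
    targets: np.ndarray,
    split: SplitPlan,
    grid: list[AnnConfig],
    seed: int = 0,
) -> EvalReport:
    """Train every configuration and rank on the held-out test set.

    A configuration that diverges is logged, kept on the leaderboard with
    a failed status and sentinel scores, and never aborts the sweep.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    tr, va, te = list(split.train), list(split.validation), list(split.test)
    rows = []
    fitted: dict[int, tuple[AnnModel, np.ndarray]] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(grid))]
    for idx, cfg in enumerate(grid):
        cfg_seeded = AnnConfig(
            algorithm=cfg.algorithm,
            learning_rate=cfg.learning_rate,
            hidden1_size=cfg.hidden1_size,
            hidden1_activation=cfg.hidden1_activation,
            hidden2_size=cfg.hidden2_size,
            hidden2_activation=cfg.hidden2_activation,
            output_activation=cfg.output_activation,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=child_seeds[idx],
        )
        row = {"config": cfg_seeded.describe(), "status": "ok"}
        try:
            model, _ = fit_regressor(
                X[tr], y[tr], cfg_seeded, validation=(X[va], y[va])
            )
            pred = predict(model, X[te])
            row["r2"] = r_squared(pred, y[te])
            row["rmsep"] = rmsep(pred, y[te])
            row["r2_identity"] = r_squared_identity(pred, y[te])
            fitted[idx] = (model, pred)
        except TrainingDivergedError as exc:
            logger.warning("config %s failed: %s", cfg_seeded.describe(), exc)
            row.update(status="failed", r2=np.nan, rmsep=np.nan, r2_identity=np.nan)
        rows.append(row)

    board = pd.DataFrame(rows)
    board["_r2_rank"] = board["r2"].fillna(-np.inf)
    board["_rmsep_rank"] = board["rmsep"].fillna(np.inf)
    board = (
        board.sort_values(["_r2_rank", "_rmsep_rank"], ascending=[False, True])
        .drop(columns=["_r2_rank", "_rmsep_rank"])
        .reset_index(drop=False)
        .rename(columns={"index": "grid_index"})
    )
    best_idx = int(board.loc[0, "grid_index"])
    if best_idx not in fitted:
        raise TrainingDivergedError("every configuration in the grid diverged")
    best_model, best_pred = fitted[best_idx]
    best_cfg = grid[best_idx]
    return EvalReport(
        best_config=best_cfg,
        best_model=best_model,
        r2_test=float(board.loc[0, "r2"]),
        rmsep_test=float(board.loc[0, "rmsep"]),
        rmsep_pct=rmsep_percentile(
            float(board.loc[0, "rmsep"]), float(y.min()), float(y.max())
        ),
        r2_identity_test=float(board.loc[0, "r2_identity"]),
        leaderboard=board,
        predictions_test=best_pred,
    )
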