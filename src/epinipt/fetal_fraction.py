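"""Sex-independent fetal-fraction estimation from binned read counts.

A deliberately simple stand-in honouring the contract of count-based
fetal-fraction estimators (SeqFF and kin): read counts are totalled in
fixed-width genomic bins, row-normalised to proportions (making predictions
invariant to sequencing depth), and a ridge-penalised linear model maps bin
proportions to the reference fetal fraction. This is explicitly NOT a SeqFF
re-implementation — no trained SeqFF weights exist to port — but a
deterministic, one-hyperparameter regression over the same representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .coverage import CoverageMatrix, window_stats


@dataclass
class FFModel:
    """Fitted fetal-fraction regressor over genomic bins."""

    bin_width: int
    bin_chrom: np.ndarray          # (B,) chromosome names
    bin_start: np.ndarray          # (B,)
    coef: np.ndarray               # (B,)
    intercept: float
    n_train: int
    penalty: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_width": self.bin_width,
                "bin_chrom": self.bin_chrom.tolist(),
                "bin_start": self.bin_start.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "n_train": self.n_train,
                "penalty": self.penalty,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FFModel":
        d = json.loads(text)
        return cls(
            bin_width=d["bin_width"],
            bin_chrom=np.asarray(d["bin_chrom"]),
            bin_start=np.asarray(d["bin_start"], dtype=np.int64),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_train=int(d["n_train"]),
            penalty=float(d["penalty"]),
            seed=int(d["seed"]),
        )


def bin_counts(matrix: CoverageMatrix, width: int = 50_000) -> tuple[np.ndarray, pd.DataFrame]:
    """Total read counts per sample in non-overlapping ``width``-bp bins.

    Returns (samples x bins totals, bin table with chrom/start/end). Bin
    totals conserve each sample's total assigned reads (bins without CG
    sites can hold no reads and are omitted).
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    ws = window_stats(matrix, width=width)
    bins = ws.window_frame()[["chrom", "start", "end"]]
    return ws.coverage.astype(np.int64), bins


def _proportions(bins: np.ndarray) -> np.ndarray:
    totals = bins.sum(axis=1, keepdims=True).astype(float)
    if np.any(totals == 0):
        totals = np.where(totals == 0, 1.0, totals)
    return bins / totals


def fit_ff(
    train_bins: np.ndarray,
    bin_table: pd.DataFrame,
    train_ff: np.ndarray,
    penalty: float = 2e-6,
    seed: int = 0,
) -> FFModel:
    """Ridge fit of fetal fraction on row-normalised bin proportions."""
    ff = np.asarray(train_ff, dtype=float)
    if train_bins.shape[0] < 10:
        raise ValueError("need at least 10 training samples")
    if np.ptp(ff) == 0:
        raise ValueError("constant fetal fraction in training set")
    x = _proportions(np.asarray(train_bins))
    # per-sample penalty: duplicating the training rows leaves the solution
    # (and hence the coefficients) unchanged; the default corresponds to a
    # total ridge of ~1e-4 at typical training sizes
    model = Ridge(alpha=penalty * x.shape[0], random_state=seed)
    model.fit(x, ff)
    return FFModel(
        bin_width=int(bin_table["end"].iloc[0] - bin_table["start"].iloc[0]),
        bin_chrom=bin_table["chrom"].to_numpy(),
        bin_start=bin_table["start"].to_numpy(),
        coef=np.asarray(model.coef_, dtype=float),
        intercept=float(model.intercept_),
        n_train=int(train_bins.shape[0]),
        penalty=float(penalty),
        seed=int(seed),
    )


def predict_ff(model: FFModel, bins: np.ndarray, bin_table: pd.DataFrame | None = None) -> np.ndarray:
    """Fetal-fraction predictions clipped to [0, 1]."""
    bins = np.asarray(bins)
    if bins.shape[1] != model.coef.size:
        raise ValueError(
            f"bin layout mismatch: model has {model.coef.size} bins, "
            f"input has {bins.shape[1]}"
        )
    if bin_table is not None:
        if not (
            np.array_equal(bin_table["chrom"].to_numpy(), model.bin_chrom)
            and np.array_equal(bin_table["start"].to_numpy(), model.bin_start)
        ):
            raise ValueError("bin definitions do not match the fitted model")
    pred = _proportions(bins) @ model.coef + model.intercept
    return np.clip(pred, 0.0, 1.0)
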