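"""Z-score karyotyping and read-depth titration.

For sample *i* the statistic X_i is the ratio of target-chromosome signal
(CG-coverage or CG-fraction) to a reference chromosome's signal. The mean mu
and standard deviation sigma of X over the healthy-pregnancy training
samples standardise every sample's statistic into Z_i = (X_i - mu) / sigma;
trisomy of the target chromosome inflates X through the extra fetal copy.

Classification is leave-one-out cross-validated logistic regression on Z
(ridge-stabilised, since Z typically separates the classes perfectly), with
accuracy at the 0.5 cutoff and the area under the ROC curve as endpoints.
Depth titration repeats the whole analysis on random without-replacement
subsamples of the assigned reads (30 repetitions per depth by default).

The reference chromosome is a configuration value; the defaults follow the
chr16-analog for uCG and the chr20-analog for 5hmCG. The source protocol's
own reporting of this pairing is internally inconsistent, so both orderings
are supported and neither is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._glm import ridge_logistic_fit, ridge_logistic_predict
from .coverage import CoverageMatrix, chrom_stats, subsample_counts
from .synthetic_data import HUMAN_CG_SITES

#: default reference-chromosome analog per assay
DEFAULT_REFERENCE = {"uCG": "chr16a", "5hmCG": "chr20a"}


def scale_depth(human_reads: float, n_sites: int,
                reference_sites: int = HUMAN_CG_SITES) -> int:
    """Synthetic-genome depth matching a human-genome-scale processed-read count."""
    return int(round(human_reads * n_sites / reference_sites))


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome.

    ``scores`` are the held-out cross-validated Z-scores (each computed with
    its fold's training mu/sigma). The AUC ranks samples by these scores:
    within a fold the logistic probability is strictly monotone in Z, but
    pooled probabilities are not on a common scale across leave-one-out
    folds (the per-fold class-imbalance shifts the intercept), so ranking by
    the cross-validated score keeps the permutation null centred at 0.5.
    ``probabilities`` still drive the accuracy at the 0.5 cutoff.
    """

    probabilities: np.ndarray      # held-out P(T21) per sample
    scores: np.ndarray             # held-out cross-validated Z per sample
    is_t21: np.ndarray
    auc: float
    accuracy: float                # at the 0.5 probability cutoff


@dataclass
class TitrationCurve:
    """Mean/SD of LOOCV AUC and accuracy per subsampling depth."""

    table: pd.DataFrame            # depth, mean_auc, sd_auc, min_auc, ...
    aucs: dict[int, np.ndarray]    # depth -> per-repetition AUC
    accuracies: dict[int, np.ndarray]
    n_reps: int
    seed: int


def chrom_ratios(
    stats: pd.DataFrame, target_chrom: str, ref_chrom: str,
    signal_kind: str = "fraction",
) -> pd.Series:
    """Target/reference chromosome signal ratio X per sample."""
    if target_chrom == ref_chrom:
        raise ValueError("reference chromosome must differ from the target")
    col = {"coverage": "total_coverage", "fraction": "cg_fraction"}.get(signal_kind)
    if col is None:
        raise ValueError("signal_kind must be 'coverage' or 'fraction'")
    wide = stats.pivot(index="sample_id", columns="chrom", values=col)
    for c in (target_chrom, ref_chrom):
        if c not in wide.columns:
            raise ValueError(f"chromosome {c!r} absent from the statistics table")
    return wide[target_chrom] / wide[ref_chrom]


def chrom_ratio_zscores(
    stats: pd.DataFrame,
    target_chrom: str,
    ref_chrom: str,
    healthy_ids: list[str],
    signal_kind: str = "fraction",
    ddof: int = 1,
) -> pd.DataFrame:
    """Reference-normalised Z-scores for every sample.

    mu and sigma are estimated from the healthy-pregnancy samples only
    (sample SD, ddof=1, by default); Z is reported for every sample present
    in ``stats`` including any non-pregnant or tissue samples.
    """
    x = chrom_ratios(stats, target_chrom, ref_chrom, signal_kind)
    missing = set(healthy_ids) - set(x.index)
    if missing:
        raise ValueError(f"healthy ids absent from stats: {sorted(missing)}")
    if len(healthy_ids) < 3:
        raise ValueError("need at least 3 healthy training samples")
    train = x.loc[list(healthy_ids)]
    mu = float(train.mean())
    sigma = float(train.std(ddof=ddof))
    if sigma == 0 or np.ptp(train.to_numpy()) == 0:
        raise ValueError("degenerate training set: sigma = 0")
    out = pd.DataFrame(
        {"sample_id": x.index, "signal_kind": signal_kind, "X": x.to_numpy(),
         "mu": mu, "sigma": sigma, "Z": (x.to_numpy() - mu) / sigma}
    ).reset_index(drop=True)
    return out


def loocv_classify(
    ratios: np.ndarray | pd.Series,
    is_t21: np.ndarray,
    healthy_mask: np.ndarray | None = None,
    eval_mask: np.ndarray | None = None,
    penalty: float = 1e-4,
    ddof: int = 1,
) -> CVResult:
    """Leave-one-out logistic classification on chromosome-ratio Z-scores.

    In every fold the training mu/sigma (from the retained reference
    samples; a held-out reference sample never enters its own training
    statistics) and the ridge-stabilised logistic fit are recomputed, and
    the held-out sample's trisomy probability recorded. AUC uses midranks
    for ties.

    ``healthy_mask`` selects the euploid reference population for mu/sigma
    (default: every non-T21 sample — including any non-pregnant controls
    present, which stabilises the fold SD at small cohort sizes).
    ``eval_mask`` selects which samples are held out and scored (default:
    all); reference-only samples stay in every training set.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(is_t21, dtype=bool)
    if healthy_mask is None:
        healthy_mask = ~y
    healthy_mask = np.asarray(healthy_mask, dtype=bool)
    if eval_mask is None:
        eval_mask = np.ones(x.size, dtype=bool)
    eval_mask = np.asarray(eval_mask, dtype=bool)
    y_eval = y[eval_mask]
    if y_eval.all() or not y_eval.any():
        raise ValueError("both classes must be present")
    if y_eval.sum() < 2 or (~y_eval).sum() < 2:
        raise ValueError("each class needs at least 2 members")
    n = x.size
    probs = np.full(n, np.nan)
    scores = np.full(n, np.nan)
    for i in np.flatnonzero(eval_mask):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train_healthy = keep & healthy_mask
        if train_healthy.sum() < 2:
            raise ValueError("too few healthy samples to train a fold")
        mu = x[train_healthy].mean()
        sigma = x[train_healthy].std(ddof=ddof)
        if sigma == 0 or np.ptp(x[train_healthy]) == 0:
            raise ValueError("degenerate fold: sigma = 0")
        z = (x - mu) / sigma
        model = ridge_logistic_fit(z[keep, None], y[keep], penalty=penalty)
        probs[i] = ridge_logistic_predict(model, z[i, None])[0]
        scores[i] = z[i]
    auc = float(roc_auc_score(y_eval, scores[eval_mask]))
    accuracy = float(np.mean((probs[eval_mask] > 0.5) == y_eval))
    return CVResult(probabilities=probs[eval_mask], scores=scores[eval_mask],
                    is_t21=y_eval, auc=auc, accuracy=accuracy)


def classify_cohort(
    matrix: CoverageMatrix,
    is_t21: np.ndarray,
    healthy_mask: np.ndarray,
    target_chrom: str,
    ref_chrom: str,
    signal_kind: str = "fraction",
    eval_mask: np.ndarray | None = None,
) -> CVResult:
    """Chromosome stats -> ratios -> LOOCV classification in one call."""
    stats = chrom_stats(matrix)
    x = chrom_ratios(stats, target_chrom, ref_chrom, signal_kind)
    x = x.loc[matrix.sample_ids].to_numpy()
    return loocv_classify(x, is_t21, healthy_mask, eval_mask=eval_mask)


def depth_titration(
    matrix: CoverageMatrix,
    is_t21: np.ndarray,
    depths: list[int],
    target_chrom: str,
    ref_chrom: str,
    signal_kind: str = "fraction",
    healthy_mask: np.ndarray | None = None,
    eval_mask: np.ndarray | None = None,
    n_reps: int = 30,
    seed: int = 0,
    shallow: tuple[CoverageMatrix, np.ndarray] | None = None,
) -> TitrationCurve:
    """LOOCV AUC/accuracy across subsampling depths.

    For each depth and repetition the matrix is subsampled without
    replacement, chromosome statistics and Z-scores are recomputed and the
    LOOCV classifier re-evaluated. ``shallow`` optionally supplies natively
    shallow samples (matrix + trisomy labels) that join the evaluation loop
    as-is, at whatever depth they were sequenced.

    ``depths`` are in synthetic-genome read units (use :func:`scale_depth`
    for human-genome-scale equivalents) and must be strictly increasing.
    """
    depths = [int(d) for d in depths]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    totals = matrix.totals()
    if max(depths) > totals.min():
        limiting = matrix.sample_ids[int(np.argmin(totals))]
        raise ValueError(
            f"depth {max(depths)} infeasible: sample {limiting!r} has only "
            f"{totals.min()} assigned reads"
        )
    y = np.asarray(is_t21, dtype=bool)
    if healthy_mask is None:
        healthy_mask = ~y
    healthy_mask = np.asarray(healthy_mask, dtype=bool)
    if eval_mask is None:
        eval_mask = np.ones(y.size, dtype=bool)
    eval_mask = np.asarray(eval_mask, dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    aucs: dict[int, np.ndarray] = {}
    accs: dict[int, np.ndarray] = {}
    rows = []
    for depth in depths:
        a = np.empty(n_reps)
        c = np.empty(n_reps)
        for rep in range(n_reps):
            sub = subsample_counts(matrix, depth, rng)
            y_eval, healthy_eval, keep_eval = y, healthy_mask, eval_mask
            if shallow is not None:
                sh_matrix, sh_t21 = shallow
                sub = CoverageMatrix.concat_samples(sub, sh_matrix)
                sh_t21 = np.asarray(sh_t21, dtype=bool)
                y_eval = np.concatenate([y, sh_t21])
                healthy_eval = np.concatenate([healthy_mask, ~sh_t21])
                keep_eval = np.concatenate(
                    [eval_mask, np.ones(sh_t21.size, dtype=bool)])
            res = classify_cohort(sub, y_eval, healthy_eval,
                                  target_chrom, ref_chrom, signal_kind,
                                  eval_mask=keep_eval)
            a[rep], c[rep] = res.auc, res.accuracy
        aucs[depth], accs[depth] = a, c
        rows.append(
            (depth, a.mean(), a.std(ddof=1) if n_reps > 1 else 0.0, a.min(),
             c.mean(), c.min())
        )
    table = pd.DataFrame(
        rows, columns=["depth", "mean_auc", "sd_auc", "min_auc",
                       "mean_accuracy", "min_accuracy"]
    )
    return TitrationCurve(table=table, aucs=aucs, accuracies=accs,
                          n_reps=n_reps, seed=seed)
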