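"""Differentially modified region (DMR) discovery over 100-bp windows.

Per window the two normalised signals are

* ``norm_cov``  = log2(window CG-coverage + 1) - log2(reference-chromosome
  total coverage)   (pseudocount 1; log-ratio, unitless),
* ``norm_frac`` = window CG-fraction / reference-chromosome CG-fraction.

Group membership (e.g. non-pregnant vs pregnant plasma, or healthy vs T21
pregnancy) is tested per window by a likelihood-ratio chi-square comparing a
full logistic model (label ~ norm_cov + norm_frac [+ fetal sex + fetal
fraction]) against the null without the two window features; df = 2. When a
full model with the fetal-sex covariate fails to converge the window is
refitted without it — and the null drops it too, keeping df = 2. Windows
that still fail get p = NA and are excluded from FDR.

Multiple testing uses Benjamini–Hochberg; DMR-set comparisons use Fisher's
exact test (Haldane 0.5 correction on degenerate tables), Pearson effect
concordance, a positional two-sample Kolmogorov–Smirnov test, and per-DMR
leave-one-out classification with a weakly-informative (scale-2.5 Gaussian
on standardised predictors) penalised logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import _sigmoid, ridge_logistic_fit, ridge_logistic_predict
from .coverage import WindowStats
from .karyotyping import loocv_classify  # noqa: F401  (re-export convenience)
from sklearn.metrics import roc_auc_score

_RIDGE_STABILISER = 1e-10


@dataclass
class WindowFeatures:
    """Reference-normalised per-window features for every sample."""

    chrom: np.ndarray              # (W,) chromosome names
    start: np.ndarray              # (W,)
    end: np.ndarray                # (W,)
    n_cg: np.ndarray               # (W,)
    norm_cov: np.ndarray           # (n_samples, W) log2 ratio
    norm_frac: np.ndarray          # (n_samples, W) fraction ratio
    lin_cov: np.ndarray            # (n_samples, W) coverage / ref total
    sample_ids: list[str]

    @property
    def n_windows(self) -> int:
        return self.chrom.size

    def subset_chrom(self, chrom: str) -> "WindowFeatures":
        m = self.chrom == chrom
        return WindowFeatures(
            self.chrom[m], self.start[m], self.end[m], self.n_cg[m],
            self.norm_cov[:, m], self.norm_frac[:, m], self.lin_cov[:, m],
            list(self.sample_ids),
        )

    def subset_samples(self, ids: list[str]) -> "WindowFeatures":
        idx = [self.sample_ids.index(s) for s in ids]
        return WindowFeatures(
            self.chrom, self.start, self.end, self.n_cg,
            self.norm_cov[idx], self.norm_frac[idx], self.lin_cov[idx],
            list(ids),
        )

    def window_ids(self) -> list[tuple[str, int]]:
        return [(c, int(s)) for c, s in zip(self.chrom, self.start)]


def normalize_window_features(
    window_stats: WindowStats,
    chrom_stats: pd.DataFrame,
    ref_chrom: str,
) -> WindowFeatures:
    """Normalise window coverage/fraction by the reference chromosome."""
    cs = chrom_stats[chrom_stats["chrom"] == ref_chrom].set_index("sample_id")
    missing = [s for s in window_stats.sample_ids if s not in cs.index]
    if missing:
        raise ValueError(f"samples missing reference-chromosome stats: {missing}")
    ref_total = cs.loc[window_stats.sample_ids, "total_coverage"].to_numpy(float)
    ref_frac = cs.loc[window_stats.sample_ids, "cg_fraction"].to_numpy(float)
    bad = np.where(ref_total <= 0)[0]
    if bad.size:
        raise ValueError(
            f"zero reference-chromosome coverage for sample "
            f"{window_stats.sample_ids[bad[0]]!r}"
        )
    cov = window_stats.coverage.astype(float)
    frac = window_stats.cg_fraction
    chrom_names = np.asarray(window_stats.chrom_names)[window_stats.chrom_id]
    return WindowFeatures(
        chrom=chrom_names,
        start=window_stats.start.copy(),
        end=window_stats.end.copy(),
        n_cg=window_stats.n_cg.copy(),
        norm_cov=np.log2(cov + 1.0) - np.log2(ref_total)[:, None],
        norm_frac=frac / ref_frac[:, None],
        lin_cov=cov / ref_total[:, None],
        sample_ids=list(window_stats.sample_ids),
    )


# ---------------------------------------------------------------------------
# batched logistic LRT
# ---------------------------------------------------------------------------

def _batched_logistic_ll(
    x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihoods of per-window logistic fits.

    ``x`` has shape (W, n, k); a tiny ridge stabilises collinear designs
    (constant windows) without perturbing the likelihood. Returns
    (loglik (W,), converged (W,) bool).
    """
    w_n, n, k = x.shape
    y = y[None, :]
    beta = np.zeros((w_n, k))
    eye = np.eye(k) * _RIDGE_STABILISER
    ll = np.full(w_n, -np.inf)
    converged = np.zeros(w_n, dtype=bool)
    active = np.ones(w_n, dtype=bool)
    for _ in range(max_iter):
        xa = x[active]
        ba = beta[active]
        eta = np.clip(np.einsum("wnk,wk->wn", xa, ba), -30.0, 30.0)
        mu = _sigmoid(eta)
        wgt = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.einsum("wnk,wn->wk", xa, y - mu)
        hess = np.einsum("wnk,wn,wnj->wkj", xa, wgt, xa) + eye
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                hess.reshape(-1, k), grad.reshape(-1, 1), rcond=None
            )[0].reshape(-1, k)
        ba = ba + step
        eta = np.clip(np.einsum("wnk,wk->wn", xa, ba), -30.0, 30.0)
        new_ll = np.sum(y * eta - np.log1p(np.exp(eta)), axis=1)
        done = np.abs(new_ll - ll[active]) < tol * (np.abs(new_ll) + 1.0)
        beta[active] = ba
        ll[active] = new_ll
        idx = np.where(active)[0]
        converged[idx[done]] = True
        active[idx[done]] = False
        if not active.any():
            break
    return ll, converged


def _single_logistic_ll(x_cols: list[np.ndarray], y: np.ndarray) -> float:
    """Log-likelihood of one logistic fit (intercept + given columns)."""
    n = y.size
    design = np.column_stack([np.ones(n)] + x_cols)[None, :, :]
    ll, _ = _batched_logistic_ll(design, y.astype(float), max_iter=200)
    return float(ll[0])


def _log_fc(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log2 fold change of per-window group means, shared-epsilon shifted."""
    mean_a = values[~y].mean(axis=0)
    mean_b = values[y].mean(axis=0)
    nonzero = np.concatenate([mean_a[mean_a > 0], mean_b[mean_b > 0]])
    eps = 0.5 * nonzero.min() if nonzero.size else 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2((mean_b + eps) / (mean_a + eps))


def dmr_lrt(
    features: WindowFeatures,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full-vs-null logistic likelihood-ratio test per window.

    ``labels`` is the binary per-sample outcome; ``covariates`` may hold
    ``fetal_sex`` (coded as XX/XY or numeric) and ``ff`` columns shared by
    both models. The two window features carry df = 2.
    """
    y = np.asarray(labels)
    if y.dtype != bool:
        y = y.astype(bool)
    if y.size != len(features.sample_ids):
        raise ValueError("labels length must match the feature samples")
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need at least 3 samples per class")
    yf = y.astype(float)

    cov_cols: list[np.ndarray] = []
    sex_col: np.ndarray | None = None
    if covariates is not None:
        covariates = covariates.copy()
        if "fetal_sex" in covariates:
            sex = covariates["fetal_sex"]
            if sex.dtype == object:
                sex = sex.map({"XX": 0.0, "XY": 1.0})
            if sex.isna().any():
                raise ValueError("fetal sex missing for some samples")
            sex_col = sex.to_numpy(float)
        for c in covariates.columns:
            if c == "fetal_sex":
                continue
            vals = covariates[c].to_numpy(float)
            if np.isnan(vals).any():
                raise ValueError(f"covariate {c!r} missing for some samples")
            cov_cols.append(vals)

    n = y.size
    w_n = features.n_windows
    f1 = features.norm_cov.T       # (W, n)
    f2 = features.norm_frac.T

    def full_design(with_sex: bool) -> np.ndarray:
        extra = list(cov_cols) + ([sex_col] if with_sex and sex_col is not None else [])
        k = 3 + len(extra)
        x = np.empty((w_n, n, k))
        x[:, :, 0] = 1.0
        x[:, :, 1] = f1
        x[:, :, 2] = f2
        for j, col in enumerate(extra):
            x[:, :, 3 + j] = col[None, :]
        return x

    has_sex = sex_col is not None
    ll_null_with = _single_logistic_ll(
        cov_cols + ([sex_col] if has_sex else []), yf
    )
    ll_full, conv = _batched_logistic_ll(full_design(with_sex=has_sex), yf)
    used_sex = np.full(w_n, has_sex)
    ll_null = np.full(w_n, ll_null_with)
    if has_sex and not conv.all():
        # retry non-convergent windows without fetal sex; the null drops it
        # too so the test keeps df = 2
        retry = ~conv
        ll_null_wo = _single_logistic_ll(list(cov_cols), yf)
        x_wo = full_design(with_sex=False)[retry]
        ll2, conv2 = _batched_logistic_ll(x_wo, yf)
        ll_full[retry] = ll2
        conv[retry] = conv2
        used_sex[retry] = False
        ll_null[retry] = ll_null_wo

    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    p = stats.chi2.sf(lrt, df=2)
    p[~conv] = np.nan
    return pd.DataFrame(
        {
            "chrom": features.chrom,
            "start": features.start,
            "end": features.end,
            "n_cg": features.n_cg,
            "lrt": lrt,
            "p": p,
            "converged": conv,
            "used_sex": used_sex,
            "logFC_cov": _log_fc(features.lin_cov, y),
            "logFC_frac": _log_fc(features.norm_frac, y),
        }
    )


# ---------------------------------------------------------------------------
# multiple testing and DMR-set statistics
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with NA passthrough."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[valid] = out
    return q


@dataclass
class OverlapResult:
    overlap: set
    table: tuple[int, int, int, int]    # (in both, A only, B only, neither)
    odds_ratio: float
    p: float
    haldane_corrected: bool


def intersect_dmr_sets(set_a, set_b, universe) -> OverlapResult:
    """Overlap of two DMR sets within a window universe.

    The 2x2 table classifies every universe window by membership in A and B;
    the sample odds ratio ad/bc gets a 0.5 Haldane correction (flagged) when
    any cell is zero, and p is Fisher's exact two-sided probability.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    u = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("DMR sets must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - n11 - n10 - n01
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    cells = (n11, n10, n01, n00)
    if 0 in cells:
        oh = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
        return OverlapResult(a & b, cells, float(oh), float(p), True)
    return OverlapResult(a & b, cells, n11 * n00 / (n10 * n01), float(p), False)


def dmr_effect_concordance(delta_a: np.ndarray, delta_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of per-window effect sizes between two contrasts."""
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 aligned windows")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("effect concordance undefined: zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def dmr_positional_ks(positions_a: np.ndarray, positions_b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS test of DMR genomic positions (asymptotic p)."""
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 positions per set")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def per_dmr_cv_auc(
    features: WindowFeatures,
    is_t21: np.ndarray,
    window_indices: np.ndarray | None = None,
    prior_scale: float = 2.5,
) -> np.ndarray:
    """Leave-one-out AUC of a per-window penalised logistic classifier.

    Each window's classifier uses its normalised CG-coverage and CG-fraction
    as predictors under a weakly-informative Gaussian prior (SD
    ``prior_scale`` on standardised coefficients), in the spirit of the
    Bayesian GLMs used for per-region karyotype scoring. Windows with
    AUC = 1 are the discriminatory ones.
    """
    y = np.asarray(is_t21, dtype=bool)
    if y.all() or not y.any() or y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("both classes need at least 2 members")
    idx = (np.arange(features.n_windows) if window_indices is None
           else np.asarray(window_indices))
    penalty = 1.0 / (2.0 * prior_scale**2)
    n = y.size
    out = np.empty(idx.size)
    for j, w in enumerate(idx):
        x = np.column_stack([features.norm_cov[:, w], features.norm_frac[:, w]])
        probs = np.empty(n)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            model = ridge_logistic_fit(x[keep], y[keep], penalty=penalty)
            probs[i] = ridge_logistic_predict(model, x[i][None, :])[0]
        out[j] = roc_auc_score(y, probs)
    return out
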