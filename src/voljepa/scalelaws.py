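"""Label-efficiency and robustness statistics.

Implements the evaluation statistics used around the frozen-feature probes:
Platt calibration of probe logits, log-linear scaling fits of F1 against
log10 of the number of positive training examples (OLS with HC3
heteroskedasticity-consistent standard errors), ANCOVA slope-equality tests
between encoders, the label-equivalence fold (how many times more positives
a baseline needs to match a reference encoder at fixed F1), subgroup ΔAUC
with a CI-separation index, and min-normalized label co-occurrence.

AUROC uses the midrank (ties count one half) convention throughout; all
bootstrap confidence intervals are seed-deterministic percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

__all__ = ["auroc", "PlattCalibrator", "platt_calibrate", "ScalingFit",
           "fit_scaling", "ancova_slopes", "equivalence_fold",
           "EquivalenceResult", "label_equivalence", "SubgroupResult",
           "subgroup_delta_auc", "CoocMatrix", "cooccurrence",
           "logit_label_auc_matrix", "hierarchical_order", "f1_at_threshold"]

EQUIVALENCE_BAND = 0.05
MIN_TRAIN_POS = 30
MIN_TEST_POS = 10


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUROC with midrank tie handling."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes")
    r = rankdata(s)  # midranks
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ------------------------------------------------------------------- Platt

@dataclass
class PlattCalibrator:
    """sigmoid(a·logit + b) fitted by ridge-penalized maximum likelihood."""

    ridge: float = 1e-6
    slope_: float = field(default=np.nan, init=False)
    intercept_: float = field(default=np.nan, init=False)

    def fit(self, logits, labels) -> "PlattCalibrator":
        z = np.asarray(logits, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float64)
        if y.min() == y.max():
            raise ValueError("Platt scaling needs both classes present")

        def nll(theta):
            a, b = theta
            u = a * z + b
            # softplus(u) - u*y, numerically stable
            val = (np.maximum(u, 0) + np.log1p(np.exp(-np.abs(u))) - u * y).sum()
            val += 0.5 * self.ridge * (a * a + b * b)
            sig = 1.0 / (1.0 + np.exp(-u))
            g = sig - y
            return val, np.array([(g * z).sum() + self.ridge * a,
                                  g.sum() + self.ridge * b])

        res = minimize(nll, x0=np.array([1.0, 0.0]), jac=True, method="BFGS")
        self.slope_, self.intercept_ = float(res.x[0]), float(res.x[1])
        return self

    def transform(self, logits) -> np.ndarray:
        z = np.asarray(logits, dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-(self.slope_ * z + self.intercept_)))


def platt_calibrate(logits, labels) -> PlattCalibrator:
    return PlattCalibrator().fit(logits, labels)


def f1_at_threshold(probs, labels, threshold: float = 0.5) -> float:
    """F1 at a fixed probability threshold (0.5 after calibration)."""
    p = np.asarray(probs) >= threshold
    y = np.asarray(labels).astype(bool)
    tp = int((p & y).sum())
    denom = 2 * tp + int((p & ~y).sum()) + int((~p & y).sum())
    return 2 * tp / denom if denom else 0.0


# ------------------------------------------------------------ scaling fits

@dataclass
class ScalingFit:
    """Per-encoder OLS of F1 on log10(n_pos) with HC3 standard errors."""

    per_encoder: dict  # encoder -> dict(slope, intercept, slope_se, ...)
    points: pd.DataFrame  # rows used after the inclusion filters
    n_excluded: int


def _filter_points(df: pd.DataFrame, min_train_pos: int,
                   min_test_pos: int) -> tuple[pd.DataFrame, int]:
    keep = df["n_pos"] >= min_train_pos
    if "n_pos_test" in df.columns:
        keep &= df["n_pos_test"] >= min_test_pos
    return df[keep].copy(), int((~keep).sum())


def fit_scaling(points: pd.DataFrame, min_train_pos: int = MIN_TRAIN_POS,
                min_test_pos: int = MIN_TEST_POS,
                modality_effects: bool = False) -> ScalingFit:
    """``points`` columns: encoder, class, f1, n_pos (train positives) and
    optionally n_pos_test, modality. Classes under the positive-count
    filters are excluded before fitting."""
    import statsmodels.formula.api as smf

    df = points.copy()
    if "encoder" not in df.columns:
        df["encoder"] = "model"
    df, n_excl = _filter_points(df, min_train_pos, min_test_pos)
    per = {}
    for enc, sub in df.groupby("encoder"):
        if len(sub) < 3:
            raise ValueError(f"encoder {enc!r}: need >= 3 classes after filters")
        sub = sub.assign(log_n=np.log10(sub["n_pos"]))
        formula = "f1 ~ log_n"
        if modality_effects and "modality" in sub.columns \
                and sub["modality"].nunique() > 1:
            formula += " + C(modality) + C(modality):log_n"
        res = smf.ols(formula, data=sub).fit(cov_type="HC3")
        per[enc] = dict(slope=float(res.params["log_n"]),
                        intercept=float(res.params["Intercept"]),
                        slope_se=float(res.bse["log_n"]),
                        intercept_se=float(res.bse["Intercept"]),
                        slope_ci=tuple(res.conf_int().loc["log_n"]),
                        n_classes=len(sub), result=res)
    return ScalingFit(per_encoder=per, points=df, n_excluded=n_excl)


def ancova_slopes(points: pd.DataFrame, alpha: float = 0.05,
                  min_train_pos: int = MIN_TRAIN_POS,
                  min_test_pos: int = MIN_TEST_POS) -> dict:
    """Test encoder×log10(n_pos) slope equality; when the interaction is
    non-significant at ``alpha``, report the shared slope from the pooled
    additive model."""
    import statsmodels.formula.api as smf

    df, _ = _filter_points(points.copy(), min_train_pos, min_test_pos)
    encoders = sorted(df["encoder"].unique())
    if len(encoders) < 2:
        raise ValueError("ANCOVA needs at least two encoders")
    df = df.assign(log_n=np.log10(df["n_pos"]))
    full = smf.ols("f1 ~ log_n * C(encoder)", data=df).fit()
    inter = [n for n in full.params.index
             if ("log_n:" in n or ":log_n" in n) and n != "log_n"]
    if not inter:
        raise ValueError("rank-deficient design: no interaction terms")
    p = float(full.f_test(", ".join(f"{n} = 0" for n in inter)).pvalue)
    pooled = smf.ols("f1 ~ log_n + C(encoder)", data=df).fit(cov_type="HC3")
    shared = p >= alpha
    out = dict(shared_slope_decision=shared, p_interaction=p, alpha=alpha,
               shared_slope=float(pooled.params["log_n"]),
               intercepts={}, encoders=encoders)
    base = encoders[0]
    for enc in encoders:
        ic = float(pooled.params["Intercept"])
        if enc != base:
            ic += float(pooled.params.get(f"C(encoder)[T.{enc}]", 0.0))
        out["intercepts"][enc] = ic
    if not shared:
        out["slopes"] = {enc: float(full.params["log_n"]) if enc == base else
                         float(full.params["log_n"]
                               + full.params.get(f"log_n:C(encoder)[T.{enc}]", 0.0))
                         for enc in encoders}
    return out


def equivalence_fold(intercept_ref: float, intercept_base: float,
                     slope: float) -> float:
    """fold = 10^((intercept_ref − intercept_base) / slope); slope must be
    positive for the fold to be defined."""
    if slope <= 0:
        raise ValueError("shared slope must be positive")
    return float(10.0 ** ((intercept_ref - intercept_base) / slope))


@dataclass
class EquivalenceResult:
    fold: float
    ci: tuple[float, float]
    shared_slope: float
    n_boot: int

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if not self.ci[0] <= self.fold <= self.ci[1]:
            raise ValueError("CI must contain the point estimate")


def _intercept_given_slope(f1, log_n, slope) -> float:
    return float(np.mean(np.asarray(f1) - slope * np.asarray(log_n)))


def label_equivalence(points_ref, points_base, shared_slope: float,
                      n_boot: int = 10_000, seed: int = 0) -> EquivalenceResult:
    """Fold-increase in positives the baseline needs to match the reference
    at fixed F1, with a class-level bootstrap CI.

    ``points_ref`` / ``points_base`` are (n, 2) arrays of (f1, n_pos) per
    class. When the two encoders share a class set (equal lengths), the
    bootstrap resamples classes in a paired fashion, so an encoder compared
    with itself yields fold = 1 in every replicate.
    """
    ref = np.asarray(points_ref, dtype=np.float64)
    base = np.asarray(points_base, dtype=np.float64)
    lr, lb = np.log10(ref[:, 1]), np.log10(base[:, 1])
    fold = equivalence_fold(_intercept_given_slope(ref[:, 0], lr, shared_slope),
                            _intercept_given_slope(base[:, 0], lb, shared_slope),
                            shared_slope)
    rng = np.random.default_rng(seed)
    paired = len(ref) == len(base)
    folds = np.empty(n_boot)
    for b in range(n_boot):
        i = rng.integers(0, len(ref), size=len(ref))
        j = i if paired else rng.integers(0, len(base), size=len(base))
        folds[b] = equivalence_fold(
            _intercept_given_slope(ref[i, 0], lr[i], shared_slope),
            _intercept_given_slope(base[j, 0], lb[j], shared_slope),
            shared_slope)
    lo, hi = np.percentile(folds, [2.5, 97.5])
    return EquivalenceResult(fold=fold, ci=(min(lo, fold), max(hi, fold)),
                             shared_slope=shared_slope, n_boot=n_boot)


# -------------------------------------------------------------- subgroups

@dataclass
class SubgroupResult:
    group: object
    delta: float  # Δg = AUC_g − AUC_all
    ci: tuple[float, float]
    separation_index: float  # S = |Δg| / CI half-width
    within_band: bool
    n_pos: int
    n_neg: int


def subgroup_delta_auc(preds, labels, groups, n_boot: int = 10_000,
                       seed: int = 0, band: float = EQUIVALENCE_BAND,
                       min_pos: int = 10, min_neg: int = 10,
                       ) -> tuple[list[SubgroupResult], dict]:
    """Per-subgroup AUC differential vs the full test set with paired
    study-level bootstrap percentile CIs.

    Returns (results, skipped) where ``skipped`` maps ineligible subgroup
    ids (fewer than ``min_pos`` positives or ``min_neg`` negatives) to the
    reason.
    """
    p = np.asarray(preds, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    g = np.asarray(groups)
    auc_all = auroc(y, p)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    results, skipped = [], {}
    for grp in pd.unique(g):
        sel = g == grp
        n_pos, n_neg = int(y[sel].sum()), int((1 - y[sel]).sum())
        if n_pos < min_pos or n_neg < min_neg:
            skipped[grp] = f"ineligible: {n_pos} positives / {n_neg} negatives"
            continue
        delta = auroc(y[sel], p[sel]) - auc_all
        reps = []
        for b in range(n_boot):
            idx = boot_idx[b]
            ys, ps, gs = y[idx], p[idx], sel[idx]
            if ys.min() == ys.max() or not gs.any():
                continue
            yg, pg = ys[gs], ps[gs]
            if yg.min() == yg.max():
                continue
            reps.append(auroc(yg, pg) - auroc(ys, ps))
        if reps:
            lo, hi = np.percentile(reps, [2.5, 97.5])
        else:
            lo = hi = delta
        half = (hi - lo) / 2.0
        s = 0.0 if delta == 0 and half == 0 else \
            (np.inf if half == 0 else abs(delta) / half)
        results.append(SubgroupResult(
            group=grp, delta=float(delta), ci=(float(lo), float(hi)),
            separation_index=float(s),
            within_band=bool(-band <= lo and hi <= band),
            n_pos=n_pos, n_neg=n_neg))
    return results, skipped


# ----------------------------------------------------------- co-occurrence

@dataclass
class CoocMatrix:
    matrix: np.ndarray  # (K, K), symmetric, diagonal 1 for nonempty labels
    label_counts: np.ndarray
    flagged_empty: list


def cooccurrence(label_matrix: np.ndarray) -> CoocMatrix:
    """Min-normalized co-occurrence M_ij = |i∩j| / min(|i|, |j|); cells
    touching an empty label are 0 and flagged."""
    lab = np.asarray(label_matrix).astype(bool)
    counts = lab.sum(axis=0)
    inter = (lab.T.astype(np.int64) @ lab.astype(np.int64)).astype(np.float64)
    mins = np.minimum.outer(counts, counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(mins > 0, inter / np.maximum(mins, 1), 0.0)
    m[mins == 0] = 0.0
    return CoocMatrix(matrix=m, label_counts=counts,
                      flagged_empty=list(np.flatnonzero(counts == 0)))


def logit_label_auc_matrix(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """K×K grid: cell (i, j) is the AUROC of logit_i against label_j
    (diagonal = per-class AUROC); NaN where label_j is single-class."""
    z = np.asarray(logits, dtype=np.float64)
    lab = np.asarray(labels).astype(int)
    k = z.shape[1]
    out = np.full((k, k), np.nan)
    for j in range(k):
        if lab[:, j].min() == lab[:, j].max():
            continue
        for i in range(k):
            out[i, j] = auroc(lab[:, j], z[:, i])
    return out


def hierarchical_order(matrix: np.ndarray) -> np.ndarray:
    """Average-linkage leaf order for heatmap display (export only)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    m = np.nan_to_num(np.asarray(matrix, dtype=np.float64), nan=0.5)
    if len(m) < 3:
        return np.arange(len(m))
    return np.asarray(leaves_list(average(pdist(m))))
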