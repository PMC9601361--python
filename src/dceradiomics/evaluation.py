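"""ROC/AUC evaluation of rad-score signatures.

AUC is the Mann–Whitney concordance probability (trapezoidal ROC
integration with ties counted half); its 95% confidence interval comes
from DeLong's asymptotic variance of the placement values, with a
seeded bootstrap fallback when that variance degenerates (e.g. a
constant score).  Operating points maximize Youden's J on a deriving
cohort and are then applied, fixed, to the other cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AucResult",
    "roc_auc",
    "operating_point",
    "apply_threshold",
    "evaluate_signature",
    "render_report",
    "EvaluationReport",
]


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str  # "delong" or "bootstrap"
    n_pos: int
    n_neg: int


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return n_pos, n_neg


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted 1/2 (via midranks)."""
    pos = scores[labels == 1]
    m, n = pos.size, scores.size - pos.size
    ranks = _midrank(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC from placement-value components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # Placement values: V10_i = P(score_neg < pos_i) with ties half.
    v10 = (all_ranks[labels == 1] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[labels == 0] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_auc(
    scores,
    labels,
    alpha: float = 0.05,
    bootstrap_reps: int = 2000,
    bootstrap_seed: int = 0,
) -> AucResult:
    """AUC with a (1 − alpha) confidence interval.

    DeLong's method is the default; when its variance estimate is zero
    (degenerate score distributions) the CI falls back to a seeded
    stratified bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(labels)
    auc = _auc_point(scores, labels)
    var = _delong_variance(scores, labels)
    if var > 0:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * np.sqrt(var)
        return AucResult(auc, max(0.0, auc - half), min(1.0, auc + half),
                         "delong", n_pos, n_neg)
    rng = np.random.default_rng(bootstrap_seed)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        idx = np.concatenate([
            rng.choice(pos_idx, n_pos, replace=True),
            rng.choice(neg_idx, n_neg, replace=True),
        ])
        reps[r] = _auc_point(scores[idx], labels[idx])
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(lo, auc), max(hi, auc)
    return AucResult(auc, float(lo), float(hi), "bootstrap", n_pos, n_neg)


def operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J; returns (threshold, sens, spec).

    Candidate thresholds are the distinct score values; a sample is
    called positive when score >= threshold.  J ties are broken toward
    the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    best = (-np.inf, np.inf, 0.0, 0.0)
    for thr in np.unique(scores)[::-1]:  # descending: ties keep higher thr
        sens, spec = apply_threshold(scores, labels, thr)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return best[1], best[2], best[3]


def apply_threshold(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    n_pos, n_neg = _check_classes(labels)
    sens = float((pred & (labels == 1)).sum() / n_pos)
    spec = float((~pred & (labels == 0)).sum() / n_neg)
    return sens, spec


def evaluate_signature(
    model,
    std_df: pd.DataFrame,
    labels,
    train_idx,
    val_idx,
    threshold_per_cohort: bool = False,
) -> list[dict]:
    """Train/validation ROC rows for one fitted rad-score model.

    By default the Youden threshold derived on the training cohort is
    applied unchanged to the validation cohort; with
    ``threshold_per_cohort`` each cohort re-optimizes its own.
    """
    labels = np.asarray(labels, dtype=int)
    rows = []
    scores_all = model.rad_score(std_df).to_numpy()
    thr_train = None
    for cohort, idx in (("training", np.asarray(train_idx, dtype=int)),
                        ("validation", np.asarray(val_idx, dtype=int))):
        s, y = scores_all[idx], labels[idx]
        res = roc_auc(s, y)
        if cohort == "training" or threshold_per_cohort:
            if np.unique(s).size > 1:
                thr, sens, spec = operating_point(s, y)
            else:
                thr, (sens, spec) = float(s[0]), apply_threshold(s, y, float(s[0]))
            if cohort == "training":
                thr_train = thr
        else:
            thr = thr_train
            sens, spec = apply_threshold(s, y, thr)
        rows.append({
            "endpoint": model.endpoint,
            "scope": model.region_scope,
            "cohort": cohort,
            "auc": res.auc,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "sensitivity": sens,
            "specificity": spec,
            "threshold": thr,
            "n_pos": res.n_pos,
            "n_neg": res.n_neg,
        })
    return rows


@dataclass
class EvaluationReport:
    """2 endpoints x 3 scopes x 2 cohorts grid of ROC summaries."""

    table: pd.DataFrame

    def cell(self, endpoint: str, scope: str, cohort: str) -> dict:
        sub = self.table[
            (self.table.endpoint == endpoint)
            & (self.table.scope == scope)
            & (self.table.cohort == cohort)
        ]
        if len(sub) != 1:
            raise KeyError((endpoint, scope, cohort))
        return sub.iloc[0].to_dict()

    def to_json(self) -> str:
        return json.dumps(
            {"cells": self.table.to_dict(orient="records")}, indent=2
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def render_report(
    endpoint_results: dict,
    labels_df: pd.DataFrame,
    figures_dir=None,
    threshold_per_cohort: bool = False,
) -> EvaluationReport:
    """Evaluate every (endpoint, scope) signature on both cohorts.

    ``endpoint_results`` maps endpoint name ('er'/'pr') to an
    :class:`~dceradiomics.selection.EndpointResult`; ``labels_df`` has
    ``{endpoint}_label`` columns aligned with the feature-table rows.
    When ``figures_dir`` is given, ROC overlays and rad-score
    distribution plots are written there as PNG.
    """
    rows = []
    for endpoint, result in endpoint_results.items():
        y = labels_df[f"{endpoint}_label"].to_numpy()
        for scope in ("intra", "peri", "multi"):
            rows.extend(
                evaluate_signature(
                    result.models[scope], result.table.df, y,
                    result.train_idx, result.val_idx,
                    threshold_per_cohort=threshold_per_cohort,
                )
            )
    report = EvaluationReport(pd.DataFrame(rows))
    if figures_dir is not None:
        _write_figures(endpoint_results, labels_df, report, figures_dir)
    return report


def _write_figures(endpoint_results, labels_df, report, figures_dir) -> None:
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    outdir = pathlib.Path(figures_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for endpoint, result in endpoint_results.items():
        y = labels_df[f"{endpoint}_label"].to_numpy()
        for cohort, idx in (("training", result.train_idx),
                            ("validation", result.val_idx)):
            fig, ax = plt.subplots(figsize=(5, 5))
            for scope in ("intra", "peri", "multi"):
                scores = result.models[scope].rad_score(result.table.df).to_numpy()
                s, yy = scores[idx], y[idx]
                cell = report.cell(endpoint, scope, cohort)
                if np.unique(s).size > 1:
                    fpr, tpr, _ = roc_curve(yy, s)
                else:
                    fpr, tpr = [0, 1], [0, 1]
                ax.plot(fpr, tpr, label=f"{scope} RS (AUC {cell['auc']:.3f})")
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            ax.set_title(f"{endpoint.upper()} status, {cohort} set")
            ax.legend(loc="lower right", fontsize=8)
            fig.tight_layout()
            fig.savefig(outdir / f"roc_{endpoint}_{cohort}.png", dpi=120)
            plt.close(fig)

        # Rad-score distributions (multiregional signature).
        scores = result.models["multi"].rad_score(result.table.df).to_numpy()
        fig, ax = plt.subplots(figsize=(6, 4))
        for lab, color in ((0, "tab:blue"), (1, "tab:red")):
            ax.hist(scores[y == lab], bins=25, alpha=0.6, color=color,
                    label=f"{endpoint.upper()} {'positive' if lab else 'negative'}")
        ax.set_xlabel("multiregional rad-score")
        ax.set_ylabel("patients")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"radscore_{endpoint}.png", dpi=120)
        plt.close(fig)
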