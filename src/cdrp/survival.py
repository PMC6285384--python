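"""Embedding-based patient stratification and survival comparison.

Hidden-layer activations of a trained prognostic network are clustered
(agglomerative, Ward linkage, 1 − Spearman correlation between patients'
embedding vectors as dissimilarity, dendrogram cut at k = 3), and the
resulting strata are compared by Kaplan-Meier curves and the log-rank test,
optionally reweighted by inverse probability weights (IPW) estimated from a
multinomial propensity model on clinical confounders.

Ward linkage on a non-Euclidean dissimilarity is formally improper; the
update rule is applied directly to the 1 − Spearman matrix anyway, the
common permissive behaviour of hierarchical-clustering implementations —
the caveat is documented, the result is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2, rankdata

from .cohort import ClinicalTable
from .nets import EmbeddingMatrix

__all__ = [
    "ClusteringConfig", "SurvivalCurve", "cluster_embedding",
    "spearman_dissimilarity", "km_estimate", "logrank", "ipw_adjust",
    "correctness_by_stage",
]


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 3
    linkage: str = "ward"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least k = 2 clusters")


def spearman_dissimilarity(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Spearman correlation between sample rows.

    A constant row has undefined rank correlation and is treated as
    maximally dissimilar (distance 1) to every other sample, with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ranks = np.vstack([rankdata(row) for row in values])
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant embedding row(s); "
            "treated as maximally dissimilar", stacklevel=2)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * ranks.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (centered @ centered.T) / denom
    d = 1.0 - rho
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical symmetry for squareform
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def cluster_embedding(e: EmbeddingMatrix | np.ndarray,
                      cfg: ClusteringConfig | None = None) -> dict:
    """Ward agglomerative clustering on the 1 − Spearman dissimilarity.

    Returns ``{"labels": 1..k array, "dendrogram": scipy linkage matrix}``.
    Labels are renumbered by order of first appearance, so the assignment is
    deterministic for fixed input.
    """
    cfg = cfg or ClusteringConfig()
    values = e.values if isinstance(e, EmbeddingMatrix) else np.asarray(e, float)
    n = values.shape[0]
    if n < cfg.k:
        raise ValueError(f"{n} samples cannot form {cfg.k} clusters")
    if not np.all(np.isfinite(values)):
        raise ValueError("embedding contains non-finite values")
    if cfg.k == n:
        return {"labels": np.arange(1, n + 1), "dendrogram": None}
    d = spearman_dissimilarity(values)
    Z = linkage(squareform(d, checks=False), method=cfg.linkage)
    raw = fcluster(Z, t=cfg.k, criterion="maxclust")
    remap, labels = {}, np.zeros(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[i] = remap[c]
    if len(remap) < cfg.k:
        raise ValueError("dendrogram cut produced fewer than k nonempty groups")
    return {"labels": labels, "dendrogram": Z}


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank (weighted product-limit, IPW-compatible)


@dataclass
class SurvivalCurve:
    """Product-limit estimate reported at each distinct observed time."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, weights=None) -> SurvivalCurve:
    """Kaplan-Meier estimator, optionally with per-sample weights.

    With unit weights this is the classical product-limit estimator; with
    IPW weights the risk sets and event counts are weighted sums.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative survival times")
    w = np.ones_like(times) if weights is None else np.asarray(weights, float)
    order = np.argsort(times, kind="stable")
    times, events, w = times[order], events[order], w[order]
    uniq = np.unique(times)
    surv, n_at, d_at = [], [], []
    s = 1.0
    for t in uniq:
        at_risk = w[times >= t].sum()
        d = w[(times == t) & (events == 1)].sum()
        if at_risk > 0 and d > 0:
            s *= 1.0 - d / at_risk
        n_at.append(at_risk)
        d_at.append(d)
        surv.append(s)
    return SurvivalCurve(uniq, np.array(n_at), np.array(d_at), np.array(surv))


def logrank(groups, times, events, weights=None) -> dict:
    """Log-rank test across g ≥ 2 groups (chi-square, g − 1 df).

    Supports a weighted variant for IPW-adjusted comparisons: observed and
    expected event counts use weighted risk sets (no variance correction for
    the estimated weights; p-values under IPW are approximate).
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    w = np.ones_like(times) if weights is None else np.asarray(weights, float)
    labels = np.unique(groups)
    g = labels.size
    if g < 2:
        raise ValueError("log-rank needs at least two groups")
    for lab in labels:
        if np.sum(groups == lab) == 0:  # pragma: no cover - unique() excludes
            raise ValueError(f"empty group {lab!r}")
    event_times = np.unique(times[events == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in event_times:
        at = times >= t
        n_t = w[at].sum()
        d_t = w[(times == t) & (events == 1)].sum()
        if n_t <= 0:
            continue
        n_i = np.array([w[at & (groups == lab)].sum() for lab in labels])
        d_i = np.array([
            w[(times == t) & (events == 1) & (groups == lab)].sum()
            for lab in labels])
        O += d_i
        E += d_t * n_i / n_t
        if n_t > 1:
            frac = n_i / n_t
            scale = d_t * (n_t - d_t) / (n_t - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    p = float(chi2.sf(stat, df=g - 1))
    return {"statistic": stat, "df": g - 1, "p": p,
            "observed": O, "expected": E}


# ---------------------------------------------------------------------------
# inverse probability weighting


def ipw_adjust(clinical: ClinicalTable, group_labels,
               confounders=("gender",), stabilized: bool = True,
               truncate_quantile: float = 0.99, seed: int = 0) -> np.ndarray:
    """Stabilized inverse-probability-of-group weights.

    A multinomial logistic propensity model P(group | confounders) is fit
    (categorical confounders one-hot encoded, age standardized); weights are
    w_i = P(group_i) / P̂(group_i | x_i) when stabilized.  Near-separation
    (propensities under 1e-3) triggers a warning and quantile truncation.
    """
    from sklearn.linear_model import LogisticRegression

    group_labels = np.asarray(group_labels)
    df = clinical.data
    cols = []
    for c in confounders:
        key = {"age": "age_days"}.get(c, c)
        if key not in df.columns:
            raise ValueError(f"confounder {c!r} absent from the clinical table")
        if key == "age_days":
            v = pd.to_numeric(df[key], errors="coerce").to_numpy(float)
            v = np.where(np.isnan(v), np.nanmean(v), v)
            sd = v.std() or 1.0
            cols.append(((v - v.mean()) / sd)[:, None])
        else:
            dummies = pd.get_dummies(df[key].astype(str), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
    X = np.hstack(cols) if cols else np.zeros((len(df), 0))
    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(X, group_labels)
    probs = model.predict_proba(X)
    class_index = {c: j for j, c in enumerate(model.classes_)}
    p_own = np.array([probs[i, class_index[gl]]
                      for i, gl in enumerate(group_labels)])
    marginal = np.array([
        np.mean(group_labels == gl) for gl in group_labels])
    w = (marginal if stabilized else 1.0) / p_own
    if (p_own < 1e-3).any():
        warnings.warn("near-separation in the propensity model; "
                      "weights truncated", stacklevel=2)
        w = np.minimum(w, np.quantile(w, truncate_quantile))
    return w


# ---------------------------------------------------------------------------
# per-stage classification summaries


def correctness_by_stage(dap_result, clinical: ClinicalTable) -> pd.DataFrame:
    """Percent correct classification per INSS stage across the CV repeats.

    For each stage: mean over its samples of (correct count / repeats),
    scaled to percent.  Stages with no samples are skipped.
    """
    ps = dap_result.per_sample_correct
    merged = ps.merge(clinical.data[["sample_id", "inss"]], on="sample_id",
                      how="left")
    rows = []
    for stage in ("1", "2", "3", "4", "4S"):
        sub = merged[merged["inss"] == stage]
        if sub.empty:
            continue
        pct = float((sub["correct"] / sub["n_repeats"]).mean() * 100.0)
        rows.append({"inss": stage, "n": len(sub), "pct_correct": pct})
    return pd.DataFrame(rows)
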