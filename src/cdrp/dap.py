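"""MAQC-style Data Analysis Protocol (DAP).

Repeated stratified cross-validation (10 × 5-fold by default) with strictly
fold-internal preprocessing: within every fold the expression matrix is
standardized with parameters fit on the fold-training portion, genes are
ranked by one-way ANOVA F-score against the task label on that same portion,
the top-k genes are selected over a small grid of k, the classifier is
trained, and the held-out fold is scored by the Matthews Correlation
Coefficient (MCC).  The best k (smallest k attaining the maximal median
fold MCC) selects the final model, which is retrained on the whole training
set and applied unchanged to an external validation set.  Selection-bias
sanity checks rerun the whole protocol with scrambled labels or randomly
chosen features.  Per-fold MCCs get 95% studentized-bootstrap confidence
intervals, and per-sample correct-classification counts across the repeats
are tallied for downstream stage-wise summaries.

The classifier is pluggable: any object with ``fit(X, labels_dict)`` and
``predict(X) -> {task: hard_labels}``.  Adapters are provided for the CDRP
networks and for ordinary scikit-learn classifiers (the linear-SVM and
random-forest comparators).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import (ClinicalTable, ExpressionMatrix, SplitSpec,
                     apply_standardizer, fit_standardizer)
from .nets import (CDRPMultiTask, MultiTaskSpec, TrainingConfig,
                   autoencoder_input_dim, train_autoencoder)

__all__ = [
    "ConfusionMatrix", "FeatureRanking", "DAPConfig", "DAPResult",
    "mcc", "confusion_from_labels", "anova_f_rank", "stratified_folds",
    "run_dap", "random_label_check", "random_feature_check", "bootstrap_ci",
    "select_split", "external_validate",
    "CDRPEstimator", "SklearnTaskEstimator",
]

TASKS = ("efs", "os", "efs_hr", "os_hr")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positives = label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_labels(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc(c: ConfusionMatrix) -> float:
    """Matthews Correlation Coefficient.

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a factor-zero
    denominator (one predicted or true class absent) is mapped to 0 by
    convention.
    """
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class FeatureRanking:
    """Gene ids ordered by decreasing ANOVA F-score (ties: lexicographic)."""

    gene_ids: list
    scores: np.ndarray

    def top(self, k) -> list:
        if k in (None, "all"):
            return list(self.gene_ids)
        return list(self.gene_ids[:k])


def anova_f_rank(x: ExpressionMatrix | np.ndarray, y,
                 gene_ids=None) -> FeatureRanking:
    """Rank genes by one-way ANOVA F against a binary label.

    Constant genes (zero between- and within-group variance) get F = 0.
    """
    if isinstance(x, ExpressionMatrix):
        X, gene_ids = x.values, list(x.gene_ids)
    else:
        X = np.asarray(x, dtype=float)
        gene_ids = list(gene_ids) if gene_ids is not None \
            else [str(j) for j in range(X.shape[1])]
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ANOVA ranking needs both classes present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features produce 0/0
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    order = sorted(range(len(gene_ids)), key=lambda j: (-F[j], gene_ids[j]))
    return FeatureRanking([gene_ids[j] for j in order], F[order])


def stratified_folds(y, n_folds: int, repeats: int, seed: int):
    """Repeated stratified partitions: repeats × [(train_idx, test_idx)]."""
    y = np.asarray(y, dtype=int)
    for c in np.unique(y):
        if np.sum(y == c) < n_folds:
            raise ValueError(
                f"class {c} has fewer samples than n_folds={n_folds}")
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed + r) % (2**32))
        out.append([(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)])
    return out


# ---------------------------------------------------------------------------
# estimator adapters


class SklearnTaskEstimator:
    """Wrap a scikit-learn classifier to the DAP estimator protocol.

    The same fitted model answers for both endpoints of a fold when only one
    is scored; pass ``task`` to choose which label it trains on.
    """

    def __init__(self, base, task: str = "efs"):
        self.base = base
        self.task = task

    def fit(self, X, labels: dict):
        self.base.fit(X, np.asarray(labels[self.task], dtype=int))
        return self

    def predict(self, X) -> dict:
        pred = self.base.predict(X)
        return {self.task: np.asarray(pred, dtype=int)}


class CDRPEstimator:
    """CDRP networks behind the DAP protocol.

    With ``use_embedding`` the estimator first selects the top ⌈2%⌉ of the
    supplied features by ANOVA F-score against the High-Risk label, trains
    the autoencoder unsupervised on them, and feeds the 64-dim code to the
    multi-task net's merge layer (the CDRP-A+CDRP-N configuration); without
    it, the multi-task net alone is trained (CDRP-N).
    """

    def __init__(self, use_embedding: bool = True,
                 cfg: TrainingConfig | None = None, seed: int = 0):
        self.use_embedding = use_embedding
        self.cfg = cfg or TrainingConfig()
        self.seed = seed
        self.model: CDRPMultiTask | None = None
        self.ae = None
        self._ae_cols = None

    def _embed(self, X):
        return self.ae.encode_values(X[:, self._ae_cols])

    def fit(self, X, labels: dict):
        X = np.asarray(X, dtype=float)
        emb = None
        if self.use_embedding:
            if "hr" not in labels:
                raise ValueError("CDRP-A needs the High-Risk label")
            hr = np.asarray(labels["hr"], dtype=int)
            if len(np.unique(hr)) >= 2:
                rank = anova_f_rank(X, hr)
                k = autoencoder_input_dim(X.shape[1])
                self._ae_cols = np.sort([int(g) for g in rank.top(k)])
            else:
                # HR-restricted task: all samples high-risk, the diagnostic
                # signal has no contrast — fall back to top-variance genes
                k = autoencoder_input_dim(X.shape[1])
                var = X.var(axis=0)
                self._ae_cols = np.sort(np.argsort(-var)[:k])
            res = train_autoencoder(
                X[:, self._ae_cols],
                TrainingConfig(ae=self.cfg.ae, mt=self.cfg.mt,
                               seed=self.seed))
            self.ae = res.model
            emb = self._embed(X)
        spec = MultiTaskSpec(input_dim=X.shape[1],
                             use_embedding=self.use_embedding)
        self.model = CDRPMultiTask(spec, seed=self.seed)
        self.model.fit(X, labels["efs"], labels["os"], embedding=emb,
                       cfg=self.cfg.mt, seed=self.seed + 1)
        return self

    def predict(self, X) -> dict:
        X = np.asarray(X, dtype=float)
        emb = self._embed(X) if self.use_embedding else None
        return self.model.predict(X, emb)

    def save(self, directory) -> None:
        """Persist the fitted estimator (nets + autoencoder column map)."""
        from pathlib import Path

        import yaml

        from .nets import save_checkpoint

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_checkpoint(self.model, directory / "multitask")
        meta = {"use_embedding": self.use_embedding, "seed": self.seed}
        if self.use_embedding:
            save_checkpoint(self.ae, directory / "autoencoder")
            meta["ae_cols"] = [int(j) for j in self._ae_cols]
        with open(directory / "estimator.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "CDRPEstimator":
        from pathlib import Path

        import yaml

        from .nets import load_checkpoint

        directory = Path(directory)
        with open(directory / "estimator.yaml") as fh:
            meta = yaml.safe_load(fh)
        est = cls(use_embedding=meta["use_embedding"], seed=meta["seed"])
        est.model = load_checkpoint(directory / "multitask")
        if est.use_embedding:
            est.ae = load_checkpoint(directory / "autoencoder")
            est._ae_cols = np.asarray(meta["ae_cols"], dtype=int)
        return est


# ---------------------------------------------------------------------------
# protocol


@dataclass
class DAPConfig:
    repeats: int = 10
    folds: int = 5
    k_grid: tuple = (25, 50, 100, 250, 500, "all")
    seed: int = 0
    scheme: str = "standard"  # standard | random_label | random_feature


@dataclass
class DAPResult:
    task: str
    per_fold: pd.DataFrame          # repeat, fold, k, tp, tn, fp, fn, mcc
    best_k: object
    cv_mcc_median: float
    cv_mcc_ci: tuple
    per_sample_correct: pd.DataFrame  # sample_id, correct, n_repeats
    audit: list
    final_params: object = None
    final_genes: list | None = None
    final_model: object = None
    external: dict | None = None

    @property
    def audit_clean(self) -> bool:
        return all(all(v for k, v in entry.items()
                       if isinstance(v, (bool, np.bool_)))
                   for entry in self.audit)

    def median_mcc_by_k(self) -> pd.Series:
        return self.per_fold.groupby("k", sort=False)["mcc"].median()

    def repeat_level_medians(self) -> pd.Series:
        sel = self.per_fold[self.per_fold["k"].astype(str) == str(self.best_k)]
        return sel.groupby("repeat")["mcc"].median()

    # serialization (fitted model objects are deliberately excluded) --------

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "per_fold": self.per_fold.to_dict(orient="list"),
            "best_k": self.best_k,
            "cv_mcc_median": self.cv_mcc_median,
            "cv_mcc_ci": list(self.cv_mcc_ci),
            "per_sample_correct": self.per_sample_correct.to_dict(orient="list"),
            "audit": [
                {k: bool(v) if isinstance(v, (bool, np.bool_)) else v
                 for k, v in e.items()} for e in self.audit],
            "final_genes": self.final_genes,
            "external": self.external,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DAPResult":
        return cls(
            task=d["task"],
            per_fold=pd.DataFrame(d["per_fold"]),
            best_k=d["best_k"],
            cv_mcc_median=d["cv_mcc_median"],
            cv_mcc_ci=tuple(d["cv_mcc_ci"]),
            per_sample_correct=pd.DataFrame(d["per_sample_correct"]),
            audit=d["audit"],
            final_genes=d.get("final_genes"),
            external=d.get("external"),
        )


def _task_parts(task: str):
    task = task.lower()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    endpoint = task.split("_")[0]
    return endpoint, task.endswith("_hr")


def _labels_for(clinical: ClinicalTable, sample_ids) -> dict:
    aligned = clinical.aligned_to(sample_ids)
    out = {}
    for col in ("efs", "os", "hr"):
        if col in aligned.data.columns:
            out[col] = aligned.data[col].to_numpy(dtype=int)
    return out


def run_dap(x: ExpressionMatrix, clinical: ClinicalTable, task: str,
            model_factory, cfg: DAPConfig | None = None) -> DAPResult:
    """Run the full protocol for one task on one training cohort.

    `model_factory(seed)` must return a fresh estimator.  HR-restricted
    tasks subset the cohort to hr == 1 before anything else.  The returned
    result carries the final model retrained on the whole training set (best
    k), ready for :func:`external_validate`.
    """
    cfg = cfg or DAPConfig()
    endpoint, hr_only = _task_parts(task)
    if hr_only:
        labels_all = _labels_for(clinical, x.sample_ids)
        keep = [s for s, h in zip(x.sample_ids, labels_all["hr"]) if h == 1]
        x = x.subset_samples(keep)
    labels = _labels_for(clinical, x.sample_ids)
    y = labels[endpoint].copy()

    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "random_label":
        # scramble the training labels, preserving class counts exactly
        perm = rng.permutation(len(y))
        y = y[perm]
        labels = dict(labels)
        labels[endpoint] = y

    folds = stratified_folds(y, cfg.folds, cfg.repeats, cfg.seed)
    rows = []
    audit = []
    n = x.n_samples
    correct = np.zeros(n, dtype=int)
    best_k_predictions = {}

    global_mean = x.values.mean(axis=0)
    fold_records = []  # (r, f, test_idx, {k: preds})

    for r, rep in enumerate(folds):
        for f, (tr, te) in enumerate(rep):
            x_tr = _take(x, tr)
            x_te = _take(x, te)
            params = fit_standardizer(x_tr)
            z_tr = apply_standardizer(params, x_tr)
            z_te = apply_standardizer(params, x_te)
            if cfg.scheme == "random_feature":
                ids = list(z_tr.gene_ids)
                ranking = None
            else:
                ranking = anova_f_rank(z_tr, y[tr])
            audit.append({
                "repeat": r, "fold": f,
                "disjoint": len(set(tr) & set(te)) == 0,
                "standardizer_fit_on_train_only": bool(
                    np.allclose(params.mean,
                                x_tr.values.mean(axis=0), atol=1e-12)
                    and not np.allclose(params.mean, global_mean, atol=1e-12)),
                "ranking_fit_on_train_only": True,
            })
            k_preds = {}
            for k in cfg.k_grid:
                if cfg.scheme == "random_feature":
                    kk = z_tr.n_genes if k in (None, "all") else min(k, z_tr.n_genes)
                    genes = list(np.array(ids)[
                        rng.choice(z_tr.n_genes, size=kk, replace=False)])
                else:
                    genes = ranking.top(
                        k if k in (None, "all") else min(k, z_tr.n_genes))
                m_tr = z_tr.subset_genes(genes)
                m_te = z_te.subset_genes(genes)
                est = model_factory(int(rng.integers(2**31)))
                fold_labels = {name: arr[tr] for name, arr in labels.items()}
                est.fit(m_tr.values, fold_labels)
                pred = est.predict(m_te.values)[endpoint]
                c = confusion_from_labels(y[te], pred)
                rows.append({
                    "repeat": r, "fold": f, "k": k, "tp": c.tp, "tn": c.tn,
                    "fp": c.fp, "fn": c.fn, "mcc": mcc(c),
                })
                k_preds[k] = pred
            fold_records.append((r, f, te, k_preds))

    per_fold = pd.DataFrame(rows)
    med = per_fold.groupby("k", sort=False)["mcc"].median()
    best_mcc = med.max()
    # parsimony tie-break: smallest numeric k attaining the best median
    def _k_order(k):
        return (np.inf if k in (None, "all") else k)
    best_k = sorted([k for k in cfg.k_grid
                     if med[k] >= best_mcc - 1e-12], key=_k_order)[0]

    for r, f, te, k_preds in fold_records:
        correct[te] += (np.asarray(k_preds[best_k]) == y[te]).astype(int)
    per_sample = pd.DataFrame({
        "sample_id": x.sample_ids,
        "correct": correct,
        "n_repeats": cfg.repeats,
    })

    fold_mccs = per_fold[per_fold["k"].astype(str) == str(best_k)]["mcc"].to_numpy()
    ci = bootstrap_ci(fold_mccs, seed=cfg.seed)

    # final model: preprocessing refit on the whole training cohort
    params = fit_standardizer(x)
    z = apply_standardizer(params, x)
    if cfg.scheme == "random_feature":
        kk = z.n_genes if best_k in (None, "all") else min(best_k, z.n_genes)
        genes = list(np.array(z.gene_ids)[
            rng.choice(z.n_genes, size=kk, replace=False)])
    else:
        ranking = anova_f_rank(z, y)
        genes = ranking.top(best_k if best_k in (None, "all")
                            else min(best_k, z.n_genes))
    final_est = model_factory(int(rng.integers(2**31)))
    final_est.fit(z.subset_genes(genes).values, labels)

    return DAPResult(
        task=task,
        per_fold=per_fold,
        best_k=best_k,
        cv_mcc_median=float(np.median(fold_mccs)),
        cv_mcc_ci=ci,
        per_sample_correct=per_sample,
        audit=audit,
        final_params=params,
        final_genes=genes,
        final_model=final_est,
    )


def _take(x: ExpressionMatrix, idx) -> ExpressionMatrix:
    return ExpressionMatrix(
        x.values[idx], [x.sample_ids[i] for i in idx], list(x.gene_ids),
        None if x.entrez_id is None else list(x.entrez_id))


def external_validate(result: DAPResult, x_val: ExpressionMatrix,
                      clinical_val: ClinicalTable) -> dict:
    """Score the final model on an external cohort, no refitting.

    The validation matrix is reduced to the training-derived gene list and
    standardized with the training parameters.
    """
    endpoint, hr_only = _task_parts(result.task)
    if hr_only:
        labels_all = _labels_for(clinical_val, x_val.sample_ids)
        keep = [s for s, h in zip(x_val.sample_ids, labels_all["hr"]) if h == 1]
        x_val = x_val.subset_samples(keep)
    missing = set(result.final_params.gene_ids) - set(x_val.gene_ids)
    if missing:
        raise ValueError(
            f"validation cohort lacks {len(missing)} training genes")
    x_val = x_val.subset_genes(list(result.final_params.gene_ids))
    z = apply_standardizer(result.final_params, x_val)
    z = z.subset_genes(result.final_genes)
    labels = _labels_for(clinical_val, x_val.sample_ids)
    pred = result.final_model.predict(z.values)[endpoint]
    c = confusion_from_labels(labels[endpoint], pred)
    out = {"task": result.task, "confusion": c, "mcc": mcc(c)}
    result.external = {"task": result.task, "mcc": out["mcc"],
                       "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
    return out


# ---------------------------------------------------------------------------
# randomization sanity checks


def random_label_check(x, clinical, task, model_factory,
                       cfg: DAPConfig | None = None, n_runs: int = 20):
    """Rerun the protocol `n_runs` times with scrambled labels."""
    return _scheme_check(x, clinical, task, model_factory, cfg, n_runs,
                         "random_label")


def random_feature_check(x, clinical, task, model_factory,
                         cfg: DAPConfig | None = None, n_runs: int = 20):
    """Rerun the protocol `n_runs` times with random feature sets."""
    return _scheme_check(x, clinical, task, model_factory, cfg, n_runs,
                         "random_feature")


def _scheme_check(x, clinical, task, model_factory, cfg, n_runs, scheme):
    cfg = cfg or DAPConfig()
    mccs = []
    for i in range(n_runs):
        run_cfg = DAPConfig(repeats=cfg.repeats, folds=cfg.folds,
                            k_grid=cfg.k_grid, seed=cfg.seed + 1000 * (i + 1),
                            scheme=scheme)
        res = run_dap(x, clinical, task, model_factory, run_cfg)
        mccs.append(res.cv_mcc_median)
    mccs = np.asarray(mccs)
    return {"scheme": scheme, "mccs": mccs, "median": float(np.median(mccs))}


# ---------------------------------------------------------------------------
# studentized bootstrap


def bootstrap_ci(values, level: float = 0.95, n_boot: int = 2000,
                 seed: int = 0) -> tuple:
    """Studentized (bootstrap-t) confidence interval for the mean.

    Each resample's statistic is studentized by its own standard error; the
    interval is mean − t*_{1−α/2}·se, mean − t*_{α/2}·se.  A constant input
    vector yields a zero-width interval.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    se = v.std(ddof=1) / np.sqrt(n)
    if se == 0.0:
        return (float(mean), float(mean))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = v[idx]
    means = samples.mean(axis=1)
    ses = samples.std(ddof=1, axis=1) / np.sqrt(n)
    ok = ses > 0
    t = (means[ok] - mean) / ses[ok]
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(t, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(mean - q_hi * se), float(mean - q_lo * se))


# ---------------------------------------------------------------------------
# train/test split selection


def select_split(x: ExpressionMatrix, clinical: ClinicalTable,
                 n_candidates: int = 100, comparator_factory=None,
                 task: str = "efs", test_size: float = 0.5,
                 lam: float = 1.0, seed: int = 0) -> SplitSpec:
    """Pick the best of `n_candidates` random stratified splits.

    Each candidate is scored with a pluggable comparator classifier
    (default: linear SVM) by validation MCC penalized by the overfitting
    gap: score = MCC_val − λ·max(0, MCC_train − MCC_val).  Fully seeded;
    comparator failures skip the candidate with a warning.
    """
    from sklearn.svm import LinearSVC

    if comparator_factory is None:
        def comparator_factory():
            return LinearSVC()
    endpoint, _ = _task_parts(task)
    y = _labels_for(clinical, x.sample_ids)[endpoint]
    best = None
    for i in range(n_candidates):
        rs = (seed + i) % (2**32)
        tr, te = train_test_split(np.arange(x.n_samples), test_size=test_size,
                                  stratify=y, random_state=rs)
        try:
            params = fit_standardizer(_take(x, tr))
            z_tr = apply_standardizer(params, _take(x, tr))
            z_te = apply_standardizer(params, _take(x, te))
            clf = comparator_factory()
            clf.fit(z_tr.values, y[tr])
            m_tr = mcc(confusion_from_labels(y[tr], clf.predict(z_tr.values)))
            m_te = mcc(confusion_from_labels(y[te], clf.predict(z_te.values)))
        except Exception as exc:  # pragma: no cover - comparator failure path
            warnings.warn(f"candidate split {i} skipped: {exc}", stacklevel=2)
            continue
        score = m_te - lam * max(0.0, m_tr - m_te)
        if best is None or score > best[0]:
            best = (score, tr, te)
    if best is None:
        raise RuntimeError("every candidate split failed")
    _, tr, te = best
    return SplitSpec([x.sample_ids[i] for i in tr],
                     [x.sample_ids[i] for i in te])
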