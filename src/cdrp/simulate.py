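"""Synthetic neuroblastoma-like cohorts with a planted severity axis.

Real cohorts of this kind couple a clinical risk call (High-Risk vs non-HR,
assigned by a deterministic clinical algorithm), two hard survival endpoints
(event-free and overall survival), and a transcriptome in which only a
subset of genes tracks disease severity.  The generator reproduces exactly
that statistical skeleton so every downstream stage — filtering,
standardization, network training, the cross-validation protocol, and
embedding-based survival stratification — can be exercised end to end
without any external download:

* a latent per-patient severity score, standard normal;
* HR assigned deterministically: severity above the normal quantile at
  1 − hr_prevalence (the "clinical algorithm" the autoencoder distills);
* informative genes = per-gene baseline + severity_effect · severity + noise,
  the remaining genes pure noise on the same log2 scale;
* EFS events Bernoulli(logistic(event_link · severity + offset)); OS events a
  severity-biased subset of EFS events, so OS prevalence ≤ EFS prevalence;
* event times exponential with rate increasing in severity, censoring times
  uniform — expected observed time decreases with severity.

Two presets anchor class balance to the published cohort stratification
tables kept in :data:`SEQC_STRATA` and :data:`TARGET_STRATA`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import ClinicalTable, ExpressionMatrix, SplitSpec

__all__ = [
    "CohortConfig", "CohortTruth", "generate", "preset",
    "SEQC_STRATA", "TARGET_STRATA", "strata_totals", "write_cohort",
]

# (HR, EFS, OS) -> (training count, validation count); the SEQC-NB cohort's
# published sample stratification over the NBt/NBv halves
SEQC_STRATA = {
    (0, 0, 0): (129, 130),
    (0, 1, 0): (26, 24),
    (0, 1, 1): (8, 5),
    (1, 0, 0): (31, 25),
    (1, 1, 0): (12, 16),
    (1, 1, 1): (43, 49),
}

# same layout for the TARGET-NB cohort (TGt/TGv halves)
TARGET_STRATA = {
    (0, 0, 0): (15, 15),
    (0, 1, 0): (0, 0),
    (0, 1, 1): (0, 0),
    (1, 0, 0): (28, 33),
    (1, 1, 0): (7, 9),
    (1, 1, 1): (73, 67),
}


def strata_totals(strata: dict) -> dict:
    """Marginal counts implied by a (HR, EFS, OS) stratification table."""
    out = {
        "n_train": 0, "n_test": 0, "n_total": 0,
        "hr": 0, "efs": 0, "os": 0,
    }
    for (hr, efs, os_), (nt, nv) in strata.items():
        out["n_train"] += nt
        out["n_test"] += nv
        n = nt + nv
        out["n_total"] += n
        out["hr"] += hr * n
        out["efs"] += efs * n
        out["os"] += os_ * n
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults define the standing study conditions.

    severity_effect is the mean log2-expression shift of an informative gene
    per unit severity; noise_sd the per-gene residual sd on the same scale.
    event_link is the logistic slope from severity to event probability;
    efs_offset fixes marginal event prevalence; os_link/os_offset govern
    which EFS events are also deaths.  time_scale_days sets the median
    event time of an average-severity patient.
    """

    n_samples: int = 498
    n_genes: int = 1000
    n_informative: int = 100
    hr_prevalence: float = 176 / 498
    severity_effect: float = 1.0
    noise_sd: float = 1.0
    censor_rate: float = 0.3
    event_link: float = 1.5
    efs_offset: float = -0.8
    os_link: float = 1.0
    os_offset: float = 0.2
    time_scale_days: float = 1200.0
    baseline_range: tuple = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.hr_prevalence < 1:
            raise ValueError("hr_prevalence must lie in (0, 1)")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd <= 0 or self.severity_effect < 0:
            raise ValueError("noise_sd must be > 0 and severity_effect >= 0")
        if self.hr_prevalence * self.n_samples < 2:
            raise ValueError(
                "degenerate config: expected fewer than 2 HR samples"
            )


@dataclass
class CohortTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    severity: np.ndarray
    informative_genes: list
    hr_threshold: float
    seed: int


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: CohortConfig):
    """Draw a cohort; identical config (incl. seed) → identical output.

    Returns
    -------
    (ExpressionMatrix, ClinicalTable, CohortTruth)
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_genes

    severity = rng.standard_normal(n)
    # deterministic clinical algorithm: threshold on the severity score
    threshold = float(norm.ppf(1.0 - config.hr_prevalence))
    hr = (severity > threshold).astype(int)

    gene_ids = [f"g{j:05d}" for j in range(p)]
    informative = list(rng.choice(p, size=config.n_informative, replace=False))
    informative.sort()
    baseline = rng.uniform(*config.baseline_range, size=p)
    values = baseline + config.noise_sd * rng.standard_normal((n, p))
    effect = np.zeros(p)
    effect[informative] = config.severity_effect
    values += severity[:, None] * effect[None, :]

    # every gene annotated (Entrez-like); the annotation filter is exercised
    # separately by attaching gaps in tests
    entrez = [str(100000 + j) for j in range(p)]
    x = ExpressionMatrix(values, [f"s{i:04d}" for i in range(n)],
                         gene_ids, entrez)

    p_efs = _sigmoid(config.event_link * severity + config.efs_offset)
    efs = rng.binomial(1, p_efs)
    # deaths are a severity-biased subset of EFS events
    p_os_given_event = _sigmoid(config.os_link * severity + config.os_offset)
    os_ = efs * rng.binomial(1, p_os_given_event)

    # event times: exponential, hazard increasing in severity; censoring
    # uniform on (0, c_max) with c_max set so that roughly censor_rate of
    # event times exceed their censoring draw
    base_rate = np.log(2.0) / config.time_scale_days
    rate = base_rate * np.exp(0.7 * severity)
    t_event = rng.exponential(1.0 / rate)
    c_max = 2.0 * config.time_scale_days / max(config.censor_rate, 1e-9) \
        if config.censor_rate > 0 else np.inf
    t_censor = rng.uniform(0.0, c_max, size=n) if np.isfinite(c_max) \
        else np.full(n, np.inf)

    days = np.where(efs == 1, t_event, np.minimum(t_event, t_censor))
    os_days = np.where(os_ == 1, t_event, np.minimum(t_event * 1.15, t_censor))
    inss = _assign_inss(severity, rng)

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": x.sample_ids,
        "hr": hr,
        "efs": efs,
        "os": os_,
        "efs_days": np.round(days, 1),
        "os_days": np.round(os_days, 1),
        "inss": inss,
        "age_days": np.round(rng.uniform(30, 1800, size=n), 0),
        "gender": rng.choice(["M", "F"], size=n),
        "country": rng.choice(["A", "B", "C"], size=n),
    }))
    truth = CohortTruth(
        severity=severity,
        informative_genes=[gene_ids[j] for j in informative],
        hr_threshold=threshold,
        seed=config.seed,
    )
    return x, clinical, truth


def _assign_inss(severity, rng):
    """Ordinal tumor stage loosely increasing with severity (4S is the
    spontaneously-regressing infant stage, drawn from the low tail)."""
    q = norm.cdf(severity)
    stage = np.select(
        [q < 0.25, q < 0.45, q < 0.65, q >= 0.65],
        np.array(["1", "2", "3", "4"]),
        default="4",
    )
    low = np.flatnonzero(q < 0.25)
    if low.size:
        flip = rng.random(low.size) < 0.15
        stage[low[flip]] = "4S"
    return stage


def preset(name: str) -> CohortConfig:
    """Named study-condition presets.

    ``seqc_like`` matches the SEQC-NB cohort balance (498 patients, 176 HR);
    ``target_like`` the HR-dominated TARGET-NB cohort (247 specimens, 217 HR
    by the stratification-table arithmetic; the originating text also quotes
    83.2%, the table-derived count is used).
    """
    if name == "seqc_like":
        t = strata_totals(SEQC_STRATA)
        return CohortConfig(
            n_samples=t["n_total"],
            hr_prevalence=t["hr"] / t["n_total"],
        )
    if name == "target_like":
        t = strata_totals(TARGET_STRATA)
        return CohortConfig(
            n_samples=t["n_total"],
            hr_prevalence=t["hr"] / t["n_total"],
            # heavily HR-enriched cohort: events are the majority
            efs_offset=0.3,
            os_offset=0.5,
        )
    raise ValueError(f"unknown preset {name!r}")


def write_cohort(x: ExpressionMatrix, clinical: ClinicalTable,
                 truth: CohortTruth, outdir) -> dict:
    """Write expression/clinical TSVs plus a truth sidecar; returns paths."""
    from . import cohort as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "genes": outdir / "genes.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.yaml",
    }
    cio.write_expression(x, paths["expression"], gene_annotation=paths["genes"])
    cio.write_clinical(clinical, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump({
            "seed": int(truth.seed),
            "hr_threshold": float(truth.hr_threshold),
            "informative_genes": list(truth.informative_genes),
            "severity": [float(v) for v in truth.severity],
        }, fh)
    return paths
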