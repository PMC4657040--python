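"""Benchmark metrics and the classical FDR procedures used as comparators.

Provides Benjamini-Hochberg adjustment, the single-lambda Storey q-value,
TPR/FDR scoring against simulation ground truth, and a scenario-grid
runner that simulates a dataset, runs the lfdr estimators and records one
tidy row per (scenario, repetition, method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lfdr import call_significant, run_pipeline
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "BenchmarkRecord",
    "bh_adjust",
    "storey_qvalue",
    "tpr_fdr",
    "run_benchmark",
]


@dataclass
class BenchmarkRecord:
    signal: float
    n_de: int
    repetition: int
    method: str
    tpr: float
    fdr: float
    n_flagged: int


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalue(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single fixed lambda.

    pi0 is estimated as #{p > lambda} / ((1 - lambda) m), capped at 1;
    q_i is the minimum of pi0 * m * p_(j) / j over the tail j >= rank(i).
    With lambda = 0 this reduces to BH (pi0 = 1).
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def tpr_fdr(flags: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """True positive rate and false discovery proportion of a call set.

    TPR = TP / (TP + FN), 0 when nothing is truly positive;
    FDR = FP / (TP + FP), 0 when nothing is flagged.
    """
    flags = np.asarray(flags, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if flags.shape != truth.shape:
        raise ValueError("flags and truth must have equal length")
    tp = int((flags & truth).sum())
    fp = int((flags & ~truth).sum())
    n_pos = int(truth.sum())
    tpr = tp / n_pos if n_pos else 0.0
    fdr = fp / max(tp + fp, 1)
    return tpr, fdr


def run_benchmark(
    scenarios: list[tuple[float, int, int]],
    methods: tuple[str, ...] = ("fdr1d", "fdr2d_product", "fdr2d_full"),
    seed: int = 0,
    threshold: float = 0.2,
    B: int = 10,
    base_config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run the estimators over a scenario grid and collect TPR/FDR records.

    Each (signal, n_de, repetition) scenario gets its own child seed
    derived deterministically from ``seed``, so the full table is
    reproducible and repetitions are independent.
    """
    template = base_config or SimulationConfig()
    rows: list[BenchmarkRecord] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(scenarios))
    for (signal, n_de, rep), child in zip(scenarios, children):
        sim_seed, perm_seed = (int(s) % 2**31 for s in child.generate_state(2))
        config = SimulationConfig(
            n_real=template.n_real,
            n_noise=template.n_noise,
            n_samples_per_group=template.n_samples_per_group,
            n_replicates=template.n_replicates,
            max_noise_sd=template.max_noise_sd,
            n_de=n_de,
            signal=signal,
            zero_rate=template.zero_rate,
            sd_profile=template.sd_profile,
            seed=sim_seed,
        )
        data = simulate_dataset(config)
        table, _ = run_pipeline(
            data.tensor,
            data.covariates,
            methods=methods,
            B=B,
            seed=perm_seed,
            threshold=threshold,
        )
        col = {"fdr1d": "lfdr_1d", "fdr2d_product": "lfdr_2d_product",
               "fdr2d_full": "lfdr_2d_full"}
        for method in methods:
            flags = call_significant(table.frame[col[method]].to_numpy(), threshold)
            tpr, fdr = tpr_fdr(flags, data.truth_de)
            rows.append(
                BenchmarkRecord(signal, n_de, rep, method, tpr, fdr, int(flags.sum()))
            )
    return pd.DataFrame([r.__dict__ for r in rows])
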