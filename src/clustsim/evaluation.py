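"""Scoring clustering runs against the generating truth.

Two quantities are tracked per replicate: whether the selected number of
clusters equals the true number of latent groups, and the (unadjusted)
Rand index between the recovered and the true partition — the proportion
of unit pairs on which the two partitions agree.  For two balanced groups
random assignment gives a Rand index near 0.5, which is why 0.5 reads as
"chance level" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import Dataset
from .results import ClusterResult

__all__ = ["ScenarioSummary", "rand_index", "summarize_scenario"]


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index: fraction of concordant unit pairs.

    A pair is concordant when it is co-clustered in both partitions or
    separated in both.  Invariant to relabeling of either partition and
    symmetric in its arguments; 1.0 means identical partitions.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labels_a and labels_b must be 1-D of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 units")
    # contingency table pair counts
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    same_a = (np.square(table.sum(axis=1)).sum() - n) / 2.0
    same_b = (np.square(table.sum(axis=0)).sum() - n) / 2.0
    same_both = (np.square(table).sum() - n) / 2.0
    total = n * (n - 1) / 2.0
    disagree = same_a + same_b - 2.0 * same_both
    return float(1.0 - disagree / total)


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregate performance of one method over one scenario's replicates."""

    label: str
    method: str
    n_replicates: int
    k_counts: dict          # full tally of selected k (1..k_max)
    prop_k: dict            # binned proportions for k in {1, 2, 3, ">3"}
    prop_correct: float
    rand_mean: float
    rand_sd: float
    n_failed: int = 0

    def to_row(self) -> dict:
        row = {
            "scenario": self.label,
            "method": self.method,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
        }
        for k in sorted(self.k_counts):
            row[f"n_k{k}"] = self.k_counts[k]
        for key in (1, 2, 3, ">3"):
            row[f"prop_k{key}"] = self.prop_k[key]
        row["prop_correct"] = self.prop_correct
        row["rand_mean"] = self.rand_mean
        row["rand_sd"] = self.rand_sd
        return row


def summarize_scenario(
    results: list[tuple[ClusterResult, Dataset]],
    n_failed: int = 0,
    k_max: int = 5,
) -> ScenarioSummary:
    """Tally selected-k proportions and Rand-index moments over replicates.

    All results must come from the same scenario and method.  The Rand
    index is computed against the true labels even when the truth is a
    single cluster (it is then driven by the recovered cluster sizes — a
    degenerate but well-defined quantity, reported for completeness).
    The reported SD is the population SD of the per-replicate values.
    """
    if not results:
        raise ValueError("results must be non-empty")
    methods = {res.method for res, _ in results}
    if len(methods) != 1:
        raise ValueError(f"mixed methods in one summary: {sorted(methods)}")
    specs = {ds.spec.label for _, ds in results if ds.spec is not None}
    if len(specs) > 1:
        raise ValueError(f"mixed scenarios in one summary: {sorted(specs)}")

    true_k = {ds.spec.true_k if ds.spec is not None else None for _, ds in results}
    true_k = true_k.pop()
    if true_k is None:
        # fall back to the labels themselves
        true_k = int(np.unique(results[0][1].true_labels).size)

    ks = np.array([res.k_selected for res, _ in results])
    rands = np.array(
        [rand_index(res.labels, ds.true_labels) for res, ds in results]
    )
    n_rep = len(results)
    k_counts = {k: int((ks == k).sum()) for k in range(1, k_max + 1)}
    prop_k = {
        1: float((ks == 1).mean()),
        2: float((ks == 2).mean()),
        3: float((ks == 3).mean()),
        ">3": float((ks > 3).mean()),
    }
    return ScenarioSummary(
        label=specs.pop() if specs else "",
        method=methods.pop(),
        n_replicates=n_rep,
        k_counts=k_counts,
        prop_k=prop_k,
        prop_correct=float((ks == true_k).mean()),
        rand_mean=float(rands.mean()),
        rand_sd=float(rands.std(ddof=0)),
        n_failed=n_failed,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack ScenarioSummary rows into a tidy DataFrame."""
    return pd.DataFrame([s.to_row() for s in summaries])
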