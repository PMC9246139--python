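"""Shared result container for the clustering methods."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ClusterResult"]


@dataclass
class ClusterResult:
    """Outcome of one cluster-number selection run.

    Attributes
    ----------
    method
        ``"mgc"`` (Gaussian mixture / BIC), ``"pam"`` or ``"hac"``.
    k_selected
        Chosen number of clusters, between 1 and the method's k_max.
    labels
        Hard assignment of each unit, integer ids starting at 1.
    criterion_by_k
        Selection-criterion values per candidate k: a Series indexed by k
        (average silhouette width, partitional methods) or a DataFrame
        indexed by k with one column per covariance family (BIC, mixtures).
    duda_hart
        One-cluster test record, present for the partitional methods only.
    extras
        Method-specific details (selected covariance family, medoids, ...).
    """

    method: str
    k_selected: int
    labels: np.ndarray
    criterion_by_k: pd.Series | pd.DataFrame | None = None
    duda_hart: Any = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.k_selected < 1:
            raise ValueError("k_selected must be >= 1")
        if self.k_selected == 1 and np.unique(self.labels).size != 1:
            raise ValueError("k_selected = 1 requires all labels equal")

    def to_json(self) -> str:
        crit = self.criterion_by_k
        if isinstance(crit, pd.DataFrame):
            crit_out = {str(k): row.dropna().to_dict() for k, row in crit.iterrows()}
        elif isinstance(crit, pd.Series):
            crit_out = {str(k): v for k, v in crit.dropna().items()}
        else:
            crit_out = None
        payload = {
            "method": self.method,
            "k_selected": int(self.k_selected),
            "labels": [int(v) for v in self.labels],
            "criterion_by_k": crit_out,
            "duda_hart": None
            if self.duda_hart is None
            else {
                "je1": self.duda_hart.je1,
                "je2": self.duda_hart.je2,
                "ratio": self.duda_hart.ratio,
                "critical_value": self.duda_hart.critical_value,
                "alpha": self.duda_hart.alpha,
                "reject_homogeneity": bool(self.duda_hart.reject_homogeneity),
            },
            "extras": {k: v for k, v in self.extras.items() if _is_jsonable(v)},
        }
        return json.dumps(payload)


def _is_jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
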