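"""Scoring inferred networks against a known ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .inference import EVIDENCE_STRONG, EVIDENCE_SUBSTANTIAL, PosteriorSamples
from .metrics import pielou_evenness
from .model import GLVModelError, Trajectory, simulate
from .synth import GroundTruthRecord

__all__ = ["RecoveryReport", "evaluate_recovery"]


@dataclass
class RecoveryReport:
    """Edge-level comparison of an inferred network with the truth.

    ``detection_rate`` is the fraction of true edges with BF > 10;
    ``false_edge_rate`` the fraction of absent edges with BF > 3;
    ``sign_accuracy`` is computed over detected edges (BF > 3) that are true;
    ``coefficient_rmse`` over true edges detected at BF > 3.  Rates are NaN
    when the denominator is empty.
    """

    per_edge: pd.DataFrame
    detection_rate: float
    false_edge_rate: float
    sign_accuracy: float
    coefficient_rmse: float
    evenness_rmse: Optional[float] = None
    extras: dict = field(default_factory=dict)


def evaluate_recovery(
    truth: GroundTruthRecord,
    summary: pd.DataFrame,
    samples: Optional[PosteriorSamples] = None,
    trajectories: Optional[Sequence[Trajectory]] = None,
) -> RecoveryReport:
    """Score an inferred edge summary against the generating parameters.

    ``summary`` is the table from
    :func:`glvnet.inference.summarize_network`.  If ``trajectories`` are
    given, an evenness-trajectory RMSE compares the median observed
    composition per baseline time point against the deterministic truth
    simulation.
    """
    sp = truth.params.species
    labels = set(sp.labels)
    inter = summary[~summary["source"].isin(("order3", "order4"))]
    seen = set(inter["source"]) | set(inter["target"])
    if not seen <= labels:
        raise GLVModelError(
            f"species mismatch: summary has {sorted(seen - labels)}"
        )
    eff = truth.params.effective_matrix()
    rows = []
    for _, row in inter.iterrows():
        i, j = sp.index(row["target"]), sp.index(row["source"])
        true_coeff = eff[i, j]
        true_edge = true_coeff != 0.0
        bf = row["bayes_factor"]
        detected = bf > EVIDENCE_SUBSTANTIAL
        rows.append(
            {
                "source": row["source"],
                "target": row["target"],
                "true_edge": true_edge,
                "true_coefficient": true_coeff,
                "bayes_factor": bf,
                "category": row["category"],
                "detected": detected,
                "inferred_sign": row["sign"],
                "true_sign": "+" if true_coeff > 0 else ("-" if true_coeff < 0 else ""),
                "mean_strength": row["mean_strength"],
            }
        )
    per_edge = pd.DataFrame(rows)

    true_edges = per_edge[per_edge["true_edge"]]
    absent_edges = per_edge[~per_edge["true_edge"]]
    detection_rate = (
        float((true_edges["bayes_factor"] > EVIDENCE_STRONG).mean())
        if len(true_edges) else math.nan
    )
    false_edge_rate = (
        float(absent_edges["detected"].mean()) if len(absent_edges) else math.nan
    )
    detected_true = true_edges[true_edges["detected"]]
    sign_accuracy = (
        float((detected_true["inferred_sign"] == detected_true["true_sign"]).mean())
        if len(detected_true) else math.nan
    )
    if len(detected_true):
        err = detected_true["mean_strength"] - detected_true["true_coefficient"]
        coefficient_rmse = float(np.sqrt(np.mean(err**2)))
    else:
        coefficient_rmse = math.nan

    evenness_rmse = None
    if trajectories is not None:
        evenness_rmse = _evenness_rmse(truth, trajectories)

    return RecoveryReport(
        per_edge=per_edge,
        detection_rate=detection_rate,
        false_edge_rate=false_edge_rate,
        sign_accuracy=sign_accuracy,
        coefficient_rmse=coefficient_rmse,
        evenness_rmse=evenness_rmse,
    )


def _evenness_rmse(
    truth: GroundTruthRecord, trajectories: Sequence[Trajectory]
) -> float:
    """RMSE between observed (replicate-median) and deterministic-truth
    evenness over the baseline condition's time grid."""
    base_label = truth.design.conditions[0][0]
    reps = [t for t in trajectories if t.condition == base_label]
    if not reps:
        raise GLVModelError(f"no trajectories for condition {base_label!r}")
    med = np.median(np.stack([t.abundances for t in reps]), axis=0)
    det = simulate(
        truth.params,
        truth.design.conditions[0][1],
        reps[0].times,
        stochastic=False,
    )
    obs = np.array([pielou_evenness(row) for row in med])
    exp = np.array([pielou_evenness(row) for row in det.abundances])
    return float(np.sqrt(np.mean((obs - exp) ** 2)))
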