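"""Virtual-screening calibration metrics: ROC AUC and enrichment factors.

AUC is the probability that a randomly chosen active outranks a randomly
chosen inactive (ties count one half) — equivalently the area under the
ROC curve of the score ranking.  The enrichment factor at a fraction f is
the active rate in the top ``ceil(f*N)`` scored compounds divided by the
active rate of the whole library.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence


@dataclass
class ScreenResult:
    ligand_id: str
    score: float
    label: int  # 1 = active


class MetricsError(ValueError):
    pass


def _check(results: Sequence[ScreenResult]) -> None:
    labels = {r.label for r in results}
    if labels - {0, 1}:
        raise MetricsError("labels must be 0/1")
    if labels != {0, 1}:
        raise MetricsError("need at least one active and one inactive")


def auc(results: Sequence[ScreenResult], higher_is_better: bool = True) -> float:
    """Rank-based ROC AUC via the Mann–Whitney U statistic."""
    _check(results)
    sign = 1.0 if higher_is_better else -1.0
    scores = [sign * r.score for r in results]
    labels = [r.label for r in results]
    # midrank assignment
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    ranks = [0.0] * len(scores)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n_act = sum(labels)
    n_inact = len(labels) - n_act
    rank_sum = sum(r for r, lab in zip(ranks, labels) if lab == 1)
    u = rank_sum - n_act * (n_act + 1) / 2.0
    return u / (n_act * n_inact)


def enrichment_factor(results: Sequence[ScreenResult], fraction: float,
                      higher_is_better: bool = True) -> float:
    """EF(f) = (actives in top set / |top set|) / (actives / N).

    The top set holds the ``ceil(f*N)`` best-scored compounds; ties at the
    threshold are broken by ligand_id so the value is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise MetricsError("fraction must be in (0, 1]")
    _check(results)
    n = len(results)
    top_n = math.ceil(fraction * n)
    sign = -1.0 if higher_is_better else 1.0
    ranked = sorted(results, key=lambda r: (sign * r.score, r.ligand_id))
    top = ranked[:top_n]
    total_actives = sum(r.label for r in results)
    top_actives = sum(r.label for r in top)
    return (top_actives / top_n) / (total_actives / n)


def read_scores_csv(path: str) -> List[ScreenResult]:
    """CSV columns: ligand_id, score, label."""
    import csv

    out: List[ScreenResult] = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(ScreenResult(row["ligand_id"], float(row["score"]),
                                    int(row["label"])))
    return out
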