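"""Detection scoring: matching, threshold sweep, FP localisation, statistics.

The scoring protocol:

* **Matching** is greedy one-to-one in descending detection probability: a
  detection is a true positive iff it satisfies the match criterion (IoU >=
  0.5 by default, or detection-box-contains-truth-center) with a so-far
  unmatched ground-truth box of the same image.
* **Threshold sweep**: at each probability threshold t in {20, 30, 40, 50} %
  only detections with probability >= t participate; sensitivity =
  TP/(TP+FN) over ground-truth lesions, PPV = TP/(TP+FP) over detections.
  TP is non-increasing in t and TP+FN equals the lesion count at every t.
* **False-positive localisation**: an unmatched detection is assigned the
  majority tissue label among its in-box pixels, restricted to cerebral
  cortex vs cerebral white matter; ties go to cortex, boxes containing
  neither label are counted as "other".
* **Mann-Whitney U** compares TP vs FP probability scores: midrank U, exact
  tail via the U-distribution recursion when ``n1*n2 <= 400`` and the data
  are tie-free, else a normal approximation with tie and continuity
  corrections.
* **Average precision** is single-class, all-point interpolated (precision
  envelope over the recall axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .types import (
    CORTEX,
    WHITE_MATTER,
    BoundingBox,
    Detection,
    TissueMask,
)

DEFAULT_THRESHOLDS = (20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class MatchCriterion:
    mode: str = "iou"              # "iou" | "center_in_box"
    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("iou", "center_in_box"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValueError("iou_threshold must lie in (0, 1]")

    def matches(self, det: BoundingBox, truth: BoundingBox) -> bool:
        if self.mode == "iou":
            return det.iou(truth) >= self.iou_threshold
        return det.contains_point(*truth.center)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_detections(
    dets: list[Detection],
    truths: list[BoundingBox],
    crit: MatchCriterion = MatchCriterion(),
) -> tuple[list[tuple[Detection, int]], list[Detection], list[int]]:
    """Greedy one-to-one matching within a single image.

    Returns ``(tp_pairs, fp_dets, fn_truth_indices)`` where each TP pair is
    ``(detection, truth_index)``.  Detections are processed in descending
    probability (ties broken by box position for determinism); each truth
    matches at most once, and among admissible truths the one with the
    largest IoU wins.
    """
    order = sorted(
        dets,
        key=lambda d: (-d.probability_percent, d.box.y_min, d.box.x_min),
    )
    matched: set[int] = set()
    tp: list[tuple[Detection, int]] = []
    fp: list[Detection] = []
    for det in order:
        best_idx, best_iou = -1, -1.0
        for i, t in enumerate(truths):
            if i in matched or not crit.matches(det.box, t):
                continue
            iou = det.box.iou(t)
            if iou > best_iou:
                best_idx, best_iou = i, iou
        if best_idx >= 0:
            matched.add(best_idx)
            tp.append((det, best_idx))
        else:
            fp.append(det)
    fn = [i for i in range(len(truths)) if i not in matched]
    return tp, fp, fn


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def sweep_thresholds(
    dets_by_image: dict[str, list[Detection]],
    truths_by_image: dict[str, list[BoundingBox]],
    crit: MatchCriterion = MatchCriterion(),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Sensitivity/PPV table over probability thresholds (percent).

    Counts are pooled over images.  PPV is NaN when no detection survives a
    threshold; sensitivity is NaN when there is no ground truth at all.
    """
    n_truth = sum(len(v) for v in truths_by_image.values())
    rows = []
    image_ids = sorted(set(dets_by_image) | set(truths_by_image))
    for t in thresholds:
        tp = fp = 0
        for iid in image_ids:
            dets = [d for d in dets_by_image.get(iid, [])
                    if d.probability_percent >= t]
            pairs, fps, _ = match_detections(dets, truths_by_image.get(iid, []), crit)
            tp += len(pairs)
            fp += len(fps)
        fn = n_truth - tp
        rows.append(
            {
                "threshold": t,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "sensitivity": tp / n_truth if n_truth else float("nan"),
                "ppv": tp / (tp + fp) if (tp + fp) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fp_detections_at(
    dets_by_image: dict[str, list[Detection]],
    truths_by_image: dict[str, list[BoundingBox]],
    crit: MatchCriterion = MatchCriterion(),
    threshold: float = 20.0,
) -> tuple[list[Detection], list[Detection]]:
    """(tp_dets, fp_dets) pooled over images at one probability threshold."""
    tps: list[Detection] = []
    fps: list[Detection] = []
    for iid in sorted(set(dets_by_image) | set(truths_by_image)):
        dets = [d for d in dets_by_image.get(iid, [])
                if d.probability_percent >= threshold]
        pairs, f, _ = match_detections(dets, truths_by_image.get(iid, []), crit)
        tps.extend(d for d, _ in pairs)
        fps.extend(f)
    return tps, fps


# ---------------------------------------------------------------------------
# false-positive localisation
# ---------------------------------------------------------------------------

def classify_fp_locations(
    fp_dets: list[Detection],
    tissue_by_image: dict[str, TissueMask],
) -> dict[str, int]:
    """Majority-tissue classification of false positives.

    Returns counts for ``cerebral_cortex``, ``cerebral_white_matter`` and
    ``other`` (boxes containing neither label).  Ties go to cortex.
    """
    counts = {"cerebral_cortex": 0, "cerebral_white_matter": 0, "other": 0}
    for det in fp_dets:
        if det.image_id not in tissue_by_image:
            raise KeyError(f"no tissue mask for image {det.image_id!r}")
        labels = tissue_by_image[det.image_id].labels
        h, w = labels.shape
        box = det.box.clip(w, h)
        if box is None:
            counts["other"] += 1
            continue
        window = labels[box.slices]
        n_cortex = int((window == CORTEX).sum())
        n_wm = int((window == WHITE_MATTER).sum())
        if n_cortex == 0 and n_wm == 0:
            counts["other"] += 1
        elif n_cortex >= n_wm:
            counts["cerebral_cortex"] += 1
        else:
            counts["cerebral_white_matter"] += 1
    return counts


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float     # U of the first sample
    p_value: float
    n1: int
    n2: int
    method: str            # "exact" | "normal"


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null distribution counts of U for sample sizes (n1, n2), tie-free.

    ``counts[u]`` is the number of the C(n1+n2, n1) rank arrangements with
    Mann-Whitney statistic exactly u; computed by the standard recursion
    f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1).
    """
    u_max = n1 * n2
    # table[m][u] for current n column; iterate n from 0..n2
    prev = [[1 if u == 0 else 0 for u in range(u_max + 1)] for _ in range(n1 + 1)]
    for n in range(1, n2 + 1):
        cur = [[0] * (u_max + 1) for _ in range(n1 + 1)]
        cur[0][0] = 1
        for m in range(1, n1 + 1):
            for u in range(u_max + 1):
                val = prev[m][u]  # f(u; m, n-1)
                if u >= n:
                    val += cur[m - 1][u - n]  # f(u - n; m - 1, n)
                cur[m][u] = val
        prev = cur
    return tuple(prev[n1])


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test comparing two score samples.

    Exact when ``n1 * n2 <= 400`` and the pooled sample is tie-free;
    otherwise a normal approximation with midranks, tie correction and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    # midranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    has_ties = np.unique(pooled).size < pooled.size
    if n1 * n2 <= 400 and not has_ties:
        counts = np.array(_u_counts(n1, n2), dtype=float)
        total = counts.sum()
        u_min = min(u1, u2)
        p = 2.0 * counts[: int(u_min) + 1].sum() / total
        return MannWhitneyResult(u1, min(p, 1.0), n1, n2, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u1, 1.0, n1, n2, "normal")
    z = max(abs(u1 - n1 * n2 / 2.0) - 0.5, 0.0) / math.sqrt(var)
    p = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0))))
    return MannWhitneyResult(u1, min(p, 1.0), n1, n2, "normal")


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def average_precision(
    dets_by_image: dict[str, list[Detection]],
    truths_by_image: dict[str, list[BoundingBox]],
    crit: MatchCriterion = MatchCriterion(),
) -> float:
    """Single-class AP: area under the enveloped precision-recall curve.

    Detections are ranked globally by probability; matching is greedy
    one-to-one per image across all thresholds (threshold 0 sweep).
    """
    n_truth = sum(len(v) for v in truths_by_image.values())
    if n_truth == 0:
        raise ValueError("average precision undefined without ground truth")
    all_dets = [
        d for iid in sorted(dets_by_image) for d in dets_by_image[iid]
    ]
    all_dets.sort(key=lambda d: (-d.probability_percent, d.image_id,
                                 d.box.y_min, d.box.x_min))
    matched: dict[str, set[int]] = {iid: set() for iid in truths_by_image}
    tp_flags = []
    for det in all_dets:
        truths = truths_by_image.get(det.image_id, [])
        used = matched.setdefault(det.image_id, set())
        best_idx, best_iou = -1, -1.0
        for i, t in enumerate(truths):
            if i in used or not crit.matches(det.box, t):
                continue
            iou = det.box.iou(t)
            if iou > best_iou:
                best_idx, best_iou = i, iou
        if best_idx >= 0:
            used.add(best_idx)
            tp_flags.append(1.0)
        else:
            tp_flags.append(0.0)
    if not tp_flags:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    recall = tp_cum / n_truth
    precision = tp_cum / np.arange(1, len(tp_flags) + 1)
    # precision envelope (all-point interpolation)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


# ---------------------------------------------------------------------------
# probability comparison + report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityComparison:
    tp_median: float
    tp_iqr: tuple[float, float]
    fp_median: float
    fp_iqr: tuple[float, float]
    u_statistic: float
    p_value: float


def compare_probabilities(tp_probs, fp_probs) -> ProbabilityComparison:
    """Median (IQR) of TP vs FP scores plus the two-sided U test."""
    tp = np.asarray(tp_probs, dtype=float)
    fp = np.asarray(fp_probs, dtype=float)
    res = mann_whitney(tp, fp)
    q = lambda a: (float(np.percentile(a, 25)), float(np.percentile(a, 75)))
    return ProbabilityComparison(
        tp_median=float(np.median(tp)),
        tp_iqr=q(tp),
        fp_median=float(np.median(fp)),
        fp_iqr=q(fp),
        u_statistic=res.u_statistic,
        p_value=res.p_value,
    )


def location_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Cortex/WM counts -> percentages over their sum, 1-decimal rounding."""
    n_cortex = counts.get("cerebral_cortex", 0)
    n_wm = counts.get("cerebral_white_matter", 0)
    total = n_cortex + n_wm
    if total == 0:
        return {"cerebral_cortex": 0.0, "cerebral_white_matter": 0.0}
    return {
        "cerebral_cortex": round(100.0 * n_cortex / total, 1),
        "cerebral_white_matter": round(100.0 * n_wm / total, 1),
    }


def summarize(
    eval_table: pd.DataFrame,
    fp_location_by_threshold: dict[float, dict[str, int]] | None = None,
    prob_comparison: ProbabilityComparison | None = None,
    set_tag: str = "",
) -> dict[str, pd.DataFrame]:
    """Assemble sensitivity/PPV and FP-location report tables.

    Returns ``{"detection": df1, "fp_location": df2}`` (the second only when
    location counts are given); each regenerates identically from its own
    CSV round trip.
    """
    det = eval_table.copy()
    if set_tag:
        det.insert(0, "set", set_tag)
    out = {"detection": det}
    if fp_location_by_threshold is not None:
        rows = []
        for t in sorted(fp_location_by_threshold):
            counts = fp_location_by_threshold[t]
            pct = location_percentages(counts)
            row = {
                "threshold": t,
                "cortex_count": counts.get("cerebral_cortex", 0),
                "cortex_percent": pct["cerebral_cortex"],
                "wm_count": counts.get("cerebral_white_matter", 0),
                "wm_percent": pct["cerebral_white_matter"],
                "other_count": counts.get("other", 0),
            }
            if set_tag:
                row = {"set": set_tag, **row}
            rows.append(row)
        out["fp_location"] = pd.DataFrame(rows)
    if prob_comparison is not None:
        pc = prob_comparison
        out["probability_comparison"] = pd.DataFrame(
            [
                {
                    "group": "true_positive",
                    "median": pc.tp_median,
                    "q1": pc.tp_iqr[0],
                    "q3": pc.tp_iqr[1],
                },
                {
                    "group": "false_positive",
                    "median": pc.fp_median,
                    "q1": pc.fp_iqr[0],
                    "q3": pc.fp_iqr[1],
                },
            ]
        )
    return out
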