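"""Normative PIB-positivity cutoff from the control distribution.

The control composite distribution is bimodal: a narrow, normally distributed
main cluster and a small number of high-retention outliers. The cutoff is
derived by (1) isolating the main cluster with iterative upper trimming at
mean + 2 SD, then (2) taking the upper bound of the central 95 % normal
range, mean + 1.96 SD, of the cluster. Subjects strictly above the cutoff are
PIB-positive; ties classify negative (negatives are "< cutoff").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: SD multiplier for the upper normal limit (central 95 % range).
DEFAULT_MULTIPLIER = 1.96
#: SD multiplier used during iterative trimming.
TRIM_MULTIPLIER = 2.0


@dataclass
class ThresholdModel:
    cluster_mean: float
    cluster_sd: float
    cluster_n: int
    cutoff: float
    multiplier: float = DEFAULT_MULTIPLIER
    excluded_controls: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"cluster_mean": self.cluster_mean, "cluster_sd": self.cluster_sd,
                "cluster_n": self.cluster_n, "cutoff": self.cutoff,
                "multiplier": self.multiplier,
                "excluded_controls": list(map(list, self.excluded_controls))}


def main_cluster(values: np.ndarray,
                 trim_multiplier: float = TRIM_MULTIPLIER
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Identify the normally distributed majority subgroup.

    Iterative upper trimming: remove values strictly above mean + 2 SD of
    the current set, recompute, repeat until stable. At sample sizes where
    that rule is mathematically unable to fire — the maximal standardized
    deviation of a sample is (n-1)/sqrt(n), below the multiplier for n <= 5
    at 2 SD — a gross outlier would be masked by its own contribution to the
    SD, so the limit is instead computed without the largest value, which is
    dropped while it exceeds it. Returns (subset, outliers), both sorted
    ascending; deterministic; a degenerate all-equal input returns everything.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size < 5:
        raise ValueError("need at least 5 values to identify the main cluster")
    keep = values
    while keep.size > 2:
        n = keep.size
        if (n - 1) / np.sqrt(n) > trim_multiplier:
            limit = keep.mean() + trim_multiplier * keep.std(ddof=1)
            trimmed = keep[keep <= limit]
            if trimmed.size < keep.size:
                keep = trimmed
                continue
        else:
            rest = keep[:-1]
            if keep[-1] > rest.mean() + trim_multiplier * rest.std(ddof=1):
                keep = rest
                continue
        break
    outliers = values[keep.size:]
    return keep, outliers


def normal_upper_limit(subset: np.ndarray,
                       multiplier: float = DEFAULT_MULTIPLIER,
                       excluded: list[tuple[str, float]] | None = None
                       ) -> ThresholdModel:
    """Upper normal limit of the main cluster: mean + multiplier x sample SD
    (n-1 denominator)."""
    subset = np.asarray(subset, dtype=float)
    if subset.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(subset.mean())
    sd = float(subset.std(ddof=1))
    if sd == 0:
        log.warning("zero variance in main cluster; cutoff equals the mean")
    return ThresholdModel(cluster_mean=mean, cluster_sd=sd,
                          cluster_n=int(subset.size),
                          cutoff=mean + multiplier * sd,
                          multiplier=multiplier,
                          excluded_controls=excluded or [])


def derive_threshold(control_values: dict[str, float] | np.ndarray,
                     multiplier: float = DEFAULT_MULTIPLIER,
                     method: str = "trim") -> ThresholdModel:
    """Full normative procedure on control composites.

    ``method="trim"`` is the iterative mean+2SD upper trimming;
    ``method="gmm"`` fits a two-component Gaussian mixture and takes the
    lower-mean component as the main cluster (sensitivity alternative).
    """
    if isinstance(control_values, dict):
        ids = np.array(list(control_values))
        vals = np.array([control_values[i] for i in ids], dtype=float)
    else:
        vals = np.asarray(control_values, dtype=float)
        ids = np.array([str(i) for i in range(vals.size)])
    order = np.argsort(vals, kind="stable")
    ids, vals = ids[order], vals[order]

    if method == "gmm":
        subset = _gmm_main_cluster(vals)
    else:
        subset, _ = main_cluster(vals)
    cut = vals.searchsorted(subset[-1], side="right")
    excluded = [(str(i), float(v)) for i, v in zip(ids[cut:], vals[cut:])]
    return normal_upper_limit(subset, multiplier, excluded)


def _gmm_main_cluster(values: np.ndarray) -> np.ndarray:
    """Two-component 1-D Gaussian mixture; return values assigned to the
    lower-mean component."""
    from scipy.stats import norm
    v = values
    # EM with deterministic quantile-based initialisation
    mu = np.quantile(v, [0.25, 0.9])
    sd = np.array([v.std(ddof=1) / 2 + 1e-6] * 2)
    w = np.array([0.8, 0.2])
    for _ in range(200):
        resp = w * norm.pdf(v[:, None], mu, np.maximum(sd, 1e-6))
        resp /= resp.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        w = nk / v.size
        mu = (resp * v[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (v[:, None] - mu) ** 2).sum(axis=0) / nk)
    low = int(np.argmin(mu))
    assign = np.argmax(w * norm.pdf(v[:, None], mu, np.maximum(sd, 1e-6)),
                       axis=1)
    subset = v[assign == low]
    return subset if subset.size >= 2 else v


def classify(composite: float, cutoff: float) -> str:
    """'positive' iff composite > cutoff (strict); ties are negative."""
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    return "positive" if composite > cutoff else "negative"


def positivity_percent(classifications: list[str] | np.ndarray) -> int:
    """Percentage of 'positive' entries, rounded to the nearest integer."""
    arr = np.asarray(classifications)
    if arr.size == 0:
        raise ValueError("no classifications")
    return int(round(100.0 * np.mean(arr == "positive")))


def split_high_low(positives: list[tuple[str, float]]
                   ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Split the PIB-positive group at its median composite.

    Values strictly above the median go to "high"; the median itself (and
    below) to "low". Returns (low, high).
    """
    if len(positives) < 2:
        raise ValueError("need at least 2 positives to split")
    values = np.array([v for _, v in positives], dtype=float)
    med = float(np.median(values))
    low = [(i, v) for i, v in positives if v <= med]
    high = [(i, v) for i, v in positives if v > med]
    if not high:
        log.warning("all positive composites equal; 'high' stratum empty")
    return low, high
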