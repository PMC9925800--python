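"""IoU-based agreement statistics and nonparametric tests.

Core quantities:

* ``iou`` / ``mean_iou`` -- intersection-over-union between binary damage
  masks and its mean over slices, used against a reference segmentation.
* ``agreement_across_cams`` (phi_m) -- for one slice and one fixed CNN
  model, the mean IoU over all unordered pairs of CAM methods
  (1 / C(|C|,2) normalisation).
* ``agreement_across_models`` (phi_c) -- symmetric statistic with the CAM
  method fixed and the model varying.
* ``correlate_with_liquid_loss`` -- Spearman's rank correlation between a
  per-sample damage score and the liquid-loss percentage; a Shapiro-Wilk
  normality check is computed and recorded alongside (rank correlation is
  always reported, since normality cannot be assumed for these data).
* ``compare_groups`` -- Kruskal-Wallis H test (tie-corrected) for
  differences between groups of agreement values.

Two empty masks have an undefined IoU (0/0).  The default policy scores
such a pair as 1.0 -- two methods that both report "no damage" agree
perfectly -- because at high t_CAM thresholds empty masks are common and
silently dropping them would bias the phi statistics; set
``both_empty="exclude"`` to drop those pairs instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .exceptions import ContractError, DomainError

__all__ = [
    "AgreementRecord",
    "CorrelationResult",
    "iou",
    "mean_iou",
    "agreement_across_cams",
    "agreement_across_models",
    "damage_fraction",
    "correlate_with_liquid_loss",
    "compare_groups",
]


@dataclass
class AgreementRecord:
    """A per-slice phi value with its fixed axis and threshold."""

    slice_id: str
    axis: str            # "model" for phi_m (CAM methods vary), "method" for phi_c
    fixed_id: str
    t_cam: float
    value: float         # in [0, 1] (nan if every pair was excluded)
    n_pairs: int


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str = "spearman"
    shapiro_p: float = float("nan")
    undefined: bool = False


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    return m.astype(bool)


def iou(a, b, both_empty: float = 1.0) -> float:
    """Intersection over union of two equal-shape binary masks.

    ``both_empty`` is returned when both masks are empty (the 0/0 case);
    pass ``np.nan`` to mark such pairs for exclusion.
    """
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return both_empty
    return float(np.logical_and(a, b).sum() / union)


def mean_iou(a_slices, b_slices, both_empty: float = 1.0) -> float:
    """Mean per-slice IoU over paired mask lists."""
    if len(a_slices) != len(b_slices):
        raise ContractError("paired mask lists must have equal length")
    if len(a_slices) == 0:
        raise ContractError("need at least one slice pair")
    return float(np.mean([iou(a, b, both_empty) for a, b in zip(a_slices, b_slices)]))


def _pairwise_phi(masks_by_key: dict, both_empty: str):
    if len(masks_by_key) < 2:
        raise ContractError("agreement needs at least 2 masks to compare")
    fill = np.nan if both_empty == "exclude" else 1.0
    values = [
        iou(masks_by_key[i], masks_by_key[j], both_empty=fill)
        for i, j in combinations(sorted(masks_by_key), 2)
    ]
    arr = np.asarray(values, dtype=float)
    kept = arr[~np.isnan(arr)]
    value = float(kept.mean()) if kept.size else float("nan")
    return value, len(values)


def agreement_across_cams(masks_by_method: dict, model_id: str = "",
                          slice_id: str = "", t_cam: float = float("nan"),
                          both_empty: str = "one") -> AgreementRecord:
    """phi_m: mean IoU over all unordered CAM-method pairs, model fixed."""
    value, n_pairs = _pairwise_phi(masks_by_method, both_empty)
    return AgreementRecord(slice_id, "model", model_id, t_cam, value, n_pairs)


def agreement_across_models(masks_by_model: dict, method_id: str = "",
                            slice_id: str = "", t_cam: float = float("nan"),
                            both_empty: str = "one") -> AgreementRecord:
    """phi_c: mean IoU over all unordered CNN-model pairs, CAM method fixed."""
    value, n_pairs = _pairwise_phi(masks_by_model, both_empty)
    return AgreementRecord(slice_id, "method", method_id, t_cam, value, n_pairs)


def damage_fraction(mask, foreground) -> float:
    """Fraction of foreground pixels flagged as damaged."""
    m, fg = _as_binary(mask), _as_binary(foreground)
    if m.shape != fg.shape:
        raise ContractError("mask and foreground shapes differ")
    n_fg = fg.sum()
    if n_fg == 0:
        raise DomainError("empty foreground")
    return float(np.logical_and(m, fg).sum() / n_fg)


def correlate_with_liquid_loss(per_sample_damage, liquid_loss) -> CorrelationResult:
    """Spearman rank correlation of per-sample damage scores with LL%."""
    x = np.asarray(per_sample_damage, dtype=float)
    y = np.asarray(liquid_loss, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("inputs must be paired 1-D sequences")
    if x.size < 3:
        raise ContractError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), int(x.size),
                                 undefined=True)
    # normality gate, recorded for the report; rank correlation is reported
    # regardless since the damage scores are bounded fractions
    sw_p = float(stats.shapiro(x).pvalue) if x.size >= 3 else float("nan")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size), shapiro_p=sw_p)


def compare_groups(values_by_group: dict):
    """Kruskal-Wallis H (tie-corrected) across >=2 groups of >=2 values."""
    if len(values_by_group) < 2:
        raise ContractError("need at least 2 groups")
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if any(g.size < 2 for g in groups):
        raise ContractError("every group needs at least 2 values")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
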