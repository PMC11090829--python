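"""Jensen-Shannon divergence scoring of bin distributions.

The similarity of two conditions (starting tissue vs organoids, untreated
vs drug-treated organoids, subtype vs subtype) is scored with the
Jensen-Shannon divergence between their bin distributions,

    JSD(P, Q) = 0.5 * sum_i p_i (log2 p_i - log2 m_i)
              + 0.5 * sum_i q_i (log2 q_i - log2 m_i),   M = 0.5 (P + Q),

which with base-2 logarithms lies in [0, 1]: 0 for identical distributions
and 1 for disjoint support.  Because all sections come from breast
epithelium, empirical comparisons never reach 1; the most disparate
comparison available (pooled ER+ vs TNBC starting tissue) defines the
practical ceiling.  Raw values are therefore rescaled to a similarity
score anchored at that ceiling:

    JSD_norm = (1 - JSD / norm_constant) * 100,

with ``norm_constant = 0.56`` by default, so 100 means identical and 0
means "as different as the two clinical subtypes".  Scores slightly below
zero occur when a comparison marginally exceeds the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinDistribution
from .errors import ConfigurationError, InvalidDistributionError

#: Practical upper anchor of raw JSD: the pooled ER+ vs TNBC starting-tissue
#: comparison.  Configurable everywhere; re-derivable from one's own data via
#: :func:`calibrate_norm_constant`.
DEFAULT_NORM_CONSTANT = 0.56

_SUM_TOL = 1e-9


@dataclass
class DivergenceResult:
    """Raw and normalized JSD for one ordered pair of condition labels."""

    label_p: str
    label_q: str
    jsd_raw: float
    jsd_norm: float
    norm_constant: float = DEFAULT_NORM_CONSTANT
    mode: str = "pooled"


def _validate(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise InvalidDistributionError(f"{name} has negative mass: {p}")
    s = p.sum()
    if abs(s - 1.0) > _SUM_TOL:
        raise InvalidDistributionError(f"{name} sums to {s!r}, not 1")
    return p


def jsd(p: Sequence[float], q: Sequence[float]) -> float:
    """Base-2 Jensen-Shannon divergence between two probability vectors.

    Zero-probability bins contribute nothing (0 * log 0 := 0); bins empty
    in both distributions are skipped entirely.  The result is clipped to
    [0, 1] against floating-point drift.
    """
    p = _validate(p, "p")
    q = _validate(q, "q")
    if p.shape != q.shape:
        raise InvalidDistributionError(
            f"shape mismatch: {p.shape} vs {q.shape}"
        )
    m = 0.5 * (p + q)
    total = 0.0
    for a in (p, q):
        nz = a > 0
        total += 0.5 * float(np.sum(a[nz] * (np.log2(a[nz]) - np.log2(m[nz]))))
    return float(np.clip(total, 0.0, 1.0))


def normalize_jsd(raw: float, norm_constant: float = DEFAULT_NORM_CONSTANT) -> float:
    """Rescale a raw JSD to the 0-100 similarity score (may go negative)."""
    if norm_constant <= 0:
        raise ConfigurationError(f"norm_constant must be > 0, got {norm_constant}")
    return (1.0 - raw / norm_constant) * 100.0


def pool_distributions(
    dists: Sequence[BinDistribution], label: str = "pooled"
) -> BinDistribution:
    """Pool conditions by summing section counts bin-wise."""
    if not dists:
        raise ConfigurationError("cannot pool an empty group")
    counts = np.sum([d.counts for d in dists], axis=0)
    return BinDistribution(condition_label=label, counts=tuple(int(c) for c in counts))


def group_jsd(
    group_a: Sequence[BinDistribution],
    group_b: Sequence[BinDistribution],
    mode: str = "pooled",
) -> float:
    """JSD between two groups of distributions.

    ``pooled`` concatenates each group's sections into one distribution and
    compares once; ``mean_pairwise`` averages the JSD over all cross-group
    pairs (identical members on both sides are skipped so a group is never
    compared with itself).
    """
    if not group_a or not group_b:
        raise ConfigurationError("both groups must be non-empty")
    if mode == "pooled":
        return jsd(pool_distributions(group_a).probs, pool_distributions(group_b).probs)
    if mode == "mean_pairwise":
        vals = [
            jsd(da.probs, db.probs)
            for da, db in product(group_a, group_b)
            if da is not db
        ]
        if not vals:
            return 0.0
        return float(np.mean(vals))
    raise ConfigurationError(f"unknown mode {mode!r}")


def calibrate_norm_constant(
    dists: Mapping[str, BinDistribution],
    group_a: Sequence[str],
    group_b: Sequence[str],
    mode: str = "pooled",
) -> float:
    """Derive a data-set-specific normalization anchor.

    The anchor is the JSD between the two most disparate groups the data
    set offers (for breast tissue: ER+-like vs TNBC-like starting tissue).
    """
    for name, labels in (("group_a", group_a), ("group_b", group_b)):
        if not labels:
            raise ConfigurationError(f"{name} is empty")
        unknown = [lb for lb in labels if lb not in dists]
        if unknown:
            raise ConfigurationError(f"{name} labels not found: {unknown}")
    return group_jsd(
        [dists[lb] for lb in group_a], [dists[lb] for lb in group_b], mode=mode
    )


def compare_conditions(
    dists: Mapping[str, BinDistribution],
    pairs: Sequence[tuple[str, str]],
    norm_constant: float = DEFAULT_NORM_CONSTANT,
    mode: str = "pooled",
) -> list[DivergenceResult]:
    """Score a list of condition pairs; order of results follows ``pairs``."""
    results = []
    for a, b in pairs:
        for lb in (a, b):
            if lb not in dists:
                raise KeyError(f"condition {lb!r} not found among {sorted(dists)}")
        raw = jsd(dists[a].probs, dists[b].probs)
        results.append(
            DivergenceResult(
                label_p=a,
                label_q=b,
                jsd_raw=raw,
                jsd_norm=normalize_jsd(raw, norm_constant),
                norm_constant=norm_constant,
                mode=mode,
            )
        )
    return results


def all_vs_all(
    dists: Mapping[str, BinDistribution],
    norm_constant: float = DEFAULT_NORM_CONSTANT,
) -> pd.DataFrame:
    """Symmetric matrix of normalized JSD scores over every condition pair."""
    labels = sorted(dists)
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            raw = jsd(dists[a].probs, dists[b].probs)
            score = normalize_jsd(raw, norm_constant)
            mat.loc[a, b] = score
            mat.loc[b, a] = score
    return mat


def results_to_frame(results: Sequence[DivergenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label_p": r.label_p,
                "label_q": r.label_q,
                "jsd_raw": r.jsd_raw,
                "jsd_norm": r.jsd_norm,
                "norm_constant": r.norm_constant,
                "mode": r.mode,
            }
            for r in results
        ]
    )
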