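"""Quartile binning of log2(K8/K14) ratios.

Each section contributes one value, ``log2(K8 area / K14 area)``.  Bin
boundaries are the 25th/50th/75th percentiles of a *reference* cohort
(histologically normal breast starting tissue), so by construction the
reference occupies all four bins equally; tumor cohorts reveal their
luminal (K8-rich, right) or basal (K14-rich, left) skew through the bin
occupancies.  A per-condition bin distribution is the probability 4-vector
of section counts per bin.

The module also implements the minimum-section sample-size rule: if the
least-represented bin has frequency ``f``, the probability that ``N``
random sections all miss it is ``(1-f)^N``, so the smallest ``N`` with
``1-(1-f)^N >= c`` guarantees, with confidence ``c``, at least one section
from that bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyConditionError,
    InsufficientReferenceError,
    NoTissueError,
)
from .image_quant import SectionQuant

N_BINS = 4


@dataclass
class LogRatioRecord:
    """One section's log2(K8/K14) value with its identity labels."""

    section_id: str
    patient_id: str
    subtype: str
    condition: str
    source_kind: str
    log2_ratio: float
    pseudocount_applied: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_ratio):
            raise ValueError(f"log2_ratio must be finite, got {self.log2_ratio}")


@dataclass
class BinScheme:
    """Quartile boundaries on the log2-ratio axis.

    Bins are left-open/right-closed: bin1 = (-inf, q25], bin2 = (q25, q50],
    bin3 = (q50, q75], bin4 = (q75, +inf).
    """

    q25: float
    q50: float
    q75: float
    reference_label: str = ""
    n_reference: int = 0

    def __post_init__(self) -> None:
        if not self.q25 <= self.q50 <= self.q75:
            raise ValueError(
                f"boundaries must be ordered: {self.q25}, {self.q50}, {self.q75}"
            )

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (self.q25, self.q50, self.q75)


@dataclass
class BinDistribution:
    """Per-condition bin occupancy: counts and exact probabilities."""

    condition_label: str
    counts: tuple[int, int, int, int]
    n_sections: int = field(init=False)
    probs: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.counts) != N_BINS or any(c < 0 for c in self.counts):
            raise ValueError(f"counts must be 4 non-negative ints, got {self.counts}")
        self.counts = tuple(int(c) for c in self.counts)
        self.n_sections = sum(self.counts)
        if self.n_sections < 1:
            raise EmptyConditionError(
                f"condition {self.condition_label!r} has no sections"
            )
        self.probs = tuple(c / self.n_sections for c in self.counts)


@dataclass
class SampleSizeSpec:
    """Minimum-section rule: smallest N with 1-(1-f)^N >= c."""

    least_bin_freq: float
    confidence: float
    n_min: int


def log2_ratio(rec: SectionQuant, pseudocount_px: int = 1) -> LogRatioRecord:
    """Compute a section's log2(K8 area / K14 area).

    When either area is zero, the pseudocount is added to *both* areas
    (symmetric, so neither direction is favoured) and the record is
    flagged.  A section with no K8, no K14 and no tissue has no defined
    phenotype and is rejected.
    """
    k8, k14 = rec.k8_area_px, rec.k14_area_px
    if k8 == 0 and k14 == 0 and rec.tissue_area_px == 0:
        raise NoTissueError(f"section {rec.section_id!r}: no tissue")
    pseudo = k8 == 0 or k14 == 0
    if pseudo:
        value = math.log2((k8 + pseudocount_px) / (k14 + pseudocount_px))
    else:
        value = math.log2(k8 / k14)
    return LogRatioRecord(
        section_id=rec.section_id,
        patient_id=rec.patient_id,
        subtype=rec.subtype,
        condition=rec.condition,
        source_kind=rec.source_kind,
        log2_ratio=value,
        pseudocount_applied=pseudo,
    )


def log2_ratios(
    quants: Iterable[SectionQuant], pseudocount_px: int = 1
) -> list[LogRatioRecord]:
    """Vector form of :func:`log2_ratio`; no-tissue sections are skipped."""
    out = []
    for q in quants:
        try:
            out.append(log2_ratio(q, pseudocount_px))
        except NoTissueError:
            warnings.warn(
                f"section {q.section_id!r} dropped: no tissue", stacklevel=2
            )
    return out


def fit_bin_scheme(
    reference: Sequence[LogRatioRecord],
    reference_label: str = "normal ST",
    quantile_method: str = "linear",
) -> BinScheme:
    """Fit quartile bin boundaries from a reference cohort.

    Quantiles use linear interpolation between order statistics by default
    (``quantile_method`` accepts any numpy quantile method name).
    """
    values = np.asarray([r.log2_ratio for r in reference], dtype=float)
    if values.size < 4:
        raise InsufficientReferenceError(
            f"need >= 4 reference records to fit quartiles, got {values.size}"
        )
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75], method=quantile_method)
    if q25 == q75:
        warnings.warn(
            "degenerate bin scheme: all three boundaries coincide", stacklevel=2
        )
    return BinScheme(
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        reference_label=reference_label,
        n_reference=int(values.size),
    )


def bin_index(value: float, scheme: BinScheme) -> int:
    """Assign a log2-ratio to its bin (1..4); boundaries close to the left bin."""
    if not math.isfinite(value):
        raise ValueError(f"value must be finite, got {value}")
    if value <= scheme.q25:
        return 1
    if value <= scheme.q50:
        return 2
    if value <= scheme.q75:
        return 3
    return 4


def make_distribution(
    records: Sequence[LogRatioRecord],
    scheme: BinScheme,
    condition_label: str,
    sample_size: SampleSizeSpec | None = None,
) -> BinDistribution:
    """Bin a condition's sections into a probability 4-vector.

    Warns when the condition has fewer sections than the active
    minimum-section rule requires (heterogeneity may be under-sampled),
    but still returns the distribution.
    """
    if not records:
        raise EmptyConditionError(f"condition {condition_label!r} has no records")
    counts = [0] * N_BINS
    for r in records:
        counts[bin_index(r.log2_ratio, scheme) - 1] += 1
    if sample_size is not None and len(records) < sample_size.n_min:
        warnings.warn(
            f"condition {condition_label!r}: n={len(records)} below the "
            f"minimum of {sample_size.n_min} sections "
            f"(f={sample_size.least_bin_freq}, c={sample_size.confidence})",
            stacklevel=2,
        )
    return BinDistribution(condition_label=condition_label, counts=tuple(counts))


def min_sections(f: float, c: float) -> SampleSizeSpec:
    """Smallest section count N with 1-(1-f)^N >= c.

    ``f`` is the frequency of the least-represented bin and ``c`` the
    required confidence of drawing at least one section from it.
    """
    if not 0 < f <= 1:
        raise ConfigurationError(f"least-bin frequency must be in (0, 1], got {f}")
    if not 0 <= c < 1:
        raise ConfigurationError(f"confidence must be in [0, 1), got {c}")
    if f == 1.0:
        return SampleSizeSpec(least_bin_freq=f, confidence=c, n_min=1)
    n = max(1, math.ceil(math.log1p(-c) / math.log1p(-f)))
    while 1.0 - (1.0 - f) ** n < c:  # guard against float rounding
        n += 1
    return SampleSizeSpec(least_bin_freq=f, confidence=c, n_min=n)


def least_bin_frequency(dists: Sequence[BinDistribution]) -> float:
    """Mean (over conditions) of each distribution's smallest bin probability."""
    if not dists:
        raise EmptyConditionError("no distributions given")
    return float(np.mean([min(d.probs) for d in dists]))


# ---------------------------------------------------------------------------
# tabular views

def records_to_frame(records: Iterable[LogRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "section_id": r.section_id,
                "patient_id": r.patient_id,
                "subtype": r.subtype,
                "condition": r.condition,
                "source_kind": r.source_kind,
                "log2_ratio": r.log2_ratio,
                "pseudocount_applied": r.pseudocount_applied,
            }
            for r in records
        ]
    )


def frame_to_records(frame: pd.DataFrame) -> list[LogRatioRecord]:
    return [
        LogRatioRecord(
            section_id=str(row.section_id),
            patient_id=str(row.patient_id),
            subtype=str(row.subtype),
            condition=str(row.condition),
            source_kind=str(row.source_kind),
            log2_ratio=float(row.log2_ratio),
            pseudocount_applied=bool(getattr(row, "pseudocount_applied", False)),
        )
        for row in frame.itertuples()
    ]


def distributions_to_frame(dists: Iterable[BinDistribution]) -> pd.DataFrame:
    """Tidy long-format table (one row per condition x bin) for plotting."""
    rows = []
    for d in dists:
        for b in range(N_BINS):
            rows.append(
                {
                    "condition": d.condition_label,
                    "bin": b + 1,
                    "count": d.counts[b],
                    "prob": d.probs[b],
                    "n_sections": d.n_sections,
                }
            )
    return pd.DataFrame(rows)
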