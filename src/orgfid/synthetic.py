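"""Ground-truthed synthetic data for every pipeline stage.

No imaging data are publicly deposited for this assay, so the package
ships a generator that emulates its statistical structure with known
ground truth:

* **Section cohorts** — each section's log2(K8/K14) is drawn from a
  two-component normal mixture on the log-ratio axis.  The left component
  is the K14-rich (basal) phenotype, the right the K8-rich (luminal)
  phenotype; the mixture weight of the right component encodes subtype
  (normal: balanced; TNBC-like: K14-heavy; ER+-like: K8-heavy).  Patients
  within a subtype share the mixture but carry a normally distributed
  per-patient offset (inter-patient heterogeneity).  Organoid cohorts may
  add a ``culture_drift`` offset; drug selection is modelled as a
  ``treatment_shift`` added to the mixture weight (K8-ward selection for
  positive shifts).
* **Section images** — two-channel fields of elliptical blobs hitting
  requested K8/K14 area fractions exactly, plus Gaussian noise, with
  ground-truth masks returned alongside.

Closed-form bin probabilities (:func:`analytic_bin_probs`) serve as the
oracle for everything downstream: mixture CDFs evaluated at the bin
boundaries give the exact expected bin distribution of any cohort spec.

Patient-level then section-level draws come from per-patient child
streams of one seed sequence, so adding patients never perturbs earlier
patients' sections, and cohorts generated from the same seed share their
underlying random numbers (common-random-number coupling: a treated
cohort differs from its untreated twin only where the treatment actually
flips a section's component).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.stats import norm

from .binning import BinScheme, LogRatioRecord
from .errors import GenerationError
from .image_quant import QuantImage, SectionQuant

Kind = Literal["ST", "organoid"]

#: Subtype mixture defaults on the log2(K8/K14) axis.
#: ``component_means`` = (K14-rich mean, K8-rich mean); ``mixture_weight``
#: is the K8-rich component's weight.  The normal tissue is a balanced,
#: symmetric mixture; TNBC-like cohorts are K14-heavy and shifted left,
#: ER+-like cohorts K8-heavy and shifted right, mirroring the left/right
#: skew of the clinical subtypes.
SUBTYPE_DEFAULTS: dict[str, dict] = {
    "normal": {
        "component_means": (-1.5, 1.5),
        "component_sds": (1.0, 1.0),
        "mixture_weight": 0.5,
    },
    "TNBC": {
        "component_means": (-2.4, 1.0),
        "component_sds": (1.1, 1.0),
        "mixture_weight": 0.2,
    },
    "ER+": {
        "component_means": (-1.0, 2.4),
        "component_sds": (1.0, 1.1),
        "mixture_weight": 0.8,
    },
}

#: Default cohort geometry: patients per subtype and sections per patient,
#: sized after a typical clinical cohort for this assay (half a dozen
#: patients per subtype, on the order of a hundred section images each).
DEFAULT_N_PATIENTS = 6
DEFAULT_SECTIONS_PER_PATIENT = 97
#: Inter-patient offset scale (log2 units) within a subtype.
DEFAULT_PATIENT_SD = 0.5


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for one subtype's section cohort."""

    subtype: str = "normal"
    n_patients: int = DEFAULT_N_PATIENTS
    sections_per_patient: int = DEFAULT_SECTIONS_PER_PATIENT
    component_means: tuple[float, float] = (-1.5, 1.5)
    component_sds: tuple[float, float] = (1.0, 1.0)
    mixture_weight: float = 0.5
    patient_sd: float = DEFAULT_PATIENT_SD
    culture_drift: float = 0.0
    treatment_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise GenerationError(f"mixture_weight {self.mixture_weight} not in [0,1]")
        if any(s <= 0 for s in self.component_sds):
            raise GenerationError("component sds must be > 0")
        if self.patient_sd < 0:
            raise GenerationError("patient_sd must be >= 0")
        if self.n_patients < 1 or self.sections_per_patient < 1:
            raise GenerationError("need >= 1 patient and >= 1 section each")

    @property
    def effective_weight(self) -> float:
        """Mixture weight after treatment selection, clipped to [0, 1]."""
        return float(np.clip(self.mixture_weight + self.treatment_shift, 0.0, 1.0))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cohort_spec(subtype: str, **overrides) -> SyntheticCohortSpec:
    """Build a cohort spec from the subtype defaults, with overrides."""
    if subtype not in SUBTYPE_DEFAULTS:
        raise GenerationError(
            f"unknown subtype {subtype!r}; choose from {sorted(SUBTYPE_DEFAULTS)}"
        )
    params = dict(SUBTYPE_DEFAULTS[subtype])
    params.update(overrides)
    return SyntheticCohortSpec(subtype=subtype, **params)


def gen_cohort(
    spec: SyntheticCohortSpec,
    kind: Kind = "ST",
    condition_label: str | None = None,
) -> list[LogRatioRecord]:
    """Draw a labelled section cohort from the mixture model.

    For each patient a mean offset is drawn with ``patient_sd``; each
    section then draws a component (K8-rich with probability
    ``effective_weight``) and a normal deviate.  ``culture_drift`` is
    added only for ``kind="organoid"``.
    """
    condition = condition_label or kind
    drift = spec.culture_drift if kind == "organoid" else 0.0
    w = spec.effective_weight
    means, sds = spec.component_means, spec.component_sds
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    records = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        offset = rng.normal(0.0, spec.patient_sd)
        patient = f"{spec.subtype}-p{i:02d}"
        for j in range(spec.sections_per_patient):
            u = rng.random()
            z = rng.standard_normal()
            comp = 1 if u < w else 0
            value = means[comp] + sds[comp] * z + offset + drift
            records.append(
                LogRatioRecord(
                    section_id=f"{patient}-{condition}-s{j:03d}",
                    patient_id=patient,
                    subtype=spec.subtype,
                    condition=condition,
                    source_kind=kind,
                    log2_ratio=value,
                )
            )
    return records


def analytic_bin_probs(
    spec: SyntheticCohortSpec, scheme: BinScheme, kind: Kind = "ST"
) -> np.ndarray:
    """Exact expected bin probabilities of a cohort spec under a scheme.

    The per-patient offset is marginalized analytically: a normal offset
    added to each component inflates its sd to
    ``sqrt(sd^2 + patient_sd^2)``.  Returns the mixture CDF mass in each of
    the four bins.
    """
    drift = spec.culture_drift if kind == "organoid" else 0.0
    w = spec.effective_weight
    m0, m1 = (m + drift for m in spec.component_means)
    s0, s1 = (math.hypot(s, spec.patient_sd) for s in spec.component_sds)

    def cdf(x: float) -> float:
        return (1.0 - w) * norm.cdf(x, m0, s0) + w * norm.cdf(x, m1, s1)

    c25, c50, c75 = (cdf(b) for b in scheme.boundaries)
    return np.array([c25, c50 - c25, c75 - c50, 1.0 - c75])


def records_to_quants(
    records: list[LogRatioRecord], base_area_px: int = 1 << 16
) -> list[SectionQuant]:
    """Materialize log-ratio records as drop-in SectionQuant rows.

    Areas are split symmetrically around ``base_area_px`` so that
    ``log2(k8/k14)`` reproduces the record's value up to integer rounding
    (negligible at the default scale).
    """
    quants = []
    for r in records:
        k8 = max(1, round(base_area_px * 2.0 ** (r.log2_ratio / 2.0)))
        k14 = max(1, round(base_area_px * 2.0 ** (-r.log2_ratio / 2.0)))
        quants.append(
            SectionQuant(
                section_id=r.section_id,
                patient_id=r.patient_id,
                subtype=r.subtype,
                condition=r.condition,
                source_kind=r.source_kind,
                image_area_px=max(4 * base_area_px, 2 * (k8 + k14)),
                tissue_area_px=k8 + k14,
                k8_area_px=k8,
                k14_area_px=k14,
            )
        )
    return quants


# ---------------------------------------------------------------------------
# synthetic section images


@dataclass
class SyntheticImageSpec:
    """Parameters of a two-channel blob image with exact ground truth."""

    height: int = 256
    width: int = 256
    k8_area_frac: float = 0.15
    k14_area_frac: float = 0.15
    overlap_frac: float = 0.0
    blob_count: int = 12
    noise_sigma: float = 0.0
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    seed: int = 0
    section_id: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("k8_area_frac", "k14_area_frac", "overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} not in [0, 1]")
        if self.overlap_frac > min(self.k8_area_frac, self.k14_area_frac):
            raise GenerationError("overlap_frac exceeds a channel's area fraction")
        if self.k8_area_frac + self.k14_area_frac - self.overlap_frac > 0.9:
            raise GenerationError("combined area fractions leave no free background")
        if self.foreground_intensity <= self.background_intensity:
            raise GenerationError("foreground must be brighter than background")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _grow_blobs(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target_px: int,
    blob_count: int,
) -> np.ndarray:
    """Accrete random ellipses inside ``allowed`` until exactly ``target_px``.

    The final ellipse is trimmed from its rim inward so the total positive
    area is exact to the pixel.
    """
    h, w = allowed.shape
    mask = np.zeros((h, w), dtype=bool)
    if target_px == 0:
        return mask
    per_blob = max(1.0, target_px / max(1, blob_count))
    r0 = math.sqrt(per_blob / math.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(10_000):
        have = int(mask.sum())
        if have >= target_px:
            break
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = r0 * rng.uniform(0.6, 1.4)
        rx = r0 * rng.uniform(0.6, 1.4)
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / rx) ** 2 + (v / ry) ** 2
        new = (d2 <= 1.0) & allowed & ~mask
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if have + n_new > target_px:
            # trim the outermost pixels of this ellipse to land exactly
            need = target_px - have
            ys, xs = np.nonzero(new)
            order = np.argsort(d2[ys, xs], kind="stable")[:need]
            keep = np.zeros_like(new)
            keep[ys[order], xs[order]] = True
            new = keep
        mask |= new
    if int(mask.sum()) != target_px:
        raise GenerationError(
            f"could not place {target_px} px in the allowed region"
        )
    return mask


def gen_section_image(
    spec: SyntheticImageSpec,
) -> tuple[QuantImage, dict[str, np.ndarray]]:
    """Generate a two-channel (K8, K14) blob image plus ground-truth masks.

    Ground-truth positive areas equal the requested fractions exactly (to
    the pixel).  Channel intensities are foreground/background levels with
    additive Gaussian noise, clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.height * spec.width
    t8 = round(spec.k8_area_frac * n_px)
    t14 = round(spec.k14_area_frac * n_px)
    tov = round(spec.overlap_frac * n_px)
    free = np.ones((spec.height, spec.width), dtype=bool)
    k8_mask = _grow_blobs(rng, free, t8, spec.blob_count)
    overlap = _grow_blobs(rng, k8_mask, tov, max(1, spec.blob_count // 2))
    outside = _grow_blobs(rng, ~k8_mask, t14 - tov, spec.blob_count)
    k14_mask = overlap | outside
    channels = []
    for mask in (k8_mask, k14_mask):
        img = np.where(mask, spec.foreground_intensity, spec.background_intensity)
        img = img.astype(float)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        channels.append(np.clip(img, 0.0, None))
    meta = dict(spec.metadata)
    qimg = QuantImage(
        pixels=np.stack(channels).astype(np.float32),
        channel_roles={"k8": 0, "k14": 1},
        section_id=spec.section_id,
        patient_id=meta.get("patient_id", ""),
        subtype=meta.get("subtype", "synthetic"),
        condition=meta.get("condition", ""),
        source_kind=meta.get("source_kind", "organoid"),
    )
    return qimg, {"k8": k8_mask, "k14": k14_mask}


def image_spec_for_ratio(
    log2_ratio: float,
    tissue_frac: float = 0.30,
    **overrides,
) -> SyntheticImageSpec:
    """Image spec whose ground-truth area ratio realizes a target log2 ratio.

    The requested tissue fraction is split between the channels so that
    ``k8_frac / k14_frac = 2**log2_ratio`` (no overlap).
    """
    k14 = tissue_frac / (1.0 + 2.0**log2_ratio)
    return SyntheticImageSpec(
        k8_area_frac=tissue_frac - k14, k14_area_frac=k14, **overrides
    )


def write_manifest(out_dir: str | Path, spec_dict: dict, extra: dict | None = None) -> Path:
    """Write the generating spec (and seed) alongside generated fixtures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"spec": spec_dict}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
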