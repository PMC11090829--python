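"""Tabular I/O: SectionQuant and log-ratio tables as tidy CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ImageFormatError
from .image_quant import SectionQuant

#: Fixed leading columns of the SectionQuant table; marker columns
#: (``marker_<role>_area_px``, ``nuclei_<role>``) follow when present.
SECTION_QUANT_COLUMNS = [
    "section_id",
    "patient_id",
    "subtype",
    "condition",
    "source_kind",
    "image_area_px",
    "tissue_area_px",
    "k8_area_px",
    "k14_area_px",
]


def quants_to_frame(quants: Iterable[SectionQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        row = {c: getattr(q, c) for c in SECTION_QUANT_COLUMNS}
        for role, area in q.marker_areas_px.items():
            row[f"marker_{role.replace('marker:', '')}_area_px"] = area
        if q.nuclei_total is not None:
            row["nuclei_total"] = q.nuclei_total
        for role, n in q.positive_nuclei.items():
            row[f"nuclei_{role.replace('marker:', '')}"] = n
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=SECTION_QUANT_COLUMNS)
    return frame


def frame_to_quants(frame: pd.DataFrame) -> list[SectionQuant]:
    missing = [c for c in SECTION_QUANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ImageFormatError(f"quant table missing columns: {missing}")
    quants = []
    for _, row in frame.iterrows():
        markers = {
            c.removeprefix("marker_").removesuffix("_area_px"): int(row[c])
            for c in frame.columns
            if c.startswith("marker_") and c.endswith("_area_px")
            and pd.notna(row[c])
        }
        nuclei = {
            c.removeprefix("nuclei_"): int(row[c])
            for c in frame.columns
            if c.startswith("nuclei_") and c != "nuclei_total"
            and pd.notna(row[c])
        }
        quants.append(
            SectionQuant(
                section_id=str(row["section_id"]),
                patient_id=str(row["patient_id"]),
                subtype=str(row["subtype"]),
                condition=str(row["condition"]),
                source_kind=str(row["source_kind"]),
                image_area_px=int(row["image_area_px"]),
                tissue_area_px=int(row["tissue_area_px"]),
                k8_area_px=int(row["k8_area_px"]),
                k14_area_px=int(row["k14_area_px"]),
                marker_areas_px=markers,
                nuclei_total=int(row["nuclei_total"])
                if "nuclei_total" in frame.columns and pd.notna(row.get("nuclei_total"))
                else None,
                positive_nuclei=nuclei,
            )
        )
    return quants


def write_quant_csv(quants: Sequence[SectionQuant], path: str | Path) -> None:
    quants_to_frame(quants).to_csv(path, index=False)


def read_quant_csv(path: str | Path) -> list[SectionQuant]:
    return frame_to_quants(pd.read_csv(path))
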