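"""Desikan-Killiany 68-ROI table: numbering, hemispheres and lobes.

Numbering convention: the 34 bilateral regions are ordered with the ten
frontal regions first, so ROI numbers 1-20 are frontal. Within each
region pair, the odd number is the right-hemisphere ROI and the even
number the left-hemisphere ROI. Lobe categories are frontal, temporal,
parietal, occipital, isthmus (kept out of the four lobes) and others
(cingulate except isthmus, insula, frontal pole).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

N_ROIS = 68

# (region name, lobe), ordered: frontal regions first so ROIs 1-20 are frontal.
_REGIONS: list[tuple[str, str]] = [
    ("superiorfrontal", "frontal"),
    ("rostralmiddlefrontal", "frontal"),
    ("caudalmiddlefrontal", "frontal"),
    ("parsopercularis", "frontal"),
    ("parstriangularis", "frontal"),
    ("parsorbitalis", "frontal"),
    ("lateralorbitofrontal", "frontal"),
    ("medialorbitofrontal", "frontal"),
    ("precentral", "frontal"),
    ("paracentral", "frontal"),
    ("superiortemporal", "temporal"),
    ("middletemporal", "temporal"),
    ("inferiortemporal", "temporal"),
    ("bankssts", "temporal"),
    ("fusiform", "temporal"),
    ("transversetemporal", "temporal"),
    ("entorhinal", "temporal"),
    ("temporalpole", "temporal"),
    ("parahippocampal", "temporal"),
    ("superiorparietal", "parietal"),
    ("inferiorparietal", "parietal"),
    ("supramarginal", "parietal"),
    ("postcentral", "parietal"),
    ("precuneus", "parietal"),
    ("lateraloccipital", "occipital"),
    ("lingual", "occipital"),
    ("cuneus", "occipital"),
    ("pericalcarine", "occipital"),
    ("isthmuscingulate", "isthmus"),
    ("caudalanteriorcingulate", "others"),
    ("posteriorcingulate", "others"),
    ("rostralanteriorcingulate", "others"),
    ("insula", "others"),
    ("frontalpole", "others"),
]

LOBES = ("frontal", "temporal", "parietal", "occipital", "isthmus", "others")


@dataclass(frozen=True)
class ROI:
    number: int  # 1-based ROI number as used in feature names
    name: str  # e.g. "superiorfrontal_lh"
    region: str  # atlas region without hemisphere suffix
    hemisphere: str  # "left" | "right"
    lobe: str


def _build_table() -> list[ROI]:
    rois = []
    for i, (region, lobe) in enumerate(_REGIONS):
        # odd number -> right hemisphere, even -> left
        rois.append(ROI(2 * i + 1, f"{region}_rh", region, "right", lobe))
        rois.append(ROI(2 * i + 2, f"{region}_lh", region, "left", lobe))
    return rois


_TABLE: list[ROI] = _build_table()


def roi_table() -> list[ROI]:
    """The packaged 68-ROI table, ordered by ROI number."""
    return list(_TABLE)


def roi_by_number(number: int) -> ROI:
    if not 1 <= number <= N_ROIS:
        raise ValueError(f"ROI number must be in 1..{N_ROIS}, got {number}")
    return _TABLE[number - 1]


def hemisphere_of(number: int) -> str:
    return roi_by_number(number).hemisphere


def lobe_of(number: int) -> str:
    return roi_by_number(number).lobe


def left_roi_numbers() -> list[int]:
    return [r.number for r in _TABLE if r.hemisphere == "left"]


def right_roi_numbers() -> list[int]:
    return [r.number for r in _TABLE if r.hemisphere == "right"]


def write_roi_csv(path) -> None:
    """Write the ROI table as CSV (roi_number, name, hemisphere, lobe)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["roi_number", "name", "hemisphere", "lobe"])
        for r in _TABLE:
            w.writerow([r.number, r.name, r.hemisphere, r.lobe])


def packaged_csv_text() -> str:
    """Contents of the packaged ROI CSV (for provenance manifests)."""
    return (
        resources.files("eegcog").joinpath("data/dk_rois.csv").read_text()
    )
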