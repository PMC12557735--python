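"""Quantitative phage-assay readouts as pure computations.

Two metrics:

* **Plaque/lawn ratio** — mean grayscale intensity inside a plaque region
  divided by the mean intensity of the surrounding bacterial lawn. A
  ratio of 1 means the spot is as opaque as the lawn (near-complete
  defense, no visible clearing); lower values mean clearer plaques and
  more effective lysis.
* **Adsorption efficiency** — percent of phage bound to cells,
  (PFU_control - PFU_sample) / PFU_control x 100, from free-phage titers
  of an infected sample versus a cell-free control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IntensityImage",
    "AdsorptionSeries",
    "plaque_lawn_ratio",
    "replicate_ratio_stats",
    "adsorption_efficiency",
    "adsorption_timecourse",
    "load_grayscale",
]


@dataclass
class IntensityImage:
    """A grayscale image with caller-supplied plaque and lawn region masks.

    Masks were drawn manually in the modeled workflow, so no automatic
    plaque detection is attempted here.
    """

    pixels: np.ndarray
    plaque_mask: np.ndarray
    lawn_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.plaque_mask = np.asarray(self.plaque_mask, dtype=bool)
        self.lawn_mask = np.asarray(self.lawn_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        for name, mask in (("plaque_mask", self.plaque_mask), ("lawn_mask", self.lawn_mask)):
            if mask.shape != self.pixels.shape:
                raise ValueError(f"{name} shape {mask.shape} != pixels {self.pixels.shape}")
            if not mask.any():
                raise ValueError(f"{name} is empty")
        if (self.plaque_mask & self.lawn_mask).any():
            raise ValueError("plaque and lawn masks overlap")


@dataclass
class AdsorptionSeries:
    """Free-phage titers over time for an infected sample vs. control."""

    timepoints: Sequence[float]  # minutes
    pfu_control: Sequence[float]
    pfu_sample: Sequence[float]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        c = np.asarray(self.pfu_control, dtype=float)
        s = np.asarray(self.pfu_sample, dtype=float)
        if not (len(t) == len(c) == len(s)):
            raise ValueError("timepoints, pfu_control, pfu_sample lengths differ")
        if (c <= 0).any():
            raise ValueError("pfu_control must be > 0 at every timepoint")
        if (s < 0).any():
            raise ValueError("pfu_sample must be >= 0")
        self.timepoints, self.pfu_control, self.pfu_sample = t, c, s


def plaque_lawn_ratio(image: IntensityImage) -> float:
    """Mean plaque intensity / mean lawn intensity (ImageJ-style means)."""
    lawn = image.pixels[image.lawn_mask].mean()
    if lawn == 0:
        raise ValueError("zero lawn intensity: ratio undefined")
    return float(image.pixels[image.plaque_mask].mean() / lawn)


def replicate_ratio_stats(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) over replicate plaque/lawn ratios."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 1:
        raise ValueError("at least one replicate required")
    if arr.size == 1 or np.ptp(arr) == 0:  # identical replicates: exactly 0
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def adsorption_efficiency(pfu_control: float, pfu_sample: float) -> float:
    """(PFU_control - PFU_sample) / PFU_control x 100 percent.

    Negative values (sample titer above control) are returned as-is; the
    time-course wrapper flags them.
    """
    if pfu_control <= 0:
        raise ValueError("pfu_control must be > 0")
    if pfu_sample < 0:
        raise ValueError("pfu_sample must be >= 0")
    return (pfu_control - pfu_sample) / pfu_control * 100.0


def adsorption_timecourse(series: AdsorptionSeries):
    """Per-timepoint percent adsorbed and percent of free phage remaining."""
    import pandas as pd

    adsorbed = [
        adsorption_efficiency(c, s)
        for c, s in zip(series.pfu_control, series.pfu_sample)
    ]
    return pd.DataFrame(
        {
            "time_min": series.timepoints,
            "percent_adsorbed": adsorbed,
            "percent_remaining": [100.0 - a for a in adsorbed],
            "negative_adsorption": [a < 0 for a in adsorbed],
        }
    )


def load_grayscale(path) -> np.ndarray:
    """Load a grayscale image from PNG/TIFF or a plain-text numeric grid."""
    path = str(path)
    if path.endswith((".txt", ".tsv", ".csv")):
        delim = "," if path.endswith(".csv") else None
        return np.loadtxt(path, delimiter=delim, dtype=float)
    from PIL import Image

    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=float)
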