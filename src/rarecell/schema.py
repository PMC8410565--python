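"""Shared column schema for per-cell feature tables.

The image pipeline and the synthetic feature-table generator emit the same
columns, so a classifier trained on either source can score the other.
"""

from __future__ import annotations

#: Fluorescence channels, in storage order (multi-page TIFF page order).
CHANNELS: tuple[str, ...] = ("dapi", "ck", "cd45")

#: Morphology features (units noted in the docs; areas in µm², lengths in µm).
MORPHOLOGY_FEATURES: tuple[str, ...] = (
    "area_um2",
    "perimeter_um",
    "equiv_diameter_um",
    "eccentricity",
    "solidity",
    "form_factor",
)

#: Per-channel intensity feature suffixes.
INTENSITY_SUFFIXES: tuple[str, ...] = (
    "mean",
    "median",
    "max",
    "integrated",
    "corr_mean",  # background-corrected mean (mean inside − annulus median)
    "fold",       # mean inside / annulus median (fold over local background)
)

INTENSITY_FEATURES: tuple[str, ...] = tuple(
    f"{ch}_{suffix}" for ch in CHANNELS for suffix in INTENSITY_SUFFIXES
)

#: Columns a classifier consumes.
FEATURE_COLUMNS: tuple[str, ...] = MORPHOLOGY_FEATURES + INTENSITY_FEATURES

#: Class-label column in labeled tables.
LABEL_COLUMN = "cell_class"

#: Positive (tumor-cell) class label.
POSITIVE_LABEL = "CTC"

#: Negative (leukocyte) class label.
NEGATIVE_LABEL = "WBC"
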