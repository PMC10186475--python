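"""Integral fluorescence quantification for paired marker/DAPI images.

The statistic at the heart of this module is an intensity-weighted
histogram index.  For a single-channel image with histogram counts
``c(b)`` over integer brightness levels ``b``,

    index = sum_b c(b) * b**2

i.e. the per-pixel sum of squared brightness.  Squaring up-weights bright
(stained) structures relative to dim background.  Each stained field is
summarised by the ratio of the marker-channel index to the DAPI
nuclei-channel index, which normalises staining intensity to the amount
of nuclear material in the field; that ratio is the unit of all group
comparisons.

Raw stored intensities are used throughout — no rescaling to [0, 1] and
no background subtraction; background is handled by comparing stained
fields against secondary-antibody-only negative controls.  Both channels
of a pair must share dimensions and bit depth so the ratio is
scale-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .stats import GroupComparison, welch_compare_values

__all__ = [
    "FluorescenceImage",
    "ImagePair",
    "ChannelIndex",
    "FluorescenceRatio",
    "UndefinedRatioError",
    "channel_index",
    "fluorescence_ratio",
    "batch_quantify",
    "aggregate_replicates",
    "control_comparison",
    "group_compare",
    "read_manifest",
    "load_image",
]

SATURATION_WARN_FRACTION = 0.01


class UndefinedRatioError(ValueError):
    """Raised when the nuclei-channel index is zero (no cells in field)."""


@dataclass(frozen=True)
class FluorescenceImage:
    """Single-channel grayscale image with its acquisition bit depth."""

    pixels: np.ndarray
    bit_depth: int = 16
    channel_role: str = "marker"  # {"marker", "nuclei"}

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            raise ValueError(
                "color image supplied; extract a named channel explicitly — "
                "implicit grayscale conversion is refused because channel "
                "identity (red/green = marker, blue = DAPI) is semantic"
            )
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a non-empty 2-D grid")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel values must be integers (raw camera counts)")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError("pixel values outside the bit-depth range")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ImagePair:
    """One imaged field: marker channel + DAPI nuclei channel + metadata."""

    marker: FluorescenceImage
    nuclei: FluorescenceImage
    line: str = ""
    passage: int = 0
    marker_name: str = ""
    bio_rep: int = 1
    tech_rep: int = 1
    is_negative_control: bool = False
    truth: dict = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        """Check the pair invariants; mismatches are reported per-row by
        :func:`batch_quantify` rather than aborting a whole manifest."""
        if self.marker.shape != self.nuclei.shape:
            raise ValueError("marker and nuclei images differ in size")
        if self.marker.bit_depth != self.nuclei.bit_depth:
            raise ValueError("marker and nuclei images differ in bit depth")


@dataclass(frozen=True)
class ChannelIndex:
    value: int
    n_pixels: int
    saturation_fraction: float


@dataclass(frozen=True)
class FluorescenceRatio:
    value: float
    marker_index: int
    nuclei_index: int
    meta: dict = field(default_factory=dict, compare=False)


def channel_index(image: FluorescenceImage) -> ChannelIndex:
    """Intensity-weighted histogram index of one channel.

    Computed from the full integer histogram (one bin per intensity
    level) with integer accumulation, so the result equals the brute
    per-pixel sum of squared brightness exactly at both bit depths.
    """
    px = image.pixels.ravel()
    counts = np.bincount(px, minlength=image.max_value + 1)
    brightness = np.arange(counts.size, dtype=np.int64)
    value = int(np.dot(counts, brightness * brightness))
    sat = float(counts[image.max_value]) / px.size
    if sat > SATURATION_WARN_FRACTION:
        warnings.warn(
            f"{sat:.1%} of pixels saturated in {image.channel_role} channel; "
            "index is biased downward at the detector ceiling",
            stacklevel=2,
        )
    return ChannelIndex(value=value, n_pixels=int(px.size), saturation_fraction=sat)


def fluorescence_ratio(pair: ImagePair) -> FluorescenceRatio:
    """Marker-index / nuclei-index ratio for one field.

    Raises :class:`UndefinedRatioError` when the DAPI channel is entirely
    zero — a field with no detectable nuclei has no meaningful staining
    level.
    """
    pair.validate()
    m = channel_index(pair.marker)
    n = channel_index(pair.nuclei)
    if n.value == 0:
        raise UndefinedRatioError("nuclei-channel index is zero; ratio undefined")
    return FluorescenceRatio(
        value=m.value / n.value,
        marker_index=m.value,
        nuclei_index=n.value,
        meta={
            "line": pair.line,
            "passage": pair.passage,
            "marker": pair.marker_name,
            "bio_rep": pair.bio_rep,
            "tech_rep": pair.tech_rep,
            "is_control": pair.is_negative_control,
        },
    )


def batch_quantify(pairs: Iterable[ImagePair]) -> pd.DataFrame:
    """Quantify a manifest of image pairs into a tidy table.

    One row per input pair, in input order.  Pairs whose ratio cannot be
    computed (no nuclei signal) are flagged via the ``error`` column, not
    dropped, so the output row count always equals the input pair count.
    """
    rows = []
    for pair in pairs:
        row = {
            "line": pair.line,
            "passage": pair.passage,
            "marker": pair.marker_name,
            "bio_rep": pair.bio_rep,
            "tech_rep": pair.tech_rep,
            "is_control": pair.is_negative_control,
            "marker_index": np.nan,
            "nuclei_index": np.nan,
            "ratio": np.nan,
            "error": "",
        }
        try:
            r = fluorescence_ratio(pair)
        except (UndefinedRatioError, ValueError) as exc:
            row["error"] = str(exc)
        else:
            row.update(
                marker_index=r.marker_index,
                nuclei_index=r.nuclei_index,
                ratio=r.value,
            )
        rows.append(row)
    columns = [
        "line", "passage", "marker", "bio_rep", "tech_rep", "is_control",
        "marker_index", "nuclei_index", "ratio", "error",
    ]
    return pd.DataFrame(rows, columns=columns)


def aggregate_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within each biological replicate.

    Group tests operate on biological replicates; averaging technical
    repeats first avoids pseudo-replication.  Rows flagged with errors
    are excluded from the averages.
    """
    ok = results[results["error"] == ""]
    keys = ["line", "passage", "marker", "is_control", "bio_rep"]
    agg = (
        ok.groupby(keys, sort=True)["ratio"]
        .agg(ratio="mean", n_tech="size")
        .reset_index()
    )
    return agg


def control_comparison(
    stained: Sequence[float], controls: Sequence[float]
) -> GroupComparison:
    """One-sided Welch comparison of stained ratios against negative controls.

    Specific staining can only add fluorescence over the secondary-only
    background, so detection is the one-sided hypothesis stained >
    control; a marker is called detected when the mean difference is
    positive and p < 0.05.
    """
    return welch_compare_values(
        stained, controls, labels=("stained", "control"), alternative="greater"
    )


def is_detected(comparison: GroupComparison) -> bool:
    """Detection call from a stained-vs-control comparison."""
    return (
        comparison.mean_difference > 0
        and comparison.p_value is not None
        and comparison.p_value < 0.05
    )


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided Welch comparison between two conditions (e.g. passages)."""
    return welch_compare_values(group_a, group_b, labels=labels, alternative="two-sided")


# ---------------------------------------------------------------------------
# I/O

def load_image(path: str | Path, channel_role: str = "marker") -> FluorescenceImage:
    """Read a single-channel grayscale TIFF into a FluorescenceImage."""
    px = tifffile.imread(str(path))
    if px.dtype == np.uint8:
        depth = 8
    elif px.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported TIFF dtype {px.dtype}; expected uint8/uint16")
    return FluorescenceImage(pixels=px, bit_depth=depth, channel_role=channel_role)


MANIFEST_COLUMNS = [
    "marker_path", "dapi_path", "line", "passage", "marker",
    "bio_rep", "tech_rep", "is_control",
]


def read_manifest(manifest_csv: str | Path) -> list[ImagePair]:
    """Load image pairs listed in a manifest CSV.

    Paths in the manifest are resolved relative to the manifest's own
    directory so a simulated dataset is relocatable.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    root = manifest_csv.parent
    pairs = []
    for rec in df.itertuples(index=False):
        pairs.append(
            ImagePair(
                marker=load_image(root / rec.marker_path, "marker"),
                nuclei=load_image(root / rec.dapi_path, "nuclei"),
                line=str(rec.line),
                passage=int(rec.passage),
                marker_name=str(rec.marker),
                bio_rep=int(rec.bio_rep),
                tech_rep=int(rec.tech_rep),
                is_negative_control=bool(rec.is_control),
            )
        )
    return pairs
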