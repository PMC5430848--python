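"""Parametric 2D model of the microfluidic co-culture device.

The device is modelled in physical (micron) coordinates with the image
convention: origin at the top-left corner, x increasing rightward, y
increasing downward. Left to right it consists of a medium channel, the
left tumor chamber, an array of narrow connecting channels, the central
immune chamber, a second channel array, the right tumor chamber and the
right medium channel. All compartments are axis-aligned rectangles; the
chip is quasi-2D, so the channel height (10 µm) and chamber depth (150 µm)
are carried as metadata only and play no role in the planar analysis.

Default physical dimensions: connecting channels 12 µm wide x 200 µm long,
tumor chambers 500 x 1000 µm footprint, immune chamber 1200 µm wide.

Rectangles are half-open, ``[x0, x1) x [y0, y1)``, except that connecting
channels claim both of their x-boundaries (closed interval in x) and take
classification priority. This makes the pixel/point partition exhaustive
and puts the shared immune/channel and channel/tumor edges inside the
channel on both sides of the device, so boundary-crossing events are
detected deterministically regardless of travel direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "REGION_LABELS",
    "Rect",
    "DeviceLayout",
    "RegionMap",
    "LayoutSizeError",
    "make_default_layout",
    "rasterize_regions",
    "classify_point",
    "classify_points",
    "crossing_boundaries",
]

#: Exhaustive, mutually exclusive region labels; integer codes index this list.
REGION_LABELS = (
    "background",
    "immune",
    "channel_left",
    "channel_right",
    "tumor_left",
    "tumor_right",
    "medium",
)
LABEL_CODE = {name: i for i, name in enumerate(REGION_LABELS)}

# Fig-derived default physical dimensions, µm.
CHANNEL_WIDTH_UM = 12.0
CHANNEL_LENGTH_UM = 200.0
CHANNEL_HEIGHT_UM = 10.0  # metadata only (quasi-2D model)
TUMOR_WIDTH_UM = 500.0
TUMOR_SPAN_UM = 1000.0
TUMOR_DEPTH_UM = 150.0  # metadata only
IMMUNE_WIDTH_UM = 1200.0
MEDIUM_WIDTH_UM = 200.0
MARGIN_UM = 20.0
DEFAULT_N_CHANNELS = 10


class LayoutSizeError(ValueError):
    """Image extent cannot contain the requested physical layout."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in µm, half-open ``[x0, x1) x [y0, y1)``."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x: float, y: float, *, closed_x: bool = False) -> bool:
        in_x = self.x0 <= x <= self.x1 if closed_x else self.x0 <= x < self.x1
        return in_x and self.y0 <= y < self.y1

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    def to_px(self, pixel_size: float) -> tuple[int, int, int, int]:
        """Half-open pixel-index bounds (x0, y0, x1, y1)."""
        return (
            int(round(self.x0 / pixel_size)),
            int(round(self.y0 / pixel_size)),
            int(round(self.x1 / pixel_size)),
            int(round(self.y1 / pixel_size)),
        )


@dataclass(frozen=True)
class DeviceLayout:
    """Compartment map of the device with pixel calibration.

    ``connecting_channels`` maps side ("left"/"right") to the list of channel
    rectangles; ``tumor_chambers`` and ``medium_channels`` map side to one
    rectangle each. ``image_extent`` is (height, width) in pixels.
    """

    pixel_size: float
    image_extent: tuple[int, int]
    immune_chamber: Rect
    connecting_channels: dict[str, list[Rect]]
    tumor_chambers: dict[str, Rect]
    medium_channels: dict[str, Rect]
    channel_height_um: float = CHANNEL_HEIGHT_UM
    tumor_depth_um: float = TUMOR_DEPTH_UM

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        h_px, w_px = self.image_extent
        named = list(self._named_rects())
        for name, rect in named:
            if rect.width <= 0 or rect.height <= 0:
                raise LayoutSizeError(f"rectangle {name!r} has non-positive size")
            if rect.x1 > w_px * self.pixel_size + 1e-9 or rect.y1 > h_px * self.pixel_size + 1e-9:
                raise LayoutSizeError(
                    f"rectangle {name!r} (x1={rect.x1:.1f} µm, y1={rect.y1:.1f} µm) "
                    f"exceeds image extent {h_px}x{w_px} px at "
                    f"{self.pixel_size} µm/px"
                )
            if rect.x0 < -1e-9 or rect.y0 < -1e-9:
                raise LayoutSizeError(f"rectangle {name!r} extends before the origin")
        for i, (name_a, a) in enumerate(named):
            for name_b, b in named[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"rectangles {name_a!r} and {name_b!r} overlap")
        for side, channels in self.connecting_channels.items():
            immune = self.immune_chamber
            tumor = self.tumor_chambers[side]
            for k, ch in enumerate(channels):
                touches_immune = math.isclose(ch.x1, immune.x0) or math.isclose(
                    ch.x0, immune.x1
                )
                touches_tumor = math.isclose(ch.x1, tumor.x0) or math.isclose(
                    ch.x0, tumor.x1
                )
                if not (touches_immune and touches_tumor):
                    raise ValueError(
                        f"channel {side}[{k}] must bridge the immune chamber "
                        "and its tumor chamber"
                    )

    def _named_rects(self):
        yield "immune", self.immune_chamber
        for side, rects in self.connecting_channels.items():
            for k, r in enumerate(rects):
                yield f"channel_{side}[{k}]", r
        for side, r in self.tumor_chambers.items():
            yield f"tumor_{side}", r
        for side, r in self.medium_channels.items():
            yield f"medium_{side}", r

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the image in µm."""
        h_px, w_px = self.image_extent
        return (h_px * self.pixel_size, w_px * self.pixel_size)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def rect_d(r: Rect) -> dict:
            return {"x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}

        return {
            "pixel_size": self.pixel_size,
            "image_extent": {"height": self.image_extent[0], "width": self.image_extent[1]},
            "immune_chamber": rect_d(self.immune_chamber),
            "connecting_channels": {
                side: [rect_d(r) for r in rects]
                for side, rects in self.connecting_channels.items()
            },
            "tumor_chambers": {s: rect_d(r) for s, r in self.tumor_chambers.items()},
            "medium_channels": {s: rect_d(r) for s, r in self.medium_channels.items()},
            "channel_height_um": self.channel_height_um,
            "tumor_depth_um": self.tumor_depth_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceLayout":
        if "pixel_size" not in d:
            raise ValueError("layout config missing mandatory field 'pixel_size'")

        def rect(rd: dict) -> Rect:
            return Rect(float(rd["x0"]), float(rd["y0"]), float(rd["x1"]), float(rd["y1"]))

        ext = d["image_extent"]
        return cls(
            pixel_size=float(d["pixel_size"]),
            image_extent=(int(ext["height"]), int(ext["width"])),
            immune_chamber=rect(d["immune_chamber"]),
            connecting_channels={
                side: [rect(r) for r in rects]
                for side, rects in d["connecting_channels"].items()
            },
            tumor_chambers={s: rect(r) for s, r in d["tumor_chambers"].items()},
            medium_channels={s: rect(r) for s, r in d["medium_channels"].items()},
            channel_height_um=float(d.get("channel_height_um", CHANNEL_HEIGHT_UM)),
            tumor_depth_um=float(d.get("tumor_depth_um", TUMOR_DEPTH_UM)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DeviceLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RegionMap:
    """Per-pixel region labels (integer codes into REGION_LABELS)."""

    labels: np.ndarray = field(repr=False)
    layout: DeviceLayout

    def label_at(self, x_um: float, y_um: float) -> str:
        j = int(x_um / self.layout.pixel_size)
        i = int(y_um / self.layout.pixel_size)
        return REGION_LABELS[self.labels[i, j]]

    def counts(self) -> dict[str, int]:
        vals, n = np.unique(self.labels, return_counts=True)
        return {REGION_LABELS[v]: int(c) for v, c in zip(vals, n)}


def make_default_layout(
    pixel_size: float,
    image_extent: tuple[int, int] | None = None,
    n_channels_per_side: int = DEFAULT_N_CHANNELS,
    *,
    immune_width_um: float = IMMUNE_WIDTH_UM,
    channel_width_um: float = CHANNEL_WIDTH_UM,
    channel_length_um: float = CHANNEL_LENGTH_UM,
    tumor_width_um: float = TUMOR_WIDTH_UM,
    tumor_span_um: float = TUMOR_SPAN_UM,
    medium_width_um: float = MEDIUM_WIDTH_UM,
    margin_um: float = MARGIN_UM,
) -> DeviceLayout:
    """Build the standard device layout at the given calibration.

    The compartments are laid out symmetrically along x:
    margin | medium | tumor | channels | immune | channels | tumor | medium
    | margin, with ``n_channels_per_side`` channels evenly spaced along the
    shared tumor-chamber edge (span ``tumor_span_um`` in y). If
    ``image_extent`` is omitted it is computed to fit the layout exactly.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if n_channels_per_side < 0:
        raise ValueError("n_channels_per_side must be >= 0")
    if n_channels_per_side * channel_width_um > tumor_span_um:
        raise LayoutSizeError(
            f"{n_channels_per_side} channels of width {channel_width_um} µm do "
            f"not fit along a {tumor_span_um} µm chamber edge"
        )

    x = margin_um
    medium_l = Rect(x, margin_um, x + medium_width_um, margin_um + tumor_span_um)
    x += medium_width_um
    tumor_l = Rect(x, margin_um, x + tumor_width_um, margin_um + tumor_span_um)
    x += tumor_width_um
    chan_l_x0, chan_l_x1 = x, x + channel_length_um
    x += channel_length_um
    immune = Rect(x, margin_um, x + immune_width_um, margin_um + tumor_span_um)
    x += immune_width_um
    chan_r_x0, chan_r_x1 = x, x + channel_length_um
    x += channel_length_um
    tumor_r = Rect(x, margin_um, x + tumor_width_um, margin_um + tumor_span_um)
    x += tumor_width_um
    medium_r = Rect(x, margin_um, x + medium_width_um, margin_um + tumor_span_um)
    x += medium_width_um + margin_um

    total_w_um = x
    total_h_um = tumor_span_um + 2 * margin_um

    def channel_rects(cx0: float, cx1: float) -> list[Rect]:
        rects = []
        pitch = tumor_span_um / n_channels_per_side if n_channels_per_side else 0.0
        for k in range(n_channels_per_side):
            cy = margin_um + (k + 0.5) * pitch
            rects.append(
                Rect(cx0, cy - channel_width_um / 2, cx1, cy + channel_width_um / 2)
            )
        return rects

    if image_extent is None:
        image_extent = (
            int(math.ceil(total_h_um / pixel_size)),
            int(math.ceil(total_w_um / pixel_size)),
        )
    else:
        h_px, w_px = image_extent
        if w_px * pixel_size < total_w_um or h_px * pixel_size < total_h_um:
            raise LayoutSizeError(
                f"image extent {h_px}x{w_px} px at {pixel_size} µm/px cannot hold "
                f"the layout ({total_h_um:.0f}x{total_w_um:.0f} µm); the full "
                f"chamber row (medium+tumor+channels+immune) is the offending span"
            )

    return DeviceLayout(
        pixel_size=pixel_size,
        image_extent=image_extent,
        immune_chamber=immune,
        connecting_channels={
            "left": channel_rects(chan_l_x0, chan_l_x1),
            "right": channel_rects(chan_r_x0, chan_r_x1),
        },
        tumor_chambers={"left": tumor_l, "right": tumor_r},
        medium_channels={"left": medium_l, "right": medium_r},
    )


def classify_point(layout: DeviceLayout, x_um: float, y_um: float) -> str:
    """Region label of a physical point.

    Channels are tested first with closed x-intervals, so points on the
    immune/channel and channel/tumor shared edges classify as channel.
    Raises ValueError for points outside the image extent.
    """
    h_um, w_um = layout.extent_um
    if not (0 <= x_um <= w_um and 0 <= y_um <= h_um):
        raise ValueError(f"point ({x_um}, {y_um}) µm outside image extent")
    for side in ("left", "right"):
        for r in layout.connecting_channels[side]:
            if r.contains(x_um, y_um, closed_x=True):
                return f"channel_{side}"
    for side in ("left", "right"):
        if layout.tumor_chambers[side].contains(x_um, y_um):
            return f"tumor_{side}"
    if layout.immune_chamber.contains(x_um, y_um):
        return "immune"
    for side in ("left", "right"):
        if layout.medium_channels[side].contains(x_um, y_um):
            return "medium"
    return "background"


def classify_points(layout: DeviceLayout, x_um, y_um) -> np.ndarray:
    """Vectorized classify_point; returns integer label codes."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    codes = np.zeros(x.shape, dtype=np.int8)

    def in_rect(r: Rect, closed_x: bool = False) -> np.ndarray:
        in_x = (x >= r.x0) & ((x <= r.x1) if closed_x else (x < r.x1))
        return in_x & (y >= r.y0) & (y < r.y1)

    for side in ("left", "right"):
        codes[in_rect(layout.medium_channels[side])] = LABEL_CODE["medium"]
    codes[in_rect(layout.immune_chamber)] = LABEL_CODE["immune"]
    for side in ("left", "right"):
        codes[in_rect(layout.tumor_chambers[side])] = LABEL_CODE[f"tumor_{side}"]
    for side in ("left", "right"):
        for r in layout.connecting_channels[side]:
            codes[in_rect(r, closed_x=True)] = LABEL_CODE[f"channel_{side}"]
    return codes


def rasterize_regions(layout: DeviceLayout) -> RegionMap:
    """Rasterize the layout to a per-pixel label image.

    Pixels are painted per rectangle on half-open pixel intervals obtained
    by rounding the µm bounds; channels are painted last so shared boundary
    pixels carry the channel label.
    """
    h_px, w_px = layout.image_extent
    labels = np.zeros((h_px, w_px), dtype=np.int8)
    ps = layout.pixel_size

    def paint(rect: Rect, code: int) -> None:
        x0, y0, x1, y1 = rect.to_px(ps)
        labels[max(y0, 0) : min(y1, h_px), max(x0, 0) : min(x1, w_px)] = code

    for side in ("left", "right"):
        paint(layout.medium_channels[side], LABEL_CODE["medium"])
    paint(layout.immune_chamber, LABEL_CODE["immune"])
    for side in ("left", "right"):
        paint(layout.tumor_chambers[side], LABEL_CODE[f"tumor_{side}"])
    for side in ("left", "right"):
        for r in layout.connecting_channels[side]:
            paint(r, LABEL_CODE[f"channel_{side}"])
    return RegionMap(labels=labels, layout=layout)


def crossing_boundaries(
    layout: DeviceLayout, side: str
) -> tuple[tuple[tuple[float, float], tuple[float, float]], tuple[tuple[float, float], tuple[float, float]]]:
    """Entry and exit lines of one channel array, in µm.

    Returns ``(entry, exit)`` where each line is ``((x, y_top), (x, y_bot))``:
    the entry line lies on the immune/channel interface and the exit line on
    the channel/tumor interface, both spanning the channel array (from the
    top edge of the first channel to the bottom edge of the last).
    """
    channels = layout.connecting_channels.get(side, [])
    if not channels:
        raise ValueError(f"side {side!r} has no connecting channels")
    y_top = min(r.y0 for r in channels)
    y_bot = max(r.y1 for r in channels)
    immune = layout.immune_chamber
    x_entry = channels[0].x1 if channels[0].x1 <= immune.x0 + 1e-9 else channels[0].x0
    x_exit = channels[0].x0 if x_entry == channels[0].x1 else channels[0].x1
    return ((x_entry, y_top), (x_entry, y_bot)), ((x_exit, y_top), (x_exit, y_bot))
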