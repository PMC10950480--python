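"""Multi-panel publication figure assembly.

A :class:`FigurePlan` is a physical canvas (mm at a target dpi) holding
ordered, non-overlapping panels with fractional bounds, so layouts are
dpi-independent. Structure panels come from the renderer; statistical
panels are accepted as pre-rendered raster images — arbitrary plotting
callbacks are out of scope to keep composition deterministic.

Panel labels are lowercase bold letters at a fixed 2 mm inset from each
panel's top-left corner. Composing the same plan twice yields
byte-identical images.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from PIL import Image, ImageDraw, ImageFont

from .errors import LayoutError
from .render import RasterImage, image_size

__all__ = [
    "JournalPreset",
    "GENERIC_PRESET",
    "PRESETS",
    "Panel",
    "FigurePlan",
    "init_figure",
    "add_panel",
    "place_image",
    "panel_pixel_rect",
    "compose",
]

LABEL_INSET_MM = 2.0


@dataclass(frozen=True)
class JournalPreset:
    """A journal's physical figure constraints."""

    name: str
    single_mm: float
    double_mm: float
    max_height_mm: float
    dpi: int = 300

    def __post_init__(self):
        if not (0 < self.single_mm < self.double_mm):
            raise LayoutError("preset needs 0 < single column < double column")
        if self.dpi < 300:
            raise LayoutError(f"preset dpi must be >= 300, got {self.dpi}")


# Column widths common to the major life-science journals.
GENERIC_PRESET = JournalPreset("generic", 89.0, 183.0, 247.0, 300)
PRESETS = {"generic": GENERIC_PRESET}


@dataclass
class Panel:
    bounds: tuple[float, float, float, float]  # x0, y0, x1, y1 fractions
    label: str
    content: RasterImage | None = None
    fit: str = "contain"


@dataclass
class FigurePlan:
    width_mm: float
    height_mm: float
    dpi: int
    panels: list[Panel] = field(default_factory=list)

    def panel(self, label: str) -> Panel:
        for p in self.panels:
            if p.label == label:
                return p
        raise LayoutError(
            f"no panel labelled {label!r}; have {[p.label for p in self.panels]}"
        )


def init_figure(
    preset: JournalPreset = GENERIC_PRESET,
    columns: str = "single",
    height_mm: float = 100.0,
    dpi: int | None = None,
) -> FigurePlan:
    """Empty plan at the preset's column width and default dpi."""
    if columns not in ("single", "double"):
        raise LayoutError(f"columns must be 'single' or 'double', got {columns!r}")
    if not (0 < height_mm <= preset.max_height_mm):
        raise LayoutError(
            f"height {height_mm} mm outside (0, {preset.max_height_mm}] "
            f"for preset {preset.name!r}"
        )
    width = preset.single_mm if columns == "single" else preset.double_mm
    return FigurePlan(
        width_mm=width, height_mm=height_mm, dpi=dpi or preset.dpi
    )


def _check_bounds(bounds) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = (float(v) for v in bounds)
    if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
        raise LayoutError(f"bounds {bounds} must satisfy 0 <= lo < hi <= 1")
    return x0, y0, x1, y1


def _interiors_overlap(a, b) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def _next_label(plan: FigurePlan) -> str:
    used = {p.label for p in plan.panels}
    letters = string.ascii_lowercase
    n = len(plan.panels)
    candidate = (
        letters[n] if n < 26 else letters[n // 26 - 1] + letters[n % 26]
    )
    while candidate in used:  # user-assigned labels may collide with auto ones
        n += 1
        candidate = (
            letters[n] if n < 26 else letters[n // 26 - 1] + letters[n % 26]
        )
    return candidate


def add_panel(plan: FigurePlan, bounds, label: str | None = None) -> FigurePlan:
    """Append a panel; labels auto-assign as a, b, c, ... when omitted."""
    bounds = _check_bounds(bounds)
    for p in plan.panels:
        if _interiors_overlap(bounds, p.bounds):
            raise LayoutError(
                f"bounds {bounds} overlap existing panel {p.label!r} {p.bounds}"
            )
    if label is None:
        label = _next_label(plan)
    elif any(p.label == label for p in plan.panels):
        raise LayoutError(f"duplicate panel label {label!r}")
    plan.panels.append(Panel(bounds=bounds, label=label))
    return plan


def place_image(
    plan: FigurePlan, label: str, image: RasterImage, fit: str = "contain"
) -> FigurePlan:
    """Attach a raster to a panel; 'contain' preserves aspect, 'stretch'
    fills the exact panel rect."""
    if fit not in ("contain", "stretch"):
        raise LayoutError(f"fit must be 'contain' or 'stretch', got {fit!r}")
    panel = plan.panel(label)
    panel.content = image
    panel.fit = fit
    return plan


def panel_pixel_rect(plan: FigurePlan, panel: Panel) -> tuple[int, int, int, int]:
    """Panel bounds in canvas pixels (x0, y0, x1, y1)."""
    W, H = image_size(plan.width_mm, plan.height_mm, plan.dpi)
    x0, y0, x1, y1 = panel.bounds
    return (round(x0 * W), round(y0 * H), round(x1 * W), round(y1 * H))


def _blit(canvas: Image.Image, panel: Panel, rect) -> None:
    x0, y0, x1, y1 = rect
    pw, ph = x1 - x0, y1 - y0
    if pw < 1 or ph < 1 or panel.content is None:
        return
    src = panel.content.to_pil()
    if panel.fit == "stretch":
        canvas.paste(src.resize((pw, ph), Image.NEAREST), (x0, y0))
        return
    scale = min(pw / src.width, ph / src.height)
    nw, nh = max(1, round(src.width * scale)), max(1, round(src.height * scale))
    nw, nh = min(nw, pw), min(nh, ph)
    canvas.paste(
        src.resize((nw, nh), Image.NEAREST),
        (x0 + (pw - nw) // 2, y0 + (ph - nh) // 2),
    )


def compose(plan: FigurePlan) -> RasterImage:
    """Rasterize the plan: white canvas, panel contents blitted at their
    pixel rects, bold lowercase labels at the 2 mm inset. Deterministic:
    nothing outside a panel's rect is written except its label text."""
    W, H = image_size(plan.width_mm, plan.height_mm, plan.dpi)
    canvas = Image.new("RGB", (W, H), (255, 255, 255))
    draw = ImageDraw.Draw(canvas)
    font = ImageFont.load_default()
    inset = round(LABEL_INSET_MM / 25.4 * plan.dpi)
    for panel in plan.panels:
        rect = panel_pixel_rect(plan, panel)
        _blit(canvas, panel, rect)
    for panel in plan.panels:
        rect = panel_pixel_rect(plan, panel)
        pos = (rect[0] + inset, rect[1] + inset)
        # fake bold: double strike one pixel apart (the embedded default
        # bitmap font has no bold face)
        draw.text(pos, panel.label, fill=(0, 0, 0), font=font)
        draw.text((pos[0] + 1, pos[1]), panel.label, fill=(0, 0, 0), font=font)
    return RasterImage.from_pil(canvas, dpi=plan.dpi)
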