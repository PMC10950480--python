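"""Deterministic backbone-trace rasterization.

The renderer draws the CA trace of a posed, colored structure as hard
(non-anti-aliased) line segments under an orthographic camera, using the
painter's algorithm for occlusion. Identical inputs always produce
byte-identical pixel buffers: there is no hidden randomness, no
timestamp, and no anti-aliasing on the default path, so every rendered
pixel is either background white or one of the assignment's colors.

"Cartoon" emphasis is approximated by scaling the trace line width with
a per-residue radius factor rather than building ribbon geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .coloring import NEUTRAL_GREY, ColorAssignment
from .errors import RenderError
from .structure_io import StructureModel

__all__ = [
    "Camera",
    "RasterImage",
    "image_size",
    "standard_camera",
    "project",
    "render_trace",
]


@dataclass(frozen=True)
class Camera:
    """Orthographic camera: proper view rotation, center (Å), px per Å."""

    rotation: np.ndarray
    center: np.ndarray
    scale: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise RenderError("camera rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise RenderError("camera rotation must be proper (det +1)")
        if self.scale <= 0:
            raise RenderError(f"camera scale must be > 0, got {self.scale}")


class RasterImage:
    """8-bit RGB raster with a white background and dpi metadata."""

    def __init__(self, array: np.ndarray, dpi: int = 300):
        array = np.asarray(array, dtype=np.uint8)
        if array.ndim != 3 or array.shape[2] != 3 or min(array.shape[:2]) < 1:
            raise RenderError(f"expected H x W x 3 pixel grid, got {array.shape}")
        self.array = array
        self.dpi = int(dpi)

    @classmethod
    def blank(cls, width: int, height: int, dpi: int = 300) -> "RasterImage":
        if width < 1 or height < 1:
            raise RenderError(f"image size must be >= 1 px, got {width}x{height}")
        return cls(np.full((height, width, 3), 255, dtype=np.uint8), dpi=dpi)

    @classmethod
    def from_pil(cls, image: Image.Image, dpi: int = 300) -> "RasterImage":
        return cls(np.asarray(image.convert("RGB")), dpi=dpi)

    @property
    def width(self) -> int:
        return self.array.shape[1]

    @property
    def height(self) -> int:
        return self.array.shape[0]

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.array, mode="RGB")

    def save(self, path) -> None:
        """Write a PNG (or TIFF by extension) with dpi metadata, no
        timestamps — repeated saves are byte-identical."""
        self.to_pil().save(path, dpi=(self.dpi, self.dpi))

    def tobytes(self) -> bytes:
        return self.array.tobytes()


def image_size(width_mm: float, height_mm: float, dpi: int) -> tuple[int, int]:
    """Pixel dimensions of a physical canvas: round(mm / 25.4 * dpi)."""
    if width_mm <= 0 or height_mm <= 0 or dpi <= 0:
        raise RenderError("canvas dimensions and dpi must be positive")
    return (
        max(1, round(width_mm / 25.4 * dpi)),
        max(1, round(height_mm / 25.4 * dpi)),
    )


def _all_ca_coords(model: StructureModel) -> np.ndarray:
    coords = [
        a.coords
        for _, res in model.residues()
        for a in res.atoms
        if a.name == "CA" and not a.is_hetatm
    ]
    return np.array(coords, dtype=float) if coords else np.empty((0, 3))


def standard_camera(
    model: StructureModel,
    target_px: tuple[int, int],
    margin_frac: float = 0.05,
) -> Camera:
    """Principal-axes camera: a reproducible 'reasonable' viewpoint.

    The CA covariance eigenvectors become the view axes (largest variance
    horizontal, second vertical); the axis-sign ambiguity is fixed by
    requiring the first CA's projected x and y to be non-negative, with
    the depth axis completed right-handed. The center is the CA centroid
    and the scale fits the projected bounding box inside
    (1 - 2 * margin_frac) of the frame. A degenerate (collinear) trace
    falls back to the identity rotation.
    """
    coords = _all_ca_coords(model)
    if len(coords) < 3:
        raise RenderError(f"need >= 3 CA atoms for a camera, got {len(coords)}")
    if not (0 <= margin_frac < 0.5):
        raise RenderError(f"margin_frac must be in [0, 0.5), got {margin_frac}")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    if eigvals[order[1]] < 1e-9:  # collinear trace: fall back to identity
        R = np.eye(3)
    else:
        ax0 = eigvecs[:, order[0]]
        ax1 = eigvecs[:, order[1]]
        first = centered[0]
        if first @ ax0 < 0:
            ax0 = -ax0
        if first @ ax1 < 0:
            ax1 = -ax1
        R = np.stack([ax0, ax1, np.cross(ax0, ax1)])
    projected = centered @ R.T
    # frame center is the centroid, so fit the worst one-sided extent
    half_x = np.abs(projected[:, 0]).max()
    half_y = np.abs(projected[:, 1]).max()
    avail_w = target_px[0] * (1.0 - 2.0 * margin_frac) / 2.0
    avail_h = target_px[1] * (1.0 - 2.0 * margin_frac) / 2.0
    options = []
    if half_x > 1e-12:
        options.append(avail_w / half_x)
    if half_y > 1e-12:
        options.append(avail_h / half_y)
    scale = min(options) if options else 1.0
    return Camera(rotation=R, center=center, scale=scale)


def project(camera: Camera, points: np.ndarray, size_px: tuple[int, int]):
    """Orthographic projection to pixel coordinates plus per-point depth.

    A point maps to ``frame_center + scale * (x, -y)`` of its camera-frame
    coordinates (pixel origin top-left); depth is the camera-frame z,
    larger meaning farther from the viewer.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cam = (points - camera.center) @ np.asarray(camera.rotation, dtype=float).T
    xy = np.empty((len(points), 2))
    xy[:, 0] = size_px[0] / 2.0 + camera.scale * cam[:, 0]
    xy[:, 1] = size_px[1] / 2.0 - camera.scale * cam[:, 1]
    return xy, cam[:, 2]


def _to_255(rgb) -> tuple[int, int, int]:
    return tuple(int(round(255 * float(c))) for c in rgb)


def render_trace(
    model: StructureModel,
    colors: ColorAssignment,
    camera: Camera,
    size_px: tuple[int, int],
    radii: dict | None = None,
    hidden: frozenset = frozenset(),
    base_width: int = 3,
) -> RasterImage:
    """Rasterize consecutive CA-CA segments of each chain.

    Segment width is ``base_width`` times the residue's radius factor and
    the segment takes the color of its first residue; single visible
    residues are drawn as dots. Segments are painted back-to-front by
    mean depth; atoms in *hidden* are omitted together with their
    incident segments.
    """
    if size_px[0] < 1 or size_px[1] < 1:
        raise RenderError(f"image size must be >= 1 px, got {size_px}")
    if radii is None:
        radii = colors.radii or {}
    img = Image.new("RGB", (int(size_px[0]), int(size_px[1])), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    primitives = []  # (mean_depth, kind, payload)
    for chain in model.chains:
        nodes = []
        for res in chain.residues:
            ca = next(
                (a for a in res.atoms if a.name == "CA" and not a.is_hetatm), None
            )
            if ca is None or ca.serial in hidden:
                nodes.append(None)
                continue
            color = _to_255(colors.colors.get(ca.serial, NEUTRAL_GREY))
            factor = radii.get((chain.chain_id, res.res_seq), 1.0)
            nodes.append((ca.coords, color, factor))
        coords = np.array([n[0] for n in nodes if n is not None])
        if not len(coords):
            continue
        xy, depth = project(camera, coords, size_px)
        k = 0
        placed = []
        for n in nodes:
            if n is None:
                placed.append(None)
            else:
                placed.append((xy[k], depth[k], n[1], n[2]))
                k += 1
        for i in range(len(placed)):
            if placed[i] is None:
                continue
            p_xy, p_depth, color, factor = placed[i]
            width = max(1, int(round(base_width * factor)))
            neighbor = placed[i + 1] if i + 1 < len(placed) else None
            if neighbor is not None:
                q_xy, q_depth, _, _ = neighbor
                primitives.append(
                    (
                        (p_depth + q_depth) / 2.0,
                        "line",
                        (tuple(p_xy), tuple(q_xy), color, width),
                    )
                )
            prev = placed[i - 1] if i > 0 else None
            if neighbor is None and prev is None:
                # isolated residue: a dot of the line width
                primitives.append((p_depth, "dot", (tuple(p_xy), color, width)))
    primitives.sort(key=lambda item: -item[0])  # farthest first
    for _, kind, payload in primitives:
        if kind == "line":
            p, q, color, width = payload
            draw.line([p, q], fill=color, width=width)
        else:
            p, color, width = payload
            r = max(1, width)
            draw.ellipse(
                [p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=color
            )
    return RasterImage.from_pil(img, dpi=300)
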