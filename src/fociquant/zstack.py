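"""Z-stack preparation: analysis-plane selection and 3-slice maximum projection.

In tissue cultures cells lie on top of each other, so a full-stack maximum
projection merges nuclei from different depths.  Instead, the DAPI plane
with the highest mean intensity is selected as the analysis plane, and the
foci channel is reduced to a maximum projection of the slices around that
plane so that slightly out-of-focus foci remain distinguishable from
background noise.  The number of planes actually projected times the z step
is the projection height, which later becomes the denominator of the
foci-per-volume density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PlaneImage, ZStack

__all__ = ["select_focus_plane", "max_project_around", "Projection"]


@dataclass(frozen=True)
class Projection:
    """A maximum projection together with its physical height."""

    plane: PlaneImage
    planes_used: int
    height_um: float


def select_focus_plane(stack: ZStack) -> tuple[int, PlaneImage]:
    """Return the index and raster of the plane with the highest mean intensity.

    The mean is the arithmetic mean over all pixels, background included.
    Ties break to the lowest index.
    """
    means = stack.planes.reshape(stack.n_planes, -1).mean(axis=1)
    index = int(np.argmax(means))  # argmax returns the first maximum
    return index, stack.plane(index)


def max_project_around(stack: ZStack, center_index: int, half_width: int = 1) -> Projection:
    """Pixelwise maximum over planes ``[center−half_width, center+half_width]``.

    At stack edges the window is clamped to the valid plane range (not
    shifted, not zero-padded) and the recorded projection height shrinks
    accordingly: ``height_um = planes_used × z_step_um``.
    """
    if not (0 <= center_index < stack.n_planes):
        raise ValueError(f"center_index {center_index} outside [0, {stack.n_planes})")
    if half_width < 0:
        raise ValueError("half_width must be ≥ 0")
    lo = max(0, center_index - half_width)
    hi = min(stack.n_planes - 1, center_index + half_width)
    planes_used = hi - lo + 1
    raster = stack.planes[lo : hi + 1].max(axis=0)
    return Projection(
        plane=PlaneImage(raster=raster, pixel_size_um=stack.pixel_size_um),
        planes_used=planes_used,
        height_um=planes_used * stack.z_step_um,
    )
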