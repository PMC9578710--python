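"""Pixel-grid cell geometry: compartment label maps and membrane faces.

The spatial domain of the PDE work is a regular 2D grid with per-pixel labels
exterior (0), cytoplasm (1), nucleus (2) and a physical pixel size in µm.
Membrane faces are the 4-adjacent cross-compartment pixel pairs derived from
the label map; nuclear-membrane faces carry the import/export fluxes, and a
valid cell has no nucleus pixel touching the exterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

EXTERIOR, CYTOPLASM_LABEL, NUCLEUS_LABEL = 0, 1, 2

__all__ = [
    "EXTERIOR",
    "CYTOPLASM_LABEL",
    "NUCLEUS_LABEL",
    "CompartmentGeometry",
    "membrane_faces",
]


def membrane_faces(label_map: np.ndarray, a: int, b: int) -> np.ndarray:
    """All 4-adjacent pixel pairs (i_a, i_b) with labels ``a`` and ``b``.

    Returns an (n, 2) array of flattened row-major pixel indices, the
    ``a``-labelled pixel first.  Each unordered adjacent pair appears once.
    """
    lab = np.asarray(label_map)
    h, w = lab.shape
    flat = np.arange(h * w).reshape(h, w)
    pairs = []
    for sl_p, sl_q in (
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),  # vertical
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),  # horizontal
    ):
        lp, lq = lab[sl_p], lab[sl_q]
        fp, fq = flat[sl_p], flat[sl_q]
        m_ab = (lp == a) & (lq == b)
        m_ba = (lp == b) & (lq == a)
        pairs.append(np.stack([fp[m_ab], fq[m_ab]], axis=1))
        pairs.append(np.stack([fq[m_ba], fp[m_ba]], axis=1))
    out = np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), int)
    return out


@dataclass
class CompartmentGeometry:
    """Compartment label map plus physical pixel size (µm/px)."""

    label_map: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int8)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def height(self) -> int:
        return self.label_map.shape[0]

    @property
    def width(self) -> int:
        return self.label_map.shape[1]

    def validate(self) -> None:
        labels = np.unique(self.label_map)
        if not np.isin(labels, [EXTERIOR, CYTOPLASM_LABEL, NUCLEUS_LABEL]).all():
            raise ValueError("label_map values must be in {0, 1, 2}")
        if membrane_faces(self.label_map, NUCLEUS_LABEL, EXTERIOR).size:
            raise ValueError("nucleus pixels must not touch the exterior")

    # masks -------------------------------------------------------------

    def mask(self, compartment: str) -> np.ndarray:
        label = {"cytoplasm": CYTOPLASM_LABEL, "nucleus": NUCLEUS_LABEL,
                 "exterior": EXTERIOR}[compartment]
        return self.label_map == label

    @property
    def cell_mask(self) -> np.ndarray:
        return self.label_map != EXTERIOR

    @property
    def nuclear_membrane_faces(self) -> np.ndarray:
        """(n, 2) flattened (cytoplasm-pixel, nucleus-pixel) adjacent pairs."""
        return membrane_faces(self.label_map, CYTOPLASM_LABEL, NUCLEUS_LABEL)

    @property
    def plasma_membrane_faces(self) -> np.ndarray:
        """(n, 2) flattened (cytoplasm-pixel, exterior-pixel) adjacent pairs."""
        return membrane_faces(self.label_map, CYTOPLASM_LABEL, EXTERIOR)

    def compartment_volumes(self) -> dict[str, float]:
        """Areal 'volumes' (µm²) of cytoplasm and nucleus."""
        px_area = self.pixel_size**2
        return {
            "cytoplasm": float(self.mask("cytoplasm").sum()) * px_area,
            "nucleus": float(self.mask("nucleus").sum()) * px_area,
        }

    def nuclear_membrane_length(self) -> float:
        """Total nuclear-membrane length (µm): faces × pixel size."""
        return self.nuclear_membrane_faces.shape[0] * self.pixel_size

    # IO ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the label map as a single-channel TIFF/PNG plus a YAML
        sidecar ``<path>.yaml`` carrying the pixel size."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self.label_map.astype(np.uint8))
        else:
            from imageio.v3 import imwrite

            imwrite(path, self.label_map.astype(np.uint8))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        sidecar.write_text(yaml.safe_dump({"pixel_size_um": float(self.pixel_size)}))

    @classmethod
    def load(cls, path: str | Path) -> "CompartmentGeometry":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            label_map = tifffile.imread(path)
        else:
            from imageio.v3 import imread

            label_map = imread(path)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = yaml.safe_load(sidecar.read_text())
        return cls(label_map=label_map, pixel_size=float(meta["pixel_size_um"]))
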