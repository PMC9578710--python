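"""Image quantification pipelines: live-cell NCR, PLA dot counting, IHC tiles.

Three pipelines share a pluggable pixel-classifier contract (image in,
per-pixel foreground probability in [0, 1] out).  The deterministic baseline
classifier — Gaussian smoothing followed by rescaling — stands in for the
interactively trained classifiers used on real microscopy; an optional
random-forest backend on standard pixel features is provided for users with
labelled training data.

* NCR: segment nuclei (nuclear-marker channel) and whole cells (effector
  channel), then divide mean nuclear by mean cytoplasmic effector intensity;
  fields of view are stratified into low/high density at the mean cell count.
* PLA: nuclei and diffraction-limited interaction dots are segmented; a
  pseudo-cytoplasmic ring is built by binary-dilating the nuclear mask
  (default 30 iterations, 3x3 square) and subtracting the nuclei; dot
  centroids are assigned to nucleus, ring, or unassigned.
* IHC: tiles (1 mm², 400x400 px contract) are kept when at least half their
  area is tissue; positive nuclei are counted from a thresholded probability
  map and normalized to the tissue area of the tile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

__all__ = [
    "PixelClassifier",
    "baseline_classifier",
    "GaussianBaselineClassifier",
    "RandomForestPixelClassifier",
    "SegmentationMaskSet",
    "NcrRecord",
    "PlaResult",
    "TileRecord",
    "segment_channels",
    "ncr_for_fov",
    "density_split",
    "pla_count",
    "ihc_quantify",
    "focus_score",
]

# A pixel classifier maps a 2D image to a per-pixel foreground probability.
PixelClassifier = Callable[[np.ndarray], np.ndarray]


class GaussianBaselineClassifier:
    """Deterministic baseline: Gaussian smoothing rescaled to [0, 1]."""

    def __init__(self, sigma: float = 1.0):
        self.sigma = sigma

    def __call__(self, image: np.ndarray) -> np.ndarray:
        sm = ndi.gaussian_filter(np.asarray(image, float), self.sigma)
        lo, hi = sm.min(), sm.max()
        if hi <= lo:
            return np.zeros_like(sm)
        return (sm - lo) / (hi - lo)


def baseline_classifier(sigma: float = 1.0) -> PixelClassifier:
    return GaussianBaselineClassifier(sigma)


class RandomForestPixelClassifier:
    """Random-forest pixel classifier on standard smoothing/edge features."""

    def __init__(self, sigmas: Sequence[float] = (1.0, 2.0, 4.0), **rf_kwargs):
        from sklearn.ensemble import RandomForestClassifier

        self.sigmas = tuple(sigmas)
        rf_kwargs.setdefault("n_estimators", 50)
        rf_kwargs.setdefault("random_state", 0)
        self.forest = RandomForestClassifier(**rf_kwargs)

    def _features(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, float)
        feats = [image]
        for s in self.sigmas:
            sm = ndi.gaussian_filter(image, s)
            feats.append(sm)
            feats.append(ndi.gaussian_gradient_magnitude(image, s))
        return np.stack([f.ravel() for f in feats], axis=1)

    def fit(self, images: Sequence[np.ndarray], labels: Sequence[np.ndarray]):
        X = np.concatenate([self._features(im) for im in images])
        y = np.concatenate([np.asarray(l).ravel() for l in labels])
        self.forest.fit(X, y)
        return self

    def __call__(self, image: np.ndarray) -> np.ndarray:
        proba = self.forest.predict_proba(self._features(image))[:, 1]
        return proba.reshape(np.asarray(image).shape)


def _prob_to_mask(
    prob: np.ndarray,
    threshold: float | None,
    min_area: int,
) -> np.ndarray:
    """Threshold a probability map (Otsu when no threshold is given) and
    drop objects below ``min_area`` pixels."""
    if threshold is None:
        if prob.max() <= prob.min():  # blank image: nothing to segment
            return np.zeros(prob.shape, bool)
        threshold = filters.threshold_otsu(prob)
    mask = prob > threshold
    if min_area > 1:
        try:  # skimage >= 0.26 renamed the size parameter
            mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
        except TypeError:  # pragma: no cover - older scikit-image
            mask = morphology.remove_small_objects(mask, min_size=min_area)
    return mask


@dataclass
class SegmentationMaskSet:
    """Nuclear / whole-cell / cytoplasmic binary masks of one field of view."""

    nuclear_mask: np.ndarray
    cell_mask: np.ndarray
    cytoplasm_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.nuclear_mask.shape == self.cell_mask.shape == self.cytoplasm_mask.shape
        ):
            raise ValueError("masks must share dimensions")
        if (self.nuclear_mask & ~self.cell_mask).any():
            raise ValueError("nuclear mask must be contained in the cell mask")
        if (self.nuclear_mask & self.cytoplasm_mask).any():
            raise ValueError("cytoplasm and nuclei must be disjoint")


@dataclass
class NcrRecord:
    """Per-FOV nuclear/cytoplasmic ratio record (FOV area 0.4 mm²)."""

    fov_id: str
    cell_count: int
    mean_nuclear_intensity: float
    mean_cytoplasmic_intensity: float
    ncr: float
    channel: str = "YAP"
    valid: bool = True


@dataclass
class PlaResult:
    image_id: str
    n_nuclei: int
    dots_nuclear: int
    dots_cytoplasmic: int
    dots_unassigned: int
    dots_per_nucleus: float
    valid: bool = True

    @property
    def dots_total(self) -> int:
        return self.dots_nuclear + self.dots_cytoplasmic + self.dots_unassigned


@dataclass
class TileRecord:
    tile_id: str
    tissue_fraction: float
    positive_nuclei: int
    density: float  # positive nuclei per tissue mm²
    excluded: bool = False


def segment_channels(
    image_stack: np.ndarray,
    classifier: PixelClassifier | None = None,
    nuclear_channel: int = 0,
    cell_channel: int = 1,
    prob_threshold: float | None = None,
    min_nucleus_area: int = 20,
    min_cell_area: int = 20,
) -> SegmentationMaskSet:
    """Classify nuclei and whole-cell foreground into a mask set.

    ``image_stack`` is (C, H, W) with the nuclear marker (H2B) and at least
    one effector channel.  The classifier yields per-pixel foreground
    probabilities, thresholded (Otsu by default) into binary masks with small
    objects removed; the cytoplasm is cell AND NOT nucleus.
    """
    stack = np.asarray(image_stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("image_stack must be (C, H, W) with >= 2 channels")
    clf = classifier or baseline_classifier()
    shape = stack.shape[1:]
    masks = {}
    for name, channel, min_area in (
        ("nuclear", nuclear_channel, min_nucleus_area),
        ("cell", cell_channel, min_cell_area),
    ):
        prob = np.asarray(clf(stack[channel]), float)
        if prob.shape != shape:
            raise ValueError("classifier output shape mismatch")
        masks[name] = _prob_to_mask(prob, prob_threshold, min_area)
    cell = masks["cell"] | masks["nuclear"]  # nuclei are part of the cell
    return SegmentationMaskSet(
        nuclear_mask=masks["nuclear"],
        cell_mask=cell,
        cytoplasm_mask=cell & ~masks["nuclear"],
    )


def ncr_for_fov(
    effector_channel: np.ndarray,
    masks: SegmentationMaskSet,
    fov_id: str = "",
    channel: str = "YAP",
) -> NcrRecord:
    """NCR of one field of view: mean nuclear over mean cytoplasmic intensity.

    The cell count is the number of labelled nuclear objects.  An empty
    compartment yields a flagged record with NaN ratio, never a fabricated
    value.
    """
    img = np.asarray(effector_channel, float)
    n_nuclei = int(measure.label(masks.nuclear_mask).max())
    if not masks.nuclear_mask.any() or not masks.cytoplasm_mask.any():
        return NcrRecord(fov_id, n_nuclei, np.nan, np.nan, np.nan, channel, False)
    mean_nuc = float(img[masks.nuclear_mask].mean())
    mean_cyt = float(img[masks.cytoplasm_mask].mean())
    if mean_cyt == 0:
        return NcrRecord(fov_id, n_nuclei, mean_nuc, mean_cyt, np.nan, channel, False)
    return NcrRecord(fov_id, n_nuclei, mean_nuc, mean_cyt, mean_nuc / mean_cyt, channel)


def density_split(records: Sequence[NcrRecord]) -> dict:
    """Stratify FOV records at the mean cell count.

    Records strictly below the mean go to ``low``, at-or-above to ``high``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split by density")
    mean_count = float(np.mean([r.cell_count for r in records]))
    return {
        "low": [r for r in records if r.cell_count < mean_count],
        "high": [r for r in records if r.cell_count >= mean_count],
        "mean_cell_count": mean_count,
    }


def pla_count(
    nuclei_image: np.ndarray,
    dot_image: np.ndarray,
    dilate_iterations: int = 30,
    image_id: str = "",
    classifier: PixelClassifier | None = None,
    dot_classifier: PixelClassifier | None = None,
    min_nucleus_area: int = 20,
    dot_area_range: tuple[int, int] = (1, 50),
    prob_threshold: float | None = None,
) -> PlaResult:
    """Compartment-resolved PLA dot counting.

    Nuclei are segmented from the DAPI image; the pseudo-cytoplasm is the
    nuclear mask dilated ``dilate_iterations`` times (3x3 square, one pass
    per iteration) minus the nuclei.  Dots are detected in the signal
    channel (classification, threshold, connected components, area filter)
    and each dot centroid is assigned to exactly one of nucleus, ring, or
    unassigned.  With zero nuclei every dot is unassigned and the record is
    flagged.
    """
    if np.asarray(nuclei_image).shape != np.asarray(dot_image).shape:
        raise ValueError("nuclei and dot images must be co-registered")
    clf = classifier or baseline_classifier(sigma=1.5)
    dclf = dot_classifier or baseline_classifier(sigma=0.7)
    nuc_mask = _prob_to_mask(
        np.asarray(clf(nuclei_image), float), prob_threshold, min_nucleus_area
    )
    dot_prob = np.asarray(dclf(dot_image), float)
    dot_mask = _prob_to_mask(dot_prob, prob_threshold, 1)
    dot_labels = measure.label(dot_mask)
    lo_area, hi_area = dot_area_range
    # touching dots merge into one component; split them at local maxima
    # (one peak = one dot), keeping the plain centroid for single-peak blobs
    from skimage.feature import peak_local_max

    centroids: list[tuple[float, float]] = []
    for p in measure.regionprops(dot_labels, intensity_image=dot_prob):
        if p.area < lo_area:
            continue
        try:
            comp = p.image_intensity
        except AttributeError:  # pragma: no cover - scikit-image < 0.26
            comp = p.intensity_image
        peaks = peak_local_max(
            comp, min_distance=2, exclude_border=False, threshold_rel=0.5
        )
        n_dots = max(len(peaks), 1)
        if not lo_area <= p.area / n_dots <= hi_area:
            continue  # per-dot footprint outside the plausible size range
        if n_dots == 1:
            centroids.append(p.centroid)
        else:
            r0, c0, _, _ = p.bbox
            centroids.extend((r0 + pr, c0 + pc) for pr, pc in peaks)

    if dilate_iterations > 0:
        ring = ndi.binary_dilation(
            nuc_mask, structure=np.ones((3, 3), bool), iterations=dilate_iterations
        ) & ~nuc_mask
    else:
        ring = np.zeros_like(nuc_mask)

    n_nuclei = int(measure.label(nuc_mask).max())
    dots_nuc = dots_cyt = dots_un = 0
    for r, c in centroids:
        i, j = int(round(r)), int(round(c))
        i = min(max(i, 0), nuc_mask.shape[0] - 1)
        j = min(max(j, 0), nuc_mask.shape[1] - 1)
        if nuc_mask[i, j]:
            dots_nuc += 1
        elif ring[i, j]:
            dots_cyt += 1
        else:
            dots_un += 1
    if n_nuclei == 0:
        return PlaResult(
            image_id, 0, 0, 0, len(centroids), float("nan"), valid=False
        )
    return PlaResult(
        image_id,
        n_nuclei,
        dots_nuc,
        dots_cyt,
        dots_un,
        dots_nuc / n_nuclei,
    )


def ihc_quantify(
    tiles: Sequence[np.ndarray],
    classifier: PixelClassifier | None = None,
    tissue_fraction_cutoff: float = 0.5,
    prob_threshold: float = 0.6,
    tile_area_mm2: float | None = None,
    pixel_size_um: float | None = None,
    tissue_threshold: float = 0.15,
    min_nucleus_area: int = 4,
    binning: int = 1,
) -> list[TileRecord]:
    """Tile-based IHC positivity quantification.

    Per tile: the tissue fraction is measured from a smoothed
    intensity-above-background mask; tiles below the cutoff are flagged
    excluded.  For kept tiles the classifier probability map is thresholded,
    connected positive nuclei are counted, and the density is the count per
    tissue area (mm²).  The physical tile area must be known, either directly
    or via ``pixel_size_um``.  ``binning`` optionally downscales tiles before
    classification (block mean), as done to reduce processing cost on whole
    slides; densities are invariant to it.
    """
    if tile_area_mm2 is None:
        if pixel_size_um is None:
            raise ValueError(
                "tile physical area unknown: pass tile_area_mm2 or pixel_size_um"
            )
    clf = classifier or baseline_classifier(sigma=1.0)
    records = []
    for i, tile in enumerate(tiles):
        tile = np.asarray(tile, float)
        if tile_area_mm2 is None:
            area_mm2 = tile.size * (pixel_size_um * 1e-3) ** 2
        else:
            area_mm2 = tile_area_mm2
        if binning > 1:
            from skimage.transform import downscale_local_mean

            work = downscale_local_mean(tile, (binning, binning))
            min_area = max(1, min_nucleus_area // binning**2)
        else:
            work = tile
            min_area = min_nucleus_area
        tissue = ndi.gaussian_filter(work, 2.0) > tissue_threshold
        tissue_fraction = float(tissue.mean())
        if tissue_fraction < tissue_fraction_cutoff:
            records.append(TileRecord(f"tile{i:04d}", tissue_fraction, 0, np.nan, True))
            continue
        prob = np.asarray(clf(work), float)
        pos = _prob_to_mask(prob, prob_threshold, min_area) & tissue
        count = int(measure.label(pos).max())
        density = count / (tissue_fraction * area_mm2)
        records.append(TileRecord(f"tile{i:04d}", tissue_fraction, count, density))
    return records


def focus_score(image: np.ndarray) -> float:
    """Variance-of-Laplacian focus score used to prescreen blurred FOVs."""
    return float(ndi.laplace(np.asarray(image, float)).var())
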