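"""Synthetic-data generators with ground truth for every pipeline.

All generators are pure functions of (spec, seed): identical seeds give
identical scenes.  They emulate the acquisition settings of the study they
stand in for — 512×512 px confocal fields of view at 1.24 µm/px for the
live-cell NCR data, high-resolution two-channel scenes for PLA dot counting,
1 mm² (400×400 px) tissue tiles for IHC, and log-scale expression time
courses with signature genes rising and falling around staggered peak times.
They do not attempt photorealism (no PSF, no chromatic effects, two-class
intensity separation for histology); what passing tests show is that the
pipelines recover known ground truth under realistic noise, not that they
match any particular instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    CYTOPLASM_LABEL,
    EXTERIOR,
    NUCLEUS_LABEL,
    CompartmentGeometry,
)
from .signature import ExpressionMatrix

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_geometry",
    "single_cell_geometry",
    "render_fluorescence",
    "make_ncr_dataset",
    "make_pla_scene",
    "make_ihc_tiles",
    "make_expression_timecourse",
    "default_signatures",
]


@dataclass(frozen=True)
class SceneSpec:
    """Acquisition and noise settings of a synthetic confocal field of view.

    Defaults follow the live-cell imaging settings emulated here: 512×512 px
    at 1.24 µm/px (0.4 mm² field).  The noise model is Poisson shot noise on
    gain-scaled intensities plus Gaussian read noise and a constant
    background offset.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.24  # µm/px
    n_cells: int = 12
    cell_radius_um: tuple[float, float] = (14.0, 20.0)
    nucleus_radius_um: tuple[float, float] = (5.5, 8.0)
    gain: float = 200.0
    read_noise_sd: float = 2.0
    background: float = 5.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_um[1] >= self.cell_radius_um[0]:
            raise ValueError("nucleus radii must be smaller than cell radii")
        if self.gain < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("gain, background and read noise must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    nuclear_mask: np.ndarray | None = None
    cell_mask: np.ndarray | None = None
    cells: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def make_geometry(
    spec: SceneSpec, seed: int | None = None
) -> tuple[CompartmentGeometry, GroundTruth]:
    """Pack non-overlapping elliptical cells with interior elliptical nuclei.

    Nuclei are concentric with a random offset, kept at least two pixels away
    from the cell boundary so no nucleus pixel can touch the exterior.
    Raises after a bounded number of rejection-sampling attempts when the
    requested cells cannot be packed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.shape
    px = spec.pixel_size
    labels = np.zeros((h, w), dtype=np.int8)
    occupied = np.zeros((h, w), dtype=bool)
    cells: list[dict] = []
    attempts = 0
    max_attempts = 400 * spec.n_cells
    while len(cells) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not pack {spec.n_cells} cells after {max_attempts} attempts"
            )
        r_cell = rng.uniform(*spec.cell_radius_um) / px
        ecc = rng.uniform(0.8, 1.0)
        radii = (r_cell / np.sqrt(ecc), r_cell * np.sqrt(ecc))
        margin = max(radii) + 1
        if 2 * margin >= min(h, w):
            raise RuntimeError("cells too large for the grid")
        center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        angle = rng.uniform(0, np.pi)
        cell = _ellipse_mask((h, w), center, radii, angle)
        if (cell & occupied).any():
            continue
        r_nuc = rng.uniform(*spec.nucleus_radius_um) / px
        max_off = max(min(radii) - r_nuc - 2.0, 0.0)
        off_r = rng.uniform(-max_off, max_off) * 0.5
        off_c = rng.uniform(-max_off, max_off) * 0.5
        nucleus = _ellipse_mask(
            (h, w),
            (center[0] + off_r, center[1] + off_c),
            (r_nuc, r_nuc * rng.uniform(0.85, 1.0)),
            rng.uniform(0, np.pi),
        )
        nucleus &= cell  # safety: nucleus stays inside its cell
        if not nucleus.any():
            continue
        labels[cell] = CYTOPLASM_LABEL
        labels[nucleus] = NUCLEUS_LABEL
        occupied |= cell
        cells.append(
            {"center": center, "cell_radii_px": radii, "nucleus_radius_px": r_nuc}
        )
    geometry = CompartmentGeometry(labels, px)
    truth = GroundTruth(
        nuclear_mask=labels == NUCLEUS_LABEL,
        cell_mask=labels != EXTERIOR,
        cells=cells,
        params={"spec": spec},
    )
    return geometry, truth


def single_cell_geometry(
    size: int = 128,
    pixel_size: float = 1.24,
    cell_radius_um: float = 50.0,
    nucleus_radius_um: float = 20.0,
    nucleus_offset_um: tuple[float, float] = (0.0, 0.0),
    ellipticity: float = 1.0,
) -> CompartmentGeometry:
    """One centered (optionally elliptical) cell, the PDE study domain."""
    labels = np.zeros((size, size), dtype=np.int8)
    c = ((size - 1) / 2.0, (size - 1) / 2.0)
    r_cell = cell_radius_um / pixel_size
    cell = _ellipse_mask(
        (size, size), c, (r_cell / np.sqrt(ellipticity), r_cell * np.sqrt(ellipticity)),
        0.0,
    )
    r_nuc = nucleus_radius_um / pixel_size
    nc = (
        c[0] + nucleus_offset_um[0] / pixel_size,
        c[1] + nucleus_offset_um[1] / pixel_size,
    )
    nucleus = _ellipse_mask((size, size), nc, (r_nuc, r_nuc), 0.0) & cell
    labels[cell] = CYTOPLASM_LABEL
    labels[nucleus] = NUCLEUS_LABEL
    return CompartmentGeometry(labels, pixel_size)


def render_fluorescence(
    geometry: CompartmentGeometry,
    effector_images: Mapping[str, np.ndarray],
    spec: SceneSpec,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a multi-channel FOV: nuclear marker + effector observables.

    Channel 0 is the nuclear marker (uniform 1.0 inside nuclei); the
    remaining channels are the supplied effector observables (typically the
    total U+P concentration of a simulation).  Each channel is scaled by the
    camera gain, Poisson-sampled (unless disabled), and offset by Gaussian
    read noise and a constant background.  The ground truth records the
    noiseless compartment means per channel.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nuc = geometry.mask("nucleus")
    cyt = geometry.mask("cytoplasm")
    channels = {"nuclear_marker": nuc.astype(float)}
    for name, img in effector_images.items():
        img = np.asarray(img, float)
        if img.shape != geometry.shape:
            raise ValueError(f"effector image {name!r} shape mismatch")
        channels[name] = img
    stack = np.empty((len(channels), *geometry.shape))
    means = {}
    for i, (name, clean) in enumerate(channels.items()):
        signal = clean * spec.gain
        noisy = rng.poisson(signal).astype(float) if spec.poisson_noise else signal.copy()
        if spec.read_noise_sd > 0:
            noisy += rng.normal(0.0, spec.read_noise_sd, size=signal.shape)
        noisy += spec.background
        stack[i] = np.clip(noisy, 0.0, None)
        means[name] = {
            "nucleus": float(signal[nuc].mean()) if nuc.any() else 0.0,
            "cytoplasm": float(signal[cyt].mean()) if cyt.any() else 0.0,
        }
    truth = GroundTruth(
        nuclear_mask=nuc,
        cell_mask=geometry.cell_mask,
        counts={"channel_means": means},
        params={"spec": spec},
    )
    return stack, truth


def make_ncr_dataset(
    n_fovs: int,
    seed: int = 0,
    spec: SceneSpec | None = None,
    n_cells_range: tuple[int, int] = (4, 24),
    ncr_range: tuple[float, float] = (0.8, 3.0),
    density_midpoint: float | None = None,
    density_steepness: float = 0.25,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Seeded FOVs whose true NCR decreases with cell density.

    The density–shuttling coupling is a logistic map from cell count to NCR
    (high NCR at sparse plating, low at confluence) — a fixture device
    emulating the observed density dependence, not a mechanistic claim.
    Each FOV is rendered as a 2-channel stack (nuclear marker, effector)
    whose effector intensity is ``ncr`` in nuclei and 1.0 in cytoplasm.
    """
    spec = spec or SceneSpec(shape=(256, 256), n_cells=4)
    rng = np.random.default_rng(seed)
    lo_n, hi_n = n_cells_range
    mid = density_midpoint if density_midpoint is not None else (lo_n + hi_n) / 2.0
    fovs = []
    for i in range(n_fovs):
        n_cells = int(rng.integers(lo_n, hi_n + 1))
        frac = 1.0 / (1.0 + np.exp(-density_steepness * (n_cells - mid)))
        true_ncr = ncr_range[1] - (ncr_range[1] - ncr_range[0]) * frac
        fov_spec = SceneSpec(
            shape=spec.shape,
            pixel_size=spec.pixel_size,
            n_cells=n_cells,
            cell_radius_um=spec.cell_radius_um,
            nucleus_radius_um=spec.nucleus_radius_um,
            gain=spec.gain,
            read_noise_sd=spec.read_noise_sd,
            background=spec.background,
            poisson_noise=spec.poisson_noise,
            seed=int(rng.integers(2**31)),
        )
        geometry, _ = make_geometry(fov_spec)
        effector = np.zeros(geometry.shape)
        effector[geometry.mask("cytoplasm")] = 1.0
        effector[geometry.mask("nucleus")] = true_ncr
        stack, truth = render_fluorescence(
            geometry, {"effector": effector}, fov_spec,
            seed=int(rng.integers(2**31)),
        )
        truth.counts["n_cells"] = n_cells
        truth.counts["true_ncr"] = float(true_ncr)
        fovs.append((stack, truth))
    return fovs


def make_pla_scene(
    n_nuclei: int,
    lam_nuclear: float,
    lam_cyto_ring: float,
    dot_radius_px: float = 2.0,
    spec: SceneSpec | None = None,
    seed: int = 0,
    ring_iterations: int = 30,
    nucleus_radius_px: tuple[float, float] = (18.0, 26.0),
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """A PLA scene: a DAPI-like nuclei image and a dot (signal) image.

    Per nucleus, Poisson(``lam_nuclear``) dots are placed uniformly inside
    the nucleus and Poisson(``lam_cyto_ring``) dots uniformly inside its
    surrounding dilation ring (``ring_iterations`` passes of the 3×3
    structuring element).  Exact placed counts per compartment are stored in
    the ground truth.
    """
    if lam_nuclear < 0 or lam_cyto_ring < 0:
        raise ValueError("dot rates must be >= 0")
    from scipy import ndimage as ndi

    spec = spec or SceneSpec(
        shape=(420, 420), pixel_size=0.18, gain=150.0, read_noise_sd=2.0,
        background=4.0,
    )
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    nuc_mask = np.zeros((h, w), bool)
    centers = []
    ring_px = ring_iterations
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 400 * max(n_nuclei, 1):
            raise RuntimeError("could not place the requested nuclei")
        r = rng.uniform(*nucleus_radius_px)
        margin = r + ring_px + 2
        if 2 * margin >= min(h, w):
            raise RuntimeError("nuclei too large for the grid")
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if any(
            np.hypot(c[0] - c0[0], c[1] - c0[1]) < (r + r0 + 2 * ring_px + 4)
            for (c0, r0) in centers
        ):
            continue
        nuc_mask |= _ellipse_mask((h, w), c, (r, r), 0.0)
        centers.append((c, r))
    ring = (
        ndi.binary_dilation(nuc_mask, np.ones((3, 3), bool), iterations=ring_iterations)
        & ~nuc_mask
    )

    def _sample_points(region: np.ndarray, count: int) -> np.ndarray:
        idx = np.flatnonzero(region)
        chosen = rng.choice(idx, size=count, replace=True)
        rr, cc = np.unravel_index(chosen, region.shape)
        return np.stack([rr, cc], axis=1).astype(float)

    n_nuc_dots = int(rng.poisson(lam_nuclear * max(n_nuclei, 0)))
    n_ring_dots = int(rng.poisson(lam_cyto_ring * max(n_nuclei, 0)))
    dot_img = np.zeros((h, w))
    points = []
    if n_nuclei > 0 and n_nuc_dots > 0:
        points.append(("nuclear", _sample_points(nuc_mask, n_nuc_dots)))
    if n_nuclei > 0 and n_ring_dots > 0:
        points.append(("ring", _sample_points(ring, n_ring_dots)))
    rr, cc = np.mgrid[0:h, 0:w]
    sigma = dot_radius_px / 1.5
    for _, pts in points:
        for p in pts:
            r0, c0 = int(p[0]), int(p[1])
            s = int(np.ceil(3 * sigma)) + 1
            sl = (slice(max(r0 - s, 0), r0 + s + 1), slice(max(c0 - s, 0), c0 + s + 1))
            d2 = (rr[sl] - p[0]) ** 2 + (cc[sl] - p[1]) ** 2
            dot_img[sl] += np.exp(-d2 / (2 * sigma**2))

    def _camera(clean: np.ndarray) -> np.ndarray:
        signal = clean * spec.gain
        noisy = rng.poisson(signal).astype(float) if spec.poisson_noise else signal
        noisy = noisy + rng.normal(0.0, spec.read_noise_sd, clean.shape)
        return np.clip(noisy + spec.background, 0.0, None)

    nuclei_img = _camera(nuc_mask.astype(float) * 0.8)
    dots_rendered = _camera(dot_img)
    truth = GroundTruth(
        nuclear_mask=nuc_mask,
        counts={
            "n_nuclei": n_nuclei,
            "dots_nuclear": n_nuc_dots if n_nuclei else 0,
            "dots_ring": n_ring_dots if n_nuclei else 0,
        },
        params={
            "lam_nuclear": lam_nuclear,
            "lam_cyto_ring": lam_cyto_ring,
            "ring_iterations": ring_iterations,
        },
    )
    return nuclei_img, dots_rendered, truth


def make_ihc_tiles(
    n_tiles: int,
    tissue_fractions: Sequence[float] | tuple[float, float] = (0.2, 0.95),
    densities_per_mm2: Sequence[float] = (2.0, 10.0, 50.0),
    tile_px: int = 400,
    tile_area_mm2: float = 1.0,
    seed: int = 0,
    tissue_intensity: float = 0.35,
    background_nucleus_intensity: float = 0.55,
    positive_intensity: float = 1.2,
    nucleus_radius_px: float = 3.0,
    noise_sd: float = 0.02,
) -> tuple[list[np.ndarray], GroundTruth]:
    """IHC-like tiles: a tissue blob with positive nuclei at known density.

    Each tile's tissue region is a smoothed-random-field blob thresholded at
    the quantile matching the requested tissue fraction; positive nuclei are
    small bright disks placed uniformly inside the tissue at the tile's
    density (count = Poisson(density × tissue area)); fainter
    hematoxylin-like background nuclei are added as distractors.  The ground
    truth stores per-tile tissue fraction, positive count and true density.
    """
    from scipy import ndimage as ndi

    if any(d < 0 for d in densities_per_mm2):
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    tiles: list[np.ndarray] = []
    records: list[dict] = []
    for i in range(n_tiles):
        # a 2-tuple is a (lo, hi) sampling range; any other sequence lists
        # explicit per-tile fractions, cycled over the tiles
        if isinstance(tissue_fractions, tuple) and len(tissue_fractions) == 2:
            frac = float(rng.uniform(*tissue_fractions))
        else:
            frac = float(tissue_fractions[i % len(tissue_fractions)])
        density = float(densities_per_mm2[int(rng.integers(len(densities_per_mm2)))])
        blob = ndi.gaussian_filter(rng.normal(size=(tile_px, tile_px)), tile_px / 8)
        if frac <= 0:
            tissue = np.zeros((tile_px, tile_px), bool)
        elif frac >= 1:
            tissue = np.ones((tile_px, tile_px), bool)
        else:
            tissue = blob >= np.quantile(blob, 1 - frac)
        tissue_frac = float(tissue.mean())
        tile = np.full((tile_px, tile_px), 0.02)
        tile[tissue] = tissue_intensity

        def _stamp_disks(n: int, intensity: float) -> int:
            placed = 0
            idx = np.flatnonzero(tissue)
            if idx.size == 0 or n == 0:
                return 0
            chosen = rng.choice(idx, size=n, replace=True)
            rr0, cc0 = np.unravel_index(chosen, tissue.shape)
            for r0, c0 in zip(rr0, cc0):
                disk = _ellipse_mask(
                    tile.shape, (float(r0), float(c0)),
                    (nucleus_radius_px, nucleus_radius_px), 0.0,
                )
                tile[disk] = intensity
                placed += 1
            return placed

        n_bg = int(rng.poisson(80 * tissue_frac * tile_area_mm2))
        _stamp_disks(n_bg, background_nucleus_intensity)
        n_pos = int(rng.poisson(density * tissue_frac * tile_area_mm2))
        n_pos = _stamp_disks(n_pos, positive_intensity)
        tile += rng.normal(0.0, noise_sd, tile.shape)
        tiles.append(np.clip(tile, 0.0, None))
        true_density = (
            n_pos / (tissue_frac * tile_area_mm2) if tissue_frac > 0 else np.nan
        )
        records.append(
            {
                "tile_id": f"tile{i:04d}",
                "tissue_fraction": tissue_frac,
                "positive_nuclei": n_pos,
                "density": true_density,
                "generating_density": density,
            }
        )
    truth = GroundTruth(counts={"tiles": records}, params={"tile_area_mm2": tile_area_mm2})
    return tiles, truth


def default_signatures() -> dict[str, dict]:
    """Synthetic stand-ins for the ROS/AKT/YAP signature gene lists.

    Sizes match the published signatures (23 ROS, 28 AKT, 23 YAP genes); the
    gene identifiers are synthetic placeholders — real lists are supplied by
    the user as one-gene-per-line text files.  Peak times follow the motif of
    a fast redox response, an intermediate survival-kinase response, and a
    late proliferative response.
    """
    return {
        "ROS": {"genes": [f"ROS_g{i:02d}" for i in range(23)], "peak_hours": 8.0},
        "AKT": {"genes": [f"AKT_g{i:02d}" for i in range(28)], "peak_hours": 18.0},
        "YAP": {"genes": [f"YAP_g{i:02d}" for i in range(23)], "peak_hours": 36.0},
    }


def make_expression_timecourse(
    signatures: Mapping[str, Mapping] | None = None,
    times_hours: Sequence[float] = (6.0, 12.0, 24.0, 48.0, 144.0, 384.0),
    n_replicates: int = 4,
    n_control_replicates: int = 4,
    amplitude: float = 3.0,
    noise_sd: float = 0.5,
    peak_width_log: float = 0.5,
    n_background_genes: int = 200,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log2-scale expression time course with staggered signature peaks.

    Signature genes follow a Gaussian bump in log-time centered at their
    signature's peak (height ``amplitude`` log2 units, width
    ``peak_width_log`` in ln-hours) on top of a gene-specific baseline;
    control samples (time 0) and background genes are baseline plus noise.
    Replicates are i.i.d. noise realizations, emulating a 3–5 animals/group
    design.  The ground truth stores each signature's generating peak hour
    and the grid time closest to it in log-time.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    sigs = {k: dict(v) for k, v in (signatures or default_signatures()).items()}
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for s in sigs.values():
        genes.extend(s["genes"])
    genes.extend(f"BG_g{i:03d}" for i in range(n_background_genes))
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers across signatures")
    baseline = pd.Series(rng.normal(8.0, 1.0, len(genes)), index=genes)

    samples: list[str] = []
    sample_times: dict[str, float] = {}
    controls: list[str] = []
    for rep in range(n_control_replicates):
        name = f"ctrl_r{rep + 1}"
        samples.append(name)
        sample_times[name] = 0.0
        controls.append(name)
    for t in times_hours:
        for rep in range(n_replicates):
            name = f"t{t:g}h_r{rep + 1}"
            samples.append(name)
            sample_times[name] = float(t)

    values = pd.DataFrame(0.0, index=genes, columns=samples)
    log_t = {s: (np.log(sample_times[s]) if sample_times[s] > 0 else None)
             for s in samples}
    for sig_name, s in sigs.items():
        amp = float(s.get("amplitude", amplitude))
        responsive_fraction = float(s.get("responsive_fraction", 1.0))
        peak = float(s["peak_hours"])
        n_resp = int(round(responsive_fraction * len(s["genes"])))
        for gi, gene in enumerate(s["genes"]):
            gene_amp = amp if gi < n_resp else 0.0
            for sample in samples:
                lt = log_t[sample]
                bump = (
                    gene_amp
                    * np.exp(-((lt - np.log(peak)) ** 2) / (2 * peak_width_log**2))
                    if lt is not None
                    else 0.0
                )
                values.loc[gene, sample] = baseline[gene] + bump
    for gene in genes:
        if not any(gene in s["genes"] for s in sigs.values()):
            values.loc[gene] = baseline[gene]
    values += rng.normal(0.0, noise_sd, values.shape)

    grid = np.asarray(times_hours, float)
    truth_peaks = {}
    for sig_name, s in sigs.items():
        peak = float(s["peak_hours"])
        nearest = float(grid[np.argmin(np.abs(np.log(grid) - np.log(peak)))])
        truth_peaks[sig_name] = {"peak_hours": peak, "grid_peak_hours": nearest}
    matrix = ExpressionMatrix(
        values=values,
        sample_times=pd.Series(sample_times),
        control_samples=tuple(controls),
        log_scale=True,
    )
    truth = GroundTruth(
        counts={"peaks": truth_peaks},
        params={
            "amplitude": amplitude,
            "noise_sd": noise_sd,
            "times_hours": list(times_hours),
        },
    )
    return matrix, truth
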