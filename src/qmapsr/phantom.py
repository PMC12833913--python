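"""Seeded synthetic subjects: brain-like phantoms with quantitative tissue values.

A phantom stands in for one scanned subject: a 2-D label image on the
high-resolution reconstruction grid (default 512 x 512, 220 mm field of
view) with cortical gray matter (GM) ribbon, white matter (WM) interior
and cerebrospinal-fluid (CSF) ventricles, optional WM lesions, and named
region masks that partition each tissue into contiguous sectors (desk
stand-ins for atlas regions of interest).

Tissue T1/T2/PD statistics default to routine-scan literature values for
healthy adult GM and WM; lesion classes (white-matter hyperintensity,
infarct, encephalomalacia) default to the midpoints of reported lesion
ranges.  CSF is not reported in the source tables and defaults to
T1 = 4000 ms, T2 = 300 ms, PD = 100% — consistent with encephalomalacia
(T1 3469-3893 ms, T2 272-350 ms, PD 101-108%) being described as
CSF-like; override via ``default_tissue_models``'s return value.

Quantitative maps carry physical units (ms for T1/T2, percent for PD)
with a stored-intensity convention: DICOM rescale slope 0.1, i.e.
stored integer = 10 x physical value, with stored maxima 43,000 / 20,000
/ 1,600 for T1 / T2 / PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "TISSUE_CLASSES", "LESION_CLASSES", "STORED_MAX", "RESCALE_SLOPE",
    "FOV_MM", "HR_GRID", "TissueModel", "QuantMap", "Phantom",
    "default_tissue_models", "make_phantom", "sample_tissue_values",
    "sample_quant_maps", "make_cohort",
]

TISSUE_CLASSES = ("background", "GM", "WM", "CSF", "WMH", "infarct",
                  "encephalomalacia")
LESION_CLASSES = ("WMH", "infarct", "encephalomalacia")
#: label integer for each tissue class, background = 0
LABELS = {name: i for i, name in enumerate(TISSUE_CLASSES)}

STORED_MAX = {"T1": 43000, "T2": 20000, "PD": 1600}
RESCALE_SLOPE = 0.1
FOV_MM = 220.0
HR_GRID = 512


@dataclass(frozen=True)
class TissueModel:
    """Per-tissue quantitative parameter statistics (subject-to-subject)."""

    tissue_class: str
    t1_mean: float  # ms
    t1_sd: float
    t2_mean: float  # ms
    t2_sd: float
    pd_mean: float  # percent of water reference
    pd_sd: float

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.tissue_class != "background":
            if min(self.t1_mean, self.t2_mean, self.pd_mean) <= 0:
                raise ValueError("tissue means must be positive")
            if not (0 < self.pd_mean <= 110):
                raise ValueError("PD mean must lie in (0, 110] percent")
        if min(self.t1_sd, self.t2_sd, self.pd_sd) < 0:
            raise ValueError("SDs must be non-negative")

    def mean(self, parameter: str) -> float:
        return {"T1": self.t1_mean, "T2": self.t2_mean, "PD": self.pd_mean}[parameter]

    def sd(self, parameter: str) -> float:
        return {"T1": self.t1_sd, "T2": self.t2_sd, "PD": self.pd_sd}[parameter]


@dataclass
class QuantMap:
    """One 2-D quantitative map in physical units with grid bookkeeping."""

    values: np.ndarray          # physical units (ms or percent), >= 0
    parameter: str              # "T1" | "T2" | "PD"
    pixel_spacing: float        # mm
    rescale_slope: float = RESCALE_SLOPE

    def __post_init__(self):
        if self.parameter not in STORED_MAX:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def grid(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def stored_max(self) -> int:
        return STORED_MAX[self.parameter]

    @property
    def physical_max(self) -> float:
        """Largest representable physical value (stored_max x slope)."""
        return self.stored_max * self.rescale_slope

    def stored(self) -> np.ndarray:
        """Stored-intensity (DICOM integer) representation: physical / slope."""
        return np.round(self.values / self.rescale_slope)

    def with_values(self, values: np.ndarray, pixel_spacing: float | None = None
                    ) -> "QuantMap":
        return QuantMap(values=values, parameter=self.parameter,
                        pixel_spacing=self.pixel_spacing if pixel_spacing is None
                        else pixel_spacing,
                        rescale_slope=self.rescale_slope)


@dataclass
class Phantom:
    subject_id: str
    label_map: np.ndarray                      # int image, 0 = background
    tissue_models: dict[str, TissueModel]
    region_masks: dict[str, np.ndarray]        # name -> bool image
    lesion_masks: dict[str, np.ndarray]        # "<class>_<k>" -> bool image
    rng_seed: int
    grid: int = HR_GRID
    fov_mm: float = FOV_MM

    @property
    def pixel_spacing(self) -> float:
        return self.fov_mm / self.grid

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.label_map == LABELS[tissue]


def default_tissue_models() -> dict[str, TissueModel]:
    """Healthy-tissue and lesion parameter models.

    GM and WM match routine-scan cohort means (SDs are across-subject);
    lesion models sit at the midpoint of the reported lesion ranges with
    an SD wide enough to span them; CSF is the documented default.
    """
    return {
        "GM": TissueModel("GM", 1232.65, 34.98, 93.33, 3.50, 80.11, 1.23),
        "WM": TissueModel("WM", 837.86, 35.88, 79.92, 2.05, 68.21, 1.29),
        "CSF": TissueModel("CSF", 4000.0, 150.0, 300.0, 30.0, 100.0, 2.0),
        "WMH": TissueModel("WMH", 1250.0, 200.0, 120.0, 25.0, 80.0, 4.0),
        "infarct": TissueModel("infarct", 1550.0, 220.0, 140.0, 10.0, 86.0, 5.0),
        "encephalomalacia": TissueModel(
            "encephalomalacia", 3680.0, 140.0, 290.0, 25.0, 105.0, 2.0),
    }


def _smooth_ellipse(grid: int, center, semi_axes, rng: np.random.Generator,
                    wobble: float = 0.03, n_harmonics: int = 4) -> np.ndarray:
    """Filled ellipse with a low-frequency seeded radial perturbation."""
    yy, xx = np.mgrid[0:grid, 0:grid].astype(float)
    dy = (yy - center[0]) / semi_axes[0]
    dx = (xx - center[1]) / semi_axes[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = np.ones_like(theta)
    for h in range(1, n_harmonics + 1):
        amp = wobble * rng.uniform(0.3, 1.0) / h
        phase = rng.uniform(0, 2 * np.pi)
        bound += amp * np.cos(h * theta + phase)
    return r <= bound


def _sector_partition(mask: np.ndarray, n_sectors: int, center) -> list[np.ndarray]:
    """Split a mask into angular sectors around ``center`` (all nonempty
    for ring/blob-shaped masks)."""
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]].astype(float)
    theta = np.mod(np.arctan2(yy - center[0], xx - center[1]), 2 * np.pi)
    edges = np.linspace(0, 2 * np.pi, n_sectors + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        out.append(mask & (theta >= lo) & (theta < hi))
    return out


def make_phantom(subject_id: str, rng_seed: int, n_lesions: int = 0,
                 lesion_classes=("WMH",), grid: int = HR_GRID,
                 n_gm_regions: int = 10, n_wm_regions: int = 9,
                 tissue_models: dict[str, TissueModel] | None = None,
                 fov_mm: float = FOV_MM) -> Phantom:
    """Generate one seeded synthetic subject.

    Geometry: head-like outer ellipse; outer ring = cortical GM ribbon,
    interior = WM, two central ellipses = CSF ventricles.  Lesions are
    disjoint discs embedded strictly inside the WM support.  Region
    masks partition GM and WM into angular sectors.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    for lc in lesion_classes:
        if lc not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {lc!r}")
    rng = np.random.default_rng(rng_seed)
    models = dict(tissue_models or default_tissue_models())

    g = grid
    center = (g / 2, g / 2)
    head = _smooth_ellipse(g, center, (0.39 * g, 0.33 * g), rng)
    # GM ribbon thickness ~4% of grid
    erode_px = max(2, int(round(0.04 * g)))
    interior = ndimage.binary_erosion(head, iterations=erode_px)
    gm = head & ~interior
    # ventricles: two small ellipses flanking the midline
    off = 0.055 * g
    v1 = _smooth_ellipse(g, (center[0] - 0.02 * g, center[1] - off),
                         (0.10 * g, 0.035 * g), rng, wobble=0.05)
    v2 = _smooth_ellipse(g, (center[0] - 0.02 * g, center[1] + off),
                         (0.10 * g, 0.035 * g), rng, wobble=0.05)
    csf = (v1 | v2) & interior
    wm = interior & ~csf

    label = np.zeros((g, g), dtype=np.int16)
    label[gm] = LABELS["GM"]
    label[wm] = LABELS["WM"]
    label[csf] = LABELS["CSF"]

    # lesions: disjoint discs fully inside (eroded) WM, away from CSF/GM
    lesion_masks: dict[str, np.ndarray] = {}
    if n_lesions:
        classes = [lesion_classes[i % len(lesion_classes)] for i in range(n_lesions)]
        safe = ndimage.binary_erosion(wm, iterations=max(2, int(0.03 * g)))
        occupied = np.zeros((g, g), dtype=bool)
        ys, xs = np.nonzero(safe)
        if ys.size == 0:
            raise ValueError("WM support too small to place lesions")
        yy, xx = np.mgrid[0:g, 0:g]
        for k, lc in enumerate(classes):
            for _attempt in range(200):
                idx = rng.integers(ys.size)
                cy, cx = ys[idx], xs[idx]
                radius = rng.uniform(0.015 * g, 0.03 * g)
                disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
                if disc.any() and (disc <= safe).all() and not (disc & occupied).any():
                    break
            else:
                raise RuntimeError("could not place a disjoint lesion")
            occupied |= disc
            lesion_masks[f"{lc}_{k}"] = disc
            label[disc] = LABELS[lc]
    wm_final = label == LABELS["WM"]

    region_masks: dict[str, np.ndarray] = {}
    for name, sec in zip(
            (f"GM_region_{i + 1}" for i in range(n_gm_regions)),
            _sector_partition(gm, n_gm_regions, center)):
        if sec.any():
            region_masks[name] = sec
    for name, sec in zip(
            (f"WM_region_{i + 1}" for i in range(n_wm_regions)),
            _sector_partition(wm_final, n_wm_regions, center)):
        if sec.any():
            region_masks[name] = sec

    return Phantom(subject_id=subject_id, label_map=label, tissue_models=models,
                   region_masks=region_masks, lesion_masks=lesion_masks,
                   rng_seed=rng_seed, grid=g, fov_mm=fov_mm)


def sample_tissue_values(models: dict[str, TissueModel],
                         rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """One subject-level draw per tissue per parameter: Normal(mean, sd).

    Draw order is fixed (sorted tissue name, then T1/T2/PD) so results
    are seed-stable regardless of dict insertion order.
    """
    out: dict[str, dict[str, float]] = {}
    for name in sorted(models):
        m = models[name]
        out[name] = {p: float(rng.normal(m.mean(p), m.sd(p)))
                     for p in ("T1", "T2", "PD")}
    return out


def sample_quant_maps(phantom: Phantom, rng_seed: int,
                      jitter_fraction: float = 0.01,
                      ) -> tuple[QuantMap, QuantMap, QuantMap]:
    """Assign subject-level tissue values to the label geometry.

    Each tissue's value is drawn once per subject from Normal(mean, sd),
    then given Gaussian within-tissue pixel jitter (SD = jitter_fraction
    x tissue mean).  All three maps share the label geometry; values are
    clipped to [0, stored_max x slope].
    """
    rng = np.random.default_rng(rng_seed)
    draws = sample_tissue_values(phantom.tissue_models, rng)
    spacing = phantom.pixel_spacing
    maps = []
    for parameter in ("T1", "T2", "PD"):
        img = np.zeros(phantom.label_map.shape, dtype=float)
        for name in sorted(phantom.tissue_models):
            mask = phantom.label_map == LABELS[name]
            if not mask.any():
                continue
            value = draws[name][parameter]
            jitter_sd = jitter_fraction * phantom.tissue_models[name].mean(parameter)
            img[mask] = value + rng.normal(0.0, jitter_sd, size=int(mask.sum())) \
                if jitter_sd > 0 else value
        hi = STORED_MAX[parameter] * RESCALE_SLOPE
        maps.append(QuantMap(np.clip(img, 0.0, hi), parameter, spacing))
    return tuple(maps)


@dataclass(frozen=True)
class CohortMember:
    subject_id: str
    seed: int
    split: str          # "train" | "test"
    n_lesions: int = 0
    lesion_classes: tuple = ()


def make_cohort(n_subjects: int, train_fraction: float, rng_seed: int,
                n_test_lesion_subjects: int = 0, lesion_classes=("WMH",),
                ) -> tuple[list[CohortMember], list[CohortMember]]:
    """Subject-level train/test split (no subject in both sets).

    Train size is round(n x fraction) clamped to [1, n-1]; subjects are
    shuffled with the run seed before splitting.  Optionally the last
    ``n_test_lesion_subjects`` test subjects carry lesions (training is
    always lesion-free, mirroring a healthy-only training set).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    ids = [f"sub-{i + 1:04d}" for i in range(n_subjects)]
    order = rng.permutation(n_subjects)
    n_train = int(round(n_subjects * train_fraction))
    n_train = min(max(n_train, 1), n_subjects - 1)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_subjects)
    train, test = [], []
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else "test"
        member = CohortMember(ids[idx], int(seeds[rank]), split)
        (train if split == "train" else test).append(member)
    for j in range(min(n_test_lesion_subjects, len(test))):
        k = len(test) - 1 - j
        test[k] = replace(test[k], n_lesions=1 + j % 3,
                          lesion_classes=tuple(lesion_classes))
    return train, test
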