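"""Seeded synthetic alpha/beta islet-cell phantoms.

The study cohort (8 alpha cells with glucagon vesicles, 7 beta cells with
insulin vesicles) is not publicly deposited, so this module generates
phantoms with the statistical structure the downstream analysis assumes:

* whole-cell geometry: spherical cell and nucleus with class-conditional
  volumes and nuclear occupancy; vesicles placed uniformly in the cytosol
  with hard-sphere rejection;
* vesicle sizes: a calibrated truncated-normal-mixture diameter law whose
  POOLED mean/SD and 120/180-nm bin masses match the cohort summaries, with
  a between-cell location shift so cells are heterogeneous;
* voxel-level LAC: per-vesicle base level = class mean + between-cell offset
  + within-cell scatter, plus a linearly decreasing radial component and
  voxel noise whose combined spread reproduces the within-vesicle SD scale
  (LAC falls from the core centre outward, so maximum-LAC voxels sit near
  the centre and minimum-LAC voxels at the periphery);
* a sub-threshold boundary shell (membrane/lumen halo) around each dense
  core, which is what separates cores from the carbon-rich cytosol under
  threshold segmentation.

Two output modes share the same class-conditional calibrations: full voxel
phantoms (:func:`generate_cell_phantom`, :func:`generate_cohort`) and direct
per-vesicle feature tables (:func:`generate_vesicle_features`) in which every
record is still derived from a sampled voxel list, never drawn marginally,
so the multicollinearity between the 11 LAC parameters is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, calibrate_diameter_distribution
from .extraction import LAC_STAT_COLUMNS, equivalent_diameter, vesicle_lac_stats
from .volumes import (
    LABEL_CELL,
    LABEL_MITOCHONDRIA,
    LABEL_NUCLEUS,
    TomogramVolume,
)

DEFAULT_SEED = 20240518

# variance of the radial coordinate rho = r/R for voxels uniform in a ball
_RHO_MEAN = 0.75
_RHO_VAR = 0.0375


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional cohort distribution parameters.

    All (mean, sd) pairs are cohort summaries: volumes in um3, occupancy in
    percent of cell volume, LAC in 1/um, diameters in nm.  ``*_cell_sd``
    values are between-cell spreads of per-cell means; pooled vesicle spreads
    are decomposed at run time into between-cell and within-cell parts.
    """

    label: str  # "alpha" | "beta"
    vesicle_kind: str  # "glucagon" | "insulin"
    n_cells: int
    cell_volume: tuple[float, float]
    nucleus_occupancy: tuple[float, float]  # percent
    vesicle_count: tuple[float, float]
    diameter_mean: float
    diameter_sd: float
    diameter_bin_edges: tuple[float, ...]
    diameter_bin_fractions: tuple[float, ...]
    diameter_cell_sd: float
    vesicle_lac_mean: float
    vesicle_lac_pooled_sd: float
    vesicle_lac_cell_sd: float
    voxel_sd: tuple[float, float]  # within-vesicle voxel SD: mean, sd
    cytosol_lac: tuple[float, float]
    nucleus_lac: tuple[float, float]
    mitochondria_lac: tuple[float, float]

    @property
    def within_cell_lac_sd(self) -> float:
        v = self.vesicle_lac_pooled_sd**2 - self.vesicle_lac_cell_sd**2
        if v <= 0:
            raise ValueError("pooled vesicle LAC sd must exceed the between-cell sd")
        return float(np.sqrt(v))


@dataclass
class GeneratorConfig:
    """Phantom generator configuration; defaults are the study conditions."""

    voxel_size: float = 35.0  # nm, instrument range 30-45
    alpha: ClassParams = None
    beta: ClassParams = None
    radial_fraction: float = 0.7  # share of within-vesicle variance on the radial term
    halo_lac: float = 0.17  # membrane/lumen shell LAC, below every window
    halo_voxels: float = 2.0  # shell thickness in voxel units
    halo_noise_sd: float = 0.005
    cytosol_noise_sd: float = 0.010
    nucleus_noise_sd: float = 0.010
    max_vesicle_density: float = 8.0  # placement-feasibility cap, per um3 cytosol
    include_mitochondria: bool = False
    mitochondria_occupancy: float = 4.0  # percent of cell volume when enabled
    seed: int = DEFAULT_SEED
    _spec_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.alpha is None:
            self.alpha = _DEFAULT_ALPHA
        if self.beta is None:
            self.beta = _DEFAULT_BETA
        self.validate()

    def validate(self) -> None:
        if not 30.0 <= self.voxel_size <= 45.0:
            raise ValueError("voxel_size must be in [30, 45] nm")
        if not 0.0 <= self.radial_fraction <= 1.0:
            raise ValueError("radial_fraction must be in [0, 1]")
        for cp in (self.alpha, self.beta):
            edges = cp.diameter_bin_edges
            if edges[0] < 100.0 or edges[-1] > 500.0:
                raise ValueError("diameter support must lie within [100, 500] nm")
            for m, s in (cp.cell_volume, cp.nucleus_occupancy, cp.vesicle_count):
                if m <= 0 or s < 0:
                    raise ValueError("volumes/occupancy/counts must be positive")
            cp.within_cell_lac_sd  # raises if the variance split is infeasible

    def class_params(self, cell_class: str) -> ClassParams:
        try:
            return {"alpha": self.alpha, "beta": self.beta}[cell_class]
        except KeyError:
            raise ValueError(f"unknown cell class {cell_class!r}") from None

    def diameter_spec(self, cell_class: str) -> DistributionSpec:
        """Calibrated within-cell diameter mixture (cached per class)."""
        cp = self.class_params(cell_class)
        key = (
            cell_class, cp.diameter_mean, cp.diameter_sd, cp.diameter_bin_edges,
            cp.diameter_bin_fractions, cp.diameter_cell_sd,
        )
        if key not in self._spec_cache:
            self._spec_cache[key] = calibrate_diameter_distribution(
                cp.diameter_mean,
                cp.diameter_sd,
                cp.diameter_bin_edges,
                cp.diameter_bin_fractions,
                cell_shift_sd=cp.diameter_cell_sd,
                seed=1,
            )
        return self._spec_cache[key]


# Cohort summary defaults: per-cell morphology and organelle LAC levels, and
# pooled-vesicle diameter/LAC calibration targets with the between-cell SDs
# taken from the across-cell spreads of per-cell means.
_DEFAULT_ALPHA = ClassParams(
    label="alpha",
    vesicle_kind="glucagon",
    n_cells=8,
    cell_volume=(579.0, 247.0),
    nucleus_occupancy=(21.0, 5.0),
    vesicle_count=(1337.0, 480.0),
    diameter_mean=194.0,
    diameter_sd=49.0,
    diameter_bin_edges=(100.0, 120.0, 180.0, 500.0),
    diameter_bin_fractions=(0.01, 0.50, 0.49),
    diameter_cell_sd=21.0,
    vesicle_lac_mean=0.365,
    vesicle_lac_pooled_sd=0.04,
    vesicle_lac_cell_sd=0.03,
    voxel_sd=(0.012, 0.005),
    cytosol_lac=(0.263, 0.02),
    nucleus_lac=(0.24, 0.02),
    mitochondria_lac=(0.357, 0.03),
)

_DEFAULT_BETA = ClassParams(
    label="beta",
    vesicle_kind="insulin",
    n_cells=7,
    cell_volume=(1191.0, 277.0),
    nucleus_occupancy=(10.0, 3.0),
    vesicle_count=(2099.0, 710.0),
    diameter_mean=157.0,
    diameter_sd=35.0,
    diameter_bin_edges=(100.0, 120.0, 180.0, 500.0),
    diameter_bin_fractions=(0.045, 0.80, 0.155),
    diameter_cell_sd=13.0,
    vesicle_lac_mean=0.328,
    vesicle_lac_pooled_sd=0.03,
    vesicle_lac_cell_sd=0.02,
    voxel_sd=(0.007, 0.003),
    cytosol_lac=(0.237, 0.02),
    nucleus_lac=(0.21, 0.02),
    mitochondria_lac=(0.335, 0.03),
)


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# voxel-level LAC sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadialLACProfile:
    """Sub-vesicular LAC law: linear radial decline plus voxel noise.

    ``within_sd`` is the total within-vesicle voxel SD; ``radial_fraction``
    of its variance is carried by the radial term (value decreases linearly
    with r/R), the rest by i.i.d. noise.  The construction is mean-zero over
    a uniformly sampled ball, so the vesicle's voxel mean stays at the base
    LAC level.
    """

    within_sd: float
    radial_fraction: float = 0.7

    @property
    def slope(self) -> float:
        return float(np.sqrt(self.radial_fraction) * self.within_sd / np.sqrt(_RHO_VAR))

    @property
    def noise_sd(self) -> float:
        return float(np.sqrt(1.0 - self.radial_fraction) * self.within_sd)


def sample_vesicle_voxel_lacs(
    mean_lac: float,
    n_voxels: int,
    profile_params: RadialLACProfile,
    seed: int | np.random.Generator = 0,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Sample voxel LAC values for one dense-core vesicle.

    ``radii`` are normalised radial positions r/R in [0, 1]; when omitted
    they are sampled from the uniform-ball density.  With zero spread the
    result is exactly ``mean_lac`` everywhere.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if radii is None:
        radii = np.cbrt(rng.random(n_voxels))
    else:
        radii = np.asarray(radii, dtype=float)
        if radii.shape != (n_voxels,):
            raise ValueError("radii must have length n_voxels")
    values = mean_lac + profile_params.slope * (_RHO_MEAN - radii)
    if profile_params.noise_sd > 0:
        values = values + rng.normal(0.0, profile_params.noise_sd, n_voxels)
    return values


# ---------------------------------------------------------------------------
# per-cell latent draws (shared by voxel and table modes)
# ---------------------------------------------------------------------------


def _tnorm(rng, mean, sd, lo, hi):
    """Truncated normal draw by rejection (fast for mild truncation)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


@dataclass
class _CellLatents:
    cell_volume: float
    nucleus_volume: float
    nucleus_occupancy: float
    n_vesicles: int
    lac_offset: float
    diameter_offset: float
    cytosol_lac: float
    nucleus_lac: float
    mitochondria_lac: float


@dataclass
class _CohortDraws:
    """Cohort-level per-cell draws for one class.

    The 8+7 study cells are treated as fixed effects: between-cell offsets
    keep their cohort spread but are centred (weighted by vesicle count for
    vesicle-pooled quantities, unweighted for per-cell averages) so the
    REALIZED cohort's pooled statistics sit at the calibration targets
    instead of wobbling with the handful of cell-level draws.
    """

    volumes: np.ndarray
    counts: np.ndarray
    occupancies: np.ndarray
    lac_offsets: np.ndarray
    diameter_offsets: np.ndarray


def _center(x: np.ndarray, weights: np.ndarray | None = None,
            target_sd: float | None = None) -> np.ndarray:
    """Centre draws (optionally count-weighted) and pin their sample SD.

    With fewer than two cells the offsets collapse to zero.
    """
    n = len(x)
    if n < 2:
        return np.zeros_like(x)
    if weights is None:
        c = x - x.mean()
    else:
        w = weights / weights.sum()
        c = x - float(np.sum(w * x))
    if target_sd is not None:
        s = c.std(ddof=1)
        c = c * (target_sd / s) if s > 0 else c
    return c


def _score_offsets(rng, n: int, target_sd: float,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Between-cell offsets as randomly assigned normal scores.

    The 7-8 study cells are a fixed cohort, so their offsets are realized as
    the expected normal order statistics (Blom scores) scaled to the
    between-cell SD and randomly permuted over cells, then count-weighted
    centred.  This pins the cohort's spread exactly and keeps its most
    extreme cell at the typical |z| for the cohort size (~1.4 sd at n = 8)
    instead of letting a single draw over-disperse the whole class.
    """
    if n < 2 or target_sd == 0:
        return np.zeros(n)
    from scipy.special import ndtri

    ranks = np.arange(1, n + 1)
    z = ndtri((ranks - 0.375) / (n + 0.25))
    z = rng.permutation(z)
    return _center(z, weights, target_sd)


def _draw_cohort_latents(config: GeneratorConfig, cp: ClassParams, rng) -> _CohortDraws:
    n = cp.n_cells
    volumes = np.array(
        [
            _tnorm(rng, *cp.cell_volume,
                   max(100.0, cp.cell_volume[0] - 2.5 * cp.cell_volume[1]),
                   cp.cell_volume[0] + 2.5 * cp.cell_volume[1])
            for _ in range(n)
        ]
    )
    occ_lo = max(2.0, cp.nucleus_occupancy[0] - 2.5 * cp.nucleus_occupancy[1])
    occ_hi = min(60.0, cp.nucleus_occupancy[0] + 2.5 * cp.nucleus_occupancy[1])
    occ = np.array([_tnorm(rng, *cp.nucleus_occupancy, occ_lo, occ_hi) for _ in range(n)])
    if n > 1:
        occ = np.clip(
            _center(occ, target_sd=cp.nucleus_occupancy[1]) + cp.nucleus_occupancy[0],
            occ_lo, occ_hi,
        )
    counts = np.array(
        [
            _tnorm(rng, *cp.vesicle_count,
                   max(50.0, cp.vesicle_count[0] - 2.5 * cp.vesicle_count[1]),
                   cp.vesicle_count[0] + 2.5 * cp.vesicle_count[1])
            for _ in range(n)
        ]
    )
    # the placement-feasibility cap is applied here, before counts become
    # calibration weights, so analytic pooling and realization agree
    counts = np.minimum(
        counts, config.max_vesicle_density * volumes * (1.0 - occ / 100.0)
    )
    return _CohortDraws(
        volumes=volumes,
        counts=counts,
        occupancies=occ,
        lac_offsets=_score_offsets(rng, n, cp.vesicle_lac_cell_sd, counts),
        diameter_offsets=_score_offsets(rng, n, cp.diameter_cell_sd, counts),
    )


def _draw_cell_latents(
    config: GeneratorConfig,
    cp: ClassParams,
    rng,
    fixed: dict | None = None,
) -> _CellLatents:
    """Per-cell latent draws; ``fixed`` supplies cohort-coordinated values."""
    fixed = fixed or {}
    vc = fixed.get("cell_volume")
    if vc is None:
        vc = _tnorm(rng, *cp.cell_volume,
                    max(100.0, cp.cell_volume[0] - 2.5 * cp.cell_volume[1]),
                    cp.cell_volume[0] + 2.5 * cp.cell_volume[1])
    occ = fixed.get("occupancy")
    if occ is None:
        occ = _tnorm(rng, *cp.nucleus_occupancy,
                     max(2.0, cp.nucleus_occupancy[0] - 2.5 * cp.nucleus_occupancy[1]),
                     min(60.0, cp.nucleus_occupancy[0] + 2.5 * cp.nucleus_occupancy[1]))
    count = fixed.get("count")
    if count is None:
        count = _tnorm(rng, *cp.vesicle_count,
                       max(50.0, cp.vesicle_count[0] - 2.5 * cp.vesicle_count[1]),
                       cp.vesicle_count[0] + 2.5 * cp.vesicle_count[1])
    lac_off = fixed.get("lac_offset")
    if lac_off is None:
        lac_off = rng.normal(0.0, cp.vesicle_lac_cell_sd)
    diam_off = fixed.get("diameter_offset")
    if diam_off is None:
        diam_off = rng.normal(0.0, cp.diameter_cell_sd)
    cytosol_volume = vc * (1.0 - occ / 100.0)
    count = min(count, config.max_vesicle_density * cytosol_volume)
    # phantom validity: threshold segmentation needs the cytosol background
    # to sit INSIDE the vesicle window as one connected component (removed by
    # the size filter); a cytosol mean straddling the 0.21 1/um window floor
    # fragments into spurious mid-size components, a regime the original
    # morphology-guided segmentation never produced
    cyto_lo = max(
        0.05,
        cp.cytosol_lac[0] - 2.0 * cp.cytosol_lac[1],
        0.21 + 1.9 * config.cytosol_noise_sd,
    )
    cyto_hi = max(cp.cytosol_lac[0] + 2.0 * cp.cytosol_lac[1], cyto_lo + 1e-3)
    return _CellLatents(
        cell_volume=vc,
        nucleus_volume=vc * occ / 100.0,
        nucleus_occupancy=occ,
        n_vesicles=int(round(count)),
        lac_offset=float(lac_off),
        diameter_offset=float(diam_off),
        cytosol_lac=_tnorm(rng, *cp.cytosol_lac, cyto_lo, cyto_hi),
        nucleus_lac=_tnorm(rng, *cp.nucleus_lac, 0.05, 0.45),
        mitochondria_lac=_tnorm(rng, *cp.mitochondria_lac, 0.1, 0.5),
    )


def _shifted_spec(spec: DistributionSpec, delta: float) -> DistributionSpec:
    if spec.family == "truncnorm_mixture":
        comps = tuple((w, mu + delta, sd) for w, mu, sd in spec.params)
        return replace(spec, params=comps)
    if spec.family == "point":
        return replace(spec, params=(float(np.clip(spec.params[0] + delta, spec.lo, spec.hi)),))
    raise ValueError("per-cell diameter shifts require the mixture or point family")


def _draw_vesicle_params(config, cp, lat, rng, n, spec=None):
    """Diameters, base LAC levels and within-vesicle SDs for n vesicles."""
    spec = _shifted_spec(spec or config.diameter_spec(cp.label), lat.diameter_offset)
    diameters = spec.sample(n, rng)
    base = cp.vesicle_lac_mean + lat.lac_offset + rng.normal(
        0.0, cp.within_cell_lac_sd, n
    )
    m, s = cp.voxel_sd
    lo = max(0.002, m - 2.5 * s)
    within = np.clip(rng.normal(m, s, n), lo, m + 3 * s)
    return diameters, base, within


# ---------------------------------------------------------------------------
# ground truth + voxel phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomGroundTruth:
    """Per-vesicle and per-cell ground truth for one phantom."""

    cell_id: str
    cell_class: str
    cell_volume: float  # um3, analytic (pre-rasterization)
    nucleus_volume: float
    centers: np.ndarray  # (n, 3) voxel coordinates (z, y, x)
    diameters: np.ndarray  # nm
    base_lac: np.ndarray  # 1/um
    voxel_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "cell_class": self.cell_class,
                "center_z": self.centers[:, 0],
                "center_y": self.centers[:, 1],
                "center_x": self.centers[:, 2],
                "diameter": self.diameters,
                "base_lac": self.base_lac,
                "voxel_sd": self.voxel_sd,
            }
        )


def _sphere_radius_nm(volume_um3: float) -> float:
    return (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0) * 1000.0


class PlacementError(RuntimeError):
    """Hard-sphere vesicle placement failed after bounded retries."""


def _place_vesicles(rng, radii_nm, r_cell, r_nuc, nuc_center, gap, margin, max_tries=300):
    """Non-overlapping sphere centers, uniform in the cytosol shell.

    Big-first placement with a uniform cell-list for neighbour queries; each
    vesicle gets ``max_tries`` rejection attempts before PlacementError.
    Returns centers in nm relative to the cell centre, in the input order.
    """
    order = np.argsort(radii_nm)[::-1]
    n = len(radii_nm)
    centers = np.zeros((n, 3))
    bucket = max(2.0 * radii_nm.max() + gap, 1.0)
    grid: dict[tuple, list[int]] = {}

    for idx in order:
        R = radii_nm[idx]
        r_max = r_cell - R - margin
        if r_max <= 0:
            raise PlacementError(
                f"vesicle of radius {R:.0f} nm cannot fit inside the cell"
            )
        ok = False
        for _ in range(max_tries):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            c = v * r_max * np.cbrt(rng.random())
            if np.linalg.norm(c - nuc_center) < r_nuc + R + margin:
                continue
            key = tuple((c // bucket).astype(int))
            clash = False
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        for j in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                            if np.linalg.norm(c - centers[j]) < R + radii_nm[j] + gap:
                                clash = True
                                break
                        if clash:
                            break
                    if clash:
                        break
                if clash:
                    break
            if not clash:
                centers[idx] = c
                grid.setdefault(key, []).append(idx)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place vesicle of radius {R:.0f} nm after {max_tries} tries"
            )
    return centers


def generate_cell_phantom(
    config: GeneratorConfig,
    cell_class: str,
    seed: int | np.random.SeedSequence,
    cell_id: str | None = None,
    _fixed: dict | None = None,
) -> tuple[TomogramVolume, PhantomGroundTruth]:
    """Rasterize one synthetic cell as a labelled LAC volume.

    The volume contains a spherical cell mask filled with noisy cytosol at
    the class LAC level, a nucleus mask, optional mitochondria blobs, and
    non-overlapping dense-core vesicles, each wrapped in a sub-threshold
    boundary shell.  Ground truth (true centers, diameters, base LACs and
    analytic volumes) is returned alongside.
    """
    cp = config.class_params(cell_class)
    rng = np.random.default_rng(seed)
    cell_id = cell_id or f"{cell_class}_0"
    lat = _draw_cell_latents(config, cp, rng, _fixed)
    v = config.voxel_size
    halo = config.halo_voxels * v
    gap = 2.5 * v

    r_cell = _sphere_radius_nm(lat.cell_volume)
    r_nuc = _sphere_radius_nm(lat.nucleus_volume)
    # nucleus stays fully inside the cell with a modest random offset
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    nuc_center = direction * rng.random() * 0.5 * (r_cell - r_nuc)

    n_side = int(np.ceil(2 * r_cell / v)) + 4
    center_nm = n_side / 2.0 * v
    ax = (np.arange(n_side) + 0.5) * v - center_nm
    d2 = (
        (ax**2)[:, None, None] + (ax**2)[None, :, None] + (ax**2)[None, None, :]
    ).astype(np.float32)
    cell_mask = d2 <= r_cell**2
    d2n = (
        ((ax - nuc_center[0]) ** 2)[:, None, None]
        + ((ax - nuc_center[1]) ** 2)[None, :, None]
        + ((ax - nuc_center[2]) ** 2)[None, None, :]
    ).astype(np.float32)
    nuc_mask = d2n <= r_nuc**2
    del d2n

    labels = np.zeros(d2.shape, dtype=np.uint8)
    labels[cell_mask] = LABEL_CELL
    labels[nuc_mask & cell_mask] = LABEL_NUCLEUS
    lac = np.zeros(d2.shape, dtype=np.float32)
    del d2
    n_cyto = int((labels == LABEL_CELL).sum())
    lac[labels == LABEL_CELL] = rng.normal(lat.cytosol_lac, config.cytosol_noise_sd, n_cyto)
    n_nuc = int((labels == LABEL_NUCLEUS).sum())
    lac[labels == LABEL_NUCLEUS] = rng.normal(lat.nucleus_lac, config.nucleus_noise_sd, n_nuc)

    diameters, base, within = _draw_vesicle_params(
        config, cp, lat, rng, lat.n_vesicles, spec=(_fixed or {}).get("diameter_spec")
    )
    radii = diameters / 2.0
    # keep each halo clear of the cell and nucleus boundaries: a halo touching
    # a boundary can trap an in-window cytosol sliver as a spurious component
    margin = halo + 2.0 * v
    mito_radii = np.array([])
    mito_centers = np.zeros((0, 3))
    if config.include_mitochondria:
        mito_vol = lat.cell_volume * config.mitochondria_occupancy / 100.0
        n_mito = max(1, int(round(mito_vol / 0.35)))
        mito_radii = np.full(n_mito, _sphere_radius_nm(0.35))
        all_r = np.concatenate([radii, mito_radii])
        centers_all = _place_vesicles(
            rng, all_r, r_cell, r_nuc, nuc_center, gap, margin=margin
        )
        centers, mito_centers = centers_all[: len(radii)], centers_all[len(radii):]
    else:
        centers = _place_vesicles(rng, radii, r_cell, r_nuc, nuc_center, gap, margin=margin)

    profile_f = config.radial_fraction

    def _local_block(c, reach):
        i0 = np.maximum(((c + center_nm - reach) / v - 0.5).astype(int), 0)
        i1 = np.minimum(((c + center_nm + reach) / v + 1.5).astype(int), n_side)
        sl = tuple(slice(a, b) for a, b in zip(i0, i1))
        local_ax = [ (np.arange(a, b) + 0.5) * v - center_nm - cc
                     for (a, b), cc in zip(zip(i0, i1), c) ]
        dist = np.sqrt(
            (local_ax[0] ** 2)[:, None, None]
            + (local_ax[1] ** 2)[None, :, None]
            + (local_ax[2] ** 2)[None, None, :]
        )
        return sl, dist

    # mitochondria first so vesicle halos are never overwritten
    for c, R in zip(mito_centers, mito_radii):
        sl, dist = _local_block(c, R)
        m = (dist <= R) & (labels[sl] == LABEL_CELL)
        labels[sl][m] = LABEL_MITOCHONDRIA
        lac[sl][m] = rng.normal(lat.mitochondria_lac, config.cytosol_noise_sd, int(m.sum()))

    for c, R, b, s in zip(centers, radii, base, within):
        sl, dist = _local_block(c, R + halo)
        shell = (dist > R) & (dist <= R + halo) & (labels[sl] == LABEL_CELL)
        lac[sl][shell] = rng.normal(config.halo_lac, config.halo_noise_sd, int(shell.sum()))
        core = dist <= R
        n_core = int(core.sum())
        if n_core == 0:
            continue
        rho = np.minimum(dist[core] / R, 1.0)
        lac[sl][core] = sample_vesicle_voxel_lacs(
            b, n_core, RadialLACProfile(s, profile_f), rng, radii=rho
        )

    np.maximum(lac, 0.0, out=lac)
    volume = TomogramVolume(
        lac=lac, voxel_size=v, labels=labels, cell_id=cell_id, cell_class=cell_class
    )
    truth = PhantomGroundTruth(
        cell_id=cell_id,
        cell_class=cell_class,
        cell_volume=lat.cell_volume,
        nucleus_volume=lat.nucleus_volume,
        centers=(centers + center_nm) / v - 0.5,
        diameters=diameters,
        base_lac=base,
        voxel_sd=within,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# cohort-level drivers
# ---------------------------------------------------------------------------


def _cohort_cells(config: GeneratorConfig) -> list[tuple[str, str]]:
    cells = [("alpha", f"alpha_{i + 1}") for i in range(config.alpha.n_cells)]
    cells += [("beta", f"beta_{i + 1}") for i in range(config.beta.n_cells)]
    return cells


def _cohort_plan(config: GeneratorConfig, seed: int):
    """Per-cell seeds plus cohort-coordinated latents for both classes.

    The diameter mixture of each class is recalibrated against the cohort's
    realized (centred, count-weighted) cell offsets, so the pooled diameter
    summary of these particular cells — not just their Gaussian average —
    hits the calibration targets.
    """
    cells = _cohort_cells(config)
    children = np.random.SeedSequence(seed).spawn(len(cells) + 1)
    cohort_rng = np.random.default_rng(children[-1])
    fixed: dict[str, dict] = {}
    for cls in ("alpha", "beta"):
        cp = config.class_params(cls)
        draws = _draw_cohort_latents(config, cp, cohort_rng)
        key = (
            cls, cp.diameter_mean, cp.diameter_sd, cp.diameter_bin_edges,
            cp.diameter_bin_fractions, tuple(draws.diameter_offsets),
            tuple(draws.counts),
        )
        if key not in config._spec_cache:
            config._spec_cache[key] = calibrate_diameter_distribution(
                cp.diameter_mean,
                cp.diameter_sd,
                cp.diameter_bin_edges,
                cp.diameter_bin_fractions,
                cell_shifts=draws.diameter_offsets,
                cell_weights=draws.counts,
                seed=1,
            )
        spec = config._spec_cache[key]
        ids = [cid for c, cid in cells if c == cls]
        for i, cid in enumerate(ids):
            fixed[cid] = {
                "cell_volume": float(draws.volumes[i]),
                "count": float(draws.counts[i]),
                "occupancy": float(draws.occupancies[i]),
                "lac_offset": float(draws.lac_offsets[i]),
                "diameter_offset": float(draws.diameter_offsets[i]),
                "diameter_spec": spec,
            }
    return [(cls, cid, child, fixed[cid]) for (cls, cid), child in zip(cells, children)]


def iter_cohort_phantoms(
    config: GeneratorConfig, seed: int | None = None
) -> Iterator[tuple[TomogramVolume, PhantomGroundTruth]]:
    """Yield the cohort's voxel phantoms one cell at a time (memory-light)."""
    seed = config.seed if seed is None else seed
    for cls, cid, child, fixed in _cohort_plan(config, seed):
        yield generate_cell_phantom(config, cls, child, cell_id=cid, _fixed=fixed)


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> list[tuple[TomogramVolume, PhantomGroundTruth]]:
    """All cohort phantoms as a list (default 8 alpha + 7 beta)."""
    return list(iter_cohort_phantoms(config, seed))


def cohort_ground_truth_table(truths) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in truths], ignore_index=True)


def generate_vesicle_features(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vesicle feature table straight from the calibrated laws.

    Skips rasterization: each vesicle's voxel count follows from its true
    diameter at the configured voxel size, radial positions are sampled from
    the ball density, and the 11 LAC parameters are computed from that voxel
    list with the same estimator used on segmented data.  Returns
    ``(features, cells)`` where ``cells`` carries the per-cell latents.
    """
    seed = config.seed if seed is None else seed
    vox = config.voxel_size
    vox_vol = vox**3

    feat_rows, cell_rows = [], []
    for cls, cid, child, fixed in _cohort_plan(config, seed):
        cp = config.class_params(cls)
        rng = np.random.default_rng(child)
        lat = _draw_cell_latents(config, cp, rng, fixed)
        diameters, base, within = _draw_vesicle_params(
            config, cp, lat, rng, lat.n_vesicles, spec=fixed.get("diameter_spec")
        )
        for k in range(lat.n_vesicles):
            n_vox = max(1, int(round(np.pi / 6.0 * diameters[k] ** 3 / vox_vol)))
            values = sample_vesicle_voxel_lacs(
                base[k], n_vox, RadialLACProfile(within[k], config.radial_fraction), rng
            )
            rec = {
                "vesicle_id": f"{cid}_v{k}",
                "cell_id": cid,
                "cell_class": cls,
                "n_voxels": n_vox,
                "diameter": equivalent_diameter(n_vox, vox),
            }
            rec.update(vesicle_lac_stats(values))
            feat_rows.append(rec)
        cell_rows.append(
            {
                "cell_id": cid,
                "cell_class": cls,
                "cell_volume": lat.cell_volume,
                "nucleus_volume": lat.nucleus_volume,
                "nuclear_occupancy": lat.nucleus_occupancy,
                "n_vesicles": lat.n_vesicles,
                "cytosol_lac": lat.cytosol_lac,
                "nucleus_lac": lat.nucleus_lac,
            }
        )
    cols = ["vesicle_id", "cell_id", "cell_class", "n_voxels", "diameter"]
    cols += LAC_STAT_COLUMNS + ["degenerate"]
    return pd.DataFrame(feat_rows, columns=cols), pd.DataFrame(cell_rows)
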