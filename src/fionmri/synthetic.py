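"""Synthetic MR data with known ground truth.

Two generators cover the two acquisition regimes the analysis needs:

* a multi-echo **phantom** of agar tubes holding iron-oxide-labeled cell
  pellets, where the per-voxel signal follows mono-exponential T2* decay with
  the relaxation rate linear in iron concentration through the agent's
  relaxivity; and
* a single-echo in-vivo-like **scene** with a lesion (tumor or lymph node)
  region, a muscle reference region, and a designed fraction of lesion voxels
  carrying labeled-macrophage signal loss.

Both add Rician noise (the magnitude of a complex Gaussian), which is the
noise distribution of magnitude MR images, and both return a
:class:`~fionmri.containers.GroundTruth` so every downstream stage can be
validated against the design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EchoSeries, GroundTruth, ROISet
from .errors import ConfigError

IRON_MOLAR_MASS_G_PER_MOL = 55.845

#: Phantom tube iron concentrations used throughout (µg Fe/mL); the labeling
#: series spans no iron up to the saturating concentration.
DEFAULT_TUBE_CONCENTRATIONS = (0.0, 12.5, 25.0, 50.0, 100.0)


def iron_to_molar(conc_ug_per_ml: float) -> float:
    """Convert an iron concentration in µg Fe/mL to mM.

    µg/mL is mg/L; dividing by the molar mass of iron (55.845 g/mol) gives
    mmol/L = mM, the unit relaxivity is quoted in.
    """
    conc = np.asarray(conc_ug_per_ml, dtype=float)
    if np.any(conc < 0):
        raise ConfigError("iron concentration must be >= 0 µg Fe/mL")
    out = conc / IRON_MOLAR_MASS_G_PER_MOL
    return float(out) if np.isscalar(conc_ug_per_ml) else out


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Rician noise to a noiseless magnitude image.

    The measured magnitude is ``sqrt((s + n1)^2 + n2^2)`` with independent
    ``n1, n2 ~ N(0, sigma^2)``; at sigma=0 the signal is returned unchanged.
    """
    if sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _ball_mask(grid: tuple, center: tuple, radius: float) -> np.ndarray:
    """Boolean disk (2-D) or ball (3-D) on a regular isotropic grid."""
    coords = np.indices(grid, dtype=float)
    d2 = sum((c - ctr) ** 2 for c, ctr in zip(coords, center))
    return d2 <= radius**2


@dataclass(frozen=True)
class Tube:
    """One cell-pellet tube in the phantom.

    ``iron_concentration`` is the labeling concentration in µg Fe/mL;
    ``intrinsic_t2star`` (ms) is the tissue T2* with no iron (100 ms for
    unlabeled macrophage pellets in agar); ``si0`` is the proton-density
    signal amplitude in arbitrary intensity units.
    """

    label: str
    iron_concentration: float
    intrinsic_t2star: float = 100.0
    si0: float = 1000.0

    def __post_init__(self):
        if self.iron_concentration < 0:
            raise ConfigError(f"tube {self.label!r}: iron concentration < 0")
        if self.intrinsic_t2star <= 0:
            raise ConfigError(f"tube {self.label!r}: intrinsic_t2star must be > 0")
        if self.si0 <= 0:
            raise ConfigError(f"tube {self.label!r}: si0 must be > 0")

    @property
    def r2star_s(self) -> float:
        """True relaxation rate in s⁻¹ under the linear relaxivity model.

        Set by the enclosing PhantomSpec; kept here as a convenience when the
        default relaxivity is meant.
        """
        return true_r2star(self.iron_concentration, self.intrinsic_t2star)


def true_r2star(
    iron_concentration: float,
    intrinsic_t2star: float,
    relaxivity_r2star: float = 324.0,
) -> float:
    """R2* (s⁻¹) = 1000/T2*_intrinsic(ms) + r2* (mM⁻¹s⁻¹) × C (mM)."""
    return 1000.0 / intrinsic_t2star + relaxivity_r2star * iron_to_molar(
        iron_concentration
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and physics of the multi-echo tube phantom.

    Tubes are disks of ``tube_radius`` voxels placed at ``tube_centers`` (or
    spread evenly along the grid mid-line when centers are omitted) in a
    background of slowly-decaying agar. ``relaxivity_r2star`` is the agent's
    r2* in mM⁻¹s⁻¹ (324 for the ferromagnetic iron-oxide nanocubes at 1.5 T);
    ``noise_sigma`` is the Rician sigma in the same intensity units as si0.
    """

    tubes: tuple = tuple(
        Tube(label=f"{c:g} ugFe/mL", iron_concentration=c)
        for c in DEFAULT_TUBE_CONCENTRATIONS
    )
    grid: tuple = (64, 64)
    tube_radius: float = 5.0
    tube_centers: tuple | None = None
    relaxivity_r2star: float = 324.0
    background_si: float = 50.0
    background_t2star: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relaxivity_r2star <= 0:
            raise ConfigError("relaxivity_r2star must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not self.tubes:
            raise ConfigError("phantom needs at least one tube")
        if self.tube_centers is not None and len(self.tube_centers) != len(self.tubes):
            raise ConfigError("one center per tube required")

    def centers(self) -> list:
        if self.tube_centers is not None:
            return [tuple(c) for c in self.tube_centers]
        n = len(self.tubes)
        axis = self.grid[-1]
        xs = np.linspace(0, axis, 2 * n + 1)[1::2]
        mid = tuple(g / 2 for g in self.grid[:-1])
        return [mid + (x,) for x in xs]

    def tube_masks(self) -> dict:
        masks = {}
        occupied = np.zeros(self.grid, dtype=bool)
        for tube, center in zip(self.tubes, self.centers()):
            m = _ball_mask(self.grid, center, self.tube_radius)
            if not m.any():
                raise ConfigError(f"tube {tube.label!r} lies outside the grid")
            if np.any(m & occupied):
                raise ConfigError(f"tube {tube.label!r} overlaps another tube")
            occupied |= m
            masks[tube.label] = m
        return masks


def simulate_phantom(
    spec: PhantomSpec, echo_times: "list[float]"
) -> tuple:
    """Generate the multi-echo phantom and its per-voxel T2* ground truth.

    Per voxel the noiseless signal is ``si0 * exp(-TE * R2*)`` with
    ``R2* (1/ms) = R2*(s⁻¹)/1000`` and R2* linear in molar iron concentration
    through the spec's relaxivity. Rician noise is drawn independently per
    echo. Returns ``(EchoSeries, ROISet of tube masks, GroundTruth)``.
    """
    te = np.asarray(echo_times, dtype=float)
    if te.size < 2:
        raise ConfigError("need at least two echo times")
    if np.any(te <= 0):
        raise ConfigError("echo times must be positive")
    if np.unique(te).size != te.size:
        raise ConfigError("duplicate echo times")
    order = np.argsort(te)
    te = te[order]

    si0_map = np.full(spec.grid, spec.background_si, dtype=float)
    r2_map = np.full(spec.grid, 1.0 / spec.background_t2star, dtype=float)  # 1/ms
    masks = spec.tube_masks()
    for tube in spec.tubes:
        m = masks[tube.label]
        si0_map[m] = tube.si0
        r2_map[m] = (
            true_r2star(
                tube.iron_concentration, tube.intrinsic_t2star, spec.relaxivity_r2star
            )
            / 1000.0
        )

    noiseless = si0_map[None] * np.exp(-te.reshape((-1,) + (1,) * len(spec.grid)) * r2_map[None])
    rng = np.random.default_rng(spec.seed)
    data = np.stack([rician_noise(v, spec.noise_sigma, rng) for v in noiseless])

    series = EchoSeries(
        data=data,
        echo_times=te,
        meta={"kind": "phantom", "relaxivity_r2star": spec.relaxivity_r2star},
    )
    truth = GroundTruth(t2star_ms=1.0 / r2_map)
    return series, ROISet(masks), truth


@dataclass(frozen=True)
class SceneSpec:
    """A single-echo in-vivo-like scene: lesion + muscle reference + noise.

    The lesion (tumor or lymph node) is a disk/ball of ``lesion_radius``
    voxels; a designed ``hypointense_fraction`` of its voxels carries
    labeled-macrophage signal loss, modeled as the multiplicative factor
    ``hypointense_si_factor`` on the baseline lesion signal at the scene's
    single echo time. The muscle disk is the normalization reference and is
    unaffected by the agent.
    """

    grid: tuple = (48, 48)
    lesion_center: tuple = (24.0, 16.0)
    lesion_radius: float = 9.0
    muscle_center: tuple = (24.0, 38.0)
    muscle_radius: float = 5.0
    baseline_lesion_si: float = 600.0
    muscle_si: float = 500.0
    hypointense_fraction: float = 0.0
    hypointense_si_factor: float = 0.25
    noise_sigma: float = 20.0
    echo_time: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hypointense_fraction <= 1.0:
            raise ConfigError("hypointense_fraction must be in [0, 1]")
        if not 0.0 < self.hypointense_si_factor < 1.0:
            raise ConfigError("hypointense_si_factor must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.baseline_lesion_si <= 0 or self.muscle_si <= 0:
            raise ConfigError("signal levels must be > 0")

    def roi_masks(self) -> dict:
        lesion = _ball_mask(self.grid, self.lesion_center, self.lesion_radius)
        muscle = _ball_mask(self.grid, self.muscle_center, self.muscle_radius)
        if not lesion.any() or not muscle.any():
            raise ConfigError("lesion/muscle mask empty — check geometry")
        for name, center, radius in (
            ("lesion", self.lesion_center, self.lesion_radius),
            ("muscle", self.muscle_center, self.muscle_radius),
        ):
            for c, g in zip(center, self.grid):
                if c - radius < -0.5 or c + radius > g - 0.5:
                    raise ConfigError(f"{name} mask does not fit inside the grid")
        if np.any(lesion & muscle):
            raise ConfigError("lesion and muscle masks overlap")
        return {"lesion": lesion, "muscle": muscle}


def simulate_scene(spec: SceneSpec) -> tuple:
    """Generate one single-echo scene.

    Exactly ``round(hypointense_fraction × n_lesion_voxels)`` lesion voxels
    (round half up), chosen uniformly at random under the spec's seed, have
    mean signal ``baseline_lesion_si × hypointense_si_factor``; the remaining
    lesion voxels sit at ``baseline_lesion_si`` and muscle at ``muscle_si``.
    Rician noise is then applied to the whole scene. Returns
    ``(EchoSeries with one echo, ROISet, GroundTruth)``.
    """
    masks = spec.roi_masks()
    lesion, muscle = masks["lesion"], masks["muscle"]

    rng = np.random.default_rng(spec.seed)
    mean = np.zeros(spec.grid, dtype=float)
    mean[lesion] = spec.baseline_lesion_si
    mean[muscle] = spec.muscle_si

    n_lesion = int(lesion.sum())
    n_hypo = _round_half_up(spec.hypointense_fraction * n_lesion)
    lesion_idx = np.flatnonzero(lesion.ravel())
    chosen = rng.choice(lesion_idx, size=n_hypo, replace=False)
    hypo = np.zeros(spec.grid, dtype=bool)
    hypo.ravel()[chosen] = True
    mean.ravel()[chosen] = spec.baseline_lesion_si * spec.hypointense_si_factor

    noisy = rician_noise(mean, spec.noise_sigma, rng)
    series = EchoSeries(
        data=noisy[None],
        echo_times=np.array([spec.echo_time]),
        meta={"kind": "scene"},
    )
    truth = GroundTruth(
        hypointense=hypo,
        designed_fraction_pct=100.0 * n_hypo / n_lesion,
    )
    return series, ROISet(masks), truth


@dataclass(frozen=True)
class CellLoadModel:
    """Bridge from per-cell iron load to a voxel iron concentration.

    With ``iron_per_cell`` in pg Fe (4.539 pg is the saturating macrophage
    uptake of the nanocubes), ``cells_per_voxel`` cells in a voxel of
    ``voxel_volume_mm3`` mm³, the voxel concentration in µg Fe/mL equals
    ``iron_per_cell * cells_per_voxel / voxel_volume_mm3 * 1e-3`` (pg/mm³ →
    µg/mL is a factor 10⁻³, since 1 mL = 10³ mm³ and 1 µg = 10⁶ pg).
    """

    iron_per_cell_pg: float = 4.539
    cells_per_voxel: float = 0.0
    voxel_volume_mm3: float = 1.0

    def __post_init__(self):
        if self.iron_per_cell_pg < 0 or self.cells_per_voxel < 0:
            raise ConfigError("iron load and cell count must be >= 0")
        if self.voxel_volume_mm3 <= 0:
            raise ConfigError("voxel volume must be > 0")

    @property
    def voxel_concentration_ug_per_ml(self) -> float:
        return (
            self.iron_per_cell_pg * self.cells_per_voxel / self.voxel_volume_mm3 * 1e-3
        )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm: n subjects whose designed hypointense fraction is drawn
    from a truncated normal (bounds [0, 1]) with the given mean and sd."""

    name: str
    n_subjects: int
    mean_fraction: float
    sd_fraction: float

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError(f"group {self.name!r}: n_subjects must be >= 1")
        if not 0.0 <= self.mean_fraction <= 1.0:
            raise ConfigError(f"group {self.name!r}: mean_fraction must be in [0, 1]")
        if self.sd_fraction < 0:
            raise ConfigError(f"group {self.name!r}: sd_fraction must be >= 0")


@dataclass(frozen=True)
class SubjectScenes:
    """Pre/post scene pair for one lesion of one subject."""

    group: str
    subject: str
    designed_fraction: float
    pre: tuple  # (EchoSeries, ROISet, GroundTruth)
    post: tuple


#: Designed hypointense fractions of the three lymph-node arms (metastatic
#: brachial and axillary, non-metastatic inguinal): group mean ± sd in
#: fraction units.
LN_GROUPS = (
    GroupSpec("brachial", 6, 0.45064, 0.11932),
    GroupSpec("axillary", 6, 0.34242, 0.11456),
    GroupSpec("inguinal", 6, 0.08413, 0.05449),
)

#: Tumor arms: macrophage-delivered agent vs free agent solution.
TUMOR_GROUPS = (
    GroupSpec("labeled_macrophages", 6, 0.12093, 0.04139),
    GroupSpec("fion_solution", 6, 0.02074, 0.01461),
)


def _draw_truncated_fraction(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_ln_cohort(
    groups: "tuple[GroupSpec, ...]" = LN_GROUPS,
    scene: SceneSpec = SceneSpec(),
    seed: int = 0,
) -> "list[SubjectScenes]":
    """Simulate a cohort of pre/post scene pairs, one lesion per subject.

    Each subject's designed post-injection hypointense fraction is drawn from
    the group's truncated normal; the pre-injection scene always has fraction
    zero (no agent on board). All randomness (fraction draws, voxel choice,
    noise) flows from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_scenes = 2 * sum(g.n_subjects for g in groups)
    scene_seeds = iter(
        np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, n_scenes)
    )

    cohort = []
    for grp in groups:
        fractions = _draw_truncated_fraction(
            grp.mean_fraction, grp.sd_fraction, grp.n_subjects, rng
        )
        for i, f in enumerate(fractions):
            pre_spec = dataclasses.replace(
                scene, hypointense_fraction=0.0, seed=int(next(scene_seeds))
            )
            post_spec = dataclasses.replace(
                scene, hypointense_fraction=float(f), seed=int(next(scene_seeds))
            )
            cohort.append(
                SubjectScenes(
                    group=grp.name,
                    subject=f"{grp.name}_{i:02d}",
                    designed_fraction=float(f),
                    pre=simulate_scene(pre_spec),
                    post=simulate_scene(post_spec),
                )
            )
    return cohort
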