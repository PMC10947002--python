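"""Synthetic longitudinal fetal-brain cohorts with full ground truth.

Real fetal MRI of this kind is not publicly deposited, so the pipeline is
exercised on a synthetic cohort whose geometry and growth are known by
construction.  Each subject carries three timepoints (before surgery, ~1
week after, ~6 weeks after, in decimal gestational weeks) and three
structures on a 0.8 mm isotropic grid:

* unmyelinated white matter — a star-shaped radial surface
  r(θ, φ) = R(ga) · E(θ, φ) · (1 + a(ga) · f(θ, φ)), where E is an
  ellipsoidal base shape, f a fixed band-limited sum of sinusoids with
  per-subject random phases (the "folding field", normalised to max |f| = 1)
  and a(ga) a gyrification amplitude increasing linearly with gestational
  age;
* ventricles — two mirrored ellipsoids (the lateral bodies) whose total
  volume follows a programmed linear growth in GA; the atrial-diameter
  surrogate is the minor-axis diameter;
* cerebellum — an ellipsoid below the cerebrum, growing linearly.

Because every timepoint of a subject is triangulated on the same (θ, φ)
parameter grid, vertices correspond across timepoints by index, lobe labels
are exact angular sectors, and all volumes/areas have quadrature ground
truth.  Group effects are programmed: ventricular global growth rates are
drawn from log-normal distributions whose medians and IQR-matched dispersion
follow the reported cohort (2500.94 (IQR 1689.70–3580.80) mm³/week for the
surgery group vs 708.21 (IQR 474.50–925.00) mm³/week for controls), with
rate multipliers for the partial-corpus-callosum-agenesis and persistent-
hindbrain-herniation subpopulations; folding amplitude grows faster
immediately after surgery and slower later in the surgery group.  Severely
enlarged ventricles stretch the white-matter mantle outwards
(hydrocephalus-like macrocephaly) so that structures always nest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .surface_io import (
    LABEL_CEREBELLUM,
    LABEL_VENTRICLES,
    LABEL_WHITE_MATTER,
    LabelVolume,
    SurfaceMesh,
    write_label_volume,
)

GA_MIN, GA_MAX = 20.0, 37.0

#: lobe codes: 4 lobes x 2 hemispheres
LOBE_NAMES = (
    "frontal_left", "frontal_right",
    "parietal_left", "parietal_right",
    "temporal_left", "temporal_right",
    "occipital_left", "occipital_right",
)

# fixed band-limited folding basis: (l, m, weight) for sin(lθ+ψ)·cos(mφ+χ),
# tapered by sin θ so the field vanishes at the poles
_FOLD_TERMS = (
    (3, 2, 1.00), (4, 3, 0.90), (5, 4, 0.80), (6, 5, 0.70),
    (5, 7, 0.60), (7, 6, 0.50), (6, 8, 0.45), (8, 7, 0.40),
)


def _lognormal_sigma(iqr: tuple[float, float]) -> float:
    """Dispersion of a log-normal matched to a printed interquartile range."""
    from scipy.stats import norm

    return float(np.log(iqr[1] / iqr[0]) / (2 * norm.ppf(0.75)))


@dataclass(frozen=True)
class GASchedule:
    """Per-group gestational-age means/SDs (decimal weeks) at T1, T2, T3."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]


@dataclass(frozen=True)
class RateModel:
    """Log-normal weekly-rate model anchored to a median and IQR."""

    median: float
    iqr: tuple[float, float]

    @property
    def sigma(self) -> float:
        return _lognormal_sigma(self.iqr)


@dataclass(frozen=True)
class FoldingProfile:
    """Gyrification amplitude a(ga): piecewise linear with a breakpoint."""

    a0: float          # amplitude at 20 weeks
    slope_early: float  # per week, ga <= break_ga
    slope_late: float   # per week, ga > break_ga
    break_ga: float = 26.0

    def amplitude(self, ga: float) -> float:
        if ga <= self.break_ga:
            return self.a0 + self.slope_early * (ga - GA_MIN)
        early = self.a0 + self.slope_early * (self.break_ga - GA_MIN)
        return early + self.slope_late * (ga - self.break_ga)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the reported cohort: 29 surgery (OSB) subjects vs 12
    controls, their GA schedules, the printed ventricular global growth
    medians/IQRs as the programmed rate model, covariate frequencies, and
    the 0.8 mm isotropic grid.
    """

    n_osb: int = 29
    n_control: int = 12
    seed: int = 0
    spacing: float = 0.8

    # surface parameter grid (rows x columns); vertices correspond by index
    n_theta: int = 40
    n_phi: int = 80

    ga_osb: GASchedule = field(
        default_factory=lambda: GASchedule((23.43, 25.86, 31.86), (1.14, 0.71, 1.0))
    )
    ga_control: GASchedule = field(
        default_factory=lambda: GASchedule((23.14, 28.86, 32.86), (1.29, 1.43, 1.71))
    )

    vent_rate_osb: RateModel = field(
        default_factory=lambda: RateModel(2500.94, (1689.70, 3580.80))
    )
    vent_rate_control: RateModel = field(
        default_factory=lambda: RateModel(708.21, (474.50, 925.00))
    )

    # covariate frequencies in the surgery group (printed cohort proportions)
    frac_myeloschisis: float = 7 / 29
    frac_pacc: float = 10 / 29
    frac_cc_abnormal: float = 6 / 29
    frac_heterotopia: float = 7 / 29
    frac_persistent_hh: float = 0.40
    vm_fractions: tuple[float, float, float] = (4 / 29, 8 / 29, 17 / 29)  # mild/mod/sev

    # ventricular-rate multipliers for effect subpopulations (ratios of the
    # printed subgroup global medians to the overall surgery median)
    pacc_rate_multiplier: float = 1.27
    hh_rate_multiplier: float = 2.0

    # white-matter base radius R(ga) = wm_radius_20wk + wm_radius_slope*(ga-20)
    wm_radius_20wk: float = 21.0
    wm_radius_slope: float = 1.5
    ellipsoid_ratios: tuple[float, float, float] = (1.0, 1.15, 0.9)

    folding_osb: FoldingProfile = field(
        default_factory=lambda: FoldingProfile(0.05, 0.022, 0.008, 26.0)
    )
    folding_control: FoldingProfile = field(
        default_factory=lambda: FoldingProfile(0.05, 0.013, 0.013, 26.0)
    )

    # lateral-ventricle shape: semi-axes proportional to (1, 1.8, 0.75) of the
    # atrial semi-diameter; mirrored pair split across the midline
    vent_axis_ratios: tuple[float, float, float] = (1.0, 1.8, 0.75)
    vent_midline_gap: float = 0.5

    # cerebellum semi-axes at 20 weeks and linear growth per week
    cb_axes_20wk: tuple[float, float, float] = (11.0, 8.5, 7.0)
    cb_growth_per_week: float = 0.055

    # control atrial diameters (no ventriculomegaly)
    control_atrial_range: tuple[float, float] = (5.0, 9.0)

    def validate(self) -> None:
        if self.n_osb < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for sched in (self.ga_osb, self.ga_control):
            if any(s < 0 for s in sched.sds):
                raise ValueError("GA SDs must be non-negative")


# ---------------------------------------------------------------------------
# Folding field
# ---------------------------------------------------------------------------

def sample_fold_phases(rng: np.random.Generator) -> np.ndarray:
    """Per-subject random phases (ψ, χ) for each folding term."""
    return rng.uniform(0, 2 * np.pi, size=(len(_FOLD_TERMS), 2))


def _fold_raw(theta: np.ndarray, phi: np.ndarray, phases: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast(theta, phi).shape)
    for (l, m, w), (psi, chi) in zip(_FOLD_TERMS, phases):
        out += w * np.sin(l * theta + psi) * np.cos(m * phi + chi)
    return out * np.sin(theta)


def _fold_norm(phases: np.ndarray) -> float:
    th = np.linspace(0, np.pi, 181)
    ph = np.linspace(0, 2 * np.pi, 361)
    T, P = np.meshgrid(th, ph, indexing="ij")
    return float(np.abs(_fold_raw(T, P, phases)).max())


def folding_field(theta, phi, phases: np.ndarray) -> np.ndarray:
    """Band-limited folding field normalised to max |f| = 1."""
    return _fold_raw(np.asarray(theta), np.asarray(phi), phases) / _fold_norm(phases)


def _ellipsoid_base(theta, phi, ratios) -> np.ndarray:
    ax, ay, az = ratios
    st = np.sin(theta)
    inv = np.sqrt(
        (st * np.cos(phi) / ax) ** 2
        + (st * np.sin(phi) / ay) ** 2
        + (np.cos(theta) / az) ** 2
    )
    return 1.0 / np.maximum(inv, 1e-12)


def radial_function(theta, phi, radius, amplitude, phases, ratios) -> np.ndarray:
    """ρ(θ, φ) of the white-matter surface in mm."""
    base = _ellipsoid_base(theta, phi, ratios)
    if amplitude == 0:
        return radius * base
    return radius * base * (1.0 + amplitude * folding_field(theta, phi, phases))


# ---------------------------------------------------------------------------
# Parameterised surface generation
# ---------------------------------------------------------------------------

def _uv_sphere_grid(n_theta: int, n_phi: int):
    """Unit-sphere UV triangulation: pole vertices plus (n_theta-1) x n_phi grid."""
    thetas = np.pi * np.arange(1, n_theta) / n_theta
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    T, P = np.meshgrid(thetas, phis, indexing="ij")
    theta = np.concatenate([[0.0], T.ravel(), [np.pi]])
    phi = np.concatenate([[0.0], P.ravel(), [0.0]])

    def vid(i, j):
        return 1 + i * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):  # north pole fan
        faces.append((0, vid(0, j), vid(0, j + 1)))
    for i in range(n_theta - 2):
        for j in range(n_phi):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    south = 1 + (n_theta - 1) * n_phi
    for j in range(n_phi):  # south pole fan
        faces.append((south, vid(n_theta - 2, j + 1), vid(n_theta - 2, j)))
    return theta, phi, np.asarray(faces, dtype=np.int64)


def _lobe_labels(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Exact angular-sector parcellation: hemisphere by x sign, lobe by the
    sagittal-plane angle (anterior = frontal, superior = parietal,
    posterior = occipital, inferior = temporal)."""
    st = np.sin(theta)
    x = st * np.cos(phi)
    y = st * np.sin(phi)
    z = np.cos(theta)
    ang = np.degrees(np.arctan2(z, y)) % 360.0
    lobe = np.empty(len(theta), dtype=np.int64)
    lobe[(ang >= 315) | (ang < 45)] = 0   # frontal  (anterior, +y)
    lobe[(ang >= 45) & (ang < 135)] = 1   # parietal (superior, +z)
    lobe[(ang >= 135) & (ang < 225)] = 3  # occipital (posterior, -y)
    lobe[(ang >= 225) & (ang < 315)] = 2  # temporal (inferior, -z)
    hemi = (x >= 0).astype(np.int64)  # 1 = right (+x), 0 = left
    order = {0: 0, 1: 2, 2: 4, 3: 6}
    return np.array([order[l] for l in lobe]) + hemi


def generate_surface(
    ga: float,
    radius: float,
    amplitude: float,
    phases: np.ndarray,
    n_theta: int = 40,
    n_phi: int = 80,
    ratios: tuple[float, float, float] = (1.0, 1.15, 0.9),
) -> SurfaceMesh:
    """Gyrified radial surface on a fixed parameter grid.

    Vertices at different GAs of the same subject (same grid, same phases)
    correspond by index; ``vertex_tags`` records that identity and
    ``lobe_labels`` the exact sector parcellation.
    """
    if not (GA_MIN <= ga <= GA_MAX):
        raise ValueError(f"gestational age {ga} outside [{GA_MIN}, {GA_MAX}] weeks")
    if amplitude < 0:
        raise ValueError("folding amplitude must be non-negative")
    if amplitude >= 1.0:  # max |f| = 1 after normalisation
        raise ValueError("amplitude * max|f| >= 1 would self-intersect")
    theta, phi, faces = _uv_sphere_grid(n_theta, n_phi)
    rho = radial_function(theta, phi, radius, amplitude, phases, ratios)
    st = np.sin(theta)
    verts = np.column_stack(
        [rho * st * np.cos(phi), rho * st * np.sin(phi), rho * np.cos(theta)]
    )
    mesh = SurfaceMesh(
        vertices=verts,
        faces=faces,
        structure_label=LABEL_WHITE_MATTER,
        vertex_tags=np.arange(len(verts)),
        lobe_labels=_lobe_labels(theta, phi),
    )
    if mesh.enclosed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


# ---------------------------------------------------------------------------
# Quadrature ground truth for radial surfaces
# ---------------------------------------------------------------------------

def radial_volume(radius, amplitude, phases, ratios, n: int = 256) -> float:
    """V = ∫∫ ρ³/3 · sinθ dθ dφ on a fine midpoint grid."""
    th = (np.arange(n) + 0.5) * np.pi / n
    ph = (np.arange(2 * n) + 0.5) * np.pi / n
    T, P = np.meshgrid(th, ph, indexing="ij")
    rho = radial_function(T, P, radius, amplitude, phases, ratios)
    dtdp = (np.pi / n) * (np.pi / n)
    return float((rho**3 / 3.0 * np.sin(T)).sum() * dtdp)


def radial_area(radius, amplitude, phases, ratios, n: int = 256) -> float:
    """A = ∫∫ ρ sqrt(ρ² sin²θ + ρ_θ² sin²θ + ρ_φ²) dθ dφ (spectral grid,
    partials by central differences on the fine grid)."""
    th = (np.arange(n) + 0.5) * np.pi / n
    ph = (np.arange(2 * n) + 0.5) * np.pi / n
    T, P = np.meshgrid(th, ph, indexing="ij")
    rho = radial_function(T, P, radius, amplitude, phases, ratios)
    dt = np.pi / n
    rho_t = np.gradient(rho, dt, axis=0)
    rho_p = np.gradient(rho, dt, axis=1)
    # periodic wrap in φ
    rho_p[:, 0] = (rho[:, 1] - rho[:, -1]) / (2 * dt)
    rho_p[:, -1] = (rho[:, 0] - rho[:, -2]) / (2 * dt)
    st = np.sin(T)
    integrand = rho * np.sqrt(rho**2 * st**2 + rho_t**2 * st**2 + rho_p**2)
    return float(integrand.sum() * dt * dt)


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    """Everything the generator knows about one subject, regenerable from
    (config, seed, subject index)."""

    subject_id: str
    group: str
    ga: np.ndarray                 # (3,) decimal weeks
    covariates: dict
    vent_rate: float               # programmed global ventricular rate mm³/week
    vent_volumes: np.ndarray       # (3,) total ventricular volume, analytic
    wm_radius: np.ndarray          # (3,) effective R per timepoint
    amplitudes: np.ndarray         # (3,) folding amplitude per timepoint
    phases: np.ndarray
    wm_volume_true: np.ndarray     # (3,) quadrature volume of the WM surface
    wm_area_true: np.ndarray       # (3,) quadrature area of the WM surface
    cb_volumes: np.ndarray         # (3,) analytic cerebellar volume
    meshes: list = field(default_factory=list)  # WM truth surfaces (shared grid)

    @property
    def wm_label_volumes(self) -> np.ndarray:
        """True volume of the white-matter *label* (ventricles carved out)."""
        return self.wm_volume_true - self.vent_volumes


def _vent_geometry(total_volume: float, ratios, gap: float):
    """Semi-axes and mirrored centres of the two lateral-ventricle ellipsoids."""
    per = total_volume / 2.0
    rx, ry, rz = ratios
    ax = (per / (4.0 / 3.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    semis = np.array([ax * rx, ax * ry, ax * rz])
    cx = semis[0] + gap
    centers = np.array([[cx, 0.0, 0.0], [-cx, 0.0, 0.0]])
    return semis, centers


def _vent_reach(semis: np.ndarray, centers: np.ndarray) -> float:
    """Largest distance from the origin to either ellipsoid surface."""
    th = np.linspace(0, np.pi, 31)
    ph = np.linspace(0, 2 * np.pi, 61)
    T, P = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack(
        [
            semis[0] * np.sin(T) * np.cos(P),
            semis[1] * np.sin(T) * np.sin(P),
            semis[2] * np.cos(T),
        ],
        axis=-1,
    ).reshape(-1, 3)
    d = 0.0
    for c in centers:
        d = max(d, float(np.linalg.norm(pts + c, axis=1).max()))
    return d


def _sample_ga(schedule: GASchedule, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        ga = np.array([rng.normal(m, s) for m, s in zip(schedule.means, schedule.sds)])
        ga = np.clip(ga, GA_MIN + 0.1, GA_MAX - 0.1)
        if ga[0] + 0.5 < ga[1] and ga[1] + 0.5 < ga[2]:
            return ga
    raise RuntimeError("could not sample strictly increasing gestational ages")


def _sample_covariates(group: str, cfg: CohortConfig, rng: np.random.Generator) -> dict:
    if group == "control":
        return {
            "lesion_type": "",
            "persistent_hh": False,
            "cc_status": "normal",
            "heterotopia": False,
            "atrial_diameter_mm": float(rng.uniform(*cfg.control_atrial_range)),
        }
    u = rng.random()
    f_mild, f_mod, f_sev = cfg.vm_fractions
    if u < f_mild:
        atrial = rng.uniform(10.0, 12.4)
    elif u < f_mild + f_mod:
        atrial = rng.uniform(12.6, 15.4)
    else:
        atrial = rng.uniform(15.6, 19.0)
    u_cc = rng.random()
    if u_cc < cfg.frac_pacc:
        cc = "pACC"
    elif u_cc < cfg.frac_pacc + cfg.frac_cc_abnormal:
        cc = "abnormal"
    else:
        cc = "normal"
    return {
        "lesion_type": (
            "myeloschisis" if rng.random() < cfg.frac_myeloschisis
            else "myelomeningocele"
        ),
        "persistent_hh": bool(rng.random() < cfg.frac_persistent_hh),
        "cc_status": cc,
        "heterotopia": bool(rng.random() < cfg.frac_heterotopia),
        "atrial_diameter_mm": float(atrial),
    }


def _rate_multiplier(cov: dict, cfg: CohortConfig) -> float:
    m = 1.0
    if cov["cc_status"] == "pACC":
        m *= cfg.pacc_rate_multiplier
    if cov["persistent_hh"]:
        m *= cfg.hh_rate_multiplier
    return m


def _mean_log_multiplier(cfg: CohortConfig) -> float:
    """Cohort-expected mean log rate-multiplier; dividing it out keeps the
    realised surgery-group median rate at the configured anchor."""
    return cfg.frac_pacc * np.log(cfg.pacc_rate_multiplier) + (
        cfg.frac_persistent_hh * np.log(cfg.hh_rate_multiplier)
    )


def sample_subject_rates(
    group: str, cov: dict, cfg: CohortConfig, rng: np.random.Generator
) -> float:
    """Programmed global ventricular growth rate (mm³/week) for one subject."""
    model = cfg.vent_rate_osb if group == "osb" else cfg.vent_rate_control
    if group == "osb":
        mult = _rate_multiplier(cov, cfg) / np.exp(_mean_log_multiplier(cfg))
    else:
        mult = 1.0
    # clip the log-normal draw at +/- 2.5 sd: medians and IQRs are untouched
    # and pathological tail geometries (ventricles larger than any plausible
    # cranium) are avoided
    z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
    return float(model.median * mult * np.exp(model.sigma * z))


def generate_subject(
    group: str,
    cfg: CohortConfig,
    subject_index: int,
    seed_seq: np.random.SeedSequence,
    render: bool = True,
    max_attempts: int = 5,
) -> tuple[list[LabelVolume] | None, SubjectTruth]:
    """Three timepoint label volumes plus ground truth for one subject."""
    rng = np.random.default_rng(seed_seq)
    sched = cfg.ga_osb if group == "osb" else cfg.ga_control
    folding = cfg.folding_osb if group == "osb" else cfg.folding_control

    ga = _sample_ga(sched, rng)
    cov = _sample_covariates(group, cfg, rng)
    rate = sample_subject_rates(group, cov, cfg, rng)

    # baseline ventricular volume from the atrial-diameter surrogate
    rx, ry, rz = cfg.vent_axis_ratios
    ax0 = cov["atrial_diameter_mm"] / 2.0
    v1 = 2.0 * (4.0 / 3.0) * np.pi * (ax0 * rx) * (ax0 * ry) * (ax0 * rz)
    vent_volumes = v1 + rate * (ga - ga[0])

    last_err = None
    for attempt in range(max_attempts):
        phases = sample_fold_phases(rng)
        try:
            vols, truth = _build_subject(
                group, cfg, subject_index, ga, cov, rate, vent_volumes,
                folding, phases, render,
            )
            return vols, truth
        except RuntimeError as err:  # overlap after placement: re-jitter
            last_err = err
    raise RuntimeError(
        f"subject {subject_index}: structure placement failed after "
        f"{max_attempts} attempts: {last_err}"
    )


def _build_subject(
    group, cfg, subject_index, ga, cov, rate, vent_volumes, folding, phases, render
):
    sid = f"{group}_{subject_index:03d}"
    n_t = 3
    wm_radius = np.empty(n_t)
    amplitudes = np.empty(n_t)
    wm_vol = np.empty(n_t)
    wm_area = np.empty(n_t)
    cb_vol = np.empty(n_t)
    meshes = []
    volumes = [] if render else None
    e_min = min(cfg.ellipsoid_ratios)

    for t in range(n_t):
        a = folding.amplitude(ga[t])
        amplitudes[t] = a
        semis, centers = _vent_geometry(
            vent_volumes[t], cfg.vent_axis_ratios, cfg.vent_midline_gap
        )
        reach = _vent_reach(semis, centers)
        r_base = cfg.wm_radius_20wk + cfg.wm_radius_slope * (ga[t] - GA_MIN)
        # hydrocephalus-like mantle stretching: enlarge R so the ventricles
        # always nest inside the folded white-matter surface
        r_needed = (reach + 2.0) / (e_min * (1.0 - a))
        R = max(r_base, r_needed)
        wm_radius[t] = R

        mesh = generate_surface(
            ga[t], R, a, phases, cfg.n_theta, cfg.n_phi, cfg.ellipsoid_ratios
        )
        meshes.append(mesh)
        wm_vol[t] = radial_volume(R, a, phases, cfg.ellipsoid_ratios)
        wm_area[t] = radial_area(R, a, phases, cfg.ellipsoid_ratios)

        grow = 1.0 + cfg.cb_growth_per_week * (ga[t] - GA_MIN)
        cb_semis = np.array(cfg.cb_axes_20wk) * grow
        cb_vol[t] = (4.0 / 3.0) * np.pi * np.prod(cb_semis)

        if render:
            vol = _rasterize_timepoint(
                cfg, R, a, phases, semis, centers, cb_semis
            )
            volumes.append(vol)

    truth = SubjectTruth(
        subject_id=sid,
        group=group,
        ga=ga,
        covariates=cov,
        vent_rate=rate,
        vent_volumes=vent_volumes,
        wm_radius=wm_radius,
        amplitudes=amplitudes,
        phases=phases,
        wm_volume_true=wm_vol,
        wm_area_true=wm_area,
        cb_volumes=cb_vol,
        meshes=meshes,
    )
    return volumes, truth


def _rasterize_timepoint(cfg, R, amplitude, phases, vent_semis, vent_centers, cb_semis):
    """Analytic voxel-centre rasterisation of the three nested structures."""
    s = cfg.spacing
    ratios = cfg.ellipsoid_ratios
    r_max = R * max(ratios) * (1.0 + amplitude)
    cb_cz = -(R * ratios[2] * (1.0 + amplitude) + cb_semis[2] + 4.0)
    lo = np.array([
        -max(r_max, cb_semis[0]) - 2 * s,
        -max(r_max, cb_semis[1]) - 2 * s,
        cb_cz - cb_semis[2] - 2 * s,
    ])
    hi = np.array([max(r_max, cb_semis[0]), max(r_max, cb_semis[1]), r_max]) + 2 * s
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / s)) + 1 for i in range(3))

    axes = [lo[i] + s * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    rr = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.divide(Z, np.maximum(rr, 1e-12)), -1, 1))
    phi = np.arctan2(Y, X) + 0.0 * Z
    # evaluate the radial surface only where it could matter
    cand = rr <= r_max + s
    rho = np.full(rr.shape, -1.0)
    rho[cand] = radial_function(theta[cand], phi[cand], R, amplitude, phases, ratios)
    inside_wm = rr <= rho

    inside_vent = np.zeros(rr.shape, dtype=bool)
    for c in vent_centers:
        inside_vent |= (
            ((X - c[0]) / vent_semis[0]) ** 2
            + ((Y - c[1]) / vent_semis[1]) ** 2
            + ((Z - c[2]) / vent_semis[2]) ** 2
        ) <= 1.0

    inside_cb = (
        (X / cb_semis[0]) ** 2
        + (Y / cb_semis[1]) ** 2
        + ((Z - cb_cz) / cb_semis[2]) ** 2
    ) <= 1.0

    if np.any(inside_vent & ~inside_wm):
        raise RuntimeError("ventricles protrude from the white-matter surface")
    if np.any(inside_cb & inside_wm):
        raise RuntimeError("cerebellum overlaps the cerebrum")

    data = np.zeros(rr.shape, dtype=np.int16)
    data[inside_wm] = LABEL_WHITE_MATTER
    data[inside_vent] = LABEL_VENTRICLES
    data[inside_cb] = LABEL_CEREBELLUM
    return LabelVolume(data=data, spacing=s, origin=lo)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    manifest: pd.DataFrame
    truths: dict
    volumes: dict | None  # (subject_id, timepoint) -> LabelVolume, if rendered


def generate_cohort(
    cfg: CohortConfig,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> Cohort:
    """Generate the full cohort; optionally write NIfTI volumes + manifest.

    Fully deterministic given (config, seed): per-subject RNG streams are
    spawned from one SeedSequence.
    """
    cfg.validate()
    groups = ["osb"] * cfg.n_osb + ["control"] * cfg.n_control
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(groups))

    rows = []
    truths: dict[str, SubjectTruth] = {}
    volumes: dict | None = {} if render else None
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for idx, (group, seq) in enumerate(zip(groups, seqs)):
        vols, truth = generate_subject(group, cfg, idx, seq, render=render)
        truths[truth.subject_id] = truth
        row = {
            "subject_id": truth.subject_id,
            "group": truth.group,
            **{f"ga_t{t + 1}": truth.ga[t] for t in range(3)},
            **truth.covariates,
        }
        if render:
            for t in range(3):
                key = (truth.subject_id, t)
                volumes[key] = vols[t]
                if out_dir is not None:
                    p = out_dir / f"{truth.subject_id}_t{t + 1}.nii.gz"
                    write_label_volume(vols[t], p)
                    row[f"volume_t{t + 1}"] = str(p)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        _write_truth_json(truths, out_dir / "truth.json")
    return Cohort(config=cfg, manifest=manifest, truths=truths, volumes=volumes)


def _write_truth_json(truths: dict, path: Path) -> None:
    ser = {}
    for sid, t in truths.items():
        ser[sid] = {
            "group": t.group,
            "ga": t.ga.tolist(),
            "covariates": t.covariates,
            "vent_rate": t.vent_rate,
            "vent_volumes": t.vent_volumes.tolist(),
            "wm_radius": t.wm_radius.tolist(),
            "amplitudes": t.amplitudes.tolist(),
            "wm_volume_true": t.wm_volume_true.tolist(),
            "wm_area_true": t.wm_area_true.tolist(),
            "cb_volumes": t.cb_volumes.tolist(),
        }
    path.write_text(json.dumps(ser, indent=1))


def sample_cohort_rates(cfg: CohortConfig) -> pd.DataFrame:
    """Programmed per-subject ventricular rates without rendering geometry.

    Draws gestational ages, covariates and rates from exactly the same
    per-subject RNG streams as :func:`generate_cohort`, so the returned
    rates equal the rendered cohort's ground truth for the same config.
    Used for statistical power/size replicates where the geometry is not
    needed.
    """
    cfg.validate()
    groups = ["osb"] * cfg.n_osb + ["control"] * cfg.n_control
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(groups))
    rows = []
    for idx, (group, seq) in enumerate(zip(groups, seqs)):
        rng = np.random.default_rng(seq)
        sched = cfg.ga_osb if group == "osb" else cfg.ga_control
        ga = _sample_ga(sched, rng)
        cov = _sample_covariates(group, cfg, rng)
        rate = sample_subject_rates(group, cov, cfg, rng)
        rows.append({
            "subject_id": f"{group}_{idx:03d}", "group": group,
            "parameter": "ventricles_volume_mm3", "period": "global",
            "rate": rate, "ga_t1": ga[0], "ga_t3": ga[2],
            "atrial_diameter_mm": cov["atrial_diameter_mm"],
        })
    return pd.DataFrame(rows)


def zero_effect_config(cfg: CohortConfig | None = None) -> CohortConfig:
    """A copy of the config with identical growth models in both groups
    (null cohort for calibration checks)."""
    import dataclasses

    cfg = cfg or CohortConfig()
    return dataclasses.replace(
        cfg,
        vent_rate_osb=cfg.vent_rate_control,
        pacc_rate_multiplier=1.0,
        hh_rate_multiplier=1.0,
    )


def make_atlas_surface(
    ga: float,
    cfg: CohortConfig | None = None,
    n_theta: int | None = None,
    n_phi: int | None = None,
) -> SurfaceMesh:
    """Synthetic labelled reference surface for lobe parcellation.

    A mildly folded surface at the requested GA with fixed phases (its own
    seed, independent of any cohort) carrying the exact sector lobe labels.
    """
    cfg = cfg or CohortConfig()
    phases = sample_fold_phases(np.random.default_rng(12345))
    a = cfg.folding_control.amplitude(ga)
    R = cfg.wm_radius_20wk + cfg.wm_radius_slope * (ga - GA_MIN)
    return generate_surface(
        ga, R, a, phases,
        n_theta or cfg.n_theta, n_phi or cfg.n_phi, cfg.ellipsoid_ratios,
    )
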