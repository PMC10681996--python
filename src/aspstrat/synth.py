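"""Synthetic PET phantoms and simulated patient cohorts.

Digital phantoms place an analytic shape (sphere, ellipsoid, cuboid, or a
sphere perturbed by real spherical harmonics) on a voxel grid, assign a
plateau tumor uptake over a uniform background, and then apply a Gaussian
point-spread blur and additive Gaussian noise — the minimal forward model
needed to exercise delineation and shape metrics against a known ground
truth.

Cohort simulation draws per-patient asphericity (ASP), gene-signature risk
(EPPI) and stage, and generates exponential event times under a Cox
proportional-hazards model with configurable log-hazard coefficients, plus
negative-binomial RNA-seq counts whose signature-gene means are coupled to
the latent risk.  Every generator is a pure function of its config and
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.ndimage import gaussian_filter

from .volumes import PetVolume, TumorMask

__all__ = [
    "ShapeSpec",
    "GridSpec",
    "AcquisitionSpec",
    "CohortConfig",
    "make_phantom",
    "reference_geometry",
    "simulate_cohort",
]

_SUPPORTED_KINDS = ("sphere", "ellipsoid", "cuboid", "perturbed_sphere")


@dataclass
class ShapeSpec:
    """Analytic ground-truth geometry.

    ``size_params`` by kind (all lengths in mm):

    - ``sphere``: ``radius``
    - ``ellipsoid``: ``semi_axes`` (a, b, c)
    - ``cuboid``: ``edge_lengths`` (lx, ly, lz)
    - ``perturbed_sphere``: ``radius`` (base), ``perturb_degree`` l and
      ``perturb_amplitudes`` mapping order m in [-l, l] to an amplitude in
      mm; the radius function is r(theta, phi) = r0 + sum_m a_m Y_lm^real.
    """

    kind: str
    radius: float | None = None
    semi_axes: tuple[float, float, float] | None = None
    edge_lengths: tuple[float, float, float] | None = None
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    perturb_degree: int = 0
    perturb_amplitudes: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _SUPPORTED_KINDS:
            raise ValueError(f"unsupported shape kind {self.kind!r}; expected one of {_SUPPORTED_KINDS}")
        if self.kind in ("sphere", "perturbed_sphere"):
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere radius must be positive")
        if self.kind == "ellipsoid":
            if self.semi_axes is None or any(a <= 0 for a in self.semi_axes):
                raise ValueError("ellipsoid semi-axes must be positive")
        if self.kind == "cuboid":
            if self.edge_lengths is None or any(e <= 0 for e in self.edge_lengths):
                raise ValueError("cuboid edge lengths must be positive")
        if self.kind == "perturbed_sphere":
            total = sum(abs(a) for a in self.perturb_amplitudes.values())
            if total >= self.radius:
                raise ValueError(
                    "perturbation amplitude must stay below the base radius "
                    f"(sum |a_m| = {total} >= r0 = {self.radius})"
                )
            for m in self.perturb_amplitudes:
                if abs(m) > self.perturb_degree:
                    raise ValueError(f"order |m|={abs(m)} exceeds degree l={self.perturb_degree}")

    # ----- geometry helpers -------------------------------------------------

    def radial_extent(self) -> tuple[float, float, float]:
        """Half-extent of the shape along each axis (bounding box from center)."""
        if self.kind == "sphere":
            r = float(self.radius)
            return (r, r, r)
        if self.kind == "ellipsoid":
            return tuple(float(a) for a in self.semi_axes)
        if self.kind == "cuboid":
            return tuple(float(e) / 2 for e in self.edge_lengths)
        rmax = float(self.radius) + sum(abs(a) for a in self.perturb_amplitudes.values())
        return (rmax, rmax, rmax)

    def radius_function(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """r(theta, phi) for star-convex kinds (sphere, perturbed_sphere)."""
        if self.kind == "sphere":
            return np.full(np.broadcast(theta, phi).shape, float(self.radius))
        if self.kind != "perturbed_sphere":
            raise ValueError(f"{self.kind} has no radial parameterization")
        r = np.full(np.broadcast(theta, phi).shape, float(self.radius))
        for m, amp in self.perturb_amplitudes.items():
            r = r + amp * _real_sph_harm(self.perturb_degree, m, theta, phi)
        return r

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Occupancy test for points given in mm relative to the shape center."""
        if self.kind == "sphere":
            return x * x + y * y + z * z < self.radius**2
        if self.kind == "ellipsoid":
            a, b, c = self.semi_axes
            return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 < 1.0
        if self.kind == "cuboid":
            lx, ly, lz = self.edge_lengths
            return (np.abs(x) < lx / 2) & (np.abs(y) < ly / 2) & (np.abs(z) < lz / 2)
        rho = np.sqrt(x * x + y * y + z * z)
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(np.divide(z, rho, out=np.zeros_like(rho), where=rho > 0), -1, 1))
        phi = np.arctan2(y, x)
        return rho < self.radius_function(theta, phi)


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real (tesseral) spherical harmonic Y_lm; theta polar, phi azimuthal."""
    y = special.sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return math.sqrt(2.0) * (-1) ** m * np.real(y)
    if m < 0:
        return math.sqrt(2.0) * (-1) ** m * np.imag(y)
    return np.real(y)


@dataclass
class GridSpec:
    """Voxel grid: counts per axis and mm spacing per axis (anisotropy allowed)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_voxels: int = 3

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("grid shape must be three positive voxel counts")
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive in every axis")
        self.spacing = tuple(float(s) for s in self.spacing)

    def center_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) / 2 * s for n, s in zip(self.shape, self.spacing))


@dataclass
class AcquisitionSpec:
    """Uptake contrast, PSF blur and noise of the simulated acquisition."""

    tumor_suv: float = 10.0
    background_suv: float = 2.0
    psf_fwhm_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumor_suv > self.background_suv >= 0:
            raise ValueError("require tumor_suv > background_suv >= 0")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm_mm and noise_sd must be non-negative")


def make_phantom(shape: ShapeSpec, grid: GridSpec, acq: AcquisitionSpec) -> tuple[PetVolume, TumorMask]:
    """Digitize ``shape`` onto ``grid`` and simulate a PET acquisition.

    Voxels whose center lies inside the analytic shape carry ``tumor_suv``,
    the rest ``background_suv``; the PSF blur and then additive Gaussian
    noise are applied in that order.  The returned ground-truth mask is the
    pre-blur voxel-center occupancy.  Identical inputs and seed give
    bit-identical output.
    """
    center = shape.center if any(shape.center) else grid.center_mm()
    extent = shape.radial_extent()
    for ax, (c, e, n, s) in enumerate(zip(center, extent, grid.shape, grid.spacing)):
        margin = grid.margin_voxels * s
        if c - e < margin - s / 2 or c + e > (n - 1) * s - margin + s / 2:
            raise ValueError(
                f"shape exceeds grid bounds along axis {ax}: extent "
                f"[{c - e:.1f}, {c + e:.1f}] mm vs grid [0, {(n - 1) * s:.1f}] mm "
                f"with a {grid.margin_voxels}-voxel background margin"
            )

    coords = [np.arange(n) * s - c for n, s, c in zip(grid.shape, grid.spacing, center)]
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    occupancy = shape.contains(x, y, z)

    data = np.where(occupancy, acq.tumor_suv, acq.background_suv).astype(float)
    if acq.psf_fwhm_mm > 0:
        sigma_vox = [acq.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s for s in grid.spacing]
        data = gaussian_filter(data, sigma_vox)
    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.seed)
        data = data + rng.normal(0.0, acq.noise_sd, size=data.shape)

    vol = PetVolume(data, grid.spacing)
    mask = TumorMask(occupancy, grid.spacing, provenance="ground_truth")
    return vol, mask


# ---------------------------------------------------------------------------
# Reference (oracle) geometry
# ---------------------------------------------------------------------------


def reference_geometry(shape: ShapeSpec, rel_tol: float = 1e-4) -> tuple[float, float]:
    """Analytic volume (mm^3) and surface (mm^2) of a :class:`ShapeSpec`.

    Sphere and cuboid use closed forms.  Ellipsoid and perturbed sphere use
    numerical quadrature of the exact surface integral on a theta-phi grid,
    refined (doubling the resolution) until successive estimates differ by
    less than ``rel_tol`` relative (default 0.01 %).
    """
    if shape.kind == "sphere":
        r = float(shape.radius)
        return 4.0 / 3.0 * math.pi * r**3, 4.0 * math.pi * r**2
    if shape.kind == "cuboid":
        lx, ly, lz = shape.edge_lengths
        return lx * ly * lz, 2.0 * (lx * ly + ly * lz + lz * lx)
    if shape.kind == "ellipsoid":
        return _ellipsoid_geometry(shape.semi_axes, rel_tol)
    if shape.kind == "perturbed_sphere":
        return _radial_geometry(shape, rel_tol)
    raise ValueError(f"unsupported shape kind {shape.kind!r}")


def _quad_refine(estimate, rel_tol: float, n0: int = 64, max_n: int = 4096) -> float:
    prev = estimate(n0)
    n = n0 * 2
    while n <= max_n:
        cur = estimate(n)
        if abs(cur - prev) <= rel_tol * abs(cur):
            return cur
        prev, n = cur, n * 2
    return prev


def _ellipsoid_geometry(axes, rel_tol: float) -> tuple[float, float]:
    a, b, c = (float(v) for v in axes)
    volume = 4.0 / 3.0 * math.pi * a * b * c

    def surf(n: int) -> float:
        # exact parametric area element |r_theta x r_phi| on a midpoint grid
        th = (np.arange(n) + 0.5) * math.pi / n
        ph = (np.arange(2 * n) + 0.5) * 2.0 * math.pi / (2 * n)
        theta, phi = np.meshgrid(th, ph, indexing="ij")
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        el = np.sqrt(
            (b * c * st * st * cp) ** 2 + (a * c * st * st * sp) ** 2 + (a * b * st * ct) ** 2
        )
        return float(el.sum() * (math.pi / n) * (2.0 * math.pi / (2 * n)))

    return volume, _quad_refine(surf, rel_tol)


def _radial_geometry(shape: ShapeSpec, rel_tol: float) -> tuple[float, float]:
    """Quadrature for star-convex shapes given by r(theta, phi).

    Surface element: dS = sqrt((r^2 + r_theta^2) sin^2 theta + r_phi^2) * r
    dtheta dphi; volume: dV = r^3/3 sin theta dtheta dphi.  Angular partial
    derivatives are taken spectrally cheap via central differences on the
    midpoint grid (periodic in phi), which converges with the grid
    refinement loop.
    """

    def vol(n: int) -> float:
        theta, phi, r, _, _ = _radial_grid(shape, n)
        return float((r**3 / 3.0 * np.sin(theta)).sum() * (math.pi / n) * (2 * math.pi / (2 * n)))

    def surf(n: int) -> float:
        theta, phi, r, r_th, r_ph = _radial_grid(shape, n)
        st = np.sin(theta)
        el = r * np.sqrt((r * r + r_th * r_th) * st * st + r_ph * r_ph)
        return float(el.sum() * (math.pi / n) * (2 * math.pi / (2 * n)))

    return _quad_refine(vol, rel_tol), _quad_refine(surf, rel_tol)


def _radial_grid(shape: ShapeSpec, n: int):
    th = (np.arange(n) + 0.5) * math.pi / n
    ph = (np.arange(2 * n) + 0.5) * 2.0 * math.pi / (2 * n)
    theta, phi = np.meshgrid(th, ph, indexing="ij")
    r = shape.radius_function(theta, phi)
    dth = math.pi / n
    dph = 2.0 * math.pi / (2 * n)
    r_th = np.gradient(r, dth, axis=0)
    r_ph = (np.roll(r, -1, axis=1) - np.roll(r, 1, axis=1)) / (2.0 * dph)
    return theta, phi, r, r_th, r_ph


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Simulation settings for a synthetic surgical NSCLC-like cohort.

    Log-hazard coefficients: ``beta_asp`` per ASP percentage point (the
    emulated metric effect corresponds to HR 1.02 per point), ``beta_eppi``
    per EPPI-score unit, ``beta_stage`` for advanced (stage > II) disease.
    Event times are exponential with rate ``baseline_hazard * exp(eta)``;
    censoring is the minimum of the administrative horizon and an
    independent uniform dropout on (0, dropout_scale].
    """

    n_patients: int = 200
    beta_asp: float = math.log(1.02)
    beta_eppi: float = math.log(1.10)
    beta_stage: float = math.log(2.0)
    baseline_hazard: float = 0.01  # events / month at eta = 0
    censor_time: float = 60.0  # months
    dropout_scale: float = 120.0  # months; uniform(0, scale] dropout
    asp_mean: float = 20.0  # percent; gamma-distributed marker
    asp_shape: float = 4.0
    eppi_mean: float = 10.0
    eppi_sd: float = 5.0
    p_advanced_stage: float = 0.3
    p_stage2_within_early: float = 0.4
    p_scc: float = 0.45
    p_male: float = 0.65
    frac_locoregional: float = 0.35  # first-event type split among recurrences
    frac_distant: float = 0.45  # remainder is death as first event
    n_background_genes: int = 200
    expr_mean_log2: float = 6.0
    expr_mean_log2_sd: float = 1.5
    nb_dispersion: float = 0.2
    risk_coupling_log2: float = 0.5  # log2 fold change per SD of latent risk
    simulate_expression: bool = True
    cohort_labels: tuple[str, ...] = ("radiogenomics", "tcga")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if not 0 <= self.frac_locoregional + self.frac_distant <= 1:
            raise ValueError("first-event type fractions must sum to <= 1")


def simulate_cohort(cfg: CohortConfig, eppi_model=None):
    """Simulate a cohort table and (optionally) an expression count matrix.

    Returns ``(cohort, counts)`` where ``cohort`` is a patient-level
    DataFrame with covariates, ASP, the latent EPPI score, event-history
    columns (months to loco-regional recurrence, distant recurrence, death,
    and last follow-up) — from which the PFS/OS/LRC/FFDM endpoints are
    derived downstream — and ``counts`` is a genes x samples DataFrame of
    negative-binomial counts (``None`` when ``simulate_expression`` is
    off).  Signature-gene means scale with the patient's latent risk so the
    planted signature-outcome association is recoverable.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    asp = rng.gamma(cfg.asp_shape, cfg.asp_mean / cfg.asp_shape, size=n)
    eppi = rng.normal(cfg.eppi_mean, cfg.eppi_sd, size=n)
    advanced = rng.random(n) < cfg.p_advanced_stage
    stage2 = (~advanced) & (rng.random(n) < cfg.p_stage2_within_early)
    uicc = np.where(advanced, "III", np.where(stage2, "II", "I"))

    with np.errstate(over="ignore", invalid="ignore"):
        eta = cfg.beta_asp * asp + cfg.beta_eppi * eppi + cfg.beta_stage * advanced.astype(float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor; check betas and marker distributions")
    rate = cfg.baseline_hazard * np.exp(eta)

    # cause-specific first events sharing the same linear predictor: the
    # all-cause (PFS) hazard is exactly baseline * exp(eta)
    f_lr, f_dm = cfg.frac_locoregional, cfg.frac_distant
    f_death = max(1.0 - f_lr - f_dm, 1e-12)
    t_lr = rng.exponential(1.0 / (rate * max(f_lr, 1e-12)))
    t_dm = rng.exponential(1.0 / (rate * max(f_dm, 1e-12)))
    t_death_first = rng.exponential(1.0 / (rate * f_death))
    # death following recurrence (so OS events exist beyond first-event deaths)
    t_death_post = rng.exponential(24.0, size=n)

    censor = np.minimum(cfg.censor_time, rng.uniform(0.0, cfg.dropout_scale, size=n))

    t_first_rec = np.minimum(t_lr, t_dm)
    t_death = np.minimum(t_death_first, t_first_rec + t_death_post)

    lr_time = np.where(t_lr <= censor, t_lr, np.nan)
    dm_time = np.where(t_dm <= censor, t_dm, np.nan)
    death_time = np.where(t_death <= censor, t_death, np.nan)
    # events after an observed death are unobserved
    lr_time = np.where(np.isnan(death_time) | (lr_time <= death_time), lr_time, np.nan)
    dm_time = np.where(np.isnan(death_time) | (dm_time <= death_time), dm_time, np.nan)

    last_fu = np.where(np.isnan(death_time), censor, death_time)

    cohort_label = np.array(cfg.cohort_labels)[rng.integers(0, len(cfg.cohort_labels), size=n)]
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "cohort": cohort_label,
            "sex": np.where(rng.random(n) < cfg.p_male, "male", "female"),
            "age": np.round(rng.normal(66.0, 9.0, size=n)).clip(35, 92),
            "uicc_stage": uicc,
            "histology": np.where(rng.random(n) < cfg.p_scc, "SCC", "AC"),
            "asp": asp,
            "eppi": eppi,
            "locoregional_months": lr_time,
            "distant_months": dm_time,
            "death_months": death_time,
            "last_followup_months": last_fu,
        }
    )

    counts = None
    if cfg.simulate_expression:
        counts = _simulate_expression(cfg, rng, eta, cohort["patient_id"].to_numpy(), eppi_model)
    return cohort, counts


def _simulate_expression(cfg: CohortConfig, rng, eta, sample_ids, eppi_model):
    from .expr import example_eppi_model  # local import to avoid a cycle

    model = eppi_model if eppi_model is not None else example_eppi_model()
    sig_genes = list(model.coefficients)
    coef_sign = np.sign([model.coefficients[g] for g in sig_genes])

    bg_genes = [f"G{i:04d}" for i in range(cfg.n_background_genes)]
    genes = sig_genes + bg_genes
    n_genes, n = len(genes), len(sample_ids)

    base_log2 = rng.normal(cfg.expr_mean_log2, cfg.expr_mean_log2_sd, size=n_genes)
    risk_z = (eta - eta.mean()) / (eta.std() if eta.std() > 0 else 1.0)
    coupling = np.zeros(n_genes)
    coupling[: len(sig_genes)] = cfg.risk_coupling_log2 * coef_sign

    mu = 2.0 ** (base_log2[:, None] + coupling[:, None] * risk_z[None, :])
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=list(sample_ids))
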