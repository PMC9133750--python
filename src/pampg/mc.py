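"""Reflectance-mode Monte Carlo photon transport in layered skin.

Standard weighted-packet random walk (the MCML scheme): exponential step
sampling with µt = µa + µs, absorption by weight attenuation, Henyey–
Greenstein scattering, Fresnel reflection/refraction at refractive-index
boundaries, and Russian roulette below weight 1e−4 with survival 0.1.
The geometry is 3-D; detected-photon visits are tallied on a 2-D (x, z)
grid projected along y.  A pencil beam enters at the origin; a disk
detector of given radius sits on the surface at a lateral offset d.  The
depth profile of the visit density in the column midway between source and
detector — where the co-aligned imaging beam axis sits — summarises how
deep the detected light sampled the tissue; its 90%-mass quantile is the
characteristic sampling depth used to choose the source–detector slit
separation.

Internal units are cm and 1/cm (the MCML convention); the public helpers
accept mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import InsufficientStatisticsError, InvalidConfigError

WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class SkinLayer:
    """One tissue layer; thickness and interaction coefficients in cm units."""

    thickness_cm: float
    mua_per_cm: float
    mus_per_cm: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise InvalidConfigError("layer thickness must be > 0 (may be np.inf)")
        if self.mua_per_cm < 0 or self.mus_per_cm < 0:
            raise InvalidConfigError("mua and mus must be >= 0")
        if not (-1.0 < self.g < 1.0):
            raise InvalidConfigError(f"anisotropy g must be in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise InvalidConfigError("refractive index must be >= 1")

    @classmethod
    def from_mm(cls, thickness_mm: float, mua_per_mm: float, mus_per_mm: float,
                g: float, n: float) -> "SkinLayer":
        return cls(thickness_mm / 10.0, mua_per_mm * 10.0, mus_per_mm * 10.0, g, n)


@dataclass(frozen=True)
class ProbeGeometry:
    """Source and detector layout on the skin surface (cm units)."""

    detector_offset_cm: float = 0.2
    detector_radius_cm: float = 0.05
    source_beam_radius_cm: float = 0.0   # 0 → pencil beam
    acceptance_deg: float = 90.0
    wavelength_nm: float = 532.0          # metadata only

    def __post_init__(self) -> None:
        # the offset is a signed position along the scan axis; the slit
        # distance is its magnitude
        if self.detector_radius_cm <= 0:
            raise InvalidConfigError("detector radius must be > 0")
        if not (0 < self.acceptance_deg <= 90):
            raise InvalidConfigError("acceptance angle must be in (0, 90] degrees")

    @classmethod
    def from_mm(cls, detector_offset_mm: float = 2.0,
                detector_radius_mm: float = 0.5, **kw) -> "ProbeGeometry":
        return cls(detector_offset_cm=detector_offset_mm / 10.0,
                   detector_radius_cm=detector_radius_mm / 10.0, **kw)


@dataclass(frozen=True)
class TallyGrid:
    """2-D (x, z) tally grid for detected-photon visits (cm units)."""

    x_min_cm: float = -0.1
    x_max_cm: float = 0.4
    z_min_cm: float = 0.0
    z_max_cm: float = 0.3
    nx: int = 100
    nz: int = 60

    @property
    def dx_cm(self) -> float:
        return (self.x_max_cm - self.x_min_cm) / self.nx

    @property
    def dz_cm(self) -> float:
        return (self.z_max_cm - self.z_min_cm) / self.nz

    @property
    def x_centers_cm(self) -> np.ndarray:
        return self.x_min_cm + (np.arange(self.nx) + 0.5) * self.dx_cm

    @property
    def z_centers_cm(self) -> np.ndarray:
        return self.z_min_cm + (np.arange(self.nz) + 0.5) * self.dz_cm


@dataclass(frozen=True)
class MCResult:
    """Tallies of one Monte Carlo run.

    The four fractions (specular + diffuse reflectance + absorbed +
    transmitted) sum to 1 up to Monte Carlo error; ``visit_density`` is the
    (z, x) weight tally of scattering-site visits by *detected* photons.
    """

    n_photons: int
    seed: int
    detected_weight: float
    specular_fraction: float
    diffuse_reflectance: float
    absorbed_fraction: float
    transmitted_fraction: float
    n_detected: int
    visit_density: np.ndarray
    grid: TallyGrid
    geometry: ProbeGeometry


@njit(cache=True)
def _fresnel(n1, n2, cos_i):
    """(reflectance, cos_t) for unpolarized light; cos_i >= 0."""
    if n1 == n2:
        return 0.0, cos_i
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True)
def _spin(ux, uy, uz, g):
    """Henyey–Greenstein scatter of direction (ux, uy, uz)."""
    if g != 0.0:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    else:
        cos_t = 2.0 * np.random.random() - 1.0
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    phi = 2.0 * np.pi * np.random.random()
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    if abs(uz) > 0.99999:
        nux = sin_t * cos_p
        nuy = sin_t * sin_p
        nuz = cos_t * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nux = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        nuy = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nuz = -sin_t * cos_p * den + uz * cos_t
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _run_photons(n_photons, seed,
                 z_top, z_bot, mua, mus, g_arr, n_arr, n_ambient,
                 src_radius, det_x, det_r, cos_accept,
                 x_min, dx, nx, z_min, dz, nz):
    np.random.seed(seed)
    n_layers = len(mua)
    visit = np.zeros((nz, nx))
    spec_tot = 0.0
    refl_tot = 0.0
    abs_tot = 0.0
    trans_tot = 0.0
    det_w = 0.0
    n_det = 0

    max_visits = 20000
    vis_ix = np.empty(max_visits, np.int64)
    vis_iz = np.empty(max_visits, np.int64)
    vis_w = np.empty(max_visits)

    for _ in range(n_photons):
        # launch
        if src_radius > 0.0:
            r = src_radius * np.sqrt(np.random.random())
            th = 2.0 * np.pi * np.random.random()
            x = r * np.cos(th)
            y = r * np.sin(th)
        else:
            x = 0.0
            y = 0.0
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        layer = 0
        # specular reflection at the entry interface
        rsp, _ = _fresnel(n_ambient, n_arr[0], 1.0)
        spec_tot += rsp
        w = 1.0 - rsp
        nvis = 0
        alive = True

        while alive:
            mut = mua[layer] + mus[layer]
            if mut <= 0.0:
                s = 1e9
            else:
                s = -np.log(np.random.random() + 1e-300) / mut

            while True:
                # distance to layer boundary along uz
                if uz > 0.0:
                    db = (z_bot[layer] - z) / uz
                elif uz < 0.0:
                    db = (z_top[layer] - z) / uz
                else:
                    db = 1e9
                if db > s:
                    # interaction inside the layer
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    break
                # move to boundary
                x += ux * db
                y += uy * db
                z += uz * db
                s -= db
                going_down = uz > 0.0
                if going_down:
                    n_next = n_arr[layer + 1] if layer + 1 < n_layers else n_ambient
                else:
                    n_next = n_arr[layer - 1] if layer > 0 else n_ambient
                cos_i = abs(uz)
                R, cos_t = _fresnel(n_arr[layer], n_next, cos_i)
                if np.random.random() < R:
                    uz = -uz  # reflect
                else:
                    # refract
                    ratio = n_arr[layer] / n_next
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= nrm
                    uy /= nrm
                    uz /= nrm
                    if going_down:
                        if layer + 1 >= n_layers:
                            trans_tot += w
                            alive = False
                            break
                        layer += 1
                    else:
                        if layer == 0:
                            # exits the top surface
                            refl_tot += w
                            if ((x - det_x) * (x - det_x) + y * y
                                    <= det_r * det_r and abs(uz) >= cos_accept):
                                det_w += w
                                n_det += 1
                                for iv in range(nvis):
                                    visit[vis_iz[iv], vis_ix[iv]] += vis_w[iv]
                            alive = False
                            break
                        layer -= 1
                # rescale remaining step for the new layer's µt
                mut_new = mua[layer] + mus[layer]
                if mut_new <= 0.0:
                    s = 1e9
                elif mut > 0.0:
                    s = s * mut / mut_new
                mut = mut_new
                if mut <= 0.0 and s >= 1e9:
                    # non-interacting layer: keep propagating to next boundary
                    continue

            if not alive:
                continue

            if mut <= 0.0:
                continue

            # absorb
            dw = w * mua[layer] / mut
            abs_tot += dw
            w -= dw

            # record visit for potential detection
            if nvis < max_visits:
                ix = int((x - x_min) / dx)
                iz = int((z - z_min) / dz)
                if 0 <= ix < nx and 0 <= iz < nz:
                    vis_ix[nvis] = ix
                    vis_iz[nvis] = iz
                    vis_w[nvis] = w
                    nvis += 1

            # scatter
            ux, uy, uz = _spin(ux, uy, uz, g_arr[layer])

            # roulette
            if w < WEIGHT_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL  # survivors compensate the killed weight
                else:
                    alive = False

    return (spec_tot, refl_tot, abs_tot, trans_tot, det_w, n_det, visit)


def launch_photons(layers: list[SkinLayer], geometry: ProbeGeometry,
                   n_photons: int, seed: int = 0,
                   grid: TallyGrid | None = None,
                   n_ambient: float = 1.0) -> MCResult:
    """Run the weighted random walk and tally detected-photon visits."""
    if n_photons < 1:
        raise InvalidConfigError("n_photons must be >= 1")
    if not layers:
        raise InvalidConfigError("at least one layer required")
    if grid is None:
        # cover the probe span plus margin
        span = max(0.4, geometry.detector_offset_cm * 2)
        grid = TallyGrid(x_min_cm=-0.1, x_max_cm=span, nx=int(span * 250) + 25)

    th = np.array([l.thickness_cm for l in layers])
    z_bounds = np.concatenate(([0.0], np.cumsum(th)))
    z_top, z_bot = z_bounds[:-1], z_bounds[1:]
    mua = np.array([l.mua_per_cm for l in layers])
    mus = np.array([l.mus_per_cm for l in layers])
    g_arr = np.array([l.g for l in layers])
    n_arr = np.array([l.n for l in layers])

    cos_accept = np.cos(np.deg2rad(geometry.acceptance_deg))

    spec, refl, absd, trans, det_w, n_det, visit = _run_photons(
        int(n_photons), int(seed) & 0x7FFFFFFF,
        z_top, z_bot, mua, mus, g_arr, n_arr, float(n_ambient),
        geometry.source_beam_radius_cm, geometry.detector_offset_cm,
        geometry.detector_radius_cm, cos_accept,
        grid.x_min_cm, grid.dx_cm, grid.nx, grid.z_min_cm, grid.dz_cm, grid.nz,
    )
    n = float(n_photons)
    return MCResult(
        n_photons=int(n_photons), seed=int(seed),
        detected_weight=det_w / n,
        specular_fraction=spec / n,
        diffuse_reflectance=refl / n,
        absorbed_fraction=absd / n,
        transmitted_fraction=trans / n,
        n_detected=int(n_det),
        visit_density=visit,
        grid=grid,
        geometry=geometry,
    )


@dataclass(frozen=True)
class DepthProfile:
    """Visit density vs depth in one lateral column, with its mass quantile."""

    depths_cm: np.ndarray
    density: np.ndarray
    lateral_position_cm: float
    characteristic_depth_cm: float
    quantile: float

    @property
    def characteristic_depth_mm(self) -> float:
        return self.characteristic_depth_cm * 10.0


def sensitivity_depth_profile(result: MCResult,
                              lateral_position_cm: float | None = None,
                              quantile: float = 0.5,
                              column_halfwidth: int = 1) -> DepthProfile:
    """Depth profile of the detected-photon visit density at one lateral position.

    Defaults to the midpoint between source and detector (the imaging-beam
    axis).  The characteristic sampling depth is the column's visit-weight
    mass quantile: with the default 0.5, half of the detected light's
    interactions in this column occur above this depth.  (Higher quantiles
    describe the deep tail of the sampling banana rather than where the
    bulk of the detected light travels.)
    """
    grid = result.grid
    if lateral_position_cm is None:
        lateral_position_cm = 0.5 * result.geometry.detector_offset_cm
    if not (grid.x_min_cm <= lateral_position_cm <= grid.x_max_cm):
        raise InvalidConfigError("lateral position outside the tally grid")
    ix = int((lateral_position_cm - grid.x_min_cm) / grid.dx_cm)
    ix = min(max(ix, 0), grid.nx - 1)
    lo = max(0, ix - column_halfwidth)
    hi = min(grid.nx, ix + column_halfwidth + 1)
    col = result.visit_density[:, lo:hi].sum(axis=1)
    total = col.sum()
    if total <= 0:
        raise InsufficientStatisticsError(
            f"no detected-photon visits in the column at x={lateral_position_cm} cm "
            f"({result.n_detected} detected photons)",
            n_detected=result.n_detected,
        )
    cum = np.cumsum(col) / total
    iz = int(np.searchsorted(cum, quantile))
    iz = min(iz, grid.nz - 1)
    # linear interpolation within the crossing bin
    z_edges = grid.z_min_cm + np.arange(grid.nz + 1) * grid.dz_cm
    c_prev = cum[iz - 1] if iz > 0 else 0.0
    frac = (quantile - c_prev) / max(cum[iz] - c_prev, 1e-300)
    depth = z_edges[iz] + frac * grid.dz_cm
    return DepthProfile(
        depths_cm=grid.z_centers_cm,
        density=col,
        lateral_position_cm=lateral_position_cm,
        characteristic_depth_cm=float(depth),
        quantile=quantile,
    )


@dataclass(frozen=True)
class SeparationChoice:
    """Result of the slit-separation design scan."""

    chosen_separation_mm: float
    target_depth_mm: float
    table: list  # rows: dict(separation_mm, depth_mm, detected_weight, ok)


def optimal_separation(layers: list[SkinLayer],
                       candidate_separations_mm: list[float],
                       target_depth_mm: float,
                       n_photons: int = 200_000,
                       seed: int = 0,
                       geometry_template: ProbeGeometry | None = None,
                       quantile: float = 0.5) -> SeparationChoice:
    """Scan candidate source–detector separations for the target sampling depth.

    Returns the candidate whose characteristic sampling depth at the probe
    midpoint is closest to the target, along with the full table.
    Candidates with no detected photons are flagged and excluded.
    """
    if len(candidate_separations_mm) < 2:
        raise InvalidConfigError("need at least 2 candidate separations")
    tmpl = geometry_template or ProbeGeometry()
    rows = []
    for i, sep in enumerate(candidate_separations_mm):
        geo = ProbeGeometry(
            detector_offset_cm=sep / 10.0,
            detector_radius_cm=tmpl.detector_radius_cm,
            source_beam_radius_cm=tmpl.source_beam_radius_cm,
            acceptance_deg=tmpl.acceptance_deg,
            wavelength_nm=tmpl.wavelength_nm,
        )
        res = launch_photons(layers, geo, n_photons, seed=seed + i)
        try:
            prof = sensitivity_depth_profile(res, quantile=quantile)
            rows.append(dict(separation_mm=float(sep),
                             depth_mm=prof.characteristic_depth_mm,
                             detected_weight=res.detected_weight, ok=True))
        except InsufficientStatisticsError:
            rows.append(dict(separation_mm=float(sep), depth_mm=np.nan,
                             detected_weight=res.detected_weight, ok=False))
    valid = [r for r in rows if r["ok"]]
    if not valid:
        raise InsufficientStatisticsError("no candidate produced detected photons")
    best = min(valid, key=lambda r: abs(r["depth_mm"] - target_depth_mm))
    return SeparationChoice(
        chosen_separation_mm=best["separation_mm"],
        target_depth_mm=float(target_depth_mm),
        table=rows,
    )


def seven_layer_skin() -> list[SkinLayer]:
    """Default seven-layer skin optical model for green (532 nm) light.

    Layer structure (stratum corneum, living epidermis, papillary dermis,
    upper blood-net dermis, reticular dermis, deep blood-net dermis,
    subcutaneous fat) with absorption/scattering coefficients assembled
    from published skin-optics compilations for the visible range.  These
    are literature-typical values, not measurements of this package's own;
    override via :class:`SkinLayer` lists or a model file for other skin
    types or wavelengths.
    """
    mm = SkinLayer.from_mm
    return [
        #      thickness  µa(/mm) µs(/mm)   g     n
        mm(0.02, 0.35, 30.0, 0.90, 1.50),   # stratum corneum
        mm(0.08, 0.60, 18.0, 0.85, 1.34),   # living epidermis
        mm(0.15, 0.25, 20.0, 0.90, 1.40),   # papillary dermis
        mm(0.10, 0.50, 20.0, 0.92, 1.39),   # upper blood-net dermis
        mm(1.50, 0.20, 20.0, 0.90, 1.40),   # reticular dermis
        mm(0.20, 0.50, 22.0, 0.92, 1.38),   # deep blood-net dermis
        mm(5.00, 0.10, 12.0, 0.80, 1.44),   # subcutaneous fat
    ]
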