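"""Condensed-step electron transport and single-interaction photon
transport through the spherical cell world.

This is a deliberately simplified condensed-history scheme aimed at
organelle-scale (micrometre) energy-deposit scoring, not at nanometre track
structure:

* Electrons lose energy continuously along straight condensed steps.  The
  collision stopping power is the relativistic Bethe formula for electrons
  (Moller closed shells, no density or shell corrections) evaluated from
  each material's electron density and mean excitation energy; below 10 keV
  it is extended by a power law matched continuously (value and log-slope)
  at 10 keV.  Step length is limited by a fraction of the remaining CSDA
  range, a maximum step, and the distance to the next region boundary, so
  every step lies in a single region and its energy is credited there.
* After each step the direction is deflected by a Gaussian polar angle of
  Highland width theta0 = 13.6 MeV/(beta*c*p) * sqrt(x/X0) *
  (1 + 0.038 ln(x/X0)) with uniform azimuth.
* The cell is embedded in an unbounded water-equivalent medium (think of a
  cell inside tissue or culture medium).  Electrons that leave the cell are
  tracked onward with coarser steps; everything they deposit outside counts
  as escaped energy, but a beta of a few hundred keV has a range of the
  order of a millimetre, so it scatters diffusely around the 12 um cell and
  can re-enter it -- this albedo contribution is of the order of 20% of the
  cell deposit and cannot be neglected for absolute eV/decay values.  An
  outside track ends when its remaining CSDA range is smaller than the
  straight-line distance back to the cell (return is then impossible), or
  at the energy cutoff.  With ``surrounding_medium=False`` tracks terminate
  at the cell boundary instead (vacuum outside).  In either case total
  deposits plus escaped energy equal the initial energy exactly.
* Electrons below the energy cutoff deposit their residual locally; a
  1 keV electron has a residual range of tens of nm, far below organelle
  sizes.
* Photons either escape outright or undergo at most one interaction: the
  free path is exponential with the water attenuation coefficient at the
  line energy, and an interaction inside the cell deposits E * mu_en/mu at
  the interaction point.  Over a 6 um cell the interaction probability is
  of order 1e-4, so this term is negligible but kept for completeness.

No delta-ray production, bremsstrahlung, Auger cascades or atomic
de-excitation are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from . import geometry as G
from .geometry import BOUNDARY_TOL, CellGeometry, Material
from .scoring import EnergyTally
from .source import (MODE_CONTINUOUS, MODE_DISCRETE, NuclideSpec,
                     sample_beta_energy, sample_decay_positions_discrete,
                     sample_unit_vectors)

BETHE_COEFFICIENT = 0.153536  # MeV cm^2/g, 2*pi*r_e^2*mc^2*N_A per mol e-
BETHE_E_MIN_KEV = 10.0  # below this the Bethe formula is replaced
CROSSING_NUDGE_NM = 1e-3  # push past a boundary to land in the next region

PHOTON_ESCAPE = "escape"
PHOTON_SINGLE = "single_interaction"


@dataclass(frozen=True)
class TransportConfig:
    step_fraction: float = 0.05  # of the remaining CSDA range
    energy_cutoff: float = 1.0  # keV; residual deposited locally
    multiple_scattering: bool = True
    photon_mode: str = PHOTON_SINGLE
    max_step: float = 1000.0  # nm
    surrounding_medium: bool = True  # track electrons beyond the cell
    outside_step_fraction: float = 0.2  # coarser steps outside the cell

    def __post_init__(self):
        if not 0.0 < self.step_fraction <= 1.0:
            raise ValueError("step_fraction must be in (0, 1]")
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be positive")
        if self.photon_mode not in (PHOTON_ESCAPE, PHOTON_SINGLE):
            raise ValueError(f"unknown photon mode {self.photon_mode!r}")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass(frozen=True)
class TrackDeposit:
    region_id: int
    energy: float  # eV


def bethe_mass_stopping(energy_kev, z_over_a: float, i_ev: float):
    """Electron collision mass stopping power (MeV cm^2/g), valid above
    about 10 keV (vectorised)."""
    e = np.asarray(energy_kev, dtype=float)
    mc2 = C.ELECTRON_MASS_KEV
    tau = e / mc2
    gamma2 = (1.0 + tau) ** 2
    beta2 = 1.0 - 1.0 / gamma2
    i_ratio = i_ev / (mc2 * 1e3)  # I in mc^2 units
    bracket = (np.log(tau * tau * (tau + 2.0) / 2.0) - 2.0 * np.log(i_ratio)
               + 1.0 - beta2
               + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / gamma2)
    return BETHE_COEFFICIENT / beta2 * z_over_a * bracket


class StoppingPowerModel:
    """Tabulated stopping power (eV/nm) and CSDA range (nm) for one
    material, with log-log interpolation and range inversion."""

    def __init__(self, material: Material, e_min: float = 0.1,
                 e_max: float = 2000.0, n_grid: int = 800):
        self.material = material
        za = material.z_over_a
        i_ev = material.mean_excitation_energy
        rho = material.density
        grid = np.geomspace(e_min, e_max, n_grid)
        s_mass = bethe_mass_stopping(np.maximum(grid, BETHE_E_MIN_KEV), za, i_ev)
        # low-energy extension: power law matched in value and log-slope
        s10 = float(bethe_mass_stopping(BETHE_E_MIN_KEV, za, i_ev))
        h = 1e-3
        slope = (math.log(bethe_mass_stopping(BETHE_E_MIN_KEV * (1 + h), za, i_ev))
                 - math.log(s10)) / math.log1p(h)
        low = grid < BETHE_E_MIN_KEV
        s_mass = np.where(low, s10 * (grid / BETHE_E_MIN_KEV) ** slope, s_mass)
        s_nm = s_mass * rho * 0.1  # MeV/cm -> eV/nm
        # CSDA range: R(E) = integral_{e_min}^{E} dE'/S(E'), in nm
        inv = 1000.0 / s_nm  # nm per keV
        r = np.concatenate([[0.0], np.cumsum(
            0.5 * (inv[1:] + inv[:-1]) * np.diff(grid))])
        # offset so R is strictly positive (residual range below e_min)
        r += grid[0] * inv[0]
        self._log_e = np.log(grid)
        self._log_s = np.log(s_nm)
        self._log_r = np.log(r)
        self._e_min, self._e_max = e_min, e_max

    def _check(self, e):
        if np.any(np.asarray(e) <= 0):
            raise ValueError("energy must be positive")

    def stopping(self, energy_kev):
        """S(E) in eV/nm."""
        self._check(energy_kev)
        loge = np.clip(np.log(energy_kev), self._log_e[0], self._log_e[-1])
        return np.exp(np.interp(loge, self._log_e, self._log_s))

    def range_nm(self, energy_kev):
        self._check(energy_kev)
        loge = np.clip(np.log(energy_kev), self._log_e[0], self._log_e[-1])
        return np.exp(np.interp(loge, self._log_e, self._log_r))

    def energy_from_range(self, range_nm: float) -> float:
        if range_nm <= math.exp(self._log_r[0]):
            return 0.0
        logr = min(math.log(range_nm), self._log_r[-1])
        return math.exp(np.interp(logr, self._log_r, self._log_e))

    def energy_after(self, energy_kev: float, path_nm: float) -> float:
        """Energy remaining after travelling ``path_nm`` (0 when the CSDA
        range is exhausted)."""
        return self.energy_from_range(float(self.range_nm(energy_kev)) - path_nm)


_MODEL_CACHE: dict = {}


def _model_for(material: Material) -> StoppingPowerModel:
    key = (round(material.z_over_a, 9), material.mean_excitation_energy,
           material.density)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = StoppingPowerModel(material)
    return _MODEL_CACHE[key]


def stopping_power(energy_kev, material: Material):
    """Electron collision stopping power in eV/nm for the material."""
    return _model_for(material).stopping(energy_kev)


def csda_range(energy_kev, material: Material, cutoff_kev: float = 1.0):
    """CSDA range in mm: integral of dE/S from ``cutoff_kev`` to E
    (0 when E <= cutoff)."""
    model = _model_for(material)
    e = np.asarray(energy_kev, dtype=float)
    r = np.where(e > cutoff_kev,
                 model.range_nm(np.maximum(e, cutoff_kev))
                 - model.range_nm(cutoff_kev), 0.0) * 1e-6
    return float(r) if np.isscalar(energy_kev) else r


# ---------------------------------------------------------------------------
# photon attenuation
# ---------------------------------------------------------------------------

_MU_LOG_E = np.log(C.PHOTON_MU_TABLE_KEV)


def photon_mu_per_nm(energy_kev: float) -> tuple[float, float]:
    """(mu, mu_en/mu) for water at the given energy; mu in 1/nm,
    log-interpolated from the embedded three-point table."""
    if not C.PHOTON_E_MIN_KEV <= energy_kev <= C.PHOTON_E_MAX_KEV:
        raise ValueError(
            f"photon energy {energy_kev} keV outside supported "
            f"[{C.PHOTON_E_MIN_KEV}, {C.PHOTON_E_MAX_KEV}] keV")
    loge = np.clip(math.log(energy_kev), _MU_LOG_E[0], _MU_LOG_E[-1])
    mu_rho = math.exp(np.interp(loge, _MU_LOG_E, np.log(C.PHOTON_MU_OVER_RHO)))
    muen_rho = math.exp(np.interp(loge, _MU_LOG_E,
                                  np.log(C.PHOTON_MUEN_OVER_RHO)))
    mu_nm = mu_rho * C.TISSUE_DENSITY * 1e-7  # cm^2/g * g/cm^3 -> 1/cm -> 1/nm
    return mu_nm, muen_rho / mu_rho


# ---------------------------------------------------------------------------
# transport context: precomputed geometry arrays and material models
# ---------------------------------------------------------------------------

class _Accumulator:
    """Mutable per-batch deposit store (eV)."""

    def __init__(self, geom: CellGeometry):
        self.roles = {r: 0.0 for r in (G.ROLE_MEMBRANE, G.ROLE_CYTOSOL,
                                       G.ROLE_NUCLEUS, G.ROLE_MITOCHONDRION,
                                       G.ROLE_NANOPARTICLE)}
        self.mito = np.zeros(geom.n_mitochondria)
        self.np_ = np.zeros(geom.n_nanoparticles)
        self.escaped = 0.0
        self.track: list[tuple[str, int | None, float]] | None = None

    def deposit(self, role: str, idx, ev: float):
        self.roles[role] += ev
        if role == G.ROLE_MITOCHONDRION:
            self.mito[idx] += ev
        elif role == G.ROLE_NANOPARTICLE:
            self.np_[idx] += ev
        if self.track is not None:
            self.track.append((role, idx, ev))


class TransportContext:
    """Geometry and material data unpacked for the stepping loop."""

    def __init__(self, geom: CellGeometry):
        self.geom = geom
        self.outer = geom.cell_radius
        self.inner = geom.inner_radius
        self.nuc_r = geom.nucleus.radius
        self.mito_c = geom.mito_centers
        self.mito_r = geom.mito_radii
        self.np_c = geom.np_centers
        self.np_r = geom.np_radii
        self.np_r_max = float(self.np_r.max()) if geom.n_nanoparticles else 0.0
        self.tree = geom.np_tree
        self.models = {role: _model_for(mat)
                       for role, mat in geom.materials.items()}
        self.x0 = {role: (C.X0_GOLD if role == G.ROLE_NANOPARTICLE
                          else C.X0_WATER) for role in geom.materials}
        self.rho = {role: mat.density for role, mat in geom.materials.items()}

    # -- point classification (mirrors geometry.region_at, on cached arrays)
    def locate(self, p: np.ndarray) -> tuple[str, int | None]:
        r2 = float(p @ p)
        if r2 > (self.outer + BOUNDARY_TOL) ** 2:
            return G.ROLE_OUTSIDE, None
        if self.tree is not None:
            dist, idx = self.tree.query(p)
            if dist <= self.np_r[idx] + BOUNDARY_TOL:
                return G.ROLE_NANOPARTICLE, int(idx)
        if len(self.mito_r):
            d2 = ((self.mito_c - p) ** 2).sum(axis=1)
            k = int(np.argmin(d2))
            if d2[k] <= (self.mito_r[k] + BOUNDARY_TOL) ** 2:
                return G.ROLE_MITOCHONDRION, k
        if r2 <= (self.nuc_r + BOUNDARY_TOL) ** 2:
            return G.ROLE_NUCLEUS, None
        if r2 > (self.inner + BOUNDARY_TOL) ** 2:
            return G.ROLE_MEMBRANE, None
        return G.ROLE_CYTOSOL, None

    def boundary_distance(self, p: np.ndarray, d: np.ndarray,
                          s_max: float) -> float:
        """Distance along d from p to the nearest sphere surface of the
        world, capped at s_max."""
        best = s_max
        pp = float(p @ p)
        b0 = float(p @ d)
        # concentric shells and nucleus
        for radius in (self.outer, self.inner, self.nuc_r):
            cq = pp - radius * radius
            disc = b0 * b0 - cq
            if disc > 0:
                sq = math.sqrt(disc)
                for t in (-b0 - sq, -b0 + sq):
                    if BOUNDARY_TOL < t < best:
                        best = t
        # mitochondria (vectorised)
        if len(self.mito_r):
            oc = p - self.mito_c
            b = oc @ d
            cq = (oc * oc).sum(axis=1) - self.mito_r ** 2
            disc = b * b - cq
            hit = disc > 0
            if hit.any():
                sq = np.sqrt(disc[hit])
                bh = b[hit]
                for t in np.concatenate([-bh - sq, -bh + sq]):
                    if BOUNDARY_TOL < t < best:
                        best = float(t)
        # nanoparticles near the step segment (k-d tree candidates)
        if self.tree is not None:
            mid = p + d * (best * 0.5)
            idxs = self.tree.query_ball_point(mid,
                                              best * 0.5 + self.np_r_max + 1.0)
            for j in idxs:
                oc = p - self.np_c[j]
                b = float(oc @ d)
                cq = float(oc @ oc) - self.np_r[j] ** 2
                disc = b * b - cq
                if disc > 0:
                    sq = math.sqrt(disc)
                    for t in (-b - sq, -b + sq):
                        if BOUNDARY_TOL < t < best:
                            best = t
        return best

    def _outside_boundary(self, p: np.ndarray, d: np.ndarray,
                          s_max: float) -> float:
        """From outside the cell: distance to the outer cell surface along
        d, capped at s_max."""
        b = float(p @ d)
        cq = float(p @ p) - self.outer * self.outer
        disc = b * b - cq
        if disc > 0:
            sq = math.sqrt(disc)
            for t in (-b - sq, -b + sq):
                if BOUNDARY_TOL < t < s_max:
                    return t
        return s_max

    # -- electron stepping
    def run_electron(self, p: np.ndarray, d: np.ndarray, energy_kev: float,
                     cfg: TransportConfig, rng, acc: _Accumulator) -> None:
        role, idx = self.locate(p)
        e = energy_kev
        p = p.astype(float).copy()
        d = d.astype(float).copy()
        outside_model = self.models[G.ROLE_MEMBRANE]  # unit-density water
        while True:
            outside = role == G.ROLE_OUTSIDE
            if outside:
                if not cfg.surrounding_medium:
                    acc.escaped += e * 1e3
                    return
                model = outside_model
                range_rem = float(model.range_nm(e))
                # return to the cell is impossible once the remaining range
                # cannot bridge the gap back to the surface
                if float(np.linalg.norm(p)) - self.outer >= range_rem:
                    acc.escaped += e * 1e3
                    return
                ds_max = cfg.outside_step_fraction * range_rem
                t_b = self._outside_boundary(p, d, ds_max)
            else:
                model = self.models[role]
                ds_max = min(cfg.step_fraction * float(model.range_nm(e)),
                             cfg.max_step)
                t_b = self.boundary_distance(p, d, ds_max)
            crossing = t_b < ds_max
            ds = t_b if crossing else ds_max
            e_new = model.energy_after(e, ds)
            if e_new <= cfg.energy_cutoff:
                # residual deposited locally (counts as escaped if outside)
                if outside:
                    acc.escaped += e * 1e3
                else:
                    acc.deposit(role, idx, e * 1e3)
                return
            if outside:
                acc.escaped += (e - e_new) * 1e3
            else:
                acc.deposit(role, idx, (e - e_new) * 1e3)
            e = e_new
            p += d * (ds + (CROSSING_NUDGE_NM if crossing else 0.0))
            if cfg.multiple_scattering:
                rho = 1.0 if outside else self.rho[role]
                x0 = C.X0_WATER if outside else self.x0[role]
                d = _deflect(d, _highland_theta0(
                    e, ds, rho, x0, char_nm=float(model.range_nm(e))), rng)
            if crossing:
                role, idx = self.locate(p)


def _highland_theta0(energy_kev: float, step_nm: float, rho: float,
                     x0_gcm2: float, char_nm: float | None = None) -> float:
    """Highland multiple-scattering width (rad) for one step.

    The logarithmic Highland term is calibrated for the full thickness a
    particle traverses; evaluating it per condensed step and adding the
    variances would systematically underestimate the accumulated scattering
    angle.  The bracket is therefore evaluated at the characteristic track
    thickness ``char_nm`` (the remaining CSDA range) while the sqrt(x)
    factor uses the actual step, which keeps the per-step variances
    additive and consistent with the full-path Highland value.
    """
    x = step_nm * 1e-7 * rho / x0_gcm2  # step thickness in units of X0
    if x <= 0:
        return 0.0
    x_char = x if char_nm is None else max(char_nm * 1e-7 * rho / x0_gcm2, x)
    mc2 = C.ELECTRON_MASS_KEV
    pc2 = energy_kev * (energy_kev + 2.0 * mc2)  # (pc)^2, keV^2
    beta_pc = pc2 / (energy_kev + mc2)  # beta * pc, keV
    bracket = 1.0 + 0.038 * math.log(x_char)
    if bracket <= 0:
        bracket = 0.0
    return 13.6e3 / beta_pc * math.sqrt(x) * bracket


def _deflect(d: np.ndarray, theta0: float, rng) -> np.ndarray:
    """Rotate d by two independent Gaussian projected angles of width
    theta0 (small-angle multiple scattering)."""
    if theta0 <= 0:
        return d
    tx, ty = rng.standard_normal(2) * theta0
    theta = math.hypot(tx, ty)
    if theta == 0:
        return d
    # orthonormal frame around d
    if abs(d[2]) < 0.9:
        e1 = np.array([-d[1], d[0], 0.0])
    else:
        e1 = np.array([0.0, -d[2], d[1]])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    phi = math.atan2(ty, tx)
    new = (math.cos(theta) * d
           + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2))
    return new / np.linalg.norm(new)


def _context_for(geom: CellGeometry) -> TransportContext:
    return geom._cached("transport_ctx", lambda: TransportContext(geom))


# ---------------------------------------------------------------------------
# public per-particle interfaces
# ---------------------------------------------------------------------------

def _check_unit(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    return d


def transport_electron(geom: CellGeometry, pos, direction, energy_kev: float,
                       cfg: TransportConfig, rng=None
                       ) -> tuple[list[TrackDeposit], float]:
    """Transport one electron; returns (per-region deposits in eV, escaped
    energy in eV).  Deposits plus escaped energy equal the initial energy."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    d = _check_unit(direction)
    rng = np.random.default_rng(rng)
    ctx = _context_for(geom)
    acc = _Accumulator(geom)
    acc.track = []
    ctx.run_electron(np.asarray(pos, dtype=float), d, energy_kev, cfg, rng, acc)
    merged: dict[int, float] = {}
    for role, idx, ev in acc.track:
        rid = geom.region_id(role, idx)
        merged[rid] = merged.get(rid, 0.0) + ev
    deposits = [TrackDeposit(rid, ev) for rid, ev in sorted(merged.items())]
    return deposits, acc.escaped


def transport_photon(geom: CellGeometry, pos, direction, energy_kev: float,
                     cfg: TransportConfig, rng=None) -> list[TrackDeposit]:
    """Transport one photon (escape or single interaction in water)."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    d = _check_unit(direction)
    rng = np.random.default_rng(rng)
    if cfg.photon_mode == PHOTON_ESCAPE:
        return []
    mu_nm, absorbed_fraction = photon_mu_per_nm(energy_kev)
    path = rng.exponential(1.0 / mu_nm)
    q = np.asarray(pos, dtype=float) + path * d
    if np.linalg.norm(q) > geom.cell_radius:
        return []
    rid = G.region_at(geom, q)
    return [TrackDeposit(rid, energy_kev * 1e3 * absorbed_fraction)]


# ---------------------------------------------------------------------------
# full decay simulation
# ---------------------------------------------------------------------------

def simulate_decays(geom: CellGeometry, nuclide: NuclideSpec, mode: str,
                    n_decays: int, cfg: TransportConfig | None = None,
                    rng=None, coulomb: bool = True,
                    monoenergetic: bool = False) -> EnergyTally:
    """Simulate ``n_decays`` radioactive decays and return the batch tally.

    Every decay consists of one beta particle (branch and spectrum energy
    sampled per the nuclide data) and zero or more gamma photons, all
    isotropic, all started from the sampled decay position (discrete mode:
    inside a nanoparticle; continuous mode: uniform in the cytosol).
    """
    if n_decays < 1:
        raise ValueError("n_decays must be >= 1")
    cfg = cfg or TransportConfig()
    rng = np.random.default_rng(rng)
    ctx = _context_for(geom)
    acc = _Accumulator(geom)

    if mode == MODE_DISCRETE:
        positions = sample_decay_positions_discrete(geom, rng, n_decays)
    elif mode == MODE_CONTINUOUS:
        positions = G.sample_point_in_cytosol(geom, rng, size=n_decays)
    else:
        raise ValueError(f"unknown source mode {mode!r}")

    # beta branch, spectrum energy and direction for every decay
    intensities = np.array([b.intensity for b in nuclide.beta_lines])
    branch = rng.choice(len(intensities), size=n_decays, p=intensities)
    energies = np.empty(n_decays)
    for k, line in enumerate(nuclide.beta_lines):
        mask = branch == k
        if mask.any():
            energies[mask] = sample_beta_energy(
                line.energy, rng, size=int(mask.sum()), coulomb=coulomb,
                daughter_z=nuclide.daughter_z, monoenergetic=monoenergetic)
    directions = sample_unit_vectors(rng, n_decays)
    for i in range(n_decays):
        ctx.run_electron(positions[i], directions[i], float(energies[i]),
                         cfg, rng, acc)

    # gamma lines, vectorised (interactions inside the cell are rare)
    if cfg.photon_mode == PHOTON_SINGLE:
        for line in nuclide.gamma_lines:
            emitted = np.nonzero(rng.random(n_decays) < line.intensity)[0]
            if len(emitted) == 0:
                continue
            mu_nm, absorbed_fraction = photon_mu_per_nm(line.energy)
            dirs = sample_unit_vectors(rng, len(emitted))
            paths = rng.exponential(1.0 / mu_nm, size=len(emitted))
            points = positions[emitted] + dirs * paths[:, None]
            inside = np.linalg.norm(points, axis=1) <= geom.cell_radius
            for q in points[inside]:
                role, idx = ctx.locate(q)
                if role != G.ROLE_OUTSIDE:
                    acc.deposit(role, idx, line.energy * 1e3 * absorbed_fraction)

    return EnergyTally(n_decays=n_decays, energy=dict(acc.roles),
                       mito_energy=acc.mito, np_energy=acc.np_,
                       escaped=acc.escaped)
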