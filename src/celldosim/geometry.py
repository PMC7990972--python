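"""Spherical cell world: nested-sphere geometry, nanoparticle placement,
point classification and ray tracing.

The cell is a ball of radius ``cell_radius`` centred at the origin.  The
outermost shell ``[cell_radius - membrane_thickness, cell_radius]`` is the
membrane; everything inside the inner membrane surface that is not nucleus,
mitochondrion or nanoparticle is cytosol.  All organelles and nanoparticles
are spheres, so overlap and containment checks are analytic, which keeps the
construction of geometries with tens of thousands of nanoparticles cheap.

Conventions
-----------
* Tangency is not overlap: two spheres whose centre distance equals the sum
  of their radii are legal.  This is required for surface-attached
  nanoparticles, which sit in exact contact with their target organelle.
* Points within ``BOUNDARY_TOL`` of a surface belong to the inner (more
  specific) region; classification precedence is
  nanoparticle > mitochondrion > nucleus > membrane > cytosol > outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import constants as C

BOUNDARY_TOL = 1e-9  # nm

# Fixed region-id encoding: singleton regions first, then one id per object.
OUTSIDE = 0
MEMBRANE = 1
CYTOSOL = 2
NUCLEUS = 3
REGION_BASE = 4  # mitochondria ids start here, nanoparticles after them

ROLE_OUTSIDE = "outside"
ROLE_MEMBRANE = "membrane"
ROLE_CYTOSOL = "cytosol"
ROLE_NUCLEUS = "nucleus"
ROLE_MITOCHONDRION = "mitochondrion"
ROLE_NANOPARTICLE = "nanoparticle"
ROLE_CELL = "cell"


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object."""


@dataclass(frozen=True)
class Material:
    """A homogeneous medium: density, elemental composition and mean
    excitation energy (the I-value entering the electron stopping power)."""

    name: str
    density: float  # g/cm^3
    mass_fractions: dict[str, float]
    mean_excitation_energy: float  # eV
    #: electron-density parameter used by the stopping power; when None it
    #: is derived from the composition.  Aqueous compartments pin it to
    #: liquid water's value (the compositions differ from water by <1%).
    stopping_z_over_a: float | None = None

    def __post_init__(self):
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions of {self.name!r} sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean excitation energy must be positive")

    @property
    def z_over_a(self) -> float:
        if self.stopping_z_over_a is not None:
            return self.stopping_z_over_a
        return C.z_over_a(self.mass_fractions)


def tissue_material(name: str, composition: dict[str, float]) -> Material:
    return Material(name, C.TISSUE_DENSITY, composition, C.I_TISSUE_EV,
                    stopping_z_over_a=C.Z_OVER_A_WATER)


def gold_material() -> Material:
    return Material("gold", C.GOLD_DENSITY, C.COMPOSITION_GOLD, C.I_GOLD_EV)


def gold_loaded_cytosol(gold_mass_fraction: float) -> Material:
    """Cytosol with a homogeneous admixture of gold (continuous-gold model).

    ``gold_mass_fraction`` is the gold mass fraction *of the cytosol medium*
    (not of the whole cell).  The mean excitation energy is combined by the
    Bragg additivity rule on ln(I) weighted by electron fractions; the
    density stays at 1.0 g/cm^3 because the admixed mass fraction is tiny
    (at most about 1e-2) in every condition considered.
    """
    if not 0.0 <= gold_mass_fraction < 1.0:
        raise ValueError("gold mass fraction must be in [0, 1)")
    w = gold_mass_fraction
    fractions = {el: f * (1 - w) for el, f in C.COMPOSITION_CYTOSOL.items()}
    if w > 0:
        fractions["Au"] = w
    za_t = C.Z_OVER_A_WATER
    za_au = C.z_over_a(C.COMPOSITION_GOLD)
    za_mix = (1 - w) * za_t + w * za_au
    ln_i = ((1 - w) * za_t * np.log(C.I_TISSUE_EV)
            + w * za_au * np.log(C.I_GOLD_EV)) / za_mix
    return Material(f"cytosol+Au({w:.3g})", C.TISSUE_DENSITY, fractions,
                    float(np.exp(ln_i)), stopping_z_over_a=za_mix)


def default_materials() -> dict[str, Material]:
    return {
        ROLE_CYTOSOL: tissue_material("cytosol", C.COMPOSITION_CYTOSOL),
        ROLE_NUCLEUS: tissue_material("nucleus", C.COMPOSITION_NUCLEUS),
        ROLE_MITOCHONDRION: tissue_material("mitochondrion",
                                            C.COMPOSITION_MITOCHONDRION),
        ROLE_MEMBRANE: tissue_material("membrane", C.COMPOSITION_MEMBRANE),
        ROLE_NANOPARTICLE: gold_material(),
    }


@dataclass
class SphereRegion:
    """One sphere of the world.  For the membrane, ``inner_radius`` holds the
    inner shell surface and ``radius`` the outer one."""

    id: int
    role: str
    center: np.ndarray
    radius: float
    material: Material
    inner_radius: float | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.inner_radius is not None and self.inner_radius >= self.radius:
            raise ValueError("membrane outer radius must exceed inner radius")


@dataclass(frozen=True)
class PlacementSpec:
    """How many nanoparticles to add, their radius, and which fraction is
    attached to the surface of the target organelle (the rest is distributed
    uniformly in the cytosol)."""

    n_np: int
    r_np: float  # nm
    fraction_targeted: float = 0.0
    target: str = ROLE_NUCLEUS
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.n_np < 0:
            raise ValueError("n_np must be >= 0")
        if self.r_np <= 0:
            raise ValueError("r_np must be positive")
        if not 0.0 <= self.fraction_targeted <= 1.0:
            raise ValueError("fraction_targeted must be in [0, 1]")
        if self.target not in (ROLE_NUCLEUS, ROLE_MITOCHONDRION):
            raise ValueError(f"unknown target {self.target!r}")

    @property
    def n_targeted(self) -> int:
        # round-half-even, so 0.5 fractions do not bias upward
        return round(self.n_np * self.fraction_targeted)


@dataclass(frozen=True)
class PathSegment:
    region_id: int
    entry: np.ndarray
    length: float


@dataclass(frozen=True)
class Violation:
    kind: str  # "overlap" | "containment"
    ids: tuple[int, ...]
    detail: str


class CellGeometry:
    """The assembled cell world.

    Mitochondria and nanoparticle centres/radii are also exposed as numpy
    arrays (``mito_centers`` etc.) and a k-d tree over nanoparticle centres
    is cached, since transport touches them millions of times.
    """

    def __init__(self, cell_radius: float, membrane_thickness: float,
                 nucleus: SphereRegion, mitochondria: list[SphereRegion],
                 nanoparticles: list[SphereRegion] | None = None,
                 materials: dict[str, Material] | None = None):
        if membrane_thickness <= 0 or membrane_thickness >= cell_radius:
            raise ValueError("membrane thickness must be in (0, cell_radius)")
        self.cell_radius = float(cell_radius)
        self.membrane_thickness = float(membrane_thickness)
        self.nucleus = nucleus
        self.mitochondria = list(mitochondria)
        self.nanoparticles = list(nanoparticles or [])
        self.materials = materials or default_materials()
        self._cache: dict = {}

    # --- structural helpers ------------------------------------------------
    @property
    def inner_radius(self) -> float:
        """Radius of the inner membrane surface."""
        return self.cell_radius - self.membrane_thickness

    @property
    def n_mitochondria(self) -> int:
        return len(self.mitochondria)

    @property
    def n_nanoparticles(self) -> int:
        return len(self.nanoparticles)

    def invalidate(self) -> None:
        self._cache.clear()

    def _cached(self, key, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def mito_centers(self) -> np.ndarray:
        return self._cached("mc", lambda: np.array(
            [m.center for m in self.mitochondria], dtype=float
        ).reshape(-1, 3))

    @property
    def mito_radii(self) -> np.ndarray:
        return self._cached("mr", lambda: np.array(
            [m.radius for m in self.mitochondria], dtype=float))

    @property
    def np_centers(self) -> np.ndarray:
        return self._cached("nc", lambda: np.array(
            [p.center for p in self.nanoparticles], dtype=float
        ).reshape(-1, 3))

    @property
    def np_radii(self) -> np.ndarray:
        return self._cached("nr", lambda: np.array(
            [p.radius for p in self.nanoparticles], dtype=float))

    @property
    def np_tree(self) -> cKDTree | None:
        if not self.nanoparticles:
            return None
        return self._cached("tree", lambda: cKDTree(self.np_centers))

    # --- region ids ---------------------------------------------------------
    def region_id(self, role: str, index: int | None = None) -> int:
        if role == ROLE_OUTSIDE:
            return OUTSIDE
        if role == ROLE_MEMBRANE:
            return MEMBRANE
        if role == ROLE_CYTOSOL:
            return CYTOSOL
        if role == ROLE_NUCLEUS:
            return NUCLEUS
        if role == ROLE_MITOCHONDRION:
            return REGION_BASE + index
        if role == ROLE_NANOPARTICLE:
            return REGION_BASE + self.n_mitochondria + index
        raise ValueError(f"unknown role {role!r}")

    def region_role(self, region_id: int) -> tuple[str, int | None]:
        """Inverse of :meth:`region_id`: (role, object index or None)."""
        if region_id == OUTSIDE:
            return ROLE_OUTSIDE, None
        if region_id == MEMBRANE:
            return ROLE_MEMBRANE, None
        if region_id == CYTOSOL:
            return ROLE_CYTOSOL, None
        if region_id == NUCLEUS:
            return ROLE_NUCLEUS, None
        k = region_id - REGION_BASE
        if k < self.n_mitochondria:
            return ROLE_MITOCHONDRION, k
        k -= self.n_mitochondria
        if k < self.n_nanoparticles:
            return ROLE_NANOPARTICLE, k
        raise ValueError(f"region id {region_id} out of range")

    # --- volumes ------------------------------------------------------------
    def cell_volume_nm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.cell_radius ** 3

    def cell_mass_kg(self) -> float:
        """Mass of the whole 6 um cell sphere at unit density (the admixed
        gold, at most 0.04% by mass, is neglected)."""
        volume_cm3 = self.cell_volume_nm3() * 1e-21
        return volume_cm3 * C.TISSUE_DENSITY * 1e-3


# ---------------------------------------------------------------------------
# elementary predicates and samplers
# ---------------------------------------------------------------------------

def sphere_overlap(c1, r1, c2, r2) -> bool:
    """Strict overlap test: touching spheres (|c1-c2| == r1+r2) do NOT
    overlap, so surface-attached nanoparticles are legal."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    return d < r1 + r2 - BOUNDARY_TOL


def sample_point_in_sphere(center, radius, rng, size=None):
    """Uniform point(s) in the ball of given centre/radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = 1 if size is None else size
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # radius ~ R * U^(1/3) gives constant density in r^3
    r = radius * rng.random((n, 1)) ** (1.0 / 3.0)
    pts = np.asarray(center, float) + v / norm * r
    return pts[0] if size is None else pts


def sample_unit_vectors(rng, size=None):
    n = 1 if size is None else size
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if size is None else v


def _inside_any(points: np.ndarray, centers: np.ndarray,
                radii: np.ndarray) -> np.ndarray:
    """Boolean mask: point i lies strictly inside any of the given spheres."""
    if centers.shape[0] == 0:
        return np.zeros(len(points), dtype=bool)
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 < (radii[None, :] + BOUNDARY_TOL) ** 2).any(axis=1)


def sample_point_in_cytosol(geom: CellGeometry, rng, size=None,
                            max_attempts: int = 10_000):
    """Uniform point(s) in the cytosol: inside the inner membrane surface,
    outside nucleus, mitochondria and nanoparticles (rejection sampling)."""
    n = 1 if size is None else size
    out = np.empty((n, 3))
    need = np.arange(n)
    tree = geom.np_tree
    r_np_max = float(geom.np_radii.max()) if geom.n_nanoparticles else 0.0
    for _ in range(max_attempts):
        pts = sample_point_in_sphere(np.zeros(3), geom.inner_radius, rng,
                                     size=len(need))
        bad = np.linalg.norm(pts - geom.nucleus.center, axis=1) \
            < geom.nucleus.radius + BOUNDARY_TOL
        bad |= _inside_any(pts, geom.mito_centers, geom.mito_radii)
        if tree is not None:
            dist, idx = tree.query(pts)
            bad |= dist < geom.np_radii[idx] + BOUNDARY_TOL
        out[need[~bad]] = pts[~bad]
        need = need[bad]
        if len(need) == 0:
            return out[0] if size is None else out
    raise PlacementError(
        f"could not sample {len(need)} cytosol point(s) in {max_attempts} rounds")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def build_cho_cell(cell_radius: float = C.CELL_RADIUS_NM,
                   membrane_thickness: float = C.MEMBRANE_THICKNESS_NM,
                   nucleus_radius: float = C.NUCLEUS_RADIUS_NM,
                   n_mitochondria: int = C.N_MITOCHONDRIA,
                   mitochondrion_radius: float = C.MITOCHONDRION_RADIUS_NM,
                   rng=None, max_attempts: int = 10_000,
                   materials: dict[str, Material] | None = None) -> CellGeometry:
    """Build the default CHO-like cell: nucleus at the origin and
    ``n_mitochondria`` mitochondria placed uniformly at random in the
    cytosol without overlaps (rejection sampling; deterministic given rng).
    """
    rng = np.random.default_rng(rng)
    materials = materials or default_materials()
    inner = cell_radius - membrane_thickness
    if nucleus_radius >= inner:
        raise ValueError(
            f"nucleus radius {nucleus_radius} does not fit inside the inner "
            f"membrane surface at {inner}")
    nucleus = SphereRegion(NUCLEUS, ROLE_NUCLEUS, np.zeros(3), nucleus_radius,
                           materials[ROLE_NUCLEUS])
    mitos: list[np.ndarray] = []
    r_m = mitochondrion_radius
    if n_mitochondria > 0 and nucleus_radius + 2 * r_m > inner:
        raise PlacementError("cytosol shell too thin for mitochondria")
    for i in range(n_mitochondria):
        for attempt in range(max_attempts):
            c = sample_point_in_sphere(np.zeros(3), inner - r_m, rng)
            if np.linalg.norm(c) < nucleus_radius + r_m:
                continue
            if mitos and bool(_inside_any(c[None, :], np.array(mitos),
                                          np.full(len(mitos), 2 * r_m))[0]):
                continue
            mitos.append(c)
            break
        else:
            raise PlacementError(
                f"failed to place mitochondrion {i} after {max_attempts} "
                f"attempts: cytosol too crowded")
    mito_regions = [
        SphereRegion(REGION_BASE + i, ROLE_MITOCHONDRION, c, r_m,
                     materials[ROLE_MITOCHONDRION])
        for i, c in enumerate(mitos)
    ]
    return CellGeometry(cell_radius, membrane_thickness, nucleus,
                        mito_regions, [], materials)


def place_nanoparticles(geom: CellGeometry, spec: PlacementSpec,
                        rng=None) -> CellGeometry:
    """Add nanoparticles to the geometry (in place; the geometry is also
    returned for chaining).

    ``round(n_np * fraction_targeted)`` particles are attached to the target
    organelle surface: centre at distance R_target + r_np from the organelle
    centre, direction uniform on the unit sphere (for mitochondria targets
    the host is drawn uniformly per particle).  The remainder is uniform in
    the cytosol.  Collisions with organelles or already-placed particles are
    resolved by resampling up to ``spec.max_attempts`` times per particle.
    """
    rng = np.random.default_rng(rng)
    if spec.n_np == 0:
        return geom
    r = spec.r_np
    inner = geom.inner_radius
    n_tar = spec.n_targeted
    n_free = spec.n_np - n_tar

    accepted = np.empty((spec.n_np, 3))
    n_acc = 0
    tree: cKDTree | None = None

    def conflicts(pts: np.ndarray) -> np.ndarray:
        bad = np.linalg.norm(pts, axis=1) > inner - r + BOUNDARY_TOL
        bad |= np.linalg.norm(pts - geom.nucleus.center, axis=1) \
            < geom.nucleus.radius + r - BOUNDARY_TOL
        if geom.n_mitochondria:
            d2 = ((pts[:, None, :] - geom.mito_centers[None, :, :]) ** 2).sum(axis=2)
            bad |= (d2 < (geom.mito_radii[None, :] + r - BOUNDARY_TOL) ** 2).any(axis=1)
        if tree is not None:
            dist, _ = tree.query(pts)
            bad |= dist < 2 * r - BOUNDARY_TOL
        return bad

    def accept_batch(sampler, n_want, what):
        nonlocal n_acc, tree
        start = n_acc
        need = n_want
        for _ in range(spec.max_attempts):
            if need == 0:
                break
            pts = sampler(need)
            bad = conflicts(pts)
            # also avoid collisions among this candidate batch itself:
            # accept greedily, deferring the later member of each close pair
            good = pts[~bad]
            if len(good) > 1:
                pairs = cKDTree(good).query_pairs(2 * r - BOUNDARY_TOL,
                                                  output_type="ndarray")
                if len(pairs):
                    drop = np.zeros(len(good), dtype=bool)
                    drop[pairs[:, 1]] = True
                    good = good[~drop]
            accepted[n_acc:n_acc + len(good)] = good
            n_acc += len(good)
            need -= len(good)
            if len(good):
                tree = cKDTree(accepted[:n_acc])
        if need:
            raise PlacementError(
                f"placed only {n_acc - start}/{n_want} {what} nanoparticles "
                f"after {spec.max_attempts} rounds")

    if n_tar:
        if spec.target == ROLE_NUCLEUS:
            dist = geom.nucleus.radius + r
            if dist > inner - r:
                raise PlacementError("targeted shell lies outside the cytosol")

            def sampler(k):
                return geom.nucleus.center + dist * sample_unit_vectors(rng, k)
        else:
            if geom.n_mitochondria == 0:
                raise PlacementError("no mitochondria to target")

            def sampler(k):
                host = rng.integers(geom.n_mitochondria, size=k)
                d = geom.mito_radii[host] + r
                return geom.mito_centers[host] \
                    + d[:, None] * sample_unit_vectors(rng, k)
        accept_batch(sampler, n_tar, "targeted")
    if n_free:
        def sampler(k):
            return sample_point_in_sphere(np.zeros(3), inner - r, rng, size=k)
        accept_batch(sampler, n_free, "cytosol")

    mat = geom.materials[ROLE_NANOPARTICLE]
    base = REGION_BASE + geom.n_mitochondria + geom.n_nanoparticles
    geom.nanoparticles.extend(
        SphereRegion(base + i, ROLE_NANOPARTICLE, accepted[i].copy(), r, mat)
        for i in range(spec.n_np))
    geom.invalidate()
    return geom


# ---------------------------------------------------------------------------
# interrogation
# ---------------------------------------------------------------------------

def region_at(geom: CellGeometry, point) -> int:
    """Region id containing ``point``.  Precedence: nanoparticle >
    mitochondrion > nucleus > membrane > cytosol > outside; points within
    BOUNDARY_TOL of a surface belong to the inner region."""
    p = np.asarray(point, dtype=float)
    r = float(np.linalg.norm(p))
    if r > geom.cell_radius + BOUNDARY_TOL:
        return OUTSIDE
    tree = geom.np_tree
    if tree is not None:
        dist, idx = tree.query(p)
        if dist <= geom.np_radii[idx] + BOUNDARY_TOL:
            return geom.region_id(ROLE_NANOPARTICLE, int(idx))
    if geom.n_mitochondria:
        d2 = ((geom.mito_centers - p) ** 2).sum(axis=1)
        k = int(np.argmin(d2))
        if d2[k] <= (geom.mito_radii[k] + BOUNDARY_TOL) ** 2:
            return geom.region_id(ROLE_MITOCHONDRION, k)
    if np.linalg.norm(p - geom.nucleus.center) <= geom.nucleus.radius + BOUNDARY_TOL:
        return NUCLEUS
    if r > geom.inner_radius + BOUNDARY_TOL:
        return MEMBRANE
    return CYTOSOL


def ray_sphere_ts(origin, direction, center, radius) -> tuple[float, float] | None:
    """Both parameters t of the intersection of origin + t*direction with the
    sphere, or None if the ray line misses it."""
    oc = np.asarray(origin, float) - np.asarray(center, float)
    b = float(np.dot(oc, direction))
    c = float(np.dot(oc, oc)) - radius * radius
    disc = b * b - c
    if disc <= 0:
        return None
    sq = np.sqrt(disc)
    return (-b - sq, -b + sq)


def trace_path(geom: CellGeometry, origin, direction,
               max_length: float = np.inf) -> list[PathSegment]:
    """Ordered contiguous segments of the ray through the geometry, from
    ``origin`` until the cell boundary or ``max_length``.  Each segment is
    labelled by the region of its midpoint."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if np.linalg.norm(origin) > geom.cell_radius + BOUNDARY_TOL:
        length = max_length if np.isfinite(max_length) else 0.0
        return [PathSegment(OUTSIDE, origin.copy(), float(length))]

    ts = ray_sphere_ts(origin, direction, np.zeros(3), geom.cell_radius)
    t_exit = ts[1] if ts is not None else 0.0
    t_end = min(t_exit, max_length)
    cuts = {0.0, t_end}
    spheres: list[tuple[np.ndarray, float]] = [
        (np.zeros(3), geom.inner_radius),
        (geom.nucleus.center, geom.nucleus.radius),
    ]
    spheres += [(m.center, m.radius) for m in geom.mitochondria]
    spheres += [(p.center, p.radius) for p in geom.nanoparticles]
    for center, radius in spheres:
        ts = ray_sphere_ts(origin, direction, center, radius)
        if ts is None:
            continue
        for t in ts:
            if BOUNDARY_TOL < t < t_end - BOUNDARY_TOL:
                cuts.add(t)
    t_sorted = sorted(cuts)
    segments = []
    for t0, t1 in zip(t_sorted[:-1], t_sorted[1:]):
        if t1 - t0 <= BOUNDARY_TOL:
            continue
        mid = origin + direction * (0.5 * (t0 + t1))
        segments.append(PathSegment(region_at(geom, mid),
                                    origin + direction * t0, t1 - t0))
    return segments


def gold_mass_percent(spec: PlacementSpec, geom: CellGeometry) -> float:
    """Gold mass of all nanoparticles as a percentage of the whole-cell
    sphere mass at unit density."""
    np_mass = spec.n_np * (4.0 / 3.0) * np.pi * spec.r_np ** 3 * C.GOLD_DENSITY
    cell_mass = (4.0 / 3.0) * np.pi * geom.cell_radius ** 3 * C.TISSUE_DENSITY
    return 100.0 * np_mass / cell_mass


def np_count_for_mass_percent(percent: float, r_np: float,
                              geom: CellGeometry) -> int:
    """Inverse of :func:`gold_mass_percent`: nanoparticle count (rounded)
    that yields the requested whole-cell gold mass percentage."""
    one = gold_mass_percent(PlacementSpec(n_np=1, r_np=r_np), geom)
    return round(percent / one)


def validate_geometry(geom: CellGeometry) -> list[Violation]:
    """Check every containment and non-overlap invariant analytically and
    return the list of violations (empty when the geometry is valid)."""
    v: list[Violation] = []
    inner = geom.inner_radius

    def check_contained(region: SphereRegion):
        d = float(np.linalg.norm(region.center)) + region.radius
        if d > inner + BOUNDARY_TOL:
            v.append(Violation("containment", (region.id,),
                               f"{region.role} {region.id} extends to radius "
                               f"{d:.3f} beyond inner membrane surface {inner}"))

    check_contained(geom.nucleus)
    for m in geom.mitochondria:
        check_contained(m)
    for p in geom.nanoparticles:
        check_contained(p)

    regions = [geom.nucleus] + geom.mitochondria
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if sphere_overlap(a.center, a.radius, b.center, b.radius):
                v.append(Violation("overlap", (a.id, b.id),
                                   f"{a.role} {a.id} overlaps {b.role} {b.id}"))
    if geom.n_nanoparticles:
        centers, radii = geom.np_centers, geom.np_radii
        d = np.linalg.norm(centers - geom.nucleus.center, axis=1)
        for j in np.nonzero(d < geom.nucleus.radius + radii - BOUNDARY_TOL)[0]:
            p = geom.nanoparticles[j]
            v.append(Violation("overlap", (geom.nucleus.id, p.id),
                               f"nucleus overlaps nanoparticle {p.id}"))
        if geom.n_mitochondria:
            d2 = ((centers[:, None, :] - geom.mito_centers[None, :, :]) ** 2).sum(axis=2)
            lim = (geom.mito_radii[None, :] + radii[:, None] - BOUNDARY_TOL) ** 2
            for j, k in zip(*np.nonzero(d2 < lim)):
                v.append(Violation(
                    "overlap",
                    (geom.mitochondria[k].id, geom.nanoparticles[j].id),
                    f"mitochondrion {k} overlaps nanoparticle {j}"))
        tree = geom.np_tree
        pairs = tree.query_pairs(float(2 * radii.max() - BOUNDARY_TOL),
                                 output_type="ndarray")
        for a, b in pairs:
            if sphere_overlap(centers[a], radii[a], centers[b], radii[b]):
                v.append(Violation(
                    "overlap",
                    (geom.nanoparticles[a].id, geom.nanoparticles[b].id),
                    f"nanoparticles {a} and {b} overlap"))
    return v


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_topas_parameters(geom: CellGeometry,
                            spec: PlacementSpec | None = None) -> str:
    """Emit the cell dimensions and nanoparticle placement as a TOPAS-style
    plain-text parameter block (s:/d:/i: key syntax), for cross-validation of
    the same geometry in external Monte-Carlo codes.  Radii round-trip
    exactly through repr formatting."""
    lines = [
        's:Ge/MyCell/Type = "TsSphericalCellSphericalNP"',
        f"d:Ge/MyCell/CellRadius = {geom.cell_radius!r} nm",
        f"d:Ge/MyCell/MembraneThickness = {geom.membrane_thickness!r} nm",
        f"d:Ge/MyCell/Nucleus/NucleusRadius = {geom.nucleus.radius!r} nm",
        f"i:Ge/MyCell/Mitochondria/NumberOfMitochondria = {geom.n_mitochondria}",
    ]
    if geom.n_mitochondria:
        lines.append("d:Ge/MyCell/Mitochondria/Radius = "
                     f"{geom.mitochondria[0].radius!r} nm")
    if spec is not None and spec.n_np > 0:
        lines += [
            f"i:Ge/MyCell/Nanoparticle/NumberOfNanoparticles = {spec.n_np}",
            f"d:Ge/MyCell/Nanoparticle/Radius = {spec.r_np!r} nm",
            "i:Ge/MyCell/Nanoparticle/NumberAtSurface = "
            f"{spec.n_targeted}",
            f's:Ge/MyCell/Nanoparticle/Target = "{spec.target}"',
        ]
    return "\n".join(lines) + "\n"


def parse_topas_parameters(text: str) -> dict[str, float | int | str]:
    """Parse the subset of TOPAS parameter syntax written by
    :func:`export_topas_parameters` back into a flat dict."""
    out: dict[str, float | int | str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key_part, value_part = line.split("=", 1)
        kind, key = key_part.strip().split(":", 1)
        tokens = value_part.strip().split()
        if kind == "d":
            out[key] = float(tokens[0])
        elif kind == "i":
            out[key] = int(tokens[0])
        else:
            out[key] = tokens[0].strip('"')
    return out


def geometry_to_frame(geom: CellGeometry):
    """All spheres of the world as a pandas DataFrame
    (role, id, x, y, z, radius, material), one row per sphere."""
    import pandas as pd

    rows = [{
        "role": ROLE_CELL, "id": -1, "x": 0.0, "y": 0.0, "z": 0.0,
        "radius": geom.cell_radius, "material": "world",
    }]
    for region in [geom.nucleus] + geom.mitochondria + geom.nanoparticles:
        rows.append({
            "role": region.role, "id": region.id,
            "x": region.center[0], "y": region.center[1], "z": region.center[2],
            "radius": region.radius, "material": region.material.name,
        })
    return pd.DataFrame(rows)
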