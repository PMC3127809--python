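"""Spine, cleft and neuropil geometry.

Coordinate system: right-handed, lengths in nm, origin at the centre of the
synaptic cleft, z normal to the postsynaptic density (PSD).  The spine head
is a regular octagonal prism (across-flats diameter ``head_diameter``) whose
top face carries the PSD square at z = -cleft_width/2; the presynaptic
bouton is an identical prism whose bottom face sits at z = +cleft_width/2.
Both prisms are reflecting obstacles inside a closed rectangular neuropil
box; the diffusion domain is the box minus the two prisms, and every surface
reflects glutamate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from numba import njit

from .kinetics import SUBTYPES

SQRT2 = math.sqrt(2.0)

# geometry parameter-vector layout (float64[13]) shared with the engine
G_A = 0        # octagon half across-flats (= head_diameter / 2)
G_C = 1        # octagon diagonal bound: |x|+|y| <= c, c = head_diameter/sqrt(2)
G_ZS_TOP = 2   # spine-head top (PSD plane), -cleft_width/2
G_ZS_BOT = 3   # spine-head bottom
G_ZB_BOT = 4   # bouton bottom (presynaptic face), +cleft_width/2
G_ZB_TOP = 5   # bouton top
G_BX = 6       # neuropil box half-extent, x
G_BY = 7       # neuropil box half-extent, y
G_BZ = 8       # neuropil box half-extent, z
G_PSD = 9      # PSD half-width
G_SA = 10      # neuropil sleeve half across-flats (0 = no sleeve)
G_SZLO = 11    # sleeve lower z
G_SZHI = 12    # sleeve upper z
G_ZD_LO = 13   # dendritic-shaft slab bottom (= sleeve lower z if absent)


@dataclass
class SpineGeometry:
    """Axis-aligned surfaces defining cleft, spine head, bouton and neuropil.

    Defaults follow the modelled prototypical thin spine: a 300x300 nm PSD
    facing an identical presynaptic face across a 20 nm cleft, and a 500 nm
    (across flats) octagonal spine head.  The surrounding neuropil membrane
    is a reflecting octagonal sleeve at 20 nm clearance around the sides of
    bouton and spine head, continuing along the axon for ``sleeve_extension`` nm,
    open at the axon end and closed below by the parent dendritic shaft (an
    octagonal slab at the sleeve scale); a closed outer box (default 4x4x4
    um) bounds the whole
    extracellular space so glutamate is conserved.  The sleeve retains
    released glutamate near the synapse for several milliseconds before it
    leaks through the end openings and dilutes into the box.  The spine
    neck is closed (no glutamate enters the head interior).
    """

    psd_width: float = 300.0
    cleft_width: float = 20.0
    head_diameter: float = 500.0
    head_height: float = 350.0
    bouton_height: float = 350.0
    box_size: tuple[float, float, float] = (4000.0, 4000.0, 4000.0)
    sleeve: bool = True
    sleeve_clearance: float = 20.0
    sleeve_extension: float = 350.0
    dendrite_thickness: float = 300.0

    def __post_init__(self) -> None:
        if min(self.psd_width, self.cleft_width, self.head_diameter,
               self.head_height, self.bouton_height, *self.box_size) <= 0:
            raise ValueError("all geometry dimensions must be positive")
        if self.cleft_width > self.head_height:
            raise ValueError("cleft width may not exceed the spine height")
        # PSD square corner (w/2, w/2) must stay inside the octagon
        if (self.psd_width / 2 > self.head_diameter / 2
                or self.psd_width > self.head_diameter / SQRT2):
            raise ValueError("PSD face not contained in spine-head top")
        total_z = (self.head_height + self.bouton_height + self.cleft_width
                   + (self.sleeve_extension + 200.0 + self.dendrite_thickness
                      if self.sleeve else 0.0))
        envelope = self.head_diameter + 2 * self.sleeve_clearance
        if (self.box_size[0] <= envelope or self.box_size[1] <= envelope
                or self.box_size[2] <= total_z):
            raise ValueError("neuropil box must enclose bouton, spine head "
                             "and sleeve")

    @property
    def release_point(self) -> np.ndarray:
        """Glutamate point source: centre of the presynaptic face, nudged
        1 nm into the cleft."""
        return np.array([0.0, 0.0, self.cleft_width / 2 - 1.0])

    @property
    def psd_area(self) -> float:
        return self.psd_width ** 2

    def octagon_area(self) -> float:
        f = self.head_diameter
        return 2.0 * (SQRT2 - 1.0) * f * f

    def head_surface_area(self) -> float:
        """Total spine-head membrane area (nm^2), used for C_m."""
        side = self.head_diameter * (SQRT2 - 1.0)
        lateral = 8.0 * side * self.head_height
        return lateral + 2.0 * self.octagon_area()

    def cleft_volume(self) -> float:
        """Volume of the cleft column over the PSD square (nm^3)."""
        return self.psd_width ** 2 * self.cleft_width

    def free_volume(self) -> float:
        """Volume of the diffusion domain (box minus both prisms), nm^3."""
        prism = self.octagon_area() * (self.head_height + self.bouton_height)
        return float(np.prod(self.box_size)) - prism

    def params(self) -> np.ndarray:
        g = np.empty(14)
        g[G_A] = self.head_diameter / 2.0
        g[G_C] = self.head_diameter / SQRT2
        g[G_ZS_TOP] = -self.cleft_width / 2.0
        g[G_ZS_BOT] = g[G_ZS_TOP] - self.head_height
        g[G_ZB_BOT] = self.cleft_width / 2.0
        # the bouton prism continues as the axon through (and slightly past)
        # the sleeve extension, so the wrap stays a thin annulus
        axon = (self.sleeve_extension + 200.0 if self.sleeve else 0.0)
        g[G_ZB_TOP] = g[G_ZB_BOT] + self.bouton_height + axon
        g[G_BX] = self.box_size[0] / 2.0
        g[G_BY] = self.box_size[1] / 2.0
        g[G_BZ] = self.box_size[2] / 2.0
        g[G_PSD] = self.psd_width / 2.0
        g[G_SA] = (self.head_diameter / 2.0 + self.sleeve_clearance
                   if self.sleeve else 0.0)
        g[G_SZLO] = g[G_ZS_BOT]
        g[G_SZHI] = (g[G_ZB_BOT] + self.bouton_height
                     + (self.sleeve_extension if self.sleeve else 0.0))
        g[G_ZD_LO] = (g[G_ZS_BOT] - self.dendrite_thickness
                      if self.sleeve and self.dendrite_thickness > 0
                      else g[G_ZS_BOT])
        return g

    def to_dict(self) -> dict:
        return {
            "psd_width": self.psd_width, "cleft_width": self.cleft_width,
            "head_diameter": self.head_diameter,
            "head_height": self.head_height,
            "bouton_height": self.bouton_height,
            "box_size": list(self.box_size),
            "sleeve": self.sleeve,
            "sleeve_clearance": self.sleeve_clearance,
            "sleeve_extension": self.sleeve_extension,
            "dendrite_thickness": self.dendrite_thickness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpineGeometry":
        d = dict(d)
        d["box_size"] = tuple(d.get("box_size", (4000.0, 4000.0, 4000.0)))
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SpineGeometry":
        return cls.from_dict(yaml.safe_load(text))


def build_geometry(config: dict | None = None) -> SpineGeometry:
    """Construct the spine geometry, validating the configured dimensions."""
    return SpineGeometry.from_dict(config or {})


# ---------------------------------------------------------------------------
# numba kernels: containment and specular reflection
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _in_prism(x, y, z, a, c, zlo, zhi):
    ax = abs(x)
    ay = abs(y)
    return (ax < a) and (ay < a) and (ax + ay < c) and (zlo < z < zhi)


@njit(cache=True, fastmath=True)
def inside_domain(x, y, z, g):
    """True when (x, y, z) lies in the extracellular diffusion domain."""
    if abs(x) > g[G_BX] or abs(y) > g[G_BY] or abs(z) > g[G_BZ]:
        return False
    if _in_prism(x, y, z, g[G_A], g[G_C], g[G_ZS_BOT], g[G_ZS_TOP]):
        return False
    if _in_prism(x, y, z, g[G_A], g[G_C], g[G_ZB_BOT], g[G_ZB_TOP]):
        return False
    if g[G_ZD_LO] < g[G_ZS_BOT]:
        sa = g[G_SA]
        if _in_prism(x, y, z, sa, sa * 1.4142135623730951,
                     g[G_ZD_LO], g[G_ZS_BOT]):
            return False
    return True


@njit(cache=True, fastmath=True)
def _prism_entry(p0x, p0y, p0z, dx, dy, dz, a, c, zlo, zhi):
    """Earliest parameter t in (0, 1] at which the segment p0 + t*d enters
    the octagonal prism, with the unit outward normal of the face crossed.
    Returns (t, nx, ny, nz); t = 2.0 when there is no entry."""
    best_t = 2.0
    bnx = bny = bnz = 0.0
    eps = 1e-12
    tol = 1e-9
    s = 0.7071067811865476
    # 10 faces: +x, -x, +y, -y, 4 diagonals, z top, z bottom
    for face in range(10):
        if face == 0:
            nx, ny, nz, d = 1.0, 0.0, 0.0, a
        elif face == 1:
            nx, ny, nz, d = -1.0, 0.0, 0.0, a
        elif face == 2:
            nx, ny, nz, d = 0.0, 1.0, 0.0, a
        elif face == 3:
            nx, ny, nz, d = 0.0, -1.0, 0.0, a
        elif face == 4:
            nx, ny, nz, d = s, s, 0.0, c * s
        elif face == 5:
            nx, ny, nz, d = s, -s, 0.0, c * s
        elif face == 6:
            nx, ny, nz, d = -s, s, 0.0, c * s
        elif face == 7:
            nx, ny, nz, d = -s, -s, 0.0, c * s
        elif face == 8:
            nx, ny, nz, d = 0.0, 0.0, 1.0, zhi
        else:
            nx, ny, nz, d = 0.0, 0.0, -1.0, -zlo
        denom = nx * dx + ny * dy + nz * dz
        if denom >= -eps:
            continue  # not moving inward through this face
        f0 = nx * p0x + ny * p0y + nz * p0z - d
        if f0 < -tol:
            continue  # start already inside this halfspace
        t = -f0 / denom
        if t <= eps or t > 1.0 or t >= best_t:
            continue
        qx = p0x + t * dx
        qy = p0y + t * dy
        qz = p0z + t * dz
        # crossing point must lie within the face bounds
        aq = abs(qx)
        bq = abs(qy)
        if face < 8:
            if not (zlo - tol <= qz <= zhi + tol):
                continue
        if face != 0 and face != 1 and aq > a + tol:
            continue
        if face != 2 and face != 3 and bq > a + tol:
            continue
        if face < 4 or face > 7:
            if aq + bq > c + tol:
                continue
        best_t = t
        bnx, bny, bnz = nx, ny, nz
    return best_t, bnx, bny, bnz


@njit(cache=True, fastmath=True)
def _oct_metric(x, y):
    """Octagon gauge: level set m = a is the regular octagon of half
    across-flats a."""
    ax = abs(x)
    ay = abs(y)
    m = ax if ax > ay else ay
    d = (ax + ay) * 0.7071067811865476
    return m if m > d else d


@njit(cache=True, fastmath=True)
def _sleeve_cross(p0x, p0y, p0z, dx, dy, dz, a_s, zlo, zhi):
    """Earliest crossing of the two-sided neuropil sleeve (octagonal tube of
    half across-flats a_s between zlo and zhi, open ends).  Returns
    (t, nx, ny, nz) with the mirror normal oriented toward the start side;
    t = 2.0 when there is no crossing."""
    best_t = 2.0
    bnx = bny = bnz = 0.0
    eps = 1e-12
    tol = 1e-9
    s = 0.7071067811865476
    c_s = a_s * 1.4142135623730951
    for face in range(8):
        if face == 0:
            nx, ny, d = 1.0, 0.0, a_s
        elif face == 1:
            nx, ny, d = -1.0, 0.0, a_s
        elif face == 2:
            nx, ny, d = 0.0, 1.0, a_s
        elif face == 3:
            nx, ny, d = 0.0, -1.0, a_s
        elif face == 4:
            nx, ny, d = s, s, c_s * s
        elif face == 5:
            nx, ny, d = s, -s, c_s * s
        elif face == 6:
            nx, ny, d = -s, s, c_s * s
        else:
            nx, ny, d = -s, -s, c_s * s
        f0 = nx * p0x + ny * p0y - d
        denom = nx * dx + ny * dy
        if abs(denom) < eps:
            continue
        f1 = f0 + denom
        if f0 * f1 >= 0.0:
            continue  # no sign change: plane not crossed
        t = -f0 / denom
        if t <= eps or t > 1.0 or t >= best_t:
            continue
        qx = p0x + t * dx
        qy = p0y + t * dy
        qz = p0z + t * dz
        if not (zlo - tol <= qz <= zhi + tol):
            continue
        aq = abs(qx)
        bq = abs(qy)
        if face > 1 and aq > a_s + tol:
            continue
        if (face == 0 or face == 1 or face > 3) and bq > a_s + tol:
            continue
        if face < 4 and aq + bq > c_s + tol:
            continue
        best_t = t
        # orient the normal toward the starting side for the nudge
        if f0 > 0.0:
            bnx, bny, bnz = nx, ny, 0.0
        else:
            bnx, bny, bnz = -nx, -ny, 0.0
    return best_t, bnx, bny, bnz


@njit(cache=True, fastmath=True)
def reflect_kernel(p0x, p0y, p0z, p1x, p1y, p1z, g):
    """Specular reflection of the segment p0 -> p1 off every crossed surface
    (outer box, both prisms, the two-sided neuropil sleeve), applied
    recursively until no surface is crossed.  After 12 reflections the step
    is truncated at the last valid surface point (nudged off the wall)."""
    for _ in range(12):
        dx = p1x - p0x
        dy = p1y - p0y
        dz = p1z - p0z
        best_t = 2.0
        bnx = bny = bnz = 0.0
        # outer box faces (domain is inside the box)
        if p1x > g[G_BX] and dx > 0.0:
            t = (g[G_BX] - p0x) / dx
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, 1.0, 0.0, 0.0
        if p1x < -g[G_BX] and dx < 0.0:
            t = (-g[G_BX] - p0x) / dx
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, -1.0, 0.0, 0.0
        if p1y > g[G_BY] and dy > 0.0:
            t = (g[G_BY] - p0y) / dy
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, 0.0, 1.0, 0.0
        if p1y < -g[G_BY] and dy < 0.0:
            t = (-g[G_BY] - p0y) / dy
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, 0.0, -1.0, 0.0
        if p1z > g[G_BZ] and dz > 0.0:
            t = (g[G_BZ] - p0z) / dz
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, 0.0, 0.0, 1.0
        if p1z < -g[G_BZ] and dz < 0.0:
            t = (-g[G_BZ] - p0z) / dz
            if 0.0 < t < best_t:
                best_t, bnx, bny, bnz = t, 0.0, 0.0, -1.0
        # spine head prism
        t, nx, ny, nz = _prism_entry(p0x, p0y, p0z, dx, dy, dz,
                                     g[G_A], g[G_C], g[G_ZS_BOT], g[G_ZS_TOP])
        if t < best_t:
            best_t, bnx, bny, bnz = t, nx, ny, nz
        # bouton prism
        t, nx, ny, nz = _prism_entry(p0x, p0y, p0z, dx, dy, dz,
                                     g[G_A], g[G_C], g[G_ZB_BOT], g[G_ZB_TOP])
        if t < best_t:
            best_t, bnx, bny, bnz = t, nx, ny, nz
        # dendritic shaft slab under the spine (closes the sleeve bottom)
        if g[G_ZD_LO] < g[G_ZS_BOT]:
            sa = g[G_SA]
            t, nx, ny, nz = _prism_entry(p0x, p0y, p0z, dx, dy, dz,
                                         sa, sa * 1.4142135623730951,
                                         g[G_ZD_LO], g[G_ZS_BOT])
            if t < best_t:
                best_t, bnx, bny, bnz = t, nx, ny, nz
        # neuropil sleeve (two-sided membrane)
        if g[G_SA] > 0.0:
            t, nx, ny, nz = _sleeve_cross(p0x, p0y, p0z, dx, dy, dz,
                                          g[G_SA], g[G_SZLO], g[G_SZHI])
            if t < best_t:
                best_t, bnx, bny, bnz = t, nx, ny, nz
        if best_t > 1.0:
            if inside_domain(p1x, p1y, p1z, g):
                return p1x, p1y, p1z
            # no crossing found (degenerate corner): truncate the step
            return p0x, p0y, p0z
        qx = p0x + best_t * dx
        qy = p0y + best_t * dy
        qz = p0z + best_t * dz
        # mirror the endpoint across the crossed plane
        dot = (p1x - qx) * bnx + (p1y - qy) * bny + (p1z - qz) * bnz
        p1x -= 2.0 * dot * bnx
        p1y -= 2.0 * dot * bny
        p1z -= 2.0 * dot * bnz
        # continue from the crossing point, nudged off the surface
        p0x = qx + 1e-9 * bnx
        p0y = qy + 1e-9 * bny
        p0z = qz + 1e-9 * bnz
    if inside_domain(p1x, p1y, p1z, g):
        return p1x, p1y, p1z
    return p0x, p0y, p0z


@njit(cache=True, fastmath=True)
def move_with_reflection(x, y, z, nx, ny, nz, step, g):
    """Advance a particle from (x, y, z) toward the proposed endpoint,
    applying reflections only when a surface may have been crossed.

    Fast paths: (1) endpoint inside the domain and the segment provably on
    one side of the sleeve (its interior is convex, so equal-side endpoints
    inside it cannot cross; outside-side chords clipping a corner are rare
    and tolerated); (2) outer-wall-only violations far from every interior
    structure are resolved by exact coordinate folding.  ``step`` is the
    per-axis SD of the proposed displacement, used to bound how far the
    folded endpoint can sit from the start."""
    if inside_domain(nx, ny, nz, g):
        a_s = g[G_SA]
        if a_s <= 0.0:
            return nx, ny, nz
        zlo = g[G_SZLO]
        zhi = g[G_SZHI]
        if (z > zhi and nz > zhi) or (z < zlo and nz < zlo):
            return nx, ny, nz
        m0 = _oct_metric(x, y)
        m1 = _oct_metric(nx, ny)
        if (m0 - a_s) * (m1 - a_s) > 0.0:
            return nx, ny, nz
        return reflect_kernel(x, y, z, nx, ny, nz, g)
    # endpoint outside: if the whole excursion provably stays clear of the
    # interior structures, fold against the box planes (exact for planar
    # walls) instead of running the full surface scan
    reach = 8.0 * step
    sx = g[G_SA] if g[G_SA] > 0.0 else g[G_A]
    clear = (abs(x) - sx > reach or abs(y) - sx > reach
             or z - g[G_SZHI] > reach or g[G_ZD_LO] - z > reach)
    if g[G_SA] <= 0.0:
        clear = (abs(x) - g[G_A] > reach or abs(y) - g[G_A] > reach
                 or z - g[G_ZB_TOP] > reach or g[G_ZS_BOT] - z > reach)
    if clear:
        bx = g[G_BX]
        by = g[G_BY]
        bz = g[G_BZ]
        for _ in range(4):
            if nx > bx:
                nx = 2.0 * bx - nx
            elif nx < -bx:
                nx = -2.0 * bx - nx
            if ny > by:
                ny = 2.0 * by - ny
            elif ny < -by:
                ny = -2.0 * by - ny
            if nz > bz:
                nz = 2.0 * bz - nz
            elif nz < -bz:
                nz = -2.0 * bz - nz
            if -bx <= nx <= bx and -by <= ny <= by and -bz <= nz <= bz:
                break
        if inside_domain(nx, ny, nz, g):
            return nx, ny, nz
    return reflect_kernel(x, y, z, nx, ny, nz, g)


def reflect(position: np.ndarray, proposed_position: np.ndarray,
            geometry: SpineGeometry) -> np.ndarray:
    """Reflect a proposed Brownian displacement off all crossed surfaces."""
    g = geometry.params()
    p0 = np.asarray(position, dtype=float)
    if not inside_domain(p0[0], p0[1], p0[2], g):
        raise ValueError("start position must lie inside the diffusion domain")
    p1 = np.asarray(proposed_position, dtype=float)
    out = reflect_kernel(p0[0], p0[1], p0[2], p1[0], p1[1], p1[2], g)
    return np.array(out)


# ---------------------------------------------------------------------------
# receptor placement
# ---------------------------------------------------------------------------

@dataclass
class ReceptorLayout:
    """Receptor positions, outward surface normals and population labels.

    Populations separate subtype x region, e.g. 10 extrasynaptic NR2B
    receptors form their own population next to 4 synaptic NR2B.
    """

    positions: np.ndarray          # (M, 3) nm
    normals: np.ndarray            # (M, 3) outward unit normals
    subtypes: list[str]            # per receptor
    regions: list[str]             # "synaptic" | "extrasynaptic"
    populations: list[str]         # e.g. "AMPAR", "NR2B_extrasyn"

    @property
    def n_receptors(self) -> int:
        return len(self.subtypes)

    def population_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen


#: Default synaptic composition: 80 AMPARs + 20 NMDARs on the PSD.
DEFAULT_COMPOSITION = {"AMPAR": 80, "NR2A": 20}

#: Mixed synapse reflecting reported PSD subtype content, plus the
#: extrasynaptic NR2B pool on the spine-head sides.
MIXED_COMPOSITION = {"AMPAR": 80, "NR2A": 8, "NR2A_NR2B": 8, "NR2B": 4}
EXTRASYNAPTIC_DEFAULT = {"NR2B": 10}

MIN_SPACING = 10.0  # nm, centre-to-centre


def place_receptors(geometry: SpineGeometry,
                    composition: dict[str, int],
                    rng: np.random.Generator,
                    extrasynaptic: dict[str, int] | None = None,
                    min_spacing: float = MIN_SPACING) -> ReceptorLayout:
    """Scatter receptors uniformly on their surfaces.

    Synaptic receptors are uniform on the PSD square, extrasynaptic ones
    uniform over the eight side faces of the spine head.  A minimum
    centre-to-centre spacing is enforced by rejection so that binding radii
    do not overlap.
    """
    extrasynaptic = extrasynaptic or {}
    for d in (composition, extrasynaptic):
        for k, v in d.items():
            if k not in SUBTYPES:
                raise ValueError(f"unknown subtype {k!r}")
            if v < 0:
                raise ValueError("receptor counts must be >= 0")
    n_syn = sum(composition.values())
    if n_syn * min_spacing ** 2 > 0.7 * geometry.psd_area:
        raise ValueError("synaptic receptor count exceeds PSD packing capacity")

    half = geometry.psd_width / 2.0
    z_psd = -geometry.cleft_width / 2.0
    pos: list[np.ndarray] = []
    nrm: list[np.ndarray] = []
    subtypes: list[str] = []
    regions: list[str] = []
    pops: list[str] = []

    def _place_syn() -> np.ndarray:
        for _ in range(10_000):
            p = np.array([rng.uniform(-half, half),
                          rng.uniform(-half, half), z_psd])
            if all(np.sum((p - q) ** 2) >= min_spacing ** 2 for q in pos):
                return p
        raise RuntimeError("could not satisfy receptor spacing on the PSD")

    for subtype in sorted(composition):
        for _ in range(composition[subtype]):
            pos.append(_place_syn())
            nrm.append(np.array([0.0, 0.0, 1.0]))  # into the cleft
            subtypes.append(subtype)
            regions.append("synaptic")
            pops.append(subtype)

    # spine-head side faces: 4 axis-aligned + 4 diagonal rectangles
    a = geometry.head_diameter / 2.0
    c = geometry.head_diameter / SQRT2
    hw = c - a  # face half-width
    z_lo = z_psd - geometry.head_height
    face_normals = [np.array(v) for v in
                    [(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0),
                     (0.0, 1.0, 0.0), (0.0, -1.0, 0.0),
                     (1 / SQRT2, 1 / SQRT2, 0.0), (1 / SQRT2, -1 / SQRT2, 0.0),
                     (-1 / SQRT2, 1 / SQRT2, 0.0), (-1 / SQRT2, -1 / SQRT2, 0.0)]]
    face_centers = [np.array(v) for v in
                    [(a, 0.0, 0.0), (-a, 0.0, 0.0), (0.0, a, 0.0), (0.0, -a, 0.0),
                     (c / 2, c / 2, 0.0), (c / 2, -c / 2, 0.0),
                     (-c / 2, c / 2, 0.0), (-c / 2, -c / 2, 0.0)]]

    def _place_ext() -> tuple[np.ndarray, np.ndarray]:
        for _ in range(10_000):
            f = int(rng.integers(8))
            n = face_normals[f]
            tangent = np.array([-n[1], n[0], 0.0])
            u = rng.uniform(-hw, hw)
            z = rng.uniform(z_lo, z_psd)
            p = face_centers[f] + u * tangent
            p[2] = z
            if all(np.sum((p - q) ** 2) >= min_spacing ** 2 for q in pos):
                return p, n
        raise RuntimeError("could not satisfy receptor spacing on the sides")

    for subtype in sorted(extrasynaptic):
        for _ in range(extrasynaptic[subtype]):
            p, n = _place_ext()
            pos.append(p)
            nrm.append(n)
            subtypes.append(subtype)
            regions.append("extrasynaptic")
            pops.append(subtype + "_extrasyn")

    m = len(pos)
    return ReceptorLayout(
        positions=np.array(pos).reshape(m, 3),
        normals=np.array(nrm).reshape(m, 3),
        subtypes=subtypes, regions=regions, populations=pops,
    )
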