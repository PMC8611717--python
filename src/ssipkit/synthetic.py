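"""Synthetic fixtures: analytic volumetric grids, a water-like surface
sample, random SSIP sets, and the two-phase tsv worked example.

Every generator is deterministic under its seed and has a closed-form
oracle:

* Gaussian density  rho(r) = sum_k A_k exp(-|r - c_k|^2 / sigma_k^2)
  — a single unit-amplitude, unit-sigma blob crosses level L on the
  sphere of radius sqrt(ln(A/L)) bohr (2.4929 bohr for L = 0.002).
* Point-charge potential  V(r) = sum_k q_k / max(|r - c_k|, 0.1)
  in hartree/e with geometry in bohr; the 0.1 bohr softening keeps grid
  nodes finite, and any node inside it is excluded from oracle checks.
* The water-like surface sample is a uniform spherical point cloud
  (area 37.4 A^2, i.e. four default SSIP footprints) carrying two
  strong positive MEPS lobes (donor hydrogens) and two strong negative
  lobes (acceptor lone pairs) in a tetrahedral arrangement.

These stand in for DFT-quality densities and potentials; they exercise
the geometry, interpolation and coarse-graining machinery, not quantum
chemistry.
"""

from __future__ import annotations

import numpy as np

from .footprint import SSIP, SSIPSet, FootprintConfig, DEFAULT_SSIP_AREA
from .formats import PhaseSpec, VolumetricGrid
from .surface import SurfaceSample

__all__ = [
    "make_gaussian_cubes",
    "make_water_like_sample",
    "make_random_ssip_set",
    "make_ethanol_like_ssip_set",
    "write_example_phase_tsv",
    "write_example_library",
    "WATER_MOLAR_VOLUME",
    "ETHANOL_MOLAR_VOLUME",
]

#: molar volumes in L/mol
WATER_MOLAR_VOLUME = 0.01807
ETHANOL_MOLAR_VOLUME = 0.05847

SOFTENING_RADIUS = 0.1  # bohr; point-charge potentials are capped inside this


def make_gaussian_cubes(centers, amplitudes, charges,
                        extent: float = 5.0, n: int = 48,
                        sigmas=None) -> tuple[VolumetricGrid, VolumetricGrid]:
    """Analytic density + ESP cube pair on a cubic grid.

    ``centers`` are (k, 3) positions in bohr; the grid spans
    ``[-extent, extent]`` bohr with ``n`` points per axis.  Density is a
    sum of Gaussians (e bohr^-3), the potential a sum of softened point
    charges (hartree/e).  Atom records (Z=1, the given nuclear charge)
    are attached at the centers.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if len(centers) < 1:
        raise ValueError("at least one center is required")
    if extent <= 0 or n < 2:
        raise ValueError("grid extent must be positive with at least 2 points")
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float),
                                 (len(centers),))
    charges = np.broadcast_to(np.asarray(charges, dtype=float), (len(centers),))
    if sigmas is None:
        sigmas = 1.0
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (len(centers),))

    axis = np.linspace(-extent, extent, n)
    step = axis[1] - axis[0]
    xs, ys, zs = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([xs, ys, zs], axis=-1)

    density = np.zeros((n, n, n))
    esp = np.zeros((n, n, n))
    for c, a, q, s in zip(centers, amplitudes, charges, sigmas):
        r2 = np.sum((pts - c) ** 2, axis=-1)
        density += a * np.exp(-r2 / s ** 2)
        r = np.sqrt(r2)
        esp += q / np.maximum(r, SOFTENING_RADIUS)

    origin = np.array([-extent, -extent, -extent])
    axes = np.eye(3) * step
    atoms = [(1, float(q), np.asarray(c, dtype=float))
             for c, q in zip(centers, charges)]
    return (VolumetricGrid(origin, axes, density, list(atoms)),
            VolumetricGrid(origin, axes, esp, list(atoms)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere point cloud (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# tetrahedral lobe directions: two donor hydrogens, two acceptor lone pairs
_DONOR_DIRS = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0]]) / np.sqrt(3.0)
_ACCEPTOR_DIRS = np.array([[-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


def make_water_like_sample(total_area: float = 4 * DEFAULT_SSIP_AREA,
                           n_points: int = 2000,
                           donor_meps: float = 130.0,
                           acceptor_meps: float = -150.0,
                           lobe_width: float = 0.7) -> SurfaceSample:
    """Spherical surface sample emulating water's four-site polar pattern.

    Two strong positive MEPS lobes and two strong negative lobes sit at
    tetrahedral directions on a sphere whose area (default 37.4 A^2 =
    four default footprints) makes the equal-area rule yield four SSIPs.
    ``lobe_width`` is the angular Gaussian width in radians.
    """
    if total_area <= 0 or n_points < 4:
        raise ValueError("need a positive area and at least 4 points")
    radius = np.sqrt(total_area / (4.0 * np.pi))
    unit = _fibonacci_sphere(n_points)
    points = unit * radius
    areas = np.full(n_points, total_area / n_points)

    meps = np.zeros(n_points)
    for d in _DONOR_DIRS:
        ang = np.arccos(np.clip(unit @ d, -1.0, 1.0))
        meps += donor_meps * np.exp(-(ang / lobe_width) ** 2)
    for d in _ACCEPTOR_DIRS:
        ang = np.arccos(np.clip(unit @ d, -1.0, 1.0))
        meps += acceptor_meps * np.exp(-(ang / lobe_width) ** 2)

    return SurfaceSample(points=points, areas=areas, meps=meps,
                         total_area=float(areas.sum()), iso_level=0.002)


def make_random_ssip_set(n: int, eps_range=(-5.0, 5.0), seed: int = 0) -> SSIPSet:
    """Random SSIP set: positions on a sphere, epsilons uniform in ``eps_range``."""
    rng = np.random.default_rng(seed)
    lo, hi = eps_range
    ssips = []
    for _ in range(n):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        eps = float(rng.uniform(lo, hi))
        ssips.append(SSIP(position=v * 1.5, epsilon=eps,
                          footprint_area=DEFAULT_SSIP_AREA, source_meps=eps / 0.03))
    return SSIPSet(ssips=ssips, molecule_title=f"random-{n}",
                   total_surface_area=n * DEFAULT_SSIP_AREA,
                   parameters=FootprintConfig(), validate=False)


def make_ethanol_like_ssip_set() -> SSIPSet:
    """Synthetic ethanol-like SSIP set (hand-written plausible stand-in).

    14 sites for a ~131 A^2 surface: one hydroxyl donor, one strong
    oxygen acceptor, and twelve weak alkyl sites.  The values are a
    synthetic stand-in with hydrogen-bond-parameter magnitudes, not the
    published solvent description.
    """
    epsilons = [2.7, -4.8] + [0.4, 0.3, 0.3, 0.2, -0.3, -0.3] + [0.2, -0.2] * 3
    n = len(epsilons)
    unit = _fibonacci_sphere(n)
    radius = np.sqrt(n * DEFAULT_SSIP_AREA / (4 * np.pi))
    ssips = [SSIP(position=unit[i] * radius, epsilon=float(e),
                  footprint_area=DEFAULT_SSIP_AREA, source_meps=float(e) / 0.03)
             for i, e in enumerate(epsilons)]
    return SSIPSet(ssips=ssips, molecule_title="ethanol-like (synthetic)",
                   total_surface_area=n * DEFAULT_SSIP_AREA,
                   parameters=FootprintConfig())


def write_example_phase_tsv(path) -> None:
    """Write the canonical two-phase example file.

    Line 1: pure water at 298 K.  Line 2: water 0.75 / ethanol 0.25 at
    298 K.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("298\twater\t1.0\n")
        fh.write("298\twater\t0.75\tethanol\t0.25\n")


def example_phase_specs() -> list[PhaseSpec]:
    """The two-phase example as in-memory specs (same content as the tsv)."""
    return [
        PhaseSpec(298.0, [("water", 1.0)]),
        PhaseSpec(298.0, [("water", 0.75), ("ethanol", 0.25)]),
    ]


def write_example_library(directory) -> None:
    """Write a small solvent library: water-like + ethanol-like components.

    The water description is produced by footprinting the water-like
    surface sample; ethanol is the synthetic stand-in set.  Layout:
    ``components.tsv`` (name, molar volume in L/mol, xml file) plus one
    SSIP XML file per component.
    """
    import os

    from .footprint import footprint
    from .formats import write_ssip_xml

    os.makedirs(directory, exist_ok=True)
    water = footprint(make_water_like_sample(), molecule_title="water-like")
    ethanol = make_ethanol_like_ssip_set()
    write_ssip_xml(water, None, os.path.join(directory, "water.ssip.xml"))
    write_ssip_xml(ethanol, None, os.path.join(directory, "ethanol.ssip.xml"))
    with open(os.path.join(directory, "components.tsv"), "w",
              encoding="utf-8") as fh:
        fh.write(f"water\t{WATER_MOLAR_VOLUME}\twater.ssip.xml\n")
        fh.write(f"ethanol\t{ETHANOL_MOLAR_VOLUME}\tethanol.ssip.xml\n")
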