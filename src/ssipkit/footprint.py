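"""Coarse-graining of a MEPS sample into equal-area surface site
interaction points (SSIPs).

A molecule's van der Waals surface is partitioned into patches of equal
footprint area (default 9.35 A^2, so that a water-sized surface of
~37.4 A^2 yields exactly four SSIPs).  Each patch contributes one SSIP,
placed at the patch's extremal-|MEPS| point, with a signed interaction
parameter epsilon obtained from the MEPS value through a calibration
curve.  Positive epsilon plays the role of the hydrogen-bond donor
parameter (alpha), negative epsilon of the acceptor parameter (-beta);
epsilon^2 has units of molar energy, so epsilon carries (kJ/mol)^(1/2).

The patching policy is greedy accretion: the number of SSIPs is split
between the positive-MEPS and negative-MEPS point classes in proportion
to their areas (largest-remainder rounding), then each patch claims the
unclaimed point of largest |MEPS| in its class and accretes the nearest
unclaimed in-class points until it reaches its area target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import SurfaceSample

__all__ = [
    "SSIP",
    "SSIPSet",
    "FootprintConfig",
    "CalibrationCurve",
    "ssip_count",
    "partition_surface",
    "calibrate_epsilon",
    "footprint",
]

DEFAULT_SSIP_AREA = 9.35  # A^2; water-sized surface (~37.4 A^2) -> 4 SSIPs
DEFAULT_CALIBRATION_SLOPE = 0.03  # (kJ/mol)^(1/2) per kJ/mol


@dataclass
class CalibrationCurve:
    """Maps a MEPS value (kJ/mol) to a signed epsilon ((kJ/mol)^(1/2)).

    Separate polynomial branches for positive and negative potentials,
    given as coefficient sequences in :func:`numpy.polyval` order (highest
    power first, zero constant term so that 0 maps to 0).  The default is
    linear on both branches; the quadratic fits of the original
    coarse-graining calibration can be supplied instead.
    """

    positive: tuple = (DEFAULT_CALIBRATION_SLOPE, 0.0)
    negative: tuple = (DEFAULT_CALIBRATION_SLOPE, 0.0)

    def __post_init__(self):
        for name, coeffs in (("positive", self.positive),
                             ("negative", self.negative)):
            if coeffs and coeffs[-1] != 0.0:
                raise ValueError(
                    f"{name} branch must map 0 -> 0 (zero constant term)")

    def __call__(self, meps):
        return calibrate_epsilon(meps, self)


@dataclass
class FootprintConfig:
    """Tunable parameters of the footprinting step."""

    ssip_area: float = DEFAULT_SSIP_AREA  # A^2 per SSIP
    iso_level: float = 0.002  # e bohr^-3
    calibration: CalibrationCurve = field(default_factory=CalibrationCurve)

    def __post_init__(self):
        if not self.ssip_area > 0:
            raise ValueError(f"ssip_area must be positive, got {self.ssip_area}")


@dataclass
class SSIP:
    """One surface site: position (angstrom), signed epsilon, footprint area."""

    position: np.ndarray
    epsilon: float
    footprint_area: float
    source_meps: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class SSIPSet:
    """A molecule's discrete interaction sites plus bookkeeping.

    Invariants (checked unless ``validate=False`` for I/O round trips):
    footprint areas sum to the total surface area within 1%, and the SSIP
    count follows the equal-area rule.
    """

    ssips: list
    molecule_title: str = ""
    total_surface_area: float = 0.0
    parameters: FootprintConfig = field(default_factory=FootprintConfig)
    validate: bool = True

    def __post_init__(self):
        if self.validate and self.ssips:
            area = sum(s.footprint_area for s in self.ssips)
            if abs(area - self.total_surface_area) > 0.01 * self.total_surface_area:
                raise ValueError(
                    f"footprint areas sum to {area:.4f}, expected "
                    f"{self.total_surface_area:.4f} within 1%")
            expected = ssip_count(self.total_surface_area,
                                  self.parameters.ssip_area)
            if len(self.ssips) != expected:
                raise ValueError(
                    f"{len(self.ssips)} SSIPs but the equal-area rule gives "
                    f"{expected}")

    def __len__(self) -> int:
        return len(self.ssips)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([s.epsilon for s in self.ssips])

    @property
    def positions(self) -> np.ndarray:
        if not self.ssips:
            return np.empty((0, 3))
        return np.stack([s.position for s in self.ssips])


def ssip_count(total_area: float, ssip_area: float = DEFAULT_SSIP_AREA) -> int:
    """Number of equal-area SSIPs for a surface: max(1, round(total/area)).

    Half-integers round to even (banker's rounding); any positive surface
    gets at least one SSIP.
    """
    if not (total_area > 0 and ssip_area > 0):
        raise ValueError("total_area and ssip_area must be positive")
    return max(1, round(total_area / ssip_area))


def calibrate_epsilon(meps, curve: CalibrationCurve | None = None):
    """Convert MEPS values (kJ/mol) to signed epsilon via the branch polynomials.

    Positive branch for V > 0, negative branch for V < 0, exactly 0 at 0.
    Scalar in, scalar out; array in, array out.
    """
    if curve is None:
        curve = CalibrationCurve()
    v = np.asarray(meps, dtype=float)
    out = np.where(v > 0, np.polyval(curve.positive, v),
                   np.where(v < 0, np.polyval(curve.negative, v), 0.0))
    if np.isscalar(meps) or v.ndim == 0:
        return float(out)
    return out


def _largest_remainder_split(n: int, weights: np.ndarray) -> np.ndarray:
    """Split integer ``n`` proportionally to ``weights`` (largest remainder)."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    exact = n * weights / total
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    # distribute the shortfall by descending fractional remainder;
    # ties go to the lower index for determinism
    order = np.lexsort((np.arange(len(weights)), -(exact - base)))
    for i in order[:short]:
        base[i] += 1
    return base


def partition_surface(sample: SurfaceSample,
                      config: FootprintConfig | None = None) -> list[dict]:
    """Partition a surface sample into equal-area patches by greedy accretion.

    Returns one record per patch with keys ``extremum`` (point index),
    ``members`` (point index array), ``area`` and ``sign`` (+1 for the
    positive-MEPS class, -1 for negative).  Patches are disjoint and
    together cover every sample point.
    """
    if config is None:
        config = FootprintConfig()
    n_points = len(sample)
    if n_points == 0:
        raise ValueError("empty surface sample")
    n = ssip_count(sample.total_area, config.ssip_area)
    if n > n_points:
        raise ValueError(
            f"{n} SSIPs requested but only {n_points} surface points; "
            "use a finer grid")

    meps = sample.meps
    areas = sample.areas
    pts = sample.points
    pos_mask = meps >= 0.0
    class_masks = {1: pos_mask, -1: ~pos_mask}
    class_areas = np.array([areas[pos_mask].sum(), areas[~pos_mask].sum()])
    quotas = dict(zip((1, -1), _largest_remainder_split(n, np.maximum(class_areas, 0))))

    for sign, quota in quotas.items():
        n_class = int(np.count_nonzero(class_masks[sign]))
        if quota > n_class:
            raise ValueError(
                f"sign class {sign:+d} needs {quota} patches but has only "
                f"{n_class} points; use a finer grid")

    # deterministic extremum selection: max |MEPS|, ties by (x, y, z)
    order_key = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], -np.abs(meps)))
    rank = np.empty(n_points, dtype=np.intp)
    rank[order_key] = np.arange(n_points)

    claimed = np.zeros(n_points, dtype=bool)
    patches = []
    for sign in (1, -1):
        quota = quotas[sign]
        if quota == 0:
            continue
        class_idx = np.flatnonzero(class_masks[sign])
        target = areas[class_idx].sum() / quota
        for p in range(quota):
            avail = class_idx[~claimed[class_idx]]
            seed = avail[np.argmin(rank[avail])]
            if p == quota - 1:
                members = avail  # last patch takes the class remainder
            else:
                d = np.linalg.norm(pts[avail] - pts[seed], axis=1)
                nearest = avail[np.argsort(d, kind="stable")]
                cum = np.cumsum(areas[nearest])
                k = int(np.searchsorted(cum, target) + 1)
                # leave at least one point per remaining patch of this class
                k = max(1, min(k, len(avail) - (quota - 1 - p)))
                members = nearest[:k]
            claimed[members] = True
            patches.append({
                "extremum": int(seed),
                "members": members,
                "area": float(areas[members].sum()),
                "sign": sign,
            })
    return patches


def footprint(sample: SurfaceSample,
              config: FootprintConfig | None = None,
              molecule_title: str = "") -> SSIPSet:
    """Coarse-grain a surface sample into an :class:`SSIPSet`.

    One SSIP per patch, positioned at the patch's extremal-|MEPS| point,
    with epsilon calibrated from that point's MEPS value.
    """
    if config is None:
        config = FootprintConfig()
    patches = partition_surface(sample, config)
    ssips = []
    for patch in patches:
        i = patch["extremum"]
        v = float(sample.meps[i])
        ssips.append(SSIP(position=sample.points[i],
                          epsilon=calibrate_epsilon(v, config.calibration),
                          footprint_area=patch["area"],
                          source_meps=v))
    return SSIPSet(ssips=ssips, molecule_title=molecule_title,
                   total_surface_area=float(sample.total_area),
                   parameters=config)
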