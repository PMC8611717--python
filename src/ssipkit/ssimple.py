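"""The SSIMPLE equilibrium engine.

A liquid (or gas) phase is a population of SSIPs, each present at a
concentration normalised by the maximum theoretical SSIP density
c_max = 300 M (the standard state that makes every association constant
dimensionless; c_max follows from the 5 A^3 reference volume per SSIP).
All sites interact pairwise 1:1.  The association constant between
sites i and j is

    K_ij = exp(-(E_vdW + min(eps_i * eps_j, 0)) / RT)

with E_vdW = -5.6 kJ/mol the constant van der Waals contact energy
(constant because all SSIPs share the same surface footprint area, and
van der Waals energies are approximately linear in surface area).  The
polar term eps_i*eps_j only contributes when the signs are opposite:
for like signs the sites are assumed to misalign and make a purely
van der Waals contact, so the polar term is set to zero.

Speciation — the split of each site population theta_i into free sites
f_i and pairwise contacts — satisfies the mass balance

    theta_i = f_i * (1 + sum_j K_ij f_j)

solved by damped fixed-point iteration.  Unoccupied volume (the void
fraction theta_E = 1 - sum theta) is an inert reference: it does not
enter the speciation solver and pairs with probe sites at K = 1, which
pins the solvation free energy of any probe in vacuum at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import GAS_CONSTANT

__all__ = [
    "ModelConstants",
    "PhaseComponent",
    "PhaseState",
    "ConvergenceError",
    "association_constant",
    "association_matrix",
    "make_phase_state",
    "build_phase_state",
    "solve_speciation",
    "contact_matrix",
    "solvation_energy",
    "transfer_energy",
    "load_solvent_library",
]


class ConvergenceError(RuntimeError):
    """Speciation solver failed to converge; carries the residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass(frozen=True)
class ModelConstants:
    """Operating constants of the model.

    e_vdw : van der Waals contact energy between two SSIPs, kJ/mol.
    c_max : maximum theoretical SSIP density, mol/L — the standard state.
    v_ssip : reference volume per SSIP, A^3 (documentation; c_max derives
        from it via the four-SSIP water molecule).
    R : gas constant, kJ/(mol K).
    """

    e_vdw: float = -5.6
    c_max: float = 300.0
    v_ssip: float = 5.0
    R: float = GAS_CONSTANT

    def __post_init__(self):
        if not self.c_max > 0:
            raise ValueError("c_max must be positive")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass
class PhaseComponent:
    """One solvent component: its SSIP description and molar volume (L/mol)."""

    name: str
    epsilons: np.ndarray
    molar_volume: float
    mole_fraction: float = 1.0

    def __post_init__(self):
        self.epsilons = np.asarray(self.epsilons, dtype=float).reshape(-1)
        if not self.molar_volume > 0:
            raise ValueError(f"molar volume of {self.name!r} must be positive")


@dataclass
class PhaseState:
    """A solvent phase at temperature T, before or after speciation.

    theta holds per-site normalised concentrations (c / c_max); theta_e is
    the void fraction 1 - sum(theta); K is the symmetric dimensionless
    association matrix; f the solved free fractions (None until solved).
    """

    temperature: float
    epsilons: np.ndarray
    theta: np.ndarray
    K: np.ndarray
    constants: ModelConstants = DEFAULT_CONSTANTS
    description: str = ""
    f: np.ndarray | None = None
    converged: bool = False
    iterations: int = 0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.epsilons = np.asarray(self.epsilons, dtype=float).reshape(-1)
        self.theta = np.asarray(self.theta, dtype=float).reshape(-1)
        if len(self.epsilons) != len(self.theta):
            raise ValueError("epsilons and theta must have equal length")
        if np.any(self.theta < 0):
            raise ValueError("theta values must be non-negative")

    @property
    def theta_e(self) -> float:
        """Void fraction: unoccupied volume under the c_max packing reference."""
        return 1.0 - float(self.theta.sum())

    @property
    def n_species(self) -> int:
        return len(self.theta)


def association_constant(eps_i: float, eps_j: float, temperature: float,
                         constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Dimensionless association constant between two SSIPs.

    K = exp(-(E_vdW + min(eps_i*eps_j, 0)) / RT): the polar term only
    contributes for opposite-sign (attractive) pairs.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    polar = min(eps_i * eps_j, 0.0)
    dg = constants.e_vdw + polar
    return float(np.exp(-dg / (constants.R * temperature)))


def association_matrix(epsilons: np.ndarray, temperature: float,
                       constants: ModelConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Symmetric matrix of association constants for a set of epsilons."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    eps = np.asarray(epsilons, dtype=float)
    polar = np.minimum(np.outer(eps, eps), 0.0)
    return np.exp(-(constants.e_vdw + polar) / (constants.R * temperature))


def build_phase_state(spec, library: dict,
                      constants: ModelConstants = DEFAULT_CONSTANTS) -> PhaseState:
    """Assemble a :class:`PhaseState` from a phase spec and a solvent library.

    ``library`` maps component names to ``(epsilons, molar_volume)`` (the
    epsilons may come from an SSIPSet via ``.epsilons``).  The mixture
    molarity is the ideal-mixing value ``c_mix = 1 / sum_k x_k V_mk``;
    every SSIP of component k enters at theta = x_k * c_mix / c_max.
    """
    missing = [name for name, _ in spec.components if name not in library]
    if missing:
        raise KeyError(f"unknown component(s) {missing}; "
                       f"library has {sorted(library)}")
    mean_volume = 0.0
    for name, x in spec.components:
        _eps, vm = _component_entry(library[name])
        if not vm > 0:
            raise ValueError(f"molar volume of {name!r} must be positive")
        mean_volume += x * vm
    c_mix = 1.0 / mean_volume  # mol/L of mixture "molecules"

    eps_all, theta_all, labels = [], [], []
    for name, x in spec.components:
        eps, _vm = _component_entry(library[name])
        eps = np.asarray(eps, dtype=float).reshape(-1)
        th = x * c_mix / constants.c_max
        for k, e in enumerate(eps):
            eps_all.append(e)
            theta_all.append(th)
            labels.append(f"{name}[{k}]")
    eps_all = np.array(eps_all)
    theta_all = np.array(theta_all)
    if theta_all.sum() > 1.0 + 1e-12:
        comp = ", ".join(f"{n} x={x:g}" for n, x in spec.components)
        raise ValueError(
            f"over-packed phase ({comp}): total theta = {theta_all.sum():.4f} "
            "exceeds the c_max packing limit")
    K = association_matrix(eps_all, spec.temperature, constants)
    desc = " + ".join(f"{n}({x:g})" for n, x in spec.components)
    return PhaseState(temperature=spec.temperature, epsilons=eps_all,
                      theta=theta_all, K=K, constants=constants,
                      description=desc, labels=labels)


def make_phase_state(epsilons, theta, temperature: float = 298.0,
                     constants: ModelConstants = DEFAULT_CONSTANTS,
                     description: str = "") -> PhaseState:
    """Assemble a :class:`PhaseState` directly from epsilon/theta arrays.

    Convenience constructor for idealised phases (and fixtures) that are
    not backed by a solvent library; the association matrix is filled in.
    """
    epsilons = np.asarray(epsilons, dtype=float).reshape(-1)
    theta = np.asarray(theta, dtype=float).reshape(-1)
    K = (association_matrix(epsilons, temperature, constants)
         if len(epsilons) else np.zeros((0, 0)))
    return PhaseState(temperature=temperature, epsilons=epsilons, theta=theta,
                      K=K, constants=constants, description=description)


def _component_entry(entry):
    """Accept (SSIPSet|epsilons, molar_volume) or a PhaseComponent."""
    if isinstance(entry, PhaseComponent):
        return entry.epsilons, entry.molar_volume
    eps, vm = entry
    if hasattr(eps, "epsilons"):
        eps = eps.epsilons
    return eps, vm


def solve_speciation(state: PhaseState, tol: float = 1e-12,
                     max_iter: int = 10_000, damping: float = 0.5) -> PhaseState:
    """Solve the coupled mass balances theta_i = f_i (1 + sum_j K_ij f_j).

    Damped fixed-point iteration ``f <- (1-d) f + d theta/(1 + K f)``.
    The solved free fractions, convergence flag and iteration count are
    stored on the state, which is returned for chaining.  Raises
    :class:`ConvergenceError` (with the residual history) on failure.
    """
    theta, K = state.theta, state.K
    if state.n_species == 0:
        state.f = np.empty(0)
        state.converged = True
        state.iterations = 0
        return state
    f = theta / (1.0 + K @ theta)
    residuals = []
    for it in range(1, max_iter + 1):
        denom = 1.0 + K @ f
        f_new = (1.0 - damping) * f + damping * theta / denom
        f = f_new
        residual = float(np.max(np.abs(theta - f * (1.0 + K @ f))))
        residuals.append(residual)
        if residual <= tol:
            state.f = f
            state.converged = True
            state.iterations = it
            return state
    raise ConvergenceError(
        f"speciation failed to reach tol={tol} in {max_iter} iterations "
        f"(last residual {residuals[-1]:.3e})", residuals)


def _require_solved(state: PhaseState):
    if state.f is None or not state.converged:
        raise ValueError("phase state is not solved; run solve_speciation first")


def contact_matrix(state: PhaseState) -> np.ndarray:
    """Equilibrium contact concentrations theta_ij (normalised units).

    Off-diagonal: theta_ij = K_ij f_i f_j.  Diagonal: theta_ii =
    K_ii f_i^2 / 2 because each i-i contact consumes two copies of site i.
    Conservation: f_i + sum_{j!=i} theta_ij + 2 theta_ii = theta_i.
    """
    _require_solved(state)
    f = state.f
    m = state.K * np.outer(f, f)
    m[np.diag_indices_from(m)] /= 2.0
    return m


def solvation_energy(eps_probe: float, state: PhaseState,
                     constants: ModelConstants | None = None) -> float:
    """Solvation free energy (kJ/mol) of an idealised solute SSIP at
    infinite dilution.

    The probe partitions over the void (weight theta_e, K = 1 — the inert
    zero-energy reference) and the free solvent sites (weights f_j, the
    probe-solvent association constants):

        dG_solv = -RT ln(theta_e + sum_j K(eps_probe, eps_j) f_j)

    The infinite-dilution contract means the probe does not perturb the
    solvent speciation.  An empty phase (theta_e = 1) gives exactly 0.
    """
    _require_solved(state)
    if constants is None:
        constants = state.constants
    rt = constants.R * state.temperature
    if state.n_species == 0:
        return 0.0
    polar = np.minimum(eps_probe * state.epsilons, 0.0)
    k_probe = np.exp(-(constants.e_vdw + polar) / rt)
    arg = state.theta_e + float(k_probe @ state.f)
    return float(-rt * np.log(arg))


def transfer_energy(eps_probe: float, state_from: PhaseState,
                    state_to: PhaseState) -> float:
    """Phase-transfer free energy dG_solv(to) - dG_solv(from), kJ/mol.

    Antisymmetric under swapping the phases; both states must be solved
    at the same temperature.
    """
    if abs(state_from.temperature - state_to.temperature) > 1e-9:
        raise ValueError(
            f"temperature mismatch: {state_from.temperature} K vs "
            f"{state_to.temperature} K")
    return (solvation_energy(eps_probe, state_to)
            - solvation_energy(eps_probe, state_from))


def load_solvent_library(directory, constants: ModelConstants = DEFAULT_CONSTANTS
                         ) -> dict:
    """Load a solvent library directory into a name -> (epsilons, V_m) map.

    The directory holds one SSIP XML file per component plus a
    ``components.tsv`` table with tab-separated columns
    ``name<TAB>molar_volume_L_per_mol<TAB>xml_filename``.
    """
    import os

    from .formats import read_ssip_xml

    table = os.path.join(directory, "components.tsv")
    library = {}
    with open(table, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, vm, fname = line.split("\t")
            ssips = read_ssip_xml(os.path.join(directory, fname))
            library[name] = (ssips.epsilons, float(vm))
    return library
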