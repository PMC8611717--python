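"""Applications on top of the equilibrium engine: functional group
interaction profiles (FGIPs) and the solvent similarity index (SSI).

An FGIP maps the free energy of bringing two idealised solute probe
SSIPs into contact in a given solvent, over a grid of (donor alpha,
acceptor beta) probe strengths (probe epsilons +alpha and -beta).  The
exchange bookkeeping implemented here is

    ddG_FGI(a, b) = dG_int(a, b) + dG_ss - dG_solv(a) - dG_solv(b)

where dG_int = E_vdW + min(eps_a * eps_b, 0) is the direct solute-solute
contact energy, the two dG_solv terms are the desolvation cost of each
probe, and dG_ss is the solvent-reorganisation credit: the
population-weighted mean solvation energy of the solvent's own sites
(the solvent-solvent contact recovered when two probes pair up).  This
is the minimal form with the correct gas-phase limit (ddG = dG_int
everywhere, so ddG(0,0) = E_vdW) and probe-exchange symmetry; it is
isolated here so an alternative bookkeeping can be substituted.

The SSI compares two phases through their solvation-energy profiles
D_P(eps) = dG_solv(eps | P) over an epsilon grid (default -10 ... +5,
step 0.1): the default metric is the uncentered cosine similarity of
the two profiles, giving 1 for identical solvents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ssimple import ModelConstants, PhaseState, solvation_energy

__all__ = [
    "FGIPGrid",
    "SSIResult",
    "solvent_reorganization_term",
    "fgip",
    "fgip_pair",
    "ssi",
    "export_fgip",
    "read_fgip",
    "plot_fgip",
]

DEFAULT_ALPHA_AXIS = np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)
DEFAULT_BETA_AXIS = np.round(np.arange(0.0, 10.0 + 1e-9, 0.2), 10)
DEFAULT_SSI_GRID = np.round(np.arange(-10.0, 5.0 + 1e-9, 0.1), 10)


@dataclass
class FGIPGrid:
    """ddG_FGI values (kJ/mol) over a (donor alpha, acceptor beta) probe grid.

    ``values[i, j]`` is computed from the probe pair (+alpha[i], -beta[j]).
    """

    alpha: np.ndarray
    beta: np.ndarray
    values: np.ndarray
    phase: str = ""
    temperature: float = 298.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(-1)
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.alpha), len(self.beta)):
            raise ValueError("values shape must be (len(alpha), len(beta))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FGIP values must be finite")


@dataclass
class SSIResult:
    """Similarity between two phases: 1 means identical solvation profiles."""

    value: float
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_SSI_GRID.copy())
    phase_1: str = ""
    phase_2: str = ""


def solvent_reorganization_term(state: PhaseState) -> float:
    """Population-weighted mean solvation energy of a phase's own sites.

    sum_j (theta_j / sum theta) * dG_solv(eps_j | phase); 0 for an empty
    phase.  This is the solvent-solvent term recovered in the FGIP
    exchange when two solute probes displace their solvation shells.
    """
    total = float(state.theta.sum())
    if total == 0.0:
        return 0.0
    weights = state.theta / total
    energies = np.array([solvation_energy(e, state) for e in state.epsilons])
    return float(weights @ energies)


def fgip_pair(eps_a: float, eps_b: float, state: PhaseState,
              constants: ModelConstants | None = None) -> float:
    """ddG_FGI (kJ/mol) of one probe pair in a solved phase.

    Symmetric under exchanging the two probe epsilons.
    """
    if constants is None:
        constants = state.constants
    dg_int = constants.e_vdw + min(eps_a * eps_b, 0.0)
    return (dg_int + solvent_reorganization_term(state)
            - solvation_energy(eps_a, state, constants)
            - solvation_energy(eps_b, state, constants))


def fgip(state: PhaseState,
         alpha: np.ndarray | None = None,
         beta: np.ndarray | None = None,
         constants: ModelConstants | None = None) -> FGIPGrid:
    """Compute the functional group interaction profile of a solved phase."""
    if alpha is None:
        alpha = DEFAULT_ALPHA_AXIS
    if beta is None:
        beta = DEFAULT_BETA_AXIS
    alpha = np.asarray(alpha, dtype=float).reshape(-1)
    beta = np.asarray(beta, dtype=float).reshape(-1)
    if len(alpha) == 0 or len(beta) == 0:
        raise ValueError("FGIP axes must be non-empty")
    if constants is None:
        constants = state.constants

    dg_ss = solvent_reorganization_term(state)
    solv_a = np.array([solvation_energy(+a, state, constants) for a in alpha])
    solv_b = np.array([solvation_energy(-b, state, constants) for b in beta])
    # direct probe-probe contact: eps_a * eps_b = -alpha*beta <= 0
    dg_int = constants.e_vdw + np.minimum(np.outer(alpha, -beta), 0.0)
    values = dg_int + dg_ss - solv_a[:, None] - solv_b[None, :]
    return FGIPGrid(alpha=alpha, beta=beta, values=values,
                    phase=state.description, temperature=state.temperature)


def solvation_profile(state: PhaseState,
                      grid: np.ndarray | None = None) -> np.ndarray:
    """dG_solv of an idealised probe over an epsilon grid (kJ/mol)."""
    if grid is None:
        grid = DEFAULT_SSI_GRID
    return np.array([solvation_energy(e, state) for e in np.asarray(grid)])


def ssi(state_1: PhaseState, state_2: PhaseState,
        grid: np.ndarray | None = None) -> SSIResult:
    """Solvent similarity index of two phases at the same temperature.

    Uncentered cosine similarity of the two solvation-energy profiles.
    Two empty (gas) phases have identical all-zero profiles and SSI = 1;
    comparing an empty phase against a dense one yields 0 by convention
    (the cosine is undefined for a zero vector).
    """
    if abs(state_1.temperature - state_2.temperature) > 1e-9:
        raise ValueError(
            f"temperature mismatch: {state_1.temperature} K vs "
            f"{state_2.temperature} K")
    if grid is None:
        grid = DEFAULT_SSI_GRID
    grid = np.asarray(grid, dtype=float).reshape(-1)
    d1 = solvation_profile(state_1, grid)
    d2 = solvation_profile(state_2, grid)
    n1 = float(np.linalg.norm(d1))
    n2 = float(np.linalg.norm(d2))
    if n1 == 0.0 and n2 == 0.0:
        value = 1.0
    elif n1 == 0.0 or n2 == 0.0:
        value = 0.0
    else:
        value = float(d1 @ d2 / (n1 * n2))
    return SSIResult(value=value, grid=grid,
                     phase_1=state_1.description, phase_2=state_2.description)


# ---------------------------------------------------------------------------
# Exporters (lossless round trips; layouts documented in docs/formats.md)

def export_fgip(grid: FGIPGrid, path, format: str = "csv") -> None:
    """Write an FGIP grid as a delimited table (``csv``) or JSON (``json``).

    Both layouts round-trip axes and values exactly through
    :func:`read_fgip` (floats are written with ``repr`` precision).
    """
    if len(grid.alpha) == 0 or len(grid.beta) == 0:
        raise ValueError("cannot export an FGIP with empty axes")
    if format == "json":
        doc = {
            "phase": grid.phase,
            "temperature": grid.temperature,
            "alpha": grid.alpha.tolist(),
            "beta": grid.beta.tolist(),
            "values": grid.values.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# phase: {grid.phase}\n")
            fh.write(f"# temperature_K: {grid.temperature!r}\n")
            fh.write("alpha\\beta," + ",".join(repr(float(b)) for b in grid.beta) + "\n")
            for a, row in zip(grid.alpha, grid.values):
                fh.write(repr(float(a)) + ","
                         + ",".join(repr(float(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown FGIP export format {format!r}")


def read_fgip(path, format: str = "csv") -> FGIPGrid:
    """Read an FGIP grid written by :func:`export_fgip`."""
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return FGIPGrid(alpha=np.array(doc["alpha"]), beta=np.array(doc["beta"]),
                        values=np.array(doc["values"]), phase=doc["phase"],
                        temperature=doc["temperature"])
    if format == "csv":
        phase, temperature = "", 298.0
        rows, alpha, beta = [], [], None
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# phase:"):
                    phase = line.split(":", 1)[1].strip()
                elif line.startswith("# temperature_K:"):
                    temperature = float(line.split(":", 1)[1])
                elif line.startswith("alpha\\beta"):
                    beta = [float(t) for t in line.split(",")[1:]]
                elif line.strip():
                    toks = line.split(",")
                    alpha.append(float(toks[0]))
                    rows.append([float(t) for t in toks[1:]])
        if beta is None:
            raise ValueError("missing header row in FGIP csv")
        return FGIPGrid(alpha=np.array(alpha), beta=np.array(beta),
                        values=np.array(rows), phase=phase,
                        temperature=temperature)
    raise ValueError(f"unknown FGIP format {format!r}")


def plot_fgip(grid: FGIPGrid, path, levels: int = 21) -> None:
    """Render a filled-contour FGIP map (blue favourable, red unfavourable).

    Convenience output only; the csv/json exports are the lossless record.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.abs(grid.values).max()) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(grid.beta, grid.alpha, grid.values, levels=levels,
                     cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(cs, ax=ax, label=r"$\Delta\Delta G_{FGI}$ / kJ mol$^{-1}$")
    ax.set_xlabel(r"acceptor $\beta$")
    ax.set_ylabel(r"donor $\alpha$")
    title = grid.phase or "phase"
    ax.set_title(f"FGIP: {title} at {grid.temperature:g} K")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
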