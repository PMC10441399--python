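"""Coarse-grained Langevin simulator for polyampholyte condensation.

A deliberately desk-scale surrogate for large explicit-solvent condensate
simulations: one bead per residue, implicit solvent, and a hydropathy-scale
(HPS-style) pair potential

    U(r) = U_AH(r; sigma, lambda, eps) + q_i q_j l_B k_B T exp(-kappa r) / r

where ``U_AH`` is the Ashbaugh-Hatch modified Lennard-Jones form
(attraction scaled by the mean bead stickiness ``lambda``), and the second
term is Debye-Hueckel screened electrostatics with Bjerrum length ``l_B``
and inverse screening length ``kappa`` set by the ionic strength.  Chains
are harmonic bead-springs (bond length 0.38 nm).  Dynamics are integrated
with the BAOAB Langevin scheme under orthorhombic periodic boundary
conditions.

The simulator is built to reproduce directional condensate phenomenology —
a lysine-rich, blocky polyampholyte linker condenses at physiological salt,
its lysine-neutralised variant disperses, and high salt dissolves the
condensate — not force-field-grade thermodynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .seqcharge import ChargeProfile, SequenceRecord

KB = 8.31446261815324e-3  # kJ/mol/K
AVOGADRO = 6.02214076e23
ELEM_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m

#: Per-residue stickiness lambda in [0, 1] from a normalised atomistic
#: hydropathy scale (HPS convention: 1 = most hydrophobic).
HYDROPATHY_LAMBDA: dict[str, float] = {
    "A": 0.730, "R": 0.000, "N": 0.432, "D": 0.378, "C": 0.595,
    "Q": 0.514, "E": 0.459, "G": 0.649, "H": 0.514, "I": 0.973,
    "L": 0.973, "K": 0.514, "M": 0.838, "F": 1.000, "P": 1.000,
    "S": 0.595, "T": 0.676, "W": 0.946, "Y": 0.865, "V": 0.892,
}

BOND_LENGTH_NM = 0.38
BOND_K = 2000.0  # kJ/mol/nm^2
LJ_CUTOFF_NM = 2.0
BEAD_MASS = 110.0  # g/mol, mean residue mass (uniform)


class SimError(RuntimeError):
    """Simulation setup or stability failure."""


@dataclass(frozen=True)
class Topology:
    """Bead topology of a multi-chain system (linear chains only)."""

    n_chains: int
    beads_per_chain: int
    bond_pairs: np.ndarray  # (n_bonds, 2) int
    charge: np.ndarray  # per bead
    stickiness: np.ndarray  # per bead, lambda_i in [0, 1]
    bead_sigma: np.ndarray  # per bead, nm
    sequence_id: str = ""

    def __post_init__(self) -> None:
        n = self.n_chains * self.beads_per_chain
        for name in ("charge", "stickiness", "bead_sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise SimError(f"{name} must have one entry per bead ({n})")
            object.__setattr__(self, name, arr)
        bonds = np.asarray(self.bond_pairs, dtype=np.int64)
        if bonds.shape != (self.n_chains * (self.beads_per_chain - 1), 2):
            raise SimError("bond_pairs must describe linear chains")
        object.__setattr__(self, "bond_pairs", bonds)

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def chain_ids(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.beads_per_chain)


@dataclass(frozen=True)
class SimConfig:
    """Integration and interaction parameters.

    Defaults: 298 K, continuum water (eps_r = 80), 100 mM ionic strength,
    0.01 ps timestep, friction 1/ps.  The box edge must exceed twice the
    largest interaction cutoff so the minimum-image convention is valid.
    """

    box_edge_nm: float = 15.0
    temperature_k: float = 298.0
    ionic_strength_m: float = 0.1
    relative_permittivity: float = 80.0
    epsilon_kj: float = 0.8  # Ashbaugh-Hatch well depth
    timestep_ps: float = 0.01
    friction_per_ps: float = 1.0
    n_steps: int = 40_000
    save_every: int = 500
    relax_steps: int = 500  # force-capped steepest-descent pre-relaxation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "box_edge_nm", "ionic_strength_m",
            "relative_permittivity", "timestep_ps", "friction_per_ps",
        ):
            if getattr(self, name) <= 0:
                raise SimError(f"{name} must be positive")
        if self.temperature_k < 0:
            raise SimError("temperature_k must be non-negative")
        if self.n_steps < 1 or self.save_every < 1:
            raise SimError("n_steps and save_every must be >= 1")
        cutoff = max(LJ_CUTOFF_NM, self.elec_cutoff_nm)
        if self.box_edge_nm <= 2 * cutoff:
            raise SimError(
                f"box edge {self.box_edge_nm} nm must exceed twice the "
                f"largest cutoff ({cutoff:.2f} nm)"
            )

    @property
    def _t_eff(self) -> float:
        # T = 0 is allowed for quenched-dynamics checks; electrostatic
        # lengths are evaluated in the T -> 0 limit (full screening, finite
        # Coulomb prefactor l_B * kB * T).
        return self.temperature_k if self.temperature_k > 0 else 1e-9

    @property
    def debye_length_nm(self) -> float:
        return debye_length(
            self.ionic_strength_m, self._t_eff, self.relative_permittivity
        )

    @property
    def elec_cutoff_nm(self) -> float:
        return 4.0 * self.debye_length_nm

    @property
    def bjerrum_length_nm(self) -> float:
        return bjerrum_length(self._t_eff, self.relative_permittivity)


@dataclass(frozen=True)
class Frame:
    """Coordinates (nm) wrapped into [0, box_edge) at one time point."""

    coordinates: np.ndarray
    box_edge_nm: float
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise SimError("coordinates must be (n_beads, 3)")
        object.__setattr__(self, "coordinates", c)


@dataclass(frozen=True)
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in self.frames:
            if f.coordinates.shape[0] != self.topology.n_beads:
                raise SimError("frame bead count does not match topology")

    def coordinates_array(self) -> np.ndarray:
        return np.stack([f.coordinates for f in self.frames])

    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])


# ---------------------------------------------------------------------------
# Electrostatics helpers
# ---------------------------------------------------------------------------

def bjerrum_length(temperature_k: float, relative_permittivity: float) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps_r kB T), in nm."""
    if temperature_k <= 0 or relative_permittivity <= 0:
        raise SimError("temperature and permittivity must be positive")
    kbt_j = 1.380649e-23 * temperature_k
    lb_m = ELEM_CHARGE**2 / (4 * np.pi * EPS0 * relative_permittivity * kbt_j)
    return lb_m * 1e9


def debye_length(
    ionic_strength_m: float,
    temperature_k: float = 298.0,
    relative_permittivity: float = 80.0,
) -> float:
    """Debye screening length kappa^-1 = (8 pi l_B N_A I)^(-1/2), in nm.

    For water at 298 K this reduces to the familiar 0.304/sqrt(I[M]) nm.
    """
    if ionic_strength_m <= 0:
        raise SimError("ionic strength must be positive")
    lb_nm = bjerrum_length(temperature_k, relative_permittivity)
    number_density = ionic_strength_m * AVOGADRO * 1e-24  # particles / nm^3
    kappa2 = 8 * np.pi * lb_nm * number_density
    return 1.0 / np.sqrt(kappa2)


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def topology_from_sequence(
    seq: SequenceRecord,
    profile: ChargeProfile,
    n_chains: int,
    sigma_nm: float = 0.6,
) -> Topology:
    """Replicate one sequence into an n-chain topology."""
    if len(profile) != len(seq):
        raise SimError("charge profile length must match sequence length")
    n_res = len(seq)
    lam = np.array([HYDROPATHY_LAMBDA[a] for a in seq.residues])
    bonds = []
    for c in range(n_chains):
        off = c * n_res
        bonds.extend((off + i, off + i + 1) for i in range(n_res - 1))
    return Topology(
        n_chains=n_chains,
        beads_per_chain=n_res,
        bond_pairs=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        charge=np.tile(profile.charges, n_chains),
        stickiness=np.tile(lam, n_chains),
        bead_sigma=np.full(n_chains * n_res, sigma_nm),
        sequence_id=seq.id,
    )


def build_system(
    seq: SequenceRecord,
    profile: ChargeProfile,
    n_chains: int,
    box_edge_nm: float,
    seed: int,
    min_separation_nm: float = 0.35,
    max_retries: int = 200,
    confine_radius_nm: float | None = None,
) -> tuple[Topology, Frame]:
    """Place chains as self-avoiding random walks in a periodic cubic box.

    Bond length 0.38 nm; any inter-bead pair closer than
    ``min_separation_nm`` (minimum image) rejects the walk.  Deterministic
    for a given seed; raises after ``max_retries`` failed placements.

    With ``confine_radius_nm`` the walks are confined to a sphere of that
    radius around the box centre, producing a pre-formed droplet — the
    starting point for droplet-stability (dissolution) protocols.
    """
    topology = topology_from_sequence(seq, profile, n_chains)
    rng = np.random.default_rng(seed)
    n_res = topology.beads_per_chain
    box = box_edge_nm
    centre = np.full(3, box / 2.0)
    placed: list[np.ndarray] = []

    def outside(pos: np.ndarray) -> bool:
        if confine_radius_nm is None:
            return False
        return bool(np.linalg.norm(pos - centre) > confine_radius_nm)

    def too_close(pos: np.ndarray, others: np.ndarray) -> bool:
        if others.size == 0:
            return False
        d = others - pos
        d -= box * np.round(d / box)
        return bool(np.any(np.einsum("ij,ij->i", d, d) < min_separation_nm**2))

    for _ in range(n_chains):
        prior = np.vstack(placed) if placed else np.empty((0, 3))
        for attempt in range(max_retries):
            if confine_radius_nm is None:
                start = rng.uniform(0, box, size=3)
            else:
                start = centre + rng.uniform(
                    -confine_radius_nm, confine_radius_nm, size=3
                )
            if outside(start) or too_close(start, prior):
                continue
            chain = [start]
            ok = True
            while ok and len(chain) < n_res:
                for _try in range(30):  # per-step direction retries
                    step = rng.standard_normal(3)
                    step *= BOND_LENGTH_NM / np.linalg.norm(step)
                    nxt = chain[-1] + step
                    obstacles = (
                        np.vstack([prior, np.vstack(chain[:-1])])
                        if len(chain) > 1
                        else prior
                    )
                    if not outside(nxt) and not too_close(nxt, obstacles):
                        chain.append(nxt)
                        break
                else:
                    ok = False
            if ok:
                placed.append(np.vstack(chain))
                break
        else:
            raise SimError(
                f"failed to pack chain {len(placed) + 1}/{n_chains} after "
                f"{max_retries} retries; enlarge the box"
            )
    coords = np.vstack(placed) % box
    return topology, Frame(coordinates=coords, box_edge_nm=box, time_ps=0.0)


# ---------------------------------------------------------------------------
# Potential (Ashbaugh-Hatch + Debye-Hueckel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_u(
    r: float, sigma: float, lam: float, eps: float,
    qq_lb_kbt: float, kappa_inv: float, elec_cut: float,
) -> float:
    u = 0.0
    if r < LJ_CUTOFF_NM:
        sr6 = (sigma / r) ** 6
        ulj = 4.0 * eps * (sr6 * sr6 - sr6)
        if r <= sigma * 2.0 ** (1.0 / 6.0):
            u += ulj + (1.0 - lam) * eps
        else:
            u += lam * ulj
    if qq_lb_kbt != 0.0 and r < elec_cut:
        u += qq_lb_kbt * np.exp(-r / kappa_inv) / r
    return u


@njit(cache=True)
def _forces_energy(
    coords: np.ndarray,
    charge: np.ndarray,
    stick: np.ndarray,
    sigma: np.ndarray,
    chain_id: np.ndarray,
    bonds: np.ndarray,
    box: float,
    eps: float,
    lb_kbt: float,
    kappa_inv: float,
    elec_cut: float,
) -> tuple[np.ndarray, float]:
    """All-pair nonbonded + harmonic-bond forces; minimum-image PBC."""
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    rc2 = max(LJ_CUTOFF_NM, elec_cut) ** 2
    for i in range(n - 1):
        xi = coords[i, 0]
        yi = coords[i, 1]
        zi = coords[i, 2]
        for j in range(i + 1, n):
            dx = xi - coords[j, 0]
            dy = yi - coords[j, 1]
            dz = zi - coords[j, 2]
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc2 or r2 == 0.0:
                continue
            # bonded neighbours on the same chain are excluded from
            # nonbonded terms (handled by the harmonic bond)
            if chain_id[i] == chain_id[j] and (j - i) == 1:
                continue
            r = np.sqrt(r2)
            sig = 0.5 * (sigma[i] + sigma[j])
            lam = 0.5 * (stick[i] + stick[j])
            fmag = 0.0  # dU/dr, to be negated
            if r < LJ_CUTOFF_NM:
                sr6 = (sig / r) ** 6
                ulj = 4.0 * eps * (sr6 * sr6 - sr6)
                dulj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                if r <= sig * 2.0 ** (1.0 / 6.0):
                    energy += ulj + (1.0 - lam) * eps
                    fmag += dulj
                else:
                    energy += lam * ulj
                    fmag += lam * dulj
            qq = charge[i] * charge[j]
            if qq != 0.0 and r < elec_cut:
                pref = qq * lb_kbt
                screen = np.exp(-r / kappa_inv)
                energy += pref * screen / r
                fmag += -pref * screen * (1.0 / (r * r) + 1.0 / (kappa_inv * r))
            s = -fmag / r
            forces[i, 0] += s * dx
            forces[i, 1] += s * dy
            forces[i, 2] += s * dz
            forces[j, 0] -= s * dx
            forces[j, 1] -= s * dy
            forces[j, 2] -= s * dz
    # harmonic bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            continue
        delta = r - BOND_LENGTH_NM
        energy += 0.5 * BOND_K * delta * delta
        s = -BOND_K * delta / r
        forces[i, 0] += s * dx
        forces[i, 1] += s * dy
        forces[i, 2] += s * dz
        forces[j, 0] -= s * dx
        forces[j, 1] -= s * dy
        forces[j, 2] -= s * dz
    return forces, energy


def pair_energy(
    r: float, i: int, j: int, topology: Topology, config: SimConfig
) -> float:
    """Nonbonded pair potential U(r) between beads i and j, in kJ/mol.

    Ashbaugh-Hatch (arithmetic-mean sigma and lambda combining rules, well
    depth ``config.epsilon_kj``, cutoff 2 nm) plus Debye-Hueckel screened
    Coulomb (cutoff 4 Debye lengths).  Zero beyond both cutoffs.
    """
    if r <= 0:
        raise ValueError("pair separation must be positive")
    sig = 0.5 * (topology.bead_sigma[i] + topology.bead_sigma[j])
    lam = 0.5 * (topology.stickiness[i] + topology.stickiness[j])
    qq = topology.charge[i] * topology.charge[j]
    lb_kbt = config.bjerrum_length_nm * KB * config._t_eff
    return float(
        _pair_u(
            r, sig, lam, config.epsilon_kj, qq * lb_kbt,
            config.debye_length_nm, config.elec_cutoff_nm,
        )
    )


def potential_energy(frame: Frame, topology: Topology, config: SimConfig) -> float:
    """Total potential energy of a frame (bonds + nonbonded), kJ/mol."""
    _, e = _forces_energy(
        frame.coordinates, topology.charge, topology.stickiness,
        topology.bead_sigma, topology.chain_ids.astype(np.int64),
        topology.bond_pairs, frame.box_edge_nm, config.epsilon_kj,
        config.bjerrum_length_nm * KB * config._t_eff,
        config.debye_length_nm, config.elec_cutoff_nm,
    )
    return float(e)


# ---------------------------------------------------------------------------
# Langevin (BAOAB) integration
# ---------------------------------------------------------------------------

def run_simulation(
    topology: Topology, start: Frame, config: SimConfig
) -> Trajectory:
    """Integrate Langevin dynamics; returns saved frames (incl. t = 0).

    BAOAB splitting with per-step Gaussian kicks from a generator seeded by
    ``config.seed`` — identical inputs give bit-identical trajectories.
    Raises when the potential energy diverges (> 1e9 kJ/mol), which
    indicates a too-large timestep.
    """
    if start.coordinates.shape[0] != topology.n_beads:
        raise SimError("start frame does not match topology")
    rng = np.random.default_rng(config.seed)
    dt = config.timestep_ps
    gamma = config.friction_per_ps
    kbt = KB * config.temperature_k
    m = BEAD_MASS
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1**2)) * kbt / m)
    box = start.box_edge_nm
    chain_id = topology.chain_ids.astype(np.int64)
    lb_kbt = config.bjerrum_length_nm * KB * config._t_eff
    args = (
        topology.charge, topology.stickiness, topology.bead_sigma, chain_id,
        topology.bond_pairs, box, config.epsilon_kj, lb_kbt,
        config.debye_length_nm, config.elec_cutoff_nm,
    )
    x = start.coordinates.copy()
    f, e = _forces_energy(x % box, *args)
    if not np.isfinite(e):
        raise SimError("non-finite initial potential energy")
    # deterministic steepest-descent relaxation removes packing overlaps
    # before dynamics (displacement capped at 0.02 nm per bead per step)
    for _ in range(config.relax_steps):
        fn = np.linalg.norm(f, axis=1, keepdims=True)
        step = 5e-4 * f
        scale = np.minimum(1.0, 0.02 / np.maximum(5e-4 * fn, 1e-12))
        x += step * scale
        f, e = _forces_energy(x % box, *args)
    v = (
        np.sqrt(kbt / m) * rng.standard_normal(x.shape)
        if config.temperature_k > 0
        else np.zeros_like(x)
    )
    frames = [Frame(coordinates=x % box, box_edge_nm=box, time_ps=start.time_ps)]
    for step in range(1, config.n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f, e = _forces_energy(x % box, *args)
        v += 0.5 * dt * f / m
        if abs(e) > 1e9 or not np.isfinite(e):
            raise SimError(
                f"energy diverged at step {step} (U = {e:.3g} kJ/mol); "
                "reduce the timestep"
            )
        if step % config.save_every == 0:
            coords = x % box
            if np.any(~np.isfinite(coords)):
                raise SimError(f"non-finite coordinates at step {step}")
            frames.append(
                Frame(
                    coordinates=coords.copy(), box_edge_nm=box,
                    time_ps=start.time_ps + step * dt,
                )
            )
    return Trajectory(topology=topology, frames=frames, seed=config.seed)


# ---------------------------------------------------------------------------
# Condition scans (condensation phenotype over variants / salts / seeds)
# ---------------------------------------------------------------------------

def condition_scan(
    variants: dict[str, SequenceRecord],
    ionic_strengths_m: Sequence[float],
    seeds: Sequence[int],
    n_chains: int = 6,
    config: SimConfig | None = None,
    tail_fraction: float = 0.25,
    start: str = "droplet",
    droplet_radius_nm: float = 3.5,
):
    """Condensate-stability summaries per (variant, ionic strength, seed).

    The default protocol mirrors how condensate stability is probed in
    coarse-grained studies: chains start as a pre-formed droplet
    (``start='droplet'``, walks confined to ``droplet_radius_nm``) and the
    run reports whether inter-chain contacts persist or dissolve under the
    given sequence and salt.  ``start='dispersed'`` instead begins from
    chains scattered through the box (a condensation assay, which needs
    far longer runs to develop contrast).

    For each condition an isolated single-chain run provides the
    ``<q_single>`` baseline; ``delta_q_final`` is the mean of dQ over the
    trailing ``tail_fraction`` of frames, reported with the final frame's
    largest-cluster fraction.  Returns (per-run DataFrame, mean +- sd
    aggregate DataFrame).
    """
    import pandas as pd

    from . import condensate
    from .seqcharge import assign_charges

    if not variants or not len(ionic_strengths_m):
        raise SimError("need at least one variant and one ionic strength")
    if len(seeds) < 1:
        raise SimError("need at least one seed")
    base = config or SimConfig()
    params = condensate.ContactParams()
    rows = []
    for name, seq in variants.items():
        profile = assign_charges(seq)
        for ionic in ionic_strengths_m:
            for seed in seeds:
                cfg = replace(base, ionic_strength_m=ionic, seed=seed)
                # isolated-chain baseline, same conditions
                topo1, start1 = build_system(
                    seq, profile, 1, cfg.box_edge_nm, seed=seed + 7_919
                )
                traj1 = run_simulation(topo1, start1, replace(cfg, seed=seed + 7_919))
                q_single = condensate.compute_q_single(traj1, params)
                topo, start_frame = build_system(
                    seq, profile, n_chains, cfg.box_edge_nm, seed,
                    confine_radius_nm=(
                        droplet_radius_nm if start == "droplet" else None
                    ),
                )
                traj = run_simulation(topo, start_frame, cfg)
                series = condensate.contact_series(traj, params, q_single_mean=q_single)
                n_tail = max(1, int(round(tail_fraction * series.deltaQ.size)))
                clusters = condensate.cluster_chains(
                    traj.frames[-1], topo, condensate.DEFAULT_CLUSTER_CUTOFF_NM
                )
                rows.append(
                    {
                        "variant": name,
                        "ionic_strength_m": ionic,
                        "seed": seed,
                        "delta_q_final": float(series.deltaQ[-n_tail:].mean()),
                        "largest_cluster_fraction": clusters.largest_fraction,
                        "q_single_mean": q_single,
                    }
                )
    table = pd.DataFrame(rows)
    agg = (
        table.groupby(["variant", "ionic_strength_m"])
        .agg(
            delta_q_mean=("delta_q_final", "mean"),
            delta_q_sd=("delta_q_final", "std"),
            largest_cluster_mean=("largest_cluster_fraction", "mean"),
            n_seeds=("seed", "count"),
        )
        .reset_index()
    )
    return table, agg


# ---------------------------------------------------------------------------
# Trajectory I/O: extended XYZ + JSON topology sidecar
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Multi-frame extended XYZ; the comment line carries box and time."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{traj.topology.n_beads}\n")
            fh.write(f"box={frame.box_edge_nm:.6f} time={frame.time_ps:.6f}\n")
            for k, (x, y, z) in enumerate(frame.coordinates):
                fh.write(f"CA{k % 100:02d} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, topology: Topology) -> Trajectory:
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            meta = dict(
                item.split("=") for item in fh.readline().split() if "=" in item
            )
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(p) for p in parts[1:4]]
            frames.append(
                Frame(
                    coordinates=coords,
                    box_edge_nm=float(meta.get("box", 0.0)),
                    time_ps=float(meta.get("time", 0.0)),
                )
            )
    return Trajectory(topology=topology, frames=frames)


def write_topology_json(topology: Topology, path: str | Path, seed: int | None = None) -> None:
    payload = {
        "n_chains": topology.n_chains,
        "beads_per_chain": topology.beads_per_chain,
        "charge": topology.charge.tolist(),
        "stickiness": topology.stickiness.tolist(),
        "bead_sigma": topology.bead_sigma.tolist(),
        "sequence_id": topology.sequence_id,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_topology_json(path: str | Path) -> Topology:
    d = json.loads(Path(path).read_text())
    n_chains, n_res = d["n_chains"], d["beads_per_chain"]
    bonds = []
    for c in range(n_chains):
        off = c * n_res
        bonds.extend((off + i, off + i + 1) for i in range(n_res - 1))
    return Topology(
        n_chains=n_chains,
        beads_per_chain=n_res,
        bond_pairs=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        charge=np.array(d["charge"]),
        stickiness=np.array(d["stickiness"]),
        bead_sigma=np.array(d["bead_sigma"]),
        sequence_id=d.get("sequence_id", ""),
    )
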