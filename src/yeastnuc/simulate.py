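"""Restrained Langevin dynamics of bead-and-spring chromosome chains.

Each chromosome is a Kremer-Grest-type chain of 30-nm beads (~3.2 kb each)
with three intra-chain energy terms:

* excluded volume — purely repulsive (WCA) Lennard-Jones between all bead
  pairs, preventing overlap and, together with the bonds, chain crossing;
* chain connectivity — FENE bonds between consecutive beads with a hard
  maximum extension of 45 nm;
* bending rigidity — a Kratky-Porod angle term with stiffness kappa = Lp/b
  (kT units), Lp = 61.7 nm for internal chromatin and 195.0 nm over the
  rigid 20-kb telomeric regions.

Nuclear organisation enters through one-sided quadratic "indent"
restraints (see :mod:`yeastnuc.geometry`): all beads confined to the
nucleus, centromere beads to the SPB sphere, rDNA beads inside / all other
beads outside the nucleolar sphere, plus a short-range Lennard-Jones
attraction pulling the terminal (telomere) beads toward the nuclear
envelope within the peripheral shell.

Chains start as stacked-rosette solenoid rods placed at random positions
and orientations (longest chromosome first, clashes rejected), restraints
are satisfied in a short preliminary run, and conformations are sampled
from a production run at regular intervals.  Internally the integrator
works in reduced Lennard-Jones units (length sigma = 30 nm, energy kT,
time tau_LJ); the public API speaks nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .geometry import NuclearGeometry
from .karyotype import BeadChain, Karyotype

__all__ = [
    "ForceField",
    "SimulationSchedule",
    "Conformation",
    "Ensemble",
    "bending_constant_from_persistence",
    "build_solenoid",
    "place_chromosomes",
    "preliminary_relax",
    "production_run",
    "run_replicate",
    "run_ensemble",
    "measure_persistence_length",
]

SIGMA_NM = 30.0


def bending_constant_from_persistence(lp_nm: float, bond_nm: float = SIGMA_NM) -> float:
    """Discrete worm-like-chain bending constant kappa = Lp / b, in kT.

    For a Kratky-Porod chain with bond length ``b`` and bending energy
    kappa (1 - cos theta) per joint, the persistence length is Lp ~ kappa b
    (kT units, stiff limit), so kappa = Lp / b.
    """
    if lp_nm <= 0 or bond_nm <= 0:
        raise ValueError("persistence and bond lengths must be positive")
    return lp_nm / bond_nm


@dataclass
class ForceField:
    """Energy parameters of the chain and its nuclear-envelope interaction.

    All energies in kT, lengths in nm.  ``telomere_eps`` is the depth of
    the NE attraction felt by terminal beads; its default was calibrated
    once (sweep over 1-4 kT) so that wild-type telomeres are found outside
    the peripheral shell in roughly 40% of sampled conformations.
    """

    sigma: float = SIGMA_NM
    epsilon: float = 1.0
    fene_R0: float = 45.0
    fene_K_red: float = 30.0  # kT / sigma^2, Kremer-Grest standard
    lp_internal: float = 61.7
    lp_terminal: float = 195.0
    telomere_eps: float = 4.5
    telomere_cutoff: float = 126.0  # from the NE, nm

    def __post_init__(self) -> None:
        if self.fene_R0 <= self.sigma:
            raise ValueError("FENE maximum extension must exceed the bead diameter")
        if self.lp_terminal < self.lp_internal:
            raise ValueError("terminal regions are stiffer than internal ones")

    @property
    def kappa_internal(self) -> float:
        return bending_constant_from_persistence(self.lp_internal, self.sigma)

    @property
    def kappa_terminal(self) -> float:
        return bending_constant_from_persistence(self.lp_terminal, self.sigma)


@dataclass
class SimulationSchedule:
    """Timing of one replicate, in tau_LJ (= sigma sqrt(m/eps), m = 1).

    Defaults follow the full-scale protocol: 60 tau_LJ of preliminary
    restraint satisfaction, 30,000 tau_LJ of production with one
    conformation retained every 3000 tau_LJ (10 per trajectory), and 1000
    replicates for a 10,000-conformation ensemble.
    """

    dt: float = 0.01
    gamma: float = 1.0  # friction, 1/tau_LJ
    prelim_duration: float = 60.0
    production_duration: float = 30_000.0
    sample_every: float = 3000.0
    n_replicates: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.sample_every <= 0:
            raise ValueError("dt and sample_every must be positive")
        if self.production_duration % self.sample_every:
            raise ValueError("production duration must be a multiple of sample_every")

    @property
    def samples_per_replicate(self) -> int:
        return int(round(self.production_duration / self.sample_every))

    def scaled(self, factor: float) -> "SimulationSchedule":
        """A schedule with production and sampling times scaled by ``factor``."""
        return SimulationSchedule(
            dt=self.dt,
            gamma=self.gamma,
            prelim_duration=self.prelim_duration,
            production_duration=self.production_duration * factor,
            sample_every=self.sample_every * factor,
            n_replicates=self.n_replicates,
        )


@dataclass
class Conformation:
    """One sampled genome conformation: bead coordinates in nm."""

    positions: np.ndarray  # (n_beads, 3)
    karyotype_name: str
    replicate: int = 0
    sample_index: int = 0
    seed: int = 0


@dataclass
class Ensemble:
    """A collection of conformations sharing one karyotype."""

    conformations: list[Conformation]
    karyotype_name: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformations)

    def positions_array(self) -> np.ndarray:
        """All coordinates stacked as (n_conformations, n_beads, 3), nm."""
        return np.stack([c.positions for c in self.conformations])


# ---------------------------------------------------------------------------
# chain topology flattening


@dataclass
class _Topology:
    """Flattened per-bead topology of a karyotype for the force kernel."""

    chain_names: list[str]
    chain_offsets: np.ndarray  # (n_chains + 1,)
    n_beads: int
    bonds: np.ndarray  # (n_bonds, 2) int64
    angles: np.ndarray  # (n_angles, 3) int64
    angle_kappa: np.ndarray  # (n_angles,) kT
    is_centromere: np.ndarray
    is_terminal: np.ndarray
    is_rdna: np.ndarray


def build_topology(chains: Sequence[BeadChain], forcefield: ForceField) -> _Topology:
    offsets = np.zeros(len(chains) + 1, dtype=np.int64)
    for i, ch in enumerate(chains):
        offsets[i + 1] = offsets[i] + ch.n_beads
    n = int(offsets[-1])
    bonds, angles, kappas = [], [], []
    is_cen = np.zeros(n, dtype=np.bool_)
    is_term = np.zeros(n, dtype=np.bool_)
    is_rdna = np.zeros(n, dtype=np.bool_)
    for ci, ch in enumerate(chains):
        o = offsets[ci]
        is_cen[o : o + ch.n_beads] = ch.is_centromere
        is_term[o : o + ch.n_beads] = ch.is_terminal
        is_rdna[o : o + ch.n_beads] = ch.is_rdna
        for i in range(ch.n_beads - 1):
            bonds.append((o + i, o + i + 1))
        for i in range(1, ch.n_beads - 1):
            angles.append((o + i - 1, o + i, o + i + 1))
            # the stiff terminal persistence length applies to joints fully
            # inside a telomeric (within 20 kb of a free end) region
            stiff = ch.is_telomeric[i - 1] and ch.is_telomeric[i] and ch.is_telomeric[i + 1]
            kappas.append(
                forcefield.kappa_terminal if stiff else forcefield.kappa_internal
            )
    return _Topology(
        chain_names=[ch.chromosome for ch in chains],
        chain_offsets=offsets,
        n_beads=n,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        angle_kappa=np.array(kappas, dtype=np.float64),
        is_centromere=is_cen,
        is_terminal=is_term,
        is_rdna=is_rdna,
    )


# ---------------------------------------------------------------------------
# initial conformations


def build_solenoid(
    n_beads: int,
    rod_radius_nm: float = 150.0,
    bond_nm: float = 34.5,
    rise_per_turn_nm: float = 32.0,
) -> np.ndarray:
    """Stacked-rosette solenoid initial conformation of one chain (nm).

    Beads advance along a helix of radius ``rod_radius_nm`` around the z
    axis with in-plane chord close to ``bond_nm`` and a rise of
    ``rise_per_turn_nm`` per turn, giving a compact, unentangled, overall
    rod-like starting state.  Consecutive spacing stays below the 45-nm
    FENE limit and non-consecutive beads keep >= 0.9 sigma separation.
    """
    if rod_radius_nm <= 0:
        raise ValueError("rod radius must be positive")
    if n_beads < 1:
        raise ValueError("need at least one bead")
    if n_beads == 1:
        return np.zeros((1, 3))
    # beads per turn from the in-plane chord; 3D bond = sqrt(chord^2 + dz^2)
    dphi = 2.0 * math.asin(min(1.0, bond_nm / (2.0 * rod_radius_nm)))
    per_turn = max(3, int(round(2.0 * math.pi / dphi)))
    dphi = 2.0 * math.pi / per_turn
    dz = rise_per_turn_nm / per_turn
    k = np.arange(n_beads)
    pos = np.empty((n_beads, 3))
    pos[:, 0] = rod_radius_nm * np.cos(k * dphi)
    pos[:, 1] = rod_radius_nm * np.sin(k * dphi)
    pos[:, 2] = k * dz
    pos[:, 2] -= pos[:, 2].mean()  # centre along the rod axis only
    chord = 2.0 * rod_radius_nm * math.sin(dphi / 2.0)
    bond3d = math.hypot(chord, dz)
    if bond3d >= 45.0 or rise_per_turn_nm < 0.9 * SIGMA_NM:
        raise ValueError("solenoid parameters violate bond or overlap limits")
    return pos


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def place_chromosomes(
    karyotype: Karyotype,
    geometry: NuclearGeometry,
    seed: int,
    bp_per_bead: Optional[int] = None,
    chains: Optional[Sequence[BeadChain]] = None,
    max_retries: int = 5000,
    rod_radius_nm: float = 150.0,
) -> Conformation:
    """Random non-clashing placement of solenoid rods inside the nucleus.

    Chromosomes are placed longest first, each with a uniformly random
    centre inside the nucleus and a uniformly random axis orientation; an
    attempt is rejected if any bead leaves the nucleus or comes within one
    bead diameter of an already placed chain.  Deterministic under ``seed``.
    """
    from .karyotype import BP_PER_BEAD

    if chains is None:
        chains = karyotype.build_chains(bp_per_bead or BP_PER_BEAD)
    rng = np.random.default_rng(seed)
    order = sorted(range(len(chains)), key=lambda i: -chains[i].n_beads)
    placed: list[np.ndarray] = [None] * len(chains)
    tree: Optional[cKDTree] = None
    occupied: Optional[np.ndarray] = None
    for idx in order:
        ch = chains[idx]
        rod = build_solenoid(ch.n_beads, rod_radius_nm=min(rod_radius_nm, geometry.R_nuc / 3))
        ok = False
        for _ in range(max_retries):
            rot = _random_rotation(rng)
            center = rng.normal(size=3)
            center *= geometry.R_nuc * rng.random() ** (1.0 / 3.0) / np.linalg.norm(center)
            cand = rod @ rot.T + center
            if np.max(np.linalg.norm(cand, axis=1)) > geometry.R_nuc - 0.5 * SIGMA_NM:
                continue
            if tree is not None:
                d, _ = tree.query(cand, k=1)
                if np.min(d) < SIGMA_NM:
                    continue
            placed[idx] = cand
            occupied = cand if occupied is None else np.vstack([occupied, cand])
            tree = cKDTree(occupied)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place chromosome {ch.chromosome!r} after {max_retries} attempts"
            )
    positions = np.vstack([placed[i] for i in range(len(chains))])
    return Conformation(positions=positions, karyotype_name=karyotype.name, seed=seed)


# ---------------------------------------------------------------------------
# force and integration kernel (reduced units: sigma = eps = m = 1)


@njit(cache=True, fastmath=True)
def _forces(
    x,
    f,
    bonds,
    angles,
    angle_kappa,
    is_cen,
    is_term,
    is_rdna,
    fene_K,
    fene_R0,
    R_nuc,
    spb_cx,
    R_spb,
    nucl_cx,
    R_nucl,
    K_indent,
    tel_eps,
    tel_cut,
):
    n = x.shape[0]
    f[:] = 0.0
    wca_cut2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2
    # excluded volume, all pairs (systems simulated here are small enough
    # that the O(N^2) loop beats neighbour-list bookkeeping)
    for i in range(n - 1):
        xi0, xi1, xi2 = x[i, 0], x[i, 1], x[i, 2]
        for j in range(i + 1, n):
            d0 = xi0 - x[j, 0]
            d1 = xi1 - x[j, 1]
            d2 = xi2 - x[j, 2]
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < wca_cut2 and r2 > 1e-12:
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                # F = 24 eps (2/r^12 - 1/r^6) / r^2 * dr
                fac = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
                f[i, 0] += fac * d0
                f[i, 1] += fac * d1
                f[i, 2] += fac * d2
                f[j, 0] -= fac * d0
                f[j, 1] -= fac * d1
                f[j, 2] -= fac * d2
    # FENE bonds
    R02 = fene_R0 * fene_R0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        denom = 1.0 - r2 / R02
        if denom < 1e-4:
            denom = 1e-4  # clamp: integrator should never reach this
        fac = -fene_K / denom
        f[i, 0] += fac * d0
        f[i, 1] += fac * d1
        f[i, 2] += fac * d2
        f[j, 0] -= fac * d0
        f[j, 1] -= fac * d1
        f[j, 2] -= fac * d2
    # Kratky-Porod bending: E = kappa (1 - cos theta)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        kap = angle_kappa[a]
        b10 = x[j, 0] - x[i, 0]
        b11 = x[j, 1] - x[i, 1]
        b12 = x[j, 2] - x[i, 2]
        b20 = x[k, 0] - x[j, 0]
        b21 = x[k, 1] - x[j, 1]
        b22 = x[k, 2] - x[j, 2]
        l1 = math.sqrt(b10 * b10 + b11 * b11 + b12 * b12)
        l2 = math.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        if l1 < 1e-9 or l2 < 1e-9:
            continue
        u10, u11, u12 = b10 / l1, b11 / l1, b12 / l1
        u20, u21, u22 = b20 / l2, b21 / l2, b22 / l2
        c = u10 * u20 + u11 * u21 + u12 * u22
        # F_i = -dE/dr_i = kappa * d(cos)/dr_i, with
        # d(cos)/dr_i = (c*u1 - u2)/l1 ; d(cos)/dr_k = (u1 - c*u2)/l2
        gi0 = (c * u10 - u20) / l1
        gi1 = (c * u11 - u21) / l1
        gi2 = (c * u12 - u22) / l1
        gk0 = (u10 - c * u20) / l2
        gk1 = (u11 - c * u21) / l2
        gk2 = (u12 - c * u22) / l2
        f[i, 0] += kap * gi0
        f[i, 1] += kap * gi1
        f[i, 2] += kap * gi2
        f[k, 0] += kap * gk0
        f[k, 1] += kap * gk1
        f[k, 2] += kap * gk2
        f[j, 0] -= kap * (gi0 + gk0)
        f[j, 1] -= kap * (gi1 + gk1)
        f[j, 2] -= kap * (gi2 + gk2)
    # nuclear restraints (one-sided quadratic "indent" forces)
    tel_shift_s = tel_cut
    for i in range(n):
        xi0, xi1, xi2 = x[i, 0], x[i, 1], x[i, 2]
        r = math.sqrt(xi0 * xi0 + xi1 * xi1 + xi2 * xi2)
        # keep everything inside the nucleus
        if r > R_nuc and r > 1e-12:
            mag = K_indent * (r - R_nuc) * (r - R_nuc)
            f[i, 0] -= mag * xi0 / r
            f[i, 1] -= mag * xi1 / r
            f[i, 2] -= mag * xi2 / r
        # centromeres inside the SPB sphere
        if is_cen[i]:
            d0 = xi0 - spb_cx
            rs = math.sqrt(d0 * d0 + xi1 * xi1 + xi2 * xi2)
            if rs > R_spb and rs > 1e-12:
                mag = K_indent * (rs - R_spb) * (rs - R_spb)
                f[i, 0] -= mag * d0 / rs
                f[i, 1] -= mag * xi1 / rs
                f[i, 2] -= mag * xi2 / rs
        # rDNA inside the nucleolar sphere, all other beads outside it
        d0 = xi0 - nucl_cx
        rn = math.sqrt(d0 * d0 + xi1 * xi1 + xi2 * xi2)
        if is_rdna[i]:
            if rn > R_nucl and rn > 1e-12:
                mag = K_indent * (rn - R_nucl) * (rn - R_nucl)
                f[i, 0] -= mag * d0 / rn
                f[i, 1] -= mag * xi1 / rn
                f[i, 2] -= mag * xi2 / rn
        else:
            if rn < R_nucl:
                mag = K_indent * (R_nucl - rn) * (R_nucl - rn)
                if rn > 1e-12:
                    f[i, 0] += mag * d0 / rn
                    f[i, 1] += mag * xi1 / rn
                    f[i, 2] += mag * xi2 / rn
                else:
                    f[i, 0] += mag  # degenerate centre: fixed +x direction
        # telomere attraction to the NE (terminal beads only): LJ well in
        # the wall distance s = R_nuc - r, truncated and shifted at tel_cut
        if is_term[i] and tel_eps > 0.0 and r > 1e-12:
            s = R_nuc - r
            if s < tel_shift_s:
                if s < 0.85:
                    s = 0.85  # clamp: wall indent handles deeper violations
                inv = 1.0 / s
                inv6 = inv**6
                # dU/ds for U = 4 eps (s^-12 - s^-6); with s = R_nuc - r,
                # F_r = -dU/dr = +dU/ds along the outward radial direction
                dUds = 4.0 * tel_eps * (-12.0 * inv6 * inv6 + 6.0 * inv6) * inv
                f[i, 0] += dUds * xi0 / r
                f[i, 1] += dUds * xi1 / r
                f[i, 2] += dUds * xi2 / r


@njit(cache=True, fastmath=True)
def _langevin(
    x,
    bonds,
    angles,
    angle_kappa,
    is_cen,
    is_term,
    is_rdna,
    fene_K,
    fene_R0,
    R_nuc,
    spb_cx,
    R_spb,
    nucl_cx,
    R_nucl,
    K_indent,
    tel_eps,
    tel_cut,
    dt,
    gamma,
    n_steps,
    sample_stride,
    seed,
    samples,
    v_max,
):
    """BAOAB Langevin integration at kT = 1; fills ``samples`` in place.

    Per-bead speeds are clamped at ``v_max`` (reduced units), which limits
    the displacement per half-step: this leaves equilibrium dynamics
    (thermal speeds ~sqrt(3)) untouched but keeps the integrator stable
    while the initial placement still grossly violates the quadratic
    landmark restraints during the preliminary run.
    """
    n = x.shape[0]
    np.random.seed(seed)
    v = np.empty((n, 3))
    for i in range(n):
        for d in range(3):
            v[i, d] = np.random.standard_normal()
    f = np.zeros((n, 3))
    _forces(
        x, f, bonds, angles, angle_kappa, is_cen, is_term, is_rdna,
        fene_K, fene_R0, R_nuc, spb_cx, R_spb, nucl_cx, R_nucl, K_indent,
        tel_eps, tel_cut,
    )
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    half = 0.5 * dt
    vmax2 = v_max * v_max
    n_sampled = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
            s2 = v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            if s2 > vmax2:
                sc = v_max / math.sqrt(s2)
                v[i, 0] *= sc
                v[i, 1] *= sc
                v[i, 2] *= sc
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        for i in range(n):
            for d in range(3):
                v[i, d] = c1 * v[i, d] + c2 * np.random.standard_normal()
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        _forces(
            x, f, bonds, angles, angle_kappa, is_cen, is_term, is_rdna,
            fene_K, fene_R0, R_nuc, spb_cx, R_spb, nucl_cx, R_nucl, K_indent,
            tel_eps, tel_cut,
        )
        for i in range(n):
            v[i, 0] += half * f[i, 0]
            v[i, 1] += half * f[i, 1]
            v[i, 2] += half * f[i, 2]
            s2 = v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            if s2 > vmax2:
                sc = v_max / math.sqrt(s2)
                v[i, 0] *= sc
                v[i, 1] *= sc
                v[i, 2] *= sc
        if sample_stride > 0 and step % sample_stride == 0:
            samples[n_sampled] = x
            n_sampled += 1
    return 0


def _kernel_args(topology: _Topology, forcefield: ForceField, geometry: NuclearGeometry):
    """Reduced-unit constants for the integration kernel."""
    s = forcefield.sigma
    return dict(
        bonds=topology.bonds,
        angles=topology.angles,
        angle_kappa=topology.angle_kappa,
        is_cen=topology.is_centromere,
        is_term=topology.is_terminal,
        is_rdna=topology.is_rdna,
        fene_K=forcefield.fene_K_red,
        fene_R0=forcefield.fene_R0 / s,
        R_nuc=geometry.R_nuc / s,
        spb_cx=geometry.c_spb[0] / s,
        R_spb=geometry.R_spb / s,
        nucl_cx=geometry.c_nucl[0] / s,
        R_nucl=geometry.R_nucl / s,
        K_indent=geometry.indent_stiffness,
        tel_eps=forcefield.telomere_eps,
        tel_cut=forcefield.telomere_cutoff / s,
    )


def _run(
    conf: Conformation,
    duration: float,
    sample_every: float,
    schedule: SimulationSchedule,
    forcefield: ForceField,
    geometry: NuclearGeometry,
    topology: _Topology,
    seed: int,
) -> list[np.ndarray]:
    """Integrate ``duration`` tau_LJ, returning samples every ``sample_every``."""
    if duration == 0:
        return []
    n_steps = int(round(duration / schedule.dt))
    stride = int(round(sample_every / schedule.dt))
    n_samples = n_steps // stride
    x = np.ascontiguousarray(conf.positions / forcefield.sigma)
    samples = np.empty((n_samples, topology.n_beads, 3))
    _langevin(
        x,
        **_kernel_args(topology, forcefield, geometry),
        dt=schedule.dt,
        gamma=schedule.gamma,
        n_steps=n_steps,
        sample_stride=stride,
        seed=int(seed) & 0x7FFFFFFF,
        samples=samples,
        v_max=10.0,
    )
    if not (np.isfinite(x).all() and np.isfinite(samples).all()):
        raise FloatingPointError(
            f"non-finite coordinates during a {duration} tau_LJ run "
            f"(seed {seed}, karyotype {conf.karyotype_name!r})"
        )
    conf.positions = x * forcefield.sigma
    return [s * forcefield.sigma for s in samples]


def preliminary_relax(
    conf: Conformation,
    schedule: SimulationSchedule,
    forcefield: ForceField,
    geometry: NuclearGeometry,
    topology: _Topology,
    seed: int,
) -> Conformation:
    """Short run that pulls centromere/rDNA/telomere beads onto their restraints."""
    if schedule.prelim_duration > 0:
        _run(
            conf, schedule.prelim_duration, schedule.prelim_duration,
            schedule, forcefield, geometry, topology, seed,
        )
    return conf


def production_run(
    conf: Conformation,
    schedule: SimulationSchedule,
    forcefield: ForceField,
    geometry: NuclearGeometry,
    topology: _Topology,
    seed: int,
) -> list[Conformation]:
    """Production dynamics returning the regularly sampled conformations."""
    frames = _run(
        conf, schedule.production_duration, schedule.sample_every,
        schedule, forcefield, geometry, topology, seed,
    )
    return [
        Conformation(
            positions=fr,
            karyotype_name=conf.karyotype_name,
            replicate=conf.replicate,
            sample_index=i,
            seed=seed,
        )
        for i, fr in enumerate(frames)
    ]


def run_replicate(
    karyotype: Karyotype,
    geometry: NuclearGeometry,
    forcefield: ForceField,
    schedule: SimulationSchedule,
    seed: int,
    replicate: int = 0,
    chains: Optional[Sequence[BeadChain]] = None,
    topology: Optional[_Topology] = None,
) -> list[Conformation]:
    """Place, relax and sample one independent trajectory."""
    if chains is None:
        chains = karyotype.build_chains()
    if topology is None:
        topology = build_topology(chains, forcefield)
    conf = place_chromosomes(karyotype, geometry, seed, chains=chains)
    conf.replicate = replicate
    preliminary_relax(conf, schedule, forcefield, geometry, topology, seed + 1)
    return production_run(conf, schedule, forcefield, geometry, topology, seed + 2)


def run_ensemble(
    karyotype: Karyotype,
    geometry: Optional[NuclearGeometry] = None,
    forcefield: Optional[ForceField] = None,
    schedule: Optional[SimulationSchedule] = None,
    master_seed: int = 0,
    bp_per_bead: Optional[int] = None,
    progress: bool = False,
) -> Ensemble:
    """Run ``schedule.n_replicates`` independent trajectories.

    Per-replicate seeds are derived deterministically from ``master_seed``
    via a counter-based seed sequence and recorded on each conformation;
    replicates that fail (placement or integration) are logged in the
    provenance and excluded.
    """
    from .karyotype import BP_PER_BEAD

    geometry = geometry or NuclearGeometry()
    forcefield = forcefield or ForceField()
    schedule = schedule or SimulationSchedule()
    chains = karyotype.build_chains(bp_per_bead or BP_PER_BEAD)
    topology = build_topology(chains, forcefield)
    seeds = [
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(master_seed).spawn(schedule.n_replicates)
    ]
    confs: list[Conformation] = []
    failures: list[dict] = []
    iterator = range(schedule.n_replicates)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=f"simulate {karyotype.name}")
        except ImportError:
            pass
    for rep in iterator:
        try:
            confs.extend(
                run_replicate(
                    karyotype, geometry, forcefield, schedule,
                    seed=seeds[rep], replicate=rep, chains=chains, topology=topology,
                )
            )
        except (RuntimeError, FloatingPointError) as exc:  # pragma: no cover
            failures.append({"replicate": rep, "seed": seeds[rep], "error": str(exc)})
    return Ensemble(
        conformations=confs,
        karyotype_name=karyotype.name,
        provenance={
            "master_seed": master_seed,
            "replicate_seeds": seeds,
            "n_replicates": schedule.n_replicates,
            "n_failed": len(failures),
            "failures": failures,
            "forcefield": vars(forcefield).copy(),
            "schedule": vars(schedule).copy(),
            "geometry": geometry.describe(),
            "chain_names": topology.chain_names,
            "chain_offsets": topology.chain_offsets.tolist(),
        },
    )


def simulate_free_chain(
    n_beads: int,
    lp_nm: float,
    duration: float,
    sample_every: float,
    seed: int,
    dt: float = 0.01,
    gamma: float = 1.0,
) -> np.ndarray:
    """A single unconfined chain with uniform stiffness; frames in nm.

    Used to validate the worm-like-chain discretisation: the measured
    tangent-correlation persistence length should recover ``lp_nm``.
    All nuclear restraints and the telomere attraction are switched off
    (the confining sphere is moved far beyond the chain's reach).
    """
    ff = ForceField(lp_internal=lp_nm, lp_terminal=lp_nm, telomere_eps=0.0)
    n_steps = int(round(duration / dt))
    stride = int(round(sample_every / dt))
    kappa = bending_constant_from_persistence(lp_nm, ff.sigma)
    x = np.zeros((n_beads, 3))
    x[:, 2] = np.arange(n_beads) * 0.97  # near FENE+WCA bond minimum
    bonds = np.column_stack(
        [np.arange(n_beads - 1, dtype=np.int64), np.arange(1, n_beads, dtype=np.int64)]
    )
    angles = np.column_stack(
        [
            np.arange(n_beads - 2, dtype=np.int64),
            np.arange(1, n_beads - 1, dtype=np.int64),
            np.arange(2, n_beads, dtype=np.int64),
        ]
    )
    samples = np.empty((n_steps // stride, n_beads, 3))
    nothing = np.zeros(n_beads, dtype=np.bool_)
    _langevin(
        x,
        bonds=bonds,
        angles=angles,
        angle_kappa=np.full(len(angles), kappa),
        is_cen=nothing,
        is_term=nothing,
        is_rdna=nothing,
        fene_K=ff.fene_K_red,
        fene_R0=ff.fene_R0 / ff.sigma,
        R_nuc=1e6,
        spb_cx=0.0,
        R_spb=1.0,
        nucl_cx=1e7,
        R_nucl=1.0,
        K_indent=0.0,
        tel_eps=0.0,
        tel_cut=1.0,
        dt=dt,
        gamma=gamma,
        n_steps=n_steps,
        sample_stride=stride,
        seed=int(seed) & 0x7FFFFFFF,
        samples=samples,
        v_max=10.0,
    )
    if not np.isfinite(samples).all():
        raise FloatingPointError("free-chain run produced non-finite coordinates")
    return samples * ff.sigma


def measure_persistence_length(
    frames: np.ndarray, max_lag: int = 3, bond_nm: Optional[float] = None
) -> float:
    """Persistence length (nm) from the tangent-tangent correlation decay.

    ``frames`` has shape (n_frames, n_beads, 3) for a single linear chain.
    Fits log <u_i . u_{i+s}> = -s b / Lp through the origin over lags
    1..max_lag.  Short lags only: at larger contour separations the
    tangent correlation of a self-avoiding chain decays slower than
    exponentially (swelling), which would bias the estimate upward.
    """
    frames = np.asarray(frames, dtype=float)
    bonds = np.diff(frames, axis=1)
    lens = np.linalg.norm(bonds, axis=-1, keepdims=True)
    u = bonds / lens
    b = float(lens.mean()) if bond_nm is None else bond_nm
    lags = np.arange(1, max_lag + 1)
    corr = np.array([np.mean(np.sum(u[:, :-s] * u[:, s:], axis=-1)) for s in lags])
    mask = corr > 0.05
    if mask.sum() < 2:
        raise ValueError("tangent correlation decays too fast to fit")
    y = np.log(corr[mask])
    s = lags[mask]
    slope = float((s @ y) / (s @ s))  # least squares constrained through C(0)=1
    return -b / slope
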