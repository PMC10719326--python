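"""Synthetic membrane/drug systems with known statistical structure.

This module is the test bed for every metric in the package.  It builds
a coarse representation of an asymmetric myocardial bilayer — one bead
per lipid head group, placed on jittered lattices at the two head-group
planes — and simulates a drug molecule as an overdamped (Brownian)
walker that reversibly adsorbs to either leaflet surface through a
square-well potential.  Because the generator's diffusivity, well depth,
well geometry and equilibrium occupancy are known in closed form, every
estimator downstream can be validated against ground truth.

Model
-----
The drug's z coordinate (membrane normal, relative to the mid-plane)
evolves by overdamped Langevin dynamics in the potential

    U(z) = -well_depth   for  z_surface - well_width <= |z| <= z_surface
           0             elsewhere in the accessible region,

with ``well_depth`` specified directly in kT.  The tail core
(|z| < core_halfwidth) and the box z faces are reflective walls, so a
molecule started above the membrane stays on that side — mirroring the
observation that unbiased trajectories do not cross the bilayer.  For a
piecewise-constant potential the deterministic drift -D*d(U/kT)/dz
vanishes almost everywhere; the potential steps at the well edges are
handled by a Metropolis acceptance on the proposed Gaussian move, which
preserves the exact Boltzmann distribution exp(-U/kT) (symmetric
proposal + detailed balance).  x and y are free diffusion, wrapped
periodically; z is never wrapped.

The closed-form two-state occupancy of the well band on one side is

    p_well = w * exp(depth) / (w * exp(depth) + L_free)

with ``w = well_width`` and ``L_free`` the accessible width outside the
well on that side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    HEADGROUP_RESIDUES,
    Atom,
    Frame,
    MembraneComposition,
    Topology,
    Trajectory,
)

#: Approximate molecular masses (amu) of the coarse head beads.
_HEAD_MASSES = {"PC": 790.2, "PE": 748.1, "PS": 792.1, "SM": 731.1}
#: Net charges (e): zwitterions are neutral, phosphatidylserine is anionic.
_HEAD_CHARGES = {"PC": 0.0, "PE": 0.0, "PS": -1.0, "SM": 0.0}


class StabilityError(ValueError):
    """The integrator step is too coarse for the requested potential."""


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth parameters of the adsorption generator.

    Defaults emulate the study conditions at coarse scale: a 64-lipid-
    per-leaflet patch (lateral box 6.4 nm at ~0.64 nm^2 per lipid),
    head-group planes at +/-2.2 nm from the mid-plane, body temperature,
    a drug bulk diffusivity of 4e-4 nm^2/ps (4e-6 cm^2/s, typical of a
    ~550 Da solute in water), and a 1.2 us run sampled every 200 ps.
    """

    D_bulk: float = 4.0e-4          # nm^2/ps
    well_depth: float = 4.0         # kT
    well_width: float = 0.5         # nm
    z_surface: float = 2.2          # nm from mid-plane
    core_halfwidth: float = 1.0     # nm; |z| below this is excluded
    box: tuple[float, float, float] = (6.4, 6.4, 10.0)  # nm
    dt: float = 1.0                 # ps
    n_steps: int = 1_200_000
    write_stride: int = 200
    temperature: float = 310.0      # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_bulk <= 0:
            raise ValueError("D_bulk must be positive")
        if self.well_width <= 0:
            raise ValueError("well_width must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.well_depth < 0:
            raise ValueError("well_depth must be non-negative (in kT)")
        if not self.core_halfwidth < self.z_surface:
            raise ValueError("core_halfwidth must be smaller than z_surface")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.z_surface >= self.box[2] / 2:
            raise ValueError("z_surface must lie inside the half-box")
        if self.n_steps < 1 or self.write_stride < 1:
            raise ValueError("n_steps and write_stride must be >= 1")

    @property
    def step_sigma(self) -> float:
        """Per-axis RMS displacement per step, sqrt(2 D dt)."""
        return math.sqrt(2.0 * self.D_bulk * self.dt)

    def potential(self, z: np.ndarray) -> np.ndarray:
        """U(z) in kT for z measured from the mid-plane."""
        z = np.asarray(z, dtype=float)
        az = np.abs(z)
        in_well = (az >= self.z_surface - self.well_width) & (az <= self.z_surface)
        return np.where(in_well, -self.well_depth, 0.0)

    def accessible_interval(self) -> tuple[float, float]:
        """One-sided accessible z interval (upper side), mid-plane frame."""
        return (self.core_halfwidth, self.box[2] / 2.0)

    def equilibrium_well_fraction(self) -> float:
        """Closed-form Boltzmann occupancy of the well band (one side)."""
        lo, hi = self.accessible_interval()
        w_lo = max(lo, self.z_surface - self.well_width)
        w_hi = min(hi, self.z_surface)
        w = max(w_hi - w_lo, 0.0)
        free = (hi - lo) - w
        boltz = w * math.exp(self.well_depth)
        return boltz / (boltz + free)


# ---------------------------------------------------------------------------
# Membrane and drug construction
# ---------------------------------------------------------------------------

def build_membrane_topology(
    composition: MembraneComposition | None = None,
    box: Sequence[float] = (6.4, 6.4, 10.0),
    seed: int = 0,
    z_surface: float = 2.2,
    jitter: float = 0.06,
) -> tuple[Topology, Frame]:
    """Build a coarse bilayer: one bead per lipid head on jittered lattices.

    Beads are placed at z = Lz/2 +/- ``z_surface`` on a square lattice
    with uniform jitter, one lattice per leaflet; head-group identities
    are assigned by a seeded shuffle so composition and geometry are
    decoupled.  Returns the membrane topology and a single frame.

    Raises ``ValueError`` if the composition is empty or a leaflet's
    count exceeds the lattice capacity for the box.
    """
    if composition is None:
        composition = MembraneComposition.myocardial()
    if composition.total == 0:
        raise ValueError("composition has zero lipids")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    z0 = box[2] / 2.0

    atoms: list[Atom] = []
    positions: list[np.ndarray] = []
    atom_id = 1
    residue_id = 1
    for leaflet, sign in (("upper", +1.0), ("lower", -1.0)):
        counts = composition.leaflet_counts(leaflet)
        n = sum(counts.values())
        if n == 0:
            raise ValueError(f"{leaflet} leaflet has zero lipids")
        n_side = math.ceil(math.sqrt(n))
        spacing = box[0] / n_side, box[1] / n_side
        if min(spacing) < 0.3:  # head beads cannot pack tighter than ~0.3 nm
            raise ValueError(
                f"{leaflet} leaflet: {n} lipids exceed the lattice capacity "
                f"of the {box[0]:.2f} x {box[1]:.2f} nm box"
            )
        # seeded shuffle of head-group identities over lattice sites
        classes = [cls for cls, k in sorted(counts.items()) for _ in range(k)]
        rng.shuffle(classes)
        sites = [(i, j) for i in range(n_side) for j in range(n_side)][:n]
        for cls, (i, j) in zip(classes, sites):
            x = (i + 0.5) * spacing[0] + rng.uniform(-jitter, jitter)
            y = (j + 0.5) * spacing[1] + rng.uniform(-jitter, jitter)
            z = z0 + sign * z_surface + rng.uniform(-jitter, jitter)
            positions.append(np.array([x % box[0], y % box[1], z]))
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    name=f"{cls}H",
                    element="P",
                    mass=_HEAD_MASSES[cls],
                    charge=_HEAD_CHARGES[cls],
                    residue_name=HEADGROUP_RESIDUES[cls],
                    residue_id=residue_id,
                    leaflet=leaflet,
                    hbond_role="acceptor",
                )
            )
            atom_id += 1
            residue_id += 1
    topology = Topology(atoms)
    frame = Frame(time=0.0, box=box, positions=np.array(positions))
    return topology, frame


def add_drug(
    topology: Topology,
    frame: Frame,
    z_offset: float = 1.3,
    with_satellites: bool = True,
) -> tuple[Topology, Frame, int]:
    """Append a drug molecule above the upper leaflet.

    The drug is a single heavy bead for the dynamics; when
    ``with_satellites`` is true it rigidly carries a polar hydrogen and
    an acceptor oxygen so hydrogen-bond and dipole analyses have
    multi-site input.  The bead is placed ``z_offset`` nm above the
    upper head-group plane (the molecules start ~1.3 nm above the
    membrane).  Returns (topology, frame, bead_index).
    """
    df = topology.to_dataframe()
    next_id = int(df["atom_id"].max()) + 1 if len(df) else 1
    next_res = int(df["residue_id"].max()) + 1 if len(df) else 1
    upper = topology.leaflet_indices("upper")
    if upper.size:
        z_top = float(frame.positions[upper, 2].mean())
    else:
        z_top = float(frame.box[2] / 2.0)
    center = np.array([frame.box[0] / 2.0, frame.box[1] / 2.0, z_top + z_offset])

    new_atoms = [
        Atom(next_id, "DC", "C", 543.5, 0.25, "DRUG", next_res,
             hbond_role="donor_and_acceptor"),
    ]
    new_pos = [center]
    if with_satellites:
        new_atoms.append(
            Atom(next_id + 1, "DH", "H", 1.008, 0.25, "DRUG", next_res,
                 hbond_role="polar_hydrogen", bonded_donor_id=next_id)
        )
        new_pos.append(center + np.array([0.10, 0.0, 0.0]))
        new_atoms.append(
            Atom(next_id + 2, "DO", "O", 15.999, -0.50, "DRUG", next_res,
                 hbond_role="acceptor")
        )
        new_pos.append(center + np.array([-0.12, 0.0, 0.0]))

    new_df = pd.concat(
        [df, Topology(new_atoms).to_dataframe()], ignore_index=True
    )
    combined = Topology(new_df)
    positions = np.vstack([frame.positions, np.array(new_pos)])
    bead_index = len(df)
    return combined, Frame(frame.time, frame.box, positions), bead_index


def build_system(
    params: SyntheticParams,
    composition: MembraneComposition | None = None,
    with_satellites: bool = True,
) -> tuple[Topology, Frame, int]:
    """Membrane plus drug in one call, seeded from ``params.seed``."""
    topology, frame = build_membrane_topology(
        composition, box=params.box, seed=params.seed, z_surface=params.z_surface
    )
    return add_drug(topology, frame, with_satellites=with_satellites)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by repeated reflection."""
    width = hi - lo
    y = np.mod(np.asarray(z, dtype=float) - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def sample_boltzmann_z(params: SyntheticParams, rng: np.random.Generator,
                       size: int = 1) -> np.ndarray:
    """Exact equilibrium z samples on the upper side (mid-plane frame).

    Inverse-CDF sampling over the piecewise-constant Boltzmann density;
    used to initialise equilibrium studies without burn-in.
    """
    lo, hi = params.accessible_interval()
    edges = np.unique(np.clip(
        [lo, params.z_surface - params.well_width, params.z_surface, hi], lo, hi
    ))
    mids = 0.5 * (edges[:-1] + edges[1:])
    weights = np.diff(edges) * np.exp(-params.potential(mids))
    probs = weights / weights.sum()
    seg = rng.choice(len(probs), size=size, p=probs)
    return rng.uniform(edges[seg], edges[seg + 1])


def _walk_z_scalar(params: SyntheticParams, z0: float, n_steps: int,
                   rng: np.random.Generator, sample_stride: int) -> np.ndarray:
    """Single-walker fast path of :func:`walk_z` (same stationary law)."""
    lo, hi = params.accessible_interval()
    w_lo = max(lo, params.z_surface - params.well_width)
    w_hi = min(hi, params.z_surface)
    exp_neg_depth = math.exp(-params.well_depth)
    noise = rng.normal(0.0, params.step_sigma, n_steps)
    out = np.empty(n_steps // sample_stride + 1)
    z = float(z0)
    out[0] = z
    in_well = w_lo <= z <= w_hi
    k = 1
    for i in range(n_steps):
        zp = z + noise[i]
        if zp > hi:
            zp = 2.0 * hi - zp
        elif zp < lo:
            zp = 2.0 * lo - zp
        if zp > hi or zp < lo:  # pathological double bounce
            zp = float(_reflect(zp, lo, hi))
        prop_in_well = w_lo <= zp <= w_hi
        if in_well and not prop_in_well:
            # uphill move out of the well: Metropolis acceptance
            if rng.random() < exp_neg_depth:
                z, in_well = zp, prop_in_well
        else:
            z, in_well = zp, prop_in_well
        if (i + 1) % sample_stride == 0:
            out[k] = z
            k += 1
    return out[:k]


def walk_z(
    params: SyntheticParams,
    z0: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    sample_stride: int = 1,
) -> np.ndarray:
    """Metropolis-adjusted Brownian walk of z walkers in the square well.

    ``z0`` is an array of starting coordinates on the upper side
    (mid-plane frame).  Returns an array of shape
    ``(n_samples, n_walkers)`` with positions every ``sample_stride``
    steps, including the initial state.  The chain's stationary law is
    exactly exp(-U/kT) on the reflected interval.
    """
    if params.step_sigma > params.well_width:
        raise StabilityError(
            f"RMS step {params.step_sigma:.3g} nm exceeds well_width "
            f"{params.well_width:.3g} nm; reduce dt"
        )
    z = np.array(z0, dtype=float).reshape(-1)
    if z.size == 1:
        return _walk_z_scalar(params, float(z[0]), n_steps, rng,
                              sample_stride)[:, None]
    lo, hi = params.accessible_interval()
    n_walkers = z.size
    out = np.empty((n_steps // sample_stride + 1, n_walkers))
    out[0] = z
    u = params.potential(z)
    sigma = params.step_sigma
    k = 1
    for step in range(1, n_steps + 1):
        prop = _reflect(z + rng.normal(0.0, sigma, n_walkers), lo, hi)
        u_prop = params.potential(prop)
        du = u_prop - u
        accept = du <= 0.0
        hill = ~accept
        if hill.any():
            accept[hill] = rng.random(int(hill.sum())) < np.exp(-du[hill])
        z = np.where(accept, prop, z)
        u = np.where(accept, u_prop, u)
        if step % sample_stride == 0:
            out[k] = z
            k += 1
    return out[:k]


def simulate_adsorption(
    params: SyntheticParams,
    topology: Topology,
    initial_frame: Frame,
) -> Trajectory:
    """Simulate the drug bead diffusing and adsorbing; membrane static.

    The drug residue's heaviest atom is the dynamic bead; any other
    DRUG atoms co-move rigidly at their initial offsets.  x and y are
    free diffusion wrapped into the box; z follows :func:`walk_z` in the
    mid-plane frame.  Frames are stored every ``write_stride`` steps,
    with time stamps in ps.  Identical params (including seed) give a
    bitwise-identical trajectory.
    """
    drug = topology.residue_indices("DRUG")
    if drug.size == 0:
        raise ValueError("topology has no DRUG residue")
    bead = int(drug[np.argmax(topology.masses[drug])])
    satellites = drug[drug != bead]
    offsets = initial_frame.positions[satellites] - initial_frame.positions[bead]

    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.box, dtype=float)
    z0_plane = box[2] / 2.0

    # z in the mid-plane frame; start from the initial frame's z
    z_start = initial_frame.positions[bead, 2] - z0_plane
    lo, hi = params.accessible_interval()
    z_start = float(np.clip(z_start, lo, hi))
    z_path = walk_z(params, np.array([z_start]), params.n_steps, rng,
                    sample_stride=params.write_stride)[:, 0]

    # lateral free diffusion, wrapped; noise drawn after the z stream so
    # the z dynamics are reproducible regardless of lateral handling
    n_frames = z_path.size
    lat_steps = rng.normal(
        0.0, math.sqrt(2.0 * params.D_bulk * params.dt * params.write_stride),
        size=(n_frames - 1, 2),
    )
    xy = np.empty((n_frames, 2))
    xy[0] = initial_frame.positions[bead, :2]
    xy[1:] = xy[0] + np.cumsum(lat_steps, axis=0)
    xy = np.mod(xy, box[:2])

    frames = []
    base = initial_frame.positions.copy()
    for i in range(n_frames):
        pos = base.copy()
        pos[bead] = [xy[i, 0], xy[i, 1], z_path[i] + z0_plane]
        if satellites.size:
            pos[satellites] = pos[bead] + offsets
        frames.append(Frame(time=i * params.dt * params.write_stride,
                            box=box.copy(), positions=pos))
    return Trajectory(topology, frames,
                      frame_interval=params.dt * params.write_stride)


def equilibrium_z_samples(
    params: SyntheticParams,
    n_walkers: int = 256,
    n_steps: int = 20_000,
    sample_stride: int = 1_000,
    seed: int | None = None,
    burn_in: int = 0,
    exact_init: bool = False,
) -> np.ndarray:
    """Equilibrium z samples from many independent walkers (upper side).

    With ``exact_init`` walkers start from the exact Boltzmann law;
    otherwise they start uniform over the accessible interval and
    ``burn_in`` steps are discarded.  Returns a flat array of samples.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.accessible_interval()
    if exact_init:
        z0 = sample_boltzmann_z(params, rng, n_walkers)
    else:
        z0 = rng.uniform(lo, hi, n_walkers)
    if burn_in:
        z0 = walk_z(params, z0, burn_in, rng, sample_stride=burn_in)[-1]
    path = walk_z(params, z0, n_steps, rng, sample_stride=sample_stride)
    return path[1:].ravel()


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def _unit_perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        p = w - np.dot(w, u) * u
        norm = np.linalg.norm(p)
        if norm > 1e-8:
            return p / norm


def make_hbond_fixture(
    n_bonded: int,
    n_near_miss_distance: int,
    n_near_miss_angle: int,
    seed: int = 0,
) -> tuple[Topology, Frame]:
    """Donor-hydrogen-acceptor triads with controlled geometry.

    Exactly ``n_bonded`` triads satisfy the geometric criterion
    (r_DoA <= 0.35 nm and donor-centred angle <= 30 deg);
    ``n_near_miss_distance`` triads sit at r = 0.36 nm with a perfect
    angle, and ``n_near_miss_angle`` triads at r = 0.30 nm with a 35 deg
    angle.  Triads are isolated on a coarse grid (>= 1.5 nm apart) so no
    cross-triad pair can satisfy the criterion; random orientations are
    seeded.  Donors/hydrogens carry residue name ``DON``, acceptors
    ``ACC``, so groups can be selected by residue.
    """
    for n in (n_bonded, n_near_miss_distance, n_near_miss_angle):
        if n < 0:
            raise ValueError("triad counts must be non-negative")
    rng = np.random.default_rng(seed)
    specs: list[tuple[float, float]] = []  # (r_DoA, angle_deg)
    for _ in range(n_bonded):
        specs.append((rng.uniform(0.26, 0.34), rng.uniform(0.0, 25.0)))
    specs += [(0.36, 0.0)] * n_near_miss_distance
    specs += [(0.30, 35.0)] * n_near_miss_angle
    n_triads = len(specs)
    if n_triads == 0:
        raise ValueError("fixture needs at least one triad")

    spacing = 1.5
    n_side = math.ceil(n_triads ** (1.0 / 3.0))
    box = np.full(3, max(5.0, n_side * spacing))
    sites = [
        (i, j, k)
        for i in range(n_side)
        for j in range(n_side)
        for k in range(n_side)
    ][:n_triads]

    atoms: list[Atom] = []
    positions: list[np.ndarray] = []
    atom_id = 1
    for res_id, ((r, angle_deg), site) in enumerate(zip(specs, sites), start=1):
        origin = (np.array(site) + 0.5) * spacing
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        perp = _unit_perpendicular(u, rng)
        theta = math.radians(angle_deg)
        v = math.cos(theta) * u + math.sin(theta) * perp
        donor_pos = origin
        h_pos = origin + 0.10 * u
        acc_pos = origin + r * v
        atoms.append(Atom(atom_id, "ND", "N", 14.007, 0.0, "DON", res_id,
                          hbond_role="donor"))
        atoms.append(Atom(atom_id + 1, "HD", "H", 1.008, 0.0, "DON", res_id,
                          hbond_role="polar_hydrogen", bonded_donor_id=atom_id))
        atoms.append(Atom(atom_id + 2, "OA", "O", 15.999, 0.0, "ACC",
                          res_id + n_triads, hbond_role="acceptor"))
        positions += [donor_pos, h_pos, acc_pos]
        atom_id += 3
    topology = Topology(atoms)
    frame = Frame(time=0.0, box=box, positions=np.array(positions))
    return topology, frame


def make_residence_fixture(
    fraction_within: float,
    n_frames: int,
    frame_interval: float = 1000.0,
    seed: int = 0,
) -> Trajectory:
    """Trajectory with a prescribed within-cutoff fraction near the lower leaflet.

    ``round(fraction_within * n_frames)`` frames place the drug 0.25 nm
    below a lower-leaflet bead (directly underneath it, so the shortest
    molecule-surface distance is exactly 0.25 nm); the remaining frames
    place it 1.5 nm below.  Both distances bracket the 0.3 nm residence
    cutoff, so the expected residence percentage near the lower leaflet
    is 100 * fraction_within.
    """
    if not 0.0 <= fraction_within <= 1.0:
        raise ValueError("fraction_within must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    membrane, frame0 = build_membrane_topology(seed=seed)
    topology, frame0, bead = add_drug(membrane, frame0, with_satellites=False)

    lower = topology.leaflet_indices("lower")
    # pick the lower-leaflet bead closest to the lateral box centre
    lateral = frame0.positions[lower, :2] - frame0.box[:2] / 2.0
    anchor = int(lower[np.argmin(np.linalg.norm(lateral, axis=1))])
    anchor_pos = frame0.positions[anchor]

    n_within = round(fraction_within * n_frames)
    frames = []
    for i in range(n_frames):
        dist = 0.25 if i < n_within else 1.5
        pos = frame0.positions.copy()
        pos[bead] = anchor_pos - np.array([0.0, 0.0, dist])
        frames.append(Frame(time=i * frame_interval, box=frame0.box.copy(),
                            positions=pos))
    return Trajectory(topology, frames, frame_interval=frame_interval)
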