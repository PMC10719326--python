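"""Trajectory-derived anchorage metrics.

Four scalar metrics quantify how strongly a molecule anchors to a
bilayer surface:

* **residence time** — the percentage of analysed frames in which the
  molecule's closest atom lies within a cutoff (default 0.3 nm, the
  average length of a biological salt bridge) of a leaflet's atoms;
* **hydrogen-bond count** — the time-averaged number of geometric
  hydrogen bonds (donor-acceptor distance <= 0.35 nm and donor-centred
  angle <= 30 deg) between the molecule and a membrane selection;
* **diffusivity reduction** — the Einstein-relation diffusion
  coefficient near the membrane relative to bulk, from the slope of the
  mean square displacement;
* **mid-plane proximity** — the molecule's mean |z| distance from the
  bilayer mid-plane, evaluated separately above and below the membrane.

Supporting profiles (1-D mass density, Boltzmann-inversion free energy)
and a block-averaged uncertainty protocol are provided alongside.
Uncertainties follow the block convention of discarding the first third
of the trajectory and splitting the remainder into four blocks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .geometry import (
    assign_midplane,
    min_image_displacement,
    pairwise_min_image_distances,
)

logger = logging.getLogger(__name__)

#: amu/nm^3 -> kg/m^3
AMU_PER_NM3_TO_KG_PER_M3 = 1.66053906660
#: 1 e*nm in Debye
E_NM_TO_DEBYE = 48.0321

DEFAULT_DISCARD_FRACTION = 1.0 / 3.0
DEFAULT_N_BLOCKS = 4


@dataclass
class MetricResult:
    """A scalar metric with block-averaged uncertainty and provenance."""

    value: float
    block_std: float
    n_blocks: int
    selection: str
    window: tuple[float, float]
    n_frames: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.block_std) and self.block_std < 0:
            raise ValueError("block_std must be non-negative")
        if np.isfinite(self.block_std) and self.n_blocks < 2:
            raise ValueError("a reported block_std needs n_blocks >= 2")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``r_max`` bounds the donor-acceptor distance; ``angle_max`` bounds
    the angle.  With the default ``angle_at="donor"`` convention the
    angle is measured at the donor between the donor->hydrogen and
    donor->acceptor vectors (hydrogen-donor-acceptor angle);
    ``angle_at="hydrogen"`` uses the deviation from linearity at the
    hydrogen instead.  Both bounds are inclusive.
    """

    r_max: float = 0.35
    angle_max: float = 30.0
    angle_at: str = "donor"

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not 0 < self.angle_max < 90:
            raise ValueError("angle_max must lie in (0, 90) degrees")
        if self.angle_at not in ("donor", "hydrogen"):
            raise ValueError("angle_at must be 'donor' or 'hydrogen'")


@dataclass
class DiffusionResult:
    """Einstein-relation diffusion estimate from an MSD fit."""

    D: float                     # nm^2/ps
    per_axis_D: np.ndarray       # (3,) nm^2/ps
    fit_r2: float
    fit_window: tuple[float, float]   # ps
    D_block_std: float = float("nan")
    ratio_pct: float | None = None    # 100 * D_membrane / D_bulk when paired

    @property
    def D_1e5_cm2_per_s(self) -> float:
        """D expressed in units of 1e-5 cm^2/s (1 nm^2/ps = 1e3 of them)."""
        return self.D * 1.0e3


@dataclass
class DensityProfile:
    """Per-species 1-D mass density along z, relative to the mid-plane."""

    bin_edges: np.ndarray            # nm
    values: dict[str, np.ndarray]    # kg/m^3 per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"z": self.bin_centers})
        for name, vals in self.values.items():
            df[name] = vals
        return df


@dataclass
class MSDCurve:
    """Mean square displacement versus lag time, total and per axis."""

    lags: np.ndarray        # ps
    total: np.ndarray       # nm^2
    per_axis: np.ndarray    # (n_lags, 3) nm^2


# ---------------------------------------------------------------------------
# Windows and block averaging
# ---------------------------------------------------------------------------

def analysis_window(times: np.ndarray,
                    discard_fraction: float = DEFAULT_DISCARD_FRACTION
                    ) -> tuple[float, float]:
    """Default equilibrated window: drop the first ``discard_fraction``."""
    times = np.asarray(times, dtype=float)
    t0, t1 = float(times[0]), float(times[-1])
    return (t0 + discard_fraction * (t1 - t0), t1)


def window_mask(times: np.ndarray, window: tuple[float, float] | None
                ) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if window is None:
        return np.ones(times.size, dtype=bool)
    lo, hi = window
    return (times >= lo) & (times <= hi)


def block_std(series: np.ndarray,
              n_blocks: int = DEFAULT_N_BLOCKS,
              reduce: Callable[[np.ndarray], float] = np.mean) -> float:
    """Sample standard deviation of a metric across consecutive blocks.

    The series is split into ``n_blocks`` consecutive, near-equal,
    non-empty blocks; ``reduce`` evaluates the metric independently on
    each block and the sample standard deviation (ddof=1) of the block
    values is returned.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    series = np.asarray(series, dtype=float)
    if series.size < n_blocks:
        raise ValueError(
            f"series of length {series.size} cannot form {n_blocks} "
            "non-empty blocks"
        )
    blocks = np.array_split(series, n_blocks)
    values = np.array([reduce(b) for b in blocks], dtype=float)
    return float(np.std(values, ddof=1))


def _blocked_uncertainty(series: np.ndarray, times: np.ndarray,
                         n_blocks: int,
                         discard_fraction: float) -> tuple[float, int]:
    """Block std over the equilibrated tail of a per-frame series."""
    mask = window_mask(times, analysis_window(times, discard_fraction))
    tail = series[mask]
    if tail.size < n_blocks:
        return float("nan"), 0
    return block_std(tail, n_blocks=n_blocks), n_blocks


# ---------------------------------------------------------------------------
# Residence time
# ---------------------------------------------------------------------------

def residence_time(
    traj: Trajectory,
    drug: np.ndarray,
    leaflet_atoms: np.ndarray,
    cutoff: float = 0.3,
    window: tuple[float, float] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    selection: str = "",
) -> MetricResult:
    """Percentage of analysed frames with the molecule within ``cutoff``.

    The molecule-surface distance of a frame is the shortest
    minimum-image distance between any drug atom and any atom of the
    leaflet selection; a frame counts as resident when that distance is
    <= ``cutoff`` (inclusive).  The value is computed over ``window``
    (default: the full trajectory); the block uncertainty follows the
    equilibrated-tail protocol.
    """
    drug = np.asarray(drug, dtype=int)
    leaflet_atoms = np.asarray(leaflet_atoms, dtype=int)
    if drug.size == 0:
        raise ValueError("drug selection is empty")
    if leaflet_atoms.size == 0:
        raise ValueError("leaflet selection is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    times = traj.times
    mask = window_mask(times, window)
    if not mask.any():
        raise ValueError("analysis window contains no frames")

    within = np.empty(traj.n_frames, dtype=float)
    for i, frame in enumerate(traj.frames):
        d = pairwise_min_image_distances(
            frame.positions[drug], frame.positions[leaflet_atoms], frame.box
        )
        within[i] = 1.0 if d.min() <= cutoff else 0.0

    value = 100.0 * float(within[mask].mean())
    std, nb = _blocked_uncertainty(within[mask], times[mask], n_blocks,
                                   discard_fraction)
    t_sel = times[mask]
    logger.info("residence_time[%s]: %d frames in window (%.0f..%.0f ps)",
                selection, int(mask.sum()), t_sel[0], t_sel[-1])
    return MetricResult(
        value=value,
        block_std=float("nan") if nb == 0 else 100.0 * std,
        n_blocks=nb if nb else 0,
        selection=selection or f"{drug.size} drug atoms vs "
                               f"{leaflet_atoms.size} leaflet atoms",
        window=(float(t_sel[0]), float(t_sel[-1])),
        n_frames=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donors_with_hydrogens(topology: Topology, group: np.ndarray
                           ) -> list[tuple[int, np.ndarray]]:
    """(donor index, indices of its polar hydrogens) for donors in group."""
    group_set = set(int(i) for i in group)
    roles = topology.hbond_roles
    donor_ids = topology.bonded_donor_ids
    atom_ids = topology.atom_ids
    out = []
    for i in group:
        if roles[i] in ("donor", "donor_and_acceptor"):
            aid = atom_ids[i]
            hyd = np.flatnonzero((roles == "polar_hydrogen") & (donor_ids == aid))
            if hyd.size:
                out.append((int(i), hyd))
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle(s) between vectors along the last axis, degrees."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.sum(v1 * v2, axis=-1) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _count_hbonds_frame(
    frame: Frame,
    topology: Topology,
    donors: list[tuple[int, np.ndarray]],
    acceptors: np.ndarray,
    criterion: HBondCriterion,
) -> list[tuple[int, int]]:
    """(donor index, acceptor index) pairs bonded in one frame.

    A donor-acceptor pair bonds when the minimum-image distance is
    within ``r_max`` and at least one of the donor's polar hydrogens
    satisfies the angle condition; each qualifying pair counts once.
    """
    bonds = []
    pos, box = frame.positions, frame.box
    if not donors or acceptors.size == 0:
        return bonds
    acc_pos = pos[acceptors]
    for d_idx, hyds in donors:
        d_vec = min_image_displacement(pos[d_idx], acc_pos, box)
        r = np.linalg.norm(d_vec, axis=-1)
        close = np.flatnonzero((r <= criterion.r_max) & (acceptors != d_idx))
        if close.size == 0:
            continue
        for a_local in close:
            a_idx = int(acceptors[a_local])
            ok = False
            for h in hyds:
                dh = min_image_displacement(pos[d_idx], pos[h], box)
                if criterion.angle_at == "donor":
                    ang = _angle_deg(dh, d_vec[a_local])
                else:  # deviation from linearity at the hydrogen
                    ha = min_image_displacement(pos[h], acc_pos[a_local], box)
                    ang = _angle_deg(dh, ha)
                if ang <= criterion.angle_max:
                    ok = True
                    break
            if ok:
                bonds.append((d_idx, a_idx))
    return bonds


def hbond_count(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    criterion: HBondCriterion | None = None,
    window: tuple[float, float] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
    selection: str = "",
) -> tuple[MetricResult, pd.Series]:
    """Time-averaged hydrogen bonds per frame between two groups.

    Both donor->acceptor directions are counted: donors (with resolvable
    polar hydrogens) in ``group_a`` against acceptors in ``group_b`` and
    vice versa.  Returns the metric and an attribution Series giving the
    mean bonds/frame credited to each ``group_b`` residue name (the
    membrane side in the usual drug-vs-leaflet call).

    A group with no donors or no acceptors is not an error: the count is
    simply zero for that direction, with a logged warning.
    """
    criterion = criterion or HBondCriterion()
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    topo = traj.topology
    roles = topo.hbond_roles

    donors_a = _donors_with_hydrogens(topo, group_a)
    donors_b = _donors_with_hydrogens(topo, group_b)
    acc_a = group_a[np.isin(roles[group_a], ("acceptor", "donor_and_acceptor"))]
    acc_b = group_b[np.isin(roles[group_b], ("acceptor", "donor_and_acceptor"))]
    if not donors_a and not donors_b:
        logger.warning("hbond_count[%s]: neither group has donors with "
                       "polar hydrogens; count is zero", selection)
    if acc_a.size == 0 and acc_b.size == 0:
        logger.warning("hbond_count[%s]: neither group has acceptors; "
                       "count is zero", selection)

    times = traj.times
    mask = window_mask(times, window)
    if not mask.any():
        raise ValueError("analysis window contains no frames")

    res_names = topo.residue_names
    counts = np.zeros(traj.n_frames)
    attribution: dict[str, float] = {}
    for i, frame in enumerate(traj.frames):
        if not mask[i]:
            continue
        bonds = _count_hbonds_frame(frame, topo, donors_a, acc_b, criterion)
        partners = [a for _, a in bonds]
        bonds_rev = _count_hbonds_frame(frame, topo, donors_b, acc_a, criterion)
        partners += [d for d, _ in bonds_rev]
        counts[i] = len(bonds) + len(bonds_rev)
        for p in partners:
            name = res_names[p]
            attribution[name] = attribution.get(name, 0.0) + 1.0

    n_sel = int(mask.sum())
    value = float(counts[mask].mean())
    std, nb = _blocked_uncertainty(counts[mask], times[mask], n_blocks,
                                   discard_fraction)
    attr = pd.Series(
        {k: v / n_sel for k, v in sorted(attribution.items())},
        dtype=float, name="bonds_per_frame",
    )
    t_sel = times[mask]
    return (
        MetricResult(
            value=value,
            block_std=std,
            n_blocks=nb if nb else 0,
            selection=selection or "hbonds",
            window=(float(t_sel[0]), float(t_sel[-1])),
            n_frames=n_sel,
        ),
        attr,
    )


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def center_of_mass(traj: Trajectory, group: np.ndarray) -> np.ndarray:
    """Per-frame mass-weighted centre of the group; (n_frames, 3)."""
    group = np.asarray(group, dtype=int)
    m = traj.topology.masses[group]
    pos = traj.positions()[:, group, :]
    return np.einsum("fgc,g->fc", pos, m) / m.sum()


def unwrap_path(com: np.ndarray, boxes: np.ndarray,
                axes: tuple[int, ...] = (0, 1)) -> np.ndarray:
    """Remove periodic wrap jumps along the given axes.

    Consecutive displacements along wrapped axes are replaced by their
    minimum image, which is exact as long as the true per-frame motion
    is below half a box length.  z (axis 2) is stored unwrapped by the
    generator convention and is checked, not altered: a z jump beyond
    half the box raises, advising that the trajectory violates the
    convention.
    """
    com = np.array(com, dtype=float)
    if com.shape[0] < 2:
        return com
    disp = np.diff(com, axis=0)
    box = boxes[:-1]
    for ax in range(3):
        if ax in axes:
            disp[:, ax] -= box[:, ax] * np.round(disp[:, ax] / box[:, ax])
        else:
            bad = np.abs(disp[:, ax]) > box[:, ax] / 2.0
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"axis {ax} jump of {disp[i, ax]:.3g} nm between frames "
                    f"{i} and {i + 1} exceeds half the box; trajectories must "
                    "be stored unwrapped in z (the generator convention) — "
                    "re-export without wrapping the membrane normal"
                )
    out = np.empty_like(com)
    out[0] = com[0]
    out[1:] = com[0] + np.cumsum(disp, axis=0)
    return out


def _msd_fft_1d(x: np.ndarray, n_lags: int) -> np.ndarray:
    """MSD over all time origins for one coordinate, FFT accelerated."""
    n = x.size
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real
    sq = x * x
    ssum = 2.0 * sq.sum()
    counts = n - np.arange(n)
    s1 = np.empty(n)
    s1[0] = ssum
    run = ssum
    for m in range(1, n):
        run -= sq[m - 1] + sq[n - m]
        s1[m] = run
    msd = (s1 - 2.0 * acf) / counts
    return msd[:n_lags]


def msd(
    traj: Trajectory,
    drug: np.ndarray,
    max_lag_fraction: float = 0.5,
    window: tuple[float, float] | None = None,
    wrapped_axes: tuple[int, ...] = (0, 1),
) -> MSDCurve:
    """Mean square displacement of the group's centre of mass.

    Averages over all time origins (sliding window) for lags up to
    ``max_lag_fraction`` of the analysed window.  Lateral axes are
    unwrapped by minimum image; z must already be unwrapped.  Requires a
    uniform frame spacing and at least 10 frames.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    times = traj.times
    mask = window_mask(times, window)
    idx = np.flatnonzero(mask)
    if idx.size < 10:
        raise ValueError("msd needs at least 10 frames in the window")
    t = times[idx]
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("msd requires uniformly spaced frames")
    com = center_of_mass(traj, drug)[idx]
    com = unwrap_path(com, traj.boxes()[idx], axes=wrapped_axes)

    n = idx.size
    n_lags = max(2, int(max_lag_fraction * n))
    per_axis = np.stack(
        [_msd_fft_1d(com[:, ax], n_lags) for ax in range(3)], axis=1
    )
    per_axis[0] = 0.0  # exact by definition
    total = per_axis.sum(axis=1)
    lags = np.arange(n_lags) * float(dts[0])
    return MSDCurve(lags=lags, total=total, per_axis=per_axis)


def diffusion_coefficient(
    curve: MSDCurve,
    fit_window: tuple[float, float] | None = None,
    dim: int = 3,
) -> DiffusionResult:
    """Least-squares Einstein-relation fit: D = slope / (2 * dim).

    ``fit_window`` is a lag-time range in ps; the default spans 10-50 %
    of the curve's maximum lag (a standard bias/variance compromise).
    A negative fitted slope is clamped to D = 0 with a warning.
    Per-axis coefficients use dim = 1 on each axis's MSD.
    """
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    max_lag = float(curve.lags[-1])
    if fit_window is None:
        fit_window = (0.1 * max_lag, 0.5 * max_lag)
    lo, hi = fit_window
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 3:
        raise ValueError(
            f"fit window {fit_window} contains {int(sel.sum())} points; need >= 3"
        )
    x = curve.lags[sel]
    y = curve.total[sel]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        warnings.warn("negative MSD slope; clamping D to 0", stacklevel=2)
        slope = 0.0
    per_axis = np.empty(3)
    for ax in range(3):
        s_ax = np.polyfit(x, curve.per_axis[sel, ax], 1)[0]
        per_axis[ax] = max(s_ax, 0.0) / 2.0
    return DiffusionResult(
        D=slope / (2.0 * dim),
        per_axis_D=per_axis,
        fit_r2=max(0.0, min(1.0, r2)),
        fit_window=(float(lo), float(hi)),
    )


def estimate_diffusion(
    traj: Trajectory,
    drug: np.ndarray,
    max_lag_fraction: float = 0.1,
    fit_window: tuple[float, float] | None = None,
    dim: int = 3,
    n_blocks: int = DEFAULT_N_BLOCKS,
    window: tuple[float, float] | None = None,
) -> DiffusionResult:
    """MSD fit plus a block-spread uncertainty on D.

    The trajectory window is additionally split into ``n_blocks``
    consecutive segments, D is refit per segment and the sample standard
    deviation of the segment values is reported as ``D_block_std``.
    """
    curve = msd(traj, drug, max_lag_fraction=max_lag_fraction, window=window)
    result = diffusion_coefficient(curve, fit_window=fit_window, dim=dim)

    times = traj.times
    mask = window_mask(times, window)
    t = times[mask]
    edges = np.linspace(t[0], t[-1], n_blocks + 1)
    block_ds = []
    for b in range(n_blocks):
        wb = (edges[b], edges[b + 1])
        try:
            c = msd(traj, drug, max_lag_fraction=max_lag_fraction, window=wb)
            fw = result.fit_window
            if fw[1] > c.lags[-1]:
                fw = (0.1 * c.lags[-1], 0.5 * c.lags[-1])
            block_ds.append(diffusion_coefficient(c, fit_window=fw, dim=dim).D)
        except ValueError:
            continue
    if len(block_ds) >= 2:
        result.D_block_std = float(np.std(block_ds, ddof=1))
    return result


def diffusivity_ratio_pct(d_membrane: DiffusionResult,
                          d_bulk: DiffusionResult) -> float:
    """Percentage ratio 100 * D_membrane / D_bulk."""
    if d_bulk.D <= 0:
        raise ValueError("bulk diffusivity must be positive to form a ratio")
    return 100.0 * d_membrane.D / d_bulk.D


# ---------------------------------------------------------------------------
# Density, mid-plane location, free energy
# ---------------------------------------------------------------------------

def density_profile(
    traj: Trajectory,
    groups: Mapping[str, np.ndarray],
    bin_width: float = 0.1,
    z_range: tuple[float, float] | None = None,
    window: tuple[float, float] | None = None,
) -> DensityProfile:
    """Time-averaged 1-D mass density (kg/m^3) along the membrane normal.

    z is measured from the per-frame mid-plane.  Each group's mass
    histogram is divided by the slab volume (lateral box area times
    ``bin_width``) and converted from amu/nm^3.  ``z_range`` defaults to
    the symmetric half-box of the first frame; the number of bins is
    chosen so widths are exactly ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times = traj.times
    mask = window_mask(times, window)
    if not mask.any():
        raise ValueError("analysis window contains no frames")
    topo = traj.topology
    lipids = topo.lipid_indices()
    if z_range is None:
        half = traj.frames[0].box[2] / 2.0
        z_range = (-half, half)
    n_bins = max(1, math.ceil((z_range[1] - z_range[0]) / bin_width - 1e-9))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)

    sums = {name: np.zeros(n_bins) for name in groups}
    n_frames = 0
    for i, frame in enumerate(traj.frames):
        if not mask[i]:
            continue
        n_frames += 1
        z0 = assign_midplane(frame, topo, lipids)
        area = frame.box[0] * frame.box[1]
        for name, idx in groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                continue
            z = frame.positions[idx, 2] - z0
            hist, _ = np.histogram(z, bins=edges,
                                   weights=topo.masses[idx])
            sums[name] += hist / (area * bin_width)
    values = {
        name: AMU_PER_NM3_TO_KG_PER_M3 * s / n_frames
        for name, s in sums.items()
    }
    return DensityProfile(bin_edges=edges, values=values)


def midplane_location(
    traj: Trajectory,
    drug: np.ndarray,
    window: tuple[float, float] | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    discard_fraction: float = DEFAULT_DISCARD_FRACTION,
) -> tuple[MetricResult, MetricResult]:
    """Mean |z| distance of the molecule from the mid-plane, per side.

    Frames are partitioned by the sign of the drug centre-of-mass z
    relative to the per-frame mid-plane (z = 0 counts as the upper
    side; there is no third category for molecules inside the bilayer).
    Returns (upper_side, lower_side); a side with no frames reports a
    NaN value with ``n_frames = 0``.
    """
    drug = np.asarray(drug, dtype=int)
    times = traj.times
    mask = window_mask(times, window)
    if not mask.any():
        raise ValueError("analysis window contains no frames")
    topo = traj.topology
    lipids = topo.lipid_indices()
    com = center_of_mass(traj, drug)
    rel_z = np.array([
        com[i, 2] - assign_midplane(traj.frames[i], topo, lipids)
        for i in range(traj.n_frames)
    ])

    t_sel = times[mask]
    results = []
    for side, side_mask in (("upper", rel_z >= 0), ("lower", rel_z < 0)):
        sel = mask & side_mask
        n = int(sel.sum())
        if n == 0:
            logger.warning("midplane_location: no frames on the %s side", side)
            results.append(MetricResult(
                value=float("nan"), block_std=float("nan"), n_blocks=0,
                selection=f"{side} side", window=(float(t_sel[0]), float(t_sel[-1])),
                n_frames=0,
            ))
            continue
        vals = np.abs(rel_z[sel])
        value = float(vals.mean())
        # block protocol on the equilibrated tail, skipping empty blocks
        tail_mask = window_mask(times, analysis_window(times, discard_fraction))
        tail = np.abs(rel_z[sel & tail_mask])
        tail_t = times[sel & tail_mask]
        std = float("nan")
        nb = 0
        if tail.size >= 2:
            edges = np.linspace(tail_t[0], tail_t[-1] + 1e-9, n_blocks + 1)
            block_vals = []
            for b in range(n_blocks):
                in_b = (tail_t >= edges[b]) & (tail_t < edges[b + 1])
                if in_b.any():
                    block_vals.append(tail[in_b].mean())
            if len(block_vals) >= 2:
                std = float(np.std(block_vals, ddof=1))
                nb = len(block_vals)
        results.append(MetricResult(
            value=value, block_std=std, n_blocks=nb,
            selection=f"{side} side",
            window=(float(t_sel[0]), float(t_sel[-1])), n_frames=n,
        ))
    return results[0], results[1]


def free_energy_profile(counts: np.ndarray,
                        temperature: float = 310.0,
                        units: str = "kT") -> np.ndarray:
    """Boltzmann inversion of an occupancy histogram.

    F(z) = -ln(p(z) / max p(z)), so the most occupied bin sits at zero.
    Empty bins yield NaN (absent), never +/-inf.  ``units`` may be
    ``"kT"`` (default) or ``"kJ/mol"`` (scaled by k_B * temperature).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D histogram")
    if np.all(counts <= 0):
        raise ValueError("all-zero occupancy histogram")
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -np.log(p / p.max())
    f[counts <= 0] = np.nan
    if units == "kT":
        return f
    if units == "kJ/mol":
        kB = 0.00831446261815324  # kJ/(mol K)
        return f * kB * temperature
    raise ValueError("units must be 'kT' or 'kJ/mol'")


# ---------------------------------------------------------------------------
# Dipole moment
# ---------------------------------------------------------------------------

def dipole_moment(positions: np.ndarray, charges: np.ndarray,
                  masses: np.ndarray | None = None) -> float:
    """|sum q_i r_i| in Debye (1 e nm = 48.0321 D).

    For net-neutral site sets the result is origin independent.  For a
    charged set the moment is reported about the centre of mass (or the
    geometric centre if no masses are given) with a neutrality warning.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    net = float(charges.sum())
    origin = np.zeros(3)
    if abs(net) > 1e-9:
        warnings.warn(
            f"site set carries net charge {net:+.3f} e; dipole reported "
            "about the centre of mass", stacklevel=2,
        )
        if masses is not None:
            origin = np.average(positions, axis=0,
                                weights=np.asarray(masses, dtype=float))
        else:
            origin = positions.mean(axis=0)
    mu = np.sum(charges[:, None] * (positions - origin), axis=0)
    return float(np.linalg.norm(mu)) * E_NM_TO_DEBYE
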