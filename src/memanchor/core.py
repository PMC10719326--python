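"""Static system description and trajectory containers.

The analysis operates on two objects: a :class:`Topology`, which is the
static annotation of every atom (element, mass, partial charge, residue,
leaflet assignment, hydrogen-bond role), and a :class:`Trajectory`, a
time-ordered sequence of :class:`Frame` objects carrying positions and
orthorhombic box dimensions.

Units are GRO-native throughout the package: lengths in nm, times in ps,
masses in amu, charges in units of the elementary charge.

Leaflet assignment is static.  Lipids are labelled ``upper`` or ``lower``
once, in the topology; membranes on the timescales considered here do not
flip-flop, so no per-frame leaflet detection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LEAFLETS = ("upper", "lower", "none")
HBOND_ROLES = ("donor", "acceptor", "donor_and_acceptor", "polar_hydrogen", "none")

#: Residue names recognised as membrane lipids.  Extend this set if a
#: topology uses additional lipid species.
LIPID_RESIDUE_NAMES = {"DSPC", "DSPE", "DSPS", "SSM"}

#: Head-group class -> default residue name used by the synthetic builder.
HEADGROUP_RESIDUES = {"PC": "DSPC", "PE": "DSPE", "PS": "DSPS", "SM": "SSM"}

SIDECAR_COLUMNS = [
    "atom_id",
    "name",
    "element",
    "mass",
    "charge",
    "residue_name",
    "residue_id",
    "leaflet",
    "hbond_role",
    "bonded_donor_id",
]


class TopologyError(ValueError):
    """Raised when a topology violates a structural invariant."""


@dataclass(frozen=True)
class Atom:
    """One annotated atom (or coarse bead).

    ``bonded_donor_id`` is meaningful only for polar hydrogens, where it
    names the heavy donor atom the hydrogen is covalently attached to;
    use ``None`` otherwise.
    """

    atom_id: int
    name: str
    element: str
    mass: float
    charge: float
    residue_name: str
    residue_id: int
    leaflet: str = "none"
    hbond_role: str = "none"
    bonded_donor_id: int | None = None


class Topology:
    """Immutable table of per-atom annotations.

    Parameters
    ----------
    atoms
        Either a sequence of :class:`Atom` or a :class:`pandas.DataFrame`
        with the sidecar columns (see :data:`SIDECAR_COLUMNS`).
    """

    def __init__(self, atoms: Sequence[Atom] | pd.DataFrame):
        if isinstance(atoms, pd.DataFrame):
            df = atoms.copy()
        else:
            df = pd.DataFrame(
                [
                    {
                        "atom_id": a.atom_id,
                        "name": a.name,
                        "element": a.element,
                        "mass": a.mass,
                        "charge": a.charge,
                        "residue_name": a.residue_name,
                        "residue_id": a.residue_id,
                        "leaflet": a.leaflet,
                        "hbond_role": a.hbond_role,
                        "bonded_donor_id": a.bonded_donor_id,
                    }
                    for a in atoms
                ]
            )
        missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
        if missing:
            raise TopologyError(f"topology table is missing columns: {missing}")
        df = df[SIDECAR_COLUMNS].reset_index(drop=True)
        df["bonded_donor_id"] = df["bonded_donor_id"].astype("Int64")
        self._df = df
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        return cls(df)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    # -- basic properties -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self._df)

    @property
    def names(self) -> np.ndarray:
        return self._df["name"].to_numpy()

    @property
    def elements(self) -> np.ndarray:
        return self._df["element"].to_numpy()

    @property
    def masses(self) -> np.ndarray:
        return self._df["mass"].to_numpy(dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return self._df["charge"].to_numpy(dtype=float)

    @property
    def residue_names(self) -> np.ndarray:
        return self._df["residue_name"].to_numpy()

    @property
    def residue_ids(self) -> np.ndarray:
        return self._df["residue_id"].to_numpy(dtype=int)

    @property
    def leaflets(self) -> np.ndarray:
        return self._df["leaflet"].to_numpy()

    @property
    def hbond_roles(self) -> np.ndarray:
        return self._df["hbond_role"].to_numpy()

    @property
    def bonded_donor_ids(self) -> np.ndarray:
        """Donor atom_id per atom; -1 where absent."""
        return self._df["bonded_donor_id"].fillna(-1).to_numpy(dtype=int)

    @property
    def atom_ids(self) -> np.ndarray:
        return self._df["atom_id"].to_numpy(dtype=int)

    # -- selections (positional indices) --------------------------------------

    def indices_where(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.asarray(mask))

    def lipid_indices(self) -> np.ndarray:
        return self.indices_where(np.isin(self.leaflets, ("upper", "lower")))

    def leaflet_indices(self, leaflet: str) -> np.ndarray:
        if leaflet not in ("upper", "lower"):
            raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
        return self.indices_where(self.leaflets == leaflet)

    def residue_indices(self, residue_name: str) -> np.ndarray:
        return self.indices_where(self.residue_names == residue_name)

    def donor_indices(self) -> np.ndarray:
        return self.indices_where(
            np.isin(self.hbond_roles, ("donor", "donor_and_acceptor"))
        )

    def acceptor_indices(self) -> np.ndarray:
        return self.indices_where(
            np.isin(self.hbond_roles, ("acceptor", "donor_and_acceptor"))
        )

    def polar_hydrogen_indices(self) -> np.ndarray:
        return self.indices_where(self.hbond_roles == "polar_hydrogen")

    def index_of_atom_id(self, atom_id: int) -> int:
        hits = np.flatnonzero(self.atom_ids == atom_id)
        if len(hits) != 1:
            raise TopologyError(f"atom_id {atom_id} is not unique or not present")
        return int(hits[0])

    # -- validation -----------------------------------------------------------

    def _validate(self) -> None:
        df = self._df
        if df["atom_id"].duplicated().any():
            raise TopologyError("duplicate atom_id values")
        if (df["mass"] <= 0).any():
            bad = df.loc[df["mass"] <= 0, "atom_id"].tolist()
            raise TopologyError(f"non-positive mass for atom_id(s) {bad}")
        bad_leaf = set(df["leaflet"]) - set(LEAFLETS)
        if bad_leaf:
            raise TopologyError(f"unknown leaflet label(s): {sorted(bad_leaf)}")
        bad_role = set(df["hbond_role"]) - set(HBOND_ROLES)
        if bad_role:
            raise TopologyError(f"unknown hbond_role label(s): {sorted(bad_role)}")

        # leaflet labels belong to lipid residues only
        non_lipid = ~df["residue_name"].isin(LIPID_RESIDUE_NAMES)
        if (non_lipid & df["leaflet"].isin(["upper", "lower"])).any():
            bad = df.loc[
                non_lipid & df["leaflet"].isin(["upper", "lower"]), "residue_name"
            ].unique()
            raise TopologyError(
                f"non-lipid residues carry a leaflet label: {sorted(bad)}"
            )

        # every lipid residue lives in exactly one leaflet (partition rule)
        lipids = df.loc[df["residue_name"].isin(LIPID_RESIDUE_NAMES)]
        if len(lipids):
            if (lipids["leaflet"] == "none").any():
                bad = lipids.loc[lipids["leaflet"] == "none", "residue_id"].tolist()
                raise TopologyError(f"lipid atoms without a leaflet: residues {bad}")
            per_res = lipids.groupby("residue_id")["leaflet"].nunique()
            if (per_res > 1).any():
                raise TopologyError(
                    f"lipid residues split across leaflets: "
                    f"{per_res[per_res > 1].index.tolist()}"
                )

        # polar hydrogens point at a real donor
        ph = df.loc[df["hbond_role"] == "polar_hydrogen"]
        if ph["bonded_donor_id"].isna().any():
            bad = ph.loc[ph["bonded_donor_id"].isna(), "atom_id"].tolist()
            raise TopologyError(f"polar hydrogens without bonded_donor_id: {bad}")
        if len(ph):
            donors = df.set_index("atom_id")["hbond_role"]
            for aid, did in zip(ph["atom_id"], ph["bonded_donor_id"]):
                if int(did) not in donors.index:
                    raise TopologyError(
                        f"polar hydrogen {aid}: bonded_donor_id {did} not in topology"
                    )
                role = donors.loc[int(did)]
                if role not in ("donor", "donor_and_acceptor"):
                    raise TopologyError(
                        f"polar hydrogen {aid}: atom {did} is not a donor (role={role})"
                    )


@dataclass
class Frame:
    """One trajectory frame: time stamp, orthorhombic box, positions.

    ``box`` holds the three edge lengths (nm) of the rectangular cell;
    ``positions`` is an ``(n_atoms, 3)`` array in nm.
    """

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if not np.all(self.box > 0):
            raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Time-ordered frames over a fixed topology.

    Frames must have strictly increasing times and a constant atom count
    matching the topology.  By the generator's convention coordinates are
    wrapped into the box in x and y but left unwrapped in z, so that the
    above/below-membrane distinction survives; analysis code never
    re-wraps z.
    """

    def __init__(self, topology: Topology, frames: Sequence[Frame],
                 frame_interval: float | None = None):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = topology.n_atoms
        for i, f in enumerate(frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {n}"
                )
        times = np.array([f.time for f in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if frame_interval is None and len(times) > 1:
            frame_interval = float(times[1] - times[0])
        self.topology = topology
        self.frames = frames
        self.frame_interval = frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions(self) -> np.ndarray:
        """All positions as an (n_frames, n_atoms, 3) array."""
        return np.stack([f.positions for f in self.frames])

    def boxes(self) -> np.ndarray:
        return np.stack([f.box for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class MembraneComposition:
    """Per-leaflet head-group counts of an asymmetric bilayer.

    Keys are head-group classes ("PC", "PE", "PS", "SM"); values are
    numbers of lipids.  The default myocardial model places sphingomyelin
    exclusively in the upper (outer) leaflet and the anionic
    phosphatidylserine exclusively in the lower leaflet.
    """

    upper: Mapping[str, int] = field(
        default_factory=lambda: {"PC": 40, "PE": 17, "SM": 7}
    )
    lower: Mapping[str, int] = field(
        default_factory=lambda: {"PC": 35, "PE": 21, "PS": 8}
    )

    def __post_init__(self) -> None:
        for leaflet in (self.upper, self.lower):
            for cls, n in leaflet.items():
                if cls not in HEADGROUP_RESIDUES:
                    raise ValueError(f"unknown head-group class {cls!r}")
                if n < 0:
                    raise ValueError(f"negative count for {cls}: {n}")

    @classmethod
    def myocardial(cls) -> "MembraneComposition":
        """The asymmetric myocardial model composition."""
        return cls()

    def leaflet_counts(self, leaflet: str) -> Mapping[str, int]:
        if leaflet == "upper":
            return dict(self.upper)
        if leaflet == "lower":
            return dict(self.lower)
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")

    def leaflet_total(self, leaflet: str) -> int:
        return sum(self.leaflet_counts(leaflet).values())

    @property
    def total(self) -> int:
        return self.leaflet_total("upper") + self.leaflet_total("lower")

    def percentages(self, leaflet: str) -> dict[str, float]:
        """Exact head-group percentages for one leaflet (sum to 100)."""
        counts = self.leaflet_counts(leaflet)
        tot = sum(counts.values())
        if tot == 0:
            raise ValueError(f"{leaflet} leaflet has zero lipids")
        return {cls: 100.0 * n / tot for cls, n in counts.items()}

    def report(self) -> pd.DataFrame:
        """Tidy per-leaflet composition table with counts and percentages."""
        rows = []
        for leaflet in ("upper", "lower"):
            pct = self.percentages(leaflet)
            for cls, n in self.leaflet_counts(leaflet).items():
                rows.append(
                    {
                        "leaflet": leaflet,
                        "headgroup": cls,
                        "residue_name": HEADGROUP_RESIDUES[cls],
                        "count": n,
                        "percent": pct[cls],
                    }
                )
        return pd.DataFrame(rows)
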