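"""Structures, Cα trajectories, Kabsch superposition and domain RMSD profiles.

All coordinates are in Ångström. Only Cα atoms are handled: residue-level
cross-correlation and RMSD analyses in this package use a single consistent
Cα selection, which approximates backbone RMSD closely at the level of whole
domains. Residue numbers from the source structure (e.g. protein numbering
such as 267–520 for a kinase domain) are preserved as labels throughout;
internal array indexing is 0-based and contiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateSelectionError,
    DomainResolutionError,
    StructureFormatError,
    TrajectoryFormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "Trajectory",
    "DomainDefinition",
    "read_structure",
    "read_trajectory",
    "write_structure_pdb",
    "write_trajectory_pdb",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "kabsch_superpose",
    "apply_transform",
    "rmsd",
    "domain_rmsd_profile",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass
class Structure:
    """A single Cα conformation.

    Parameters
    ----------
    resnums
        Residue sequence numbers, one per Cα, unique and in file order.
    coords
        ``(n, 3)`` Cartesian coordinates in Å.
    resnames
        Optional three-letter residue names (defaults to ``ALA`` on write).
    """

    resnums: np.ndarray
    coords: np.ndarray
    resnames: list[str] | None = None

    def __post_init__(self):
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.resnums) != len(self.coords):
            raise ValueError("resnums and coords length mismatch")
        if len(np.unique(self.resnums)) != len(self.resnums):
            raise ValueError("residue numbers must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return len(self.resnums)


@dataclass
class Trajectory:
    """An ordered stack of Cα frames sharing one residue labelling.

    ``coords`` has shape ``(n_frames, n_residues, 3)``; ``times`` (ns) is
    optional metadata used only for window labelling.
    """

    resnums: np.ndarray
    coords: np.ndarray
    resnames: list[str] | None = None
    times: np.ndarray | None = None

    def __post_init__(self):
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != len(self.resnums):
            raise ValueError("frame width does not match residue count")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def structure(self, i: int) -> Structure:
        """The ``i``-th frame as a standalone :class:`Structure`."""
        return Structure(self.resnums.copy(), self.coords[i].copy(), self.resnames)


@dataclass
class DomainDefinition:
    """Named inclusive residue-number ranges, e.g. ``{"SH3": [(84, 145)]}``.

    Ranges use the structure's own residue numbering (the labels carried by
    :class:`Structure`), not 0-based indices.
    """

    ranges: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, rngs in self.ranges.items():
            if not rngs:
                raise ValueError(f"domain {name!r} has no ranges")
            for lo, hi in rngs:
                if hi < lo:
                    raise ValueError(f"domain {name!r}: range {lo}-{hi} is inverted")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)

    def resolve(self, resnums: np.ndarray) -> dict[str, np.ndarray]:
        """Map each domain to 0-based indices into ``resnums``.

        Raises
        ------
        DomainResolutionError
            If a domain matches no residue in the structure.
        """
        resnums = np.asarray(resnums)
        out: dict[str, np.ndarray] = {}
        for name, rngs in self.ranges.items():
            mask = np.zeros(len(resnums), dtype=bool)
            for lo, hi in rngs:
                mask |= (resnums >= lo) & (resnums <= hi)
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                raise DomainResolutionError(
                    f"domain {name!r} ({list(rngs)}) matches no residue"
                )
            out[name] = idx
        return out


# ---------------------------------------------------------------------------
# File I/O (PDB / DCD via MDAnalysis, CSV via pandas)


def _mda_ca_selection(universe):
    import MDAnalysis as mda  # noqa: F401  (deferred; heavy import)

    ca = universe.select_atoms("name CA")
    if ca.n_atoms == 0:
        raise StructureFormatError("no Cα atoms found")
    # first chain only
    try:
        segids = ca.segids
        first = segids[0]
        ca = ca[segids == first]
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    # altloc: keep blank or 'A'
    try:
        alt = ca.altLocs
        keep = np.isin(alt, ["", " ", "A"])
        if not keep.all():
            ca = ca[keep]
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    try:
        icodes = ca.icodes
        if any(c.strip() for c in icodes):
            logger.warning("insertion codes present; they are ignored")
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    return ca


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read the Cα trace of the first chain from a PDB file.

    Altloc ``A`` (or blank) is kept; insertion codes are ignored with a
    warning. Raises :class:`StructureFormatError` when the file has no ATOM
    records or cannot be parsed.
    """
    import MDAnalysis as mda

    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="PDB")
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise StructureFormatError(f"{path}: {exc}") from exc
    ca = _mda_ca_selection(u)
    return Structure(
        resnums=ca.resids.copy(),
        coords=ca.positions.astype(float).copy(),
        resnames=[str(r) for r in ca.resnames],
    )


def _dcd_header_nframes(path: Path) -> int | None:
    """Frame count (NSET) stored in a DCD header, or None if unreadable."""
    import struct

    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12:
        return None
    for endian in ("<", ">"):
        marker = struct.unpack(endian + "i", head[:4])[0]
        if marker == 84 and head[4:8] == b"CORD":
            return struct.unpack(endian + "i", head[8:12])[0]
    return None


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology: str | Path | None = None,
) -> Trajectory:
    """Read a Cα trajectory from multi-model PDB, DCD or CSV.

    DCD requires a companion ``topology`` structure (PDB) defining the atom
    order. CSV uses the plain dialect written by
    :func:`write_trajectory_csv`. Frames with mismatched atom counts raise
    :class:`TrajectoryFormatError` naming the frame.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    format = format.lower()

    if format == "csv":
        return read_trajectory_csv(path)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "pdb":
                u = mda.Universe(str(path), format="PDB")
            elif format == "dcd":
                if topology is None:
                    raise TrajectoryFormatError("DCD requires a companion structure")
                u = mda.Universe(str(topology), str(path))
            else:
                raise ValueError(f"unsupported trajectory format: {format!r}")
        ca = _mda_ca_selection(u)
        frames = []
        for its, _ts in enumerate(u.trajectory):
            pos = ca.positions.astype(float)
            if frames and pos.shape != frames[0].shape:
                raise TrajectoryFormatError(
                    f"frame {its}: atom count {pos.shape[0]} != {frames[0].shape[0]}"
                )
            frames.append(pos.copy())
    except (TrajectoryFormatError, ValueError):
        raise
    except Exception as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    if format == "dcd":
        declared = _dcd_header_nframes(path)
        if declared is not None and declared > 0 and declared != len(frames):
            raise TrajectoryFormatError(
                f"{path}: header declares {declared} frames but "
                f"{len(frames)} were read (truncated or corrupted file)"
            )
    return Trajectory(
        resnums=ca.resids.copy(),
        coords=np.stack(frames),
        resnames=[str(r) for r in ca.resnames],
    )


def _as_universe(resnums, coords, resnames):
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=np.float32)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
    )
    u.add_TopologyAttr("name", ["CA"] * n)
    u.add_TopologyAttr("type", ["C"] * n)
    u.add_TopologyAttr("resname", list(resnames) if resnames else ["ALA"] * n)
    u.add_TopologyAttr("resid", np.asarray(resnums, dtype=int))
    u.load_new(coords, order="fac")
    return u


def write_structure_pdb(struct: Structure, path: str | Path) -> None:
    """Write a single-model Cα-only PDB file."""
    write_trajectory_pdb(
        Trajectory(struct.resnums, struct.coords[None], struct.resnames), path
    )


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model Cα-only PDB file (one MODEL per frame)."""
    import MDAnalysis as mda

    u = _as_universe(traj.resnums, traj.coords, traj.resnames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_residues) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write the plain CSV dialect ``frame,residue_index,x,y,z``.

    ``residue_index`` holds residue *numbers* (labels), so the table
    round-trips through :func:`read_trajectory_csv` without extra metadata.
    """
    n_f, n_r = traj.n_frames, traj.n_residues
    frame = np.repeat(np.arange(n_f), n_r)
    resid = np.tile(traj.resnums, n_f)
    flat = traj.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {"frame": frame, "residue_index": resid,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "residue_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryFormatError(
            f"{path}: CSV must have columns {sorted(required)}"
        )
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    resnums = first["residue_index"].to_numpy(dtype=int)
    coords = np.empty((len(frames), len(resnums), 3), dtype=float)
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != len(resnums):
            raise TrajectoryFormatError(
                f"frame {f}: {len(sub)} residues, expected {len(resnums)}"
            )
        sub = sub.set_index("residue_index").loc[resnums]
        coords[k] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(resnums=resnums, coords=coords)


# ---------------------------------------------------------------------------
# Superposition and RMSD


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (Å) without any fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an ``(n, 3)`` coordinate array."""
    return np.asarray(coords, float) @ np.asarray(rotation).T + translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` best fits the selected atoms of
    ``reference`` in the least-squares sense; the rotation is proper
    (determinant +1), so mirror images are never matched by reflection.
    The RMSD is evaluated over the selection.

    Raises
    ------
    DegenerateSelectionError
        Fewer than two selected atoms, or all selected atoms coincident.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise DegenerateSelectionError("empty selection")
        sel_m, sel_r = mobile[selection], reference[selection]
    if sel_m.shape != sel_r.shape:
        raise ValueError("selection shape mismatch between mobile and reference")
    n = len(sel_m)
    if n < 2:
        raise DegenerateSelectionError(f"selection of {n} atom(s) cannot define a fit")
    cm = sel_m.mean(axis=0)
    cr = sel_r.mean(axis=0)
    p = sel_m - cm
    q = sel_r - cr
    if np.allclose(p, 0.0) or np.allclose(q, 0.0):
        raise DegenerateSelectionError("all selected atoms coincide")
    with warnings.catch_warnings():
        # scipy warns when the rotation is not unique (collinear selections);
        # any minimiser is acceptable, so demote to a log message.
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(q, p)
    rotation = rot.as_matrix()
    translation = cr - rotation @ cm
    fit_rmsd = float(rssd) / np.sqrt(n)
    return rotation, translation, fit_rmsd


def domain_rmsd_profile(
    traj: Trajectory,
    target: Structure,
    domains: DomainDefinition,
    mode: str = "per-domain",
) -> pd.DataFrame:
    """Per-domain RMSD (Å) of every frame against a target conformation.

    ``mode='per-domain'`` superposes each domain independently before
    measuring it (each domain gets its own best fit). ``mode='global'``
    superposes on all Cα atoms and then measures each domain without
    refitting, so domain curves share one alignment frame.

    Returns a tidy frame with columns ``frame, time_ns, domain, rmsd_A``.
    """
    if mode not in ("per-domain", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if traj.n_residues != target.n_residues or not np.array_equal(
        traj.resnums, target.resnums
    ):
        raise ValueError("trajectory and target residue labelling differ")
    idx = domains.resolve(target.resnums)
    rows = []
    times = traj.times if traj.times is not None else np.full(traj.n_frames, np.nan)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        if mode == "global":
            rot, t, _ = kabsch_superpose(frame, target.coords)
            fitted = apply_transform(frame, rot, t)
            for name, sel in idx.items():
                rows.append((f, times[f], name, rmsd(fitted[sel], target.coords[sel])))
        else:
            for name, sel in idx.items():
                _, _, r = kabsch_superpose(frame, target.coords, selection=sel)
                rows.append((f, times[f], name, r))
    return pd.DataFrame(rows, columns=["frame", "time_ns", "domain", "rmsd_A"])
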