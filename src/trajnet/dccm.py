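"""Dynamical cross-correlation maps (DCCM) over trajectory windows.

The DCCM entry for residues *i*, *j* over a frame window is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with dr_i(t) = r_i(t) - <r_i> the Cα positional fluctuation about the
window mean and the dot product taken over x, y, z (the standard 3-D vector
convention). C_ij is +1 for perfectly correlated motion, -1 for perfectly
anti-correlated motion.

By default each frame is first least-squares superposed (all Cα) onto a
reference — the mean structure of the window unless one is supplied —
because a trajectory with net drift or rotation otherwise shows spurious
all-positive correlations from the shared rigid-body motion. Disabling
superposition reproduces the raw-coordinate reading of the formula.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import DomainDefinition, Trajectory, apply_transform, kabsch_superpose

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "DCCMatrix",
    "compute_dccm",
    "dccm_block_summary",
    "write_dccm_csv",
    "read_dccm_csv",
]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open frame interval ``[start, stop)`` with an optional label."""

    start: int
    stop: int
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.stop):
            raise ValueError(f"invalid window [{self.start}, {self.stop})")

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def name(self) -> str:
        return self.label or f"frames_{self.start}_{self.stop}"


@dataclass
class DCCMatrix:
    """A symmetric residue–residue correlation matrix with labels."""

    matrix: np.ndarray
    resnums: np.ndarray
    window: WindowSpec | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.resnums = np.asarray(self.resnums, int)
        n = len(self.resnums)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match residue labels")

    @property
    def n_residues(self) -> int:
        return len(self.resnums)


def compute_dccm(
    traj: Trajectory,
    window: WindowSpec | None = None,
    superpose: bool = True,
    reference: np.ndarray | None = None,
) -> DCCMatrix:
    """Cross-correlation map of a trajectory window.

    Parameters
    ----------
    traj
        Source trajectory.
    window
        Frame window; the whole trajectory when omitted.
    superpose
        Least-squares fit every frame (all Cα) to ``reference`` before
        measuring fluctuations; on by default.
    reference
        ``(n, 3)`` reference coordinates; defaults to the mean structure of
        the (raw) window.

    A residue with zero positional variance gets a zeroed row/column with
    diagonal 1 and a logged warning rather than an exception.
    """
    if window is None:
        window = WindowSpec(0, traj.n_frames)
    if window.stop > traj.n_frames:
        raise ValueError(
            f"window [{window.start}, {window.stop}) exceeds {traj.n_frames} frames"
        )
    if window.n_frames < 2:
        raise ValueError("window must contain at least 2 frames")
    x = traj.coords[window.start : window.stop].copy()

    if superpose:
        ref = x.mean(axis=0) if reference is None else np.asarray(reference, float)
        for k in range(len(x)):
            rot, t, _ = kabsch_superpose(x[k], ref)
            x[k] = apply_transform(x[k], rot, t)

    delta = x - x.mean(axis=0)
    cov = np.einsum("fia,fja->ij", delta, delta) / len(x)
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    if zero.any():
        logger.warning(
            "%d residue(s) with zero variance; rows/columns set to 0", zero.sum()
        )
        var[zero] = 1.0
    c = cov / np.sqrt(np.outer(var, var))
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    np.fill_diagonal(c, np.where(zero, 1.0, np.diag(c)))
    over = np.abs(c) > 1.0 + 1e-9
    if over.any():
        logger.warning("%d |C| entries exceeded 1 numerically; clipped", over.sum())
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    c = 0.5 * (c + c.T)
    return DCCMatrix(matrix=c, resnums=traj.resnums.copy(), window=window)


def dccm_block_summary(dccm: DCCMatrix, domains: DomainDefinition) -> pd.DataFrame:
    """Mean correlation for every ordered domain pair.

    Self-pairs exclude the diagonal; a singleton domain's self-pair is
    reported as 1 by convention. Useful for the qualitative inter-domain
    reading of a correlation map (e.g. "the SH3–SH2 coupling is negative").
    """
    idx = domains.resolve(dccm.resnums)
    rows = []
    for a, ia in idx.items():
        for b, ib in idx.items():
            block = dccm.matrix[np.ix_(ia, ib)]
            if a == b:
                if len(ia) == 1:
                    mean = 1.0
                else:
                    off = ~np.eye(len(ia), dtype=bool)
                    mean = float(block[off].mean())
            else:
                mean = float(block.mean())
            rows.append((a, b, mean))
    return pd.DataFrame(rows, columns=["domain_i", "domain_j", "mean_C"])


def write_dccm_csv(dccm: DCCMatrix, path: str | Path) -> None:
    """CSV matrix with residue-number header row/column; window metadata in a
    ``<path>.json`` sidecar."""
    df = pd.DataFrame(dccm.matrix, index=dccm.resnums, columns=dccm.resnums)
    df.to_csv(path, index_label="residue")
    if dccm.window is not None:
        meta = {
            "start": dccm.window.start,
            "stop": dccm.window.stop,
            "label": dccm.window.label,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_dccm_csv(path: str | Path) -> DCCMatrix:
    df = pd.read_csv(path, index_col=0)
    resnums = df.index.to_numpy(dtype=int)
    window = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        window = WindowSpec(meta["start"], meta["stop"], meta.get("label"))
    return DCCMatrix(matrix=df.to_numpy(dtype=float), resnums=resnums, window=window)
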