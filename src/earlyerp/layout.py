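"""64-channel scalp montage: names, idealized spherical positions, region masks.

The packaged coordinate table is an idealized (synthetic) unit-sphere
rendering of the extended 10-20 (10-10) system for a standard 64-channel
active-electrode cap, with x pointing right, y anterior and z superior.
Two bipolar electro-oculogram derivations (vertical and horizontal) are
carried alongside the scalp channels; they have no scalp position.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

EOG_CHANNELS = ("VEOG", "HEOG")

#: prefixes of sensor names lying over the posterior hemiscalp
_POSTERIOR_PREFIXES = ("P", "PO", "O", "I")


@dataclass(frozen=True)
class ChannelLayout:
    """Scalp sensor montage with 3-D unit-sphere positions.

    Attributes
    ----------
    names : list of str
        Scalp channel names (length 64 for the packaged montage).
    positions : ndarray, shape (n_channels, 3)
        Unit-sphere coordinates; x right, y anterior, z superior.
    eog_names : tuple of str
        Names of the EOG derivations appended after the scalp channels
        in recordings produced by the simulator.
    """

    names: list[str]
    positions: np.ndarray
    eog_names: tuple[str, ...] = EOG_CHANNELS

    def __post_init__(self):
        if len(self.names) != self.positions.shape[0]:
            raise ValueError("names and positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def posterior_mask(self) -> np.ndarray:
        """Boolean mask of posterior-hemiscalp channels (P*, PO*, O*, Iz)."""
        return np.array(
            [n.startswith(_POSTERIOR_PREFIXES) for n in self.names], dtype=bool
        )

    def hemisphere(self, tol: float = 1e-6) -> np.ndarray:
        """Per-channel hemisphere label: 'L', 'R' or 'M' from the x sign."""
        x = self.positions[:, 0]
        out = np.where(x < -tol, "L", np.where(x > tol, "R", "M"))
        return out

    def laterality_mask(self, laterality: str) -> np.ndarray:
        """Mask for 'bilateral' (all), 'left' or 'right' (side + midline)."""
        hemi = self.hemisphere()
        if laterality == "bilateral":
            return np.ones(self.n_channels, dtype=bool)
        if laterality == "left":
            return (hemi == "L") | (hemi == "M")
        if laterality == "right":
            return (hemi == "R") | (hemi == "M")
        raise ValueError(f"unknown laterality {laterality!r}")


def make_layout() -> ChannelLayout:
    """Load the packaged 64-channel montage.

    Returns a :class:`ChannelLayout` with 64 scalp channels on the unit
    sphere plus the two standard EOG derivation names.
    """
    ref = resources.files("earlyerp.data").joinpath("biosemi64_sphere.tsv")
    names: list[str] = []
    rows: list[list[float]] = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return ChannelLayout(names=names, positions=np.asarray(rows, dtype=float))


def load_layout_table(path) -> ChannelLayout:
    """Read a whitespace-delimited channel table (name, x, y, z)."""
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return ChannelLayout(names=names, positions=np.asarray(rows, dtype=float))


def build_adjacency(layout: ChannelLayout, radius: float = 0.45) -> np.ndarray:
    """Neighbor graph of scalp channels by Euclidean distance threshold.

    Parameters
    ----------
    radius : float
        Normalized (unit-sphere chord) distance under which two distinct
        channels count as neighbors. The default yields a mean degree of
        roughly six on the packaged montage.

    Returns
    -------
    ndarray of bool, shape (n, n)
        Symmetric adjacency matrix with a zero diagonal.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d < radius) & (d > 0)
    if not adj.any():
        # radius so small that the graph is empty; still a valid graph,
        # callers needing neighbors should raise
        pass
    return adj
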