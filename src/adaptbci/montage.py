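"""Electrode grids and bipolar derivations.

The decoder consumes bipolar derivations: difference signals between two
electrodes that lie on a common line of a rectangular scalp grid.  Rows run
front-to-back (coronal lines), columns left-to-right (sagittal lines).  A
derivation along a column is called *sagittal*, one along a row *coronal*,
and it may skip zero or one intermediate grid positions (``gap``).

The "scalp area covered" by a derivation — used to forbid overlapping
derivations during greedy channel selection — is the inclusive set of grid
positions between its two electrodes along their line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ElectrodeGrid",
    "BipolarDerivation",
    "MontageError",
    "make_derivation",
    "parse_derivation",
    "enumerate_bipolar_derivations",
    "derivations_overlap",
    "apply_derivation",
    "derive_epochs",
    "default_montage",
]


class MontageError(ValueError):
    """Raised for inconsistent montage configuration."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """A sparse rectangular electrode layout.

    Parameters
    ----------
    labels : sequence of str
        Unique electrode names.
    coords : mapping label -> (row, col)
        Integer grid position per label; row = coronal line index
        (front-to-back), col = sagittal line index (left-to-right).
    """

    labels: tuple[str, ...]
    coords: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise MontageError("electrode labels must be unique")
        if set(self.labels) != set(self.coords):
            raise MontageError("labels and coords must cover the same electrodes")
        positions = list(self.coords.values())
        if len(set(positions)) != len(positions):
            raise MontageError("grid positions must be unique")

    @classmethod
    def from_pairs(cls, entries: Iterable[tuple[str, int, int]]) -> "ElectrodeGrid":
        entries = list(entries)
        labels = tuple(e[0] for e in entries)
        coords = {e[0]: (int(e[1]), int(e[2])) for e in entries}
        return cls(labels=labels, coords=coords)

    @classmethod
    def from_yaml(cls, path) -> "ElectrodeGrid":
        """Load a montage from a YAML list of ``{label, row, col}`` mappings."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls.from_pairs((e["label"], e["row"], e["col"]) for e in raw)
        except (KeyError, TypeError) as exc:
            raise MontageError(f"malformed montage file {path!r}: {exc}") from exc

    def position(self, label: str) -> tuple[int, int]:
        try:
            return self.coords[label]
        except KeyError:
            raise MontageError(f"unknown electrode label {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BipolarDerivation:
    """An anode-minus-cathode channel pair on a grid line.

    ``covered`` is the inclusive set of grid positions from anode to cathode
    along the shared row or column; ``gap`` counts skipped intermediate
    positions (0 or 1).
    """

    anode: str
    cathode: str
    orientation: str  # "sagittal" (same column) or "coronal" (same row)
    gap: int
    covered: frozenset[tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise MontageError("anode and cathode must differ")
        if self.orientation not in ("sagittal", "coronal"):
            raise MontageError(f"bad orientation {self.orientation!r}")
        if self.gap not in (0, 1):
            raise MontageError("gap must be 0 or 1")
        if len(self.covered) != self.gap + 2:
            raise MontageError("covered set inconsistent with gap")

    @property
    def name(self) -> str:
        return f"{self.anode}-{self.cathode}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def make_derivation(grid: ElectrodeGrid, anode: str, cathode: str) -> BipolarDerivation:
    """Build a derivation between two grid electrodes, canonical polarity.

    Canonical polarity is anterior-minus-posterior (sagittal) or
    left-minus-right (coronal); if the arguments are given in the opposite
    order they are swapped.
    """
    ra, ca = grid.position(anode)
    rc, cc = grid.position(cathode)
    if ca == cc and ra != rc:
        orientation = "sagittal"
        if ra > rc:  # canonical: smaller row (anterior) first
            anode, cathode, ra, rc = cathode, anode, rc, ra
        step = rc - ra
        covered = frozenset((r, ca) for r in range(ra, rc + 1))
    elif ra == rc and ca != cc:
        orientation = "coronal"
        if ca > cc:  # canonical: smaller column (left) first
            anode, cathode, ca, cc = cathode, anode, cc, ca
        step = cc - ca
        covered = frozenset((ra, c) for c in range(ca, cc + 1))
    else:
        raise MontageError(
            f"{anode} and {cathode} share neither a row nor a column"
        )
    gap = step - 1
    if gap > 1:
        raise MontageError(
            f"{anode}-{cathode}: {gap} skipped positions; at most 1 allowed"
        )
    return BipolarDerivation(anode, cathode, orientation, gap, covered)


def parse_derivation(grid: ElectrodeGrid, name: str) -> BipolarDerivation:
    """Parse an ``"Anode-Cathode"`` string against a grid."""
    parts = name.split("-")
    # electrode labels themselves contain no '-', so exactly one split point
    if len(parts) != 2:
        raise MontageError(f"cannot parse derivation name {name!r}")
    return make_derivation(grid, parts[0], parts[1])


def enumerate_bipolar_derivations(
    grid: ElectrodeGrid,
    max_gap: int = 1,
    require_occupied_gaps: bool = False,
) -> list[BipolarDerivation]:
    """Enumerate every canonical derivation on the grid with gap <= max_gap.

    Pairs must share a row or column and be separated by at most
    ``max_gap + 1`` grid steps.  By default skipped positions need not hold
    an electrode (the montage is a sparse grid); set
    ``require_occupied_gaps`` to demand an electrode at every skipped
    position.
    """
    if max_gap < 0:
        raise MontageError("max_gap must be >= 0")
    if len(grid) == 0:
        raise MontageError("grid is empty")
    occupied = set(grid.coords.values())
    out: list[BipolarDerivation] = []
    by_pos = {grid.coords[lab]: lab for lab in grid.labels}
    for (r, c), lab in sorted(by_pos.items()):
        for step in range(1, max_gap + 2):
            # sagittal partner: same column, `step` rows behind
            for (r2, c2) in ((r + step, c), (r, c + step)):
                partner = by_pos.get((r2, c2))
                if partner is None:
                    continue
                if require_occupied_gaps:
                    if r2 > r:
                        between = {(rr, c) for rr in range(r + 1, r2)}
                    else:
                        between = {(r, cc) for cc in range(c + 1, c2)}
                    if not between <= occupied:
                        continue
                out.append(make_derivation(grid, lab, partner))
    return out


def derivations_overlap(d1: BipolarDerivation, d2: BipolarDerivation) -> bool:
    """True iff the two derivations cover at least one common grid position."""
    return bool(d1.covered & d2.covered)


def apply_derivation(
    recording: np.ndarray,
    channel_labels: Sequence[str],
    derivation: BipolarDerivation,
) -> np.ndarray:
    """Bipolar-reference a multichannel recording.

    ``recording`` has channels on its second-to-last axis (``(..., channels,
    samples)``); the output drops that axis: ``anode(t) - cathode(t)``.
    """
    labels = list(channel_labels)
    for lab in (derivation.anode, derivation.cathode):
        if lab not in labels:
            raise MontageError(f"channel {lab!r} missing from recording")
    ia = labels.index(derivation.anode)
    ic = labels.index(derivation.cathode)
    rec = np.asarray(recording)
    return rec[..., ia, :] - rec[..., ic, :]


def derive_epochs(
    epochs: np.ndarray,
    channel_labels: Sequence[str],
    derivations: Sequence[BipolarDerivation],
) -> np.ndarray:
    """Stack several derivations of an epochs array into a new channel axis.

    Input ``(trials, channels, samples)`` -> output ``(trials,
    len(derivations), samples)``.
    """
    return np.stack(
        [apply_derivation(epochs, channel_labels, d) for d in derivations], axis=-2
    )


# Default 30-electrode layout approximating a 10/20 montage over frontal to
# occipital rows.  Columns 0..8 span left temporal to right temporal; midline
# electrodes sit at column 4.  Rows 0..6 run front to back.
_DEFAULT_MONTAGE: tuple[tuple[str, int, int], ...] = (
    ("Fpz", 0, 4),
    ("F7", 1, 0), ("F3", 1, 2), ("Fz", 1, 4), ("F4", 1, 6), ("F8", 1, 8),
    ("FC3", 2, 2), ("FCz", 2, 4), ("FC4", 2, 6),
    ("T3", 3, 0), ("C3", 3, 2), ("Cz", 3, 4), ("C4", 3, 6), ("T4", 3, 8),
    ("CP3", 4, 2), ("CPz", 4, 4), ("CP4", 4, 6),
    ("P7", 5, 0), ("P3", 5, 2), ("P1", 5, 3), ("Pz", 5, 4), ("P2", 5, 5),
    ("P4", 5, 6), ("P8", 5, 8),
    ("PO3", 6, 2), ("POz", 6, 4), ("PO4", 6, 6),
    ("O1", 7, 3), ("Oz", 7, 4), ("O2", 7, 5),
)


def default_montage() -> ElectrodeGrid:
    """The packaged 30-channel 10/20-style grid."""
    return ElectrodeGrid.from_pairs(_DEFAULT_MONTAGE)
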