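"""Spatial profile containers and their delimited-text I/O.

The two central data objects are :class:`DensityProfile` — a cell-density
distribution p(x) over ordered tissue compartments — and
:class:`EntropyProfile` — a local entropy curve S(x) through the epidermis
thickness.  Both are thin, validated wrappers around numpy arrays and
round-trip losslessly through comma-separated text.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import InvalidDistributionError, ProfileIOError, ShapeError

logger = logging.getLogger(__name__)

#: Default positive floor applied before ratio evaluation in KL computations.
DEFAULT_FLOOR = 1e-12


@dataclass
class DensityProfile:
    """Positive cell densities over ordered compartments.

    Parameters
    ----------
    positions
        Compartment coordinates (strictly increasing when numeric).
    values
        Non-negative densities, one per compartment.
    label
        Free text, e.g. ``"young"`` or ``"old"``.
    floor
        Small positive constant used when clamping values away from zero.
    """

    positions: np.ndarray
    values: np.ndarray
    label: str = ""
    floor: float = DEFAULT_FLOOR

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise ShapeError("positions and values must be one-dimensional")
        if len(self.positions) != len(self.values):
            raise ShapeError(
                f"positions ({len(self.positions)}) and values "
                f"({len(self.values)}) differ in length"
            )
        if len(self.values) < 1:
            raise InvalidDistributionError("profile must have at least one compartment")
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidDistributionError("positions must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise InvalidDistributionError("densities must be finite")
        if np.any(self.values < 0):
            idx = int(np.argmax(self.values < 0))
            raise InvalidDistributionError(
                f"negative density {self.values[idx]} at compartment {idx}"
            )
        if not (self.floor > 0):
            raise InvalidDistributionError("floor must be strictly positive")

    def __len__(self) -> int:
        return len(self.values)

    def clamped(self) -> np.ndarray:
        """Values with zeros lifted to ``floor``; warns when clamping occurs."""
        if np.any(self.values < self.floor):
            n = int(np.sum(self.values < self.floor))
            logger.warning(
                "clamping %d density value(s) below floor %g in profile %r",
                n, self.floor, self.label,
            )
        return np.maximum(self.values, self.floor)

    def normalized(self) -> np.ndarray:
        """Values rescaled to unit total mass."""
        total = float(self.values.sum())
        if total <= 0:
            raise InvalidDistributionError("cannot normalize an all-zero profile")
        return self.values / total

    def with_values(self, values: np.ndarray, label: str | None = None) -> "DensityProfile":
        """Copy with the same positions/floor but new densities."""
        return DensityProfile(
            positions=self.positions.copy(),
            values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
            floor=self.floor,
        )


@dataclass
class EntropyProfile:
    """Local entropy S(x) through the tissue, with thickness L.

    x = 0 is the basal (deepest) layer; x = L the surface.
    """

    x_nodes: np.ndarray
    S: np.ndarray
    L: float
    label: str = ""

    def __post_init__(self):
        self.x_nodes = np.asarray(self.x_nodes, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if len(self.x_nodes) != len(self.S):
            raise ShapeError("x_nodes and S differ in length")
        if len(self.S) < 1:
            raise InvalidDistributionError("entropy profile must be non-empty")
        if np.any(np.diff(self.x_nodes) <= 0):
            raise InvalidDistributionError("x_nodes must be strictly increasing")
        if not (self.L > 0):
            raise InvalidDistributionError("thickness L must be positive")

    def __len__(self) -> int:
        return len(self.S)


@dataclass
class CountVector:
    """Non-negative occupation numbers n_i with total N = sum n_i."""

    counts: np.ndarray
    total: int = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.size == 0:
            raise InvalidDistributionError("count vector must be non-empty")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=np.int64)
            if np.any(as_int != self.counts):
                raise InvalidDistributionError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise InvalidDistributionError("counts must be non-negative")
        self.total = int(self.counts.sum())


ProfileLike = Union[DensityProfile, Sequence[float], np.ndarray]


def as_density_values(p: ProfileLike) -> np.ndarray:
    """Extract a validated density array from a profile or bare sequence."""
    if isinstance(p, DensityProfile):
        return p.values
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError("expected a non-empty 1-D density sequence")
    if np.any(arr < 0):
        raise InvalidDistributionError("densities must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Format: comma-separated, mandatory header, one row per
# compartment, numbers written with repr-level precision so read(write(p)) is
# exact.

_DENSITY_HEADER = ("position", "value")
_ENTROPY_HEADER = ("x", "S")


def write_profile(profile: Union[DensityProfile, EntropyProfile], path) -> None:
    """Write a profile as CSV with a fixed header and 17-significant-digit
    numbers (lossless round-trip)."""
    path = Path(path)
    if isinstance(profile, DensityProfile):
        header, cols = _DENSITY_HEADER, (profile.positions, profile.values)
    else:
        header, cols = _ENTROPY_HEADER, (profile.x_nodes, profile.S)
    lines = [",".join(header)]
    for row in zip(*cols):
        lines.append(",".join(format(v, ".17g") for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_profile(path, expected_columns: Sequence[str] = _DENSITY_HEADER,
                 label: str = "") -> Union[DensityProfile, EntropyProfile]:
    """Read a density or entropy profile from CSV.

    ``expected_columns`` selects the flavour: ``("position", "value")`` yields
    a :class:`DensityProfile`, ``("x", "S")`` an :class:`EntropyProfile`.
    Malformed rows raise :class:`ProfileIOError` citing the 1-based line.
    """
    path = Path(path)
    if not path.exists():
        raise ProfileIOError(f"profile file not found: {path}")
    expected = tuple(expected_columns)
    xs, ys = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ProfileIOError(f"empty profile file: {path}", line=1) from None
        if tuple(h.strip() for h in header) != expected:
            raise ProfileIOError(
                f"header {header!r} does not match expected {list(expected)!r}",
                line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ProfileIOError(
                    f"line {lineno}: expected 2 fields, got {len(row)}", line=lineno
                )
            try:
                x, y = float(row[0]), float(row[1])
            except ValueError:
                raise ProfileIOError(
                    f"line {lineno}: non-numeric entry in {row!r}", line=lineno
                ) from None
            xs.append(x)
            ys.append(y)
    try:
        if expected == _ENTROPY_HEADER:
            arr = np.asarray(xs)
            thickness = float(arr[-1]) if len(arr) and arr[-1] > 0 else 1.0
            return EntropyProfile(x_nodes=arr, S=np.asarray(ys), L=thickness,
                                  label=label or path.stem)
        return DensityProfile(positions=np.asarray(xs), values=np.asarray(ys),
                              label=label or path.stem)
    except (InvalidDistributionError, ShapeError) as exc:
        # locate the offending row for the error message where possible
        bad_line = None
        if "negative density" in str(exc):
            for i, v in enumerate(ys):
                if v < 0:
                    bad_line = i + 2
                    break
        raise ProfileIOError(f"invalid profile in {path}: {exc}", line=bad_line) from exc
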