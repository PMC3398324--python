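"""Expression-profile time series: containers, normalization, phase slicing.

Expression profiles are dimensionless intensity ratios X_mu(tau_k) =
I_mu(tau_k) / I_mu^R of a gene's fluorescence intensity against a
time-independent, gene-specific reference intensity.  All downstream analysis
(clustering, ODE modelling) operates on such ratio profiles sampled on a
shared multi-phase time grid.  Data are assumed already normalized across
hybridizations; missing values are rejected at load time.

Two time coordinates are carried for every grid: real time in hours and a
1-based time-point index.  ODE fitting on series with strongly uneven
sampling (e.g. a full developmental series whose adult phase spans weeks)
uses the index coordinate, while phase-homogeneous series use hours.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_ORDER",
    "TimeGrid",
    "ExpressionProfile",
    "ProfileSet",
    "read_time_grid",
    "write_time_grid",
    "read_expression_matrix",
    "write_expression_matrix",
    "ratio_profiles",
    "select_phase",
]

#: canonical developmental-phase order
PHASE_ORDER = ("embryonic", "larval", "pupal", "adult")


class ProfileDataError(ValueError):
    """Raised on malformed expression matrices or time grids."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared sampling grid: real times (hours) plus per-point phase labels.

    ``index_times`` (consecutive integers 1..N) is always available as an
    alternative integration coordinate.
    """

    points: np.ndarray
    phase_labels: tuple[str, ...]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "phase_labels", tuple(self.phase_labels))
        if pts.ndim != 1 or pts.size < 2:
            raise ProfileDataError("time grid needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ProfileDataError("non-finite time point in grid")
        if not np.all(np.diff(pts) > 0):
            raise ProfileDataError("time points must be strictly increasing")
        if len(self.phase_labels) != pts.size:
            raise ProfileDataError("one phase label required per time point")
        seen = [p for i, p in enumerate(self.phase_labels)
                if i == 0 or self.phase_labels[i - 1] != p]
        if len(set(seen)) != len(seen):
            raise ProfileDataError("phase labels must form contiguous runs")
        order = [p for p in PHASE_ORDER if p in seen]
        if seen != order:
            raise ProfileDataError(
                f"phases must appear in the order {PHASE_ORDER}, got {seen}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def index_times(self) -> np.ndarray:
        """1-based consecutive time-point indices."""
        return np.arange(1, self.n_points + 1, dtype=float)

    @property
    def phases(self) -> tuple[str, ...]:
        """Distinct phases in order of appearance."""
        out = []
        for p in self.phase_labels:
            if not out or out[-1] != p:
                out.append(p)
        return tuple(out)

    def coordinate(self, coord: str = "hours") -> np.ndarray:
        if coord == "hours":
            return self.points
        if coord == "index":
            return self.index_times
        raise ValueError(f"unknown coordinate {coord!r}")

    # -- coordinate maps ---------------------------------------------------
    def index_to_hours(self, idx) -> np.ndarray:
        """Piecewise-linear index -> hours map, linearly extrapolated
        beyond the grid using the edge segments."""
        return _interp_extrap(np.asarray(idx, float), self.index_times, self.points)

    def hours_to_index(self, hours) -> np.ndarray:
        return _interp_extrap(np.asarray(hours, float), self.points, self.index_times)

    def extrapolation_horizon(self, coord: str = "hours", factor: float = 3.0,
                              cap_hours: float = 80.0 * 24.0) -> float:
        """End time for extrapolation: ``factor`` times the measured span
        (from tau_1) capped at ``cap_hours`` of real time, expressed on the
        requested integration coordinate."""
        t_h = self.points
        end_h = min(t_h[0] + factor * (t_h[-1] - t_h[0]), cap_hours)
        if coord == "hours":
            return float(end_h)
        return float(self.hours_to_index(end_h))

    def phase_mask(self, phase: str) -> np.ndarray:
        if phase not in self.phases:
            raise ProfileDataError(
                f"phase {phase!r} not present (have {self.phases})")
        return np.array([p == phase for p in self.phase_labels])

    def subgrid(self, mask: np.ndarray) -> "TimeGrid":
        mask = np.asarray(mask, bool)
        return TimeGrid(self.points[mask],
                        tuple(np.array(self.phase_labels, object)[mask]))


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation from the first/last segments."""
    y = np.interp(x, xp, fp)
    lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
    hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    y = np.where(x < xp[0], fp[0] + (x - xp[0]) * lo_slope, y)
    y = np.where(x > xp[-1], fp[-1] + (x - xp[-1]) * hi_slope, y)
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's ratio profile X_mu(tau_k) on the owning grid."""

    gene_id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ProfileDataError(f"gene {self.gene_id}: non-finite value")
        if np.any(v < 0):
            raise ProfileDataError(
                f"gene {self.gene_id}: negative intensity ratio")


@dataclass(frozen=True)
class ProfileSet:
    """A collection of profiles sharing one TimeGrid."""

    grid: TimeGrid
    profiles: tuple[ExpressionProfile, ...]

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        ids = [p.gene_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ProfileDataError(f"duplicate gene ids: {dup}")
        for p in self.profiles:
            if p.values.size != self.grid.n_points:
                raise ProfileDataError(
                    f"gene {p.gene_id}: {p.values.size} values for a "
                    f"{self.grid.n_points}-point grid")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.profiles]

    def values_matrix(self) -> np.ndarray:
        """(n_genes, N) array of profile values."""
        return np.array([p.values for p in self.profiles], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values_matrix(), index=self.gene_ids,
                            columns=[f"t{k}" for k in range(1, self.grid.n_points + 1)])


# ---------------------------------------------------------------------------
# text formats: TSV matrix (gene_id + one column per time point) and TSV grid
# (time_hours, phase)
# ---------------------------------------------------------------------------

def read_time_grid(path) -> TimeGrid:
    df = pd.read_csv(path, sep="\t", dtype={"phase": str})
    for col in ("time_hours", "phase"):
        if col not in df.columns:
            raise ProfileDataError(f"grid file missing column {col!r}")
    return TimeGrid(df["time_hours"].to_numpy(float), tuple(df["phase"]))


def write_time_grid(grid: TimeGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_hours\tphase\n")
        for t, p in zip(grid.points, grid.phase_labels):
            fh.write(f"{float(t)!r}\t{p}\n")


def read_expression_matrix(path, grid_path) -> ProfileSet:
    """Load a TSV expression matrix against its grid file.

    Fails fast on dimension mismatches, non-numeric cells ("NA" etc.),
    negative ratios and duplicate gene ids, naming the offending row/cell.
    """
    grid = read_time_grid(grid_path)
    # na_filter off: "NA" must surface as a parse error, not become NaN
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    if df.columns[0] != "gene_id":
        raise ProfileDataError("first column of the matrix must be 'gene_id'")
    n_cols = df.shape[1] - 1
    if n_cols != grid.n_points:
        raise ProfileDataError(
            f"matrix has {n_cols} data columns but grid has "
            f"{grid.n_points} points")
    profiles = []
    for row_i, row in enumerate(df.itertuples(index=False), start=1):
        gene = row[0]
        vals = np.empty(n_cols)
        for j, cell in enumerate(row[1:]):
            try:
                vals[j] = float(cell)
            except (TypeError, ValueError):
                raise ProfileDataError(
                    f"non-numeric cell {cell!r} at row {row_i} "
                    f"(gene {gene}), column {df.columns[j + 1]!r}") from None
        if not np.all(np.isfinite(vals)):
            raise ProfileDataError(
                f"non-finite value at row {row_i} (gene {gene})")
        profiles.append(ExpressionProfile(gene, vals))
    return ProfileSet(grid, tuple(profiles))


def write_expression_matrix(pset: ProfileSet, path) -> None:
    """Write the canonical TSV form (floats via repr: read/write round-trips
    the text bit-identically)."""
    buf = io.StringIO()
    cols = "\t".join(f"t{k}" for k in range(1, pset.grid.n_points + 1))
    buf.write(f"gene_id\t{cols}\n")
    for p in pset.profiles:
        buf.write(p.gene_id + "\t"
                  + "\t".join(repr(float(v)) for v in p.values) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ratio_profiles(sample_intensities: dict[str, np.ndarray],
                   reference_intensities: dict[str, float],
                   grid: TimeGrid) -> ProfileSet:
    """Form X_mu(tau_k) = I_mu(tau_k) / I_mu^R per gene.

    The reference intensity must be strictly positive for every gene.
    """
    profiles = []
    for gene, intens in sample_intensities.items():
        try:
            ref = float(reference_intensities[gene])
        except KeyError:
            raise ProfileDataError(f"no reference intensity for gene {gene}") from None
        if not ref > 0:
            raise ProfileDataError(
                f"gene {gene}: reference intensity must be > 0, got {ref}")
        profiles.append(ExpressionProfile(gene, np.asarray(intens, float) / ref))
    return ProfileSet(grid, tuple(profiles))


def select_phase(pset: ProfileSet, phase: str = "all") -> ProfileSet:
    """Restrict a ProfileSet to one developmental phase ("all" = identity)."""
    if phase == "all":
        return pset
    mask = pset.grid.phase_mask(phase)
    sub = pset.grid.subgrid(mask)
    return ProfileSet(sub, tuple(ExpressionProfile(p.gene_id, p.values[mask])
                                 for p in pset.profiles))
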