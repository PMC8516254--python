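"""Haplotype panel data model.

A *panel* is a set of inbred lines scored at a set of *reference ranges*
(genomic intervals bounded by gene models). At each range every line carries
a single integer haplotype ID drawn from the founder haplotypes of the
population; fully homozygous inbreds are represented by one ID per range.

From the panel this module builds the linear-algebra objects used by the
mixed models downstream:

* per-range 0/1 haplotype indicator (design) matrices ``Z``,
* trace-normalised haplotype relationship matrices ``H = ZZ' / (tr(ZZ')/n)``,
  either per range (the *cis* kernel) or concatenated over all genic ranges
  (the *trans* kernel),
* haplotype frequency spectra and their Shannon entropy (plug-in estimator,
  natural log).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputError, NumericalError

#: sentinel for a missing haplotype assignment
MISSING = -1


@dataclass(frozen=True)
class ReferenceRange:
    """A genomic interval hosting one haplotype per line (BED convention:
    0-based, half-open)."""

    range_id: str
    chrom: str
    start: int
    end: int
    genic: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"range {self.range_id}: start ({self.start}) must be < end ({self.end})"
            )


class HaplotypePanel:
    """Lines x reference-ranges table of integer haplotype IDs.

    Parameters
    ----------
    assignments
        DataFrame indexed by line ID with one column per range ID, integer
        haplotype IDs, ``MISSING`` (= -1) marking absent assignments.
    ranges
        Optional list of :class:`ReferenceRange` giving coordinates for the
        columns; when omitted, ranges are treated as abstract ordered labels.
    """

    def __init__(
        self,
        assignments: pd.DataFrame,
        ranges: Sequence[ReferenceRange] | None = None,
    ) -> None:
        if assignments.index.duplicated().any():
            dupes = assignments.index[assignments.index.duplicated()].unique().tolist()
            raise InputError(f"duplicated line ids: {dupes}")
        self.assignments = assignments.astype(np.int64)
        if ranges is not None:
            by_id = {r.range_id: r for r in ranges}
            if len(by_id) != len(ranges):
                raise InputError("duplicated range_ids in range definitions")
            missing = [c for c in assignments.columns if c not in by_id]
            if missing:
                raise InputError(f"ranges absent from BED definitions: {missing}")
            ranges = [by_id[c] for c in assignments.columns]
        self.ranges = ranges

    # -- basic accessors ---------------------------------------------------
    @property
    def line_ids(self) -> pd.Index:
        return self.assignments.index

    @property
    def range_ids(self) -> pd.Index:
        return self.assignments.columns

    @property
    def n_lines(self) -> int:
        return len(self.assignments.index)

    @property
    def n_ranges(self) -> int:
        return len(self.assignments.columns)

    def counts(self, range_id: str) -> dict[int, int]:
        """Haplotype ID -> number of carriers at ``range_id`` (missing excluded)."""
        if range_id not in self.assignments.columns:
            raise InputError(f"unknown range_id: {range_id}")
        col = self.assignments[range_id].to_numpy()
        col = col[col != MISSING]
        ids, cnt = np.unique(col, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, cnt)}

    def subset_lines(self, line_ids: Iterable[str]) -> "HaplotypePanel":
        return HaplotypePanel(self.assignments.loc[list(line_ids)], self.ranges)

    @staticmethod
    def concat(panels: Sequence["HaplotypePanel"]) -> "HaplotypePanel":
        """Stack panels scored on identical ranges (line ids must be disjoint)."""
        cols = panels[0].assignments.columns
        for p in panels[1:]:
            if not p.assignments.columns.equals(cols):
                raise InputError("panels have different range sets; cannot concatenate")
        return HaplotypePanel(
            pd.concat([p.assignments for p in panels], axis=0), panels[0].ranges
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return self.assignments.equals(other.assignments)

    def __repr__(self) -> str:
        return f"HaplotypePanel({self.n_lines} lines x {self.n_ranges} ranges)"


@dataclass
class DesignMatrix:
    """0/1 haplotype indicator matrix for one reference range.

    Rows follow the panel's line order restricted to the lines given in
    ``line_ids``; columns follow ascending haplotype ID. A line missing its
    assignment keeps an all-zero row and is flagged in ``missing_lines``.
    """

    Z: np.ndarray
    haplotypes: np.ndarray  # ascending integer IDs, one per column
    line_ids: pd.Index
    range_id: str
    missing_lines: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def drop_missing(self) -> "DesignMatrix":
        """Restrict to lines with a present assignment."""
        keep = self.Z.sum(axis=1) > 0
        return DesignMatrix(
            self.Z[keep],
            self.haplotypes,
            self.line_ids[keep],
            self.range_id,
            pd.Index([]),
        )


@dataclass
class RelationshipMatrix:
    """Trace-normalised similarity between lines: ``H = ZZ' / (tr(ZZ')/n)``."""

    H: np.ndarray
    line_ids: pd.Index
    kind: str = "cis"  # "cis" or "trans"

    @property
    def n(self) -> int:
        return self.H.shape[0]


def build_design_matrix(panel: HaplotypePanel, range_id: str) -> DesignMatrix:
    """Indicator matrix over the haplotypes observed at ``range_id``.

    Column order is ascending haplotype ID; zero-carrier columns never
    appear because columns are built from observed IDs only.
    """
    if range_id not in panel.assignments.columns:
        raise InputError(f"unknown range_id: {range_id}")
    col = panel.assignments[range_id].to_numpy()
    present = col != MISSING
    if not present.any():
        raise InputError(f"range {range_id}: all assignments missing")
    haps = np.unique(col[present])
    Z = np.zeros((len(col), len(haps)))
    idx = np.searchsorted(haps, col[present])
    Z[np.flatnonzero(present), idx] = 1.0
    return DesignMatrix(
        Z=Z,
        haplotypes=haps,
        line_ids=panel.line_ids,
        range_id=range_id,
        missing_lines=panel.line_ids[~present],
    )


def build_hrm(design: DesignMatrix | np.ndarray, kind: str = "cis") -> RelationshipMatrix:
    """``H = ZZ' / (tr(ZZ')/n)`` so that ``tr(H) = n`` exactly."""
    if isinstance(design, DesignMatrix):
        Z, line_ids = design.Z, design.line_ids
    else:
        Z = np.asarray(design, dtype=float)
        line_ids = pd.RangeIndex(Z.shape[0])
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise InputError("design matrix must be 2-D with at least one column")
    n = Z.shape[0]
    if n < 2:
        raise InputError("relationship matrix needs at least 2 lines")
    G = Z @ Z.T
    tr = np.trace(G)
    if tr <= 0:
        raise NumericalError("zero trace: all design rows are zero")
    H = G * (n / tr)
    return RelationshipMatrix(H=H, line_ids=line_ids, kind=kind)


def build_trans_hrm(
    panel: HaplotypePanel,
    range_ids: Sequence[str] | None = None,
    exclude: str | None = None,
) -> RelationshipMatrix:
    """Genome-wide ("trans") HRM from the column-concatenated indicators of
    all supplied genic ranges.

    ``exclude`` optionally leaves one focal range out; by default all ranges
    are included, the focal gene's own range among them.
    """
    if range_ids is None:
        range_ids = list(panel.range_ids)
    range_ids = [r for r in range_ids if r != exclude]
    if len(range_ids) == 0:
        raise InputError("empty range list for trans HRM")
    A = panel.assignments[range_ids].to_numpy()  # n x m of IDs
    n = A.shape[0]
    # ZZ' entry (i,j) = number of ranges where i and j share a present haplotype
    G = np.zeros((n, n))
    for k in range(A.shape[1]):
        col = A[:, k]
        match = (col[:, None] == col[None, :]) & (col != MISSING)[:, None] & (
            col != MISSING
        )[None, :]
        G += match
    tr = np.trace(G)
    if tr <= 0:
        raise NumericalError("zero trace: no present assignments in trans ranges")
    H = G * (n / tr)
    return RelationshipMatrix(H=H, line_ids=panel.line_ids, kind="trans")


def haplotype_entropy(counts: Mapping[int, int] | Sequence[int]) -> float:
    """Plug-in (maximum-likelihood) Shannon entropy, in nats.

    ``-sum p ln p`` with ``p = count / total``; zero counts are ignored.
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts),
        dtype=float,
    )
    if (vals < 0).any():
        raise InputError("negative haplotype counts")
    total = vals.sum()
    if total <= 0:
        raise InputError("entropy undefined: all counts are zero")
    p = vals[vals > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class EntropyReport:
    """Per-range haplotype counts and entropy plus panel-wide medians."""

    counts: dict[str, dict[int, int]]
    entropy: pd.Series  # per range, nats
    median_frequency: float  # median over all (range, haplotype) count entries
    median_entropy: float

    def frequencies(self) -> np.ndarray:
        """All (range, haplotype) count entries, flattened."""
        return np.array(
            [c for per_range in self.counts.values() for c in per_range.values()],
            dtype=float,
        )


def panel_summary(panel: HaplotypePanel) -> EntropyReport:
    """Haplotype frequency spectrum and per-range entropy of a panel."""
    if panel.n_lines == 0 or panel.n_ranges == 0:
        raise InputError("empty panel")
    counts = {rid: panel.counts(rid) for rid in panel.range_ids}
    entropy = pd.Series(
        {rid: haplotype_entropy(c) for rid, c in counts.items()}, name="entropy"
    )
    freqs = np.array(
        [c for per_range in counts.values() for c in per_range.values()], dtype=float
    )
    return EntropyReport(
        counts=counts,
        entropy=entropy,
        median_frequency=float(np.median(freqs)),
        median_entropy=float(entropy.median()),
    )


def tissue_pairs(tissues: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of tissue labels (7 tissues -> 21 pairs)."""
    return list(itertools.combinations(tissues, 2))
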