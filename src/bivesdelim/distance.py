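"""Raw pairwise difference counts with pairwise deletion.

Distances are model-free: the number of mismatching columns between two
sequences, counted only over columns where *both* sequences carry an
unambiguous base (pairwise deletion of gaps, N and IUPAC ambiguity
codes). This is the "No. of differences" metric with the joint
"Gaps/Missing Data = Pairwise deletion" treatment, the substrate for
both threshold OTU clustering and neighbour-joining here. A pair with
no jointly resolved column has an *undefined* distance (NaN), which is
reported rather than imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .seq_core import Alignment

__all__ = [
    "DistanceMatrix",
    "DistanceError",
    "pairwise_differences",
    "group_distance_summary",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MISSING_CODE = -1


class DistanceError(ValueError):
    """Invalid distance-matrix input or operation."""


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode an alignment as an int8 matrix; missing/ambiguous -> -1."""
    n, length = len(aln), aln.length
    codes = np.full((n, length), MISSING_CODE, dtype=np.int8)
    for i, seq in enumerate(aln):
        row = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
        for base, code in _CODE.items():
            codes[i, row == ord(base)] = code
    return codes


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus the per-pair count of comparable sites.

    ``values[i, j]`` is NaN when the pair shares no comparable column.
    """

    labels: tuple
    values: np.ndarray
    comparable_sites: np.ndarray
    metric: str = "raw_differences"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise DistanceError("matrix shapes do not match label count")
        if self.metric not in ("raw_differences", "p_distance"):
            raise DistanceError(f"unknown metric {self.metric!r}")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise DistanceError("duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def comparable(self, a: str, b: str) -> int:
        return int(self.comparable_sites[self._index[a], self._index[b]])

    def undefined_pairs(self) -> list:
        """Label pairs (i < j) whose distance is undefined."""
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_p_distance(self) -> "DistanceMatrix":
        """Convert raw differences to proportional distances.

        Exact relationship: p_distance * comparable_sites == raw_differences.
        """
        if self.metric != "raw_differences":
            raise DistanceError("already a p-distance matrix")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.values / self.comparable_sites
        np.fill_diagonal(p, 0.0)
        return DistanceMatrix(self.labels, p, self.comparable_sites.copy(),
                              metric="p_distance")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | os.PathLike) -> None:
        """Square CSV with a leading label column."""
        self.to_dataframe().to_csv(path, index_label="id")

    def to_phylip(self, path: str | os.PathLike) -> None:
        """PHYLIP square (relaxed label) format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                cells = " ".join("NA" if np.isnan(v) else f"{v:g}" for v in row)
                fh.write(f"{lab}  {cells}\n")

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(tuple(labels),
                              self.values[np.ix_(idx, idx)].copy(),
                              self.comparable_sites[np.ix_(idx, idx)].copy(),
                              metric=self.metric)


def pairwise_differences(aln: Alignment) -> DistanceMatrix:
    """Count mismatching columns per pair under pairwise deletion.

    For each pair, columns where either member carries a gap, N or an
    ambiguity code are excluded; the distance is the number of the
    remaining columns at which the two sequences differ, and
    ``comparable_sites`` records how many columns were included.
    """
    codes = encode_alignment(aln)
    valid = (codes != MISSING_CODE)
    v = valid.astype(np.float64)
    comparable = v @ v.T
    # matches = sum over bases of co-occurrence of that base at a column
    matches = np.zeros_like(comparable)
    for b in range(4):
        ind = ((codes == b) & valid).astype(np.float64)
        matches += ind @ ind.T
    diffs = comparable - matches
    values = diffs.copy()
    values[comparable == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    comp = comparable.astype(np.int64)
    return DistanceMatrix(aln.ids, values, comp, metric="raw_differences")


@dataclass
class GroupDistanceSummary:
    within: pd.DataFrame   # group, n, min, max (NaN for singletons)
    between: pd.DataFrame  # group_a, group_b, min, max


def group_distance_summary(dm: DistanceMatrix,
                           groups: Mapping[str, str]) -> GroupDistanceSummary:
    """Min/max distances within each group and between each group pair.

    Singleton groups have undefined within-group values. Undefined
    pairwise distances are skipped in the extrema (all-undefined cells
    yield NaN).
    """
    missing = [lab for lab in dm.labels if lab not in groups]
    if missing:
        raise DistanceError(f"labels without a group assignment: {missing}")
    unknown = [lab for lab in groups if lab not in dm.labels]
    if unknown:
        raise DistanceError(f"group labels not in matrix: {unknown}")

    order: list = []
    for lab in dm.labels:
        g = groups[lab]
        if g not in order:
            order.append(g)
    members = {g: [lab for lab in dm.labels if groups[lab] == g] for g in order}

    def _extrema(labs_a, labs_b, exclude_self: bool) -> tuple:
        vals = []
        for a in labs_a:
            for b in labs_b:
                if exclude_self and a >= b:
                    continue
                v = dm.get(a, b)
                if not np.isnan(v):
                    vals.append(v)
        if not vals:
            return (np.nan, np.nan)
        return (min(vals), max(vals))

    within_rows = []
    for g in order:
        labs = members[g]
        lo, hi = (np.nan, np.nan) if len(labs) < 2 else _extrema(labs, labs, True)
        within_rows.append({"group": g, "n": len(labs), "min": lo, "max": hi})
    between_rows = []
    for i, g1 in enumerate(order):
        for g2 in order[i + 1:]:
            lo, hi = _extrema(members[g1], members[g2], False)
            between_rows.append({"group_a": g1, "group_b": g2, "min": lo, "max": hi})
    return GroupDistanceSummary(
        within=pd.DataFrame(within_rows, columns=["group", "n", "min", "max"]),
        between=pd.DataFrame(between_rows, columns=["group_a", "group_b", "min", "max"]),
    )
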