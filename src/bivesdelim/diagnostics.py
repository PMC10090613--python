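"""Pre-analysis alignment quality checks.

Two diagnostics are run on each marker before distances and trees are
computed, mirroring the usual barcode workflow:

* base-composition stationarity — a classic R x C chi-square test of the
  per-taxon A/C/G/T counts against the pooled expectation. Strong
  compositional heterogeneity between taxa violates the assumptions of
  most distance and tree methods.
* substitution saturation — an entropy-based saturation index compared
  against a seeded randomization null. A fully saturated alignment has
  columns indistinguishable from uniform random draws over the four
  bases; the alignment is declared saturated when its index is *not*
  significantly below that null.

Neither check blocks the pipeline; both annotate the run report, which
matches how such tests are used in practice (go/no-go context for the
analyst, not filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance import encode_alignment
from .seq_core import Alignment

__all__ = [
    "CompositionTest",
    "SaturationReport",
    "composition_chi2",
    "saturation_index",
    "DiagnosticsError",
]

BASES = ("A", "C", "G", "T")


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionTest:
    statistic: float
    df: int
    p_value: float
    per_taxon_counts: pd.DataFrame
    sites: str = "all"

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "sites": self.sites}


def composition_chi2(aln: Alignment, sites: str = "all") -> CompositionTest:
    """Chi-square test of base-composition homogeneity across taxa.

    Counts only unambiguous A/C/G/T characters. ``sites="variable"``
    restricts counting to variable alignment columns (implementations of
    this test differ on this point, so both are offered; all sites is
    the default). The statistic is the classic contingency-table
    chi-square with df = (n_taxa - 1) * 3; cells whose expectation is
    zero (a base absent from the whole table) contribute nothing.
    """
    if sites not in ("all", "variable"):
        raise DiagnosticsError(f"unknown sites option {sites!r}")
    codes = encode_alignment(aln)
    if sites == "variable":
        keep = []
        for j in range(codes.shape[1]):
            col = codes[:, j]
            obs = col[col >= 0]
            if obs.size and not np.all(obs == obs[0]):
                keep.append(j)
        codes = codes[:, keep] if keep else codes[:, :0]
    counts = np.zeros((len(aln), 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=1)
    row_tot = counts.sum(axis=1)
    empty = [aln.ids[i] for i in np.nonzero(row_tot == 0)[0]]
    if empty:
        raise DiagnosticsError(f"taxa with no countable bases: {empty}")
    col_tot = counts.sum(axis=0)
    total = counts.sum()
    expected = np.outer(row_tot, col_tot) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    statistic = float(cells.sum())
    dof = (len(aln) - 1) * 3
    p = float(stats.chi2.sf(statistic, dof)) if statistic > 0 else 1.0
    table = pd.DataFrame(counts, index=aln.ids, columns=BASES)
    return CompositionTest(statistic=statistic, df=dof, p_value=p,
                           per_taxon_counts=table, sites=sites)


@dataclass(frozen=True)
class SaturationReport:
    iss: float
    null_mean: float
    null_q05: float
    null_q50: float
    null_q95: float
    saturated: bool
    n_randomizations: int
    alpha: float
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {"iss": self.iss, "null_mean": self.null_mean,
                "null_q05": self.null_q05, "null_q50": self.null_q50,
                "null_q95": self.null_q95, "saturated": self.saturated,
                "n_randomizations": self.n_randomizations,
                "alpha": self.alpha, "warnings": list(self.warnings)}


def _column_entropy_index(counts: np.ndarray, n_taxa: int) -> np.ndarray:
    """Mean per-column Shannon entropy scaled to [0, 1].

    ``counts``: (..., n_columns, 4) base counts per column. The scaling
    denominator is log(min(4, n_taxa)), the maximum entropy a column of
    n_taxa states can attain over a 4-letter alphabet.
    """
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    h = terms.sum(axis=-1)
    h_max = np.log(min(4, n_taxa))
    return h.mean(axis=-1) / h_max


def saturation_index(aln: Alignment, n_randomizations: int = 1000,
                     seed: int = 0, alpha: float = 0.05) -> SaturationReport:
    """Entropy-based substitution-saturation assessment.

    The index is the mean per-site Shannon entropy of the observed
    columns divided by its maximum, so an invariant alignment scores 0
    and an alignment of uniform-random columns scores near 1. The null
    distribution of the index under full saturation is obtained by
    drawing, for each randomization, every column's base counts from a
    uniform multinomial over A/C/G/T with the same taxon count. The
    alignment is reported saturated when the observed index is not below
    the lower ``alpha`` quantile of that null (one-sided test).

    Deterministic for a fixed seed.
    """
    n = len(aln)
    if n < 4:
        raise DiagnosticsError("saturation test requires >= 4 sequences")
    warnings = []
    if n_randomizations < 100:
        warnings.append(
            f"n_randomizations={n_randomizations} < 100: null quantiles are coarse"
        )
    codes = encode_alignment(aln)
    length = codes.shape[1]
    obs_counts = np.zeros((length, 4), dtype=np.int64)
    for b in range(4):
        obs_counts[:, b] = (codes == b).sum(axis=0)
    iss = float(_column_entropy_index(obs_counts, n))

    rng = np.random.default_rng(seed)
    null_counts = rng.multinomial(n, [0.25] * 4,
                                  size=(n_randomizations, length))
    null = _column_entropy_index(null_counts, n)
    q05, q50, q95 = np.quantile(null, [alpha, 0.5, 1 - alpha])
    saturated = bool(iss >= q05)
    return SaturationReport(iss=iss, null_mean=float(null.mean()),
                            null_q05=float(q05), null_q50=float(q50),
                            null_q95=float(q95), saturated=saturated,
                            n_randomizations=n_randomizations, alpha=alpha,
                            warnings=tuple(warnings))
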