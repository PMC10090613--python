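"""Host/locality records, distinction flags and morphometric derivations.

The molecular side of the pipeline (distances, OTUs, trees) says which
lineages exist; this module carries the non-molecular evidence the
decision engine combines with it:

* host records — which fish species (and families) each OTU or taxon
  infects, with prevalence counts; the default biological-distinction
  rule is *shared host family*, because regional populations of one
  species routinely differ in host species across localities while
  family-level disjunction (e.g. apogonids vs a pomacentrid) marks
  genuinely different biology;
* morphological distinction — an expert-judgement flag per pair, not a
  measurement-derived one. The morphometric helpers here (ratios,
  %-of-body-length positions, host-family shape comparisons) support
  that judgement; they do not replace it;
* shape comparison — body elongation (length/width) by host family,
  with exceedance counts and a rank-based two-sided test. The test is
  an addition over the plotted comparison it reproduces and is labelled
  as such in reports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HostRecord",
    "MorphRecord",
    "DistinctionMatrix",
    "EvidenceError",
    "assess_host_distinction",
    "host_association_summary",
    "derive_morphometrics",
    "shape_comparison",
    "read_host_records_csv",
    "write_host_records_csv",
]

HOST_FAMILIES = ("Holocentridae", "Muraenidae", "Serranidae", "other")

MORPH_FLAGS = ("distinct", "indistinguishable", "unknown")
BIO_FLAGS = ("distinct", "overlapping", "unknown")


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class HostRecord:
    """One OTU/taxon-host-locality infection record."""

    label: str
    host_species: str
    host_family: str
    locality: str = ""
    n_infected: int = 0
    n_examined: int = 0

    def __post_init__(self) -> None:
        if self.n_infected < 0 or self.n_examined < 0 \
                or self.n_infected > self.n_examined:
            raise EvidenceError(
                f"{self.label}: need 0 <= n_infected <= n_examined, got "
                f"{self.n_infected}/{self.n_examined}"
            )


HOST_CSV_COLUMNS = ["label", "host_species", "host_family", "locality",
                    "n_infected", "n_examined"]


def read_host_records_csv(path: str | os.PathLike) -> list:
    df = pd.read_csv(path)
    missing = set(HOST_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise EvidenceError(f"{path}: missing columns {sorted(missing)}")
    return [
        HostRecord(label=str(r.label), host_species=str(r.host_species),
                   host_family=str(r.host_family), locality=str(r.locality),
                   n_infected=int(r.n_infected), n_examined=int(r.n_examined))
        for r in df.itertuples()
    ]


def write_host_records_csv(records: Iterable[HostRecord],
                           path: str | os.PathLike) -> None:
    pd.DataFrame([vars(r) for r in records])[HOST_CSV_COLUMNS].to_csv(
        path, index=False)


def assess_host_distinction(records: Iterable[HostRecord], a: str, b: str,
                            rule: str = "shared_family") -> str:
    """Biology flag for a pair of labels from their host records.

    ``shared_family`` (default): "overlapping" iff the two labels share
    at least one host family, else "distinct". ``shared_species``: the
    same at host-species level. A label with no records yields
    "unknown".
    """
    if rule not in ("shared_family", "shared_species"):
        raise EvidenceError(f"unknown rule {rule!r}")
    key = "host_family" if rule == "shared_family" else "host_species"
    sets = {a: set(), b: set()}
    for rec in records:
        if rec.label in sets:
            sets[rec.label].add(getattr(rec, key))
    if not sets[a] or not sets[b]:
        return "unknown"
    return "overlapping" if sets[a] & sets[b] else "distinct"


@dataclass
class HostAssociationSummary:
    per_species: pd.DataFrame       # species, host_families, host_species, localities
    species_per_family: dict        # family -> count of species with >= 1 record
    species_per_host: dict          # host species name -> count of species

    def species_from_host(self, host_species: str) -> int:
        return self.species_per_host.get(host_species, 0)


def host_association_summary(records: Iterable[HostRecord],
                             species_map: Mapping[str, str]) -> HostAssociationSummary:
    """Host families/species/localities per species plus global counts.

    ``species_map`` maps record labels (OTUs or taxa) to species names;
    every record's label must be mapped. Counts are invariant to record
    order and duplication of identical records.
    """
    records = list(records)
    unmapped = sorted({r.label for r in records} - set(species_map))
    if unmapped:
        raise EvidenceError(f"record labels without a species mapping: {unmapped}")
    fam: dict = {}
    hosts: dict = {}
    locs: dict = {}
    for rec in records:
        sp = species_map[rec.label]
        fam.setdefault(sp, set()).add(rec.host_family)
        hosts.setdefault(sp, set()).add(rec.host_species)
        locs.setdefault(sp, set()).add(rec.locality)
    species = sorted(fam)
    per_species = pd.DataFrame(
        {"species": species,
         "host_families": [sorted(fam[s]) for s in species],
         "host_species": [sorted(hosts[s]) for s in species],
         "localities": [sorted(locs[s]) for s in species]})
    species_per_family: dict = {}
    species_per_host: dict = {}
    for s in species:
        for f in fam[s]:
            species_per_family[f] = species_per_family.get(f, 0) + 1
        for h in hosts[s]:
            species_per_host[h] = species_per_host.get(h, 0) + 1
    return HostAssociationSummary(per_species=per_species,
                                  species_per_family=species_per_family,
                                  species_per_host=species_per_host)


@dataclass(frozen=True)
class MorphRecord:
    """Raw morphometrics of one specimen, in micrometres.

    Positional fields record the distance of a landmark from the body
    extremity named in the field (``*_from_anterior`` /
    ``*_from_posterior``), following the convention of the species
    descriptions ("% body length, from anterior extremity").
    """

    specimen_id: str
    label: str
    host_family: str
    body_length: float
    body_width: float
    gravid: bool = True
    pharynx_length: Optional[float] = None
    pharynx_width: Optional[float] = None
    oesophagus_length: Optional[float] = None
    caeca_end_from_posterior: Optional[float] = None
    testis_length: Optional[float] = None
    testis_width: Optional[float] = None
    testis_from_anterior: Optional[float] = None
    cirrus_sac_length: Optional[float] = None
    cirrus_sac_width: Optional[float] = None
    cirrus_sac_from_anterior: Optional[float] = None
    ovary_length: Optional[float] = None
    ovary_width: Optional[float] = None
    ovary_from_posterior: Optional[float] = None
    vitelline_start_from_anterior: Optional[float] = None
    vitelline_end_from_posterior: Optional[float] = None
    egg_length: Optional[float] = None
    egg_width: Optional[float] = None
    excretory_arm_tip_from_anterior: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.body_length or self.body_length <= 0:
            raise EvidenceError(f"{self.specimen_id}: body_length must be positive")
        if not self.body_width or self.body_width <= 0:
            raise EvidenceError(f"{self.specimen_id}: body_width must be positive")
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v is not None:
                if v <= 0:
                    raise EvidenceError(f"{self.specimen_id}: {f.name} must be positive")
                if f.name.endswith(("_from_anterior", "_from_posterior")) \
                        and v > self.body_length:
                    raise EvidenceError(
                        f"{self.specimen_id}: {f.name}={v} exceeds body_length")


def _pct(position: float, body_length: float) -> float:
    return 100.0 * position / body_length


def derive_morphometrics(rec: MorphRecord) -> dict:
    """Ratios and %-of-body-length positions derived from one record.

    Every positional landmark is reported in absolute micrometres and as
    a percentage of body length from both extremities (the two
    percentages sum to exactly 100). Metrics whose raw fields are absent
    are omitted.
    """
    L = rec.body_length
    out: dict = {
        "body_length": L,
        "body_width": rec.body_width,
        "elongation": L / rec.body_width,
    }
    if rec.pharynx_length and rec.pharynx_width:
        out["pharynx_ratio"] = rec.pharynx_length / rec.pharynx_width
    if rec.pharynx_length:
        out["pharynx_pct_body_length"] = _pct(rec.pharynx_length, L)
    positional = {
        "caeca_end": ("posterior", rec.caeca_end_from_posterior),
        "testis": ("anterior", rec.testis_from_anterior),
        "cirrus_sac": ("anterior", rec.cirrus_sac_from_anterior),
        "ovary": ("posterior", rec.ovary_from_posterior),
        "vitelline_start": ("anterior", rec.vitelline_start_from_anterior),
        "vitelline_end": ("posterior", rec.vitelline_end_from_posterior),
        "excretory_arm_tip": ("anterior", rec.excretory_arm_tip_from_anterior),
    }
    for name, (ref, value) in positional.items():
        if value is None:
            continue
        pct = _pct(value, L)
        out[f"{name}_um_from_{ref}"] = value
        out[f"{name}_pct_from_{ref}"] = pct
        other = "posterior" if ref == "anterior" else "anterior"
        out[f"{name}_pct_from_{other}"] = 100.0 - pct
    if (rec.vitelline_start_from_anterior is not None
            and rec.vitelline_end_from_posterior is not None):
        vit = L - rec.vitelline_start_from_anterior - rec.vitelline_end_from_posterior
        out["vitelline_field_um"] = vit
        out["vitelline_field_pct_body_length"] = _pct(vit, L)
    if rec.egg_length and rec.egg_width:
        out["egg_ratio"] = rec.egg_length / rec.egg_width
    return out


@dataclass
class ShapeComparison:
    metric: str
    group_stats: pd.DataFrame     # group, n, min, median, max
    exceedance: pd.DataFrame      # group_a, group_b, n_a_exceeding_max_b
    p_value: Optional[float]
    test: str
    scatter: pd.DataFrame         # specimen_id, group, body_length, body_width, metric
    notes: tuple = field(default_factory=tuple)


def shape_comparison(records: Iterable[MorphRecord], metric: str = "elongation",
                     group_by: str = "host_family") -> ShapeComparison:
    """Compare a derived shape metric between specimen groups.

    Groups with fewer than 2 records are described but excluded from the
    test. The two-sided p-value is a Mann-Whitney U rank test between
    the two eligible groups (more than two eligible groups is an error
    for the test; stats are still reported). Exceedance counts how many
    members of one group exceed the other group's maximum, in both
    directions.
    """
    rows = []
    for rec in records:
        derived = derive_morphometrics(rec)
        if metric not in derived:
            raise EvidenceError(
                f"metric {metric!r} not derivable for specimen {rec.specimen_id}")
        rows.append({"specimen_id": rec.specimen_id,
                     "group": getattr(rec, group_by),
                     "body_length": rec.body_length,
                     "body_width": rec.body_width,
                     "metric": derived[metric]})
    df = pd.DataFrame(rows)
    if df.empty or df["group"].nunique() < 2:
        raise EvidenceError("shape comparison requires >= 2 groups")
    notes = []
    stats_rows = []
    eligible = []
    for g, sub in df.groupby("group", sort=True):
        stats_rows.append({"group": g, "n": len(sub),
                           "min": sub["metric"].min(),
                           "median": sub["metric"].median(),
                           "max": sub["metric"].max()})
        if len(sub) >= 2:
            eligible.append(g)
        else:
            notes.append(f"group {g!r} has < 2 records; excluded from test")
    exceed_rows = []
    groups = sorted(df["group"].unique())
    for ga in groups:
        for gb in groups:
            if ga == gb:
                continue
            max_b = df.loc[df["group"] == gb, "metric"].max()
            n_exc = int((df.loc[df["group"] == ga, "metric"] > max_b).sum())
            exceed_rows.append({"group_a": ga, "group_b": gb,
                                "n_a_exceeding_max_b": n_exc})
    p_value = None
    if len(eligible) == 2:
        x = df.loc[df["group"] == eligible[0], "metric"]
        y = df.loc[df["group"] == eligible[1], "metric"]
        p_value = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    elif len(eligible) > 2:
        notes.append("more than two eligible groups; pairwise test not computed")
    else:
        notes.append("fewer than two eligible groups; test not computed")
    return ShapeComparison(
        metric=metric,
        group_stats=pd.DataFrame(stats_rows, columns=["group", "n", "min", "median", "max"]),
        exceedance=pd.DataFrame(exceed_rows,
                                columns=["group_a", "group_b", "n_a_exceeding_max_b"]),
        p_value=p_value,
        test="Mann-Whitney U, two-sided (rank-based; reporting addition, not a "
             "species criterion)",
        scatter=df,
        notes=tuple(notes),
    )


def plot_shape_scatter(comparison: ShapeComparison, path: str | os.PathLike) -> None:
    """Length-vs-width scatter by group (SVG/PNG by file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    markers = ["o", "s", "^", "D", "v"]
    for i, (g, sub) in enumerate(comparison.scatter.groupby("group", sort=True)):
        ax.scatter(sub["body_length"], sub["body_width"],
                   marker=markers[i % len(markers)],
                   facecolors="none" if i % 2 else None, label=str(g))
    ax.set_xlabel("body length (um)")
    ax.set_ylabel("body width (um)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


class DistinctionMatrix:
    """Symmetric per-pair morphology and biology distinction flags.

    Morphology flags are expert inputs ({distinct, indistinguishable,
    unknown}); biology flags ({distinct, overlapping, unknown}) may be
    set directly or derived from host records. Diagonals are fixed at
    indistinguishable/overlapping.
    """

    def __init__(self, labels: Iterable[str]):
        self.labels = tuple(labels)
        if len(set(self.labels)) != len(self.labels):
            raise EvidenceError("duplicate labels")
        self._morph: dict = {}
        self._bio: dict = {}

    @staticmethod
    def _key(a: str, b: str) -> frozenset:
        return frozenset((a, b))

    def _check(self, a: str, b: str) -> None:
        for lab in (a, b):
            if lab not in self.labels:
                raise EvidenceError(f"unknown label {lab!r}")

    def set_morphology(self, a: str, b: str, flag: str) -> None:
        self._check(a, b)
        if flag not in MORPH_FLAGS:
            raise EvidenceError(f"bad morphology flag {flag!r}")
        if a != b:
            self._morph[self._key(a, b)] = flag

    def set_biology(self, a: str, b: str, flag: str) -> None:
        self._check(a, b)
        if flag not in BIO_FLAGS:
            raise EvidenceError(f"bad biology flag {flag!r}")
        if a != b:
            self._bio[self._key(a, b)] = flag

    def morphology(self, a: str, b: str) -> str:
        self._check(a, b)
        if a == b:
            return "indistinguishable"
        return self._morph.get(self._key(a, b), "unknown")

    def biology(self, a: str, b: str) -> str:
        self._check(a, b)
        if a == b:
            return "overlapping"
        return self._bio.get(self._key(a, b), "unknown")

    def fill_biology_from_hosts(self, records: Iterable[HostRecord],
                                rule: str = "shared_family") -> None:
        records = list(records)
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                self.set_biology(a, b, assess_host_distinction(records, a, b, rule))

    def missing_pairs(self) -> list:
        out = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                if self._key(a, b) not in self._morph:
                    out.append((a, b))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                rows.append({"a": a, "b": b,
                             "morphology": self.morphology(a, b),
                             "biology": self.biology(a, b)})
        return pd.DataFrame(rows, columns=["a", "b", "morphology", "biology"])
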