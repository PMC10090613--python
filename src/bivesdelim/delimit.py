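"""The species-decision engine.

The recognition criterion: a species must be reciprocally monophyletic
on at least the most informative molecular marker (the guide tree,
cox1 by default) *plus* distinct either morphologically or biologically
(differing host distributions). Operationally the engine works the
other way round — it decides which OTUs may be *lumped*:

1. a pair of OTUs is merge-compatible iff its morphology flag is
   "indistinguishable" AND its biology flag is "overlapping"; an
   "unknown" flag blocks merging (absence of evidence never lumps);
2. candidate species are bipartition-clades of the guide tree whose
   member OTUs are pairwise merge-compatible; maximal such clades are
   selected greedily (largest first, lexicographic tie-break) without
   overlap, singletons filling the remainder;
3. an optional distance ceiling can veto lumps (off by default:
   divergence alone is explicitly not a criterion — conspecific
   populations can sit above the divergence of heterospecific pairs);
4. OTUs with unknown morphology (no voucher specimen) become
   provisional sequence-only species;
5. morphology-only taxa (no sequences) distinct from every OTU are
   appended as unsequenced morphospecies;
6. every hypothesis carries a justification trace naming, for each
   other hypothesis, the criterion separating them — including the
   purely topological case of cryptic non-sister lineages "separated by
   another clearly distinct species".

Taxa marked *comparative* (reference material from outside the sampled
collection) are delimited the same way but reported separately and not
counted among the collection's species hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

from .distance import DistanceMatrix
from .evidence import DistinctionMatrix
from .phylo import edge_bipartitions, is_bipartition_clade, restrict_tree

__all__ = [
    "CriteriaConfig",
    "EvidenceTable",
    "SpeciesHypothesis",
    "DelimitationResult",
    "DelimitError",
    "delimit_species",
    "explain_decision",
]


class DelimitError(ValueError):
    pass


@dataclass(frozen=True)
class CriteriaConfig:
    """Tunables of the recognition criteria."""

    otu_threshold: int = 10
    marker_priority: tuple = ("cox1", "ITS2", "28S")
    biology_rule: str = "shared_family"
    merge_distance_ceiling: Optional[int] = None

    def __post_init__(self) -> None:
        if self.otu_threshold < 1:
            raise DelimitError("otu_threshold must be >= 1")
        if not self.marker_priority:
            raise DelimitError("marker_priority must be non-empty")


@dataclass
class EvidenceTable:
    """Everything the engine consumes, bundled per analysis.

    ``guide_tree`` is the tree over OTU labels from the most informative
    marker; ``marker_trees`` may carry trees from the other markers
    (reported, never vetoing). ``comparative`` labels OTUs from outside
    the sampled collection. ``otu_distances`` (optional) holds OTU-level
    minimum raw differences for the distance-ceiling veto.
    """

    otus: tuple
    guide_tree: dendropy.Tree
    distinctions: DistinctionMatrix
    host_records: tuple = ()
    marker_trees: dict = field(default_factory=dict)
    morphospecies: tuple = ()
    comparative: frozenset = frozenset()
    name_hints: dict = field(default_factory=dict)
    otu_distances: Optional[DistanceMatrix] = None

    def __post_init__(self) -> None:
        self.otus = tuple(self.otus)
        self.comparative = frozenset(self.comparative)
        self.morphospecies = tuple(self.morphospecies)
        self.host_records = tuple(self.host_records)
        tree_leaves = frozenset(
            l.taxon.label for l in self.guide_tree.leaf_node_iter())
        if tree_leaves != frozenset(self.otus):
            raise DelimitError(
                "guide tree leaf set does not match OTU set: "
                f"tree-only {sorted(tree_leaves - set(self.otus))}, "
                f"otu-only {sorted(set(self.otus) - tree_leaves)}")
        if not self.comparative <= set(self.otus):
            raise DelimitError("comparative labels must be OTUs")
        expected = set(self.otus) | set(self.morphospecies)
        if set(self.distinctions.labels) != expected:
            raise DelimitError(
                "distinction matrix labels must cover all OTUs and morphospecies")


@dataclass
class JustificationEntry:
    other: str
    basis: str        # morphology | biology | topology | provisional | comparative
    detail: str

    def to_dict(self) -> dict:
        return {"other": self.other, "basis": self.basis, "detail": self.detail}


@dataclass
class SpeciesHypothesis:
    members: tuple                    # OTU labels; empty for morphology-only taxa
    status: str                       # named | provisional_sequence_only | unsequenced_morphospecies
    name: Optional[str] = None
    comparative: bool = False
    morpho_label: Optional[str] = None  # distinction-matrix label of a morphospecies
    justification: list = field(default_factory=list)

    @property
    def key(self) -> str:
        return self.name or "+".join(self.members)

    def to_dict(self) -> dict:
        return {"members": list(self.members), "status": self.status,
                "name": self.name, "comparative": self.comparative,
                "justification": [j.to_dict() for j in self.justification]}


@dataclass
class DelimitationResult:
    hypotheses: list                  # the collection's species hypotheses
    comparative_taxa: list            # reference taxa delimited alongside
    config: CriteriaConfig
    warnings: tuple = ()

    @property
    def n_species(self) -> int:
        return len(self.hypotheses)

    def all_hypotheses(self) -> list:
        return self.hypotheses + self.comparative_taxa

    def species_map(self) -> dict:
        """OTU/morphospecies label -> species key, over all hypotheses."""
        out = {}
        for hyp in self.all_hypotheses():
            for m in hyp.members:
                out[m] = hyp.key
            if not hyp.members:
                out[hyp.key] = hyp.key
        return out

    def find(self, which: str) -> SpeciesHypothesis:
        for hyp in self.all_hypotheses():
            if which == hyp.name or which == hyp.key or which in hyp.members:
                return hyp
        raise DelimitError(f"no species hypothesis matching {which!r}")

    def to_dict(self) -> dict:
        return {"n_species": self.n_species,
                "hypotheses": [h.to_dict() for h in self.hypotheses],
                "comparative_taxa": [h.to_dict() for h in self.comparative_taxa],
                "warnings": list(self.warnings)}


def _pair_compatible(dmx: DistinctionMatrix, a: str, b: str) -> bool:
    return (dmx.morphology(a, b) == "indistinguishable"
            and dmx.biology(a, b) == "overlapping")


def _set_compatible(dmx: DistinctionMatrix, members: Iterable[str]) -> bool:
    members = list(members)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if not _pair_compatible(dmx, a, b):
                return False
    return True


def _candidate_clades(tree: dendropy.Tree, focal: set) -> list:
    """Edge-induced leaf sets (both sides) of the tree restricted to focal OTUs."""
    if len(focal) < 2:
        return []
    sub = restrict_tree(tree, focal)
    leaves = frozenset(l.taxon.label for l in sub.leaf_node_iter())
    clades = {leaves}  # the full set is a clade by convention
    for side in edge_bipartitions(sub, include_trivial=True):
        for s in (side, leaves - side):
            if len(s) > 1:  # singletons are appended unconditionally later
                clades.add(s)
    return sorted(clades, key=lambda c: (-len(c), tuple(sorted(c))))


def delimit_species(ev: EvidenceTable,
                    cfg: CriteriaConfig | None = None) -> DelimitationResult:
    """Apply the recognition criteria; returns the full hypothesis set."""
    cfg = cfg or CriteriaConfig()
    dmx = ev.distinctions
    warnings: list = []

    def resolve(labels: Iterable[str]) -> list:
        """Greedy maximal merge-compatible clades over one label set."""
        labels = set(labels)
        provisional = {o for o in labels
                       if all(dmx.morphology(o, other) == "unknown"
                              for other in labels | set(ev.morphospecies)
                              if other != o)}
        mergeable = labels - provisional
        chosen: list = []
        taken: set = set()
        for clade in _candidate_clades(ev.guide_tree, labels):
            members = set(clade)
            if not members <= mergeable or members & taken:
                continue
            if len(members) < 2 or not _set_compatible(dmx, members):
                continue
            if cfg.merge_distance_ceiling is not None and ev.otu_distances is not None:
                mlist = sorted(members)
                if any(ev.otu_distances.get(a, b) > cfg.merge_distance_ceiling
                       for i, a in enumerate(mlist) for b in mlist[i + 1:]):
                    warnings.append(
                        f"merge of {mlist} vetoed by distance ceiling "
                        f"{cfg.merge_distance_ceiling}")
                    continue
            chosen.append(tuple(sorted(members)))
            taken |= members
        for o in sorted(labels - taken):
            chosen.append((o,))
        # post-hoc laminarity check (greedy construction guarantees it)
        seen: set = set()
        for members in chosen:
            assert not (set(members) & seen), "species members overlap"
            seen |= set(members)
        assert seen == labels
        hyps = []
        for members in sorted(chosen):
            if len(members) > 1:
                assert is_bipartition_clade(
                    restrict_tree(ev.guide_tree, labels), members)
            status = ("provisional_sequence_only"
                      if set(members) <= provisional else "named")
            names = {ev.name_hints[m] for m in members if m in ev.name_hints}
            if len(names) > 1:
                raise DelimitError(
                    f"conflicting name hints for merged OTUs {members}: {sorted(names)}")
            hyps.append(SpeciesHypothesis(
                members=members, status=status,
                name=names.pop() if names else None))
        return hyps

    focal = set(ev.otus) - ev.comparative
    hypotheses = resolve(focal)
    comparative_taxa = []
    if ev.comparative:
        comparative_taxa = resolve(ev.comparative)
        for hyp in comparative_taxa:
            hyp.comparative = True

    # morphology-only taxa
    for morpho in ev.morphospecies:
        flags = [dmx.morphology(morpho, o) for o in ev.otus]
        if any(f == "indistinguishable" for f in flags):
            culprits = [o for o in ev.otus
                        if dmx.morphology(morpho, o) == "indistinguishable"]
            warnings.append(
                f"morphospecies {morpho!r} is indistinguishable from OTU(s) "
                f"{culprits}; not appended as a separate species")
            continue
        if any(f == "unknown" for f in flags):
            warnings.append(
                f"morphospecies {morpho!r} has unknown distinction vs some OTUs; "
                "appended on the strength of the assessed pairs")
        hypotheses.append(SpeciesHypothesis(
            members=(), status="unsequenced_morphospecies",
            name=ev.name_hints.get(morpho, morpho), morpho_label=morpho))

    _attach_justifications(ev, hypotheses, comparative_taxa)
    return DelimitationResult(hypotheses=hypotheses,
                              comparative_taxa=comparative_taxa,
                              config=cfg, warnings=tuple(warnings))


def _pair_basis(ev: EvidenceTable, hyp_a: SpeciesHypothesis,
                hyp_b: SpeciesHypothesis) -> JustificationEntry:
    """Why two hypotheses are separate species."""
    dmx = ev.distinctions
    mem_a = hyp_a.members or (hyp_a.morpho_label or hyp_a.name,)
    mem_b = hyp_b.members or (hyp_b.morpho_label or hyp_b.name,)
    morph = {dmx.morphology(a, b) for a in mem_a for b in mem_b}
    bio = {dmx.biology(a, b) for a in mem_a for b in mem_b}
    if hyp_b.comparative and not hyp_a.comparative:
        prefix = "comparative reference taxon; "
    else:
        prefix = ""
    if "distinct" in morph:
        return JustificationEntry(hyp_b.key, "morphology",
                                  prefix + "morphologically distinct")
    if "distinct" in bio:
        return JustificationEntry(hyp_b.key, "biology",
                                  prefix + "host distributions do not overlap "
                                  "(differing host families)")
    if "unknown" in morph:
        return JustificationEntry(
            hyp_b.key, "provisional",
            prefix + "morphological comparison impossible (no voucher); "
            "held apart pending specimens")
    # cryptic pair: morphology indistinguishable, biology overlapping
    if hyp_a.members and hyp_b.members:
        both = set(hyp_a.members) | set(hyp_b.members)
        joint_clade = is_bipartition_clade(
            restrict_tree(ev.guide_tree,
                          set(ev.otus) - ev.comparative
                          if not (hyp_a.comparative or hyp_b.comparative)
                          else set(ev.otus)),
            both)
        if not joint_clade:
            return JustificationEntry(
                hyp_b.key, "topology",
                "morphologically indistinguishable with overlapping hosts, but "
                "not sister lineages on the guide tree: separated by another "
                "clearly distinct species, so the union is no clade")
    return JustificationEntry(
        hyp_b.key, "topology",
        "reciprocally monophyletic lineages retained as separate species")


def _attach_justifications(ev: EvidenceTable, hypotheses: list,
                           comparative_taxa: list) -> None:
    everything = hypotheses + comparative_taxa
    for hyp in everything:
        hyp.justification = [
            _pair_basis(ev, hyp, other)
            for other in everything if other is not hyp
        ]


def explain_decision(result: DelimitationResult, a: str, b: str,
                     ev: Optional[EvidenceTable] = None) -> str:
    """Human-readable trace of why two species in a result are separate."""
    hyp_a = result.find(a)
    hyp_b = result.find(b)
    if hyp_a is hyp_b:
        raise DelimitError(
            f"{a!r} and {b!r} resolve to the same species hypothesis ({hyp_a.key})")
    entry = next((j for j in hyp_a.justification if j.other == hyp_b.key), None)
    lines = [f"{hyp_a.key} vs {hyp_b.key}:"]
    lines.append(f"  members: {list(hyp_a.members) or '(morphology only)'} vs "
                 f"{list(hyp_b.members) or '(morphology only)'}")
    if entry is not None:
        lines.append(f"  separating criterion: {entry.basis}")
        lines.append(f"  detail: {entry.detail}")
    if ev is not None and hyp_a.members and hyp_b.members:
        both = set(hyp_a.members) | set(hyp_b.members)
        sister = is_bipartition_clade(
            restrict_tree(ev.guide_tree, set(ev.otus)), both)
        lines.append("  guide tree: the two lineages "
                     + ("form" if sister else "do not form")
                     + " an exclusive clade together")
    return "\n".join(lines)
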