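"""Pipeline orchestration and the JSON run report.

One run follows the analysis order diagnostics -> distances -> OTUs ->
trees -> synthesis: every marker alignment is quality-checked,
converted to a raw-difference matrix, clustered into OTUs and given a
bootstrapped neighbour-joining tree; if an evidence table is supplied
the species-decision engine then produces the hypothesis set with its
justification traces. All randomness flows from the single configured
seed, and every number in the report is reproducible from the archived
config + inputs + seed (reports carry no timestamps for this reason).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .delimit import CriteriaConfig, EvidenceTable, delimit_species
from .diagnostics import composition_chi2, saturation_index
from .distance import pairwise_differences
from .evidence import DistinctionMatrix, read_host_records_csv
from .otu_cluster import cluster_otus, partition_summary
from .phylo import bootstrap_support, parse_newick, tree_to_dict
from .seq_core import GeneticCode, read_fasta, scan_reading_frames

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_evidence_yaml",
           "export_evidence_yaml", "render_markdown"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    marker_inputs: dict                      # marker -> FASTA path
    out_dir: str
    threshold: int = 10
    bootstrap_replicates: int = 1000
    seed: int = 0
    evidence_path: Optional[str] = None      # YAML evidence table
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    saturation_randomizations: int = 1000

    def __post_init__(self) -> None:
        if not self.marker_inputs:
            raise PipelineError("at least one marker input is required")


def load_evidence_yaml(path: str | os.PathLike) -> EvidenceTable:
    """Read an evidence table from the documented YAML schema.

    Keys: ``otus`` (list), ``guide_tree`` (newick string or ``file:``
    path), ``morphology`` (list of [a, b, flag] triples; unlisted pairs
    are unknown), ``biology`` ("from_hosts" or a list of triples),
    ``host_records`` (CSV path, relative to the YAML file),
    ``morphospecies``, ``comparative``, ``name_hints``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    otus = [str(o) for o in doc["otus"]]
    tree_spec = doc["guide_tree"]
    if isinstance(tree_spec, str) and tree_spec.startswith("file:"):
        tree_text = (path.parent / tree_spec[5:]).read_text()
    else:
        tree_text = tree_spec
    guide_tree = parse_newick(tree_text)
    morphospecies = [str(m) for m in doc.get("morphospecies", [])]
    dmx = DistinctionMatrix(tuple(otus) + tuple(morphospecies))
    for a, b, flag in doc.get("morphology", []):
        dmx.set_morphology(str(a), str(b), str(flag))
    host_records = ()
    if doc.get("host_records"):
        host_records = tuple(read_host_records_csv(path.parent / doc["host_records"]))
    bio = doc.get("biology", "from_hosts")
    if bio == "from_hosts":
        if host_records:
            dmx.fill_biology_from_hosts(
                host_records, rule=doc.get("biology_rule", "shared_family"))
    else:
        for a, b, flag in bio:
            dmx.set_biology(str(a), str(b), str(flag))
    return EvidenceTable(
        otus=tuple(otus),
        guide_tree=guide_tree,
        distinctions=dmx,
        host_records=host_records,
        morphospecies=tuple(morphospecies),
        comparative=frozenset(str(c) for c in doc.get("comparative", [])),
        name_hints={str(k): str(v) for k, v in (doc.get("name_hints") or {}).items()},
    )


def export_evidence_yaml(ev: EvidenceTable, out_dir: str | os.PathLike,
                         stem: str = "evidence") -> Path:
    """Write an evidence table to the YAML schema ``load_evidence_yaml`` reads.

    Host records go to ``<stem>_hosts.csv`` next to the YAML; biology
    flags are written explicitly (not re-derived on load) so the export
    is faithful even for hand-set flags.
    """
    from .evidence import write_host_records_csv
    from .phylo import write_newick

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc: dict = {
        "otus": list(ev.otus),
        "guide_tree": write_newick(ev.guide_tree),
        "morphospecies": list(ev.morphospecies),
        "comparative": sorted(ev.comparative),
        "name_hints": dict(ev.name_hints),
        "morphology": [],
        "biology": [],
    }
    labels = ev.distinctions.labels
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            doc["morphology"].append([a, b, ev.distinctions.morphology(a, b)])
            doc["biology"].append([a, b, ev.distinctions.biology(a, b)])
    if ev.host_records:
        csv_name = f"{stem}_hosts.csv"
        write_host_records_csv(ev.host_records, out_dir / csv_name)
        doc["host_records"] = csv_name
    path = out_dir / f"{stem}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def _marker_section(marker: str, fasta_path: str, cfg: RunConfig,
                    out_dir: Path, seed: int) -> dict:
    coll = read_fasta(fasta_path, marker=marker)
    section: dict = {"input": str(fasta_path), "n_sequences": len(coll),
                     "alignment_capable": coll.is_alignment_capable}
    if not coll.is_alignment_capable:
        section["note"] = "unequal sequence lengths; marker skipped"
        return section
    aln = coll.to_alignment()
    section["alignment_length"] = aln.length

    diagnostics: dict = {"composition_chi2": composition_chi2(aln).to_dict()}
    if len(aln) >= 4:
        diagnostics["saturation"] = saturation_index(
            aln, n_randomizations=cfg.saturation_randomizations,
            seed=seed).to_dict()
    if marker == "cox1":
        code = GeneticCode.from_ncbi(9)
        frames = [scan_reading_frames(s, code) for s in aln]
        diagnostics["reading_frames"] = {
            "table_id": 9,
            "n_with_open_frame": sum(1 for f in frames if f.has_open_frame),
            "frame0_internal_stops": {f.sequence_id: f.stop_counts[0]
                                      for f in frames},
        }
    section["diagnostics"] = diagnostics

    dm = pairwise_differences(aln)
    dm.to_csv(out_dir / f"{marker}_distances.csv")
    section["distances"] = {
        "metric": dm.metric,
        "n_undefined_pairs": len(dm.undefined_pairs()),
        "max": float(np.nanmax(dm.values)) if len(dm) > 1 else 0.0,
        "csv": f"{marker}_distances.csv",
    }

    part = cluster_otus(dm, threshold=cfg.threshold)
    part.to_csv(out_dir / f"{marker}_otus.csv")
    summ = partition_summary(part, dm)
    section["otus"] = {
        "threshold": cfg.threshold,
        "n_otus": part.n_otus,
        "assignment": dict(part.assignment),
        "per_otu": summ.per_otu.to_dict(orient="records"),
        "warnings": list(part.warnings),
        "csv": f"{marker}_otus.csv",
    }

    if len(aln) >= 3 and not dm.undefined_pairs():
        tree = bootstrap_support(aln, replicates=cfg.bootstrap_replicates,
                                 seed=seed)
        tdict = tree_to_dict(tree)
        (out_dir / f"{marker}_nj.nwk").write_text(tdict["newick"] + "\n")
        section["tree"] = {**tdict,
                           "bootstrap_replicates": cfg.bootstrap_replicates,
                           "newick_file": f"{marker}_nj.nwk"}
    return section


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run; writes the report and artifacts to ``out_dir``.

    Returns the report dict. On error, partial outputs are preserved and
    the MANIFEST marks the run incomplete before the error propagates.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "outputs": []}
    report: dict = {
        "tool": {"name": "bivesdelim", "version": __version__},
        "seed": cfg.seed,
        "config": {"threshold": cfg.threshold,
                   "bootstrap_replicates": cfg.bootstrap_replicates,
                   "markers": {m: str(p) for m, p in cfg.marker_inputs.items()},
                   "evidence": cfg.evidence_path and str(cfg.evidence_path)},
        "markers": {},
    }
    try:
        rng = np.random.default_rng(cfg.seed)
        for marker in cfg.marker_inputs:
            marker_seed = int(rng.integers(0, 2**31 - 1))
            report["markers"][marker] = _marker_section(
                marker, cfg.marker_inputs[marker], cfg, out_dir, marker_seed)
            manifest["outputs"].append(f"{marker}_distances.csv")
        if cfg.evidence_path:
            ev = load_evidence_yaml(cfg.evidence_path)
            result = delimit_species(ev, cfg.criteria)
            report["species"] = result.to_dict()
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str))
        (out_dir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Human-readable rendering of the JSON run report."""
    lines = [f"# bivesdelim run report", "",
             f"seed: {report.get('seed')}", ""]
    for marker, sec in report.get("markers", {}).items():
        lines.append(f"## Marker: {marker}")
        lines.append(f"- sequences: {sec.get('n_sequences')}")
        if "alignment_length" in sec:
            lines.append(f"- alignment length: {sec['alignment_length']}")
        diag = sec.get("diagnostics", {})
        if "composition_chi2" in diag:
            c = diag["composition_chi2"]
            lines.append(f"- composition chi2 = {c['statistic']:.2f} "
                         f"(df {c['df']}, p = {c['p_value']:.3g})")
        if "saturation" in diag:
            s = diag["saturation"]
            lines.append(f"- saturation index = {s['iss']:.3f} "
                         f"({'saturated' if s['saturated'] else 'not saturated'})")
        if "otus" in sec:
            lines.append(f"- OTUs at threshold {sec['otus']['threshold']}: "
                         f"{sec['otus']['n_otus']}")
        lines.append("")
    if "species" in report:
        sp = report["species"]
        lines.append("## Species hypotheses")
        lines.append(f"- recognized species: {sp['n_species']}")
        for hyp in sp["hypotheses"]:
            name = hyp["name"] or "+".join(hyp["members"]) or "(unnamed)"
            members = ", ".join(hyp["members"]) or "morphology only"
            lines.append(f"  - {name} [{hyp['status']}]: {members}")
        if sp.get("comparative_taxa"):
            lines.append("- comparative reference taxa: "
                         + ", ".join(h["name"] or "+".join(h["members"])
                                     for h in sp["comparative_taxa"]))
        lines.append("")
    return "\n".join(lines)
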