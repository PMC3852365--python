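"""End-to-end orchestration: simulate -> pcr -> classify -> search ->
consensus -> annotate -> context -> rbip, with file-mediated stages and a
final truth-comparison report.

Every stage writes plain-text artifacts (FASTA/GFF3/TSV/JSON) into the run
directory so any stage can be re-run standalone; the run seed is recorded
in every provenance block and derives one sub-seed per stage.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio, reference
from .annotate import annotate_element, rt_core_peptide, assign_lineage
from .classify import (ClassifyParams, clone_from_amplicon, cut_families,
                       family_distribution_test, p_distance_matrix, trim_to_core)
from .consensus import InsufficientCopyError, iterative_extend, seed_consensus
from .context import ContextParams, family_context_report, profile_copies
from .pcr import amplify
from .rbip import NoMarkerError, design_marker, find_recent_insertions, genotype
from .search import SearchParams, count_hits
from .synthetic import implant_copies, plant_genes, random_genome, simulate_accessions


@dataclass
class RunConfig:
    seed: int = 7
    genome_size: int = 800_000
    copies_per_family: int = 3
    divergence: float = 0.02
    n_clones: int = 60
    clone_lines: list[str] = field(default_factory=lambda: list(reference.CLONE_LINES))
    primer_sets: list[str] = field(default_factory=lambda: ["F", "V"])
    families: list[str] = field(default_factory=lambda: [s.name for s in reference.FAMILY_TABLE])
    marker_family: str = "Jc7"
    panel_accessions: list[str] = field(default_factory=lambda: list(reference.PANEL_ACCESSIONS))
    panel_absent: list[str] = field(default_factory=lambda: list(reference.PANEL_ABSENT))
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    search: SearchParams = field(default_factory=SearchParams)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls()
        for k, v in data.items():
            if k == "classify":
                cfg.classify = ClassifyParams(**v)
            elif k == "search":
                cfg.search = SearchParams(**v)
            elif hasattr(cfg, k):
                setattr(cfg, k, v)
            else:
                raise KeyError(f"unknown config key {k!r}")
        return cfg


def _stage_seed(config: RunConfig, stage: str) -> int:
    import zlib

    tag = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([config.seed, tag]).generate_state(1)[0] % (2**31 - 1))


def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Build the reference genome, implant families, plant genes, write truth."""
    specs = [reference.FAMILIES[name] for name in config.families]
    templates = reference.build_reference_templates(config.seed,
                                                    families=specs if specs else None)
    genome = random_genome(config.genome_size, _stage_seed(config, "background"))
    for i, spec in enumerate(specs):
        implant_copies(genome, templates[spec.name], config.copies_per_family,
                       divergence=config.divergence,
                       seed=_stage_seed(config, f"implant:{spec.name}"))
    # one extra zero-divergence copy of the marker family: the RBIP locus
    if config.marker_family in templates:
        implant_copies(genome, templates[config.marker_family], 1, divergence=0.0,
                       seed=_stage_seed(config, "implant:marker"))
    plant_genes(genome, {s.name: s.flank_gene_prob for s in specs},
                seed=_stage_seed(config, "genes"))
    fileio.write_fasta(genome.contigs, outdir / "genome.fa")
    fileio.write_truth_gff3(genome, outdir / "truth.gff3", templates)
    fileio.write_provenance({"seed": config.seed, "genome_size": config.genome_size,
                             "families": config.families,
                             "copies_per_family": config.copies_per_family,
                             "divergence": config.divergence},
                            outdir / "provenance.json")
    return {"genome": genome, "templates": templates}


def pcr_stage(config: RunConfig, genome, outdir: Path) -> dict:
    amplicons = []
    for name in config.primer_sets:
        amplicons.extend(amplify(genome, reference.PRIMER_SETS[name]))
    rows = [{"contig": a.contig, "start": a.start, "end": a.end, "strand": a.strand,
             "length": len(a), "primer_set": a.primer_set, "mismatches": a.mismatches}
            for a in amplicons]
    pd.DataFrame(rows).to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
    fileio.write_fasta({f"amp{i}_{a.primer_set}": a.sequence
                        for i, a in enumerate(amplicons)}, outdir / "amplicons.fa")
    return {"amplicons": amplicons}


def classify_stage(config: RunConfig, amplicons, outdir: Path) -> dict:
    """Sample clones from the amplicon pool, classify into families."""
    rng = np.random.default_rng(_stage_seed(config, "clones"))
    clones = []
    if amplicons:
        picks = rng.integers(0, len(amplicons), size=config.n_clones)
        for i, pick in enumerate(picks):
            a = amplicons[pick]
            line = config.clone_lines[i % len(config.clone_lines)]
            clone = clone_from_amplicon(f"clone{i:03d}", line, a.primer_set, a.sequence,
                                        config.classify)
            if clone is None:
                warnings.warn(f"clone{i:03d} has no credible RT peptide; dropped")
                continue
            clones.append(clone)
    result = {"clones": clones, "assignment": None, "chi2": None}
    if len(clones) >= 3:
        block = trim_to_core(clones, config.classify)
        D = p_distance_matrix(block)
        assignment = cut_families(D, [c.id for c in clones], config.classify.family_cut)
        result["assignment"] = assignment
        (outdir / "tree.nwk").write_text(assignment.tree.newick() + "\n")
        fam = assignment.families
        table = pd.crosstab(pd.Series([c.accession for c in clones], name="accession"),
                            pd.Series([fam[c.id] for c in clones], name="family"))
        try:
            chi2, df, p = family_distribution_test(table.values)
            result["chi2"] = {"chi2": chi2, "df": df, "p": p}
        except ValueError as exc:
            result["chi2"] = {"error": str(exc)}
        pd.DataFrame([{"id": c.id, "accession": c.accession, "primer_set": c.primer_set,
                       "family": fam[c.id], "frameshifts": c.frameshift_events,
                       "aa_len": len(c.aa)} for c in clones]
                     ).to_csv(outdir / "clones.tsv", sep="\t", index=False)
        fileio.write_provenance(result["chi2"] or {}, outdir / "chi2.json")
    return result


def consensus_stage(config: RunConfig, genome, clones, assignment, outdir: Path) -> dict:
    """Per-family RT consensus, copy-number estimate, iterative full consensus."""
    by_family: dict[str, list] = {}
    if assignment:
        for c in clones:
            by_family.setdefault(assignment.families[c.id], []).append(c)
    counts, consensi, logs = {}, {}, {}
    for fam in sorted(by_family):
        members = by_family[fam]
        seed_nt = seed_consensus([c.nt for c in members])
        counts[fam] = count_hits(seed_nt, genome, config.search)
        try:
            state = iterative_extend(seed_nt, genome, fam, config.search)
            consensi[fam] = state.consensus
            logs[fam] = state.log
        except InsufficientCopyError as exc:
            logs[fam] = [{"error": str(exc)}]
    pd.DataFrame(sorted(counts.items()), columns=["family", "hit_loci"]
                 ).to_csv(outdir / "copynumber.tsv", sep="\t", index=False)
    if consensi:
        fileio.write_fasta(consensi, outdir / "consensus.fa")
    fileio.write_provenance(logs, outdir / "consensus_log.json")
    return {"counts": counts, "consensi": consensi}


def annotate_stage(config: RunConfig, consensi: dict[str, str], outdir: Path) -> dict:
    """Structural summary table of each recovered consensus."""
    refs, outgroup = reference.lineage_reference_peptides(config.seed)
    rows = []
    annotations = {}
    for fam, seq in sorted(consensi.items()):
        try:
            ann = annotate_element(seq)
        except ValueError as exc:
            rows.append({"family": fam, "error": str(exc)})
            continue
        annotations[fam] = ann
        lineage, support = "unassigned", 0
        core = rt_core_peptide(ann.orf) if ann.orf else None
        if core:
            lineage, support = assign_lineage(core, refs, outgroup,
                                              seed=_stage_seed(config, f"boot:{fam}"))
        rows.append({"family": fam, "lineage": lineage, "bootstrap": support,
                     "total_len": ann.total_len, "ltr_len": ann.ltr_len,
                     "gagpol_aa": ann.orf.aa_len if ann.orf else 0,
                     "pbs_spacer": ann.pbs_spacer, "ltr_identity": round(ann.ltr_identity, 4),
                     "copia_order": ann.orf.copia_order if ann.orf else False})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "structure.tsv", sep="\t", index=False)
    return {"structure": df, "annotations": annotations}


def context_stage(config: RunConfig, genome, outdir: Path) -> dict:
    profiles = profile_copies(genome, ContextParams(min_flanks_per_family=2),
                              config.search)
    pd.DataFrame([vars(p) for p in profiles]).to_csv(outdir / "context.tsv",
                                                     sep="\t", index=False)
    report = family_context_report(profiles, ContextParams(min_flanks_per_family=2))
    report.to_csv(outdir / "context_summary.tsv", sep="\t", index=False)
    return {"profiles": profiles, "report": report}


def rbip_stage(config: RunConfig, genome, outdir: Path) -> dict:
    """Design a marker at the recent marker-family insertion, genotype the panel."""
    recent = [i for i in find_recent_insertions(genome)
              if genome.elements[i].family == config.marker_family]
    if not recent:
        return {"error": "no recent marker-family insertion with identical LTRs"}
    locus = recent[-1]
    try:
        marker = design_marker(genome, locus, search_params=config.search)
    except NoMarkerError as exc:
        return {"error": str(exc)}
    presence = pd.DataFrame(True, index=config.panel_accessions, columns=[locus])
    for acc in config.panel_absent:
        presence.loc[acc, locus] = False
    panel = simulate_accessions(genome, presence, seed=_stage_seed(config, "panel"))
    calls = genotype(panel, marker)
    calls.to_csv(outdir / "genotypes.tsv", sep="\t")
    fileio.write_provenance(vars(marker), outdir / "marker.json")
    return {"marker": marker, "panel": panel, "calls": calls, "locus": locus,
            "presence": presence}


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage and write a truth-comparison report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    sim = simulate_stage(config, outdir)
    genome, templates = sim["genome"], sim["templates"]
    report["stages"]["simulate"] = {"contigs": len(genome.contigs),
                                    "elements": len(genome.elements),
                                    "genes": len(genome.genes)}

    amplicons = pcr_stage(config, genome, outdir)["amplicons"]
    report["stages"]["pcr"] = {"amplicons": len(amplicons)}

    cls = classify_stage(config, amplicons, outdir)
    n_rec = cls["assignment"].n_families if cls["assignment"] else 0
    report["stages"]["classify"] = {"clones": len(cls["clones"]),
                                    "families_recovered": n_rec,
                                    "families_implanted": len(config.families),
                                    "chi2": cls["chi2"]}

    cons = consensus_stage(config, genome, cls["clones"], cls["assignment"], outdir)
    report["stages"]["consensus"] = {"families_with_consensus": len(cons["consensi"]),
                                     "hit_counts": cons["counts"]}

    ann = annotate_stage(config, cons["consensi"], outdir)
    report["stages"]["annotate"] = {"structures": len(ann["annotations"])}

    ctx = context_stage(config, genome, outdir)
    report["stages"]["context"] = {"families_reported": len(ctx["report"])}

    rb = rbip_stage(config, genome, outdir)
    if "error" in rb:
        report["stages"]["rbip"] = {"error": rb["error"]}
    else:
        calls = rb["calls"]["call"]
        truth = rb["presence"][rb["locus"]]
        agree = all((calls[acc] == "occupied") == bool(truth[acc]) and
                    (calls[acc] == "empty") == (not truth[acc])
                    for acc in calls.index)
        report["stages"]["rbip"] = {"locus": rb["marker"].locus,
                                    "occupied": int((calls == "occupied").sum()),
                                    "empty": int((calls == "empty").sum()),
                                    "matches_truth": bool(agree)}
    fileio.write_provenance(report, outdir / "report.json")
    return report
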