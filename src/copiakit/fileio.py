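"""FASTA / GFF3 / JSON serialization of simulated genomes and annotations.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive.  Feature vocabulary: LTR_retrotransposon, long_terminal_repeat,
primer_binding_site, RR_tract, gene, target_site_duplication.
"""
from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import AnnotatedGenome, ElementCopy, FamilyTemplate, Gene


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _gff_line(contig, source, ftype, start0, end0, strand, attrs) -> str:
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr}"


def write_truth_gff3(genome: AnnotatedGenome, path,
                     templates: dict[str, FamilyTemplate] | None = None) -> None:
    """Ground-truth feature track of a simulated genome.

    With templates given, non-truncated copies also get their internal LTR,
    PBS and PPT sub-features mapped from the template layout.
    """
    lines = ["##gff-version 3"]
    for name, seq in genome.contigs.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for idx, el in enumerate(genome.elements):
        eid = f"element{idx}"
        lines.append(_gff_line(el.contig, "copiakit", "LTR_retrotransposon",
                               el.start, el.end, el.strand,
                               {"ID": eid, "family": el.family, "tsd": el.tsd,
                                "divergence": el.pct_divergence,
                                "ltr_identical": str(el.ltr_identical).lower()}))
        for pos, ftype in (((el.start - len(el.tsd), el.start), "target_site_duplication"),
                           ((el.end, el.end + len(el.tsd)), "target_site_duplication")):
            lines.append(_gff_line(el.contig, "copiakit", ftype, pos[0], pos[1], "+",
                                   {"Parent": eid}))
        tpl = templates.get(el.family) if templates else None
        if tpl is not None and not (el.truncated_5p or el.truncated_3p):
            ann = tpl.annotation
            subs = [("long_terminal_repeat", ann.ltr5), ("long_terminal_repeat", ann.ltr3),
                    ("primer_binding_site", ann.pbs), ("RR_tract", ann.ppt)]
            for ftype, span in subs:
                if span is None:
                    continue
                if el.strand == "+":
                    s, e = el.start + span[0], el.start + span[1]
                else:
                    s, e = el.end - span[1], el.end - span[0]
                lines.append(_gff_line(el.contig, "copiakit", ftype, s, e, el.strand,
                                       {"Parent": eid}))
    for g in genome.genes:
        lines.append(_gff_line(g.contig, "copiakit", "gene", g.start, g.end, g.strand,
                               {"ID": g.id}))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[dict]:
    """Parse a GFF3 file back to dicts with 0-based half-open coordinates."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, source, ftype, start, end, _score, strand, _phase, attr = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in attr.split(";") if kv)
        out.append({"contig": contig, "type": ftype, "start": int(start) - 1,
                    "end": int(end), "strand": strand, "attrs": attrs})
    return out


def genome_from_gff3(fasta_path, gff3_path) -> AnnotatedGenome:
    """Rebuild an AnnotatedGenome from its FASTA + truth GFF3 pair."""
    contigs = read_fasta(fasta_path)
    genome = AnnotatedGenome(contigs=contigs)
    for feat in read_gff3(gff3_path):
        if feat["type"] == "LTR_retrotransposon":
            a = feat["attrs"]
            genome.elements.append(ElementCopy(
                family=a.get("family", "?"), contig=feat["contig"],
                start=feat["start"], end=feat["end"], strand=feat["strand"],
                tsd=a.get("tsd", ""), pct_divergence=float(a.get("divergence", 0)),
                ltr_identical=a.get("ltr_identical", "true") == "true"))
        elif feat["type"] == "gene":
            genome.genes.append(Gene(feat["contig"], feat["start"], feat["end"],
                                     feat["strand"], feat["attrs"].get("ID", "gene")))
    return genome


def write_provenance(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
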