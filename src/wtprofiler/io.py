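"""File-format readers and writers.

VCF goes through pysam, FASTQ/FASTA through Biopython; tabular outputs are
TSV via pandas.  All internal coordinates are 1-based closed; BED export is
the single place where conversion to 0-based half-open happens.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .baf import Segment, SnpSite
from .bisulfite import AmpliconRef
from .expression import ExpressionMatrix, MarkerGeneSet

logger = logging.getLogger(__name__)


def to_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open (BED)."""
    if start < 1 or end < start:
        raise ValueError("invalid 1-based closed interval")
    return start - 1, end


# ---------------------------------------------------------------------------
# VCF

_FORMAT_FIELDS = ("GT", "AD", "DP", "GQ")


def read_vcf_sites(
    path: str | Path,
    tumour_sample: str,
    normal_sample: str,
) -> tuple[list[SnpSite], Counter]:
    """Parse biallelic SNV records from a paired tumour/normal VCF.

    Multiallelic and indel records are skipped and counted.  Returns the site
    list (input order) and a counter of skipped-record reasons.
    """
    skipped: Counter = Counter()
    sites: list[SnpSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for sample in (tumour_sample, normal_sample):
            if sample not in vcf.header.samples:
                raise ValueError(f"sample {sample!r} not in VCF header")
        for fld in _FORMAT_FIELDS:
            if fld not in vcf.header.formats:
                raise ValueError(f"VCF lacks required FORMAT field {fld}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic_or_no_alt"] += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped["indel"] += 1
                continue
            normal = rec.samples[normal_sample]
            tumour = rec.samples[tumour_sample]
            for fld in _FORMAT_FIELDS:
                if fld == "GQ":
                    continue
                if normal.get(fld) is None or tumour.get(fld) is None:
                    raise ValueError(f"record {rec.chrom}:{rec.pos} missing FORMAT {fld}")
            gt = normal["GT"]
            sep = "|" if normal.phased else "/"
            gt_str = sep.join("." if a is None else str(a) for a in gt)
            t_ad = tumour["AD"]
            gq = normal.get("GQ")
            sites.append(SnpSite(
                chrom=rec.chrom,
                pos=rec.pos,
                normal_genotype=gt_str,
                normal_depth=int(normal["DP"]),
                tumour_ref_depth=int(t_ad[0]),
                tumour_alt_depth=int(t_ad[1]),
                genotype_quality=float(gq) if gq is not None else 0.0,
            ))
    if skipped:
        logger.info("read_vcf_sites: skipped %s", dict(skipped))
    return sites, skipped


def write_sites_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    tumour_sample: str = "TUMOUR",
    normal_sample: str = "NORMAL",
) -> None:
    """Write a synthetic site table as a minimal two-sample VCF (GT:AD:DP:GQ)."""
    header = pysam.VariantHeader()
    for chrom, sub in sites.groupby("chrom", sort=True):
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(normal_sample)
    header.add_sample(tumour_sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in sites.sort_values(["chrom", "pos"]).itertuples():
            rec = vcf.new_record(
                contig=row.chrom, start=row.pos - 1, stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            n = rec.samples[normal_sample]
            a, b = (int(x) for x in row.normal_genotype.replace("|", "/").split("/"))
            n["GT"] = (a, b)
            n["AD"] = (row.normal_ref_depth, row.normal_alt_depth)
            n["DP"] = int(row.normal_ref_depth + row.normal_alt_depth)
            n["GQ"] = int(row.genotype_quality)
            t = rec.samples[tumour_sample]
            t["GT"] = (a, b)
            t["AD"] = (row.tumour_ref_depth, row.tumour_alt_depth)
            t["DP"] = int(row.tumour_ref_depth + row.tumour_alt_depth)
            t["GQ"] = int(row.genotype_quality)
            vcf.write(rec)


def sites_from_frame(df: pd.DataFrame) -> list[SnpSite]:
    """Build SnpSite records from a synthetic site table."""
    return [SnpSite(
        chrom=r.chrom, pos=int(r.pos), normal_genotype=r.normal_genotype,
        normal_depth=int(r.normal_ref_depth + r.normal_alt_depth),
        tumour_ref_depth=int(r.tumour_ref_depth),
        tumour_alt_depth=int(r.tumour_alt_depth),
        genotype_quality=float(r.genotype_quality),
    ) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# FASTQ / FASTA

def write_fastq(reads: list[str], path: str | Path, ids: list[str] | None = None,
                quality: int = 38) -> None:
    records = []
    for i, seq in enumerate(reads):
        rid = ids[i] if ids is not None else f"read_{i}"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    ids, reads = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        reads.append(str(rec.seq))
    return reads, ids


def write_amplicon_fasta(ref: AmpliconRef, path: str | Path) -> None:
    desc = "cpg_positions=" + ",".join(str(p) for p in ref.cpg_positions)
    if ref.genomic_anchor:
        desc += f" anchor={ref.genomic_anchor[0]}:{ref.genomic_anchor[1]}"
    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.name, description=desc)],
                str(path), "fasta")


def read_amplicon_fasta(path: str | Path, cpg_positions: list[int] | None = None) -> AmpliconRef:
    """Load an amplicon reference; CpG sites auto-detected unless given."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    positions: tuple[int, ...] = tuple(cpg_positions or ())
    if not positions and "cpg_positions=" in rec.description:
        tok = [t for t in rec.description.split() if t.startswith("cpg_positions=")][0]
        positions = tuple(int(x) for x in tok.split("=", 1)[1].split(","))
    return AmpliconRef(name=rec.id, sequence=str(rec.seq), cpg_positions=positions)


# ---------------------------------------------------------------------------
# Expression / marker sets

def write_expression_tsv(matrix: ExpressionMatrix, values_path: str | Path,
                         groups_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="probe_id")
    matrix.sample_groups.rename("group").to_csv(groups_path, sep="\t",
                                                index_label="sample_id")


def read_expression_tsv(values_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
    values.index.name = None
    groups.index.name = None
    return ExpressionMatrix(values=values, sample_groups=groups)


def write_gmt(marker_sets: list[MarkerGeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ms in marker_sets:
            fh.write("\t".join([ms.stage_name, "na", *ms.gene_ids]) + "\n")


def read_gmt(path: str | Path) -> list[MarkerGeneSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(MarkerGeneSet(stage_name=parts[0], gene_ids=tuple(parts[2:])))
    return out


# ---------------------------------------------------------------------------
# Segments / runs / JSON

def write_segments_bed(segments: list[Segment], path: str | Path) -> None:
    """Export segments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for s in segments:
            b0, b1 = to_zero_based_half_open(s.start, s.end)
            fh.write(f"{s.chrom}\t{b0}\t{b1}\t{s.state}\t{s.n_sites}\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
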