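"""Readers and writers for the standard text formats used by the pipeline.

FASTA/FASTQ via Biopython; BED, VCF, BEDPE, and TSV written directly.
Panel BED files are 6-column with the control flag encoded as a
``CTRL|`` prefix in the name field.  FASTQ qualities are constant Q30
(Phred+33).  VCF output is v4.2 with 1-based positions.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cnv import AmpliconCounts, CopyNumberProfile
from .errors import ConfigError
from .fusions import RearrangementCandidate
from .sim.cohort import COHORT_COLUMNS
from .sim.panel import Amplicon, PanelDesign
from .sim.reads import CnvSpec, FusionSpec, LesionSpec, SimRead, SnvSpec
from .sim.reference import ReferenceModel
from .variants import VariantCall

FASTQ_QUALITY_CHAR = chr(30 + 33)  # constant Q30


# -- FASTA -------------------------------------------------------------------

def write_fasta(reference: ReferenceModel, path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in reference.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> ReferenceModel:
    segments = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return ReferenceModel(segments)


# -- FASTQ -------------------------------------------------------------------

def write_fastq(reads: Sequence[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n"
                     f"{FASTQ_QUALITY_CHAR * len(read.seq)}\n")


def read_fastq(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fastq")}


# -- BED panel ---------------------------------------------------------------

def write_panel_bed(panel: PanelDesign, path: str) -> None:
    with open(path, "w") as fh:
        for a in panel:
            name = f"CTRL|{a.amplicon_id}" if a.is_control else a.amplicon_id
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{name}\t0\t+\n")


def read_panel_bed(path: str, reference: Optional[ReferenceModel] = None) -> PanelDesign:
    amplicons: List[Amplicon] = []
    genes: Dict[str, List[int]] = {}
    gene_chrom: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            is_control = name.startswith("CTRL|")
            amp_id = name[5:] if is_control else name
            gene = chrom if is_control else amp_id.rsplit("_a", 1)[0]
            amplicons.append(Amplicon(amp_id, chrom, start, end, gene, is_control))
            if not is_control:
                genes.setdefault(gene, []).extend([start, end])
                gene_chrom[gene] = chrom
    target = {g: (gene_chrom[g], min(v), max(v)) for g, v in genes.items()}
    return PanelDesign(amplicons, target, reference=reference)


# -- truth / lesions JSON ----------------------------------------------------

def write_truth_json(truth: LesionSpec, path: str) -> None:
    payload = {
        "snvs": [dataclasses.asdict(s) for s in truth.snvs],
        "fusions": [dataclasses.asdict(f) for f in truth.fusions],
        "cnvs": [dataclasses.asdict(c) for c in truth.cnvs],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_lesions_json(path: str) -> LesionSpec:
    with open(path) as fh:
        payload = json.load(fh)
    return lesions_from_dict(payload)


def lesions_from_dict(payload: dict) -> LesionSpec:
    return LesionSpec(
        snvs=[SnvSpec(**s) for s in payload.get("snvs", [])],
        fusions=[FusionSpec(**f) for f in payload.get("fusions", [])],
        cnvs=[CnvSpec(**c) for c in payload.get("cnvs", [])],
    )


# -- cohort TSV --------------------------------------------------------------

def write_cohort_tsv(cohort: pd.DataFrame, path: str) -> None:
    """Write the cohort table as TSV; missing values become empty fields."""
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("fgfr1_score", "fgfr3_score"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"cohort table missing columns: {sorted(missing)}")
    return df


# -- VCF ---------------------------------------------------------------------

def write_vcf(calls: Sequence[VariantCall], reference: ReferenceModel,
              path: str, sample_id: str = "sample") -> None:
    """VCF v4.2; FILTER encodes which rule(s) failed for non-PASS calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in reference.names:
            fh.write(f"##contig=<ID={name},length={reference.length(name)}>\n")
        fh.write('##FILTER=<ID=lowAF,Description="Alternate allele fraction below threshold">\n')
        fh.write('##FILTER=<ID=lowDepth,Description="Fewer alternate reads than required">\n')
        fh.write('##FILTER=<ID=bgRatio,Description="Allele fraction below the required '
                 'multiple of the background error rate">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate read count">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n')
        fh.write('##INFO=<ID=BG,Number=1,Type=Float,Description="Background error rate">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            filt = ";".join(c.filter_tags())
            info = f"DP={c.depth};AC={c.alt_count};AF={c.af:.6g};BG={c.background:.6g}"
            fh.write(f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t{info}\n")


# -- BEDPE -------------------------------------------------------------------

def write_bedpe(candidates: Sequence[RearrangementCandidate], path: str,
                flagged_only: bool = False) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            if flagged_only and not c.flagged:
                continue
            name = f"{c.gene_a or c.chrom_a}-{c.gene_b or c.chrom_b}"
            fh.write(f"{c.chrom_a}\t{max(0, c.pos_a - 1)}\t{c.pos_a}\t"
                     f"{c.chrom_b}\t{c.pos_b}\t{c.pos_b + 1}\t"
                     f"{name}\t{c.support}\t{c.strand_a}\t{c.strand_b}\n")


def write_fusion_evidence_json(candidates: Sequence[RearrangementCandidate],
                               path: str) -> None:
    payload = [dataclasses.asdict(c) for c in candidates]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# -- amplicon counts / CNV TSV ----------------------------------------------

def write_counts_tsv(counts: AmpliconCounts, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon_id\tcount\n")
        for amp_id, n in counts.counts.items():
            fh.write(f"{amp_id}\t{n}\n")


def read_counts_tsv(path: str, sample_id: Optional[str] = None) -> AmpliconCounts:
    df = pd.read_csv(path, sep="\t")
    return AmpliconCounts(sample_id or path,
                          dict(zip(df["amplicon_id"], df["count"].astype(int))))


def write_cnv_tsv(profile: CopyNumberProfile, tumor: AmpliconCounts,
                  baseline: AmpliconCounts, panel: PanelDesign, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon_id\tgene\tis_control\traw\tcorrected\tbaseline_raw\tlog2_ratio\n")
        for a in panel:
            raw = tumor.counts[a.amplicon_id]
            fh.write(f"{a.amplicon_id}\t{a.gene}\t{int(a.is_control)}\t{raw}\t"
                     f"{raw / profile.tumor_factor:.6g}\t{baseline.counts[a.amplicon_id]}\t"
                     f"{profile.log2_ratios[a.amplicon_id]:.6g}\n")


def write_gene_calls_tsv(profile: CopyNumberProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tn_amplicons\tmedian_log2_ratio\tcall\n")
        for gene, gc in sorted(profile.gene_calls.items()):
            fh.write(f"{gene}\t{gc.n_amplicons}\t{gc.median_log2_ratio:.6g}\t{gc.call}\n")
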