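"""Reading and writing the pipeline's file formats.

VCF is read with cyvcf2 and written as plain VCF 4.2 text (the synthetic
files are small and uncompressed). FASTA goes through Biopython, GFF3
reading through gffutils. Panels are TSV with the sample id in the first
column; the simulation truth travels as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import MISSING, GenotypeMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(catalog: pd.DataFrame, matrix: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF 4.2 with GT calls; loci ordered as in the
    catalog (which must be position-sorted per chromosome)."""
    path = Path(path)
    cat = catalog.loc[matrix.locus_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(cat["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, matrix.sample_ids)) + "\n")
        quals = cat["qual"] if "qual" in cat else pd.Series(".", index=cat.index)
        for i, (locus, row) in enumerate(cat.iterrows()):
            gts = "\t".join(_GT[int(c)] for c in matrix.calls[i])
            qual = quals.iloc[i]
            qual_s = "." if pd.isna(qual) else f"{float(qual):g}"
            fh.write(f"{row['chrom']}\t{row['pos']}\t{locus}\t{row['ref']}\t"
                     f"{row['alt']}\t{qual_s}\tPASS\t.\tGT\t{gts}\n")
    return path


def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a VCF into (catalog, GenotypeMatrix) with cyvcf2.

    Multi-allelic records are kept as comma-joined ALT strings so the
    quality filter can reject them explicitly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, calls, ids = [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        locus = v.ID or f"snp_{v.CHROM}_{v.POS}"
        ids.append(locus)
        rows.append((v.CHROM, v.POS, v.REF, ",".join(v.ALT),
                     v.QUAL if v.QUAL is not None else np.nan))
        calls.append(remap[v.gt_types])
    vcf.close()
    catalog = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"],
                           index=pd.Index(ids, name="locus_id"))
    matrix = GenotypeMatrix(np.vstack(calls) if calls
                            else np.empty((0, len(samples)), dtype=np.int8),
                            np.asarray(ids, dtype=object),
                            np.asarray(samples, dtype=object))
    return catalog, matrix


def write_fasta(model, path, seed: int = 0) -> Path:
    """Emit a random nucleotide sequence per chromosome (the analyses only
    need coordinates; the sequence content is a deterministic filler)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    records = []
    bases = np.array(list("ACGT"))
    for chrom, length in model.chrom_lengths.items():
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        records.append(SeqRecord(Seq(seq), id=chrom, description=""))
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def write_gff3(model, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in model.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom, start, end, gid in model.gene_intervals:
            fh.write(f"{chrom}\ttetrasnp\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gid}\n")
    return path


def read_gff3(path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end, gene_id; 1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True)
    rows = [(f.seqid, f.start, f.end, f.id)
            for f in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_panel(panel: pd.DataFrame, path) -> Path:
    path = Path(path)
    panel.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                        keep_default_na=False)
    if "admixed" in panel.columns:
        panel["admixed"] = panel["admixed"].astype(str).str.lower().isin(
            ("true", "1", "yes"))
    return panel.set_index("sample_id")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth(truth: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, cls=_NumpyEncoder)
    return path


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
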