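"""Readers and writers for the pipeline's on-disk formats.

FASTA (60-column wrap, case-normalized to upper on read), GFF3 (1-based
inclusive, ``gene`` features), BED6 (0-based half-open, lossless
round-trip), TSV tables (counts, design, truth, DE, similarity) and PWM
files in JASPAR-counts or MEME-minimal dialects (parsed with Bio.motifs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .promoter import GeneModel
from .pwm import ALPHABET, PWM, ScoredSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed6",
    "write_bed6",
    "sites_to_bed6",
    "read_pwm",
    "read_tsv",
    "write_tsv",
]


# -- FASTA ----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# -- GFF3 -----------------------------------------------------------------

def read_gff3(path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene models from a GFF3 file (1-based inclusive coordinates kept)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path, source: str = "dsxtargets") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# -- BED6 -----------------------------------------------------------------

def read_bed6(path) -> pd.DataFrame:
    """BED6 rows (chrom, start, end, name, score, strand); errors carry line numbers."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            try:
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "name": parts[3],
                        "score": int(parts[4]),
                        "strand": parts[5],
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed6(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.strand}\n"
            )


def sites_to_bed6(sites: list[ScoredSite], name: str) -> pd.DataFrame:
    """ScoredSites as BED6 with score = round(-10*log10 p), capped at 1000."""
    rows = []
    for s in sites:
        score = 1000 if s.p_value <= 0 else int(round(min(-10 * np.log10(s.p_value), 1000)))
        rows.append(
            {
                "chrom": s.seq_id,
                "start": s.start,
                "end": s.end,
                "name": name,
                "score": score,
                "strand": s.strand,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def sites_to_table(sites: list[ScoredSite]) -> pd.DataFrame:
    """Exact per-site scores and p-values as a TSV-ready frame."""
    return pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "score_bits": s.score,
                "p_value": s.p_value,
            }
            for s in sites
        ],
        columns=["seq_id", "start", "end", "strand", "score_bits", "p_value"],
    )


# -- PWM ------------------------------------------------------------------

def read_pwm(path, fmt: str = "jaspar", pseudocount: float = 0.01) -> PWM:
    """PWM from a JASPAR counts file or a MEME-minimal probability file."""
    fmt = fmt.lower()
    with open(path) as fh:
        if fmt == "jaspar":
            motif = motifs.read(fh, "jaspar")
            counts = np.array([[motif.counts[b][i] for b in ALPHABET]
                               for i in range(motif.length)])
            return PWM.from_counts(counts, name=motif.matrix_id or motif.name or "pwm",
                                   pseudocount=pseudocount)
        if fmt in ("meme", "minimal"):
            motif = motifs.read(fh, "minimal")
            probs = np.array([[motif.pwm[b][i] for b in ALPHABET]
                              for i in range(motif.length)])
            return PWM(probs, name=motif.name or "pwm", pseudocount=pseudocount)
    raise ValueError(f"unknown PWM format {fmt!r}; use 'jaspar' or 'meme'")


def write_pwm_jaspar(pwm: PWM, path, counts_scale: int = 100) -> None:
    """Write a PWM as JASPAR-style integer counts (probs * counts_scale)."""
    mat = np.rint(pwm.probs * counts_scale).astype(int)
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.name}\n")
        for bi, base in enumerate(ALPHABET):
            vals = " ".join(str(v) for v in mat[:, bi])
            fh.write(f"{base} [ {vals} ]\n")


# -- TSV ------------------------------------------------------------------

def read_tsv(path, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from None


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
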