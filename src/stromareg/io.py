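"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are 0-based half-open.  Each reader validates
column counts and numeric fields and raises :class:`FormatError` with the
file and 1-based line number on the first malformed line; write/read
round-trips are lossless on canonical form.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from stromareg.containers import CountMatrix, conditions_from_sample_names
from stromareg.enrichment import GeneSet
from stromareg.errors import FormatError
from stromareg.motif import MotifModel

__all__ = [
    "read_counts", "write_counts",
    "read_narrowpeak", "write_narrowpeak",
    "read_bed6", "write_bed6",
    "read_gene_models", "write_gene_models",
    "read_gmt", "write_gmt",
    "read_rnk", "write_rnk",
    "read_fasta", "write_fasta",
    "read_meme_motifs", "write_meme_motifs",
    "read_cohort", "write_cohort",
]


def read_counts(path, conditions: pd.Series | None = None,
                lengths: pd.Series | None = None) -> CountMatrix:
    """Counts TSV: header ``feature`` then one column per sample.

    Condition labels default to the ``COND_rep`` sample-name convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = df.astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer count value: {exc}", path=path) from exc
    if conditions is None:
        conditions = conditions_from_sample_names(counts.columns)
    return CountMatrix(counts, conditions, lengths=lengths)


def write_counts(cm: CountMatrix, path):
    out = cm.counts.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


_NP_COLS = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "pvalue", "qvalue", "summit"]


def read_narrowpeak(path) -> pd.DataFrame:
    """10-column narrowPeak; column 10 is the 0-based summit offset (-1 = absent)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise FormatError(f"expected 10 columns, got {len(parts)}",
                                  path=path, line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
                summit = int(parts[9])
            except ValueError as exc:
                raise FormatError(f"non-numeric coordinate: {exc}",
                                  path=path, line=lineno) from exc
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", path=path, line=lineno)
            if summit >= 0 and not (0 <= summit < end - start):
                raise FormatError(f"summit offset {summit} outside peak",
                                  path=path, line=lineno)
            rows.append((parts[0], start, end, parts[3], float(parts[4]), parts[5],
                         float(parts[6]), float(parts[7]), float(parts[8]), summit))
    return pd.DataFrame(rows, columns=_NP_COLS)


def write_narrowpeak(df: pd.DataFrame, path):
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "."),
                         ("signal", 0.0), ("pvalue", -1.0), ("qvalue", -1.0),
                         ("summit", -1)):
        if col not in out.columns:
            out[col] = default
    if "support" in df.columns:  # reference peaks carry support in the score column
        out["score"] = df["support"]
    out[_NP_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"expected 6 columns, got {len(parts)}",
                                  path=path, line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"non-numeric coordinate: {exc}",
                                  path=path, line=lineno) from exc
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", path=path, line=lineno)
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def write_bed6(df: pd.DataFrame, path):
    out = df.copy()
    for col, default in (("name", "."), ("score", "0"), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_gene_models(path) -> pd.DataFrame:
    """Gene model TSV: gene_id, chrom, strand, tss, length (header row)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "length"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene model file missing columns {sorted(missing)}", path=path)
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.index[~df["strand"].isin(["+", "-"])][0]
        raise FormatError("strand must be + or -", path=path, line=int(bad) + 2)
    return df


def write_gene_models(df: pd.DataFrame, path):
    df[["gene_id", "chrom", "strand", "tss", "length"]].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("GMT line needs name, description and >=1 member",
                                  path=path, line=lineno)
            members = [m for m in parts[2:] if m]
            if len(set(members)) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set "
                              f"{parts[0]!r} deduplicated", stacklevel=2)
            sets.append(GeneSet(parts[0], members, description=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path):
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na"] + gs.members) + "\n")


def read_rnk(path) -> pd.Series:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 2 columns, got {len(parts)}",
                                  path=path, line=lineno)
            try:
                rows.append((parts[0], float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"non-numeric score: {exc}",
                                  path=path, line=lineno) from exc
    s = pd.Series(dict(rows), name="score")
    s = s.loc[[g for g, _ in rows]]
    return s


def write_rnk(rnk: pd.Series, path):
    with open(path, "w") as fh:
        for gene, score in rnk.items():
            fh.write(f"{gene}\t{score:.6g}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_meme_motifs(path) -> list[MotifModel]:
    """Minimal MEME motif text: background line, MOTIF blocks with
    letter-probability matrices over the ACGT alphabet."""
    motifs = []
    background = np.full(4, 0.25)
    name = None
    rows: list[list[float]] = []
    expect = 0

    def flush():
        nonlocal name, rows
        if name is not None:
            motifs.append(MotifModel(name, np.array(rows), background=background.copy()))
        name, rows = None, []

    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            flush()
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            expect = w
            for k in range(w):
                i += 1
                vals = [float(v) for v in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError("letter-probability row needs 4 values",
                                      path=path, line=i + 1)
                rows.append(vals)
            if len(rows) != expect:
                raise FormatError("truncated letter-probability matrix", path=path)
        i += 1
    flush()
    if not motifs:
        raise FormatError("no MOTIF blocks found", path=path)
    return motifs


def write_meme_motifs(motifs: list[MotifModel], path):
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip("ACGT", bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_cohort(path) -> pd.DataFrame:
    """Cohort TSV: patient, time, event, then one expression column per gene."""
    df = pd.read_csv(path, sep="\t")
    for col in ("patient", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"cohort file missing column {col!r}", path=path)
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event indicator must be 0 or 1", path=path)
    if (df["time"] <= 0).any():
        raise FormatError("survival times must be positive", path=path)
    return df.set_index("patient")


def write_cohort(df: pd.DataFrame, path):
    out = df.reset_index()
    if "patient" not in out.columns:
        out = out.rename(columns={out.columns[0]: "patient"})
    lead = ["patient", "time", "event"]
    cols = lead + [c for c in out.columns if c not in lead]
    out[cols].to_csv(path, sep="\t", index=False)
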