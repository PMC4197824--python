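"""Plain-text readers and writers: annotation/truth TSV, tag and fragment
BED, coverage bedGraph, and promoter FASTA.

BED rows are 0-based half-open with the strand in column 6; tag BED rows
are 1-bp intervals at the stranded 5' position. bedGraph rows are
(chrom, start, end, value) runs.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .synthetic_cohort import GeneTruth
from .tag_processing import TagTrack

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_annotation_tsv(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[GeneTruth]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.to_dict("records"):
        opp = row.get("opposite_tss")
        row["opposite_tss"] = None if pd.isna(opp) else int(opp)
        genes.append(GeneTruth(**row))
    return genes


def write_tags_bed(track: TagTrack, path) -> None:
    rows = []
    for strand, counter in (("+", track.plus), ("-", track.minus)):
        for pos in sorted(counter):
            rows.append((track.chrom, pos, pos + 1, "tag",
                         counter[pos], strand))
    pd.DataFrame(rows, columns=_BED_COLS).to_csv(path, sep="\t", index=False,
                                                 header=False)


def read_tags_bed(path) -> dict[str, TagTrack]:
    df = pd.read_csv(path, sep="\t", names=_BED_COLS)
    tracks: dict[str, TagTrack] = {}
    for chrom, sub in df.groupby("chrom"):
        track = TagTrack(str(chrom))
        for strand, counter in (("+", track.plus), ("-", track.minus)):
            rows = sub[sub.strand == strand]
            for pos, score in zip(rows.start, rows.score):
                counter[int(pos)] += int(score)
        tracks[str(chrom)] = track
    return tracks


def write_fragments_bed(fragments: np.ndarray, chrom: str, path) -> None:
    frags = np.asarray(fragments).reshape(-1, 2)
    df = pd.DataFrame({"chrom": chrom, "start": frags[:, 0],
                       "end": frags[:, 1], "name": "frag", "score": 0,
                       "strand": "+"})
    df.to_csv(path, sep="\t", index=False, header=False)


def read_fragments_bed(path) -> tuple[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", names=_BED_COLS)
    chroms = df.chrom.unique()
    if len(chroms) > 1:
        raise ValueError("fragment BED spans multiple contigs")
    return str(chroms[0]), df[["start", "end"]].to_numpy(dtype=np.int64)


def write_bedgraph(positions, chrom: str, path) -> None:
    """Write a sparse position->value map as run-length bedGraph rows."""
    items = sorted((int(p), v) for p, v in positions.items() if v != 0)
    rows = []
    run_start = run_end = None
    run_val = None
    for pos, val in items:
        if run_start is not None and pos == run_end and val == run_val:
            run_end += 1
            continue
        if run_start is not None:
            rows.append((chrom, run_start, run_end, run_val))
        run_start, run_end, run_val = pos, pos + 1, val
    if run_start is not None:
        rows.append((chrom, run_start, run_end, run_val))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> dict[str, Counter]:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])
    out: dict[str, Counter] = {}
    for chrom, sub in df.groupby("chrom"):
        counter: Counter = Counter()
        for start, end, value in zip(sub.start, sub.end, sub.value):
            for pos in range(int(start), int(end)):
                counter[pos] = value
        out[str(chrom)] = counter
    return out


def read_promoter_fasta(path) -> dict[str, str]:
    """Promoter window sequences keyed by record id (gene_id)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(Path(path), "fasta")}
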