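"""Promoter neighborhood classes, expression strata and sequence features.

Averaged PolII profiles carry an upstream "shoulder" near −200 bp that
comes from oppositely directed transcription at bidirectional promoters,
so genes are classified by their neighborhood before profile modeling:
*isolated* promoters have no other TSS or PAS within ±1 kb of their TSS;
*bidirectional* promoters have an opposite-strand TSS less than 1 kb
upstream, with the 170–200 bp sub-class matching the mode of the
opposite-TSS distance distribution. Sequence features (CpG dinucleotide
count and GC content in TSS ± 1 kb, a TATA-box log-odds score) stratify
the occupancy/expression summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Expression strata boundaries, microarray units.
EXPRESSION_LOW = 6.0
EXPRESSION_HIGH = 8.0

# CpG-rich promoters carry more than this many CG dinucleotides in ±1 kb.
CPG_RICH_MIN = 50

# Promoters scoring above this log2-odds value have a "strong" TATA box.
TATA_STRONG_THRESHOLD = -5.0

_BASES = "ACGT"

# Position-weight matrix for the canonical TATAWAWR TATA-box consensus
# (W = A/T, R = A/G), log2-odds against a uniform 0.25 background.
_TATA_PROBS = np.array([
    # A     C     G     T
    [0.03, 0.03, 0.03, 0.91],  # T
    [0.91, 0.03, 0.03, 0.03],  # A
    [0.03, 0.03, 0.03, 0.91],  # T
    [0.91, 0.03, 0.03, 0.03],  # A
    [0.46, 0.04, 0.04, 0.46],  # W
    [0.91, 0.03, 0.03, 0.03],  # A
    [0.46, 0.04, 0.04, 0.46],  # W
    [0.46, 0.04, 0.46, 0.04],  # R
])
TATA_PWM = np.log2(_TATA_PROBS / 0.25)
TATA_MOTIF_LEN = TATA_PWM.shape[0]


def expression_stratum(expr: float) -> str:
    """'low' (<6.0), 'moderate' (6.0–8.0 inclusive) or 'high' (>8.0)."""
    if not np.isfinite(expr):
        raise ValueError("expression must be finite")
    if expr < EXPRESSION_LOW:
        return "low"
    if expr <= EXPRESSION_HIGH:
        return "moderate"
    return "high"


def expression_strata(expr) -> pd.Series:
    """Vectorized :func:`expression_stratum`."""
    e = pd.Series(expr, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("expression must be finite")
    return pd.Series(
        np.select([e < EXPRESSION_LOW, e <= EXPRESSION_HIGH],
                  ["low", "moderate"], default="high"),
        index=e.index)


def _upstream_opposite_distance(row, annot: pd.DataFrame) -> float:
    """Distance to the nearest opposite-strand TSS upstream of this gene."""
    sign = 1 if row.strand == "+" else -1
    others = annot[(annot.chrom == row.chrom)
                   & (annot.strand != row.strand)
                   & (annot.gene_id != row.gene_id)]
    dists = (row.annotated_tss - others.annotated_tss.to_numpy()) * sign
    dists = dists[dists > 0]
    return float(dists.min()) if dists.size else np.nan


def classify_promoters(annot: pd.DataFrame) -> pd.DataFrame:
    """Neighborhood classification of every promoter in the annotation.

    Returns one row per gene with the nearest foreign TSS/PAS distance,
    the nearest upstream opposite-strand TSS distance, boolean columns
    ``isolated`` (no other TSS or PAS within ±1 kb; the gene's own PAS
    counts, its own TSS does not), ``bidirectional_lt1kb`` (opposite
    TSS < 1 kb upstream) and ``bidirectional_170_200`` (that distance in
    [170, 200] bp), plus the most specific label in ``promoter_class``.
    """
    required = {"gene_id", "chrom", "strand", "annotated_tss", "pas"}
    if missing := required - set(annot.columns):
        raise ValueError(f"annotation lacks columns: {sorted(missing)}")
    if annot.strand.isna().any():
        raise ValueError("missing strand")
    rows = []
    for row in annot.itertuples(index=False):
        same_chrom = annot[annot.chrom == row.chrom]
        foreign_tss = same_chrom.annotated_tss[
            same_chrom.gene_id != row.gene_id].to_numpy()
        feature_pos = np.concatenate([foreign_tss,
                                      same_chrom.pas.to_numpy()])
        feat_dist = np.abs(feature_pos - row.annotated_tss)
        nearest_feature = float(feat_dist.min()) if feat_dist.size else np.nan
        opp = _upstream_opposite_distance(row, annot)
        isolated = not np.isnan(nearest_feature) and nearest_feature > 1000
        bidir = not np.isnan(opp) and opp < 1000
        bidir_170_200 = bidir and 170 <= opp <= 200
        if bidir_170_200:
            label = "bidirectional_170_200"
        elif bidir:
            label = "bidirectional_lt1kb"
        elif isolated:
            label = "isolated"
        else:
            label = "all"
        rows.append({"gene_id": row.gene_id,
                     "nearest_feature_dist": nearest_feature,
                     "nearest_opposite_tss_dist": opp,
                     "isolated": isolated,
                     "bidirectional_lt1kb": bidir,
                     "bidirectional_170_200": bidir_170_200,
                     "promoter_class": label})
    return pd.DataFrame(rows)


def cpg_count(seq: str) -> int:
    """Number of CG dinucleotides (CG cannot overlap itself)."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.upper().count("CG")


def gc_content(seq: str) -> float:
    """G+C fraction over non-N bases."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    counts = {b: s.count(b) for b in _BASES}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["C"] + counts["G"]) / denom


def tata_score(seq: str) -> float:
    """Maximum log2-odds TATA-box PWM score over all motif windows.

    N bases contribute 0 (background odds). The sequence must span at
    least one motif window (e.g. the [−40, −15] region upstream of the
    TSS plus motif length).
    """
    s = seq.upper()
    if len(s) < TATA_MOTIF_LEN:
        raise ValueError(f"window shorter than the {TATA_MOTIF_LEN}-bp motif")
    idx = np.full(len(s), -1, dtype=int)
    for j, b in enumerate(_BASES):
        idx[[i for i, ch in enumerate(s) if ch == b]] = j
    best = -np.inf
    for start in range(len(s) - TATA_MOTIF_LEN + 1):
        window = idx[start:start + TATA_MOTIF_LEN]
        score = sum(TATA_PWM[k, window[k]] if window[k] >= 0 else 0.0
                    for k in range(TATA_MOTIF_LEN))
        best = max(best, score)
    return float(best)


def tata_max_score() -> float:
    """Highest attainable PWM score (perfect consensus)."""
    return float(TATA_PWM.max(axis=1).sum())


def top_tata_genes(scores: pd.Series, fraction: float = 0.02) -> pd.Index:
    """The ceil(fraction·N) gene ids with the highest TATA scores."""
    n = int(np.ceil(fraction * len(scores)))
    return scores.sort_values(ascending=False).index[:n]


def sequence_features(annot: pd.DataFrame, sequences: dict[str, str]) -> pd.DataFrame:
    """Per-gene CpG count, GC content and TATA score.

    ``sequences`` maps gene_id to the promoter window sequence (the
    TSS ± 1 kb window for CpG/GC; the TATA score scans the same string).
    """
    rows = []
    for gid in annot.gene_id:
        seq = sequences[gid]
        rows.append({"gene_id": gid,
                     "cpg_count": cpg_count(seq),
                     "gc_content": gc_content(seq),
                     "tata_score": tata_score(seq),
                     "cpg_rich": cpg_count(seq) > CPG_RICH_MIN})
    return pd.DataFrame(rows)


def nearest_opposite_tss_histogram(annot: pd.DataFrame, bin_width: int = 20,
                                   max_dist: int = 1000):
    """Histogram of nearest upstream opposite-strand TSS distances.

    Returns (counts, bin_edges, distances); genes without an upstream
    opposite TSS within ``max_dist`` do not contribute.
    """
    if len(annot) < 1:
        raise ValueError("empty annotation")
    dists = np.array([_upstream_opposite_distance(row, annot)
                      for row in annot.itertuples(index=False)])
    dists = dists[np.isfinite(dists) & (dists <= max_dist)]
    edges = np.arange(0, max_dist + bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return counts, edges, dists
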