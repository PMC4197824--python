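"""Metagene aggregation: averaged profiles, stacked matrices, re-centering,
and occupancy-vs-expression tables.

Per-gene promoter profiles on a common window are combined into
genome-averaged (metagene) profiles, stacked heat-map matrices sorted by
peak position or first-exon length, and binned summaries of expression
as a function of promoter occupancy stratified by CpG content.
Re-centering each profile by its model shift aligns initiation peaks and
sharpens the averaged profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tag_processing import CoverageProfile


@dataclass
class ProfileMatrix:
    gene_ids: list
    window: tuple[int, int]
    rows: np.ndarray
    normalization: str = "none"
    sort_key: str = "none"


def _common_window(profiles) -> tuple[int, int]:
    windows = {p.window for p in profiles}
    if len(windows) != 1:
        raise ValueError("profiles must share a common window")
    return windows.pop()


def average_profile(profiles) -> CoverageProfile:
    """Per-position arithmetic mean of a set of profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot average an empty set of profiles")
    window = _common_window(profiles)
    mean = np.mean([p.values for p in profiles], axis=0)
    return CoverageProfile("average", window, mean, anchor=None, oriented=True)


def normalize_self_max(rows: np.ndarray) -> np.ndarray:
    """Scale each nonzero row to maximum 1 (idempotent)."""
    rows = np.asarray(rows, dtype=float)
    maxes = rows.max(axis=1, keepdims=True)
    safe = np.where(maxes > 0, maxes, 1.0)
    return rows / safe


def stacked_matrix(profiles, normalization: str = "self_max",
                   sort_key: str = "max_position",
                   first_exon_lengths: dict | None = None) -> ProfileMatrix:
    """Rows = normalized per-gene profiles, stably sorted for display.

    ``sort_key`` is one of ``max_position`` (position of the row
    maximum), ``first_exon_length`` (requires the mapping argument) or
    ``none``. All-zero rows sort last.
    """
    profiles = list(profiles)
    window = _common_window(profiles) if profiles else (0, 0)
    rows = np.array([p.values for p in profiles], dtype=float) \
        if profiles else np.zeros((0, 0))
    gene_ids = [p.gene_id for p in profiles]
    if normalization == "self_max":
        rows = normalize_self_max(rows)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if len(profiles) and sort_key != "none":
        zero = rows.max(axis=1) == 0
        if sort_key == "max_position":
            key = np.where(zero, np.inf, np.argmax(rows, axis=1))
        elif sort_key == "first_exon_length":
            if first_exon_lengths is None:
                raise ValueError("first_exon_lengths required for this sort")
            key = np.where(zero, np.inf,
                           [first_exon_lengths[g] for g in gene_ids])
        else:
            raise ValueError(f"unknown sort key {sort_key!r}")
        order = np.argsort(key, kind="stable")
        rows = rows[order]
        gene_ids = [gene_ids[i] for i in order]
    return ProfileMatrix(gene_ids, window, rows, normalization, sort_key)


def recenter(profiles, shifts) -> list[CoverageProfile]:
    """Translate each profile by −shift (edge bins truncated, zero-filled).

    A profile whose model places its initiation peak at +s, re-centered
    with shift s, has the peak moved to 0: new[x] = old[x + s].
    """
    out = []
    for p, s in zip(profiles, shifts, strict=True):
        s = int(round(s))
        n = len(p.values)
        if abs(s) >= n:
            raise ValueError("shift exceeds the window span")
        vals = np.zeros_like(np.asarray(p.values, dtype=float))
        if s >= 0:
            vals[:n - s] = p.values[s:]
        else:
            vals[-s:] = p.values[:n + s]
        out.append(CoverageProfile(p.gene_id, p.window, vals,
                                   anchor=p.anchor, oriented=p.oriented))
    return out


def occupancy_vs_expression(occupancy, expression, strata,
                            n_bins: int = 20,
                            low_support_frac: float = 0.01) -> pd.DataFrame:
    """Mean expression per (log-occupancy bin × stratum) with support flags.

    Genes are binned by log10 occupancy into ``n_bins`` equal bins over
    the observed range; per bin and CpG stratum the table reports the
    mean expression, the gene count, and a low-support flag set when the
    count is below ``low_support_frac`` of all genes. Genes with zero
    occupancy are excluded from binning but counted in the flag
    denominator.
    """
    occ = np.asarray(occupancy, dtype=float)
    expr = np.asarray(expression, dtype=float)
    strata = np.asarray(strata)
    if not (len(occ) == len(expr) == len(strata)):
        raise ValueError("inputs must be aligned")
    n_total = len(occ)
    if n_total == 0:
        raise ValueError("no genes")
    pos = occ > 0
    log_occ = np.log10(occ[pos])
    lo, hi = log_occ.min(), log_occ.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(log_occ, edges) - 1, 0, n_bins - 1)
    df = pd.DataFrame({"bin": idx, "expression": expr[pos],
                       "stratum": strata[pos]})
    grouped = (df.groupby(["bin", "stratum"], observed=True)
                 .agg(mean_expression=("expression", "mean"),
                      count=("expression", "size"))
                 .reset_index())
    grouped["bin_center"] = 0.5 * (edges[grouped["bin"]]
                                   + edges[grouped["bin"] + 1])
    grouped["low_support"] = grouped["count"] < low_support_frac * n_total
    return grouped[["bin", "bin_center", "stratum", "mean_expression",
                    "count", "low_support"]]
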