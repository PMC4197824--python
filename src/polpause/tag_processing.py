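"""Stranded tag tracks and their conversion to oriented promoter profiles.

ChIP-seq reads are reduced to stranded 5' "tag" positions. Because a
fragment is sequenced from either end, plus- and minus-strand tag pileups
flank the fragment population symmetrically: the cross-correlation lag
between the two strands estimates the fragment length, and shifting each
strand by half of it centers tags on fragment midpoints. This module
implements that shift estimation and application, per-promoter pileup in
gene orientation, the PCR tower filter, and the paired-end
fragment-center histogram used as the single-end-free cross-check.

Coordinates are 0-based and half-open throughout. A plus-strand tag sits
at the fragment (or read) start; a minus-strand tag is the half-open end
coordinate of the fragment, i.e. one past its 5'-most base. Tracks whose
minus tags were instead recorded at the leftmost alignment coordinate
(the common mapper convention) are handled by the ``read_len`` argument
of :func:`apply_shifts`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


class InsufficientDataError(ValueError):
    """A strand or profile carries too little signal for the operation."""


@dataclass
class TagTrack:
    """Sparse stranded tag counts for one contig."""

    chrom: str
    plus: Counter = field(default_factory=Counter)
    minus: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.plus.values()) + sum(self.minus.values())

    def copy(self) -> "TagTrack":
        return TagTrack(self.chrom, Counter(self.plus), Counter(self.minus))

    def update(self, other: "TagTrack") -> None:
        if other.chrom != self.chrom:
            raise ValueError(f"contig mismatch: {self.chrom} vs {other.chrom}")
        self.plus.update(other.plus)
        self.minus.update(other.minus)

    def add_positions(self, positions, strand: str) -> None:
        counter = self.plus if strand == "+" else self.minus
        counter.update(int(p) for p in np.asarray(positions).ravel())


@dataclass
class CoverageProfile:
    """Real-valued coverage on a window around an anchor, 5'->3' of the gene.

    ``window`` is (start_rel, end_rel), half-open, in bp relative to the
    anchor; positive coordinates are downstream in gene orientation when
    ``oriented`` is true.
    """

    gene_id: str
    window: tuple[int, int]
    values: np.ndarray
    anchor: int | None = None
    oriented: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.window[1] - self.window[0]:
            raise ValueError("profile length does not match window span")

    def rel_coords(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1])


def counts_vector(positions, window: tuple[int, int]) -> np.ndarray:
    """Dense per-bp counts of a sparse position->count map over ``window``."""
    a, b = window
    out = np.zeros(b - a, dtype=float)
    for pos, c in positions.items():
        if a <= pos < b:
            out[pos - a] += c
    return out


def estimate_strand_shift(track: TagTrack, window: tuple[int, int],
                          max_lag: int = 500) -> int:
    """Lag maximizing the plus/minus cross-correlation over 0..max_lag.

    The returned lag estimates the fragment length; half of it is the
    per-strand centering shift. Raises :class:`InsufficientDataError`
    when either strand is empty inside the window.
    """
    a, b = window
    p = counts_vector(track.plus, (a, b))
    m = counts_vector(track.minus, (a, b + max_lag))
    if p.sum() == 0 or m.sum() == 0:
        raise InsufficientDataError("both strands need tags in the window")
    n = len(p)
    scores = np.array([p @ m[lag:lag + n] for lag in range(max_lag + 1)])
    return int(np.argmax(scores))


def apply_shifts(track: TagTrack, read_len: int = 0,
                 half_fragment: int = 74) -> Counter:
    """Center stranded tags on fragment midpoints; returns a strandless map.

    Plus tags move downstream by ``half_fragment``. Minus tags move by
    ``read_len − half_fragment``: the ``read_len`` term converts a
    leftmost-alignment coordinate to the 5' end first (pass 0 when minus
    tags already are 5' positions, as in the synthetic tracks). The total
    tag count is conserved.
    """
    if read_len < 0 or half_fragment < 0:
        raise ValueError("read_len and half_fragment must be non-negative")
    out: Counter = Counter()
    for pos, c in track.plus.items():
        out[pos + half_fragment] += c
    for pos, c in track.minus.items():
        out[pos + read_len - half_fragment] += c
    return out


def pileup(positions, anchor: int, strand: str, window: tuple[int, int],
           gene_id: str = "") -> CoverageProfile:
    """Per-bp counts on a window anchored at a TSS, flipped for minus genes.

    ``positions`` is a strandless position->count map (e.g. the output of
    :func:`apply_shifts`). Positive relative coordinates are downstream
    of the anchor in gene orientation.
    """
    a, b = window
    if b <= a:
        raise ValueError("empty window")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    sign = 1 if strand == "+" else -1
    vals = [positions.get(anchor + sign * rel, 0) for rel in range(a, b)]
    return CoverageProfile(gene_id, (a, b), np.asarray(vals, dtype=float),
                           anchor=anchor, oriented=True)


def _filter_strand(counter: Counter, min_count: int, radius: int,
                   support: float) -> Counter:
    if not counter:
        return Counter()
    pos = np.array(sorted(counter))
    cnt = np.array([counter[p] for p in pos], dtype=float)
    keep = np.ones(len(pos), dtype=bool)
    for i in np.flatnonzero(cnt > min_count):
        lo = np.searchsorted(pos, pos[i] - radius, "left")
        hi = np.searchsorted(pos, pos[i] + radius, "right")
        neighbors = np.r_[cnt[lo:i], cnt[i + 1:hi]]
        if neighbors.size == 0 or neighbors.max() <= support * cnt[i]:
            keep[i] = False
    return Counter({int(p): int(c) for p, c in zip(pos[keep], cnt[keep])})


def pcr_filter(track: TagTrack, min_count: int = 10, radius: int = 50,
               support: float = 2.0 / 3.0) -> TagTrack:
    """Zero out isolated tag towers typical of PCR amplification.

    Every position with more than ``min_count`` tags must be supported by
    some other position within ±``radius`` bp carrying strictly more than
    ``support`` times its count; otherwise its signal is dropped. Strands
    are filtered independently; decisions use the original counts.
    """
    return TagTrack(track.chrom,
                    _filter_strand(track.plus, min_count, radius, support),
                    _filter_strand(track.minus, min_count, radius, support))


def fragment_center_histogram(fragments, min_len: int = 150,
                              max_len: int = 170) -> Counter:
    """Histogram of midpoints of fragments with length in [min_len, max_len].

    Bounds are inclusive. The midpoint of a half-open fragment [s, e) is
    floor((s + e − 1) / 2), i.e. even-length fragments round down.
    """
    frags = np.asarray(fragments, dtype=np.int64).reshape(-1, 2)
    if frags.size and not np.all(frags[:, 0] < frags[:, 1]):
        raise ValueError("fragments must satisfy start < end")
    lens = frags[:, 1] - frags[:, 0] if frags.size else np.array([], dtype=int)
    sel = frags[(lens >= min_len) & (lens <= max_len)]
    centers = (sel[:, 0] + sel[:, 1] - 1) // 2
    vals, counts = np.unique(centers, return_counts=True)
    return Counter({int(v): int(c) for v, c in zip(vals, counts)})
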