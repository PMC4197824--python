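"""Synthetic promoter cohorts with bimodal PolII structure.

Generates gene annotations, stranded PolII ChIP-seq tags and RNA-seq
coverage with the statistical features the downstream analysis assumes:

* promoter PolII fragment midpoints drawn from a two-Gaussian mixture —
  an initiation peak centered ~15 bp upstream of the true TSS and a
  pausing peak 110±20 bp downstream of it, the upstream peak about
  twice as wide as the downstream one;
* expression-scaled tag depth plus a uniform background that doubles as
  the gene-body elongation signal;
* a fraction of head-to-head (bidirectional) promoter pairs with
  opposite-TSS distances peaking near 200 bp, producing the upstream
  shoulder seen in averaged profiles;
* RNA-seq coverage that is roughly rectangular from ~15 bp downstream
  of the true TSS to the first splice junction, with a gradual (probit)
  onset and Poisson counts;
* optional isolated single-position PCR tag towers for filter testing.

Every generator is deterministic given its seed. Annotated TSSs deviate
from true TSSs by a truncated Normal(0, 40²) error capped at ±200 bp, so
TSS-refinement operations have something to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .tag_processing import CoverageProfile, TagTrack


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class GeneTruth:
    """One promoter's coordinates, expression, and generative parameters.

    Relative offsets (``upstream_peak_offset``, ``rna_onset_offset``) are
    in gene orientation: positive = downstream of the true TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    true_tss: int
    annotated_tss: int
    first_junction: int
    pas: int
    expression: float
    interpeak_d: float
    sigma_u: float
    sigma_d: float
    height_ratio_r: float
    upstream_peak_offset: int = -15
    rna_onset_offset: int = 15
    opposite_tss: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ConfigurationError(f"bad strand {self.strand!r}")
        if min(self.interpeak_d, self.sigma_u, self.sigma_d,
               self.height_ratio_r) <= 0:
            raise ConfigurationError("d, sigmas and r must be positive")
        if (self.first_junction - self.true_tss) * self.orientation <= 0:
            raise ConfigurationError("first_junction must lie downstream of the TSS")
        if abs(self.annotated_tss - self.true_tss) > 200:
            raise ConfigurationError("annotation error exceeds 200 bp")

    @property
    def orientation(self) -> int:
        return 1 if self.strand == "+" else -1

    def to_genomic(self, rel):
        """Gene-oriented offset from the true TSS -> genomic coordinate."""
        return self.true_tss + self.orientation * np.asarray(rel)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters.

    ``depth`` is the expected number of promoter fragments for a gene at
    reference expression (``expr_ref`` microarray units); per-gene depth
    scales as 2**(expression − expr_ref), spanning roughly two orders of
    magnitude over the expressed range. ``background_rate`` (fragments
    per bp over the gene region) sets the gene-body signal and is a free
    knob. The bimodal shape hyper-parameters reproduce the consensus
    promoter architecture: inter-peak distance Normal(110, 20²) truncated
    to [60, 180], downstream width Normal(20, 5²) truncated below at 5,
    upstream width = 2 × downstream × LogNormal(0, 0.2²), and
    log r ~ Normal(−0.525, 0.25²) so that ~70% of genes have more area
    under the upstream peak than the downstream one (ρ > 0).
    """

    n_genes: int
    seed: int
    depth: float = 2000.0
    background_rate: float = 0.02
    fraction_bidirectional: float = 0.15
    fragment_len_mean: float = 148.0
    fragment_len_sd: float = 15.0
    read_len: int = 100
    d_mean: float = 110.0
    d_sd: float = 20.0
    d_bounds: tuple[float, float] = (60.0, 180.0)
    sigma_d_mean: float = 20.0
    sigma_d_sd: float = 5.0
    sigma_d_min: float = 5.0
    sigma_u_factor: float = 2.0
    sigma_u_log_sd: float = 0.2
    log_r_mean: float = -0.525
    log_r_sd: float = 0.25
    expr_mean: float = 7.5
    expr_sd: float = 1.2
    expr_ref: float = 7.5
    annotation_err_sd: float = 40.0
    annotation_err_max: int = 200
    opposite_dist_mean: float = 200.0
    opposite_dist_sd: float = 30.0
    rna_depth: float = 20.0
    rna_onset_sigma: float = 40.0
    chrom: str = "chrS"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if min(self.depth, self.background_rate, self.rna_depth) < 0:
            raise ConfigurationError("rates must be non-negative")
        if not 0.0 <= self.fraction_bidirectional <= 1.0:
            raise ConfigurationError("fraction_bidirectional must be in [0, 1]")


def _trunc_normal(rng, mean, sd, lo=-math.inf, hi=math.inf):
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x


def expression_scale(expression: float, config: CohortConfig) -> float:
    """Depth multiplier for a gene's expression level."""
    return float(2.0 ** (np.asarray(expression) - config.expr_ref))


def _draw_shape(rng, cfg: CohortConfig):
    d = _trunc_normal(rng, cfg.d_mean, cfg.d_sd, *cfg.d_bounds)
    sigma_d = _trunc_normal(rng, cfg.sigma_d_mean, cfg.sigma_d_sd,
                            lo=cfg.sigma_d_min)
    sigma_u = cfg.sigma_u_factor * sigma_d * math.exp(
        rng.normal(0.0, cfg.sigma_u_log_sd))
    r = math.exp(rng.normal(cfg.log_r_mean, cfg.log_r_sd))
    return d, sigma_u, sigma_d, r


def _make_gene(rng, cfg: CohortConfig, gene_id: str, true_tss: int,
               strand: str, exon1: int, glen: int,
               opposite_tss: int | None = None) -> GeneTruth:
    d, sigma_u, sigma_d, r = _draw_shape(rng, cfg)
    expr = rng.normal(cfg.expr_mean, cfg.expr_sd)
    err = int(round(_trunc_normal(rng, 0.0, cfg.annotation_err_sd,
                                  -cfg.annotation_err_max,
                                  cfg.annotation_err_max)))
    sign = 1 if strand == "+" else -1
    return GeneTruth(
        gene_id=gene_id, chrom=cfg.chrom, strand=strand,
        true_tss=true_tss, annotated_tss=true_tss + sign * err,
        first_junction=true_tss + sign * exon1,
        pas=true_tss + sign * glen, expression=float(expr),
        interpeak_d=d, sigma_u=sigma_u, sigma_d=sigma_d, height_ratio_r=r,
        opposite_tss=opposite_tss)


def _geometry(rng) -> tuple[int, int]:
    """(first-exon length, gene length); exon >= 250 so the junction stays
    downstream of any annotated TSS (error capped at 200)."""
    exon1 = int(np.clip(rng.lognormal(math.log(500.0), 0.4), 250, 2500))
    glen = max(int(rng.uniform(2000, 8000)), exon1 + 500)
    return exon1, glen


def generate_cohort(config: CohortConfig) -> tuple[list[GeneTruth], pd.DataFrame]:
    """Place genes on one synthetic contig and draw per-gene parameters.

    Genes are spaced by >= 3 kb gaps except designated head-to-head
    bidirectional pairs, whose opposite-TSS distances are drawn from
    Normal(200, 30²) truncated to [120, 950] bp. Returns the truth list
    and the annotation table (gene_id, chrom, strand, annotated_tss,
    first_junction, pas, expression).
    """
    rng = np.random.default_rng(config.seed)
    genes: list[GeneTruth] = []
    cursor = 10_000
    i = 0
    while i < config.n_genes:
        pair = (rng.random() < config.fraction_bidirectional
                and i + 1 < config.n_genes)
        if pair:
            dist = int(round(_trunc_normal(rng, config.opposite_dist_mean,
                                           config.opposite_dist_sd, 120, 950)))
            exon_a, glen_a = _geometry(rng)
            exon_b, glen_b = _geometry(rng)
            tss_a = cursor + glen_a          # minus gene, body to the left
            tss_b = tss_a + dist             # plus gene, body to the right
            ga = _make_gene(rng, config, f"g{i:05d}", tss_a, "-", exon_a,
                            glen_a, opposite_tss=tss_b)
            gb = _make_gene(rng, config, f"g{i + 1:05d}", tss_b, "+", exon_b,
                            glen_b, opposite_tss=tss_a)
            ga = replace(ga, opposite_tss=gb.annotated_tss)
            gb = replace(gb, opposite_tss=ga.annotated_tss)
            genes += [ga, gb]
            cursor = tss_b + glen_b + int(rng.uniform(3000, 6000))
            i += 2
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            exon1, glen = _geometry(rng)
            tss = cursor if strand == "+" else cursor + glen
            genes.append(_make_gene(rng, config, f"g{i:05d}", tss, strand,
                                    exon1, glen))
            cursor += glen + int(rng.uniform(3000, 6000))
            i += 1
    return genes, annotation_table(genes)


def annotation_table(genes: list[GeneTruth]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "strand": [g.strand for g in genes],
        "annotated_tss": [g.annotated_tss for g in genes],
        "first_junction": [g.first_junction for g in genes],
        "pas": [g.pas for g in genes],
        "expression": [g.expression for g in genes],
    })


def truth_table(genes: list[GeneTruth]) -> pd.DataFrame:
    rows = []
    for g in genes:
        row = {f: getattr(g, f) for f in g.__dataclass_fields__}
        rows.append(row)
    return pd.DataFrame(rows)


def gene_region(truth: GeneTruth, upstream: int = 1500,
                downstream: int = 500) -> tuple[int, int]:
    """Genomic interval covered by a gene's simulated tags."""
    ends = sorted((int(truth.to_genomic(-upstream)),
                   int(truth.pas + truth.orientation * downstream)))
    return ends[0], ends[1]


def simulate_polII_tags(truth: GeneTruth, config: CohortConfig,
                        rng=None) -> tuple[TagTrack, np.ndarray]:
    """Draw PolII fragments for one gene; returns (tag track, fragments).

    Fragment midpoints come from the two-Gaussian promoter mixture
    (component areas in ratio r·σu : σd, matching maxima in ratio r)
    plus a uniform background over the gene region. Each fragment emits
    a plus-strand tag at its start and a minus-strand tag at its
    half-open end. Expected promoter fragment count is
    depth × 2**(expression − expr_ref).
    """
    if rng is None:
        rng = np.random.default_rng((config.seed * 1_000_003 + 17) % 2**31)
    scale = expression_scale(truth.expression, config)
    n_sig = rng.poisson(config.depth * scale)
    w_u = (truth.height_ratio_r * truth.sigma_u
           / (truth.height_ratio_r * truth.sigma_u + truth.sigma_d))
    comp_u = rng.random(n_sig) < w_u
    rel = np.where(
        comp_u,
        rng.normal(truth.upstream_peak_offset, truth.sigma_u, n_sig),
        rng.normal(truth.upstream_peak_offset + truth.interpeak_d,
                   truth.sigma_d, n_sig))
    mids = truth.to_genomic(rel)
    lo, hi = gene_region(truth)
    n_bg = rng.poisson(config.background_rate * (hi - lo))
    mids = np.concatenate([mids, rng.uniform(lo, hi, n_bg)])
    mids = np.round(mids).astype(np.int64)
    lens = np.maximum(np.round(rng.normal(config.fragment_len_mean,
                                          config.fragment_len_sd,
                                          len(mids))), 30).astype(np.int64)
    starts = mids - lens // 2
    ends = starts + lens
    track = TagTrack(truth.chrom)
    track.add_positions(starts, "+")
    track.add_positions(ends, "-")
    return track, np.column_stack([starts, ends])


def simulate_rnaseq_coverage(truth: GeneTruth, config: CohortConfig,
                             rng=None, noise: bool = True) -> CoverageProfile:
    """RNA-seq coverage on [annotated_tss − 500, first_junction + 200).

    Expected coverage rises as a probit step of width ``rna_onset_sigma``
    centered ``rna_onset_offset`` bp downstream of the *true* TSS, stays
    flat at rna_depth × 2**(expression − expr_ref), and drops to zero at
    the first splice junction. Counts are Poisson unless ``noise`` is
    false. The profile is anchored at the annotated TSS, gene-oriented.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed * 1_000_003 + 29) % 2**31)
    sign = truth.orientation
    junction_rel = (truth.first_junction - truth.annotated_tss) * sign
    if junction_rel <= 0:
        raise ConfigurationError("first splice junction upstream of annotated TSS")
    a, b = -500, junction_rel + 200
    rel = np.arange(a, b)
    # switch to the true-TSS frame where onset and junction are defined
    x = rel + (truth.annotated_tss - truth.true_tss) * sign
    junc_true = (truth.first_junction - truth.true_tss) * sign
    if config.rna_onset_sigma > 0:
        rise = ndtr((x + 0.5 - truth.rna_onset_offset) / config.rna_onset_sigma)
    else:
        rise = (x >= truth.rna_onset_offset).astype(float)
    amplitude = config.rna_depth * expression_scale(truth.expression, config)
    expected = amplitude * rise * (x < junc_true)
    values = rng.poisson(expected).astype(float) if noise else expected
    return CoverageProfile(truth.gene_id, (a, b), values,
                           anchor=truth.annotated_tss, oriented=True)


def inject_pcr_duplicates(track: TagTrack, n_spikes: int, spike_height: int,
                          seed: int) -> TagTrack:
    """Add isolated single-position tag towers; the input is not modified.

    Spikes are placed on previously empty positions, >= 100 bp away from
    any same-strand position holding more than 2/3 of the spike height
    (and from each other), so that every spike is removed by
    :func:`polpause.tag_processing.pcr_filter`.
    """
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    if spike_height <= 10:
        raise ValueError("spike_height must exceed 10 to be filterable")
    out = track.copy()
    if n_spikes == 0:
        return out
    rng = np.random.default_rng(seed)
    all_pos = list(track.plus) + list(track.minus)
    lo = (min(all_pos) if all_pos else 0) - 500
    hi = (max(all_pos) if all_pos else 10_000) + 500
    placed: list[int] = []
    threshold = 2.0 * spike_height / 3.0
    for _ in range(n_spikes):
        for _attempt in range(10_000):
            p = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            counter = out.plus if strand == "+" else out.minus
            near = [q for q in counter
                    if abs(q - p) <= 100 and counter[q] > threshold]
            if counter.get(p, 0) == 0 and not near and all(
                    abs(q - p) > 100 for q in placed):
                counter[p] = spike_height
                placed.append(p)
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not place an isolated spike")
    return out
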