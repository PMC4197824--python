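"""Shared constructors for hand-built fixtures."""

from polpause.synthetic_cohort import GeneTruth


def single_gene(strand="+", **overrides):
    """A lone promoter with round-number consensus parameters."""
    fields = dict(gene_id="g", chrom="chrS", strand=strand, true_tss=50_000,
                  annotated_tss=50_000, expression=7.5, interpeak_d=110.0,
                  sigma_u=40.0, sigma_d=20.0, height_ratio_r=1.2)
    sign = 1 if strand == "+" else -1
    fields["first_junction"] = 50_000 + sign * 600
    fields["pas"] = 50_000 + sign * 5000
    fields.update(overrides)
    return GeneTruth(**fields)
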