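# polpause

Quantification of bimodal promoter-proximal RNA polymerase II (PolII)
profiles from stranded ChIP-seq tags, for regulatory genomicists who
want per-gene pausing metrics rather than metagene averages alone.

High-coverage PolII ChIP-seq at active mammalian promoters shows two
distinct peaks: an initiation peak near the TSS and a pausing peak
~110 bp downstream. `polpause` fits, gene by gene, the empirical
two-Gaussian model

```
f(x) = A · [ exp(−(x−μu)²/2σu²) + (1/r) · exp(−(x−μu−d)²/2σd²) ]
```

(μu = initiation-peak position relative to the annotated TSS, d =
inter-peak distance, σu/σd = peak widths, r = ratio of maxima), scores
each fit by the Pearson correlation between model and data, and derives

* the **promoter-escape index** ρ = (p_u − p_d)/max(p_u, p_d) from the
  Gaussian areas p_u = Aσu√2π, p_d = (A/r)σd√2π, and
* the **pause-release index** π = gene-body density / downstream-peak
  density.

Around the model it provides the full pipeline: strand-shift estimation
and tag centering, per-promoter oriented pileups, an opt-in PCR-tower
filter, promoter neighborhood classification (isolated vs bidirectional),
CpG/GC/TATA sequence features, rectangular-function TSS refinement from
RNA-seq first-exon coverage, metagene aggregation with model-shift
re-centering, and a fully seeded synthetic-cohort simulator that makes
every stage testable without external data. See `docs/methods.md` for
the model, parameter conventions and limitations.

## Worked example

Simulate a 150-gene cohort and run the pipeline (each script reads the
previous one's outputs under `results/`):

```sh
python analysis/01_simulate_cohort.py     # cohort + tags + RNA coverage
python analysis/02_profile_promoters.py   # shift estimation + pileups
python analysis/03_fit_bimodal.py         # per-gene two-Gaussian fits
python analysis/04_refine_tss.py          # RNA rectangle fits + concordance
python analysis/05_aggregate_report.py    # classes, re-centering, tables
```

prints, among other things:

```
strand cross-correlation lag 148 bp -> per-strand centering shift 74 bp
fitted 150/150 genes; 129 with quality > 0.85
inter-peak distance: mode 117 bp, median 116.0 bp
promoter-escape index: 71% of genes with rho > 0, median rho +0.242
rectangle fits: 141/150 accepted (|shift| <= 120 bp rule)
PolII vs RNA TSS shifts over 97 genes: R^2 = 0.97, mean offset (rna - polII) = +29.1 bp
re-centering by the model shift: averaged peak height 30.60 -> 39.54
```

The 148-bp lag is the simulated fragment length, recovered from the
strand cross-correlation; the fitted inter-peak distances cluster at the
~110-bp consensus; ~70% of promoters hold more area under the initiation
peak (ρ > 0); and the RNA-derived TSS shifts track the PolII model
shifts up to the expected systematic ~30 bp offset (initiation peak
~15 bp upstream of the consensus TSS, RNA onset ~15 bp downstream of
it). Re-centering profiles by the fitted μu visibly sharpens the
metagene peak. Per-gene tables land in `results/*.tsv`.

The same operations are importable directly:

```python
from polpause import bimodal_fit as bf

profile = ...  # CoverageProfile on [-300, 400) around a TSS
fit = bf.fit_bimodal(profile)
p_u, p_d = bf.peak_areas(fit.params)
rho = bf.escape_index(p_u, p_d)
```

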