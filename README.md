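# kranzsep

Analysis toolkit for bundle-sheath (BS) / mesophyll (M) tissue-separation
experiments in C4 leaves — for researchers who enrich the two cell types by
serial filtration, mechanical separation or laser micro-dissection and need
to (a) recover true tissue distributions from imperfectly enriched
fractions and (b) tell real tissue specificity apart from RNA-degradation
artifacts when comparing studies.

## What it does

**Marker-anchored deconvolution.**  Enrichment fractions are mixtures, not
pure tissues.  With fraction-of-total profiles of an M marker (PEPC
activity) and a BS marker (NADP-ME activity) as tissue proxies, the OLS
slope b of ln(target/M) on ln(BS/M) estimates the fraction of a target
analyte residing in pure BS; b is tested against the 50/50 null
(t = (b − 0.5)/SE, n−2 df) and pure abundances are reconstructed as
b·2ā and (1−b)·2ā from the slice mean ā.

**3'-bias diagnostics.**  Degrading RNA loses its 5' ends, so per-gene
coverage bias — mean coverage over the 3'-most 100 nt divided by the
transcript-wide mean — flags degradation, per sample (median over the top
1000 expressed genes) and per gene set.  Under the positional model
cov(t) ∝ exp(−d·s_g·t), a gene's surviving signal is
R = (1 − e^(−d·s_g))/(d·s_g): degradation sensitivity s_g that differs
between genes, combined with degradation severity d that differs between a
study's BS and M samples, silently converts RNA quality into apparent
tissue specificity.

**Differential expression for both regimes.**  A conditional
negative-binomial exact-style test with pluggable common dispersion
(var = μ + φμ²) for well-separated samples, and a purity-adjusted
linear-unmixing estimator for enriched fractions: regressing normalized
expression on [π, 1−π] (π = BS purity) undoes the fold-change attenuation
(πF + 1−π)/((1−π)F + π) that contamination imposes on naive group ratios.

**Cross-study meta-analysis.**  Quantile normalization of log2 fold
changes, back-calculation of tissue TPM pairs from (ℓ, mean TPM), conflict
sets (genes significant in opposite directions in two studies), ortholog
agreement fractions, degradation-sensitive gene detection against
unseparated controls, correlation-distance clustering with Newick export,
developmental-switch support testing, Fisher category enrichment with
MapMan-style dot-path hierarchies and BH FDR.

**Synthetic data with ground truth.**  A first-class generator simulates
two-tissue mixture counts, positional coverage and marker-anchored activity
tables under the model above, with study templates for the three
separation strategies — so every estimator in the package is exercised
against known truth, no downloads required.

## Worked example

Deconvolve three analytes measured across three enrichment fractions
(purities 0.7/0.5/0.3, four replicates, 10% lognormal noise; true BS
fractions 0.15, 0.30 and 0.85):

```python
from kranzsep import SimConfig, simulate_activity_table, deconvolve

config = SimConfig(noise_sigma=0.1, seed=4)
activity = simulate_activity_table(
    [("malate", 0.30, 1.0), ("AspAT", 0.15, 1.0), ("RuBisCO", 0.85, 1.0)],
    purities=(0.7, 0.5, 0.3), replicates=4, config=config)
print(deconvolve(activity, "PEPC", "NADPME").round(4).to_string(index=False))
```

```
analyte_id  slice  slope_b     se  t_stat  p_value  bs_pure  m_pure
     AspAT      1   0.1862 0.0469 -6.6870   0.0001   0.3674  1.6058
   RuBisCO      1   0.7900 0.0312  9.3010   0.0000   1.5566  0.4139
    malate      1   0.3117 0.0429 -4.3934   0.0013   0.6248  1.3795
```

`slope_b` is the estimated fraction of each analyte in pure BS (compare the
true 0.15/0.30/0.85); `p_value` tests the 50/50 null, so all three analytes
are confidently tissue-biased — AspAT and malate toward M, RuBisCO toward
BS; `bs_pure`/`m_pure` are the reconstructed pure-tissue abundances (their
mean is the slice mean by construction).

The full synthetic degradation-artifact experiment — two pseudo-studies
sharing one truth with *no* tissue-specific genes, one study degrading its
M samples more than its BS samples — runs from the command line:

```
kranzsep demo --seed 1 --out demo_out/
```

and writes counts, DE tables, conflict sets with provenance, bias tables,
Newick trees, enrichment results and a `summary.json` reporting, among
other things, that the conflict set "BS-specific in the degrading study, M
in the clean one" contains 14 genes, is enriched for the most
degradation-sensitive quartile at p ≈ 3e-9, and shows elevated 3' bias over
the genomic background in all 20 samples — a technical artifact
reconstructed end to end from simulated reads.  Other subcommands
(`simulate`, `tpm`, `deconvolve`, `bias`, `de`, `compare`, `enrich`) expose
the individual stages; all outputs are plain text and byte-identical under
a fixed seed (see `manifest.json` in each output directory).

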