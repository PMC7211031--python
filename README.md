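# hotspotkit

Detection of recurrently mutated protein positions (hotspots) in somatic
mutation cohorts, with passenger-likelihood annotation.

The core model is a per-gene beta-binomial mixed model: the histogram
`h[i]` of protein positions mutated in exactly `i` distinct patients is
decomposed as `h[i] = BetaBin(a, b)[i] + F[i]`, where the background
beta-binomial captures over-dispersed per-site mutation counts and the
fixed-effect vector `F` is built by a greedy stepwise search that removes
grid fractions of histogram bins, refits the background and keeps the
removal with the lowest Kullback–Leibler divergence. Positions in bins
carrying fixed effects are flagged, given upper-tail beta-binomial
p-values, Benjamini–Hochberg corrected over warm spots (recurrence >= 4)
and filtered by `q < 0.01` or recurrence >= 7.

Flagged hotspots can then be annotated with two passenger warnings:

- **Hairpin stem strength** — scores potential DNA hairpins around the
  mutated base (3 per G:C pair, 1 per A:T pair, loops of 3–11 nt) and
  labels each hotspot `Likely` / `Unlikely` / `No` as an APOBEC3A
  artifact via a nine-entry threshold table over (loop position, loop
  length) combinations.
- **Gene-level dN/dS** — a simplified counting estimator of `wmis`,
  `wnon` (plus optional `wspl` / `wind`) from codon-table opportunity
  enumeration of the coding sequence, with one-sided Poisson p-values
  and the summary `max(wmis, wnon)`.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end statistical acceptance
checks (simulation-based recovery, spike detection, null calibration);
the rest are unit and property tests per module.

## CLI

```sh
# synthetic cohort with planted hotspots
hotspotkit simulate --spec scenario.yaml --out simdir/

# hotspot detection: MAF in, hotspot/model/fit tables out
hotspotkit detect --maf simdir/cohort.maf.tsv --out outdir/ \
    --n-patients auto --protein-lengths lengths.tsv

# hairpin + dN/dS annotation of the detected hotspots
hotspotkit annotate --hotspots outdir/hotspots.tsv --maf simdir/cohort.maf.tsv \
    --ref genome.fa --cds cds.fa --out annotated.tsv

# hypergeometric enrichment of hit genes in a reference list
hotspotkit enrich --hits hits.txt --reference-set census.txt --universe-size 20000
```

A simulation scenario file looks like:

```yaml
n_patients: 500
seed: 7
genes:
  - {name: G1, protein_length: 800, a: 0.05, b: 400.0}
spikes:
  - {gene: G1, position: 50, recurrence: 25}
```

All outputs are TSV with a comment header recording the tool version and
parameters. The same pipeline is available programmatically via
`hotspotkit.cli.detect_hotspots` and the per-module functions
(`hotspotkit.betabinom`, `hotspotkit.hairpin`, `hotspotkit.dnds`,
`hotspotkit.simulate`).

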