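# chipsip

Trophic-strategy analysis for Chip-SIP experiments: stable-isotope probing
of microbial communities in which ¹⁵N-labeled rRNA is hybridized to a
phylogenetic microarray and spot-level isotope enrichment is measured by
NanoSIMS imaging. The package takes probe-spot tables (fluorescence plus
δ¹⁵N or raw ¹²C¹⁴N⁻/¹²C¹⁵N⁻ ion counts) and a 16S tree of the targeted
OTUs, and classifies every taxon's response to substrate availability —
who incorporates amino acids, how incorporation scales with concentration,
and whether those strategies are phylogenetically conserved.

It is written for microbial ecologists running substrate-gradient SIP
incubations (e.g. high/medium/low amino-acid additions spanning three
orders of magnitude) who want a tested, reproducible route from raw spot
measurements to trophic guilds.

## The analysis

1. **δ¹⁵N conversion.** Raw ion counts become delta values via
   δ = [(R_meas / R_standard) − 1] × 1000, with R the ¹⁵N/¹⁴N ratio and
   R_standard measured on unhybridized regions of the array.
2. **Hybridization-corrected enrichment (HCE).** For each taxon and
   treatment, δ of its probe spots is regressed on spot fluorescence by
   ordinary least squares; the slope (‰ per fluorescence unit) corrects
   isotope signal for hybridization strength and is the per-taxon measure
   of substrate incorporation. Enrichment is flagged by a one-sided
   slope > 0 *t*-test at α = 0.05 (plus mean δ > 0).
3. **Activity classes.** Taxa are ranked by HCE at one reference
   concentration; those at ≥ 50 % of the maximum are HIGH activity.
4. **Trophic guilds.** An ANCOVA (δ ~ fluorescence × treatment) tests for
   a concentration effect at α = 0.05; directional pairwise post-hoc tests
   among (H,M), (H,L), (M,L) then place each taxon in
   H≈M≈L (saturated at the lowest concentration, oligotroph-like),
   H≈M>L (saturated only at the highest), H>M>L (never saturated,
   copiotroph-like), or OTHER.
5. **Ternary diagram.** HCE triplets, normalized to their sum, are plotted
   in barycentric coordinates (H apex, M bottom-left, L bottom-right).
6. **Phylogenetic signal.** Each guild becomes a binary character on the
   16S tree; its Fitch parsimony score is compared to a null built from
   1000 tip-label reshuffles. The one-sided empirical p-value
   (1 + #{null ≤ observed}) / (1 + n) is the headline statistic; an
   F-style variance-ratio statistic is reported alongside. Ancestral
   states are reconstructed by parsimony.

A synthetic-data generator produces datasets with known ground truth
(guild-dependent slope triplets, lognormal fluorescence, optional
clade-seeded clustering on a simulated tree), so every stage is testable
without external data.

## Worked example

```python
from chipsip import simulate_dataset, TrophicResponseModel

table, tree, truth = simulate_dataset(n_taxa=30, rng_seed=11)
res = TrophicResponseModel(table, tree=tree).fit(seed=11)
print(res.summary())
```

```
Trophic response analysis
============================================================
taxa classified: 30   (excluded: 0)

guild                pattern      n
----------------------------------------
NULL_HML             H≈M≈L        11
INTERMEDIATE         H≈M>L        11
COPIOTROPH           H>M>L         7
OTHER                other         1
----------------------------------------
activity (ref H, 50% of max): HIGH 30, LOW 0

phylogenetic signal (tip-reshuffling null)
------------------------------------------------------------
guild                score  null mean   p_emp    p_F
COPIOTROPH               7       6.47        1   0.447
INTERMEDIATE            11       9.04        1   0.114
NULL_HML                 9       9.11   0.5894   0.927
```

Thirty simulated taxa were classified; the tallies per guild sit close to
the generator's equal-thirds proportions (one taxon drew a borderline
pattern and landed in OTHER). Because this dataset scatters guilds
randomly over the tree, the observed parsimony scores sit inside their
reshuffling nulls — the empirical p-values near 1 correctly report no
phylogenetic clustering. All taxa share the same true HCE at the high
concentration, so all are HIGH activity at the 50 %-of-maximum cutoff.
`res.hce_frame()`, `res.results_table()`, `res.plot_ternary(path)` and
`res.to_files(outdir)` expose the per-taxon estimates, coordinates and
plots; `res.run_summary()` is the JSON-ready record of the run.

The same pipeline runs from the shell:

```sh
chipsip simulate --n-taxa 100 --seed 1 --out data/
chipsip analyze --probes data/probes.tsv --tree data/tree.nwk --out run/ --seed 1
chipsip report --run run/
```

For externally deposited probe tables, pass a column mapping to
`chipsip.read_probe_table` (or `TrophicResponseModel.from_files`) to adapt
whatever header names the deposit uses.

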