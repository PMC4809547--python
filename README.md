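# nucphase

Nucleosome phasing analysis around transcription-factor binding sites, from
paired-end fragment intervals.

In metazoan genomes, nucleosomes form strikingly regular arrays flanking the
binding sites of factors such as CTCF: the bound factor acts as a barrier,
and ATP-dependent remodellers (the ISWI-family ATPases SNF2H and SNF2L)
pack nucleosomes against it with a characteristic repeat. Because read depth
rarely permits calling nucleosomes at single loci, the standard readout is a
*metaprofile*: fragment midpoints (dyad proxies) from MNase-seq or ChIP-seq
are counted per base in a ±1 kb window around thousands of aligned sites.
`nucphase` implements that analysis end to end:

- **I/O** for BED6/narrowPeak sites, BEDPE/BED3 fragments, DE tables and
  profile TSVs (0-based half-open coordinates throughout).
- **Digestion matching** — mean fragment length tracks MNase digestion
  extent (147 bp for bare cores vs ~169 bp for light digests); samples are
  comparable only when means agree within 5 bp.
- **Site selection** — sites with a CTCF site center within 500 bp are
  excluded, so CTCF's own phasing does not contaminate other factors'
  profiles.
- **Metaprofiles** — per-base dyad counts around site anchors, divided by
  `n_sites × total_fragments`, rescaled to a common window mean, and
  smoothed with a 50 bp sliding window.
- **Phasing metrics** — peak detection (prominence threshold relative to the
  profile s.d., minimum separation, centroid refinement), the +1/−1
  nucleosome distance, and the nucleosome repeat length (NRL) estimated per
  flank as the least-squares slope of peak offset on outward peak index:
  for peaks at offsets *x₁ < x₂ < … < x_k* on one flank,
  `NRL = argmin_b Σ (x_i − a − b·i)²`.
- **Occupancy change** — percent loss of background-relative central
  enrichment between conditions (e.g. cohesin ChIP after CTCF depletion).
- **Co-regulation** — two DE tables filtered at |FC| > 1.5, p < 0.05,
  q < 0.05; overlap tested with a one-sided hypergeometric tail summed in
  log space (exact far below double underflow); concordance by Spearman
  correlation of log2 fold changes.
- **Synthetic chromatin generator** — a barrier-model simulator (phased
  dyad lattices with index-growing jitter, digestion-dependent fragment
  lengths, ChIP peak mixtures, paired DE tables) that makes every stage
  testable without any external data download.

## Worked example

```python
from nucphase import scenario_presets, run_synthetic_cohort, compare_conditions

presets = scenario_presets()
control = run_synthetic_cohort(presets["control"], n_sites=2000, seed=1)
depleted = run_synthetic_cohort(presets["snf2h_depleted"], n_sites=2000, seed=1)

s = control.summary
print(f"control: +1 at {s.plus_one:+.1f} bp, -1 at {s.minus_one:+.1f} bp, "
      f"+1/-1 distance {s.p1m1_distance:.1f} bp, NRL {s.nrl:.1f} bp")
s = depleted.summary
print(f"snf2h_depleted: +1/-1 distance {s.p1m1_distance:.1f} bp, NRL {s.nrl:.1f} bp")

delta = compare_conditions(control.summary, control.profile,
                           depleted.summary, depleted.profile)
print(f"delta: +1/-1 {delta.delta_p1m1:+.1f} bp, NRL {delta.delta_nrl:+.1f} bp, "
      f"central occupancy {delta.delta_center_occupancy:+.3f}")
```

prints

```
control: +1 at +139.6 bp, -1 at -140.2 bp, +1/-1 distance 279.8 bp, NRL 176.0 bp
snf2h_depleted: +1/-1 distance 304.7 bp, NRL 182.9 bp
delta: +1/-1 +24.9 bp, NRL +6.9 bp, central occupancy +0.021
```

The control cohort is generated with a 176 bp repeat; the pipeline recovers
it to 0.1 bp from 2000 sites. The SNF2H-depletion-like scenario widens the
+1/−1 distance by 25 bp and relaxes the repeat to 183 bp — both changes are
read back out by `compare_conditions`, together with the small gain in
nucleosome occupancy over the now more often vacant sites.

The same analysis is available from the shell:

```sh
nucphase simulate --scenario control --n-sites 2000 --seed 1 --out-dir ctrl/
nucphase profile --sites ctrl/sites.bed --fragments ctrl/fragments.bedpe --out ctrl.tsv
nucphase phasing --profile ctrl.tsv
nucphase check-digestion ctrl/fragments.bedpe other/fragments.bedpe
nucphase run config.yaml          # whole pipeline from a YAML config
```

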