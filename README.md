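# mitoret

Mitotic retention analysis of chromatin-binding proteins.

When cells divide, most sequence-specific chromatin proteins are
displaced from the condensed chromosomes; a protein that stays bound at
specific sites can "bookmark" them for rapid re-establishment of
regulation after mitosis. Deciding whether a protein is such a
bookmarking factor takes three independent lines of evidence, each with
its own quantification:

1. **Two-condition ChIP-seq** (interphase/control vs sorted mitotic
   cells): call peaks in both conditions, ask which control sites keep a
   mitotic peak ("persistent"), whether retention favors the
   strongest-ranked sites, and whether the apparent mitotic signal could
   be explained by a small fraction of interphase cells contaminating
   the sort.
2. **Subcellular fractionation**: the percentage of protein in the
   chromatin pellet (P3) of a mitotically arrested culture, corrected
   for the culture's mitotic index.
3. **Immunofluorescence**: the ratio of protein signal on the
   chromosomes versus in the cytoplasm of single cells.

`mitoret` implements all three quantifications as a tested library plus
a thin CLI, and ships a synthetic-data generator with known ground truth
so every stage can be validated end-to-end without any downloads.

## The statistics at the core

**Peak calling.** Single-end reads are extended to a fixed fragment
length *L* (default 36 bp) and piled up. Windows of width *w* (default
200 bp) are scored against a Poisson background: with *N* mapped reads
on an effective genome of *G* bp, the expected fragments intersecting a
window is λ = N(w + L − 1)/G, and a window with *k* fragments is a
candidate when P(X ≥ k) < 10⁻⁵ under X ~ Poisson(λ). Nearby candidate
windows are merged into peaks carrying the four ranking metrics used
downstream: Poisson p-value, reads in peak, pileup height, and fold over
background. With a sequencing-input track, an empirical FDR is attached
by the sample-swap convention (peaks called with treatment and control
exchanged), filtered at 5%.

**Retention.** A control peak is *persistent* if it overlaps a mitotic
peak by ≥ 1 bp. Control peaks are ranked by each metric and split into
deciles; the percentage of mitotic peaks per decile measures whether
retention favors the strongest sites. Agreement between two samples is
summarized as Pearson's r over per-peak read counts on the union of
peaks called in either sample.

**Contamination null.** The average mitotic read-density profile (RPM,
50-bp bins) around peak anchors is compared with a profile built from
5% of the control reads in peak regions, kept on the control's RPM
scale. The headline statistic is the ratio of central-bin enrichment
(each profile measured above its own baseline): ≈ 1 means the mitotic
profile is indistinguishable from sort contamination; ≫ 1 means genuine
retained binding.

**Fractionation correction.** A G2/M-arrested culture with mitotic
index *m* mixes mitotic and interphase-like cells, so

    P3_mitotic = (P3_observed − (1 − m) · P3_control) / m

and retention is reported as 100 · P3_mitotic / P3_control.

**Colocalization.** Both channels are thresholded with the Li minimum
cross-entropy method; the DNA mask comes from the DNA channel, the cell
mask from the protein channel, cytoplasm = cell − DNA, and the readout
is mean protein intensity on DNA over mean intensity in cytoplasm.

## Worked example

```sh
mitoret simulate --n-sites 1000 --depth 50000 --contamination 0.05 \
    --seed 1 --outdir sim
mitoret retention \
    --genome sim/genome.chrom.sizes \
    --control-reads sim/control_reads.bed \
    --mitotic-reads sim/mitotic_reads.bed \
    --borders sim/truth_borders.bed \
    --outdir out
```

The first command writes a 4-Mb toy genome with 1,000 binding sites of
log-normal occupancy, 10% of which are retained in the mitotic
condition at 30% occupancy, plus a 5% interphase contamination of the
mitotic sample; the truth tables record which sites are retained. The
second command prints (abridged):

```json
{
  "n_peaks_control": 819,
  "n_peaks_mitotic": 105,
  "retention": {
    "n_control": 819,
    "n_persistent": 105,
    "n_control_only": 714,
    "n_mitotic_only": 0,
    "fraction_persistent": 0.1282051282051282
  },
  "contamination_central_ratio": 2.676,
  "reads_in_peaks_pearson_r": 0.8498
}
```

Reading the output: 819 control peaks were called (the weakest of the
1,000 planted sites fall below the Poisson cutoff), 105 of them keep a
mitotic peak — recovering the 100 truly retained sites with a Jaccard
index of 0.92 against truth — and no peak is mitotic-only. The
contamination ratio of 2.7 says the mitotic profile, averaged over all
control-peak anchors, carries nearly three times the enrichment
expected from sort contamination alone (anchored on retained sites only
it is ~6); with `--retained-fraction 0` (pure contamination) the ratio
falls to ≈ 1. The per-peak Pearson r of 0.85 reflects that both the
retained signal and the contamination are proportional to control
occupancy. The output directory also contains the per-decile retention
table, RPM profiles, border-overlap summary, per-chromosome
distributions and a run manifest.

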