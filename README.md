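# fightsync

Dyadic behavioral and brain-transcriptomic synchrony analysis for
fighting-fish experiments.

When two male *Betta splendens* fight, their behaviors interleave in a
stereotyped way — surface-breathing and bite/strike attacks happen only in
the intervals between mouth-locking episodes — and over the course of a
long fight the two opponents' behavior, and eventually their brain
transcriptomes, become synchronized. `fightsync` implements the full
statistical pipeline for detecting and characterizing that synchrony from
a gene-by-sample RNA-seq count matrix plus behavioral event logs, together
with ground-truthed simulators of both data types so every stage is
testable without access to the original animals.

## The statistics at the core

With five fighting pairs (10 fish) per group there are C(10,2) = 45
*dyads*: 5 **paired** (the actual opponents) and 40 **unpaired**.

* **Global synchrony** — Pearson r of log₂ TMM expression profiles for all
  45 dyads; a permutation test (exact rank or full enumeration of all
  C(45,5) = 1,221,759 label assignments) asks whether paired r exceed
  unpaired r.
* **Per-gene synchrony** — for gene *i* and dyad *j* with TMM values
  A<sub>ij</sub>, B<sub>ij</sub>, the expression distance is
  D<sub>ij</sub> = |log₁₀(A<sub>ij</sub>/B<sub>ij</sub>)|. A one-sided
  permutation test per gene (paired distances smaller, p < 0.05) calls the
  gene *synchronized*.
* **Pair assignment** — each synchronized gene's baseline B<sub>i</sub> is
  the 25th percentile of its 40 unpaired distances; the gene counts as
  synchronized in pair *j* when D<sub>ij</sub> < B<sub>i</sub> (strict),
  yielding the tally of genes synchronized in 1…5 pairs.
* **Set statistics** — DEG calling vs the non-fighting baseline (Welch t on
  log₂ TMM, BH-FDR; thresholds FDR ≤ 0.05 with |log₂FC| > 2 or log₂FC > 0),
  Venn partitions, and an upper-tail hypergeometric overlap test evaluated
  via log-gamma so probabilities far below 1e-300 stay representable.
* **Behavioral synchrony** — event logs windowed into 2-minute windows with
  1-minute overlap; Pearson r of the two opponents' windowed frequencies.

Supporting machinery: TMM normalization (30 % M-trim / 5 % A-trim,
precision-weighted, factors rescaled to geometric mean 1), a
negative-binomial count simulator with pair-shared log₂ effects, a dyadic
event-log simulator with mouth-lock gating, and generic hypergeometric
over-representation analysis.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (2,000 genes, 5 baseline fish + 5 pairs per fighting group):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_normalize.py
python analysis/03_differential_expression.py
python analysis/04_synchronization.py --seed 1
python analysis/05_behavior.py
python analysis/06_enrichment.py --seed 1
```

which prints, among other things:

```
D20: paired-vs-unpaired correlation p = 1.93e-02; 15/408 DEGs synchronized; coclustering score 0.20
D60: paired-vs-unpaired correlation p = 8.18e-07; 120/343 DEGs synchronized; coclustering score 1.00
synchrony strengthens with fight duration: 15 synchronized genes after 20 min vs 120 after 60 min
10 pairs: behaviors start in the order breath < bite < mouth-lock (True); 60-min fights average
11.2 mouth-locks covering 23.8% of the fight; opponents' bite frequencies correlate at r = 0.86
```

Reading: after a 20-minute fight the dyad-correlation test is barely
significant and only one fighting pair clusters together (score 0.20 = 1 of
5 pairs as sister leaves), while after 60 minutes the paired dyads are at
the most extreme attainable p (1/1,221,759), all five pairs co-cluster, and
about a third of the up-regulated DEGs are synchronized in at least one
pair. The behavioral output mirrors the fight timeline: breathing starts
first, then biting, then mouth-locking, and the opponents' windowed bite
frequencies are strongly correlated.

The same pipeline is available as a CLI (`fightsync simulate | normalize |
de | sync | behavior | enrich | run-all`) for use on real count matrices
and event logs in the documented TSV/CSV formats.

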