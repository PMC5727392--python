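# branchsense

Sequence determinants of 3′ splice-site sensitivity to SF3B1-targeting
drugs — a tested, reusable analysis pipeline.

Splicing-modulating compounds such as Spliceostatin A (SSA) and the
Sudemycins bind SF3B1, the U2 snRNP subunit that presents the branch
point (BP) for catalysis. At moderate doses these drugs do not shut
splicing down globally: some 3′ splice sites respond strongly (introns
retained, cassette exons skipped) while others resist. `branchsense`
implements the computational side of dissecting why, for computational
biologists studying splicing modulation:

* **3′ss sequence features** — BP candidates and their base-pairing with
  U2 snRNA's GUAGUA region, an SF1-style PWM binding score, a
  polypyrimidine-tract (Py-tract) strength score, GC content, lengths,
  and multi-BP counts near the 3′ss.
* **PSI/PIR quantification** — percent spliced in / percent intron
  retention from junction read counts, Δ values between treated and
  control, and event classification (|Δ| ≥ 25 regulated, |Δ| ≤ 5
  non-regulated).
* **Group statistics** — Mann–Whitney feature comparisons with the
  field's star conventions, χ² enrichment, Welch t-tests, RNA maps,
  cross-drug overlaps and heatmap clustering.
* **A synthetic-data generator** — introns with planted BPs, Py-tracts
  and extra BP elements whose drug response follows a known logistic
  model, so every analysis is testable end to end with recoverable
  ground truth.

## The model at the core

For an event with standardized features *z* (BP strength, Py-tract
strength, log intron length, GC content) and a multi-BP indicator *m*,
the generator plants a true response

&nbsp;&nbsp;Δ = Δ<sub>max</sub> · σ(β₀ − β<sub>bp</sub>z<sub>bp</sub> −
β<sub>ppt</sub>z<sub>ppt</sub> − β<sub>len</sub>z<sub>len</sub> +
β<sub>gc</sub>z<sub>gc</sub> − β<sub>multi</sub>m)

(σ the logistic function; positive sign for intron retention, negative
for exon skipping). Weak BPs and Py-tracts, short and GC-rich introns
respond most; additional BP-consensus elements 5′ of the branch point
protect. The analysis half of the package must recover exactly these
directions from sequence and counts alone — and does.

## Worked example

```bash
python examples/03_group_comparisons.py
```

simulates 1,000 retained-intron events (seed 1), scores their 3′ ends
from the generated FASTA-level sequences, quantifies PSI/PIR from the
generated junction counts, and compares features between drug-retained
(`regulated_up`) and non-regulated (`nondiff`) introns:

```
        feature  n1  n2  median1  median2  p_value stars
bp_best_pairing 478 166      4.5        5 7.81e-22   ***
      ppt_score 478 166        6     10.5 2.05e-15   ***
      gc_intron 478 166    0.483      0.4 1.18e-25   ***
     len_intron 478 166      993 3.68e+03 4.16e-31   ***
    bp_distance 478 166     46.5       26 1.48e-10   ***

multi-BP events: median dPIR 17.6 (n=586) vs single-BP 26.8 (n=292), p=7.6e-07
```

Read: drug-retained introns have weaker U2 pairing at the BP (median
4.5 vs 5.0 of 6), weaker Py-tracts (6 vs 10.5), higher GC (0.48 vs
0.40), are ~4× shorter, and use more distant branch points; events with
two or more BP-consensus matches in the 3′ 100 nt change ~9 percent
points less than single-BP events. Other examples cover single-intron
scoring, quantification, response-model recovery, and the cross-drug
pipeline (`examples/05_cross_drug_pipeline.py` prints overlap
percentages and a clustered Δ heatmap ordering).

The same analyses are exposed as a thin CLI:

```bash
branchsense simulate --seed 1 --n-events 500 --out-prefix sim/
branchsense features --fasta sim/genome.fa --bed sim/introns.bed --out feat.tsv
branchsense quantify --events sim/events.tsv --control CTRL_1,CTRL_2 \
    --treated TRT_1,TRT_2 --out psi.tsv
branchsense run --config config.json   # full pipeline + manifest
```

## Layout

```
src/branchsense/
  io_formats.py      FASTA / BED6 / event-table / PWM readers & writers
  ss_features.py     motif scanning, U2 pairing, PPT, PWM, per-intron features
  splice_quant.py    PSI/PIR, delta, classification, regulated sets
  group_stats.py     Mann-Whitney, chi-square, t-test, RNA maps, clustering
  synthetic_data.py  generator with planted effects + response-model fitting
  pipeline.py        end-to-end orchestration, manifest, report
  cli.py             thin click wrapper (subcommand per stage)
docs/methods.md      model, assumptions, parameter choices, limitations
examples/            one narrative script per capability
```
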