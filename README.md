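# barcodegap

Evaluation of candidate DNA barcode loci for species identification within a
genus. Given species-labelled, pre-aligned sequences for one or more loci
(e.g. the plastid markers *matK*, *rbcL* and *psbA-trnH* in plants),
`barcodegap` quantifies everything a barcoding study reports when it asks
"which locus discriminates species best?":

- **alignment variability** — conserved, variable, parsimony-informative and
  singleton sites per locus;
- **genetic distances** — Kimura 2-parameter (K2P) or p-distance under
  pairwise deletion of gaps/ambiguities, with saturated pairs flagged rather
  than clamped;
- **divergence structure** — six intra/inter-specific metrics (all
  intraspecific distances, mean θ, coalescent depth, all interspecific
  distances, θ′, minimum interspecific distance), each as mean ± SD;
- **the barcoding gap** — intra vs inter distance histograms at 0.001
  resolution, zero-distance fractions, and Wilcoxon rank tests (signed-rank
  between loci on shared sample pairs; rank-sum for intra vs inter);
- **identification efficiency** — leave-one-out species assignment by the
  nearest-distance and best-hit (local-alignment, E-value-thresholded)
  methods, for single loci and multi-locus traffic-light combinations, with
  sample- and species-level success rates.

A seeded synthetic-data generator produces genus-level datasets with known
truth — species structure, transition/transversion bias, per-locus
amplification dropout, and large AT-repeat-flanked indels typical of
non-coding spacers — so every statistic can be validated against ground truth.

## The core quantities

For two aligned sequences compared at the n sites where both carry an
unambiguous base (pairwise deletion), with transition proportion P and
transversion proportion Q:

```
K2P distance   d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
p-distance     d = P + Q
```

Distances are partitioned into conspecific and heterospecific pairs. Per
species, θ is the mean intraspecific distance, coalescent depth the maximum
intraspecific distance, θ′ the mean distance to heterospecific samples, and
the minimum interspecific distance its nearest heterospecific neighbour.
Identification is leave-one-out: each sample is queried against all
remaining samples; a nearest-distance call requires the closest match under
a distance threshold (default 0.01 substitutions/site), a best-hit call
requires E = K·m·n·e^(−λS) below a cutoff (default 1e−6). A species counts
as identified only if *all* of its samples are called correctly, so species
efficiency ≤ sample efficiency, and singleton species (unidentifiable under
leave-one-out) stay in every denominator.

## Worked example

```python
from barcodegap import (dioscorea_like_profile, generate_dataset,
                        distance_matrix, partition_pairs, divergence_summary,
                        identify_all_nearest, efficiency_report)

dataset, truth = generate_dataset(dioscorea_like_profile(seed=1))
for aln in dataset.loci:
    part = partition_pairs(distance_matrix(aln, "k2p"))
    s = divergence_summary(part, aln.locus)
    print(f"{aln.locus}: intra {s['all_intra'].mean:.4f}+/-{s['all_intra'].sd:.4f}"
          f" (n={s['all_intra'].n}), inter {s['all_inter'].mean:.4f}"
          f"+/-{s['all_inter'].sd:.4f} (n={s['all_inter'].n})")
```

prints

```
matK: intra 0.0095+/-0.0036 (n=130), inter 0.0294+/-0.0061 (n=4721)
rbcL: intra 0.0019+/-0.0018 (n=187), inter 0.0115+/-0.0047 (n=6953)
psbA-trnH: intra 0.0189+/-0.0078 (n=148), inter 0.0892+/-0.0177 (n=5957)
```

i.e. for every locus the interspecific divergence is several-fold the
intraspecific variation, the precondition for a usable barcoding gap; n is
the number of sample pairs behind each mean. Continuing with leave-one-out
identification (see `examples/04_identification.py`):

```
matK: species 18.42% (samples 52.38%), 6 singleton species
rbcL: species 26.32% (samples 71.43%), 6 singleton species
psbA-trnH: species 0.00% (samples 12.93%), 6 singleton species
matK+rbcL+psbA-trnH: species 60.53% (samples 88.44%)
```

Combining loci raises efficiency because a sample dropped or misidentified
at one locus can still be rescued by another (the traffic-light rule).

The `examples/` directory has one short script per capability; the
`barcodegap` command exposes the same pipeline from the shell
(`barcodegap evaluate --seed 1 --out run/`).

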