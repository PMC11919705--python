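# catfish-quant

A quantification and statistics pipeline for **two-epoch catFISH** experiments:
cellular compartment analysis of temporal activity by fluorescent in situ
hybridisation, read out through two immediate-early genes (IEGs). Because
*Homer-1a* and *Arc* transcription foci appear in the nucleus on different
time scales after neuronal firing, a single brain imaged once reports which
neurons were active during each of two behavioural test entries (here: two
5-minute entries into a conditioned place preference arena, 20 minutes
apart). The package takes multi-channel confocal z-stacks
(DAPI / FITC-Homer / Cy3-Arc), atlas-derived ROIs and video-tracked
trajectories, and produces per-structure activity descriptors, behavioural
correctness scores, stratified group statistics, cross-structure correlation
networks and a stability-wrapped all-relevant feature selection.

It is written for neuroscientists running engram-mapping experiments of this
design, and ships a ground-truthed synthetic-data generator so every stage —
from watershed nucleus segmentation to Boruta feature selection — is testable
without any raw microscopy data.

## The quantities computed

For every brain structure, nuclei are segmented per z-layer on the DAPI
channel (watershed + moment ellipse fit), IEG transcription foci are detected
with a Laplacian-of-Gaussian blob detector, and each nucleus is classified by
its per-IEG dot counts into **both / Arc-only / Homer-only / negative**. The
three bottom-most and three top-most z-layers are discarded (partial cells),
both hemispheres are pooled at the nucleus level, and the per-class median
over the retained layers gives the structure's class fractions. From these:

- `f_first = f_homer_only + f_both`, `f_second = f_arc_only + f_both`,
  `f_any = 1 − f_negative`, plus the exclusive fractions;
- the **co-localisation coefficient**

  ```
  coloc = f_both / (f_first · f_second)
  ```

  the double-positive fraction over its expectation under independent
  activation across entries — 1 under independence, < 1 for exclusive
  activation, > 1 when the same sub-population re-activates;
- the behavioural **correctness score**: the fraction of total corner dwell
  time spent in the conditioned corner (chance level 0.25 with four
  equivalent corners).

Inference uses two-sided Mann-Whitney-Wilcoxon tests, stratified over
structures with van Elteren's combination, Holm correction (Benjamini-
Hochberg for the correlation-network families), two-sided Spearman
correlation networks per descriptor class, and a from-scratch Boruta
shadow-feature selector over Random-Forest importances, wrapped in median
imputation and a repeat-and-vote stability layer (a feature is reported when
selected — confirmed or tentative — in at least half of the repeats).

## Worked example

```python
import numpy as np
from catfish.synth import ActivityModel, sample_nuclei, render_zstack
from catfish.imagequant import ROI, QuantParams, quantify_roi
from catfish.descriptors import to_descriptors

poly = [(8, 8), (376, 8), (376, 376), (8, 376)]
model = ActivityModel(p_first=0.30, p_second=0.25, rho=0.0)
nuclei = sample_nuclei(poly, density=500 / (8 * 368**2), model=model,
                       n_layers=8, rng_seed=1)
stack = render_zstack(nuclei, (384, 384), rng_seed=1, n_layers=8)
rec = quantify_roi(stack, [ROI(structure="VTA", polygon=np.asarray(poly, float))],
                   QuantParams())
vec = to_descriptors(rec)
print(f"f_first={vec.f_first:.3f} f_second={vec.f_second:.3f} "
      f"f_both={vec.f_both:.3f} coloc={vec.coloc:.2f}")
```

prints

```
f_first=0.306 f_second=0.315 f_both=0.097 coloc=1.00
```

a single ~500-nucleus field quantified back to within binomial sampling error
of the generating model (marginal activation probabilities 0.30 / 0.25 — with
~60 nuclei per retained layer one field scatters by a few hundredths, here
visible in `f_second`), and a co-localisation coefficient at its independence
value of 1. Averaged over 10 seeded fields the recovered fractions land
within ±0.03 of the model — that is the ground-truth recovery check in
`tests/test_acceptance.py`.

The full staged pipeline (simulate → quantify → describe → behave → stats →
select) runs from one YAML config:

```bash
catfish run --config examples/demo.yaml
```

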