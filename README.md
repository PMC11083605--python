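# chewsim

Quantitative toolkit for comparing child and adult mastication of a soft,
sticky cheese and for choosing the settings of an artificial mouth (a
*masticator*) that best reproduce in vivo chewing.

## The problem

A processed cream cheese is a homogeneous white paste, so ordinary
particle-size methods (sieving) cannot track how far it has been chewed.
The trick is to colour only the *surface* of each cheese piece purple: as
the coloured and white phases fold into each other during chewing, the
spatial variance of the red channel inside the bolus region of a photograph
becomes a homogeneity index — the higher the variance, the less mixed the
bolus.  Combined with a texture endpoint (the *final charge*, i.e. the
force at the end of a back-extrusion compression), this gives two
instrumental axes on which in vivo boli (collected from children and adults
at 33 / 66 / 99 % of each subject's own chewing time) can be compared with
in vitro boli produced by a masticator run at different numbers of
tongue–palate compressions and plunger rotation speeds.

The package implements the full chain:

* **colorimetry** — CIE76 colour difference ΔE = √(ΔL\*² + Δa\*² + Δb\*²)
  and the ΔE > 5 visibility rule, to verify the colouring is detectable;
* **imaging** — chroma-key ROI extraction on the green photo background and
  the population red-channel pixel variance on a normalised [0, 1] scale,
  plus data-driven colour-channel selection via a one-way group-effect F;
* **texture** — final-charge hardness from penetration or back-extrusion
  force–displacement curves;
* **invivo** — per-subject masticatory parameters: chewing frequency n/t,
  saliva content (bolus WC/DM × cheese DM − cheese WC, in %), saliva volume
  (content × 10⁻² × consumed mass), stage times 0.33/0.66/0.99 t, and panel
  summaries (mean ± population SD);
* **transposition** — in vivo → masticator mapping: cheese mass =
  container volume / (mouth volume per quantity consumed), saliva schedule
  = saliva rate × pieces × compressions, and the compressions × rpm grid;
* **matching** — per group × stage × metric nearest-value selection of the
  masticator setting, with a fewer-compressions-then-lower-rpm tie-break
  and an image-metric-first final recommendation;
* **stats** — one-way, mixed two-way and mixed three-way (split-plot)
  ANOVA with Type III sums, and the exact binomial triangle test;
* **synthetic** — generators for panels, two-phase mixing images, force
  curves and triangle sessions, so the whole pipeline runs without the
  (non-public) raw study data.

## Worked example

```python
>>> import chewsim as cs
>>> from chewsim import datasets as ds

>>> round(cs.delta_e(ds.UNCOLORED_CHEESE_LAB, ds.COLORED_CHEESE_LAB), 2)
42.24
>>> cs.is_visually_distinct(42.24)          # far above the ΔE > 5 rule
True

>>> cs.in_vitro_cheese_mass(cs.MasticatorConfig(), 11.47)
32.69
>>> cs.in_vitro_saliva_volume(0.05, 7, 18)  # mL before an 18-compression run
6.3
```

The 32.69 g is the cheese mass whose ratio to the 375 mL container equals
the panel's pooled mouth-volume-per-bite ratio (11.47 mL/g); the saliva
volumes keep the pooled 0.05 mL/s in vivo salivation rate over 7 pieces.

Matching the published swallowing-stage (99 %) bolus measurements against
the candidate masticator settings:

```python
>>> from chewsim.matching import StageMeasurement, match_stage
>>> from chewsim.transposition import InVitroSetting
>>> cands = [(InVitroSetting(n, r, cs.in_vitro_saliva_volume(0.05, 7, n), 32.69), v)
...          for (n, r), v in ds.INVITRO_RED_VARIANCE.items()]
>>> m = match_stage(StageMeasurement(("child", 99), "red_variance", 0.0018), cands)
>>> m.selected.n_compressions, m.selected.rotation_speed, m.in_vitro_value
(6, 4.0, 0.0022)
```

i.e. the child swallowing point is best mimicked by 6 compressions at
4 rpm (in vitro red variance 0.0022 vs 0.0018 in vivo); the same procedure
over all stages and both metrics recommends 14 compressions – 15 rpm for
adults.

A full synthetic run (panel simulation → images → scoring → ANOVA →
matching → report bundle):

```sh
chewsim report --seed 1 --out results/run1
```

or, step by step, `chewsim simulate-panel / simulate-images /
simulate-curves / score-images / score-texture / transpose / match /
stats` — all with uniform `--seed`, `--config`, `--out` flags.

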