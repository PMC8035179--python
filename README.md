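# salispect

Quantitative salivary-gland SPECT/CT analysis: automated gland
segmentation and per-gland uptake/excretion quantification for the
two-timepoint Tc-99m pertechnetate protocol.

## The problem

Salivary gland dysfunction (after radioiodine therapy, in Sjögren's
syndrome, after alpha-particle radionuclide therapy) is assessed
functionally with Tc-99m pertechnetate imaging.  A quantitative SPECT/CT
protocol images the glands at 20 min post-injection (SPECT + CT), applies
a sialagogue, and images again at 40 min (SPECT only, reconstructed in
the 20-min CT frame).  Two imaging biomarkers are computed per gland —
parotid and submandibular, each side:

* **%ID** — percent injected dose, `100 * A_gland / A_injected`, with the
  gland activity summed over a CT-drawn volume of interest (VOI) and the
  reference activity decay-corrected (Tc-99m half-life 6.0058 h);
* **%EF** — percent excretion fraction,
  `100 * (%ID_20 - %ID_40) / %ID_20`.

Manual VOI drawing takes ~15 min per scan; this package provides the
full pipeline to automate and validate it:

* `salispect.volumes` — calibrated CT/SPECT volume types, NIfTI and
  DICOM-series I/O, grid resampling;
* `salispect.phantom` — a synthetic head-and-neck phantom population
  with programmed gland kinetics, PSF blur, Poisson noise,
  inter-timepoint misalignment and simulated manual raters;
* `salispect.preprocess` — soft-tissue-profile CT cropping to the fixed
  network matrix and intensity normalization;
* `salispect.segmentation` — a 3D U-Net (compact CPU implementation)
  that labels the four glands on CT, with training, inference, cleanup
  and cross-validation;
* `salispect.registration` — rigid correction of 40-min SPECT
  misregistration by multiresolution normalized cross-correlation;
* `salispect.quantify` — VOI volume, %ID, %EF and protocol
  radiation-dose accounting;
* `salispect.evaluate` — DSC, MAPE, R², Bland–Altman, paired t, and
  two-way ICC agreement statistics;
* `salispect.cli` / `salispect.pipeline` — a `salispect` command with
  `phantom`, `preprocess`, `segnet`, `register`, `quantify`, `evaluate`
  and `run` subcommands.

See `docs/methods.md` for the model and all numerical conventions.

## Worked example

Generate a small synthetic cohort, quantify it with its ground-truth
VOIs, and print the per-gland table:

```python
from salispect import PhantomSpec, generate_study, quantify_study
from salispect.quantify import quant_table

spec = PhantomSpec(noiseless=True, misalign_translation_mm=0.0,
                   misalign_rotation_deg=0.0, seed=1)
rec = generate_study(spec, 0)
q = quantify_study(rec.spect20, rec.spect40, rec.truth_labels,
                   rec.injected_activity_MBq)
print(quant_table(q, rec.study_id).to_string(index=False))
```

```
          study_id           gland  voi_mL    pid20    pid40        ef
phantom_00001_0000       parotid_r  16.752 0.403218 0.169936 57.855137
phantom_00001_0000       parotid_l  20.412 0.495482 0.145299 70.675248
phantom_00001_0000 submandibular_r  12.504 0.138103 0.092704 32.873253
phantom_00001_0000 submandibular_l   9.660 0.135916 0.094252 30.654149
```

Each row is one gland: the VOI volume in mL, the 20- and 40-min percent
injected dose, and the excretion fraction.  This phantom drew a
right-parotid uptake of 0.403 %ID that fell to 0.170 %ID after the
sialagogue, i.e. 57.9% of the tracer was excreted.  On noiseless
phantoms the recovered values match the programmed kinetics to better
than 0.1%; with the default Poisson noise a parotid VOI sum carries
about 3% counting noise.

The dose bookkeeping of the one-CT protocol:

```python
from salispect.quantify import (tracer_effective_dose, ct_effective_dose,
                                protocol_effective_dose, round_reported)
tracer = round_reported(tracer_effective_dose(555.0))   # 7.22 mSv
ct     = round_reported(ct_effective_dose(60.31))       # 0.19 mSv
total  = protocol_effective_dose(tracer, [ct])          # 7.41 mSv
```

Omitting the second CT session reduces the protocol effective dose from
7.59 mSv to 7.41 mSv.

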