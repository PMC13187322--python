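# memtopo

Segmentation and quantification of T-cell plasma-membrane topography in
multi-channel live-cell fluorescence time lapses.

The pipeline separates the membrane into thin actin-rich **protrusions** and
the **main-body membrane**, detects contacts with an approaching target cell
and bright receptor clusters, and quantifies protein localisation with
region-normalised statistics over time:

- **enrichment** — mean intensity in a membrane region / mean over the whole
  plasma membrane;
- **relative enrichment** — a protein's enrichment divided by that of a
  uniformly distributed membrane marker in the same cell (1 = no
  preference); at contact sets, the ratio of contacting to non-contacting
  enrichment;
- **membrane-bound signal** — contacting minus non-contacting enrichment (a
  recruitment readout for cytoplasm-dominated proteins), optionally
  normalised by a marker reference;

with standard errors propagated through every difference and ratio, time
aligned to the first detected contact, window aggregation (first minute /
first two minutes), per-replicate summaries and paired/unpaired t tests.

A fully ground-truthed synthetic-scene generator (`memtopo.synthetic`)
renders cell body + shell + tubular protrusions + approaching target +
nucleating clusters with Poisson/Gaussian noise, so every stage is validated
against planted parameters without microscopy data.

## Pipeline stages

1. **Preprocessing** (`image_model`): rolling-ball background subtraction
   (radius 50 px; flat-disc dialect by default, true ball available) and
   Gaussian blur (sigma 1 px for measurement, 2 px for segmentation).
2. **Membrane segmentation** (`membrane`): channel-averaged segmentation
   image; inner body from dark-hole enhancement of the inverted image;
   9-px dilation to cover the main-body membrane and 35-px dilation for the
   neighbourhood; tubeness (Hessian ridge) enhancement and thresholding for
   membrane structures; protrusions = ridge pixels beyond the dilated body,
   inside the neighbourhood, minus single-pixel objects.
3. **Contacts** (`contacts`): target mask from the moment-preserving
   ("Moments") threshold computed on the preprocessed last frame and applied
   stack-wide; contact/non-contact partition per region; first-contact frame
   defines t = 0; contact-area percentages.
4. **Clusters** (`clusters`): receptor image normalised by its whole-membrane
   mean, pixels strictly above 2, components with area in [5, 100] px,
   assigned to protrusion/body by overlap; per-cluster channel ratios.
5. **Metrics & aggregation** (`metrics`, `pipeline`): per-frame metric
   records with uncertainties, window means, replicate summaries, two-sided
   paired/unpaired t tests (raw p values).

## Command line

```sh
# render a synthetic scene (TIFF stack + truth masks + analytic expectations)
memtopo simulate --out scene/ --seed 7

# segment membrane regions and the target; write 8-bit mask TIFFs + stats
memtopo segment --input scene/stack.tiff \
    --roles "0=membrane_reference,1=receptor,2=protein,3=target" \
    --holes-radius-px 70 --out seg/

# full quantification of one stack -> tidy metric CSV + provenance JSON
memtopo quantify --input scene/stack.tiff \
    --roles "0=membrane_reference,1=receptor,2=protein,3=target" \
    --config config.yaml --out quant/

# many stacks via a YAML manifest, with cross-event summary + t tests
memtopo run --manifest manifest.yaml

# aggregate existing metric CSVs
memtopo summarise --metrics quant/stack_metrics.csv --out summary/
```

Configuration is a YAML/JSON file mirroring `PipelineConfig` field names;
every exposed flag overrides the file. Note that `holes_radius_px` (dark-hole
enhancement) must exceed the cell radius in pixels and
`inner_body_min_area_px` must sit below the cell's interior area —
`memtopo.synthetic.suggested_config` derives both from scene geometry.

## Layout

```
src/memtopo/
  image_model.py   data model, TIFF I/O, preprocessing, uncertainty algebra
  thresholds.py    Otsu + Tsai moment-preserving ("Moments") thresholds
  membrane.py      inner body, dilation, tubeness, protrusion/body masks
  contacts.py      target mask, contact partition, first contact, fractions
  clusters.py      receptor cluster detection and per-cluster ratios
  metrics.py       enrichment family, timecourses, window aggregation
  synthetic.py     ground-truthed scene generator + analytic expectations
  pipeline.py      per-event orchestration, summaries, t tests, tables
  cli.py           click CLI (simulate / segment / quantify / run / summarise)
```
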