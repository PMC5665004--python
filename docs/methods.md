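# Methods

This note records what `colldigi` models, the parameter and numerical
choices baked into it, how faithful the synthetic generator is to real
digitisation conditions, and where the model deliberately stops.

## The model

The package implements a mass-digitisation workflow for pinned-insect
collections in which the photograph is the primary act of data capture and
everything else is derived from it:

1. **Imaging.** Specimens are staged in unit trays (neutral grey background,
   raised label area on the right of the frame) and photographed with a
   DataMatrix-barcoded identifier among the labels. Images are dropped off
   in a `Drawer##/Taxon/*.jpg` folder tree.
2. **Batch processing.** For each new frame the pipeline crops the rightmost
   quarter (the label panel), resizes it to a fixed 800×1219 label image,
   decodes the barcode from the original-resolution crop, renames both files
   to `<barcode>.jpg` / `<barcode>_label.jpg`, and creates a specimen record
   whose drawer and taxon come from the folder path. `*_b.jpg` files are
   reverse-side label photographs attached to the sibling frame's specimen.
3. **Transcription** captures verbatim strings (site, date, collector,
   registration) exactly as written; each distinct string is a *variant*
   keyed once. Only unambiguous dates are parsed into calendar ranges;
   two-digit years are refused and flagged rather than guessed.
4. **Normalisation** assigns variants to standardised *masters*
   (many-to-one, replaceable, with history). Site masters are the unit of
   georeferencing; taxon masters come from a seeded checklist.
5. **Georeferencing** attaches a point-radius (latitude, longitude, extent)
   to each site master, triaged by specimen count with threshold 5, the
   remainder split A–M / N–Z with an advisory 15-minute budget per site.
   Quality assessment re-georeferences a seeded random sample independently
   and scores agreement by great-circle distance against the extents.
6. **CMS ingest** exports CSVs of records lacking an IRN in dependency
   order (catalogue last), imports the returned (local id, IRN) pairs, and
   applies per-type duplication policies: catalogue/multimedia/events/sites
   always create new records, taxonomy and parties match-by-name or create,
   locations only match a pre-registered set.
7. **Publication** emits a Darwin Core occurrence table for ingested,
   non-embargoed specimens, carrying both `verbatimLocality` (the label
   string) and `locality` (the master), the point-radius georeference, and
   ISO 8601 event-date ranges (`start/end`).

Throughput analytics use classical three-point (PERT) estimation per stage:
E = (a + 4m + b)/6 and SD = (b − a)/6 with a = observed minimum, m = median,
b = 90th percentile of per-specimen stage times.

## Parameter choices

- **Barcode scheme**: `NHMUK` prefix + 9 digits; ECC 200 DataMatrix, square
  symbols 10×10 to 26×26, ASCII encodation, Reed–Solomon over GF(256) with
  primitive polynomial 0x12D.
- **Label crop**: rightmost `width // 4` pixels, bicubic-resampled to
  exactly 800×1219 (portrait label aspect); decode failures retry on a
  sharpened half-scale copy before giving up.
- **Triage threshold**: 5 specimens per site master; split-pass budget 15
  minutes per site (advisory, recorded not enforced).
- **Haversine radius**: R = 6,371 km (mean Earth radius).
- **Workflow statuses**: `imaged → transcribed → normalized → georeferenced
  → exported`, monotone; stage-skips are allowed but audited.

## Numerical conventions

- **Rounding is half-up** (via `decimal.Decimal`), not banker's: 2 decimal
  places for times, whole numbers for percentages. This is the convention
  that reproduces the published tables from their own printed inputs.
- **Project totals** sum the *unrounded* per-stage estimates and round once
  (giving 2.40 and 3.80 for the butterfly and diptera pilots); applying the
  three-point formula to the printed TOTAL column instead gives 2.39 for
  butterflies. Two published cells do not reconcile with their printed
  inputs under any rounding we tried — the moth imaging base estimate
  (printed 1.16, computed 1.153) and consequently the moth total — and are
  treated as printing artefacts: excluded from targets, not force-fitted.
- **Quantiles** (median, 90th percentile from timing logs) use linear
  interpolation between order statistics (`numpy.quantile` default), with a
  minimum of 10 observations per stage.
- **Percent reduction** from deduplication is
  `100·(variants − masters)/variants`, rounded half-up, reproducing the
  published 50% (9,591→4,835) and 48% (10,353→5,429).

## Generator fidelity

The synthetic collection reproduces the statistical structure the pipeline
is sensitive to, not photographic realism:

- geometry: 2400×1600 frames, grey stage, light right-quarter label panel,
  typed label lines, DataMatrix at 10 px/module — so cropping, thresholding
  and symbol location behave as on real staged photographs;
- identity failures: a configurable fraction of barcodes is corrupted by
  overpainting a rectangle covering ~30% of the symbol (defeating error
  correction, as intended) or omitted entirely;
- variant structure: a weighted site pool maps several verbatim spellings
  to each master, with a coverage guarantee that every configured spelling
  occurs; `emulate_dedup_profile` constructs pools with an exact
  variants/masters census and Zipf-like weights so a few sites dominate, as
  in real collections;
- label content: dates in the common Lepidoptera conventions (roman-numeral
  months, month-only, year-only), drawn from a configurable year range.

The same seed yields a byte-identical manifest. What the generator does
*not* model: handwriting (all text is typed), focus/lighting variation,
specimen occlusion of labels, and OCR — transcription quality is out of
scope because the workflow under study is human transcription.

## Limitations

- The image-level DataMatrix reader assumes roughly axis-aligned symbols
  (the four 90° rotations are tried); arbitrary rotation and perspective
  are not handled, matching staged unit-tray photography rather than
  hand-held capture.
- The CMS is emulated (`MockCMS`) at the level of the CSV/IRN contract and
  duplication policies; no network protocol is implemented.
- Collection-scale published outcomes (181,545 specimens digitised, 60–70%
  triage coverage, cost per specimen £2.02 vs the arithmetic £2.04) are
  outcomes of the real multi-year project and are not desk-reproducible;
  they appear only as generator parameters or documented discrepancies.
- Georeferencing QA measures point/extent agreement only; it does not model
  gazetteer error or systematic bias between georeferencers.
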