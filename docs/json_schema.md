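# The `wellinvert-json` experiment schema

Versioned JSON document used both for archival saves and for result
export. Times are minutes since the start of the experiment.

```json
{
 "schema_version": 1,
 "plate_shape": [8, 12],
 "metadata": {"instrument": "…", "…": "…"},
 "wells": {
  "A5": {
   "absorbance": {
    "times": [0.0, 2.0, …],
    "values": [0.105, 0.107, …],
    "outlier_mask": [false, false, …],
    "corrected_values": null
   },
   "fluorescence:gfp": { "…": "…" }
  }
 },
 "well_groups": {"glucose": ["A5", "A6", "A7"]},
 "background_assignments": [
  {"wells": ["A5", "A6"], "channel": "absorbance", "method": "fixed"}
 ],
 "results": [
  {
   "well_label": "A5",
   "quantity": "growth_rate",
   "times": [306.0, …],
   "values": [0.0124, …],
   "validity_mask": [true, …],
   "lambda": 10000.0
  }
 ]
}
```

Rules:

- `schema_version` is required; the current version is 1.
- Channel names are `absorbance` or `fluorescence:<name>`.
- `times` are strictly increasing within a series; `values`,
  `outlier_mask` and `corrected_values` (when non-null) have the same
  length.
- The **archival** document (written when saving an experiment) omits
  `results` but keeps everything needed to reproduce an analysis:
  outlier masks, background assignments, well groups, corrected values.
- The **export** document additionally embeds `results` blocks, one per
  estimated quantity per well; `lambda` is the regularization weight used
  (null for the ratio-based reporter concentration).
- Parsing a document and re-writing it reproduces times, values, labels,
  masks, groups and metadata exactly.
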