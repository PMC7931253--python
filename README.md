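# foodex

Tools for auditing proximate food-composition tables and deriving meal-planning
exchange lists from them.

Given per-100 g proximate records (moisture, ash, protein, fat, carbohydrate,
energy), the package:

- **completes** records — carbohydrate by difference
  (`CHO = 100 − (moisture + ash + protein + fat)`) and energy via Atwater
  factors (4 / 4 / 9 kcal/g for CHO / protein / fat, half-up integer display);
- **audits** internal consistency — mass-closure residuals, printed-vs-derived
  CHO gaps and printed-vs-Atwater energy gaps are reported as findings, never
  silently repaired;
- **profiles %DV** of 100 g portions against a 2000 kcal daily reference
  (275 g CHO, 50 g protein, 78 g fat), with one-decimal reporting (truncation
  by default, half-up available) and low / good-source / high claim tiers at
  the 5% and 20% cut points;
- **derives exchange lists** — banded round-off of single portions to
  0 / 0.5 / 1 servings, grams-per-exchange (one exchange = 15 g CHO, 7 g
  protein or 5 g fat), quarter-quantized per-100 g exchange counts,
  one-CHO-exchange serving sizing and per-serving scaling with one-decimal
  truncation;
- **parses and writes** the tabular dialects involved: serving measures like
  `"100 g (1/2 cup)"`, exchange strings with decimal commas
  (`"1,25 starch, 1 fat"`, `"1, 25 starch, 1 MFM"`), CSV and markdown
  renderings;
- **generates synthetic data** — seeded, closure-consistent records with
  class-specific component ranges, plus controlled closure corruption, so the
  full pipeline is testable without any external data.

Two CSV fixtures ship with the package under `src/foodex/data/`: a 65-food
composition table (30 dishes + 35 sweets) and the matching exchange/serving
table. Printed inconsistencies in the source tables (sweets that fail mass
closure or the Atwater check, floored serving sizes, back-computed fat cells)
are preserved verbatim and marked with explicit `flags`.

## CLI

```sh
foodex validate  --input composition.csv            # audit; exit 1 on findings
foodex analyze   --input composition.csv --output dv.csv
foodex exchanges --input composition.csv --annotations servings.csv --output ex.csv
foodex simulate  --n 50 --class-label sweet --seed 7 --output synth.csv
```

All subcommands use the packaged composition fixture when `--input` is
omitted, and accept `--config config.yaml` (see `foodex.config.PipelineConfig`
for the schema: Atwater factors, daily reference, exchange quanta, band cut
points, rounding modes, tolerances, seed). Logs go to stderr, data to files or
stdout.

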