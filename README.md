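# emeserv

Emergy-based ecosystem-services accounting with partial-differential driver
attribution.

The package values the services of nine ecosystem classes — forest (F1),
shrub (F2), high/medium/low-coverage grassland (G1–G3), wetland (A1), lake
(A2), reservoir/pond (A3) and river (A4) — as annual emergy flows
(sej·yr⁻¹), combines them into double-counting-safe totals, and decomposes
the change of those totals between two epochs into the contributions of

- **R** — natural drivers (precipitation, wind, elevation, insolation,
  NPP, evapotranspiration),
- **τ** — the cognition driver (per-capita health-expenditure emergy),
- **S** — the human driver (ecosystem area change), and
- **δ** — the first-order residual,

with per-region summary tables in the three precipitation zones
(north of 400 mm / 400–800 mm / south of 800 mm).

## Layout

| module | responsibility |
| --- | --- |
| `emeserv.parameters` | domain types, constants, YAML parameter tables, validation |
| `emeserv.emergy_base` | NDVI vegetation-fraction area correction, renewable-emergy MAX rule |
| `emeserv.services` | the eleven services (NPP, CS, SB/SBa, GR, AP, WP, SR, MR, MT, HG, CR) |
| `emeserv.totals` | MAX-group totals per class, river hydropower cases, aggregation, change rates |
| `emeserv.attribution` | bilinear driver model, first-order decomposition, rates, regional summaries |
| `emeserv.synthetic_data` | seeded two-epoch fixture generator with controlled driver deltas |
| `emeserv.io` / `emeserv.cli` | CSV round-trip tables and the five-stage CLI |

The shipped demo parameter set (`emeserv.parameters.demo_params`) is
**non-authoritative**: magnitudes are chosen only so service values land in
a realistic 1e18–1e23 sej·yr⁻¹ range. Real studies must supply their own
UEV/DALY/PDF tables (YAML schema in `parameters.save_params`).

## CLI

```sh
emeserv simulate --seed 7 --out ws/       # two-epoch synthetic workspace
emeserv account   --workspace ws/         # per-record service ledgers
emeserv totals    --workspace ws/         # totals + change rates
emeserv attribute --workspace ws/         # R/τ/S/δ decomposition
emeserv report    --workspace ws/         # three-region summary table
```

Every command appends a JSON-lines `run.log` (config echo + output
manifest); all tables are plain CSV and round-trip bit-exactly.

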