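# pmrkit

Quantification toolkit for live-cell **plasma-membrane repair (PMR)**
assays and the calcium-handling phenotypes that accompany repair failure
in muscular-dystrophy patient muscle cells.

When a cell's plasma membrane is wounded — by a focal laser pulse or by
rolling glass beads — a healthy cell reseals within about a minute, while
a repair-deficient cell keeps admitting extracellular dye and accumulates
cytosolic Ca²⁺ it cannot clear.  `pmrkit` turns the time-lapse recordings
of these experiments into numbers:

| assay | readout |
| --- | --- |
| FM-dye laser injury | ΔF/F dye-entry kinetics; repaired/failed call per cell; fraction repaired per group |
| Fluo-4 Ca²⁺ imaging | peak ΔF/F, time for the peak to fall by 75 % (clearance-75 = τ·ln 4 for an exponential decay), area under the curve |
| ER morphology | fragmented fraction of the injury axis: length of the tubular→punctate ("bead-on-string") conversion from the injury point over the cell's longest axis |
| FRAP | mobile fraction and recovery τ from a y₀ + M·(1 − e^(−t/τ)) fit of the normalised recovery |
| dual-dextran bead injury | % failed = 100 · (green⁺red⁺ cells) / (green⁺ cells) |
| statistics | unpaired Student's t / Mann–Whitney (auto-selected), two-sided |

ΔF/F is computed as (F − F₀)/F₀ against a pre-injury baseline window.
Because no public dataset defines these assays, the package includes a
first-class synthetic-data module (`pmrkit.synth`) that generates every
assay's inputs with machine-readable ground truth; all quantification
stages are validated against it.  See `docs/methods.md` for the models,
defaults and design decisions.

## Worked example

Classify a small synthetic cohort — six healthy-like cells that reseal at
25–35 s and six patient-like cells that never plateau — and compare the
final dye loads:

```python
import pmrkit as pk

results, labels = [], []
for i in range(12):
    healthy = i < 6
    model = pk.InfluxModel(
        repair_time=25.0 + 5.0 * (i % 3) if healthy else None,
        noise_sd=2.0,
    )
    trace, _ = pk.generate_influx_trace(model, seed=i)
    dff = pk.to_delta_f_over_f(trace)
    results.append(pk.classify_repair(dff))
    labels.append("healthy" if healthy else "patient")

summary, timecourse = pk.cohort_repair_summary(results, labels)
print(summary.to_string(index=False))

final = [r.final_dff for r in results]
cmp = pk.compare_groups(final[:6], final[6:],
                        group_a="healthy", group_b="patient")
print(f"final dF/F: {cmp.test}, p = {cmp.p_value:.2e}")
```

prints

```
  group  n  n_repaired  fraction_repaired
healthy  6           6                1.0
patient  6           0                0.0
final dF/F: student_t, p = 1.55e-14
```

Every healthy cell is called repaired (its ΔF/F slope drops below
0.005 s⁻¹ within the 120 s horizon) and every patient cell failed; the
final ΔF/F dye load differs between groups (≈0.6 vs ≈3.4), and with both
samples passing the normality and equal-variance pre-checks the
auto-selection runs Student's t-test.

A command-line layer mirrors the library: `pmrkit synth | trace | repair |
calcium | erfrag | frap | bead | report` (see `pmrkit --help`).  Stacks
are multi-page TIFF; ROIs are a small documented JSON schema; all tabular
output is tidy CSV.

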