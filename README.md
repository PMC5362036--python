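# memloc

Single-cell quantification of **membrane versus cytosolic protein
localization** in fluorescence micrographs of rod-shaped bacteria, plus a
physics-based synthetic microscopy generator that provides ground-truthed
test and calibration data.

Many bacterial regulators signal by changing subcellular address — for
example, c-di-GMP effector proteins in *Caulobacter crescentus* that sit
on the inner membrane at low second-messenger levels and disperse into the
cytosol at high levels. Deciding, cell by cell, whether a fluorescent
fusion is membrane-associated or cytosolic is therefore a routine but
error-prone measurement. `memloc` makes it reproducible for anyone with a
fluorescence image and cell outlines (from any segmenter that can emit
closed polygons).

## The statistic

For each cell outline, the pixel mask is partitioned into the **membrane
ring** — the first *k* intracellular pixels flanking the outline
(Chebyshev distance ≤ k to the exterior; default k = 4) — and the
remaining **cytosolic interior**. The per-cell score is

```
ratio_membrane_cytosol = mean(I[ring]) / mean(I[interior])
```

A cell is classified *membrane-associated* when the ratio exceeds a
threshold τ (default 0.7) and *cytosolic* at or below it. Because a
cytosolic label projects the chord depth of the cell body (dim at the
edge) while a membrane label projects an edge-peaked shell path, the two
states separate cleanly around τ = 0.7; the threshold is calibrated with
two control populations (a soluble fluorophore and a lipophilic membrane
dye), both of which classify 100% correctly at the defaults. Time-lapse
traces of the ratio are scanned for *dispersal episodes* — runs of ≥ 2
consecutive cytosolic frames — reporting onset time and duration.

See `docs/methods.md` for the model, parameter table and limitations.

## Worked example

```python
from memloc import (SimulationConfig, CompartmentParams, simulate_cohort,
                    measure_image, summarize)

cfg = SimulationConfig(canvas_shape=(600, 600), n_cells=30,
                       population_membrane_prob=0.6, seed=11)
cohort = simulate_cohort(cfg)                 # image + ground-truth outlines
params = CompartmentParams(background_mode="constant",
                           background_value=cfg.background)
cells = measure_image(cohort.image, cohort.outlines[0], params,
                      cfg.pixel_size_um)
for m in cells[:3]:
    print(m.cell_id, round(m.length_um, 3), round(m.ratio, 3), m.label)
print(summarize(cells, threshold=0.7).to_dict())
```

prints

```
cell_0000 2.234 0.621 cytosolic
cell_0001 2.237 0.623 cytosolic
cell_0002 3.288 1.136 membrane
{'n_total': 30, 'n_membrane': 22, 'n_cytosolic': 8, 'n_excluded': 0,
 'fraction_membrane': 0.7333333333333333, 'threshold': 0.7}
```

Each line is one cell: its length in µm (Feret diameter of the outline ×
pixel size), its membrane/cytosol intensity ratio, and its class. The
summary says 22 of 30 analyzed cells (73.3%) are membrane-associated —
here exactly the simulated ground-truth fraction, since no cell was
flagged and the classes separate fully at the defaults.

## Command line

```sh
memloc simulate --config sim.yaml --out cohort/ --seed 7
memloc segment  --image cohort/image.tif --out outlines.json
memloc quantify --image cohort/image.tif --outlines cohort/outlines.json \
                --out cells.csv --ring 4 --threshold 0.7 --background constant:100
memloc report   --cells cells.csv --out summary.json
memloc calibrate --cyto cyto_cells.csv --mem mem_cells.csv --out calib.json
memloc run --config run.yaml        # simulate -> quantify -> report, one seed
```

Images are grayscale TIFF (multi-page for time lapse); outlines are a
small JSON schema of closed polygons; per-cell results are CSV with
columns `cell_id,frame,length_um,mean_membrane,mean_cytosol,ratio,class,flags`.

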