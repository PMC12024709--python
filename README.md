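# phantomfield

Mapping tDCS-induced electric fields in a spherical phantom head.

Transcranial direct current stimulation (tDCS) injects 1–2 mA through
scalp pads, and the field it creates inside the head is hard to predict.
One inexpensive way to characterise it is a physical phantom: a
head-sized conducting sphere carrying the 21 electrodes of the 10–20
system, into which a recording electrode is inserted radially at each
position to read the voltage difference ΔV against a reference riding on
a stimulating pad, at four depths — the surface (Z0), one third (Z33)
and two thirds (Z66) of the diameter, and the full diameter (Z100).

`phantomfield` turns such recordings into field maps. It is written for
neurostimulation researchers who have (or want to simulate) phantom
depth-voltage tables and need reproducible geometry, field estimates and
topographic plots. It provides:

* **Geometry** — the spherical 10–20 montage, projection of each
  electrode to the four nested recording spheres (radius *R* for
  Z0/Z100, *R*/3 for Z33/Z66), translation to the recording reference,
  and the distance |E − R| for every site.
* **Field pipeline** — the estimate **EF = ΔV / |E − R|** (mV/mm),
  neighbour-mean imputation of the sites hidden under stimulating pads,
  and per-depth summaries.
* **Simulator** — a quasi-static point-source forward model
  (V = Σ I_k / 4πσr_k) with presets for three standard montages
  (monopolar motor-cortex, fronto-occipital, latero-lateral), so the
  full pipeline runs and is tested without hardware.
* **Maps** — ΔV/EF on orthographic disc views (anterior, posterior,
  superior), warm colours high, inverse-distance-weighted shading.

A measured monopolar-montage recording set (240.80 mm phantom,
reference C3, pads over C3 and C4, 2 mA) is bundled with the package.

## Worked example

```python
import phantomfield as pf

recordings = pf.load_condition_a_fixture()          # bundled measured set
layout = pf.MontageLayout.standard(recordings.metadata.diameter_mm)
table = pf.build_field_table(recordings, layout)

print(table[table.electrode.isin(["Cz", "C3"])].round(2).to_string(index=False))
```

```text
electrode depth  x_mm  y_mm    z_mm  distance_mm  delta_v_mV  imputed  ef_mV_per_mm
       C3    Z0  0.00   0.0    0.00         0.00         NaN  ef_mean        381.82
       C3   Z33 47.18  -0.0  -64.94        80.27     35040.0  dv_mean        436.54
       C3   Z66 47.18  -0.0 -129.87       138.18     38080.0  dv_mean        275.59
       C3  Z100  0.00  -0.0 -194.81       194.81     42800.0  dv_mean        219.70
       Cz    Z0 70.77   0.0   22.99        74.41     28000.0 measured        376.29
       Cz   Z33 70.77  -0.0  -57.27        91.04     33200.0 measured        364.67
       Cz   Z66 70.77  -0.0 -137.54       154.68     43600.0 measured        281.88
       Cz  Z100 70.77  -0.0 -217.81       229.01     52000.0 measured        227.06
```

Reading this: Cz sits 74.41 mm from the C3 reference on the surface and
229.01 mm at full depth; its measured ΔV rises with depth while EF
(ΔV/distance) falls from 376 to 227 mV/mm. C3 is a pad site — its ΔV at
Z33–Z100 is the mean of its five neighbours (flag `dv_mean`), and its
surface site, at distance 0, gets the neighbours' mean surface EF
instead (flag `ef_mean`).

```python
summary = pf.summarize(table)
print(summary[(summary.depth == "Z0") & (summary.quantity == "delta_v_mV")]
      .round(1).to_string(index=False))
```

```text
depth   quantity    min argmin     max argmax    mean  left_mean  right_mean
   Z0 delta_v_mV 8080.0    Fpz 39600.0    Fp2 27250.0    29342.9     28040.0
```

The surface maximum (39 600 mV at Fp2) and minimum (8080 mV at Fpz) and
the hemispheric means come straight from the recording set.

The same pipeline runs from a shell:

```sh
phantomfield montage  --diameter-mm 240.80 --reference C3 --out grid.csv
phantomfield simulate --condition B --seed 7 --out sim.csv --meta-out sim.json
phantomfield efield   --recordings sim.csv --meta sim.json --out field.csv
phantomfield plot     --table field.csv --quantity ef --view superior --out map.png
phantomfield run      --condition A --seed 1 --plots --out-dir out/
```

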