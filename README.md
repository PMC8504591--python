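# slitfield

Measure how far a radiographic X-ray field extends **beyond** the image
detector, using only the system's own detector: a thin metal foil above the
detector emits K-alpha fluorescence where the beam irradiates it, and a slit
camera (the linear analogue of a pinhole camera) projects that emission back
onto the detector, making the invisible field boundary visible inside the
image.

The package is aimed at medical physicists doing collimation and
light-field/X-ray-field congruence QC on mammography and digital breast
tomosynthesis (DBT) systems, where regulations bound the field overhang
(2% of the source-to-image distance under MQSA/CFR; 5 mm under the European
guidelines) and where no established method measures the field in individual
DBT projections.

## The measurement

With the origin at the nearest detector edge and distances in mm, the field
boundary `X_FOV` (negative = beyond the detector) follows from similar
triangles through the slit:

```
X_FOV = [ x_edge + (y_foil/y_slit) (x_slit - x_edge)
          - (y_foil/y_source) x_source ] / (1 - y_foil/y_source)
```

where `x_edge` is the position where the fluorescence signal inside the
camera vanishes, `x_slit` the slit position read off the image, and
`y_slit`, `y_foil`, `y_source` (= SID) the component heights.  `x_edge` is
located by integrating a wide region of interest into a line profile,
smoothing with a 5-pixel mean filter, normalizing to the minimum intensity
inside the camera shadow, and extrapolating an ordinary least-squares line
fitted to the steep intensity fall down to the normalization baseline of 1.

The foil is chosen by an analytic depth-resolved signal model: for primary
energy E, foil attenuation `mu_p(E)`, K-shell photoelectric coefficient
`mu_K(E)`, K-alpha escape coefficient `mu_f` and total radiative K-alpha
yield `w_Ka`, the fluorescence reaching the camera from a foil of thickness
t is

```
S(t) = sum_E  phi(E) w_Ka E_Ka  mu_K(E) [exp(-mu_f t) - exp(-mu_p(E) t)]
              / (mu_p(E) - mu_f)  x  T_path
```

which captures the trade-off between absorbing the primary beam (thick
foils) and letting the fluorescence escape (thin foils).  Attenuation
coefficients ship as packaged tables (1-150 keV, log-log interpolation,
absorption edges preserved); spectra come from a filtered Kramers generator
or from two-column text files.

## Worked example

Render a synthetic chest-wall acquisition with a known boundary 7.68 mm
beyond the detector, then measure it back:

```python
import slitfield as sf

chest = sf.SlitGeometry(y_foil=63.5, y_slit=31.35, x_slit=33.0,
                        y_source=661.2, x_source=23.6, side="chest_wall")
cfg = sf.ScenarioConfig(geom=chest, x_fov_true=-7.68, seed=42)
image, audit = sf.render_scene(cfg)

result = sf.measure_field(image, chest, view="Mammo., 24x29")
print(result.measurement.x_edge, result.measurement.x_fov)
# 69.74309767735963 -7.685280994705455
```

The measured edge (69.743 mm) sits 5 µm from the rendered truth
(`audit.x_edge_true` = 69.738 mm), and the boundary formula converts it to
-7.685 mm: the field extends 7.69 mm beyond the chest-wall edge, recovering
the configured truth to better than 0.01 mm at clinical noise levels
(fit R² = 0.9999).  A compliance report wraps the verdicts:

```python
print(sf.build_report([result.measurement], sid_mm=661.2, ruleset="mqsa").to_text())
```

```
slitfield compliance report
Distances in mm; negative = X-ray field boundary beyond the detector edge.
SID = 661.2 mm, ruleset = MQSA, reference view = (none)

view                  side          x_edge   x_fov    diff
Mammo., 24x29         chest_wall      69.7    -7.7       -

MQSA chest_wall: overhang 7.7 mm vs limit 13.2 mm -> PASS
```

The overhang (7.7 mm) is under the MQSA limit of 2% x 661.2 = 13.2 mm and
the beam does reach past the chest-wall edge, so the view passes; under the
EU 5 mm rule the same measurement fails.

The same pipeline is available from the shell:

```
slitfield measure --images view.dcm --geometry geom.yaml --ruleset mqsa --out report.json
slitfield simulate --scenario scenario.yaml --seed 42 --out scene.tif
slitfield optimize-foil --elements Mo,Zr --kvp 39 --filter Ag:60um \
    --grid 5,10,25,50,100,250 --out curves.csv
```

The last command prints the modelled optima for a 39 kVp W-anode beam with
60 µm Ag filtration:

```
Mo: best thickness 25 um
Zr: best thickness 50 um
```

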