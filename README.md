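# cellcom

Center-of-mass analysis of 3D receptor-accumulation distributions in
single micropatterned cells.

Transmembrane receptors such as the BMP receptor subunits BMPRIb and
BMPRII form puncta ("accumulations") whose whole-cell spatial
organization reflects complex assembly, signaling mode, and cell
polarization. Micropatterned substrates (50 µm circle or crossbow
islands) fix single cells to a reproducible geometry, which makes their
receptor distributions comparable across cells and conditions. `cellcom`
consumes the object tables an upstream segmentation tool (e.g., Ilastik)
exports — per accumulation: 3D centroid, volume in voxels, mean
intensity — and analyzes them with intensity-weighted center-of-mass
statistics. It is aimed at quantitative microscopists comparing receptor
localization between shapes, treatments, or receptor types.

## The model

Each accumulation *i* gets a **virtual mass** in place of a physical
mass,

```
v_i = (I_i / I_g) · n_i
```

with `I_i` its mean intensity, `I_g` the image's global mean intensity,
and `n_i` its volume in voxels. The distribution's center of mass is

```
r = Σ v_i · r_i / Σ v_i  =  Σ I_i n_i r_i / Σ I_i n_i     (I_g cancels)
```

Two per-cell metrics, in µm after per-axis voxel-size conversion
(default voxel volume 0.0037 µm³):

- **reference metric** — Euclidean distance `|r_receptors − r_nucleus|`
  between the receptor distribution COM and the nucleus COM; detects a
  *shift* of the distribution.
- **spread metric** — mean distance of each accumulation to the
  distribution COM; detects *dispersion*.

Groups of cells are compared metric-wise with a two-sided Mann–Whitney U
test (`*` p<0.05 … `****` p<0.0001).

Detectability is validated by simulation: pooled experimental values of
each variable (x, y, z, volume, intensity) are resampled by inverse
transform sampling after an optional perturbation — a shift
`x → x + n·x̄` or a spread `x → x + n·x̄·(x_rnd − x̄)/b` — and the
simulated groups are compared back to the source. Simulation fidelity is
scored with the cosine distance, percentage histogram overlap, and
Hellinger distance. Pixel-level colocalization of two channels is scored
with Pearson's correlation and Li's intensity correlation quotient.

## Worked example

Generate a synthetic study group (36 circle-pattern cells, the built-in
fixture generator), compute both metrics, and run the simulation study:

```sh
cellcom fixtures --kind cells --n-cells 36 --seed 42 -o fx
cellcom metrics fx/circle_cells.csv -o metrics.csv
cellcom simstudy fx/circle_cells.csv --reps 5 --seed 7 -o study
```

The metric table summarizes as (mean ± sd over 36 cells):

```
reference   10.81 ± 1.15 µm
spread       9.26 ± 0.39 µm
```

i.e., the receptor cloud's COM sits ~10.8 µm from the nucleus COM (the
generator plants a 12 µm offset, pulled inward by the footprint
boundary), and accumulations lie on average ~9.3 µm from their COM.
The simulation study prints, per perturbation mode and magnitude `n`,
the median Mann–Whitney p over replicates:

```
  mode   n    metric     median_p  significant stars
 shift 0.0 reference 6.004897e-01        False     -
 shift 0.2 reference 3.046341e-13         True  ****
 shift 1.0 reference 3.046341e-13         True  ****
 shift 2.0 reference 3.046341e-13         True  ****
spread 0.2 reference 6.810186e-01        False     -
spread 2.0 reference 7.397099e-01        False     -
spread 0.0    spread 7.912685e-01        False     -
spread 0.2    spread 4.242830e-05         True  ****
spread 2.0    spread 3.046341e-13         True  ****
```

Read: the reference metric flags every shift with `n ≥ 0.2` but is blind
to pure spreading; the spread metric flags every spread with `n ≥ 0.2`.
An unperturbed simulation (`n = 0`) is indistinguishable from its
source, as it should be.

For experimental data, point `cellcom compare study.yaml` at your own
object tables with a YAML config mapping the export's column names and
declaring which groups (shape / treatment / receptor) to compare.

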