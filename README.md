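# choroidmap

Geographic choroidal-thickness mapping and simultaneous axial-length
measurement from 3D spectral-domain OCT volumes, with a synthetic scan
generator so that every stage of the pipeline is verifiable against
known ground truth.

## The problem

The choroid — the vascular bed between the retina and the sclera — thins
progressively with myopia while the eye elongates. Quantifying both
requires (i) a geographic map of choroidal thickness (CT) around the
macula, summarised on a fovea-centred grid of concentric rings (1, 5,
10 mm diameters) split into quadrant sectors (Fovea; nasal / superior /
temporal / inferior inner and outer macula: NIM, SIM, TIM, IIM, NOM,
SOM, TOM, IOM), and (ii) the intraocular length (IOL, anterior cornea to
RPE along the optical axis). This package implements that measurement
chain for long-wavelength SD-OCT raster scans (512 A-lines × 256 B-scans
over ~10 × 5 mm; scaled to 256 × 64 by default) and is aimed at
researchers building or validating ocular-biometry pipelines.

## The measurements

**Choroidal thickness.** After cross-correlation removal of inter-B-scan
axial motion, three boundaries are delineated per B-scan by a
dynamic-programming minimum-cost path through the signed vertical
gradient (subject to an inter-column smoothness bound, with subpixel
parabolic refinement): the inner limiting membrane (ILM), the outer edge
of the bright RPE band, and the choroid–sclera interface (CSI). CT at
each (x, y) is the Euclidean distance from the RPE surface to the CSI
**along the local RPE normal**, in geometric µm (air pitch ÷ tissue
index). The fovea is located at the deepest point of the smoothed ILM
pit; sector means and a 1-mm-step nasal–temporal ring profile (±5 mm)
are computed on the laterality-normalised grid (nasal always points
toward the optic disc). Eyes whose two independent segmentation analyses
disagree by more than 15% are excluded.

**Axial length.** A dual-reference-arm geometry places the corneal
reflection inside the same A-scan window as the retina. With mirror
offset ΔL_ref and measured fovea→cornea peak separation d,

    IOL = (ΔL_ref − d) / n,      ΔL_ref = 35 mm,  n = 1.3375.

**Cohort statistics.** Eyes are grouped by refractive error (low |D| ≤ 3,
moderate 3 < |D| < 6, high |D| ≥ 6), tabulated as mean ± STD, compared
with the pooled-variance Student's t-test, and per-diopter reduction
rates are computed over the 3 D span between adjacent group midpoints.

**Synthetic eyes.** The generator draws per-sector CT targets and axial
lengths from configurable group distributions (shipped defaults in
`src/choroidmap/data/cohort_defaults.yaml`), builds a smooth CT field
whose sector means equal the drawn targets exactly, and renders volumes
with layered reflectivity, a foveal pit, unit-mean exponential speckle,
6 dB/3 mm sensitivity roll-off and integer per-B-scan axial motion — so
parameter recovery through the full pipeline is a meaningful test.

## Worked example

```bash
python examples/01_axial_length.py
```

```
true axial length      : 24.605 mm
peak separation d      : 2.090 mm
measured axial length  : 24.605 mm
worked example         : IOL(d=2.236) = 24.496 mm
```

The composite A-scan of a synthetic low-myopia eye is inverted to its
true axial length within half an axial sample, and the closed-form
worked example (d = 2.236 mm) gives 24.496 mm. A full single-eye
thickness map:

```bash
python examples/02_single_eye_thickness_map.py
```

```
sector  measured um  truth um
Fovea         227.4     225.4
NIM           218.1     218.3
...
ring profile (nasal -5 mm ... temporal +5 mm), um:
[217.1 214.  214.6 218.1 222.3 227.4 255.5 278.6 261.2 256.8 262.6]
```

Measured sector means track the generator's drawn ground truth to a few
µm. `examples/03–05` demonstrate motion correction, a small three-group
cohort study with t-tests and reduction rates, and the colour-mapped
fundus overlay.

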