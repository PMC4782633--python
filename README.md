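# septumfem

Thin-plate finite-element modal analysis of the cartilaginous nasal septum,
with automatic classification of each vibration mode as a clinically
recognised deviation pattern — septal tilt (type I), C-shape (type II) or
S-shape (type III) — and mapping of von Mises stress hotspots to the
anatomical landmarks where septal fracture and dislocation occur.

## Who this is for

Surgeons and biomechanics researchers studying why a traumatised septum
settles into a small family of deviated shapes, and which regions (the
bony-cartilaginous junction, the anterior nasal spine, the vomer-ethmoid
junction, the vomerine groove) concentrate stress and therefore matter for
septoplasty planning. Septal cartilage is invisible on CT/MRI, so a
computational model of its deformation repertoire is the practical route to
preoperative insight.

## The model

The quadrangular cartilage is idealized as a flat plate of uniform
thickness t = 2 mm in the sagittal plane (x: posterior→anterior, y:
inferior→superior), homogeneous and linearly elastic with E = 5 MPa,
ν = 0.32, ρ = 2000 kg/m³. Its bony interfaces — nasal bone (14 mm overlap),
ethmoid, vomer, hard palate — are rigidly fixed; the dorsal and caudal
edges are free. The nasal tip (anterior septal angle) is either free or
supported by a grounded spring of k = 20 kN/m along each orthogonal axis,
representing the elastic recoil of the lower lateral cartilages via the
cantilever model k = 3EI/L³ = E·w·h³/(4L³).

Two in-plane loading conditions emulate a frontal blow: a couple of 1 N
forces at the nodes flanking the tip, and a 2000 Pa pressure on the dorsal
and caudal edges (carried as an inward edge traction p·t). A static
membrane solve recovers the preload stress field; a linear-perturbation
frequency step then extracts the first N = 10 natural modes from the two
decoupled families,

* membrane (in-plane): constant-strain triangles, `Km φ = ω² Mm φ`,
* bending (out-of-plane): discrete-Kirchhoff triangles (DKT),
  `(Kb + Kg) φ = ω² Mb φ`,

where `Kg = ∫ t (∇w)ᵀ σ (∇w) dA` is the geometric (initial-stress)
stiffness assembled from the membrane stress σ. At the reference load
magnitudes the stress-stiffening term is at the buckling scale of this
soft plate, so the default frequency step is linear about the unstressed
state (see `docs/methods.md`); `Kg` is fully implemented and enabled with
`include_preload: true`.

Each merged mode is classified by the number of connected same-sign lobes
of its transverse field w: one lobe = tilt (I), two = C-shape (II, with
anteroposterior/cephalocaudal orientation from the nodal-line principal
axis), three or more = S-shape (III); modes with out-of-plane modal-mass
fraction below τ = 0.1 vibrate in-plane and carry no deviation shape ("–").

## Worked example

```bash
septumfem classify --tip spring --load couple
```

prints the per-mode table of the default spring-supported model
(322 nodes, 2 mm mesh):

```
 mode  frequency_hz   family type  type_numeric  sign_regions nodal_line_orientation     top_hotspot
    1     80.169883  bending    I             1             1                   none     BC_junction
    2    160.441004  bending   II             2             2          cephalocaudal             ANS
    3    192.882184  bending   II             2             2        anteroposterior vomerine_groove
    4    283.579088  bending  III             3             3        anteroposterior             VEJ
    5    319.530222  bending  III             3             3        anteroposterior     BC_junction
    6    413.996270  bending  III             3             4        anteroposterior             ANS
    7    447.664448 membrane    -             0            -1                   none             ANS
    8    505.301843  bending  III             3             4        anteroposterior vomerine_groove
    9    532.981003  bending  III             3             4        anteroposterior             ANS
   10    584.787954  bending  III             3             5        anteroposterior     BC_junction
```

(the full CLI table also prints each mode's complete landmark ranking)

Reading: the fundamental mode (80 Hz) tilts the whole septum in one piece
(type I) and loads the bony-cartilaginous junction; the next modes crumple
it into C-shapes and then S-shapes — severity increases with mode number,
i.e. with the energy required — while mode 7 is an in-plane membrane mode
with no deviation shape. The same type column is obtained under the edge
pressure load, and stress hotspots concentrate at the four surgical
landmarks. Hotspot stresses are modal (arbitrary amplitude): only their
locations and rankings are meaningful, never absolute values.

The numbered drivers under `analysis/` retrace the full study:

| script | what it does |
|---|---|
| `01_idealized_model.py` | builds and meshes the idealized outline |
| `02_modal_taxonomy.py` | 4 runs (tip condition × load case), type table |
| `03_stress_hotspots.py` | landmark hotspot ranking per mode |
| `04_plate_validation.py` | solver vs Kirchhoff plate closed form |
| `05_patient_like_models.py` | perturbed "patient-like" surrogates |

Each writes its tables under `results/`.

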