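# Methods

## Scope and model

`septumfem` models the quadrangular (septal) cartilage as a flat Kirchhoff
plate in the sagittal midplane and asks which deformation shapes it can
adopt and where they concentrate stress. The driving observation is
clinical: deviated septa overwhelmingly present as a tilt, a C-shape or an
S-shape, and these are exactly the low-order vibration modes of a plate
held rigidly along its bony margins. Modal analysis therefore serves as a
force-free surrogate for increasing trauma: lower modes need less energy,
so the tilt is the most probable deviation, followed by the C- and then
the S-shape.

Cartilage is nonhomogeneous, anisotropic and viscoelastic; for the small
strains relevant here it is reduced to a homogeneous, isotropic, linearly
elastic solid. Defaults (configurable in `RunConfig`):

| parameter | default | meaning |
|---|---|---|
| E | 5 MPa | Young's modulus (midrange of reported tensile moduli) |
| ν | 0.32 | Poisson ratio |
| ρ | 2000 kg/m³ | density (hydrated cartilage estimate) |
| t | 2 mm | uniform plate thickness |
| k | 20 kN/m | grounded tip-spring stiffness per axis |
| F | 1 N | magnitude of each tip-couple force |
| p | 2000 Pa | free-edge pressure |
| overlap | 14 mm | nasal-bone overlap (normal range 3–15 mm) |
| N | 10 | number of extracted modes |
| h | 2 mm | target mesh edge length |
| τ | 0.1 | in-plane ("dash") threshold on the transverse modal-mass fraction |
| ε | 0.02 | nodal-band threshold relative to max \|w\| |

## Geometry

The midplane outline is a hexagon with labeled edges: hard palate
(inferior, fixed), caudal free edge rising to the anterior septal angle
(ASA, taken as the nasal tip), dorsal free edge, nasal-bone overlap
segment (fixed, 14 mm), and a vertical posterior edge split into ethmoid
(upper) and vomer (lower) fixed segments. Only the overlap length is an
anatomically reported constant; the other dimensions are documented
surrogates for an adult septum, frozen at inferior 38 mm, posterior 26 mm,
caudal 24 mm, caudal rake 20° and ethmoid fraction 0.55. This default was
fixed once against the reference per-mode type column of the
spring-supported model (frozen in the acceptance tests) and is part of
the package contract: changing any
dimension requires re-running the regression table in
`analysis/02_modal_taxonomy.py`. The mode-type sequence is insensitive to
the mesh (identical at h = 2, 1.5 and 1.25 mm) and to the load case.

Meshing places boundary nodes exactly on the outline (so the triangulation
tiles the polygon; total area matches the shoelace area to 1e-9 relative),
fills the interior with a staggered point lattice kept 0.71 h clear of the
boundary, Delaunay-triangulates, and keeps triangles whose centroid lies
inside the polygon. Two repair passes make this robust for perturbed
outlines: boundary edges missing from the triangulation are midpoint-split
and retried, and zero-area slivers from collinear boundary triples are
removed by a diagonal flip (or dropped when they are zero-width boundary
flaps). Landmark regions collect elements within a radius (default 3 mm)
of the ANS, the bony-cartilaginous junction (dorsal/nasal-bone corner) and
the vomer-ethmoid junction (posterior split point); the vomerine groove
region spans the whole inferior fixed edge.

## Elements and operators

Membrane: constant-strain triangles (plane stress), consistent mass.
Bending: discrete-Kirchhoff triangles (DKT) constructed from the quadratic
rotation interpolation with Kirchhoff constraints imposed at edge
midpoints (normal rotation linear along each edge; tangential rotation
matching the cubic Hermite edge deflection). The implementation passes the
constant-curvature patch test to machine precision and carries exactly
three rigid-body modes per element. Bending mass uses the linear
interpolant for w plus rotary inertia ρt³/12 on the rotations; this makes
the transverse modal-mass fraction of a bending mode slightly below 1
(rotary share ~ t²/L²), which is irrelevant to the in-plane screen at
τ = 0.1. For a flat, midplane-symmetric plate the membrane and bending
families decouple exactly, so they are assembled and solved as separate
operators and merged by frequency afterwards — this is exact, not an
approximation, for this geometry.

All DOFs on bony-interface nodes are eliminated (rigid interfaces: bone is
orders of magnitude stiffer than cartilage). The tip spring is grounded at
the ASA node and adds k to the u, v (membrane) and w (bending) diagonal.
A commonly quoted form of the tip-spring formula is dimensionally
inconsistent (it reads "(width×height)³"); the implementation uses the standard cantilever
stiffness k = 3EI/L³ = E·w·h³/(4L³), which reproduces the intended 20 kN/m
scale and evaluates to 625 N/m for a 4 × 10 × 20 mm beam at E = 5 MPa.

## Loading, preload and its deliberate exclusion from the default eigensolve

Both loading conditions are in-plane (only in-plane preload shifts the
bending modes of a flat plate). The couple is two oblique forces of
magnitude F at the two nodes flanking the tip, components (−F, −F)/√2 and
(−F, +F)/√2 — simultaneously a net posterior push and a couple; the exact
arrangement of the original loading is not reported, so this surrogate is
exposed in config. The pressure case integrates an inward traction p·t
consistently over the dorsal and caudal edges.

The geometric stiffness Kg (initial-stress integral over the linear
interpolant of w, entering only the transverse DOFs) is linear in the
stress state and validated against the closed-form plate-buckling
interaction: a uniaxial membrane stress at 30% of the critical load lowers
the fundamental frequency-squared by 30.0% (obtained 0.69992 vs 0.7).

At the reference magnitudes, however, the preload is *not* a small
perturbation for this plate: D ≈ 3.7·10⁻³ N·m puts the buckling scale of
the structure near 1 N, so the tip couple drives the free-tip model past
its first buckling load (the solver reports this honestly as a
`BuckledError`) and shifts the spring model's fundamental by tens of
percent. A reference per-mode table that is *identical* across both load
cases is only consistent with a frequency step carried out about the
unstressed state — the behaviour of a geometrically linear static step
followed by a linear-perturbation frequency step. The default pipeline
therefore solves the eigenproblem without Kg (`include_preload: false`);
the preload static solve still runs (its stress field is exported), and
enabling `include_preload` reproduces the full prestressed analysis, which
for the 2000 Pa pressure case changes no classification. This is the one
place the package deviates from a naive reading of the procedure, and it
is a deliberate modelling choice, not a solver limitation.

## Eigensolve

Each family's constrained generalized eigenproblem is solved densely
(LAPACK `eigh` with an index subset) below 2500 free DOFs — fully
deterministic — and by shift-invert Lanczos with a fixed start vector
above. Eigenpairs are checked to a 1e-8 relative residual,
mass-normalized, sign-fixed (largest component positive), and the two
families are merged into the globally lowest N modes with a stable
bending-first tie-break. A non-positive eigenvalue raises `BuckledError`.
The solver was verified against: the 1-DOF closed form √(k/m)/2π, the
fixed-free axial bar family (2j−1)√(E/ρ)/4L (within 2%), and the
simply-supported Kirchhoff plate f_mn = (π/2)(m²/a²+n²/b²)√(D/ρt) — first
five modes within 1% at a 1.2 mm mesh, f₁₁ ≈ 106.4 Hz for the 30 mm square
at the cartilage constants.

## Classification

A mode with transverse modal-mass fraction below τ vibrates in-plane and
is reported as "–". Otherwise the transverse field w is thresholded at
ε·max|w|; connected components of same-sign suprathreshold nodes on the
mesh adjacency graph are counted (components peaking below 10% of max|w|
are ignored as numerical debris; the floor is configurable). One lobe maps
to type I, two to type II, three to type III; counts above three are
folded into type III with a warning because the clinical taxonomy stops at
the S-shape. Orientation comes from the principal axis of the nodal line,
located robustly as the set of zero crossings of w along mesh edges with a
strict sign change (fixed edges hold w = 0 exactly and therefore never
pollute the fit): a nodal line within 30° of the x-axis is
"anteroposterior", within 30° of the y-axis "cephalocaudal", otherwise
"mixed". Classification is invariant under mode sign flip and amplitude
scaling by construction and by test.

Hotspots: the modal von Mises field is evaluated per element — bending
surface stress (t/2)·C·κ at z = t/2 from the DKT curvatures at the
centroid, or CST membrane stress for in-plane modes — and each landmark
region is ranked by its peak value. Modal amplitudes are arbitrary, so
every output carries the caveat that only locations and rankings are
meaningful; no absolute stresses are reported anywhere.

## Synthetic patient-like data

The CT-derived patient geometry behind the original study is not
deposited. The surrogate generator perturbs the idealized boundary with
low-order harmonic displacement along vertex normals (amplitude a fraction
of the mean outline radius, default 5%, retried with damping if the
polygon self-intersects) and assigns a smooth harmonic per-element
thickness field with exact 2 mm area-weighted mean and bounded variation
(default ±25%). A single seeded generator drives both, so runs are
bit-reproducible. This emulates smooth anatomical variation and thickness
inhomogeneity; it does not emulate population morphometrics, septal
curvature out of plane, or real CT segmentation noise — passing tests on
surrogates therefore show robustness of the pipeline to smooth geometric
variation, not validation against real anatomy. Across seeds, surrogate
models stay within the four-label taxonomy and agree with the idealized
type column on most modes (9.4/10 mean over the first five seeds).

## Numerical choices and degenerate inputs

0-based node/element indexing; internal SI units (m, Pa, kg) with mm/MPa
accepted at the config boundary. Zero-area elements raise immediately;
meshes failing boundary conformity after six refinement rounds raise a
`MeshingError` naming the offending region. Membrane statics use sparse LU
with a 1e-10 residual guard. Ties in the merged mode list break
bending-first, then input order. The dash test is binary in practice
(fractions are 0 or >0.95); τ and ε only matter for strongly perturbed
geometries. Problem sizes were chosen for interactive use: the default
model (322 nodes, ~1000 bending DOFs) solves in about a second, and the
full acceptance sweep in well under a minute.

## Known limitations

Flat midplane (no intrinsic septal curvature or out-of-plane warp); no
Mindlin shear, anisotropy or viscoelasticity; no bony-vault compliance
(interfaces rigid); fracture is inferred from stress-line locations, not
simulated; the tip spring is grounded at a single node rather than
connecting the paired tip cartilages; and the idealized dimensions beyond
the 14 mm overlap are surrogates, so per-mode agreement with any specific
anatomy should be assessed via the regression table, not assumed.
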