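# Methods

## Input model

The unit of input is a string that is either a SMILES notation or a
trivial name. Name resolution is a case-insensitive lookup in a bundled
dictionary of ~70 molecules common in introductory chemistry; anything
not found is treated as SMILES. This keeps the tool fully offline — no
database round-trips — at the cost of only covering textbook names.

Batches come from a comma-separated list (tokens trimmed, blank tokens
rejected) or from a CSV file (UTF-8, first column, optional header row).
Order is always preserved and duplicates are rendered as given. A batch
aborts on the first invalid entry by default, because a silently
incomplete teaching set is worse than a loud failure; `--skip-invalid`
opts into skip-and-warn.

## Molecular graphs and hydrogens

Parsing, kekulization, and hydrogenation are delegated to RDKit. Graphs
are exposed as plain atom/bond lists; bond orders after kekulization are
only `single`/`double`/`triple`, which is what the mesh builders can
draw as parallel sticks. Hydrogens are appended after the heavy atoms so
heavy-atom indices are stable, and hydrogenation is idempotent.
Disconnected SMILES (dot notation) is accepted and embedded jointly as
one model. Stereo descriptors are passed through to the embedder but not
rendered as wedges.

## Conformer embedding

Coordinates come from ETKDGv3 distance-geometry embedding with an
explicit `randomSeed`, which makes an embedding a pure function of
(molecule, seed): identical inputs give bit-identical coordinates across
processes, and different seeds give different conformations — the tool's
deliberate "different orientation each time" behavior, surfaced on the
CLI as `--seed N` (default 0) vs `--random`. The centroid is translated
to the origin. Seeds are kept below 2³¹ because the embedder takes a
signed 32-bit seed.

Each embedding is validated against two geometric invariants: bonded
atom pairs must be 0.7–2.2 Å apart and non-bonded pairs must be > 0.5 Å
apart. On failure (or if the embedder itself fails), up to 10 fallback
seeds deterministically derived from the requested seed are tried before
an error is raised. The 2.2 Å bonded ceiling is tuned to organic
teaching molecules; bonds between two heavy third-row-plus elements
(e.g. Si–Sn, ~2.6 Å) would be rejected, a known limitation.

## Representations

All three representations place atom spheres at the same conformer
coordinates, so switching styles never moves a molecule — this is what
makes the side-by-side multi-representation scene line up, and what
"consistent batch style" means at the mesh level.

| parameter | building kit | ball-and-stick | space-filling |
|---|---|---|---|
| sphere radius | 0.45 × (2 × covalent) | 0.25 × vdW | 1.0 × vdW |
| stick radius | 0.12 Å, uniform gray | 0.10 Å, colored per half | — |

Colors follow the CPK convention, covalent radii the Cordero set, vdW
radii the Bondi set. Elements outside the table render in a conspicuous
pink fallback (covalent 0.75 Å, vdW 1.50 Å) with a logged warning —
never an error. Double/triple bonds are drawn as 2/3 parallel sticks
offset by 0.20 Å perpendicular to the bond, in the plane spanned by the
bond and its first non-collinear neighbor (so ring double bonds stay in
the ring plane), falling back to an arbitrary fixed perpendicular for
isolated linear fragments like CO₂. In ball-and-stick mode each stick is
split at the bond midpoint and each half colored by its nearer atom.

Spheres are UV spheres (`lon·(lat−1)+2` vertices, `2·lon·(lat−1)`
triangles), bonds capped cylinders (`2·seg+2` vertices, `4·seg`
triangles); defaults 12×24 and 16 segments, configurable down to
desk-scale (3×4, 4) for tests. Every primitive is watertight with
outward winding before merging; merged models may interpenetrate
(sphere/stick overlap is intentional, as in physical kits —
no boolean union is performed). Shading is flat-facet vertex-color;
no smooth normals are stored, which keeps the exporter surface minimal
and identical across formats.

## Scene layout

k models are placed in ⌈√k⌉ columns (left-to-right, then down) in the
XY plane; a grid rather than one row keeps 100-model scenes viewable.
Cells are sized from the largest model/label box in the batch plus a 2 Å
spacing, which guarantees pairwise-disjoint bounding boxes separated by
at least the spacing; the grid is recentered on the origin, and a single
model sits exactly at the origin. Labels are flat ribbon meshes from a
built-in stroke font (cap height 1 Å, 0.5 Å below the model box, facing
+Z); characters without stroke definitions render as box glyphs. Node
names always carry the input string, so viewers that ignore label
geometry still identify molecules. Layout is deterministic: equal input
gives bit-equal translations.

## Export formats

Everything is exported Y-up, right-handed, scaled by a single
meters-per-Ångström factor (default 0.02, chosen so a cyclohexane model
spans roughly 10 cm — tabletop size in AR).

* **glTF/GLB** via trimesh: one named mesh node per scene node,
  per-vertex colors, labels as separate `<name>__label` nodes so a
  node's counts equal its model's.
* **USDZ** written directly: the scene is authored as USDA text (one
  `Xform`/`Mesh` prim pair per node, `displayColor` primvar with vertex
  interpolation, `metersPerUnit` and `upAxis` stage metadata) and packed
  into the USDZ container — a zip whose entries are all stored
  (method 0) with file data aligned to 64-byte offsets, padding carried
  in each local header's extra field, led by the USD file. Timestamps
  are fixed to the DOS epoch so packages are byte-reproducible.
* **zip-of-USDZ**: one .usdz per molecule (filesystem-unsafe name
  characters replaced, duplicates suffixed `_2`, `_3`, …).
* **OBJ**: one named object per node, global 1-based indices, vertex
  colors as the widely supported `v x y z r g b` extension. **STL**:
  classic binary layout (80-byte header, uint32 triangle count, 50 bytes
  per triangle); STL carries no color by design.
* **PNG**: a built-in software rasterizer — perspective camera auto-fit
  to the scene's bounding sphere (azimuth 35°, elevation 25°, 45° FOV,
  1.15 fit margin by default), painter's-algorithm depth sort on
  triangle mean depth, flat Lambert shading from one fixed camera-space
  directional light, white background. Working coordinates are
  recentered on the scene and rounded to float32, which makes renders
  byte-deterministic and invariant under whole-scene translation.
  Back faces are shaded by |n·l|, so thin one-sided ribbons (labels)
  remain legible from either side.

## Synthetic fixtures

The fixture generator emits deterministic batches of chemically trivial
molecules — linear alkanes/alcohols with cycling chain lengths, and a
seeded `mixed` family drawn from a pool of small alkanes, alcohols,
ethers, carbonyls and rings. It deliberately contains no stereocenters,
charges, or exotic elements: capacity runs (100-model inline batches,
300-row CSV batches) measure pipeline robustness, not embedder corner
cases. Consequently, passing capacity tests says nothing about
macromolecules, organometallics, or pathological ring systems; single
worked examples and the element-fallback path cover breadth instead.

## Problem sizes and numerical choices

The capacity measurements run the full pipeline at default tessellation
on mixed-family batches of 25/50/100 (inline) and 75/150/300 (CSV)
molecules, stopping at the documented capacities of the two input modes;
each tier completes in seconds on one CPU. Degenerate-geometry guards:
sphere/cylinder construction rejects non-positive radii, coincident
endpoints and sub-minimal tessellation; triangle areas are bounded away
from zero at 1e−9; the renderer skips triangles with |area| < 1e−12 in
screen space. Grid disjointness and label placement tolerances are exact
up to 1e−9.

## Known limitations

* Trivial-name coverage is the bundled dictionary only — no online
  lookup.
* No InChI input, 2D depiction, wedge/hash stereo rendering, or
  texture materials.
* The building-kit style approximates physical kits with overlapping
  spheres and sticks; it has no peg-and-hole connector detailing.
* The PNG renderer has no shadows, antialiasing or per-pixel z-buffer;
  painter's sorting can misorder mutually intersecting triangles in
  rare overlap configurations.
* FBX export and in-browser interactive viewing are out of scope.
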