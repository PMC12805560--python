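# molforge

Generate 3D molecular models from SMILES notation — as a **building
kit**, **ball-and-stick**, or **space-filling (CPK)** representation —
and export them in AR-capable and cross-platform 3D formats.

The tool targets chemistry education: teachers and students describe a
molecule by its SMILES string (or a common trivial name such as
`ethanol`), and get back a colored 3D model that can be dropped into an
augmented-reality viewer (USDZ on Apple devices), a game engine or web
viewer (glTF/GLB), a 3D printer toolchain (STL, OBJ), or a slide deck
(PNG). Batches of up to a few hundred molecules can be generated in one
run in a consistent visual style, laid out side by side and labeled with
their SMILES notation.

## How it works

SMILES encodes a molecule's connectivity — atoms, bond orders, rings,
branches — but no geometry. The pipeline is:

1. **Resolve & parse.** Trivial names are looked up in a small bundled
   offline dictionary; everything else is parsed as SMILES into a
   molecular graph. Aromatic rings are kekulized to alternating
   single/double bonds so the builders only draw discrete bond orders.
2. **Hydrogenate.** Explicit hydrogens are added until every atom
   reaches its standard valence (an *n*-carbon alkane becomes the
   familiar C*n*H*2n+2*, i.e. 3n+2 atoms and 3n+1 bonds).
3. **Embed.** 3D coordinates come from seeded ETKDG distance-geometry
   embedding. Because SMILES fixes no conformation, each seed yields one
   random plausible conformer — regenerating with `--random` shows
   students that chair/twist-boat rings and freely rotating chains have
   many spatial forms. A fixed `--seed` makes runs bit-reproducible.
4. **Build.** Atoms become UV spheres (CPK colors; Bondi van-der-Waals
   or Cordero covalent radii), bonds become capped cylinders; double and
   triple bonds are drawn as parallel sticks in the local bond plane.
   All primitives are watertight with outward-facing normals.
5. **Lay out & export.** Batches are arranged in a labeled grid
   (⌈√k⌉ columns, disjoint bounding boxes) and written as USDZ, glTF,
   GLB, a zip of per-molecule USDZ files, OBJ, binary STL, or a
   software-rendered PNG. All 3D formats are Y-up and scaled from
   Ångström to meters (default 0.02 m/Å ≈ tabletop size in AR).

## Worked example

```console
$ molforge generate "C1CCCCC1" --format glb -o cyclohexane.glb
C1CCCCC1: 18 atoms, ok
wrote cyclohexane.glb
```

The log line confirms cyclohexane parsed to 6 carbons + 12 added
hydrogens = 18 atoms; `cyclohexane.glb` contains the building-kit model
(the default representation) with its SMILES label.

```console
$ molforge generate "CCO, CO" --format usdz-zip -o batch.zip
CCO: 9 atoms, ok
CO: 6 atoms, ok
wrote batch.zip
```

Ethanol (9 atoms) and methanol (6 atoms) are generated side by side;
`batch.zip` contains `CCO.usdz` and `CO.usdz`, one AR-ready package per
molecule. Other useful invocations:

```sh
molforge generate "COC" --representations all --format png -o compare.png
molforge generate ethanol --style ball-and-stick --format usdz -o ethanol.usdz
molforge fixtures --count 100 --family mixed -o batch.csv
molforge generate --csv batch.csv --format glb -o batch.glb
```

`--representations all` renders one molecule as building-kit,
ball-and-stick, and space-filling models in a single row — all three
share the same conformer, so the representations line up exactly.

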