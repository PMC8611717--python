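# File formats

## Gaussian cube (read/write)

Standard layout: two comment lines; a line with the atom count and grid
origin (bohr); three lines with the voxel count and step vector of each
grid axis (bohr); one line per atom (atomic number, nuclear charge, x, y,
z in bohr); then the scalar values, up to six per line, x slowest / z
fastest. Values are written as `%13.5E` (6 significant figures).

A negative atom count — a dialect used by some generators to flag an
extra header line (e.g. orbital ids) between the atom block and the data —
is accepted; the extra line is skipped and the grid's `extra_header` flag
records it. Parse errors name the offending line.

## Structures (read)

* **XYZ**: atom count, comment/title line, then `symbol x y z` (Å).
  A declared count that mismatches the listed atoms is an error.
* **Minimal CML**: any XML document containing `atom` elements with
  `elementType` and `x3`/`y3`/`z3` attributes (Å); namespaces are
  ignored. No schema validation beyond this subset.

Element symbols are canonicalised (`CL` → `Cl`); unknown symbols are
errors.

## SSIP XML (read/write)

A minimal documented dialect (no namespaces):

```xml
<ssipMolecule title="water-like" surfaceArea="37.400000"
              ssipArea="9.350000" isoLevel="0.002">
  <atoms>
    <atom element="O" x="0.000000" y="0.000000" z="0.000000"/>
  </atoms>
  <ssips>
    <ssip x="1.044254" y="0.990209" z="0.951429" epsilon="3.886755"
          area="9.163000" meps="129.558513"/>
  </ssips>
</ssipMolecule>
```

Positions in Å, epsilon in (kJ mol⁻¹)^½, area in Ų, meps in kJ mol⁻¹;
all attributes written to six decimals, and the write→read round trip
preserves them to that precision. A `ssip` element without an `epsilon`
attribute is an error naming the element index.

## Phase tsv (read/write)

UTF-8, tab-separated, one phase per line; `#`-prefixed and blank lines
are ignored. The first column is the temperature in kelvin; each
subsequent pair of columns is a component name and its mole fraction:

```
298	water	1.0
298	water	0.75	ethanol	0.25
```

Mole fractions must each lie in (0, 1] and sum to 1 within 10⁻⁶; the
temperature must be positive; an odd number of trailing columns is an
error. All errors name the line.

## Solvent library directory

`components.tsv` with one line per component —
`name<TAB>molar_volume_L_per_mol<TAB>xml_filename` — plus the referenced
SSIP XML files in the same directory.

## FGIP exports

* **csv** (bit-exact round trip): two `#` comment lines carrying the phase
  descriptor and temperature; a header row `alpha\beta,<beta values>`;
  then one row per alpha value: `alpha,<ΔΔG values>`. Floats are written
  with `repr` precision, so reading recovers them exactly.
* **json**: object with keys `phase`, `temperature`, `alpha`, `beta`,
  `values` (row-major, rows indexed by alpha).
* **png**: filled-contour rendering (convenience only, not lossless).
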