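# specs-score

Superposition-based comparison of a predicted protein model against its
native structure, combining a GDT-style multi-threshold C&alpha; distance
component with side-chain distance and side-chain *orientation* components
computed in a united-residue (C&alpha; + side-chain centroid)
representation. The package also computes &chi;1 torsion angles and the
(normalized) angular RMSD between a model and a native.

## How the score works

Each residue is reduced to its C&alpha; atom and the centroid of its
side-chain heavy atoms. After pairing residues by identifier, a GDT-style
multi-superposition search over the paired C&alpha; atoms reports, for each
threshold (0.5 / 1 / 2 / 4 &Aring;), the largest number of residues
simultaneously superimposable within it; the mean fraction is the C&alpha;
component. A single reference superposition then carries the model
side-chains into the native frame, where each aligned pair yields the
centroid distance *r*, two planar angles &theta;&sup1;, &theta;&sup2;
(between each virtual C&alpha;&rarr;centroid bond and the inter-structure
centroid displacement), and a counterclockwise dihedral &Phi;. Each
side-chain quantity is scored over cumulative bins with linearly decaying
weights, and the total is

```
total = (4*dCA + rSC + theta1 + theta2 + phi) / 8
```

so main-chain and side-chain terms carry equal overall weight. All
components lie in [0, 1]; 1 means identity.

## Command line

```sh
# five components + total, with optional reports
specs score --model model.pdb --native native.pdb \
    [--per-residue] [--tsv scores.tsv] [--json report.json] \
    [--dihedral-bin7 {201,210}]

# chi1 torsion comparison: per-residue table + (normalized) angular RMSD
specs chi1 --model model.pdb --native native.pdb [--tsv t.tsv] [--json r.json]
```

Scores are printed to 4 decimals; the JSON report carries full precision,
the bin-occupancy profiles of every component and the chosen reference
superposition. `--dihedral-bin7` switches the seventh dihedral bin edge
between the uniform 210&deg; progression (default) and the 201&deg;
variant.

## Python API

```python
from specs import FixtureSpec, make_native, make_decoy, evaluate, compare_chi1

native = make_native(FixtureSpec(n_residues=40, gly_fraction=0.1, seed=7))
decoy = make_decoy(native, FixtureSpec(n_residues=40, ca_noise_sigma=0.8,
                                       sc_rotation_deg=45.0, seed=7))
components = evaluate(decoy, native)
print(components.dca, components.total)
```

`specs.synthetic_fixtures` generates deterministic PDB test structures
with controllable C&alpha; noise, side-chain rotation about an axis
through the C&alpha;, side-chain displacement, and two-domain
displacements — everything the test-suite scores is generated from code,
no downloads needed.

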