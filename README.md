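# ballcore

Composable building blocks for structural bioinformatics and molecular
modelling: a hierarchical molecular data model with processors and
expression-based selections, PDB/XYZ/MOL-SDF I/O, fragment-database structure
preparation (name normalization, hydrogen inference, bond building, residue
checking, rotamers), an AMBER-functional-form force field with analytic
gradients, energy minimizers (steepest descent, conjugate gradient, L-BFGS)
and velocity-Verlet dynamics with a randomized quick-optimizer, a peptide
builder driven by backbone torsions, a SMILES-subset reader, bond-order
perception with kekulization and aromaticity, and hydrogen-bond /
secondary-structure analysis.

## Library quick start

```python
from ballcore.build import build_peptide
from ballcore.prep import FragmentDatabase, check_residues
from ballcore.forcefield import AmberForceField
from ballcore.selection import apply_selection
from ballcore.optimize import MinimizerOptions, minimize_conjugate_gradient
from ballcore.analysis import assign_secondary_structure

db = FragmentDatabase()
system = build_peptide("AAAAAAAAAAAA", (-57.0, -47.0), db=db)   # alpha helix
print(check_residues(system, db).is_clean())                    # True
print(assign_secondary_structure(system).string())              # CHHHHHHHHHHC

ff = AmberForceField(db=db).setup(system)
apply_selection(system, "element(H)")     # only hydrogens move
result = minimize_conjugate_gradient(system, ff,
                                     MinimizerOptions(max_iterations=50))
print(result.final_energy)
```

The canonical preparation pipeline for an existing structure is:

```python
from ballcore.io import read_pdb
system = read_pdb("input.pdb")
system.apply(db.normalize_names)
system.apply(db.add_hydrogens)
system.apply(db.build_bonds)
report = check_residues(system, db)
```

## Command line

The `ballcore` entry point (or `python -m ballcore.cli`) provides:

```
ballcore convert IN OUT [--from FMT --to FMT]    # pdb/xyz/mol/sdf
ballcore prepare IN.pdb --out OUT.pdb            # full prep + H optimization
ballcore minimize IN.pdb --method {sd,cg,lbfgs} --select EXPR --out OUT.pdb
ballcore build-peptide SEQ --phi -57 --psi -47 --out OUT.pdb
ballcore assign-bonds IN.sdf --max-results K --out OUT.sdf
ballcore analyze IN.pdb --hbonds --ss [--out report.txt]
ballcore selftest
```

`prepare` reproduces the standard workflow: read, normalize atom names, add
missing hydrogens, build bonds, run the residue checker, set up the force
field, select hydrogens, and conjugate-gradient minimize for 50 iterations
with the energy logged every iteration. Selection expressions combine
predicates (`element(H)`, `name(CA)`, `residue(ALA)`, `chain(A)`,
`residueID(5-10)`, `backbone`, `all`) with `AND`/`OR`/`NOT` and parentheses.

## Bundled data

Plain-text data files under `src/ballcore/data/`:

- `fragments.txt` — self-authored reference templates for the 20 standard
  amino acids (+ water) in internal/n-terminal/c-terminal/free variants:
  atom names, elements, force-field types, partial charges, ideal internal
  coordinates, and bonds.
- `amber_params.txt` — a minimal AMBER-functional-form parameter set
  (stretch/bend/torsion/vdW tables, scale factors scee=1.2, scnb=2.0).
- `names.txt` — atom-name alias map; `rotamers.txt` — illustrative chi-angle
  rotamer library; `penalties.txt` — atomic valence penalties for bond-order
  assignment.

These are functional stand-ins with standard geometry and charge values, not
redistributions of any published parameter release.

## Tests and acceptance report

```sh
python -m pytest -q tests/          # full suite incl. tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the end-to-end property checks (analytic
gradient vs finite differences, analytic energy identities, minimizer
contracts, builder/secondary-structure round trip, bond-order oracle
equivalence, I/O round trips, MD conservation, and the preparation pipeline)
and writes the JSON report. There are no numeric literature targets to
reproduce, so the JSON object is empty; a non-zero exit signals a failed
check.
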