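# contactforge

Contact analysis for protein structures: a rotamer-based **contact degree**
(CD) metric, three classical distance-based contact definitions, statistical
contact potentials derived from any of them, decoy-discrimination statistics,
a hybrid metric that augments co-evolution scores (DCA direct information or
MetaPSICOV precision scores) with MSA-averaged contact-potential energies,
and an evaluation suite (PPV curves, separation-binned PPV, contact-map
diversity, per-contact decoy elimination).

## Contact definitions

| kind        | metric                                            | contact rule      |
|-------------|---------------------------------------------------|-------------------|
| `cd`        | probability-weighted fraction of allowed rotamer pairs whose side-chain heavy atoms come within 3 Å | value ≥ 0.1 |
| `any-heavy` | minimum heavy-atom distance (backbone included)   | value < 8 Å       |
| `cbeta`     | Cβ–Cβ distance (Cα for Gly)                       | value < 8 Å       |
| `centroid`  | side-chain centroid distance                      | value < 6 Å       |

The contact degree of a position pair enumerates, for every amino acid in
the rotamer library, every rotamer that does not clash with the backbone
(heavy-atom clearance 2 Å), and sums the normalized rotamer pair
probabilities of interfering placements. It is sequence-independent and can
be computed from backbone-only models; side chains are built from a bundled
ideal-geometry table by internal-coordinate placement.

Contact potentials use the log-odds form
`E(a,b) = -ln[ Nc(a,b) / ((1+I_ab) f(a) f(b) Nc) ]`
(zero under random redistribution of amino acids among contacts; an
alternative "as-printed" convention with `(1+I)` in the numerator is
available and differs by exactly `2 ln 2` on hetero cells).

The hybrid score for a scored column pair is `S' = S (1 - Ê / S_max)`, where
`Ê` is the contact-potential energy averaged over the alignment rows (or a
single randomly selected row) and `S_max` the maximum co-evolution score
after separation filtering.

## CLI

All pipelines are exposed through one entry point (`contactforge --help`):

```sh
# contact-degree map of a structure
contactforge cd --pdb protein.pdb --rotlib lib.txt --cutoff 0.1

# contact map under a distance definition
contactforge contacts --pdb protein.pdb --definition cbeta --min-separation 5

# derive a contact potential from a structure set
contactforge potential --pdb-list structures.txt --definition cd --rotlib lib.txt

# decoy discrimination
contactforge score-decoys --native n.pdb --decoys decoys/ --potential cp.csv
contactforge rank-stats --fixture itasser --friedman cd any_heavy

# hybrid co-evolution scoring and evaluation
contactforge hybrid --msa family.fasta --scores di.txt --potential cp-cd.csv
contactforge evaluate --ranked pairs.tsv --truth contacts.tsv --mode N --values 5,10,20
contactforge diversity --ranked pairs.tsv --length 120

# synthetic fixtures (toy backbones, databases, MSAs, decoys)
contactforge simulate --what msa --seed 7 --out-dir sim/
```

Rotamer libraries are read in the Dunbrack-2010 backbone-dependent text
format (`--rotlib-dialect dunbrack2010`) or in a simple whitespace fixture
dialect (`resname phi psi prob chi1..chi4`, `*` for backbone-independent
records). Potentials are CSV (`aa1,aa2,energy`, one unordered pair per
line). Score files are `i j score` triples with 1-based columns.

## Bundled data

* `src/contactforge/data/ideal_geometry.txt` — per-amino-acid side-chain
  internal coordinates used for rotamer placement.
* `src/contactforge/data/fixtures/table2_itasser_ranks.tsv`,
  `table3_rosetta_ranks.tsv` — native ranks of the 56-protein I-TASSER and
  59-protein Rosetta decoy benchmarks under the four contact potentials
  (load with `contactforge.decoys.load_rank_table_fixture`).

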