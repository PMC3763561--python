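# unskit

Design and in-silico verification of **UNS-addressed, hierarchical DNA
circuit assemblies** — a toolkit for synthetic biologists building
multi-transcription-unit (multi-TU) gene circuits on single vectors.

## The problem and the method

Large mammalian gene circuits (tens of kb, 5–12 transcription units)
are hard to build: mammalian promoters and genes are long, often
repetitive, and riddled with common restriction sites, so Type IIs or
PCR-heavy assembly strategies scale poorly. The framework implemented
here sidesteps sequence content entirely by giving every circuit
position its own **unique nucleotide sequence (UNS)**: a designed
40-bp address block.

Each TU lives on a circular *position vector* whose insert reads,
5′→3′: I-SceI site — UNS*n* — tandem insulator — promoter — gene —
polyA — UNS*n+1* — I-SceI site. Digestion with the 18-bp-site homing
endonuclease I-SceI (a site absent from mammalian cargo by rarity)
releases the TU flanked by its two addresses. In a one-pot isothermal
(Gibson) reaction, the exonuclease exposes the terminal UNSs as single
strands; complementary addresses anneal, so fragment order around the
final circle is dictated purely by the address pairs:

```
TU_i  ↦ (UNS_i, UNS_{i+1}),  i = 1..n
adaptor ↦ (UNS_{n+1}, UNSX)       carrier ↦ (UNSX → UNS1)
```

An n-TU circuit therefore needs n position vectors, one *adaptor*
(which also contributes a Kan or Tet marker, alternated between
rounds to select against parental vectors) and one *carrier*
(propagation elements plus UNS1 and UNSX). Because annealing happens
only at fragment *ends*, repeated promoters or genes inside fragments
cannot scramble the assembly. Assembled circuits carry an I-SceI site
upstream of UNS1 and — when closed with a hierarchical adaptor —
downstream of a hand-off address, so a finished circuit digests into
a position 1–2 part for the next round: assembly is re-entrant.

UNS design itself is an orthogonality problem. Candidates are uniform
random 40-mers filtered on GC (0.40–0.60), homopolymer runs (≤4),
nearest-neighbor duplex Tm (62–72 °C at 25 nM strands, 50 mM Na⁺),
hairpin stem length (≤5 nt with loop ≥3) and self-complementarity;
sets are chosen greedily to keep the worst pairwise cross-annealing
stretch ≤12 nt while intended pairings score the full 40.

## What the package provides

| module | role |
| --- | --- |
| `unskit.seqcore` | DNA strings, restriction enzymes, site finding, digestion |
| `unskit.uns_designer` | orthogonal 40-bp address design and validation |
| `unskit.parts_model` | position/carrier/adaptor anatomy + synthetic fixture libraries |
| `unskit.assembly_planner` | addressing, adaptor alternation, pooling arithmetic, sequence prediction |
| `unskit.gibson_simulator` | one-pot assembly simulation, ambiguity detection |
| `unskit.diagnostics` | restriction maps, diagnostic panel selection, colony screening stats |
| `unskit.cli` | `unskit` command-line tool binding it all together |

## Worked example

```python
from unskit import (make_fixture_library, plan_assembly, simulate_one_pot,
                    verify_junctions)
from unskit.assembly_planner import design_from_library

lib = make_fixture_library(rng_seed=1, n_tus=5)       # parts + UNS set + vectors
plan = plan_assembly(design_from_library(lib), lib.uns_set, lib)
print([r.flanks for r in plan.roster])
print(plan.adaptor.flanks, len(plan.predicted_sequence))

product = simulate_one_pot(plan.fragments)[0]
print(product.status, product.sequence.residues == plan.predicted_sequence.residues)
print(verify_junctions(product, lib.uns_set).passed)
```

prints

```
[('UNS1', 'UNS2'), ('UNS2', 'UNS3'), ('UNS3', 'UNS4'), ('UNS4', 'UNS5'), ('UNS5', 'UNS6')]
('UNS6', 'UNSX') 24227
unique_circular True
True
```

i.e. the five TUs are addressed with consecutive pairs 1–2 … 5–6, the
adaptor bridges 6–X, the planner predicts a 24,227-bp circle, and the
simulated one-pot reaction produces exactly that sequence as its
unique circular product with all seven junctions verified as clean
single-UNS joints.

The same pipeline from a shell:

```bash
unskit fixtures --seed 1 --n-tus 5 --out fx
unskit plan     --fixture fx --out fx/plan      # plan.json, predicted.gb, protocol.csv
unskit simulate --fixture fx --out fx/sim       # prints: status unique_circular
unskit screen --p 0.7 --k 2                     # P(all 2 colonies incorrect) = 0.0900
```

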