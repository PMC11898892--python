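# hgtscan

Screening and gene-tree topology classification for interkingdom horizontal
gene transfer (HGT) candidates in fungi.

Claims of horizontal gene transfer into eukaryotes — especially into the
filamentous fungi of the subphylum Pezizomycotina — usually rest on
phylogenetic anomalies: a fungal protein whose closest database matches are
bacterial or plant sequences. Most such anomalies have mundane
explanations. `hgtscan` turns the manual vetting procedure for these
candidates into an automated pipeline for phylogeneticists and comparative
genomicists:

1. **Screen** proteome-wide hit tables with a lineage probability index
   (LPI): the bitscore-weighted mean lineage overlap
   `LPI(q) = Σ_h b_h·overlap(q,h) / Σ_h b_h ∈ [0,1]`. A query is a
   candidate iff `LPI < 0.7` and its best hit lies outside the fungal
   kingdom.
2. **Classify** each candidate's unrooted gene tree by clan analysis
   (monophyly = one side of an edge bipartition) into four archetypes:
   **A** — a taxonomically narrow fungal patch nested among non-fungal
   homologs (HGT-compatible); **B** — a wide, cohesive fungal group
   (vertical descent); **C** — a sparse patch spanning multiple fungal phyla
   (ancient transfer or, more parsimoniously, ancestral presence plus
   loss); **D** — no fungal homolog besides the candidate (contamination
   suspect); plus UNINFORMATIVE for trees with too few leaves or donors.
3. **Triage** pattern-D candidates by the kingdoms of best hits of the
   genes flanking the candidate on its contig: an entirely non-fungal
   contig is presumed contamination.
4. **Map** accepted HGT calls to their minimum transfer node — the MRCA of
   the receptor species on a rooted species tree.

A seeded synthetic-data module generates taxonomies, gene trees, hit tables
and contig contexts with planted ground truth (self-verified at generation
time), including replication manifests that reproduce the published
composition of a 246-candidate de novo screen and a 275-candidate
literature set.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Run the combined replication (246 de novo + 275 literature candidates)
end-to-end — generate every gene tree, classify it, triage the no-fungal
cases, finalize calls and map transfers:

```
$ hgtscan replicate --preset combined --seed 1 --out report.json
[replicate] combined (seed 1): HGT=8, VERTICAL=377, ANCIENT_TRANSFER_OR_LOSS=31, CONTAMINATION=103, UNINFORMATIVE=2 -> report.json (0.8s)
```

Of 521 anomalous phylogenies, only 8 (1.5 %) survive as HGT: 377 show
vertical-descent topologies, 31 would require an ancient transfer followed
by massive loss, 103 are contamination (101 of them no-fungal de novo
candidates sitting on foreign contigs), and 2 are too sparse to call. The
report records per-candidate evidence and the transfer table:

```
$ python -c "import json; r=json.load(open('report.json')); print(r['percentages']['HGT']); print(r['transfers'][0])"
1.5
{'candidate_id': 'denovo-0001', 'n_receptors': 1, 'transfer_node': 'Pezizomycotina_o2f2g1_sp1'}
```

The single de novo HGT call is species-specific — its minimum transfer node
is a leaf of the species tree — while multi-receptor literature cases map
to internal nodes (genus/family-level taxa).

Each stage is also available separately (`hgtscan generate | screen |
classify | triage | map-transfers`; see `--help`) and as library functions
(`hgtscan.screen_candidates`, `hgtscan.classify_pattern`, …).

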