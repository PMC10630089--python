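# corona-evo

Evolutionary and proteomic analyses of the kinetochore **fibrous corona**
machinery — the RZZ-S complex (ROD / ZW10 / ZWILCH + SPINDLY) and the
kinesin-7 motor CENP-E — packaged as a tested, reusable Python library and
command-line tool.

## What it does

The fibrous corona is a transient protein meshwork that covers unattached
kinetochores in early mitosis. Its expansion depends on C-terminal
**farnesylation**: a CAAX box — operationally, a cysteine at offset −4 from
the C-terminus (terminal residue = −1) — marks the acceptor cysteine for the
farnesyl transfer. The package implements the four computational analyses
needed to study how this machinery evolved and what the farnesylated
C-terminus of CENP-E interacts with:

1. **`corona_evo.caax`** — fragment-aware CAAX-motif inference. Calls are
   three-state: *present* (C at −4 on a complete sequence), *absent*, or
   *unknown* for fragmentary predictions whose true terminus is unobserved.
   Includes a construct builder for truncation / alanine-scan / point-mutant
   / CAAX-swap panels (e.g. the 2111-C fragment of CENP-E, its 2,111–2,689
   truncation, C2698A, and the KRAS4b CIIM swap).
2. **`corona_evo.profiles`** — species × trait matrices over {1, 0, ?},
   co-occurrence (agreement and phi coefficient, unknowns excluded
   pairwise), and module coherence. Ships a ten-lineage eukaryote reference
   profile of the corona gene set.
3. **`corona_evo.ancestral`** — ancestral presence/absence reconstruction on
   a rooted species tree: exact Sankoff dynamic programming over {0, 1} with
   asymmetric gain/loss costs (unknown leaves as zero-cost wildcards,
   polytomies native) and Dollo parsimony (single gain, loss-minimal
   resolution, earliest/latest origin reporting).
4. **`corona_evo.proteomics`** — TurboID proximity-biotinylation
   differential enrichment: unique-peptide / replicate filtering,
   variance-stabilizing normalization by sample group, left-shifted Gaussian
   imputation for missing-not-at-random dropout, per-protein Welch (or
   pooled) tests, and volcano-style hit calling at log2 FC > 2 and
   −log10 p > 2.

A first-class synthetic-data module (`corona_evo.synthetic`) generates every
input with known ground truth: trait histories with exact event lists,
proteomes whose orthologs carry or lack CAAX boxes (including flagged
C-terminal fragments), and intensity tables with planted enrichment and
logistic MNAR dropout.

## Worked example

```python
from corona_evo.caax import (ProteinRecord, detect_caax, build_construct,
                             cenp_e_construct_specs, synthetic_cenp_e_parent)

parent = synthetic_cenp_e_parent(length=2701)   # synthetic stand-in ending CKTQ
call = detect_caax(ProteinRecord("fl", "Hsap", "CENP-E", parent, partial_flag=False))
print(call.acceptor_position_1based, call.acceptor_offset_from_C, call.motif)
# 2698 -4 CKTQ

specs = cenp_e_construct_specs()
mutant, report = build_construct(parent, specs["C2698A"])
print(report.length, detect_caax(mutant).state)
# 591 absent
```

Reconstructing CAAX-box evolution on the packaged eukaryote tree:

```python
from corona_evo import eukaryote_fixture_tree, sankoff_reconstruct, CostModel
from corona_evo.profiles import fixture_profile

tree = eukaryote_fixture_tree()
states = fixture_profile().matrix["CENP-E-CAAX"].to_dict()
result = sankoff_reconstruct(tree, states, CostModel(1, 1, "forced-0"))
print(result.n_gains, result.n_losses)
# 2 0
```

Two independent gains, no losses: the CAAX box on CENP-E arose separately in
the Opisthokonta/Apusozoa and the Stramenopila/Alveolata lineages.

The same stages are exposed on the command line:

```bash
corona-evo simulate-evolution --seed 1 --out scratch/evo
corona-evo simulate-proteomics --seed 1 --out scratch/prot
corona-evo scan-caax --fasta scratch/evo/proteome_Opisthokonta.fasta --out calls.tsv
corona-evo reconstruct --states states.tsv --mode dollo --out-events events.tsv
```

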