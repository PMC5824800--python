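# protocode

An agent-based simulator of how a genetic code can emerge in a population of
protocells purely through **horizontal transfer of code fragments** — no
replication, no selection, no vertical descent.

Each protocell carries a "black box" translation system: a 3-6-11
feed-forward perceptron that maps a codon (U=0, C=0.3, A=0.7, G=1 per base)
to a point in an 11-dimensional amino-acid chemical space. Repeatedly, a
random donor transmits 10 codon–amino-acid pairs — amino acids drawn by
cellular-abundance-weighted sampling without replacement, codons chosen by
the donor's *obverter* readout (the codon whose own decoding lands closest
to the target amino acid) — and a random receiver assimilates them by
backpropagation (500 presentations per transfer). Out of nothing but these
interactions, codes emerge that are expressive (up to all 20 amino acids),
error-robust (low Δ_code), increasingly universal (shrinking pairwise table
distance) and regular (simple/light/abundant amino acids claim more codons).

## Command-line interface

```bash
# a desk-scale run (full scale is --population 16 --transfers 100000 --runs 50)
protocode simulate --population 16 --transfers 2000 --runs 2 --seed 1 --out out/

# score any codon table file (TSV: codon <tab> amino_acid); 'Stop' rows are
# excluded from the measures
protocode score out/run_000/tables/protocell_00.tsv

# regularity report over the most robust code of each run
protocode analyze out/ --plot
```

`simulate` writes, per run: `metrics.tsv` (box-plot statistics of receiver
expressivity and Δ_code plus population universality, one row per recording
interval), the 16 final codon tables, the most robust table (`optimal.tsv`),
an optional JSON-lines transfer log (`--log-transfers`), and a resolved
`config.yaml` echo so every run directory is self-describing. Config
precedence: CLI flags > `--config` YAML > defaults.

## Key measures

- **expressivity** — distinct amino acids in a code (1–20).
- **Δ_code** — mean over codons of the mean squared polar-requirement
  difference to the amino acids of the 9 single-nucleotide neighbour
  codons; lower = more error-robust. The standard genetic code scores
  5.24 over its 61 sense codons (stops excluded as sources and as
  neighbour targets).
- **universality** — mean pairwise table distance (0–64) across the
  population.

## Package layout

| module | contents |
| --- | --- |
| `chemical_space` | 20 amino acids as 11-D vectors + polar requirement, mass, class, transfer weight; nearest-neighbour queries |
| `codon_space` | 64 codons, input encoding, single-nucleotide neighbourhoods, `CodonTable` + TSV/JSON round-trip |
| `translation_network` | the 3-6-11 logistic perceptron, init, forward, online backprop |
| `code_readout` | decode a network into a codon table; expressivity; obverter codon choice |
| `horizontal_transfer` | weighted fragment sampling, assimilation training, transfer records |
| `simulation` | population loop, RNG stream discipline, metrics series, checkpointing, replicates |
| `metrics` | Δ_code (configurable readings) and universality |
| `regularity` | optimal-code selection, per-class assignment counts, abundance/mass correlations |
| `sgc_reference` | the canonical standard genetic code and its baseline statistics |
| `cli` | `protocode simulate / score / analyze` |
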