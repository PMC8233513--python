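# clockshift

Lineage-specific substitution-rate analysis for phylogenetics:

* **Local-clock models** — maximum-likelihood node ages plus per-class branch
  rate multipliers (background class fixed at rate 1) under HKY with
  discrete-gamma among-site rate variation, fitted by Felsenstein pruning.
* **Rate-acceleration test** — compare a focal branch class between a focal
  locus (e.g. a promoter) and a reference locus (e.g. concatenated introns)
  fitted independently, with delta-method standard errors and two P-value
  conventions (a published normal-approximation formula with a 1.96 divisor,
  labeled "paper convention", and the standard one-sided z-test).
* **Ancestral reconstruction** — marginal (empirical-Bayes) posterior state
  distributions at every internal node under HKY+gamma.
* **M0 codon model** — single-ratio dN/dS estimation over the 61 sense
  codons with curvature-based standard errors.
* **Comparative methods** — Fitch parsimony counts of binary-trait changes,
  phylogenetic logistic regression (exponentially decaying working
  correlation in patristic distance), Pearson correlations on log scales,
  and a genome-wide expression/trait correlation screen with
  multiple-testing adjustment.
* **Simulator** — seeded sequence evolution along trees with branch-class
  rate multipliers (nucleotide and codon), latent-threshold binary traits
  with phylogenetic signal, and bundled 13-taxon primate / 29-taxon mammal
  fixture trees.

## Test

```bash
python -m pytest tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py`, which implements the acceptance criteria
(simulation-recovery studies run several minutes on one CPU).

## Command line

```bash
# simulate a promoter-like alignment on the bundled primate fixture
clockshift simulate --sites 690 --rate 1=0.53 --rate 2=0.35 --seed 1 --out out/promoter

# local-clock fit with branch rate classes taken from #k marks in the tree
clockshift fit-clock --aln promoter.fasta --tree tree.nwk

# two-locus acceleration test (all three P-value variants in the report)
clockshift accel --focal promoter.fasta --ref introns.fasta \
    --tree tree.nwk --labels labels.yaml --out report.json

# dN/dS under M0
clockshift dnds --aln cds.fasta --tree tree.nwk

# marginal ancestral reconstruction
clockshift ancestral --aln promoter.fasta --tree fitted.nwk --out anc.tsv

# comparative analyses on a trait table (TSV: species, expression_fpkm, ...)
clockshift fitch --tree mammals.nwk --traits traits.tsv --threshold 1.0
clockshift phyloglm --tree mammals.nwk --traits traits.tsv
clockshift screen --expr expr.tsv --traits traits.tsv --out ranked.tsv

# end-to-end demonstration on synthetic data
clockshift full-demo --seed 1 --outdir demo_out
```

Branch rate classes are written in Newick as `#k` (single branch) or `$k`
(whole clade), or supplied as YAML labeling rules:

```yaml
labels:
  - {class: 1, branch: [Rhesus_macaque, Green_monkey]}   # stem branch of that MRCA
  - {class: 2, mrca: [Gibbon, Human], include_stem: false}
```

Alignment columns are 0-based internally and 1-based in all reports and CLI
output. Gap/ambiguous characters are treated as missing data by default; a
strict mode (`Alignment.drop_ambiguous_columns`) drops affected columns.

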