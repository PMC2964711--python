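# mtn1a — mitochondrial haplogroup N1a phylogeography

Tools for the classic control-region workflow of human mtDNA
phylogeography, built around haplogroup **N1a** — the rare lineage cluster
famous for its presence in early Neolithic farmer remains from central
Europe.  The package is aimed at population geneticists who work with
published HVS-I/HVS-II haplotype tables and complete mitogenomes:

* **Mutation-motif nomenclature** — parse and emit the standard notation
  (`147A-172-189-193iC-223-248-320-355`: HVS-I minus 16000, base suffix =
  transversion, `d` = deletion, `iX` = insertion, `@` = back mutation),
  scored against an rCRS-like reference.
* **Subclade classification** — assign haplotypes to the finest N1a
  subclade (N1a1, N1a1a, N1a1a1, N1a1a1a, N1a1a2, N1a1a3, N1a1b) by a
  motif matching / near-matching strategy over a nested clade-definition
  tree (shipped as an editable YAML config).
* **Reduced median networks** — binary-recode haplotypes, compute the
  median closure, reduce weakly supported conflicts, and extract a rooted
  most-parsimonious tree with an outgroup.
* **ρ-statistic dating** — clade coalescence ages as ρ × (years per
  mutation) with the tree-structured standard error of Saillard et al.,
  σ² = Σ_edges (n_below/n)² · m_edge, under six packaged clock
  calibrations (all coding-region substitutions, or synonymous transitions
  only).
* **Heterogeneity statistics** — haplotype × origin contingency tables and
  the Pearson χ² test behind "center of expansion" arguments, plus
  regional frequency tables.
* **Ground-truth simulation** — clock genealogies with class-specific
  Poisson mutation counts, emitted as complete mitogenomes and as
  published-style motif tables, so every stage is testable offline.

The packaged reference (`data/synthetic_rcrs.fasta`) is a **synthetic**
stand-in with rCRS-like coordinates (16,569 nt, canonical gene map, poly-C
tracts); drop in the real rCRS via `load_reference(path)` for real-data
work — every coordinate convention is identical.

## Worked example

The packaged survey table transcribes 115 published N1a haplotype records
(166 mtDNAs).  Classify it and test the heterogeneity of the N1a1a1a
subclade:

```
$ mtn1a classify --input src/mtn1a/data/n1a_haplotypes.tsv --out-dir out
N1a     33      (cumulative 166)
...
N1a1a1  40      (cumulative 82)
N1a1a1a 42      (cumulative 42)
total 166; concordance with recorded labels 1.000

$ mtn1a heterogeneity --input src/mtn1a/data/n1a_haplotypes.tsv --out-dir out
n = 42; chi2 = 125.995; d.f. 81; p = 0.00102
```

Reading: the central subcluster N1a1a1 (including its inner subclade
N1a1a1a) accounts for 82 of the 166 sampled mtDNAs; the 42 N1a1a1a
genomes show significant haplotype heterogeneity across sampling origins
(10 distinct HVS-I haplotypes × 10 origin groups, χ² = 125.995 at 81
degrees of freedom), the signature of a center of expansion in the
Eurasian steppe belt.  Every assignment agrees with the label recorded in
the source table.

The dating stage, demonstrated on a simulated 19-genome dataset with the
study's clade sizes (`analysis/03_network_and_dating.py`):

```
  clade  n             a             b             c            b2             d             e
 N1a1a1 10 7,710 ± 2,355 6,915 ± 2,113 6,088 ± 2,620 6,885 ± 2,963 7,096 ± 3,053 7,191 ± 3,095
 N1a1a2  4 6,425 ± 2,873 5,762 ± 2,577 6,764 ± 3,382 7,650 ± 3,825 7,884 ± 3,942 7,990 ± 3,995
```

Columns a–e are the calibrations (years per coding substitution: 5,140 and
4,610; years per synonymous transition: 6,764, 7,650, 7,884, 7,990); each
cell is age ± SE in years, computed as ρ·rate ± σ·rate on the
network-extracted tree.

## Analysis drivers

Numbered scripts under `analysis/` rerun the full study pipeline and write
their tables to `results/`:

1. `01_classify_survey.py` — survey classification and headline counts
2. `02_heterogeneity.py` — the N1a1a1a χ² test and regional frequencies
3. `03_network_and_dating.py` — network, tree extraction and ρ ages on the
   simulated 19-genome fixture
4. `04_clock_calibration_check.py` — ρ ± 2σ coverage calibration on 1,000
   star genealogies

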