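# shellome

Characterization toolkit for shell matrix proteins (SMPs) — the proteins
occluded in the calcified shells of mollusks and recovered from decalcified
shell matrix extracts. Given protein sequences plus the standard predictor
outputs a shell-proteome study produces (domain annotations, signal-peptide /
transmembrane flags, phosphorylation-site probabilities, peptide-evidence
counts and lectin-assay plates), the package reproduces the downstream
sequence characterization such studies report:

* **Low-complexity region (LCR) detection** by sliding-window composition.
  Over every full window of *w* = 10 residues, criterion (i) flags a window
  for residue *X* when count(X) ≥ ⌈0.5 w⌉, and criterion (ii) flags it for an
  unordered pair {X, Y} when the most abundant residue X has count(X) ≥ ⌈0.4 w⌉
  and a second residue Y has count(Y) ≥ ⌈0.2 w⌉. Positions covered by flagged
  windows are unioned; maximal consecutive runs are trimmed at both ends to
  the enriched residue(s) and reported when they span > 14 (single) or > 19
  (pair) successive residues. Labels follow the `T-rich` / `GS-rich`
  convention. Poly-aspartate homopolymer runs are detected separately.
* **Physicochemical profiles**: average molecular weight, amino-acid
  composition, Asp+Glu fraction, and the theoretical isoelectric point — the
  unique zero of the Henderson–Hasselbalch net charge
  Q(pH) = Σ_b n_b/(1+10^(pH−pKa_b)) − Σ_a n_a/(1+10^(pKa_a−pH)),
  found by bisection with named pKa sets (`IPC_protein` default, `IPC_peptide`
  and `EMBOSS` as alternatives). A protein is called *acidic* when pI < 3.5
  and Asp+Glu > 20% (both strict).
* **Classification**: the two-peptide acceptance rule (> 1 distinct peptide in
  total across extracts), the four-extract presence partition
  (common-to-four / in-three / ASM-specific / AIM-specific / other), the
  three-way category scheme (conserved-domain, LCR-containing,
  uncharacterized) with sub-categories driven by a configurable
  accession → function catalog, and detection of the BMSP architecture
  (≥ 2 N-terminal VWA domains in tandem immediately followed by ≥ 1
  chitin-binding domain).
* **Phospho overlay**: thresholding per-residue phosphorylation probabilities
  (likely when p > 0.5) and quantifying their overlap with LCRs without
  double-counting sites under overlapping regions.
* **ELLA normalization**: enzyme-linked lectin assay plates are
  background-subtracted (mean of the no-lectin control), averaged per lectin
  and scaled so the strongest lectin reads 100%, with sample SD on the same
  percent scale.
* **Synthetic data**: a seeded generator plants single/pair LCR stretches,
  poly-Asp tails, domain annotations, evidence patterns, phospho tracks and
  lectin plates with known ground truth, so the whole pipeline is testable
  without any deposited raw data.

## Worked example

```python
from shellome import ProteinRecord, detect_lcrs, find_homopolymer_runs, profile

rec = ProteinRecord("demo", "MKT" + "GS" * 12 + "AQNVPL" * 6 + "D" * 18)

for r in detect_lcrs(rec):
    print(r.kind, r.label, r.start, r.end, r.length)
p = profile(rec)
print("MW", round(p.molecular_weight, 2), "pI", round(p.pI, 2),
      "D+E%", round(100 * p.asp_glu_fraction, 1), "acidic:", p.is_acidic)
print("poly-D runs:", [(r.start, r.end) for r in find_homopolymer_runs(rec, "D", 5)])
```

prints

```
pair GS-rich 4 27 24
single G-rich 4 26 23
single S-rich 5 27 23
single D-rich 64 81 18
MW 7915.98 pI 2.84 D+E% 22.2 acidic: True
poly-D runs: [(64, 81)]
```

The alternating GS stretch satisfies the pair criterion over its full 24
residues and, because each window also holds 50% G and 50% S, both single
criteria as well — single and pair regions are reported independently, each
trimmed to end on its own enriched residue. The aspartate tail is a D-rich
LCR and a poly-D homopolymer run; with 22.2% Asp+Glu and pI 2.84 the protein
is classified acidic.

The same stages are available from the shell:

```bash
shellome synth --outdir demo --n-proteins 4 --seed 2 --plant single:T:20 --plant pair:GS:24
shellome scan --fasta demo/proteins.faa --out demo/lcr.tsv
shellome profile --fasta demo/proteins.faa --out demo/profile.tsv
shellome run --fasta demo/proteins.faa --evidence demo/ev.csv \
    --phospho demo/sites.tsv --plate demo/plate.csv --outdir demo/run
```

`shellome run` writes a per-protein classification report (`classification.tsv`), per-stage TSVs
and a `summary.json` with category counts, presence-class counts, the acidic
protein list and every threshold used.

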