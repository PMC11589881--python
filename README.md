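# memtail

Analysis toolkit for the C-terminal transmembrane helices (cTMs) of
multispanning membrane proteins.

A TM can only be inserted cotranslationally by the Sec translocon once
roughly 45 further residues have been synthesised behind it — shorter
C-terminal tails leave the helix inside the ribosome exit tunnel when
translation ends, forcing **posttranslational** insertion by Oxa1-family
insertases (YidC in bacteria, EMC in the mammalian ER). These insertases
translocate only short, relatively hydrophobic flanking segments, which
constrains the C-tails of proteins with an extracytosolic C-terminus
(C_ext) to stay short and hydrophobic, while cytosolic-C-terminus (C_cyt)
proteins keep long hydrophilic tails that anchor them in the cytosol.
`memtail` implements the desk half of studying this constraint:

* **ΔG^app scoring** (`memtail.scale`) — per-residue apparent insertion
  free energies from the biological hydrophobicity scale (shipped as a
  versioned TSV); summed loop/tail hydrophilicity
  (`ΔG^app_tail = Σ_i ΔG^app(aa_i)`, positive = hydrophilic); windowed TM
  scoring and the minimal-ΔG scan within ±5–6 residues of an annotated TM
  centre.
* **Topology I/O and consensus** (`memtail.topology_io`,
  `memtail.consensus`) — TOPCONS-dialect topology strings and TM-segment
  tables from CCTOP/TMAlphaFold/PolyPhobius-style predictors, merged by
  agreement in TM count and core-residue position (14-residue window) with
  high/low quality labels and the priority rules CCTOP+TMAlphaFold >
  TMAlphaFold+PolyPhobius > PolyPhobius fallback.
* **C-tail classification** (`memtail.ctail`) — proteome filters (length
  18–10,000, ≥3 TMs, organelle exclusion lists), C_cyt/C_ext orientation
  by loop-side parity, and the <45-residue posttranslational rule.
* **Group statistics** (`memtail.group_stats`) — two-sided Mann–Whitney
  comparisons of tail length/hydrophilicity between orientation classes.
* **Stop-loss variants** (`memtail.variant_nonstop`) — extension of
  translation through a mutated stop codon to the next in-frame stop,
  re-classification of the extended tail, and misinsertion prediction for
  C_ext proteins whose extended tail crosses the insertase capacity
  threshold (ΔG^app ≈ 5–6 kcal/mol).
* **Insertion assay quantification** (`memtail.insertion_assay`) — the
  Cys-accessibility/PEGylation statistic
  `%insertion = 100·(1 − %PEG_AMS/%PEG_untreated)/(1 − %PEG_NEM/%PEG_untreated)`
  with densitometry calibration and replicate aggregation (mean ± SEM).
* **Synthetic data** (`memtail.synthetic_data`) — seeded generators for
  proteomes with ground-truth topology labels, discordant predictor
  outputs, CDSs carrying nonstop variants, and noisy gel quantifications.

## Worked example

```python
from memtail import (HydrophobicityScale, GelQuantification, percent_insertion,
                     NonstopVariant, apply_nonstop, TailProfile, classify_effect)

scale = HydrophobicityScale.default()
for ext in ["GSGS", "NNNN", "HSDS", "GPNFYVPFSNKTG"]:
    print(f"{ext:>14s}  dG_app = {scale.tail_hydrophilicity(ext):+.2f} kcal/mol")

wt = TailProfile(id="UbiA", tail_seq="WHF", tail_len=3,
                 tail_dg=scale.tail_hydrophilicity("WHF"),
                 orientation="C_ext", route="posttranslational",
                 penultimate_loop_dg=0.0, n_tail_dg=0.0)
for ext in ["GSGS", "NNNN"]:
    eff = classify_effect(wt, ext, scale=scale)
    print(f"WHF+{ext}: new tail dG {eff.new_tail_dg:+.2f}, route {eff.route_after}, "
          f"misinsertion predicted: {eff.misinsertion_flag}")

res = percent_insertion(GelQuantification("UbiA-C", peg_untreated=90,
                                          peg_nem=10, peg_ams=30))
print(f"%insertion = {res.percent_insertion:.1f}")

v = NonstopVariant("ATP6V0C-like", "ATGAAATAATTTTGA", hgvs_c="c.7T>C",
                   wt_protein_len=2)
ext = apply_nonstop(v)
print(f"extension {ext.extension_seq!r}, extended protein {ext.new_seq!r}")
```

prints

```
          GSGS  dG_app = +3.16 kcal/mol
          NNNN  dG_app = +8.20 kcal/mol
          HSDS  dG_app = +7.23 kcal/mol
 GPNFYVPFSNKTG  dG_app = +13.84 kcal/mol
WHF+GSGS: new tail dG +5.20, route posttranslational, misinsertion predicted: False
WHF+NNNN: new tail dG +10.24, route posttranslational, misinsertion predicted: True
%insertion = 75.0
extension 'QF', extended protein 'MKQF'
```

Reading: a GSGS extension of the UbiA tail stays below the ≈5–6 kcal/mol
capacity band of the YidC insertase while 4×N (like the similarly
hydrophilic HSDS, or the popular opsin tag) crosses it, predicting
misinsertion; a gel with 90/10/30 %PEGylation in the mock/NEM/AMS lanes
quantifies 75 % insertion; and the toy nonstop variant `c.7T>C` converts
the TAA stop to Gln, extending the protein by `QF` up to the next in-frame
stop.

## Command line

The same pipeline is scriptable as subcommands, each writing its
effective configuration next to its outputs:

```
memtail simulate  --seed 5 --out sim/
memtail consensus sim/proteome.fasta sim/segments.tsv --out cons/
memtail classify  sim/proteome.fasta cons/consensus.json --out cohort/
memtail nonstop   --variants variants.tsv --cohort cohort/cohort.tsv --out ns/
memtail insertion --bands bands.tsv --out ins/
```

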