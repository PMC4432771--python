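# protdescal

General-purpose numerical descriptors for protein sequences and 3D
structures, for anyone building machine-learning models on proteins —
function prediction, PTM-site classification, similarity ranking — who needs
a large, application-independent feature matrix rather than hand-crafted,
task-specific features.

## The model

A descriptor is produced by a four-level combinatorial pipeline. For each
protein:

1. **Index** — a per-residue value `L_i`: an amino-acid property scale
   (Kyte–Doolittle hydropathy `HP`, the `z1`–`z3` principal properties,
   Levitt's `Pa`/`Pb`/`Pt` preferences, isoelectric point, mass, or any
   user-loaded table), a contact-based topographic index, or a
   thermodynamic-style energy term.

   Topographic indices redefine classic whole-protein quantities at residue
   level. The weighted contact order is

   `wCO_i = (1/(2·N·N_c)) · Σ_{j≠i} ω_ij δ_ij`

   where `δ_ij = 1` iff the Cα–Cα distance is below `d` (default 8 Å) and
   the sequence separation `|i−j|` exceeds `t` (default 4), `N_c` is the
   contact count, and the weight `ω_ij` is 1, the sequence separation
   `ΔN_ij`, or a property product `ω_i·ω_j`. Summed over residues with
   `ω = ΔN` this recovers Plaxco's whole-protein contact order; `wLRO`,
   `wTCD`, `wNc` and the cliquishness `wCLQ` follow the same per-residue
   splitting rule.

2. **Weighting operator** — an optional neighbourhood transform of the
   vector `L` over sequence topology (`d_ij = |j−i|`): autocorrelation
   `AC_i^k = Σ_j L_i·L_j·δ(d_ij − k)`, plus Kier–Hall, electrotopological
   state, Ivanciuc–Balaban and gravitational-like operators.

3. **Group** — the residue subset aggregated over: one group per amino-acid
   type, physicochemical classes (polar, basic `BSC`, acidic, aromatic
   `ARM`, …), or structural groups — buried `INT` / exposed `SUP` at a
   relative-SASA cutoff (default 0.25), helix/sheet/turn (`HEX`/`SHT`/`TRN`)
   from explicit PDB records, coil `RCL`, and the whole protein `PRT`.

4. **Aggregator** — the statistic collapsing the group's values to one
   number: Minkowski norms `N1`–`N3`, central tendency (`AM`, `GM`, `HM`,
   quartiles, extremes), dispersion (`V`, `SD`, `CV`, `SK`, `RG`, `IQ`), and
   information content (`TIC`, `MIC`, `SIC`) over rounding-based value
   classes.

Every combination yields one named column — `HP_PRT_Q2` is the median (Q2)
Kyte–Doolittle hydropathy over the whole protein; `z1_AC2_GLY_Q2` is the
median over glycines of the `z1` scale after autocorrelation with `k = 2` —
so the output always has `|I|·|W|·|G|·|A|` columns. Descriptor relevance can
then be ranked by the Shannon entropy of each column's histogram across the
dataset, and inter-protein distance matrices computed from any descriptor
subset.

PDB input enables everything; FASTA input enables the sequence-based subset
(structure-dependent columns become `NA`).

## Worked example

```python
import pandas as pd
from protdescal import DescriptorCalculator, read_fasta

# demo.fasta: >prion_fragment HGGGWGQP / >lysozyme_nterm KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAK
models = read_fasta("demo.fasta")
calc = DescriptorCalculator(
    indices=["HP", "z1"],
    weightings=["none", "AC2"],
    groups=["PRT", "GLY", "CHG"],
    aggregators=["Q2", "AM"],
).fit()
frame = pd.DataFrame(calc.transform(models),
                     index=[m.id for m in models],
                     columns=calc.get_feature_names_out())
print(frame[["HP_PRT_Q2", "HP_CHG_AM", "z1_AC2_GLY_Q2"]].round(4))
```

prints

```
                HP_PRT_Q2  HP_CHG_AM  z1_AC2_GLY_Q2
prion_fragment      -0.65    -3.2000         3.6126
lysozyme_nterm      -0.40    -3.9333         1.5275
```

Both sequences have a hydrophilic median residue (negative `HP_PRT_Q2`); the
mean hydropathy over charged residues (`HP_CHG_AM`) is strongly negative, as
charged side chains are; and the glycine-neighbourhood autocorrelation of the
hydrophilicity scale `z1` separates the glycine-rich prion fragment from the
lysozyme fragment.

`DescriptorCalculator` is a scikit-learn transformer, so it drops into
`sklearn.pipeline.Pipeline`; `ShannonRelevanceFilter` is a matching feature
selector (`fit` computes `entropies_`, `transform` keeps informative
columns).

The same run from the shell:

```bash
protdescal run project.yaml           # writes <prefix>_AA.txt, <prefix>_Prot.txt
protdescal multi a.yaml b.yaml        # batch mode, failures isolated
protdescal relevance out_Prot.txt     # Shannon-entropy ranking
protdescal distmat out_Prot.txt --metric manhattan
protdescal fixtures --kind synthetic_helix --n 50 --seed 1 --out helix.pdb
```

`*_AA.txt` holds the per-residue index values (rows labelled
`<id>_aa<position>_<TYPE>`); `*_Prot.txt` holds the protein × descriptor
matrix, tab-delimited, with `NA` as the missing-value sentinel.

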