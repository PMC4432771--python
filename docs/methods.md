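# Methods

This note documents the models, conventions and deliberate design choices
behind protdescal, in the order the pipeline applies them.

## Protein models

A `ProteinModel` is an ordered list of residues with 1-based consecutive
positions; the original PDB `resSeq` is kept only as metadata. Parsing is
single-chain (first chain by default, selectable), first NMR model only.
MSE→MET and SEC→CYS are mapped; other nonstandard residues, and residues
lacking a Cα atom, are dropped with a logged warning. FASTA input produces
sequence-only models; letters outside the 20 standard types are dropped with
a warning so property lookups never see them.

Secondary structure is taken **only** from explicit HELIX/SHEET/TURN records
(HELIX wins on overlap, then SHEET, then TURN); nothing is recomputed from
geometry, so a PDB file without these records yields an all-coil model and
empty HEX/SHT/TRN groups by design.

## Solvent accessibility

SASA uses the Shrake–Rupley method: each atom's probe-inflated sphere
(probe 1.4 Å default) is sampled at 960 golden-spiral points; a point is
accessible when outside every other inflated sphere. Van der Waals radii are
by element (C 1.70, N 1.55, O 1.52, S 1.80 Å; 1.70 fallback).

Relative SASA divides the residue's summed atom area by a per-type
reference. For full-atom models this is a Tien-style theoretical maximum
table. For Cα-only models (all synthetic fixtures) those maxima would be
meaningless — a single sphere can never approach a full side chain's area —
so the reference is the isolated-sphere area 4π(r_C + probe)² instead.
Values are clipped to [0, 1].

## Contact maps and topographic indices

Contacts are between Cα atoms: `δ_ij = 1` iff distance < `d` (default 8 Å)
**and** `|i−j| > t` (default 4, strict). Weights `ω_ij` are 1, the sequence
separation, or a raw property product `ω_i·ω_j` (raw rather than normalised
scale values; normalisation would only rescale every descriptor built on
them). Residues without Cα join no contacts.

Per-residue topographic indices follow the half-share-per-pair-member
template, chosen so the summation identity is exact: with `ω ≡ 1`,
`Σ wLRO_i = N_c/N`, `Σ wTCD_i = Σ_contacts ΔN / N²`, `Σ wNc_i = 2·N_c`, and
with `ω = ΔN`, `Σ wCO_i` equals the classic whole-protein contact order.
These identities are asserted to 1e-12 relative in the tests. `wCLQ_i` is
the ω-weighted clustering coefficient of residue i's contact neighbourhood
(0 when the degree is below 2). A structure with zero contacts makes the
contact-normalised indices undefined; this raises by default, with a
`zero_on_degenerate` flag mapping it to all-zeros for batch robustness.

`lnFD_i` is the log of a per-residue folding-degree contribution: the mean
of `(1 + cos θ)/2` over the residue's available backbone dihedrals (φ/ψ on
full-atom models, the Cα pseudo-dihedral on traces), floored at a
configurable ε (default 1e-6) before the log. Downstream worked-example
tests use the *embedded printed* lnFD values as inputs, deliberately
decoupling them from this definition.

### Thermodynamic-style indices

The energy-like indices are documented surrogate forms, registered in a
pluggable table (`THERMO_REGISTRY`) so alternative parameterisations can be
swapped in without API changes; favourable contributions are negative:

- `Gc`: screened Coulomb over charged side chains (D/E −1, K/R +1, H +0.5),
  332·q_i·q_j·e^(−r/10 Å)/(40·r) kcal/mol on Cα positions, half per partner.
- `Gw`: 12-6 Lennard-Jones over Cα pairs (|i−j| ≥ 3, r ≤ 12 Å), well depth
  0.1 kcal/mol, contact radius 0.8·Mw^⅓ per residue type.
- `Ghb`: −1 kcal/mol per backbone O_i···N_j pair under 3.5 Å (|i−j| ≥ 3),
  half per partner; zero on Cα-only models.
- `Gtor`: threefold dihedral potential Σ [½(1+cos 3θ) − 1] over available
  backbone dihedrals.
- `Ghp`: hydropathy × buried fraction, `HP_i·(1 − relSASA_i)` — 0 when fully
  exposed, the full scale value when fully buried.
- Sequence-based analogues `Gc(U)`, `Ghp(U)`, `Gtor(U)` use scale lookups
  only (short-range charge products, sign-flipped hydropathy, and
  −ln max(Pα, Pβ, Pτ) as a conformational-entropy proxy).

## Weighting operators

All five operators act on sequence topology `d_ij = |j−i|` with truncated
(non-reflective) chain ends, matching the worked octapeptide example where
terminal residues sum a single product. Exact forms are in the `weighting`
module docstring. Inverse-square-root terms drop contributions with
|product| < 1e-12 — this avoids infinities from near-zero index values
without perturbing normal-scale ones. All operators are checked against
naive O(N²) loop references and are covariant under sequence reversal.

## Groups

Property classes are IUPAC-conventional and may overlap: HIS is in both
basic and aromatic; charged = basic ∪ acidic by construction. The INT/SUP
split uses a relative-SASA cutoff, default 0.25 (exposed ⇔ ≥ 0.25). Empty
groups are kept; their descriptors become the sentinel, keeping the table
rectangular across proteins.

## Aggregators

Population (not sample) variance and skewness — descriptor semantics, not
inference. Quartiles use linear interpolation between closest ranks.
GM drops signs and propagates zeros, keeping it defined for energy-like
negative indices. Information measures form equivalence classes by rounding
to `precision` decimals (default 6): TIC = n·log₂n − Σ n_g·log₂n_g,
MIC = Shannon entropy of class frequencies, SIC = MIC/log₂n. Degeneracies
(empty input, zero in HM, zero mean in CV, zero spread in SK, n = 1 in SIC,
and any float overflow/underflow) map to the sentinel (`NA` in files, NaN in
memory) and never raise. Input values are sorted internally before
aggregation: every operator is symmetric, and the canonical order makes
results bit-identical under input permutation despite floating-point
non-associativity.

## Engine

Descriptor names follow `<index>[_<op><k>]_<group>_<aggregator>`; the column
count is exactly |indices|·|weightings|·|groups|·|aggregators| and the
pipeline is deterministic given its configuration. Output numbers are
written in scientific notation with six significant digits — more than the
three the worked example prints, to support byte-exact regression tests.
Incompatible selections (structure-based index or group on FASTA input)
yield sentinel columns with a warning, or raise under `strict`.

Shannon relevance bins each descriptor into `n_bins` (default 20)
equal-width bins over its observed range and reports H = −Σ p·log₂p;
columns whose range is below the bin-edge float resolution count as
constant (H = 0). Distance matrices use only sentinel-free columns and
require at least one of them plus two proteins.

## Synthetic data

The generators emulate only the geometric features each test needs; none
emulates real protein chemistry, so passing tests demonstrate correctness of
the computations, not biological realism:

- **helix**: Cα on ideal α-helix geometry (rise 1.5 Å, 100°/residue, radius
  2.3 Å), HELIX-labelled, random sequence.
- **coil**: self-avoiding random walk, 3.8 Å bonds — a generic compact
  random topology for contact-map and contact-order identities.
- **cluster**: an all-ALA two-layer packing with a known buried core: core
  residues on a 3.4 Å cubic grid, shell layers on enclosing spheres at
  ~4 Å point spacing (outer overflow layers are offset radially by 6.5 Å so
  they cannot occlude inner ones). The construction guarantees the
  designated core falls below, and the shell above, the 0.25 relative-SASA
  cutoff for shell:core ratios of roughly 2.5:1 and up; much smaller shells
  cannot bury the core and are out of contract. ALA throughout so burial is
  judged against a uniform reference area.
- **octapeptide**: sequence HGGGWGQP with synthetic helical stand-in
  coordinates; the embedded per-residue lnFD values and their k = 2
  autocorrelation outputs are stored at their printed 3-significant-figure
  precision. Comparisons use relative tolerance 5e-3 (one unit in the third
  significant figure); position 5's stored output is truncated by one
  print-ulp relative to the recomputed product, so that position is compared
  at 1e-2.

All generators are seeded and byte-reproducible; generated PDB files
re-parse into equal models (within single-precision coordinate storage).

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: structures of 20–100
residues, 100-structure identity sweeps, 1000-vector property sweeps, and a
500-residue / ~1100-descriptor throughput check — sizes chosen so the whole
suite completes in seconds while still exercising every code path at
non-trivial N.

Known limitations: no mmCIF, no multi-chain or multi-model handling, no
DSSP-style secondary-structure recomputation, hydrogen atoms ignored, and
the thermodynamic index forms are surrogates (see above) rather than fitted
potentials. The cliquishness index is O(deg²) per residue and dominates cost
on dense contact graphs.
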