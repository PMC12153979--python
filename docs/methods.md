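# Methods

## The model

Amyloid nucleation is the rate-limiting step of fibril formation. By
transition-state theory the nucleation rate constant is

    k = A · exp(−ΔG‡ / RT)

with a pre-factor `A` treated as mutation-invariant, so a mutation's change
in the free energy of activation is

    ΔΔG‡ = R·T · ln(k_WT / k_mut)        (R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T = 303 K)

In a pooled selection whose cell growth rate tracks nucleation, the
WT-relative log enrichment of a variant (its relative growth rate, GR) is
linear in ΔΔG‡ — up to the upper and lower bounds of the assay. The package
therefore models the observable as a bounded, monotonically decreasing
sigmoid of an additive latent trait (global epistasis):

    GR(v) = L + (U − L) / (1 + exp(φ(v))),   φ(v) = Σᵢ θᵢ xᵢ(v) + Σᵢⱼ θᵢⱼ xᵢⱼ(v)

where `x(v)` is a binary encoding of the variant's amino-acid substitutions
(and, at order 2, substitution pairs), `θᵢ` are per-mutation activation-energy
terms and `θᵢⱼ` are pairwise energetic couplings (ΔΔΔG‡): the deviation of a
double mutant's energy from the sum of its singles. Fitting minimizes the
inverse-variance weighted squared error plus an elastic-net penalty
λ(‖θ‖₁ + ‖θ‖₂²), λ = 10⁻⁵ by default.

Downstream, calibrated ΔΔG‡ maps are compared with per-polymorph fibril
stability changes (ΔΔG) through phi-like ratios R = ΔΔG‡/ΔΔG, and couplings
are aggregated per position pair (interaction score = mean |ΔΔΔG‡|) and
rank-correlated against inverse minimal side-chain heavy-atom distances
(scHA_min) in fibril structures.

## Identifiability and numerical choices

- **Sigmoid scale.** `g` is parameterized with learnable bounds `L`, `U` and
  a trait scale fixed at 1. A free scale multiplies φ and divides θ exactly,
  so it is not identifiable; absolute units come from the kinetic
  calibration instead (below).
- **Early stopping.** The L-BFGS-B fits are capped at 2000 iterations
  (`energy_model.MAX_ITER`). For variants saturated at the assay's
  growth-rate floor the loss is nearly flat in their energy terms, and
  counting noise that lands just below the fitted floor rewards arbitrarily
  large terms; running the optimizer to full convergence inflates those
  unidentifiable terms while changing the well-identified ones by nothing.
  The cap acts as early stopping — the same implicit regularization that
  neural-network trainers for this model class rely on. Well-identified
  terms are fully converged long before the cap.
- **L1 at zero.** The L1 penalty uses the smooth surrogate
  |t| ≈ √(t² + 10⁻¹²), keeping the objective differentiable.
- **Multi-start.** The final fit uses 3 optimizer starts (zero terms plus
  jittered restarts); each cross-validation fold restarts from the full-data
  optimum.
- **Per-term standard errors** are across-fold standard deviations of the
  term estimates from 10-fold cross-validation; the Z-test and
  Benjamini-Hochberg FDR (q < 0.05) classify terms as increasing or
  decreasing ΔΔG‡. This across-fold SE is an approximation, documented as
  such: it reflects estimation variability, not a full posterior.
- **Spearman p-values** use the t-approximation for n ≥ 10 and exact
  permutation enumeration below.
- **Percentile threshold** for top interacting pairs uses linear
  interpolation; ties at the threshold are all kept.

## Calibration

Trait-unit terms are converted to kcal/mol by regressing the model's trait
values on ΔΔG‡ derived from published in vitro nucleation rate constants
(secondary-nucleation rates by default; primary behind a flag) and dividing
every term by the slope. Multiplicative rate terms (elongation × nucleation)
may be used directly: a mutation-invariant elongation factor cancels in the
WT/variant ratio — an assumption that fails if a mutation alters elongation.
Combinatorial-library fits are anchored by an artificial reference genotype
(GR = 0, σ = 100) because the selected pools lack WT; their energy scale is
then mapped onto the double-mutant scale by an affine regression over shared
terms (slope and intercept applied to every combinatorial term).

## Structure analysis

scHA_min between two residues is the minimum Euclidean distance over all
pairs of heavy (non-hydrogen) side-chain atoms, one from each residue; side
chain means atoms beyond and including Cβ, and glycine contributes its Cα.
Contacts use a strict 8 Å threshold. Monomer mode computes within-chain
distances; dimer mode takes, for positions (i, j), the minimum over both
cross-chain assignments of two facing chains. Deposited fibril structures
that start mid-sequence are realigned with an explicit residue-number
offset, never inferred. For disordered atoms the parser's selected
(highest-occupancy) conformer is used; residues lacking all designated atoms
are flagged and excluded from matrices rather than silently dropped.

## Ratio analysis

Per-polymorph assembly ΔΔG values (computed externally on stacked
single-filament tetramers, trimer for one polymorph) are divided by the
chain count to per-monomer values and filtered to moderate effects,
0.6 < |ΔΔG| < 10 kcal/mol: below the lower bound a ratio is noise-dominated,
above the upper bound the mutation likely remodels the fibril itself. The
absolute-value form of the filter is a deliberate choice (stabilizing
mutations contribute ratios too); ratios are computed per mutation and then
averaged per position, not as a ratio of means. Polymorphs are ranked by the
RMSD of their (optionally region-masked) ratios to 1.

## The synthetic generator

The generator emulates the study conditions end to end so that every stage
is testable without downloads:

- **Landscapes.** First-order effects follow a three-part mixture chosen to
  mirror the observed sign split: 72% destabilizing (Gamma(2, 0.6) kcal/mol,
  mean 1.2), 14% accelerating (−Gamma(2, 0.25)), the rest near zero
  (N(0, 0.05)). Couplings are Bernoulli-sparse with heavy-tailed
  (Student-t₃ × 0.6) magnitudes, so most are small and a few are strong.
- **Growth map.** Decreasing sigmoid with L = −4, U = 0, scale 1, centered
  so WT maps to 0 (centered range ±2, matching the order of magnitude of
  WT-relative log enrichments in such selections).
- **Selections.** One effective growth round: the library composition is a
  log-normal draw (σ = 0.5) shared across three replicates; input counts are
  multinomial at the chosen depth and output counts multinomial with weights
  ∝ composition × exp(GR), with optional per-variant log-normal
  overdispersion (off by default in oracle tests). The real assay's plating
  and colony-formation steps are collapsed into this exponential form, which
  is exactly the log-linearity the enrichment stage assumes — passing
  recovery tests therefore validates the inference chain, not the biology of
  colony formation.
- **Scaled designs.** Recovery experiments simulate all single mutants plus
  a random subset of doubles per scan (2000/1200/1200 for the full-length,
  N-terminal and C-terminal scans) at 150 reads/variant, and ~3000
  combinatorial genotypes — sizes chosen so a full recovery run takes
  minutes on one CPU while every substitution is still observed in multiple
  backgrounds.
- **Stability surrogate.** Per-mutation stability tables with a configurable
  correlation to ΔΔG‡ inside a designated region (emulating agreement in the
  C-terminal aggregation-prone region and disagreement elsewhere); this is a
  synthetic stand-in consumed through the same interface as externally
  computed tables, not a physical model.
- **Structure fixtures.** Minimal PDB text from explicit residue/atom specs,
  or an idealized serpentine (snaking) fold whose sequence neighbours and
  cross-row neighbours form side-chain contacts — fibril-like in its contact
  statistics but not a real fold. Glycines are emitted Cα-only.

What the generator does **not** emulate: sequencing error and read-level
processing, codon-level synonymous structure (beyond WT-synonym tags),
overdispersion between biological replicates (available but off by default),
and any real fibril geometry. Passing tests show the inference chain is
correct under its own assumptions; they are not evidence about real data.

## Known limitations

- Mutations whose true ΔΔG‡ exceeds the assay's dynamic range (trait beyond
  ≈ ±3 at the default sigmoid) are censored: their terms are bounded below
  by the floor but not identified, which caps achievable recovery
  correlations.
- The error model is Poisson counting plus a 0.5 pseudocount; replicate
  overdispersion beyond counting noise is not learned.
- Couplings are pairwise only; no third-order terms.
- The PDB reader handles ATOM records of standard residues; mmCIF and
  modified residues are out of scope.
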